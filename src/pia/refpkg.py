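"""Reference packages: the bundled unit one gene family is annotated against.

A package directory holds the family's bait proteins (``baits.faa``),
the fixed reference alignment (``ref.aln.faa``), the reference tree with
dense ``{N}`` edge tags (``ref.nwk``), the landmark table
(``landmarks.tsv``) and a ``manifest.json`` recording the model,
creation parameters and per-file MD5 checksums. Building a package from
captured family sequences involves dereplication, long-branch pruning
and branch-length re-optimization on a user-supplied topology; topology
search itself is out of scope — trees come from any external tool.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from statistics import median

from .annotate import LandmarkMap
from .model import SubstitutionModel, optimize_branch, pruning_loglik
from .profilealn import Alignment
from .seqs import ProteinSequence, read_fasta, write_fasta
from .tree import Tree

MANIFEST = "manifest.json"
FILES = {"baits": "baits.faa", "alignment": "ref.aln.faa",
         "tree": "ref.nwk", "landmarks": "landmarks.tsv"}


class RefPkgError(ValueError):
    pass


@dataclass
class ReferencePackage:
    family: str
    baits: list[ProteinSequence]
    ref_alignment: Alignment
    tree: Tree
    landmarks: LandmarkMap
    model: SubstitutionModel
    manifest: dict = field(default_factory=dict)

    def validate(self) -> list[str]:
        """Raise RefPkgError on structural problems; return warnings."""
        tips = set(self.tree.tip_names())
        rows = set(self.ref_alignment.rows)
        if tips != rows:
            raise RefPkgError(
                f"tree/alignment mismatch in family {self.family!r}: "
                f"tips-only {sorted(tips - rows)}, rows-only {sorted(rows - tips)}")
        if not self.baits:
            raise RefPkgError(f"family {self.family!r} has no baits")
        return self.landmarks.validate(self.tree)


def dereplicate(seqs: list[ProteinSequence], identity_threshold: float = 1.0):
    """Greedy longest-first dereplication.

    At threshold 1.0, removes exact duplicates and exact substrings of a
    longer retained sequence. Below 1.0, a sequence is removed when its
    best ungapped identity to a retained representative — matches at the
    best sliding offset divided by the shorter length — reaches the
    threshold. Returns (retained, removal_log) where the log maps each
    removed id to its representative.
    """
    if not seqs:
        raise ValueError("no sequences to dereplicate")
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity threshold must be in (0, 1]")
    order = sorted(seqs, key=lambda s: (-len(s), s.id))
    retained: list[ProteinSequence] = []
    log: dict[str, str] = {}
    for s in order:
        rep = None
        for r in retained:
            if identity_threshold >= 1.0:
                if s.residues in r.residues:
                    rep = r
                    break
            else:
                if _ungapped_identity(s.residues, r.residues) >= identity_threshold:
                    rep = r
                    break
        if rep is None:
            retained.append(s)
        else:
            log[s.id] = rep.id
    retained.sort(key=lambda s: s.id)
    return retained, log


def _ungapped_identity(a: str, b: str) -> float:
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    if not short:
        return 0.0
    best = 0
    for off in range(len(long_) - len(short) + 1):
        matches = sum(1 for x, y in zip(short, long_[off:off + len(short)]) if x == y)
        best = max(best, matches)
    return best / len(short)


def prune_long_branches(tree: Tree, aln: Alignment | None = None,
                        factor: float = 10.0):
    """Iteratively drop tips on terminal branches > factor x median.

    The longest offender is removed first and the median recomputed
    after each removal; iteration stops when no terminal branch exceeds
    the threshold or only 3 tips remain. Alignment rows are dropped in
    sync. Returns (tree, alignment, removal_log).
    """
    if factor <= 1:
        raise ValueError("factor must be > 1")
    if tree.n_tips < 4:
        raise ValueError("tree must have at least 4 tips to prune")
    tree = tree.copy()
    log = []
    while tree.n_tips > 3:
        terms = tree.terminal_branch_lengths()
        med = median(terms.values())
        over = [(l, name) for name, l in terms.items() if l > factor * med]
        if not over:
            break
        l, name = max(over)
        tree.prune_tip(name)
        log.append({"tip": name, "length": l, "median": med})
        if aln is not None:
            aln = aln.drop_row(name)
    return tree, aln, log


def reoptimize_branch_lengths(tree: Tree, aln: Alignment,
                              model: SubstitutionModel, sweeps: int = 3,
                              converge: float = 1e-4):
    """Per-edge branch-length sweeps on a fixed topology.

    Each sweep optimizes every edge in turn with ``optimize_branch``;
    the log-likelihood is non-decreasing across every step. Stops after
    ``sweeps`` sweeps or when a full sweep improves it by < ``converge``.
    Returns (tree, final_logL, logL_trace).
    """
    tree = tree.copy()
    trace = [pruning_loglik(tree, aln, model)]
    for _ in range(sweeps):
        before = trace[-1]
        for edge_id in sorted(tree.edges()):
            _, ll = optimize_branch(tree, edge_id, aln, model)
            if ll < trace[-1] - 1e-9:
                raise AssertionError("likelihood decreased during optimization")
            trace.append(ll)
        if trace[-1] - before < converge:
            break
    return tree, trace[-1], trace


def _md5(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def write_refpkg(pkg: ReferencePackage, directory) -> Path:
    pkg.validate()
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_fasta(pkg.baits, d / FILES["baits"])
    pkg.ref_alignment.to_fasta(d / FILES["alignment"])
    (d / FILES["tree"]).write_text(pkg.tree.to_newick(edge_tags=True) + "\n")
    pkg.landmarks.to_tsv(d / FILES["landmarks"])
    manifest = {
        "format_version": 1,
        "family": pkg.family,
        "model": pkg.model.to_dict(),
        "files": {k: v for k, v in FILES.items()},
        "checksums": {k: _md5(d / v) for k, v in FILES.items()},
        **({"parameters": pkg.manifest} if pkg.manifest else {}),
    }
    (d / MANIFEST).write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return d


def read_refpkg(directory) -> ReferencePackage:
    d = Path(directory)
    mpath = d / MANIFEST
    if not mpath.exists():
        raise RefPkgError(f"{d}: missing {MANIFEST}")
    manifest = json.loads(mpath.read_text())
    for key, fname in manifest.get("files", FILES).items():
        if not (d / fname).exists():
            raise RefPkgError(f"{d}: manifest field {key!r} references missing "
                              f"file {fname!r}")
        want = manifest.get("checksums", {}).get(key)
        if want and _md5(d / fname) != want:
            raise RefPkgError(f"{d}: checksum mismatch for field {key!r} ({fname})")
    files = manifest.get("files", FILES)
    pkg = ReferencePackage(
        family=manifest["family"],
        baits=read_fasta(d / files["baits"], alphabet="prot"),
        ref_alignment=Alignment.from_fasta(d / files["alignment"]),
        tree=Tree.from_newick((d / files["tree"]).read_text()),
        landmarks=LandmarkMap.from_tsv(d / files["landmarks"]),
        model=SubstitutionModel.from_dict(manifest.get("model", {})),
        manifest=manifest.get("parameters", {}),
    )
    pkg.validate()
    return pkg
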