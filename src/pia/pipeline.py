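"""End-to-end annotation runs: ORFs -> search -> align -> place -> report.

Each (transcriptome, family package) pair is processed independently and
deterministically: candidate ORFs are extracted, screened against the
family baits with the E-value gate and top-k retention, added one by
one to the fixed reference alignment, placed on the reference tree, and
classified against the landmarks. Outputs per family are a jplace
document and a tagged Newick tree; across families and samples the run
emits a flat annotation TSV, a family x sample presence matrix, a run
manifest with per-stage counts, and a log. Re-running an identical
configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .annotate import classify_query, presence_matrix, tag_tree
from .placement import (PlacementEngine, epa_place, graft_placements,
                        write_jplace)
from .profilealn import add_to_alignment, mask_query_to_ref
from .refpkg import read_refpkg
from .search import ScoringScheme, search_family
from .seqs import (ProteinSequence, orf_protein, query_label, read_fasta,
                   six_frame_orfs)

log = logging.getLogger("pia")


@dataclass
class RunConfig:
    transcriptomes: list  # FASTA paths
    packages: list        # reference package directories
    out_dir: str = "pia_out"
    input_type: str = "nuc"  # "nuc" (translate 6 frames) or "prot"
    min_orf_aa: int = 30
    evalue_cutoff: float = 1e-20
    top_k: int = 3
    keep_placements: int | None = None  # None = all edges in jplace
    pendant_max: float | None = None    # None = 2x median terminal branch
    seed: int = 0

    def __post_init__(self):
        if self.min_orf_aa < 1 or self.top_k < 1 or self.evalue_cutoff <= 0:
            raise ValueError("thresholds must be positive")


def validate_inputs(config: RunConfig) -> list[str]:
    """Blocking issues with the configuration; empty means runnable."""
    issues = []
    if not config.transcriptomes:
        issues.append("no transcriptomes given")
    for t in config.transcriptomes:
        if not Path(t).exists():
            issues.append(f"transcriptome file missing: {t}")
    if not config.packages:
        issues.append("no reference packages given")
    for p in config.packages:
        if not Path(p).is_dir():
            issues.append(f"package directory missing: {p}")
            continue
        try:
            read_refpkg(p)
        except Exception as e:
            issues.append(f"package {p} invalid: {e}")
    try:
        RunConfig(**vars(config))
    except ValueError as e:
        issues.append(str(e))
    return issues


def _sample_name(path) -> str:
    return Path(path).stem


def _candidate_proteins(path, config: RunConfig):
    """(ProteinSequence, transcript_id, orf_index) candidates of one sample."""
    out = []
    if config.input_type == "nuc":
        for seq in read_fasta(path, alphabet="nuc"):
            for orf in six_frame_orfs(seq, min_aa=config.min_orf_aa):
                out.append((orf_protein(orf), orf.transcript_id, orf.orf_index))
    else:
        for seq in read_fasta(path, alphabet="prot"):
            out.append((ProteinSequence(seq.id + "_ORF1", seq.residues), seq.id, 1))
    return out


def run_pia(config: RunConfig) -> Path:
    """Run the full pipeline; returns the output directory."""
    issues = validate_inputs(config)
    if issues:
        raise ValueError("invalid inputs:\n  " + "\n  ".join(issues))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "run.log", mode="w")
    log.addHandler(fh)
    scheme = ScoringScheme()
    packages = sorted((read_refpkg(p) for p in config.packages),
                      key=lambda p: p.family)
    stage_counts = {}
    records_by_sample = {}
    ann_rows = []
    try:
        for tpath in sorted(config.transcriptomes, key=_sample_name):
            sample = _sample_name(tpath)
            cands = _candidate_proteins(tpath, config)
            log.info("sample %s: %d candidate ORFs (min %d aa)",
                     sample, len(cands), config.min_orf_aa)
            records = []
            for pkg in packages:
                fam = pkg.family
                key = f"{sample}/{fam}"
                try:
                    by_id = {c[0].id: c for c in cands}
                    hits = search_family([c[0] for c in cands], pkg, scheme,
                                         evalue_cutoff=config.evalue_cutoff,
                                         top_k=config.top_k)
                    engine = PlacementEngine(pkg.tree, pkg.ref_alignment,
                                             pkg.model) if hits else None
                    placements = {}
                    fam_records = []
                    for hit in hits:
                        prot, tid, oi = by_id[hit.query_id]
                        label = query_label(fam, tid, oi)
                        ext = add_to_alignment(pkg.ref_alignment,
                                               ProteinSequence(label, prot.residues),
                                               scheme)
                        masked = mask_query_to_ref(ext, label)
                        ps = epa_place(engine, label, masked,
                                       keep=config.keep_placements)
                        placements[label] = ps
                        rec = classify_query(ps[0], pkg.landmarks, pkg.tree,
                                             family=fam,
                                             pendant_max=config.pendant_max)
                        fam_records.append(rec)
                    write_jplace(placements, pkg.tree,
                                 out / f"{sample}.{fam}.jplace")
                    display = graft_placements(pkg.tree, placements)
                    tagged = tag_tree(display, pkg.landmarks,
                                      sorted(placements))
                    (out / f"{sample}.{fam}.tagged.nwk").write_text(
                        tagged + "\n")
                    stage_counts[key] = {"orfs": len(cands), "hits": len(hits),
                                         "placed": len(placements),
                                         "records": len(fam_records)}
                    records.extend(fam_records)
                    log.info("%s: %d hits passed (E<=%.3g, top %d), %d placed",
                             key, len(hits), config.evalue_cutoff,
                             config.top_k, len(placements))
                except Exception as e:
                    raise RuntimeError(
                        f"stage failure in {key}: {e}") from e
            records_by_sample[sample] = records
            for r in sorted(records, key=lambda r: (r.family, r.query_id)):
                ann_rows.append(r)
    finally:
        log.removeHandler(fh)
        fh.close()

    ann_path = out / "annotations.tsv"
    with open(ann_path, "w") as f:
        f.write("query_id\tfamily\tbest_edge\tbest_lwr\tpendant_length\t"
                "nearest_LANDMARK1\tdist_LANDMARK1\tnearest_LANDMARK2\t"
                "dist_LANDMARK2\tflag\n")
        for r in ann_rows:
            f.write("\t".join([
                r.query_id, r.family, str(r.best_edge_id),
                f"{r.best_lwr:.6f}", f"{r.pendant_length:.6f}",
                r.nearest_l1 or ".",
                f"{r.nearest_l1_dist:.6f}" if r.nearest_l1_dist is not None else ".",
                r.nearest_l2 or ".",
                f"{r.nearest_l2_dist:.6f}" if r.nearest_l2_dist is not None else ".",
                r.flag]) + "\n")

    mat = presence_matrix(records_by_sample) if records_by_sample else None
    if mat is not None:
        all_fams = sorted({p.family for p in packages})
        mat = mat.reindex(all_fams, fill_value=0)
        mat.to_csv(out / "presence_matrix.tsv", sep="\t")

    manifest = {
        "pia_version": __version__,
        "config": {k: (list(map(str, v)) if isinstance(v, list) else v)
                   for k, v in vars(config).items()},
        "stage_counts": stage_counts,
    }
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return out
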