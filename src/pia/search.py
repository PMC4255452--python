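"""Candidate-family search: local protein alignment plus E-value gating.

Each translated ORF is scored against every bait of a family by optimal
Smith-Waterman local alignment with affine gaps (BLOSUM62, gap open -11 /
extend -1 by default), and the raw score is converted to an E-value with
the Karlin-Altschul formula ``E = K * m * n * exp(-lambda * S)`` using
the standard gapped blastp constants lambda = 0.267, K = 0.041. ORFs are
kept when their best-bait E-value passes the cutoff (default 1e-20) and
at most ``top_k`` (default 3) survivors are retained per family.

Gap convention: ``gap_open`` is the score of the first gap residue and
``gap_extend`` of each subsequent one, so a gap of length k scores
``gap_open + (k-1)*gap_extend``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio.Align import PairwiseAligner, substitution_matrices

from .seqs import ProteinSequence


@dataclass
class ScoringScheme:
    matrix_name: str = "BLOSUM62"
    gap_open: int = -11
    gap_extend: int = -1
    lambda_: float = 0.267
    K: float = 0.041

    def __post_init__(self):
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")
        if self.lambda_ <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")
        self.matrix = substitution_matrices.load(self.matrix_name)

    def aligner(self) -> PairwiseAligner:
        a = PairwiseAligner(mode="local")
        a.substitution_matrix = self.matrix
        a.open_gap_score = self.gap_open
        a.extend_gap_score = self.gap_extend
        return a


@dataclass(frozen=True)
class Hit:
    query_id: str
    family_id: str
    bait_id: str
    raw_score: int
    bitscore: float
    evalue: float
    q_start: int = 0
    q_end: int = 0
    b_start: int = 0
    b_end: int = 0


def local_align(query: ProteinSequence, target: ProteinSequence,
                s: ScoringScheme | None = None):
    """Optimal affine-gap local alignment.

    Returns ``(raw_score, (q_start, q_end, t_start, t_end), (aln_q, aln_t))``
    with 0-based half-open spans. A pair with no positive-scoring residue
    pair yields score 0 and an empty alignment.
    """
    s = s or ScoringScheme()
    if len(query) == 0 or len(target) == 0:
        raise ValueError("cannot align empty sequences")
    a = s.aligner()
    score = a.score(query.residues, target.residues)
    if score <= 0:
        return 0, (0, 0, 0, 0), ("", "")
    aln = a.align(query.residues, target.residues)[0]
    qs, ts = aln.aligned[0], aln.aligned[1]
    span = (int(qs[0][0]), int(qs[-1][1]), int(ts[0][0]), int(ts[-1][1]))
    # aln[0]/aln[1] are the gapped rows of the local block, first-arg first
    return int(round(score)), span, (str(aln[0]), str(aln[1]))


def evalue(raw_score: float, m: int, n: int, s: ScoringScheme | None = None) -> float:
    """Karlin-Altschul expectation E = K*m*n*exp(-lambda*S)."""
    s = s or ScoringScheme()
    if m < 1 or n < 1:
        raise ValueError("search-space dimensions must be >= 1")
    return s.K * m * n * math.exp(-s.lambda_ * raw_score)


def bitscore(raw_score: float, s: ScoringScheme | None = None) -> float:
    s = s or ScoringScheme()
    return (s.lambda_ * raw_score - math.log(s.K)) / math.log(2)


def search_family(orfs, refpkg, s: ScoringScheme | None = None,
                  evalue_cutoff: float = 1e-20, top_k: int = 3) -> list[Hit]:
    """Score ORFs against a family's baits; gate and retain the best.

    ``orfs`` is an iterable of ProteinSequence (or objects with id/residues).
    An ORF's family-level E-value is the best E-value over all baits
    (search space n = total bait letters of the family). Survivors of the
    E-value cutoff are ranked by (E-value, -raw score, query id) and at
    most ``top_k`` are kept, so retention is independent of input order.
    """
    s = s or ScoringScheme()
    baits = list(refpkg.baits) if hasattr(refpkg, "baits") else list(refpkg)
    if not baits:
        raise ValueError("reference package has no bait sequences")
    family = getattr(refpkg, "family", "family")
    n_total = sum(len(b) for b in baits)
    best: list[Hit] = []
    for orf in sorted(orfs, key=lambda o: o.id):
        top: Hit | None = None
        for bait in baits:
            raw, span, _ = local_align(orf, bait, s)
            e = evalue(raw, len(orf), n_total, s)
            h = Hit(orf.id, family, bait.id, raw, bitscore(raw, s), e,
                    span[0], span[1], span[2], span[3])
            if top is None or (h.evalue, -h.raw_score, h.bait_id) < \
                    (top.evalue, -top.raw_score, top.bait_id):
                top = h
        if top is not None and top.evalue <= evalue_cutoff:
            best.append(top)
    best.sort(key=lambda h: (h.evalue, -h.raw_score, h.query_id))
    if top_k is not None and math.isfinite(top_k):
        best = best[:int(top_k)]
    return best


def import_tabular_hits(path, family_id: str = "family") -> list[Hit]:
    """Read BLAST outfmt-6 tabular hits (12 tab-separated columns).

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore. 1-based inclusive coordinates are
    converted to 0-based half-open.
    """
    hits = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ValueError(
                    f"{path}, line {lineno}: expected 12 tab-separated columns, "
                    f"got {len(cols)}")
            q, b = cols[0], cols[1]
            qs, qe, bs, be = (int(cols[6]), int(cols[7]), int(cols[8]), int(cols[9]))
            hits.append(Hit(q, family_id, b, int(round(float(cols[11]))),
                            float(cols[11]), float(cols[10]),
                            qs - 1, qe, bs - 1, be))
    return hits
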