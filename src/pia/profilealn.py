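"""Add query sequences to a fixed reference alignment.

The reference alignment is immutable: a query is aligned to the column
profile (frequency-weighted average substitution score per column,
scaled by the column's non-gap fraction) by affine-gap dynamic
programming, and the only columns ever added are all-gap *insert*
columns holding query residues that match nothing. Stripping the query
row and those insert columns always reproduces the input alignment
exactly — the property phylogenetic placement relies on, since the
reference tree was fit to those columns.

Terminal deletions (reference columns before/after the aligned query
span) are unpenalized: transcript-derived ORFs are routinely fragments
of the full-length proteins in the reference rows.
"""

from __future__ import annotations

import numpy as np

from ._wag import AA_ORDER
from .model import AA_INDEX
from .search import ScoringScheme
from .seqs import GAP, ProteinSequence, read_fasta, write_fasta


class Alignment:
    """Ordered id -> gapped-row mapping with equal-length rows."""

    def __init__(self, rows: dict[str, str], insert_columns=()):
        if not rows:
            raise ValueError("alignment must have at least one row")
        lens = {len(r) for r in rows.values()}
        if len(lens) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lens)}")
        self.rows = dict(rows)
        self.n_cols = lens.pop()
        # columns added for query residues with no reference column
        self.insert_columns = tuple(sorted(insert_columns))

    def __eq__(self, other):
        return isinstance(other, Alignment) and self.rows == other.rows

    def ids(self):
        return list(self.rows)

    def ungapped(self, row_id: str) -> str:
        return self.rows[row_id].replace(GAP, "").replace(".", "").upper()

    def drop_row(self, row_id: str) -> "Alignment":
        rows = {i: r for i, r in self.rows.items() if i != row_id}
        return Alignment(rows)

    def drop_all_gap_columns(self) -> "Alignment":
        keep = [j for j in range(self.n_cols)
                if any(r[j] != GAP for r in self.rows.values())]
        return Alignment({i: "".join(r[j] for j in keep)
                          for i, r in self.rows.items()})

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        pairs = read_fasta(path, alphabet="prot", allow_gaps=True)
        return cls({i: r.upper() for i, r in pairs})

    def to_fasta(self, path, line_width: int = 60):
        write_fasta(list(self.rows.items()), path, line_width)


def column_profile(aln: Alignment):
    """Per-column residue frequencies and occupancy.

    Returns ``(freqs, occupancy)``: freqs is (n_cols, 20) with rows
    summing to 1 where occupancy > 0 (all-gap columns are flagged by
    occupancy 0 and a zero frequency row).
    """
    if aln.n_cols < 1:
        raise ValueError("empty alignment")
    counts = np.zeros((aln.n_cols, 20))
    nongap = np.zeros(aln.n_cols)
    for row in aln.rows.values():
        for j, c in enumerate(row):
            if c == GAP or c == ".":
                continue
            nongap[j] += 1
            i = AA_INDEX.get(c.upper())
            if i is not None:  # X contributes to occupancy only
                counts[j, i] += 1
    tot = counts.sum(axis=1)
    freqs = np.divide(counts, np.where(tot > 0, tot, 1.0)[:, None])
    occupancy = nongap / len(aln.rows)
    return freqs, occupancy


def _profile_match_scores(aln: Alignment, query: str, s: ScoringScheme):
    freqs, occ = column_profile(aln)
    sub = np.zeros((20, 20))
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            sub[i, j] = s.matrix[a, b]
    qidx = np.array([AA_INDEX.get(c, -1) for c in query])
    M = np.zeros((aln.n_cols, len(query)))
    valid = qidx >= 0
    M[:, valid] = (freqs @ sub)[:, qidx[valid]]
    return M * occ[:, None]


def add_to_alignment(aln: Alignment, query: ProteinSequence,
                     s: ScoringScheme | None = None) -> Alignment:
    """Align a query to the profile and append it as a new row.

    Global in the query, semi-global in the profile (free terminal
    deletions). Insert states create new all-gap columns; the returned
    Alignment records them in ``insert_columns`` and renders the query's
    inserted residues lower-case (a2m convention) on output.
    """
    s = s or ScoringScheme()
    if query.id in aln.rows:
        raise ValueError(f"query id {query.id!r} collides with an alignment row")
    q = query.residues
    if not q:
        raise ValueError("empty query")
    C, L = aln.n_cols, len(q)
    M = _profile_match_scores(aln, q, s)
    go, ge = float(s.gap_open), float(s.gap_extend)
    NEG = -1e30

    # DP over (column i 0..C, query pos j 0..L); states:
    #   m: q[j-1] matched to column i-1
    #   x: q[j-1] in an insert column after column i
    #   y: column i-1 deleted (query gap), query consumed up to j
    m = np.full((C + 1, L + 1), NEG)
    x = np.full((C + 1, L + 1), NEG)
    y = np.full((C + 1, L + 1), NEG)
    m[0, 0] = 0.0
    for i in range(1, C + 1):
        y[i, 0] = 0.0  # leading deletions are free
    for j in range(1, L + 1):
        x[0, j] = (m[0, j - 1] + go) if j == 1 else (x[0, j - 1] + ge)
        x[0, j] = max(x[0, j], m[0, j - 1] + go)
    for i in range(1, C + 1):
        for j in range(1, L + 1):
            best_prev = max(m[i - 1, j - 1], x[i - 1, j - 1], y[i - 1, j - 1])
            m[i, j] = best_prev + M[i - 1, j - 1]
            x[i, j] = max(m[i, j - 1] + go, x[i, j - 1] + ge, y[i, j - 1] + go)
            y[i, j] = max(m[i - 1, j] + go, y[i - 1, j] + ge, x[i - 1, j] + go)
        # free trailing deletions handled at termination
    # termination: query fully consumed at any column, trailing cols free
    end_scores = np.maximum(m[:, L], x[:, L])
    end_i = int(np.argmax(end_scores))

    # traceback
    path = []  # list of ("M"|"X"|"Y", i, j)
    i, j = end_i, L
    state = "M" if m[i, j] >= x[i, j] else "X"
    while i > 0 or j > 0:
        if j == 0:
            path.append(("Y", i, j))
            i -= 1
            continue
        if state == "M":
            path.append(("M", i, j))
            prevs = (m[i - 1, j - 1], x[i - 1, j - 1], y[i - 1, j - 1])
            state = "MXY"[int(np.argmax(prevs))]
            i, j = i - 1, j - 1
        elif state == "X":
            path.append(("X", i, j))
            cands = (m[i, j - 1] + go, x[i, j - 1] + ge, y[i, j - 1] + go)
            state = "MXY"[int(np.argmax(cands))]
            j -= 1
        else:  # Y
            path.append(("Y", i, j))
            if i == 0:
                raise AssertionError("bad traceback")
            cands = (m[i - 1, j] + go, y[i - 1, j] + ge, x[i - 1, j] + go)
            state = "MXY"[int(np.argmax(cands))]
            i -= 1
        if i == 0 and j == 0:
            break
    path.reverse()

    # build the extended rows: walk reference columns 0..C-1 in order,
    # interleaving inserts where the path says so
    events = []  # ("col", query_char|None) or ("ins", query_char)
    col_cursor = 0
    for state, i, j in path:
        if state == "M":
            while col_cursor < i - 1:
                events.append(("col", None))
                col_cursor += 1
            events.append(("col", q[j - 1]))
            col_cursor = i
        elif state == "Y":
            while col_cursor < i - 1:
                events.append(("col", None))
                col_cursor += 1
            events.append(("col", None))
            col_cursor = i
        else:  # X: insert after column i
            while col_cursor < i:
                events.append(("col", None))
                col_cursor += 1
            events.append(("ins", q[j - 1]))
    while col_cursor < C:
        events.append(("col", None))
        col_cursor += 1

    new_rows = {rid: [] for rid in aln.rows}
    qrow = []
    inserts = []
    ref_col = 0
    out_col = 0
    for kind, ch in events:
        if kind == "col":
            for rid in aln.rows:
                new_rows[rid].append(aln.rows[rid][ref_col])
            qrow.append(ch.upper() if ch else GAP)
            ref_col += 1
        else:
            for rid in aln.rows:
                new_rows[rid].append(GAP)
            qrow.append(ch.lower())
            inserts.append(out_col)
        out_col += 1
    assert ref_col == C
    rows = {rid: "".join(v) for rid, v in new_rows.items()}
    rows[query.id] = "".join(qrow)
    return Alignment(rows, insert_columns=inserts)


def mask_query_to_ref(extended: Alignment, query_id: str) -> str:
    """The query row restricted to the original reference columns.

    Residues falling in insert columns are dropped, so the returned
    gapped row has exactly the reference column count and can be scored
    against the reference tree.
    """
    if query_id not in extended.rows:
        raise KeyError(f"no row {query_id!r} in alignment")
    row = extended.rows[query_id]
    if extended.insert_columns:
        ins = set(extended.insert_columns)
    else:
        others = [r for i, r in extended.rows.items() if i != query_id]
        ins = {j for j in range(extended.n_cols)
               if others and all(r[j] == GAP for r in others)
               and row[j] != GAP}
    return "".join(c.upper() for j, c in enumerate(row) if j not in ins)
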