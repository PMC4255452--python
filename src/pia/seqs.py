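"""Sequence containers, FASTA I/O and six-frame ORF extraction.

Transcript contigs (isotigs) are read as nucleotide FASTA, translated in
all six reading frames, and every maximal stop-to-stop (or edge-to-stop)
stretch at least ``min_aa`` residues long is reported as a candidate ORF.
ORFs are open reading in the EMBOSS "getorf" sense: no start codon is
required, and stretches truncated by the ends of the transcript are kept,
because assembled transcript fragments frequently cut into coding
sequence.

Coordinates are 0-based half-open on the forward strand of the
transcript, so ``transcript[nuc_start:nuc_end]`` (reverse-complemented
for minus-strand ORFs) always re-translates to ``aa_seq``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

from Bio.Seq import Seq

NUC_LETTERS = set("ACGTN")
AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}
GAP = "-"


class FastaFormatError(ValueError):
    """Malformed FASTA input; message names the offending line number."""


@dataclass(frozen=True)
class NucSequence:
    id: str
    residues: str

    def __post_init__(self):
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - NUC_LETTERS
        if not self.id:
            raise ValueError("empty sequence id")
        if bad:
            raise ValueError(f"illegal nucleotide letters {sorted(bad)} in {self.id!r}")

    def __len__(self):
        return len(self.residues)


@dataclass(frozen=True)
class ProteinSequence:
    id: str
    residues: str

    def __post_init__(self):
        res = self.residues.upper()
        if res.endswith("*"):  # terminal stop marker stripped on storage
            res = res[:-1]
        object.__setattr__(self, "residues", res)
        if not self.id:
            raise ValueError("empty sequence id")
        bad = set(res) - AA_LETTERS
        if bad:
            raise ValueError(f"illegal amino-acid letters {sorted(bad)} in {self.id!r}")

    def __len__(self):
        return len(self.residues)


@dataclass(frozen=True)
class Orf:
    """A translated open reading frame with provenance on its transcript."""

    transcript_id: str
    frame: int  # 1..3 within its strand
    strand: str  # "+" or "-"
    nuc_start: int  # 0-based half-open, forward strand of the transcript
    nuc_end: int
    aa_seq: str
    orf_index: int = 0  # 1-based ordinal within transcript, longest first

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if (self.nuc_end - self.nuc_start) % 3:
            raise ValueError("ORF span not a multiple of 3")
        if len(self.aa_seq) != (self.nuc_end - self.nuc_start) // 3:
            raise ValueError("aa length inconsistent with nucleotide span")


def read_fasta(path, alphabet: Literal["nuc", "prot"] = "prot",
               allow_gaps: bool = False):
    """Read a FASTA file into a list of Nuc/ProteinSequence.

    A small line-aware reader is used (rather than Bio.SeqIO) so that
    malformed headers, illegal residues and duplicate ids can be reported
    with the line number at which they occur.
    """
    path = Path(path)
    seqs = []
    seen = {}
    cur_id = None
    cur_lines: list[str] = []
    cur_lineno = 0

    def flush():
        if cur_id is None:
            return
        res = "".join(cur_lines)
        if allow_gaps:
            check = res.replace(GAP, "").replace(".", "")
        else:
            check = res
        try:
            if alphabet == "nuc":
                NucSequence(cur_id, check)
            else:
                ProteinSequence(cur_id, check)
        except ValueError as e:
            raise FastaFormatError(f"{path}, record starting line {cur_lineno}: {e}") from e
        seqs.append((cur_id, res.upper() if not allow_gaps else res))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise FastaFormatError(f"{path}, line {lineno}: empty FASTA header")
                if header in seen:
                    raise FastaFormatError(
                        f"{path}, line {lineno}: duplicate id {header!r} "
                        f"(first seen line {seen[header]})")
                seen[header] = lineno
                cur_id, cur_lines, cur_lineno = header, [], lineno
            else:
                if cur_id is None:
                    raise FastaFormatError(
                        f"{path}, line {lineno}: sequence data before first header")
                cur_lines.append(line)
    flush()
    if alphabet == "nuc":
        return [NucSequence(i, r) for i, r in seqs]
    if allow_gaps:
        return seqs  # (id, gapped string) pairs for alignment reading
    return [ProteinSequence(i, r) for i, r in seqs]


def write_fasta(seqs: Iterable, path, line_width: int = 60) -> None:
    """Write sequences as FASTA wrapped at ``line_width`` columns."""
    seqs = list(seqs)
    if not seqs:
        raise ValueError("refusing to write an empty FASTA file")
    with open(path, "w") as fh:
        for s in seqs:
            sid, res = (s.id, s.residues) if hasattr(s, "id") else s
            fh.write(f">{sid}\n")
            for k in range(0, max(len(res), 1), line_width):
                fh.write(res[k:k + line_width] + "\n")


def _translate(codons: str) -> str:
    # Bio.Seq handles ambiguous codons (any N) as X under the standard code
    return str(Seq(codons).translate(table=1))


def revcomp(nuc: str) -> str:
    return str(Seq(nuc).reverse_complement())


def six_frame_orfs(seq: NucSequence, min_aa: int = 30) -> list[Orf]:
    """All maximal stop-free translated stretches of >= min_aa residues.

    Scans the three frames of both strands; each frame is cut at stop
    codons and every piece (including edge-truncated ones) whose
    translation reaches ``min_aa`` residues becomes an Orf. ``orf_index``
    is assigned in descending length order, ties by (strand, nuc_start).
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    n = len(seq.residues)
    found = []
    for strand in "+-":
        s = seq.residues if strand == "+" else revcomp(seq.residues)
        for frame in (1, 2, 3):
            off = frame - 1
            usable = (n - off) // 3 * 3
            if usable <= 0:
                continue
            aa = _translate(s[off:off + usable])
            # split at stops; track aa offsets of each piece
            start = 0
            for piece in aa.split("*"):
                if len(piece) >= min_aa:
                    a0 = start          # aa offset in this frame
                    a1 = start + len(piece)
                    s0 = off + 3 * a0   # nt coords on strand s
                    s1 = off + 3 * a1
                    if strand == "+":
                        nuc_start, nuc_end = s0, s1
                    else:
                        nuc_start, nuc_end = n - s1, n - s0
                    found.append(Orf(seq.id, frame, strand, nuc_start, nuc_end, piece))
                start += len(piece) + 1
    found.sort(key=lambda o: (-len(o.aa_seq), o.strand, o.nuc_start))
    return [Orf(o.transcript_id, o.frame, o.strand, o.nuc_start, o.nuc_end,
                o.aa_seq, i + 1) for i, o in enumerate(found)]


def orf_protein(orf: Orf) -> ProteinSequence:
    return ProteinSequence(f"{orf.transcript_id}_ORF{orf.orf_index}", orf.aa_seq)


def query_label(family: str, transcript_id: str, orf_index: int) -> str:
    """Whitespace-free query tag, e.g. ``Gprk1_hit_UN0029_ORF1``."""
    if not family or not transcript_id:
        raise ValueError("family and transcript_id must be non-empty")
    return f"{family}_hit_{transcript_id}_ORF{orf_index}"
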