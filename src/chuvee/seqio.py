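"""Sequence and interval primitives.

Contigs are plain upper-case DNA strings over {A,C,G,T,N}; intervals are
0-based half-open with an explicit strand.  ORF finding is six-frame,
stop-to-stop (no start-codon requirement, matching EMBOSS getorf's default
behaviour), with N-containing codons translated as ``X`` and never treated
as terminators.  Open contig ends count as ORF boundaries, so partial ORFs
at assembly edges are reported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Seq import Seq

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_INVALID_RE = re.compile(r"[^ACGTN]")


class FastaFormatError(ValueError):
    """Raised on malformed FASTA input (empty file, duplicate ids, bad characters)."""


@dataclass(frozen=True)
class Interval:
    """Genomic interval: 0-based, half-open, stranded."""

    contig_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Interval") -> int:
        if self.contig_id != other.contig_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class Contig:
    """A named assembly sequence over {A,C,G,T,N}."""

    id: str
    seq: str
    assembly_id: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("contig id must be non-empty")
        if not self.seq:
            raise ValueError(f"contig {self.id!r}: empty sequence")
        bad = _INVALID_RE.search(self.seq)
        if bad:
            raise ValueError(
                f"contig {self.id!r}: invalid character {bad.group()!r} "
                f"at position {bad.start()}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Orf:
    """Open reading frame: forward-strand coordinates, per-strand frame, peptide."""

    interval: Interval
    frame: int
    peptide: str


def clean_seq(raw: str, context: str = "sequence") -> str:
    """Upper-case, map RNA U to T, and validate the alphabet."""
    s = raw.upper().replace("U", "T")
    bad = _INVALID_RE.search(s)
    if bad:
        raise FastaFormatError(
            f"{context}: invalid character {bad.group()!r} at position {bad.start()}"
        )
    return s


def read_fasta(path, assembly_id: str = "") -> list[Contig]:
    """Read a FASTA file into Contig records.

    Lower-case and U are normalised; any character outside {A,C,G,T,N,U}
    (case-insensitive) is rejected.  Duplicate ids raise, naming the id.
    """
    contigs: list[Contig] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []

    def flush():
        if header is None:
            return
        if not chunks:
            raise FastaFormatError(f"contig {header!r}: empty sequence")
        contigs.append(Contig(header, clean_seq("".join(chunks), f"contig {header!r}"),
                              assembly_id))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise FastaFormatError("FASTA header with empty id")
                if header in seen:
                    raise FastaFormatError(f"duplicate contig id {header!r}")
                seen.add(header)
                chunks = []
            else:
                if header is None:
                    raise FastaFormatError("sequence data before first FASTA header")
                chunks.append(line.strip())
        flush()
    if not contigs:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return contigs


def write_fasta(records: Iterable[tuple[str, str] | Contig], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, Contig):
                name, seq = rec.id, rec.seq
            else:
                name, seq = rec
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; involution; N maps to N."""
    bad = _INVALID_RE.search(seq)
    if bad:
        raise ValueError(f"invalid character {bad.group()!r} in sequence")
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate (standard table); trailing partial codon dropped; N codons -> X."""
    trimmed = seq[: len(seq) - len(seq) % 3]
    if not trimmed:
        return ""
    return str(Seq(trimmed).translate())


def find_orfs(contig: Contig, min_aa: int) -> list[Orf]:
    """Six-frame stop-to-stop ORF scan.

    An ORF is a maximal stop-free codon stretch in one frame of one strand,
    reported when its peptide has at least ``min_aa`` residues.  Coordinates
    are on the forward strand of the contig; the stop codon is excluded.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    n = len(contig.seq)
    out: list[Orf] = []
    for strand in ("+", "-"):
        s = contig.seq if strand == "+" else revcomp(contig.seq)
        for frame in range(3):
            pep = translate(s[frame:])
            if not pep:
                continue
            aa_pos = 0
            for segment in pep.split("*"):
                if len(segment) >= min_aa:
                    nt_start = frame + 3 * aa_pos
                    nt_end = frame + 3 * (aa_pos + len(segment))
                    if strand == "+":
                        iv = Interval(contig.id, nt_start, nt_end, "+")
                    else:
                        iv = Interval(contig.id, n - nt_end, n - nt_start, "-")
                    out.append(Orf(iv, frame, segment))
                aa_pos += len(segment) + 1  # +1 skips the stop
    out.sort(key=lambda o: (o.interval.start, o.interval.end, o.interval.strand))
    return out


def find_n_runs(contig: Contig) -> list[Interval]:
    """Maximal runs of undetermined bases (N)."""
    return [Interval(contig.id, m.start(), m.end())
            for m in re.finditer(r"N+", contig.seq)]


def extract_with_flanks(contig: Contig, locus: Interval,
                        flank_bp: int) -> tuple[str, int, int]:
    """Slice ``locus`` plus up to ``flank_bp`` on each side, clipped at contig ends.

    Returns (sequence, actual_left_flank, actual_right_flank); the sequence
    length always equals len(locus) + left + right.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    if locus.contig_id != contig.id or locus.end > len(contig.seq):
        raise ValueError(f"interval {locus} not valid on contig {contig.id!r}")
    left = min(flank_bp, locus.start)
    right = min(flank_bp, len(contig.seq) - locus.end)
    return contig.seq[locus.start - left: locus.end + right], left, right
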