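"""Homology screening and the EVE voting rule.

Hit tables are 12-column tab-separated (the classic BLAST ``-outfmt 6``
dialect) from two search strategies: viral genomes vs. assembly (translated)
and previously known EVEs vs. assembly (nucleotide).  In both, the assembly
contig is the *subject* and carries the genomic coordinates; the query side
(a viral protein or a known EVE) is what the subject-taxonomy table
classifies as viral / non-viral, and is what the voting rule counts.

The voting rule: a locus with four or fewer distinct reference matches is an
EVE iff the best match is viral; with five or more, it is an EVE iff at
least three of the five best distinct references are viral.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .align import KmerIndex, PeptideHit, encode_dna, peptide_hits
from .seqio import Contig, Interval, extract_with_flanks, find_orfs, revcomp, translate


class Strategy(str, Enum):
    VIRUS_GENOME_TBLASTX = "VIRUS_GENOME_TBLASTX"
    KNOWN_EVE_BLASTN = "KNOWN_EVE_BLASTN"


class ProductClass(str, Enum):
    GLY = "GLY"
    RDRP = "RDRP"
    NP = "NP"
    OTHER = "OTHER"


@dataclass
class HomologyHit:
    """One row of a 12-column tabular similarity search."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    q_start: int  # 1-based inclusive, dialect order encodes strand
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    strategy: Strategy = Strategy.VIRUS_GENOME_TBLASTX

    @property
    def subject_interval(self) -> tuple[int, int, str]:
        """Subject coordinates as (start0, end0, strand)."""
        if self.s_start <= self.s_end:
            return self.s_start - 1, self.s_end, "+"
        return self.s_end - 1, self.s_start, "-"


@dataclass
class SubjectRecord:
    """Taxonomy of one reference sequence used in the screens."""

    subject_id: str
    is_viral: bool
    product_class: ProductClass
    taxon_label: str = ""

    def __post_init__(self):
        if not self.is_viral:
            self.product_class = ProductClass.OTHER


@dataclass
class EveCall:
    """A genomic locus annotated as a chuvirus-derived EVE."""

    locus: Interval
    product_class: ProductClass
    best_hit: HomologyHit
    n_hits: int
    n_viral_in_top5: int
    strategies: set[Strategy]
    mode_i_seq: str = ""
    mode_ii_seq: str = ""
    mode_ii_flanks: tuple[int, int] = (0, 0)
    filter_flag: str | None = None

    @property
    def id(self) -> str:
        return f"{self.locus.contig_id}:{self.locus.start}-{self.locus.end}({self.locus.strand})"


def parse_hit_table(path, strategy: Strategy) -> list[HomologyHit]:
    """Parse a 12-column tab-separated hit table; '#' comment lines are skipped."""
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                hits.append(HomologyHit(
                    query_id=fields[0], subject_id=fields[1],
                    pct_identity=float(fields[2]), aln_len=int(fields[3]),
                    mismatches=int(fields[4]), gap_opens=int(fields[5]),
                    q_start=int(fields[6]), q_end=int(fields[7]),
                    s_start=int(fields[8]), s_end=int(fields[9]),
                    evalue=float(fields[10]), bitscore=float(fields[11]),
                    strategy=strategy,
                ))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return hits


def parse_taxonomy_table(path) -> dict[str, SubjectRecord]:
    """Tab-separated: subject_id, is_viral {0,1}, product_class, taxon_label."""
    records: dict[str, SubjectRecord] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
            records[fields[0]] = SubjectRecord(
                subject_id=fields[0],
                is_viral=fields[1] not in ("0", "false", "False"),
                product_class=ProductClass(fields[2]),
                taxon_label=fields[3] if len(fields) > 3 else "",
            )
    return records


def _rank_key(hit: HomologyHit):
    return (hit.evalue, -hit.bitscore, hit.subject_id)


def rank_hits(hits: list[HomologyHit]) -> list[HomologyHit]:
    """Deterministic total order: evalue asc, bitscore desc, subject_id lex."""
    queries = {h.query_id for h in hits}
    if len(queries) > 1:
        raise ValueError(f"rank_hits requires a single query, got {sorted(queries)}")
    return sorted(hits, key=_rank_key)


def vote_eve(ranked_hits: list[HomologyHit],
             subjects: dict[str, SubjectRecord],
             vote_id=None) -> tuple[bool, dict]:
    """Apply the EVE annotation voting rule to a ranked hit list.

    ``vote_id`` selects which hit attribute identifies the voted reference
    (default: the hit's subject_id).  Multiple HSPs to one reference count
    once; the window is the first five *distinct* references in rank order.
    """
    if vote_id is None:
        vote_id = lambda h: h.subject_id
    flags: list[tuple[str, bool]] = []
    seen: set[str] = set()
    for h in ranked_hits:
        sid = vote_id(h)
        if sid in seen:
            continue
        seen.add(sid)
        rec = subjects.get(sid)
        if rec is None:
            raise KeyError(f"reference {sid!r} missing from taxonomy table")
        flags.append((sid, rec.is_viral))
    if not flags:
        return False, {"reason": "no hits", "n_subjects": 0, "n_viral_in_top5": 0}
    n = len(flags)
    top5 = flags[:5]
    n_viral_top5 = sum(1 for _, v in top5 if v)
    if n <= 4:
        is_eve = flags[0][1]
        window = "top-1 (four or fewer matches)"
    else:
        is_eve = n_viral_top5 >= 3
        window = "top-5 majority (three or more viral)"
    return is_eve, {"reason": window, "n_subjects": n,
                    "n_viral_in_top5": n_viral_top5,
                    "counted": top5}


@dataclass
class _GenomicHit:
    contig_id: str
    start: int
    end: int
    strand: str
    hit: HomologyHit


def _normalize(hits: list[HomologyHit],
               contigs: dict[str, Contig]) -> list[_GenomicHit]:
    out = []
    for h in hits:
        if h.subject_id not in contigs:
            raise KeyError(f"hit references unknown contig {h.subject_id!r}")
        start, end, strand = h.subject_interval
        if end > len(contigs[h.subject_id].seq):
            raise ValueError(
                f"hit coordinates {start}-{end} exceed contig {h.subject_id!r}")
        out.append(_GenomicHit(h.subject_id, start, end, strand, h))
    return out


def call_eves(hit_tables: dict[Strategy, list[HomologyHit]],
              subjects: dict[str, SubjectRecord],
              contigs: list[Contig] | dict[str, Contig],
              flank_bp: int = 10_000,
              evalue_max: float = 1e-4) -> list[EveCall]:
    """Merge genomic hits into loci, vote each locus, and materialise both modes.

    Overlapping same-strand hits (pooled over both strategies) are merged by
    interval union into one locus; the five-best voting window is applied per
    merged locus over distinct references; the product class comes from the
    best viral hit.  Mode I is the merged aligned region, mode II adds up to
    ``flank_bp`` of genomic flank on each side.
    """
    if not isinstance(contigs, dict):
        contigs = {c.id: c for c in contigs}
    pooled: list[_GenomicHit] = []
    for strategy, hits in hit_tables.items():
        kept = [h for h in hits if h.evalue <= evalue_max]
        pooled.extend(_normalize(kept, contigs))

    # group by (contig, strand), merge overlapping intervals
    by_key: dict[tuple[str, str], list[_GenomicHit]] = {}
    for gh in pooled:
        by_key.setdefault((gh.contig_id, gh.strand), []).append(gh)

    calls: list[EveCall] = []
    for (contig_id, strand), ghits in sorted(by_key.items()):
        ghits.sort(key=lambda g: (g.start, g.end))
        cluster: list[_GenomicHit] = []
        cur_end = -1
        groups: list[list[_GenomicHit]] = []
        for gh in ghits:
            if cluster and gh.start >= cur_end:
                groups.append(cluster)
                cluster = []
            cluster.append(gh)
            cur_end = max(cur_end, gh.end)
        if cluster:
            groups.append(cluster)
        for group in groups:
            start = min(g.start for g in group)
            end = max(g.end for g in group)
            ranked = sorted((g.hit for g in group), key=_rank_key)
            is_eve, evidence = vote_eve(ranked, subjects, vote_id=lambda h: h.query_id)
            if not is_eve:
                continue
            best_viral = next(h for h in ranked
                              if subjects[h.query_id].is_viral)
            product = subjects[best_viral.query_id].product_class
            locus = Interval(contig_id, start, end, strand)
            contig = contigs[contig_id]
            mode_ii, left, right = extract_with_flanks(contig, locus, flank_bp)
            calls.append(EveCall(
                locus=locus, product_class=product, best_hit=best_viral,
                n_hits=evidence["n_subjects"],
                n_viral_in_top5=evidence["n_viral_in_top5"],
                strategies={g.hit.strategy for g in group},
                mode_i_seq=contig.seq[start:end],
                mode_ii_seq=mode_ii, mode_ii_flanks=(left, right),
            ))
    calls.sort(key=lambda c: (c.locus.contig_id, c.locus.start, c.locus.strand))
    return calls


# ---------------------------------------------------------------------------
# Built-in desk-scale translated search (tBLASTx stand-in)
# ---------------------------------------------------------------------------

_LN2 = 0.6931471805599453
_KA_LAMBDA = 0.267  # ungapped BLOSUM62 Karlin-Altschul parameters
_KA_K = 0.041


def _bitscore(raw: int) -> float:
    import math
    return (_KA_LAMBDA * raw - math.log(_KA_K)) / _LN2


def naive_translated_search(contigs: list[Contig],
                            proteins: dict[str, str],
                            k: int = 4,
                            min_score: int = 60) -> list[HomologyHit]:
    """Six-frame translated search of viral peptides against an assembly.

    Exact amino-acid k-mer seeds with ungapped BLOSUM62 extension; hits are
    reported in the 12-column dialect with the contig as subject (nucleotide
    coordinates, minus strand encoded by descending s_start/s_end).
    """
    if not (3 <= k <= 6):
        raise ValueError("seed length k must be in [3, 6]")
    hits: list[HomologyHit] = []
    db_len = sum(len(p) for p in proteins.values())
    for contig in contigs:
        n = len(contig.seq)
        for strand in ("+", "-"):
            s = contig.seq if strand == "+" else revcomp(contig.seq)
            for frame in range(3):
                pep = translate(s[frame:])
                if len(pep) < k:
                    continue
                for prot_id, prot in proteins.items():
                    for ph in peptide_hits(prot, pep, seed_k=k,
                                           min_score=min_score):
                        nt_start = frame + 3 * ph.t_start
                        nt_end = frame + 3 * ph.t_end
                        if strand == "+":
                            s_start, s_end = nt_start + 1, nt_end
                        else:
                            s_start, s_end = n - nt_start, n - nt_end + 1
                        bits = _bitscore(ph.score)
                        evalue = db_len * len(pep) * 2.0 ** (-bits)
                        hits.append(HomologyHit(
                            query_id=prot_id, subject_id=contig.id,
                            pct_identity=round(ph.identity, 2),
                            aln_len=ph.length,
                            mismatches=ph.length - ph.matches, gap_opens=0,
                            q_start=ph.q_start + 1, q_end=ph.q_end,
                            s_start=s_start, s_end=s_end,
                            evalue=evalue, bitscore=round(bits, 1),
                            strategy=Strategy.VIRUS_GENOME_TBLASTX,
                        ))
    hits.sort(key=lambda h: (h.subject_id, min(h.s_start, h.s_end), h.query_id))
    return hits


def write_hit_table(hits: list[HomologyHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write("\t".join(str(x) for x in (
                h.query_id, h.subject_id, f"{h.pct_identity:.2f}", h.aln_len,
                h.mismatches, h.gap_opens, h.q_start, h.q_end,
                h.s_start, h.s_end, f"{h.evalue:.3g}", f"{h.bitscore:.1f}",
            )) + "\n")


def write_taxonomy_table(records: dict[str, SubjectRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records.values():
            fh.write("\t".join((rec.subject_id, "1" if rec.is_viral else "0",
                                rec.product_class.value, rec.taxon_label)) + "\n")
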