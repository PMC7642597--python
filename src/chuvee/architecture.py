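"""BEL-Pao architecture annotation and locus classification.

A BEL-Pao element carries a GAG capsid domain and a polyprotein with
protease (PR), reverse transcriptase (RT), RNase H (RH) and integrase (INT)
domains, bounded by two long terminal repeats of 100-900 bp.  Loci are
sorted into the category scheme used for per-genome summary tables:

* ANAKIN_COMPLETE / PAO_COMPLETE  - both LTRs and all five domains, with /
  without a chuvirus glycoprotein inside the LTR boundaries;
* *_DEFECTIVE_2LTR                - both LTRs but an incomplete domain set;
* *_DEFECTIVE                     - at least one domain, one or no LTR;
* SOLO_LTR                        - a lone LTR-length repeat with no
  surrounding Pao domain;
* SOLO_GLY                        - a glycoprotein EVE with neither domains
  nor LTRs in its window;
* RDRP_EVE / NP_EVE               - EVEs from the other chuvirus genes,
  reported regardless of genomic context.

Domain order along the element (GAG<PR<RT<RH<INT) is recorded as evidence
but not required: the categories are presence/count based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .align import (KmerIndex, PeptideIndex, Segment, best_window, encode_dna,
                    kmer_codes, peptide_hits, segments_from_mask,
                    ungapped_search)
from .filters import greedy_cluster
from .screen import EveCall, ProductClass
from .seqio import Contig, Interval, find_orfs, revcomp

PAO_DOMAINS = ("GAG", "PR", "RT", "RH", "INT")


class Domain(str, Enum):
    GAG = "GAG"
    PR = "PR"
    RT = "RT"
    RH = "RH"
    INT = "INT"
    GLY = "GLY"
    OTHER = "OTHER"


class Category(str, Enum):
    ANAKIN_COMPLETE = "ANAKIN_COMPLETE"
    ANAKIN_DEFECTIVE_2LTR = "ANAKIN_DEFECTIVE_2LTR"
    ANAKIN_DEFECTIVE = "ANAKIN_DEFECTIVE"
    PAO_COMPLETE = "PAO_COMPLETE"
    PAO_DEFECTIVE_2LTR = "PAO_DEFECTIVE_2LTR"
    PAO_DEFECTIVE = "PAO_DEFECTIVE"
    SOLO_LTR = "SOLO_LTR"
    SOLO_GLY = "SOLO_GLY"
    RDRP_EVE = "RDRP_EVE"
    NP_EVE = "NP_EVE"
    NONE = "NONE"  # sentinel: no evidence at all (not a summary category)


@dataclass
class DomainAnnotation:
    interval: Interval
    domain: Domain
    score: float
    source: str = "NAIVE_SCAN"  # or EXTERNAL_TABLE
    peptide: str = ""


@dataclass
class LtrPair:
    left: Interval
    right: Interval
    identity: float
    inner: Interval


@dataclass
class ClassifiedLocus:
    """One classified element locus with its supporting evidence."""

    locus: Interval
    category: Category
    domains: list[DomainAnnotation] = field(default_factory=list)
    ltr_pair: LtrPair | None = None
    n_single_ltrs: int = 0
    eve: EveCall | None = None
    gly_peptide: str = ""

    @property
    def domain_set(self) -> frozenset[str]:
        return frozenset(d.domain.value for d in self.domains
                         if d.domain.value in PAO_DOMAINS)


# ---------------------------------------------------------------------------
# Domain scanning
# ---------------------------------------------------------------------------

_DOMAIN_INDEX_CACHE: dict[tuple, PeptideIndex] = {}


def _domain_index(domain_refs: dict[str, str], seed_k: int) -> PeptideIndex:
    key = (tuple(sorted(domain_refs.items())), seed_k)
    if key not in _DOMAIN_INDEX_CACHE:
        if len(_DOMAIN_INDEX_CACHE) > 8:
            _DOMAIN_INDEX_CACHE.clear()
        _DOMAIN_INDEX_CACHE[key] = PeptideIndex(domain_refs, seed_k=seed_k)
    return _DOMAIN_INDEX_CACHE[key]


def scan_domains(contig: Contig, window: Interval,
                 domain_refs: dict[str, str], min_score: int = 60,
                 min_orf_aa: int = 30, seed_k: int = 4) -> list[DomainAnnotation]:
    """Annotate Pao signature domains in a window by translated comparison.

    ORFs of the window (six frames, short cutoff so that point-mutation
    stop codons only fragment, not erase, a domain) are compared against the
    domain reference peptides with the ungapped BLOSUM62 scorer.  The best
    non-overlapping labels are reported in genomic coordinates.
    """
    sub = Contig("_w", contig.seq[window.start:window.end])
    index = _domain_index(domain_refs, seed_k)
    candidates: list[DomainAnnotation] = []
    for orf in find_orfs(sub, min_orf_aa):
        for name, hits in index.scan(orf.peptide, min_score=min_score).items():
            for ph in hits:
                if orf.interval.strand == "+":
                    g_start = window.start + orf.interval.start + 3 * ph.t_start
                    g_end = window.start + orf.interval.start + 3 * ph.t_end
                else:
                    g_end = window.start + orf.interval.end - 3 * ph.t_start
                    g_start = window.start + orf.interval.end - 3 * ph.t_end
                candidates.append(DomainAnnotation(
                    Interval(contig.id, g_start, g_end, orf.interval.strand),
                    Domain(name) if name in Domain.__members__ else Domain.OTHER,
                    float(ph.score),
                    peptide=orf.peptide[ph.t_start:ph.t_end],
                ))
    candidates.sort(key=lambda d: (-d.score, d.interval.start))
    kept: list[DomainAnnotation] = []
    for cand in candidates:
        if all(cand.interval.overlap(k.interval) == 0 for k in kept):
            kept.append(cand)
    kept.sort(key=lambda d: d.interval.start)
    return kept


def ingest_domain_table(path, contig_ids: set[str] | None = None
                        ) -> list[DomainAnnotation]:
    """Read an external CDD-style domain table.

    Tab-separated columns: query_orf (``contig:start-end:strand`` of the
    translated ORF), domain_label, start, end (amino-acid, 1-based within
    the ORF), score, evalue.  Rows map to genomic coordinates here.
    """
    out: list[DomainAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns")
            query_orf, label, aa_start, aa_end, score, _evalue = fields[:6]
            loc, strand = query_orf.rsplit(":", 1)
            contig_id, span = loc.rsplit(":", 1)
            orf_start, orf_end = (int(x) for x in span.split("-"))
            if contig_ids is not None and contig_id not in contig_ids:
                raise KeyError(f"{path}:{lineno}: unknown contig {contig_id!r}")
            a, b = 3 * (int(aa_start) - 1), 3 * int(aa_end)
            if strand == "+":
                g_start, g_end = orf_start + a, orf_start + b
            else:
                g_start, g_end = orf_end - b, orf_end - a
            out.append(DomainAnnotation(
                Interval(contig_id, g_start, g_end, strand),
                Domain(label) if label in Domain.__members__ else Domain.OTHER,
                float(score), source="EXTERNAL_TABLE"))
    return out


# ---------------------------------------------------------------------------
# LTR pair detection (direct-repeat search)
# ---------------------------------------------------------------------------

def find_ltr_pairs(window_seq: str, contig_id: str = "_w", offset: int = 0,
                   min_len: int = 100, max_len: int = 900,
                   min_pair_identity: float = 80.0,
                   min_sep: int = 1_000, max_sep: int = 15_000,
                   seed_k: int = 20, max_miss_run: int = 5) -> list[LtrPair]:
    """Find direct-repeat (LTR) pairs in a window by exact-seed extension.

    Candidate repeats follow the segment rule of :mod:`chuvee.align` on the
    self-comparison diagonals d in [min_len+min_sep, max_len+max_sep].
    Overlapping candidates are resolved by highest identity x length with a
    deterministic leftmost tie-break.  Coordinates are genomic when
    ``offset`` is the window start.
    """
    n = len(window_seq)
    codes = encode_dna(window_seq)
    valid = codes < 4
    packed, wvalid = kmer_codes(codes, seed_k)
    d_lo = min_len + min_sep
    d_hi = min(max_len + max_sep, n - seed_k)
    # diagonals with at least one shared exact k-mer
    positions: dict[int, list[int]] = {}
    diags: set[int] = set()
    pos_valid = np.flatnonzero(wvalid)
    keys = packed[pos_valid]
    order = np.argsort(keys, kind="stable")
    keys_sorted = keys[order]
    pos_sorted = pos_valid[order]
    bounds = np.concatenate((
        [0], np.flatnonzero(np.diff(keys_sorted)) + 1, [len(keys_sorted)]))
    for gi in range(len(bounds) - 1):
        a, b = int(bounds[gi]), int(bounds[gi + 1])
        if b - a < 2:
            continue
        grp = pos_sorted[a:b]
        for i in range(len(grp)):
            for j in range(i + 1, len(grp)):
                d = int(grp[j] - grp[i])
                if d_lo <= d <= d_hi:
                    diags.add(d)
    candidates: list[tuple[float, int, int, LtrPair]] = []
    for d in sorted(diags):
        mask = (codes[:-d] == codes[d:]) & valid[:-d] & valid[d:]
        for a, b, m in segments_from_mask(mask, seed_k, max_miss_run):
            allowed_max = min(max_len, d - min_sep)
            if allowed_max < min_len:
                continue
            if b - a > allowed_max:
                a, b, m = best_window(mask, a, b, allowed_max)
            length = b - a
            if length < min_len:
                continue
            identity = 100.0 * m / length
            if identity < min_pair_identity:
                continue
            sep = d - length
            if not (min_sep <= sep <= max_sep):
                continue
            pair = LtrPair(
                left=Interval(contig_id, offset + a, offset + b),
                right=Interval(contig_id, offset + a + d, offset + b + d),
                identity=identity,
                inner=Interval(contig_id, offset + b, offset + a + d),
            )
            candidates.append((identity * length, a, d, pair))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    kept: list[LtrPair] = []
    for _, _, _, pair in candidates:
        clash = any(
            pair.left.overlap(p.left) or pair.left.overlap(p.right)
            or pair.right.overlap(p.left) or pair.right.overlap(p.right)
            for p in kept)
        if not clash:
            kept.append(pair)
    kept.sort(key=lambda p: (p.left.start, p.right.start))
    return kept


# ---------------------------------------------------------------------------
# Classification decision tree
# ---------------------------------------------------------------------------

def classify_locus(eve: EveCall | None,
                   domains: list[DomainAnnotation] | frozenset[str],
                   ltr_pairs: list[LtrPair],
                   n_single_ltrs: int = 0,
                   gly_interval: Interval | None = None) -> tuple[Category, dict]:
    """Decide the Table-style category for one locus from its evidence.

    Total over the evidence space: every combination of LTR count, Pao
    domain subset and glycoprotein state (inside a pair / outside / absent)
    maps to exactly one category.
    """
    if isinstance(domains, (set, frozenset)):
        domset = frozenset(d for d in domains if d in PAO_DOMAINS)
        dom_list: list[DomainAnnotation] = []
    else:
        dom_list = domains
        domset = frozenset(d.domain.value for d in dom_list
                           if d.domain.value in PAO_DOMAINS)
    evidence = {"domains": sorted(domset), "n_pairs": len(ltr_pairs),
                "n_single_ltrs": n_single_ltrs, "gly_inside": False}

    if eve is not None and eve.product_class is ProductClass.RDRP:
        return Category.RDRP_EVE, evidence
    if eve is not None and eve.product_class is ProductClass.NP:
        return Category.NP_EVE, evidence

    gly_iv = gly_interval
    if gly_iv is None and eve is not None:
        gly_iv = eve.locus
    has_gly = gly_iv is not None

    containing = None
    if has_gly and ltr_pairs:
        hits = [p for p in ltr_pairs
                if p.inner.start <= gly_iv.start and gly_iv.end <= p.inner.end]
        if len(hits) > 1:
            warnings.warn("glycoprotein contained in multiple LTR pairs; "
                          "using the highest-identity pair")
        if hits:
            containing = max(hits, key=lambda p: (p.identity, -p.left.start))
            evidence["gly_inside"] = True

    if has_gly:
        if containing is not None:
            if domset == frozenset(PAO_DOMAINS):
                return Category.ANAKIN_COMPLETE, evidence
            return Category.ANAKIN_DEFECTIVE_2LTR, evidence
        if domset:
            return Category.ANAKIN_DEFECTIVE, evidence
        return Category.SOLO_GLY, evidence

    if domset:
        if ltr_pairs:
            if domset == frozenset(PAO_DOMAINS):
                return Category.PAO_COMPLETE, evidence
            return Category.PAO_DEFECTIVE_2LTR, evidence
        return Category.PAO_DEFECTIVE, evidence

    if ltr_pairs or n_single_ltrs > 0:
        return Category.SOLO_LTR, evidence
    return Category.NONE, evidence


def _evidence_span(contig_id: str, parts: list[Interval]) -> Interval:
    start = min(p.start for p in parts)
    end = max(p.end for p in parts)
    return Interval(contig_id, start, end)


def classify_window(contig: Contig, core: Interval, domain_refs: dict[str, str],
                    eve: EveCall | None = None,
                    window_bp: int = 10_000, min_score: int = 60,
                    ltr_params: dict | None = None) -> ClassifiedLocus:
    """Annotate the +/- window around a core locus and classify it."""
    w_start = max(0, core.start - window_bp)
    w_end = min(len(contig.seq), core.end + window_bp)
    window = Interval(contig.id, w_start, w_end)
    domains = scan_domains(contig, window, domain_refs, min_score=min_score)
    pairs = find_ltr_pairs(contig.seq[w_start:w_end], contig.id, offset=w_start,
                           **(ltr_params or {}))
    category, evidence = classify_locus(eve, domains, pairs)
    pair = None
    if evidence.get("gly_inside") and pairs:
        pair = next((p for p in pairs
                     if p.inner.start <= (eve.locus.start if eve else core.start)
                     and (eve.locus.end if eve else core.end) <= p.inner.end), None)
    elif pairs and category in (Category.PAO_COMPLETE, Category.PAO_DEFECTIVE_2LTR):
        pair = pairs[0]
    parts = [core] + [d.interval for d in domains]
    if pair is not None:
        parts += [pair.left, pair.right]
    return ClassifiedLocus(
        locus=_evidence_span(contig.id, parts), category=category,
        domains=domains, ltr_pair=pair, eve=eve)


# ---------------------------------------------------------------------------
# Solo LTRs and homolog expansion
# ---------------------------------------------------------------------------

def _merge_intervals(spans: list[tuple[int, int]], gap: int = 0) -> list[tuple[int, int]]:
    if not spans:
        return []
    spans = sorted(spans)
    merged = [list(spans[0])]
    for s, e in spans[1:]:
        if s <= merged[-1][1] + gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _nt_hits(query: str, contig: Contig, index: KmerIndex, codes: np.ndarray,
             seed_k: int = 20, min_len: int = 50, min_identity: float = 75.0
             ) -> list[Segment]:
    """Both-strand seeded nucleotide hits of query on a contig (target coords)."""
    hits = []
    for strand_seq in (query, revcomp(query)):
        hits.extend(ungapped_search(
            encode_dna(strand_seq), codes, index, seed_k=seed_k,
            min_len=min_len, min_identity=min_identity))
    return hits


def detect_solo_ltrs(contigs: list[Contig], ltr_library: dict[str, str],
                     domain_refs: dict[str, str], mean_len: float | None = None,
                     tolerance: int = 200, window_bp: int = 10_000,
                     min_identity: float = 75.0, min_score: int = 60,
                     seed_k: int = 20) -> list[ClassifiedLocus]:
    """Find solo LTRs: lone LTR-length repeats with empty Pao windows.

    Library LTRs (taken from classified complete elements) are searched
    against the assembly; merged hits whose length sits within
    mean_len +/- tolerance (inside the 100-900 bp band) and whose window
    holds no Pao domain and no second LTR hit are reported as SOLO_LTR.
    """
    if not ltr_library:
        warnings.warn("empty LTR library; no solo-LTR search performed")
        return []
    if mean_len is None:
        mean_len = sum(len(s) for s in ltr_library.values()) / len(ltr_library)
    lo = max(100, mean_len - tolerance)
    hi = min(900, mean_len + tolerance)
    out: list[ClassifiedLocus] = []
    for contig in contigs:
        codes = encode_dna(contig.seq)
        index = KmerIndex(codes, seed_k)
        spans: list[tuple[int, int]] = []
        for ltr_seq in ltr_library.values():
            for seg in _nt_hits(ltr_seq, contig, index, codes, seed_k=seed_k,
                                min_len=int(lo * 0.5), min_identity=min_identity):
                spans.append((seg.t_start, seg.t_end))
        merged = _merge_intervals(spans, gap=50)
        for s, e in merged:
            if not (lo <= e - s <= hi):
                continue
            w_start = max(0, s - window_bp)
            w_end = min(len(contig.seq), e + window_bp)
            second = any(o_s < e2 and o_e > s2
                         for (s2, e2) in [(w_start, w_end)]
                         for (o_s, o_e) in merged if (o_s, o_e) != (s, e))
            if second:
                continue
            window = Interval(contig.id, w_start, w_end)
            if scan_domains(contig, window, domain_refs, min_score=min_score):
                continue
            out.append(ClassifiedLocus(
                locus=Interval(contig.id, s, e), category=Category.SOLO_LTR,
                n_single_ltrs=1))
    return out


def expand_homologs(complete_elements: dict[str, str], contigs: list[Contig],
                    domain_refs: dict[str, str],
                    eve_calls: list[EveCall] | None = None,
                    min_identity: float = 75.0, min_hit_len: int = 150,
                    merge_gap: int = 1_000, window_bp: int = 10_000,
                    min_score: int = 60, seed_k: int = 20,
                    existing: list[ClassifiedLocus] | None = None,
                    min_overlap: float = 0.5,
                    ltr_params: dict | None = None) -> list[ClassifiedLocus]:
    """Recover and classify all copies homologous to complete elements.

    Near-identical complete queries are first collapsed (greedy clustering
    at 0.9 identity); merged nucleotide hit loci are re-annotated with the
    same window pipeline and deduplicated against already-classified loci by
    >= ``min_overlap`` of the shorter interval.  Loci with neither domains
    nor an LTR pair are left to the solo-LTR detector.
    """
    if not complete_elements:
        return []
    reps = {c.representative_id: complete_elements[c.representative_id]
            for c in greedy_cluster(sorted(complete_elements.items()), 0.9)}
    eves_by_contig: dict[str, list[EveCall]] = {}
    for eve in eve_calls or []:
        eves_by_contig.setdefault(eve.locus.contig_id, []).append(eve)
    existing = list(existing or [])
    out: list[ClassifiedLocus] = []
    for contig in contigs:
        codes = encode_dna(contig.seq)
        index = KmerIndex(codes, seed_k)
        spans: list[tuple[int, int]] = []
        for query in reps.values():
            for seg in _nt_hits(query, contig, index, codes, seed_k=seed_k,
                                min_len=min_hit_len, min_identity=min_identity):
                spans.append((seg.t_start, seg.t_end))
        for s, e in _merge_intervals(spans, gap=merge_gap):
            if e - s < min_hit_len:
                continue
            core = Interval(contig.id, s, e)
            overlapping_eve = None
            for eve in eves_by_contig.get(contig.id, []):
                ov = core.overlap(eve.locus)
                if ov >= min_overlap * min(len(core), len(eve.locus)) or \
                        ov == len(eve.locus):
                    overlapping_eve = eve
                    break
            locus = classify_window(contig, core, domain_refs,
                                    eve=overlapping_eve, window_bp=window_bp,
                                    min_score=min_score, ltr_params=ltr_params)
            if not locus.domains and locus.ltr_pair is None and \
                    locus.category in (Category.NONE, Category.SOLO_LTR,
                                       Category.SOLO_GLY):
                continue
            dup = any(
                locus.locus.overlap(prev.locus) >=
                min_overlap * min(len(locus.locus), len(prev.locus))
                for prev in existing + out)
            if dup:
                continue
            out.append(locus)
    out.sort(key=lambda l: (l.locus.contig_id, l.locus.start))
    return out
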