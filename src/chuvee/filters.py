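"""Redundancy removal and assembly-quality filters.

Greedy incremental clustering follows the CD-HIT convention: sequences are
sorted by length (descending), each joins the first representative it
matches at or above the identity threshold (identity = alignment matches /
length of the shorter sequence), otherwise it founds a new cluster.
Identities are computed from global edit-distance alignments (edlib), whose
extended cigar gives exact match counts.

Assembly filters mirror the characterization step of the screen: an EVE
locus needs at least ``min_flank`` of genomic flank on both sides, no
undetermined bases in the locus or those flanks, and a >= ``min_orf_aa``
ORF overlapping the locus.  Checks apply in that order; the first failure
is terminal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

import edlib
import numpy as np

from .align import encode_dna, kmer_codes
from .seqio import Contig, Interval, find_orfs
from .screen import EveCall

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")
_WORD_K = 16  # short-word prefilter, as in CD-HIT's word index


class FilterFlag(str, Enum):
    PASS = "PASS"
    FAIL_FLANK_LT_4KB = "FAIL_FLANK_LT_4KB"
    FAIL_CONTAINS_N = "FAIL_CONTAINS_N"
    FAIL_ORF_LT_100AA = "FAIL_ORF_LT_100AA"
    REDUNDANT = "REDUNDANT"


@dataclass
class FilterReport:
    eve_id: str
    flag: FilterFlag
    representative: str | None = None  # set for REDUNDANT


@dataclass
class Cluster:
    representative_id: str
    member_ids: list[str]
    threshold: float


def alignment_counts(a: str, b: str, max_dist: int = -1) -> tuple[int, int]:
    """(matches, alignment columns) of the global edit-distance alignment of a and b.

    With ``max_dist`` >= 0 the comparison is banded: pairs whose edit
    distance exceeds it report zero matches (used as a fast reject).
    """
    if not a or not b:
        return 0, max(len(a), len(b))
    res = edlib.align(a, b, mode="NW", task="path", k=max_dist)
    if res["editDistance"] < 0:
        return 0, max(len(a), len(b))
    matches = 0
    columns = 0
    for num, op in _CIGAR_RE.findall(res["cigar"]):
        num = int(num)
        columns += num
        if op == "=":
            matches += num
    return matches, columns


def pair_identity(a: str, b: str, threshold: float | None = None) -> float:
    """CD-HIT-style identity: alignment matches / length of the shorter sequence.

    ``threshold`` enables the banded comparison: reaching identity t needs
    mismatches + paired indels <= (1-t)*shorter, hence an edit distance of at
    most 2*(1-t)*shorter plus the length difference; anything beyond that
    band cannot reach the threshold and reports 0.
    """
    shorter = min(len(a), len(b))
    if shorter == 0:
        return 0.0
    max_dist = -1
    if threshold is not None:
        max_dist = int(2 * (1 - threshold) * shorter) + abs(len(a) - len(b)) + 8
    matches, _ = alignment_counts(a, b, max_dist=max_dist)
    return matches / shorter


def pair_similarity(a: str, b: str) -> float:
    """Simple similarity with gaps retained: matches / alignment columns."""
    matches, columns = alignment_counts(a, b)
    return matches / columns if columns else 0.0


def _word_set(seq: str) -> np.ndarray:
    packed, valid = kmer_codes(encode_dna(seq), _WORD_K)
    return np.unique(packed[valid])


def greedy_cluster(records: list[tuple[str, str]],
                   identity_threshold: float) -> list[Cluster]:
    """CD-HIT-style greedy incremental clustering; deterministic.

    A short-word index prefilters candidate pairs (sequences reaching the
    identity threshold share exact words; pairs with none in common are
    rejected without alignment), then the banded global comparison decides.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity threshold must be in (0, 1]")
    ordered = sorted(records, key=lambda r: (-len(r[1]), r[0]))
    clusters: list[Cluster] = []
    rep_seqs: list[str] = []
    rep_words: list[np.ndarray] = []
    for rec_id, seq in ordered:
        words = _word_set(seq)
        placed = False
        for cluster, rep_seq, rwords in zip(clusters, rep_seqs, rep_words):
            if len(seq) >= 4 * _WORD_K and len(rep_seq) >= 4 * _WORD_K:
                if len(np.intersect1d(words, rwords, assume_unique=True)) == 0:
                    continue
            if pair_identity(seq, rep_seq, identity_threshold) >= identity_threshold:
                cluster.member_ids.append(rec_id)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(rec_id, [rec_id], identity_threshold))
            rep_seqs.append(seq)
            rep_words.append(words)
    return clusters


def apply_assembly_filters(eve: EveCall, contig: Contig,
                           min_flank: int = 4_000,
                           min_orf_aa: int = 100) -> FilterReport:
    """Terminal-status quality check for one EVE call (flank, N, ORF order)."""
    locus = eve.locus
    left_space = locus.start
    right_space = len(contig.seq) - locus.end
    if left_space < min_flank or right_space < min_flank:
        return FilterReport(eve.id, FilterFlag.FAIL_FLANK_LT_4KB)
    region_start = locus.start - min_flank
    region_end = locus.end + min_flank
    if "N" in contig.seq[region_start:region_end]:
        return FilterReport(eve.id, FilterFlag.FAIL_CONTAINS_N)
    # ORF check on the locus +/- min_flank slice (ORFs longer than the slice
    # margin are truncated; at 4 kb the margin holds ORFs up to ~1300 aa)
    sub = Contig("_region", contig.seq[region_start:region_end])
    for orf in find_orfs(sub, min_orf_aa):
        g_start = region_start + orf.interval.start
        g_end = region_start + orf.interval.end
        if g_start < locus.end and g_end > locus.start:
            return FilterReport(eve.id, FilterFlag.PASS)
    return FilterReport(eve.id, FilterFlag.FAIL_ORF_LT_100AA)


def filter_and_deduplicate(eves: list[EveCall], contigs: dict[str, Contig],
                           min_flank: int = 4_000, min_orf_aa: int = 100,
                           cluster_identity: float = 0.90
                           ) -> tuple[list[EveCall], list[FilterReport]]:
    """Run quality filters then flank-extended redundancy clustering.

    Every input EVE receives exactly one terminal flag; survivors (cluster
    representatives among PASS calls) are returned with their flag set.
    """
    reports: list[FilterReport] = []
    passing: list[EveCall] = []
    for eve in eves:
        report = apply_assembly_filters(eve, contigs[eve.locus.contig_id],
                                        min_flank, min_orf_aa)
        if report.flag is FilterFlag.PASS:
            passing.append(eve)
        else:
            eve.filter_flag = report.flag.value
            reports.append(report)
    by_id = {e.id: e for e in passing}
    clusters = greedy_cluster([(e.id, e.mode_ii_seq) for e in passing],
                              cluster_identity)
    survivors: list[EveCall] = []
    for cluster in clusters:
        for member in cluster.member_ids:
            eve = by_id[member]
            if member == cluster.representative_id:
                eve.filter_flag = FilterFlag.PASS.value
                reports.append(FilterReport(member, FilterFlag.PASS))
                survivors.append(eve)
            else:
                eve.filter_flag = FilterFlag.REDUNDANT.value
                reports.append(FilterReport(member, FilterFlag.REDUNDANT,
                                            cluster.representative_id))
    survivors.sort(key=lambda e: (e.locus.contig_id, e.locus.start))
    reports.sort(key=lambda r: r.eve_id)
    return survivors, reports


def representatives_90(peptides: list[tuple[str, str]],
                       threshold: float = 0.90) -> list[str]:
    """Single-linkage components at > threshold similarity; one representative each.

    Similarity is simple similarity with gaps retained (matches / alignment
    columns); the representative is the longest member, ties broken by id.
    """
    n = len(peptides)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if pair_similarity(peptides[i][1], peptides[j][1]) > threshold:
                parent[find(i)] = find(j)
    components: dict[int, list[int]] = {}
    for i in range(n):
        components.setdefault(find(i), []).append(i)
    reps = []
    for members in components.values():
        best = min(members, key=lambda i: (-len(peptides[i][1]), peptides[i][0]))
        reps.append(peptides[best][0])
    return sorted(reps)
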