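"""Seed-and-extend ungapped matching.

This module implements the deterministic matching rule shared by the LTR
direct-repeat finder, the nucleotide homolog search and the desk-scale
translated search.

Nucleotide rule (documented in docs/methods.md): given a per-position match
mask between two sequences at a fixed offset, the mask is first split into
blocks at runs of more than ``max_miss_run`` consecutive mismatches; within
each block the candidate segment is the maximum-scoring subsegment under
match +1 / mismatch -2 (leftmost, then longest, on score ties), which trims
the random overshoot that plain run-extension accumulates at repeat edges.
A candidate is reported only if it contains at least one run of ``seed_k``
consecutive matches (an exact shared k-mer).  Positions with N never match.
Candidates longer than an allowed maximum are reduced to their best
(most matches, leftmost on tie) window of that maximum length, then
re-trimmed to end on matches.  Identity is matches / segment length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_NT_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _NT_CODE[ord(_b)] = _i
_N_CODE = 4


def encode_dna(seq: str) -> np.ndarray:
    """Encode DNA as uint8 codes A=0 C=1 G=2 T=3, N (and anything else) = 4."""
    return _NT_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed 2-bit k-mer codes and a validity mask (windows containing N are invalid)."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    a = codes.astype(np.int64)
    valid_base = codes < 4
    a = np.where(valid_base, a, 0)
    packed = np.zeros(n, dtype=np.int64)
    for i in range(k):
        packed = packed * 4 + a[i:n + i]
    cs = np.concatenate(([0], np.cumsum(valid_base.astype(np.int64))))
    window_valid = (cs[k:] - cs[:-k]) == k
    return packed, window_valid


@dataclass(frozen=True)
class Segment:
    """Ungapped matching segment between query[q_start:q_end] and target at offset."""

    q_start: int
    q_end: int
    t_start: int
    t_end: int
    matches: int

    @property
    def length(self) -> int:
        return self.q_end - self.q_start

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.length


def _runs(mask: np.ndarray) -> list[tuple[int, int, bool]]:
    """Run-length encode a boolean mask as (start, end, value)."""
    if len(mask) == 0:
        return []
    change = np.flatnonzero(mask[1:] != mask[:-1]) + 1
    bounds = np.concatenate(([0], change, [len(mask)]))
    return [(int(bounds[i]), int(bounds[i + 1]), bool(mask[bounds[i]]))
            for i in range(len(bounds) - 1)]


MISMATCH_PENALTY = 2  # Kadane trim score: match +1, mismatch -MISMATCH_PENALTY


def _max_scoring_subsegment(mask: np.ndarray, a: int, b: int) -> tuple[int, int]:
    """Leftmost-then-longest maximum-scoring subsegment of mask[a:b].

    Scores runs (not single positions) for speed; candidate boundaries of an
    optimal subsegment always fall on match-run edges.
    """
    best_score = 0
    best = (a, a)
    cur_score = 0
    cur_start = a
    for s, e, v in _runs(mask[a:b]):
        gain = (e - s) if v else -MISMATCH_PENALTY * (e - s)
        if cur_score <= 0:
            cur_score = 0
            if v:
                cur_start = a + s
        cur_score += gain
        if v and cur_score > best_score:
            best_score = cur_score
            best = (cur_start, a + e)
    return best


def segments_from_mask(mask: np.ndarray, seed_k: int,
                       max_miss_run: int) -> list[tuple[int, int, int]]:
    """Apply the segment rule to a match mask.

    Returns (start, end, matches) triples in mask coordinates, without any
    length/identity filtering (callers apply their own bounds).
    """
    out: list[tuple[int, int, int]] = []
    runs = _runs(mask)
    if not runs:
        return out
    # split points: mismatch runs longer than max_miss_run
    seg_start = 0
    boundaries: list[tuple[int, int]] = []
    for start, end, value in runs:
        if not value and (end - start) > max_miss_run:
            boundaries.append((seg_start, start))
            seg_start = end
    boundaries.append((seg_start, len(mask)))
    cum = np.concatenate(([0], np.cumsum(mask.astype(np.int64))))
    for a, b in boundaries:
        if b - a < seed_k:
            continue
        a2, b2 = _max_scoring_subsegment(mask, a, b)
        if b2 - a2 < seed_k:
            continue
        # require an exact seed: a run of >= seed_k consecutive matches
        best_run = 0
        for s, e, v in _runs(mask[a2:b2]):
            if v:
                best_run = max(best_run, e - s)
        if best_run < seed_k:
            continue
        out.append((a2, b2, int(cum[b2] - cum[a2])))
    return out


def best_window(mask: np.ndarray, start: int, end: int,
                max_len: int) -> tuple[int, int, int]:
    """Best sub-window of at most max_len (most matches, leftmost), trimmed to matches."""
    if end - start <= max_len:
        a, b = start, end
    else:
        cum = np.concatenate(([0], np.cumsum(mask[start:end].astype(np.int64))))
        scores = cum[max_len:] - cum[:-max_len]
        off = int(np.argmax(scores))  # argmax is leftmost on ties
        a, b = start + off, start + off + max_len
    sub = mask[a:b]
    ones = np.flatnonzero(sub)
    if len(ones) == 0:
        raise ValueError("window contains no matches")
    a2, b2 = a + int(ones[0]), a + int(ones[-1]) + 1
    return a2, b2, int(sub[ones[0]:ones[-1] + 1].sum())


class KmerIndex:
    """Sorted-array index of valid k-mers of a target sequence."""

    def __init__(self, codes: np.ndarray, k: int):
        self.k = k
        packed, valid = kmer_codes(codes, k)
        pos = np.flatnonzero(valid)
        keys = packed[pos]
        order = np.argsort(keys, kind="stable")
        self.keys = keys[order]
        self.positions = pos[order]

    def lookup(self, query_packed: np.ndarray,
               query_valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """All (query_pos, target_pos) seed pairs for valid query k-mers."""
        qpos = np.flatnonzero(query_valid)
        if len(qpos) == 0 or len(self.keys) == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        qk = query_packed[qpos]
        lo = np.searchsorted(self.keys, qk, side="left")
        hi = np.searchsorted(self.keys, qk, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        q_out = np.repeat(qpos, counts)
        t_out = np.empty(total, dtype=np.int64)
        idx = 0
        nz = np.flatnonzero(counts)
        for i in nz:
            c = int(counts[i])
            t_out[idx:idx + c] = self.positions[lo[i]:hi[i]]
            idx += c
        return q_out, t_out


def ungapped_search(query_codes: np.ndarray, target_codes: np.ndarray,
                    index: KmerIndex | None = None, *, seed_k: int = 20,
                    min_len: int = 50, max_len: int | None = None,
                    min_identity: float = 75.0,
                    max_miss_run: int = 5) -> list[Segment]:
    """Seeded ungapped search of query against target.

    Seeds are exact shared k-mers; every seeded diagonal is scanned once with
    the segment rule.  Results are deduplicated and sorted by target start.
    """
    if index is None:
        index = KmerIndex(target_codes, seed_k)
    qpacked, qvalid = kmer_codes(query_codes, seed_k)
    qpos, tpos = index.lookup(qpacked, qvalid)
    if len(qpos) == 0:
        return []
    diags = tpos - qpos
    out: list[Segment] = []
    nq, nt = len(query_codes), len(target_codes)
    qv = query_codes < 4
    tv = target_codes < 4
    for d in np.unique(diags):
        d = int(d)
        q_lo = max(0, -d)
        q_hi = min(nq, nt - d)
        if q_hi - q_lo < seed_k:
            continue
        qs = query_codes[q_lo:q_hi]
        ts = target_codes[q_lo + d:q_hi + d]
        mask = (qs == ts) & qv[q_lo:q_hi] & tv[q_lo + d:q_hi + d]
        for a, b, m in segments_from_mask(mask, seed_k, max_miss_run):
            if max_len is not None and (b - a) > max_len:
                a, b, m = best_window(mask, a, b, max_len)
            length = b - a
            if length < min_len:
                continue
            if 100.0 * m / length < min_identity:
                continue
            out.append(Segment(q_lo + a, q_lo + b, q_lo + d + a, q_lo + d + b, m))
    out.sort(key=lambda s: (s.t_start, s.t_end, s.q_start))
    return out


# ---------------------------------------------------------------------------
# Translated (peptide) seed-and-extend with BLOSUM62
# ---------------------------------------------------------------------------

_BLOSUM = None


def _blosum62():
    global _BLOSUM
    if _BLOSUM is None:
        from Bio.Align import substitution_matrices
        mat = substitution_matrices.load("BLOSUM62")
        table = {}
        for a in mat.alphabet:
            for b in mat.alphabet:
                table[a + b] = int(mat[a, b])
        _BLOSUM = table
    return _BLOSUM


def blosum_score(a: str, b: str) -> int:
    return _blosum62().get(a + b, -4)


@dataclass(frozen=True)
class PeptideHit:
    """Ungapped local peptide match (query = reference peptide, target = translated frame)."""

    q_start: int
    q_end: int
    t_start: int
    t_end: int
    score: int
    matches: int

    @property
    def length(self) -> int:
        return self.q_end - self.q_start

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.length


def _extend_seed(ref: str, pep: str, i: int, j: int, seed_k: int,
                 table: dict, x_drop: int) -> tuple[int, int, int, int, int]:
    """Ungapped X-drop extension of a seed; returns (score, qs, qe, ts, te)."""
    nq, nt = len(ref), len(pep)
    score = sum(table.get(ref[i + t] + pep[j + t], -4) for t in range(seed_k))
    best = score
    q_end, t_end = i + seed_k, j + seed_k
    run, qe, te = score, q_end, t_end
    while qe < nq and te < nt:
        run += table.get(ref[qe] + pep[te], -4)
        qe += 1
        te += 1
        if run > best:
            best, q_end, t_end = run, qe, te
        elif best - run > x_drop:
            break
    run = best
    q_start, t_start = i, j
    qs, ts = i, j
    while qs > 0 and ts > 0:
        qs -= 1
        ts -= 1
        run += table.get(ref[qs] + pep[ts], -4)
        if run > best:
            best, q_start, t_start = run, qs, ts
        elif best - run > x_drop:
            break
    return best, q_start, q_end, t_start, t_end


class PeptideIndex:
    """Shared exact k-mer seed index over a set of reference peptides.

    Built once per reference set so that scanning many translated ORFs does
    not rebuild the per-reference seed dictionaries each time.
    """

    def __init__(self, refs: dict[str, str], seed_k: int = 4):
        if not (3 <= seed_k <= 6):
            raise ValueError("seed length must be in [3, 6]")
        self.refs = dict(refs)
        self.seed_k = seed_k
        self.seeds: dict[str, list[tuple[str, int]]] = {}
        for name in sorted(refs):
            ref = refs[name]
            for i in range(len(ref) - seed_k + 1):
                self.seeds.setdefault(ref[i:i + seed_k], []).append((name, i))

    def scan(self, pep: str, min_score: int = 60,
             x_drop: int = 20) -> dict[str, list[PeptideHit]]:
        """Best hit per (reference, diagonal) with score >= min_score."""
        table = _blosum62()
        k = self.seed_k
        nt = len(pep)
        best: dict[tuple[str, int], PeptideHit] = {}
        seen: dict[tuple[str, int], int] = {}
        for j in range(nt - k + 1):
            entries = self.seeds.get(pep[j:j + k])
            if not entries:
                continue
            for name, i in entries:
                d = j - i
                key = (name, d)
                if key in seen and j < seen[key]:
                    continue
                ref = self.refs[name]
                score, qs, qe, ts, te = _extend_seed(ref, pep, i, j, k,
                                                     table, x_drop)
                seen[key] = te
                if score < min_score:
                    continue
                matches = sum(1 for t in range(qe - qs)
                              if ref[qs + t] == pep[ts + t])
                hit = PeptideHit(qs, qe, ts, te, score, matches)
                prev = best.get(key)
                if prev is None or hit.score > prev.score:
                    best[key] = hit
        out: dict[str, list[PeptideHit]] = {}
        for (name, _), hit in best.items():
            out.setdefault(name, []).append(hit)
        for name in out:
            out[name].sort(key=lambda h: (-h.score, h.t_start, h.q_start))
        return out


def peptide_hits(ref: str, pep: str, *, seed_k: int = 4, min_score: int = 60,
                 x_drop: int = 20) -> list[PeptideHit]:
    """Ungapped BLOSUM62 seed-and-extend of one reference peptide against a peptide.

    Exact ``seed_k``-mer seeds; X-drop extension in both directions; one best
    hit per diagonal is kept; hits below ``min_score`` are dropped.
    """
    if len(ref) < seed_k or len(pep) < seed_k:
        return []
    index = PeptideIndex({"_q": ref}, seed_k=seed_k)
    return index.scan(pep, min_score=min_score, x_drop=x_drop).get("_q", [])
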