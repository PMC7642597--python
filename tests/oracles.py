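"""Independent brute-force oracles used by the test suite.

These deliberately re-derive expected results by the most direct route
available (hand-written codon table, exhaustive enumeration, O(n^2) scans)
and share no code with the implementation paths they check.
"""

from __future__ import annotations

import numpy as np

# hand-written standard genetic code (independent of Biopython)
_CODON_TABLE = {}
_AAS = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
_B = "TCAG"
for _i, _b1 in enumerate(_B):
    for _j, _b2 in enumerate(_B):
        for _k, _b3 in enumerate(_B):
            _CODON_TABLE[_b1 + _b2 + _b3] = _AAS[16 * _i + 4 * _j + _k]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def oracle_translate_codon(codon: str) -> str:
    if "N" in codon:
        # ambiguous codon: X unless every completion agrees
        options = {oracle_translate_codon(codon.replace("N", b, 1))
                   for b in "ACGT"}
        return options.pop() if len(options) == 1 else "X"
    return _CODON_TABLE[codon]


def oracle_orfs(seq: str, min_aa: int) -> set[tuple]:
    """Exhaustive six-frame stop-partition scan.

    Returns {(start, end, strand, frame, peptide)} on forward coordinates.
    """
    out = set()
    n = len(seq)
    for strand in ("+", "-"):
        s = seq if strand == "+" else "".join(_COMP[b] for b in reversed(seq))
        for frame in range(3):
            codons = [s[i:i + 3] for i in range(frame, n - 2, 3)]
            aas = [oracle_translate_codon(c) for c in codons]
            start_codon = 0
            i = 0
            while i <= len(aas):
                if i == len(aas) or aas[i] == "*":
                    length = i - start_codon
                    if length >= min_aa:
                        nt_a = frame + 3 * start_codon
                        nt_b = frame + 3 * i
                        if strand == "+":
                            coords = (nt_a, nt_b)
                        else:
                            coords = (n - nt_b, n - nt_a)
                        out.add((coords[0], coords[1], strand, frame,
                                 "".join(aas[start_codon:i])))
                    start_codon = i + 1
                i += 1
    return out


def oracle_vote(viral_flags: list[bool]) -> bool:
    """Literal transcription of the screening annotation rule."""
    n = len(viral_flags)
    if n == 0:
        return False
    if n <= 4:
        return viral_flags[0]
    return sum(viral_flags[:5]) >= 3


def oracle_rank(rows: list[tuple]) -> list[tuple]:
    """(evalue, bitscore, subject_id) rows ordered by the stated total order."""
    return sorted(rows, key=lambda r: (r[0], -r[1], r[2]))


# ---------------------------------------------------------------------------
# Direct-repeat (LTR) oracle: O(n^2) scan of every in-bounds diagonal
# ---------------------------------------------------------------------------

def _oracle_blocks(mask: np.ndarray, max_miss_run: int) -> list[tuple[int, int]]:
    """Split at mismatch runs longer than max_miss_run."""
    n = len(mask)
    blocks = []
    start = 0
    i = 0
    while i < n:
        if mask[i]:
            i += 1
            continue
        j = i
        while j < n and not mask[j]:
            j += 1
        if j - i > max_miss_run:
            blocks.append((start, i))
            start = j
        i = j
    blocks.append((start, n))
    return [(a, b) for a, b in blocks if b > a]


def _oracle_best_subsegment(mask, a, b, penalty=2):
    """Brute force over all (i, j): max score, then min end, then max start."""
    boundaries = [a + i for i in range(b - a) if mask[a + i]]
    best = None
    for i in boundaries:
        score = 0
        for j in range(i, b):
            score += 1 if mask[j] else -penalty
            if not mask[j]:
                continue
            key = (score, -(j + 1), i)
            if best is None or key > best[0]:
                best = (key, i, j + 1)
    if best is None:
        return a, a
    return best[1], best[2]


def _oracle_longest_match_run(mask, a, b):
    best = run = 0
    for i in range(a, b):
        run = run + 1 if mask[i] else 0
        best = max(best, run)
    return best


def oracle_direct_repeats(seq: str, min_len=100, max_len=900,
                          min_pair_identity=80.0, min_sep=1000,
                          max_sep=15000, seed_k=20,
                          max_miss_run=5) -> list[tuple]:
    """All candidate pairs (left_start, left_end, right_start, right_end,
    identity) before overlap resolution, by direct per-diagonal scanning."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(seq)
    is_n = arr == ord("N")
    out = []
    for d in range(min_len + min_sep, min(max_len + max_sep, n - seed_k) + 1):
        mask = (arr[:-d] == arr[d:]) & ~is_n[:-d] & ~is_n[d:]
        # a candidate must contain seed_k consecutive matches; diagonals
        # without any such run cannot produce one (vectorised prefilter)
        cs = np.concatenate(([0], np.cumsum(mask.astype(np.int64))))
        if len(cs) <= seed_k or not (cs[seed_k:] - cs[:-seed_k] == seed_k).any():
            continue
        for a, b in _oracle_blocks(mask, max_miss_run):
            if b - a < seed_k:
                continue
            a2, b2 = _oracle_best_subsegment(mask, a, b)
            if b2 - a2 < seed_k:
                continue
            if _oracle_longest_match_run(mask, a2, b2) < seed_k:
                continue
            allowed_max = min(max_len, d - min_sep)
            if allowed_max < min_len:
                continue
            if b2 - a2 > allowed_max:
                # best window of allowed_max length (most matches, leftmost),
                # trimmed to matches
                best = None
                for w in range(a2, b2 - allowed_max + 1):
                    m = int(mask[w:w + allowed_max].sum())
                    if best is None or m > best[0]:
                        best = (m, w)
                w = best[1]
                sub = mask[w:w + allowed_max]
                ones = np.flatnonzero(sub)
                a2, b2 = w + int(ones[0]), w + int(ones[-1]) + 1
            length = b2 - a2
            if length < min_len:
                continue
            matches = int(mask[a2:b2].sum())
            identity = 100.0 * matches / length
            if identity < min_pair_identity:
                continue
            sep = d - length
            if not (min_sep <= sep <= max_sep):
                continue
            out.append((a2, b2, a2 + d, b2 + d, identity))
    return sorted(out)


def oracle_greedy_cluster(records, threshold, identity_fn):
    """Single-pass all-pairs application of the stated clustering rule."""
    ordered = sorted(records, key=lambda r: (-len(r[1]), r[0]))
    reps = []  # (id, seq, members)
    for rec_id, seq in ordered:
        for rep in reps:
            if identity_fn(seq, rep[1]) >= threshold:
                rep[2].append(rec_id)
                break
        else:
            reps.append((rec_id, seq, [rec_id]))
    return {r[0]: sorted(r[2]) for r in reps}
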