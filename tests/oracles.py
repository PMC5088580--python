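"""Independent reference implementations used only to check the package.

Each oracle recomputes a result by brute force or exhaustive enumeration,
sharing no code path with the implementation it validates:

* ``scan_occurrences`` — exact pattern matching by string scan.
* ``exhaustive_hits`` — scores *every* reference window of every reference
  on both strands with a banded dynamic program over the same op space as
  the backward search (match/substitution, insertion, deletion with the
  same positional gates), keeping the best log-probability per start.
* ``overlap_components`` — single-linkage clustering as explicit connected
  components of the O(n^2) pairwise-overlap graph.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
LOG_EPS = 1e-9


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def scan_occurrences(references: list[tuple[str, str]], pattern: str) -> list[tuple[str, int]]:
    """All exact occurrences of pattern, by naive scan.  0-based positions."""
    out = []
    for name, seq in references:
        seq = seq.upper()
        start = 0
        while True:
            i = seq.find(pattern.upper(), start)
            if i < 0:
                break
            out.append((name, i))
            start = i + 1
    return sorted(out)


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(c, 4) for c in seq.upper()], dtype=np.int64)


def _complement_matrix(M: np.ndarray) -> np.ndarray:
    comp = np.array([3, 2, 1, 0])
    return M[np.ix_(comp, comp)]


def _strand_scores(ref_codes: np.ndarray, read_codes: np.ndarray, log_M5: np.ndarray,
                   log_n: float, log_I: float, log_D: float, log_t: float,
                   k: int) -> np.ndarray:
    """Best log p per start position for one oriented read against one
    reference; -inf where no alignment reaches the threshold band."""
    R, L = len(ref_codes), len(read_codes)
    n_starts = R
    pad = np.full(L + k + 1, 4, dtype=np.int64)
    refp = np.concatenate([ref_codes, pad])
    neg = -math.inf
    dp = {d: np.full(n_starts, neg) for d in range(-k, k + 1)}
    dp[0] = np.zeros(n_starts)
    starts = np.arange(n_starts)
    for f in range(L):
        qb = int(read_codes[f])
        new = {}
        for d in range(-k, k + 1):
            idx = starts + f + d
            rb = refp[idx]
            if qb >= 0:
                fac = log_M5[rb, qb]
            else:
                fac = np.where(rb < 4, log_n, neg)
            new[d] = dp[d] + fac
        if 2 <= f <= L - 3 and log_I > neg:
            for d in range(-k, k):
                new[d] = np.maximum(new[d], dp[d + 1] + log_I)
        # deletions at read level f+1 (after f+1 read bases are consumed)
        if 3 <= f + 1 <= L - 2 and log_D > neg:
            for d in range(-k + 1, k + 1):
                new[d] = np.maximum(new[d], new[d - 1] + log_D)
        dp = new
    best = np.full(n_starts, neg)
    for d in range(-k, k + 1):
        # alignments must not run off the reference (pad rows are -inf already)
        best = np.maximum(best, dp[d])
    return best


def exhaustive_hits(references: list[tuple[str, str]], read_seq: str,
                    profile, T: float, allow_indels: bool = True,
                    both_strands: bool = True) -> dict[tuple[str, int, str], float]:
    """Best-path log p of every accepted placement, by window scoring.

    Returns {(ref_name, 1-based start, strand): log_p} for every placement
    whose best alignment reaches T.  The op space (indel gates: insertions
    at read offsets [2, L-3], deletions after 3..L-2 consumed bases, both
    only when ``allow_indels``) mirrors the backward search.
    """
    L = len(read_seq)
    log_t = math.log(T)
    bound = max(float(profile.M.diagonal().max()), 1.0 - (profile.I + profile.D))
    log_bound = math.log(bound) if bound < 1 else 0.0
    max_id = max(profile.I, profile.D)
    k = 0
    if allow_indels and max_id > 0:
        while (k + 1) * math.log(max_id) + L * log_bound >= log_t - LOG_EPS:
            k += 1
            if k > 2:
                raise ValueError("oracle supports at most 2 indels above threshold")
        # guard: >=3 consecutive indels must be sub-threshold, else the
        # implementation's run cap would diverge from this DP
        if 3 * math.log(max_id) + L * log_bound >= log_t - LOG_EPS:
            raise ValueError("profile admits 3+ indel runs; oracle not applicable")
    log_I = math.log(profile.I) if (allow_indels and profile.I > 0) else -math.inf
    log_D = math.log(profile.D) if (allow_indels and profile.D > 0) else -math.inf
    # read N bases score as the smallest matrix entry, matching the aligner
    read_f = np.array([_CODE.get(c, -1) for c in read_seq.upper()], dtype=np.int64)
    hits: dict[tuple[str, int, str], float] = {}
    strands = [("+", read_f, profile.M)]
    if both_strands:
        rc = np.array([_CODE.get(c, -1) for c in revcomp(read_seq)], dtype=np.int64)
        strands.append(("-", rc, _complement_matrix(profile.M)))
    for strand, codes, M in strands:
        with np.errstate(divide="ignore"):
            log_M = np.log(M)
        log_M5 = np.vstack([log_M, np.full((1, 4), -math.inf)])
        log_n = float(log_M.min())
        for name, seq in references:
            ref_codes = _encode(seq)
            best = _strand_scores(ref_codes, codes, log_M5, log_n, log_I, log_D,
                                  log_t, k)
            for s in np.nonzero(best >= log_t - LOG_EPS)[0]:
                hits[(name, int(s) + 1, strand)] = float(best[s])
    return hits


def overlap_components(intervals: list[tuple[str, str, int, int]],
                       min_overlap: int = 5) -> list[frozenset[int]]:
    """Connected components of the pairwise overlap graph (O(n^2)).

    ``intervals[i] = (ref, strand, start, end)`` with 1-based inclusive
    coordinates; i and j are linked iff same ref and strand and their
    intervals share at least ``min_overlap`` bases.
    """
    n = len(intervals)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in itertools.combinations(range(n), 2):
        ri, si, ai, bi = intervals[i]
        rj, sj, aj, bj = intervals[j]
        if ri != rj or si != sj:
            continue
        if min(bi, bj) - max(ai, aj) + 1 >= min_overlap:
            parent[find(i)] = find(j)
    comps: dict[int, set[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(i)
    return [frozenset(c) for c in comps.values()]
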