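"""Estimation of the probability models driving simulation and alignment.

Two sides of the same coin:

* the aligner consumes an :class:`ErrorProfile` — the 4x4 substitution
  matrix ``M`` (row = reference base, column = read base) plus per-position
  insertion/deletion probabilities ``I`` and ``D``.  In PAR-CLIP data the
  T->C entry of ``M`` is dominated by cross-link conversions and sits far
  above sequencing-error level (around 6%).
* the simulator consumes a :class:`BackgroundProfile` ``epsilon`` (the same
  matrix with the T->C entry replaced by the mean of the eleven other
  off-diagonal rates, so it models sequencing error only), a
  :class:`ConversionModel` (ranked site conversion frequencies ``alpha``,
  the positional preference ``beta`` of the major conversion site and the
  per-cluster site-count distribution), and :class:`PositionModels`
  (per-read-position indel rates ``mu`` and Phred-score distributions
  ``delta``).

Matrix orientation is fixed as ``M[ref][read]``: a T->C conversion is a
reference T observed as a read C, i.e. row T, column C.  Reverse-strand
alignments are complement-flipped before counting so conversions are always
scored in sense orientation.  Every estimated matrix entry is floored at
``PROB_FLOOR`` and rows renormalised, so no substitution is ever
categorically impossible for the aligner.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .formats_io import SamRecord

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMP_INDEX = np.array([3, 2, 1, 0])   # A<->T, C<->G
PROB_FLOOR = 1e-4
T, C = BASE_INDEX["T"], BASE_INDEX["C"]
N_BETA_BINS = 20
MAX_PHRED = 41


class EstimationError(ValueError):
    """Raised when an estimator has no usable events to count."""


def _floor_and_renormalize(matrix: np.ndarray, floor: float = PROB_FLOOR) -> np.ndarray:
    m = np.maximum(np.asarray(matrix, dtype=float), floor)
    return m / m.sum(axis=1, keepdims=True)


@dataclass
class ErrorProfile:
    """Aligner-side error model: substitution matrix M plus indel rates."""

    M: np.ndarray                 # 4x4, M[ref][read], rows sum to 1
    I: float                      # insertion probability per aligned position
    D: float                      # deletion probability per aligned position

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=float)
        if self.M.shape != (4, 4):
            raise ValueError("M must be 4x4")
        if not np.allclose(self.M.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows of M must sum to 1 within 1e-9")
        if np.any(self.M < 0) or np.any(self.M > 1):
            raise ValueError("entries of M must lie in [0,1]")
        if not (0 <= self.I <= 1 and 0 <= self.D <= 1):
            raise ValueError("I and D must lie in [0,1]")

    def complemented(self) -> "ErrorProfile":
        """Profile seen by a reverse-complemented query: M'[r][b] = M[comp r][comp b]."""
        return ErrorProfile(
            _floor_and_renormalize(self.M[np.ix_(COMP_INDEX, COMP_INDEX)], 0.0),
            self.I, self.D)


@dataclass
class BackgroundProfile:
    """Simulator-side sequencing-error matrix (T->C entry de-conversioned)."""

    epsilon: np.ndarray

    def __post_init__(self):
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        if self.epsilon.shape != (4, 4):
            raise ValueError("epsilon must be 4x4")
        if not np.allclose(self.epsilon.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows of epsilon must sum to 1 within 1e-9")


@dataclass
class ConversionModel:
    """T->C conversion structure of binding sites.

    ``alpha[r]`` is the conversion frequency of the rank-(r+1) site (rank 1 =
    major site); ``beta`` the distribution of the major site's relative
    position within the cluster (20 equal-width bins); ``n_sites_dist[k]``
    the probability of k+1 conversion sites per cluster.
    """

    alpha: np.ndarray
    beta: np.ndarray
    n_sites_dist: np.ndarray
    alpha_hist: list[np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.n_sites_dist = np.asarray(self.n_sites_dist, dtype=float)
        if np.any(self.alpha < 0) or np.any(self.alpha > 1):
            raise ValueError("alpha entries must lie in [0,1]")
        if np.any(np.diff(self.alpha) > 1e-12):
            raise ValueError("alpha must be non-increasing with rank")
        if not np.isclose(self.beta.sum(), 1.0):
            raise ValueError("beta must sum to 1")
        if not np.isclose(self.n_sites_dist.sum(), 1.0):
            raise ValueError("n_sites_dist must sum to 1")


@dataclass
class PositionModels:
    """Per-read-position indel rates (mu) and Phred distributions (delta)."""

    mu: np.ndarray                # length = max read length
    delta: np.ndarray             # shape (max read length, 42); rows sum to 1

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        if np.any(self.mu < 0) or np.any(self.mu > 1):
            raise ValueError("mu entries must lie in [0,1]")
        if self.delta.shape[1] != MAX_PHRED + 1:
            raise ValueError(f"delta must have {MAX_PHRED + 1} score columns")
        if not np.allclose(self.delta.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each delta row must sum to 1")


# ---------------------------------------------------------------------------
# counting helpers
# ---------------------------------------------------------------------------

def _substitution_counts(sam_records: list[SamRecord]) -> tuple[np.ndarray, int, int, int]:
    """Count aligned base pairs and indel events in sense orientation.

    Returns (counts[ref][read], n_insertion_events, n_deletion_events,
    n_aligned_positions).  Reverse-strand records are complement-flipped so
    a genomic A->G on the minus strand counts as T->C.
    """
    counts = np.zeros((4, 4), dtype=np.int64)
    n_ins = n_del = 0
    n_aligned = 0
    for rec in sam_records:
        if rec.is_unmapped:
            continue
        pairs = rec.aligned_pairs()
        for _, _, read_b, ref_b in pairs:
            ri, bi = BASE_INDEX.get(ref_b.upper()), BASE_INDEX.get(read_b.upper())
            if ri is None or bi is None:
                continue
            if rec.is_reverse:
                ri, bi = COMP_INDEX[ri], COMP_INDEX[bi]
            counts[ri, bi] += 1
            n_aligned += 1
        for op, n in rec.cigar_ops():
            if op == "I":
                n_ins += 1
            elif op == "D":
                n_del += 1
    return counts, n_ins, n_del, n_aligned


def _empirical_rates(counts: np.ndarray) -> np.ndarray:
    row_tot = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        rates = np.where(row_tot > 0, counts / np.maximum(row_tot, 1), 0.0)
    # rows with no observations fall back to identity
    for i in range(4):
        if row_tot[i, 0] == 0:
            rates[i] = np.eye(4)[i]
    return rates


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def estimate_error_profile(sam_records: list[SamRecord], reference=None) -> ErrorProfile:
    """Estimate M, I, D from an alignment.

    The T->C entry reflects the *observed* frequency, conversions included —
    this is the aligner-side profile in which T->C is allowed to sit far
    above sequencing-error level.  ``reference`` is unused when MD tags are
    present (the usual case) and accepted for interface symmetry.
    """
    counts, n_ins, n_del, n_aligned = _substitution_counts(sam_records)
    if n_aligned == 0:
        raise EstimationError("no aligned positions; cannot estimate an error profile")
    M = _floor_and_renormalize(_empirical_rates(counts))
    I = max(n_ins / n_aligned, PROB_FLOOR)
    D = max(n_del / n_aligned, PROB_FLOOR)
    return ErrorProfile(M, I, D)


def estimate_background_profile(sam_records: list[SamRecord], reference=None) -> BackgroundProfile:
    """Estimate epsilon: the empirical substitution matrix with the T->C rate
    replaced by the mean of the eleven other off-diagonal rates (PAR-CLIP
    conversions must not leak into the background model)."""
    counts, _, _, n_aligned = _substitution_counts(sam_records)
    if n_aligned == 0:
        raise EstimationError("no aligned positions; cannot estimate a background profile")
    rates = _empirical_rates(counts)
    off = [(i, j) for i in range(4) for j in range(4) if i != j and not (i == T and j == C)]
    rates[T, C] = float(np.mean([rates[i, j] for i, j in off]))
    rates[T, T] = 1.0 - rates[T, [j for j in range(4) if j != T]].sum()
    return BackgroundProfile(_floor_and_renormalize(rates))


def estimate_conversion_model(clusters, min_site_coverage: int = 5,
                              min_site_frequency: float = 0.05) -> ConversionModel:
    """Estimate alpha, beta and the per-cluster site-count distribution from
    high-confidence clusters.

    A T->C *site* is a sense-T position with coverage >= ``min_site_coverage``
    and conversion frequency >= ``min_site_frequency``; sites are ranked per
    cluster by frequency, and alpha[r] is the mean frequency of rank-r sites
    across clusters.
    """
    per_rank: list[list[float]] = []
    beta_counts = np.zeros(N_BETA_BINS, dtype=float)
    site_counts: list[int] = []
    for cl in clusters:
        sites = []
        for pos, (cov, tc) in cl.site_table.items():
            if cov >= min_site_coverage and cov > 0 and tc / cov >= min_site_frequency:
                sites.append((tc / cov, pos))
        if not sites:
            continue
        sites.sort(key=lambda s: (-s[0], s[1]))
        site_counts.append(len(sites))
        for rank, (freq, _) in enumerate(sites):
            while len(per_rank) <= rank:
                per_rank.append([])
            per_rank[rank].append(freq)
        major_pos = sites[0][1]
        span = max(cl.end - cl.start + 1, 1)
        rel = (major_pos - cl.start) / span
        beta_counts[min(int(rel * N_BETA_BINS), N_BETA_BINS - 1)] += 1
    if not site_counts:
        raise EstimationError("no cluster contains a usable T-C conversion site")
    alpha = np.array([float(np.mean(v)) for v in per_rank])
    alpha = np.minimum.accumulate(alpha)   # enforce non-increasing ranks
    beta = beta_counts / beta_counts.sum()
    max_sites = max(site_counts)
    n_dist = np.bincount(site_counts, minlength=max_sites + 1)[1:].astype(float)
    n_dist /= n_dist.sum()
    hist = [np.asarray(v, dtype=float) for v in per_rank]
    return ConversionModel(alpha, beta, n_dist, alpha_hist=hist)


def estimate_position_models(sam_records: list[SamRecord]) -> PositionModels:
    """Per-read-position indel rates mu and Phred-score distributions delta."""
    max_len = 0
    mapped = [r for r in sam_records if not r.is_unmapped]
    if not mapped:
        raise EstimationError("no mapped records")
    for r in mapped:
        max_len = max(max_len, len(r.sequence))
    indel_events = np.zeros(max_len, dtype=np.int64)
    covering = np.zeros(max_len, dtype=np.int64)
    qual_counts = np.zeros((max_len, MAX_PHRED + 1), dtype=np.int64)
    for r in mapped:
        L = len(r.sequence)
        covering[:L] += 1
        quals = r.qualities
        if r.is_reverse:
            quals = quals[::-1]
        for i, q in enumerate(quals):
            qual_counts[i, min(q, MAX_PHRED)] += 1
        qpos = 0
        for op, n in r.cigar_ops():
            if op in "MS":
                qpos += n
            elif op == "I":
                off = qpos if not r.is_reverse else L - 1 - qpos
                indel_events[off] += 1
                qpos += n
            elif op in "DN":
                off = min(qpos, L - 1)
                if r.is_reverse:
                    off = L - 1 - off
                if op == "D":
                    indel_events[off] += 1
    mu = indel_events / np.maximum(covering, 1)
    delta = qual_counts.astype(float)
    empty = delta.sum(axis=1) == 0
    delta[empty, 30] = 1.0        # unobserved tail positions: nominal Q30
    delta /= delta.sum(axis=1, keepdims=True)
    return PositionModels(mu, delta)


# ---------------------------------------------------------------------------
# profile document I/O
# ---------------------------------------------------------------------------

def save_profiles(path: str | os.PathLike, *,
                  error: ErrorProfile | None = None,
                  background: BackgroundProfile | None = None,
                  conversion: ConversionModel | None = None,
                  position: PositionModels | None = None) -> None:
    """Persist any subset of the profiles as one JSON document with fixed keys."""
    doc: dict[str, object] = {}
    if error is not None:
        doc["M"] = error.M.tolist()
        doc["I"] = error.I
        doc["D"] = error.D
    if background is not None:
        doc["epsilon"] = background.epsilon.tolist()
    if conversion is not None:
        doc["alpha"] = conversion.alpha.tolist()
        doc["beta"] = conversion.beta.tolist()
        doc["n_sites_dist"] = conversion.n_sites_dist.tolist()
    if position is not None:
        doc["mu"] = position.mu.tolist()
        doc["delta"] = position.delta.tolist()
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_profiles(path: str | os.PathLike) -> dict[str, object]:
    """Load a profile document; returns a dict with any of the keys
    'error', 'background', 'conversion', 'position' populated."""
    with open(path) as fh:
        doc = json.load(fh)
    out: dict[str, object] = {}
    if "M" in doc:
        out["error"] = ErrorProfile(np.array(doc["M"]), float(doc["I"]), float(doc["D"]))
    if "epsilon" in doc:
        out["background"] = BackgroundProfile(np.array(doc["epsilon"]))
    if "alpha" in doc:
        out["conversion"] = ConversionModel(np.array(doc["alpha"]), np.array(doc["beta"]),
                                            np.array(doc["n_sites_dist"]))
    if "mu" in doc:
        out["position"] = PositionModels(np.array(doc["mu"]), np.array(doc["delta"]))
    return out
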