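"""Permutation statistics on dissimilarity matrices.

Bray-Curtis dissimilarities over residual-RBH profiles, one-way and crossed
two-way ANOSIM, the Mantel test, and the 1-D Euclidean matrix built from
per-bacterium 16S distances to the archaeal root. All three permutation tests
are implemented here directly (they are the statistical core of the analysis);
p-values use the add-one rule p = (b + 1) / (n_perm + 1) and are therefore
never zero.

ANOSIM: with mid-ranks r over all M = n(n-1)/2 pairwise dissimilarities,
R = (mean between-group rank - mean within-group rank) / (M/2), which lies in
[-1, 1]. The two-way crossed form tests one factor by averaging the one-way R
computed within each stratum (level) of the other factor, permuting labels
within strata only.
"""
from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, rankdata

from .errors import DegenerateDataError, DomainError, InputError, InsufficientDataError
from .models import DistanceMatrix, PermutationResult

__all__ = [
    "bray_curtis",
    "anosim_oneway",
    "anosim_twoway",
    "mantel",
    "root_distance_matrix",
]


def bray_curtis(profiles: pd.DataFrame, offset_policy: str = "shift_to_zero") -> DistanceMatrix:
    """Bray-Curtis dissimilarity BC(x, y) = sum|x-y| / sum(x+y) between rows.

    Residual profiles can be negative; under ``shift_to_zero`` (default) the
    global minimum is subtracted first, under ``error_on_negative`` negative
    entries raise. A pair of all-zero rows gets distance 0 with a warning.
    """
    if offset_policy not in ("shift_to_zero", "error_on_negative"):
        raise DomainError(f"unknown offset_policy {offset_policy!r}")
    X = profiles.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise InputError("profiles must be finite")
    lo = X.min() if X.size else 0.0
    if lo < 0:
        if offset_policy == "error_on_negative":
            raise DomainError("negative entries not allowed under error_on_negative")
        X = X - lo
    n = X.shape[0]
    rowsum = X.sum(axis=1)
    D = np.zeros((n, n))
    # |x_i - x_j| summed over features, chunked over rows to bound memory
    chunk = max(1, int(2e7 // max(X.size, 1)))
    for start in range(0, n, chunk):
        stop = min(n, start + chunk)
        num = np.abs(X[start:stop, None, :] - X[None, :, :]).sum(axis=2)
        D[start:stop] = num
    den = rowsum[:, None] + rowsum[None, :]
    zero_pairs = den == 0
    if zero_pairs.sum() > n:  # off-diagonal all-zero row pairs
        warnings.warn("pairs of all-zero profiles: distance set to 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(zero_pairs, 0.0, D / np.where(zero_pairs, 1.0, den))
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0  # symmetrize away float jitter
    return DistanceMatrix(ids=list(profiles.index), values=D)


def _check_groups(labels: np.ndarray) -> None:
    values, counts = np.unique(labels, return_counts=True)
    if len(values) < 2:
        raise InsufficientDataError("ANOSIM needs >= 2 groups")
    small = values[counts < 2]
    if small.size:
        raise InsufficientDataError(f"group {small[0]!r} has fewer than 2 members")


def _anosim_r(ranks: np.ndarray, same: np.ndarray, denom: float) -> float:
    rw = ranks[same].mean()
    rb = ranks[~same].mean()
    return float((rb - rw) / denom)


def anosim_oneway(
    dist: DistanceMatrix,
    labels: Sequence,
    n_perm: int = 999,
    seed: Optional[int] = None,
) -> PermutationResult:
    """One-way ANOSIM with label-permutation p-value (upper tail)."""
    labels = np.asarray(labels)
    if len(labels) != dist.n:
        raise InputError("labels length does not match distance matrix")
    _check_groups(labels)
    n = dist.n
    iu = np.triu_indices(n, 1)
    ranks = rankdata(dist.values[iu])  # mid-ranks for ties
    denom = len(ranks) / 2.0
    same = labels[iu[0]] == labels[iu[1]]
    observed = _anosim_r(ranks, same, denom)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = labels[rng.permutation(n)]
        if _anosim_r(ranks, perm[iu[0]] == perm[iu[1]], denom) >= observed:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return PermutationResult(statistic=observed, p_value=p, n_perm=n_perm, seed=seed)


class _Stratum:
    """Precomputed rank structure of one stratum of the nuisance factor."""

    __slots__ = ("idx", "ranks", "iu", "denom", "labels")

    def __init__(self, values: np.ndarray, idx: np.ndarray, labels: np.ndarray):
        self.idx = idx
        sub = values[np.ix_(idx, idx)]
        self.iu = np.triu_indices(len(idx), 1)
        self.ranks = rankdata(sub[self.iu])
        self.denom = len(self.ranks) / 2.0
        self.labels = labels

    def r(self, labels: np.ndarray) -> float:
        same = labels[self.iu[0]] == labels[self.iu[1]]
        return _anosim_r(self.ranks, same, self.denom)


def _valid_stratum(labels: np.ndarray) -> bool:
    values, counts = np.unique(labels, return_counts=True)
    return len(values) >= 2 and counts.min() >= 2


def anosim_twoway(
    dist: DistanceMatrix,
    factor1: Sequence,
    factor2: Sequence,
    n_perm: int = 999,
    seed: Optional[int] = None,
) -> tuple[PermutationResult, PermutationResult]:
    """Crossed two-way ANOSIM: each factor tested within strata of the other.

    The statistic for a factor is the mean one-way R over strata of the other
    factor in which the factor still has >= 2 groups of >= 2 members (other
    strata are skipped); significance comes from permuting labels within
    strata. A factor with no usable stratum (e.g. constant within every
    stratum) gets a NaN result; if neither factor is testable the call
    errors. Returns (result for factor1, result for factor2); with a
    constant second factor, the first result equals the one-way ANOSIM at
    the same seed.
    """
    f1 = np.asarray(factor1)
    f2 = np.asarray(factor2)
    if len(f1) != dist.n or len(f2) != dist.n:
        raise InputError("factor lengths do not match distance matrix")
    out = []
    for tested, strata in ((f1, f2), (f2, f1)):
        parts = []
        for level in np.unique(strata):
            idx = np.flatnonzero(strata == level)
            labs = tested[idx]
            if _valid_stratum(labs):
                parts.append(_Stratum(dist.values, idx, labs))
        if not parts:
            out.append(
                PermutationResult(statistic=float("nan"), p_value=float("nan"),
                                  n_perm=n_perm, seed=seed)
            )
            continue
        rng = np.random.default_rng(seed)  # fresh stream per factor
        observed = float(np.mean([s.r(s.labels) for s in parts]))
        hits = 0
        for _ in range(n_perm):
            stat = float(
                np.mean([s.r(s.labels[rng.permutation(len(s.labels))]) for s in parts])
            )
            if stat >= observed:
                hits += 1
        out.append(
            PermutationResult(
                statistic=observed, p_value=(hits + 1) / (n_perm + 1),
                n_perm=n_perm, seed=seed,
            )
        )
    if all(np.isnan(r.statistic) for r in out):
        raise InsufficientDataError(
            "no stratum with >= 2 groups of >= 2 members for either factor"
        )
    return out[0], out[1]


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: Optional[int] = None,
) -> PermutationResult:
    """Mantel test: Pearson r over strict lower triangles, permutation p.

    Rows/columns of the second matrix are permuted simultaneously; the upper
    tail of r is counted.
    """
    if d1.n != d2.n:
        raise InputError("distance matrices differ in size")
    if d1.ids != d2.ids:
        raise InputError("distance matrices have mismatched ids")
    n = d1.n
    il = np.tril_indices(n, -1)
    v1 = d1.values[il]
    v2 = d2.values[il]
    if np.std(v1) == 0 or np.std(v2) == 0:
        raise DegenerateDataError("constant distance matrix: Mantel r undefined")
    observed = float(pearsonr(v1, v2).statistic)
    rng = np.random.default_rng(seed)
    # center once; r under permutation is a dot product of standardized vectors
    z1 = (v1 - v1.mean()) / v1.std()
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pv2 = d2.values[np.ix_(perm, perm)][il]
        r = float(np.mean(z1 * (pv2 - pv2.mean()) / pv2.std()))
        if r >= observed:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return PermutationResult(statistic=observed, p_value=p, n_perm=n_perm, seed=seed)


def root_distance_matrix(dist_to_root: pd.Series) -> DistanceMatrix:
    """Bacteria-bacteria matrix |d_i - d_j| of 16S distances to the archaeal root.

    Treating each bacterium as a point on the root-distance axis removes the
    bacteria-bacteria phylogenetic signal and keeps only depth relative to
    the archaea.
    """
    vals = pd.to_numeric(dist_to_root, errors="coerce")
    if vals.isna().any():
        bad = sorted(vals.index[vals.isna()].tolist())
        raise InputError(f"missing root distance for bacteria: {bad}")
    v = vals.to_numpy(dtype=float)
    D = np.abs(v[:, None] - v[None, :])
    return DistanceMatrix(ids=list(dist_to_root.index), values=D)
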