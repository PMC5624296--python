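"""Enriched archaea-bacteria pairs and false-positive accounting.

A pair is "enriched" when its residual RBH count (or its transferred-gene
count) exceeds 1.96 standard deviations above the reference level — one-sided,
excess sharing only, strict inequality. No multiple-testing correction is
applied to individual calls; instead, the expected number of bacteria enriched
by chance (a binomial tail over archaea) is reported, and a corroboration rule
removes bacteria supported by a single archaeon in a single evidence source.
"""
from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .errors import DomainError, InsufficientDataError
from .models import EnrichedPair, ResidualMatrix

__all__ = [
    "call_enriched_pairs",
    "call_hgt_enriched_pairs",
    "corroborate_pairs",
    "expected_false_positives",
]


def call_enriched_pairs(residuals: ResidualMatrix, z_threshold: float = 1.96) -> list[EnrichedPair]:
    """Pairs whose residual RBHs exceed z_threshold residual SDs above zero."""
    out = []
    for a in residuals.values.columns:
        sd = float(residuals.residual_sd[a])
        if sd <= 0:
            warnings.warn(f"archaeon {a}: residual_sd is 0, skipped", stacklevel=2)
            continue
        col = residuals.values[a]
        z = col / sd
        for b in col.index[z > z_threshold]:
            out.append(
                EnrichedPair(archaeon=a, bacterium=b, residual=float(col[b]),
                             z=float(z[b]), source="rbh")
            )
    return out


def call_hgt_enriched_pairs(hgt_counts: pd.DataFrame, z_threshold: float = 1.96) -> list[EnrichedPair]:
    """Pairs whose transferred-gene count exceeds the per-archaeon mean by z_threshold SDs.

    ``hgt_counts``: bacteria (rows) x archaea (columns) transferred-gene
    counts. The mean and sample SD are taken over bacteria within each
    archaeon's column.
    """
    if hgt_counts.shape[0] < 3:
        raise InsufficientDataError("need >= 3 bacteria per archaeon for HGT enrichment")
    out = []
    for a in hgt_counts.columns:
        col = hgt_counts[a].astype(float)
        sd = float(col.std(ddof=1))
        if sd == 0:
            continue  # zero variance: nothing can be enriched
        mean = float(col.mean())
        z = (col - mean) / sd
        for b in col.index[z > z_threshold]:
            out.append(
                EnrichedPair(archaeon=a, bacterium=b, residual=float(col[b] - mean),
                             z=float(z[b]), source="hgt")
            )
    return out


def corroborate_pairs(
    rbh_pairs: Iterable[EnrichedPair],
    hgt_pairs: Iterable[EnrichedPair],
    min_archaea: int = 3,
) -> tuple[set, set]:
    """Split enriched bacteria into (robust, dropped).

    A bacterium is robust when either evidence source links it to
    ``min_archaea`` or more archaea, or when both sources support it
    (regardless of how many archaea). Bacteria enriched with fewer archaea in
    only one source are dropped as potential false positives.
    """
    by_source = {"rbh": {}, "hgt": {}}
    for p in rbh_pairs:
        by_source["rbh"].setdefault(p.bacterium, set()).add(p.archaeon)
    for p in hgt_pairs:
        by_source["hgt"].setdefault(p.bacterium, set()).add(p.archaeon)
    robust, dropped = set(), set()
    for b in set(by_source["rbh"]) | set(by_source["hgt"]):
        n_rbh = len(by_source["rbh"].get(b, ()))
        n_hgt = len(by_source["hgt"].get(b, ()))
        if max(n_rbh, n_hgt) >= min_archaea or (n_rbh > 0 and n_hgt > 0):
            robust.add(b)
        else:
            dropped.add(b)
    return robust, dropped


def expected_false_positives(
    n_bacteria: int, n_archaea: int, alpha: float, k: int
) -> tuple[float, float]:
    """Chance enrichment under independence.

    Returns (p_per_bacterium, expected_bacteria) where p_per_bacterium is
    P(Binomial(n_archaea, alpha) >= k): the probability that a null bacterium
    is flagged as enriched with at least k archaea when each archaeon flags
    it independently with probability alpha.
    """
    if not 0.0 <= alpha <= 1.0:
        raise DomainError(f"alpha must lie in [0, 1], got {alpha}")
    if k < 1:
        raise DomainError(f"k must be >= 1, got {k}")
    p = float(binom.sf(k - 1, n_archaea, alpha))
    return p, n_bacteria * p
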