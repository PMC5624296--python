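"""COG functional-category profiling of shared and transferred genes.

Profiles count genes per single-letter COG category (a gene mapping to
several categories is counted once in each; proportions are over category
assignments). Category-level genome-size correction reuses the per-archaeon
log-logistic machinery on counts restricted to one category, followed by the
same decorrelation check and optional GC adjustment. Category-level ANOSIM
p-values pass through a Bonferroni gate (alpha / n_tests, strict).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import DomainError, InputError
from .models import ResidualMatrix
from .size_model import (
    decorrelation_check,
    fit_log_logistic,
    residual_matrix,
    secondary_residuals,
)

__all__ = [
    "COG_CATEGORIES",
    "TRANSPORTER_CATEGORY",
    "CategoryProfile",
    "category_profile",
    "category_enrichment",
    "split_counts_by_category",
    "per_category_residuals",
    "per_category_gc_adjust",
    "bonferroni_gate",
    "CategoryFit",
]

#: the standard COG functional-category alphabet
COG_CATEGORIES = "JAKLBDYVTMNZWUOCGEFHIPQRS"
#: inorganic ion transport and metabolism; the transporter-rich category
TRANSPORTER_CATEGORY = "P"


@dataclass
class CategoryProfile:
    """Per-category counts and proportions over a gene subset."""

    counts: pd.Series
    proportions: pd.Series
    n_uncategorized: int


def _validate_map(cog_map: pd.DataFrame) -> pd.DataFrame:
    if not {"gene_id", "category"}.issubset(cog_map.columns):
        raise InputError("cog_map needs columns gene_id, category")
    bad = ~cog_map["category"].isin(set(COG_CATEGORIES))
    if bad.any():
        raise InputError(
            f"unknown COG categories: {sorted(cog_map.loc[bad, 'category'].unique())}"
        )
    return cog_map


def category_profile(gene_ids: Iterable[str], cog_map: pd.DataFrame) -> CategoryProfile:
    """Count categories among ``gene_ids``; proportions sum to 1 over assignments.

    ``cog_map`` has one row per (gene_id, category) assignment. Genes absent
    from the map are tallied separately as uncategorized.
    """
    _validate_map(cog_map)
    genes = set(gene_ids)
    sub = cog_map.loc[cog_map["gene_id"].isin(genes)]
    counts = (
        sub["category"].value_counts().reindex(list(COG_CATEGORIES), fill_value=0)
    )
    total = int(counts.sum())
    proportions = counts / total if total else counts.astype(float)
    n_uncat = len(genes - set(sub["gene_id"]))
    return CategoryProfile(counts=counts, proportions=proportions, n_uncategorized=n_uncat)


def category_enrichment(
    profile_subset: CategoryProfile, profile_background: CategoryProfile
) -> pd.Series:
    """Per-category ratio subset proportion / background proportion.

    Zero background with nonzero subset yields +inf (flagged infinite);
    0/0 yields NaN.
    """
    ps = profile_subset.proportions
    pb = profile_background.proportions.reindex(ps.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = ps / pb
    ratio[(pb == 0) & (ps > 0)] = np.inf
    ratio[(pb == 0) & (ps == 0)] = np.nan
    return ratio


def split_counts_by_category(
    pair_genes: pd.DataFrame,
    cog_map: pd.DataFrame,
    bacteria: list,
    archaea: list,
    gene_col: str = "gene_b",
) -> dict:
    """Per-category bacteria x archaea RBH count matrices.

    ``pair_genes`` has one row per RBH gene pair with columns bacterium,
    archaeon and ``gene_col``; the category of a pair is looked up through
    ``gene_col`` (multi-category genes contribute to every category they map
    to). Categories with no assignments are omitted.
    """
    _validate_map(cog_map)
    merged = pair_genes.merge(cog_map, left_on=gene_col, right_on="gene_id", how="inner")
    out = {}
    for cat, sub in merged.groupby("category"):
        counts = (
            sub.groupby(["bacterium", "archaeon"]).size().unstack(fill_value=0)
            .reindex(index=bacteria, columns=archaea, fill_value=0)
        )
        out[cat] = counts
    return out


@dataclass
class CategoryFit:
    """Genome-size-corrected residuals for one COG category."""

    category: str
    residuals: ResidualMatrix
    fits: dict
    decorrelation_r2: pd.Series


def per_category_residuals(
    counts_by_category: Mapping[str, pd.DataFrame],
    sizes: pd.Series,
    min_nonzero: int = 5,
    seed: int = 0,
) -> tuple[dict, list]:
    """Fit the log-logistic size model per (archaeon, category).

    Categories with fewer than ``min_nonzero`` bacteria holding nonzero
    counts are skipped (returned in the second element). For fitted
    categories the residual-vs-size decorrelation R^2 is reported per
    archaeon.
    """
    fitted, skipped = {}, []
    for cat, counts in counts_by_category.items():
        nonzero = int((counts.sum(axis=1) > 0).sum())
        if nonzero < min_nonzero:
            skipped.append(cat)
            continue
        x = sizes.loc[counts.index].to_numpy(dtype=float)
        fits = {
            a: fit_log_logistic(x, counts[a].to_numpy(dtype=float), seed=seed, archaeon=a)
            for a in counts.columns
        }
        resid = residual_matrix(counts, fits, sizes)
        r2 = pd.Series(
            {a: decorrelation_check(resid.values[a].to_numpy(), x) for a in counts.columns}
        )
        fitted[cat] = CategoryFit(category=cat, residuals=resid, fits=fits, decorrelation_r2=r2)
    return fitted, skipped


def per_category_gc_adjust(
    category_fits: Mapping[str, CategoryFit], sizes: pd.Series, gc: pd.Series
) -> dict:
    """GC + size adjustment of each category's residuals (delegates per category)."""
    return {
        cat: secondary_residuals(cf.residuals, sizes, gc)
        for cat, cf in category_fits.items()
    }


def bonferroni_gate(p_values, n_tests: int = 15, alpha: float = 0.05) -> np.ndarray:
    """Significance flags: p < alpha / n_tests (strict inequality)."""
    p = np.asarray(p_values, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise DomainError("p-values must lie in (0, 1]")
    return p < alpha / n_tests
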