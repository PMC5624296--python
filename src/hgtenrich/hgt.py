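"""Flagging shared genes as horizontal transfers and orienting them.

The lineage probability index (LPI) is a score in [0, 1] that is high when a
gene's closest database matches come from the host genome's own lineage and
low when they are phylogenetically distant. A reciprocal best hit whose LPI is
below 0.2 on either side is tagged as horizontally transferred; the low-LPI
side is the recipient (the gene is "alien" there), which orients the transfer.

Precomputed LPI tables (gene_id -> lpi) are the fidelity path; a simplified
scorer, :func:`simple_lpi`, is provided for data without them — it scores a
gene by the fraction of leading taxonomic ranks its best non-self-genus match
shares with the host lineage, a deliberately reduced form of lineage-weighted
scoring (no candidate-list weighting).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .models import A2B, AMBIGUOUS, B2A, LINEAGE_RANKS, NO_TRANSFER, RBHPair

__all__ = [
    "LPIRecord",
    "simple_lpi",
    "flag_transfers",
    "assign_direction",
    "hgt_count_table",
]

#: columns of the HGT record table returned by :func:`flag_transfers`
HGT_COLUMNS = [
    "gene_b", "gene_a", "bacterium", "archaeon",
    "lpi_b", "lpi_a", "transferred", "direction",
]


@dataclass(frozen=True)
class LPIRecord:
    """A gene's LPI within its genome; ``lpi`` is None when unscorable."""

    gene_id: str
    genome: str
    lpi: Optional[float]


def simple_lpi(
    gene_id: str,
    genome: str,
    ranked_matches: Sequence,
    self_lineage: Sequence[str],
    exclude_rank: str = "genus",
) -> LPIRecord:
    """Score a gene by lineage agreement of its best non-self match.

    ``ranked_matches`` is a best-first sequence of 6-rank lineages (tuples
    domain..genus) of database matches. Matches sharing the host genome's
    name at ``exclude_rank`` are discarded (self-matches at e.g. the genus
    level carry no transfer information); the top survivor contributes
    lpi = (number of leading ranks shared with the host lineage) / 6.
    With no surviving matches the LPI is undefined (None).
    """
    if exclude_rank not in LINEAGE_RANKS:
        raise InputError(f"unknown rank {exclude_rank!r}")
    self_lineage = tuple(self_lineage)
    if len(self_lineage) != 6:
        raise InputError(f"gene {gene_id}: self lineage must have 6 ranks")
    excl = LINEAGE_RANKS.index(exclude_rank)
    for match in ranked_matches:
        lin = tuple(match)
        if len(lin) != 6:
            raise InputError(f"gene {gene_id}: match lineage must have 6 ranks")
        if lin[excl] == self_lineage[excl]:
            continue
        shared = 0
        for a, b in zip(lin, self_lineage):
            if a != b:
                break
            shared += 1
        return LPIRecord(gene_id=gene_id, genome=genome, lpi=shared / 6.0)
    return LPIRecord(gene_id=gene_id, genome=genome, lpi=None)


def assign_direction(lpi_b, lpi_a, transferred: bool, threshold: float = 0.2) -> str:
    """Orient a transfer from its two LPI values.

    A low LPI marks the recipient: lpi_b < threshold with lpi_a >= threshold
    means the gene is alien in the bacterium, i.e. transferred archaea ->
    bacteria (and conversely). Both sides low is ambiguous. Undefined LPIs
    (None/NaN) never count as low.
    """
    if not transferred:
        return NO_TRANSFER
    b_low = lpi_b is not None and not pd.isna(lpi_b) and lpi_b < threshold
    a_low = lpi_a is not None and not pd.isna(lpi_a) and lpi_a < threshold
    if b_low and a_low:
        return AMBIGUOUS
    if b_low:
        return A2B
    if a_low:
        return B2A
    # transferred must have come from a low LPI; unreachable for consistent input
    return AMBIGUOUS


def flag_transfers(
    pairs: Iterable[RBHPair],
    lpi_table: Mapping[str, float],
    threshold: float = 0.2,
) -> pd.DataFrame:
    """Tag RBH pairs as horizontally transferred via the LPI < threshold rule.

    A pair is transferred iff a *defined* LPI on either side is below the
    threshold; genes absent from ``lpi_table`` are treated as unscorable and
    never trigger a transfer. Returns a DataFrame with :data:`HGT_COLUMNS`.
    The vectorized rule is identical to :func:`assign_direction` row by row.
    """
    if isinstance(pairs, pd.DataFrame):
        df = pairs[["gene_b", "gene_a", "bacterium", "archaeon"]].copy()
    else:
        df = pd.DataFrame(
            [(p.gene_b, p.gene_a, p.bacterium, p.archaeon) for p in pairs],
            columns=["gene_b", "gene_a", "bacterium", "archaeon"],
        )
    if not isinstance(lpi_table, pd.Series):
        lpi_table = pd.Series(lpi_table, dtype=float)
    lb = df["gene_b"].map(lpi_table)
    la = df["gene_a"].map(lpi_table)
    b_low = lb.notna() & (lb < threshold)
    a_low = la.notna() & (la < threshold)
    df["lpi_b"] = lb
    df["lpi_a"] = la
    df["transferred"] = (b_low | a_low).to_numpy()
    df["direction"] = np.select(
        [b_low & a_low, b_low, a_low],
        [AMBIGUOUS, A2B, B2A],
        default=NO_TRANSFER,
    )
    return df[HGT_COLUMNS]


def hgt_count_table(records: pd.DataFrame) -> pd.DataFrame:
    """Transferred-gene counts per (bacterium, archaeon), split by direction.

    Columns: total, a2b, b2a, ambiguous; total = a2b + b2a + ambiguous.
    Pairs with no transferred gene are absent (treat missing as zero).
    """
    t = records.loc[records["transferred"]]
    if t.empty:
        idx = pd.MultiIndex.from_arrays([[], []], names=["bacterium", "archaeon"])
        return pd.DataFrame(columns=["total", "a2b", "b2a", "ambiguous"], index=idx)
    tab = (
        t.groupby(["bacterium", "archaeon"])["direction"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=[A2B, B2A, AMBIGUOUS], fill_value=0)
    )
    out = pd.DataFrame(
        {"a2b": tab[A2B], "b2a": tab[B2A], "ambiguous": tab[AMBIGUOUS]}
    )
    out.insert(0, "total", out.sum(axis=1))
    return out
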