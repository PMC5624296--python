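"""Reciprocal best hits from pairwise protein alignment tables.

Hits arrive as a DataFrame in the 12-column BLAST tabular dialect augmented
with ``query_genome``, ``subject_genome`` and ``query_len`` (joined from a
gene sidecar table, see :mod:`hgtenrich.io`). Filtering keeps hits with
e-value <= 1e-10 whose alignment covers more than 50% of the query; best
hits maximize bitscore (ties: lower e-value, then lexicographically smaller
subject id); a reciprocal best hit is a mutual best pair across a genome
pair and stands proxy for a shared (orthologous) gene.
"""
from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .models import BestHit, GenomeMeta, RBHPair

__all__ = [
    "filter_hits",
    "best_hits",
    "best_hits_frame",
    "reciprocal_best_hits",
    "reciprocal_best_hits_frame",
    "rbh_count_matrix",
]

#: columns required on a hit table, beyond the outfmt-6 basics
HIT_COLUMNS = [
    "query_id", "subject_id", "query_genome", "subject_genome",
    "percent_identity", "align_len", "evalue", "bitscore", "query_len",
]


def filter_hits(
    hits: pd.DataFrame, max_evalue: float = 1e-10, min_query_cov: float = 0.5
) -> pd.DataFrame:
    """Keep hits with evalue <= max_evalue and align_len > min_query_cov * query_len.

    Coverage uses the query length only, and the inequality is strict. Row
    order is preserved. Rows with missing query_len raise, naming the genes.
    """
    qlen = pd.to_numeric(hits["query_len"], errors="coerce")
    if qlen.isna().any():
        bad = sorted(hits.loc[qlen.isna(), "query_id"].unique().tolist())
        raise InputError(f"missing query_len for genes: {bad}")
    keep = (hits["evalue"] <= max_evalue) & (hits["align_len"] > min_query_cov * qlen)
    return hits.loc[keep]


def best_hits_frame(hits: pd.DataFrame) -> pd.DataFrame:
    """One row per (query gene, subject genome): its best subject.

    Self-genome hits are excluded. Best = highest bitscore; ties broken by
    lower e-value, then lexicographically smaller subject id.
    """
    h = hits.loc[hits["query_genome"] != hits["subject_genome"]]
    if h.empty:
        return pd.DataFrame(columns=["query_id", "subject_id", "query_genome",
                                     "subject_genome"])
    return h.sort_values(
        ["bitscore", "evalue", "subject_id"],
        ascending=[False, True, True],
        kind="mergesort",
    ).drop_duplicates(["query_id", "subject_genome"], keep="first")[
        ["query_id", "subject_id", "query_genome", "subject_genome"]
    ]


def best_hits(hits: pd.DataFrame) -> dict:
    """Map (query gene, subject genome) -> :class:`BestHit` (see best_hits_frame)."""
    return {
        (row.query_id, row.subject_genome): BestHit(
            subject_id=row.subject_id,
            query_genome=row.query_genome,
            subject_genome=row.subject_genome,
        )
        for row in best_hits_frame(hits).itertuples(index=False)
    }


def reciprocal_best_hits(best_fwd: Mapping, best_rev: Mapping) -> list[RBHPair]:
    """Mutual best pairs: (x, y) with best_fwd(x)=y and best_rev(y)=x.

    ``best_fwd`` must be keyed by bacterial query genes (targets archaea) and
    ``best_rev`` by archaeal query genes, as produced by :func:`best_hits`.
    """
    pairs = []
    for (q, target_genome), bh in best_fwd.items():
        back = best_rev.get((bh.subject_id, bh.query_genome))
        if back is not None and back.subject_id == q:
            pairs.append(
                RBHPair(
                    gene_b=q, gene_a=bh.subject_id,
                    bacterium=bh.query_genome, archaeon=target_genome,
                )
            )
    pairs.sort(key=lambda p: (p.bacterium, p.archaeon, p.gene_b))
    return pairs


def reciprocal_best_hits_frame(best_fwd: pd.DataFrame, best_rev: pd.DataFrame) -> pd.DataFrame:
    """Vectorized mutual-best computation on :func:`best_hits_frame` outputs.

    Returns a DataFrame with columns gene_b, gene_a, bacterium, archaeon,
    equal (as a set) to :func:`reciprocal_best_hits` on the corresponding maps.
    """
    if best_fwd.empty or best_rev.empty:
        return pd.DataFrame(columns=["gene_b", "gene_a", "bacterium", "archaeon"])
    merged = best_fwd.merge(
        best_rev,
        left_on=["subject_id", "query_genome"],
        right_on=["query_id", "subject_genome"],
        suffixes=("_f", "_r"),
    )
    mutual = merged.loc[merged["query_id_f"] == merged["subject_id_r"]]
    out = pd.DataFrame(
        {
            "gene_b": mutual["query_id_f"].to_numpy(),
            "gene_a": mutual["subject_id_f"].to_numpy(),
            "bacterium": mutual["query_genome_f"].to_numpy(),
            "archaeon": mutual["subject_genome_f"].to_numpy(),
        }
    )
    return out.sort_values(["bacterium", "archaeon", "gene_b"], ignore_index=True)


def rbh_count_matrix(pairs, genomes: Sequence[GenomeMeta]) -> pd.DataFrame:
    """Bacteria x archaea table of RBH counts; cells with no pair are 0.

    ``pairs`` may be an iterable of :class:`RBHPair` or a DataFrame with
    columns bacterium/archaeon (and gene ids).
    """
    bacteria = [g.id for g in genomes if g.domain == "bacteria"]
    archaea = [g.id for g in genomes if g.domain == "archaea"]
    if not isinstance(pairs, pd.DataFrame):
        pairs = pd.DataFrame(
            [(p.gene_b, p.gene_a, p.bacterium, p.archaeon) for p in pairs],
            columns=["gene_b", "gene_a", "bacterium", "archaeon"],
        )
    if len(pairs):
        bad_b = ~pairs["bacterium"].isin(set(bacteria))
        bad_a = ~pairs["archaeon"].isin(set(archaea))
        if bad_b.any() or bad_a.any():
            row = pairs.loc[bad_b | bad_a].iloc[0]
            raise InputError(
                f"pair ({row.gene_b}, {row.gene_a}) references unknown genome "
                f"{row.bacterium!r}/{row.archaeon!r}"
            )
    counts = (
        pairs.groupby(["bacterium", "archaeon"]).size().unstack(fill_value=0)
        if len(pairs)
        else pd.DataFrame()
    )
    return counts.reindex(index=bacteria, columns=archaea, fill_value=0).astype(int)
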