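"""Readers/writers for the plain-text formats the pipeline exchanges.

Everything is TSV with a documented header except the hit table, which is the
externally-defined 12-column BLAST tabular (outfmt-6) dialect plus a gene
sidecar mapping gene ids to genomes and lengths. Files written by the
pipeline carry a comment header with the configuration hash and seed so
reruns can be verified; readers skip '#' comment lines.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .models import (
    DOMAINS,
    GenomeMeta,
    O2_CLASSES,
    SALT_CLASSES,
    SyntheticTruth,
    TEMP_CLASSES,
)

__all__ = [
    "config_hash",
    "write_tsv",
    "read_tsv",
    "write_metadata",
    "read_metadata",
    "write_blast_tab",
    "read_blast_tab",
    "read_lpi",
    "write_lpi",
    "read_cog",
    "write_cog",
    "read_distances",
    "write_distances",
    "write_truth",
    "read_truth",
]

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def config_hash(config_dict: dict) -> str:
    """Short stable hash of a configuration mapping."""
    payload = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header_comment(cfg_hash: Optional[str], seed: Optional[int]) -> str:
    if cfg_hash is None:
        return ""
    return f"# hgt-enrich config={cfg_hash} seed={seed}\n"


def write_tsv(df: pd.DataFrame, path, cfg_hash: Optional[str] = None,
              seed: Optional[int] = None, index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_comment(cfg_hash, seed))
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# -- genome metadata ---------------------------------------------------------

_META_COLUMNS = ["id", "domain", "n_genes", "gc", "temp_class", "o2_class",
                 "salt_class", "pathogen", "habitat", "lineage"]


def write_metadata(genomes: Sequence[GenomeMeta], path, cfg_hash=None, seed=None) -> None:
    rows = [
        (g.id, g.domain, g.n_genes, g.gc, g.temp_class, g.o2_class, g.salt_class,
         int(g.pathogen), g.habitat, ";".join(g.lineage))
        for g in genomes
    ]
    write_tsv(pd.DataFrame(rows, columns=_META_COLUMNS), path, cfg_hash, seed)


def read_metadata(path) -> list:
    """Parse and validate a metadata TSV; errors carry file:line locations."""
    df = read_tsv(path, dtype=str)
    missing = set(_META_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    genomes = []
    # data line numbers: header is line 1 (+1 per leading comment line)
    n_comments = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n_comments += 1
            else:
                break
    for i, row in df.iterrows():
        lineno = n_comments + 2 + int(i)
        for col, allowed in (("domain", DOMAINS), ("temp_class", TEMP_CLASSES),
                             ("o2_class", O2_CLASSES), ("salt_class", SALT_CLASSES)):
            if row[col] not in allowed:
                raise InputError(f"{path}:{lineno}: invalid {col} {row[col]!r}")
        try:
            genomes.append(
                GenomeMeta(
                    id=row["id"], domain=row["domain"], n_genes=int(row["n_genes"]),
                    gc=float(row["gc"]), temp_class=row["temp_class"],
                    o2_class=row["o2_class"], salt_class=row["salt_class"],
                    pathogen=bool(int(row["pathogen"])), habitat=row["habitat"],
                    lineage=tuple(row["lineage"].split(";")),
                )
            )
        except (ValueError, InputError) as exc:
            raise InputError(f"{path}:{lineno}: {exc}") from exc
    return genomes


# -- hit tables --------------------------------------------------------------

def write_blast_tab(hits: pd.DataFrame, genes: pd.DataFrame, hits_path, genes_path,
                    cfg_hash=None, seed=None) -> None:
    """Write the 12-column tabular dialect plus the gene sidecar TSV.

    Fields the internal table does not model (mismatch, gapopen, coordinates)
    are written as placeholder values.
    """
    n = len(hits)
    out = pd.DataFrame(
        {
            "qseqid": hits["query_id"], "sseqid": hits["subject_id"],
            "pident": hits["percent_identity"], "length": hits["align_len"],
            "mismatch": 0, "gapopen": 0, "qstart": 1, "qend": hits["align_len"],
            "sstart": 1, "send": hits["align_len"],
            "evalue": hits["evalue"], "bitscore": hits["bitscore"],
        }
    )
    path = Path(hits_path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_comment(cfg_hash, seed))
        out.to_csv(fh, sep="\t", index=False, header=False)
    write_tsv(genes, genes_path, cfg_hash, seed)


def read_blast_tab(hits_path, genes_path) -> pd.DataFrame:
    """Read outfmt-6 hits and join genome ids and query lengths from the sidecar."""
    hits = pd.read_csv(hits_path, sep="\t", comment="#", header=None,
                       names=OUTFMT6_COLUMNS)
    genes = read_tsv(genes_path)
    for col in ("gene_id", "genome", "length"):
        if col not in genes.columns:
            raise InputError(f"{genes_path}: missing column {col!r}")
    gmap = genes.set_index("gene_id")
    for col, src in (("query_genome", "qseqid"), ("subject_genome", "sseqid")):
        mapped = hits[src].map(gmap["genome"])
        if mapped.isna().any():
            bad = sorted(hits.loc[mapped.isna(), src].unique().tolist())[:5]
            raise InputError(f"{hits_path}: genes missing from sidecar: {bad}")
        hits[col] = mapped
    hits["query_len"] = hits["qseqid"].map(gmap["length"])
    return hits.rename(
        columns={"qseqid": "query_id", "sseqid": "subject_id",
                 "pident": "percent_identity", "length": "align_len"}
    )[["query_id", "subject_id", "query_genome", "subject_genome",
       "percent_identity", "align_len", "evalue", "bitscore", "query_len"]]


# -- simple two-column tables ------------------------------------------------

def _read_two_col(path, col2: str, lo=None, hi=None) -> pd.DataFrame:
    df = read_tsv(path)
    if "gene_id" not in df.columns or col2 not in df.columns:
        raise InputError(f"{path}: expected columns gene_id, {col2}")
    if lo is not None:
        v = pd.to_numeric(df[col2], errors="coerce")
        bad = v.isna() | (v < lo) | (v > hi)
        if bad.any():
            raise InputError(f"{path}: {col2} outside [{lo}, {hi}] at data row "
                             f"{int(bad.idxmax()) + 1}")
        df[col2] = v
    return df


def read_lpi(path) -> pd.DataFrame:
    return _read_two_col(path, "lpi", 0.0, 1.0)


def write_lpi(lpi: pd.DataFrame, path, cfg_hash=None, seed=None) -> None:
    write_tsv(lpi, path, cfg_hash, seed)


def read_cog(path) -> pd.DataFrame:
    return _read_two_col(path, "category")


def write_cog(cog: pd.DataFrame, path, cfg_hash=None, seed=None) -> None:
    write_tsv(cog, path, cfg_hash, seed)


def read_distances(path) -> pd.Series:
    df = read_tsv(path)
    if "bacterium" not in df.columns or "root_distance" not in df.columns:
        raise InputError(f"{path}: expected columns bacterium, root_distance")
    return df.set_index("bacterium")["root_distance"].astype(float)


def write_distances(distances: pd.Series, path, cfg_hash=None, seed=None) -> None:
    df = distances.rename("root_distance").rename_axis("bacterium").reset_index()
    write_tsv(df, path, cfg_hash, seed)


# -- truth ledger ------------------------------------------------------------

def write_truth(truth: SyntheticTruth, path) -> None:
    payload = {
        "enriched_pairs": sorted([list(p) for p in truth.enriched_pairs]),
        "transferred_genes": [
            [gb, ga, d] for (gb, ga), d in sorted(truth.transferred_genes.items())
        ],
        "true_fit_params": {a: list(p) for a, p in sorted(truth.true_fit_params.items())},
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=1))


def read_truth(path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    return SyntheticTruth(
        enriched_pairs={tuple(p) for p in payload["enriched_pairs"]},
        transferred_genes={(gb, ga): d for gb, ga, d in payload["transferred_genes"]},
        true_fit_params={a: tuple(p) for a, p in payload["true_fit_params"].items()},
    )
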