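"""Synthetic archaea-bacteria communities with known ground truth.

The generator emits everything the analysis consumes — genome metadata,
a BLAST-style hit table with a gene sidecar, per-gene LPI and COG tables,
per-bacterium 16S root distances — together with a :class:`SyntheticTruth`
ledger of the injected enrichments and transfers, so recovery can be scored
exactly.

Statistical structure emulated:

* shared-gene (RBH) counts follow a per-archaeon four-parameter log-logistic
  curve in bacterial gene count, plus Gaussian noise (the noise model is an
  assumption; real residuals are heavier-tailed);
* a fraction ``p_enrich_matched`` of phenotype-matched pairs (same oxygen
  class, or both/neither (hyper)thermophilic) receives an injected excess of
  ``enrich_effect * noise_sd`` RBHs, mirrored by extra archaea->bacteria
  transfers among those pairs' genes;
* background transfers run bacteria->archaea : archaea->bacteria at
  ``direction_ratio`` (default 5:1) with a mean of ``mean_a2b`` (default 4)
  archaea->bacteria transfers per genome pair;
* transferred genes draw recipient-side LPI uniformly on [0, 0.15] and all
  other LPIs uniformly on [0.3, 1.0], leaving a guard band around the 0.2
  decision threshold so the flagged set is unambiguous;
* transferred genes are transporters (COG category P) with probability
  ``hgt_transporter_frac`` (default 15%) against ``background_transporter_frac``
  (default 5%) otherwise;
* 16S root distances correlate with a bacterium's baseline sharing level at
  strength ``mantel_coupling``.

Each operation draws from its own seed stream derived from ``config.seed``,
so outputs are deterministic per operation regardless of call order.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError
from .models import (
    A2B,
    B2A,
    GenomeMeta,
    SimConfig,
    SyntheticTruth,
    split_domains,
)
from .size_model import log_logistic

__all__ = [
    "generate_community",
    "generate_rbh_matrix",
    "generate_gene_tables",
    "generate_root_distances",
    "phenotype_matched",
]

# per-operation seed-stream keys
_K_COMMUNITY, _K_PARAMS, _K_RBH, _K_GENES, _K_ROOT = 11, 13, 17, 19, 23

_HABITATS = {
    ("hyperthermophile", None): ("hot_spring", "hydrothermal_vent"),
    ("thermophile", None): ("hot_spring", "oil_well"),
    (None, "anaerobe"): ("sediment", "gut", "sludge"),
    (None, None): ("marine", "soil", "freshwater"),
}

_NON_TRANSPORTER_CATEGORIES = list("CEGHFJKLMNOTUV")


def _rng(key: int, seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([key, seed]))


def _draw_class(rng, freqs: dict) -> str:
    names = sorted(freqs)
    p = np.array([freqs[n] for n in names], dtype=float)
    return str(rng.choice(names, p=p / p.sum()))


def _habitat(rng, temp_class: str, o2_class: str) -> str:
    for (t, o), options in _HABITATS.items():
        if (t is None or t == temp_class) and (o is None or o == o2_class):
            return str(rng.choice(options))
    return "soil"


def _lineage(rng, domain: str, genome_id: str) -> tuple:
    dom = domain.capitalize()
    phy = f"{dom[0]}_phy{rng.integers(8)}"
    cls = f"{phy}_c{rng.integers(3)}"
    order = f"{cls}_o{rng.integers(3)}"
    fam = f"{order}_f{rng.integers(3)}"
    return (dom, phy, cls, order, fam, f"genus_{genome_id}")


def generate_community(config: SimConfig) -> tuple[list[GenomeMeta], SyntheticTruth]:
    """Draw labelled genomes for both domains; returns (genomes, truth stub)."""
    config.validate()
    rng = _rng(_K_COMMUNITY, config.seed)
    genomes: list[GenomeMeta] = []
    for domain, n, o2f, tf, sf in (
        ("bacteria", config.n_bacteria, config.bacteria_o2_freqs, config.bacteria_temp_freqs,
         config.bacteria_salt_freqs),
        ("archaea", config.n_archaea, config.archaea_o2_freqs, config.archaea_temp_freqs,
         config.archaea_salt_freqs),
    ):
        prefix = "B" if domain == "bacteria" else "A"
        for i in range(n):
            gid = f"{prefix}{i:04d}"
            temp = _draw_class(rng, tf)
            o2 = _draw_class(rng, o2f)
            salt = _draw_class(rng, sf)
            if domain == "bacteria":
                mean, sd = config.size_range[temp]
                lo, hi = config.bacteria_size_bounds
                gc_mean = {"aerobe": 59.0, "anaerobe": 45.0, "facultative": 52.0}[o2]
                pathogen = bool(rng.random() < config.pathogen_frac)
            else:
                mean, sd = config.archaea_size
                lo, hi = config.archaea_size_bounds
                gc_mean = 50.0
                pathogen = False
            n_genes = int(np.clip(np.round(rng.normal(mean, sd)), lo, hi))
            gc = float(np.clip(rng.normal(gc_mean, 8.0), 20.0, 80.0))
            genomes.append(
                GenomeMeta(
                    id=gid, domain=domain, n_genes=n_genes, gc=gc,
                    temp_class=temp, o2_class=o2, salt_class=salt,
                    pathogen=pathogen, habitat=_habitat(rng, temp, o2),
                    lineage=_lineage(rng, domain, gid),
                )
            )
    return genomes, SyntheticTruth()


def phenotype_matched(b: GenomeMeta, a: GenomeMeta) -> bool:
    """Matched = same oxygen class, or same temperature group.

    Temperature groups pool thermophiles with hyperthermophiles (mesophile
    vs (hyper)thermophile).
    """
    if b.o2_class == a.o2_class:
        return True
    group = lambda g: "mesophile" if g.temp_class == "mesophile" else "thermophile"
    return group(b) == group(a)


def _true_params(config: SimConfig, archaea_ids: list) -> dict:
    rng = _rng(_K_PARAMS, config.seed)
    out = {}
    for a in archaea_ids:
        out[a] = tuple(
            float(rng.uniform(*config.baseline_params[p])) for p in ("b", "c", "d", "e")
        )
    return out


def generate_rbh_matrix(
    genomes: list, config: SimConfig
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Shared-gene count matrix with injected phenotype-matched enrichments.

    count(b, a) = round(loglogistic(n_genes_b; params_a) + noise + delta),
    clipped to [0, min(n_genes_b, n_genes_a)], where delta =
    enrich_effect * noise_sd on injected pairs. Truth records the injections
    and the per-archaeon true parameters.
    """
    config.validate()
    bacteria, archaea = split_domains(genomes)
    if not bacteria or not archaea:
        raise InputError("need at least one genome of each domain")
    params = _true_params(config, [a.id for a in archaea])
    rng = _rng(_K_RBH, config.seed)
    nb, na = len(bacteria), len(archaea)
    sizes_b = np.array([g.n_genes for g in bacteria], dtype=float)
    sizes_a = np.array([g.n_genes for g in archaea], dtype=float)

    matched = np.array(
        [[phenotype_matched(b, a) for a in archaea] for b in bacteria], dtype=bool
    )
    injected = matched & (rng.random((nb, na)) < config.p_enrich_matched)
    noise = (
        rng.normal(0.0, config.noise_sd, size=(nb, na)) if config.noise_sd > 0
        else np.zeros((nb, na))
    )
    curve = np.column_stack(
        [log_logistic(sizes_b, *params[a.id]) for a in archaea]
    )
    delta = config.enrich_effect * config.noise_sd
    raw = np.rint(curve + noise + delta * injected)
    cap = np.minimum(sizes_b[:, None], sizes_a[None, :])
    counts = np.clip(raw, 0, cap).astype(int)

    matrix = pd.DataFrame(
        counts, index=[b.id for b in bacteria], columns=[a.id for a in archaea]
    )
    truth = SyntheticTruth(
        enriched_pairs={
            (archaea[j].id, bacteria[i].id) for i, j in zip(*np.nonzero(injected))
        },
        true_fit_params=params,
    )
    return matrix, truth


def generate_gene_tables(
    genomes: list,
    rbh_matrix: pd.DataFrame,
    truth: SyntheticTruth,
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Emit gene-level tables for every counted RBH.

    Returns (hits, genes, lpi, cog):
    ``hits`` — forward (bacterial query) and reverse rows in the outfmt-6
    dialect plus genome/length columns; all true RBH partners are mutual best
    hits, and a small rate of sub-threshold decoy hits exercises filtering.
    ``genes`` — sidecar (gene_id, genome, length). ``lpi`` — (gene_id, lpi).
    ``cog`` — (gene_id, category). ``truth.transferred_genes`` is populated
    in place with (gene_b, gene_a) -> direction.
    """
    config.validate()
    bacteria, archaea = split_domains(genomes)
    meta = {g.id: g for g in genomes}
    for b in rbh_matrix.index:
        if b not in meta:
            raise InputError(f"rbh_matrix row {b!r} not among genomes")
    rng = _rng(_K_GENES, config.seed)
    extra = int(np.rint(config.enrich_effect * config.noise_sd))

    hit_rows, gene_rows, lpi_rows, cog_rows = [], [], [], []
    transferred = {}

    for bi, b in enumerate(rbh_matrix.index):
        for aj, a in enumerate(rbh_matrix.columns):
            k = int(rbh_matrix.iloc[bi, aj])
            if k <= 0:
                continue
            genes_b = [f"{b}.{a}.{j}b" for j in range(k)]
            genes_a = [f"{b}.{a}.{j}a" for j in range(k)]
            len_b = rng.integers(150, 600, size=k)
            len_a = rng.integers(150, 600, size=k)

            # transfer draws: background both directions + injected excess a->b
            n_b2a = rng.poisson(config.mean_a2b * config.direction_ratio)
            n_a2b = rng.poisson(config.mean_a2b)
            if (a, b) in truth.enriched_pairs:
                n_a2b += extra
            dirs = np.array([B2A] * n_b2a + [A2B] * n_a2b)
            if len(dirs) > k:
                dirs = rng.choice(dirs, size=k, replace=False)
            tidx = rng.choice(k, size=len(dirs), replace=False)

            lpi_b = rng.uniform(0.3, 1.0, size=k)
            lpi_a = rng.uniform(0.3, 1.0, size=k)
            is_transfer = np.zeros(k, dtype=bool)
            for i, d in zip(tidx, dirs):
                is_transfer[i] = True
                if d == A2B:
                    lpi_b[i] = rng.uniform(0.0, 0.15)
                else:
                    lpi_a[i] = rng.uniform(0.0, 0.15)
                transferred[(genes_b[i], genes_a[i])] = str(d)

            p_transporter = np.where(
                is_transfer, config.hgt_transporter_frac, config.background_transporter_frac
            )
            is_p = rng.random(k) < p_transporter
            cats = np.array(rng.choice(_NON_TRANSPORTER_CATEGORIES, size=k))
            cats[is_p] = "P"

            # mutual best hits between partners (vectorized per pair)
            bits = rng.uniform(200.0, 500.0, size=k)
            ev = 10.0 ** (-rng.uniform(15.0, 60.0, size=k))
            pid = rng.uniform(30.0, 70.0, size=k)
            gb = np.array(genes_b)
            ga = np.array(genes_a)
            al_f = np.ceil(0.8 * len_b).astype(int)
            al_r = np.ceil(0.8 * len_a).astype(int)
            hit_rows.append(dict(query_id=gb, subject_id=ga, query_genome=b,
                                 subject_genome=a, percent_identity=pid,
                                 align_len=al_f, evalue=ev, bitscore=bits,
                                 query_len=len_b))
            hit_rows.append(dict(query_id=ga, subject_id=gb, query_genome=a,
                                 subject_genome=b, percent_identity=pid,
                                 align_len=al_r, evalue=ev, bitscore=bits,
                                 query_len=len_a))
            # sub-threshold decoys (weak e-value): removed by the filter
            n_decoy = rng.binomial(k, config.decoy_hit_rate)
            if n_decoy:
                dj = rng.choice(k, size=n_decoy, replace=False)
                hit_rows.append(dict(query_id=gb[dj], subject_id=ga[(dj + 1) % k],
                                     query_genome=b, subject_genome=a,
                                     percent_identity=25.0, align_len=al_f[dj],
                                     evalue=1e-5, bitscore=40.0, query_len=len_b[dj]))

            gene_rows.append((np.concatenate([gb, ga]),
                              np.concatenate([np.repeat(b, k), np.repeat(a, k)]),
                              np.concatenate([len_b, len_a])))
            lpi_rows.append((np.concatenate([gb, ga]), np.concatenate([lpi_b, lpi_a])))
            cog_rows.append((np.concatenate([gb, ga]), np.concatenate([cats, cats])))

    hit_cols = ["query_id", "subject_id", "query_genome", "subject_genome",
                "percent_identity", "align_len", "evalue", "bitscore", "query_len"]
    if hit_rows:
        stacked = {c: [] for c in hit_cols}
        for block in hit_rows:
            n = len(block["query_id"])
            for c in hit_cols:
                v = block[c]
                stacked[c].append(v if isinstance(v, np.ndarray) else np.repeat(v, n))
        hits = pd.DataFrame({c: np.concatenate(stacked[c]) for c in hit_cols})
    else:
        hits = pd.DataFrame(columns=hit_cols)

    def _cat(blocks, i):
        return np.concatenate([blk[i] for blk in blocks]) if blocks else np.array([])

    genes = pd.DataFrame({"gene_id": _cat(gene_rows, 0), "genome": _cat(gene_rows, 1),
                          "length": _cat(gene_rows, 2)})
    lpi = pd.DataFrame({"gene_id": _cat(lpi_rows, 0), "lpi": _cat(lpi_rows, 1)})
    cog = pd.DataFrame({"gene_id": _cat(cog_rows, 0), "category": _cat(cog_rows, 1)})
    truth.transferred_genes = transferred
    return hits, genes, lpi, cog


def generate_root_distances(genomes: list, config: SimConfig) -> pd.Series:
    """Per-bacterium 16S distance to the archaeal root.

    Distances are positive and correlate (strength ``mantel_coupling``) with
    the bacterium's baseline sharing level, i.e. the mean of the true
    log-logistic curves at its gene count — deep-branching bacteria share
    more with archaea.
    """
    config.validate()
    bacteria, archaea = split_domains(genomes)
    if not bacteria:
        raise InputError("no bacteria present")
    params = _true_params(config, [a.id for a in archaea])
    sizes = np.array([g.n_genes for g in bacteria], dtype=float)
    if archaea:
        base = np.mean([log_logistic(sizes, *params[a.id]) for a in archaea], axis=0)
    else:
        base = np.zeros(len(bacteria))
    sd = np.std(base)
    z = (base - base.mean()) / sd if sd > 0 else np.zeros_like(base)
    rng = _rng(_K_ROOT, config.seed)
    c = config.mantel_coupling
    eps = rng.standard_normal(len(bacteria))
    d = 2.0 + 0.5 * (c * z + np.sqrt(max(0.0, 1.0 - c * c)) * eps)
    d = np.clip(d, 1e-3, None)
    return pd.Series(d, index=[g.id for g in bacteria], name="root_distance")
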