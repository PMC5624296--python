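"""Canned simulation studies that validate the method end to end.

Each function generates synthetic communities under the study conditions,
runs the relevant part of the analysis from scratch, and returns summary
metrics as a flat dict. They back both the validation test suite and the
reproduction script; problem sizes are chosen so the full battery runs on a
single CPU in a few minutes.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import binom

from . import enrichment, size_model, synthetic_data
from .models import SimConfig
from .pipeline import RunConfig, run_pipeline

__all__ = [
    "loglogistic_recovery",
    "null_calibration",
    "enrichment_recovery",
    "model_comparison",
    "cog_recovery",
]


def _fit_residuals(genomes, matrix, seed=0):
    sizes = pd.Series({g.id: float(g.n_genes) for g in genomes})
    x = sizes.loc[matrix.index].to_numpy()
    fits = {
        a: size_model.fit_log_logistic(x, matrix[a].to_numpy(float), seed=seed,
                                       archaeon=a)
        for a in matrix.columns
    }
    return size_model.residual_matrix(matrix, fits, sizes), fits, x


def loglogistic_recovery(seed: int, n_bacteria: int = 400, n_archaea: int = 40,
                         rel_tol: float = 0.10) -> dict:
    """Fit recovery of known per-archaeon (b, c, d, e) under noise_sd = 5.

    Returns the fraction of archaea whose four parameters are all within
    ``rel_tol`` relative error, and the worst residual-vs-size R^2.
    """
    cfg = SimConfig(n_bacteria=n_bacteria, n_archaea=n_archaea, seed=seed)
    genomes, _ = synthetic_data.generate_community(cfg)
    matrix, truth = synthetic_data.generate_rbh_matrix(genomes, cfg)
    residuals, fits, x = _fit_residuals(genomes, matrix, seed)
    n_ok = 0
    r2 = []
    for a, f in fits.items():
        true = truth.true_fit_params[a]
        rel = [abs(got - want) / abs(want)
               for got, want in zip((f.b, f.c, f.d, f.e), true)]
        n_ok += max(rel) <= rel_tol
        r2.append(size_model.decorrelation_check(residuals.values[a].to_numpy(), x))
    return {
        "recovery_rate": n_ok / n_archaea,
        "max_decorrelation_r2": float(np.nanmax(r2)),
        "n_archaea": n_archaea,
    }


def null_calibration(seed: int, n_seeds: int = 20, n_bacteria: int = 400,
                     n_archaea: int = 10, z_threshold: float = 1.96) -> dict:
    """Enrichment calls with no injected signal.

    Pools the enriched-cell fraction over ``n_seeds`` independent
    communities and compares the per-bacterium >=k enrichment rates
    (k = 1, 3) with the binomial prediction of
    :func:`~hgtenrich.enrichment.expected_false_positives`.
    """
    alpha = 0.025  # one-sided nominal rate at z = 1.96
    n_cells = n_enriched = 0
    frac_k = {1: [], 3: []}
    for i in range(n_seeds):
        cfg = SimConfig(n_bacteria=n_bacteria, n_archaea=n_archaea,
                        p_enrich_matched=0.0, seed=seed + i)
        genomes, _ = synthetic_data.generate_community(cfg)
        matrix, _ = synthetic_data.generate_rbh_matrix(genomes, cfg)
        residuals, _, _ = _fit_residuals(genomes, matrix, seed + i)
        pairs = enrichment.call_enriched_pairs(residuals, z_threshold)
        n_cells += matrix.size
        n_enriched += len(pairs)
        per_b = pd.Series([p.bacterium for p in pairs]).value_counts()
        counts = per_b.reindex(matrix.index, fill_value=0)
        for k in frac_k:
            frac_k[k].append(float((counts >= k).mean()))
    lo = float(binom.ppf(0.005, n_cells, alpha) / n_cells)
    hi = float(binom.ppf(0.995, n_cells, alpha) / n_cells)
    out = {
        "null_rate": n_enriched / n_cells,
        "envelope_lo": lo,
        "envelope_hi": hi,
        "n_cells": n_cells,
    }
    n_total_bacteria = n_seeds * n_bacteria
    for k in (1, 3):
        pred, _ = enrichment.expected_false_positives(n_bacteria, n_archaea, alpha, k)
        sim = float(np.mean(frac_k[k]))
        out[f"frac_ge{k}_sim"] = sim
        out[f"frac_ge{k}_pred"] = pred
        out[f"frac_ge{k}_3se"] = 3 * float(
            np.sqrt(pred * (1 - pred) / n_total_bacteria)
        )
    return out


def enrichment_recovery(seed: int, n_bacteria: int = 250, n_archaea: int = 20,
                        n_perm: int = 999) -> dict:
    """Full-pipeline recovery of injected enrichments plus phenotype tests.

    Runs every stage (hit table onwards) on one community with the default
    injection conditions (5% of phenotype-matched pairs, +4 noise SD) and
    reports sensitivity/false-discovery proportion of the corroborated
    enriched-pair set, the crossed two-way ANOSIM for oxygen and
    temperature, the Mantel statistic, the pooled non-enriched direction
    ratio, and whether the transfer flags matched the generator's ledger
    exactly.
    """
    cfg = RunConfig(sim=SimConfig(n_bacteria=n_bacteria, n_archaea=n_archaea,
                                  seed=seed), n_perm=n_perm)
    report = run_pipeline(cfg)
    rec = report["recovery"]
    stats = report["stages"]["stats"]
    return {
        "sensitivity": rec["sensitivity"],
        "false_discovery_proportion": rec["false_discovery_proportion"],
        "direction_ratio": rec["direction_ratio_nonenriched"],
        "n_a2b_nonenriched": rec["n_a2b_nonenriched"],
        "n_b2a_nonenriched": rec["n_b2a_nonenriched"],
        "transfer_flags_match_truth": rec["transfer_flags_match_truth"],
        "anosim_oxygen_R": stats["anosim_oxygen_R"],
        "anosim_oxygen_p": stats["anosim_oxygen_p"],
        "anosim_temperature_R": stats["anosim_temperature_R"],
        "anosim_temperature_p": stats["anosim_temperature_p"],
        "mantel_r": stats["mantel_r"],
        "mantel_p": stats["mantel_p"],
        "n_true_enriched": report["stages"]["simulate"]["n_true_enriched_pairs"],
    }


def model_comparison(seed: int, n_seeds: int = 20, n_bacteria: int = 300,
                     n_archaea: int = 10, size_cut: float = 5000.0) -> dict:
    """Log-logistic vs Korbel-scale prediction error for large genomes.

    For each community, both models are fit per archaeon and their RMSE is
    compared on bacteria with more than ``size_cut`` genes; reports the
    fraction of communities where the log-logistic fit is at least as good.
    """
    wins = 0
    for i in range(n_seeds):
        cfg = SimConfig(n_bacteria=n_bacteria, n_archaea=n_archaea,
                        p_enrich_matched=0.0, seed=seed + i)
        genomes, _ = synthetic_data.generate_community(cfg)
        matrix, _ = synthetic_data.generate_rbh_matrix(genomes, cfg)
        arch_sizes = {g.id: float(g.n_genes) for g in genomes if g.domain == "archaea"}
        sizes = pd.Series({g.id: float(g.n_genes) for g in genomes})
        x = sizes.loc[matrix.index].to_numpy()
        big = x > size_cut
        ll_sq, ko_sq = [], []
        for a in matrix.columns:
            y = matrix[a].to_numpy(float)
            f = size_model.fit_log_logistic(x, y, seed=seed + i, archaeon=a)
            A = arch_sizes[a]
            s = size_model.fit_korbel_scale(
                np.column_stack([np.full_like(x, A), x]), y
            )
            ll_sq.append((y[big] - f.predict(x[big])) ** 2)
            ko_sq.append((y[big] - s * size_model.korbel_weight(A, x[big])) ** 2)
        wins += np.sqrt(np.mean(np.concatenate(ll_sq))) <= np.sqrt(
            np.mean(np.concatenate(ko_sq))
        )
    return {"loglogistic_win_rate": wins / n_seeds, "n_seeds": n_seeds}


def cog_recovery(seed: int, n_bacteria: int = 80, n_archaea: int = 8) -> dict:
    """Functional-profile recovery on a gene-level community.

    Compares the transporter (category P) share among transferred genes to
    the non-transferred background — the generator's configured contrast —
    and checks that every per-category log-logistic fit decorrelates
    residuals from genome size.
    """
    from . import cog as cog_mod
    from . import hgt as hgt_mod

    cfg = SimConfig(n_bacteria=n_bacteria, n_archaea=n_archaea, seed=seed)
    genomes, _ = synthetic_data.generate_community(cfg)
    matrix, truth = synthetic_data.generate_rbh_matrix(genomes, cfg)
    hits, genes, lpi, cog_tab = synthetic_data.generate_gene_tables(
        genomes, matrix, truth, cfg
    )
    fwd = hits.loc[
        (hits["evalue"] <= 1e-10)
        & hits["query_genome"].isin({g.id for g in genomes if g.domain == "bacteria"})
    ]
    pairs = pd.DataFrame({
        "gene_b": fwd["query_id"].to_numpy(),
        "gene_a": fwd["subject_id"].to_numpy(),
        "bacterium": fwd["query_genome"].to_numpy(),
        "archaeon": fwd["subject_genome"].to_numpy(),
    })
    records = hgt_mod.flag_transfers(pairs, lpi.set_index("gene_id")["lpi"])
    tr = records.loc[records["transferred"]]
    bg = records.loc[~records["transferred"]]
    hgt_genes = set(tr["gene_b"]) | set(tr["gene_a"])
    bg_genes = set(bg["gene_b"]) | set(bg["gene_a"])
    prof_hgt = cog_mod.category_profile(hgt_genes, cog_tab)
    prof_bg = cog_mod.category_profile(bg_genes, cog_tab)
    tp = cog_mod.TRANSPORTER_CATEGORY
    ratio = float(cog_mod.category_enrichment(prof_hgt, prof_bg)[tp])
    p1 = float(prof_hgt.proportions[tp])
    p2 = float(prof_bg.proportions[tp])
    n1 = int(prof_hgt.counts.sum())
    n2 = int(prof_bg.counts.sum())
    ratio_se = ratio * np.sqrt((1 - p1) / (n1 * p1) + (1 - p2) / (n2 * p2))

    sizes = pd.Series({g.id: float(g.n_genes) for g in genomes})
    split = cog_mod.split_counts_by_category(
        pairs, cog_tab, list(matrix.index), list(matrix.columns)
    )
    fitted, skipped = cog_mod.per_category_residuals(split, sizes, seed=seed)
    max_r2 = max(float(cf.decorrelation_r2.max()) for cf in fitted.values())
    return {
        "transporter_ratio": ratio,
        "transporter_ratio_3se": 3 * float(ratio_se),
        "configured_ratio": cfg.hgt_transporter_frac / cfg.background_transporter_frac,
        "n_categories_fit": len(fitted),
        "n_categories_skipped": len(skipped),
        "max_category_decorrelation_r2": max_r2,
    }
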