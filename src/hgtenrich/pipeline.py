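"""End-to-end orchestration: simulate -> rbh -> fit -> hgt -> enrich -> stats -> cog.

The pipeline consumes either synthetic data (generated in-process from a
:class:`~hgtenrich.models.SimConfig`) or externally supplied files, runs each
enabled stage in dependency order, logs record counts at stage boundaries so
filter attrition is auditable, and returns a machine-readable report. Given
the same configuration and seed, two runs produce identical reports.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import cog as cog_mod
from . import enrichment, hgt, io, rbh, size_model, stats, synthetic_data
from .errors import ConfigError, InputError
from .models import A2B, B2A, SimConfig, SyntheticTruth, split_domains

logger = logging.getLogger("hgtenrich")

STAGES = ("simulate", "rbh", "fit", "hgt", "enrich", "stats", "cog")


@dataclass
class RunConfig:
    """Thresholds, stage toggles and file paths for one pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    stages: tuple = STAGES
    max_evalue: float = 1e-10
    min_query_cov: float = 0.5
    z_threshold: float = 1.96
    lpi_threshold: float = 0.2
    min_archaea: int = 3
    n_perm: int = 999
    outdir: Optional[str] = None
    # external inputs, used when the simulate stage is disabled
    meta_path: Optional[str] = None
    hits_path: Optional[str] = None
    genes_path: Optional[str] = None
    lpi_path: Optional[str] = None
    cog_path: Optional[str] = None
    distances_path: Optional[str] = None

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"stages: unknown stage(s) {sorted(unknown)}")
        if not 0 < self.min_query_cov < 1:
            raise ConfigError(f"min_query_cov must lie in (0, 1), got {self.min_query_cov}")
        if self.max_evalue < 0:
            raise ConfigError(f"max_evalue must be >= 0, got {self.max_evalue}")
        if not 0 <= self.lpi_threshold <= 1:
            raise ConfigError(f"lpi_threshold must lie in [0, 1], got {self.lpi_threshold}")
        if self.min_archaea < 1:
            raise ConfigError(f"min_archaea must be >= 1, got {self.min_archaea}")
        if self.n_perm < 1:
            raise ConfigError(f"n_perm must be >= 1, got {self.n_perm}")
        self.sim.validate()

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self) if f.name != "sim"}
        d["sim"] = self.sim.to_dict()
        d["stages"] = list(self.stages)
        return d


def _require(path: Optional[str], stage: str, what: str):
    if path is None:
        raise InputError(f"stage {stage!r}: missing upstream artifact {what} "
                         f"(enable the simulate stage or provide the file)")
    if not Path(path).exists():
        raise InputError(f"stage {stage!r}: file not found for {what}: {path}")
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and return the run report (a JSON-able dict)."""
    config.validate()
    on = set(config.stages)
    cfg_hash = io.config_hash(config.to_dict())
    seed = config.sim.seed
    report: dict = {"config_hash": cfg_hash, "seed": seed, "stages": {}}
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def save(df, name, index=False):
        if outdir is not None:
            io.write_tsv(df, outdir / name, cfg_hash, seed, index=index)

    # -- inputs ---------------------------------------------------------
    truth: Optional[SyntheticTruth] = None
    if "simulate" in on:
        genomes, _ = synthetic_data.generate_community(config.sim)
        matrix_truth, truth = synthetic_data.generate_rbh_matrix(genomes, config.sim)
        hits, genes, lpi_tab, cog_tab = synthetic_data.generate_gene_tables(
            genomes, matrix_truth, truth, config.sim
        )
        distances = synthetic_data.generate_root_distances(genomes, config.sim)
        if outdir is not None:
            io.write_metadata(genomes, outdir / "meta.tsv", cfg_hash, seed)
            io.write_blast_tab(hits, genes, outdir / "hits.tsv", outdir / "genes.tsv",
                               cfg_hash, seed)
            io.write_lpi(lpi_tab, outdir / "lpi.tsv", cfg_hash, seed)
            io.write_cog(cog_tab, outdir / "cog.tsv", cfg_hash, seed)
            io.write_distances(distances, outdir / "distances.tsv", cfg_hash, seed)
            io.write_truth(truth, outdir / "truth.json")
        report["stages"]["simulate"] = {
            "n_genomes": len(genomes), "n_hits": int(len(hits)),
            "n_true_enriched_pairs": len(truth.enriched_pairs),
            "n_true_transfers": len(truth.transferred_genes),
        }
        logger.info("simulate: %d genomes, %d hit rows", len(genomes), len(hits))
    else:
        genomes = io.read_metadata(_require(config.meta_path, "rbh", "metadata"))
        hits = io.read_blast_tab(
            _require(config.hits_path, "rbh", "hit table"),
            _require(config.genes_path, "rbh", "gene sidecar"),
        )
        lpi_tab = io.read_lpi(_require(config.lpi_path, "hgt", "LPI table"))
        cog_tab = io.read_cog(config.cog_path) if config.cog_path else None
        distances = (
            io.read_distances(config.distances_path) if config.distances_path else None
        )

    bacteria, archaea = split_domains(genomes)
    meta = pd.DataFrame(
        {
            "n_genes": {g.id: g.n_genes for g in genomes},
            "gc": {g.id: g.gc for g in genomes},
            "o2_class": {g.id: g.o2_class for g in genomes},
            "temp_class": {g.id: g.temp_class for g in genomes},
        }
    )
    sizes = meta["n_genes"].astype(float)

    # -- rbh ------------------------------------------------------------
    matrix = None
    pairs = None
    if "rbh" in on:
        filtered = rbh.filter_hits(hits, config.max_evalue, config.min_query_cov)
        logger.info("rbh: %d/%d hits pass filters", len(filtered), len(hits))
        b_ids = {g.id for g in bacteria}
        fwd = rbh.best_hits_frame(filtered.loc[filtered["query_genome"].isin(b_ids)])
        rev = rbh.best_hits_frame(filtered.loc[~filtered["query_genome"].isin(b_ids)])
        pairs = rbh.reciprocal_best_hits_frame(fwd, rev)
        matrix = rbh.rbh_count_matrix(pairs, genomes)
        save(matrix.rename_axis("bacterium"), "rbh_matrix.tsv", index=True)
        report["stages"]["rbh"] = {
            "n_hits_in": int(len(hits)), "n_hits_filtered": int(len(filtered)),
            "n_pairs": len(pairs), "matrix_total": int(matrix.to_numpy().sum()),
        }

    # -- fit ------------------------------------------------------------
    residuals = None
    if "fit" in on:
        if matrix is None:
            raise InputError("stage 'fit': missing upstream artifact rbh matrix "
                             "(enable the rbh stage)")
        x = sizes.loc[matrix.index].to_numpy()
        fits = {
            a: size_model.fit_log_logistic(x, matrix[a].to_numpy(float),
                                           seed=seed, archaeon=a)
            for a in matrix.columns
        }
        residuals = size_model.residual_matrix(matrix, fits, sizes)
        r2 = {
            a: size_model.decorrelation_check(residuals.values[a].to_numpy(), x)
            for a in matrix.columns
        }
        fit_rows = pd.DataFrame(
            [
                (a, f.b, f.c, f.d, f.e, f.residual_sd, f.converged, r2[a])
                for a, f in fits.items()
            ],
            columns=["archaeon", "b", "c", "d", "e", "residual_sd", "converged",
                     "decorrelation_r2"],
        )
        save(fit_rows, "fits.tsv")
        save(residuals.values.rename_axis("bacterium"), "residuals.tsv", index=True)
        report["stages"]["fit"] = {
            "n_archaea_fit": len(fits),
            "n_converged": int(sum(f.converged for f in fits.values())),
            "max_decorrelation_r2": float(np.nanmax(list(r2.values()))),
        }
        logger.info("fit: %d archaea, max residual-size R^2 %.4g",
                    len(fits), report["stages"]["fit"]["max_decorrelation_r2"])

    # -- hgt ------------------------------------------------------------
    records = None
    hgt_counts_full = None
    if "hgt" in on:
        if pairs is None:
            raise InputError("stage 'hgt': missing upstream artifact RBH pairs "
                             "(enable the rbh stage)")
        lpi_map = lpi_tab.set_index("gene_id")["lpi"].to_dict()
        records = hgt.flag_transfers(pairs, lpi_map, config.lpi_threshold)
        counts = hgt.hgt_count_table(records)
        hgt_counts_full = (
            counts["total"].unstack(fill_value=0) if len(counts) else pd.DataFrame()
        )
        hgt_counts_full = hgt_counts_full.reindex(
            index=[g.id for g in bacteria], columns=[g.id for g in archaea], fill_value=0
        )
        save(records, "hgt_records.tsv")
        save(counts.reset_index(), "hgt_counts.tsv")
        n_tr = int(records["transferred"].sum())
        report["stages"]["hgt"] = {
            "n_records": int(len(records)), "n_transferred": n_tr,
            "n_a2b": int((records["direction"] == A2B).sum()),
            "n_b2a": int((records["direction"] == B2A).sum()),
        }
        logger.info("hgt: %d/%d records transferred", n_tr, len(records))

    # -- enrich ---------------------------------------------------------
    final_pairs = None
    if "enrich" in on:
        if residuals is None:
            raise InputError("stage 'enrich': missing upstream artifact residuals "
                             "(enable the fit stage)")
        rbh_enriched = enrichment.call_enriched_pairs(residuals, config.z_threshold)
        hgt_enriched = (
            enrichment.call_hgt_enriched_pairs(hgt_counts_full, config.z_threshold)
            if hgt_counts_full is not None and len(hgt_counts_full) >= 3
            else []
        )
        robust, dropped = enrichment.corroborate_pairs(
            rbh_enriched, hgt_enriched, config.min_archaea
        )
        final_pairs = sorted(
            (p.archaeon, p.bacterium) for p in rbh_enriched if p.bacterium in robust
        )
        alpha = 0.025 if config.z_threshold == 1.96 else float("nan")
        all_pairs = rbh_enriched + hgt_enriched
        save(
            pd.DataFrame(
                [(p.bacterium, p.archaeon, p.residual, p.z, p.source) for p in all_pairs],
                columns=["bacterium", "archaeon", "residual", "z", "source"],
            ),
            "enriched_pairs.tsv",
        )
        report["stages"]["enrich"] = {
            "n_rbh_enriched": len(rbh_enriched), "n_hgt_enriched": len(hgt_enriched),
            "n_robust_bacteria": len(robust), "n_dropped_bacteria": len(dropped),
            "n_final_pairs": len(final_pairs),
        }
        logger.info("enrich: %d rbh + %d hgt pairs; %d bacteria robust, %d dropped",
                    len(rbh_enriched), len(hgt_enriched), len(robust), len(dropped))

    # -- stats ----------------------------------------------------------
    if "stats" in on:
        if residuals is None:
            raise InputError("stage 'stats': missing upstream artifact residuals "
                             "(enable the fit stage)")
        bc = stats.bray_curtis(residuals.values)
        b_index = list(residuals.values.index)
        o2 = meta.loc[b_index, "o2_class"].to_numpy()
        temp = meta.loc[b_index, "temp_class"].to_numpy()
        r_o2, r_temp = stats.anosim_twoway(bc, o2, temp, config.n_perm, seed)
        stat_report = {
            "anosim_oxygen_R": r_o2.statistic, "anosim_oxygen_p": r_o2.p_value,
            "anosim_temperature_R": r_temp.statistic, "anosim_temperature_p": r_temp.p_value,
        }
        if distances is not None:
            # vertical-inheritance check: shared-gene (raw count) profiles,
            # not residuals, against 16S depth relative to the archaea
            bc_shared = stats.bray_curtis(matrix.loc[b_index].astype(float))
            root = stats.root_distance_matrix(distances.loc[b_index])
            m = stats.mantel(bc_shared, root, config.n_perm, seed)
            stat_report["mantel_r"] = m.statistic
            stat_report["mantel_p"] = m.p_value
        report["stages"]["stats"] = stat_report
        logger.info("stats: %s", stat_report)

    # -- cog ------------------------------------------------------------
    if "cog" in on:
        if records is None or cog_tab is None:
            raise InputError("stage 'cog': missing upstream artifact HGT records or "
                             "COG table (enable the hgt stage / provide cog file)")
        all_genes = set(cog_tab["gene_id"])
        rbh_genes = set(records["gene_b"]) | set(records["gene_a"])
        tr = records.loc[records["transferred"]]
        hgt_genes = set(tr["gene_b"]) | set(tr["gene_a"])
        prof_all = cog_mod.category_profile(all_genes, cog_tab)
        prof_rbh = cog_mod.category_profile(rbh_genes, cog_tab)
        prof_hgt = cog_mod.category_profile(hgt_genes, cog_tab)
        ratio = cog_mod.category_enrichment(prof_hgt, prof_all)
        tp = cog_mod.TRANSPORTER_CATEGORY
        profiles = pd.DataFrame(
            {
                "all": prof_all.proportions, "rbh": prof_rbh.proportions,
                "hgt": prof_hgt.proportions, "hgt_vs_all": ratio,
            }
        ).rename_axis("category")
        save(profiles, "cog_profiles.tsv", index=True)
        report["stages"]["cog"] = {
            "transporter_frac_hgt": float(prof_hgt.proportions[tp]),
            "transporter_frac_all": float(prof_all.proportions[tp]),
            "transporter_ratio": float(ratio[tp]),
        }

    # -- recovery vs ground truth ---------------------------------------
    if truth is not None and final_pairs is not None:
        called = set(final_pairs)
        true_set = set(truth.enriched_pairs)
        tp_n = len(called & true_set)
        report["recovery"] = {
            "sensitivity": tp_n / len(true_set) if true_set else float("nan"),
            "false_discovery_proportion": (
                (len(called) - tp_n) / len(called) if called else 0.0
            ),
        }
    if truth is not None and records is not None:
        flagged = set(
            zip(records.loc[records["transferred"], "gene_b"],
                records.loc[records["transferred"], "gene_a"])
        )
        report.setdefault("recovery", {})["transfer_flags_match_truth"] = bool(
            flagged == set(truth.transferred_genes)
        )
        rec = records.loc[records["transferred"]].copy()
        enriched_set = truth.enriched_pairs
        mask = [
            (a, b) not in enriched_set
            for a, b in zip(rec["archaeon"], rec["bacterium"])
        ]
        rec = rec.loc[mask]
        n_a2b = int((rec["direction"] == A2B).sum())
        n_b2a = int((rec["direction"] == B2A).sum())
        recov = report.setdefault("recovery", {})
        recov["direction_ratio_nonenriched"] = (
            n_b2a / n_a2b if n_a2b else float("nan")
        )
        recov["n_a2b_nonenriched"] = n_a2b
        recov["n_b2a_nonenriched"] = n_b2a

    if outdir is not None:
        (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
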