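"""Shared domain types.

Genomes, simulation configuration, fit results and the light record types
passed between pipeline stages. Larger tabular objects (hit tables, RBH count
matrices, LPI/COG tables) are plain :class:`pandas.DataFrame` objects with
documented column schemas; the dataclasses here carry the strongly-typed
metadata around them.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError

DOMAINS = ("bacteria", "archaea")
TEMP_CLASSES = ("mesophile", "thermophile", "hyperthermophile")
O2_CLASSES = ("aerobe", "anaerobe", "facultative")
SALT_CLASSES = ("non", "moderate", "extreme")
LINEAGE_RANKS = ("domain", "phylum", "class", "order", "family", "genus")

#: transfer directions for HGTRecord rows
A2B = "archaea_to_bacteria"
B2A = "bacteria_to_archaea"
AMBIGUOUS = "ambiguous"
NO_TRANSFER = "none"
DIRECTIONS = (A2B, B2A, AMBIGUOUS, NO_TRANSFER)


@dataclass(frozen=True)
class GenomeMeta:
    """A genome and its phenotype labels.

    ``n_genes`` is the protein-coding gene count ("genome size" throughout
    this package). ``lineage`` is an ordered 6-tuple
    (domain, phylum, class, order, family, genus).
    """

    id: str
    domain: str
    n_genes: int
    gc: float
    temp_class: str
    o2_class: str
    salt_class: str
    pathogen: bool
    habitat: str
    lineage: tuple[str, ...]

    def __post_init__(self):
        if self.domain not in DOMAINS:
            raise InputError(f"genome {self.id}: unknown domain {self.domain!r}")
        if self.n_genes < 1:
            raise InputError(f"genome {self.id}: n_genes must be >= 1")
        if not 20.0 <= self.gc <= 80.0:
            raise InputError(f"genome {self.id}: gc {self.gc} outside [20, 80]")
        if self.temp_class not in TEMP_CLASSES:
            raise InputError(f"genome {self.id}: unknown temp_class {self.temp_class!r}")
        if self.o2_class not in O2_CLASSES:
            raise InputError(f"genome {self.id}: unknown o2_class {self.o2_class!r}")
        if self.salt_class not in SALT_CLASSES:
            raise InputError(f"genome {self.id}: unknown salt_class {self.salt_class!r}")
        lin = tuple(self.lineage)
        object.__setattr__(self, "lineage", lin)
        if len(lin) != 6 or any(not r for r in lin):
            raise InputError(f"genome {self.id}: lineage must have 6 non-empty ranks")
        if lin[0].lower() != self.domain:
            raise InputError(
                f"genome {self.id}: lineage domain rank {lin[0]!r} != domain {self.domain!r}"
            )


def _freqs(d: Mapping[str, float]) -> dict[str, float]:
    return dict(d)


@dataclass
class SimConfig:
    """Synthetic-community configuration.

    The defaults are the study conditions this package simulates: community
    composition mirrors the 448-bacteria / 57-archaea collection the method
    was designed for (mostly aerobic mesophilic bacteria, mostly anaerobic
    and/or (hyper)thermophilic archaea), shared-gene counts saturate with
    bacterial gene count along a four-parameter log-logistic curve, a small
    fraction of phenotype-matched pairs carry injected excess sharing,
    background transfers run bacteria->archaea : archaea->bacteria at 5:1
    with a mean of 4 archaea->bacteria transfers per pair, and transporters
    make up 15% of transferred genes against a 5% background.
    """

    n_bacteria: int = 400
    n_archaea: int = 40
    # phenotype class frequencies per domain
    bacteria_o2_freqs: dict = field(
        default_factory=lambda: _freqs({"aerobe": 0.64, "anaerobe": 0.18, "facultative": 0.18})
    )
    bacteria_temp_freqs: dict = field(
        default_factory=lambda: _freqs({"mesophile": 0.90, "thermophile": 0.06, "hyperthermophile": 0.04})
    )
    bacteria_salt_freqs: dict = field(
        default_factory=lambda: _freqs({"non": 0.82, "moderate": 0.165, "extreme": 0.015})
    )
    archaea_o2_freqs: dict = field(
        default_factory=lambda: _freqs({"aerobe": 0.25, "anaerobe": 0.60, "facultative": 0.15})
    )
    archaea_temp_freqs: dict = field(
        default_factory=lambda: _freqs({"mesophile": 0.40, "thermophile": 0.30, "hyperthermophile": 0.30})
    )
    archaea_salt_freqs: dict = field(
        default_factory=lambda: _freqs({"non": 0.49, "moderate": 0.40, "extreme": 0.11})
    )
    pathogen_frac: float = 0.39
    #: per temperature class: (mean, sd) of the bacterial gene count (normal, clipped)
    size_range: dict = field(
        default_factory=lambda: {
            "mesophile": (3857.0, 1753.0),
            "thermophile": (2491.0, 727.0),
            "hyperthermophile": (2200.0, 700.0),
        }
    )
    bacteria_size_bounds: tuple = (500, 9500)
    archaea_size: tuple = (2500.0, 800.0)
    archaea_size_bounds: tuple = (800, 6000)
    #: uniform ranges for the per-archaeon true log-logistic parameters
    baseline_params: dict = field(
        default_factory=lambda: {
            "b": (-2.2, -1.2),
            "c": (40.0, 80.0),
            "d": (250.0, 650.0),
            "e": (2200.0, 4500.0),
        }
    )
    noise_sd: float = 5.0
    p_enrich_matched: float = 0.05
    enrich_effect: float = 4.0  # in multiples of noise_sd
    direction_ratio: float = 5.0  # bacteria->archaea : archaea->bacteria, non-enriched pairs
    mean_a2b: float = 4.0  # mean archaea->bacteria transfers per genome pair
    hgt_transporter_frac: float = 0.15
    background_transporter_frac: float = 0.05
    mantel_coupling: float = 0.5
    decoy_hit_rate: float = 0.05  # sub-threshold hits per RBH pair, exercises the filter
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "p_enrich_matched",
            "hgt_transporter_frac",
            "background_transporter_frac",
            "mantel_coupling",
            "pathogen_frac",
            "decoy_hit_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_bacteria", "n_archaea"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ConfigError(f"{name} must be a non-negative integer, got {v!r}")
        for name in ("direction_ratio", "mean_a2b"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("noise_sd", "enrich_effect"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name, classes in (
            ("bacteria_o2_freqs", O2_CLASSES),
            ("bacteria_temp_freqs", TEMP_CLASSES),
            ("bacteria_salt_freqs", SALT_CLASSES),
            ("archaea_o2_freqs", O2_CLASSES),
            ("archaea_temp_freqs", TEMP_CLASSES),
            ("archaea_salt_freqs", SALT_CLASSES),
        ):
            freqs = getattr(self, name)
            if set(freqs) - set(classes):
                raise ConfigError(f"{name}: unknown classes {sorted(set(freqs) - set(classes))}")
            total = sum(freqs.values())
            if any(p < 0 for p in freqs.values()) or not np.isclose(total, 1.0, atol=1e-6):
                raise ConfigError(f"{name} must be non-negative and sum to 1, got sum {total}")
        for p in ("b", "c", "d", "e"):
            if p not in self.baseline_params:
                raise ConfigError(f"baseline_params missing range for {p!r}")
            lo, hi = self.baseline_params[p]
            if not lo <= hi:
                raise ConfigError(f"baseline_params[{p!r}]: empty range ({lo}, {hi})")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class SyntheticTruth:
    """Ground-truth ledger written by the generator.

    ``enriched_pairs`` holds (archaeon_id, bacterium_id) tuples with injected
    excess sharing; ``transferred_genes`` maps (gene_b, gene_a) id pairs to
    their true transfer direction; ``true_fit_params`` maps archaeon id to the
    (b, c, d, e) used to generate its column of the RBH matrix.
    """

    enriched_pairs: set = field(default_factory=set)
    transferred_genes: dict = field(default_factory=dict)
    true_fit_params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class RBHPair:
    """A reciprocal best hit: one bacterial and one archaeal gene."""

    gene_b: str
    gene_a: str
    bacterium: str
    archaeon: str


@dataclass(frozen=True)
class BestHit:
    """Best subject for a (query gene, target genome) combination."""

    subject_id: str
    query_genome: str
    subject_genome: str


@dataclass
class LogLogisticFit:
    """Per-archaeon four-parameter log-logistic fit.

    Model: f(x) = c + (d - c) / (1 + (x/e)^b) with x the bacterial gene
    count; c and d are the lower/upper asymptotes (RBH counts), e the
    inflection gene count, and b the shape (b < 0 gives a curve increasing
    in x).
    """

    archaeon: str
    b: float
    c: float
    d: float
    e: float
    residual_sd: float
    converged: bool
    n_points: int
    degenerate: bool = False

    def predict(self, x):
        from .size_model import log_logistic

        return log_logistic(x, self.b, self.c, self.d, self.e)


@dataclass
class ResidualMatrix:
    """Residual RBHs (observed minus fitted) with per-archaeon residual SD.

    ``values``: DataFrame indexed by bacterium id, columns archaeon ids.
    ``residual_sd``: Series indexed by archaeon id.
    """

    values: pd.DataFrame
    residual_sd: pd.Series

    def __post_init__(self):
        missing = [a for a in self.values.columns if a not in self.residual_sd.index]
        if missing:
            raise InputError(f"residual_sd missing archaea: {missing}")


@dataclass(frozen=True)
class EnrichedPair:
    """An archaeon-bacterium pair above the enrichment threshold."""

    archaeon: str
    bacterium: str
    residual: float
    z: float
    source: str  # "rbh" or "hgt"


@dataclass(frozen=True)
class PermutationResult:
    """A permutation-test outcome; p uses the (b+1)/(n_perm+1) rule."""

    statistic: float
    p_value: float
    n_perm: int
    seed: int | None = None


@dataclass
class DistanceMatrix:
    """Symmetric non-negative matrix with zero diagonal over labelled ids."""

    ids: list
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise InputError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-10):
            raise InputError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise InputError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise InputError("distances must be non-negative")
        self.values = v
        self.ids = list(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def split_domains(genomes: Sequence[GenomeMeta]):
    """Return (bacteria, archaea) sublists preserving order."""
    bacteria = [g for g in genomes if g.domain == "bacteria"]
    archaea = [g for g in genomes if g.domain == "archaea"]
    return bacteria, archaea
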