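"""Synthetic paired-kingdom dyad cohorts with planted ground truth.

The generator draws, per sample, a latent multivariate normal over all
bacterial and fungal taxa (a Gaussian copula) whose correlation matrix
encodes the planted bacteria-fungus edges, adds dyad-shared shifts,
sample-type baselines and covariate log-effects, maps to a per-kingdom
composition, and draws multinomial counts at a lognormal depth. Structural
zeros are applied afterwards by per-taxon Bernoulli thinning so prevalence
and correlation are separately tunable.

Spearman's rho is invariant to the monotone exp/normalisation maps, so a
planted latent correlation is directly interpretable as a rank signal;
multinomial sampling then attenuates it (quantified in tests, not assumed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from .core_data import ABX_FLAGS, SAMPLE_TYPES, SampleMetadata, TaxaTable
import pandas as pd

SCHEMA_VERSION = 1

# depth defaults echo typical per-sample sequencing yields for the two kingdoms
DEFAULT_DEPTH_MEAN = {"bacteria": 29762.0, "fungi": 7162.0}

DEFAULT_EXPOSURE_PROBS = {
    "birth_mode": 0.15,  # probability of cesarean
    "prenatal_abx": 0.22,
    "perinatal_abx": 0.25,
    "maternal_postpartum_abx": 0.20,
    "infant_postnatal_abx": 0.10,
}


class ConfigError(ValueError):
    """Raised for invalid cohort configuration."""


@dataclass
class CovariateEffect:
    """Effect of one binary exposure on the cohort.

    ``taxa_log_effects`` maps taxon id -> log-fold-change added to the
    latent log-abundance of exposed dyads' samples. ``rho_multiplier``
    scales the magnitude of every planted correlation for exposed dyads,
    emulating connectedness differences between subgroups.
    """

    taxa_log_effects: dict[str, float] = field(default_factory=dict)
    rho_multiplier: float = 1.0


@dataclass
class CohortConfig:
    n_dyads: int = 30
    n_bact: int = 20
    n_fung: int = 15
    depth_mean_bact: float = DEFAULT_DEPTH_MEAN["bacteria"]
    depth_mean_fung: float = DEFAULT_DEPTH_MEAN["fungi"]
    depth_log_sd: float = 0.4
    baseline_log_sd: float = 1.5
    sample_type_log_sd: float = 0.5
    latent_log_sd: float = 1.0
    prevalence: float = 1.0  # per-taxon retention probability of a nonzero draw
    planted_edges: list[tuple[str, str, float]] = field(default_factory=list)
    dyad_effect_sd: float = 0.0
    covariate_effects: dict[str, CovariateEffect] = field(default_factory=dict)
    exposure_probs: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dyads < 3:
            raise ConfigError("n_dyads must be >= 3")
        if self.depth_mean_bact < 1 or self.depth_mean_fung < 1:
            raise ConfigError("sequencing depths must be >= 1")
        if not 0 < self.prevalence <= 1:
            raise ConfigError("prevalence must be in (0, 1]")
        for b, f, rho in self.planted_edges:
            if abs(rho) > 1:
                raise ConfigError(f"planted edge ({b}, {f}) has |rho| > 1")
        probs = dict(DEFAULT_EXPOSURE_PROBS)
        probs.update(self.exposure_probs)
        self.exposure_probs = probs
        # fail fast on a non-PSD base correlation request
        _edge_correlation_matrix(self, multiplier=1.0)

    @property
    def bact_taxa(self) -> list[str]:
        return [f"bact_{i + 1:03d}" for i in range(self.n_bact)]

    @property
    def fung_taxa(self) -> list[str]:
        return [f"fung_{i + 1:03d}" for i in range(self.n_fung)]

    def to_yaml(self, path) -> None:
        doc = {
            "schema_version": SCHEMA_VERSION,
            "n_dyads": self.n_dyads,
            "n_bact": self.n_bact,
            "n_fung": self.n_fung,
            "depth_mean_bact": self.depth_mean_bact,
            "depth_mean_fung": self.depth_mean_fung,
            "depth_log_sd": self.depth_log_sd,
            "baseline_log_sd": self.baseline_log_sd,
            "sample_type_log_sd": self.sample_type_log_sd,
            "latent_log_sd": self.latent_log_sd,
            "prevalence": self.prevalence,
            "planted_edges": [list(e) for e in self.planted_edges],
            "dyad_effect_sd": self.dyad_effect_sd,
            "covariate_effects": {
                k: {"taxa_log_effects": v.taxa_log_effects,
                    "rho_multiplier": v.rho_multiplier}
                for k, v in self.covariate_effects.items()
            },
            "exposure_probs": self.exposure_probs,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ConfigError("config file is not a mapping")
        version = doc.pop("schema_version", None)
        if version != SCHEMA_VERSION:
            raise ConfigError(f"unsupported schema_version {version!r}")
        effects = {
            k: CovariateEffect(**v)
            for k, v in doc.pop("covariate_effects", {}).items()
        }
        doc["planted_edges"] = [tuple(e) for e in doc.get("planted_edges", [])]
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(covariate_effects=effects, **doc)


@dataclass
class SyntheticTruth:
    """Planted parameters and realized latent state of a generated cohort."""

    sample_ids: list[str]
    taxa_ids: list[str]  # bacterial then fungal, copula column order
    latent: np.ndarray  # samples x taxa copula normals (unit marginals)
    log_abundance: np.ndarray  # samples x taxa full latent log-abundance
    planted_edges: list[tuple[str, str, float]]
    dyad_covariates: pd.DataFrame  # one row per dyad, exposure booleans


def _edge_correlation_matrix(config: CohortConfig, multiplier: float) -> np.ndarray:
    """Correlation matrix over (bact + fung) taxa implied by the planted edges."""
    p = config.n_bact + config.n_fung
    bact_pos = {t: i for i, t in enumerate(config.bact_taxa)}
    fung_pos = {t: config.n_bact + j for j, t in enumerate(config.fung_taxa)}
    corr = np.eye(p)
    for b, f, rho in config.planted_edges:
        if b not in bact_pos:
            raise ConfigError(f"planted edge names unknown bacterial taxon {b!r}")
        if f not in fung_pos:
            raise ConfigError(f"planted edge names unknown fungal taxon {f!r}")
        r = float(np.clip(rho * multiplier, -0.999, 0.999))
        corr[bact_pos[b], fung_pos[f]] = r
        corr[fung_pos[f], bact_pos[b]] = r
    eigmin = float(np.linalg.eigvalsh(corr).min())
    if eigmin < -1e-10:
        edges = [(b, f) for b, f, _ in config.planted_edges]
        raise ConfigError(
            f"planted edge set {edges} implies a non-positive-semi-definite "
            f"correlation matrix (min eigenvalue {eigmin:.3g}) "
            f"at multiplier {multiplier}"
        )
    return corr


def _lognormal_depth(rng: np.random.Generator, mean: float, log_sd: float,
                     size: int) -> np.ndarray:
    mu = math.log(mean) - 0.5 * log_sd**2
    return np.maximum(1, np.round(rng.lognormal(mu, log_sd, size))).astype(np.int64)


def generate_cohort(
    config: CohortConfig,
) -> tuple[TaxaTable, TaxaTable, SampleMetadata, SyntheticTruth]:
    """Generate a paired-kingdom cohort: three samples per dyad.

    Bit-exactly reproducible from (config, config.seed).
    """
    rng = np.random.default_rng(config.seed)
    n_b, n_f = config.n_bact, config.n_fung
    p = n_b + n_f
    taxa = config.bact_taxa + config.fung_taxa
    taxon_pos = {t: i for i, t in enumerate(taxa)}
    n_samples = config.n_dyads * len(SAMPLE_TYPES)

    # fixed per-taxon structure
    baseline = rng.normal(0.0, config.baseline_log_sd, p)
    type_offset = rng.normal(0.0, config.sample_type_log_sd, (len(SAMPLE_TYPES), p))

    # per-dyad exposures
    cov_names = sorted(
        set(config.covariate_effects) | set(DEFAULT_EXPOSURE_PROBS)
    )
    exposures = {}
    for name in cov_names:
        prob = config.exposure_probs.get(name)
        if prob is None:
            raise ConfigError(f"no exposure probability for covariate {name!r}")
        exposures[name] = rng.random(config.n_dyads) < prob
    dyad_cov = pd.DataFrame(exposures,
                            index=[f"D{d + 1:03d}" for d in range(config.n_dyads)])

    # dyad-shared latent shift
    dyad_shift = rng.normal(0.0, config.dyad_effect_sd, (config.n_dyads, p)) \
        if config.dyad_effect_sd > 0 else np.zeros((config.n_dyads, p))

    # per-dyad rho multiplier -> cached Cholesky factors
    multipliers = np.ones(config.n_dyads)
    for name, eff in config.covariate_effects.items():
        if eff.rho_multiplier != 1.0:
            multipliers = np.where(exposures[name],
                                   multipliers * eff.rho_multiplier, multipliers)
    chol_cache: dict[float, np.ndarray] = {}
    for m in np.unique(multipliers):
        corr = _edge_correlation_matrix(config, float(m))
        # tiny jitter guards cholesky of a PSD-but-singular matrix
        chol_cache[float(m)] = np.linalg.cholesky(corr + 1e-12 * np.eye(p))

    # per-dyad additive covariate log-effects
    dyad_lfc = np.zeros((config.n_dyads, p))
    for name, eff in config.covariate_effects.items():
        for taxon, lfc in eff.taxa_log_effects.items():
            if taxon not in taxon_pos:
                raise ConfigError(f"covariate effect names unknown taxon {taxon!r}")
            dyad_lfc[exposures[name], taxon_pos[taxon]] += lfc

    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    latent = np.empty((n_samples, p))
    log_abund = np.empty((n_samples, p))
    s = 0
    for d in range(config.n_dyads):
        dyad_id = f"D{d + 1:03d}"
        chol = chol_cache[float(multipliers[d])]
        for ti, stype in enumerate(SAMPLE_TYPES):
            z = chol @ rng.standard_normal(p)
            latent[s] = z
            log_abund[s] = (baseline + type_offset[ti] + dyad_shift[d]
                            + dyad_lfc[d] + config.latent_log_sd * z)
            sid = f"{dyad_id}_{stype}"
            sample_ids.append(sid)
            subject = f"M{d + 1:03d}" if stype == "milk" else f"I{d + 1:03d}"
            row = {
                "sample_id": sid,
                "subject_id": subject,
                "dyad_id": dyad_id,
                "sample_type": stype,
                "birth_mode": "cesarean" if exposures["birth_mode"][d] else "vaginal",
            }
            for flag in ABX_FLAGS:
                row[flag] = bool(exposures[flag][d])
            for name in cov_names:
                if name not in DEFAULT_EXPOSURE_PROBS:
                    row[name] = bool(exposures[name][d])
            meta_rows.append(row)
            s += 1

    # compositions and counts, per kingdom
    depth_b = _lognormal_depth(rng, config.depth_mean_bact, config.depth_log_sd,
                               n_samples)
    depth_f = _lognormal_depth(rng, config.depth_mean_fung, config.depth_log_sd,
                               n_samples)
    counts_b = np.empty((n_b, n_samples), dtype=np.int64)
    counts_f = np.empty((n_f, n_samples), dtype=np.int64)
    for s in range(n_samples):
        for sl, depth, out in ((slice(0, n_b), depth_b[s], counts_b),
                               (slice(n_b, p), depth_f[s], counts_f)):
            a = np.exp(log_abund[s, sl] - log_abund[s, sl].max())
            out[:, s] = rng.multinomial(depth, a / a.sum())

    if config.prevalence < 1.0:
        keep_b = rng.random((n_b, n_samples)) < config.prevalence
        keep_f = rng.random((n_f, n_samples)) < config.prevalence
        counts_b *= keep_b
        counts_f *= keep_f

    bact = TaxaTable("bacteria", config.bact_taxa, sample_ids, counts_b)
    fung = TaxaTable("fungi", config.fung_taxa, sample_ids, counts_f)
    meta = SampleMetadata(pd.DataFrame(meta_rows))
    truth = SyntheticTruth(
        sample_ids=sample_ids,
        taxa_ids=taxa,
        latent=latent,
        log_abundance=log_abund,
        planted_edges=list(config.planted_edges),
        dyad_covariates=dyad_cov,
    )
    return bact, fung, meta, truth


def null_cohort(
    n_samples: int,
    n_bact: int,
    n_fung: int,
    depth: float = 5000.0,
    seed: int = 0,
) -> tuple[TaxaTable, TaxaTable]:
    """Paired tables with fully independent taxa (no edges, dyads, covariates)."""
    rng = np.random.default_rng(seed)
    ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    tables = []
    for kingdom, n_taxa, prefix in (("bacteria", n_bact, "bact"),
                                    ("fungi", n_fung, "fung")):
        baseline = rng.normal(0.0, 1.0, n_taxa)
        log_a = baseline[:, None] + rng.standard_normal((n_taxa, n_samples))
        counts = np.empty((n_taxa, n_samples), dtype=np.int64)
        depths = _lognormal_depth(rng, depth, 0.3, n_samples)
        for s in range(n_samples):
            a = np.exp(log_a[:, s] - log_a[:, s].max())
            counts[:, s] = rng.multinomial(depths[s], a / a.sum())
        taxa = [f"{prefix}_{i + 1:03d}" for i in range(n_taxa)]
        tables.append(TaxaTable(kingdom, taxa, ids, counts))
    return tables[0], tables[1]
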