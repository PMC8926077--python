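"""Synthetic multi-condition expression studies with planted coexpression modules.

The generator emulates the design of a multi-cohort transcriptomic comparison:
several conditions share one gene universe; within each condition, blocks of
genes are driven by a latent factor (one factor per module, the generative
analogue of a module eigengene), with per-condition factor loadings that
encode whether the module is preserved, weakened, split in two, or destroyed
in that condition.  Additive batch location/scale effects, a linear age effect
and a binary sex shift are layered on top, and everything is reproducible from
a single integer seed.

Model for gene g in module m, sample s of condition c::

    x_gs = b_g + delta_batch(s) * (lambda_mc * f_s + eps_gs) + gamma_batch(s)
           + age/sex terms

with ``f_s`` standard normal per sample, ``eps_gs ~ N(0, noise_sd^2)`` and
``b_g`` a per-gene baseline abundance on the log2 scale.  Background genes
(ground-truth label 0) have ``lambda = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset

REGIMES = ("preserved", "weakened", "split", "destroyed")

#: default module loading and noise level: unit gene variance with
#: within-module correlation lambda^2/(lambda^2 + sigma^2) = 0.64
DEFAULT_LOADING = 0.8
DEFAULT_NOISE_SD = 0.6


class ConfigurationError(ValueError):
    """Raised for inconsistent simulation configurations."""


# --------------------------------------------------------------------------- #


@dataclass
class PlantedModule:
    """A block of coexpressed genes driven by one latent factor per condition.

    Parameters
    ----------
    size
        Number of genes in the module.
    loadings
        Mapping condition -> factor loading in [0, 1].  A loading of 0 means
        the module is absent (destroyed) in that condition.
    regimes
        Optional mapping condition -> one of ``preserved``, ``weakened``,
        ``split``, ``destroyed``.  If omitted, inferred as ``destroyed`` where
        the loading is 0 and ``preserved`` elsewhere.  ``split`` replaces the
        single factor by two independent factors on the module halves.
    min_loading_fraction
        Hub-structure control.  1.0 (default) gives every gene the module
        loading (the plain single-factor model).  Below 1, per-gene loadings
        decay geometrically from ``lambda`` at the first gene to
        ``lambda * min_loading_fraction`` at the last, so the leading genes
        are the module hubs and the network's connectivity distribution
        acquires the heavy tail required for scale-free topology.
    """

    size: int
    loadings: Dict[str, float]
    regimes: Optional[Dict[str, str]] = None
    min_loading_fraction: float = 1.0
    #: optional explicit per-gene loading multipliers in (0, 1], length = size;
    #: overrides the geometric decay when given
    custom_profile: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ConfigurationError(f"module size must be positive, got {self.size}")
        for cond, lam in self.loadings.items():
            if not 0.0 <= lam <= 1.0:
                raise ConfigurationError(
                    f"loading for condition {cond!r} must lie in [0, 1], got {lam}"
                )
        if self.regimes is None:
            self.regimes = {
                cond: ("destroyed" if lam == 0.0 else "preserved")
                for cond, lam in self.loadings.items()
            }
        for cond, regime in self.regimes.items():
            if regime not in REGIMES:
                raise ConfigurationError(f"unknown regime {regime!r}")
            lam = self.loadings.get(cond, 0.0)
            if (regime == "destroyed") != (lam == 0.0):
                raise ConfigurationError(
                    f"regime 'destroyed' must coincide with loading 0 "
                    f"(condition {cond!r}: regime={regime!r}, loading={lam})"
                )
            if regime == "split" and self.size < 4:
                raise ConfigurationError("'split' needs a module of >= 4 genes")
        if not 0.0 < self.min_loading_fraction <= 1.0:
            raise ConfigurationError("min_loading_fraction must lie in (0, 1]")
        if self.custom_profile is not None:
            prof = np.asarray(self.custom_profile, dtype=float)
            if prof.shape != (self.size,):
                raise ConfigurationError("custom_profile length must equal module size")
            if prof.min() <= 0 or prof.max() > 1:
                raise ConfigurationError("custom_profile values must lie in (0, 1]")

    def loading_profile(self, condition: str) -> np.ndarray:
        """Per-gene loadings for one condition (geometric hub decay or the
        explicit custom profile)."""
        lam = self.loadings.get(condition, 0.0)
        if self.custom_profile is not None:
            return lam * np.asarray(self.custom_profile, dtype=float)
        if self.min_loading_fraction == 1.0 or self.size == 1:
            return np.full(self.size, lam)
        decay = self.min_loading_fraction ** (np.arange(self.size) / (self.size - 1))
        return lam * decay

    @classmethod
    def from_regimes(
        cls,
        size: int,
        conditions: Sequence[str],
        regimes: Mapping[str, str],
        base_loading: float = DEFAULT_LOADING,
        weakened_factor: float = 0.5,
        min_loading_fraction: float = 1.0,
    ) -> "PlantedModule":
        """Build a module from a regime map, deriving loadings automatically.

        Conditions missing from ``regimes`` are treated as ``preserved``.
        """
        loadings = {}
        full = {c: regimes.get(c, "preserved") for c in conditions}
        for cond, regime in full.items():
            if regime == "destroyed":
                loadings[cond] = 0.0
            elif regime == "weakened":
                loadings[cond] = base_loading * weakened_factor
            else:
                loadings[cond] = base_loading
        return cls(
            size=size,
            loadings=loadings,
            regimes=full,
            min_loading_fraction=min_loading_fraction,
        )


@dataclass
class BatchEffect:
    """Additive location / multiplicative scale effect on a sample range.

    ``samples`` is a half-open index range within the condition's samples.
    The effect acts on the expression component around the gene baseline:
    centred values are multiplied by ``scale`` and shifted by ``shift``.
    """

    condition: str
    samples: Tuple[int, int]
    shift: float = 0.0
    scale: float = 1.0
    #: SD of gene-specific variation around ``shift``; real batch effects are
    #: probe-specific, which is also what the empirical-Bayes correction model
    #: assumes.  0 = the same shift for every gene.
    gene_shift_sd: float = 0.0
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ConfigurationError(f"batch scale factor must be > 0, got {self.scale}")
        if self.gene_shift_sd < 0:
            raise ConfigurationError("gene_shift_sd must be non-negative")
        lo, hi = self.samples
        if not 0 <= lo < hi:
            raise ConfigurationError(f"invalid sample range {self.samples}")


@dataclass
class CovariateConfig:
    """Age and sex effects.

    Age is uniform on ``age_range`` (years); ``n_age_genes`` genes (taken from
    the end of the gene universe, outside the planted blocks in the default
    layouts) get expression ``+ age_slope * age``.  Sex is Bernoulli(0.5) coded
    0/1; ``n_sex_genes`` genes (immediately before the age genes) get
    ``+ sex_shift`` in the sex==1 group.
    """

    age_range: Tuple[float, float] = (60.0, 90.0)
    age_slope: float = 0.0
    n_age_genes: int = 0
    sex_shift: float = 0.0
    n_sex_genes: int = 0


@dataclass
class SimulationConfig:
    n_genes: int
    samples_per_condition: Dict[str, int]
    modules: List[PlantedModule] = field(default_factory=list)
    noise_sd: float = DEFAULT_NOISE_SD
    batches: List[BatchEffect] = field(default_factory=list)
    covariates: CovariateConfig = field(default_factory=CovariateConfig)
    baseline_range: Tuple[float, float] = (6.0, 12.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        for cond, n in self.samples_per_condition.items():
            if n <= 0:
                raise ConfigurationError(f"sample count for {cond!r} must be positive")
        total = sum(m.size for m in self.modules)
        if total > self.n_genes:
            raise ConfigurationError(
                f"module sizes sum to {total} > n_genes = {self.n_genes}"
            )

    @property
    def conditions(self) -> List[str]:
        return list(self.samples_per_condition)

    def module_slices(self) -> List[slice]:
        """Disjoint contiguous gene index blocks, one per planted module."""
        out, start = [], 0
        for m in self.modules:
            out.append(slice(start, start + m.size))
            start += m.size
        return out

    def gene_ids(self) -> List[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]


@dataclass
class GroundTruth:
    """Planted structure for one simulated condition."""

    labels: pd.Series  # gene id -> planted module id, 0 = background
    loadings: pd.Series  # planted module id -> loading in this condition
    regimes: pd.Series  # planted module id -> regime in this condition
    batch: pd.Series  # sample id -> batch label
    age: pd.Series
    sex: pd.Series
    age_genes: List[str]
    sex_genes: List[str]

    def to_tsv(self, path) -> None:
        out = pd.DataFrame({"gene_id": self.labels.index, "planted_label": self.labels.values})
        out["age_gene"] = out["gene_id"].isin(self.age_genes).astype(int)
        out["sex_gene"] = out["gene_id"].isin(self.sex_genes).astype(int)
        out.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------- #


def _rngs(config: SimulationConfig) -> Dict[str, np.random.Generator]:
    """One child generator per condition plus a shared one for gene baselines."""
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(config.conditions) + 1)
    rngs = {"__baseline__": np.random.default_rng(children[0])}
    for i, cond in enumerate(config.conditions):
        rngs[cond] = np.random.default_rng(children[i + 1])
    return rngs


def _covariate_gene_sets(config: SimulationConfig) -> Tuple[slice, slice]:
    cov = config.covariates
    n = config.n_genes
    age_sl = slice(n - cov.n_age_genes, n)
    sex_sl = slice(n - cov.n_age_genes - cov.n_sex_genes, n - cov.n_age_genes)
    if sex_sl.start < 0:
        raise ConfigurationError("covariate gene subsets exceed the gene universe")
    return age_sl, sex_sl


def simulate_condition(
    config: SimulationConfig, condition: str
) -> Tuple[ExpressionDataset, GroundTruth]:
    """Simulate one condition of the study.

    Module genes follow the factor model ``lambda * f + eps``; batch and
    covariate effects are added afterwards.  Reproducible given
    ``config.seed`` (each condition has its own deterministic substream, so a
    condition simulated standalone equals the same condition inside
    :func:`simulate_study`).
    """
    if condition not in config.samples_per_condition:
        raise ConfigurationError(f"unknown condition {condition!r}")
    rngs = _rngs(config)
    baseline = rngs["__baseline__"].uniform(*config.baseline_range, size=config.n_genes)
    rng = rngs[condition]
    n = config.samples_per_condition[condition]
    genes = config.gene_ids()
    samples = [f"{condition}_S{j + 1:03d}" for j in range(n)]

    x = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n))
    labels = np.zeros(config.n_genes, dtype=int)
    loadings, regimes = {}, {}
    for mid, (module, sl) in enumerate(zip(config.modules, config.module_slices()), start=1):
        labels[sl] = mid
        lam = module.loadings.get(condition, 0.0)
        regime = module.regimes.get(condition, "destroyed" if lam == 0 else "preserved")
        loadings[mid], regimes[mid] = lam, regime
        if lam == 0.0:
            continue
        lam_g = module.loading_profile(condition)
        if regime == "split":
            half = module.size // 2
            f1 = rng.standard_normal(n)
            f2 = rng.standard_normal(n)
            x[sl.start : sl.start + half] += lam_g[:half, None] * f1
            x[sl.start + half : sl.stop] += lam_g[half:, None] * f2
        else:
            f = rng.standard_normal(n)
            x[sl] += lam_g[:, None] * f

    # covariates
    cov = config.covariates
    age = rng.uniform(*cov.age_range, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    age_sl, sex_sl = _covariate_gene_sets(config)
    if cov.n_age_genes and cov.age_slope:
        x[age_sl] += cov.age_slope * age
    if cov.n_sex_genes and cov.sex_shift:
        x[sex_sl] += cov.sex_shift * sex

    # batch effects: scale acts on the centred component, shift is additive
    batch_labels = np.array([f"{condition}:batch0"] * n, dtype=object)
    for k, eff in enumerate(b for b in config.batches if b.condition == condition):
        lo, hi = eff.samples
        if hi > n:
            raise ConfigurationError(
                f"batch range {eff.samples} exceeds {n} samples of {condition!r}"
            )
        name = eff.name or f"{condition}:batch{k + 1}"
        batch_labels[lo:hi] = name
        gene_shift = eff.shift
        if eff.gene_shift_sd > 0:
            gene_shift = rng.normal(eff.shift, eff.gene_shift_sd, size=config.n_genes)[
                :, None
            ]
        x[:, lo:hi] = x[:, lo:hi] * eff.scale + gene_shift

    x += baseline[:, None]

    values = pd.DataFrame(x, index=genes, columns=samples)
    metadata = pd.DataFrame(
        {"condition": condition, "batch": batch_labels, "age": age, "sex": sex},
        index=samples,
    )
    truth = GroundTruth(
        labels=pd.Series(labels, index=genes, name="planted_label"),
        loadings=pd.Series(loadings, dtype=float),
        regimes=pd.Series(regimes, dtype=object),
        batch=pd.Series(batch_labels, index=samples),
        age=pd.Series(age, index=samples),
        sex=pd.Series(sex, index=samples),
        age_genes=genes[age_sl],
        sex_genes=genes[sex_sl],
    )
    return ExpressionDataset(values, metadata), truth


def simulate_study(
    config: SimulationConfig,
) -> Dict[str, Tuple[ExpressionDataset, GroundTruth]]:
    """Simulate every configured condition over one shared gene universe."""
    if len(config.conditions) < 2:
        raise ConfigurationError("a study needs at least 2 conditions")
    return {cond: simulate_condition(config, cond) for cond in config.conditions}


def config_from_dict(raw: Mapping) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a plain (YAML-friendly) dict."""
    conditions = list(raw["samples_per_condition"])
    modules = []
    for entry in raw.get("modules", []):
        entry = dict(entry)
        if "loadings" in entry:
            modules.append(
                PlantedModule(
                    size=int(entry["size"]),
                    loadings={c: float(v) for c, v in entry["loadings"].items()},
                    regimes=entry.get("regimes"),
                    min_loading_fraction=float(entry.get("min_loading_fraction", 1.0)),
                )
            )
        else:
            modules.append(
                PlantedModule.from_regimes(
                    int(entry["size"]),
                    conditions,
                    entry.get("regimes", {}),
                    base_loading=float(entry.get("base_loading", DEFAULT_LOADING)),
                    weakened_factor=float(entry.get("weakened_factor", 0.5)),
                    min_loading_fraction=float(entry.get("min_loading_fraction", 1.0)),
                )
            )
    batches = [
        BatchEffect(
            condition=b["condition"],
            samples=(int(b["start"]), int(b["end"])),
            shift=float(b.get("shift", 0.0)),
            scale=float(b.get("scale", 1.0)),
            name=b.get("name"),
        )
        for b in raw.get("batches", [])
    ]
    cov = raw.get("covariates", {})
    covariates = CovariateConfig(
        age_range=tuple(cov.get("age_range", (60.0, 90.0))),
        age_slope=float(cov.get("age_slope", 0.0)),
        n_age_genes=int(cov.get("n_age_genes", 0)),
        sex_shift=float(cov.get("sex_shift", 0.0)),
        n_sex_genes=int(cov.get("n_sex_genes", 0)),
    )
    return SimulationConfig(
        n_genes=int(raw["n_genes"]),
        samples_per_condition={c: int(n) for c, n in raw["samples_per_condition"].items()},
        modules=modules,
        noise_sd=float(raw.get("noise_sd", DEFAULT_NOISE_SD)),
        batches=batches,
        covariates=covariates,
        seed=int(raw.get("seed", 0)),
    )


def config_from_yaml(path) -> SimulationConfig:
    import yaml

    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


# --------------------------------------------------------------------------- #
# convenience study layouts used by the pipeline demo and the test-bench


def demo_config(
    n_genes: int = 300,
    n_modules: int = 3,
    module_size: int = 50,
    samples: int = 60,
    loading: float = DEFAULT_LOADING,
    noise_sd: float = DEFAULT_NOISE_SD,
    min_loading_fraction: float = 0.6,
    seed: int = 0,
) -> SimulationConfig:
    """Reference condition plus two tests: one preserves all modules, the other
    destroys the last planted module (the classic gain/loss contrast)."""
    conditions = ["ref", "testA", "testB"]
    modules = []
    for i in range(n_modules):
        regime = {"testB": "destroyed"} if i == n_modules - 1 else {}
        modules.append(
            PlantedModule.from_regimes(
                module_size,
                conditions,
                regime,
                base_loading=loading,
                min_loading_fraction=min_loading_fraction,
            )
        )
    return SimulationConfig(
        n_genes=n_genes,
        samples_per_condition={c: samples for c in conditions},
        modules=modules,
        noise_sd=noise_sd,
        seed=seed,
    )


def modular_study_config(
    n_genes: int = 1000,
    n_modules: int = 10,
    module_size: int = 50,
    samples: int = 100,
    loading: float = DEFAULT_LOADING,
    noise_sd: float = DEFAULT_NOISE_SD,
    min_loading_fraction: float = 0.1,
    conditions: Sequence[str] = ("ref", "test"),
    seed: int = 0,
) -> SimulationConfig:
    """The modular benchmark study used for soft-threshold selection.

    Hub-structured modules (geometric loading decay to
    ``min_loading_fraction``) give the network the heavy-tailed connectivity
    distribution that makes the scale-free topology criterion attainable,
    mirroring how the field's reference simulator spreads gene-eigengene
    correlations between a maximum and a minimum within each module.
    """
    conditions = list(conditions)
    modules = [
        PlantedModule(
            module_size,
            {c: loading for c in conditions},
            min_loading_fraction=min_loading_fraction,
        )
        for _ in range(n_modules)
    ]
    return SimulationConfig(
        n_genes=n_genes,
        samples_per_condition={c: samples for c in conditions},
        modules=modules,
        noise_sd=noise_sd,
        seed=seed,
    )
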