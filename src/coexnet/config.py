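"""Configuration objects for the simulation and the end-to-end pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

GROUPS = ("control", "enrichment", "exercise", "fluoxetine")
#: Numeric antidepressant-trait code per group: interventions with an
#: antidepressant-like effect (exercise, fluoxetine) are 1, the others 0.
TRAIT_OF_GROUP = {"control": 0, "enrichment": 0, "exercise": 1, "fluoxetine": 1}


class ConfigError(ValueError):
    """A configuration value is out of range or inconsistent."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic four-group hippocampal expression study.

    The defaults emulate the design this package targets: four groups
    (control, environmental enrichment, voluntary exercise, fluoxetine) of
    seven animals each, a few thousand genes of which roughly half are
    detected above background, four planted co-expression modules whose
    latent factors track the antidepressant trait, and a set of
    differentially expressed genes whose fluoxetine/exercise/enrichment
    log2 effects are correlated across treatments.

    All scales are log2 expression units.
    """

    n_genes: int = 5000
    n_per_group: int = 7
    groups: Sequence[str] = GROUPS
    module_sizes: Sequence[int] = (200, 150, 120, 100)
    module_trait_loadings: Sequence[float] = (0.85, 0.80, -0.80, -0.85)
    module_sd: float = 1.5
    n_de_genes: int = 500
    effect_sd: float = 1.2
    rho_flx_ex: float = 0.49
    rho_flx_enr: float = 0.15
    rho_ex_enr: float | None = None  # defaults to rho_flx_enr
    noise_sd: float = 0.5
    detect_rate: float = 0.487
    replication_rho: float = 0.57
    seed: int = 0

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    @property
    def n_samples(self) -> int:
        return self.n_per_group * len(self.groups)

    @property
    def rho_ex_enr_effective(self) -> float:
        return self.rho_flx_enr if self.rho_ex_enr is None else self.rho_ex_enr

    def effect_correlation_matrix(self) -> np.ndarray:
        """3x3 correlation of (fluoxetine, exercise, enrichment) effects."""
        r_fx, r_fe, r_xe = self.rho_flx_ex, self.rho_flx_enr, self.rho_ex_enr_effective
        return np.array([[1.0, r_fx, r_fe], [r_fx, 1.0, r_xe], [r_fe, r_xe, 1.0]])

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_per_group <= 0:
            raise ConfigError("n_genes and n_per_group must be positive")
        if len(self.groups) < 2 or "control" not in self.groups:
            raise ConfigError("groups must include 'control' and at least one treatment")
        if len(set(self.groups)) != len(self.groups):
            raise ConfigError("group labels must be unique")
        if len(self.module_sizes) != len(self.module_trait_loadings):
            raise ConfigError("module_sizes and module_trait_loadings lengths differ")
        if any(s <= 0 for s in self.module_sizes):
            raise ConfigError("module sizes must be positive")
        if sum(self.module_sizes) + self.n_de_genes > self.n_genes:
            raise ConfigError(
                "module sizes plus n_de_genes exceed n_genes "
                f"({sum(self.module_sizes)} + {self.n_de_genes} > {self.n_genes})"
            )
        for name in ("rho_flx_ex", "rho_flx_enr", "replication_rho"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [-1, 1]")
        if not -1.0 <= self.rho_ex_enr_effective <= 1.0:
            raise ConfigError("rho_ex_enr outside [-1, 1]")
        if any(abs(a) > 1 for a in self.module_trait_loadings):
            raise ConfigError("module_trait_loadings must lie in [-1, 1]")
        for name in ("effect_sd", "noise_sd", "module_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_de_genes < 0:
            raise ConfigError("n_de_genes must be >= 0")
        if not 0.0 < self.detect_rate <= 1.0:
            raise ConfigError("detect_rate must be in (0, 1]")
        # The trivariate effect model needs a valid correlation matrix.
        if self.n_de_genes > 0:
            eigvals = np.linalg.eigvalsh(self.effect_correlation_matrix())
            if eigvals.min() < -1e-10:
                raise ConfigError(
                    "effect correlation matrix (rho_flx_ex=%g, rho_flx_enr=%g, "
                    "rho_ex_enr=%g) is not positive semi-definite; "
                    "smallest eigenvalue %g"
                    % (
                        self.rho_flx_ex,
                        self.rho_flx_enr,
                        self.rho_ex_enr_effective,
                        eigvals.min(),
                    )
                )

    @classmethod
    def null(cls, **overrides) -> "SimulationConfig":
        """A no-signal configuration: no treatment effects and no latent
        module factors, so every gene is independent noise and satisfies
        the ANOVA null hypothesis (module factors, even trait-silent ones,
        shift group means within a realization)."""
        defaults: dict = {
            "n_de_genes": 0,
            "module_sizes": (),
            "module_trait_loadings": (),
        }
        defaults.update(overrides)
        cfg = cls(**defaults)
        if cfg.n_de_genes != 0 or cfg.n_modules != 0:
            raise ConfigError("null() requires n_de_genes=0 and no modules")
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["groups"] = list(self.groups)
        d["module_sizes"] = [int(s) for s in self.module_sizes]
        d["module_trait_loadings"] = [float(a) for a in self.module_trait_loadings]
        return d

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


_PIPELINE_FIELDS_DOC = """Stage parameters for the end-to-end report pipeline."""


@dataclass
class PipelineConfig:
    """All stage parameters of the simulate -> DE -> concordance -> network
    pipeline, with validation and YAML/JSON loading."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    alpha: float = 0.05          # per-sample detection P threshold
    min_frac: float = 0.80       # fraction of samples required detected
    fdr: float = 0.05            # q-value call threshold
    qvalue_mode: str = "smoother"  # "smoother" (Storey) or "bh"
    top_k_genes: int = 4000      # most-variable genes entering the network
    beta: float = 14.0           # soft-threshold power
    min_module_size: int = 30
    merge_threshold: float = 0.8
    cut_height_frac: float = 0.90
    concordance_mode: str = "yates"  # or "fisher"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("alpha", "min_frac"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigError(f"{name}={v} outside (0, 1]")
        if not 0.0 < self.fdr < 1.0:
            raise ConfigError("fdr must be in (0, 1)")
        if self.qvalue_mode not in ("smoother", "bh"):
            raise ConfigError("qvalue_mode must be 'smoother' or 'bh'")
        if self.concordance_mode not in ("yates", "fisher"):
            raise ConfigError("concordance_mode must be 'yates' or 'fisher'")
        if self.top_k_genes <= 0 or self.min_module_size <= 0:
            raise ConfigError("top_k_genes and min_module_size must be positive")
        if self.beta <= 0:
            raise ConfigError("beta must be positive")
        if not 0.0 < self.merge_threshold <= 1.0:
            raise ConfigError("merge_threshold outside (0, 1]")
        if not 0.0 < self.cut_height_frac <= 1.0:
            raise ConfigError("cut_height_frac outside (0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        known_sim = {f.name for f in dataclasses.fields(SimulationConfig)}
        unknown = set(sim) - known_sim
        if unknown:
            raise ConfigError(f"unknown simulation keys: {sorted(unknown)}")
        for key in ("groups", "module_sizes", "module_trait_loadings"):
            if key in sim and isinstance(sim[key], list):
                sim[key] = tuple(sim[key])
        known = {f.name for f in dataclasses.fields(cls)} - {"simulation"}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown pipeline keys: {sorted(unknown)}")
        return cls(simulation=SimulationConfig(**sim), **d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
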