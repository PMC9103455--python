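"""Configuration objects for the simulation and the evaluation pipeline.

The default :class:`SimulationConfig` emulates a two-line divergent selection
experiment on residual feed intake (RFI): eight pedigree generations (founders
G0 plus seven progeny generations G1..G7), weekly feed-intake records over a
ten-week test period, SNP genotypes restricted to the parents of phenotyped
animals, and a small fraction of missing weekly records concentrated in a
subset of animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

__all__ = ["SimulationConfig", "RunConfig", "default_variance_components"]


def _default_K_a() -> np.ndarray:
    # calibrated so the genetic covariance function has eigen-shares near
    # 60/26/14% and index heritabilities near 0.36/0.20/0.15
    return np.array(
        [
            [0.0330, 0.0030, 0.0010],
            [0.0030, 0.0122, 0.0020],
            [0.0010, 0.0020, 0.0063],
        ]
    )


def _default_K_b() -> np.ndarray:
    return np.array(
        [
            [0.0430, 0.0040, 0.0000],
            [0.0040, 0.0380, 0.0030],
            [0.0000, 0.0030, 0.0240],
        ]
    )


def _default_D() -> np.ndarray:
    # weekly residual variances (kg^2/day^2), mildly heterogeneous over weeks
    return np.array(
        [0.080, 0.074, 0.069, 0.065, 0.062, 0.060, 0.060, 0.062, 0.066, 0.072]
    )


@dataclass
class SimulationConfig:
    """Parameters of the synthetic divergent-selection experiment.

    Counts are per line; the design is symmetric between the low-RFI and
    high-RFI lines.  ``K_a`` and ``K_b`` are the 3x3 covariance matrices of
    the genetic and permanent-environment random-regression coefficients
    (trait units squared); ``D`` holds the ten weekly residual variances.
    ``beta1``/``beta2``/``beta3`` are the partial regression coefficients of
    feed intake on metabolic body weight, average daily gain and backfat
    thickness.
    """

    n_generations: int = 8
    n_sires_per_gen: int = 6
    n_dams_per_gen: int = 18
    progeny_per_mating: int = 11
    lines: Sequence[str] = ("LRFI", "HRFI")
    phenotyped_generations: Sequence[int] | None = None  # default: 1..last
    n_weeks: int = 10
    n_snps: int = 1200
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    K_a: np.ndarray = field(default_factory=_default_K_a)
    K_b: np.ndarray = field(default_factory=_default_K_b)
    D: np.ndarray = field(default_factory=_default_D)
    beta1: float = 0.07   # kg feed per kg^0.75 metabolic body weight
    beta2: float = 1.40   # kg feed per kg average daily gain
    beta3: float = 0.02   # kg feed per mm backfat
    # magnitudes (SD) of the simulated fixed effects
    sd_week_gen: float = 0.15
    sd_batch_sex: float = 0.10
    sd_herd: float = 0.05
    sd_pen: float = 0.05
    age_slope: float = 0.01     # kg feed per day of age deviation at test start
    n_batches: int = 14
    n_pens: int = 16
    missing_animal_fraction: float = 0.20
    missing_week_rate: float = 0.21
    selection_mode: str = "divergent_on_sbv1"  # or "none"
    seed: int = 20220513

    def __post_init__(self) -> None:
        self.K_a = np.asarray(self.K_a, dtype=float)
        self.K_b = np.asarray(self.K_b, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        self.validate()
        if self.phenotyped_generations is None:
            self.phenotyped_generations = tuple(range(1, self.n_generations))
        self.phenotyped_generations = tuple(self.phenotyped_generations)

    def validate(self) -> None:
        for name, K in (("K_a", self.K_a), ("K_b", self.K_b)):
            if K.shape != (3, 3):
                raise ValueError(f"{name} must be 3x3, got {K.shape}")
            if not np.allclose(K, K.T, atol=1e-12):
                raise ValueError(f"{name} must be symmetric")
            if np.min(np.linalg.eigvalsh(K)) < -1e-10:
                raise ValueError(f"{name} must be positive semi-definite")
        if self.D.shape != (self.n_weeks,):
            raise ValueError(f"D must have {self.n_weeks} entries")
        if np.any(self.D <= 0):
            raise ValueError("all weekly residual variances must be > 0")
        lo, hi = self.founder_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("founder_maf_range must lie in (0, 0.5]")
        for name in ("missing_animal_fraction", "missing_week_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.selection_mode not in ("none", "divergent_on_sbv1"):
            raise ValueError(f"unknown selection_mode {self.selection_mode!r}")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if len(self.lines) not in (1, 2):
            raise ValueError("one or two lines are required")
        if self.selection_mode == "divergent_on_sbv1" and len(self.lines) != 2:
            raise ValueError("divergent selection requires two lines")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("K_a", "K_b", "D"):
            d[k] = np.asarray(d[k]).tolist()
        d["lines"] = list(self.lines)
        d["phenotyped_generations"] = list(self.phenotyped_generations)
        d["founder_maf_range"] = list(self.founder_maf_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "founder_maf_range" in d:
            d["founder_maf_range"] = tuple(d["founder_maf_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    blend_weight: float = 0.05
    n_cuts: int = 5
    use_genomics: bool = True
    apply_missingness: bool = True
    run_reml: bool = False
    sigma2_ustar: float | None = None  # group genetic variance for reliability
    seed: int = 20220513
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.blend_weight <= 1:
            raise ValueError("blend_weight must lie in [0, 1]")
        if self.n_cuts < 1:
            raise ValueError("n_cuts must be >= 1")

    def to_dict(self) -> dict:
        d = {k: v for k, v in asdict(self).items() if k != "simulation"}
        d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        return cls(simulation=SimulationConfig.from_dict(sim), **d)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_variance_components():
    """The generating (K_a, K_b, D) triple of the default configuration."""
    return _default_K_a(), _default_K_b(), _default_D()
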