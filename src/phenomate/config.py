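"""Configuration, domain types, and constant covariance structures.

The simulator is parameterised by a single :class:`SimulationConfig` holding
the founder census size, the bivariate trait distribution (return day and
reproductive lifespan, RLS), the stabilizing-selection width, and the
interannual environmental variances of the trait optima.  Two constant 2x2
matrices are derived from it once per run:

* ``P`` — the phenotypic covariance matrix of (return day, RLS), with
  diagonal (var_return_day, var_rls) and off-diagonal rho*sqrt(v1*v2).
* ``Omega`` — the selection-surface covariance describing the shape of the
  Gaussian fitness landscape.  The width scalar ``omega_scalar`` counts
  phenotypic standard deviations, so Omega = S C S with
  S = diag(omega*sd_rd, omega*sd_rls) and C the 2x2 correlation matrix whose
  off-diagonal defaults to the phenotypic rho (then Omega = omega**2 * P).
  The surface correlation can be overridden independently via
  ``omega_correlation`` for sensitivity checks.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Optional

import numpy as np
import yaml

logger = logging.getLogger("phenomate")

#: sex codes used in array storage
MALE: int = 0
FEMALE: int = 1

SEX_LABELS = {MALE: "male", FEMALE: "female"}

MATING_MODES = ("assortative", "random", "random_uniform")
RS_MODES = ("poisson_quantile", "poisson_thinned")
OMEGA_MODES = ("variance_scaled", "sd_scaled")
FITNESS_SCALINGS = ("cohort_minmax", "none")


class ConfigError(ValueError):
    """Raised when a configuration is missing keys or violates an invariant."""


@dataclass(frozen=True)
class SimulationConfig:
    """Validated input parameters for one simulation.

    Required fields have no default; everything else takes the standard run
    controls (30-day season, Poisson rate 2, 10 generations, 100 iterations,
    functional-extinction threshold of 50 individuals, assortative mating).
    """

    nc_initial: int
    mu_return_day: float
    mu_rls: float
    var_return_day: float
    var_rls: float
    rho: float
    omega_scalar: float
    var_theta_return_day: float
    var_theta_rls: float
    season_length: float = 30.0
    lambda_rs: float = 2.0
    generations: int = 10
    iterations: int = 100
    extinction_threshold: int = 50
    mating_mode: str = "assortative"
    rs_mode: str = "poisson_quantile"
    omega_mode: str = "variance_scaled"
    fitness_scaling: str = "cohort_minmax"
    omega_correlation: Optional[float] = None
    exact_sex_split: bool = False
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.nc_initial < 2:
            raise ConfigError(f"nc_initial must be >= 2, got {self.nc_initial}")
        for name in ("var_return_day", "var_rls", "var_theta_return_day",
                     "var_theta_rls"):
            v = getattr(self, name)
            if name.startswith("var_theta"):
                if v < 0:
                    raise ConfigError(f"{name} must be >= 0, got {v}")
            elif v <= 0:
                raise ConfigError(f"{name} must be > 0, got {v}")
        if abs(self.rho) > 1:
            raise ConfigError(f"|rho| must be <= 1, got {self.rho}")
        if self.omega_correlation is not None and abs(self.omega_correlation) > 1:
            raise ConfigError(
                f"|omega_correlation| must be <= 1, got {self.omega_correlation}")
        if self.omega_scalar <= 0:
            raise ConfigError(f"omega_scalar must be > 0, got {self.omega_scalar}")
        if not (self.season_length > self.mu_return_day > 0):
            raise ConfigError(
                "require season_length > mu_return_day > 0, got "
                f"season_length={self.season_length}, mu_return_day={self.mu_return_day}")
        if self.mu_rls < 1:
            raise ConfigError(f"mu_rls must be >= 1, got {self.mu_rls}")
        if self.lambda_rs <= 0:
            raise ConfigError(f"lambda_rs must be > 0, got {self.lambda_rs}")
        if self.generations < 1:
            raise ConfigError(f"generations must be >= 1, got {self.generations}")
        if self.iterations < 1:
            raise ConfigError(f"iterations must be >= 1, got {self.iterations}")
        if self.extinction_threshold < 0:
            raise ConfigError("extinction_threshold must be >= 0")
        if self.mating_mode not in MATING_MODES:
            raise ConfigError(
                f"mating_mode must be one of {MATING_MODES}, got {self.mating_mode!r}")
        if self.rs_mode not in RS_MODES:
            raise ConfigError(
                f"rs_mode must be one of {RS_MODES}, got {self.rs_mode!r}")
        if self.omega_mode not in OMEGA_MODES:
            raise ConfigError(
                f"omega_mode must be one of {OMEGA_MODES}, got {self.omega_mode!r}")
        if self.fitness_scaling not in FITNESS_SCALINGS:
            raise ConfigError(
                f"fitness_scaling must be one of {FITNESS_SCALINGS}, "
                f"got {self.fitness_scaling!r}")

    def replace(self, **overrides) -> "SimulationConfig":
        """Return a copy with the given fields replaced (and re-validated)."""
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_REQUIRED = ("nc_initial", "mu_return_day", "mu_rls", "var_return_day",
             "var_rls", "rho", "omega_scalar", "var_theta_return_day",
             "var_theta_rls")

_ALL_KEYS = {f.name for f in dataclasses.fields(SimulationConfig)}


def validate_config(raw: Mapping) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a key-value mapping.

    Unknown keys are rejected; missing required keys raise; run controls not
    supplied take their defaults.
    """
    unknown = set(raw) - _ALL_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    missing = [k for k in _REQUIRED if k not in raw]
    if missing:
        raise ConfigError(f"missing required configuration keys: {missing}")
    return SimulationConfig(**dict(raw))


def load_config(path) -> SimulationConfig:
    """Read a YAML or JSON config file and validate it."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ConfigError(f"config file {path} did not parse to a mapping")
    return validate_config(raw)


@dataclass(frozen=True)
class CovarianceSet:
    """The constant phenotypic (P) and selection-surface (Omega) covariances."""

    P: np.ndarray
    Omega: np.ndarray
    Omega_inv: np.ndarray = field(repr=False, default=None)


def _check_pd(m: np.ndarray, name: str) -> None:
    eigvals = np.linalg.eigvalsh(m)
    if eigvals.min() <= 0:
        raise ConfigError(
            f"{name} is not positive definite (eigenvalues {eigvals}); "
            "|rho| = 1 makes the trait distribution degenerate")


def build_covariances(cfg: SimulationConfig) -> CovarianceSet:
    """Construct P and Omega from the config.

    ``omega_mode`` sets how the width scalar stretches the surface relative
    to the trait distribution:

    * ``variance_scaled`` (default): surface variances are omega times the
      trait variances, Omega = omega * D C D with D = diag(sd); with the
      surface correlation matched to rho this is Omega = omega * P.  This is
      the calibration under which the simulator reproduces the published
      sensitivity trajectories.
    * ``sd_scaled``: surface standard deviations are omega times the trait
      standard deviations, Omega = omega**2 * P — the textbook
      "width in phenotypic SD units" reading.

    The surface correlation defaults to the phenotypic rho and can be set
    independently via ``omega_correlation``.
    """
    sd = np.sqrt([cfg.var_return_day, cfg.var_rls])
    rho = cfg.rho
    P = np.array([[sd[0] ** 2, rho * sd[0] * sd[1]],
                  [rho * sd[0] * sd[1], sd[1] ** 2]])
    rho_omega = cfg.rho if cfg.omega_correlation is None else cfg.omega_correlation
    C = np.array([[1.0, rho_omega], [rho_omega, 1.0]])
    scale = (cfg.omega_scalar if cfg.omega_mode == "variance_scaled"
             else cfg.omega_scalar ** 2)
    D = np.diag(sd)
    Omega = scale * (D @ C @ D)
    _check_pd(P, "P")
    _check_pd(Omega, "Omega")
    return CovarianceSet(P=P, Omega=Omega, Omega_inv=np.linalg.inv(Omega))


@dataclass
class Individual:
    """One fish: identity, sex, phenology, fitness bookkeeping, parentage."""

    id: int
    sex: str
    generation: int
    return_day: float
    rls: float
    rs_exp: Optional[int] = None
    rs_obs: Optional[int] = None
    dam_id: Optional[int] = None
    sire_id: Optional[int] = None


class Cohort:
    """One generation of individuals, stored column-wise for speed.

    Columns: ``ids``, ``sex`` (0 = male, 1 = female), ``return_day``, ``rls``,
    ``rs_exp``, ``rs_obs``, ``dam_id``, ``sire_id`` (-1 marks a founder's
    missing parent).  ``theta`` holds the realized bivariate optimum
    (theta_return_day, theta_rls) once drawn for this generation.
    """

    def __init__(self, generation: int, ids, sex, return_day, rls,
                 dam_id=None, sire_id=None):
        n = len(ids)
        self.generation = int(generation)
        self.ids = np.asarray(ids, dtype=np.int64)
        self.sex = np.asarray(sex, dtype=np.int8)
        self.return_day = np.asarray(return_day, dtype=float)
        self.rls = np.asarray(rls, dtype=float)
        self.dam_id = (np.full(n, -1, dtype=np.int64) if dam_id is None
                       else np.asarray(dam_id, dtype=np.int64))
        self.sire_id = (np.full(n, -1, dtype=np.int64) if sire_id is None
                        else np.asarray(sire_id, dtype=np.int64))
        self.rs_exp: Optional[np.ndarray] = None
        self.rs_obs: Optional[np.ndarray] = None
        self.theta: Optional[np.ndarray] = None

    @classmethod
    def empty(cls, generation: int) -> "Cohort":
        return cls(generation, np.empty(0, dtype=np.int64),
                   np.empty(0, dtype=np.int8), np.empty(0), np.empty(0))

    @property
    def size(self) -> int:
        return len(self.ids)

    @property
    def is_female(self) -> np.ndarray:
        return self.sex == FEMALE

    @property
    def is_male(self) -> np.ndarray:
        return self.sex == MALE

    @property
    def traits(self) -> np.ndarray:
        """n x 2 array of (return_day, rls)."""
        return np.column_stack([self.return_day, self.rls])

    def individuals(self) -> Iterator[Individual]:
        rs_exp = self.rs_exp if self.rs_exp is not None else [None] * self.size
        rs_obs = self.rs_obs if self.rs_obs is not None else [None] * self.size
        for i in range(self.size):
            yield Individual(
                id=int(self.ids[i]),
                sex=SEX_LABELS[int(self.sex[i])],
                generation=self.generation,
                return_day=float(self.return_day[i]),
                rls=float(self.rls[i]),
                rs_exp=None if rs_exp[i] is None else int(rs_exp[i]),
                rs_obs=None if rs_obs[i] is None else int(rs_obs[i]),
                dam_id=None if self.dam_id[i] < 0 else int(self.dam_id[i]),
                sire_id=None if self.sire_id[i] < 0 else int(self.sire_id[i]),
            )

    def __len__(self) -> int:
        return self.size

    def __repr__(self) -> str:
        return (f"Cohort(generation={self.generation}, n={self.size}, "
                f"females={int(self.is_female.sum())})")
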