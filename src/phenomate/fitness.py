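"""Stabilizing selection: fluctuating optimum, fitness weights, expected RS.

Each generation draws a fresh bivariate optimum theta around the initial
trait means with the configured interannual environmental variances.  An
individual's raw fitness weight is the Gaussian kernel

    W(z) = exp(-1/2 (z - theta)' Omega^-1 (z - theta)),

and a scaling step then maps the cohort's weights onto [0, 1].  The default
(``fitness_scaling="cohort_minmax"``) rescales within the cohort so the
least-fit breeder gets 0 and the fittest gets 1; this makes lambda = 2 an
exact stability point (uniformly spread weights give mean quantile-mapped RS
equal to lambda), so growth and decline are driven by the *shape* of the
cohort's fitness distribution around the optimum.  ``"none"`` keeps the raw
kernel values.  Weights map to expected reproductive success RS_exp either
deterministically, as the Poisson(lambda) quantile of the weight (default),
or stochastically as a Poisson(lambda * weight) draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import Cohort, SimulationConfig

# the Poisson quantile diverges as w -> 1; cap the probability just below it
_W_CAP = 1.0 - 1e-9


@dataclass(frozen=True)
class OptimumDraw:
    """The realized bivariate optimum for one generation."""

    theta_return_day: float
    theta_rls: float

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.theta_return_day, self.theta_rls])


def draw_optima(cfg: SimulationConfig, rng) -> OptimumDraw:
    """Draw theta ~ Normal(mu, var_theta), independently per trait.

    The draw is untruncated: an optimum outside the season window is a
    legitimately bad year that no individual can match.
    """
    t_rd = cfg.mu_return_day + np.sqrt(cfg.var_theta_return_day) * rng.standard_normal()
    t_rls = cfg.mu_rls + np.sqrt(cfg.var_theta_rls) * rng.standard_normal()
    return OptimumDraw(float(t_rd), float(t_rls))


def fitness_weight(z, theta, Omega, Omega_inv=None):
    """Gaussian fitness weight of trait vector(s) ``z`` around ``theta``.

    ``z`` may be a single 2-vector or an (n, 2) array; returns a float or an
    array of weights in (0, 1].
    """
    if Omega_inv is None:
        Omega = np.asarray(Omega, dtype=float)
        det = np.linalg.det(Omega)
        if not np.isfinite(det) or abs(det) < 1e-300:
            raise ValueError("Omega is singular; fitness surface undefined")
        Omega_inv = np.linalg.inv(Omega)
    t = theta.vector if isinstance(theta, OptimumDraw) else np.asarray(theta, float)
    z = np.asarray(z, dtype=float)
    d = z - t
    if d.ndim == 1:
        q = float(d @ Omega_inv @ d)
        return float(np.exp(-0.5 * q))
    q = np.einsum("ij,jk,ik->i", d, Omega_inv, d)
    return np.exp(-0.5 * q)


def expected_rs(w, lambda_rs: float = 2.0, mode: str = "poisson_quantile",
                rng=None):
    """Map fitness weight(s) in [0, 1] to expected reproductive success.

    ``poisson_quantile`` (default): the smallest integer k with
    Poisson(lambda) CDF(k) >= w — deterministic and non-decreasing in w, with
    w capped just below 1 so the quantile stays finite.
    ``poisson_thinned``: a Poisson(lambda * w) draw (requires ``rng``).
    """
    w_arr = np.asarray(w, dtype=float)
    if np.any((w_arr < 0) | (w_arr > 1)):
        raise ValueError("fitness weights must lie in [0, 1]")
    if mode == "poisson_quantile":
        capped = np.minimum(w_arr, _W_CAP)
        k = stats.poisson.ppf(capped, lambda_rs)
        k = np.maximum(k, 0.0)  # scipy returns -1 at w == 0
        out = k.astype(np.int64)
    elif mode == "poisson_thinned":
        if rng is None:
            raise ValueError("poisson_thinned mode needs an rng")
        out = rng.poisson(lambda_rs * w_arr).astype(np.int64)
    else:
        raise ValueError(f"unknown rs mode {mode!r}")
    if np.ndim(w) == 0:
        return int(out.item() if out.ndim else out)
    return out


def rescale_weights(w: np.ndarray, mode: str = "cohort_minmax") -> np.ndarray:
    """Apply the cohort-level weight scaling (the y step).

    ``cohort_minmax`` maps the cohort's weights affinely onto [0, 1]; a
    cohort with identical weights maps to 0.5 everywhere (no information to
    rank on).  ``none`` returns the raw kernel values.
    """
    if mode == "none":
        return w
    if mode != "cohort_minmax":
        raise ValueError(f"unknown fitness scaling {mode!r}")
    w = np.asarray(w, dtype=float)
    lo, hi = w.min(), w.max()
    if hi <= lo:
        return np.full_like(w, 0.5)
    return (w - lo) / (hi - lo)


def assign_expected_rs(cohort: Cohort, cfg: SimulationConfig, Omega, rng,
                       Omega_inv=None) -> Cohort:
    """Set ``rs_exp`` for every individual from its own trait pair.

    Requires ``cohort.theta`` to have been drawn.  Both sexes use the same
    map; selection acts identically on males and females.
    """
    if cohort.theta is None:
        raise ValueError("cohort.theta must be drawn before assigning rs_exp")
    w = fitness_weight(cohort.traits, cohort.theta, Omega, Omega_inv=Omega_inv)
    w = rescale_weights(w, cfg.fitness_scaling)
    cohort.rs_exp = expected_rs(w, cfg.lambda_rs, cfg.rs_mode, rng=rng)
    return cohort
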