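"""Founder-cohort construction.

Founder (F0) traits are drawn from a truncated bivariate normal: return day
first from its truncated marginal on [1, season_length - 1], then RLS from
the conditional normal given return day, truncated to
[1, season_length - return_day] so no fish outlives the spawning season.
Both draws use the inverse-CDF on the truncated interval, so sampling is
deterministic given the RNG stream and never rejects.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, ndtri

from .config import Cohort, SimulationConfig

# below this standard deviation the truncated draw collapses to the clipped mean
_SD_FLOOR = 1e-12


def _truncated_normal(u, mean, sd, lo, hi):
    """Inverse-CDF draw from Normal(mean, sd^2) truncated to [lo, hi].

    ``u`` are uniforms on (0, 1); all arguments broadcast.  Degenerate cases
    (sd ~ 0, or the interval carrying no mass in double precision) return the
    mean clipped to the interval.
    """
    u = np.asarray(u, dtype=float)
    mean = np.broadcast_to(np.asarray(mean, dtype=float), u.shape).copy()
    sd = np.broadcast_to(np.asarray(sd, dtype=float), u.shape)
    lo = np.broadcast_to(np.asarray(lo, dtype=float), u.shape)
    hi = np.broadcast_to(np.asarray(hi, dtype=float), u.shape)

    out = np.clip(mean, lo, hi)
    ok = sd > _SD_FLOOR
    if np.any(ok):
        a = ndtr((lo[ok] - mean[ok]) / sd[ok])
        b = ndtr((hi[ok] - mean[ok]) / sd[ok])
        mass = b - a
        q = a + u[ok] * mass
        # keep the quantile strictly inside (0, 1) for ndtri
        tiny = np.finfo(float).tiny
        q = np.clip(q, tiny, 1.0 - np.finfo(float).epsneg)
        x = mean[ok] + sd[ok] * ndtri(q)
        x = np.clip(x, lo[ok], hi[ok])
        # intervals with no mass in double precision: fall back to clipped mean
        x = np.where(mass > 0, x, np.clip(mean[ok], lo[ok], hi[ok]))
        out[ok] = x
    return out


def sample_trait_pair(mean_rd, mean_rls, P, season_length, rng, size=None):
    """Draw (return_day, rls) pairs from the truncated bivariate normal.

    Return day comes from the marginal Normal(mean_rd, P[0,0]) truncated to
    [1, season_length - 1]; RLS then comes from the conditional
    Normal(mean_rls + (P01/P00)(rd - mean_rd), P11 - P01^2/P00) truncated to
    [1, season_length - rd].  ``mean_rd``/``mean_rls`` may be arrays (one mean
    per draw, as in mid-parent inheritance).

    Returns a pair of arrays if ``size`` is given or the means are arrays,
    otherwise a pair of floats.
    """
    P = np.asarray(P, dtype=float)
    scalar = size is None and np.ndim(mean_rd) == 0 and np.ndim(mean_rls) == 0
    if size is None:
        size = np.broadcast_shapes(np.shape(mean_rd), np.shape(mean_rls))
        if size == ():
            size = (1,)
    n = int(np.prod(size))

    sd_rd = np.sqrt(P[0, 0])
    u1 = rng.random(n)
    rd = _truncated_normal(u1, np.broadcast_to(mean_rd, size).ravel(),
                           sd_rd, 1.0, season_length - 1.0)

    slope = P[0, 1] / P[0, 0]
    cond_var = P[1, 1] - P[0, 1] ** 2 / P[0, 0]
    cond_mean = (np.broadcast_to(mean_rls, size).ravel()
                 + slope * (rd - np.broadcast_to(mean_rd, size).ravel()))
    u2 = rng.random(n)
    rls = _truncated_normal(u2, cond_mean, np.sqrt(max(cond_var, 0.0)),
                            1.0, season_length - rd)

    if scalar:
        return float(rd[0]), float(rls[0])
    return rd.reshape(size), rls.reshape(size)


def sample_sexes(n: int, rng, exact_split: bool = False) -> np.ndarray:
    """Sex codes for ``n`` individuals: Bernoulli(0.5) or an exact 1:1 split."""
    if exact_split:
        sexes = np.zeros(n, dtype=np.int8)
        sexes[: n // 2] = 1
        rng.shuffle(sexes)
        return sexes
    return rng.integers(0, 2, size=n).astype(np.int8)


def init_founders(cfg: SimulationConfig, rng, P=None) -> Cohort:
    """Create the founder cohort: generation 0, no recorded parents.

    Sexes are assigned male or female with equal probability; traits come
    from :func:`sample_trait_pair` centred on the configured population means.
    """
    if P is None:
        from .config import build_covariances

        P = build_covariances(cfg).P
    n = cfg.nc_initial
    sexes = sample_sexes(n, rng, cfg.exact_sex_split)
    rd, rls = sample_trait_pair(cfg.mu_return_day, cfg.mu_rls, P,
                                cfg.season_length, rng, size=n)
    return Cohort(generation=0, ids=np.arange(n, dtype=np.int64),
                  sex=sexes, return_day=rd, rls=rls)
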