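"""Per-cohort summary statistics and replicate aggregation.

The inbreeding effective size follows the sex-specific mean/variance-of-
reproductive-success formulation: within each sex s with N_s potential
breeders, mean offspring number k̄_s and sample variance V_s (n-1
denominator),

    Ne_s = (N_s * k̄_s - 1) / (k̄_s - 1 + V_s / k̄_s),

and the two sexes combine as Ne = 4 Ne_m Ne_f / (Ne_m + Ne_f).  Ne computed
from a cohort's RS_obs is attributed to that (breeding) cohort, and Ne/Nc
uses the same cohort's census size.  Replicate aggregation reports the mean
across iterations per generation with a normal-approximation 95% CI
(mean ± 1.96 * SD / sqrt(n)); undefined Ne values are excluded pairwise with
the contributing count reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import Cohort

logger = logging.getLogger("phenomate")


@dataclass
class CohortSummary:
    """Demographic and trait statistics for one generation of one iteration."""

    generation: int
    nc: int
    ne: float
    ne_nc_ratio: float
    mean_return_day: float
    var_return_day: float
    mean_rls: float
    var_rls: float
    theta_return_day: float
    theta_rls: float
    extinct_flag: bool

    def to_dict(self) -> dict:
        return asdict(self)


def _sex_ne(rs_obs: np.ndarray) -> float:
    n = len(rs_obs)
    if n == 0:
        return math.nan
    kbar = rs_obs.mean()
    if kbar == 0:
        return math.nan
    vk = rs_obs.var(ddof=1) if n > 1 else 0.0
    denom = kbar - 1.0 + vk / kbar
    if denom <= 0:
        # every breeder contributes exactly one offspring: no drift signal
        return math.inf
    return (n * kbar - 1.0) / denom


def effective_size(parents: Cohort) -> float:
    """Sex-combined inbreeding Ne from a breeding cohort's RS_obs.

    Returns NaN when either sex is absent or produced no offspring (Ne
    undefined for that cohort); the event is logged.
    """
    if parents.rs_obs is None:
        raise ValueError("rs_obs must be assigned before computing Ne")
    ne_m = _sex_ne(parents.rs_obs[parents.is_male])
    ne_f = _sex_ne(parents.rs_obs[parents.is_female])
    if math.isnan(ne_m) or math.isnan(ne_f) or (ne_m + ne_f) <= 0:
        logger.debug("generation %d: Ne undefined (ne_m=%s, ne_f=%s)",
                     parents.generation, ne_m, ne_f)
        return math.nan
    if math.isinf(ne_m) and math.isinf(ne_f):
        return math.inf
    if math.isinf(ne_m):
        return 4.0 * ne_f  # limit of the harmonic combination
    if math.isinf(ne_f):
        return 4.0 * ne_m
    return 4.0 * ne_m * ne_f / (ne_m + ne_f)


def summarize_cohort(cohort: Cohort, extinction_threshold: int) -> CohortSummary:
    """All per-cohort outputs; trait statistics are NaN for an empty cohort."""
    nc = cohort.size
    if nc == 0:
        return CohortSummary(cohort.generation, 0, math.nan, math.nan,
                             math.nan, math.nan, math.nan, math.nan,
                             math.nan, math.nan, True)
    ne = effective_size(cohort) if cohort.rs_obs is not None else math.nan
    theta = cohort.theta
    return CohortSummary(
        generation=cohort.generation,
        nc=nc,
        ne=ne,
        ne_nc_ratio=ne / nc if np.isfinite(ne) else math.nan,
        mean_return_day=float(cohort.return_day.mean()),
        var_return_day=float(cohort.return_day.var(ddof=1)) if nc > 1 else 0.0,
        mean_rls=float(cohort.rls.mean()),
        var_rls=float(cohort.rls.var(ddof=1)) if nc > 1 else 0.0,
        theta_return_day=float(theta[0]) if theta is not None else math.nan,
        theta_rls=float(theta[1]) if theta is not None else math.nan,
        extinct_flag=bool(nc < extinction_threshold),
    )


def summaries_to_frame(streams: Sequence[Sequence[CohortSummary]],
                       iteration_ids: Optional[Sequence[int]] = None
                       ) -> pd.DataFrame:
    """Stack per-iteration summary streams into one long DataFrame."""
    if iteration_ids is None:
        iteration_ids = range(len(streams))
    rows = []
    for it, stream in zip(iteration_ids, streams):
        for s in stream:
            d = s.to_dict()
            d["iteration"] = it
            rows.append(d)
    df = pd.DataFrame(rows)
    cols = ["iteration"] + [c for c in df.columns if c != "iteration"]
    return df[cols]


#: outputs aggregated across iterations
_AGG_COLS = ("nc", "ne", "ne_nc_ratio", "mean_return_day", "var_return_day",
             "mean_rls", "var_rls")


def aggregate_iterations(per_iteration) -> pd.DataFrame:
    """Replicate means with 95% CIs per generation.

    Accepts either a long DataFrame (from :func:`summaries_to_frame`) or a
    sequence of per-iteration summary streams.  For each output column the
    result holds ``<col>_mean``, ``<col>_lo``, ``<col>_hi`` and ``<col>_n``
    (iterations contributing, after pairwise NaN exclusion).
    """
    if not isinstance(per_iteration, pd.DataFrame):
        per_iteration = summaries_to_frame(per_iteration)
    df = per_iteration
    if df["iteration"].nunique() < 2:
        raise ValueError("aggregation needs at least 2 iterations")

    out = {}
    g = df.groupby("generation")
    for col in _AGG_COLS:
        mean = g[col].mean()  # pandas skips NaN
        sd = g[col].std(ddof=1)
        n = g[col].count()
        half = 1.96 * sd / np.sqrt(n)
        out[f"{col}_mean"] = mean
        out[f"{col}_lo"] = mean - half
        out[f"{col}_hi"] = mean + half
        out[f"{col}_n"] = n
    out["extinct_fraction"] = g["extinct_flag"].mean()
    return pd.DataFrame(out).reset_index()
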