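"""Mating and reproduction: pair weights, recruitment, parentage assignment.

Recruitment is female-limited: the next generation's census size is the sum
of RS_exp over females.  Every offspring in that pool is then assigned a
(sire, dam) pair by a weighted draw with replacement, with pair weight

    W[i, j] = W_m(i) * W_f(j) * W_o(i, j),

where W_m and W_f are each parent's RS_exp relative to the whole-cohort mean
RS_exp, and W_o is a binary temporal-overlap gate: 1 if male i and female j
were on the spawning grounds on at least one common day, 0 otherwise.
Overlap duration does not matter.  Mating modes:

* ``assortative`` — the gate is active (mate choice by timing).
* ``random``      — W_o = 1 for all pairs; selection still acts through
  W_m * W_f.
* ``random_uniform`` — W[i, j] = 1 for all pairs: fully neutral assignment
  (no mate choice, no selection on parentage).

Realized (observed) reproductive success RS_obs is the offspring count per
parent after assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import Cohort

logger = logging.getLogger("phenomate")


def presence_interval(ind):
    """Days an individual is on the spawning grounds: [return_day, return_day + rls].

    Accepts an :class:`Individual` or any object with ``return_day`` and
    ``rls`` attributes.
    """
    return (ind.return_day, ind.return_day + ind.rls)


def overlap_weight(male, female) -> int:
    """1 if the two presence intervals intersect (touching counts), else 0."""
    s1, e1 = presence_interval(male)
    s2, e2 = presence_interval(female)
    return int(max(s1, s2) <= min(e1, e2))


@dataclass
class PairWeightMatrix:
    """Pair weights with rows = males, columns = females.

    ``w = w_male[:, None] * w_female[None, :] * overlap`` element-wise.
    """

    w: np.ndarray
    w_male: np.ndarray
    w_female: np.ndarray
    overlap: np.ndarray
    male_index: np.ndarray    # row -> position in cohort arrays
    female_index: np.ndarray  # column -> position in cohort arrays
    male_ids: np.ndarray
    female_ids: np.ndarray

    @property
    def total(self) -> float:
        return float(self.w.sum())


def _overlap_matrix(start_m, end_m, start_f, end_f) -> np.ndarray:
    return ((start_m[:, None] <= end_f[None, :])
            & (start_f[None, :] <= end_m[:, None]))


def pair_weights(cohort: Cohort, mode: str = "assortative") -> PairWeightMatrix:
    """Compute the full male x female pair-weight matrix for one cohort.

    The RS_exp normalizer is the mean over the whole cohort (both sexes).
    A cohort whose mean RS_exp is zero, or with a sex missing, yields an
    all-zero / empty matrix; the caller treats that as reproductive failure.
    """
    if cohort.rs_exp is None:
        raise ValueError("rs_exp must be assigned before computing pair weights")
    m_idx = np.flatnonzero(cohort.is_male)
    f_idx = np.flatnonzero(cohort.is_female)
    n_m, n_f = len(m_idx), len(f_idx)

    mean_rs = cohort.rs_exp.mean() if cohort.size else 0.0
    if mean_rs > 0:
        w_m = cohort.rs_exp[m_idx] / mean_rs
        w_f = cohort.rs_exp[f_idx] / mean_rs
    else:
        w_m = np.zeros(n_m)
        w_f = np.zeros(n_f)

    if mode == "assortative":
        start = cohort.return_day
        end = cohort.return_day + cohort.rls
        ov = _overlap_matrix(start[m_idx], end[m_idx], start[f_idx], end[f_idx])
    elif mode in ("random", "random_uniform"):
        ov = np.ones((n_m, n_f), dtype=bool)
    else:
        raise ValueError(f"unknown mating mode {mode!r}")

    if mode == "random_uniform":
        w = ov.astype(float)
        w_m = np.ones(n_m)
        w_f = np.ones(n_f)
    else:
        w = w_m[:, None] * w_f[None, :] * ov

    return PairWeightMatrix(
        w=w, w_male=w_m, w_female=w_f, overlap=ov.astype(np.int8),
        male_index=m_idx, female_index=f_idx,
        male_ids=cohort.ids[m_idx], female_ids=cohort.ids[f_idx])


def recruit_count(cohort: Cohort) -> int:
    """Census size of the next generation: the sum of RS_exp over females."""
    if cohort.rs_exp is None:
        raise ValueError("rs_exp must be assigned before counting recruits")
    if cohort.size == 0:
        return 0
    return int(cohort.rs_exp[cohort.is_female].sum())


def assign_parents(cohort: Cohort, n_offspring: int,
                   weights: PairWeightMatrix, rng):
    """Assign each offspring a (dam, sire) pair by weighted draw with replacement.

    Each of the ``n_offspring`` draws picks pair (i, j) with probability
    W[i, j] / sum(W), independently; no per-female fecundity cap and no
    monogamy.  Sets ``cohort.rs_obs`` (offspring counted for both parents)
    and returns ``(dam_ids, sire_ids)`` arrays.  If all weights are zero the
    cohort fails to reproduce and empty arrays are returned.
    """
    cohort.rs_obs = np.zeros(cohort.size, dtype=np.int64)
    empty = (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
    if n_offspring == 0:
        return empty
    total = weights.w.sum()
    if weights.w.size == 0 or total <= 0:
        logger.warning(
            "generation %d: reproductive failure (no positive pair weights, "
            "%d offspring unassigned)", cohort.generation, n_offspring)
        return empty

    flat = weights.w.ravel()
    n_f = len(weights.female_index)
    cells = rng.choice(flat.size, size=n_offspring, p=flat / total)
    rows, cols = np.divmod(cells, n_f)
    sire_pos = weights.male_index[rows]
    dam_pos = weights.female_index[cols]
    counts = np.bincount(sire_pos, minlength=cohort.size)
    counts += np.bincount(dam_pos, minlength=cohort.size)
    cohort.rs_obs = counts.astype(np.int64)
    return cohort.ids[dam_pos], cohort.ids[sire_pos]
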