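"""Quantitative-genetic inheritance and next-cohort assembly.

Offspring traits follow deterministic mid-parent inheritance: each
offspring's trait pair is drawn from the same truncated bivariate normal
used at initialization, but centred on the average of its dam's and sire's
(return_day, rls).  The segregation covariance is the full constant
phenotypic matrix P (no explicit G/R split; heritability is implicit).
Return day is drawn first from its truncated marginal, then RLS from the
conditional given return day — so the truncation bias in RLS is part of the
model, not corrected.
"""

from __future__ import annotations

import numpy as np

from .config import Cohort, SimulationConfig
from .initialization import sample_trait_pair, sample_sexes


def midparent(dam, sire) -> np.ndarray:
    """Element-wise mean of the two parents' (return_day, rls)."""
    return np.array([(dam.return_day + sire.return_day) / 2.0,
                     (dam.rls + sire.rls) / 2.0])


def draw_offspring_traits(mid, P, season_length, rng):
    """Draw one (return_day, rls) pair around a mid-parent vector.

    Identical sampling scheme to founder initialization, centred on ``mid``.
    """
    mid = np.asarray(mid, dtype=float)
    return sample_trait_pair(mid[0], mid[1], P, season_length, rng)


def make_offspring_cohort(parent_cohort: Cohort, assignments,
                          cfg: SimulationConfig, rng, P=None,
                          id_start: int = 0) -> Cohort:
    """Build generation t+1 from (dam_id, sire_id) assignments.

    One offspring per assignment: fresh sequential ids starting at
    ``id_start``, sex male/female with equal probability, traits drawn around
    each pair's mid-parent vector.  RS fields stay unset until the new cohort
    itself reproduces.
    """
    if P is None:
        from .config import build_covariances

        P = build_covariances(cfg).P
    dam_ids, sire_ids = assignments
    dam_ids = np.asarray(dam_ids, dtype=np.int64)
    sire_ids = np.asarray(sire_ids, dtype=np.int64)
    n = len(dam_ids)
    gen = parent_cohort.generation + 1
    if n == 0:
        return Cohort.empty(gen)

    # parent ids are sorted ascending by construction
    dam_pos = np.searchsorted(parent_cohort.ids, dam_ids)
    sire_pos = np.searchsorted(parent_cohort.ids, sire_ids)
    n_par = parent_cohort.size
    if (dam_pos.max(initial=-1) >= n_par or sire_pos.max(initial=-1) >= n_par
            or np.any(parent_cohort.ids[dam_pos] != dam_ids)
            or np.any(parent_cohort.ids[sire_pos] != sire_ids)):
        raise ValueError("assignment refers to ids not in the parent cohort")

    mid_rd = (parent_cohort.return_day[dam_pos]
              + parent_cohort.return_day[sire_pos]) / 2.0
    mid_rls = (parent_cohort.rls[dam_pos] + parent_cohort.rls[sire_pos]) / 2.0
    rd, rls = sample_trait_pair(mid_rd, mid_rls, P, cfg.season_length, rng)
    sexes = sample_sexes(n, rng, cfg.exact_sex_split)
    ids = np.arange(id_start, id_start + n, dtype=np.int64)
    return Cohort(generation=gen, ids=ids, sex=sexes, return_day=rd, rls=rls,
                  dam_id=dam_ids, sire_id=sire_ids)
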