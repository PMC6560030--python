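"""Simplified ROI-timecourse psychophysiological interaction (PPI).

Task-dependent connectivity between a seed region and a target region is
indexed by the coefficient of the product of the (centered) seed
timecourse and an HRF-convolved psychological regressor, over and above
both main effects.  No BOLD deconvolution is attempted: the psychological
term is convolved with the canonical HRF and multiplied with the measured
seed timecourse, a stated simplification relative to SPM's deconvolved
PPI.

Two analyses are provided: a general PPI per task state (state 1,
feedback, rest; conjunction = minimum statistic across states), and a
learning PPI whose psychological term contrasts late learning
(correct-repetition bins 2 and 3) against early learning (bins 0 and 1)
at state 1, omitting mazes that were never learned.  At the group level
the learning PPI coefficient is tested against zero and correlated across
participants with each participant's future x correct-repetition
decoding effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import GroupResult, correlate, one_sample_test
from .glm import convolve_events


@dataclass
class PpiFit:
    interaction: float
    t: float
    p: float
    coefficients: dict[str, float]


def _psych_regressor(events: pd.DataFrame, weights: np.ndarray, n_scans: int,
                     tr: float) -> np.ndarray:
    X = convolve_events(events["onset"].to_numpy(), events["duration"].to_numpy(),
                        n_scans, tr)
    return X @ np.asarray(weights, float)


def _ppi_regression(target: np.ndarray, seed: np.ndarray, psych: np.ndarray,
                    nuisance: np.ndarray | None = None) -> PpiFit:
    if len(target) != len(seed):
        raise ValueError("seed and target timecourses must have equal length")
    if np.std(psych) == 0:
        raise ValueError("psychological regressor has zero variance")
    phys = seed - seed.mean()
    psy = psych - psych.mean()
    inter = phys * psy
    cols = [np.ones(len(seed)), phys, psy, inter]
    names = ["intercept", "physio", "psych", "interaction"]
    if nuisance is not None:
        nuis = np.atleast_2d(np.asarray(nuisance, float))
        if nuis.shape[0] != len(seed):
            nuis = nuis.T
        for j in range(nuis.shape[1]):
            cols.append(nuis[:, j])
            names.append(f"nuisance{j}")
    X = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(X, target, rcond=None)
    resid = target - X @ coef
    dof = len(target) - X.shape[1]
    sigma2 = float(resid @ resid) / max(dof, 1)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    j = names.index("interaction")
    se = np.sqrt(cov[j, j])
    from scipy import stats
    t = coef[j] / se if se > 0 else np.nan
    p = 2 * stats.t.sf(abs(t), max(dof, 1)) if np.isfinite(t) else np.nan
    return PpiFit(float(coef[j]), float(t), float(p),
                  dict(zip(names, map(float, coef))))


def general_ppi(seed_tc: np.ndarray, target_tc: np.ndarray,
                events: pd.DataFrame, state: str, tr: float,
                nuisance: np.ndarray | None = None) -> PpiFit:
    """PPI for one state: boxcar of that state's events as psychological term."""
    seed = np.asarray(seed_tc, float)
    target = np.asarray(target_tc, float)
    ev = events[events["state"] == state]
    if len(ev) == 0:
        raise ValueError(f"no events at state {state!r}")
    psych = _psych_regressor(ev, np.ones(len(ev)), len(seed), tr)
    return _ppi_regression(target, seed, psych, nuisance)


def conjunction(fits: list[PpiFit]) -> float:
    """Minimum-statistic conjunction across states."""
    return float(min(f.t for f in fits))


def late_early_weights(events: pd.DataFrame, covariate: pd.Series,
                       behavior: pd.DataFrame, state: str = "S1",
                       drop_unlearned: bool = True) -> tuple[pd.DataFrame, np.ndarray]:
    """Zero-sum late-versus-early learning contrast over state events.

    +1 for events in correct-repetition bins 2-3, −1 for bins 0-1, scaled
    so the weights sum to zero; mazes never performed above chance
    (the correct S3 never reached) are omitted when ``drop_unlearned``.
    """
    ev = events[(events["state"] == state) & (events["of_interest"])].copy()
    if drop_unlearned:
        learned = behavior.groupby("maze_id")["reached_correct_s3"].any()
        ev = ev[ev["maze_id"].map(learned).fillna(False)]
    if len(ev) == 0:
        raise ValueError("no usable events for the late-early contrast")
    bins = np.array([covariate.get((r.maze_id, r.repetition), 0)
                     for r in ev.itertuples(index=False)], float)
    w = np.where(bins >= 2, 1.0, -1.0)
    n_pos, n_neg = (w > 0).sum(), (w < 0).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("late-early contrast needs events in both halves")
    w = np.where(w > 0, 1.0 / n_pos, -1.0 / n_neg)
    return ev.reset_index(drop=True), w


def learning_ppi_participant(seed_tc: np.ndarray, target_tc: np.ndarray,
                             events: pd.DataFrame, covariate: pd.Series,
                             behavior: pd.DataFrame, tr: float,
                             state: str = "S1", drop_unlearned: bool = True,
                             nuisance: np.ndarray | None = None) -> PpiFit:
    """Late-versus-early learning PPI coefficient for one participant."""
    seed = np.asarray(seed_tc, float)
    ev, w = late_early_weights(events, covariate, behavior, state, drop_unlearned)
    psych = _psych_regressor(ev, w, len(seed), tr)
    return _ppi_regression(np.asarray(target_tc, float), seed, psych, nuisance)


def learning_ppi(fits: list[PpiFit],
                 future_rep_effects: np.ndarray) -> tuple[GroupResult, float, float]:
    """Group test of learning-PPI coefficients plus covariate correlation.

    Returns (group one-sample t on the interaction coefficients, Pearson r
    with the per-participant future x correct-repetition decoding effect,
    its p value).
    """
    if len(fits) < 3:
        raise ValueError("need at least 3 participants")
    coefs = np.array([f.interaction for f in fits])
    if len(coefs) != len(future_rep_effects):
        raise ValueError("one covariate value per participant required")
    group = one_sample_test(coefs)
    r, p = correlate(coefs, np.asarray(future_rep_effects, float))
    return group, r, p
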