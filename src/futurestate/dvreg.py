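"""Decision-value regressions: the core inference on prospective coding.

For each category classifier, the decision values of state-1 events from
the eight mazes of interest are regressed on five predictors: a binary
current-state indicator (the on-screen S1 category matches the category of
interest), a binary future-state indicator (the correct S3 category
matches), the correct-repetition counter, and the two interactions of the
binary indicators with the counter.  The future x correct-repetition
interaction is the critical test: decision values for the distal category
should rise only as the correct distal room accumulates observations.

Coefficients are averaged across the three category models within each
participant (categories whose classifier failed the cross-phase
generalization check are excluded), and group inference is a one-sample
two-sided t test on the participant means.  Control models cover per-bin
breakdowns, reduced models dropping the current- or future-state terms,
variants at states 2, 3 and feedback, and a multi-ROI sweep reported with
uncorrected p values.

Predictors are left uncentered (binary 0/1 and 0-3 counts); centering is
available as an option and changes only the main-effect interpretation,
not the interaction.  "Future state" means the category of the correct
arm's S3 room — the state that would be visited under the correct policy —
regardless of the arm actually visited on a given repetition
(``future="visited"`` switches to the experienced arm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import GroupResult, one_sample_test
from .design import Design
from .simulate import correct_rep_covariate

PREDICTORS = ("current", "future", "correct_rep", "current_x_rep", "future_x_rep")


def build_correct_rep(behavior: pd.DataFrame, coding: str = "observed") -> pd.Series:
    """Correct-repetition covariate per maze x repetition (0..3).

    ``observed`` (primary): 0 at repetition 1 and until the repetition
    following the first visit to the correct S3, then +1 per repetition.
    ``correct_only``: increments only on correct trials.
    """
    return correct_rep_covariate(behavior, coding)


@dataclass
class CategoryRegressionFit:
    category: str
    coefficients: dict[str, float]
    intercept: float
    residual_sd: float
    n_obs: int
    valid: bool = True

    def coef(self, name: str) -> float:
        return self.coefficients[name]


def _lstsq_named(y: np.ndarray, cols: dict[str, np.ndarray]):
    names = list(cols)
    X = np.column_stack([np.ones(len(y))] + [cols[k] for k in names])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = [n for j, n in enumerate(["intercept"] + names)
               if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank]
        raise np.linalg.LinAlgError(
            f"rank-deficient design ({rank}/{X.shape[1]}); collinear columns: {bad}")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = max(1, len(y) - X.shape[1])
    return coef[0], dict(zip(names, coef[1:])), float(np.sqrt(resid @ resid / dof))


def build_state1_predictors(events: pd.DataFrame, design: Design,
                            covariate: pd.Series, target_category: str,
                            center: bool = False) -> pd.DataFrame:
    """Predictor columns for one category's S1 regression model.

    ``events`` must contain the S1 rows to model (of-interest mazes);
    binary current/future indicators are derived from the maze specs, the
    repetition column from the correct-repetition covariate, and the
    interactions are elementwise products.
    """
    idx = {m.maze_id: m for m in design.mazes}
    rows = []
    for ev in events.itertuples(index=False):
        m = idx.get(ev.maze_id)
        if m is None:
            raise KeyError(f"event references unknown maze {ev.maze_id}")
        cur = 1.0 if m.s1_category == target_category else 0.0
        fut = 1.0 if m.s3_correct_category == target_category else 0.0
        rep = float(covariate.get((ev.maze_id, ev.repetition), 0))
        rows.append((cur, fut, rep))
    X = pd.DataFrame(rows, columns=["current", "future", "correct_rep"])
    if center:
        X = X - X.mean()
    X["current_x_rep"] = X["current"] * X["correct_rep"]
    X["future_x_rep"] = X["future"] * X["correct_rep"]
    return X


def fit_decision_regression(dv: np.ndarray, predictors: pd.DataFrame,
                            category: str = "") -> CategoryRegressionFit:
    """OLS fit of one category's decision values on the five predictors."""
    y = np.asarray(dv, float)
    if len(y) < 6:
        raise ValueError("need at least 6 observations")
    cols = {k: predictors[k].to_numpy(float) for k in predictors.columns}
    icpt, coefs, rsd = _lstsq_named(y, cols)
    return CategoryRegressionFit(category=category, coefficients=coefs,
                                 intercept=icpt, residual_sd=rsd, n_obs=len(y))


def reduced_models(dv: np.ndarray, predictors: pd.DataFrame,
                   drop: str, category: str = "") -> CategoryRegressionFit:
    """Control model with the current- or future-state terms removed.

    Dropping a state removes both its binary indicator and its interaction
    with the correct-repetition counter.
    """
    if drop not in ("current", "future"):
        raise ValueError("drop must be 'current' or 'future' (not both)")
    keep = [c for c in predictors.columns if not c.startswith(drop)]
    return fit_decision_regression(dv, predictors[keep], category)


def per_bin_models(dv: np.ndarray, predictors: pd.DataFrame) -> pd.DataFrame:
    """Current and future effects estimated separately per repetition bin.

    For each value of the correct-repetition counter, decision values are
    regressed on the current and future indicators alone.  Bins with too
    few observations or a constant indicator are skipped.  Supports the
    breakdown in which future-state information grows with learning while
    current-state information stays flat.
    """
    y = np.asarray(dv, float)
    rep = predictors["correct_rep"].to_numpy(float)
    rows = []
    for b in sorted(np.unique(rep)):
        m = rep == b
        if m.sum() < 4:
            continue
        cols = {"current": predictors.loc[m, "current"].to_numpy(float),
                "future": predictors.loc[m, "future"].to_numpy(float)}
        if np.std(cols["current"]) == 0 or np.std(cols["future"]) == 0:
            continue
        try:
            _, coefs, _ = _lstsq_named(y[m], cols)
        except np.linalg.LinAlgError:
            continue    # degenerate bin (e.g. future = 1 - current exactly)
        rows.append({"bin": int(b), "n": int(m.sum()),
                     "current": coefs["current"], "future": coefs["future"]})
    return pd.DataFrame(rows)


def participant_fits(dv_table: pd.DataFrame, design: Design,
                     covariate: pd.Series, validity: dict[str, bool],
                     center: bool = False, state: str = "S1",
                     future: str = "correct") -> list[CategoryRegressionFit]:
    """Fit all three category models for one participant at one state."""
    ev = dv_table[(dv_table["state"] == state) & (dv_table["of_interest"])]
    ev = ev.reset_index(drop=True)
    fits = []
    for cat in validity:
        X = build_state1_predictors(ev, design, covariate, cat, center=center)
        if future == "visited":
            idx = {m.maze_id: m for m in design.mazes}
            X["future"] = [1.0 if _visited_s3(r, idx[r.maze_id]) == cat else 0.0
                           for r in ev.itertuples(index=False)]
            X["future_x_rep"] = X["future"] * X["correct_rep"]
        try:
            fit = fit_decision_regression(ev[f"dv_{cat}"].to_numpy(), X, category=cat)
            fit.valid = validity[cat]
        except np.linalg.LinAlgError:
            # e.g. no maze of this category was ever learned: the
            # interaction column is identically zero; flag, don't fit
            fit = CategoryRegressionFit(category=cat,
                                        coefficients={k: np.nan for k in PREDICTORS},
                                        intercept=np.nan, residual_sd=np.nan,
                                        n_obs=len(ev), valid=False)
        fits.append(fit)
    return fits


def _visited_s3(row, maze) -> str:
    reached = getattr(row, "reached_correct_s3", None)
    if reached is None:
        return maze.s3_correct_category
    return maze.s3_correct_category if reached else maze.s3_incorrect_category


@dataclass
class ParticipantEffect:
    means: dict[str, float]
    n_valid_categories: int


def average_categories(fits: list[CategoryRegressionFit]) -> ParticipantEffect | None:
    """Average coefficients over the participant's valid category models."""
    valid = [f for f in fits if f.valid]
    if not valid:
        return None
    keys = valid[0].coefficients.keys()
    means = {k: float(np.mean([f.coefficients[k] for f in valid])) for k in keys}
    return ParticipantEffect(means=means, n_valid_categories=len(valid))


def aggregate_and_infer(per_participant: list[list[CategoryRegressionFit]]
                        ) -> tuple[pd.DataFrame, dict[str, GroupResult]]:
    """Group inference over participants' category-averaged coefficients.

    Participants with no valid category are dropped (recorded in the
    returned table's ``included`` count).  Returns the per-participant
    coefficient table and a one-sample two-sided t test per predictor.
    """
    effects = [average_categories(fits) for fits in per_participant]
    rows = [e.means | {"n_valid_categories": e.n_valid_categories}
            for e in effects if e is not None]
    if len(rows) < 3:
        raise ValueError("need at least 3 included participants")
    table = pd.DataFrame(rows)
    group = {}
    for pred in table.columns:
        if pred == "n_valid_categories":
            continue
        group[pred] = one_sample_test(table[pred].to_numpy())
    return table, group


def state_variant_models(dv_table: pd.DataFrame, design: Design,
                         covariate: pd.Series, state: str,
                         category: str) -> CategoryRegressionFit:
    """Control regressions at state 2, state 3, or feedback.

    S2 (no on-screen stimulus): future indicator, counter, and their
    interaction.  S3: on-screen (current) indicator, counter, their
    interaction, plus past-state (S1 category) terms.  FEEDBACK: past-state
    terms for the S1 and the visited S3 categories with the counter.
    """
    ev = dv_table[(dv_table["state"] == state) & (dv_table["of_interest"])]
    ev = ev.reset_index(drop=True)
    if len(ev) == 0:
        raise ValueError(f"no events at state {state!r}")
    idx = {m.maze_id: m for m in design.mazes}
    y = ev[f"dv_{category}"].to_numpy(float)
    rep = np.array([float(covariate.get((r.maze_id, r.repetition), 0))
                    for r in ev.itertuples(index=False)])
    cols: dict[str, np.ndarray] = {"correct_rep": rep}
    if state == "S2":
        fut = np.array([1.0 if idx[r.maze_id].s3_correct_category == category else 0.0
                        for r in ev.itertuples(index=False)])
        cols |= {"future": fut, "future_x_rep": fut * rep}
    elif state == "S3":
        cur = (ev["onscreen_category"] == category).to_numpy(float)
        past = np.array([1.0 if idx[r.maze_id].s1_category == category else 0.0
                         for r in ev.itertuples(index=False)])
        cols |= {"current": cur, "current_x_rep": cur * rep,
                 "past_s1": past, "past_s1_x_rep": past * rep}
    elif state == "FEEDBACK":
        past1 = np.array([1.0 if idx[r.maze_id].s1_category == category else 0.0
                          for r in ev.itertuples(index=False)])
        past3 = np.array([1.0 if _visited_s3(r, idx[r.maze_id]) == category else 0.0
                          for r in ev.itertuples(index=False)])
        cols |= {"past_s1": past1, "past_s1_x_rep": past1 * rep,
                 "past_s3": past3, "past_s3_x_rep": past3 * rep}
    else:
        raise ValueError(f"unsupported state {state!r}")
    icpt, coefs, rsd = _lstsq_named(y, cols)
    return CategoryRegressionFit(category=category, coefficients=coefs,
                                 intercept=icpt, residual_sd=rsd, n_obs=len(y))


def roi_sweep(group_effects: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-ROI group tests of the future x correct-repetition effect.

    ``group_effects`` maps ROI label to the per-participant
    category-averaged future x repetition coefficients.  One row per ROI
    with mean, t, and uncorrected p (no multiple-comparison correction is
    applied; the count of p < 0.05 regions is exposed via the ``sig``
    column sum).
    """
    rows = []
    for roi, eff in group_effects.items():
        g = one_sample_test(np.asarray(eff, float))
        rows.append({"roi": roi, "mean": g.mean, "t": g.t, "df": g.df,
                     "p": g.p, "sig": bool(g.p < 0.05)})
    return pd.DataFrame(rows).sort_values("p", ignore_index=True)
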