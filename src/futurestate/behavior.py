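"""Behavioral statistics, OSPAN scoring, and equivalence/power calculators.

Group inference throughout the package is the one-sample two-sided t test
on within-participant summaries, with Cohen's d = mean/sd.  Equivalence
claims use the two one-sided tests (TOST) procedure against symmetric
bounds expressed in Cohen's d; power and sample-size calculators use the
noncentral-t distribution with integer search, matching the conventions of
G*Power and the TOSTER R package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


@dataclass
class GroupResult:
    """One-sample test summary: mean, 95% CI, t, df, p, Cohen's d."""

    mean: float
    ci_low: float
    ci_high: float
    t: float
    df: int
    p: float
    cohen_d: float
    note: str = ""

    @property
    def degenerate(self) -> bool:
        return bool(self.note)


@dataclass
class TOSTResult:
    """Equivalence test result: max of the two one-sided p values."""

    bound_d: float
    t_lower: float
    t_upper: float
    p_tost: float
    equivalent: bool
    alpha: float = 0.05
    note: str = ""


def one_sample_test(sample: np.ndarray, popmean: float = 0.0,
                    alpha: float = 0.05) -> GroupResult:
    """Two-sided one-sample t test with CI and Cohen's d.

    A zero-variance sample is flagged (t and p set to NaN) rather than
    silently reported as infinite.
    """
    x = np.asarray(sample, float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 observations")
    m = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    df = n - 1
    if sd == 0.0:
        return GroupResult(m, m, m, np.nan, df, np.nan, np.nan,
                           note="zero-variance sample: t undefined")
    se = sd / np.sqrt(n)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    t = (m - popmean) / se
    p = 2 * stats.t.sf(abs(t), df)
    return GroupResult(m, m - tcrit * se, m + tcrit * se, float(t), df,
                       float(p), (m - popmean) / sd)


def accuracy_by_repetition(tables: list, chance: float = 0.5):
    """Per-repetition group accuracy with t tests versus chance.

    ``tables`` holds one behavior table per participant (mazes of interest
    only are scored).  Repetition 1 is reported descriptively — its
    expected accuracy is 50% by design, since the first outcome is forced
    for half the mazes — while repetitions 2+ are tested against chance.
    Returns a DataFrame indexed by repetition.
    """
    import pandas as pd

    if len(tables) < 2:
        raise ValueError("need at least 2 participants")
    acc = []
    for t in tables:
        ti = t[t["of_interest"]]
        acc.append(ti.groupby("repetition")["correct"].mean())
    acc = pd.DataFrame(acc).sort_index(axis=1)

    rows = {}
    for rep in acc.columns:
        x = acc[rep].to_numpy()
        if rep == 1:
            rows[rep] = {"mean": float(np.mean(x)), "ci_low": np.nan,
                         "ci_high": np.nan, "t": np.nan, "p": np.nan,
                         "tested": False}
        else:
            g = one_sample_test(x, popmean=chance)
            rows[rep] = {"mean": g.mean, "ci_low": g.ci_low, "ci_high": g.ci_high,
                         "t": g.t, "p": g.p, "tested": True}
    out = pd.DataFrame(rows).T
    out.index.name = "repetition"
    return out


def initial_feedback_split(tables: list, repetition: int = 2):
    """Accuracy at a repetition conditional on the repetition-1 outcome.

    Returns (mean after initial reward, mean after initial loss, paired
    GroupResult on the within-participant difference).  Participants
    lacking one of the conditions are excluded and listed in the result's
    note.
    """
    import pandas as pd

    rew, loss, dropped = [], [], []
    for i, t in enumerate(tables):
        ti = t[(t["of_interest"]) & (t["repetition"] == repetition)]
        by = ti.groupby("initial_reward")["correct"].mean()
        if True in by.index and False in by.index:
            rew.append(by[True])
            loss.append(by[False])
        else:
            dropped.append(i)
    if len(rew) < 2:
        raise ValueError("too few participants with both conditions")
    diff = np.asarray(rew) - np.asarray(loss)
    g = one_sample_test(diff)
    if dropped:
        g.note = (g.note + f" excluded participants lacking a condition: {dropped}").strip()
    return float(np.mean(rew)), float(np.mean(loss)), g


def ospan_score(responses: list, truths: list) -> int:
    """Operation-span working-memory score.

    Fifteen letter-sequence trials (lengths 4-8, three of each); a trial
    contributes its length only if the recalled sequence is fully correct
    and in order.  Maximum score 3 x (4+5+6+7+8) = 90.
    """
    if len(responses) != 15 or len(truths) != 15:
        raise ValueError("OSPAN has exactly 15 trials")
    lengths = sorted(len(t) for t in truths)
    if lengths != sorted([4, 5, 6, 7, 8] * 3):
        raise ValueError("trial lengths must be 4-8, three of each")
    return sum(len(t) for r, t in zip(responses, truths) if list(r) == list(t))


def _t_power(n: int, d: float, alpha: float, tails: int) -> float:
    df = n - 1
    nc = d * np.sqrt(n)
    if tails == 2:
        tc = stats.t.ppf(1 - alpha / 2, df)
        return float(stats.nct.sf(tc, df, nc) + stats.nct.cdf(-tc, df, nc))
    tc = stats.t.ppf(1 - alpha, df)
    return float(stats.nct.sf(tc, df, nc))


def required_n(d: float, power: float = 0.80, alpha: float = 0.05,
               tails: int = 2, n_max: int = 1_000_000) -> int:
    """Smallest n giving a one-sample t test the target power.

    Uses the noncentral-t distribution with an integer search (the
    convention printed sample sizes follow); n is never below 2 so the
    test has at least one degree of freedom.
    """
    if not (0 < power < 1 and 0 < alpha < 1 and d > 0):
        raise ValueError("require 0<power<1, 0<alpha<1, d>0")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    n = 2
    while _t_power(n, d, alpha, tails) < power:
        n += 1
        if n > n_max:
            raise ValueError(f"required n exceeds {n_max}: request unattainable")
    return n


def tost_power(n: int, bound_d: float, alpha: float = 0.05) -> float:
    """Power of a one-sample TOST at symmetric +-bound_d when the true
    effect is zero: P(lower reject) + P(upper reject) − 1, each one-sided
    test evaluated with the noncentral-t distribution."""
    df = n - 1
    tc = stats.t.ppf(1 - alpha, df)
    nc = bound_d * np.sqrt(n)
    return float(stats.nct.sf(tc, df, nc) + stats.nct.cdf(-tc, df, -nc) - 1)


def tost_bound_for_power(n: int, power: float = 0.80, alpha: float = 0.05,
                         decimals: int | None = 2) -> float:
    """Equivalence bound (Cohen's d) at which TOST reaches the target power.

    Root-finds the noncentral-t TOST power in the bound; by convention the
    result is reported to two decimals (pass ``decimals=None`` for the
    unrounded root).
    """
    if n < 3:
        raise ValueError("need n >= 3")
    b = optimize.brentq(lambda d: tost_power(n, d, alpha) - power, 1e-4, 50.0)
    return round(float(b), decimals) if decimals is not None else float(b)


def tost_test(sample: np.ndarray, bound_d: float, alpha: float = 0.05) -> TOSTResult:
    """One-sample TOST against symmetric bounds given in Cohen's d.

    The bound is converted to raw units via the sample SD; equivalence is
    declared when both one-sided tests reject, i.e. when the larger of the
    two one-sided p values is below alpha.
    """
    x = np.asarray(sample, float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        return TOSTResult(bound_d, np.nan, np.nan, np.nan, False, alpha,
                          note="zero-variance sample")
    se = sd / np.sqrt(n)
    bound = bound_d * sd
    df = n - 1
    t_lower = (np.mean(x) + bound) / se      # H0: mean <= -bound
    t_upper = (np.mean(x) - bound) / se      # H0: mean >= +bound
    p_lower = stats.t.sf(t_lower, df)
    p_upper = stats.t.cdf(t_upper, df)
    p_tost = float(max(p_lower, p_upper))
    return TOSTResult(bound_d, float(t_lower), float(t_upper), p_tost,
                      p_tost < alpha, alpha)


def correlate(x: np.ndarray, y: np.ndarray, fisher: bool = False):
    """Pearson correlation with p value and optional Fisher z transform."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    if fisher:
        return float(r), float(p), float(np.arctanh(r))
    return float(r), float(p)
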