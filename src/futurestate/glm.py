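"""Design-matrix construction and beta estimation at ROI level.

Two uses: single-event (least-squares-all, LSA) designs in which every
event in every state — including the rest period — gets its own regressor,
yielding one beta pattern per event for the multivariate analyses; and
condition-level univariate models with a geometrically decaying encoding
modulator across repetitions and a +1/−1 reward-versus-loss contrast at
feedback.

Regressors are boxcars at the event's modeled duration convolved with the
canonical double-gamma HRF on a 16-bin microtime grid, sampled at the TR.
Estimation is ordinary least squares; an optional whitening hook accepts a
time x time matrix for users who want AR-prewhitened fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from nilearn.glm.first_level.hemodynamic_models import spm_hrf
from scipy.signal import fftconvolve

MICROTIME = 16

#: Geometric 50% decay across the four repetitions.
DECAY_VALUES = (1.0, 0.50, 0.25, 0.125)


def decay_modulator(repetitions: np.ndarray | pd.Series, ratio: float = 0.5) -> np.ndarray:
    """Decaying encoding modulator: ``ratio**(k-1)`` for repetition k."""
    reps = np.asarray(repetitions, dtype=float)
    if np.any(reps < 1):
        raise ValueError("repetitions are 1-based")
    return ratio ** (reps - 1)


def convolve_events(onsets: np.ndarray, durations: np.ndarray, n_scans: int,
                    tr: float, oversampling: int = MICROTIME) -> np.ndarray:
    """One HRF-convolved boxcar column per event, sampled at scan times.

    Returns (n_scans, n_events).  Vectorized over events: all boxcars are
    built on the shared microtime grid and convolved with the canonical
    HRF in one FFT pass.
    """
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    durations = np.atleast_1d(np.asarray(durations, dtype=float))
    dt = tr / oversampling
    n_fine = n_scans * oversampling
    box = np.zeros((n_fine, len(onsets)))
    for j, (on, dur) in enumerate(zip(onsets, durations)):
        a = int(np.round(on / dt))
        b = int(np.round((on + dur) / dt))
        box[a:min(b, n_fine), j] = 1.0
    h = spm_hrf(tr, oversampling=oversampling)
    conv = fftconvolve(box, h[:, None], axes=0)[:n_fine]
    return conv[::oversampling]


@dataclass
class DesignMatrix:
    """Time x regressor matrix with labels and an event-to-column map."""

    matrix: np.ndarray
    labels: list[str]
    event_columns: np.ndarray      # column index of each event of interest
    events: pd.DataFrame
    n_interest: int

    @property
    def n_regressors_of_interest(self) -> int:
        return self.n_interest


def _block_slices(blocks: np.ndarray, n_scans: int) -> dict[int, slice]:
    uniq = sorted(set(int(b) for b in blocks))
    return {b: slice(i * n_scans, (i + 1) * n_scans) for i, b in enumerate(uniq)}


def build_lsa_design(events: pd.DataFrame, n_scans: int, tr: float,
                     nuisance: np.ndarray | None = None,
                     oversampling: int = MICROTIME) -> DesignMatrix:
    """Single-event (LSA) design over one or more concatenated blocks.

    Each event row gets its own convolved regressor within its block's
    rows; per-block intercepts and any nuisance columns (e.g. six
    motion-like series over the concatenated timeline) are appended as
    effects of no interest.  For the default learning design of 40 maze
    trials x 5 states this yields 200 regressors of interest.
    """
    events = events.reset_index(drop=True)
    blocks = events["block"].to_numpy() if "block" in events else np.ones(len(events), int)
    sl = _block_slices(blocks, n_scans) if len(events) else {1: slice(0, n_scans)}
    n_blocks = len(sl)
    total = n_blocks * n_scans

    if np.any(events["onset"].to_numpy(float) + events["duration"].to_numpy(float)
              > n_scans * tr) if len(events) else False:
        raise ValueError("event extends beyond the end of its block")

    cols = []
    labels = []
    event_cols = np.arange(len(events))
    for b, s in sl.items():
        in_b = np.flatnonzero(blocks == b)
        if len(in_b) == 0:
            continue
        sub = events.iloc[in_b]
        X_b = convolve_events(sub["onset"].to_numpy(), sub["duration"].to_numpy(),
                              n_scans, tr, oversampling)
        for k, i in enumerate(in_b):
            col = np.zeros(total)
            col[s] = X_b[:, k]
            cols.append(col)
            r = events.iloc[i]
            labels.append(f"ev{i:03d}_{r.get('state', r.get('category', 'event'))}")
            event_cols[i] = len(cols) - 1
    n_interest = len(cols)

    for b, s in sl.items():
        col = np.zeros(total)
        col[s] = 1.0
        cols.append(col)
        labels.append(f"block{b}_intercept")
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, float))
        if nuisance.shape[0] != total:
            nuisance = nuisance.T
        if nuisance.shape[0] != total:
            raise ValueError("nuisance rows must match total scans")
        for j in range(nuisance.shape[1]):
            cols.append(nuisance[:, j])
            labels.append(f"nuisance{j}")

    X = np.column_stack(cols) if cols else np.zeros((total, 0))
    return DesignMatrix(matrix=X, labels=labels, event_columns=event_cols,
                        events=events, n_interest=n_interest)


def fit_betas(bold: np.ndarray, design: DesignMatrix,
              whitener: np.ndarray | None = None,
              roi_label: str = "roi"):
    """OLS betas per event per voxel; returns a :class:`VoxelPatternSet`.

    A rank-deficient design fails loudly, naming the collinear columns.
    ``whitener`` (time x time) is applied to both sides before fitting.
    """
    from .simulate import VoxelPatternSet

    X = design.matrix
    y = np.asarray(bold, float)
    if y.ndim == 1:
        y = y[:, None]
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"design has {X.shape[0]} rows but BOLD has {y.shape[0]}")
    if whitener is not None:
        X = whitener @ X
        y = whitener @ y
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        bad = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(design.labels[j])
        raise np.linalg.LinAlgError(
            f"rank-deficient design ({rank}/{X.shape[1]}); collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    ev_betas = beta[design.event_columns]
    return VoxelPatternSet(ev_betas, design.events.copy(), roi_label)


def _ols_coef(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef


def decay_effect(roi_amplitude: np.ndarray, events: pd.DataFrame,
                 state: str = "S1", ratio: float = 0.5,
                 center: bool = True) -> float:
    """Per-participant decaying-encoding effect at one state.

    Regresses the ROI amplitude of the state's events (mazes of interest,
    all four repetitions) on the geometric decay modulator.  The modulator
    is mean-centered before entering the design, so the intercept absorbs
    the mean response and the returned coefficient is the pure decay
    effect.  Mazes missing repetitions are dropped.
    """
    ev = events.reset_index(drop=True)
    amp = np.asarray(roi_amplitude, float)
    mask = (ev["state"] == state) & ev.get("of_interest", True)
    ev_s = ev[mask]
    n_reps = ev_s["repetition"].max()
    counts = ev_s.groupby("maze_id")["repetition"].nunique()
    full = counts[counts == n_reps].index
    keep = mask & ev["maze_id"].isin(full)
    if keep.sum() < 3:
        raise ValueError(f"too few complete {state} events for the decay model")
    mod = decay_modulator(ev.loc[keep, "repetition"], ratio)
    if center:
        mod = mod - mod.mean()
    X = np.column_stack([np.ones(keep.sum()), mod])
    return float(_ols_coef(amp[keep.to_numpy()], X)[1])


def univariate_decay_model(participants: list[tuple[np.ndarray, pd.DataFrame]],
                           state: str = "S1", ratio: float = 0.5):
    """Group-level decaying-encoding test across participants.

    ``participants`` is a list of (roi_amplitude_per_event, events) pairs.
    Returns (per-participant effects, GroupResult of a one-sample t test).
    """
    from .behavior import one_sample_test

    effects = np.array([decay_effect(a, e, state, ratio) for a, e in participants])
    return effects, one_sample_test(effects)


def reward_feedback_model(roi_amplitude: np.ndarray, events: pd.DataFrame,
                          include_rest: bool = False) -> float:
    """Reward-versus-loss parametric effect at feedback (+1/−1 coding).

    With ``include_rest`` the subsequent 12-s rest events are pooled in,
    testing for lasting reward effects.  Fails if only one outcome type is
    present (the contrast is undefined).
    """
    ev = events.reset_index(drop=True)
    states = ["FEEDBACK"] + (["REST"] if include_rest else [])
    mask = ev["state"].isin(states)
    out = ev.loc[mask, "outcome"]
    if out.nunique() < 2:
        raise ValueError("both reward and loss outcomes are required")
    code = out.map({"reward": 1.0, "loss": -1.0}).to_numpy()
    amp = np.asarray(roi_amplitude, float)[mask.to_numpy()]
    X = np.column_stack([np.ones(len(code)), code])
    return float(_ols_coef(amp, X)[1])
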