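"""Synthetic behavior, voxel patterns, and BOLD with known ground truth.

The generative model plants exactly the statistical structure the analysis
is designed to detect.  Multivoxel patterns are built from mutually
orthonormal category templates ``T(c)``:

* localizer trial of category c:  ``a_localizer * T(c) + noise``
* learning S1 event:              ``a_current * T(onscreen) +
  g_future * r * T(correct-S3 category) + noise``, where ``r`` is the
  correct-repetition counter (0 until the correct distal room has been
  seen, then +1 per subsequent repetition)
* learning S3 event:              ``a_current * T(visited category)`` plus an
  optional repetition-sloped term for suppression analyses
* S2 / feedback / rest events carry optional planted terms (all 0 by
  default) plus noise.

Setting ``g_future = 0`` gives a null world in which current-state
decoding succeeds but no prospective signal exists — the double
dissociation the analysis relies on.

Behavior follows a two-parameter observe-then-exploit rule: the first
choice is random and its outcome is forced by the design (half the mazes
of interest reward the first exposure); from the second repetition the
correct door is chosen with probability ``p_learn_after_reward`` once the
correct distal room has been observed and ``p_learn_after_loss`` before
that (after an initial loss the correct room has not yet been seen, only
inferred).  The defaults reproduce the observed second-repetition
accuracies of 82.1% after an initial reward and 71.4% after an initial
loss (76% overall).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import CATEGORIES, Design, build_events
from .glm import convolve_events

DEFAULT_TR = 1.24


@dataclass
class SimTruth:
    """Planted simulation parameters for parameter-recovery tests."""

    category_templates: dict[str, np.ndarray]
    a_current: float = 0.6
    a_localizer: float = 1.0
    g_future: float = 0.15
    noise_sd: float = 0.5
    tr: float = DEFAULT_TR
    seed: int = 0
    # optional planted effects for control analyses (all 0 by default)
    g_s3_current_slope: float = 0.0
    g_s2_future: float = 0.0
    g_feedback_past: float = 0.0
    nonlinear_future: bool = False   # if True, future signal grows as sqrt(r)

    @property
    def n_voxels(self) -> int:
        return len(next(iter(self.category_templates.values())))

    @classmethod
    def default(cls, n_voxels: int = 64, seed: int = 0, **kwargs) -> "SimTruth":
        """Orthonormal templates via QR of a seeded Gaussian matrix."""
        if n_voxels < len(CATEGORIES):
            raise ValueError(
                f"n_voxels={n_voxels} must be >= number of categories ({len(CATEGORIES)})"
            )
        rng = np.random.default_rng(seed)
        q, _ = np.linalg.qr(rng.standard_normal((n_voxels, len(CATEGORIES))))
        templates = {c: q[:, i].copy() for i, c in enumerate(CATEGORIES)}
        return cls(category_templates=templates, seed=seed, **kwargs)

    def null_world(self) -> "SimTruth":
        return replace(self, g_future=0.0)


@dataclass
class VoxelPatternSet:
    """Event-by-voxel beta matrix with per-row event metadata."""

    betas: np.ndarray            # (n_events, n_voxels)
    events: pd.DataFrame         # one row per beta row
    roi_label: str = "roi"

    def __post_init__(self) -> None:
        if self.betas.shape[0] != len(self.events):
            raise ValueError("betas rows must match event metadata rows")
        if not np.all(np.isfinite(self.betas)):
            raise ValueError("non-finite beta values")

    def select(self, mask: np.ndarray | pd.Series) -> "VoxelPatternSet":
        mask = np.asarray(mask)
        return VoxelPatternSet(self.betas[mask], self.events[mask].reset_index(drop=True),
                               self.roi_label)


def simulate_behavior(design: Design,
                      p_learn_after_reward: float = 0.821,
                      p_learn_after_loss: float = 0.714,
                      seed: int = 0) -> pd.DataFrame:
    """Simulate choices and outcomes for one participant.

    Returns a table with one row per maze x repetition: ``chosen_action``,
    ``correct``, ``reached_correct_s3``, ``outcome`` plus bookkeeping
    columns.  Repetition-1 outcomes are forced by the design's
    initial-reward plan regardless of the choice, and the correct action is
    fixed from the repetition-1 choice (the chosen door if rewarded, the
    other door otherwise).  The two extra mazes lose on every repetition.
    """
    for p in (p_learn_after_reward, p_learn_after_loss):
        if not 0.0 <= p <= 1.0:
            raise ValueError("learning probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    other = {"left": "right", "right": "left"}
    n_reps = int(design.trials["repetition"].max())

    rows = []
    for m in design.mazes:
        if not m.of_interest:
            for rep in range(1, n_reps + 1):
                rows.append((m.maze_id, rep, str(rng.choice(["left", "right"])),
                             "none", False, False, "loss", False, m.of_interest))
            continue
        first_choice = str(rng.choice(["left", "right"]))
        correct_action = first_choice if m.initial_reward else other[first_choice]
        observed = m.initial_reward       # correct S3 seen on rep 1 iff rewarded
        for rep in range(1, n_reps + 1):
            if rep == 1:
                choice = first_choice
                reached = m.initial_reward
                outcome = "reward" if m.initial_reward else "loss"
            else:
                p = p_learn_after_reward if observed else p_learn_after_loss
                is_correct = rng.random() < p
                choice = correct_action if is_correct else other[correct_action]
                reached = is_correct
                outcome = "reward" if is_correct else "loss"
            rows.append((m.maze_id, rep, choice, correct_action,
                         choice == correct_action, reached, outcome,
                         m.initial_reward, m.of_interest))
            if reached:
                observed = True
    return pd.DataFrame(rows, columns=[
        "maze_id", "repetition", "chosen_action", "correct_action", "correct",
        "reached_correct_s3", "outcome", "initial_reward", "of_interest"])


def correct_rep_covariate(behavior: pd.DataFrame, coding: str = "observed") -> pd.Series:
    """Correct-repetition counter per maze x repetition.

    ``observed`` (primary): 0 until the repetition after the correct S3 was
    first reached, then +1 every subsequent repetition.  ``correct_only``:
    counts only prior repetitions that actually reached the correct S3.
    Indexed by (maze_id, repetition).
    """
    if coding not in ("observed", "correct_only"):
        raise ValueError(f"unknown coding {coding!r}")
    out = {}
    for maze_id, grp in behavior.groupby("maze_id"):
        grp = grp.sort_values("repetition")
        reached = grp["reached_correct_s3"].to_numpy()
        reps = grp["repetition"].to_numpy()
        if coding == "observed":
            hits = np.flatnonzero(reached)
            first = reps[hits[0]] if len(hits) else np.inf
            vals = np.maximum(0, reps - first)
        else:
            vals = np.concatenate([[0], np.cumsum(reached[:-1])])
        for rep, v in zip(reps, vals):
            out[(maze_id, int(rep))] = int(v)
    s = pd.Series(out)
    s.index.names = ["maze_id", "repetition"]
    return s


def _event_pattern(row, truth: SimTruth, rmap: pd.Series,
                   maze_index: dict) -> np.ndarray:
    T = truth.category_templates
    V = truth.n_voxels
    x = np.zeros(V)
    m = maze_index.get(row.maze_id)
    r = rmap.get((row.maze_id, row.repetition), 0)
    gain = np.sqrt(r) if truth.nonlinear_future else r
    if row.state == "S1":
        x += truth.a_current * T[row.onscreen_category]
        if m is not None and m.of_interest:
            x += truth.g_future * gain * T[m.s3_correct_category]
    elif row.state == "S3":
        amp = truth.a_current + truth.g_s3_current_slope * r
        x += amp * T[row.onscreen_category]
    elif row.state == "S2":
        if m is not None and m.of_interest:
            x += truth.g_s2_future * gain * T[m.s3_correct_category]
    elif row.state == "FEEDBACK":
        if m is not None:
            x += truth.g_feedback_past * T[m.s1_category]
    return x


def simulate_patterns(design: Design, behavior: pd.DataFrame, truth: SimTruth,
                      roi_label: str = "roi",
                      participant: str = "sub-01") -> tuple[VoxelPatternSet, VoxelPatternSet]:
    """Noiseless planted signal plus iid Gaussian pattern noise.

    Returns ``(localizer, learning)`` pattern sets aligned to their event
    tables; the learning set covers all five states of every trial.
    """
    from .design import generate_localizer

    if len(truth.category_templates) < 3:
        raise ValueError("need templates spanning at least 3 categories")
    rng = np.random.default_rng(truth.seed)
    rmap = correct_rep_covariate(behavior, "observed")
    maze_index = {m.maze_id: m for m in design.mazes}

    events = build_events(design, behavior, participant=participant)
    learn = np.zeros((len(events), truth.n_voxels))
    for i, row in enumerate(events.itertuples(index=False)):
        learn[i] = _event_pattern(row, truth, rmap, maze_index)
    if truth.noise_sd > 0:
        learn = learn + rng.normal(0, truth.noise_sd, learn.shape)

    loc_events = generate_localizer(design.mazes, all_seen=True, seed=truth.seed)
    loc = np.zeros((len(loc_events), truth.n_voxels))
    for i, row in enumerate(loc_events.itertuples(index=False)):
        if row.category in truth.category_templates:
            loc[i] = truth.a_localizer * truth.category_templates[row.category]
    if truth.noise_sd > 0:
        loc = loc + rng.normal(0, truth.noise_sd, loc.shape)

    return (VoxelPatternSet(loc, loc_events, roi_label),
            VoxelPatternSet(learn, events, roi_label))


def simulate_bold(events: pd.DataFrame, amplitudes: np.ndarray, n_scans: int,
                  truth: SimTruth | None = None, tr: float = DEFAULT_TR,
                  noise_sd: float = 0.0, drift: bool = False,
                  seed: int = 0) -> np.ndarray:
    """Forward-simulate a BOLD run: boxcar events x canonical HRF.

    ``amplitudes`` is (n_events, n_voxels): each event contributes its
    convolved regressor scaled by its per-voxel amplitude.  Optional linear
    and low-frequency cosine drifts emulate scanner nuisance.  Events must
    fit inside the run.
    """
    if truth is not None:
        tr = truth.tr
    events = events.reset_index(drop=True)
    if len(events) != amplitudes.shape[0]:
        raise ValueError("one amplitude row per event required")
    if np.any(events["onset"].to_numpy() + events["duration"].to_numpy() > n_scans * tr):
        raise ValueError("event extends beyond the end of the run")
    X = convolve_events(events["onset"].to_numpy(), events["duration"].to_numpy(),
                        n_scans, tr)                      # (n_scans, n_events)
    y = X @ amplitudes
    rng = np.random.default_rng(seed)
    if drift:
        t = np.arange(n_scans) / n_scans
        amp = rng.normal(0, 1.0, (3, amplitudes.shape[1]))
        y = y + np.outer(t - 0.5, amp[0]) \
              + np.outer(np.cos(np.pi * t), amp[1]) \
              + np.outer(np.cos(2 * np.pi * t), amp[2])
    if noise_sd > 0:
        y = y + rng.normal(0, noise_sd, y.shape)
    return y
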