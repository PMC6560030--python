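"""Experimental design generation for the maze-learning task.

The task is a Y-maze navigation paradigm: on each trial the participant
enters a choice room (state 1, S1) showing a maze-unique picture, picks a
left or right door, traverses a hallway room (S2), reaches a pre-outcome
room (S3) showing the picture behind the chosen door, and finally receives
reward or loss feedback followed by a rest period.  Eight mazes of interest
are each repeated four times; two extra mazes that always end in a loss
balance the reward/loss associations.  Every maze assigns the three stimulus
categories (face, scene, object) to S1, the correct S3 and the incorrect S3,
one category per state, with maze- and state-unique stimuli.

A separate post-learning localizer phase presents each stimulus in
isolation (plus scrambled-object and motion trials) to estimate
category-specific multivoxel templates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CATEGORIES = ("face", "scene", "object")

#: GLM event durations in seconds, per state.
STATE_DURATIONS = {"S1": 5.0, "S2": 4.0, "S3": 5.0, "FEEDBACK": 5.0, "REST": 12.0}

#: Localizer event durations: static pictures 2 s, moving-dot stimuli 3 s.
LOCALIZER_STATIC_DUR = 2.0
LOCALIZER_MOTION_DUR = 3.0


@dataclass(frozen=True)
class MazeSpec:
    """Static description of one maze: stimuli, categories, reward plan."""

    maze_id: int
    s1_category: str
    s1_stimulus: str
    correct_action: str                 # provisional; finalized after repetition 1
    s3_correct_category: str
    s3_incorrect_category: str
    s3_correct_stimulus: str
    s3_incorrect_stimulus: str
    initial_reward: bool
    of_interest: bool


@dataclass
class Design:
    """A generated experiment: maze specs plus the ordered, timed trial list.

    ``trials`` has one row per maze trial with columns ``trial``, ``block``,
    ``maze_id``, ``repetition`` and within-block state onsets
    ``onset_s1 .. onset_rest`` (seconds).
    """

    mazes: list[MazeSpec]
    trials: pd.DataFrame
    seed: int
    block_duration: float = field(default=0.0)

    @property
    def interest_ids(self) -> list[int]:
        return [m.maze_id for m in self.mazes if m.of_interest]

    def maze(self, maze_id: int) -> MazeSpec:
        return self._index()[maze_id]

    def _index(self) -> dict[int, MazeSpec]:
        return {m.maze_id: m for m in self.mazes}


class CounterbalanceError(ValueError):
    """Raised when the requested maze counts cannot be counterbalanced."""


def _assign_categories(n_mazes: int, rng: np.random.Generator) -> list[tuple[str, str, str]]:
    # Each maze uses all three categories, one per state; greedily pick
    # permutations so category counts at S1 and at the correct S3 stay
    # near-equal (within 1) across mazes.
    perms = list(itertools.permutations(CATEGORIES))
    s1_n = {c: 0 for c in CATEGORIES}
    s3_n = {c: 0 for c in CATEGORIES}
    out = []
    for _ in range(n_mazes):
        rng.shuffle(perms)
        pick = min(perms, key=lambda p: (s1_n[p[0]] + s3_n[p[1]], s1_n[p[0]]))
        out.append(pick)
        s1_n[pick[0]] += 1
        s3_n[pick[1]] += 1
    return out


def _make_mazes(n_interest: int, n_extra: int, rng: np.random.Generator) -> list[MazeSpec]:
    if n_interest < 0 or n_extra < 0:
        raise CounterbalanceError("maze counts must be non-negative")
    n_total = n_interest + n_extra
    cats = _assign_categories(n_total, rng)
    rewarded = set(rng.choice(n_interest, size=n_interest // 2, replace=False)) if n_interest else set()
    counters: dict[str, int] = {c: 0 for c in CATEGORIES}

    def new_stim(cat: str) -> str:
        counters[cat] += 1
        return f"{cat}_{counters[cat]:02d}"

    mazes = []
    for i in range(n_total):
        s1c, s3c, s3i = cats[i]
        of_interest = i < n_interest
        mazes.append(
            MazeSpec(
                maze_id=i + 1,
                s1_category=s1c,
                s1_stimulus=new_stim(s1c),
                correct_action=str(rng.choice(["left", "right"])),
                s3_correct_category=s3c,
                s3_incorrect_category=s3i,
                s3_correct_stimulus=new_stim(s3c),
                s3_incorrect_stimulus=new_stim(s3i),
                initial_reward=(i in rewarded) if of_interest else False,
                of_interest=of_interest,
            )
        )
    return mazes


def _staged_order(n_interest: int, n_extra: int, n_reps: int,
                  rng: np.random.Generator) -> list[tuple[int, int]]:
    """Staged maze introduction as (maze_id, repetition) pairs.

    The first half of the of-interest mazes runs through its early
    repetitions before the second half is introduced; the always-loss extra
    mazes are interleaved last.  Within a stage the order is a seeded
    permutation; repetitions of any one maze always occur in order.
    """
    first = list(range(1, n_interest // 2 + 1))
    second = list(range(n_interest // 2 + 1, n_interest + 1))
    extra = list(range(n_interest + 1, n_interest + n_extra + 1))

    def perm(ids, rep):
        out = [(m, rep) for m in ids]
        rng.shuffle(out)
        return out

    order: list[tuple[int, int]] = []
    for rep in range(1, n_reps):            # first set, early repetitions
        order += perm(first, rep)
    stage = perm(first, n_reps) + perm(second, 1)   # 2nd set enters with rep 4 of 1st
    rng.shuffle(stage)
    order += stage
    for rep in range(2, n_reps):
        order += perm(second, rep)
    stage = perm(second, n_reps) + perm(extra, 1)
    rng.shuffle(stage)
    order += stage
    for rep in range(2, n_reps):
        order += perm(extra, rep)
    if extra:
        order += perm(extra, n_reps)
    return order


def generate_design(n_interest: int = 8, n_extra: int = 2, n_reps: int = 4,
                    seed: int = 0, compact_timing: bool = False) -> Design:
    """Generate maze specs and the ordered, timed learning-phase trial list.

    With the defaults this reproduces the printed design: 10 mazes x 4
    repetitions = 40 trials in 4 scanning blocks of 10, exactly half of the
    8 of-interest mazes rewarded on first exposure, and the 2 extra mazes
    always ending in a loss.  Inter-state intervals are jittered uniformly
    so that the mean S1-to-S3 interval is ~31 s and the mean maze duration
    (S1 onset to end of feedback) is ~48.5 s.

    Parameters
    ----------
    compact_timing:
        If True, shrink hallway/ITI periods to near-minimal values.  Useful
        when forward-simulating BOLD for small demonstrations; the default
        reproduces the study's timing.
    """
    rng = np.random.default_rng(seed)
    mazes = _make_mazes(n_interest, n_extra, rng)
    order = _staged_order(n_interest, n_extra, n_reps, rng)

    n_trials = len(order)
    n_blocks = max(1, int(np.ceil(n_trials / 10))) if n_trials >= 10 else 1
    per_block = int(np.ceil(n_trials / n_blocks))

    if compact_timing:
        gap12 = gap23 = (1.0, 2.0)
        gap3f = (1.0, 2.0)
        iti = (1.0, 2.0)
    else:
        # means: hallway gaps 11.1, 11.1, 7.3 s; post-rest ITI 4 s =>
        # S1->S3 = 5 + 11.1 + 4 + 11.1 ~ 31.2 s, maze ~ 48.5 s.
        gap12 = gap23 = (9.1, 13.1)
        gap3f = (5.3, 9.3)
        iti = (3.0, 5.0)

    rows = []
    t = 0.0
    block_end = 0.0
    for i, (maze_id, rep) in enumerate(order):
        block = i // per_block + 1
        if i % per_block == 0:
            t = 0.0
        on_s1 = t
        on_s2 = on_s1 + STATE_DURATIONS["S1"] + rng.uniform(*gap12)
        on_s3 = on_s2 + STATE_DURATIONS["S2"] + rng.uniform(*gap23)
        on_fb = on_s3 + STATE_DURATIONS["S3"] + rng.uniform(*gap3f)
        on_rest = on_fb + STATE_DURATIONS["FEEDBACK"]
        t = on_rest + STATE_DURATIONS["REST"] + rng.uniform(*iti)
        block_end = max(block_end, t)
        rows.append((i + 1, block, maze_id, rep, on_s1, on_s2, on_s3, on_fb, on_rest))

    trials = pd.DataFrame(
        rows,
        columns=["trial", "block", "maze_id", "repetition",
                 "onset_s1", "onset_s2", "onset_s3", "onset_feedback", "onset_rest"],
    )
    return Design(mazes=mazes, trials=trials, seed=seed, block_duration=block_end)


def build_events(design: Design, behavior: pd.DataFrame | None = None,
                 participant: str = "sub-01") -> pd.DataFrame:
    """Expand the trial list into one row per GLM event (5 states per trial).

    ``behavior`` (from :func:`futurestate.simulate.simulate_behavior`)
    supplies the chosen action per trial, which determines the on-screen
    category at S3 and the outcome.  Without it, S3 shows the correct arm
    and outcomes follow the initial-reward plan (a convenience for
    design-only uses).
    """
    idx = {m.maze_id: m for m in design.mazes}
    beh = None
    if behavior is not None:
        beh = behavior.set_index(["maze_id", "repetition"])

    rows = []
    for tr in design.trials.itertuples(index=False):
        m = idx[tr.maze_id]
        if beh is not None:
            b = beh.loc[(tr.maze_id, tr.repetition)]
            reached_correct = bool(b["reached_correct_s3"])
            outcome = b["outcome"]
            chosen = b["chosen_action"]
        else:
            reached_correct = True
            outcome = ("reward" if m.initial_reward else "loss") if tr.repetition == 1 else "reward"
            chosen = m.correct_action
        s3_cat = m.s3_correct_category if reached_correct else m.s3_incorrect_category
        onsets = {
            "S1": tr.onset_s1, "S2": tr.onset_s2, "S3": tr.onset_s3,
            "FEEDBACK": tr.onset_feedback, "REST": tr.onset_rest,
        }
        onscreen = {"S1": m.s1_category, "S2": "none", "S3": s3_cat,
                    "FEEDBACK": "none", "REST": "none"}
        for state in ("S1", "S2", "S3", "FEEDBACK", "REST"):
            rows.append({
                "participant": participant,
                "block": tr.block,
                "maze_id": tr.maze_id,
                "repetition": tr.repetition,
                "state": state,
                "onset": onsets[state],
                "duration": STATE_DURATIONS[state],
                "onscreen_category": onscreen[state],
                "outcome": outcome if state in ("FEEDBACK", "REST") else "none",
                "chosen_action": chosen if state == "S1" else "none",
                "reached_correct_s3": reached_correct,
                "of_interest": m.of_interest,
            })
    ev = pd.DataFrame(rows)
    return ev.sort_values(["block", "onset"], kind="stable").reset_index(drop=True)


def learning_stimuli(design: Design, behavior: pd.DataFrame | None = None) -> set[str]:
    """Stimulus identifiers actually seen during learning.

    All S1 stimuli are seen; an S3 stimulus is seen only on repetitions
    whose path visited its arm.  Without behavior, assume everything was
    seen (the all-seen localizer base list).
    """
    seen: set[str] = set()
    idx = {m.maze_id: m for m in design.mazes}
    for m in design.mazes:
        seen.add(m.s1_stimulus)
    if behavior is None:
        for m in design.mazes:
            seen.add(m.s3_correct_stimulus)
            seen.add(m.s3_incorrect_stimulus)
        return seen
    for row in behavior.itertuples(index=False):
        m = idx[row.maze_id]
        seen.add(m.s3_correct_stimulus if row.reached_correct_s3 else m.s3_incorrect_stimulus)
    return seen


def generate_localizer(maze_specs: list[MazeSpec], all_seen: bool = True,
                       seed: int = 0, seen_stimuli: set[str] | None = None,
                       probe_fraction: float = 0.25) -> pd.DataFrame:
    """Generate the localizer trial list.

    Three mini-blocks, each with 40 face/scene/object trials (every learning
    stimulus repeated so category counts are balanced), 4-8 scrambled-object
    trials placed in sets of four at the mini-block end flanking 5
    moving-dot trials.  With the default 10-maze design and ``all_seen``
    this yields the printed 155 trials: 120 category, 20 scrambled, 15
    motion, with probes after 25% of the category trials.

    When ``all_seen`` is False, trials for stimuli not in ``seen_stimuli``
    are dropped and replaced by added inter-trial interval.
    """
    rng = np.random.default_rng(seed)
    by_cat: dict[str, list[str]] = {c: [] for c in CATEGORIES}
    for m in maze_specs:
        by_cat[m.s1_category].append(m.s1_stimulus)
        by_cat[m.s3_correct_category].append(m.s3_correct_stimulus)
        by_cat[m.s3_incorrect_category].append(m.s3_incorrect_stimulus)

    stim_all = [(c, s) for c in CATEGORIES for s in by_cat[c]]
    n_stim = len(stim_all)
    # Repeat each stimulus so the base list holds 120 category trials (four
    # appearances each for the default 30-stimulus inventory): one per
    # mini-block plus one extra, with extras dealt evenly (10 per mini-block)
    # so every mini-block carries 40 face/scene/object trials.
    reps_per_stim = max(1, int(round(120 / n_stim))) if n_stim else 0
    base_mbs = [1 + (k % 3) for k in range(max(0, reps_per_stim - 1))]
    extra_mb = np.array([1 + (k % 3) for k in range(n_stim)])
    rng.shuffle(extra_mb)

    mb_trials: dict[int, list[tuple[str, str]]] = {1: [], 2: [], 3: []}
    for k, (c, s) in enumerate(stim_all):
        for mb in base_mbs:
            mb_trials[mb].append((c, s))
        if reps_per_stim > len(base_mbs):
            mb_trials[int(extra_mb[k])].append((c, s))

    # scrambled sets of four: first two mini-blocks get 4+4, the third 4.
    scram_plan = {1: 8, 2: 8, 3: 4}

    rows = []
    scram_i = 0
    motion_i = 0
    for mb in (1, 2, 3):
        cat_trials = list(mb_trials[mb])
        rng.shuffle(cat_trials)
        for c, s in cat_trials:
            rows.append({"miniblock": mb, "category": c, "stimulus": s,
                         "duration": LOCALIZER_STATIC_DUR})
        n_scram = scram_plan.get(mb, 4)
        for k in range(n_scram // 2):
            scram_i += 1
            rows.append({"miniblock": mb, "category": "scrambled",
                         "stimulus": f"scrambled_{scram_i:02d}",
                         "duration": LOCALIZER_STATIC_DUR})
        for k in range(5):
            motion_i += 1
            rows.append({"miniblock": mb, "category": "motion",
                         "stimulus": f"motion_{motion_i:02d}",
                         "duration": LOCALIZER_MOTION_DUR})
        for k in range(n_scram - n_scram // 2):
            scram_i += 1
            rows.append({"miniblock": mb, "category": "scrambled",
                         "stimulus": f"scrambled_{scram_i:02d}",
                         "duration": LOCALIZER_STATIC_DUR})

    loc = pd.DataFrame(rows)

    if not all_seen:
        if seen_stimuli is None:
            raise ValueError("seen_stimuli required when all_seen=False")
        keep = loc["category"].isin(["scrambled", "motion"]) | loc["stimulus"].isin(seen_stimuli)
        loc = loc[keep].reset_index(drop=True)

    is_cat = loc["category"].isin(CATEGORIES)
    n_cat = int(is_cat.sum())
    n_probe = int(round(probe_fraction * n_cat))
    probe_rows = rng.choice(np.flatnonzero(is_cat.to_numpy()), size=n_probe, replace=False)
    loc["probe"] = False
    loc.loc[loc.index[probe_rows], "probe"] = True

    # sequential onsets: stimulus + ITI (mean 2.5 s, range 1.5-4.5);
    # probes add response time; dropped trials add 2 s ITI upstream.
    t = 0.0
    onsets = []
    for r in loc.itertuples(index=False):
        onsets.append(t)
        t += r.duration + rng.uniform(1.5, 4.5)
        if r.probe:
            t += rng.uniform(2.0, 5.0)
    loc["onset"] = onsets
    loc["index"] = np.arange(1, len(loc) + 1)
    return loc[["index", "miniblock", "category", "stimulus", "probe", "onset", "duration"]]
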