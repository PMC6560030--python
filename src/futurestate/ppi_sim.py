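"""Forward simulation for the learning-PPI analysis.

Generates per-participant seed and target ROI timecourses in which the
seed-to-target coupling gain changes from early to late learning by a
planted amount, then recovers the change with the learning-PPI model.  In
the cohort version the planted coupling change is proportional to each
participant's own future-state learning slope, so the across-participant
correlation between the PPI coefficient and the decoded future x
correct-repetition effect has a known positive ground truth.
"""

from __future__ import annotations

import numpy as np

from . import ppi
from .design import Design
from .glm import convolve_events


def concatenated_events(design: Design, behavior, tr: float):
    """Learning events on one concatenated multi-block timeline."""
    from .design import build_events

    ev = build_events(design, behavior)
    n_scans = int(np.ceil(design.block_duration / tr)) + 8
    ev = ev.copy()
    ev["onset"] = ev["onset"] + (ev["block"] - 1) * n_scans * tr
    return ev, n_scans * ev["block"].max()


def simulate_ppi_timecourses(design: Design, behavior, covariate, tr: float,
                             coupling: float = 0.5, coupling_change: float = 0.0,
                             noise_sd: float = 1.0, seed: int = 0,
                             drop_unlearned: bool = True):
    """Seed/target timecourse pair with a planted late-early coupling change.

    target = coupling * seed + coupling_change * (late-early psych) * seed
    + noise; the seed carries evoked S1 responses on top of noise so the
    interaction has stimulus-locked structure to bite on.
    """
    rng = np.random.default_rng(seed)
    events, total_scans = concatenated_events(design, behavior, tr)
    s1 = events[events["state"] == "S1"]
    evoked = convolve_events(s1["onset"].to_numpy(), s1["duration"].to_numpy(),
                             int(total_scans), tr) @ np.ones(len(s1))
    seed_tc = evoked + rng.normal(0, noise_sd, int(total_scans))

    ev_c, w = ppi.late_early_weights(events, covariate, behavior,
                                     drop_unlearned=drop_unlearned)
    psych = convolve_events(ev_c["onset"].to_numpy(), ev_c["duration"].to_numpy(),
                            int(total_scans), tr) @ w
    psych = psych - psych.mean()
    target_tc = (coupling * seed_tc + coupling_change * psych * seed_tc
                 + rng.normal(0, noise_sd, int(total_scans)))
    return seed_tc, target_tc, events


def simulate_learning_ppi_cohort(config, coupling_per_slope: float = 4.0,
                                 noise_sd: float = 1.0) -> dict:
    """Cohort-level learning PPI with the decoding effect as covariate.

    Each participant gets a heterogeneous future-state slope (uniform on
    [0, 2 x configured slope]); the planted PPI coupling change is
    proportional to that slope.  Runs the full decoding pipeline to obtain
    each participant's future x correct-repetition coefficient, then the
    learning PPI, and returns group statistics plus the across-participant
    covariate correlation.
    """
    from .dvreg import average_categories
    from .pipeline import _substream, run_participant

    rng = np.random.default_rng(_substream(config.seed, "ppi"))
    fits, covariate_effects = [], []
    for i in range(config.n_participants):
        g_i = float(rng.uniform(0, 2 * config.g_future))
        res = run_participant(config, i, g_future_override=g_i)
        eff = average_categories(res.fits)
        covariate_effects.append(eff.means["future_x_rep"] if eff else 0.0)
        seed_tc, target_tc, events = simulate_ppi_timecourses(
            res.design, res.behavior, res.covariate, tr=1.24,
            coupling_change=coupling_per_slope * g_i, noise_sd=noise_sd,
            seed=_substream(config.seed, "ppi_tc", i))
        fits.append(ppi.learning_ppi_participant(
            seed_tc, target_tc, events, res.covariate, res.behavior, tr=1.24))
    group, r, p = ppi.learning_ppi(fits, np.array(covariate_effects))
    return {"group_mean": group.mean, "group_t": group.t, "group_p": group.p,
            "covariate_r": r, "covariate_p": p,
            "n": config.n_participants}
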