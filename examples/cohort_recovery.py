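"""Group-level parameter recovery: signal world versus null world.

Simulates two 24-participant cohorts through the full pipeline — one with
the default planted future-state slope, one with the slope set to zero —
and compares the group decision-value regression results.
"""

from futurestate.pipeline import PipelineConfig, run_cohort

for label, g in (("signal world (g_future = 0.15)", 0.15),
                 ("null world   (g_future = 0)", 0.0)):
    cohort = run_cohort(PipelineConfig(seed=9, n_participants=24, g_future=g))
    print(f"\n{label}: {cohort.n_included} participants included")
    for pred in ("current", "future_x_rep", "current_x_rep"):
        r = cohort.group[pred]
        print(f"  {pred:14s} mean={r.mean:+.4f}  t({r.df})={r.t:+.2f}  p={r.p:.4f}")

print("\nIn the signal world only future_x_rep (and current) should be "
      "reliably positive; in the null world current-state decoding remains "
      "while the future interaction sits at zero — the double dissociation "
      "the design is built around.")
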