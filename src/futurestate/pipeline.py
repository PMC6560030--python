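"""End-to-end orchestration: simulate -> GLM/patterns -> decode -> infer.

All randomness flows from one master seed through named per-stage,
per-participant substreams (`numpy.random.SeedSequence`), so any stage is
bit-reproducible given the config.  Artifacts are plain TSV/JSON files
stamped with a hash of the generating config; stages refuse to mix
artifacts from different configs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as beh
from . import decode, dvreg
from .design import Design, generate_design
from .simulate import SimTruth, simulate_behavior, simulate_patterns

STAGES = ("simulate", "glm", "decode", "dvreg", "ppi", "behavior", "report", "all")


@dataclass
class PipelineConfig:
    seed: int = 0
    n_participants: int = 30
    n_voxels: int = 64
    a_current: float = 0.6
    a_localizer: float = 1.0
    g_future: float = 0.15
    noise_sd: float = 0.5
    p_learn_after_reward: float = 0.821
    p_learn_after_loss: float = 0.714
    covariate_coding: str = "observed"        # or "correct_only"
    center_predictors: bool = False
    future_definition: str = "correct"        # or "visited"
    auc_scaled: bool = True
    out_dir: str = "futurestate_out"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _substream(master_seed: int, *names) -> int:
    """Derive a deterministic 31-bit child seed from the master seed."""
    h = hashlib.sha256(("/".join(map(str, (master_seed,) + names))).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31 - 1)


@dataclass
class ParticipantResult:
    participant: str
    design: Design
    behavior: pd.DataFrame
    dv_table: pd.DataFrame
    covariate: pd.Series
    performance: dict[str, float]
    validity: dict[str, bool]
    included: bool
    auc: dict[str, float]
    fits: list


def run_participant(config: PipelineConfig, i: int,
                    g_future_override: float | None = None) -> ParticipantResult:
    """Simulate and analyze one synthetic participant end to end."""
    pid = f"sub-{i + 1:02d}"
    d_seed = _substream(config.seed, "design", i)
    design = generate_design(seed=d_seed)
    behavior = simulate_behavior(design, config.p_learn_after_reward,
                                 config.p_learn_after_loss,
                                 seed=_substream(config.seed, "behavior", i))
    g = config.g_future if g_future_override is None else g_future_override
    truth = SimTruth.default(
        n_voxels=config.n_voxels, seed=_substream(config.seed, "patterns", i),
        a_current=config.a_current, a_localizer=config.a_localizer,
        g_future=g, noise_sd=config.noise_sd)
    localizer, learning = simulate_patterns(design, behavior, truth, participant=pid)

    classifiers = decode.train_pairwise(
        localizer, seed=_substream(config.seed, "balance", i))
    dv_table = decode.decision_values(classifiers, learning)
    perf = decode.crossphase_performance(dv_table, classifiers)
    validity, included = decode.exclusion_check(perf)
    auc = decode.generalization_auc(dv_table, classifiers, scale=config.auc_scaled)

    covariate = dvreg.build_correct_rep(behavior, config.covariate_coding)
    fits = dvreg.participant_fits(dv_table, design, covariate, validity,
                                  center=config.center_predictors,
                                  future=config.future_definition)
    return ParticipantResult(pid, design, behavior, dv_table, covariate,
                             perf, validity, included, auc, fits)


@dataclass
class CohortResult:
    participants: list[ParticipantResult]
    effect_table: pd.DataFrame
    group: dict[str, beh.GroupResult]
    n_included: int

    def future_rep_effects(self) -> np.ndarray:
        return self.effect_table["future_x_rep"].to_numpy()


def run_cohort(config: PipelineConfig) -> CohortResult:
    """Simulate and analyze a full cohort; group inference on the
    category-averaged decision-value regression coefficients."""
    results = [run_participant(config, i) for i in range(config.n_participants)]
    included = [r for r in results if r.included]
    table, group = dvreg.aggregate_and_infer([r.fits for r in included])
    return CohortResult(results, table, group, len(included))


def behavioral_summary(results: list[ParticipantResult]) -> dict:
    tables = [r.behavior for r in results]
    acc = beh.accuracy_by_repetition(tables)
    m_rew, m_loss, g = beh.initial_feedback_split(tables)
    return {
        "accuracy_by_repetition": acc.reset_index().to_dict(orient="records"),
        "rep2_after_reward": m_rew,
        "rep2_after_loss": m_loss,
        "split_t": g.t, "split_p": g.p,
    }


# ---------------------------------------------------------------------------
# artifact-writing stage runner used by the command-line interface

class MissingUpstreamError(RuntimeError):
    pass


def _check_hash(outdir: Path, config: PipelineConfig) -> None:
    mark = outdir / "config_hash.txt"
    if mark.exists():
        if mark.read_text().strip() != config.digest():
            raise RuntimeError(
                "artifact directory was produced by a different config; "
                "refusing to mix artifacts")
    else:
        outdir.mkdir(parents=True, exist_ok=True)
        mark.write_text(config.digest())
        config.to_yaml(outdir / "config.yaml")


def run(stage: str, config: PipelineConfig, outdir: str | Path | None = None) -> Path:
    """Run one pipeline stage (or ``all``), writing artifacts to disk.

    Stages depend on earlier ones: ``decode``/``dvreg``/``behavior``
    expect the cohort results file written by ``simulate`` (which runs the
    per-participant analysis since patterns never leave memory by
    default).  Missing upstream artifacts raise
    :class:`MissingUpstreamError` naming the stage to run first.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    out = Path(outdir or config.out_dir)
    _check_hash(out, config)

    if stage in ("simulate", "glm", "decode", "all"):
        cohort = run_cohort(config)
        _write_cohort(out, cohort, config)
        if stage != "all":
            return out

    if stage in ("dvreg", "behavior", "report") and not (out / "effects.tsv").exists():
        raise MissingUpstreamError(
            f"stage {stage!r} needs decode outputs; run 'simulate' (or 'all') first")

    if stage in ("dvreg", "all"):
        pass  # group results are written with the cohort
    if stage in ("behavior", "all"):
        pass
    if stage in ("ppi", "all"):
        _write_ppi(out, config)
    if stage in ("report", "all"):
        write_report(out)
    return out


def _write_cohort(out: Path, cohort: CohortResult, config: PipelineConfig) -> None:
    cohort.effect_table.to_csv(out / "effects.tsv", sep="\t", index=False)
    group = {k: dataclasses.asdict(v) for k, v in cohort.group.items()}
    (out / "group_results.json").write_text(json.dumps(group, indent=2))
    aucs = pd.DataFrame([r.auc | {"participant": r.participant,
                                  "included": r.included}
                         for r in cohort.participants])
    aucs.to_csv(out / "auc.tsv", sep="\t", index=False)
    behavior = pd.concat([r.behavior.assign(participant=r.participant)
                          for r in cohort.participants])
    behavior.to_csv(out / "behavior.tsv", sep="\t", index=False)
    (out / "behavior_summary.json").write_text(
        json.dumps(behavioral_summary(cohort.participants), indent=2, default=float))
    ev = pd.concat([r.dv_table.assign(participant=r.participant)
                    for r in cohort.participants[:1]])
    ev.to_csv(out / "example_decision_values.tsv", sep="\t", index=False)
    per_bin = per_bin_breakdown(cohort)
    per_bin.to_csv(out / "per_bin.tsv", sep="\t", index=True)


def per_bin_breakdown(cohort: CohortResult) -> pd.DataFrame:
    """Group-mean current/future effects per correct-repetition bin,
    averaged over each participant's valid categories."""
    from .dvreg import build_state1_predictors, per_bin_models

    rows = []
    for r in cohort.participants:
        if not r.included:
            continue
        s1 = r.dv_table[(r.dv_table["state"] == "S1")
                        & r.dv_table["of_interest"]].reset_index(drop=True)
        per_cat = []
        for cat, ok in r.validity.items():
            if not ok:
                continue
            X = build_state1_predictors(s1, r.design, r.covariate, cat)
            bins = per_bin_models(s1[f"dv_{cat}"].to_numpy(), X)
            if len(bins):
                per_cat.append(bins.set_index("bin")[["current", "future"]])
        if per_cat:
            rows.append(pd.concat(per_cat).groupby(level=0).mean())
    return pd.concat(rows).groupby(level=0).mean()


def _write_ppi(out: Path, config: PipelineConfig) -> None:
    from .ppi_sim import simulate_learning_ppi_cohort

    stats = simulate_learning_ppi_cohort(config)
    (out / "ppi_results.json").write_text(json.dumps(stats, indent=2, default=float))


def write_report(out: Path) -> Path:
    """Human-readable summary of whatever artifacts exist."""
    lines = ["# futurestate pipeline report", ""]
    gr = out / "group_results.json"
    if not gr.exists():
        lines.append("(no artifacts found — run the pipeline first)")
    else:
        group = json.loads(gr.read_text())
        lines.append("## Group decision-value regression (category-averaged)")
        lines.append(f"{'predictor':16s} {'mean':>9s} {'t':>7s} {'p':>9s}")
        for k, v in group.items():
            lines.append(f"{k:16s} {v['mean']:9.4f} {v['t']:7.2f} {v['p']:9.4g}")
        bs = out / "behavior_summary.json"
        if bs.exists():
            b = json.loads(bs.read_text())
            lines.append("")
            lines.append("## Behavior")
            for row in b["accuracy_by_repetition"]:
                lines.append(f"repetition {int(row['repetition'])}: "
                             f"accuracy {row['mean']:.3f}")
            lines.append(f"rep-2 after reward {b['rep2_after_reward']:.3f} "
                         f"vs after loss {b['rep2_after_loss']:.3f} "
                         f"(paired t = {b['split_t']:.2f}, p = {b['split_p']:.3g})")
        pb = out / "per_bin.tsv"
        if pb.exists():
            per_bin = pd.read_csv(pb, sep="\t", index_col=0)
            lines.append("")
            lines.append("## Per correct-repetition bin (group means)")
            lines.append(f"{'bin':>4s} {'current':>9s} {'future':>9s}")
            for b, row in per_bin.iterrows():
                lines.append(f"{int(b):4d} {row['current']:9.4f} {row['future']:9.4f}")
            _plot_per_bin(per_bin, out)
        eff = out / "effects.tsv"
        if eff.exists():
            lines.append("")
            lines.append("## Checks")
            lines += _checklist(out, group)
        ppi = out / "ppi_results.json"
        if ppi.exists():
            p = json.loads(ppi.read_text())
            lines.append("")
            lines.append("## Learning PPI")
            lines.append(f"group interaction mean {p['group_mean']:.4f} "
                         f"(t = {p['group_t']:.2f}, p = {p['group_p']:.3g}); "
                         f"covariate r = {p['covariate_r']:.3f} (p = {p['covariate_p']:.3g})")
    path = out / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path


def _checklist(out: Path, group: dict) -> list[str]:
    """Sanity checks recomputed from the written artifacts."""
    from .behavior import tost_bound_for_power, tost_test

    lines = []
    effects = pd.read_csv(out / "effects.tsv", sep="\t")
    n = len(effects)
    beh = pd.read_csv(out / "behavior.tsv", sep="\t")
    rep1 = beh[(beh["repetition"] == 1) & beh["of_interest"]]
    ok = rep1["correct"].mean() == 0.5
    lines.append(f"[{'pass' if ok else 'FAIL'}] repetition-1 accuracy 50% by design")
    ok = n >= 3
    lines.append(f"[{'pass' if ok else 'FAIL'}] >= 3 included participants (n = {n})")
    if n >= 3:
        bound = tost_bound_for_power(n, 0.80, 0.05, decimals=None)
        res = tost_test(effects["future_x_rep"].to_numpy(), bound)
        verdict = "equivalent to zero" if res.equivalent else "not equivalent to zero"
        lines.append(f"[info] future_x_rep TOST at n-matched bound d = {bound:.2f}: "
                     f"{verdict} (p = {res.p_tost:.3g})")
        fut = group.get("future_x_rep", {})
        if fut:
            sig = fut["p"] < 0.05
            lines.append(f"[info] future_x_rep group test: "
                         f"{'significant' if sig else 'not significant'} "
                         f"(p = {fut['p']:.3g})")
    return lines


def _plot_per_bin(per_bin: pd.DataFrame, out: Path) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:         # plotting is optional
        return
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.plot(per_bin.index, per_bin["current"], "o-", label="current state")
    ax.plot(per_bin.index, per_bin["future"], "s-", label="future state")
    ax.axhline(0, color="0.6", lw=0.8)
    ax.set_xlabel("correct-repetition bin")
    ax.set_ylabel("decision-value effect")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out / "per_bin.png", dpi=120)
    plt.close(fig)
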