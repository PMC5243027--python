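"""End-to-end experiments: simulation batteries plus their analyses.

Each experiment mirrors one of the study designs:

* **stimulation** — within-subject blocks under no stimulation,
  depolarizing and hyperpolarizing injected currents, with paired
  comparisons of accuracy threshold, decision-time difference slopes,
  indecision-point shift and hysteresis ratio.
* **isi** — independent subject groups per inter-stimulus interval,
  testing the decay of choice hysteresis with longer ISIs (one-way ANOVA
  across levels).
* **controls** — falsification and robustness variants: input-parameter
  changes (60 Hz total input, 30/120 Hz refresh), stimulation-pattern
  controls (pyramidal-only, interneuron-only, uniform), reinitialized
  sessions, and the accumulator architecture.

All randomness derives from a single master seed; subject-level and
block-level seeds are spawned deterministically, so rerunning with the
same master seed reproduces every table.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior
from .behavior import (
    HysteresisLogit,
    WeibullPsychometric,
    anova_oneway,
    dt_difference_regression,
    filter_trials,
    indecision_points,
    wilcoxon_signed_rank,
)
from .params import Architecture, NetworkConfig
from .task import (
    DEFAULT_COHERENCES,
    InputSpec,
    SessionSpec,
    VirtualSubject,
    make_trial_list,
    run_session,
    sample_virtual_subject,
)

__all__ = [
    "ExperimentConfig",
    "run_stimulation_experiment",
    "run_isi_experiment",
    "run_control_experiments",
    "summarize_subject_condition",
]

logger = logging.getLogger("attractorchoice")


@dataclass(frozen=True)
class ExperimentConfig:
    """Scale and condition settings for one experiment run."""

    experiment: str = "stimulation"
    n_subjects: int = 20
    coherences: tuple[float, ...] = DEFAULT_COHERENCES
    reps_per_direction: int = 10
    conditions: tuple[str, ...] = ("none", "depolarizing", "hyperpolarizing")
    isi: float = 2.0
    isi_levels: tuple[float, ...] = (1.5, 2.0, 3.0, 5.0)
    total_rate: float = 80.0
    refresh_hz: float = 60.0
    continuity: str = "continuous"
    architecture: str = "attractor"
    master_seed: int = 0
    output_dir: str | None = None

    def scaled(self, ci: bool) -> "ExperimentConfig":
        """Desk-scale variant: 4 subjects, 2 coherences, 40 trials/block."""
        if not ci:
            return self
        return replace(
            self, n_subjects=4, coherences=(0.032, 0.512), reps_per_direction=10
        )


def _subject_for(config: ExperimentConfig, sid: int, architecture: str) -> VirtualSubject:
    rng = np.random.default_rng(np.random.SeedSequence([config.master_seed, sid]))
    subj = sample_virtual_subject(sid, architecture, rng)
    return subj


def _block_seed(config: ExperimentConfig, sid: int, tag: str) -> int:
    # zlib.crc32 is process-independent (unlike hash(), which is salted)
    ss = np.random.SeedSequence([config.master_seed, sid, zlib.crc32(tag.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def _run_block(
    config: ExperimentConfig,
    subject: VirtualSubject,
    condition: str,
    *,
    isi: float | None = None,
    continuity: str | None = None,
    net_config: NetworkConfig | None = None,
    input_spec: InputSpec | None = None,
    block: int = 0,
):
    isi = config.isi if isi is None else isi
    continuity = config.continuity if continuity is None else continuity
    # trial order and noise streams are shared across stimulation conditions
    # (common random numbers): within a subject, blocks differ only in the
    # injected currents, which sharpens the paired comparisons
    rng = np.random.default_rng(_block_seed(config, subject.subject_id, f"trials@{isi}"))
    pre = min(1.0, isi - 1.0)
    trials = make_trial_list(
        config.coherences, config.reps_per_direction, rng, input_onset=pre,
        input_offset=pre + 1.0, trial_duration=pre + 2.0,
    )
    session = SessionSpec(
        trials=tuple(trials), isi=isi, continuity=continuity, stimulation=condition
    )
    subject = replace(subject, session_seed=_block_seed(config, subject.subject_id, f"sess@{isi}"))
    if input_spec is None:
        input_spec = InputSpec(
            total_rate=config.total_rate,
            refresh_hz=config.refresh_hz,
            background_rate=subject.background_rate,
        )
    return run_session(
        subject, session, config=net_config, input_spec=input_spec,
        condition_label=condition, block=block,
    )


def summarize_subject_condition(records: pd.DataFrame) -> pd.DataFrame:
    """Per subject × condition analysis summary.

    One row per subject × condition with the Weibull accuracy threshold,
    hysteresis coefficients (a0, a1, a2, a2/a1), indecision-point shift
    and mean decision time per coherence level.
    """
    records = filter_trials(
        records.rename(columns={"decision_time_s": "decision_time"}),
        time_col="decision_time",
    )
    rows = []
    for (sid, cond), grp in records.groupby(["subject_id", "condition"]):
        row: dict = {"subject_id": sid, "condition": cond}
        valid = grp[grp["valid"]]
        try:
            wb = WeibullPsychometric.from_trials(grp).fit()
            row.update(threshold=wb.accuracy_threshold, weibull_converged=wb.converged)
        except ValueError:
            row.update(threshold=np.nan, weibull_converged=False)
        try:
            fit = HysteresisLogit.from_trials(grp).fit()
            row.update(a0=fit.a0, a1=fit.a1, a2=fit.a2, ratio=fit.ratio)
        except ValueError:
            row.update(a0=np.nan, a1=np.nan, a2=np.nan, ratio=np.nan)
        ip_l, ip_r, shift = indecision_points(grp)
        row.update(ip_after_left=ip_l, ip_after_right=ip_r, shift=shift)
        row.update(
            n_valid=len(valid),
            mean_dt=valid["decision_time"].mean(),
            response_rate=grp["responded"].mean(),
        )
        for c_abs, cg in valid.groupby(valid["coherence_signed"].abs()):
            row[f"dt_{c_abs:g}"] = cg["decision_time"].mean()
        rows.append(row)
    return pd.DataFrame(rows)


def _paired_tests(summary: pd.DataFrame, conditions, baseline="none") -> dict:
    """Wilcoxon comparisons of each stimulation condition against baseline."""
    tests: dict = {}
    base = summary[summary["condition"] == baseline].set_index("subject_id")
    for cond in conditions:
        if cond == baseline:
            continue
        other = summary[summary["condition"] == cond].set_index("subject_id")
        common = base.index.intersection(other.index)
        if len(common) < 5:
            continue
        for metric in ("threshold", "ratio", "shift", "a2"):
            x = other.loc[common, metric].astype(float)
            y = base.loc[common, metric].astype(float)
            ok = x.notna() & y.notna()
            if ok.sum() < 5 or (x[ok] == y[ok]).all():
                continue
            tests[f"{metric}_{cond}_vs_{baseline}"] = wilcoxon_signed_rank(
                x[ok].to_numpy(), y[ok].to_numpy()
            )
    return tests


def _dt_regressions(records: pd.DataFrame, conditions, coherences, baseline="none") -> dict:
    """Decision-time difference slopes per stimulation condition."""
    records = filter_trials(
        records.rename(columns={"decision_time_s": "decision_time"}),
        time_col="decision_time",
    )
    valid = records[records["valid"]]
    cells = (
        valid.assign(c_abs=valid["coherence_signed"].abs())
        .groupby(["subject_id", "condition", "c_abs"])["decision_time"]
        .mean()
        .unstack("c_abs")
    )
    out = {}
    grid = sorted(cells.columns)
    if len(grid) < 2:  # slope undefined on a single coherence level
        return out
    for cond in conditions:
        if cond == baseline:
            continue
        try:
            stim = cells.xs(cond, level="condition")
            ctrl = cells.xs(baseline, level="condition")
        except KeyError:
            continue
        common = stim.index.intersection(ctrl.index)
        if len(common) == 0:
            continue
        out[cond] = dt_difference_regression(
            stim.loc[common, grid].to_numpy(),
            ctrl.loc[common, grid].to_numpy(),
            coherences=grid,
        )
    return out


def run_stimulation_experiment(config: ExperimentConfig) -> dict:
    """Within-subject stimulation experiment: one block per condition.

    Every subject keeps its wiring and parameters across conditions; only
    the injected currents change.  Returns records, per-subject summaries,
    paired Wilcoxon tests and decision-time difference regressions.
    """
    all_records = []
    all_traces = []
    for sid in range(config.n_subjects):
        subj = _subject_for(config, sid, config.architecture)
        for bi, cond in enumerate(config.conditions):
            logger.info("subject %d condition %s", sid, cond)
            res = _run_block(config, subj, cond, block=bi)
            all_records.append(res.records)
            res.traces["subject_id"] = sid
            res.traces["condition"] = cond
            all_traces.append(res.traces)
    records = pd.concat(all_records, ignore_index=True)
    summary = summarize_subject_condition(records)
    tests = _paired_tests(summary, config.conditions)
    regressions = _dt_regressions(records, config.conditions, config.coherences)
    out = {
        "records": records,
        "summary": summary,
        "tests": tests,
        "dt_regressions": regressions,
        "traces": pd.concat(all_traces, ignore_index=True),
    }
    _maybe_write(config, out)
    return out


def run_isi_experiment(config: ExperimentConfig) -> dict:
    """Between-group ISI experiment: independent subjects per ISI level.

    With four levels and 20 subjects each this matches an F(3, 76) ANOVA
    design; scaled-down runs keep the structure with fewer subjects.
    """
    if len(config.isi_levels) < 2:
        raise ValueError("need at least two ISI levels")
    all_records = []
    rows = []
    for li, isi in enumerate(config.isi_levels):
        for sid in range(config.n_subjects):
            gid = li * config.n_subjects + sid
            subj = _subject_for(config, gid, config.architecture)
            res = _run_block(config, subj, "none", isi=isi)
            rec = res.records
            rec["isi"] = isi
            all_records.append(rec)
    records = pd.concat(all_records, ignore_index=True)
    summary = summarize_subject_condition(records)
    isi_of = records.groupby("subject_id")["isi"].first()
    summary["isi"] = summary["subject_id"].map(isi_of)
    groups_ratio = [
        summary.loc[summary["isi"] == isi, "ratio"].dropna().to_numpy()
        for isi in config.isi_levels
    ]
    groups_shift = [
        summary.loc[summary["isi"] == isi, "shift"].dropna().to_numpy()
        for isi in config.isi_levels
    ]
    tests = {}
    try:
        tests["anova_ratio"] = anova_oneway(groups_ratio)
        tests["anova_shift"] = anova_oneway(groups_shift)
    except ValueError as err:
        tests["anova_error"] = str(err)
    out = {"records": records, "summary": summary, "tests": tests}
    _maybe_write(config, out)
    return out


#: Control-variant specification: name -> session/config overrides.
CONTROL_VARIANTS = {
    "total_rate_60": {"total_rate": 60.0},
    "refresh_30": {"refresh_hz": 30.0},
    "refresh_120": {"refresh_hz": 120.0},
    "pyramidal_only": {"conditions": ("none", "pyramidal_only_depol", "pyramidal_only_hyper")},
    "interneuron_only": {"conditions": ("none", "interneuron_only_depol", "interneuron_only_hyper")},
    "uniform": {"conditions": ("none", "uniform_depol", "uniform_hyper")},
    "reinitialization": {"continuity": "reinitialized"},
    "accumulator": {"architecture": "accumulator"},
}


def run_control_experiments(config: ExperimentConfig, variants=None) -> dict:
    """Run the control variants and emit the same metric set per variant."""
    variants = list(CONTROL_VARIANTS) if variants is None else list(variants)
    unknown = set(variants) - set(CONTROL_VARIANTS)
    if unknown:
        raise ValueError(f"unknown control variants: {sorted(unknown)}")
    results = {}
    for name in variants:
        overrides = CONTROL_VARIANTS[name]
        sub_cfg = replace(
            config,
            experiment=f"controls/{name}",
            output_dir=None,
            **{k: v for k, v in overrides.items()},
        )
        logger.info("control variant %s", name)
        results[name] = run_stimulation_experiment(sub_cfg)
    out = {"variants": results}
    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, res in results.items():
            res["records"].to_csv(outdir / f"records_{name}.csv", index=False)
            res["summary"].to_csv(outdir / f"summary_{name}.csv", index=False)
        _write_tests_json(
            outdir / "tests.json",
            {f"{name}.{k}": v for name, res in results.items() for k, v in res["tests"].items()},
        )
    return out


def _write_tests_json(path: Path, tests: dict) -> None:
    payload = {}
    for k, v in tests.items():
        if isinstance(v, behavior.TestResult):
            payload[k] = {
                "statistic": v.statistic,
                "p_value": v.p_value,
                "n": list(v.n),
                "test": v.test_name,
            }
        elif isinstance(v, behavior.RegressionFit):
            payload[k] = {"beta0": v.beta0, "beta1": v.beta1, "p_slope": v.p_slope}
        else:
            payload[k] = str(v)
    path.write_text(json.dumps(payload, indent=2))


def _maybe_write(config: ExperimentConfig, out: dict) -> None:
    if not config.output_dir:
        return
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    out["records"].to_csv(outdir / "records.csv", index=False)
    out["summary"].to_csv(outdir / "summary.csv", index=False)
    tests = dict(out.get("tests", {}))
    tests.update(out.get("dt_regressions", {}))
    _write_tests_json(outdir / "tests.json", tests)
    manifest = {
        "experiment": config.experiment,
        "master_seed": config.master_seed,
        "n_subjects": config.n_subjects,
        "coherences": list(config.coherences),
        "conditions": list(config.conditions),
        "continuity": config.continuity,
        "architecture": config.architecture,
    }
    (outdir / "config.json").write_text(json.dumps(manifest, indent=2))
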