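"""End-to-end orchestration: cohort in, statistical report out.

Stage order is fixed: participant screening -> band-pass filter -> EOG
regression correction -> scenario slicing and 2-s epoching -> amplitude
rejection -> averaged periodogram -> theta band power -> within-subjects
ANOVAs. The input cohort is either synthetic (in memory, with ground truth)
or a directory of EDF recordings with sidecar annotation/behavioral CSVs.

Emitted tables:

* a channel x condition matrix of cohort-mean theta power with a "Mean" row
  (the overall workload summary),
* a behavioral summary (task-load and engine-stop means +/- SD per scenario),
* ANOVA and Bonferroni pairwise tables for the terrain-complexity 3 x channel
  design, the driving-vs-baseline and pre-vs-post-baseline 2 x channel
  designs, and the behavioral one-ways,
* a per-subject/condition discard report, and
* a run log with package version, seed, and a config hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from eegworkload import __version__
from eegworkload.io import (
    Recording,
    ScenarioAnnotation,
    read_annotations,
    read_behavioral,
    read_recording,
)
from eegworkload.preprocess import apply_bandpass, design_bandpass, fit_eog_model, remove_eog
from eegworkload.spectral import (
    average_periodogram,
    build_band_power_table,
    condition_channel_matrix,
    reject_epochs,
    slice_and_epoch,
)
from eegworkload.stats import (
    bonferroni_pairwise,
    complete_cases_matrix,
    rm_anova_oneway,
    rm_anova_twoway,
    screen_participants,
)
from eegworkload.synthetic import SimulationConfig, generate_cohort

__all__ = ["PipelineConfig", "PipelineResult", "run", "make_report", "preprocess_subject"]


@dataclass
class PipelineConfig:
    """Configuration of one analysis run.

    Exactly one of ``synthetic`` (a SimulationConfig) or ``recordings_dir``
    (a directory of ``sub-<id>.edf`` + ``sub-<id>_annotations.csv`` files
    with a ``behavioral.csv``) must be set.
    """

    synthetic: SimulationConfig | None = None
    recordings_dir: str | None = None
    behavioral_path: str | None = None
    filter_low_hz: float = 0.5
    filter_high_hz: float = 32.0
    filter_order: int = 4
    filter_passes: str = "zero_phase"
    eog_correction: bool = True
    eog_fit_span: tuple[float, float] | None = None
    epoch_length_s: float = 2.0
    reject_threshold_uv: float = 100.0
    band: tuple[float, float] = (4.0, 8.0)
    alpha: float = 0.05
    exclude_eeg_subjects: tuple[int, ...] = ()
    output_dir: str | None = None
    seed: int | None = None

    def __post_init__(self):
        if (self.synthetic is None) == (self.recordings_dir is None):
            raise ValueError("set exactly one of synthetic config or recordings_dir")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.seed is not None and self.synthetic is not None:
            self.synthetic = replace(self.synthetic, seed=int(self.seed))

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = asdict(self.synthetic)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        from eegworkload.synthetic import BehavioralSpec, ConditionSpec

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic", None)
        if syn is not None:
            if "conditions" in syn:
                syn["conditions"] = tuple(
                    ConditionSpec(**c) for c in syn["conditions"]
                )
            if "behavioral" in syn:
                syn["behavioral"] = {
                    k: BehavioralSpec(**v) for k, v in syn["behavioral"].items()
                }
            for key in ("channels", "channel_gains", "propagation_v", "propagation_h"):
                if key in syn and syn[key] is not None:
                    syn[key] = tuple(syn[key])
            syn = SimulationConfig(**syn)
        for key in ("band", "eog_fit_span", "exclude_eeg_subjects"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(synthetic=syn, **raw)


@dataclass
class PipelineResult:
    """All tables and fitted results of one pipeline run."""

    band_power: pd.DataFrame
    theta_matrix: pd.DataFrame
    behavioral_summary: pd.DataFrame
    anova_table: pd.DataFrame
    pairwise_table: pd.DataFrame
    discard_table: pd.DataFrame
    anovas: dict
    pairwise: dict
    log: dict


def preprocess_subject(recording: Recording, config: PipelineConfig) -> Recording:
    """Filter and (optionally) EOG-correct one recording, in that order."""
    spec = design_bandpass(
        config.filter_low_hz, config.filter_high_hz, recording.fs,
        order=config.filter_order, passes=config.filter_passes,
    )
    rec = apply_bandpass(recording, spec)
    if config.eog_correction:
        model = fit_eog_model(rec, fit_span=config.eog_fit_span)
        rec = remove_eog(rec, model)
    return rec


def _load_real_cohort(config: PipelineConfig):
    root = Path(config.recordings_dir)
    behavioral = read_behavioral(config.behavioral_path or root / "behavioral.csv")
    bundles = []
    for edf in sorted(root.glob("sub-*.edf")):
        subj = int(edf.stem.split("-")[1])
        annots = read_annotations(edf.with_name(f"{edf.stem}_annotations.csv"))
        bundles.append((subj, read_recording(edf), annots))
    if not bundles:
        raise FileNotFoundError(f"no sub-*.edf recordings found in {root}")
    return bundles, behavioral


def _order_conditions(annotations: list[ScenarioAnnotation]):
    """Scenario labels by complexity rank; baselines by time (pre first)."""
    scen = sorted(
        {(a.complexity_rank, a.label) for a in annotations if a.complexity_rank > 0}
    )
    base = [a.label for a in sorted(annotations, key=lambda a: a.start_s)
            if a.complexity_rank == 0]
    return [lab for _, lab in scen], base


def run(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis and return the report bundle."""
    if config.synthetic is not None:
        cohort, _truth = generate_cohort(config.synthetic)
        bundles = [(truth.subject, rec, annots) for rec, annots, truth in cohort]
        behavioral = _truth.behavioral
    else:
        bundles, behavioral = _load_real_cohort(config)

    # participant screening on pre-task sleepiness
    sss = behavioral.groupby("subject")["sss"].first()
    included = set(sss.index[screen_participants(sss.to_numpy())])
    n_screened_out = len(sss) - len(included)
    behavioral = behavioral[behavioral["subject"].isin(included)]

    scenario_labels, baseline_labels = _order_conditions(bundles[0][2])
    excluded_eeg = set(config.exclude_eeg_subjects)

    spectra: dict[int, dict] = {}
    discard_rows = []
    for subj, rec, annots in bundles:
        if subj not in included or subj in excluded_eeg:
            continue
        clean = preprocess_subject(rec, config)
        per_cond = {}
        for ann in annots:
            es = slice_and_epoch(clean, ann, config.epoch_length_s)
            es, rep = reject_epochs(es, config.reject_threshold_uv)
            rep["subject"] = subj
            discard_rows.append(rep)
            per_cond[ann.label] = average_periodogram(es)
        spectra[subj] = per_cond

    eeg_labels = [bundles[0][1].labels[i] for i in bundles[0][1].eeg_indices]
    band_table = build_band_power_table(spectra, band=config.band, eeg_labels=eeg_labels)

    cond_order = ([baseline_labels[0]] if baseline_labels else []) + scenario_labels + (
        baseline_labels[1:] if len(baseline_labels) > 1 else []
    )
    theta_matrix = condition_channel_matrix(band_table, cond_order)

    anovas: dict = {}
    pairwise: dict = {}
    dropped: dict[str, int] = {}

    scen_table = band_table[band_table["condition"].isin(scenario_labels)]
    y, _, _, ndrop = complete_cases_matrix(
        scen_table, "theta_power", factors=["condition", "channel"],
        levels={"condition": scenario_labels, "channel": eeg_labels},
    )
    dropped["terrain x channel"] = ndrop
    anovas["terrain x channel"] = rm_anova_twoway(
        y, len(scenario_labels), len(eeg_labels),
        effect_names=("terrain", "channel"), alpha_gg=config.alpha,
    )
    # pairwise terrain contrasts on channel-averaged marginal means
    marg = y.reshape(y.shape[0], len(scenario_labels), len(eeg_labels)).mean(axis=2)
    pairwise["terrain"] = bonferroni_pairwise(marg, scenario_labels)

    if baseline_labels:
        pre = baseline_labels[0]
        ba_table = band_table[band_table["condition"].isin([pre] + scenario_labels)]
        yba, _, _, _ = complete_cases_matrix(
            ba_table, "theta_power", factors=["condition", "channel"],
            levels={"condition": [pre] + scenario_labels, "channel": eeg_labels},
        )
        yba = yba.reshape(yba.shape[0], 1 + len(scenario_labels), len(eeg_labels))
        # driving-vs-baseline: average the scenarios per channel first
        drive = yba[:, 1:, :].mean(axis=1)
        stacked = np.concatenate([yba[:, 0, :], drive], axis=1)
        anovas["activity x channel"] = rm_anova_twoway(
            stacked, 2, len(eeg_labels),
            effect_names=("activity", "channel"), alpha_gg=config.alpha,
        )
        if len(baseline_labels) > 1:
            post = baseline_labels[-1]
            pp_table = band_table[band_table["condition"].isin([pre, post])]
            ypp, _, _, _ = complete_cases_matrix(
                pp_table, "theta_power", factors=["condition", "channel"],
                levels={"condition": [pre, post], "channel": eeg_labels},
            )
            anovas["time x channel"] = rm_anova_twoway(
                ypp, 2, len(eeg_labels),
                effect_names=("measurement_time", "channel"), alpha_gg=config.alpha,
            )

    behav_rows = []
    for measure in ("tlx", "stops"):
        scen_behav = behavioral[behavioral["condition"].isin(scenario_labels)]
        yb, _, _, ndrop = complete_cases_matrix(
            scen_behav, measure, factors=["condition"],
            levels={"condition": scenario_labels},
        )
        dropped[measure] = ndrop
        anovas[measure] = {measure: rm_anova_oneway(yb, effect=measure,
                                                    alpha_gg=config.alpha)}
        pairwise[measure] = bonferroni_pairwise(yb, scenario_labels)
        for j, lab in enumerate(scenario_labels):
            behav_rows.append(
                {"measure": measure, "condition": lab,
                 "mean": yb[:, j].mean(), "sd": yb[:, j].std(ddof=1), "n": yb.shape[0]}
            )
    behavioral_summary = pd.DataFrame(behav_rows)

    anova_rows = []
    for analysis, effects in anovas.items():
        for name, r in effects.items():
            anova_rows.append(
                {"analysis": analysis, "effect": name, "F": r.F,
                 "df1": r.df1, "df2": r.df2, "epsilon_gg": r.epsilon_gg,
                 "df1_corr": r.df1_corr, "df2_corr": r.df2_corr,
                 "p_uncorrected": r.p_uncorrected, "p_gg": r.p_gg,
                 "use_gg": r.use_gg, "partial_eta_sq": r.partial_eta_sq,
                 "formatted": r.format()}
            )
    pairwise_rows = []
    for analysis, results in pairwise.items():
        for pr in results:
            pairwise_rows.append(
                {"analysis": analysis, "level_a": pr.pair[0], "level_b": pr.pair[1],
                 "mean_diff": pr.mean_diff, "t": pr.t, "df": pr.df,
                 "p_raw": pr.p_raw, "p_bonferroni": pr.p_bonferroni, "m": pr.m}
            )

    discard_table = pd.DataFrame(discard_rows)
    log = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.synthetic.seed if config.synthetic is not None else None,
        "config_hash": config.config_hash(),
        "stage_order": "screen > filter > eog_correct > epoch > reject > psd > band_power > stats",
        "eog_correction": config.eog_correction,
        "n_subjects_input": len(bundles),
        "n_screened_out": n_screened_out,
        "n_eeg_excluded": len(excluded_eeg & included),
        "n_eeg_analyzed": len(spectra),
        "listwise_dropped": dropped,
    }

    result = PipelineResult(
        band_power=band_table,
        theta_matrix=theta_matrix,
        behavioral_summary=behavioral_summary,
        anova_table=pd.DataFrame(anova_rows),
        pairwise_table=pd.DataFrame(pairwise_rows),
        discard_table=discard_table,
        anovas=anovas,
        pairwise=pairwise,
        log=log,
    )
    if config.output_dir is not None:
        make_report(result, config.output_dir)
    return result


def make_report(result: PipelineResult, output_dir, text: bool = True) -> list[Path]:
    """Write the report bundle as CSVs (plus a human-readable summary)."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df, with_index in [
        ("band_power.csv", result.band_power, False),
        ("theta_matrix.csv", result.theta_matrix, True),
        ("behavioral_summary.csv", result.behavioral_summary, False),
        ("anova.csv", result.anova_table, False),
        ("pairwise.csv", result.pairwise_table, False),
        ("discard.csv", result.discard_table, False),
    ]:
        path = out / name
        df.to_csv(path, index=with_index)
        written.append(path)
    (out / "run_log.json").write_text(json.dumps(result.log, indent=2, default=str))
    written.append(out / "run_log.json")
    if text:
        lines = ["# Analysis summary", "", "## ANOVA effects"]
        for analysis, effects in result.anovas.items():
            for name, r in effects.items():
                lines.append(f"{analysis} / {name}: {r.format()}")
        lines += ["", "## Pairwise contrasts (Bonferroni)"]
        if not result.pairwise:
            lines.append("none")
        for analysis, results in result.pairwise.items():
            if not results:
                lines.append(f"{analysis}: none")
            for pr in results:
                lines.append(
                    f"{analysis}: {pr.pair[0]} vs {pr.pair[1]}: "
                    f"diff = {pr.mean_diff:.2f}, t({pr.df}) = {pr.t:.2f}, "
                    f"corrected p = {pr.p_bonferroni:.3f}"
                )
        path = out / "summary.txt"
        path.write_text("\n".join(lines) + "\n")
        written.append(path)
    return written
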