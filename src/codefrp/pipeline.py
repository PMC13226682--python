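"""End-to-end orchestration: simulate -> gaze -> EEG -> cluster test.

A single validated configuration drives the whole analysis. Every trial
that drops out is recorded once, at its first failing stage, in an
exclusion ledger whose counts are additive (trials in = excluded + used).
Outputs are written under a run directory with a fixed layout:

    ledger.tsv      per-trial exclusion ledger
    clusters.tsv    cluster table for both one-sided tests
    report.txt      human-readable cluster report
    averages/       grand averages, difference wave, topography tables
    log.jsonl       structured run log (seed, config hash, stage tallies)
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import eeg as eeg_mod
from . import gaze as gaze_mod
from .cluster import PermutationResult, cluster_permutation_test, summarize_clusters
from .containers import DifferenceWaveSet, Epoch, ParticipantAverage
from .montage import load_default_adjacency
from .synthetic import (
    DesignSpec,
    EffectSpec,
    GazeNoiseSpec,
    ParticipantData,
    StudyBundle,
    generate_study,
)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "RunReport"]


# --------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class AnalysisSettings:
    downsample_hz: float = 100.0
    window_ms: tuple[float, float] = (100.0, 1000.0)
    alpha: float = 0.05
    max_exhaustive: int = 2**20
    n_monte_carlo: int = 10_000
    excluded_electrodes: tuple[str, ...] = ("T7", "T8", "O1", "O2")
    min_cluster_size: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class GeneratorSettings:
    noise_sd_uv: float = 10.0
    artifact_rate: float = 0.015
    bad_gaze_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.noise_sd_uv < 0 or not 0 <= self.artifact_rate <= 1:
            raise ValueError("invalid generator settings")


@dataclass(frozen=True)
class QCSettings:
    max_missing_fraction: float = 0.25
    max_gap_ms: float = 1000.0


@dataclass(frozen=True)
class FilterSettings:
    low_hz: float = 0.05
    high_hz: float = 30.0
    order: int = 4
    notch_hz: float = 50.0


@dataclass(frozen=True)
class EpochSettings:
    window_ms: tuple[float, float] = (-300.0, 1000.0)
    baseline_ms: tuple[float, float] = (-300.0, 0.0)


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 1
    design: DesignSpec = field(default_factory=DesignSpec)
    effect: EffectSpec = field(default_factory=EffectSpec)
    gaze_noise: GazeNoiseSpec = field(default_factory=GazeNoiseSpec)
    generator: GeneratorSettings = field(default_factory=GeneratorSettings)
    qc: QCSettings = field(default_factory=QCSettings)
    detection: gaze_mod.I2MCParams = field(default_factory=gaze_mod.I2MCParams)
    outlier_k_line_heights: float = 2.0
    filter: FilterSettings = field(default_factory=FilterSettings)
    epoch: EpochSettings = field(default_factory=EpochSettings)
    artifact: eeg_mod.ArtifactCriteria = field(default_factory=eeg_mod.ArtifactCriteria)
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)
    fixation_source: str = "detected"  # "truth" bypasses gaze processing (diagnostics)

    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: conv(getattr(obj, f.name)) for f in dataclasses.fields(obj)
                }
            if isinstance(obj, (tuple, list)):
                return [conv(v) for v in obj]
            return obj

        d = conv(self)
        d["effect"] = {
            k: v for k, v in d["effect"].items() if k not in ("epoch_bounds_ms",)
        }
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


_SECTION_TYPES = {
    "design": DesignSpec,
    "effect": EffectSpec,
    "gaze_noise": GazeNoiseSpec,
    "generator": GeneratorSettings,
    "qc": QCSettings,
    "detection": gaze_mod.I2MCParams,
    "filter": FilterSettings,
    "epoch": EpochSettings,
    "artifact": eeg_mod.ArtifactCriteria,
    "analysis": AnalysisSettings,
}
_SCALAR_KEYS = {"seed", "outlier_k_line_heights", "fixation_source"}


def _reject_unknown(given: set[str], allowed: set[str], context: str) -> None:
    unknown = given - allowed
    if unknown:
        msgs = []
        for key in sorted(unknown):
            hint = difflib.get_close_matches(key, allowed, n=1)
            suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
            msgs.append(f"{context}: unknown key {key!r}{suffix}")
        raise ValueError("; ".join(msgs))


def validate_config(raw: dict | str | Path | None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file or dict.

    Unknown keys are rejected with a suggestion; missing keys take the
    defaults (which match the study's stated parameters wherever those
    exist); value constraints are enforced by the dataclass constructors.
    An empty file yields the fully defaulted configuration.
    """
    if raw is None:
        raw = {}
    if isinstance(raw, (str, Path)):
        import yaml

        text = Path(raw).read_text()
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    _reject_unknown(set(raw), set(_SECTION_TYPES) | _SCALAR_KEYS, "config")
    kwargs: dict = {}
    for name, cls in _SECTION_TYPES.items():
        section = raw.get(name, {})
        if not isinstance(section, dict):
            raise ValueError(f"config section {name!r} must be a mapping")
        allowed = {f.name for f in dataclasses.fields(cls)}
        if name == "effect":
            allowed -= {"epoch_bounds_ms"}
        _reject_unknown(set(section), allowed, name)
        coerced = {
            k: tuple(v) if isinstance(v, list) else v for k, v in section.items()
        }
        kwargs[name] = cls(**coerced)
    for key in _SCALAR_KEYS & set(raw):
        kwargs[key] = raw[key]
    cfg = PipelineConfig(**kwargs)
    if cfg.fixation_source not in ("detected", "truth"):
        raise ValueError("fixation_source must be 'detected' or 'truth'")
    return cfg


# --------------------------------------------------------------------------
# staged processing (per participant)


def process_gaze_participant(
    pdata: ParticipantData, layouts: dict, cfg: PipelineConfig
) -> tuple[list[tuple[str, int, str]], dict[str, gaze_mod.FixationSequence], list[dict]]:
    """QC, detect, correct, and select the first-AOI fixation per trial.

    Returns EEG event tuples (trial_id, sample, condition), the corrected
    fixation sequences, and ledger rows for excluded trials.
    """
    ledger: list[dict] = []
    events: list[tuple[str, int, str]] = []
    sequences: dict[str, gaze_mod.FixationSequence] = {}
    rate = pdata.eeg.rate_hz

    if cfg.fixation_source == "truth":
        # diagnostic shortcut: time-lock on the generator's ground truth,
        # bypassing detection/correction entirely
        for row in pdata.trials.itertuples():
            tf = pdata.truth.first_aoi.get(row.trial_id)
            if tf is None:
                ledger.append(
                    {
                        "trial_id": row.trial_id,
                        "stage": "aoi_selection",
                        "reason": "no_aoi_fixation",
                    }
                )
                continue
            sample = int(round((row.snippet_on_s + tf.onset_ms / 1000.0) * rate))
            events.append((row.trial_id, sample, row.condition))
        return events, sequences, ledger

    for block, btrials in pdata.trials.groupby("block"):
        detected: dict[str, gaze_mod.FixationSequence] = {}
        blayouts: dict[str, object] = {}
        for row in btrials.itertuples():
            tid = row.trial_id
            stream = pdata.gaze[tid]
            qc = gaze_mod.assess_trial_quality(
                stream, cfg.qc.max_missing_fraction, cfg.qc.max_gap_ms
            )
            if not qc.retained:
                ledger.append(
                    {"trial_id": tid, "stage": "gaze_qc", "reason": qc.reasons[0]}
                )
                continue
            seq = gaze_mod.detect_fixations(stream, cfg.detection)
            if len(seq) == 0:
                ledger.append(
                    {"trial_id": tid, "stage": "fixation_detection", "reason": "no_fixations"}
                )
                continue
            layout = layouts[row.snippet_id]
            seq, _ = gaze_mod.remove_outlier_fixations(
                seq, layout, cfg.outlier_k_line_heights
            )
            if len(seq) == 0:
                ledger.append(
                    {"trial_id": tid, "stage": "outlier_removal", "reason": "all_outliers"}
                )
                continue
            detected[tid] = seq
            blayouts[tid] = layout
        if detected:
            offset = gaze_mod.estimate_constant_offset(
                list(detected.values()), [blayouts[t] for t in detected]
            )
            for tid, seq in detected.items():
                shifted = gaze_mod.apply_constant_offset(seq, offset)
                corrected = gaze_mod.choose_correction(shifted, blayouts[tid])
                sequences[tid] = corrected

    selected: dict[str, gaze_mod.Fixation] = {}
    for row in pdata.trials.itertuples():
        tid = row.trial_id
        if tid not in sequences:
            continue
        layout = layouts[row.snippet_id]
        fix = gaze_mod.first_aoi_fixation(sequences[tid], layout.aoi)
        if fix is None:
            ledger.append(
                {"trial_id": tid, "stage": "aoi_selection", "reason": "no_aoi_fixation"}
            )
            continue
        sample = int(round((row.snippet_on_s + fix.onset_ms / 1000.0) * rate))
        events.append((tid, sample, row.condition))
        selected[tid] = fix
    return events, sequences, ledger


def snippet_onset_events(pdata: ParticipantData) -> list[tuple[str, int, str]]:
    """Stimulus-onset events (trial_id, sample, condition) for the ERP
    control analysis: the same epoch/average machinery applied with the
    snippet onset instead of the first AOI fixation as the time-lock."""
    rate = pdata.eeg.rate_hz
    return [
        (row.trial_id, int(round(row.snippet_on_s * rate)), row.condition)
        for row in pdata.trials.itertuples()
    ]


def process_eeg_participant(
    pdata: ParticipantData,
    events: list[tuple[str, int, str]],
    cfg: PipelineConfig,
    timelock: str = "fixation",
) -> tuple[list[Epoch], list[dict]]:
    """Filter, re-reference, epoch, baseline-correct, and screen epochs.

    With ``timelock="stimulus"`` (the ERP control) the baseline may reach
    back into the fixation-cross period, so the lower epoching bound is
    the trial start rather than the snippet onset.
    """
    ledger: list[dict] = []
    rec = eeg_mod.bandpass_notch(
        pdata.eeg,
        cfg.filter.low_hz,
        cfg.filter.high_hz,
        cfg.filter.order,
        cfg.filter.notch_hz,
    )
    rec = eeg_mod.rereference_to_mastoids(rec)
    rate = rec.rate_hz
    start_col = "snippet_on_s" if timelock == "fixation" else "trial_start_s"
    bounds = {
        row.trial_id: (
            int(round(getattr(row, start_col) * rate)),
            int(round(row.snippet_off_s * rate)),
        )
        for row in pdata.trials.itertuples()
    }
    epochs: list[Epoch] = []
    for tid, sample, cond in events:
        t0, t1 = bounds[tid]
        out = eeg_mod.extract_epoch(
            rec, sample, t0, t1, cfg.epoch.window_ms, trial_id=tid, condition=cond
        )
        if isinstance(out, str):
            ledger.append({"trial_id": tid, "stage": "epoching", "reason": out})
            continue
        out = eeg_mod.baseline_correct(out, cfg.epoch.baseline_ms)
        out = eeg_mod.detect_artifacts(out, cfg.artifact)
        if out.verdict == "rejected":
            ledger.append(
                {
                    "trial_id": tid,
                    "stage": "artifact_rejection",
                    "reason": "+".join(out.reasons),
                }
            )
        epochs.append(out)
    return epochs, ledger


# --------------------------------------------------------------------------
# full run


@dataclass
class RunReport:
    config: PipelineConfig
    ledger: pd.DataFrame
    cluster_table: pd.DataFrame
    results: dict[str, PermutationResult]
    grand_averages: dict[str, ParticipantAverage]
    diffs: DifferenceWaveSet
    participants_used: tuple[object, ...]
    trials_in: int
    trials_used: int

    @property
    def trials_excluded(self) -> int:
        return int(len(self.ledger))


def _downsample_diffs(
    diffs: DifferenceWaveSet, rate_hz: float, target_hz: float
) -> DifferenceWaveSet:
    binned, t = eeg_mod.downsample_average(diffs.data, diffs.times_ms, rate_hz, target_hz)
    return DifferenceWaveSet(diffs.participants, diffs.channels, t, binned)


def run_pipeline(
    cfg: PipelineConfig, out_dir: str | Path | None = None
) -> RunReport:
    """Run the complete analysis on a synthetic study defined by ``cfg``.

    Deterministic given the configuration (which embeds the seed).
    """
    bundle: StudyBundle = generate_study(
        cfg.design,
        cfg.effect,
        cfg.gaze_noise,
        cfg.seed,
        noise_sd_uv=cfg.generator.noise_sd_uv,
        artifact_rate=cfg.generator.artifact_rate,
        bad_gaze_rate=cfg.generator.bad_gaze_rate,
    )
    ledger_rows: list[dict] = []
    all_avgs: list[ParticipantAverage] = []
    diff_stack = []
    used_participants = []
    channels = None
    times = None
    trials_in = 0
    accepted_total = 0
    log_events: list[dict] = []

    for pdata in bundle.iter_participants():
        trials_in += len(pdata.trials)
        events, _seqs, gaze_ledger = process_gaze_participant(
            pdata, bundle.layouts, cfg
        )
        epochs, eeg_ledger = process_eeg_participant(pdata, events, cfg)
        for row in gaze_ledger + eeg_ledger:
            row["participant"] = pdata.participant
            ledger_rows.append(row)
        accepted = [e for e in epochs if e.verdict == "accepted"]
        accepted_total += len(accepted)
        log_events.append(
            {
                "stage": "participant",
                "participant": pdata.participant,
                "trials": int(len(pdata.trials)),
                "events": len(events),
                "accepted_epochs": len(accepted),
            }
        )
        try:
            avgs, _, diff1 = eeg_mod.average_frps({pdata.participant: accepted})
        except ValueError:
            log_events.append(
                {
                    "stage": "participant_dropped",
                    "participant": pdata.participant,
                    "reason": "empty_condition_cell",
                }
            )
            continue
        all_avgs.extend(avgs)
        diff_stack.append(diff1.data[0])
        used_participants.append(pdata.participant)
        channels = diff1.channels
        times = diff1.times_ms

    if not used_participants:
        raise RuntimeError("pipeline failed: no usable participants")
    diffs = DifferenceWaveSet(
        tuple(used_participants), channels, times, np.stack(diff_stack)
    )
    diffs_ds = _downsample_diffs(diffs, cfg.design.eeg_rate_hz, cfg.analysis.downsample_hz)
    adjacency = load_default_adjacency(set(cfg.analysis.excluded_electrodes))

    results = {}
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7701]))
    for direction in ("greater", "less"):
        results[direction] = cluster_permutation_test(
            diffs_ds,
            adjacency,
            direction=direction,
            alpha=cfg.analysis.alpha,
            window_ms=cfg.analysis.window_ms,
            min_size=cfg.analysis.min_cluster_size,
            max_exhaustive=cfg.analysis.max_exhaustive,
            n_monte_carlo=cfg.analysis.n_monte_carlo,
            seed=int(rng.integers(2**31)),
        )
    cluster_table = summarize_clusters([results["greater"], results["less"]])

    grand: dict[str, ParticipantAverage] = {}
    for cond in ("confusing", "clean"):
        stack = np.stack([a.data for a in all_avgs if a.condition == cond])
        grand[cond] = ParticipantAverage(
            "grand", cond, channels, times, stack.mean(axis=0), stack.shape[0]
        )

    ledger = pd.DataFrame(
        ledger_rows, columns=["participant", "trial_id", "stage", "reason"]
    )
    report = RunReport(
        config=cfg,
        ledger=ledger,
        cluster_table=cluster_table,
        results=results,
        grand_averages=grand,
        diffs=diffs_ds,
        participants_used=tuple(used_participants),
        trials_in=trials_in,
        trials_used=accepted_total,
    )
    if out_dir is not None:
        _write_outputs(report, Path(out_dir), log_events)
    return report


def _topography_table(diffs: DifferenceWaveSet, bin_ms: float = 50.0,
                      span_ms: tuple[float, float] = (400.0, 700.0)) -> pd.DataFrame:
    """Mean difference per channel in consecutive time bins (figure data)."""
    rows = []
    lo = span_ms[0]
    while lo < span_ms[1]:
        hi = lo + bin_ms
        sel = (diffs.times_ms >= lo) & (diffs.times_ms < hi)
        if sel.any():
            means = diffs.data[:, :, sel].mean(axis=(0, 2))
            for ch, v in zip(diffs.channels, means):
                rows.append({"bin_start_ms": lo, "bin_end_ms": hi, "channel": ch,
                             "mean_diff_uv": float(v)})
        lo = hi
    return pd.DataFrame(rows)


def _write_outputs(report: RunReport, out: Path, log_events: list[dict]) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "averages").mkdir(exist_ok=True)
    report.ledger.to_csv(out / "ledger.tsv", sep="\t", index=False)
    report.cluster_table.to_csv(
        out / "clusters.tsv", sep="\t", index=False, float_format="%.6g"
    )
    for cond, avg in report.grand_averages.items():
        df = pd.DataFrame(avg.data.T, columns=list(avg.channels))
        df.insert(0, "time_ms", avg.times_ms)
        df.to_csv(out / "averages" / f"grand_{cond}.tsv", sep="\t", index=False,
                  float_format="%.6g")
    diff_df = pd.DataFrame(
        report.diffs.data.mean(axis=0).T, columns=list(report.diffs.channels)
    )
    diff_df.insert(0, "time_ms", report.diffs.times_ms)
    diff_df.to_csv(out / "averages" / "grand_difference.tsv", sep="\t", index=False,
                   float_format="%.6g")
    _topography_table(report.diffs).to_csv(
        out / "averages" / "difference_topography_50ms.tsv", sep="\t", index=False,
        float_format="%.6g"
    )

    lines = [
        "Cluster-based permutation test report",
        f"participants used: {len(report.participants_used)}",
        f"trials in: {report.trials_in}; excluded: {report.trials_excluded}; "
        f"accepted epochs: {report.trials_used}",
        "",
    ]
    for direction, res in report.results.items():
        lines.append(
            f"direction {direction}: {res.mode}, {res.n_permutations} permutations, "
            f"threshold t = {res.threshold_t:.4f} (df = {res.df})"
        )
        if not res.clusters:
            lines.append("  no clusters")
        for c in res.clusters:
            flag = " *" if c.p_value < res.alpha else ""
            lines.append(
                f"  cluster {c.tmin_ms:.0f}-{c.tmax_ms:.0f} ms, "
                f"{len(c.electrodes)} electrodes, mass {c.mass:.2f}, "
                f"p = {c.p_value:.4f}{flag}"
            )
        lines.append("")
    (out / "report.txt").write_text("\n".join(lines))

    header = {
        "stage": "run",
        "package_version": __version__,
        "seed": report.config.seed,
        "config_hash": report.config.content_hash(),
        "config": report.config.to_dict(),
    }
    with open(out / "log.jsonl", "w") as fh:
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        for ev in log_events:
            fh.write(json.dumps(ev, sort_keys=True) + "\n")
        fh.write(
            json.dumps(
                {
                    "stage": "summary",
                    "trials_in": report.trials_in,
                    "trials_excluded": report.trials_excluded,
                    "accepted_epochs": report.trials_used,
                    "participants_used": len(report.participants_used),
                },
                sort_keys=True,
            )
            + "\n"
        )
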