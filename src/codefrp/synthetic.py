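"""Synthetic co-registered gaze + EEG studies with known ground truth.

Emulates the recording setup of a two-condition (confusing vs. clean code)
reading experiment: 24 participants, three blocks of 24 trials, gaze
sampled at 1200 Hz, 34-channel EEG at 500 Hz referenced to the left
mastoid. A configurable frontal positivity is injected into the EEG of
one condition, time-locked to the first fixation inside each trial's area
of interest, so that the downstream pipeline can be validated by
parameter recovery rather than against irreproducible recordings.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from . import design as design_mod
from .containers import (
    EEGRecording,
    GazeStream,
    LineBox,
    Rect,
    StimulusLayout,
)
from .montage import (
    ALL_CHANNELS,
    SCALP_CHANNELS,
    frontal_topography,
    occipital_topography,
)

__all__ = [
    "DesignSpec",
    "EffectSpec",
    "GazeNoiseSpec",
    "TruthFixation",
    "SyntheticTruth",
    "ParticipantData",
    "StudyBundle",
    "generate_layout",
    "generate_gaze",
    "generate_eeg",
    "generate_study",
    "pink_noise",
]


# --------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class DesignSpec:
    """Study geometry: participants, blocks, trials, rates, durations."""

    n_participants: int = 24
    n_blocks: int = 3
    trials_per_block: int = 24
    n_pairs: int = 72
    fixation_cross_s: float = 5.0
    snippet_min_s: float = 3.0
    snippet_max_s: float = 30.0
    et_rate_hz: float = 1200.0
    eeg_rate_hz: float = 500.0
    n_atoms: int = 9

    def __post_init__(self) -> None:
        if self.trials_per_block * self.n_blocks != self.n_pairs:
            raise ValueError("trials_per_block * n_blocks must equal n_pairs")
        if self.snippet_min_s > self.snippet_max_s:
            raise ValueError("snippet_min_s must not exceed snippet_max_s")
        if min(self.n_participants, self.n_blocks, self.trials_per_block) < 1:
            raise ValueError("counts must be positive")

    @property
    def trials_per_participant(self) -> int:
        return self.n_blocks * self.trials_per_block


@dataclass(frozen=True)
class EffectSpec:
    """The injected condition effect: a boxcar positivity.

    window_ms is relative to fixation onset; topography maps channel names
    to weights in [0, 1] (defaults to a frontal Gaussian peaking at Fz);
    amplitude_uv is the amplitude at the maximally weighted channel.
    """

    window_ms: tuple[float, float] = (390.0, 660.0)
    topography: dict[str, float] | None = None
    amplitude_uv: float = 2.0
    condition: str = "confusing"
    epoch_bounds_ms: tuple[float, float] = (-300.0, 1000.0)

    def __post_init__(self) -> None:
        lo, hi = self.window_ms
        if not (self.epoch_bounds_ms[0] <= lo < hi <= self.epoch_bounds_ms[1]):
            raise ValueError("effect window must lie within the epoch bounds")
        for ch in self.resolved_topography():
            if ch not in ALL_CHANNELS:
                raise ValueError(f"unknown channel in topography: {ch!r}")

    def resolved_topography(self) -> dict[str, float]:
        return frontal_topography() if self.topography is None else self.topography


@dataclass(frozen=True)
class GazeNoiseSpec:
    """Gaze degradation: jitter, drift, offset, and tracking loss."""

    jitter_sd_px: float = 5.0
    y_drift_lines: float = 0.5
    x_offset_px: float = 0.0
    missing_fraction: float = 0.05
    missing_gap_ms: float = 300.0

    def __post_init__(self) -> None:
        if min(self.jitter_sd_px, self.y_drift_lines, self.missing_gap_ms) < 0:
            raise ValueError("noise magnitudes must be non-negative")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class TruthFixation:
    onset_ms: float
    duration_ms: float
    x: float
    y: float
    line_index: int
    in_aoi: bool

    @property
    def offset_ms(self) -> float:
        return self.onset_ms + self.duration_ms


@dataclass
class SyntheticTruth:
    """Ground truth for one participant's trials."""

    fixations: dict[str, tuple[TruthFixation, ...]] = field(default_factory=dict)
    first_aoi: dict[str, TruthFixation | None] = field(default_factory=dict)
    effect_trials: dict[str, bool] = field(default_factory=dict)
    artifact_trials: set[str] = field(default_factory=set)
    bad_gaze_trials: set[str] = field(default_factory=set)

    def merge(self, other: "SyntheticTruth") -> None:
        self.fixations.update(other.fixations)
        self.first_aoi.update(other.first_aoi)
        self.effect_trials.update(other.effect_trials)
        self.artifact_trials |= other.artifact_trials
        self.bad_gaze_trials |= other.bad_gaze_trials


# --------------------------------------------------------------------------
# layout


def generate_layout(
    n_lines: int,
    line_height_px: float = 40.0,
    informative_pattern: list[bool] | None = None,
    seed: int = 0,
    snippet_id: str = "snippet",
    screen: tuple[int, int] = (1920, 1080),
) -> StimulusLayout:
    """Random code-like layout: stacked line boxes with one AOI.

    The AOI is the central third of a randomly chosen informative line, so
    the line's centre always falls inside it. Line boxes occupy 80% of the
    line pitch, leaving interline gaps.
    """
    if n_lines < 2:
        raise ValueError("a snippet needs at least 2 lines")
    if informative_pattern is None:
        informative_pattern = [True] * n_lines
    if len(informative_pattern) != n_lines:
        raise ValueError("informative_pattern length must equal n_lines")
    if not any(informative_pattern):
        raise ValueError(
            "all lines uninformative: the AOI needs an informative line to sit on"
        )
    rng = np.random.default_rng(seed)
    x0 = 300.0
    y_top = 200.0
    boxes = []
    for i, informative in enumerate(informative_pattern):
        width = float(rng.uniform(300, 900)) if informative else float(rng.uniform(60, 120))
        y0 = y_top + i * line_height_px
        boxes.append(
            LineBox(x0, y0, x0 + width, y0 + 0.8 * line_height_px, bool(informative))
        )
    informative_idx = [i for i, f in enumerate(informative_pattern) if f]
    aoi_line = int(rng.choice(informative_idx))
    box = boxes[aoi_line]
    third = (box.x1 - box.x0) / 3
    aoi = Rect(box.x0 + third, box.y0, box.x1 - third, box.y1)
    return StimulusLayout(
        snippet_id=snippet_id, lines=tuple(boxes), aoi=aoi, screen=screen
    )


# --------------------------------------------------------------------------
# gaze


def generate_gaze(
    layout: StimulusLayout,
    scanpath: list[tuple[int, float]],
    noise: GazeNoiseSpec,
    duration_ms: float | None = None,
    seed: int = 0,
    rate_hz: float = 1200.0,
    trial_id: str = "trial",
) -> tuple[GazeStream, tuple[TruthFixation, ...]]:
    """Render a planned scanpath into a noisy gaze stream.

    scanpath is a list of (line index, dwell ms) fixations; each fixation
    targets the centre of its line box. Jitter is white Gaussian scatter,
    vertical drift grows linearly over the trial, the x offset is constant,
    and tracking losses are inserted as NaN gaps until the requested
    missing fraction is reached (at least). The returned truth records the
    planned fixations with their empirical (jittered) centroids.
    """
    if not scanpath:
        raise ValueError("scanpath must contain at least one fixation")
    for line, dwell in scanpath:
        if not 0 <= line < len(layout.lines):
            raise ValueError(f"scanpath references nonexistent line {line}")
        if dwell < 100:
            raise ValueError("dwell times must be at least 100 ms")
    total_ms = sum(d for _, d in scanpath)
    if duration_ms is None:
        duration_ms = total_ms
    if duration_ms < total_ms:
        raise ValueError("duration must cover the scanpath")
    # stretch the last dwell to fill the trial
    scanpath = list(scanpath)
    line, dwell = scanpath[-1]
    scanpath[-1] = (line, dwell + (duration_ms - total_ms))

    rng = np.random.default_rng(seed)
    n_per = [int(round(d * rate_hz / 1000.0)) for _, d in scanpath]
    n = sum(n_per)
    t_ms = np.arange(n) * (1000.0 / rate_hz)
    x = np.empty(n)
    y = np.empty(n)
    line_of_sample = np.empty(n, dtype=int)
    start = 0
    bounds = []
    for (line, _), k in zip(scanpath, n_per):
        cx, cy = layout.lines[line].center
        x[start : start + k] = cx
        y[start : start + k] = cy
        line_of_sample[start : start + k] = line
        bounds.append((start, start + k))
        start += k

    if noise.jitter_sd_px > 0:
        x += rng.normal(0, noise.jitter_sd_px, n)
        y += rng.normal(0, noise.jitter_sd_px, n)
    drift = noise.y_drift_lines * layout.line_height * (np.arange(n) / max(n - 1, 1))
    y += drift
    x += noise.x_offset_px

    valid = np.ones(n, dtype=bool)
    if noise.missing_fraction > 0:
        target = int(np.ceil(noise.missing_fraction * n))
        gap_max = max(1, int(noise.missing_gap_ms * rate_hz / 1000.0))
        guard = 0
        while valid.sum() > n - target and guard < 10_000:
            g0 = int(rng.integers(0, n))
            glen = int(rng.integers(1, gap_max + 1))
            valid[g0 : g0 + glen] = False
            guard += 1
    x[~valid] = np.nan
    y[~valid] = np.nan

    truth = []
    for (line, _), (i0, i1) in zip(scanpath, bounds):
        seg_valid = valid[i0:i1]
        if seg_valid.any():
            cx = float(np.mean(x[i0:i1][seg_valid]))
            cy = float(np.mean(y[i0:i1][seg_valid]))
        else:
            cx, cy = layout.lines[line].center
        tx, ty = layout.lines[line].center
        truth.append(
            TruthFixation(
                onset_ms=float(t_ms[i0]),
                duration_ms=(i1 - i0) * 1000.0 / rate_hz,
                x=cx,
                y=cy,
                line_index=line,
                in_aoi=layout.aoi.contains(tx, ty),
            )
        )
    stream = GazeStream(
        trial_id=trial_id, t_ms=t_ms, x_px=x, y_px=y, valid=valid, rate_hz=rate_hz
    )
    return stream, tuple(truth)


# --------------------------------------------------------------------------
# EEG


def pink_noise(n_samples: int, rate_hz: float, sd: float, rng: np.random.Generator,
               f_floor_hz: float = 0.1, n_channels: int | None = None) -> np.ndarray:
    """1/f-shaped Gaussian noise, scaled to the requested SD per channel.

    Spectral shaping by 1/sqrt(f) with the power flattened below
    ``f_floor_hz`` (keeps the variance finite; the analysis high-pass sits
    below that anyway). Returns (n_samples,) or (n_channels, n_samples).
    """
    from scipy.fft import irfft, next_fast_len

    squeeze = n_channels is None
    nc = 1 if squeeze else n_channels
    n_fft = next_fast_len(n_samples, real=True)  # pad to an FFT-friendly size
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate_hz)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = 1.0 / np.sqrt(np.maximum(freqs[nz], f_floor_hz))
    spectrum = shape[None, :] * (
        rng.normal(size=(nc, freqs.size)) + 1j * rng.normal(size=(nc, freqs.size))
    )
    sig = irfft(spectrum, n=n_fft, axis=-1)[..., :n_samples]
    s = sig.std(axis=-1, keepdims=True)
    sig = np.where(s > 0, sig * (sd / np.where(s > 0, s, 1.0)), sig)
    return sig[0] if squeeze else sig


def generate_eeg(
    design: DesignSpec,
    events: list[tuple[str, int, str]],
    effect: EffectSpec,
    noise_sd_uv: float = 10.0,
    seed: int = 0,
    n_samples: int | None = None,
    lambda_uv: float = 5.0,
    alpha_uv: float = 0.0,
    alpha_hz: float = 10.0,
    extra_events: list[tuple[str, int]] | None = None,
) -> EEGRecording:
    """Continuous EEG: pink noise + fixation-locked responses.

    events are (trial_id, fixation-onset sample, condition). Every event
    receives an occipitally weighted early (lambda-like) deflection; events
    of the effect condition additionally receive the boxcar positivity of
    ``effect``. ``noise_sd_uv`` is the background-noise SD of the recorded
    channels: the recording is referenced to the left mastoid, whose own
    trace is therefore zero, and every other channel (including the right
    mastoid and the EOG) carries independent noise of that SD.
    """
    rate = design.eeg_rate_hz
    if n_samples is None:
        last = max((s for _, s, _ in events), default=0)
        n_samples = last + int(1.5 * rate)
    for tid, s, _ in events:
        if not 0 <= s < n_samples:
            raise ValueError(f"event for trial {tid!r} at sample {s} outside recording")

    rng = np.random.default_rng(seed)
    n_ch = len(ALL_CHANNELS)
    data = pink_noise(n_samples, rate, noise_sd_uv, rng, n_channels=n_ch)
    if alpha_uv > 0:
        t = np.arange(n_samples) / rate
        phase = rng.uniform(0, 2 * np.pi, n_ch)
        data += alpha_uv * np.sin(2 * np.pi * alpha_hz * t[None, :] + phase[:, None])

    scalp_idx = {ch: ALL_CHANNELS.index(ch) for ch in SCALP_CHANNELS}
    occ = occipital_topography()
    topo = effect.resolved_topography()

    # early fixation-locked deflection (lambda-like), all events
    if lambda_uv != 0:
        peak_s, sd_s = 0.110, 0.035
        k = np.arange(int(-0.05 * rate), int(0.30 * rate))
        bump = lambda_uv * np.exp(-0.5 * ((k / rate - peak_s) / sd_s) ** 2)
        for _, s, _ in events:
            sl = slice(max(s + k[0], 0), min(s + k[-1] + 1, n_samples))
            seg = bump[(sl.start - (s + k[0])) : (sl.start - (s + k[0])) + (sl.stop - sl.start)]
            for ch, i in scalp_idx.items():
                data[i, sl] += occ.get(ch, 0.0) * seg

    # condition effect: boxcar positivity inside the window
    if effect.amplitude_uv != 0:
        w0 = int(round(effect.window_ms[0] * rate / 1000.0))
        w1 = int(round(effect.window_ms[1] * rate / 1000.0))
        for _, s, cond in events:
            if cond != effect.condition:
                continue
            sl = slice(max(s + w0, 0), min(s + w1 + 1, n_samples))
            for ch, w in topo.items():
                if ch in scalp_idx and w != 0:
                    data[scalp_idx[ch], sl] += effect.amplitude_uv * w

    # the left mastoid is the online reference: its recorded trace is zero
    data[ALL_CHANNELS.index("M1")] = 0.0

    ev = [(f"fix/{tid}/{cond}", s) for tid, s, cond in events]
    if extra_events:
        ev.extend(extra_events)
    ev.sort(key=lambda e: (e[1], e[0]))
    return EEGRecording(
        channels=ALL_CHANNELS,
        rate_hz=rate,
        data=data,
        events=tuple(ev),
        reference="left_mastoid",
    )


# --------------------------------------------------------------------------
# whole study


@dataclass
class ParticipantData:
    participant: int
    trials: pd.DataFrame  # trial_id, block, trial_in_block, pair_id, atom,
    # condition, snippet_id, trial_start_s, snippet_on_s, snippet_off_s
    gaze: dict[str, GazeStream]
    eeg: EEGRecording
    truth: SyntheticTruth


def _reading_scanpath(
    layout: StimulusLayout, duration_ms: float, rng: np.random.Generator
) -> list[tuple[int, float]]:
    """Roughly top-to-bottom reading with regressions, visiting the AOI line.

    Dwells are 250-550 ms. The forward pass runs through the informative
    lines (readers skip brace-only lines, which carry no content - the
    very behaviour motivating the informative-only correction variants);
    uninformative lines receive only rare stray glances. If time remains,
    random informative revisits are appended. The pass is truncated if
    the trial is too short, but an AOI-line visit is always kept.
    """
    informative = [i for i, ln in enumerate(layout.lines) if ln.informative]
    aoi_cx = (layout.aoi.x0 + layout.aoi.x1) / 2
    aoi_cy = (layout.aoi.y0 + layout.aoi.y1) / 2
    aoi_line = next(
        i for i, ln in enumerate(layout.lines) if ln.contains(aoi_cx, aoi_cy)
    )
    path: list[int] = []
    for i in informative:
        path.append(i)
        if len(path) > 2 and rng.random() < 0.15:  # occasional regression
            prev = [j for j in informative if j < i]
            cand = int(rng.choice(prev))
            if cand != path[-1]:
                path.append(cand)
    if aoi_line not in path:
        path.append(aoi_line)
    dwells = rng.uniform(250, 550, size=len(path))
    # truncate to the trial duration, preserving an AOI visit if possible
    out: list[tuple[int, float]] = []
    used = 0.0
    for line, dwell in zip(path, dwells):
        if used + dwell > duration_ms:
            break
        out.append((int(line), float(dwell)))
        used += dwell
    if not any(line == aoi_line for line, _ in out):
        if len(out) >= 2:
            out[len(out) // 2] = (aoi_line, out[len(out) // 2][1])
        else:
            out = [(aoi_line, min(400.0, duration_ms))]
    while used + 350 <= duration_ms and len(out) < 200:
        if rng.random() < 0.05 and len(informative) < len(layout.lines):
            others = [i for i in range(len(layout.lines)) if i not in informative]
            line = int(rng.choice(others))
        else:
            line = int(rng.choice(informative))
        dwell = float(rng.uniform(250, 550))
        if line == out[-1][0] or used + dwell > duration_ms:
            if used + dwell > duration_ms:
                break
            continue
        out.append((line, dwell))
        used += dwell
    return out


@dataclass
class StudyBundle:
    """Lazy study container: trial tables and layouts up front,
    per-participant gaze/EEG generated on demand (a full study's raw data
    does not fit comfortably in memory at once)."""

    design: DesignSpec
    effect: EffectSpec
    noise: GazeNoiseSpec
    seed: int
    layouts: dict[str, StimulusLayout]
    pair_geometry: dict[object, str]  # pair_id -> layout snippet_id prefix
    trial_table: pd.DataFrame
    artifact_rate: float = 0.015
    artifact_amp_uv: float = 120.0
    bad_gaze_rate: float = 0.02
    noise_sd_uv: float = 10.0

    def participants(self) -> list[int]:
        return sorted(int(p) for p in self.trial_table["participant"].unique())

    def iter_participants(self) -> Iterator[ParticipantData]:
        for p in self.participants():
            yield self.participant(p)

    def participant(self, p: int) -> ParticipantData:
        root = np.random.SeedSequence([self.seed, int(p)])
        child = root.spawn(3)
        rng = np.random.default_rng(child[0])
        trials = (
            self.trial_table[self.trial_table["participant"] == p]
            .sort_values(["block", "trial_in_block"])
            .reset_index(drop=True)
        )
        d = self.design
        truth = SyntheticTruth()
        gaze: dict[str, GazeStream] = {}
        rows = []
        events: list[tuple[str, int, str]] = []
        markers: list[tuple[str, int]] = []
        t_cursor = 0.0
        rate = d.eeg_rate_hz
        for row in trials.itertuples():
            tid = row.trial_id
            layout = self.layouts[row.snippet_id]
            duration_ms = float(rng.uniform(d.snippet_min_s, d.snippet_max_s) * 1000.0)
            scanpath = _reading_scanpath(layout, duration_ms, rng)
            bad = rng.random() < self.bad_gaze_rate
            noise = self.noise
            if bad:
                from dataclasses import replace as _replace

                noise = _replace(noise, missing_fraction=0.4, missing_gap_ms=1500.0)
                truth.bad_gaze_trials.add(tid)
            stream, fixes = generate_gaze(
                layout,
                scanpath,
                noise,
                duration_ms=duration_ms,
                seed=int(rng.integers(2**31)),
                rate_hz=d.et_rate_hz,
                trial_id=tid,
            )
            gaze[tid] = stream
            truth.fixations[tid] = fixes
            first_aoi = next((f for f in fixes if f.in_aoi), None)
            truth.first_aoi[tid] = first_aoi
            truth.effect_trials[tid] = row.condition == self.effect.condition

            trial_start_s = t_cursor
            snippet_on_s = trial_start_s + d.fixation_cross_s
            snippet_off_s = snippet_on_s + duration_ms / 1000.0
            t_cursor = snippet_off_s + 0.5  # short inter-trial gap
            markers.append((f"trial_start/{tid}", int(round(trial_start_s * rate))))
            markers.append((f"snippet_on/{tid}", int(round(snippet_on_s * rate))))
            markers.append((f"snippet_off/{tid}", int(round(snippet_off_s * rate))))
            if first_aoi is not None:
                sample = int(round((snippet_on_s + first_aoi.onset_ms / 1000.0) * rate))
                events.append((tid, sample, row.condition))
            rows.append((trial_start_s, snippet_on_s, snippet_off_s))

        n_samples = int(round((t_cursor + 1.0) * rate))
        eeg = generate_eeg(
            d,
            events,
            self.effect,
            noise_sd_uv=self.noise_sd_uv,
            seed=int(np.random.default_rng(child[1]).integers(2**31)),
            n_samples=n_samples,
            extra_events=markers,
        )
        # injected artifacts: a large slow half-sine on one scalp channel
        art_rng = np.random.default_rng(child[2])
        for row, (t0, s_on, s_off) in zip(trials.itertuples(), rows):
            if art_rng.random() < self.artifact_rate:
                tid = row.trial_id
                ch = int(art_rng.integers(0, len(SCALP_CHANNELS)))
                dur = int(0.3 * rate)
                start = int(art_rng.uniform(s_on, max(s_on, s_off - 0.4)) * rate)
                seg = self.artifact_amp_uv * np.sin(np.linspace(0, np.pi, dur))
                stop = min(start + dur, eeg.n_samples)
                eeg.data[ch, start:stop] += seg[: stop - start]
                truth.artifact_trials.add(tid)
        trials = trials.assign(
            trial_start_s=[r[0] for r in rows],
            snippet_on_s=[r[1] for r in rows],
            snippet_off_s=[r[2] for r in rows],
        )
        return ParticipantData(p, trials, gaze, eeg, truth)


def generate_study(
    design: DesignSpec,
    effect: EffectSpec,
    noise: GazeNoiseSpec,
    seed: int,
    noise_sd_uv: float = 10.0,
    artifact_rate: float = 0.015,
    bad_gaze_rate: float = 0.02,
    layout_lines: tuple[int, int] = (6, 12),
    uninformative_line_prob: float = 0.15,
) -> StudyBundle:
    """Assemble a full study: layouts, counterbalancing, orders, timing.

    Gaze and EEG are generated lazily per participant (see StudyBundle).
    Each snippet pair shares one layout geometry; both conditions of a pair
    use the same AOI. Presentation orders satisfy the run-length and
    atom-separation constraints; condition assignment is counterbalanced
    across participants.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 901]))
    pair_ids = list(range(design.n_pairs))
    atoms = [i % design.n_atoms for i in pair_ids]
    pairs_df = pd.DataFrame({"pair_id": pair_ids, "atom": atoms})

    layouts: dict[str, StimulusLayout] = {}
    pair_geometry: dict[object, str] = {}
    for pid in pair_ids:
        n_lines = int(rng.integers(layout_lines[0], layout_lines[1] + 1))
        pattern = [bool(rng.random() >= uninformative_line_prob) for _ in range(n_lines)]
        if not any(pattern):
            pattern[0] = True
        lseed = int(rng.integers(2**31))
        for cond in ("confusing", "clean"):
            sid = f"pair{pid:03d}_{cond}"
            layouts[sid] = generate_layout(
                n_lines,
                informative_pattern=pattern,
                seed=lseed,  # identical geometry for both pair members
                snippet_id=sid,
            )
        pair_geometry[pid] = f"pair{pid:03d}"

    cb = design_mod.counterbalance_conditions(pair_ids, design.n_participants)
    constraints = design_mod.OrderConstraints()
    tables = []
    for p in range(design.n_participants):
        assignment = dict(
            zip(cb[cb.participant == p].pair_id, cb[cb.participant == p].condition)
        )
        order = design_mod.generate_presentation_order(
            pairs_df,
            design.n_blocks,
            design.trials_per_block,
            constraints,
            assignment,
            seed=int(rng.integers(2**31)),
        )
        order = order.assign(
            participant=p,
            trial_id=[
                f"p{p:02d}_b{b}_t{t:02d}"
                for b, t in zip(order["block"], order["trial_in_block"])
            ],
            snippet_id=[
                f"pair{pid:03d}_{cond}"
                for pid, cond in zip(order["pair_id"], order["condition"])
            ],
        )
        tables.append(order)
    trial_table = pd.concat(tables, ignore_index=True)

    return StudyBundle(
        design=design,
        effect=effect,
        noise=noise,
        seed=seed,
        layouts=layouts,
        pair_geometry=pair_geometry,
        trial_table=trial_table,
        artifact_rate=artifact_rate,
        bad_gaze_rate=bad_gaze_rate,
        noise_sd_uv=noise_sd_uv,
    )
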