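"""EEG preprocessing: filtering, re-referencing, epoching, artifact
rejection, FRP averaging, and downsampling.

Filters are zero-phase (forward-backward) order-4 Butterworth band-pass
plus a 50 Hz notch. Epochs are cut from -300 to 1000 ms around fixation
onset, baseline-corrected over [-300, 0) ms, and screened with three
voltage criteria: a maximal step between consecutive samples, a maximal
peak-to-peak range within any 0.2 s window, and a maximal absolute
amplitude after baseline correction. EOG and reference electrodes are
exempt from artifact screening.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .containers import (
    DifferenceWaveSet,
    EEGRecording,
    Epoch,
    ParticipantAverage,
)
from .montage import ARTIFACT_EXEMPT, EOG_CHANNELS, MASTOID_CHANNELS

__all__ = [
    "ArtifactCriteria",
    "bandpass_notch",
    "rereference_to_mastoids",
    "extract_epoch",
    "baseline_correct",
    "detect_artifacts",
    "average_frps",
    "downsample_average",
]


@dataclass(frozen=True)
class ArtifactCriteria:
    """Voltage thresholds marking an epoch as artifactual.

    Rejection on any non-exempt channel when: a consecutive-sample step
    reaches ``max_step_uv``; the peak-to-peak range within any sliding
    ``range_window_s`` window exceeds ``max_range_uv``; or the absolute
    amplitude exceeds ``max_abs_uv`` anywhere.
    """

    max_step_uv: float = 30.0
    max_range_uv: float = 100.0
    range_window_s: float = 0.2
    max_abs_uv: float = 70.0

    def __post_init__(self) -> None:
        if min(self.max_step_uv, self.max_range_uv, self.range_window_s, self.max_abs_uv) <= 0:
            raise ValueError("artifact thresholds must be positive")


def bandpass_notch(
    recording: EEGRecording,
    low_hz: float = 0.05,
    high_hz: float = 30.0,
    order: int = 4,
    notch_hz: float = 50.0,
    notch_q: float = 30.0,
) -> EEGRecording:
    """Zero-phase Butterworth band-pass plus notch on every channel.

    Channels are demeaned first and the forward-backward pass uses
    reflective padding spanning several time constants of the high-pass
    corner; otherwise the slow (1/low_hz-scale) edge transients of a
    0.05 Hz high-pass bleed far into the recording.
    """
    nyq = recording.rate_hz / 2.0
    if high_hz >= nyq or notch_hz >= nyq:
        raise ValueError("cutoff must stay below the Nyquist frequency")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=recording.rate_hz, output="sos")
    n = recording.data.shape[1]
    padlen = min(n - 1, int(round(recording.rate_hz * 0.5 / low_hz)))
    centered = recording.data - recording.data.mean(axis=1, keepdims=True)
    data = signal.sosfiltfilt(sos, centered, axis=1, padlen=padlen)
    b, a = signal.iirnotch(notch_hz, notch_q, fs=recording.rate_hz)
    data = signal.filtfilt(b, a, data, axis=1)
    return replace(recording, data=data)


def rereference_to_mastoids(recording: EEGRecording) -> EEGRecording:
    """Re-express scalp and mastoid channels against the mastoid mean.

    The recording is referenced to the left mastoid, whose own trace is
    implicitly zero; the new reference is (M1 + M2)/2, so each non-EOG
    channel loses half of the recorded right-mastoid signal. EOG channels
    are untouched.
    """
    for m in MASTOID_CHANNELS:
        if m not in recording.channels:
            raise ValueError(f"mastoid channel {m} missing")
    if recording.reference != "left_mastoid":
        raise ValueError(f"expected left_mastoid reference, got {recording.reference!r}")
    new_ref = (recording.get("M1") + recording.get("M2")) / 2.0
    data = recording.data.copy()
    for i, ch in enumerate(recording.channels):
        if ch in EOG_CHANNELS:
            continue
        data[i] = data[i] - new_ref
    return replace(recording, data=data, reference="linked_mastoids")


def extract_epoch(
    recording: EEGRecording,
    event_sample: int,
    trial_start_sample: int,
    trial_end_sample: int,
    window_ms: tuple[float, float] = (-300.0, 1000.0),
    trial_id: str = "trial",
    condition: str = "unknown",
) -> Epoch | str:
    """Cut one fixation-locked epoch, or return an exclusion reason.

    The epoch spans ``window_ms`` inclusive (651 samples at 500 Hz for
    -300..1000 ms). Events too close to the trial start lack a baseline
    (``insufficient_baseline``); events whose tail crosses the trial end
    are excluded as ``epoch_overrun``.
    """
    rate = recording.rate_hz
    pre = int(round(-window_ms[0] * rate / 1000.0))
    post = int(round(window_ms[1] * rate / 1000.0))
    if event_sample - trial_start_sample < pre:
        return "insufficient_baseline"
    if trial_end_sample - event_sample < post:
        return "epoch_overrun"
    if event_sample - pre < 0 or event_sample + post >= recording.n_samples:
        return "recording_bounds"
    data = recording.data[:, event_sample - pre : event_sample + post + 1].copy()
    times = (np.arange(-pre, post + 1)) * 1000.0 / rate
    return Epoch(
        trial_id=trial_id,
        condition=condition,
        channels=recording.channels,
        times_ms=times,
        data=data,
        window_ms=window_ms,
    )


def baseline_correct(
    epoch: Epoch, baseline_window_ms: tuple[float, float] = (-300.0, 0.0)
) -> Epoch:
    """Subtract each channel's mean over [baseline start, 0) from all
    samples."""
    lo, hi = baseline_window_ms
    sel = (epoch.times_ms >= lo) & (epoch.times_ms < hi)
    if not sel.any():
        raise ValueError("baseline window outside epoch")
    base = epoch.data[:, sel].mean(axis=1, keepdims=True)
    return replace(
        epoch, data=epoch.data - base, baseline_window_ms=(float(lo), float(hi))
    )


def detect_artifacts(
    epoch: Epoch,
    criteria: ArtifactCriteria = ArtifactCriteria(),
    exempt_channels: frozenset[str] | set[str] = ARTIFACT_EXEMPT,
    rate_hz: float | None = None,
) -> Epoch:
    """Screen one baseline-corrected epoch against the voltage criteria.

    Returns a copy with verdict "accepted" or "rejected" and per-criterion
    reasons ("step", "range", "abs").
    """
    if rate_hz is None:
        dt = float(np.median(np.diff(epoch.times_ms)))
        rate_hz = 1000.0 / dt
    rows = [i for i, ch in enumerate(epoch.channels) if ch not in exempt_channels]
    data = epoch.data[rows]
    reasons = []
    if data.size:
        if data.shape[1] > 1 and np.abs(np.diff(data, axis=1)).max() >= criteria.max_step_uv:
            reasons.append("step")
        w = int(round(criteria.range_window_s * rate_hz))
        w = min(max(w, 2), data.shape[1])
        # with edge replication every clipped window is a subset of a full
        # one, so the global max over centers equals the max over all full
        # sliding windows
        mx = maximum_filter1d(data, size=w, axis=1, mode="nearest")
        mn = minimum_filter1d(data, size=w, axis=1, mode="nearest")
        if (mx - mn).max() > criteria.max_range_uv:
            reasons.append("range")
        if np.abs(data).max() > criteria.max_abs_uv:
            reasons.append("abs")
    verdict = "rejected" if reasons else "accepted"
    return replace(epoch, verdict=verdict, reasons=tuple(reasons))


def average_frps(
    epochs_by_participant: dict[object, list[Epoch]],
    conditions: tuple[str, str] = ("confusing", "clean"),
) -> tuple[list[ParticipantAverage], dict[str, ParticipantAverage], DifferenceWaveSet]:
    """Average accepted epochs per participant/condition; build grand
    averages and the per-participant (confusing - clean) difference waves.

    Participants missing accepted epochs in either condition are dropped
    with a warning.
    """
    import warnings

    averages: list[ParticipantAverage] = []
    diffs = []
    kept_participants = []
    channels = None
    times = None
    for participant in sorted(epochs_by_participant, key=repr):
        epochs = [e for e in epochs_by_participant[participant] if e.verdict == "accepted"]
        per_cond = {}
        for cond in conditions:
            sel = [e for e in epochs if e.condition == cond]
            if sel:
                per_cond[cond] = (
                    np.mean([e.data for e in sel], axis=0),
                    len(sel),
                    sel[0],
                )
        if len(per_cond) < len(conditions):
            warnings.warn(f"participant {participant!r} dropped: empty condition cell")
            continue
        kept_participants.append(participant)
        for cond in conditions:
            mean, n, ref = per_cond[cond]
            channels = ref.channels
            times = ref.times_ms
            averages.append(
                ParticipantAverage(participant, cond, ref.channels, ref.times_ms, mean, n)
            )
        diffs.append(per_cond[conditions[0]][0] - per_cond[conditions[1]][0])
    if not kept_participants:
        raise ValueError("no participant has accepted epochs in every condition")
    grand = {}
    for cond in conditions:
        stack = np.stack([a.data for a in averages if a.condition == cond])
        grand[cond] = ParticipantAverage(
            "grand", cond, channels, times, stack.mean(axis=0), stack.shape[0]
        )
    diff_set = DifferenceWaveSet(
        participants=tuple(kept_participants),
        channels=channels,
        times_ms=times,
        data=np.stack(diffs),
    )
    return averages, grand, diff_set


def downsample_average(
    data: np.ndarray, times_ms: np.ndarray, rate_hz: float, target_hz: float = 100.0
) -> tuple[np.ndarray, np.ndarray]:
    """Downsample by non-overlapping bin means (..., time) -> (..., bins).

    The source rate must be an integer multiple of the target; a trailing
    partial bin is dropped. Returned time stamps are bin centres.
    """
    ratio = rate_hz / target_hz
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("source rate must be an integer multiple of target rate")
    k = int(round(ratio))
    n = data.shape[-1]
    nbins = n // k
    trimmed = data[..., : nbins * k]
    binned = trimmed.reshape(*data.shape[:-1], nbins, k).mean(axis=-1)
    t = times_ms[: nbins * k].reshape(nbins, k).mean(axis=1)
    return binned, t
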