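"""Gaze processing: QC, fixation detection, line correction, AOI selection.

The stages mirror a reading-study eye-movement pipeline: trials with too
much tracking loss are excluded; fixations are detected with a
noise-robust two-means/change-point scheme (I2MC family); isolated
off-stimulus fixations are removed; vertical drift is corrected by
mapping fixation y-positions onto code-line centres (``cluster`` and
``stretch`` algorithms, each with a variant that ignores uninformative
lines such as lone braces); a constant per-block offset is removed; and
the first fixation inside the trial's area of interest is selected as the
FRP time-lock event.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import PchipInterpolator

from .containers import (
    Fixation,
    FixationSequence,
    GazeStream,
    QCResult,
    Rect,
    StimulusLayout,
)

__all__ = [
    "I2MCParams",
    "assess_trial_quality",
    "detect_fixations",
    "remove_outlier_fixations",
    "correct_fixations",
    "choose_correction",
    "estimate_constant_offset",
    "apply_constant_offset",
    "first_aoi_fixation",
    "CORRECTION_METHODS",
]

CORRECTION_METHODS = ("cluster_informative", "stretch_informative", "cluster", "stretch")


# --------------------------------------------------------------------------
# trial quality


def assess_trial_quality(
    stream: GazeStream,
    max_missing_fraction: float = 0.25,
    max_gap_ms: float = 1000.0,
) -> QCResult:
    """Exclude trials with too much tracking loss.

    A trial is retained iff its overall missing fraction is at most
    ``max_missing_fraction`` and no contiguous invalid interval exceeds
    ``max_gap_ms``.
    """
    if len(stream) == 0:
        raise ValueError("empty gaze stream")
    invalid = ~stream.valid
    missing = float(invalid.mean())
    longest = 0
    run = 0
    for v in invalid:
        run = run + 1 if v else 0
        longest = max(longest, run)
    longest_ms = longest * 1000.0 / stream.rate_hz
    reasons = []
    if missing > max_missing_fraction:
        reasons.append("missing_fraction")
    if longest_ms > max_gap_ms:
        reasons.append("long_gap")
    return QCResult(
        retained=not reasons,
        missing_fraction=missing,
        longest_gap_ms=longest_ms,
        reasons=tuple(reasons),
    )


# --------------------------------------------------------------------------
# fixation detection


@dataclass(frozen=True)
class I2MCParams:
    """Detection settings (published I2MC defaults where applicable)."""

    window_ms: float = 200.0
    step_ms: float = 20.0
    cutoff_sd: float = 2.0
    merge_gap_ms: float = 30.0
    merge_dist_deg: float = 0.7
    px_per_deg: float = 40.0
    min_fix_ms: float = 200.0
    interp_max_gap_ms: float = 100.0
    min_split_improvement: float = 0.25


def _interpolate_gaps(stream: GazeStream, max_gap_ms: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fill short invalid gaps by monotone cubic interpolation.

    Returns (x, y, usable); gaps longer than the limit, and gaps touching
    the stream edges, stay unusable.
    """
    x = stream.x_px.copy()
    y = stream.y_px.copy()
    usable = stream.valid.copy()
    n = len(stream)
    max_gap = int(max_gap_ms * stream.rate_hz / 1000.0)
    if usable.sum() < 4 or usable.all():
        return x, y, usable
    vi = np.flatnonzero(stream.valid)
    fx = PchipInterpolator(vi, x[vi])
    fy = PchipInterpolator(vi, y[vi])
    i = 0
    while i < n:
        if not usable[i]:
            j = i
            while j < n and not usable[j]:
                j += 1
            if i > 0 and j < n and (j - i) <= max_gap:
                idx = np.arange(i, j)
                x[idx] = fx(idx)
                y[idx] = fy(idx)
                usable[idx] = True
            i = j
        else:
            i += 1
    return x, y, usable


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, stop) runs of True."""
    out = []
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def _transition_weights(
    x: np.ndarray,
    y: np.ndarray,
    usable: np.ndarray,
    window: int,
    step: int,
    min_improvement: float,
) -> np.ndarray:
    """Per-sample saccade evidence from windowed two-means change points.

    Every window of ``window`` samples inside a usable run is split at the
    temporal change point minimising the two-segment sum of squares (the
    contiguous two-means solution). A window votes for its change point
    only when the split explains at least ``min_improvement`` of the
    window's total variance, so structureless (pure-jitter) windows
    abstain. Votes are normalised by window coverage.
    """
    n = len(usable)
    count = np.zeros(n)
    coverage = np.zeros(n)
    for r0, r1 in _runs(usable):
        m = r1 - r0
        if m < window:
            continue
        starts = np.arange(r0, r1 - window + 1, step)
        if starts[-1] != r1 - window:
            starts = np.append(starts, r1 - window)
        idx = starts[:, None] + np.arange(window)[None, :]
        Z = np.stack([x[idx], y[idx]], axis=-1)  # (nw, L, 2)
        c1 = np.cumsum(Z, axis=1)
        c2 = np.cumsum(Z * Z, axis=1)
        sizes = np.arange(1, window, dtype=float)
        pre1, pre2 = c1[:, :-1, :], c2[:, :-1, :]
        tot1, tot2 = c1[:, -1:, :], c2[:, -1:, :]
        sse_pre = (pre2 - pre1**2 / sizes[None, :, None]).sum(-1)
        suf1 = tot1 - pre1
        suf2 = tot2 - pre2
        sse_suf = (suf2 - suf1**2 / (window - sizes)[None, :, None]).sum(-1)
        cost = sse_pre + sse_suf
        sse_tot = (tot2[:, 0, :] - tot1[:, 0, :] ** 2 / window).sum(-1)
        best = np.argmin(cost, axis=1)
        improvement = sse_tot - cost[np.arange(len(best)), best]
        vote = improvement > min_improvement * np.maximum(sse_tot, 1e-12)
        np.add.at(count, starts[vote] + best[vote] + 1, 1.0)
        np.add.at(coverage, idx.ravel(), 1.0)
    weights = np.zeros(n)
    nz = coverage > 0
    weights[nz] = count[nz] / coverage[nz]
    return weights


def detect_fixations(
    stream: GazeStream, params: I2MCParams = I2MCParams()
) -> FixationSequence:
    """Detect fixations in one trial's gaze stream.

    Short invalid gaps are interpolated; transition weights are computed
    over sliding windows; samples whose weight exceeds mean + k*SD are
    saccade samples; the remaining usable runs become fixation candidates,
    which are merged when closer than the merge gap/distance and finally
    filtered at the minimum duration. Centroids are means of member
    samples.
    """
    if len(stream) == 0 or not stream.valid.any():
        return FixationSequence(stream.trial_id, (), all_invalid=True)
    rate = stream.rate_hz
    x, y, usable = _interpolate_gaps(stream, params.interp_max_gap_ms)
    window = max(4, int(round(params.window_ms * rate / 1000.0)))
    step = max(1, int(round(params.step_ms * rate / 1000.0)))
    weights = _transition_weights(
        x, y, usable, window, step, params.min_split_improvement
    )
    scored = usable.copy()
    mu = weights[scored].mean()
    sd = weights[scored].std()
    cutoff = mu + params.cutoff_sd * sd
    candidate = usable & ~(weights > cutoff)

    segs = _runs(candidate)
    # merge nearby candidates
    merged: list[tuple[int, int]] = []
    max_dist = params.merge_dist_deg * params.px_per_deg
    for seg in segs:
        if not merged:
            merged.append(seg)
            continue
        p0, p1 = merged[-1]
        gap_ms = (seg[0] - p1) * 1000.0 / rate
        cx_a, cy_a = np.nanmean(x[p0:p1]), np.nanmean(y[p0:p1])
        cx_b, cy_b = np.nanmean(x[seg[0] : seg[1]]), np.nanmean(y[seg[0] : seg[1]])
        if gap_ms < params.merge_gap_ms and np.hypot(cx_a - cx_b, cy_a - cy_b) < max_dist:
            merged[-1] = (p0, seg[1])
        else:
            merged.append(seg)

    fixations = []
    for i0, i1 in merged:
        duration = (i1 - i0) * 1000.0 / rate
        if duration < params.min_fix_ms:
            continue
        sel = usable[i0:i1]
        fixations.append(
            Fixation(
                onset_ms=float(stream.t_ms[i0]),
                offset_ms=float(stream.t_ms[i0]) + duration,
                x=float(np.mean(x[i0:i1][sel])),
                y=float(np.mean(y[i0:i1][sel])),
            )
        )
    return FixationSequence(stream.trial_id, tuple(fixations))


# --------------------------------------------------------------------------
# outlier removal


def remove_outlier_fixations(
    seq: FixationSequence, layout: StimulusLayout, k_line_heights: float = 2.0
) -> tuple[FixationSequence, int]:
    """Drop fixations whose vertical distance to the nearest line box
    exceeds ``k_line_heights`` line heights (cannot be associated with any
    code line)."""
    limit = k_line_heights * layout.line_height
    kept = []
    removed = 0
    for f in seq:
        dists = [
            0.0 if ln.y0 <= f.y <= ln.y1 else min(abs(f.y - ln.y0), abs(f.y - ln.y1))
            for ln in layout.lines
        ]
        if min(dists) > limit:
            removed += 1
        else:
            kept.append(f)
    return seq.with_fixations(kept), removed


# --------------------------------------------------------------------------
# line-assignment correction


def _kmeans_1d(values: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Optimal 1-D k-means by dynamic programming.

    In one dimension the optimal clusters are contiguous intervals of the
    sorted values, so the global optimum is found exactly (no
    initialisation sensitivity). Returns (labels, cluster means); empty
    clusters cannot occur for k <= n.
    """
    order = np.argsort(values, kind="stable")
    v = values[order]
    n = len(v)
    k = min(k, n)
    c1 = np.concatenate([[0.0], np.cumsum(v)])
    c2 = np.concatenate([[0.0], np.cumsum(v * v)])

    def sse(a: int, b: int) -> float:  # segment [a, b)
        s = c1[b] - c1[a]
        return float(c2[b] - c2[a] - s * s / (b - a))

    INF = np.inf
    cost = np.full((k + 1, n + 1), INF)
    split = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for j in range(1, k + 1):
        for i in range(j, n + 1):
            best, arg = INF, j - 1
            for a in range(j - 1, i):
                c = cost[j - 1, a] + sse(a, i)
                if c < best - 1e-12:
                    best, arg = c, a
            cost[j, i] = best
            split[j, i] = arg
    # recover segment boundaries
    bounds = [n]
    i = n
    for j in range(k, 0, -1):
        i = split[j, i]
        bounds.append(i)
    bounds = bounds[::-1]
    labels_sorted = np.empty(n, dtype=int)
    centers = np.empty(k)
    for j in range(k):
        a, b = bounds[j], bounds[j + 1]
        labels_sorted[a:b] = j
        centers[j] = v[a:b].mean()
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels, centers


def _assign(
    seq: FixationSequence,
    layout: StimulusLayout,
    method: str,
    informative_only: bool,
) -> FixationSequence:
    candidates = layout.candidate_line_indices(informative_only)
    if not candidates:
        raise ValueError("no informative lines to correct against")
    centers = np.array([layout.lines[i].center[1] for i in candidates])
    ys = np.array([f.y for f in seq])
    if len(ys) == 0:
        return replace(seq, correction_method=method + ("_informative" if informative_only else ""))

    if method == "cluster":
        k = min(len(candidates), len(ys))
        labels, cluster_centers = _kmeans_1d(ys, k)
        cluster_line = np.argmin(
            np.abs(cluster_centers[:, None] - centers[None, :]), axis=1
        )
        line_idx = [candidates[cluster_line[l]] for l in labels]
    elif method == "stretch":
        span = 2.0 * layout.line_height

        def grid_best(scales: np.ndarray, offsets: np.ndarray) -> tuple[float, float, float]:
            # cost(s, o) = sum_i min_l |s*y_i + o - c_l|, fully broadcast
            t = scales[:, None, None] * ys[None, None, :] + offsets[None, :, None]
            cost = np.abs(t[..., None] - centers[None, None, None, :]).min(-1).sum(-1)
            i, j = np.unravel_index(int(np.argmin(cost)), cost.shape)
            return float(cost[i, j]), float(scales[i]), float(offsets[j])

        c0, s0, o0 = grid_best(np.linspace(0.9, 1.1, 21), np.linspace(-span, span, 41))
        c1, s1, o1 = grid_best(
            np.linspace(s0 - 0.01, s0 + 0.01, 11),
            np.linspace(o0 - span / 20, o0 + span / 20, 21),
        )
        if c1 > c0 - 1e-12:  # keep the coarse optimum on ties
            s1, o1 = s0, o0
        t = s1 * ys + o1
        line_idx = [candidates[int(j)] for j in np.argmin(np.abs(t[:, None] - centers[None, :]), axis=1)]
    else:
        raise ValueError(f"unknown correction method {method!r}")

    fixed = [
        replace(
            f,
            y=float(layout.lines[li].center[1]),
            line_index=int(li),
            in_aoi=layout.aoi.contains(f.x, layout.lines[li].center[1]),
        )
        for f, li in zip(seq, line_idx)
    ]
    tag = method + ("_informative" if informative_only else "")
    return seq.with_fixations(fixed, method=tag)


def correct_fixations(
    seq: FixationSequence,
    layout: StimulusLayout,
    method: str = "cluster",
    informative_only: bool = False,
) -> FixationSequence:
    """Map fixation y-positions onto code lines.

    ``cluster`` groups fixation y-values (one group per plausible line,
    deterministic 1-D k-means) and maps groups to the nearest line centre;
    ``stretch`` finds the vertical scale/offset minimising total distance
    to line centres, then assigns each fixation to its nearest line. With
    ``informative_only`` uninformative lines are removed from the
    candidate set beforehand. Onsets, offsets and durations are untouched;
    x is unchanged.
    """
    if method.endswith("_informative"):
        method = method[: -len("_informative")]
        informative_only = True
    return _assign(seq, layout, method, informative_only)


def choose_correction(
    seq: FixationSequence, layout: StimulusLayout
) -> FixationSequence:
    """Deterministic stand-in for the manual dual-rater review: apply all
    four correction variants and keep the one maximising the fraction of
    fixations assigned to informative lines; ties break in the fixed order
    cluster_informative > stretch_informative > cluster > stretch."""
    best: tuple[float, int, FixationSequence] | None = None
    for rank, tag in enumerate(CORRECTION_METHODS):
        corrected = correct_fixations(seq, layout, tag)
        if len(corrected) == 0:
            score = 0.0
        else:
            score = float(
                np.mean([layout.lines[f.line_index].informative for f in corrected])
            )
        key = (score, -rank)
        if best is None or key > (best[0], -best[1]):
            best = (score, rank, corrected)
    return best[2]


# --------------------------------------------------------------------------
# constant offset


def estimate_constant_offset(
    sequences: list[FixationSequence], layouts: list[StimulusLayout]
) -> tuple[float, float]:
    """Median displacement between fixations and their line anchors.

    Anchors are the centres of the assigned lines (nearest line when the
    sequence is uncorrected). Computed across all trials of a block, since
    the offset is constant within a block.
    """
    dx, dy = [], []
    for seq, layout in zip(sequences, layouts):
        centers = np.array([ln.center for ln in layout.lines])
        for f in seq:
            if f.line_index is not None:
                ax, ay = layout.lines[f.line_index].center
            else:
                j = int(np.argmin(np.abs(centers[:, 1] - f.y)))
                ax, ay = centers[j]
            dx.append(f.x - ax)
            dy.append(f.y - ay)
    if not dx:
        raise ValueError("no assignable fixations to estimate an offset from")
    return float(np.median(dx)), float(np.median(dy))


def apply_constant_offset(
    seq: FixationSequence, offset: tuple[float, float]
) -> FixationSequence:
    dx, dy = offset
    fixed = [replace(f, x=f.x - dx, y=f.y - dy) for f in seq]
    out = seq.with_fixations(fixed)
    out.offset_applied = (dx, dy)
    return out


# --------------------------------------------------------------------------
# AOI selection


def first_aoi_fixation(seq: FixationSequence, aoi: Rect) -> Fixation | None:
    """Earliest fixation whose centroid lies in the AOI (boundary
    inclusive); None if the AOI was never fixated."""
    for f in seq:
        if aoi.contains(f.x, f.y):
            return f
    return None
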