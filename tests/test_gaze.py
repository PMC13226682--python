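"""Gaze processing: QC, detection, correction, offset, AOI selection."""

from dataclasses import replace

import numpy as np
import pytest

from codefrp import gaze
from codefrp.containers import Fixation, FixationSequence
from codefrp.synthetic import GazeNoiseSpec, generate_gaze

from conftest import make_stream


class TestTrialQuality:
    def test_excess_missing_excluded(self):
        n = 1000
        valid = np.ones(n, bool)
        valid[:300] = False  # 30% missing, in short scattered form
        valid[:300:3] = True
        valid[: int(0.3 * n)] = False
        qc = gaze.assess_trial_quality(make_stream(np.zeros(n), np.zeros(n), valid))
        assert not qc.retained and "missing_fraction" in qc.reasons

    def test_long_gap_excluded_despite_low_total(self):
        n = 14400  # 12 s at 1200 Hz
        valid = np.ones(n, bool)
        valid[1000 : 1000 + 1440] = False  # single 1.2 s gap, 10% of trial
        qc = gaze.assess_trial_quality(make_stream(np.zeros(n), np.zeros(n), valid))
        assert not qc.retained
        assert qc.reasons == ("long_gap",)
        assert qc.longest_gap_ms == pytest.approx(1200.0)

    def test_clean_stream_retained(self):
        qc = gaze.assess_trial_quality(make_stream(np.zeros(600), np.zeros(600)))
        assert qc.retained and qc.missing_fraction == 0.0

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError):
            gaze.assess_trial_quality(make_stream([], []))


class TestDetection:
    def test_constant_gaze_one_fixation(self):
        seq = gaze.detect_fixations(
            make_stream(np.full(600, 400.0), np.full(600, 300.0))
        )
        assert len(seq) == 1
        f = seq.fixations[0]
        assert f.duration_ms == pytest.approx(500.0)
        assert (f.x, f.y) == (400.0, 300.0)

    def test_short_stable_segment_dropped(self, layout10, quiet_noise):
        noise = GazeNoiseSpec(2.0, 0, 0, 0, 0)
        stream, _ = generate_gaze(
            layout10, [(0, 400.0), (5, 150.0), (9, 400.0)], noise, seed=6
        )
        seq = gaze.detect_fixations(stream)
        mid_y = layout10.lines[5].center[1]
        assert not any(abs(f.y - mid_y) < 10 for f in seq)

    def test_jittered_fixations_recovered_within_20ms(self, layout10):
        noise = GazeNoiseSpec(8.0, 0, 0, 0, 0)
        for seed in range(5):
            stream, truth = generate_gaze(
                layout10, [(2, 500.0), (5, 500.0)], noise, seed=seed
            )
            seq = gaze.detect_fixations(stream)
            assert len(seq) == 2
            for f, tf in zip(seq, truth):
                assert abs(f.onset_ms - tf.onset_ms) < 20.0

    def test_all_invalid_flags_warning(self):
        n = 600
        seq = gaze.detect_fixations(
            make_stream(np.full(n, np.nan), np.full(n, np.nan), np.zeros(n, bool))
        )
        assert len(seq) == 0 and seq.all_invalid

    def test_lower_minimum_never_loses_fixations(self, layout10):
        noise = GazeNoiseSpec(6.0, 0, 0, 0, 0)
        stream, _ = generate_gaze(
            layout10, [(0, 250.0), (3, 500.0), (6, 220.0)], noise, seed=2
        )
        base = gaze.I2MCParams()
        n_default = len(gaze.detect_fixations(stream, base))
        n_lower = len(gaze.detect_fixations(stream, replace(base, min_fix_ms=120.0)))
        assert n_lower >= n_default

    def test_sequences_ordered_disjoint_and_bounded(self, layout10):
        noise = GazeNoiseSpec(7.0, 0.2, 3.0, 0.05, 150.0)
        stream, _ = generate_gaze(
            layout10,
            [(0, 300.0), (2, 400.0), (4, 350.0), (6, 500.0)],
            noise,
            seed=13,
        )
        seq = gaze.detect_fixations(stream)
        for a, b in zip(seq, seq.fixations[1:]):
            assert b.onset_ms >= a.offset_ms
        total_fix = sum(f.duration_ms for f in seq)
        assert total_fix <= stream.duration_ms + 1e-9


class TestOutliers:
    def test_on_stimulus_fixations_untouched(self, layout10):
        fixes = tuple(
            Fixation(100.0 * i, 100.0 * i + 90, *layout10.lines[i].center)
            for i in range(3)
        )
        seq = FixationSequence("t", fixes)
        out, removed = gaze.remove_outlier_fixations(seq, layout10)
        assert removed == 0 and out.fixations == fixes

    def test_far_fixation_removed(self, layout10):
        lh = layout10.line_height
        below = layout10.lines[-1].y1 + 5 * lh
        fixes = (
            Fixation(0.0, 300.0, *layout10.lines[0].center),
            Fixation(400.0, 700.0, 500.0, below),
        )
        out, removed = gaze.remove_outlier_fixations(
            FixationSequence("t", fixes), layout10
        )
        assert removed == 1
        assert len(out) == 1

    def test_empty_sequence(self, layout10):
        out, removed = gaze.remove_outlier_fixations(
            FixationSequence("t", ()), layout10
        )
        assert removed == 0 and len(out) == 0


def _detected_with_offset(layout, dy, seed, jitter=4.0):
    noise = GazeNoiseSpec(jitter, 0, 0, 0, 0)
    sp = [(0, 400.0), (1, 350.0), (3, 400.0), (4, 300.0), (5, 350.0), (7, 400.0),
          (4, 300.0), (7, 300.0)]
    stream, truth = generate_gaze(layout, sp, noise, seed=seed)
    seq = gaze.detect_fixations(stream)
    shifted = seq.with_fixations([replace(f, y=f.y + dy) for f in seq])
    return shifted, truth


class TestCorrection:
    def test_zero_drift_matches_nearest_line(self, layout_braces):
        seq, truth = _detected_with_offset(layout_braces, 0.0, seed=4)
        for method in ("cluster", "stretch"):
            cor = gaze.correct_fixations(seq, layout_braces, method)
            centers = [ln.center[1] for ln in layout_braces.lines]
            for f_orig, f_cor in zip(seq, cor):
                nearest = int(np.argmin(np.abs(np.array(centers) - f_orig.y)))
                assert f_cor.line_index == nearest

    @pytest.mark.parametrize("method", gaze.CORRECTION_METHODS)
    def test_constant_offset_recovered(self, layout_braces, method):
        lh = layout_braces.line_height
        hits, total = 0, 0
        for seed in range(10):
            seq, truth = _detected_with_offset(layout_braces, 0.6 * lh, seed=seed)
            if len(seq) != len(truth):
                continue
            cor = gaze.correct_fixations(seq, layout_braces, method)
            hits += sum(f.line_index == tf.line_index for f, tf in zip(cor, truth))
            total += len(truth)
        assert total > 0 and hits / total >= 0.95

    def test_informative_only_never_uses_brace_lines(self, layout_braces):
        uninformative = {
            i for i, ln in enumerate(layout_braces.lines) if not ln.informative
        }
        for seed in range(5):
            seq, _ = _detected_with_offset(layout_braces, 10.0, seed=seed)
            for method in ("cluster", "stretch"):
                cor = gaze.correct_fixations(
                    seq, layout_braces, method, informative_only=True
                )
                assert not any(f.line_index in uninformative for f in cor)

    def test_correction_only_touches_assignment(self, layout_braces):
        seq, _ = _detected_with_offset(layout_braces, 12.0, seed=3)
        for method in gaze.CORRECTION_METHODS:
            cor = gaze.correct_fixations(seq, layout_braces, method)
            for f_in, f_out in zip(seq, cor):
                assert f_out.onset_ms == f_in.onset_ms
                assert f_out.offset_ms == f_in.offset_ms
                assert f_out.x == f_in.x

    def test_method_selection_tiebreak_order(self, layout_braces):
        seq, _ = _detected_with_offset(layout_braces, 0.0, seed=1)
        chosen = gaze.choose_correction(seq, layout_braces)
        # informative variants score 1.0 by construction; the fixed order
        # puts cluster_informative first
        assert chosen.correction_method == "cluster_informative"


class TestConstantOffset:
    def _block(self, layout, noise, n_trials=6, seed0=100, corrected=False):
        sp = [(0, 400.0), (1, 350.0), (3, 400.0), (4, 300.0), (5, 350.0), (7, 400.0)]
        seqs = []
        for s in range(n_trials):
            stream, _ = generate_gaze(layout, sp, noise, seed=seed0 + s)
            sq = gaze.detect_fixations(stream)
            sq, _ = gaze.remove_outlier_fixations(sq, layout)
            seqs.append(sq)
        return seqs

    def test_injected_offset_recovered(self, layout_braces):
        noise = GazeNoiseSpec(4.0, 0, 12.0, 0, 0)
        seqs = self._block(layout_braces, noise)
        dx, dy = gaze.estimate_constant_offset(seqs, [layout_braces] * len(seqs))
        assert abs(dx - 12.0) <= 3.0
        assert abs(dy) <= 3.0

    def test_zero_offset_estimated_near_zero(self, layout_braces):
        noise = GazeNoiseSpec(4.0, 0, 0, 0, 0)
        seqs = self._block(layout_braces, noise, seed0=200)
        dx, dy = gaze.estimate_constant_offset(seqs, [layout_braces] * len(seqs))
        assert abs(dx) <= 3.0 and abs(dy) <= 3.0

    def test_single_fixation_equals_displacement(self, layout10):
        ln = layout10.lines[2]
        f = Fixation(0.0, 300.0, ln.center[0] + 7.0, ln.center[1] - 4.0, line_index=2)
        dx, dy = gaze.estimate_constant_offset(
            [FixationSequence("t", (f,))], [layout10]
        )
        assert (dx, dy) == pytest.approx((7.0, -4.0))

    def test_no_fixations_rejected(self, layout10):
        with pytest.raises(ValueError):
            gaze.estimate_constant_offset([FixationSequence("t", ())], [layout10])

    def test_apply_subtracts_and_records(self, layout10):
        f = Fixation(0.0, 300.0, 100.0, 200.0)
        out = gaze.apply_constant_offset(FixationSequence("t", (f,)), (10.0, -5.0))
        assert out.fixations[0].x == 90.0 and out.fixations[0].y == 205.0
        assert out.offset_applied == (10.0, -5.0)


class TestFirstAoiFixation:
    def test_single_candidate(self, layout10):
        aoi = layout10.aoi
        f = Fixation(0.0, 300.0, (aoi.x0 + aoi.x1) / 2, (aoi.y0 + aoi.y1) / 2)
        assert gaze.first_aoi_fixation(FixationSequence("t", (f,)), aoi) is f

    def test_earliest_wins(self, layout10):
        aoi = layout10.aoi
        cx, cy = (aoi.x0 + aoi.x1) / 2, (aoi.y0 + aoi.y1) / 2
        f1 = Fixation(1000.0, 1300.0, cx, cy)
        f2 = Fixation(2500.0, 2800.0, cx, cy)
        got = gaze.first_aoi_fixation(FixationSequence("t", (f1, f2)), aoi)
        assert got.onset_ms == 1000.0

    def test_boundary_inclusive(self, layout10):
        aoi = layout10.aoi
        f = Fixation(0.0, 300.0, aoi.x0, aoi.y1)
        assert gaze.first_aoi_fixation(FixationSequence("t", (f,)), aoi) is f

    def test_no_candidate_returns_none(self, layout10):
        aoi = layout10.aoi
        f = Fixation(0.0, 300.0, aoi.x0 - 50.0, aoi.y0 - 50.0)
        assert gaze.first_aoi_fixation(FixationSequence("t", (f,)), aoi) is None


def test_end_to_end_first_aoi_recovery_under_drift_and_offset():
    """Selected first-AOI fixations match ground truth (onset within 20 ms)
    in at least 90% of trials under vertical drift plus a constant x offset."""
    from codefrp.pipeline import process_gaze_participant, validate_config
    from codefrp.synthetic import generate_study

    cfg = validate_config(
        {
            "design": {
                "n_participants": 4, "n_blocks": 2, "trials_per_block": 8,
                "n_pairs": 16, "fixation_cross_s": 0.5,
                "snippet_min_s": 3.0, "snippet_max_s": 6.0,
            },
            "gaze_noise": {
                "jitter_sd_px": 5.0, "y_drift_lines": 0.5,
                "x_offset_px": 12.0, "missing_fraction": 0.0,
            },
            "generator": {"bad_gaze_rate": 0.0},
        }
    )
    bundle = generate_study(
        cfg.design, cfg.effect, cfg.gaze_noise, seed=42, bad_gaze_rate=0.0
    )
    total = matched = 0
    for pdata in bundle.iter_participants():
        events, _, _ = process_gaze_participant(pdata, bundle.layouts, cfg)
        got = {tid: s for tid, s, _ in events}
        for row in pdata.trials.itertuples():
            tf = pdata.truth.first_aoi.get(row.trial_id)
            if tf is None:
                continue
            total += 1
            if row.trial_id in got:
                onset_ms = (got[row.trial_id] / 500.0 - row.snippet_on_s) * 1000.0
                if abs(onset_ms - tf.onset_ms) <= 20.0:
                    matched += 1
    assert total >= 50
    assert matched / total >= 0.90
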