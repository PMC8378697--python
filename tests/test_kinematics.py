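"""Gaze composition, spread, peak detection, and head-contribution binning."""

import numpy as np
import pytest

from gazekit.kinematics import (
    EccentricityBinning,
    GazeShiftPeak,
    bin_head_contributions,
    compose_gaze,
    detect_gaze_peaks,
    head_contribution,
    spread,
)
from gazekit.series import RotationSeries, make_timeline


def _series(values, effector="gaze", rate=30.0):
    values = np.asarray(values, dtype=float)
    return RotationSeries(np.arange(values.size) / rate, values, effector)


class TestComposeGaze:
    def test_worked_example_left_rotations(self):
        """Eyes 20 deg left + head 20 deg left = gaze 40 deg left."""
        eye = _series([-20.0] * 5, "eye")
        head = _series([-20.0] * 5, "head")
        gaze = compose_gaze(eye, head)
        assert np.all(gaze.angle == -40.0)
        assert gaze.effector == "gaze"

    def test_compensatory_movement_cancels(self):
        gaze = compose_gaze(_series([10.0] * 3, "eye"), _series([-10.0] * 3, "head"))
        assert np.all(gaze.angle == 0.0)

    def test_matches_elementwise_loop(self):
        rng = np.random.default_rng(1)
        e = rng.normal(0, 10, 200)
        h = rng.normal(0, 10, 200)
        gaze = compose_gaze(_series(e, "eye"), _series(h, "head"))
        expected = np.array([e[i] + h[i] for i in range(200)])
        assert np.array_equal(gaze.angle, expected)

    def test_missing_propagates(self):
        e = np.array([1.0, np.nan, 3.0])
        gaze = compose_gaze(_series(e, "eye"), _series([1.0, 1.0, 1.0], "head"))
        assert np.isnan(gaze.angle[1]) and gaze.angle[2] == 4.0

    def test_mismatched_timelines_rejected(self):
        eye = _series([0.0] * 5, "eye")
        head = RotationSeries(np.arange(5) / 30.0 + 0.001, np.zeros(5), "head")
        with pytest.raises(ValueError):
            compose_gaze(eye, head)


class TestSpread:
    def test_constant_series_zero(self):
        assert spread(_series([5.0] * 100)) == 0.0

    def test_alternating_two_point_closed_form(self):
        """SD of +-10 alternation: 10 * sqrt(n/(n-1)) for even n."""
        n = 1000
        vals = np.tile([-10.0, 10.0], n // 2)
        expected = 10.0 * np.sqrt(n / (n - 1))
        assert spread(_series(vals)) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(10.005, abs=1e-3)

    def test_missing_excluded(self):
        vals = np.array([1.0, np.nan, 3.0, np.nan, 5.0])
        assert spread(_series(vals)) == pytest.approx(np.std([1, 3, 5], ddof=1))

    def test_all_missing_window_rejected(self):
        with pytest.raises(ValueError):
            spread(_series([np.nan] * 10))


class TestHeadContribution:
    @pytest.mark.parametrize(
        "eye,head,expected",
        [(20, 20, 50.0), (-20, -20, 50.0), (20, 0, 0.0), (5, 15, 75.0), (0, 10, 100.0)],
    )
    def test_known_splits(self, eye, head, expected):
        assert head_contribution(eye, head) == expected

    def test_zero_eccentricity_rejected(self):
        with pytest.raises(ValueError):
            head_contribution(0.0, 0.0)

    def test_opposite_directions_rejected(self):
        with pytest.raises(ValueError):
            head_contribution(20.0, -5.0)


def _triangle(peak_value, n_side=15):
    """Symmetric excursion 0 -> peak -> 0."""
    up = np.linspace(0, peak_value, n_side, endpoint=False)
    down = np.linspace(peak_value, 0, n_side + 1)
    return np.concatenate([up, down, np.zeros(5)])


class TestDetectGazePeaks:
    def test_single_triangular_excursion(self):
        g = _triangle(30.0)
        gaze, eye, head = _series(g), _series(g / 2, "eye"), _series(g / 2, "head")
        peaks = detect_gaze_peaks(gaze, eye, head)
        assert len(peaks) == 1
        pk = peaks[0]
        assert pk.direction == "right"
        assert pk.gaze_eccentricity == pytest.approx(30.0)
        assert pk.head_contribution == pytest.approx(50.0)

    def test_leftward_excursion_is_minimum(self):
        g = -_triangle(25.0)
        peaks = detect_gaze_peaks(
            _series(g), _series(g * 0.4, "eye"), _series(g * 0.6, "head")
        )
        assert len(peaks) == 1 and peaks[0].direction == "left"
        assert peaks[0].head_contribution == pytest.approx(60.0)

    def test_opposite_sign_components_excluded(self):
        """Eye right but head left at the extremum: peak not recorded."""
        g = _triangle(15.0)
        eye = _series(g + 5.0, "eye")  # eye positive at peak
        head = _series(-5.0 * np.ones_like(g), "head")
        gaze = compose_gaze(eye, head)
        assert detect_gaze_peaks(gaze, eye, head) == []

    def test_separation_keeps_larger_eccentricity(self):
        """Two extrema 0.2 s apart: only the 40 deg one is retained."""
        rate = 30.0
        g = np.zeros(40)
        g[10] = 40.0  # strict max at t = 10/30
        g[16] = 25.0  # strict max at t = 16/30, 0.2 s later
        g[13] = 5.0
        gaze = _series(g)
        eye, head = _series(g / 2, "eye"), _series(g / 2, "head")
        peaks = detect_gaze_peaks(gaze, eye, head)
        eccs = [p.gaze_eccentricity for p in peaks]
        assert 40.0 in eccs and 25.0 not in eccs

    def test_plateau_center_rule(self):
        g = np.array([0, 0, 10, 10, 10, 0, 0], dtype=float)
        gaze = _series(g)
        peaks = detect_gaze_peaks(gaze, _series(g / 2, "eye"), _series(g / 2, "head"))
        assert len(peaks) == 1
        assert peaks[0].t_peak == pytest.approx(3 / 30.0)

    def test_matches_brute_force_oracle(self):
        """Exhaustive reference agreement on 200 random 30 s series."""
        rng = np.random.default_rng(42)
        rate, n = 30.0, 900
        for _ in range(200):
            g = np.cumsum(rng.normal(0, 2.0, n))
            g -= g.mean()
            eye = 0.4 * g + rng.normal(0, 3.0, n)
            head = g - eye
            gaze = _series(g)
            es, hs = _series(eye, "eye"), _series(head, "head")
            got = detect_gaze_peaks(gaze, es, hs)
            want = _oracle_peaks(g, eye, head, rate, min_sep=10 / 30.0)
            assert [(p.t_peak, p.direction) for p in got] == want


def _oracle_peaks(g, eye, head, rate, min_sep):
    """Independent O(n^2) reference: scan strict extrema (plateau-center),
    apply the same-direction rule, then resolve separation conflicts by
    repeatedly keeping the globally largest remaining eccentricity."""
    n = len(g)
    cands = []
    for i in range(1, n - 1):
        lo = i
        while lo - 1 >= 0 and g[lo - 1] == g[i]:
            lo -= 1
        hi = i
        while hi + 1 < n and g[hi + 1] == g[i]:
            hi += 1
        if lo == 0 or hi == n - 1:
            continue
        center = (lo + hi) // 2
        if i != center:
            continue
        left, right = g[lo - 1], g[hi + 1]
        if left < g[i] and right < g[i]:
            direction = "right"
        elif left > g[i] and right > g[i]:
            direction = "left"
        else:
            continue
        if np.sign(eye[i]) == 0 or np.sign(eye[i]) != np.sign(head[i]):
            continue
        if abs(g[i]) == 0:
            continue
        cands.append((i / rate, direction, abs(g[i])))
    kept = []
    remaining = list(cands)
    while remaining:
        best = max(remaining, key=lambda c: c[2])
        kept.append(best)
        remaining = [
            c for c in remaining if c is not best and abs(c[0] - best[0]) >= min_sep
        ]
    kept.sort(key=lambda c: c[0])
    return [(t, d) for t, d, _ in kept]


def _peak(ecc, contribution_pct, t=0.0):
    head = ecc * contribution_pct / 100.0
    return GazeShiftPeak(t, "right", ecc, ecc - head, head)


class TestBinning:
    def test_eight_bins_labelled_by_lower_bound(self):
        b = EccentricityBinning()
        assert b.labels == [10, 20, 30, 40, 50, 60, 70, 80]

    def test_hand_computed_bin_mean(self):
        """Peaks at 15 deg (40%) and 17 deg (60%) average to 50% in bin 10."""
        out = bin_head_contributions([_peak(15, 40, 0.0), _peak(17, 60, 1.0)])
        assert list(out.index) == [10]
        assert out.loc[10, "mean_contribution"] == pytest.approx(50.0)
        assert out.loc[10, "n_peaks"] == 2

    def test_half_open_boundary(self):
        """A peak at exactly 20 deg belongs to bin 20, not bin 10."""
        assert EccentricityBinning().assign(20.0) == 20

    def test_sub_ten_degree_peaks_discarded(self):
        out = bin_head_contributions([_peak(9.9, 50), _peak(5, 50)])
        assert len(out) == 0

    def test_open_ended_top_bin(self):
        assert EccentricityBinning().assign(95.0) == 80
        assert EccentricityBinning().assign(300.0) == 80

    def test_empty_bins_absent_not_zero(self):
        out = bin_head_contributions([_peak(15, 40), _peak(85, 90)])
        assert list(out.index) == [10, 80]
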