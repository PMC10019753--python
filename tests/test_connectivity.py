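"""Correlation and phase-locking against brute-force definition oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meditfc import (
    UndefinedFeatureError,
    connectivity_matrix,
    instantaneous_phase,
    pearson_corr,
    plv,
)
from meditfc.preprocessing import BAND_BY_NAME, BandEpoch, bandpass

FS = 250.0


def corr_by_definition(x, y):
    """Independent oracle: covariance / sqrt of variances via explicit sums."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    vx = sum((a - mx) ** 2 for a in x) / n
    vy = sum((b - my) ** 2 for b in y) / n
    return cov / (vx * vy) ** 0.5


class TestPearson:
    def test_identity_and_sign_flip(self, rng):
        x = rng.standard_normal(50)
        assert pearson_corr(x, x) == pytest.approx(1.0)
        assert pearson_corr(x, -x) == pytest.approx(-1.0)

    def test_affine_relation_is_perfect(self):
        assert pearson_corr([1, 2, 3, 4], [2, 4, 6, 8]) == pytest.approx(1.0)

    def test_textbook_example_matches_definition(self):
        x, y = [1, 2, 3, 4], [1, 3, 2, 4]
        assert pearson_corr(x, y) == pytest.approx(corr_by_definition(x, y), abs=1e-12)

    def test_many_random_instances_match_definition(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 30))
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            assert pearson_corr(x, y) == pytest.approx(
                corr_by_definition(x, y), abs=1e-10
            )

    def test_constant_input_flagged_not_zeroed(self):
        with pytest.raises(UndefinedFeatureError):
            pearson_corr(np.ones(10), np.arange(10.0))

    @given(
        a=st.floats(0.1, 10), b=st.floats(0.1, 10),
        c=st.floats(-5, 5), d=st.floats(-5, 5),
        flip=st.booleans(),
    )
    @settings(max_examples=50, deadline=None)
    def test_location_scale_invariance(self, a, b, c, d, flip):
        rng = np.random.default_rng(99)
        x = rng.standard_normal(40)
        y = rng.standard_normal(40)
        sa = -a if flip else a
        base = pearson_corr(x, y)
        assert pearson_corr(sa * x + c, b * y + d) == pytest.approx(
            np.sign(sa * b) * base, abs=1e-9
        )


class TestInstantaneousPhase:
    def test_cosine_phase_slope_matches_frequency(self):
        t = np.arange(0, 4, 1 / FS)
        phase = instantaneous_phase(np.cos(2 * np.pi * 10 * t))
        mid = slice(100, -100)
        slope = np.polyfit(t[mid], np.unwrap(phase)[mid], 1)[0]
        assert abs(slope / (2 * np.pi * 10) - 1) < 0.01

    def test_constant_phase_offset_recovered(self):
        t = np.arange(0, 4, 1 / FS)
        p1 = instantaneous_phase(np.cos(2 * np.pi * 10 * t + np.pi / 4))
        p0 = instantaneous_phase(np.cos(2 * np.pi * 10 * t))
        diff = np.angle(np.exp(1j * (p1 - p0)))[100:-100]
        assert np.abs(diff - np.pi / 4).max() < 0.01 * 2 * np.pi

    def test_narrowband_noise_phase_advances_at_band_center(self, rng):
        """Mean phase increment over many realizations sits near the
        band's center frequency."""
        band = BAND_BY_NAME["alpha"]
        rates = []
        for _ in range(50):
            x = bandpass(rng.standard_normal(2000), FS, band)[0]
            dphi = np.diff(np.unwrap(instantaneous_phase(x)))[50:-50]
            rates.append(dphi.mean() * FS / (2 * np.pi))
        mean_rate = np.mean(rates)
        assert band.low < mean_rate < band.high

    def test_all_zero_input_flagged(self):
        with pytest.raises(UndefinedFeatureError):
            instantaneous_phase(np.zeros(100))


class TestPLV:
    def test_self_synchrony_is_one(self, rng):
        x = bandpass(rng.standard_normal(2000), FS, BAND_BY_NAME["alpha"])[0]
        assert plv(x, x) == pytest.approx(1.0, abs=1e-9)

    def test_constant_phase_offset_gives_unit_plv(self):
        t = np.arange(0, 8, 1 / FS)
        x = np.cos(2 * np.pi * 10 * t)
        y = np.cos(2 * np.pi * 10 * t + 1.1)
        assert plv(x, y) == pytest.approx(1.0, abs=1e-6)

    def test_independent_white_noise_null_floor(self, rng):
        """For ~iid phases the null PLV is O(1/sqrt(L)); at L ~ 10000 the
        mean over 100 trials stays below 0.02."""
        vals = [
            plv(rng.standard_normal(11112), rng.standard_normal(11112))
            for _ in range(100)
        ]
        assert np.mean(vals) < 0.02

    def test_amplitude_invariance(self, rng):
        x = bandpass(rng.standard_normal(1500), FS, BAND_BY_NAME["theta"])[0]
        y = bandpass(rng.standard_normal(1500), FS, BAND_BY_NAME["theta"])[0]
        assert plv(3.7 * x, 0.2 * y) == pytest.approx(plv(x, y), abs=1e-12)

    def test_symmetry(self, rng):
        x = bandpass(rng.standard_normal(1500), FS, BAND_BY_NAME["alpha"])[0]
        y = bandpass(rng.standard_normal(1500), FS, BAND_BY_NAME["alpha"])[0]
        assert plv(x, y) == pytest.approx(plv(y, x), abs=1e-12)


def _epoch_from(data):
    n = data.shape[0]
    return BandEpoch(
        subject_id="s", group="NM", state="meditation",
        band=BAND_BY_NAME["alpha"], epoch_index=0,
        data=data, sampling_rate=FS,
        hemisphere_split=(np.arange(n // 2), np.arange(n // 2, n)),
    )


class TestConnectivityMatrix:
    def test_identical_channels_give_all_ones(self, rng):
        base = bandpass(rng.standard_normal(1000), FS, BAND_BY_NAME["alpha"])[0]
        ep = _epoch_from(np.tile(base, (4, 1)) * np.array([[1.0], [2.0], [0.5], [3.0]]))
        for method in ("correlation", "plv"):
            m = connectivity_matrix(ep, method).matrix
            np.testing.assert_allclose(m, 1.0, atol=1e-9)

    def test_matrix_symmetric_unit_diagonal_and_ranges(self, rng):
        data = bandpass(rng.standard_normal((6, 1200)), FS, BAND_BY_NAME["theta"])
        ep = _epoch_from(data)
        for method in ("correlation", "plv"):
            cm = connectivity_matrix(ep, method)
            np.testing.assert_array_equal(cm.matrix, cm.matrix.T)
            np.testing.assert_allclose(np.diag(cm.matrix), 1.0)
            if method == "plv":
                assert cm.matrix.min() >= 0
            assert cm.matrix.max() <= 1
            assert np.abs(cm.matrix).max() <= 1

    def test_plv_matrix_matches_pairwise_calls(self, rng):
        data = bandpass(rng.standard_normal((6, 1000)), FS, BAND_BY_NAME["alpha"])
        cm = connectivity_matrix(_epoch_from(data), "plv")
        for i in range(6):
            for j in range(i + 1, 6):
                assert cm.matrix[i, j] == pytest.approx(
                    plv(data[i], data[j]), abs=1e-10
                )

    def test_interhemispheric_block_shape(self, rng):
        data = bandpass(rng.standard_normal((8, 1000)), FS, BAND_BY_NAME["alpha"])
        cm = connectivity_matrix(_epoch_from(data), "correlation")
        assert cm.interhemispheric_block().shape == (4, 4)

    def test_constant_channel_rejected(self):
        data = np.vstack([np.zeros(500), np.random.default_rng(0).standard_normal(500)])
        with pytest.raises(UndefinedFeatureError, match="constant"):
            connectivity_matrix(_epoch_from(data), "correlation")
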