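"""The 19-feature battery: hand-computed examples, brute-force oracle
agreement, invariances, and degenerate-input sentinels."""

import math

import numpy as np
import pytest

import _oracles
from prvarr.features import (
    FEATURE_NAMES,
    csampen,
    extract_all,
    lf_hf,
    permutation_entropy,
    poincare,
    sample_entropy,
    shannon_entropy,
    time_features,
    turning_point_ratio,
)

from conftest import make_segment


class TestTimeFeatures:
    def test_constant_rate(self):
        out = time_features(make_segment(prv=[60.0, 60.0, 60.0]))
        assert out["Mean"] == 60.0
        assert out["Std"] == 0.0
        assert out["RMSD"] == 0.0
        assert out["nRMSD"] == 0.0
        assert out["Mid"] == 60.0

    def test_arithmetic_sequence(self):
        out = time_features(make_segment(prv=[1.0, 2.0, 3.0, 4.0, 5.0]))
        assert out["Mean"] == pytest.approx(3.0)
        assert out["Std"] == pytest.approx(math.sqrt(2.5))
        assert out["RMSD"] == pytest.approx(1.0)  # sqrt(4 * 1 / 4)
        assert out["Mid"] == pytest.approx(3.0)
        assert out["nRMSD"] == pytest.approx(1.0 / 3.0)

    def test_pnn_counts_on_interval_differences(self):
        out = time_features(make_segment(ppi=[800.0, 850.0, 860.0, 950.0]))
        # |diffs| = {50, 10, 90}: two exceed 40 ms, one exceeds 70 ms
        assert out["PNN40"] == pytest.approx(2.0 / 3.0)
        assert out["PNN70"] == pytest.approx(1.0 / 3.0)

    def test_iqr_is_quartile_ratio(self, rng):
        x = rng.uniform(50.0, 100.0, 40)
        out = time_features(make_segment(prv=x))
        s25, s75 = np.percentile(x, [25, 75])
        assert out["IQR"] == pytest.approx(s75 / s25)

    def test_rmsd_apm_uses_amplitudes(self):
        seg = make_segment(prv=[60.0] * 4, apm=[1.0, 2.0, 1.0, 2.0])
        out = time_features(seg)
        assert out["RMSD_APM"] == pytest.approx(math.sqrt(3.0 / 3.0))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            time_features(make_segment(prv=[60.0]))


class TestPoincare:
    def test_constant_series_degenerates(self):
        out = poincare(make_segment(prv=[70.0] * 10))
        assert out["Sd1"] == 0.0 and out["Sd2"] == 0.0 and out["Se"] == 0.0
        assert math.isnan(out["Sd1_Sd2"])

    def test_alternating_series(self):
        a, b = 50.0, 80.0
        out = poincare(make_segment(prv=[a, b] * 5))
        assert out["Sd2"] == pytest.approx(0.0, abs=1e-9)
        assert out["Sd1"] == pytest.approx(abs(b - a) / math.sqrt(2.0))

    def test_matches_direct_sum_oracle(self, rng):
        for _ in range(50):
            x = rng.uniform(40.0, 160.0, rng.integers(8, 31))
            got = poincare(make_segment(prv=x))
            sd1, sd2 = _oracles.poincare(x)
            assert got["Sd1"] == pytest.approx(sd1, abs=1e-12)
            assert got["Sd2"] == pytest.approx(sd2, abs=1e-12)
            assert got["Se"] == pytest.approx(math.pi * sd1 * sd2, abs=1e-9)


class TestTurningPointRatio:
    def test_monotone_has_none(self):
        assert turning_point_ratio(np.arange(10.0)) == 0.0

    def test_hand_enumeration(self):
        assert turning_point_ratio([1.0, 3.0, 2.0, 4.0, 3.0]) == pytest.approx(0.6)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            turning_point_ratio([1.0, 2.0])

    def test_iid_expectation_two_thirds(self, rng):
        n = 3000
        x = rng.uniform(size=n)
        scaled = turning_point_ratio(x) * n / (n - 2)
        assert scaled == pytest.approx(2.0 / 3.0, abs=0.03)


class TestShannonEntropy:
    def test_constant_is_zero(self):
        assert shannon_entropy(np.full(20, 5.0), bins=16) == 0.0

    def test_uniform_occupancy_is_one(self):
        # one value per bin centre: exactly uniform occupancy
        x = np.arange(16) + 0.5
        assert shannon_entropy(x, bins=16) == pytest.approx(1.0)

    def test_hand_histogram(self):
        # occupancy {1/2, 0, 1/4, 1/4} over 4 bins -> 1.5 bits / log2(4)
        x = [0.5, 0.5, 1.5, 2.5]
        assert shannon_entropy(x, bins=4) == pytest.approx(0.75)

    def test_matches_oracle(self, rng):
        for _ in range(50):
            x = rng.normal(size=rng.integers(8, 31))
            assert shannon_entropy(x, 16) == pytest.approx(
                _oracles.shannon_entropy(x, 16), abs=1e-12
            )


class TestSampleEntropy:
    def test_constant_series_is_zero(self):
        assert sample_entropy(np.full(12, 800.0), m=2) == 0.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(60):
            x = rng.normal(size=rng.integers(8, 31))
            r = 0.25 * float(np.std(x, ddof=1))
            got = sample_entropy(x, m=2, r=r)
            expect = _oracles.sample_entropy(x, 2, r)
            if math.isnan(expect):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(expect, abs=1e-12)

    def test_periodic_below_shuffled(self, rng):
        x = np.tile([60.0, 75.0, 90.0, 75.0], 6)
        base = sample_entropy(x, m=2, r=0.25 * np.std(x, ddof=1))
        shuffled = []
        for _ in range(20):
            y = rng.permutation(x)
            s = sample_entropy(y, m=2, r=0.25 * np.std(y, ddof=1))
            if not math.isnan(s):
                shuffled.append(s)
        assert base < np.median(shuffled)


class TestCSampEn:
    def test_identity_composition(self, rng):
        # smooth series so template matches exist at both lengths
        x = 800.0 + 60.0 * np.sin(0.4 * np.arange(24)) + rng.normal(0, 2.0, 24)
        r = 0.25 * float(np.std(x, ddof=1))
        s = sample_entropy(x, m=2, r=r)
        assert csampen(x, m=2, r=r) == pytest.approx(
            s + math.log(2 * r) - math.log(np.mean(x)), abs=1e-12
        )

    def test_constant_series_uses_sentinel_path(self):
        assert math.isnan(csampen(np.full(12, 800.0), m=2))


class TestPermutationEntropy:
    def test_monotone_single_pattern(self):
        assert permutation_entropy(np.arange(30.0), m=5) == 0.0

    def test_matches_enumeration_oracle(self, rng):
        for m in (3, 4, 5):
            for _ in range(30):
                x = rng.normal(size=rng.integers(m + 3, 31))
                assert permutation_entropy(x, m=m) == pytest.approx(
                    _oracles.permutation_entropy(x, m), abs=1e-12
                )

    def test_iid_limit_log_m_factorial(self, rng):
        x = rng.uniform(size=5000)
        assert permutation_entropy(x, m=3) == pytest.approx(math.log(6), abs=0.01)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            permutation_entropy([1.0, 2.0, 3.0], m=5)


class TestLfHf:
    @staticmethod
    def _modulated_segment(freq, amp=50.0, n=200, base=800.0):
        ppi = np.empty(n)
        t = 0.0
        for i in range(n):
            ppi[i] = base + amp * math.sin(2 * math.pi * freq * t / 1000.0)
            t += ppi[i]
        return make_segment(ppi=ppi)

    def test_low_frequency_modulation_dominates(self):
        assert lf_hf(self._modulated_segment(0.1)) > 5.0

    def test_high_frequency_modulation_dominates(self):
        assert lf_hf(self._modulated_segment(0.3)) < 0.2

    def test_short_segment_returns_sentinel(self):
        assert math.isnan(lf_hf(make_segment(ppi=np.full(16, 800.0))))

    def test_balanced_modulation_matches_periodogram_oracle(self, rng):
        # 120 bpm base rate keeps linear-interpolation attenuation of the
        # 0.3 Hz component negligible; broadband jitter regularises the AR
        # fit (pure line spectra are degenerate for band integration)
        from scipy.signal import periodogram

        n, base, amp = 400, 500.0, 30.0
        ppi = np.empty(n)
        t = 0.0
        for i in range(n):
            s = math.sin(2 * math.pi * 0.1 * t / 1000.0) + math.sin(
                2 * math.pi * 0.3 * t / 1000.0
            )
            ppi[i] = base + amp * s + rng.normal(0.0, 8.0)
            t += ppi[i]
        ratio = lf_hf(make_segment(ppi=ppi))
        tt = np.cumsum(ppi) / 1000.0
        grid = np.arange(tt[0], tt[-1], 0.25)
        x = np.interp(grid, tt, ppi)
        f, p = periodogram(x - x.mean(), fs=4.0)
        lf = p[(f >= 0.04) & (f <= 0.15)].sum()
        hf = p[(f >= 0.15) & (f <= 0.4)].sum()
        assert ratio == pytest.approx(lf / hf, rel=0.2)
        assert 0.8 <= ratio <= 1.3


class TestExtractAll:
    def test_full_vector_names_and_order(self, small_dataset):
        row = extract_all(small_dataset.segments[0])
        assert list(row.index) == FEATURE_NAMES
        assert len(row) == 19

    def test_short_segment_gets_lfhf_sentinel_only(self):
        # periodic 16-beat window: every feature defined except the
        # spectral ratio (covers only ~13 s of signal time)
        seg = make_segment(prv=np.tile([60.0, 75.0, 90.0, 75.0], 4), label=1)
        row = extract_all(seg)
        assert math.isnan(row["LF_HF"])
        others = row.drop("LF_HF")
        assert np.isfinite(others.to_numpy(dtype=float)).all()

    def test_deterministic(self, small_dataset):
        seg = small_dataset.segments[3]
        a = extract_all(seg)
        b = extract_all(seg)
        assert a.equals(b)

    def test_scale_equivariance_and_invariance(self, rng):
        x = rng.uniform(50.0, 110.0, 16)
        seg = make_segment(prv=x)
        seg2 = make_segment(prv=2.0 * x)
        a, b = extract_all(seg), extract_all(seg2)
        for name in ("Mean", "Std", "RMSD", "Mid"):
            assert b[name] == pytest.approx(2.0 * a[name], rel=1e-9)
        for name in ("nRMSD", "IQR", "Sd1_Sd2", "TPR_PR", "PE_PR", "ShE_PR"):
            assert b[name] == pytest.approx(a[name], rel=1e-9)

    def test_shift_invariance_of_dispersion(self, rng):
        x = rng.uniform(60.0, 90.0, 16)
        a = poincare(make_segment(prv=x))
        b = poincare(make_segment(prv=x + 25.0))
        assert b["Sd1"] == pytest.approx(a["Sd1"], abs=1e-9)
        out_a = time_features(make_segment(prv=x))
        out_b = time_features(make_segment(prv=x + 25.0))
        assert out_b["RMSD"] == pytest.approx(out_a["RMSD"], abs=1e-9)
        assert out_b["Mean"] == pytest.approx(out_a["Mean"] + 25.0, abs=1e-9)

    def test_rhythm_class_separation(self, small_dataset):
        feats = small_dataset.features
        mean_et = feats.loc[feats["label"] == 3, "Mean"]
        mean_eb = feats.loc[feats["label"] == 2, "Mean"]
        assert mean_et.mean() > 140 * 0.9
        assert mean_eb.mean() < 40 * 1.1 + 30  # windows mix episode and background
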