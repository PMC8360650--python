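"""Pitch autocorrelation, tilt modelling and pattern classification."""

import numpy as np
import pytest

from kerafil import helix, simulate
from kerafil.core import Image2D, ParticleRecord, ParticleTable, PipelineConfig
from kerafil.helix import (apparent_pitch_curve, axial_autocorrelation,
                           classify_pattern, detect_pitch, estimate_tilt,
                           order_patterns, tilt_project)

PX = 2.206


def brute_force_acf(signal):
    """O(n²) direct-sum biased autocorrelation oracle."""
    s = signal - signal.mean()
    n = len(s)
    var = np.dot(s, s) / n
    out = np.empty(n // 2 + 1)
    for k in range(n // 2 + 1):
        acc = 0.0
        for i in range(n - k):
            acc += s[i] * s[i + k]
        out[k] = acc / (n * var)
    return out


class TestAxialAutocorrelation:
    def test_cosine_period_recovered(self, cosine_image):
        sp = axial_autocorrelation(cosine_image)
        assert sp.peak_lag_A == pytest.approx(163.0, abs=PX)

    def test_white_noise_has_no_peak(self):
        rng = np.random.default_rng(7)
        img = Image2D(rng.normal(size=(250, 250)), PX)
        sp = axial_autocorrelation(img)
        assert sp.peak_lag_A is None

    def test_matches_direct_sum_oracle(self):
        rng = np.random.default_rng(3)
        z = np.arange(200) * PX
        sig = (np.cos(2 * np.pi * z / 163.0)
               + 0.3 * np.cos(2 * np.pi * z / 81.5)
               + 0.1 * rng.normal(size=200))
        img = Image2D(np.tile(sig[:, None], (1, 64)), PX)
        sp = axial_autocorrelation(img, lateral_mask_A=64 * PX)
        oracle = brute_force_acf(sig)
        np.testing.assert_allclose(sp.acf, oracle, atol=1e-10)
        # the first qualifying peak is the fundamental, not the harmonic
        assert sp.peak_lag_A == pytest.approx(163.0, abs=2 * PX)

    def test_acf_normalization_bound(self, helical_class):
        sp = axial_autocorrelation(helical_class)
        assert sp.acf[0] == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.abs(sp.acf) <= 1.0 + 1e-9)

    def test_empty_mask_rejected(self, helical_class):
        with pytest.raises(ValueError):
            axial_autocorrelation(helical_class, lateral_mask_A=0.0)


class TestDetectPitch:
    def test_none_on_monotone_decay(self):
        lags = np.arange(100) * PX
        sp = helix.AutocorrSpectrum(lags, np.exp(-lags / 80.0))
        assert detect_pitch(sp) is None

    def test_recovery_under_noise_snr3(self):
        errors = []
        for seed in range(20):
            spec = simulate.FilamentSpec(pitch_A=140.0, noise_sigma=1 / 3,
                                         seed=seed)
            img = simulate.generate_filament_image(spec, 250, PX)
            sp = axial_autocorrelation(img)
            assert sp.peak_lag_A is not None
            errors.append(abs(sp.peak_lag_A - 140.0))
        assert np.mean(errors) < 3.0

    @pytest.mark.parametrize("pitch", [132.0, 140.0, 150.0, 163.0])
    def test_zero_noise_recovery_within_one_lag_step(self, pitch):
        img = simulate.generate_filament_image(
            simulate.FilamentSpec(pitch_A=pitch), 250, PX)
        sp = axial_autocorrelation(img)
        assert sp.peak_lag_A == pytest.approx(pitch, abs=PX)


class TestTiltProject:
    def test_zero_tilt_is_identity(self, helical_class):
        out = tilt_project(helical_class, 0.0)
        c = np.corrcoef(out.pixels.ravel(),
                        helical_class.pixels.ravel())[0, 1]
        assert c == pytest.approx(1.0, abs=1e-12)

    def test_34_degrees_shortens_163_to_about_132(self, helical_class):
        tilted = tilt_project(helical_class, 34.0)
        sp = axial_autocorrelation(tilted)
        # projection foreshortens the repeat; the published pairing is
        # 163 Å -> 132 Å at ~34° (cos model predicts 135.1 Å)
        assert sp.peak_lag_A == pytest.approx(132.0, abs=4.0)

    def test_60_degrees_halves_the_pitch(self, helical_class):
        tilted = tilt_project(helical_class, 60.0)
        sp = axial_autocorrelation(tilted, min_lag_A=50.0)
        assert sp.peak_lag_A == pytest.approx(81.5, abs=PX)

    def test_lateral_dimension_unchanged(self, helical_class):
        assert tilt_project(helical_class, 40.0).shape[1] == 250

    def test_tilt_composition_matches_product_of_cosines(self, helical_class):
        a = tilt_project(tilt_project(helical_class, 30.0), 25.0)
        sp_two = axial_autocorrelation(a)
        combined = np.degrees(np.arccos(np.cos(np.deg2rad(30))
                                        * np.cos(np.deg2rad(25))))
        b = tilt_project(helical_class, combined)
        sp_one = axial_autocorrelation(b)
        assert sp_two.peak_lag_A == pytest.approx(sp_one.peak_lag_A, abs=PX)

    def test_out_of_range_rejected(self, helical_class):
        with pytest.raises(ValueError):
            tilt_project(helical_class, 90.0)


class TestApparentPitchCurve:
    def test_monotone_and_anchored_at_zero(self):
        curve = apparent_pitch_curve(163.0, [0, 10, 20, 30, 40, 50],
                                     box_px=250)
        thetas, pitches = zip(*curve)
        assert pitches[0] == pytest.approx(163.0, abs=PX)
        valid = [p for p in pitches if p is not None]
        assert all(a >= b - PX for a, b in zip(valid, valid[1:]))

    def test_tilt_interval_mapping_into_pitch_band(self):
        # apparent pitch in [132, 163] corresponds to tilts [0, acos(132/163)]
        theta_max = np.degrees(np.arccos(132.0 / 163.0))
        assert theta_max == pytest.approx(35.9, abs=0.1)
        curve = apparent_pitch_curve(163.0, [theta_max], box_px=250)
        assert curve[0][1] == pytest.approx(132.0, abs=2 * PX)


class TestEstimateTilt:
    def test_equal_pitches_mean_no_tilt(self):
        assert estimate_tilt(163.0, 163.0) == 0.0

    def test_half_pitch_means_60_degrees(self):
        assert estimate_tilt(81.5, 163.0) == pytest.approx(60.0, abs=1e-9)

    def test_published_pitch_pair(self):
        # cos model: acos(132/163) = 35.9°, close to the quoted ~34°
        assert estimate_tilt(132.0, 163.0) == pytest.approx(35.9, abs=0.1)

    def test_super_reference_pitch_rejected(self):
        with pytest.raises(ValueError):
            estimate_tilt(170.0, 163.0)


class TestClassification:
    def test_strong_modulation_is_helical(self, config, helical_class):
        lab = classify_pattern(helical_class, config, class_id=1)
        assert lab.label == "helical"

    def test_featureless_ridge_is_straight(self, config):
        spec = simulate.FilamentSpec(modulation=0.0)
        img = simulate.generate_filament_image(spec, 250, PX)
        lab = classify_pattern(img, config, class_id=2)
        assert lab.label == "straight"

    def test_roc_separation_at_snr3(self, config):
        proms, truth = [], []
        for seed in range(25):
            for mod, is_helical in ((0.5, True), (0.0, False)):
                spec = simulate.FilamentSpec(modulation=mod,
                                             noise_sigma=1 / 3, seed=seed)
                img = simulate.generate_filament_image(spec, 250, PX)
                lab = classify_pattern(img, config)
                proms.append(lab.prominence)
                truth.append(is_helical)
        proms, truth = np.array(proms), np.array(truth)
        # rank-based AUC
        order = np.argsort(proms)
        ranks = np.empty(len(proms))
        ranks[order] = np.arange(1, len(proms) + 1)
        n_pos, n_neg = truth.sum(), (~truth).sum()
        auc = (ranks[truth].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        assert auc > 0.95


class TestOrderPatterns:
    def _table(self, labels_per_tube):
        recs, cid = [], 1
        for tube, labels in labels_per_tube.items():
            for i, _ in enumerate(labels):
                recs.append(ParticleRecord("m", 0, 0, 0, tube, i,
                                           class_id=cid))
                cid += 1
        return ParticleTable(recs, 1.0)

    def _labels(self, labels_per_tube):
        out, cid = {}, 1
        for labels in labels_per_tube.values():
            for lab in labels:
                out[cid] = helix.PatternLabel(cid, lab, 1.0)
                cid += 1
        return out

    def test_order_preserved_along_tube(self):
        seq_in = {0: ["helical", "helical", "straight", "straight",
                      "helical"]}
        seqs = order_patterns(self._table(seq_in), self._labels(seq_in))
        assert [lab for _, lab in seqs[0].entries] == seq_in[0]

    def test_two_tubes_give_two_sequences(self):
        seq_in = {0: ["helical"] * 3, 1: ["straight"] * 5}
        seqs = order_patterns(self._table(seq_in), self._labels(seq_in))
        assert len(seqs) == 2
        assert [len(s.entries) for s in seqs] == [3, 5]

    def test_shuffled_input_gives_identical_output(self):
        seq_in = {0: ["helical", "straight", "helical", "straight"]}
        table = self._table(seq_in)
        labels = self._labels(seq_in)
        shuffled = ParticleTable(table.records[::-1], 1.0)
        assert order_patterns(table, labels) == order_patterns(shuffled,
                                                               labels)

    def test_unlabeled_class_rejected(self):
        seq_in = {0: ["helical", "straight"]}
        with pytest.raises(ValueError, match="no labeled class"):
            order_patterns(self._table(seq_in), {})
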