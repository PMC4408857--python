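"""Surrogate generators, artifact injection, and study dataset shape."""

import numpy as np
import pytest

from eegosc.block import EEGBlock
from eegosc.features import BAND_NAMES, band_powers, feature_vector, sample_entropy
from eegosc.preprocessing import clean_block, detect_artifacts
from eegosc.synth import (
    ArtifactSpec,
    CONDITION_PARAMS,
    DEFAULT_PROFILES,
    SurrogateProfile,
    generate_model_blocks,
    generate_study_dataset,
    generate_surrogate_blocks,
    inject_artifacts,
)


class TestSurrogates:
    def test_round_trip_band_fractions(self):
        profile = DEFAULT_PROFILES["EC-CTL"]
        blocks = generate_surrogate_blocks(profile, 10, seed=2)
        measured = np.mean([band_powers(b) for b in blocks], axis=0)
        assert np.mean(np.abs(measured - np.array(profile.band_fractions))) < 0.03

    def test_ec_ctl_alpha_dominant(self):
        blocks = generate_surrogate_blocks(DEFAULT_PROFILES["EC-CTL"], 5, seed=1)
        for b in blocks:
            bp = band_powers(b)
            assert BAND_NAMES[int(np.argmax(bp))] == "alpha"

    def test_ec_ad_theta_at_least_alpha(self):
        blocks = generate_surrogate_blocks(DEFAULT_PROFILES["EC-AD"], 5, seed=1)
        bp = np.mean([band_powers(b) for b in blocks], axis=0)
        frac = dict(zip(BAND_NAMES, bp))
        assert frac["theta"] >= frac["alpha"]

    def test_eo_profiles_flat(self):
        for cond in ("EO-CTL", "EO-AD"):
            blocks = generate_surrogate_blocks(DEFAULT_PROFILES[cond], 5, seed=4)
            bp = np.mean([band_powers(b) for b in blocks], axis=0)
            frac = dict(zip(BAND_NAMES, bp))
            mid = [frac[n] for n in ("upper_delta", "theta", "alpha", "lower_beta")]
            assert max(mid) <= 0.35

    def test_all_power_in_alpha_without_floor(self):
        profile = SurrogateProfile("EC-CTL", (0, 0, 0, 1.0, 0, 0, 0),
                                   noise_floor=0.0)
        block = generate_surrogate_blocks(profile, 1, seed=9)[0]
        # leakage-free check: full-length periodogram is exactly in-band
        spec = np.abs(np.fft.rfft(block.data)) ** 2
        freqs = np.fft.rfftfreq(block.n_samples, 1 / block.fs)
        in_alpha = spec[(freqs >= 8) & (freqs < 13)].sum()
        total = spec[(freqs >= 1) & (freqs <= 60)].sum()
        assert in_alpha / total > 0.999
        # the 2-s Hann Welch estimator smears band edges by a few percent
        frac = dict(zip(BAND_NAMES, band_powers(block)))
        assert frac["alpha"] > 0.9

    def test_longer_blocks_converge_closer(self):
        profile = DEFAULT_PROFILES["EO-CTL"]
        target = np.array(profile.band_fractions)

        def mean_err(duration, n=8):
            p = SurrogateProfile(profile.condition, profile.band_fractions,
                                 profile.noise_floor, duration=duration)
            blocks = generate_surrogate_blocks(p, n, seed=12)
            return np.mean([np.abs(band_powers(b) - target).mean()
                            for b in blocks])

        assert mean_err(160.0) < mean_err(40.0)

    def test_seed_determinism(self):
        a = generate_surrogate_blocks(DEFAULT_PROFILES["EC-AD"], 3, seed=7)
        b = generate_surrogate_blocks(DEFAULT_PROFILES["EC-AD"], 3, seed=7)
        for x, y in zip(a, b):
            assert np.array_equal(x.data, y.data)

    def test_blocks_pass_feature_extraction(self):
        for cond, profile in DEFAULT_PROFILES.items():
            block = generate_surrogate_blocks(profile, 1, seed=8)[0]
            fv = feature_vector(block)
            assert np.isfinite(fv.sampen)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            SurrogateProfile("EC-CTL", (0.5, 0.5, 0.5, 0, 0, 0, 0))


class TestModelBlocks:
    def test_zero_blocks_empty(self, feasible_params):
        assert generate_model_blocks(feasible_params, 0, seed=1) == []

    def test_determinism_and_labels(self, feasible_params, short_cfg):
        a = generate_model_blocks(feasible_params, 3, seed=5, config=short_cfg,
                                  condition="EC-CTL")
        b = generate_model_blocks(feasible_params, 3, seed=5, config=short_cfg,
                                  condition="EC-CTL")
        for x, y in zip(a, b):
            assert np.array_equal(x.data, y.data)
            assert (x.condition, x.group) == ("EC", "CTL")

    def test_blocks_are_independent(self, feasible_params, short_cfg):
        blocks = generate_model_blocks(feasible_params, 2, seed=5, config=short_cfg)
        assert not np.array_equal(blocks[0].data, blocks[1].data)


class TestArtifacts:
    def test_rate_zero_unchanged(self, rng):
        block = EEGBlock(rng.standard_normal(1000), 125.0)
        out, mask = inject_artifacts(block, ArtifactSpec(rate=0), seed=1)
        assert np.array_equal(out.data, block.data)
        assert not mask.any()

    def test_detector_recovers_most_contaminated_samples(self):
        """Injected-transient samples that are observably beyond the
        4.5-sigma threshold of the clean distribution are flagged by the
        (robust two-pass) detector at a >= 95% rate over 50 trials."""
        profile = DEFAULT_PROFILES["EC-CTL"]
        hits, total = 0, 0
        for seed in range(50):
            clean = generate_surrogate_blocks(profile, 1, seed=seed)[0]
            dirty, truth = inject_artifacts(
                clean, ArtifactSpec(rate=3, amplitude=8.0, width=12), seed=seed + 500)
            mask = detect_artifacts(dirty, robust=True)
            observable = truth & (np.abs(dirty.data - clean.data.mean())
                                  > 4.5 * clean.data.std())
            hits += int((mask.flags & observable).sum())
            total += int(observable.sum())
        assert total > 0
        assert hits / total >= 0.95

    def test_repair_preserves_sample_entropy(self):
        profile = DEFAULT_PROFILES["EO-CTL"]
        diffs = []
        for seed in range(20):
            clean = generate_surrogate_blocks(profile, 1, seed=seed)[0]
            dirty, _ = inject_artifacts(clean, ArtifactSpec(), seed=seed + 900)
            repaired = clean_block(dirty)
            diffs.append(abs(sample_entropy(repaired.data)
                             - sample_entropy(clean.data)))
        assert np.mean(diffs) < 0.1

    def test_amplitude_must_exceed_detection_threshold(self):
        with pytest.raises(ValueError):
            ArtifactSpec(amplitude=3.0)


class TestStudyDataset:
    def test_default_shape(self):
        blocks = generate_study_dataset(seed=3)
        labels = [f"{b.condition}-{b.group}" for b in blocks]
        assert labels.count("EC-CTL") == 20
        assert labels.count("EO-CTL") == 20
        assert labels.count("EC-AD") == 10
        assert labels.count("EO-AD") == 10

    def test_condition_params_table_values(self):
        # the published group-mean parameter sets used as simulation inputs
        p = CONDITION_PARAMS["EC-CTL"]
        assert (p.k1, p.k2, p.mu) == (7286.5, 4523.5, 2.34)
        assert set(CONDITION_PARAMS) == {"EC-CTL", "EO-CTL", "EC-AD", "EO-AD"}
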