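import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirtriad.errors import ArgumentError, ConfigurationError
from mirtriad.synthetic import (
    PlantedEffect,
    SimulationConfig,
    pool_patients,
    read_truth_table,
    simulate_cohort,
    write_truth_table,
)
from mirtriad.types import AssayRole

from conftest import make_ct_matrix, make_manifest


def small_config(**kw):
    defaults = dict(
        n_targets=10,
        group_sizes={"LM": 3, "PER": 3, "M0": 3},
        pool_size=3,
        baseline_ct_range=(20.0, 28.0),
        noise_sd=0.0,
        detection_ceiling=None,
        seed=0,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    def test_pool_larger_than_group(self):
        with pytest.raises(ConfigurationError, match="pool_size"):
            small_config(group_sizes={"LM": 2, "PER": 3, "M0": 3})

    def test_bad_baseline_range(self):
        with pytest.raises(ConfigurationError, match="baseline_ct_range"):
            small_config(baseline_ct_range=(30.0, 20.0))

    def test_negative_noise(self):
        with pytest.raises(ConfigurationError, match="noise_sd"):
            small_config(noise_sd=-0.1)

    def test_bad_probability(self):
        with pytest.raises(ConfigurationError, match="classifier_positive_prob"):
            small_config(classifier_positive_prob={"LM": 1.3})

    def test_effect_on_control_rejected(self):
        with pytest.raises(ConfigurationError, match="RNU44"):
            small_config(planted_effects=[PlantedEffect("RNU44", "PER", 2.0)])


class TestSimulateCohort:
    def test_zero_noise_zero_effect_constant_rows(self):
        ct, _, _ = simulate_cohort(small_config())
        targets = ct.ids_with_role(AssayRole.TARGET)
        for aid in targets:
            row = ct.values.loc[aid]
            assert row.nunique() == 1

    def test_zero_noise_planted_effect_exact_shift(self):
        aid = "hsa-miR-sim-0001"
        cfg = small_config(planted_effects=[PlantedEffect(aid, "PER", 2.0)])
        ct, manifest, _ = simulate_cohort(cfg)
        lm = manifest.samples_in_group("LM")[0]
        per = manifest.samples_in_group("PER")[0]
        assert ct.values.at[aid, lm] - ct.values.at[aid, per] == pytest.approx(2.0)

    def test_monte_carlo_mean_shift(self):
        # 200 seeds: mean CT_LM - CT_PER for the affected assay should sit
        # within 3 standard errors of the planted +2 cycles
        aid = "hsa-miR-sim-0001"
        noise = 0.25
        diffs = []
        for seed in range(200):
            cfg = small_config(
                n_targets=2,
                noise_sd=noise,
                planted_effects=[PlantedEffect(aid, "PER", 2.0)],
                seed=seed,
            )
            ct, manifest, _ = simulate_cohort(cfg)
            lm = manifest.samples_in_group("LM")[0]
            per = manifest.samples_in_group("PER")[0]
            diffs.append(ct.values.at[aid, lm] - ct.values.at[aid, per])
        se = noise * math.sqrt(2) / math.sqrt(len(diffs))
        assert abs(np.mean(diffs) - 2.0) < 3 * se

    def test_negative_control_always_non_detected(self):
        ct, _, _ = simulate_cohort(small_config(noise_sd=0.5, seed=9))
        assert ct.values.loc["ath-miR-159a"].isna().all()

    def test_detection_ceiling(self):
        cfg = small_config(baseline_ct_range=(34.0, 39.9), detection_ceiling=35.0, seed=2)
        ct, _, _ = simulate_cohort(cfg)
        vals = ct.values.loc[ct.ids_with_role(AssayRole.TARGET)]
        assert (vals.fillna(0) <= 35.0).all().all()
        assert vals.isna().any().any()

    def test_housekeepers_have_no_group_effect(self):
        cfg = small_config(planted_effects=[PlantedEffect("hsa-miR-sim-0001", "PER", 3.0)])
        ct, _, _ = simulate_cohort(cfg)
        for hk in ("RNU44", "RNU48", "U6"):
            assert ct.values.loc[hk].nunique() == 1  # zero noise, no shift

    def test_determinism(self):
        a = simulate_cohort(small_config(noise_sd=0.3, seed=7))
        b = simulate_cohort(small_config(noise_sd=0.3, seed=7))
        assert a[0].values.equals(b[0].values)
        assert a[1].frame.equals(b[1].frame)

    def test_classifier_probabilities_extreme(self):
        cfg = small_config(
            group_sizes={"LM": 5, "PER": 5, "M0": 3},
            classifier_positive_prob={"LM": 1.0, "PER": 0.0, "M0": 0.0},
            seed=4,
        )
        _, manifest, _ = simulate_cohort(cfg)
        f = manifest.frame
        assert (f.loc[f["group"] == "LM", "classifier_positive"] == 1).all()
        assert (f.loc[f["group"] != "LM", "classifier_positive"] == 0).all()


class TestPoolPatients:
    def patients(self, rows):
        samples = ["p1", "p2", "p3"]
        ct = make_ct_matrix({"m1": rows, "RNU44": [20, 20, 20]}, samples)
        manifest = make_manifest({s: {"group": "LM"} for s in samples})
        return ct, manifest

    def test_identical_values_identity(self):
        ct, manifest = self.patients([20.0, 20.0, 20.0])
        pooled, _, _ = pool_patients(ct, manifest, 3, seed=0)
        assert pooled.values.at["m1", "LM"] == pytest.approx(20.0)

    def test_linear_space_mean(self):
        # oracle: direct arithmetic -log2(mean(2^-20, 2^-20, 2^-23))
        ct, manifest = self.patients([20.0, 20.0, 23.0])
        pooled, _, _ = pool_patients(ct, manifest, 3, seed=0)
        expected = -math.log2((2**-20.0 + 2**-20.0 + 2**-23.0) / 3)
        assert pooled.values.at["m1", "LM"] == pytest.approx(expected, abs=1e-12)
        assert round(expected, 3) == 20.497

    def test_non_detected_contributes_zero(self):
        ct, manifest = self.patients([20.0, np.nan, 20.0])
        pooled, _, _ = pool_patients(ct, manifest, 3, seed=0)
        expected = -math.log2((2**-20.0 + 0 + 2**-20.0) / 3)
        assert pooled.values.at["m1", "LM"] == pytest.approx(expected, abs=1e-12)

    def test_all_non_detected_pools_non_detected(self):
        ct, manifest = self.patients([np.nan, np.nan, np.nan])
        pooled, _, _ = pool_patients(ct, manifest, 3, seed=0)
        assert math.isnan(pooled.values.at["m1", "LM"])

    def test_group_too_small(self):
        ct, manifest = self.patients([20.0, 20.0, 20.0])
        with pytest.raises(ArgumentError, match="LM"):
            pool_patients(ct, manifest, 4, seed=0)

    def test_selection_reproducible_by_seed(self):
        ct, manifest, _ = simulate_cohort(small_config(group_sizes={"LM": 6, "PER": 6, "M0": 3}))
        _, _, c1 = pool_patients(ct, manifest, 3, seed=5)
        _, _, c2 = pool_patients(ct, manifest, 3, seed=5)
        _, _, c3 = pool_patients(ct, manifest, 3, seed=6)
        assert c1 == c2
        assert all(len(v) == 3 for v in c3.values())

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(st.floats(min_value=5, max_value=39), min_size=3, max_size=3),
        st.integers(min_value=0, max_value=2),
        st.floats(min_value=0.1, max_value=5),
    )
    def test_pooling_bounds_and_monotonicity(self, cts, idx, dec):
        ct, manifest = self.patients(list(cts))
        pooled, _, _ = pool_patients(ct, manifest, 3, seed=0)
        v = pooled.values.at["m1", "LM"]
        assert min(cts) - 1e-9 <= v <= max(cts) + 1e-9
        # decreasing one contributing CT never increases the pooled CT
        lowered = list(cts)
        lowered[idx] = max(lowered[idx] - dec, 1.0)
        ct2, manifest2 = self.patients(lowered)
        pooled2, _, _ = pool_patients(ct2, manifest2, 3, seed=0)
        assert pooled2.values.at["m1", "LM"] <= v + 1e-9


class TestTruthTable:
    def test_roundtrip(self):
        truth = [PlantedEffect("hsa-miR-sim-0001", "PER", 2.5),
                 PlantedEffect("hsa-miR-sim-0002", "LM", -1.5)]
        buf = io.StringIO()
        write_truth_table(truth, buf)
        buf.seek(0)
        assert read_truth_table(buf) == truth


class TestEffectRecovery:
    def test_noiseless_pipeline_recovers_planted_log2fc_exactly(self):
        """With zero noise and no pooling loss the estimated log2 fold change
        equals the planted value for every affected assay."""
        from mirtriad.quantify import QuantConfig, delta_ct, detection_filter
        from mirtriad.screen import ScreenConfig, call_contrast

        effects = [
            PlantedEffect("hsa-miR-sim-0001", "PER", 2.0),
            PlantedEffect("hsa-miR-sim-0002", "PER", -1.5),
            PlantedEffect("hsa-miR-sim-0003", "LM", 3.0),
        ]
        cfg = small_config(baseline_ct_range=(20.0, 26.0), planted_effects=effects)
        ct, manifest, _ = simulate_cohort(cfg)
        pooled, _, _ = pool_patients(ct, manifest, 3, seed=0)
        _, filtered = detection_filter(pooled, QuantConfig(), pooled.samples)
        norm = delta_ct(filtered)
        results = {r.assay_id: r for r in call_contrast(norm, ("PER", "M0"), ScreenConfig())}
        assert math.log2(results["hsa-miR-sim-0001"].fold_change) == pytest.approx(2.0, abs=1e-9)
        assert math.log2(results["hsa-miR-sim-0002"].fold_change) == pytest.approx(-1.5, abs=1e-9)
        results_lm = {r.assay_id: r for r in call_contrast(norm, ("LM", "M0"), ScreenConfig())}
        assert math.log2(results_lm["hsa-miR-sim-0003"].fold_change) == pytest.approx(3.0, abs=1e-9)
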