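import math

import numpy as np
import pandas as pd
import pytest

from mirqpcr import (
    SimulationConfig,
    compare_profiles,
    inject_hemolysis,
    normalize_profile,
    pool_groups,
    pool_samples,
    simulate_cohort,
)
from mirqpcr.panel_io import CtMatrix
from mirqpcr.qc import qc_matrix
from mirqpcr.simulate import fr_to_log2, log2_to_fr


def _small_config(**overrides):
    defaults = dict(
        group_sizes={"control": 3, "IFG": 3, "T2D": 3},
        seed=1,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "overrides",
        [
            {"group_sizes": {"control": 0}},
            {"noise_sd": -1.0},
            {"hemolysis_shift": -2.0},
            {"reference_group": "nope"},
            {"effects": {"not-a-panel-assay": {"T2D": 1.0}}},
            {"effects": {"hsa-miR-1281": {"unknown-group": 1.0}}},
            {"censor_ct": 30.0},
        ],
    )
    def test_invalid_configs_rejected(self, overrides):
        with pytest.raises(ValueError):
            _small_config(**overrides)


class TestDeterminism:
    def test_same_seed_same_output(self):
        m1, t1 = simulate_cohort(_small_config())
        m2, t2 = simulate_cohort(_small_config())
        pd.testing.assert_frame_equal(m1.values, m2.values)
        pd.testing.assert_series_equal(t1.offsets, t2.offsets)

    def test_different_seed_different_output(self):
        m1, _ = simulate_cohort(_small_config(seed=1))
        m2, _ = simulate_cohort(_small_config(seed=2))
        assert not m1.values.equals(m2.values)


class TestNullModel:
    def test_zero_everything_gives_identical_samples_and_unit_fr(self):
        cfg = _small_config(noise_sd=0.0, offset_sd=0.0, effects={})
        matrix, truth = simulate_cohort(cfg)
        ctrl = matrix.group_samples("control")
        t2d = matrix.group_samples("T2D")
        pd.testing.assert_series_equal(
            matrix.values[ctrl[0]], matrix.values[ctrl[1]], check_names=False
        )
        pooled = pool_groups(matrix)
        panel = cfg.panel
        profiles = {
            g: normalize_profile(pooled.sample_profile(g), panel, name=g)
            for g in ("control", "T2D")
        }
        records = compare_profiles(profiles["T2D"], profiles["control"], panel=panel)
        frs = [r.fold_regulation for r in records if r.label != "not_evaluable"]
        assert frs and np.allclose(frs, 1.0, atol=1e-9)

    def test_single_planted_effect_closed_form(self):
        # e = +3 in T2D, spike-in normalization (effect-free reference):
        # pooled FR must be exactly 2^3 = +8
        cfg = _small_config(
            noise_sd=0.0, offset_sd=0.0,
            effects={"hsa-miR-1281": {"T2D": 3.0}},
        )
        matrix, _ = simulate_cohort(cfg)
        pooled = pool_groups(matrix)
        profiles = {
            g: normalize_profile(
                pooled.sample_profile(g), cfg.panel, method="spike_in", name=g
            )
            for g in ("control", "T2D")
        }
        records = {
            r.mirna: r
            for r in compare_profiles(profiles["T2D"], profiles["control"])
        }
        assert records["hsa-miR-1281"].fold_regulation == pytest.approx(8.0, abs=1e-9)


class TestPooling:
    def _matrix(self, cts_by_sample, group="g"):
        values = pd.DataFrame(cts_by_sample)
        groups = pd.Series(group, index=values.columns)
        return CtMatrix(values=values, groups=groups)

    def test_identical_profiles_identity(self):
        matrix = self._matrix({"s1": [20.0, 25.0], "s2": [20.0, 25.0]})
        pooled = pool_samples(matrix, "g")
        assert pooled.tolist() == pytest.approx([20.0, 25.0], abs=1e-9)

    def test_linear_scale_formula(self):
        matrix = self._matrix({"s1": [20.0], "s2": [22.0]})
        pooled = pool_samples(matrix, "g")
        expected = -math.log2((2.0 ** -20 + 2.0 ** -22) / 2.0)
        assert pooled.iloc[0] == pytest.approx(expected)
        assert pooled.iloc[0] == pytest.approx(20.678, abs=1e-3)

    def test_pooled_between_min_and_max(self):
        rng = np.random.default_rng(3)
        values = pd.DataFrame(
            rng.uniform(18, 35, size=(25, 6)),
            columns=[f"s{i}" for i in range(6)],
        )
        matrix = CtMatrix(values=values, groups=pd.Series("g", index=values.columns))
        pooled = pool_samples(matrix, "g")
        assert (pooled >= values.min(axis=1) - 1e-9).all()
        assert (pooled <= values.max(axis=1) + 1e-9).all()

    def test_partial_detection_uses_detected_samples_only(self):
        matrix = self._matrix({"s1": [math.nan], "s2": [25.0]})
        pooled = pool_samples(matrix, "g")
        assert pooled.iloc[0] == pytest.approx(25.0)

    def test_all_undetermined_stays_undetermined(self):
        matrix = self._matrix({"s1": [math.nan], "s2": [math.nan]})
        assert math.isnan(pool_samples(matrix, "g").iloc[0])

    def test_empty_group_raises(self):
        matrix = self._matrix({"s1": [20.0]})
        with pytest.raises(ValueError):
            pool_samples(matrix, "other")


class TestHemolysisInjection:
    def test_shift_moves_only_the_red_cell_mirna(self):
        profile = pd.Series({"hsa-miR-451a": 24.0, "hsa-miR-23a-3p": 26.0})
        out = inject_hemolysis(profile, 6.0)
        assert out["hsa-miR-451a"] == pytest.approx(18.0)
        assert out["hsa-miR-23a-3p"] == 26.0
        assert profile["hsa-miR-451a"] == 24.0  # input untouched

    def test_zero_shift_is_identity(self):
        profile = pd.Series({"hsa-miR-451a": 24.0})
        pd.testing.assert_series_equal(inject_hemolysis(profile, 0.0), profile)

    def test_absent_mirna_raises(self):
        with pytest.raises(KeyError):
            inject_hemolysis(pd.Series({"miR-x": 20.0}), 3.0)

    def test_qc_flags_exactly_the_injected_samples(self):
        contaminated = ("control_02", "T2D_01")
        cfg = _small_config(hemolysis_samples=contaminated, hemolysis_shift=6.0)
        matrix, _ = simulate_cohort(cfg)
        report = qc_matrix(matrix, cfg.panel)
        flagged = set(report.index[~report["hemolysis_pass"]])
        assert flagged == set(contaminated)


class TestTruthRecovery:
    def test_zero_noise_global_mean_recovery_is_exact(self):
        cfg = _small_config(noise_sd=0.0, offset_sd=0.0)
        matrix, truth = simulate_cohort(cfg)
        pooled = pool_groups(matrix)
        profiles = {
            g: normalize_profile(pooled.sample_profile(g), cfg.panel, name=g)
            for g in pooled.samples
        }
        for test, ref in (("IFG", "control"), ("T2D", "control"), ("T2D", "IFG")):
            records = {
                r.mirna: r.fold_regulation
                for r in compare_profiles(profiles[test], profiles[ref], panel=cfg.panel)
                if r.label != "not_evaluable"
            }
            expected = truth.expected_fr(test, ref, "global_mean")
            assert set(records) == set(expected.index)
            for mirna, fr in expected.items():
                assert records[mirna] == pytest.approx(fr, rel=1e-9), mirna

    def test_offsets_do_not_move_global_mean_results(self):
        # baselines bounded away from the detection and censoring cut-offs
        # so that per-sample offsets cannot flip any assay's detection
        # status — the domain on which the shift-cancellation holds
        base = _small_config(
            noise_sd=0.0, offset_sd=0.0, baseline_low=(30.2, 32.5)
        )
        shifted = _small_config(
            noise_sd=0.0, offset_sd=0.8, baseline_low=(30.2, 32.5)
        )
        frs = {}
        for tag, cfg in (("flat", base), ("offset", shifted)):
            matrix, _ = simulate_cohort(cfg)
            pooled = pool_groups(matrix)
            profiles = {
                g: normalize_profile(pooled.sample_profile(g), cfg.panel, name=g)
                for g in ("control", "T2D")
            }
            frs[tag] = {
                r.mirna: r.fold_regulation
                for r in compare_profiles(
                    profiles["T2D"], profiles["control"], panel=cfg.panel
                )
                if r.label != "not_evaluable"
            }
        common = set(frs["flat"]) & set(frs["offset"])
        assert len(common) > 100
        for mirna in common:
            assert frs["flat"][mirna] == pytest.approx(frs["offset"][mirna], rel=1e-6)

    def test_effect_free_controls_make_methods_agree(self):
        # noiseless cohort, effects only on targets: reference-gene ddCt
        # equals spike-in ddCt exactly, and both equal the planted closed form
        cfg = _small_config(noise_sd=0.0, offset_sd=0.0)
        matrix, truth = simulate_cohort(cfg)
        pooled = pool_groups(matrix)
        planted = truth.planted_fr("T2D", "control")
        for method in ("reference_genes", "spike_in"):
            profiles = {
                g: normalize_profile(
                    pooled.sample_profile(g), cfg.panel, method=method, name=g
                )
                for g in ("control", "T2D")
            }
            records = {
                r.mirna: r.fold_regulation
                for r in compare_profiles(
                    profiles["T2D"], profiles["control"], panel=cfg.panel
                )
                if r.label != "not_evaluable"
            }
            for mirna in cfg.effects:
                assert records[mirna] == pytest.approx(
                    planted[mirna], rel=1e-9
                ), (method, mirna)


def test_fr_log2_round_trip():
    for fr in (124.8, 2.0, 1.0, -2.0, -52.22):
        assert log2_to_fr(fr_to_log2(fr)) == pytest.approx(fr, rel=1e-12)
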