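import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirqpcr import (
    classify_contrast,
    compare_profiles,
    condition_specific_set,
    delta_delta_ct,
    fold_regulation,
    high_stringency_set,
    normalization_concordance,
    packaged_fixture,
    progression_signature,
    records_from_fixture,
)
from mirqpcr.diffexp import classify_fr, count_labels
from mirqpcr.normalize import NormalizedProfile

PROGRESSION_NINE = (
    "hsa-miR-3610", "hsa-miR-3200-5p", "hsa-miR-4651", "hsa-miR-3135b",
    "hsa-miR-1281", "hsa-miR-4301", "hsa-miR-195-5p", "hsa-miR-523-5p",
    "hsa-let-7a-5p",
)


def _profile(dct: dict, method="global_mean", name="p"):
    return NormalizedProfile(
        name=name, method=method, reference_value=25.0,
        dct=pd.Series(dct, dtype=float),
    )


class TestFoldRegulation:
    @pytest.mark.parametrize(
        "ddct, fc, fr",
        [(-1.0, 2.0, 2.0), (1.0, 0.5, -2.0), (0.0, 1.0, 1.0)],
    )
    def test_closed_form(self, ddct, fc, fr):
        got_fc, got_fr = fold_regulation(ddct)
        assert got_fc == pytest.approx(fc)
        assert got_fr == pytest.approx(fr)

    def test_inverts_to_table_scale(self):
        # a ddCt of -log2(124.8) must read back as +124.8 fold regulation
        _, fr = fold_regulation(-math.log2(124.8))
        assert fr == pytest.approx(124.8, rel=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            fold_regulation(math.inf)

    @given(ddct=st.floats(-20, 20, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_algebraic_invariants(self, ddct):
        fc, fr = fold_regulation(ddct)
        assert fc > 0
        assert abs(fr) >= 1
        assert fc * 2.0 ** ddct == pytest.approx(1.0, abs=1e-12)
        # antisymmetry: reversing the contrast flips the sign unless FC = 1
        _, fr_rev = fold_regulation(-ddct)
        if fc == 1.0:
            assert fr == fr_rev == 1.0
        else:
            assert fr_rev == pytest.approx(-fr, rel=1e-9)


class TestDeltaDeltaCt:
    def test_simple_difference(self):
        ddct = delta_delta_ct(_profile({"m": 3.0}), _profile({"m": 5.0}))
        assert ddct["m"] == pytest.approx(-2.0)

    def test_method_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            delta_delta_ct(
                _profile({"m": 1.0}), _profile({"m": 1.0}, method="spike_in")
            )

    def test_undetected_in_one_side_not_evaluable(self, tiny_panel):
        test = _profile({"miR-A": 1.0, "miR-B": 2.0})
        ref = _profile({"miR-A": 0.0})
        records = {r.mirna: r for r in compare_profiles(test, ref, panel=tiny_panel)}
        assert records["miR-B"].label == "not_evaluable"
        assert records["miR-A"].label != "not_evaluable"

    def test_additivity_across_three_groups(self):
        rng = np.random.default_rng(5)
        assays = [f"m{i}" for i in range(40)]
        profiles = {
            g: _profile(dict(zip(assays, rng.normal(0, 2, 40))), name=g)
            for g in ("ctrl", "ifg", "t2d")
        }
        d_ti = delta_delta_ct(profiles["t2d"], profiles["ifg"])
        d_tc = delta_delta_ct(profiles["t2d"], profiles["ctrl"])
        d_ic = delta_delta_ct(profiles["ifg"], profiles["ctrl"])
        np.testing.assert_allclose(d_ti, d_tc - d_ic, atol=1e-9)


class TestClassification:
    def test_printed_table_counts(self):
        counts = {
            name: count_labels(records_from_fixture(packaged_fixture(name)))
            for name in ("ifg_vs_control", "t2d_vs_ifg")
        }
        assert counts["ifg_vs_control"]["up"] == 95
        assert counts["ifg_vs_control"]["down"] == 54
        assert counts["t2d_vs_ifg"]["up"] == 49
        assert counts["t2d_vs_ifg"]["down"] == 33

    @pytest.mark.parametrize(
        "fr, label",
        [(1.99, "unchanged"), (2.0, "up"), (-2.0, "down"), (-1.99, "unchanged"),
         (2.004, "up")],  # rounds to 2.00 at printed precision
    )
    def test_boundary_contract(self, fr, label):
        assert classify_fr(fr) == label

    def test_raising_threshold_never_adds_members(self):
        records = records_from_fixture(packaged_fixture("ifg_vs_control"))
        for lo, hi in [(2, 5), (5, 10), (10, 20)]:
            lo_set = {
                r.mirna for r in classify_contrast(records, threshold=lo)
                if r.label in ("up", "down")
            }
            hi_set = {
                r.mirna for r in classify_contrast(records, threshold=hi)
                if r.label in ("up", "down")
            }
            assert hi_set <= lo_set


class TestSignatures:
    def test_high_stringency_on_printed_column(self):
        records = records_from_fixture(packaged_fixture("ifg_vs_control"))
        sig = high_stringency_set({"ifg_vs_control": records})
        # printed IFG-vs-control values with |FR| >= 10: 18 over, 5 under
        ups = [m for m in sig.selected if sig.evidence[m]["fold_regulation"]["ifg_vs_control"] > 0]
        assert len(ups) == 18
        assert len(sig) == 23

    def test_threshold_one_selects_everything(self):
        records = records_from_fixture(packaged_fixture("t2d_vs_ifg"))
        sig = high_stringency_set({"c": records}, threshold=1.0)
        assert len(sig) == len(records)

    def test_selects_only_at_or_above_cutoff(self):
        records = classify_contrast(
            records_from_fixture_dict({"a": 12.0, "b": 9.9})
        )
        sig = high_stringency_set({"c": records})
        assert sig.selected == ["a"]

    def test_progression_requires_strict_increase(self):
        ifg = classify_contrast(records_from_fixture_dict({"a": 5.0, "b": 3.0}))
        t2d = classify_contrast(records_from_fixture_dict({"a": 5.0, "b": 7.0}))
        sig = progression_signature(ifg, t2d)
        assert sig.selected == ["b"]

    def test_progression_nine_from_printed_tables(self):
        ifg = records_from_fixture(packaged_fixture("ifg_vs_control"))
        t2d = records_from_fixture(packaged_fixture("t2d_vs_control"))
        sig = progression_signature(ifg, t2d)
        for mirna in PROGRESSION_NINE:
            assert mirna in sig, mirna
        assert sig.evidence["hsa-miR-1281"]["fr_ifg_vs_ctrl"] == pytest.approx(7.85)
        assert sig.evidence["hsa-miR-1281"]["fr_t2d_vs_ctrl"] == pytest.approx(14.9)

    def test_condition_specific_rule(self):
        focal = classify_contrast(
            records_from_fixture_dict({"up1": 3.62, "dn1": -2.64, "both": 2.5})
        )
        other = classify_contrast(
            records_from_fixture_dict({"up1": 1.9, "dn1": -1.3, "both": 2.5})
        )
        sig = condition_specific_set(focal, other)
        assert sig.selected == ["dn1", "up1"]
        assert sig.evidence["up1"]["direction"] == "up"
        assert sig.evidence["dn1"]["direction"] == "down"

    def test_condition_specific_sign_disagreement_excluded(self):
        focal = classify_contrast(records_from_fixture_dict({"m": 2.5}))
        other = classify_contrast(records_from_fixture_dict({"m": -1.5}))
        assert len(condition_specific_set(focal, other)) == 0


class TestConcordance:
    def test_identity(self):
        records = records_from_fixture(packaged_fixture("t2d_vs_ifg"))
        reports = normalization_concordance(
            {"global_mean": records, "reference_genes": records}
        )
        assert reports[0].label_agreement == 1.0
        assert reports[0].sign_agreement == 1.0
        assert reports[0].n_a_leq_b == reports[0].n_common

    def test_one_sign_flip_among_ten(self):
        frs = {f"m{i}": 4.0 for i in range(9)}
        a = classify_contrast(records_from_fixture_dict({**frs, "m9": 4.0}))
        b = classify_contrast(records_from_fixture_dict({**frs, "m9": -4.0}))
        report = normalization_concordance({"global_mean": a, "other": b})[0]
        assert report.sign_agreement == pytest.approx(0.9)

    def test_disjoint_assay_sets_raise(self):
        a = classify_contrast(records_from_fixture_dict({"x": 2.0}))
        b = classify_contrast(records_from_fixture_dict({"y": 2.0}))
        with pytest.raises(ValueError):
            normalization_concordance({"global_mean": a, "other": b})


def records_from_fixture_dict(frs: dict):
    from mirqpcr.panel_io import ComparisonFixture

    return records_from_fixture(
        ComparisonFixture(contrast="test", fold_regulation=frs)
    )
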