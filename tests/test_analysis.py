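import math
import random

import numpy as np
import pytest

from htearray import (
    AnalysisError,
    AssayControls,
    Calibration,
    FitError,
    PlateFormat,
    Reagent,
    ReagentClass,
    ResultRecord,
    TruthModel,
    WellAddress,
    assay_yield,
    fit_dose_response,
    percent_inhibition,
    product_is_ratio,
    read_results,
    replicate_agreement,
    selectivity,
    synth_results,
    top_performers,
    z_prime,
)
from htearray.analysis import four_pl

P24 = PlateFormat(24)
PRODUCT = Reagent(name="ester", molecular_weight=200.0, reagent_class=ReagentClass.OTHER)


class TestReadResults:
    def test_reads_channels_from_header(self, tmp_path):
        path = tmp_path / "res.csv"
        lines = ["well,area_product,area_is"]
        for r in "ABCD":
            for c in range(1, 7):
                lines.append(f"{r}{c},{50 + c},100")
        path.write_text("\n".join(lines) + "\n")
        records = read_results(path, P24)
        assert len(records) == 24
        assert set(records[0].channels) == {"area_product", "area_is"}

    def test_duplicate_well_rejected(self, tmp_path):
        path = tmp_path / "res.csv"
        path.write_text("well,v\nA1,1\nA1,2\n")
        with pytest.raises(AnalysisError, match="duplicate"):
            read_results(path, P24)

    def test_empty_cell_is_missing_not_zero(self, tmp_path):
        path = tmp_path / "res.csv"
        path.write_text("well,a,b\nA1,,5\n")
        (rec,) = read_results(path, P24)
        assert rec.get("a") is None
        assert rec.get("b") == 5.0

    def test_non_numeric_cell_rejected(self, tmp_path):
        path = tmp_path / "res.csv"
        path.write_text("well,a\nA1,high\n")
        with pytest.raises(AnalysisError, match="high"):
            read_results(path, P24)


class TestRatioAndYield:
    @pytest.mark.parametrize("p,i,expected", [(50, 100, 0.5), (0, 100, 0.0), (47, 100, 0.47)])
    def test_product_is_ratio(self, p, i, expected):
        assert product_is_ratio(p, i) == pytest.approx(expected)

    def test_zero_is_area_rejected(self):
        with pytest.raises(AnalysisError):
            product_is_ratio(10, 0)

    def test_assay_yield_calibration(self):
        cal = Calibration(product=PRODUCT, reference_ratio=0.5)
        assert assay_yield(0.25, cal) == pytest.approx(50.0)
        assert assay_yield(0.0, cal) == 0.0
        assert assay_yield(0.5, cal) == pytest.approx(100.0)
        assert assay_yield(0.6, cal) > 100.0  # flagged upstream, not clipped

    def test_ratio_and_yield_scale_invariant(self):
        cal = Calibration(product=PRODUCT, reference_ratio=0.5)
        for c in (0.1, 3.0, 250.0):
            assert product_is_ratio(47 * c, 100 * c) == pytest.approx(0.47)
        assert assay_yield(product_is_ratio(47, 100), cal) == pytest.approx(94.0)


class TestSelectivity:
    def test_regioisomer_fractions(self):
        fr = selectivity({"gamma": 80.0, "alpha": 15.0, "olefin": 5.0})
        assert fr == pytest.approx({"gamma": 0.80, "alpha": 0.15, "olefin": 0.05})
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-9)

    def test_single_product(self):
        assert selectivity({"only": 12.3}) == {"only": 1.0}

    def test_two_equal_areas(self):
        assert selectivity({"a": 7.0, "b": 7.0}) == pytest.approx({"a": 0.5, "b": 0.5})

    def test_all_zero_rejected(self):
        with pytest.raises(AnalysisError):
            selectivity({"a": 0.0, "b": 0.0})

    @pytest.mark.parametrize("seed", range(5))
    def test_fractions_always_sum_to_one(self, seed):
        rng = random.Random(seed)
        areas = {f"p{i}": rng.uniform(0.01, 100) for i in range(rng.randint(1, 8))}
        assert sum(selectivity(areas).values()) == pytest.approx(1.0, abs=1e-9)


class TestInhibition:
    CONTROLS = AssayControls(positive=[2.0, 2.0, 2.0], negative=[100.0, 100.0, 100.0])

    def test_anchors_and_linearity(self):
        assert percent_inhibition(100.0, self.CONTROLS) == pytest.approx(0.0)
        assert percent_inhibition(2.0, self.CONTROLS) == pytest.approx(100.0)
        assert percent_inhibition(51.0, self.CONTROLS) == pytest.approx(50.0)

    def test_affine_in_signal(self):
        s1, s2 = 30.0, 70.0
        mid = percent_inhibition((s1 + s2) / 2, self.CONTROLS)
        avg = (percent_inhibition(s1, self.CONTROLS) + percent_inhibition(s2, self.CONTROLS)) / 2
        assert mid == pytest.approx(avg)


class TestZPrime:
    def test_noiseless_limit_is_one(self):
        controls = AssayControls(positive=[10.0, 10.0], negative=[0.0, 0.0])
        assert z_prime(controls) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # mu_p=10, mu_n=0, sd_p=sd_n=0.5 -> 1 - 3(1.0)/10 = 0.70
        pos = [9.5, 10.5, 9.5, 10.5]
        neg = [-0.5, 0.5, -0.5, 0.5]
        sd = float(np.std(pos, ddof=1))
        controls = AssayControls(positive=pos, negative=neg)
        expected = 1.0 - 3.0 * (2 * sd) / 10.0
        assert z_prime(controls) == pytest.approx(expected)
        # with sd exactly 0.5 the hand value is 0.70
        assert 1.0 - 3.0 * (0.5 + 0.5) / 10.0 == pytest.approx(0.70)

    def test_boundary_zero(self):
        # 3(sd_p + sd_n) = |mu_p - mu_n| -> Z' = 0
        pos = [10.0 - 0.5, 10.0 + 0.5]
        neg = [-0.5, 0.5]
        sd = float(np.std(pos, ddof=1))
        delta = 6 * sd  # make 3(2 sd) = delta
        controls = AssayControls(
            positive=[delta - 0.5, delta + 0.5], negative=[-0.5, 0.5]
        )
        assert z_prime(controls) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_at_most_one_and_decreasing_in_noise(self, seed):
        rng = np.random.default_rng(seed)
        mu_p, mu_n = 100.0, 0.0
        last = 1.0
        for sd in (0.5, 2.0, 5.0):
            noise = rng.standard_normal(24)
            pos = (mu_p + sd * noise).tolist()
            neg = (mu_n + sd * rng.standard_normal(24)).tolist()
            z = z_prime(AssayControls(positive=pos, negative=neg))
            assert z <= 1.0
            assert z < last
            last = z


class TestReplicateAgreement:
    def test_mixed_pairs(self):
        # 5% relative error agrees at 10%; 33% does not
        assert replicate_agreement([(10, 10.5), (10, 15)], 0.10) == pytest.approx(0.5)

    def test_identical_pairs(self):
        assert replicate_agreement([(3.3, 3.3)] * 7, 0.10) == 1.0

    def test_both_zero_counts_as_agreeing(self):
        assert replicate_agreement([(0.0, 0.0), (0.0, 0.0)], 0.10) == 1.0


class TestDoseResponseFit:
    @pytest.mark.parametrize("ic50", [0.1, 1.0, 5.06, 50.0])
    def test_parameter_recovery_noiseless(self, ic50):
        """4PL recovery within 1% on noiseless curves across an IC50 grid."""
        x = np.logspace(math.log10(ic50) - 2, math.log10(ic50) + 2, 8)
        y = four_pl(x, 0.0, 100.0, ic50, 1.0)
        fit = fit_dose_response(x.tolist(), y.tolist())
        assert fit.ic50 == pytest.approx(ic50, rel=0.01)
        assert fit.bottom == pytest.approx(0.0, abs=1.0)
        assert fit.top == pytest.approx(100.0, rel=0.01)
        assert fit.hill == pytest.approx(1.0, rel=0.01)

    def test_steep_hill_recovery(self):
        x = np.logspace(-1, 2, 10)
        y = four_pl(x, 5.0, 95.0, 5.06, 1.8)
        fit = fit_dose_response(x.tolist(), y.tolist())
        assert fit.ic50 == pytest.approx(5.06, rel=0.01)
        assert fit.hill == pytest.approx(1.8, rel=0.01)

    def test_flat_responses_rejected(self):
        x = [0.1, 1.0, 10.0, 100.0]
        with pytest.raises(FitError, match="flat"):
            fit_dose_response(x, [50.0, 50.0, 50.0, 50.0])

    def test_permutation_invariance(self):
        x = np.logspace(-1, 2, 8)
        y = four_pl(x, 0.0, 100.0, 5.06, 1.0)
        fwd = fit_dose_response(x.tolist(), y.tolist())
        rev = fit_dose_response(x.tolist()[::-1], y.tolist()[::-1])
        assert fwd.ic50 == rev.ic50
        assert fwd.hill == rev.hill

    def test_too_few_points(self):
        with pytest.raises(FitError):
            fit_dose_response([1.0, 10.0, 100.0], [90.0, 50.0, 10.0])


class TestTopPerformers:
    def test_planted_best_ligand_recovered(self, multiplex_factors, design24):
        best = multiplex_factors.groups[ReagentClass.LIGAND1][2].name
        truth = TruthModel(
            base_yield=30.0,
            effects={(ReagentClass.LIGAND1, best): 30.0},
            noise_sd=5.0,
            seed=7,
        )
        records = synth_results(design24, truth)
        ranking = top_performers(design24, records, "ratio")
        assert ranking[ReagentClass.LIGAND1][0][0] == best

    def test_single_reagent_class_trivially_first(self, design24):
        records = synth_results(design24, TruthModel(noise_sd=0.0, seed=0))
        ranking = top_performers(design24, records, "ratio")
        assert len(ranking[ReagentClass.ELECTROPHILE]) == 1

    def test_all_equal_ties_break_alphabetically(self, design24):
        records = synth_results(design24, TruthModel(noise_sd=0.0, seed=0))
        ranking = top_performers(design24, records, "ratio")
        names = [n for n, _ in ranking[ReagentClass.LIGAND1]]
        assert names == sorted(names)

    def test_missing_channel_rejected(self, design24):
        records = synth_results(design24, TruthModel(seed=0))
        with pytest.raises(AnalysisError):
            top_performers(design24, records, "nope")

    def test_result_for_unoccupied_well_rejected(self, design24):
        design24.reactions.pop(WellAddress(0, 0))
        rec = ResultRecord(well=WellAddress(0, 0), channels={"ratio": 1.0})
        with pytest.raises(AnalysisError, match="unoccupied"):
            top_performers(design24, [rec], "ratio")
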