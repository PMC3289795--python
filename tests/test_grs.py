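import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grsnbc.assoc import (
    ADDITIVE,
    GENOTYPIC,
    SeparationWarning,
    SnpEffect,
    fit_additive,
    fit_genotypic,
)
from grsnbc.data import GenotypeCountTable, GenotypeMatrix, PhenotypeVector
from grsnbc.grs import (
    CASE1,
    CASE2,
    CASE3,
    GrsModel,
    WeightScheme,
    build_weights,
    calibrate,
    compute_grs,
    read_weights_tsv,
    shift_threshold_intercept,
    shift_threshold_slope,
    write_weights_tsv,
)


def additive(snp_id, slope):
    return SnpEffect(snp_id, ADDITIVE, 0.0, slope)


def genotypic(snp_id, v, z):
    return SnpEffect(snp_id, GENOTYPIC, 0.0, v, z)


def matrix_from_codes(codes, snp_ids=None):
    codes = np.asarray(codes, dtype=np.int8)
    n, k = codes.shape
    snp_ids = snp_ids or tuple(f"rs{j}" for j in range(k))
    return GenotypeMatrix(
        tuple(f"s{i}" for i in range(n)), tuple(snp_ids),
        tuple(("A", "G") for _ in range(k)), codes,
    )


class TestBuildWeights:
    def test_case1_risk_allele_b(self):
        scheme = build_weights(CASE1, [additive("rs1", 0.4)])
        np.testing.assert_array_equal(scheme.weights[0], [0, 1, 2])
        assert scheme.risk_alleles == ("B",)

    def test_case1_risk_allele_a(self):
        scheme = build_weights(CASE1, [additive("rs1", -0.4)])
        np.testing.assert_array_equal(scheme.weights[0], [2, 1, 0])
        assert scheme.risk_alleles == ("A",)

    def test_case1_exactly_one_homozygote_weight_is_two(self):
        scheme = build_weights(CASE1, [additive("rs1", 0.4), additive("rs2", -0.1)])
        for row in scheme.weights:
            assert sorted(row) == [0, 1, 2]

    def test_case2_doubles_slope(self):
        scheme = build_weights(CASE2, [additive("rs1", math.log(1.5))])
        np.testing.assert_allclose(scheme.weights[0], [0, math.log(1.5), 2 * math.log(1.5)])

    def test_case3_from_counts(self):
        t = GenotypeCountTable("rs1", np.array([[10, 20, 10], [20, 10, 5]]))
        scheme = build_weights(CASE3, [fit_genotypic(t, smoothing=0)])
        np.testing.assert_allclose(scheme.weights[0], [0, math.log(4), math.log(4)], atol=1e-12)

    def test_model_mismatch_rejected(self):
        with pytest.raises(ValueError, match="need"):
            build_weights(CASE1, [genotypic("rs1", 0.1, 0.2)])
        with pytest.raises(ValueError, match="need"):
            build_weights(CASE3, [additive("rs1", 0.1)])


class TestComputeGrs:
    def test_case1_counts_risk_alleles(self):
        scheme = build_weights(
            CASE1, [additive("rs1", 0.5), additive("rs2", 0.5), additive("rs3", 0.5)]
        )
        matrix = matrix_from_codes([[1, 2, 0]], snp_ids=("rs1", "rs2", "rs3"))
        assert compute_grs(matrix, scheme)[0] == pytest.approx(3.0)

    def test_all_aa_referent_is_zero(self):
        for case, effects in (
            (CASE2, [additive("rs0", 0.5), additive("rs1", -0.3)]),
            (CASE3, [genotypic("rs0", 0.5, 0.7), genotypic("rs1", -0.3, 0.1)]),
        ):
            scheme = build_weights(case, effects)
            matrix = matrix_from_codes([[0, 0]])
            assert compute_grs(matrix, scheme)[0] == 0.0

    def test_case3_hand_sum(self):
        scheme = build_weights(
            CASE3,
            [genotypic("rs0", math.log(2), math.log(5)), genotypic("rs1", math.log(7), math.log(3))],
        )
        matrix = matrix_from_codes([[1, 2]])
        assert compute_grs(matrix, scheme)[0] == pytest.approx(math.log(2) + math.log(3))

    def test_missing_genotype_contributes_zero(self):
        scheme = build_weights(CASE2, [additive("rs0", 1.0), additive("rs1", 10.0)])
        matrix = matrix_from_codes([[1, -1]])
        assert compute_grs(matrix, scheme)[0] == pytest.approx(1.0)

    def test_unknown_snp_rejected(self):
        scheme = build_weights(CASE2, [additive("other", 1.0)])
        matrix = matrix_from_codes([[1]])
        with pytest.raises(ValueError, match="absent"):
            compute_grs(matrix, scheme)

    def test_additive_over_snp_partition(self):
        rng = np.random.default_rng(4)
        k = 8
        effects = [genotypic(f"rs{j}", rng.normal(), rng.normal()) for j in range(k)]
        scheme = build_weights(CASE3, effects)
        codes = rng.integers(0, 3, size=(20, k)).astype(np.int8)
        matrix = matrix_from_codes(codes)
        full = compute_grs(matrix, scheme)
        left = build_weights(CASE3, effects[:3])
        right = build_weights(CASE3, effects[3:])
        part = compute_grs(matrix.subset_snps(range(3)), left) + compute_grs(
            matrix.subset_snps(range(3, k)), right
        )
        np.testing.assert_allclose(full, part, atol=1e-12)

    def test_case1_score_is_risk_allele_count(self):
        rng = np.random.default_rng(6)
        k = 5
        effects = [additive(f"rs{j}", rng.normal()) for j in range(k)]
        scheme = build_weights(CASE1, effects)
        codes = rng.integers(0, 3, size=(50, k)).astype(np.int8)
        scores = compute_grs(matrix_from_codes(codes), scheme)
        assert scores.min() >= 0 and scores.max() <= 2 * k
        # oracle: count risk-allele copies subject by subject
        for i in range(50):
            count = 0
            for j in range(k):
                copies_b = codes[i, j]
                count += copies_b if scheme.risk_alleles[j] == "B" else 2 - copies_b
            assert scores[i] == count


class TestCalibrate:
    def test_separation_warns(self):
        y = PhenotypeVector(tuple(f"s{i}" for i in range(6)), np.array([0, 0, 0, 1, 1, 1], np.int8))
        with pytest.warns(SeparationWarning):
            model = calibrate(np.array([0, 0, 0, 1, 1, 1.0]), y)
        assert model.separated
        assert model.gamma1 == math.inf

    def test_degenerate_scores_rejected(self):
        y = PhenotypeVector(("a", "b"), np.array([0, 1], np.int8))
        with pytest.raises(ValueError, match="distinct"):
            calibrate(np.array([1.0, 1.0]), y)

    def test_single_class_rejected(self):
        y = PhenotypeVector(("a", "b"), np.array([1, 1], np.int8))
        with pytest.raises(ValueError, match="classes"):
            calibrate(np.array([1.0, 2.0]), y)

    def test_null_association_slope_near_zero(self):
        rng = np.random.default_rng(21)
        scores = rng.normal(size=4000)
        labels = rng.integers(0, 2, size=4000).astype(np.int8)
        y = PhenotypeVector(tuple(f"s{i}" for i in range(4000)), labels)
        model = calibrate(scores, y)
        assert abs(model.gamma1) < 2.5 * model.se_gamma1 + 1e-9

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(22)
        scores = rng.normal(size=500)
        prob = 1 / (1 + np.exp(-(0.3 + 0.8 * scores)))
        labels = (rng.random(500) < prob).astype(np.int8)
        y = PhenotypeVector(tuple(f"s{i}" for i in range(500)), labels)
        model = calibrate(scores, y)
        sm_fit = sm.Logit(labels, sm.add_constant(scores)).fit(disp=0)
        np.testing.assert_allclose([model.gamma0, model.gamma1], sm_fit.params, atol=1e-6)

    def test_true_weights_give_unit_slope(self, mixed_design):
        # score with the generative log-odds-ratio weights: calibration slope -> 1
        from grsnbc.simulate import (
            case_genotype_freqs,
            control_genotype_freqs,
            simulate_dataset,
            truth_table,
        )

        design = mixed_design
        matrix, phenotype, truth = simulate_dataset(design)
        causal = [j for j in range(len(truth.snp_ids)) if truth.is_causal[j]]
        effects = []
        for j in causal:
            case = case_genotype_freqs(
                float(truth.mafs[j]), float(truth.odds_ratios[j]), truth.modes[j]
            )
            control = control_genotype_freqs(float(truth.mafs[j]))
            llr = np.log(case) - np.log(control)
            effects.append(genotypic(truth.snp_ids[j], llr[1] - llr[0], llr[2] - llr[0]))
        scheme = build_weights(CASE3, effects)
        scores = compute_grs(matrix.subset_snps(causal), scheme)
        model = calibrate(scores, phenotype, scheme)
        assert model.gamma1 == pytest.approx(1.0, abs=3 * model.se_gamma1)


class TestThresholdShifts:
    def test_identical_intercepts(self):
        assert shift_threshold_intercept(0.0, 1.0, 1.0) == 0.0

    def test_printed_intercept_shift(self):
        assert shift_threshold_intercept(0.5, 0.0, 2.0) == pytest.approx(2.5)

    def test_slope_shift_at_intercept(self):
        assert shift_threshold_slope(1.5, 1.5, 2.0, 7.0, 3.0) == pytest.approx(7.0)

    def test_printed_slope_shift(self):
        assert shift_threshold_slope(1.0, 0.0, 2.0, 1.0, 4.0) == pytest.approx(3.0)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            shift_threshold_slope(1.0, 0.0, 0.0, 1.0, 4.0)

    def test_sign_flip_warns(self):
        with pytest.warns(UserWarning, match="orientation"):
            shift_threshold_slope(1.0, 0.0, 2.0, 1.0, -4.0)

    def test_intercept_shift_label_equivalence(self):
        rng = np.random.default_rng(31)
        linear = rng.normal(size=1000) * 3
        tau, a0, b0 = 0.7, rng.normal(), rng.normal()
        labels1 = a0 + linear > tau
        labels2 = b0 + linear > shift_threshold_intercept(tau, a0, b0)
        np.testing.assert_array_equal(labels1, labels2)

    @settings(max_examples=50, deadline=None)
    @given(
        tau=st.floats(-5, 5),
        g0=st.floats(-3, 3),
        g1=st.floats(0.1, 5),
        b0=st.floats(-3, 3),
        b1=st.floats(0.1, 5),
    )
    def test_slope_shift_label_equivalence(self, tau, g0, g1, b0, b1):
        grs = np.linspace(-10, 10, 201)
        score1 = g0 + g1 * grs
        # skip points within float rounding of the boundary itself
        keep = np.abs(score1 - tau) > 1e-9 * (1.0 + np.abs(tau))
        labels1 = score1[keep] > tau
        labels2 = b0 + b1 * grs[keep] > shift_threshold_slope(tau, g0, g1, b0, b1)
        np.testing.assert_array_equal(labels1, labels2)


class TestCase2Case3Agreement:
    def test_equal_when_genotypic_fit_is_additive(self):
        # when z happens to equal 2v, case 2 and case 3 scores coincide
        v = math.log(1.4)
        scheme2 = build_weights(CASE2, [additive("rs0", v)])
        scheme3 = build_weights(CASE3, [genotypic("rs0", v, 2 * v)])
        matrix = matrix_from_codes([[0], [1], [2]])
        np.testing.assert_allclose(compute_grs(matrix, scheme2), compute_grs(matrix, scheme3))

    def test_close_on_purely_additive_simulation(self):
        from grsnbc.data import count_genotypes
        from grsnbc.simulate import SimulationDesign, simulate_dataset

        design = SimulationDesign(
            n_cases=2000, n_controls=2000, or_grid=(1.6,), maf_grid=(0.3, 0.5),
            modes=("additive",), n_null=0, n_replicates=1, seed=77,
        )
        matrix, phenotype, _ = simulate_dataset(design)
        tables = count_genotypes(matrix, phenotype)
        scheme2 = build_weights(CASE2, [fit_additive(t) for t in tables])
        scheme3 = build_weights(CASE3, [fit_genotypic(t) for t in tables])
        s2 = compute_grs(matrix, scheme2)
        s3 = compute_grs(matrix, scheme3)
        # fitted z_i only approximately equals 2 v_i, so near- not exact equality
        assert np.corrcoef(s2, s3)[0, 1] > 0.95


class TestSerialization:
    def test_weights_round_trip(self, tmp_path):
        scheme = build_weights(CASE3, [genotypic("rs1", 0.25, 0.5), genotypic("rs2", -0.1, 0.3)])
        model = GrsModel(gamma0=-1.5, gamma1=0.9, scheme=scheme)
        path = tmp_path / "w.tsv"
        write_weights_tsv(scheme, path, model=model)
        scheme2, model2 = read_weights_tsv(path)
        assert scheme2.case == CASE3
        assert scheme2.snp_ids == scheme.snp_ids
        np.testing.assert_allclose(scheme2.weights, scheme.weights)
        assert model2.gamma0 == pytest.approx(-1.5)
        assert model2.gamma1 == pytest.approx(0.9)
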