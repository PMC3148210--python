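import math

import numpy as np
import pytest
from scipy import stats

from tagpower.errors import (
    ConsistencyError,
    DegenerateTableError,
    DomainError,
    InfeasibleModelError,
    SimulationError,
)
from tagpower.power import (
    CaseControlCounts,
    DiseaseModel,
    ModelKind,
    PowerEstimate,
    _rejection_sample_pairs,
    aggregate_power_by_maf,
    analytic_power,
    case_control_genotype_freqs,
    chi2_2df_test,
    estimate_power,
    hwe_genotype_freqs,
    simulate_case_control,
    simulate_power_direct,
    solve_penetrance,
)

from .conftest import make_panel


class TestDiseaseModel:
    def test_constraints_enforced(self):
        with pytest.raises(DomainError):
            DiseaseModel(ModelKind.DOMINANT, 0.01, 1.4, 1.8)
        with pytest.raises(DomainError):
            DiseaseModel(ModelKind.RECESSIVE, 0.01, 1.2, 3.2)
        with pytest.raises(DomainError):
            DiseaseModel(ModelKind.ADDITIVE, 0.01, 1.4, 2.0)
        with pytest.raises(DomainError):
            DiseaseModel(ModelKind.MULTIPLICATIVE, 0.01, 1.4, 2.0)

    def test_from_rr_hom(self):
        assert DiseaseModel.from_rr_hom("dominant", 1.8).rr_het == 1.8
        assert DiseaseModel.from_rr_hom("recessive", 3.2).rr_het == 1.0
        assert DiseaseModel.from_rr_hom("additive", 1.8).rr_het == pytest.approx(1.4)
        assert DiseaseModel.from_rr_hom("multiplicative", 1.8).rr_het == pytest.approx(
            math.sqrt(1.8)
        )

    def test_null_valid_for_every_kind(self):
        for kind in ModelKind:
            model = DiseaseModel.null(kind)
            assert model.is_null

    def test_prevalence_domain(self):
        with pytest.raises(DomainError):
            DiseaseModel(ModelKind.DOMINANT, 0.0, 1.8, 1.8)


class TestHweGenotypeFreqs:
    def test_half(self):
        assert hwe_genotype_freqs(0.5) == pytest.approx([0.25, 0.5, 0.25])

    def test_low(self):
        assert hwe_genotype_freqs(0.05) == pytest.approx([0.9025, 0.095, 0.0025])

    def test_zero(self):
        assert hwe_genotype_freqs(0.0) == pytest.approx([1.0, 0.0, 0.0])

    def test_domain(self):
        with pytest.raises(DomainError):
            hwe_genotype_freqs(1.2)


class TestSolvePenetrance:
    def test_dominant_example(self):
        model = DiseaseModel.from_rr_hom("dominant", 1.8, 0.01)
        pen = solve_penetrance(model, 0.05)
        assert pen.f0 == pytest.approx(0.01 / 1.078, rel=1e-9)
        assert pen.f1 == pytest.approx(1.8 * 0.01 / 1.078, rel=1e-9)
        assert pen.f2 == pen.f1

    def test_null_collapses_to_prevalence(self):
        pen = solve_penetrance(DiseaseModel.null(prevalence=0.01), 0.3)
        assert pen.f0 == pen.f1 == pen.f2 == pytest.approx(0.01)

    def test_prevalence_identity(self):
        model = DiseaseModel.from_rr_hom("multiplicative", 1.8, 0.05)
        pen = solve_penetrance(model, 0.2)
        geno = hwe_genotype_freqs(0.2)
        assert float(pen.as_array() @ geno) == pytest.approx(0.05, rel=1e-12)

    def test_infeasible(self):
        model = DiseaseModel.from_rr_hom("recessive", 3.2, 0.5)
        with pytest.raises(InfeasibleModelError):
            solve_penetrance(model, 0.5)


class TestCaseControlFreqs:
    def test_null_equals_population(self):
        model = DiseaseModel.null(prevalence=0.1)
        geno = hwe_genotype_freqs(0.3)
        pen = solve_penetrance(model, 0.3)
        case, control = case_control_genotype_freqs(pen, geno, 0.1)
        assert case == pytest.approx(geno)
        assert control == pytest.approx(geno)

    def test_dominant_example(self):
        model = DiseaseModel.from_rr_hom("dominant", 1.8, 0.01)
        pen = solve_penetrance(model, 0.05)
        case, control = case_control_genotype_freqs(
            pen, hwe_genotype_freqs(0.05), 0.01
        )
        assert case == pytest.approx([0.8372, 0.1586, 0.0042], abs=5e-5)
        assert case.sum() == pytest.approx(1.0, abs=1e-12)
        assert control.sum() == pytest.approx(1.0, abs=1e-12)

    def test_inconsistent_rejected(self):
        pen = solve_penetrance(DiseaseModel.from_rr_hom("dominant", 1.8, 0.01), 0.05)
        with pytest.raises(ConsistencyError):
            case_control_genotype_freqs(pen, hwe_genotype_freqs(0.4), 0.01)


class TestChi2Test:
    def test_no_difference(self):
        counts = CaseControlCounts((50, 30, 20), (50, 30, 20))
        stat, p = chi2_2df_test(counts)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        counts = CaseControlCounts((50, 40, 10), (70, 25, 5))
        stat, p = chi2_2df_test(counts)
        # independent textbook computation of the expected table
        observed = np.array([[50, 40, 10], [70, 25, 5]], dtype=float)
        expected_stat = 0.0
        total = observed.sum()
        for i in range(2):
            for j in range(3):
                e = observed[i].sum() * observed[:, j].sum() / total
                expected_stat += (observed[i, j] - e) ** 2 / e
        assert stat == pytest.approx(expected_stat)
        assert p == pytest.approx(stats.chi2.sf(expected_stat, 2))

    def test_zero_column_reduces_df(self):
        counts = CaseControlCounts((60, 40, 0), (70, 30, 0))
        stat, p = chi2_2df_test(counts)
        assert p == pytest.approx(stats.chi2.sf(stat, 1))

    def test_degenerate(self):
        with pytest.raises(DegenerateTableError):
            chi2_2df_test(CaseControlCounts((100, 0, 0), (100, 0, 0)))


@pytest.fixture(scope="module")
def resampling_panel():
    # causal column with alternate frequency exactly 0.05 over 200 chromosomes
    causal = [1] * 10 + [0] * 190
    other = ([1, 0] * 100)[:200]
    return make_panel([causal, other], positions=[1000, 2000])


class TestSimulateCaseControl:
    def test_deterministic(self, resampling_panel):
        a = simulate_case_control(
            resampling_panel, "v1", DiseaseModel.from_rr_hom("dominant", 1.8), 50, 50, seed=9
        )
        b = simulate_case_control(
            resampling_panel, "v1", DiseaseModel.from_rr_hom("dominant", 1.8), 50, 50, seed=9
        )
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_null_case_genotypes_match_population(self, resampling_panel):
        model = DiseaseModel.null(prevalence=0.1)
        genotypes, status = simulate_case_control(
            resampling_panel, "v1", model, 3000, 100, seed=1, sites=["v1"]
        )
        g = genotypes[status == 1, 0]
        observed = np.bincount(g, minlength=3)
        expected = hwe_genotype_freqs(0.05) * 3000
        keep = expected > 0
        chi = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        assert stats.chi2.sf(chi, keep.sum() - 1) > 0.001

    def test_dominant_case_triple_within_3se(self, resampling_panel):
        model = DiseaseModel.from_rr_hom("dominant", 1.8, 0.01)
        n = 5000
        genotypes, status = simulate_case_control(
            resampling_panel, "v1", model, n, 10, seed=2, sites=["v1"]
        )
        g = genotypes[status == 1, 0]
        observed = np.bincount(g, minlength=3) / n
        pen = solve_penetrance(model, 0.05)
        case_p, _ = case_control_genotype_freqs(pen, hwe_genotype_freqs(0.05), 0.01)
        for obs, exp in zip(observed, case_p):
            se = math.sqrt(exp * (1 - exp) / n)
            assert abs(obs - exp) <= 3 * se + 1e-12

    def test_zero_acceptance_raises(self, resampling_panel):
        rng = np.random.default_rng(0)
        col = resampling_panel.haplotypes[:, 0]
        with pytest.raises(SimulationError):
            _rejection_sample_pairs(rng, col, np.zeros(3), 10)


class TestEstimatePower:
    def test_null_calibrated(self, resampling_panel):
        model = DiseaseModel.null(prevalence=0.5)
        est = estimate_power(
            resampling_panel, "v2", model, 400, 400, replicates=2000, seed=3
        )
        se = math.sqrt(0.05 * 0.95 / 2000)
        assert abs(est.power - 0.05) <= 3 * se

    def test_direct_mode_matches_analytic(self):
        rng = np.random.default_rng(7)
        col = (rng.random(400) < 0.3).astype(int)
        col[0], col[1] = 1, 0  # guarantee polymorphism
        other = ([1, 0] * 200)[:400]
        panel = make_panel([list(col), other], positions=[10, 20])
        p_risk = float(np.mean(col))
        model = DiseaseModel.from_rr_hom("additive", 1.6, 0.1)
        est = estimate_power(
            panel, "v1", model, 800, 800, replicates=1000, mode="all_snps", seed=5
        )
        oracle = analytic_power(model, p_risk, 800, 800)
        se = math.sqrt(max(oracle * (1 - oracle), est.power * (1 - est.power)) / 1000)
        assert abs(est.power - oracle) <= 3 * se + 1e-9

    def test_no_proxy_reports_zero(self, caplog):
        panel = make_panel([[0, 1, 1, 0, 1, 0]])
        model = DiseaseModel.from_rr_hom("dominant", 1.8, 0.2)
        est = estimate_power(
            panel, "v1", model, 100, 100, replicates=10, mode="exclude_causal", seed=1
        )
        assert est.power == 0.0
        assert est.tested is None

    def test_panel_restricted_requires_manifest(self, resampling_panel):
        model = DiseaseModel.from_rr_hom("dominant", 1.8, 0.2)
        with pytest.raises(ConsistencyError):
            estimate_power(
                resampling_panel, "v1", model, 10, 10, mode="panel_restricted"
            )

    def test_mc_se_formula(self):
        est = PowerEstimate(
            causal="x", model=DiseaseModel.null(), n_cases=10, n_controls=10,
            alpha=0.05, mode="all_snps", replicates=400, power=0.25,
        )
        assert est.mc_se == pytest.approx(math.sqrt(0.25 * 0.75 / 400))


class TestAnalyticPower:
    def test_null_equals_alpha(self):
        assert analytic_power(DiseaseModel.null(), 0.3, 1000, 1000) == pytest.approx(0.05)

    def test_increasing_in_sample_size(self):
        model = DiseaseModel.from_rr_hom("additive", 1.8, 0.01)
        values = [analytic_power(model, 0.05, n, n) for n in (500, 1000, 2000, 5000)]
        assert values == sorted(values)
        assert values[0] < values[-1]

    def test_infeasible_propagates(self):
        model = DiseaseModel.from_rr_hom("recessive", 3.2, 0.5)
        with pytest.raises(InfeasibleModelError):
            analytic_power(model, 0.5, 100, 100)


class TestSimulatePowerDirect:
    def test_matches_analytic_at_friendly_point(self):
        model = DiseaseModel.from_rr_hom("multiplicative", 1.5, 0.1)
        est = simulate_power_direct(model, 0.2, 1000, 1000, replicates=2000, seed=13)
        oracle = analytic_power(model, 0.2, 1000, 1000)
        se = math.sqrt(max(oracle * (1 - oracle), est.power * (1 - est.power)) / 2000)
        assert abs(est.power - oracle) <= 3 * se

    def test_null_rejection_rate(self):
        est = simulate_power_direct(
            DiseaseModel.null(prevalence=0.3), 0.3, 1000, 1000,
            replicates=5000, seed=21,
        )
        se = math.sqrt(0.05 * 0.95 / 5000)
        assert abs(est.power - 0.05) <= 3 * se


class TestAggregatePower:
    def _estimate(self, causal, power):
        return PowerEstimate(
            causal=causal, model=DiseaseModel.null(), n_cases=10, n_controls=10,
            alpha=0.05, mode="all_snps", replicates=100, power=power,
        )

    def test_single_estimate(self):
        panel = make_panel([[0, 1, 1, 0, 1, 0, 0, 0]])
        table = aggregate_power_by_maf([self._estimate("v1", 0.42)], panel)
        assert len(table) == 1
        assert table["mean_power"].iloc[0] == pytest.approx(0.42)

    def test_mean_within_bin(self):
        col_a = [0, 1, 1, 0, 1, 0, 0, 0]  # maf 0.375
        col_b = [1, 0, 1, 0, 1, 0, 0, 0]  # maf 0.375
        panel = make_panel([col_a, col_b])
        table = aggregate_power_by_maf(
            [self._estimate("v1", 0.2), self._estimate("v2", 0.4)], panel
        )
        assert len(table) == 1
        assert table["mean_power"].iloc[0] == pytest.approx(0.3)

    def test_heterogeneous_rejected(self):
        panel = make_panel([[0, 1, 1, 0, 1, 0, 0, 0]])
        bad = PowerEstimate(
            causal="v1", model=DiseaseModel.null(), n_cases=99, n_controls=10,
            alpha=0.05, mode="all_snps", replicates=100, power=0.5,
        )
        with pytest.raises(ConsistencyError):
            aggregate_power_by_maf([self._estimate("v1", 0.1), bad], panel)
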