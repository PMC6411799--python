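import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.base import clone

from conftest import le_tensor_oracle, random_instance
from orthovar.designs import multilocus_additive, multilocus_dominance
from orthovar.frequencies import LDSpec, PopulationFrequencies, frequencies_from_ldspec
from orthovar.gpmaps import bdm_map, sign_epistasis_map
from orthovar.solver import (
    GPMap,
    VarianceDecomposition,
    decompose,
    joint_vs_sequential_check,
    one_step_vs_sequential_check,
    orthogonality_audit,
    variance_table,
    weighted_mean,
    wls_project,
)


def single_locus_hwe(p1):
    return PopulationFrequencies([p1**2, 2 * p1 * (1 - p1), (1 - p1) ** 2])


class TestWeightedMean:
    def test_f2_sign_epistasis_mean(self):
        p = frequencies_from_ldspec(LDSpec(0.5, 0.5, 0.0, 0.0))
        mu, ybar = weighted_mean(sign_epistasis_map(), p)
        assert mu == pytest.approx(1.0, abs=1e-14)
        assert p.p @ ybar == pytest.approx(0.0, abs=1e-14)

    def test_constant_map(self):
        mu, ybar = weighted_mean([2.5] * 9, np.full(9, 1 / 9))
        assert mu == pytest.approx(2.5)
        np.testing.assert_allclose(ybar, 0.0, atol=1e-14)

    def test_single_locus(self):
        mu, _ = weighted_mean([0, 1, 0], [0.25, 0.5, 0.25])
        assert mu == pytest.approx(0.5)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            weighted_mean([0, 1, 0], np.full(9, 1 / 9))


class TestWlsProject:
    def test_full_span_block_reproduces_input(self, rng):
        block = multilocus_dominance(1)  # identity: spans everything
        p = PopulationFrequencies(rng.dirichlet(np.ones(3)))
        y = rng.normal(size=3)
        y -= p.p @ y
        step = wls_project(y, block, p)
        np.testing.assert_allclose(step.fitted, y, atol=1e-12)
        np.testing.assert_allclose(step.residuals, 0.0, atol=1e-12)

    def test_two_locus_additive_has_one_nil_eigenvalue(self, rng):
        block = multilocus_additive(2)
        p = PopulationFrequencies(rng.dirichlet(np.ones(9)))
        y = rng.normal(size=9)
        y -= p.p @ y
        step = wls_project(y, block, p)
        assert step.rank == 3
        assert step.eigenvalues.size == 4

    def test_symmetric_overdominant_map_has_no_additive_part(self):
        p = PopulationFrequencies([0.25, 0.5, 0.25])
        _, ybar = weighted_mean([0, 1, 0], p)
        step = wls_project(ybar, multilocus_additive(1), p)
        np.testing.assert_allclose(step.fitted, 0.0, atol=1e-12)

    def test_projection_is_weighted_orthogonal(self, rng):
        block = multilocus_additive(2)
        p = PopulationFrequencies(rng.dirichlet(np.ones(9)))
        y = rng.normal(size=9)
        y -= p.p @ y
        step = wls_project(y, block, p)
        assert abs(p.p @ (step.fitted * step.residuals)) < 1e-12

    def test_uncentered_input_rejected(self):
        p = PopulationFrequencies([0.25, 0.5, 0.25])
        with pytest.raises(ValueError, match="weighted mean zero"):
            wls_project(np.array([1.0, 2.0, 3.0]), multilocus_additive(1), p)


class TestSingleLocusOracle:
    """V_A = 2pq[a + d(q-p)]^2 and V_D = (2pqd)^2 under Hardy-Weinberg."""

    @pytest.mark.parametrize(
        "a, d, p1", [(1.0, 0.5, 0.3), (2.0, -1.0, 0.7), (0.8, 0.0, 0.5)]
    )
    def test_closed_form(self, a, d, p1):
        q = 1 - p1
        res = decompose(GPMap([a, d, -a]), single_locus_hwe(p1))
        alpha = a + d * (q - p1)
        assert res.V_A == pytest.approx(2 * p1 * q * alpha**2, abs=1e-12)
        assert res.V_D == pytest.approx((2 * p1 * q * d) ** 2, abs=1e-12)

    def test_worked_example(self):
        res = decompose(GPMap([1.0, 0.5, -1.0]), single_locus_hwe(0.3))
        assert res.V_A == pytest.approx(0.6048, abs=1e-10)
        assert res.V_D == pytest.approx(0.0441, abs=1e-10)

    @given(
        a=st.floats(-2, 2),
        d=st.floats(-2, 2),
        p1=st.floats(0.05, 0.95),
    )
    def test_closed_form_property(self, a, d, p1):
        q = 1 - p1
        res = decompose(GPMap([a, d, -a]), single_locus_hwe(p1))
        assert res.V_A == pytest.approx(
            2 * p1 * q * (a + d * (q - p1)) ** 2, abs=1e-10
        )
        assert res.V_D == pytest.approx((2 * p1 * q * d) ** 2, abs=1e-10)


class TestDecompose:
    def test_f2_sign_epistasis_is_pure_aa(self):
        p = frequencies_from_ldspec(LDSpec(0.5, 0.5, 0.0, 0.0))
        res = decompose(sign_epistasis_map(), p)
        assert res.V_A == pytest.approx(0.0, abs=1e-12)
        assert res.V_D == pytest.approx(0.0, abs=1e-12)
        assert res.variances["AA"] == pytest.approx(0.25, abs=1e-12)
        assert res.V_I == pytest.approx(0.25, abs=1e-12)
        assert res.split_variances["DA"] == pytest.approx(0.0, abs=1e-12)
        assert res.split_variances["AD"] == pytest.approx(0.0, abs=1e-12)
        assert res.variances["DD"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_map_has_no_variance(self):
        res = decompose(np.full(9, 4.2), np.full(9, 1 / 9))
        for lab, v in res.variances.items():
            assert v == pytest.approx(0.0, abs=1e-12), lab

    @pytest.mark.parametrize("loci", [1, 2, 3])
    def test_reconstruction_and_additivity_random(self, rng, loci):
        for _ in range(10):
            G, p = random_instance(rng, loci)
            res = decompose(G, p)
            recon = res.mu + sum(res.components.values())
            np.testing.assert_allclose(recon, G, atol=1e-10)
            v = res.variances
            assert v["G"] == pytest.approx(v["A"] + v["D"] + v["I"], abs=1e-12)
            class_sum = sum(v[lab] for lab in res.epistasis_labels)
            assert v["I"] == pytest.approx(class_sum, abs=1e-12)

    def test_le_hwe_reduction_to_classical_tensor_decomposition(self, rng):
        for _ in range(10):
            G = rng.normal(size=9)
            pa, pb = rng.uniform(0.15, 0.85, size=2)
            res = decompose(G, frequencies_from_ldspec(LDSpec(pa, pb, 0.0, 0.0)))
            oracle = le_tensor_oracle(G, pa, pb)
            assert res.mu == pytest.approx(oracle["mu"], abs=1e-10)
            np.testing.assert_allclose(res.components["A"], oracle["A"], atol=1e-8)
            np.testing.assert_allclose(res.components["D"], oracle["D"], atol=1e-8)
            np.testing.assert_allclose(res.components["AA"], oracle["AA"], atol=1e-8)
            np.testing.assert_allclose(res.components["DD"], oracle["DD"], atol=1e-8)
            np.testing.assert_allclose(
                res.split_components["DA"], oracle["DA"], atol=1e-8
            )
            np.testing.assert_allclose(
                res.split_components["AD"], oracle["AD"], atol=1e-8
            )

    def test_zero_frequency_class_does_not_affect_variances(self, rng):
        p = rng.dirichlet(np.ones(9))
        p[4] = 0.0
        p /= p.sum()
        G = rng.normal(size=9)
        res1 = decompose(G, p)
        G2 = G.copy()
        G2[4] += 7.0  # unsupported genotype: value is irrelevant
        res2 = decompose(G2, p)
        for lab in res1.variances:
            assert res1.variances[lab] == pytest.approx(
                res2.variances[lab], abs=1e-10
            )

    def test_extreme_ld_collapses_to_single_locus(self):
        # complete positive association: three genotypes remain with values
        # (0, 1, 0) at (1/4, 1/2, 1/4) -- pure overdominance
        p = frequencies_from_ldspec(LDSpec(0.5, 0.5, 1.0, 0.0))
        res = decompose(sign_epistasis_map(), p)
        assert res.V_A == pytest.approx(0.0, abs=1e-10)
        assert res.V_D == pytest.approx(0.25, abs=1e-10)
        assert res.V_I == pytest.approx(0.0, abs=1e-10)

    def test_loci_mismatch_rejected(self):
        with pytest.raises(ValueError, match="loci"):
            decompose(np.zeros(9), np.full(3, 1 / 3))


class TestOrthogonality:
    def test_provable_pairs_vanish_under_arbitrary_frequencies(self, rng):
        for _ in range(5):
            G, p = random_instance(rng, 2)
            audit = orthogonality_audit(decompose(G, p))
            provable = audit[audit["provable"]]
            assert not provable.empty
            assert provable["normalized_dot"].abs().max() < 1e-10

    def test_additive_component_orthogonal_to_all_others(self, rng):
        G, p = random_instance(rng, 2)
        audit = orthogonality_audit(decompose(G, p))
        a_rows = audit[audit["component_1"] == "A"]
        assert a_rows["provable"].all()

    def test_cross_class_orthogonality_can_fail_off_equilibrium(self):
        # the D vs AA cross-product is not implied by the chain and is
        # measurably non-zero under combined HWD and LD
        p = frequencies_from_ldspec(LDSpec(0.4, 0.6, -0.4, 0.2))
        audit = orthogonality_audit(decompose(bdm_map(), p))
        row = audit[
            (audit["component_1"] == "D") & (audit["component_2"] == "AA")
        ].iloc[0]
        assert not row["provable"]
        assert abs(row["normalized_dot"]) > 1e-3


class TestMixedClassDetachment:
    def test_equivalent_under_linkage_equilibrium(self, rng):
        for _ in range(5):
            G = rng.normal(size=9)
            pa, pb = rng.uniform(0.15, 0.85, size=2)
            rep = joint_vs_sequential_check(
                G, frequencies_from_ldspec(LDSpec(pa, pb, 0.0, 0.0))
            )
            assert rep["agreement"], rep

    def test_divergence_under_linkage_disequilibrium_is_reported(self):
        # the concatenated DA|AD projection and the sequential DA-then-AD
        # chain agree only when the weights factorize across loci; under LD
        # they measurably differ, and the report says so rather than hiding it
        p = frequencies_from_ldspec(LDSpec(0.5, 0.5, -0.5, 0.0))
        rep = joint_vs_sequential_check(bdm_map(), p)
        assert not rep["agreement"]
        assert rep["max_dd_difference"] > 1e-3

    def test_both_modes_leave_total_variances_identical(self, rng):
        G, p = random_instance(rng, 2)
        joint = decompose(G, p, da_ad_mode="concatenated")
        seq = decompose(G, p, da_ad_mode="sequential")
        for lab in ("A", "D", "AA", "G", "I"):
            assert joint.variances[lab] == pytest.approx(
                seq.variances[lab], abs=1e-12
            )


class TestOneStepVsTwoStep:
    def test_generic_instance_differs(self):
        rep = one_step_vs_sequential_check([0, 1, 0], [0.25, 0.5, 0.25])
        assert rep["differs"]
        assert rep["mu_two_step"] == pytest.approx(0.5)
        assert rep["mu_difference"] > 1e-3

    def test_zero_map_coincides(self):
        rep = one_step_vs_sequential_check([0.0, 0.0, 0.0], [0.25, 0.5, 0.25])
        assert not rep["differs"]

    def test_random_instances_generically_differ(self, rng):
        for _ in range(10):
            G = rng.normal(size=3)
            p = rng.dirichlet(np.ones(3))
            assert one_step_vs_sequential_check(G, p)["differs"]


class TestVarianceTable:
    def test_f2_sign_epistasis_shares(self):
        p = frequencies_from_ldspec(LDSpec(0.5, 0.5, 0.0, 0.0))
        table = variance_table(decompose(sign_epistasis_map(), p))
        table = table.set_index("component")
        assert table.loc["AA", "share"] == pytest.approx(1.0, abs=1e-12)
        assert table.loc["I", "share"] == pytest.approx(1.0, abs=1e-12)

    def test_single_locus_share(self):
        table = variance_table(
            decompose(GPMap([1.0, 0.5, -1.0]), single_locus_hwe(0.3))
        ).set_index("component")
        assert table.loc["A", "share"] == pytest.approx(0.6048 / 0.6489, abs=1e-10)

    def test_constant_map_shares_missing(self):
        table = variance_table(decompose(np.full(9, 1.0), np.full(9, 1 / 9)))
        assert table["share"].isna().all()

    def test_component_shares_sum_to_one(self, rng):
        G, p = random_instance(rng, 2)
        table = variance_table(decompose(G, p))
        shares = table.set_index("component")["share"]
        total = shares.drop(["I", "G"]).sum()
        assert total == pytest.approx(1.0, abs=1e-10)


class TestEstimator:
    def test_fit_exposes_attributes(self):
        p = frequencies_from_ldspec(LDSpec(0.5, 0.5, 0.0, 0.0))
        vd = VarianceDecomposition().fit(sign_epistasis_map(), p)
        assert vd.mu_ == pytest.approx(1.0)
        assert vd.n_loci_ == 2
        assert vd.variances_["AA"] == pytest.approx(0.25, abs=1e-12)
        assert set(vd.components_) == {"A", "D", "AA", "DA|AD", "DD"}

    def test_unfitted_access_raises(self):
        with pytest.raises(AttributeError, match="not fitted"):
            VarianceDecomposition().variance_table()

    def test_get_params_and_clone(self):
        vd = VarianceDecomposition(da_ad_mode="sequential", eig_rtol=1e-9)
        params = vd.get_params()
        assert params["da_ad_mode"] == "sequential"
        cloned = clone(vd)
        assert cloned.get_params() == params

    def test_invalid_mode_rejected_on_fit(self):
        vd = VarianceDecomposition(da_ad_mode="bogus")
        with pytest.raises(ValueError, match="da_ad_mode"):
            vd.fit(np.zeros(9), np.full(9, 1 / 9))
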