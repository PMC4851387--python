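import numpy as np
import pytest

from togglepop.equilibria import (
    EquilibriumRecord,
    MultistartPlan,
    bistability_scan,
    classify_stability,
    enumerate_equilibria,
    find_equilibrium,
    reduced_spectrum_check,
    single_toggle_equilibria,
)
from togglepop.experiments import make_population_state
from togglepop.models import PopulationSpec, mirror_state
from togglepop.params import mirror_params

from conftest import fixed_point_oracle_s


@pytest.fixture
def ref_d0(reference):
    return reference.replace(d=0.0)


class TestFindEquilibrium:
    def test_g_state_from_guess(self, ref_d0, spec_s1):
        rec = find_equilibrium([30, 0, 3, 0, 0, 0], ref_d0, spec_s1)
        x, y, g, r = fixed_point_oracle_s(ref_d0)
        np.testing.assert_allclose(rec.state[:4], [x, y, g, r], rtol=1e-6)
        assert rec.stable
        assert rec.labels == ("G",)
        assert rec.residual_norm < 1e-10

    def test_mirrored_guess_gives_mirrored_state(self, ref_d0, spec_s1):
        rec_g = find_equilibrium([30, 0, 3, 0, 0, 0], ref_d0, spec_s1)
        rec_r = find_equilibrium([0, 30, 0, 3, 0, 0], ref_d0, spec_s1)
        np.testing.assert_allclose(
            rec_r.state, mirror_state(rec_g.state, spec_s1), atol=1e-9)
        assert rec_r.labels == ("R",)

    def test_symmetric_saddle(self, ref_d0, spec_s1):
        # oracle: Newton restricted to the mirror-fixed subspace x=y, g=r
        from scipy.optimize import brentq
        from togglepop.models import hill_act, hill_rep
        p = ref_d0

        def phi(x):
            g = p.a5 * hill_rep(x, p.nY) / p.delta_g
            return p.a1 * hill_rep(x, p.nY) + p.a3 * hill_act(g, p.nG) - x

        x_sym = brentq(phi, 0.5, 25.0, xtol=1e-12)
        g_sym = p.a5 * hill_rep(x_sym, p.nY) / p.delta_g
        rec = find_equilibrium([x_sym, x_sym, g_sym, g_sym, 0, 0],
                               p, PopulationSpec("S", (1,)))
        assert rec.state[0] == pytest.approx(rec.state[1], rel=1e-8)
        assert not rec.stable
        assert max(rec.eigenvalues.real) > 0

    def test_rejects_bad_guess(self, ref_d0, spec_s1):
        with pytest.raises(ValueError):
            find_equilibrium([np.nan] * 6, ref_d0, spec_s1)
        with pytest.raises(ValueError):
            find_equilibrium([-1, 0, 0, 0, 0, 0], ref_d0, spec_s1)


class TestEnumerate:
    def test_s_reference_three_equilibria(self, ref_d0, spec_s1):
        recs = enumerate_equilibria(ref_d0, spec_s1)
        stable = [r for r in recs if r.stable]
        unstable = [r for r in recs if not r.stable]
        assert len(stable) == 2
        assert len(unstable) == 1
        assert {r.labels[0] for r in stable} == {"G", "R"}
        # the unstable state sits on the mirror-fixed subspace
        u = unstable[0].state
        assert u[0] == pytest.approx(u[1], rel=1e-6)

    def test_reduced_design_keeps_bistability(self, ref_d0, spec_s1):
        # removing the direct cross-repression genes (a1 = a2 = 0)
        recs = enumerate_equilibria(ref_d0.replace(a1=0.0, a2=0.0), spec_s1)
        assert sum(r.stable for r in recs) == 2

    def test_a_reference_bistable(self, ref_d0, spec_a1):
        recs = enumerate_equilibria(ref_d0, spec_a1)
        assert sum(r.stable for r in recs) == 2

    def test_multistart_completeness(self, ref_d0, spec_s1):
        coarse = enumerate_equilibria(ref_d0, spec_s1,
                                      MultistartPlan(n_random=100, seed=1))
        dense = enumerate_equilibria(ref_d0, spec_s1,
                                     MultistartPlan(n_random=1000, seed=2))
        assert len(coarse) == len(dense)
        for a, b in zip(coarse, dense):
            np.testing.assert_allclose(a.state, b.state, atol=1e-6)

    def test_signature_consistency(self, ref_d0, spec_s1):
        for rec in enumerate_equilibria(ref_d0, spec_s1):
            if rec.stable:
                assert "?" not in rec.labels


class TestClassify:
    def test_diagonal_linear_system(self, ref_d0, spec_s1):
        rec = EquilibriumRecord(
            state=np.zeros(2), params=ref_d0, spec=spec_s1,
            residual_norm=0.0, eigenvalues=np.array([-1.0, -2.0]),
            stable=True, labels=("G",), ratio=(1, 0))
        verdict, lead = classify_stability(rec)
        assert verdict == "stable" and lead == -1.0

    def test_marginal_band(self, ref_d0, spec_s1):
        rec = EquilibriumRecord(
            state=np.zeros(2), params=ref_d0, spec=spec_s1,
            residual_norm=0.0, eigenvalues=np.array([1e-9 + 0j, -1.0 + 0j]),
            stable=False, labels=("G",), ratio=(1, 0))
        assert classify_stability(rec)[0] == "marginal"

    def test_stable_homogeneous(self, reference):
        res = make_population_state((1, 0), reference.replace(d=0.1),
                                    PopulationSpec("S", (2,)))
        assert classify_stability(res.record)[0] == "stable"

    def test_symmetric_mixed_unstable_past_bp(self, reference):
        params = reference.replace(d=1.6)
        spec = PopulationSpec("S", (1, 1))
        res = make_population_state((1, 1), params, spec)
        # the symmetric state still exists at d=1.6 but has lost stability
        assert res.exists
        assert classify_stability(res.record)[0] == "unstable"


class TestMirrorPairing:
    def test_sigma_pairs_share_spectra(self, ref_d0, spec_s1):
        recs = enumerate_equilibria(ref_d0, spec_s1)
        for rec in recs:
            mirrored = mirror_state(rec.state, spec_s1)
            if np.allclose(mirrored, rec.state, atol=1e-8):
                continue  # on the fixed subspace
            partner = min(recs, key=lambda r: np.max(np.abs(r.state - mirrored)))
            assert np.max(np.abs(partner.state - mirrored)) < 1e-7
            np.testing.assert_allclose(
                np.sort_complex(partner.eigenvalues),
                np.sort_complex(rec.eigenvalues), atol=1e-8)


class TestBistabilityScan:
    GRID = np.arange(0.0, 51.0, 10.0)

    # the leakiness sweep applies to the repressor-gene promoters: gamma_x
    # and gamma_y for the S toggle; for the A toggle the synthase is
    # co-transcribed with tetR, so gamma_r follows gamma_y
    @pytest.mark.parametrize("gamma", [0.0, 0.01, 0.1, 1.0])
    def test_s_whole_quadrant_bistable(self, ref_d0, gamma):
        params = ref_d0.replace(gamma_x=gamma, gamma_y=gamma)
        rmap = bistability_scan("S", params, self.GRID, self.GRID)
        assert rmap.all_bistable

    def test_a_proper_subregion(self, ref_d0):
        rmap = bistability_scan("A", ref_d0, self.GRID, self.GRID)
        assert rmap.any_bistable
        assert not rmap.all_bistable

    def test_a_gamma_above_half_no_bistability(self, ref_d0):
        params = ref_d0.replace(gamma_x=0.6, gamma_y=0.6, gamma_r=0.6)
        rmap = bistability_scan("A", params, self.GRID, self.GRID)
        assert not rmap.any_bistable

    def test_counts_at_least_one(self, ref_d0):
        rmap = bistability_scan("S", ref_d0, [0.0, 20.0], [0.0, 20.0])
        assert np.all(rmap.counts[~rmap.failed] >= 1)

    def test_requires_decoupled(self, reference):
        with pytest.raises(ValueError, match="d = 0"):
            bistability_scan("S", reference.replace(d=0.1))


class TestSpectrumReduction:
    @pytest.mark.parametrize("N", [2, 4, 8])
    def test_homogeneous_reduces_to_two_toggles(self, reference, N):
        params = reference.replace(d=1.0)
        res = make_population_state((1, 0), params, PopulationSpec("S", (N,)))
        rep = reduced_spectrum_check(res.record, reduction_size=2)
        assert rep.matched, rep.max_mismatch
        assert rep.max_mismatch < 1e-6

    @pytest.mark.parametrize("N", [4, 6, 10])
    def test_one_one_mixed_reduces_to_three(self, reference, N):
        params = reference.replace(d=0.1)
        spec = PopulationSpec("S", (N // 2, N // 2))
        res = make_population_state((1, 1), params, spec)
        rep = reduced_spectrum_check(res.record, reduction_size=3)
        assert rep.matched

    def test_nine_one_mixed(self, reference):
        params = reference.replace(d=0.1)
        res = make_population_state((9, 1), params, PopulationSpec("S", (9, 1)))
        rep = reduced_spectrum_check(res.record)
        assert rep.matched
        # the single-cell minority subpopulation contributes no
        # anti-synchronous class: 3 toggle blocks at N = 10
        assert rep.reduction_size == 3

    def test_nine_one_larger_population_four_toggles(self, reference):
        params = reference.replace(d=0.1)
        res = make_population_state((9, 1), params, PopulationSpec("S", (18, 2)))
        rep = reduced_spectrum_check(res.record, reduction_size=4)
        assert rep.matched

    def test_n2_homogeneous_identity(self, reference):
        params = reference.replace(d=1.0)
        res = make_population_state((1, 0), params, PopulationSpec("S", (2,)))
        rep = reduced_spectrum_check(res.record, reduction_size=2)
        # reduction of a 2-cell population is the full system
        assert len(rep.reduced_eigenvalues) == len(rep.full_eigenvalues) == 10
        assert rep.matched

    def test_wrong_expected_size_raises(self, reference):
        params = reference.replace(d=1.0)
        res = make_population_state((1, 0), params, PopulationSpec("S", (4,)))
        with pytest.raises(ValueError, match="toggle blocks"):
            reduced_spectrum_check(res.record, reduction_size=3)

    def test_a_model_homogeneous(self, reference):
        params = reference.replace(d=1.0)
        res = make_population_state((1, 0), params, PopulationSpec("A", (6,)))
        rep = reduced_spectrum_check(res.record, reduction_size=2)
        assert rep.matched
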