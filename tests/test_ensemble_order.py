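"""Order parameters from conformer ensembles: exact oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from disorderbench import (
    EnsembleStructure,
    OrderConfig,
    angle_std,
    build_ivm,
    compute_dihedrals,
    coord_variation,
    dihedral_order_profile,
    ensemble_order_profile,
    order_params,
    shw,
)
from disorderbench.containers import VarianceMatrix
from disorderbench.errors import DisorderBenchError, EnsembleTooSmallError
from disorderbench.synthetic_data import GeneratorConfig, build_backbone, gen_ensemble

from conftest import ca_only_ensemble


def brute_dihedral_deg(p0, p1, p2, p3):
    """Independent scalar dihedral: two-plane-normal acos with triple-product
    sign (different route from the package implementation)."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
    if np.dot(np.cross(n1, n2), b2) < 0:
        ang = -ang
    return ang


def angles_ensemble(phi_sets, psi_sets):
    """Ensemble whose conformers realize the given per-conformer dihedrals."""
    coords = np.stack([build_backbone(p, s) for p, s in zip(phi_sets, psi_sets)])
    L = coords.shape[1]
    return EnsembleStructure(
        "built", [("A", i + 1, "ALA") for i in range(L)], coords
    )


class TestShw:
    @pytest.mark.parametrize(
        "angles,expected",
        [
            ([33.0] * 5, 1.0),
            ([-120.0, -120.0], 1.0),
            ([0.0, 90.0, 180.0, 270.0], 0.0),
            ([0.0, 90.0], np.sqrt(2) / 2),
        ],
    )
    def test_known_values(self, angles, expected):
        assert shw(np.array(angles)) == pytest.approx(expected, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(DisorderBenchError):
            shw(np.array([]))

    @given(
        st.lists(st.floats(-180, 180), min_size=1, max_size=20),
        st.floats(-720, 720),
    )
    @settings(max_examples=100, deadline=None)
    def test_bounded_and_rotation_invariant(self, angles, offset):
        a = np.array(angles)
        v = shw(a)
        assert 0.0 <= v <= 1.0 + 1e-12
        assert shw(a + offset) == pytest.approx(v, abs=1e-9)

    @given(
        st.lists(st.floats(-179, 179), min_size=2, max_size=15),
        st.floats(0.0, 1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_concentration_monotonicity(self, angles, lam):
        """Shrinking all deviations from the circular mean never lowers shw."""
        a = np.radians(np.array(angles))
        mean = np.arctan2(np.sin(a).sum(), np.cos(a).sum())
        dev = np.degrees(np.angle(np.exp(1j * (a - mean))))
        loose = np.degrees(mean) + dev
        tight = np.degrees(mean) + lam * dev
        assert shw(tight) >= shw(loose) - 1e-12


class TestDihedrals:
    def test_recompute_matches_independent_oracle(self):
        rng = np.random.default_rng(7)
        L, K = 6, 3
        phis = rng.uniform(-170, 170, (K, L))
        psis = rng.uniform(-170, 170, (K, L))
        ens = angles_ensemble(phis, psis)
        dset = compute_dihedrals(ens)
        xyz = ens.coords
        for k in range(K):
            for i in range(1, L):
                ref = brute_dihedral_deg(
                    xyz[k, i - 1, 2], xyz[k, i, 0], xyz[k, i, 1], xyz[k, i, 2]
                )
                assert dset.phi[i, k] == pytest.approx(ref, abs=1e-9)
                assert dset.phi[i, k] == pytest.approx(phis[k, i], abs=1e-6)
            for i in range(L - 1):
                ref = brute_dihedral_deg(
                    xyz[k, i, 0], xyz[k, i, 1], xyz[k, i, 2], xyz[k, i + 1, 0]
                )
                assert dset.psi[i, k] == pytest.approx(ref, abs=1e-9)
                assert dset.psi[i, k] == pytest.approx(psis[k, i], abs=1e-6)

    def test_extended_chain(self):
        L = 4
        ens = angles_ensemble([np.full(L, 180.0)], [np.full(L, 180.0)])
        dset = compute_dihedrals(ens)
        assert np.allclose(np.abs(dset.phi[1:, 0]), 180.0, atol=1e-6)
        assert np.allclose(np.abs(dset.psi[:-1, 0]), 180.0, atol=1e-6)

    def test_termini_undefined(self, rigid_ensemble):
        dset = compute_dihedrals(rigid_ensemble)
        assert np.isnan(dset.phi[0]).all()
        assert np.isnan(dset.psi[-1]).all()
        assert np.isfinite(dset.phi[1:]).all()
        assert np.isfinite(dset.psi[:-1]).all()

    def test_identical_conformers_identical_angles(self, rigid_ensemble):
        dset = compute_dihedrals(rigid_ensemble)
        for arr in (dset.phi, dset.psi):
            finite = np.isfinite(arr).all(axis=1)
            assert np.all(arr[finite] == arr[finite][:, [0]])

    def test_chain_break_undefines_spanning_angles(self):
        L = 8
        xyz = build_backbone(np.full(L, -65.0), np.full(L, -40.0))
        xyz[4:] += np.array([50.0, 0.0, 0.0])  # tear the chain after residue 4
        ens = EnsembleStructure(
            "broken", [("A", i + 1, "ALA") for i in range(L)], xyz[None]
        )
        dset = compute_dihedrals(ens)
        assert np.isnan(dset.phi[4]).all()  # phi of the first post-break residue
        assert np.isnan(dset.psi[3]).all()  # psi of the last pre-break residue
        assert np.isfinite(dset.phi[1:4]).all() and np.isfinite(dset.phi[5:]).all()


class TestDihedralOrderProfile:
    def test_rigid_interior_is_one(self, rigid_ensemble):
        D = dihedral_order_profile(compute_dihedrals(rigid_ensemble))
        assert np.allclose(D[1:-1], 1.0, atol=1e-12)

    def test_brute_force_window_average(self):
        rng = np.random.default_rng(3)
        L, K = 5, 3
        phis = rng.uniform(-170, 170, (K, L))
        psis = rng.uniform(-170, 170, (K, L))
        dset = compute_dihedrals(angles_ensemble(phis, psis))
        D = dihedral_order_profile(dset)
        # brute-force D_3 (index 2): six shw terms over residues 2, 3, 4
        terms = []
        for j in (1, 2, 3):
            terms.append(shw(dset.phi[j]))
            terms.append(shw(dset.psi[j]))
        assert D[2] == pytest.approx(np.mean(terms), abs=1e-12)

    def test_termini_use_defined_terms_only(self, rigid_ensemble):
        D = dihedral_order_profile(compute_dihedrals(rigid_ensemble))
        # first residue: phi_0 undefined but the remaining window terms are 1
        assert D[0] == pytest.approx(1.0)
        assert np.isfinite(D).all()
        assert np.all((D >= 0) & (D <= 1))


class TestAngleStd:
    def test_anchors(self):
        assert angle_std(1.0) == pytest.approx(0.0, abs=1e-12)
        assert angle_std(np.exp(-4)) == pytest.approx(360.0, abs=1e-9)
        D75 = np.exp(2.0 * (np.cos(np.radians(37.5)) - 1.0))
        assert angle_std(D75) == pytest.approx(75.0, abs=1e-9)

    def test_domain_error(self):
        with pytest.raises(DisorderBenchError):
            angle_std(0.0)
        with pytest.raises(DisorderBenchError):
            angle_std(-0.5)

    def test_strictly_increasing_in_disorder(self):
        D = np.linspace(np.exp(-4), 1.0, 200)
        s = angle_std(D)
        assert np.all(np.diff(s) < 0)  # s falls as order D rises
        assert s.min() == pytest.approx(0.0, abs=1e-9)
        assert s.max() == pytest.approx(360.0, abs=1e-6)


class TestVarianceMatrix:
    def test_identical_conformers_zero(self, rigid_ensemble):
        vm = build_ivm(rigid_ensemble)
        assert np.allclose(vm.v, 0.0, atol=1e-18)

    def test_two_conformer_hand_value(self):
        ca = np.zeros((2, 5, 3))
        ca[:, :, 0] = np.arange(5) * 3.8
        delta = 0.7
        ca[1, 4, 0] += delta  # one pair's distance shifts by delta
        vm = build_ivm(ca_only_ensemble(ca))
        assert vm.v[0, 4] == pytest.approx(delta**2 / 4.0, abs=1e-12)
        assert vm.v[0, 3] == pytest.approx(0.0, abs=1e-15)

    def test_brute_force_and_symmetry(self):
        rng = np.random.default_rng(11)
        ca = rng.normal(scale=4.0, size=(4, 6, 3))
        vm = build_ivm(ca_only_ensemble(ca))
        K, L = ca.shape[:2]
        for i in range(L):
            for j in range(L):
                d = [np.linalg.norm(ca[k, i] - ca[k, j]) for k in range(K)]
                v_ref = np.mean((np.array(d) - np.mean(d)) ** 2)  # divisor N
                assert vm.v[i, j] == pytest.approx(v_ref, abs=1e-12)
        assert np.allclose(vm.v, vm.v.T, atol=1e-15)
        assert np.allclose(np.diag(vm.v), 0.0)

    def test_single_conformer_rejected(self):
        ca = np.zeros((1, 5, 3))
        ca[0, :, 0] = np.arange(5)
        with pytest.raises(EnsembleTooSmallError):
            build_ivm(ca_only_ensemble(ca))


class TestCoordVariation:
    def test_zero_variance_gives_zero(self, rigid_ensemble):
        t = coord_variation(build_ivm(rigid_ensemble))
        assert np.allclose(t, 0.0, atol=1e-12)

    def test_constant_rows_give_sqrt(self):
        L, c = 7, 0.36
        v = np.full((L, L), c)
        np.fill_diagonal(v, 0.0)
        vm = VarianceMatrix(np.arange(1, L + 1), v, np.ones((L, L)))
        for beta in (1.0, 10.0, 40.0):
            t = coord_variation(vm, beta=beta)
            assert np.allclose(t, np.sqrt(c), atol=1e-12)

    def test_brute_force_toy_matrix(self):
        rng = np.random.default_rng(5)
        L = 6
        m = rng.uniform(0.1, 2.0, (L, L))
        v = (m + m.T) / 2.0
        np.fill_diagonal(v, 0.0)
        vm = VarianceMatrix(np.arange(1, L + 1), v, np.ones((L, L)))
        beta = 10.0
        t = coord_variation(vm, beta=beta)
        i = 2
        lam = np.sort([v[i, j] for j in range(L) if abs(i - j) > 1])
        n = len(lam)
        w = np.exp(-beta * ((np.arange(1, n + 1) / n) ** 2))
        t_ref = np.sum(w * np.sqrt(lam)) / np.sum(w)
        assert t[i] == pytest.approx(t_ref, abs=1e-12)


class TestOrderParams:
    @pytest.mark.parametrize(
        "s,t,S_exp,T_exp",
        [
            (0.0, 0.0, 1.0, 1.0),
            (75.0, 1.5, 0.5, 0.5),
            (75.0, 3.0, 0.5, 0.2),
        ],
    )
    def test_anchors(self, s, t, S_exp, T_exp):
        S, T = order_params(s, t, OrderConfig())
        assert S == pytest.approx(S_exp, abs=1e-12)
        assert T == pytest.approx(T_exp, abs=1e-12)

    def test_strictly_decreasing_and_bounded(self):
        s = np.linspace(0, 400, 100)
        S, T = order_params(s, s / 50.0, OrderConfig())
        assert np.all(np.diff(S) < 0) and np.all(np.diff(T) < 0)
        assert np.all((S > 0) & (S <= 1)) and np.all((T > 0) & (T <= 1))

    def test_negative_rejected(self):
        with pytest.raises(DisorderBenchError):
            order_params(-1.0, 0.0)


class TestEnsembleOrderProfile:
    def test_rigid_ensemble_fully_ordered(self, rigid_ensemble):
        prof = ensemble_order_profile(rigid_ensemble)
        assert np.allclose(prof.S[prof.s_defined], 1.0, atol=1e-9)
        assert np.allclose(prof.T[prof.t_defined], 1.0, atol=1e-9)

    def test_disordered_tail_scores_lower(self):
        cfg = GeneratorConfig(
            seed=42, length=40, n_conformers=8,
            fraction_disordered=0.25, core_amplitude=3.0, tail_amplitude=60.0,
        )
        ens, mask = gen_ensemble(cfg)
        prof = ensemble_order_profile(ens)
        assert np.nanmean(prof.S[mask]) < np.nanmean(prof.S[~mask])
        assert np.nanmean(prof.T[mask]) < np.nanmean(prof.T[~mask])

    def test_perturbation_amplitude_tracks_one_minus_t(self):
        """Planted per-residue amplitude correlates with 1-T (rank r > 0.8
        at a 5x amplitude contrast, averaged over seeds)."""
        rhos = []
        for seed in range(10):
            cfg = GeneratorConfig(
                seed=seed, length=40, n_conformers=10,
                fraction_disordered=0.5, core_amplitude=8.0, tail_amplitude=40.0,
            )
            ens, mask = gen_ensemble(cfg)
            prof = ensemble_order_profile(ens)
            amp = np.where(mask, 40.0, 8.0)
            ok = np.isfinite(prof.T)
            rhos.append(stats.spearmanr(amp[ok], 1.0 - prof.T[ok])[0])
        assert np.mean(rhos) > 0.8
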