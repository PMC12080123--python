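"""Wave-function factors, local energy and parameter derivatives."""

import time

import numpy as np
import pytest

from elqdo.errors import ConfigurationError, ParameterError
from elqdo.model import ElQdoSystem, Nucleus, make_qdo
from elqdo.wavefunction import (
    AnsatzParameters,
    BasisFunction,
    MolecularOrbitals,
    apply_parameter_update,
    coupling_factor,
    delta_log_psi,
    drudon_factor,
    evaluate,
    hydrogen_1s_orbitals,
    jastrow_three_body,
    jastrow_two_body,
    local_energy,
    log_abs_psi,
    parameter_labels,
    parameter_log_derivatives,
    slater_factor,
)


def _helium_like_setup(seed=3, n_qdos=2):
    """2 electrons + QDOs with every ansatz block active."""
    rng = np.random.default_rng(seed)
    qdos = [make_qdo("Ar", [3.0, 0, 0]), make_qdo("H2O", [0, 3.0, 1.0])][:n_qdos]
    system = ElQdoSystem(nuclei=[Nucleus([0, 0, 0], 2)], n_up=1, n_down=1, qdos=qdos)
    basis = (
        BasisFunction(center=[0, 0, 0], kind="gto", angular=(0, 0, 0),
                      exponents=(0.5, 1.5), coefficients=(0.7, 0.4)),
        BasisFunction(center=[0, 0, 0], kind="gto", angular=(1, 0, 0),
                      exponents=(0.8,), coefficients=(1.0,)),
    )
    mo = MolecularOrbitals(basis=basis, coefficients=np.array([[1.0, 0.2]]))
    jb = (
        BasisFunction(center=[0, 0, 0], kind="gto", angular=(0, 0, 0),
                      exponents=(0.6,), coefficients=(1.0,)),
        BasisFunction(center=[0, 0, 0], kind="gto", angular=(0, 0, 1),
                      exponents=(0.9,), coefficients=(1.0,)),
    )
    gamma = np.array([[0.1, -0.05], [-0.05, 0.2]])
    nq3 = 3 * len(qdos)
    A = np.diag(np.repeat(np.linspace(0.2, 0.3, len(qdos)), 3)) + 0.02
    A = 0.5 * (A + A.T)
    B = 0.03 * rng.standard_normal((3, nq3))
    params = AnsatzParameters(mo=mo, b_par=1.2, b_anti=0.9, g_par=[0.1],
                              zeta_par=[0.7], g_anti=[-0.05], zeta_anti=[1.1],
                              jastrow_basis=jb, gamma=gamma, A=A, B=B)
    e = 1.3 * rng.standard_normal((2, 3))
    d = np.stack([q.center for q in qdos]) + 0.4 * rng.standard_normal((len(qdos), 3))
    return params, system, e, d


class TestFactors:
    def test_pure_qdo_log_psi_is_gaussian(self, ar_qdo_system, ar_exact_params):
        d = np.array([[0.2, -0.4, 1.1]])
        lp, sign = log_abs_psi(ar_exact_params, ar_qdo_system, None, d)
        mw = 0.3020 * 0.7272
        assert lp == pytest.approx(-0.5 * mw * np.sum(d**2))
        assert sign == 1.0

    def test_hydrogen_exact_1s_log_psi(self, hydrogen_system, hydrogen_exact_params):
        e = np.array([[0.3, -1.2, 0.4]])
        lp, _ = log_abs_psi(hydrogen_exact_params, hydrogen_system, e, None)
        assert lp == pytest.approx(-np.linalg.norm(e))

    def test_same_spin_swap_flips_sign(self):
        system = ElQdoSystem(nuclei=[Nucleus([0, 0, 0], 3)], n_up=2, n_down=0)
        basis = (BasisFunction(center=[0, 0, 0], kind="sto1s", zeta=2.7),
                 BasisFunction(center=[0, 0, 0], kind="sto1s", zeta=0.65))
        mo = MolecularOrbitals(basis=basis, coefficients=np.eye(2))
        p = AnsatzParameters(mo=mo)
        e = np.array([[0.5, 0.1, -0.2], [-1.0, 0.7, 0.3]])
        lp1, s1 = log_abs_psi(p, system, e, None)
        lp2, s2 = log_abs_psi(p, system, e[::-1], None)
        assert lp1 == pytest.approx(lp2)
        assert s1 == -s2

    def test_slater_examples(self):
        system = ElQdoSystem(nuclei=[Nucleus([0, 0, 0], 1)], n_up=1)
        mo = hydrogen_1s_orbitals([0, 0, 0], 1.0)
        p = AnsatzParameters(mo=mo)
        e = np.array([[0.0, 0.0, 2.0]])
        la, s = slater_factor(p, system, e)
        assert s * np.exp(la) == pytest.approx(np.exp(-2.0))
        # two same-spin electrons at identical positions -> node
        sys2 = ElQdoSystem(nuclei=[Nucleus([0, 0, 0], 3)], n_up=2)
        mo2 = MolecularOrbitals(
            basis=(BasisFunction(center=[0, 0, 0], kind="sto1s", zeta=2.7),
                   BasisFunction(center=[0, 0, 0], kind="sto1s", zeta=0.65)),
            coefficients=np.eye(2))
        la2, s2 = slater_factor(AnsatzParameters(mo=mo2), sys2,
                                np.array([[1.0, 0, 0], [1.0, 0, 0]]))
        assert s2 == 0 or la2 == -np.inf

    def test_slater_2x2_vs_cofactor(self, rng):
        sys2 = ElQdoSystem(nuclei=[Nucleus([0, 0, 0], 3)], n_up=2)
        basis = (BasisFunction(center=[0, 0, 0], kind="sto1s", zeta=2.7),
                 BasisFunction(center=[0, 0, 0], kind="gto", angular=(0, 0, 0),
                               exponents=(0.4,), coefficients=(1.0,)))
        mo = MolecularOrbitals(basis=basis, coefficients=np.eye(2))
        p = AnsatzParameters(mo=mo)
        e = rng.standard_normal((2, 3))
        la, s = slater_factor(p, sys2, e)
        # brute-force cofactor expansion
        m = np.array([[b.evaluate(e[i])[0] for b in basis] for i in range(2)])
        det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
        assert s * np.exp(la) == pytest.approx(det, rel=1e-12)

    def test_missing_orbitals_rejected(self):
        sys2 = ElQdoSystem(nuclei=[Nucleus([0, 0, 0], 3)], n_up=2)
        p = AnsatzParameters(mo=hydrogen_1s_orbitals([0, 0, 0], 1.0))
        with pytest.raises(ConfigurationError):
            slater_factor(p, sys2, np.zeros((2, 3)))

    def test_jastrow_cusp_conditions(self):
        """du/dr at r=0 equals 1/4 (parallel) and 1/2 (antiparallel)."""
        system = ElQdoSystem(nuclei=[Nucleus([0, 0, 0], 2)], n_up=1, n_down=1)
        sys_par = ElQdoSystem(nuclei=[Nucleus([0, 0, 0], 2)], n_up=2, n_down=0)
        p = AnsatzParameters(mo=hydrogen_1s_orbitals([0, 0, 0]), b_par=1.3, b_anti=0.8)
        h = 1e-6
        for sys_, expected in ((system, 0.5), (sys_par, 0.25)):
            e0 = np.array([[0, 0, 0], [h, 0, 0]], float)
            e1 = np.array([[0, 0, 0], [2 * h, 0, 0]], float)
            du = (jastrow_two_body(p, sys_, e1) - jastrow_two_body(p, sys_, e0)) / h
            assert du == pytest.approx(expected, rel=1e-4)

    def test_jastrow_single_electron_zero(self, hydrogen_system):
        p = AnsatzParameters(mo=hydrogen_1s_orbitals([0, 0, 0]))
        assert jastrow_two_body(p, hydrogen_system, np.ones((1, 3))) == 0.0

    def test_jastrow_permutation_invariant(self, rng):
        params, system, e, _ = _helium_like_setup()
        assert jastrow_two_body(params, system, e) == pytest.approx(
            jastrow_two_body(params, system, e[::-1]))
        assert jastrow_three_body(params, system, e) == pytest.approx(
            jastrow_three_body(params, system, e[::-1]))

    def test_jastrow_three_body_against_triple_loop(self, rng):
        """Vectorised three-body Jastrow equals the naive loop to 1e-12."""
        for ne, qj in ((4, 3), (8, 5), (6, 1)):
            n_up = ne // 2
            system = ElQdoSystem(nuclei=[Nucleus([0, 0, 0], ne)], n_up=n_up,
                                 n_down=ne - n_up)
            jb = tuple(
                BasisFunction(center=rng.standard_normal(3) * 0.5, kind="gto",
                              angular=(0, 0, 0), exponents=(float(z),),
                              coefficients=(1.0,))
                for z in rng.uniform(0.3, 1.5, qj))
            g = rng.standard_normal((qj, qj))
            gamma = 0.5 * (g + g.T)
            p = AnsatzParameters(mo=hydrogen_1s_orbitals([0, 0, 0]),
                                 jastrow_basis=jb, gamma=gamma)
            e = rng.standard_normal((ne, 3))
            got = jastrow_three_body(p, system, e)
            ref = 0.0
            for i in range(ne):
                for j in range(i + 1, ne):
                    for a in range(qj):
                        for b in range(qj):
                            ref += gamma[a, b] * jb[a].evaluate(e[i])[0] * \
                                jb[b].evaluate(e[j])[0]
            assert got == pytest.approx(ref, abs=1e-12 * max(1, abs(ref)))

    def test_gamma_symmetry_enforced(self):
        jb = (BasisFunction(center=[0, 0, 0], kind="gto", angular=(0, 0, 0),
                            exponents=(0.5,), coefficients=(1.0,)),) * 2
        with pytest.raises(ParameterError):
            AnsatzParameters(jastrow_basis=jb, gamma=np.array([[0.1, 0.2], [0.3, 0.1]]))

    def test_gamma_zero_and_single_term(self):
        system = ElQdoSystem(nuclei=[Nucleus([0, 0, 0], 2)], n_up=1, n_down=1)
        chi = BasisFunction(center=[0, 0, 0], kind="gto", angular=(0, 0, 0),
                            exponents=(0.7,), coefficients=(1.0,))
        p0 = AnsatzParameters(mo=hydrogen_1s_orbitals([0, 0, 0]),
                              jastrow_basis=(chi,), gamma=np.zeros((1, 1)))
        e = np.array([[0.5, 0, 0], [0, 0.5, 0]])
        assert jastrow_three_body(p0, system, e) == 0.0
        c = 0.37
        p1 = AnsatzParameters(mo=hydrogen_1s_orbitals([0, 0, 0]),
                              jastrow_basis=(chi,), gamma=np.array([[c]]))
        expected = c * chi.evaluate(e[0])[0] * chi.evaluate(e[1])[0]
        assert jastrow_three_body(p1, system, e) == pytest.approx(expected)

    def test_drudon_factor_properties(self, ar_qdo_system):
        a = 0.35
        p = AnsatzParameters(A=a * np.eye(3))
        assert drudon_factor(p, ar_qdo_system, np.zeros((1, 3))) == 0.0
        d = np.array([[0.0, 0.0, 0.7]])
        assert drudon_factor(p, ar_qdo_system, d) == pytest.approx(-0.5 * a * 0.49)
        # block-diagonal A over two oscillators is separable
        sys2 = ElQdoSystem(qdos=[make_qdo("Ar", [0, 0, 0]), make_qdo("Ar", [0, 0, 9.0])])
        A2 = np.diag([0.3] * 3 + [0.5] * 3)
        p2 = AnsatzParameters(A=A2)
        d2 = np.array([[0.1, 0.2, -0.1], [0, 0, 9.4]])
        v_sum = (drudon_factor(AnsatzParameters(A=0.3 * np.eye(3)),
                               ElQdoSystem(qdos=[make_qdo("Ar", [0, 0, 0])]),
                               d2[:1])
                 + drudon_factor(AnsatzParameters(A=0.5 * np.eye(3)),
                                 ElQdoSystem(qdos=[make_qdo("Ar", [0, 0, 9.0])]),
                                 d2[1:]))
        assert drudon_factor(p2, sys2, d2) == pytest.approx(v_sum)

    def test_a_must_be_spd(self, ar_qdo_system):
        with pytest.raises(ParameterError):
            AnsatzParameters(A=-np.eye(3))
        with pytest.raises(ParameterError):
            AnsatzParameters(A=np.array([[1.0, 0.5, 0], [0.4, 1, 0], [0, 0, 1]]))

    def test_coupling_factor_trivial_zeros(self):
        params, system, e, d = _helium_like_setup()
        pB0 = AnsatzParameters(mo=params.mo, A=params.A,
                               B=np.zeros_like(params.B))
        assert coupling_factor(pB0, system, e, d) == 0.0
        # drudons at centers -> zero regardless of electrons
        d_at = np.stack([q.center for q in system.qdos])
        assert coupling_factor(params, system, e, d_at) == 0.0
        # vanishing dipole -> zero
        sys_h = ElQdoSystem(nuclei=[Nucleus([0, 0, 0], 1)], n_up=1,
                            qdos=[make_qdo("Ar", [4.0, 0, 0])])
        pB = AnsatzParameters(mo=hydrogen_1s_orbitals([0, 0, 0]),
                              A=np.diag(np.repeat(sys_h.qdo_mu * sys_h.qdo_omega, 3)),
                              B=np.ones((3, 3)))
        assert coupling_factor(pB, sys_h, np.zeros((1, 3)), d[:1]) == 0.0

    def test_drudon_distinguishability(self):
        """Permuting drudons of different oscillators changes the wave function."""
        sys2 = ElQdoSystem(qdos=[make_qdo("Ar", [0, 0, 0]), make_qdo("Ar", [0, 0, 9.0])])
        p = AnsatzParameters(A=np.diag([0.3] * 3 + [0.5] * 3))
        d = np.array([[0.1, 0.0, 0.3], [0.2, -0.1, 8.8]])
        lp1, _ = log_abs_psi(p, sys2, None, d)
        lp2, _ = log_abs_psi(p, sys2, None, d[::-1])
        assert abs(lp1 - lp2) > 1.0


class TestLocalEnergy:
    def test_qdo_exact_eigenstate_zero_variance(self, ar_qdo_system, ar_exact_params, rng):
        d = rng.standard_normal((200, 1, 3)) * 1.5
        el = local_energy(ar_exact_params, ar_qdo_system, None, d)
        assert np.allclose(el, 1.5 * 0.7272, atol=1e-12)
        assert np.var(el) < 1e-18

    def test_hydrogen_exact_eigenstate(self, hydrogen_system, hydrogen_exact_params, rng):
        e = rng.standard_normal((200, 1, 3))
        el = local_energy(hydrogen_exact_params, hydrogen_system, e, None)
        assert np.allclose(el, -0.5, atol=1e-10)
        assert np.var(el) < 1e-18

    def test_local_energy_matches_finite_difference(self):
        """Analytic kinetic assembly vs central finite differences of log|Psi|."""
        params, system, e, d = _helium_like_setup()
        res = evaluate(params, system, e, d)
        h = 1e-4

        def lp(e_, d_):
            return log_abs_psi(params, system, e_, d_)[0]

        for arr, grad, laplog, which in (
            (e, res["grad_e"], res["laplog_e"], "e"),
            (d, res["grad_d"], res["laplog_d"], "d"),
        ):
            for i in range(arr.shape[0]):
                lap_fd = 0.0
                for a in range(3):
                    up, dn = arr.copy(), arr.copy()
                    up[i, a] += h
                    dn[i, a] -= h
                    if which == "e":
                        fp, f0, fm = lp(up, d), lp(arr, d), lp(dn, d)
                    else:
                        fp, f0, fm = lp(e, up), lp(e, arr), lp(e, dn)
                    assert (fp - fm) / (2 * h) == pytest.approx(grad[i, a], rel=1e-6, abs=1e-8)
                    lap_fd += (fp - 2 * f0 + fm) / h**2
                assert lap_fd == pytest.approx(laplog[i], rel=1e-5, abs=1e-6)

    def test_same_spin_permutation_leaves_local_energy(self):
        rng = np.random.default_rng(7)
        system = ElQdoSystem(nuclei=[Nucleus([0, 0, 0], 3)], n_up=2, n_down=1)
        mo = MolecularOrbitals(
            basis=(BasisFunction(center=[0, 0, 0], kind="sto1s", zeta=2.7),
                   BasisFunction(center=[0, 0, 0], kind="sto1s", zeta=0.65)),
            coefficients=np.eye(2))
        p = AnsatzParameters(mo=mo, b_par=1.0, b_anti=1.0)
        e = rng.standard_normal((3, 3))
        e_swapped = e[[1, 0, 2]]
        el1 = local_energy(p, system, e, None)
        el2 = local_energy(p, system, e_swapped, None)
        assert el1 == pytest.approx(el2, rel=1e-12)


class TestParameterDerivatives:
    def test_against_finite_differences(self):
        params, system, e, d = _helium_like_setup()
        O = parameter_log_derivatives(params, system, e, d)
        labels = parameter_labels(params, system)
        assert O.shape == (len(labels),)
        h = 1e-5
        for k in range(len(labels)):
            dv = np.zeros(len(labels))
            dv[k] = h
            pp = apply_parameter_update(params, system, dv, spd_floor=-np.inf)
            pm = apply_parameter_update(params, system, -dv, spd_floor=-np.inf)
            fd = (log_abs_psi(pp, system, e, d)[0] - log_abs_psi(pm, system, e, d)[0]) / (2 * h)
            assert fd == pytest.approx(O[k], rel=1e-6, abs=1e-8), labels[k]

    def test_a_derivatives_vanish_at_centers(self, ar_qdo_system, ar_exact_params):
        O = parameter_log_derivatives(ar_exact_params, ar_qdo_system, None,
                                      np.zeros((1, 3)))
        assert np.allclose(O, 0.0)


class TestSingleParticleRatio:
    def test_delta_matches_full_recomputation(self):
        params, system, e, d = _helium_like_setup()
        rng = np.random.default_rng(11)
        lp0, _ = log_abs_psi(params, system, e, d)
        for species, idx in (("e", 0), ("e", 1), ("d", 0), ("d", 1)):
            new = (e if species == "e" else d)[idx] + 0.3 * rng.standard_normal(3)
            dlog, _ = delta_log_psi(params, system, e, d, species, idx, new)
            e2, d2 = e.copy(), d.copy()
            (e2 if species == "e" else d2)[idx] = new
            lp1, _ = log_abs_psi(params, system, e2, d2)
            assert dlog == pytest.approx(lp1 - lp0, rel=1e-10, abs=1e-12)


class TestCostScaling:
    def test_three_body_jastrow_quadratic_walltime(self):
        """Wall time of the three-body Jastrow grows ~quadratically in N_e."""
        rng = np.random.default_rng(0)
        qj = 4
        jb = tuple(
            BasisFunction(center=[0, 0, 0], kind="gto", angular=(0, 0, 0),
                          exponents=(float(z),), coefficients=(1.0,))
            for z in np.linspace(0.4, 1.2, qj))
        g = rng.standard_normal((qj, qj))
        gamma = 0.5 * (g + g.T)
        sizes = [8, 16, 32, 64]
        batch = 4096
        times = []
        for ne in sizes:
            system = ElQdoSystem(nuclei=[Nucleus([0, 0, 0], ne)], n_up=ne // 2,
                                 n_down=ne - ne // 2)
            p = AnsatzParameters(mo=hydrogen_1s_orbitals([0, 0, 0]),
                                 jastrow_basis=jb, gamma=gamma)
            e = rng.standard_normal((batch, ne, 3))
            jastrow_three_body(p, system, e)  # warm up
            reps = []
            for _ in range(5):
                t0 = time.perf_counter()
                jastrow_three_body(p, system, e)
                reps.append(time.perf_counter() - t0)
            times.append(min(reps))
        slope = np.polyfit(np.log(sizes), np.log(times), 1)[0]
        assert 1.7 <= slope <= 2.3, (sizes, times, slope)
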