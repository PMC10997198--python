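"""TrEsp and point-dipole couplings, matrix assembly, TDM fold change."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbsquench.constants import (
    DEBYE_PER_E_ANGSTROM,
    PDA_WAVENUMBER_ANGSTROM3_PER_DEBYE2 as PDA_C,
    TRESP_COULOMB_WAVENUMBER_ANGSTROM as TRESP_K,
)
from pbsquench.couplings import (
    CouplingRuleSet,
    build_coupling_matrix,
    load_transition_charges,
    orientation_factor,
    point_dipole_coupling,
    tdm_fold_change,
    tresp_coupling,
)
from pbsquench.errors import CoincidentAtomsError, ConfigurationError
from pbsquench.network import (
    Pigment,
    PigmentClass,
    PigmentNetwork,
    TransitionChargeSet,
)


def discretized_dipole(pid, center, axis, q=0.1, extent=1.0):
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    pts = [center - 0.5 * extent * axis, center + 0.5 * extent * axis]
    return TransitionChargeSet(pid, pts, [-q, q])


class TestTresp:
    def test_unit_charges_at_one_angstrom(self):
        a = TransitionChargeSet("a", [[0, 0, 0]], [1.0], charge_sum_tol=10)
        b = TransitionChargeSet("b", [[1, 0, 0]], [1.0], charge_sum_tol=10)
        assert tresp_coupling(a, b) == pytest.approx(TRESP_K)
        assert tresp_coupling(a, b) == pytest.approx(1.1614e5, rel=1e-4)

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetric_in_arguments(self, seed):
        rng = np.random.default_rng(seed)
        qa = rng.normal(size=4)
        qa -= qa.mean()
        qb = rng.normal(size=5)
        qb -= qb.mean()
        a = TransitionChargeSet("a", rng.normal(size=(4, 3)), qa)
        b = TransitionChargeSet("b", rng.normal(size=(5, 3)) + 20.0, qb)
        assert tresp_coupling(a, b) == pytest.approx(tresp_coupling(b, a), rel=1e-9)

    def test_linear_scaling_in_charges(self):
        a = discretized_dipole("a", np.zeros(3), [1, 0, 0])
        b = discretized_dipole("b", np.array([0.0, 0.0, 30.0]), [1, 0, 0])
        doubled = TransitionChargeSet("a2", a.atom_positions, 2 * a.charges)
        assert tresp_coupling(doubled, b) == pytest.approx(
            2 * tresp_coupling(a, b), rel=1e-12
        )

    def test_coincident_atoms_raise(self):
        a = TransitionChargeSet("a", [[0, 0, 0], [1, 0, 0]], [0.1, -0.1])
        with pytest.raises(CoincidentAtomsError):
            tresp_coupling(a, a)

    def test_converges_to_point_dipole(self):
        """Discretized ±0.1e dipoles approach the ideal-dipole coupling as
        the separation grows; < 1% beyond 25× the dipole extent."""
        mu = 0.1 * 1.0 * DEBYE_PER_E_ANGSTROM
        pa = Pigment("a", PigmentClass.APCA_PCB, [0, 0, 0], [1, 0, 0],
                     tdm_magnitude=mu)
        errs = []
        for sep in (10.0, 25.0, 50.0, 100.0):
            a = discretized_dipole("a", np.zeros(3), [1, 0, 0])
            b = discretized_dipole("b", np.array([0, 0, sep]), [1, 0, 0])
            pb = Pigment("b", PigmentClass.APCA_PCB, [0, 0, sep], [1, 0, 0],
                         tdm_magnitude=mu)
            exact = point_dipole_coupling(pa, pb)
            errs.append(abs(tresp_coupling(a, b) - exact) / abs(exact))
        assert all(e2 < e1 for e1, e2 in zip(errs, errs[1:]))
        assert errs[1] < 0.01  # 25 Å = 25× the 1 Å extent


class TestPointDipole:
    def _pig(self, pid, pos, u, mu=7.0):
        return Pigment(pid, PigmentClass.APCA_PCB, pos,
                       np.asarray(u, float) / np.linalg.norm(u),
                       tdm_magnitude=mu)

    def test_parallel_perpendicular_geometry(self):
        # μ = 7 D each, R = 15 Å, κ = 1
        a = self._pig("a", [0, 0, 0], [1, 0, 0])
        b = self._pig("b", [0, 0, 15.0], [1, 0, 0])
        expected = PDA_C * 49.0 / 15.0**3
        assert point_dipole_coupling(a, b) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(73.1, abs=0.5)

    def test_collinear_doubles_and_flips_sign(self):
        a = self._pig("a", [0, 0, 0], [0, 0, 1])
        head_tail = self._pig("b", [0, 0, 15.0], [0, 0, 1])
        side = self._pig("c", [0, 0, 15.0], [1, 0, 0])
        perp_a = self._pig("d", [0, 0, 0], [1, 0, 0])
        v_kappa1 = point_dipole_coupling(perp_a, side)
        v_kappa_m2 = point_dipole_coupling(a, head_tail)
        assert v_kappa_m2 == pytest.approx(-2.0 * v_kappa1, rel=1e-12)

    def test_screening_scales_linearly(self):
        a = self._pig("a", [0, 0, 0], [1, 0, 0])
        b = self._pig("b", [0, 0, 20.0], [1, 0, 0])
        assert point_dipole_coupling(a, b, screening=0.5) == pytest.approx(
            0.5 * point_dipole_coupling(a, b), rel=1e-12
        )

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_orientation_factor_bounded(self, seed):
        rng = np.random.default_rng(seed)
        u1, u2, r = (x / np.linalg.norm(x) for x in rng.normal(size=(3, 3)))
        assert -2.0 - 1e-12 <= orientation_factor(u1, u2, r) <= 2.0 + 1e-12

    def test_errors(self):
        a = self._pig("a", [0, 0, 0], [1, 0, 0])
        with pytest.raises(CoincidentAtomsError):
            point_dipole_coupling(a, self._pig("b", [0, 0, 0], [1, 0, 0]))
        bare = Pigment("c", PigmentClass.APCA_PCB, [0, 0, 9], [1, 0, 0])
        with pytest.raises(ConfigurationError):
            point_dipole_coupling(a, bare)


class TestFoldChange:
    def test_identity_and_threefold_drop(self):
        assert tdm_fold_change(7.0, 7.0) == 0.0
        assert tdm_fold_change(7.0 / 3, 7.0) == pytest.approx(-0.4771, abs=1e-4)

    @settings(derandomize=True, max_examples=25)
    @given(st.floats(0.1, 50), st.floats(0.1, 50))
    def test_antisymmetry(self, a, b):
        assert tdm_fold_change(a, b) == pytest.approx(-tdm_fold_change(b, a),
                                                      abs=1e-12)

    def test_natural_log_base(self):
        assert tdm_fold_change(2.0, 1.0, base=math.e) == pytest.approx(math.log(2))

    @pytest.mark.parametrize("mu,ref", [(0.0, 1.0), (1.0, -2.0)])
    def test_nonpositive_raises(self, mu, ref):
        with pytest.raises(ValueError):
            tdm_fold_change(mu, ref)


class TestBuildCouplingMatrix:
    def _network(self):
        pigments = [
            Pigment("pcb1", PigmentClass.APCA_PCB, [0, 0, 0], [1, 0, 0],
                    tdm_magnitude=7.0),
            Pigment("pcb2", PigmentClass.APCA_PCB, [0, 0, 20.0], [1, 0, 0],
                    tdm_magnitude=7.0),
            Pigment("pcb3", PigmentClass.APCB_PCB, [0, 20.0, 0], [0, 1, 0],
                    tdm_magnitude=7.0),
            Pigment("can1", PigmentClass.CAN, [12.0, 0, 0], [1, 0, 0],
                    tdm_magnitude=7.0),
        ]
        return PigmentNetwork(pigments=pigments)

    def test_sampled_printed_means_and_zeros_elsewhere(self):
        net = self._network()
        rules = CouplingRuleSet(
            can_pcb_whitelist=(("can1", "pcb1"), ("can1", "pcb2")),
        )
        out = build_coupling_matrix(
            net, rules,
            sampled={("can1", "pcb1"): 54.0, ("can1", "pcb2"): 27.0},
        )
        i = out.index_of("can1")
        assert out.couplings[i, out.index_of("pcb1")] == 54.0
        assert out.couplings[i, out.index_of("pcb2")] == 27.0
        assert out.couplings[i, out.index_of("pcb3")] == 0.0  # neglected: exact 0
        # PCB-PCB entries via the point-dipole approximation
        v12 = point_dipole_coupling(net.pigments[0], net.pigments[1])
        assert out.couplings[0, 1] == pytest.approx(v12)
        assert np.array_equal(out.couplings, out.couplings.T)
        assert np.all(np.diag(out.couplings) == 0)

    def test_single_pigment_zero_matrix(self):
        net = PigmentNetwork(pigments=[
            Pigment("p", PigmentClass.APCA_PCB, [0, 0, 0], [1, 0, 0],
                    tdm_magnitude=7.0)
        ])
        out = build_coupling_matrix(net, CouplingRuleSet())
        assert out.couplings.shape == (1, 1)
        assert out.couplings[0, 0] == 0.0

    def test_missing_sampled_value_names_pair(self):
        net = self._network()
        rules = CouplingRuleSet(can_pcb_whitelist=(("can1", "pcb1"),))
        with pytest.raises(ConfigurationError, match="can1.*pcb1"):
            build_coupling_matrix(net, rules, sampled={})

    def test_whitelist_unknown_pigment_raises(self):
        with pytest.raises(ConfigurationError, match="ghost"):
            build_coupling_matrix(
                self._network(),
                CouplingRuleSet(can_pcb_whitelist=(("can1", "ghost"),)),
                sampled={("can1", "ghost"): 1.0},
            )

    def test_tresp_mode_requires_charges(self):
        net = self._network()
        rules = CouplingRuleSet(
            can_pcb_method="tresp",
            can_pcb_whitelist=(("can1", "pcb1"),),
        )
        with pytest.raises(ConfigurationError, match="charges"):
            build_coupling_matrix(net, rules)


def test_load_transition_charges(tmp_path):
    table = tmp_path / "charges.dat"
    table.write_text(
        "atom x y z q\n"
        "C1 0.0 0.0 0.0 -0.10\n"
        "C2 1.0 0.0 0.0 0.10\n"
    )
    tcs = load_transition_charges(table, "pig")
    assert tcs.charges.tolist() == [-0.10, 0.10]
    assert tcs.dipole_debye() == pytest.approx(0.48032, abs=1e-4)
    bad = tmp_path / "bad.dat"
    bad.write_text("foo bar\n1 2\n")
    with pytest.raises(ConfigurationError, match="columns"):
        load_transition_charges(bad, "pig")
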