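"""Stimulus arithmetic, homogenization and both mechanics backends."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import callusim as cs
from callusim.fe import FEBackend, HexGrid, solve_poroelastic
from callusim.mechanics import MATERIALS, MaterialField
from callusim.orchestrator import _ElementMaterials
from callusim.tissue import TissueFractions


class TestOctahedralShear:
    @pytest.mark.parametrize(
        "strain, expected",
        [
            ((0, 0, 0, 0, 0, 0), 0.0),
            ((0.03, 0, 0, 0, 0, 0), 2.0 * np.sqrt(2.0) / 3.0 * 0.03),
            ((0, 0, 0, 0.01, 0, 0), 2.0 / 3.0 * np.sqrt(6.0) * 0.01),
        ],
    )
    def test_closed_forms(self, strain, expected):
        assert cs.octahedral_shear(np.array(strain)) == pytest.approx(expected)

    def test_pure_shear_matches_symbolic_oracle(self):
        """Independent symbolic evaluation of the invariant definition."""
        import sympy as sp

        s = 0.0123
        e = sp.Matrix([[0, s, 0], [s, 0, 0], [0, 0, 0]])
        ev = e.eigenvals()
        e1, e2, e3 = [sp.nsimplify(k) for k, m in ev.items() for _ in range(m)]
        gamma_sym = sp.Rational(2, 3) * sp.sqrt(
            (e1 - e2) ** 2 + (e2 - e3) ** 2 + (e1 - e3) ** 2
        )
        got = cs.octahedral_shear(np.array([0, 0, 0, s, 0, 0]))
        assert got == pytest.approx(float(gamma_sym), rel=1e-12)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(3)
        e = rng.normal(scale=0.01, size=(3, 3))
        e = (e + e.T) / 2
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        er = q @ e @ q.T

        def comps(m):
            return np.array(
                [m[0, 0], m[1, 1], m[2, 2], m[0, 1], m[1, 2], m[0, 2]]
            )

        assert cs.octahedral_shear(comps(e)) == pytest.approx(
            cs.octahedral_shear(comps(er)), rel=1e-10
        )

    def test_unsquared_variant_clamps_negative_radicand(self):
        e = np.array([0, 0, 0, -0.1, 0, 0])
        assert cs.octahedral_shear(e, unsquared_shear=True) == 0.0


class TestStimulus:
    @pytest.mark.parametrize(
        "gamma, v, expected",
        [(0.0375, 3.0, 2.0), (0.0, 0.0, 0.0), (0.075, 6.0, 4.0)],
    )
    def test_reference_values(self, gamma, v, expected):
        assert cs.stimulus(gamma, v) == pytest.approx(expected)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            cs.stimulus(-0.01, 0.0)
        with pytest.raises(ValueError):
            cs.stimulus(0.01, -1.0)

    @given(
        g=st.floats(0, 0.5), v=st.floats(0, 50),
        dg=st.floats(1e-6, 0.1), dv=st.floats(1e-6, 10),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_strictly_increasing_in_each_argument(self, g, v, dg, dv):
        base = cs.stimulus(g, v)
        assert cs.stimulus(g + dg, v) > base
        assert cs.stimulus(g, v + dv) > base


class TestHomogenization:
    def test_pure_granulation_reproduces_card(self):
        fractions = np.zeros((1, 4))
        fractions[0, 0] = 1.0
        mats = cs.homogenize_materials(fractions)
        assert mats.young_modulus[0] == pytest.approx(0.2)
        assert mats.poisson_ratio[0] == pytest.approx(0.167)

    def test_fifty_fifty_bone_cartilage(self):
        # arithmetic rule of mixtures by hand: (5000 + 10)/2
        fractions = np.array([[0.0, 0.0, 0.5, 0.5]])
        mats = cs.homogenize_materials(fractions)
        assert mats.young_modulus[0] == pytest.approx(2505.0)

    def test_single_tissue_reproduces_its_card(self):
        for col, tissue in enumerate(("granulation", "fibrous", "cartilage", "bone")):
            fractions = np.zeros((1, 4))
            fractions[0, col] = 1.0
            mats = cs.homogenize_materials(fractions)
            card = MATERIALS[tissue]
            assert mats.young_modulus[0] == pytest.approx(card.young_modulus)
            assert mats.permeability[0] == pytest.approx(card.permeability)

    def test_unknown_tissue_label_rejected(self):
        with pytest.raises(KeyError):
            cs.homogenize_materials(
                np.array([[1.0, 0.0]]), tissue_order=("granulation", "mystery")
            )

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            cs.homogenize_materials(np.array([[0.5, 0.1, 0.1, 0.1]]))


def _affine_patch_bc(grid, exx, eyy, ezz):
    coords = grid.node_coords()
    nx, ny, nz = grid.node_shape
    bc = {}
    for n in range(grid.n_nodes):
        i, j, k = n // (ny * nz), (n // nz) % ny, n % nz
        if i in (0, nx - 1) or j in (0, ny - 1) or k in (0, nz - 1):
            x, y, z = coords[n]
            bc[(n, 0)] = exx * x
            bc[(n, 1)] = eyy * y
            bc[(n, 2)] = ezz * z
    return bc


class TestFiniteElements:
    def test_patch_test_uniform_strain(self):
        """Affine boundary displacement reproduces the constant strain."""
        grid = HexGrid.box((3, 3, 3), 0.5)
        mats = MaterialField.uniform(MATERIALS["granulation"], 27)
        target = (0.01, -0.005, 0.02)
        res = solve_poroelastic(grid, mats, _affine_patch_bc(grid, *target),
                                drained=True)
        err = np.abs(res["strain"] - np.array(target + (0, 0, 0))).max()
        assert err < 1e-8 * max(abs(t) for t in target)

    def test_linearity_doubling_stiffness_halves_displacement(self):
        grid = HexGrid.box((2, 2, 6), 0.5)

        def solve(scale):
            E = np.full(24, 10.0 * scale)
            mats = MaterialField(E, np.full(24, 0.3), np.ones(24),
                                 np.full(24, 2300.0), np.full(24, 2300.0))
            bc = {(int(n), d): 0.0 for n in grid.boundary_nodes(2, 0)
                  for d in range(3)}
            top = grid.boundary_nodes(2, 1)
            forces = {(int(n), 2): -1.0 / top.size for n in top}
            res = solve_poroelastic(grid, mats, bc, forces=forces, drained=True)
            return res["u"][2::3].min()

        assert solve(2.0) == pytest.approx(solve(1.0) / 2.0, rel=1e-9)

    def test_stiffer_callus_smaller_interfragmentary_strain(self):
        """Two-spring series oracle: the soft segment in a stiff/soft column
        strains more than in an all-stiff column, and matches E_hard/E_soft
        load sharing analytically."""
        grid = HexGrid.box((2, 2, 8), 0.5)
        bc = {(int(n), d): 0.0 for n in grid.boundary_nodes(2, 0) for d in range(3)}
        top = grid.boundary_nodes(2, 1)
        forces = {(int(n), 2): -1.0 / top.size for n in top}

        # active elements are ordered (i, j, k) with k fastest: the top
        # half of each column is k >= 4
        top_half = (np.arange(32) % 8) >= 4

        def gap_strain(E_gap):
            E = np.full(32, 5000.0)
            E[top_half] = E_gap
            mats = MaterialField(E, np.full(32, 0.3), np.ones(32),
                                 np.full(32, 2300.0), np.full(32, 2300.0))
            res = solve_poroelastic(grid, mats, bc, forces=forces, drained=True)
            return abs(res["strain"][top_half, 2].mean())

        soft = gap_strain(10.0)
        hard = gap_strain(5000.0)
        assert hard < soft
        # series springs: strain ratio ~ E_hard / E_soft (uniaxial oracle)
        area = 4 * 0.5**2
        sigma = 1.0 / area
        assert soft == pytest.approx(sigma / 10.0, rel=0.15)
        assert hard == pytest.approx(sigma / 5000.0, rel=0.15)

    def test_zero_permeability_means_zero_fluid_speed(self):
        grid = HexGrid.box((2, 2, 2), 0.5)
        mats = MaterialField(np.full(8, 1.0), np.full(8, 0.3), np.zeros(8),
                             np.full(8, 2300.0), np.full(8, 2300.0))
        bc = {(int(n), d): 0.0 for n in grid.boundary_nodes(2, 0) for d in range(3)}
        for n in grid.boundary_nodes(2, 1):
            bc[(int(n), 2)] = -0.01
        res = solve_poroelastic(grid, mats, bc, ramp_seconds=1.0)
        assert np.all(res["fluid_speed"] == 0.0)

    def test_consolidation_produces_fluid_flow(self):
        grid = HexGrid.box((2, 2, 2), 0.5)
        mats = MaterialField(np.full(8, 1.0), np.full(8, 0.3), np.ones(8),
                             np.full(8, 2300.0), np.full(8, 2300.0))
        bc = {(int(n), d): 0.0 for n in grid.boundary_nodes(2, 0) for d in range(3)}
        for n in grid.boundary_nodes(2, 1):
            bc[(int(n), 2)] = -0.01
        res = solve_poroelastic(grid, mats, bc, ramp_seconds=1.0)
        assert res["fluid_speed"].max() > 0.0


class TestBackends:
    def test_fe_backend_axisymmetric_field(self, small_domain):
        lattice = cs.build_domain(small_domain)
        mats = _ElementMaterials(lattice).build(TissueFractions(lattice))
        backend = FEBackend(lattice)
        state = backend.solve(mats, cs.LoadCase(kind="gait", gait_force_n=7.0))
        S = state.S.reshape(lattice.element_shape)
        assert np.abs(S - np.rot90(S, 1, axes=(0, 1))).max() < 1e-6

    @pytest.mark.parametrize("backend_cls", [cs.SurrogateBackend, FEBackend])
    def test_crossbar_removal_increases_displacement(self, small_domain,
                                                     backend_cls):
        lattice = cs.build_domain(small_domain)
        mats = _ElementMaterials(lattice).build(TissueFractions(lattice))
        backend = backend_cls(lattice)
        with_bar = backend.solve(
            mats, cs.LoadCase(kind="gait", crossbar_present=True)
        )
        without = backend.solve(
            mats, cs.LoadCase(kind="gait", crossbar_present=False)
        )
        assert (
            without.interfragmentary_displacement_mm
            > with_bar.interfragmentary_displacement_mm
        )

    def test_surrogate_all_bone_stiffer_than_granulation(self, small_domain):
        lattice = cs.build_domain(small_domain)
        backend = cs.SurrogateBackend(lattice)
        soft = TissueFractions(lattice)
        hard = TissueFractions(lattice)
        hard.fractions[:, :] = 0.0
        hard.fractions[:, 3] = 1.0
        builder = _ElementMaterials(lattice)
        load = cs.LoadCase(kind="gait", gait_force_n=7.0)
        d_soft = backend.solve(builder.build(soft), load)
        d_hard = backend.solve(builder.build(hard), load)
        assert (
            d_hard.interfragmentary_displacement_mm
            < d_soft.interfragmentary_displacement_mm
        )

    def test_surrogate_state_invariants(self, small_domain):
        lattice = cs.build_domain(small_domain)
        backend = cs.SurrogateBackend(lattice)
        mats = _ElementMaterials(lattice).build(TissueFractions(lattice))
        state = backend.solve(mats, cs.LoadCase(kind="gait"))
        assert np.all(state.gamma >= 0)
        assert np.all(state.fluid_speed >= 0)
        assert np.all(state.S >= 0)


class TestLoadCase:
    def test_stimulation_requires_crossbar_removed(self):
        with pytest.raises(ValueError):
            cs.LoadCase(kind="stimulation", crossbar_present=True)

    def test_stimulation_ramp_from_rate(self):
        lc = cs.LoadCase(kind="stimulation", axial_displacement_um=500,
                         ramp_rate_um_s=10, crossbar_present=False)
        assert lc.ramp_seconds == pytest.approx(50.0)

    def test_fixator_stiffness_positive_and_configurable(self):
        k = cs.fixator_axial_stiffness()
        assert 1.0 < k < 1000.0
        rigid = cs.fixator_axial_stiffness(pin_diameter_mm=5.0,
                                           pin_free_length_mm=2.0)
        assert rigid > k
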