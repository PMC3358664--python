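"""Exact and HCP engines: oracle agreement, accounting, scaling."""

import math

import numpy as np
import pytest

from hcpesp import (
    ALPBParams,
    CoincidentPointError,
    HCPThresholds,
    VertexSet,
    build_hierarchy,
    esp_exact,
    esp_hcp,
    generate_structure,
    generate_vertices,
    scaling_experiment,
    SynthSpec,
)

from conftest import make_atom


def brute_force_potentials(structure, vertices, params):
    """Independent double-loop oracle, written directly from the ALPB formula."""
    beta = params.eps_in / params.eps_out
    pref = params.unit_factor / (params.eps_in * (1.0 + params.alpha * beta))
    out = []
    center = vertices.center
    for v in vertices.points:
        r = math.dist(v, center)
        phi = 0.0
        for a in structure.atoms:
            d = math.dist(v, a.position)
            phi += pref * a.charge * ((1.0 + params.alpha) / d - params.alpha * (1.0 - beta) / r)
        out.append(phi)
    return np.array(out)


class TestExactEngine:
    def test_single_atom_coulomb_limit(self):
        s = build_hierarchy([make_atom(1, [0, 0, 0], 1.0)])
        vs = VertexSet(points=[[0, 0, 2.0]], center=[0.0, 0.0, 0.0])
        res = esp_exact(s, vs, ALPBParams(eps_in=80.0, eps_out=80.0))
        assert res.potentials[0] == pytest.approx(0.00625, rel=1e-13)
        assert res.kernel_calls == 1
        assert res.level_usage == {"atom": 1}

    def test_empty_vertices_rejected(self, toy_structure):
        with pytest.raises(ValueError):
            esp_exact(toy_structure, VertexSet(points=np.empty((0, 3)).reshape(0, 3)))

    def test_matches_brute_force_oracle(self):
        s = generate_structure(SynthSpec(n_strands=2, residues_per_strand=10,
                                         atoms_per_residue=10, seed=31))
        assert s.n_atoms == 200
        vs = generate_vertices(s, 50, seed=31)
        params = ALPBParams(eps_in=1.0, eps_out=80.0)
        res = esp_exact(s, vs, params)
        expected = brute_force_potentials(s, vs, params)
        np.testing.assert_allclose(res.potentials, expected, rtol=1e-10)
        assert res.kernel_calls == 200 * 50

    def test_coincident_vertex_identified(self):
        s = build_hierarchy([make_atom(1, [0, 0, 0], 1.0), make_atom(2, [3, 0, 0], -0.5)])
        vs = VertexSet(points=[[0, 0, 5.0], [3.0, 0, 0]], center=s.center)
        with pytest.raises(CoincidentPointError, match="vertex 1.*atom 1"):
            esp_exact(s, vs)

    def test_total_potential_is_reduce_of_vertices(self, small_structure, small_vertices):
        res = esp_exact(small_structure, small_vertices)
        assert res.total_potential == pytest.approx(res.potentials.sum(), rel=1e-12)


class TestHCPEngine:
    def test_infinite_thresholds_equal_exact(self, small_structure, small_vertices):
        params = ALPBParams(eps_in=1.0, eps_out=80.0)
        exact = esp_exact(small_structure, small_vertices, params)
        hcp = esp_hcp(small_structure, small_vertices, params, HCPThresholds.infinite())
        np.testing.assert_allclose(hcp.potentials, exact.potentials, rtol=1e-12)
        assert set(hcp.level_usage) == {"atom"}
        assert hcp.kernel_calls == exact.kernel_calls

    def test_single_atom_residues_lossless_at_zero_threshold(self):
        # one atom per residue: its order-2 approximation is the atom itself
        atoms = [make_atom(i + 1, [4.0 * i, 0, 0], (-1) ** i * 0.3, resnum=i + 1)
                 for i in range(6)]
        s = build_hierarchy(atoms)
        vs = VertexSet(points=[[10.0, 15.0, 0]], center=s.center)
        params = ALPBParams(eps_in=1.0, eps_out=80.0)
        exact = esp_exact(s, vs, params)
        hcp = esp_hcp(s, vs, params, HCPThresholds(residue=0.0, strand=math.inf), order=2)
        np.testing.assert_allclose(hcp.potentials, exact.potentials, rtol=1e-12)

    def test_two_dipole_residues_hand_sum(self):
        """A far vertex sees two neutral dipole residues through their four
        approximate point charges; the engine must equal that hand-built sum."""
        atoms = [
            make_atom(1, [0.0, 0, 0], 0.5, resnum=1),
            make_atom(2, [1.0, 0, 0], -0.5, resnum=1),
            make_atom(3, [5.0, 0, 0], 0.5, resnum=2),
            make_atom(4, [6.0, 0, 0], -0.5, resnum=2),
        ]
        s = build_hierarchy(atoms)
        v = np.array([100.0, 0.0, 0.0])
        vs = VertexSet(points=[v], center=s.center)
        params = ALPBParams(eps_in=1.0, eps_out=80.0)
        hcp = esp_hcp(s, vs, params, HCPThresholds(residue=10.0, strand=math.inf), order=2)
        beta = params.eps_in / params.eps_out
        pref = 1.0 / (1.0 + params.alpha * beta)
        r = math.dist(v, s.center)
        expected = sum(
            pref * q * ((1 + params.alpha) / math.dist(v, x) - params.alpha * (1 - beta) / r)
            for q, x in [(0.5, [0, 0, 0]), (-0.5, [1, 0, 0]), (0.5, [5, 0, 0]), (-0.5, [6, 0, 0])]
        )
        assert hcp.potentials[0] == pytest.approx(expected, rel=1e-12)
        assert hcp.kernel_calls == 4
        assert hcp.level_usage == {"residue": 2}

    def test_work_bound_under_finite_thresholds(self, ensemble):
        for structure, vertices in ensemble[:5]:
            exact = esp_exact(structure, vertices)
            hcp = esp_hcp(structure, vertices, thresholds=HCPThresholds())
            assert hcp.kernel_calls <= exact.kernel_calls

    def test_traversal_deterministic(self, small_structure, small_vertices):
        a = esp_hcp(small_structure, small_vertices)
        b = esp_hcp(small_structure, small_vertices)
        np.testing.assert_array_equal(a.potentials, b.potentials)
        assert a.kernel_calls == b.kernel_calls

    def test_rigid_motion_invariance(self):
        from scipy.spatial.transform import Rotation

        spec = SynthSpec(n_strands=4, residues_per_strand=15, atoms_per_residue=5, seed=3)
        s = generate_structure(spec)
        vs = generate_vertices(s, 48, seed=3)
        R = Rotation.random(rng=np.random.default_rng(11)).as_matrix()
        t = np.array([13.0, -7.0, 101.0])
        atoms_t = [
            make_atom(a.serial, R @ a.position + t, a.charge, chain=a.chain_id,
                      resnum=a.residue_number)
            for a in s.atoms
        ]
        s_t = build_hierarchy(atoms_t)
        vs_t = VertexSet(points=vs.points @ R.T + t, center=R @ vs.center + t)
        for engine in (esp_exact, esp_hcp):
            ref = engine(s, vs).potentials
            moved = engine(s_t, vs_t).potentials
            np.testing.assert_allclose(moved, ref, rtol=1e-9)


class TestScalingExperiment:
    def test_exact_calls_are_product(self):
        tab = scaling_experiment([100], 10, seed=1)
        assert tab.kernel_calls_exact[0] == 1000

    def test_infinite_thresholds_match_exact_counts(self):
        tab = scaling_experiment([100], 10, thresholds=HCPThresholds.infinite(), seed=1)
        assert tab.kernel_calls_hcp[0] == tab.kernel_calls_exact[0]

    def test_sublinear_growth_on_spread_out_fixture(self):
        tab = scaling_experiment([1000, 2000], 50, seed=42)
        assert tab.kernel_calls_exact[1] / tab.kernel_calls_exact[0] == 2.0
        assert tab.kernel_calls_hcp[1] / tab.kernel_calls_hcp[0] < 1.9

    def test_decreasing_sizes_rejected(self):
        with pytest.raises(ValueError):
            scaling_experiment([200, 100], 10, seed=1)
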