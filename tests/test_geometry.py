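"""FAPE, chirality pseudoscalar, bonded geometry, lDDT — against brute force."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atomdenoise.autodiff import Tensor
from atomdenoise.chemgraph import ChiralCenter, Conformation
from atomdenoise.fixtures import FixtureSpec, _random_rotation, make_molecule
from atomdenoise.geometry import (bonded_geometry_errors, chirality_bias_vectors,
                                  enumerate_frames, fape_allatom, lddt_per_atom,
                                  triple_product_V)
from conftest import random_molecule

TET = np.array([[1.0, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(3)
V_IDEAL = 4.0 / (3.0 * np.sqrt(3.0))


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def frame_basis(coords, a, b, c):
    x = coords[c] - coords[b]
    x = x / np.linalg.norm(x)
    y = coords[a] - coords[b]
    y = y - np.dot(y, x) * x
    y = y / np.linalg.norm(y)
    return np.stack([x, y, np.cross(x, y)])


def fape_brute(model, ref, graph, clamp=10.0):
    frames = enumerate_frames(graph, ref)
    devs = []
    for (a, b, c) in frames:
        Rm, Rr = frame_basis(model, a, b, c), frame_basis(ref, a, b, c)
        for i in range(len(model)):
            lm = Rm @ (model[i] - model[b])
            lr = Rr @ (ref[i] - ref[b])
            devs.append(min(np.linalg.norm(lm - lr), clamp))
    return float(np.mean(devs))


def lddt_brute(model, ref, graph, radius=15.0, thresholds=(0.5, 1, 2, 4)):
    n = len(model)
    sep = graph.bond_separation
    vals, defined = np.zeros(n), np.zeros(n, dtype=bool)
    for i in range(n):
        fr = []
        for j in range(n):
            if j == i or sep[i, j] < 4:
                continue
            dr = np.linalg.norm(ref[i] - ref[j])
            if dr >= radius:
                continue
            dm = np.linalg.norm(model[i] - model[j])
            fr.append(np.mean([abs(dm - dr) < t for t in thresholds]))
        if fr:
            vals[i], defined[i] = np.mean(fr), True
    return vals, defined


def geometry_brute(model, ref, graph):
    def angle(c, i, j, k):
        u, v = c[i] - c[j], c[k] - c[j]
        return np.degrees(np.arccos(np.clip(
            np.dot(u, v) / np.linalg.norm(u) / np.linalg.norm(v), -1, 1)))

    bond = [abs(np.linalg.norm(model[i] - model[j])
                - np.linalg.norm(ref[i] - ref[j])) for i, j, _ in graph.bonds]
    ang = []
    for (a, b, c) in enumerate_frames(graph):
        d = angle(model, a, b, c) - angle(ref, a, b, c)
        ang.append(abs((d + 180) % 360 - 180))
    return (np.mean(bond) if bond else 0.0, np.mean(ang) if ang else 0.0)


# ---------------------------------------------------------------------------
# frames
# ---------------------------------------------------------------------------

class TestEnumerateFrames:
    def test_three_atom_chain_single_frame(self):
        graph, _ = make_molecule(FixtureSpec("chain", size=3))
        assert enumerate_frames(graph) == [(0, 1, 2)]

    def test_six_ring_has_six_frames(self, ring6):
        graph, _ = ring6
        assert len(enumerate_frames(graph)) == 6

    def test_disconnected_diatomics_have_no_frames(self):
        from atomdenoise.chemgraph import build_chemgraph
        from atomdenoise.io_formats import MolRecord

        recs = [MolRecord(f"d{k}", [("C", 0), ("C", 0)], [(0, 1, 1)],
                          np.array([[0, 0, 3.0 * k], [1.5, 0, 3.0 * k]]))
                for k in range(2)]
        graph, _ = build_chemgraph(ligands=recs)
        assert enumerate_frames(graph) == []

    def test_collinear_reference_triples_are_excluded(self):
        from atomdenoise.chemgraph import build_chemgraph
        from atomdenoise.io_formats import MolRecord

        rec = MolRecord("lin", [("C", 0)] * 3, [(0, 1, 1), (1, 2, 1)],
                        np.array([[0, 0, 0], [1.5, 0, 0], [3.0, 0, 0.0]]))
        graph, ref = build_chemgraph(ligands=[rec])
        assert enumerate_frames(graph) == [(0, 1, 2)]
        assert enumerate_frames(graph, ref) == []


# ---------------------------------------------------------------------------
# FAPE
# ---------------------------------------------------------------------------

class TestFape:
    def test_identity_and_rigid_motion_give_zero(self, chain5, rng):
        graph, ref = chain5
        assert fape_allatom(ref, ref, graph) == pytest.approx(0.0, abs=1e-9)
        R = _random_rotation(rng)
        moved = Conformation(ref.coords @ R.T + np.array([4.0, -2, 1]), ref.mask)
        assert fape_allatom(moved, ref, graph) == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_on_random_molecules(self):
        for seed in range(6):
            g = np.random.default_rng(100 + seed)
            graph, ref = random_molecule(g, 8, 12)
            model = ref.coords + g.normal(0, 0.7, ref.coords.shape)
            got = fape_allatom(model, ref.coords, graph)
            want = fape_brute(model, ref.coords, graph)
            assert got == pytest.approx(want, abs=1e-6)

    def test_terminal_atom_50A_away_contributes_the_clamp(self):
        graph, ref = make_molecule(FixtureSpec("chain", size=4))
        model = ref.coords.copy()
        model[3] += np.array([0.0, 50.0, 0.0])
        # deviation of atom 3 in the frame of atoms 0-1-2 is clamped at 10 Å
        Rm = frame_basis(model, 0, 1, 2)
        lm = Rm @ (model[3] - model[1])
        lr = frame_basis(ref.coords, 0, 1, 2) @ (ref.coords[3] - ref.coords[1])
        assert np.linalg.norm(lm - lr) > 10.0
        assert min(np.linalg.norm(lm - lr), 10.0) == pytest.approx(10.0)
        got = fape_allatom(model, ref.coords, graph)
        assert got == pytest.approx(fape_brute(model, ref.coords, graph), abs=1e-6)

    def test_gradient_vanishes_beyond_the_clamp(self):
        # the displaced atom must not define any frame itself, so use a
        # disconnected probe atom scored in the chain's single frame
        from atomdenoise.chemgraph import build_chemgraph
        from atomdenoise.io_formats import MolRecord

        chain = MolRecord("tri", [("C", 0)] * 3, [(0, 1, 1), (1, 2, 1)],
                          np.array([[0, 0, 0], [1.5, 0, 0], [2.3, 1.3, 0.0]]))
        probe = MolRecord("probe", [("O", 0)], [], np.array([[0.0, 3.0, 0.0]]))
        graph, ref = build_chemgraph(ligands=[chain, probe])
        model = ref.coords.copy()
        model[3] += np.array([0.0, 50.0, 0.0])
        t = Tensor(model, requires_grad=True)
        fape_allatom(t, ref.coords, graph).backward()
        assert np.allclose(t.grad[3], 0.0)  # saturated in every frame
        assert np.isfinite(t.grad).all()

    def test_fewer_than_one_frame_is_an_error(self):
        from atomdenoise.chemgraph import build_chemgraph
        from atomdenoise.io_formats import MolRecord

        rec = MolRecord("di", [("C", 0), ("C", 0)], [(0, 1, 1)],
                        np.array([[0, 0, 0], [1.5, 0, 0.0]]))
        graph, ref = build_chemgraph(ligands=[rec])
        with pytest.raises(ValueError):
            fape_allatom(ref, ref, graph)


# ---------------------------------------------------------------------------
# chirality
# ---------------------------------------------------------------------------

class TestTripleProduct:
    def test_ideal_tetrahedron_magnitude(self):
        v = triple_product_V(np.zeros(3), *TET[:3])
        assert abs(abs(v) - V_IDEAL) < 1e-12

    def test_coplanar_gives_zero_and_mirror_flips(self):
        o = np.zeros(3)
        a, b, c = np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([1.0, 1, 0])
        assert triple_product_V(o, a, b, c) == pytest.approx(0.0, abs=1e-12)
        p = np.array([0.3, 0.9, 0.6])
        q = np.array([-0.8, 0.2, 0.4])
        r = np.array([0.1, -0.7, 0.9])
        v = triple_product_V(o, p, q, r)
        m = np.array([-1.0, 1, 1])
        assert triple_product_V(o * m, p * m, q * m, r * m) == pytest.approx(-v)

    def test_degenerate_center_is_an_error(self):
        with pytest.raises(ValueError):
            triple_product_V(np.zeros(3), np.zeros(3),
                             np.array([1.0, 0, 0]), np.array([0, 1.0, 0]))

    @given(st.integers(0, 10**6))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_pseudoscalar_parity_property(self, seed):
        """Mirroring any non-degenerate configuration flips the sign of V
        and preserves its magnitude."""
        g = np.random.default_rng(seed)
        pts = g.normal(0, 1.5, (4, 3))
        if min(np.linalg.norm(pts[1:] - pts[0], axis=1)) < 1e-3:
            return
        v = triple_product_V(*pts)
        mirrored = pts * np.array([1.0, -1.0, 1.0])
        assert triple_product_V(*mirrored) == pytest.approx(-v, abs=1e-12)


class TestBiasVectors:
    def _center(self):
        return ChiralCenter(center=0, a=1, b=2, c=3, sign=+1)

    def test_zero_at_ideal_configuration(self):
        coords = np.vstack([np.zeros(3), TET[:3] * 1.5])
        # (A,B,C) ordered so V is already at +V_ideal
        v = triple_product_V(coords[0], coords[1], coords[2], coords[3])
        cc = ChiralCenter(0, 1, 2, 3, sign=int(np.sign(v)))
        assert np.allclose(chirality_bias_vectors(cc, coords), 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.normal(0, 1.2, (4, 3))
        cc = self._center()
        analytic = chirality_bias_vectors(cc, coords)

        def objective(flat):
            c = flat.reshape(4, 3)
            v = triple_product_V(c[0], c[1], c[2], c[3])
            return (v - cc.v_ideal) ** 2

        eps = 1e-5
        flat = coords.flatten()
        num = np.zeros_like(flat)
        for k in range(flat.size):
            up, dn = flat.copy(), flat.copy()
            up[k] += eps
            dn[k] -= eps
            num[k] = (objective(up) - objective(dn)) / (2 * eps)
        scale = max(np.abs(num).max(), 1e-12)
        assert np.abs(analytic.flatten() - num).max() / scale < 1e-6

    @pytest.mark.parametrize("seed", range(20))
    def test_descent_restores_requested_handedness(self, seed):
        rng = np.random.default_rng(1000 + seed)
        coords = np.vstack([np.zeros(3), (TET[:3] + rng.normal(0, 0.1, (3, 3))) * 1.5])
        v0 = triple_product_V(*coords)
        cc = ChiralCenter(0, 1, 2, 3, sign=-int(np.sign(v0)))  # wrong-handed now
        lr = 0.8
        for step in range(200):
            coords -= lr * chirality_bias_vectors(cc, coords)
            if np.sign(triple_product_V(*coords)) == cc.sign:
                break
        assert np.sign(triple_product_V(*coords)) == cc.sign


# ---------------------------------------------------------------------------
# bonded geometry + lDDT
# ---------------------------------------------------------------------------

class TestBondedGeometry:
    def test_identical_structures_report_zero(self, dipeptide):
        graph, ref = dipeptide
        rep = bonded_geometry_errors(ref, ref, graph)
        assert rep.bond_length_mae == 0 and rep.bond_angle_mae == 0
        assert rep.planar_angle_mae == 0 and rep.chiral_angle_mae == 0

    def test_stretched_diatomic_reports_bond_mae_only(self):
        from atomdenoise.chemgraph import build_chemgraph
        from atomdenoise.io_formats import MolRecord

        rec = MolRecord("di", [("C", 0), ("O", 0)], [(0, 1, 1)],
                        np.array([[0, 0, 0], [1.5, 0, 0.0]]))
        graph, ref = build_chemgraph(ligands=[rec])
        model = ref.coords.copy()
        model[1, 0] += 0.2
        rep = bonded_geometry_errors(model, ref, graph)
        assert rep.bond_length_mae == pytest.approx(0.2, abs=1e-9)
        assert rep.n_angles == 0 and rep.bond_angle_mae == 0.0

    def test_matches_explicit_trigonometry_oracle(self):
        for seed in range(5):
            g = np.random.default_rng(300 + seed)
            graph, ref = random_molecule(g, 8, 12)
            model = ref.coords + g.normal(0, 0.3, ref.coords.shape)
            rep = bonded_geometry_errors(model, ref.coords, graph)
            bond, ang = geometry_brute(model, ref.coords, graph)
            assert rep.bond_length_mae == pytest.approx(bond, abs=1e-6)
            assert rep.bond_angle_mae == pytest.approx(ang, abs=1e-6)

    def test_differentiable_loss_is_finite(self, dipeptide):
        from atomdenoise.geometry import bonded_geometry_loss

        graph, ref = dipeptide
        rng = np.random.default_rng(4)
        t = Tensor(ref.coords + rng.normal(0, 0.4, ref.coords.shape),
                   requires_grad=True)
        loss = bonded_geometry_loss(t, ref, graph)
        loss.backward()
        assert np.isfinite(loss.value) and np.isfinite(t.grad).all()


class TestLddt:
    def test_identity_scores_one(self, toy_pocket):
        vals, defined = lddt_per_atom(toy_pocket.reference,
                                      toy_pocket.reference, toy_pocket.graph)
        assert defined.any()
        assert np.allclose(vals[defined], 1.0)

    def test_scrambled_structure_scores_near_zero(self, toy_pocket):
        rng = np.random.default_rng(0)
        model = Conformation(rng.uniform(-500, 500,
                                         toy_pocket.reference.coords.shape),
                             toy_pocket.reference.mask)
        vals, defined = lddt_per_atom(model, toy_pocket.reference,
                                      toy_pocket.graph)
        assert vals[defined].mean() < 0.05

    def test_matches_brute_force(self):
        for seed in range(4):
            g = np.random.default_rng(500 + seed)
            graph, ref = random_molecule(g, 10, 14)
            model = ref.coords + g.normal(0, 1.0, ref.coords.shape)
            vals, defined = lddt_per_atom(model, ref.coords, graph)
            bvals, bdefined = lddt_brute(model, ref.coords, graph)
            assert (defined == bdefined).all()
            assert np.allclose(vals, bvals, atol=1e-12)
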