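"""Featurization, neighbor graph, equivariance and training mechanics."""

import numpy as np
import pytest

from atomdenoise.chemgraph import UNCONNECTED, Conformation, build_chemgraph
from atomdenoise.corruption import CorruptionConfig, corrupt_training
from atomdenoise.fixtures import (FixtureSpec, _random_rotation, make_molecule,
                                  make_training_set)
from atomdenoise.io_formats import MolRecord
from atomdenoise.network import (ModelConfig, build_neighbor_graph,
                                 count_parameters, featurize_1d, featurize_2d,
                                 forward, init_params, load_weights,
                                 save_weights)
from atomdenoise.training import TrainSchedule, train_micro
from conftest import random_molecule


@pytest.fixture(scope="module")
def micro():
    cfg = ModelConfig.micro(seed=0)
    return cfg, init_params(cfg)


def randomized_params(cfg, seed=1):
    """init_params with the zero-initialized coordinate heads filled in."""
    params = init_params(cfg)
    rng = np.random.default_rng(seed)
    for k in params:
        if "_ha" in k or "_eta" in k or k == "conf_skip":
            params[k].value = rng.normal(0, 0.3, params[k].value.shape)
    return params


class TestFeaturization:
    def test_permuting_atoms_permutes_features(self, rng):
        graph, ref = random_molecule(rng)
        n = graph.n_atoms
        perm = np.random.default_rng(1).permutation(n)
        inv = np.argsort(perm)
        rec = MolRecord("perm", [(graph.atoms[p].element, graph.atoms[p].charge)
                                 for p in perm],
                        [(int(inv[i]), int(inv[j]), o) for i, j, o in graph.bonds],
                        ref.coords[perm])
        pgraph, _ = build_chemgraph(ligands=[rec])
        assert np.allclose(featurize_1d(pgraph), featurize_1d(graph)[perm])
        assert np.allclose(featurize_2d(pgraph),
                           featurize_2d(graph)[np.ix_(perm, perm)])

    def test_disconnected_pair_gets_unconnected_token(self):
        recs = [MolRecord("a", [("C", 0), ("C", 0)], [(0, 1, 1)],
                          np.array([[0, 0, 0], [1.5, 0, 0.0]])),
                MolRecord("b", [("O", 0)], [], np.array([[8.0, 0, 0]]))]
        graph, _ = build_chemgraph(ligands=recs)
        f2 = featurize_2d(graph)
        unconn_dim = -2  # ... , unconnected token, same-component flag
        assert f2[0, 2, unconn_dim] == 1.0 and f2[0, 1, unconn_dim] == 0.0
        assert f2[0, 2, -1] == 0.0 and f2[0, 1, -1] == 1.0

    def test_dipeptide_features_match_hand_enumeration(self, dipeptide):
        graph, _ = dipeptide
        f1, f2 = featurize_1d(graph), featurize_2d(graph)
        from atomdenoise.network import ELEMENTS, _ROLES

        idx = {(a.resnum, a.name): i for i, a in enumerate(graph.atoms)}
        ca1 = idx[(1, "CA")]
        assert f1[ca1, ELEMENTS.index("C")] == 1.0
        assert f1[ca1, len(ELEMENTS) + 1 + _ROLES.index("backbone")] == 1.0
        cb1 = idx[(1, "CB")]
        assert f1[cb1, len(ELEMENTS) + 1 + _ROLES.index("sidechain")] == 1.0
        # bonded flag + order one-hot for N1-CA1; separation one-hot N1->N2 = 3
        n1, n2 = idx[(1, "N")], idx[(2, "N")]
        assert f2[n1, ca1, 0] == 1.0 and f2[n1, ca1, 1] == 1.0
        sep_base = 1 + 4
        assert f2[n1, n2, sep_base + 3] == 1.0
        assert f2[n1, n2, -1] == 1.0  # one covalent component

    def test_unsupported_element_is_an_error(self):
        rec = MolRecord("u", [("U", 0)], [], np.zeros((1, 3)))
        from atomdenoise.io_formats import KNOWN_ELEMENTS

        KNOWN_ELEMENTS.add("U")
        try:
            graph, _ = build_chemgraph(ligands=[rec])
            with pytest.raises(ValueError, match="unsupported element"):
                featurize_1d(graph)
        finally:
            KNOWN_ELEMENTS.discard("U")


class TestNeighborGraph:
    def test_lists_are_exactly_K_on_a_large_fixture(self):
        graph, ref = make_molecule(FixtureSpec("chain", size=120))
        nbr, mask = build_neighbor_graph(graph, ref.coords, 32)
        assert nbr.shape == (120, 32)
        assert mask.all()
        assert not (nbr == np.arange(120)[:, None]).any()

    def test_small_molecule_padded_with_sentinels(self, ring6):
        graph, ref = ring6
        nbr, mask = build_neighbor_graph(graph, ref.coords, 16)
        for i in range(6):
            assert sorted(nbr[i][mask[i]]) == sorted(set(range(6)) - {i})
            assert (nbr[i][~mask[i]] == 6).all()

    def test_chemical_half_matches_sorting_oracle(self, rng):
        graph, ref = random_molecule(rng, 20, 30)
        K = 8
        nbr, mask = build_neighbor_graph(graph, ref.coords, K)
        d = np.linalg.norm(ref.coords[:, None] - ref.coords[None], axis=-1)
        sep = graph.bond_separation
        for i in range(graph.n_atoms):
            order = sorted((dd, j) for j, dd in enumerate(d[i]) if j != i)
            spatial = [j for _, j in order[:K // 2]]
            chem_sorted = sorted((sep[i, j], j) for j in range(graph.n_atoms)
                                 if j != i and sep[i, j] < UNCONNECTED)
            expect_chem = []
            for s, j in chem_sorted:
                if j not in spatial:
                    expect_chem.append(j)
                if len(expect_chem) == K // 2:
                    break
            got = list(nbr[i][mask[i]])
            assert got[:K // 2] == spatial
            assert got[K // 2:K // 2 + len(expect_chem)] == expect_chem


class TestEquivariance:
    def test_forward_commutes_with_rigid_motion(self, rng):
        graph, ref = random_molecule(rng, 8, 14)
        cfg = ModelConfig.micro(seed=0)
        params = randomized_params(cfg)
        corrupted = corrupt_training(graph, ref, CorruptionConfig(seed=6))
        out1, conf1, _ = forward(graph, corrupted, params, cfg)
        R = _random_rotation(np.random.default_rng(3))
        t = np.array([5.0, -3.0, 2.0])
        moved = Conformation(corrupted.coords @ R.T + t, corrupted.mask)
        out2, conf2, _ = forward(graph, moved, params, cfg)
        assert np.abs(out2.coords - (out1.coords @ R.T + t)).max() < 1e-3
        assert np.abs(np.asarray(conf2[-1].sigma.value)
                      - np.asarray(conf1[-1].sigma.value)).max() < 1e-5
        assert np.abs(np.asarray(conf2[-1].plddt.value)
                      - np.asarray(conf1[-1].plddt.value)).max() < 1e-5

    def test_zero_blocks_is_identity(self, ring6, micro):
        cfg, params = micro
        graph, ref = ring6
        corrupted = corrupt_training(graph, ref, CorruptionConfig(seed=1))
        out, confs, _ = forward(graph, corrupted, params, cfg, n_blocks=0)
        assert (out.coords == corrupted.coords).all()
        assert confs == []

    def test_untrained_block_leaves_coordinates_unchanged(self, ring6, micro):
        # coordinate-update heads are zero-initialized
        cfg, params = micro
        graph, ref = ring6
        corrupted = corrupt_training(graph, ref, CorruptionConfig(seed=1))
        out, _, _ = forward(graph, corrupted, params, cfg)
        assert np.allclose(out.coords, corrupted.coords)

    def test_network_is_deterministic(self, ring6, micro):
        cfg, params = micro
        graph, ref = ring6
        corrupted = corrupt_training(graph, ref, CorruptionConfig(seed=1))
        a, _, _ = forward(graph, corrupted, params, cfg)
        b, _, _ = forward(graph, corrupted, params, cfg)
        assert (a.coords == b.coords).all()


class TestConfigAndWeights:
    def test_reference_preset_constants(self):
        ref = ModelConfig.reference_scale()
        assert ref.n_blocks == 8 and ref.K == 32

    def test_parameter_count_independent_of_blocks(self):
        a = count_parameters(init_params(ModelConfig(n_blocks=2)))
        b = count_parameters(init_params(ModelConfig(n_blocks=8)))
        assert a == b  # shared weights: depth adds compute, not parameters

    def test_weight_round_trip(self, tmp_path, micro):
        cfg, params = micro
        save_weights(tmp_path / "w.json", params, cfg)
        loaded, lcfg = load_weights(tmp_path / "w.json")
        assert lcfg == cfg
        for k in params:
            assert np.allclose(loaded[k].value, params[k].value)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(K=7)
        with pytest.raises(ValueError):
            ModelConfig(rounds=0)


class TestTrainMicro:
    def test_short_run_is_reproducible_and_staged(self):
        ds = make_training_set(2, seed=0)
        cfg = ModelConfig(seed=0, d1=24, d2=12, d_hidden=24, dv=4, rounds=2)
        sched = TrainSchedule(stage1_steps=4, stage2_steps=4)
        p1, t1 = train_micro(ds, cfg, sched)
        p2, t2 = train_micro(ds, cfg, sched)
        assert [t["loss"] for t in t1] == [t["loss"] for t in t2]
        assert all(t["n_blocks"] == sched.stage1_blocks
                   for t in t1 if t["stage"] == 1)
        assert all(t["n_blocks"] == cfg.n_blocks
                   for t in t1 if t["stage"] == 2)
        assert all(np.isfinite(t["loss"]) for t in t1)
        for k in p1:
            assert np.allclose(p1[k].value, p2[k].value)

    def test_bond_separation_feature_matters_for_convergence(self):
        """Replacing the bond-separation feature with only the binary bonded
        flag degrades converged denoising quality (direction only)."""
        ds = [make_molecule(FixtureSpec("macrocycle", size=10)),
              make_molecule(FixtureSpec("chain", size=10))]
        sched = TrainSchedule(stage1_steps=400, stage2_steps=0)
        from atomdenoise.training import evaluate_denoising

        fapes = {}
        for ablate in (False, True):
            cfg = ModelConfig(seed=0, ablate_bond_separation=ablate)
            params, _ = train_micro(ds, cfg, sched)
            res = evaluate_denoising(ds, params, cfg, sched.corruption,
                                     n_runs=8, seed=777)
            fapes[ablate] = np.mean([r["fape"] for r in res])
        assert fapes[True] > fapes[False]

    def test_systems_beyond_the_crop_cap_are_rejected(self, micro):
        cfg, params = micro
        graph, ref = make_molecule(FixtureSpec("chain", size=30))
        small_cap = ModelConfig(max_atoms=20)
        from atomdenoise.network import embed_inputs, init_params as ip

        with pytest.raises(ValueError, match="crop"):
            embed_inputs(graph, ref, ip(small_cap), small_cap)

    def test_loss_decreases_on_a_tiny_problem(self):
        ds = make_training_set(1, seed=0)
        cfg = ModelConfig(seed=0, d1=32, d2=16, d_hidden=48, dv=4, rounds=3)
        sched = TrainSchedule(stage1_steps=60, stage2_steps=0)
        _, trace = train_micro(ds, cfg, sched)
        first = np.mean([t["fape"] for t in trace[:10]])
        last = np.mean([t["fape"] for t in trace[-10:]])
        assert last < first * 0.8
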