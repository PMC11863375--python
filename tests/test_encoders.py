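import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from confdiff.autograd import Tensor
from confdiff.encoders import (
    AdaptiveScale, CFConv, EdgeEncoder, EncoderConfig, GlobalEncoder,
    InteractionBlock, LocalEncoder, distance_weight,
)
from confdiff.molgraph import (EdgeSet, build_local_edges,
                               build_spatial_edges, edge_lengths, merge_edges)
from confdiff.toydata import ToySpec, make_toy


@pytest.fixture
def cfg():
    return EncoderConfig(hidden=16, n_filters=16, n_filters_reduced=8,
                         n_blocks=2, gin_depth=2)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def all_edges_with_lengths(mol):
    local = build_local_edges(mol)
    spatial = build_spatial_edges(mol.coords, 10.0, exclude=local)
    return edge_lengths(mol.coords, merge_edges(local, spatial))


class TestDistanceWeight:
    def test_unit_at_zero(self):
        assert distance_weight(0.0, 10.0) == pytest.approx(1.0)

    def test_envelope_at_cutoff(self):
        # sigma = d_cutoff -> exp(-1/2) at d = cutoff
        assert distance_weight(10.0, 10.0) == pytest.approx(np.exp(-0.5),
                                                            abs=1e-12)

    def test_hard_zero_beyond_cutoff(self):
        assert distance_weight(12.0, 10.0) == 0.0
        assert distance_weight(12.0, 10.0, learned=np.array(5.0)) == 0.0

    def test_learned_factor_multiplies(self):
        d = np.array([1.0, 5.0])
        got = distance_weight(d, 10.0, learned=np.array([2.0, 0.5]))
        base = distance_weight(d, 10.0)
        np.testing.assert_allclose(got, base * [2.0, 0.5])


class TestEdgeEncoder:
    def test_identical_inputs_identical_embeddings(self, cfg, rng):
        enc = EdgeEncoder(cfg, rng)
        out = enc(np.array([1.5, 1.5, 2.0]), np.array([0, 0, 3])).data
        np.testing.assert_array_equal(out[0], out[1])
        assert not np.allclose(out[0], out[2])

    def test_permuting_edges_permutes_rows(self, cfg, rng):
        enc = EdgeEncoder(cfg, rng)
        lengths = np.array([1.0, 2.0, 3.0])
        types = np.array([0, 4, 6])
        perm = np.array([2, 0, 1])
        a = enc(lengths, types).data
        b = enc(lengths[perm], types[perm]).data
        np.testing.assert_allclose(b, a[perm])

    def test_zero_length_edge_is_finite(self, cfg, rng):
        enc = EdgeEncoder(cfg, rng)
        out = enc(np.array([0.0]), np.array([0])).data
        assert np.all(np.isfinite(out))

    def test_unknown_type_rejected(self, cfg, rng):
        enc = EdgeEncoder(cfg, rng)
        with pytest.raises(ValueError):
            enc(np.array([1.0]), np.array([7]))

    def test_output_width_is_hidden(self, cfg, rng):
        enc = EdgeEncoder(cfg, rng)
        assert enc(np.array([1.0]), np.array([0])).shape == (1, cfg.hidden)


class TestCFConv:
    def test_no_edges_gives_atomwise_constant(self, cfg, rng):
        conv = CFConv(cfg, cfg.n_filters, rng)
        conv.eval()
        h = Tensor(rng.standard_normal((4, cfg.hidden)))
        out = conv(h, EdgeSet.empty(), Tensor(np.zeros((0, cfg.hidden))),
                   np.zeros(0)).data
        # zero aggregation: every atom sees the same bias-driven output
        assert np.allclose(out, out[0])
        assert np.all(np.isfinite(out))

    def test_duplicated_edge_doubles_its_message(self, cfg, rng, monkeypatch):
        """Sum aggregation on a 2-atom graph: doubling an edge doubles the
        aggregated message before normalization (probed with the
        normalization bypassed, since it rescales per-feature afterwards)."""
        conv = CFConv(cfg, cfg.n_filters, rng)
        conv.eval()
        monkeypatch.setattr(conv, "bn", lambda x: x)
        h = Tensor(rng.standard_normal((2, cfg.hidden)))
        ee = Tensor(rng.standard_normal((1, cfg.hidden)))
        single = EdgeSet(np.array([[0, 1]]), np.array([0]), np.array([True]))
        double = EdgeSet(np.array([[0, 1], [0, 1]]), np.array([0, 0]),
                         np.array([True, True]))
        ee2 = Tensor(np.vstack([ee.data, ee.data]))
        base = conv(h, EdgeSet.empty(), Tensor(np.zeros((0, cfg.hidden))),
                    np.zeros(0)).data
        one = conv(h, single, ee, np.array([1.2])).data
        two = conv(h, double, ee2, np.array([1.2, 1.2])).data
        np.testing.assert_allclose(two - base, 2 * (one - base), atol=1e-9)

    def test_permutation_equivariance(self, cfg, rng, tet5):
        conv = CFConv(cfg, cfg.n_filters, rng)
        conv.eval()
        edges = all_edges_with_lengths(tet5)
        h = Tensor(rng.standard_normal((5, cfg.hidden)))
        ee = Tensor(rng.standard_normal((len(edges), cfg.hidden)))
        out = conv(h, edges, ee, edges.lengths).data
        perm = np.array([2, 0, 4, 1, 3])
        inv = np.argsort(perm)
        p_edges = EdgeSet(inv[edges.pairs], edges.types, edges.is_local,
                          edges.lengths)
        p_out = conv(Tensor(h.data[perm]), p_edges, ee, edges.lengths).data
        np.testing.assert_allclose(p_out, out[perm], atol=1e-9)


class TestInteractionBlock:
    def test_attention_gate_strictly_in_unit_interval(self, cfg, rng, tet5):
        block = InteractionBlock(cfg, rng)
        block.eval()
        x = Tensor(rng.standard_normal((5, cfg.n_filters
                                        + cfg.n_filters_reduced)))
        gate = block.attention(x).data
        assert np.all(gate > 0) and np.all(gate < 1)

    def test_rotation_invariance_through_lengths(self, cfg, rng, tet5):
        block = InteractionBlock(cfg, rng)
        block.eval()
        edges = all_edges_with_lengths(tet5)
        enc = EdgeEncoder(cfg, rng)
        h = Tensor(rng.standard_normal((5, cfg.hidden)))
        out = block(h, edges, enc(edges.lengths, edges.types),
                    edges.lengths).data
        R = Rotation.random(random_state=1).as_matrix()
        moved = tet5.coords @ R.T + np.array([1.0, 2.0, 3.0])
        m_edges = edge_lengths(moved, edges)
        m_out = block(h, m_edges, enc(m_edges.lengths, m_edges.types),
                      m_edges.lengths).data
        np.testing.assert_allclose(m_out, out, atol=1e-5)


class TestAdaptiveScale:
    def test_unit_network_output_is_identity(self, cfg, rng, monkeypatch):
        scale = AdaptiveScale(cfg.hidden, rng)
        monkeypatch.setattr(scale, "net",
                            lambda x: Tensor(np.full((1, cfg.hidden), 1e9)))
        h = Tensor(rng.standard_normal((3, cfg.hidden)))
        # sigmoid(1e9) = 1 -> scale = 2; halve to probe pure scaling
        out = scale(h).data
        np.testing.assert_allclose(out, 2.0 * h.data)

    def test_single_atom_pools_to_itself(self, cfg, rng):
        scale = AdaptiveScale(cfg.hidden, rng)
        h = Tensor(rng.standard_normal((1, cfg.hidden)))
        context = h.mean(axis=0, keepdims=True)
        np.testing.assert_array_equal(context.data, h.data)

    def test_scaling_is_channelwise_multiplication(self, cfg, rng):
        scale = AdaptiveScale(cfg.hidden, rng)
        h = Tensor(np.ones((4, cfg.hidden)))
        out = scale(h).data
        doubled = scale(h * 2.0).data / 2.0
        # same pooled context direction -> columns scale channel-wise
        assert out.shape == (4, cfg.hidden)
        assert np.allclose(out, out[0])
        assert doubled.shape == out.shape


class TestGlobalEncoder:
    def test_rigid_motion_invariance(self, cfg, rng, tet5):
        enc = GlobalEncoder(cfg, rng)
        enc.eval()
        eenc = EdgeEncoder(cfg, rng)
        edges = all_edges_with_lengths(tet5)
        base = enc(tet5.atom_numbers, edges,
                   eenc(edges.lengths, edges.types), edges.lengths).data
        for k in range(3):
            R = Rotation.random(random_state=k).as_matrix()
            moved = tet5.coords @ R.T + rng.normal(size=3)
            m_edges = edge_lengths(moved, edges)
            got = enc(tet5.atom_numbers, m_edges,
                      eenc(m_edges.lengths, m_edges.types),
                      m_edges.lengths).data
            np.testing.assert_allclose(got, base, atol=1e-5)

    def test_output_width(self, cfg, rng, tet5):
        enc = GlobalEncoder(cfg, rng)
        enc.eval()
        eenc = EdgeEncoder(cfg, rng)
        edges = all_edges_with_lengths(tet5)
        out = enc(tet5.atom_numbers, edges, eenc(edges.lengths, edges.types),
                  edges.lengths)
        assert out.shape == (tet5.n_atoms, cfg.hidden)

    def test_disconnected_copies_embed_identically(self, cfg, rng):
        """Two copies of a molecule >cutoff apart form a block-diagonal
        graph; per-copy embeddings must match the single-molecule result's
        structure (copy 1 == copy 2)."""
        from confdiff.molgraph import MoleculeGraph

        mol = make_toy(ToySpec())
        n = mol.n_atoms
        coords = np.vstack([mol.coords, mol.coords + np.array([50.0, 0, 0])])
        bonds = mol.bonds + [(i + n, j + n, o) for i, j, o in mol.bonds]
        double = MoleculeGraph(np.tile(mol.atom_numbers, 2), bonds, coords)
        edges = all_edges_with_lengths(double)
        # sanity: no cross-copy edges at 50 A separation
        assert not np.any((edges.pairs[:, 0] < n) & (edges.pairs[:, 1] >= n))
        enc = GlobalEncoder(cfg, rng)
        enc.eval()
        eenc = EdgeEncoder(cfg, rng)
        out = enc(double.atom_numbers, edges,
                  eenc(edges.lengths, edges.types), edges.lengths).data
        np.testing.assert_allclose(out[n:], out[:n], atol=1e-9)


class TestInvarianceSweep:
    def test_both_encoders_invariant_on_50_random_toys(self, cfg):
        """Rigid-motion invariance of global and local node features across
        50 randomized toy geometries (<=1e-5 relative)."""
        from confdiff.toydata import ToySpec

        rng = np.random.default_rng(77)
        init_rng = np.random.default_rng(5)
        genc = GlobalEncoder(cfg, init_rng)
        lenc = LocalEncoder(cfg, init_rng)
        eenc = EdgeEncoder(cfg, init_rng)
        for m in (genc, lenc, eenc):
            m.eval()
        for _ in range(50):
            template = rng.choice(["tetrahedral_center", "linear_chain",
                                   "ring", "torsion_chain"])
            if template == "tetrahedral_center":
                spec = ToySpec()
            elif template == "ring":
                spec = ToySpec(template="ring",
                               n_atoms=int(rng.integers(3, 8)),
                               aromatic=bool(rng.integers(2)))
            else:
                n = int(rng.integers(2, 8))
                spec = ToySpec(template=template, n_atoms=n,
                               torsions=list(rng.uniform(-180, 180,
                                                         max(n - 3, 0))))
            mol = make_toy(spec)
            edges = all_edges_with_lengths(mol)
            local = build_local_edges(mol)
            local = edge_lengths(mol.coords, local)
            hg = genc(mol.atom_numbers, edges,
                      eenc(edges.lengths, edges.types), edges.lengths).data
            hl = lenc(mol.atom_numbers, local,
                      eenc(local.lengths, local.types)).data
            R = Rotation.random(
                random_state=int(rng.integers(2 ** 31))).as_matrix()
            moved = mol.coords @ R.T + rng.normal(0, 5, size=3)
            m_edges = edge_lengths(moved, edges)
            m_local = edge_lengths(moved, local)
            hg2 = genc(mol.atom_numbers, m_edges,
                       eenc(m_edges.lengths, m_edges.types),
                       m_edges.lengths).data
            hl2 = lenc(mol.atom_numbers, m_local,
                       eenc(m_local.lengths, m_local.types)).data
            scale_g = max(1.0, float(np.abs(hg).max()))
            scale_l = max(1.0, float(np.abs(hl).max()))
            assert np.abs(hg2 - hg).max() / scale_g < 1e-5
            assert np.abs(hl2 - hl).max() / scale_l < 1e-5


class TestLocalEncoder:
    def test_deterministic_in_eval_mode(self, cfg, rng, path4):
        enc = LocalEncoder(cfg, rng)
        enc.eval()
        eenc = EdgeEncoder(cfg, rng)
        edges = edge_lengths(path4.coords, build_local_edges(path4))
        a = enc(path4.atom_numbers, edges,
                eenc(edges.lengths, edges.types)).data
        b = enc(path4.atom_numbers, edges,
                eenc(edges.lengths, edges.types)).data
        np.testing.assert_array_equal(a, b)

    def test_hop_edges_change_output(self, cfg, rng, path4):
        """Dropping the 2-/3-hop edges from a 4-atom path must change the
        encoding: they carry real signal, not padding."""
        enc = LocalEncoder(cfg, rng)
        enc.eval()
        eenc = EdgeEncoder(cfg, rng)
        full = edge_lengths(path4.coords, build_local_edges(path4))
        keep = full.types < 4  # covalent codes only
        bonds_only = EdgeSet(full.pairs[keep], full.types[keep],
                             full.is_local[keep], full.lengths[keep])
        a = enc(path4.atom_numbers, full,
                eenc(full.lengths, full.types)).data
        b = enc(path4.atom_numbers, bonds_only,
                eenc(bonds_only.lengths, bonds_only.types)).data
        assert not np.allclose(a, b)

    def test_permutation_equivariance(self, cfg, rng, path4):
        enc = LocalEncoder(cfg, rng)
        enc.eval()
        eenc = EdgeEncoder(cfg, rng)
        edges = edge_lengths(path4.coords, build_local_edges(path4))
        out = enc(path4.atom_numbers, edges,
                  eenc(edges.lengths, edges.types)).data
        perm = np.array([3, 1, 0, 2])
        inv = np.argsort(perm)
        p_edges = EdgeSet(inv[edges.pairs], edges.types, edges.is_local,
                          edges.lengths)
        p_out = enc(path4.atom_numbers[perm], p_edges,
                    eenc(p_edges.lengths, p_edges.types)).data
        np.testing.assert_allclose(p_out, out[perm], atol=1e-9)


class TestParameterRoundTrip:
    def test_state_dict_restores_outputs_bit_exactly(self, cfg, tet5):
        from confdiff.score_model import ScoreModel, ScoreModelConfig
        from confdiff.diffusion import DiffusionConfig, make_schedule

        sched = make_schedule(DiffusionConfig(T=10, beta_max=0.1))
        a = ScoreModel(ScoreModelConfig(encoder=cfg, seed=5))
        b = ScoreModel(ScoreModelConfig(encoder=cfg, seed=6))
        a.eval(), b.eval()
        state = a.state_dict()
        b.load_state_dict(state)
        xt = tet5.coords
        np.testing.assert_array_equal(a.predict_eps(tet5, xt, 5, sched),
                                      b.predict_eps(tet5, xt, 5, sched))

    def test_checkpoint_file_round_trip(self, cfg, tet5, tmp_path):
        from confdiff.score_model import (ScoreModel, ScoreModelConfig,
                                          load_checkpoint, save_checkpoint)
        from confdiff.diffusion import DiffusionConfig, make_schedule

        sched = make_schedule(DiffusionConfig(T=10, beta_max=0.1))
        model = ScoreModel(ScoreModelConfig(encoder=cfg, seed=5))
        model.eval()
        path = str(tmp_path / "model.npz")
        save_checkpoint(path, model, extra={"note": "test"})
        back, extra = load_checkpoint(path)
        assert extra["note"] == "test"
        np.testing.assert_array_equal(
            model.predict_eps(tet5, tet5.coords, 5, sched),
            back.predict_eps(tet5, tet5.coords, 5, sched))
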