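"""Architecture contracts: embeddings, encoder invariances, decoder heads."""

import numpy as np
import pytest

from peakgene.autograd import Tensor
from peakgene.model import ModelConfig, PeakSetModel
from peakgene.nn import Adam
from peakgene.vocab import PeakVocabulary, collate, tokenize_cell


def make_model(**kw):
    cfg = dict(n_peaks=30, n_chroms=2, n_genes=12, n_batches=3,
               d_model=16, n_layers=2, n_heads=4, ff_mult=2, seed=0)
    cfg.update(kw)
    return PeakSetModel(ModelConfig(**cfg))


@pytest.fixture
def vocab30():
    return PeakVocabulary([f"p{i}" for i in range(30)],
                          ["chr1" if i < 15 else "chr2" for i in range(30)])


def encode_row(model, vocab, row, rng=0):
    seq = tokenize_cell(np.asarray(row), vocab, max_peaks=100, rng=rng)
    tokens, chroms, mask = collate([seq], vocab.pad_id, vocab.null_chrom_id)
    return model.encode_cell(tokens, chroms, mask)


class TestInputEmbedding:
    def test_zeroed_chromosome_table_leaves_peak_embedding(self):
        m = make_model()
        m.e_chr.weight.data[:] = 0.0
        tokens = np.array([[m.config.n_peaks, 1, 5]])   # CLS + two peaks
        chroms = np.array([[2, 0, 1]])
        z = m.embed_inputs(tokens, chroms)
        assert np.allclose(z.data, m.e_peak.weight.data[tokens[0]])

    def test_ablation_flag_removes_chromosome_term(self):
        m_on = make_model()
        m_off = make_model(use_chromosome_embedding=False)
        m_off.load_state_arrays(m_on.state_arrays())
        tokens = np.array([[30, 3, 7]])
        chroms = np.array([[2, 0, 0]])
        z_off = m_off.embed_inputs(tokens, chroms)
        assert np.allclose(z_off.data, m_off.e_peak.weight.data[tokens[0]])
        z_on = m_on.embed_inputs(tokens, chroms)
        assert not np.allclose(z_on.data, z_off.data)

    def test_same_chromosome_term_cancels_between_tokens(self):
        m = make_model()
        z = m.embed_inputs(np.array([[3, 7]]), np.array([[0, 0]]))
        diff = z.data[0, 0] - z.data[0, 1]
        expected = m.e_peak.weight.data[3] - m.e_peak.weight.data[7]
        assert np.allclose(diff, expected)

    def test_out_of_vocabulary_token_rejected(self):
        m = make_model()
        with pytest.raises(IndexError):
            m.embed_inputs(np.array([[99]]), np.array([[0]]))


class TestEncodeCell:
    def test_permutation_of_peak_tokens_leaves_z_c_invariant(self, vocab30):
        m = make_model()
        rng = np.random.default_rng(0)
        row = np.zeros(30)
        row[rng.choice(30, 12, replace=False)] = 1
        seq = tokenize_cell(row, vocab30, 100)
        perm = np.concatenate([[0], 1 + rng.permutation(len(seq) - 1)])
        from peakgene.vocab import CellTokenSequence
        shuffled = CellTokenSequence(seq.token_ids[perm], seq.chrom_ids[perm])
        z1 = m.encode_sequences([seq], vocab30).data
        z2 = m.encode_sequences([shuffled], vocab30).data
        assert np.allclose(z1, z2, rtol=1e-5, atol=1e-8)

    def test_zero_layer_model_returns_cls_input_embedding(self, vocab30):
        m = make_model(n_layers=0)
        z = encode_row(m, vocab30, np.ones(30)).data[0]
        cls_embed = (m.e_peak.weight.data[vocab30.cls_id]
                     + m.e_chr.weight.data[vocab30.null_chrom_id])
        assert np.allclose(z, cls_embed)

    def test_disjoint_peak_sets_give_distinct_embeddings(self, vocab30):
        m = make_model()
        a = np.zeros(30); a[:10] = 1
        b = np.zeros(30); b[20:] = 1
        za = encode_row(m, vocab30, a).data
        zb = encode_row(m, vocab30, b).data
        assert not np.allclose(za, zb, atol=1e-6)

    def test_deterministic_in_eval_mode(self, vocab30):
        m = make_model()
        z1 = encode_row(m, vocab30, np.ones(30)).data
        z2 = encode_row(m, vocab30, np.ones(30)).data
        assert np.array_equal(z1, z2)


class TestFuseBatch:
    def test_concatenation_layout(self):
        m = make_model(d_model=16)
        z = Tensor(np.random.default_rng(1).normal(size=(2, 16)))
        zt = m.fuse_batch(z, np.array([0, 2]))
        assert zt.shape == (2, 32)
        assert np.array_equal(zt.data[:, :16], z.data)
        assert np.array_equal(zt.data[0, 16:], m.e_batch.weight.data[0])

    def test_same_batch_shares_second_half(self):
        m = make_model()
        z = Tensor(np.random.default_rng(2).normal(size=(2, 16)))
        zt = m.fuse_batch(z, np.array([1, 1]))
        assert np.array_equal(zt.data[0, 16:], zt.data[1, 16:])

    def test_ablation_flag_zeroes_batch_half(self):
        m = make_model(use_batch_embedding=False)
        z = Tensor(np.ones((2, 16)))
        zt = m.fuse_batch(z, np.array([0, 1]))
        assert np.all(zt.data[:, 16:] == 0)

    def test_unknown_batch_id_rejected(self):
        m = make_model()
        with pytest.raises(IndexError):
            m.fuse_batch(Tensor(np.ones((1, 16))), np.array([7]))


class TestDecoders:
    def test_binary_probabilities_in_open_unit_interval(self):
        m = make_model()
        zt = Tensor(np.random.default_rng(3).normal(size=(2, 32)))
        probs = m.predict_binary_expression(zt, np.arange(12))
        assert probs.shape == (2, 12)
        assert np.all((probs > 0) & (probs < 1))

    def test_duplicate_and_permuted_gene_ids(self):
        m = make_model()
        zt = Tensor(np.random.default_rng(4).normal(size=(1, 32)))
        p = m.predict_binary_expression(zt, np.array([3, 3, 5]))
        assert np.isclose(p[0, 0], p[0, 1])
        perm = m.predict_binary_expression(zt, np.array([5, 3, 3]))
        assert np.allclose(np.sort(p[0]), np.sort(perm[0]))

    def test_empty_gene_list_gives_empty_output(self):
        m = make_model()
        zt = Tensor(np.ones((2, 32)))
        assert m.predict_binary_expression(zt, np.array([], dtype=int)).shape == (2, 0)

    def test_cell_type_scores_softmax_normalized(self):
        m = make_model(n_cell_types=4)
        z = Tensor(np.random.default_rng(5).normal(size=(3, 16)))
        scores = m.predict_cell_type(z)
        assert scores.shape == (3, 4)
        assert np.allclose(scores.sum(axis=1), 1.0, atol=1e-6)
        assert np.array_equal(scores, m.predict_cell_type(z))

    def test_cell_type_head_must_be_initialized(self):
        m = make_model()
        with pytest.raises(RuntimeError, match="not initialized"):
            m.predict_cell_type(Tensor(np.ones((1, 16))))

    def test_binned_predictions_clamped_to_bin_range(self):
        m = make_model(n_bins=10)
        z = Tensor(np.random.default_rng(6).normal(size=(2, 16)) * 50)
        out = m.predict_binned_expression(z, np.arange(12))
        assert out.shape == (2, 12)
        assert out.min() >= 0 and out.max() <= 9


class TestPersistenceAndGradients:
    def test_save_load_round_trip(self, tmp_path):
        m = make_model(n_cell_types=3)
        m.save(tmp_path / "m.npz")
        re = PeakSetModel.load(tmp_path / "m.npz")
        for a, b in zip(m.state_arrays(), re.state_arrays()):
            assert np.array_equal(a, b)
        assert re.config.n_cell_types == 3

    def test_one_step_updates_only_present_peak_rows(self, vocab30):
        """Sparse-update sanity: absent peaks receive no gradient."""
        m = make_model()
        row = np.zeros(30)
        present = [2, 5, 11]
        row[present] = 1
        seq = tokenize_cell(row, vocab30, 100)
        tokens, chroms, mask = collate([seq], vocab30.pad_id, vocab30.null_chrom_id)
        before = m.e_peak.weight.data.copy()
        opt = Adam(m.parameters(), lr=1e-2)
        z = m.encode_cell(tokens, chroms, mask)
        zt = m.fuse_batch(z, np.array([0]))
        logits = m.predict_binary_expression_logits(zt, np.array([[0, 1]]))
        loss = logits.bce_with_logits(np.array([[1.0, 0.0]]))
        loss.backward()
        opt.step()
        after = m.e_peak.weight.data
        changed = ~np.all(np.isclose(before, after, atol=1e-15), axis=1)
        for j in present + [vocab30.cls_id]:
            assert changed[j]
        absent = sorted(set(range(30)) - set(present))
        assert not changed[absent].any()
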