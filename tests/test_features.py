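import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

import epitopescan as es
from epitopescan import features as feat
from epitopescan.errors import AlphabetError

from util import oracle_ngram, random_peptide

peptides = st.text(alphabet=feat.ALPHABET, min_size=1, max_size=25)


class TestDimensions:
    @pytest.mark.parametrize(
        "n,expected", [(1, 20), (2, 230), (3, 1770), (4, 10625), (5, 53129)]
    )
    def test_cumulative_ngram_ladder(self, n, expected):
        assert es.ngram_dimension(n) == expected
        assert len(feat.multiset_vocabulary(n)) == expected - es.ngram_dimension(n - 1)

    def test_total_dimension_with_all_blocks(self):
        assert es.FeatureConfig().dimension == 53633

    @pytest.mark.parametrize(
        "block,dim", [("pssm", 400), ("ss", 63), ("acc", 20), ("disorder", 20), ("seg", 1)]
    )
    def test_annotation_block_dimensions(self, block, dim):
        assert feat.block_dimension(block) == dim

    def test_empty_block_set_gives_dimension_zero(self):
        config = es.FeatureConfig(blocks=())
        assert config.dimension == 0


class TestNgramBlock:
    def test_homopolymer_order1(self):
        entries = es.ngram_block("AAA", 1)
        assert entries == {0: 1.0}

    def test_two_orders_on_aca(self):
        entries = es.ngram_block("ACA", 2)
        vocab1 = feat.multiset_vocabulary(1)
        vocab2 = feat.multiset_vocabulary(2)
        by_key = {}
        for idx, v in entries.items():
            if idx < 20:
                by_key[(1, vocab1[idx])] = v
            else:
                by_key[(2, vocab2[idx - 20])] = v
        assert by_key == {
            (1, "A"): pytest.approx(2 / 3),
            (1, "C"): pytest.approx(1 / 3),
            (2, "AC"): pytest.approx(1.0),  # windows AC and CA both canonicalize
        }

    def test_non_standard_residue_raises(self):
        with pytest.raises(AlphabetError):
            es.ngram_block("ACX", 2)

    def test_matches_brute_force_oracle_exactly(self, rng):
        offsets = [0] + [es.ngram_dimension(k) for k in range(1, 6)]
        for _ in range(200):
            peptide = random_peptide(rng, int(rng.integers(7, 31)))
            entries = es.ngram_block(peptide, 5)
            translated = {}
            for idx, v in entries.items():
                k = next(i for i in range(1, 6) if idx < offsets[i])
                translated[(k, feat.multiset_vocabulary(k)[idx - offsets[k - 1]])] = v
            assert translated == oracle_ngram(peptide, 5)

    @given(peptide=peptides)
    @settings(max_examples=100, deadline=None)
    def test_reversal_invariance(self, peptide):
        assert es.ngram_block(peptide, 3) == es.ngram_block(peptide[::-1], 3)

    @given(peptide=peptides)
    @settings(max_examples=100, deadline=None)
    def test_each_realized_order_sums_to_one(self, peptide):
        entries = es.ngram_block(peptide, 3)
        offsets = [0, 20, 230, 1770]
        for k in range(1, 4):
            total = sum(
                v for i, v in entries.items() if offsets[k - 1] <= i < offsets[k]
            )
            if len(peptide) >= k:
                assert total == pytest.approx(1.0)
            else:
                assert total == 0


class TestAnnotationBlocks:
    def test_single_identity_peptide_occupies_one_pssm_row(self, rng):
        ann = es.synthesize_annotations("AAAAA", 0.0, seed=1)
        entries = feat.pssm_block("AAAAA", ann, 0)
        rows = {i // 20 for i in entries}
        assert rows == {0}  # A is alphabet index 0

    def test_uniform_percentages_give_uniform_cells(self, rng):
        seq = "ACDEF"
        ann = es.synthesize_annotations(seq, 0.0, seed=1)
        ann.pssm_pct[:] = 5.0
        entries = feat.pssm_block(seq, ann, 0)
        assert len(entries) == 5 * 20
        assert all(v == pytest.approx(0.05) for v in entries.values())

    def test_all_coil_composition_triple(self, rng):
        seq = random_peptide(rng, 12)
        ann = es.synthesize_annotations(seq, 0.0, seed=2)
        ann.ss_state[:] = "C"
        entries = feat.ss_block(seq, ann, 0)
        assert entries.get(60, 0.0) == 0.0  # H fraction
        assert entries.get(61, 0.0) == 0.0  # E fraction
        assert entries[62] == 1.0  # C fraction

    def test_composition_triple_sums_to_one(self, rng):
        for seed in range(100):
            seq = random_peptide(rng, int(rng.integers(7, 20)))
            ann = es.synthesize_annotations(seq, float(rng.random()), seed=seed)
            entries = feat.ss_block(seq, ann, 0)
            total = sum(entries.get(60 + j, 0.0) for j in range(3))
            assert total == pytest.approx(1.0)

    def test_constant_accessibility_fills_occupied_entries(self, rng):
        seq = random_peptide(rng, 10)
        ann = es.synthesize_annotations(seq, 0.0, seed=3)
        ann.accessibility[:] = 0.5
        entries = feat.acc_block(seq, ann, 0)
        assert set(entries) == {feat.AA_INDEX[a] for a in set(seq)}
        assert all(v == pytest.approx(0.5) for v in entries.values())

    def test_seg_fraction(self, rng):
        seq = random_peptide(rng, 15)
        ann = es.synthesize_annotations(seq, 0.0, seed=4)
        ann.low_complexity[:] = False
        assert feat.seg_block(seq, ann, 0) == {}
        ann.low_complexity[:3] = True
        assert feat.seg_block(seq, ann, 0) == {0: pytest.approx(0.2)}
        ann.low_complexity[:] = True
        assert feat.seg_block(seq, ann, 0) == {0: 1.0}

    def test_identity_blocks_invariant_to_position_permutation(self, rng):
        seq = random_peptide(rng, 20)
        ann = es.synthesize_annotations(seq, 0.5, seed=5)
        perm = rng.permutation(20)
        permuted_seq = "".join(seq[i] for i in perm)
        permuted_ann = es.ResidueAnnotations(
            protein_id=ann.protein_id,
            length=20,
            pssm_pct=ann.pssm_pct[perm],
            ss_probs=ann.ss_probs[perm],
            ss_state=np.asarray(ann.ss_state)[perm],
            accessibility=ann.accessibility[perm],
            disorder=ann.disorder[perm],
            low_complexity=ann.low_complexity[perm],
        )
        for block in (feat.pssm_block, feat.ss_block, feat.acc_block,
                      feat.disorder_block, feat.seg_block):
            original = block(seq, ann, 0)
            shuffled = block(permuted_seq, permuted_ann, 0)
            assert set(original) == set(shuffled)
            for key in original:
                assert original[key] == pytest.approx(shuffled[key], abs=1e-12)

    def test_span_outside_annotations_raises(self, rng):
        seq = random_peptide(rng, 10)
        ann = es.synthesize_annotations(seq, 0.0, seed=6)
        with pytest.raises(ValueError):
            feat.pssm_block(seq, ann, 5)


class TestAssemble:
    def test_block_offsets_ordered_and_disjoint(self, rng):
        seq = random_peptide(rng, 15)
        ann = es.synthesize_annotations(seq, 0.2, seed=7)
        fv = es.assemble(seq, ann, 0, es.FeatureConfig())
        assert fv.dimension == 53633
        spans = list(fv.block_offsets.values())
        assert spans == sorted(spans)
        for (s1, l1), (s2, _) in zip(spans, spans[1:]):
            assert s1 + l1 == s2
        assert max(fv.entries) < 53633

    def test_ngram_only_order1_dimension(self):
        fv = es.assemble("ACDEF", None, 0, es.FeatureConfig(ngram_max=1, blocks=("ngram",)))
        assert fv.dimension == 20

    def test_empty_config_gives_empty_vector(self):
        fv = es.assemble("ACDEF", None, 0, es.FeatureConfig(blocks=()))
        assert fv.dimension == 0 and fv.entries == {}

    def test_annotation_blocks_without_annotations_raise(self):
        with pytest.raises(ValueError):
            es.assemble("ACDEF", None, 0, es.FeatureConfig(blocks=("ss",)))


class TestScaler:
    def test_midpoint_maps_to_half(self):
        scaler = es.FeatureScaler().fit(np.array([[0.0], [10.0]]))
        assert scaler.transform(np.array([[5.0]]))[0, 0] == pytest.approx(0.5)

    def test_out_of_range_values_not_clipped(self):
        scaler = es.FeatureScaler().fit(np.array([[0.0], [10.0]]))
        assert scaler.transform(np.array([[12.0]]))[0, 0] == pytest.approx(1.2)

    def test_constant_features_map_to_zero(self):
        scaler = es.FeatureScaler().fit(np.array([[3.0, 1.0], [3.0, 2.0]]))
        out = scaler.transform(np.array([[3.0, 1.5]]))
        assert out[0, 0] == 0.0 and out[0, 1] == pytest.approx(0.5)

    def test_refit_on_scaled_data_is_identity(self, rng):
        X = rng.random((20, 6)) * np.array([1, 2, 5, 0.1, 10, 3])
        scaler = es.FeatureScaler().fit(X)
        Xs = scaler.transform(X)
        rescaled = es.FeatureScaler().fit(Xs).transform(Xs)
        assert np.abs(rescaled - Xs).max() < 1e-12

    def test_sparse_and_dense_paths_agree(self, rng):
        dense = rng.random((30, 40))
        dense[dense < 0.7] = 0.0
        dense[:, 5] += 0.5  # a column with nonzero minimum
        sparse = sp.csr_matrix(dense)
        scaler = es.FeatureScaler().fit(sparse)
        out_sparse = scaler.transform(sparse).toarray()
        out_dense = es.FeatureScaler().fit(dense).transform(dense)
        assert np.abs(out_sparse - out_dense).max() < 1e-12
        assert out_sparse.min() >= -1e-12 and out_sparse.max() <= 1 + 1e-12

    def test_dimension_mismatch_raises(self):
        scaler = es.FeatureScaler().fit(np.zeros((2, 3)))
        with pytest.raises(ValueError):
            scaler.transform(np.zeros((1, 4)))

    def test_apply_scaler_preserves_layout(self, rng):
        seq = random_peptide(rng, 15)
        ann = es.synthesize_annotations(seq, 0.5, seed=8)
        config = es.FeatureConfig(blocks=("ngram", "acc"), ngram_max=1)
        vectors = [
            es.assemble(random_peptide(rng, 15), es.synthesize_annotations(
                random_peptide(rng, 15), 0.0, seed=i), 0, config)
            for i in range(3)
        ]
        # scale the vector against a scaler fitted on its own singleton set
        fv = es.assemble(seq, ann, 0, config)
        scaler = es.fit_scaler([fv])
        scaled = es.apply_scaler(scaler, fv)
        assert scaled.block_offsets == fv.block_offsets
        assert scaled.entries == {}  # single fitting vector: everything constant


class TestSvmlightIO:
    def test_round_trip(self, rng, tmp_path):
        dense = rng.random((10, 25))
        dense[dense < 0.6] = 0.0
        dense = np.round(dense, 6)  # the format carries 6 decimals
        X = sp.csr_matrix(dense)
        y = rng.choice([-1, 1], size=10)
        path = tmp_path / "features.svml"
        feat.write_svmlight_file(X, y, path)
        X2, y2 = feat.read_svmlight_file(path, 25)
        assert np.array_equal(y, y2)
        assert np.abs(X2.toarray() - dense).max() < 1e-12
        first = path.read_text().splitlines()[0]
        assert first.startswith(("+1 ", "-1 "))
        assert all(":" in tok for tok in first.split()[1:])
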