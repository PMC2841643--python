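import numpy as np
import pytest

from metaprof.composition import (
    cluster_separation,
    feature_names,
    filter_contigs,
    pca_profiles,
    reverse_complement_permutation,
    word_frequency_profile,
)
from metaprof.io import SequenceRecord
from metaprof.simulate import GenomeModel, make_contigs, reverse_complement, simulate_genome

from .oracles import brute_word_frequencies


class TestWordFrequencyProfile:
    def test_homopolymer_single_base(self):
        prof = word_frequency_profile("AAAA", L=1)
        assert prof.vector.tolist() == [1.0, 0.0, 0.0, 0.0]

    def test_feature_count_for_L5(self):
        assert len(feature_names(5)) == 1364
        prof = word_frequency_profile("ACGTACGTACGT", L=5)
        assert prof.vector.shape == (1364,)

    def test_hand_counted_dimers(self):
        prof = word_frequency_profile("ACGT", L=2)
        names = feature_names(2)
        freq = dict(zip(names, prof.vector))
        assert freq["AC"] == pytest.approx(1 / 3)
        assert freq["CG"] == pytest.approx(1 / 3)
        assert freq["GT"] == pytest.approx(1 / 3)
        assert freq["AA"] == 0.0

    def test_matches_bruteforce_counts(self, rng):
        seq = "".join(rng.choice(list("ACGTN"), size=400, p=[0.24] * 4 + [0.04]))
        prof = word_frequency_profile(seq, L=3)
        names = feature_names(3)
        offset = {1: 0, 2: 4, 3: 20}
        for k in (1, 2, 3):
            expected = brute_word_frequencies(seq, k)
            block = prof.vector[offset[k] : offset[k] + 4**k]
            for name, value in zip(names[offset[k] :], block):
                assert value == pytest.approx(expected.get(name, 0.0))

    def test_within_length_normalization(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        prof = word_frequency_profile(seq, L=4)
        offset = 0
        for k in range(1, 5):
            assert prof.vector[offset : offset + 4**k].sum() == pytest.approx(1.0)
            offset += 4**k

    def test_n_windows_skipped_and_all_n_errors(self):
        prof = word_frequency_profile("ANAT", L=2)
        names = feature_names(2)
        freq = dict(zip(names, prof.vector))
        assert freq["AT"] == 1.0  # the only N-free dimer window
        with pytest.raises(ValueError, match="countable"):
            word_frequency_profile("NNNN", L=2)

    def test_reverse_complement_feature_permutation(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=500))
        perm = reverse_complement_permutation(4)
        fwd = word_frequency_profile(seq, L=4).vector
        rev = word_frequency_profile(reverse_complement(seq), L=4).vector
        np.testing.assert_allclose(rev, fwd[perm], atol=1e-12)

    def test_rc_collapsed_profile_is_strand_symmetric(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=500))
        a = word_frequency_profile(seq, L=3, collapse_rc=True).vector
        b = word_frequency_profile(reverse_complement(seq), L=3, collapse_rc=True).vector
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestFilterContigs:
    def test_strictly_greater_than(self):
        recs = [SequenceRecord("a", "A" * 1500), SequenceRecord("b", "A" * 1501)]
        assert [r.id for r in filter_contigs(recs)] == ["b"]

    def test_empty_and_identity(self):
        assert filter_contigs([]) == []
        recs = [SequenceRecord("a", "A" * 2000)]
        assert filter_contigs(recs) == recs


def _two_population_profiles(n_per=15, seed=0):
    g1 = simulate_genome(GenomeModel("lowgc", 60_000, gc=0.30), seed)
    g2 = simulate_genome(GenomeModel("higc", 60_000, gc=0.70), seed + 1)
    contigs = make_contigs(g1, n_per, length_mean=2500, seed=seed + 2)
    contigs += make_contigs(g2, n_per, length_mean=2500, seed=seed + 3)
    profiles = [word_frequency_profile(c, L=4) for c in contigs]
    labels = [c.id.split("_")[0] for c in contigs]
    return profiles, labels


class TestPca:
    def test_gc_extremes_separate_on_pc1(self):
        profiles, labels = _two_population_profiles()
        coords = pca_profiles(profiles, n_components=2)
        pc1 = coords.coords[:, 0]
        low = [x for x, l in zip(pc1, labels) if l == "lowgc"]
        high = [x for x, l in zip(pc1, labels) if l == "higc"]
        assert max(low) < min(high) or max(high) < min(low)

    def test_identical_profiles_center_to_zero(self):
        prof = word_frequency_profile("ACGTACGTAA" * 30, L=3)
        coords = pca_profiles([prof] * 5, n_components=2, standardize=False)
        np.testing.assert_allclose(coords.coords, 0.0, atol=1e-10)

    def test_explained_variance_properties(self):
        profiles, _ = _two_population_profiles()
        coords = pca_profiles(profiles, n_components=3)
        evr = coords.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)  # non-increasing
        assert 0 < evr.sum() <= 1.0 + 1e-12

    def test_too_few_profiles_rejected(self):
        profiles, _ = _two_population_profiles(n_per=2)
        with pytest.raises(ValueError):
            pca_profiles(profiles[:3], n_components=3)

    def test_input_order_invariance(self, rng):
        profiles, _ = _two_population_profiles()
        order = rng.permutation(len(profiles))
        a = pca_profiles(profiles, n_components=3)
        b = pca_profiles([profiles[i] for i in order], n_components=3)
        lookup = {cid: row for cid, row in zip(b.contig_ids, b.coords)}
        for cid, row in zip(a.contig_ids, a.coords):
            np.testing.assert_allclose(row, lookup[cid], atol=1e-8)


class TestClusterSeparation:
    def test_perfect_separation_gives_ari_one(self):
        X = np.vstack([np.random.default_rng(0).normal(c, 0.05, (20, 3))
                       for c in (0.0, 5.0)])
        labels = ["a"] * 20 + ["b"] * 20
        m = cluster_separation(X, labels)
        assert m["ari"] == 1.0 and m["silhouette"] > 0.9

    def test_shuffled_labels_give_near_zero_ari(self, rng):
        X = np.vstack([rng.normal(c, 0.05, (100, 3)) for c in (0.0, 5.0)])
        labels = list(rng.permutation(["a"] * 100 + ["b"] * 100))
        m = cluster_separation(X, labels)
        assert abs(m["ari"]) < 0.1

    def test_coincident_clouds_nonpositive_silhouette(self, rng):
        X = rng.normal(0, 1.0, (60, 3))
        labels = ["a"] * 30 + ["b"] * 30
        assert cluster_separation(X, labels)["silhouette"] <= 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cluster_separation(np.zeros((10, 2)), ["a"] * 10)
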