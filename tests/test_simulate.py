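import numpy as np
import pytest

from metaprof.simulate import (
    GenomeModel,
    PathwayStudySpec,
    align_reads,
    build_pathway_db,
    mutate_genome,
    reverse_complement,
    shed_reads,
    simulate_genome,
    simulate_pathway_study,
)


def _identity(a, b):
    return sum(x == y for x, y in zip(a, b)) / len(a)


class TestSimulateGenome:
    def test_gc_setpoint_hit_within_binomial_tolerance(self):
        g = simulate_genome(GenomeModel("g", 100_000, gc=0.30), 7)
        gc = (g.seq.count("G") + g.seq.count("C")) / len(g.seq)
        assert abs(gc - 0.30) < 0.02

    def test_deterministic_under_seed(self):
        m = GenomeModel("g", 5000, gc=0.5)
        assert simulate_genome(m, 11).seq == simulate_genome(m, 11).seq
        assert simulate_genome(m, 11).seq != simulate_genome(m, 12).seq

    def test_degenerate_markov_row_rejected(self):
        t = np.zeros((4, 4, 4, 4))
        with pytest.raises(ValueError, match="zeros"):
            GenomeModel("g", 1000, transitions=t)

    def test_all_mass_on_A_yields_poly_A_tail(self):
        t = np.zeros((4, 4, 4, 4))
        t[..., 0] = 1.0
        g = simulate_genome(GenomeModel("g", 200, transitions=t), 3)
        # after the seeded context, every base is A
        assert set(g.seq[3:]) == {"A"}

    def test_markov_model_preserves_dinucleotide_bias(self):
        # order-1 chain strongly favouring repeats: AA/CC/GG/TT enriched
        t = np.full((4, 4), 0.1)
        np.fill_diagonal(t, 0.7)
        g = simulate_genome(GenomeModel("g", 50_000, transitions=t, order=1), 5)
        same = sum(a == b for a, b in zip(g.seq, g.seq[1:])) / (len(g.seq) - 1)
        assert same > 0.6


class TestMutateGenome:
    def test_zero_divergence_is_identity(self):
        g = simulate_genome(GenomeModel("g", 2000, gc=0.5), 1)
        assert mutate_genome(g, 0.0, 2).seq == g.seq

    def test_divergence_recovered_as_global_identity(self):
        g = simulate_genome(GenomeModel("g", 100_000, gc=0.5), 1)
        m = mutate_genome(g, 0.10, 2)
        assert 0.895 <= _identity(g.seq, m.seq) <= 0.905

    def test_half_divergence_on_poly_A(self):
        from metaprof.io import SequenceRecord

        g = SequenceRecord("a", "A" * 100_000)
        m = mutate_genome(g, 0.5, 3)
        frac_a = m.seq.count("A") / len(m.seq)
        assert abs(frac_a - 0.5) < 0.01

    def test_out_of_range_divergence(self):
        g = simulate_genome(GenomeModel("g", 1000, gc=0.5), 1)
        with pytest.raises(ValueError):
            mutate_genome(g, 0.6, 1)


class TestShedReads:
    def test_bookkeeping_counts_and_intervals(self):
        g = simulate_genome(GenomeModel("g", 50_000, gc=0.4), 1)
        reads, truth = shed_reads(g, 100, seed=2)
        assert len(reads) == 200 and len(truth) == 200
        by_id = {t.read_id: t for t in truth}
        for t in truth:
            assert 0 <= t.start < t.end <= 50_000
            assert by_id[t.mate_id].mate_id == t.read_id  # symmetric mates

    def test_error_free_reads_match_source_interval(self):
        g = simulate_genome(GenomeModel("g", 30_000, gc=0.5), 1)
        reads, truth = shed_reads(g, 30, error_rate=0.0, seed=4)
        seqs = {r.id: r.seq for r in reads}
        for t in truth:
            source = g.seq[t.start : t.end]
            expected = source if t.strand == "+" else reverse_complement(source)
            assert seqs[t.read_id] == expected

    def test_zero_sd_gives_exact_lengths(self):
        g = simulate_genome(GenomeModel("g", 30_000, gc=0.5), 1)
        reads, _ = shed_reads(g, 20, read_len_mean=800, read_len_sd=0.0,
                              insert_mean=2000, insert_sd=0.0, seed=5)
        assert {len(r.seq) for r in reads} == {800}

    def test_short_genome_rejected(self):
        g = simulate_genome(GenomeModel("g", 1500, gc=0.5), 1)
        with pytest.raises(ValueError, match="shorter"):
            shed_reads(g, 5, insert_mean=1600, seed=1)

    def test_identity_recovery_through_mutation_and_errors(self):
        # reads shed from a mutated genome vs the original: mean identity
        # ~ (1-d)(1-error_rate) within one percentage point
        d, err = 0.05, 0.005
        g = simulate_genome(GenomeModel("g", 120_000, gc=0.5), 9)
        m = mutate_genome(g, d, 10)
        reads, truth = shed_reads(m, 80, error_rate=err, seed=11)
        seqs = {r.id: r.seq for r in reads}
        matches = total = 0
        for t in truth:
            ref = g.seq[t.start : t.end]
            if t.strand == "-":
                ref = reverse_complement(ref)
            read = seqs[t.read_id]
            matches += sum(a == b for a, b in zip(read, ref))
            total += len(ref)
        assert total > 100_000
        expected = (1 - d) * (1 - err)
        assert abs(matches / total - expected) < 0.01


class TestFixtureAligner:
    def test_self_alignment_is_perfect_and_plus_strand(self):
        g = simulate_genome(GenomeModel("g", 20_000, gc=0.5), 1)
        reads, truth = shed_reads(g, 5, error_rate=0.0, seed=2)
        hits = align_reads(reads, [g])
        assert len(hits) == 10
        by_id = {t.read_id: t for t in truth}
        for h in hits:
            assert h.pct_identity == 100.0 and h.evalue < 1e-100
            t = by_id[h.query_id]
            assert h.minus_strand == (t.strand == "-")
            assert (h.s_lo - 1, h.s_hi) == (t.start, t.end)

    def test_unrelated_reference_scores_below_threshold(self):
        a = simulate_genome(GenomeModel("a", 20_000, gc=0.5), 1)
        b = simulate_genome(GenomeModel("b", 20_000, gc=0.5), 2)
        reads, _ = shed_reads(a, 10, error_rate=0.0, seed=3)
        hits = align_reads(reads, [b], min_bitscore=0.0)
        assert all(h.evalue > 1e-10 for h in hits)


class TestPathwayStudy:
    def test_duplicate_variants_have_no_penalty_structure(self, rng):
        spec = PathwayStudySpec(n_pathways=10, n_duplicate_variants=3)
        db = build_pathway_db(spec, rng)
        dup_ids = [p for p in db.pathways if "-VAR" in p]
        assert len(dup_ids) == 3
        for vid in dup_ids:
            src = vid.rsplit("-VAR", 1)[0]
            assert db.pathways[vid] == db.pathways[src]
        # a reaction in two identical pathways has n_totrxn/n_unirxn == n_pw
        vid = dup_ids[0]
        for rxn in db.pathways[vid]:
            n_pw, n_tot, n_uni = db.reaction_counts(rxn)
            if n_pw == 2:  # exactly the pathway and its duplicate
                assert n_tot / n_uni == pytest.approx(n_pw)

    def test_noise_free_study_hits_only_encoded_reactions(self):
        spec = PathwayStudySpec(n_pathways=10, n_duplicate_variants=0)
        db, sample_hits, truth, content = simulate_pathway_study(
            spec, n_samples=2, noise_queries_per_sample=0, decoy_hit_prob=0.0,
            matched_genomes=False, seed=5,
        )
        for sample, hits in sample_hits.items():
            touched = set()
            for h in hits:
                assert h.bitscore > 50
                touched.update(db.protein_reactions(h.subject_id))
            assert touched == set(content[sample])

    def test_truth_table_matches_unique_query_counts(self):
        spec = PathwayStudySpec(n_pathways=6, n_duplicate_variants=0)
        db, sample_hits, truth, content = simulate_pathway_study(
            spec, n_samples=1, noise_queries_per_sample=0, decoy_hit_prob=0.0,
            matched_genomes=False, seed=6,
        )
        (sample,) = sample_hits
        per_rxn = {}
        for h in sample_hits[sample]:
            for r in db.protein_reactions(h.subject_id):
                per_rxn.setdefault(r, set()).add(h.query_id)
        for row in truth.itertuples(index=False):
            assert len(per_rxn[row.reaction]) == row.true_count

    def test_determinism(self):
        spec = PathwayStudySpec(n_pathways=8)
        a = simulate_pathway_study(spec, n_samples=2, seed=3)
        b = simulate_pathway_study(spec, n_samples=2, seed=3)
        assert a[2].equals(b[2])
        assert {s: [h.bitscore for h in hs] for s, hs in a[1].items()} == {
            s: [h.bitscore for h in hs] for s, hs in b[1].items()
        }
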