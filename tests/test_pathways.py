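import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaprof.io import AlignmentHit, PathwayDB
from metaprof.pathways import (
    activity_score,
    cluster_score_matrix,
    completeness_matrix,
    completeness_score,
    filter_sample_hits,
    filtered_hit_list,
    reaction_hit_counts,
    select_key_pathways,
    specificity_weight,
    specificity_weights,
)

from .conftest import random_pathway_dict
from .oracles import brute_completeness, brute_weight


def _hit(query, protein, bit):
    return AlignmentHit(query, protein, 90.0, 150, 5, 0, 1, 150, 1, 150,
                        2.0 ** (-bit) * 1e6 if bit < 500 else 0.0, bit)


def _db_with_partial(partial_rxns=()):
    """P1 has R1..R3; P2 has R3..R5. Each reaction has one protein."""
    pathways = {"P1": ["R1", "R2", "R3"], "P2": ["R3", "R4", "R5"]}
    rxns = ["R1", "R2", "R3", "R4", "R5"]
    proteins = {r: {f"{r}.p"} for r in rxns}
    ec = {r: ("1.1.1.1", r in partial_rxns) for r in rxns}
    return PathwayDB(pathways, proteins, ec)


class TestSpecificityWeight:
    def test_private_reaction_has_unit_weight(self, small_db):
        assert specificity_weight("R1", small_db) == 1.0

    def test_identical_duplicate_pathways_carry_no_penalty(self):
        db = PathwayDB({"A": ["R1", "R2", "R3", "R4", "R5"],
                        "Adup": ["R1", "R2", "R3", "R4", "R5"]})
        # n_pw=2, n_totrxn=10, n_unirxn=5 -> w = (10/5)/2 = 1
        assert specificity_weight("R1", db) == 1.0

    def test_shared_across_disjoint_pathways_discounted(self):
        db = PathwayDB({"A": ["RS", "R1", "R2", "R3", "R4"],
                        "B": ["RS", "R5", "R6", "R7", "R8"]})
        # n_totrxn=10, n_unirxn=9 -> w = (10/9)/2
        assert specificity_weight("RS", db) == pytest.approx((10 / 9) / 2)

    def test_orphan_reaction_rejected(self, small_db):
        with pytest.raises(KeyError):
            specificity_weight("R99", small_db)

    def test_matches_bruteforce_on_random_dbs(self, rng):
        for _ in range(20):
            pw = random_pathway_dict(rng)
            db = PathwayDB(pw)
            for r in {x for v in pw.values() for x in v}:
                assert specificity_weight(r, db) == pytest.approx(
                    brute_weight(pw, r)
                )

    def test_no_penalty_invariances_under_duplication(self, rng):
        """Exact duplicates cost nothing: weights of reactions outside a
        duplicated pathway never move, reactions private to a pathway keep
        w=1 at any copy number, and duplicating the whole DB is a no-op."""
        pw = random_pathway_dict(rng)
        before = specificity_weights(PathwayDB(pw))
        for victim in list(pw):
            dup = dict(pw)
            dup[victim + "_copy"] = list(pw[victim])
            after = specificity_weights(PathwayDB(dup))
            for r, w in before.items():
                if r not in pw[victim]:
                    assert after[r] == pytest.approx(w)
        whole = dict(pw) | {k + "_c": list(v) for k, v in pw.items()}
        after_all = specificity_weights(PathwayDB(whole))
        for r, w in before.items():
            assert after_all[r] == pytest.approx(w)
        # a private reaction stays at weight 1 for any number of exact copies
        solo = {"P": ["RA", "RB", "RC"]}
        for copies in range(1, 5):
            dbs = {f"P{c}": ["RA", "RB", "RC"] for c in range(copies)}
            assert specificity_weight("RA", PathwayDB(dbs)) == pytest.approx(1.0)


class TestCompletenessScore:
    def test_all_present_is_one_and_none_is_zero(self, small_db):
        rxns = small_db.pathways["P1"]
        assert completeness_score("P1", {r: 1 for r in rxns}, small_db) == 1.0
        assert completeness_score("P1", {}, small_db) == 0.0

    def test_shared_low_weight_reaction_absent(self):
        db = PathwayDB({"A": ["RS", "R1", "R2", "R3", "R4"],
                        "B": ["RS", "R5", "R6", "R7", "R8"]})
        presence = {r: 1 for r in ["R1", "R2", "R3", "R4"]}
        # 4 unit weights present, shared w=(10/9)/2=5/9 absent: 4/(4+5/9)=36/41
        assert completeness_score("A", presence, db) == pytest.approx(36 / 41)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.data())
    def test_monotone_in_indicators(self, seed, data):
        rng = np.random.default_rng(seed)
        pw = random_pathway_dict(rng, n_pathways=5)
        db = PathwayDB(pw)
        pid = sorted(pw)[0]
        rxns = pw[pid]
        present = set(
            data.draw(st.sets(st.sampled_from(sorted(rxns)), max_size=len(rxns)))
        )
        flip = data.draw(st.sampled_from(sorted(rxns)))
        base = completeness_score(pid, {r: 1 for r in present}, db)
        more = completeness_score(pid, {r: 1 for r in present | {flip}}, db)
        assert more >= base - 1e-12
        assert 0.0 <= base <= 1.0

    def test_matches_bruteforce(self, rng):
        pw = random_pathway_dict(rng)
        db = PathwayDB(pw)
        weights = specificity_weights(db)
        all_rxns = sorted({r for v in pw.values() for r in v})
        for _ in range(50):
            present = set(rng.choice(all_rxns, size=10, replace=False))
            for pid in pw:
                assert completeness_score(
                    pid, {r: 1 for r in present}, db
                ) == pytest.approx(brute_completeness(pw[pid], weights, present))


class TestActivityScore:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({"R1": 0, "R2": 2, "R3": 4}, 2.0),
            ({"R1": 0, "R2": 0, "R3": 0, "R4": 8}, 0.0),
            ({"R1": 1, "R2": 3}, 2.0),
        ],
    )
    def test_median_rules(self, counts, expected):
        db = PathwayDB({"P": list(counts)})
        assert activity_score("P", counts, db) == expected

    def test_missing_reactions_count_as_zero(self):
        db = PathwayDB({"P": ["R1", "R2", "R3"]})
        assert activity_score("P", {"R1": 9}, db) == 0.0


class TestFilteredHitList:
    def test_window_and_floor(self):
        db = _db_with_partial()
        hits = [_hit("q", "R1.p", 100), _hit("q", "R2.p", 85),
                _hit("q", "R3.p", 79), _hit("q", "R4.p", 45)]
        fl = filtered_hit_list(hits, db)
        assert sorted(h.protein_id for h in fl.hits) == ["R1.p", "R2.p"]

    def test_single_hit_above_floor_retained(self):
        db = _db_with_partial()
        fl = filtered_hit_list([_hit("q", "R1.p", 51)], db)
        assert [h.protein_id for h in fl.hits] == ["R1.p"]
        assert filtered_hit_list([_hit("q", "R1.p", 50)], db).hits == []

    def test_partial_only_suppressed_when_full_association_exists(self):
        db = _db_with_partial(partial_rxns={"R5"})
        hits = [_hit("q", "R1.p", 60), _hit("q", "R5.p", 90)]
        fl = filtered_hit_list(hits, db)
        assert [h.protein_id for h in fl.hits] == ["R1.p"]

    def test_partial_only_kept_when_no_full_above_floor(self):
        db = _db_with_partial(partial_rxns={"R5"})
        hits = [_hit("q", "R1.p", 40), _hit("q", "R5.p", 90)]
        fl = filtered_hit_list(hits, db)
        assert [h.protein_id for h in fl.hits] == ["R5.p"]
        assert fl.reactions == {"R5"}

    def test_unknown_protein_rejected(self):
        db = _db_with_partial()
        with pytest.raises(KeyError):
            filtered_hit_list([_hit("q", "nope", 80)], db)

    def test_mixed_queries_rejected(self):
        db = _db_with_partial()
        with pytest.raises(ValueError):
            filtered_hit_list([_hit("a", "R1.p", 80), _hit("b", "R1.p", 80)], db)


class TestReactionHitCounts:
    def test_uniqueness_rules(self):
        db = _db_with_partial()
        lists = filter_sample_hits(
            [
                _hit("q1", "R1.p", 100),  # q1 touches R1 only
                _hit("q2", "R1.p", 100), _hit("q2", "R2.p", 95),
            ],
            db,
        )
        counts = reaction_hit_counts({"s": lists}, db)
        assert counts.loc["R1", "s"] == 2
        assert counts.loc["R2", "s"] == 1
        assert counts.loc["R3", "s"] == 0

    def test_three_proteins_one_reaction_counts_once(self):
        pathways = {"P": ["R1"]}
        proteins = {"R1": {"a", "b", "c"}}
        db = PathwayDB(pathways, proteins, {"R1": ("1.1.1.1", False)})
        lists = filter_sample_hits(
            [_hit("q", "a", 100), _hit("q", "b", 95), _hit("q", "c", 90)], db
        )
        counts = reaction_hit_counts({"s": lists}, db)
        assert counts.loc["R1", "s"] == 1


class TestSelectKeyPathways:
    def _scores(self, db, varying):
        samples = [f"s{i}" for i in range(6)]
        data = {}
        for pid in db.pathways:
            if pid == varying:
                data[pid] = [1, 1, 1, 0, 0, 0]
            else:
                data[pid] = [0.5] * 6
        return pd.DataFrame(data, index=samples).T

    def test_only_varying_pathway_ranks_first(self, rng):
        pw = {f"P{i}": [f"R{i}_{j}" for j in range(6)] for i in range(8)}
        db = PathwayDB(pw)
        scores = self._scores(db, "P3")
        assert select_key_pathways(scores, db, top_k=3)[0] == "P3"

    def test_identical_pathways_collapse_to_one(self):
        pw = {"A": ["R1", "R2", "R3", "R4", "R5"],
              "B": ["R1", "R2", "R3", "R4", "R5"],
              "C": ["X1", "X2", "X3", "X4", "X5"],
              "D": ["Y1", "Y2", "Y3", "Y4", "Y5"]}
        db = PathwayDB(pw)
        rng = np.random.default_rng(0)
        scores = pd.DataFrame(
            rng.random((4, 6)), index=list(pw), columns=[f"s{i}" for i in range(6)]
        )
        scores.loc["B"] = scores.loc["A"]
        selected = select_key_pathways(scores, db, top_k=4)
        assert len({p for p in selected if p in ("A", "B")}) == 1

    def test_small_pathways_filtered_in_completeness_mode(self, rng):
        pw = {"small": ["R1", "R2"],
              **{f"P{i}": [f"R{i}_{j}" for j in range(5)] for i in range(5)}}
        db = PathwayDB(pw)
        scores = pd.DataFrame(
            np.random.default_rng(1).random((6, 5)),
            index=list(pw), columns=[f"s{i}" for i in range(5)],
        )
        assert "small" not in select_key_pathways(scores, db, top_k=6)
        assert "small" in select_key_pathways(
            scores, db, top_k=6, apply_size_filter=False
        )

    def test_result_size_capped_and_errors(self, rng):
        pw = {f"P{i}": [f"R{i}_{j}" for j in range(5)] for i in range(10)}
        db = PathwayDB(pw)
        scores = pd.DataFrame(
            np.random.default_rng(2).random((10, 6)),
            index=list(pw), columns=[f"s{i}" for i in range(6)],
        )
        assert len(select_key_pathways(scores, db, top_k=4)) <= 4
        with pytest.raises(ValueError, match="variance"):
            select_key_pathways(scores * 0 + 0.3, db)
        with pytest.raises(ValueError, match="columns"):
            select_key_pathways(scores.iloc[:, :3], db)


class TestClusterScoreMatrix:
    def test_identical_rows_merge_at_zero_height(self):
        m = pd.DataFrame(
            [[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0]],
            index=["a", "b", "c"], columns=list("wxyz"), dtype=float,
        )
        cl = cluster_score_matrix(m, "completeness")
        assert cl.row_linkage[0, 2] == 0.0  # first merge at height 0
        merged = {cl.row_order.index("a"), cl.row_order.index("b")}
        assert max(merged) - min(merged) == 1  # adjacent leaves

    def test_opposed_rows_merge_last(self):
        m = pd.DataFrame(
            [[0, 0, 1, 1], [1, 1, 0, 0], [0, 0, 1, 1]],
            index=["a", "b", "a2"], columns=list("wxyz"), dtype=float,
        )
        cl = cluster_score_matrix(m, "completeness")
        # final merge height equals the a/b euclidean distance (2.0)
        assert cl.row_linkage[-1, 2] == pytest.approx(2.0)

    def test_linkage_heights_non_decreasing(self, rng):
        m = pd.DataFrame(rng.random((8, 5)),
                         index=[f"p{i}" for i in range(8)],
                         columns=[f"s{i}" for i in range(5)])
        for mode in ("completeness", "activity"):
            cl = cluster_score_matrix(m, mode)
            heights = cl.row_linkage[:, 2]
            assert np.all(np.diff(heights) >= -1e-12)

    def test_activity_uses_log_pearson_and_handles_flat_rows(self, rng):
        m = pd.DataFrame(rng.random((4, 5)) * 10,
                         index=list("abcd"), columns=[f"s{i}" for i in range(5)])
        m.loc["a"] = 3.0  # zero variance row
        cl = cluster_score_matrix(m, "activity")
        # the flat row joins last at the maximal Pearson distance
        assert cl.row_linkage[-1, 2] == pytest.approx(2.0)

    def test_newick_exports_all_leaves(self, rng):
        m = pd.DataFrame(rng.random((4, 4)), index=list("abcd"),
                         columns=list("wxyz"))
        cl = cluster_score_matrix(m, "completeness")
        nwk = cl.row_newick()
        for leaf in "abcd":
            assert leaf in nwk
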