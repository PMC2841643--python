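"""Pathway completeness and activity scoring from filtered protein hit lists.

The scoring chain mirrors reaction-level evidence up to pathway-level
summaries:

1.  Per query translation, retain hits with bit score strictly above 50 and
    within 20% of the top retained hit's score; proteins linked to reactions
    only through partial EC numbers are suppressed whenever any fully
    associated protein clears the floor.
2.  Per (sample, reaction), count the unique query translations whose
    filtered list touches the reaction.
3.  Weight each reaction by its pathway specificity,
    ``w_i = (n_totrxn_i / n_unirxn_i) / n_pw_i``: reactions occurring in many
    distinct pathways are discounted, while exact duplicate pathway variants
    cost nothing (for identical pathways ``n_totrxn/n_unirxn = n_pw``).
4.  Pathway completeness is the weighted fraction of its reactions with at
    least one hit, ``C_j = sum(w_i * I_i) / sum(w_i)`` over the pathway's
    reactions; pathway activity is the median per-reaction unique-hit count,
    zero-count reactions included.

Key pathways for presentation are chosen by PCA contribution and pruned of
near-duplicate variants; score matrices are clustered two-way with average
linkage (Euclidean for completeness, Pearson distance on log(1+x) for
activity).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode

from .io import AlignmentHit, PathwayDB

__all__ = [
    "FilteredHit",
    "FilteredHitList",
    "filtered_hit_list",
    "reaction_hit_counts",
    "specificity_weight",
    "specificity_weights",
    "completeness_score",
    "completeness_matrix",
    "activity_score",
    "activity_matrix",
    "select_key_pathways",
    "TwoWayClustering",
    "cluster_score_matrix",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilteredHit:
    protein_id: str
    bitscore: float
    reactions_full: frozenset[str]  # via direct association or full EC
    reactions_partial: frozenset[str]

    @property
    def reactions(self) -> frozenset[str]:
        return self.reactions_full | self.reactions_partial


@dataclass
class FilteredHitList:
    query_id: str
    hits: list[FilteredHit]

    @property
    def reactions(self) -> set[str]:
        out: set[str] = set()
        for h in self.hits:
            out.update(h.reactions)
        return out


def _split_associations(db: PathwayDB, protein_id: str) -> tuple[frozenset[str], frozenset[str]]:
    rxns = db.protein_reactions(protein_id)
    full = frozenset(r for r in rxns if not db.reaction_ec.get(r, ("", False))[1])
    partial = frozenset(rxns) - full
    return full, partial


def filtered_hit_list(
    hits: Sequence[AlignmentHit],
    db: PathwayDB,
    bit_floor: float = 50.0,
    window: float = 0.20,
) -> FilteredHitList:
    """Filter one query's protein hits by bit floor, top-score window, and
    the partial-EC suppression rule.

    Retained hits score strictly above ``bit_floor`` and at least
    ``(1 - window)`` times the best score of the candidate set. Proteins
    whose only reaction associations are via partial EC numbers enter the
    candidate set only when no fully associated protein scores above the
    floor; the window's top score is computed over the surviving candidates.
    """
    if not hits:
        raise ValueError("empty hit list; caller should skip hitless queries")
    queries = {h.query_id for h in hits}
    if len(queries) != 1:
        raise ValueError(f"hits must share one query, got {sorted(queries)}")
    query_id = hits[0].query_id
    annotated: list[FilteredHit] = []
    for h in hits:
        full, partial = _split_associations(db, h.subject_id)
        if not (full | partial):
            raise KeyError(f"protein {h.subject_id!r} absent from pathway database")
        annotated.append(FilteredHit(h.subject_id, h.bitscore, full, partial))
    has_full_above_floor = any(
        fh.reactions_full and fh.bitscore > bit_floor for fh in annotated
    )
    if has_full_above_floor:
        candidates = [fh for fh in annotated if fh.reactions_full]
        suppressed = len(annotated) - len(candidates)
        if suppressed:
            logger.debug(
                "query %s: %d partial-EC-only hit(s) suppressed", query_id, suppressed
            )
    else:
        candidates = annotated
    retained: list[FilteredHit] = []
    if candidates:
        top = max(fh.bitscore for fh in candidates)
        retained = [
            fh
            for fh in candidates
            if fh.bitscore > bit_floor and fh.bitscore >= (1.0 - window) * top
        ]
    return FilteredHitList(query_id=query_id, hits=retained)


def filter_sample_hits(
    hits: Iterable[AlignmentHit],
    db: PathwayDB,
    bit_floor: float = 50.0,
    window: float = 0.20,
) -> list[FilteredHitList]:
    """Group a sample's hit table by query and filter each query's list."""
    by_query: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    return [
        filtered_hit_list(qhits, db, bit_floor, window)
        for _, qhits in sorted(by_query.items())
    ]


def reaction_hit_counts(
    filtered: Mapping[str, Sequence[FilteredHitList]],
    db: PathwayDB,
) -> pd.DataFrame:
    """Count unique query translations per (sample, reaction).

    A query touching several proteins of the same reaction counts once for
    that reaction; one query may contribute to several reactions. Rows are
    all reactions in the database, columns the samples.
    """
    reactions = sorted(db.reactions)
    table = pd.DataFrame(0, index=reactions, columns=list(filtered), dtype=int)
    for sample, lists in filtered.items():
        for fl in lists:
            for rxn in fl.reactions:
                table.loc[rxn, sample] += 1
    return table


def specificity_weight(reaction_id: str, db: PathwayDB) -> float:
    """Pathway specificity weight ``w_i = (n_totrxn_i / n_unirxn_i) / n_pw_i``.

    ``n_pw`` counts distinct pathways containing the reaction, ``n_totrxn``
    the reactions (with multiplicity) in those pathways, ``n_unirxn`` the
    unique reactions among them. A reaction private to one pathway gets
    weight 1; sharing across genuinely different pathways discounts it, but
    duplicate identical pathways do not (no-penalty property).
    """
    n_pw, n_totrxn, n_unirxn = db.reaction_counts(reaction_id)
    return (n_totrxn / n_unirxn) / n_pw


def specificity_weights(db: PathwayDB) -> dict[str, float]:
    return {
        r: specificity_weight(r, db)
        for rxns in db.pathways.values()
        for r in rxns
    }


def completeness_score(
    pathway_id: str,
    presence: Mapping[str, int] | Mapping[str, bool],
    db: PathwayDB,
    weights: Mapping[str, float] | None = None,
) -> float:
    """Weighted fraction of the pathway's reactions with at least one hit.

    ``presence`` maps reaction id to a hit indicator (truthy = present);
    missing reactions count as absent. ``C_j = sum(w_i I_i) / sum(w_i)``
    over the pathway's reaction set.
    """
    if pathway_id not in db.pathways:
        raise KeyError(f"unknown pathway {pathway_id!r}")
    if weights is None:
        weights = specificity_weights(db)
    rxns = db.pathways[pathway_id]
    total = sum(weights[r] for r in rxns)
    present = sum(weights[r] for r in rxns if presence.get(r))
    return present / total


def activity_score(
    pathway_id: str,
    counts: Mapping[str, int],
    db: PathwayDB,
) -> float:
    """Median unique-hit count over ALL reactions of the pathway.

    Reactions with no hits contribute a zero; an even reaction count takes
    the arithmetic mean of the central pair.
    """
    if pathway_id not in db.pathways:
        raise KeyError(f"unknown pathway {pathway_id!r}")
    values = [counts.get(r, 0) for r in db.pathways[pathway_id]]
    return float(np.median(values))


def completeness_matrix(
    counts: pd.DataFrame, db: PathwayDB
) -> pd.DataFrame:
    """Pathway x sample completeness scores from a reaction hit-count table."""
    weights = specificity_weights(db)
    data = {}
    for sample in counts.columns:
        presence = counts[sample].to_dict()
        data[sample] = {
            pid: completeness_score(pid, presence, db, weights)
            for pid in db.pathways
        }
    return pd.DataFrame(data)


def activity_matrix(counts: pd.DataFrame, db: PathwayDB) -> pd.DataFrame:
    """Pathway x sample activity (median hit count) scores."""
    data = {}
    for sample in counts.columns:
        cc = counts[sample].to_dict()
        data[sample] = {pid: activity_score(pid, cc, db) for pid in db.pathways}
    return pd.DataFrame(data)


def select_key_pathways(
    scores: pd.DataFrame,
    db: PathwayDB,
    n_pc: int = 3,
    top_k: int = 15,
    min_reactions: int = 5,
    apply_size_filter: bool = True,
) -> list[str]:
    """Rank pathways by PCA contribution and prune near-duplicate variants.

    Pathways with fewer than ``min_reactions`` reactions are dropped first
    (completeness-mode analyses; pass ``apply_size_filter=False`` for
    activity scores). Samples are the observations and pathways the
    variables; a pathway's contribution is the variance-weighted sum of its
    squared loadings on the top ``n_pc`` components. The ``top_k`` pathways
    by contribution are kept, then any pair whose reaction sets differ by at
    most one reaction is reduced to the higher-contribution member.
    """
    if scores.shape[1] < n_pc + 1:
        raise ValueError(f"need at least {n_pc + 1} sample columns")
    work = scores
    if apply_size_filter:
        keep = [p for p in work.index if len(db.pathways[p]) >= min_reactions]
        work = work.loc[keep]
    X = work.T.to_numpy(dtype=float)  # samples x pathways
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise ValueError("score matrix has no variance across samples")
    # spectral decomposition of the covariance keeps everything deterministic
    cov = np.cov(Xc, rowvar=False)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1][:n_pc]
    var = np.clip(eigval[order], 0.0, None)
    load = eigvec[:, order]
    contribution = (load**2 * var).sum(axis=1)
    ranked = sorted(
        zip(work.index, contribution), key=lambda t: (-t[1], t[0])
    )
    selected = [p for p, _ in ranked[:top_k]]
    # redundancy removal: higher-contribution member of any near-duplicate pair wins
    contrib = dict(ranked)
    kept: list[str] = []
    for p in sorted(selected, key=lambda p: (-contrib[p], p)):
        dup = any(
            len(set(db.pathways[p]) ^ set(db.pathways[q])) <= 1 for q in kept
        )
        if not dup:
            kept.append(p)
    return sorted(kept, key=lambda p: (-contrib[p], p))


@dataclass
class TwoWayClustering:
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list[str]
    col_order: list[str]
    row_tree: TreeNode
    col_tree: TreeNode

    def row_newick(self) -> str:
        return str(self.row_tree).strip()

    def col_newick(self) -> str:
        return str(self.col_tree).strip()


def _pearson_distance(X: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distances; zero-variance rows get the maximal
    distance 2 to everything (logged), matching the treat-as-unrelated rule."""
    sd = X.std(axis=1)
    degenerate = np.where(sd == 0)[0]
    if degenerate.size:
        logger.warning(
            "%d zero-variance row(s) under Pearson metric set to maximal distance",
            degenerate.size,
        )
    n = X.shape[0]
    D = np.full((n, n), 2.0)
    ok = sd > 0
    if ok.sum() >= 2:
        sub = X[ok]
        corr = np.corrcoef(sub)
        D[np.ix_(ok, ok)] = 1.0 - corr
    np.fill_diagonal(D, 0.0)
    return squareform(D, checks=False)


def cluster_score_matrix(
    scores: pd.DataFrame, score_type: str = "completeness"
) -> TwoWayClustering:
    """Average-linkage two-way clustering of a pathway x sample score matrix.

    Completeness matrices use Euclidean distance; activity matrices are
    transformed log(1 + x) and use Pearson correlation distance.
    """
    if scores.shape[0] < 2 or scores.shape[1] < 2:
        raise ValueError("need at least a 2 x 2 score matrix")
    if score_type not in ("completeness", "activity"):
        raise ValueError("score_type must be completeness|activity")
    X = scores.to_numpy(dtype=float)
    if score_type == "activity":
        X = np.log1p(X)
        row_d = _pearson_distance(X)
        col_d = _pearson_distance(X.T)
    else:
        row_d = pdist(X, metric="euclidean")
        col_d = pdist(X.T, metric="euclidean")
    row_Z = hierarchy.average(row_d)
    col_Z = hierarchy.average(col_d)
    row_ids = [str(i) for i in scores.index]
    col_ids = [str(c) for c in scores.columns]
    row_tree = TreeNode.from_linkage_matrix(row_Z, row_ids)
    col_tree = TreeNode.from_linkage_matrix(col_Z, col_ids)
    return TwoWayClustering(
        row_linkage=row_Z,
        col_linkage=col_Z,
        row_order=[row_ids[i] for i in hierarchy.leaves_list(row_Z)],
        col_order=[col_ids[i] for i in hierarchy.leaves_list(col_Z)],
        row_tree=row_tree,
        col_tree=col_tree,
    )
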