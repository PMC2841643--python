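"""Nucleotide word-frequency signatures and PCA clustering of assemblies.

Genomes differ in oligonucleotide composition, so the relative frequencies of
all DNA words of lengths 1..L (1364 features at L=5) separate contigs by
source organism without any reference database. Profiles are computed per
contig (contigs above a minimum length, 1500 bp by default), standardized,
and projected with a deterministic full-rank PCA; separation is quantified
with silhouette and adjusted Rand index against k-means.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .io import SequenceRecord

__all__ = [
    "KmerProfile",
    "PcaCoordinates",
    "feature_names",
    "word_frequency_profile",
    "reverse_complement_permutation",
    "filter_contigs",
    "pca_profiles",
    "cluster_separation",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_RC_INDEX = {0: 3, 1: 2, 2: 1, 3: 0}


@dataclass
class KmerProfile:
    """Relative word frequencies of one contig, lengths 1..L concatenated.

    Within each word length the frequencies sum to 1 (when any word of that
    length was counted); feature order is lexicographic within length,
    lengths ascending.
    """

    contig_id: str
    vector: np.ndarray
    L: int
    contig_length: int


@dataclass
class PcaCoordinates:
    contig_ids: list[str]
    coords: np.ndarray  # (n_contigs, n_components)
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray  # (n_features, n_components)


def feature_names(L: int) -> list[str]:
    """All words of lengths 1..L, lexicographic within each length."""
    names: list[str] = []
    for k in range(1, L + 1):
        names.extend("".join(w) for w in product("ACGT", repeat=k))
    return names


def _word_indices(seq: str, k: int) -> np.ndarray:
    """Base-4 indices of all k-mers; windows containing N return -1."""
    codes = np.array([_BASE_INDEX.get(c, -1) for c in seq], dtype=np.int64)
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    idx = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        window = codes[j : j + n]
        idx = idx * 4 + np.where(window >= 0, window, 0)
        valid &= window >= 0
    idx[~valid] = -1
    return idx


def word_frequency_profile(
    contig: SequenceRecord | str,
    L: int = 5,
    collapse_rc: bool = False,
) -> KmerProfile:
    """Count every overlapping word of lengths 1..L, normalized within length.

    Windows containing N are skipped. With ``collapse_rc`` each word's count
    is pooled with its reverse complement's (both get the pooled frequency),
    making the profile strand-symmetric.
    """
    if isinstance(contig, SequenceRecord):
        cid, seq = contig.id, contig.seq
    else:
        cid, seq = "<anonymous>", contig
    seq = seq.upper()
    if any(c not in "ACGTN" for c in set(seq)):
        bad = next(c for c in seq if c not in "ACGTN")
        raise ValueError(f"contig {cid!r}: illegal character {bad!r}")
    blocks: list[np.ndarray] = []
    counted_any = False
    for k in range(1, L + 1):
        idx = _word_indices(seq, k)
        idx = idx[idx >= 0]
        counts = np.bincount(idx, minlength=4**k).astype(float)
        if collapse_rc:
            counts = counts + counts[_rc_perm(k)]
        total = counts.sum()
        if total > 0:
            counted_any = True
            counts /= total
        blocks.append(counts)
    if not counted_any:
        raise ValueError(f"contig {cid!r}: no countable words after N filtering")
    return KmerProfile(
        contig_id=cid,
        vector=np.concatenate(blocks),
        L=L,
        contig_length=len(seq),
    )


def _rc_perm(k: int) -> np.ndarray:
    """Permutation sending each k-mer index to its reverse complement's index."""
    n = 4**k
    idx = np.arange(n)
    out = np.zeros(n, dtype=np.int64)
    for j in range(k):
        digit = (idx // 4**j) % 4
        comp = 3 - digit  # A<->T, C<->G in base-4 coding
        out += comp * 4 ** (k - 1 - j)
    return out


def reverse_complement_permutation(L: int) -> np.ndarray:
    """Feature permutation P with profile(revcomp(s)) = profile(s)[P]."""
    parts: list[np.ndarray] = []
    offset = 0
    for k in range(1, L + 1):
        parts.append(_rc_perm(k) + offset)
        offset += 4**k
    return np.concatenate(parts)


def filter_contigs(
    records: Iterable[SequenceRecord], min_length: int = 1500
) -> list[SequenceRecord]:
    """Keep contigs strictly longer than ``min_length`` bases."""
    return [r for r in records if len(r.seq) > min_length]


def pca_profiles(
    profiles: Sequence[KmerProfile],
    n_components: int = 3,
    standardize: bool = True,
) -> PcaCoordinates:
    """Deterministic PCA of word-frequency profiles.

    Features are centred and, by default, scaled to unit variance
    (zero-variance features are left unscaled) — word counts at different
    lengths differ in scale by orders of magnitude otherwise. A full SVD
    solver is used and each component's sign is fixed so that its
    largest-magnitude loading is positive, making coordinates reproducible
    and invariant to contig input order.
    """
    if len(profiles) < n_components + 1:
        raise ValueError(
            f"need at least {n_components + 1} profiles for {n_components} components"
        )
    X = np.vstack([p.vector for p in profiles])
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = X / sd
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    loadings = pca.components_.T.copy()
    for c in range(n_components):
        j = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1
            coords[:, c] *= -1
    return PcaCoordinates(
        contig_ids=[p.contig_id for p in profiles],
        coords=coords,
        explained_variance_ratio=np.nan_to_num(pca.explained_variance_ratio_),
        loadings=loadings,
    )


def cluster_separation(
    coords: PcaCoordinates | np.ndarray,
    labels: Sequence[str],
    seed: int = 0,
) -> dict[str, float]:
    """Quantify how well the PCA coordinates separate the labelled classes.

    Returns the silhouette score of the given labels and the adjusted Rand
    index between the labels and a k-means clustering at k = number of
    classes.
    """
    X = coords.coords if isinstance(coords, PcaCoordinates) else np.asarray(coords)
    labels = list(labels)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least two label classes")
    km = KMeans(n_clusters=len(classes), n_init=10, random_state=seed)
    predicted = km.fit_predict(X)
    return {
        "silhouette": float(silhouette_score(X, labels)),
        "ari": float(adjusted_rand_score(labels, predicted)),
    }
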