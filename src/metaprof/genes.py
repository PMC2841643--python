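"""Candidate ORF extraction from reads, GC binning, and greedy dereplication.

Candidate open reading frames are the maximal stop-free stretches in all six
translation frames (bacterial/archaeal code, table 11), allowing run-on at
read edges so partial genes on sequence fragments are kept. Translations are
dereplicated with a greedy longest-first incremental clusterer in the CD-HIT
style: each sequence joins the first earlier cluster representative it
matches at or above the identity threshold, else founds a new cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import edlib
from Bio.Seq import Seq

from .io import SequenceRecord
from .simulate import reverse_complement

__all__ = [
    "OrfCandidate",
    "six_frame_orfs",
    "gc_bin_reads",
    "SequenceCluster",
    "greedy_cluster",
    "global_identity",
]

FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class OrfCandidate:
    """A stop-free candidate ORF on one frame of a read.

    ``start``/``end`` are 0-based half-open on the read's forward strand and
    cover exactly the translated codons (never a stop codon). ``partial5`` /
    ``partial3`` flag run-on at the candidate's own 5'/3' end: true when the
    ORF abuts the frame's edge with no delimiting stop codon.
    """

    read_id: str
    frame: int
    start: int
    end: int
    partial5: bool
    partial3: bool
    protein: str

    def __post_init__(self) -> None:
        if self.frame not in FRAMES:
            raise ValueError(f"frame must be one of {FRAMES}")
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF interval length must be divisible by 3")
        if len(self.protein) != (self.end - self.start) // 3:
            raise ValueError("protein length must equal interval length / 3")
        if "*" in self.protein:
            raise ValueError("candidate protein must not contain a stop")


def _frame_orfs(
    read_id: str,
    seq: str,
    frame: int,
    read_len: int,
    min_aa: int,
    table: int,
) -> list[OrfCandidate]:
    """ORFs of one forward frame of ``seq`` (already reverse-complemented for
    minus frames), with coordinates mapped back to the forward strand."""
    offset = abs(frame) - 1
    n_codons = (len(seq) - offset) // 3
    if n_codons <= 0:
        return []
    coding = seq[offset : offset + 3 * n_codons]
    aa = str(Seq(coding).translate(table=table))
    out: list[OrfCandidate] = []
    pos = 0
    for i, chunk in enumerate(aa.split("*")):
        codon_start = pos
        pos += len(chunk) + 1  # skip the stop
        if len(chunk) < min_aa:
            continue
        partial5 = codon_start == 0
        partial3 = codon_start + len(chunk) == n_codons
        lo = offset + 3 * codon_start  # on the strand of `seq`
        hi = lo + 3 * len(chunk)
        if frame > 0:
            start, end = lo, hi
        else:
            start, end = read_len - hi, read_len - lo
        out.append(
            OrfCandidate(
                read_id=read_id,
                frame=frame,
                start=start,
                end=end,
                partial5=partial5,
                partial3=partial3,
                protein=chunk,
            )
        )
    return out


def six_frame_orfs(
    read: SequenceRecord,
    min_aa: int = 30,
    translation_table: int = 11,
    require_start: bool = False,
) -> list[OrfCandidate]:
    """Extract stop-bounded candidate ORFs from all six frames of a read.

    Candidates are maximal stop-free codon runs of at least ``min_aa``
    residues; they need not begin with a start codon (set ``require_start``
    to demand an internal ATG and trim to it). Runs abutting a read edge are
    flagged partial (run-on). Codons containing N translate to X unless the
    residue is determined regardless of the ambiguity (e.g. GGN -> G).
    """
    seq = read.seq.upper()
    if any(c not in "ACGTN" for c in set(seq)):
        bad = next(c for c in seq if c not in "ACGTN")
        raise ValueError(f"read {read.id!r}: non-ACGTN character {bad!r}")
    if len(seq) < 3 * min_aa:
        raise ValueError(
            f"read {read.id!r} shorter than 3*min_aa ({3 * min_aa}) bases"
        )
    rc = reverse_complement(seq)
    out: list[OrfCandidate] = []
    for frame in FRAMES:
        strand_seq = seq if frame > 0 else rc
        cands = _frame_orfs(read.id, strand_seq, frame, len(seq), min_aa,
                            translation_table)
        if require_start:
            cands = [c for c in (_trim_to_start(c, seq) for c in cands) if c]
        out.extend(cands)
    return out


def _trim_to_start(c: OrfCandidate, seq: str) -> OrfCandidate | None:
    i = c.protein.find("M")
    if i < 0 or len(c.protein) - i == 0:
        return None
    if c.frame > 0:
        start, end = c.start + 3 * i, c.end
    else:
        start, end = c.start, c.end - 3 * i
    return OrfCandidate(c.read_id, c.frame, start, end, False, c.partial3,
                        c.protein[i:])


def gc_fraction(seq: str) -> float:
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt


def gc_bin_reads(
    reads: Sequence[SequenceRecord], bin_size: int = 10000
) -> list[list[SequenceRecord]]:
    """Sort reads by GC fraction (ties by id) and chunk into bins.

    All bins have ``bin_size`` reads except possibly the last; downstream
    per-bin gene prediction then sees compositionally homogeneous input.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    ordered = sorted(reads, key=lambda r: (gc_fraction(r.seq), r.id))
    return [ordered[i : i + bin_size] for i in range(0, len(ordered), bin_size)]


# ---------------------------------------------------------------------------
# Greedy incremental clustering


@dataclass
class SequenceCluster:
    representative: SequenceRecord
    members: list[SequenceRecord]


def global_identity(a: str, b: str) -> float:
    """Identity of the global (end-to-end) alignment: matches / columns."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    res = edlib.align(a, b, mode="NW", task="path")
    cols = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            cols += int(num)
            num = ""
    return (cols - res["editDistance"]) / cols


def _kmer_set(seq: str, k: int = 5) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def greedy_cluster(
    seqs: Sequence[SequenceRecord],
    identity_threshold: float = 0.97,
    prescreen_k: int = 5,
) -> list[SequenceCluster]:
    """Longest-first greedy incremental clustering at a global identity cutoff.

    Sequences are processed longest first (ties by id); each joins the first
    existing representative whose global identity is at or above the
    threshold, else founds its own cluster — so every representative is the
    longest member of its cluster and the clusters partition the input. A
    shared-k-mer prescreen skips hopeless alignments.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must be in (0, 1]")
    ordered = sorted(seqs, key=lambda r: (-len(r.seq), r.id))
    clusters: list[SequenceCluster] = []
    kmer_cache: list[set[str]] = []
    for rec in ordered:
        rec_kmers = _kmer_set(rec.seq, prescreen_k)
        placed = False
        for cl, rep_kmers in zip(clusters, kmer_cache):
            rep = cl.representative
            if len(rec.seq) / len(rep.seq) < identity_threshold:
                continue  # too short to ever reach the threshold globally
            # heuristic word filter, only sound near-identity where shared
            # k-mer fraction stays far above the cutoff
            if identity_threshold >= 0.9 and rec_kmers and rep_kmers:
                shared = len(rec_kmers & rep_kmers) / len(rec_kmers)
                if shared < identity_threshold / 2:
                    continue
            if global_identity(rec.seq, rep.seq) >= identity_threshold:
                cl.members.append(rec)
                placed = True
                break
        if not placed:
            clusters.append(SequenceCluster(representative=rec, members=[rec]))
            kmer_cache.append(rec_kmers)
    return clusters
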