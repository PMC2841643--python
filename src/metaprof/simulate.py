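"""Synthetic shotgun communities with known ground truth.

Everything downstream of sequencing — binning, composition PCA, gene calling,
pathway scoring, marker screening — is exercised against communities generated
here, so no external data or database downloads are needed. Genomes are drawn
from simple compositional models (a GC setpoint or an order-k Markov chain),
reads mimic paired Sanger-style shotgun sequencing (~800 bp trimmed reads from
~2 kb inserts), and reference genomes at controlled divergence are produced by
a substitution-only mutation model so that expected nucleotide identity equals
1 - d exactly.

A small edit-distance fixture aligner (:func:`align_reads`) stands in for a
nucleotide search tool when a hit table is needed for a generated fixture;
real analyses consume externally produced tabular hit files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .io import AlignmentHit, PathwayDB, SequenceRecord

__all__ = [
    "GenomeModel",
    "ReadTruth",
    "simulate_genome",
    "mutate_genome",
    "reverse_complement",
    "shed_reads",
    "make_contigs",
    "align_reads",
    "PathwayStudySpec",
    "simulate_pathway_study",
    "simulate_marker_study",
]

BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class GenomeModel:
    """Compositional model for one community member.

    Either ``gc`` (an i.i.d. GC setpoint) or ``transitions`` (an order-``k``
    Markov transition model over A,C,G,T; shape ``(4,)*k + (4,)`` with rows
    summing to 1) must be given. ``pathway_content`` lists reaction IDs the
    genome truly encodes, consumed by the pathway-study generator.
    """

    genome_id: str
    length: int
    gc: float | None = None
    transitions: np.ndarray | None = None
    order: int = 3
    pathway_content: frozenset[str] = frozenset()
    taxon_label: str = ""

    def __post_init__(self) -> None:
        if (self.gc is None) == (self.transitions is None):
            raise ValueError("specify exactly one of gc or transitions")
        if self.gc is not None and not 0.0 < self.gc < 1.0:
            raise ValueError("gc setpoint must be in (0, 1)")
        if self.transitions is not None:
            t = np.asarray(self.transitions, dtype=float)
            if t.shape != (4,) * self.order + (4,):
                raise ValueError(
                    f"transition array must have shape {(4,) * self.order + (4,)}"
                )
            rows = t.reshape(-1, 4)
            if np.any(rows.sum(axis=1) == 0):
                raise ValueError("degenerate transition matrix: a row of zeros")
            if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("transition rows must sum to 1 within 1e-9")
            self.transitions = t


@dataclass(frozen=True)
class ReadTruth:
    """Provenance of one simulated read."""

    read_id: str
    source_genome: str
    start: int  # 0-based half-open interval on the source genome
    end: int
    strand: str  # '+' or '-'
    mate_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if not 0 <= self.start < self.end:
            raise ValueError("interval must be non-empty and nonnegative")


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_genome(model: GenomeModel, seed: int | np.random.Generator) -> SequenceRecord:
    """Draw a genome sequence from the model's composition; deterministic per seed."""
    rng = _rng(seed)
    n = model.length
    if model.gc is not None:
        p = np.array([(1 - model.gc) / 2, model.gc / 2, model.gc / 2, (1 - model.gc) / 2])
        idx = rng.choice(4, size=n, p=p)
    else:
        k = model.order
        t = model.transitions.reshape(-1, 4)
        cum = np.cumsum(t, axis=1)
        idx = np.empty(n, dtype=np.int64)
        idx[:k] = rng.integers(0, 4, size=k)
        # context index in base-4; rolled forward one base at a time
        ctx = 0
        for i in range(k):
            ctx = ctx * 4 + idx[i]
        mod = 4 ** (k - 1)
        u = rng.random(n)
        for i in range(k, n):
            idx[i] = np.searchsorted(cum[ctx], u[i], side="right")
            ctx = (ctx % mod) * 4 + idx[i]
    seq = BASES[idx].tobytes().decode()
    return SequenceRecord(id=model.genome_id, seq=seq, description=model.taxon_label)


def mutate_genome(
    genome: SequenceRecord, divergence: float, seed: int | np.random.Generator
) -> SequenceRecord:
    """Substitute each site independently with probability ``divergence``.

    Substitutions are uniform over the three alternative bases; no indels, so
    alignment-free identity to the parent is exactly ``1 - divergence`` in
    expectation.
    """
    if not 0.0 <= divergence <= 0.5:
        raise ValueError("divergence must be in [0, 0.5]")
    rng = _rng(seed)
    arr = np.frombuffer(genome.seq.encode(), dtype="S1").copy()
    hit = rng.random(arr.size) < divergence
    n_hit = int(hit.sum())
    if n_hit:
        base_idx = np.searchsorted(BASES, arr[hit])
        # uniform choice among the three other bases
        shift = rng.integers(1, 4, size=n_hit)
        arr[hit] = BASES[(base_idx + shift) % 4]
    return SequenceRecord(
        id=f"{genome.id}_d{divergence:g}",
        seq=arr.tobytes().decode(),
        description=f"mutated copy of {genome.id} at d={divergence:g}",
    )


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(arr.size) < error_rate
    n_hit = int(hit.sum())
    if n_hit:
        base_idx = np.searchsorted(BASES, arr[hit])
        shift = rng.integers(1, 4, size=n_hit)
        arr[hit] = BASES[(base_idx + shift) % 4]
    return arr.tobytes().decode()


def shed_reads(
    genome: SequenceRecord,
    n_pairs: int,
    read_len_mean: int = 800,
    read_len_sd: float = 60.0,
    insert_mean: int = 2000,
    insert_sd: float = 150.0,
    error_rate: float = 0.005,
    seed: int | np.random.Generator = 0,
) -> tuple[list[SequenceRecord], list[ReadTruth]]:
    """Shed mated read pairs from opposite strands of shared inserts.

    Each pair consists of a plus-strand read from the left end of a randomly
    placed insert and a minus-strand (reverse-complemented) read from its
    right end, emulating opposite-end paired Sanger sequencing. Per-base
    substitution errors are applied at ``error_rate``. A truth record is
    emitted for every read.
    """
    if insert_mean < 2 * read_len_mean:
        raise ValueError("insert_mean must be >= 2 * read_len_mean")
    L = len(genome.seq)
    if L < insert_mean:
        raise ValueError(
            f"genome {genome.id!r} ({L} bp) shorter than mean insert ({insert_mean})"
        )
    rng = _rng(seed)
    reads: list[SequenceRecord] = []
    truths: list[ReadTruth] = []
    for i in range(n_pairs):
        insert = int(np.clip(round(rng.normal(insert_mean, insert_sd)), 2 * 50, L))
        start = int(rng.integers(0, L - insert + 1))
        len_f = int(np.clip(round(rng.normal(read_len_mean, read_len_sd)), 50, insert))
        len_r = int(np.clip(round(rng.normal(read_len_mean, read_len_sd)), 50, insert))
        id_f = f"{genome.id}_p{i:05d}.f"
        id_r = f"{genome.id}_p{i:05d}.r"
        fwd = genome.seq[start : start + len_f]
        rev = reverse_complement(genome.seq[start + insert - len_r : start + insert])
        reads.append(SequenceRecord(id_f, _apply_errors(fwd, error_rate, rng)))
        reads.append(SequenceRecord(id_r, _apply_errors(rev, error_rate, rng)))
        truths.append(ReadTruth(id_f, genome.id, start, start + len_f, "+", id_r))
        truths.append(
            ReadTruth(id_r, genome.id, start + insert - len_r, start + insert, "-", id_f)
        )
    return reads, truths


def make_contigs(
    genome: SequenceRecord,
    n_contigs: int,
    length_mean: int = 3000,
    length_sd: float = 800.0,
    min_length: int = 200,
    seed: int | np.random.Generator = 0,
) -> list[SequenceRecord]:
    """Cut pseudo-assembly contigs out of a genome at random positions.

    Stands in for an assembler's output: contiguous error-free genome slices
    with a spread of lengths.
    """
    rng = _rng(seed)
    L = len(genome.seq)
    out: list[SequenceRecord] = []
    for i in range(n_contigs):
        clen = int(np.clip(round(rng.normal(length_mean, length_sd)), min_length, L))
        start = int(rng.integers(0, L - clen + 1))
        out.append(
            SequenceRecord(
                id=f"{genome.id}_c{i:04d}",
                seq=genome.seq[start : start + clen],
                description=f"contig from {genome.id} [{start}, {start + clen})",
            )
        )
    return out


# ---------------------------------------------------------------------------
# Fixture aligner
#
# Semi-global edit-distance alignment (query contained in subject) on both
# strands, scored with a blastn-flavoured scheme (match +1, mismatch/gap -2)
# and mapped to bit scores with the classic ungapped blastn parameters
# lambda = 1.28, K = 0.46. The E-value uses the search-space product
# |query| x total subject length. Good enough to rank and threshold hits in
# generated fixtures; not a BLAST replacement.

_LAMBDA = 1.28
_K = 0.46
_LN2 = math.log(2.0)


def _cigar_stats(cigar: str) -> tuple[int, int, int, int]:
    """Return (matches, mismatches, gap_columns, gap_opens) from an extended CIGAR."""
    matches = mismatches = gapcols = gapopens = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch == "=":
            matches += n
        elif ch == "X":
            mismatches += n
        elif ch in "ID":
            gapcols += n
            gapopens += 1
        else:  # plain 'M' never appears with edlib's extended CIGAR
            raise ValueError(f"unexpected CIGAR op {ch!r}")
    return matches, mismatches, gapcols, gapopens


def align_reads(
    reads: Sequence[SequenceRecord],
    references: Sequence[SequenceRecord],
    min_bitscore: float = 0.0,
) -> list[AlignmentHit]:
    """Align every read against every reference on both strands.

    Emits at most one hit per (read, reference): the better-scoring strand.
    Hits with bit score below ``min_bitscore`` are dropped.
    """
    total_ref = sum(len(r.seq) for r in references)
    hits: list[AlignmentHit] = []
    for read in reads:
        qlen = len(read.seq)
        rc = reverse_complement(read.seq)
        for ref in references:
            best = None
            for strand, q in (("+", read.seq), ("-", rc)):
                res = edlib.align(q, ref.seq, mode="HW", task="path")
                if res["editDistance"] < 0:
                    continue
                m, mm, gc_, go = _cigar_stats(res["cigar"])
                score = m - 2 * (mm + gc_)
                if best is None or score > best[0]:
                    best = (score, strand, res, m, mm, gc_, go)
            if best is None:
                continue
            score, strand, res, m, mm, gc_, go = best
            bit = (_LAMBDA * score - math.log(_K)) / _LN2
            if bit < min_bitscore:
                continue
            evalue = qlen * total_ref * math.pow(2.0, -bit) if bit < 1000 else 0.0
            s0, s1 = res["locations"][0]  # 0-based inclusive on the subject
            aln_len = m + mm + gc_
            if strand == "+":
                s_start, s_end = s0 + 1, s1 + 1
            else:
                s_start, s_end = s1 + 1, s0 + 1
            hits.append(
                AlignmentHit(
                    query_id=read.id,
                    subject_id=ref.id,
                    pct_identity=round(100.0 * m / aln_len, 2),
                    aln_len=aln_len,
                    mismatches=mm,
                    gap_opens=go,
                    q_start=1,
                    q_end=qlen,
                    s_start=s_start,
                    s_end=s_end,
                    evalue=evalue,
                    bitscore=round(bit, 1),
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Planted pathway studies


@dataclass
class PathwayStudySpec:
    """Shape of a synthetic pathway database and its planted signal.

    ``n_pathways`` ordinary pathways of ``reactions_per_pathway`` (inclusive
    range) reactions each; ``shared_fraction`` of a pathway's reactions are
    drawn from a common pool shared across pathways (promiscuous reactions,
    the ones the specificity weight discounts); ``n_duplicate_variants``
    pathways are exact duplicates of existing ones (alternate variants, which
    the weight must not penalize). Each reaction carries
    ``proteins_per_reaction`` reference proteins, a ``partial_ec_fraction``
    of reactions being linked only through partial EC numbers.
    """

    n_pathways: int = 50
    reactions_per_pathway: tuple[int, int] = (5, 9)
    shared_fraction: float = 0.2
    shared_pool_size: int = 30
    n_duplicate_variants: int = 5
    proteins_per_reaction: int = 2
    partial_ec_fraction: float = 0.1


def build_pathway_db(spec: PathwayStudySpec, rng: np.random.Generator) -> PathwayDB:
    """Generate a synthetic pathway database with the spec's overlap structure."""
    shared_pool = [f"RXN-S{i:03d}" for i in range(spec.shared_pool_size)]
    pathways: dict[str, list[str]] = {}
    serial = 0
    for p in range(spec.n_pathways):
        lo, hi = spec.reactions_per_pathway
        size = int(rng.integers(lo, hi + 1))
        n_shared = min(int(round(size * spec.shared_fraction)), len(shared_pool))
        rxns = list(rng.choice(shared_pool, size=n_shared, replace=False))
        for _ in range(size - n_shared):
            rxns.append(f"RXN-U{serial:04d}")
            serial += 1
        rng.shuffle(rxns)
        pathways[f"PWY-{p:03d}"] = rxns
    base_ids = list(pathways)
    for v in range(spec.n_duplicate_variants):
        src = base_ids[int(rng.integers(0, len(base_ids)))]
        pathways[f"{src}-VAR{v}"] = list(pathways[src])
    all_rxns = sorted({r for rxns in pathways.values() for r in rxns})
    reaction_proteins = {
        r: {f"{r}.P{k}" for k in range(spec.proteins_per_reaction)} for r in all_rxns
    }
    reaction_ec = {}
    for r in all_rxns:
        partial = bool(rng.random() < spec.partial_ec_fraction)
        ec = f"{rng.integers(1, 7)}.{rng.integers(1, 20)}.{rng.integers(1, 20)}"
        reaction_ec[r] = (ec + (".-" if partial else f".{rng.integers(1, 50)}"), partial)
    return PathwayDB(pathways, reaction_proteins, reaction_ec)


def simulate_pathway_study(
    spec: PathwayStudySpec,
    sample_content: Mapping[str, Iterable[str]] | None = None,
    n_samples: int = 5,
    sample_names: Sequence[str] | None = None,
    pathway_presence: float = 0.5,
    signal_bitscore: tuple[float, float] = (120.0, 30.0),
    noise_bitscore: tuple[float, float] = (35.0, 10.0),
    noise_queries_per_sample: int = 40,
    decoy_hit_prob: float = 0.5,
    matched_genomes: bool = True,
    seed: int | np.random.Generator = 0,
) -> tuple[PathwayDB, dict[str, list[AlignmentHit]], pd.DataFrame, dict[str, frozenset[str]]]:
    """Plant pathway content in samples and emit per-sample protein hit tables.

    Per sample, each pathway is either fully encoded (probability
    ``pathway_presence``) or partially encoded (a random subset of its
    reactions), giving a spread of true completeness values. Every encoded
    reaction receives ``1 + Poisson(1)`` unique query translations whose hits
    to that reaction's proteins draw bit scores from the signal distribution
    (a normal truncated above 55, so every signal hit clears the bit-50
    floor by construction). Noise comes in two documented flavours: decoy
    hits appended to signal queries (exercising the 20%-of-top window) and
    stand-alone spurious queries whose scores draw from the noise
    distribution (mostly below the bit-50 floor). Set
    ``noise_queries_per_sample=0`` and ``decoy_hit_prob=0`` for a noise-free
    study.

    With ``matched_genomes`` each sample also gets a noise-free
    ``ref_<sample>`` column with identical planted content and one query per
    encoded reaction, standing in for a sequenced reference genome whose
    pathway complement matches that community.

    Returns ``(db, hits per sample, truth table, encoded reaction sets)``;
    the truth table has columns sample, reaction, true_count.
    """
    rng = _rng(seed)
    db = build_pathway_db(spec, rng)
    all_rxns = sorted({r for rxns in db.pathways.values() for r in rxns})
    if sample_names is None:
        sample_names = [f"sample{s + 1}" for s in range(n_samples)]
    if sample_content is None:
        sample_content = {}
        base_ids = [p for p in db.pathways if "-VAR" not in p]
        for name in sample_names:
            encoded: set[str] = set()
            for pid in base_ids:
                rxns = db.pathways[pid]
                if rng.random() < pathway_presence:
                    encoded.update(rxns)
                else:
                    # partial pathway: keep a random strict subset (possibly empty)
                    k = int(rng.integers(0, len(rxns)))
                    encoded.update(rng.choice(rxns, size=k, replace=False))
            sample_content[name] = encoded
    content = {s: frozenset(r) for s, r in sample_content.items()}
    if matched_genomes:
        # one noise-free "reference genome" column per sample, carrying the
        # same planted reaction content as its matched community
        for s in list(content):
            content[f"ref_{s}"] = content[s]

    sig_mu, sig_sd = signal_bitscore
    noi_mu, noi_sd = noise_bitscore
    if sig_mu <= 0 or noi_mu <= 0:
        raise ValueError("bit-score distribution means must be positive")

    def _signal_bit() -> float:
        while True:
            b = rng.normal(sig_mu, sig_sd)
            if b > 55.0:
                return round(b, 1)

    def _noise_bit() -> float:
        return round(max(rng.normal(noi_mu, noi_sd), 1.0), 1)

    def _hit(query: str, protein: str, bit: float) -> AlignmentHit:
        return AlignmentHit(
            query_id=query,
            subject_id=protein,
            pct_identity=round(min(99.9, 30.0 + bit / 3.0), 1),
            aln_len=150,
            mismatches=10,
            gap_opens=0,
            q_start=1,
            q_end=150,
            s_start=1,
            s_end=150,
            evalue=math.pow(2.0, -bit) * 1e7,
            bitscore=bit,
        )

    sample_hits: dict[str, list[AlignmentHit]] = {}
    truth_rows: list[tuple[str, str, int]] = []
    for sample, encoded in content.items():
        is_genome = sample.startswith("ref_")
        hits: list[AlignmentHit] = []
        qserial = 0
        for rxn in sorted(encoded):
            prots = sorted(db.reaction_proteins[rxn])
            n_q = 1 if is_genome else 1 + int(rng.poisson(1.0))
            for _ in range(n_q):
                query = f"{sample}.t{qserial:05d}"
                qserial += 1
                for prot in prots:
                    hits.append(_hit(query, prot, _signal_bit()))
                if not is_genome and decoy_hit_prob and rng.random() < decoy_hit_prob:
                    decoy_rxn = all_rxns[int(rng.integers(0, len(all_rxns)))]
                    if decoy_rxn not in encoded:
                        decoy_prot = sorted(db.reaction_proteins[decoy_rxn])[0]
                        hits.append(_hit(query, decoy_prot, _noise_bit()))
            truth_rows.append((sample, rxn, n_q))
        for _ in range(0 if is_genome else noise_queries_per_sample):
            query = f"{sample}.noise{qserial:05d}"
            qserial += 1
            rxn = all_rxns[int(rng.integers(0, len(all_rxns)))]
            prot = sorted(db.reaction_proteins[rxn])[0]
            hits.append(_hit(query, prot, _noise_bit()))
        sample_hits[sample] = hits
    truth = pd.DataFrame(truth_rows, columns=["sample", "reaction", "true_count"])
    return db, sample_hits, truth, content


# ---------------------------------------------------------------------------
# Planted marker studies


def simulate_marker_study(
    registry: "pd.DataFrame | None" = None,
    samples: Sequence[str] = ("S1", "S2", "S3", "S4", "S5"),
    plants: Mapping[str, int] | None = None,
    n_false_positives: int = 0,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, list[AlignmentHit], pd.DataFrame, pd.DataFrame]:
    """Plant marker genes in samples; emit hit and reverse-annotation tables.

    ``plants`` maps gene symbol -> copies planted per sample (every sample
    gets the same planted truth, the noise differs). With
    ``n_false_positives > 0``, each sample also receives that many decoy
    environmental sequences that hit a marker query but whose reverse
    annotation points at a different family member (screen rule i), a
    different process (rule ii), or has insufficient query coverage.

    Returns ``(registry, hits, reverse annotations, truth)`` where truth has
    columns sample, gene_symbol, true_count.
    """
    rng = _rng(seed)
    if registry is None:
        registry = default_marker_registry()
    if plants is None:
        plants = {"sqr": 2, "dsrA": 1, "aclB": 1}
    reg = registry.set_index("gene_symbol")
    hits: list[AlignmentHit] = []
    rev_rows: list[tuple[str, str, str]] = []
    truth_rows: list[tuple[str, str, int]] = []
    symbols = list(registry["gene_symbol"])
    for sample in samples:
        serial = 0
        for symbol, n_copies in plants.items():
            qid = reg.loc[symbol, "query_id"]
            qlen = int(reg.loc[symbol, "query_len"])
            process = reg.loc[symbol, "process"]
            for _ in range(n_copies):
                env = f"{sample}.env{serial:04d}"
                serial += 1
                span = int(qlen * (0.7 + 0.25 * rng.random()))
                q_start = int(rng.integers(1, qlen - span + 2))
                bit = round(150.0 + 50.0 * rng.random(), 1)
                hits.append(
                    AlignmentHit(qid, env, 85.0, span, 5, 0, q_start,
                                 q_start + span - 1, 1, span * 3, 1e-50, bit)
                )
                rev_rows.append((env, symbol, process))
            truth_rows.append((sample, symbol, n_copies))
        for _ in range(n_false_positives):
            env = f"{sample}.env{serial:04d}"
            serial += 1
            symbol = symbols[int(rng.integers(0, len(symbols)))]
            qid = reg.loc[symbol, "query_id"]
            qlen = int(reg.loc[symbol, "query_len"])
            kind = int(rng.integers(0, 3))
            family = reg.loc[symbol, "family"]
            siblings = [s for s in symbols
                        if s != symbol and reg.loc[s, "family"] == family]
            if kind == 0 and not siblings:
                kind = 1  # no same-family decoy possible; use a rule-ii decoy
            if kind == 0:  # wrong family member (rule i)
                span = int(qlen * 0.8)
                rev_rows.append((env, siblings[0], reg.loc[symbol, "process"]))
            elif kind == 1:  # homologous region, different function (rule ii)
                span = int(qlen * 0.8)
                rev_rows.append((env, f"{symbol}-homolog", "unrelated housekeeping"))
            else:  # too short relative to the query
                span = max(10, int(qlen * 0.15))
                rev_rows.append((env, symbol, reg.loc[symbol, "process"]))
            hits.append(
                AlignmentHit(qid, env, 60.0, span, 20, 1, 1, span, 1, span * 3,
                             1e-20, 80.0)
            )
    rev = pd.DataFrame(rev_rows, columns=["env_id", "label_symbol", "label_process"])
    truth = pd.DataFrame(truth_rows, columns=["sample", "gene_symbol", "true_count"])
    return registry, hits, rev, truth


def default_marker_registry() -> pd.DataFrame:
    """Marker-gene query registry used by the synthetic marker studies.

    Symbols follow the field's usual markers for chemolithotrophic energy
    metabolism: aclB (rTCA CO2 fixation), sqr (sulfide oxidation), doxB and
    soxM (terminal oxidases), sreA (sulfur reduction), dsrA (dissimilatory
    sulfite reduction), arsB and merA (As/Hg detoxification).
    """
    rows = [
        ("aclB", "Q-aclB", 397, "CO2 fixation (rTCA)", "ATP-citrate lyase"),
        ("sqr", "Q-sqr", 430, "sulfide oxidation", "sulfide:quinone oxidoreductase"),
        ("doxB", "Q-doxB", 587, "terminal oxidation", "heme Cu oxidase"),
        ("soxM", "Q-soxM", 602, "terminal oxidation", "heme Cu oxidase"),
        ("sreA", "Q-sreA", 712, "sulfur reduction", "Mo-pterin oxidoreductase"),
        ("dsrA", "Q-dsrA", 421, "sulfite reduction", "dissimilatory sulfite reductase"),
        ("arsB", "Q-arsB", 429, "arsenite efflux", "arsenite transporter"),
        ("merA", "Q-merA", 561, "mercuric reduction", "mercuric reductase"),
    ]
    return pd.DataFrame(
        rows, columns=["gene_symbol", "query_id", "query_len", "process", "family"]
    )
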