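"""End-to-end orchestration: community -> binning -> composition -> genes ->
pathway scoring -> marker screen, from one declarative config.

A run is fully determined by its seed: one global seed fans out to per-stage
child seeds through :func:`numpy.random.SeedSequence`, so any stage can be
re-run in isolation with the same stream. Every run writes a report bundle
(TSV tables, Newick dendrograms) plus a provenance manifest recording the
config hash, package version, and a per-stage log.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import SequenceRecord, write_blast_tabular, write_fasta, write_pathway_db
from .simulate import (
    GenomeModel,
    PathwayStudySpec,
    align_reads,
    make_contigs,
    mutate_genome,
    shed_reads,
    simulate_genome,
    simulate_marker_study,
    simulate_pathway_study,
)
from . import binning, composition, genes, markers, pathways

__all__ = ["GenomeSpec", "SampleSpec", "Thresholds", "RunConfig", "run_profile"]

logger = logging.getLogger(__name__)

_STAGES = ("community", "binning", "composition", "genes", "pathways", "markers")


@dataclass
class GenomeSpec:
    genome_id: str
    gc: float
    length: int = 40000
    taxon_label: str = ""


@dataclass
class SampleSpec:
    sample_id: str
    n_pairs: int
    proportions: list[float] | None = None  # per community genome; uniform if None


@dataclass
class Thresholds:
    e_value: float = 1e-10
    band_edges: tuple[float, ...] = binning.DEFAULT_EDGES
    min_contig_length: int = 1500
    word_length: int = 5
    bit_floor: float = 50.0
    window: float = 0.20
    cluster_identity: float = 0.97
    min_aa: int = 30
    marker_min_coverage: float = 0.3

    def validate(self) -> None:
        if not 0 < self.e_value <= 1:
            raise ValueError("e_value must be in (0, 1]")
        if not 0 < self.window < 1:
            raise ValueError("window must be in (0, 1)")
        if not 0 < self.cluster_identity <= 1:
            raise ValueError("cluster_identity must be in (0, 1]")
        if not 0 <= self.marker_min_coverage <= 1:
            raise ValueError("marker_min_coverage must be in [0, 1]")
        if self.min_aa < 1 or self.min_contig_length < 0 or self.word_length < 1:
            raise ValueError("length thresholds must be positive")


@dataclass
class RunConfig:
    seed: int
    out_dir: str
    genomes: list[GenomeSpec]
    samples: list[SampleSpec]
    reference_divergence: float = 0.05
    read_len_mean: int = 800
    read_len_sd: float = 60.0
    insert_mean: int = 2000
    error_rate: float = 0.005
    contigs_per_genome: int = 30
    orf_reads_per_sample: int = 40
    thresholds: Thresholds = field(default_factory=Thresholds)
    pathway_study: PathwayStudySpec = field(default_factory=PathwayStudySpec)
    marker_plants: dict[str, int] = field(default_factory=lambda: {"sqr": 2, "dsrA": 1})
    marker_false_positives: int = 3

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["genomes"] = [GenomeSpec(**g) for g in d["genomes"]]
        d["samples"] = [SampleSpec(**s) for s in d["samples"]]
        if "thresholds" in d:
            d["thresholds"] = Thresholds(**d["thresholds"])
        if "pathway_study" in d:
            d["pathway_study"] = PathwayStudySpec(**d["pathway_study"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not self.genomes or not self.samples:
            raise ValueError("need at least one genome and one sample")
        for s in self.samples:
            if s.n_pairs <= 0:
                raise ValueError(f"sample {s.sample_id!r} has no reads configured")
            if s.proportions is not None:
                if len(s.proportions) != len(self.genomes):
                    raise ValueError(
                        f"sample {s.sample_id!r}: proportions do not match genomes"
                    )
                if abs(sum(s.proportions) - 1.0) > 1e-6 or min(s.proportions) < 0:
                    raise ValueError(
                        f"sample {s.sample_id!r}: proportions must be a distribution"
                    )
        if not 0 <= self.reference_divergence <= 0.5:
            raise ValueError("reference_divergence must be in [0, 0.5]")
        self.thresholds.validate()

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    idx = _STAGES.index(stage)
    return np.random.default_rng(np.random.SeedSequence([seed, idx]))


def run_profile(config: RunConfig) -> dict:
    """Run the full profiling pipeline; returns the report bundle as a dict
    and writes its artifacts under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "version": __version__,
        "seed": config.seed,
        "stages": [],
    }
    bundle: dict = {"manifest": manifest}

    def _log_stage(name: str, t0: float, **info) -> None:
        entry = {"stage": name, "seconds": round(time.time() - t0, 2), **info}
        manifest["stages"].append(entry)
        logger.info("stage %s done in %.1fs", name, entry["seconds"])

    try:
        # ---- community -------------------------------------------------
        t0 = time.time()
        rng = _stage_rng(config.seed, "community")
        genomes = [
            simulate_genome(
                GenomeModel(g.genome_id, g.length, gc=g.gc, taxon_label=g.taxon_label),
                rng,
            )
            for g in config.genomes
        ]
        references = [
            mutate_genome(g, config.reference_divergence, rng) for g in genomes
        ]
        sample_reads: dict[str, list[SequenceRecord]] = {}
        truths = []
        for s in config.samples:
            props = s.proportions or [1 / len(genomes)] * len(genomes)
            reads: list[SequenceRecord] = []
            for g, p in zip(genomes, props):
                n = int(round(s.n_pairs * p))
                if n == 0:
                    continue
                r, t = shed_reads(
                    g,
                    n,
                    read_len_mean=config.read_len_mean,
                    read_len_sd=config.read_len_sd,
                    insert_mean=config.insert_mean,
                    error_rate=config.error_rate,
                    seed=rng,
                )
                # read ids are made sample-unique downstream of shedding
                reads.extend(
                    SequenceRecord(f"{s.sample_id}.{x.id}", x.seq) for x in r
                )
                truths.extend(
                    (f"{s.sample_id}.{x.read_id}", x.source_genome, x.start, x.end,
                     x.strand)
                    for x in t
                )
            sample_reads[s.sample_id] = reads
        contigs = []
        for g in genomes:
            contigs.extend(
                make_contigs(g, config.contigs_per_genome, seed=rng)
            )
        write_fasta(references, out / "references.fa")
        pd.DataFrame(
            truths, columns=["read_id", "genome", "start", "end", "strand"]
        ).to_csv(out / "read_truth.tsv", sep="\t", index=False)
        _log_stage("community", t0, reads=sum(map(len, sample_reads.values())),
                   contigs=len(contigs))

        # ---- binning ---------------------------------------------------
        t0 = time.time()
        all_reads = [r for reads in sample_reads.values() for r in reads]
        hits = align_reads(all_reads, references, min_bitscore=20.0)
        write_blast_tabular(hits, out / "read_hits.tsv")
        bins = binning.best_hit_bin(
            hits, config.thresholds.e_value, config.thresholds.band_edges
        )
        summary = binning.bin_summary(bins, total_reads=len(all_reads))
        summary.to_csv(out / "bin_summary.tsv", sep="\t", index=False)
        profiles = {
            ref.id: binning.recruit(hits, ref.id, len(ref.seq))
            for ref in references
        }
        with open(out / "recruitment.tsv", "w") as fh:
            fh.write("subject_id\tposition\tpct_identity\tread_id\tcoverage_x\n")
            for ref_id, prof in profiles.items():
                for pos, ident, read_id in prof.points:
                    fh.write(
                        f"{ref_id}\t{pos:.1f}\t{ident}\t{read_id}\t"
                        f"{prof.coverage_x:.3f}\n"
                    )
        bundle["bin_summary"] = summary
        bundle["recruitment"] = profiles
        _log_stage("binning", t0, hits=len(hits),
                   assigned=sum(b.assigned for b in bins.values()))

        # ---- composition ----------------------------------------------
        t0 = time.time()
        kept = composition.filter_contigs(contigs, config.thresholds.min_contig_length)
        profs = [
            composition.word_frequency_profile(c, L=config.thresholds.word_length)
            for c in kept
        ]
        coords = composition.pca_profiles(profs, n_components=3)
        labels = [c.id.rsplit("_c", 1)[0] for c in kept]
        separation = composition.cluster_separation(coords, labels, seed=config.seed)
        df = pd.DataFrame(coords.coords, columns=["PC1", "PC2", "PC3"])
        df.insert(0, "contig_id", coords.contig_ids)
        df.insert(1, "source", labels)
        df.to_csv(out / "pca_coords.tsv", sep="\t", index=False)
        bundle["pca"] = coords
        bundle["separation"] = separation
        _log_stage("composition", t0, contigs=len(kept), **separation)

        # ---- gene calling ----------------------------------------------
        t0 = time.time()
        orf_proteins: list[SequenceRecord] = []
        for s in config.samples:
            for read in sample_reads[s.sample_id][: config.orf_reads_per_sample]:
                for i, orf in enumerate(
                    genes.six_frame_orfs(read, min_aa=config.thresholds.min_aa)
                ):
                    orf_proteins.append(
                        SequenceRecord(f"{read.id}.orf{i}", orf.protein)
                    )
        clusters = genes.greedy_cluster(
            orf_proteins, config.thresholds.cluster_identity
        )
        with open(out / "orf_clusters.tsv", "w") as fh:
            fh.write("representative\tsize\tmembers\n")
            for cl in clusters:
                fh.write(
                    f"{cl.representative.id}\t{len(cl.members)}\t"
                    f"{','.join(m.id for m in cl.members)}\n"
                )
        _log_stage("genes", t0, orfs=len(orf_proteins), clusters=len(clusters))

        # ---- pathway scoring -------------------------------------------
        t0 = time.time()
        rng_p = _stage_rng(config.seed, "pathways")
        db, sample_hits, truth, content = simulate_pathway_study(
            config.pathway_study,
            sample_names=[s.sample_id for s in config.samples],
            seed=rng_p,
        )
        write_pathway_db(db, out / "pathway_db.tsv")
        filtered = {
            sample: pathways.filter_sample_hits(
                hlist, db, config.thresholds.bit_floor, config.thresholds.window
            )
            for sample, hlist in sample_hits.items()
        }
        counts = pathways.reaction_hit_counts(filtered, db)
        comp = pathways.completeness_matrix(counts, db)
        act = pathways.activity_matrix(counts, db)
        comp.to_csv(out / "completeness.tsv", sep="\t")
        act.to_csv(out / "activity.tsv", sep="\t")
        key = pathways.select_key_pathways(comp, db)
        (out / "key_pathways.txt").write_text("\n".join(key) + "\n")
        clustering = pathways.cluster_score_matrix(comp.loc[key], "completeness")
        (out / "pathway_dendrogram.nwk").write_text(clustering.row_newick() + "\n")
        (out / "sample_dendrogram.nwk").write_text(clustering.col_newick() + "\n")
        bundle.update(
            pathway_db=db, completeness=comp, activity=act, key_pathways=key,
            clustering=clustering, pathway_truth=truth, planted_content=content,
        )
        _log_stage("pathways", t0, pathways=len(db.pathways), key=len(key))

        # ---- marker screen ---------------------------------------------
        t0 = time.time()
        rng_m = _stage_rng(config.seed, "markers")
        registry_df, mhits, rev, mtruth = simulate_marker_study(
            samples=[s.sample_id for s in config.samples],
            plants=config.marker_plants,
            n_false_positives=config.marker_false_positives,
            seed=rng_m,
        )
        registry = markers.load_registry(registry_df)
        by_symbol = {q.gene_symbol: q for q in registry.values()}
        candidates = markers.screen_markers(mhits, registry, config.thresholds.e_value)
        rev_map = {
            r.env_id: (r.label_symbol, r.label_process)
            for r in rev.itertuples(index=False)
        }
        calls = markers.validate_all(
            candidates, rev_map, by_symbol,
            min_coverage=config.thresholds.marker_min_coverage,
        )
        sample_of = {env: env.split(".")[0] for env in rev_map}
        table = markers.marker_count_table(
            calls, sample_of, by_symbol, [s.sample_id for s in config.samples]
        )
        table.to_csv(out / "markers.tsv", sep="\t")
        bundle.update(marker_table=table, marker_calls=calls, marker_truth=mtruth)
        _log_stage("markers", t0,
                   confirmed=sum(c.status == "confirmed" for c in calls))
    except Exception as exc:
        stage = _STAGES[len(manifest["stages"])]
        manifest["error"] = {"stage": stage, "message": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return bundle
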