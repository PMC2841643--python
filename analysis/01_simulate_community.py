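#!/usr/bin/env python
"""Simulate the study community: four genomes spanning GC 0.30-0.70,
references at 5% divergence, paired ~800 bp shotgun reads, and
pseudo-assembly contigs.

Writes reads.fa, references.fa, contigs.fa and read_truth.tsv under
results/community/ — the inputs every later analysis step consumes.
"""

import argparse
from pathlib import Path

import pandas as pd

from metaprof.io import write_fasta
from metaprof.simulate import (
    GenomeModel,
    make_contigs,
    mutate_genome,
    shed_reads,
    simulate_genome,
)

GC_SETPOINTS = {"G1": 0.30, "G2": 0.45, "G3": 0.60, "G4": 0.70}
GENOME_LENGTH = 40_000
PAIRS_PER_GENOME = 500
DIVERGENCE = 0.05


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/community"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    genomes, references, reads, truths, contigs = [], [], [], [], []
    for i, (gid, gc) in enumerate(GC_SETPOINTS.items()):
        g = simulate_genome(GenomeModel(gid, GENOME_LENGTH, gc=gc), args.seed + i)
        genomes.append(g)
        references.append(mutate_genome(g, DIVERGENCE, args.seed + 100 + i))
        r, t = shed_reads(g, PAIRS_PER_GENOME, error_rate=0.005,
                          seed=args.seed + 200 + i)
        reads.extend(r)
        truths.extend(t)
        contigs.extend(
            make_contigs(g, 50, length_mean=3000, length_sd=700,
                         min_length=1600, seed=args.seed + 300 + i)
        )

    write_fasta(genomes, args.out / "genomes.fa")
    write_fasta(references, args.out / "references.fa")
    write_fasta(reads, args.out / "reads.fa")
    write_fasta(contigs, args.out / "contigs.fa")
    pd.DataFrame(
        [(t.read_id, t.source_genome, t.start, t.end, t.strand, t.mate_id)
         for t in truths],
        columns=["read_id", "genome", "start", "end", "strand", "mate_id"],
    ).to_csv(args.out / "read_truth.tsv", sep="\t", index=False)

    print(f"community: {len(genomes)} genomes x {GENOME_LENGTH/1000:.0f} kb, "
          f"{len(reads)} reads ({PAIRS_PER_GENOME} pairs/genome), "
          f"{len(contigs)} contigs, references at d={DIVERGENCE}")
    print(f"wrote {args.out}/")


if __name__ == "__main__":
    main()
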