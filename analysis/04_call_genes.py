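#!/usr/bin/env python
"""Extract candidate ORFs from community reads and dereplicate the
translations.

Stop-bounded six-frame extraction (run-on allowed at read edges) over a
subset of reads, GC-binning of the read set, and greedy longest-first
clustering of the candidate proteins at 97% global identity. Writes
orfs.faa and orf_clusters.tsv under results/genes/.
"""

import argparse
from pathlib import Path

from metaprof.genes import gc_bin_reads, gc_fraction, greedy_cluster, six_frame_orfs
from metaprof.io import SequenceRecord, read_fasta, write_fasta


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--community", type=Path, default=Path("results/community"))
    ap.add_argument("--out", type=Path, default=Path("results/genes"))
    ap.add_argument("--n-reads", type=int, default=200)
    ap.add_argument("--min-aa", type=int, default=30)
    ap.add_argument("--identity", type=float, default=0.97)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    reads = read_fasta(args.community / "reads.fa")[: args.n_reads]
    gc_bins = gc_bin_reads(reads, bin_size=100)
    print(f"{len(reads)} reads in {len(gc_bins)} GC bins "
          f"(GC {gc_fraction(gc_bins[0][0].seq):.2f} to "
          f"{gc_fraction(gc_bins[-1][-1].seq):.2f})")

    proteins = []
    for read in reads:
        for i, orf in enumerate(six_frame_orfs(read, min_aa=args.min_aa)):
            flags = ("5'" if orf.partial5 else "") + ("3'" if orf.partial3 else "")
            proteins.append(
                SequenceRecord(
                    f"{read.id}.orf{i}",
                    orf.protein,
                    description=f"frame {orf.frame:+d} run-on:{flags or 'none'}",
                )
            )
    write_fasta(proteins, args.out / "orfs.faa")

    clusters = greedy_cluster(proteins, args.identity)
    with open(args.out / "orf_clusters.tsv", "w") as fh:
        fh.write("representative\tsize\tmembers\n")
        for cl in clusters:
            fh.write(f"{cl.representative.id}\t{len(cl.members)}\t"
                     f"{','.join(m.id for m in cl.members)}\n")

    sizes = sorted((len(c.members) for c in clusters), reverse=True)
    print(f"{len(proteins)} candidate ORFs (>= {args.min_aa} aa) -> "
          f"{len(clusters)} clusters at {args.identity:.0%} identity; "
          f"largest cluster {sizes[0]}")


if __name__ == "__main__":
    main()
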