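"""Best-hit taxonomic binning, identity banding, and fragment recruitment.

Reads are assigned to the closest reference genome by their single best
nucleotide hit (highest bit score among hits with E-value below threshold),
then categorized into percent-identity bands spanning 47-100%. Fragment
recruitment collects every hit against one reference as (position, identity)
points and summarizes mean fold coverage as aligned bases over reference
length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import AlignmentHit

__all__ = [
    "UNASSIGNED",
    "TaxonBin",
    "RecruitmentProfile",
    "default_band_edges",
    "identity_band",
    "best_hit_bin",
    "recruit",
    "bin_summary",
]

UNASSIGNED = "Unassigned"

DEFAULT_EDGES = (47.0, 50.0, 60.0, 70.0, 80.0, 90.0, 95.0, 100.0)
BELOW_RANGE = "<47"


def default_band_edges() -> tuple[float, ...]:
    return DEFAULT_EDGES


@dataclass(frozen=True)
class TaxonBin:
    """One read's best-hit assignment. ``subject_id`` is UNASSIGNED when no
    hit survived the E-value threshold."""

    read_id: str
    subject_id: str
    pct_identity: float | None = None
    band_label: str | None = None
    evalue: float | None = None
    bitscore: float | None = None

    @property
    def assigned(self) -> bool:
        return self.subject_id != UNASSIGNED


@dataclass
class RecruitmentProfile:
    """All hits recruited to one reference genome."""

    subject_id: str
    subject_length: int
    points: list[tuple[float, float, str]]  # (subject midpoint, % identity, read)
    coverage_x: float


def identity_band(
    pct_identity: float, edges: Sequence[float] = DEFAULT_EDGES
) -> str:
    """Map a percent identity to its half-open band ``[e_k, e_{k+1})``.

    The top band is closed at 100; identities below the first edge map to a
    below-range label.
    """
    edges = tuple(edges)
    if len(edges) < 2 or any(a >= b for a, b in zip(edges, edges[1:])):
        raise ValueError("band edges must be strictly increasing")
    if not 0.0 <= pct_identity <= 100.0:
        raise ValueError(f"pct_identity {pct_identity} outside [0, 100]")
    if pct_identity < edges[0]:
        return f"<{edges[0]:g}"
    for lo, hi in zip(edges, edges[1:]):
        if lo <= pct_identity < hi:
            return f"{lo:g}-{hi:g}"
    # closure: the maximum edge itself belongs to the top band
    return f"{edges[-2]:g}-{edges[-1]:g}"


def best_hit_bin(
    hits: Iterable[AlignmentHit],
    e_threshold: float = 1e-10,
    edges: Sequence[float] = DEFAULT_EDGES,
) -> dict[str, TaxonBin]:
    """Assign each read to the subject of its best surviving hit.

    Hits with ``evalue >= e_threshold`` are discarded; among survivors the
    highest bit score wins, with ties broken by lower E-value then
    lexicographic subject id (the assignment is deterministic). Reads whose
    hits all fail the threshold are returned labelled UNASSIGNED.
    """
    if e_threshold <= 0:
        raise ValueError("e_threshold must be > 0")
    by_read: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_read.setdefault(h.query_id, []).append(h)
    bins: dict[str, TaxonBin] = {}
    for read_id, read_hits in by_read.items():
        surviving = [h for h in read_hits if h.evalue < e_threshold]
        if not surviving:
            bins[read_id] = TaxonBin(read_id, UNASSIGNED)
            continue
        best = min(surviving, key=lambda h: (-h.bitscore, h.evalue, h.subject_id))
        band = identity_band(best.pct_identity, edges)
        bins[read_id] = TaxonBin(
            read_id, best.subject_id, best.pct_identity, band, best.evalue,
            best.bitscore,
        )
    return bins


def recruit(
    hits: Iterable[AlignmentHit], subject_id: str, subject_length: int
) -> RecruitmentProfile:
    """Collect hits against one reference into a recruitment profile.

    Each hit contributes one point at the midpoint of its subject interval;
    ``coverage_x`` is the total aligned length divided by the reference
    length (mean fold coverage).
    """
    if subject_length <= 0:
        raise ValueError("subject_length must be > 0")
    points: list[tuple[float, float, str]] = []
    aligned = 0
    for h in hits:
        if h.subject_id != subject_id:
            continue
        if h.s_hi > subject_length:
            raise ValueError(
                f"hit {h.query_id!r} ends at {h.s_hi}, beyond reference "
                f"length {subject_length}"
            )
        points.append(((h.s_lo + h.s_hi) / 2.0, h.pct_identity, h.query_id))
        aligned += h.aln_len
    return RecruitmentProfile(
        subject_id=subject_id,
        subject_length=subject_length,
        points=points,
        coverage_x=aligned / subject_length,
    )


def bin_summary(
    bins: Mapping[str, TaxonBin], total_reads: int
) -> pd.DataFrame:
    """Tabulate per-reference read counts, fractions, and band breakdowns.

    Reads absent from ``bins`` (never aligned at all) count as UNASSIGNED.
    Because the denominator question is genuinely ambiguous for community
    percentages, two fractions are reported: ``fraction_total`` over all
    reads and ``fraction_binned`` over assigned reads only.
    """
    if total_reads < len(bins):
        raise ValueError("total_reads smaller than number of binned reads")
    rows: dict[str, dict] = {}
    n_assigned = 0
    for b in bins.values():
        row = rows.setdefault(b.subject_id, {"read_count": 0, "bands": {}})
        row["read_count"] += 1
        if b.assigned:
            n_assigned += 1
            row["bands"][b.band_label] = row["bands"].get(b.band_label, 0) + 1
    n_unseen = total_reads - len(bins)
    if n_unseen or UNASSIGNED in rows:
        row = rows.setdefault(UNASSIGNED, {"read_count": 0, "bands": {}})
        row["read_count"] += n_unseen
    out_rows = []
    for subject, row in sorted(rows.items()):
        count = row["read_count"]
        band_frac = {
            f"band_{band}": n / count for band, n in sorted(row["bands"].items())
        }
        out_rows.append(
            {
                "subject_id": subject,
                "read_count": count,
                "fraction_total": count / total_reads,
                "fraction_binned": (
                    count / n_assigned if subject != UNASSIGNED and n_assigned else 0.0
                ),
                **band_frac,
            }
        )
    df = pd.DataFrame(out_rows).fillna(0.0)
    return df
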