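"""File formats: FASTA, 12-column BLAST tabular hit tables, and the pathway-DB TSV.

All other modules consume the three carrier types defined here.
Internal coordinates are 0-based half-open; the BLAST tabular dialect keeps its
native 1-based inclusive convention (with ``s_start > s_end`` marking a
minus-strand subject hit) and is converted by consumers, not here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SequenceRecord",
    "AlignmentHit",
    "PathwayDB",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_blast_tabular",
    "write_blast_tabular",
    "read_pathway_db",
    "write_pathway_db",
]

_NUC_RE = re.compile(r"^[ACGTN]+$")
# the 20 standard residues plus ambiguity codes B/J/X/Z, U/O, and the stop '*'
_PROT_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYBJXZUO*]+$")


class FormatError(ValueError):
    """Raised for malformed input files, with the offending location."""


@dataclass(frozen=True)
class SequenceRecord:
    """One named nucleotide or protein sequence."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record must have a non-empty id")
        if not self.seq:
            raise ValueError(f"sequence record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


def _validate_alphabet(rec: SequenceRecord, mode: str) -> None:
    pattern = _NUC_RE if mode == "nucleotide" else _PROT_RE
    if not pattern.match(rec.seq):
        bad = next(c for c in rec.seq if not pattern.match(c))
        raise FormatError(
            f"record {rec.id!r}: illegal character {bad!r} for {mode} mode"
        )


@dataclass(frozen=True)
class AlignmentHit:
    """One row of a 12-column tabular hit table (``outfmt 6`` dialect).

    Coordinates are 1-based inclusive as in the file; ``s_start > s_end``
    means the hit is on the subject's minus strand.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity {self.pct_identity} outside [0, 100]")
        if self.q_start > self.q_end:
            raise ValueError("q_start must be <= q_end")
        if self.aln_len < 1:
            raise ValueError("alignment length must be >= 1")
        if self.evalue < 0:
            raise ValueError("evalue must be nonnegative")
        if self.bitscore < 0:
            raise ValueError("bitscore must be nonnegative")

    @property
    def s_lo(self) -> int:
        """Leftmost subject coordinate (1-based), strand-independent."""
        return min(self.s_start, self.s_end)

    @property
    def s_hi(self) -> int:
        return max(self.s_start, self.s_end)

    @property
    def minus_strand(self) -> bool:
        return self.s_start > self.s_end


class PathwayDB:
    """Pathways as ordered reaction sets, plus reaction -> protein / EC links.

    Caches, per reaction *i*, the three counts the specificity weight needs:

    * ``n_pw``     — number of distinct pathways containing *i*
    * ``n_totrxn`` — total number of reactions (with multiplicity across
      pathways) in all pathways containing *i*
    * ``n_unirxn`` — number of unique reactions in all pathways containing *i*
    """

    def __init__(
        self,
        pathways: Mapping[str, Iterable[str]],
        reaction_proteins: Mapping[str, Iterable[str]] | None = None,
        reaction_ec: Mapping[str, tuple[str, bool]] | None = None,
    ) -> None:
        self.pathways: dict[str, tuple[str, ...]] = {}
        for pid, rxns in pathways.items():
            rxns = tuple(dict.fromkeys(rxns))  # ordered, deduplicated
            if not rxns:
                raise FormatError(f"pathway {pid!r} has zero reactions")
            self.pathways[pid] = rxns
        self.reaction_proteins: dict[str, frozenset[str]] = {
            r: frozenset(ps) for r, ps in (reaction_proteins or {}).items()
        }
        # reaction_ec maps reaction -> (EC string, is_partial)
        self.reaction_ec: dict[str, tuple[str, bool]] = dict(reaction_ec or {})
        declared = set(self.reaction_proteins) | set(self.reaction_ec)
        if declared:
            for pid, rxns in self.pathways.items():
                for r in rxns:
                    if r not in declared:
                        raise FormatError(
                            f"pathway {pid!r} references undeclared reaction {r!r}"
                        )
        self._protein_reactions: dict[str, set[str]] | None = None

    # -- derived views ----------------------------------------------------

    @property
    def reactions(self) -> set[str]:
        out: set[str] = set(self.reaction_proteins) | set(self.reaction_ec)
        for rxns in self.pathways.values():
            out.update(rxns)
        return out

    def pathways_with_reaction(self, reaction_id: str) -> list[str]:
        return [p for p, rxns in self.pathways.items() if reaction_id in rxns]

    def reaction_counts(self, reaction_id: str) -> tuple[int, int, int]:
        """Return ``(n_pw, n_totrxn, n_unirxn)`` for one reaction."""
        containing = self.pathways_with_reaction(reaction_id)
        if not containing:
            raise KeyError(f"reaction {reaction_id!r} occurs in no pathway")
        n_pw = len(containing)
        n_totrxn = sum(len(self.pathways[p]) for p in containing)
        union: set[str] = set()
        for p in containing:
            union.update(self.pathways[p])
        return n_pw, n_totrxn, len(union)

    def protein_reactions(self, protein_id: str) -> set[str]:
        """All reactions a protein is associated with (any association kind)."""
        if self._protein_reactions is None:
            idx: dict[str, set[str]] = {}
            for r, prots in self.reaction_proteins.items():
                for p in prots:
                    idx.setdefault(p, set()).add(r)
            self._protein_reactions = idx
        return self._protein_reactions.get(protein_id, set())

    def protein_is_partial_only(self, protein_id: str) -> bool:
        """True if every reaction this protein maps to is a partial-EC link."""
        rxns = self.protein_reactions(protein_id)
        if not rxns:
            raise KeyError(f"protein {protein_id!r} not in database")
        return all(self.reaction_ec.get(r, ("", False))[1] for r in rxns)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, mode: str = "nucleotide") -> list[SequenceRecord]:
    """Read a multi-record FASTA file; sequences are case-folded to upper.

    ``mode`` is ``"nucleotide"`` (alphabet ACGTN) or ``"protein"``.
    """
    if mode not in ("nucleotide", "protein"):
        raise ValueError(f"unknown mode {mode!r}")
    path = Path(path)
    records: list[SequenceRecord] = []
    for bio in SeqIO.parse(str(path), "fasta"):
        seq = str(bio.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {bio.id!r} has an empty sequence")
        rec = SequenceRecord(id=bio.id, seq=seq, description=bio.description)
        _validate_alphabet(rec, mode)
        records.append(rec)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, wrap: int = 70) -> None:
    """Write records as wrapped FASTA; round-trips with :func:`read_fasta`."""
    if wrap < 1:
        raise ValueError("wrap must be >= 1")
    path = Path(path)
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(
            _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
            for r in records
        )


# ---------------------------------------------------------------------------
# BLAST tabular


def read_blast_tabular(path: str | Path) -> list[AlignmentHit]:
    """Parse a 12-column tab-separated hit table; '#' comment lines skipped."""
    path = Path(path)
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                hits.append(
                    AlignmentHit(
                        query_id=fields[0],
                        subject_id=fields[1],
                        pct_identity=float(fields[2]),
                        aln_len=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        q_start=int(fields[6]),
                        q_end=int(fields[7]),
                        s_start=int(fields[8]),
                        s_end=int(fields[9]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_blast_tabular(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pct_identity:.2f}\t{h.aln_len}\t"
                f"{h.mismatches}\t{h.gap_opens}\t{h.q_start}\t{h.q_end}\t"
                f"{h.s_start}\t{h.s_end}\t{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )


# ---------------------------------------------------------------------------
# Pathway DB TSV
#
# Line-oriented dialect, diffable in tests:
#   PATHWAY <TAB> pathway_id <TAB> rxn1,rxn2,...
#   REACTION <TAB> reaction_id <TAB> EC <TAB> full|partial <TAB> prot1,prot2,...
# EC and protein fields may be '-' when absent.


def read_pathway_db(path: str | Path) -> PathwayDB:
    path = Path(path)
    pathways: dict[str, list[str]] = {}
    reaction_proteins: dict[str, set[str]] = {}
    reaction_ec: dict[str, tuple[str, bool]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            kind = fields[0]
            if kind == "PATHWAY":
                if len(fields) != 3:
                    raise FormatError(f"{path}:{lineno}: PATHWAY needs 3 fields")
                pid, rxns = fields[1], [r for r in fields[2].split(",") if r]
                if pid in pathways:
                    raise FormatError(f"{path}:{lineno}: duplicate pathway {pid!r}")
                if not rxns:
                    raise FormatError(f"{path}:{lineno}: pathway {pid!r} has zero reactions")
                pathways[pid] = rxns
            elif kind == "REACTION":
                if len(fields) != 5:
                    raise FormatError(f"{path}:{lineno}: REACTION needs 5 fields")
                rid, ec, flag, prots = fields[1], fields[2], fields[3], fields[4]
                if flag not in ("full", "partial"):
                    raise FormatError(
                        f"{path}:{lineno}: association flag must be full|partial"
                    )
                # '-' in any EC position marks an incomplete number; the explicit
                # flag wins but must agree with a fully specified EC
                partial = flag == "partial" or "-" in ec.split(".")
                if ec != "-":
                    reaction_ec[rid] = (ec, partial)
                else:
                    reaction_ec[rid] = ("", partial)
                if prots != "-":
                    reaction_proteins[rid] = set(p for p in prots.split(",") if p)
            else:
                raise FormatError(f"{path}:{lineno}: unknown record type {kind!r}")
    return PathwayDB(pathways, reaction_proteins, reaction_ec)


def write_pathway_db(db: PathwayDB, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid in sorted(set(db.reaction_ec) | set(db.reaction_proteins)):
            ec, partial = db.reaction_ec.get(rid, ("", False))
            prots = ",".join(sorted(db.reaction_proteins.get(rid, ()))) or "-"
            fh.write(
                f"REACTION\t{rid}\t{ec or '-'}\t"
                f"{'partial' if partial else 'full'}\t{prots}\n"
            )
        for pid, rxns in db.pathways.items():
            fh.write(f"PATHWAY\t{pid}\t{','.join(rxns)}\n")
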