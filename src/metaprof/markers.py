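"""Rule-based marker-gene screening with false-positive elimination.

Assemblies are screened for genes diagnostic of energy and detoxification
metabolism (e.g. aclB for rTCA CO2 fixation, sqr for sulfide oxidation, dsrA
for dissimilatory sulfite reduction). Candidates are environmental sequences
hitting a marker query below an E-value threshold; each candidate is then
validated against its best reverse annotation and rejected by one of three
rules — (i) right protein family but a different member than the query gene,
(ii) homologous region but clearly different function, (iii) a blacklisted
mis-annotation label — or for insufficient aligned query coverage. Every
decision is recorded so a human can audit the calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import AlignmentHit

__all__ = [
    "MarkerQuery",
    "MarkerCall",
    "load_registry",
    "screen_markers",
    "validate_marker",
    "validate_all",
    "marker_count_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MarkerQuery:
    gene_symbol: str
    query_id: str
    query_len: int
    process: str
    family: str


@dataclass(frozen=True)
class MarkerCall:
    env_id: str
    gene_symbol: str
    evalue: float
    coverage: float
    status: str  # candidate | confirmed | rejected | undetermined
    reject_rule: str = "none"  # i | ii | iii | coverage | none
    reverse_label: str = ""


def load_registry(table: pd.DataFrame) -> dict[str, MarkerQuery]:
    """Index a registry table (gene_symbol, query_id, query_len, process,
    family) by query id."""
    out: dict[str, MarkerQuery] = {}
    for row in table.itertuples(index=False):
        q = MarkerQuery(
            gene_symbol=row.gene_symbol,
            query_id=row.query_id,
            query_len=int(row.query_len),
            process=row.process,
            family=row.family,
        )
        out[q.query_id] = q
    return out


def screen_markers(
    hits: Iterable[AlignmentHit],
    registry: Mapping[str, MarkerQuery],
    e_threshold: float = 1e-10,
) -> list[MarkerCall]:
    """Turn a marker-query-vs-assembly hit table into candidate calls.

    Hit queries are marker proteins and subjects environmental sequences.
    One candidate is kept per (environmental sequence, gene symbol): the
    best E-value among its passing hits. Query coverage is the aligned query
    span over the query length.
    """
    best: dict[tuple[str, str], tuple[AlignmentHit, MarkerQuery]] = {}
    for h in hits:
        if h.query_id not in registry:
            raise KeyError(f"query {h.query_id!r} absent from marker registry")
        if h.evalue >= e_threshold:
            continue
        q = registry[h.query_id]
        key = (h.subject_id, q.gene_symbol)
        if key not in best or h.evalue < best[key][0].evalue:
            best[key] = (h, q)
    calls = []
    for (env_id, symbol), (h, q) in sorted(best.items()):
        coverage = (h.q_end - h.q_start + 1) / q.query_len
        calls.append(
            MarkerCall(env_id, symbol, h.evalue, coverage, status="candidate")
        )
    return calls


def validate_marker(
    candidate: MarkerCall,
    reverse_annotation: Mapping[str, tuple[str, str]],
    registry_by_symbol: Mapping[str, MarkerQuery],
    blacklist: frozenset[str] = frozenset(),
    min_coverage: float = 0.3,
) -> MarkerCall:
    """Apply the false-positive rules to one candidate.

    ``reverse_annotation`` maps environmental sequence id to its best
    reverse-search annotation as ``(label_symbol, label_process)``. Rules in
    order: (i) label is a different member of the query's protein family;
    (ii) label's function differs from the query's process; (iii) label is
    blacklisted as a known mis-annotation; coverage below ``min_coverage``.
    Candidates missing from the reverse table come back undetermined.
    """
    q = registry_by_symbol[candidate.gene_symbol]
    if candidate.env_id not in reverse_annotation:
        logger.warning("no reverse annotation for %s; left undetermined",
                       candidate.env_id)
        return _with(candidate, status="undetermined")
    label_symbol, label_process = reverse_annotation[candidate.env_id]
    family_of = {s: mq.family for s, mq in registry_by_symbol.items()}
    if (
        label_symbol != q.gene_symbol
        and family_of.get(label_symbol) == q.family
    ):
        return _with(candidate, status="rejected", reject_rule="i",
                     reverse_label=label_symbol)
    if label_process != q.process:
        return _with(candidate, status="rejected", reject_rule="ii",
                     reverse_label=label_symbol)
    if label_symbol in blacklist:
        return _with(candidate, status="rejected", reject_rule="iii",
                     reverse_label=label_symbol)
    if candidate.coverage < min_coverage:
        return _with(candidate, status="rejected", reject_rule="coverage",
                     reverse_label=label_symbol)
    return _with(candidate, status="confirmed", reverse_label=label_symbol)


def _with(c: MarkerCall, **kw) -> MarkerCall:
    data = {**c.__dict__, **kw}
    return MarkerCall(**data)


def validate_all(
    candidates: Iterable[MarkerCall],
    reverse_annotation: Mapping[str, tuple[str, str]],
    registry_by_symbol: Mapping[str, MarkerQuery],
    blacklist: frozenset[str] = frozenset(),
    min_coverage: float = 0.3,
) -> list[MarkerCall]:
    out = [
        validate_marker(c, reverse_annotation, registry_by_symbol, blacklist,
                        min_coverage)
        for c in candidates
    ]
    for call in out:
        if call.status == "confirmed":
            assert call.reject_rule == "none" and call.coverage >= min_coverage
        logger.debug("%s/%s -> %s (%s)", call.env_id, call.gene_symbol,
                     call.status, call.reject_rule)
    return out


def marker_count_table(
    confirmed: Iterable[MarkerCall],
    sample_of: Mapping[str, str],
    registry_by_symbol: Mapping[str, MarkerQuery],
    samples: Sequence[str],
) -> pd.DataFrame:
    """Process x sample table of distinct confirmed environmental sequences.

    ``sample_of`` maps environmental sequence id to its sample; each call's
    process label comes from the registry via its gene symbol. The full
    row/column frame is kept, zero cells printed as 0.
    """
    processes = list(dict.fromkeys(q.process for q in registry_by_symbol.values()))
    table = pd.DataFrame(0, index=processes, columns=list(samples), dtype=int)
    seen: set[tuple[str, str, str]] = set()
    for call in confirmed:
        if call.status != "confirmed":
            continue
        process = registry_by_symbol[call.gene_symbol].process
        sample = sample_of[call.env_id]
        key = (process, sample, call.env_id)
        if key in seen:
            continue
        seen.add(key)
        table.loc[process, sample] += 1
    return table
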