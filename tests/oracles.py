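"""Independent brute-force oracles used to check the library implementations.

Everything here is deliberately written from first principles — plain loops
over explicit definitions, no imports from the code paths under test beyond
the shared data containers.
"""

from __future__ import annotations

import statistics

# Standard bacterial/archaeal genetic code (translation table 11 shares all
# codon assignments with the standard code; only start-codon sets differ,
# which stop-bounded extraction never consults).
_CODONS = {}
_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            _CODONS[_b1 + _b2 + _b3] = _AA[16 * _i + 4 * _j + _k]


def translate(seq: str) -> str:
    out = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        out.append(_CODONS.get(codon, "X"))  # any N -> X
    return "".join(out)


def revcomp(seq: str) -> str:
    return seq[::-1].translate(str.maketrans("ACGTN", "TGCAN"))


def brute_six_frame(seq: str, min_aa: int) -> list[tuple[int, str, bool, bool]]:
    """All stop-free candidate proteins as (frame, protein, partial5, partial3).

    Translates each frame in full, splits on '*', and flags run-on at the
    frame edges. Coordinates are left to the implementation's own tests; the
    oracle compares frame, sequence and partial flags.
    """
    out: list[tuple[int, str, bool, bool]] = []
    for frame in (1, 2, 3, -1, -2, -3):
        s = seq if frame > 0 else revcomp(seq)
        aa = translate(s[abs(frame) - 1 :])
        chunks = aa.split("*")
        for idx, chunk in enumerate(chunks):
            if len(chunk) < min_aa:
                continue
            partial5 = idx == 0
            partial3 = idx == len(chunks) - 1
            out.append((frame, chunk, partial5, partial3))
    return out


def brute_reaction_counts(db_pathways: dict[str, list[str]], reaction: str):
    """(n_pw, n_totrxn, n_unirxn) by explicit enumeration."""
    containing = [p for p, rxns in db_pathways.items() if reaction in rxns]
    n_pw = len(containing)
    n_totrxn = 0
    union = set()
    for p in containing:
        n_totrxn += len(db_pathways[p])
        union |= set(db_pathways[p])
    return n_pw, n_totrxn, len(union)


def brute_weight(db_pathways: dict[str, list[str]], reaction: str) -> float:
    n_pw, n_tot, n_uni = brute_reaction_counts(db_pathways, reaction)
    return (n_tot / n_uni) / n_pw


def brute_completeness(
    rxns: list[str], weights: dict[str, float], present: set[str]
) -> float:
    num = sum(weights[r] for r in rxns if r in present)
    den = sum(weights[r] for r in rxns)
    return num / den


def brute_activity(rxns: list[str], counts: dict[str, int]) -> float:
    return float(statistics.median([counts.get(r, 0) for r in rxns]))


def brute_filter(
    hits: list[tuple[str, float, bool]], bit_floor: float, window: float
) -> list[str]:
    """Exhaustive filtered-hit-list: hits are (protein, bitscore, partial_only).

    Partial-EC-only proteins are candidates only when no fully associated
    protein scores above the floor; retained = candidates with score
    strictly above the floor and at least (1 - window) of the candidates'
    top score. Returns retained protein ids, input order preserved.
    """
    full_above = [h for h in hits if not h[2] and h[1] > bit_floor]
    if full_above:
        candidates = [h for h in hits if not h[2]]
    else:
        candidates = list(hits)
    if not candidates:
        return []
    top = max(h[1] for h in candidates)
    return [
        p for p, b, _ in candidates if b > bit_floor and b >= (1.0 - window) * top
    ]


def brute_word_frequencies(seq: str, k: int) -> dict[str, float]:
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if "N" in w:
            continue
        counts[w] = counts.get(w, 0) + 1
    total = sum(counts.values())
    return {w: c / total for w, c in counts.items()} if total else {}
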