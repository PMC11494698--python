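"""Amino-acid n-gram tallies per strength quartile and gram classification.

Sequences are decomposed into all overlapping 2-, 3- and 4-grams; constructs
are split into four strength quartiles (Q1 strongest); grams are tallied per
quartile and classified by how over- or under-represented they are in the
extreme quartiles:

* strong  — at least 2x over-represented in Q1 and under-represented in Q4;
* weak    — at least 2x over-represented in Q4 and under-represented in Q1;
* moderate — within +/-25% of the pooled frequency in all four quartiles;
* unclassified — anything else, including grams whose ratios are undefined.

Representation is measured on frequencies (count divided by the quartile's
total number of grams of the same length), which makes quartiles with
unequal total sequence length comparable.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    GAL4_ID,
    SRDX_ID,
    ConstructSummary,
    Motif,
    ParameterError,
    QuartilePartition,
)

logger = logging.getLogger(__name__)

DEFAULT_NS: tuple[int, ...] = (2, 3, 4)
DEFAULT_CONTROLS: tuple[str, ...] = (GAL4_ID, SRDX_ID)


def decompose(sequence: str, n: int) -> list[str]:
    """All overlapping n-grams of ``sequence`` in order.

    A sequence shorter than ``n`` yields an empty list (logged, not an
    error), so short motifs simply contribute nothing at that gram length.
    """
    if n not in (2, 3, 4):
        raise ParameterError("n must be one of 2, 3, 4")
    if len(sequence) < n:
        logger.info("sequence of length %d has no %d-grams", len(sequence), n)
        return []
    return [sequence[i:i + n] for i in range(len(sequence) - n + 1)]


def quartile_partition(
    summaries: Sequence[ConstructSummary],
    controls: Iterable[str] = DEFAULT_CONTROLS,
) -> QuartilePartition:
    """Split non-control constructs into four strength quartiles.

    Constructs are ranked by repression strength (1 - relative GFP)
    descending, ties broken by construct id; Q1 holds the strongest. When n
    is not divisible by 4 the remainder goes to the stronger quartiles
    first, so group sizes differ by at most one.
    """
    ctrl = set(controls)
    members = [s for s in summaries if s.construct_id not in ctrl]
    if len(members) < 4:
        raise ParameterError("need at least 4 non-control constructs")
    ranked = sorted(members, key=lambda s: (-s.strength, s.construct_id))
    n = len(ranked)
    base, rem = divmod(n, 4)
    sizes = [base + (1 if q < rem else 0) for q in range(4)]
    groups = []
    i = 0
    for size in sizes:
        groups.append(tuple(s.construct_id for s in ranked[i:i + size]))
        i += size
    return QuartilePartition(groups=tuple(groups))


def build_ngram_table(
    motifs: Sequence[Motif] | Mapping[str, str],
    partition: QuartilePartition,
    ns: Sequence[int] = DEFAULT_NS,
    count_mode: str = "occurrence",
) -> pd.DataFrame:
    """Tally grams per quartile and compute representation ratios.

    ``count_mode`` is "occurrence" (each overlapping occurrence counts, the
    default) or "presence" (at most one count per construct). Frequencies
    are counts divided by the quartile's total gram tokens of the same
    length; the overall frequency pools all four quartiles; ratios divide
    quartile frequency by overall frequency. A quartile with zero tokens of
    some length yields NaN ratios there (flagged downstream).
    """
    if count_mode not in ("occurrence", "presence"):
        raise ParameterError(f"unknown count_mode {count_mode!r}")
    if isinstance(motifs, Mapping):
        seqs = dict(motifs)
    else:
        seqs = {m.id: m.sequence for m in motifs}
    for q in partition.groups:
        for cid in q:
            if cid not in seqs:
                raise ParameterError(f"no sequence for construct {cid!r}")
    counts: dict[int, list[Counter]] = {n: [Counter() for _ in range(4)] for n in ns}
    totals = {n: np.zeros(4) for n in ns}
    for qi, group in enumerate(partition.groups):
        for cid in group:
            for n in ns:
                grams = decompose(seqs[cid], n)
                totals[n][qi] += len(grams)
                if count_mode == "occurrence":
                    counts[n][qi].update(grams)
                else:
                    counts[n][qi].update(set(grams))
    rows = []
    for n in ns:
        all_grams = sorted(set().union(*[c.keys() for c in counts[n]]))
        pooled_total = totals[n].sum()
        for gram in all_grams:
            c = np.array([counts[n][qi][gram] for qi in range(4)], dtype=float)
            overall = c.sum() / pooled_total if pooled_total else np.nan
            with np.errstate(divide="ignore", invalid="ignore"):
                freq = np.where(totals[n] > 0, c / totals[n], np.nan)
                ratio = freq / overall if overall else np.full(4, np.nan)
            rows.append(
                {
                    "gram": gram,
                    "n": n,
                    "count_q1": int(c[0]), "count_q2": int(c[1]),
                    "count_q3": int(c[2]), "count_q4": int(c[3]),
                    "freq_q1": freq[0], "freq_q2": freq[1],
                    "freq_q3": freq[2], "freq_q4": freq[3],
                    "overall_freq": overall,
                    "ratio_q1": ratio[0], "ratio_q2": ratio[1],
                    "ratio_q3": ratio[2], "ratio_q4": ratio[3],
                }
            )
    return pd.DataFrame(rows)


def _classify_one(r1: float, r2: float, r3: float, r4: float) -> str:
    ratios = np.array([r1, r2, r3, r4], dtype=float)
    if np.isnan(ratios).any():
        return "unclassified"
    if r1 >= 2.0 and r4 < 1.0:
        return "strong"
    if r4 >= 2.0 and r1 < 1.0:
        return "weak"
    if np.all((ratios >= 0.75) & (ratios <= 1.25)):
        return "moderate"
    return "unclassified"


def classify_ngrams(table: pd.DataFrame) -> pd.DataFrame:
    """Assign each gram its strength class (adds a ``gram_class`` column).

    Grams with undefined ratios (empty quartile totals) are marked
    unclassified with a warning; grams with zero overall count are dropped.
    """
    out = table[table[[f"count_q{i}" for i in range(1, 5)]].sum(axis=1) > 0].copy()
    out["gram_class"] = [
        _classify_one(r.ratio_q1, r.ratio_q2, r.ratio_q3, r.ratio_q4)
        for r in out.itertuples()
    ]
    n_undef = int(out[[f"ratio_q{i}" for i in range(1, 5)]].isna().any(axis=1).sum())
    if n_undef:
        logger.warning("%d grams have undefined ratios; marked unclassified",
                       n_undef)
    return out


def gram_classes(classified: pd.DataFrame) -> dict[str, list[str]]:
    """Mapping class -> sorted gram list, for the SynEAR generator."""
    out: dict[str, list[str]] = {"strong": [], "moderate": [], "weak": []}
    for row in classified.itertuples():
        if row.gram_class in out:
            out[row.gram_class].append(row.gram)
    return {k: sorted(v) for k, v in out.items()}
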