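"""Canonical EAR-motif scanning, enrichment tests and length-strength analysis.

The two canonical EAR patterns are LxLxL and DLNxxP (x = any residue).
Enrichment of dual-motif constructs in the stronger half of a library is
tested with Fisher's exact test; motif length vs repression strength is
summarised with per-length box statistics and a Spearman rank correlation;
groupwise strength comparisons use a Dunn rank post-hoc test with Bonferroni
correction.
"""

from __future__ import annotations

import itertools
import logging
import re
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    STANDARD_AA,
    CanonicalScan,
    ConstructSummary,
    LengthStrengthResult,
    ParameterError,
)

logger = logging.getLogger(__name__)

_LXLXL = re.compile(r"L.L.L")
_DLNXXP = re.compile(r"DLN..P")


def scan_canonical(sequence: str, construct_id: str = "") -> CanonicalScan:
    """Presence/absence of the canonical LxLxL and DLNxxP patterns.

    Overlapping matches are treated as presence only. Raises on residues
    outside the 20 standard amino acids.
    """
    if not sequence:
        raise ParameterError("sequence must be non-empty")
    bad = set(sequence) - set(STANDARD_AA)
    if bad:
        raise ParameterError(f"non-amino-acid characters {sorted(bad)}")
    return CanonicalScan(
        construct_id=construct_id,
        has_LxLxL=_LXLXL.search(sequence) is not None,
        has_DLNxxP=_DLNXXP.search(sequence) is not None,
    )


def scan_library(sequences: Mapping[str, str]) -> pd.DataFrame:
    """Scan every sequence; returns a frame with one row per construct."""
    rows = []
    for cid in sorted(sequences):
        s = scan_canonical(sequences[cid], cid)
        rows.append(
            {
                "construct_id": cid,
                "has_LxLxL": s.has_LxLxL,
                "has_DLNxxP": s.has_DLNxxP,
                "has_both": s.has_both,
            }
        )
    return pd.DataFrame(rows)


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> dict[str, float]:
    """Fisher's exact test on a 2x2 contingency table.

    One-sided p is the upper hypergeometric tail P(X >= a) for the top-left
    cell; two-sided p sums all tables (margins fixed) whose point probability
    does not exceed the observed one (minimum-likelihood convention).
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ParameterError("table must be 2x2 with non-negative integers")
    if t.sum() == 0:
        raise ParameterError("all-zero table: Fisher test undefined")
    _, p_greater = stats.fisher_exact(t, alternative="greater")
    _, p_two = stats.fisher_exact(t, alternative="two-sided")
    return {"p_one_sided": float(p_greater), "p_two_sided": float(p_two)}


def stronger_half(
    summaries: Sequence[ConstructSummary],
    exclude: Iterable[str] = (),
) -> set[str]:
    """Top ceil(n/2) constructs by mean repression, controls excluded.

    Ties in strength are broken by construct id (ascending), so the split is
    deterministic.
    """
    excl = set(exclude)
    members = [s for s in summaries if s.construct_id not in excl]
    ranked = sorted(members, key=lambda s: (-s.strength, s.construct_id))
    k = -(-len(ranked) // 2)  # ceil
    return {s.construct_id for s in ranked[:k]}


def dual_motif_enrichment(
    summaries: Sequence[ConstructSummary],
    sequences: Mapping[str, str],
    exclude: Iterable[str] = (),
) -> dict:
    """Fisher test: are dual-canonical-motif constructs enriched in the
    stronger half of the library?

    Returns the 2x2 table (rows: both motifs yes/no; columns: stronger
    half yes/no) and the Fisher p-values.
    """
    excl = set(exclude)
    members = [s for s in summaries if s.construct_id not in excl]
    strong_ids = stronger_half(members)
    a = b = c = d = 0
    for s in members:
        scan = scan_canonical(sequences[s.construct_id], s.construct_id)
        in_strong = s.construct_id in strong_ids
        if scan.has_both:
            a, b = (a + 1, b) if in_strong else (a, b + 1)
        else:
            c, d = (c + 1, d) if in_strong else (c, d + 1)
    table = [[a, b], [c, d]]
    return {"table": table, "n_both": a + b, **fisher_exact_2x2(table)}


def length_strength(
    summaries: Sequence[ConstructSummary],
    sequences: Mapping[str, str],
    exclude: Iterable[str] = (),
) -> LengthStrengthResult:
    """Per-length box statistics of repression strength and rank correlation.

    Strength is 1 - relative GFP. Constructs named in ``exclude`` (e.g. the
    SRDX control) are omitted. With fewer than 2 distinct lengths the
    correlation is undefined and reported as ``None``.
    """
    excl = set(exclude)
    rows = [
        (len(sequences[s.construct_id]), s.strength)
        for s in summaries
        if s.construct_id not in excl and s.construct_id in sequences
    ]
    if len(rows) < 2:
        raise ParameterError("need at least 2 constructs with sequences")
    df = pd.DataFrame(rows, columns=["length", "strength"])
    box = (
        df.groupby("length")["strength"]
        .agg(
            n="count",
            q25=lambda v: float(np.percentile(v, 25)),
            median="median",
            q75=lambda v: float(np.percentile(v, 75)),
        )
        .reset_index()
    )
    if df["length"].nunique() < 2:
        logger.warning("all motif lengths equal; rank correlation undefined")
        rho = pval = None
    else:
        rho_, p_ = stats.spearmanr(df["length"], df["strength"])
        rho, pval = float(rho_), float(p_)
    return LengthStrengthResult(table=box, spearman_rho=rho, spearman_p=pval,
                                n=len(df))


def dunn_test(
    groups: Mapping[str, Sequence[float]],
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Dunn's rank-based post hoc test for all group pairs.

    All values are ranked jointly (average ranks for ties); for groups i, j
    the statistic is

        z = (Rbar_i - Rbar_j) / sqrt( (N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j) )

    with tie correction T = sum(t^3 - t) over tie groups. Raw two-sided p
    values come from the normal distribution; Bonferroni multiplies by the
    number of pairwise comparisons (capped at 1). Groups with fewer than two
    values are excluded with a warning.
    """
    if correction != "bonferroni":
        raise ParameterError(f"unsupported correction {correction!r}")
    usable: dict[str, np.ndarray] = {}
    for name, vals in groups.items():
        arr = np.asarray(list(vals), dtype=float)
        if arr.size < 2:
            logger.warning("group %r has < 2 values; excluded from Dunn test",
                           name)
            continue
        usable[name] = arr
    if len(usable) < 2:
        raise ParameterError("Dunn test requires >= 2 groups with >= 2 values")
    names = sorted(usable)
    pooled = np.concatenate([usable[n] for n in names])
    ranks = stats.rankdata(pooled)
    big_n = pooled.size
    # mean rank per group
    mean_rank: dict[str, float] = {}
    i = 0
    for n in names:
        k = usable[n].size
        mean_rank[n] = float(ranks[i:i + k].mean())
        i += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    base_var = big_n * (big_n + 1) / 12.0 - tie_term / (12.0 * (big_n - 1))
    pairs = list(itertools.combinations(names, 2))
    rows = []
    for g1, g2 in pairs:
        n1, n2 = usable[g1].size, usable[g2].size
        se = np.sqrt(base_var * (1.0 / n1 + 1.0 / n2))
        z = (mean_rank[g1] - mean_rank[g2]) / se
        p_raw = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "z": float(z),
                "p_raw": float(p_raw),
                "p_adj": float(min(1.0, p_raw * len(pairs))),
            }
        )
    return pd.DataFrame(rows)
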