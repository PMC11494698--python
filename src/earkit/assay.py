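"""Quantification of the fluorescence repression assay and ΔΔCq expression.

Technical (leaf-disk) replicates are collapsed to one biological value per
plant first; construct means, SEMs and relative-GFP scores are computed over
biological replicates only. Relative GFP is fluorescence divided by the mean
of the Gal4-only baseline; a construct repressing GFP by at least half
(relative GFP <= 0.5) is classified a repressor. Cross-library scores map the
two shared controls onto a common scale (Gal4 -> 0, SRDX -> 1).
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    GAL4_ID,
    SRDX_ID,
    ConstructSummary,
    DegenerateControlsError,
    MissingControlError,
    ParameterError,
)

logger = logging.getLogger(__name__)

#: Relative-GFP threshold at or below which a construct is a repressor.
REPRESSOR_THRESHOLD = 0.5

_PLATE_COLUMNS = ("construct_id", "plant_id", "fluorescence")


def _check_plate(table: pd.DataFrame) -> None:
    if table.empty:
        raise ParameterError("plate table is empty")
    missing = [c for c in _PLATE_COLUMNS if c not in table.columns]
    if missing:
        raise ParameterError(f"plate table lacks columns {missing}")
    if (table["fluorescence"] <= 0).any():
        raise ParameterError("fluorescence values must be > 0")


def aggregate_replicates(table: pd.DataFrame) -> dict[str, list[float]]:
    """Collapse technical replicates: one mean per (construct, plant).

    Returns a mapping construct_id -> list of per-plant means, plants in
    sorted plant_id order. Constructs with no rows simply do not appear.
    """
    _check_plate(table)
    grouped = (
        table.groupby(["construct_id", "plant_id"], sort=True)["fluorescence"]
        .mean()
    )
    out: dict[str, list[float]] = {}
    for (cid, _plant), v in grouped.items():
        out.setdefault(cid, []).append(float(v))
    return out


def classify_repressor(relative_gfp: float) -> bool:
    """True iff the construct reduces GFP by at least 50%."""
    if relative_gfp <= 0:
        raise ParameterError("relative_gfp must be > 0")
    return relative_gfp <= REPRESSOR_THRESHOLD


def summarize(
    construct_id: str,
    bio_values: Sequence[float],
    gal4_mean: float,
) -> ConstructSummary:
    """Summarise one construct from its per-plant biological values.

    SEM is the sample (n-1) standard deviation over biological replicates
    divided by sqrt(n); with a single plant it is undefined and reported as
    ``None``. Activators (relative GFP > 1) are flagged, never classified
    as repressors.
    """
    if gal4_mean <= 0:
        raise ParameterError("gal4_mean must be > 0")
    vals = np.asarray(list(bio_values), dtype=float)
    if vals.size == 0:
        raise ParameterError(f"construct {construct_id!r} has no biological values")
    mean = float(vals.mean())
    sem = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size >= 2 else None
    rel = mean / gal4_mean
    return ConstructSummary(
        construct_id=construct_id,
        bio_values=[float(v) for v in vals],
        mean_fluor=mean,
        sem=sem,
        relative_gfp=rel,
        is_repressor=classify_repressor(rel),
        is_activator=rel > 1.0,
    )


def normalize_cross_library(
    mean_fluor: float, gal4_mean: float, srdx_mean: float
) -> float:
    """Affine score anchored on the shared controls: Gal4 -> 0, SRDX -> 1.

    Values above 1 (stronger than SRDX) and below 0 (activators) are allowed.
    """
    if srdx_mean <= 0 or gal4_mean <= 0:
        raise ParameterError("control means must be > 0")
    if gal4_mean <= srdx_mean:
        raise DegenerateControlsError(
            "Gal4 mean must exceed SRDX mean to anchor normalization"
        )
    return (gal4_mean - mean_fluor) / (gal4_mean - srdx_mean)


def summarize_library(
    table: pd.DataFrame,
    gal4_id: str = GAL4_ID,
    srdx_id: str = SRDX_ID,
    normalize: bool = True,
) -> list[ConstructSummary]:
    """Full quantification of one library's plate table.

    The Gal4 reference mean is computed from this table (i.e. per library /
    batch, not globally). Normalized scores are added when the SRDX control
    is present and the controls are non-degenerate.
    """
    bio = aggregate_replicates(table)
    if gal4_id not in bio:
        raise MissingControlError(
            f"plate table lacks the {gal4_id!r} baseline control"
        )
    gal4_mean = float(np.mean(bio[gal4_id]))
    summaries = [summarize(cid, vals, gal4_mean) for cid, vals in sorted(bio.items())]
    if normalize:
        if srdx_id not in bio:
            logger.warning("no %r control; normalized scores omitted", srdx_id)
        else:
            srdx_mean = float(np.mean(bio[srdx_id]))
            for s in summaries:
                s.normalized_score = normalize_cross_library(
                    s.mean_fluor, gal4_mean, srdx_mean
                )
    return summaries


def summaries_to_frame(summaries: Iterable[ConstructSummary]) -> pd.DataFrame:
    """Tabular view of construct summaries (one row per construct)."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "construct_id": s.construct_id,
                "n_plants": len(s.bio_values),
                "mean_fluor": s.mean_fluor,
                "sem": s.sem,
                "relative_gfp": s.relative_gfp,
                "strength": s.strength,
                "is_repressor": s.is_repressor,
                "is_activator": s.is_activator,
                "normalized_score": s.normalized_score,
            }
        )
    return pd.DataFrame(rows)


def delta_delta_cq(
    cq: pd.DataFrame,
    target: str,
    reference: str,
    wildtype_ids: set[str] | Sequence[str],
) -> pd.DataFrame:
    """Relative expression by the ΔΔCq method, wild-type mean scaled to 1.

    ``cq`` is a tidy table with columns ``sample_id, gene, cq`` (extra
    columns such as genotype are carried through). For each sample,
    ΔCq = Cq(target) - Cq(reference) and expression = 2**(-ΔCq); expressions
    are then rescaled so the mean over ``wildtype_ids`` samples is exactly 1.
    Amplification efficiency is assumed to be exactly 2. Samples missing
    either gene are dropped with a warning.
    """
    wt = set(wildtype_ids)
    if not wt:
        raise ParameterError("wildtype_ids must be non-empty")
    for col in ("sample_id", "gene", "cq"):
        if col not in cq.columns:
            raise ParameterError(f"Cq table lacks column {col!r}")
    wide = cq.pivot_table(index="sample_id", columns="gene", values="cq",
                          aggfunc="mean")
    for gene in (target, reference):
        if gene not in wide.columns:
            raise ParameterError(f"gene {gene!r} absent from Cq table")
    complete = wide[[target, reference]].dropna()
    dropped = set(wide.index) - set(complete.index)
    if dropped:
        logger.warning("samples %s missing a gene; dropped", sorted(dropped))
    dcq = complete[target] - complete[reference]
    expr = np.power(2.0, -dcq)
    wt_present = [s for s in complete.index if s in wt]
    if not wt_present:
        raise ParameterError("no wild-type sample has complete Cq data")
    expr = expr / expr.loc[wt_present].mean()
    out = pd.DataFrame(
        {
            "sample_id": complete.index,
            "delta_cq": dcq.values,
            "expression": expr.values,
            "is_wildtype": [s in wt for s in complete.index],
        }
    ).reset_index(drop=True)
    if "genotype" in cq.columns:
        geno = cq.drop_duplicates("sample_id").set_index("sample_id")["genotype"]
        out["genotype"] = out["sample_id"].map(geno)
    return out
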