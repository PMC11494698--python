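"""End-to-end pipeline: simulate, quantify, classify, design, evaluate.

One global seed fans out into per-stage substreams (via
:class:`numpy.random.SeedSequence`), so a full run is reproducible
bit-for-bit from a single integer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import assay, evaluate, motifs as motif_analysis, ngram, synear
from . import synthetic_data as sd
from .datatypes import (
    GAL4_ID,
    SRDX_ID,
    ConstructSummary,
    EvalResult,
    GroundTruthModel,
    LengthStrengthResult,
    Motif,
    SynEARSpec,
)

logger = logging.getLogger(__name__)

DEFAULT_SYNEAR_COUNTS = {"weak": 20, "moderate": 20, "strong": 20,
                         "strongest": 20}


@dataclass
class PipelineResult:
    """Everything one end-to-end run produces."""

    seed: int
    model: GroundTruthModel
    natural_motifs: list[Motif]
    natural_plate: pd.DataFrame
    natural_summaries: list[ConstructSummary]
    scan: pd.DataFrame
    enrichment: dict
    length_strength: LengthStrengthResult
    ngram_table: pd.DataFrame
    classes: dict[str, list[str]]
    synear_motifs: list[Motif]
    synear_plate: pd.DataFrame
    synear_summaries: list[ConstructSummary]
    eval_result: EvalResult
    skipped_classes: list[str] = field(default_factory=list)

    def summary_frames(self) -> dict[str, pd.DataFrame]:
        return {
            "natural": assay.summaries_to_frame(self.natural_summaries),
            "synear": assay.summaries_to_frame(self.synear_summaries),
        }


def _stage_seeds(seed: int, k: int) -> list[int]:
    children = np.random.SeedSequence(seed).spawn(k)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


def run_pipeline(
    seed: int = 0,
    n_constructs: int = 84,
    lengths: Sequence[int] = tuple(range(5, 17)),
    n_strong: int = 5,
    n_weak: int = 5,
    effect_size: float = 0.3,
    tech_noise_sd: float = 0.05,
    bio_noise_sd: float = 0.05,
    synear_counts: Optional[dict[str, int]] = None,
    strongest_factor: float = 1.5,
    n_perm: int = 1000,
    n_boot: int = 1000,
) -> PipelineResult:
    """Run the whole analysis at desk scale from a single seed.

    Stages: plant a ground-truth n-gram model; generate and assay a natural
    library; quantify it; scan canonical motifs and test enrichment;
    classify n-grams per strength quartile; generate SynEARs per class;
    assay and quantify the SynEAR library under the same ground truth; and
    evaluate predicted vs observed strength classes against permutation and
    random-guess nulls. SynEAR classes whose gram set came out empty on this
    seed are skipped and recorded in ``skipped_classes``.
    """
    counts = dict(synear_counts or DEFAULT_SYNEAR_COUNTS)
    s = _stage_seeds(seed, 6)
    model = sd.generate_ground_truth(
        n_strong, n_weak, effect_size,
        tech_noise_sd=tech_noise_sd, bio_noise_sd=bio_noise_sd, seed=s[0],
    )
    natural = sd.generate_motif_library(n_constructs, lengths, model, seed=s[1])
    assayed_natural = natural + sd.control_motifs()
    plate = sd.simulate_assay(assayed_natural, model, seed=s[2])
    summaries = assay.summarize_library(plate)
    sequences = {m.id: m.sequence for m in assayed_natural}

    scan = motif_analysis.scan_library(sequences)
    enrichment = motif_analysis.dual_motif_enrichment(
        summaries, sequences, exclude=(GAL4_ID, SRDX_ID)
    )
    length_res = motif_analysis.length_strength(
        summaries, sequences, exclude=(GAL4_ID, SRDX_ID)
    )

    partition = ngram.quartile_partition(summaries)
    table = ngram.classify_ngrams(ngram.build_ngram_table(natural, partition))
    classes = ngram.gram_classes(table)

    skipped = [c for c in list(counts) if
               not classes.get("strong" if c == "strongest" else c)]
    for c in skipped:
        logger.warning("no grams classified %r on this seed; class skipped",
                       "strong" if c == "strongest" else c)
        counts.pop(c)
    length_source = tuple(len(m.sequence) for m in natural)
    class_seeds = _stage_seeds(s[3], len(counts))
    synears = []
    for cls_seed, cls in zip(class_seeds, sorted(counts)):
        spec = SynEARSpec(
            counts={cls: counts[cls]},
            length_source=length_source,
            strongest_factor=strongest_factor,
            seed=cls_seed,
        )
        try:
            synears.extend(synear.generate_library(spec, classes))
        except synear.GenerationError as err:
            # tiny gram pools cannot yield the requested number of unique
            # sequences; keep what was generated and record the shortfall
            logger.warning("%s; keeping %d partial %r SynEARs", err,
                           len(err.partial), cls)
            synears.extend(err.partial)
            skipped.append(f"{cls} (partial: {len(err.partial)})")
    synears = [
        Motif(
            id=m.id, sequence=m.sequence, library=m.library,
            predicted_class=m.predicted_class,
            true_strength=sd.true_strength_from_sequence(m.sequence, model),
        )
        for m in synears
    ]
    syn_plate = sd.simulate_assay(synears + sd.control_motifs(), model, seed=s[4])
    syn_summaries = assay.summarize_library(syn_plate)

    by_id = {m.id: m for m in synears}
    eval_members = [t for t in syn_summaries if t.construct_id in by_id]
    predicted = [by_id[t.construct_id].predicted_class for t in eval_members]
    observed = [t.strength for t in eval_members]
    eval_result = evaluate.evaluate_predictions(
        predicted, observed, n_perm=n_perm, n_boot=n_boot, seed=s[5]
    )
    return PipelineResult(
        seed=seed,
        model=model,
        natural_motifs=natural,
        natural_plate=plate,
        natural_summaries=summaries,
        scan=scan,
        enrichment=enrichment,
        length_strength=length_res,
        ngram_table=table,
        classes=classes,
        synear_motifs=synears,
        synear_plate=syn_plate,
        synear_summaries=syn_summaries,
        eval_result=eval_result,
        skipped_classes=skipped,
    )


def planted_gram_recovery(result: PipelineResult, min_occurrences: int = 3
                          ) -> dict:
    """How well the n-gram classifier recovered the planted strong grams.

    Considers planted strong grams occurring at least ``min_occurrences``
    times across the natural library; recovery is the fraction of those
    classified "strong".
    """
    lib_counts = {
        g: sum(sd.count_occurrences(m.sequence, g)
               for m in result.natural_motifs)
        for g in result.model.strong_grams
    }
    eligible = sorted(g for g, c in lib_counts.items()
                      if c >= min_occurrences)
    classified = set(result.classes.get("strong", []))
    recovered = [g for g in eligible if g in classified]
    return {
        "eligible": eligible,
        "recovered": recovered,
        "recovery_rate": (len(recovered) / len(eligible)) if eligible else None,
    }
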