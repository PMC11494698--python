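"""Generation of synthetic EAR (SynEAR) motifs from classified n-grams.

SynEARs come in four predicted strength classes. Weak, moderate and strong
SynEARs are random concatenations of the correspondingly classified grams,
with lengths resampled from the natural library's empirical length
distribution; the "strongest" class reuses the strong gram set but draws
from a lengthened distribution (natural length times a configurable factor),
reflecting the positive length-strength correlation of natural EARs.
Assembly truncates the final gram so the output hits the target length
exactly.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import numpy as np

from .datatypes import CLASS_ORDER, Motif, ParameterError, SynEARSpec

logger = logging.getLogger(__name__)


class GenerationError(RuntimeError):
    """The generator could not satisfy the requested library spec."""

    def __init__(self, message: str, partial: Optional[list[Motif]] = None):
        super().__init__(message)
        self.partial = partial or []


def sample_length(cls: str, spec: SynEARSpec, rng: np.random.Generator) -> int:
    """Draw a target length for one SynEAR of class ``cls``.

    Weak/moderate/strong draw uniformly from the empirical natural lengths;
    strongest scales the draw by ``spec.strongest_factor`` and rounds to the
    nearest integer (ties to even).
    """
    if cls not in CLASS_ORDER:
        raise ParameterError(f"unknown class {cls!r}")
    length = int(rng.choice(np.asarray(spec.length_source, dtype=int)))
    if cls == "strongest":
        length = int(round(spec.strongest_factor * length))
    return length


def assemble_synear(
    grams: Sequence[str],
    target_length: int,
    rng: np.random.Generator,
    return_trace: bool = False,
) -> str | tuple[str, list[str]]:
    """Concatenate uniformly sampled grams to exactly ``target_length``.

    Grams are drawn uniformly with replacement from the (sorted,
    deduplicated) class set until the concatenation reaches the target; the
    final gram is truncated so the output length is exact. With
    ``return_trace`` the list of drawn grams (untruncated) is also returned,
    which lets callers verify that every complete assembly unit belongs to
    the class set.
    """
    pool = sorted(set(grams))
    if not pool:
        raise GenerationError("empty gram set")
    if target_length < min(len(g) for g in pool):
        raise ParameterError("target_length shorter than the shortest gram")
    parts: list[str] = []
    trace: list[str] = []
    total = 0
    while total < target_length:
        g = pool[int(rng.integers(len(pool)))]
        trace.append(g)
        parts.append(g)
        total += len(g)
    seq = "".join(parts)[:target_length]
    return (seq, trace) if return_trace else seq


def generate_library(
    spec: SynEARSpec,
    classes: Mapping[str, Sequence[str]],
    max_attempts_per_motif: int = 200,
) -> list[Motif]:
    """Generate the SynEAR library described by ``spec``.

    ``classes`` maps "weak"/"moderate"/"strong" to their gram lists; the
    "strongest" class uses the strong gram set. Sequences are unique within
    the library (duplicates are regenerated within a bounded retry budget);
    exhausting the budget raises :class:`GenerationError` carrying the
    partial library. Identical seeds yield identical libraries.
    """
    rng = np.random.default_rng(spec.seed)
    seen: set[str] = set()
    out: list[Motif] = []
    for cls in CLASS_ORDER:
        want = int(spec.counts.get(cls, 0))
        if want == 0:
            continue
        pool = list(classes["strong" if cls == "strongest" else cls])
        if not pool:
            raise GenerationError(
                f"class {cls!r} requested but its gram set is empty", out
            )
        made = 0
        attempts = 0
        budget = max_attempts_per_motif * want
        while made < want:
            if attempts >= budget:
                raise GenerationError(
                    f"could not generate {want} unique {cls!r} SynEARs "
                    f"within {budget} attempts", out,
                )
            attempts += 1
            length = sample_length(cls, spec, rng)
            seq = assemble_synear(pool, length, rng)
            if seq in seen:
                continue
            seen.add(seq)
            made += 1
            out.append(
                Motif(
                    id=f"SynEAR_{cls}_{made:03d}",
                    sequence=seq,
                    library="SynEAR",
                    predicted_class=cls,
                )
            )
    return out
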