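"""Synthetic motif libraries, reporter-assay plates and qPCR tables.

The generator emulates the structure of a Gal4/UAS-GFP transient repression
assay in *N. benthamiana*: a library of short peptide motifs fused to the Gal4
DNA-binding domain, each infiltrated into three plants with eight leaf-disk
technical replicates per plant, bracketed by a Gal4-only baseline control and
an SRDX strong-repressor control. Ground truth is a planted n-gram model:
designated "strong" grams push repression up, "weak" grams push it down, and
a bounded logistic link maps the net planted effect onto a repression
strength in [-0.6, 1.0] (fraction of GFP reduction; negative = activation).
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
    STANDARD_AA,
    GroundTruthModel,
    MissingControlError,
    Motif,
    ParameterError,
)

logger = logging.getLogger(__name__)

# Link bounds: strongest observed activation is a 60% GFP increase, strongest
# repression asymptotically complete; the link is strictly decreasing in the
# summed planted effect (strong grams contribute -effect_size each).
_LINK_LO = -0.6
_LINK_HI = 1.0
#: Logistic steepness; at the default planted effect of 0.3 per occurrence,
#: three net strong occurrences cross the 50%-reduction repressor threshold.
LINK_TAU = 0.5
# Offset chosen so a motif with no planted grams has strength exactly 0.
_LINK_S0 = LINK_TAU * math.log(0.375 / 0.625)  # tau * logit((0 - lo)/(hi - lo))

#: Default per-motif distribution of planted-gram insertions per class
#: (probability of embedding 0, 1, 2, ... grams); heavy enough in the tail
#: that the library spans strong activation to strong repression.
DEFAULT_INSERTION_PROBS: tuple[float, ...] = (0.45, 0.20, 0.13, 0.10, 0.07,
                                              0.05)

#: Background residue frequencies for filler positions. EAR-family motifs
#: are leucine-rich with frequent D/N/P (the canonical patterns are LxLxL
#: and DLNxxP), so the background is deliberately non-uniform.
BACKGROUND_AA_FREQS: dict[str, float] = {
    "L": 0.15, "S": 0.08, "A": 0.08, "D": 0.07, "N": 0.06, "P": 0.06,
    "E": 0.06, "G": 0.06, "T": 0.05, "V": 0.05, "K": 0.05, "I": 0.04,
    "R": 0.04, "Q": 0.04, "F": 0.03, "M": 0.02, "H": 0.02, "Y": 0.02,
    "W": 0.01, "C": 0.01,
}

#: First residues of the yeast Gal4 DNA-binding domain (baseline control).
GAL4_SEQUENCE = "MKLLSSIEQACDICRLKKLKCSKEKPKC"
#: The canonical 12-aa SRDX strong-repressor motif.
SRDX_SEQUENCE = "LDLDLELRLGFA"
#: Assigned ground-truth strength of the SRDX positive control.
SRDX_TRUE_STRENGTH = 0.9


def link_strength(net_effect: float) -> float:
    """Map a summed planted-gram effect onto a repression strength.

    Logistic in the net effect, strictly decreasing, with range
    (-0.6, 1.0) and ``link_strength(0) == 0``.
    """
    s = _LINK_LO + (_LINK_HI - _LINK_LO) / (
        1.0 + math.exp((net_effect - _LINK_S0) / LINK_TAU)
    )
    return float(np.clip(s, _LINK_LO, _LINK_HI))


def _random_grams(rng: np.random.Generator, k: int, alphabet: str,
                  taken: set[str]) -> set[str]:
    grams: set[str] = set()
    letters = list(alphabet)
    while len(grams) < k:
        n = int(rng.integers(2, 5))
        g = "".join(rng.choice(letters, size=n))
        if g not in taken and g not in grams:
            grams.add(g)
    return grams


def generate_ground_truth(
    n_strong: int,
    n_weak: int,
    effect_size: float,
    tech_noise_sd: float = 0.05,
    bio_noise_sd: float = 0.05,
    seed: int = 0,
    baseline_fluor: float = 1000.0,
    alphabet: str = STANDARD_AA,
) -> GroundTruthModel:
    """Draw disjoint planted strong/weak gram sets and noise parameters.

    Identical seeds yield identical models. ``baseline_fluor`` is the
    Gal4-only fluorescence in arbitrary units (stored as its natural log).
    """
    if n_strong < 0 or n_weak < 0:
        raise ParameterError("gram counts must be >= 0")
    if effect_size < 0:
        raise ParameterError("effect_size must be >= 0")
    if tech_noise_sd < 0 or bio_noise_sd < 0:
        raise ParameterError("noise standard deviations must be >= 0")
    if baseline_fluor <= 0:
        raise ParameterError("baseline_fluor must be > 0")
    rng = np.random.default_rng(seed)
    strong = _random_grams(rng, n_strong, alphabet, set())
    weak = _random_grams(rng, n_weak, alphabet, set(strong))
    return GroundTruthModel(
        strong_grams=frozenset(strong),
        weak_grams=frozenset(weak),
        effect_size=effect_size,
        baseline_log_fluor=math.log(baseline_fluor),
        tech_noise_sd=tech_noise_sd,
        bio_noise_sd=bio_noise_sd,
        seed=seed,
        alphabet=alphabet,
    )


def count_occurrences(sequence: str, gram: str) -> int:
    """Number of (possibly overlapping) occurrences of ``gram``, one per
    start position."""
    n = len(gram)
    return sum(1 for i in range(len(sequence) - n + 1) if sequence[i:i + n] == gram)


def true_strength_from_sequence(sequence: str, model: GroundTruthModel) -> float:
    """Ground-truth repression strength of a sequence under a planted model.

    Each occurrence of a planted strong gram contributes ``-effect_size`` to
    the net effect and each weak-gram occurrence ``+effect_size``; overlapping
    occurrences count once per start position.
    """
    net = 0.0
    for g in model.strong_grams:
        net -= model.effect_size * count_occurrences(sequence, g)
    for g in model.weak_grams:
        net += model.effect_size * count_occurrences(sequence, g)
    return link_strength(net)


def control_motifs(srdx_strength: float = SRDX_TRUE_STRENGTH) -> list[Motif]:
    """The two shared controls: Gal4 baseline (strength 0) and SRDX."""
    return [
        Motif(id=GAL4_ID, sequence=GAL4_SEQUENCE, library="control",
              true_strength=0.0),
        Motif(id=SRDX_ID, sequence=SRDX_SEQUENCE, library="control",
              true_strength=srdx_strength),
    ]


def _normalize_length_dist(
    length_dist: Mapping[int, float] | Sequence[int],
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(length_dist, Mapping):
        items = sorted(length_dist.items())
        lengths = np.array([l for l, _ in items], dtype=int)
        probs = np.array([p for _, p in items], dtype=float)
        if probs.sum() <= 0:
            raise ParameterError("length distribution has zero total mass")
        probs = probs / probs.sum()
    else:
        lengths = np.asarray(sorted(set(length_dist)), dtype=int)
        probs = np.full(len(lengths), 1.0 / max(len(lengths), 1))
    if lengths.size == 0:
        raise ParameterError("length distribution is empty")
    if lengths.min() < 2:
        raise ParameterError("motif lengths must be >= 2")
    return lengths, probs


def generate_motif_library(
    n_constructs: int,
    length_dist: Mapping[int, float] | Sequence[int],
    model: GroundTruthModel,
    seed: int = 0,
    library: str = "naturalEAR",
    insertion_probs: Sequence[float] = DEFAULT_INSERTION_PROBS,
) -> list[Motif]:
    """Generate ``n_constructs`` motifs with planted n-gram effects.

    Each motif draws a target length, then independently draws how many
    strong and how many weak planted grams to embed (``insertion_probs``
    gives the probability of embedding 0, 1, 2, ... grams of each class);
    grams and filler residues are concatenated in random order and the
    result truncated to the target length. ``true_strength`` is computed
    from the *realised* sequence, so truncated grams do not count.
    """
    if n_constructs < 1:
        raise ParameterError("n_constructs must be >= 1")
    lengths, probs = _normalize_length_dist(length_dist)
    ins = np.asarray(insertion_probs, dtype=float)
    if ins.min() < 0 or ins.sum() <= 0:
        raise ParameterError("insertion_probs must be non-negative with mass")
    ins = ins / ins.sum()
    rng = np.random.default_rng(seed)
    letters = list(model.alphabet)
    weights = np.array(
        [BACKGROUND_AA_FREQS.get(l, 1.0 / len(letters)) for l in letters]
    )
    weights = weights / weights.sum()
    strong = sorted(model.strong_grams)
    weak = sorted(model.weak_grams)
    motifs: list[Motif] = []
    width = max(2, len(str(n_constructs)))
    for i in range(n_constructs):
        target = int(rng.choice(lengths, p=probs))
        k_strong = int(rng.choice(len(ins), p=ins)) if strong else 0
        k_weak = int(rng.choice(len(ins), p=ins)) if weak else 0
        tokens = [strong[int(rng.integers(len(strong)))] for _ in range(k_strong)]
        tokens += [weak[int(rng.integers(len(weak)))] for _ in range(k_weak)]
        planted_len = sum(len(t) for t in tokens)
        n_fill = max(target - planted_len, 0)
        tokens += [str(rng.choice(letters, p=weights)) for _ in range(n_fill)]
        order = rng.permutation(len(tokens))
        seq = "".join(tokens[j] for j in order)[:target]
        if len(seq) < target:  # only when planted tokens undershoot; pad
            seq += "".join(rng.choice(letters, p=weights,
                                      size=target - len(seq)))
        motifs.append(
            Motif(
                id=f"{library}_{i + 1:0{width}d}",
                sequence=seq,
                library=library,
                true_strength=true_strength_from_sequence(seq, model),
            )
        )
    return motifs


def simulate_assay(
    motifs: Sequence[Motif],
    model: GroundTruthModel,
    n_bio: int = 3,
    n_tech: int = 8,
    seed: int = 0,
    relative_floor: float = 1e-4,
) -> pd.DataFrame:
    """Simulate the plate-reader fluorescence table for a motif library.

    Every motif is measured in ``n_bio`` plants with ``n_tech`` leaf disks
    each; fluorescence is ``exp(baseline + log(1 - true_strength) + bio +
    tech)`` with Gaussian log-scale noise terms. A motif with true_strength
    at (or numerically near) 1 is clamped to ``relative_floor`` of baseline
    and flagged in the ``clamped`` column.

    Returns a tidy frame with columns ``construct_id, plant_id, disk_id,
    fluorescence, clamped``.
    """
    if n_bio < 1 or n_tech < 1:
        raise ParameterError("n_bio and n_tech must be >= 1")
    ids = {m.id for m in motifs}
    for ctrl in (GAL4_ID, SRDX_ID):
        if ctrl not in ids:
            raise MissingControlError(
                f"simulated library must contain the {ctrl!r} control"
            )
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str, str, float, bool]] = []
    for m in motifs:
        ts = m.true_strength if m.true_strength is not None else 0.0
        rel = 1.0 - ts
        clamped = rel < relative_floor
        if clamped:
            rel = relative_floor
            logger.warning("construct %s at repression ceiling; fluorescence "
                           "clamped to floor", m.id)
        log_expect = model.baseline_log_fluor + math.log(rel)
        for b in range(n_bio):
            bio = rng.normal(0.0, model.bio_noise_sd) if model.bio_noise_sd else 0.0
            for t in range(n_tech):
                tech = (rng.normal(0.0, model.tech_noise_sd)
                        if model.tech_noise_sd else 0.0)
                rows.append(
                    (m.id, f"{m.id}_p{b + 1}", f"d{t + 1}",
                     math.exp(log_expect + bio + tech), clamped)
                )
    return pd.DataFrame(
        rows, columns=["construct_id", "plant_id", "disk_id", "fluorescence",
                       "clamped"],
    )


def simulate_qpcr(
    genotypes: Sequence[str],
    n_lines: int,
    true_fold_changes: Mapping[str, float],
    seed: int = 0,
    wildtype: str = "Col0",
    noise_sd: float = 0.0,
    target_gene: str = "target",
    reference_gene: str = "reference",
    base_cq_reference: float = 20.0,
    base_delta_cq: float = 3.0,
) -> pd.DataFrame:
    """Simulate a Cq table for a ΔΔCq worked example.

    Each genotype gets ``n_lines`` independent samples with one Cq per gene.
    The target-minus-reference Cq of a genotype differs from the wild-type
    mean by ``-log2(fold_change)`` plus Gaussian noise, so a fold change of 2
    shifts ΔCq down by one cycle.
    """
    if wildtype not in genotypes:
        raise ParameterError(f"wild-type genotype {wildtype!r} must be present")
    if n_lines < 1:
        raise ParameterError("n_lines must be >= 1")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for geno in genotypes:
        fc = float(true_fold_changes.get(geno, 1.0))
        if fc <= 0:
            raise ParameterError(f"fold change for {geno!r} must be > 0")
        for line in range(n_lines):
            sample = f"{geno}_L{line + 1}"
            cq_ref = base_cq_reference + (rng.normal(0, noise_sd) if noise_sd else 0.0)
            dcq = base_delta_cq - math.log2(fc) + (
                rng.normal(0, noise_sd) if noise_sd else 0.0)
            rows.append((sample, geno, reference_gene, cq_ref))
            rows.append((sample, geno, target_gene, cq_ref + dcq))
    return pd.DataFrame(rows, columns=["sample_id", "genotype", "gene", "cq"])
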