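"""Shared container types for the repression-motif pipeline.

These are deliberately lightweight dataclasses; tabular data (plate reads,
n-gram tallies, Cq tables) travels as tidy :class:`pandas.DataFrame` objects
whose required columns are documented on the functions that consume them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: The 20 standard amino-acid one-letter codes.
STANDARD_AA: str = "ACDEFGHIKLMNPQRSTVWY"

#: Names of the two shared controls every assayed library carries.
GAL4_ID = "Gal4"
SRDX_ID = "SRDX"

#: Ordinal strength classes, weakest first; index+1 is the ordinal code.
CLASS_ORDER: tuple[str, ...] = ("weak", "moderate", "strong", "strongest")


class ParameterError(ValueError):
    """An argument violated a documented precondition."""


class MissingControlError(ValueError):
    """A required control construct (Gal4 / SRDX) is absent."""


class DegenerateControlsError(ValueError):
    """Controls cannot anchor a normalization (e.g. Gal4 mean <= SRDX mean)."""


@dataclass(frozen=True)
class Motif:
    """A peptide repression motif with optional simulation ground truth.

    ``true_strength`` is the fraction of GFP reduction the motif causes in a
    noise-free assay: 1.0 is complete repression, 0.0 is the Gal4 baseline and
    negative values denote activation (bounded below at -0.6).
    """

    id: str
    sequence: str
    library: str = "naturalEAR"
    true_strength: Optional[float] = None
    predicted_class: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParameterError(f"motif {self.id!r} has an empty sequence")
        if len(self.sequence) > 60:
            raise ParameterError(f"motif {self.id!r} longer than 60 aa")
        bad = set(self.sequence) - set(STANDARD_AA)
        if bad:
            raise ParameterError(
                f"motif {self.id!r} contains non-standard residues {sorted(bad)}"
            )
        if self.true_strength is not None and not (-0.6 <= self.true_strength <= 1.0):
            raise ParameterError(
                f"motif {self.id!r} true_strength {self.true_strength} outside [-0.6, 1]"
            )


@dataclass(frozen=True)
class GroundTruthModel:
    """Planted-effect model behind the simulated reporter assay.

    Strong grams lower (repress) and weak grams raise (activate) reporter
    output; each occurrence contributes ``-effect_size`` or ``+effect_size``
    to a net score that a logistic link maps onto the observed range of
    repression strengths. Noise standard deviations act on the natural-log
    fluorescence scale.
    """

    strong_grams: frozenset[str]
    weak_grams: frozenset[str]
    effect_size: float
    baseline_log_fluor: float
    tech_noise_sd: float
    bio_noise_sd: float
    seed: int
    alphabet: str = STANDARD_AA

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ParameterError("effect_size must be >= 0")
        if self.tech_noise_sd < 0 or self.bio_noise_sd < 0:
            raise ParameterError("noise standard deviations must be >= 0")
        if self.strong_grams & self.weak_grams:
            raise ParameterError("strong and weak gram sets must be disjoint")
        for g in self.strong_grams | self.weak_grams:
            if len(g) not in (2, 3, 4):
                raise ParameterError(f"planted gram {g!r} must have length 2-4")
            if set(g) - set(self.alphabet):
                raise ParameterError(f"planted gram {g!r} outside alphabet")


@dataclass
class ConstructSummary:
    """Per-construct summary of the fluorescence assay.

    ``relative_gfp`` is fluorescence relative to the Gal4-only control mean;
    a construct is a repressor when it reduces GFP by at least half, i.e.
    relative_gfp <= 0.5. ``normalized_score`` maps Gal4 to 0 and SRDX to 1.
    """

    construct_id: str
    bio_values: list[float]
    mean_fluor: float
    sem: Optional[float]
    relative_gfp: float
    is_repressor: bool
    is_activator: bool = False
    normalized_score: Optional[float] = None

    @property
    def strength(self) -> float:
        """Repression strength, 1 - relative GFP."""
        return 1.0 - self.relative_gfp


@dataclass(frozen=True)
class CanonicalScan:
    """Presence of the two canonical EAR patterns in one sequence."""

    construct_id: str
    has_LxLxL: bool
    has_DLNxxP: bool

    @property
    def has_both(self) -> bool:
        return self.has_LxLxL and self.has_DLNxxP


@dataclass(frozen=True)
class QuartilePartition:
    """Constructs split into four strength quartiles, Q1 strongest."""

    groups: tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...], tuple[str, ...]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.groups:
            if seen & set(g):
                raise ParameterError("quartile groups must be disjoint")
            seen |= set(g)
        sizes = [len(g) for g in self.groups]
        if max(sizes) - min(sizes) > 1:
            raise ParameterError("quartile sizes may differ by at most 1")

    @property
    def all_ids(self) -> set[str]:
        return {cid for g in self.groups for cid in g}


@dataclass
class NullComparison:
    """Summary of one null model (permutation or random-guess bootstrap)."""

    accuracies: np.ndarray
    real_accuracy: float
    null_mean: float
    null_sd: float
    percentile_outperformed: float  # percent of null runs strictly below real
    p_two_tailed_empirical: float
    p_two_tailed_normal: float
    n_iterations: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "real_accuracy": self.real_accuracy,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "percentile_outperformed": self.percentile_outperformed,
            "p_two_tailed_empirical": self.p_two_tailed_empirical,
            "p_two_tailed_normal": self.p_two_tailed_normal,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
        }


@dataclass
class EvalResult:
    """Confusion-matrix evaluation of predicted vs observed strength class."""

    thresholds: tuple[float, float, float]
    confusion: np.ndarray  # rows = predicted class 1..4, cols = observed
    accuracy: float
    n: int
    seed: int
    permutation: Optional[NullComparison] = None
    bootstrap: Optional[NullComparison] = None

    def to_dict(self) -> dict:
        out = {
            "thresholds": list(self.thresholds),
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "n": self.n,
            "seed": self.seed,
        }
        if self.permutation is not None:
            out["permutation"] = self.permutation.to_dict()
        if self.bootstrap is not None:
            out["bootstrap"] = self.bootstrap.to_dict()
        return out


@dataclass(frozen=True)
class SynEARSpec:
    """Recipe for a synthetic EAR library.

    ``counts`` maps each predicted class to the number of motifs to generate;
    ``length_source`` is the empirical length list of the natural library from
    which non-"strongest" lengths are resampled; "strongest" lengths are the
    resampled lengths scaled by ``strongest_factor`` and rounded.
    """

    counts: dict[str, int]
    length_source: tuple[int, ...]
    strongest_factor: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.length_source:
            raise ParameterError("length_source must be non-empty")
        for cls, k in self.counts.items():
            if cls not in CLASS_ORDER:
                raise ParameterError(f"unknown class {cls!r}")
            if k < 0:
                raise ParameterError("class counts must be >= 0")
        if min(self.length_source) < 2:
            raise ParameterError("lengths must be >= 2")


@dataclass
class IdentityMatrix:
    """Symmetric pairwise percent-identity matrix over a set of sequences."""

    ids: list[str]
    identity: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.identity.shape != (n, n):
            raise ParameterError("identity matrix shape does not match ids")


@dataclass
class LengthStrengthResult:
    """Per-length repression-strength box statistics plus rank correlation."""

    table: "object"  # pandas DataFrame: length, n, q25, median, q75
    spearman_rho: Optional[float]
    spearman_p: Optional[float]
    n: int
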