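"""Per-allele percentile rescaling of binding scores and combined models.

Predicted 1-log50k binding affinities differ systematically between
alleles, so before combining them with structural features each allele's
scores are divided by the score exceeded by a small top fraction
(default 1%) of a large random natural-peptide background for that allele
("Rescaled01").  The combined ligand-likelihood score is additive:

    x = rescaled + alpha * feature_mean              (single feature)
    x = rescaled + alpha * coil_mean + beta * rsa_mean  (coil + RSA)

with the binding term's weight fixed at 1; any monotone reparameterization
yields identical ROC results.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from mhc2lig.data_io import ValidationError, normalize_allele

#: Background amino-acid frequencies of natural proteins
#: (Robinson & Robinson-style composition; normalized at import).
NATURAL_AA_FREQUENCIES: dict[str, float] = {
    "A": 0.078, "R": 0.051, "N": 0.045, "D": 0.053, "C": 0.019,
    "Q": 0.043, "E": 0.063, "G": 0.072, "H": 0.023, "I": 0.053,
    "L": 0.091, "K": 0.059, "M": 0.023, "F": 0.039, "P": 0.052,
    "S": 0.068, "T": 0.059, "W": 0.014, "Y": 0.032, "V": 0.066,
}
_total = sum(NATURAL_AA_FREQUENCIES.values())
NATURAL_AA_FREQUENCIES = {a: f / _total for a, f in NATURAL_AA_FREQUENCIES.items()}

COMBINED_FEATURES = ("rsa", "coil", "helix", "strand", "coil+rsa")


def percentile_threshold(background_scores, percentile: float = 1.0) -> float:
    """Score exceeded by exactly ``percentile`` percent of the background.

    This is the ``100 - percentile`` percentile of the score distribution,
    computed with linear interpolation between order statistics.
    """
    scores = np.asarray(background_scores, dtype=float)
    if scores.size == 0:
        raise ValidationError("background score set is empty")
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    return float(np.percentile(scores, 100.0 - percentile))


@dataclass(frozen=True)
class AlleleScaler:
    """Per-allele rescaling anchor for 1-log50k binding scores."""

    allele: str
    percentile: float
    threshold: float
    background_size: int

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValidationError(
                f"scaler for {self.allele}: threshold must be positive, "
                f"got {self.threshold}"
            )

    @classmethod
    def from_background(cls, allele: str, background_scores,
                        percentile: float = 1.0) -> "AlleleScaler":
        scores = np.asarray(background_scores, dtype=float)
        return cls(
            allele=normalize_allele(allele),
            percentile=percentile,
            threshold=percentile_threshold(scores, percentile),
            background_size=int(scores.size),
        )


def rescale_scores(scores, scaler: AlleleScaler) -> np.ndarray:
    """Divide binding scores by the allele's percentile threshold.

    No clipping: rescaled values above 1 are legitimate (scores stronger
    than the background anchor).  The transform is a positive scalar, so
    any single-allele ROC curve is unchanged by rescaling.
    """
    if scaler.threshold <= 0:
        raise ValidationError("scaler threshold must be positive")
    return np.asarray(scores, dtype=float) / scaler.threshold


def build_scalers(backgrounds: dict[str, np.ndarray],
                  percentile: float = 1.0) -> dict[str, AlleleScaler]:
    """One :class:`AlleleScaler` per allele from background score lists."""
    return {
        allele: AlleleScaler.from_background(allele, scores, percentile)
        for allele, scores in backgrounds.items()
    }


@dataclass(frozen=True)
class ModelWeights:
    """Weights of the combined ligand-likelihood score."""

    feature: str
    alpha: float = 0.0
    beta: float = 0.0

    def __post_init__(self) -> None:
        if self.feature not in COMBINED_FEATURES:
            raise ValueError(
                f"feature must be one of {COMBINED_FEATURES}, got {self.feature!r}"
            )
        for name, w in (("alpha", self.alpha), ("beta", self.beta)):
            if not np.isfinite(w) or w < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {w}")
        if self.beta != 0 and self.feature != "coil+rsa":
            raise ValueError("beta is only meaningful for feature='coil+rsa'")


def combined_score(rescaled, feature_mean, weights: ModelWeights):
    """Single-feature ligand-likelihood score ``rescaled + alpha * feature``."""
    if weights.feature == "coil+rsa":
        raise ValueError("use combined_score2 for the coil+rsa model")
    return np.asarray(rescaled, dtype=float) + \
        weights.alpha * np.asarray(feature_mean, dtype=float)


def combined_score2(rescaled, coil_mean, rsa_mean, weights: ModelWeights):
    """Two-feature score ``rescaled + alpha * coil + beta * rsa``.

    Reduces to :func:`combined_score` when either weight is zero.
    """
    if weights.feature != "coil+rsa":
        raise ValueError("combined_score2 requires feature='coil+rsa'")
    return (np.asarray(rescaled, dtype=float)
            + weights.alpha * np.asarray(coil_mean, dtype=float)
            + weights.beta * np.asarray(rsa_mean, dtype=float))


# ---------------------------------------------------------------------------
# Scaler table I/O
# ---------------------------------------------------------------------------

_SCALER_COLUMNS = ["allele", "percentile", "threshold", "background_size"]


def write_scalers(scalers: dict[str, AlleleScaler], path: str | Path) -> None:
    df = pd.DataFrame(
        [(s.allele, s.percentile, s.threshold, s.background_size)
         for s in scalers.values()],
        columns=_SCALER_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_scalers(path: str | Path) -> dict[str, AlleleScaler]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _SCALER_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    return {
        normalize_allele(str(r.allele)): AlleleScaler(
            allele=normalize_allele(str(r.allele)),
            percentile=float(r.percentile),
            threshold=float(r.threshold),
            background_size=int(r.background_size),
        )
        for r in df.itertuples(index=False)
    }
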