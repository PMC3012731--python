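"""Per protein-ligand-pair ROC evaluation, grid search and cross-validation.

For each protein-ligand pair the source protein is tiled at the ligand's
length, all windows except the annotated ligand are negatives, and the
pair contributes one AUC and one AUC0.1 value.  AUC0.1 is the partial
ROC area up to a false-positive rate of 0.1 (specificity 0.9), linearly
interpolated at FPR = 0.1 and normalized by 0.1 so a perfect classifier
scores 1.  Dataset performance is the unweighted mean over pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from mhc2lig.data_io import ValidationError
from mhc2lig.scaling_model import AlleleScaler, ModelWeights
from mhc2lig.window_features import PairWindows

DEFAULT_GRID = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2))


# ---------------------------------------------------------------------------
# ROC primitives
# ---------------------------------------------------------------------------

def roc_points(scores, labels) -> np.ndarray:
    """ROC curve as an array of (FPR, TPR) vertices.

    Thresholds descend along the curve; tied scores are collapsed into a
    single step so that the trapezoidal area equals the Mann-Whitney
    statistic with ties counted 1/2.  The curve starts at (0, 0) and ends
    at (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError(
            "ROC requires at least one positive and one negative label"
        )
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # last index of each tied block of scores
    last = np.nonzero(np.append(np.diff(s) != 0, True))[0]
    tp = np.cumsum(y)[last]
    fp = np.cumsum(~y)[last]
    fpr = np.concatenate(([0.0], fp / n_neg))
    tpr = np.concatenate(([0.0], tp / n_pos))
    return np.column_stack([fpr, tpr])


def auc(curve: np.ndarray) -> float:
    """Trapezoidal area under a ROC curve from :func:`roc_points`."""
    curve = np.asarray(curve, dtype=float)
    return float(np.trapezoid(curve[:, 1], curve[:, 0]))


def auc01(curve: np.ndarray, fpr_max: float = 0.1) -> float:
    """Partial ROC area up to ``fpr_max``, normalized to [0, 1].

    The TPR at ``fpr_max`` is linearly interpolated between the bracketing
    ROC vertices, and the partial area is divided by ``fpr_max`` so that a
    perfect classifier scores 1.
    """
    curve = np.asarray(curve, dtype=float)
    fpr, tpr = curve[:, 0], curve[:, 1]
    if fpr_max <= 0 or fpr_max > 1:
        raise ValueError("fpr_max must be in (0, 1]")
    mask = fpr <= fpr_max
    x = fpr[mask]
    y = tpr[mask]
    if x[-1] < fpr_max:
        # fpr_max strictly inside a segment: interpolate the bracketing
        # vertices (a vertical jump exactly at fpr_max has zero width and
        # is excluded from the partial area)
        tpr_at = float(np.interp(fpr_max, fpr, tpr))
        x = np.concatenate([x, [fpr_max]])
        y = np.concatenate([y, [tpr_at]])
    return float(np.trapezoid(y, x) / fpr_max)


def auc_from_scores(scores, labels) -> float:
    return auc(roc_points(scores, labels))


def auc01_from_scores(scores, labels, fpr_max: float = 0.1) -> float:
    return auc01(roc_points(scores, labels), fpr_max)


# ---------------------------------------------------------------------------
# Pair-level evaluation
# ---------------------------------------------------------------------------

@dataclass
class PairData:
    """Numeric view of one protein-ligand pair for fast scoring."""

    protein_id: str
    ligand_id: str
    allele: str
    rescaled: np.ndarray
    raw: np.ndarray
    features: dict[str, np.ndarray]
    labels: np.ndarray

    @classmethod
    def from_windows(cls, pair: PairWindows,
                     scalers: dict[str, AlleleScaler] | None = None,
                     ) -> "PairData":
        """Extract score/feature arrays; rescales if scalers are given."""
        raw = np.array([w.score_1log50k for w in pair.windows])
        if scalers is not None:
            if pair.allele not in scalers:
                raise ValidationError(f"no scaler for allele {pair.allele!r}")
            rescaled = raw / scalers[pair.allele].threshold
        else:
            rescaled = raw.copy()
        return cls(
            protein_id=pair.protein_id,
            ligand_id=pair.ligand_id,
            allele=pair.allele,
            rescaled=rescaled,
            raw=raw,
            features={
                "rsa": np.array([w.mean_rsa for w in pair.windows]),
                "helix": np.array([w.mean_helix for w in pair.windows]),
                "strand": np.array([w.mean_strand for w in pair.windows]),
                "coil": np.array([w.mean_coil for w in pair.windows]),
            },
            labels=np.array([w.is_ligand for w in pair.windows], dtype=bool),
        )


def model_scores(pair: PairData, weights: ModelWeights) -> np.ndarray:
    """Combined ligand-likelihood scores for every window of a pair."""
    if weights.feature == "coil+rsa":
        return (pair.rescaled
                + weights.alpha * pair.features["coil"]
                + weights.beta * pair.features["rsa"])
    return pair.rescaled + weights.alpha * pair.features[weights.feature]


def evaluate_pair(pair: PairData, weights: ModelWeights) -> tuple[float, float]:
    """(AUC, AUC0.1) of the combined model on one pair."""
    if not pair.labels.any():
        raise ValidationError(f"pair {pair.ligand_id!r}: ligand window missing")
    curve = roc_points(model_scores(pair, weights), pair.labels)
    return auc(curve), auc01(curve)


@dataclass
class BenchmarkResult:
    """Per-pair AUC / AUC0.1 records with dataset means."""

    records: list[tuple[str, str, str, float, float]]
    mean_auc: float
    mean_auc01: float

    @property
    def n_pairs(self) -> int:
        return len(self.records)

    @property
    def auc01_values(self) -> np.ndarray:
        return np.array([r[4] for r in self.records])

    @property
    def auc_values(self) -> np.ndarray:
        return np.array([r[3] for r in self.records])


def evaluate_dataset(pairs: list[PairData],
                     weights: ModelWeights) -> BenchmarkResult:
    """Unweighted per-pair mean AUC and AUC0.1 over the dataset."""
    if not pairs:
        raise ValidationError("evaluate_dataset requires at least one pair")
    records = []
    for pair in pairs:
        a, a01 = evaluate_pair(pair, weights)
        records.append((pair.protein_id, pair.ligand_id, pair.allele, a, a01))
    return BenchmarkResult(
        records=records,
        mean_auc=float(np.mean([r[3] for r in records])),
        mean_auc01=float(np.mean([r[4] for r in records])),
    )


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

@dataclass
class GridSearchResult:
    grid: list[ModelWeights]
    objective: list[float]
    best_weights: ModelWeights
    best_objective: float


def _mean_auc01(pairs: list[PairData], weights: ModelWeights) -> float:
    return float(np.mean([
        auc01_from_scores(model_scores(p, weights), p.labels) for p in pairs
    ]))


def grid_search(pairs: list[PairData], feature: str,
                alphas=DEFAULT_GRID, betas=None) -> GridSearchResult:
    """Brute-force search for the weights maximizing mean AUC0.1.

    Ties are broken toward the smallest weights (alpha first, then beta),
    so an uninformative feature yields alpha = 0.
    """
    if feature == "coil+rsa":
        if betas is None:
            betas = DEFAULT_GRID
        grid = [ModelWeights(feature, float(a), float(b))
                for a in sorted(alphas) for b in sorted(betas)]
        # sort so ties resolve toward smallest (alpha, beta)
        grid.sort(key=lambda w: (w.alpha, w.beta))
    else:
        grid = [ModelWeights(feature, float(a)) for a in sorted(alphas)]
    if not grid:
        raise ValueError("grid must be non-empty")
    objective = [_mean_auc01(pairs, w) for w in grid]
    best_i = 0
    for i in range(1, len(grid)):
        if objective[i] > objective[best_i]:
            best_i = i
    return GridSearchResult(
        grid=grid,
        objective=objective,
        best_weights=grid[best_i],
        best_objective=objective[best_i],
    )


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CrossValResult:
    k: int
    fold_alphas: list[float]
    fold_auc01: list[float]
    pooled_auc01: float
    alpha_mean: float
    alpha_sd: float
    fold_assignment: list[int] = field(default_factory=list)


def cross_validate(pairs: list[PairData], feature: str, k: int = 5,
                   seed: int = 0, alphas=DEFAULT_GRID) -> CrossValResult:
    """k-fold cross-validation of the single-feature combined model.

    Pairs are partitioned at random into k near-equal folds (seeded).  For
    each fold, alpha is fitted by grid search on the other k-1 folds and
    the held-out fold is evaluated with it.  The pooled AUC0.1 is the
    unweighted mean over all pairs of their held-out AUC0.1.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(pairs) < k:
        raise ValidationError(f"fewer pairs ({len(pairs)}) than folds ({k})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pairs))
    assignment = np.empty(len(pairs), dtype=int)
    for fold, chunk in enumerate(np.array_split(perm, k)):
        assignment[chunk] = fold
    fold_alphas, fold_auc01 = [], []
    held_out_scores = np.empty(len(pairs))
    for fold in range(k):
        train = [p for p, f in zip(pairs, assignment) if f != fold]
        test_idx = [i for i, f in enumerate(assignment) if f == fold]
        best = grid_search(train, feature, alphas=alphas).best_weights
        per_pair = [
            auc01_from_scores(model_scores(pairs[i], best), pairs[i].labels)
            for i in test_idx
        ]
        held_out_scores[test_idx] = per_pair
        fold_alphas.append(best.alpha)
        fold_auc01.append(float(np.mean(per_pair)))
    fold_alphas_arr = np.array(fold_alphas)
    return CrossValResult(
        k=k,
        fold_alphas=fold_alphas,
        fold_auc01=fold_auc01,
        pooled_auc01=float(np.mean(held_out_scores)),
        alpha_mean=float(fold_alphas_arr.mean()),
        alpha_sd=float(fold_alphas_arr.std(ddof=1)),
        fold_assignment=assignment.tolist(),
    )


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

def paired_model_test(auc01_a, auc01_b) -> tuple[float, float]:
    """Paired two-sided t-test on per-pair AUC0.1 values of two models."""
    a = np.asarray(auc01_a, dtype=float)
    b = np.asarray(auc01_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired lists must have equal length")
    if a.size < 2:
        raise ValidationError("paired test requires at least 2 pairs")
    diff = a - b
    if np.all(diff == 0):
        raise ValidationError("degenerate pairing: all differences are zero")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
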