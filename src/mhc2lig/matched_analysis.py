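"""Affinity-matched ligand/non-ligand pairing and statistical comparison.

For every protein-ligand pair, the candidate non-ligands are the windows
of the same protein (same allele, same length) that do not overlap the
ligand and whose predicted 1-log50k binding score lies within a relative
tolerance (default +/-5%) of the ligand's.  Optionally the pool must
bracket the ligand score (contain at least one stronger and one weaker
candidate) or the ligand is dropped.  One candidate is then drawn at
random (seeded), and the resulting matched pairs are compared feature by
feature with paired t-tests, plus exact binomial tests for glycosylation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from mhc2lig.data_io import ValidationError
from mhc2lig.window_features import PairWindows, PeptideWindow

#: window-feature attribute per reported comparison row
FEATURE_ATTRS = {
    "helix": "mean_helix",
    "strand": "mean_strand",
    "coil": "mean_coil",
    "rsa": "mean_rsa",
    "1-log50k": "score_1log50k",
}


@dataclass(frozen=True)
class MatchedPair:
    """A ligand window paired with an affinity-matched non-ligand window."""

    ligand: PeptideWindow
    nonligand: PeptideWindow

    def __post_init__(self) -> None:
        if self.ligand.protein_id != self.nonligand.protein_id:
            raise ValidationError("matched windows must share a protein")
        if self.ligand.allele != self.nonligand.allele:
            raise ValidationError("matched windows must share an allele")
        if self.ligand.length != self.nonligand.length:
            raise ValidationError("matched windows must have equal length")
        if self.ligand.overlaps(self.nonligand):
            raise ValidationError("matched windows must not overlap")


def candidate_nonligands(pair: PairWindows, tolerance: float = 0.05,
                         require_bracketing: bool = True,
                         ) -> list[PeptideWindow]:
    """Affinity-matched non-ligand candidates for one protein-ligand pair.

    Candidates are non-ligand windows whose score lies in
    ``[(1 - tol) * a, (1 + tol) * a]`` where ``a`` is the ligand's score,
    excluding any window sharing a residue position with the ligand.  With
    ``require_bracketing`` the pool is returned only if it contains at
    least one strictly stronger and one strictly weaker candidate than the
    ligand; otherwise it is empty.  An empty list is a valid outcome
    (very strong binders typically have no candidate within -5%).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    lig = pair.ligand_window
    a = lig.score_1log50k
    lo, hi = (1.0 - tolerance) * a, (1.0 + tolerance) * a
    pool = [
        w for w in pair.windows
        if not w.is_ligand and not w.overlaps(lig) and lo <= w.score_1log50k <= hi
    ]
    if require_bracketing:
        has_weaker = any(w.score_1log50k < a for w in pool)
        has_stronger = any(w.score_1log50k > a for w in pool)
        if not (has_weaker and has_stronger):
            return []
    return pool


def select_matched_pair(ligand: PeptideWindow,
                        candidates: list[PeptideWindow],
                        rng: np.random.Generator | int,
                        ) -> MatchedPair | None:
    """Uniform seeded draw of one candidate; None when the pool is empty."""
    if not candidates:
        return None
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    chosen = candidates[int(rng.integers(len(candidates)))]
    return MatchedPair(ligand=ligand, nonligand=chosen)


@dataclass
class MatchFunnel:
    """Accounting of how many ligands survive each matching step."""

    n_ligands: int = 0
    n_with_tolerance_pool: int = 0
    n_matched: int = 0

    @property
    def n_dropped(self) -> int:
        return self.n_ligands - self.n_matched


def match_dataset(pairs: list[PairWindows], tolerance: float = 0.05,
                  require_bracketing: bool = True, seed: int = 0,
                  ) -> tuple[list[MatchedPair], MatchFunnel]:
    """Draw one matched non-ligand per ligand where the criteria allow.

    Returns the matched pairs and a funnel recording how many ligands had
    a non-empty tolerance pool and how many ended up matched.
    """
    rng = np.random.default_rng(seed)
    funnel = MatchFunnel(n_ligands=len(pairs))
    matched = []
    for pair in pairs:
        tol_pool = candidate_nonligands(pair, tolerance, require_bracketing=False)
        if tol_pool:
            funnel.n_with_tolerance_pool += 1
        pool = candidate_nonligands(pair, tolerance, require_bracketing)
        mp = select_matched_pair(pair.ligand_window, pool, rng)
        if mp is not None:
            matched.append(mp)
    funnel.n_matched = len(matched)
    return matched, funnel


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedTestResult:
    mean_x: float
    sd_x: float
    mean_y: float
    sd_y: float
    t: float
    p: float
    n: int


def paired_t_test(x, y) -> PairedTestResult:
    """Classical two-sided paired t-test against zero mean difference.

    Standard deviations are sample SDs (n - 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValidationError("paired t-test requires at least 2 pairs")
    diff = x - y
    if np.allclose(diff.std(ddof=1), 0.0):
        raise ValidationError("degenerate pairing: zero variance of differences")
    t, p = stats.ttest_rel(x, y)
    return PairedTestResult(
        mean_x=float(x.mean()), sd_x=float(x.std(ddof=1)),
        mean_y=float(y.mean()), sd_y=float(y.std(ddof=1)),
        t=float(t), p=float(p), n=int(x.size),
    )


def binomial_test(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p-value: ``2 * min(P(X<=k), P(X>=k))`` capped at 1."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, n], got k={k}, n={n}")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    lower = stats.binom.cdf(k, n, p0)
    upper = stats.binom.sf(k - 1, n, p0)
    return float(min(1.0, 2.0 * min(lower, upper)))


@dataclass
class GlycComparison:
    ligand_count: int
    nonligand_count: int
    p: float | None  # None when no window of either side is glycosylated


@dataclass
class ComparisonReport:
    """Feature-wise ligand vs non-ligand comparison over matched pairs."""

    n_pairs: int
    features: dict[str, PairedTestResult]
    glycosylation: dict[str, GlycComparison] = field(default_factory=dict)


def compare_features(pairs: list[MatchedPair]) -> ComparisonReport:
    """Paired comparison of structure, exposure, binding and glycosylation.

    Features compared: helix, strand, helix+strand, coil, RSA and the
    1-log50k binding score (paired t-tests; within matched pairs the
    binding means are near-equal by construction).  Glycosylation is
    compared with exact binomial tests (p0 = 0.5) on the counts of
    glycosylated ligands vs glycosylated non-ligands, per type (N, O)
    and overall.
    """
    if len(pairs) < 2:
        raise ValidationError("compare_features requires at least 2 pairs")
    lig = {name: np.array([getattr(p.ligand, attr) for p in pairs])
           for name, attr in FEATURE_ATTRS.items()}
    non = {name: np.array([getattr(p.nonligand, attr) for p in pairs])
           for name, attr in FEATURE_ATTRS.items()}
    lig["helix+strand"] = lig["helix"] + lig["strand"]
    non["helix+strand"] = non["helix"] + non["strand"]
    order = ["helix", "strand", "helix+strand", "coil", "rsa", "1-log50k"]
    features = {name: paired_t_test(lig[name], non[name]) for name in order}

    glyc: dict[str, GlycComparison] = {}
    for label, pred in (
        ("nglyc", lambda w: w.glyc_n >= 1),
        ("oglyc", lambda w: w.glyc_o >= 1),
        ("any", lambda w: w.is_glycosylated),
    ):
        k = sum(pred(p.ligand) for p in pairs)
        m = sum(pred(p.nonligand) for p in pairs)
        p_val = binomial_test(k, k + m) if k + m > 0 else None
        glyc[label] = GlycComparison(ligand_count=k, nonligand_count=m, p=p_val)
    return ComparisonReport(n_pairs=len(pairs), features=features,
                            glycosylation=glyc)
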