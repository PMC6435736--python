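"""Benchmarking statistics for disorder predictions against Z-scores.

A predictor is scored against per-residue Z-scores along three axes:

* continuous agreement — Pearson (R_P) and Spearman (R_S) correlation of
  estimated disorder probability p with Z (negative is good: Z measures
  order, p measures disorder);
* binary classification at Z < 8 — ROC curve and AUC, confusion counts,
  MCC, false-positive/negative rates;
* bias decomposition — the mean predicted probability over disordered
  (pZL, Z < 8) and ordered (pZH, Z > 8) residues; their average
  pZA = (pZL+pZH)/2 is the predictor's bias (0.5 = unbiased) and their
  difference pZD = pZL-pZH its discrimination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DisorderPrediction, ZScoreProfile
from .errors import PairingError

#: Z-score below which a residue counts as disordered
DEFAULT_Z_THRESHOLD = 8.0

#: probability cutoff for predicted-disordered in the confusion analysis
DEFAULT_P_CUTOFF = 0.5

#: pZA bounds of the unbiased range
PZA_UNDER, PZA_OVER = 0.3, 0.7


@dataclass
class PairedScores:
    """Aligned (Z, p) vectors over the residues shared by both profiles."""

    z: np.ndarray
    p: np.ndarray
    entry_id: str = ""
    method_name: str = ""
    is_binary: bool = False

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.z.shape != self.p.shape:
            raise ValueError("z and p must have equal length")

    def __len__(self) -> int:
        return len(self.z)


@dataclass
class ConfusionCounts:
    """2x2 counts with positive class = disordered (Z below threshold)."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class ConfusionResult:
    counts: ConfusionCounts
    mcc: float
    fpr: float
    fnr: float
    tpr: float


@dataclass
class BiasMetrics:
    """Bias/discrimination decomposition of a predictor.

    pZL/pZH are mean predicted probabilities over low-Z (disordered) and
    high-Z (ordered) residues; pZA = (pZL+pZH)/2, pZD = pZL-pZH.
    """

    pZL: float
    pZH: float
    pZA: float
    pZD: float
    nL: int
    nH: int


@dataclass
class BenchmarkResult:
    """One method's full metric row (the per-predictor performance record)."""

    method_name: str
    n: int
    r_p: float | None
    r_s: float | None
    auc: float | None
    confusion: ConfusionCounts
    mcc: float
    fpr: float
    fnr: float
    bias: BiasMetrics | None
    is_binary: bool = False


def pair_scores(z: ZScoreProfile, pred: DisorderPrediction) -> PairedScores:
    """Intersect a Z-score profile and a prediction on residue number.

    Residues present in only one profile are excluded; an empty
    intersection raises :class:`PairingError`.
    """
    common, zi, pi = np.intersect1d(
        z.residue_numbers, pred.residue_numbers, return_indices=True
    )
    if common.size == 0:
        raise PairingError(
            f"{z.entry_id}/{pred.method_name}: no shared residue numbers"
        )
    return PairedScores(
        z=z.z[zi],
        p=pred.p[pi],
        entry_id=z.entry_id,
        method_name=pred.method_name,
        is_binary=pred.is_binary,
    )


def pool_scores(scores: list[PairedScores]) -> PairedScores:
    """Concatenate paired scores across proteins (residue-pooled mode)."""
    if not scores:
        raise PairingError("nothing to pool")
    return PairedScores(
        z=np.concatenate([s.z for s in scores]),
        p=np.concatenate([s.p for s in scores]),
        entry_id="pooled",
        method_name=scores[0].method_name,
        is_binary=all(s.is_binary for s in scores),
    )


def _constant(x: np.ndarray) -> bool:
    return np.all(x == x[0])


def pearson(scores: PairedScores) -> float | None:
    """Pearson correlation R_P of (p, Z); None (n.a.) if either is constant.

    Sign is preserved: -1 is a perfect predictor, 0 no correlation.
    """
    if len(scores) < 3 or _constant(scores.z) or _constant(scores.p):
        warnings.warn(
            f"{scores.method_name}: Pearson undefined (constant or too short)"
        )
        return None
    return float(stats.pearsonr(scores.p, scores.z)[0])


def spearman(scores: PairedScores) -> float | None:
    """Spearman rank correlation R_S; n.a. for binary predictors by policy."""
    if scores.is_binary:
        return None
    if len(scores) < 3 or _constant(scores.z) or _constant(scores.p):
        warnings.warn(
            f"{scores.method_name}: Spearman undefined (constant or too short)"
        )
        return None
    return float(stats.spearmanr(scores.p, scores.z)[0])


def binarize(z: np.ndarray, threshold: float = DEFAULT_Z_THRESHOLD) -> np.ndarray:
    """True where disordered: Z strictly below the threshold."""
    return np.asarray(z, dtype=float) < threshold


def roc_auc(
    scores: PairedScores, threshold: float = DEFAULT_Z_THRESHOLD
) -> tuple[np.ndarray | None, float | None]:
    """ROC curve and trapezoidal AUC for predicting Z < threshold from p.

    The curve is built over the unique probability values (ties grouped),
    so the trapezoidal area equals the tie-corrected Mann-Whitney
    statistic.  Returns ``(points, auc)`` with points as an (m, 2) array of
    (FPR, TPR) from (0, 0) to (1, 1); ``(None, None)`` with a warning when
    one class is empty or the predictor is binary.
    """
    if scores.is_binary:
        warnings.warn(f"{scores.method_name}: AUC not applicable to binary output")
        return None, None
    y = binarize(scores.z, threshold)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        warnings.warn(f"{scores.method_name}: one class empty, AUC undefined")
        return None, None
    order = np.argsort(-scores.p, kind="mergesort")
    p_sorted, y_sorted = scores.p[order], y[order]
    # group tied probabilities: cut where the value changes
    last_in_group = np.r_[np.nonzero(np.diff(p_sorted))[0], len(p_sorted) - 1]
    tp = np.cumsum(y_sorted)[last_in_group]
    fp = np.cumsum(~y_sorted)[last_in_group]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def confusion(
    scores: PairedScores,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    p_cutoff: float = DEFAULT_P_CUTOFF,
) -> ConfusionResult:
    """Confusion counts and summary rates at fixed cutoffs.

    A residue is predicted disordered when p >= p_cutoff and truly
    disordered when Z < z_threshold.  MCC follows the zero-marginal
    convention (0 when any marginal is empty); FPR/FNR are NaN when their
    denominator is zero.
    """
    y = binarize(scores.z, z_threshold)
    yhat = scores.p >= p_cutoff
    tp = int(np.sum(y & yhat))
    fp = int(np.sum(~y & yhat))
    tn = int(np.sum(~y & ~yhat))
    fn = int(np.sum(y & ~yhat))
    counts = ConfusionCounts(tp, fp, tn, fn)
    denom = (
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / np.sqrt(denom)
    fpr = fp / (fp + tn) if (fp + tn) else float("nan")
    fnr = fn / (fn + tp) if (fn + tp) else float("nan")
    tpr = tp / (tp + fn) if (tp + fn) else float("nan")
    return ConfusionResult(counts, float(mcc), fpr, fnr, tpr)


def bias_metrics(
    scores: PairedScores, z_threshold: float = DEFAULT_Z_THRESHOLD
) -> BiasMetrics | None:
    """Bias/discrimination decomposition pZL, pZH, pZA, pZD.

    pZL is the mean p over residues with Z strictly below the threshold,
    pZH over residues strictly above it (Z exactly at the threshold is in
    neither mean).  Returns None with a warning when either side is empty.
    """
    low = scores.z < z_threshold
    high = scores.z > z_threshold
    nL, nH = int(low.sum()), int(high.sum())
    if nL == 0 or nH == 0:
        warnings.warn(
            f"{scores.method_name}: empty {'low' if nL == 0 else 'high'}-Z side"
        )
        return None
    pZL = float(scores.p[low].mean())
    pZH = float(scores.p[high].mean())
    return BiasMetrics(pZL, pZH, (pZL + pZH) / 2.0, pZL - pZH, nL, nH)


def classify_bias(bias: BiasMetrics) -> str:
    """Bias category from pZA: under-predicting disorder below 0.3,
    over-predicting above 0.7, unbiased in between."""
    if bias.pZA < PZA_UNDER:
        return "under-predicts-disorder"
    if bias.pZA > PZA_OVER:
        return "over-predicts-disorder"
    return "unbiased-range"


def optimal_z_threshold(
    datasets: list[PairedScores],
    grid: np.ndarray | list[float],
    p_cutoffs: dict[str, float] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Z threshold maximising the mean MCC across methods.

    Each candidate threshold re-binarizes Z for every method (each at its
    configured probability cutoff) and the objective is the across-method
    mean MCC.  Ties are broken toward 8.0, then toward the smaller
    threshold.  Returns the winning threshold and the per-threshold table.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0 or not datasets:
        raise ValueError("need a nonempty grid and at least one method")
    p_cutoffs = p_cutoffs or {}
    rows = []
    for thr in grid:
        mccs = [
            confusion(
                s, z_threshold=thr,
                p_cutoff=p_cutoffs.get(s.method_name, DEFAULT_P_CUTOFF),
            ).mcc
            for s in datasets
        ]
        rows.append({"threshold": thr, "mean_mcc": float(np.mean(mccs))})
    table = pd.DataFrame(rows)
    best_obj = table["mean_mcc"].max()
    if not np.isfinite(best_obj):
        raise ValueError("objective undefined on the whole grid")
    cands = table.loc[table["mean_mcc"] == best_obj, "threshold"].to_numpy()
    # toward 8.0, then toward the smaller threshold
    cands = cands[np.lexsort((cands, np.abs(cands - 8.0)))]
    return float(cands[0]), table


def rank_methods(results: list[BenchmarkResult]) -> list[BenchmarkResult]:
    """Order methods best-first by |R_P|, tie-broken by AUC then name."""
    def key(r: BenchmarkResult):
        rp = abs(r.r_p) if r.r_p is not None else -np.inf
        auc = r.auc if r.auc is not None else -np.inf
        return (-rp, -auc, r.method_name)

    return sorted(results, key=key)


def benchmark_method(
    scores: PairedScores,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    p_cutoff: float = DEFAULT_P_CUTOFF,
) -> BenchmarkResult:
    """All metrics for one method over (pooled) paired scores."""
    conf = confusion(scores, z_threshold, p_cutoff)
    return BenchmarkResult(
        method_name=scores.method_name,
        n=len(scores),
        r_p=pearson(scores),
        r_s=spearman(scores),
        auc=roc_auc(scores, z_threshold)[1],
        confusion=conf.counts,
        mcc=conf.mcc,
        fpr=conf.fpr,
        fnr=conf.fnr,
        bias=bias_metrics(scores, z_threshold),
        is_binary=scores.is_binary,
    )
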