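"""Fit and classification statistics for woody-breast prediction models.

Implements every quantity reported alongside the candidate logistic models:
confusion-matrix rates at the most-likely (0.5) threshold, the rank-statistic
AUC, Nagelkerke's generalized R-squared, RMSE and MAD of the predicted
probability against the 0/1 outcome, the stratified 70/30 training/validation
split over tactile-score bins, and the Spearman correlation screen of the
twelve conformational measurements against the ordinal score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EvalReport",
    "evaluate",
    "evaluate_fit",
    "roc_auc",
    "nagelkerke_r2",
    "score_bin",
    "stratified_split",
    "spearman_screen",
]

_MEASUREMENTS = tuple(f"M{i}" for i in range(12))


@dataclass(frozen=True)
class EvalReport:
    """Classification and fit statistics of one model on one data split.

    Rates are percentages; ``auc`` is None when the split contains a single
    class (the ROC is undefined there, which is not the same as 0).
    """

    n: int
    tp: int
    fp: int
    tn: int
    fn: int
    mr: float
    tpr: float
    fpr: float
    specificity: float
    auc: float | None
    gen_r2: float
    rmse: float
    mad: float

    def to_dict(self) -> dict:
        d = {
            "n": self.n,
            "TP": self.tp,
            "FP": self.fp,
            "TN": self.tn,
            "FN": self.fn,
            "MR": self.mr,
            "TPR": self.tpr,
            "FPR": self.fpr,
            "specificity": self.specificity,
            "AUC": self.auc,
            "GenR2": self.gen_r2,
            "RMSE": self.rmse,
            "MAD": self.mad,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EvalReport":
        return cls(
            n=d["n"], tp=d["TP"], fp=d["FP"], tn=d["TN"], fn=d["FN"],
            mr=d["MR"], tpr=d["TPR"], fpr=d["FPR"],
            specificity=d["specificity"], auc=d["AUC"],
            gen_r2=d["GenR2"], rmse=d["RMSE"], mad=d["MAD"],
        )


def roc_auc(y: np.ndarray, p: np.ndarray) -> float:
    """AUC by the Mann–Whitney rank statistic, counting ties as 1/2.

    Equivalent to the proportion of (positive, negative) pairs in which the
    positive case receives the higher score.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(p)  # average ranks on ties
    r1 = ranks[y == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def nagelkerke_r2(y: np.ndarray, p: np.ndarray) -> float:
    """Nagelkerke's generalized R² of predicted probabilities on a split.

    Uses the split's own marginal prevalence for the null likelihood, so a
    validation split is scored against its own base rate.  Floored at 0
    (a fit worse than the null carries no explanatory power).
    """
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), 1e-12, 1.0 - 1e-12)
    n = len(y)
    pbar = y.mean()
    if pbar in (0.0, 1.0):
        return math.nan
    ll1 = float(y @ np.log(p) + (1.0 - y) @ np.log(1.0 - p))
    ll0 = float(n * (pbar * math.log(pbar) + (1 - pbar) * math.log(1 - pbar)))
    r2_cs = 1.0 - math.exp(2.0 * (ll0 - ll1) / n)
    denom = 1.0 - math.exp(2.0 * ll0 / n)
    return max(0.0, r2_cs / denom)


def evaluate(y, p, threshold: float = 0.5) -> EvalReport:
    """Score predicted probabilities ``p`` against 0/1 outcomes ``y``.

    MR, TPR (sensitivity), FPR and specificity are percentages from the
    confusion matrix at ``threshold``; AUC, Nagelkerke GenR², RMSE and MAD
    are computed on the probability scale.
    """
    y = np.asarray(y, dtype=float).ravel()
    p = np.asarray(p, dtype=float).ravel()
    if len(y) == 0:
        raise ValueError("empty split")
    if len(y) != len(p):
        raise ValueError("y and p lengths differ")
    yhat = p >= threshold
    pos = y == 1
    tp = int(np.sum(yhat & pos))
    fp = int(np.sum(yhat & ~pos))
    fn = int(np.sum(~yhat & pos))
    tn = int(np.sum(~yhat & ~pos))
    n = len(y)
    n1, n0 = tp + fn, fp + tn
    mr = 100.0 * (fp + fn) / n
    tpr = 100.0 * tp / n1 if n1 else math.nan
    fpr = 100.0 * fp / n0 if n0 else math.nan
    auc = roc_auc(y, p) if (n1 and n0) else None
    return EvalReport(
        n=n,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        mr=mr,
        tpr=tpr,
        fpr=fpr,
        specificity=100.0 - fpr if not math.isnan(fpr) else math.nan,
        auc=auc,
        gen_r2=nagelkerke_r2(y, p) if (n1 and n0) else math.nan,
        rmse=float(np.sqrt(np.mean((y - p) ** 2))),
        mad=float(np.mean(np.abs(y - p))),
    )


def evaluate_fit(results, data: pd.DataFrame, response: str = "wb_binary") -> EvalReport:
    """Evaluate a fitted :class:`~wbconform.logit.BinaryLogitResults` on a split."""
    return evaluate(data[response].to_numpy(dtype=float), results.predict(data))


# ---------------------------------------------------------------------------
# stratified split over tactile-score bins

#: the four ordinal-score strata used for the 70/30 split
SCORE_BINS = ((0.0, 0.5), (1.0, 1.5), (2.0, 2.5), (3.0,))


def score_bin(score) -> np.ndarray:
    """Map tactile scores to stratum index 0..3 ({0,.5}, {1,1.5}, {2,2.5}, {3})."""
    s = np.asarray(score, dtype=float)
    out = np.full(s.shape, -1, dtype=int)
    out[s <= 0.5] = 0
    out[(s >= 1.0) & (s <= 1.5)] = 1
    out[(s >= 2.0) & (s <= 2.5)] = 2
    out[s >= 3.0] = 3
    return out


def _stratum_train_counts(sizes: np.ndarray, frac: float) -> np.ndarray:
    """Largest-remainder apportionment of round(frac*n) across strata."""
    sizes = np.asarray(sizes, dtype=int)
    target = int(round(frac * sizes.sum()))
    exact = frac * sizes
    base = np.floor(exact).astype(int)
    deficit = target - base.sum()
    order = np.argsort(-(exact - base), kind="stable")
    for i in range(int(deficit)):
        base[order[i]] += 1
    return base


def stratified_split(
    data: pd.DataFrame,
    train_frac: float = 0.70,
    seed: int = 0,
    score_col: str = "wb_score",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified random training/validation split over score bins.

    Per-stratum training counts follow largest-remainder rounding so the
    totals equal ``round(train_frac * n)`` exactly; assignment within a
    stratum is a seeded permutation.  The two frames are disjoint and
    exhaust the input.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie strictly in (0, 1)")
    bins = score_bin(data[score_col])
    if (bins < 0).any():
        bad = data.index[bins < 0][0]
        raise ValueError(f"score outside the 0-3 half-step grid at index {bad}")
    rng = np.random.default_rng(seed)
    present = [b for b in range(4) if (bins == b).any()]
    sizes = np.array([(bins == b).sum() for b in present])
    k_train = _stratum_train_counts(sizes, train_frac)
    train_idx: list[np.ndarray] = []
    for b, k in zip(present, k_train):
        idx = data.index[bins == b].to_numpy()
        perm = rng.permutation(len(idx))
        train_idx.append(idx[perm[:k]])
    train_set = set(np.concatenate(train_idx))
    in_train = data.index.isin(train_set)
    return data.loc[in_train], data.loc[~in_train]


# ---------------------------------------------------------------------------
# Spearman screen

#: correlation-strength bands used when ranking measurements
BANDS = (("high", 0.65), ("moderate", 0.40))


def _band(rs: float) -> str:
    if math.isnan(rs):
        return "undefined"
    a = abs(rs)
    for name, lo in BANDS:
        if a >= lo:
            return name
    return "low"


def spearman_screen(
    data: pd.DataFrame,
    score_col: str = "wb_score",
    columns: tuple[str, ...] = _MEASUREMENTS,
) -> pd.DataFrame:
    """Spearman rank correlation of each measurement with the ordinal score.

    Uses average ranks on ties and the t-approximation for p-values.
    Returns a frame indexed by measurement with columns ``rs``, ``pvalue``
    and ``band`` (high >= 0.65, moderate >= 0.40, low below), sorted by
    descending |rs|.  A constant measurement is flagged ``undefined``.
    """
    if len(data) < 3:
        raise ValueError("need at least 3 records for the screen")
    score = data[score_col].to_numpy(dtype=float)
    if np.ptp(score) == 0:
        raise ValueError("ordinal score is constant; correlations undefined")
    rows = []
    for col in columns:
        x = data[col].to_numpy(dtype=float)
        if np.ptp(x[~np.isnan(x)] if np.isnan(x).any() else x) == 0:
            rs, pv = math.nan, math.nan
        else:
            rs, pv = stats.spearmanr(x, score, nan_policy="omit")
        rows.append({"measurement": col, "rs": rs, "pvalue": pv, "band": _band(rs)})
    out = pd.DataFrame(rows).set_index("measurement")
    return out.reindex(out["rs"].abs().sort_values(ascending=False).index)
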