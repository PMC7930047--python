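"""Epoch-level classification metrics and endpoint-level agreement statistics.

Epoch metrics are the usual confusion-matrix summaries (accuracy,
sensitivity, specificity, PPV, NPV, F1, and AUC when probability scores are
available).  Endpoint agreement against a reference method uses the Pearson
correlation coefficient with its two-sided p-value, and Bland-Altman
analysis: bias = mean paired difference, limits of agreement =
bias +/- 1.96 * SD of the differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix, roc_auc_score


@dataclass(frozen=True)
class AgreementStats:
    """Pearson and Bland-Altman agreement between two paired measurements."""

    pearson_r: float
    p_value: float
    bias: float
    loa_low: float
    loa_high: float
    n: int


def epoch_metrics(
    pred,
    ref,
    positive_class: str,
    scores: np.ndarray | None = None,
    strict: bool = True,
) -> dict:
    """Confusion-matrix metrics of a predicted vs reference state sequence.

    ``positive_class`` defines which label counts as a positive (e.g.
    ``"sleep"`` for the sleep module, ``"scratch"`` for the scratch module).
    With ``scores`` given (probability of the positive class), AUC of the
    ROC is included.  Zero-denominator ratios are returned as NaN with a
    warning (or silently when ``strict`` is False, as in LOSO folds where a
    held-out subject may lack one class).
    """
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    if len(pred) != len(ref):
        raise ValueError(f"length mismatch: {len(pred)} predictions vs {len(ref)} references")
    if len(pred) == 0:
        raise ValueError("empty sequences")
    p = pred == positive_class
    r = ref == positive_class
    tn, fp, fn, tp = confusion_matrix(r, p, labels=[False, True]).ravel()

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            if strict:
                warnings.warn(f"{name} undefined (zero denominator)", RuntimeWarning)
            return float("nan")
        return num / den

    out = {
        "accuracy": (tp + tn) / len(pred),
        "sensitivity": ratio(tp, tp + fn, "sensitivity"),
        "specificity": ratio(tn, tn + fp, "specificity"),
        "ppv": ratio(tp, tp + fp, "PPV"),
        "npv": ratio(tn, tn + fn, "NPV"),
        "f1": ratio(2 * tp, 2 * tp + fp + fn, "F1"),
        "tp": int(tp),
        "fp": int(fp),
        "fn": int(fn),
        "tn": int(tn),
    }
    if scores is not None and len(np.unique(r)) == 2:
        out["auc"] = float(roc_auc_score(r, np.asarray(scores, dtype=float)))
    else:
        out["auc"] = float("nan")
    return out


def bland_altman(a, b) -> dict:
    """Bland-Altman bias and 95% limits of agreement for paired values.

    bias = mean(a - b); LoA = bias +/- 1.96 * SD(a - b), with the sample
    (ddof = 1) standard deviation of the paired differences.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired inputs must have equal shape")
    if a.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("inputs must be finite")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return {
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
        "n": int(a.size),
    }


def pearson(a, b) -> tuple[float, float]:
    """Sample Pearson correlation with two-sided p-value (t-transform)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("inputs must be finite")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def agreement_stats(a, b) -> AgreementStats:
    """Combined Pearson + Bland-Altman summary for one endpoint."""
    r, p = pearson(a, b)
    ba = bland_altman(a, b)
    return AgreementStats(
        pearson_r=r,
        p_value=p,
        bias=ba["bias"],
        loa_low=ba["loa_low"],
        loa_high=ba["loa_high"],
        n=ba["n"],
    )


def agreement_table(pred: pd.DataFrame, ref: pd.DataFrame) -> pd.DataFrame:
    """Per-column agreement between two aligned endpoint tables.

    Rows of ``pred`` and ``ref`` must be paired (same order); every shared
    numeric column yields one row of Pearson and Bland-Altman statistics.
    """
    shared = [
        c
        for c in pred.columns
        if c in ref.columns and np.issubdtype(pred[c].dtype, np.number)
    ]
    rows = []
    for c in shared:
        mask = pred[c].notna().to_numpy() & ref[c].notna().to_numpy()
        if mask.sum() < 3:
            continue
        s = agreement_stats(pred[c].to_numpy()[mask], ref[c].to_numpy()[mask])
        rows.append(
            {
                "endpoint": c,
                "n": s.n,
                "pearson_r": s.pearson_r,
                "p_value": s.p_value,
                "bias": s.bias,
                "loa_low": s.loa_low,
                "loa_high": s.loa_high,
            }
        )
    return pd.DataFrame(rows)


def bland_altman_plot(a, b, ax=None, label: str | None = None):
    """Standard Bland-Altman scatter (mean vs difference) with bias/LoA lines."""
    import matplotlib.pyplot as plt

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ba = bland_altman(a, b)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((a + b) / 2.0, a - b, s=18, alpha=0.7)
    ax.axhline(ba["bias"], color="k", lw=1)
    for y in (ba["loa_low"], ba["loa_high"]):
        ax.axhline(y, color="k", lw=1, ls="--")
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference (a - b)")
    if label:
        ax.set_title(label)
    return ax
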