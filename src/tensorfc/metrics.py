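"""Binary classification measures: ACC, SEN, SPE, Youden's index, F-score, BAC.

Conventions: the patient group (e.g. eMCI) is the positive class.  A metric
whose denominator is zero (no positives evaluated, say) is reported as NaN
with a warning rather than silently coerced to 0 — silent zeros bias
aggregate summaries of permutation experiments.
"""

from __future__ import annotations

import math
import warnings

import pandas as pd

from .classify import ConfusionCounts

__all__ = ["compute_metrics", "aggregate_metrics", "metrics_frame", "METRIC_NAMES"]

METRIC_NAMES = ("ACC", "SEN", "SPE", "YI", "F_score", "BAC")


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN", stacklevel=3)
        return math.nan
    return num / den


def compute_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, Youden's index, F-score and balanced accuracy.

    ACC=(TP+TN)/total, SEN=TP/(TP+FN), SPE=TN/(TN+FP), YI=SEN+SPE-1,
    F=2*precision*recall/(precision+recall) with precision=TP/(TP+FP) and
    recall=SEN, BAC=(SEN+SPE)/2.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics from empty confusion counts")
    sen = _ratio(c.tp, c.tp + c.fn, "SEN")
    spe = _ratio(c.tn, c.tn + c.fp, "SPE")
    precision = _ratio(c.tp, c.tp + c.fp, "precision")
    if math.isnan(precision) or math.isnan(sen) or precision + sen == 0:
        if not (math.isnan(precision) or math.isnan(sen)):
            warnings.warn("F_score undefined (precision + recall = 0); reporting NaN",
                          stacklevel=2)
        f_score = math.nan
    else:
        f_score = 2 * precision * sen / (precision + sen)
    return {
        "ACC": (c.tp + c.tn) / c.total,
        "SEN": sen,
        "SPE": spe,
        "YI": sen + spe - 1,
        "F_score": f_score,
        "BAC": (sen + spe) / 2,
    }


def metrics_frame(runs: list[dict[str, float]], run_ids: list[str] | None = None) -> pd.DataFrame:
    """One row per run with the six measures, indexed by run id."""
    if run_ids is None:
        run_ids = [f"run_{i + 1}" for i in range(len(runs))]
    df = pd.DataFrame(runs, index=pd.Index(run_ids, name="run_id"))
    return df[list(METRIC_NAMES)]


def aggregate_metrics(runs: list[dict[str, float]], run_ids: list[str] | None = None) -> pd.DataFrame:
    """Per-run table plus mean/sd aggregate rows (NaN runs excluded with a warning)."""
    df = metrics_frame(runs, run_ids)
    if df.isna().any().any():
        warnings.warn(
            "some runs have undefined metrics; they are excluded from the aggregates",
            stacklevel=2,
        )
    agg = pd.DataFrame(
        {"mean": df.mean(skipna=True), "sd": df.std(skipna=True, ddof=1)}
    ).T
    agg.index.name = "run_id"
    return pd.concat([df, agg])
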