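"""Overlap metrics, agreement overlays, and summary tables.

With P the predicted disc pixel set and T the expert (ground-truth) set:

    Dice        = 2|P n T| / (|P| + |T|)
    Sensitivity = |P n T| / |T|
    PPV         = |P n T| / |P|

Dice is the harmonic mean of sensitivity and PPV whenever both are
defined. Metrics are exact integer pixel-set arithmetic per image,
computed at the network resolution. Summaries report mean +- sample
(n-1) standard deviation per model x dataset, flag the best model per
metric, and export box-plot statistics (median, quartiles, 1.5 x IQR
whiskers, outliers).

The overlay follows the red/blue/green convention: red = correctly
segmented (P n T), blue = under-segmented (T \\ P, missed disc), green =
over-segmented (P \\ T, false positives); everything else shows the
grayscale base image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

METRIC_NAMES = ("dice", "sensitivity", "ppv")

OVERLAY_RED = (255, 0, 0)
OVERLAY_BLUE = (0, 0, 255)
OVERLAY_GREEN = (0, 255, 0)


class UndefinedMetricError(ValueError):
    """Raised when the ground-truth mask is empty (|T| = 0)."""


@dataclass
class MetricRecord:
    """Per-image pixel-set sizes and the three derived overlap ratios.

    ``empty_prediction`` flags the |P| = 0 case, where PPV is the 0/0
    form; it is recorded as 0.0 so group means stay computable.
    """

    p_area: int
    t_area: int
    intersection: int
    dice: float
    sensitivity: float
    ppv: float
    sample_id: str = ""
    empty_prediction: bool = False

    def as_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "p_area": self.p_area,
            "t_area": self.t_area,
            "intersection": self.intersection,
            "dice": self.dice,
            "sensitivity": self.sensitivity,
            "ppv": self.ppv,
            "empty_prediction": self.empty_prediction,
        }


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Foreground iff probability >= threshold (inclusive at the boundary)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    return (np.asarray(prob) >= threshold).astype(np.uint8)


def compute_metrics(predicted: np.ndarray, truth: np.ndarray, sample_id: str = "") -> MetricRecord:
    """Exact Dice / sensitivity / PPV from two binary masks of equal shape."""
    p = np.asarray(predicted) > 0
    t = np.asarray(truth) > 0
    if p.shape != t.shape:
        raise ValueError(f"predicted shape {p.shape} != truth shape {t.shape}")
    t_area = int(t.sum())
    if t_area == 0:
        raise UndefinedMetricError("ground-truth mask is empty; metrics undefined")
    p_area = int(p.sum())
    inter = int((p & t).sum())
    dice = 2.0 * inter / (p_area + t_area)
    sens = inter / t_area
    if p_area == 0:
        return MetricRecord(p_area, t_area, inter, dice, sens, ppv=0.0,
                            sample_id=sample_id, empty_prediction=True)
    return MetricRecord(p_area, t_area, inter, dice, sens, ppv=inter / p_area,
                        sample_id=sample_id)


def render_overlay(predicted: np.ndarray, truth: np.ndarray, base_image: np.ndarray) -> np.ndarray:
    """RGB agreement overlay (red/blue/green) on the grayscale base image."""
    p = np.asarray(predicted) > 0
    t = np.asarray(truth) > 0
    base = np.asarray(base_image)
    if not (p.shape == t.shape == base.shape):
        raise ValueError(
            f"shape mismatch: predicted {p.shape}, truth {t.shape}, base {base.shape}"
        )
    if base.dtype != np.uint8:
        b = base.astype(np.float64)
        if b.max() <= 1.0:
            b = b * 255.0
        base = np.clip(np.rint(b), 0, 255).astype(np.uint8)
    out = np.stack([base, base, base], axis=-1)
    out[p & t] = OVERLAY_RED
    out[t & ~p] = OVERLAY_BLUE
    out[p & ~t] = OVERLAY_GREEN
    return out


def records_to_frame(records: list[MetricRecord], model: str = "", dataset: str = "") -> pd.DataFrame:
    df = pd.DataFrame([r.as_dict() for r in records])
    if model:
        df.insert(1, "model", model)
    if dataset:
        df.insert(2, "dataset", dataset)
    return df


def _box_stats(values: np.ndarray) -> dict:
    """Median, quartiles, 1.5 x IQR whiskers, and outliers beyond them."""
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    outliers = values[(values < lo_fence) | (values > hi_fence)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "outliers": ";".join(f"{v:.6g}" for v in np.sort(outliers)),
        "n_outliers": int(outliers.size),
    }


def summarize(per_image: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean +- SD summary and box-plot statistics per model x dataset.

    ``per_image`` must carry columns ``model``, ``dataset`` and the three
    metric columns. Returns ``(summary, box_stats)``; ``summary`` has one
    row per dataset x model with ``<metric>_mean``, ``<metric>_sd`` and a
    ``<metric>_best`` flag marking the highest mean within the dataset.
    """
    required = {"model", "dataset", *METRIC_NAMES}
    missing = required - set(per_image.columns)
    if missing:
        raise ValueError(f"per-image table missing columns: {sorted(missing)}")
    if per_image.groupby(["dataset", "model"]).size().min() < 2:
        raise ValueError("every model x dataset group needs >= 2 records")

    rows, box_rows = [], []
    for (dataset, model), g in per_image.groupby(["dataset", "model"], sort=True):
        row = {"dataset": dataset, "model": model, "n": len(g)}
        for m in METRIC_NAMES:
            vals = g[m].to_numpy(dtype=float)
            row[f"{m}_mean"] = float(vals.mean())
            row[f"{m}_sd"] = float(vals.std(ddof=1))
            box_rows.append({"dataset": dataset, "model": model, "metric": m,
                             **_box_stats(vals)})
        rows.append(row)
    summary = pd.DataFrame(rows)
    for m in METRIC_NAMES:
        best = summary.groupby("dataset")[f"{m}_mean"].transform("max")
        summary[f"{m}_best"] = summary[f"{m}_mean"] >= best
    return summary, pd.DataFrame(box_rows)


def format_summary_table(summary: pd.DataFrame, letters: dict | None = None) -> str:
    """Render the summary as text: ``mean +- sd`` with bold-max markers.

    ``letters`` optionally maps ``(dataset, model)`` to a per-metric dict
    of letter-group strings, appended as superscript-style suffixes; the
    best mean per metric within a dataset is wrapped in ``**``.
    """
    lines = [f"{'Dataset':<12}{'Model':<14}" + "".join(f"{m.capitalize():<22}" for m in METRIC_NAMES)]
    for _, row in summary.iterrows():
        cells = []
        for m in METRIC_NAMES:
            cell = f"{row[f'{m}_mean']:.2f} ± {row[f'{m}_sd']:.2f}"
            if letters is not None:
                lg = letters.get((row["dataset"], row["model"]), {})
                if m in lg:
                    cell += f" ^{lg[m]}"
            if row[f"{m}_best"]:
                cell = f"**{cell}**"
            cells.append(f"{cell:<22}")
        lines.append(f"{row['dataset']:<12}{row['model']:<14}" + "".join(cells))
    return "\n".join(lines)
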