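"""Jaccard-similarity evaluation of segmentations against ground truth."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple

import numpy as np
import pandas as pd

from .types import CSF, GM, WM, LabelMap, TISSUE_NAMES


@dataclass
class EvalReport:
    """Per-class Jaccard values, their mean, and a 4x4 label confusion matrix."""

    js_per_class: Tuple[float, float, float]  # (CSF, GM, WM)
    mean_js: float
    confusion: np.ndarray

    def as_dict(self) -> Dict[str, float]:
        out = {TISSUE_NAMES[c]: js for c, js in zip((CSF, GM, WM), self.js_per_class)}
        out["mean"] = self.mean_js
        return out


def jaccard(pred: LabelMap, truth: LabelMap, cls: int) -> float:
    """|pred=cls AND truth=cls| / |pred=cls OR truth=cls| for one tissue class.

    An empty union (the class absent from both maps) counts as perfect
    agreement and returns 1.
    """
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth must have the same shape")
    if cls not in (CSF, GM, WM):
        raise ValueError(f"class id must be 1, 2, or 3; got {cls}")
    p = pred.labels == cls
    t = truth.labels == cls
    union = np.logical_or(p, t).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(p, t).sum() / union)


def evaluate(pred: LabelMap, truth: LabelMap) -> EvalReport:
    """Per-class Jaccard plus a confusion matrix over non-background voxels."""
    js = tuple(jaccard(pred, truth, c) for c in (CSF, GM, WM))
    evaluated = (truth.labels > 0) | (pred.labels > 0)
    conf = np.zeros((4, 4), dtype=np.int64)
    t = truth.labels[evaluated]
    p = pred.labels[evaluated]
    np.add.at(conf, (t, p), 1)
    return EvalReport(js_per_class=js, mean_js=float(np.mean(js)), confusion=conf)


def evaluate_batch(
    pairs: Iterable[Tuple[LabelMap, LabelMap]], names: Iterable[str] = None
) -> pd.DataFrame:
    """Tabulate per-image, per-class Jaccard with a mean +/- sd summary row."""
    rows: List[dict] = []
    pairs = list(pairs)
    names = list(names) if names is not None else [str(i) for i in range(len(pairs))]
    for name, (pred, truth) in zip(names, pairs):
        rep = evaluate(pred, truth)
        rows.append(
            {"image": name, "CSF": rep.js_per_class[0], "GM": rep.js_per_class[1],
             "WM": rep.js_per_class[2], "mean": rep.mean_js}
        )
    df = pd.DataFrame(rows)
    if len(df):
        summary = {"image": "mean±sd"}
        for col in ("CSF", "GM", "WM", "mean"):
            summary[col] = f"{df[col].mean():.4f}±{df[col].std(ddof=1 if len(df) > 1 else 0):.4f}"
        df = pd.concat([df, pd.DataFrame([summary])], ignore_index=True)
    return df
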