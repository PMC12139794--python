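"""Predicted-vs-experimental water matching and precision/recall.

Predicted and experimental oxygen positions are matched one-to-one:
all pairs within the cutoff (default 2.2 A, inclusive) are visited in
ascending distance and a pair is accepted when neither member is
already matched.  This is deterministic, order-independent, and
enforces "one prediction per experimental water".  From the matching,

    precision = TP / (TP + FP),   recall = TP / (TP + FN),

with TP the accepted pairs, FP the unmatched predictions and FN the
unmatched experimental waters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model import ValidationError
from .sitefinder import PredictedSite

__all__ = ["MatchReport", "match_waters", "precision_recall_curve"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatchReport:
    """Counts, rates, and the accepted assignment list of one matching."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    assignments: list[tuple[int, int, float]]
    cutoff: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.assignments,
            columns=["predicted_index", "experimental_index", "distance"],
        )


def _as_points(x) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.size == 0:
        return arr.reshape(0, 3)
    return arr.reshape(-1, 3)


def match_waters(
    predicted,
    experimental,
    cutoff: float = 2.2,
) -> MatchReport:
    """Globally greedy one-to-one matching within *cutoff* (inclusive).

    Candidate pairs are sorted by (distance, predicted index,
    experimental index), making the result invariant to input order up
    to the stated tie-break.
    """
    if not (cutoff > 0):
        raise ValidationError("cutoff must be > 0")
    pred = _as_points(predicted)
    exp = _as_points(experimental)
    assignments: list[tuple[int, int, float]] = []
    if len(pred) and len(exp):
        pairs = cKDTree(pred).query_ball_tree(cKDTree(exp), r=cutoff)
        pi, ei = [], []
        for i, js in enumerate(pairs):
            pi.extend([i] * len(js))
            ei.extend(js)
        if pi:
            pi = np.asarray(pi)
            ei = np.asarray(ei)
            d = np.linalg.norm(pred[pi] - exp[ei], axis=1)
            keep = d <= cutoff
            pi, ei, d = pi[keep], ei[keep], d[keep]
            order = np.lexsort((ei, pi, d))
            used_p: set[int] = set()
            used_e: set[int] = set()
            for k in order:
                i, j = int(pi[k]), int(ei[k])
                if i in used_p or j in used_e:
                    continue
                used_p.add(i)
                used_e.add(j)
                assignments.append((i, j, float(d[k])))
    tp = len(assignments)
    fp = len(pred) - tp
    fn = len(exp) - tp
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        logger.warning("no predictions: precision defined as 0")
        precision = 0.0
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        logger.warning("no experimental waters: recall defined as 0")
        recall = 0.0
    return MatchReport(
        tp=tp, fp=fp, fn=fn,
        precision=precision, recall=recall,
        assignments=assignments, cutoff=float(cutoff),
    )


def precision_recall_curve(
    ranked_sites: Sequence[PredictedSite],
    experimental,
    cutoff: float = 2.2,
    wt_thresholds: Sequence[float] | None = None,
    top_k: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Precision/recall as predicted sites are admitted by WT threshold
    or by top-k rank.

    *ranked_sites* must be sorted ascending by WT (most favorable
    first), as produced by ``wtcalc.score_sites``.  Exactly one of
    *wt_thresholds* / *top_k* may be given; by default the curve is
    traced over every k = 1..N.
    """
    wts = [s.wt for s in ranked_sites]
    if any(w is None for w in wts):
        raise ValidationError("all sites must be WT-scored")
    if any(a > b for a, b in zip(wts, wts[1:])):
        raise ValidationError("sites must be ranked ascending by WT")
    if wt_thresholds is not None and top_k is not None:
        raise ValidationError("give wt_thresholds or top_k, not both")
    positions = [
        s.mean_position if s.mean_position is not None else s.cube_center
        for s in ranked_sites
    ]
    rows = []
    if wt_thresholds is not None:
        selectors = [("wt_threshold", float(t)) for t in wt_thresholds]
    else:
        ks = top_k if top_k is not None else range(1, len(ranked_sites) + 1)
        selectors = [("top_k", int(k)) for k in ks]
    for kind, value in selectors:
        if kind == "wt_threshold":
            subset = [p for p, w in zip(positions, wts) if w <= value]
        else:
            subset = positions[: value]
        report = match_waters(subset, experimental, cutoff=cutoff)
        rows.append(
            {
                kind: value,
                "n_predicted": len(subset),
                "tp": report.tp,
                "fp": report.fp,
                "fn": report.fn,
                "precision": report.precision,
                "recall": report.recall,
            }
        )
    return pd.DataFrame(rows)
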