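"""Splice-impact score benchmarking.

Applies each predictor's published decision threshold to per-variant scores,
computes ROC curves and AUC against binary experimental splice-altering
labels, and builds the categorical crosstabs behind river plots
(ClinVar-style 5-level and SpliceVarDB-style 3-level labels).

AUC is the rank (concordance) statistic — the probability that a random
positive outscores a random negative, with half credit for ties — which
equals the trapezoidal area under the empirical ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ValidationError
from .junctions import POSITIONS
from .variants import AnnotatedJunctionVariant


@dataclass(frozen=True)
class ToolThresholdSpec:
    """Decision rule for one predictor.

    ``rule`` is one of ``gt`` (strictly greater), ``ge`` (at least) or
    ``band`` (two edges, three categories).  ``higher_disrupts=False`` marks
    inverted scales where low scores mean strong disruption potential.
    """

    tool: str
    rule: str
    threshold: float | None = None
    band_edges: tuple[float, float] | None = None
    band_labels: tuple[str, str, str] = ("low", "medium", "high")
    higher_disrupts: bool = True

    def __post_init__(self):
        if self.rule in ("gt", "ge") and self.threshold is None:
            raise ValidationError(f"{self.tool}: rule {self.rule} needs a threshold")
        if self.rule == "band":
            if self.band_edges is None or not (self.band_edges[0] < self.band_edges[1]):
                raise ValidationError(f"{self.tool}: band edges must strictly increase")

    def call(self, score: float):
        """Boolean for gt/ge rules, a category label for banded rules."""
        if self.rule == "gt":
            return score > self.threshold
        if self.rule == "ge":
            return score >= self.threshold
        lo, hi = self.band_edges
        if score < lo:
            label = self.band_labels[0]
        elif score < hi:  # left-closed bands: an edge value falls upward
            label = self.band_labels[1]
        else:
            label = self.band_labels[2]
        return label


#: Published decision thresholds for the predictors whose scores are consumed.
DEFAULT_THRESHOLDS: dict[str, ToolThresholdSpec] = {
    "spliceai": ToolThresholdSpec("spliceai", "gt", threshold=0.22),
    "pangolin": ToolThresholdSpec("pangolin", "gt", threshold=0.20),
    "maxentscan_diff": ToolThresholdSpec("maxentscan_diff", "gt", threshold=0.0),
    "maxentscan_alt": ToolThresholdSpec(
        "maxentscan_alt",
        "band",
        band_edges=(6.2, 8.5),
        band_labels=("high", "moderate", "low"),  # alt score < 6.2 = high potential
        higher_disrupts=False,
    ),
    "cadd": ToolThresholdSpec("cadd", "ge", threshold=20.0),
    "spip": ToolThresholdSpec("spip", "gt", threshold=0.45),
    "absplice": ToolThresholdSpec(
        "absplice", "band", band_edges=(0.05, 0.2), band_labels=("low", "medium", "high")
    ),
}


@dataclass
class EvalResult:
    tool: str
    n_scored: int
    n_unscored: int
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def apply_thresholds(
    annotated: Sequence[AnnotatedJunctionVariant],
    tool: str,
    spec: ToolThresholdSpec | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-variant threshold calls and per-position summary for one tool.

    Unscored variants are reported (``call`` = NA), never counted as failed.
    For banded rules the summary holds the fraction per category; for binary
    rules the fraction of scored variants passing.
    """
    if spec is None:
        spec = DEFAULT_THRESHOLDS.get(tool)
        if spec is None:
            raise ValidationError(f"unknown tool {tool!r} and no spec given")
    rows = []
    for av in annotated:
        score = av.variant.scores.get(tool)
        rows.append(
            {
                "contig": av.variant.contig,
                "pos": av.variant.position + 1,
                "ref": av.variant.ref,
                "alt": av.variant.alt,
                "position_label": av.position_label,
                "score": score,
                "call": None if score is None else spec.call(score),
            }
        )
    calls = pd.DataFrame(rows)
    summary_rows = []
    for position in POSITIONS:
        sub = calls[calls["position_label"] == position]
        scored = sub[sub["score"].notna()]
        row = {
            "position": position,
            "n": len(sub),
            "n_scored": len(scored),
            "n_unscored": len(sub) - len(scored),
        }
        if spec.rule == "band":
            for label in spec.band_labels:
                row[f"frac_{label}"] = (
                    float((scored["call"] == label).mean()) if len(scored) else float("nan")
                )
        else:
            row["pass_fraction"] = (
                float(scored["call"].astype(bool).mean()) if len(scored) else float("nan")
            )
        summary_rows.append(row)
    return calls, pd.DataFrame(summary_rows).set_index("position")


def roc_auc(
    scores: Sequence[float], labels: Sequence[int], tool: str = "score"
) -> EvalResult:
    """ROC curve and concordance AUC of a score column against binary labels.

    ``labels`` are 1 for splice-altering, 0 for neutral.  NaN scores are
    excluded from the denominator and counted as unscored.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels differ in length")
    mask = ~np.isnan(scores)
    n_unscored = int((~mask).sum())
    scores, labels = scores[mask], labels[mask]
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("need both classes to compute a ROC curve")

    # concordance AUC via midranks: half credit for ties
    ranks = rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    # empirical ROC: sweep thresholds from high to low over unique scores
    order = np.argsort(-scores, kind="mergesort")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    tp = np.cumsum(sorted_labels)
    fp = np.cumsum(1 - sorted_labels)
    # keep the last index of each tied score block
    distinct = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tpr = np.r_[0.0, tp[distinct] / n_pos]
    fpr = np.r_[0.0, fp[distinct] / n_neg]
    return EvalResult(
        tool=tool,
        n_scored=int(mask.sum()),
        n_unscored=n_unscored,
        fpr=fpr,
        tpr=tpr,
        auc=float(auc),
    )


def roc_auc_for_tool(
    annotated: Sequence[AnnotatedJunctionVariant],
    tool: str,
    label_name: str = "splice_altering",
) -> EvalResult:
    """AUC of one tool's scores over variants carrying a binary label."""
    scores, labels = [], []
    seen: set[tuple] = set()
    for av in annotated:
        label = av.variant.labels.get(label_name)
        if label is None or av.key in seen:
            continue
        seen.add(av.key)
        scores.append(av.variant.scores.get(tool, float("nan")))
        labels.append(int(label in ("1", "altering", "splice_altering", "true", "True")))
    result = roc_auc(scores, labels, tool=tool)
    return result


def category_crosstab(
    groups: Mapping[str, Iterable[str | None]],
) -> pd.DataFrame:
    """Counts and percentages of each category label per source group.

    Input maps group name (e.g. ``all`` / ``cosmic`` / ``gnomad_rare``) to an
    iterable of labels; missing labels become ``unreported``.  Percentages per
    group sum to 100.
    """
    rows = []
    for group, labels in groups.items():
        counts: dict[str, int] = {}
        for label in labels:
            label = "unreported" if label is None or label == "" else str(label)
            counts[label] = counts.get(label, 0) + 1
        total = sum(counts.values())
        if total == 0:
            counts = {"unreported": 0}
        for label in sorted(counts):
            rows.append(
                {
                    "group": group,
                    "label": label,
                    "count": counts[label],
                    "percent": 100.0 * counts[label] / total if total else 100.0,
                }
            )
    return pd.DataFrame(rows)


def crosstab_for_label(
    annotated: Sequence[AnnotatedJunctionVariant], label_name: str
) -> pd.DataFrame:
    """River-plot table of one label column for all / per-dataset variant groups."""
    def labels_of(subset):
        seen: set[tuple] = set()
        out = []
        for av in subset:
            if av.key in seen:
                continue
            seen.add(av.key)
            out.append(av.variant.labels.get(label_name))
        return out

    groups = {"all": labels_of(annotated)}
    for dataset in sorted({av.variant.dataset for av in annotated}):
        groups[dataset] = labels_of(
            [av for av in annotated if av.variant.dataset == dataset]
        )
    return category_crosstab(groups)
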