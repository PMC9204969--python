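"""Comparison of predicted networks with the undirected ground truth.

Predictions are undirected gene-pair sets or rankings; the truth is the
undirected projection of the generated regulatory graph. Confusion
counts, precision, trapezoidal AUROC and AUPR, and mean squared deviation
of gene–gene Pearson correlations by reaction class are provided. When
the top-N threshold equals the number of true links, precision equals
recall, so precision reads directly as the fraction of true links
recovered.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .inference import RankedEdgeList, gene_pairs
from .topology import ACTIVATION, GRNTopology

CLASSES = ("all", "activation", "inhibition", "non_reaction")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class CorrelationMSD:
    """Mean squared deviation of pairwise correlations for one reaction class."""

    value: float
    n_pairs: int
    n_excluded: int


@dataclass(frozen=True)
class EvaluationResult:
    confusion: ConfusionCounts
    precision: float
    tpr: float
    fpr: float
    auroc: float
    aupr: float

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def confusion(
    predicted: set[tuple[int, int]], truth: GRNTopology
) -> ConfusionCounts:
    """Confusion counts over all unordered gene pairs."""
    true_pairs = truth.undirected_pairs()
    predicted = {tuple(sorted(p)) for p in predicted}
    all_pairs = set(gene_pairs(truth.n_genes))
    if not predicted <= all_pairs:
        raise ValueError("predicted pairs outside the gene range")
    tp = len(predicted & true_pairs)
    fp = len(predicted - true_pairs)
    fn = len(true_pairs - predicted)
    tn = len(all_pairs) - tp - fp - fn
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def rates(c: ConfusionCounts) -> tuple[float, float, float]:
    """(FPR, TPR, precision) with the 0/0 → 0 convention."""
    fpr = c.fp / (c.fp + c.tn) if (c.fp + c.tn) else 0.0
    tpr = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    return fpr, tpr, precision


def _sweep_points(ranked: RankedEdgeList, truth: GRNTopology):
    """Cumulative (TP, FP) after each tied score block along the ranking."""
    true_pairs = truth.undirected_pairs()
    labels = np.array([1 if p in true_pairs else 0 for p in ranked.pairs])
    scores = ranked.scores
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    # block boundaries: indices where the score changes
    boundaries = np.flatnonzero(np.diff(scores)) + 1
    cum_tp = np.cumsum(labels)
    cum_fp = np.cumsum(1 - labels)
    ends = np.append(boundaries - 1, labels.size - 1)
    return cum_tp[ends], cum_fp[ends], n_pos, n_neg


def auroc(ranked: RankedEdgeList, truth: GRNTopology) -> float:
    """Trapezoidal area under the ROC sweep of the ranking.

    Tied score blocks contribute a single diagonal segment, so the tie
    handling averages over orderings within a block and random scores
    average to 0.5.
    """
    tp, fp, n_pos, n_neg = _sweep_points(ranked, truth)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("truth must contain both linked and unlinked pairs")
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    return float(np.trapezoid(tpr, fpr))


def aupr(ranked: RankedEdgeList, truth: GRNTopology) -> float:
    """Trapezoidal area under the precision–recall sweep of the ranking.

    The curve starts at recall 0 with the first block's precision and
    ends at recall 1.
    """
    tp, fp, n_pos, _ = _sweep_points(ranked, truth)
    if n_pos == 0:
        raise ValueError("truth must contain at least one link")
    recall = tp / n_pos
    precision = tp / (tp + fp)
    recall = np.concatenate([[0.0], recall])
    precision = np.concatenate([[precision[0]], precision])
    return float(np.trapezoid(precision, recall))


def evaluate_ranking(
    ranked: RankedEdgeList, truth: GRNTopology, n_top: int | None = None
) -> EvaluationResult:
    """Threshold at ``n_top`` (default: the number of true links) and score."""
    if n_top is None:
        n_top = len(truth.undirected_pairs())
    c = confusion(ranked.top_n(n_top), truth)
    fpr, tpr, precision = rates(c)
    return EvaluationResult(
        confusion=c,
        precision=precision,
        tpr=tpr,
        fpr=fpr,
        auroc=auroc(ranked, truth),
        aupr=aupr(ranked, truth),
    )


def _pair_class(pair: tuple[int, int], signs: dict[tuple[int, int], str]) -> str:
    if pair not in signs:
        return "non_reaction"
    return "activation" if signs[pair] == ACTIVATION else "inhibition"


def correlation_msd(
    reference: np.ndarray,
    processed: np.ndarray,
    truth: GRNTopology,
    cls: str = "all",
) -> CorrelationMSD:
    """Mean squared deviation of pairwise Pearson correlations for one class.

    ``reference`` is conventionally the volume-scaled ground truth. Pairs
    touching a zero-variance gene (in either matrix) are excluded and
    counted. Classes: activation / inhibition (signed ground-truth links),
    non_reaction (unlinked pairs), or all.
    """
    reference = np.asarray(reference, dtype=float)
    processed = np.asarray(processed, dtype=float)
    if reference.shape != processed.shape:
        raise ValueError("matrices must have matching shapes")
    if cls not in CLASSES:
        raise ValueError(f"unknown class {cls!r}")
    ok = (reference.std(axis=1) > 0) & (processed.std(axis=1) > 0)
    with np.errstate(invalid="ignore"):
        corr_ref = np.corrcoef(reference)
        corr_proc = np.corrcoef(processed)
    signs = truth.pair_signs()
    sq_devs = []
    n_excluded = 0
    for i, j in gene_pairs(truth.n_genes):
        if cls != "all" and _pair_class((i, j), signs) != cls:
            continue
        if not (ok[i] and ok[j]):
            n_excluded += 1
            continue
        sq_devs.append((corr_ref[i, j] - corr_proc[i, j]) ** 2)
    value = float(np.mean(sq_devs)) if sq_devs else 0.0
    return CorrelationMSD(value=value, n_pairs=len(sq_devs), n_excluded=n_excluded)


def write_metrics(result: EvaluationResult, path: str | Path, **context) -> None:
    """One JSON object per (dataset stage, method, seed) evaluation."""
    payload = {**context, **result.to_dict()}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def metrics_to_csv(records: list[dict], path: str | Path) -> None:
    """Flatten evaluation records (nested confusion counts) to one CSV table."""
    import pandas as pd

    flat = []
    for rec in records:
        row = dict(rec)
        conf = row.pop("confusion", {})
        for key, value in conf.items():
            row[f"confusion_{key}"] = value
        flat.append(row)
    pd.DataFrame(flat).to_csv(path, index=False)
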