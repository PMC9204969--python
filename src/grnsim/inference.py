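"""Network inference: score every unordered gene pair from an expression matrix.

Three scoring families are provided alongside a random baseline:

* PIDC-style: for each gene pair the "proportional unique contribution"
  (PUC) sums, over every context gene Z, the unique information each
  pair member carries about the other beyond Z (partial information
  decomposition with the Williams–Beer minimal-specific-information
  redundancy), divided by the pair's mutual information. Edge confidence
  is the sum of the two genes' empirical-CDF values of the pair's PUC.
* CLR: each pair's mutual information z-scored against both genes'
  background MI distributions, combined as sqrt(z_i^2 + z_j^2).
* GENIE3-style: per-target random-forest regressions on all other genes;
  the undirected pair score is the larger of the two directed
  impurity-importance totals.

All scorers emit a :class:`RankedEdgeList` over unordered pairs, sorted
by descending score with deterministic tie-breaking by pair index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

UNIFORM = "uniform"
RANK = "rank"


def gene_pairs(n_genes: int) -> list[tuple[int, int]]:
    """Canonical enumeration of unordered gene pairs (lexicographic)."""
    return [(i, j) for i in range(n_genes) for j in range(i + 1, n_genes)]


@dataclass(frozen=True)
class RankedEdgeList:
    """Scored unordered gene pairs, sorted by descending score.

    Ties are broken by the canonical pair index so rankings are
    deterministic for a fixed score vector.
    """

    pairs: tuple[tuple[int, int], ...]
    scores: np.ndarray
    method: str

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if len(self.pairs) != len(scores):
            raise ValueError("one score per pair required")
        if not np.all(np.isfinite(scores)):
            raise ValueError("scores must be finite")
        object.__setattr__(self, "scores", scores)

    @classmethod
    def from_scores(
        cls, n_genes: int, scores: np.ndarray, method: str
    ) -> "RankedEdgeList":
        pairs = gene_pairs(n_genes)
        scores = np.asarray(scores, dtype=float)
        order = np.lexsort((np.arange(len(pairs)), -scores))
        return cls(tuple(pairs[k] for k in order), scores[order], method)

    def __len__(self) -> int:
        return len(self.pairs)

    def top_n(self, n: int) -> set[tuple[int, int]]:
        """The first ``n`` pairs of the ranking as an undirected edge set."""
        if n < 0:
            raise ValueError("n must be non-negative")
        return set(self.pairs[:n])

    def write_tsv(self, path: str | Path) -> None:
        rows = [
            f"{a}\t{b}\t{s:.10g}\t{r + 1}"
            for r, ((a, b), s) in enumerate(zip(self.pairs, self.scores))
        ]
        header = "# gene_a\tgene_b\tscore\trank"
        Path(path).write_text("\n".join([header] + rows) + "\n")


def top_n(ranked: RankedEdgeList, n: int) -> set[tuple[int, int]]:
    """Top-N thresholding of a ranking (module-level convenience)."""
    return ranked.top_n(n)


def default_bins(n_cells: int) -> int:
    return min(10, max(2, math.ceil(math.sqrt(n_cells))))


def discretize(
    matrix: np.ndarray, n_bins: int | None = None, strategy: str = UNIFORM
) -> np.ndarray:
    """Per-gene binning into integer labels.

    ``uniform`` splits each gene's observed range into equal-width bins;
    ``rank`` uses equal-frequency (quantile) bins, which makes downstream
    MI estimates invariant to monotone per-gene transforms. Constant
    genes map to a single label.
    """
    matrix = np.asarray(matrix, dtype=float)
    if n_bins is None:
        n_bins = default_bins(matrix.shape[1])
    if n_bins < 1:
        raise ValueError("n_bins must be positive")
    labels = np.zeros(matrix.shape, dtype=np.int64)
    for g in range(matrix.shape[0]):
        x = matrix[g]
        lo, hi = x.min(), x.max()
        if hi == lo:
            continue
        if strategy == UNIFORM:
            edges = np.linspace(lo, hi, n_bins + 1)[1:-1]
            labels[g] = np.searchsorted(edges, x, side="right")
        elif strategy == RANK:
            q = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
            labels[g] = np.searchsorted(q, x, side="right")
        else:
            raise ValueError(f"unknown strategy {strategy!r}")
    return labels


def _joint_counts(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    nx = int(x.max()) + 1
    ny = int(y.max()) + 1
    return np.bincount(x * ny + y, minlength=nx * ny).reshape(nx, ny)


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information of two label vectors, in bits."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("label vectors must have equal length")
    joint = _joint_counts(x, y) / x.size
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    ratio = joint[mask] / (px @ py)[mask]
    return float(np.sum(joint[mask] * np.log2(ratio)))


def _mi_matrix(labels: np.ndarray) -> np.ndarray:
    G = labels.shape[0]
    mi = np.zeros((G, G))
    for i in range(G):
        for j in range(i + 1, G):
            mi[i, j] = mi[j, i] = mutual_information(labels[i], labels[j])
    return mi


def _specific_information(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """I_spec(S; T=t) for each target label t (Williams–Beer specific information)."""
    joint = _joint_counts(source, target) / source.size  # (ns, nt)
    ps = joint.sum(axis=1, keepdims=True)
    pt = joint.sum(axis=0, keepdims=True)
    spec = np.zeros(joint.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        for t in range(joint.shape[1]):
            if pt[0, t] <= 0:
                continue
            p_s_given_t = joint[:, t] / pt[0, t]
            mask = p_s_given_t > 0
            # log2( p(t|s)/p(t) ) = log2( p(s,t) / (p(s) p(t)) )
            spec[t] = np.sum(
                p_s_given_t[mask]
                * np.log2(joint[mask, t] / (ps[mask, 0] * pt[0, t]))
            )
    return spec


def _redundancy(spec_a: np.ndarray, spec_b: np.ndarray, p_target: np.ndarray) -> float:
    """I_min redundancy: expected minimum of the two specific informations."""
    return float(np.sum(p_target * np.minimum(spec_a, spec_b)))


def pidc_scores(
    matrix: np.ndarray,
    n_bins: int | None = None,
    strategy: str = UNIFORM,
) -> RankedEdgeList:
    """PIDC-style edge confidences from an expression matrix.

    Requires at least 3 genes (the decomposition needs a context gene).
    Pairs with zero mutual information receive PUC 0.
    """
    matrix = np.asarray(matrix, dtype=float)
    G = matrix.shape[0]
    if G < 3:
        raise ValueError("PIDC requires at least 3 genes")
    labels = discretize(matrix, n_bins, strategy)
    mi = _mi_matrix(labels)
    # Specific information of source s about target t, per target label,
    # and target marginals, cached per ordered pair.
    p_marg = [np.bincount(labels[g]) / labels.shape[1] for g in range(G)]
    spec = {}
    for s in range(G):
        for t in range(G):
            if s != t:
                spec[(s, t)] = _specific_information(labels[s], labels[t])
    puc = np.zeros((G, G))
    for x in range(G):
        for y in range(x + 1, G):
            if mi[x, y] <= 0:
                continue
            total = 0.0
            for z in range(G):
                if z == x or z == y:
                    continue
                # unique info X carries about Y beyond Z, plus the reverse
                red_xy = _redundancy(spec[(x, y)], spec[(z, y)], p_marg[y])
                red_yx = _redundancy(spec[(y, x)], spec[(z, x)], p_marg[x])
                total += (mi[x, y] - red_xy) + (mi[x, y] - red_yx)
            puc[x, y] = puc[y, x] = total / mi[x, y]
    # Per-gene empirical CDF over that gene's PUC scores.
    scores = np.zeros(len(gene_pairs(G)))
    gene_scores = [np.sort(puc[g][np.arange(G) != g]) for g in range(G)]
    for k, (x, y) in enumerate(gene_pairs(G)):
        fx = np.searchsorted(gene_scores[x], puc[x, y], side="right") / (G - 1)
        fy = np.searchsorted(gene_scores[y], puc[x, y], side="right") / (G - 1)
        scores[k] = fx + fy
    return RankedEdgeList.from_scores(G, scores, "PIDC")


def clr_scores(
    matrix: np.ndarray,
    n_bins: int | None = None,
    strategy: str = UNIFORM,
    mi: np.ndarray | None = None,
) -> RankedEdgeList:
    """Context-likelihood-of-relatedness scores.

    Each pair's MI is z-scored (negatives floored at 0) against the
    background MI distribution of each member gene; the pair score is the
    Euclidean combination of the two z-scores. A precomputed symmetric MI
    matrix may be passed via ``mi``.
    """
    if mi is None:
        labels = discretize(np.asarray(matrix, dtype=float), n_bins, strategy)
        mi = _mi_matrix(labels)
    mi = np.asarray(mi, dtype=float)
    G = mi.shape[0]
    off = ~np.eye(G, dtype=bool)
    means = np.array([mi[g][off[g]].mean() for g in range(G)])
    sds = np.array([mi[g][off[g]].std() for g in range(G)])
    scores = []
    for i, j in gene_pairs(G):
        zi = max(0.0, (mi[i, j] - means[i]) / sds[i]) if sds[i] > 0 else 0.0
        zj = max(0.0, (mi[i, j] - means[j]) / sds[j]) if sds[j] > 0 else 0.0
        scores.append(math.sqrt(zi * zi + zj * zj))
    return RankedEdgeList.from_scores(G, np.array(scores), "CLR")


def genie3_scores(
    matrix: np.ndarray,
    n_trees: int = 1000,
    rng: np.random.Generator | None = None,
    max_features: str | float = "sqrt",
) -> RankedEdgeList:
    """Tree-ensemble importances, aggregated to undirected pair scores.

    For each target gene a random-forest regression on all other genes
    (each gene standardised to unit variance) yields directed importances
    w(i→j); the pair score is max(w(i→j), w(j→i)).
    """
    if rng is None:
        raise ValueError("rng is required")
    X = np.asarray(matrix, dtype=float)
    G, C = X.shape
    if C < 2:
        raise ValueError("need at least 2 cells")
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=1, keepdims=True)) / sd
    W = np.zeros((G, G))  # W[i, j] = importance of regulator i for target j
    for j in range(G):
        others = [i for i in range(G) if i != j]
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=max_features,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(Xs[others].T, Xs[j])
        W[others, j] = forest.feature_importances_
    scores = [max(W[i, j], W[j, i]) for i, j in gene_pairs(G)]
    return RankedEdgeList.from_scores(G, np.array(scores), "GENIE3")


def random_scores(
    n_genes: int, rng: np.random.Generator | None = None
) -> RankedEdgeList:
    """Random baseline: i.i.d. uniform scores per pair."""
    if rng is None:
        raise ValueError("rng is required")
    n_pairs = n_genes * (n_genes - 1) // 2
    return RankedEdgeList.from_scores(n_genes, rng.random(n_pairs), "RAND")


INFERENCE_METHODS = {
    "PIDC": pidc_scores,
    "CLR": clr_scores,
    "GENIE3": genie3_scores,
    "RAND": random_scores,
}


def write_predicted_network(edges: set[tuple[int, int]], path: str | Path) -> None:
    """Write a thresholded undirected edge set as 2-column TSV."""
    lines = ["# gene_a\tgene_b (0-based gene indices, undirected)"]
    lines += [f"{a}\t{b}" for a, b in sorted(edges)]
    Path(path).write_text("\n".join(lines) + "\n")
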