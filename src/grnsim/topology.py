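"""Ground-truth gene regulatory network topologies.

Two random-graph families are provided: "random one regulation" (ROR),
in which every gene has at most one regulator, and a static-model
scale-free family in which hub regulators emerge from rank-dependent
attachment weights and each gene accepts at most four regulators.
Sparsity is expressed as a fraction of the unordered, non-self gene
pairs, so a 20-gene network has 190 possible links.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

ACTIVATION = "activation"
INHIBITION = "inhibition"

ROR = "ROR"
SCALE_FREE = "scale_free"

ADDITIVE = "additive"
MULTIPLICATIVE = "multiplicative"


class TopologyGenerationError(RuntimeError):
    """Raised when a random generator cannot place the requested links."""


@dataclass(frozen=True)
class Edge:
    """A directed regulation: ``regulator`` controls ``target``'s transcription."""

    regulator: int
    target: int
    sign: str = ACTIVATION

    def __post_init__(self) -> None:
        if self.regulator == self.target:
            raise ValueError("self-regulation is excluded")
        if self.sign not in (ACTIVATION, INHIBITION):
            raise ValueError(f"unknown sign {self.sign!r}")

    @property
    def pair(self) -> tuple[int, int]:
        """Unordered gene pair, canonically sorted."""
        a, b = self.regulator, self.target
        return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class GRNTopology:
    """Directed, signed regulatory graph over ``n_genes`` genes.

    ``combination_mode`` states how multiple regulators of one gene are
    combined in the transcription propensity (sum vs product of Hill
    terms); it is a global property of the network.
    """

    n_genes: int
    edges: tuple[Edge, ...]
    combination_mode: str = MULTIPLICATIVE
    topology_family: str | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.combination_mode not in (ADDITIVE, MULTIPLICATIVE):
            raise ValueError(f"unknown combination_mode {self.combination_mode!r}")
        pairs = [e.pair for e in self.edges]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate or reciprocal edges are not allowed")
        for e in self.edges:
            if not (0 <= e.regulator < self.n_genes and 0 <= e.target < self.n_genes):
                raise ValueError("edge gene index out of range")
        indeg = self.in_degrees()
        if self.topology_family == ROR and indeg.max(initial=0) > 1:
            raise ValueError("ROR topology requires in-degree <= 1")
        if self.topology_family == SCALE_FREE and indeg.max(initial=0) > 4:
            raise ValueError("scale-free topology requires in-degree <= 4")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def in_degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_genes, dtype=int)
        for e in self.edges:
            deg[e.target] += 1
        return deg

    def out_degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_genes, dtype=int)
        for e in self.edges:
            deg[e.regulator] += 1
        return deg

    def regulators_of(self, gene: int) -> list[Edge]:
        return [e for e in self.edges if e.target == gene]

    def undirected_pairs(self) -> set[tuple[int, int]]:
        """Unordered gene pairs carrying a link (the evaluation ground truth)."""
        return {e.pair for e in self.edges}

    def pair_signs(self) -> dict[tuple[int, int], str]:
        return {e.pair: e.sign for e in self.edges}


def n_possible_links(n_genes: int) -> int:
    """Unordered, non-self gene pairs: n(n-1)/2."""
    return n_genes * (n_genes - 1) // 2


def n_links(n_genes: int, sparsity: float) -> int:
    """Number of links implied by a sparsity fraction.

    Sparsity is the fraction of possible undirected links (self-regulation
    excluded); the product is rounded half-up, so 2.5% of a 20-gene
    network's 190 possible links gives 5.
    """
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    if not (0.0 < sparsity <= 1.0):
        raise ValueError("sparsity must lie in (0, 1]")
    links = math.floor(sparsity * n_possible_links(n_genes) + 0.5)
    if links == 0:
        raise ValueError("sparsity too small: zero links would be degenerate")
    return links


def generate_ror(
    n_genes: int,
    n_links: int,
    rng: np.random.Generator,
    combination_mode: str = MULTIPLICATIVE,
) -> GRNTopology:
    """Random-one-regulation topology: every gene has at most one regulator.

    ``n_links`` distinct targets are drawn uniformly; each receives a
    uniformly chosen regulator among the other genes. Reciprocal pairs
    (A→B together with B→A) are rejected so the undirected projection is
    unambiguous.
    """
    if n_links < 0 or n_links > n_genes:
        raise ValueError("ROR requires 0 <= n_links <= n_genes (in-degree <= 1)")
    targets = rng.choice(n_genes, size=n_links, replace=False) if n_links else []
    edges: list[Edge] = []
    taken_pairs: set[tuple[int, int]] = set()
    for t in targets:
        t = int(t)
        while True:
            r = int(rng.integers(n_genes))
            if r == t:
                continue
            pair = (r, t) if r < t else (t, r)
            if pair in taken_pairs:
                continue
            break
        taken_pairs.add(pair)
        edges.append(Edge(r, t))
    return GRNTopology(n_genes, tuple(edges), combination_mode, ROR)


def generate_scale_free(
    n_genes: int,
    n_links: int,
    exponent: float = 2.5,
    max_in_degree: int = 4,
    rng: np.random.Generator | None = None,
    combination_mode: str = MULTIPLICATIVE,
    max_attempts: int | None = None,
) -> GRNTopology:
    """Static-model scale-free topology.

    Genes receive attachment weights w_i ∝ i^(−1/(exponent−1)) over a
    random permutation of ranks; regulator–target pairs are sampled with
    probability proportional to the weight product. Self-loops, duplicate
    or reciprocal pairs, and targets already holding ``max_in_degree``
    regulators are rejected, producing a power-law-ish degree sequence
    with bounded in-degree.
    """
    if rng is None:
        raise ValueError("rng is required")
    if not (2.0 <= exponent <= 3.0):
        raise ValueError("power-law exponent must lie in [2, 3]")
    if n_links < 0:
        raise ValueError("n_links must be non-negative")
    if n_links > max_in_degree * n_genes or n_links > n_possible_links(n_genes):
        raise TopologyGenerationError(
            f"cannot place {n_links} links in {n_genes} genes "
            f"with in-degree cap {max_in_degree}"
        )
    ranks = rng.permutation(n_genes) + 1
    weights = ranks.astype(float) ** (-1.0 / (exponent - 1.0))
    weights /= weights.sum()
    budget = max_attempts if max_attempts is not None else 1000 + 500 * max(n_links, 1)
    edges: list[Edge] = []
    taken_pairs: set[tuple[int, int]] = set()
    indeg = Counter()
    attempts = 0
    while len(edges) < n_links:
        attempts += 1
        if attempts > budget:
            raise TopologyGenerationError(
                f"placed only {len(edges)}/{n_links} links after {budget} attempts"
            )
        r = int(rng.choice(n_genes, p=weights))
        t = int(rng.choice(n_genes, p=weights))
        if r == t or indeg[t] >= max_in_degree:
            continue
        pair = (r, t) if r < t else (t, r)
        if pair in taken_pairs:
            continue
        taken_pairs.add(pair)
        indeg[t] += 1
        edges.append(Edge(r, t))
    return GRNTopology(n_genes, tuple(edges), combination_mode, SCALE_FREE)


def assign_signs(
    topology: GRNTopology,
    p_activation: float = 0.5,
    rng: np.random.Generator | None = None,
) -> GRNTopology:
    """Coin-flip each edge to activation (probability ``p_activation``) or inhibition."""
    if not (0.0 <= p_activation <= 1.0):
        raise ValueError("p_activation must lie in [0, 1]")
    if rng is None:
        raise ValueError("rng is required")
    draws = rng.random(len(topology.edges))
    edges = tuple(
        replace(e, sign=ACTIVATION if u < p_activation else INHIBITION)
        for e, u in zip(topology.edges, draws)
    )
    return replace(topology, edges=edges)


def count_combination_reactions(topology: GRNTopology) -> dict[str, int]:
    """Classify multiply-regulated genes.

    A gene with two or more regulators is a combination reaction: combined
    activation if all regulators activate, combined inhibition if all
    inhibit, combined action if mixed. Genes with in-degree <= 1 do not
    contribute.
    """
    counts = {"combined_activation": 0, "combined_inhibition": 0, "combined_action": 0}
    by_target: dict[int, list[str]] = {}
    for e in topology.edges:
        by_target.setdefault(e.target, []).append(e.sign)
    for signs in by_target.values():
        if len(signs) < 2:
            continue
        if all(s == ACTIVATION for s in signs):
            counts["combined_activation"] += 1
        elif all(s == INHIBITION for s in signs):
            counts["combined_inhibition"] += 1
        else:
            counts["combined_action"] += 1
    return counts


def write_edge_list(topology: GRNTopology, path: str | Path) -> None:
    """Write edges as 3-column TSV (regulator, target, sign), 0-based indices."""
    path = Path(path)
    lines = ["# regulator\ttarget\tsign (0-based gene indices)"]
    lines += [f"{e.regulator}\t{e.target}\t{e.sign}" for e in topology.edges]
    path.write_text("\n".join(lines) + "\n")


def read_edge_list(
    path: str | Path,
    n_genes: int,
    combination_mode: str = MULTIPLICATIVE,
    topology_family: str | None = None,
) -> GRNTopology:
    edges = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        r, t, sign = line.split("\t")
        edges.append(Edge(int(r), int(t), sign))
    return GRNTopology(n_genes, tuple(edges), combination_mode, topology_family)
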