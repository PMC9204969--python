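"""Agent-based population of growing, dividing cells with stochastic gene expression.

Each cell runs a birth–death reaction network (volume-coupled
transcription, translation, mRNA and protein decay, Hill regulation of
transcription by the regulators' mRNA levels)
advanced by exact SSA or tau-leaping over a fixed operator-splitting
window τ, after which volumes grow exponentially and cells at their adder
division target split. Division partitions every molecular species
binomially between the daughters; the population size is capped, a new
daughter displacing a uniformly chosen other cell. Only the final
snapshot is exported downstream, mimicking the single-time-point nature
of scRNA-seq.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import GeneKinetics, RegulationEdge, unregulated_steady_state
from .topology import ACTIVATION, ADDITIVE, GRNTopology

SSA = "SSA"
TAU_LEAPING = "tau_leaping"


@dataclass(frozen=True)
class DivisionModel:
    """Adder size control with noisy binomial partitioning.

    The division target follows the noisy linear map V_F = a·V_I + b (+ η1);
    a = b = 1 gives the adder: each cycle adds one volume unit. At division
    the split fraction η2 ~ N(0.5, η2_sd) (clamped away from 0 and 1) sets
    both daughter volumes and the binomial partition probability of every
    molecular species.
    """

    a: float = 1.0
    b: float = 1.0
    eta1_sd: float = 0.0
    eta2_sd: float = 0.05
    eta2_bounds: tuple[float, float] = (0.05, 0.95)

    def __post_init__(self) -> None:
        if self.a < 0 or self.b <= 0:
            raise ValueError("require a >= 0 and b > 0")
        lo, hi = self.eta2_bounds
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("eta2_bounds must lie strictly inside (0, 1)")

    def sample_eta2(self, rng: np.random.Generator) -> float:
        eta2 = rng.normal(0.5, self.eta2_sd) if self.eta2_sd > 0 else 0.5
        return float(np.clip(eta2, *self.eta2_bounds))

    def division_target(self, birth_volume: float, rng: np.random.Generator) -> float:
        target = self.a * birth_volume + self.b
        if self.eta1_sd > 0:
            target += rng.normal(0.0, self.eta1_sd)
        return max(target, birth_volume * 1.01)


@dataclass(frozen=True)
class SimulationConfig:
    n_cells: int
    t_end: float = 500.0  # hours
    tau: float = 0.1  # operator-splitting window, hours
    method: str = TAU_LEAPING
    doubling_time: float = 50.0  # hours
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")
        if self.tau <= 0 or self.t_end < 0:
            raise ValueError("require tau > 0 and t_end >= 0")
        if self.method not in (SSA, TAU_LEAPING):
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def growth_rate(self) -> float:
        """Exponential growth rate µ = ln 2 / doubling time."""
        return float(np.log(2.0) / self.doubling_time)


@dataclass
class CellState:
    """One cell: volume, size-control bookkeeping, and integer copy numbers."""

    volume: float
    growth_rate: float
    birth_volume: float
    division_target: float
    mrna: np.ndarray  # (n_genes,) int
    protein: np.ndarray  # (n_genes,) int

    def __post_init__(self) -> None:
        self.mrna = np.asarray(self.mrna, dtype=np.int64)
        self.protein = np.asarray(self.protein, dtype=np.int64)
        if self.volume <= 0:
            raise ValueError("volume must be positive")
        if (self.mrna < 0).any() or (self.protein < 0).any():
            raise ValueError("copy numbers must be non-negative")


@dataclass(frozen=True)
class GroundTruthData:
    """Final-snapshot ground truth: genes × cells counts plus cell volumes."""

    mrna: np.ndarray  # (n_genes, n_cells) int
    protein: np.ndarray  # (n_genes, n_cells) int
    volumes: np.ndarray  # (n_cells,)
    time: float

    @property
    def n_genes(self) -> int:
        return self.mrna.shape[0]

    @property
    def n_cells(self) -> int:
        return self.mrna.shape[1]


class GeneExpressionModel:
    """A topology bound to per-gene kinetics and per-edge Hill parameters.

    Precomputes flat rate vectors and edge arrays so propensity evaluation
    is vectorized over cells.
    """

    def __init__(
        self,
        topology: GRNTopology,
        kinetics: list[GeneKinetics],
        regulations: list[RegulationEdge],
    ) -> None:
        if len(kinetics) != topology.n_genes:
            raise ValueError("one GeneKinetics record per gene required")
        if len(regulations) != len(topology.edges):
            raise ValueError("one RegulationEdge per topology edge required")
        for edge, reg in zip(topology.edges, regulations):
            if edge.sign != reg.sign:
                raise ValueError("edge sign and regulation sign disagree")
        self.topology = topology
        self.kinetics = list(kinetics)
        self.regulations = list(regulations)
        self.n_genes = topology.n_genes
        self.k1 = np.array([g.k1 for g in kinetics])
        self.k2 = np.array([g.k2 for g in kinetics])
        self.dm = np.array([g.dm for g in kinetics])
        self.dp = np.array([g.dp for g in kinetics])
        self._reg_idx = np.array([e.regulator for e in topology.edges], dtype=int)
        self._tgt_idx = np.array([e.target for e in topology.edges], dtype=int)
        self._hill_K = np.array([r.hill_K for r in regulations])
        self._hill_n = np.array([r.hill_n for r in regulations])
        self._is_act = np.array([r.sign == ACTIVATION for r in regulations])
        self._additive = topology.combination_mode == ADDITIVE
        self._regulated = np.zeros(self.n_genes, dtype=bool)
        self._regulated[self._tgt_idx] = True

    def regulation_factors(self, mrna: np.ndarray, volumes: np.ndarray) -> np.ndarray:
        """Per-gene transcription modulation R from regulator mRNA concentrations.

        Binding is concentration-based: the Hill input for an edge is the
        regulator's mRNA copy number divided by the cell volume, and K is
        a concentration. This keeps regulation invariant to cell-cycle
        position (copy numbers scale with volume, concentrations do not).
        ``mrna`` is (n_genes, n_cells); unregulated genes get R = 1.
        Multiplicative mode multiplies the regulators' Hill terms, additive
        mode sums them.
        """
        n_cells = mrna.shape[1]
        if self._additive:
            acc = np.zeros((self.n_genes, n_cells))
        else:
            acc = np.ones((self.n_genes, n_cells))
        for k in range(len(self._reg_idx)):
            x = mrna[self._reg_idx[k]].astype(float) / volumes
            ratio = np.power(x / self._hill_K[k], self._hill_n[k])
            f = ratio / (1.0 + ratio) if self._is_act[k] else 1.0 / (1.0 + ratio)
            if self._additive:
                acc[self._tgt_idx[k]] += f
            else:
                acc[self._tgt_idx[k]] *= f
        if self._additive:
            acc[~self._regulated] = 1.0
        return acc

    def propensity_matrix(
        self, mrna: np.ndarray, protein: np.ndarray, volumes: np.ndarray
    ) -> np.ndarray:
        """(4, n_genes, n_cells) rates: transcription, translation, mRNA decay, protein decay."""
        R = self.regulation_factors(mrna, volumes)
        return np.stack(
            [
                self.k1[:, None] * volumes[None, :] * R,
                self.k2[:, None] * mrna,
                self.dm[:, None] * mrna,
                self.dp[:, None] * protein,
            ]
        )

    def steady_state_init(
        self, volumes: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Rounded unregulated steady-state means at each cell's volume."""
        mean_m = self.k1[:, None] * volumes[None, :] / self.dm[:, None]
        mean_p = mean_m * (self.k2 / self.dp)[:, None]
        return (
            np.round(mean_m).astype(np.int64),
            np.round(mean_p).astype(np.int64),
        )


def propensities(cell: CellState, model: GeneExpressionModel) -> np.ndarray:
    """Reaction rates of one cell, shape (4, n_genes); see ``propensity_matrix``."""
    mat = model.propensity_matrix(
        cell.mrna[:, None], cell.protein[:, None], np.array([cell.volume])
    )
    return mat[:, :, 0]


def _tau_leap(
    model: GeneExpressionModel,
    mrna: np.ndarray,
    protein: np.ndarray,
    volumes: np.ndarray,
    tau: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One Poisson-leap window with rates frozen at window start.

    Negative excursions (decay counts exceeding the current copy number)
    are truncated to zero.
    """
    a = model.propensity_matrix(mrna, protein, volumes)
    counts = rng.poisson(a * tau)
    new_m = np.maximum(mrna + counts[0] - counts[2], 0)
    new_p = np.maximum(protein + counts[1] - counts[3], 0)
    return new_m, new_p


# Stoichiometry per channel: (mRNA change, protein change)
_STOICH = ((1, 0), (0, 1), (-1, 0), (0, -1))


def _ssa_cell(
    model: GeneExpressionModel,
    mrna: np.ndarray,
    protein: np.ndarray,
    volume: float,
    tau: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact Gillespie within [0, τ) for one cell at fixed volume."""
    m = mrna.copy()
    p = protein.copy()
    vol = np.array([volume])
    t = 0.0
    while True:
        a = model.propensity_matrix(m[:, None], p[:, None], vol)[:, :, 0]
        a_flat = a.ravel()
        a0 = a_flat.sum()
        if a0 <= 0:
            break
        t += rng.exponential(1.0 / a0)
        if t >= tau:
            break
        u = rng.random() * a0
        idx = int(np.searchsorted(np.cumsum(a_flat), u, side="right"))
        idx = min(idx, a_flat.size - 1)
        channel, gene = divmod(idx, model.n_genes)
        dm_, dp_ = _STOICH[channel]
        m[gene] += dm_
        p[gene] += dp_
    return m, p


def advance_reactions(
    cell: CellState,
    model: GeneExpressionModel,
    tau: float,
    method: str = TAU_LEAPING,
    rng: np.random.Generator | None = None,
) -> CellState:
    """Advance one cell's reactions over a window of length τ at fixed volume."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    if rng is None:
        raise ValueError("rng is required")
    if method == TAU_LEAPING:
        m, p = _tau_leap(
            model,
            cell.mrna[:, None],
            cell.protein[:, None],
            np.array([cell.volume]),
            tau,
            rng,
        )
        m, p = m[:, 0], p[:, 0]
    elif method == SSA:
        m, p = _ssa_cell(model, cell.mrna, cell.protein, cell.volume, tau, rng)
    else:
        raise ValueError(f"unknown method {method!r}")
    return replace(cell, mrna=m, protein=p)


def grow(cell: CellState, tau: float) -> CellState:
    """Exponential volume growth: V ← V·exp(µτ)."""
    return replace(cell, volume=cell.volume * float(np.exp(cell.growth_rate * tau)))


def divide(
    cell: CellState, model: DivisionModel, rng: np.random.Generator
) -> tuple[CellState, CellState]:
    """Split a cell at its division target into two daughters.

    The split fraction η2 sets daughter volumes V·η2 and V·(1−η2); every
    species goes Binomial(count, η2) to daughter 1, remainder to daughter
    2, so totals are conserved exactly. Each daughter receives a fresh
    adder target from its own birth volume.
    """
    if cell.volume < cell.division_target:
        raise ValueError("cell has not reached its division target")
    eta2 = model.sample_eta2(rng)
    v1 = cell.volume * eta2
    v2 = cell.volume - v1  # exact volume conservation
    m1 = rng.binomial(cell.mrna, eta2)
    p1 = rng.binomial(cell.protein, eta2)
    d1 = CellState(
        volume=v1,
        growth_rate=cell.growth_rate,
        birth_volume=v1,
        division_target=model.division_target(v1, rng),
        mrna=m1,
        protein=p1,
    )
    d2 = CellState(
        volume=v2,
        growth_rate=cell.growth_rate,
        birth_volume=v2,
        division_target=model.division_target(v2, rng),
        mrna=cell.mrna - m1,
        protein=cell.protein - p1,
    )
    return d1, d2


def simulate_population(
    model: GeneExpressionModel,
    config: SimulationConfig,
    division_model: DivisionModel | None = None,
    rng: np.random.Generator | None = None,
    track_cells: tuple[int, ...] = (),
    record_every: int = 10,
) -> tuple[GroundTruthData, pd.DataFrame | None]:
    """Simulate the capped population and return the final snapshot.

    Cells start de-synchronized (volumes uniform on [1, 2), copy numbers at
    the rounded unregulated steady-state means for their volume) and are
    advanced by operator splitting: reactions for τ, exponential growth,
    then division of any cell at its adder target. One daughter keeps the
    parent's slot; the other overwrites a uniformly chosen different slot,
    keeping the population size constant.

    If ``track_cells`` names slot indices, a long-format trajectory table
    (time, cell, gene, mRNA, protein, volume) sampled every
    ``record_every`` windows is returned alongside the snapshot.
    """
    if division_model is None:
        division_model = DivisionModel()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    G, C = model.n_genes, config.n_cells
    mu = config.growth_rate
    V = rng.uniform(1.0, 2.0, size=C)
    V_F = np.full(C, division_model.a * 1.0 + division_model.b)
    M, P = model.steady_state_init(V)
    n_steps = int(round(config.t_end / config.tau))
    growth_factor = float(np.exp(mu * config.tau))
    records: list[tuple] = []

    def record(t: float) -> None:
        for c in track_cells:
            for g in range(G):
                records.append((t, c, g, int(M[g, c]), int(P[g, c]), float(V[c])))

    if track_cells:
        record(0.0)
    for step in range(n_steps):
        if config.method == TAU_LEAPING:
            M, P = _tau_leap(model, M, P, V, config.tau, rng)
        else:
            for c in range(C):
                M[:, c], P[:, c] = _ssa_cell(model, M[:, c], P[:, c], V[c], config.tau, rng)
        V *= growth_factor
        dividers = np.flatnonzero(V >= V_F)
        for i in dividers:
            if V[i] < V_F[i]:  # may have been displaced by an earlier divider
                continue
            eta2 = division_model.sample_eta2(rng)
            m1 = rng.binomial(M[:, i], eta2)
            p1 = rng.binomial(P[:, i], eta2)
            m2 = M[:, i] - m1
            p2 = P[:, i] - p1
            v1 = V[i] * eta2
            v2 = V[i] - v1
            # daughter 1 keeps the parent's slot
            M[:, i], P[:, i], V[i] = m1, p1, v1
            V_F[i] = division_model.division_target(v1, rng)
            # daughter 2 displaces a uniformly chosen other cell
            j = int(rng.integers(C - 1))
            if j >= i:
                j += 1
            M[:, j], P[:, j], V[j] = m2, p2, v2
            V_F[j] = division_model.division_target(v2, rng)
        if track_cells and (step + 1) % record_every == 0:
            record((step + 1) * config.tau)
    snapshot = GroundTruthData(
        mrna=M.copy(), protein=P.copy(), volumes=V.copy(), time=n_steps * config.tau
    )
    trajectory = None
    if track_cells:
        trajectory = pd.DataFrame(
            records, columns=["time", "cell", "gene", "mrna", "protein", "volume"]
        )
    return snapshot, trajectory


def write_ground_truth(gt: GroundTruthData, outdir: str | Path, prefix: str = "gt") -> None:
    """Write counts (CSV and MatrixMarket) and per-cell metadata."""
    from scipy import io as spio
    from scipy import sparse

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = [f"gene_{g}" for g in range(gt.n_genes)]
    cells = [f"cell_{c}" for c in range(gt.n_cells)]
    pd.DataFrame(gt.mrna, index=genes, columns=cells).to_csv(
        outdir / f"{prefix}_mrna.csv"
    )
    pd.DataFrame(gt.protein, index=genes, columns=cells).to_csv(
        outdir / f"{prefix}_protein.csv"
    )
    spio.mmwrite(str(outdir / f"{prefix}_mrna.mtx"), sparse.coo_matrix(gt.mrna))
    (outdir / f"{prefix}_genes.txt").write_text("\n".join(genes) + "\n")
    (outdir / f"{prefix}_cells.txt").write_text("\n".join(cells) + "\n")
    pd.DataFrame({"cell_id": cells, "volume": gt.volumes}).to_csv(
        outdir / f"{prefix}_cells.csv", index=False
    )
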