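"""Per-gene kinetic rates and per-edge Hill regulation parameters.

Each gene carries four rates: basal transcription k1 (molecules per hour
at unit cell volume), translation k2 (per mRNA per hour), mRNA decay dm
and protein decay dp (per hour). Rates are drawn from a multivariate
log-normal over (dp, dm, k1, k2); the shipped default is parameterised to
give mammalian-scale copy numbers (tens of mRNAs, 10^2–10^5 proteins per
cell at unit volume) with positively skewed, nearly uncorrelated
marginals. Parameter sets whose unregulated steady-state protein count
exceeds 100,000 at unit volume are rejected to keep simulations cheap.

Regulation strength is a Hill function of the regulator's mRNA
concentration (copy number per unit cell volume): the Hill coefficient n
is log-uniform on [1, 10] and the dissociation constant K is anchored
proportionally to the regulator's unregulated steady-state mRNA
concentration. Anchoring to the mRNA level keeps regulator and target
fluctuating on comparable (hours-scale) timescales, which is what lets
the regulatory structure leave a detectable imprint on a
single-time-point expression snapshot; using concentrations makes
regulation invariant to cell-cycle position.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .topology import ACTIVATION, INHIBITION

RATE_ORDER = ("protein_decay", "mrna_decay", "transcription", "translation")


class DistributionInfeasibleError(RuntimeError):
    """Raised when the steady-state protein cap rejects essentially all draws."""


@dataclass(frozen=True)
class GeneKinetics:
    """Rates of one gene's two-stage (transcription/translation) expression."""

    k1: float  # basal transcription, molecules/h at unit volume
    k2: float  # translation, 1/h per mRNA
    dm: float  # mRNA decay, 1/h
    dp: float  # protein decay, 1/h

    def __post_init__(self) -> None:
        if min(self.k1, self.k2, self.dm, self.dp) <= 0:
            raise ValueError("all rates must be strictly positive")


@dataclass(frozen=True)
class RegulationEdge:
    """Hill parameters of one regulatory interaction.

    ``hill_K`` is the microscopic dissociation constant in units of the
    regulator's mRNA concentration (copies per unit cell volume).
    """

    hill_n: float
    hill_K: float
    sign: str

    def __post_init__(self) -> None:
        if not (1.0 <= self.hill_n <= 10.0):
            raise ValueError("Hill coefficient must lie in [1, 10]")
        if self.hill_K <= 0:
            raise ValueError("dissociation constant must be positive")
        if self.sign not in (ACTIVATION, INHIBITION):
            raise ValueError(f"unknown sign {self.sign!r}")


@dataclass(frozen=True)
class RateDistribution:
    """Multivariate log-normal over (dp, dm, k1, k2)."""

    log_mean: np.ndarray  # (4,) mean of log rates, order RATE_ORDER
    log_cov: np.ndarray  # (4, 4) covariance of log rates

    def __post_init__(self) -> None:
        lm = np.asarray(self.log_mean, dtype=float)
        lc = np.asarray(self.log_cov, dtype=float)
        if lm.shape != (4,) or lc.shape != (4, 4):
            raise ValueError("log_mean must be (4,), log_cov (4, 4)")
        if not np.allclose(lc, lc.T):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(lc).min() < -1e-10:
            raise ValueError("covariance must be positive semi-definite")
        object.__setattr__(self, "log_mean", lm)
        object.__setattr__(self, "log_cov", lc)


#: Default rate distribution. Log-scale medians correspond to a protein
#: half-life of ~23 h, mRNA half-life of ~7 h, ~2 transcripts/h and
#: ~10 proteins per mRNA per hour, giving median steady states of ~20
#: mRNAs and ~6,700 proteins at unit volume; diagonal covariance reflects
#: the weak inter-rate correlations of mammalian turnover data.
DEFAULT_RATE_DISTRIBUTION = RateDistribution(
    log_mean=np.log([0.03, 0.1, 2.0, 10.0]),
    log_cov=np.diag([0.6, 0.6, 0.8, 0.8]) ** 2,
)

MAX_PROTEIN = 100_000.0


def fit_rate_distribution(rate_table: pd.DataFrame | np.ndarray) -> RateDistribution:
    """Maximum-likelihood log-normal fit to a per-gene rate table.

    The table must have >= 5 rows and columns (or array columns) ordered
    as ``RATE_ORDER``; the MLE is the sample mean and population
    covariance (ddof=0) of the element-wise logarithms.
    """
    if isinstance(rate_table, pd.DataFrame):
        missing = set(RATE_ORDER) - set(rate_table.columns)
        if missing:
            raise ValueError(f"rate table missing columns: {sorted(missing)}")
        values = rate_table.loc[:, list(RATE_ORDER)].to_numpy(dtype=float)
    else:
        values = np.asarray(rate_table, dtype=float)
    if values.ndim != 2 or values.shape[1] != 4:
        raise ValueError("rate table must have 4 columns")
    if (values <= 0).any():
        raise ValueError("all rates must be strictly positive")
    logs = np.log(values)
    mean = logs.mean(axis=0)
    centred = logs - mean
    cov = centred.T @ centred / len(logs)
    return RateDistribution(mean, cov)


def read_rate_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV of per-gene rates with header columns ``RATE_ORDER``."""
    table = pd.read_csv(path)
    missing = set(RATE_ORDER) - set(table.columns)
    if missing:
        raise ValueError(f"rate table missing columns: {sorted(missing)}")
    if (table[list(RATE_ORDER)] <= 0).any().any():
        raise ValueError("all rates must be strictly positive")
    return table


def steady_state_protein(dp: float, dm: float, k1: float, k2: float) -> float:
    """Unregulated steady-state protein mean at unit volume."""
    return k1 * k2 / (dm * dp)


def sample_kinetics(
    n_genes: int,
    dist: RateDistribution = DEFAULT_RATE_DISTRIBUTION,
    max_protein: float = MAX_PROTEIN,
    rng: np.random.Generator | None = None,
) -> list[GeneKinetics]:
    """Draw per-gene rates, rejecting sets with steady-state protein above the cap."""
    if rng is None:
        raise ValueError("rng is required")
    accepted: list[GeneKinetics] = []
    attempts = 0
    while len(accepted) < n_genes:
        batch = max(2 * (n_genes - len(accepted)), 64)
        draws = np.exp(
            rng.multivariate_normal(dist.log_mean, dist.log_cov, size=batch)
        )
        attempts += batch
        for dp, dm, k1, k2 in draws:
            if steady_state_protein(dp, dm, k1, k2) <= max_protein:
                accepted.append(GeneKinetics(k1=k1, k2=k2, dm=dm, dp=dp))
                if len(accepted) == n_genes:
                    break
        if attempts >= 20_000 and len(accepted) / attempts < 1e-4:
            raise DistributionInfeasibleError(
                f"acceptance rate {len(accepted) / attempts:.2e} below 1e-4"
            )
    return accepted


def unregulated_steady_state(gk: GeneKinetics, V: float = 1.0) -> tuple[float, float]:
    """Mean mRNA and protein of the unregulated gene at volume ``V``.

    Transcription scales with volume (k1·V), so both means are linear in V:
    mRNA = k1·V/dm, protein = k1·V·k2/(dm·dp).
    """
    if V <= 0:
        raise ValueError("volume must be positive")
    mean_mrna = gk.k1 * V / gk.dm
    return mean_mrna, mean_mrna * gk.k2 / gk.dp


def sample_hill(
    sign: str,
    regulator_gk: GeneKinetics,
    K_scale: float = 1.0,
    v_ref: float = 1.0,
    rng: np.random.Generator | None = None,
) -> RegulationEdge:
    """Draw Hill parameters for one edge.

    n is log-uniform on [1, 10]; K = K_scale × the regulator's unregulated
    steady-state mRNA concentration, so regulation operates near
    half-saturation. Since both the steady-state copy number and the
    Hill input scale with volume, the concentration anchor k1/dm is
    independent of the reference volume ``v_ref``.
    """
    if rng is None:
        raise ValueError("rng is required")
    if K_scale <= 0:
        raise ValueError("K_scale must be positive")
    hill_n = float(np.exp(rng.uniform(0.0, np.log(10.0))))
    mrna_mean, _ = unregulated_steady_state(regulator_gk, v_ref)
    concentration = mrna_mean / v_ref
    return RegulationEdge(hill_n=hill_n, hill_K=K_scale * concentration, sign=sign)


def hill_activation(x, K: float, n: float):
    """f_act(X) = X^n / (K^n + X^n); 0 at X = 0."""
    x = np.asarray(x, dtype=float)
    ratio = np.power(x / K, n)
    return ratio / (1.0 + ratio)


def hill_inhibition(x, K: float, n: float):
    """f_inh(X) = K^n / (K^n + X^n) = 1 − f_act(X)."""
    x = np.asarray(x, dtype=float)
    ratio = np.power(x / K, n)
    return 1.0 / (1.0 + ratio)
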