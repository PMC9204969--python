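"""Sequencing noise and normalisation: binomial capture, scaling, imputed-file adapter.

A cell's observed transcript counts are a binomial thinning of its true
counts with a cell-specific capture efficiency β_j drawn from a
log-normal centred on the experiment's mean efficiency. The scaling
correction divides each cell's noisy counts by θ_j = β_j·V_j/V_max,
undoing (in expectation) both capture loss and the cell-volume scaling of
transcription. Externally imputed matrices (e.g. from bayNorm, MAGIC,
SAVER or SANITY runs) are loaded through a file adapter; the imputation
algorithms themselves are out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

GT = "GT"
NOISY = "ND"
SCALED = "SD"
IMPUTED = "imputed"

#: Mean capture efficiencies benchmarked by default.
DEFAULT_BETAS = (0.03, 0.1, 0.2, 0.3, 0.5)


class FormatError(ValueError):
    """Raised when an external matrix does not parse or has the wrong shape."""


@dataclass(frozen=True)
class ExpressionDataset:
    """A genes × cells matrix with its processing stage and per-cell metadata."""

    matrix: np.ndarray
    stage: str
    volumes: np.ndarray | None = None
    betas: np.ndarray | None = None

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]


def sample_capture_efficiencies(
    n_cells: int,
    beta_mean: float,
    log_var: float = 0.2,
    rng: np.random.Generator | None = None,
    anchor: str = "mean",
) -> np.ndarray:
    """Draw per-cell capture efficiencies β_j from a log-normal.

    With ``anchor="mean"`` the log-normal's arithmetic mean equals
    ``beta_mean`` (log-mean m = ln β − s²/2); ``anchor="median"`` centres
    the median instead (m = ln β). ``log_var`` is the log-scale variance.
    Draws above 1 are resampled, keeping all β_j in (0, 1].
    """
    if rng is None:
        raise ValueError("rng is required")
    if not (0.0 < beta_mean < 1.0):
        raise ValueError("beta_mean must lie in (0, 1)")
    if log_var < 0:
        raise ValueError("log_var must be non-negative")
    s = float(np.sqrt(log_var))
    if anchor == "mean":
        m = np.log(beta_mean) - log_var / 2.0
    elif anchor == "median":
        m = np.log(beta_mean)
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    if s > 0:
        from scipy.stats import norm

        frac_above_one = float(norm.sf(-m / s))
        if frac_above_one > 0.5:
            raise ValueError(
                f"beta_mean={beta_mean} with log_var={log_var}: "
                f"{frac_above_one:.0%} of draws would exceed 1"
            )
    betas = np.exp(rng.normal(m, s, size=n_cells))
    while (bad := betas > 1.0).any():
        betas[bad] = np.exp(rng.normal(m, s, size=int(bad.sum())))
    return betas


def downsample(
    gt_matrix: np.ndarray, betas: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Binomial capture: entry n_gj → Binomial(n_gj, β_j), independently."""
    gt_matrix = np.asarray(gt_matrix)
    if not np.issubdtype(gt_matrix.dtype, np.integer):
        raise ValueError("ground-truth counts must be integer")
    betas = np.asarray(betas, dtype=float)
    if betas.shape != (gt_matrix.shape[1],):
        raise ValueError("one capture efficiency per cell required")
    if (betas <= 0).any() or (betas > 1).any():
        raise ValueError("capture efficiencies must lie in (0, 1]")
    return rng.binomial(gt_matrix, betas[None, :])


def scaling_factor(betas, volumes, v_max: float):
    """θ_j = β_j · V_j / V_max."""
    if v_max <= 0:
        raise ValueError("V_max must be positive")
    return np.asarray(betas, dtype=float) * np.asarray(volumes, dtype=float) / v_max


def scale_data(nd_matrix: np.ndarray, thetas: np.ndarray) -> np.ndarray:
    """Divide each cell's noisy counts by its scaling factor θ_j (real output)."""
    thetas = np.asarray(thetas, dtype=float)
    if (thetas <= 0).any():
        raise ValueError("scaling factors must be positive")
    return np.asarray(nd_matrix, dtype=float) / thetas[None, :]


def volume_scale(matrix: np.ndarray, volumes: np.ndarray) -> np.ndarray:
    """Divide each cell's counts by its volume (ground-truth correlation convention)."""
    volumes = np.asarray(volumes, dtype=float)
    if (volumes <= 0).any():
        raise ValueError("volumes must be positive")
    return np.asarray(matrix, dtype=float) / volumes[None, :]


def make_noisy_dataset(
    gt: "ExpressionDataset | np.ndarray",
    beta_mean: float,
    rng: np.random.Generator,
    volumes: np.ndarray | None = None,
    log_var: float = 0.2,
) -> ExpressionDataset:
    """Convenience: sample β_j and downsample a ground-truth matrix."""
    if isinstance(gt, ExpressionDataset):
        matrix, volumes = gt.matrix, gt.volumes
    else:
        matrix = gt
    betas = sample_capture_efficiencies(matrix.shape[1], beta_mean, log_var, rng)
    nd = downsample(matrix, betas, rng)
    return ExpressionDataset(nd, NOISY, volumes=volumes, betas=betas)


def make_scaled_dataset(nd: ExpressionDataset) -> ExpressionDataset:
    """Apply the θ scaling to a noisy dataset carrying volumes and betas."""
    if nd.volumes is None or nd.betas is None:
        raise ValueError("noisy dataset must carry volumes and betas")
    thetas = scaling_factor(nd.betas, nd.volumes, float(nd.volumes.max()))
    return ExpressionDataset(
        scale_data(nd.matrix, thetas), SCALED, volumes=nd.volumes, betas=nd.betas
    )


def write_matrix(matrix: np.ndarray, path: str | Path) -> None:
    """Write genes × cells to CSV (gene index, cell-ID header) or MatrixMarket."""
    path = Path(path)
    if path.suffix == ".mtx":
        spio.mmwrite(str(path), sparse.coo_matrix(matrix))
    else:
        genes = [f"gene_{g}" for g in range(matrix.shape[0])]
        cells = [f"cell_{c}" for c in range(matrix.shape[1])]
        pd.DataFrame(matrix, index=genes, columns=cells).to_csv(path)


def write_cell_metadata(
    path: str | Path, volumes: np.ndarray, betas: np.ndarray | None = None
) -> None:
    cells = [f"cell_{c}" for c in range(len(volumes))]
    data = {"cell_id": cells, "volume": volumes}
    if betas is not None:
        data["beta"] = betas
        data["theta"] = scaling_factor(betas, volumes, float(np.max(volumes)))
    pd.DataFrame(data).to_csv(path, index=False)


def load_imputed(
    path: str | Path, expected_shape: tuple[int, int], stage: str = IMPUTED
) -> ExpressionDataset:
    """Load an externally imputed genes × cells matrix (CSV or MatrixMarket).

    The shape must match ``expected_shape`` exactly; a transposed or
    truncated file raises :class:`FormatError`.
    """
    path = Path(path)
    try:
        if path.suffix == ".mtx":
            raw = spio.mmread(str(path))
            matrix = np.asarray(
                raw.todense() if sparse.issparse(raw) else raw, dtype=float
            )
        else:
            matrix = pd.read_csv(path, index_col=0).to_numpy(dtype=float)
    except FormatError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap any parse failure
        raise FormatError(f"could not parse {path}: {exc}") from exc
    if matrix.shape != tuple(expected_shape):
        raise FormatError(
            f"matrix in {path} has shape {matrix.shape}, expected {tuple(expected_shape)}"
        )
    return ExpressionDataset(matrix, stage)
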