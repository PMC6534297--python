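"""Least-squares Zernike decomposition of MP maps and optimiser benchmarking.

The map restricted to the unit disk is modelled as a weighted sum of Zernike
basis functions, ``MP = sum_j C_j Z_j + eps``.  Because the model is linear
in the coefficients, the production fit is a linear least-squares solve on
the pixel-by-basis design matrix; quasi-Newton and Levenberg–Marquardt
solvers are provided only for the optimiser benchmark, which scores each
method by accuracy (mean normalised RMSE on noise-free fields), robustness
(spread of the error under added noise) and uniqueness (coefficient Hamming
distance between generating and recovered vectors).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.linalg import lstsq, matrix_rank
from scipy import optimize

from . import zernike_core as zc
from .map_io import MPMap
from .zernike_core import DiskGrid, design_matrix, index_to_nm, make_disk_grid

FIT_METHODS = ("least_squares", "quasi_newton", "levenberg_marquardt")
NOISE_MODELS = ("gaussian", "uniform")


@dataclass
class CoefficientVector:
    """Ordered Zernike amplitudes ``C_j`` under a fixed indexing convention."""

    values: np.ndarray
    convention: str = "ansi"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size > zc.N_FULL_BASIS:
            raise ValueError(f"at most {zc.N_FULL_BASIS} coefficients supported")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("coefficients must be finite")
        if self.convention not in zc.CONVENTIONS:
            raise ValueError(f"unknown convention {self.convention!r}")

    def __len__(self) -> int:
        return int(self.values.size)

    def to_frame(self) -> pd.DataFrame:
        nm = [index_to_nm(j, self.convention) for j in range(len(self))]
        return pd.DataFrame({
            "j": np.arange(len(self)),
            "n": [n for n, _ in nm],
            "m": [m for _, m in nm],
            "coefficient": self.values,
            "convention": self.convention,
        })

    def save(self, path: str | Path) -> Path:
        self.to_frame().to_csv(path, index=False)
        return Path(path)

    @classmethod
    def load(cls, path: str | Path) -> "CoefficientVector":
        df = pd.read_csv(path)
        conv = str(df["convention"].iloc[0])
        return cls(values=df.sort_values("j")["coefficient"].to_numpy(),
                   convention=conv)


@dataclass
class FitResult:
    coefficients: CoefficientVector
    nrmse: float
    method: str
    grid: DiskGrid = dc_field(repr=False)


@dataclass
class OptimizerReport:
    """Per-method accuracy / robustness / uniqueness scores (benchmark twin)."""

    accuracy: dict
    robustness: dict
    uniqueness: dict
    n_trials: int
    noise_frac: float
    noise_model: str

    def to_frame(self) -> pd.DataFrame:
        methods = list(self.accuracy)
        return pd.DataFrame({
            "method": methods,
            "accuracy_mean_nrmse": [self.accuracy[m] for m in methods],
            "robustness_std_nrmse": [self.robustness[m] for m in methods],
            "uniqueness_mean_hamming": [self.uniqueness[m] for m in methods],
        })


def nrmse(a: MPMap | np.ndarray, b: MPMap | np.ndarray,
          mask: np.ndarray | None = None, normaliser: str = "range") -> float:
    """Normalised RMSE between maps ``a`` (reference) and ``b``.

    The RMSE over unmasked pixels is divided by the reference's value range
    (``normaliser="range"``), mean, or max.  A constant reference makes the
    range normaliser degenerate; it then falls back to max with a warning.
    """
    av = a.values if isinstance(a, MPMap) else np.asarray(a, float)
    bv = b.values if isinstance(b, MPMap) else np.asarray(b, float)
    if av.shape != bv.shape:
        raise ValueError(f"shape mismatch: {av.shape} vs {bv.shape}")
    if mask is None and isinstance(a, MPMap):
        mask = a.grid().mask
    if mask is not None:
        av, bv = av[mask], bv[mask]
    rmse = float(np.sqrt(np.mean((av - bv) ** 2)))
    if normaliser == "range":
        denom = float(av.max() - av.min())
        if denom == 0.0:
            import logging
            logging.getLogger(__name__).warning(
                "constant reference: range normaliser undefined, using max")
            normaliser, denom = "max", float(np.max(np.abs(av)))
    if normaliser == "mean":
        denom = float(np.mean(av))
    elif normaliser == "max":
        denom = float(np.max(np.abs(av)))
    elif normaliser != "range":
        raise ValueError(f"unknown normaliser {normaliser!r}")
    if denom == 0.0:
        return 0.0 if rmse == 0.0 else np.inf
    return rmse / denom


def coefficient_hamming(c1, c2, tol: float = 0.01) -> int:
    """Hamming distance between normalised coefficient vectors.

    Both vectors are normalised by the maximum absolute amplitude of the
    first; positions whose normalised values differ by more than ``tol``
    (default 0.01, i.e. 1%) count as different.
    """
    v1 = c1.values if isinstance(c1, CoefficientVector) else np.asarray(c1, float)
    v2 = c2.values if isinstance(c2, CoefficientVector) else np.asarray(c2, float)
    if v1.shape != v2.shape:
        raise ValueError("coefficient vectors must have equal length")
    scale = float(np.max(np.abs(v1)))
    if scale == 0.0:
        raise ValueError("reference coefficient vector is identically zero")
    return int(np.sum(np.abs(v1 - v2) / scale > tol))


def _solve(A: np.ndarray, y: np.ndarray, method: str) -> np.ndarray:
    if method == "least_squares":
        coef, _, rank, _ = lstsq(A, y, rcond=None)
        if rank < A.shape[1]:
            raise np.linalg.LinAlgError(
                f"rank-deficient design: rank {rank} < {A.shape[1]} columns")
        return coef
    x0 = np.zeros(A.shape[1])
    if method == "quasi_newton":
        res = optimize.minimize(
            lambda c: 0.5 * np.sum((A @ c - y) ** 2), x0,
            jac=lambda c: A.T @ (A @ c - y),
            method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-12})
        return res.x
    if method == "levenberg_marquardt":
        res = optimize.least_squares(
            lambda c: A @ c - y, x0, jac=lambda c: A, method="lm",
            xtol=1e-12, ftol=1e-12, gtol=1e-12)
        return res.x
    raise ValueError(f"unknown fitting method {method!r}; "
                     f"expected one of {FIT_METHODS}")


def fit_zernike(mp: MPMap, J: int = zc.N_FULL_BASIS,
                method: str = "least_squares", convention: str = "ansi",
                normaliser: str = "range") -> FitResult:
    """Fit ``J`` Zernike coefficients to a map over its unit disk.

    For the default linear least-squares method on a full-rank design the
    solution is the unique minimiser of the pixel-wise squared residual;
    the reported normalised RMSE is computed on the unmasked pixels.
    """
    grid = mp.grid()
    A = design_matrix(grid, J, convention)
    y = mp.values[grid.mask]
    coef = _solve(A, y, method)
    resid = nrmse(y, A @ coef, mask=None, normaliser=normaliser)
    return FitResult(CoefficientVector(coef, convention), float(resid),
                     method, grid)


def reconstruct(coeffs: CoefficientVector, grid: DiskGrid,
                convention: str | None = None) -> MPMap:
    """Evaluate a coefficient vector on a disk grid.

    In-disk pixels receive ``sum_j C_j Z_j``; pixels outside the disk are
    set to the NaN sentinel.
    """
    if convention is not None and convention != coeffs.convention:
        raise ValueError(f"convention mismatch: coefficients are "
                         f"{coeffs.convention!r}, requested {convention!r}")
    A = design_matrix(grid, len(coeffs), coeffs.convention)
    values = np.full((grid.size, grid.size), np.nan)
    values[grid.mask] = A @ coeffs.values
    return MPMap(values, grid.centre, grid.radius,
                 meta={"reconstruction": True,
                       "convention": coeffs.convention})


def fit_cohort(maps, J: int = zc.N_FULL_BASIS, method: str = "least_squares",
               convention: str = "ansi") -> np.ndarray:
    """Stack fitted coefficient vectors for a list of maps (rows = maps)."""
    return np.vstack([fit_zernike(m, J, method, convention).coefficients.values
                      for m in maps])


def _random_field(rng: np.random.Generator, A: np.ndarray, J: int):
    """Draw a random coefficient vector, rescale its field to [0, 1].

    Returns the rescaled field and the coefficient vector that generates it
    exactly (the affine rescale maps onto the piston term).
    """
    c = rng.uniform(-1.0, 1.0, size=J)
    field = A @ c
    lo, hi = field.min(), field.max()
    a = 1.0 / (hi - lo)
    c_scaled = a * c
    c_scaled[0] += -lo * a  # piston basis is identically 1
    return a * (field - lo), c_scaled


def evaluate_optimizers(n_trials: int = 10, J: int = zc.N_FULL_BASIS,
                        noise_frac: float = 0.10,
                        methods=FIT_METHODS, size: int = 81,
                        noise_model: str = "gaussian",
                        seed: int | None = None) -> OptimizerReport:
    """Benchmark fitting methods on self-generated Zernike fields.

    Per trial a random coefficient vector is drawn, its field evaluated on
    the disk grid and rescaled to [0, 1].  Accuracy is the mean normalised
    RMSE of the noise-free refit; robustness is the standard deviation of
    the normalised RMSE when noise of amplitude ``noise_frac`` times the
    field range is added (Gaussian by default, uniform selectable);
    uniqueness is the mean coefficient Hamming distance (tolerance 0.01)
    between generating and recovered vectors.  Fully reproducible per seed.
    """
    if not methods:
        raise ValueError("at least one method required")
    for m in methods:
        if m not in FIT_METHODS:
            raise ValueError(f"unknown method {m!r}; expected {FIT_METHODS}")
    if noise_model not in NOISE_MODELS:
        raise ValueError(f"unknown noise model {noise_model!r}")
    rng = np.random.default_rng(seed)
    grid = make_disk_grid(size)
    A = design_matrix(grid, J)
    acc = {m: [] for m in methods}
    rob = {m: [] for m in methods}
    uniq = {m: [] for m in methods}
    for _ in range(n_trials):
        field, c_true = _random_field(rng, A, J)
        rng_range = field.max() - field.min()
        if noise_model == "gaussian":
            noise = rng.normal(0.0, noise_frac * rng_range, size=field.shape)
        else:
            half = noise_frac * rng_range
            noise = rng.uniform(-half, half, size=field.shape)
        noisy = field + noise
        for m in methods:
            c_fit = _solve(A, field, m)
            acc[m].append(nrmse(field, A @ c_fit, normaliser="range"))
            uniq[m].append(coefficient_hamming(c_true, c_fit))
            c_noisy = _solve(A, noisy, m)
            rob[m].append(nrmse(field, A @ c_noisy, normaliser="range"))
    return OptimizerReport(
        accuracy={m: float(np.mean(acc[m])) for m in methods},
        robustness={m: float(np.std(rob[m], ddof=1)) if n_trials > 1 else 0.0
                    for m in methods},
        uniqueness={m: float(np.mean(uniq[m])) for m in methods},
        n_trials=n_trials, noise_frac=noise_frac, noise_model=noise_model)
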