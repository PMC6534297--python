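"""Discriminative ranking and spatial-pattern analysis of Zernike features.

Coefficients are ranked per binary test by the absolute two-sample (two-
tailed) t-statistic, optionally aggregated over leave-one-out repetitions
by a per-position mode consensus.  Each basis function is categorised by
its azimuthal frequency as a magnitude (m = 0), asymmetry (|m| = 1) or
peripheral-irregularity (|m| >= 2) descriptor.  One-way MANOVA (Wilks'
Lambda with Bartlett's chi-square approximation) quantifies overall group
separation, and simple peak/total features provide the conventional
baseline representation for comparison.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fitting import CoefficientVector, reconstruct
from .map_io import MPMap
from .zernike_core import DiskGrid, index_to_nm

logger = logging.getLogger(__name__)

CATEGORIES = ("magnitude", "asymmetry", "irregularity")


def categorize_basis(j: int, convention: str = "ansi") -> str:
    """Spatial-pattern category of basis function ``j``.

    The rule is defined on the azimuthal frequency, so it is independent of
    the indexing convention used to reach ``(n, m)``: rotationally
    symmetric terms (m = 0) describe magnitude, single-lobed terms
    (|m| = 1) radial asymmetry, and higher azimuthal frequencies
    (|m| >= 2) irregularity of the periphery.
    """
    _, m = index_to_nm(j, convention)
    if m == 0:
        return "magnitude"
    if abs(m) == 1:
        return "asymmetry"
    return "irregularity"


@dataclass
class RankingResult:
    """Coefficient indices ordered by discriminative significance."""

    indices: np.ndarray
    scores: np.ndarray
    categories: tuple
    convention: str = "ansi"
    aggregation: str = "single_shot"

    def __post_init__(self):
        self.indices = np.asarray(self.indices, int)
        self.scores = np.asarray(self.scores, float)
        if len(set(self.indices.tolist())) != len(self.indices):
            raise ValueError("ranking contains duplicate indices")

    def top(self, k: int) -> np.ndarray:
        return self.indices[:k]


def _tstats(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-column absolute two-sample t-statistics (pooled variance).

    Columns with zero pooled variance fall back to +inf when the class
    means differ and -inf (ranked last) when they do not.
    """
    Xa, Xb = X[y == 0], X[y == 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t, _ = stats.ttest_ind(Xa, Xb, axis=0)
    t = np.abs(t)
    bad = ~np.isfinite(t)
    if np.any(bad):
        mean_diff = np.abs(Xa.mean(axis=0) - Xb.mean(axis=0))
        t[bad] = np.where(mean_diff[bad] > 0, np.inf, -np.inf)
        logger.warning("%d coefficients had zero pooled variance", bad.sum())
    return t


def rank_ttest(X: np.ndarray, y: np.ndarray,
               convention: str = "ansi") -> RankingResult:
    """Rank coefficients by descending absolute two-sample t-statistic."""
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    for cls in (0, 1):
        if np.sum(y == cls) < 2:
            raise ValueError("each class needs at least 2 samples")
    t = _tstats(X, y)
    order = np.argsort(-t, kind="stable")
    return RankingResult(indices=order, scores=t[order],
                         categories=tuple(categorize_basis(j, convention)
                                          for j in order),
                         convention=convention, aggregation="single_shot")


def loo_consensus_ranking(X: np.ndarray, y: np.ndarray,
                          convention: str = "ansi") -> RankingResult:
    """Consensus ranking over leave-one-out repetitions.

    The ranking is recomputed with each sample left out in turn; the
    consensus index at each position is the mode over repetitions.  An
    index that wins several positions keeps only its highest (earliest)
    one; a vacated position falls to the next-most-frequent index there
    that is still unused, ties breaking to the smaller index.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    n, p = X.shape
    rankings = np.empty((n, p), dtype=int)
    for i in range(n):
        keep = np.arange(n) != i
        rankings[i] = rank_ttest(X[keep], y[keep], convention).indices
    used: set[int] = set()
    consensus = []
    mean_score = np.zeros(p)
    all_scores = _tstats(X, y)
    for pos in range(p):
        counts = Counter(rankings[:, pos].tolist())
        # most frequent unused index at this position; ties -> smaller j
        for j, _ in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
            if j not in used:
                break
        else:
            j = min(set(range(p)) - used)
        used.add(j)
        consensus.append(j)
        mean_score[pos] = all_scores[j]
    consensus = np.asarray(consensus, int)
    return RankingResult(indices=consensus, scores=mean_score,
                         categories=tuple(categorize_basis(j, convention)
                                          for j in consensus),
                         convention=convention, aggregation="loo_mode")


def _scatter_matrices(X: np.ndarray, labels: np.ndarray):
    grand = X.mean(axis=0)
    W = np.zeros((X.shape[1], X.shape[1]))
    B = np.zeros_like(W)
    for g in np.unique(labels):
        Xg = X[labels == g]
        if len(Xg) < 2:
            raise ValueError(f"group {g} has fewer than 2 samples")
        d = Xg - Xg.mean(axis=0)
        W += d.T @ d
        offset = (Xg.mean(axis=0) - grand)[:, None]
        B += len(Xg) * (offset @ offset.T)
    return W, B


def manova_wilks(X: np.ndarray, labels: np.ndarray,
                 shrink: bool | None = None) -> tuple[float, float]:
    """One-way MANOVA: Wilks' Lambda and Bartlett's approximate p-value.

    Lambda = det(W) / det(W + B) from the within- and between-group
    scatter matrices.  When the within scatter is singular or nearly so
    (more features than residual degrees of freedom), a Ledoit–Wolf-style
    shrinkage towards the scaled identity is applied to W before the
    determinant ratio (logged); ``shrink`` forces the behaviour either way.
    """
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("MANOVA needs at least 2 groups")
    n, p = X.shape
    g = len(groups)
    W, B = _scatter_matrices(X, labels)
    if shrink is None:
        shrink = (n - g) <= p or np.linalg.cond(W) > 1e12
    if shrink:
        from sklearn.covariance import ledoit_wolf

        # shrinkage intensity estimated on the pooled within-group residuals
        resid = np.vstack([X[labels == gg] - X[labels == gg].mean(axis=0)
                           for gg in groups])
        _, gamma = ledoit_wolf(resid, assume_centered=True)
        mu = np.trace(W) / p
        W = (1.0 - gamma) * W + gamma * mu * np.eye(p)
        logger.info("MANOVA within-scatter shrinkage gamma=%.4f", gamma)
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(W + B)
    if sign_t <= 0:
        raise np.linalg.LinAlgError("total scatter is not positive definite")
    if sign_w == 0 or not np.isfinite(logdet_w):
        lam = 0.0  # exactly singular within-scatter: perfect separation
    elif sign_w < 0:
        raise np.linalg.LinAlgError("within scatter is not positive definite")
    else:
        lam = float(np.exp(logdet_w - logdet_t))
    # Bartlett's chi-square approximation
    if lam == 0.0:
        return 0.0, 0.0
    chi2 = -(n - 1 - (p + g) / 2.0) * np.log(lam)
    df = p * (g - 1)
    p_value = float(stats.chi2.sf(chi2, df))
    return lam, p_value


@dataclass
class GroupSummary:
    """Per-group mean coefficient vectors and their reconstructed maps."""

    mean_coefficients: dict
    mean_maps: dict
    n_samples: dict


def group_mean_maps(coeff_matrix: np.ndarray, labels: np.ndarray,
                    grid: DiskGrid, convention: str = "ansi",
                    outdir=None) -> GroupSummary:
    """Mean coefficient vector per group, reconstructed on ``grid``.

    When ``outdir`` is given, 3-D elevation and 2-D contour figures are
    written there (one pair per group).
    """
    coeff_matrix = np.asarray(coeff_matrix, float)
    labels = np.asarray(labels)
    means, maps, ns = {}, {}, {}
    for g in np.unique(labels):
        cv = CoefficientVector(coeff_matrix[labels == g].mean(axis=0),
                               convention)
        means[int(g)] = cv
        maps[int(g)] = reconstruct(cv, grid)
        ns[int(g)] = int(np.sum(labels == g))
    if outdir is not None:
        _plot_group_maps(maps, outdir)
    return GroupSummary(mean_coefficients=means, mean_maps=maps, n_samples=ns)


def _plot_group_maps(maps: dict, outdir) -> None:
    from pathlib import Path

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for g, mp in maps.items():
        vals = np.ma.masked_invalid(mp.values)
        fig = plt.figure(figsize=(10, 4))
        ax1 = fig.add_subplot(1, 2, 1, projection="3d")
        size = mp.size
        xx, yy = np.meshgrid(np.arange(size), np.arange(size))
        ax1.plot_surface(xx, yy, np.where(np.isfinite(mp.values),
                                          mp.values, 0.0),
                         cmap="viridis", linewidth=0)
        ax1.set_title(f"group {g} mean MP (elevation)")
        ax2 = fig.add_subplot(1, 2, 2)
        cs = ax2.contour(vals, levels=10)
        ax2.clabel(cs, inline=True, fontsize=6)
        ax2.set_aspect("equal")
        ax2.set_title(f"group {g} mean MP (contours)")
        fig.savefig(outdir / f"group{g}_mean_map.png", dpi=120)
        plt.close(fig)


def baseline_features(mp: MPMap) -> tuple[float, float]:
    """Conventional scalar MP features: peak value and total amount.

    ``peak`` is the maximum over in-disk pixels; ``total`` integrates the
    in-disk values with pixel area ``(2/size)^2`` in unit-disk units (the
    disk spans [-1, 1] in both axes).
    """
    grid = mp.grid()
    vals = mp.values[grid.mask]
    pixel_area = (2.0 / mp.size) ** 2
    return float(vals.max()), float(vals.sum() * pixel_area)


def baseline_matrix(maps) -> np.ndarray:
    """Stack (peak, total) baseline features for a list of maps."""
    return np.array([baseline_features(m) for m in maps], dtype=float)
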