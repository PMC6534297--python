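"""Reading, writing and preprocessing of macular pigment (MP) maps.

An MP map is a square matrix of pigment concentration values in [0, 1]
covering a 4-degree-eccentricity patch centred on the foveola.  Maps arrive
either as delimited-text matrices (CSV/TSV) or as 8/16-bit grayscale images,
which are linearly rescaled full-range to [0, 1].  Any clamping or rescaling
applied on load is recorded through the module logger and in the map
metadata — loading never silently alters values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .zernike_core import DiskGrid, make_disk_grid

logger = logging.getLogger(__name__)

DEFAULT_SIZE = 81

MANIFEST_COLUMNS = ("path", "subject", "group")


@dataclass
class MPMap:
    """A square MP concentration map with its unit-disk geometry.

    Attributes
    ----------
    values : ndarray
        ``size x size`` matrix of concentrations (arbitrary units, [0, 1]).
    centre : (row, col)
        Sub-pixel disk centre; defaults to the geometric grid centre.
    disk_radius : float
        Disk radius in pixels; defaults to ``(size-1)/2``.
    centring_mode : {"foveola", "peak"}
        Whether the disk sits at the manually placed foveola (as loaded) or
        has been translated onto the MP peak.
    meta : dict
        Provenance: subject id, group label (1, 2, or 3), source tag,
        scaling/clamping notes.
    """

    values: np.ndarray
    centre: tuple[float, float] | None = None
    disk_radius: float | None = None
    centring_mode: str = "foveola"
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"map must be square, got shape {self.values.shape}")
        s = self.size
        if self.centre is None:
            self.centre = ((s - 1) / 2.0, (s - 1) / 2.0)
        if self.disk_radius is None:
            self.disk_radius = (s - 1) / 2.0

    @property
    def size(self) -> int:
        return int(self.values.shape[0])

    def grid(self) -> DiskGrid:
        """Unit-disk sampling of this map's pixel raster."""
        return make_disk_grid(self.size, self.centre, self.disk_radius)

    def disk_values(self) -> np.ndarray:
        """Flat vector of values over the unmasked (in-disk) pixels."""
        return self.values[self.grid().mask]


def load_map(path: str | Path, format: str | None = None) -> MPMap:
    """Load an MP map from a delimited-text matrix or grayscale image.

    Text matrices must be rectangular, numeric and NaN-free.  Grayscale
    images (PNG/TIFF, 8- or 16-bit) are linearly rescaled full-range to
    [0, 1] (value / dtype max); the scaling is recorded in ``meta``.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    meta: dict = {"source": str(path)}
    if fmt in ("csv", "tsv", "txt"):
        sep = "\t" if fmt == "tsv" else ","
        try:
            df = pd.read_csv(path, header=None, sep=sep)
        except pd.errors.ParserError as exc:
            raise ValueError(f"ragged or malformed matrix in {path}: {exc}") from exc
        values = df.to_numpy(dtype=float)
        bad = np.argwhere(~np.isfinite(values))
        if bad.size:
            r, c = bad[0]
            raise ValueError(f"non-finite cell at row {r}, col {c} in {path}")
    elif fmt in ("png", "tif", "tiff"):
        import imageio.v3 as iio

        img = iio.imread(path)
        if img.ndim == 3:
            # accept only degenerate colour (all bands equal)
            if img.shape[2] > 1 and not np.array_equal(img[..., 0], img[..., 1]):
                raise ValueError(f"non-grayscale image (band 1 differs) in {path}")
            img = img[..., 0]
        if img.dtype == np.uint8:
            scale = 255.0
        elif img.dtype == np.uint16:
            scale = 65535.0
        else:
            raise ValueError(f"unsupported image dtype {img.dtype} in {path}")
        values = img.astype(float) / scale
        meta["scaling"] = f"full-range /{int(scale)}"
        logger.info("rescaled %s by 1/%d to [0,1]", path.name, int(scale))
    else:
        raise ValueError(f"unknown map format: {fmt!r}")

    if values.shape[0] != values.shape[1]:
        raise ValueError(f"map must be square, got {values.shape} in {path}")
    lo, hi = float(values.min()), float(values.max())
    if lo < 0.0 or hi > 1.0:
        n_clamped = int(np.sum((values < 0) | (values > 1)))
        logger.warning("clamping %d pixels of %s into [0,1] (range %.3g..%.3g)",
                       n_clamped, path.name, lo, hi)
        meta["clamped_pixels"] = n_clamped
        values = np.clip(values, 0.0, 1.0)
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    return MPMap(values=values, meta=meta)


def save_map(mp: MPMap, path: str | Path, sidecar: bool = False) -> Path:
    """Write a map as CSV (exact) or 16-bit PNG (quantised to 1/65535)."""
    path = Path(path)
    fmt = path.suffix.lstrip(".").lower()
    if fmt == "csv":
        np.savetxt(path, mp.values, delimiter=",", fmt="%.17g")
    elif fmt == "png":
        import imageio.v3 as iio

        iio.imwrite(path, np.round(np.clip(mp.values, 0, 1) * 65535).astype(np.uint16))
    else:
        raise ValueError(f"unsupported save format: {fmt!r}")
    if sidecar:
        side = path.with_suffix(path.suffix + ".json")
        side.write_text(json.dumps(
            {k: v for k, v in mp.meta.items() if isinstance(v, (str, int, float))},
            indent=2))
    return path


def gaussian_smooth(mp: MPMap, sigma: float) -> MPMap:
    """Convolve a map with an isotropic Gaussian kernel of width ``sigma`` px.

    Boundaries use nearest-neighbour extension so the in-disk mass is
    preserved up to boundary effects; a constant map is returned unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return MPMap(mp.values.copy(), mp.centre, mp.disk_radius,
                     mp.centring_mode, dict(mp.meta))
    sm = ndimage.gaussian_filter(mp.values, sigma=sigma, mode="nearest")
    return MPMap(sm, mp.centre, mp.disk_radius, mp.centring_mode, dict(mp.meta))


def _integer_shift_edge(values: np.ndarray, drow: int, dcol: int) -> np.ndarray:
    """Translate by whole pixels, filling vacated borders by edge replication."""
    padded = np.pad(values, ((max(drow, 0), max(-drow, 0)),
                             (max(dcol, 0), max(-dcol, 0))), mode="edge")
    r0 = max(-drow, 0)
    c0 = max(-dcol, 0)
    return padded[r0:r0 + values.shape[0], c0:c0 + values.shape[1]]


def recentre_on_peak(mp: MPMap, smoothing_sigma: float = 2.0) -> MPMap:
    """Translate a map so the (smoothed) MP peak sits at the grid centre.

    The peak is located on a Gaussian-smoothed copy (default sigma 2 px,
    robust to single-pixel spikes); the translation itself is applied to the
    raw values with edge replication on vacated borders.  Ties between equal
    maxima break deterministically to the lowest row, then lowest column.
    Idempotent: a map already peaked at centre is returned unchanged.
    """
    smoothed = gaussian_smooth(mp, smoothing_sigma).values if smoothing_sigma > 0 \
        else mp.values
    flat = np.argwhere(smoothed == smoothed.max())
    if len(flat) > 1:
        logger.warning("%d tied maxima; breaking tie to lowest row, then col",
                       len(flat))
    peak = tuple(int(v) for v in flat[0])  # argwhere scans rows then cols
    target = (int(round((mp.size - 1) / 2.0)),) * 2
    drow, dcol = target[0] - peak[0], target[1] - peak[1]
    if (drow, dcol) != (0, 0):
        logger.info("recentring: translating by (%d, %d) px with edge fill",
                    drow, dcol)
    shifted = _integer_shift_edge(mp.values, drow, dcol)
    meta = dict(mp.meta)
    meta["recentre_translation"] = (drow, dcol)
    return MPMap(shifted, ((mp.size - 1) / 2.0, (mp.size - 1) / 2.0),
                 mp.disk_radius, "peak", meta)


def radial_profile(mp: MPMap, centre: tuple[float, float] | None = None,
                   n_bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Mean map value per radial bin over the unit disk.

    Bin ``b`` averages values with ``rho`` in ``[b/n_bins, (b+1)/n_bins)``
    (the outermost bin is closed at 1).  Returns ``(profile, counts)``;
    empty bins hold NaN and count 0.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    grid = make_disk_grid(mp.size, centre or mp.centre, mp.disk_radius)
    vals = mp.values[grid.mask]
    idx = np.minimum((grid.rho * n_bins).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=vals, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        profile = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if np.any(counts == 0):
        logger.warning("radial profile has %d empty bins", int(np.sum(counts == 0)))
    return profile, counts


@dataclass
class CohortManifest:
    """Table assigning each map file a subject id and a group label (1/2/3)."""

    table: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in MANIFEST_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        groups = set(self.table["group"].astype(int))
        if not groups <= {1, 2, 3}:
            raise ValueError(f"group labels must be in {{1,2,3}}, got {sorted(groups)}")

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def read(cls, path: str | Path, check_files: bool = True) -> "CohortManifest":
        table = pd.read_csv(path)
        man = cls(table=table)
        if check_files:
            base = Path(path).parent
            for i, p in enumerate(table["path"]):
                if not (base / p).exists() and not Path(p).exists():
                    raise FileNotFoundError(f"manifest row {i}: missing file {p}")
        return man

    def write(self, path: str | Path) -> Path:
        self.table.to_csv(path, index=False)
        return Path(path)

    def load_maps(self, base: str | Path | None = None) -> list[MPMap]:
        base = Path(base) if base is not None else Path(".")
        maps = []
        for _, row in self.table.iterrows():
            p = Path(row["path"])
            if not p.exists():
                p = base / row["path"]
            m = load_map(p)
            m.meta.update(subject=row["subject"], group=int(row["group"]))
            maps.append(m)
        return maps
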