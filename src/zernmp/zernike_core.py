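"""Zernike basis functions on the unit disk.

The Zernike polynomials form an orthogonal family on the unit disk, indexed
by a radial order ``n`` and a signed azimuthal frequency ``m`` with
``|m| <= n`` and ``n - |m|`` even.  A basis function is the product of a
radial polynomial :math:`R_n^{|m|}(\\rho)` and an azimuthal harmonic,
``cos(m phi)`` for ``m >= 0`` and ``sin(|m| phi)`` for ``m < 0``.  No
normalisation factor is applied, so every basis function is bounded by 1 in
absolute value on the disk.

Two sequential orderings of the same 105 functions (all complete radial
orders ``n = 0..13``) are supported:

``ansi``
    OSA/ANSI single index ``j = (n(n+2) + m) / 2``.
``noll0``
    Zero-based Noll ordering (the classical Noll index minus one), under
    which defocus ("cup") is term 3 and primary spherical ("Mexican hat")
    is term 10.

Either convention is a pure permutation of the other; fitting and
reconstructing under a fixed convention are equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from math import factorial

import numpy as np

#: Number of basis functions spanning all complete radial orders n = 0..13.
N_FULL_BASIS = 105
#: Highest radial order included in the full 105-term basis.
MAX_RADIAL_ORDER = 13

CONVENTIONS = ("ansi", "noll0")


@dataclass(frozen=True)
class ZernikeIndex:
    """Identity of a single basis function.

    Attributes
    ----------
    n : int
        Radial order (non-negative).
    m : int
        Signed azimuthal frequency, ``|m| <= n`` with ``n - |m|`` even.
    j : int
        Sequential index under the ANSI convention.
    """

    n: int
    m: int
    j: int


def _check_nm(n: int, m: int) -> None:
    if n < 0:
        raise ValueError(f"radial order must be non-negative, got n={n}")
    if abs(m) > n:
        raise ValueError(f"|m| must not exceed n, got (n, m)=({n}, {m})")
    if (n - abs(m)) % 2 != 0:
        raise ValueError(f"n - |m| must be even, got (n, m)=({n}, {m})")


def ansi_index(n: int, m: int) -> int:
    """ANSI sequential index ``j = (n(n+2) + m) / 2`` of a valid ``(n, m)``."""
    _check_nm(n, m)
    return (n * (n + 2) + m) // 2


def ansi_to_nm(j: int) -> tuple[int, int]:
    """Invert the ANSI sequential index back to ``(n, m)``."""
    if j < 0:
        raise ValueError(f"sequential index must be non-negative, got {j}")
    # smallest n with n(n+2)/2 + n/2... solve n from j range [n(n+2)-n, n(n+2)+n]/2
    n = int(np.ceil((-3.0 + np.sqrt(9.0 + 8.0 * j)) / 2.0))
    m = 2 * j - n * (n + 2)
    _check_nm(n, m)
    return n, m


def _noll_index(n: int, m: int) -> int:
    """Classical (one-based) Noll index of ``(n, m)``."""
    base = n * (n + 1) // 2 + abs(m)
    if n % 4 in (0, 1):
        extra = 1 if m <= 0 else 0
    else:
        extra = 1 if m >= 0 else 0
    return base + extra


@lru_cache(maxsize=4)
def _noll0_table(n_terms: int = N_FULL_BASIS) -> tuple[tuple[int, int], ...]:
    """(n, m) pairs in zero-based Noll order for the first ``n_terms`` terms."""
    pairs = []
    for n in range(MAX_RADIAL_ORDER + 1):
        for m in range(-n, n + 1, 2):
            pairs.append((_noll_index(n, m), n, m))
    pairs.sort()
    nolls = [p[0] for p in pairs]
    if nolls != list(range(1, len(pairs) + 1)):  # pragma: no cover - sanity
        raise RuntimeError("Noll index table is not a bijection")
    return tuple((n, m) for _, n, m in pairs[:n_terms])


def index_to_nm(j: int, convention: str = "ansi") -> tuple[int, int]:
    """Map a sequential index to ``(n, m)`` under the given convention."""
    if convention == "ansi":
        return ansi_to_nm(j)
    if convention == "noll0":
        table = _noll0_table()
        if not 0 <= j < len(table):
            raise ValueError(f"noll0 index out of range: {j}")
        return table[j]
    raise ValueError(f"unknown indexing convention: {convention!r}")


def nm_to_index(n: int, m: int, convention: str = "ansi") -> int:
    """Map ``(n, m)`` to the sequential index under the given convention."""
    if convention == "ansi":
        return ansi_index(n, m)
    if convention == "noll0":
        _check_nm(n, m)
        return _noll0_table().index((n, m))
    raise ValueError(f"unknown indexing convention: {convention!r}")


@lru_cache(maxsize=256)
def _radial_coeffs(n: int, m_abs: int) -> tuple[float, ...]:
    """Monomial coefficients of R_n^m, highest power first (np.polyval order)."""
    coeffs = [0.0] * (n + 1)
    for k in range((n - m_abs) // 2 + 1):
        c = ((-1) ** k * factorial(n - k)
             / (factorial(k)
                * factorial((n + m_abs) // 2 - k)
                * factorial((n - m_abs) // 2 - k)))
        coeffs[n - (n - 2 * k)] = float(c)  # position of power n-2k from front
    return tuple(coeffs)


def radial_poly(n: int, m: int, rho):
    """Radial polynomial :math:`R_n^{|m|}` evaluated at ``rho``.

    ``rho`` may be a scalar or array; values are expected in [0, 1] where the
    defining finite sum is bounded by 1.
    """
    _check_nm(n, m)
    coeffs = _radial_coeffs(n, abs(m))
    return np.polyval(coeffs, np.asarray(rho, dtype=float))


def basis_value(j: int, rho, phi, convention: str = "ansi"):
    """Value of basis function ``Z_j`` at polar coordinates ``(rho, phi)``.

    For ``m >= 0`` the even (cosine) harmonic is used, for ``m < 0`` the odd
    (sine) harmonic.  ``rho`` must lie in [0, 1].
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0) or np.any(rho > 1):
        raise ValueError("rho must lie within [0, 1]")
    n, m = index_to_nm(j, convention)
    r = radial_poly(n, abs(m), rho)
    if m >= 0:
        return r * np.cos(m * np.asarray(phi, dtype=float))
    return r * np.sin(abs(m) * np.asarray(phi, dtype=float))


@dataclass
class DiskGrid:
    """Polar sampling of a square pixel grid restricted to the unit disk.

    ``rho`` and ``phi`` are flat arrays over the unmasked (in-disk) pixels,
    in row-major pixel order.  ``mask`` is True for in-disk pixels.  The
    azimuth is measured counter-clockwise from the +x image axis, with the
    row index increasing downward (so +y points up the image).
    """

    size: int
    centre: tuple[float, float]
    radius: float
    mask: np.ndarray = field(repr=False)
    rho: np.ndarray = field(repr=False)
    phi: np.ndarray = field(repr=False)

    @property
    def n_unmasked(self) -> int:
        return int(self.rho.size)

    def key(self) -> tuple:
        """Hashable descriptor used for design-matrix caching."""
        return (self.size, round(self.centre[0], 6), round(self.centre[1], 6),
                round(self.radius, 6))


def make_disk_grid(size: int, centre: tuple[float, float] | None = None,
                   radius: float | None = None) -> DiskGrid:
    """Build the unit-disk sampling of a ``size``-pixel square grid.

    Pixel-centre coordinates are used; a boundary pixel is kept iff its
    radial distance satisfies ``rho <= 1`` exactly.

    Parameters
    ----------
    size : int
        Pixels per side, at least 3.
    centre : (row, col), optional
        Sub-pixel disk centre; defaults to the geometric centre
        ``((size-1)/2, (size-1)/2)``.
    radius : float, optional
        Disk radius in pixels; defaults to ``(size-1)/2``.
    """
    if size < 3:
        raise ValueError(f"grid size must be at least 3, got {size}")
    if centre is None:
        centre = ((size - 1) / 2.0, (size - 1) / 2.0)
    if radius is None:
        radius = (size - 1) / 2.0
    if radius <= 0:
        raise ValueError(f"disk radius must be positive, got {radius}")
    rows, cols = np.mgrid[0:size, 0:size].astype(float)
    dy = centre[0] - rows  # +y up the image
    dx = cols - centre[1]
    rho = np.hypot(dx, dy) / radius
    mask = rho <= 1.0
    phi = np.mod(np.arctan2(dy, dx), 2.0 * np.pi)
    return DiskGrid(size=size, centre=(float(centre[0]), float(centre[1])),
                    radius=float(radius), mask=mask,
                    rho=rho[mask], phi=phi[mask])


_DESIGN_CACHE: dict[tuple, np.ndarray] = {}


def design_matrix(grid: DiskGrid, J: int = N_FULL_BASIS,
                  convention: str = "ansi", cache: bool = True) -> np.ndarray:
    """Basis evaluation matrix over the unmasked pixels of ``grid``.

    Column ``j`` holds ``Z_j(rho, phi)`` at every in-disk pixel; columns are
    ordered by the sequential index of the chosen convention.
    """
    if not 1 <= J <= N_FULL_BASIS:
        raise ValueError(f"J must be in 1..{N_FULL_BASIS}, got {J}")
    key = grid.key() + (convention,)
    cached = _DESIGN_CACHE.get(key)
    if cached is not None and cached.shape[1] >= J:
        return cached[:, :J]
    A = np.empty((grid.n_unmasked, J), dtype=float)
    for j in range(J):
        A[:, j] = basis_value(j, grid.rho, grid.phi, convention)
    if cache and J == N_FULL_BASIS:
        if len(_DESIGN_CACHE) > 16:
            _DESIGN_CACHE.clear()
        _DESIGN_CACHE[key] = A
    return A


def convention_permutation(convention: str) -> np.ndarray:
    """Permutation ``p`` with ``p[j_conv] = j_ansi`` over the full basis."""
    if convention == "ansi":
        return np.arange(N_FULL_BASIS)
    return np.array([ansi_index(*index_to_nm(j, convention))
                     for j in range(N_FULL_BASIS)])
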