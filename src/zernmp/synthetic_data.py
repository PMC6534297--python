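"""Synthetic MP phantom maps with group-structured spatial patterns.

The generator emulates the three qualitative contrasts reported between
subject groups: a high, rotationally symmetric central peak for younger
healthy subjects (group 1); a moderate peak with radial asymmetry for older
subjects without disease (group 2); and an elevated peripheral baseline with
irregular high-azimuthal-frequency texture and a reduced relative peak for
older subjects with AMD (group 3).

A phantom is built as

    baseline + peak * Gaussian(offset centre)
             + asymmetry * rho * cos(phi - orientation)
             + irregularity * (weighted high-|m| Zernike components)
             + pixel noise,

clamped to [0, 1].  The central peak is a raised Gaussian — deliberately
outside the Zernike span — so that fitting the phantoms is a genuine
approximation problem rather than a circular exercise.  The asymmetry
orientation and the irregularity component set are population-level
characteristics: cohorts draw them once and jitter them per subject, which
is what makes the planted contrasts visible to mean-based statistics
(t-ranking, LDA) the way systematic anatomical patterns would be.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .map_io import CohortManifest, MPMap, save_map
from .zernike_core import basis_value, index_to_nm, make_disk_grid

logger = logging.getLogger(__name__)

#: Coefficient of variation of the per-subject log-normal parameter jitter.
SUBJECT_JITTER_CV = 0.20
#: Standard deviation (radians) of per-subject asymmetry-orientation jitter.
ORIENTATION_JITTER_SD = 0.2
#: Number of high-|m| basis components in an irregularity template.
N_IRREGULAR_COMPONENTS = 4

MAX_CLAMP_FRACTION = 0.20


@dataclass
class GroupPhantomParams:
    """Generative parameters of a group phantom (all amplitudes in A.U.).

    ``peak_width`` is the Gaussian sigma as a fraction of the disk radius;
    ``centre_offset`` displaces the peak radially by that many pixels (the
    direction is drawn per map); ``irregularity_components`` fixes the
    high-|m| texture as ``(ansi_index, weight)`` pairs — when None, a
    template is drawn from the map's own random stream.
    """

    peak_amplitude: float
    peak_width: float = 0.35
    centre_offset: float = 0.0
    asymmetry_amplitude: float = 0.0
    asymmetry_orientation: float = 0.0
    irregularity_amplitude: float = 0.0
    irregularity_min_order: int = 3
    irregularity_components: tuple | None = None
    peripheral_baseline: float = 0.15
    noise_sd: float = 0.02

    def __post_init__(self):
        for name in ("peak_amplitude", "asymmetry_amplitude",
                     "irregularity_amplitude", "peripheral_baseline",
                     "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def replace(self, **kw) -> "GroupPhantomParams":
        return dataclasses.replace(self, **kw)


def default_group_params(group: int) -> GroupPhantomParams:
    """Default phantom parameters for cohort groups 1, 2 and 3.

    Group 1 (under 50, no AMD): high symmetric peak, no asymmetry or
    irregularity.  Group 2 (50+, no AMD): moderate peak with radial
    asymmetry.  Group 3 (50+, AMD): reduced relative peak, elevated
    peripheral baseline, irregular peripheral texture.  The numeric values
    are a documented calibration of the generator, not measured quantities.
    """
    if group == 1:
        return GroupPhantomParams(peak_amplitude=0.55, peak_width=0.35,
                                  centre_offset=0.5, peripheral_baseline=0.15)
    if group == 2:
        return GroupPhantomParams(peak_amplitude=0.40, peak_width=0.35,
                                  centre_offset=1.0, asymmetry_amplitude=0.08,
                                  peripheral_baseline=0.15)
    if group == 3:
        return GroupPhantomParams(peak_amplitude=0.30, peak_width=0.40,
                                  centre_offset=1.5,
                                  irregularity_amplitude=0.06,
                                  peripheral_baseline=0.25)
    raise ValueError(f"unknown group {group!r}; expected 1, 2 or 3")


def draw_irregularity_components(rng: np.random.Generator,
                                 min_order: int = 3,
                                 n_components: int = N_IRREGULAR_COMPONENTS
                                 ) -> tuple:
    """Draw a high-azimuthal-frequency texture template.

    Components are ANSI indices with ``|m| >= min_order`` and ``n <= 9``,
    with random weights normalised to unit maximum absolute weight.
    """
    candidates = [j for j in range(105)
                  for (n, m) in [index_to_nm(j)]
                  if abs(m) >= min_order and n <= 9]
    picks = rng.choice(len(candidates), size=n_components, replace=False)
    weights = rng.normal(size=n_components)
    weights /= np.max(np.abs(weights))
    return tuple((int(candidates[i]), float(w)) for i, w in zip(picks, weights))


def _component_fields(params: GroupPhantomParams, size: int,
                      rng: np.random.Generator):
    """Noise-free additive components of a phantom, plus realised draws."""
    grid_centre = ((size - 1) / 2.0, (size - 1) / 2.0)
    radius = (size - 1) / 2.0
    rows, cols = np.mgrid[0:size, 0:size].astype(float)
    dy = grid_centre[0] - rows
    dx = cols - grid_centre[1]
    rho = np.hypot(dx, dy) / radius
    phi = np.mod(np.arctan2(dy, dx), 2.0 * np.pi)
    # Zernike components are radially clamped at the disk edge so corner
    # pixels (rho > 1) stay bounded.
    rho_c = np.minimum(rho, 1.0)

    offset_angle = float(rng.uniform(0.0, 2.0 * np.pi))
    off = params.centre_offset / radius
    peak_x, peak_y = off * np.cos(offset_angle), off * np.sin(offset_angle)
    d2 = (dx / radius - peak_x) ** 2 + (dy / radius - peak_y) ** 2
    peak = params.peak_amplitude * np.exp(-d2 / (2.0 * params.peak_width ** 2))

    asym = (params.asymmetry_amplitude * rho_c
            * np.cos(phi - params.asymmetry_orientation))

    components = params.irregularity_components
    if components is None and params.irregularity_amplitude > 0:
        components = draw_irregularity_components(
            rng, params.irregularity_min_order)
    irr = np.zeros_like(rho)
    if params.irregularity_amplitude > 0 and components:
        for j, w in components:
            irr += w * basis_value(j, rho_c.ravel(), phi.ravel()).reshape(rho.shape)
        irr *= params.irregularity_amplitude / max(np.max(np.abs(irr)), 1e-12)
    return peak, asym, irr, components, offset_angle


def phantom_map(params: GroupPhantomParams, size: int = 81,
                seed: int | None = None,
                rng: np.random.Generator | None = None
                ) -> tuple[MPMap, dict]:
    """Generate one phantom map and its ground-truth record.

    The ground truth records every planted component (including realised
    random draws) so the noise-free phantom can be rebuilt exactly; see
    :func:`reconstruct_truth`.  Raises if more than 20% of pixels would be
    clamped out of [0, 1].
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    peak, asym, irr, components, offset_angle = _component_fields(
        params, size, rng)
    clean = params.peripheral_baseline + peak + asym + irr
    noise = rng.normal(0.0, params.noise_sd, size=clean.shape) \
        if params.noise_sd > 0 else 0.0
    values = clean + noise
    clamped = np.mean((values < 0.0) | (values > 1.0))
    if clamped > MAX_CLAMP_FRACTION:
        raise ValueError(f"phantom out of range: {clamped:.0%} of pixels "
                         f"clamped (limit {MAX_CLAMP_FRACTION:.0%})")
    if clamped > 0:
        logger.info("clamped %.2f%% of phantom pixels", 100 * clamped)
    values = np.clip(values, 0.0, 1.0)
    truth = {
        "params": dataclasses.asdict(params),
        "size": size,
        "offset_angle": offset_angle,
        "irregularity_components": components,
        "clamp_fraction": float(clamped),
    }
    mp = MPMap(values, meta={"source": "phantom"})
    return mp, truth


def reconstruct_truth(truth: dict) -> np.ndarray:
    """Rebuild the noise-free phantom exactly from its ground-truth record."""
    p = dict(truth["params"])
    p["irregularity_components"] = (
        tuple(tuple(c) for c in truth["irregularity_components"])
        if truth["irregularity_components"] else None)
    params = GroupPhantomParams(**p)
    size = truth["size"]

    class _Replay:
        def __init__(self, angle):
            self.angle = angle

        def uniform(self, lo, hi):
            return self.angle

    peak, asym, irr, _, _ = _component_fields(
        params, size, _Replay(truth["offset_angle"]))
    return np.clip(params.peripheral_baseline + peak + asym + irr, 0.0, 1.0)


def _jitter(rng: np.random.Generator, value: float,
            cv: float = SUBJECT_JITTER_CV) -> float:
    """Multiplicative log-normal jitter with the given CV (no-op on zero)."""
    if value == 0.0 or cv == 0.0:
        return value
    sigma = np.sqrt(np.log1p(cv ** 2))
    return float(value * rng.lognormal(-0.5 * sigma ** 2, sigma))


def make_cohort(n_per_group: int = 30, seed: int | None = None,
                size: int = 81, groups=(1, 2, 3),
                group_params: dict | None = None
                ) -> tuple[CohortManifest, list[MPMap], list[dict]]:
    """Generate a balanced synthetic cohort with per-subject variability.

    Population-level draws (asymmetry orientation, irregularity template)
    are made once per cohort; each subject then receives log-normal
    amplitude jitter (CV 20%), a small orientation jitter, and its own
    pixel noise.  Subject ids are unique; reproducible per seed.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be at least 1")
    rng = np.random.default_rng(seed)
    base = {g: (group_params or {}).get(g) or default_group_params(g)
            for g in groups}
    theta0 = float(rng.uniform(0.0, 2.0 * np.pi))
    min_order = max(p.irregularity_min_order for p in base.values())
    template = draw_irregularity_components(rng, min_order)

    rows, maps, truths = [], [], []
    for g in groups:
        for i in range(n_per_group):
            p = base[g]
            subject = f"g{g}s{i:03d}"
            params = p.replace(
                peak_amplitude=_jitter(rng, p.peak_amplitude),
                asymmetry_amplitude=_jitter(rng, p.asymmetry_amplitude),
                irregularity_amplitude=_jitter(rng, p.irregularity_amplitude),
                peripheral_baseline=_jitter(rng, p.peripheral_baseline),
                asymmetry_orientation=theta0 + float(
                    rng.normal(0.0, ORIENTATION_JITTER_SD)),
                irregularity_components=(
                    template if p.irregularity_amplitude > 0 else None),
            )
            mp, truth = phantom_map(params, size=size, rng=rng)
            mp.meta.update(subject=subject, group=g)
            truth["subject"] = subject
            truth["group"] = g
            rows.append({"path": f"{subject}.csv", "subject": subject,
                         "group": g})
            maps.append(mp)
            truths.append(truth)
    manifest = CohortManifest(pd.DataFrame(rows))
    return manifest, maps, truths


def write_cohort(outdir: str | Path, manifest: CohortManifest,
                 maps: list[MPMap], truths: list[dict]) -> Path:
    """Write cohort maps (CSV), manifest (CSV) and ground truth (JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for row, mp in zip(manifest.table.itertuples(), maps):
        save_map(mp, outdir / row.path)
    manifest.write(outdir / "manifest.csv")
    (outdir / "ground_truth.json").write_text(json.dumps(truths, indent=1))
    return outdir
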