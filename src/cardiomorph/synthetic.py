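"""Seeded synthetic data for the NAFLD cardiovascular-risk analysis pipeline.

Every downstream stage of the package (cardiomyocyte morphometry, collagen
quantification, atherogenic ratios, ΔΔCt fold changes, group statistics) can
be exercised against ground-truthed inputs produced here:

* tissue-like fields of cross-sectioned cardiomyocytes with a per-cell truth
  table (class label, nominal area, elongation),
* picrosirius-red-like collagen fields with an exactly known stained fraction,
* group-structured serum panels (symmetric or right-skewed analytes),
* qPCR Ct tables whose group fold changes are known by construction.

All generators require an explicit seed and are deterministic: identical
specification plus identical seed yields byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import PlacementError, ValidationError

__all__ = [
    "AreaParams",
    "IrregularityParams",
    "PopulationSpec",
    "CellTruth",
    "RenderConfig",
    "CollagenTruth",
    "AnalyteSpec",
    "SerumGroupSpec",
    "DEFAULT_AREA_PARAMS",
    "DEFAULT_IRREGULARITY_PARAMS",
    "sample_cell_truth",
    "render_field",
    "simulate_collagen_field",
    "simulate_serum_panel",
    "simulate_ct_table",
]

# Morphometric class labels: N normal, I normal-size irregular, HR/HI
# hypertrophic regular/irregular, AR/AI atrophic regular/irregular.
CLASS_LABELS = ("N", "I", "HR", "HI", "AR", "AI")


@dataclass(frozen=True)
class AreaParams:
    """Mean and SD of cross-sectional cell area, in µm²."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValidationError(f"area mean must be positive, got {self.mean}")
        if self.sd < 0:
            raise ValidationError(f"area sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class IrregularityParams:
    """Shape-irregularity levels of a morphometric class.

    ``elongation`` is the major/minor axis ratio of the underlying ellipse
    (>= 1); ``boundary_noise`` is the RMS relative amplitude of the radial
    boundary perturbation (dimensionless, >= 0).
    """

    elongation_mean: float = 1.3
    elongation_sd: float = 0.15
    boundary_noise: float = 0.02

    def __post_init__(self) -> None:
        if self.elongation_mean < 1:
            raise ValidationError("elongation mean must be >= 1")
        if self.elongation_sd < 0 or self.boundary_noise < 0:
            raise ValidationError("elongation sd and boundary noise must be >= 0")


# Realism anchors for a rat heart cross-section: normal cardiomyocytes around
# 300 µm², hypertrophic around 550 µm², atrophic around 120 µm²; regular
# classes are mildly elongated smooth ellipses, irregular classes are strongly
# elongated with a noisy boundary.
DEFAULT_AREA_PARAMS: dict[str, AreaParams] = {
    "N": AreaParams(300.0, 40.0),
    "I": AreaParams(300.0, 40.0),
    "HR": AreaParams(550.0, 60.0),
    "HI": AreaParams(550.0, 60.0),
    "AR": AreaParams(120.0, 20.0),
    "AI": AreaParams(120.0, 20.0),
}

_REGULAR = IrregularityParams(1.3, 0.15, 0.02)
_IRREGULAR = IrregularityParams(2.3, 0.3, 0.10)

DEFAULT_IRREGULARITY_PARAMS: dict[str, IrregularityParams] = {
    "N": _REGULAR,
    "HR": _REGULAR,
    "AR": _REGULAR,
    "I": _IRREGULAR,
    "HI": _IRREGULAR,
    "AI": _IRREGULAR,
}


@dataclass(frozen=True)
class CellTruth:
    """Ground truth for one synthetic cardiomyocyte cross-section."""

    cell_id: int
    class_label: str
    center: tuple[float, float]  # (row, col) px
    nominal_area: float  # µm²
    elongation: float  # >= 1
    boundary_noise: float  # >= 0


@dataclass(frozen=True)
class PopulationSpec:
    """Specification of one animal's cardiomyocyte population.

    ``class_mixture`` maps class labels to proportions summing to 1.
    ``area_params`` / ``irregularity_params`` default to the module-level
    class presets; ``pixel_size`` is the image calibration in µm/px.
    """

    class_mixture: Mapping[str, float]
    n_cells: int
    seed: int
    pixel_size: float = 0.35
    area_params: Mapping[str, AreaParams] = field(default_factory=lambda: dict(DEFAULT_AREA_PARAMS))
    irregularity_params: Mapping[str, IrregularityParams] = field(
        default_factory=lambda: dict(DEFAULT_IRREGULARITY_PARAMS)
    )
    field_shape: tuple[int, int] | None = None
    packing: float = 0.24  # bounding-circle packing fraction for auto field sizing

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("a seed is required; refusing to randomize silently")
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be positive")
        total = float(sum(self.class_mixture.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"class mixture must sum to 1, got {total!r}")
        for label, p in self.class_mixture.items():
            if p < 0:
                raise ValidationError(f"negative proportion for class {label!r}")
            if p > 0 and label not in self.area_params:
                raise ValidationError(f"no area parameters for class {label!r}")
            if p > 0 and label not in self.irregularity_params:
                raise ValidationError(f"no irregularity parameters for class {label!r}")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lower: float, size: int) -> np.ndarray:
    """Normal draws conditioned on being > lower (vectorised rejection)."""
    if sd == 0:
        if mean <= lower:
            raise ValidationError(f"degenerate distribution at {mean} entirely below bound {lower}")
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    bad = out <= lower
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= lower
    return out


def sample_cell_truth(spec: PopulationSpec) -> list[CellTruth]:
    """Draw per-cell ground truths and place them without overlap.

    Class labels follow the mixture multinomially; areas are truncated
    Gaussians per class; centers are dart-thrown so that bounding circles
    (semi-major axis plus a 2 px margin) never intersect.

    Raises
    ------
    PlacementError
        If the requested density cannot be achieved; the message names how
        many cells were placed.
    """
    rng = np.random.default_rng(spec.seed)
    labels_avail = [c for c in spec.class_mixture if spec.class_mixture[c] > 0]
    probs = np.array([spec.class_mixture[c] for c in labels_avail], dtype=float)
    probs = probs / probs.sum()
    labels = rng.choice(np.array(labels_avail, dtype=object), size=spec.n_cells, p=probs)

    areas = np.empty(spec.n_cells)
    elong = np.empty(spec.n_cells)
    noise = np.empty(spec.n_cells)
    for lab in labels_avail:
        idx = np.flatnonzero(labels == lab)
        ap = spec.area_params[lab]
        ip = spec.irregularity_params[lab]
        areas[idx] = _truncated_normal(rng, ap.mean, ap.sd, ap.mean * 0.05, idx.size)
        elong[idx] = _truncated_normal(rng, ip.elongation_mean, ip.elongation_sd, 1.0, idx.size)
        noise[idx] = ip.boundary_noise

    # semi-major axis in px of the (unperturbed) ellipse
    area_px = areas / spec.pixel_size**2
    a_px = np.sqrt(area_px * elong / math.pi) * (1.0 + noise)

    if spec.field_shape is None:
        bound_area = float(np.sum(math.pi * (a_px + 2.0) ** 2))
        side = int(math.ceil(math.sqrt(bound_area / spec.packing))) + 2 * int(a_px.max() + 4)
        shape = (side, side)
    else:
        shape = spec.field_shape

    order = np.argsort(-a_px, kind="stable")  # place large cells first
    centers = np.full((spec.n_cells, 2), np.nan)
    placed_xy = np.empty((spec.n_cells, 2))
    placed_r = np.empty(spec.n_cells)
    n_placed = 0
    margin = 2.0
    max_attempts = 400 * spec.n_cells
    attempts = 0
    for k, i in enumerate(order):
        r = a_px[i]
        lo = r + margin
        ok = False
        while attempts < max_attempts:
            attempts += 1
            cand = rng.uniform([lo, lo], [shape[0] - lo, shape[1] - lo])
            if n_placed:
                d2 = ((placed_xy[:n_placed] - cand) ** 2).sum(axis=1)
                if np.any(d2 <= (placed_r[:n_placed] + r + margin) ** 2):
                    continue
            ok = True
            break
        if not ok:
            raise PlacementError(
                f"placed only {k} of {spec.n_cells} cells in a {shape} field; reduce density"
            )
        placed_xy[n_placed] = cand
        placed_r[n_placed] = r
        n_placed += 1
        centers[i] = cand

    return [
        CellTruth(
            cell_id=i + 1,
            class_label=str(labels[i]),
            center=(float(centers[i, 0]), float(centers[i, 1])),
            nominal_area=float(areas[i]),
            elongation=float(elong[i]),
            boundary_noise=float(noise[i]),
        )
        for i in range(spec.n_cells)
    ]


@dataclass(frozen=True)
class RenderConfig:
    """Rasterisation settings for :func:`render_field`."""

    pixel_size: float = 0.35  # µm/px
    seed: int = 0
    shape: tuple[int, int] | None = None  # auto from truths when None
    n_vertices: int = 256
    n_harmonics: int = 5  # boundary-noise Fourier harmonics (k = 2 .. n+1)
    background_rgb: tuple[int, int, int] = (235, 214, 224)
    cell_rgb: tuple[int, int, int] = (192, 122, 144)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be positive")


def _cell_polygon(truth: CellTruth, cfg: RenderConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Vertex rows/cols of the noisy-ellipse outline of one cell."""
    area_px = truth.nominal_area / cfg.pixel_size**2
    e = truth.elongation
    a = math.sqrt(area_px * e / math.pi)
    b = a / e
    phi = rng.uniform(0.0, math.pi)
    theta = np.linspace(0.0, 2.0 * math.pi, cfg.n_vertices, endpoint=False)
    tp = theta - phi
    r_ell = a * b / np.sqrt((b * np.cos(tp)) ** 2 + (a * np.sin(tp)) ** 2)
    if truth.boundary_noise > 0:
        sigma = truth.boundary_noise / math.sqrt(cfg.n_harmonics)
        pert = np.zeros_like(theta)
        for k in range(2, 2 + cfg.n_harmonics):
            ak, bk = rng.normal(0.0, sigma, 2)
            pert += ak * np.cos(k * theta) + bk * np.sin(k * theta)
        r_ell = r_ell * np.clip(1.0 + pert, 0.3, None)
        # renormalise so the perturbed polygon keeps the nominal area
        poly_area = 0.5 * np.abs(np.sum(r_ell * np.roll(r_ell, -1) * np.sin(np.diff(theta, append=theta[:1] + 2 * math.pi))))
        r_ell = r_ell * math.sqrt(area_px / poly_area)
    rows = truth.center[0] + r_ell * np.sin(theta)
    cols = truth.center[1] + r_ell * np.cos(theta)
    return rows, cols


def render_field(
    truths: Sequence[CellTruth], cfg: RenderConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterise cell truths into an RGB image and a labelled mask.

    Returns ``(rgb, labels)`` where ``labels`` is uint16 and label value
    ``k`` covers exactly the pixels of the cell with ``cell_id == k``.

    Raises
    ------
    PlacementError
        If two truths overlap once rasterised (should not happen for truths
        produced by :func:`sample_cell_truth`).
    """
    from skimage.draw import polygon as draw_polygon

    cfg = cfg or RenderConfig()
    if len(truths) == 0:
        shape = cfg.shape or (64, 64)
        rgb = np.empty(shape + (3,), np.uint8)
        rgb[:] = cfg.background_rgb
        return rgb, np.zeros(shape, np.uint16)

    if cfg.shape is None:
        pad = 4.0
        extent = 0.0
        for t in truths:
            a = math.sqrt(t.nominal_area / cfg.pixel_size**2 * t.elongation / math.pi)
            extent = max(extent, t.center[0] + a * (1 + t.boundary_noise), t.center[1] + a * (1 + t.boundary_noise))
        side = int(math.ceil(extent + pad))
        shape = (side, side)
    else:
        shape = cfg.shape

    labels = np.zeros(shape, np.uint16)
    rng = np.random.default_rng(cfg.seed)
    bg = np.array(cfg.background_rgb, float)
    cell_col = np.array(cfg.cell_rgb, float)
    rgb = np.empty(shape + (3,), float)
    rgb[:] = bg
    rgb += rng.normal(0.0, 4.0, rgb.shape)

    for t in sorted(truths, key=lambda t: t.cell_id):
        cell_rng = np.random.default_rng((cfg.seed, t.cell_id))
        rows, cols = _cell_polygon(t, cfg, cell_rng)
        rr, cc = draw_polygon(rows, cols, shape=shape)
        if np.any(labels[rr, cc] != 0):
            raise PlacementError(f"cell {t.cell_id} overlaps a previously drawn cell")
        labels[rr, cc] = t.cell_id
        jitter = cell_rng.normal(0.0, 8.0, 3)
        rgb[rr, cc] = cell_col + jitter

    return np.clip(rgb, 0, 255).astype(np.uint8), labels


@dataclass(frozen=True)
class CollagenTruth:
    """Ground truth of a synthetic picrosirius field."""

    true_fraction: float
    stain_mask: np.ndarray  # bool, True where collagen colour was rendered


def simulate_collagen_field(
    true_fraction: float,
    seed: int,
    shape: tuple[int, int] = (512, 512),
    correlation_px: float = 6.0,
    stain_rgb: tuple[int, int, int] = (165, 35, 45),
    background_rgb: tuple[int, int, int] = (225, 215, 190),
) -> tuple[np.ndarray, CollagenTruth]:
    """Render a collagen-stain field whose stained pixel share is exact.

    A smoothed Gaussian random field is thresholded at the quantile giving
    exactly ``round(true_fraction * n_pixels)`` stained pixels, which makes
    the rendered fraction accurate to ±1 pixel. Stain and background colours
    are chosen so the red-dominance rule of ``collagen_quant`` separates them.
    """
    from scipy.ndimage import gaussian_filter

    if not (0.0 <= true_fraction <= 1.0):
        raise ValidationError(f"true_fraction must be in [0, 1], got {true_fraction}")
    if seed is None:
        raise ValidationError("a seed is required; refusing to randomize silently")

    rng = np.random.default_rng(seed)
    n = shape[0] * shape[1]
    k = int(round(true_fraction * n))
    fld = gaussian_filter(rng.standard_normal(shape), correlation_px)
    mask = np.zeros(shape, bool)
    if k > 0:
        flat = fld.ravel()
        idx = np.argpartition(flat, n - k)[n - k:]
        mask.ravel()[idx] = True

    rgb = np.empty(shape + (3,), float)
    rgb[:] = background_rgb
    rgb[mask] = stain_rgb
    rgb += rng.normal(0.0, 6.0, rgb.shape)
    return np.clip(rgb, 0, 255).astype(np.uint8), CollagenTruth(true_fraction, mask)


@dataclass(frozen=True)
class AnalyteSpec:
    """Location/scale/family of one serum analyte within a group."""

    loc: float
    scale: float
    family: str = "symmetric"  # "symmetric" (Gaussian) or "skewed" (log-normal)

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise ValidationError("scale must be >= 0")
        if self.family not in ("symmetric", "skewed"):
            raise ValidationError(f"unknown family {self.family!r}")
        if self.family == "skewed" and self.loc <= 0:
            raise ValidationError("skewed (log-normal) analytes need loc > 0")


@dataclass(frozen=True)
class SerumGroupSpec:
    """One experimental group of a serum panel simulation."""

    name: str
    analytes: Mapping[str, AnalyteSpec]
    n_animals: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_animals < 2:
            raise ValidationError("n_animals must be >= 2")
        if self.seed is None:
            raise ValidationError("a seed is required; refusing to randomize silently")


def simulate_serum_panel(specs: Sequence[SerumGroupSpec]) -> pd.DataFrame:
    """Long-format serum table: one row per group × animal × analyte.

    Symmetric analytes are Gaussian(loc, scale); skewed analytes are
    log-normal with median ``loc`` and log-SD ``sqrt(log1p((scale/loc)^2))``
    so that the coefficient of variation matches ``scale/loc``.
    """
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate group names in {names}")
    rows = []
    for s in specs:
        rng = np.random.default_rng(s.seed)
        for analyte, a in s.analytes.items():
            if a.family == "symmetric":
                vals = rng.normal(a.loc, a.scale, s.n_animals)
            else:
                sigma = math.sqrt(math.log1p((a.scale / a.loc) ** 2))
                vals = a.loc * np.exp(rng.normal(0.0, sigma, s.n_animals))
            for i, v in enumerate(vals):
                rows.append((s.name, f"{s.name}_{i + 1:02d}", analyte, float(v)))
    return pd.DataFrame(rows, columns=["group", "animal_id", "analyte", "value"])


def simulate_ct_table(
    group_fold_changes: Mapping[str, float],
    ct_base: float = 26.0,
    seed: int | None = None,
    reference_group: str = "control",
    n_per_group: int = 10,
    noise_sd: float = 0.2,
    target: str = "miR-122",
    normalizer_ct: float = 21.0,
) -> pd.DataFrame:
    """Simulate a qPCR Ct table with a spike-in normaliser column.

    Each sample gets ``ct_normalizer ~ N(normalizer_ct, noise_sd)`` and
    ``ct_target ~ N(ct_base - log2(fold), noise_sd)``, so the group mean of
    2^−ΔΔCt against ``reference_group`` recovers the requested fold change.
    """
    if seed is None:
        raise ValidationError("a seed is required; refusing to randomize silently")
    if reference_group not in group_fold_changes:
        raise ValidationError(f"reference group {reference_group!r} missing from fold-change map")
    for g, f in group_fold_changes.items():
        if f <= 0:
            raise ValidationError(f"fold change for group {g!r} must be > 0, got {f}")
    if abs(group_fold_changes[reference_group] - 1.0) > 1e-12:
        raise ValidationError("the reference group must have fold change 1")

    rng = np.random.default_rng(seed)
    rows = []
    for g, f in group_fold_changes.items():
        shift = -math.log2(f)
        for i in range(n_per_group):
            ct_n = normalizer_ct + rng.normal(0.0, noise_sd)
            ct_t = ct_base + shift + rng.normal(0.0, noise_sd)
            rows.append((f"{g}_{i + 1:02d}", g, target, float(ct_t), float(ct_n)))
    return pd.DataFrame(rows, columns=["sample_id", "group", "target", "ct_target", "ct_normalizer"])
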