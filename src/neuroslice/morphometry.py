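"""Per-cell microglia morphometry: territories, skeletons, Sholl profiles.

The automated tracing pipeline that replaces manual microglia tracing:

1. **Soma markers** — DAPI and Iba1 are colocalized (pixelwise minimum)
   and binarized with the minimum-dark threshold; component centers mark
   microglial nuclei.  The Iba1 channel is grayscale area-attribute
   filtered (area opening, 99 px) to emphasize somata over thin
   processes, thresholded, and components smaller than 300 px dropped;
   each retained soma containing a colocalization center becomes one
   marker.
2. **Territories** — somata are dilated by 100 px to bound the watershed
   domain, and a marker-controlled watershed on the inverted (smoothed)
   Iba1 intensity ascribes an area to each cell.
3. **Skeletons** — within each territory the Iba1 signal is unsharp-
   masked, despeckled, morphologically closed, max-entropy (Kapur)
   thresholded, reconstructed from the soma seed and thinned to a
   1-px-wide skeleton.
4. **Sholl** — concentric circles around the colocalization center;
   a crossing is a maximal run of skeleton pixels along the sampled
   circle, which avoids double-counting thick diagonal steps.

Pixel-based defaults (99 / 300 / 100 px) correspond to the native
0.31 µm/px scan; callers working at other scales pass rescaled values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from skimage.filters import gaussian, unsharp_mask
from skimage.segmentation import watershed

from .counting import ChannelImage, _center_roi_slices
from .thresholds import threshold_max_entropy, threshold_minimum_dark

__all__ = [
    "SomaMarkers",
    "CellTerritoryMap",
    "Skeleton",
    "ShollProfile",
    "find_soma_markers",
    "assign_territories",
    "skeletonize_cell",
    "sholl",
    "morphometry_pipeline",
]

DEFAULT_MORPHO_ROI_UM = 300.0


@dataclass(frozen=True)
class SomaMarkers:
    """Labeled somata and their colocalization centers (one per soma)."""

    soma_labels: np.ndarray
    centers_px: tuple[tuple[float, float], ...]  # (row, col) per label 1..n

    @property
    def n(self) -> int:
        return len(self.centers_px)


@dataclass(frozen=True)
class CellTerritoryMap:
    """Watershed partition: 0 = background, k = territory of cell k."""

    labels: np.ndarray
    soma_centers_px: tuple[tuple[float, float], ...]
    pixel_um: float

    @property
    def n_cells(self) -> int:
        return len(self.soma_centers_px)

    @property
    def soma_centers_um(self) -> list[tuple[float, float]]:
        return [(c * self.pixel_um, r * self.pixel_um) for r, c in self.soma_centers_px]


@dataclass(frozen=True)
class Skeleton:
    """1-px-wide skeleton of one cell, with its Sholl center."""

    image: np.ndarray  # bool, full frame
    center_px: tuple[float, float]
    owner_label: int
    pixel_um: float


@dataclass(frozen=True)
class ShollProfile:
    radii_um: np.ndarray
    intersections: np.ndarray

    @property
    def auc(self) -> float:
        """Area under the Sholl curve (intersections x µm)."""
        return float(np.trapezoid(self.intersections, self.radii_um))


def _normalize(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    lo, hi = img.min(), img.max()
    return (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)


def find_soma_markers(
    dapi: np.ndarray,
    iba1: np.ndarray,
    min_soma_px: int = 300,
    attribute_area_px: int = 99,
    soma_threshold: float | None = None,
    min_coloc_px: int = 20,
) -> SomaMarkers:
    """Locate microglial somata and their nuclear colocalization centers.

    ``soma_threshold`` is an absolute threshold on the attribute-filtered
    (normalized) Iba1 image; by default 0.75 of its maximum — after area
    opening the somata are the brightest remaining structures.
    """
    dapi_n, iba_n = _normalize(dapi), _normalize(iba1)
    coloc = np.minimum(dapi_n, iba_n)
    coloc_bin = threshold_minimum_dark(coloc)
    coloc_lbl = measure.label(coloc_bin, connectivity=2)
    centers = [
        p.centroid
        for p in measure.regionprops(coloc_lbl)
        if p.area >= min_coloc_px
    ]

    filtered = morphology.area_opening(iba_n, area_threshold=attribute_area_px)
    thr = soma_threshold if soma_threshold is not None else 0.75 * filtered.max()
    soma_bin = filtered > thr
    if soma_bin.mean() > 0.25:
        # somata are compact bright islands; a mostly-foreground mask
        # means the channel has no distinct somatic structure at all
        warnings.warn("no distinct somatic structure in Iba1 channel")
        return SomaMarkers(np.zeros(iba_n.shape, dtype=np.int32), ())
    soma_lbl = measure.label(soma_bin, connectivity=2)

    out_labels = np.zeros_like(soma_lbl)
    out_centers: list[tuple[float, float]] = []
    next_label = 1
    for p in measure.regionprops(soma_lbl):
        if p.area < min_soma_px:
            continue
        inside = [
            c for c in centers if soma_lbl[int(round(c[0])), int(round(c[1]))] == p.label
        ]
        if not inside:
            continue
        if len(inside) > 1:
            warnings.warn(f"soma blob {p.label}: {len(inside)} nuclei centers merged")
        out_labels[soma_lbl == p.label] = next_label
        out_centers.append(tuple(np.mean(inside, axis=0)))
        next_label += 1
    return SomaMarkers(soma_labels=out_labels, centers_px=tuple(out_centers))


def assign_territories(
    iba1: np.ndarray,
    markers: SomaMarkers,
    dilation_px: float = 100.0,
    pixel_um: float = 0.31,
    relief_sigma_px: float = 1.0,
) -> CellTerritoryMap:
    """Marker-controlled watershed partition of the dilated-soma domain.

    The relief is the inverted, Gaussian-smoothed Iba1 intensity, so
    basins follow the cells' processes; every marker yields exactly one
    territory and pixels outside the dilated-soma domain stay 0.
    """
    if markers.n < 1:
        raise ValueError("watershed requires at least one marker")
    soma_mask = markers.soma_labels > 0
    domain = ndimage.distance_transform_edt(~soma_mask) <= dilation_px
    relief = -gaussian(_normalize(iba1), sigma=relief_sigma_px)
    labels = watershed(relief, markers=markers.soma_labels, mask=domain)
    # watershed preserves marker labels, already contiguous 1..n
    assert labels[~domain].max(initial=0) == 0
    return CellTerritoryMap(
        labels=labels, soma_centers_px=markers.centers_px, pixel_um=pixel_um
    )


def skeletonize_cell(
    iba1: np.ndarray,
    territories: CellTerritoryMap,
    label: int,
    unsharp_radius_px: float = 2.0,
    unsharp_amount: float = 1.0,
    closing_radius_px: int = 2,
) -> Skeleton:
    """Thin one cell's within-territory Iba1 signal to a 1-px skeleton."""
    mask = territories.labels == label
    if not mask.any():
        raise ValueError(f"territory {label} is empty")
    img = _normalize(iba1)
    img = unsharp_mask(img, radius=unsharp_radius_px, amount=unsharp_amount)
    img = ndimage.median_filter(img, size=3)
    img = morphology.closing(img, morphology.disk(closing_radius_px))
    img = np.where(mask, img, 0.0)
    binary = threshold_max_entropy(img, mask=mask)
    center = territories.soma_centers_px[label - 1]
    r, c = int(round(center[0])), int(round(center[1]))
    lbl = measure.label(binary, connectivity=2)
    seed_label = lbl[r, c]
    if seed_label == 0:
        # seed fell on background: take the component nearest the center
        if lbl.max() == 0:
            warnings.warn(f"cell {label}: empty foreground after threshold")
            return Skeleton(np.zeros_like(binary), center, label, territories.pixel_um)
        fg = np.argwhere(lbl > 0)
        d2 = ((fg - np.array([r, c])) ** 2).sum(axis=1)
        seed_label = lbl[tuple(fg[np.argmin(d2)])]
    binary = lbl == seed_label
    skel = morphology.skeletonize(binary)
    return Skeleton(skel, center, label, territories.pixel_um)


def sholl(
    skeleton: Skeleton,
    step_um: float = 5.0,
    start_um: float | None = None,
    max_um: float | None = None,
) -> ShollProfile:
    """Count skeleton crossings of concentric circles around the center.

    One crossing = one maximal run of skeleton pixels along the densely
    sampled circle (the skeleton is tolerance-dilated by one pixel for
    the membership test so diagonal steps are not missed).
    """
    px = skeleton.pixel_um
    img = ndimage.binary_dilation(skeleton.image, structure=np.ones((3, 3)))
    h, w = img.shape
    r0, c0 = skeleton.center_px
    if start_um is None:
        start_um = step_um
    if max_um is None:
        max_um = float(np.hypot(max(r0, h - r0), max(c0, w - c0))) * px
    radii = np.arange(start_um, max_um + 1e-9, step_um)
    counts = np.zeros(radii.size, dtype=int)
    for i, r_um in enumerate(radii):
        r_px = r_um / px
        n_samples = max(90, int(np.ceil(2 * np.pi * r_px * 3)))
        theta = np.linspace(0, 2 * np.pi, n_samples, endpoint=False)
        rr = np.round(r0 + r_px * np.sin(theta)).astype(int)
        cc = np.round(c0 + r_px * np.cos(theta)).astype(int)
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        hit = np.zeros(n_samples, dtype=bool)
        hit[ok] = img[rr[ok], cc[ok]]
        if hit.all():
            counts[i] = 1
        else:
            counts[i] = int(np.sum(hit & ~np.roll(hit, 1)))
    return ShollProfile(radii_um=radii, intersections=counts)


@dataclass(frozen=True)
class MorphometryResult:
    territories: CellTerritoryMap
    skeletons: tuple[Skeleton, ...]
    profiles: tuple[ShollProfile, ...]
    provenance: dict = field(default_factory=dict)

    @property
    def mean_auc(self) -> float:
        if not self.profiles:
            return 0.0
        return float(np.mean([p.auc for p in self.profiles]))


def morphometry_pipeline(
    dapi: ChannelImage,
    iba1: ChannelImage,
    roi_um: float | None = DEFAULT_MORPHO_ROI_UM,
    min_soma_px: int = 300,
    attribute_area_px: int = 99,
    dilation_px: float = 100.0,
    soma_threshold: float | None = None,
    sholl_step_um: float = 5.0,
) -> MorphometryResult:
    """Full per-cell morphometry on a (by default 300 µm) centered ROI."""
    if dapi.pixel_um != iba1.pixel_um:
        raise ValueError("channel pixel sizes differ")
    px = dapi.pixel_um
    dapi_a = np.asarray(dapi.pixels, dtype=float)
    iba_a = np.asarray(iba1.pixels, dtype=float)
    if roi_um is not None:
        rs, cs = _center_roi_slices(dapi_a.shape, int(round(roi_um / px)))
        dapi_a, iba_a = dapi_a[rs, cs], iba_a[rs, cs]
    provenance = {
        "roi_um": roi_um,
        "min_soma_px": min_soma_px,
        "attribute_area_px": attribute_area_px,
        "dilation_px": dilation_px,
        "soma_threshold": soma_threshold,
        "sholl_step_um": sholl_step_um,
        "pixel_um": px,
    }
    markers = find_soma_markers(
        dapi_a,
        iba_a,
        min_soma_px=min_soma_px,
        attribute_area_px=attribute_area_px,
        soma_threshold=soma_threshold,
    )
    if markers.n == 0:
        empty = CellTerritoryMap(np.zeros(dapi_a.shape, dtype=int), (), px)
        return MorphometryResult(empty, (), (), provenance)
    territories = assign_territories(iba_a, markers, dilation_px=dilation_px, pixel_um=px)
    skeletons, profiles = [], []
    for label in range(1, territories.n_cells + 1):
        sk = skeletonize_cell(iba_a, territories, label)
        skeletons.append(sk)
        profiles.append(sholl(sk, step_um=sholl_step_um))
    return MorphometryResult(territories, tuple(skeletons), tuple(profiles), provenance)
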