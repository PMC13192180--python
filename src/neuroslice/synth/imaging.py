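"""Synthetic two-channel (DAPI / Iba1) fluorescence image pairs.

Emulates z-projected confocal fields of microglia in slice-culture
tissue: the DAPI channel holds blurred nuclear disks at all cell
positions (microglia plus other cells at ``nuclei_density_per_mm2``);
the Iba1 channel holds soma disks and piecewise-linear branch trees at
the microglia positions only.  Both channels are blurred with a Gaussian
point-spread approximation and carry additive Gaussian noise before
quantization to the requested bit depth.

Phenotypes modulate branch geometry at a fixed branch-count budget:

* ``ramified``    — baseline branch length, regular soma;
* ``deramified``  — branches shortened to 40% (activation-associated
  process retraction), so total branch length is strictly lower;
* ``hypertrophic`` — 30% longer branches on a 25% larger soma.

Ground truth records the microglia centers and a per-cell branch graph
(:mod:`networkx`, node positions in µm), so skeleton length and Sholl
expectations are computable analytically without re-running the
generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line

from .ground_truth import GroundTruth

__all__ = ["ImageGenSpec", "generate_image_pair"]

PHENOTYPES = ("ramified", "deramified", "hypertrophic")
_PHENOTYPE_SCALE = {  # (branch length multiplier, soma radius multiplier)
    "ramified": (1.0, 1.0),
    "deramified": (0.4, 1.0),
    "hypertrophic": (1.3, 1.25),
}


@dataclass(frozen=True)
class ImageGenSpec:
    field_um: tuple[float, float] = (300.0, 300.0)
    pixel_um: float = 0.31
    n_cells: int = 10
    phenotype: str = "ramified"
    soma_radius_um: float = 6.0
    n_branches: int = 4
    branch_length_um: float = 30.0
    nuclei_density_per_mm2: float = 1000.0
    nucleus_radius_um: float = 4.5
    psf_sigma_um: float = 0.4
    noise_sd: float = 0.01  # fraction of full scale
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"phenotype must be one of {PHENOTYPES}")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.pixel_um <= 0 or min(self.field_um) <= 0:
            raise ValueError("field and pixel size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) = (height, width) in pixels."""
        w, h = self.field_um
        return (int(round(h / self.pixel_um)), int(round(w / self.pixel_um)))


def _place_centers(spec: ImageGenSpec, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample microglia centers >= 2 soma radii apart (µm, (x, y))."""
    len_mult, soma_mult = _PHENOTYPE_SCALE[spec.phenotype]
    soma_r = spec.soma_radius_um * soma_mult
    margin = soma_r + spec.branch_length_um * len_mult * 0.5
    w, h = spec.field_um
    margin = min(margin, w / 4, h / 4)
    min_sep = 2.0 * spec.soma_radius_um
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < spec.n_cells:
        attempts += 1
        if attempts > 2000 * max(spec.n_cells, 1):
            raise ValueError(
                f"field {spec.field_um} µm too small for {spec.n_cells} cells "
                f"at minimum separation {min_sep} µm"
            )
        x = rng.uniform(margin, w - margin)
        y = rng.uniform(margin, h - margin)
        if all((x - cx) ** 2 + (y - cy) ** 2 >= min_sep**2 for cx, cy in centers):
            centers.append((x, y))
    return np.asarray(centers, dtype=float).reshape(-1, 2)


def _branch_graph(spec: ImageGenSpec, center, rng) -> nx.Graph:
    """Two-segment radial branches with a gentle mid-branch bend."""
    len_mult, soma_mult = _PHENOTYPE_SCALE[spec.phenotype]
    soma_r = spec.soma_radius_um * soma_mult
    length = spec.branch_length_um * len_mult
    g = nx.Graph()
    cx, cy = center
    g.add_node(0, pos=(cx, cy), kind="soma")
    angle0 = rng.uniform(0, 2 * np.pi)
    node_id = 1
    for b in range(spec.n_branches):
        theta = angle0 + 2 * np.pi * b / max(spec.n_branches, 1)
        bend = rng.uniform(-0.35, 0.35)  # radians, keeps arms near-radial
        l1, l2 = 0.6 * length, 0.4 * length
        p0 = (cx + soma_r * math.cos(theta), cy + soma_r * math.sin(theta))
        p1 = (p0[0] + l1 * math.cos(theta), p0[1] + l1 * math.sin(theta))
        p2 = (p1[0] + l2 * math.cos(theta + bend), p1[1] + l2 * math.sin(theta + bend))
        g.add_node(node_id, pos=p0, kind="root")
        g.add_node(node_id + 1, pos=p1, kind="mid")
        g.add_node(node_id + 2, pos=p2, kind="tip")
        g.add_edge(0, node_id, length=soma_r)
        g.add_edge(node_id, node_id + 1, length=l1)
        g.add_edge(node_id + 1, node_id + 2, length=l2)
        node_id += 3
    return g


def _graph_to_dict(g: nx.Graph) -> dict:
    return {
        "nodes": [
            {"id": int(n), "x": float(d["pos"][0]), "y": float(d["pos"][1]), "kind": d["kind"]}
            for n, d in g.nodes(data=True)
        ],
        "edges": [
            {"u": int(u), "v": int(v), "length_um": float(d["length"])}
            for u, v, d in g.edges(data=True)
        ],
    }


def _px(spec: ImageGenSpec, xy) -> tuple[int, int]:
    """µm (x, y) -> pixel (row, col)."""
    return (int(round(xy[1] / spec.pixel_um)), int(round(xy[0] / spec.pixel_um)))


def _render(spec: ImageGenSpec, centers, graphs, rng):
    shape = spec.shape
    dapi = np.full(shape, 0.02)
    iba1 = np.full(shape, 0.02)
    _, soma_mult = _PHENOTYPE_SCALE[spec.phenotype]
    soma_r_px = max(1, int(round(spec.soma_radius_um * soma_mult / spec.pixel_um)))
    nuc_r_px = max(1, int(round(spec.nucleus_radius_um / spec.pixel_um)))
    branch_half_w = max(1, int(round(0.6 / spec.pixel_um)))  # ~1.2 µm wide processes

    # non-microglial nuclei (neurons, astrocytes): DAPI only
    area_mm2 = spec.field_um[0] * spec.field_um[1] / 1e6
    n_other = rng.poisson(spec.nuclei_density_per_mm2 * area_mm2)
    w, h = spec.field_um
    for _ in range(n_other):
        r, c = _px(spec, (rng.uniform(0, w), rng.uniform(0, h)))
        rr, cc = draw_disk((r, c), nuc_r_px, shape=shape)
        dapi[rr, cc] = 0.9

    for center, g in zip(centers, graphs):
        r, c = _px(spec, center)
        rr, cc = draw_disk((r, c), nuc_r_px, shape=shape)
        dapi[rr, cc] = 0.95
        rr, cc = draw_disk((r, c), soma_r_px, shape=shape)
        iba1[rr, cc] = 0.9
        mask = np.zeros(shape, dtype=bool)
        pos = nx.get_node_attributes(g, "pos")
        for u, v in g.edges():
            r0, c0 = _px(spec, pos[u])
            r1, c1 = _px(spec, pos[v])
            rr, cc = draw_line(r0, c0, r1, c1)
            ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
            mask[rr[ok], cc[ok]] = True
        mask = ndimage.binary_dilation(mask, iterations=branch_half_w - 1) if branch_half_w > 1 else mask
        iba1[mask & (iba1 < 0.5)] = 0.7

    sigma_px = spec.psf_sigma_um / spec.pixel_um
    if sigma_px > 0:
        dapi = ndimage.gaussian_filter(dapi, sigma_px)
        iba1 = ndimage.gaussian_filter(iba1, sigma_px)
    if spec.noise_sd > 0:
        dapi = dapi + rng.normal(0, spec.noise_sd, shape)
        iba1 = iba1 + rng.normal(0, spec.noise_sd, shape)

    full = 2**spec.bit_depth - 1
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    dapi = np.clip(np.round(dapi * full), 0, full).astype(dtype)
    iba1 = np.clip(np.round(iba1 * full), 0, full).astype(dtype)
    return dapi, iba1


def generate_image_pair(spec: ImageGenSpec) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Generate a (dapi, iba1, truth) triple; bit-identical for same spec+seed."""
    rng = np.random.default_rng(spec.seed)
    centers = _place_centers(spec, rng)
    graphs = [_branch_graph(spec, c, rng) for c in centers]
    dapi, iba1 = _render(spec, centers, graphs, rng)
    len_mult, soma_mult = _PHENOTYPE_SCALE[spec.phenotype]
    truth = GroundTruth(
        "image",
        {
            "n_cells": spec.n_cells,
            "phenotype": spec.phenotype,
            "pixel_um": spec.pixel_um,
            "field_um": list(spec.field_um),
            "centers_um": centers,
            "soma_radius_um": spec.soma_radius_um * soma_mult,
            "branch_length_um": spec.branch_length_um * len_mult,
            "n_branches": spec.n_branches,
            "total_branch_length_um": float(
                sum(
                    d["length"]
                    for g in graphs
                    for _, _, d in g.edges(data=True)
                )
            ),
            "branch_graphs": [_graph_to_dict(g) for g in graphs],
        },
    )
    return dapi, iba1, truth
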