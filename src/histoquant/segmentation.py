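"""Nuclei segmentation by mathematical morphology.

The chain mirrors classical slide-scanner nucleus counting: local contrast
normalization (CLAHE), white top-hat background subtraction with a
structuring element sized to the theoretical nucleus radius, seed detection
on the Euclidean distance transform (h-maxima suppression, the workhorse for
separating touching nuclei), seeded watershed, rule-based removal of
artifacts and nuclear clusters, and finally a Voronoi partition of the tissue
into per-nucleus "cell" regions with a distance map.

Coordinates are 0-based (row, col); areas are reported in µm² via
``pixel_size_um``².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import disk, h_maxima, white_tophat
from skimage.segmentation import watershed

from .io import TissueImage

__all__ = [
    "SegmentationConfig",
    "SeedSet",
    "NucleusLabelMap",
    "CellPartition",
    "normalize_contrast_clahe",
    "subtract_background_tophat",
    "find_seeds_ultimate_opening",
    "segment_nuclei_watershed",
    "remove_artifacts_and_clusters",
    "compute_cell_partition",
    "segment",
]


@dataclass
class SegmentationConfig:
    """Tunable parameters of the segmentation chain.

    ``nucleus_radius_um`` is the theoretical nucleus radius that sizes the
    top-hat structuring element; set it to the upper end of the expected
    radius distribution — an element that fits inside the largest nuclei
    flattens them out of the top-hat response.  ``h_maxima_depth`` is the
    minimum depth (in pixels of distance-transform height) a regional maximum
    must have to seed its own nucleus; smaller values split touching nuclei
    more aggressively, and discretization plateaus along elongated nuclei are
    absorbed by merging maxima closer than ``min_seed_separation_px``
    (deepest survivor wins).  Area limits and ``min_solidity`` drive
    artifact/cluster removal.
    """

    nucleus_radius_um: float = 8.0
    clahe_tile_px: int = 64
    clahe_clip: float = 0.01
    h_maxima_depth: float = 0.5
    min_seed_separation_px: float = 4.0
    min_nucleus_area_um2: float = 20.0
    max_nucleus_area_um2: float = 400.0
    min_solidity: float = 0.8
    foreground_threshold: float | None = None  # None = Otsu on the top-hat

    def __post_init__(self) -> None:
        if self.nucleus_radius_um <= 0:
            raise ValueError("nucleus_radius_um must be positive")
        if self.clahe_tile_px < 1:
            raise ValueError("clahe_tile_px must be a positive integer")
        if not 0 < self.clahe_clip <= 1:
            raise ValueError("clahe_clip must lie in (0, 1]")
        if self.h_maxima_depth <= 0:
            raise ValueError("h_maxima_depth must be positive")
        if self.min_seed_separation_px < 0:
            raise ValueError("min_seed_separation_px must be non-negative")
        if not self.min_nucleus_area_um2 < self.max_nucleus_area_um2:
            raise ValueError("min_nucleus_area_um2 must be < max_nucleus_area_um2")
        if not 0 < self.min_solidity <= 1:
            raise ValueError("min_solidity must lie in (0, 1]")


@dataclass
class SeedSet:
    """Unique 0-based (row, col) nucleus-center candidates, in row-major order."""

    coordinates: np.ndarray  # (n, 2) int array

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=int).reshape(-1, 2)
        if len(self.coordinates) != len(np.unique(self.coordinates, axis=0)):
            raise ValueError("seed coordinates must be unique")

    def __len__(self) -> int:
        return len(self.coordinates)


@dataclass
class NucleusLabelMap:
    """Integer raster assigning each pixel to one nucleus (0 = background)."""

    labels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2 or self.labels.min() < 0:
            raise ValueError("labels must be a 2-D non-negative integer raster")

    @property
    def n_nuclei(self) -> int:
        return int(self.labels.max())

    def areas_um2(self) -> np.ndarray:
        """Area of each label 1..K in µm²."""
        counts = np.bincount(self.labels.ravel(), minlength=self.n_nuclei + 1)[1:]
        return counts * self.pixel_size_um**2


@dataclass
class CellPartition:
    """Voronoi-style per-cell regions seeded by nuclei, plus a distance map.

    ``cell_labels`` carries the same label ids as the nucleus map;
    ``distance_map`` holds, per pixel, the Euclidean distance in µm to the
    boundary of the assigned nucleus (0 inside the nucleus itself).
    """

    cell_labels: np.ndarray
    distance_map: np.ndarray
    pixel_size_um: float


# ---------------------------------------------------------------------------
# CLAHE

def normalize_contrast_clahe(channel: np.ndarray, config: SegmentationConfig) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization onto [0, 1].

    The image is divided into ``clahe_tile_px`` tiles (edge tiles absorb the
    remainder).  Each tile's histogram (256 bins over the global range) is
    clipped at ``clahe_clip`` × tile-pixel-count, the excess redistributed
    uniformly, and the tile mapping is its cumulative distribution.  Pixel
    values are mapped through the bilinear blend of the four nearest tile
    mappings, so with a single tile and ``clahe_clip=1`` the operation reduces
    to plain histogram equalization.
    """
    channel = np.asarray(channel, dtype=float)
    if not np.all(np.isfinite(channel)) or channel.min() < 0:
        raise ValueError("channel must be finite and non-negative")
    h, w = channel.shape
    tile = int(config.clahe_tile_px)
    if tile > h or tile > w:
        raise ValueError(
            f"clahe_tile_px={tile} exceeds image dimensions {h}x{w}; "
            "tiles must fit inside the image"
        )

    nbins = 256
    vmin, vmax = channel.min(), channel.max()
    span = vmax - vmin
    if span == 0:
        bins = np.zeros((h, w), dtype=int)
    else:
        bins = np.minimum(((channel - vmin) / span * nbins).astype(int), nbins - 1)

    nty, ntx = h // tile, w // tile  # edge tiles absorb the remainder
    row_edges = [i * tile for i in range(nty)] + [h]
    col_edges = [j * tile for j in range(ntx)] + [w]

    luts = np.empty((nty, ntx, nbins))
    centers_r = np.empty(nty)
    centers_c = np.empty(ntx)
    for i in range(nty):
        r0, r1 = row_edges[i], row_edges[i + 1]
        centers_r[i] = (r0 + r1 - 1) / 2
        for j in range(ntx):
            c0, c1 = col_edges[j], col_edges[j + 1]
            centers_c[j] = (c0 + c1 - 1) / 2
            hist = np.bincount(bins[r0:r1, c0:c1].ravel(), minlength=nbins).astype(float)
            n_px = (r1 - r0) * (c1 - c0)
            limit = config.clahe_clip * n_px
            excess = np.maximum(hist - limit, 0).sum()
            hist = np.minimum(hist, limit)
            hist += excess / nbins
            luts[i, j] = np.cumsum(hist) / hist.sum()

    # bilinear blend of the four neighbouring tile mappings
    rr = np.arange(h)[:, None]
    cc = np.arange(w)[None, :]
    fi = np.interp(rr, centers_r, np.arange(nty))
    fj = np.interp(cc, centers_c, np.arange(ntx))
    i0 = np.floor(fi).astype(int)
    j0 = np.floor(fj).astype(int)
    i1 = np.minimum(i0 + 1, nty - 1)
    j1 = np.minimum(j0 + 1, ntx - 1)
    wi = fi - i0
    wj = fj - j0

    i0b, i1b = np.broadcast_to(i0, (h, w)), np.broadcast_to(i1, (h, w))
    j0b, j1b = np.broadcast_to(j0, (h, w)), np.broadcast_to(j1, (h, w))
    out = (
        (1 - wi) * (1 - wj) * luts[i0b, j0b, bins]
        + (1 - wi) * wj * luts[i0b, j1b, bins]
        + wi * (1 - wj) * luts[i1b, j0b, bins]
        + wi * wj * luts[i1b, j1b, bins]
    )
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# top-hat

def tophat_radius_px(config: SegmentationConfig, pixel_size_um: float) -> int:
    return int(np.ceil(config.nucleus_radius_um / pixel_size_um))


def subtract_background_tophat(
    channel: np.ndarray, config: SegmentationConfig, pixel_size_um: float
) -> np.ndarray:
    """White top-hat: image minus its opening with a nucleus-radius disk.

    Removes background structures larger than the structuring element while
    retaining nucleus-scale features; the result is non-negative by
    construction.
    """
    channel = np.asarray(channel, dtype=float)
    if not np.all(np.isfinite(channel)):
        raise ValueError("channel contains non-finite pixels")
    radius = tophat_radius_px(config, pixel_size_um)
    if radius < 1:
        raise ValueError(
            "nucleus_radius_um must correspond to a structuring element of "
            f"at least 1 px at pixel size {pixel_size_um} um"
        )
    return white_tophat(channel, footprint=disk(radius))


# ---------------------------------------------------------------------------
# seeds

def foreground_mask(prepared: np.ndarray, config: SegmentationConfig) -> np.ndarray:
    """Binarize the top-hat output (Otsu unless a fixed threshold is set).

    Interior holes are filled: with the structuring element sized to the
    nucleus radius, the opening partially reconstructs the largest nuclei and
    the top-hat response there is ring-like.
    """
    prepared = np.asarray(prepared, dtype=float)
    if config.foreground_threshold is not None:
        thr = config.foreground_threshold
    else:
        if prepared.max() == prepared.min():
            return np.zeros(prepared.shape, dtype=bool)
        thr = threshold_otsu(prepared)
    return ndi.binary_fill_holes(prepared > thr)


def find_seeds_ultimate_opening(
    prepared: np.ndarray, config: SegmentationConfig
) -> SeedSet:
    """Locate one seed per nucleus center on the top-hat image.

    Realization of the ultimate-opening idea: Euclidean distance transform of
    the binarized foreground, h-maxima suppression at ``h_maxima_depth``, one
    candidate per surviving regional maximum (the deepest pixel of its
    plateau, row-major on ties), then single-linkage merging of candidates
    closer than ``min_seed_separation_px`` keeping the deepest member.
    Touching nuclei produce distinct distance-transform peaks and therefore
    distinct seeds.
    """
    mask = foreground_mask(prepared, config)
    if not mask.any():
        return SeedSet(np.empty((0, 2), dtype=int))
    edt = ndi.distance_transform_edt(mask)
    maxima = h_maxima(edt, config.h_maxima_depth)
    plateau_labels, n = ndi.label(maxima)
    if n == 0:
        return SeedSet(np.empty((0, 2), dtype=int))
    seeds = []
    # per plateau: the highest-EDT pixel, first in row-major order on ties
    objects = ndi.find_objects(plateau_labels)
    for lab, sl in enumerate(objects, start=1):
        sub = np.where(plateau_labels[sl] == lab, edt[sl], -np.inf)
        flat = np.argmax(sub)
        r, c = np.unravel_index(flat, sub.shape)
        seeds.append((r + sl[0].start, c + sl[1].start))
    seeds = np.array(sorted(set(seeds)), dtype=int)
    seeds = _merge_close_seeds(seeds, edt, config.min_seed_separation_px)
    return SeedSet(seeds)


def _merge_close_seeds(
    seeds: np.ndarray, edt: np.ndarray, min_sep: float
) -> np.ndarray:
    """Single-linkage merge of seed candidates closer than ``min_sep`` pixels.

    Each cluster keeps its deepest member (highest distance-transform value,
    row-major first on ties), so duplicate plateaus along one elongated
    nucleus collapse to one seed without displacing true centers.
    """
    if min_sep <= 0 or len(seeds) < 2:
        return seeds
    tree = cKDTree(seeds)
    parent = np.arange(len(seeds))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in tree.query_pairs(min_sep):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict[int, list[int]] = {}
    for i in range(len(seeds)):
        groups.setdefault(find(i), []).append(i)
    depth = edt[seeds[:, 0], seeds[:, 1]]
    keep = sorted(max(g, key=lambda i: (depth[i], -i)) for g in groups.values())
    return seeds[keep]


# ---------------------------------------------------------------------------
# watershed

def segment_nuclei_watershed(
    prepared: np.ndarray,
    seeds: SeedSet,
    foreground: np.ndarray,
    pixel_size_um: float = 1.0,
) -> NucleusLabelMap:
    """Seeded watershed of the foreground, flooding the negated distance transform.

    Seeds are labeled 1..K in row-major order.  Every foreground pixel ends up
    assigned: components not reached by flooding (disconnected from all seeds)
    are attached to the nearest labeled pixel, so the union of the labels
    equals the foreground mask whenever at least one seed exists.
    """
    foreground = np.asarray(foreground, dtype=bool)
    coords = seeds.coordinates
    order = np.lexsort((coords[:, 1], coords[:, 0])) if len(coords) else []
    coords = coords[order] if len(coords) else coords
    for k, (r, c) in enumerate(coords):
        if not foreground[r, c]:
            raise ValueError(f"seed {k} at ({r}, {c}) lies outside the foreground mask")
    labels = np.zeros(foreground.shape, dtype=np.int32)
    if len(coords) == 0:
        return NucleusLabelMap(labels, pixel_size_um)
    markers = np.zeros(foreground.shape, dtype=np.int32)
    markers[coords[:, 0], coords[:, 1]] = np.arange(1, len(coords) + 1)
    edt = ndi.distance_transform_edt(foreground)
    labels = watershed(-edt, markers=markers, mask=foreground).astype(np.int32)
    leftover = foreground & (labels == 0)
    if leftover.any():
        _, (ir, ic) = ndi.distance_transform_edt(labels == 0, return_indices=True)
        labels[leftover] = labels[ir[leftover], ic[leftover]]
    return NucleusLabelMap(labels, pixel_size_um)


# ---------------------------------------------------------------------------
# artifact / cluster removal

def remove_artifacts_and_clusters(
    nuclei: NucleusLabelMap,
    config: SegmentationConfig,
    artifact_mask: np.ndarray | None = None,
) -> NucleusLabelMap:
    """Drop labels that are too small, too large, too concave, or artifactual.

    A label is removed when its area falls outside
    [min_nucleus_area_um2, max_nucleus_area_um2], its solidity (area /
    convex-hull area) is below ``min_solidity``, or more than half of it lies
    under ``artifact_mask``.  Survivors are compacted to 1..K preserving order.
    """
    labels = nuclei.labels
    px_area = nuclei.pixel_size_um**2
    keep = []
    for prop in regionprops(labels):
        area_um2 = prop.area * px_area
        if not (config.min_nucleus_area_um2 <= area_um2 <= config.max_nucleus_area_um2):
            continue
        if prop.solidity < config.min_solidity:
            continue
        if artifact_mask is not None and np.asarray(artifact_mask).any():
            rr, cc = prop.coords[:, 0], prop.coords[:, 1]
            if np.asarray(artifact_mask, bool)[rr, cc].mean() > 0.5:
                continue
        keep.append(prop.label)
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    lut[keep] = np.arange(1, len(keep) + 1)
    return NucleusLabelMap(lut[labels], nuclei.pixel_size_um)


# ---------------------------------------------------------------------------
# Voronoi cell partition

def compute_cell_partition(
    nuclei: NucleusLabelMap, tissue_mask: np.ndarray
) -> CellPartition:
    """Assign every tissue pixel to the nucleus with the nearest boundary.

    Distances are Euclidean, measured in µm to the assigned nucleus's region
    (0 inside the nucleus).  Assignment is restricted to ``tissue_mask``.
    """
    labels = nuclei.labels
    if labels.max() == 0:
        raise ValueError("cell partition requires at least one nucleus label")
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    if ((labels > 0) & ~tissue_mask).any():
        raise ValueError("tissue_mask must cover all nucleus labels")
    dist_px, (ir, ic) = ndi.distance_transform_edt(labels == 0, return_indices=True)
    cell = labels[ir, ic].astype(np.int32)
    cell[~tissue_mask] = 0
    distance = dist_px * nuclei.pixel_size_um
    distance[~tissue_mask] = 0.0
    return CellPartition(cell, distance, nuclei.pixel_size_um)


# ---------------------------------------------------------------------------
# full chain

def segment(
    img: TissueImage,
    config: SegmentationConfig | None = None,
    dapi_channel: str = "DAPI",
    artifact_mask: np.ndarray | None = None,
    tissue_mask: np.ndarray | None = None,
) -> tuple[NucleusLabelMap, CellPartition]:
    """Run the full chain on the DAPI channel of ``img``.

    CLAHE → white top-hat → seed detection → seeded watershed → artifact and
    cluster removal → Voronoi cell partition.  The total cell count is the
    maximum label of the returned nucleus map.
    """
    config = config or SegmentationConfig()
    if dapi_channel not in img.channels:
        raise ValueError(
            f"no {dapi_channel!r} channel in image (channels: {img.channel_names()}); "
            "nucleus segmentation requires the nuclear counterstain"
        )
    dapi = img.channel(dapi_channel)
    normalized = normalize_contrast_clahe(dapi, config)
    prepared = subtract_background_tophat(normalized, config, img.pixel_size_um)
    fg = foreground_mask(prepared, config)
    seeds = find_seeds_ultimate_opening(prepared, config)
    nuclei = segment_nuclei_watershed(prepared, seeds, fg, img.pixel_size_um)
    nuclei = remove_artifacts_and_clusters(nuclei, config, artifact_mask)
    if tissue_mask is None:
        tissue_mask = np.ones(dapi.shape, dtype=bool)
    if nuclei.n_nuclei == 0:
        partition = CellPartition(
            np.zeros(dapi.shape, dtype=np.int32),
            np.zeros(dapi.shape, dtype=float),
            img.pixel_size_um,
        )
        return nuclei, partition
    partition = compute_cell_partition(nuclei, tissue_mask)
    return nuclei, partition
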