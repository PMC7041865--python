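"""Synthetic tissue-scene generator with ground truth.

Emulates the statistical structure of scanned tumor cryosections: densely
packed, partially overlapping elliptical nuclei on an autofluorescent
background; nuclear and cytosolic marker channels with a controllable
positive fraction; whole-tissue uptake images with viable/necrotic
subregions; and optional fold/edge artifacts.  Every scene ships with its
ground truth (label map, per-cell positivity, region annotation, artifact
mask) so the downstream quantification is testable without external data.

Generation is fully deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import disk

from .io import (
    TissueImage,
    read_label_map,
    read_mask,
    read_tissue_image,
    write_label_map,
    write_mask,
    write_tissue_image,
)
from .intensity import RegionAnnotation
from .segmentation import NucleusLabelMap

__all__ = [
    "MarkerSpec",
    "SceneParams",
    "GroundTruth",
    "generate_tissue_scene",
    "generate_uptake_scene",
    "write_scene",
    "read_scene",
    "default_viability_params",
]

CYTO_DILATION_PX = 3  # cytosolic annulus = nucleus dilated by this, minus nucleus


@dataclass
class MarkerSpec:
    """One stain channel: where it localizes and how bright positives are."""

    name: str
    compartment: str  # nuclear | cytosolic | whole_tissue
    positive_fraction: float
    positive_intensity_mean: float
    negative_intensity_mean: float
    intensity_sd: float

    def __post_init__(self) -> None:
        if self.compartment not in ("nuclear", "cytosolic", "whole_tissue"):
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if not 0 <= self.positive_fraction <= 1:
            raise ValueError("positive_fraction must lie in [0, 1]")
        for f in ("positive_intensity_mean", "negative_intensity_mean", "intensity_sd"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")


@dataclass
class SceneParams:
    """Study conditions for one synthetic section.

    Defaults describe a 512×512 µm field at 0.5 µm/px holding ~1200 nuclei of
    10 µm nominal diameter, 30% of them touching a neighbour, with a viability
    marker panel whose positive fractions sit in the 10–20% regime typical of
    proliferation/apoptosis staining in tumor sections.
    """

    image_height_px: int = 1024
    image_width_px: int = 1024
    pixel_size_um: float = 0.5
    n_nuclei: int = 1200
    nucleus_radius_um_mean: float = 5.0
    nucleus_radius_um_sd: float = 0.75
    touching_fraction: float = 0.3
    touching_max_overlap: float = 0.4
    marker_specs: list[MarkerSpec] = field(default_factory=lambda: default_marker_panel())
    background_autofluorescence_mean: float = 60.0
    background_autofluorescence_sd: float = 8.0
    artifact_fraction: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be non-negative")
        if self.nucleus_radius_um_mean <= 0 or self.nucleus_radius_um_sd <= 0:
            raise ValueError("nucleus radius mean and sd must be positive")
        r_px = self.nucleus_radius_um_mean / self.pixel_size_um
        if 2 * r_px >= min(self.image_height_px, self.image_width_px):
            raise ValueError("nucleus radius larger than the image")
        if not 0 <= self.touching_fraction <= 1:
            raise ValueError("touching_fraction must lie in [0, 1]")
        if not 0 <= self.touching_max_overlap <= 0.4:
            raise ValueError("touching_max_overlap must lie in [0, 0.4]")
        if self.background_autofluorescence_mean < 0 or self.background_autofluorescence_sd < 0:
            raise ValueError("background autofluorescence must be non-negative")
        if not 0 <= self.artifact_fraction <= 1:
            raise ValueError("artifact_fraction must lie in [0, 1]")
        self.marker_specs = [
            m if isinstance(m, MarkerSpec) else MarkerSpec(**m) for m in self.marker_specs
        ]


def default_marker_panel() -> list[MarkerSpec]:
    """DAPI counterstain plus a proliferation/apoptosis/autophagy viability panel."""
    return [
        MarkerSpec("DAPI", "nuclear", 1.0, 160.0, 0.0, 10.0),
        MarkerSpec("Ki67", "nuclear", 0.15, 140.0, 12.0, 10.0),
        MarkerSpec("CC-3", "cytosolic", 0.10, 140.0, 12.0, 10.0),
        MarkerSpec("Beclin1", "cytosolic", 0.12, 140.0, 12.0, 10.0),
    ]


def default_viability_params(
    n_nuclei: int = 250,
    size_px: int = 512,
    positive_fractions: dict[str, float] | None = None,
    rng_seed: int = 0,
) -> SceneParams:
    """A smaller per-section variant used for multi-section viability studies.

    20 such sections hold ~5000 nuclei per condition, the conventional QC
    floor for percent-positive estimates.
    """
    panel = default_marker_panel()
    if positive_fractions:
        for m in panel:
            if m.name in positive_fractions:
                m.positive_fraction = positive_fractions[m.name]
    return SceneParams(
        image_height_px=size_px,
        image_width_px=size_px,
        n_nuclei=n_nuclei,
        marker_specs=panel,
        rng_seed=rng_seed,
    )


@dataclass
class GroundTruth:
    """What the generator knows: labels, per-cell positivity, regions, artifacts."""

    nucleus_label_map: NucleusLabelMap
    per_cell_positivity: dict[str, np.ndarray]  # marker -> bool array indexed 1..K at [label-1]
    region_annotation: RegionAnnotation | None = None
    artifact_mask: np.ndarray | None = None

    def positive_labels(self, marker: str) -> np.ndarray:
        flags = self.per_cell_positivity[marker]
        return np.flatnonzero(flags) + 1

    def positive_fraction(self, marker: str) -> float:
        flags = self.per_cell_positivity[marker]
        return float(flags.mean()) if len(flags) else 0.0


# ---------------------------------------------------------------------------
# nucleus placement and rendering

def _place_nuclei(params: SceneParams, rng: np.random.Generator):
    """Sample centers, semi-axes and orientations for all nuclei.

    The first (1 - touching_fraction) nuclei are placed with rejection
    sampling at center separations ≥ 2.3 mean radii; the remainder are each
    anchored to a previously placed nucleus at a center distance uniform
    between external contact (2 mean radii) and the separation at which two
    mean-radius disks overlap by ``touching_max_overlap`` of their area.
    """
    n = params.n_nuclei
    r_px_mean = params.nucleus_radius_um_mean / params.pixel_size_um
    r_px_sd = params.nucleus_radius_um_sd / params.pixel_size_um
    h, w = params.image_height_px, params.image_width_px
    margin = 1.6 * r_px_mean + 2

    radii = np.maximum(rng.normal(r_px_mean, r_px_sd, size=n), 2.0)
    aspect = rng.uniform(1.15, 1.6, size=n)  # semi-major / semi-minor
    theta = rng.uniform(0, np.pi, size=n)

    n_touch = int(round(params.touching_fraction * n))
    n_free = n - n_touch
    centers = np.empty((n, 2))
    placed = 0
    min_sep = 2.3 * r_px_mean
    attempts = 0
    while placed < n_free and attempts < 200 * max(n_free, 1):
        cand = np.array([rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)])
        if placed == 0 or np.min(
            np.hypot(*(centers[:placed] - cand).T)
        ) >= min_sep:
            centers[placed] = cand
            placed += 1
        attempts += 1
    n_free = placed  # density may cap the separated count
    # Touchers anchor to the separated nuclei (without replacement while they
    # last) and never come closer than the overlap-cap separation to ANY
    # neighbour, so pairwise overlap stays capped and clusters stay small.
    d_min = _separation_for_overlap(params.touching_max_overlap) * r_px_mean
    anchor_pool = rng.permutation(n_free) if n_free else np.array([], dtype=int)
    for k in range(n_free, n):
        if len(anchor_pool) == 0:
            anchor = np.array([h / 2, w / 2])
        else:
            anchor = centers[anchor_pool[(k - n_free) % len(anchor_pool)]]
        best = None
        for _ in range(60):
            d = rng.uniform(d_min, 2.0 * r_px_mean)
            ang = rng.uniform(0, 2 * np.pi)
            cand = anchor + d * np.array([np.sin(ang), np.cos(ang)])
            cand = np.clip(cand, margin, [h - margin, w - margin])
            if k == 0 or np.min(np.hypot(*(centers[:k] - cand).T)) >= d_min:
                best = cand
                break
        centers[k] = best if best is not None else cand
    return centers[:n], radii, aspect, theta


def _separation_for_overlap(overlap_fraction: float) -> float:
    """Center separation (in units of radius) at which two unit disks overlap
    by ``overlap_fraction`` of one disk's area (lens area / πr²)."""
    if overlap_fraction <= 0:
        return 2.0

    def lens_frac(x: float) -> float:  # x = d / r
        return (2 * np.arccos(x / 2) - (x / 2) * np.sqrt(4 - x * x)) / np.pi

    from scipy.optimize import brentq

    return float(brentq(lambda x: lens_frac(x) - overlap_fraction, 1e-9, 2 - 1e-9))


def _render_label_map(params: SceneParams, centers, radii, aspect, theta) -> np.ndarray:
    """Paint rotated ellipses; overlap pixels go to the radius-normalized nearest center."""
    h, w = params.image_height_px, params.image_width_px
    labels = np.zeros((h, w), dtype=np.int32)
    claim = np.full((h, w), np.inf)  # normalized ellipse coordinate of current owner
    for i in range(len(centers)):
        a = radii[i] * np.sqrt(aspect[i])
        b = radii[i] / np.sqrt(aspect[i])
        cy, cx = centers[i]
        ext = radii[i] * np.sqrt(aspect[i]) + 1
        r0, r1 = max(int(cy - ext), 0), min(int(cy + ext) + 2, h)
        c0, c1 = max(int(cx - ext), 0), min(int(cx + ext) + 2, w)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(theta[i]) + dx * np.sin(theta[i])
        v = -dy * np.sin(theta[i]) + dx * np.cos(theta[i])
        q = (u / a) ** 2 + (v / b) ** 2  # ≤ 1 inside the ellipse
        inside = q <= 1.0
        win_claim = claim[r0:r1, c0:c1]
        take = inside & (q < win_claim)
        labels[r0:r1, c0:c1][take] = i + 1
        win_claim[take] = q[take]
    return labels


def _artifact_mask(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """Fold-like bright bands covering approximately artifact_fraction of the image."""
    h, w = params.image_height_px, params.image_width_px
    mask = np.zeros((h, w), dtype=bool)
    target = params.artifact_fraction * h * w
    guard = 0
    while mask.sum() < target and guard < 100:
        guard += 1
        if rng.uniform() < 0.5:  # horizontal band
            r = int(rng.integers(0, h))
            thick = int(rng.integers(max(h // 60, 3), max(h // 20, 6)))
            mask[r : min(r + thick, h), :] = True
        else:
            c = int(rng.integers(0, w))
            thick = int(rng.integers(max(w // 60, 3), max(w // 20, 6)))
            mask[:, c : min(c + thick, w)] = True
    return mask


def generate_tissue_scene(params: SceneParams) -> tuple[TissueImage, GroundTruth]:
    """Render a multichannel stained section and its ground truth.

    One channel per :class:`MarkerSpec`.  DAPI (required, nuclear) is elevated
    in all nuclei; other nuclear markers only inside Bernoulli-positive
    nuclei; cytosolic markers in a 3-px dilated annulus around positive
    nuclei, clipped at the nearest-nucleus Voronoi boundary.  Additive
    Gaussian autofluorescence covers everything; intensities are clipped at 0.
    """
    dapi = [m for m in params.marker_specs if m.name == "DAPI"]
    if not dapi or dapi[0].compartment != "nuclear":
        raise ValueError("marker_specs must include a nuclear marker named 'DAPI'")
    rng = np.random.default_rng(params.rng_seed)
    h, w = params.image_height_px, params.image_width_px

    if params.n_nuclei > 0:
        centers, radii, aspect, theta = _place_nuclei(params, rng)
        labels = _render_label_map(params, centers, radii, aspect, theta)
    else:
        labels = np.zeros((h, w), dtype=np.int32)
    n = int(labels.max())
    nucleus_any = labels > 0

    # Voronoi ownership of every pixel, for clipping cytosolic annuli
    if n > 0:
        _, (ir, ic) = ndi.distance_transform_edt(labels == 0, return_indices=True)
        voronoi = labels[ir, ic]
    else:
        voronoi = np.zeros((h, w), dtype=np.int32)

    artifact = _artifact_mask(params, rng) if params.artifact_fraction > 0 else np.zeros((h, w), bool)

    channels: dict[str, np.ndarray] = {}
    positivity: dict[str, np.ndarray] = {}
    for spec in params.marker_specs:
        ch = rng.normal(
            params.background_autofluorescence_mean,
            params.background_autofluorescence_sd,
            size=(h, w),
        )
        if spec.name == "DAPI":
            pos = np.ones(n, dtype=bool)
        else:
            pos = rng.uniform(size=n) < spec.positive_fraction
        positivity[spec.name] = pos
        if n > 0 and spec.compartment in ("nuclear", "cytosolic"):
            pos_label_mask = np.zeros(n + 1, dtype=bool)
            pos_label_mask[1:][pos] = True
            if spec.compartment == "nuclear":
                pos_region = pos_label_mask[labels]
                neg_region = nucleus_any & ~pos_region
            else:
                fp = disk(CYTO_DILATION_PX)
                pos_nuc = pos_label_mask[labels]
                pos_halo = ndi.binary_dilation(pos_nuc, structure=fp) & pos_label_mask[voronoi]
                pos_region = pos_halo & ~nucleus_any
                neg_halo = ndi.binary_dilation(nucleus_any & ~pos_nuc, structure=fp) & ~pos_label_mask[voronoi]
                neg_region = neg_halo & ~nucleus_any
            npx = int(pos_region.sum())
            ch[pos_region] += rng.normal(spec.positive_intensity_mean, spec.intensity_sd, npx)
            npx = int(neg_region.sum())
            if spec.negative_intensity_mean > 0:
                ch[neg_region] += rng.normal(spec.negative_intensity_mean, spec.intensity_sd, npx)
        if artifact.any():
            ch[artifact] *= 2.0  # folds: doubled optical path
        channels[spec.name] = np.clip(ch, 0, None)

    img = TissueImage(
        channels=channels,
        pixel_size_um=params.pixel_size_um,
        channel_meta={m.name: {"stain": m.name, "compartment": m.compartment} for m in params.marker_specs},
    )
    truth = GroundTruth(
        nucleus_label_map=NucleusLabelMap(labels, params.pixel_size_um),
        per_cell_positivity=positivity,
        artifact_mask=artifact,
    )
    return img, truth


# ---------------------------------------------------------------------------
# uptake scenes

def generate_uptake_scene(
    params: SceneParams,
    viable_mean: float,
    necrotic_mean: float,
    necrotic_area_fraction: float,
    noise_sd: float | None = None,
) -> tuple[TissueImage, GroundTruth]:
    """Render a single-channel whole-tissue uptake image with a necrotic blob.

    The tissue fills the frame; a contiguous elliptical necrotic region of the
    requested area fraction carries ``necrotic_mean`` intensity, the rest
    ``viable_mean``, with additive Gaussian noise (sd defaults to the
    background autofluorescence sd).
    """
    if viable_mean < 0 or necrotic_mean < 0:
        raise ValueError("region mean intensities must be non-negative")
    if not 0 <= necrotic_area_fraction <= 1:
        raise ValueError("necrotic_area_fraction must lie in [0, 1]")
    sd = params.background_autofluorescence_sd if noise_sd is None else noise_sd
    rng = np.random.default_rng(params.rng_seed)
    h, w = params.image_height_px, params.image_width_px

    necrotic = np.zeros((h, w), dtype=bool)
    if necrotic_area_fraction > 0:
        area = necrotic_area_fraction * h * w
        aspect = rng.uniform(1.0, 1.8)
        b = np.sqrt(area / (np.pi * aspect))
        a = aspect * b
        a, b = min(a, w / 2 - 1), min(b, h / 2 - 1)
        cy = rng.uniform(b, h - b) if h - 2 * b > 0 else h / 2
        cx = rng.uniform(a, w - a) if w - 2 * a > 0 else w / 2
        yy, xx = np.mgrid[0:h, 0:w]
        necrotic = ((yy - cy) / b) ** 2 + ((xx - cx) / a) ** 2 <= 1.0

    ch = np.full((h, w), float(viable_mean))
    ch[necrotic] = necrotic_mean
    ch = np.clip(ch + rng.normal(0, sd, size=(h, w)), 0, None)

    img = TissueImage(
        channels={"uptake": ch},
        pixel_size_um=params.pixel_size_um,
        channel_meta={"uptake": {"stain": "uptake", "compartment": "whole_tissue"}},
    )
    truth = GroundTruth(
        nucleus_label_map=NucleusLabelMap(np.zeros((h, w), dtype=np.int32), params.pixel_size_um),
        per_cell_positivity={},
        region_annotation=RegionAnnotation(viable_mask=~necrotic, necrotic_mask=necrotic),
        artifact_mask=np.zeros((h, w), dtype=bool),
    )
    return img, truth


# ---------------------------------------------------------------------------
# disk round-trip

def write_scene(
    img: TissueImage,
    truth: GroundTruth,
    directory: str | Path,
    params: SceneParams | None = None,
) -> Path:
    """Write a scene as TIFFs + CSV/JSON text so it round-trips through the readers."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_tissue_image(img, directory, stem="image")
    write_label_map(truth.nucleus_label_map.labels, directory / "nuclei_labels.tif")
    if truth.artifact_mask is not None:
        write_mask(truth.artifact_mask, directory / "artifact_mask.tif")
    if truth.region_annotation is not None:
        write_mask(truth.region_annotation.viable_mask, directory / "viable_mask.tif")
        write_mask(truth.region_annotation.necrotic_mask, directory / "necrotic_mask.tif")
    if truth.per_cell_positivity:
        n = truth.nucleus_label_map.n_nuclei
        table = pd.DataFrame({"nucleus_label": np.arange(1, n + 1)})
        for marker, flags in truth.per_cell_positivity.items():
            table[marker] = flags.astype(int)
        table.to_csv(directory / "positivity.csv", index=False)
    if params is not None:
        with open(directory / "params.json", "w") as fh:
            json.dump(asdict(params), fh, indent=2)
    return directory


def read_scene(directory: str | Path) -> tuple[TissueImage, GroundTruth]:
    """Read a scene written by :func:`write_scene`."""
    directory = Path(directory)
    img = read_tissue_image(directory, stem="image")
    labels = read_label_map(directory / "nuclei_labels.tif")
    positivity: dict[str, np.ndarray] = {}
    pos_path = directory / "positivity.csv"
    if pos_path.exists():
        table = pd.read_csv(pos_path)
        for marker in table.columns:
            if marker != "nucleus_label":
                positivity[marker] = table[marker].to_numpy().astype(bool)
    annotation = None
    if (directory / "necrotic_mask.tif").exists():
        annotation = RegionAnnotation(
            viable_mask=read_mask(directory / "viable_mask.tif"),
            necrotic_mask=read_mask(directory / "necrotic_mask.tif"),
        )
    artifact = None
    if (directory / "artifact_mask.tif").exists():
        artifact = read_mask(directory / "artifact_mask.tif")
    truth = GroundTruth(
        nucleus_label_map=NucleusLabelMap(labels, img.pixel_size_um),
        per_cell_positivity=positivity,
        region_annotation=annotation,
        artifact_mask=artifact,
    )
    return img, truth


def read_scene_params(path: str | Path) -> SceneParams:
    with open(path) as fh:
        payload = json.load(fh)
    payload["marker_specs"] = [MarkerSpec(**m) for m in payload["marker_specs"]]
    return SceneParams(**payload)
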