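"""Synthetic Sirius-Red liver slide generator with ground-truth masks.

Renders desk-scale whole-slide images of rodent liver stained with
Picrosirius Red (collagen red, parenchyma pale yellow) for each Kleiner
CRN fibrosis stage, together with pixel-exact ground truth.  The lobular
geometry is a hexagonal packing of circular lobules: a central vein sits
at each lobule center and portal tracts sit at the lobule vertices
(computed as Delaunay-triangle centroids of the vein lattice), so that
"zone-3 perisinusoidal" and "portal/periportal" collagen are geometrically
distinct, testable regions.

Stage geometry rules
--------------------
0   collagen confined to vessel-wall annuli (normal vascular collagen)
1A  sparse short perisinusoidal strands in the zone-3 annulus of each
    central vein
1B  the same pattern at 3x the 1A strand density
1C  collagen annuli around portal tracts only
2   union of the 1B and 1C patterns
3   stage-2 pattern plus continuous collagen septa bridging a central
    vein to a portal tract
4   stage-3 burden plus closed collagen septa along every lobule
    boundary, partitioning the tissue into cirrhotic nodules

All random geometry is drawn in micron units from a generator seeded by
(score, seed), so the same scene rendered at 20x and 40x covers the same
physical tissue and identical (score, spec) calls are byte-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from scipy import ndimage
from scipy.spatial import Delaunay, Voronoi
from skimage.color import hsv2rgb
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line

SCORES = ("0", "1A", "1B", "1C", "2", "3", "4")
MICRONS_PER_PIXEL = {"40x": 0.264, "20x": 0.528}
#: patch side in pixels at each magnification (0.27 mm of tissue)
PATCH_SIDE = {"40x": 1024, "20x": 512}


class SceneSizeError(ValueError):
    """Canvas too small to hold a single patch at the scene magnification."""


@dataclass(frozen=True)
class CollagenColorModel:
    """Sirius-Red color model: collagen red band vs pale-yellow parenchyma.

    Hue/saturation/value centers are on the [0, 1] HSV scale.  Per-pixel
    Gaussian jitter (sd per channel) emulates staining variability; zero
    jitter gives exactly separable stain colors.
    """

    collagen_hsv_center: tuple[float, float, float] = (0.98, 0.78, 0.62)
    parenchyma_hsv_center: tuple[float, float, float] = (0.13, 0.42, 0.90)
    hsv_jitter_sd: tuple[float, float, float] = (0.0, 0.0, 0.0)
    background_rgb: tuple[int, int, int] = (246, 244, 240)


@dataclass(frozen=True)
class SceneSpec:
    """Geometry and color parameters of one synthetic slide."""

    width_px: int = 1024
    height_px: int = 1024
    magnification: str = "20x"
    microns_per_pixel: float | None = None  # default set from magnification
    n_lobules: int | None = None  # None = as many as fit the canvas
    lobule_radius_um: float = 60.0
    vessel_radius_um: float = 8.0
    stain_model: CollagenColorModel = field(default_factory=CollagenColorModel)
    artifact_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.magnification not in MICRONS_PER_PIXEL:
            raise ValueError(f"unknown magnification {self.magnification!r}")
        if self.microns_per_pixel is None:
            object.__setattr__(
                self, "microns_per_pixel", MICRONS_PER_PIXEL[self.magnification]
            )
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("canvas dimensions must be positive")
        if not (0.0 <= self.artifact_rate <= 1.0):
            raise ValueError("artifact_rate must lie in [0, 1]")
        side = PATCH_SIDE[self.magnification]
        if self.width_px < side or self.height_px < side:
            raise SceneSizeError(
                f"canvas {self.width_px}x{self.height_px} px is smaller than one "
                f"{side}x{side} patch at {self.magnification}"
            )

    def with_magnification(self, magnification: str) -> "SceneSpec":
        """Same physical scene re-rendered at another magnification."""
        factor = MICRONS_PER_PIXEL[self.magnification] / MICRONS_PER_PIXEL[magnification]
        return dataclasses.replace(
            self,
            magnification=magnification,
            microns_per_pixel=MICRONS_PER_PIXEL[magnification],
            width_px=int(round(self.width_px * factor)),
            height_px=int(round(self.height_px * factor)),
        )


@dataclass
class GroundTruth:
    """Pixel-exact annotation of a synthetic scene."""

    collagen_mask: np.ndarray
    central_vein_mask: np.ndarray
    portal_tract_mask: np.ndarray
    tissue_mask: np.ndarray
    score: str

    def __post_init__(self) -> None:
        shapes = {
            m.shape
            for m in (
                self.collagen_mask,
                self.central_vein_mask,
                self.portal_tract_mask,
                self.tissue_mask,
            )
        }
        if len(shapes) != 1:
            raise ValueError("ground-truth masks must share dimensions")


# geometric constants (microns)
_TISSUE_MARGIN_UM = 8.0    # unstained glass border around the section
_WALL_UM = 1.2             # normal vessel-wall collagen thickness
_STRAND_WIDTH_UM = 1.2
_STRAND_LEN_UM = (10.0, 16.0)
_SEPTUM_WIDTH_UM = 2.5
_RING_WIDTH_UM = 2.5
_STRANDS_1A = 7            # perisinusoidal strands per central vein at 1A
_STRAND_DENSITY_RATIO = 3  # 1B = 3x the 1A strand density


def _scene_rng(score: str, seed: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([SCORES.index(score), seed & 0x7FFFFFFF])
    )


def _vein_lattice(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Hexagonal lattice of central-vein centers (micron coordinates)."""
    w_um = spec.width_px * spec.microns_per_pixel
    h_um = spec.height_px * spec.microns_per_pixel
    s = 2.0 * spec.lobule_radius_um
    dy = s * np.sqrt(3.0) / 2.0
    inset = _TISSUE_MARGIN_UM + spec.vessel_radius_um + _WALL_UM
    centers = []
    row = 0
    y = inset + 0.35 * s
    while y < h_um - inset:
        x0 = inset + 0.35 * s + (s / 2.0 if row % 2 else 0.0)
        x = x0
        while x < w_um - inset:
            centers.append((x, y))
            x += s
        y += dy
        row += 1
    pts = np.asarray(centers, dtype=float)
    # small positional jitter so lobules are not perfectly crystalline
    pts += rng.normal(scale=0.02 * s, size=pts.shape)
    pts[:, 0] = np.clip(pts[:, 0], inset, w_um - inset)
    pts[:, 1] = np.clip(pts[:, 1], inset, h_um - inset)
    if spec.n_lobules is not None and len(pts) < spec.n_lobules:
        raise ValueError(
            f"canvas fits only {len(pts)} lobules, {spec.n_lobules} requested"
        )
    return pts


def _portal_sites(veins_um: np.ndarray, spec: SceneSpec) -> np.ndarray:
    """Portal tracts at lobule vertices = Delaunay-triangle centroids."""
    tri = Delaunay(veins_um)
    cent = veins_um[tri.simplices].mean(axis=1)
    w_um = spec.width_px * spec.microns_per_pixel
    h_um = spec.height_px * spec.microns_per_pixel
    inset = _TISSUE_MARGIN_UM + spec.vessel_radius_um + _WALL_UM
    keep = (
        (cent[:, 0] > inset)
        & (cent[:, 0] < w_um - inset)
        & (cent[:, 1] > inset)
        & (cent[:, 1] < h_um - inset)
    )
    return cent[keep]


def _disk_mask(
    shape: tuple[int, int], centers_px: np.ndarray, radius_px: float
) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for cx, cy in centers_px:
        rr, cc = draw_disk((cy, cx), radius_px, shape=shape)
        mask[rr, cc] = True
    return mask


def _thicken(thin: np.ndarray, width_px: float) -> np.ndarray:
    r = max(1, int(round(width_px / 2.0)))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return ndimage.binary_dilation(thin, structure=(xx**2 + yy**2) <= r**2)


def _draw_segments(
    shape: tuple[int, int], segments_px: list[tuple[float, float, float, float]],
    width_px: float,
) -> np.ndarray:
    thin = np.zeros(shape, dtype=bool)
    h, w = shape
    for x0, y0, x1, y1 in segments_px:
        rr, cc = draw_line(
            int(round(y0)), int(round(x0)), int(round(y1)), int(round(x1))
        )
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        thin[rr[ok], cc[ok]] = True
    if not thin.any():
        return thin
    return _thicken(thin, width_px)


def _strand_segments(
    veins_um: np.ndarray, spec: SceneSpec, rng: np.random.Generator, per_vein: int
) -> list[tuple[float, float, float, float]]:
    """Short radial collagen strands in the zone-3 annulus of each vein."""
    segs = []
    r_lob = spec.lobule_radius_um
    r_in = spec.vessel_radius_um + 2.0
    for vx, vy in veins_um:
        theta = rng.uniform(0.0, 2.0 * np.pi, size=per_vein)
        a = rng.uniform(r_in, 0.4 * r_lob, size=per_vein)
        length = rng.uniform(*_STRAND_LEN_UM, size=per_vein)
        for t, a0, ln in zip(theta, a, length):
            segs.append(
                (
                    vx + a0 * np.cos(t),
                    vy + a0 * np.sin(t),
                    vx + (a0 + ln) * np.cos(t),
                    vy + (a0 + ln) * np.sin(t),
                )
            )
    return segs


def _septum_pairs(
    veins_um: np.ndarray, portals_um: np.ndarray, rng: np.random.Generator, n: int
) -> list[tuple[float, float, float, float]]:
    """Vein-to-nearest-portal bridges; each septum spans two vessel disks."""
    if len(portals_um) == 0:
        return []
    order = rng.permutation(len(veins_um))[:n]
    segs = []
    for i in order:
        vx, vy = veins_um[i]
        d = np.hypot(portals_um[:, 0] - vx, portals_um[:, 1] - vy)
        px, py = portals_um[int(np.argmin(d))]
        segs.append((vx, vy, px, py))
    return segs


def _voronoi_ridges(
    veins_um: np.ndarray, spec: SceneSpec
) -> list[tuple[float, float, float, float]]:
    """Finite lobule-boundary segments (Voronoi ridges of the vein lattice).

    Ghost points mirrored across the canvas edges close the outer cells so
    every interior ridge is finite.
    """
    w_um = spec.width_px * spec.microns_per_pixel
    h_um = spec.height_px * spec.microns_per_pixel
    mirrors = [
        veins_um * [-1, 1],
        veins_um * [1, -1],
        np.column_stack([2 * w_um - veins_um[:, 0], veins_um[:, 1]]),
        np.column_stack([veins_um[:, 0], 2 * h_um - veins_um[:, 1]]),
    ]
    pts = np.vstack([veins_um, *mirrors])
    vor = Voronoi(pts)
    n_real = len(veins_um)
    segs = []
    for (p, q), verts in zip(vor.ridge_points, vor.ridge_vertices):
        if p >= n_real and q >= n_real:
            continue
        if -1 in verts:
            continue
        (x0, y0), (x1, y1) = vor.vertices[verts]
        segs.append((x0, y0, x1, y1))
    return segs


def _collagen_mask(
    score: str,
    spec: SceneSpec,
    rng: np.random.Generator,
    veins_um: np.ndarray,
    portals_um: np.ndarray,
    vein_disks: np.ndarray,
    portal_disks: np.ndarray,
    lumen: np.ndarray,
    tissue: np.ndarray,
    shape: tuple[int, int],
) -> np.ndarray:
    mpp = spec.microns_per_pixel
    to_px = lambda um: um / mpp  # noqa: E731
    veins_px = veins_um / mpp
    portals_px = portals_um / mpp

    # normal vascular collagen: wall annuli of every vessel
    wall = (vein_disks | portal_disks) & ~lumen
    collagen = wall.copy()

    n_strands = {
        "1A": _STRANDS_1A,
        "1B": _STRANDS_1A * _STRAND_DENSITY_RATIO,
        "2": _STRANDS_1A * _STRAND_DENSITY_RATIO,
        "3": _STRANDS_1A * _STRAND_DENSITY_RATIO,
        "4": _STRANDS_1A * _STRAND_DENSITY_RATIO,
    }.get(score, 0)
    # draw from the rng in a fixed order so geometry is reproducible
    if n_strands:
        segs_um = _strand_segments(veins_um, spec, rng, n_strands)
        segs_px = [tuple(to_px(v) for v in s) for s in segs_um]
        collagen |= _draw_segments(shape, segs_px, to_px(_STRAND_WIDTH_UM))

    if score in ("1C", "2", "3", "4"):
        r_p = to_px(spec.vessel_radius_um)
        ring = _disk_mask(shape, portals_px, r_p + to_px(_RING_WIDTH_UM))
        ring &= ~_disk_mask(shape, portals_px, r_p)
        collagen |= ring

    if score in ("3", "4"):
        # established bridging: on the order of one septum per lobule at
        # stage 3; fewer at stage 4, where the boundary network dominates
        n_septa = max(1, len(veins_um) // 3) if score == "4" else len(veins_um)
        segs_um = _septum_pairs(veins_um, portals_um, rng, n_septa)
        segs_px = [tuple(to_px(v) for v in s) for s in segs_um]
        collagen |= _draw_segments(shape, segs_px, to_px(_SEPTUM_WIDTH_UM))

    if score == "4":
        segs_um = _voronoi_ridges(veins_um, spec)
        segs_px = [tuple(to_px(v) for v in s) for s in segs_um]
        collagen |= _draw_segments(shape, segs_px, to_px(_SEPTUM_WIDTH_UM))

    # collagen lives in tissue (vessel walls included, lumens excluded)
    return collagen & tissue


def generate_scene(score: str, spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic Sirius-Red slide for a Kleiner fibrosis stage.

    Returns an (H, W, 3) uint8 RGB image and its :class:`GroundTruth`.
    Deterministic given ``(score, spec.seed)``.
    """
    if score not in SCORES:
        raise ValueError(f"score must be one of {SCORES}, got {score!r}")
    rng = _scene_rng(score, spec.seed)
    shape = (spec.height_px, spec.width_px)
    mpp = spec.microns_per_pixel

    veins_um = _vein_lattice(spec, rng)
    portals_um = _portal_sites(veins_um, spec)

    r_v_px = spec.vessel_radius_um / mpp
    wall_px = _WALL_UM / mpp
    vein_disks = _disk_mask(shape, veins_um / mpp, r_v_px)
    portal_disks = _disk_mask(shape, portals_um / mpp, r_v_px)
    lumen = _disk_mask(shape, veins_um / mpp, r_v_px - wall_px)
    lumen |= _disk_mask(shape, portals_um / mpp, r_v_px - wall_px)

    margin_px = int(round(_TISSUE_MARGIN_UM / mpp))
    tissue = np.zeros(shape, dtype=bool)
    tissue[margin_px:-margin_px, margin_px:-margin_px] = True
    tissue &= ~lumen

    collagen = _collagen_mask(
        score, spec, rng, veins_um, portals_um,
        vein_disks, portal_disks, lumen, tissue, shape,
    )

    img = _render(spec.stain_model, tissue, collagen, shape, rng)
    gt = GroundTruth(
        collagen_mask=collagen,
        central_vein_mask=vein_disks,
        portal_tract_mask=portal_disks,
        tissue_mask=tissue,
        score=score,
    )
    return img, gt


def _render(
    model: CollagenColorModel,
    tissue: np.ndarray,
    collagen: np.ndarray,
    shape: tuple[int, int],
    rng: np.random.Generator,
) -> np.ndarray:
    hsv = np.empty(shape + (3,), dtype=np.float64)
    bg = np.asarray(model.background_rgb, dtype=np.float64) / 255.0
    # background stored directly in RGB; tissue painted from HSV centers
    par = np.asarray(model.parenchyma_hsv_center)
    col = np.asarray(model.collagen_hsv_center)
    hsv[:] = 0.0
    hsv[tissue] = par
    hsv[collagen] = col
    sd = np.asarray(model.hsv_jitter_sd, dtype=float)
    stained = tissue | collagen
    if sd.any():
        noise = rng.normal(scale=sd, size=(int(stained.sum()), 3))
        hsv[stained] += noise
        hsv[stained, 0] %= 1.0
        hsv[stained, 1:] = np.clip(hsv[stained][:, 1:], 0.0, 1.0)
    rgb = hsv2rgb(hsv)
    rgb[~stained] = bg
    return (np.clip(rgb, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)


# ---------------------------------------------------------------------------
# artifacts

ARTIFACT_KINDS = ("overstain_patch", "debris")


def inject_artifact(rgb_image: np.ndarray, kind: str, seed: int) -> np.ndarray:
    """Recolor a localized blob to emulate a slide-preparation artifact.

    ``overstain_patch`` pulls pixels toward the collagen red (a stain pool
    that reads as false-positive fibrosis); ``debris`` darkens a smaller
    blob.  Ground truth is never updated: artifacts are not fibrosis.
    """
    if rgb_image.ndim != 3 or rgb_image.shape[2] != 3:
        raise ValueError("expected an RGB image")
    if kind not in ARTIFACT_KINDS:
        raise ValueError(f"unknown artifact kind {kind!r}")
    rng = np.random.default_rng(
        np.random.SeedSequence([ARTIFACT_KINDS.index(kind) + 17, seed & 0x7FFFFFFF])
    )
    h, w = rgb_image.shape[:2]
    cy = rng.uniform(0.15 * h, 0.85 * h)
    cx = rng.uniform(0.15 * w, 0.85 * w)
    if kind == "overstain_patch":
        radius = rng.uniform(w / 24, w / 12)
        color = np.array([178, 34, 48], dtype=np.float64)
        blend = 0.65
    else:
        radius = rng.uniform(w / 40, w / 24)
        color = np.array([70, 60, 55], dtype=np.float64)
        blend = 0.8
    ry = radius * rng.uniform(0.7, 1.3)
    yy, xx = np.mgrid[0:h, 0:w]
    theta = rng.uniform(0, np.pi)
    u = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    v = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
    mask = (u / radius) ** 2 + (v / ry) ** 2 <= 1.0
    out = rgb_image.astype(np.float64).copy()
    out[mask] = (1.0 - blend) * out[mask] + blend * color
    return (out + 0.5).astype(np.uint8)


# ---------------------------------------------------------------------------
# dataset assembly

def build_dataset(
    per_class_wsi_counts: Mapping[str, int],
    spec_template: SceneSpec | Mapping[str, SceneSpec],
    out_dir: str | Path,
    seed: int = 0,
    image_format: str = "tiff",
    write_masks: bool = False,
) -> pd.DataFrame:
    """Write one synthetic slide per requested WSI plus a manifest CSV.

    ``spec_template`` is either a single :class:`SceneSpec` applied to every
    class or a mapping score -> SceneSpec (e.g. to mix magnifications).
    Returns the manifest (columns ``wsi_id,path,magnification,score``), also
    written to ``out_dir/manifest.csv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if image_format not in ("tiff", "png"):
        raise ValueError("image_format must be 'tiff' or 'png'")
    rng = np.random.default_rng(np.random.SeedSequence([997, seed & 0x7FFFFFFF]))
    rows = []
    for score in SCORES:
        if score not in per_class_wsi_counts:
            continue
        count = int(per_class_wsi_counts[score])
        if count < 1:
            raise ValueError(f"count for class {score!r} must be >= 1")
        template = (
            spec_template[score]
            if isinstance(spec_template, Mapping)
            else spec_template
        )
        for idx in range(count):
            scene_seed = int(rng.integers(0, 2**31))
            spec = dataclasses.replace(template, seed=scene_seed)
            img, gt = generate_scene(score, spec)
            if spec.artifact_rate > 0 and rng.random() < spec.artifact_rate:
                kind = ARTIFACT_KINDS[int(rng.integers(len(ARTIFACT_KINDS)))]
                img = inject_artifact(img, kind, int(rng.integers(0, 2**31)))
            wsi_id = f"s{score}_{idx:03d}"
            ext = "tif" if image_format == "tiff" else "png"
            path = out_dir / f"{wsi_id}.{ext}"
            if image_format == "tiff":
                tifffile.imwrite(path, img, tile=(256, 256), photometric="rgb")
            else:
                Image.fromarray(img).save(path)
            if write_masks:
                for name, mask in (
                    ("collagen", gt.collagen_mask),
                    ("central_vein", gt.central_vein_mask),
                    ("portal_tract", gt.portal_tract_mask),
                    ("tissue", gt.tissue_mask),
                ):
                    Image.fromarray((mask * np.uint8(255))).save(
                        out_dir / f"{wsi_id}_{name}.png"
                    )
            rows.append(
                {
                    "wsi_id": wsi_id,
                    "path": str(path),
                    "magnification": spec.magnification,
                    "score": score,
                }
            )
    manifest = pd.DataFrame(rows, columns=["wsi_id", "path", "magnification", "score"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


# ---------------------------------------------------------------------------
# mask-level staging oracle

def collagen_fraction(gt: GroundTruth) -> float:
    """Collagen proportionate area: collagen pixels / tissue pixels."""
    return float(gt.collagen_mask.sum()) / float(gt.tissue_mask.sum())


def stage_from_masks(gt: GroundTruth, spec: SceneSpec) -> str:
    """Rule-based Kleiner stage read directly off the ground-truth masks.

    A pixel-level oracle: strips vessel-wall collagen, then tests (in
    order) nodular partition (4), vessel-bridging septa (3), and the
    periportal/pericentral localization and density of what remains.
    Exists to certify that generated scenes are stageable in principle.
    """
    mpp = spec.microns_per_pixel
    vessels = gt.central_vein_mask | gt.portal_tract_mask
    # wall collagen sits inside the vessel disk; a 1-px guard band suffices
    wall_zone = ndimage.binary_dilation(vessels)
    path_col = gt.collagen_mask & ~wall_zone
    tissue_area = float(gt.tissue_mask.sum())
    if path_col.sum() < 0.0008 * tissue_area:
        return "0"

    # stage 4: collagen septa partition the tissue into many nodules
    open_tissue = gt.tissue_mask & ~ndimage.binary_dilation(gt.collagen_mask)
    piece_labels, n_pieces = ndimage.label(open_tissue)
    sizes = ndimage.sum(open_tissue, piece_labels, range(1, n_pieces + 1))
    n_nodules = int(np.sum(np.asarray(sizes) > 0.005 * tissue_area))
    if n_nodules >= 4:
        return "4"

    # stage 3: a connected collagen component touching >= 2 distinct vessels
    vessel_labels, _ = ndimage.label(vessels)
    comp_labels, n_comp = ndimage.label(gt.collagen_mask)
    grown = ndimage.binary_dilation(vessels)
    for comp in range(1, n_comp + 1):
        touched = np.unique(vessel_labels[(comp_labels == comp) & grown])
        if np.count_nonzero(touched) >= 2:
            return "3"

    # localization of the remaining (non-wall) collagen: compare each
    # compartment's collagen with the area its minimal lesion would cover
    r_pp = int(round((spec.vessel_radius_um + 12.0) / mpp))
    near_portal = _grow(gt.portal_tract_mask, r_pp)
    near_vein = _grow(
        gt.central_vein_mask, int(round(0.75 * spec.lobule_radius_um / mpp))
    )
    n_portals = ndimage.label(gt.portal_tract_mask)[1]
    n_veins = ndimage.label(gt.central_vein_mask)[1]
    r_p = spec.vessel_radius_um
    ring_area_px = np.pi * ((r_p + _RING_WIDTH_UM) ** 2 - r_p**2) / mpp**2
    # mean strand footprint: mean length at the ~3-px painted line width
    strand_area_px = (sum(_STRAND_LEN_UM) / 2.0 / mpp) * 3.0
    portal_col = float((path_col & near_portal).sum())
    central_col = float((path_col & near_vein & ~near_portal).sum())
    portal_present = portal_col > 0.3 * n_portals * ring_area_px
    central_present = central_col > 0.5 * n_veins * _STRANDS_1A * strand_area_px
    if portal_present and central_present:
        return "2"
    if portal_present:
        return "1C"

    # pericentral only: density separates mild (1A) from moderate (1B)
    per_vein = central_col / max(1, n_veins)
    cutoff = strand_area_px * _STRANDS_1A * np.sqrt(_STRAND_DENSITY_RATIO)
    return "1B" if per_vein > cutoff else "1A"


def _grow(mask: np.ndarray, r: int) -> np.ndarray:
    if r <= 0:
        return mask
    d = ndimage.distance_transform_edt(~mask)
    return d <= r
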