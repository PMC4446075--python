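"""Cross-section reformatting and ROI-based SNR/CNR quantification.

Mirrors the measurement protocol of the reference study: 0.5 mm thick 2D
cross-sections perpendicular to the vessel centerline at five bilateral
locations; lumen signal S_l as the mean over the whole lumen ROI (sign
flipped for the signed SNAP images), wall signal S_w as the mean over the
middle path of the wall ring, and the noise SD sigma_n from an ROI in the
adjacent reference tissue (muscle in the neck, white matter in the head)
rather than background air, because the noise level varies spatially.
SNR_w = S_w / sigma_n, SNR_l = S_l / sigma_n, and the wall-lumen contrast is
SNR_w - SNR_l for magnitude images but SNR_w + SNR_l for SNAP, whose lumen
is of opposite polarity. ROIs are derived from the phantom's ground-truth
labels eroded away from partial-volume boundaries — the stand-in for the
study's manually drawn ROIs. Rician bias is deliberately not corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import skeletonize

from .phantom import BuiltPhantom, AcquiredVolume, WAYPOINTS

__all__ = [
    "CrossSection",
    "ROIMeasurement",
    "reformat_cross_sections",
    "extract_section",
    "measure_rois",
    "measure_volume",
    "measurements_to_frame",
    "segment_class",
]

EXTRACRANIAL = ("CCA", "BULB")


def segment_class(location: str) -> str:
    return "extracranial" if location in EXTRACRANIAL else "intracranial"


@dataclass
class CrossSection:
    """A 0.5 mm thick cross-sectional slice normal to the centerline."""

    image: np.ndarray  # 2D, in-plane
    labels: dict  # label name -> resampled fraction channel
    location: str
    side: str
    origin_mm: np.ndarray
    normal: np.ndarray
    in_plane_spacing_mm: float
    thickness_mm: float = 0.5

    def area_mm2(self, label: str) -> float:
        """Area of one label from its partial-volume fractions."""
        return float(np.sum(self.labels[label]) * self.in_plane_spacing_mm**2)


@dataclass
class ROIMeasurement:
    """SNR/CNR measurement at one location and side."""

    subject_id: str
    sequence: str
    location: str
    side: str
    s_w: float
    s_l: float
    sigma_n: float
    snr_w: float
    snr_l: float
    cnr_w_l: float
    excluded: bool = False

    @classmethod
    def missing(cls, subject_id, sequence, location, side) -> "ROIMeasurement":
        return cls(subject_id, sequence, location, side,
                   np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, excluded=True)


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = normal / np.linalg.norm(normal)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, n)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(helper, n)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def _resample_plane(
    volume: np.ndarray,
    affine: np.ndarray,
    origin: np.ndarray,
    normal: np.ndarray,
    half_size_mm: float,
    spacing_mm: float,
    thickness_mm: float,
    n_through: int = 5,
) -> np.ndarray:
    """Trilinear resampling onto a plane with through-plane averaging."""
    u, v = _plane_basis(normal)
    n = normal / np.linalg.norm(normal)
    coords_1d = np.arange(-half_size_mm, half_size_mm + 1e-9, spacing_mm)
    uu, vv = np.meshgrid(coords_1d, coords_1d, indexing="ij")
    base = origin[None, None, :] + uu[..., None] * u[None, None, :] + vv[..., None] * v[None, None, :]
    inv = np.linalg.inv(affine)
    out = np.zeros(uu.shape)
    offsets = np.linspace(-thickness_mm / 2.0, thickness_mm / 2.0, n_through)
    for dz in offsets:
        pts = base + dz * n[None, None, :]
        idx = pts @ inv[:3, :3].T + inv[:3, 3]
        out += ndimage.map_coordinates(
            volume, [idx[..., 0], idx[..., 1], idx[..., 2]], order=1, mode="nearest"
        )
    return out / len(offsets)


def extract_section(
    image: np.ndarray,
    affine: np.ndarray,
    centerline: pd.DataFrame,
    waypoint_z_mm: float,
    location: str,
    side: str,
    label_volumes: dict | None = None,
    in_plane_spacing_mm: float = 0.4,
    half_size_mm: float = 12.8,
    thickness_mm: float = 0.5,
    flip_tangent: bool = False,
) -> CrossSection:
    """One cross-section at a centerline waypoint.

    The plane origin is the centerline point nearest the waypoint FH
    position; the normal is the local centerline tangent (central
    difference).
    """
    z = centerline["z_mm"].to_numpy()
    i = int(np.argmin(np.abs(z - waypoint_z_mm)))
    pts = centerline[["x_mm", "y_mm", "z_mm"]].to_numpy()
    if not (0 <= i < len(pts)):
        raise ValueError(f"waypoint z={waypoint_z_mm} outside the centerline")
    lo, hi = max(i - 4, 0), min(i + 4, len(pts) - 1)
    tangent = pts[hi] - pts[lo]
    tangent = tangent / np.linalg.norm(tangent)
    if flip_tangent:
        tangent = -tangent
    origin = pts[i]
    img = _resample_plane(
        image, affine, origin, tangent, half_size_mm, in_plane_spacing_mm, thickness_mm
    )
    labels = {}
    if label_volumes:
        for name, vol in label_volumes.items():
            labels[name] = _resample_plane(
                vol.astype(float), affine, origin, tangent,
                half_size_mm, in_plane_spacing_mm, thickness_mm,
            )
    return CrossSection(
        image=img,
        labels=labels,
        location=location,
        side=side,
        origin_mm=origin,
        normal=tangent,
        in_plane_spacing_mm=in_plane_spacing_mm,
        thickness_mm=thickness_mm,
    )


def reformat_cross_sections(
    image: np.ndarray,
    affine: np.ndarray,
    centerline: pd.DataFrame,
    waypoints: dict[str, float] = WAYPOINTS,
    side: str = "right",
    label_volumes: dict | None = None,
    **kwargs,
) -> list[CrossSection]:
    """Cross-sections at every named waypoint along one centerline."""
    return [
        extract_section(image, affine, centerline, wz, loc, side, label_volumes, **kwargs)
        for loc, wz in waypoints.items()
    ]


# ---------------------------------------------------------------------------
# ROI measurement


@dataclass
class ROISpec:
    """Geometry of the derived ROIs (the stand-in for manual drawing)."""

    wall_fraction_threshold: float = 0.5
    lumen_erosion_px: int = 1
    reference_area_mm2: float = 20.0
    reference_clearance_mm: float = 3.0
    reference_purity: float = 0.95


def _reference_roi(
    section: CrossSection, ref_label: str, spec: ROISpec
) -> np.ndarray | None:
    """Fixed-size disc in the adjacent reference tissue.

    Tries eight angular positions at increasing clearance from the vessel
    until the disc lies in (nearly) pure reference tissue.
    """
    sp = section.in_plane_spacing_mm
    radius_px = np.sqrt(spec.reference_area_mm2 / np.pi) / sp
    ny, nx = section.image.shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    frac = section.labels[ref_label]
    yy, xx = np.mgrid[0:ny, 0:nx]
    vessel = section.labels["wall"] + section.labels["lumen"] + section.labels.get(
        "csf", np.zeros_like(frac)
    )
    vr = np.sqrt(((yy - cy) ** 2 + (xx - cx) ** 2))
    outer_px = np.max(vr[vessel > 0.05], initial=0.0)
    for clearance in (spec.reference_clearance_mm, spec.reference_clearance_mm + 2.0):
        dist_px = outer_px + clearance / sp + radius_px
        for ang in np.arange(0, 360, 45):
            oy = cy + dist_px * np.sin(np.deg2rad(ang))
            ox = cx + dist_px * np.cos(np.deg2rad(ang))
            if not (radius_px < oy < ny - radius_px and radius_px < ox < nx - radius_px):
                continue
            mask = (yy - oy) ** 2 + (xx - ox) ** 2 <= radius_px**2
            if frac[mask].mean() >= spec.reference_purity:
                return mask
    return None


def measure_rois(
    section: CrossSection,
    sequence_kind: str,
    subject_id: str = "subject0",
    spec: ROISpec | None = None,
) -> ROIMeasurement:
    """SNR/CNR measurement on one cross-section.

    Wall signal is averaged over the middle path of the wall ring (the
    skeleton of the eroded wall mask); lumen signal over the full lumen mask
    eroded one pixel from the wall boundary; sigma_n is the SD within a
    20 mm^2 disc in the adjacent reference tissue. For SNAP the (negative)
    lumen mean is sign-flipped. Empty ROIs yield a measurement marked
    excluded.
    """
    spec = spec or ROISpec()
    img = section.image
    wall_mask = section.labels["wall"] > spec.wall_fraction_threshold
    midpath = skeletonize(wall_mask)
    lumen_mask = ndimage.binary_erosion(
        section.labels["lumen"] > 0.5, iterations=spec.lumen_erosion_px
    )
    ref_label = "muscle" if segment_class(section.location) == "extracranial" else "white_matter"
    ref_mask = _reference_roi(section, ref_label, spec)
    if midpath.sum() == 0 or lumen_mask.sum() == 0 or ref_mask is None:
        return ROIMeasurement.missing(subject_id, sequence_kind, section.location, section.side)
    s_w = float(img[midpath].mean())
    s_l = float(img[lumen_mask].mean())
    if sequence_kind == "SNAP":
        s_l = -s_l  # negative-polarity lumen reported as positive
    sigma_n = float(img[ref_mask].std(ddof=1))
    snr_w = s_w / sigma_n
    snr_l = s_l / sigma_n
    cnr = snr_w + snr_l if sequence_kind == "SNAP" else snr_w - snr_l
    return ROIMeasurement(
        subject_id=subject_id,
        sequence=sequence_kind,
        location=section.location,
        side=section.side,
        s_w=s_w,
        s_l=s_l,
        sigma_n=sigma_n,
        snr_w=snr_w,
        snr_l=snr_l,
        cnr_w_l=cnr,
    )


def measure_volume(
    acq: AcquiredVolume,
    built: BuiltPhantom,
    scene=None,
    sequence_kind: str | None = None,
    sides: tuple = ("left", "right"),
    spec: ROISpec | None = None,
) -> list[ROIMeasurement]:
    """All bilateral waypoint measurements of one acquired volume.

    Locations marked occluded in the scene are returned as excluded
    measurements (mirroring subjects dropped from quantitative analysis).
    """
    scene = scene if scene is not None else built.scene
    kind = sequence_kind or acq.kind
    needed = ["wall", "lumen", "csf", "muscle", "white_matter"]
    label_volumes = {n: built.fractions[n] for n in needed}
    out = []
    for side in sides:
        cl = scene.centerline(side)
        for loc, wz in WAYPOINTS.items():
            if scene.occluded_location == loc:
                out.append(ROIMeasurement.missing(scene.subject_id, kind, loc, side))
                continue
            section = extract_section(
                acq.data, acq.affine, cl, wz, loc, side, label_volumes
            )
            out.append(measure_rois(section, kind, subject_id=scene.subject_id, spec=spec))
    return out


def measurements_to_frame(measurements: list[ROIMeasurement]) -> pd.DataFrame:
    return pd.DataFrame([asdict(m) for m in measurements])
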