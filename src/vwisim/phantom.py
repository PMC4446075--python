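"""Digital neurovascular phantom: geometry, acquisition simulation, cohorts.

The phantom stands in for patient scans: a bilateral tubular vessel (lumen +
wall) running foot-to-head through five named segments — common carotid
(CCA), carotid bifurcation (BULB), internal carotid C2 and C5, and middle
cerebral M1 — with a CSF sheath around the intracranial segments, muscle and
white-matter backgrounds, a two-source surface-coil gain field whose trough
sits at the mid-ICA (the segment farthest from both coils), segment-dependent
flow uniformity, and Rician noise on magnitude images.

Coordinates are RAS millimetres; array axes are (x = LR, y = AP, z = FH);
voxel indices are 0-based with voxel centers at (i + 0.5) * voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .params import TissueParams, FlowSpec, SequenceProtocol, default_tissue_table
from . import sequences as seqs

__all__ = [
    "SegmentSpec",
    "PhantomScene",
    "BuiltPhantom",
    "AcquiredVolume",
    "compact_scene",
    "full_scene",
    "build_phantom",
    "acquire",
    "synthetic_cohort",
    "calibrate_noise",
    "LABELS",
    "WAYPOINTS",
]

LABELS = {
    "background": 0,
    "muscle": 1,
    "white_matter": 2,
    "csf": 3,
    "wall": 4,
    "lumen": 5,
    "plaque_iph": 6,
    "plaque_loose_matrix": 7,
}

#: Locations used for quantification (waypoint FH position, mm).
WAYPOINTS = {"CCA": 30.0, "BULB": 70.0, "ICA_C2": 110.0, "ICA_C5": 160.0, "MCA_M1": 215.0}

#: FH position separating muscle (neck) from white-matter (head) background.
NECK_HEAD_BOUNDARY_MM = 80.0


@dataclass(frozen=True)
class SegmentSpec:
    """One named vessel segment with its geometry and flow."""

    name: str
    z_start_mm: float
    z_end_mm: float
    waypoint_z_mm: float
    lumen_radius_mm: float
    wall_thickness_mm: float
    csf_thickness_mm: float
    flow: FlowSpec

    def __post_init__(self) -> None:
        if self.lumen_radius_mm <= 0:
            raise ValueError(f"{self.name}: lumen radius must be > 0")
        if self.wall_thickness_mm <= 0:
            raise ValueError(f"{self.name}: wall thickness must be > 0")
        if self.csf_thickness_mm < 0:
            raise ValueError(f"{self.name}: csf thickness must be >= 0")


def default_segments() -> tuple[SegmentSpec, ...]:
    """Radii taper from CCA (3.0 mm) to MCA M1 (1.4 mm); recirculating flow
    (wide intravoxel spread, 0.9) at CCA/BULB versus more uniform flow (0.4)
    in the distal ICA/MCA; CSF sheath on the intracranial segments only."""
    return (
        SegmentSpec("CCA", 0, 60, 30, 3.0, 1.0, 0.0, FlowSpec(0.30, 0.9, (0, 0, 1), "complex")),
        SegmentSpec("BULB", 60, 80, 70, 3.6, 1.1, 0.0, FlowSpec(0.25, 0.9, (0, 0, 1), "complex")),
        SegmentSpec("ICA_C2", 80, 140, 110, 2.3, 0.8, 0.0, FlowSpec(0.35, 0.4, (0, 0, 1), "uniform")),
        SegmentSpec("ICA_C5", 140, 180, 160, 2.0, 0.7, 1.0, FlowSpec(0.35, 0.4, (0, 0, 1), "uniform")),
        SegmentSpec("MCA_M1", 180, 250, 215, 1.4, 0.5, 1.0, FlowSpec(0.40, 0.4, (0, 0, 1), "uniform")),
    )


@dataclass
class PhantomScene:
    """Full specification of one synthetic subject.

    ``noise_sigma`` maps sequence kind to the complex-noise floor sigma0; the
    local noise SD is sigma0 / gain, emulating the spatially varying noise of
    coil-combined images, so the measured SNR scales with gain^2.
    ``snr_scale`` is a per-subject global SNR factor (cohort jitter).
    """

    voxel_mm: float = 0.8
    fov_mm: tuple[float, float, float] = (64.0, 40.0, 250.0)  # (LR, AP, FH)
    side_offset_mm: float = 15.0
    segments: tuple[SegmentSpec, ...] = field(default_factory=default_segments)
    plaque_inserts: tuple = ()  # (location, tissue_name, angle_start_deg, angle_end_deg)
    csf_flow: FlowSpec = field(default_factory=lambda: FlowSpec(0.015, 1.0, (0, 0, 1), "complex"))
    coil_sources_mm: tuple = (((0.0, -40.0, 30.0), 1.0), ((0.0, 0.0, 225.0), 1.0))
    coil_scale_mm: float = 80.0
    noise_sigma: dict = field(default_factory=dict)
    snr_scale: float = 1.0
    # SNAP inflow bookkeeping: path-averaged transit velocity from the
    # inversion-coverage edge, and how far below the FOV that edge sits.
    snap_transit_velocity_m_per_s: float = 0.25
    snap_coverage_offset_mm: float = 200.0
    tissue_table: dict = field(default_factory=default_tissue_table)
    seed: int = 0
    subject_id: str = "subject0"
    occluded_location: str | None = None
    straight: bool = False  # axis-aligned straight tubes (analytic tests)

    def centerline(self, side: str, dz_mm: float = 0.25) -> pd.DataFrame:
        """Ordered centerline points (world mm) with segment names.

        Gentle in-plane bowing plus a lateral MCA bend; ``side`` is 'left'
        (-x) or 'right' (+x).
        """
        sgn = {"left": -1.0, "right": +1.0}[side]
        z = np.arange(0.0, self.fov_mm[2] + 1e-9, dz_mm)
        if self.straight:
            x = np.full(z.size, sgn * self.side_offset_mm)
            y = np.zeros(z.size)
        else:
            x = sgn * (self.side_offset_mm + 3.0 * np.sin(np.pi * z / self.fov_mm[2]))
            x = x + sgn * np.clip(z - 180.0, 0.0, None) * 0.10
            y = 3.0 * np.sin(np.pi * z / 125.0)
        seg = np.empty(z.size, dtype=object)
        for s in self.segments:
            seg[(z >= s.z_start_mm) & (z < s.z_end_mm + 1e-9)] = s.name
        seg[pd.isna(seg)] = self.segments[-1].name
        return pd.DataFrame({"x_mm": x, "y_mm": y, "z_mm": z, "segment_name": seg})

    def segment_nodes(self):
        zs = np.array([s.waypoint_z_mm for s in self.segments])
        r = np.array([s.lumen_radius_mm for s in self.segments])
        w = np.array([s.wall_thickness_mm for s in self.segments])
        c = np.array([s.csf_thickness_mm for s in self.segments])
        return zs, r, w, c

    def coil_gain(self, points_mm: np.ndarray) -> np.ndarray:
        """Smooth surface-coil sensitivity: sum of exponential falloffs from
        the neck and head coil sources."""
        p = np.atleast_2d(points_mm)
        g = np.zeros(p.shape[0])
        for src, amp in self.coil_sources_mm:
            d = np.linalg.norm(p - np.asarray(src), axis=1)
            g += amp * np.exp(-d / self.coil_scale_mm)
        return g

    def segment_by_name(self, name: str) -> SegmentSpec:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)


def compact_scene(seed: int = 0, **overrides) -> PhantomScene:
    """Default desk-scale scene: full 250 mm FH coverage, LR cropped to the
    64 mm band containing both carotids."""
    return PhantomScene(seed=seed, **overrides)


def full_scene(seed: int = 0, **overrides) -> PhantomScene:
    """Full-FOV scene matching the protocol's 250 x 160 x 40 mm coverage."""
    overrides.setdefault("fov_mm", (160.0, 40.0, 250.0))
    return PhantomScene(seed=seed, **overrides)


@dataclass
class BuiltPhantom:
    """Ground-truth fields of a built scene.

    ``fractions`` holds one partial-volume channel per label (sum = 1);
    ``label`` is the majority label; ``rho`` the lumen-normalized radial
    coordinate d / r_lumen; ``seg_index`` indexes into scene.segments;
    ``gain`` the coil sensitivity; ``z_mm`` the FH coordinate per voxel.
    """

    scene: PhantomScene
    fractions: dict
    label: np.ndarray
    seg_index: np.ndarray
    rho: np.ndarray
    gain: np.ndarray
    z_mm: np.ndarray
    shape: tuple

    def affine(self) -> np.ndarray:
        v = self.scene.voxel_mm
        a = np.diag([v, v, v, 1.0])
        a[0, 3] = -self.scene.fov_mm[0] / 2.0 + v / 2.0
        a[1, 3] = -self.scene.fov_mm[1] / 2.0 + v / 2.0
        a[2, 3] = v / 2.0
        return a

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine())
        p = np.atleast_2d(points_mm)
        return (p @ inv[:3, :3].T) + inv[:3, 3]

    def save_nifti(self, out_dir) -> None:
        import nibabel as nib
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        nib.save(nib.Nifti1Image(self.label.astype(np.int16), self.affine()), out / "labels.nii.gz")
        for side in ("left", "right"):
            self.scene.centerline(side).to_csv(out / f"centerline_{side}.csv", index=False)


def _grid_coords(scene: PhantomScene):
    v = scene.voxel_mm
    fx, fy, fz = scene.fov_mm
    nx, ny, nz = (int(round(f / v)) for f in (fx, fy, fz))
    xs = (np.arange(nx) + 0.5) * v - fx / 2.0
    ys = (np.arange(ny) + 0.5) * v - fy / 2.0
    zs = (np.arange(nz) + 0.5) * v
    return (nx, ny, nz), xs, ys, zs


def _classify(scene: PhantomScene, pts: np.ndarray, trees, cl_z, seg_of_point):
    """Shell label + radial info at arbitrary points."""
    zs_nodes, r_n, w_n, c_n = scene.segment_nodes()
    best_d = np.full(pts.shape[0], np.inf)
    best_idx = np.zeros(pts.shape[0], dtype=np.int64)
    for tree in trees:
        d, idx = tree.query(pts, workers=-1)
        better = d < best_d
        best_d[better] = d[better]
        best_idx[better] = idx[better]
    zc = cl_z[best_idx]
    r = np.interp(zc, zs_nodes, r_n)
    w = np.interp(zc, zs_nodes, w_n)
    c = np.interp(zc, zs_nodes, c_n)
    seg_idx = seg_of_point(zc)
    lab = np.where(
        pts[:, 2] < NECK_HEAD_BOUNDARY_MM, LABELS["muscle"], LABELS["white_matter"]
    ).astype(np.int8)
    lab[best_d < r + w + c] = LABELS["csf"]
    lab[best_d < r + w] = LABELS["wall"]
    lab[best_d < r] = LABELS["lumen"]
    for loc, tissue_name, a0, a1 in scene.plaque_inserts:
        s = scene.segment_by_name(loc)
        in_wall = (best_d >= r) & (best_d < r + w)
        near = np.abs(zc - s.waypoint_z_mm) < 5.0
        ang = np.degrees(np.arctan2(pts[:, 1], np.abs(pts[:, 0]) - scene.side_offset_mm))
        sector = (ang >= a0) & (ang <= a1)
        lab[in_wall & near & sector] = LABELS[tissue_name]
    rho = np.where(r > 0, best_d / r, np.inf)
    return lab, rho, seg_idx, best_d, r, w, c


def build_phantom(scene: PhantomScene, supersample: int = 4) -> BuiltPhantom:
    """Construct ground-truth label fractions and fields.

    Interface voxels (centers within one voxel size of a tissue boundary)
    are supersampled ``supersample``^3-fold to produce partial-volume
    fractions; interior voxels are assigned analytically. Deterministic
    given the scene.
    """
    shape, xs, ys, zs = _grid_coords(scene)
    cl = {side: scene.centerline(side) for side in ("left", "right")}
    zs_nodes, r_n, w_n, c_n = scene.segment_nodes()
    for side, df in cl.items():
        outer = np.interp(df.z_mm.values, zs_nodes, r_n + w_n + c_n)
        for wp_name, wz in WAYPOINTS.items():
            i = int(np.argmin(np.abs(df.z_mm.values - wz)))
            if (
                abs(df.x_mm.values[i]) + outer[i] > scene.fov_mm[0] / 2.0
                or abs(df.y_mm.values[i]) + outer[i] > scene.fov_mm[1] / 2.0
            ):
                raise ValueError(f"vessel tube exits the grid near waypoint {wp_name} ({side})")
    pts_cl = [df[["x_mm", "y_mm", "z_mm"]].to_numpy() for df in cl.values()]
    trees = [cKDTree(p) for p in pts_cl]
    cl_z = pts_cl[0][:, 2]  # same z sampling on both sides

    seg_starts = np.array([s.z_start_mm for s in scene.segments])

    def seg_of_point(zc):
        return np.clip(np.searchsorted(seg_starts, zc, side="right") - 1, 0, len(seg_starts) - 1)

    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    lab, rho, seg_idx, d, r, w, c = _classify(scene, pts, trees, cl_z, seg_of_point)

    n_lab = len(LABELS)
    frac = np.zeros((n_lab, pts.shape[0]), dtype=np.float32)
    frac[lab, np.arange(pts.shape[0])] = 1.0

    bdist = np.min(np.abs(d[:, None] - np.column_stack([r, r + w, r + w + c])), axis=1)
    iface = bdist < scene.voxel_mm * 0.9
    if np.any(iface):
        s = supersample
        off = (np.arange(s) + 0.5) / s - 0.5
        ox, oy, oz = np.meshgrid(off, off, off, indexing="ij")
        offsets = np.column_stack([ox.ravel(), oy.ravel(), oz.ravel()]) * scene.voxel_mm
        ip = pts[iface]
        sub = (ip[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
        sub_lab = _classify(scene, sub, trees, cl_z, seg_of_point)[0]
        sub_lab = sub_lab.reshape(ip.shape[0], offsets.shape[0])
        counts = np.stack([(sub_lab == k).sum(axis=1) for k in range(n_lab)]).astype(np.float32)
        frac[:, iface] = counts / offsets.shape[0]

    fractions = {name: frac[code].reshape(shape) for name, code in LABELS.items()}
    return BuiltPhantom(
        scene=scene,
        fractions=fractions,
        label=lab.reshape(shape),
        seg_index=np.asarray(seg_idx).reshape(shape).astype(np.int8),
        rho=rho.reshape(shape).astype(np.float32),
        gain=scene.coil_gain(pts).reshape(shape).astype(np.float32),
        z_mm=Z.astype(np.float32),
        shape=shape,
    )


# ---------------------------------------------------------------------------
# Acquisition


@dataclass
class AcquiredVolume:
    """One simulated acquisition: image data plus provenance."""

    data: np.ndarray  # magnitude (MERGE/VISTA) or signed corrected-real (SNAP)
    kind: str
    voxel_mm: float
    affine: np.ndarray
    noiseless: np.ndarray  # ideal signal x gain, no noise
    sigma0: float

    def save_nifti(self, path) -> None:
        import nibabel as nib

        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), str(path))


def _lumen_flow_factor(built: BuiltPhantom, m1: float) -> np.ndarray:
    """Per-voxel dephasing factor of lumen blood.

    Poiseuille-like radial profile: voxel velocity 2 v_seg (1 - rho^2) with
    the segment's intravoxel spread; near-wall voxels are slow and therefore
    incompletely dephased, which is what leaves the measurable lumen
    residual.
    """
    from .params import GAMMA_RAD_PER_S_PER_T

    scene = built.scene
    v_seg = np.array([s.flow.mean_velocity_m_per_s for s in scene.segments])
    d_seg = np.array([s.flow.intravoxel_spread_fraction for s in scene.segments])
    v = 2.0 * v_seg[built.seg_index] * np.clip(1.0 - built.rho.astype(float) ** 2, 0.0, None)
    delta = d_seg[built.seg_index]
    half = GAMMA_RAD_PER_S_PER_T * m1 * 1e-9 * v * delta
    out = np.ones_like(half)
    nz = half > 0
    out[nz] = np.abs(np.sin(half[nz]) / half[nz])
    return out


def _signal_fields(built: BuiltPhantom, protocol: SequenceProtocol, table: dict):
    """Noiseless per-voxel signal (and for SNAP the IR/reference pair)."""
    scene = built.scene
    shape = built.shape
    kind = protocol.kind
    sig = np.zeros(shape)
    ref_sig = np.zeros(shape) if kind == "SNAP" else None
    for name in LABELS:
        fracs = built.fractions[name]
        if name == "background" or not np.any(fracs):
            continue
        tissue_name = "blood" if name == "lumen" else name
        if tissue_name not in table:
            raise KeyError(f"tissue table is missing an entry for label {name!r}")
        tissue = table[tissue_name]
        if kind == "MERGE":
            prep = protocol.prep_duration_ms or seqs.merge_prep_duration(
                protocol.m1_mT_ms2_per_m or 0.0
            )
            base = (
                tissue.proton_density
                * np.sin(np.deg2rad(protocol.flip_deg))
                * np.exp(-prep / tissue.t2_ms)
            )
            if name == "lumen":
                factor = _lumen_flow_factor(built, protocol.m1_mT_ms2_per_m or 0.0)
            elif name == "csf":
                factor = seqs.flow_dephasing_factor(scene.csf_flow, protocol.m1_mT_ms2_per_m or 0.0)
            else:
                factor = 1.0
            sig += fracs * base * factor
        elif kind == "VISTA":
            _, center = seqs.vista_signal(tissue, FlowSpec(), protocol)
            if name == "lumen":
                factor = _lumen_flow_factor(built, protocol.fsd_m1_mT_ms2_per_m or 0.0)
            else:
                factor = 1.0
            sig += fracs * center * factor
        elif kind == "SNAP":
            sin_ir = np.sin(np.deg2rad(protocol.flip_deg))
            sin_ref = np.sin(np.deg2rad(protocol.reference_flip_deg or protocol.flip_deg))
            if name == "lumen":
                blood = table["blood"] if "blood" in table else tissue
                if protocol.inversion_mode == "selective":
                    mz = np.ones(shape)
                else:
                    dist = built.z_mm.astype(float) + scene.snap_coverage_offset_mm
                    transit_ms = dist / scene.snap_transit_velocity_m_per_s
                    n_cycles = 1 + (transit_ms // protocol.ir_tr_ms).astype(int)
                    e_irtr = np.exp(-protocol.ir_tr_ms / blood.t1_ms)
                    e_ti = np.exp(-protocol.ti_ms / blood.t1_ms)
                    eta = protocol.inversion_efficiency
                    mz_pre = np.ones(shape)
                    extra = n_cycles - 1
                    for k in range(1, int(extra.max()) + 1):
                        sel = extra >= k
                        mz_pre[sel] = 1.0 + (-eta * mz_pre[sel] - 1.0) * e_irtr
                    mz = 1.0 + (-eta * mz_pre - 1.0) * e_ti
                mz_ref = seqs.snap_longitudinal_cycle(blood, protocol).mz_reference
                sig += fracs * tissue.proton_density * sin_ir * mz
                ref_sig += fracs * tissue.proton_density * sin_ref * mz_ref
            else:
                cyc = seqs.snap_longitudinal_cycle(tissue, protocol)
                sig += fracs * tissue.proton_density * sin_ir * cyc.mz_ti
                ref_sig += fracs * tissue.proton_density * sin_ref * cyc.mz_reference
    return sig, ref_sig


def acquire(
    built: BuiltPhantom,
    protocol: SequenceProtocol,
    tissue_table: dict | None = None,
    seed: int = 0,
    noiseless: bool = False,
) -> AcquiredVolume:
    """Simulate one acquisition of the built phantom.

    The ideal voxel signal is the fraction-weighted sum of per-tissue
    sequence signals (flow-aware for lumen and CSF) times the coil gain.
    Complex Gaussian noise of SD sigma0 / gain / sqrt(averages) is added in
    quadrature; MERGE/VISTA return the magnitude (Rician noise), SNAP the
    phase-corrected real reconstruction of its IR/reference pair.
    """
    scene = built.scene
    table = tissue_table if tissue_table is not None else scene.tissue_table
    sig, ref_sig = _signal_fields(built, protocol, table)
    # lumen label maps to blood relaxation parameters
    gain = built.gain.astype(float)
    ideal = sig * gain
    sigma0 = float(scene.noise_sigma.get(protocol.kind, 0.0)) / scene.snr_scale
    kind_tag = {"MERGE": 1, "VISTA": 2, "SNAP": 3}[protocol.kind]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), kind_tag]))
    sigma_map = sigma0 / gain / np.sqrt(protocol.averages)
    # smooth background phase common to the object; removed by the
    # phase-sensitive recon for SNAP, irrelevant for magnitude images
    phase = np.exp(1j * (0.3 + 0.002 * built.z_mm.astype(float)))

    def complex_noise():
        if noiseless or sigma0 == 0:
            return 0.0
        return (
            rng.standard_normal(built.shape) + 1j * rng.standard_normal(built.shape)
        ) * sigma_map

    if protocol.kind in ("MERGE", "VISTA"):
        img = np.abs(ideal * phase + complex_noise())
        return AcquiredVolume(img, protocol.kind, scene.voxel_mm, built.affine(), ideal, sigma0)
    ir = ideal * phase + complex_noise()
    ref = (ref_sig * gain) * phase + complex_noise()
    corrected, _ = seqs.phase_sensitive_recon(ir, ref)
    return AcquiredVolume(corrected, "SNAP", scene.voxel_mm, built.affine(), ideal, sigma0)


# ---------------------------------------------------------------------------
# Noise calibration and cohorts


#: Pooled wall SNR anchors per sequence used to calibrate the generator's
#: noise floors to the reference patient study.
SNR_W_TARGETS = {"MERGE": 19.07, "VISTA": 20.64, "SNAP": 10.96}


def reformat_noise_factor(built: BuiltPhantom, seed: int = 20250101) -> float:
    """SD reduction of white noise under the cross-section reformatting.

    Trilinear resampling to the finer in-plane grid and 0.5 mm through-plane
    averaging correlate and shrink voxel noise; the factor is measured once
    by pushing a fixed-seed unit-variance volume through the same resampler.
    """
    from .quantify import extract_section

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(built.shape)
    cl = built.scene.centerline("right")
    sds = []
    for wz in WAYPOINTS.values():
        sec = extract_section(noise, built.affine(), cl, wz, "CCA", "right")
        sds.append(sec.image.std())
    return float(np.mean(sds))


def calibrate_noise(
    scene: PhantomScene,
    protocols: dict[str, SequenceProtocol],
    targets: dict[str, float] = SNR_W_TARGETS,
    built: BuiltPhantom | None = None,
) -> dict[str, float]:
    """Noise floors mapping the measured wall signal onto the target pooled
    wall SNR.

    Runs one noiseless acquisition per sequence through the actual ROI
    pipeline, so the calibration accounts for partial-volume dilution of the
    wall midpath; the reformatting's noise-SD shrink factor is measured on a
    fixed-seed white-noise volume. The measured pooled SNR_w of a noisy
    acquisition then lands near the target by construction, while all
    ratios (lumen vs wall, across locations, across sequences) remain
    emergent. Deterministic.
    """
    from .quantify import measure_volume

    if built is None:
        built = build_phantom(scene)
    kappa = reformat_noise_factor(built)
    cl = scene.centerline("right")
    wp_pts = []
    for wz in WAYPOINTS.values():
        i = int(np.argmin(np.abs(cl.z_mm.values - wz)))
        wp_pts.append(cl[["x_mm", "y_mm", "z_mm"]].to_numpy()[i])
    g_wp = scene.coil_gain(np.array(wp_pts))
    out = {}
    for kind, proto in protocols.items():
        acq = acquire(built, proto, seed=0, noiseless=True)
        meas = measure_volume(acq, built, sides=("right",))
        s_w = np.array([m.s_w for m in meas if not m.excluded])
        if kind == "SNAP":
            s_w = np.abs(s_w)
        # measured SNR at a waypoint = s_w / (kappa * sigma0 / g / sqrt(avg))
        out[kind] = float(
            np.mean(s_w * g_wp[: s_w.size]) * np.sqrt(proto.averages) / (kappa * targets[kind])
        )
    return out


def synthetic_cohort(
    n_subjects: int,
    seed: int = 0,
    radius_jitter: float = 0.10,
    thickness_jitter: float = 0.10,
    snr_jitter: float = 0.30,
    occlusion_probability: float = 0.08,
    scene_factory=compact_scene,
    protocols: dict | None = None,
    noise_sigma: dict | None = None,
) -> list[PhantomScene]:
    """Per-subject scenes jittered around the default anatomy.

    Radii and wall thickness get lognormal multiplicative jitter; a global
    lognormal SNR factor emulates between-subject coil loading and noise;
    each subject may be marked occluded at one random location (excluded
    from quantitative analysis downstream). Per-subject seeds derive
    deterministically from the master seed.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    from .params import default_protocols

    protocols = protocols or default_protocols()
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    base = scene_factory(seed=seed)
    base_sigma = noise_sigma if noise_sigma is not None else calibrate_noise(base, protocols)
    scenes = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        r_f = float(np.exp(rng.normal(0.0, radius_jitter))) if radius_jitter > 0 else 1.0
        w_f = float(np.exp(rng.normal(0.0, thickness_jitter))) if thickness_jitter > 0 else 1.0
        # mean-one lognormal so the cohort-average SNR stays on calibration
        snr_f = (
            float(np.exp(rng.normal(-0.5 * snr_jitter**2, snr_jitter))) if snr_jitter > 0 else 1.0
        )
        segs = tuple(
            replace(
                s,
                lumen_radius_mm=s.lumen_radius_mm * r_f,
                wall_thickness_mm=s.wall_thickness_mm * w_f,
            )
            for s in base.segments
        )
        occluded = None
        if rng.random() < occlusion_probability:
            occluded = str(rng.choice(list(WAYPOINTS.keys())))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        scenes.append(
            replace(
                base,
                segments=segs,
                snr_scale=snr_f,
                noise_sigma=dict(base_sigma),
                seed=sub_seed,
                subject_id=f"subject{i:02d}",
                occluded_location=occluded,
            )
        )
    return scenes
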