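"""Cross-section reformatting geometry and ROI SNR/CNR conventions."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from vwisim.params import merge_protocol, snap_protocol
from vwisim.phantom import acquire, build_phantom, compact_scene
from vwisim.quantify import (
    CrossSection,
    ROIMeasurement,
    extract_section,
    measure_rois,
    measure_volume,
    measurements_to_frame,
    segment_class,
)


def _oblique_cylinder_volume(angle_deg, radius=3.0, voxel=0.8, half=16.0, length=60.0):
    """Partial-volume lumen fractions of a cylinder tilted in the x-z plane,
    plus its centerline; analytic ground truth for reformatting tests."""
    n = int(round(2 * half / voxel))
    nz = int(round(length / voxel))
    xs = (np.arange(n) + 0.5) * voxel - half
    ys = xs.copy()
    zs = (np.arange(nz) + 0.5) * voxel
    a = np.deg2rad(angle_deg)
    axis = np.array([np.sin(a), 0.0, np.cos(a)])
    p0 = np.array([0.0, 0.0, length / 2]) - axis * length
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    frac = np.zeros_like(X)
    s = 4
    off = ((np.arange(s) + 0.5) / s - 0.5) * voxel
    for dx in off:
        for dy in off:
            for dz in off:
                p = np.stack([X + dx, Y + dy, Z + dz], axis=-1) - p0
                t = p @ axis
                d2 = np.sum(p**2, axis=-1) - t**2
                frac += d2 < radius**2
    frac /= s**3
    affine = np.diag([voxel, voxel, voxel, 1.0])
    affine[:3, 3] = [-half + voxel / 2, -half + voxel / 2, voxel / 2]
    t_line = np.linspace(0, 2 * length, 400)
    pts = p0[None, :] + t_line[:, None] * axis[None, :]
    cl = pd.DataFrame({"x_mm": pts[:, 0], "y_mm": pts[:, 1], "z_mm": pts[:, 2],
                       "segment_name": "CCA"})
    return frac, affine, cl


class TestReformat:
    def test_axis_aligned_section_equals_native_slice(self):
        """A z-invariant volume reformatted along z reproduces the axial
        values exactly (through-plane averaging sees identical slices)."""
        frac, affine, cl = _oblique_cylinder_volume(0.0)
        sec = extract_section(frac, affine, cl, 30.0, "CCA", "right")
        k = int(round(30.0 / 0.8 - 0.5))
        # compare against direct bilinear sampling of the native slice
        assert abs(sec.image.max() - 1.0) < 1e-6
        mid = sec.image[sec.image.shape[0] // 2]
        native = frac[:, frac.shape[1] // 2, k]
        assert abs(mid.max() - native.max()) < 1e-6

    @pytest.mark.parametrize("angle", [30.0, 45.0])
    def test_oblique_tube_area_recovered(self, angle):
        """The reformatted cross-section recovers the analytic circle area to
        < 3%, where the native axial slice would see a 1/cos(angle)
        elongated ellipse."""
        frac, affine, cl = _oblique_cylinder_volume(angle)
        sec = extract_section(frac, affine, cl, 24.0, "CCA", "right",
                              label_volumes={"lumen": frac})
        measured = sec.area_mm2("lumen")
        analytic = np.pi * 3.0**2
        assert measured == pytest.approx(analytic, rel=0.03)
        # native-slice ellipse check: area inflated by ~1/cos(angle)
        k = int(round(24.0 / 0.8 - 0.5))
        native_area = frac[:, :, k].sum() * 0.8**2
        assert native_area > analytic * (1.0 / np.cos(np.deg2rad(angle))) * 0.9

    def test_reversed_tangent_gives_flipped_section(self):
        frac, affine, cl = _oblique_cylinder_volume(45.0)
        sec = extract_section(frac, affine, cl, 24.0, "CCA", "right")
        rev = extract_section(frac, affine, cl, 24.0, "CCA", "right", flip_tangent=True)
        assert sec.image.sum() == pytest.approx(rev.image.sum(), rel=1e-6)
        assert np.allclose(np.sort(sec.image.ravel()), np.sort(rev.image.ravel()), atol=1e-9)

    def test_waypoint_outside_volume_rejected(self):
        frac, affine, cl = _oblique_cylinder_volume(0.0)
        bad_cl = cl.copy()
        with pytest.raises(ValueError):
            extract_section(frac, affine, bad_cl.iloc[:0], 30.0, "CCA", "right")


class TestMeasureROIs:
    def test_snr_arithmetic_and_snap_cnr_rule(self):
        """CNR is SNR_w + SNR_l for the signed SNAP images: with wall at
        10.96 sigma and lumen at -17.79 sigma the contrast is 28.75."""
        rng = np.random.default_rng(0)
        n = 96
        yy, xx = np.mgrid[0:n, 0:n]
        c = (n - 1) / 2
        r = np.hypot(yy - c, xx - c) * 0.4
        sigma = 1.0
        img = np.where(r < 3.0, -17.79, np.where(r < 4.0, 10.96, 0.05))
        img = img + rng.normal(0, 1e-9, img.shape)  # noiseless up to epsilon
        labels = {
            "wall": ((r >= 3.0) & (r < 4.0)).astype(float),
            "lumen": (r < 3.0).astype(float),
            "csf": np.zeros_like(img),
            "white_matter": (r >= 4.0).astype(float),
            "muscle": np.zeros_like(img),
        }
        sec = CrossSection(img, labels, "ICA_C2", "right", np.zeros(3), np.array([0, 0, 1.0]), 0.4)
        m = measure_rois(sec, "SNAP")
        # noiseless sigma is ~1e-9, so check the ROI means and the CNR rule
        assert m.s_w == pytest.approx(10.96, rel=1e-6)
        assert m.s_l == pytest.approx(17.79, rel=1e-6)  # sign-flipped
        assert m.cnr_w_l == pytest.approx(m.snr_w + m.snr_l)
        assert m.snr_w * m.sigma_n == pytest.approx(m.s_w)

    def test_zero_lumen_signal_cnr_equals_wall_snr(self):
        n = 96
        yy, xx = np.mgrid[0:n, 0:n]
        r = np.hypot(yy - (n - 1) / 2, xx - (n - 1) / 2) * 0.4
        rng = np.random.default_rng(1)
        img = np.where(r < 3.0, 0.0, np.where(r < 4.0, 5.0, 1.0)) + rng.normal(0, 0.1, (n, n))
        labels = {
            "wall": ((r >= 3.0) & (r < 4.0)).astype(float),
            "lumen": (r < 3.0).astype(float),
            "csf": np.zeros_like(img),
            "muscle": (r >= 4.0).astype(float),
            "white_matter": np.zeros_like(img),
        }
        sec = CrossSection(img, labels, "CCA", "left", np.zeros(3), np.array([0, 0, 1.0]), 0.4)
        m = measure_rois(sec, "MERGE")
        assert m.cnr_w_l == pytest.approx(m.snr_w - m.snr_l)
        assert abs(m.snr_l) < 0.5  # lumen is noise-only

    def test_global_scaling_invariance(self):
        n = 96
        yy, xx = np.mgrid[0:n, 0:n]
        r = np.hypot(yy - (n - 1) / 2, xx - (n - 1) / 2) * 0.4
        rng = np.random.default_rng(2)
        img = np.where(r < 3.0, 0.5, np.where(r < 4.0, 5.0, 1.0)) + rng.normal(0, 0.2, (n, n))
        labels = {
            "wall": ((r >= 3.0) & (r < 4.0)).astype(float),
            "lumen": (r < 3.0).astype(float),
            "csf": np.zeros_like(img),
            "muscle": (r >= 4.0).astype(float),
            "white_matter": np.zeros_like(img),
        }
        sec = CrossSection(img, labels, "CCA", "left", np.zeros(3), np.array([0, 0, 1.0]), 0.4)
        m1 = measure_rois(sec, "MERGE")
        sec3 = dataclasses.replace(sec, image=img * 3.0)
        m3 = measure_rois(sec3, "MERGE")
        assert m3.snr_w == pytest.approx(m1.snr_w)
        assert m3.snr_l == pytest.approx(m1.snr_l)
        assert m3.cnr_w_l == pytest.approx(m1.cnr_w_l)

    def test_empty_roi_marks_measurement_missing(self):
        n = 48
        img = np.zeros((n, n))
        labels = {k: np.zeros((n, n)) for k in ("wall", "lumen", "csf", "muscle", "white_matter")}
        sec = CrossSection(img, labels, "CCA", "left", np.zeros(3), np.array([0, 0, 1.0]), 0.4)
        m = measure_rois(sec, "MERGE")
        assert m.excluded
        assert np.isnan(m.snr_w)

    def test_segment_class_mapping(self):
        assert segment_class("CCA") == "extracranial"
        assert segment_class("BULB") == "extracranial"
        for loc in ("ICA_C2", "ICA_C5", "MCA_M1"):
            assert segment_class(loc) == "intracranial"


class TestPipelineRecovery:
    def test_noiseless_wall_signal_recovered(self, built_default, protocols):
        """On noiseless images the measured wall signal matches the
        ground-truth wall signal x gain at the waypoint to a few percent
        (partial-volume-eroded ROI)."""
        from vwisim.sequences import merge_center_signal
        from vwisim.params import FlowSpec

        acq = acquire(built_default, protocols["MERGE"], noiseless=True)
        meas = measure_volume(acq, built_default, sides=("right",))
        truth_sig = merge_center_signal(
            built_default.scene.tissue_table["wall"], FlowSpec(), protocols["MERGE"]
        )
        cl = built_default.scene.centerline("right")
        from vwisim.phantom import WAYPOINTS

        for m in meas:
            if m.location == "MCA_M1":
                continue  # wall thinner than a voxel: dilution expected
            i = int(np.argmin(np.abs(cl.z_mm.values - WAYPOINTS[m.location])))
            gain = built_default.scene.coil_gain(
                cl[["x_mm", "y_mm", "z_mm"]].to_numpy()[i]
            )[0]
            assert m.s_w == pytest.approx(truth_sig * gain, rel=0.25)

    def test_measurement_unbiased_over_noise_replicates(self, built_default, protocols):
        """Mean measured wall SNR over noisy replicates is within 2 standard
        errors of the noiseless measurement divided by the local noise SD."""
        from vwisim.phantom import WAYPOINTS
        from vwisim.quantify import extract_section, measure_rois

        proto = protocols["MERGE"]
        built = built_default
        scene = built.scene
        cl = scene.centerline("right")
        label_volumes = {n: built.fractions[n] for n in
                         ("wall", "lumen", "csf", "muscle", "white_matter")}
        noiseless = acquire(built, proto, noiseless=True)
        sec0 = extract_section(noiseless.data, noiseless.affine, cl, 30.0, "CCA", "right",
                               label_volumes)
        m0 = measure_rois(sec0, "MERGE")
        vals = []
        for rep in range(60):
            acq = acquire(built, proto, seed=1000 + rep)
            sec = extract_section(acq.data, acq.affine, cl, 30.0, "CCA", "right", label_volumes)
            m = measure_rois(sec, "MERGE")
            vals.append(m.snr_w)
        vals = np.asarray(vals)
        # reference: noiseless wall signal over the mean measured noise SD
        sigma_meas = np.mean(
            [measure_rois(extract_section(acquire(built, proto, seed=2000 + r).data,
                                          noiseless.affine, cl, 30.0, "CCA", "right",
                                          label_volumes), "MERGE").sigma_n
             for r in range(10)]
        )
        expected = m0.s_w / sigma_meas
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - expected) < 2.0 * se + 0.02 * expected

    def test_occluded_location_excluded(self, protocols):
        scene = compact_scene(seed=2, occluded_location="ICA_C5")
        built = build_phantom(scene)
        acq = acquire(built, protocols["MERGE"], noiseless=True)
        meas = measure_volume(acq, built)
        flags = {m.location: m.excluded for m in meas}
        assert flags["ICA_C5"]
        df = measurements_to_frame(meas)
        assert df.loc[df.location == "ICA_C5", "excluded"].all()
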