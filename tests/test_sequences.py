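"""Closed forms, numeric oracles and trend properties of the sequence models."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vwisim.params import (
    GAMMA_RAD_PER_S_PER_T,
    FlowSpec,
    TissueParams,
    merge_protocol,
    snap_protocol,
    vista_protocol,
)
from vwisim import sequences as sq


class TestFlowDephasing:
    def test_no_encoding_no_attenuation(self, wall):
        flow = FlowSpec(0.5, 0.8)
        assert sq.flow_dephasing_factor(flow, 0.0) == 1.0
        prep = 17.0
        assert sq.imsde_attenuation(wall, flow, 0.0, prep) == pytest.approx(
            np.exp(-prep / wall.t2_ms)
        )

    def test_coherent_phase_arithmetic(self):
        """1000 mT*ms^2/m at 0.01 m/s gives ~2.675 rad per-voxel phase but no
        attenuation when the intravoxel spread is zero."""
        flow = FlowSpec(0.01, 0.0)
        phase = GAMMA_RAD_PER_S_PER_T * 1000e-9 * 0.01
        assert phase == pytest.approx(2.675)
        assert sq.flow_dephasing_factor(flow, 1000.0) == 1.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        v=st.floats(0.0, 1.0),
        delta=st.floats(0.0, 1.0),
        m1=st.floats(0.0, 2000.0),
    )
    def test_factor_bounded(self, v, delta, m1):
        f = sq.flow_dephasing_factor(FlowSpec(v, delta), m1)
        assert 0.0 <= f <= 1.0

    def test_sinc_matches_quadrature_oracle(self):
        """Uniform-velocity expectation against direct numeric integration
        over 1e5 velocity samples."""
        for v, delta, m1 in [(0.1, 0.4, 500.0), (0.3, 0.9, 1000.0), (0.02, 1.0, 1500.0)]:
            n = 100_000  # midpoint rule over the uniform velocity density
            vs = v * (1 - delta) + (np.arange(n) + 0.5) / n * 2 * v * delta
            phases = GAMMA_RAD_PER_S_PER_T * m1 * 1e-9 * vs
            oracle = abs(np.mean(np.exp(1j * phases)))
            got = sq.flow_dephasing_factor(FlowSpec(v, delta), m1)
            assert got == pytest.approx(oracle, abs=1e-6)

    def test_more_encoding_more_suppression(self):
        flow = FlowSpec(0.05, 0.5)
        assert sq.flow_dephasing_factor(flow, 1500.0) <= sq.flow_dephasing_factor(flow, 500.0)

    def test_negative_moment_rejected(self, wall):
        with pytest.raises(ValueError):
            sq.flow_dephasing_factor(FlowSpec(0.1, 0.5), -1.0)


class TestPrepDuration:
    def test_strictly_increasing_in_m1(self):
        m1s = [250.0, 500.0, 1000.0, 1500.0, 3000.0]
        durs = [sq.merge_prep_duration(m) for m in m1s]
        assert np.all(np.diff(durs) > 0)

    def test_relaxed_gradient_cap_never_longer(self):
        for m1 in (500.0, 1000.0, 1500.0):
            assert sq.merge_prep_duration(m1, max_gradient_mT_per_m=40.0) <= sq.merge_prep_duration(
                m1, max_gradient_mT_per_m=20.0
            )

    def test_waveform_moment_matches_numeric_integral(self):
        """Closed-form trapezoid moment against the numeric integral of the
        sampled waveform, including the rectangular (infinite-slew) limit."""
        for m1, slew in [(1000.0, 100.0), (500.0, 100.0), (1000.0, 1e9)]:
            lobes = sq.design_bipolar(m1, 20.0, slew)
            t, g = lobes.waveform(dt_ms=5e-4)
            numeric = abs(np.trapezoid(g * t, t))
            assert numeric == pytest.approx(m1, rel=1e-4)
            assert lobes.first_moment == pytest.approx(m1, rel=1e-9)

    def test_zero_moment_returns_rf_overhead(self):
        assert sq.merge_prep_duration(0.0) == sq.IMSDE_RF_OVERHEAD_MS


class TestMergeSignal:
    def test_zero_flip_zero_signal(self, wall):
        p = merge_protocol(flip_deg=1e-12)
        assert sq.merge_center_signal(wall, FlowSpec(), p) == pytest.approx(0.0, abs=1e-12)

    def test_static_tissue_factorization(self, wall):
        """With no flow encoding the center signal reduces to
        exp(-prep/T2) * PD * sin(alpha)."""
        prep = 12.0
        p = merge_protocol(m1_mT_ms2_per_m=0.0, prep_duration_ms=prep)
        got = sq.merge_center_signal(wall, FlowSpec(), p)
        assert got == pytest.approx(
            np.exp(-prep / wall.t2_ms) * np.sin(np.deg2rad(p.flip_deg))
        )

    def test_wall_blood_contrast_at_protocol_settings(self, wall):
        blood = TissueParams(1660.0, 150.0, 1.0, "blood")
        p = merge_protocol(m1_mT_ms2_per_m=1000.0)
        s_wall = sq.merge_center_signal(wall, FlowSpec(), p)
        s_blood = sq.merge_center_signal(blood, FlowSpec(0.3, 0.9), p)
        assert s_wall / s_blood > 2.0

    def test_wrong_kind_rejected(self, wall):
        with pytest.raises(ValueError):
            sq.merge_center_signal(wall, FlowSpec(), vista_protocol())


class TestVistaSignal:
    def test_cpmg_limit_center_equals_t2_decay(self, wall):
        p = vista_protocol(flip_deg=180.0, n_startup=0)
        echoes, center = sq.vista_signal(wall, FlowSpec(), p)
        idx = sq.center_echo_index(p.turbo_factor)
        te_eff = p.esp_first_ms + (idx - 1) * p.esp_rest_ms
        assert center == pytest.approx(np.exp(-te_eff / wall.t2_ms), rel=1e-9)

    def test_reduced_flip_beats_pure_t2_decay(self, wall):
        """The pseudo-steady train stores magnetization along z, so the
        center echo exceeds exp(-TE_eff/T2) — the equivalent-TE effect."""
        p = vista_protocol()
        _, center = sq.vista_signal(wall, FlowSpec(), p)
        assert center > np.exp(-255.0 / wall.t2_ms)

    def test_rfa_late_train_dominates_vfa(self, wall):
        p = vista_protocol()
        e_rfa, _ = sq.vista_signal(wall, FlowSpec(), p, "RFA")
        e_vfa, _ = sq.vista_signal(wall, FlowSpec(), p, "VFA")
        assert np.all(e_rfa[100:] >= e_vfa[100:] - 1e-12)

    def test_vfa_center_exceeds_rfa(self, wall):
        """The constant-signal VFA plateau holds the center echo above the
        decaying RFA train (the RFA scheme trades SNR for edge sharpness)."""
        p = vista_protocol()
        _, c_rfa = sq.vista_signal(wall, FlowSpec(), p, "RFA")
        _, c_vfa = sq.vista_signal(wall, FlowSpec(), p, "VFA")
        assert c_vfa > c_rfa

    def test_center_monotone_in_te_eff(self, wall):
        p = vista_protocol()
        echoes, _ = sq.vista_signal(wall, FlowSpec(), p)
        centers = [echoes[i] for i in (40, 64, 90, 120)]
        assert np.all(np.diff(centers) < 0)

    def test_unknown_scheme_rejected(self, wall):
        with pytest.raises(ValueError):
            sq.vista_signal(wall, FlowSpec(), vista_protocol(), "XFA")

    def test_equivalent_te_diagnostic(self, wall):
        p = vista_protocol()
        _, center = sq.vista_signal(wall, FlowSpec(), p)
        te_eq = sq.equivalent_te(center, wall)
        assert 0 < te_eq < 255.0


class TestSnapCycle:
    def test_single_cycle_closed_form(self, wall):
        p = snap_protocol()
        res = sq.snap_longitudinal_cycle(wall, p, n_cycles=1)
        assert res.mz_ti == pytest.approx(1.0 - 2.0 * np.exp(-p.ti_ms / wall.t1_ms), rel=1e-12)

    def test_null_at_t1_ln2(self):
        t1 = 1000.0
        p = snap_protocol(ti_ms=t1 * np.log(2.0))
        res = sq.snap_longitudinal_cycle(TissueParams(t1, 80.0), p, n_cycles=1)
        assert res.mz_ti == pytest.approx(0.0, abs=1e-12)

    def test_short_t1_full_recovery(self):
        p = snap_protocol()
        res = sq.snap_longitudinal_cycle(TissueParams(0.5, 0.4), p, n_cycles=1)
        assert res.mz_ti == pytest.approx(1.0, abs=1e-3)

    def test_steady_state_matches_50_cycle_iteration(self, wall):
        p = snap_protocol()
        exact = sq.snap_longitudinal_cycle(wall, p)
        iterated = sq.snap_longitudinal_cycle(wall, p, n_cycles=50)
        assert abs(exact.mz_ti - iterated.mz_ti) < 1e-8

    def test_steady_state_independent_of_initialization(self, wall):
        p = snap_protocol()
        a = sq.snap_longitudinal_cycle(wall, p, n_cycles=60, m_initial=1.0)
        b = sq.snap_longitudinal_cycle(wall, p, n_cycles=60, m_initial=-1.0)
        assert abs(a.mz_ti - b.mz_ti) < 1e-8

    def test_ti_must_fit_cycle(self, wall):
        with pytest.raises(ValueError):
            snap_protocol(ti_ms=2000.0)  # >= IRTR
        p = snap_protocol(ti_ms=1500.0)  # readout no longer fits
        with pytest.raises(ValueError):
            sq.snap_longitudinal_cycle(wall, p)

    def test_mz_bounded(self):
        p = snap_protocol()
        for t1, t2 in [(300.0, 80.0), (1114.0, 55.0), (4000.0, 2000.0)]:
            res = sq.snap_longitudinal_cycle(TissueParams(t1, t2), p)
            assert -1.0 <= res.mz_ti <= 1.0
            assert -1.0 <= res.mz_reference <= 1.0


class TestSnapBlood:
    def test_selective_inflow_is_bright(self):
        p = snap_protocol(inversion_mode="selective")
        mz = sq.snap_blood_state(FlowSpec(0.3, 0.4), 50.0, p)
        assert mz == 1.0

    def test_nonselective_single_inversion_closed_form(self):
        p = snap_protocol()
        blood = TissueParams(1660.0, 150.0)
        mz = sq.snap_blood_state(FlowSpec(0.3, 0.4), 50.0, p, blood=blood)
        assert mz == pytest.approx(1.0 - 2.0 * np.exp(-p.ti_ms / blood.t1_ms), rel=1e-12)
        assert mz < 0

    def test_distal_multi_cycle_blood_less_suppressed(self):
        """Blood that saw >= 2 inversion cycles relaxes between inversions,
        so its |Mz| at TI is smaller than single-inversion blood."""
        p = snap_protocol()
        blood = TissueParams(1660.0, 150.0)
        flow = FlowSpec(0.05, 0.4)  # slow: long transit
        near = sq.snap_blood_state(flow, 50.0, p, blood=blood)
        far = sq.snap_blood_state(flow, 350.0, p, blood=blood)  # >= 2 cycles
        assert abs(far) < abs(near)


class TestPhaseSensitiveRecon:
    def test_matched_phase_recovers_signed_magnitude(self):
        rng = np.random.default_rng(0)
        mag = rng.uniform(0.1, 1.0, (16, 16))
        pol = np.sign(rng.normal(size=(16, 16)))
        phase = np.exp(1j * rng.uniform(-np.pi, np.pi, (16, 16)))
        ir = mag * pol * phase
        ref = mag * phase
        out, valid = sq.phase_sensitive_recon(ir, ref)
        assert valid.all()
        np.testing.assert_allclose(out, mag * pol, atol=1e-12)

    def test_global_phase_invariance(self):
        rng = np.random.default_rng(1)
        ir = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
        ref = rng.uniform(0.5, 1.0, (8, 8)) + 0.2j
        out1, _ = sq.phase_sensitive_recon(ir, ref)
        g = np.exp(0.7j)
        out2, _ = sq.phase_sensitive_recon(ir * g, ref * g)
        np.testing.assert_allclose(out1, out2, atol=1e-12)

    def test_zero_reference_flagged(self):
        ir = np.array([1.0 + 0j, -2.0 + 0j])
        ref = np.array([0.0 + 0j, 1.0 + 0j])
        out, valid = sq.phase_sensitive_recon(ir, ref)
        assert not valid[0] and valid[1]
        assert out[0] == 1.0 and out[1] == -2.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sq.phase_sensitive_recon(np.zeros(3, complex), np.zeros(4, complex))
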