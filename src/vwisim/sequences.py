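"""Signal models for the three 3D black-blood sequences.

* MERGE — improved motion-sensitized driven equilibrium (iMSDE) preparation
  followed by a centric-ordered spoiled gradient echo train (T1 weighting).
  Moving spins accrue velocity-dependent phase gamma*M1*v from the
  flow-encoding gradients; intravoxel velocity spread then dephases the
  voxel, which is the black-blood mechanism.
* VISTA — reduced-flip-angle 3D turbo spin echo (T2 weighting) with
  flow-sensitized dephasing (FSD) gradients along the readout; echo
  amplitudes come from the EPG engine.
* SNAP — phase-sensitive inversion-recovery SPGR (heavy T1 weighting)
  producing signed images: inverted blood is negative at the chosen TI while
  wall tissue has recovered through zero.

All signals are in arbitrary units proportional to proton density; flow
attenuation factors are dimensionless in [0, 1]; signed SNAP longitudinal
magnetizations are fractions of M0 in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epg import EchoTrain, constant_flip_train, simulate_echo_train, startup_flip_ramp
from .params import GAMMA_RAD_PER_S_PER_T, TissueParams, FlowSpec, SequenceProtocol

__all__ = [
    "flow_dephasing_factor",
    "imsde_attenuation",
    "merge_prep_duration",
    "merge_center_signal",
    "vista_signal",
    "vista_train",
    "equivalent_te",
    "snap_longitudinal_cycle",
    "snap_blood_state",
    "phase_sensitive_recon",
    "SnapCycleResult",
]

#: mT*ms^2/m -> T*s^2/m
_M1_SI = 1e-9


def flow_dephasing_factor(flow: FlowSpec, m1_mT_ms2_per_m: float) -> float:
    """|E[exp(i gamma M1 v)]| over the intravoxel velocity distribution.

    Velocities uniform on [v(1-delta), v(1+delta)] give
    |sin(dphi/2) / (dphi/2)| with dphi = 2 gamma M1 v delta, the phase spread
    across the voxel. Static tissue (or zero spread) returns 1: a coherent
    per-voxel phase does not attenuate a magnitude image.
    """
    if m1_mT_ms2_per_m < 0:
        raise ValueError("first gradient moment must be >= 0")
    v = flow.mean_velocity_m_per_s
    delta = flow.intravoxel_spread_fraction
    half_spread = GAMMA_RAD_PER_S_PER_T * m1_mT_ms2_per_m * _M1_SI * v * delta
    if half_spread == 0.0:
        return 1.0
    return float(abs(np.sin(half_spread) / half_spread))


def imsde_attenuation(
    tissue: TissueParams,
    flow: FlowSpec,
    m1_mT_ms2_per_m: float,
    prep_duration_ms: float,
) -> float:
    """Attenuation of the iMSDE preparation: T2 decay over the prep interval
    times the intravoxel flow-dephasing factor. In [0, 1]."""
    if prep_duration_ms <= 0:
        raise ValueError("prep duration must be > 0")
    t2_loss = float(np.exp(-prep_duration_ms / tissue.t2_ms))
    return t2_loss * flow_dephasing_factor(flow, m1_mT_ms2_per_m)


# ---------------------------------------------------------------------------
# iMSDE gradient timing


@dataclass(frozen=True)
class BipolarLobes:
    """Two opposite trapezoidal lobes realizing a first moment; times in ms,
    gradient in mT/m."""

    amplitude: float
    ramp_ms: float
    flat_ms: float

    @property
    def lobe_duration_ms(self) -> float:
        return self.flat_ms + 2.0 * self.ramp_ms

    @property
    def area(self) -> float:  # mT*ms/m
        return self.amplitude * (self.flat_ms + self.ramp_ms)

    @property
    def first_moment(self) -> float:  # mT*ms^2/m, magnitude
        return self.area * self.lobe_duration_ms

    def waveform(self, dt_ms: float = 1e-4) -> tuple[np.ndarray, np.ndarray]:
        """Sampled G(t) of the back-to-back bipolar pair (for the numeric
        moment oracle)."""
        T = self.lobe_duration_ms
        t = np.arange(0.0, 2 * T + dt_ms, dt_ms)

        def lobe(tt):
            g = np.zeros_like(tt)
            if self.ramp_ms > 0:
                up = tt < self.ramp_ms
                g[up] = self.amplitude * tt[up] / self.ramp_ms
                down = (tt >= self.ramp_ms + self.flat_ms) & (tt <= T)
                g[down] = self.amplitude * (T - tt[down]) / self.ramp_ms
            mid = (tt >= self.ramp_ms) & (tt < self.ramp_ms + self.flat_ms)
            g[mid] = self.amplitude
            return g

        g = np.where(t < T, lobe(t), -lobe(np.clip(t - T, 0, None)))
        return t, g


def design_bipolar(
    m1_mT_ms2_per_m: float,
    max_gradient_mT_per_m: float = 20.0,
    slew_mT_per_m_per_ms: float = 100.0,
) -> BipolarLobes:
    """Minimum-duration back-to-back bipolar pair with |M1| = m1 at the
    gradient amplitude cap.

    For identical opposite trapezoids of amplitude G, ramp r = G/S and flat
    top f, the pair's first-moment magnitude is area x lobe duration =
    G (f + r)(f + 2r); minimal duration uses G at the cap and solves the
    quadratic for f (triangular lobes below the cap if f would be negative).
    """
    if m1_mT_ms2_per_m <= 0:
        raise ValueError("m1 must be > 0 for gradient design")
    G = max_gradient_mT_per_m
    r = G / slew_mT_per_m_per_ms
    # G (f^2 + 3 r f + 2 r^2) = m1  =>  f = (-3r + sqrt(r^2 + 4 m1/G)) / 2
    f = (-3.0 * r + np.sqrt(r * r + 4.0 * m1_mT_ms2_per_m / G)) / 2.0
    if f < 0:
        # triangular lobes: f = 0, M1 = 2 G r^2, r = G/S  =>  G = (m1 S^2/2)^(1/3)
        G = (m1_mT_ms2_per_m * slew_mT_per_m_per_ms**2 / 2.0) ** (1.0 / 3.0)
        r = G / slew_mT_per_m_per_ms
        f = 0.0
    return BipolarLobes(amplitude=float(G), ramp_ms=float(r), flat_ms=float(f))


#: Fixed RF overhead of the iMSDE block (90x - composite refocusing - 90-x), ms.
IMSDE_RF_OVERHEAD_MS = 5.0


def merge_prep_duration(
    m1_mT_ms2_per_m: float,
    max_gradient_mT_per_m: float = 20.0,
    slew_mT_per_m_per_ms: float = 100.0,
    rf_overhead_ms: float = IMSDE_RF_OVERHEAD_MS,
) -> float:
    """Minimal iMSDE preparation duration (ms) achieving the requested first
    moment at the gradient cap; strictly increasing in m1."""
    if m1_mT_ms2_per_m < 0:
        raise ValueError("m1 must be >= 0")
    if m1_mT_ms2_per_m == 0:
        return rf_overhead_ms
    lobes = design_bipolar(m1_mT_ms2_per_m, max_gradient_mT_per_m, slew_mT_per_m_per_ms)
    return rf_overhead_ms + 2.0 * lobes.lobe_duration_ms


# ---------------------------------------------------------------------------
# MERGE


def spgr_transient_mz(
    mz0: float, flip_deg: float, tr_ms: float, t1_ms: float, n_echoes: int
) -> np.ndarray:
    """Longitudinal magnetization just before each pulse of a spoiled
    gradient echo train started from mz0 (standard spoiled recursion)."""
    e1 = np.exp(-tr_ms / t1_ms) if np.isfinite(t1_ms) else 1.0
    ca = np.cos(np.deg2rad(flip_deg))
    mz = np.empty(n_echoes)
    m = mz0
    for k in range(n_echoes):
        mz[k] = m
        m = m * ca * e1 + (1.0 - e1)
    return mz


def merge_center_signal(
    tissue: TissueParams,
    flow: FlowSpec,
    protocol: SequenceProtocol,
    center_echo: int = 1,
) -> float:
    """k-space-center signal of iMSDE-prepared SPGR with centric ordering.

    Centric ordering samples the k-space center at the first readout after
    the preparation: signal = PD * attenuation * sin(flip) * Mz at echo
    ``center_echo``, Mz evolved by the spoiled recursion from the post-prep
    state.
    """
    if protocol.kind != "MERGE":
        raise ValueError(f"expected MERGE protocol, got {protocol.kind}")
    m1 = protocol.m1_mT_ms2_per_m or 0.0
    prep = protocol.prep_duration_ms or merge_prep_duration(m1)
    if m1 == 0 and protocol.prep_duration_ms is None:
        prep = IMSDE_RF_OVERHEAD_MS
    att = imsde_attenuation(tissue, flow, m1, prep)
    mz = spgr_transient_mz(att, protocol.flip_deg, protocol.tr_ms, tissue.t1_ms, center_echo)
    return float(
        tissue.proton_density * np.sin(np.deg2rad(protocol.flip_deg)) * mz[center_echo - 1]
    )


# ---------------------------------------------------------------------------
# VISTA


def vfa_flip_schedule(
    tissue: TissueParams,
    n_acq: int,
    esp_first_ms: float,
    esp_rest_ms: float,
    n_startup: int = 4,
    first_flip_deg: float = 12.0,
) -> tuple[float, ...]:
    """Variable-flip-angle schedule holding the echo amplitude constant.

    Constant-target prescription: the first acquired echo (reached through
    the start-up ramp toward ``first_flip_deg``) sets the target amplitude;
    each later flip is solved by bisection so its echo equals the target,
    capped at 180 deg (beyond the cap amplitudes decay at the CPMG rate).
    """
    from .epg import EPGState, apply_rf, relax_and_dephase

    flips = list(startup_flip_ramp(first_flip_deg, n_startup)) + [first_flip_deg]
    n_total = len(flips) + (n_acq - 1)
    state = EPGState.equilibrium(2 * n_total + 4)
    state = apply_rf(state, 90.0, 90.0)
    state = relax_and_dephase(state, esp_first_ms / 2.0, tissue)

    def echo_of(st, flip, first=False):
        half = (esp_first_ms if first else esp_rest_ms) / 2.0
        st = apply_rf(st, flip, 0.0)
        st = relax_and_dephase(st, half, tissue)
        return float(np.real(st.echo_amplitude)), st

    target = 0.0
    for i, f in enumerate(flips):
        target, state = echo_of(state, f, first=(i == 0))
        state = relax_and_dephase(state, esp_rest_ms / 2.0, tissue)
    # The echo is not monotone in the flip (stimulated pathways recall stored
    # Z), so each pulse scans a coarse flip grid and refines around the
    # smallest flip meeting the target; when no flip reaches it the schedule
    # follows the maximum achievable echo.
    grid = np.arange(5.0, 180.1, 5.0)
    for _ in range(n_acq - 1):
        echoes = np.array([echo_of(state, f)[0] for f in grid])
        feasible = np.where(echoes >= target)[0]
        if feasible.size:
            j = feasible[0]
            lo = grid[j - 1] if j > 0 else grid[0]
            hi = grid[j]
            for _ in range(25):
                mid = 0.5 * (lo + hi)
                if echo_of(state, mid)[0] < target:
                    lo = mid
                else:
                    hi = mid
            best = hi
        else:
            best = float(grid[np.argmax(echoes)])
            target = float(echoes.max())
        flips.append(best)
        target, state = echo_of(state, best)
        state = relax_and_dephase(state, esp_rest_ms / 2.0, tissue)
    return tuple(flips)


def vista_train(
    protocol: SequenceProtocol,
    tissue: TissueParams,
    scheme: str = "RFA",
) -> EchoTrain:
    """Echo train for the requested refocusing scheme (RFA or VFA)."""
    if scheme == "RFA":
        return constant_flip_train(
            protocol.flip_deg,
            protocol.turbo_factor,
            n_startup=protocol.n_startup,
            esp_first_ms=protocol.esp_first_ms,
            esp_rest_ms=protocol.esp_rest_ms,
        )
    if scheme == "VFA":
        flips = vfa_flip_schedule(
            tissue,
            protocol.turbo_factor,
            protocol.esp_first_ms,
            protocol.esp_rest_ms,
            n_startup=protocol.n_startup,
        )
        return EchoTrain(
            flip_schedule_deg=flips,
            esp_first_ms=protocol.esp_first_ms,
            esp_rest_ms=protocol.esp_rest_ms,
            n_startup=protocol.n_startup,
        )
    raise ValueError(f"unknown refocusing scheme {scheme!r}")


def center_echo_index(n_acq: int) -> int:
    """1-based acquired-echo index holding the k-space center under linear
    (near-center) ordering; ceil(n/2) by default."""
    return int(np.ceil(n_acq / 2))


def vista_signal(
    tissue: TissueParams,
    flow: FlowSpec,
    protocol: SequenceProtocol,
    scheme: str = "RFA",
    center_index: int | None = None,
) -> tuple[np.ndarray, float]:
    """(echo amplitudes, k-space-center signal) of the VISTA train.

    Flowing spins are additionally dephased by the readout-direction FSD
    gradients (moment ``protocol.fsd_m1_mT_ms2_per_m``). Amplitudes include
    proton density.
    """
    if protocol.kind != "VISTA":
        raise ValueError(f"expected VISTA protocol, got {protocol.kind}")
    train = vista_train(protocol, tissue, scheme)
    echoes = simulate_echo_train(train, tissue) * tissue.proton_density
    fsd = flow_dephasing_factor(flow, protocol.fsd_m1_mT_ms2_per_m or 0.0)
    echoes = echoes * fsd
    idx = center_index if center_index is not None else center_echo_index(train.n_acq)
    return echoes, float(echoes[idx - 1])


def equivalent_te(center_signal: float, tissue: TissueParams, s0: float | None = None) -> float:
    """Conventional spin-echo TE giving the same attenuation as the train's
    center echo: -T2 ln(S_center / S0). Diagnostic only."""
    s0 = s0 if s0 is not None else tissue.proton_density
    if center_signal <= 0 or s0 <= 0:
        raise ValueError("signals must be positive for the equivalent-TE diagnostic")
    return float(-tissue.t2_ms * np.log(center_signal / s0))


# ---------------------------------------------------------------------------
# SNAP


@dataclass(frozen=True)
class SnapCycleResult:
    """Periodic steady state (or finite iteration) of the SNAP IR cycle."""

    mz_ti: float  # signed Mz just before the first readout pulse (fraction of M0)
    mz_reference: float  # Mz at the reference acquisition (end of cycle)
    mz_pre_inversion: float
    n_cycles: int


def _snap_cycle_map(
    m_start: float,
    tissue: TissueParams,
    protocol: SequenceProtocol,
) -> tuple[float, float]:
    """One IRTR cycle: inversion -> TI recovery -> SPGR readout -> recovery.

    Returns (mz_ti, m_before_next_inversion). The IR readout block
    (turbo_factor pulses at flip_deg, spacing tr_ms) starts at TI; the
    low-flip reference segment is modeled at the end of the cycle where Mz
    has recovered toward +M0.
    """
    eta = protocol.inversion_efficiency
    t1 = tissue.t1_ms

    def recover(m, t):
        e = np.exp(-t / t1) if np.isfinite(t1) else 1.0
        return 1.0 + (m - 1.0) * e

    m = -eta * m_start
    mz_ti = recover(m, protocol.ti_ms)
    mz = spgr_transient_mz(mz_ti, protocol.flip_deg, protocol.tr_ms, t1, protocol.turbo_factor + 1)
    readout_ms = protocol.turbo_factor * protocol.tr_ms
    remainder = protocol.ir_tr_ms - protocol.ti_ms - readout_ms
    if remainder < 0:
        raise ValueError("TI + readout exceeds IRTR; shorten TI or the echo train")
    m_end = recover(mz[-1], remainder)
    return float(mz_ti), float(m_end)


def snap_longitudinal_cycle(
    tissue: TissueParams,
    protocol: SequenceProtocol,
    n_cycles: int | None = None,
    m_initial: float = 1.0,
) -> SnapCycleResult:
    """Signed Mz(TI) of the SNAP inversion-recovery cycle.

    With ``n_cycles`` given, iterates that many cycles from ``m_initial``
    (full equilibrium by default) — one cycle with perfect inversion gives
    the familiar 1 - 2 exp(-TI/T1), zero at TI = T1 ln 2. Otherwise solves
    the periodic steady state exactly: every stage is affine in Mz, so the
    cycle map is m -> a m + b with |a| < 1 and the fixed point is b/(1 - a).
    """
    if protocol.kind != "SNAP":
        raise ValueError(f"expected SNAP protocol, got {protocol.kind}")
    if n_cycles is not None:
        m = m_initial
        mz_ti = 0.0
        for _ in range(n_cycles):
            mz_ti, m = _snap_cycle_map(m, tissue, protocol)
        return SnapCycleResult(mz_ti, m, m, n_cycles)
    _, b = _snap_cycle_map(0.0, tissue, protocol)
    _, ab = _snap_cycle_map(1.0, tissue, protocol)
    a = ab - b
    m_star = b / (1.0 - a)
    mz_ti, m_end = _snap_cycle_map(m_star, tissue, protocol)
    return SnapCycleResult(float(mz_ti), float(m_end), float(m_star), 0)


def snap_blood_state(
    flow: FlowSpec,
    distance_into_volume_mm: float,
    protocol: SequenceProtocol,
    blood: TissueParams | None = None,
    coverage_mm: float = 400.0,
) -> float:
    """Signed Mz of blood arriving ``distance_into_volume_mm`` downstream of
    the inversion-coverage entry, at acquisition time.

    Selective inversion: blood entering from outside the imaging slab was
    never inverted -> +M0 (the bright inflow artifact). Nonselective: blood
    within ``coverage_mm`` of travel is inverted; a spin whose transit from
    the coverage edge spans several IRTR cycles relaxes between repeated
    inversions, so distal blood is less completely suppressed than blood
    seeing a single inversion.
    """
    if distance_into_volume_mm < 0:
        raise ValueError("distance must be >= 0")
    if protocol.kind != "SNAP":
        raise ValueError(f"expected SNAP protocol, got {protocol.kind}")
    if blood is None:
        from .params import default_tissue_table

        blood = default_tissue_table()["blood"]
    if protocol.inversion_mode == "selective":
        return 1.0
    v = flow.mean_velocity_m_per_s
    t1 = blood.t1_ms
    e_ti = np.exp(-protocol.ti_ms / t1)
    eta = protocol.inversion_efficiency
    if v <= 0:
        return float(snap_longitudinal_cycle(blood, protocol).mz_ti)
    if distance_into_volume_mm > coverage_mm:
        return 1.0  # refreshed from beyond the inversion band
    transit_ms = distance_into_volume_mm / v  # mm / (m/s) == mm / (mm/ms) = ms
    n_cycles = 1 + int(transit_ms // protocol.ir_tr_ms)
    e_irtr = np.exp(-protocol.ir_tr_ms / t1)
    m = 1.0
    for _ in range(n_cycles - 1):
        m = 1.0 + (-eta * m - 1.0) * e_irtr
    return float(1.0 + (-eta * m - 1.0) * e_ti)


def phase_sensitive_recon(
    ir_complex: np.ndarray,
    reference_complex: np.ndarray,
    eps: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Phase-corrected real reconstruction of an IR image.

    Uses the reference image's phase to restore signal polarity:
    Re[IR * conj(ref) / |ref|]. Returns (signed image, valid mask); where the
    reference vanishes the IR real part's sign is kept and the voxel is
    flagged invalid in the mask.
    """
    ir = np.asarray(ir_complex)
    ref = np.asarray(reference_complex)
    if ir.shape != ref.shape:
        raise ValueError("IR and reference images must have the same shape")
    mag = np.abs(ref)
    valid = mag > eps
    out = np.empty(ir.shape, dtype=float)
    out[valid] = np.real(ir[valid] * np.conj(ref[valid]) / mag[valid])
    out[~valid] = np.sign(np.real(ir[~valid])) * np.abs(ir[~valid])
    return out, valid
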