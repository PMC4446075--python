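"""Extended phase graph (EPG) engine for multi-pulse refocusing trains.

The magnetization of a voxel subjected to repeated RF pulses and crusher
gradients is represented by configuration states (F+_k, F-_k, Z_k) indexed by
integer dephasing order k >= 0, with F-_k holding conj(F(-k)). An RF pulse
mixes the three families order-by-order; a gradient interval shifts transverse
orders by one and leaves Z untouched; relaxation scales transverse states by
E2 = exp(-t/T2) and longitudinal ones by E1 = exp(-t/T1) with M0 regrowth
into Z_0 only. Hard pulses (no relaxation during RF) are assumed throughout:
pulse durations are ~ms against T2 of tens of ms.

The engine uses one dephasing shift per half echo spacing, so spin echoes
form at order k = 0 midway between refocusing pulses. Under the CPMG phase
convention (90deg excitation about x, refocusing about y) echo amplitudes
are real and non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import TissueParams

__all__ = [
    "EPGState",
    "EchoTrain",
    "apply_rf",
    "relax_and_dephase",
    "simulate_echo_train",
    "startup_flip_ramp",
]


class CapacityError(RuntimeError):
    """Raised when a dephasing shift would push amplitude past max_order."""


@dataclass
class EPGState:
    """Configuration state amplitudes up to a fixed maximum dephasing order.

    Attributes
    ----------
    f_plus, f_minus, z : complex arrays of length max_order + 1
        F(k), conj(F(-k)) and Z(k) for k = 0 .. max_order, as fractions of M0.
    allow_truncation : bool
        When False (default) a shift that would move amplitude beyond
        max_order raises CapacityError instead of silently truncating.
    """

    max_order: int
    f_plus: np.ndarray = field(default=None)  # type: ignore[assignment]
    f_minus: np.ndarray = field(default=None)  # type: ignore[assignment]
    z: np.ndarray = field(default=None)  # type: ignore[assignment]
    allow_truncation: bool = False

    def __post_init__(self) -> None:
        n = self.max_order + 1
        if self.f_plus is None:
            self.f_plus = np.zeros(n, dtype=complex)
            self.f_minus = np.zeros(n, dtype=complex)
            self.z = np.zeros(n, dtype=complex)
            self.z[0] = 1.0  # thermal equilibrium

    @classmethod
    def equilibrium(cls, max_order: int) -> "EPGState":
        return cls(max_order=max_order)

    def copy(self) -> "EPGState":
        return EPGState(
            max_order=self.max_order,
            f_plus=self.f_plus.copy(),
            f_minus=self.f_minus.copy(),
            z=self.z.copy(),
            allow_truncation=self.allow_truncation,
        )

    @property
    def echo_amplitude(self) -> complex:
        """Transverse amplitude of the fully rephased (k = 0) configuration."""
        return self.f_plus[0]

    def norm_squared(self) -> float:
        """Conserved quadratic invariant of RF rotations and lossless shifts.

        Parseval norm of the underlying isochromat ensemble,
        mean(|Mxy|^2 + Mz^2) = sum_k |F(k)|^2 + sum_k |Z(k)|^2 over all
        integer orders; F(0) is counted once (f_minus[0] duplicates its
        conjugate) and Z(-k) = conj(Z(k)) doubles the k >= 1 terms.
        """
        s = (
            np.sum(np.abs(self.f_plus) ** 2)
            + np.sum(np.abs(self.f_minus[1:]) ** 2)
            + np.abs(self.z[0]) ** 2
            + 2.0 * np.sum(np.abs(self.z[1:]) ** 2)
        )
        return float(s)


@dataclass(frozen=True)
class EchoTrain:
    """A refocusing echo train: flip schedule, spacings and acquisition window.

    ``flip_schedule_deg`` covers start-up plus acquired refocusing pulses
    (length n_startup + n_acq). Echoes formed by the first ``n_startup``
    pulses establish the static pseudo steady state and are excluded from
    the returned acquisition window.
    """

    flip_schedule_deg: tuple[float, ...]
    excitation_flip_deg: float = 90.0
    esp_first_ms: float = 3.6
    esp_rest_ms: float = 3.6
    n_startup: int = 0
    # CPMG: excitation and refocusing axes 90 deg apart so echoes are real.
    excitation_phase_deg: float = 90.0
    rf_phase_deg: float = 0.0

    def __post_init__(self) -> None:
        flips = np.asarray(self.flip_schedule_deg, dtype=float)
        if flips.size == 0:
            raise ValueError("flip schedule is empty")
        if np.any(flips <= 0) or np.any(flips > 180):
            raise ValueError("refocusing flips must lie in (0, 180] degrees")
        if self.esp_first_ms <= 0 or self.esp_rest_ms <= 0:
            raise ValueError("echo spacings must be > 0")
        if self.n_startup < 0:
            raise ValueError("n_startup must be >= 0")
        if self.n_acq < 1:
            raise ValueError("need at least one acquired echo")

    @property
    def n_pulses(self) -> int:
        return len(self.flip_schedule_deg)

    @property
    def n_acq(self) -> int:
        return self.n_pulses - self.n_startup


def startup_flip_ramp(alpha_deg: float, n_startup: int) -> np.ndarray:
    """Start-up flip schedule approaching the static pseudo steady state.

    Linear ramp from the asymptotic first-pulse prescription 90 + alpha/2
    down to the constant target flip alpha over ``n_startup`` pulses. This is
    a policy choice (swappable): any schedule ending at alpha works, the ramp
    merely damps the transient amplitude oscillation.
    """
    if n_startup == 0:
        return np.empty(0)
    first = 90.0 + alpha_deg / 2.0
    return np.linspace(first, alpha_deg, n_startup + 1)[:-1]


def constant_flip_train(
    alpha_deg: float,
    n_acq: int,
    n_startup: int = 4,
    esp_first_ms: float = 3.6,
    esp_rest_ms: float = 3.6,
) -> EchoTrain:
    """Reduced-flip-angle (RFA) train: start-up ramp then constant alpha."""
    flips = tuple(startup_flip_ramp(alpha_deg, n_startup)) + (alpha_deg,) * n_acq
    return EchoTrain(
        flip_schedule_deg=flips,
        esp_first_ms=esp_first_ms,
        esp_rest_ms=esp_rest_ms,
        n_startup=n_startup,
    )


def _rotation_matrix(flip_deg: float, phase_deg: float) -> np.ndarray:
    """3x3 complex EPG rotation acting on (F+_k, F-_k, Z_k)."""
    a = np.deg2rad(flip_deg)
    p = np.deg2rad(phase_deg)
    ca2 = np.cos(a / 2.0) ** 2
    sa2 = np.sin(a / 2.0) ** 2
    sa = np.sin(a)
    ca = np.cos(a)
    eip = np.exp(1j * p)
    return np.array(
        [
            [ca2, np.exp(2j * p) * sa2, -1j * eip * sa],
            [np.exp(-2j * p) * sa2, ca2, 1j * np.conj(eip) * sa],
            [-0.5j * np.conj(eip) * sa, 0.5j * eip * sa, ca],
        ],
        dtype=complex,
    )


def apply_rf(state: EPGState, flip_deg: float, phase_deg: float = 0.0) -> EPGState:
    """Mix configuration states with the standard EPG rotation matrix.

    Returns a new state; the input is not modified. ``flip_deg`` must lie in
    [0, 180].
    """
    if not (0.0 <= flip_deg <= 180.0):
        raise ValueError(f"flip angle {flip_deg} outside [0, 180] degrees")
    T = _rotation_matrix(flip_deg, phase_deg)
    out = state.copy()
    stacked = np.vstack([state.f_plus, state.f_minus, state.z])
    mixed = T @ stacked
    out.f_plus, out.f_minus, out.z = mixed[0], mixed[1], mixed[2]
    return out


def relax_and_dephase(
    state: EPGState,
    interval_ms: float,
    tissue: TissueParams,
    n_shifts: int = 1,
) -> EPGState:
    """Free evolution over ``interval_ms``: T1/T2 relaxation then ``n_shifts``
    unit increments of the dephasing order.

    Transverse orders decay with E2, longitudinal with E1, and M0 regrows
    into Z_0. The order shift moves F(k) -> F(k+1); the new F(0) is taken
    from the negative-order family (F(-1) rephasing through zero).
    """
    if interval_ms < 0:
        raise ValueError("evolution interval must be >= 0")
    out = state.copy()
    if interval_ms > 0:
        e2 = np.exp(-interval_ms / tissue.t2_ms) if np.isfinite(tissue.t2_ms) else 1.0
        e1 = np.exp(-interval_ms / tissue.t1_ms) if np.isfinite(tissue.t1_ms) else 1.0
        out.f_plus *= e2
        out.f_minus *= e2
        out.z *= e1
        out.z[0] += 1.0 - e1
    for _ in range(n_shifts):
        _shift_up(out)
    return out


def _shift_up(s: EPGState) -> None:
    if not s.allow_truncation and abs(s.f_plus[-1]) > 1e-14:
        raise CapacityError(
            f"dephasing order would exceed max_order={s.max_order}; "
            "increase capacity or enable truncation explicitly"
        )
    # F(k) -> F(k+1) for k >= 0; F(-k) -> F(-k+1), so f_minus shifts down and
    # the rephased f_minus[1] becomes the new F(0).
    new_fp = np.empty_like(s.f_plus)
    new_fp[1:] = s.f_plus[:-1]
    new_fm = np.empty_like(s.f_minus)
    new_fm[:-1] = s.f_minus[1:]
    new_fm[-1] = 0.0
    new_fp[0] = np.conj(new_fm[0])
    s.f_plus = new_fp
    s.f_minus = new_fm


def simulate_echo_train(
    train: EchoTrain,
    tissue: TissueParams,
    max_order: int | None = None,
    return_startup: bool = False,
) -> np.ndarray:
    """Echo amplitudes of a refocusing train, CPMG phase convention.

    Simulates 90deg(x) excitation followed by the train's refocusing pulses
    (about y), with one dephasing unit per half echo spacing so each echo is
    read at configuration order zero. Start-up echoes are simulated but
    excluded from the returned array unless ``return_startup`` is set.

    Returns real amplitudes (fractions of M0), one per acquired echo.
    """
    n_pulses = train.n_pulses
    if max_order is None:
        max_order = 2 * n_pulses + 4
    state = EPGState.equilibrium(max_order)
    state = apply_rf(state, train.excitation_flip_deg, train.excitation_phase_deg)
    state = relax_and_dephase(state, train.esp_first_ms / 2.0, tissue)
    echoes = np.empty(n_pulses)
    for i, flip in enumerate(train.flip_schedule_deg):
        # pulse i sits half a spacing before echo i; echo i sits half of the
        # *next* spacing before pulse i+1 (first spacing may differ).
        half_after = (train.esp_first_ms if i == 0 else train.esp_rest_ms) / 2.0
        state = apply_rf(state, flip, train.rf_phase_deg)
        state = relax_and_dephase(state, half_after, tissue)
        echoes[i] = np.real(state.echo_amplitude)
        if i < n_pulses - 1:
            state = relax_and_dephase(state, train.esp_rest_ms / 2.0, tissue)
    if return_startup:
        return echoes
    return echoes[train.n_startup :]
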