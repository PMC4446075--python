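"""Tissue relaxation parameters, flow specifications and acquisition protocols.

Defaults reproduce the published 3 T joint intra-/extracranial protocol:
three coronal 3D acquisitions (MERGE / VISTA / SNAP) with a shared
250 x 160 x 40 mm FOV and 0.8 mm isotropic acquisition resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import yaml

#: Gyromagnetic ratio of the proton, rad s^-1 T^-1.
GAMMA_RAD_PER_S_PER_T = 2.675e8


@dataclass(frozen=True)
class TissueParams:
    """Relaxation times and proton density of one tissue class.

    T1/T2 in ms; proton_density in arbitrary units (fraction of water).
    ``np.inf`` relaxation times are allowed (lossless limit).
    """

    t1_ms: float
    t2_ms: float
    proton_density: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.t2_ms <= self.t1_ms):
            raise ValueError(
                f"require 0 < T2 <= T1, got T1={self.t1_ms}, T2={self.t2_ms} ({self.name!r})"
            )
        if self.proton_density <= 0:
            raise ValueError("proton_density must be > 0")


@dataclass(frozen=True)
class FlowSpec:
    """Intravoxel velocity distribution of a (possibly) moving tissue.

    Velocities are uniform on [v(1-delta), v(1+delta)] along ``direction``;
    ``uniformity_class`` tags plug/parabolic-like segments ("uniform", distal
    ICA/MCA) versus recirculating ones ("complex", CCA/bulb), which in this
    model simply carry a wider spread delta.
    """

    mean_velocity_m_per_s: float = 0.0
    intravoxel_spread_fraction: float = 0.0
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    uniformity_class: str = "uniform"

    def __post_init__(self) -> None:
        if self.mean_velocity_m_per_s < 0:
            raise ValueError("mean velocity must be >= 0")
        if not (0.0 <= self.intravoxel_spread_fraction <= 1.0):
            raise ValueError("intravoxel spread fraction must be in [0, 1]")
        if self.uniformity_class not in ("uniform", "complex"):
            raise ValueError("uniformity_class must be 'uniform' or 'complex'")


STATIC = FlowSpec(0.0, 0.0)


@dataclass
class SequenceProtocol:
    """Acquisition parameters of one 3D black-blood sequence.

    ``kind`` is MERGE (iMSDE-prepared SPGR), VISTA (reduced-flip-angle TSE)
    or SNAP (phase-sensitive IR SPGR). Fields that only apply to one kind are
    None elsewhere. Durations in ms, flips in degrees, M1 in mT*ms^2/m.
    """

    kind: str
    fov_mm: tuple[float, float, float] = (250.0, 160.0, 40.0)
    acq_resolution_mm: float = 0.8
    recon_resolution_mm: float = 0.4
    te_ms: float = 0.0
    tr_ms: float = 0.0
    ir_tr_ms: Optional[float] = None
    ti_ms: Optional[float] = None
    flip_deg: float = 0.0
    reference_flip_deg: Optional[float] = None
    turbo_factor: int = 1
    n_startup: int = 0
    esp_first_ms: Optional[float] = None
    esp_rest_ms: Optional[float] = None
    averages: int = 1
    m1_mT_ms2_per_m: Optional[float] = None
    prep_duration_ms: Optional[float] = None
    fsd_m1_mT_ms2_per_m: Optional[float] = None
    inversion_mode: str = "nonselective"
    inversion_efficiency: float = 1.0
    te_equivalent_ms: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("MERGE", "VISTA", "SNAP"):
            raise ValueError(f"unknown sequence kind {self.kind!r}")
        for name in ("te_ms", "tr_ms", "acq_resolution_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.kind == "SNAP":
            if self.ir_tr_ms is None or self.ti_ms is None:
                raise ValueError("SNAP requires ir_tr_ms and ti_ms")
            if not (0 < self.ti_ms < self.ir_tr_ms):
                raise ValueError("require 0 < TI < IRTR")
        if self.inversion_mode not in ("selective", "nonselective"):
            raise ValueError("inversion_mode must be 'selective' or 'nonselective'")


def merge_protocol(**overrides) -> SequenceProtocol:
    """T1-weighted iMSDE-prepared spoiled gradient echo (3D-MERGE) defaults."""
    kw = dict(
        kind="MERGE",
        te_ms=4.2,
        tr_ms=9.0,
        flip_deg=6.0,
        turbo_factor=90,
        averages=2,
        m1_mT_ms2_per_m=1000.0,
    )
    kw.update(overrides)
    return SequenceProtocol(**kw)


def vista_protocol(**overrides) -> SequenceProtocol:
    """T2-weighted reduced-flip-angle TSE (VISTA) defaults.

    Effective TE 255 ms (k-space-center echo) with an equivalent
    conventional-spin-echo TE of 86 ms; 130 acquired echoes after 4
    start-up echoes; first/other echo spacing 10.8/3.6 ms.
    """
    kw = dict(
        kind="VISTA",
        te_ms=255.0,
        te_equivalent_ms=86.0,
        tr_ms=2500.0,
        flip_deg=32.0,
        turbo_factor=130,
        n_startup=4,
        esp_first_ms=10.8,
        esp_rest_ms=3.6,
        averages=1,
        fsd_m1_mT_ms2_per_m=300.0,
    )
    kw.update(overrides)
    return SequenceProtocol(**kw)


def snap_protocol(**overrides) -> SequenceProtocol:
    """Phase-sensitive IR SPGR (SNAP) defaults: SPGR TR 10 ms inside an
    inversion-recovery cycle of 1987 ms; IR / reference flips 11 / 5 deg."""
    kw = dict(
        kind="SNAP",
        te_ms=4.5,
        tr_ms=10.0,
        ir_tr_ms=1987.0,
        ti_ms=800.0,
        flip_deg=11.0,
        reference_flip_deg=5.0,
        turbo_factor=98,
        averages=2,
    )
    kw.update(overrides)
    return SequenceProtocol(**kw)


def default_protocols() -> dict[str, SequenceProtocol]:
    return {"MERGE": merge_protocol(), "VISTA": vista_protocol(), "SNAP": snap_protocol()}


# Wall relaxation is the simulation tissue used throughout train optimization;
# blood/CSF/muscle/white matter are literature-typical 3 T values.
def default_tissue_table() -> dict[str, TissueParams]:
    return {
        "wall": TissueParams(1114.0, 55.0, 1.0, "wall"),
        "blood": TissueParams(1660.0, 150.0, 1.0, "blood"),
        "csf": TissueParams(4000.0, 2000.0, 1.0, "csf"),
        "muscle": TissueParams(1420.0, 32.0, 0.9, "muscle"),
        "white_matter": TissueParams(840.0, 70.0, 0.75, "white_matter"),
        "plaque_iph": TissueParams(500.0, 40.0, 1.0, "plaque_iph"),
        "plaque_loose_matrix": TissueParams(1500.0, 120.0, 1.0, "plaque_loose_matrix"),
    }


# ---------------------------------------------------------------------------
# YAML round-trip of the protocol/tissue configuration


def protocols_to_dict(protocols: dict[str, SequenceProtocol]) -> dict:
    out = {}
    for k, p in protocols.items():
        d = asdict(p)
        d["fov_mm"] = list(d["fov_mm"])
        out[k] = d
    return out


def protocols_from_dict(d: dict) -> dict[str, SequenceProtocol]:
    out = {}
    for k, kw in d.items():
        kw = dict(kw)
        if isinstance(kw.get("fov_mm"), list):
            kw["fov_mm"] = tuple(kw["fov_mm"])
        out[k] = SequenceProtocol(**kw)
    return out


def save_config(path, protocols: Optional[dict] = None, tissues: Optional[dict] = None) -> None:
    protocols = protocols if protocols is not None else default_protocols()
    tissues = tissues if tissues is not None else default_tissue_table()
    doc = {
        "protocols": protocols_to_dict(protocols),
        "tissues": {k: asdict(t) for k, t in tissues.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_config(path) -> tuple[dict[str, SequenceProtocol], dict[str, TissueParams]]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    protocols = protocols_from_dict(doc["protocols"])
    tissues = {k: TissueParams(**kw) for k, kw in doc["tissues"].items()}
    return protocols, tissues
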