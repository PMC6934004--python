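"""Spoiled gradient-echo signal physics and protocol optimisation.

Everything downstream — phantom simulation, decay fitting, calibration —
derives from the steady-state signal model implemented here. Angles at the
interface are in degrees, echo times in milliseconds; conversions to radians
and seconds happen inside the functions.
"""
from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np

from ._utils import sinc

#: proton gyromagnetic ratio, rad s^-1 T^-1
GAMMA_PROTON = 2.675222e8

__all__ = [
    "GAMMA_PROTON",
    "AcqProtocol",
    "TissueParams",
    "steady_state_factor",
    "saturation_level",
    "tr_for_saturation",
    "flip_max_for_saturation",
    "snr_per_unit_time",
    "signal_model",
]


@dataclasses.dataclass(frozen=True)
class AcqProtocol:
    """Scanner/sequence metadata governing the signal physics.

    Parameters
    ----------
    tr_s : repetition time in seconds.
    flip_deg : nominal excitation flip angle in degrees.
    te_ms : strictly increasing echo times in milliseconds.
    cal_factor : ratio of effective to nominal flip angle (scanner
        calibration property, e.g. 0.8 on some systems).
    voxel_mm : (dx, dy, dz); dz is the excited slice thickness.
    field_t : static field strength in tesla (used only to convert
        ppm frequency offsets to Hz).
    gamma : gyromagnetic ratio in rad s^-1 T^-1.
    """

    tr_s: float
    flip_deg: float
    te_ms: tuple[float, ...]
    cal_factor: float = 1.0
    voxel_mm: tuple[float, float, float] = (1.04, 1.38, 1.5)
    field_t: float = 3.0
    gamma: float = GAMMA_PROTON

    def __post_init__(self):
        object.__setattr__(self, "te_ms", tuple(float(t) for t in self.te_ms))
        object.__setattr__(self, "voxel_mm", tuple(float(v) for v in self.voxel_mm))
        if not self.tr_s > 0:
            raise ValueError(f"tr_s must be positive, got {self.tr_s}")
        if not 0 < self.flip_deg <= 180:
            raise ValueError(f"flip_deg must be in (0, 180], got {self.flip_deg}")
        if not 0 < self.cal_factor <= 1.5:
            raise ValueError(f"cal_factor must be in (0, 1.5], got {self.cal_factor}")
        te = np.asarray(self.te_ms)
        if te.size == 0 or np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ValueError("te_ms must be strictly increasing and positive")
        if len(self.voxel_mm) != 3 or any(v <= 0 for v in self.voxel_mm):
            raise ValueError("voxel_mm must be three positive lengths")

    @property
    def flip_eff_deg(self) -> float:
        """Effective flip angle = cal_factor x nominal, degrees."""
        return self.cal_factor * self.flip_deg

    @property
    def n_echoes(self) -> int:
        return len(self.te_ms)

    @property
    def te_s(self) -> np.ndarray:
        return np.asarray(self.te_ms) * 1e-3

    # ------------------------------------------------------------------ JSON
    def to_dict(self) -> dict:
        return {
            "tr_s": self.tr_s,
            "flip_deg": self.flip_deg,
            "cal_factor": self.cal_factor,
            "te_ms": list(self.te_ms),
            "voxel_mm": list(self.voxel_mm),
            "field_T": self.field_t,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcqProtocol":
        d = dict(d)
        if "te_ms" not in d and {"te1_ms", "dte_ms", "n_echoes"} <= d.keys():
            te1, dte, n = d.pop("te1_ms"), d.pop("dte_ms"), d.pop("n_echoes")
            d["te_ms"] = [te1 + dte * i for i in range(int(n))]
        field = d.pop("field_T", d.pop("field_t", 3.0))
        return cls(
            tr_s=d["tr_s"],
            flip_deg=d["flip_deg"],
            te_ms=tuple(d["te_ms"]),
            cal_factor=d.get("cal_factor", 1.0),
            voxel_mm=tuple(d.get("voxel_mm", (1.04, 1.38, 1.5))),
            field_t=field,
        )

    def save_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load_json(cls, path) -> "AcqProtocol":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def from_echo_train(cls, te1_ms: float, dte_ms: float, n_echoes: int, **kw) -> "AcqProtocol":
        te = tuple(te1_ms + dte_ms * i for i in range(n_echoes))
        return cls(te_ms=te, **kw)

    @classmethod
    def default_3t(cls, n_echoes: int = 32) -> "AcqProtocol":
        """Long-TR 3T protocol: TR 10 s, 90 deg nominal, 0.8 calibration,
        TE1 3.87 ms, dTE 4.08 ms."""
        return cls.from_echo_train(
            3.87, 4.08, n_echoes, tr_s=10.0, flip_deg=90.0, cal_factor=0.8,
            voxel_mm=(1.04, 1.38, 1.5), field_t=3.0,
        )


@dataclasses.dataclass(frozen=True)
class TissueParams:
    """Relaxation and water-content parameters of one tissue class."""

    label: str
    water_pct: float
    t1_s: float
    t2star_ms: float
    freq_offset_ppm: float = 0.0

    def __post_init__(self):
        if not 0 <= self.water_pct <= 100:
            raise ValueError(f"water_pct must be in [0, 100], got {self.water_pct}")
        if not self.t1_s > 0:
            raise ValueError(f"t1_s must be positive, got {self.t1_s}")
        if not self.t2star_ms > 0:
            raise ValueError(f"t2star_ms must be positive, got {self.t2star_ms}")


def _check_physics_args(tr_s, t1_s, flip_eff_deg) -> None:
    if np.any(np.asarray(tr_s) <= 0):
        raise ValueError("tr_s must be positive")
    if np.any(np.asarray(t1_s) <= 0):
        raise ValueError("t1_s must be positive")
    f = np.asarray(flip_eff_deg)
    if np.any(f <= 0) or np.any(f > 180):
        raise ValueError("flip_eff_deg must be in (0, 180]")


def steady_state_factor(tr_s, t1_s, flip_eff_deg):
    """Longitudinal steady-state factor (1 - E1) / (1 - cos(a) E1).

    E1 = exp(-TR/T1). The factor lies in (0, 1]; it reduces the available
    magnetization when TR is not much longer than T1. Accepts scalars or
    broadcastable arrays.
    """
    _check_physics_args(tr_s, t1_s, flip_eff_deg)
    e1 = np.exp(-np.asarray(tr_s, float) / np.asarray(t1_s, float))
    cosa = np.cos(np.deg2rad(np.asarray(flip_eff_deg, float)))
    out = (1.0 - e1) / (1.0 - cosa * e1)
    return out if out.ndim else float(out)


def saturation_level(tr_s, t1_s, flip_eff_deg):
    """Fractional signal loss due to incomplete T1 recovery, 1 - steady-state factor."""
    out = 1.0 - np.asarray(steady_state_factor(tr_s, t1_s, flip_eff_deg))
    return out if out.ndim else float(out)


def tr_for_saturation(level: float, t1_s: float, flip_eff_deg: float,
                      tol_s: float = 1e-4) -> float:
    """Smallest TR at which the saturation level drops to ``level``.

    Solved by bisection to ``tol_s`` seconds; at 90 degrees this equals
    ``-t1 * ln(level)`` in closed form (used as a test oracle, not here).
    """
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    _check_physics_args(1.0, t1_s, flip_eff_deg)
    lo = tol_s
    hi = t1_s
    while saturation_level(hi, t1_s, flip_eff_deg) > level:
        hi *= 2.0
        if hi > 1e6 * t1_s:  # pragma: no cover - unreachable for level>0
            raise ValueError("saturation level not reachable")
    while hi - lo > tol_s:
        mid = 0.5 * (lo + hi)
        if saturation_level(mid, t1_s, flip_eff_deg) > level:
            lo = mid
        else:
            hi = mid
    return hi


def flip_max_for_saturation(tr_s: float, t1_s: float, level: float,
                            tol_deg: float = 1e-3) -> float:
    """Largest flip angle in (0, 90] keeping saturation at or below ``level``.

    Saturation grows monotonically with flip angle on (0, 90]; returns 90
    when even a 90-degree pulse satisfies the limit. Bisection to
    ``tol_deg`` degrees.
    """
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if saturation_level(tr_s, t1_s, 90.0) <= level:
        return 90.0
    lo, hi = tol_deg, 90.0
    while hi - lo > tol_deg:
        mid = 0.5 * (lo + hi)
        if saturation_level(tr_s, t1_s, mid) <= level:
            lo = mid
        else:
            hi = mid
    return lo


def snr_per_unit_time(tr_s, t1_s, flip_eff_deg):
    """Relative SNR efficiency, steady-state factor x sin(flip) / sqrt(TR).

    A ranking measure for comparing TR choices at fixed readout; absolute
    scaling is arbitrary.
    """
    f = np.asarray(steady_state_factor(tr_s, t1_s, flip_eff_deg))
    out = f * np.sin(np.deg2rad(np.asarray(flip_eff_deg, float))) / np.sqrt(
        np.asarray(tr_s, float))
    return out if out.ndim else float(out)


def signal_model(m0: float, protocol: AcqProtocol, tissue: TissueParams,
                 b1plus: float = 1.0, b1minus: float = 1.0, gz: float = 0.0,
                 phi0: float = 0.0) -> np.ndarray:
    """Complex multi-echo signal of one voxel.

    Magnitude per echo: ``m0 * f(TR, T1, a_eff*b1+) * sin(a_eff*b1+) * b1-
    * sinc(gamma/2 * gz * dz * TE) * exp(-TE/T2*)``; phase per echo:
    ``phi0 + 2 pi df TE`` with ``df`` from the tissue ppm offset at the
    protocol field strength. ``gz`` is the through-slice background gradient
    in T/m; ``dz`` is the excited slice thickness.
    """
    if b1plus <= 0 or b1minus <= 0:
        raise ValueError("b1plus and b1minus must be positive")
    flip = protocol.flip_eff_deg * b1plus
    f = steady_state_factor(protocol.tr_s, tissue.t1_s, flip)
    te = protocol.te_s
    dz_m = protocol.voxel_mm[2] * 1e-3
    mag = (m0 * f * math.sin(math.radians(flip)) * b1minus
           * sinc(0.5 * protocol.gamma * gz * dz_m * te)
           * np.exp(-te / (tissue.t2star_ms * 1e-3)))
    df_hz = tissue.freq_offset_ppm * 1e-6 * protocol.gamma * protocol.field_t / (2 * np.pi)
    phase = phi0 + 2 * np.pi * df_hz * te
    return mag * np.exp(1j * phase)
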