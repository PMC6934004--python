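"""NIfTI / JSON input-output and the 4D echo-series container."""
from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np

from .acquisition import AcqProtocol

__all__ = [
    "EchoSeriesVolume",
    "save_volume",
    "load_volume",
    "save_echo_series",
    "load_echo_series",
]


@dataclasses.dataclass
class EchoSeriesVolume:
    """4D magnitude + phase multi-echo dataset with spatial metadata.

    ``magnitude`` and ``phase`` are ``(nx, ny, nz, n_echoes)`` arrays; phase
    is in radians, wrapped to (-pi, pi]. ``affine`` is a 4x4 RAS transform in
    millimetres.
    """

    magnitude: np.ndarray
    phase: np.ndarray
    protocol: AcqProtocol
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.magnitude.ndim != 4:
            raise ValueError("magnitude must be 4D (x, y, z, echo)")
        if self.magnitude.shape != self.phase.shape:
            raise ValueError("magnitude and phase shapes differ")
        if self.magnitude.shape[-1] != self.protocol.n_echoes:
            raise ValueError(
                f"series has {self.magnitude.shape[-1]} echoes but protocol lists "
                f"{self.protocol.n_echoes}")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude must be non-negative")
        if self.affine is None:
            self.affine = np.diag([*self.protocol.voxel_mm, 1.0])
        else:
            self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.magnitude.shape[:3]


def save_volume(data: np.ndarray, affine: np.ndarray, path, dtype=np.float32) -> None:
    """Write an array as uncompressed NIfTI (deterministic bytes)."""
    img = nib.Nifti1Image(np.asarray(data).astype(dtype), np.asarray(affine))
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def save_echo_series(series: EchoSeriesVolume, out_dir, prefix: str = "echo") -> dict:
    """Write magnitude/phase 4D NIfTI plus the acquisition sidecar JSON.

    Returns the paths written, keyed by role.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "magnitude": out / f"{prefix}_mag.nii",
        "phase": out / f"{prefix}_phase.nii",
        "sidecar": out / f"{prefix}_acq.json",
    }
    save_volume(series.magnitude, series.affine, paths["magnitude"])
    save_volume(series.phase, series.affine, paths["phase"])
    series.protocol.save_json(paths["sidecar"])
    return paths


def load_echo_series(magnitude_path, phase_path, sidecar_path) -> EchoSeriesVolume:
    mag, affine = load_volume(magnitude_path)
    phase, _ = load_volume(phase_path)
    protocol = AcqProtocol.load_json(sidecar_path)
    return EchoSeriesVolume(magnitude=mag, phase=phase, protocol=protocol, affine=affine)
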