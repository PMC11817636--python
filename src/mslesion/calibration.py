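"""Flat-field / dark-frame reflectance calibration and cube preprocessing.

Raw multispectral counts are converted to reflectance with the standard
two-reference correction

    R(i, j) = k * (S_lesion - S_dark) / (S_neutral - S_dark)

per band, where k is the known reflectance of the neutral-gray reference.
Because the neutral frame shares the illumination field of the lesion frame,
the division cancels spatial gain: the result depends only on the scene.
Cubes are then resized to the network input side (area averaging) and can be
restricted to the three bands closest to the channel peaks of a color camera
(447, 524, 671 nm).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

RGB_BANDS = (447.0, 524.0, 671.0)

#: minimum valid denominator (counts) for the flat-field division
DENOMINATOR_EPS = 1.0


class CalibrationError(ValueError):
    """Raised for corrupt captures (too many invalid denominator pixels)."""


@dataclass
class ReflectanceCube:
    """Calibrated H x W x B reflectance cube in [0, 1] with a wavelength axis."""

    values: np.ndarray                      # (H, W, B) float
    wavelengths_nm: tuple[float, ...]
    label: str | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[2] != len(self.wavelengths_nm):
            raise ValueError("cube shape inconsistent with wavelength axis")
        if not np.isfinite(self.values).all():
            raise ValueError("cube contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def band_count(self) -> int:
        return len(self.wavelengths_nm)


def _fill_invalid(band: np.ndarray, invalid: np.ndarray) -> np.ndarray:
    """Replace invalid pixels by the median of valid neighbors, growing the
    window until every hole is filled."""
    out = band.copy()
    todo = invalid.copy()
    radius = 1
    h, w = band.shape
    while todo.any():
        rows, cols = np.nonzero(todo)
        for r, c in zip(rows, cols):
            r0, r1 = max(0, r - radius), min(h, r + radius + 1)
            c0, c1 = max(0, c - radius), min(w, c + radius + 1)
            patch = out[r0:r1, c0:c1]
            ok = ~invalid[r0:r1, c0:c1]
            if ok.any():
                out[r, c] = float(np.median(patch[ok]))
                todo[r, c] = False
        radius += 1
        if radius > max(h, w):      # fully invalid band; caller already errored
            break
    return out


def calibrate(capture, k: float | None = None) -> ReflectanceCube:
    """Apply the two-reference reflectance correction to a raw capture set.

    ``k`` defaults to the capture's recorded neutral-gray reflectance.  Pixels
    whose denominator (neutral minus dark) falls at or below
    ``DENOMINATOR_EPS`` counts are filled from the local median of valid
    neighbors; more than 5% such pixels in any band marks the capture corrupt.
    """
    if k is None:
        k = capture.neutral_reflectance_k
    if not 0.0 < k < 1.0:
        raise ValueError("k must lie in (0, 1)")
    lesion = capture.lesion_frames.astype(float)
    dark = capture.dark_frames.astype(float)
    neutral = capture.neutral_frames.astype(float)
    if not lesion.shape == dark.shape == neutral.shape:
        raise ValueError("lesion/dark/neutral frames must share one shape")

    nb = lesion.shape[0]
    out = np.empty((lesion.shape[1], lesion.shape[2], nb), dtype=float)
    for b in range(nb):
        denom = neutral[b] - dark[b]
        invalid = denom <= DENOMINATOR_EPS
        frac = float(invalid.mean())
        if frac > 0.05:
            raise CalibrationError(
                f"band {capture.wavelengths_nm[b]:.0f} nm: "
                f"{frac:.1%} invalid denominator pixels (corrupt capture)")
        safe = np.where(invalid, 1.0, denom)
        r = k * (lesion[b] - dark[b]) / safe
        if invalid.any():
            r = _fill_invalid(r, invalid)
        out[:, :, b] = r
    out = np.clip(out, 0.0, 1.0)
    return ReflectanceCube(
        values=out, wavelengths_nm=tuple(capture.wavelengths_nm),
        label=capture.true_label,
        provenance={**capture.provenance, "k": k, "calibrated": True})


def resize_cube(cube: ReflectanceCube, side: int) -> ReflectanceCube:
    """Resample each band independently to ``side`` x ``side`` (area averaging)."""
    if side < 8:
        raise ValueError("side must be >= 8")
    h, w, nb = cube.shape
    if (h, w) == (side, side):
        values = cube.values.copy()
    else:
        values = np.empty((side, side, nb), dtype=float)
        for b in range(nb):
            img = Image.fromarray(cube.values[:, :, b].astype(np.float32), mode="F")
            values[:, :, b] = np.asarray(
                img.resize((side, side), Image.Resampling.BOX), dtype=float)
        values = np.clip(values, 0.0, 1.0)
    return ReflectanceCube(
        values=values, wavelengths_nm=cube.wavelengths_nm, label=cube.label,
        provenance={**cube.provenance, "resized_to": side})


def select_bands(cube: ReflectanceCube, wanted_nm) -> ReflectanceCube:
    """Return the sub-cube at the requested wavelengths, in the given order."""
    indices = []
    for wl in wanted_nm:
        matches = [i for i, w in enumerate(cube.wavelengths_nm)
                   if abs(w - wl) < 1e-9]
        if not matches:
            raise ValueError(f"wavelength {wl} nm not present in cube")
        indices.append(matches[0])
    return ReflectanceCube(
        values=cube.values[:, :, indices].copy(),
        wavelengths_nm=tuple(float(w) for w in wanted_nm),
        label=cube.label,
        provenance={**cube.provenance, "band_subset": [float(w) for w in wanted_nm]})


def write_cube(cube: ReflectanceCube, path: str | Path) -> Path:
    """Multi-page float32 TIFF (page order = wavelength order) + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, cube.values.transpose(2, 0, 1).astype(np.float32))
    sidecar = {
        "wavelengths_nm": list(cube.wavelengths_nm),
        "label": cube.label,
        "provenance": cube.provenance,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_cube(path: str | Path) -> ReflectanceCube:
    path = Path(path)
    values = np.asarray(tifffile.imread(path), dtype=float)
    meta = json.loads(path.with_suffix(".json").read_text())
    return ReflectanceCube(
        values=values.transpose(1, 2, 0),
        wavelengths_nm=tuple(float(w) for w in meta["wavelengths_nm"]),
        label=meta.get("label"), provenance=meta.get("provenance", {}))
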