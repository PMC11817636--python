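"""Synthetic multispectral skin-lesion phantoms.

Emulates an LED-ring multispectral dermatology camera: for each lesion it
produces raw 12-bit sensor frames at eight narrow bands (414-995 nm) together
with the dark frame and neutral-gray reference frame needed for reflectance
calibration.  Lesions are soft-edged, irregular ellipses whose interior
reflectance is attenuated by a Beer-Lambert-style mixture of skin
chromophores (melanin, oxy-/deoxy-hemoglobin, water), so the class signal is
spectral, controllable, and known exactly per pixel.

The ``separability_mode`` knob decides where the class signal lives:

* ``all_bands`` - classes differ in melanin, hemoglobin and water content, so
  every band is informative (the realistic default).
* ``nir_only`` - classes share identical visible-band chromophore content and
  differ only in water, whose absorption here is non-zero only at
  735/890/995 nm; the RGB-like bands (447/524/671 nm) carry no class signal.
* ``none`` - all classes are drawn from identical ranges (negative control).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter

CLASS_NAMES = ("nevus", "melanoma", "bcc")
DEFAULT_BANDS = (414.0, 447.0, 477.0, 524.0, 671.0, 735.0, 890.0, 995.0)
CHROMOPHORES = ("melanin", "oxyhemoglobin", "deoxyhemoglobin", "water")

# Relative absorption of each chromophore at the 8 device bands (dimensionless,
# shipped constants).  Shapes follow the qualitative optics: melanin decays
# monotonically from violet to NIR; hemoglobins peak in the blue/green with a
# deep minimum in the red; water is transparent in the visible and rises
# steeply toward 995 nm.  Water is exactly zero at every visible band so that
# water-only class contrast is invisible to the RGB-like subset.
_REFERENCE_ABSORPTION = {
    "melanin":         (1.00, 0.85, 0.72, 0.55, 0.30, 0.22, 0.12, 0.08),
    "oxyhemoglobin":   (1.00, 0.55, 0.30, 0.45, 0.04, 0.06, 0.10, 0.12),
    "deoxyhemoglobin": (0.95, 0.80, 0.45, 0.40, 0.10, 0.08, 0.06, 0.05),
    "water":           (0.00, 0.00, 0.00, 0.00, 0.00, 0.04, 0.15, 0.60),
}

# Background (lesion-free) skin reflectance at the reference bands: skin is
# darker in the violet/blue and bright in the red/NIR.
_REFERENCE_SKIN = (0.30, 0.35, 0.40, 0.45, 0.62, 0.68, 0.72, 0.70)


class PhantomError(ValueError):
    """Raised for invalid phantom configurations or mis-scaled renders."""


@dataclass(frozen=True)
class SpectralBandSet:
    """Ordered set of LED band peak wavelengths, in nm."""

    wavelengths_nm: tuple[float, ...] = DEFAULT_BANDS

    def __post_init__(self):
        w = self.wavelengths_nm
        if len(w) == 0 or any(x <= 0 for x in w):
            raise PhantomError("wavelengths must be positive")
        if any(b <= a for a, b in zip(w, w[1:])):
            raise PhantomError("wavelengths must be strictly increasing")

    @property
    def band_count(self) -> int:
        return len(self.wavelengths_nm)


@dataclass(frozen=True)
class ChromophorePanel:
    """Relative absorption coefficient of each chromophore at each band."""

    bands: SpectralBandSet
    absorption: dict[str, tuple[float, ...]]

    def __post_init__(self):
        for name, vals in self.absorption.items():
            if len(vals) != self.bands.band_count:
                raise PhantomError(f"{name}: one absorption value per band required")
            if any(v < 0 for v in vals):
                raise PhantomError(f"{name}: absorption must be non-negative")
        mel = self.absorption.get("melanin")
        if mel is not None and any(b > a for a, b in zip(mel, mel[1:])):
            raise PhantomError("melanin absorption must be non-increasing with wavelength")

    def coefficient(self, chromophore: str, wavelength_nm: float) -> float:
        i = self.bands.wavelengths_nm.index(wavelength_nm)
        return self.absorption[chromophore][i]

    def matrix(self) -> np.ndarray:
        """(n_chromophores, n_bands) array in CHROMOPHORES order."""
        return np.array([self.absorption[c] for c in CHROMOPHORES])


def build_default_chromophore_panel(bands: SpectralBandSet | None = None) -> ChromophorePanel:
    """Interpolate the shipped absorption table onto ``bands``."""
    bands = bands or SpectralBandSet()
    wl = np.asarray(bands.wavelengths_nm)
    ref = np.asarray(DEFAULT_BANDS)
    absorption = {
        name: tuple(np.interp(wl, ref, np.asarray(vals)))
        for name, vals in _REFERENCE_ABSORPTION.items()
    }
    return ChromophorePanel(bands=bands, absorption=absorption)


def background_reflectance(bands: SpectralBandSet) -> np.ndarray:
    return np.interp(np.asarray(bands.wavelengths_nm),
                     np.asarray(DEFAULT_BANDS), np.asarray(_REFERENCE_SKIN))


Range = tuple[float, float]

# Class-conditional chromophore concentration ranges (dimensionless optical
# load).  ``all_bands``: melanotic melanoma, lightly pigmented vascular BCC,
# intermediate nevus.  ``nir_only``: identical pigment/blood across classes,
# water alone separates them (invisible below 735 nm by construction).
_RANGES_ALL: dict[str, dict[str, Range]] = {
    "nevus":    {"melanin": (0.30, 0.60), "oxyhemoglobin": (0.20, 0.50),
                 "deoxyhemoglobin": (0.10, 0.30), "water": (0.20, 0.40)},
    "melanoma": {"melanin": (1.00, 1.60), "oxyhemoglobin": (0.30, 0.60),
                 "deoxyhemoglobin": (0.40, 0.80), "water": (0.50, 0.90)},
    "bcc":      {"melanin": (0.05, 0.25), "oxyhemoglobin": (0.60, 1.00),
                 "deoxyhemoglobin": (0.20, 0.50), "water": (0.80, 1.20)},
}
_SHARED_VIS = {"melanin": (0.50, 0.70), "oxyhemoglobin": (0.30, 0.50),
               "deoxyhemoglobin": (0.20, 0.40)}
_RANGES_NIR: dict[str, dict[str, Range]] = {
    "nevus":    {**_SHARED_VIS, "water": (0.10, 0.30)},
    "melanoma": {**_SHARED_VIS, "water": (1.20, 1.60)},
    "bcc":      {**_SHARED_VIS, "water": (2.40, 3.00)},
}
_RANGES_NONE: dict[str, dict[str, Range]] = {
    cls: {**_SHARED_VIS, "water": (0.20, 0.60)} for cls in CLASS_NAMES
}

_IRREGULARITY = {"nevus": 0.08, "melanoma": 0.25, "bcc": 0.12}


@dataclass
class SimulationConfig:
    """Full description of one simulated acquisition campaign."""

    frame_shape: tuple[int, int] = (192, 256)       # (height, width), px
    bit_depth: int = 12
    dark_offset_mean: float = 48.0
    dark_noise_sd: float = 1.0
    sensor_noise_sd: float = 2.0
    neutral_reflectance_k: float = 0.5
    illumination_gain: float = 1.0                  # global multiplier on the gain map
    illumination_curvature: tuple[float, float, float] = (0.12, 0.18, 0.05)
    separability_mode: str = "all_bands"
    class_counts: dict[str, int] = field(
        default_factory=lambda: {"nevus": 327, "melanoma": 112, "bcc": 70})
    class_concentration_ranges: dict[str, dict[str, Range]] | None = None
    bands: SpectralBandSet = field(default_factory=SpectralBandSet)
    seed: int = 0
    store_truth: bool = True

    def __post_init__(self):
        if not 8 <= self.bit_depth <= 16:
            raise PhantomError("bit_depth must be in [8, 16]")
        if not 0.0 < self.neutral_reflectance_k < 1.0:
            raise PhantomError("neutral_reflectance_k must lie in (0, 1)")
        if self.separability_mode not in ("all_bands", "nir_only", "none"):
            raise PhantomError(f"unknown separability_mode {self.separability_mode!r}")
        if self.class_concentration_ranges is None:
            table = {"all_bands": _RANGES_ALL, "nir_only": _RANGES_NIR,
                     "none": _RANGES_NONE}[self.separability_mode]
            self.class_concentration_ranges = {
                cls: dict(rngs) for cls, rngs in table.items()}
        for cls, rngs in self.class_concentration_ranges.items():
            for chromo, (lo, hi) in rngs.items():
                if lo > hi:
                    raise PhantomError(f"{cls}/{chromo}: low > high")

    @property
    def max_count(self) -> int:
        return 2 ** self.bit_depth - 1


@dataclass(frozen=True)
class PhantomLesion:
    """Geometric and biochemical description of one synthetic lesion."""

    class_label: str
    center: tuple[float, float]          # (row, col), px
    semi_axes: tuple[float, float]       # px
    orientation: float                   # rad
    border_softness: float               # Gaussian edge sigma, px
    border_irregularity: float
    irregularity_coeffs: tuple[tuple[int, float, float], ...]  # (harmonic, amp, phase)
    chromophore_concentrations: dict[str, float]


@dataclass
class RawCaptureSet:
    """Raw integer frames for one lesion: per-band lesion/dark/neutral triplets."""

    lesion_frames: np.ndarray            # (B, H, W) uint16
    dark_frames: np.ndarray
    neutral_frames: np.ndarray
    wavelengths_nm: tuple[float, ...]
    true_label: str
    bit_depth: int
    neutral_reflectance_k: float
    lesion_mask: np.ndarray | None = None          # ground truth, tests only
    true_reflectance: np.ndarray | None = None     # (H, W, B), tests only
    provenance: dict = field(default_factory=dict)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.lesion_frames.shape[1:]


def synthesize_lesion(config: SimulationConfig, label: str,
                      rng: np.random.Generator) -> PhantomLesion:
    """Draw one lesion's geometry and chromophore load from its class ranges."""
    if label not in config.class_concentration_ranges:
        raise PhantomError(f"unknown class label {label!r}")
    h, w = config.frame_shape
    scale = min(h, w)
    center = (h / 2 + rng.uniform(-0.06, 0.06) * h,
              w / 2 + rng.uniform(-0.06, 0.06) * w)
    a = rng.uniform(0.18, 0.30) * scale
    b = a * rng.uniform(0.6, 1.0)
    # class-dependent border irregularity is cosmetic realism; under the
    # controlled separability modes geometry must not carry class signal
    if config.separability_mode == "all_bands":
        irr = _IRREGULARITY.get(label, 0.1)
    else:
        irr = 0.1
    coeffs = tuple(
        (n, float(rng.uniform(0.3, 1.0)), float(rng.uniform(0, 2 * np.pi)))
        for n in (2, 3, 5))
    conc = {chromo: float(rng.uniform(lo, hi))
            for chromo, (lo, hi) in config.class_concentration_ranges[label].items()}
    return PhantomLesion(
        class_label=label, center=center, semi_axes=(a, b),
        orientation=float(rng.uniform(0, np.pi)),
        border_softness=float(rng.uniform(1.0, 2.5) * scale / 64),
        border_irregularity=irr, irregularity_coeffs=coeffs,
        chromophore_concentrations=conc)


def lesion_footprint(lesion: PhantomLesion, frame_shape: tuple[int, int]) -> np.ndarray:
    """Soft occupancy map in [0, 1]: irregular ellipse blurred at the border."""
    h, w = frame_shape
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    dr, dc = rows - lesion.center[0], cols - lesion.center[1]
    ct, st = np.cos(lesion.orientation), np.sin(lesion.orientation)
    u = (ct * dr + st * dc) / lesion.semi_axes[0]
    v = (-st * dr + ct * dc) / lesion.semi_axes[1]
    rho = np.hypot(u, v)
    theta = np.arctan2(v, u)
    boundary = np.ones_like(theta)
    for n, amp, phase in lesion.irregularity_coeffs:
        boundary += lesion.border_irregularity * amp * np.cos(n * theta + phase)
    boundary = np.maximum(boundary, 0.3)
    hard = (rho <= boundary).astype(float)
    if lesion.border_softness > 0:
        return gaussian_filter(hard, lesion.border_softness)
    return hard


def illumination_field(config: SimulationConfig) -> np.ndarray:
    """Smooth spatial gain map shared by lesion and neutral frames, max 1."""
    h, w = config.frame_shape
    y = np.linspace(-1, 1, h)[:, None]
    x = np.linspace(-1, 1, w)[None, :]
    cy, cx, cxy = config.illumination_curvature
    f = 1.0 - cy * y ** 2 - cx * x ** 2 + cxy * x * y
    return f / f.max()


def _band_amplitude(config: SimulationConfig, bg: np.ndarray) -> float:
    """Per-band illumination amplitude keeping the brightest pixel at ~90% FSR."""
    top = max(config.neutral_reflectance_k, float(bg.max()))
    return config.illumination_gain * 0.9 * \
        (config.max_count - config.dark_offset_mean) / top


def render_capture(lesion: PhantomLesion, panel: ChromophorePanel,
                   config: SimulationConfig, rng: np.random.Generator) -> RawCaptureSet:
    """Render the raw lesion/dark/neutral frame triplets for one lesion.

    Forward model per band: counts = dark_offset + I(i,j) * R(i,j) + noise,
    where R inside the lesion footprint is the background skin reflectance
    attenuated by exp(-sum_c concentration_c * absorption_c(band)).
    """
    h, w = config.frame_shape
    bands = panel.bands
    nb = bands.band_count
    soft = lesion_footprint(lesion, (h, w))
    bg = background_reflectance(bands)
    conc = np.array([lesion.chromophore_concentrations.get(c, 0.0)
                     for c in CHROMOPHORES])
    absorb = conc @ panel.matrix()                     # per band optical load
    r_true = bg[None, None, :] * np.exp(-soft[:, :, None] * absorb[None, None, :])
    field_map = illumination_field(config)
    amp = _band_amplitude(config, bg)
    gain = field_map * amp                             # (H, W)

    def _quantize(analog: np.ndarray) -> np.ndarray:
        return np.clip(np.rint(analog), 0, config.max_count).astype(np.uint16)

    lesion_frames = np.empty((nb, h, w), dtype=np.uint16)
    neutral_frames = np.empty((nb, h, w), dtype=np.uint16)
    dark_frames = np.empty((nb, h, w), dtype=np.uint16)
    for b in range(nb):
        noise = rng.normal(0, config.sensor_noise_sd, (h, w)) \
            if config.sensor_noise_sd > 0 else 0.0
        lesion_frames[b] = _quantize(config.dark_offset_mean + gain * r_true[:, :, b] + noise)
        noise = rng.normal(0, config.sensor_noise_sd, (h, w)) \
            if config.sensor_noise_sd > 0 else 0.0
        neutral_frames[b] = _quantize(
            config.dark_offset_mean + gain * config.neutral_reflectance_k + noise)
        noise = rng.normal(0, config.dark_noise_sd, (h, w)) \
            if config.dark_noise_sd > 0 else 0.0
        dark_frames[b] = _quantize(config.dark_offset_mean + noise)

    saturated = np.mean(lesion_frames == config.max_count)
    if saturated > 0.10:
        raise PhantomError(
            f"{saturated:.0%} of lesion pixels saturated: illumination mis-scaled")

    return RawCaptureSet(
        lesion_frames=lesion_frames, dark_frames=dark_frames,
        neutral_frames=neutral_frames, wavelengths_nm=bands.wavelengths_nm,
        true_label=lesion.class_label, bit_depth=config.bit_depth,
        neutral_reflectance_k=config.neutral_reflectance_k,
        lesion_mask=soft > 0.5,
        true_reflectance=r_true if config.store_truth else None,
        provenance={"seed": config.seed, "label": lesion.class_label})


def expected_lesion_reflectance(lesion: PhantomLesion,
                                panel: ChromophorePanel) -> np.ndarray:
    """Noise-free interior reflectance per band (footprint fully inside)."""
    bg = background_reflectance(panel.bands)
    conc = np.array([lesion.chromophore_concentrations.get(c, 0.0)
                     for c in CHROMOPHORES])
    return bg * np.exp(-conc @ panel.matrix())


def simulate_dataset(config: SimulationConfig) -> list[RawCaptureSet]:
    """Render the full campaign: ``class_counts`` captures per class, seeded."""
    if any(n <= 0 for n in config.class_counts.values()):
        raise PhantomError("class_counts must be positive")
    panel = build_default_chromophore_panel(config.bands)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    captures: list[RawCaptureSet] = []
    for label in config.class_counts:
        for i in range(config.class_counts[label]):
            lesion = synthesize_lesion(config, label, rng)
            cap = render_capture(lesion, panel, config, rng)
            cap.provenance.update({"index": i, "label": label, "seed": config.seed})
            captures.append(cap)
    return captures


def write_capture(capture: RawCaptureSet, out_dir: str | Path) -> Path:
    """One directory per capture: 16-bit PNGs plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for b, wl in enumerate(capture.wavelengths_nm):
        stem = f"band_{wl:.0f}"
        iio.imwrite(out / f"{stem}_lesion.png", capture.lesion_frames[b])
        iio.imwrite(out / f"{stem}_dark.png", capture.dark_frames[b])
        iio.imwrite(out / f"{stem}_neutral.png", capture.neutral_frames[b])
    sidecar = {
        "label": capture.true_label,
        "wavelengths_nm": list(capture.wavelengths_nm),
        "bit_depth": capture.bit_depth,
        "k": capture.neutral_reflectance_k,
        "provenance": capture.provenance,
    }
    (out / "capture.json").write_text(json.dumps(sidecar, indent=2))
    return out


def read_capture(capture_dir: str | Path) -> RawCaptureSet:
    d = Path(capture_dir)
    meta = json.loads((d / "capture.json").read_text())
    wavelengths = tuple(float(w) for w in meta["wavelengths_nm"])
    stacks = {}
    for kind in ("lesion", "dark", "neutral"):
        stacks[kind] = np.stack([
            np.asarray(iio.imread(d / f"band_{wl:.0f}_{kind}.png"), dtype=np.uint16)
            for wl in wavelengths])
    return RawCaptureSet(
        lesion_frames=stacks["lesion"], dark_frames=stacks["dark"],
        neutral_frames=stacks["neutral"], wavelengths_nm=wavelengths,
        true_label=meta["label"], bit_depth=meta["bit_depth"],
        neutral_reflectance_k=meta["k"], provenance=meta.get("provenance", {}))
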