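"""Synthetic multispectral scene generator.

Emulates a sequential-illumination MSI acquisition: 7 illuminants x 3 RGB
sensors = 21 spectral channels, 11 tissue classes with smooth class-specific
reflectance spectra, Poisson photon noise, irregular foreground masks, and
grouping of scenes into "specimens" so that train/validation/test splits can
be made leakage-free at the specimen level.

The acquisition protocol mirrors the physical system: a UV+NIR blocking
filter sits in front of the sensors for every illuminant except the IR one,
for which it is removed.  Illuminant peak powers are calibrated so that the
21 channel SNRs span roughly 9-49 dB, with broadband channels at the top,
matched narrowband/sensor pairs in the 30 dB range, and the UV channels at
the bottom (the blocker makes UV light nearly undetectable).
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .radiometry import (
    DEFAULT_GRID_NM,
    ILLUMINANT_ROSTER,
    KIND_ILLUMINANT,
    KIND_QE,
    SENSOR_ROSTER,
    ChannelSpec,
    ConfigurationError,
    SpectralFunction,
    ValidationError,
    all_channel_ids,
    energy_to_photon_rate,
)

logger = logging.getLogger(__name__)

#: The 11 head-and-neck tissue classes, alphabetical.
TISSUE_CLASSES: tuple[str, ...] = (
    "artery", "bone", "cartilage", "dura", "fascia", "fat",
    "muscle", "nerve", "parotid", "skin", "vein",
)

#: Illuminants acquired with the blocking filter removed.
NO_FILTER_ILLUMINANTS: tuple[str, ...] = ("ir808",)

FULL_WELL = 65535  # 16-bit full-well clip for stored photon counts

# Peak spectral powers (W m^-2 nm^-1), calibrated once so the default SNR
# table spans ~9-49 dB with the qualitative ordering of a real sequential-MSI
# microscope: broadband white highest, matched narrowband pairs ~30 dB,
# UV lowest (blocked).
DEFAULT_ILLUMINANTS: dict[str, dict] = {
    "arri_white": {"kind": "broadband", "support_nm": (400.0, 810.0),
                   "edge_nm": 10.0, "peak_power": 1.0e-2},
    "sony_white": {"kind": "broadband", "support_nm": (450.0, 700.0),
                   "edge_nm": 10.0, "peak_power": 8.4e-4},
    "uv405": {"kind": "narrowband", "peak_nm": 405.0, "fwhm_nm": 10.0,
              "peak_power": 1.1e-2},
    "blue445": {"kind": "narrowband", "peak_nm": 445.0, "fwhm_nm": 10.0,
                "peak_power": 4.0e-3},
    "green525": {"kind": "narrowband", "peak_nm": 525.0, "fwhm_nm": 10.0,
                 "peak_power": 4.2e-3},
    "red638": {"kind": "narrowband", "peak_nm": 638.0, "fwhm_nm": 10.0,
               "peak_power": 3.4e-3},
    "ir808": {"kind": "narrowband", "peak_nm": 808.0, "fwhm_nm": 12.0,
              "peak_power": 6.3e-3},
}

DEFAULT_SENSOR: dict = {
    # main visible lobes (Gaussian: center, sigma, peak QE), plus a small
    # UV shoulder and a flat color-filter cross-talk pedestal over 400-700 nm
    # (real dyed color filters leak a few percent across the visible band)
    "R": {"center_nm": 615.0, "sigma_nm": 45.0, "peak_qe": 0.70,
          "nir_peak_qe": 0.30, "uv_peak_qe": 0.08, "pedestal_qe": 0.05},
    "G": {"center_nm": 540.0, "sigma_nm": 42.0, "peak_qe": 0.73,
          "nir_peak_qe": 0.22, "uv_peak_qe": 0.18, "pedestal_qe": 0.05},
    "B": {"center_nm": 460.0, "sigma_nm": 35.0, "peak_qe": 0.67,
          "nir_peak_qe": 0.20, "uv_peak_qe": 0.12, "pedestal_qe": 0.05},
    # shared NIR response shoulder of silicon sensors
    "nir_center_nm": 820.0,
    "nir_sigma_nm": 45.0,
    "uv_center_nm": 405.0,
    "uv_sigma_nm": 15.0,
    "pedestal_range_nm": (400.0, 700.0),
    # blocker: raised-cosine passband with a small out-of-band leak
    "blocker_passband_nm": (420.0, 700.0),
    "blocker_edge_nm": 25.0,
    "blocker_leak": 0.01,
}


@dataclass(frozen=True)
class IlluminantSet:
    """The 7 illuminant spectra keyed by the fixed roster ids."""

    curves: Mapping[str, SpectralFunction]

    def __post_init__(self) -> None:
        missing = [r for r in ILLUMINANT_ROSTER if r not in self.curves]
        if missing or len(self.curves) != len(ILLUMINANT_ROSTER):
            raise ConfigurationError(
                f"illuminant roster must have exactly {len(ILLUMINANT_ROSTER)} entries; "
                f"missing {missing}")

    def __getitem__(self, key: str) -> SpectralFunction:
        return self.curves[key]

    def in_roster_order(self) -> list[SpectralFunction]:
        return [self.curves[r] for r in ILLUMINANT_ROSTER]


@dataclass(frozen=True)
class SensorModel:
    """Three RGB quantum-efficiency curves plus the UV+NIR blocker."""

    qe: Mapping[str, SpectralFunction]
    blocker: SpectralFunction
    blocker_engaged: bool = True

    def __post_init__(self) -> None:
        for s in SENSOR_ROSTER:
            if s not in self.qe:
                raise ConfigurationError(f"missing sensor curve {s}")
        if np.any(self.blocker.values > 1.0):
            raise ValidationError("blocker transmission must lie in [0, 1]")

    def effective_qe(self, sensor: str, illuminant: str | None = None,
                     grid_nm: np.ndarray | None = None) -> SpectralFunction:
        """QE seen during acquisition under ``illuminant``.

        The blocker multiplies the QE unless it is disengaged globally or the
        illuminant is one for which the filter is physically removed.
        """
        grid = DEFAULT_GRID_NM if grid_nm is None else np.asarray(grid_nm, float)
        q = self.qe[sensor].resample(grid)
        engaged = self.blocker_engaged and (
            illuminant is None or illuminant not in NO_FILTER_ILLUMINANTS)
        if engaged:
            q = q * self.blocker.resample(grid)
        return SpectralFunction(grid, q, KIND_QE, name=f"{sensor}_effective")

    def in_roster_order(self) -> list[SpectralFunction]:
        return [self.qe[s] for s in SENSOR_ROSTER]


def _gaussian(grid: np.ndarray, center: float, sigma: float, peak: float) -> np.ndarray:
    return peak * np.exp(-0.5 * ((grid - center) / sigma) ** 2)


def _flat_top(grid: np.ndarray, lo: float, hi: float, edge: float, peak: float) -> np.ndarray:
    """Flat-top with raised-cosine edges of width ``edge`` just inside [lo, hi]."""
    v = np.zeros_like(grid)
    inside = (grid >= lo) & (grid <= hi)
    v[inside] = peak
    rise = inside & (grid < lo + edge)
    v[rise] = peak * 0.5 * (1 - np.cos(np.pi * (grid[rise] - lo) / edge))
    fall = inside & (grid > hi - edge)
    v[fall] = peak * 0.5 * (1 - np.cos(np.pi * (hi - grid[fall]) / edge))
    return v


def make_illuminants(config: Mapping[str, Mapping] | None = None,
                     grid_nm: np.ndarray | None = None) -> IlluminantSet:
    """Build the 7-illuminant roster on the standard wavelength grid.

    ``config`` overrides per-illuminant entries of ``DEFAULT_ILLUMINANTS``
    (e.g. ``{"ir808": {"peak_power": 6.3e-3}}``).  Narrowband lights are Gaussian
    lines at their nominal peaks; broadband lights are flat-tops with smooth
    edges.
    """
    grid = DEFAULT_GRID_NM if grid_nm is None else np.asarray(grid_nm, float)
    cfg = copy.deepcopy(DEFAULT_ILLUMINANTS)
    if config:
        for key, over in config.items():
            if key not in cfg:
                raise ConfigurationError(f"unknown illuminant id {key!r}")
            cfg[key].update(over)
    curves = {}
    for il in ILLUMINANT_ROSTER:
        c = cfg[il]
        if c["kind"] == "narrowband":
            sigma = c["fwhm_nm"] / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            v = _gaussian(grid, c["peak_nm"], sigma, c["peak_power"])
        else:
            lo, hi = c["support_nm"]
            v = _flat_top(grid, lo, hi, c["edge_nm"], c["peak_power"])
        curves[il] = SpectralFunction(grid, v, KIND_ILLUMINANT, name=il)
    return IlluminantSet(curves=curves)


def make_sensor(config: Mapping | None = None, blocker_engaged: bool = True,
                grid_nm: np.ndarray | None = None) -> SensorModel:
    """Build the RGB sensor model: visible Gaussian lobes + NIR shoulder.

    With the blocker engaged, the effective QE at 405 nm falls below 1% of
    the channel peak, reproducing a sensor that cannot detect UV light.
    """
    grid = DEFAULT_GRID_NM if grid_nm is None else np.asarray(grid_nm, float)
    cfg = copy.deepcopy(DEFAULT_SENSOR)
    if config:
        for key, over in config.items():
            if isinstance(over, Mapping) and isinstance(cfg.get(key), dict):
                cfg[key].update(over)
            else:
                cfg[key] = over
    qe = {}
    for s in SENSOR_ROSTER:
        c = cfg[s]
        v = _gaussian(grid, c["center_nm"], c["sigma_nm"], c["peak_qe"])
        v = v + _gaussian(grid, cfg["nir_center_nm"], cfg["nir_sigma_nm"],
                          c["nir_peak_qe"])
        v = v + _gaussian(grid, cfg["uv_center_nm"], cfg["uv_sigma_nm"],
                          c["uv_peak_qe"])
        p_lo, p_hi = cfg["pedestal_range_nm"]
        v = v + _flat_top(grid, p_lo, p_hi, 20.0, c["pedestal_qe"])
        if np.any(v > 1.0):
            raise ValidationError(f"sensor {s}: composed QE exceeds 1")
        qe[s] = SpectralFunction(grid, v, KIND_QE, name=f"qe_{s}")
    lo, hi = cfg["blocker_passband_nm"]
    trans = _flat_top(grid, lo, hi, cfg["blocker_edge_nm"], 1.0 - cfg["blocker_leak"])
    trans = trans + cfg["blocker_leak"]
    blocker = SpectralFunction(grid, np.clip(trans, 0.0, 1.0), KIND_QE, name="blocker")
    return SensorModel(qe=qe, blocker=blocker, blocker_engaged=blocker_engaged)


@dataclass
class ReflectanceLibrary:
    """Per-class mean reflectance spectra plus intra-class variation knobs.

    ``curves`` is (K, L) in [0, 1] on ``wavelengths_nm``.  ``separability``
    scales the between-class spectral offsets; ``scale_jitter_sd`` (lognormal
    sd of a per-scene multiplicative factor) and ``perturb_amplitude``
    (amplitude of a per-scene smooth additive perturbation) control
    within-class variation.
    """

    class_names: tuple[str, ...]
    wavelengths_nm: np.ndarray
    curves: np.ndarray
    separability: float
    scale_jitter_sd: float = 0.005
    perturb_amplitude: float = 0.003
    seed: int = 0

    def __post_init__(self) -> None:
        self.curves = np.asarray(self.curves, dtype=float)
        K = len(self.class_names)
        if K < 2:
            raise ValidationError("need at least two classes")
        if self.curves.shape != (K, self.wavelengths_nm.size):
            raise ValidationError("curves shape must be (K, len(grid))")
        if np.any(self.curves < 0) or np.any(self.curves > 1):
            raise ValidationError("reflectance must lie in [0, 1]")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def class_index(self, name: str) -> int:
        return self.class_names.index(name)


def _smooth_basis(grid: np.ndarray, n_basis: int, sigma_nm: float = 60.0) -> np.ndarray:
    centers = np.linspace(grid[0], grid[-1], n_basis)
    return np.stack([np.exp(-0.5 * ((grid - c) / sigma_nm) ** 2) for c in centers])


def sample_reflectance_library(
    n_classes: int = len(TISSUE_CLASSES),
    separability: float = 0.02,
    seed: int = 0,
    band_nm: tuple[float, float] | None = None,
    class_names: Sequence[str] | None = None,
    base_level: float = 0.45,
    n_basis: int = 10,
    scale_jitter_sd: float = 0.005,
    perturb_amplitude: float = 0.003,
    grid_nm: np.ndarray | None = None,
) -> ReflectanceLibrary:
    """Draw K smooth class-mean reflectance spectra from a shared bump basis.

    Each class mean is a common smooth base curve plus a class-specific random
    combination of broad Gaussian bumps whose root-mean-square amplitude over
    wavelength equals ``separability`` (absolute reflectance units).  With
    ``band_nm`` set, the class offsets are windowed to that wavelength band,
    planting all between-class information there and nowhere else.
    """
    if n_classes < 2:
        raise ValidationError("n_classes must be >= 2")
    grid = DEFAULT_GRID_NM if grid_nm is None else np.asarray(grid_nm, float)
    if class_names is None:
        if n_classes <= len(TISSUE_CLASSES):
            class_names = TISSUE_CLASSES[:n_classes]
        else:
            class_names = tuple(f"class{i}" for i in range(n_classes))
    rng = np.random.default_rng(seed)
    base_basis = _smooth_basis(grid, n_basis)

    base = base_level + 0.12 * (rng.standard_normal(n_basis) @ base_basis) / np.sqrt(n_basis)
    base = np.clip(base, 0.1, 0.9)

    if band_nm is not None:
        lo, hi = band_nm
        width = max(hi - lo, 1.0)
        window = np.exp(-0.5 * ((grid - 0.5 * (lo + hi)) / (0.25 * width)) ** 4)
        # localized bumps give several independent degrees of freedom in-band
        centers = np.linspace(lo, hi, max(4, n_basis // 2))
        basis = np.stack([np.exp(-0.5 * ((grid - c) / (0.25 * width)) ** 2)
                          for c in centers]) * window
    else:
        window = np.ones_like(grid)
        basis = base_basis

    # normalize by the basis's expected rms (class-independent), so distinct
    # classes keep distinct offsets and the rms amplitude is ~separability
    support = window > 0.05
    exp_rms = np.sqrt(np.mean((basis ** 2).sum(axis=0)[support]))
    curves = np.empty((n_classes, grid.size))
    for k in range(n_classes):
        offset = (rng.standard_normal(basis.shape[0]) @ basis) / exp_rms
        curves[k] = np.clip(base + separability * offset, 0.0, 1.0)
    return ReflectanceLibrary(
        class_names=tuple(class_names),
        wavelengths_nm=grid,
        curves=curves,
        separability=separability,
        scale_jitter_sd=scale_jitter_sd,
        perturb_amplitude=perturb_amplitude,
        seed=seed,
    )


@dataclass
class MsiCube:
    """One acquired scene: H x W x 21 photon counts plus metadata.

    Channel order is roster-major: index = 3 * illuminant + sensor, with
    sensors in R, G, B order.
    """

    pixels: np.ndarray
    specimen_id: str
    class_label: str
    scene_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 21:
            raise ValidationError("MsiCube pixels must be H x W x 21")
        if np.any(np.asarray(self.pixels, dtype=float) < 0):
            raise ValidationError("photon counts must be >= 0")

    @property
    def channel_ids(self) -> list[str]:
        return all_channel_ids()


@dataclass
class ForegroundMask:
    """Binary H x W mask; True marks tissue foreground."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValidationError("mask must be 2-d")
        if not self.mask.any():
            raise ValidationError("mask must contain at least one foreground pixel")


def channel_mean_counts(
    reflectance: np.ndarray,
    lights: IlluminantSet,
    sensor: SensorModel,
    spec: ChannelSpec,
    grid_nm: np.ndarray | None = None,
) -> np.ndarray:
    """Mean photon count per channel for a surface of the given reflectance.

    Returns a length-21 vector in roster-major channel order: for channel
    (illuminant i, sensor s), mu = sum_lambda rate_i * qe_s,eff * r(lambda)
    * dlambda * pixel_area * exposure.
    """
    grid = DEFAULT_GRID_NM if grid_nm is None else np.asarray(grid_nm, float)
    step = float(grid[1] - grid[0])
    r = np.asarray(reflectance, dtype=float)
    mu = np.empty(21)
    for i_il, il in enumerate(ILLUMINANT_ROSTER):
        rate = energy_to_photon_rate(lights[il]).resample(grid)
        for i_s, s in enumerate(SENSOR_ROSTER):
            if spec.filter_nir_uv_block:
                q = sensor.effective_qe(s, illuminant=il, grid_nm=grid).values
            else:
                q = sensor.qe[s].resample(grid)
            mu[3 * i_il + i_s] = np.sum(rate * q * r) * step \
                * spec.pixel_area_m2 * spec.exposure_s
    return mu


def _blob_mask(height: int, width: int, rng: np.random.Generator,
               coverage_range: tuple[float, float] = (0.3, 0.8),
               n_harmonics: int = 6) -> np.ndarray:
    """Irregular smooth closed contour filled as a boolean mask."""
    target = rng.uniform(*coverage_range)
    cy = height / 2 + rng.uniform(-0.05, 0.05) * height
    cx = width / 2 + rng.uniform(-0.05, 0.05) * width
    amp = rng.uniform(0.03, 0.12, size=n_harmonics)
    phase = rng.uniform(0, 2 * np.pi, size=n_harmonics)
    yy, xx = np.mgrid[0:height, 0:width]
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    dist = np.hypot(dy, dx)
    wobble = np.ones_like(theta)
    for k in range(n_harmonics):
        wobble += amp[k] * np.cos((k + 2) * theta + phase[k])
    # mean radius for target coverage of an equivalent circle
    r0 = np.sqrt(target * height * width / np.pi)
    mask = dist <= r0 * wobble
    if not mask.any():  # degenerate wobble; fall back to the plain disk
        mask = dist <= r0
    return mask


def render_cube(
    scene_class: str | np.ndarray,
    lib: ReflectanceLibrary,
    lights: IlluminantSet,
    sensor: SensorModel,
    spec: ChannelSpec,
    seed: int,
    height: int = 256,
    width: int = 256,
    coverage_range: tuple[float, float] = (0.3, 0.8),
    texture_sd: float = 0.05,
    background_reflectance: float = 0.02,
    poisson: bool = True,
    specimen_id: str = "spec0",
    scene_id: str = "",
) -> tuple[MsiCube, ForegroundMask]:
    """Render one scene: signal = light x QE x reflectance, noise = Poisson.

    ``scene_class`` is a single class name (whole foreground is one tissue)
    or an H x W integer class map (-1 = background) for composite scenes with
    several labelled regions.  Per-pixel spatial texture is a lognormal gain
    on the reflectance; per-scene intra-class variation jitters the class
    spectrum before integration.  With ``poisson=False`` the cube equals the
    mean counts exactly (deterministic mode).
    """
    rng = np.random.default_rng(seed)
    grid = lib.wavelengths_nm

    if isinstance(scene_class, str):
        mask = _blob_mask(height, width, rng, coverage_range)
        class_map = np.where(mask, lib.class_index(scene_class), -1)
        label = scene_class
    else:
        class_map = np.asarray(scene_class)
        if class_map.shape != (height, width):
            raise ValidationError("class map shape must match scene size")
        mask = class_map >= 0
        if not mask.any():
            raise ValidationError("composite scene has no foreground")
        present = sorted(set(class_map[mask].tolist()))
        label = "+".join(lib.class_names[k] for k in present)

    # per-scene realized reflectance per class present (intra-class variation)
    mu_bg = channel_mean_counts(np.full(grid.size, background_reflectance),
                                lights, sensor, spec, grid_nm=grid)
    mean = np.empty((height, width, 21), dtype=np.float64)
    mean[:] = mu_bg
    basis = _smooth_basis(grid, 8)
    for k in sorted(set(class_map[mask].tolist())):
        r = lib.curves[k] * np.exp(rng.normal(0.0, lib.scale_jitter_sd))
        perturb = (rng.standard_normal(basis.shape[0]) @ basis)
        rms = np.sqrt(np.mean(perturb ** 2))
        if rms > 0:
            perturb = perturb / rms * lib.perturb_amplitude
        r = np.clip(r + perturb, 0.0, 1.0)
        mu_k = channel_mean_counts(r, lights, sensor, spec, grid_nm=grid)
        mean[class_map == k] = mu_k

    texture = np.exp(rng.normal(0.0, texture_sd, size=(height, width)))
    texture[~mask] = 1.0
    mean = mean * texture[:, :, None]

    if poisson:
        counts = rng.poisson(mean).astype(np.float64)
        clipped = counts > FULL_WELL
        clip_rate = float(clipped.mean())
        if clip_rate > 0:
            logger.info("render_cube %s: full-well clip rate %.4f", scene_id, clip_rate)
        pixels = np.minimum(counts, FULL_WELL).astype(np.uint16)
    else:
        clip_rate = 0.0
        pixels = mean.astype(np.float32)

    meta = {
        "seed": int(seed),
        "exposure_ms": spec.exposure_ms,
        "pixel_area_um2": spec.pixel_area_um2,
        "poisson": bool(poisson),
        "clip_rate": clip_rate,
        "texture_sd": texture_sd,
    }
    cube = MsiCube(pixels=pixels, specimen_id=specimen_id, class_label=label,
                   scene_id=scene_id, meta=meta)
    return cube, ForegroundMask(mask=mask)


@dataclass
class SceneRecord:
    cube: MsiCube
    mask: ForegroundMask
    specimen_id: str
    split: str
    class_label: str
    scene_id: str


SPLIT_NAMES = ("train", "validation", "test")


def generate_dataset(
    lib: ReflectanceLibrary,
    lights: IlluminantSet,
    sensor: SensorModel,
    spec: ChannelSpec,
    seed: int,
    n_specimens: tuple[int, int, int] = (6, 2, 1),
    scenes_per_class: tuple[int, int, int] = (1, 1, 1),
    classes: Sequence[str] | None = None,
    **render_kwargs,
) -> Iterator[SceneRecord]:
    """Yield scenes grouped into specimens with leakage-free split assignment.

    Specimen ids are disjoint across splits by construction.  Each specimen
    contributes ``scenes_per_class[split]`` scenes per class.  Scene seeds are
    derived deterministically from ``seed``, so the same arguments reproduce
    the same dataset.  Scenes are yielded lazily so large datasets can be
    tiled on the fly without holding every cube in memory.
    """
    if any(n < 1 for n in n_specimens):
        raise ConfigurationError("each split needs at least one specimen")
    classes = tuple(classes) if classes is not None else lib.class_names
    counter = 0
    specimen_no = 0
    for split, n_spec, n_scene in zip(SPLIT_NAMES, n_specimens, scenes_per_class):
        for _ in range(n_spec):
            specimen_id = f"cadaver{specimen_no:02d}"
            specimen_no += 1
            for cls in classes:
                for rep in range(n_scene):
                    scene_seed = (seed * 1_000_003 + counter * 7919) % (2 ** 31)
                    scene_id = f"{specimen_id}_{cls}_{rep:02d}"
                    cube, mask = render_cube(
                        cls, lib, lights, sensor, spec, seed=scene_seed,
                        specimen_id=specimen_id, scene_id=scene_id,
                        **render_kwargs)
                    counter += 1
                    yield SceneRecord(cube=cube, mask=mask, specimen_id=specimen_id,
                                      split=split, class_label=cls, scene_id=scene_id)


def dataset_manifest(records: Iterable[SceneRecord]) -> pd.DataFrame:
    rows = [{
        "scene_id": r.scene_id,
        "specimen_id": r.specimen_id,
        "split": r.split,
        "class_label": r.class_label,
    } for r in records]
    return pd.DataFrame(rows)
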