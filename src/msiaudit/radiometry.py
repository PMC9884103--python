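"""Photon-limited radiometry of illuminant x sensor spectral channels.

A spectral channel is one (illuminant, sensor) pair.  Its signal ``S`` is the
maximum photon count a pixel can collect in one exposure: the illuminant's
spectral power is converted to a photon rate, weighted by the sensor quantum
efficiency, and integrated over wavelength, pixel area and exposure time.
Photon shot noise is Poisson, so the noise equals ``sqrt(S)`` and the channel
signal-to-noise ratio in decibels is

    SNR = 20 log10(S / sqrt(S)) = 10 log10(S),

which doubles as the channel dynamic range.  Sensor (read) noise is
deliberately excluded: modern CMOS sensors contribute < 2 electrons, far below
shot noise at the photon counts considered here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# CODATA values
PLANCK_H = 6.62607015e-34  # J s
LIGHT_SPEED_C = 299792458.0  # m / s

#: Fixed illuminant roster order used for every 3 x 7 table and for the
#: roster-major channel index (channel = 3 * illuminant + sensor).
ILLUMINANT_ROSTER: tuple[str, ...] = (
    "arri_white",
    "sony_white",
    "uv405",
    "blue445",
    "green525",
    "red638",
    "ir808",
)

SENSOR_ROSTER: tuple[str, ...] = ("R", "G", "B")

#: Default wavelength grid: 380-900 nm at 2 nm, covering the 400-810 nm
#: broadband lights plus the 808 nm IR tail.
DEFAULT_GRID_NM = np.arange(380.0, 902.0, 2.0)

KIND_ILLUMINANT = "illuminant_power"
KIND_QE = "quantum_efficiency"
_KINDS = (KIND_ILLUMINANT, KIND_QE)


class ValidationError(ValueError):
    """Raised when a spectral curve or channel spec violates its invariants."""


class ConfigurationError(ValueError):
    """Raised for roster/size mismatches in table construction."""


@dataclass(frozen=True)
class SpectralFunction:
    """A sampled curve over wavelength.

    ``kind`` is ``"illuminant_power"`` (W m^-2 nm^-1) or
    ``"quantum_efficiency"`` (dimensionless, in [0, 1]).  Wavelengths must be
    strictly increasing; values are non-negative.  Outside the sampled support
    the curve is taken to be zero.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    kind: str
    name: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "values", v)
        if self.kind not in _KINDS:
            raise ValidationError(f"unknown spectral kind {self.kind!r}")
        if w.ndim != 1 or v.ndim != 1 or w.size != v.size:
            raise ValidationError("wavelengths and values must be 1-d and of equal length")
        if w.size == 0:
            raise ValidationError("empty spectral function")
        if np.any(np.diff(w) <= 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValidationError("spectral values must be finite and >= 0")
        if self.kind == KIND_QE and np.any(v > 1.0):
            raise ValidationError("quantum efficiency must lie in [0, 1]")

    def resample(self, grid_nm: np.ndarray) -> np.ndarray:
        """Linear interpolation onto ``grid_nm``; zero outside the support."""
        return np.interp(grid_nm, self.wavelengths_nm, self.values, left=0.0, right=0.0)

    def scaled(self, factor: float, name: str | None = None) -> "SpectralFunction":
        kind = self.kind
        return SpectralFunction(self.wavelengths_nm, self.values * factor, kind,
                                name if name is not None else self.name)

    @classmethod
    def from_csv(cls, path: str | Path, kind: str, name: str = "") -> "SpectralFunction":
        """Read a two-column calibration CSV with header ``wavelength_nm,value``."""
        df = pd.read_csv(path)
        if list(df.columns[:2]) != ["wavelength_nm", "value"]:
            raise ValidationError(f"{path}: expected header 'wavelength_nm,value'")
        return cls(df["wavelength_nm"].to_numpy(), df["value"].to_numpy(), kind,
                   name or Path(path).stem)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"wavelength_nm": self.wavelengths_nm, "value": self.values}).to_csv(
            path, index=False)


@dataclass(frozen=True)
class ChannelSpec:
    """Acquisition geometry shared by all channels of a measurement.

    ``filter_nir_uv_block`` records whether the UV+NIR blocking filter is in
    the optical path for every illuminant except the IR one (the acquisition
    protocol removes it only for IR illumination).
    """

    pixel_area_um2: float = 1.0
    exposure_ms: float = 30.0
    filter_nir_uv_block: bool = True

    def __post_init__(self) -> None:
        if self.pixel_area_um2 <= 0:
            raise ValidationError("pixel_area_um2 must be > 0")
        if self.exposure_ms <= 0:
            raise ValidationError("exposure_ms must be > 0")

    @property
    def pixel_area_m2(self) -> float:
        return self.pixel_area_um2 * 1e-12

    @property
    def exposure_s(self) -> float:
        return self.exposure_ms * 1e-3


def channel_id(illuminant: str, sensor: str) -> str:
    return f"{illuminant}:{sensor}"


def channel_index(illuminant: str, sensor: str) -> int:
    """Roster-major flat index of a channel: 3 * illuminant + sensor."""
    return 3 * ILLUMINANT_ROSTER.index(illuminant) + SENSOR_ROSTER.index(sensor)


def all_channel_ids() -> list[str]:
    return [channel_id(il, s) for il in ILLUMINANT_ROSTER for s in SENSOR_ROSTER]


def energy_to_photon_rate(spectrum: SpectralFunction) -> SpectralFunction:
    """Convert spectral power E(lambda) to a photon rate curve.

    Each photon at wavelength lambda carries energy h*c/lambda, so the rate is
    ``E(lambda) * lambda / (h * c)`` in photons s^-1 m^-2 nm^-1 (lambda in
    metres inside the quotient).
    """
    if spectrum.kind != KIND_ILLUMINANT:
        raise ValidationError("energy_to_photon_rate expects an illuminant_power spectrum")
    lam_m = spectrum.wavelengths_nm * 1e-9
    rate = spectrum.values * lam_m / (PLANCK_H * LIGHT_SPEED_C)
    # photon-rate curve reuses the illuminant kind: same wavelength axis,
    # different per-sample unit
    return SpectralFunction(spectrum.wavelengths_nm, rate, KIND_ILLUMINANT,
                            name=f"{spectrum.name}_photon_rate")


def channel_signal(
    light: SpectralFunction,
    qe: SpectralFunction,
    spec: ChannelSpec,
    grid_nm: np.ndarray | None = None,
) -> float:
    """Maximum photon count S of one channel for one pixel and exposure.

    Both curves are resampled (linear interpolation, zero outside support)
    onto a common uniform grid and the product of photon rate and quantum
    efficiency is summed with the grid step as the wavelength bin width.
    """
    if grid_nm is None:
        grid_nm = DEFAULT_GRID_NM
    grid_nm = np.asarray(grid_nm, dtype=float)
    steps = np.diff(grid_nm)
    if grid_nm.size < 2 or not np.allclose(steps, steps[0]):
        raise ValidationError("channel_signal requires a uniform wavelength grid")
    rate = energy_to_photon_rate(light).resample(grid_nm)
    q = qe.resample(grid_nm)
    if not np.any((rate > 0) & (q > 0)):
        logger.warning("channel_signal: disjoint supports for light %r and sensor %r",
                       light.name, qe.name)
    s = float(np.sum(rate * q) * steps[0] * spec.pixel_area_m2 * spec.exposure_s)
    return s


def snr_db(signal_photons: float) -> float:
    """Shot-noise-limited SNR in dB: 20 log10(S / sqrt(S)) = 10 log10(S).

    Non-positive signals have no defined SNR and return NaN (a flagged
    sentinel, never -inf), so downstream tables can render them as NA.
    """
    s = float(signal_photons)
    if s <= 0 or not np.isfinite(s):
        return float("nan")
    return 20.0 * np.log10(s / np.sqrt(s))


@dataclass
class SnrTable:
    """3 sensors x 7 illuminants matrix of channel signal and SNR.

    Rows follow ``SENSOR_ROSTER`` (R, G, B), columns ``ILLUMINANT_ROSTER``.
    Entries with zero signal carry NaN SNR and are flagged, not zeroed.
    """

    signal_photons: np.ndarray
    snr_db: np.ndarray
    illuminants: tuple[str, ...] = ILLUMINANT_ROSTER
    sensors: tuple[str, ...] = SENSOR_ROSTER

    def __post_init__(self) -> None:
        self.signal_photons = np.asarray(self.signal_photons, dtype=float)
        self.snr_db = np.asarray(self.snr_db, dtype=float)
        shape = (len(self.sensors), len(self.illuminants))
        if self.signal_photons.shape != shape or self.snr_db.shape != shape:
            raise ConfigurationError(f"SnrTable matrices must have shape {shape}")

    def channel_snr(self, illuminant: str, sensor: str) -> float:
        return float(self.snr_db[self.sensors.index(sensor),
                                 self.illuminants.index(illuminant)])

    def as_series(self) -> pd.Series:
        """SNR per channel id, in roster-major channel order."""
        data = {
            channel_id(il, s): self.snr_db[i_s, i_il]
            for i_il, il in enumerate(self.illuminants)
            for i_s, s in enumerate(self.sensors)
        }
        return pd.Series(data, name="snr_db")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.snr_db, index=list(self.sensors),
                            columns=list(self.illuminants))

    def to_csv(self, path: str | Path) -> None:
        """Wide-format report: rows R,G,B, columns in roster order, NaN as NA."""
        self.to_frame().to_csv(path, na_rep="NA")

    def to_long_csv(self, path: str | Path) -> None:
        rows = []
        for i_il, il in enumerate(self.illuminants):
            for i_s, s in enumerate(self.sensors):
                rows.append({
                    "channel_id": channel_id(il, s),
                    "illuminant": il,
                    "sensor": s,
                    "S_photons": self.signal_photons[i_s, i_il],
                    "snr_db": self.snr_db[i_s, i_il],
                })
        pd.DataFrame(rows).to_csv(path, index=False, na_rep="NA")


def build_snr_table(
    lights: Mapping[str, SpectralFunction] | Sequence[SpectralFunction],
    sensors: Mapping[str, SpectralFunction] | Sequence[SpectralFunction],
    spec: ChannelSpec,
    blocker: SpectralFunction | None = None,
    no_filter_illuminants: Iterable[str] = ("ir808",),
    grid_nm: np.ndarray | None = None,
) -> SnrTable:
    """Fill the 3 x 7 SNR table over the fixed channel roster.

    ``blocker`` is the UV+NIR blocking filter transmission curve.  When
    ``spec.filter_nir_uv_block`` is set, each sensor's quantum efficiency is
    multiplied by the blocker transmission before integration for every
    illuminant except those in ``no_filter_illuminants`` (the filter is
    physically removed for IR illumination).
    """
    lights_map = _as_roster_map(lights, ILLUMINANT_ROSTER, "illuminant")
    sensors_map = _as_roster_map(sensors, SENSOR_ROSTER, "sensor")
    no_filter = set(no_filter_illuminants)

    grid = DEFAULT_GRID_NM if grid_nm is None else np.asarray(grid_nm, dtype=float)
    signal = np.zeros((len(SENSOR_ROSTER), len(ILLUMINANT_ROSTER)))
    blocked_qe: dict[str, SpectralFunction] = {}
    if spec.filter_nir_uv_block and blocker is not None:
        trans = blocker.resample(grid)
        for s_id, qe in sensors_map.items():
            blocked_qe[s_id] = SpectralFunction(grid, qe.resample(grid) * trans,
                                                KIND_QE, name=f"{qe.name}_blocked")
    for i_il, il in enumerate(ILLUMINANT_ROSTER):
        for i_s, s_id in enumerate(SENSOR_ROSTER):
            qe = sensors_map[s_id]
            if blocked_qe and il not in no_filter:
                qe = blocked_qe[s_id]
            signal[i_s, i_il] = channel_signal(lights_map[il], qe, spec, grid_nm=grid)
    with np.errstate(divide="ignore"):
        snr = np.where(signal > 0, 10.0 * np.log10(np.where(signal > 0, signal, 1.0)),
                       np.nan)
    return SnrTable(signal_photons=signal, snr_db=snr)


def rank_channels_by_snr(table: SnrTable) -> list[str]:
    """All 21 channel ids ordered by descending SNR.

    Ties are broken by roster-major channel order; channels with undefined
    (NaN) SNR sort last, keeping the ranking total.
    """
    series = table.as_series()
    ids = list(series.index)
    # stable sort on (-snr); NaN placed after every finite value
    keys = [(-v if np.isfinite(v) else np.inf, i) for i, v in enumerate(series.to_numpy())]
    order = sorted(range(len(ids)), key=lambda i: keys[i])
    return [ids[i] for i in order]


def _as_roster_map(
    curves: Mapping[str, SpectralFunction] | Sequence[SpectralFunction],
    roster: tuple[str, ...],
    what: str,
) -> dict[str, SpectralFunction]:
    if isinstance(curves, Mapping):
        mapping = dict(curves)
    else:
        curves = list(curves)
        if len(curves) != len(roster):
            raise ConfigurationError(
                f"expected {len(roster)} {what} curves, got {len(curves)}")
        mapping = dict(zip(roster, curves))
    missing = [r for r in roster if r not in mapping]
    if missing:
        raise ConfigurationError(f"missing {what} curves for roster entries {missing}")
    extra = [k for k in mapping if k not in roster]
    if extra:
        raise ConfigurationError(f"unknown {what} ids {extra}")
    return {r: mapping[r] for r in roster}
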