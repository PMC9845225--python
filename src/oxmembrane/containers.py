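"""Shared in-memory containers for all analysis stages.

Conventions used throughout the package: distances in Å, times in ns,
wavelengths in nm, scattering vectors in Å⁻¹, viscosities in cP,
temperatures in °C unless a function says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "DecayTrace",
    "FLIMStack",
    "EmissionSpectrum",
    "ScatteringProfile",
    "BilayerTrajectory",
]


@dataclass
class DecayTrace:
    """A single TCSPC decay with its instrument response function.

    channel_times are ascending, uniformly spaced (ns); counts and
    irf_counts share that grid.
    """

    channel_times: np.ndarray
    counts: np.ndarray
    irf_counts: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channel_times = np.asarray(self.channel_times, dtype=float)
        self.counts = np.asarray(self.counts)
        self.irf_counts = np.asarray(self.irf_counts, dtype=float)
        n = self.channel_times.size
        if self.counts.size != n or self.irf_counts.size != n:
            raise ValueError("channel_times, counts and irf_counts must have equal length")
        if n >= 2:
            widths = np.diff(self.channel_times)
            if np.any(widths <= 0):
                raise ValueError("channel_times must be strictly ascending")
            if np.ptp(widths) > 1e-9:
                raise ValueError("channel width must be uniform to within 1e-9 ns")
        if np.any(self.counts < 0) or np.any(self.irf_counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def channel_width(self) -> float:
        return float(self.channel_times[1] - self.channel_times[0])

    @property
    def peak_counts(self) -> int:
        return int(self.counts.max())


@dataclass
class FLIMStack:
    """Per-pixel TCSPC data: a (ny, nx, n_channels) photon-count cube."""

    data: np.ndarray
    channel_width: float
    irf_counts: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.irf_counts = np.asarray(self.irf_counts, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("FLIM stack must be (ny, nx, n_channels)")
        if self.irf_counts.size != self.data.shape[2]:
            raise ValueError("IRF length must match the channel axis")
        if self.channel_width <= 0:
            raise ValueError("channel_width must be positive")

    @property
    def channel_times(self) -> np.ndarray:
        return np.arange(self.data.shape[2]) * self.channel_width

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]


@dataclass
class EmissionSpectrum:
    """Steady-state emission spectrum on an ascending wavelength grid (nm)."""

    wavelengths: np.ndarray
    intensities: np.ndarray
    temperature: float | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.size != self.intensities.size:
            raise ValueError("wavelengths and intensities must have equal length")
        if self.wavelengths.size >= 2 and np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly ascending")


@dataclass
class ScatteringProfile:
    """1-D azimuthally averaged scattering profile I(q), q in Å⁻¹."""

    q: np.ndarray
    intensity: np.ndarray
    uncertainty: np.ndarray | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.size != self.intensity.size:
            raise ValueError("q and intensity must have equal length")
        if np.any(self.q <= 0):
            raise ValueError("q must be positive")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly ascending")
        if self.uncertainty is not None:
            self.uncertainty = np.asarray(self.uncertainty, dtype=float)
            if self.uncertainty.size != self.q.size:
                raise ValueError("uncertainty length mismatch")


class BilayerTrajectory:
    """Frames of labelled particles in a laterally periodic box.

    Particles are static in identity across frames: ``species``,
    ``leaflet`` ("upper"/"lower"), ``role`` ("phosphate", "chain_<k>",
    "peroxide_O") and ``mol_id`` are per-particle arrays of length
    n_particles; ``coords`` is (n_frames, n_particles, 3) in Å with x, y
    wrapped into [0, Lx) × [0, Ly).  ``unwrapped_xy``, when present,
    carries the continuous in-plane path used for MSD analysis.
    """

    def __init__(
        self,
        coords: np.ndarray,
        species: np.ndarray,
        leaflet: np.ndarray,
        role: np.ndarray,
        mol_id: np.ndarray,
        box: tuple[float, float],
        dt: float,
        unwrapped_xy: np.ndarray | None = None,
        weights: np.ndarray | None = None,
        metadata: dict[str, Any] | None = None,
    ) -> None:
        self.coords = np.asarray(coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (n_frames, n_particles, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        n = self.coords.shape[1]
        self.species = np.asarray(species)
        self.leaflet = np.asarray(leaflet)
        self.role = np.asarray(role)
        self.mol_id = np.asarray(mol_id)
        for name, arr in (
            ("species", self.species),
            ("leaflet", self.leaflet),
            ("role", self.role),
            ("mol_id", self.mol_id),
        ):
            if arr.size != n:
                raise ValueError(f"{name} must have one entry per particle")
        if not set(np.unique(self.leaflet)) <= {"upper", "lower"}:
            raise ValueError("leaflet labels must be 'upper' or 'lower'")
        if len(box) < 2 or box[0] <= 0 or box[1] <= 0:
            raise ValueError("box must provide positive (Lx, Ly)")
        self.box = (float(box[0]), float(box[1]))
        if dt <= 0:
            raise ValueError("dt must be positive (ns)")
        self.dt = float(dt)
        self.unwrapped_xy = None if unwrapped_xy is None else np.asarray(unwrapped_xy, dtype=float)
        self.weights = None if weights is None else np.asarray(weights, dtype=float)
        self.metadata = dict(metadata or {})

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_particles(self) -> int:
        return self.coords.shape[1]

    def select(self, **criteria: Any) -> np.ndarray:
        """Boolean particle mask for species=/leaflet=/role=/mol_id= filters.

        ``role`` may be given as a prefix (e.g. ``"chain"``) to match all
        chain sites.
        """
        mask = np.ones(self.n_particles, dtype=bool)
        for key, value in criteria.items():
            if key == "role":
                arr = self.role.astype(str)
                mask &= (arr == value) | np.char.startswith(arr, value + "_")
            elif key in ("species", "leaflet"):
                mask &= getattr(self, key).astype(str) == value
            elif key == "mol_id":
                mask &= self.mol_id == value
            else:
                raise ValueError(f"unknown selection key: {key}")
        return mask
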