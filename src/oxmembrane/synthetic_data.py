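"""Synthetic input generators with known ground truth.

Every downstream stage of the package (decay fitting, spectral
decomposition, lamellar peak analysis, trajectory statistics) consumes
data of the same shape as the corresponding wet-lab or simulation
measurement.  This module produces all of those modalities from explicit
specifications so that every estimator can be validated against planted
truth:

* TCSPC decays — Poisson-noised, IRF-convolved multi-exponentials.
* FLIM stacks — vesicle-rim images with region-wise lifetimes.
* Emission spectra — sums of asymmetric lognormal bands.
* Scattering profiles — lamellar Bragg peaks with order-dependent
  broadening plus a Lorentzian wide-angle peak.
* Bilayer trajectories — two-leaflet overdamped Brownian dynamics with
  tunable same-species attraction, chain-orientation order, and slow
  two-state snorkelling of peroxide oxygens.

Units: Å, ns, nm, Å⁻¹.  All randomness flows through a single
``numpy.random.Generator`` seeded from the spec, so identical specs give
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from ._models import (
    convolve_irf,
    gaussian_irf,
    gaussian_peak,
    lognormal_band,
    lorentzian_peak,
    multi_exponential,
)
from .containers import (
    BilayerTrajectory,
    DecayTrace,
    EmissionSpectrum,
    FLIMStack,
    ScatteringProfile,
)

__all__ = [
    "DecaySimSpec",
    "SpectrumSimSpec",
    "ScatterSimSpec",
    "BilayerSimSpec",
    "RimGeometry",
    "gen_decay",
    "gen_flim_stack",
    "gen_spectrum",
    "gen_scatter",
    "gen_bilayer_traj",
]


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------


@dataclass
class DecaySimSpec:
    """Ground truth for one TCSPC acquisition.

    ``peak_counts`` scales the noiseless model so its brightest channel
    has that expectation, emulating acquisition until a target peak
    count; ``background_rate`` adds a uniform counts/channel pedestal.
    """

    lifetimes: Sequence[float]
    amplitudes: Sequence[float]
    irf_center: float = 1.0
    irf_fwhm: float = 0.2
    n_channels: int = 256
    channel_width: float = 0.05
    peak_counts: int = 10_000
    background_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.lifetimes = [float(x) for x in self.lifetimes]
        self.amplitudes = [float(x) for x in self.amplitudes]
        if len(self.lifetimes) != len(self.amplitudes) or not self.lifetimes:
            raise ValueError("lifetimes and amplitudes must be non-empty and matched")
        if any(tau <= 0 for tau in self.lifetimes):
            raise ValueError("lifetimes must be strictly positive")
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be non-negative")
        if abs(sum(self.amplitudes) - 1.0) > 1e-12:
            raise ValueError("amplitudes must sum to 1 within 1e-12")
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if self.channel_width <= 0 or self.irf_fwhm < 0:
            raise ValueError("channel_width must be positive, irf_fwhm non-negative")
        if self.peak_counts < 1:
            raise ValueError("peak_counts must be ≥ 1")
        if self.background_rate < 0:
            raise ValueError("background_rate must be ≥ 0")


@dataclass
class SpectrumSimSpec:
    """Sum-of-lognormal-bands emission spectrum.

    ``components`` are (center nm, FWHM nm, asymmetry ρ, amplitude)
    tuples; noise is multiplicative Gaussian with relative SD
    ``noise_sd``.
    """

    components: Sequence[tuple[float, float, float, float]]
    noise_sd: float = 0.0
    wavelength_grid: np.ndarray = field(
        default_factory=lambda: np.arange(380.0, 600.0 + 1e-9, 0.5)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.wavelength_grid = np.asarray(self.wavelength_grid, dtype=float)
        if np.any(np.diff(self.wavelength_grid) <= 0):
            raise ValueError("wavelength grid must be strictly ascending")
        lo, hi = self.wavelength_grid[0], self.wavelength_grid[-1]
        for c, w, rho, a in self.components:
            if not (lo <= c <= hi):
                raise ValueError(f"band center {c} nm outside the wavelength grid")
            if w <= 0 or rho <= 0:
                raise ValueError("band width and asymmetry must be positive")
            if a < 0:
                raise ValueError("band amplitudes must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be ≥ 0")


@dataclass
class ScatterSimSpec:
    """Lamellar SAXS orders plus one wide-angle Lorentzian.

    Bragg maxima sit at q_n = 2πn/d.  The n-th order FWHM is
    ``first_order_fwhm · (1 + peak_width_growth · (n² − 1))`` — the n²
    scaling mimics fluctuation (Caillé-type) broadening of soft stacks.
    Peak heights fall off as 1/n².
    """

    d_spacing: float
    n_orders: int = 3
    first_order_fwhm: float = 0.004
    peak_width_growth: float = 0.0
    peak_amplitude: float = 1000.0
    waxs_center: float = 1.396
    waxs_hwhm: float = 0.08
    waxs_amplitude: float = 100.0
    background: Sequence[float] = (5.0,)
    noise_sd: float = 0.0
    q_grid: np.ndarray = field(default_factory=lambda: np.arange(0.02, 2.0, 0.0005))
    seed: int = 0

    def __post_init__(self) -> None:
        self.q_grid = np.asarray(self.q_grid, dtype=float)
        if self.d_spacing <= 0:
            raise ValueError("d_spacing must be positive")
        if self.n_orders < 1:
            raise ValueError("n_orders must be ≥ 1")
        if self.first_order_fwhm <= 0 or self.waxs_hwhm <= 0:
            raise ValueError("peak widths must be positive")
        if self.peak_width_growth < 0:
            raise ValueError("peak_width_growth must be ≥ 0")
        if np.any(np.diff(self.q_grid) <= 0) or self.q_grid[0] <= 0:
            raise ValueError("q_grid must be positive and ascending")


@dataclass
class BilayerSimSpec:
    """Two-leaflet lateral bilayer model with planted observables.

    The defaults emulate the simulated systems the package analyses: 200
    lipids per leaflet in a box sized for ~66 Å² per lipid, phosphate
    planes at ±thickness/2, lateral diffusion of order 1 Å²/ns, and for
    oxidized species a slow two-state snorkelling equilibrium with ~40%
    of peroxide groups near the interface.
    """

    box_lengths: tuple[float, float] = (115.0, 115.0)
    n_per_leaflet: int = 200
    species_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"POPC": 1.0}
    )
    diffusion_coeffs: Mapping[str, float] = field(default_factory=dict)
    attraction_eps: float = 0.0
    attraction_range: float = 10.0
    core_repulsion: float = 0.0
    core_radius: float = 7.0
    order_target: Mapping[str, float] = field(default_factory=dict)
    snorkel_fraction: float = 0.4
    snorkel_rates: tuple[float, float] | None = None
    dt: float = 1.0
    n_frames: int = 500
    seed: int = 0
    thickness: float = 39.2
    n_chain_sites: int = 4
    segment_length: float = 1.27
    z_jitter: float = 1.0
    oxidized_species: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.box_lengths[0] <= 0 or self.box_lengths[1] <= 0:
            raise ValueError("box lengths must be positive")
        fracs = dict(self.species_fractions)
        if abs(sum(fracs.values()) - 1.0) > 1e-9:
            raise ValueError("species fractions must sum to 1")
        if any(f < 0 for f in fracs.values()):
            raise ValueError("species fractions must be non-negative")
        self.species_fractions = fracs
        self.diffusion_coeffs = {
            sp: float(self.diffusion_coeffs.get(sp, 1.0)) for sp in fracs
        }
        if any(d < 0 for d in self.diffusion_coeffs.values()):
            raise ValueError("diffusion coefficients must be ≥ 0")
        self.order_target = {sp: float(self.order_target.get(sp, 0.2)) for sp in fracs}
        for sp, s in self.order_target.items():
            if not (-0.5 <= s <= 1.0):
                raise ValueError(f"order target for {sp} outside [-0.5, 1]")
        if self.core_repulsion < 0 or self.core_radius <= 0:
            raise ValueError("core repulsion must be ≥ 0 and core radius positive")
        if not (0.0 <= self.snorkel_fraction <= 1.0):
            raise ValueError("snorkel_fraction must lie in [0, 1]")
        if self.dt <= 0 or self.n_frames < 1 or self.n_per_leaflet < 1:
            raise ValueError("dt, n_frames and n_per_leaflet must be positive")
        rms_step = math.sqrt(2.0 * max(self.diffusion_coeffs.values()) * self.dt)
        if rms_step > min(self.box_lengths) / 4.0:
            raise ValueError(
                "unphysical step: sqrt(2 D dt) exceeds a quarter of the box; "
                "reduce dt or D"
            )
        if self.oxidized_species is None:
            self.oxidized_species = tuple(
                sp for sp in fracs if "OOH" in sp or sp.lower().startswith("ox")
            )
        if self.snorkel_rates is not None:
            r_up, r_dn = self.snorkel_rates
            if r_up < 0 or r_dn < 0 or r_up + r_dn <= 0:
                raise ValueError("snorkel rates must be non-negative, not both zero")
            stat = r_up / (r_up + r_dn)
            if abs(stat - self.snorkel_fraction) > 1e-6:
                raise ValueError(
                    "snorkel_rates stationary fraction "
                    f"{stat:.6f} disagrees with snorkel_fraction {self.snorkel_fraction}"
                )


@dataclass
class RimGeometry:
    """Annular vesicle-rim mask for synthetic FLIM images."""

    shape: tuple[int, int] = (48, 48)
    center: tuple[float, float] | None = None
    radius: float = 16.0
    rim_width: float = 3.0

    def mask(self) -> np.ndarray:
        ny, nx = self.shape
        cy, cx = self.center if self.center is not None else ((ny - 1) / 2, (nx - 1) / 2)
        yy, xx = np.mgrid[0:ny, 0:nx]
        r = np.hypot(yy - cy, xx - cx)
        return np.abs(r - self.radius) <= self.rim_width / 2.0

    def angles(self) -> np.ndarray:
        """Polar angle of every pixel in degrees ∈ [0, 360)."""
        ny, nx = self.shape
        cy, cx = self.center if self.center is not None else ((ny - 1) / 2, (nx - 1) / 2)
        yy, xx = np.mgrid[0:ny, 0:nx]
        return np.degrees(np.arctan2(yy - cy, xx - cx)) % 360.0


# ---------------------------------------------------------------------------
# decay / FLIM
# ---------------------------------------------------------------------------


def _decay_model(spec: DecaySimSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(channel_times, noiseless expectation, IRF counts) for a spec."""
    t = np.arange(spec.n_channels) * spec.channel_width
    irf = gaussian_irf(t, spec.irf_center, spec.irf_fwhm)
    kernel = multi_exponential(t, spec.lifetimes, spec.amplitudes)
    model = convolve_irf(irf, kernel)
    peak = model.max()
    if peak <= 0:
        raise ValueError("decay model has no signal inside the window")
    mu = model * (spec.peak_counts / peak) + spec.background_rate
    return t, mu, irf * spec.peak_counts


def gen_decay(spec: DecaySimSpec) -> DecayTrace:
    """Simulate one TCSPC decay trace.

    Counts per channel are Poisson with mean equal to the IRF-convolved
    multi-exponential scaled so the expected peak equals
    ``spec.peak_counts``, plus the uniform background.  The noiseless
    IRF (scaled to the same peak) is returned alongside, and the full
    ground truth is recorded in the trace metadata.
    """
    t, mu, irf_counts = _decay_model(spec)
    rng = np.random.default_rng(spec.seed)
    counts = rng.poisson(mu)
    return DecayTrace(
        channel_times=t,
        counts=counts,
        irf_counts=irf_counts,
        metadata={
            "truth": {
                "lifetimes_ns": list(spec.lifetimes),
                "amplitudes": list(spec.amplitudes),
                "peak_counts": spec.peak_counts,
                "background_rate": spec.background_rate,
                "irf_center_ns": spec.irf_center,
                "irf_fwhm_ns": spec.irf_fwhm,
                "expected_total_counts": float(mu.sum()),
            },
            "seed": spec.seed,
            "channel_width_ns": spec.channel_width,
        },
    )


def gen_flim_stack(
    geometry: RimGeometry,
    populations: Sequence[tuple[float, float, tuple[float, float] | None]],
    decay_spec: DecaySimSpec,
) -> FLIMStack:
    """Simulate a FLIM image of a vesicle rim.

    ``populations`` lists (lifetime ns, fraction, region); a region is an
    angular sector (deg_lo, deg_hi) of the rim, or None, in which case
    rim pixels are assigned at random according to the fractions.
    Angular regions must be mutually disjoint.  Off-rim pixels contain
    background only.  The per-pixel true lifetime map is stored in
    ``metadata["truth_lifetime"]`` (NaN off-rim).
    """
    if not populations:
        raise ValueError("need at least one population")
    mask = geometry.mask()
    angles = geometry.angles()
    rng = np.random.default_rng(decay_spec.seed)

    regions = [p[2] for p in populations]
    explicit = [r for r in regions if r is not None]
    if explicit and len(explicit) != len(regions):
        raise ValueError("mix of angular and fraction-assigned regions not supported")
    truth = np.full(geometry.shape, np.nan)
    if explicit:
        covered = np.zeros(geometry.shape, dtype=bool)
        for (tau, _frac, (lo, hi)) in populations:
            lo_ = lo % 360.0
            hi_ = hi % 360.0 if hi % 360.0 > 0 else 360.0
            if lo_ < hi_:
                sel = mask & (angles >= lo_) & (angles < hi_)
            else:  # wraps through 0°
                sel = mask & ((angles >= lo_) | (angles < hi_))
            if np.any(covered & sel):
                raise ValueError("population regions overlap on the rim")
            covered |= sel
            truth[sel] = tau
    else:
        fracs = np.array([p[1] for p in populations], dtype=float)
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ValueError("population fractions must sum to 1")
        rim_idx = np.flatnonzero(mask.ravel())
        draw = rng.choice(len(populations), size=rim_idx.size, p=fracs)
        flat = truth.ravel()
        for k, (tau, _f, _r) in enumerate(populations):
            flat[rim_idx[draw == k]] = tau

    t = np.arange(decay_spec.n_channels) * decay_spec.channel_width
    irf = gaussian_irf(t, decay_spec.irf_center, decay_spec.irf_fwhm)
    data = np.zeros((*geometry.shape, decay_spec.n_channels), dtype=np.int64)
    # one noiseless template per distinct lifetime, Poisson-sampled per pixel
    templates: dict[float, np.ndarray] = {}
    for tau in {p[0] for p in populations}:
        kernel = np.exp(-t / tau)
        model = convolve_irf(irf, kernel)
        templates[tau] = model * (decay_spec.peak_counts / model.max())
    flat_truth = truth.ravel()
    flat_data = data.reshape(-1, decay_spec.n_channels)
    for i in np.flatnonzero(np.isfinite(flat_truth)):
        mu = templates[float(flat_truth[i])] + decay_spec.background_rate
        flat_data[i] = rng.poisson(mu)
    if decay_spec.background_rate > 0:
        off = np.flatnonzero(~np.isfinite(flat_truth))
        flat_data[off] = rng.poisson(
            decay_spec.background_rate, size=(off.size, decay_spec.n_channels)
        )
    return FLIMStack(
        data=data,
        channel_width=decay_spec.channel_width,
        irf_counts=irf * decay_spec.peak_counts,
        metadata={
            "truth_lifetime": truth,
            "rim_mask": mask,
            "seed": decay_spec.seed,
            "populations": [(p[0], p[1]) for p in populations],
        },
    )


# ---------------------------------------------------------------------------
# spectra / scattering
# ---------------------------------------------------------------------------


def gen_spectrum(spec: SpectrumSimSpec) -> EmissionSpectrum:
    """Sum the lognormal bands and apply multiplicative Gaussian noise."""
    wl = spec.wavelength_grid
    intensity = np.zeros_like(wl)
    for c, w, rho, a in spec.components:
        intensity += lognormal_band(wl, c, w, rho, a)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        intensity = intensity * (1.0 + spec.noise_sd * rng.standard_normal(wl.size))
        intensity = np.clip(intensity, 0.0, None)
    return EmissionSpectrum(
        wavelengths=wl,
        intensities=intensity,
        metadata={
            "truth": {"components": [tuple(c) for c in spec.components]},
            "seed": spec.seed,
        },
    )


def gen_scatter(spec: ScatterSimSpec) -> ScatteringProfile:
    """Build the lamellar + wide-angle analytic profile and add noise.

    Emits a warning in the metadata if a requested Bragg order falls
    outside the q grid (the profile is still generated).
    """
    q = spec.q_grid
    intensity = np.polyval(list(spec.background)[::-1], q)
    truth_orders = []
    clipped = []
    for n in range(1, spec.n_orders + 1):
        qn = 2.0 * math.pi * n / spec.d_spacing
        fwhm = spec.first_order_fwhm * (1.0 + spec.peak_width_growth * (n**2 - 1))
        amp = spec.peak_amplitude / n**2
        if not (q[0] <= qn <= q[-1]):
            clipped.append(n)
        intensity = intensity + gaussian_peak(q, qn, fwhm, amp)
        truth_orders.append({"order": n, "q": qn, "fwhm": fwhm, "amplitude": amp})
    intensity = intensity + lorentzian_peak(q, spec.waxs_center, spec.waxs_hwhm, spec.waxs_amplitude)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        intensity = intensity * (1.0 + spec.noise_sd * rng.standard_normal(q.size))
    meta: dict[str, Any] = {
        "truth": {
            "d_spacing": spec.d_spacing,
            "orders": truth_orders,
            "waxs": {"center": spec.waxs_center, "hwhm": spec.waxs_hwhm},
        },
        "seed": spec.seed,
    }
    if clipped:
        meta["warning"] = f"Bragg orders {clipped} fall outside the q grid"
    return ScatteringProfile(q=q, intensity=np.clip(intensity, 0.0, None), metadata=meta)


# ---------------------------------------------------------------------------
# bilayer trajectory
# ---------------------------------------------------------------------------


def _sample_chain_vectors(rng: np.random.Generator, n: int, target: float) -> np.ndarray:
    """Unit vectors whose order parameter ½⟨3cos²θ−1⟩ equals ``target``.

    Mixture construction: with probability p a vector is drawn from the
    pure-limit population (aligned with the normal for positive targets,
    uniformly in-plane for negative ones) and otherwise isotropically,
    so the expectation is exactly p·S_limit.
    """
    iso = rng.standard_normal((n, 3))
    iso /= np.linalg.norm(iso, axis=1, keepdims=True)
    if target == 0.0:
        return iso
    if target > 0:
        p = target  # aligned limit S = 1
        limit = np.zeros((n, 3))
        limit[:, 2] = 1.0
    else:
        p = target / -0.5  # in-plane limit S = −0.5
        phi = rng.uniform(0.0, 2.0 * math.pi, n)
        limit = np.column_stack([np.cos(phi), np.sin(phi), np.zeros(n)])
    use_limit = rng.random(n) < p
    return np.where(use_limit[:, None], limit, iso)


def gen_bilayer_traj(spec: BilayerSimSpec) -> BilayerTrajectory:
    """Simulate a labelled two-leaflet trajectory.

    Per leaflet, lipid anchor points follow overdamped 2-D Brownian
    motion (step SD √(2D·dt) per axis).  When pair energies are active
    (``attraction_eps`` or ``core_repulsion`` > 0) each proposed step is
    Metropolis-accepted on the change of
    E = −ε_attr·n_same(< attraction_range) + ε_core·n_all(< core_radius)
    in kT units, evaluated against the other lipids' current positions.
    The soft core mimics lateral incompressibility: without it strong
    same-species attraction condenses the leaflet into dense mixed
    aggregates instead of demixing it.  Each lipid contributes a phosphate particle at
    ±thickness/2 (thermal z jitter), ``n_chain_sites`` chain sites whose
    successive bond vectors are sampled each frame to match the species'
    order-parameter target, and — for oxidized species — one peroxide
    oxygen whose |z| follows a slow two-state snorkelling Markov chain
    (up state near the interface, down state near the midplane).
    """
    rng = np.random.default_rng(spec.seed)
    Lx, Ly = spec.box_lengths
    half = spec.thickness / 2.0
    n_leaf = spec.n_per_leaflet

    # deterministic per-leaflet species assignment by largest remainder
    species_names = list(spec.species_fractions)
    counts = {sp: int(math.floor(spec.species_fractions[sp] * n_leaf)) for sp in species_names}
    remainder = n_leaf - sum(counts.values())
    order = sorted(
        species_names,
        key=lambda sp: spec.species_fractions[sp] * n_leaf - counts[sp],
        reverse=True,
    )
    for sp in order[:remainder]:
        counts[sp] += 1
    leaf_species = np.concatenate(
        [np.repeat(sp, counts[sp]) for sp in species_names]
    )

    mol_species = np.concatenate([leaf_species, leaf_species])
    mol_leaflet = np.repeat(["upper", "lower"], n_leaf)
    n_mol = 2 * n_leaf
    is_ox = np.isin(mol_species, list(spec.oxidized_species))

    # particle layout per lipid: phosphate, chain sites, optional peroxide O
    part_species: list[str] = []
    part_leaflet: list[str] = []
    part_role: list[str] = []
    part_mol: list[int] = []
    for m in range(n_mol):
        roles = ["phosphate"] + [f"chain_{k}" for k in range(spec.n_chain_sites)]
        if is_ox[m]:
            roles.append("peroxide_O")
        for r in roles:
            part_species.append(mol_species[m])
            part_leaflet.append(mol_leaflet[m])
            part_role.append(r)
            part_mol.append(m)
    part_species = np.array(part_species)
    part_leaflet = np.array(part_leaflet)
    part_role = np.array(part_role)
    part_mol = np.array(part_mol)
    n_part = part_mol.size
    phos_of_mol = np.flatnonzero(part_role == "phosphate")  # ordered by mol id

    # anchors
    xy = rng.uniform([0.0, 0.0], [Lx, Ly], size=(n_mol, 2))
    unwrapped = xy.copy()
    step_sd = np.array(
        [math.sqrt(2.0 * spec.diffusion_coeffs[sp] * spec.dt) for sp in mol_species]
    )

    # snorkelling Markov chain
    if spec.snorkel_rates is not None:
        r_up, r_dn = spec.snorkel_rates
    else:
        dwell = 50.0  # ns; slow interconversion
        r_up = spec.snorkel_fraction / dwell
        r_dn = (1.0 - spec.snorkel_fraction) / dwell
    snork_state = rng.random(n_mol) < spec.snorkel_fraction  # True = up
    p_up = min(r_up * spec.dt, 1.0)
    p_dn = min(r_dn * spec.dt, 1.0)

    seg = spec.segment_length
    coords = np.empty((spec.n_frames, n_part, 3))
    unwrapped_xy = np.empty((spec.n_frames, n_mol, 2))
    states = np.empty((spec.n_frames, n_mol), dtype=bool)
    sign = np.where(mol_leaflet == "upper", 1.0, -1.0)

    leaf_masks = {leaf: np.flatnonzero(mol_leaflet == leaf) for leaf in ("upper", "lower")}

    for f in range(spec.n_frames):
        if f > 0:
            # snorkelling transitions
            flips_up = (~snork_state) & (rng.random(n_mol) < p_up)
            flips_dn = snork_state & (rng.random(n_mol) < p_dn)
            snork_state = (snork_state | flips_up) & ~flips_dn
            # lateral Brownian step, leaflet by leaflet
            disp = rng.standard_normal((n_mol, 2)) * step_sd[:, None]
            if spec.attraction_eps > 0 or spec.core_repulsion > 0:
                for leaf, idx in leaf_masks.items():
                    pos = np.mod(xy[idx], [Lx, Ly])
                    tree = cKDTree(pos, boxsize=[Lx, Ly])
                    prop = np.mod(pos + disp[idx], [Lx, Ly])
                    sp_leaf = mol_species[idx]

                    def pair_energy(neighbour_lists, self_idx):
                        e = np.zeros(idx.size)
                        for j, lst in enumerate(neighbour_lists):
                            same = sum(
                                1 for k in lst if k != self_idx[j] and sp_leaf[k] == sp_leaf[j]
                            )
                            e[j] += -spec.attraction_eps * same
                        return e

                    e_old = pair_energy(
                        tree.query_ball_point(pos, spec.attraction_range), np.arange(idx.size)
                    )
                    e_new = pair_energy(
                        tree.query_ball_point(prop, spec.attraction_range),
                        np.arange(idx.size),
                    )
                    if spec.core_repulsion > 0:
                        core_old = tree.query_ball_point(pos, spec.core_radius)
                        core_new = tree.query_ball_point(prop, spec.core_radius)
                        for j in range(idx.size):
                            n_old = sum(1 for k in core_old[j] if k != j)
                            n_new = sum(1 for k in core_new[j] if k != j)
                            e_old[j] += spec.core_repulsion * n_old
                            e_new[j] += spec.core_repulsion * n_new
                    d_e = e_new - e_old
                    reject = (d_e > 0) & (rng.random(idx.size) >= np.exp(-np.clip(d_e, 0, 50)))
                    disp[idx[reject]] = 0.0
            unwrapped += disp
            xy = np.mod(xy + disp, [Lx, Ly])
        unwrapped_xy[f] = unwrapped
        states[f] = snork_state

        # phosphates
        zp = sign * (half + spec.z_jitter * rng.standard_normal(n_mol))
        coords[f, phos_of_mol, 0:2] = xy
        coords[f, phos_of_mol, 2] = zp

        # chain sites: bond vectors matched to per-species order targets
        vecs = np.empty((n_mol, spec.n_chain_sites, 3))
        for sp in species_names:
            sel = mol_species == sp
            nsel = int(sel.sum())
            if nsel == 0:
                continue
            v = _sample_chain_vectors(
                rng, nsel * spec.n_chain_sites, spec.order_target[sp]
            ).reshape(nsel, spec.n_chain_sites, 3)
            vecs[sel] = v
        # descend towards the midplane: flip z-component sign per leaflet
        vecs[:, :, 2] *= -sign[:, None]
        start = np.column_stack([xy, sign * (half - 1.0)])
        site = start
        for k in range(spec.n_chain_sites):
            site = site + seg * vecs[:, k, :]
            mask_k = part_role == f"chain_{k}"
            coords[f, mask_k, :] = site
            coords[f, mask_k, 0] = np.mod(coords[f, mask_k, 0], Lx)
            coords[f, mask_k, 1] = np.mod(coords[f, mask_k, 1], Ly)

        # peroxide oxygens: up → near interface, down → near midplane
        if is_ox.any():
            z_up, z_dn = 0.85 * half, 0.15 * half
            zo = np.where(snork_state, z_up, z_dn) * sign
            zo = zo + 0.5 * rng.standard_normal(n_mol) * sign
            mask_o = part_role == "peroxide_O"
            mols_o = part_mol[mask_o]
            coords[f, mask_o, 0:2] = xy[mols_o]
            coords[f, mask_o, 2] = zo[mols_o]

    unwrapped_full = unwrapped_xy[:, part_mol, :]
    traj = BilayerTrajectory(
        coords=coords,
        species=part_species,
        leaflet=part_leaflet,
        role=part_role,
        mol_id=part_mol,
        box=(Lx, Ly),
        dt=spec.dt,
        unwrapped_xy=unwrapped_full,
        metadata={
            "truth": {
                "diffusion_coeffs": dict(spec.diffusion_coeffs),
                "order_target": dict(spec.order_target),
                "snorkel_fraction": spec.snorkel_fraction,
                "snorkel_mean_observed": float(states.mean()) if is_ox.any() else None,
                "thickness": spec.thickness,
                "attraction_eps": spec.attraction_eps,
            },
            "snorkel_states": states,
            "seed": spec.seed,
        },
    )
    return traj
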