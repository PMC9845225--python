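"""Bilayer trajectory statistics.

Operates on :class:`~oxmembrane.containers.BilayerTrajectory` objects —
frames of labelled particles (phosphate anchors, acyl-chain sites,
peroxide oxygens) in a laterally periodic box — and computes the
standard membrane observables:

* electron/number density profiles along the bilayer normal,
* bilayer thickness as the phosphate–phosphate distance,
* the chain order parameter S_cd = ½⟨3cos²θ − 1⟩, θ the angle between
  a chain bond vector and the bilayer normal,
* per-lipid Voronoi areas (periodic tessellation) and the bimodality of
  their distribution,
* fractional enrichment E_ij = C_j,local/C_j,bulk within a lateral
  neighbourhood (default 12 Å), the lipid-clustering readout,
* snorkelling statistics of peroxide oxygens,
* lateral diffusion from the mean squared displacement, and the
  Saffman–Delbrück bridge between diffusion and membrane viscosity,
* site-to-site contact maps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
from scipy import optimize, spatial, stats

from .containers import BilayerTrajectory

__all__ = [
    "DensityProfile",
    "OrderProfile",
    "APLMap",
    "APLDistribution",
    "EnrichmentMatrix",
    "SnorkelResult",
    "DiffusionEstimate",
    "electron_density_profile",
    "bilayer_thickness",
    "order_parameter",
    "apl_voronoi",
    "apl_distribution",
    "enrichment",
    "snorkelling_fraction",
    "msd_diffusion",
    "saffman_delbruck",
    "saffman_delbruck_viscosity",
    "contact_map",
]

KB = 1.380649e-23  # J/K
EULER_GAMMA = 0.5772156649015329


# ---------------------------------------------------------------------------
# density / thickness
# ---------------------------------------------------------------------------


@dataclass
class DensityProfile:
    z_centers: np.ndarray  # Å, midplane-centred
    density: dict[str, np.ndarray]  # weight per Å³
    bin_width: float
    metadata: dict[str, Any] = field(default_factory=dict)


def _midplane(traj: BilayerTrajectory, frame: int) -> float:
    phos = traj.select(role="phosphate")
    if phos.any():
        up = phos & (traj.leaflet == "upper")
        lo = phos & (traj.leaflet == "lower")
        if up.any() and lo.any():
            return 0.5 * (
                traj.coords[frame, up, 2].mean() + traj.coords[frame, lo, 2].mean()
            )
    return float(traj.coords[frame, :, 2].mean())


def electron_density_profile(
    traj: BilayerTrajectory,
    bin_width: float = 1.0,
    groups: Mapping[str, np.ndarray] | None = None,
) -> DensityProfile:
    """Weighted density vs z, midplane-centred and frame-averaged.

    ``groups`` maps a name to a boolean particle mask (default: one
    group per species).  Particle weights default to 1 (number density);
    supply electron counts via ``traj.weights`` for true electron
    density.  Normalization is per unit area and bin width, so the
    profile integrates (×LxLy) to the total group weight per frame.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if groups is None:
        groups = {str(sp): traj.species == sp for sp in np.unique(traj.species)}
    for name, mask in groups.items():
        if not np.any(mask):
            raise ValueError(f"empty group: {name}")
    w = traj.weights if traj.weights is not None else np.ones(traj.n_particles)
    area = traj.box[0] * traj.box[1]

    z_rel = np.empty_like(traj.coords[:, :, 2])
    for f in range(traj.n_frames):
        z_rel[f] = traj.coords[f, :, 2] - _midplane(traj, f)
    zmin, zmax = z_rel.min(), z_rel.max()
    edges = np.arange(
        math.floor(zmin / bin_width) * bin_width,
        math.ceil(zmax / bin_width) * bin_width + bin_width * 0.5,
        bin_width,
    )
    if edges.size < 2:
        edges = np.array([zmin - bin_width / 2, zmin + bin_width / 2])
    centers = 0.5 * (edges[:-1] + edges[1:])
    density: dict[str, np.ndarray] = {}
    for name, mask in groups.items():
        hist = np.zeros(centers.size)
        for f in range(traj.n_frames):
            h, _ = np.histogram(z_rel[f, mask], bins=edges, weights=w[mask])
            hist += h
        density[name] = hist / (traj.n_frames * area * bin_width)
    return DensityProfile(
        z_centers=centers,
        density=density,
        bin_width=bin_width,
        metadata={"area": area, "n_frames": traj.n_frames},
    )


def bilayer_thickness(traj: BilayerTrajectory) -> tuple[float, float]:
    """Phosphate–phosphate thickness: (mean Å, SE over frames)."""
    up = traj.select(role="phosphate", leaflet="upper")
    lo = traj.select(role="phosphate", leaflet="lower")
    if not up.any() or not lo.any():
        raise ValueError("both leaflets must contain phosphate particles")
    per_frame = traj.coords[:, up, 2].mean(axis=1) - traj.coords[:, lo, 2].mean(axis=1)
    se = per_frame.std(ddof=1) / math.sqrt(per_frame.size) if per_frame.size > 1 else 0.0
    return float(per_frame.mean()), float(se)


# ---------------------------------------------------------------------------
# order parameter
# ---------------------------------------------------------------------------


@dataclass
class OrderProfile:
    site_index: np.ndarray
    s_cd: np.ndarray
    se: np.ndarray
    species: str | None
    metadata: dict[str, Any] = field(default_factory=dict)


def _min_image(d: np.ndarray, box: tuple[float, float]) -> np.ndarray:
    """Minimum-image convention applied to the in-plane components."""
    out = d.copy()
    for k in (0, 1):
        L = box[k]
        out[..., k] -= L * np.round(out[..., k] / L)
    return out


def order_parameter(
    traj: BilayerTrajectory, species: str | None = None
) -> OrderProfile:
    """Chain order parameter per bond index.

    For each molecule the chain sites ``chain_0 … chain_k`` define
    successive bond vectors (periodic-wrapped in-plane); for each bond
    index S_cd = ½⟨3cos²θ − 1⟩ with θ against the z axis, averaged over
    molecules and frames.  The SE is the frame-to-frame scatter of the
    per-frame mean.
    """
    mask = traj.select(role="chain")
    if species is not None:
        mask &= traj.species == species
    if not mask.any():
        raise ValueError("no chain sites selected")
    roles = traj.role[mask].astype(str)
    site_idx = np.array([int(r.split("_", 1)[1]) for r in roles])
    mols = traj.mol_id[mask]
    n_sites = site_idx.max() + 1
    if n_sites < 2:
        raise ValueError("need at least 2 chain sites to form a bond vector")
    # organize particle indices as (n_molecules, n_sites)
    part_idx = np.flatnonzero(mask)
    order = np.lexsort((site_idx, mols))
    part_sorted = part_idx[order]
    uniq_mols = np.unique(mols)
    grid = part_sorted.reshape(uniq_mols.size, n_sites)

    coords = traj.coords[:, grid, :]  # (frames, mols, sites, 3)
    bonds = coords[:, :, 1:, :] - coords[:, :, :-1, :]
    bonds = _min_image(bonds, traj.box)
    norm = np.linalg.norm(bonds, axis=-1)
    cos2 = (bonds[..., 2] / np.where(norm > 0, norm, 1.0)) ** 2
    s_frame = 0.5 * (3.0 * cos2 - 1.0)  # (frames, mols, bonds)
    per_frame = s_frame.mean(axis=1)  # (frames, bonds)
    s = per_frame.mean(axis=0)
    if traj.n_frames > 1:
        se = per_frame.std(axis=0, ddof=1) / math.sqrt(traj.n_frames)
    else:
        se = s_frame[0].std(axis=0, ddof=1) / math.sqrt(max(uniq_mols.size, 2))
    return OrderProfile(
        site_index=np.arange(n_sites - 1),
        s_cd=s,
        se=se,
        species=species,
        metadata={"n_molecules": int(uniq_mols.size), "n_frames": traj.n_frames},
    )


# ---------------------------------------------------------------------------
# Voronoi area per lipid
# ---------------------------------------------------------------------------


@dataclass
class APLMap:
    areas: np.ndarray  # Å² per seed
    mol_ids: np.ndarray
    seeds: np.ndarray  # (n, 2) wrapped positions
    box: tuple[float, float]
    leaflet: str
    frame: int
    species: np.ndarray | None = None

    def rasterize(self, n_pixels: int = 128) -> np.ndarray:
        """Nearest-seed (periodic) raster of the per-lipid area, Å²."""
        Lx, Ly = self.box
        xs = (np.arange(n_pixels) + 0.5) * Lx / n_pixels
        ys = (np.arange(n_pixels) + 0.5) * Ly / n_pixels
        gx, gy = np.meshgrid(xs, ys)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        tree = spatial.cKDTree(np.mod(self.seeds, [Lx, Ly]), boxsize=[Lx, Ly])
        _, idx = tree.query(pts)
        return self.areas[idx].reshape(n_pixels, n_pixels)


@dataclass
class APLDistribution:
    mean: float
    sd: float
    delta_bic: float
    gmm_means: np.ndarray
    gmm_weights: np.ndarray
    n: int


def _polygon_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def apl_voronoi(
    traj: BilayerTrajectory, leaflet: str = "upper", frame: int = 0
) -> APLMap:
    """Per-lipid Voronoi areas for one leaflet of one frame.

    Seeds are the phosphate (x, y) positions.  Periodicity is handled by
    tessellating the seed set together with its 8 periodic images and
    reading the areas of the primary-copy cells, so the areas sum to
    exactly the box area.  Coincident seeds are jittered by 1e-6 Å.
    """
    mask = traj.select(role="phosphate", leaflet=leaflet)
    if mask.sum() < 4:
        raise ValueError("need at least 4 phosphate seeds per leaflet")
    Lx, Ly = traj.box
    seeds = np.mod(traj.coords[frame, mask, 0:2], [Lx, Ly])
    mol_ids = traj.mol_id[mask]
    # jitter exact duplicates
    _, inverse, cnts = np.unique(
        np.round(seeds, 9), axis=0, return_inverse=True, return_counts=True
    )
    if np.any(cnts > 1):
        warnings.warn("duplicate seed positions jittered by 1e-6 Å", stacklevel=2)
        rng = np.random.default_rng(0)
        dup = cnts[inverse] > 1
        seeds[dup] += rng.uniform(-1e-6, 1e-6, size=(int(dup.sum()), 2))
    n = seeds.shape[0]
    images = []
    for ix in (-1, 0, 1):
        for iy in (-1, 0, 1):
            images.append(seeds + [ix * Lx, iy * Ly])
    tiled = np.vstack(images)
    central = 4 * n  # offset of the (0, 0) image in the stacking order above
    vor = spatial.Voronoi(tiled)
    areas = np.empty(n)
    for i in range(n):
        region = vor.regions[vor.point_region[central + i]]
        if -1 in region or len(region) == 0:
            raise RuntimeError("unbounded Voronoi cell in the primary copy")
        areas[i] = _polygon_area(vor.vertices[region])
    return APLMap(
        areas=areas,
        mol_ids=mol_ids,
        seeds=seeds,
        box=traj.box,
        leaflet=leaflet,
        frame=frame,
        species=traj.species[mask],
    )


def apl_distribution(
    areas: np.ndarray | Sequence[APLMap], seed: int = 0
) -> APLDistribution:
    """Summary + two-component Gaussian-mixture bimodality of APL values.

    ``delta_bic`` = BIC(1) − BIC(2); values ≳ 10 indicate strong support
    for two coexisting packing densities.
    """
    if not isinstance(areas, np.ndarray):
        areas = np.concatenate([m.areas for m in areas])
    areas = np.asarray(areas, dtype=float)
    if areas.size < 10:
        raise ValueError("need at least 10 areas")
    from sklearn.mixture import GaussianMixture

    x = areas.reshape(-1, 1)
    g1 = GaussianMixture(1, random_state=seed).fit(x)
    g2 = GaussianMixture(2, n_init=3, random_state=seed).fit(x)
    order = np.argsort(g2.means_.ravel())
    return APLDistribution(
        mean=float(areas.mean()),
        sd=float(areas.std(ddof=1)),
        delta_bic=float(g1.bic(x) - g2.bic(x)),
        gmm_means=g2.means_.ravel()[order],
        gmm_weights=g2.weights_[order],
        n=areas.size,
    )


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentMatrix:
    species: list[str]
    E: np.ndarray  # E[i, j] = C_local(j around i)/C_bulk(j)
    se: np.ndarray
    c_local: np.ndarray
    c_bulk: np.ndarray
    radius: float
    mode: str
    metadata: dict[str, Any] = field(default_factory=dict)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.species.index(pair[0])
        j = self.species.index(pair[1])
        return float(self.E[i, j])


def _enrichment_frame_leaflet(
    pos: np.ndarray, species: np.ndarray, names: list[str],
    radius: float, box: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame, per-leaflet mean neighbour counts n̄(j|i) and bulk counts."""
    Lx, Ly = box
    tree = spatial.cKDTree(np.mod(pos, [Lx, Ly]), boxsize=[Lx, Ly])
    neigh = tree.query_ball_point(np.mod(pos, [Lx, Ly]), radius)
    k = len(names)
    sp_idx = np.searchsorted(np.array(names), species)
    counts = np.zeros((k, k))
    n_i = np.zeros(k)
    for p, lst in enumerate(neigh):
        i = sp_idx[p]
        n_i[i] += 1
        for q in lst:
            if q == p:
                continue
            counts[i, sp_idx[q]] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_counts = counts / n_i[:, None]
    bulk = np.array([(species == s).sum() for s in names], dtype=float)
    return mean_counts, bulk


def enrichment(
    traj: BilayerTrajectory,
    radius: float = 12.0,
    mode: str = "in_plane",
    frames: slice | Sequence[int] | None = None,
    n_boot: int = 100,
    block: int = 10,
    seed: int = 0,
) -> EnrichmentMatrix:
    """Fractional enrichment E_ij = C_j,local / C_j,bulk.

    C_j,local is the mean concentration of species j inside the lateral
    neighbourhood (radius ``radius`` Å) of a species-i lipid, the central
    lipid excluded; C_j,bulk = N_j/(Lx·Ly) per leaflet.  Leaflets are
    evaluated separately and averaged, then frames averaged; the SE
    comes from a seeded block bootstrap over frames.  E ≈ 1 means ideal
    mixing; E_ii > 1 with E_ij < 1 (i ≠ j) signals same-species
    clustering.
    """
    Lx, Ly = traj.box
    if radius > min(Lx, Ly) / 2.0:
        raise ValueError("radius exceeds half the box: minimum-image violation")
    if mode not in ("in_plane", "3d"):
        raise ValueError("mode must be 'in_plane' or '3d'")
    phos = traj.select(role="phosphate")
    names = sorted(str(s) for s in np.unique(traj.species[phos]))
    k = len(names)
    frame_ids = (
        list(range(traj.n_frames))
        if frames is None
        else list(np.arange(traj.n_frames)[frames])
        if isinstance(frames, slice)
        else list(frames)
    )
    area = Lx * Ly
    neigh_area = math.pi * radius**2

    per_frame_E = []
    c_local_acc = np.zeros((k, k))
    c_bulk_acc = np.zeros(k)
    for f in frame_ids:
        e_leafs = []
        for leaf in ("upper", "lower"):
            mask = phos & (traj.leaflet == leaf)
            if not mask.any():
                continue
            if mode == "in_plane":
                pos = traj.coords[f, mask, 0:2]
                mean_counts, bulk_n = _enrichment_frame_leaflet(
                    pos, traj.species[mask].astype(str), names, radius, traj.box
                )
                c_local = mean_counts / neigh_area
                c_bulk = bulk_n / area
            else:
                pos3 = traj.coords[f, mask, :]
                d = pos3[:, None, :] - pos3[None, :, :]
                d[..., 0] -= Lx * np.round(d[..., 0] / Lx)
                d[..., 1] -= Ly * np.round(d[..., 1] / Ly)
                dist = np.linalg.norm(d, axis=-1)
                np.fill_diagonal(dist, np.inf)
                sp = traj.species[mask].astype(str)
                sp_idx = np.searchsorted(np.array(names), sp)
                counts = np.zeros((k, k))
                n_i = np.zeros(k)
                within = dist < radius
                for i_name in range(k):
                    rows = sp_idx == i_name
                    n_i[i_name] = rows.sum()
                    for j_name in range(k):
                        cols = sp_idx == j_name
                        counts[i_name, j_name] = within[np.ix_(rows, cols)].sum()
                with np.errstate(invalid="ignore", divide="ignore"):
                    mean_counts = counts / n_i[:, None]
                vol = 4.0 / 3.0 * math.pi * radius**3
                z_ext = float(np.ptp(pos3[:, 2])) or 1.0
                c_local = mean_counts / vol
                c_bulk = np.array([(sp == s).sum() for s in names]) / (area * z_ext)
            with np.errstate(invalid="ignore", divide="ignore"):
                e_leafs.append(c_local / c_bulk[None, :])
            c_local_acc += np.nan_to_num(c_local)
            c_bulk_acc += c_bulk
        per_frame_E.append(np.nanmean(e_leafs, axis=0))
    per_frame_E = np.array(per_frame_E)  # (frames, k, k)
    E = per_frame_E.mean(axis=0)

    rng = np.random.default_rng(seed)
    nf = per_frame_E.shape[0]
    block = max(1, min(block, nf))
    n_blocks = max(nf // block, 1)
    boots = np.empty((n_boot, k, k))
    starts = np.arange(0, nf - block + 1)
    for b in range(n_boot):
        picks = rng.choice(starts, size=n_blocks, replace=True)
        idx = np.concatenate([np.arange(s, s + block) for s in picks])
        boots[b] = per_frame_E[idx].mean(axis=0)
    se = boots.std(axis=0, ddof=1)

    denom = 2 * len(frame_ids)
    return EnrichmentMatrix(
        species=names,
        E=E,
        se=se,
        c_local=c_local_acc / denom,
        c_bulk=c_bulk_acc / denom,
        radius=radius,
        mode=mode,
        metadata={
            "n_frames": len(frame_ids),
            "leaflet_handling": "separate per leaflet, then averaged",
            "self_excluded": True,
        },
    )


# ---------------------------------------------------------------------------
# snorkelling
# ---------------------------------------------------------------------------


@dataclass
class SnorkelResult:
    fraction: float  # time-averaged up-state fraction
    fraction_se: float
    per_frame: np.ndarray
    states: np.ndarray  # (frames, molecules) boolean
    mean_dwell_up: float  # ns
    mean_dwell_down: float  # ns
    z_threshold: float


def snorkelling_fraction(
    traj: BilayerTrajectory,
    species: str | None = None,
    z_threshold: float = 0.6,
) -> SnorkelResult:
    """Fraction of peroxide oxygens near the water interface.

    A peroxide oxygen counts as snorkelling ("up") in a frame when
    |z| > z_threshold · (thickness/2), strictly — an oxygen exactly at
    the threshold is "down".  Dwell times are mean contiguous run
    lengths of each state, in ns.
    """
    if not (0.0 < z_threshold <= 1.0):
        raise ValueError("z_threshold must lie in (0, 1]")
    mask = traj.select(role="peroxide_O")
    if species is not None:
        mask &= traj.species == species
    if not mask.any():
        raise ValueError("no peroxide_O particles for the requested species")
    thickness, _ = bilayer_thickness(traj)
    cut = z_threshold * thickness / 2.0
    z = traj.coords[:, mask, 2]
    states = np.abs(z) > cut  # strict inequality
    per_frame = states.mean(axis=1)
    nf = per_frame.size
    se = per_frame.std(ddof=1) / math.sqrt(nf) if nf > 1 else 0.0

    def mean_run(seq: np.ndarray, value: bool) -> list[int]:
        runs = []
        count = 0
        for s in seq:
            if s == value:
                count += 1
            elif count:
                runs.append(count)
                count = 0
        if count:
            runs.append(count)
        return runs

    ups: list[int] = []
    downs: list[int] = []
    for m in range(states.shape[1]):
        ups += mean_run(states[:, m], True)
        downs += mean_run(states[:, m], False)
    dwell_up = float(np.mean(ups) * traj.dt) if ups else float("nan")
    dwell_down = float(np.mean(downs) * traj.dt) if downs else float("nan")
    return SnorkelResult(
        fraction=float(per_frame.mean()),
        fraction_se=float(se),
        per_frame=per_frame,
        states=states,
        mean_dwell_up=dwell_up,
        mean_dwell_down=dwell_down,
        z_threshold=z_threshold,
    )


# ---------------------------------------------------------------------------
# diffusion
# ---------------------------------------------------------------------------


@dataclass
class DiffusionEstimate:
    D: float  # Å²/ns
    se: float
    lags: np.ndarray  # ns
    msd: np.ndarray  # Å²
    fit_window: tuple[float, float]
    loglog_slope: float
    non_diffusive: bool
    metadata: dict[str, Any] = field(default_factory=dict)


def _unwrap_xy(traj: BilayerTrajectory, mask: np.ndarray) -> np.ndarray:
    """Unwrap wrapped lateral coordinates by minimum-image steps."""
    xy = traj.coords[:, mask, 0:2]
    steps = np.diff(xy, axis=0)
    for k in (0, 1):
        L = traj.box[k]
        if np.any(np.abs(np.abs(steps[..., k]) - L / 2) < 1e-9) or np.any(
            np.abs(steps[..., k]) > L
        ):
            raise ValueError(
                "wrap-ambiguous steps (≥ box/2) detected; record frames more often"
            )
        steps[..., k] -= L * np.round(steps[..., k] / L)
    out = np.empty_like(xy)
    out[0] = xy[0]
    out[1:] = xy[0] + np.cumsum(steps, axis=0)
    return out


def msd_diffusion(
    traj: BilayerTrajectory,
    species: str | None = None,
    fit_fraction: tuple[float, float] = (0.1, 0.5),
) -> DiffusionEstimate:
    """Lateral diffusion coefficient from the time-averaged MSD.

    Uses one anchor (phosphate) per molecule, on unwrapped coordinates.
    The MSD is averaged over all time origins and molecules; D is
    slope/4 of a weighted linear fit restricted to the interior lag
    window (default 10–50% of the maximum lag, excluding the noisy
    short-lag and poorly sampled long-lag ends).  A log-log slope far
    from 1 over the window marks the motion as non-diffusive.
    """
    mask = traj.select(role="phosphate")
    if species is not None:
        mask &= traj.species == species
    if not mask.any():
        raise ValueError("no particles selected for MSD")
    if traj.n_frames < 5:
        raise ValueError("need at least 5 frames for an MSD")
    if traj.unwrapped_xy is not None:
        xy = traj.unwrapped_xy[:, mask, :]
    else:
        xy = _unwrap_xy(traj, mask)
    nf = xy.shape[0]
    max_lag = nf - 1
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(lags.size)
    for li, lag in enumerate(lags):
        d = xy[lag:] - xy[:-lag]
        msd[li] = np.mean(np.sum(d * d, axis=-1))
    t = lags * traj.dt
    lo = max(int(fit_fraction[0] * max_lag), 1)
    hi = max(int(fit_fraction[1] * max_lag), lo + 2)
    wsel = slice(lo - 1, hi)
    res = stats.linregress(t[wsel], msd[wsel])
    D = res.slope / 4.0
    se = res.stderr / 4.0 if res.stderr is not None else float("nan")
    pos = msd[wsel] > 0
    ll = stats.linregress(np.log(t[wsel][pos]), np.log(msd[wsel][pos]))
    non_diffusive = abs(ll.slope - 1.0) > 0.3
    return DiffusionEstimate(
        D=float(max(D, 0.0)),
        se=float(se),
        lags=t,
        msd=msd,
        fit_window=(float(t[wsel][0]), float(t[wsel][-1])),
        loglog_slope=float(ll.slope),
        non_diffusive=bool(non_diffusive),
        metadata={"n_molecules": int(mask.sum() if traj.unwrapped_xy is None else xy.shape[1])},
    )


# ---------------------------------------------------------------------------
# Saffman–Delbrück
# ---------------------------------------------------------------------------


def saffman_delbruck(
    membrane_viscosity: float,
    thickness: float,
    probe_radius: float,
    water_viscosity: float = 1.0,
    temperature: float = 300.0,
) -> float:
    """Lateral diffusion coefficient of a membrane inclusion, µm²/s.

    D = k_BT/(4π η_m h) · (ln(L_sd/r) − γ) with the Saffman–Delbrück
    length L_sd = η_m h/(2 η_w).  Inputs: membrane (bulk-equivalent)
    viscosity η_m in cP, hydrophobic thickness h in nm, inclusion radius
    r in nm, surrounding water viscosity in cP, temperature in K.  Valid
    only for r < L_sd.
    """
    if membrane_viscosity <= 0 or thickness <= 0 or probe_radius <= 0:
        raise ValueError("viscosity, thickness and radius must be positive")
    if water_viscosity <= 0 or temperature <= 0:
        raise ValueError("water viscosity and temperature must be positive")
    eta_m = membrane_viscosity * 1e-3  # Pa·s
    eta_w = water_viscosity * 1e-3
    h = thickness * 1e-9  # m
    r = probe_radius * 1e-9
    l_sd = eta_m * h / (2.0 * eta_w)
    if r >= l_sd:
        raise ValueError(
            "probe radius exceeds the Saffman–Delbrück length: outside the SD regime"
        )
    d = KB * temperature / (4.0 * math.pi * eta_m * h) * (math.log(l_sd / r) - EULER_GAMMA)
    return d * 1e12  # m²/s → µm²/s


def saffman_delbruck_viscosity(
    diffusion: float,
    thickness: float,
    probe_radius: float,
    water_viscosity: float = 1.0,
    temperature: float = 300.0,
) -> float:
    """Invert the Saffman–Delbrück relation: η_m (cP) from D (µm²/s).

    D is strictly decreasing in η_m, so the root is bracketed and found
    by bisection.
    """
    if diffusion <= 0:
        raise ValueError("diffusion coefficient must be positive")

    def f(eta):
        try:
            return saffman_delbruck(
                eta, thickness, probe_radius, water_viscosity, temperature
            ) - diffusion
        except ValueError:
            return float("inf")  # below the SD-regime floor: D undefined, treat as too-high D

    lo, hi = 1e-3, 1e9
    while f(lo) == float("inf"):
        lo *= 10.0
        if lo > hi:
            raise ValueError("no viscosity satisfies the SD regime for these inputs")
    if f(lo) < 0:
        raise ValueError("requested D too high for the SD regime at this geometry")
    sol = optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-12)
    return float(sol)


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------


def contact_map(
    traj: BilayerTrajectory,
    roles: Sequence[str],
    cutoff: float = 3.5,
) -> tuple[np.ndarray, list[str]]:
    """Intermolecular contact frequencies between site roles.

    For each role pair (a, b) the entry is the fraction of
    frame × molecule-pair combinations in which the role-a site of one
    molecule lies within ``cutoff`` Å (in-plane minimum image, plain z)
    of the role-b site of the other, symmetrized over the two
    assignments.  Returns (matrix, roles).
    """
    roles = list(roles)
    known = set(traj.role.astype(str))
    site_idx: dict[str, np.ndarray] = {}
    site_mols: dict[str, np.ndarray] = {}
    for r in roles:
        m = traj.select(role=r)
        if not m.any():
            raise ValueError(f"unknown or absent site role: {r}")
        site_idx[r] = np.flatnonzero(m)
        site_mols[r] = traj.mol_id[m]
    Lx, Ly = traj.box
    k = len(roles)
    freq = np.zeros((k, k))
    for ia, ra in enumerate(roles):
        for jb in range(ia, k):
            rb = roles[jb]
            total = 0
            hits = 0
            mols_a, mols_b = site_mols[ra], site_mols[rb]
            pa_idx, pb_idx = site_idx[ra], site_idx[rb]
            diff_mol = mols_a[:, None] != mols_b[None, :]
            for f in range(traj.n_frames):
                pa = traj.coords[f, pa_idx, :]
                pb = traj.coords[f, pb_idx, :]
                d = pa[:, None, :] - pb[None, :, :]
                d[..., 0] -= Lx * np.round(d[..., 0] / Lx)
                d[..., 1] -= Ly * np.round(d[..., 1] / Ly)
                within = (np.sum(d * d, axis=-1) < cutoff**2) & diff_mol
                if ra == rb:
                    hits += int(np.triu(within, 1).sum())
                    total += int(np.triu(diff_mol, 1).sum())
                else:
                    # unordered molecule pairs; contact if either assignment matches
                    pair_hit = within | within.T if within.shape[0] == within.shape[1] else within
                    hits += int(np.triu(pair_hit, 1).sum()) if pair_hit.shape[0] == pair_hit.shape[1] else int(pair_hit.sum())
                    total += (
                        int(np.triu(diff_mol, 1).sum())
                        if diff_mol.shape[0] == diff_mol.shape[1]
                        else int(diff_mol.sum())
                    )
            freq[ia, jb] = freq[jb, ia] = hits / total if total else float("nan")
    return freq, roles
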