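"""Trajectory metrics: analytic limits, brute-force oracles and
periodic-boundary invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxmembrane import bilayer as bl
from oxmembrane import synthetic_data as syn

from conftest import make_traj


# ---------------------------------------------------------------------------
# order parameter
# ---------------------------------------------------------------------------


def _chain_traj(vectors, box=(100.0, 100.0)):
    """One frame, molecules with 2 chain sites separated by given vectors."""
    vectors = np.asarray(vectors, dtype=float)
    n = vectors.shape[0]
    base = np.column_stack(
        [np.linspace(5, 95, n), np.linspace(5, 95, n), np.full(n, 10.0)]
    )
    coords = np.empty((1, 2 * n, 3))
    coords[0, 0::2] = base
    coords[0, 1::2] = base + vectors
    roles = np.tile(["chain_0", "chain_1"], n)
    mols = np.repeat(np.arange(n), 2)
    return make_traj(coords, role=roles, mol_id=mols, box=box)


class TestOrderParameter:
    def test_aligned_vectors_give_one(self):
        traj = _chain_traj(np.tile([0.0, 0.0, 1.27], (10, 1)))
        assert bl.order_parameter(traj).s_cd[0] == pytest.approx(1.0, abs=1e-12)

    def test_inplane_vectors_give_minus_half(self):
        traj = _chain_traj(np.tile([1.27, 0.0, 0.0], (10, 1)))
        assert bl.order_parameter(traj).s_cd[0] == pytest.approx(-0.5, abs=1e-12)

    def test_isotropic_vectors_give_zero(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal((100_000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        traj = _chain_traj(v * 1.27, box=(1e6, 1e6))
        s = bl.order_parameter(traj).s_cd[0]
        # brute-force oracle on the same sample
        cos2 = (v[:, 2]) ** 2
        s_oracle = 0.5 * (3 * cos2.mean() - 1)
        assert s == pytest.approx(s_oracle, abs=1e-12)
        assert abs(s) < 0.01

    def test_generator_order_target_recovered(self, mixing_traj):
        prof = bl.order_parameter(mixing_traj, species="POPC")
        target = mixing_traj.metadata["truth"]["order_target"]["POPC"]
        np.testing.assert_allclose(prof.s_cd, target, atol=0.02)

    def test_bounds_respected_on_arbitrary_vectors(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal((500, 3)) * rng.uniform(0.1, 3.0, (500, 1))
        traj = _chain_traj(v, box=(1e6, 1e6))
        s = bl.order_parameter(traj).s_cd[0]
        assert -0.5 - 1e-9 <= s <= 1.0 + 1e-9

    def test_single_site_rejected(self):
        coords = np.zeros((1, 3, 3))
        traj = make_traj(coords, role=["chain_0"] * 3)
        with pytest.raises(ValueError):
            bl.order_parameter(traj)


# ---------------------------------------------------------------------------
# thickness / density profiles
# ---------------------------------------------------------------------------


def _phosphate_sheet(z_up, z_lo, n=50, jitter=0.0, seed=0, frames=1):
    rng = np.random.default_rng(seed)
    xy = rng.uniform(0, 100, (n, 2))
    coords = np.empty((frames, 2 * n, 3))
    for f in range(frames):
        coords[f, :n, 0:2] = xy
        coords[f, n:, 0:2] = xy
        coords[f, :n, 2] = z_up + jitter * rng.standard_normal(n)
        coords[f, n:, 2] = z_lo + jitter * rng.standard_normal(n)
    return make_traj(
        coords,
        leaflet=["upper"] * n + ["lower"] * n,
        role=["phosphate"] * (2 * n),
    )


class TestThickness:
    def test_planted_planes(self):
        traj = _phosphate_sheet(16.2, -16.2)
        t, _ = bl.bilayer_thickness(traj)
        assert t == pytest.approx(32.4, abs=1e-9)

    def test_unbiased_under_jitter(self):
        traj = _phosphate_sheet(19.6, -19.6, n=500, jitter=1.0, frames=10, seed=2)
        t, se = bl.bilayer_thickness(traj)
        samples = 2 * 500 * 10
        se_analytic = 2.0 / math.sqrt(samples)  # SD 1 Å per plane
        assert abs(t - 39.2) < 3 * max(se, se_analytic)

    def test_flat_sheets_zero(self):
        traj = _phosphate_sheet(0.0, 0.0)
        assert bl.bilayer_thickness(traj)[0] == 0.0

    def test_one_leaflet_missing_rejected(self):
        coords = np.zeros((1, 4, 3))
        traj = make_traj(coords, leaflet=["upper"] * 4)
        with pytest.raises(ValueError):
            bl.bilayer_thickness(traj)


class TestDensityProfile:
    def test_twin_phosphate_peaks(self):
        traj = _phosphate_sheet(19.6, -19.6, n=2000, jitter=0.2, seed=3)
        prof = bl.electron_density_profile(traj, bin_width=0.5)
        dens = prof.density["A"]
        # find the two modes
        upper = prof.z_centers[prof.z_centers > 0][np.argmax(dens[prof.z_centers > 0])]
        lower = prof.z_centers[prof.z_centers < 0][np.argmax(dens[prof.z_centers < 0])]
        assert upper - lower == pytest.approx(39.2, abs=0.5)

    def test_profile_integral_conserves_weight(self):
        traj = _phosphate_sheet(10.0, -10.0, n=100, jitter=2.0, seed=4, frames=3)
        prof = bl.electron_density_profile(traj, bin_width=1.0)
        area = traj.box[0] * traj.box[1]
        total = sum(d.sum() * prof.bin_width * area for d in prof.density.values())
        assert total == pytest.approx(traj.n_particles, rel=1e-9)

    def test_uniform_slab_flat(self):
        rng = np.random.default_rng(5)
        n = 20_000
        coords = np.empty((1, n, 3))
        coords[0, :, 0:2] = rng.uniform(0, 100, (n, 2))
        coords[0, :, 2] = rng.uniform(-10, 10, n)
        traj = make_traj(coords)
        prof = bl.electron_density_profile(traj, bin_width=2.0)
        dens = prof.density["A"]
        interior = dens[(prof.z_centers > -8) & (prof.z_centers < 8)]
        expected = n / (100 * 100 * 20)
        np.testing.assert_allclose(interior, expected, rtol=0.15)

    def test_empty_group_rejected(self):
        traj = _phosphate_sheet(10.0, -10.0)
        with pytest.raises(ValueError, match="empty group"):
            bl.electron_density_profile(traj, groups={"none": np.zeros(traj.n_particles, bool)})


# ---------------------------------------------------------------------------
# Voronoi APL
# ---------------------------------------------------------------------------


class TestVoronoi:
    def test_square_lattice_equal_cells(self):
        xs = np.array([25.0, 75.0])
        seeds = np.array([[x, y] for x in xs for y in xs])
        coords = np.zeros((1, 4, 3))
        coords[0, :, 0:2] = seeds
        traj = make_traj(coords)
        amap = bl.apl_voronoi(traj)
        np.testing.assert_allclose(amap.areas, 2500.0, rtol=1e-9)

    def test_area_conservation_random_seeds(self):
        rng = np.random.default_rng(6)
        n = 200
        coords = np.zeros((1, n, 3))
        coords[0, :, 0:2] = rng.uniform(0, 100, (n, 2))
        traj = make_traj(coords)
        amap = bl.apl_voronoi(traj)
        assert amap.areas.sum() == pytest.approx(100.0 * 100.0, rel=1e-6)

    def test_duplicate_seeds_jittered_with_warning(self):
        coords = np.zeros((1, 5, 3))
        coords[0, :, 0:2] = [[10, 10], [10, 10], [50, 50], [90, 10], [50, 90]]
        traj = make_traj(coords)
        with pytest.warns(UserWarning, match="jittered"):
            amap = bl.apl_voronoi(traj)
        assert amap.areas.sum() == pytest.approx(1e4, rel=1e-6)

    def test_too_few_seeds_rejected(self):
        coords = np.zeros((1, 3, 3))
        traj = make_traj(coords)
        with pytest.raises(ValueError):
            bl.apl_voronoi(traj)

    def test_bimodal_areas_detected(self):
        # dense and sparse half-boxes with mean areas near 63 / 81 Å²
        rng = np.random.default_rng(7)
        box = (120.0, 120.0)
        n_dense = int(60.0 * 120.0 / 63.0)
        n_sparse = int(60.0 * 120.0 / 81.0)
        dense = np.column_stack(
            [rng.uniform(0, 60, n_dense), rng.uniform(0, 120, n_dense)]
        )
        sparse = np.column_stack(
            [rng.uniform(60, 120, n_sparse), rng.uniform(0, 120, n_sparse)]
        )
        seeds = np.vstack([dense, sparse])
        coords = np.zeros((1, seeds.shape[0], 3))
        coords[0, :, 0:2] = seeds
        traj = make_traj(coords, box=box)
        areas = bl.apl_voronoi(traj).areas
        dist = bl.apl_distribution(areas)
        assert dist.delta_bic > 10


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


def _brute_force_enrichment(pos, species, names, radius, box):
    """O(n²) minimum-image neighbour counting oracle."""
    Lx, Ly = box
    n = pos.shape[0]
    k = len(names)
    counts = np.zeros((k, k))
    n_i = np.zeros(k)
    idx = {s: i for i, s in enumerate(names)}
    for a in range(n):
        ia = idx[species[a]]
        n_i[ia] += 1
        for b in range(n):
            if a == b:
                continue
            dx = pos[a, 0] - pos[b, 0]
            dy = pos[a, 1] - pos[b, 1]
            dx -= Lx * round(dx / Lx)
            dy -= Ly * round(dy / Ly)
            if dx * dx + dy * dy < radius * radius:
                counts[ia, idx[species[b]]] += 1
    c_local = counts / n_i[:, None] / (math.pi * radius**2)
    c_bulk = np.array([(np.asarray(species) == s).sum() for s in names]) / (Lx * Ly)
    return c_local / c_bulk[None, :]


class TestEnrichment:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        n = 300
        box = (80.0, 80.0)
        pos = rng.uniform(0, 80, (n, 2))
        species = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))
        coords = np.zeros((1, n, 3))
        coords[0, :, 0:2] = pos
        traj = make_traj(coords, species=species, box=box)
        enr = bl.enrichment(traj, radius=12.0, n_boot=5)
        oracle = _brute_force_enrichment(pos, species, enr.species, 12.0, box)
        np.testing.assert_allclose(enr.E, oracle, atol=1e-12)

    def test_segregated_halves_match_oracle(self):
        rng = np.random.default_rng(9)
        n = 200
        box = (100.0, 100.0)
        pos = np.vstack(
            [
                np.column_stack([rng.uniform(0, 50, n // 2), rng.uniform(0, 100, n // 2)]),
                np.column_stack([rng.uniform(50, 100, n // 2), rng.uniform(0, 100, n // 2)]),
            ]
        )
        species = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
        coords = np.zeros((1, n, 3))
        coords[0, :, 0:2] = pos
        traj = make_traj(coords, species=species, box=box)
        enr = bl.enrichment(traj, radius=12.0, n_boot=5)
        oracle = _brute_force_enrichment(pos, species, enr.species, 12.0, box)
        np.testing.assert_allclose(enr.E, oracle, atol=1e-12)
        assert enr[("A", "A")] > 1.0 and enr[("A", "B")] < 1.0

    def test_ideal_mixing_gives_unity(self):
        # independent uniform frames (200/leaflet, 50:50) — no temporal
        # correlation, so E must sit at 1 to high precision
        rng = np.random.default_rng(12)
        n, frames, L = 400, 100, 115.0
        coords = np.zeros((frames, n, 3))
        coords[:, :, 0:2] = rng.uniform(0, L, (frames, n, 2))
        species = np.array(["A", "B"] * (n // 2))
        leaflet = np.array(["upper"] * (n // 2) + ["lower"] * (n // 2))
        traj = make_traj(coords, species=species, leaflet=leaflet, box=(L, L))
        enr = bl.enrichment(traj, n_boot=10)
        np.testing.assert_allclose(enr.E, 1.0, atol=0.05)

    def test_radius_beyond_half_box_rejected(self, mixing_traj):
        with pytest.raises(ValueError, match="minimum-image"):
            bl.enrichment(mixing_traj, radius=60.0)

    @given(st.floats(min_value=-200.0, max_value=200.0), st.floats(min_value=-200.0, max_value=200.0))
    @settings(deadline=None, max_examples=10)
    def test_periodic_translation_invariance(self, sx, sy):
        rng = np.random.default_rng(10)
        n = 100
        coords = np.zeros((1, n, 3))
        coords[0, :, 0:2] = rng.uniform(0, 80, (n, 2))
        species = np.array(["A"] * 50 + ["B"] * 50)
        traj = make_traj(coords, species=species, box=(80.0, 80.0))
        shifted = coords.copy()
        shifted[0, :, 0] = np.mod(shifted[0, :, 0] + sx, 80.0)
        shifted[0, :, 1] = np.mod(shifted[0, :, 1] + sy, 80.0)
        traj2 = make_traj(shifted, species=species, box=(80.0, 80.0))
        e1 = bl.enrichment(traj, n_boot=2).E
        e2 = bl.enrichment(traj2, n_boot=2).E
        np.testing.assert_allclose(e1, e2, atol=1e-9)


# ---------------------------------------------------------------------------
# snorkelling
# ---------------------------------------------------------------------------


class TestSnorkelling:
    def test_planted_fraction_recovered(self):
        spec = syn.BilayerSimSpec(
            n_per_leaflet=100,
            box_lengths=(82.0, 82.0),
            species_fractions={"POPC-OOH": 1.0},
            snorkel_fraction=0.4,
            n_frames=400,
            seed=13,
        )
        traj = syn.gen_bilayer_traj(spec)
        res = bl.snorkelling_fraction(traj)
        assert res.fraction == pytest.approx(0.40, abs=0.03)
        assert res.mean_dwell_up > 5 * traj.dt  # slow interconversion

    def test_midplane_oxygens_give_zero(self):
        n = 20
        coords = np.zeros((2, 2 * n, 3))
        coords[:, :n, 2] = 19.6
        coords[:, n:, 2] = 0.0  # peroxide at midplane
        traj = make_traj(
            coords,
            leaflet=["upper"] * (2 * n),
            role=["phosphate"] * n + ["peroxide_O"] * n,
            mol_id=list(range(n)) * 2,
        )
        # add a lower leaflet phosphate sheet so thickness is defined
        coords2 = np.concatenate([coords, np.zeros((2, n, 3))], axis=1)
        coords2[:, 2 * n :, 2] = -19.6
        traj = make_traj(
            coords2,
            leaflet=["upper"] * (2 * n) + ["lower"] * n,
            role=["phosphate"] * n + ["peroxide_O"] * n + ["phosphate"] * n,
            mol_id=list(range(n)) * 2 + list(range(n, 2 * n)),
        )
        assert bl.snorkelling_fraction(traj).fraction == 0.0

    def test_boundary_is_strict(self):
        n = 10
        coords = np.zeros((1, 3 * n, 3))
        coords[0, :n, 2] = 20.0
        coords[0, n : 2 * n, 2] = -20.0
        coords[0, 2 * n :, 2] = 20.0  # peroxides exactly at the phosphate plane
        traj = make_traj(
            coords,
            leaflet=["upper"] * n + ["lower"] * n + ["upper"] * n,
            role=["phosphate"] * (2 * n) + ["peroxide_O"] * n,
            mol_id=list(range(2 * n)) + list(range(n)),
        )
        res = bl.snorkelling_fraction(traj, z_threshold=1.0)
        assert res.fraction == 0.0  # strict inequality at the threshold

    def test_invalid_threshold_rejected(self, mixing_traj):
        with pytest.raises(ValueError):
            bl.snorkelling_fraction(mixing_traj, z_threshold=1.5)


# ---------------------------------------------------------------------------
# diffusion
# ---------------------------------------------------------------------------


class TestDiffusion:
    def test_ballistic_motion_flagged(self):
        n, frames = 20, 50
        coords = np.zeros((frames, n, 3))
        unwrapped = np.zeros((frames, n, 2))
        for f in range(frames):
            unwrapped[f, :, 0] = 2.0 * f
            coords[f, :, 0] = np.mod(2.0 * f, 100.0)
        traj = make_traj(coords)
        traj.unwrapped_xy = unwrapped
        est = bl.msd_diffusion(traj)
        assert est.non_diffusive
        assert est.loglog_slope == pytest.approx(2.0, abs=0.05)

    def test_two_species_ratio_recovered(self):
        spec = syn.BilayerSimSpec(
            n_per_leaflet=150,
            box_lengths=(100.0, 100.0),
            species_fractions={"POPC": 0.5, "POPC-OOH": 0.5},
            diffusion_coeffs={"POPC": 1.0, "POPC-OOH": 0.8},
            n_frames=300,
            seed=14,
        )
        traj = syn.gen_bilayer_traj(spec)
        d1 = bl.msd_diffusion(traj, species="POPC").D
        d2 = bl.msd_diffusion(traj, species="POPC-OOH").D
        assert d2 / d1 == pytest.approx(0.8, rel=0.05)

    def test_unwrap_fallback_matches_unwrapped(self, mixing_traj):
        est_ref = bl.msd_diffusion(mixing_traj, species="POPC")
        stripped = syn.BilayerTrajectory(
            coords=mixing_traj.coords,
            species=mixing_traj.species,
            leaflet=mixing_traj.leaflet,
            role=mixing_traj.role,
            mol_id=mixing_traj.mol_id,
            box=mixing_traj.box,
            dt=mixing_traj.dt,
        )
        est = bl.msd_diffusion(stripped, species="POPC")
        assert est.D == pytest.approx(est_ref.D, rel=1e-9)

    def test_too_few_frames_rejected(self):
        traj = make_traj(np.zeros((3, 5, 3)))
        with pytest.raises(ValueError):
            bl.msd_diffusion(traj)


# ---------------------------------------------------------------------------
# Saffman–Delbrück
# ---------------------------------------------------------------------------


class TestSaffmanDelbruck:
    def test_roundtrip_identity(self):
        d = bl.saffman_delbruck(241.0, 3.24, 0.45)
        eta = bl.saffman_delbruck_viscosity(d, 3.24, 0.45)
        assert eta == pytest.approx(241.0, rel=1e-8)

    def test_monotone_decreasing_in_viscosity(self):
        d1 = bl.saffman_delbruck(150.0, 3.24, 0.45)
        d2 = bl.saffman_delbruck(300.0, 3.24, 0.45)
        assert d2 < d1

    def test_against_closed_form_oracle(self):
        # independent direct evaluation of the formula
        kb, T = 1.380649e-23, 300.0
        eta_m, h, r, eta_w = 241.0 * 1e-3, 3.24e-9, 0.45e-9, 1.0e-3
        l_sd = eta_m * h / (2 * eta_w)
        d_oracle = kb * T / (4 * math.pi * eta_m * h) * (math.log(l_sd / r) - 0.5772156649015329)
        assert bl.saffman_delbruck(241.0, 3.24, 0.45) == pytest.approx(d_oracle * 1e12, rel=1e-12)

    def test_outside_regime_rejected(self):
        with pytest.raises(ValueError, match="SD regime"):
            bl.saffman_delbruck(1.0, 3.24, 10.0)


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------


class TestContacts:
    @staticmethod
    def _pair_traj(separation):
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 0] = separation
        return make_traj(
            coords, role=["peroxide_O", "peroxide_O"], mol_id=[0, 1], species=["ox", "ox"]
        )

    def test_close_pair_full_contact(self):
        freq, _ = bl.contact_map(self._pair_traj(2.8), roles=["peroxide_O"], cutoff=3.5)
        assert freq[0, 0] == 1.0

    def test_distant_pair_no_contact(self):
        freq, _ = bl.contact_map(self._pair_traj(10.0), roles=["peroxide_O"], cutoff=3.5)
        assert freq[0, 0] == 0.0

    def test_symmetry(self, mixing_traj):
        sub = syn.BilayerTrajectory(
            coords=mixing_traj.coords[:5],
            species=mixing_traj.species,
            leaflet=mixing_traj.leaflet,
            role=mixing_traj.role,
            mol_id=mixing_traj.mol_id,
            box=mixing_traj.box,
            dt=mixing_traj.dt,
        )
        freq, roles = bl.contact_map(sub, roles=["phosphate", "peroxide_O"], cutoff=10.0)
        np.testing.assert_allclose(freq, freq.T, atol=1e-12)

    def test_unknown_role_rejected(self, mixing_traj):
        with pytest.raises(ValueError, match="unknown"):
            bl.contact_map(mixing_traj, roles=["ester_O"], cutoff=3.5)
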