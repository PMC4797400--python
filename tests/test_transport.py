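import numpy as np
import pytest

from mobydose.decay import NuclideData
from mobydose.phantom import PhantomSpec, VoxelPhantom
from mobydose.transport import (
    KEV_TO_J,
    SFactorMatrix,
    _physics,
    read_s_matrix,
    simulate_s_factors,
    split_self_vs_cross,
)


def photon_only_nuclide(energy_kev, intensity=1.0):
    """Single-line emitter with a vanishing beta contribution."""
    return NuclideData(
        half_life_days=6.647,
        beta_energies_kev=np.array([1e-3]),
        beta_density_per_kev=np.array([1e-12]),
        photon_lines=np.array([[energy_kev, intensity]]),
    )


def two_sphere_phantom(separation_vox, grid=(40, 40, 120), voxel=2.0, r_vox=4):
    """Two equal spheres in a water block (handcrafted labels)."""
    spec = PhantomSpec(
        body_weight_g=1.0, organ_masses_g={}, tumor_mass_g=0.0,
        grid=grid, voxel_size_mm=voxel,
    )
    labels = np.ones(grid, dtype=np.uint8)  # all water ("body")
    zc = grid[2] // 2
    centers = [
        (grid[0] // 2, grid[1] // 2, zc - separation_vox // 2),
        (grid[0] // 2, grid[1] // 2, zc + separation_vox - separation_vox // 2),
    ]
    xx, yy, zz = np.meshgrid(*[np.arange(n) for n in grid], indexing="ij")
    for rid, (cx, cy, cz) in enumerate(centers, start=2):
        m = (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2 <= r_vox**2
        labels[m] = rid
    return VoxelPhantom(
        labels=labels, region_ids={"body": 1, "a": 2, "b": 3}, spec=spec
    )


class TestElectronEquilibrium:
    def test_self_dose_equals_mean_beta_energy(self, water_block, nuclide):
        # source region much larger than the ~2 mm maximum beta range:
        # almost all emitted beta energy is reabsorbed, S*m = E_mean
        s = simulate_s_factors(
            water_block, nuclide, 100_000, seed=11, include_photons=False
        )
        m_g = water_block.region_masses()["body"]
        val = s.s[("body", "body")] * m_g  # Gy*g = mJ per decay... (1e-3 J/kg * g)
        expected = nuclide.mean_beta_energy_kev * KEV_TO_J / 1e-3
        assert val == pytest.approx(expected, rel=0.02)

    def test_uncertainty_scales_inverse_sqrt_n(self, water_block, nuclide):
        u = []
        for n in (20_000, 80_000):
            s = simulate_s_factors(
                water_block, nuclide, n, seed=5, include_photons=False
            )
            u.append(s.rel_uncertainty[("body", "body")])
        ratio = u[0] / u[1]
        assert 2.0 == pytest.approx(ratio, rel=0.2)


class TestPhotonTransport:
    def test_distant_cross_factor_strongly_attenuated(self):
        # 208 keV line, >10 cm of water between two small spheres:
        # cross S-factor must be < 1e-3 of the self S-factor
        ph = two_sphere_phantom(separation_vox=70, voxel=2.0)  # 140 mm apart
        nuc = photon_only_nuclide(208.37)
        s = simulate_s_factors(
            ph, nuc, 100_000, seed=3, include_electrons=False, source_regions=["a"]
        )
        assert s.s[("b", "a")] < 1e-3 * s.s[("a", "a")]

    def test_reciprocity_between_equal_regions(self):
        # uniform medium, equal-shaped regions: m_T S(T<-S) ~ m_S S(S<-T)
        ph = two_sphere_phantom(separation_vox=10, voxel=2.0)
        nuc = photon_only_nuclide(208.37)
        s = simulate_s_factors(
            ph, nuc, 40_000, seed=7, include_electrons=False,
            source_regions=["a", "b"],
        )
        masses = ph.region_masses()
        ab = masses["a"] * s.s[("a", "b")]
        ba = masses["b"] * s.s[("b", "a")]
        sigma = np.hypot(
            ab * s.rel_uncertainty[("a", "b")], ba * s.rel_uncertainty[("b", "a")]
        )
        assert abs(ab - ba) < 3 * sigma + 1e-18

    def test_energy_conservation(self, small_phantom, nuclide):
        # total deposited energy never exceeds total emitted energy
        s = simulate_s_factors(
            small_phantom, nuclide, 5_000, seed=9, source_regions=["liver"]
        )
        masses = small_phantom.region_masses()
        deposited = sum(
            s.s[(t, "liver")] * masses[t] for t in small_phantom.region_names
        )
        emitted = nuclide.mean_energy_per_decay_kev * KEV_TO_J / 1e-3
        assert deposited <= emitted * 1.001
        assert deposited > 0.5 * emitted  # most beta energy stays inside


class TestDeterminismAndValidation:
    def test_same_seed_same_matrix(self, water_block, nuclide):
        a = simulate_s_factors(water_block, nuclide, 5_000, seed=42)
        b = simulate_s_factors(water_block, nuclide, 5_000, seed=42)
        assert a.s == b.s

    def test_unphysical_cutoff_rejected(self, water_block, nuclide):
        with pytest.raises(ValueError, match="cutoff"):
            simulate_s_factors(water_block, nuclide, 5_000, seed=1, cutoff_kev=0.5)
        with pytest.raises(ValueError, match="cutoff"):
            simulate_s_factors(water_block, nuclide, 5_000, seed=1, cutoff_kev=500.0)

    def test_unknown_source_region_rejected(self, water_block, nuclide):
        with pytest.raises(ValueError, match="unknown source"):
            simulate_s_factors(
                water_block, nuclide, 5_000, seed=1, source_regions=["spleen"]
            )

    def test_csv_round_trip(self, tmp_path):
        s = SFactorMatrix(
            s={("a", "a"): 1e-9, ("b", "a"): 5e-12},
            rel_uncertainty={("a", "a"): 0.01, ("b", "a"): 0.2},
            n_histories=1000,
        )
        path = tmp_path / "smat.csv"
        s.save(path)
        back = read_s_matrix(path)
        assert back.s == s.s
        assert back.n_histories == 1000


class TestSelfVsCrossSplit:
    def test_single_source_self_equals_total(self):
        s = SFactorMatrix(
            s={("a", "a"): 1e-9}, rel_uncertainty={("a", "a"): 0.0}, n_histories=1
        )
        out = split_self_vs_cross(s, {"a": 1e9})
        assert out["a"] == (1.0, 1.0)

    def test_self_never_exceeds_total(self):
        s = SFactorMatrix(
            s={("a", "a"): 1e-9, ("a", "b"): 2e-10, ("b", "b"): 8e-10, ("b", "a"): 1e-10},
            rel_uncertainty={}, n_histories=1,
        )
        out = split_self_vs_cross(s, {"a": 1e9, "b": 2e9})
        for self_d, total in out.values():
            assert self_d <= total

    def test_zero_cumulated_gives_zero_dose(self):
        s = SFactorMatrix(s={("a", "a"): 1e-9}, rel_uncertainty={}, n_histories=1)
        out = split_self_vs_cross(s, {"a": 0.0})
        assert out["a"] == (0.0, 0.0)

    def test_region_mismatch_raises(self):
        s = SFactorMatrix(s={("a", "a"): 1e-9}, rel_uncertainty={}, n_histories=1)
        with pytest.raises(ValueError, match="no S entries"):
            split_self_vs_cross(s, {"c": 1e9})


class TestWaterPhysicsTables:
    def test_klein_nishina_matches_published_value_at_100kev(self):
        # incoherent mass attenuation of water at 100 keV ~ 0.165 cm^2/g
        mu = _physics().mu_incoherent(100.0) * 10.0  # per mm -> per cm
        assert mu == pytest.approx(0.165, rel=0.02)

    def test_photoelectric_dominates_at_low_energy_only(self):
        p = _physics()
        assert p.mu_photoelectric(15.0) > p.mu_incoherent(15.0)
        assert p.mu_photoelectric(208.0) < 0.01 * p.mu_incoherent(208.0)

    def test_csda_range_below_two_mm(self):
        # the hardest Lu-177 betas (~0.5 MeV) travel under ~2 mm in water
        assert _physics().csda_range_mm(np.array([497.0]))[0] < 2.0
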