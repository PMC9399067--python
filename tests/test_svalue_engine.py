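import numpy as np
import pytest

from radiocell import cell_geometry as cg
from radiocell import nuclide_data as nd
from radiocell import svalue_engine as sv
from radiocell.stopping import (
    ALPHA_WATER,
    ELECTRON_CSDA,
    J_PER_MEV,
    sample_beta_spectrum,
)


class TestStoppingModel:
    def test_alpha_ranges_plausible(self):
        # ~46 um at the Ac-225 alpha energy, ~81 um at the Po-213 energy
        assert 35 < ALPHA_WATER.range_um(5.79) < 55
        assert 65 < ALPHA_WATER.range_um(8.376) < 95

    def test_range_monotone_in_energy(self):
        e = np.linspace(0.1, 9.5, 50)
        r = ALPHA_WATER.range_um(e)
        assert np.all(np.diff(r) > 0)

    def test_deposit_never_exceeds_energy(self):
        rng = np.random.default_rng(0)
        e0 = rng.uniform(0.05, 9.0, 1000)
        s1 = rng.uniform(0, 50, 1000)
        s2 = s1 + rng.uniform(0, 50, 1000)
        dep = ALPHA_WATER.deposit_along(e0, s1, s2)
        assert np.all(dep >= 0)
        assert np.all(dep <= e0 + 1e-12)

    def test_full_track_deposits_full_energy(self):
        e0 = np.array([1.0, 5.0, 8.0])
        dep = ALPHA_WATER.deposit_along(e0, np.zeros(3), np.full(3, 1e4))
        assert dep == pytest.approx(e0, rel=1e-3)

    def test_beta_spectrum_mean_tracks_tabulated_value(self):
        rng = np.random.default_rng(1)
        sample = sample_beta_spectrum(0.4983, 100_000, rng, daughter_z=72)
        assert sample.mean() == pytest.approx(0.1494, rel=0.08)
        assert sample.max() <= 0.4983

    def test_electron_kernel_conserves_energy(self):
        # integral of 4 pi r^2 e(r) dr over all r equals the emitted energy
        from radiocell.stopping import electron_point_kernel_energy_density

        energy = 0.3
        r0 = ELECTRON_CSDA.range_um(energy)
        r = np.linspace(1e-3, 1.2 * r0, 4000)
        e_density = electron_point_kernel_energy_density(r, energy)
        total = np.trapezoid(4 * np.pi * r**2 * e_density, r)
        assert total == pytest.approx(energy, rel=1e-2)


class TestMediumSValue:
    def test_lu177_matches_full_transport_reference(self, lu177):
        assert sv.medium_svalue(lu177) == pytest.approx(2.30e-11, rel=0.10)

    def test_ac225_matches_full_transport_reference(self, ac225):
        assert sv.medium_svalue(ac225) == pytest.approx(4.57e-9, rel=0.10)

    def test_scales_inversely_with_mass(self, lu177):
        assert sv.medium_svalue(lu177, 2.0) == pytest.approx(
            sv.medium_svalue(lu177) / 2.0
        )

    def test_nonpositive_mass_rejected(self, lu177):
        with pytest.raises(ValueError):
            sv.medium_svalue(lu177, 0.0)


class TestSelfSValue:
    def test_surface_alpha_source_matches_1d_quadrature_oracle(self):
        """Independent oracle: for a monoenergetic alpha source on the
        surface of a large spherical nucleus, the absorbed energy per
        emission reduces to a 1-D integral over the inward direction
        cosine (chord = 2 R mu); the 3-D MC engine must match it."""
        energy = 6.0
        chain = nd.DecayChain(
            steps=(
                nd.NuclideStep(
                    name="X", half_life_s=1000.0,
                    emissions=(nd.Emission("alpha", energy, 1.0),),
                    daughters=(("Y", 1.0),),
                ),
                nd.NuclideStep(name="Y", half_life_s=np.inf),
            )
        )
        r_n = 299.99
        geom = cg.FloatingCellGeometry(cell_radius_um=300.0, nucleus_radius_um=r_n)
        result = sv.self_svalue(geom, "cell_membrane", chain,
                                n_histories=200_000, seed=3)
        r0 = ALPHA_WATER.range_um(energy)
        mu = np.linspace(1e-6, 1.0, 20_000)
        chord = 2.0 * r_n * mu
        deposit = energy - ALPHA_WATER.energy_at_range(
            np.clip(r0 - chord, 0.0, None)
        )
        expected_mev = 0.5 * np.trapezoid(deposit, mu)  # inward hemisphere
        m_kg = geom.nucleus_volume_um3 * 1e-15
        expected = expected_mev * J_PER_MEV / m_kg
        assert result.value == pytest.approx(expected, rel=0.015)

    def test_size_monotonicity(self, ac225, lu177):
        for chain, n in ((ac225, 40_000), (lu177, 60_000)):
            values = []
            for size in ("minimum", "average", "maximum"):
                floating, _ = cg.default_geometries(size)
                values.append(
                    sv.self_svalue(
                        floating, "cytoplasm", chain, n_histories=n, seed=7
                    ).value
                )
            assert values[0] > values[1] > values[2]

    def test_fixed_seed_reproducible(self, ac225):
        floating, _ = cg.default_geometries("average")
        r1 = sv.self_svalue(floating, "cytoplasm", ac225, n_histories=20_000, seed=11)
        r2 = sv.self_svalue(floating, "cytoplasm", ac225, n_histories=20_000, seed=11)
        assert r1.value == r2.value

    def test_absorbed_fraction_bounded(self, ac225):
        floating, attached = cg.default_geometries("minimum")
        e_total = nd.charged_energy_per_decay(ac225)
        for geom in (floating, attached):
            m_kg = geom.nucleus_volume_um3 * 1e-15
            for source in ("cell_membrane", "cytoplasm"):
                value = sv.self_svalue(
                    geom, source, ac225, n_histories=20_000, seed=5
                ).value
                absorbed_fraction = value * m_kg / (e_total * J_PER_MEV)
                assert 0.0 <= absorbed_fraction <= 1.0

    def test_invalid_source_rejected(self, ac225):
        floating, _ = cg.default_geometries("average")
        with pytest.raises(ValueError):
            sv.self_svalue(floating, "medium", ac225)

    def test_too_few_histories_rejected(self, ac225):
        floating, _ = cg.default_geometries("average")
        with pytest.raises(ValueError):
            sv.self_svalue(floating, "cytoplasm", ac225, n_histories=100)


class TestCrossSValue:
    def test_zero_occupancy_gives_zero(self, lu177):
        config = sv.CrossDoseConfig(occupancy=1e-9)
        result = sv.cross_svalue(config, lu177, n_realizations=2, seed=0)
        assert result.value == 0.0

    def test_ac225_cross_far_below_self(self, ac225, reference_table):
        result = sv.cross_svalue(
            sv.CrossDoseConfig(), ac225, n_realizations=8, seed=1
        )
        self_avg = reference_table.self_svalue(
            "Ac-225", "cytoplasm", "floating", "average"
        )
        assert result.value < 0.01 * self_avg

    def test_lattice_cell_count_from_occupancy(self):
        config = sv.CrossDoseConfig()
        # 0.027% of a 500 um cube in 8-um cells -> 16 cells
        assert config.n_cells == 16


class TestSValueTable:
    def test_reference_lookup_and_missing_key(self, reference_table):
        val = reference_table.self_svalue(
            "Ac-225", "cell_membrane", "floating", "minimum"
        )
        assert val == pytest.approx(1.05e-1)
        with pytest.raises(KeyError):
            reference_table.self_svalue("Lu-177", "cytoplasm", "floating", "huge")

    def test_reference_fold_ratio_bounds(self, reference_table):
        ratios = [
            reference_table.self_svalue("Ac-225", src, setup, size)
            / reference_table.self_svalue("Lu-177", src, setup, size)
            for src in ("cell_membrane", "cytoplasm")
            for setup in ("floating", "attached")
            for size in ("minimum", "average", "maximum")
        ]
        assert min(ratios) >= 200.0
        assert max(ratios) <= 600.0

    def test_frame_round_trip_columns(self, reference_table):
        df = reference_table.to_frame()
        assert {"nuclide", "source", "geometry", "size_class",
                "s_value_gy_per_bq_s"} <= set(df.columns)
        assert len(df) == 24 + 2 + 2
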