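"""Ground-truth properties and reproducibility of the synthetic generators."""

import numpy as np
import pytest

from aqpflux.collective_coordinate import collective_coordinate, occupancy
from aqpflux.diffusion import estimate_permeability
from aqpflux.exceptions import SpecError
from aqpflux.io_trajectory import read_dcd, read_pdb, write_dcd, write_pdb
from aqpflux.selectivity_filter import FilterSpec, area_series
from aqpflux.synthetic import (
    BilayerConfig,
    ChannelWaterConfig,
    FilterConfig,
    gen_bilayer,
    gen_channel_water,
    gen_filter,
)


class TestChannelWaterGenerator:
    def test_truth_closed_form(self):
        sys = gen_channel_water(ChannelWaterConfig(n_frames=10))
        # N_w * D_w / L^2 with the default study conditions
        assert sys.truth["D_n_expected_per_ps"] == pytest.approx(8 * 0.2 / 400.0)

    def test_zero_diffusion_static_pipeline(self):
        sys = gen_channel_water(
            ChannelWaterConfig(d_water=0.0, n_frames=401, seed=3)
        )
        series = [
            collective_coordinate(sys.trajectory, ids, ch)
            for ids, ch in zip(sys.water_ids_per_channel, sys.channels)
        ]
        est, _ = estimate_permeability(series)
        assert est.d_n == 0.0
        assert est.p_u_tet == 0.0

    def test_doubling_waters_doubles_recovered_diffusivity(self):
        ests = []
        for n_w in (4, 8):
            sys = gen_channel_water(
                ChannelWaterConfig(
                    n_waters_per_channel=n_w, n_frames=20_001, seed=17
                )
            )
            series = [
                collective_coordinate(sys.trajectory, ids, ch)
                for ids, ch in zip(sys.water_ids_per_channel, sys.channels)
            ]
            est, _ = estimate_permeability(series)
            ests.append(est.d_n)
        assert ests[1] / ests[0] == pytest.approx(2.0, rel=0.2)

    def test_occupancy_constant_in_periodic_mode(self, small_channel_system):
        sys = small_channel_system
        for ids, ch in zip(sys.water_ids_per_channel, sys.channels):
            occ = occupancy(sys.trajectory, ids, ch)
            assert np.all(occ.counts == len(ids))

    def test_reflective_mode_keeps_waters_confined(self):
        sys = gen_channel_water(
            ChannelWaterConfig(boundary="reflective", n_frames=2001, seed=5)
        )
        ch = sys.channels[0]
        z = sys.trajectory.coords[:, sys.water_ids_per_channel[0], 2]
        assert z.min() >= ch.z_min - 1e-4
        assert z.max() <= ch.z_max + 1e-4
        assert sys.truth["exact"] is False

    def test_bit_reproducible(self):
        a = gen_channel_water(ChannelWaterConfig(n_frames=100, seed=9))
        b = gen_channel_water(ChannelWaterConfig(n_frames=100, seed=9))
        assert np.array_equal(a.trajectory.coords, b.trajectory.coords)

    def test_invalid_config(self):
        with pytest.raises(SpecError):
            ChannelWaterConfig(channel_length=-1.0)
        with pytest.raises(SpecError):
            ChannelWaterConfig(boundary="absorbing")


class TestBilayerGenerator:
    def test_zero_amplitude_truth_is_zero(self):
        sys = gen_bilayer(BilayerConfig(amplitude=0.0, seed=2))
        assert sys.delta_expected(5.0) == 0.0

    def test_truth_monotone_in_cutoff(self, bilayer_system):
        vals = [bilayer_system.delta_expected(c) for c in (3.0, 5.0, 10.0, 20.0)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_truth_against_continuum_integral(self, bilayer_system):
        """The lattice-site shell average approximates the continuum annulus
        integral of the deformation profile."""
        from scipy import integrate

        cfg = bilayer_system.truth["config"]
        cutoff = 5.0
        rp, A, s = cfg.protein_radius, cfg.amplitude, cfg.decay_width

        num, _ = integrate.quad(
            lambda r: A * np.exp(-((r - rp) ** 2) / (2 * s * s)) * r, rp, rp + cutoff
        )
        den, _ = integrate.quad(lambda r: r, rp, rp + cutoff)
        continuum = num / den
        assert bilayer_system.delta_expected(cutoff) == pytest.approx(
            continuum, abs=0.35
        )

    def test_reference_is_flat_and_protein_free(self, bilayer_system):
        ref = bilayer_system.reference
        assert ref.n_atoms == len(bilayer_system.p_ids)
        cfg = bilayer_system.truth["config"]
        mean_upper = ref.coords[:, bilayer_system.leaflet_labels > 0, 2].mean()
        mean_lower = ref.coords[:, bilayer_system.leaflet_labels < 0, 2].mean()
        assert mean_upper - mean_lower == pytest.approx(cfg.d0, abs=0.1)

    def test_protein_radius_validation(self):
        with pytest.raises(SpecError):
            BilayerConfig(protein_radius=100.0)

    def test_bit_reproducible(self):
        a = gen_bilayer(BilayerConfig(seed=4, n_frames=5))
        b = gen_bilayer(BilayerConfig(seed=4, n_frames=5))
        assert np.array_equal(a.trajectory.coords, b.trajectory.coords)
        assert np.array_equal(a.reference.coords, b.reference.coords)


class TestFilterGenerator:
    def test_no_jitter_no_switching_constant_area(self):
        sys = gen_filter(
            FilterConfig(jitter=0.0, switch_prob=0.0, n_frames=20, seed=1)
        )
        spec = FilterSpec(residues=(("A", 43), ("A", 174), ("A", 183), ("A", 189)))
        series = area_series(sys.trajectory, sys.topology, spec)
        np.testing.assert_allclose(series.area, 5.0, atol=1e-4)

    def test_markov_stationary_distribution(self):
        sys = gen_filter(FilterConfig(switch_prob=0.1, n_frames=20_000, seed=6))
        frac = np.bincount(sys.state_labels, minlength=2) / len(sys.state_labels)
        # symmetric chain: stationary distribution (1/2, 1/2); MC error at
        # effective sample size n*p_switch
        assert frac[0] == pytest.approx(0.5, abs=0.06)

    def test_labels_match_side_lengths(self):
        sys = gen_filter(FilterConfig(jitter=0.0, n_frames=500, seed=8))
        spec = FilterSpec(residues=(("A", 43), ("A", 174), ("A", 183), ("A", 189)))
        series = area_series(sys.trajectory, sys.topology, spec)
        expect = np.where(sys.state_labels == 0, 5.0, 9.0)
        np.testing.assert_allclose(series.area, expect, atol=1e-3)

    def test_invalid_config(self):
        with pytest.raises(SpecError):
            FilterConfig(area_low=0.0)
        with pytest.raises(SpecError):
            FilterConfig(switch_prob=1.5)


class TestRoundTrips:
    """Every generator output survives write -> read at format precision."""

    @pytest.mark.parametrize("kind", ["channel", "bilayer", "filter"])
    def test_pdb_and_dcd_round_trip(self, kind, tmp_path):
        if kind == "channel":
            sys = gen_channel_water(ChannelWaterConfig(n_frames=10, seed=12))
        elif kind == "bilayer":
            sys = gen_bilayer(BilayerConfig(n_frames=6, seed=12))
        else:
            sys = gen_filter(FilterConfig(n_frames=10, seed=12))
        topo, traj = sys.topology, sys.trajectory

        write_pdb(topo, traj, tmp_path / "t.pdb")
        topo2, traj2 = read_pdb(tmp_path / "t.pdb")
        assert topo2.n_atoms == topo.n_atoms
        assert list(topo2.atom_name) == list(topo.atom_name)
        np.testing.assert_allclose(traj2.coords, traj.coords, atol=1e-3 + 1e-6)

        write_dcd(traj, tmp_path / "t.dcd")
        traj3 = read_dcd(tmp_path / "t.dcd", topo)
        assert np.array_equal(traj3.coords, traj.coords)
        np.testing.assert_allclose(traj3.box, traj.box)
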