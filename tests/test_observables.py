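"""Free-energy profiles, escape times, concentrations, localization, H-bonds."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import copolyscan as cps
from copolyscan.lattice_model import Conformation, Sequence
from copolyscan.observables import (
    FreeEnergyProfile,
    LocalizationCriterion,
    barrier_height,
    branch_point_profile,
    com_bin,
    escape_time_from_free_energies,
    free_energy_profile,
    localization_score,
    mean_escape_time,
    monomer_concentration,
)


def _conf(seq, coords, w=1.0):
    return Conformation(Sequence.from_string(seq), np.asarray(coords, np.int64), w)


def _profile_from_f(f):
    f = np.asarray(f, dtype=float)
    return FreeEnergyProfile(
        z=np.arange(len(f), dtype=float),
        sums=np.exp(-f),
        counts=np.ones(len(f), dtype=np.int64),
    )


class TestCenterOfMassBinning:
    def test_ties_at_half_go_to_lower_bin(self):
        assert com_bin(2.5) == 2
        assert com_bin(-2.5) == -3
        assert com_bin(2.49) == 2
        assert com_bin(2.51) == 3


class TestFreeEnergyProfile:
    def test_single_conformation_bin_value(self, box5, thin_membrane):
        conf = _conf("T", [(2, 2, 1)])
        w, h = 0.25, 1.3
        prof = free_energy_profile([(conf, w, h)], box5, thin_membrane.mid_plane)
        bidx = 1 - box5.z_min
        assert prof.sums[bidx] == pytest.approx(w * math.exp(-h))
        prof.empty_bin = "inf"
        assert prof.f[bidx] == pytest.approx(h - math.log(w))

    def test_empty_bin_raises_with_bin_named(self, box5):
        conf = _conf("T", [(2, 2, 0)])
        prof = free_energy_profile([(conf, 1.0, 0.0)], box5, 0.0)
        with pytest.raises(ValueError, match="empty free-energy bin"):
            prof.f

    def test_zero_field_profile_is_flat_away_from_walls(self):
        """With all eps = 0 translational symmetry makes F(z) flat in the
        interior (within Monte Carlo error)."""
        box = cps.SimulationBox(Lx=16, Ly=16, Lz=16, z_min=-8)
        stack = cps.planar_membrane(box, 2, 1)
        prof = cps.sample_free_energy_profile(
            Sequence.from_string("TH"), stack=stack, box=box,
            imap=cps.InteractionMap.zeros(), samples=100_000, seed=21,
        )
        interior = slice(4, 12)
        f = prof.f[interior]
        se = prof.f_stderr[interior]
        assert np.all(np.abs(f - f.mean()) < 3 * se + 0.02)


class TestEscapeTime:
    def test_flat_profile_closed_form(self):
        for m in (1, 2, 4, 8, 32, 64):
            assert escape_time_from_free_energies(np.zeros(m)) == m * (m + 1) / 2
            assert escape_time_from_free_energies(np.full(m, 3.7)) == pytest.approx(
                m * (m + 1) / 2, rel=1e-12
            )

    def test_flat_32_bins_matches_free_diffusion_order(self):
        # |2 z|^2 ~ 1e3 for a 32-layer box; the exact double sum gives 528
        assert escape_time_from_free_energies(np.zeros(32)) == 528

    def test_single_barrier_bin_matches_direct_double_sum(self):
        f = np.zeros(8)
        f[4] = 2.0
        direct = sum(
            math.exp(f[z]) * sum(math.exp(-f[zp]) for zp in range(z + 1))
            for z in range(8)
        )
        assert escape_time_from_free_energies(f) == pytest.approx(direct, rel=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(-8, 8), min_size=1, max_size=40),
        st.floats(-30, 30),
    )
    def test_invariant_under_constant_shift(self, f, c):
        f = np.asarray(f)
        t1 = escape_time_from_free_energies(f)
        t2 = escape_time_from_free_energies(f + c)
        assert t2 == pytest.approx(t1, rel=1e-9)

    def test_non_finite_profile_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            escape_time_from_free_energies(np.array([0.0, np.inf]))

    def test_result_carries_bounds_and_positive_tau(self):
        prof = _profile_from_f([0.0, 1.0, 0.0])
        res = mean_escape_time(prof)
        assert res.tau > 0
        assert (res.z_minus, res.z_plus) == (0.0, 2.0)


class TestBarrier:
    def test_plateau_minus_minimum(self):
        z = np.arange(-15.5, 16.5)
        f = np.zeros_like(z)
        f[np.abs(z) >= 8.5] = 5.0
        f[np.abs(z) <= 2.5] = -2.0
        prof = FreeEnergyProfile(z=z, sums=np.exp(-f), counts=np.ones(z.size, np.int64))
        res = barrier_height(prof)
        assert res.barrier == pytest.approx(7.0)
        assert res.plateau == pytest.approx(5.0)

    def test_effective_coordination_scaling(self):
        assert cps.effective_coordination(18.0) == pytest.approx(15.0)
        assert cps.effective_coordination(12.0, 0.1, 10) == pytest.approx(12.0)


class TestConcentration:
    def test_rows_sum_to_one_and_single_conformation_indicator(self, box5):
        conf = _conf("TH", [(1, 1, -1), (1, 1, 0)])
        prof = monomer_concentration([(conf, 0.5, 0.7)], box5, "planar-z", 0.0)
        np.testing.assert_allclose(prof.cbar.sum(axis=1), 1.0)
        assert prof.cbar[0, -1 - box5.z_min] == 1.0
        assert prof.cbar[1, 0 - box5.z_min] == 1.0

    def test_zero_total_weight_rejected(self, box5):
        conf = _conf("T", [(0, 0, 0)], w=0.0)
        with pytest.raises(ValueError, match="zero total"):
            monomer_concentration([(conf, 0.0, 0.0)], box5)


class TestLocalization:
    def _uniform_conc(self, n=4, shells=20):
        cbar = np.zeros((n, shells))
        cbar[:, 3] = 1.0
        return cps.ConcentrationProfile(np.arange(shells), cbar, 1.0)

    def test_whole_box_scores_chain_length(self):
        conc = self._uniform_conc()
        crit = LocalizationCriterion(tuple(range(1, 5)), 0.0, 100.0)
        assert localization_score(conc, crit) == pytest.approx(4.0)

    def test_interval_outside_occupancy_scores_zero(self):
        conc = self._uniform_conc()
        crit = LocalizationCriterion((1,), 10.0, 12.0)
        assert localization_score(conc, crit) == 0.0

    def test_criterion_validation(self):
        with pytest.raises(ValueError, match="at least one"):
            LocalizationCriterion((), 0, 2)
        with pytest.raises(ValueError, match="r_lo < r_hi"):
            LocalizationCriterion((1,), 5, 5)
        with pytest.raises(ValueError, match="1-based"):
            LocalizationCriterion((0,), 0, 2)
        conc = self._uniform_conc()
        with pytest.raises(ValueError, match="exceed"):
            localization_score(conc, LocalizationCriterion((9,), 0, 2))

    def test_shell_mask_matches_open_intervals(self):
        crit = LocalizationCriterion((1,), 0.0, 2.0)
        assert list(np.flatnonzero(crit.shell_mask(6))) == [0, 1]
        crit = LocalizationCriterion((1,), 13.0, 16.0)
        assert list(np.flatnonzero(crit.shell_mask(20))) == [13, 14, 15]


class TestHBondAnnealing:
    def test_uniform_field_gives_half_probability_everywhere(self):
        # constant phi_p = 0.5: both states cost the same, every assignment
        # is degenerate, so each position carries the composition fraction
        flat = cps.DensityProfile(amplitude=0.5, midpoint=100.0)
        hb = cps.hbond_anneal(flat, n=8, samples=1500, seed=31,
                              box=cps.SimulationBox(16, 16, 16, -8))
        np.testing.assert_allclose(hb.position_prob, 0.5, atol=1e-9)
        assert hb.mean_fraction == pytest.approx(0.5)

    def test_composition_must_be_integral(self):
        with pytest.raises(ValueError, match="integer"):
            cps.hbond_anneal(cps.sigmoid_globule(1.0), n=7, hb_fraction=0.5,
                             samples=100)


class TestBranchProfile:
    def test_theta_zero_ensemble_has_no_branch_points(self):
        box = cps.SimulationBox(16, 16, 16, -8)
        ens = [cps.grow_branched(8, 0.0, 2, box, seed=41, sample_index=k)
               for k in range(50)]
        prof = branch_point_profile(ens, box)
        assert prof.n_branch_points == 0
        assert prof.branch_density.sum() == 0.0

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            branch_point_profile([], cps.SimulationBox())
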