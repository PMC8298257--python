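"""Cell-agent rules: migration, proliferation, differentiation, apoptosis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import callusim as cs
from callusim.cells import (
    CHONDROCYTE,
    EMPTY,
    FIBROBLAST,
    MSC,
    OSTEOBLAST,
    CellLattice,
    rate_to_probability,
)
from conftest import open_box_lattice


def place(lattice, sites, phenotype=MSC):
    cells = CellLattice.empty(lattice)
    for s in sites:
        cells.phenotype[s] = phenotype
    return cells


class TestRateConversion:
    @pytest.mark.parametrize(
        "rate, dt_days, expected",
        [
            # MSC 0.60/day over 2 h -> 1 - exp(-0.05)
            (0.60, 2 / 24, 1.0 - np.exp(-0.05)),
            # osteoblast apoptosis 0.16/day over 2 h
            (0.16, 2 / 24, 0.013245),
            (0.0, 1.0, 0.0),
        ],
    )
    def test_poisson_waiting_time(self, rate, dt_days, expected):
        assert rate_to_probability(rate, dt_days) == pytest.approx(
            expected, rel=1e-4
        )


class TestDifferentiationRanges:
    @pytest.mark.parametrize(
        "S, phenotype, mature",
        [
            (2.0, OSTEOBLAST, True),
            (2.53, OSTEOBLAST, True),
            (2.6, OSTEOBLAST, False),
            (3.0, OSTEOBLAST, False),
            (4.0, CHONDROCYTE, False),
            (5.0, CHONDROCYTE, False),
            (6.0, FIBROBLAST, False),
        ],
    )
    def test_fate_windows_as_printed(self, S, phenotype, mature):
        ranges = cs.DifferentiationRanges()
        fate, mat = ranges.phenotype_for(np.array([S]))
        assert fate[0] == phenotype
        assert bool(mat[0]) == mature

    @given(S=st.floats(0, 100, allow_nan=False))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_windows_partition_stimulus_axis(self, S):
        """Every stimulus maps to exactly one fate."""
        fate, _ = cs.DifferentiationRanges().phenotype_for(np.array([S]))
        assert fate[0] in (OSTEOBLAST, CHONDROCYTE, FIBROBLAST)

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            cs.DifferentiationRanges(mature_osteoblast_max=4.0,
                                     immature_osteoblast_max=3.0)


class TestRecruitmentPolicy:
    def test_limited_zeroes_msc_rates_after_cutoff(self):
        rates = cs.RateTable()
        policy = cs.RecruitmentPolicy("limited", 10.0)
        out = cs.apply_recruitment_policy(rates, 11.0, policy)
        assert out.msc_migration == 0.0
        assert out.msc_proliferation == 0.0
        # differentiation and apoptosis kept unaltered
        assert out.msc_differentiation == rates.msc_differentiation
        assert out.msc_apoptosis == rates.msc_apoptosis

    def test_before_cutoff_unchanged(self):
        rates = cs.RateTable()
        policy = cs.RecruitmentPolicy("limited", 10.0)
        assert cs.apply_recruitment_policy(rates, 9.0, policy) == rates

    def test_continuous_identity(self):
        rates = cs.RateTable()
        policy = cs.RecruitmentPolicy("continuous", 10.0)
        assert cs.apply_recruitment_policy(rates, 1000.0, policy) == rates

    def test_negative_day_rejected(self):
        with pytest.raises(ValueError):
            cs.apply_recruitment_policy(
                cs.RateTable(), -1.0, cs.RecruitmentPolicy("limited", 10.0)
            )


class TestMigration:
    def test_blocked_cell_stays(self, box_lattice):
        center = (4, 4, 4)
        sites = [center] + [
            (4 + d[0], 4 + d[1], 4 + d[2])
            for d in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                      (0, 0, 1), (0, 0, -1)]
        ]
        cells = place(box_lattice, sites)
        before = cells.phenotype.copy()
        cs.migrate(cells, np.ones(box_lattice.shape), cs.RateTable(),
                   np.random.default_rng(0))
        assert cells.phenotype[center] == MSC
        # neighbors may move outward but the cage keeps the center fixed
        assert cells.count() == np.count_nonzero(before)

    def _direction_counts(self, chem_value_up, n_trials=100, n_cells=1000):
        """Many isolated walkers, one hop each per call; count +z moves."""
        lattice = open_box_lattice(shape=(41, 41, 44))
        chem = np.ones(lattice.shape)
        chem[:, :, 2::4] = chem_value_up  # +z neighbor of every start site
        rng = np.random.default_rng(7)
        starts = [
            (i, j, k)
            for i in range(2, 39, 4)
            for j in range(2, 39, 4)
            for k in range(1, 42, 4)
        ][:n_cells]
        up = 0
        total = 0
        for _ in range(n_trials):
            cells = place(lattice, starts)
            cs.migrate(cells, chem, cs.RateTable(), rng)
            occ = np.argwhere(cells.phenotype != EMPTY)
            for i, j, k in occ:
                total += 1
                if (k - 1) % 4 == 1:  # moved +z from its start layer
                    up += 1
        return up, total

    def test_weighted_choice_matches_multinomial(self):
        """Index 3.5 on the +z candidate, 1.0 elsewhere -> P(+z) = 3.5/8.5."""
        up, total = self._direction_counts(3.5)
        expected = 3.5 / 8.5
        observed = np.array([up, total - up])
        chi2 = stats.chisquare(
            observed, [expected * total, (1 - expected) * total]
        )
        assert chi2.pvalue > 0.01

    def test_uniform_field_isotropic(self):
        """No chemotaxis -> empirically uniform over the 6 directions."""
        lattice = open_box_lattice(shape=(41, 41, 41))
        rng = np.random.default_rng(11)
        starts = [
            (i, j, k)
            for i in range(2, 39, 4)
            for j in range(2, 39, 4)
            for k in range(2, 39, 4)
        ]
        counts = np.zeros(6)
        offsets = {(1, 0, 0): 0, (-1, 0, 0): 1, (0, 1, 0): 2,
                   (0, -1, 0): 3, (0, 0, 1): 4, (0, 0, -1): 5}
        for _ in range(120):
            cells = place(lattice, starts)
            before = {s: True for s in starts}
            cs.migrate(cells, np.ones(lattice.shape), cs.RateTable(), rng)
            occ = np.argwhere(cells.phenotype != EMPTY)
            for i, j, k in occ:
                # recover the start site (walkers are 4 apart)
                s = (round((i - 2) / 4) * 4 + 2, round((j - 2) / 4) * 4 + 2,
                     round((k - 2) / 4) * 4 + 2)
                d = (i - s[0], j - s[1], k - s[2])
                if d in offsets:
                    counts[offsets[d]] += 1
        chi2 = stats.chisquare(counts)
        assert counts.sum() > 1e5
        assert chi2.pvalue > 0.01

    def test_chemotaxis_index_below_one_rejected(self, box_lattice):
        cells = place(box_lattice, [(4, 4, 4)])
        with pytest.raises(ValueError):
            cs.migrate(cells, np.full(box_lattice.shape, 0.5),
                       cs.RateTable(), np.random.default_rng(0))

    def test_hop_probability_scales_with_pitch_squared(self):
        """Coarser lattice -> fewer hops, preserving the diffusivity."""
        moved = {}
        for spacing in (60.0, 120.0):
            lattice = open_box_lattice(shape=(31, 31, 31), spacing_um=spacing)
            starts = [(i, j, k) for i in range(2, 29, 4)
                      for j in range(2, 29, 4) for k in range(2, 29, 4)]
            rng = np.random.default_rng(5)
            n_moves = 0
            for _ in range(40):
                cells = place(lattice, starts)
                before = cells.phenotype.copy()
                cs.migrate(cells, np.ones(lattice.shape), cs.RateTable(), rng)
                n_moves += np.count_nonzero(before != cells.phenotype) // 2
            moved[spacing] = n_moves
        ratio = moved[120.0] / moved[60.0]
        assert ratio == pytest.approx(0.25, rel=0.15)


class TestProliferation:
    def test_no_free_neighbor_no_daughter(self, box_lattice):
        sites = [(4, 4, 4)] + [
            (4 + d[0], 4 + d[1], 4 + d[2])
            for d in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                      (0, 0, 1), (0, 0, -1)]
        ]
        cells = place(box_lattice, sites)
        n0 = cells.count()
        # enormous rate: every cell attempts to divide
        rates = cs.RateTable(msc_proliferation=1e6)
        cs.proliferate(cells, np.zeros(box_lattice.shape), 1.0, rates,
                       np.random.default_rng(0))
        # the caged center produced no daughter; cage cells may have
        assert cells.count() <= n0 + 6

    def test_division_probability_matches_rate(self):
        rng = np.random.default_rng(2)
        p_expected = 1.0 - np.exp(-0.60 * 2 / 24)
        lattice = open_box_lattice((41, 41, 41))
        starts = [(i, j, k) for i in range(2, 39, 4) for j in range(2, 39, 4)
                  for k in range(2, 39, 4)][:100]
        divisions = 0
        trials = 0
        for _ in range(40):
            cells = place(lattice, starts)
            n0 = cells.count()
            cs.proliferate(cells, np.zeros(lattice.shape), 1.0,
                           cs.RateTable(), rng)
            divisions += cells.count() - n0
            trials += n0
        p_obs = divisions / trials
        assert p_obs == pytest.approx(p_expected, abs=0.015)

    def test_bmp_factor_doubles_msc_division(self):
        lattice = open_box_lattice((41, 41, 41))
        starts = [(i, j, k) for i in range(2, 39, 4) for j in range(2, 39, 4)
                  for k in range(2, 39, 4)]
        rng = np.random.default_rng(9)
        grown = {}
        for factor in (1.0, 2.0):
            total = 0
            for _ in range(30):
                cells = place(lattice, starts)
                n0 = cells.count()
                cs.proliferate(cells, np.zeros(lattice.shape), factor,
                               cs.RateTable(), rng)
                total += cells.count() - n0
            grown[factor] = total
        # effective rate doubling: p ratio ~ 2 for small p
        assert grown[2.0] / grown[1.0] == pytest.approx(2.0, rel=0.12)

    def test_unfavorable_stimulus_blocks_differentiated_division(self,
                                                                 box_lattice):
        cells = place(box_lattice, [(4, 4, 4)], phenotype=CHONDROCYTE)
        S = np.zeros(box_lattice.shape)  # far below the cartilage window
        rates = cs.RateTable(chondrocyte_proliferation=1e6)
        cs.proliferate(cells, S, 1.0, rates, np.random.default_rng(0))
        assert cells.count() == 1

    def test_factor_below_one_rejected(self, box_lattice):
        cells = place(box_lattice, [(4, 4, 4)])
        with pytest.raises(ValueError):
            cs.proliferate(cells, np.zeros(box_lattice.shape), 0.5,
                           cs.RateTable(), np.random.default_rng(0))


class TestDifferentiationStep:
    def test_fate_follows_local_stimulus(self, box_lattice):
        rng = np.random.default_rng(1)
        cells = place(box_lattice, [(1, 1, 1), (4, 4, 4), (7, 7, 7)])
        S = np.zeros(box_lattice.shape)
        S[1, 1, 1], S[4, 4, 4], S[7, 7, 7] = 2.0, 4.0, 6.0
        rates = cs.RateTable(msc_differentiation=1e6)  # convert surely
        cs.differentiate(cells, S, cs.DifferentiationRanges(), rates, rng)
        assert cells.phenotype[1, 1, 1] == OSTEOBLAST
        assert cells.mature[1, 1, 1]
        assert cells.phenotype[4, 4, 4] == CHONDROCYTE
        assert cells.phenotype[7, 7, 7] == FIBROBLAST

    def test_immature_osteoblast_matures_at_low_stimulus(self, box_lattice):
        cells = place(box_lattice, [(4, 4, 4)], phenotype=OSTEOBLAST)
        S = np.full(box_lattice.shape, 1.0)
        rates = cs.RateTable(msc_differentiation=1e6)
        cs.differentiate(cells, S, cs.DifferentiationRanges(), rates,
                         np.random.default_rng(0))
        assert cells.mature[4, 4, 4]


class TestApoptosis:
    def test_zero_rate_nobody_dies(self, box_lattice):
        cells = place(box_lattice, [(4, 4, 4)])
        rates = cs.RateTable(msc_apoptosis=0.0)
        cs.apoptose(cells, np.zeros(box_lattice.shape), rates,
                    np.random.default_rng(0))
        assert cells.count() == 1

    def test_population_decay_matches_exponential(self):
        """Repeated apoptosis-only updates follow exp(-rate t)."""
        lattice = open_box_lattice((21, 21, 21))
        cells = CellLattice.empty(lattice)
        cells.phenotype[:, :, :] = OSTEOBLAST
        rng = np.random.default_rng(4)
        n0 = cells.count()
        days = 5.0
        steps = int(days * 12)
        S = np.zeros(lattice.shape)  # favorable for osteoblasts
        for _ in range(steps):
            cs.apoptose(cells, S, cs.RateTable(), rng)
        expected = n0 * np.exp(-0.16 * days)
        sigma = np.sqrt(expected)
        assert abs(cells.count() - expected) < 5 * sigma

    def test_unfavorable_stimulus_boosts_death(self):
        lattice = open_box_lattice((21, 21, 21))
        rng = np.random.default_rng(8)
        survivors = {}
        for S_val in (0.0, 10.0):  # favorable vs far outside the bone window
            cells = CellLattice.empty(lattice)
            cells.phenotype[:, :, :] = OSTEOBLAST
            S = np.full(lattice.shape, S_val)
            for _ in range(24):
                cs.apoptose(cells, S, cs.RateTable(), rng)
            survivors[S_val] = cells.count()
        assert survivors[10.0] < survivors[0.0]


class TestInvariants:
    def test_zero_rates_lattice_is_fixed_point(self, box_lattice):
        rates = cs.RateTable(
            msc_migration=0, msc_proliferation=0, msc_differentiation=0,
            msc_apoptosis=0, fibroblast_migration=0,
            fibroblast_proliferation=0, fibroblast_apoptosis=0,
            chondrocyte_proliferation=0, chondrocyte_apoptosis=0,
            osteoblast_proliferation=0, osteoblast_apoptosis=0,
            mature_osteoblast_proliferation=0,
        )
        rng = np.random.default_rng(0)
        cells = place(box_lattice, [(2, 2, 2), (5, 5, 5)])
        before = cells.phenotype.copy()
        S = np.zeros(box_lattice.shape)
        cs.differentiate(cells, S, cs.DifferentiationRanges(), rates, rng)
        cs.proliferate(cells, S, 1.0, rates, rng)
        cs.migrate(cells, np.ones(box_lattice.shape), rates, rng)
        cs.apoptose(cells, S, rates, rng)
        assert np.array_equal(cells.phenotype, before)

    def test_occupancy_and_domain_invariants_after_full_update(self):
        lattice = open_box_lattice((15, 15, 15))
        rng = np.random.default_rng(12)
        cells = CellLattice.empty(lattice)
        mask = rng.random(lattice.shape) < 0.4
        cells.phenotype[mask] = MSC
        S = rng.uniform(0, 6, lattice.shape)
        chem = 1.0 + rng.uniform(0, 3, lattice.shape)
        for _ in range(10):
            cs.differentiate(cells, S, cs.DifferentiationRanges(),
                             cs.RateTable(), rng)
            cs.proliferate(cells, S, 1.5, cs.RateTable(), rng)
            cs.migrate(cells, chem, cs.RateTable(), rng)
            cs.apoptose(cells, S, cs.RateTable(), rng)
            cells.check_invariants()
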