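"""Simulator statistics: planting rates, spectrum, pool signal, determinism."""

import numpy as np
import pytest
from scipy import stats as sps

from scampr import pooling, synthdata
from scampr.pileup import counts_from_pileup
from scampr.synthdata import (
    HomeologSNP,
    PlantedMutation,
    SimParams,
    SimTruth,
    expected_alt_fraction,
    simulate_pool_counts,
    simulate_population,
    write_fixture,
)


class TestSimParams:
    @pytest.mark.parametrize("kwargs", [
        {"error_rate": -0.1}, {"error_rate": 1.5}, {"het_fraction": 2.0},
        {"depth": 0}, {"density": -1.0},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimParams(**kwargs)


class TestSimulatePopulation:
    def test_zero_density_plants_nothing(self):
        params = SimParams(density=0.0, seed=1)
        truth = simulate_population({"amp1": "ACGT" * 100}, params)
        assert truth.mutations == []

    def test_poisson_planting_rate(self):
        # 384 lines x 1.6 kb at 1/109 per kb per line: lambda = 5.64 per
        # population; across 30 populations the total must fall in the
        # central 99.9% Poisson interval
        amp = {"amp1": synthdata.random_amplicon(1600, seed=5)}
        lam_one = 384 * 1.6 / 109
        total = 0
        for seed in range(30):
            params = SimParams(density=1 / 109, seed=seed)
            total += len(simulate_population(amp, params).mutations)
        lo, hi = sps.poisson.interval(0.999, 30 * lam_one)
        assert lo <= total <= hi

    def test_spectrum_fraction_of_planted_mutations(self):
        params = SimParams(spectrum_fraction=0.99, seed=3)
        amp = {"amp1": synthdata.random_amplicon(2000, seed=3)}
        truth = simulate_population(amp, params, n_mutations=3000)
        ems = sum((m.ref, m.alt) in {("G", "A"), ("C", "T")}
                  for m in truth.mutations)
        frac = ems / len(truth.mutations)
        # binomial 99.9% band around 0.99 at n=3000
        lo, hi = sps.binom.interval(0.999, 3000, 0.99)
        assert lo / 3000 <= frac <= hi / 3000

    def test_het_fraction_controls_zygosity(self):
        params = SimParams(het_fraction=1.0, seed=4)
        amp = {"amp1": "ACGT" * 50}
        truth = simulate_population(amp, params, n_mutations=200)
        assert all(m.zygosity == "het" for m in truth.mutations)

    def test_planted_positions_within_amplicon_and_alt_differs(self):
        params = SimParams(seed=6)
        amp = {"a": synthdata.random_amplicon(500, seed=6),
               "b": synthdata.random_amplicon(700, seed=7)}
        truth = simulate_population(amp, params, n_mutations=300,
                                    n_homeologs=5)
        for m in truth.mutations:
            assert 1 <= m.pos <= len(amp[m.amplicon])
            assert amp[m.amplicon][m.pos - 1] == m.ref != m.alt
        mut_sites = {(m.amplicon, m.pos) for m in truth.mutations}
        for h in truth.homeologs:
            assert (h.amplicon, h.pos) not in mut_sites

    def test_deterministic_under_fixed_seed(self):
        amp = {"amp1": synthdata.random_amplicon(800, seed=9)}
        a = simulate_population(amp, SimParams(seed=9), n_mutations=20)
        b = simulate_population(amp, SimParams(seed=9), n_mutations=20)
        assert a.mutations == b.mutations

    def test_empty_amplicon_rejected(self):
        with pytest.raises(ValueError):
            simulate_population({"amp1": ""}, SimParams(seed=1))


class TestExpectedSignal:
    def test_heterozygote_signal_is_half_percent(self):
        assert expected_alt_fraction(1, 96) == pytest.approx(1 / 192)
        assert round(100 * expected_alt_fraction(1, 96), 1) == 0.5

    def test_homozygote_doubles_the_signal(self):
        assert expected_alt_fraction(2, 96) == pytest.approx(2 / 192)


class TestSimulatePoolCounts:
    @pytest.fixture
    def design(self, canonical_design):
        return canonical_design

    def test_noiseless_limit_has_reference_only_counts(self, design):
        params = SimParams(error_rate=0.0, depth=500, seed=2)
        truth = SimTruth(mutations=[], homeologs=[],
                         amplicons={"amp1": "ACGT" * 25}, params=params)
        counts = simulate_pool_counts(truth, design)
        for matrix in counts.values():
            data = matrix.data
            for base in "ACGT":
                nonref = data[data["ref"] != base]
                assert (nonref[base] == 0).all()

    def test_carrier_alt_fraction_matches_binomial_expectation(self, design):
        # one heterozygote at high depth: observed alt fraction in each
        # of its three pools must sit in the central binomial band
        params = SimParams(error_rate=0.0, depth=200_000, seed=8)
        carrier = pooling.LineAddress(1, "A", 1)
        truth = SimTruth(
            mutations=[PlantedMutation(carrier, "amp1", 50, "C", "T", "het")],
            homeologs=[], amplicons={"amp1": "C" * 100}, params=params,
        )
        counts = simulate_pool_counts(truth, design)
        p = 1 / 192
        lo, hi = sps.binom.interval(0.999, params.depth, p)
        for pool_id in design.pools_for_line(carrier):
            row = counts[pool_id].data.query("pos == 50").iloc[0]
            assert lo <= row["T"] <= hi
        # and zero signal outside the carrier's triple (error rate 0)
        for pool_id in set(design.pool_ids) - design.pools_for_line(carrier):
            row = counts[pool_id].data.query("pos == 50").iloc[0]
            assert row["T"] == 0

    def test_homozygote_doubles_the_expected_count(self, design):
        params = SimParams(error_rate=0.0, depth=200_000, seed=12)
        carrier = pooling.LineAddress(2, "D", 7)
        truth = SimTruth(
            mutations=[PlantedMutation(carrier, "amp1", 10, "G", "A", "hom")],
            homeologs=[], amplicons={"amp1": "G" * 20}, params=params,
        )
        counts = simulate_pool_counts(truth, design)
        lo, hi = sps.binom.interval(0.999, params.depth, 2 / 192)
        for pool_id in design.pools_for_line(carrier):
            row = counts[pool_id].data.query("pos == 10").iloc[0]
            assert lo <= row["A"] <= hi

    def test_homeolog_fraction_in_every_pool(self, design):
        params = SimParams(error_rate=0.0, depth=50_000, seed=13)
        truth = SimTruth(
            mutations=[],
            homeologs=[HomeologSNP("amp1", 30, "T", "G", 0.5)],
            amplicons={"amp1": "T" * 60}, params=params,
        )
        counts = simulate_pool_counts(truth, design)
        lo, hi = sps.binom.interval(0.999, params.depth, 0.5)
        for matrix in counts.values():
            row = matrix.data.query("pos == 30").iloc[0]
            assert lo <= row["G"] <= hi

    def test_carrier_outside_design_rejected(self):
        small = pooling.build_design(4)
        params = SimParams(seed=1)
        truth = SimTruth(
            mutations=[PlantedMutation(pooling.LineAddress(9, "A", 1),
                                       "amp1", 1, "C", "T", "het")],
            homeologs=[], amplicons={"amp1": "CCC"}, params=params,
        )
        with pytest.raises(ValueError, match="not covered"):
            simulate_pool_counts(truth, small)


class TestWriteFixture:
    def test_fixture_bytes_reproducible_and_round_trip(self, tmp_path,
                                                       recovery_sim,
                                                       canonical_design):
        truth, counts = recovery_sim
        dir_a = tmp_path / "a"
        dir_b = tmp_path / "b"
        paths_a = write_fixture(truth, counts, canonical_design, dir_a)
        paths_b = write_fixture(truth, counts, canonical_design, dir_b)
        for key in paths_a:
            assert paths_a[key].read_bytes() == paths_b[key].read_bytes()
        # mpileup output round-trips through the pileup reader exactly
        with open(paths_a["mpileup:5"]) as fh:
            parsed = counts_from_pileup(fh, pool_id=5)
        assert counts[5].equals(parsed)

    def test_empty_truth_writes_reference_only_files(self, tmp_path,
                                                     canonical_design):
        params = SimParams(error_rate=0.0, depth=100, seed=21)
        truth = SimTruth(mutations=[], homeologs=[],
                         amplicons={"amp1": "ACGT" * 10}, params=params)
        counts = simulate_pool_counts(truth, canonical_design)
        paths = write_fixture(truth, counts, canonical_design, tmp_path / "f")
        truth_lines = paths["truth"].read_text().strip().splitlines()
        assert len(truth_lines) == 1  # header only
        parsed = counts_from_pileup(paths["mpileup:1"].read_text(), pool_id=1)
        assert parsed.equals(counts[1])
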