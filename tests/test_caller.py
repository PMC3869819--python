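"""Background model, t-test, homeolog discrimination and candidate calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special

from scampr import pooling, synthdata
from scampr.caller import (
    BackgroundModel,
    call_candidates,
    classify_homeolog,
    ems_consistency,
    fit_background,
)
from scampr.caller import test_position as position_pvalue
from scampr.pileup import combined_frequencies


def make_freq_table(rows):
    """rows: (pool, pos, ref, alt, freq, depth)."""
    df = pd.DataFrame(rows, columns=["pool", "pos", "ref", "alt", "freq",
                                     "depth"])
    df["amplicon"] = "amp1"
    df["alt_count"] = (df["freq"] * df["depth"]).round().astype(int)
    df["no_data"] = df["depth"] == 0
    return df


class TestEmsConsistency:
    @pytest.mark.parametrize("ref,alt,expected", [
        ("C", "T", True), ("G", "A", True),
        ("A", "G", False), ("T", "C", False), ("G", "T", False),
    ])
    def test_signature(self, ref, alt, expected):
        assert ems_consistency(ref, alt) is expected

    def test_identity_rejected(self):
        with pytest.raises(ValueError):
            ems_consistency("C", "C")


class TestClassifyHomeolog:
    def test_half_frequency_in_all_pools(self):
        assert classify_homeolog([0.5] * 12) is True

    def test_low_frequency_triple_is_not_homeolog(self):
        assert classify_homeolog([0.005] * 3 + [0.0] * 9) is False

    def test_eleven_of_twelve_pools_crosses_the_fraction(self):
        freqs = [0.25] * 11 + [0.0]
        assert classify_homeolog(freqs) is True  # 11/12 = 0.917 >= 0.9

    def test_ten_of_twelve_pools_does_not(self):
        assert classify_homeolog([0.25] * 10 + [0.0] * 2) is False


class TestFitBackground:
    def test_mean_and_sd_arithmetic(self):
        rows = [(1, p, "C", "T", f, 1000)
                for p, f in enumerate([0.001, 0.002, 0.003], start=1)]
        table = make_freq_table([(1, i + 1, "C", "T", f, 1000)
                                 for i, f in enumerate([0.001, 0.002, 0.003])])
        bg = fit_background(table, pool=1, ref="C", alt="T")
        assert bg.mean == pytest.approx(0.002)
        assert bg.sd == pytest.approx(0.001)
        assert bg.n == 3

    def test_excluding_focal_position_drops_n_by_one(self):
        table = make_freq_table([(1, i + 1, "C", "T", 0.001, 1000)
                                 for i in range(5)])
        full = fit_background(table, 1, "C", "T")
        loo = fit_background(table, 1, "C", "T", exclude=[("amp1", 3)])
        assert full.n - loo.n == 1

    def test_all_zero_background_fits_degenerate_model(self):
        table = make_freq_table([(1, i + 1, "G", "A", 0.0, 1000)
                                 for i in range(4)])
        bg = fit_background(table, 1, "G", "A")
        assert (bg.mean, bg.sd) == (0.0, 0.0)

    def test_insufficient_positions_rejected(self):
        table = make_freq_table([(1, 1, "G", "A", 0.0, 1000)])
        with pytest.raises(ValueError, match=">=2"):
            fit_background(table, 1, "G", "A")


class TestTestPosition:
    def test_focal_at_background_mean_gives_half(self):
        bg = BackgroundModel(1, "C", "T", mean=0.002, sd=0.001, n=100)
        assert position_pvalue(0.002, bg) == pytest.approx(0.5, abs=1e-12)

    def test_below_mean_never_significant(self):
        bg = BackgroundModel(1, "C", "T", mean=0.002, sd=0.001, n=100)
        assert position_pvalue(0.0005, bg) > 0.5

    def test_matches_reference_t_tail_to_1e_10(self):
        # independent oracle: one-sided tail via the regularised
        # incomplete beta function
        bg = BackgroundModel(1, "C", "T", mean=0.0002, sd=0.0002, n=1000)
        p = position_pvalue(0.005, bg)
        t = (0.005 - bg.mean) / (bg.sd * np.sqrt(1 + 1 / bg.n))
        df = bg.n - 1
        oracle = 0.5 * special.betainc(df / 2, 0.5, df / (df + t * t))
        assert p == pytest.approx(oracle, abs=1e-10)

    def test_sd_floor_prevents_infinite_statistic(self):
        bg = BackgroundModel(1, "C", "T", mean=0.0, sd=0.0, n=50)
        p = position_pvalue(0.005, bg, sd_floor=1e-4)
        assert 0.0 < p < 1e-6

    @given(st.lists(st.floats(min_value=0, max_value=0.02), min_size=2,
                    max_size=6, unique=True))
    @settings(deadline=None, max_examples=50)
    def test_monotone_decreasing_in_frequency(self, freqs):
        bg = BackgroundModel(1, "C", "T", mean=0.001, sd=0.0005, n=200)
        ps = [position_pvalue(f, bg) for f in sorted(freqs)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))


class TestCallCandidates:
    def test_recovers_planted_mutations_with_no_false_positives(
            self, canonical_design, recovery_sim):
        truth, counts = recovery_sim
        cands = call_candidates(counts.values(), canonical_design)
        truth_keys = {(m.pos, m.ref, m.alt) for m in truth.mutations}
        called_keys = {(c.position, c.ref, c.alt) for c in cands}
        assert called_keys == truth_keys
        homeolog_keys = {(h.pos, h.ref, h.alt) for h in truth.homeologs}
        assert not called_keys & homeolog_keys

    def test_positive_pools_are_the_carrier_triple(self, canonical_design,
                                                   recovery_sim):
        truth, counts = recovery_sim
        cands = {(c.position, c.ref, c.alt): c
                 for c in call_candidates(counts.values(), canonical_design)}
        for m in truth.mutations:
            cand = cands[(m.pos, m.ref, m.alt)]
            expected = canonical_design.pools_for_line(m.line)
            assert cand.positive_pools == expected
            assert m.line in cand.lines
            assert len(cand.lines) == 6

    def test_single_heterozygote_resolves_to_its_six_wells(
            self, canonical_design):
        # one het carrier at plate 4 well E5: candidate must surface in
        # pools {2, 7, 12} and decode to wells E4-F6 of plate 4
        params = synthdata.SimParams(depth=5000, error_rate=5e-4, seed=7)
        amp = {"amp1": "C" * 400}
        carrier = pooling.LineAddress(4, "E", 5)
        truth = synthdata.SimTruth(
            mutations=[synthdata.PlantedMutation(carrier, "amp1", 200, "C",
                                                 "T", "het")],
            homeologs=[], amplicons=amp, params=params,
        )
        counts = synthdata.simulate_pool_counts(truth, canonical_design)
        cands = call_candidates(counts.values(), canonical_design)
        assert len(cands) == 1
        c = cands[0]
        assert (c.position, c.ref, c.alt) == (200, "C", "T")
        assert c.positive_pools == {2, 7, 12}
        assert {a.well for a in c.lines} == {"E4", "E5", "E6",
                                             "F4", "F5", "F6"}
        assert c.ems_consistent and not c.needs_review

    def test_two_significant_pools_do_not_make_a_candidate(
            self, canonical_design):
        # signal present in a column and a row pool only (no plate pool)
        rows = []
        for pool in canonical_design.pool_ids:
            for pos in range(1, 41):
                freq = 0.005 if (pool in (2, 7) and pos == 20) else 0.0001
                rows.append((pool, pos, "C", "T", freq, 5000))
        cands = call_candidates(make_freq_table(rows), canonical_design)
        assert cands == []

    def test_homeolog_pattern_is_never_a_candidate(self, canonical_design):
        rows = []
        for pool in canonical_design.pool_ids:
            for pos in range(1, 41):
                freq = 0.5 if pos == 20 else 0.0001
                rows.append((pool, pos, "G", "A", freq, 5000))
        cands = call_candidates(make_freq_table(rows), canonical_design)
        assert cands == []

    def test_missing_pool_rejected(self, canonical_design, recovery_sim):
        _, counts = recovery_sim
        partial = [m for pid, m in counts.items() if pid != 12]
        with pytest.raises(ValueError, match="pools \\[12\\]"):
            call_candidates(partial, canonical_design)

    def test_ems_only_filters_non_signature_candidates(self, canonical_design):
        params = synthdata.SimParams(depth=5000, error_rate=5e-4, seed=11,
                                     spectrum_fraction=0.0)
        amp = {"amp1": "A" * 300}
        carrier = pooling.LineAddress(2, "C", 8)
        truth = synthdata.SimTruth(
            mutations=[synthdata.PlantedMutation(carrier, "amp1", 150, "A",
                                                 "C", "hom")],
            homeologs=[], amplicons=amp, params=params,
        )
        counts = synthdata.simulate_pool_counts(truth, canonical_design)
        assert len(call_candidates(counts.values(), canonical_design)) == 1
        assert call_candidates(counts.values(), canonical_design,
                               ems_only=True) == []
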