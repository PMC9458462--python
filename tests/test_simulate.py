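"""Synthetic-data generator: rate conservation, readout behaviour, determinism."""

import numpy as np
import pytest

from inoseq import simulate
from inoseq.io import RNA_BASES, TranscriptRef
from inoseq.simulate import (
    MisincorporationModel, ReadoutModel, SimulationConfig,
    gen_transcript, simulate_molecules, simulate_ms, simulate_pileup,
    simulate_polysome_trace, simulate_two_condition,
)


class TestGenTranscript:
    def test_reproducible_full_length(self):
        probs = {b: 0.25 for b in RNA_BASES}
        a = gen_transcript(1650, probs, seed=7)
        b = gen_transcript(1650, probs, seed=7)
        assert a.length == 1650
        assert a.seq == b.seq

    def test_degenerate_probs(self):
        ref = gen_transcript(12, {"A": 1.0, "C": 0, "G": 0, "U": 0}, seed=1)
        assert ref.seq == "A" * 12

    def test_composition_converges(self):
        probs = {"A": 0.4, "C": 0.1, "G": 0.2, "U": 0.3}
        ref = gen_transcript(50_000, probs, seed=3)
        for b in RNA_BASES:
            assert ref.base_fractions[b] == pytest.approx(probs[b], abs=0.01)

    @pytest.mark.parametrize("length", [0, -5])
    def test_rejects_bad_length(self, length):
        with pytest.raises(ValueError):
            gen_transcript(length, {b: 0.25 for b in RNA_BASES}, seed=1)


class TestMisincorporationModel:
    def test_normalization_is_exact(self):
        """Composition-weighted mean of per-base probabilities equals the
        overall rate analytically."""
        model = MisincorporationModel(1 / 185)
        fractions = {"A": 0.3, "C": 0.2, "G": 0.25, "U": 0.25}
        probs = model.per_base_probs(fractions)
        mean = sum(fractions[b] * probs[b] for b in RNA_BASES)
        assert mean == pytest.approx(1 / 185, abs=1e-12)

    def test_default_weights_preserve_hierarchy(self):
        probs = MisincorporationModel(1 / 185).per_base_probs(
            {b: 0.25 for b in RNA_BASES}
        )
        assert probs["G"] > probs["C"] > probs["A"] > probs["U"]

    def test_excessive_rate_rejected(self):
        model = MisincorporationModel(0.9, {"G": 100.0, "C": 1.0, "A": 1.0, "U": 1.0})
        with pytest.raises(ValueError, match="> 1"):
            model.per_base_probs({b: 0.25 for b in RNA_BASES})

    @pytest.mark.parametrize("weights", [
        {"G": 0.0, "C": 1, "A": 1, "U": 1},
        {"G": 1, "C": 1, "A": 1},
    ])
    def test_invalid_weights(self, weights):
        with pytest.raises(ValueError):
            MisincorporationModel(0.01, weights)


class TestSimulateMolecules:
    def test_zero_rate_all_zero(self, luc_ref):
        counts = simulate_molecules(luc_ref, MisincorporationModel(0.0), 1000, seed=1)
        assert (counts == 0).all()

    def test_rate_conservation_within_3_se(self):
        """Empirical inosine fraction matches 1/185 within 3 binomial SE."""
        ref = gen_transcript(1650, {b: 0.25 for b in RNA_BASES}, seed=2)
        rate, n = 1 / 185, 1_000_000
        counts = simulate_molecules(ref, MisincorporationModel(rate), n, seed=2)
        total_bases = n * ref.length
        empirical = counts.sum() / total_bases
        se = np.sqrt(rate * (1 - rate) / total_bases)
        assert abs(empirical - rate) < 3 * se

    def test_support_constraint(self, luc_ref):
        model = MisincorporationModel(
            0.01, {"G": 1.0, "C": 1e-12, "A": 1e-12, "U": 1e-12}
        )
        counts = simulate_molecules(luc_ref, model, 200_000, seed=3)
        non_g = np.array([b != "G" for b in luc_ref.seq])
        assert counts[non_g].sum() == 0

    def test_per_base_ordering_matches_weights(self):
        """Per-template-base inosine fractions realise the G>C>A>U hierarchy."""
        ref = gen_transcript(4000, {b: 0.25 for b in RNA_BASES}, seed=4)
        counts = simulate_molecules(ref, MisincorporationModel(1 / 185), 100_000, seed=4)
        seq = np.array(list(ref.seq))
        by_base = {b: counts[seq == b].sum() / (seq == b).sum() for b in RNA_BASES}
        assert by_base["G"] > by_base["C"] > by_base["A"] > by_base["U"]


class TestSimulatePileup:
    def test_null_case_perfect_accuracy(self, luc_ref):
        readout = ReadoutModel("direct_rna", background_miscall=0.0)
        table = simulate_pileup(luc_ref, np.zeros(luc_ref.length), readout, 50, seed=1)
        assert (table.rows["mismatches"] == 0).all()
        assert (table.rows["matches"] == 50).all()

    def test_short_read_expected_g_count(self):
        """At an A position with inosine fraction f, E[count_G] = f*depth."""
        ref = TranscriptRef(id="a", seq="A" * 300)
        f, depth = 0.1, 2000
        readout = ReadoutModel("short_read", background_miscall=0.0)
        table = simulate_pileup(ref, np.full(300, f), readout, depth, seed=5)
        total = table.rows["count_G"].sum()
        n = 300 * depth
        se = np.sqrt(n * f * (1 - f))
        assert abs(total - f * n) < 3 * se

    def test_short_read_mismatches_only_g_and_only_with_inosine(self, luc_ref):
        incidence = np.zeros(luc_ref.length)
        incidence[::3] = 0.5
        readout = ReadoutModel("short_read", background_miscall=0.0)
        table = simulate_pileup(luc_ref, incidence, readout, 100, seed=6)
        df = table.rows
        mismatch_rows = df[df["mismatches"] > 0]
        assert (incidence[mismatch_rows["pos"].to_numpy() - 1] > 0).all()
        # every mismatch call is a G (reverse-transcription rule)
        non_g = mismatch_rows[mismatch_rows["ref_base"] != "G"]
        assert (non_g["mismatches"] == non_g["count_G"]).all()
        assert (df[df["ref_base"] == "G"]["mismatches"] == 0).all()

    def test_direct_rna_background_accuracy_near_97(self):
        ref = gen_transcript(1000, {b: 0.25 for b in RNA_BASES}, seed=7)
        readout = ReadoutModel("direct_rna", background_miscall=0.03)
        table = simulate_pileup(ref, np.zeros(1000), readout, 200, seed=7)
        acc = 100.0 * table.rows["matches"].sum() / table.rows["depth"].sum()
        assert 96.0 < acc < 98.0

    def test_depth_below_one_rejected(self, luc_ref):
        with pytest.raises(ValueError):
            simulate_pileup(luc_ref, np.zeros(luc_ref.length),
                            ReadoutModel("direct_rna"), 0, seed=1)


class TestTwoCondition:
    def test_determinism_byte_identical(self):
        cfg = SimulationConfig(seed=11, transcript_length=120, depth=30,
                               n_molecules=2000)
        a1, b1 = simulate_two_condition(cfg)
        a2, b2 = simulate_two_condition(cfg)
        assert a1.rows.equals(a2.rows) and b1.rows.equals(b2.rows)

    def test_equal_rates_centred_delta(self):
        cfg = SimulationConfig(seed=12, transcript_length=400, depth=200,
                               n_molecules=2000, rate_control=0.0, rate_treated=0.0)
        control, treated = simulate_two_condition(cfg)
        diff = (treated.rows["mismatches"] - control.rows["mismatches"]).to_numpy()
        # exchangeable conditions: mean difference within 3 SE of zero
        se = diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) < 3 * se

    def test_treated_mean_frequency_strictly_greater(self):
        cfg = SimulationConfig(seed=13, transcript_length=600, depth=300,
                               n_molecules=20_000)
        control, treated = simulate_two_condition(cfg)
        fc = control.rows["mismatches"].sum() / control.rows["depth"].sum()
        ft = treated.rows["mismatches"].sum() / treated.rows["depth"].sum()
        assert ft > fc


class TestSimulateMs:
    def test_zero_sd_is_analytic(self):
        expected = 1 / 9037 / 0.2504 * 1e6  # ~442 IMP per 10^6 AMP
        levels = simulate_ms(1 / 9037, 0.2504, sd=0.0, n=3, seed=1)
        assert levels == pytest.approx([expected] * 3, abs=1e-9)
        assert round(expected) == 442

    def test_replicate_sd_recovered(self):
        levels = simulate_ms(1 / 9037, 0.2504, sd=25.0, n=400, seed=2)
        assert np.std(levels, ddof=1) == pytest.approx(25.0, rel=0.25)

    def test_invalid_f_a(self):
        with pytest.raises(ValueError):
            simulate_ms(0.001, 0.0, sd=1.0, n=3, seed=1)


class TestPolysomeTrace:
    def test_single_gaussian_peak_height(self):
        trace = simulate_polysome_trace([(10.0, 1.0, 1.0)], baseline=0.0,
                                        noise_sd=0.0, n_points=2001, seed=1,
                                        x_range=(0.0, 20.0))
        assert trace.absorbance.max() == pytest.approx(1.0, abs=1e-6)
        assert trace.positions[np.argmax(trace.absorbance)] == pytest.approx(10.0, abs=0.02)

    def test_trapezoid_area_matches_analytic(self):
        h, sigma = 0.8, 1.3
        trace = simulate_polysome_trace([(15.0, sigma, h)], baseline=0.0,
                                        noise_sd=0.0, n_points=4001, seed=1,
                                        x_range=(0.0, 30.0))
        area = np.trapezoid(trace.absorbance, trace.positions)
        assert area == pytest.approx(h * sigma * np.sqrt(2 * np.pi), rel=0.01)

    def test_seed_determinism(self):
        kw = dict(baseline=0.05, noise_sd=0.02, n_points=500, seed=9)
        a = simulate_polysome_trace([(5.0, 1.0, 1.0)], **kw)
        b = simulate_polysome_trace([(5.0, 1.0, 1.0)], **kw)
        np.testing.assert_array_equal(a.absorbance, b.absorbance)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            simulate_polysome_trace([(5.0, 1.0, 1.0)], 0.0, 0.0, n_points=5, seed=1)


def test_component_seed_streams_differ():
    """Different components derive distinct deterministic streams."""
    a = simulate.rng_for(1, "pileup_control").integers(0, 2**31, 5)
    b = simulate.rng_for(1, "pileup_treated").integers(0, 2**31, 5)
    c = simulate.rng_for(1, "pileup_control").integers(0, 2**31, 5)
    assert not np.array_equal(a, b)
    np.testing.assert_array_equal(a, c)
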