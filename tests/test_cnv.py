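"""Segmentation, chromosome-level calling, CNV load, frequency comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from ptprmeth import (ValidationError, alteration_frequency_table,
                      call_chromosomes, cnv_load, compare_frequencies,
                      segment_profile, write_seg)


def bins_for(n, chrom="chr1", size=1_000_000):
    return pd.DataFrame({"chromosome": chrom,
                         "start": np.arange(n) * size,
                         "end": (np.arange(n) + 1) * size})


def segs_from(rows):
    """rows: (chromosome, start, end, mean_value, n_bins)"""
    df = pd.DataFrame(rows, columns=["chromosome", "start", "end",
                                     "mean_value", "n_bins"])
    df["length"] = df["end"] - df["start"]
    return df


class TestSegmentation:
    def test_flat_profile_single_segment(self):
        segs = segment_profile(bins_for(40), np.zeros(40))
        assert len(segs) == 1
        assert segs.iloc[0]["mean_value"] == 0.0
        assert segs.iloc[0]["n_bins"] == 40

    def test_noiseless_step_recovered_exactly(self):
        x = np.concatenate([np.zeros(50), np.full(50, -0.3)])
        segs = segment_profile(bins_for(100), x)
        assert len(segs) == 2
        assert segs["n_bins"].tolist() == [50, 50]
        assert segs["mean_value"].tolist() == [0.0, pytest.approx(-0.3)]
        assert segs.iloc[1]["start"] == 50 * 1_000_000

    def test_breakpoint_recovery_under_noise(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = np.concatenate([np.zeros(50), np.full(50, -0.3)])
            x = x + rng.normal(0, 0.15, 100)
            segs = segment_profile(bins_for(100), x)
            starts = (segs["start"] // 1_000_000).tolist()[1:]
            if any(abs(s - 50) <= 3 for s in starts):
                hits += 1
        assert hits >= 90

    def test_idempotent_on_piecewise_constant_reconstruction(self, rng):
        x = np.concatenate([rng.normal(0.0, 0.15, 60),
                            rng.normal(0.4, 0.15, 40)])
        first = segment_profile(bins_for(100), x)
        recon = np.repeat(first["mean_value"].to_numpy(),
                          first["n_bins"].to_numpy())
        second = segment_profile(bins_for(100), recon)
        assert second["start"].tolist() == first["start"].tolist()
        assert second["n_bins"].tolist() == first["n_bins"].tolist()

    def test_short_chromosome_single_segment_with_warning(self):
        with pytest.warns(UserWarning, match="min_bins"):
            segs = segment_profile(bins_for(3), np.array([0.5, 0.4, 0.6]))
        assert len(segs) == 1


class TestChromosomeCalls:
    def test_uniform_gain(self):
        segs = segs_from([("chr1", 0, 10_000, 0.25, 10)])
        calls = call_chromosomes(segs)
        assert calls.iloc[0]["call"] == "gain"

    def test_boundary_value_is_neutral(self):
        segs = segs_from([("chr1", 0, 10_000, 0.1, 10)])
        assert call_chromosomes(segs).iloc[0]["call"] == "neutral"
        segs = segs_from([("chr1", 0, 10_000, -0.1, 10)])
        assert call_chromosomes(segs).iloc[0]["call"] == "neutral"

    def test_length_weighting_half_altered(self):
        segs = segs_from([("chr1", 0, 5_000, 0.3, 5),
                          ("chr1", 5_000, 10_000, 0.0, 5)])
        calls = call_chromosomes(segs)
        assert calls.iloc[0]["summary_value"] == pytest.approx(0.15)
        assert calls.iloc[0]["call"] == "gain"

    def test_matches_bruteforce_weighting_with_sign_symmetry(self, rng):
        for _ in range(1000):
            n_seg = rng.integers(1, 6)
            lengths = rng.integers(1, 50, n_seg) * 1000
            means = rng.normal(0, 0.2, n_seg)
            start = np.concatenate([[0], np.cumsum(lengths)[:-1]])
            segs = segs_from(list(zip(["chr5"] * n_seg, start,
                                      start + lengths, means,
                                      np.ones(n_seg, dtype=int))))
            call = call_chromosomes(segs).iloc[0]
            expected = float(np.sum(lengths * means) / lengths.sum())
            assert call["summary_value"] == pytest.approx(expected, abs=1e-12)
            flipped = segs.assign(mean_value=-segs["mean_value"])
            fcall = call_chromosomes(flipped).iloc[0]
            swap = {"gain": "loss", "loss": "gain", "neutral": "neutral"}
            assert fcall["call"] == swap[call["call"]]

    def test_majority_length_rule(self):
        segs = segs_from([("chr1", 0, 6_000, 0.3, 6),
                          ("chr1", 6_000, 10_000, -0.5, 4)])
        assert call_chromosomes(segs).iloc[0]["call"] == "neutral"
        assert call_chromosomes(segs, rule="majority_length") \
            .iloc[0]["call"] == "gain"


class TestCnvLoad:
    def test_neutral_genome_zero(self):
        segs = segs_from([("chr1", 0, 1000, 0.0, 1),
                          ("chr2", 0, 1000, 0.05, 1)])
        assert cnv_load(segs) == 0.0

    def test_fully_altered_genome_one(self):
        segs = segs_from([("chr1", 0, 1000, 0.3, 1),
                          ("chr2", 0, 1000, -0.3, 1)])
        assert cnv_load(segs) == 1.0

    def test_proportional_to_altered_length(self):
        segs = segs_from([("chr1", 0, 3000, 0.3, 3),
                          ("chr2", 0, 7000, 0.0, 7)])
        assert cnv_load(segs) == pytest.approx(0.3)

    def test_sex_chromosomes_excluded_by_default(self):
        segs = segs_from([("chr1", 0, 1000, 0.0, 1),
                          ("chrX", 0, 9000, 0.5, 9)])
        assert cnv_load(segs) == 0.0

    def test_zero_length_raises(self):
        segs = segs_from([("chrX", 0, 1000, 0.0, 1)])
        with pytest.raises(ValidationError):
            cnv_load(segs)


class TestFrequencies:
    def _calls(self, n, n_loss, chrom="chr10"):
        rows = []
        for i in range(n):
            call = "loss" if i < n_loss else "neutral"
            rows.append((f"s{i}", chrom, -0.3 if i < n_loss else 0.0, call))
        return pd.DataFrame(rows, columns=["sample_id", "chromosome",
                                           "summary_value", "call"])

    def test_overall_fraction_arithmetic(self):
        # 70 of 75 chr10-loss calls -> 93.3%
        calls = self._calls(75, 70)
        labels = {f"s{i}": "G" for i in range(75)}
        tab = alteration_frequency_table(calls, labels)
        assert tab.iloc[0]["frac_overall"] == pytest.approx(70 / 75)
        assert round(100 * tab.iloc[0]["frac_overall"], 1) == 93.3

    def test_no_alterations_empty_table(self):
        calls = self._calls(10, 0)
        tab = alteration_frequency_table(calls, {f"s{i}": "G"
                                                 for i in range(10)})
        assert len(tab) == 0

    def test_fractions_match_bruteforce_tally(self, rng):
        samples = [f"s{i}" for i in range(60)]
        labels = {s: rng.choice(["A", "B"]) for s in samples}
        rows = []
        for s in samples:
            for chrom in ("chr1", "chr2"):
                rows.append((s, chrom, 0.0,
                             rng.choice(["gain", "loss", "neutral"])))
        calls = pd.DataFrame(rows, columns=["sample_id", "chromosome",
                                            "summary_value", "call"])
        tab = alteration_frequency_table(calls, labels)
        sizes = {g: sum(1 for s in samples if labels[s] == g)
                 for g in ("A", "B")}
        for _, row in tab.iterrows():
            for g in ("A", "B"):
                manual = sum(1 for _, r in calls.iterrows()
                             if r["chromosome"] == row["chromosome"]
                             and r["call"] == row["alteration"]
                             and labels[r["sample_id"]] == g)
                assert row[f"count_{g}"] == manual
                assert row[f"frac_{g}"] == pytest.approx(manual / sizes[g])

    def test_unlabeled_sample_raises(self):
        calls = self._calls(3, 1)
        with pytest.raises(ValidationError):
            alteration_frequency_table(calls, {"s0": "A"})


def fisher_two_sided_oracle(a, n1, b, n2):
    """Hypergeometric enumeration: sum the probabilities of all tables with
    the same margins that are no more probable than the observed one."""
    k = a + b           # successes total
    n = n1 + n2
    p_obs = hypergeom.pmf(a, n, k, n1)
    total = 0.0
    for x in range(max(0, k - n2), min(k, n1) + 1):
        p = hypergeom.pmf(x, n, k, n1)
        if p <= p_obs * (1 + 1e-10):
            total += p
    return min(1.0, total)


class TestFisher:
    def test_equal_frequencies_p_one(self):
        assert compare_frequencies(5, 10, 5, 10) == pytest.approx(1.0)

    def test_degenerate_margin_p_one(self):
        assert compare_frequencies(0, 10, 0, 10) == pytest.approx(1.0)

    def test_extreme_subtype_difference(self):
        # the B1-vs-B2 chromosome 3 loss configuration: 22/24 vs 0/31
        p = compare_frequencies(22, 24, 0, 31)
        assert p == pytest.approx(fisher_two_sided_oracle(22, 24, 0, 31),
                                  rel=1e-9)
        assert 1e-14 < p < 1e-12

    def test_negative_count_raises(self):
        with pytest.raises(ValidationError):
            compare_frequencies(-1, 10, 0, 10)


def test_seg_export_converts_to_one_based_inclusive(tmp_path):
    segs = segs_from([("chr1", 0, 5_000, 0.2, 5),
                      ("chr1", 5_000, 9_000, -0.1, 4)])
    write_seg({"samp1": segs}, tmp_path / "out.seg")
    back = pd.read_csv(tmp_path / "out.seg", sep="\t")
    assert back["loc.start"].tolist() == [1, 5001]
    assert back["loc.end"].tolist() == [5000, 9000]
    assert back["ID"].unique().tolist() == ["samp1"]
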