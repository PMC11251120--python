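"""Rank-sum differential methylation and the promoter-calling rule."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from ptprmeth import (DiffMethConfig, ValidationError, aggregate_promoters,
                      call_dmps, rank_sum_test)

from conftest import make_beta


def brute_force_rank_sum_p(x, y):
    """Independent oracle: enumerate every group assignment of the pooled
    values and compare Mann-Whitney U statistics (ties counted 0.5)."""
    pooled = np.concatenate([x, y])
    n, n1 = len(pooled), len(x)

    def u_stat(a, b):
        a, b = np.asarray(a, float), np.asarray(b, float)
        return ((a[:, None] > b[None, :]).sum()
                + 0.5 * (a[:, None] == b[None, :]).sum())

    u_obs = u_stat(x, y)
    n_le = n_ge = total = 0
    for chosen in combinations(range(n), n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(chosen)] = True
        u = u_stat(pooled[mask], pooled[~mask])
        total += 1
        n_le += u <= u_obs + 1e-12
        n_ge += u >= u_obs - 1e-12
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


class TestRankSum:
    def test_identical_groups_give_p_one(self):
        assert rank_sum_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_fully_separated_small_groups(self):
        # 1/20 of assignments per tail under exact enumeration
        assert rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_tied_samples_match_enumeration(self, rng):
        x = rng.integers(0, 5, size=8).astype(float)
        y = rng.integers(0, 5, size=8).astype(float)
        assert rank_sum_test(x, y) == pytest.approx(
            brute_force_rank_sum_p(x, y), abs=1e-6)

    def test_empty_group_raises(self):
        with pytest.raises(ValidationError):
            rank_sum_test([], [1.0])


class TestCallDmps:
    def _two_group_matrix(self, rows, samples_a=4, samples_b=4):
        vals = np.array(rows, dtype=float)
        bm = make_beta(vals)
        labels = {f"s{j}": ("A" if j < samples_a else "B")
                  for j in range(samples_a + samples_b)}
        return bm, labels

    def test_large_delta_low_p_is_significant(self):
        bm, labels = self._two_group_matrix(
            [[0.81, 0.80, 0.82, 0.79, 0.30, 0.31, 0.29, 0.32]])
        out = call_dmps(bm, labels, groups=("A", "B"))
        rec = out.iloc[0]
        assert rec["significant"] and rec["direction"] == "hyper"
        assert rec["delta_beta"] == pytest.approx(0.5, abs=1e-9)

    def test_small_delta_fails_filter_despite_tiny_p(self):
        a = np.full(20, 0.50) + np.linspace(0, 0.001, 20)
        b = np.full(20, 0.40) + np.linspace(0, 0.001, 20)
        bm = make_beta(np.concatenate([a, b])[None, :])
        labels = {f"s{j}": ("A" if j < 20 else "B") for j in range(40)}
        out = call_dmps(bm, labels, groups=("A", "B"))
        assert out.iloc[0]["p_value"] < 1e-6
        assert not out.iloc[0]["significant"]

    def test_large_delta_but_nonsignificant_p_fails(self):
        bm, labels = self._two_group_matrix(
            [[0.99, 0.05, 0.95, 0.96, 0.45, 0.50, 0.55, 0.52]])
        out = call_dmps(bm, labels, groups=("A", "B"))
        assert abs(out.iloc[0]["delta_beta"]) > 0.2
        assert out.iloc[0]["p_value"] > 0.05
        assert not out.iloc[0]["significant"]

    def test_direction_antisymmetry_under_group_swap(self, rng):
        vals = rng.random((30, 10))
        bm = make_beta(vals)
        labels = {f"s{j}": ("A" if j < 5 else "B") for j in range(10)}
        fwd = call_dmps(bm, labels, groups=("A", "B"))
        rev = call_dmps(bm, labels, groups=("B", "A"))
        assert np.allclose(fwd["p_value"], rev["p_value"], atol=1e-12)
        assert np.allclose(fwd["delta_beta"], -rev["delta_beta"], atol=1e-12)
        nontrivial = fwd["delta_beta"].abs() > 0
        assert (fwd.loc[nontrivial, "direction"].to_numpy()
                != rev.loc[nontrivial, "direction"].to_numpy()).all()

    def test_lowering_delta_threshold_is_monotone(self, rng):
        vals = rng.random((50, 12))
        bm = make_beta(vals)
        labels = {f"s{j}": ("A" if j < 6 else "B") for j in range(12)}
        strict = call_dmps(bm, labels, DiffMethConfig(delta_threshold=0.3))
        loose = call_dmps(bm, labels, DiffMethConfig(delta_threshold=0.1))
        assert set(strict.loc[strict["significant"], "probe_id"]) <= \
            set(loose.loc[loose["significant"], "probe_id"])

    def test_undersized_group_raises(self):
        bm, _ = self._two_group_matrix([[0.1] * 8])
        labels = {f"s{j}": ("A" if j < 1 else "B") for j in range(8)}
        with pytest.raises(ValidationError):
            call_dmps(bm, labels)

    def test_three_groups_rejected(self, rng):
        bm = make_beta(rng.random((5, 6)))
        labels = {f"s{j}": "ABC"[j % 3] for j in range(6)}
        with pytest.raises(ValidationError):
            call_dmps(bm, labels)


def _dmp_table(rows):
    return pd.DataFrame(rows, columns=["probe_id", "p_value", "delta_beta",
                                       "direction", "significant"])


def _manifest_for(probes, gene="G1"):
    return pd.DataFrame({"probe_id": probes, "chromosome": "chr1",
                         "position": range(len(probes)),
                         "promoter_gene": gene})


class TestPromoterAggregation:
    @pytest.mark.parametrize("n_hyper,n_hypo,expected", [
        (3, 0, "hyper"),   # rule forced
        (2, 0, "none"),    # "more than two" unmet
        (3, 1, "none"),    # opposite direction nonzero
        (0, 4, "hypo"),
    ])
    def test_calling_rule(self, n_hyper, n_hypo, expected):
        rows = []
        for i in range(n_hyper):
            rows.append((f"p{i}", 0.01, 0.3, "hyper", True))
        for i in range(n_hypo):
            rows.append((f"q{i}", 0.01, -0.3, "hypo", True))
        rows.append(("r0", 0.9, 0.0, "hypo", False))   # insignificant: ignored
        dmps = _dmp_table(rows)
        calls = aggregate_promoters(dmps, _manifest_for(dmps["probe_id"]))
        assert calls.iloc[0]["call"] == expected

    def test_unmapped_probes_never_emit_genes(self):
        dmps = _dmp_table([("p0", 0.01, 0.3, "hyper", True)])
        manifest = _manifest_for(["p0"], gene=pd.NA)
        calls = aggregate_promoters(dmps, manifest)
        assert len(calls) == 0

    def test_matches_bruteforce_recount(self, rng):
        probes = [f"p{i}" for i in range(200)]
        genes = rng.choice([f"G{g}" for g in range(30)], size=200)
        manifest = pd.DataFrame({"probe_id": probes, "chromosome": "chr1",
                                 "position": range(200),
                                 "promoter_gene": genes})
        sig = rng.random(200) < 0.4
        direction = rng.choice(["hyper", "hypo"], size=200)
        dmps = _dmp_table(list(zip(probes, rng.random(200),
                                   rng.normal(0, 0.3, 200), direction, sig)))
        calls = aggregate_promoters(dmps, manifest).set_index("gene")
        for g in np.unique(genes):
            members = dmps[np.isin(probes, np.array(probes)[genes == g])]
            n_hyper = int(((members["direction"] == "hyper")
                           & members["significant"]).sum())
            n_hypo = int(((members["direction"] == "hypo")
                          & members["significant"]).sum())
            expected = ("hyper" if n_hyper >= 3 and n_hypo == 0 else
                        "hypo" if n_hypo >= 3 and n_hyper == 0 else "none")
            assert calls.loc[g, "call"] == expected
            assert calls.loc[g, "n_sig_hyper"] == n_hyper
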