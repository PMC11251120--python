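"""Two-group differential methylation and promoter-level calls.

A probe is differentially methylated (a DMP) when a two-sided rank-sum test
gives p < 0.05 and the absolute mean beta difference exceeds 0.2 (raw
p-values, no multiple-testing correction; a Benjamini-Hochberg option exists
but is off by default). A gene promoter is called hyper-(hypo-)methylated
when more than two of its probes are significantly hyper-(hypo-)methylated
and none are significant in the opposite direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .errors import ValidationError
from .io import BetaMatrix

#: largest number of group assignments enumerated exactly for tied samples
_MAX_ENUMERATION = 50_000


@dataclass
class DiffMethConfig:
    p_threshold: float = 0.05
    delta_threshold: float = 0.2
    min_sig_probes: int = 3       # "more than two" significant probes
    fdr_correction: bool = False  # Benjamini-Hochberg on p before filtering

    def validate(self) -> None:
        if not (0.0 < self.p_threshold < 1.0):
            raise ValidationError("p_threshold must lie in (0, 1)")
        if not (0.0 < self.delta_threshold < 1.0):
            raise ValidationError("delta_threshold must lie in (0, 1)")
        if self.min_sig_probes < 1:
            raise ValidationError("min_sig_probes must be >= 1")


def _mwu_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x vs y with the tie convention U += 0.5 per tie."""
    return float((x[:, None] > y[None, :]).sum()
                 + 0.5 * (x[:, None] == y[None, :]).sum())


def _exact_p_with_ties(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact p by full enumeration of group assignments.

    p = min(1, 2 * min(P(U <= u_obs), P(U >= u_obs))) over the permutation
    distribution of U given the pooled values.
    """
    pooled = np.concatenate([x, y])
    n, n1 = len(pooled), len(x)
    u_obs = _mwu_statistic(x, y)
    n_le = n_ge = total = 0
    idx = np.arange(n)
    for chosen in combinations(range(n), n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(chosen)] = True
        u = _mwu_statistic(pooled[mask], pooled[~mask])
        total += 1
        if u <= u_obs + 1e-12:
            n_le += 1
        if u >= u_obs - 1e-12:
            n_ge += 1
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def rank_sum_test(x: Sequence[float], y: Sequence[float],
                  mode: str = "auto") -> float:
    """Two-sided Mann-Whitney rank-sum p-value.

    ``mode='auto'``: exact distribution when both groups have <= 25
    observations and there are no ties; exact enumeration over group
    assignments for tied samples small enough to enumerate (C(n, n1) <= 5e4);
    tie-corrected normal approximation with continuity correction otherwise.
    ``mode`` may force ``'exact'`` or ``'asymptotic'``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if mode == "auto":
        if not has_ties and len(x) <= 25 and len(y) <= 25:
            mode = "exact"
        elif has_ties and comb(len(x) + len(y), len(x)) <= _MAX_ENUMERATION:
            return _exact_p_with_ties(x, y)
        else:
            mode = "asymptotic"
    if mode == "exact":
        if has_ties:
            return _exact_p_with_ties(x, y)
        method = "exact"
    elif mode == "asymptotic":
        method = "asymptotic"
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0.0, 1.0)
    return out


def call_dmps(matrix: BetaMatrix, labels: Mapping[str, str],
              config: DiffMethConfig | None = None,
              groups: tuple[str, str] | None = None) -> pd.DataFrame:
    """Per-probe differential methylation between exactly two groups.

    ``labels`` maps each sample to one of two group names; ``groups`` fixes the
    orientation (delta_beta = mean(groups[0]) - mean(groups[1]); default
    order of first appearance in the matrix's samples). Returns a DataFrame
    with columns probe_id, p_value, delta_beta, direction (hyper/hypo of the
    first group), significant.
    """
    config = config or DiffMethConfig()
    config.validate()
    sample_groups = {s: labels[s] for s in matrix.sample_ids}
    uniq = list(dict.fromkeys(sample_groups.values())) if groups is None \
        else list(groups)
    present = set(sample_groups.values())
    if len(present) != 2 or set(uniq) != present:
        raise ValidationError(
            f"exactly two groups required, got {sorted(present)}")
    ga, gb = uniq
    cols_a = [s for s in matrix.sample_ids if sample_groups[s] == ga]
    cols_b = [s for s in matrix.sample_ids if sample_groups[s] == gb]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValidationError("each group needs at least 2 samples")

    xa = matrix.values[cols_a].to_numpy(dtype=float)
    xb = matrix.values[cols_b].to_numpy(dtype=float)
    delta = xa.mean(axis=1) - xb.mean(axis=1)

    if len(cols_a) > 25 or len(cols_b) > 25:
        # vectorized tie-corrected normal approximation across probes
        res = mannwhitneyu(xa, xb, alternative="two-sided",
                           method="asymptotic", axis=1)
        pvals = np.asarray(res.pvalue, dtype=float)
    else:
        pvals = np.array([rank_sum_test(xa[i], xb[i])
                          for i in range(xa.shape[0])])

    p_for_filter = _bh_adjust(pvals) if config.fdr_correction else pvals
    significant = (p_for_filter < config.p_threshold) & \
        (np.abs(delta) > config.delta_threshold)
    return pd.DataFrame({
        "probe_id": matrix.probe_ids,
        "p_value": pvals,
        "delta_beta": delta,
        "direction": np.where(delta > 0, "hyper", "hypo"),
        "significant": significant,
    }).reset_index(drop=True)


def aggregate_promoters(dmps: pd.DataFrame, manifest: pd.DataFrame,
                        config: DiffMethConfig | None = None) -> pd.DataFrame:
    """Promoter-level hyper/hypo calls from the per-probe DMP table.

    For each gene with at least one manifest-mapped probe, count significant
    hyper- and hypo-methylated probes; call hyper iff n_sig_hyper >=
    ``min_sig_probes`` (default 3, i.e. "more than two") and n_sig_hypo == 0,
    and symmetrically for hypo; otherwise none.
    """
    config = config or DiffMethConfig()
    config.validate()
    gene_of = manifest.set_index("probe_id")["promoter_gene"]
    merged = dmps.merge(gene_of.rename("gene"), left_on="probe_id",
                        right_index=True, how="left")
    merged = merged.dropna(subset=["gene"])

    sig = merged[merged["significant"]]
    genes = merged["gene"].unique()
    hyper = sig[sig["direction"] == "hyper"].groupby("gene").size()
    hypo = sig[sig["direction"] == "hypo"].groupby("gene").size()
    rows = []
    for g in sorted(genes):
        n_hyper = int(hyper.get(g, 0))
        n_hypo = int(hypo.get(g, 0))
        if n_hyper >= config.min_sig_probes and n_hypo == 0:
            call = "hyper"
        elif n_hypo >= config.min_sig_probes and n_hyper == 0:
            call = "hypo"
        else:
            call = "none"
        rows.append((g, n_hyper, n_hypo, call))
    return pd.DataFrame(rows, columns=["gene", "n_sig_hyper", "n_sig_hypo",
                                       "call"])
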