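"""Copy-number analysis from bin-level log2 ratios.

The input is a per-sample genomic profile of log2 copy-number ratios over
fixed bins (0-based half-open coordinates). The analysis chain is:

1. per-chromosome segmentation by recursive binary splitting, minimizing the
   within-segment sum of squares with a BIC-style penalty per split;
2. chromosome-level gain/loss calls from the length-weighted mean of segment
   means against a strict ±cutoff (default ±0.1);
3. a per-sample CNV load: the fraction of the binned autosomal genome lying
   in segments whose |mean| exceeds the cutoff;
4. per-subtype alteration frequency tables and Fisher exact comparisons.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, mannwhitneyu

from .errors import ValidationError
from .io import AUTOSOMES

SEGMENT_COLUMNS = ("chromosome", "start", "end", "mean_value", "n_bins",
                   "length")


class BinProfile:
    """Bin-level log2 copy-number ratios for one or more samples.

    Parameters
    ----------
    bins
        DataFrame with columns chromosome, start, end (0-based half-open),
        sorted by chromosome then start, non-overlapping within a chromosome.
    values
        DataFrame of log2 ratios, one row per bin (aligned with ``bins``),
        one column per sample.
    """

    def __init__(self, bins: pd.DataFrame, values: pd.DataFrame,
                 validate: bool = True):
        bins = bins.reset_index(drop=True)
        values = values.reset_index(drop=True)
        if validate:
            self._validate(bins, values)
        self.bins = bins
        self.values = values

    @staticmethod
    def _validate(bins: pd.DataFrame, values: pd.DataFrame) -> None:
        for col in ("chromosome", "start", "end"):
            if col not in bins.columns:
                raise ValidationError(f"bin table missing column {col!r}")
        if len(bins) != len(values):
            raise ValidationError("bins and values row counts differ")
        if (bins["end"] <= bins["start"]).any():
            raise ValidationError("bins must satisfy end > start")
        for chrom, grp in bins.groupby("chromosome", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if (np.diff(starts) <= 0).any():
                raise ValidationError(f"bins not sorted on {chrom}")
            if (starts[1:] < ends[:-1]).any():
                raise ValidationError(f"overlapping bins on {chrom}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def sample_values(self, sample_id: str) -> np.ndarray:
        return self.values[sample_id].to_numpy(dtype=float)


def read_bin_profile(path: str | Path) -> BinProfile:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    bins = df[["chromosome", "start", "end"]]
    values = df.drop(columns=["chromosome", "start", "end"])
    return BinProfile(bins, values)


def write_bin_profile(profile: BinProfile, path: str | Path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    pd.concat([profile.bins, profile.values], axis=1).to_csv(
        path, sep=sep, index=False, float_format="%.6g")


def _robust_noise_variance(x: np.ndarray, chrom_index: np.ndarray) -> float:
    """Noise variance from median absolute first differences within chromosomes.

    diff of adjacent bins has variance 2*sigma^2 under a piecewise-constant
    signal; the median absolute deviation is robust to the few breakpoints.
    """
    diffs = []
    for c in np.unique(chrom_index):
        xc = x[chrom_index == c]
        if len(xc) >= 2:
            diffs.append(np.diff(xc))
    if not diffs:
        return 0.0
    d = np.abs(np.concatenate(diffs))
    sigma = np.median(d) / (np.sqrt(2.0) * 0.67448975)
    return float(sigma ** 2)


def _best_split(x: np.ndarray, min_bins: int) -> tuple[int, float]:
    """Best split point of x and the SSE reduction it achieves.

    Returns (t, gain): splitting into x[:t] / x[t:]. gain = SSE(whole) -
    SSE(left) - SSE(right), maximized over t in [min_bins, n - min_bins].
    Ties broken toward the smallest t.
    """
    n = len(x)
    if n < 2 * min_bins:
        return -1, -np.inf
    csum = np.cumsum(x)
    total = csum[-1]
    t = np.arange(min_bins, n - min_bins + 1)
    left_sum = csum[t - 1]
    right_sum = total - left_sum
    # SSE reduction = sum_left^2/nl + sum_right^2/nr - total^2/n
    gain = left_sum ** 2 / t + right_sum ** 2 / (n - t) - total ** 2 / n
    best = int(np.argmax(gain))
    return int(t[best]), float(gain[best])


def _split_recursive(x: np.ndarray, lo: int, hi: int, penalty: float,
                     min_bins: int, breaks: list[int]) -> None:
    t, gain = _best_split(x[lo:hi], min_bins)
    if t < 0 or gain <= penalty:
        return
    breaks.append(lo + t)
    _split_recursive(x, lo, lo + t, penalty, min_bins, breaks)
    _split_recursive(x, lo + t, hi, penalty, min_bins, breaks)


def segment_profile(bins: pd.DataFrame, values: np.ndarray | pd.Series,
                    min_bins: int = 5, penalty: float | None = None,
                    penalty_scale: float = 2.0) -> pd.DataFrame:
    """Segment one sample's bin profile into constant-mean segments.

    Recursive binary splitting per chromosome: a split is accepted when it
    reduces the within-segment sum of squares by more than ``penalty``
    (default ``penalty_scale * sigma_hat^2 * ln(n_bins_chrom)``, a BIC-style
    cost with a robust noise-variance estimate). Deterministic; a chromosome
    with fewer than ``min_bins`` bins yields a single segment with a warning.
    """
    x = np.asarray(values, dtype=float)
    if len(x) != len(bins):
        raise ValidationError("values length does not match bin table")
    chrom_codes, chrom_labels = pd.factorize(bins["chromosome"], sort=False)
    sigma2 = _robust_noise_variance(x, chrom_codes) if penalty is None else None

    rows = []
    starts_all = bins["start"].to_numpy()
    ends_all = bins["end"].to_numpy()
    lengths_all = ends_all - starts_all
    for c, chrom in enumerate(chrom_labels):
        idx = np.nonzero(chrom_codes == c)[0]
        xc = x[idx]
        n = len(xc)
        if n < min_bins:
            warnings.warn(f"{chrom}: only {n} bins (< min_bins={min_bins}); "
                          "emitting a single segment", stacklevel=2)
            breaks: list[int] = []
        else:
            if penalty is not None:
                pen = penalty
            else:
                # floor guards exactly piecewise-constant inputs, where the
                # robust noise estimate is 0 and float jitter in segment
                # means would otherwise admit spurious splits
                pen = max(penalty_scale * sigma2 * np.log(max(n, 2)), 1e-10)
            breaks = []
            _split_recursive(xc, 0, n, pen, min_bins, breaks)
        bounds = [0] + sorted(breaks) + [n]
        for a, b in zip(bounds[:-1], bounds[1:]):
            seg_idx = idx[a:b]
            seg_len = int(lengths_all[seg_idx].sum())
            rows.append((chrom, int(starts_all[seg_idx[0]]),
                         int(ends_all[seg_idx[-1]]),
                         float(xc[a:b].mean()), b - a, seg_len))
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def call_chromosomes(segments: pd.DataFrame, cutoff: float = 0.1,
                     rule: str = "weighted_mean") -> pd.DataFrame:
    """Chromosome-level gain/neutral/loss calls from one sample's segments.

    ``rule='weighted_mean'`` (default): the chromosome summary is the
    length-weighted mean of its segment means; gain iff summary > +cutoff,
    loss iff summary < -cutoff (strict inequalities, so a summary of exactly
    ±cutoff is neutral). ``rule='majority_length'``: gain/loss iff more than
    half the chromosome's binned length lies in segments beyond the cutoff.
    """
    if rule not in ("weighted_mean", "majority_length"):
        raise ValidationError(f"unknown calling rule {rule!r}")
    rows = []
    for chrom, grp in segments.groupby("chromosome", sort=False):
        w = grp["length"].to_numpy(dtype=float)
        m = grp["mean_value"].to_numpy(dtype=float)
        total = w.sum()
        if rule == "weighted_mean":
            summary = float((w * m).sum() / total)
            call = "gain" if summary > cutoff else (
                "loss" if summary < -cutoff else "neutral")
        else:
            gain_frac = w[m > cutoff].sum() / total
            loss_frac = w[m < -cutoff].sum() / total
            summary = float(gain_frac - loss_frac)
            call = "gain" if gain_frac > 0.5 else (
                "loss" if loss_frac > 0.5 else "neutral")
        rows.append((chrom, summary, call))
    return pd.DataFrame(rows, columns=["chromosome", "summary_value", "call"])


def cnv_load(segments: pd.DataFrame, cutoff: float = 0.1,
             autosomes_only: bool = True) -> float:
    """Fraction of the binned genome in segments with |mean| > cutoff."""
    segs = segments
    if autosomes_only:
        segs = segs[segs["chromosome"].isin(AUTOSOMES)]
    total = segs["length"].sum()
    if total == 0:
        raise ValidationError("zero total segment length")
    altered = segs.loc[segs["mean_value"].abs() > cutoff, "length"].sum()
    return float(altered / total)


def segment_cohort(profile: BinProfile, min_bins: int = 5,
                   penalty: float | None = None) -> dict[str, pd.DataFrame]:
    """Segment every sample of a bin profile; returns sample_id -> segments."""
    return {s: segment_profile(profile.bins, profile.sample_values(s),
                               min_bins=min_bins, penalty=penalty)
            for s in profile.sample_ids}


def call_cohort(segments_by_sample: Mapping[str, pd.DataFrame],
                cutoff: float = 0.1, rule: str = "weighted_mean",
                ) -> pd.DataFrame:
    """Chromosome calls for every sample, long format."""
    frames = []
    for sid, segs in segments_by_sample.items():
        calls = call_chromosomes(segs, cutoff=cutoff, rule=rule)
        calls.insert(0, "sample_id", sid)
        frames.append(calls)
    return pd.concat(frames, ignore_index=True)


def alteration_frequency_table(calls: pd.DataFrame,
                               labels: Mapping[str, str]) -> pd.DataFrame:
    """Per-(chromosome, alteration) counts and fractions by subtype.

    ``calls`` is the long table from :func:`call_cohort`; ``labels`` maps every
    sample id to its subtype. Fractions are count / subtype size; an
    ``overall`` column pools all samples.
    """
    missing = set(calls["sample_id"]) - set(labels)
    if missing:
        raise ValidationError(f"unlabeled samples: {sorted(missing)[:10]}")
    calls = calls.assign(subtype=calls["sample_id"].map(labels))
    group_sizes = (calls[["sample_id", "subtype"]].drop_duplicates()
                   .groupby("subtype").size())
    n_total = int(calls["sample_id"].nunique())
    subtypes = list(group_sizes.index)

    rows = []
    for (chrom, kind), grp in calls[calls["call"] != "neutral"].groupby(
            ["chromosome", "call"], sort=True):
        row: dict[str, object] = {"chromosome": chrom, "alteration": kind}
        for st in subtypes:
            cnt = int((grp["subtype"] == st).sum())
            row[f"count_{st}"] = cnt
            row[f"frac_{st}"] = cnt / int(group_sizes[st])
        row["count_overall"] = int(len(grp))
        row["frac_overall"] = len(grp) / n_total
        rows.append(row)
    if not rows:
        cols = ["chromosome", "alteration"]
        for st in subtypes:
            cols += [f"count_{st}", f"frac_{st}"]
        cols += ["count_overall", "frac_overall"]
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)


def compare_frequencies(a: int, n1: int, b: int, n2: int) -> float:
    """Two-sided Fisher exact p for alteration counts a/n1 vs b/n2."""
    for v in (a, n1, b, n2):
        if v < 0:
            raise ValidationError("counts must be non-negative")
    if a > n1 or b > n2:
        raise ValidationError("count exceeds group size")
    if n1 < 1 or n2 < 1:
        raise ValidationError("group sizes must be >= 1")
    table = np.array([[a, n1 - a], [b, n2 - b]])
    return float(fisher_exact(table, alternative="two-sided")[1])


def compare_cnv_load(loads: Mapping[str, float], labels: Mapping[str, str],
                     group_a: str, group_b: str) -> tuple[float, float, float]:
    """Rank-sum comparison of CNV load between two subtypes.

    Returns (mean load A, mean load B, two-sided rank-sum p).
    """
    xa = [v for s, v in loads.items() if labels[s] == group_a]
    xb = [v for s, v in loads.items() if labels[s] == group_b]
    if not xa or not xb:
        raise ValidationError("both groups must be non-empty")
    p = float(mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
    return float(np.mean(xa)), float(np.mean(xb)), p


def write_seg(segments_by_sample: Mapping[str, pd.DataFrame],
              path: str | Path) -> None:
    """Export segments in IGV ``.seg`` format (1-based inclusive coordinates)."""
    rows = []
    for sid, segs in segments_by_sample.items():
        for _, r in segs.iterrows():
            rows.append((sid, r["chromosome"], int(r["start"]) + 1,
                         int(r["end"]), int(r["n_bins"]),
                         float(r["mean_value"])))
    out = pd.DataFrame(rows, columns=["ID", "chrom", "loc.start", "loc.end",
                                      "num.mark", "seg.mean"])
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
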