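"""Synthetic PTPR-like cohort generator.

Emulates the statistical structure of a papillary-tumor-of-the-pineal-region
methylation cohort: three subtypes (PTPR-A, PTPR-B1, PTPR-B2) of sizes
20/24/31 that differ in

* global mean methylation (PTPR-A is globally hypomethylated by a small
  offset relative to B1/B2),
* planted differentially methylated probes (A vs B1/B2, and a separate,
  smaller-effect B1-vs-B2 signature),
* whole-chromosome copy-number events planted per subtype at configurable
  frequencies (defaults reproduce the reported per-subtype frequent
  alterations, e.g. chromosome 3 loss in 22/24 B1 tumors and 0/31 B2 tumors),
* subtype-specific progression-free-survival distributions (exponential,
  medians 178/63/29 months) under administrative uniform censoring.

Copy-number events and beta values are simulated independently: coupling
between copy number and measured methylation fraction is not modeled.
Beta noise is added on the logit scale and back-transformed, which preserves
the bimodal beta distribution without clipping artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit

from .errors import ConfigurationError
from .io import BetaMatrix
from .cnv import BinProfile

SUBTYPE_A = "PTPR-A"
SUBTYPE_B1 = "PTPR-B1"
SUBTYPE_B2 = "PTPR-B2"

#: Approximate autosome lengths (Mb), used to lay out probes and CNV bins.
CHROM_LENGTHS_MB: dict[str, float] = {
    "chr1": 249, "chr2": 243, "chr3": 198, "chr4": 191, "chr5": 181,
    "chr6": 171, "chr7": 159, "chr8": 146, "chr9": 141, "chr10": 136,
    "chr11": 135, "chr12": 134, "chr13": 115, "chr14": 107, "chr15": 103,
    "chr16": 90, "chr17": 81, "chr18": 78, "chr19": 59, "chr20": 63,
    "chr21": 48, "chr22": 51,
}


def default_cnv_freq() -> dict[tuple[str, str, str], float]:
    """Per-(subtype, chromosome, gain|loss) event frequencies.

    Frequent (>=30%) alterations per subtype, with the exactly reported
    fractions where available (chr3 loss 22/24 in B1, 7/24 chr14 loss in B1,
    zero in B2; 60% chr3/chr14 loss in A). Remaining frequencies are chosen so
    the cohort-wide expectations match the reported overall rates:
    chr3 loss 34/75 = 45.3%, chr10 loss 70/75 = 93.3%, chr8 gain 37/75 = 49.3%.
    """
    freq: dict[tuple[str, str, str], float] = {}
    for c in ("chr4", "chr5", "chr7", "chr11", "chr12", "chr15", "chr16",
              "chr17", "chr18", "chr20"):
        freq[(SUBTYPE_A, c, "gain")] = 0.40
    for c in ("chr1", "chr6", "chr9", "chr19", "chr22"):
        freq[(SUBTYPE_A, c, "loss")] = 0.40
    freq[(SUBTYPE_A, "chr3", "loss")] = 0.60      # 12/20
    freq[(SUBTYPE_A, "chr14", "loss")] = 0.60     # 12/20
    freq[(SUBTYPE_A, "chr10", "loss")] = 0.90     # 18/20
    freq[(SUBTYPE_A, "chr8", "gain")] = 0.25      # 5/20, below the >=30% lists

    freq[(SUBTYPE_B1, "chr8", "gain")] = 0.50     # 12/24
    freq[(SUBTYPE_B1, "chr3", "loss")] = 22 / 24
    freq[(SUBTYPE_B1, "chr10", "loss")] = 23 / 24
    freq[(SUBTYPE_B1, "chr14", "loss")] = 7 / 24

    freq[(SUBTYPE_B2, "chr8", "gain")] = 20 / 31
    freq[(SUBTYPE_B2, "chr9", "gain")] = 12 / 31
    freq[(SUBTYPE_B2, "chr12", "gain")] = 12 / 31
    freq[(SUBTYPE_B2, "chr10", "loss")] = 29 / 31
    return freq


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    All frequencies lie in [0, 1], counts are positive, and identical
    ``seed`` values yield byte-identical cohorts.
    """

    n_per_subtype: dict[str, int] = field(
        default_factory=lambda: {SUBTYPE_A: 20, SUBTYPE_B1: 24, SUBTYPE_B2: 31})
    global_mean_shift: float = -0.03       # beta offset of PTPR-A vs B1/B2
    n_dmp_probes: int = 200                # planted A-vs-B1/B2 probes
    dmp_delta: float = 0.3                 # planted beta difference
    n_dmp_b1b2: int = 300                  # planted B1-vs-B2 probes
    dmp_delta_b1b2: float = 0.25           # smaller B1-vs-B2 effect
    frac_hypo_in_a: float = 0.75           # share of A-vs-B DMPs hypo in A
    n_probes_total: int = 20_000
    n_genes: int = 500                     # promoters, 1-8 probes each
    cnv_freq: dict[tuple[str, str, str], float] = field(
        default_factory=default_cnv_freq)
    cnv_gain_shift: float = 0.25           # log2-ratio shift of a gain
    cnv_loss_shift: float = -0.30
    bin_size_mb: float = 2.5
    bin_noise_sd: float = 0.15             # per-bin Gaussian noise
    beta_noise_sd: float = 0.4             # logit-scale noise
    pfs_median: dict[str, float] = field(
        default_factory=lambda: {SUBTYPE_A: 178.0, SUBTYPE_B1: 63.0,
                                 SUBTYPE_B2: 29.0})
    os_median: dict[str, float] = field(
        default_factory=lambda: {SUBTYPE_A: 178.0, SUBTYPE_B1: 95.0,
                                 SUBTYPE_B2: 77.0})
    censor_rate: float = 0.5
    os_censor_rate: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        for st, n in self.n_per_subtype.items():
            if n <= 0:
                raise ConfigurationError(f"sample count for {st} must be > 0")
        for key, f in self.cnv_freq.items():
            if not (0.0 <= f <= 1.0):
                raise ConfigurationError(f"cnv_freq{key} = {f} outside [0, 1]")
            if key[0] not in self.n_per_subtype:
                raise ConfigurationError(
                    f"cnv_freq names subtype {key[0]!r} absent from "
                    f"n_per_subtype {sorted(self.n_per_subtype)}")
            if key[1] not in CHROM_LENGTHS_MB:
                raise ConfigurationError(f"unknown chromosome {key[1]!r}")
            if key[2] not in ("gain", "loss"):
                raise ConfigurationError(f"event kind must be gain|loss: {key}")
        for name, med in {**self.pfs_median, **self.os_median}.items():
            if med <= 0:
                raise ConfigurationError(f"median for {name} must be > 0")
        for rate in (self.censor_rate, self.os_censor_rate):
            if not (0.0 <= rate <= 1.0):
                raise ConfigurationError("censor rates must lie in [0, 1]")
        if self.n_dmp_probes + self.n_dmp_b1b2 > self.n_probes_total:
            raise ConfigurationError("more planted DMPs than probes")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cnv_freq" in raw:
            raw["cnv_freq"] = {
                (e["subtype"], e["chromosome"], e["kind"]): float(e["freq"])
                for e in raw["cnv_freq"]}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        raw["cnv_freq"] = [
            {"subtype": s, "chromosome": c, "kind": k, "freq": f}
            for (s, c, k), f in self.cnv_freq.items()]
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery tests."""

    true_labels: dict[str, str]                       # sample -> subtype
    planted_dmps: pd.DataFrame                        # probe_id, contrast, direction
    planted_events: set[tuple[str, str, str]]         # (sample, chrom, kind)
    true_survival_params: dict[str, float]            # subtype -> exp rate

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_labels": self.true_labels,
            "planted_dmps": self.planted_dmps.to_dict(orient="records"),
            "planted_events": sorted(self.planted_events),
            "true_survival_params": self.true_survival_params,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            true_labels=payload["true_labels"],
            planted_dmps=pd.DataFrame(payload["planted_dmps"]),
            planted_events={tuple(e) for e in payload["planted_events"]},
            true_survival_params=payload["true_survival_params"],
        )


def _censoring_horizon(median_months: float, censor_rate: float) -> float:
    """Uniform-censoring window length giving the requested censored fraction.

    Censoring times are Uniform(0, tau); for exponential event times with rate
    lam the expected censored fraction is (1 - exp(-lam*tau)) / (lam*tau),
    which decreases from 1 (tau -> 0) to 0 (tau -> inf). Solve for tau.
    """
    lam = np.log(2.0) / median_months

    def frac(tau: float) -> float:
        x = lam * tau
        return float(-np.expm1(-x) / x)

    lo, hi = 1e-9, 1e9
    return float(brentq(lambda t: frac(t) - censor_rate, lo, hi, xtol=1e-10,
                        rtol=1e-12))


def sample_survival(median_months: float, n: int, censor_rate: float,
                    seed: int | np.random.Generator | None = None,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Draw exponential event times with administrative uniform censoring.

    Event times are Exponential with rate ln2 / ``median_months``. Each sample
    carries an independent censoring time Uniform(0, tau) with tau calibrated
    so the expected censored fraction equals ``censor_rate`` (independent
    censoring, so Kaplan–Meier estimation is unbiased). Returns
    ``(times, event_flags)``; the flag is False for censored samples.
    """
    if median_months <= 0:
        raise ConfigurationError("median_months must be > 0")
    if not (0.0 <= censor_rate <= 1.0):
        raise ConfigurationError("censor_rate must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    lam = np.log(2.0) / median_months
    times = rng.exponential(scale=1.0 / lam, size=n)
    if censor_rate == 0.0:
        return times, np.ones(n, dtype=bool)
    if censor_rate == 1.0:
        return np.zeros(n), np.zeros(n, dtype=bool)
    tau = _censoring_horizon(median_months, censor_rate)
    censor_times = rng.uniform(0.0, tau, size=n)
    events = times <= censor_times
    observed = np.where(events, times, censor_times)
    return observed, events


def _allocate_counts(total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of `total` across weights."""
    raw = weights / weights.sum() * total
    counts = np.floor(raw).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    return counts


def _make_manifest(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    chroms = list(CHROM_LENGTHS_MB)
    lengths = np.array([CHROM_LENGTHS_MB[c] for c in chroms], dtype=float)
    counts = _allocate_counts(cfg.n_probes_total, lengths)
    chrom_col, pos_col = [], []
    for c, n_c, length in zip(chroms, counts, lengths):
        pos = np.sort(rng.integers(0, int(length * 1e6), size=n_c))
        chrom_col.extend([c] * n_c)
        pos_col.append(pos)
    probe_ids = [f"cg{i:08d}" for i in range(cfg.n_probes_total)]
    manifest = pd.DataFrame({
        "probe_id": probe_ids,
        "chromosome": chrom_col,
        "position": np.concatenate(pos_col),
        "promoter_gene": pd.array([pd.NA] * cfg.n_probes_total,
                                  dtype="string"),
    })
    # assign 1-8 probes to each of n_genes promoters, disjoint probe sets
    perm = rng.permutation(cfg.n_probes_total)
    sizes = rng.integers(1, 9, size=cfg.n_genes)
    cursor = 0
    genes = manifest["promoter_gene"].copy()
    for g, size in enumerate(sizes):
        idx = perm[cursor:cursor + size]
        genes.iloc[idx] = f"GENE{g:04d}"
        cursor += size
    manifest["promoter_gene"] = genes
    return manifest


def _make_bins(cfg: CohortConfig) -> pd.DataFrame:
    rows = []
    step = int(cfg.bin_size_mb * 1e6)
    for c, length_mb in CHROM_LENGTHS_MB.items():
        length = int(length_mb * 1e6)
        for start in range(0, length, step):
            rows.append((c, start, min(start + step, length)))
    return pd.DataFrame(rows, columns=["chromosome", "start", "end"])


def generate_cohort(config: CohortConfig,
                    ) -> tuple[BetaMatrix, pd.DataFrame, BinProfile,
                               pd.DataFrame, GroundTruth]:
    """Generate a full synthetic cohort.

    Returns ``(beta, manifest, bin_profile, sample_sheet, ground_truth)``.
    Beta values are clipped to [0.001, 0.999]; per-probe baseline means come
    from a bimodal (unmethylated ~0.2 / methylated ~0.8) logit-normal mixture;
    subtype-A samples receive ``global_mean_shift``; planted DMPs receive
    ±``dmp_delta`` in the designated subtype(s); bin profiles are planted
    whole-chromosome shifts plus Gaussian noise; survival times are
    exponential with rate ln2/median under uniform censoring.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    subtypes = list(config.n_per_subtype)
    sample_ids, labels = [], {}
    for st in subtypes:
        for i in range(config.n_per_subtype[st]):
            sid = f"{st.replace('PTPR-', '')}{i + 1:03d}"
            sample_ids.append(sid)
            labels[sid] = st
    n_samples = len(sample_ids)
    label_arr = np.array([labels[s] for s in sample_ids])
    is_a = label_arr == SUBTYPE_A
    is_b1 = label_arr == SUBTYPE_B1
    is_b2 = label_arr == SUBTYPE_B2

    manifest = _make_manifest(config, rng)
    probe_ids = manifest["probe_id"].to_numpy()

    # --- baseline methylation: bimodal logit-normal mixture ---
    high = rng.random(config.n_probes_total) < 0.5
    mu = np.where(high, logit(0.8), logit(0.2))
    baseline = expit(mu + rng.normal(0.0, 0.5, size=config.n_probes_total))

    # --- plant DMPs ---
    dmp_pool = rng.permutation(config.n_probes_total)
    idx_ab = dmp_pool[:config.n_dmp_probes]
    idx_b1b2 = dmp_pool[config.n_dmp_probes:
                        config.n_dmp_probes + config.n_dmp_b1b2]

    mean = np.tile(baseline[:, None], (1, n_samples))
    if config.global_mean_shift and SUBTYPE_A in subtypes:
        mean[:, is_a] += config.global_mean_shift

    dmp_rows = []
    hypo_in_a = rng.random(len(idx_ab)) < config.frac_hypo_in_a
    for j, p in enumerate(idx_ab):
        # direction is hypo/hyper of PTPR-A relative to B1/B2; the shift is
        # applied on whichever side keeps the mean inside (0, 1)
        if hypo_in_a[j]:
            if baseline[p] <= 0.5:
                mean[p, ~is_a] += config.dmp_delta
            else:
                mean[p, is_a] -= config.dmp_delta
            direction = "hypo"
        else:
            if baseline[p] <= 0.5:
                mean[p, is_a] += config.dmp_delta
            else:
                mean[p, ~is_a] -= config.dmp_delta
            direction = "hyper"
        dmp_rows.append((probe_ids[p], "A_vs_B", direction))

    up_in_b1 = rng.random(len(idx_b1b2)) < 0.5
    for j, p in enumerate(idx_b1b2):
        target = is_b1 if up_in_b1[j] else is_b2
        other = is_b2 if up_in_b1[j] else is_b1
        if baseline[p] <= 0.5:
            mean[p, target] += config.dmp_delta_b1b2
        else:
            mean[p, other] -= config.dmp_delta_b1b2
        dmp_rows.append((probe_ids[p], "B1_vs_B2",
                         "hyper" if up_in_b1[j] else "hypo"))
    planted_dmps = pd.DataFrame(dmp_rows,
                                columns=["probe_id", "contrast", "direction"])

    mean = np.clip(mean, 0.001, 0.999)
    if config.beta_noise_sd > 0:
        beta_vals = expit(logit(mean) + rng.normal(
            0.0, config.beta_noise_sd, size=mean.shape))
        beta_vals = np.clip(beta_vals, 0.001, 0.999)
    else:
        beta_vals = mean
    beta = BetaMatrix(
        pd.DataFrame(beta_vals, index=probe_ids, columns=sample_ids),
        platforms={s: ("EPIC" if rng.random() < 0.5 else "EPICv2")
                   for s in sample_ids},
        validate=False)

    # --- copy-number bin profiles: whole-chromosome planted events ---
    bins = _make_bins(config)
    shift_per_chrom = {c: np.zeros(n_samples) for c in CHROM_LENGTHS_MB}
    planted_events: set[tuple[str, str, str]] = set()
    for (st, chrom, kind), freq in sorted(config.cnv_freq.items()):
        members = np.nonzero(label_arr == st)[0]
        hit = members[rng.random(len(members)) < freq]
        amount = config.cnv_gain_shift if kind == "gain" else config.cnv_loss_shift
        shift_per_chrom[chrom][hit] += amount
        for s in hit:
            planted_events.add((sample_ids[s], chrom, kind))

    bin_vals = np.empty((len(bins), n_samples))
    for chrom, grp in bins.groupby("chromosome", sort=False):
        bin_vals[grp.index.to_numpy(), :] = shift_per_chrom[chrom][None, :]
    if config.bin_noise_sd > 0:
        bin_vals = bin_vals + rng.normal(0.0, config.bin_noise_sd,
                                         size=bin_vals.shape)
    profile = BinProfile(bins, pd.DataFrame(bin_vals, columns=sample_ids))

    # --- clinical outcomes ---
    pfs_t = np.empty(n_samples)
    pfs_e = np.empty(n_samples, dtype=bool)
    os_t = np.empty(n_samples)
    os_e = np.empty(n_samples, dtype=bool)
    for st in subtypes:
        mask = label_arr == st
        t, e = sample_survival(config.pfs_median[st], int(mask.sum()),
                               config.censor_rate, rng)
        pfs_t[mask], pfs_e[mask] = t, e
        t, e = sample_survival(config.os_median[st], int(mask.sum()),
                               config.os_censor_rate, rng)
        os_t[mask], os_e[mask] = t, e

    sample_sheet = pd.DataFrame({
        "sample_id": sample_ids,
        "platform": [beta.platforms[s] for s in sample_ids],
        "subtype_label": label_arr,
        "age": rng.integers(1, 64, size=n_samples),
        "sex": rng.choice(["F", "M"], size=n_samples),
        "pfs_months": np.round(pfs_t, 3),
        "pfs_event": pfs_e,
        "os_months": np.round(os_t, 3),
        "os_event": os_e,
        "excluded_flag": False,
    })

    truth = GroundTruth(
        true_labels=labels,
        planted_dmps=planted_dmps,
        planted_events=planted_events,
        true_survival_params={st: float(np.log(2.0) / config.pfs_median[st])
                              for st in subtypes},
    )
    return beta, manifest, profile, sample_sheet, truth


def write_cohort(outdir: str | Path, beta: BetaMatrix, manifest: pd.DataFrame,
                 profile: BinProfile, sample_sheet: pd.DataFrame,
                 truth: GroundTruth) -> None:
    """Write all cohort artifacts as delimited/JSON text files."""
    from . import io as _io
    from . import cnv as _cnv
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _io.write_beta_matrix(beta, outdir / "beta.tsv")
    _io.write_manifest(manifest, outdir / "manifest.tsv")
    _cnv.write_bin_profile(profile, outdir / "bins.tsv")
    _io.write_sample_sheet(sample_sheet, outdir / "samples.tsv")
    truth.to_json(outdir / "ground_truth.json")
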