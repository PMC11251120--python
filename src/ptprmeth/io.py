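"""Tabular I/O and cross-platform integration of methylation beta matrices.

Beta matrices are stored probes × samples with values in [0, 1] (methylation
fraction at a CpG probe). Different array platforms share a large common probe
set; integration intersects probe names and concatenates sample columns.

Coordinates in manifests and bin tables are 0-based half-open throughout the
package; conversion to 1-based inclusive happens only at ``.seg`` export
(see :mod:`ptprmeth.cnv`).
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import IntegrationError, ValidationError

logger = logging.getLogger(__name__)

VALID_CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX", "chrY")
AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))
SEX_CHROMOSOMES = ("chrX", "chrY")

MANIFEST_COLUMNS = ("probe_id", "chromosome", "position", "promoter_gene")
SAMPLE_SHEET_COLUMNS = (
    "sample_id", "platform", "subtype_label", "age", "sex",
    "pfs_months", "pfs_event", "os_months", "os_event", "excluded_flag",
)


class BetaMatrix:
    """A probes × samples matrix of methylation beta values.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with one column per sample. Values must
        lie in [0, 1]; NaN marks a missing measurement.
    platforms
        Optional mapping sample id → platform label.
    """

    def __init__(self, values: pd.DataFrame,
                 platforms: Mapping[str, str] | None = None,
                 validate: bool = True):
        if validate:
            _validate_beta_frame(values)
        self.values = values
        self.platforms = dict(platforms) if platforms is not None else None

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_probes(self, probes: Sequence[str]) -> "BetaMatrix":
        """Return a new matrix restricted to *probes* (kept in given order)."""
        return BetaMatrix(self.values.loc[list(probes)], self.platforms,
                          validate=False)

    def subset_samples(self, samples: Sequence[str]) -> "BetaMatrix":
        platforms = None
        if self.platforms is not None:
            platforms = {s: self.platforms[s] for s in samples
                         if s in self.platforms}
        return BetaMatrix(self.values[list(samples)], platforms, validate=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"BetaMatrix({self.n_probes} probes x {self.n_samples} samples)"


def _validate_beta_frame(values: pd.DataFrame) -> None:
    if values.index.has_duplicates:
        dups = values.index[values.index.duplicated()].unique().tolist()[:10]
        raise ValidationError(f"duplicate probe ids: {dups}")
    if values.columns.has_duplicates:
        dups = values.columns[values.columns.duplicated()].unique().tolist()[:10]
        raise ValidationError(f"duplicate sample ids: {dups}")
    arr = values.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (arr < 0.0) | (arr > 1.0)
    if bad.any():
        rows, cols = np.nonzero(bad)
        offenders = [
            (values.index[r], values.columns[c], float(arr[r, c]))
            for r, c in zip(rows[:10], cols[:10])
        ]
        raise ValidationError(
            f"beta values outside [0, 1] at {int(bad.sum())} cells; "
            f"first offenders (probe, sample, value): {offenders}"
        )


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_beta_matrix(path: str | Path,
                     platforms: Mapping[str, str] | None = None) -> BetaMatrix:
    """Read a delimited beta table (probes as rows, header row of sample ids)."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return BetaMatrix(df.astype(float), platforms=platforms)


def write_beta_matrix(matrix: BetaMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep=_sep_for(path), float_format="%.10g",
                         index_label="probe_id")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a probe manifest (probe_id, chromosome, position, promoter_gene)."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"probe_id": str})
    return validate_manifest(df)


def validate_manifest(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("probe_id", "chromosome", "position")
               if c not in df.columns]
    if missing:
        raise ValidationError(f"manifest missing columns: {missing}")
    if df["probe_id"].duplicated().any():
        raise ValidationError("manifest probe_id values are not unique")
    if (df["position"] < 0).any():
        raise ValidationError("manifest positions must be >= 0")
    bad_chrom = set(df["chromosome"]) - set(VALID_CHROMOSOMES)
    if bad_chrom:
        raise ValidationError(f"unknown chromosome labels: {sorted(bad_chrom)}")
    if "promoter_gene" not in df.columns:
        df = df.assign(promoter_gene=pd.NA)
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValidationError("sample sheet requires a 'sample_id' column")
    if df["sample_id"].duplicated().any():
        raise ValidationError("sample sheet sample_id values are not unique")
    for col in ("pfs_months", "os_months"):
        if col in df.columns and (df[col].dropna() < 0).any():
            raise ValidationError(f"negative times in column {col!r}")
    return df


def write_sample_sheet(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep=_sep_for(path), index=False)


def integrate_by_probe_name(matrices: Sequence[BetaMatrix]) -> BetaMatrix:
    """Merge beta matrices from different platforms by probe-name intersection.

    The retained probe set is the intersection of all inputs, in the probe
    order of the first matrix (determinism for downstream PCA); sample columns
    are concatenated in input order. Sample ids must be globally unique.
    """
    if len(matrices) == 0:
        raise ValidationError("integrate_by_probe_name requires >= 1 matrix")
    if len(matrices) == 1:
        return matrices[0]

    all_samples = pd.Index([])
    for m in matrices:
        overlap = all_samples.intersection(m.sample_ids)
        if len(overlap):
            raise ValidationError(
                f"sample ids appear in multiple inputs: {overlap[:10].tolist()}")
        all_samples = all_samples.append(m.sample_ids)

    common = matrices[0].probe_ids
    for m in matrices[1:]:
        common = common.intersection(m.probe_ids)
    if len(common) == 0:
        counts = [m.n_probes for m in matrices]
        raise IntegrationError(
            f"empty probe intersection across {len(matrices)} matrices "
            f"with probe counts {counts}")
    # preserve first input's probe order
    keep = matrices[0].probe_ids[matrices[0].probe_ids.isin(common)]

    merged = pd.concat([m.values.loc[keep] for m in matrices], axis=1)
    platforms: dict[str, str] = {}
    for m in matrices:
        if m.platforms:
            platforms.update(m.platforms)
    return BetaMatrix(merged, platforms=platforms or None, validate=False)


def mean_genomic_methylation(matrix: BetaMatrix) -> pd.Series:
    """Per-sample arithmetic mean beta over shared probes.

    Missing values are excluded pairwise; the number of excluded cells is
    logged. An empty matrix is an error.
    """
    if matrix.n_probes == 0 or matrix.n_samples == 0:
        raise ValidationError("cannot average an empty beta matrix")
    n_missing = int(matrix.values.isna().to_numpy().sum())
    if n_missing:
        logger.info("mean_genomic_methylation: excluding %d missing cells",
                    n_missing)
    return matrix.values.mean(axis=0, skipna=True).rename("mean_methylation")


def exclude_probes_by_chromosome(matrix: BetaMatrix, manifest: pd.DataFrame,
                                 chromosomes: Iterable[str],
                                 missing_probe_policy: str = "drop",
                                 ) -> BetaMatrix:
    """Drop probes mapping to the given chromosomes.

    Probes absent from the manifest are dropped with a warning
    (``missing_probe_policy='drop'``) or raise (``'error'``).
    """
    chromosomes = set(chromosomes)
    bad = chromosomes - set(VALID_CHROMOSOMES)
    if bad:
        raise ValidationError(f"invalid chromosome labels: {sorted(bad)}")
    chrom_of = manifest.set_index("probe_id")["chromosome"]
    known = matrix.probe_ids.isin(chrom_of.index)
    if not known.all():
        n_unknown = int((~known).sum())
        if missing_probe_policy == "error":
            raise ValidationError(
                f"{n_unknown} probes absent from manifest")
        warnings.warn(f"dropping {n_unknown} probes absent from manifest",
                      stacklevel=2)
    kept_ids = matrix.probe_ids[known]
    on_excluded = chrom_of.loc[kept_ids].isin(chromosomes).to_numpy()
    retained = kept_ids[~on_excluded]
    return matrix.subset_probes(retained)


def drop_incomplete_probes(matrix: BetaMatrix) -> BetaMatrix:
    """Complete-case filter: drop probes missing in any sample (count logged)."""
    complete = ~matrix.values.isna().any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropping %d probes with missing values", n_dropped)
    return BetaMatrix(matrix.values.loc[complete], matrix.platforms,
                      validate=False)
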