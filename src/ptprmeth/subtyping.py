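"""Methylation subtype discovery.

The chain is: select the most variable probes, run PCA on centered (unscaled)
beta values, keep the "non-trivial" principal components chosen by Horn-style
parallel analysis (eigenvalues of the observed data compared against a
permutation null built by shuffling every probe's values across samples),
embed with UMAP for visualization, and assign subtypes by Ward hierarchical
clustering of the selected PC scores.

Beta values share a common [0, 1] scale, so PCA is run unscaled by default:
scaling to unit variance would inflate near-constant probes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage

from .errors import ValidationError
from .io import BetaMatrix


@dataclass
class PCAResult:
    eigenvalues: np.ndarray          # descending, sample-covariance scale
    variance_fractions: np.ndarray   # sums to 1 (0 for a constant matrix)
    scores: pd.DataFrame             # samples x components

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


@dataclass
class ParallelAnalysisResult:
    n_selected: int
    observed_eigenvalues: np.ndarray
    null_quantiles: np.ndarray
    n_permutations: int
    quantile_level: float
    seed: int | None
    scheme: str = "per_probe"
    summary: str = "quantile"


@dataclass
class Embedding:
    coordinates: pd.DataFrame        # samples x (x, y)
    params: dict = field(default_factory=dict)


@dataclass
class ClusterLabels:
    labels: pd.Series                # sample_id -> cluster label (1..k)
    k: int
    linkage: str
    metric: str


def select_top_variable_probes(matrix: BetaMatrix, n: int = 10_000,
                               ) -> BetaMatrix:
    """Keep the *n* probes with the largest standard deviation across samples.

    Ties are broken by probe-id lexicographic order; the returned matrix
    preserves the input probe order.
    """
    if n > matrix.n_probes:
        raise ValidationError(
            f"requested {n} probes but matrix has {matrix.n_probes}")
    sds = matrix.values.std(axis=1, ddof=1).to_numpy()
    ids = matrix.probe_ids.to_numpy().astype(str)
    order = np.lexsort((ids, -sds))          # sd desc, then probe id asc
    keep = np.zeros(matrix.n_probes, dtype=bool)
    keep[order[:n]] = True
    return matrix.subset_probes(matrix.probe_ids[keep])


def _sample_matrix(matrix: BetaMatrix | np.ndarray | pd.DataFrame,
                   ) -> tuple[np.ndarray, pd.Index]:
    """Return (samples x features array, sample index) from a probes x samples
    beta matrix, or pass a samples x features array through."""
    if isinstance(matrix, BetaMatrix):
        return matrix.values.to_numpy(dtype=float).T, matrix.sample_ids
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float), matrix.index
    arr = np.asarray(matrix, dtype=float)
    return arr, pd.RangeIndex(arr.shape[0])


def _eigenvalues(x: np.ndarray) -> np.ndarray:
    """Descending eigenvalues of the sample covariance of x (samples x feats),
    via the Gram matrix so large probe counts stay cheap."""
    n = x.shape[0]
    xc = x - x.mean(axis=0, keepdims=True)
    gram = xc @ xc.T / (n - 1)
    ev = np.linalg.eigvalsh(gram)[::-1]
    return np.clip(ev, 0.0, None)


def run_pca(matrix: BetaMatrix | np.ndarray, center: bool = True,
            scale: bool = False) -> PCAResult:
    """PCA of samples over probes (centered, unscaled by default)."""
    x, sample_index = _sample_matrix(matrix)
    n, p = x.shape
    if n < 2:
        raise ValidationError("PCA requires at least 2 samples")
    if np.isnan(x).any():
        raise ValidationError("PCA input contains missing values")
    xw = x.copy()
    if center:
        xw -= xw.mean(axis=0, keepdims=True)
    if scale:
        sd = xw.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        xw /= sd
    u, s, _ = np.linalg.svd(xw, full_matrices=False)
    eigenvalues = s ** 2 / (n - 1)
    total = eigenvalues.sum()
    if total <= 0:
        warnings.warn("constant matrix: total variance is zero", stacklevel=2)
        fractions = np.zeros_like(eigenvalues)
    else:
        fractions = eigenvalues / total
    scores = u * s
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(eigenvalues=eigenvalues, variance_fractions=fractions,
                     scores=pd.DataFrame(scores, index=sample_index,
                                         columns=cols))


def parallel_analysis(matrix: BetaMatrix | np.ndarray,
                      n_permutations: int = 1_000,
                      quantile_level: float = 0.95,
                      seed: int | None = None,
                      scheme: str = "per_probe",
                      summary: str = "quantile") -> ParallelAnalysisResult:
    """Horn-style parallel analysis for the number of non-trivial PCs.

    Each of ``n_permutations`` permutations independently shuffles every
    probe's values across samples (``scheme='per_probe'``), destroying
    inter-probe correlation while preserving per-probe marginals
    (``scheme='full_matrix'`` shuffles all entries jointly instead). The null
    reference at each rank is the ``quantile_level`` quantile of the permuted
    eigenvalues (``summary='mean'`` uses the mean). The number of selected
    components is the largest m such that the observed eigenvalue exceeds the
    null at every rank r <= m (stop at the first failure).
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    if scheme not in ("per_probe", "full_matrix"):
        raise ValidationError(f"unknown permutation scheme {scheme!r}")
    if summary not in ("quantile", "mean"):
        raise ValidationError(f"unknown null summary {summary!r}")
    x, _ = _sample_matrix(matrix)
    observed = _eigenvalues(x)
    rng = np.random.default_rng(seed)

    probes = x.T                      # probes x samples, shuffle along samples
    null = np.empty((n_permutations, len(observed)))
    for i in range(n_permutations):
        if scheme == "per_probe":
            perm = rng.permuted(probes, axis=1)
        else:
            perm = rng.permutation(probes.ravel()).reshape(probes.shape)
        null[i] = _eigenvalues(perm.T)
    if summary == "quantile":
        null_ref = np.quantile(null, quantile_level, axis=0)
    else:
        null_ref = null.mean(axis=0)

    exceeds = observed > null_ref
    n_selected = int(np.argmin(exceeds)) if not exceeds.all() else len(exceeds)
    return ParallelAnalysisResult(
        n_selected=n_selected, observed_eigenvalues=observed,
        null_quantiles=null_ref, n_permutations=n_permutations,
        quantile_level=quantile_level, seed=seed, scheme=scheme,
        summary=summary)


def umap_embed(scores: pd.DataFrame, n_neighbors: int = 15,
               min_dist: float = 0.1, metric: str = "euclidean",
               seed: int | None = None) -> Embedding:
    """2-D UMAP of PC scores (rows = samples). Deterministic for a fixed seed."""
    if n_neighbors >= len(scores):
        raise ValidationError(
            f"n_neighbors={n_neighbors} must be < n samples={len(scores)}")
    import umap  # deferred: numba compilation is slow to import

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(n_neighbors=n_neighbors, min_dist=min_dist,
                            metric=metric, n_components=2, random_state=seed)
        coords = reducer.fit_transform(scores.to_numpy(dtype=float))
    frame = pd.DataFrame(coords, index=scores.index, columns=["x", "y"])
    return Embedding(coordinates=frame,
                     params={"n_neighbors": n_neighbors, "min_dist": min_dist,
                             "metric": metric, "seed": seed})


def cluster_assign(scores: pd.DataFrame, k: int = 3, linkage: str = "ward",
                   metric: str = "euclidean") -> ClusterLabels:
    """Agglomerative clustering of PC scores, tree cut at k clusters.

    Labels are renamed deterministically: 1 for the largest cluster, then by
    descending size, ties broken by the lexicographically smallest member
    sample id.
    """
    n = len(scores)
    if k > n:
        raise ValidationError(f"k={k} exceeds n samples={n}")
    if k == 1:
        raw = np.ones(n, dtype=int)
    else:
        z = scipy_linkage(scores.to_numpy(dtype=float), method=linkage,
                          metric=metric)
        raw = fcluster(z, t=k, criterion="maxclust")
    index = scores.index
    order = sorted(
        np.unique(raw),
        key=lambda c: (-(raw == c).sum(), str(min(index[raw == c]))))
    remap = {c: i + 1 for i, c in enumerate(order)}
    labels = pd.Series([remap[c] for c in raw], index=index, name="cluster")
    return ClusterLabels(labels=labels, k=k, linkage=linkage, metric=metric)
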