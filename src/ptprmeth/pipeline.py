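"""End-to-end subtyping pipeline orchestration.

Chains the pieces the way the analysis is meant to be run: optional probe
filters (sex chromosomes, user-requested chromosome exclusions, user-supplied
sample exclusion list), top-variable-probe selection, PCA, parallel analysis
to pick the non-trivial components, hierarchical clustering on the selected
scores, and (optionally) a UMAP embedding for visualization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .io import (BetaMatrix, SEX_CHROMOSOMES, drop_incomplete_probes,
                 exclude_probes_by_chromosome)
from .subtyping import (ClusterLabels, Embedding, ParallelAnalysisResult,
                        PCAResult, cluster_assign, parallel_analysis, run_pca,
                        select_top_variable_probes, umap_embed)


@dataclass
class SubtypingResult:
    pca: PCAResult
    parallel: ParallelAnalysisResult
    selected_scores: pd.DataFrame
    clusters: ClusterLabels
    embedding: Embedding | None = None
    n_probes_used: int = 0
    excluded_samples: list[str] = field(default_factory=list)

    @property
    def labels(self) -> pd.Series:
        return self.clusters.labels


def subtype_pipeline(beta: BetaMatrix, manifest: pd.DataFrame | None = None,
                     exclude_chromosomes: Sequence[str] = (),
                     drop_sex_chromosomes: bool = True,
                     exclude_samples: Sequence[str] = (),
                     n_top: int = 10_000, n_permutations: int = 1_000,
                     quantile_level: float = 0.95, k: int = 3,
                     seed: int | None = None,
                     compute_embedding: bool = False,
                     n_neighbors: int = 15, min_dist: float = 0.1,
                     ) -> SubtypingResult:
    """Run the full subtype-discovery chain on an integrated beta matrix.

    Ambiguous samples (the analysis supports a user-supplied exclusion list,
    applied before clustering) are removed first; chromosome filters need a
    manifest. When fewer than ``n_top`` probes survive filtering, all are used.
    """
    work = beta
    if exclude_samples:
        keep = [s for s in work.sample_ids if s not in set(exclude_samples)]
        work = work.subset_samples(keep)
    if manifest is not None:
        drop = list(exclude_chromosomes)
        if drop_sex_chromosomes:
            drop += [c for c in SEX_CHROMOSOMES if c not in drop]
        if drop:
            work = exclude_probes_by_chromosome(work, manifest, drop)
    work = drop_incomplete_probes(work)
    work = select_top_variable_probes(work, n=min(n_top, work.n_probes))

    pca = run_pca(work, center=True, scale=False)
    pa = parallel_analysis(work, n_permutations=n_permutations,
                           quantile_level=quantile_level, seed=seed)
    n_keep = max(pa.n_selected, 1)   # cluster on >= 1 component
    selected = pca.scores.iloc[:, :n_keep]
    clusters = cluster_assign(selected, k=k)
    embedding = None
    if compute_embedding:
        embedding = umap_embed(selected, n_neighbors=n_neighbors,
                               min_dist=min_dist, seed=seed)
    return SubtypingResult(pca=pca, parallel=pa, selected_scores=selected,
                           clusters=clusters, embedding=embedding,
                           n_probes_used=work.n_probes,
                           excluded_samples=list(exclude_samples))
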