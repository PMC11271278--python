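"""Multi-sample interaction-score matrix assembly and correlation clustering."""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from hapi.core import HapiCall
from hapi.io import header_comment

__all__ = [
    "interaction_score",
    "build_score_matrix",
    "spearman_cluster",
    "write_matrix",
]


def interaction_score(intensity: float, contact_value: float) -> float:
    """score = log10(interaction intensity) * enhancer contact value."""
    if intensity < 1:
        raise ValueError(f"interaction intensity must be >= 1, got {intensity}")
    return math.log10(intensity) * contact_value


def build_score_matrix(per_sample_calls: Mapping[str, Sequence[HapiCall]]) -> pd.DataFrame:
    """Genes x samples matrix of interaction scores.

    Rows are the union of genes called in at least one sample; an entry is
    the gene's score where it is called in that sample and 0 elsewhere
    (sub-threshold scores are not carried over — zero-fill is the stated
    convention for absent entries).
    """
    if len(per_sample_calls) < 2:
        raise ValueError("need >= 2 samples to build a score matrix")
    genes = sorted(
        {c.gene for calls in per_sample_calls.values() for c in calls if c.is_hapi}
    )
    samples = list(per_sample_calls)
    matrix = pd.DataFrame(0.0, index=genes, columns=samples)
    for sample, calls in per_sample_calls.items():
        for c in calls:
            if c.is_hapi and c.gene in matrix.index:
                matrix.loc[c.gene, sample] = interaction_score(c.intensity, c.contact_value)
    return matrix


def spearman_cluster(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Spearman correlation of samples plus an average-linkage ordering.

    Returns the symmetric, unit-diagonal correlation matrix (NaN against
    constant columns, whose rank correlation is undefined) and a sample
    ordering from hierarchical clustering on 1 - rho; samples with
    undefined correlations are placed last.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples to cluster")
    samples = list(matrix.columns)
    values = matrix.to_numpy(dtype=float)

    constant = [s for s, col in zip(samples, values.T) if np.all(col == col[0])]
    usable = [s for s in samples if s not in constant]

    corr = pd.DataFrame(np.nan, index=samples, columns=samples, dtype=float)
    np.fill_diagonal(corr.values, 1.0)
    for i, si in enumerate(samples):
        for j in range(i + 1, len(samples)):
            sj = samples[j]
            if si in constant or sj in constant:
                continue
            rho = spearmanr(values[:, i], values[:, j]).statistic
            corr.loc[si, sj] = corr.loc[sj, si] = rho

    if len(usable) >= 2:
        sub = corr.loc[usable, usable].to_numpy()
        dist = 1.0 - sub
        np.fill_diagonal(dist, 0.0)
        dist = np.clip(dist, 0.0, None)  # guard float jitter at rho=1
        link = hierarchy.linkage(squareform(dist, checks=False), method="average")
        order = [usable[i] for i in hierarchy.leaves_list(link)]
    else:
        order = list(usable)
    order.extend(sorted(constant))
    return corr, order


def write_matrix(matrix: pd.DataFrame, path: str | Path, **params) -> None:
    with open(path, "w") as fh:
        fh.write(header_comment(**params) + "\n")
        matrix.to_csv(fh, sep="\t", index_label="gene", na_rep="NA")
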