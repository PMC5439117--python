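"""Classical (Torgerson) multidimensional scaling of alteration profiles.

The alteration matrix codes mutations as binary indicators and broad
copy-number states as −1/0/+1 per region.  Distances default to
Euclidean; the embedding is the standard double-centered Gram matrix
eigendecomposition, deterministic up to the documented sign convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .cna import GAIN, LOSS, CnaCallSet

log = logging.getLogger(__name__)

#: default mutation genes and CNA regions for the alteration matrix
DEFAULT_MUTATION_GENES = ("IDH1", "IDH2", "TP53", "ATRX", "BRAF")
DEFAULT_CNA_REGIONS = (
    "1p", "1q", "19p", "19q", "chr4", "chr7", "9p", "chr10", "chr14", "chr20",
)


@dataclass
class AlterationMatrix:
    """Sample × feature matrix; mutations ∈ {0,1}, CNA states ∈ {−1,0,+1}."""

    samples: list[str]
    features: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.features)):
            raise ValueError("value matrix shape mismatch")
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicate feature names")
        allowed = np.isin(self.values, (-1.0, 0.0, 1.0))
        if not allowed.all():
            raise ValueError("alteration matrix values restricted to {-1, 0, +1}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.features)


@dataclass
class Embedding:
    """k-dimensional MDS coordinates with eigenvalues and burden weights."""

    samples: list[str]
    coordinates: np.ndarray  # (n, k)
    eigenvalues: np.ndarray  # (k,) non-increasing
    burden: np.ndarray | None = None

    table_columns: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.table_columns = [f"mds{i + 1}" for i in range(self.coordinates.shape[1])]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coordinates, columns=self.table_columns)
        df.insert(0, "sample_id", self.samples)
        if self.burden is not None:
            df["burden"] = self.burden
        return df


def build_alteration_matrix(
    mutations: pd.DataFrame,
    callsets: list[CnaCallSet],
    mutation_genes: tuple[str, ...] = DEFAULT_MUTATION_GENES,
    cna_regions: tuple[str, ...] = DEFAULT_CNA_REGIONS,
) -> AlterationMatrix:
    """One binary column per mutation gene, one ternary column per CNA region.

    Samples present in only one source get zeros for the other (warned).
    """
    features = [f"mut:{g}" for g in mutation_genes] + [f"cna:{r}" for r in cna_regions]
    if not features:
        raise ValueError("empty feature set")
    cs_by_sample = {cs.sample_id: cs for cs in callsets}
    mut_by_sample = mutations.groupby("sample_id")["gene"].agg(set).to_dict()
    samples = sorted(set(cs_by_sample) | set(mut_by_sample))
    only_cna = set(cs_by_sample) - set(mut_by_sample)
    only_mut = set(mut_by_sample) - set(cs_by_sample)
    if only_cna:
        log.warning("%d sample(s) lack mutation rows; mutation features set to 0", len(only_cna))
    if only_mut:
        log.warning("%d sample(s) lack CNA calls; CNA features set to 0", len(only_mut))

    values = np.zeros((len(samples), len(features)))
    for i, s in enumerate(samples):
        muts = mut_by_sample.get(s, set())
        for j, g in enumerate(mutation_genes):
            values[i, j] = 1.0 if g in muts else 0.0
        cs = cs_by_sample.get(s)
        if cs is not None:
            for j, r in enumerate(cna_regions):
                state = cs.region_states.get(r)
                values[i, len(mutation_genes) + j] = {GAIN: 1.0, LOSS: -1.0}.get(state, 0.0)
    return AlterationMatrix(samples=samples, features=features, values=values)


def pairwise_distance(matrix: AlterationMatrix, metric: str = "euclidean") -> np.ndarray:
    """Symmetric zero-diagonal distance matrix over samples.

    ``jaccard`` operates on the binarized (|value| > 0) profiles.
    """
    if len(matrix.samples) < 2:
        raise ValueError("need at least 2 samples for pairwise distances")
    if metric == "euclidean":
        return squareform(pdist(matrix.values, metric="euclidean"))
    if metric == "jaccard":
        return squareform(pdist(np.abs(matrix.values) > 0, metric="jaccard"))
    raise ValueError(f"unknown metric {metric!r}")


def classical_mds(dist: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Torgerson classical MDS of a distance matrix.

    Returns (coordinates (n, k), eigenvalues (k,) non-increasing).
    Axes with negative eigenvalues among the top k are zeroed with a
    warning.  Per-axis sign is fixed by making the largest-magnitude
    loading positive.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not (1 <= k <= n - 1):
        raise ValueError(f"k must be in [1, n-1]; got k={k}, n={n}")

    j_center = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j_center @ (dist**2) @ j_center
    b = (b + b.T) / 2.0  # enforce exact symmetry for eigh
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    top_vals = eigvals[:k].copy()
    coords = np.zeros((n, k))
    for i in range(k):
        if top_vals[i] > 0:
            coords[:, i] = eigvecs[:, i] * np.sqrt(top_vals[i])
        elif top_vals[i] < 0:
            warnings.warn(
                f"axis {i + 1}: negative eigenvalue {top_vals[i]:.3g}; coordinates zeroed",
                RuntimeWarning,
                stacklevel=2,
            )
    # deterministic sign: largest |loading| positive per axis
    for i in range(k):
        col = coords[:, i]
        if col.any():
            j = int(np.argmax(np.abs(col)))
            if col[j] < 0:
                coords[:, i] = -col
    return coords, top_vals


def embed_cohort(
    mutations: pd.DataFrame,
    callsets: list[CnaCallSet],
    k: int = 2,
    metric: str = "euclidean",
    mutation_genes: tuple[str, ...] = DEFAULT_MUTATION_GENES,
    cna_regions: tuple[str, ...] = DEFAULT_CNA_REGIONS,
    clusters: dict[str, str] | None = None,
) -> tuple[Embedding, pd.DataFrame]:
    """Alteration matrix → distances → classical MDS, with burden weights.

    Returns the :class:`Embedding` and its per-sample table (coordinates,
    burden, and cluster label when provided).
    """
    matrix = build_alteration_matrix(mutations, callsets, mutation_genes, cna_regions)
    dist = pairwise_distance(matrix, metric=metric)
    coords, eigvals = classical_mds(dist, k)
    burden_by_sample = {cs.sample_id: cs.alteration_burden for cs in callsets}
    burden = np.array([burden_by_sample.get(s, 0) for s in matrix.samples], dtype=float)
    emb = Embedding(samples=matrix.samples, coordinates=coords, eigenvalues=eigvals, burden=burden)
    table = emb.to_frame()
    if clusters is not None:
        table["cluster"] = [clusters.get(s, "") for s in matrix.samples]
    return emb, table
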