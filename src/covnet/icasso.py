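"""ICASSO-style stability analysis for stochastic ICA.

Infomax ICA is a stochastic algorithm: different random initial unmixing
matrices can yield slightly (or substantially) different components.  The
stability analysis repeats the ICA run R times from distinct random starts,
pools all R·k component estimates, clusters them by absolute Pearson
correlation (average linkage, cut at k clusters), and summarizes each
cluster by

* a **quality index** Iq = mean intra-cluster similarity − mean similarity
  of cluster members to non-members (close to 1 for a reliably re-estimated
  component), and
* a **centrotype**: the member with the largest summed similarity to its
  cluster, used as the representative component map.

A cluster may contain several estimates from the same run (this is not
forbidden, merely diagnostic of an unstable decomposition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .ica import WhitenedData, infomax_ica

__all__ = ["IcassoResult", "run_icasso", "component_similarity", "cluster_and_select"]


@dataclass
class IcassoResult:
    """All per-run estimates plus the clustering that stabilizes them."""

    run_sources: np.ndarray  # (R*k) × m stacked source estimates
    n_runs: int
    k: int
    similarity: np.ndarray  # (R*k) × (R*k), |Pearson r|
    clusters: list  # list of k index arrays into run_sources, by descending iq
    iq: np.ndarray  # per cluster, same order as ``clusters``
    centrotype_indices: np.ndarray  # per cluster, index into run_sources
    converged: list  # per run

    @property
    def centrotypes(self) -> np.ndarray:
        """The k representative components (cluster centrotypes), k × m."""
        return self.run_sources[self.centrotype_indices]

    def iq_per_centrotype(self) -> np.ndarray:
        return self.iq.copy()


def component_similarity(run_sources: np.ndarray) -> np.ndarray:
    """Absolute Pearson correlation between all component estimates.

    ``run_sources`` is the (R·k) × m stack of source estimates.  Sign is
    irrelevant for ICA components, hence the absolute value.  Zero-variance
    estimates get similarity 0 to everything (with a warning) and 1 on the
    diagonal.
    """
    S = np.asarray(run_sources, dtype=float)
    sd = S.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance component estimate(s)")
    Z = (S - S.mean(axis=1, keepdims=True))
    norm = np.where(degenerate, 1.0, sd * np.sqrt(S.shape[1]))
    Z = Z / norm[:, None]
    sim = np.abs(Z @ Z.T)
    sim[degenerate, :] = 0.0
    sim[:, degenerate] = 0.0
    np.fill_diagonal(sim, 1.0)
    return np.clip(sim, 0.0, 1.0)


def cluster_and_select(similarity: np.ndarray, k: int):
    """Average-linkage clustering of estimates; quality index and centrotypes.

    Clusters the dissimilarity ``1 − similarity`` with average linkage, cut
    at ``k`` clusters.  For each cluster, ``iq`` is the mean intra-cluster
    similarity over *distinct* member pairs (0 for singletons, by
    convention) minus the mean similarity of members to all non-members;
    the centrotype is the member maximizing summed intra-cluster similarity.
    Clusters are returned sorted by descending iq.
    """
    sim = np.asarray(similarity, dtype=float)
    n = sim.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of estimates ({n})")
    sym = 0.5 * (sim + sim.T)
    dist = 1.0 - sym
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    assign = fcluster(Z, t=k, criterion="maxclust")
    # fcluster can return fewer clusters for degenerate input; handle ids as-is
    ids = np.unique(assign)

    clusters, iqs, centros = [], [], []
    all_idx = np.arange(n)
    for cid in ids:
        members = all_idx[assign == cid]
        outside = all_idx[assign != cid]
        sub = sym[np.ix_(members, members)]
        if members.size > 1:
            intra = float((sub.sum() - np.trace(sub)) / (members.size * (members.size - 1)))
        else:
            intra = 0.0
        extra = float(sym[np.ix_(members, outside)].mean()) if outside.size else 0.0
        iq = intra - extra
        # centrotype: max summed similarity to own cluster
        centro = members[int(np.argmax(sub.sum(axis=1)))]
        clusters.append(members)
        iqs.append(iq)
        centros.append(centro)

    order = np.argsort(iqs)[::-1]
    clusters = [clusters[i] for i in order]
    iqs = np.array([iqs[i] for i in order])
    centros = np.array([centros[i] for i in order])
    return clusters, iqs, centros


def run_icasso(
    Xw: WhitenedData,
    k: int,
    n_runs: int = 20,
    seed: int = 0,
    max_steps: int = 512,
    tol: float = 1e-6,
) -> IcassoResult:
    """Repeat Infomax ``n_runs`` times and stabilize by similarity clustering.

    Every run starts from a distinct seeded random unmixing matrix on the
    same whitened data.  Non-converged runs are kept (and flagged): their
    estimates simply land in low-similarity clusters and depress iq.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    root = np.random.default_rng(seed)
    run_seeds = root.integers(0, 2**31 - 1, size=n_runs)
    sources, converged = [], []
    for r in range(n_runs):
        _, S, conv = infomax_ica(Xw, seed=int(run_seeds[r]),
                                 max_steps=max_steps, tol=tol)
        sources.append(S)
        converged.append(bool(conv))
    run_sources = np.vstack(sources)
    sim = component_similarity(run_sources)
    clusters, iqs, centros = cluster_and_select(sim, k)
    return IcassoResult(
        run_sources=run_sources, n_runs=n_runs, k=k, similarity=sim,
        clusters=clusters, iq=iqs, centrotype_indices=centros,
        converged=converged,
    )
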