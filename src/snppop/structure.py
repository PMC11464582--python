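"""Population structure: PCA, IBS neighbors, pairwise F_ST, Nei distances,
neighbor-joining trees, and kNN population networks.

PCA standardizes each variant's genotype column by centering at 2p and
scaling by sqrt(2p(1-p)) (missing entries imputed to the mean, i.e. zero
after centering) and eigendecomposes the sample covariance of the
standardized matrix.

Pairwise differentiation uses the Weir-Cockerham ratio-of-sums estimate per
population pair, its Slatkin linearization F_ST/(1-F_ST), the island-model
migrant number Nm = [(1/F_ST) - 1]/4, and a label-permutation p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset
from .diversity import per_marker_fst


@dataclass
class PCAResult:
    eigenvectors: np.ndarray  # (n_samples, k)
    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    sample_ids: list
    n_imputed: int


@dataclass
class PairwiseFstResult:
    populations: list
    fst: np.ndarray
    slatkin_linearized: np.ndarray
    nm: np.ndarray
    p_values: np.ndarray


@dataclass
class DistanceMatrixAndTree:
    labels: list
    nei_d: np.ndarray
    tree_newick: str | None = None


def standardize_genotypes(data: GenotypeDataset):
    """Center genotype codes at 2p and scale by sqrt(2p(1-p)).

    Missing calls become 0 after centering (mean imputation).  Returns
    ``(X, n_imputed)``; raises on monomorphic variants.
    """
    p = data.allele_b_freq()
    if np.any(np.isnan(p)) or np.any((p <= 0) | (p >= 1)):
        raise ValueError(
            "monomorphic or all-missing variants present; apply a MAF filter first"
        )
    G = data.calls.astype(float)
    miss = G == MISSING
    G[miss] = 0.0
    X = (G - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    X[miss] = 0.0
    return X, int(miss.sum())


def pca(data: GenotypeDataset, n_components: int = 10) -> PCAResult:
    """Sample-space PCA of the standardized genotype matrix."""
    X, n_imputed = standardize_genotypes(data)
    n = X.shape[0]
    n_components = min(n_components, n)
    cov = (X @ X.T) / X.shape[1]
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    pct = vals / vals.sum() if vals.sum() > 0 else np.zeros_like(vals)
    return PCAResult(
        eigenvectors=vecs[:, :n_components],
        eigenvalues=vals[:n_components],
        pct_variance=pct[:n_components],
        sample_ids=list(data.samples["sample_id"]),
        n_imputed=n_imputed,
    )


def pc_scores(result: PCAResult) -> np.ndarray:
    """Sample scores scaled by sqrt(eigenvalue) (PLINK-style eigenvec scaling)."""
    return result.eigenvectors * np.sqrt(result.eigenvalues)


def ibs_matrix(data: GenotypeDataset) -> np.ndarray:
    """Identity-by-state proportion per sample pair over complete variants.

    Entry (i, j) = mean of (2 - |g_i - g_j|)/2.  Raises when a pair shares no
    called variant.
    """
    n = data.n_samples
    called = (data.calls != MISSING).astype(np.float64)
    # decompose |gi - gj| via one-hot indicators of each genotype class
    onehot = [((data.calls == g) & (data.calls != MISSING)).astype(np.float64) for g in (0, 1, 2)]
    absdiff = np.zeros((n, n))
    for a in range(3):
        for b in range(3):
            if a == b:
                continue
            absdiff += abs(a - b) * (onehot[a] @ onehot[b].T)
    n_complete = called @ called.T
    if np.any(n_complete == 0):
        raise ValueError("a sample pair shares no called variants")
    return (2.0 * n_complete - absdiff) / (2.0 * n_complete)


def nearest_neighbors(ibs: np.ndarray, sample_ids, k: int = 5) -> pd.DataFrame:
    """k nearest neighbors per sample by IBS distance (1 - IBS).

    Ties broken by lexicographic sample ID.  Returns a long-format frame
    (sample_id, rank, neighbor_id, ibs_distance) sorted by ascending distance
    within sample.
    """
    n = len(sample_ids)
    if n < k + 1:
        raise ValueError("need at least k+1 samples")
    dist = 1.0 - ibs
    rows = []
    ids = [str(s) for s in sample_ids]
    for i in range(n):
        order = sorted((dist[i, j], ids[j], j) for j in range(n) if j != i)
        for rank, (d, nid, _) in enumerate(order[:k], start=1):
            rows.append({"sample_id": ids[i], "rank": rank, "neighbor_id": nid, "ibs_distance": d})
    return pd.DataFrame(rows)


def _pair_fst(data: GenotypeDataset, pop_a: str, pop_b: str) -> float:
    mask = data.population_mask(pop_a) | data.population_mask(pop_b)
    sub = data.take_samples(np.flatnonzero(mask))
    _, mean_fst = per_marker_fst(sub, [pop_a, pop_b])
    return mean_fst


def nm_from_fst(fst: float) -> float:
    """Island-model migrant number Nm = [(1/F_ST) - 1]/4; inf when F_ST <= 0."""
    if fst <= 0:
        return np.inf
    return ((1.0 / fst) - 1.0) / 4.0


def pairwise_fst(
    data: GenotypeDataset,
    populations: list[str] | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
) -> PairwiseFstResult:
    """Pairwise W&C F_ST with Slatkin linearization, Nm, and permutation p.

    The permutation null shuffles population labels within each pair of
    populations and recomputes the ratio-of-sums F_ST.
    """
    pops = populations or data.populations
    r = len(pops)
    fst = np.zeros((r, r))
    slatkin = np.zeros((r, r))
    nm = np.full((r, r), np.nan)
    pvals = np.full((r, r), np.nan)
    rng = np.random.default_rng(seed)
    for i in range(r):
        for j in range(i + 1, r):
            obs = _pair_fst(data, pops[i], pops[j])
            mask = data.population_mask(pops[i]) | data.population_mask(pops[j])
            sub = data.take_samples(np.flatnonzero(mask))
            labels = sub.samples["population"].to_numpy().copy()
            count = 0
            for _ in range(n_permutations):
                rng.shuffle(labels)
                sub.samples["population"] = labels
                perm = _pair_fst(sub, pops[i], pops[j])
                if not np.isnan(perm) and perm >= obs:
                    count += 1
            p = (count + 1) / (n_permutations + 1)
            fst[i, j] = fst[j, i] = obs
            if obs < 1:
                slatkin[i, j] = slatkin[j, i] = obs / (1.0 - obs)
            else:
                slatkin[i, j] = slatkin[j, i] = np.inf
            if obs <= 0:
                warnings.warn(
                    f"F_ST <= 0 for pair ({pops[i]}, {pops[j]}); Nm reported as inf",
                    stacklevel=2,
                )
            nm[i, j] = nm[j, i] = nm_from_fst(obs)
            pvals[i, j] = pvals[j, i] = p
    return PairwiseFstResult(
        populations=list(pops), fst=fst, slatkin_linearized=slatkin, nm=nm, p_values=pvals
    )


def nei_distance(
    data: GenotypeDataset,
    populations: list[str] | None = None,
    ceiling: float = 10.0,
) -> DistanceMatrixAndTree:
    """Nei (1972) standard genetic distance between populations.

    D = -ln(Jxy / sqrt(Jx * Jy)) with J the mean (over variants) sum of
    squared (or cross-multiplied) allele frequencies; both alleles of each
    biallelic variant contribute.  Infinite distances are capped at
    ``ceiling`` with a warning.
    """
    pops = populations or data.populations
    freqs = []
    for p in pops:
        sub = data.subset_population(p)
        freqs.append(sub.allele_b_freq())
    freqs = np.array(freqs)  # (r, m)
    r = len(pops)
    D = np.zeros((r, r))
    for i in range(r):
        for j in range(i + 1, r):
            ok = ~np.isnan(freqs[i]) & ~np.isnan(freqs[j])
            pi, pj = freqs[i, ok], freqs[j, ok]
            jx = float(np.mean(pi**2 + (1 - pi) ** 2))
            jy = float(np.mean(pj**2 + (1 - pj) ** 2))
            jxy = float(np.mean(pi * pj + (1 - pi) * (1 - pj)))
            if jxy <= 0:
                warnings.warn(
                    f"Jxy = 0 for pair ({pops[i]}, {pops[j]}); distance capped", stacklevel=2
                )
                d = ceiling
            else:
                d = min(-np.log(jxy / np.sqrt(jx * jy)), ceiling)
            D[i, j] = D[j, i] = max(d, 0.0)
    return DistanceMatrixAndTree(labels=list(pops), nei_d=D)


def nj_tree(distance: np.ndarray, labels: list[str]) -> str:
    """Saitou-Nei neighbor joining; returns an unrooted Newick string.

    Negative branch lengths are clamped to zero with the excess moved to the
    sister branch (the usual adjustment for NJ on noisy distances).
    """
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = np.asarray(distance, dtype=float).copy()
    if not np.allclose(D, D.T) or np.any(~np.isfinite(D)):
        raise ValueError("distance matrix must be symmetric and finite")
    nodes = [str(lab) for lab in labels]  # newick fragment per active node
    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        total = sub.sum(axis=1)
        q = (m - 2) * sub - total[:, None] - total[None, :]
        np.fill_diagonal(q, np.inf)
        a, b = np.unravel_index(np.argmin(q), q.shape)
        ia, ib = active[a], active[b]
        d_ab = sub[a, b]
        va = 0.5 * d_ab + (total[a] - total[b]) / (2.0 * (m - 2))
        vb = d_ab - va
        if va < 0:
            vb += -va  # transfer the negative excess to the sister branch
            va = 0.0
        if vb < 0:
            va += -vb
            vb = 0.0
        new = f"({nodes[ia]}:{va:.10g},{nodes[ib]}:{vb:.10g})"
        d_new = 0.5 * (D[ia, active] + D[ib, active] - d_ab)
        D = np.pad(D, ((0, 1), (0, 1)))
        for k_idx, k in enumerate(active):
            D[-1, k] = D[k, -1] = d_new[k_idx]
        D[-1, -1] = 0.0
        nodes.append(new)
        active = [k for k in active if k not in (ia, ib)] + [len(nodes) - 1]
    ia, ib = active
    v = max(D[ia, ib], 0.0)
    # unrooted: attach the last two nodes by the remaining distance
    if nodes[ib].startswith("("):
        inner = nodes[ib][1:-1]
        return f"({nodes[ia]}:{v:.10g},{inner});"
    return f"({nodes[ia]}:{v:.10g},{nodes[ib]}:0);"


def knn_network(distance: np.ndarray, labels: list[str], populations: list[str], k: int = 10):
    """Symmetrized k-nearest-neighbor graph over samples.

    Returns a networkx Graph with a ``population`` node attribute; connected
    components are available via ``networkx.connected_components``.
    """
    n = len(labels)
    if not 1 <= k < n:
        raise ValueError("require 1 <= k < n_samples")
    G = nx.Graph()
    for lab, pop in zip(labels, populations):
        G.add_node(lab, population=pop)
    for i in range(n):
        order = sorted((distance[i, j], str(labels[j]), j) for j in range(n) if j != i)
        for d, _, j in order[:k]:
            G.add_edge(labels[i], labels[j], weight=float(d))
    return G
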