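"""PCA-based selection outlier scan, F_ST flagging, and candidate windows.

Each variant's standardized genotype vector is regressed on the leading K
principal-component score vectors; the vector of per-PC z-scores gets a
robust Mahalanobis distance (median/MAD location-scale with comedian
off-diagonals), which after genomic-inflation rescaling is chi-squared with
K degrees of freedom under neutrality.  Benjamini-Hochberg controls the FDR.
Flagged markers are exported as +/-500 kb candidate windows in BED form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataset import GenotypeDataset
from .structure import pca, standardize_genotypes


@dataclass
class ScanResult:
    table: pd.DataFrame  # per-variant: chrom, pos, id, d2, p_value, q_value, flagged
    z: np.ndarray  # (m, K) regression z-scores
    lambda_gc: float
    K: int
    alpha: float


def _robust_covariance(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Median/MAD location-scale with comedian off-diagonal covariance.

    Deterministic and resistant to a small fraction of outlying variants;
    any residual scale bias is absorbed by the genomic-inflation factor.
    """
    med = np.median(z, axis=0)
    zc = z - med
    mad = np.median(np.abs(zc), axis=0) * 1.4826
    mad = np.where(mad <= 0, np.std(zc, axis=0) + 1e-12, mad)
    k = z.shape[1]
    cov = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            if i == j:
                cov[i, i] = mad[i] ** 2
            else:
                com = np.median(zc[:, i] * zc[:, j]) * 1.4826**2
                com = np.clip(com, -0.99 * mad[i] * mad[j], 0.99 * mad[i] * mad[j])
                cov[i, j] = cov[j, i] = com
    return med, cov


def pcadapt_scan(
    data: GenotypeDataset,
    K: int = 3,
    alpha: float = 0.05,
    scores: np.ndarray | None = None,
) -> ScanResult:
    """Outlier scan on PC-regression z-scores with BH correction.

    Parameters
    ----------
    data : GenotypeDataset
        MAF-filtered genotypes (dense; pruning not required).
    K : int
        Number of leading principal components capturing population structure.
    alpha : float
        BH false-discovery level for flagging.
    scores : optional (n_samples, >=K) array
        Externally computed PC scores (e.g. from a pruned dataset); defaults
        to PCA of ``data`` itself.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K >= data.n_samples:
        raise ValueError("K must be smaller than the number of samples")
    X, _ = standardize_genotypes(data)  # (n, m)
    n, m = X.shape
    if scores is None:
        scores = pca(data, n_components=K).eigenvectors
    U = np.asarray(scores, dtype=float)[:, :K]
    # orthonormalize so per-PC simple regressions are exact
    U, _ = np.linalg.qr(U)

    beta = U.T @ X  # (K, m)
    rss = np.maximum((X * X).sum(axis=0) - (beta * beta).sum(axis=0), 0.0)
    dof = n - K
    sigma = np.sqrt(rss / dof)
    keep = sigma > 0
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} zero-residual variants excluded", stacklevel=2)
    z = np.full((m, K), np.nan)
    z[keep] = (beta[:, keep] / sigma[keep]).T

    zk = z[keep]
    med, cov = _robust_covariance(zk)
    prec = np.linalg.inv(cov)
    d2 = np.full(m, np.nan)
    diff = zk - med
    d2[keep] = np.einsum("ij,jk,ik->i", diff, prec, diff)

    lam = float(np.nanmedian(d2) / stats.chi2.median(K))
    pvals = np.full(m, np.nan)
    pvals[keep] = stats.chi2.sf(d2[keep] / lam, df=K)

    qvals = np.full(m, np.nan)
    flags = np.zeros(m, dtype=bool)
    rej, q = multipletests(pvals[keep], alpha=alpha, method="fdr_bh")[:2]
    qvals[keep] = q
    flags[keep] = rej

    table = pd.DataFrame(
        {
            "chrom": data.variants["chrom"],
            "pos": data.variants["pos"],
            "id": data.variants["id"],
            "d2": d2,
            "p_value": pvals,
            "q_value": qvals,
            "flagged_pcadapt": flags,
        }
    )
    return ScanResult(table=table, z=z, lambda_gc=lam, K=K, alpha=alpha)


def fst_flags(per_marker: pd.DataFrame, threshold: float = 0.5) -> np.ndarray:
    """Strict-inequality flags on per-marker F_ST (> threshold)."""
    return (per_marker["fst"].to_numpy() > threshold) & ~np.isnan(per_marker["fst"].to_numpy())


def candidate_windows(
    variants: pd.DataFrame,
    flagged: np.ndarray,
    flank_bp: int = 500_000,
) -> pd.DataFrame:
    """Merged +/-flank windows around flagged markers, 0-based half-open BED.

    ``variants`` needs columns chrom, pos, id.  Overlapping windows on one
    chromosome are merged; anchor IDs are concatenated comma-separated.
    """
    sel = variants.loc[np.asarray(flagged, dtype=bool), ["chrom", "pos", "id"]]
    rows = []
    for chrom, group in sel.groupby("chrom", sort=False):
        group = group.sort_values("pos")
        cur = None
        for r in group.itertuples(index=False):
            start = max(0, int(r.pos) - flank_bp)
            end = int(r.pos) + flank_bp
            if cur is not None and start <= cur["end"]:
                cur["end"] = max(cur["end"], end)
                cur["anchors"].append(str(r.id))
            else:
                if cur is not None:
                    rows.append(cur)
                cur = {"chrom": str(chrom), "start": start, "end": end, "anchors": [str(r.id)]}
        if cur is not None:
            rows.append(cur)
    return pd.DataFrame(
        [
            {"chrom": r["chrom"], "start": r["start"], "end": r["end"], "anchors": ",".join(r["anchors"])}
            for r in rows
        ],
        columns=["chrom", "start", "end", "anchors"],
    )


def write_bed(windows: pd.DataFrame, dest) -> None:
    windows.to_csv(dest, sep="\t", header=False, index=False)
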