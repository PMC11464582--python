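"""Linkage disequilibrium and LD-based effective population size.

LD between two variants is the squared Pearson correlation of their {0,1,2}
genotype codes over pairwise-complete samples (the Rogers-Huff composite
measure; no phasing).  Physical distance maps to recombination distance at
1 cM per Mb, so a pair at distance d bp sits at c = d * 1e-8 Morgans.

The effective population size t = 1/(2c) generations ago is estimated from
the sample-size-adjusted mean r-squared of pairs around recombination
distance c:

    Ne(t) = (1 / (4 c)) * (1 / r2_adj - alpha),   r2_adj = mean r2 - 1/n

with alpha the mutation-correction constant (1 by default, 2.2 to allow for
mutation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset

MORGANS_PER_BP = 1e-8  # 1 Mb = 1 cM


class LDUndefinedError(ValueError):
    """r2 undefined (monomorphic after missingness or too few complete pairs)."""


def genotype_r2(gi: np.ndarray, gj: np.ndarray) -> float:
    """Squared Pearson correlation of two genotype-code vectors.

    Uses pairwise-complete samples; raises :class:`LDUndefinedError` when
    fewer than 3 complete pairs remain or either variant is monomorphic
    among them.
    """
    gi = np.asarray(gi, dtype=float)
    gj = np.asarray(gj, dtype=float)
    ok = (gi != MISSING) & (gj != MISSING)
    if ok.sum() < 3:
        raise LDUndefinedError("fewer than 3 pairwise-complete samples")
    x, y = gi[ok], gj[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise LDUndefinedError("variant monomorphic among complete pairs")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def pairwise_r2_matrix(calls: np.ndarray) -> np.ndarray:
    """All-pairs r2 for a (n_samples, m) genotype block, pairwise-complete.

    Entries are NaN where undefined.  Vectorised via masked cross-products so
    decay curves over tens of thousands of pairs stay fast.
    """
    G = np.asarray(calls, dtype=float).T  # (m, n)
    M = (G != MISSING).astype(float)
    G0 = np.where(G == MISSING, 0.0, G)
    n = M @ M.T
    s_i = G0 @ M.T  # sum of gi over complete pairs, per (i, j)
    s_j = M @ G0.T
    ss_i = (G0 * G0) @ M.T
    ss_j = M @ (G0 * G0).T
    s_ij = G0 @ G0.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = s_ij - s_i * s_j / n
        var_i = ss_i - s_i * s_i / n
        var_j = ss_j - s_j * s_j / n
        r2 = (cov * cov) / (var_i * var_j)
    r2[(n < 3) | ~np.isfinite(r2)] = np.nan
    return r2


@dataclass
class LDDecayCurve:
    population: str
    bins: pd.DataFrame  # columns: lo_bp, hi_bp, mean_r2, n_pairs
    mean_r2: float
    mean_distance_bp: float
    max_distance_r2_gt_03_bp: float  # largest distance with bin mean r2 > 0.3


@dataclass
class NeTrajectory:
    points: pd.DataFrame  # columns: t, ne, mean_c_morgans, mean_r2, r2_adj, n_pairs
    alpha: float
    sample_n: int


def ld_pairs(data: GenotypeDataset, max_distance_bp: int = 1_000_000) -> pd.DataFrame:
    """Enumerate all intra-chromosomal variant pairs within ``max_distance_bp``.

    Returns a frame with columns ``i, j, distance_bp, r2`` (undefined pairs
    excluded).
    """
    frames = []
    for chrom, idx in data.variants.groupby("chrom", sort=False).groups.items():
        idx = np.asarray(idx)
        pos = data.variants.loc[idx, "pos"].to_numpy()
        m = len(idx)
        if m < 2:
            continue
        r2 = pairwise_r2_matrix(data.calls[:, idx])
        ii, jj = np.triu_indices(m, k=1)
        dist = pos[jj] - pos[ii]
        keep = (dist > 0) & (dist <= max_distance_bp) & np.isfinite(r2[ii, jj])
        frames.append(
            pd.DataFrame(
                {
                    "i": idx[ii[keep]],
                    "j": idx[jj[keep]],
                    "distance_bp": dist[keep],
                    "r2": r2[ii[keep], jj[keep]],
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["i", "j", "distance_bp", "r2"])
    return pd.concat(frames, ignore_index=True)


def ld_decay(
    data: GenotypeDataset,
    max_distance_bp: int = 1_000_000,
    bin_width_bp: int = 50_000,
    population: str | None = None,
) -> LDDecayCurve:
    """Distance-binned LD decay curve up to ``max_distance_bp``."""
    sub = data.subset_population(population) if population else data
    pairs = ld_pairs(sub, max_distance_bp)
    edges = np.arange(0, max_distance_bp + bin_width_bp, bin_width_bp)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (pairs["distance_bp"] > lo) & (pairs["distance_bp"] <= hi)
        rows.append(
            {
                "lo_bp": lo,
                "hi_bp": hi,
                "mean_r2": float(pairs.loc[sel, "r2"].mean()) if sel.any() else np.nan,
                "n_pairs": int(sel.sum()),
            }
        )
    bins = pd.DataFrame(rows)
    above = bins[(bins["mean_r2"] > 0.3) & (bins["n_pairs"] > 0)]
    return LDDecayCurve(
        population=population or "ALL",
        bins=bins,
        mean_r2=float(pairs["r2"].mean()) if len(pairs) else np.nan,
        mean_distance_bp=float(pairs["distance_bp"].mean()) if len(pairs) else np.nan,
        max_distance_r2_gt_03_bp=float(above["hi_bp"].max()) if len(above) else 0.0,
    )


def ne_point(c_morgans: float, r2_adj: float, alpha: float = 1.0) -> float:
    """Closed-form Ne from adjusted mean r2 at recombination distance c."""
    if c_morgans <= 0:
        raise ValueError("recombination distance must be positive")
    if r2_adj <= 0:
        raise ValueError("adjusted r2 must be positive")
    return (1.0 / (4.0 * c_morgans)) * (1.0 / r2_adj - alpha)


def generation_for_c(c_morgans: float) -> float:
    """Past generation probed by recombination distance c: t = 1/(2c)."""
    return 1.0 / (2.0 * c_morgans)


def ne_from_ld(
    pairs: pd.DataFrame,
    generations=range(1, 51),
    alpha: float = 1.0,
    sample_n: int | None = None,
    bin_halfwidth_frac: float = 0.2,
) -> NeTrajectory:
    """Ne per past generation from an LD pair table.

    For each target generation t the pairs with c in a relative bin around
    c_t = 1/(2t) (half-width ``bin_halfwidth_frac`` * c_t) are averaged; the
    sample-size correction 1/n is subtracted before inverting the LD-drift
    relation.  Generations with empty bins or non-positive adjusted r2 are
    omitted.
    """
    if sample_n is None or sample_n <= 0:
        raise ValueError("sample_n (number of genotyped individuals) is required")
    c = pairs["distance_bp"].to_numpy() * MORGANS_PER_BP
    r2 = pairs["r2"].to_numpy()
    rows = []
    for t in generations:
        c_t = 1.0 / (2.0 * t)
        lo, hi = c_t * (1 - bin_halfwidth_frac), c_t * (1 + bin_halfwidth_frac)
        sel = (c >= lo) & (c <= hi)
        if not sel.any():
            continue
        mean_r2 = float(r2[sel].mean())
        r2_adj = mean_r2 - 1.0 / sample_n
        c_bin = float(c[sel].mean())
        if r2_adj <= 0:
            warnings.warn(f"t={t}: adjusted r2 <= 0, point dropped", stacklevel=2)
            continue
        rows.append(
            {
                "t": generation_for_c(c_bin),
                "t_target": t,
                "ne": ne_point(c_bin, r2_adj, alpha),
                "mean_c_morgans": c_bin,
                "mean_r2": mean_r2,
                "r2_adj": r2_adj,
                "n_pairs": int(sel.sum()),
            }
        )
    return NeTrajectory(points=pd.DataFrame(rows), alpha=alpha, sample_n=sample_n)
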