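"""Within- and among-population diversity statistics.

Per population: the MAF spectrum, observed/expected homozygosity with the
small-sample 2n/(2n-1) correction, the heterozygosity-ratio inbreeding
coefficient F_IS = 1 - (1 - Ho)/(1 - He), and the per-individual excess
homozygosity F_HOM = (O - E)/(L - E).

Among populations: the Weir & Cockerham (1984) per-marker theta with its
variance components a (among populations), b (among individuals within
populations) and c (within individuals), averaged as a ratio of sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset

MAF_BIN_EDGES = (0.0, 0.05, 0.1, 0.2, 0.5)
MAF_BIN_LABELS = ("fixed", "(0,0.05)", "[0.05,0.1)", "[0.1,0.2)", "[0.2,0.5]")


@dataclass
class DiversitySummary:
    population: str
    n_samples: int
    maf_mean: float
    maf_spectrum: dict
    ho: float | None = None
    he: float | None = None
    f_is: float | None = None
    f_hom_per_sample: np.ndarray | None = None


def maf_spectrum(data: GenotypeDataset, population: str | None = None) -> DiversitySummary:
    """MAF mean and binned spectrum: fixed, <0.05, <0.1, <0.2, rest.

    A variant is "fixed" when its MAF is exactly 0 over non-missing calls.
    """
    sub = data.subset_population(population) if population else data
    maf = sub.maf()
    maf = maf[~np.isnan(maf)]
    spectrum = {
        MAF_BIN_LABELS[0]: int((maf == 0).sum()),
        MAF_BIN_LABELS[1]: int(((maf > 0) & (maf < 0.05)).sum()),
        MAF_BIN_LABELS[2]: int(((maf >= 0.05) & (maf < 0.1)).sum()),
        MAF_BIN_LABELS[3]: int(((maf >= 0.1) & (maf < 0.2)).sum()),
        MAF_BIN_LABELS[4]: int((maf >= 0.2).sum()),
    }
    return DiversitySummary(
        population=population or "ALL",
        n_samples=sub.n_samples,
        maf_mean=float(maf.mean()) if len(maf) else np.nan,
        maf_spectrum=spectrum,
    )


def expected_homozygosity(calls: np.ndarray) -> np.ndarray:
    """Per-variant expected homozygosity 1 - 2p(1-p) * 2n/(2n-1).

    The 2n/(2n-1) factor is the unbiased correction to expected
    heterozygosity for n called diploid samples; NaN where n < 2.
    """
    called = calls != MISSING
    n = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, calls, 0).sum(axis=0) / (2.0 * n)
        het = 2.0 * p * (1.0 - p) * (2.0 * n / (2.0 * n - 1.0))
    he = 1.0 - het
    he[n < 2] = np.nan
    return he


def homozygosity_and_fis(data: GenotypeDataset, population: str | None = None) -> DiversitySummary:
    """Observed/expected homozygosity, F_IS, and per-sample F_HOM.

    F_HOM follows the standard excess-homozygosity form (O - E)/(L - E): O is
    the sample's observed homozygous count, E the HWE-expected homozygous
    count over its called variants (with the small-sample correction), L the
    called-variant count.
    """
    sub = data.subset_population(population) if population else data
    if sub.n_samples < 2:
        raise ValueError("expected homozygosity undefined for a single sample")
    called = sub.calls != MISSING
    hom = (sub.calls == 0) | (sub.calls == 2)
    ho = float(hom[called].sum() / called.sum())
    he_v = expected_homozygosity(sub.calls)
    defined = ~np.isnan(he_v)
    he = float(he_v[defined].mean())
    f_is = 1.0 - (1.0 - ho) / (1.0 - he) if he < 1 else 1.0

    E = np.where(called[:, defined], he_v[defined][None, :], 0.0).sum(axis=1)
    O = (hom & called)[:, defined].sum(axis=1).astype(float)
    L = called[:, defined].sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_hom = (O - E) / (L - E)

    spec = maf_spectrum(data, population)
    return DiversitySummary(
        population=population or "ALL",
        n_samples=sub.n_samples,
        maf_mean=spec.maf_mean,
        maf_spectrum=spec.maf_spectrum,
        ho=ho,
        he=he,
        f_is=f_is,
        f_hom_per_sample=f_hom,
    )


def weir_cockerham_components(data: GenotypeDataset, populations: list[str] | None = None):
    """Weir-Cockerham (1984) variance components per variant.

    Returns ``(a, b, c)`` arrays over variants, each NaN where fewer than two
    populations have at least two called samples or the variant is
    monomorphic across all populations.
    """
    pops = populations or data.populations
    masks = [data.population_mask(p) for p in pops]
    m = data.n_variants
    ni, pi, hi = [], [], []
    for mask in masks:
        calls = data.calls[mask]
        called = calls != MISSING
        n = called.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called, calls, 0).sum(axis=0) / (2.0 * n)
            h = ((calls == 1) & called).sum(axis=0) / n
        ni.append(n)
        pi.append(p)
        hi.append(h)
    ni = np.array(ni)  # (r, m)
    pi = np.array(pi)
    hi = np.array(hi)

    usable = (ni >= 2) & ~np.isnan(pi)
    r_eff = usable.sum(axis=0).astype(float)
    ni = np.where(usable, ni, 0.0)
    pi = np.where(usable, pi, 0.0)
    hi = np.where(usable, hi, 0.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        nsum = ni.sum(axis=0)
        nbar = nsum / r_eff
        nc = (nsum - (ni**2).sum(axis=0) / nsum) / (r_eff - 1.0)
        pbar = (ni * pi).sum(axis=0) / nsum
        s2 = (ni * (pi - pbar) ** 2).sum(axis=0) / ((r_eff - 1.0) * nbar)
        hbar = (ni * hi).sum(axis=0) / nsum

        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r_eff - 1.0) / r_eff * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - (r_eff - 1.0) / r_eff * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0

    # undefined: fewer than two usable populations, or monomorphic overall
    bad = (r_eff < 2) | ~np.isfinite(pbar) | (pbar <= 0) | (pbar >= 1)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def per_marker_fst(data: GenotypeDataset, populations: list[str] | None = None):
    """Per-marker Weir-Cockerham theta and the ratio-of-sums global mean.

    Returns ``(table, mean_fst)`` where table has columns chrom, pos, id,
    fst, a, b, c; variants with undefined theta are NaN and excluded from
    the mean.
    """
    a, b, c = weir_cockerham_components(data, populations)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = a / (a + b + c)
    table = pd.DataFrame(
        {
            "chrom": data.variants["chrom"],
            "pos": data.variants["pos"],
            "id": data.variants["id"],
            "fst": fst,
            "a": a,
            "b": b,
            "c": c,
        }
    )
    ok = ~np.isnan(a)
    denom = (a + b + c)[ok].sum()
    mean_fst = float(a[ok].sum() / denom) if ok.any() and denom != 0 else np.nan
    return table, mean_fst


def summary_table(data: GenotypeDataset) -> pd.DataFrame:
    """Per-population diversity table (one row per population)."""
    rows = []
    for pop in data.populations:
        s = homozygosity_and_fis(data, pop)
        rows.append(
            {
                "population": pop,
                "n_samples": s.n_samples,
                "maf_mean": s.maf_mean,
                "ho": s.ho,
                "he": s.he,
                "f_is": s.f_is,
                "f_hom_mean": float(np.nanmean(s.f_hom_per_sample)),
            }
        )
    return pd.DataFrame(rows)
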