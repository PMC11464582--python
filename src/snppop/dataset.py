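"""Core genotype container shared by every analysis stage.

A :class:`GenotypeDataset` holds a sample x variant matrix of diploid
biallelic genotype codes counting copies of the B allele (0, 1, 2), with
``-1`` marking a missing call.  Variants are kept sorted by (chromosome,
position) and carry the two observed allele characters; samples carry a
population label (family ID in PED terms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: columns of the ``variants`` table
VARIANT_COLUMNS = ["chrom", "id", "cm", "pos", "allele_a", "allele_b"]
SAMPLE_COLUMNS = ["sample_id", "population"]


class GenotypeDataError(ValueError):
    """Malformed genotype data (format, dimensions, or allele problems)."""


def _chrom_sort_key(chrom: pd.Series) -> pd.Series:
    """Numeric-aware chromosome ordering ('1' < '2' < ... < '10' < 'X')."""

    def key(c):
        s = str(c)
        return (0, int(s), "") if s.isdigit() else (1, 0, s)

    return chrom.map(key)


@dataclass
class GenotypeDataset:
    """Diploid biallelic genotypes for labelled samples.

    Parameters
    ----------
    samples : pandas.DataFrame
        Columns ``sample_id`` and ``population``; order defines matrix rows.
    variants : pandas.DataFrame
        Columns ``chrom, id, cm, pos, allele_a, allele_b``; order defines
        matrix columns and must be sorted by (chromosome, position).
    calls : numpy.ndarray
        ``int8`` array of shape (n_samples, n_variants) with values in
        {0, 1, 2, -1}; entries count copies of ``allele_b``.
    """

    samples: pd.DataFrame
    variants: pd.DataFrame
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.variants = self.variants.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise GenotypeDataError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise GenotypeDataError("genotype codes must be in {0, 1, 2, -1}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def populations(self) -> list[str]:
        return list(pd.unique(self.samples["population"]))

    def population_mask(self, population: str) -> np.ndarray:
        return (self.samples["population"] == population).to_numpy()

    # -- per-variant statistics -----------------------------------------
    def allele_b_freq(self) -> np.ndarray:
        """Frequency of the counted (B) allele per variant, over called genotypes.

        Returns NaN where no genotype is called.
        """
        called = self.calls != MISSING
        n = called.sum(axis=0)
        tot = np.where(called, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, tot / (2.0 * n), np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_b_freq()
        return np.minimum(p, 1.0 - p)

    def variant_call_rate(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=1)

    # -- subsetting ------------------------------------------------------
    def take_variants(self, index: np.ndarray) -> "GenotypeDataset":
        index = np.asarray(index)
        return GenotypeDataset(
            self.samples.copy(),
            self.variants.iloc[index].reset_index(drop=True),
            self.calls[:, index].copy(),
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeDataset":
        index = np.asarray(index)
        return GenotypeDataset(
            self.samples.iloc[index].reset_index(drop=True),
            self.variants.copy(),
            self.calls[index, :].copy(),
        )

    def subset_population(self, population: str) -> "GenotypeDataset":
        return self.take_samples(np.flatnonzero(self.population_mask(population)))

    def copy(self) -> "GenotypeDataset":
        return GenotypeDataset(self.samples.copy(), self.variants.copy(), self.calls.copy())

    def sort_variants(self) -> "GenotypeDataset":
        """Return a copy sorted by (chromosome, position)."""
        order = (
            self.variants.assign(_k=_chrom_sort_key(self.variants["chrom"]))
            .sort_values(["_k", "pos"], kind="mergesort")
            .index.to_numpy()
        )
        return self.take_variants(order)

    def canonicalized(self) -> "GenotypeDataset":
        """Copy recoded so the counted (B) allele is the minor allele.

        Ties at frequency 0.5 count the lexicographically later character;
        monomorphic variants get allele_b = "0".  This is the form the
        PED/MAP reader produces, so canonical datasets round-trip exactly.
        """
        out = self.copy()
        p = out.allele_b_freq()
        a = out.variants["allele_a"].to_numpy().copy()
        b = out.variants["allele_b"].to_numpy().copy()
        tie_swap = (p == 0.5) & (b < a)
        swap = (p > 0.5) | tie_swap
        cols = np.flatnonzero(swap)
        if len(cols):
            block = out.calls[:, cols]
            out.calls[:, cols] = np.where(block == MISSING, MISSING, 2 - block)
            a[cols], b[cols] = b[cols].copy(), a[cols].copy()
        p2 = np.where(swap, 1.0 - p, p)
        mono = p2 == 0.0
        b[mono] = "0"
        empty = np.isnan(p2)
        a[empty] = "0"
        b[empty] = "0"
        out.variants["allele_a"] = a
        out.variants["allele_b"] = b
        return out

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.samples[SAMPLE_COLUMNS].astype(str).equals(other.samples[SAMPLE_COLUMNS].astype(str))
            and self.variants[VARIANT_COLUMNS].astype(str).equals(
                other.variants[VARIANT_COLUMNS].astype(str)
            )
            and np.array_equal(self.calls, other.calls)
        )


def make_dataset(
    calls: np.ndarray,
    *,
    populations=None,
    chrom=None,
    pos=None,
    sample_ids=None,
    variant_ids=None,
    allele_a=None,
    allele_b=None,
) -> GenotypeDataset:
    """Convenience constructor filling in default metadata.

    Used pervasively by the simulators and tests: pass a (n_samples,
    n_variants) code matrix and only the metadata you care about.
    """
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(n)]
    if populations is None:
        populations = ["POP1"] * n
    if chrom is None:
        chrom = ["1"] * m
    if pos is None:
        # default spacing keeps positions unique per chromosome
        pos = np.zeros(m, dtype=int)
        counters: dict[str, int] = {}
        for j, c in enumerate(chrom):
            counters[c] = counters.get(c, 0) + 1
            pos[j] = counters[c] * 1000
    if variant_ids is None:
        variant_ids = [f"snp{j + 1}" for j in range(m)]
    samples = pd.DataFrame({"sample_id": sample_ids, "population": populations})
    variants = pd.DataFrame(
        {
            "chrom": [str(c) for c in chrom],
            "id": variant_ids,
            "cm": 0.0,
            "pos": np.asarray(pos, dtype=np.int64),
            "allele_a": allele_a if allele_a is not None else ["A"] * m,
            "allele_b": allele_b if allele_b is not None else ["G"] * m,
        }
    )
    return GenotypeDataset(samples, variants, calls)
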