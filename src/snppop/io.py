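"""PED/MAP text input/output and dataset merging.

PED rows are six pedigree fields followed by two allele characters per
variant; the family-ID column is used as the population label.  MAP rows are
``chrom  id  cM  bp``.  ``0`` or ``N`` denote a missing allele.  The counted
(B) allele is chosen per variant as the less frequent allele, ties broken to
the lexicographically later character, so that MAF = mean(calls)/2.

Merging resolves variants by (chromosome, position), flips strand where the
right dataset's alleles are the reverse-complement pair of the left's, and
drops palindromic (A/T, C/G) and irreconcilable variants.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataError, GenotypeDataset

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_MISSING_ALLELES = {"0", "N"}
#: default autosome whitelist: accept any purely numeric chromosome label
AUTOSOME_ANY_NUMERIC = "numeric"


class MergeError(ValueError):
    """Datasets cannot be merged (e.g. empty variant intersection)."""


@dataclass
class MergeReport:
    n_common_variants: int
    n_flipped: int
    n_dropped_incompatible: int
    concordance_on_control: float


class _maybe_open:
    """Context manager: open paths (gzip-transparent), pass streams through."""

    def __init__(self, source, mode: str = "rt"):
        self.source, self.mode = source, mode
        self.fh: IO[str] | None = None
        self.owned = False

    def __enter__(self) -> IO[str]:
        if hasattr(self.source, "read") or hasattr(self.source, "write"):
            self.fh = self.source
        else:
            path = Path(self.source)
            self.fh = gzip.open(path, self.mode) if path.suffix == ".gz" else open(path, self.mode)
            self.owned = True
        return self.fh

    def __exit__(self, *exc) -> None:
        if self.owned and self.fh is not None:
            self.fh.close()


def _open_text(source, mode: str = "rt") -> _maybe_open:
    return _maybe_open(source, mode)


def _is_autosome(chrom: str, whitelist) -> bool:
    if whitelist is None:
        return True
    if whitelist == AUTOSOME_ANY_NUMERIC:
        return chrom.isdigit() and int(chrom) > 0
    return chrom in set(map(str, whitelist))


def read_ped_map(ped_source, map_source, autosomes=AUTOSOME_ANY_NUMERIC) -> GenotypeDataset:
    """Read a PED/MAP pair into a :class:`GenotypeDataset`.

    Parameters
    ----------
    ped_source, map_source : path or text stream
        Plain or gzipped text.
    autosomes : None, "numeric", or iterable of labels
        Variants on chromosomes outside the whitelist (sex chromosomes,
        mitochondrial, unplaced) are excluded at read time.  ``None``
        disables the filter.
    """
    with _open_text(map_source) as fh:
        map_rows = []
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise GenotypeDataError(f"MAP line {lineno}: expected 4 fields, got {len(parts)}")
            map_rows.append((parts[0], parts[1], float(parts[2]), int(parts[3])))
    m_total = len(map_rows)
    keep = [j for j, row in enumerate(map_rows) if _is_autosome(row[0], autosomes)]
    m = len(keep)

    sample_rows = []
    allele_pairs = []  # list of (n, 2m) char arrays is wasteful; store per sample
    with _open_text(ped_source) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * m_total:
                raise GenotypeDataError(
                    f"PED line {lineno}: expected {6 + 2 * m_total} fields "
                    f"({m_total} variants), got {len(parts)}"
                )
            sample_rows.append((parts[1], parts[0]))  # (sample_id, family/population)
            alleles = np.array(parts[6:], dtype="U1").reshape(m_total, 2)
            allele_pairs.append(alleles[keep])

    n = len(sample_rows)
    a_mat = (
        np.stack(allele_pairs) if n else np.empty((0, m, 2), dtype="U1")
    )  # (n, m, 2)

    calls = np.full((n, m), MISSING, dtype=np.int8)
    allele_a = np.empty(m, dtype="U1")
    allele_b = np.empty(m, dtype="U1")
    for j in range(m):
        col = a_mat[:, j, :] if n else np.empty((0, 2), dtype="U1")
        flat = col.ravel()
        present = ~np.isin(flat, list(_MISSING_ALLELES))
        observed = flat[present]
        uniq, counts = np.unique(observed, return_counts=True)
        if len(uniq) > 2:
            vid = map_rows[keep[j]][1]
            raise GenotypeDataError(f"variant {vid}: {len(uniq)} alleles observed")
        if len(uniq) == 0:
            allele_a[j], allele_b[j] = "0", "0"
            continue
        if len(uniq) == 1:
            allele_a[j], allele_b[j] = uniq[0], "0"
        else:
            # B allele = minor; tie -> lexicographically later character
            if counts[0] < counts[1] or (counts[0] == counts[1] and uniq[0] > uniq[1]):
                b, a = uniq[0], uniq[1]
            else:
                b, a = uniq[1], uniq[0]
            allele_a[j], allele_b[j] = a, b
        both_called = present.reshape(n, 2).all(axis=1)
        g = (col == allele_b[j]).sum(axis=1).astype(np.int8)
        calls[both_called, j] = g[both_called]

    samples = pd.DataFrame(sample_rows, columns=["sample_id", "population"])
    kept_rows = [map_rows[j] for j in keep]
    variants = pd.DataFrame(kept_rows, columns=["chrom", "id", "cm", "pos"])
    variants["allele_a"] = allele_a
    variants["allele_b"] = allele_b
    data = GenotypeDataset(samples, variants, calls)
    return data.sort_variants()


def write_ped_map(data: GenotypeDataset, ped_dest, map_dest) -> None:
    """Write a dataset as a PED/MAP pair (inverse of :func:`read_ped_map`)."""
    with _open_text(map_dest, "wt") as fh:
        for row in data.variants.itertuples(index=False):
            fh.write(f"{row.chrom} {row.id} {row.cm:g} {row.pos}\n")
    with _open_text(ped_dest, "wt") as fh:
        for i, srow in enumerate(data.samples.itertuples(index=False)):
            fields = [str(srow.population), str(srow.sample_id), "0", "0", "0", "0"]
            for j, vrow in enumerate(data.variants.itertuples(index=False)):
                g = data.calls[i, j]
                a, b = vrow.allele_a, vrow.allele_b
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [a, a]
                elif g == 1:
                    fields += [a, b]
                else:
                    fields += [b, b]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def _is_palindromic(a: str, b: str) -> bool:
    return a in COMPLEMENT and COMPLEMENT[a] == b


def reconcile_alleles(left: tuple[str, str], right: tuple[str, str]):
    """Decide how the right variant's alleles map onto the left's.

    Returns ``(action, allele_a, allele_b, swap)``: action is ``"keep"``,
    ``"flip"`` (strand complement applied to the right) or ``"drop"``;
    ``allele_a``/``allele_b`` are the merged variant's alleles on the left
    strand; ``swap`` is True when the right genotype codes must be recoded
    g -> 2 - g so they count ``allele_b``.  Palindromic pairs (A/T, C/G) are
    dropped because strand cannot be inferred.
    """
    la, lb = left
    ra, rb = right
    lset = {x for x in (la, lb) if x not in _MISSING_ALLELES}
    if len(lset) == 2 and _is_palindromic(*sorted(lset)):
        return "drop", la, lb, False

    for action, fmap in (("keep", lambda x: x), ("flip", lambda x: COMPLEMENT.get(x, "?"))):
        rset = {fmap(x) for x in (ra, rb) if x not in _MISSING_ALLELES}
        if "?" in rset:
            continue
        if len(rset) == 2 and _is_palindromic(*sorted(rset)):
            return "drop", la, lb, False
        union = lset | rset
        if len(union) > 2:
            continue
        if len(union) == 2 and _is_palindromic(*sorted(union)):
            # only reachable when both sides are monomorphic for complementary
            # alleles: strand ambiguous, drop
            return "drop", la, lb, False
        # merged alleles on the left strand
        a = la if la not in _MISSING_ALLELES else (sorted(rset)[0] if rset else "0")
        others = sorted(union - {a})
        if lb not in _MISSING_ALLELES:
            b = lb
        else:
            b = others[0] if others else "0"
        # how the right codes relate to the merged counting allele b
        if rb not in _MISSING_ALLELES:
            swap = fmap(rb) != b
        else:
            # right monomorphic (all codes 0, homozygous for ra)
            swap = ra not in _MISSING_ALLELES and fmap(ra) == b and b != "0"
        return action, a, b, swap
    return "drop", la, lb, False


def merge_datasets(left: GenotypeDataset, right: GenotypeDataset):
    """Merge two datasets on shared (chromosome, position) variants.

    Strand-complementary allele pairs in ``right`` are flipped; palindromic
    and irreconcilable variants are dropped.  Samples whose IDs occur in both
    inputs act as merge controls: their genotype concordance is reported and
    the left copy is retained.

    Returns ``(merged, MergeReport)``.
    """
    lkey = list(zip(left.variants["chrom"], left.variants["pos"]))
    rkey = {k: j for j, k in enumerate(zip(right.variants["chrom"], right.variants["pos"]))}
    pairs = [(jl, rkey[k]) for jl, k in enumerate(lkey) if k in rkey]
    if not pairs:
        raise MergeError("datasets share no variants by (chromosome, position)")

    keep_l, keep_r, swaps, merged_ab = [], [], [], []
    n_flipped = 0
    n_dropped = 0
    for jl, jr in pairs:
        lrow = left.variants.iloc[jl]
        rrow = right.variants.iloc[jr]
        action, a, b, swap = reconcile_alleles(
            (lrow["allele_a"], lrow["allele_b"]), (rrow["allele_a"], rrow["allele_b"])
        )
        if action == "drop":
            n_dropped += 1
            continue
        if action == "flip":
            n_flipped += 1
        keep_l.append(jl)
        keep_r.append(jr)
        swaps.append(swap)
        merged_ab.append((a, b))

    if not keep_l:
        raise MergeError("no reconcilable shared variants after strand checks")

    lsub = left.take_variants(np.array(keep_l))
    lsub.variants["allele_a"] = [ab[0] for ab in merged_ab]
    lsub.variants["allele_b"] = [ab[1] for ab in merged_ab]
    rsub = right.take_variants(np.array(keep_r))
    rcalls = rsub.calls.copy()
    swaps = np.array(swaps, dtype=bool)
    if swaps.any():
        cols = np.flatnonzero(swaps)
        block = rcalls[:, cols]
        rcalls[:, cols] = np.where(block == MISSING, MISSING, 2 - block)

    dup_ids = set(lsub.samples["sample_id"]) & set(rsub.samples["sample_id"])
    if dup_ids:
        li = {s: i for i, s in enumerate(lsub.samples["sample_id"])}
        ri = {s: i for i, s in enumerate(rsub.samples["sample_id"])}
        agree = total = 0
        for s in sorted(dup_ids):
            gl = lsub.calls[li[s]]
            gr = rcalls[ri[s]]
            ok = (gl != MISSING) & (gr != MISSING)
            agree += int((gl[ok] == gr[ok]).sum())
            total += int(ok.sum())
        concordance = agree / total if total else 1.0
        keep_rows = ~rsub.samples["sample_id"].isin(dup_ids).to_numpy()
        rsamples = rsub.samples[keep_rows].reset_index(drop=True)
        rcalls = rcalls[keep_rows]
    else:
        concordance = 1.0
        rsamples = rsub.samples

    merged = GenotypeDataset(
        pd.concat([lsub.samples, rsamples], ignore_index=True),
        lsub.variants.copy(),
        np.vstack([lsub.calls, rcalls]),
    ).sort_variants()
    report = MergeReport(
        n_common_variants=len(pairs),
        n_flipped=n_flipped,
        n_dropped_incompatible=n_dropped,
        concordance_on_control=concordance,
    )
    return merged, report
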