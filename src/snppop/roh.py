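"""Runs of homozygosity, F_ROH, and the segment-length-to-generations map.

Detection follows the sliding-window scheme used by SNP-array tools: windows
of ``window_snps`` consecutive variants scan each sample/chromosome; a window
is homozygous when it contains at most ``max_het_in_window`` heterozygous and
``max_missing_in_window`` missing calls; a variant is ROH-eligible when the
fraction of overlapping windows that are homozygous reaches
``window_threshold``.  Maximal non-heterozygous runs that carry window
support (at least one eligible variant), split at inter-variant gaps above
``max_gap_kb``, become segments if they are long enough, dense enough and
contain enough variants; run endpoints are the first/last variant of the run.

F_ROH divides summed segment length by the autosomal genome length
(2,265,770 kb for the pig Sscrofa11.1 assembly) and decomposes it into the
1-4 / 4-8 / 8-12 / >12 Mb length classes (lower bound inclusive).  A segment
of length L Morgans reflects a common ancestor about g = 1/(2L) generations
back; with 1 Mb = 1 cM that is g = 100/(2 * L_Mb).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset

AUTOSOMAL_GENOME_KB = 2_265_770.0

LENGTH_CLASSES = (
    ("1-4Mb", 1_000.0, 4_000.0),
    ("4-8Mb", 4_000.0, 8_000.0),
    ("8-12Mb", 8_000.0, 12_000.0),
    (">12Mb", 12_000.0, np.inf),
)


@dataclass
class ROHConfig:
    window_snps: int = 50
    window_threshold: float = 0.05
    min_length_kb: float = 1_000.0
    min_snps: int = 20
    max_density_kb_per_snp: float = 150.0
    max_het_in_window: int = 0
    max_missing_in_window: int = 5
    max_gap_kb: float = 1_000.0

    def __post_init__(self) -> None:
        if not 0 < self.window_threshold <= 1:
            raise ValueError("window_threshold must lie in (0, 1]")
        for v in (self.window_snps, self.min_length_kb, self.min_snps, self.max_density_kb_per_snp):
            if v <= 0:
                raise ValueError("ROH parameters must be positive")


@dataclass
class ROHSegment:
    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp) / 1000.0


@dataclass
class FROHSummary:
    sample_id: str
    froh_total: float
    froh_by_class: dict
    genome_length_kb: float = AUTOSOMAL_GENOME_KB


def _eligible_fraction(het: np.ndarray, miss: np.ndarray, cfg: ROHConfig) -> np.ndarray:
    """Per-variant fraction of overlapping windows that are homozygous."""
    m = len(het)
    w = min(cfg.window_snps, m)
    n_windows = m - w + 1
    het_c = np.concatenate([[0], np.cumsum(het)])
    mis_c = np.concatenate([[0], np.cumsum(miss)])
    starts = np.arange(n_windows)
    ok = (
        (het_c[starts + w] - het_c[starts] <= cfg.max_het_in_window)
        & (mis_c[starts + w] - mis_c[starts] <= cfg.max_missing_in_window)
    ).astype(float)
    # each variant j is covered by windows starting in [j-w+1, j] clipped
    ok_c = np.concatenate([[0.0], np.cumsum(ok)])
    j = np.arange(m)
    lo = np.clip(j - w + 1, 0, n_windows - 1)
    hi = np.clip(j, 0, n_windows - 1)
    hits = ok_c[hi + 1] - ok_c[lo]
    return hits / (hi - lo + 1)


def _maximal_runs(good: np.ndarray, pos: np.ndarray, max_gap_kb: float):
    """Maximal runs of True entries, split at inter-variant gaps above the cap."""
    runs = []
    start = None
    for j in range(len(good)):
        if good[j]:
            if start is None:
                start = j
            elif pos[j] - pos[j - 1] > max_gap_kb * 1000:
                runs.append((start, j - 1))
                start = j
        elif start is not None:
            runs.append((start, j - 1))
            start = None
    if start is not None:
        runs.append((start, len(good) - 1))
    return runs


def detect_roh(data: GenotypeDataset, cfg: ROHConfig | None = None) -> list[ROHSegment]:
    """Call ROH segments for every sample (sliding-window scheme)."""
    cfg = cfg or ROHConfig()
    segments: list[ROHSegment] = []
    groups = list(data.variants.groupby("chrom", sort=False).groups.items())
    for i, srow in enumerate(data.samples.itertuples(index=False)):
        for chrom, idx in groups:
            idx = np.asarray(idx)
            calls = data.calls[i, idx]
            pos = data.variants.loc[idx, "pos"].to_numpy()
            het = calls == 1
            miss = calls == MISSING
            frac = _eligible_fraction(het.astype(int), miss.astype(int), cfg)
            eligible = frac >= cfg.window_threshold
            # candidate = maximal non-heterozygous run containing window support;
            # bounds come from the run so edges are not trimmed by window overlap
            for a, b in _maximal_runs(~het, pos, cfg.max_gap_kb):
                if not eligible[a : b + 1].any():
                    continue
                n_snps = b - a + 1
                length_kb = (pos[b] - pos[a]) / 1000.0
                if (
                    length_kb >= cfg.min_length_kb
                    and n_snps >= cfg.min_snps
                    and length_kb / n_snps <= cfg.max_density_kb_per_snp
                ):
                    segments.append(
                        ROHSegment(
                            sample_id=str(srow.sample_id),
                            chromosome=str(chrom),
                            start_bp=int(pos[a]),
                            end_bp=int(pos[b]),
                            n_snps=n_snps,
                        )
                    )
    return segments


def length_class(length_kb: float) -> str | None:
    """Length class of a segment (lower bound inclusive); None below 1 Mb."""
    for name, lo, hi in LENGTH_CLASSES:
        if lo <= length_kb < hi:
            return name
    return None


def froh(
    segments: list[ROHSegment],
    sample_ids,
    genome_length_kb: float = AUTOSOMAL_GENOME_KB,
) -> list[FROHSummary]:
    """Per-sample F_ROH totals and length-class decomposition."""
    by_sample: dict[str, list[ROHSegment]] = {str(s): [] for s in sample_ids}
    for seg in segments:
        by_sample.setdefault(seg.sample_id, []).append(seg)
    out = []
    for sid in map(str, sample_ids):
        per_class = {name: 0.0 for name, _, _ in LENGTH_CLASSES}
        for seg in by_sample[sid]:
            cls = length_class(seg.length_kb)
            if cls is not None:
                per_class[cls] += seg.length_kb / genome_length_kb
        out.append(
            FROHSummary(
                sample_id=sid,
                froh_total=sum(per_class.values()),
                froh_by_class=per_class,
                genome_length_kb=genome_length_kb,
            )
        )
    return out


def generations_from_length(length_mb: float) -> float:
    """Generations since the common ancestor implied by a segment length.

    Expected autozygous segment length for a g-generation-deep ancestor is
    1/(2g) Morgans; with 1 cM/Mb that inverts to g = 100/(2 * length_mb),
    e.g. 12 Mb segments point to the last ~4.17 generations.
    """
    if length_mb <= 0:
        raise ValueError("segment length must be positive")
    return 100.0 / (2.0 * length_mb)


def segments_table(segments: list[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "chrom": s.chromosome,
                "start_bp": s.start_bp,
                "end_bp": s.end_bp,
                "n_snps": s.n_snps,
                "length_kb": s.length_kb,
            }
            for s in segments
        ],
        columns=["sample_id", "chrom", "start_bp", "end_bp", "n_snps", "length_kb"],
    )


def froh_table(summaries: list[FROHSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"sample_id": s.sample_id, "froh_total": s.froh_total}
        row.update({f"froh_{k}": v for k, v in s.froh_by_class.items()})
        rows.append(row)
    return pd.DataFrame(rows)
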