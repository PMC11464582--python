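"""Quality control: call-rate filtering, MAF filtering, and windowed LD pruning.

The data-reduction path mirrors the usual SNP-array pipeline: variants with
call rate <= threshold are removed first, then samples are re-scored on the
surviving variants; MAF filtering is strict (> maf_min retained); pruning is
the greedy 50-SNP / 10-step / r2 > 0.2 windowed scheme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dataset import GenotypeDataset
from .ldne import pairwise_r2_matrix


class EmptyDatasetError(ValueError):
    """A filter removed every variant."""


@dataclass
class QCConfig:
    variant_call_rate_min: float = 0.95
    sample_call_rate_min: float = 0.95
    maf_min: float = 0.05
    prune_window_snps: int = 50
    prune_step_snps: int = 10
    prune_r2_max: float = 0.20

    def __post_init__(self) -> None:
        for f in (self.variant_call_rate_min, self.sample_call_rate_min, self.maf_min, self.prune_r2_max):
            if not 0 <= f <= 1:
                raise ValueError("QC fractions must lie in [0, 1]")
        if not self.prune_window_snps > self.prune_step_snps > 0:
            raise ValueError("require prune_window_snps > prune_step_snps > 0")


@dataclass
class QCReport:
    n_variants_in: int
    n_variants_out: int
    n_samples_in: int
    n_samples_out: int
    removed_variants: list = field(default_factory=list)
    removed_samples: list = field(default_factory=list)
    stage_order: list = field(default_factory=list)

    def to_tsv(self) -> str:
        lines = ["stage\tremoved\tids"]
        lines.append(f"variants\t{len(self.removed_variants)}\t{','.join(map(str, self.removed_variants))}")
        lines.append(f"samples\t{len(self.removed_samples)}\t{','.join(map(str, self.removed_samples))}")
        return "\n".join(lines) + "\n"


def filter_call_rate(data: GenotypeDataset, cfg: QCConfig | None = None):
    """Remove low-call-rate variants, then low-call-rate samples.

    Sample call rates are computed on the variants that survived stage one,
    so a sample dragged down by a bad variant is given the chance to pass.
    Thresholds are exclusive: call rate must exceed the minimum.
    """
    cfg = cfg or QCConfig()
    vkeep = data.variant_call_rate() > cfg.variant_call_rate_min
    if not vkeep.any():
        raise EmptyDatasetError("all variants fail the call-rate threshold")
    removed_variants = list(data.variants.loc[~vkeep, "id"])
    out = data.take_variants(np.flatnonzero(vkeep))

    skeep = out.sample_call_rate() > cfg.sample_call_rate_min
    removed_samples = list(out.samples.loc[~skeep, "sample_id"])
    out = out.take_samples(np.flatnonzero(skeep))

    report = QCReport(
        n_variants_in=data.n_variants,
        n_variants_out=out.n_variants,
        n_samples_in=data.n_samples,
        n_samples_out=out.n_samples,
        removed_variants=removed_variants,
        removed_samples=removed_samples,
        stage_order=["variants", "samples"],
    )
    return out, report


def filter_maf(data: GenotypeDataset, maf_min: float = 0.05):
    """Keep variants with MAF strictly above ``maf_min`` (over non-missing calls)."""
    maf = data.maf()
    keep = np.nan_to_num(maf, nan=0.0) > maf_min
    removed = list(data.variants.loc[~keep, "id"])
    out = data.take_variants(np.flatnonzero(keep))
    if out.n_variants == 0:
        warnings.warn("MAF filter removed every variant", stacklevel=2)
    report = QCReport(
        n_variants_in=data.n_variants,
        n_variants_out=out.n_variants,
        n_samples_in=data.n_samples,
        n_samples_out=out.n_samples,
        removed_variants=removed,
        stage_order=["maf"],
    )
    return out, report


def _prune_chromosome(calls: np.ndarray, maf: np.ndarray, pos: np.ndarray, cfg: QCConfig) -> np.ndarray:
    """Greedy windowed pruning on one chromosome; returns kept local indices."""
    m = calls.shape[1]
    alive = np.ones(m, dtype=bool)
    changed = True
    while changed:
        changed = False
        start = 0
        while True:
            live = np.flatnonzero(alive)
            if start >= len(live):
                break
            window = live[start : start + cfg.prune_window_snps]
            if len(window) >= 2:
                r2 = pairwise_r2_matrix(calls[:, window])
                # repeatedly drop the worse member of the worst offending pair
                w_alive = np.ones(len(window), dtype=bool)
                while True:
                    sub = np.where(
                        np.outer(w_alive, w_alive), np.nan_to_num(r2, nan=0.0), 0.0
                    )
                    np.fill_diagonal(sub, 0.0)
                    if sub.max() <= cfg.prune_r2_max:
                        break
                    a, b = np.unravel_index(np.argmax(sub), sub.shape)
                    # remove the lower-MAF member; tie -> later position
                    ga, gb = window[a], window[b]
                    if maf[ga] < maf[gb]:
                        victim = a
                    elif maf[gb] < maf[ga]:
                        victim = b
                    else:
                        victim = a if pos[ga] > pos[gb] else b
                    w_alive[victim] = False
                    alive[window[victim]] = False
                    changed = True
            if start + cfg.prune_window_snps >= len(live):
                break
            start += cfg.prune_step_snps
    return np.flatnonzero(alive)


def ld_prune(data: GenotypeDataset, cfg: QCConfig | None = None):
    """Windowed LD pruning: no surviving within-window pair with r2 above the cap.

    Windows of ``prune_window_snps`` consecutive surviving variants advance by
    ``prune_step_snps``; within a window the member of the worst offending
    pair with the lower MAF (tie: the later position) is removed; passes
    repeat until stable.  Output keeps the original variant order.
    """
    cfg = cfg or QCConfig()
    maf = np.nan_to_num(data.maf(), nan=0.0)
    pos = data.variants["pos"].to_numpy()
    keep_global = []
    for chrom, idx in data.variants.groupby("chrom", sort=False).groups.items():
        idx = np.asarray(idx)
        kept_local = _prune_chromosome(data.calls[:, idx], maf[idx], pos[idx], cfg)
        keep_global.extend(idx[kept_local])
    keep_global = np.sort(np.array(keep_global, dtype=int))
    removed_mask = np.ones(data.n_variants, dtype=bool)
    removed_mask[keep_global] = False
    removed = list(data.variants.loc[removed_mask, "id"])
    out = data.take_variants(keep_global)
    report = QCReport(
        n_variants_in=data.n_variants,
        n_variants_out=out.n_variants,
        n_samples_in=data.n_samples,
        n_samples_out=out.n_samples,
        removed_variants=removed,
        stage_order=["ld_prune"],
    )
    return out, report
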