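"""Synthetic genotype generators with known truth for every pipeline stage.

Three mechanisms cover the statistical structure SNP-array analyses assume:

* Balding-Nichols demes: deme allele frequencies drawn Beta around a shared
  ancestral frequency with a target F_ST, genotypes binomial — truth for
  differentiation, diversity, structure and outlier-scan tests.
* Forward Wright-Fisher simulation with recombination at 1 cM/Mb on standing
  variation — truth for LD-decay and LD-based Ne recovery and for realistic
  ROH background.
* Direct manipulation: implanted autozygous segments and binomially mixed
  admixed samples with a known Q matrix.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dataset import MISSING, GenotypeDataset, make_dataset


@dataclass
class SimulationConfig:
    n_populations: int = 2
    n_samples_per_pop: int = 50
    n_chromosomes: int = 1
    chromosome_length_bp: int = 100_000_000
    n_variants_per_chrom: int = 5000
    target_fst: float = 0.15
    ne_history: list = field(default_factory=lambda: [(0, 50)])
    recombination_cm_per_mb: float = 1.0
    outlier_variants: list = field(default_factory=list)  # (variant index, elevated fst)
    missing_rate: float = 0.0
    seed: int = 0


def _positions(rng, cfg) -> tuple[list, np.ndarray]:
    """Chromosome labels and sorted unique positions for the variant panel."""
    chrom, pos = [], []
    for c in range(cfg.n_chromosomes):
        p = np.sort(
            rng.choice(
                np.arange(1, cfg.chromosome_length_bp, 100), size=cfg.n_variants_per_chrom, replace=False
            )
        )
        chrom += [str(c + 1)] * cfg.n_variants_per_chrom
        pos.append(p)
    return chrom, np.concatenate(pos)


def _apply_missingness(calls: np.ndarray, rate: float, rng) -> np.ndarray:
    if rate > 0:
        mask = rng.random(calls.shape) < rate
        calls = np.where(mask, MISSING, calls)
    return calls.astype(np.int8)


def simulate_balding_nichols(cfg: SimulationConfig):
    """Balding-Nichols deme genotypes with optional elevated-F_ST outliers.

    Returns ``(dataset, truth)``; truth holds ancestral and deme frequencies
    and the outlier variant indexes.
    """
    if not 0 <= cfg.target_fst < 1:
        raise ValueError("target_fst must lie in [0, 1)")
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_chromosomes * cfg.n_variants_per_chrom
    p_anc = rng.uniform(0.05, 0.95, size=m)
    fst_per_variant = np.full(m, cfg.target_fst)
    for idx, f in cfg.outlier_variants:
        fst_per_variant[idx] = f

    outlier_set = {idx for idx, _ in cfg.outlier_variants}
    deme_freq = np.empty((cfg.n_populations, m))
    for j in range(m):
        F = fst_per_variant[j]
        if F == 0:
            deme_freq[:, j] = p_anc[j]
            continue
        a = p_anc[j] * (1 - F) / F
        b = (1 - p_anc[j]) * (1 - F) / F
        draw = rng.beta(a, b, size=cfg.n_populations)
        if j in outlier_set:
            # an implanted outlier must realize its elevated differentiation:
            # redraw until the among-deme frequency variance reaches the
            # requested level (and the variant segregates in the panel)
            for _ in range(500):
                pbar = draw.mean()
                denom = pbar * (1 - pbar)
                if denom > 0 and draw.var() / denom >= F:
                    break
                draw = rng.beta(a, b, size=cfg.n_populations)
        deme_freq[:, j] = draw

    n = cfg.n_populations * cfg.n_samples_per_pop
    calls = np.empty((n, m), dtype=np.int64)
    pops = []
    for k in range(cfg.n_populations):
        rows = slice(k * cfg.n_samples_per_pop, (k + 1) * cfg.n_samples_per_pop)
        calls[rows] = rng.binomial(2, deme_freq[k], size=(cfg.n_samples_per_pop, m))
        pops += [f"POP{k + 1}"] * cfg.n_samples_per_pop
    calls = _apply_missingness(calls, cfg.missing_rate, rng)

    chrom, pos = _positions(rng, cfg)
    data = make_dataset(calls, populations=pops, chrom=chrom, pos=pos).canonicalized()
    truth = {
        "ancestral_freq": p_anc,
        "deme_freq": deme_freq,
        "outlier_variants": list(cfg.outlier_variants),
        "target_fst": cfg.target_fst,
    }
    return data, truth


# ---------------------------------------------------------------------------
# forward Wright-Fisher with recombination
# ---------------------------------------------------------------------------

def _recombine(haps: np.ndarray, parents: np.ndarray, cm_pos: np.ndarray, rng) -> np.ndarray:
    """Produce one gamete per parent by Poisson-crossover recombination.

    ``haps``: (n_individuals, 2, m) haplotypes for one chromosome;
    ``cm_pos``: variant positions in Morgans; ``parents``: index per gamete.
    """
    n_gam = len(parents)
    m = haps.shape[2]
    length_m = cm_pos[-1] - cm_pos[0] if m > 1 else 0.0
    start = rng.integers(0, 2, size=n_gam)
    n_cross = rng.poisson(length_m, size=n_gam)
    gametes = haps[parents, start, :].copy()
    for g in np.flatnonzero(n_cross > 0):
        cuts = np.sort(rng.uniform(cm_pos[0], cm_pos[-1], size=n_cross[g]))
        phase = (start[g] + np.searchsorted(cuts, cm_pos, side="right")) % 2
        gametes[g] = haps[parents[g], phase, np.arange(m)]
    return gametes


def simulate_wright_fisher(cfg: SimulationConfig):
    """Forward diploid Wright-Fisher simulation on standing variation.

    ``ne_history`` is a list of (generation, N) change points: the population
    has size N from that generation (0 = start) until the next change point.
    No new mutation; initial haplotype alleles are independent Bernoulli
    draws at Uniform(0.1, 0.9) frequencies (linkage equilibrium), and LD then
    accrues by drift against recombination at ``recombination_cm_per_mb``.
    The final generation is sampled (``n_samples_per_pop`` individuals).

    Returns ``(dataset, truth)`` with the realized size per generation.
    """
    if not cfg.ne_history:
        raise ValueError("ne_history must be non-empty")
    for _, N in cfg.ne_history:
        if N < 2:
            raise ValueError("population size must be at least 2")
    rng = np.random.default_rng(cfg.seed)
    history = sorted(cfg.ne_history)
    total_gens = max(g for g, _ in history) if len(history) > 1 else history[0][0]
    # size per generation: step function over change points
    def size_at(gen: int) -> int:
        N = history[0][1]
        for g0, n0 in history:
            if gen >= g0:
                N = n0
        return N

    n_gens = max(total_gens, 1)
    m_per = cfg.n_variants_per_chrom
    morgans_per_bp = cfg.recombination_cm_per_mb * 1e-8
    chrom_labels, pos_all = _positions(rng, cfg)
    pos_per_chrom = pos_all.reshape(cfg.n_chromosomes, m_per)

    N0 = size_at(0)
    chroms = []
    for c in range(cfg.n_chromosomes):
        p0 = rng.uniform(0.1, 0.9, size=m_per)
        chroms.append((rng.random((N0, 2, m_per)) < p0).astype(np.int8))

    for gen in range(1, n_gens + 1):
        N_next = size_at(gen)
        mothers = rng.integers(0, chroms[0].shape[0], size=N_next)
        fathers = rng.integers(0, chroms[0].shape[0], size=N_next)
        new_chroms = []
        for c in range(cfg.n_chromosomes):
            cm_pos = pos_per_chrom[c] * morgans_per_bp
            egg = _recombine(chroms[c], mothers, cm_pos, rng)
            sperm = _recombine(chroms[c], fathers, cm_pos, rng)
            new_chroms.append(np.stack([egg, sperm], axis=1))
        chroms = new_chroms

    N_final = chroms[0].shape[0]
    n_sample = min(cfg.n_samples_per_pop, N_final)
    take = rng.choice(N_final, size=n_sample, replace=False)
    calls = np.concatenate([c[take].sum(axis=1) for c in chroms], axis=1)
    calls = _apply_missingness(calls.astype(np.int64), cfg.missing_rate, rng)
    data = make_dataset(
        calls, populations=["WF"] * n_sample, chrom=chrom_labels, pos=pos_all
    ).canonicalized()
    truth = {"size_per_generation": [size_at(g) for g in range(n_gens + 1)], "n_generations": n_gens}
    return data, truth


def implant_roh(data: GenotypeDataset, implants, seed: int = 0):
    """Force homozygosity inside given intervals for given samples.

    ``implants``: iterable of (sample_id, chrom, start_bp, length_bp).
    Heterozygotes collapse to a random homozygote (seeded); missing calls are
    left missing.  Overlapping implants for one sample are merged with a
    warning.  Returns ``(dataset, truth)`` where truth lists the realized
    intervals.
    """
    rng = np.random.default_rng(seed)
    out = data.copy()
    sid_index = {str(s): i for i, s in enumerate(data.samples["sample_id"])}
    merged: dict[tuple, list] = {}
    for sid, chrom, start, length in implants:
        key = (str(sid), str(chrom))
        merged.setdefault(key, []).append((int(start), int(start) + int(length)))
    truth = []
    for (sid, chrom), intervals in merged.items():
        intervals.sort()
        clean = [list(intervals[0])]
        for s, e in intervals[1:]:
            if s <= clean[-1][1]:
                warnings.warn(f"overlapping implants merged for sample {sid}", stacklevel=2)
                clean[-1][1] = max(clean[-1][1], e)
            else:
                clean.append([s, e])
        i = sid_index[sid]
        on_chrom = (out.variants["chrom"] == chrom).to_numpy()
        pos = out.variants["pos"].to_numpy()
        for s, e in clean:
            sel = on_chrom & (pos >= s) & (pos <= e)
            g = out.calls[i, sel]
            hets = g == 1
            g[hets] = rng.choice([0, 2], size=int(hets.sum())).astype(np.int8)
            out.calls[i, sel] = g
            truth.append({"sample_id": sid, "chrom": chrom, "start_bp": s, "end_bp": e})
    return out, truth


def mix_admixture(deme_freq: np.ndarray, q_truth: np.ndarray, template: GenotypeDataset, seed: int = 0):
    """Admixed samples from source deme frequencies and a truth Q matrix.

    Genotype of sample i at variant j ~ Binomial(2, sum_k q_ik f_kj).
    ``template`` supplies the variant panel.  Returns ``(dataset, q_truth)``.
    """
    q_truth = np.asarray(q_truth, dtype=float)
    if not np.allclose(q_truth.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("q rows must sum to 1")
    rng = np.random.default_rng(seed)
    p = q_truth @ deme_freq  # (n, m)
    calls = rng.binomial(2, np.clip(p, 0, 1)).astype(np.int8)
    data = make_dataset(
        calls,
        populations=["ADMIX"] * q_truth.shape[0],
        chrom=list(template.variants["chrom"]),
        pos=template.variants["pos"].to_numpy(),
        variant_ids=list(template.variants["id"]),
        allele_a=list(template.variants["allele_a"]),
        allele_b=list(template.variants["allele_b"]),
    )
    return data, q_truth
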