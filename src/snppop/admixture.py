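"""Maximum-likelihood admixture model with EM fitting and cross-validation.

Model: genotype g_ij ~ Binomial(2, p_ij) with p_ij = sum_k q_ik f_kj, where
q_ik are per-individual ancestry fractions (rows on the simplex) and f_kj
the allele frequencies of k ancestral populations.  Fitting alternates the
classic multiplicative EM updates; the log-likelihood is non-decreasing.
Cross-validation masks a fraction of genotype entries, refits, and scores
the held-out entries by mean binomial deviance, which selects k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import comb, xlogy

from .dataset import MISSING, GenotypeDataset

F_EPS = 1e-6


@dataclass
class AdmixtureFit:
    k: int
    q: np.ndarray  # (n, k)
    f: np.ndarray  # (k, m)
    loglik: float
    loglik_path: np.ndarray
    n_iterations: int
    converged: bool
    seed: int
    cv_error: float | None = None


def _loglik(g: np.ndarray, called: np.ndarray, q: np.ndarray, f: np.ndarray) -> float:
    p = q @ f
    g0 = np.where(called, g, 0.0)
    ll = xlogy(g0, p) + xlogy(2.0 - g0, 1.0 - p) + np.log(comb(2, g0))
    return float(ll[called].sum())


def fit_admixture(
    data: GenotypeDataset,
    k: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
    n_restarts: int = 5,
) -> AdmixtureFit:
    """Fit the k-ancestral-population admixture model by EM.

    ``n_restarts`` independent seeded initializations are run and the fit
    with the best log-likelihood returned.  Q rows initialize from
    Dirichlet(1); F from Uniform(0.05, 0.95).  Missing genotypes are skipped.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > data.n_samples:
        raise ValueError("k cannot exceed the number of samples")
    g = data.calls.astype(float)
    called = data.calls != MISSING
    best: AdmixtureFit | None = None
    for r in range(max(1, n_restarts)):
        run_seed = seed + r
        fit = _fit_once(g, called, k, run_seed, tol, max_iter)
        if best is None or fit.loglik > best.loglik:
            best = fit
    return best


def _fit_once(g, called, k, seed, tol, max_iter) -> AdmixtureFit:
    rng = np.random.default_rng(seed)
    n, m = g.shape
    q = rng.dirichlet(np.ones(k), size=n)
    f = rng.uniform(0.05, 0.95, size=(k, m))
    g0 = np.where(called, g, 0.0)
    g2 = np.where(called, 2.0 - g, 0.0)  # zero where missing so sums skip them
    denom_i = 2.0 * called.sum(axis=1, keepdims=True)  # 2 * called variants per sample

    path = [_loglik(g, called, q, f)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = q @ f
        np.clip(p, F_EPS, 1 - F_EPS, out=p)
        rg = g0 / p  # (n, m), zero where missing
        rh = g2 / (1.0 - p)
        # E-step expected allele-copy counts; M-step closed form
        a_num = q * (rg @ f.T)  # sum_j a_ikj
        b_num = q * (rh @ (1.0 - f).T)  # sum_j b_ikj
        q_new = (a_num + b_num) / denom_i
        q_new /= q_new.sum(axis=1, keepdims=True)

        a_f = f * (q.T @ rg)  # sum_i a_ikj, shape (k, m)
        b_f = (1.0 - f) * (q.T @ rh)
        f_new = a_f / np.clip(a_f + b_f, 1e-300, None)
        np.clip(f_new, F_EPS, 1 - F_EPS, out=f_new)

        q, f = q_new, f_new
        ll = _loglik(g, called, q, f)
        path.append(ll)
        if abs(ll - path[-2]) <= tol * (abs(path[-2]) + 1e-12):
            converged = True
            break
    return AdmixtureFit(
        k=k,
        q=q,
        f=f,
        loglik=path[-1],
        loglik_path=np.array(path),
        n_iterations=it,
        converged=converged,
        seed=seed,
    )


def predict_dosage(fit: AdmixtureFit) -> np.ndarray:
    """Expected genotype dosage 2 * QF under the fitted model."""
    return 2.0 * (fit.q @ fit.f)


def cv_error(
    data: GenotypeDataset,
    k: int,
    n_folds: int = 5,
    mask_fraction: float = 0.1,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
    n_restarts: int = 1,
) -> float:
    """Masked-entry cross-validation error for model-order selection.

    Each fold masks ``mask_fraction`` of the non-missing genotype entries
    (seeded), refits, and scores the held-out entries by mean binomial
    deviance between observed g and fitted dosage 2*p-hat; folds average.
    """
    rng = np.random.default_rng(seed)
    called = data.calls != MISSING
    obs_idx = np.argwhere(called)
    errors = []
    for fold in range(n_folds):
        n_mask = max(1, int(round(mask_fraction * len(obs_idx))))
        sel = rng.choice(len(obs_idx), size=n_mask, replace=False)
        rows, cols = obs_idx[sel, 0], obs_idx[sel, 1]
        masked = data.copy()
        masked.calls[rows, cols] = MISSING
        # variants emptied by the mask cannot be scored in this fold
        nonempty = (masked.calls != MISSING).any(axis=0)
        fit = fit_admixture(
            masked, k, seed=seed * 1000 + fold, tol=tol, max_iter=max_iter, n_restarts=n_restarts
        )
        p = np.clip(fit.q @ fit.f, F_EPS, 1 - F_EPS)
        g = data.calls[rows, cols].astype(float)
        score_ok = nonempty[cols]
        g, ph = g[score_ok], p[rows[score_ok], cols[score_ok]]
        dev = 2.0 * (xlogy(g, g / (2.0 * ph)) + xlogy(2.0 - g, (2.0 - g) / (2.0 - 2.0 * ph)))
        errors.append(float(dev.mean()))
    return float(np.mean(errors))


def cv_scan(data: GenotypeDataset, k_values, **kwargs) -> dict[int, float]:
    """Cross-validation error for each k in ``k_values``."""
    return {int(k): cv_error(data, int(k), **kwargs) for k in k_values}


def align_labels(fit_a: AdmixtureFit, fit_b: AdmixtureFit) -> np.ndarray:
    """Column permutation of ``fit_b`` best matching ``fit_a`` (Hungarian).

    Cost is the negative correlation between Q columns (falling back to a
    dot-product score for constant columns).  Returns ``perm`` such that
    ``fit_b.q[:, perm]`` aligns with ``fit_a.q``.
    """
    if fit_a.k != fit_b.k:
        raise ValueError("fits must have equal k")
    k = fit_a.k
    if k == 1:
        return np.array([0])
    qa, qb = fit_a.q, fit_b.q
    cost = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            xa, xb = qa[:, i], qb[:, j]
            if np.std(xa) == 0 or np.std(xb) == 0:
                cost[i, j] = -float(xa @ xb) / len(xa)
            else:
                cost[i, j] = -float(np.corrcoef(xa, xb)[0, 1])
    _, perm = linear_sum_assignment(cost)
    return perm
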