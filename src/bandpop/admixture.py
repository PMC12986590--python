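"""Bayesian admixture clustering of binary band profiles.

Model (haploid binary loci): each accession i has ancestry proportions
q_i ~ Dirichlet(alpha, ..., alpha) over K clusters; each cluster k has a
band frequency f_kl ~ Beta(lambda, lambda) per locus; the origin of call
x_il is z_il ~ Categorical(q_i) and x_il ~ Bernoulli(f_{z_il, l}).
A Gibbs sampler updates z, f, q in turn; reported Q and F are posterior
means over the recorded (post-burn-in) sweeps, and the data
log-likelihood

    L = sum_il ln sum_k q_ik f_kl^x_il (1 - f_kl)^(1 - x_il)

is recorded each sweep.  Across independent runs per K, Evanno's
delta-K statistic selects the number of clusters, and accessions whose
largest ancestry proportion falls below a threshold (0.6 by default)
are called admixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .io_core import MISSING, BandMatrix, summarize_loci


@dataclass
class AdmixtureFit:
    K: int
    Q: np.ndarray  # (N, K) posterior-mean ancestry, rows sum to 1
    F: np.ndarray  # (K, L) posterior-mean cluster band frequencies
    loglik_trace: np.ndarray  # one entry per recorded sweep
    posterior_mean_loglik: float
    ln_prob_data: float  # mean(LL) - var(LL)/2, the model log-probability estimate
    seed: int
    burn_in: int
    samples: int
    accession_ids: list[str]

    def q_frame(self) -> pd.DataFrame:
        cols = [f"cluster{k + 1}" for k in range(self.K)]
        return pd.DataFrame(self.Q, index=self.accession_ids, columns=cols)


@njit(cache=True, fastmath=True)
def _gibbs(x, K, alpha, lam, burn_in, samples, seed, init_c):  # pragma: no cover - numba
    np.random.seed(seed)
    n, l = x.shape
    # start each individual in its initial cluster; without symmetry breaking
    # the sampler can sit on the saddle where all clusters are identical
    q = np.full((n, K), 0.1 / K)
    for i in range(n):
        q[i, init_c[i]] += 0.9
    # initial cluster frequencies from the assigned individuals' counts
    f = np.empty((K, l))
    for k in range(K):
        for j in range(l):
            ones = 0.0
            tot = 0.0
            for i in range(n):
                if init_c[i] == k and x[i, j] >= 0:
                    tot += 1.0
                    ones += x[i, j]
            f[k, j] = (ones + lam) / (tot + 2.0 * lam)

    q_sum = np.zeros((n, K))
    f_sum = np.zeros((K, l))
    trace = np.empty(samples)
    probs = np.empty(K)
    # lik[c, k, j]: cell likelihood for call c (0/1/missing) under cluster k
    lik = np.empty((3, K, l))

    for it in range(burn_in + samples):
        for k in range(K):
            for j in range(l):
                lik[0, k, j] = 1.0 - f[k, j]
                lik[1, k, j] = f[k, j]
                lik[2, k, j] = 1.0
        n1 = np.zeros((K, l))
        n0 = np.zeros((K, l))
        mq = np.zeros((n, K))
        record = it >= burn_in
        ll = 0.0
        for i in range(n):
            for j in range(l):
                xi = x[i, j]
                c = xi if xi >= 0 else 2
                s = 0.0
                for k in range(K):
                    w = q[i, k] * lik[c, k, j]
                    probs[k] = w
                    s += w
                # s is the mixture likelihood of this cell at the current state
                if record and xi >= 0:
                    ll += math.log(s)
                u = np.random.random() * s
                acc = 0.0
                kk = K - 1
                for k in range(K):
                    acc += probs[k]
                    if u <= acc:
                        kk = k
                        break
                mq[i, kk] += 1.0
                if xi == 1:
                    n1[kk, j] += 1.0
                elif xi == 0:
                    n0[kk, j] += 1.0
        for k in range(K):
            for j in range(l):
                g1 = np.random.gamma(lam + n1[k, j], 1.0)
                g2 = np.random.gamma(lam + n0[k, j], 1.0)
                f[k, j] = (g1 + 1e-12) / (g1 + g2 + 2e-12)
        for i in range(n):
            s = 0.0
            for k in range(K):
                g = np.random.gamma(alpha + mq[i, k], 1.0)
                q[i, k] = g + 1e-12
                s += q[i, k]
            for k in range(K):
                q[i, k] /= s

        if record:
            trace[it - burn_in] = ll
            q_sum += q
            f_sum += f

    return q_sum / samples, f_sum / samples, trace


def _kmeans_labels(x: np.ndarray, K: int, rng: np.random.Generator,
                   n_iter: int = 25) -> np.ndarray:
    """k-means++ labels of the band profiles (missing imputed to locus mean).

    Used to initialise the Gibbs sampler near a data-supported mode;
    different seeds give different local optima, so independent runs
    still start in different places.
    """
    prof = x.astype(float)
    prof[x < 0] = np.nan
    col_mean = np.nanmean(prof, axis=0)
    nan_rows, nan_cols = np.where(np.isnan(prof))
    prof[nan_rows, nan_cols] = col_mean[nan_cols]

    n = prof.shape[0]
    centers = np.empty((K, prof.shape[1]))
    centers[0] = prof[rng.integers(n)]
    d2 = ((prof - centers[0]) ** 2).sum(axis=1)
    for k in range(1, K):
        tot = d2.sum()
        if tot <= 0:
            centers[k] = prof[rng.integers(n)]
        else:
            centers[k] = prof[rng.choice(n, p=d2 / tot)]
        d2 = np.minimum(d2, ((prof - centers[k]) ** 2).sum(axis=1))
    labels = np.zeros(n, dtype=np.int64)
    for _ in range(n_iter):
        dists = ((prof[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = dists.argmin(axis=1)
        if (new_labels == labels).all():
            break
        labels = new_labels
        for k in range(K):
            members = prof[labels == k]
            if len(members):
                centers[k] = members.mean(axis=0)
    return labels


def fit_admixture(
    m: BandMatrix,
    K: int,
    burn_in: int = 5000,
    samples: int = 5000,
    alpha: float = 1.0,
    lam: float = 1.0,
    seed: int = 0,
    init: str = "kmeans",
) -> AdmixtureFit:
    """Fit the admixture model for one K with one MCMC run.

    ``init`` chooses the starting assignment: ``kmeans`` (default) seeds
    the chain from a k-means++ clustering of the band profiles, ``random``
    assigns each accession to a uniform random cluster.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > m.n_accessions:
        raise ValueError(f"K={K} exceeds the number of accessions ({m.n_accessions})")
    if burn_in < 1 or samples < 1:
        raise ValueError("burn_in and samples must be >= 1")
    summarize_loci(m)  # raises on all-missing loci
    x = m.calls.astype(np.int8)
    rng = np.random.default_rng(seed)
    if init == "kmeans" and K > 1:
        init_c = _kmeans_labels(x, K, rng)
    elif init in ("random", "kmeans"):
        init_c = rng.integers(0, K, size=m.n_accessions)
    else:
        raise ValueError(f"unknown init {init!r}")
    q, f, trace = _gibbs(x, K, float(alpha), float(lam), int(burn_in), int(samples),
                         int(seed) % (2**31), init_c.astype(np.int64))
    q = q / q.sum(axis=1, keepdims=True)
    return AdmixtureFit(
        K=K,
        Q=q,
        F=f,
        loglik_trace=trace,
        posterior_mean_loglik=float(trace.mean()),
        ln_prob_data=float(trace.mean() - trace.var() / 2.0),
        seed=seed,
        burn_in=burn_in,
        samples=samples,
        accession_ids=list(m.accession_ids),
    )


def _run_seed(seed: int, k: int, run: int) -> int:
    return int(np.random.SeedSequence((seed, k, run)).generate_state(1)[0] % (2**31))


def run_k_grid(
    m: BandMatrix,
    k_min: int,
    k_max: int,
    runs: int = 5,
    burn_in: int = 5000,
    samples: int = 5000,
    alpha: float = 1.0,
    lam: float = 1.0,
    seed: int = 0,
) -> dict[int, list[AdmixtureFit]]:
    """Independent runs over a consecutive K grid (one RNG stream per run)."""
    if k_min < 1 or k_max < k_min:
        raise ValueError("invalid K range")
    out: dict[int, list[AdmixtureFit]] = {}
    for k in range(k_min, k_max + 1):
        out[k] = [
            fit_admixture(
                m, k, burn_in=burn_in, samples=samples, alpha=alpha, lam=lam,
                seed=_run_seed(seed, k, r),
            )
            for r in range(runs)
        ]
    return out


@dataclass
class DeltaKTable:
    ks: list[int]
    mean_loglik: np.ndarray
    sd_loglik: np.ndarray
    l_prime: np.ndarray  # nan at the first K
    l_second_abs: np.ndarray  # nan at the boundary Ks
    delta_k: np.ndarray  # nan where undefined (boundaries, sd = 0)
    best_k: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "K": self.ks,
                "mean_LnK": self.mean_loglik,
                "sd_LnK": self.sd_loglik,
                "LnK_prime": self.l_prime,
                "abs_LnK_second": self.l_second_abs,
                "delta_K": self.delta_k,
            }
        ).set_index("K")


def delta_k(runs: Mapping[int, Sequence[AdmixtureFit]] | Mapping[int, Sequence[float]]) -> DeltaKTable:
    """Evanno delta-K table from per-K collections of runs.

    Accepts either fitted models (their per-run posterior-mean data
    log-likelihoods are used as L(K)) or raw per-run L(K) values.
    delta-K = |L(K+1) - 2 L(K) + L(K-1)| / sd(L(K)) is defined only at
    interior grid points and reported as missing where the run-to-run
    sd is zero.
    """
    ks = sorted(runs)
    if len(ks) < 3:
        raise ValueError("need at least 3 consecutive K values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K grid must be consecutive")
    loglik: dict[int, np.ndarray] = {}
    for k in ks:
        vals = [
            r.posterior_mean_loglik if isinstance(r, AdmixtureFit) else float(r)
            for r in runs[k]
        ]
        if len(vals) < 2:
            raise ValueError(f"K={k}: need at least 2 runs")
        loglik[k] = np.asarray(vals, dtype=float)

    mean_l = np.array([loglik[k].mean() for k in ks])
    sd_l = np.array([loglik[k].std(ddof=1) for k in ks])
    nk = len(ks)
    l_prime = np.full(nk, np.nan)
    l_second = np.full(nk, np.nan)
    dk = np.full(nk, np.nan)
    for i in range(1, nk):
        l_prime[i] = mean_l[i] - mean_l[i - 1]
    for i in range(1, nk - 1):
        l_second[i] = abs(mean_l[i + 1] - 2.0 * mean_l[i] + mean_l[i - 1])
        if sd_l[i] > 0:
            dk[i] = l_second[i] / sd_l[i]
    best: int | None = None
    if np.isfinite(dk).any() and np.nanmax(dk) > 0:
        best = ks[int(np.nanargmax(dk))]
    return DeltaKTable(ks, mean_l, sd_l, l_prime, l_second, dk, best)


def align_runs(fits: Sequence[AdmixtureFit]) -> np.ndarray:
    """Average Q matrices across runs after greedy label alignment.

    Columns of each run are matched to the first run by maximal column
    correlation (greedy, without replacement); the averaged Q rows are
    renormalised to sum to 1.
    """
    if not fits:
        raise ValueError("no fits given")
    k = fits[0].K
    if any(f.K != k for f in fits):
        raise ValueError("all fits must share the same K")
    ref = fits[0].Q
    total = ref.copy()
    for fit in fits[1:]:
        qm = fit.Q
        if k == 1:
            total += qm
            continue
        corr = np.zeros((k, k))
        for a in range(k):
            for b in range(k):
                sa, sb = np.std(ref[:, a]), np.std(qm[:, b])
                if sa == 0 or sb == 0:
                    corr[a, b] = -np.inf if not np.allclose(ref[:, a], qm[:, b]) else 1.0
                else:
                    corr[a, b] = np.corrcoef(ref[:, a], qm[:, b])[0, 1]
        perm = np.full(k, -1)
        used_a, used_b = set(), set()
        flat = sorted(
            ((corr[a, b], a, b) for a in range(k) for b in range(k)),
            key=lambda t: -t[0],
        )
        for c, a, b in flat:
            if a not in used_a and b not in used_b:
                perm[a] = b
                used_a.add(a)
                used_b.add(b)
        total += qm[:, perm]
    avg = total / len(fits)
    return avg / avg.sum(axis=1, keepdims=True)


def call_admixed(
    q: np.ndarray,
    threshold: float = 0.6,
    accession_ids: Sequence[str] | None = None,
) -> pd.Series:
    """Assign each accession to its argmax cluster or call it admixed.

    An accession is assigned to cluster ``cluster{k}`` when its largest
    ancestry proportion is >= threshold (inclusive boundary), otherwise
    labelled ``admixed``.  Threshold must exceed 1/K (below that every
    row trivially passes) and be at most 1.
    """
    q = np.asarray(q, dtype=float)
    k = q.shape[1]
    if not (1.0 / k < threshold <= 1.0):
        raise ValueError(f"threshold must be in (1/K, 1], got {threshold}")
    labels = []
    for row in q:
        j = int(np.argmax(row))
        labels.append(f"cluster{j + 1}" if row[j] >= threshold else "admixed")
    index = list(accession_ids) if accession_ids is not None else list(range(len(labels)))
    return pd.Series(labels, index=index, name="assignment")
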