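"""Ancestry and introgression statistics.

Four pieces:

* per-SNP Weir-Cockerham FST between two populations, from pooled allele
  frequencies and sample sizes;
* ancestry-informative-marker (AIM) panel selection by FST-threshold
  rules with non-missing-count floors (breed-specific admixture analysis
  panels);
* an EM estimator of the admixture model (the likelihood maximized by
  ADMIXTURE/Structure): each individual is a mixture over k clusters with
  proportions Q, each cluster has ancestral allele frequencies P, and the
  genotype likelihood is binomial with success probability sum_c q_c p_c;
* the four-population f4 statistic, its ratio normalization f4n that
  estimates the admixture fraction of a source population in a test
  population relative to a reference, and a contiguous-block jackknife for
  its confidence interval (f4n +/- 2 SD, approximately P < 0.05).

f4 for sources (src1, src2), reference ``ref`` and test population X is
mean over SNPs of (f_src1 - f_src2)(f_ref - f_X); the normalization
divides by the same expression with X replaced by src2, so that X = src2
scores exactly 1 and X = ref exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distances import FreqTable
from .genotypes import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------


def fst_per_snp(freqs: FreqTable, pop_a: str, pop_b: str) -> np.ndarray:
    """Per-SNP two-population Weir-Cockerham FST estimate.

    Computed from allele frequencies and allele sample sizes (random union
    of gametes).  The estimator can be negative; values are NaN where
    either population is ungenotyped or the denominator is 0.
    """
    fa, ca = freqs.row(pop_a)
    fb, cb = freqs.row(pop_b)
    return _weir_cockerham(fa, ca.astype(float), fb, cb.astype(float))


def fst_overall(freqs: FreqTable, pop_a: str, pop_b: str) -> float:
    """Multi-locus Weir-Cockerham FST: ratio of summed variance components
    (the weighted average PLINK prints), robust where per-SNP ratios are
    noisy.  For two populations each drifted F from a common ancestor this
    estimates approximately F."""
    fa, ca = freqs.row(pop_a)
    fb, cb = freqs.row(pop_b)
    a, b = _wc_components(fa, ca.astype(float), fb, cb.astype(float))
    ok = np.isfinite(a) & np.isfinite(b)
    return float(a[ok].sum() / (a[ok] + b[ok]).sum())


def _wc_components(p1, n1, p2, n2):
    # n1, n2 are allele counts (2 x individuals); r = 2 populations
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / 2.0
        nc = ((n1 + n2) - (n1**2 + n2**2) / (n1 + n2))  # (r nbar - sum n^2/(r nbar))/(r-1)
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar  # /(r-1)=1
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 / 2.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - s2 / 2.0)
    bad = (n1 <= 0) | (n2 <= 0)
    return np.where(bad, np.nan, a), np.where(bad, np.nan, b)


def _weir_cockerham(p1, n1, p2, n2) -> np.ndarray:
    a, b = _wc_components(p1, n1, p2, n2)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = a / (a + b)
    return np.where(np.isfinite(fst), fst, np.nan)


# ---------------------------------------------------------------------------
# AIM panels
# ---------------------------------------------------------------------------


@dataclass
class FstRule:
    """One clause of an AIM rule: FST(pop_a, pop_b) OP threshold."""

    pop_a: str
    pop_b: str
    op: str  # ">" or "<"
    threshold: float

    def passes(self, fst: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            if self.op == ">":
                ok = fst > self.threshold
            elif self.op == "<":
                ok = fst < self.threshold
            else:
                raise ValueError(f"unknown operator {self.op!r}")
        return ok & ~np.isnan(fst)


@dataclass
class AIMPanel:
    name: str
    snp_ids: list[str]
    rules: list[FstRule]
    count_floors: dict[str, int]
    table: pd.DataFrame = field(default_factory=pd.DataFrame)


def select_aims(
    freqs: FreqTable,
    rules: list[FstRule],
    count_floors: dict[str, int] | None = None,
    name: str = "custom",
) -> AIMPanel:
    """Select the SNPs passing every FST clause and every count floor.

    ``count_floors`` maps population label -> minimum non-missing allele
    count at the SNP.  Deterministic: the panel is exactly the set of SNPs
    satisfying all criteria, in map order.
    """
    count_floors = count_floors or {}
    for rule in rules:
        for p in (rule.pop_a, rule.pop_b):
            if p not in freqs.pops:
                raise ValueError(f"rule references unknown population {p!r}")
    for p in count_floors:
        if p not in freqs.pops:
            raise ValueError(f"count floor references unknown population {p!r}")

    n = len(freqs.snp_ids)
    ok = np.ones(n, dtype=bool)
    cols: dict[str, np.ndarray] = {}
    for rule in rules:
        fst = fst_per_snp(freqs, rule.pop_a, rule.pop_b)
        cols[f"fst_{rule.pop_a}_{rule.pop_b}"] = fst
        ok &= rule.passes(fst)
    for p, floor in count_floors.items():
        _, cnt = freqs.row(p)
        ok &= cnt >= floor
    idx = np.flatnonzero(ok)
    table = pd.DataFrame({"snp_id": [freqs.snp_ids[i] for i in idx]})
    for key, col in cols.items():
        table[key] = col[idx]
    return AIMPanel(name, list(table["snp_id"]), rules, count_floors, table)


# ---------------------------------------------------------------------------
# Admixture EM
# ---------------------------------------------------------------------------

_P_EPS = 1e-6


@dataclass
class QMatrix:
    samples: list[str]
    clusters: list[str]
    q: np.ndarray  # (n_samples, k) ancestry proportions
    p: np.ndarray  # (k, n_snps) cluster allele frequencies
    mode: str  # "supervised" | "unsupervised"
    loglik_trace: list[float]
    seed: int | None
    converged: bool
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.q, index=self.samples, columns=self.clusters)


def admixture_em(
    gm: GenotypeMatrix,
    k: int,
    mode: str = "unsupervised",
    reference_assignments: dict[str, str] | None = None,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    n_starts: int = 5,
) -> QMatrix:
    """Maximum-likelihood admixture proportions by EM.

    Maximizes the binomial admixture log-likelihood
    ``sum_ij [g ln(mu) + (2-g) ln(1-mu)]`` with ``mu = sum_c q_ic p_cj``,
    skipping missing genotypes.  In supervised mode, cluster frequencies P
    are estimated once from the labelled reference individuals and held
    fixed; only Q is iterated.  In unsupervised mode both Q and P are
    updated, from the best of ``n_starts`` Dirichlet(1) random starts.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    g = gm.calls.astype(float)
    obs = gm.calls != MISSING
    g = np.where(obs, g, 0.0)

    if mode == "supervised":
        if not reference_assignments:
            raise ValueError("supervised mode needs reference_assignments")
        clusters = sorted(set(reference_assignments.values()))
        if len(clusters) != k:
            raise ValueError(f"{len(clusters)} reference clusters for k={k}")
        p0 = np.empty((k, gm.n_snps))
        ref_counts = np.empty((k, gm.n_snps))
        for c, lab in enumerate(clusters):
            ids = [s for s, l in reference_assignments.items() if l == lab]
            if not ids:
                raise ValueError(f"cluster {lab} has no reference individuals")
            rows = [gm.samples.index(s) for s in ids]
            sub, subobs = g[rows], obs[rows]
            denom = 2.0 * subobs.sum(axis=0)
            ref_counts[c] = denom
            p0[c] = np.where(denom > 0, sub.sum(axis=0) / np.maximum(denom, 1), 0.5)
        degenerate = _is_degenerate(p0, ref_counts)
        p0 = np.clip(p0, _P_EPS, 1 - _P_EPS)
        q0 = np.full((gm.n_samples, k), 1.0 / k)
        q, p, trace, converged = _em_iterate(
            g, obs, q0, p0, fix_p=True, max_iter=max_iter, tol=tol
        )
        return QMatrix(list(gm.samples), clusters, q, p, mode, trace, seed,
                       converged, degenerate)

    # unsupervised: best of n_starts seeded random starts
    clusters = [f"K{c + 1}" for c in range(k)]
    best = None
    for s in range(n_starts):
        rng = np.random.default_rng((seed + s) % (2**31))
        q0 = rng.dirichlet(np.ones(k), size=gm.n_samples)
        p0 = np.clip(rng.uniform(0.05, 0.95, size=(k, gm.n_snps)), _P_EPS, 1 - _P_EPS)
        q, p, trace, converged = _em_iterate(
            g, obs, q0, p0, fix_p=False, max_iter=max_iter, tol=tol
        )
        if best is None or trace[-1] > best[2][-1]:
            best = (q, p, trace, converged)
    q, p, trace, converged = best
    return QMatrix(list(gm.samples), clusters, q, p, "unsupervised", trace,
                   seed, converged, _is_degenerate(p))


def _is_degenerate(p: np.ndarray, counts: np.ndarray | None = None) -> bool:
    """Clusters with (near-)identical frequencies make Q unidentifiable.

    With reference allele counts available (supervised mode) the check is
    whether any cluster pair's frequency differentiation is within
    sampling noise (multi-locus Weir-Cockerham FST ~ 0); otherwise it is
    whether two estimated frequency rows have collapsed together.
    """
    k = p.shape[0]
    for a in range(k):
        for b in range(a + 1, k):
            if counts is not None:
                ca, cb = counts[a].astype(float), counts[b].astype(float)
                wa, wb = _wc_components(p[a], ca, p[b], cb)
                ok = np.isfinite(wa) & np.isfinite(wb)
                denom = (wa[ok] + wb[ok]).sum()
                fst = wa[ok].sum() / denom if denom > 0 else 0.0
                if fst < 0.005:
                    return True
            elif np.abs(p[a] - p[b]).max() < 1e-3:
                return True
    return False


def _em_iterate(g, obs, q, p, fix_p, max_iter, tol):
    n, k = q.shape
    trace: list[float] = []
    converged = False
    two_minus_g = np.where(obs, 2.0 - g, 0.0)
    for _ in range(max_iter):
        mu = q @ p  # (n, n_snps)
        mu = np.clip(mu, _P_EPS, 1 - _P_EPS)
        ll = float(
            np.where(obs, g * np.log(mu) + two_minus_g * np.log1p(-mu), 0.0).sum()
        )
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        # E-step responsibilities folded into the M-step updates
        a_num = g / mu  # weight for the "allele B" term
        b_num = two_minus_g / (1.0 - mu)
        # q update: expected ancestry copies per cluster / (2 * n obs SNPs)
        ea = (a_num @ p.T) * q  # sum_j g * q p / mu per cluster
        eb = (b_num @ (1.0 - p).T) * q
        denom = 2.0 * obs.sum(axis=1, keepdims=True)
        q = (ea + eb) / np.maximum(denom, 1e-300)
        q = q / q.sum(axis=1, keepdims=True)
        if not fix_p:
            # p update: expected B alleles from cluster c / expected total
            pa = (q.T @ a_num) * p  # (k, n_snps): sum_i q_ic g_ij p_cj / mu_ij
            pb = (q.T @ b_num) * (1.0 - p)
            p = np.clip(pa / np.maximum(pa + pb, 1e-300), _P_EPS, 1 - _P_EPS)
    return q, p, trace, converged


# ---------------------------------------------------------------------------
# f4 / f4n
# ---------------------------------------------------------------------------


@dataclass
class F4Result:
    test_pop: str
    f4: float
    f4n: float
    ci_low: float
    ci_high: float
    n_snps: int
    n_blocks: int


def _f4_contributions(freqs: FreqTable, src1, src2, ref, x):
    f1, _ = freqs.row(src1)
    f2, _ = freqs.row(src2)
    fr, _ = freqs.row(ref)
    fx, _ = freqs.row(x)
    ok = ~(np.isnan(f1) | np.isnan(f2) | np.isnan(fr) | np.isnan(fx))
    if not ok.any():
        raise ValueError("zero usable SNPs for f4")
    num = (f1[ok] - f2[ok]) * (fr[ok] - fx[ok])
    den = (f1[ok] - f2[ok]) * (fr[ok] - f2[ok])
    return num, den, ok


def f4_stat(freqs: FreqTable, src1: str, src2: str, ref: str, x: str) -> float:
    """Mean over usable SNPs of (f_src1 - f_src2)(f_ref - f_X)."""
    num, _, _ = _f4_contributions(freqs, src1, src2, ref, x)
    return float(num.mean())


def jackknife_sd(num: np.ndarray, den: np.ndarray, n_blocks: int = 100) -> float:
    """Delete-one-block jackknife SD of the ratio mean(num)/mean(den).

    Blocks are contiguous runs of SNPs (SNPs must arrive in genome order),
    so the estimate is robust to local LD.
    """
    n = len(num)
    if n_blocks < 10:
        raise ValueError("n_blocks must be >= 10")
    if n_blocks > n:
        raise ValueError(f"n_blocks={n_blocks} exceeds {n} SNPs")
    bounds = np.linspace(0, n, n_blocks + 1).astype(int)
    tot_num, tot_den = num.sum(), den.sum()
    thetas = np.empty(n_blocks)
    for b in range(n_blocks):
        lo, hi = bounds[b], bounds[b + 1]
        nn = tot_num - num[lo:hi].sum()
        dd = tot_den - den[lo:hi].sum()
        thetas[b] = nn / dd
    mean_theta = thetas.mean()
    var = (n_blocks - 1) / n_blocks * ((thetas - mean_theta) ** 2).sum()
    return float(np.sqrt(var))


def f4n_profile(
    freqs: FreqTable,
    src1: str,
    src2: str,
    ref: str,
    test_pops: list[str],
    n_blocks: int = 100,
) -> list[F4Result]:
    """Normalized f4 ratio for each test population, with jackknife CI.

    f4n(X) = mean[(f_src1 - f_src2)(f_ref - f_X)]
           / mean[(f_src1 - f_src2)(f_ref - f_src2)],
    the admixture fraction of src2 in X relative to ref: src2 itself scores
    1, ref scores 0.  CI is f4n +/- 2 x block-jackknife SD.
    """
    results = []
    for x in test_pops:
        num, den, _ = _f4_contributions(freqs, src1, src2, ref, x)
        mean_den = den.mean()
        if abs(mean_den) < 1e-12:
            raise ValueError(
                f"sources {src1}/{src2} not differentiated relative to {ref}"
            )
        f4 = float(num.mean())
        f4n = f4 / float(mean_den)
        nb = min(n_blocks, len(num))
        sd = jackknife_sd(num, den, nb) if nb >= 10 else float("nan")
        results.append(
            F4Result(x, f4, f4n, f4n - 2 * sd, f4n + 2 * sd, len(num), nb)
        )
    return results


def f4_results_to_frame(results: list[F4Result]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "X": r.test_pop,
                "f4": r.f4,
                "f4n": r.f4n,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "n_snps": r.n_snps,
                "n_blocks": r.n_blocks,
            }
            for r in results
        ]
    )
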