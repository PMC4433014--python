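"""The OPTPDT: variable p-value threshold SNP selection with a sign-flip
permutation null.

For a set of n SNPs, each SNP's PDT statistic T^2 and asymptotic p-value are
computed.  For every threshold k in a descending grid (default 0.05, 0.03,
0.01, 0.005) the SNPs with p < k form L_k and Y_k = sum of their T^2.  A
permutation flips one fair sign per family across *all* SNPs simultaneously
(swapping transmitted and non-transmitted alleles negates the family's D at
every SNP, so flipping a shared row sign preserves both LD between SNPs and
linkage between sibs).  Y_k is standardized against the permutation null,
Z_k = (Y_k - mu_k) / sigma_k, and the test statistic is M = max_k Z_k.  The
same permutations yield M_j and the p-value #(M_j >= M) / m.
"""
from __future__ import annotations

import concurrent.futures
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from ._seeds import derive_rng
from .famio import SNPSet, StudyData
from .pdt_core import DMatrix, build_d_matrix

DEFAULT_THRESHOLDS = (0.05, 0.03, 0.01, 0.005)

RngLike = Union[int, np.random.Generator]


def _as_rng(rng: RngLike) -> np.random.Generator:
    if hasattr(rng, "integers"):  # Generator or any object with the same draw API
        return rng
    return np.random.default_rng(rng)


def validate_thresholds(thresholds: Sequence[float]) -> tuple[float, ...]:
    ts = tuple(float(t) for t in thresholds)
    if not ts:
        raise ValueError("at least one p-value threshold is required")
    if any(not (0.0 < t < 1.0) for t in ts):
        raise ValueError(f"thresholds must lie in (0, 1): {ts}")
    if any(a <= b for a, b in zip(ts, ts[1:])):
        raise ValueError(f"thresholds must be strictly decreasing: {ts}")
    return ts


@dataclass
class OPTPDTResult:
    set_name: str
    thresholds: tuple[float, ...]
    n_markers: int
    n_informative_families: int
    selected: dict[float, list[str]]  # threshold -> marker ids in L_k
    Y: dict[float, float]
    mu_hat: dict[float, float]
    sigma_hat: dict[float, float]
    z_scores: dict[float, Optional[float]]  # None where sigma_hat == 0
    M: Optional[float]
    best_threshold: Optional[float]
    m: int
    exceedances: int
    p: float
    min_attainable_p: float
    seed: Optional[int] = None
    testable: bool = True
    estimator: str = "plain"
    mendelian_errors: int = 0


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance cutoff alpha / n_tests."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    return alpha / n_tests


def select_and_sum(
    t2_values: Sequence[float], p_values: Sequence[float], threshold: float
) -> tuple[np.ndarray, float]:
    """SNPs with p strictly below the threshold and the sum of their T^2.

    An empty selection returns Y = 0 (empty-sum convention).
    """
    t2 = np.asarray(t2_values, dtype=float)
    p = np.asarray(p_values, dtype=float)
    if t2.shape != p.shape:
        raise ValueError("t2_values and p_values must be aligned per marker")
    selected = np.nonzero(p < threshold)[0]
    return selected, float(t2[selected].sum())


def permute_once(d_matrix: DMatrix, rng: RngLike) -> tuple[np.ndarray, np.ndarray]:
    """One sign-flip permutation: per-marker (T^2, p) on the flipped D matrix.

    Each family draws one fair sign applied to its whole row, which is exactly
    what swapping transmitted/non-transmitted alleles for all children at all
    SNPs produces; LD between markers and IBD between sibs are untouched.
    """
    rng = _as_rng(rng)
    signs = rng.integers(0, 2, size=d_matrix.n_families) * 2 - 1
    ssq = d_matrix.column_ssq()  # invariant under sign flips
    sums = signs @ d_matrix.values
    testable = ssq > 0
    t2 = np.zeros(d_matrix.n_markers)
    np.divide(sums**2, ssq, out=t2, where=testable)
    p = np.ones(d_matrix.n_markers)
    p[testable] = stats.chi2.sf(t2[testable], df=1)
    return t2, p


def _null_y_table(values: np.ndarray, ssq: np.ndarray, signs: np.ndarray, crits: np.ndarray) -> np.ndarray:
    """Y_k for every sign vector: (n_signs, n_thresholds).

    Selection 'p < k' is applied as 'T^2 > chi2.isf(k, 1)', avoiding per-cell
    survival-function calls; the map is exact because the chi-square sf is
    strictly decreasing.
    """
    sums = signs @ values  # (n_signs, n_markers)
    t2 = np.zeros_like(sums)
    np.divide(sums * sums, ssq, out=t2, where=ssq > 0)
    out = np.empty((signs.shape[0], crits.size))
    for k, crit in enumerate(crits):
        out[:, k] = np.sum(t2 * (t2 > crit), axis=1)
    return out


def _untestable_result(set_name, thresholds, n_markers, n_inf, m, estimator, seed, mendel) -> OPTPDTResult:
    return OPTPDTResult(
        set_name=set_name,
        thresholds=thresholds,
        n_markers=n_markers,
        n_informative_families=n_inf,
        selected={k: [] for k in thresholds},
        Y={k: 0.0 for k in thresholds},
        mu_hat={},
        sigma_hat={},
        z_scores={k: None for k in thresholds},
        M=None,
        best_threshold=None,
        m=m,
        exceedances=m,
        p=1.0,
        min_attainable_p=1.0 / m if m else np.nan,
        seed=seed if isinstance(seed, int) else None,
        testable=False,
        estimator=estimator,
        mendelian_errors=mendel,
    )


def optpdt_test(
    d_matrix: DMatrix,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    m: int = 2000,
    seed: RngLike = 0,
    estimator: str = "plain",
    set_name: str = "set",
) -> OPTPDTResult:
    """Run the OPTPDT on one SNP set's D matrix with m sign-flip permutations.

    ``estimator`` is "plain" for #(M_j >= M)/m (ties count as exceedances) or
    "add-one" for (#+1)/(m+1).  One pass of m sign vectors serves every
    threshold, which is what makes M and the M_j comparable.
    """
    thresholds = validate_thresholds(thresholds)
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if estimator not in ("plain", "add-one"):
        raise ValueError(f"unknown estimator {estimator!r}")

    values, mask = d_matrix.values, d_matrix.mask
    n_inf = int(np.any(mask, axis=1).sum())
    ssq = d_matrix.column_ssq()
    if not np.any(ssq > 0):
        return _untestable_result(
            set_name, thresholds, d_matrix.n_markers, n_inf, m, estimator, seed,
            d_matrix.mendelian_errors,
        )

    t2_obs, p_obs = d_matrix.t2_pvalues()
    crits = stats.chi2.isf(np.asarray(thresholds), df=1)
    selected = {}
    y_obs = np.empty(len(thresholds))
    for k, (thr, crit) in enumerate(zip(thresholds, crits)):
        idx = np.nonzero((ssq > 0) & (t2_obs > crit))[0]
        selected[thr] = [d_matrix.marker_ids[i] for i in idx]
        y_obs[k] = t2_obs[idx].sum()

    rng = _as_rng(seed)
    signs = (rng.integers(0, 2, size=(m, d_matrix.n_families)) * 2 - 1).astype(np.float64)
    y_perm = _null_y_table(values, ssq, signs, crits)

    mu = y_perm.mean(axis=0)
    sigma = y_perm.std(axis=0, ddof=1) if m > 1 else np.zeros(len(thresholds))
    available = sigma > 0

    z_obs = np.full(len(thresholds), np.nan)
    z_obs[available] = (y_obs[available] - mu[available]) / sigma[available]

    all_empty = all(len(selected[thr]) == 0 for thr in thresholds)
    if not np.any(available) or all_empty:
        M = None
        best = None
        exceed = m
        p = 1.0
    else:
        M = float(np.max(z_obs[available]))
        best = thresholds[int(np.nanargmax(np.where(available, z_obs, -np.inf)))]
        z_perm = (y_perm[:, available] - mu[available]) / sigma[available]
        m_j = z_perm.max(axis=1)
        exceed = int(np.sum(m_j >= M))
        p = exceed / m if estimator == "plain" else (exceed + 1) / (m + 1)

    return OPTPDTResult(
        set_name=set_name,
        thresholds=thresholds,
        n_markers=d_matrix.n_markers,
        n_informative_families=n_inf,
        selected=selected,
        Y={thr: float(y_obs[k]) for k, thr in enumerate(thresholds)},
        mu_hat={thr: float(mu[k]) for k, thr in enumerate(thresholds) if available[k]},
        sigma_hat={thr: float(sigma[k]) for k, thr in enumerate(thresholds) if available[k]},
        z_scores={thr: (float(z_obs[k]) if available[k] else None) for k, thr in enumerate(thresholds)},
        M=M,
        best_threshold=best,
        m=m,
        exceedances=exceed,
        p=float(p),
        min_attainable_p=(1.0 / m if estimator == "plain" else 1.0 / (m + 1)),
        seed=seed if isinstance(seed, int) else None,
        testable=True,
        estimator=estimator,
        mendelian_errors=d_matrix.mendelian_errors,
    )


def optpdt_test_exact(
    d_matrix: DMatrix,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    set_name: str = "set",
) -> OPTPDTResult:
    """Exhaustive-enumeration OPTPDT over all 2^N family sign vectors.

    Exact reference for small N (the identity sign vector is one of the
    enumerated permutations, so p >= 1/2^N).  Feasible up to N ~ 20.
    """
    thresholds = validate_thresholds(thresholds)
    n_fam = d_matrix.n_families
    if n_fam > 20:
        raise ValueError(f"exact enumeration over 2^{n_fam} sign vectors is not feasible")
    m = 2**n_fam
    signs = (((np.arange(m)[:, None] >> np.arange(n_fam)[None, :]) & 1) * 2 - 1).astype(np.float64)

    values = d_matrix.values
    ssq = d_matrix.column_ssq()
    n_inf = int(np.any(d_matrix.mask, axis=1).sum())
    if not np.any(ssq > 0):
        return _untestable_result(
            set_name, thresholds, d_matrix.n_markers, n_inf, m, "plain", None,
            d_matrix.mendelian_errors,
        )

    t2_obs, _ = d_matrix.t2_pvalues()
    crits = stats.chi2.isf(np.asarray(thresholds), df=1)
    selected = {}
    y_obs = np.empty(len(thresholds))
    for k, (thr, crit) in enumerate(zip(thresholds, crits)):
        idx = np.nonzero((ssq > 0) & (t2_obs > crit))[0]
        selected[thr] = [d_matrix.marker_ids[i] for i in idx]
        y_obs[k] = t2_obs[idx].sum()

    y_perm = _null_y_table(values, ssq, signs, crits)
    mu = y_perm.mean(axis=0)
    sigma = y_perm.std(axis=0, ddof=1)
    available = sigma > 0

    z_obs = np.full(len(thresholds), np.nan)
    z_obs[available] = (y_obs[available] - mu[available]) / sigma[available]

    all_empty = all(len(selected[thr]) == 0 for thr in thresholds)
    if not np.any(available) or all_empty:
        M, best, exceed, p = None, None, m, 1.0
    else:
        M = float(np.max(z_obs[available]))
        best = thresholds[int(np.nanargmax(np.where(available, z_obs, -np.inf)))]
        z_perm = (y_perm[:, available] - mu[available]) / sigma[available]
        exceed = int(np.sum(z_perm.max(axis=1) >= M))
        p = exceed / m

    return OPTPDTResult(
        set_name=set_name,
        thresholds=thresholds,
        n_markers=d_matrix.n_markers,
        n_informative_families=n_inf,
        selected=selected,
        Y={thr: float(y_obs[k]) for k, thr in enumerate(thresholds)},
        mu_hat={thr: float(mu[k]) for k, thr in enumerate(thresholds) if available[k]},
        sigma_hat={thr: float(sigma[k]) for k, thr in enumerate(thresholds) if available[k]},
        z_scores={thr: (float(z_obs[k]) if available[k] else None) for k, thr in enumerate(thresholds)},
        M=M,
        best_threshold=best,
        m=m,
        exceedances=exceed,
        p=float(p),
        min_attainable_p=1.0 / m,
        testable=True,
        estimator="exact",
        mendelian_errors=d_matrix.mendelian_errors,
    )


def _run_one_set(args) -> OPTPDTResult:
    study, snp_set, thresholds, m, seed, estimator = args
    dmat = build_d_matrix(study, snp_set)
    rng = derive_rng(seed, "set", snp_set.name)
    res = optpdt_test(dmat, thresholds, m=m, seed=rng, estimator=estimator, set_name=snp_set.name)
    res.seed = seed
    return res


def run_sets(
    study: StudyData,
    snp_sets: Sequence[SNPSet],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    m: int = 2000,
    seed: int = 0,
    workers: int = 1,
    estimator: str = "plain",
) -> list[OPTPDTResult]:
    """Run the OPTPDT over many SNP sets.

    Each set's RNG stream is derived from (seed, set name), so the output is
    identical for any worker count or execution order.
    """
    thresholds = validate_thresholds(thresholds)
    jobs = [(study, s, thresholds, m, seed, estimator) for s in snp_sets]
    if workers <= 1 or len(jobs) <= 1:
        return [_run_one_set(j) for j in jobs]
    with concurrent.futures.ProcessPoolExecutor(max_workers=workers) as pool:
        return list(pool.map(_run_one_set, jobs))
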