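"""Type-I-error and power experiments with comparator set-tests.

Every replicate simulates a fresh family sample from one scenario-level
haplotype pool and calibrated penetrance model, runs each requested method on
the *same* replicate (a paired design, so power differences are not
simulation-noise artifacts), and tallies rejections at the nominal levels
with exact Clopper-Pearson intervals.

Comparator methods:

* ``fixed_threshold`` — the single-threshold (default 0.05) special case of
  the variable-threshold engine, the documented stand-in for the PLINK-style
  set test;
* ``fisher`` / ``simes`` / ``minp`` — classical p-value combination tests on
  the per-SNP PDT p-values.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

from ._seeds import derive_rng
from .engine import DEFAULT_THRESHOLDS, OPTPDTResult, RngLike, optpdt_test
from .pdt_core import DMatrix, build_d_matrix
from .simulate import SimulationConfig, build_study_model, simulate_study_from_pool

DEFAULT_ALPHAS = (0.05, 0.01)

METHODS = ("optpdt", "fixed_threshold", "fisher", "simes", "minp")


@dataclass
class ExperimentResult:
    scenario: str
    method: str
    n_replicates: int
    alphas: tuple[float, ...]
    rejections: dict[float, int]
    rates: dict[float, float]
    intervals: dict[float, tuple[float, float]]  # 95% Clopper-Pearson
    p_values: Optional[np.ndarray] = None


def clopper_pearson(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval for k successes in n trials."""
    if not 0 <= k <= n or n < 1:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    tail = (1.0 - confidence) / 2.0
    lo = 0.0 if k == 0 else float(stats.beta.ppf(tail, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1.0 - tail, k + 1, n - k))
    return lo, hi


def _tally(scenario, method, pvals: np.ndarray, alphas) -> ExperimentResult:
    n = pvals.size
    rejections = {a: int(np.sum(pvals <= a)) for a in alphas}
    return ExperimentResult(
        scenario=scenario,
        method=method,
        n_replicates=n,
        alphas=tuple(alphas),
        rejections=rejections,
        rates={a: rejections[a] / n for a in alphas},
        intervals={a: clopper_pearson(rejections[a], n) for a in alphas},
        p_values=pvals,
    )


def fixed_threshold_test(
    d_matrix: DMatrix,
    threshold: float = 0.05,
    m: int = 2000,
    seed: RngLike = 0,
    set_name: str = "set",
) -> OPTPDTResult:
    """Single fixed-threshold sum test: the one-threshold special case of the engine."""
    return optpdt_test(d_matrix, thresholds=(threshold,), m=m, seed=seed, set_name=set_name)


def pvalue_combination_tests(p_values: Sequence[float]) -> dict[str, float]:
    """Fisher, Simes and Bonferroni-min-p combined p-values for a set of tests.

    Fisher: -2 sum(log p) against chi-square with 2n df.  Simes: min over the
    ordered p of n * p_(i) / i.  minp: n * min(p), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("p_values must be non-empty")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p_values must lie in (0, 1]")
    n = p.size
    fisher_stat = -2.0 * np.sum(np.log(p))
    fisher = float(stats.chi2.sf(fisher_stat, df=2 * n))
    ordered = np.sort(p)
    simes = float(np.min(n * ordered / np.arange(1, n + 1)))
    minp = float(min(1.0, n * ordered[0]))
    return {"fisher": fisher, "simes": min(simes, 1.0), "minp": minp}


def _method_pvalue(method: str, dmat: DMatrix, m: int, rng: np.random.Generator,
                   thresholds) -> float:
    if method == "optpdt":
        return optpdt_test(dmat, thresholds=thresholds, m=m, seed=rng).p
    if method == "fixed_threshold":
        return fixed_threshold_test(dmat, threshold=0.05, m=m, seed=rng).p
    if method in ("fisher", "simes", "minp"):
        _, p = dmat.t2_pvalues()
        testable = dmat.column_ssq() > 0
        if not np.any(testable):
            return 1.0
        return pvalue_combination_tests(p[testable])[method]
    raise ValueError(f"unknown method {method!r}; available: {METHODS}")


def _replicate_pvalues(
    sim_config: SimulationConfig,
    methods: Sequence[str],
    n_replicates: int,
    m: int,
    thresholds,
    seed: int,
    progress: Optional[Callable[[int], None]] = None,
) -> dict[str, np.ndarray]:
    pool, disease_model, _ = build_study_model(sim_config)
    out = {method: np.empty(n_replicates) for method in methods}
    for r in range(n_replicates):
        rng_fam = derive_rng(seed, "rep", r, "families")
        study, _ = simulate_study_from_pool(pool, disease_model, sim_config, rng_fam)
        dmat = build_d_matrix(study)
        for method in methods:
            rng_test = derive_rng(seed, "rep", r, "test", method)
            out[method][r] = _method_pvalue(method, dmat, m, rng_test, thresholds)
        if progress is not None:
            progress(r + 1)
    return out


def type_i_error_experiment(
    sim_config_null: SimulationConfig,
    n_replicates: int = 500,
    m: int = 1000,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    seed: int = 0,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    scenario: str = "null",
    progress: Optional[Callable[[int], None]] = None,
) -> ExperimentResult:
    """Empirical OPTPDT type I error under a null (no associated SNPs) scenario."""
    if n_replicates < 1:
        raise ValueError(f"n_replicates must be >= 1, got {n_replicates}")
    if sim_config_null.n_disease != 0 and sim_config_null.odds_ratio != 1.0:
        raise ValueError("type I error scenario must have no associated SNPs (all odds ratios 1)")
    pvals = _replicate_pvalues(
        sim_config_null, ["optpdt"], n_replicates, m, thresholds, seed, progress
    )["optpdt"]
    return _tally(scenario, "optpdt", pvals, alphas)


def power_experiment(
    sim_config_alt: SimulationConfig,
    methods: Sequence[str] = METHODS,
    n_replicates: int = 500,
    m: int = 1000,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    seed: int = 0,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    scenario: str = "power",
    progress: Optional[Callable[[int], None]] = None,
) -> list[ExperimentResult]:
    """Paired power comparison: every method sees the identical replicate studies."""
    if n_replicates < 1:
        raise ValueError(f"n_replicates must be >= 1, got {n_replicates}")
    for method in methods:
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}; available: {METHODS}")
    by_method = _replicate_pvalues(
        sim_config_alt, list(methods), n_replicates, m, thresholds, seed, progress
    )
    return [_tally(scenario, method, by_method[method], alphas) for method in methods]
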