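"""Synthetic nuclear-family GWAS data.

The generator mirrors a two-step family-study simulation: first a pool of
LD-structured haplotypes (a latent first-order autoregressive Gaussian
thresholded at per-marker quantiles, giving controllable minor-allele
frequencies and monotone LD decay), then random mating and gene dropping to
form families, with affection status drawn from a multi-locus logistic
penetrance P(Affected | X) = expit(alpha + B.X) whose intercept alpha is
calibrated so the population prevalence hits a target (default 5%).
Families are ascertained by rejection sampling until they match the
requested structure:

* ``nuclear`` — two genotyped parents, three sibs: one affected, two unaffected;
* ``triad`` — two genotyped parents, one affected child;
* ``discordant_sibship`` — parents missing, one affected and two unaffected sibs.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from ._seeds import derive_rng
from .famio import Child, Marker, NuclearFamily, SNPSet, StudyData

STRUCTURES = ("nuclear", "triad", "discordant_sibship")
MODELS = ("additive", "dominant", "recessive")

# Minor-allele frequencies used for designated disease SNPs when 5 or 10 are
# requested; arbitrary common-variant values otherwise.
DISEASE_MAFS_5 = (0.1, 0.13, 0.2, 0.4, 0.42)
DISEASE_MAFS_10 = (0.04, 0.05, 0.1, 0.1, 0.13, 0.2, 0.37, 0.4, 0.42, 0.43)


@dataclass
class HaplotypePool:
    haplotypes: np.ndarray  # (n_haplotypes, n_markers) uint8; 1 = minor allele
    maf_targets: np.ndarray
    rho: float
    block_starts: tuple[int, ...] = (0,)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]

    def empirical_mafs(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    def allelic_r2(self, i: int, j: int) -> float:
        """Squared allelic correlation between two markers across the pool."""
        a = self.haplotypes[:, i].astype(float)
        b = self.haplotypes[:, j].astype(float)
        if a.std() == 0 or b.std() == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1] ** 2)


@dataclass
class DiseaseModel:
    model: str  # additive | dominant | recessive
    disease_indices: np.ndarray  # marker column indices
    beta: np.ndarray  # per-disease-marker log odds ratios
    alpha: float
    prevalence: float

    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.beta)


@dataclass
class SimulationConfig:
    """Full generative description of one synthetic study."""

    n_families: int = 500
    structure: str = "triad"
    n_markers: int = 46
    n_genes: int = 1
    rho: float = 0.8
    n_haplotypes: int = 10_000
    model: str = "additive"
    odds_ratio: float = 1.0
    n_disease: int = 0
    disease_mafs: Optional[tuple[float, ...]] = None
    prevalence: float = 0.05
    maf_low: float = 0.05
    maf_high: float = 0.5
    r2_cap: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.structure not in STRUCTURES:
            raise ValueError(f"structure must be one of {STRUCTURES}, got {self.structure!r}")
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError(f"prevalence must be in (0, 1), got {self.prevalence}")
        if self.n_disease and self.disease_mafs is None:
            if self.n_disease == 5:
                self.disease_mafs = DISEASE_MAFS_5
            elif self.n_disease == 10:
                self.disease_mafs = DISEASE_MAFS_10
            else:
                raise ValueError("disease_mafs must be given when n_disease is not 5 or 10")
        if self.disease_mafs is not None and len(self.disease_mafs) != self.n_disease:
            raise ValueError("len(disease_mafs) must equal n_disease")


# Preset study scales: 46 SNPs in 1 gene, 1207 SNPs across 10 genes.
PRESETS: dict[str, SimulationConfig] = {
    "triad-1gene-null": SimulationConfig(n_families=500, structure="triad", n_markers=46, n_genes=1),
    "nuclear-1gene-null": SimulationConfig(n_families=500, structure="nuclear", n_markers=46, n_genes=1),
    "dsp-1gene-null": SimulationConfig(
        n_families=500, structure="discordant_sibship", n_markers=46, n_genes=1
    ),
    "triad-1gene-or1.2": SimulationConfig(
        n_families=500, structure="triad", n_markers=46, n_genes=1,
        odds_ratio=1.2, n_disease=5,
    ),
    "triad-10gene-null": SimulationConfig(n_families=500, structure="triad", n_markers=1207, n_genes=10),
    "triad-10gene-or1.2": SimulationConfig(
        n_families=500, structure="triad", n_markers=1207, n_genes=10,
        odds_ratio=1.2, n_disease=10,
    ),
}


def preset_config(name: str) -> SimulationConfig:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return replace(PRESETS[name])


# ---------------------------------------------------------------------------
# haplotype pool


def build_haplotype_pool(
    n_markers: int,
    maf_targets: Sequence[float],
    rho: float,
    n_haplotypes: int,
    rng: np.random.Generator,
    block_starts: Sequence[int] = (0,),
) -> HaplotypePool:
    """Draw haplotypes from a thresholded AR(1) latent Gaussian.

    Marker i carries the minor allele when its latent value falls below the
    normal quantile of maf_targets[i]; neighbouring latents have correlation
    rho (restarting at each block/gene boundary), so allelic LD decays
    geometrically with marker distance within a gene and vanishes across
    genes.
    """
    maf = np.asarray(maf_targets, dtype=float)
    if maf.shape != (n_markers,):
        raise ValueError("maf_targets must have one entry per marker")
    if np.any((maf <= 0) | (maf > 0.5)):
        raise ValueError("maf_targets must lie in (0, 0.5]")
    if not (0.0 <= rho < 1.0):
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    starts = set(block_starts)
    noise = rng.standard_normal((n_haplotypes, n_markers))
    z = np.empty_like(noise)
    scale = np.sqrt(1.0 - rho**2)
    for j in range(n_markers):
        if j in starts or j == 0:
            z[:, j] = noise[:, j]
        else:
            z[:, j] = rho * z[:, j - 1] + scale * noise[:, j]
    haplotypes = (z < norm.ppf(maf)[None, :]).astype(np.uint8)
    return HaplotypePool(haplotypes, maf, rho, tuple(sorted(starts | {0})))


# ---------------------------------------------------------------------------
# disease model


def genotype_code(genotype_count: int, model: str) -> int:
    """Risk-allele genotype coding: additive 0/1/2, dominant 0/1/1, recessive 0/0/1."""
    if genotype_count not in (0, 1, 2):
        raise ValueError(f"genotype_count must be 0, 1 or 2, got {genotype_count}")
    if model == "additive":
        return genotype_count
    if model == "dominant":
        return int(genotype_count > 0)
    if model == "recessive":
        return int(genotype_count == 2)
    raise ValueError(f"model must be one of {MODELS}, got {model!r}")


def _code_array(counts: np.ndarray, model: str) -> np.ndarray:
    if model == "additive":
        return counts.astype(np.float64)
    if model == "dominant":
        return (counts > 0).astype(np.float64)
    if model == "recessive":
        return (counts == 2).astype(np.float64)
    raise ValueError(f"model must be one of {MODELS}, got {model!r}")


def calibrate_intercept(
    pool: HaplotypePool,
    disease_indices: np.ndarray,
    beta: np.ndarray,
    model: str,
    prevalence: float,
    rng: np.random.Generator,
    n_samples: int = 200_000,
) -> float:
    """Solve the logistic intercept so the population prevalence hits the target.

    The population genotype distribution is random mating over the pool; the
    expectation is taken over a Monte-Carlo sample of genotype scores and the
    (monotone in alpha) equation E[expit(alpha + B.X)] = prevalence is solved
    by bracketed root finding.  With all effects zero the closed form
    alpha = logit(prevalence) is returned.
    """
    if not (0.0 < prevalence < 1.0):
        raise ValueError(f"prevalence must be in (0, 1), got {prevalence}")
    beta = np.asarray(beta, dtype=float)
    if beta.size == 0 or np.all(beta == 0.0):
        return float(logit(prevalence))
    idx = rng.integers(0, pool.n_haplotypes, size=(2, n_samples))
    counts = (
        pool.haplotypes[idx[0]][:, disease_indices].astype(np.int16)
        + pool.haplotypes[idx[1]][:, disease_indices]
    )
    scores = _code_array(counts, model) @ beta

    def residual(alpha: float) -> float:
        return float(np.mean(expit(alpha + scores))) - prevalence

    lo, hi = -40.0, 40.0
    if residual(lo) > 0 or residual(hi) < 0:
        raise RuntimeError(
            f"intercept calibration failed to bracket the root: "
            f"residual({lo})={residual(lo):.3g}, residual({hi})={residual(hi):.3g}"
        )
    return float(brentq(residual, lo, hi, xtol=1e-10))


def select_disease_markers(
    pool: HaplotypePool,
    n_disease: int,
    rng: np.random.Generator,
    maf_min: float = 0.01,
    r2_cap: float = 0.1,
) -> np.ndarray:
    """Randomly pick disease markers with MAF > maf_min and pairwise r^2 < r2_cap."""
    mafs = pool.empirical_mafs()
    candidates = np.nonzero(mafs > maf_min)[0]
    order = rng.permutation(candidates)
    chosen: list[int] = []
    for j in order:
        if all(pool.allelic_r2(int(j), i) < r2_cap for i in chosen):
            chosen.append(int(j))
            if len(chosen) == n_disease:
                return np.array(sorted(chosen))
    raise RuntimeError(
        f"could only find {len(chosen)} of {n_disease} disease markers with "
        f"MAF > {maf_min} and pairwise r^2 < {r2_cap}"
    )


# ---------------------------------------------------------------------------
# family generation


_STRUCTURE_CHILDREN = {"nuclear": 3, "triad": 1, "discordant_sibship": 3}


def _draw_family_batch(
    pool: HaplotypePool,
    structure: str,
    disease_model: DiseaseModel,
    n_families: int,
    rng: np.random.Generator,
    max_attempts_per_family: int = 1_000_000,
):
    """Rejection-sample families matching the structure's affected/unaffected counts.

    Returns (father_geno, mother_geno, child_geno, child_affected,
    acceptance_rate); genotypes are (n_families, n_markers) int8 arrays, child
    arrays have a leading per-child axis.
    """
    H = pool.haplotypes
    n_hap, n_markers = H.shape
    n_children = _STRUCTURE_CHILDREN[structure]
    didx = disease_model.disease_indices
    beta = disease_model.beta
    alpha = disease_model.alpha

    # expected acceptance probability under no-effect: used only for batch sizing
    prev = disease_model.prevalence
    rate_guess = prev if structure == "triad" else 3 * prev * (1 - prev) ** 2

    fa_out, mo_out, ch_out, aff_out = [], [], [], []
    got, attempts = 0, 0
    cap = max_attempts_per_family * n_families
    while got < n_families:
        if attempts >= cap:
            raise RuntimeError(
                f"family rejection sampling exceeded {cap} attempts "
                f"(acceptance rate so far {got / max(attempts, 1):.2e}); "
                "check the disease model configuration"
            )
        need = n_families - got
        batch = min(int(need / max(rate_guess, 1e-4) * 1.2) + 64, 2_000_000)
        attempts += batch

        idx = rng.integers(0, n_hap, size=(batch, 4))
        hap = H[idx]  # (batch, 4, n_markers)
        father = hap[:, 0] + hap[:, 1]
        mother = hap[:, 2] + hap[:, 3]

        # gene dropping: each child takes one haplotype from each parent
        pick = rng.integers(0, 2, size=(batch, n_children, 2))
        rows = np.arange(batch)[:, None]
        child = (
            hap[rows, pick[:, :, 0]]  # father's transmitted haplotype
            + hap[rows, 2 + pick[:, :, 1]]  # mother's
        ).astype(np.int16)  # (batch, n_children, n_markers)

        if didx.size:
            scores = _code_array(child[:, :, didx], disease_model.model) @ beta
        else:
            scores = np.zeros((batch, n_children))
        affected = rng.random((batch, n_children)) < expit(alpha + scores)

        if structure == "triad":
            keep = affected[:, 0]
        else:
            keep = affected.sum(axis=1) == 1
        kept = np.nonzero(keep)[0][: n_families - got]
        if kept.size:
            fa_out.append(father[kept].astype(np.int8))
            mo_out.append(mother[kept].astype(np.int8))
            ch_out.append(child[kept].astype(np.int8))
            aff_out.append(affected[kept])
            got += kept.size

    acceptance = n_families / attempts
    return (
        np.concatenate(fa_out),
        np.concatenate(mo_out),
        np.concatenate(ch_out),
        np.concatenate(aff_out),
        acceptance,
    )


def simulate_family(
    pool: HaplotypePool,
    structure: str,
    disease_model: DiseaseModel,
    rng: np.random.Generator,
) -> NuclearFamily:
    """Draw one ascertained family (see :func:`_draw_family_batch`)."""
    if structure not in STRUCTURES:
        raise ValueError(f"structure must be one of {STRUCTURES}, got {structure!r}")
    fa, mo, ch, aff, _ = _draw_family_batch(pool, structure, disease_model, 1, rng)
    return _build_family("F1", structure, fa[0], mo[0], ch[0], aff[0])


def _build_family(fid, structure, father, mother, children, affected) -> NuclearFamily:
    mask_parents = structure == "discordant_sibship"
    kids = [
        Child(f"{fid}_c{j + 1}", bool(affected[j]), children[j])
        for j in range(children.shape[0])
    ]
    return NuclearFamily(
        family_id=fid,
        father=None if mask_parents else father,
        mother=None if mask_parents else mother,
        children=kids,
        father_id=f"{fid}_f",
        mother_id=f"{fid}_m",
    )


# ---------------------------------------------------------------------------
# whole-study pipeline


def _maf_targets_for_config(config: SimulationConfig, rng: np.random.Generator):
    """Per-marker MAF targets with disease MAFs planted at spread-out indices."""
    maf = rng.uniform(config.maf_low, config.maf_high, size=config.n_markers)
    if config.n_disease:
        didx = np.round(
            (np.arange(config.n_disease) + 0.5) * config.n_markers / config.n_disease
        ).astype(int)
        maf[didx] = config.disease_mafs
    else:
        didx = np.array([], dtype=int)
    return maf, didx


def _gene_blocks(config: SimulationConfig) -> list[tuple[int, int]]:
    bounds = np.linspace(0, config.n_markers, config.n_genes + 1).astype(int)
    return [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]


def build_study_model(config: SimulationConfig) -> tuple[HaplotypePool, DiseaseModel, dict]:
    """Build the haplotype pool and calibrated disease model for a config.

    Split out from :func:`simulate_study` so experiment harnesses can reuse
    one pool across replicates (one haplotype panel, many family samples).
    """
    rng_pool = derive_rng(config.seed, "pool")
    rng_calib = derive_rng(config.seed, "calibrate")
    maf_targets, didx = _maf_targets_for_config(config, rng_pool)
    blocks = _gene_blocks(config)
    pool = build_haplotype_pool(
        config.n_markers,
        maf_targets,
        config.rho,
        config.n_haplotypes,
        rng_pool,
        block_starts=[a for a, _ in blocks],
    )
    beta = np.full(didx.size, np.log(config.odds_ratio))
    alpha = calibrate_intercept(pool, didx, beta, config.model, config.prevalence, rng_calib)
    disease_model = DiseaseModel(config.model, didx, beta, alpha, config.prevalence)

    emp = pool.empirical_mafs()
    truth = {
        "disease_marker_indices": didx.tolist(),
        "disease_marker_ids": [_marker_id(i) for i in didx],
        "odds_ratio": config.odds_ratio,
        "model": config.model,
        "alpha": alpha,
        "prevalence": config.prevalence,
        "maf_targets": maf_targets.tolist(),
        "empirical_disease_mafs": emp[didx].tolist(),
        "gene_blocks": blocks,
        "disease_pairwise_r2_max": max(
            (pool.allelic_r2(int(a), int(b)) for i, a in enumerate(didx) for b in didx[i + 1:]),
            default=0.0,
        ),
    }
    return pool, disease_model, truth


def _marker_id(i: int) -> str:
    return f"rs{i + 1:05d}"


def study_markers(config: SimulationConfig) -> list[Marker]:
    """Marker metadata: genes on chromosome 1, 2 kb marker spacing within a gene."""
    markers = []
    blocks = _gene_blocks(config)
    for g, (a, b) in enumerate(blocks):
        for j in range(a, b):
            pos = g * 1_000_000 + (j - a) * 2_000 + 1
            markers.append(Marker(_marker_id(j), "1", pos, allele1="A", allele2="G", counted_allele="A"))
    return markers


def gene_sets(config: SimulationConfig) -> list[SNPSet]:
    """One SNPSet per simulated gene block."""
    return [
        SNPSet(f"GENE{g + 1}", [_marker_id(j) for j in range(a, b)])
        for g, (a, b) in enumerate(_gene_blocks(config))
    ]


def simulate_study_from_pool(
    pool: HaplotypePool,
    disease_model: DiseaseModel,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[StudyData, float]:
    """Draw one study's families from an existing pool and calibrated model."""
    fa, mo, ch, aff, acceptance = _draw_family_batch(
        pool, config.structure, disease_model, config.n_families, rng
    )
    families = [
        _build_family(f"F{i + 1}", config.structure, fa[i], mo[i], ch[i], aff[i])
        for i in range(config.n_families)
    ]
    study = StudyData(
        markers=study_markers(config),
        families=families,
        provenance={"format": "simulated", "structure": config.structure},
    )
    return study, acceptance


def simulate_study(config: SimulationConfig) -> tuple[StudyData, dict]:
    """Generate a full synthetic study; returns (StudyData, truth record).

    The truth record lists the disease markers, effects, calibrated intercept
    and the achieved ascertainment acceptance rate.
    """
    pool, disease_model, truth = build_study_model(config)
    rng_fam = derive_rng(config.seed, "families")
    study, acceptance = simulate_study_from_pool(pool, disease_model, config, rng_fam)
    truth = dict(truth)
    truth.update(
        {
            "n_families": config.n_families,
            "structure": config.structure,
            "acceptance_rate": acceptance,
            "seed": config.seed,
        }
    )
    return study, truth
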