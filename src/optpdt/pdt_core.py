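"""The pedigree disequilibrium test (PDT).

Per-family transmission summaries at a SNP combine two sources of evidence:

* triads — an affected child with two genotyped parents, at least one of them
  heterozygous; the unit score is (counted alleles transmitted) minus
  (counted alleles not transmitted), which for genotype *counts* f, m, c is
  simply 2c - f - m;
* discordant sib pairs (DSPs) — an affected and an unaffected sibling with
  different genotypes; the unit score is the affected child's count minus the
  unaffected child's count.

A family's D is the average unit score over its informative triads and DSPs.
Across N families the PDT statistic is T^2 = (sum D_i)^2 / (sum D_i^2),
asymptotically chi-square with 1 df under the null of no linkage or no
association.  T^2 is squared, so it is invariant to which allele is counted.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .famio import MISSING, NuclearFamily, SNPSet, StudyData

# _CHILD_OK[f, m, c] is True when a child count c is Mendelian-consistent with
# parent counts f and m (a parent with count 0/2 transmits 0/1 copies, a het
# parent transmits either).
_CHILD_OK = np.zeros((3, 3, 3), dtype=bool)
for _f in range(3):
    for _m in range(3):
        _from_f = {0} if _f == 0 else {1} if _f == 2 else {0, 1}
        _from_m = {0} if _m == 0 else {1} if _m == 2 else {0, 1}
        for _a in _from_f:
            for _b in _from_m:
                _CHILD_OK[_f, _m, _a + _b] = True


@dataclass
class FamilyScore:
    """Transmission summary for one family at one SNP."""

    family_id: str
    n_T: int
    n_S: int
    X_T: int
    X_S: int
    informative: bool
    D: Optional[float]  # (X_T + X_S) / (n_T + n_S); None when uninformative


@dataclass
class PDTResult:
    marker_id: Optional[str]
    T2: float
    p: float
    n_informative: int


@dataclass
class DMatrix:
    """Families x markers matrix of family PDT scores, the permutation substrate.

    ``values`` holds D with 0 in masked (uninformative) cells; ``mask`` marks
    informative cells.  Columns with no informative family are untestable.
    """

    family_ids: list[str]
    marker_ids: list[str]
    values: np.ndarray  # (N, n) float64
    mask: np.ndarray  # (N, n) bool
    mendelian_errors: int = 0

    @property
    def n_families(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def column_ssq(self) -> np.ndarray:
        return np.einsum("ij,ij->j", self.values, self.values)

    def t2_pvalues(self) -> tuple[np.ndarray, np.ndarray]:
        """Observed per-marker T^2 and asymptotic chi-square(1) p-values."""
        ssq = self.column_ssq()
        sums = self.values.sum(axis=0)
        testable = ssq > 0
        t2 = np.zeros(self.n_markers)
        np.divide(sums**2, ssq, out=t2, where=testable)
        p = np.ones(self.n_markers)
        p[testable] = stats.chi2.sf(t2[testable], df=1)
        return t2, p


def triad_score(father_genotype: int, mother_genotype: int, child_genotype: int) -> tuple[bool, int]:
    """Unit triad score for an affected child with two genotyped parents.

    Returns (informative, x_t) with x_t = transmitted minus non-transmitted
    counted alleles over both meioses.  Missing genotypes or a Mendelian
    inconsistency make the triad uninformative.
    """
    f, m, c = father_genotype, mother_genotype, child_genotype
    if MISSING in (f, m, c):
        return False, 0
    if not _CHILD_OK[f, m, c]:
        return False, 0
    informative = f == 1 or m == 1
    x_t = 2 * c - f - m
    return informative, x_t if informative else 0


def dsp_score(affected_genotype: int, unaffected_genotype: int) -> tuple[bool, int]:
    """Unit DSP score: counted-allele count in the affected minus the unaffected sib.

    Informative only when both genotypes are observed and differ.
    """
    if MISSING in (affected_genotype, unaffected_genotype):
        return False, 0
    if affected_genotype == unaffected_genotype:
        return False, 0
    return True, affected_genotype - unaffected_genotype


def family_score(family: NuclearFamily, marker_index: int) -> FamilyScore:
    """Per-family transmission summary at one marker."""
    n_t = n_s = x_t_sum = x_s_sum = 0
    father = family.father
    mother = family.mother
    affected = [c for c in family.children if c.affected]
    unaffected = [c for c in family.children if not c.affected]

    if father is not None and mother is not None:
        f, m = int(father[marker_index]), int(mother[marker_index])
        for child in affected:
            ok, x = triad_score(f, m, int(child.genotypes[marker_index]))
            if ok:
                n_t += 1
                x_t_sum += x
    for a in affected:
        for u in unaffected:
            ok, x = dsp_score(int(a.genotypes[marker_index]), int(u.genotypes[marker_index]))
            if ok:
                n_s += 1
                x_s_sum += x

    informative = (n_t + n_s) > 0
    d = (x_t_sum + x_s_sum) / (n_t + n_s) if informative else None
    return FamilyScore(family.family_id, n_t, n_s, x_t_sum, x_s_sum, informative, d)


def pdt_statistic(d_values: Sequence[float], marker_id: Optional[str] = None) -> PDTResult:
    """The PDT statistic T^2 = (sum D)^2 / (sum D^2) over informative families.

    An empty list or all-zero denominator makes the marker untestable:
    T^2 = 0, p = 1.
    """
    d = np.asarray(d_values, dtype=float)
    ssq = float(np.sum(d * d))
    if d.size == 0 or ssq == 0.0:
        return PDTResult(marker_id, 0.0, 1.0, int(d.size))
    t2 = float(np.sum(d)) ** 2 / ssq
    return PDTResult(marker_id, t2, float(stats.chi2.sf(t2, df=1)), int(d.size))


def _family_row(family: NuclearFamily, column_indices: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorized family_score over the selected marker columns.

    Returns (d_row, informative_mask, n_mendelian_errors).
    """
    n = column_indices.size
    n_t = np.zeros(n, dtype=np.int32)
    n_s = np.zeros(n, dtype=np.int32)
    x_sum = np.zeros(n, dtype=np.int32)
    mendel = 0

    affected = [c.genotypes[column_indices] for c in family.children if c.affected]
    unaffected = [c.genotypes[column_indices] for c in family.children if not c.affected]

    if family.father is not None and family.mother is not None and affected:
        f = family.father[column_indices].astype(np.int64)
        m = family.mother[column_indices].astype(np.int64)
        parents_ok = (f >= 0) & (m >= 0)
        het = (f == 1) | (m == 1)
        for child in affected:
            c = child.astype(np.int64)
            present = parents_ok & (c >= 0)
            consistent = np.zeros(n, dtype=bool)
            idx = np.nonzero(present)[0]
            if idx.size:
                consistent[idx] = _CHILD_OK[f[idx], m[idx], c[idx]]
            mendel += int(np.sum(present & ~consistent))
            inf = present & consistent & het
            n_t += inf
            x_sum += np.where(inf, 2 * c - f - m, 0).astype(np.int32)

    for a in affected:
        ga = a.astype(np.int64)
        for u in unaffected:
            gu = u.astype(np.int64)
            inf = (ga >= 0) & (gu >= 0) & (ga != gu)
            n_s += inf
            x_sum += np.where(inf, ga - gu, 0).astype(np.int32)

    denom = n_t + n_s
    mask = denom > 0
    d = np.zeros(n)
    np.divide(x_sum, denom, out=d, where=mask)
    return d, mask, mendel


def build_d_matrix(study: StudyData, snp_set: Optional[SNPSet] = None) -> DMatrix:
    """Assemble the families x markers D matrix for a SNP set (default: all markers).

    Column-wise :func:`pdt_statistic` over unmasked cells reproduces the
    marker-by-marker PDT exactly.
    """
    if snp_set is None:
        cols = np.arange(study.n_markers)
        marker_ids = [m.id for m in study.markers]
    else:
        index = study.marker_index()
        unknown = [mid for mid in snp_set.marker_ids if mid not in index]
        if unknown:
            raise KeyError(f"set {snp_set.name}: markers not in study: {unknown}")
        cols = np.array([index[mid] for mid in snp_set.marker_ids], dtype=np.intp)
        marker_ids = list(snp_set.marker_ids)

    n_fam = study.n_families
    values = np.zeros((n_fam, cols.size))
    mask = np.zeros((n_fam, cols.size), dtype=bool)
    mendel = 0
    for i, fam in enumerate(study.families):
        d, inf, me = _family_row(fam, cols)
        values[i] = d
        mask[i] = inf
        mendel += me
    return DMatrix(
        family_ids=[f.family_id for f in study.families],
        marker_ids=marker_ids,
        values=values,
        mask=mask,
        mendelian_errors=mendel,
    )
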