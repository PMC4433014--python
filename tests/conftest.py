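"""Shared fixtures: hand-built families and small random studies."""
from __future__ import annotations

import numpy as np
import pytest

from optpdt.famio import Child, Marker, NuclearFamily, StudyData


def make_markers(n, prefix="rs"):
    return [
        Marker(f"{prefix}{i + 1}", "1", 1000 * (i + 1), allele1="A", allele2="G", counted_allele="A")
        for i in range(n)
    ]


def make_family(fid, father, mother, children, n_markers=None):
    """children: list of (affected, genotype list); parents: genotype list or None."""

    def vec(g):
        return None if g is None else np.asarray(g, dtype=np.int8)

    kids = [
        Child(f"{fid}_c{j + 1}", affected, np.asarray(g, dtype=np.int8))
        for j, (affected, g) in enumerate(children)
    ]
    return NuclearFamily(fid, vec(father), vec(mother), kids,
                         father_id=f"{fid}_f", mother_id=f"{fid}_m")


def make_study(families, n_markers):
    return StudyData(markers=make_markers(n_markers), families=families, provenance={})


def random_triad_study(rng, n_families, n_markers, maf=0.3):
    """Null triads drawn by direct gene dropping at independent markers."""
    fams = []
    for i in range(n_families):
        haps = (rng.random((4, n_markers)) < maf).astype(np.int8)
        father = haps[0] + haps[1]
        mother = haps[2] + haps[3]
        pick = rng.integers(0, 2, size=2)
        child = haps[pick[0]] + haps[2 + pick[1]]
        fams.append(make_family(f"F{i + 1}", father, mother, [(True, child)]))
    return make_study(fams, n_markers)


@pytest.fixture
def rng():
    return np.random.default_rng(20251)
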