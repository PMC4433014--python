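"""Pedigree/genotype I/O: PLINK PED/MAP and BED/BIM/FAM, SNP-set files, results.

Genotypes are stored internally as the number of copies of the *counted*
allele (0, 1, 2) with ``MISSING`` (-1) for no-calls.  Families are nuclear:
two (possibly ungenotyped) parents plus one or more phenotyped children.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

log = logging.getLogger(__name__)

MISSING = -1

BED_MAGIC = b"\x6c\x1b"
BED_SNP_MAJOR = b"\x01"


class ParseError(ValueError):
    """Malformed text input (PED/MAP/set file)."""


class FormatError(ValueError):
    """Binary file with wrong magic/mode or inconsistent payload size."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class Marker:
    """One biallelic SNP. ``counted_allele`` plays the role of A1 in the PDT."""

    id: str
    chromosome: str
    position: int
    allele1: str
    allele2: str
    counted_allele: str

    def other_allele(self) -> str:
        return self.allele2 if self.counted_allele == self.allele1 else self.allele1


@dataclass
class Child:
    id: str
    affected: bool
    genotypes: np.ndarray  # int8, counted-allele copies, MISSING allowed


@dataclass
class NuclearFamily:
    family_id: str
    father: Optional[np.ndarray]  # genotype vector or None if ungenotyped
    mother: Optional[np.ndarray]
    children: list[Child]
    father_id: str = "0"
    mother_id: str = "0"


@dataclass
class SNPSet:
    name: str
    marker_ids: list[str]


@dataclass
class StudyData:
    markers: list[Marker]
    families: list[NuclearFamily]
    provenance: dict = field(default_factory=dict)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_families(self) -> int:
        return len(self.families)

    def marker_index(self) -> dict[str, int]:
        return {m.id: i for i, m in enumerate(self.markers)}

    def missing_genotype_count(self) -> int:
        total = 0
        for fam in self.families:
            for vec in (fam.father, fam.mother):
                if vec is not None:
                    total += int(np.sum(vec == MISSING))
            for child in fam.children:
                total += int(np.sum(child.genotypes == MISSING))
        return total


# ---------------------------------------------------------------------------
# PED/MAP (text)


def _read_map(map_path) -> list[tuple[str, str, int]]:
    rows = []
    for lineno, line in enumerate(Path(map_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        tok = line.split()
        if len(tok) == 4:
            chrom, mid, _cm, pos = tok
        elif len(tok) == 3:
            chrom, mid, pos = tok
        else:
            raise ParseError(f"{map_path}: line {lineno}: expected 3 or 4 columns, got {len(tok)}")
        rows.append((chrom, mid, int(pos)))
    return rows


@dataclass
class _PedRow:
    fid: str
    iid: str
    pid: str
    mid: str
    sex: str
    phenotype: str
    alleles: list[tuple[str, str]]


def _parse_ped(ped_path, n_markers: int) -> list[_PedRow]:
    rows = []
    for lineno, line in enumerate(Path(ped_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        tok = line.split()
        if len(tok) != 6 + 2 * n_markers:
            raise ParseError(
                f"{ped_path}: line {lineno}: expected {6 + 2 * n_markers} fields "
                f"for {n_markers} markers, got {len(tok)}"
            )
        pairs = [(tok[6 + 2 * j], tok[7 + 2 * j]) for j in range(n_markers)]
        rows.append(_PedRow(*tok[:6], alleles=pairs))
    return rows


def _resolve_alleles(rows: Sequence[_PedRow], map_rows, path) -> list[Marker]:
    """Determine allele symbols per marker; counted allele = sample minor allele."""
    markers = []
    for j, (chrom, mid, pos) in enumerate(map_rows):
        counts: dict[str, int] = {}
        for row in rows:
            for a in row.alleles[j]:
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
        alleles = sorted(counts)
        if len(alleles) > 2:
            raise ParseError(f"{path}: marker {mid} has >2 alleles: {alleles}")
        if len(alleles) == 2:
            # minor by observed frequency; ties broken by sort order
            a, b = sorted(alleles, key=lambda x: (counts[x], x))
            markers.append(Marker(mid, chrom, pos, allele1=a, allele2=b, counted_allele=a))
        elif len(alleles) == 1:
            # monomorphic: counted allele absent from the sample
            markers.append(Marker(mid, chrom, pos, allele1="0", allele2=alleles[0], counted_allele="0"))
        else:
            markers.append(Marker(mid, chrom, pos, allele1="0", allele2="0", counted_allele="0"))
    return markers


def _genotype_vector(pairs: Sequence[tuple[str, str]], markers: Sequence[Marker]) -> np.ndarray:
    g = np.empty(len(markers), dtype=np.int8)
    for j, ((a, b), m) in enumerate(zip(pairs, markers)):
        if a == "0" or b == "0":
            g[j] = MISSING
        else:
            g[j] = (a == m.counted_allele) + (b == m.counted_allele)
    return g


def _assemble_families(rows: Sequence[_PedRow], markers: Sequence[Marker]) -> list[NuclearFamily]:
    by_fid: dict[str, list[_PedRow]] = {}
    for row in rows:
        by_fid.setdefault(row.fid, []).append(row)

    families: list[NuclearFamily] = []
    for fid, members in by_fid.items():
        ids = {r.iid: r for r in members}
        children = [r for r in members if r.pid != "0" or r.mid != "0"]
        if not children:
            log.warning("family %s has no individuals with declared parents; skipped", fid)
            continue
        parent_pairs = {(r.pid, r.mid) for r in children}
        if len(parent_pairs) > 1:
            raise ParseError(
                f"family {fid}: children declare multiple parent pairs {sorted(parent_pairs)}; "
                "only two-generation nuclear families are supported"
            )
        (pid, mid) = next(iter(parent_pairs))
        for parent_id in (pid, mid):
            parent_row = ids.get(parent_id)
            if parent_row is not None and (parent_row.pid != "0" or parent_row.mid != "0"):
                raise ParseError(
                    f"family {fid}: parent {parent_id} has declared parents of its own; "
                    "pedigrees deeper than two generations are not supported"
                )

        def parent_geno(parent_id: str) -> Optional[np.ndarray]:
            row = ids.get(parent_id)
            return None if row is None else _genotype_vector(row.alleles, markers)

        father, mother = parent_geno(pid), parent_geno(mid)
        if (father is None) != (mother is None):
            log.warning(
                "family %s: only one declared parent genotyped; the absent parent is "
                "treated as missing, so triads cannot be formed", fid,
            )

        kids = []
        for r in children:
            if r.phenotype == "2":
                affected = True
            elif r.phenotype == "1":
                affected = False
            else:
                log.warning("family %s: child %s has missing phenotype %r; dropped", fid, r.iid, r.phenotype)
                continue
            kids.append(Child(r.iid, affected, _genotype_vector(r.alleles, markers)))
        if not kids:
            log.warning("family %s has no phenotyped children; skipped", fid)
            continue
        families.append(NuclearFamily(fid, father, mother, kids, father_id=pid, mother_id=mid))
    return families


def read_plink_text(ped_path, map_path) -> StudyData:
    """Read a PLINK PED/MAP pair into a :class:`StudyData`.

    The counted allele at each marker defaults to the minor allele by observed
    sample frequency; "0" alleles are missing genotypes.
    """
    map_rows = _read_map(map_path)
    rows = _parse_ped(ped_path, len(map_rows))
    markers = _resolve_alleles(rows, map_rows, ped_path)
    families = _assemble_families(rows, markers)
    return StudyData(
        markers=markers,
        families=families,
        provenance={"format": "ped", "ped": str(ped_path), "map": str(map_path)},
    )


def _family_rows(study: StudyData) -> list[tuple[str, str, str, str, str, str, Optional[np.ndarray]]]:
    """(fid, iid, pid, mid, sex, phenotype, genotypes) rows in a stable order."""
    rows = []
    for fam in study.families:
        fid = fam.family_id
        pid = fam.father_id if fam.father_id != "0" else f"{fid}_f"
        mid = fam.mother_id if fam.mother_id != "0" else f"{fid}_m"
        if fam.father is not None:
            rows.append((fid, pid, "0", "0", "1", "1", fam.father))
        if fam.mother is not None:
            rows.append((fid, mid, "0", "0", "2", "1", fam.mother))
        for child in fam.children:
            rows.append((fid, child.id, pid, mid, "0", "2" if child.affected else "1", child.genotypes))
    return rows


def write_plink_text(study: StudyData, ped_path, map_path) -> None:
    """Write a StudyData as PLINK PED/MAP."""
    with open(map_path, "w") as fh:
        for m in study.markers:
            fh.write(f"{m.chromosome}\t{m.id}\t0\t{m.position}\n")
    with open(ped_path, "w") as fh:
        for fid, iid, pid, mid, sex, pheno, geno in _family_rows(study):
            fields = [fid, iid, pid, mid, sex, pheno]
            for g, m in zip(geno, study.markers):
                k, o = m.counted_allele, m.other_allele()
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 2:
                    fields += [k, k]
                elif g == 1:
                    fields += [k, o]
                else:
                    fields += [o, o]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# BED/BIM/FAM (binary, SNP-major v1.00)
#
# 2-bit codes per individual, LSB first within each byte:
#   00 homozygous A1 (counted allele, BIM col 5) -> 2 copies
#   01 missing
#   10 heterozygous -> 1 copy
#   11 homozygous A2 -> 0 copies

_CODE_TO_COUNT = np.array([2, MISSING, 1, 0], dtype=np.int8)
_COUNT_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def write_plink_binary(study: StudyData, bed_path, bim_path, fam_path) -> None:
    """Write StudyData as a PLINK .bed/.bim/.fam triple (SNP-major v1.00)."""
    rows = _family_rows(study)
    with open(bim_path, "w") as fh:
        for m in study.markers:
            fh.write(f"{m.chromosome}\t{m.id}\t0\t{m.position}\t{m.counted_allele}\t{m.other_allele()}\n")
    with open(fam_path, "w") as fh:
        for fid, iid, pid, mid, sex, pheno, _ in rows:
            fh.write(f"{fid} {iid} {pid} {mid} {sex} {pheno}\n")
    n_ind = len(rows)
    geno = np.stack([r[6] for r in rows]) if rows else np.zeros((0, study.n_markers), np.int8)
    with open(bed_path, "wb") as fh:
        fh.write(BED_MAGIC + BED_SNP_MAJOR)
        n_bytes = (n_ind + 3) // 4
        for j in range(study.n_markers):
            packed = bytearray(n_bytes)
            for i in range(n_ind):
                code = _COUNT_TO_CODE[int(geno[i, j])]
                packed[i // 4] |= code << (2 * (i % 4))
            fh.write(bytes(packed))


def read_plink_binary(bed_path, bim_path, fam_path) -> StudyData:
    """Read a PLINK BED/BIM/FAM triple; BIM column 5 is the counted allele."""
    markers = []
    for lineno, line in enumerate(Path(bim_path).read_text().splitlines(), start=1):
        tok = line.split()
        if len(tok) != 6:
            raise ParseError(f"{bim_path}: line {lineno}: expected 6 columns, got {len(tok)}")
        chrom, mid, _cm, pos, a1, a2 = tok
        markers.append(Marker(mid, chrom, int(pos), allele1=a1, allele2=a2, counted_allele=a1))

    fam_rows = []
    for lineno, line in enumerate(Path(fam_path).read_text().splitlines(), start=1):
        tok = line.split()
        if len(tok) != 6:
            raise ParseError(f"{fam_path}: line {lineno}: expected 6 columns, got {len(tok)}")
        fam_rows.append(tok)

    n_ind, n_markers = len(fam_rows), len(markers)
    payload = Path(bed_path).read_bytes()
    if payload[:2] != BED_MAGIC:
        raise FormatError(f"{bed_path}: not a PLINK BED file (bad magic bytes)")
    if payload[2:3] != BED_SNP_MAJOR:
        raise FormatError(f"{bed_path}: only SNP-major (mode 0x01) BED files are supported")
    n_bytes = (n_ind + 3) // 4
    expected = 3 + n_bytes * n_markers
    if len(payload) != expected:
        raise FormatError(
            f"{bed_path}: payload size {len(payload)} does not match {n_ind} individuals "
            f"x {n_markers} markers (expected {expected}); file truncated or corrupt"
        )

    raw = np.frombuffer(payload, dtype=np.uint8, offset=3).reshape(n_markers, n_bytes)
    # unpack 2-bit codes, LSB first
    codes = np.stack([(raw >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2)
    codes = codes.reshape(n_markers, n_bytes * 4)[:, :n_ind]
    geno = _CODE_TO_COUNT[codes]  # (n_markers, n_ind)

    rows = [
        _PedRow(fid, iid, pid, mid, sex, pheno, alleles=[])
        for fid, iid, pid, mid, sex, pheno in fam_rows
    ]
    geno_by_iid = {(r.fid, r.iid): geno[:, i].astype(np.int8) for i, r in enumerate(rows)}

    # reuse the PED family assembly with direct genotype vectors
    families = _assemble_families_binary(rows, geno_by_iid)
    return StudyData(
        markers=markers,
        families=families,
        provenance={"format": "bed", "bed": str(bed_path), "bim": str(bim_path), "fam": str(fam_path)},
    )


def _assemble_families_binary(rows, geno_by_iid) -> list[NuclearFamily]:
    for r in rows:
        r.alleles = geno_by_iid[(r.fid, r.iid)]  # reuse the slot for the vector

    by_fid: dict[str, list[_PedRow]] = {}
    for row in rows:
        by_fid.setdefault(row.fid, []).append(row)

    families = []
    for fid, members in by_fid.items():
        ids = {r.iid: r for r in members}
        children = [r for r in members if r.pid != "0" or r.mid != "0"]
        if not children:
            log.warning("family %s has no individuals with declared parents; skipped", fid)
            continue
        parent_pairs = {(r.pid, r.mid) for r in children}
        if len(parent_pairs) > 1:
            raise ParseError(
                f"family {fid}: children declare multiple parent pairs; "
                "only two-generation nuclear families are supported"
            )
        pid, mid = next(iter(parent_pairs))
        for parent_id in (pid, mid):
            prow = ids.get(parent_id)
            if prow is not None and (prow.pid != "0" or prow.mid != "0"):
                raise ParseError(
                    f"family {fid}: parent {parent_id} has declared parents; "
                    "pedigrees deeper than two generations are not supported"
                )
        father = ids[pid].alleles if pid in ids else None
        mother = ids[mid].alleles if mid in ids else None
        kids = []
        for r in children:
            if r.phenotype == "2":
                affected = True
            elif r.phenotype == "1":
                affected = False
            else:
                log.warning("family %s: child %s has missing phenotype; dropped", fid, r.iid)
                continue
            kids.append(Child(r.iid, affected, r.alleles))
        if not kids:
            continue
        families.append(NuclearFamily(fid, father, mother, kids, father_id=pid, mother_id=mid))
    return families


# ---------------------------------------------------------------------------
# SNP sets


def read_snp_sets(set_path, markers: Sequence[Marker], set_format: Optional[str] = None) -> list[SNPSet]:
    """Read SNP-set definitions (PLINK --set dialect or two-column gene/marker TSV).

    Marker IDs absent from ``markers`` are dropped; sets that become empty are
    dropped with a warning.  ``set_format`` may be "plink" or "tsv" to skip
    autodetection.
    """
    text = Path(set_path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if set_format is None:
        tokens = text.split()
        if "END" in tokens:
            set_format = "plink"
        elif all(len(ln.split()) == 2 for ln in lines):
            set_format = "tsv"
        else:
            raise ParseError(f"{set_path}: cannot autodetect set-file format (no END terminator, not 2-column)")

    raw: list[tuple[str, list[str]]] = []
    if set_format == "plink":
        current: Optional[str] = None
        members: list[str] = []
        for tok in text.split():
            if current is None:
                current = tok
                members = []
            elif tok == "END":
                raw.append((current, members))
                current = None
            else:
                members.append(tok)
        if current is not None:
            raise ParseError(f"{set_path}: set block {current!r} not terminated by END")
    elif set_format == "tsv":
        order: dict[str, list[str]] = {}
        for lineno, ln in enumerate(lines, start=1):
            tok = ln.split()
            if len(tok) != 2:
                raise ParseError(f"{set_path}: line {lineno}: expected 2 columns")
            order.setdefault(tok[0], []).append(tok[1])
        raw = list(order.items())
    else:
        raise ValueError(f"unknown set_format {set_format!r}")

    names = [name for name, _ in raw]
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ParseError(f"{set_path}: duplicate set names {dupes}")

    known = {m.id for m in markers}
    sets, n_dropped = [], 0
    for name, member_ids in raw:
        seen: list[str] = []
        for mid in member_ids:
            if mid in known and mid not in seen:
                seen.append(mid)
        missing = len(member_ids) - len(seen)
        if missing:
            log.warning("set %s: %d marker(s) not in the study data; dropped", name, missing)
        if not seen:
            log.warning("set %s is empty after filtering; dropped", name)
            n_dropped += 1
            continue
        sets.append(SNPSet(name, seen))
    if n_dropped:
        log.warning("%d set(s) dropped as empty", n_dropped)
    return sets


def sets_from_intervals(
    intervals: Iterable[tuple[str, str, int, int]],
    markers: Sequence[Marker],
    padding: int = 0,
) -> list[SNPSet]:
    """Assign markers to genes by position: 1-based closed interval membership.

    ``intervals`` are (name, chromosome, start, end); ``padding`` widens each
    interval symmetrically.  Empty sets are dropped with a warning.
    """
    sets = []
    for name, chrom, start, end in intervals:
        ids = [
            m.id
            for m in markers
            if m.chromosome == chrom and start - padding <= m.position <= end + padding
        ]
        if not ids:
            log.warning("gene %s: no markers in [%d, %d]; dropped", name, start, end)
            continue
        sets.append(SNPSet(name, ids))
    return sets


# ---------------------------------------------------------------------------
# results output


RESULT_COLUMNS = ["SET", "NSNPS", "THRESHOLD", "M", "P", "P_DISPLAY", "MIN_P"]


def write_results(results: Sequence, out_path, thresholds: Optional[Sequence[float]] = None) -> None:
    """Write engine results as a TSV, one row per set, in input order.

    ``results`` are objects exposing set_name, n_markers, best_threshold, M, p,
    m and z_scores (threshold -> Z or None).  A p of exactly 0 additionally
    gets a "<1/m" sentinel in P_DISPLAY so the resolution is explicit.
    """
    if thresholds is None:
        thresholds = results[0].thresholds if results else ()
    header = RESULT_COLUMNS + [f"Z_{k:g}" for k in thresholds]
    with open(out_path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for res in results:
            min_p = 1.0 / res.m if res.m else math.nan
            display = f"<{min_p:.6e}" if res.p == 0 else f"{res.p:.6e}"
            row = [
                res.set_name,
                str(res.n_markers),
                "NA" if res.best_threshold is None else f"{res.best_threshold:g}",
                "NA" if res.M is None else f"{res.M:.6g}",
                f"{res.p:.6e}",
                display,
                f"{min_p:.6e}",
            ]
            for k in thresholds:
                z = res.z_scores.get(k)
                row.append("NA" if z is None else f"{z:.6g}")
            fh.write("\t".join(row) + "\n")
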