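"""Labeled biallelic genotype tables and PLINK text PED/MAP / CSV readers.

The in-memory model is :class:`GenotypeTable`: diploid, biallelic,
unphased genotypes coded as insertion (1) / deletion (0) alleles, with a
per-sample population label and a population -> superpopulation (continental
group) mapping.  This is the universal input for every downstream analysis.

Allele codes follow the forensic InDel convention of recoding the insertion
sequence to allele 1 and the deletion sequence to allele 0; PED files carry
arbitrary allele strings and are recoded through an explicit ``allele_map``.
Missing alleles are the PED code ``"0"`` on disk and the sentinel
:data:`MISSING` (= -1) in memory.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "LocusInfo",
    "GenotypeTable",
    "GenotypeFormatError",
    "AlleleRecodingError",
    "read_ped_map",
    "write_ped_map",
    "read_csv_genotypes",
    "write_csv_genotypes",
    "read_label_maps",
]

#: Sentinel allele code for a missing allele. Valid codes are 0 and 1.
MISSING: int = -1


class GenotypeFormatError(ValueError):
    """Malformed PED/MAP/CSV input (column counts, locus mismatch...)."""


class AlleleRecodingError(ValueError):
    """An allele string could not be mapped to {0, 1}."""


@dataclass(frozen=True)
class LocusInfo:
    """One biallelic InDel locus as described by a MAP-file row."""

    locus_id: str
    chromosome: str = "0"
    position: int = 0


@dataclass
class GenotypeTable:
    """Individuals x loci diploid biallelic genotypes with population labels.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, length ``n_samples``.
    population
        Per-sample population label (e.g. ``"GNT"``, ``"CHB"``).
    superpopulation
        Per-sample continental label (e.g. ``"EAS"``).  Each population must
        map to exactly one superpopulation.
    loci
        Ordered loci.
    genotypes
        ``(n_samples, n_loci, 2)`` int8 array over {0, 1, MISSING}.  Phase is
        ignored; genotypes are stored as unordered pairs (capillary
        electrophoresis genotypes carry no phase).
    """

    sample_ids: list[str]
    population: list[str]
    superpopulation: list[str]
    loci: list[LocusInfo]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.validate()

    # -- contracts ---------------------------------------------------------
    def validate(self) -> None:
        n, m = len(self.sample_ids), len(self.loci)
        if self.genotypes.shape != (n, m, 2):
            raise GenotypeFormatError(
                f"genotype array shape {self.genotypes.shape} != {(n, m, 2)}"
            )
        if len(self.population) != n or len(self.superpopulation) != n:
            raise GenotypeFormatError("label lengths do not match sample count")
        if len(set(self.sample_ids)) != n:
            raise GenotypeFormatError("sample_ids are not unique")
        ids = [l.locus_id for l in self.loci]
        if len(set(ids)) != m:
            raise GenotypeFormatError("locus_ids are not unique")
        ok = np.isin(self.genotypes, (0, 1, MISSING))
        if not ok.all():
            bad = np.unique(self.genotypes[~ok])
            raise GenotypeFormatError(f"invalid allele codes {bad.tolist()}")
        pop2sup: dict[str, str] = {}
        for p, s in zip(self.population, self.superpopulation):
            if pop2sup.setdefault(p, s) != s:
                raise GenotypeFormatError(
                    f"population {p!r} maps to multiple superpopulations"
                )

    # -- convenience -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    def population_to_superpopulation(self) -> dict[str, str]:
        return dict(zip(self.population, self.superpopulation))

    def dosage(self) -> np.ndarray:
        """Insertion-allele dosage matrix ``(n_samples, n_loci)``.

        Non-missing genotypes give the count of 1-alleles in {0, 1, 2};
        genotypes with any missing allele give ``nan``.
        """
        g = self.genotypes
        d = g.sum(axis=2).astype(float)
        d[(g == MISSING).any(axis=2)] = np.nan
        return d

    def subset_samples(self, index: Sequence[int]) -> "GenotypeTable":
        idx = list(index)
        return GenotypeTable(
            sample_ids=[self.sample_ids[i] for i in idx],
            population=[self.population[i] for i in idx],
            superpopulation=[self.superpopulation[i] for i in idx],
            loci=list(self.loci),
            genotypes=self.genotypes[idx].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.population == other.population
            and self.superpopulation == other.superpopulation
            and self.loci == other.loci
            and np.array_equal(self.genotypes, other.genotypes)
        )


# ---------------------------------------------------------------------------
# PLINK text PED/MAP
# ---------------------------------------------------------------------------

def _read_map(map_path: Path) -> list[LocusInfo]:
    loci = []
    for line in Path(map_path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise GenotypeFormatError(f"map row has {len(parts)} fields, need 4")
        chrom, locus_id, _gdist, pos = parts[:4]
        loci.append(LocusInfo(locus_id=locus_id, chromosome=chrom, position=int(pos)))
    ids = [l.locus_id for l in loci]
    if len(set(ids)) != len(ids):
        raise GenotypeFormatError("duplicate locus ids in map file")
    return loci


def read_ped_map(
    ped_path: str | Path,
    map_path: str | Path,
    allele_map: Mapping[str, int],
    labels: Mapping[str, str] | None = None,
    superpopulations: Mapping[str, str] | None = None,
) -> GenotypeTable:
    """Read a whitespace-delimited PED/MAP pair, recoding alleles to {0, 1}.

    The PED dialect is 6 leading metadata columns (family, individual,
    father, mother, sex, phenotype) followed by two allele columns per MAP
    locus.  ``allele_map`` sends each allele string (e.g. ``"I"``/``"D"`` or
    the raw sequences) to 1 (insertion) or 0 (deletion); the PED missing
    code ``"0"`` becomes :data:`MISSING`.

    Population labels are not part of PED; pass ``labels`` (sample id ->
    population) and ``superpopulations`` (population -> superpopulation), or
    omit both to label everything ``"UNK"``.
    """
    for v in allele_map.values():
        if v not in (0, 1):
            raise AlleleRecodingError(f"allele_map values must be 0/1, got {v!r}")
    loci = _read_map(Path(map_path))
    n_loci = len(loci)
    sample_ids: list[str] = []
    rows: list[list[int]] = []
    for line in Path(ped_path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * n_loci:
            raise GenotypeFormatError(
                f"ped row has {len(parts) - 6} allele columns for {n_loci} map loci"
            )
        sid = parts[1]
        alleles: list[int] = []
        for j, tok in enumerate(parts[6:]):
            if tok == "0":
                alleles.append(MISSING)
            elif tok in allele_map:
                alleles.append(allele_map[tok])
            else:
                raise AlleleRecodingError(
                    f"allele {tok!r} at locus {loci[j // 2].locus_id} "
                    f"(sample {sid}) not in allele_map"
                )
        sample_ids.append(sid)
        rows.append(alleles)
    geno = (
        np.asarray(rows, dtype=np.int8).reshape(len(rows), n_loci, 2)
        if rows
        else np.empty((0, n_loci, 2), dtype=np.int8)
    )
    # half-missing genotypes are uninterpretable: treat the genotype as missing
    half = (geno == MISSING).any(axis=2) & ~(geno == MISSING).all(axis=2)
    geno[half] = MISSING
    labels = labels or {}
    pops = [labels.get(s, "UNK") for s in sample_ids]
    sups = [(superpopulations or {}).get(p, "UNK") for p in pops]
    return GenotypeTable(sample_ids, pops, sups, loci, geno)


def write_ped_map(
    table: GenotypeTable, ped_path: str | Path, map_path: str | Path
) -> None:
    """Write a PED/MAP pair readable by :func:`read_ped_map`.

    Alleles are serialized as ``"I"`` (insertion) / ``"D"`` (deletion) and
    missing as ``"0"``; ``read_ped_map(..., allele_map={"I": 1, "D": 0})``
    round-trips the table exactly.
    """
    with open(map_path, "w") as fh:
        for l in table.loci:
            fh.write(f"{l.chromosome}\t{l.locus_id}\t0\t{l.position}\n")
    code = {1: "I", 0: "D", MISSING: "0"}
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(table.sample_ids):
            fields = [sid, sid, "0", "0", "0", "-9"]
            g = table.genotypes[i]
            for j in range(table.n_loci):
                a, b = int(g[j, 0]), int(g[j, 1])
                if MISSING in (a, b):  # ped convention: whole genotype "0 0"
                    a = b = MISSING
                fields += [code[a], code[b]]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# CSV dosage table
# ---------------------------------------------------------------------------

def read_csv_genotypes(csv_path: str | Path) -> GenotypeTable:
    """Read a CSV dosage table into a :class:`GenotypeTable`.

    Expected columns: ``sample_id, population, superpopulation`` then one
    column per locus holding the insertion-allele dosage in {0, 1, 2, NA}.
    Dosage ``d`` expands to the unordered pair with ``d`` insertion alleles;
    NA becomes a fully missing genotype.
    """
    df = pd.read_csv(csv_path, dtype={"sample_id": str, "population": str,
                                      "superpopulation": str})
    meta = ["sample_id", "population", "superpopulation"]
    if df.columns[:3].tolist() != meta:
        raise GenotypeFormatError(f"first three columns must be {meta}")
    locus_cols = df.columns[3:].tolist()
    dos = df[locus_cols].to_numpy(dtype=float)
    bad = ~(np.isnan(dos) | np.isin(dos, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"dosage {dos[i, j]!r} at sample {df['sample_id'].iloc[i]!r}, "
            f"locus {locus_cols[j]!r} not in {{0,1,2,NA}}"
        )
    n, m = dos.shape
    geno = np.full((n, m, 2), MISSING, dtype=np.int8)
    known = ~np.isnan(dos)
    # dosage d -> pair with d ones, written as (first allele, second allele)
    geno[..., 0] = np.where(known & (dos == 2), 1, np.where(known, 0, MISSING))
    geno[..., 1] = np.where(known & (dos >= 1), 1, np.where(known, 0, MISSING))
    loci = [LocusInfo(locus_id=c) for c in locus_cols]
    return GenotypeTable(
        df["sample_id"].tolist(),
        df["population"].tolist(),
        df["superpopulation"].tolist(),
        loci,
        geno,
    )


def write_csv_genotypes(table: GenotypeTable, csv_path: str | Path) -> None:
    """Write the CSV dosage form read by :func:`read_csv_genotypes`."""
    d = table.dosage()
    df = pd.DataFrame(d, columns=table.locus_ids)
    df = df.astype("Int64")
    df.insert(0, "superpopulation", table.superpopulation)
    df.insert(0, "population", table.population)
    df.insert(0, "sample_id", table.sample_ids)
    df.to_csv(csv_path, index=False)


def read_label_maps(
    sample_pop_tsv: str | Path, pop_super_tsv: str | Path
) -> tuple[dict[str, str], dict[str, str]]:
    """Read the two two-column TSV label maps used alongside PED files.

    Returns ``(sample_id -> population, population -> superpopulation)``.
    """
    def _two_col(path: str | Path) -> dict[str, str]:
        out: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            k, v = line.split("\t")[:2]
            out[k.strip()] = v.strip()
        return out

    return _two_col(sample_pop_tsv), _two_col(pop_super_tsv)
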