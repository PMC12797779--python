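"""Allele frequencies, HWE/LD screening and forensic parameters.

Implements the locus-screening and panel-characterisation statistics used
for forensic biallelic InDel panels:

* per-population insertion-allele frequencies (:class:`LocusFrequencies`);
* the exact Hardy-Weinberg test conditioning on allele counts (the Levene
  distribution for a biallelic locus);
* a permutation test of pairwise linkage disequilibrium on the squared
  dosage correlation (a Burrows composite-LD style statistic that needs no
  phase information);
* Bonferroni thresholds for the two screens;
* the forensic parameter suite Ho, He, PIC, MP, PD, PE and the panel-level
  cumulative powers CPD and CPE.

Conventions (documented because the statistics literature varies): He uses
Nei's unbiased small-sample correction 2n/(2n-1); MP is the sum of squared
*observed* genotype frequencies; PE is Brenner's trio-exclusion formula on
observed heterozygosity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import MISSING, GenotypeTable

__all__ = [
    "LocusFrequencies",
    "TestResult",
    "ForensicLocusParams",
    "allele_frequencies",
    "genotype_counts",
    "hwe_exact_test",
    "ld_test",
    "forensic_params",
    "forensic_param_table",
    "cumulative_power",
    "bonferroni",
    "hwe_test_table",
    "ld_test_table",
]


# ---------------------------------------------------------------------------
# Frequencies
# ---------------------------------------------------------------------------

class LocusFrequencies:
    """Per-(population, locus) insertion-allele frequency and sample size.

    Thin wrapper around a long-format DataFrame with columns
    ``population, locus_id, p_ins, n`` (n = diploid individuals with a
    non-missing genotype).  The deletion-allele frequency is ``1 - p_ins``.
    """

    COLUMNS = ["population", "locus_id", "p_ins", "n"]

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"frequency table lacks columns {missing}")
        df = df[self.COLUMNS].copy()
        if ((df["p_ins"] < 0) | (df["p_ins"] > 1)).any():
            raise ValueError("p_ins outside [0, 1]")
        if (df["n"] < 1).any():
            raise ValueError("sample size n < 1")
        self.df = df.reset_index(drop=True)

    # -- access ------------------------------------------------------------
    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.df["population"]))

    @property
    def locus_ids(self) -> list[str]:
        return list(dict.fromkeys(self.df["locus_id"]))

    def matrix(self) -> pd.DataFrame:
        """Populations x loci matrix of insertion frequencies."""
        m = self.df.pivot(index="population", columns="locus_id", values="p_ins")
        return m.reindex(index=self.populations, columns=self.locus_ids)

    def for_population(self, population: str) -> pd.Series:
        """Insertion frequencies of one population, indexed by locus."""
        sub = self.df[self.df["population"] == population]
        if sub.empty:
            raise KeyError(f"population {population!r} not in frequency table")
        return sub.set_index("locus_id")["p_ins"].reindex(self.locus_ids)

    def mean_by_group(self, group_of: dict[str, str]) -> "LocusFrequencies":
        """Collapse populations into groups by unweighted mean frequency."""
        df = self.df.copy()
        df["group"] = df["population"].map(group_of)
        df = df.dropna(subset=["group"])
        out = (
            df.groupby(["group", "locus_id"], sort=False)
            .agg(p_ins=("p_ins", "mean"), n=("n", "sum"))
            .reset_index()
            .rename(columns={"group": "population"})
        )
        return LocusFrequencies(out)

    # -- serialization -----------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, path: str | Path) -> "LocusFrequencies":
        return cls(pd.read_csv(path))


def allele_frequencies(
    table: GenotypeTable, group_by: Literal["population", "superpopulation"] = "population"
) -> LocusFrequencies:
    """Insertion-allele frequencies per (group, locus).

    Missing genotypes are excluded from the sample size ``n``.  A (group,
    locus) cell with no non-missing genotype is excluded with a warning.
    """
    labels = np.asarray(getattr(table, group_by))
    d = table.dosage()  # nan where missing
    rows = []
    for g in dict.fromkeys(labels):
        sub = d[labels == g]
        n = np.sum(~np.isnan(sub), axis=0)
        with np.errstate(invalid="ignore"):
            p = np.nansum(sub, axis=0) / (2 * n)
        for j, locus in enumerate(table.locus_ids):
            if n[j] == 0:
                warnings.warn(
                    f"no non-missing genotypes for ({g}, {locus}); cell excluded"
                )
                continue
            rows.append((g, locus, float(p[j]), int(n[j])))
    return LocusFrequencies(pd.DataFrame(rows, columns=LocusFrequencies.COLUMNS))


def genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    """(n_II, n_ID, n_DD) from a dosage vector, ignoring NaN."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    return int((d == 2).sum()), int((d == 1).sum()), int((d == 0).sum())


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestResult:
    """Outcome of one HWE or LD test with its Bonferroni screen."""

    statistic: float
    p_value: float
    bonferroni_alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.bonferroni_alpha


def _levene_log_pmf(n: int, n_ins: int) -> tuple[np.ndarray, np.ndarray]:
    """Log pmf of the heterozygote count given allele counts (exact HWE null).

    P(n_het | n_ins, n) = n! 2^n_het n_ins! n_del! / (n_II! n_het! n_DD! (2n)!)
    over heterozygote counts with the parity of n_ins, admissible for the
    allele counts.  Returns (het_counts, log_probs).
    """
    n_del = 2 * n - n_ins
    h_max = min(n_ins, n_del)
    hs = np.arange(n_ins % 2, h_max + 1, 2)
    n_II = (n_ins - hs) // 2
    n_DD = (n_del - hs) // 2
    logp = (
        gammaln(n + 1)
        + hs * math.log(2)
        + gammaln(n_ins + 1)
        + gammaln(n_del + 1)
        - gammaln(n_II + 1)
        - gammaln(hs + 1)
        - gammaln(n_DD + 1)
        - gammaln(2 * n + 1)
    )
    return hs, logp


def hwe_exact_test(
    n_II: int, n_ID: int, n_DD: int, bonferroni_alpha: float = 0.05
) -> TestResult:
    """Exact two-sided Hardy-Weinberg test for a biallelic locus.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose exact-null probability does not exceed
    that of the observed count (the standard two-sided exact-test
    convention).  The statistic reported is the observed heterozygote count.
    """
    if min(n_II, n_ID, n_DD) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_II + n_ID + n_DD
    if n < 1:
        raise ValueError("at least one genotype required")
    n_ins = 2 * n_II + n_ID
    if n_ins in (0, 2 * n):  # monomorphic: the observed table is the only one
        return TestResult(float(n_ID), 1.0, bonferroni_alpha)
    hs, logp = _levene_log_pmf(n, n_ins)
    p_obs = logp[hs == n_ID][0]
    # tolerance guards against log-space ties broken by rounding
    keep = logp <= p_obs + 1e-9
    p = float(np.exp(logp[keep]).sum())
    return TestResult(float(n_ID), min(p, 1.0), bonferroni_alpha)


def ld_test(
    dosages_a: Sequence[float],
    dosages_b: Sequence[float],
    n_perm: int = 9999,
    seed: int | None = None,
    bonferroni_alpha: float = 0.05,
) -> TestResult:
    """Permutation test of linkage disequilibrium between two loci.

    The statistic is ``n * r^2`` where ``r`` is the Pearson correlation of
    insertion-allele dosages over individuals typed at both loci (a
    composite-LD statistic that requires no phase).  The p-value is the
    permutation p over ``n_perm`` random re-pairings,
    ``p = (1 + #{perm >= observed}) / (1 + n_perm)``.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors differ in length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    n = a.size
    if n < 2:
        raise ValueError("need >= 2 jointly typed individuals")
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero dosage variance at one locus; LD undefined, p = 1")
        return TestResult(0.0, 1.0, bonferroni_alpha)
    rng = np.random.default_rng(seed)

    ac = a - a.mean()
    bc = b - b.mean()
    ss_a, ss_b = float(ac @ ac), float(bc @ bc)
    observed = n * (float(ac @ bc)) ** 2 / (ss_a * ss_b)
    # permutations preserve the mean and sum of squares of b, so only the
    # cross-product needs recomputing; fully vectorized over permutations
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    cross = bc[perm_idx] @ ac
    perms = n * cross**2 / (ss_a * ss_b)
    p = (1.0 + int(np.sum(perms >= observed - 1e-12))) / (1.0 + n_perm)
    return TestResult(observed, float(p), bonferroni_alpha)


def bonferroni(alpha: float, n_tests: int) -> float:
    """Per-test significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# Forensic parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForensicLocusParams:
    """Per-locus forensic parameter suite (all values in [0, 1])."""

    Ho: float
    He: float
    PIC: float
    MP: float
    PD: float
    PE: float


def forensic_params(n_II: int, n_ID: int, n_DD: int) -> ForensicLocusParams:
    """Forensic parameters of one biallelic locus from genotype counts.

    With insertion frequency ``p``, ``q = 1 - p``, observed heterozygosity
    ``h = n_ID / n`` and ``H = 1 - h``:

    * ``Ho = h``
    * ``He = (2n / (2n - 1)) (1 - p^2 - q^2)``  (Nei unbiased)
    * ``PIC = 1 - p^2 - q^2 - 2 p^2 q^2``       (Botstein)
    * ``MP = sum over genotypes of (observed genotype frequency)^2``
    * ``PD = 1 - MP``
    * ``PE = h^2 (1 - 2 h H^2)``                (Brenner trio exclusion)
    """
    if min(n_II, n_ID, n_DD) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_II + n_ID + n_DD
    if n < 2:
        raise ValueError("need >= 2 genotypes for forensic parameters")
    p = (2 * n_II + n_ID) / (2 * n)
    q = 1.0 - p
    h = n_ID / n
    H = 1.0 - h
    He = (2 * n / (2 * n - 1)) * (1 - p * p - q * q)
    PIC = 1 - p * p - q * q - 2 * p * p * q * q
    MP = (n_II / n) ** 2 + (n_ID / n) ** 2 + (n_DD / n) ** 2
    PE = h * h * (1 - 2 * h * H * H)
    return ForensicLocusParams(Ho=h, He=He, PIC=PIC, MP=MP, PD=1 - MP, PE=PE)


def cumulative_power(per_locus: Iterable[ForensicLocusParams]) -> tuple[float, float]:
    """Panel-level (CPD, CPE) = 1 - prod(1 - PD_i), 1 - prod(1 - PE_i).

    Computed in log space so a long panel of highly discriminating loci
    does not underflow the product.
    """
    params = list(per_locus)
    if not params:
        raise ValueError("need at least one locus")
    log1m_pd = sum(math.log1p(-pp.PD) if pp.PD < 1 else -math.inf for pp in params)
    log1m_pe = sum(math.log1p(-pp.PE) if pp.PE < 1 else -math.inf for pp in params)
    return -math.expm1(log1m_pd), -math.expm1(log1m_pe)


# ---------------------------------------------------------------------------
# Table-level drivers
# ---------------------------------------------------------------------------

def forensic_param_table(table: GenotypeTable) -> pd.DataFrame:
    """Per-(population, locus) forensic parameters plus panel CPD/CPE rows.

    Returns a long DataFrame with columns ``population, locus_id, Ho, He,
    PIC, MP, PD, PE``; the panel-level cumulative values are attached as
    ``df.attrs["cumulative"]`` mapping population -> (CPD, CPE).
    """
    d = table.dosage()
    pops = np.asarray(table.population)
    rows, cumulative = [], {}
    for g in dict.fromkeys(table.population):
        per_locus = []
        for j, locus in enumerate(table.locus_ids):
            counts = genotype_counts(d[pops == g, j])
            fp = forensic_params(*counts)
            per_locus.append(fp)
            rows.append((g, locus, fp.Ho, fp.He, fp.PIC, fp.MP, fp.PD, fp.PE))
        cumulative[g] = cumulative_power(per_locus)
    df = pd.DataFrame(
        rows, columns=["population", "locus_id", "Ho", "He", "PIC", "MP", "PD", "PE"]
    )
    df.attrs["cumulative"] = cumulative
    return df


def hwe_test_table(table: GenotypeTable, alpha: float = 0.05) -> pd.DataFrame:
    """Exact HWE tests for every (population, locus), Bonferroni-corrected
    within each population over its locus count."""
    d = table.dosage()
    pops = np.asarray(table.population)
    thr = bonferroni(alpha, table.n_loci)
    rows = []
    for g in dict.fromkeys(table.population):
        for j, locus in enumerate(table.locus_ids):
            res = hwe_exact_test(*genotype_counts(d[pops == g, j]), bonferroni_alpha=thr)
            rows.append((g, locus, res.statistic, res.p_value, thr, res.significant))
    return pd.DataFrame(
        rows,
        columns=["population", "locus_id", "n_het", "p_value", "bonferroni_alpha",
                 "significant"],
    )


def ld_test_table(
    table: GenotypeTable, n_perm: int = 999, seed: int = 0, alpha: float = 0.05
) -> pd.DataFrame:
    """Pairwise LD permutation tests within each population.

    The Bonferroni denominator is the number of tests actually run
    (n_populations * C(n_loci, 2)), reported in the output.
    """
    d = table.dosage()
    pops = np.asarray(table.population)
    groups = list(dict.fromkeys(table.population))
    m = table.n_loci
    n_tests = len(groups) * m * (m - 1) // 2
    thr = bonferroni(alpha, max(n_tests, 1))
    rng = np.random.default_rng(seed)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # monomorphic cells report p = 1
        for g in groups:
            sub = d[pops == g]
            for j in range(m):
                for k in range(j + 1, m):
                    res = ld_test(
                        sub[:, j], sub[:, k], n_perm=n_perm,
                        seed=int(rng.integers(2**31)), bonferroni_alpha=thr,
                    )
                    rows.append(
                        (g, table.locus_ids[j], table.locus_ids[k],
                         res.statistic, res.p_value, thr, res.significant)
                    )
    return pd.DataFrame(
        rows,
        columns=["population", "locus_a", "locus_b", "statistic", "p_value",
                 "bonferroni_alpha", "significant"],
    )
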