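"""Structured synthetic genotype panels for exercising the full pipeline.

The generator emulates the statistical skeleton of a continental reference
panel typed at ancestry-informative InDels: five continental clusters
(superpopulations) subdivided into sub-populations, plus a few "target"
groups genetically nested inside one cluster at small divergence.  Allele
frequencies follow a hierarchical Balding-Nichols model — each group's
insertion frequency is Beta-distributed around its parent's frequency with
divergence parameter F, i.e. Beta(p(1-F)/F, (1-p)(1-F)/F) — and genotypes
are drawn binomially under HWE within each population, with no linkage
between loci.  Candidate loci are screened by the ancestry-informative
selection rule (global minor-allele frequency and large intercontinental
frequency differences) until the requested panel size passes.

This reproduces exactly the properties the analyses assume (per-locus
frequency structure, HWE, no LD, known divergence); it makes no attempt to
emulate real haplotype LD or demographic history.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .forensic import LocusFrequencies
from .io import GenotypeTable, LocusInfo

__all__ = [
    "PanelSpec",
    "AimFilterSpec",
    "PanelFrequencies",
    "paper_like_spec",
    "balding_nichols_freqs",
    "apply_aim_filter",
    "sample_genotypes",
    "make_reference_panel",
]


@dataclass
class AimFilterSpec:
    """Ancestry-informative locus selection rule.

    Retain a locus iff its global minor-allele frequency (of the unweighted
    mean over superpopulations) is at least ``min_maf``, the largest
    pairwise frequency difference among the three designated major
    continental groups exceeds ``min_diff_major``, and the largest
    difference in any pair involving a remaining group exceeds
    ``min_diff_minor``.  ``max_indel_len`` is carried as metadata only (a
    sequence-level constraint with no statistical content here).
    """

    min_maf: float = 0.1
    min_diff_major: float = 0.5
    min_diff_minor: float = 0.2
    max_indel_len: int = 20
    major_groups: tuple[str, str, str] | None = None

    def __post_init__(self) -> None:
        for t in (self.min_maf, self.min_diff_major, self.min_diff_minor):
            if not 0.0 <= t <= 1.0:
                raise ValueError("filter thresholds must lie in [0, 1]")


@dataclass
class PanelSpec:
    """Hierarchical panel layout and divergence parameters.

    ``superpopulations`` maps each continental group to its (sub-population
    name, sample size) list; ``target_groups`` are (name, n, parent
    superpopulation, divergence F) tuples nested inside one cluster.
    ``fst_between`` is the Balding-Nichols divergence of superpopulations
    from the global ancestor, ``fst_within`` that of sub-populations from
    their superpopulation.
    """

    superpopulations: list[tuple[str, list[tuple[str, int]]]]
    target_groups: list[tuple[str, int, str, float]] = field(default_factory=list)
    n_loci: int = 56
    fst_between: float = 0.15
    fst_within: float = 0.005
    ancestral_maf_range: tuple[float, float] = (0.1, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.ancestral_maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("ancestral_maf_range must lie within (0, 0.5]")
        for f in (self.fst_between, self.fst_within,
                  *(t[3] for t in self.target_groups)):
            if not 0.0 <= f < 1.0:
                raise ValueError("divergence parameters must lie in [0, 1)")
        sups = {name for name, _ in self.superpopulations}
        for name, n, parent, _ in self.target_groups:
            if parent not in sups:
                raise ValueError(f"target group {name!r} parent {parent!r} unknown")
        for _, subs in self.superpopulations:
            if any(n < 1 for _, n in subs):
                raise ValueError("every group needs n >= 1")

    @property
    def population_to_superpopulation(self) -> dict[str, str]:
        out = {sub: sup for sup, subs in self.superpopulations for sub, _ in subs}
        out.update({name: parent for name, _, parent, _ in self.target_groups})
        return out

    @property
    def sample_sizes(self) -> dict[str, int]:
        out = {sub: n for _, subs in self.superpopulations for sub, n in subs}
        out.update({name: n for name, n, _, _ in self.target_groups})
        return out


def paper_like_spec(n_per_pop: int = 20, seed: int = 0) -> PanelSpec:
    """A scaled continental reference layout: 26 sub-populations in 5
    clusters (7 African-, 4 American-, 5 East-Asian-, 5 European-, 5
    South-Asian-analogue) plus 3 target groups nested in the East-Asian
    cluster at divergence F = 0.01.

    ``n_per_pop`` defaults to 20 individuals per population (~580 total)
    so the whole pipeline stays fast; pass a larger value for full-size
    panels.
    """
    # first three groups are the "major" ones the selection rule demands a
    # frequency difference > 0.5 among (African/East-Asian/European analogues)
    counts = {"AFR": 7, "EAS": 5, "EUR": 5, "AMR": 4, "SAS": 5}
    sups = [
        (sup, [(f"{sup}{i + 1}", n_per_pop) for i in range(k)])
        for sup, k in counts.items()
    ]
    targets = [(name, n_per_pop, "EAS", 0.01) for name in ("TGA", "TGB", "TGC")]
    return PanelSpec(superpopulations=sups, target_groups=targets, seed=seed)


@dataclass
class PanelFrequencies:
    """True frequencies of a generated panel at both hierarchy levels."""

    population: LocusFrequencies
    superpopulation: pd.DataFrame  # superpopulations x loci
    population_to_superpopulation: dict[str, str]


def _bn_draw(rng: np.random.Generator, parent: np.ndarray, F: float) -> np.ndarray:
    """Balding-Nichols daughter frequencies around ``parent`` at divergence F."""
    if F <= 0.0:
        return parent.copy()
    lam = (1.0 - F) / F
    return rng.beta(np.maximum(parent * lam, 1e-12),
                    np.maximum((1.0 - parent) * lam, 1e-12))


def balding_nichols_freqs(
    spec: PanelSpec, n_loci: int | None = None, seed: int | None = None
) -> PanelFrequencies:
    """Draw hierarchical allele frequencies for every group in ``spec``.

    Ancestral frequencies are uniform on the MAF range, reflected to
    (maf, 1 - maf) with equal probability; superpopulations diverge at
    ``fst_between``, sub-populations at ``fst_within`` around their
    superpopulation, target groups at their own F.  Deterministic given
    the seed (default: ``spec.seed``).
    """
    L = n_loci if n_loci is not None else spec.n_loci
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    lo, hi = spec.ancestral_maf_range
    anc = rng.uniform(lo, hi, size=L)
    flip = rng.random(L) < 0.5
    anc = np.where(flip, 1.0 - anc, anc)

    locus_ids = [f"L{j + 1:04d}" for j in range(L)]
    sup_rows = {}
    rows = []
    sizes = spec.sample_sizes
    for sup, subs in spec.superpopulations:
        sup_p = _bn_draw(rng, anc, spec.fst_between)
        sup_rows[sup] = sup_p
        for sub, n in subs:
            sub_p = _bn_draw(rng, sup_p, spec.fst_within)
            rows += [(sub, lid, float(p), n) for lid, p in zip(locus_ids, sub_p)]
    for name, n, parent, F in spec.target_groups:
        tg_p = _bn_draw(rng, sup_rows[parent], F)
        rows += [(name, lid, float(p), n) for lid, p in zip(locus_ids, tg_p)]
    pop = LocusFrequencies(pd.DataFrame(rows, columns=LocusFrequencies.COLUMNS))
    sup_df = pd.DataFrame(sup_rows, index=locus_ids).T
    return PanelFrequencies(pop, sup_df, spec.population_to_superpopulation)


def apply_aim_filter(
    superpop_freqs: pd.DataFrame, filter_spec: AimFilterSpec | None = None
) -> list[str]:
    """Locus ids passing the ancestry-informative selection rule.

    ``superpop_freqs`` is a superpopulations x loci frequency matrix with
    at least three rows.  Major groups default to the first three rows.
    Returns an empty list with a warning when nothing passes.
    """
    f = filter_spec or AimFilterSpec()
    if superpop_freqs.shape[0] < 3:
        raise ValueError("need >= 3 superpopulation frequency sets")
    major = list(f.major_groups) if f.major_groups else list(superpop_freqs.index[:3])
    minor = [g for g in superpop_freqs.index if g not in major]
    P = superpop_freqs.to_numpy(dtype=float)
    pbar = P.mean(axis=0)
    maf_ok = np.minimum(pbar, 1.0 - pbar) >= f.min_maf
    M = superpop_freqs.loc[major].to_numpy()
    dmaj = M.max(axis=0) - M.min(axis=0)
    major_ok = dmaj > f.min_diff_major
    if minor:
        # largest |dp| over pairs involving at least one remaining group
        Q = superpop_freqs.loc[minor].to_numpy()
        dmin = np.maximum(
            Q.max(axis=0) - P.min(axis=0), P.max(axis=0) - Q.min(axis=0)
        )
        minor_ok = dmin > f.min_diff_minor
    else:
        minor_ok = np.ones_like(major_ok)
    keep = maf_ok & major_ok & minor_ok
    retained = [lid for lid, k in zip(superpop_freqs.columns, keep) if k]
    if not retained:
        warnings.warn("no locus passes the ancestry-informative filter")
    return retained


def sample_genotypes(
    freqs: LocusFrequencies,
    population_to_superpopulation: dict[str, str],
    seed: int = 0,
    sample_sizes: dict[str, int] | None = None,
) -> GenotypeTable:
    """Draw diploid genotypes under HWE within each population.

    Each individual's dosage at a locus is Binomial(2, p_ins) for its
    population; loci are independent (no LD).  Sample sizes default to the
    ``n`` column of the frequency table.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    mat = freqs.matrix()
    locus_ids = list(mat.columns)
    sample_ids, pops, sups, blocks = [], [], [], []
    for pop in mat.index:
        p = mat.loc[pop].to_numpy(dtype=float)
        n = (sample_sizes or {}).get(
            pop, int(freqs.df.loc[freqs.df["population"] == pop, "n"].iloc[0])
        )
        alleles = rng.random((n, p.size, 2)) < p[None, :, None]
        blocks.append(alleles.astype(np.int8))
        sample_ids += [f"{pop}_{i + 1:03d}" for i in range(n)]
        pops += [pop] * n
        sups += [population_to_superpopulation.get(pop, "UNK")] * n
    geno = np.concatenate(blocks, axis=0)
    loci = [LocusInfo(locus_id=lid) for lid in locus_ids]
    return GenotypeTable(sample_ids, pops, sups, loci, geno)


def make_reference_panel(
    preset: str = "paper_like",
    seed: int = 0,
    n_per_pop: int = 20,
    spec: PanelSpec | None = None,
    filter_spec: AimFilterSpec | None = None,
    max_rounds: int = 200,
) -> tuple[GenotypeTable, PanelFrequencies]:
    """Generate a filtered ancestry-informative panel and its genotypes.

    Loci are generated in batches under the hierarchical model and passed
    through :func:`apply_aim_filter` until ``spec.n_loci`` survive; the
    retained loci are renamed ``rs0001...`` in selection order.  Returns
    the genotype table and the true frequencies behind it.
    """
    if spec is None:
        if preset != "paper_like":
            raise ValueError(f"unknown preset {preset!r}")
        spec = paper_like_spec(n_per_pop=n_per_pop, seed=seed)
    rng = np.random.default_rng(seed)
    batch = max(4 * spec.n_loci, 64)
    kept_pop: list[pd.DataFrame] = []
    kept_sup: dict[str, pd.Series] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty-batch warnings are expected here
        for _ in range(max_rounds):
            pf = balding_nichols_freqs(
                spec, n_loci=batch, seed=int(rng.integers(2**31))
            )
            for lid in apply_aim_filter(pf.superpopulation, filter_spec):
                if len(kept_sup) >= spec.n_loci:
                    break
                final = f"rs{len(kept_sup) + 1:04d}"
                kept_sup[final] = pf.superpopulation[lid]
                sub = pf.population.df[pf.population.df["locus_id"] == lid].copy()
                sub["locus_id"] = final
                kept_pop.append(sub)
            if len(kept_sup) >= spec.n_loci:
                break
        else:
            raise RuntimeError(
                f"ancestry-informative filter retained only {len(kept_sup)} loci "
                f"after {max_rounds} rounds; relax the filter or divergence "
                "parameters"
            )
    sup = pd.DataFrame(kept_sup)
    pop_df = pd.concat(kept_pop, ignore_index=True)
    # canonical ordering: populations in spec order, loci in selection order
    order = {lid: i for i, lid in enumerate(sup.columns)}
    pop_order = {p: i for i, p in enumerate(spec.sample_sizes)}
    pop_df = pop_df.sort_values(
        ["population", "locus_id"],
        key=lambda s: s.map(pop_order if s.name == "population" else order),
        kind="stable",
    ).reset_index(drop=True)
    pf_out = PanelFrequencies(
        LocusFrequencies(pop_df), sup, spec.population_to_superpopulation
    )
    table = sample_genotypes(
        pf_out.population, pf_out.population_to_superpopulation,
        seed=int(rng.integers(2**31)), sample_sizes=spec.sample_sizes,
    )
    return table, pf_out
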