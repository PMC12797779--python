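"""Pairwise kinship likelihood ratios and simulation under IBD models.

A relationship hypothesis between two non-inbred individuals is summarised
by the IBD coefficients ``(k0, k1, k2)``: the probabilities that the pair
shares 0, 1 or 2 alleles identical by descent at an autosomal locus.
Built-in models: unrelated (1,0,0), half siblings (0.5,0.5,0) and full
siblings (0.25,0.5,0.25).

For a biallelic locus with insertion frequency ``p`` under HWE, the joint
genotype probability of a pair under model ``k`` is

    P(g1, g2) = k0 P(g1)P(g2) + k1 P(g1) T(g2|g1) + k2 P(g1) [g1 = g2]

where ``T`` is the one-IBD-allele transition kernel.  The likelihood ratio
of hypothesis H1 (the pair is related as ``k``) against H0 (unrelated) is
the product across independent loci of the per-locus ratios; all arithmetic
is done in log10.

The module both simulates related pairs locus-by-locus (drawing IBD states,
then shared/independent alleles) and computes the *exact* distribution of
the combined log10 LR by convolving the per-locus atoms on a fine grid —
the latter serves as a closed-form check on the Monte-Carlo path and gives
threshold sensitivities without simulation noise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KinshipModel",
    "UNRELATED",
    "HALF_SIBLING",
    "FULL_SIBLING",
    "PairSimulation",
    "genotype_probs",
    "ibd1_transition",
    "joint_genotype_prob",
    "lr_locus",
    "simulate_pairs",
    "threshold_accuracy",
    "exact_log10lr_distribution",
    "exact_threshold_sensitivity",
]


@dataclass(frozen=True)
class KinshipModel:
    """A relationship hypothesis named by its IBD-sharing probabilities."""

    name: str
    k0: float
    k1: float
    k2: float

    def __post_init__(self) -> None:
        ks = (self.k0, self.k1, self.k2)
        if any(k < 0 or k > 1 for k in ks) or abs(sum(ks) - 1.0) > 1e-12:
            raise ValueError(f"IBD coefficients {ks} must be in [0,1] and sum to 1")


UNRELATED = KinshipModel("unrelated", 1.0, 0.0, 0.0)
HALF_SIBLING = KinshipModel("half_sibling", 0.5, 0.5, 0.0)
FULL_SIBLING = KinshipModel("full_sibling", 0.25, 0.5, 0.25)

_BUILTINS = {m.name: m for m in (UNRELATED, HALF_SIBLING, FULL_SIBLING)}
_BUILTINS["full_sib"] = FULL_SIBLING
_BUILTINS["half_sib"] = HALF_SIBLING


def get_model(name: str) -> KinshipModel:
    """Look up a built-in model by name (full_sibling, half_sibling, unrelated)."""
    try:
        return _BUILTINS[name]
    except KeyError:
        raise KeyError(f"unknown kinship model {name!r}; "
                       f"choose from {sorted(set(_BUILTINS))}") from None


# ---------------------------------------------------------------------------
# Single-locus likelihoods; genotypes are insertion dosages 0 (DD), 1 (ID), 2 (II)
# ---------------------------------------------------------------------------

def _check_p(p: float) -> None:
    if not 0.0 < p < 1.0:
        raise ValueError(f"insertion frequency must be in (0, 1), got {p}")


def genotype_probs(p: float) -> np.ndarray:
    """HWE genotype probabilities [P(DD), P(ID), P(II)] = [q^2, 2pq, p^2]."""
    _check_p(p)
    q = 1.0 - p
    return np.array([q * q, 2 * p * q, p * p])


def ibd1_transition(p: float) -> np.ndarray:
    """T[g1, g2]: genotype of a relative sharing exactly one IBD allele.

    One allele is copied from the first individual (picked uniformly from
    its two), the other drawn from the population.
    """
    _check_p(p)
    q = 1.0 - p
    return np.array([
        [q, p, 0.0],            # from DD
        [q / 2, 0.5, p / 2],    # from ID
        [0.0, q, p],            # from II
    ])


def joint_genotype_prob(g1: int, g2: int, p: float, model: KinshipModel) -> float:
    """P(g1, g2) for an ordered genotype pair under the IBD model."""
    P = genotype_probs(p)
    T = ibd1_transition(p)
    return (
        model.k0 * P[g1] * P[g2]
        + model.k1 * P[g1] * T[g1, g2]
        + model.k2 * P[g1] * (1.0 if g1 == g2 else 0.0)
    )


def lr_locus(g1: int, g2: int, p: float, model: KinshipModel) -> float:
    """Per-locus LR of model vs unrelated: k0 + k1 T(g2|g1)/P(g2) + k2 [g1=g2]/P(g2)."""
    P = genotype_probs(p)
    T = ibd1_transition(p)
    if P[g2] == 0:
        raise ValueError("impossible genotype under the allele frequency")
    return float(
        model.k0
        + model.k1 * T[g1, g2] / P[g2]
        + model.k2 * (1.0 if g1 == g2 else 0.0) / P[g2]
    )


def _lr_matrix(p: float, model: KinshipModel) -> np.ndarray:
    P = genotype_probs(p)
    T = ibd1_transition(p)
    return model.k0 + model.k1 * T / P[None, :] + model.k2 * np.eye(3) / P[None, :]


def _usable_freqs(freqs: Mapping[str, float] | pd.Series) -> pd.Series:
    s = pd.Series(dict(freqs)) if not isinstance(freqs, pd.Series) else freqs.copy()
    if s.empty:
        raise ValueError("empty frequency set")
    mono = (s <= 0.0) | (s >= 1.0)
    if mono.any():
        warnings.warn(
            f"{int(mono.sum())} monomorphic loci contribute LR = 1 and are skipped"
        )
        s = s[~mono]
    if s.empty:
        raise ValueError("no polymorphic loci in frequency set")
    return s.astype(float)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class PairSimulation:
    """Simulated genotype pairs and their combined log10 likelihood ratios.

    ``genotypes1``/``genotypes2`` are (n_pairs, n_loci) insertion-dosage
    arrays; ``log10_lr`` is the per-pair combined log10 LR of ``model``
    against unrelatedness (sum of per-locus log10 LRs).
    """

    model: KinshipModel
    locus_ids: list[str]
    genotypes1: np.ndarray
    genotypes2: np.ndarray
    log10_lr: np.ndarray

    @property
    def n_pairs(self) -> int:
        return self.log10_lr.size


def simulate_pairs(
    freqs: Mapping[str, float] | pd.Series,
    model: KinshipModel,
    n_pairs: int,
    seed: int | None = None,
    lr_model: KinshipModel | None = None,
) -> PairSimulation:
    """Simulate ``n_pairs`` genotype pairs under ``model`` and score LRs.

    Per pair and locus an IBD state is drawn with probabilities
    ``(k0, k1, k2)``; shared alleles are copied, the rest drawn from the
    insertion frequency.  The combined log10 LR compares ``lr_model``
    (default: ``model`` itself; pass the related hypothesis when simulating
    unrelated pairs for specificity curves) against unrelatedness.

    Monomorphic frequencies (p in {0, 1}) contribute LR = 1 and are skipped
    with a warning.  Deterministic given ``seed``.
    """
    s = _usable_freqs(freqs)
    lr_model = lr_model or model
    p = s.to_numpy()  # (L,)
    L = p.size
    rng = np.random.default_rng(seed)

    ibd = rng.choice(3, size=(n_pairs, L), p=(model.k0, model.k1, model.k2))
    # individual 1: two independent allele draws
    a11 = rng.random((n_pairs, L)) < p
    a12 = rng.random((n_pairs, L)) < p
    # individual 2: fresh draws, overwritten by IBD-shared copies
    a21 = rng.random((n_pairs, L)) < p
    a22 = rng.random((n_pairs, L)) < p
    # one shared allele: copy a uniformly chosen allele of individual 1
    pick = rng.random((n_pairs, L)) < 0.5
    shared1 = np.where(pick, a11, a12)
    one = ibd == 1
    a21 = np.where(one, shared1, a21)
    two = ibd == 2
    a21 = np.where(two, a11, a21)
    a22 = np.where(two, a12, a22)

    g1 = a11.astype(np.int8) + a12.astype(np.int8)
    g2 = a21.astype(np.int8) + a22.astype(np.int8)

    log10lr = np.zeros(n_pairs)
    for j in range(L):
        log10lr += np.log10(_lr_matrix(p[j], lr_model))[g1[:, j], g2[:, j]]
    return PairSimulation(model, list(s.index), g1, g2, log10lr)


def threshold_accuracy(
    log10_lrs: Sequence[float], thresholds: Sequence[float]
) -> dict[float, float]:
    """Proportion of pairs whose combined LR meets each threshold.

    On pairs simulated under the related hypothesis this is the sensitivity
    (the "accuracy rate" of sibling identification at that LR threshold);
    on unrelated pairs it is the false-positive rate.
    """
    lrs = np.asarray(log10_lrs, dtype=float)
    out = {}
    for t in thresholds:
        if t <= 0:
            raise ValueError("LR thresholds must be positive")
        out[float(t)] = float(np.mean(lrs >= math.log10(t)))
    return out


# ---------------------------------------------------------------------------
# Exact combined-LR distribution (convolution of per-locus atoms)
# ---------------------------------------------------------------------------

def exact_log10lr_distribution(
    freqs: Mapping[str, float] | pd.Series,
    sim_model: KinshipModel,
    lr_model: KinshipModel | None = None,
    step: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the combined log10 LR, discretized on a grid.

    Each locus contributes at most 9 atoms (ordered genotype pairs) with
    joint probabilities under ``sim_model`` and values log10 LR of
    ``lr_model`` vs unrelated.  Atoms are rounded to a grid of width
    ``step`` and convolved across loci.  Returns ``(grid_values, probs)``.
    Rounding displaces the combined value by at most ``n_loci * step / 2``.
    """
    s = _usable_freqs(freqs)
    lr_model = lr_model or sim_model
    dist = np.array([1.0])
    grid_lo = 0  # grid offset of dist[0]
    for p in s.to_numpy():
        P = genotype_probs(p)
        T = ibd1_transition(p)
        joint = (
            sim_model.k0 * np.outer(P, P)
            + sim_model.k1 * P[:, None] * T
            + sim_model.k2 * np.diag(P)
        ).ravel()
        offs = np.round(np.log10(_lr_matrix(p, lr_model)) / step).astype(int).ravel()
        offs, joint = offs[joint > 0], joint[joint > 0]
        omin = int(offs.min())
        new = np.zeros(dist.size + int(offs.max()) - omin)
        for o, pr in zip(offs, joint):
            new[o - omin: o - omin + dist.size] += pr * dist
        dist = new
        grid_lo += omin
    grid = (np.arange(dist.size) + grid_lo) * step
    return grid, dist


def exact_threshold_sensitivity(
    freqs: Mapping[str, float] | pd.Series,
    sim_model: KinshipModel,
    thresholds: Sequence[float],
    lr_model: KinshipModel | None = None,
    step: float = 1e-3,
) -> dict[float, float]:
    """P(combined LR >= t) under ``sim_model``, from the exact convolution."""
    grid, dist = exact_log10lr_distribution(freqs, sim_model, lr_model, step)
    out = {}
    for t in thresholds:
        if t <= 0:
            raise ValueError("LR thresholds must be positive")
        out[float(t)] = float(dist[grid >= math.log10(t) - 1e-12].sum())
    return out
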