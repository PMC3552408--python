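"""Neutral-marker statistics: diversity, Weir–Cockerham θ, IBD linearization, ΔK.

Pairwise differentiation uses the Weir & Cockerham (1984) θ estimator,
multi-allelic, with the per-locus, per-allele variance components a (among
populations), b (among individuals within populations) and c (within
individuals) summed before taking the ratio θ = Σa / Σ(a+b+c) — the
ratio-of-sums convention, not the mean of per-locus ratios.  θ can be
slightly negative; that is a property of the estimator, not an error.

Diversity per population: observed heterozygosity H_O, Nei's unbiased
expected heterozygosity H_E = (2n/(2n−1))(1 − Σp²), effective allele number
A_e = 1/Σp², and F_IS = 1 − H_O/H_E, each computed per locus and averaged
over loci with data (F_IS only over polymorphic loci).

ΔK post-processes log-likelihood traces from Bayesian clustering runs:
ΔK(K) = |L(K+1) − 2L(K) + L(K−1)| / sd(L(K)) over replicates; the most
likely number of clusters is the interior K maximizing ΔK.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    ClusterLikelihoodTrace,
    DistanceMatrix,
    GenotypeTable,
    ValidationError,
)

__all__ = [
    "DiversityStats",
    "DeltaKResult",
    "diversity",
    "fst_pair",
    "fst_matrix",
    "linearize_fst",
    "delta_k",
    "weir_cockerham_components",
]


@dataclass
class DiversityStats:
    """Per-population marker diversity, averaged over loci with data."""

    per_population: dict[str, dict[str, float]]  # pop -> {H_O, H_E, A_e, F_IS, n}

    def __getitem__(self, pop: str) -> dict[str, float]:
        return self.per_population[pop]


@dataclass
class DeltaKResult:
    """ΔK summary: per-K likelihood means/sds, ΔK at interior K, best K."""

    per_k: dict[int, dict[str, float]]  # K -> {mean_lnL, sd_lnL, delta_k (interior only)}
    best_k: int | None
    ambiguous: bool = False


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------


def _locus_pop_counts(g: GenotypeTable, pop_idx: np.ndarray, locus: int):
    """(allele codes, allele counts, n typed individuals, n heterozygous)."""
    cells = g.alleles[pop_idx, locus]  # (m, 2)
    typed = cells[(cells > 0).all(axis=1)]
    if typed.size == 0:
        return None
    codes, counts = np.unique(typed.ravel(), return_counts=True)
    het = int((typed[:, 0] != typed[:, 1]).sum())
    return codes, counts, len(typed), het


def diversity(g: GenotypeTable) -> DiversityStats:
    """H_O, H_E (unbiased), A_e and F_IS per population."""
    out: dict[str, dict[str, float]] = {}
    for pop in g.population_labels:
        idx = g.population_indices(pop)
        ho_list, he_list, ae_list, fis_list = [], [], [], []
        for locus in range(len(g.loci)):
            res = _locus_pop_counts(g, idx, locus)
            if res is None:
                continue
            codes, counts, n, het = res
            p = counts / counts.sum()
            sum_p2 = float((p**2).sum())
            h_o = het / n
            h_e = (2 * n / (2 * n - 1)) * (1.0 - sum_p2) if n > 0 else 0.0
            ho_list.append(h_o)
            he_list.append(h_e)
            ae_list.append(1.0 / sum_p2)
            if h_e > 0:
                fis_list.append(1.0 - h_o / h_e)
        if not ho_list:
            raise ValidationError(f"population {pop!r} has no typed locus")
        out[pop] = {
            "H_O": float(np.mean(ho_list)),
            "H_E": float(np.mean(he_list)),
            "A_e": float(np.mean(ae_list)),
            "F_IS": float(np.mean(fis_list)) if fis_list else float("nan"),
            "n": int(len(idx)),
        }
    return DiversityStats(out)


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------


def weir_cockerham_components(
    g: GenotypeTable, pops: list[str]
) -> tuple[float, float]:
    """Summed W&C (a, a+b+c) over all loci and alleles for the given populations.

    Per locus, individuals with missing genotypes are excluded; loci
    monomorphic across the populations (or typed in < 2 of them, or with
    mean sample size <= 1) contribute nothing.
    """
    pop_idx = [g.population_indices(p) for p in pops]
    r = len(pop_idx)
    if r < 2:
        raise ValidationError("need >= 2 populations for theta")
    sum_a = 0.0
    sum_abc = 0.0
    for locus in range(len(g.loci)):
        per_pop = []
        for idx in pop_idx:
            res = _locus_pop_counts(g, idx, locus)
            if res is not None:
                per_pop.append(res)
        if len(per_pop) < r:
            continue  # locus not typed in every population of the comparison
        all_codes = np.unique(np.concatenate([codes for codes, _, _, _ in per_pop]))
        if len(all_codes) < 2:
            continue  # monomorphic across the comparison
        n = np.array([ni for _, _, ni, _ in per_pop], dtype=float)
        nbar = n.mean()
        if nbar <= 1:
            continue
        nc = (n.sum() - (n**2).sum() / n.sum()) / (r - 1)
        cells = [g.alleles[idx, locus] for idx in pop_idx]
        typed = [c[(c > 0).all(axis=1)] for c in cells]
        for allele in all_codes:
            p_i = np.array([
                (t == allele).sum() / (2.0 * len(t)) for t in typed
            ])
            h_i = np.array([
                ((t == allele).sum(axis=1) == 1).mean() for t in typed
            ])
            pbar = float((n * p_i).sum() / n.sum())
            s2 = float((n * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar))
            hbar = float((n * h_i).sum() / n.sum())
            a = (nbar / nc) * (
                s2
                - (1.0 / (nbar - 1))
                * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - s2 * (r - 1) / r
                - hbar * (2 * nbar - 1) / (4 * nbar)
            )
            c = hbar / 2.0
            sum_a += a
            sum_abc += a + b + c
    return sum_a, sum_abc


def fst_pair(g: GenotypeTable, pop_a: str, pop_b: str) -> float:
    """Weir & Cockerham θ between two populations (ratio of summed components)."""
    sum_a, sum_abc = weir_cockerham_components(g, [pop_a, pop_b])
    if sum_abc == 0.0:
        raise ValidationError(
            f"theta undefined for ({pop_a!r}, {pop_b!r}): no co-polymorphic locus"
        )
    return float(sum_a / sum_abc)


def fst_matrix(g: GenotypeTable) -> DistanceMatrix:
    """All unordered pairwise θ values (P populations -> P(P−1)/2 entries)."""
    pops = g.population_labels
    if len(pops) < 2:
        raise ValidationError("need >= 2 populations")
    n = len(pops)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                theta = fst_pair(g, pops[i], pops[j])
            except ValidationError as err:
                raise ValidationError(f"pair ({pops[i]}, {pops[j]}): {err}") from err
            values[i, j] = values[j, i] = theta
    return DistanceMatrix(pops, values, kind="fst")


def linearize_fst(m: DistanceMatrix) -> DistanceMatrix:
    """Rousset's isolation-by-distance linearization F_ST/(1−F_ST), elementwise.

    Negative estimates pass through (the transform is monotone); any entry
    equal to 1 makes the transform infinite and is rejected naming the pair.
    """
    at_one = np.argwhere(np.isclose(m.values, 1.0))
    if at_one.size:
        i, j = at_one[0]
        raise ValidationError(
            f"F_ST = 1 for pair ({m.labels[i]}, {m.labels[j]}): linearization infinite"
        )
    if (m.values >= 1.0).any():
        raise ValidationError("F_ST values must be < 1 for linearization")
    values = m.values / (1.0 - m.values)
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(list(m.labels), values, kind=m.kind)


# ---------------------------------------------------------------------------
# delta-K
# ---------------------------------------------------------------------------


def delta_k(trace: ClusterLikelihoodTrace) -> DeltaKResult:
    """Second-order rate of change of clustering likelihood across K.

    ΔK(K) = |mean L(K+1) − 2 mean L(K) + mean L(K−1)| / sd(L(K)), sd over
    replicates (sample sd, n−1).  Defined for interior K only; the best K
    is the argmax.  Zero curvature everywhere is flagged ambiguous.
    """
    grouped = trace.entries.groupby("K")["lnL"]
    means = grouped.mean()
    sds = grouped.std(ddof=1)
    ks = trace.k_values
    per_k: dict[int, dict[str, float]] = {}
    deltas: dict[int, float] = {}
    for k in ks:
        per_k[int(k)] = {"mean_lnL": float(means[k]), "sd_lnL": float(sds[k])}
    for k in ks[1:-1]:
        sd = float(sds[k])
        if sd == 0.0:
            raise ValidationError(f"sd of lnL is 0 at interior K={int(k)}: ΔK undefined")
        dk = abs(means[k + 1] - 2.0 * means[k] + means[k - 1]) / sd
        deltas[int(k)] = float(dk)
        per_k[int(k)]["delta_k"] = float(dk)
    ambiguous = all(v == 0.0 for v in deltas.values())
    best = None if ambiguous else max(deltas, key=deltas.get)
    return DeltaKResult(per_k=per_k, best_k=best, ambiguous=ambiguous)
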