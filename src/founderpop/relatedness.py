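"""Genomic and pedigree relationship matrices, and unrelated-set selection.

The genomic relationship matrix (GRM) follows VanRaden's first method:
with ``M`` the allele-count matrix (missing calls imputed by the
genotype-dosage mean ``2 p_j``) and ``P`` the row-replicated frequency
vector,

    Z = M - 2P,      G = Z Z' / (2 * sum_j p_j (1 - p_j)).

Because sampled founders contain large sib groups, frequencies observed
over all individuals are biased towards those groups, which shrinks the
apparent relationship within large families.  The de-biasing pass
therefore (1) extracts a maximal set of pairwise-unrelated individuals
from the pedigree relationship matrix ``A``, (2) re-estimates allele
frequencies from that set only, and (3) rebuilds ``G`` for everyone with
the corrected frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_model import AlleleFrequencies, GenotypeMatrix, Pedigree

__all__ = [
    "GMatrix",
    "AMatrix",
    "estimate_frequencies",
    "build_g",
    "build_a",
    "select_unrelated",
    "refine_g",
]

log = logging.getLogger("founderpop")

_UNKNOWN = "0"


@dataclass
class GMatrix:
    """Symmetric genomic relationship matrix for one population."""

    individual_ids: list[str]
    values: np.ndarray
    frequencies_used: AlleleFrequencies
    population: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.individual_ids)
        if self.values.shape != (n, n):
            raise ValueError("G dimensions do not match individual ids")
        if n and not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("G is not symmetric")

    def pair(self, a: str, b: str) -> float:
        i = self.individual_ids.index(a)
        j = self.individual_ids.index(b)
        return float(self.values[i, j])


@dataclass
class AMatrix:
    """Pedigree-based numerator relationship matrix."""

    individual_ids: list[str]
    values: np.ndarray
    pedigree: Pedigree | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.individual_ids)
        if self.values.shape != (n, n):
            raise ValueError("A dimensions do not match individual ids")
        if n and not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("A is not symmetric")
        if n and np.any(np.diag(self.values) < 1 - 1e-9):
            raise ValueError("A diagonal below 1")

    def pair(self, a: str, b: str) -> float:
        i = self.individual_ids.index(a)
        j = self.individual_ids.index(b)
        return float(self.values[i, j])


def estimate_frequencies(
    g: GenotypeMatrix, subset: Sequence[str] | None = None
) -> AlleleFrequencies:
    """Observed counted-allele frequencies, optionally over a subset.

    ``p_j`` is half the mean non-missing allele count at SNP j over the
    chosen individuals.  A SNP with no non-missing call in the subset
    has no defined frequency and raises.
    """
    sub = g if subset is None else g.subset_individuals(list(subset))
    if sub.n_individuals == 0:
        raise ValueError("empty individual subset")
    calls = sub.masked_calls()
    counts = np.asarray((~sub.missing_mask()).sum(axis=0))
    if (counts == 0).any():
        bad = [s for s, c in zip(sub.snp_ids, counts) if c == 0]
        raise ValueError(f"SNPs with no non-missing call in subset: {bad[:10]}")
    p = np.asarray(calls.mean(axis=0)) / 2.0
    return AlleleFrequencies(
        snp_ids=list(sub.snp_ids), p=p, source_individuals=list(sub.individual_ids)
    )


def build_g(
    g: GenotypeMatrix, freqs: AlleleFrequencies, population: str = ""
) -> GMatrix:
    """VanRaden (method 1) genomic relationship matrix.

    Missing calls are imputed by the dosage mean ``2 p_j`` before
    centring, so an imputed cell contributes exactly zero to ``Z``.
    """
    if list(freqs.snp_ids) != list(g.snp_ids):
        lookup = dict(zip(freqs.snp_ids, freqs.p))
        try:
            p = np.array([lookup[s] for s in g.snp_ids], dtype=float)
        except KeyError as e:
            raise ValueError(f"frequencies missing for SNP {e.args[0]!r}") from None
    else:
        p = np.asarray(freqs.p, dtype=float)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ZeroDivisionError(
            "all SNPs monomorphic at the supplied frequencies; G undefined"
        )
    m = g.calls.astype(float)
    miss = g.missing_mask()
    two_p = 2.0 * p
    m[miss] = np.broadcast_to(two_p, m.shape)[miss]
    z = m - two_p[np.newaxis, :]
    values = (z @ z.T) / denom
    values = (values + values.T) / 2.0  # kill numerical asymmetry
    return GMatrix(
        individual_ids=list(g.individual_ids),
        values=values,
        frequencies_used=freqs,
        population=population,
    )


def build_a(p: Pedigree, include_parents: bool = False) -> AMatrix:
    """Numerator relationship matrix by the tabular method.

    Individuals are processed parents-first; for y with parents s, d and
    x already processed,

        a_xy = (a_xs + a_xd) / 2,      a_yy = 1 + a_sd / 2,

    with unknown parents contributing zero.  By default the returned
    matrix is restricted to the pedigree's recorded individuals (the
    observed generation); founders that only appear as parents are kept
    when ``include_parents`` is set.
    """
    order = p.topological_order()
    idx = {ind: k for k, ind in enumerate(order)}
    n = len(order)
    a = np.zeros((n, n), dtype=float)
    recorded = {r[0]: (r[1], r[2]) for r in p.records}
    for y, ind in enumerate(order):
        sire, dam = recorded.get(ind, (_UNKNOWN, _UNKNOWN))
        si = idx.get(sire, -1) if sire != _UNKNOWN else -1
        di = idx.get(dam, -1) if dam != _UNKNOWN else -1
        a_sd = a[si, di] if si >= 0 and di >= 0 else 0.0
        a[y, y] = 1.0 + 0.5 * a_sd
        for x in range(y):
            val = 0.0
            if si >= 0:
                val += 0.5 * a[x, si]
            if di >= 0:
                val += 0.5 * a[x, di]
            a[x, y] = a[y, x] = val
    if include_parents:
        keep = order
    else:
        wanted = set(r[0] for r in p.records)
        keep = [ind for ind in order if ind in wanted]
    ki = [idx[ind] for ind in keep]
    return AMatrix(individual_ids=keep, values=a[np.ix_(ki, ki)], pedigree=p)


def select_unrelated(a: AMatrix) -> list[str]:
    """Greedy maximal set of pairwise-unrelated individuals.

    The construction order is: first every individual unrelated
    (``a_ij = 0``) to all others; then, repeatedly, the remaining
    individual with the lowest mean relationship to the other remaining
    individuals is appended and it and all its relatives
    (``a_ij > 0``) are removed, until nobody remains.  Mean relationship
    is taken over off-diagonal entries of the current, shrinking matrix;
    ties go to the earliest individual in input order.

    The result is an independent set in the relatedness graph and is
    maximal: every excluded individual is related to some member.
    """
    ids = list(a.individual_ids)
    vals = a.values.copy()
    n = len(ids)
    if n == 0:
        return []
    off = vals - np.diag(np.diag(vals))
    related = off > 0

    selected: list[str] = []
    remaining = list(range(n))

    # step (2): individuals unrelated to every other individual
    isolated = [i for i in remaining if not related[i, remaining].any()]
    selected.extend(ids[i] for i in isolated)
    remaining = [i for i in remaining if i not in set(isolated)]

    # steps (3)-(4): lowest mean relationship, then drop it and its kin
    while remaining:
        sub = off[np.ix_(remaining, remaining)]
        if len(remaining) == 1:
            means = np.zeros(1)
        else:
            means = sub.sum(axis=1) / (len(remaining) - 1)
        best = int(np.argmin(means))  # argmin takes the earliest on ties
        chosen = remaining[best]
        selected.append(ids[chosen])
        kin = {j for j in remaining if related[chosen, j]}
        kin.add(chosen)
        remaining = [j for j in remaining if j not in kin]
    return selected


def refine_g(
    g: GenotypeMatrix,
    population: str,
    prelim_a: AMatrix,
    min_unrelated: int = 5,
) -> tuple[GMatrix, list[str]]:
    """Second-pass G: frequencies from the unrelated set, G for everyone.

    ``prelim_a`` is the pedigree relationship matrix from the
    preliminary sibship assignment of this population.  Returns the
    regenerated GRM over all individuals of the population together
    with the unrelated individual list used for frequency estimation.
    A set smaller than ``min_unrelated`` is accepted but flagged: the
    frequency estimates are then imprecise.
    """
    pop_ids = g.individuals_of(population)
    if not pop_ids:
        raise ValueError(f"no individuals in population {population!r}")
    unrelated = select_unrelated(prelim_a)
    unknown = set(unrelated) - set(pop_ids)
    if unknown:
        raise ValueError(f"unrelated ids outside population: {sorted(unknown)[:5]}")
    if len(unrelated) < min_unrelated:
        log.warning(
            "population %s: only %d putatively unrelated individuals; "
            "allele-frequency estimates are imprecise",
            population,
            len(unrelated),
        )
    sub = g.subset_individuals(pop_ids)
    freqs = estimate_frequencies(sub, unrelated)
    return build_g(sub, freqs, population=population), unrelated
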