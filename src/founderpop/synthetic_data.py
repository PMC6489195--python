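"""Synthetic genotype data with known pedigree and differentiation.

The generator emulates the sampling design the pipeline is built for:
several weakly differentiated river populations, each a single sampled
generation containing a mixture of singletons and large full-sib /
half-sib families, genotyped at ~1000 unlinked biallelic SNPs with a
few percent missing calls.

Differentiation follows the Balding-Nichols model: each population's
allele frequency at a SNP is Beta-distributed around the ancestral
frequency ``p`` with shape parameters ``p(1-F)/F`` and
``(1-p)(1-F)/F``, so that ``F`` is the expected Wright F_ST between
populations.  Genotypes descend by gene drop: ungenotyped founder
parents are drawn binomial(2, p) per SNP (Hardy-Weinberg), and each
offspring receives one uniformly chosen allele from each parent.  SNPs
are unlinked (independent across loci).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import (
    MISSING,
    AlleleFrequencies,
    GenotypeMatrix,
    Pedigree,
    PopulationSpec,
    SimConfig,
)
from .sibship import HalfSibLink, SibshipAssignment, realise_parent_sharing

__all__ = [
    "simulate_frequencies",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_dataset",
    "default_config",
    "SimulatedPedigree",
    "SimulatedDataset",
]

_UNKNOWN = "0"


def simulate_frequencies(
    n_snps: int,
    maf_low: float,
    maf_high: float,
    pop_names: list[str],
    fst_target: float,
    seed: int,
) -> tuple[AlleleFrequencies, dict[str, AlleleFrequencies]]:
    """Ancestral and per-population counted-allele frequencies.

    Ancestral minor-allele frequencies are Uniform(maf_low, maf_high)
    with random polarity (the counted allele is the minor one for half
    the SNPs).  Population frequencies are Balding-Nichols draws with
    ``F = fst_target``; ``fst_target = 0`` copies the ancestral vector.
    """
    if not 0 <= maf_low <= maf_high <= 0.5:
        raise ValueError("require 0 <= maf_low <= maf_high <= 0.5")
    if not 0 <= fst_target < 1:
        raise ValueError("fst_target must be in [0, 1)")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(maf_low, maf_high, size=n_snps)
    flip = rng.random(n_snps) < 0.5
    p_anc = np.where(flip, 1.0 - maf, maf)
    snp_ids = [f"snp{j:05d}" for j in range(n_snps)]
    ancestral = AlleleFrequencies(snp_ids=snp_ids, p=p_anc)
    pops: dict[str, AlleleFrequencies] = {}
    for name in pop_names:
        if fst_target == 0:
            p = p_anc.copy()
        else:
            shape = (1.0 - fst_target) / fst_target
            p = rng.beta(p_anc * shape, (1.0 - p_anc) * shape)
        pops[name] = AlleleFrequencies(snp_ids=snp_ids, p=p)
    return ancestral, pops


@dataclass
class SimulatedPedigree:
    """True pedigree plus the ground-truth sibship it encodes."""

    pedigree: Pedigree
    assignments: dict[str, SibshipAssignment]
    populations: dict[str, str]  # every id (founders included) -> population


def simulate_pedigree(config: SimConfig) -> SimulatedPedigree:
    """One-generation pedigree realising the configured family structure.

    Per population: each full-sib family shares two founder parents;
    half-sib-linked families share exactly one (links are realised with
    the same two-slot logic the sibship assigner uses, so an
    inconsistent specification raises); singletons have unique parents.
    The observed individuals are exactly the offspring generation —
    founder parents are never genotyped.
    """
    records: list[tuple[str, str, str]] = []
    assignments: dict[str, SibshipAssignment] = {}
    populations: dict[str, str] = {}
    for spec in config.populations:
        spec.validate()
        groups: list[list[str]] = []
        n_fam = len(spec.family_sizes)
        links = [(a, b, 0.25) for a, b in spec.half_sib_links]
        group_parents, accepted, _ = realise_parent_sharing(
            n_fam + spec.n_singletons, links, strict=True
        )
        shared_name = {
            pid: f"{spec.name}_shared{pid}"
            for pids in group_parents.values()
            for pid in pids
        }
        private = 0

        def fresh_parent() -> str:
            nonlocal private
            name = f"{spec.name}_founder{private}"
            private += 1
            return name

        for k, size in enumerate(spec.family_sizes):
            parents = [shared_name[pid] for pid in group_parents[k]]
            while len(parents) < 2:
                parents.append(fresh_parent())
            members = [f"{spec.name}_f{k}_{i}" for i in range(size)]
            groups.append(members)
            for ind in members:
                records.append((ind, parents[0], parents[1]))
                populations[ind] = spec.name
            for par in parents:
                populations[par] = spec.name
        for s in range(spec.n_singletons):
            ind = f"{spec.name}_s{s}"
            sire, dam = fresh_parent(), fresh_parent()
            records.append((ind, sire, dam))
            groups.append([ind])
            populations[ind] = spec.name
            populations[sire] = populations[dam] = spec.name
        assignments[spec.name] = SibshipAssignment(
            population=spec.name,
            full_sib_groups=groups,
            half_sib_links=[HalfSibLink(a, b, 0.25) for a, b in accepted],
        )
    return SimulatedPedigree(
        pedigree=Pedigree(records=records),
        assignments=assignments,
        populations=populations,
    )


def _drop_allele(parent_geno: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One transmitted allele per SNP from a parent's genotype vector."""
    # genotype 0 -> 0, 2 -> 1, 1 -> Bernoulli(1/2)
    het = parent_geno == 1
    out = (parent_geno == 2).astype(np.int16)
    out[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int16)
    return out


#: Fraction of markers belonging to the poor-call-rate class, and the
#: per-call missing probability of the good class relative to the mean.
#: Reduced-representation platforms show strongly marker-clustered
#: missingness: most markers call almost everywhere while a minority
#: have poor reproducibility.  The bimodal profile reproduces that:
#: 15% of SNPs carry most of the missingness, the rest sit well under
#: the QC missing-rate threshold.
_POOR_MARKER_FRACTION = 0.15
_GOOD_MARKER_RELATIVE_RATE = 0.3


def simulate_genotypes(
    sim_ped: SimulatedPedigree,
    pop_frequencies: dict[str, AlleleFrequencies],
    missing_rate: float = 0.0,
    error_rate: float = 0.0,
    seed: int = 0,
    fragment_pair_fraction: float = 0.0,
    missing_profile: str = "bimodal",
    return_founders: bool = False,
) -> GenotypeMatrix | tuple[GenotypeMatrix, dict[str, np.ndarray]]:
    """Gene-drop genotypes for the observed (offspring) generation.

    Founders are drawn binomial(2, p) from their population's
    frequencies; offspring inherit one uniformly chosen allele from
    each parent.  Calls are set missing at overall rate
    ``missing_rate``: with the default ``"bimodal"`` profile the rate
    is marker-specific (a poor-call-rate minority of SNPs carries most
    of the missingness, as on reduced-representation platforms), while
    ``"uniform"`` drops every call independently with the same
    probability.  With probability ``error_rate`` a non-missing call is
    perturbed to a uniformly chosen different valid count.  Fragment
    ids are assigned so that ``fragment_pair_fraction`` of fragments
    carry two SNPs.
    """
    rng = np.random.default_rng(seed)
    some_pop = next(iter(pop_frequencies.values()))
    snp_ids = list(some_pop.snp_ids)
    n_snps = len(snp_ids)

    recorded = {r[0]: (r[1], r[2]) for r in sim_ped.pedigree.records}
    order = sim_ped.pedigree.topological_order()
    genomes: dict[str, np.ndarray] = {}
    # founders first, then gene-drop down the (parents-first) order
    for ind in order:
        if ind in recorded:
            continue
        pop = sim_ped.populations.get(ind)
        if pop is None or pop not in pop_frequencies:
            raise ValueError(f"unknown population for individual {ind!r}")
        genomes[ind] = rng.binomial(2, pop_frequencies[pop].p).astype(np.int16)
    for ind in order:
        if ind not in recorded:
            continue
        sire, dam = recorded[ind]
        genomes[ind] = _drop_allele(genomes[sire], rng) + _drop_allele(
            genomes[dam], rng
        )

    founder_genotypes = {
        ind: genomes[ind].copy() for ind in order if ind not in recorded
    }
    observed = [r[0] for r in sim_ped.pedigree.records]
    calls = np.stack([genomes[ind] for ind in observed])

    if error_rate > 0:
        err = rng.random(calls.shape) < error_rate
        # uniformly one of the two other valid counts
        shift = rng.integers(1, 3, size=calls.shape)
        calls = np.where(err, (calls + shift) % 3, calls).astype(np.int16)
    if missing_rate > 0:
        if missing_profile == "uniform":
            per_snp = np.full(n_snps, missing_rate)
        elif missing_profile == "bimodal":
            good = missing_rate * _GOOD_MARKER_RELATIVE_RATE
            # solve the mixture mean so the overall rate stays missing_rate
            poor = (
                missing_rate - (1 - _POOR_MARKER_FRACTION) * good
            ) / _POOR_MARKER_FRACTION
            poor = min(poor, 1.0)
            is_poor = rng.random(n_snps) < _POOR_MARKER_FRACTION
            per_snp = np.where(is_poor, poor, good)
        else:
            raise ValueError(f"unknown missing_profile {missing_profile!r}")
        miss = rng.random(calls.shape) < per_snp[np.newaxis, :]
        calls[miss] = MISSING

    fragment_ids = _assign_fragments(n_snps, fragment_pair_fraction, rng)
    matrix = GenotypeMatrix(
        individual_ids=observed,
        snp_ids=snp_ids,
        fragment_ids=fragment_ids,
        populations=[sim_ped.populations[i] for i in observed],
        calls=calls,
    )
    if return_founders:
        return matrix, founder_genotypes
    return matrix


def _assign_fragments(
    n_snps: int, pair_fraction: float, rng: np.random.Generator
) -> list[str]:
    """Fragment labels with the requested fraction of two-SNP fragments."""
    # pairs / (pairs + singles) = f  with  2*pairs + singles = n_snps
    n_pairs = int(round(pair_fraction * n_snps / (1.0 + pair_fraction)))
    n_pairs = min(n_pairs, n_snps // 2)
    order = rng.permutation(n_snps)
    labels = [""] * n_snps
    frag = 0
    for k in range(n_pairs):
        labels[order[2 * k]] = f"frag{frag:05d}"
        labels[order[2 * k + 1]] = f"frag{frag:05d}"
        frag += 1
    for j in order[2 * n_pairs :]:
        labels[j] = f"frag{frag:05d}"
        frag += 1
    return labels


@dataclass
class SimulatedDataset:
    """Everything a downstream evaluation needs: data plus truth."""

    genotypes: GenotypeMatrix
    truth: SimulatedPedigree
    ancestral: AlleleFrequencies
    population_frequencies: dict[str, AlleleFrequencies]
    config: SimConfig = field(repr=False, default=None)


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate a full dataset from one configuration (deterministic)."""
    rng = np.random.default_rng(config.seed)
    freq_seed, geno_seed = (int(s) for s in rng.integers(2**31, size=2))
    pop_names = [p.name for p in config.populations]
    ancestral, pop_freqs = simulate_frequencies(
        config.n_snps,
        config.maf_low,
        config.maf_high,
        pop_names,
        config.fst_target,
        seed=freq_seed,
    )
    sim_ped = simulate_pedigree(config)
    genotypes = simulate_genotypes(
        sim_ped,
        pop_freqs,
        missing_rate=config.missing_rate,
        error_rate=config.genotyping_error_rate,
        seed=geno_seed,
        fragment_pair_fraction=config.fragment_pair_fraction,
        missing_profile=config.missing_profile,
    )
    return SimulatedDataset(
        genotypes=genotypes,
        truth=sim_ped,
        ancestral=ancestral,
        population_frequencies=pop_freqs,
        config=config,
    )


def default_config(seed: int = 0) -> SimConfig:
    """Default three-river scenario.

    Roughly half-scale replicas of the sampled rivers: one population
    dominated by singletons, the other two by a few large full-sib
    families with one half-sib link each; 3000 raw SNPs (matching the
    scale of the marker panel the pipeline targets, so that QC leaves
    a realistic analysis set), weak differentiation (F about 0.01),
    5% missing calls concentrated in a poor-call-rate marker minority.
    """
    return SimConfig(
        populations=[
            PopulationSpec(
                name="riverA", n_singletons=50, family_sizes=[4, 3], half_sib_links=[]
            ),
            PopulationSpec(
                name="riverB",
                n_singletons=16,
                family_sizes=[12, 10, 8, 6, 5],
                half_sib_links=[(0, 1)],
            ),
            PopulationSpec(
                name="riverC",
                n_singletons=16,
                family_sizes=[14, 12, 10, 8],
                half_sib_links=[(1, 2)],
            ),
        ],
        n_snps=3000,
        maf_low=0.02,
        maf_high=0.5,
        fst_target=0.01,
        missing_rate=0.05,
        genotyping_error_rate=0.001,
        fragment_pair_fraction=0.15,
        seed=seed,
    )
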