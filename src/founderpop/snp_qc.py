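"""Four-stage SNP quality control for reduced-representation genotypes.

Stages, in order:

1. marker filter — drop SNPs with missing rate above 0.05 or observed
   minor allele frequency below 0.05 (both computed over all
   individuals);
2. fragment dedup — keep one randomly chosen SNP per restriction
   fragment, since SNPs on one fragment are effectively one marker;
3. LD pruning — iteratively drop one random member of the SNP pair with
   the highest squared Pearson correlation of allele counts until all
   pairwise r-squared values fall below 0.2;
4. Hardy-Weinberg filter — chi-squared goodness-of-fit per SNP and
   population on a putatively unrelated subset, Dunn-Sidak corrected;
   a SNP failing in any population is dropped.

Each stage returns the filtered matrix plus a report entry recording
what entered, what survived, and which SNPs were removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_model import GenotypeMatrix

__all__ = [
    "QCReport",
    "filter_missingness_maf",
    "dedup_fragments",
    "pairwise_r2",
    "ld_prune",
    "hwe_filter",
    "maf_subset",
]

log = logging.getLogger("founderpop")


@dataclass
class StageReport:
    name: str
    n_in: int
    n_out: int
    removed: list[str]

    def __post_init__(self) -> None:
        if self.n_out > self.n_in or self.n_in - self.n_out != len(self.removed):
            raise ValueError(
                f"stage {self.name}: inconsistent counts "
                f"({self.n_in} in, {self.n_out} out, {len(self.removed)} removed)"
            )


@dataclass
class QCReport:
    """Accumulated per-stage accounting of the QC cascade."""

    stages: list[StageReport] = field(default_factory=list)
    seed: int | None = None
    details: dict = field(default_factory=dict)

    def add(self, stage: StageReport) -> None:
        if self.stages and stage.n_in != self.stages[-1].n_out:
            raise ValueError(
                f"stage {stage.name} enters with {stage.n_in} SNPs but the "
                f"previous stage left {self.stages[-1].n_out}"
            )
        self.stages.append(stage)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "stages": [
                {
                    "name": s.name,
                    "n_in": s.n_in,
                    "n_out": s.n_out,
                    "removed": s.removed,
                }
                for s in self.stages
            ],
            "details": self.details,
        }


def _observed_maf(g: GenotypeMatrix) -> np.ndarray:
    """Minor allele frequency per SNP over all non-missing calls."""
    calls = g.masked_calls()
    p = np.asarray(calls.mean(axis=0)) / 2.0
    n_obs = (~g.missing_mask()).sum(axis=0)
    p = np.where(n_obs > 0, p, np.nan)
    return np.minimum(p, 1.0 - p)


def filter_missingness_maf(
    g: GenotypeMatrix, max_missing: float = 0.05, min_maf: float = 0.05
) -> tuple[GenotypeMatrix, StageReport]:
    """Drop SNPs with missing rate > ``max_missing`` or MAF < ``min_maf``.

    Retention is inclusive at both thresholds: a SNP at MAF exactly
    ``min_maf`` or missing rate exactly ``max_missing`` survives.
    A SNP with no calls at all has undefined MAF and is dropped.
    """
    if g.n_snps == 0:
        raise ValueError("empty genotype matrix")
    miss_rate = g.missing_mask().mean(axis=0)
    maf = _observed_maf(g)
    keep = (miss_rate <= max_missing) & ~np.isnan(maf) & (maf >= min_maf)
    kept_ids = [s for s, k in zip(g.snp_ids, keep) if k]
    removed = [s for s, k in zip(g.snp_ids, keep) if not k]
    if not kept_ids:
        log.warning("missingness/MAF filter removed every SNP")
    out = g.subset_snps(kept_ids)
    report = StageReport("missingness_maf", g.n_snps, out.n_snps, removed)
    log.info("missingness/MAF filter: %d -> %d SNPs", g.n_snps, out.n_snps)
    return out, report


def dedup_fragments(
    g: GenotypeMatrix, seed: int = 0
) -> tuple[GenotypeMatrix, StageReport]:
    """Keep exactly one SNP per distinct fragment, chosen at random."""
    rng = np.random.default_rng(seed)
    by_fragment: dict[str, list[int]] = {}
    for j, frag in enumerate(g.fragment_ids):
        by_fragment.setdefault(frag, []).append(j)
    keep_idx = set()
    for frag, members in by_fragment.items():
        keep_idx.add(members[int(rng.integers(len(members)))])
    kept_ids = [s for j, s in enumerate(g.snp_ids) if j in keep_idx]
    removed = [s for j, s in enumerate(g.snp_ids) if j not in keep_idx]
    out = g.subset_snps(kept_ids)
    report = StageReport("fragment_dedup", g.n_snps, out.n_snps, removed)
    log.info("fragment dedup: %d -> %d SNPs", g.n_snps, out.n_snps)
    return out, report


def _pairwise_r2_matrix(calls: np.ndarray, missing: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between all SNP pairs.

    Pairwise-complete observations; entries are NaN where fewer than two
    complete pairs exist or either SNP has zero variance over the
    complete pairs (no pruning constraint).
    """
    x = calls.astype(float)
    m = (~missing).astype(float)
    x = np.where(missing, 0.0, x)
    n = m.T @ m  # complete pairs per SNP pair
    sx = x.T @ m
    sxx = (x * x).T @ m
    sxy = x.T @ x
    with np.errstate(divide="ignore", invalid="ignore"):
        ex = sx / n
        ey = sx.T / n
        cov = sxy / n - ex * ey
        vx = sxx / n - ex**2
        vy = sxx.T / n - ey**2
        r2 = cov**2 / (vx * vy)
    r2[n < 2] = np.nan
    # zero variance -> undefined, flagged NaN
    tiny = 1e-12
    r2[(vx < tiny) | (vy < tiny)] = np.nan
    return r2


def pairwise_r2(g: GenotypeMatrix, snp_a: str, snp_b: str) -> float:
    """r-squared of allele counts between two SNPs (pairwise complete).

    Returns NaN when undefined (zero variance or < 2 complete pairs);
    the pruner treats NaN as imposing no constraint.
    """
    ja = g.snp_ids.index(snp_a)
    jb = g.snp_ids.index(snp_b)
    both = ~(g.missing_mask()[:, [ja, jb]].any(axis=1))
    a = g.calls[both, ja].astype(float)
    b = g.calls[both, jb].astype(float)
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_prune(
    g: GenotypeMatrix, r2_max: float = 0.2, seed: int = 0
) -> tuple[GenotypeMatrix, StageReport]:
    """Iteratively remove one random SNP of the worst pair until all
    defined pairwise r-squared values are below ``r2_max``.

    When several pairs tie at the maximum, the lexicographically
    smallest index pair goes first; within the chosen pair the victim is
    drawn uniformly with the given seed.  Because correlations are
    pairwise-complete, removing a SNP never changes the r-squared of the
    surviving pairs, so the matrix is computed once.
    """
    rng = np.random.default_rng(seed)
    n = g.n_snps
    if n < 2:
        return g, StageReport("ld_prune", n, n, [])
    r2 = _pairwise_r2_matrix(g.calls, g.missing_mask())
    np.fill_diagonal(r2, np.nan)
    work = np.where(np.isnan(r2), -np.inf, r2)
    # only consider the upper triangle to get deterministic (i, j) ties
    work[np.tril_indices(n)] = -np.inf
    removed_idx: list[int] = []
    while True:
        flat = np.argmax(work)
        i, j = np.unravel_index(flat, work.shape)
        if work[i, j] < r2_max:
            break
        victim = int(i if rng.integers(2) == 0 else j)
        removed_idx.append(victim)
        work[victim, :] = -np.inf
        work[:, victim] = -np.inf
    removed_set = set(removed_idx)
    kept_ids = [s for j, s in enumerate(g.snp_ids) if j not in removed_set]
    removed = [g.snp_ids[j] for j in removed_idx]
    out = g.subset_snps(kept_ids)
    report = StageReport("ld_prune", n, out.n_snps, removed)
    log.info("LD pruning (r2 < %g): %d -> %d SNPs", r2_max, n, out.n_snps)
    return out, report


def _hwe_chisq_pvalues(sub: GenotypeMatrix) -> np.ndarray:
    """Per-SNP 1-df chi-squared HWE p-values; NaN where untestable."""
    calls = sub.calls
    miss = sub.missing_mask()
    n0 = ((calls == 0) & ~miss).sum(axis=0).astype(float)
    n1 = ((calls == 1) & ~miss).sum(axis=0).astype(float)
    n2 = ((calls == 2) & ~miss).sum(axis=0).astype(float)
    n = n0 + n1 + n2
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (n1 + 2 * n2) / (2 * n)
        q = 1.0 - p
        e0, e1, e2 = n * q * q, 2 * n * p * q, n * p * p
        chi2 = (n0 - e0) ** 2 / e0 + (n1 - e1) ** 2 / e1 + (n2 - e2) ** 2 / e2
    pvals = stats.chi2.sf(chi2, df=1)
    # monomorphic or empty: no evidence against HWE, not a test
    untestable = (n == 0) | (p <= 0) | (p >= 1)
    pvals = np.where(untestable, np.nan, pvals)
    return pvals


def hwe_filter(
    g: GenotypeMatrix,
    test_individuals: dict[str, list[str]],
    alpha: float = 0.05,
    n_tests: int | None = None,
) -> tuple[GenotypeMatrix, StageReport]:
    """Remove SNPs deviating from Hardy-Weinberg in any population.

    ``test_individuals`` maps population label to the individuals the
    test runs on — intended to be the putatively unrelated subsets, so
    that sib-group structure is not mistaken for genotyping problems.
    The per-test level is the Dunn-Sidak corrected
    ``1 - (1 - alpha)**(1/m)`` with ``m`` the number of tests actually
    performed (testable SNP x population combinations); pass ``n_tests``
    to fix ``m`` explicitly.
    """
    if not test_individuals:
        raise ValueError("no test populations supplied")
    pvals = []
    for pop, ids in test_individuals.items():
        if not ids:
            raise ValueError(f"empty test subset for population {pop!r}")
        pvals.append(_hwe_chisq_pvalues(g.subset_individuals(list(ids))))
    pmat = np.vstack(pvals)  # populations x SNPs
    m = int(np.sum(~np.isnan(pmat))) if n_tests is None else int(n_tests)
    if m == 0:
        alpha_adj = alpha
    else:
        alpha_adj = 1.0 - (1.0 - alpha) ** (1.0 / m)
    with np.errstate(invalid="ignore"):
        fails = np.nansum(pmat < alpha_adj, axis=0) > 0
    kept_ids = [s for s, f in zip(g.snp_ids, fails) if not f]
    removed = [s for s, f in zip(g.snp_ids, fails) if f]
    out = g.subset_snps(kept_ids)
    report = StageReport("hwe", g.n_snps, out.n_snps, removed)
    log.info(
        "HWE filter (alpha=%g, m=%d, alpha_adj=%.3g): %d -> %d SNPs",
        alpha,
        m,
        alpha_adj,
        g.n_snps,
        out.n_snps,
    )
    return out, report


def maf_subset(g: GenotypeMatrix, min_maf: float = 0.2) -> GenotypeMatrix:
    """SNPs with MAF strictly above ``min_maf`` (sibship-inference set).

    Highly informative markers only; used when assigning sibship, where
    low-MAF SNPs contribute little contrast between sib groups.
    """
    maf = _observed_maf(g)
    kept = [s for s, v in zip(g.snp_ids, maf) if not np.isnan(v) and v > min_maf]
    return g.subset_snps(kept)
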