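"""Diversity and differentiation statistics on the putative founders.

These summaries are meant to run on the putatively unrelated subsets
identified by the relatedness stage — large sib groups otherwise bias
allele-frequency-based statistics.  Implemented here:

* observed/expected heterozygosity per SNP and population, with a
  paired t-test of H_obs vs H_exp and a permutation test for pairwise
  differences in mean H_exp;
* the Weir & Cockerham (1984) multi-locus F_ST estimator theta with a
  percentile bootstrap confidence interval over loci;
* a two-level analysis of molecular variance (AMOVA) on pairwise
  Hamming distances of allele counts, with a permutation p-value;
* rarefied allelic richness and private allelic richness from
  hypergeometric sampling theory (the ADZE approach);
* K-means clustering of principal components scored by a BIC, to ask
  how many clusters the genotypes actually support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .data_model import GenotypeMatrix

__all__ = [
    "DiversityTable",
    "FstResult",
    "AmovaResult",
    "RichnessCurves",
    "ClusterScan",
    "heterozygosity",
    "hexp_permutation_test",
    "wc_fst",
    "amova",
    "rarefied_richness",
    "pca_kmeans_bic",
]

log = logging.getLogger("founderpop")


# ---------------------------------------------------------------------------
# Heterozygosity
# ---------------------------------------------------------------------------


@dataclass
class DiversityTable:
    """Per-SNP and per-population heterozygosities with tests."""

    per_snp: pd.DataFrame  # columns: population, snp_id, h_obs, h_exp, n
    means: dict[str, dict[str, float]]  # pop -> {"h_obs": ..., "h_exp": ...}
    t_tests: dict[str, dict[str, float]]  # pop -> {"t": ..., "p": ...}


def _per_snp_het(
    sub: GenotypeMatrix, correction: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    calls = sub.calls
    miss = sub.missing_mask()
    n = (~miss).sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        het = ((calls == 1) & ~miss).sum(axis=0) / n
        p = np.asarray(sub.masked_calls().mean(axis=0)) / 2.0
        hexp = 2.0 * p * (1.0 - p)
        if correction:
            hexp = hexp * n / (n - 1.0)
    het = np.where(n > 0, het, np.nan)
    hexp = np.where(n > 0, hexp, np.nan)
    return het, hexp, n


def heterozygosity(
    g: GenotypeMatrix,
    subsets: dict[str, list[str]],
    correction: bool = False,
) -> DiversityTable:
    """Observed and expected heterozygosity by SNP and population.

    H_obs is the heterozygote fraction among non-missing calls; H_exp
    is ``2 p (1 - p)`` from the subset allele frequency, optionally
    multiplied by the small-sample factor ``n / (n - 1)``.  SNPs with
    no calls in a subset are excluded from that subset's means.  The
    paired t-test compares H_obs with H_exp across SNPs within each
    population.
    """
    if not subsets:
        raise ValueError("no subsets supplied")
    rows = []
    means: dict[str, dict[str, float]] = {}
    t_tests: dict[str, dict[str, float]] = {}
    for pop, ids in subsets.items():
        sub = g.subset_individuals(list(ids))
        hobs, hexp, n = _per_snp_het(sub, correction)
        ok = ~np.isnan(hobs)
        if (~ok).any():
            log.info(
                "population %s: %d SNPs with no calls excluded from "
                "heterozygosity means",
                pop,
                int((~ok).sum()),
            )
        for snp, o, e, c in zip(g.snp_ids, hobs, hexp, n):
            rows.append((pop, snp, o, e, int(c)))
        means[pop] = {
            "h_obs": float(np.mean(hobs[ok])),
            "h_exp": float(np.mean(hexp[ok])),
        }
        diffs = hobs[ok] - hexp[ok]
        if diffs.size > 1 and np.ptp(diffs) > 0:
            t, p = stats.ttest_rel(hobs[ok], hexp[ok])
        else:  # undefined with < 2 SNPs or constant difference
            t, p = np.nan, np.nan
        t_tests[pop] = {"t": float(t), "p": float(p)}
    per_snp = pd.DataFrame(
        rows, columns=["population", "snp_id", "h_obs", "h_exp", "n"]
    )
    return DiversityTable(per_snp=per_snp, means=means, t_tests=t_tests)


def hexp_permutation_test(
    g: GenotypeMatrix,
    subset_a: list[str],
    subset_b: list[str],
    n_sim: int = 999,
    seed: int = 0,
) -> float:
    """Permutation p-value for a difference in mean expected
    heterozygosity between two groups of individuals.

    Statistic: |mean over SNPs of H_exp(a) - mean of H_exp(b)|.  The
    null distribution reassigns the pooled individuals to groups of the
    original sizes ``n_sim`` times; the p-value uses the add-one
    convention ``(1 + exceedances) / (1 + n_sim)``.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if set(subset_a) & set(subset_b):
        raise ValueError("subsets overlap")
    rng = np.random.default_rng(seed)
    pooled = list(subset_a) + list(subset_b)
    sub = g.subset_individuals(pooled)
    calls = sub.calls
    miss = sub.missing_mask()
    na = len(subset_a)

    def stat(index_a: np.ndarray, index_b: np.ndarray) -> float:
        out = []
        for idx in (index_a, index_b):
            c = calls[idx]
            m = miss[idx]
            nn = (~m).sum(axis=0).astype(float)
            with np.errstate(divide="ignore", invalid="ignore"):
                p = np.where(m, 0, c).sum(axis=0) / (2.0 * nn)
                hexp = 2.0 * p * (1.0 - p)
            out.append(float(np.nanmean(np.where(nn > 0, hexp, np.nan))))
        return abs(out[0] - out[1])

    all_idx = np.arange(len(pooled))
    observed = stat(all_idx[:na], all_idx[na:])
    exceed = 0
    for _ in range(n_sim):
        perm = rng.permutation(all_idx)
        if stat(perm[:na], perm[na:]) >= observed:
            exceed += 1
    return (1 + exceed) / (1 + n_sim)


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST
# ---------------------------------------------------------------------------


@dataclass
class FstResult:
    """Multi-locus Weir-Cockerham theta with a bootstrap CI over loci."""

    pair: tuple[str, str]
    theta: float
    ci_low: float
    ci_high: float
    n_loci: int
    n_boot: int
    components: pd.DataFrame = field(repr=False, default=None)


def _wc_components(
    calls_by_pop: list[np.ndarray], miss_by_pop: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus W&C (1984) variance components a, b, c for r populations.

    Inputs are per-population allele-count matrices over common loci.
    Returns (a, b, c, defined) arrays; loci where the estimator is
    undefined (a population without calls, or mean sample size <= 1)
    are flagged out.
    """
    r = len(calls_by_pop)
    n_i, p_i, h_i = [], [], []
    for calls, miss in zip(calls_by_pop, miss_by_pop):
        n = (~miss).sum(axis=0).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(miss, 0, calls).sum(axis=0) / (2.0 * n)
            h = ((calls == 1) & ~miss).sum(axis=0) / n
        n_i.append(n)
        p_i.append(p)
        h_i.append(h)
    n_i = np.stack(n_i)  # r x L
    p_i = np.stack(p_i)
    h_i = np.stack(h_i)

    nbar = n_i.mean(axis=0)
    rn = r * nbar
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = (rn - (n_i**2).sum(axis=0) / rn) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / rn
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / rn
        inner = pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0
        a = (nbar / nc) * (s2 - inner / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
    defined = (n_i > 0).all(axis=0) & (nbar > 1) & (nc > 0)
    return a, b, c, defined


def wc_fst(
    g: GenotypeMatrix,
    subset_a: list[str],
    subset_b: list[str],
    n_boot: int = 2000,
    seed: int = 0,
    pair: tuple[str, str] = ("a", "b"),
) -> FstResult:
    """Pairwise multi-locus Weir & Cockerham (1984) theta.

    Per-locus among-population (a), among-individual (b) and
    within-individual (c) variance components are combined as
    ``theta = sum(a) / sum(a + b + c)`` over loci with defined
    components.  The 95% CI is the 2.5/97.5 percentile of theta
    recomputed on ``n_boot`` resamples of loci with replacement.
    """
    if len(subset_a) < 2 or len(subset_b) < 2:
        raise ValueError("each subset needs at least two individuals")
    sa = g.subset_individuals(list(subset_a))
    sb = g.subset_individuals(list(subset_b))
    a, b, c, defined = _wc_components(
        [sa.calls, sb.calls], [sa.missing_mask(), sb.missing_mask()]
    )
    # a locus monomorphic overall contributes nothing to either sum
    poly = defined & ((a + b + c) != 0)
    if int(poly.sum()) < 2:
        raise ValueError("fewer than two polymorphic loci with defined components")
    a, b, c = a[defined], b[defined], c[defined]
    tot = a + b + c
    theta = float(a.sum() / tot.sum())
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    L = a.size
    for k in range(n_boot):
        idx = rng.integers(0, L, size=L)
        denom = tot[idx].sum()
        boots[k] = a[idx].sum() / denom if denom != 0 else np.nan
    ci_low, ci_high = np.nanpercentile(boots, [2.5, 97.5])
    snp_ids = [s for s, d in zip(g.snp_ids, defined) if d]
    comp = pd.DataFrame({"snp_id": snp_ids, "a": a, "b": b, "c": c})
    return FstResult(
        pair=pair,
        theta=theta,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_loci=int(L),
        n_boot=n_boot,
        components=comp,
    )


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


@dataclass
class AmovaResult:
    """Two-level AMOVA: among populations / among individuals within."""

    sigma_among: float
    sigma_within: float
    proportion_among: float
    p_value: float
    df_among: int
    df_within: int
    n_loci: int
    n_perm: int


def _hamming_distances(calls: np.ndarray, miss: np.ndarray) -> np.ndarray:
    """Pairwise allele-count Hamming distances, missing-rescaled.

    d_ij = sum over pairwise-complete loci of |c_i - c_j|, rescaled by
    L / L_complete so individuals with missing data are comparable.
    """
    n, L = calls.shape
    x = np.where(miss, 0, calls).astype(float)
    ok = (~miss).astype(float)
    d = np.zeros((n, n))
    for i in range(n):
        both = ok[i] * ok  # n x L
        diff = np.abs(x[i] - x) * both
        used = both.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            d[i] = diff.sum(axis=1) * (L / used)
        d[i, used == 0] = 0.0
    np.fill_diagonal(d, 0.0)
    return d


def _amova_components(
    d2: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float]:
    """Variance components from a squared-distance matrix.

    Standard sums-of-squared-deviations partition: SS_total over all
    pairs divided by N, SS_within per group divided by group size.
    """
    n = d2.shape[0]
    groups = np.unique(labels)
    r = groups.size
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    sizes = []
    for grp in groups:
        idx = np.where(labels == grp)[0]
        sizes.append(idx.size)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    ss_among = ss_total - ss_within
    sizes = np.array(sizes, dtype=float)
    df_among = r - 1
    df_within = n - r
    sigma_within = ss_within / df_within
    ms_among = ss_among / df_among
    n0 = (n - (sizes**2).sum() / n) / df_among
    sigma_among = (ms_among - sigma_within) / n0
    total = sigma_among + sigma_within
    prop = sigma_among / total if total > 0 else 0.0
    return sigma_among, sigma_within, prop


def amova(
    g: GenotypeMatrix,
    subsets: dict[str, list[str]],
    missing_cutoff: float = 0.1,
    n_perm: int = 999,
    seed: int = 0,
) -> AmovaResult:
    """Two-level AMOVA on allele-count Hamming distances.

    SNPs with missing rate above ``missing_cutoff`` (over the analysed
    individuals) are dropped first.  Within-individual variance is not
    partitioned.  Significance: the among-population proportion is
    recomputed under ``n_perm`` random permutations of individuals
    across populations; add-one p-value.
    """
    if len(subsets) < 2:
        raise ValueError("AMOVA needs at least two populations")
    for pop, ids in subsets.items():
        if len(ids) < 2:
            raise ValueError(f"population {pop!r} has fewer than two individuals")
    ids = [i for pop in subsets.values() for i in pop]
    labels = np.array(
        [k for k, pop in enumerate(subsets.values()) for _ in pop]
    )
    sub = g.subset_individuals(ids)
    miss_rate = sub.missing_mask().mean(axis=0)
    keep = [s for s, r in zip(sub.snp_ids, miss_rate) if r <= missing_cutoff]
    sub = sub.subset_snps(keep)
    if sub.n_snps == 0:
        raise ValueError("no SNPs below the missing-data cutoff")
    d = _hamming_distances(sub.calls, sub.missing_mask())
    d2 = d**2
    sigma_among, sigma_within, prop = _amova_components(d2, labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        _, _, p = _amova_components(d2, perm)
        if p >= prop:
            exceed += 1
    p_value = (1 + exceed) / (1 + n_perm)
    return AmovaResult(
        sigma_among=float(sigma_among),
        sigma_within=float(sigma_within),
        proportion_among=float(prop),
        p_value=float(p_value),
        df_among=len(subsets) - 1,
        df_within=len(ids) - len(subsets),
        n_loci=sub.n_snps,
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# Rarefied allelic richness (ADZE-style)
# ---------------------------------------------------------------------------


@dataclass
class RichnessCurves:
    """Richness and private richness vs standardised sample size."""

    curves: pd.DataFrame  # columns: population, g, richness, private_richness


def _absent_prob(n_total: np.ndarray, n_allele: np.ndarray, q: int) -> np.ndarray:
    """P(allele absent from a sample of q copies) = C(N-Na, q) / C(N, q)."""
    n_total = np.asarray(n_total, dtype=float)
    n_other = n_total - np.asarray(n_allele, dtype=float)
    with np.errstate(invalid="ignore"):
        lognum = gammaln(n_other + 1) - gammaln(q + 1) - gammaln(n_other - q + 1)
        logden = gammaln(n_total + 1) - gammaln(q + 1) - gammaln(n_total - q + 1)
        out = np.exp(lognum - logden)
    out = np.where(n_other < q, 0.0, out)
    return out


def rarefied_richness(
    g: GenotypeMatrix, subsets: dict[str, list[str]], max_g: int
) -> RichnessCurves:
    """Expected allele counts at standardised sample sizes (rarefaction).

    For each locus and population with ``N`` sampled gene copies of
    which ``N_a`` carry allele a, the expected number of distinct
    alleles in a subsample of ``q`` copies is
    ``sum_a (1 - C(N - N_a, q) / C(N, q))``; the private richness of a
    population is the expected number of alleles present in its
    subsample and absent from every other population's.  Curves are
    means over loci for q = 1..max_g.
    """
    pops = list(subsets)
    copies: dict[str, np.ndarray] = {}
    count1: dict[str, np.ndarray] = {}
    for pop in pops:
        sub = g.subset_individuals(list(subsets[pop]))
        n_obs = (~sub.missing_mask()).sum(axis=0)
        copies[pop] = 2 * n_obs
        count1[pop] = np.where(sub.missing_mask(), 0, sub.calls).sum(axis=0)
        min_copies = int(copies[pop].min()) if copies[pop].size else 0
        if max_g > min_copies:
            raise ValueError(
                f"standardised size {max_g} exceeds the gene copies "
                f"({min_copies}) available in population {pop!r}"
            )
    rows = []
    for q in range(1, max_g + 1):
        present: dict[str, dict[int, np.ndarray]] = {}
        for pop in pops:
            n = copies[pop]
            na1 = count1[pop]
            na0 = n - na1
            present[pop] = {
                1: 1.0 - _absent_prob(n, na1, q),
                0: 1.0 - _absent_prob(n, na0, q),
            }
        for pop in pops:
            rich = present[pop][0] + present[pop][1]
            priv = np.zeros_like(rich)
            for allele in (0, 1):
                term = present[pop][allele].copy()
                for other in pops:
                    if other != pop:
                        term = term * (1.0 - present[other][allele])
                priv += term
            rows.append((pop, q, float(rich.mean()), float(priv.mean())))
    curves = pd.DataFrame(
        rows, columns=["population", "g", "richness", "private_richness"]
    )
    return RichnessCurves(curves=curves)


# ---------------------------------------------------------------------------
# PCA + K-means + BIC
# ---------------------------------------------------------------------------


@dataclass
class ClusterScan:
    """BIC profile over K and the chosen optimum."""

    bic: pd.DataFrame  # columns: k, wss, bic
    optimum_k: int


def pca_kmeans_bic(
    g: GenotypeMatrix,
    max_k: int = 20,
    n_components: int | None = None,
    n_starts: int = 20,
    seed: int = 0,
) -> ClusterScan:
    """How many clusters do the genotypes support?

    Genotypes are mean-imputed and centred, projected on principal
    components (default: all with positive variance), and K-means is
    fitted for K = 1..max_k, keeping the best of ``n_starts`` random
    initialisations each.  Model size is scored by
    ``BIC(K) = n ln(WSS_K / n) + K ln(n)`` on the retained components;
    the optimum is the K minimising it.  K values reaching WSS = 0 are
    excluded (degenerate fit).
    """
    n = g.n_individuals
    if max_k > n:
        raise ValueError(f"max_k={max_k} exceeds the {n} individuals")
    x = g.calls.astype(float)
    miss = g.missing_mask()
    col_mean = np.asarray(g.masked_calls().mean(axis=0), dtype=float)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    x[miss] = np.broadcast_to(col_mean, x.shape)[miss]
    x = x - x.mean(axis=0)
    k_max_comp = min(n - 1, x.shape[1])
    pca = PCA(n_components=k_max_comp, random_state=seed)
    scores = pca.fit_transform(x)
    if n_components is not None:
        scores = scores[:, : min(n_components, scores.shape[1])]
    else:
        scores = scores[:, pca.explained_variance_ > 1e-12]
    rng = np.random.default_rng(seed)
    rows = []
    best_k, best_bic = None, np.inf
    for k in range(1, max_k + 1):
        km = KMeans(
            n_clusters=k,
            n_init=n_starts,
            random_state=int(rng.integers(2**31)),
        ).fit(scores)
        wss = float(km.inertia_)
        if wss <= 0:
            rows.append((k, wss, np.nan))
            continue
        bic = n * np.log(wss / n) + k * np.log(n)
        rows.append((k, wss, bic))
        if bic < best_bic:
            best_bic, best_k = bic, k
    table = pd.DataFrame(rows, columns=["k", "wss", "bic"])
    if best_k is None:
        raise ValueError("no K produced a finite BIC")
    return ClusterScan(bic=table, optimum_k=int(best_k))
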