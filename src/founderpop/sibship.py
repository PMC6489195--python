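"""Sibship assignment on genomic relationships and the founder pipeline.

In a single sampled generation with no genotyped parents, the expected
additive relationship is 0.5 within a full-sib family, 0.25 between
half-sib families and 0 otherwise.  The assigner formalises the visual
reading of a clustered GRM heatmap: individuals joined by a genomic
relationship of at least ``full_cutoff`` (default 0.375, the midpoint
of 0.25 and 0.5) form full-sib groups via connected components, and
group pairs whose mean between-group relationship falls in
``[half_low, half_high)`` (defaults 0.125 and 0.375, the midpoints of
0/0.25 and 0.25/0.5) are declared half-sib linked.  Each group then
receives two dummy parents, with linked groups sharing exactly one, so
that the pedigree relationship matrix reproduces the assignment.

``run_founder_pipeline`` chains everything: QC (the Hardy-Weinberg
stage running on preliminary unrelated subsets), a first-pass GRM from
frequencies observed in all individuals, preliminary sibship, maximal
unrelated-set extraction, frequency re-estimation from that set, a
second-pass GRM, final sibship and the dummy-parent pedigree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import snp_qc
from .data_model import GenotypeMatrix, Pedigree
from .relatedness import (
    AMatrix,
    GMatrix,
    build_a,
    build_g,
    estimate_frequencies,
    refine_g,
    select_unrelated,
)

__all__ = [
    "SibshipAssignment",
    "HalfSibLink",
    "PipelineConfig",
    "PopulationResult",
    "cluster_order",
    "assign_full_sib_groups",
    "link_half_sibs",
    "build_dummy_pedigree",
    "render_heatmaps",
    "run_founder_pipeline",
    "realise_parent_sharing",
]

log = logging.getLogger("founderpop")


@dataclass(frozen=True)
class HalfSibLink:
    """Unordered pair of full-sib group indices sharing one parent."""

    group_a: int
    group_b: int
    mean_g: float

    def pair(self) -> frozenset[int]:
        return frozenset((self.group_a, self.group_b))


@dataclass
class SibshipAssignment:
    """Partition into full-sib groups plus half-sib links between them."""

    population: str
    full_sib_groups: list[list[str]]
    half_sib_links: list[HalfSibLink]
    full_cutoff: float = 0.375
    half_low: float = 0.125
    half_high: float = 0.375

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for grp in self.full_sib_groups:
            for ind in grp:
                if ind in seen:
                    raise ValueError(f"{ind!r} appears in two full-sib groups")
                seen.add(ind)
        n = len(self.full_sib_groups)
        for link in self.half_sib_links:
            if link.group_a == link.group_b:
                raise ValueError("half-sib link must connect distinct groups")
            if not (0 <= link.group_a < n and 0 <= link.group_b < n):
                raise ValueError("half-sib link references unknown group")

    @property
    def individual_ids(self) -> list[str]:
        return [i for grp in self.full_sib_groups for i in grp]

    def group_of(self) -> dict[str, int]:
        return {
            ind: k for k, grp in enumerate(self.full_sib_groups) for ind in grp
        }

    def canonical(self) -> tuple:
        """Order-free representation for equality across runs."""
        groups = sorted(tuple(sorted(g)) for g in self.full_sib_groups)
        index = {tuple(sorted(g)): k for k, g in enumerate(groups)}
        remap = {}
        for k, grp in enumerate(self.full_sib_groups):
            remap[k] = index[tuple(sorted(grp))]
        links = sorted(
            tuple(sorted((remap[l.group_a], remap[l.group_b])))
            for l in self.half_sib_links
        )
        return tuple(groups), tuple(links)


def cluster_order(g: GMatrix) -> tuple[list[str], np.ndarray]:
    """Ward clustering leaf order for heatmap display.

    Dissimilarity is ``max(G) - g_ij`` (diagonal excluded), which
    preserves the relationship ranking without requiring a PSD
    correction; linkage is the Ward criterion on that dissimilarity
    (the 'Ward2' convention of hierarchical clustering on
    distances).  Returns (leaf-ordered ids, linkage matrix).
    """
    n = len(g.individual_ids)
    if n < 2:
        raise ValueError("clustering needs at least two individuals")
    off = g.values.copy()
    np.fill_diagonal(off, -np.inf)
    top = float(off.max())
    d = top - g.values
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)
    z = hierarchy.linkage(squareform(d, checks=False), method="ward")
    order = hierarchy.leaves_list(z)
    return [g.individual_ids[i] for i in order], z


def assign_full_sib_groups(
    g: GMatrix, full_cutoff: float = 0.375
) -> list[list[str]]:
    """Full-sib groups by average-linkage agglomeration at ``full_cutoff``.

    Clusters are merged while the mean between-cluster relationship is
    at least ``full_cutoff`` (highest first), which is the block
    structure a clustered heatmap shows.  A true full-sib family is a
    clique of relationships near 0.5, so its group survives individual
    noisy pairs; conversely two half-sib families (mean near 0.25) are
    never joined by one outlying pair, which single-linkage components
    would be vulnerable to.  Group cohesion is audited: a group whose
    mean internal relationship falls below 0.4 is logged as suspicious.
    """
    ids = g.individual_ids
    n = len(ids)
    if n == 1:
        return [[ids[0]]]
    off = g.values.copy()
    np.fill_diagonal(off, -np.inf)
    shift = float(off.max())
    d = shift - g.values
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)
    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    # merges at height < shift - cutoff have mean similarity >= cutoff
    labels = hierarchy.fcluster(z, t=shift - full_cutoff, criterion="distance")
    groups: list[list[str]] = []
    for lab in np.unique(labels):
        members = np.where(labels == lab)[0]
        groups.append([ids[i] for i in members])
        if members.size > 1:
            sub = g.values[np.ix_(members, members)]
            tri = sub[np.triu_indices(members.size, k=1)]
            if tri.mean() < 0.4:
                log.warning(
                    "full-sib group %s has mean within-group g %.3f < 0.4; "
                    "possibly not a single family",
                    [ids[i] for i in members],
                    tri.mean(),
                )
    groups.sort(key=lambda grp: ids.index(grp[0]))
    return groups


def _between_group_mean(g: GMatrix, ga: list[str], gb: list[str]) -> float:
    idx = {v: i for i, v in enumerate(g.individual_ids)}
    ia = [idx[x] for x in ga]
    ib = [idx[x] for x in gb]
    return float(g.values[np.ix_(ia, ib)].mean())


def realise_parent_sharing(
    n_groups: int,
    links: list[tuple[int, int, float]],
    strict: bool = False,
) -> tuple[dict[int, list[int]], list[tuple[int, int]], list[tuple[int, int]]]:
    """Reduce half-sib links to a parent-sharing structure.

    Each group owns two parent slots.  Links are processed in the given
    order (callers sort by closeness of the mean relationship to 0.25):
    a link joins an existing shared parent when every induced group pair
    is itself a candidate link, otherwise a fresh shared parent is
    created if both groups still have a free slot; otherwise the link is
    dropped (or, with ``strict``, raises).

    Returns ``(group_parents, accepted, dropped)`` where
    ``group_parents`` maps group index to its (up to two) shared-parent
    ids; unshared slots are filled by the caller.
    """
    link_set = {frozenset((a, b)) for a, b, _ in links}
    realised: set[frozenset[int]] = set()
    parent_groups: dict[int, set[int]] = {}
    group_parents: dict[int, list[int]] = {k: [] for k in range(n_groups)}
    accepted: list[tuple[int, int]] = []
    dropped: list[tuple[int, int]] = []
    next_parent = 0
    for a, b, _ in links:
        key = frozenset((a, b))
        if key in realised:
            accepted.append((a, b))
            continue
        joined = False
        for x, y in ((a, b), (b, a)):
            if joined:
                break
            for pid in group_parents[x]:
                others = parent_groups[pid] - {x}
                if len(group_parents[y]) < 2 and all(
                    frozenset((y, c)) in link_set for c in others
                ):
                    parent_groups[pid].add(y)
                    group_parents[y].append(pid)
                    realised.update(
                        frozenset((y, c)) for c in parent_groups[pid] if c != y
                    )
                    joined = True
                    break
        if not joined:
            if len(group_parents[a]) < 2 and len(group_parents[b]) < 2:
                pid = next_parent
                next_parent += 1
                parent_groups[pid] = {a, b}
                group_parents[a].append(pid)
                group_parents[b].append(pid)
                realised.add(key)
            elif strict:
                raise ValueError(
                    f"half-sib link {(a, b)} unrealisable: a group would "
                    "need more than two parents"
                )
            else:
                dropped.append((a, b))
                continue
        accepted.append((a, b))
    return group_parents, accepted, dropped


def link_half_sibs(
    g: GMatrix,
    groups: list[list[str]],
    half_low: float = 0.125,
    half_high: float = 0.375,
) -> list[HalfSibLink]:
    """Half-sib links between full-sib groups.

    A group pair whose mean between-group relationship falls in
    ``[half_low, half_high)`` is a candidate link; candidates are then
    reduced to a structure realisable with two parents per group,
    dropping the links whose mean is farthest from 0.25 first.
    """
    candidates: list[tuple[int, int, float]] = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            mean = _between_group_mean(g, groups[i], groups[j])
            if half_low <= mean < half_high:
                candidates.append((i, j, mean))
    candidates.sort(key=lambda t: (abs(t[2] - 0.25), t[0], t[1]))
    _, accepted, dropped = realise_parent_sharing(len(groups), candidates)
    if dropped:
        log.warning(
            "dropped %d unrealisable half-sib links (groups would need >2 "
            "parents): %s",
            len(dropped),
            dropped,
        )
    means = {(a, b): m for a, b, m in candidates}
    return [HalfSibLink(a, b, means[(a, b)]) for a, b in accepted]


def build_dummy_pedigree(assignment: SibshipAssignment) -> Pedigree:
    """Pedigree with two dummy parents per group, one shared per link.

    The resulting numerator relationship matrix is exactly 0.5 within
    groups, 0.25 across linked groups and 0 elsewhere.  'Sire' and
    'dam' columns are positional slots of each family, not sexes: a
    dummy parent may occupy the sire slot of one family and the dam
    slot of another.
    """
    groups = assignment.full_sib_groups
    links = [
        (l.group_a, l.group_b, l.mean_g)
        for l in sorted(
            assignment.half_sib_links,
            key=lambda l: (abs(l.mean_g - 0.25), l.group_a, l.group_b),
        )
    ]
    group_parents, _, dropped = realise_parent_sharing(len(groups), links)
    if dropped:
        log.warning("build_dummy_pedigree dropped unrealisable links: %s", dropped)
    pop = assignment.population or "pop"
    shared_name = {pid: f"D_{pop}_S{pid}" for pids in group_parents.values() for pid in pids}
    records: list[tuple[str, str, str]] = []
    dummies: set[str] = set(shared_name.values())
    private = 0
    for k, grp in enumerate(groups):
        parents = [shared_name[pid] for pid in group_parents[k]]
        while len(parents) < 2:
            name = f"D_{pop}_P{private}"
            private += 1
            parents.append(name)
            dummies.add(name)
        for ind in grp:
            records.append((ind, parents[0], parents[1]))
    return Pedigree(records=records, dummy_parents=dummies)


def render_heatmaps(
    g: GMatrix,
    a: AMatrix,
    ordering: list[str],
    path: str,
    first_pass_g: GMatrix | None = None,
    first_pass_a: AMatrix | None = None,
) -> None:
    """Side-by-side GRM and pedigree-A heatmaps in a common ordering.

    The A panel uses the three-level scheme: 0.50 black (full sibs),
    0.25 dark grey (half sibs), 0.00 light grey (unrelated).  The G
    panel carries a histogram inset of its off-diagonal relationships.
    Optional first-pass matrices prepend two panels, giving the
    four-panel biased-vs-debiased comparison.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap

    if set(g.individual_ids) != set(a.individual_ids) or set(ordering) != set(
        g.individual_ids
    ):
        raise ValueError("G, A and ordering must cover the same individuals")

    def _perm(ids: list[str]) -> np.ndarray:
        pos = {v: i for i, v in enumerate(ids)}
        return np.array([pos[x] for x in ordering])

    panels: list[tuple[str, np.ndarray, str]] = []
    if first_pass_g is not None:
        pg = _perm(first_pass_g.individual_ids)
        panels.append(("G (observed freqs, all)", first_pass_g.values[np.ix_(pg, pg)], "g"))
    if first_pass_a is not None:
        pa = _perm(first_pass_a.individual_ids)
        panels.append(("A (preliminary)", first_pass_a.values[np.ix_(pa, pa)], "a"))
    pg = _perm(g.individual_ids)
    panels.append(("G (unrelated-set freqs)", g.values[np.ix_(pg, pg)], "g"))
    pa = _perm(a.individual_ids)
    panels.append(("A (final sibship)", a.values[np.ix_(pa, pa)], "a"))

    a_cmap = ListedColormap(["#d9d9d9", "#636363", "#000000"])
    a_norm = BoundaryNorm([-0.125, 0.125, 0.375, 0.625], a_cmap.N)
    fig, axes = plt.subplots(1, len(panels), figsize=(5 * len(panels), 4.6))
    axes = np.atleast_1d(axes)
    for ax, (title, mat, kind) in zip(axes, panels):
        if kind == "a":
            shown = mat.copy()
            np.fill_diagonal(shown, 0.5)  # render self like full sib (black)
            ax.imshow(shown, cmap=a_cmap, norm=a_norm, interpolation="nearest")
        else:
            im = ax.imshow(mat, cmap="viridis", interpolation="nearest")
            fig.colorbar(im, ax=ax, fraction=0.045)
            inset = ax.inset_axes([0.62, 0.72, 0.35, 0.25])
            tri = mat[np.triu_indices(mat.shape[0], k=1)]
            inset.hist(tri, bins=40, color="grey")
            inset.tick_params(labelsize=5)
        ax.set_title(title, fontsize=9)
        ax.set_xticks([])
        ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass
class PipelineConfig:
    """Thresholds and seeds of the founder-characterisation pipeline."""

    max_missing: float = 0.05
    min_maf: float = 0.05
    r2_max: float = 0.2
    hwe_alpha: float = 0.05
    full_cutoff: float = 0.375
    half_low: float = 0.125
    half_high: float = 0.375
    sibship_min_maf: float = 0.2
    use_sibship_maf_subset: bool = True
    min_unrelated: int = 5
    max_refine_passes: int = 4
    seed: int = 0


@dataclass
class PopulationResult:
    """All per-population artifacts of one pipeline run."""

    population: str
    first_pass_g: GMatrix
    preliminary_assignment: SibshipAssignment
    preliminary_a: AMatrix
    unrelated_ids: list[str]
    second_pass_g: GMatrix
    final_assignment: SibshipAssignment
    pedigree: Pedigree
    final_a: AMatrix
    ordering: list[str]


def _threshold_sibship(
    g: GMatrix, population: str, cfg: PipelineConfig
) -> SibshipAssignment:
    groups = assign_full_sib_groups(g, cfg.full_cutoff)
    links = link_half_sibs(g, groups, cfg.half_low, cfg.half_high)
    return SibshipAssignment(
        population=population,
        full_sib_groups=groups,
        half_sib_links=links,
        full_cutoff=cfg.full_cutoff,
        half_low=cfg.half_low,
        half_high=cfg.half_high,
    )


def _sibship_view(g: GenotypeMatrix, cfg: PipelineConfig) -> GenotypeMatrix:
    if not cfg.use_sibship_maf_subset:
        return g
    sub = snp_qc.maf_subset(g, cfg.sibship_min_maf)
    return sub if sub.n_snps > 0 else g


def run_founder_pipeline(
    g: GenotypeMatrix, config: PipelineConfig | None = None
) -> tuple[dict[str, PopulationResult], snp_qc.QCReport]:
    """Full founder characterisation from raw genotypes.

    Stage order: marker filter -> fragment dedup -> LD prune ->
    preliminary per-population sibship (on a high-MAF SNP view) to
    obtain putatively unrelated subsets -> Hardy-Weinberg filter on
    those subsets -> per population: first-pass GRM (observed
    frequencies), preliminary sibship, pedigree A, maximal unrelated
    set, frequency re-estimation, second-pass GRM, final sibship,
    dummy-parent pedigree and final A.

    The frequency de-biasing pass is iterated: each round re-selects the
    unrelated set from the current assignment's pedigree A, re-estimates
    frequencies from it and rebuilds G, stopping when the assignment is
    stable (a fixed point, so a further pass changes nothing) or after
    ``max_refine_passes`` rounds.
    """
    cfg = config or PipelineConfig()
    rng = np.random.default_rng(cfg.seed)
    dedup_seed, prune_seed = (int(s) for s in rng.integers(2**31, size=2))

    report = snp_qc.QCReport(seed=cfg.seed)
    filtered, st = snp_qc.filter_missingness_maf(g, cfg.max_missing, cfg.min_maf)
    report.add(st)
    deduped, st = snp_qc.dedup_fragments(filtered, seed=dedup_seed)
    report.add(st)
    pruned, st = snp_qc.ld_prune(deduped, cfg.r2_max, seed=prune_seed)
    report.add(st)

    populations = pruned.population_labels()

    def preliminary_unrelated(geno: GenotypeMatrix, pop: str) -> list[str]:
        pop_g = geno.subset_individuals(geno.individuals_of(pop))
        view = _sibship_view(pop_g, cfg)
        grm = build_g(view, estimate_frequencies(view), population=pop)
        asg = _threshold_sibship(grm, pop, cfg)
        amat = build_a(build_dummy_pedigree(asg))
        return select_unrelated(amat)

    hwe_subsets = {pop: preliminary_unrelated(pruned, pop) for pop in populations}
    qc_done, st = snp_qc.hwe_filter(pruned, hwe_subsets, alpha=cfg.hwe_alpha)
    report.add(st)
    report.details["hwe_subset_sizes"] = {
        pop: len(ids) for pop, ids in hwe_subsets.items()
    }

    results: dict[str, PopulationResult] = {}
    for pop in populations:
        pop_g = qc_done.subset_individuals(qc_done.individuals_of(pop))
        first_g = build_g(pop_g, estimate_frequencies(pop_g), population=pop)
        prelim_view = _sibship_view(pop_g, cfg)
        prelim_grm = build_g(
            prelim_view, estimate_frequencies(prelim_view), population=pop
        )
        prelim_asg = _threshold_sibship(prelim_grm, pop, cfg)
        prelim_a = build_a(build_dummy_pedigree(prelim_asg))
        current_a = prelim_a
        previous = prelim_asg.canonical()
        for _ in range(max(1, cfg.max_refine_passes)):
            second_g, unrelated = refine_g(
                qc_done, pop, current_a, min_unrelated=cfg.min_unrelated
            )
            final_asg = _threshold_sibship(second_g, pop, cfg)
            current_a = build_a(build_dummy_pedigree(final_asg))
            if final_asg.canonical() == previous:
                break
            previous = final_asg.canonical()
        pedigree = build_dummy_pedigree(final_asg)
        final_a = build_a(pedigree)
        if len(second_g.individual_ids) >= 2:
            ordering, _ = cluster_order(second_g)
        else:
            ordering = list(second_g.individual_ids)
        results[pop] = PopulationResult(
            population=pop,
            first_pass_g=first_g,
            preliminary_assignment=prelim_asg,
            preliminary_a=prelim_a,
            unrelated_ids=unrelated,
            second_pass_g=second_g,
            final_assignment=final_asg,
            pedigree=pedigree,
            final_a=final_a,
            ordering=ordering,
        )
        log.info(
            "population %s: %d individuals, %d full-sib groups, %d half-sib "
            "links, %d putatively unrelated",
            pop,
            pop_g.n_individuals,
            len(final_asg.full_sib_groups),
            len(final_asg.half_sib_links),
            len(unrelated),
        )
    return results, report
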