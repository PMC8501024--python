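"""Peak-to-gene association, random-set fold enrichment, and direct-target
calling.

Two mapping modes are provided: simple peak-center-to-TSS distance (the
default, used for the enrichment grid and target calling) and GREAT-style
basal-plus-extension regulatory domains.  The enrichment statistic compares
a gene cluster's peak-association rate with the mean rate over random gene
sets drawn from the expressed population, with a two-tailed Fisher exact
test on the pooled 2x2 table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .expression import GeneCluster, bh_adjust
from .io_formats import GeneModel, GenomicInterval, Peak
from .peaks import peak_center

__all__ = [
    "RegulatoryDomain",
    "AssociationCell",
    "TargetCall",
    "nearest_tss",
    "genes_with_peak_within",
    "great_domains",
    "peaks_in_domains",
    "sample_random_gene_sets",
    "fold_enrichment",
    "fisher_exact_two_tailed",
    "association_table",
    "call_direct_targets",
]


@dataclass(frozen=True)
class RegulatoryDomain:
    """A gene's basal-plus-extension regulatory domain."""

    gene_id: str
    interval: GenomicInterval
    basal: GenomicInterval


@dataclass
class AssociationCell:
    """One cluster x peak-group cell of the enrichment grid."""

    cluster_label: str
    peak_group: str
    n_cluster_genes: int
    n_associated: int
    random_set_proportions: list[float]
    fold_enrichment: float
    fisher_p: float
    fisher_fdr: float = float("nan")

    @property
    def f_obs(self) -> float:
        return self.n_associated / self.n_cluster_genes if self.n_cluster_genes else 0.0


@dataclass
class TargetCall:
    """A dysregulated gene's direct-target status and supporting peaks."""

    gene_id: str
    cluster_label: str
    peak_ids: list[str] = field(default_factory=list)
    distances: list[int] = field(default_factory=list)
    is_direct_target: bool = False


# ---------------------------------------------------------------------------
# distance-based mapping


def _tss_by_chrom(genes: list[GeneModel]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
    out = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        tss = np.array([p[0] for p in pairs], dtype=np.int64)
        ids = np.array([p[1] for p in pairs], dtype=object)
        out[chrom] = (tss, ids)
    return out


def nearest_tss(peak: Peak, genes: list[GeneModel]) -> tuple[str, int] | None:
    """Nearest gene TSS to the peak center (ties: smallest gene_id).

    Returns None when the peak's chromosome carries no gene.
    """
    index = _tss_by_chrom(genes)
    chrom = peak.interval.chrom
    if chrom not in index:
        return None
    tss, ids = index[chrom]
    center = peak_center(peak)
    dist = np.abs(tss - center)
    best = dist.min()
    candidates = sorted(ids[dist == best])
    return candidates[0], int(best)


def genes_with_peak_within(
    genes: list[GeneModel],
    peaks: list[Peak],
    d: int = 10_000,
    peak_filter=None,
) -> set[str]:
    """Genes with >= 1 (filtered) peak center within d bp of their TSS
    (inclusive)."""
    if d < 0:
        raise ValueError("d must be >= 0")
    selected = [p for p in peaks if peak_filter is None or peak_filter(p)]
    centers: dict[str, np.ndarray] = {}
    for p in selected:
        centers.setdefault(p.interval.chrom, [])
    for p in selected:
        centers[p.interval.chrom].append(peak_center(p))
    centers = {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in centers.items()}
    out = set()
    for g in genes:
        arr = centers.get(g.chrom)
        if arr is None or arr.size == 0:
            continue
        i = np.searchsorted(arr, g.tss)
        near = min(
            abs(int(arr[j]) - g.tss) for j in (i - 1, i) if 0 <= j < arr.size
        )
        if near <= d:
            out.add(g.gene_id)
    return out


# ---------------------------------------------------------------------------
# GREAT-style regulatory domains


def great_domains(
    genes: list[GeneModel],
    chrom_sizes: dict[str, int],
    basal_up: int = 2000,
    basal_down: int = 2000,
    max_ext: int = 200_000,
) -> list[RegulatoryDomain]:
    """Basal-plus-extension regulatory domains.

    The basal region is strand-oriented: ``basal_up`` bp upstream and
    ``basal_down`` bp downstream of the TSS.  Each side is extended
    outward by up to ``max_ext`` bp but stops at the nearest neighboring
    gene's basal boundary, never shrinking below the gene's own basal
    region, and is clipped to the chromosome.
    """
    for g in genes:
        if g.chrom not in chrom_sizes:
            raise ValueError(f"no chromosome size for {g.chrom}")

    basal: dict[str, tuple[int, int]] = {}
    for g in genes:
        if g.strand == "+":
            lo, hi = g.tss - basal_up, g.tss + basal_down
        else:
            lo, hi = g.tss + 1 - basal_down, g.tss + 1 + basal_up
        size = chrom_sizes[g.chrom]
        basal[g.gene_id] = (max(0, lo), min(size, hi))

    domains = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, members in by_chrom.items():
        size = chrom_sizes[chrom]
        for g in members:
            b_lo, b_hi = basal[g.gene_id]
            left_stop, right_stop = 0, size
            for other in members:
                if other.gene_id == g.gene_id:
                    continue
                o_lo, o_hi = basal[other.gene_id]
                if o_hi <= b_lo:
                    left_stop = max(left_stop, o_hi)
                if o_lo >= b_hi:
                    right_stop = min(right_stop, o_lo)
            lo = min(b_lo, max(b_lo - max_ext, left_stop))
            hi = max(b_hi, min(b_hi + max_ext, right_stop))
            domains.append(
                RegulatoryDomain(
                    gene_id=g.gene_id,
                    interval=GenomicInterval(chrom, lo, hi, g.strand),
                    basal=GenomicInterval(chrom, b_lo, b_hi, g.strand),
                )
            )
    return domains


def peaks_in_domains(
    peaks: list[Peak], domains: list[RegulatoryDomain]
) -> dict[str, list[str]]:
    """Map each peak to every regulatory domain containing its center."""
    out: dict[str, list[str]] = {}
    by_chrom: dict[str, list[RegulatoryDomain]] = {}
    for dom in domains:
        by_chrom.setdefault(dom.interval.chrom, []).append(dom)
    for p in peaks:
        center = peak_center(p)
        hits = [
            dom.gene_id
            for dom in by_chrom.get(p.interval.chrom, [])
            if dom.interval.start <= center < dom.interval.end
        ]
        out[p.peak_id] = sorted(hits)
    return out


# ---------------------------------------------------------------------------
# enrichment statistics


def sample_random_gene_sets(
    population: list[str],
    n_sets: int = 10,
    set_size: int = 200,
    seed: int | np.random.Generator = 0,
) -> list[list[str]]:
    """Draw n_sets independent gene sets without replacement within a set.

    Sets may overlap across draws; a fixed seed reproduces the sets.
    """
    if set_size > len(population):
        raise ValueError(
            f"set_size={set_size} exceeds population size {len(population)}"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    population = sorted(population)
    return [
        list(rng.choice(population, size=set_size, replace=False))
        for _ in range(n_sets)
    ]


def fold_enrichment(
    cluster_genes: set[str],
    random_sets: list[list[str]],
    associated_genes: set[str],
) -> tuple[float, dict]:
    """Observed association rate over the mean rate in random sets.

    ``associated_genes`` is the precomputed set of genes with a passing
    peak within the association distance (see genes_with_peak_within).
    Returns (FE, counts); FE is inf when f_rand is 0 but f_obs > 0.
    """
    if not cluster_genes:
        raise ValueError("cluster is empty")
    if not random_sets:
        raise ValueError("need >= 1 random set")
    n_assoc = len(cluster_genes & associated_genes)
    f_obs = n_assoc / len(cluster_genes)
    props = [
        sum(1 for g in s if g in associated_genes) / len(s) for s in random_sets
    ]
    f_rand = float(np.mean(props))
    if f_rand == 0:
        fe = 0.0 if f_obs == 0 else float("inf")
    else:
        fe = f_obs / f_rand
    counts = {
        "n_cluster": len(cluster_genes),
        "n_associated": n_assoc,
        "f_obs": f_obs,
        "f_rand": f_rand,
        "random_set_proportions": props,
        "random_associated": int(sum(round(p * len(s)) for p, s in zip(props, random_sets))),
        "random_total": int(sum(len(s) for s in random_sets)),
    }
    return fe, counts


def fisher_exact_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Enumerates the hypergeometric distribution over all tables with the
    observed margins and sums the probabilities of tables no more likely
    than the observed one (small-p method).
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("cells must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1, col1 = a + b, a + c
    k_min = max(0, row1 + col1 - n)
    k_max = min(row1, col1)
    support = np.arange(k_min, k_max + 1)
    probs = hypergeom.pmf(support, n, row1, col1)
    p_obs = probs[support == a][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-7)].sum()))


def fisher_randomized_p(a: int, b: int, c: int, d: int, u: float) -> float:
    """Randomized ("smoothed") two-tailed Fisher p-value.

    p = P(table strictly less likely than observed) + u * P(equally
    likely), with u ~ Uniform(0, 1) supplied by the caller.  Exactly
    uniform under the conditional null, so it is the right quantity for
    calibration diagnostics of the discrete exact test; the reported
    statistic everywhere else remains the exact (conservative)
    :func:`fisher_exact_two_tailed`.
    """
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        return float(u)
    row1, col1 = a + b, a + c
    k_min = max(0, row1 + col1 - n)
    k_max = min(row1, col1)
    support = np.arange(k_min, k_max + 1)
    probs = hypergeom.pmf(support, n, row1, col1)
    p_obs = probs[support == a][0]
    lower = probs[probs < p_obs * (1 - 1e-7)].sum()
    equal = probs[np.abs(probs - p_obs) <= p_obs * 1e-7].sum()
    return float(min(1.0, lower + u * equal))


def association_table(
    clusters: list[GeneCluster],
    peaks: list[Peak],
    genes: list[GeneModel],
    random_sets: list[list[str]],
    d: int = 10_000,
    peak_groups: tuple[str, ...] = ("I", "II", "III"),
) -> list[AssociationCell]:
    """One enrichment cell per (cluster, peak group).

    The Fisher 2x2 compares associated/not-associated counts in the
    cluster against the pooled random-set draws; BH FDR across the grid
    is reported alongside the raw p.
    """
    cells = []
    for group in peak_groups:
        assoc = genes_with_peak_within(
            genes, peaks, d=d, peak_filter=lambda p, g=group: p.group == g
        )
        for cluster in clusters:
            members = set(cluster.members)
            fe, counts = fold_enrichment(members, random_sets, assoc)
            a = counts["n_associated"]
            b = counts["n_cluster"] - a
            c = counts["random_associated"]
            dd = counts["random_total"] - c
            cells.append(
                AssociationCell(
                    cluster_label=cluster.label,
                    peak_group=group,
                    n_cluster_genes=counts["n_cluster"],
                    n_associated=a,
                    random_set_proportions=counts["random_set_proportions"],
                    fold_enrichment=fe,
                    fisher_p=fisher_exact_two_tailed(a, b, c, dd),
                )
            )
    fdr = bh_adjust([cell.fisher_p for cell in cells])
    for cell, q in zip(cells, fdr):
        cell.fisher_fdr = float(q)
    return cells


def call_direct_targets(
    clusters: list[GeneCluster],
    peaks: list[Peak],
    genes: list[GeneModel],
    d: int = 10_000,
    eligible_clusters: set[str] = frozenset({"A", "C"}),
    peak_filter=None,
) -> list[TargetCall]:
    """Direct target: gene in an eligible (p53-dependent) cluster with at
    least one peak center within d bp of its TSS.

    One TargetCall per clustered gene, with supporting peaks and
    distances recorded for those that qualify.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    selected = [p for p in peaks if peak_filter is None or peak_filter(p)]
    by_chrom: dict[str, list[Peak]] = {}
    for p in selected:
        by_chrom.setdefault(p.interval.chrom, []).append(p)

    calls = []
    for cluster in clusters:
        for gene_id in cluster.members:
            gene = gene_by_id.get(gene_id)
            call = TargetCall(gene_id=gene_id, cluster_label=cluster.label)
            if gene is not None:
                for p in by_chrom.get(gene.chrom, []):
                    dist = abs(peak_center(p) - gene.tss)
                    if dist <= d:
                        call.peak_ids.append(p.peak_id)
                        call.distances.append(int(dist))
            call.is_direct_target = (
                cluster.label in eligible_clusters and len(call.peak_ids) > 0
            )
            calls.append(call)
    return calls
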