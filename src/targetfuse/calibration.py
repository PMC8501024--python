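"""Null-calibration harnesses for the DE and association stages.

Two checks that the pipeline's statistics behave under the null:

* with no planted programs, the DE stage's false-positive calls at a given
  FDR stay within binomial tolerance of the nominal rate;
* with uniformly placed peaks and gene "clusters" sampled at random from
  the population, the association grid's Fisher p-values are approximately
  uniform.

The association fixture uses cluster and random-set sizes large enough
that the hypergeometric 2x2 cells sit in their near-continuous regime;
exact-test p-values on very small tables are intrinsically discrete and
conservative, which would confound a uniformity check.
"""

from __future__ import annotations

import numpy as np

from .association import (
    association_table,
    fisher_randomized_p,
    sample_random_gene_sets,
)
from .expression import (
    GeneCluster,
    call_dysregulated,
    common_dispersion_from_design,
    de_table,
)
from .io_formats import GeneModel, GenomicInterval, Peak
from .synthetic import ScenarioConfig, generate_scenario

__all__ = ["null_de_call_counts", "null_association_pvalues"]


def null_de_call_counts(
    n_scenarios: int,
    seed: int,
    n_genes: int = 300,
    fdr_thresh: float = 0.05,
    fc_thresh: float = 2.0,
) -> list[int]:
    """Dysregulated-gene calls per pure-null scenario (expected ~0).

    Each scenario is a full synthetic count experiment with all program
    counts at zero; the WT-IR vs WT contrast is tested at the given
    thresholds and the number of (false-positive) calls recorded.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_scenarios) % (2**31)
    counts_per_scenario = []
    for s in seeds:
        cfg = ScenarioConfig(
            n_genes=n_genes,
            chrom_length=max(10_000_000, n_genes * 30_000),
            n_a_genes=0,
            n_b_genes=0,
            n_c_genes=0,
            n_group1_peaks=10,
            n_group2_peaks=5,
            n_group3_peaks=5,
            seed=int(s),
        )
        sc = generate_scenario(cfg)
        cm = sc.counts
        dispersion = common_dispersion_from_design(cm.counts, cm.design)
        de = de_table(
            cm.counts,
            cm.samples("WT", "UT"),
            cm.samples("WT", "IR"),
            dispersion=dispersion,
        )
        called = call_dysregulated(de, fc_thresh=fc_thresh, fdr_thresh=fdr_thresh)
        counts_per_scenario.append(int(called["dysregulated"].sum()))
    return counts_per_scenario


def _uniform_layout(
    rng: np.random.Generator,
    n_genes: int,
    chrom_length: int,
    peak_group_counts: dict[str, int],
) -> tuple[list[GeneModel], list[Peak]]:
    tss = np.sort(rng.integers(1000, chrom_length - 1000, size=n_genes))
    genes = [
        GeneModel(f"g{i:05d}", f"G{i:05d}", GenomicInterval("chr1", int(t), int(t) + 100, "+"))
        for i, t in enumerate(tss, start=1)
    ]
    peaks = []
    for group, count in peak_group_counts.items():
        centers = rng.integers(1000, chrom_length - 1000, size=count)
        for c in centers:
            p = Peak(f"p{len(peaks) + 1:05d}", GenomicInterval("chr1", int(c) - 100, int(c) + 100))
            p.group = group
            peaks.append(p)
    return genes, peaks


def null_association_pvalues(
    n_grids: int,
    seed: int,
    n_genes: int = 8000,
    chrom_length: int = 50_000_000,
    peak_group_counts: dict[str, int] | None = None,
    cluster_sizes: tuple[int, ...] = (150, 100, 80),
    n_random_sets: int = 10,
    random_set_size: int = 200,
    d: int = 10_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Fisher p-values from association grids with no real structure.

    Peaks are placed uniformly and the "clusters" are disjoint random
    draws from the gene population, so every cell's fold enrichment is 1
    in expectation.  Returns ``(exact, randomized)`` p-value arrays: the
    exact two-tailed p-values (stochastically larger than uniform, as for
    any discrete exact test) and their randomized transform, which is
    uniform exactly when the test's conditional null model holds and is
    the quantity to feed a uniformity check.

    The population is kept an order of magnitude larger than the cluster
    and set sizes — as in the motivating study design, where sets of 200
    are drawn from >13k expressed genes — so that finite-population and
    set-overlap correlations stay negligible.
    """
    if peak_group_counts is None:
        peak_group_counts = {"I": 300, "II": 200, "III": 250}
    master = np.random.SeedSequence(seed)
    exact, randomized = [], []
    for child in master.spawn(n_grids):
        rng = np.random.default_rng(child)
        genes, peaks = _uniform_layout(rng, n_genes, chrom_length, peak_group_counts)
        gene_ids = [g.gene_id for g in genes]
        picked = rng.choice(gene_ids, size=sum(cluster_sizes), replace=False)
        clusters = []
        offset = 0
        for label, size in zip("ABC", cluster_sizes):
            clusters.append(GeneCluster(label, list(picked[offset : offset + size])))
            offset += size
        random_sets = sample_random_gene_sets(
            gene_ids, n_sets=n_random_sets, set_size=random_set_size, seed=rng
        )
        cells = association_table(clusters, peaks, genes, random_sets, d=d)
        total_random = n_random_sets * random_set_size
        for cell in cells:
            a = cell.n_associated
            b = cell.n_cluster_genes - a
            c = int(round(sum(cell.random_set_proportions) * random_set_size))
            exact.append(cell.fisher_p)
            randomized.append(
                fisher_randomized_p(a, b, c, total_random - c, rng.uniform())
            )
    return np.asarray(exact), np.asarray(randomized)
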