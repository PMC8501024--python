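"""Expression normalization, differential expression, and response clustering.

The differential-expression test is a deliberately simple negative-binomial
stand-in: a common dispersion estimated by the method of moments and an
exact conditional test on the per-group sums given their total, computed on
pseudo-equalized library sizes.  The biological thresholds (linear fold
change >= 2, BH FDR <= 0.05, both inclusive) — not the internals of any
particular DE package — define the pipeline downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import nbinom, rankdata
from statsmodels.stats.multitest import multipletests

from .io_formats import CountMatrix

__all__ = [
    "DEResult",
    "GeneCluster",
    "compute_cpm",
    "filter_expressed",
    "quantile_normalize",
    "tmm_factors",
    "nb_exact_test",
    "estimate_common_dispersion",
    "common_dispersion_from_design",
    "bh_adjust",
    "call_dysregulated",
    "relative_expression",
    "cluster_dysregulated",
    "label_clusters",
    "cluster_and_label",
    "classify_response_genes",
    "de_table",
]


@dataclass
class DEResult:
    """Per-gene differential expression result for one contrast."""

    gene_id: str
    fold_change: float  # linear, contrast / reference
    p_value: float
    fdr: float
    mean_cpm_ref: float
    mean_cpm_contrast: float

    @property
    def log2fc(self) -> float:
        return float(np.log2(self.fold_change))


@dataclass
class GeneCluster:
    """A response cluster of dysregulated genes (labels A / B / C)."""

    label: str
    members: list[str]
    centroid: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# normalization


def compute_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: cpm[g, s] = count[g, s] * 1e6 / library_size[s]."""
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"zero library size for samples {bad}")
    return counts * 1e6 / lib


def filter_expressed(cpm: pd.DataFrame, min_cpm: float = 5.0, min_samples: int = 3) -> pd.Index:
    """Genes with CPM >= min_cpm in at least min_samples samples (inclusive)."""
    if min_cpm <= 0 or min_samples <= 0:
        raise ValueError("thresholds must be positive")
    if min_samples > cpm.shape[1]:
        raise ValueError(
            f"min_samples={min_samples} exceeds number of samples ({cpm.shape[1]})"
        )
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    return cpm.index[keep]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the mean distribution of order statistics.

    Ties within a column receive the mean of their tied reference values,
    so the result is deterministic and permutation-equivariant.
    """
    values = matrix.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("missing values not allowed")
    n, m = values.shape
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(m):
        order = np.argsort(values[:, j], kind="stable")
        assigned = np.empty(n)
        assigned[order] = reference
        # every member of a tie group receives the mean of the reference
        # values over the ranks the group occupies
        _, inverse = np.unique(values[:, j], return_inverse=True)
        sums = np.bincount(inverse, weights=assigned)
        sizes = np.bincount(inverse)
        out[:, j] = (sums / sizes)[inverse]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def tmm_factors(
    counts: pd.DataFrame,
    reference_sample: str | None = None,
    log_ratio_trim: float = 0.3,
    abs_expr_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    For each sample vs the reference, genes with a zero count in either
    sample are excluded; the remaining genes are doubly trimmed (30% on
    the log-ratio M, 5% on the mean log-intensity A) and the factor is
    2**(precision-weighted mean of M).
    """
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    if reference_sample is None:
        # edgeR-style: sample whose upper quartile of count fractions is
        # closest to the mean upper quartile
        frac = counts / lib
        uq = frac.quantile(0.75, axis=0)
        reference_sample = (uq - uq.mean()).abs().idxmin()
    ref = counts[reference_sample].to_numpy(dtype=float)
    n_ref = lib[reference_sample]

    log_factors = {}
    for sample in counts.columns:
        obs = counts[sample].to_numpy(dtype=float)
        n_obs = lib[sample]
        if sample == reference_sample:
            log_factors[sample] = 0.0
            continue
        usable = (obs > 0) & (ref > 0)
        if usable.sum() < 10:
            warnings.warn(
                f"fewer than 10 usable genes for TMM between {sample} and "
                f"{reference_sample}; factor set to 1"
            )
            log_factors[sample] = 0.0
            continue
        o, r = obs[usable], ref[usable]
        m = np.log2((o / n_obs) / (r / n_ref))
        a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
        w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
        n = m.size
        lo_m, hi_m = np.floor(n * log_ratio_trim) + 1, n - np.floor(n * log_ratio_trim)
        lo_a, hi_a = np.floor(n * abs_expr_trim) + 1, n - np.floor(n * abs_expr_trim)
        rank_m = rankdata(m, method="average")
        rank_a = rankdata(a, method="average")
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not keep.any():
            log_factors[sample] = 0.0
            continue
        log_factors[sample] = float(np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))

    f = pd.Series(log_factors).reindex(counts.columns)
    f -= f.mean()  # geometric mean of 2**f is 1
    return np.exp2(f)


# ---------------------------------------------------------------------------
# differential expression


def estimate_common_dispersion(
    pseudo: np.ndarray,
    group_sizes: tuple[int, ...] | None = None,
    floor: float = 1e-4,
    method: str = "qcml",
) -> float:
    """Common NB dispersion on (pseudo-equalized) normalized counts.

    ``qcml`` (default) maximizes the conditional log-likelihood of the
    within-group counts given their group totals — the mean parameter is
    conditioned out entirely, so the estimator is nearly unbiased at
    small replicate numbers and matches the exact conditional test that
    consumes it.  ``moments`` averages the per-gene-per-group moment
    estimates phi = (var - mean) / mean^2 over genes with mean >= 1; it
    is simpler but biased low by a few percent at 3 replicates.
    """
    if group_sizes is None:
        group_sizes = (pseudo.shape[1],)
    blocks = []
    start = 0
    for size in group_sizes:
        if size >= 2:
            blocks.append(pseudo[:, start : start + size])
        start += size
    if not blocks:
        return floor

    if method == "moments":
        phis = []
        for block in blocks:
            mu = block.mean(axis=1)
            var = block.var(axis=1, ddof=1)
            ok = mu >= 1
            phis.append((var[ok] - mu[ok]) / mu[ok] ** 2)
        phi = np.concatenate(phis)
        if phi.size == 0:
            return floor
        return max(float(np.mean(phi)), floor)

    if method != "qcml":
        raise ValueError(f"unknown dispersion method {method!r}")

    from scipy.optimize import minimize_scalar
    from scipy.special import gammaln

    # keep informative genes only (conditional likelihood of an all-zero
    # group is flat in phi)
    blocks = [b[b.sum(axis=1) >= 1] for b in blocks]
    blocks = [b for b in blocks if b.shape[0] > 0]
    if not blocks:
        return floor

    def neg_cond_loglik(log_phi: float) -> float:
        r = 1.0 / np.exp(log_phi)
        total = 0.0
        for b in blocks:
            n = b.shape[1]
            z = b.sum(axis=1)
            total += float(
                np.sum(gammaln(b + r)) - b.size * gammaln(r)
                + np.sum(gammaln(n * r) - gammaln(z + n * r))
            )
        return -total

    res = minimize_scalar(
        neg_cond_loglik, bounds=(np.log(1e-6), np.log(10.0)), method="bounded"
    )
    return max(float(np.exp(res.x)), floor)


def common_dispersion_from_design(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    norm_factors: pd.Series | None = None,
    method: str = "qcml",
) -> float:
    """Common dispersion across all genotype x treatment groups.

    Using every replicate group in the design (rather than only the two
    groups of one contrast) stabilizes the estimate; within-group
    structure means planted condition effects never inflate it.
    """
    lib = counts.sum(axis=0).astype(float)
    if norm_factors is None:
        norm_factors = tmm_factors(counts)
    eff = lib * norm_factors.reindex(counts.columns)
    common_size = float(np.exp(np.log(eff).mean()))

    ordered_cols: list[str] = []
    group_sizes: list[int] = []
    for (_, _), block in design.loc[counts.columns].groupby(
        ["genotype", "treatment"], sort=True
    ):
        cols = [s for s in counts.columns if s in block.index]
        if len(cols) >= 2:
            ordered_cols.extend(cols)
            group_sizes.append(len(cols))
    if not group_sizes:
        raise ValueError("no replicate group with >= 2 samples")
    pseudo = counts[ordered_cols].to_numpy(dtype=float) * (
        common_size / eff[ordered_cols].to_numpy()
    )
    return estimate_common_dispersion(pseudo, tuple(group_sizes), method=method)


def _nb_conditional_p(a: int, t: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided exact conditional NB test of the group-A sum.

    The sum of n iid NB(mu, phi) is NB(n*mu, phi/n).  Conditional on the
    total t, p is the sum of probabilities of outcomes no more likely
    than the observed one (small-p method).
    """
    if t == 0:
        return 1.0
    mu0 = t / (n_a + n_b)
    r_a, r_b = n_a / phi, n_b / phi
    m_a, m_b = n_a * mu0, n_b * mu0
    k = np.arange(t + 1)
    lp = nbinom.logpmf(k, r_a, r_a / (r_a + m_a)) + nbinom.logpmf(
        t - k, r_b, r_b / (r_b + m_b)
    )
    lp -= np.max(lp)
    prob = np.exp(lp)
    prob /= prob.sum()
    return min(1.0, float(prob[prob <= prob[a] * (1 + 1e-7)].sum()))


def nb_exact_test(
    counts_group_a: pd.DataFrame,
    counts_group_b: pd.DataFrame,
    norm_factors: pd.Series | None = None,
    dispersion: float | None = None,
) -> pd.Series:
    """Per-gene two-sided exact NB p-values for group A vs group B.

    Counts are scaled to a common (pseudo-equalized) library size using
    TMM-adjusted effective library sizes, the common dispersion is
    estimated by moments unless given, and each gene's group sums are
    tested conditionally on their total.
    """
    if counts_group_a.shape[1] < 2 or counts_group_b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per group")
    counts = pd.concat([counts_group_a, counts_group_b], axis=1)
    lib = counts.sum(axis=0).astype(float)
    if norm_factors is None:
        norm_factors = pd.Series(1.0, index=counts.columns)
    eff = lib * norm_factors.reindex(counts.columns)
    common_size = float(np.exp(np.log(eff).mean()))
    pseudo = counts.to_numpy(dtype=float) * (common_size / eff.to_numpy())

    n_a = counts_group_a.shape[1]
    n_b = counts_group_b.shape[1]
    if dispersion is None:
        dispersion = estimate_common_dispersion(pseudo, group_sizes=(n_a, n_b))
    sum_a = np.round(pseudo[:, :n_a].sum(axis=1)).astype(np.int64)
    sum_b = np.round(pseudo[:, n_a:].sum(axis=1)).astype(np.int64)

    pvals = np.ones(counts.shape[0])
    cache: dict[tuple[int, int], float] = {}
    for i, (a, b) in enumerate(zip(sum_a, sum_b)):
        key = (int(a), int(b))
        if key not in cache:
            cache[key] = _nb_conditional_p(int(a), int(a + b), n_a, n_b, dispersion)
        pvals[i] = cache[key]
    return pd.Series(pvals, index=counts.index, name="p_value")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_table(
    counts: pd.DataFrame,
    samples_ref: list[str],
    samples_contrast: list[str],
    norm_factors: pd.Series | None = None,
    fc_pseudocount_cpm: float = 0.1,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Run the NB exact test for one contrast and assemble a DE table.

    The fold change is the ratio of TMM-normalized mean CPMs (with a
    small CPM pseudocount guarding zeros).
    """
    sub = counts[samples_ref + samples_contrast]
    if norm_factors is None:
        norm_factors = tmm_factors(sub)
    eff = sub.sum(axis=0) * norm_factors.reindex(sub.columns)
    cpm = sub * 1e6 / eff
    mean_ref = cpm[samples_ref].mean(axis=1)
    mean_con = cpm[samples_contrast].mean(axis=1)
    fc = (mean_con + fc_pseudocount_cpm) / (mean_ref + fc_pseudocount_cpm)
    p = nb_exact_test(
        sub[samples_ref], sub[samples_contrast], norm_factors, dispersion=dispersion
    )
    return pd.DataFrame(
        {
            "gene_id": sub.index,
            "fold_change": fc.values,
            "log2fc": np.log2(fc.values),
            "p_value": p.values,
            "fdr": bh_adjust(p.values),
            "mean_cpm_ref": mean_ref.values,
            "mean_cpm_contrast": mean_con.values,
        }
    ).set_index("gene_id", drop=False)


def call_dysregulated(
    de: pd.DataFrame, fc_thresh: float = 2.0, fdr_thresh: float = 0.05
) -> pd.DataFrame:
    """Flag genes with max(FC, 1/FC) >= fc_thresh and FDR <= fdr_thresh.

    Both thresholds are inclusive; direction is up for FC > 1, down for
    FC < 1.
    """
    if fc_thresh <= 1:
        raise ValueError("fc_thresh must be > 1")
    if not (0 < fdr_thresh <= 1):
        raise ValueError("fdr_thresh must be in (0, 1]")
    fc = de["fold_change"].to_numpy(dtype=float)
    mag = np.maximum(fc, 1.0 / fc)
    called = (mag >= fc_thresh) & (de["fdr"].to_numpy() <= fdr_thresh)
    direction = np.where(fc > 1, "up", np.where(fc < 1, "down", "none"))
    out = de.copy()
    out["dysregulated"] = called
    out["direction"] = np.where(called, direction, "none")
    return out


# ---------------------------------------------------------------------------
# clustering


def relative_expression(
    cpm: pd.DataFrame, design: pd.DataFrame, reference_genotype: str = "WT",
    quantile: bool = True,
) -> pd.DataFrame:
    """log2(CPM + 1), optionally quantile-normalized, centred on the mean
    of the untreated reference-genotype samples."""
    logcpm = np.log2(cpm + 1.0)
    if quantile:
        logcpm = quantile_normalize(logcpm)
    ref_samples = [
        s
        for s in cpm.columns
        if design.loc[s, "genotype"] == reference_genotype
        and design.loc[s, "treatment"] == "UT"
    ]
    if not ref_samples:
        raise ValueError("no untreated reference-genotype samples in design")
    return logcpm.sub(logcpm[ref_samples].mean(axis=1), axis=0)


def cluster_dysregulated(rel_expr: pd.DataFrame, k: int = 3) -> list[list[str]]:
    """Agglomerative clustering with 1 - Pearson r distance and complete
    linkage, cut into exactly k clusters.

    Constant-profile genes (correlation undefined) are excluded with a
    warning.  Returned clusters are sorted by size, largest first.
    """
    profiles = rel_expr.to_numpy(dtype=float)
    variable = profiles.std(axis=1) > 0
    if not variable.all():
        dropped = list(rel_expr.index[~variable])
        warnings.warn(f"excluding {len(dropped)} constant-profile genes from clustering")
    rel = rel_expr.loc[variable]
    if rel.shape[0] < k:
        raise ValueError(f"need at least k={k} genes with variable profiles")
    z = linkage(rel.to_numpy(dtype=float), method="complete", metric="correlation")
    assignment = fcluster(z, t=k, criterion="maxclust")
    clusters = [list(rel.index[assignment == c]) for c in np.unique(assignment)]
    clusters.sort(key=lambda m: (-len(m), m[0]))
    return clusters


_GROUP_ORDER = ("WT_UT", "WT_IR", "KO_UT", "KO_IR")


def condition_means(rel_expr: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Mean relative expression per genotype x treatment condition."""
    cols = {}
    for cond in _GROUP_ORDER:
        gt, tr = cond.split("_")
        samples = [
            s
            for s in rel_expr.columns
            if design.loc[s, "genotype"] == gt and design.loc[s, "treatment"] == tr
        ]
        if samples:
            cols[cond] = rel_expr[samples].mean(axis=1)
    return pd.DataFrame(cols)


def label_clusters(
    clusters: list[list[str]],
    group_means: pd.DataFrame,
    up_thresh: float = 0.5,
) -> list[GeneCluster]:
    """Assign response labels A / B / C from cluster centroids.

    A: centroid up in WT-IR (vs untreated WT) but not in KO-IR;
    B: up in both IR conditions; C: down in WT-IR.  ``up_thresh`` is the
    log2 margin that counts as "up".  With exactly three clusters the
    labels are made mutually exclusive by maximizing total cosine
    similarity to the three archetype directions; an ambiguous centroid
    falls back to the nearest archetype with a warning.
    """
    required = {"WT_IR", "KO_IR"}
    if not required <= set(group_means.columns):
        raise ValueError(f"group means must include {sorted(required)}")

    deltas = []
    for members in clusters:
        c = group_means.loc[members].mean(axis=0)
        base = c.get("WT_UT", 0.0)
        deltas.append((c["WT_IR"] - base, c["KO_IR"] - base))

    archetypes = {
        "A": np.array([1.0, 0.0]),
        "B": np.array([1.0, 1.0]) / np.sqrt(2),
        "C": np.array([-1.0, 0.0]),
    }

    def rule_label(d1: float, d2: float) -> str | None:
        if d1 <= -up_thresh:
            return "C"
        if d1 >= up_thresh and d2 >= up_thresh / 2:
            return "B"
        if d1 >= up_thresh:
            return "A"
        return None

    def cosine(d: np.ndarray, arch: np.ndarray) -> float:
        norm = np.linalg.norm(d)
        return float(d @ arch / norm) if norm > 0 else -1.0

    labels: list[str]
    if len(clusters) == 3:
        from scipy.optimize import linear_sum_assignment

        names = list(archetypes)
        score = np.array(
            [[cosine(np.asarray(d), archetypes[n]) for n in names] for d in deltas]
        )
        rows, cols = linear_sum_assignment(-score)
        labels = [""] * 3
        for r, c in zip(rows, cols):
            labels[r] = names[c]
        for (d1, d2), lab in zip(deltas, labels):
            if rule_label(d1, d2) not in (lab, None):
                warnings.warn(
                    f"cluster centroid (dWT-IR={d1:.2f}, dKO-IR={d2:.2f}) matched "
                    f"rule {rule_label(d1, d2)} but was assigned {lab} for exclusivity"
                )
    else:
        labels = []
        for d1, d2 in deltas:
            lab = rule_label(d1, d2)
            if lab is None:
                d = np.array([d1, d2])
                lab = max(archetypes, key=lambda n: cosine(d, archetypes[n]))
                warnings.warn(
                    f"ambiguous cluster centroid (dWT-IR={d1:.2f}, dKO-IR={d2:.2f}); "
                    f"labelled {lab} by nearest archetype"
                )
            labels.append(lab)

    out = []
    for members, lab in zip(clusters, labels):
        centroid = group_means.loc[members].mean(axis=0).to_dict()
        out.append(GeneCluster(label=lab, members=list(members), centroid=centroid))
    out.sort(key=lambda c: c.label)
    return out


def classify_response_genes(
    de_wt: pd.DataFrame,
    de_ko: pd.DataFrame | None,
    group_means: pd.DataFrame | None = None,
) -> list[GeneCluster]:
    """Contrast-defined response classes over the dysregulated genes.

    A gene called up in the knockout-IR contrast is p53-independent
    (class B) regardless of its WT call; a gene up only in WT-IR is
    class A (p53-dependent induction); a dysregulated gene that is not
    up in either contrast is class C (repression).  This mirrors the
    definition of the factor-dependent target set — dysregulated after
    irradiation in wild type but not in the knockout — at the gene
    level, which is robust where a tree cut over correlation distances
    is not: the A/B distinction lives in a single coordinate.
    """
    up_wt = set(de_wt.index[(de_wt["dysregulated"]) & (de_wt["direction"] == "up")])
    down_wt = set(de_wt.index[(de_wt["dysregulated"]) & (de_wt["direction"] == "down")])
    if de_ko is not None:
        up_ko = set(de_ko.index[(de_ko["dysregulated"]) & (de_ko["direction"] == "up")])
        down_ko = set(de_ko.index[(de_ko["dysregulated"]) & (de_ko["direction"] == "down")])
    else:
        up_ko, down_ko = set(), set()

    members: dict[str, list[str]] = {"A": [], "B": [], "C": []}
    for g in sorted(up_wt | down_wt | up_ko | down_ko):
        if g in up_ko:
            members["B"].append(g)
        elif g in up_wt:
            members["A"].append(g)
        else:
            members["C"].append(g)

    out = []
    for lab in "ABC":
        if not members[lab]:
            continue
        centroid = (
            group_means.loc[members[lab]].mean(axis=0).to_dict()
            if group_means is not None
            else {}
        )
        out.append(GeneCluster(label=lab, members=members[lab], centroid=centroid))
    return out


def cluster_and_label(
    profiles: pd.DataFrame,
    group_means: pd.DataFrame,
    k: int = 3,
    n_subclusters: int | None = None,
) -> list[GeneCluster]:
    """Cut the tree finer than k, label each subcluster, merge by label.

    Complete linkage tends to isolate a handful of outlier genes into
    their own cluster, which at a hard k-cut can force two real response
    programs into one cluster.  Cutting into ~2k subclusters and merging
    subclusters that share a response label is robust to this while
    still yielding at most k labeled clusters.
    """
    if n_subclusters is None:
        n_subclusters = 2 * k
    n_subclusters = min(n_subclusters, max(k, len(profiles) - 1))
    subclusters = cluster_dysregulated(profiles, k=n_subclusters)
    labelled = label_clusters(subclusters, group_means)
    merged: dict[str, list[str]] = {}
    for c in labelled:
        merged.setdefault(c.label, []).extend(c.members)
    out = []
    for lab in sorted(merged):
        members = sorted(merged[lab])
        out.append(
            GeneCluster(
                label=lab,
                members=members,
                centroid=group_means.loc[members].mean(axis=0).to_dict(),
            )
        )
    return out
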