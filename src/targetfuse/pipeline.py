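"""End-to-end orchestration: load inputs, run every stage, emit tables.

All outputs are plain TSV with a leading comment line recording the config
hash and seed; ``run_log.json`` records parameters, versions, and the
counts at every stage so a run can be audited without re-executing it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import association as assoc_mod
from . import expression as expr_mod
from . import peaks as peaks_mod
from . import triage as triage_mod
from .io_formats import (
    CountMatrix,
    parse_gene_models,
    parse_peaks,
    read_bedgraph,
    read_count_matrix,
)

__all__ = [
    "PipelineConfig",
    "StageError",
    "run_pipeline",
    "summarize_run",
    "derive_partition_totals",
]

OUTPUT_FILES = (
    "de_results.tsv",
    "clusters.tsv",
    "peak_groups.tsv",
    "association_stats.tsv",
    "direct_targets.tsv",
    "triage_report.tsv",
    "run_log.json",
)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    genes: str
    counts: str
    design: str
    peaks: str
    out_dir: str
    coverage_ut: str | None = None
    coverage_ir: str | None = None
    known_lists: list[str] = field(default_factory=list)
    literature_index: str | None = None
    druggable: str | None = None
    min_cpm: float = 5.0
    min_samples: int = 3
    fc_thresh: float = 2.0
    fdr_thresh: float = 0.05
    peak_fc_thresh: float = 1.5
    peak_pseudocount: float = 0.5
    proximity_thresh: int = 1000
    assoc_distance: int = 10_000
    n_random_sets: int = 10
    random_set_size: int = 200
    k_clusters: int = 3
    eligible_clusters: tuple[str, ...] = ("A", "C")
    mapping: str = "distance"  # or "great"
    basal_up: int = 2000
    basal_down: int = 2000
    max_ext: int = 200_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "min_cpm",
            "min_samples",
            "fc_thresh",
            "fdr_thresh",
            "peak_fc_thresh",
            "proximity_thresh",
            "assoc_distance",
            "k_clusters",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mapping not in ("distance", "great"):
            raise ValueError("mapping must be 'distance' or 'great'")

    @classmethod
    def from_yaml(cls, path: str | Path, out_dir: str | Path | None = None) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        inputs = raw.get("inputs", {})
        params = raw.get("params", {})
        base = path.parent

        def resolve(p):
            return str(base / p) if p is not None else None

        return cls(
            genes=resolve(inputs["genes"]),
            counts=resolve(inputs["counts"]),
            design=resolve(inputs["design"]),
            peaks=resolve(inputs["peaks"]),
            coverage_ut=resolve(inputs.get("coverage_ut")),
            coverage_ir=resolve(inputs.get("coverage_ir")),
            known_lists=[resolve(p) for p in inputs.get("known_lists", [])],
            literature_index=resolve(inputs.get("literature_index")),
            druggable=resolve(inputs.get("druggable")),
            out_dir=str(out_dir if out_dir is not None else base / "out"),
            seed=int(raw.get("seed", 0)),
            **{
                k: (tuple(v) if k == "eligible_clusters" else v)
                for k, v in params.items()
            },
        )

    def loggable(self) -> dict:
        """Config fields excluding the output location, so that the same
        inputs + parameters + seed give byte-identical outputs anywhere."""
        d = asdict(self)
        d.pop("out_dir")
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.loggable(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, header_comment: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and write the full output set to out_dir."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tag = f"targetfuse {__version__} config_hash={config.config_hash()} seed={config.seed}"
    log: dict = {
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": config.loggable(),
        "counts": {},
    }

    def stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, exc) from exc
                return False

        return _Ctx()

    # --- load -------------------------------------------------------------
    with stage("load"):
        for label, p in (
            ("genes", config.genes),
            ("counts", config.counts),
            ("design", config.design),
            ("peaks", config.peaks),
        ):
            if not Path(p).exists():
                raise FileNotFoundError(f"{label} file not found: {p}")
        genes = parse_gene_models(config.genes)
        counts = read_count_matrix(config.counts, config.design)
        peaks_raw = parse_peaks(config.peaks)
        track_ut = read_bedgraph(config.coverage_ut) if config.coverage_ut else None
        track_ir = read_bedgraph(config.coverage_ir) if config.coverage_ir else None
    log["counts"]["genes"] = len(genes)
    log["counts"]["samples"] = counts.counts.shape[1]
    log["counts"]["genes_in_count_matrix"] = counts.counts.shape[0]
    log["counts"]["peaks"] = len(peaks_raw)

    # --- expression -------------------------------------------------------
    with stage("expression"):
        cpm = expr_mod.compute_cpm(counts.counts)
        expressed = expr_mod.filter_expressed(cpm, config.min_cpm, config.min_samples)
        filtered = counts.counts.loc[expressed]
        norm_factors = expr_mod.tmm_factors(filtered)
        # one common dispersion from every replicate group in the design
        dispersion = expr_mod.common_dispersion_from_design(
            filtered, counts.design, norm_factors
        )

        contrasts = {}
        wt = counts.samples("WT", "UT")
        for name, contrast_samples in (
            ("WT_IR_vs_WT", counts.samples("WT", "IR")),
            ("KO_IR_vs_WT", counts.samples("KO", "IR")),
        ):
            if len(wt) >= 2 and len(contrast_samples) >= 2:
                de = expr_mod.de_table(
                    filtered, wt, contrast_samples, dispersion=dispersion
                )
                contrasts[name] = expr_mod.call_dysregulated(
                    de, config.fc_thresh, config.fdr_thresh
                )
        if not contrasts:
            raise ValueError("no contrast has >= 2 replicates per group")
        de_all = pd.concat(
            [df.assign(contrast=name) for name, df in contrasts.items()]
        ).reset_index(drop=True)
        dysregulated = sorted(
            set().union(*(df.index[df["dysregulated"]] for df in contrasts.values()))
        )
    log["counts"]["expressed_genes"] = int(len(expressed))
    primary = contrasts.get("WT_IR_vs_WT", next(iter(contrasts.values())))
    log["counts"]["dysregulated_total"] = len(dysregulated)
    log["counts"]["dysregulated_up"] = int(
        ((primary["direction"] == "up") & primary["dysregulated"]).sum()
    )
    log["counts"]["dysregulated_down"] = int(
        ((primary["direction"] == "down") & primary["dysregulated"]).sum()
    )

    # --- response classes -------------------------------------------------
    with stage("clustering"):
        rel = expr_mod.relative_expression(cpm.loc[expressed], counts.design)
        rel_dys = rel.loc[[g for g in dysregulated if g in rel.index]]
        group_means = expr_mod.condition_means(rel_dys, counts.design)
        # per-gene contrast-defined classes; a tree cut over correlation
        # distances cannot reliably separate classes that differ in a
        # single (knockout-IR) coordinate
        de_wt = contrasts.get("WT_IR_vs_WT")
        if de_wt is None:
            de_wt = next(iter(contrasts.values()))
        clusters = expr_mod.classify_response_genes(
            de_wt, contrasts.get("KO_IR_vs_WT"), group_means
        )
    log["counts"]["cluster_sizes"] = {c.label: len(c.members) for c in clusters}

    # --- peaks ------------------------------------------------------------
    with stage("peaks"):
        peaks = peaks_mod.quantify_peaks(
            peaks_raw,
            track_ut,
            track_ir,
            pseudocount=config.peak_pseudocount,
            group_thresh=config.peak_fc_thresh,
        )
        nearest = [assoc_mod.nearest_tss(p, genes) for p in peaks]
        proximity = [
            peaks_mod.classify_proximity(hit[1], config.proximity_thresh)
            if hit is not None
            else "unknown"
            for hit in nearest
        ]
    group_counts = {
        g: sum(1 for p in peaks if p.group == g) for g in ("I", "II", "III")
    }
    log["counts"]["peak_groups"] = group_counts
    log["counts"]["proximal_peaks"] = proximity.count("proximal")
    log["counts"]["distal_peaks"] = proximity.count("distal")

    # --- association ------------------------------------------------------
    with stage("association"):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
        random_sets = assoc_mod.sample_random_gene_sets(
            list(expressed),
            n_sets=config.n_random_sets,
            set_size=min(config.random_set_size, len(expressed)),
            seed=rng,
        )
        cells = assoc_mod.association_table(
            clusters, peaks, genes, random_sets, d=config.assoc_distance
        )
        if config.mapping == "great":
            chrom_sizes = _infer_chrom_sizes(genes, peaks)
            domains = assoc_mod.great_domains(
                genes, chrom_sizes, config.basal_up, config.basal_down, config.max_ext
            )
            domain_map = assoc_mod.peaks_in_domains(peaks, domains)
        else:
            domain_map = None
        calls = assoc_mod.call_direct_targets(
            clusters,
            peaks,
            genes,
            d=config.assoc_distance,
            eligible_clusters=set(config.eligible_clusters),
        )
        direct = [c for c in calls if c.is_direct_target]
    log["counts"]["direct_targets"] = len(direct)

    # --- triage -----------------------------------------------------------
    with stage("triage"):
        known = triage_mod.load_gene_lists(config.known_lists) if config.known_lists else {}
        index = (
            triage_mod.load_literature_index(config.literature_index)
            if config.literature_index
            else {}
        )
        druggable = (
            triage_mod.load_druggable_set(config.druggable) if config.druggable else set()
        )
        records = triage_mod.triage_targets(direct, known, index, druggable)
    log["counts"]["novel_targets"] = sum(1 for r in records if r.novel)
    log["counts"]["novel_druggable_targets"] = sum(
        1 for r in records if r.novel and r.druggable
    )

    # --- write outputs ----------------------------------------------------
    with stage("write"):
        _write_tsv(
            de_all[
                [
                    "contrast",
                    "gene_id",
                    "fold_change",
                    "log2fc",
                    "p_value",
                    "fdr",
                    "dysregulated",
                    "direction",
                ]
            ],
            out_dir / "de_results.tsv",
            tag,
        )
        _write_tsv(
            pd.DataFrame(
                [
                    {"gene_id": g, "cluster_label": c.label}
                    for c in clusters
                    for g in c.members
                ]
            ),
            out_dir / "clusters.tsv",
            tag,
        )
        _write_tsv(
            pd.DataFrame(
                {
                    "peak_id": [p.peak_id for p in peaks],
                    "chrom": [p.interval.chrom for p in peaks],
                    "center": [peaks_mod.peak_center(p) for p in peaks],
                    "signal_ut": [p.signal_ut for p in peaks],
                    "signal_ir": [p.signal_ir for p in peaks],
                    "fc": [p.fc for p in peaks],
                    "group": [p.group for p in peaks],
                    "nearest_gene": [h[0] if h else "" for h in nearest],
                    "distance": [h[1] if h else -1 for h in nearest],
                    "proximity": proximity,
                }
            ),
            out_dir / "peak_groups.tsv",
            tag,
        )
        _write_tsv(
            pd.DataFrame(
                {
                    "cluster": [c.cluster_label for c in cells],
                    "peak_group": [c.peak_group for c in cells],
                    "n_cluster_genes": [c.n_cluster_genes for c in cells],
                    "n_associated": [c.n_associated for c in cells],
                    "f_obs": [c.f_obs for c in cells],
                    "f_rand": [float(np.mean(c.random_set_proportions)) for c in cells],
                    "random_set_proportions": [
                        ",".join(f"{p:.4f}" for p in c.random_set_proportions)
                        for c in cells
                    ],
                    "fold_enrichment": [c.fold_enrichment for c in cells],
                    "fisher_p": [c.fisher_p for c in cells],
                    "fisher_fdr": [c.fisher_fdr for c in cells],
                }
            ),
            out_dir / "association_stats.tsv",
            tag + " | fisher 2x2 pools all random sets",
        )
        rows = []
        peak_group = {p.peak_id: p.group for p in peaks}
        for c in direct:
            for pid, dist in zip(c.peak_ids, c.distances):
                rows.append(
                    {
                        "gene_id": c.gene_id,
                        "cluster_label": c.cluster_label,
                        "peak_id": pid,
                        "distance": dist,
                        "peak_group": peak_group[pid],
                    }
                )
        _write_tsv(
            pd.DataFrame(rows, columns=["gene_id", "cluster_label", "peak_id", "distance", "peak_group"]),
            out_dir / "direct_targets.tsv",
            tag,
        )
        _write_tsv(
            pd.DataFrame(
                {
                    "gene_id": [r.gene_id for r in records],
                    "known_lists": [";".join(r.known_lists_hit) for r in records],
                    "literature_hits": [r.literature_hits for r in records],
                    "druggable": [r.druggable for r in records],
                    "novel": [r.novel for r in records],
                }
            ),
            out_dir / "triage_report.tsv",
            tag,
        )
        if domain_map is not None:
            _write_tsv(
                pd.DataFrame(
                    {
                        "peak_id": list(domain_map),
                        "domain_genes": [";".join(v) for v in domain_map.values()],
                    }
                ),
                out_dir / "peak_domains.tsv",
                tag,
            )
        (out_dir / "run_log.json").write_text(json.dumps(log, indent=1, default=str))
    return out_dir


def _infer_chrom_sizes(genes, peaks) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for g in genes:
        sizes[g.chrom] = max(sizes.get(g.chrom, 0), g.interval.end + 300_000)
    for p in peaks:
        sizes[p.interval.chrom] = max(sizes.get(p.interval.chrom, 0), p.interval.end + 300_000)
    return sizes


def derive_partition_totals(
    n_up: int,
    n_down: int,
    cluster_up_sizes: dict[str, int],
    peak_group_sizes: dict[str, int],
    n_proximal: int,
) -> dict[str, float]:
    """Summarize-style arithmetic over partition counts.

    Returns the derived totals and percentages implied by a set of
    partition counts: total dysregulated, total upregulated from the
    up-cluster sizes, total peaks, distal count, and the proximal
    percentage.
    """
    total_peaks = sum(peak_group_sizes.values())
    return {
        "dysregulated_total": n_up + n_down,
        "upregulated_total": sum(cluster_up_sizes.values()),
        "peaks_total": total_peaks,
        "distal_peaks": total_peaks - n_proximal,
        "proximal_pct": 100.0 * n_proximal / total_peaks if total_peaks else float("nan"),
    }


def summarize_run(output_dir: str | Path) -> pd.DataFrame:
    """One-page counts for a completed run directory."""
    output_dir = Path(output_dir)
    missing = [f for f in OUTPUT_FILES if not (output_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run directory, missing {missing}")
    log = json.loads((output_dir / "run_log.json").read_text())
    counts = log["counts"]
    n_prox, n_dist = counts["proximal_peaks"], counts["distal_peaks"]
    located = n_prox + n_dist
    rows = [
        ("expressed_genes", counts["expressed_genes"]),
        ("dysregulated_total", counts["dysregulated_total"]),
        ("dysregulated_up", counts["dysregulated_up"]),
        ("dysregulated_down", counts["dysregulated_down"]),
    ]
    for label, size in sorted(counts["cluster_sizes"].items()):
        rows.append((f"cluster_{label}_genes", size))
    for grp, size in counts["peak_groups"].items():
        rows.append((f"group_{grp}_peaks", size))
    rows += [
        ("proximal_peaks", n_prox),
        ("distal_peaks", n_dist),
        ("proximal_pct", round(100.0 * n_prox / located, 2) if located else float("nan")),
        ("distal_pct", round(100.0 * n_dist / located, 2) if located else float("nan")),
        ("direct_targets", counts["direct_targets"]),
        ("novel_targets", counts["novel_targets"]),
        ("novel_druggable_targets", counts["novel_druggable_targets"]),
    ]
    return pd.DataFrame(rows, columns=["metric", "value"])
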