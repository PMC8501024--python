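"""Synthetic scenario generator with planted structure and a truth manifest.

Emulates the study design the pipeline targets: a 2-genotype (WT / KO) x
2-treatment (UT / IR) negative-binomial count experiment with three planted
response programs — A-like genes induced only in WT-IR, B-like genes induced
in both IR conditions, C-like genes repressed in WT-IR — plus null genes;
and a peak compartment with Group-I peaks planted near a configurable
fraction of A-like TSSs, background peaks placed uniformly, and per-peak
UT/IR signals drawn consistent with group labels under multiplicative
log-normal noise.

Every randomized choice flows from the single ``seed`` in the config, so a
fixed seed reproduces the scenario byte for byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    CountMatrix,
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    Peak,
    write_bedgraph,
    write_gene_models_tsv,
    write_peaks_bed,
)

__all__ = ["ScenarioConfig", "Scenario", "generate_scenario", "write_fixture"]


@dataclass
class ScenarioConfig:
    """Study conditions for a synthetic scenario.

    Defaults are desk-scale: one 50-Mb chromosome, 2,000 genes with
    150/50/80 planted A/B/C program genes (log2 effects ~ N(+-2, 0.5)),
    NB dispersion 0.1, 3 replicates per condition, 600/50/100 planted
    Group I/II/III peaks, and 70% of A-like genes receiving a Group-I
    peak within the 10-kb association distance.
    """

    n_chromosomes: int = 1
    chrom_length: int = 50_000_000
    n_genes: int = 2000
    n_a_genes: int = 150
    n_b_genes: int = 50
    n_c_genes: int = 80
    log2fc_a: tuple[float, float] = (2.0, 0.5)  # (mean, sd)
    log2fc_b: tuple[float, float] = (2.0, 0.5)
    log2fc_c: tuple[float, float] = (-2.0, 0.5)
    dispersion: float = 0.1
    # baseline mean counts: log-normal; program genes are drawn from the
    # moderately-to-highly expressed range (detected responders are
    # expressed genes), null genes from a broader distribution
    baseline_log_mean: float = math.log(50.0)
    baseline_log_sd: float = 1.3
    program_log_mean: float = math.log(100.0)
    program_log_sd: float = 0.7
    program_min_mean: float = 10.0
    replicates: int = 3
    depth_range: tuple[float, float] = (0.7, 1.3)
    n_group1_peaks: int = 600
    n_group2_peaks: int = 50
    n_group3_peaks: int = 100
    frac_a_with_peak: float = 0.7
    assoc_distance: int = 10_000
    peak_width_range: tuple[int, int] = (200, 600)
    binding_base_range: tuple[float, float] = (10.0, 60.0)
    group1_log2fc_range: tuple[float, float] = (1.0, 2.585)
    group2_log2fc_range: tuple[float, float] = (-0.2, 0.2)
    signal_noise_sd: float = 0.15
    basal_up: int = 2000
    basal_down: int = 2000
    call_fc_thresh: float = 2.0  # dysregulation definition used by the truth manifest
    seed: int = 0

    def __post_init__(self) -> None:
        n_program = self.n_a_genes + self.n_b_genes + self.n_c_genes
        if n_program > self.n_genes:
            raise ValueError("program gene counts exceed n_genes")
        for name in ("n_genes", "replicates", "chrom_length", "n_chromosomes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


CONDITIONS = ("WT_UT", "WT_IR", "KO_UT", "KO_IR")


@dataclass
class Scenario:
    config: ScenarioConfig
    genes: list[GeneModel]
    counts: CountMatrix
    peaks: list[Peak]
    track_ut: CoverageTrack
    track_ir: CoverageTrack
    truth: dict = field(default_factory=dict)


def _place_genes(cfg: ScenarioConfig, rng: np.random.Generator) -> list[GeneModel]:
    """Place stranded gene intervals so that no two basal domains overlap."""
    max_len = 20_000
    min_len = 2_000
    slot = max_len + cfg.basal_up + cfg.basal_down + 100
    per_chrom = [cfg.n_genes // cfg.n_chromosomes] * cfg.n_chromosomes
    for i in range(cfg.n_genes % cfg.n_chromosomes):
        per_chrom[i] += 1
    genes = []
    idx = 0
    for c, n in enumerate(per_chrom, start=1):
        margin = cfg.chrom_length - n * slot - cfg.basal_up - cfg.basal_down
        if margin <= 0:
            raise ValueError(
                f"cannot place {n} genes on a {cfg.chrom_length}-bp chromosome"
            )
        offsets = np.sort(rng.uniform(0, margin, size=n))
        lengths = rng.integers(min_len, max_len + 1, size=n)
        strands = rng.choice(["+", "-"], size=n)
        for j in range(n):
            start = int(offsets[j] + j * slot) + cfg.basal_up
            idx += 1
            gene_id = f"g{idx:05d}"
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    symbol=gene_id.upper(),
                    interval=GenomicInterval(
                        f"chr{c}", start, start + int(lengths[j]), str(strands[j])
                    ),
                )
            )
    return genes


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    if phi <= 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mean))


def _bumps_to_runs(bumps: list[tuple[int, int, float]]):
    """Sum rectangular bumps into sorted non-overlapping coverage runs."""
    events: dict[int, float] = {}
    for start, end, height in bumps:
        events[start] = events.get(start, 0.0) + height
        events[end] = events.get(end, 0.0) - height
    xs = sorted(events)
    starts, ends, values = [], [], []
    level = 0.0
    for i, x in enumerate(xs[:-1]):
        level += events[x]
        if level > 1e-12:
            starts.append(x)
            ends.append(xs[i + 1])
            values.append(level)
    return np.array(starts, dtype=np.int64), np.array(ends, dtype=np.int64), np.array(values)


def generate_scenario(config: ScenarioConfig | None = None) -> Scenario:
    """Generate coupled genes, counts, peaks, coverage, and truth manifest."""
    cfg = config or ScenarioConfig()
    rng = np.random.default_rng(cfg.seed)

    genes = _place_genes(cfg, rng)
    gene_ids = [g.gene_id for g in genes]
    n = cfg.n_genes

    # --- programs and expression truth -----------------------------------
    program = np.array(["null"] * n, dtype=object)
    order = rng.permutation(n)
    a_idx = order[: cfg.n_a_genes]
    b_idx = order[cfg.n_a_genes : cfg.n_a_genes + cfg.n_b_genes]
    c_idx = order[
        cfg.n_a_genes + cfg.n_b_genes : cfg.n_a_genes + cfg.n_b_genes + cfg.n_c_genes
    ]
    program[a_idx], program[b_idx], program[c_idx] = "A", "B", "C"

    baseline = np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=n))
    is_program = program != "null"
    baseline[is_program] = np.maximum(
        np.exp(rng.normal(cfg.program_log_mean, cfg.program_log_sd, size=is_program.sum())),
        cfg.program_min_mean,
    )

    lfc_wt_ir = np.zeros(n)
    lfc_ko_ir = np.zeros(n)
    lfc_wt_ir[a_idx] = rng.normal(*cfg.log2fc_a, size=a_idx.size)
    delta_b = rng.normal(*cfg.log2fc_b, size=b_idx.size)
    lfc_wt_ir[b_idx] = delta_b
    lfc_ko_ir[b_idx] = delta_b
    lfc_wt_ir[c_idx] = rng.normal(*cfg.log2fc_c, size=c_idx.size)

    # --- counts -----------------------------------------------------------
    samples = [
        f"{cond}_{r + 1}" for cond in CONDITIONS for r in range(cfg.replicates)
    ]
    depth = rng.uniform(*cfg.depth_range, size=len(samples))
    mult = {
        "WT_UT": np.ones(n),
        "WT_IR": np.exp2(lfc_wt_ir),
        "KO_UT": np.ones(n),
        "KO_IR": np.exp2(lfc_ko_ir),
    }
    count_cols = {}
    for s, d in zip(samples, depth):
        cond = s.rsplit("_", 1)[0]
        count_cols[s] = _nb_draw(rng, baseline * mult[cond] * d, cfg.dispersion)
    counts_df = pd.DataFrame(count_cols, index=pd.Index(gene_ids, name="gene_id"))
    design = pd.DataFrame(
        {
            "sample": samples,
            "genotype": [s.split("_")[0] for s in samples],
            "treatment": [s.split("_")[1] for s in samples],
            "replicate": [int(s.rsplit("_", 1)[1]) for s in samples],
        }
    ).set_index("sample")
    counts = CountMatrix(counts=counts_df, design=design)

    # --- peaks ------------------------------------------------------------
    chrom_names = [f"chr{c + 1}" for c in range(cfg.n_chromosomes)]
    peaks: list[Peak] = []
    peak_truth: dict[str, dict] = {}

    def add_peak(chrom: str, center: int, group: str, true_l2fc: float, linked: str | None):
        width = int(rng.integers(*cfg.peak_width_range))
        start = max(0, center - width // 2)
        end = min(cfg.chrom_length, start + width)
        base = rng.uniform(*cfg.binding_base_range)
        true_fc = 2.0**true_l2fc
        sig_ut = base * math.exp(rng.normal(0, cfg.signal_noise_sd))
        sig_ir = base * true_fc * math.exp(rng.normal(0, cfg.signal_noise_sd))
        pid = f"p{len(peaks) + 1:05d}"
        peaks.append(
            Peak(pid, GenomicInterval(chrom, start, end), round(sig_ut, 4), round(sig_ir, 4))
        )
        peak_truth[pid] = {
            "group": group,
            "true_log2fc": round(float(true_l2fc), 4),
            "linked_gene": linked,
        }

    # planted Group-I peaks near a fraction of A-like TSSs
    n_planted = int(round(cfg.frac_a_with_peak * a_idx.size))
    planted_genes = [genes[i] for i in rng.permutation(a_idx)[:n_planted]]
    margin = 500  # keep planted centers strictly inside the association radius
    for g in planted_genes:
        offset = int(rng.integers(-(cfg.assoc_distance - margin), cfg.assoc_distance - margin + 1))
        center = int(np.clip(g.tss + offset, 1000, cfg.chrom_length - 1000))
        add_peak(g.chrom, center, "I", rng.uniform(*cfg.group1_log2fc_range), g.gene_id)

    # background peaks, uniform across the genome
    lo1, hi1 = cfg.group1_log2fc_range
    lo2, hi2 = cfg.group2_log2fc_range
    background = [
        ("I", cfg.n_group1_peaks - n_planted, lambda: rng.uniform(lo1, hi1)),
        ("II", cfg.n_group2_peaks, lambda: rng.uniform(lo2, hi2)),
        ("III", cfg.n_group3_peaks, lambda: -rng.uniform(lo1, hi1)),
    ]
    for group, count, draw in background:
        if count < 0:
            raise ValueError("frac_a_with_peak plants more Group-I peaks than configured")
        for _ in range(count):
            chrom = chrom_names[int(rng.integers(cfg.n_chromosomes))]
            center = int(rng.integers(1000, cfg.chrom_length - 1000))
            add_peak(chrom, center, group, draw(), None)

    # --- coverage tracks --------------------------------------------------
    runs_ut, runs_ir = {}, {}
    for chrom in chrom_names:
        bumps_ut, bumps_ir = [], []
        for p in peaks:
            if p.interval.chrom != chrom:
                continue
            bumps_ut.append((p.interval.start, p.interval.end, p.signal_ut))
            bumps_ir.append((p.interval.start, p.interval.end, p.signal_ir))
        if bumps_ut:
            runs_ut[chrom] = _bumps_to_runs(bumps_ut)
            runs_ir[chrom] = _bumps_to_runs(bumps_ir)
    track_ut, track_ir = CoverageTrack(runs_ut), CoverageTrack(runs_ir)

    # --- truth manifest ---------------------------------------------------
    centers_by_chrom: dict[str, list[int]] = {}
    for p in peaks:
        c = (p.interval.start + p.interval.end - 1) // 2
        centers_by_chrom.setdefault(p.interval.chrom, []).append(c)
    centers_sorted = {c: np.sort(np.array(v)) for c, v in centers_by_chrom.items()}

    def has_peak_within(g: GeneModel, d: int) -> bool:
        arr = centers_sorted.get(g.chrom)
        if arr is None or arr.size == 0:
            return False
        i = int(np.searchsorted(arr, g.tss))
        return any(
            abs(int(arr[j]) - g.tss) <= d for j in (i - 1, i) if 0 <= j < arr.size
        )

    # a true direct target is p53-dependently dysregulated *at the study's
    # fold-change definition* (programs A/C, drawn effect >= the threshold)
    # and carries a peak within the association distance
    lfc_mag = np.maximum(np.exp2(lfc_wt_ir), np.exp2(-lfc_wt_ir))
    direct_targets = sorted(
        genes[i].gene_id
        for i in range(n)
        if program[i] in ("A", "C")
        and lfc_mag[i] >= cfg.call_fc_thresh
        and has_peak_within(genes[i], cfg.assoc_distance)
    )

    # toy triage resources: some program genes are already-known targets,
    # literature-covered, or druggable
    prog_genes = sorted(gene_ids[i] for i in np.concatenate([a_idx, c_idx]))
    n_known = len(prog_genes) // 3
    known = sorted(rng.choice(prog_genes, size=n_known, replace=False)) if n_known else []
    druggable = sorted(
        rng.choice(sorted(gene_ids), size=max(1, n // 5), replace=False)
    )

    truth = {
        "config": asdict(cfg),
        "genes": {
            gene_ids[i]: {
                "program": str(program[i]),
                "log2fc_wt_ir": round(float(lfc_wt_ir[i]), 4),
                "log2fc_ko_ir": round(float(lfc_ko_ir[i]), 4),
                "baseline_mean": round(float(baseline[i]), 4),
            }
            for i in range(n)
        },
        "peaks": peak_truth,
        "direct_targets": direct_targets,
        "known_genes": [str(g) for g in known],
        "druggable_genes": [str(g) for g in druggable],
    }
    return Scenario(cfg, genes, counts, peaks, track_ut, track_ir, truth)


def write_fixture(scenario: Scenario, directory: str | Path) -> Path:
    """Write the scenario as the plain-text file set the pipeline reads.

    Emits genes.tsv, counts.tsv, design.tsv, peaks.bed, coverage bedGraphs,
    truth.json, toy triage resources, and a ready-to-run config.yaml.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    write_gene_models_tsv(scenario.genes, directory / "genes.tsv")
    scenario.counts.counts.to_csv(directory / "counts.tsv", sep="\t")
    scenario.counts.design.to_csv(directory / "design.tsv", sep="\t")
    write_peaks_bed(scenario.peaks, directory / "peaks.bed")
    write_bedgraph(scenario.track_ut, directory / "coverage_ut.bedGraph")
    write_bedgraph(scenario.track_ir, directory / "coverage_ir.bedGraph")
    (directory / "truth.json").write_text(json.dumps(scenario.truth, indent=1, sort_keys=True))

    known = scenario.truth["known_genes"]
    (directory / "known_targets.txt").write_text(
        "".join(f"{scenario_symbol(scenario, g)}\n" for g in known)
    )
    with open(directory / "druggable.tsv", "w") as fh:
        fh.write("gene\n")
        for g in scenario.truth["druggable_genes"]:
            fh.write(f"{scenario_symbol(scenario, g)}\n")
    with open(directory / "literature.tsv", "w") as fh:
        fh.write("id\ttitle\tabstract\n")
        for i, g in enumerate(known, start=1):
            sym = scenario_symbol(scenario, g)
            fh.write(
                f"rec{i:04d}\t{sym} is a p53 target\t"
                f"Induction of {sym} by p53 under genotoxic stress.\n"
            )
        fh.write("rec9999\tUnrelated record\tNo factor terms mentioned here.\n")

    config = {
        "inputs": {
            "genes": "genes.tsv",
            "counts": "counts.tsv",
            "design": "design.tsv",
            "peaks": "peaks.bed",
            "known_lists": ["known_targets.txt"],
            "literature_index": "literature.tsv",
            "druggable": "druggable.tsv",
        },
        "params": {
            "min_cpm": 5.0,
            "min_samples": 3,
            "fc_thresh": 2.0,
            "fdr_thresh": 0.05,
            "peak_fc_thresh": 1.5,
            "proximity_thresh": 1000,
            "assoc_distance": scenario.config.assoc_distance,
            "n_random_sets": 10,
            "random_set_size": 200,
            "k_clusters": 3,
            "eligible_clusters": ["A", "C"],
            "mapping": "distance",
        },
        "seed": scenario.config.seed,
    }
    with open(directory / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return directory


def scenario_symbol(scenario: Scenario, gene_id: str) -> str:
    """Display symbol for a generated gene (ids are their own symbols)."""
    return gene_id.upper()
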