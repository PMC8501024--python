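"""Readers and writers for the genomic and tabular formats the pipeline touches.

All coordinates are BED-style 0-based half-open internally.  GTF-style
1-based inclusive inputs are converted on read; no downstream operation
reinterprets coordinates.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "CoverageTrack",
    "CountMatrix",
    "FormatError",
    "parse_bed",
    "parse_peaks",
    "parse_gene_models",
    "read_count_matrix",
    "read_bedgraph",
    "write_peaks_bed",
    "write_gene_models_tsv",
    "write_bedgraph",
]

VALID_GENOTYPES = ("WT", "KO")
VALID_TREATMENTS = ("UT", "IR")


class FormatError(ValueError):
    """A malformed record in an input file."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise FormatError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Peak:
    """A ChIP binding site with optional per-condition signal.

    ``fc`` is the binding fold change (IR/UT) and ``group`` one of
    I / II / III / unassigned; both are filled in by the peaks stage.
    """

    peak_id: str
    interval: GenomicInterval
    signal_ut: float | None = None
    signal_ir: float | None = None
    fc: float | None = None
    group: str = "unassigned"

    def __post_init__(self) -> None:
        for name in ("signal_ut", "signal_ir"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise FormatError(f"{name} must be >= 0 for peak {self.peak_id}")


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene with its derived transcription start site.

    The TSS is the 5' end of the gene interval: ``start`` on the plus
    strand, ``end - 1`` on the minus strand (0-based base positions).
    """

    gene_id: str
    symbol: str
    interval: GenomicInterval
    tss: int = field(init=False)

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise FormatError(
                f"gene {self.gene_id}: strand must be + or - (TSS undefined otherwise)"
            )
        tss = self.interval.start if self.interval.strand == "+" else self.interval.end - 1
        object.__setattr__(self, "tss", tss)

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand


class CoverageTrack:
    """Per-chromosome run-length coverage (sorted, non-overlapping runs).

    Supports fast interval integrals via a piecewise-linear cumulative
    function; see :func:`targetfuse.peaks.mean_signal`.
    """

    def __init__(self, runs_by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._runs = {}
        self._cum = {}
        for chrom, (starts, ends, values) in runs_by_chrom.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends <= starts):
                raise FormatError(f"{chrom}: run with end <= start")
            if np.any(values < 0):
                raise FormatError(f"{chrom}: negative coverage value")
            if starts.size > 1 and np.any(starts[1:] < ends[:-1]):
                raise FormatError(f"{chrom}: overlapping coverage runs")
            self._runs[chrom] = (starts, ends, values)
            # knots of the cumulative integral: (x, I(x)) at run boundaries
            areas = values * (ends - starts)
            cum_end = np.cumsum(areas)
            cum_start = cum_end - areas
            x = np.empty(2 * starts.size, dtype=float)
            y = np.empty_like(x)
            x[0::2], x[1::2] = starts, ends
            y[0::2], y[1::2] = cum_start, cum_end
            self._cum[chrom] = (x, y)

    @property
    def chroms(self) -> list[str]:
        return list(self._runs)

    def runs(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._runs[chrom]

    def integral(self, chrom: str, starts, ends) -> np.ndarray:
        """Vectorized integral of coverage over [start, end) windows.

        Bases outside any run contribute 0.
        """
        starts = np.asarray(starts, dtype=float)
        ends = np.asarray(ends, dtype=float)
        if chrom not in self._cum:
            return np.zeros(np.broadcast(starts, ends).shape)
        x, y = self._cum[chrom]
        return np.interp(ends, x, y) - np.interp(starts, x, y)


@dataclass
class CountMatrix:
    """Integer gene x sample counts plus the sample design table.

    ``counts`` is indexed by gene_id with sample columns; ``design`` is
    indexed by sample with genotype / treatment / replicate columns.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [s for s in self.counts.columns if s not in self.design.index]
        if missing:
            raise FormatError(f"samples missing from design: {missing}")
        if (self.counts.values < 0).any():
            raise FormatError("negative counts")

    def samples(self, genotype: str | None = None, treatment: str | None = None) -> list[str]:
        sel = pd.Series(True, index=self.design.index)
        if genotype is not None:
            sel &= self.design["genotype"] == genotype
        if treatment is not None:
            sel &= self.design["treatment"] == treatment
        return [s for s in self.counts.columns if sel.get(s, False)]

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


# ---------------------------------------------------------------------------
# readers


def _as_lines(source) -> Iterable[str]:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            yield from fh
    else:
        yield from source


def parse_bed(source) -> list[GenomicInterval]:
    """Parse BED3+ lines into intervals (input order preserved)."""
    out = []
    for lineno, line in enumerate(_as_lines(source), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"line {lineno}: expected >= 3 tab-separated columns")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-integer coordinate") from exc
        try:
            out.append(GenomicInterval(chrom, start, end))
        except FormatError as exc:
            raise FormatError(f"line {lineno}: {exc}") from exc
    return out


def parse_peaks(source) -> list[Peak]:
    """Parse a BED3+ peak file.

    Optional columns 4-6: peak name, untreated signal, irradiated signal.
    Peaks lacking a name get ``peak_<n>`` in input order.
    """
    peaks = []
    for lineno, line in enumerate(_as_lines(source), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"line {lineno}: expected >= 3 tab-separated columns")
        try:
            iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
        except (ValueError, FormatError) as exc:
            raise FormatError(f"line {lineno}: {exc}") from exc
        name = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else f"peak_{len(peaks) + 1}"
        sig_ut = float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
        sig_ir = float(fields[5]) if len(fields) > 5 and fields[5] != "." else None
        try:
            peaks.append(Peak(name, iv, sig_ut, sig_ir))
        except FormatError as exc:
            raise FormatError(f"line {lineno}: {exc}") from exc
    ids = [p.peak_id for p in peaks]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"duplicate peak ids: {dup}")
    return peaks


def parse_gene_models(source, format: str = "tsv") -> list[GeneModel]:
    """Parse gene models from a 6-column TSV or GTF-lite lines.

    TSV columns: gene_id, symbol, chrom, start, end, strand with 0-based
    half-open coordinates (header optional, detected on the first line).
    GTF rows are 1-based inclusive and converted; only ``gene`` features
    are used.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()

    def _add(gene_id, symbol, chrom, start, end, strand, lineno):
        if gene_id in seen:
            raise FormatError(f"line {lineno}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        try:
            genes.append(GeneModel(gene_id, symbol, GenomicInterval(chrom, start, end, strand)))
        except FormatError as exc:
            raise FormatError(f"line {lineno}: {exc}") from exc

    if format == "tsv":
        for lineno, line in enumerate(_as_lines(source), start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "gene_id":
                continue
            if len(fields) < 6:
                raise FormatError(f"line {lineno}: expected 6 columns")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer coordinate") from exc
            _add(fields[0], fields[1], fields[2], start, end, fields[5], lineno)
    elif format == "gtf":
        for lineno, line in enumerate(_as_lines(source), start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise FormatError(f"line {lineno}: expected 9 GTF columns")
            if fields[2] != "gene":
                continue
            attrs = {}
            for item in fields[8].split(";"):
                item = item.strip()
                if not item:
                    continue
                key, _, val = item.partition(" ")
                attrs[key] = val.strip('"')
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise FormatError(f"line {lineno}: missing gene_id attribute")
            symbol = attrs.get("gene_name", gene_id)
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer coordinate") from exc
            _add(gene_id, symbol, fields[0], start1 - 1, end1, fields[6], lineno)
    else:
        raise ValueError(f"unknown gene model format {format!r}")
    return genes


def read_count_matrix(counts_source, design_source) -> CountMatrix:
    """Read a genes x samples TSV of raw counts plus its design sidecar.

    The counts table's first column is gene ids; the design sidecar maps
    sample -> (genotype in {WT, KO}, treatment in {UT, IR}, replicate).
    """
    if isinstance(counts_source, (str, Path)):
        counts = pd.read_csv(counts_source, sep="\t", index_col=0)
    else:
        counts = pd.read_csv(io.StringIO("".join(counts_source)), sep="\t", index_col=0)
    if isinstance(design_source, (str, Path)):
        design = pd.read_csv(design_source, sep="\t")
    else:
        design = pd.read_csv(io.StringIO("".join(design_source)), sep="\t")

    for col in ("sample", "genotype", "treatment", "replicate"):
        if col not in design.columns:
            raise FormatError(f"design table missing column {col!r}")
    design = design.set_index("sample")
    bad_gt = set(design["genotype"]) - set(VALID_GENOTYPES)
    if bad_gt:
        raise FormatError(f"unknown genotypes in design: {sorted(bad_gt)}")
    bad_tr = set(design["treatment"]) - set(VALID_TREATMENTS)
    if bad_tr:
        raise FormatError(f"unknown treatments in design: {sorted(bad_tr)}")

    if counts.index.has_duplicates:
        raise FormatError("duplicate gene ids in count matrix")
    try:
        numeric = counts.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric count: {exc}") from exc
    if numeric.isna().values.any():
        raise FormatError("missing count value")
    if (numeric.values < 0).any():
        raise FormatError("negative count")
    if not np.allclose(numeric.values, np.round(numeric.values)):
        raise FormatError("non-integer count")
    counts = numeric.round().astype(np.int64)
    return CountMatrix(counts=counts, design=design)


def read_bedgraph(source) -> CoverageTrack:
    """Read a 4-column bedGraph into a CoverageTrack (runs sorted on load)."""
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, line in enumerate(_as_lines(source), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise FormatError(f"line {lineno}: expected 4 bedGraph columns")
        try:
            start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: bad coordinate or value") from exc
        by_chrom.setdefault(fields[0], []).append((start, end, value))
    runs = {}
    for chrom, triples in by_chrom.items():
        starts, ends, values = zip(*triples)
        runs[chrom] = (np.array(starts), np.array(ends), np.array(values))
    return CoverageTrack(runs)


# ---------------------------------------------------------------------------
# writers (round-trip partners of the readers above)


def write_peaks_bed(peaks: Sequence[Peak], path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            ut = "." if p.signal_ut is None else f"{p.signal_ut:.6g}"
            ir = "." if p.signal_ir is None else f"{p.signal_ir:.6g}"
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}"
                f"\t{p.peak_id}\t{ut}\t{ir}\n"
            )


def write_gene_models_tsv(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tsymbol\tchrom\tstart\tend\tstrand\n")
        for g in genes:
            iv = g.interval
            fh.write(f"{g.gene_id}\t{g.symbol}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\n")


def write_bedgraph(track: CoverageTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            starts, ends, values = track.runs(chrom)
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")
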