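"""Novelty and druggability triage of called direct targets.

A target is "novel" when it appears in none of the supplied known-target
lists and has zero co-mentions with the factor term ("p53") in the offline
literature index.  All resources are plain-text file inputs; no network
queries are made, so the literature matcher is a stated approximation of a
title/abstract database search.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .association import TargetCall

__all__ = [
    "TriageRecord",
    "load_gene_lists",
    "load_literature_index",
    "load_druggable_set",
    "literature_hits",
    "flag_druggable",
    "triage_targets",
]

FACTOR_TERM = "p53"


@dataclass
class TriageRecord:
    gene_id: str
    known_lists_hit: list[str] = field(default_factory=list)
    literature_hits: int = 0
    druggable: bool = False

    @property
    def novel(self) -> bool:
        return not self.known_lists_hit and self.literature_hits == 0


def _norm(symbol: str) -> str:
    return symbol.strip().lower()


def load_gene_lists(files: list[str | Path]) -> dict[str, set[str]]:
    """Load one known-target list per file (one symbol per line).

    List names come from file stems; symbols are case-normalized and
    deduplicated.
    """
    lists = {}
    for path in files:
        path = Path(path)
        symbols = {
            _norm(line)
            for line in path.read_text().splitlines()
            if line.strip() and not line.startswith("#")
        }
        if not symbols:
            warnings.warn(f"gene list {path.name} is empty")
        lists[path.stem] = symbols
    return lists


def load_literature_index(path: str | Path) -> dict[str, tuple[str, str]]:
    """Load a TSV of (id, title, abstract) literature records."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("id", "title", "abstract"):
        if col not in df.columns:
            raise ValueError(f"literature index missing column {col!r}")
    return {r.id: (r.title, r.abstract) for r in df.itertuples()}


def load_druggable_set(path: str | Path) -> set[str]:
    """Load a druggable-gene TSV export (first column = gene symbol)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {_norm(s) for s in df.iloc[:, 0].dropna()}


def _word_match(symbol: str, text: str) -> bool:
    # alphanumeric word boundaries: "p53" must not match inside "Trp53bp1"
    pattern = rf"(?<![A-Za-z0-9]){re.escape(symbol)}(?![A-Za-z0-9])"
    return re.search(pattern, text, flags=re.IGNORECASE) is not None


def literature_hits(gene_symbol: str, index: dict[str, tuple[str, str]]) -> int:
    """Count records whose title or abstract co-mentions the gene symbol
    and the factor term, both as whole words, case-insensitive."""
    if not index:
        warnings.warn("literature index is empty")
        return 0
    hits = 0
    for title, abstract in index.values():
        text = f"{title}\n{abstract}"
        if _word_match(gene_symbol, text) and _word_match(FACTOR_TERM, text):
            hits += 1
    return hits


def flag_druggable(gene_symbol: str, druggable_set: set[str]) -> bool:
    return _norm(gene_symbol) in druggable_set


def triage_targets(
    target_calls: list[TargetCall],
    known_lists: dict[str, set[str]],
    index: dict[str, tuple[str, str]],
    druggable_set: set[str],
) -> list[TriageRecord]:
    """One TriageRecord per called direct target, novel+druggable first.

    Pure function of its inputs; identical inputs give identical records.
    """
    records = []
    for call in target_calls:
        if not call.is_direct_target:
            continue
        sym = call.gene_id
        hit_lists = sorted(
            name for name, members in known_lists.items() if _norm(sym) in members
        )
        n_hits = literature_hits(sym, index) if index else 0
        records.append(
            TriageRecord(
                gene_id=sym,
                known_lists_hit=hit_lists,
                literature_hits=n_hits,
                druggable=flag_druggable(sym, druggable_set),
            )
        )
    records.sort(key=lambda r: (-(r.novel and r.druggable), -r.novel, r.gene_id))
    return records
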