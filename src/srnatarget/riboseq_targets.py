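"""Target calling from paired RNA-seq / Ribo-seq differential tables.

Fold changes follow the sRNA-minus / sRNA-plus orientation, so a positive
log2 value marks a gene repressed by the sRNA. Calling is a pure
fold-change filter applied after a read-coverage floor; differential
statistics themselves are upstream of this module. Passing genes are then
classified by regulation mode: a Ribo-seq change substantially exceeding
the RNA-seq change indicates regulation of translation, concordant
significant changes indicate regulation of mRNA abundance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "GeneMeasurement",
    "TargetCall",
    "filter_low_coverage",
    "call_targets",
    "classify_mode",
    "fold_linear",
    "summarize",
    "load_measurements",
    "load_reference_table",
    "calls_to_frame",
]

MIN_READS_DEFAULT = 200
LOG2_THRESHOLD_DEFAULT = 1.0
SIG_ALPHA_DEFAULT = 0.05
DELTA_THRESHOLD_DEFAULT = 0.5


@dataclass(frozen=True)
class GeneMeasurement:
    """Per-gene differential measurements from both assays.

    ``rna_reads``/``ribo_reads`` of ``None`` mean the counts are unknown
    because the table was already coverage-filtered upstream.
    """

    gene: str
    rna_log2fc: float
    rna_p: float
    ribo_log2fc: float
    ribo_p: float
    rna_reads: int | None = None
    ribo_reads: int | None = None

    def __post_init__(self) -> None:
        for label, p in (("rna_p", self.rna_p), ("ribo_p", self.ribo_p)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.gene}: {label}={p} outside [0, 1]")
        for label, fc in (("rna_log2fc", self.rna_log2fc),
                          ("ribo_log2fc", self.ribo_log2fc)):
            if not math.isfinite(fc):
                raise ValueError(f"{self.gene}: {label} is not finite")
        for label, reads in (("rna_reads", self.rna_reads),
                             ("ribo_reads", self.ribo_reads)):
            if reads is not None and reads < 0:
                raise ValueError(f"{self.gene}: {label} negative")


@dataclass(frozen=True)
class TargetCall:
    gene: str
    passes: bool
    direction: str  # repressed / activated / none
    mode: str  # translational / stability / mixed / undetermined
    qualifying_assay: str  # rna / ribo / both / none
    conflicting_signs: bool = False


def filter_low_coverage(
    genes: Iterable[GeneMeasurement],
    min_reads: int = MIN_READS_DEFAULT,
) -> tuple[list[GeneMeasurement], list[tuple[str, str]]]:
    """Retain genes with both assays at or above the read floor.

    Unknown read counts (``None``) pass: they mark tables that were
    coverage-filtered before reaching this module. Returns the retained
    list and an exclusion log of (gene, reason)."""
    kept, excluded = [], []
    for g in genes:
        low = []
        if g.rna_reads is not None and g.rna_reads < min_reads:
            low.append(f"rna_reads={g.rna_reads}")
        if g.ribo_reads is not None and g.ribo_reads < min_reads:
            low.append(f"ribo_reads={g.ribo_reads}")
        if low:
            excluded.append((g.gene, f"below {min_reads} reads ({', '.join(low)})"))
        else:
            kept.append(g)
    return kept, excluded


def _call_one(
    g: GeneMeasurement,
    log2_threshold: float,
    sig_alpha: float,
    delta_threshold: float,
) -> TargetCall:
    rna_hit = abs(g.rna_log2fc) >= log2_threshold
    ribo_hit = abs(g.ribo_log2fc) >= log2_threshold
    if not (rna_hit or ribo_hit):
        return TargetCall(g.gene, False, "none", "undetermined", "none")
    if rna_hit and ribo_hit:
        assay = "both"
    else:
        assay = "rna" if rna_hit else "ribo"
    signs = []
    if rna_hit:
        signs.append(g.rna_log2fc > 0)
    if ribo_hit:
        signs.append(g.ribo_log2fc > 0)
    conflicting = len(set(signs)) > 1
    if conflicting:
        # Direction from the larger-magnitude qualifying assay.
        positive = (
            g.rna_log2fc > 0
            if abs(g.rna_log2fc) >= abs(g.ribo_log2fc)
            else g.ribo_log2fc > 0
        )
    else:
        positive = signs[0]
    direction = "repressed" if positive else "activated"
    call = TargetCall(g.gene, True, direction, "undetermined", assay, conflicting)
    mode = classify_mode(call, g, sig_alpha=sig_alpha, delta_threshold=delta_threshold)
    return TargetCall(g.gene, True, direction, mode, assay, conflicting)


def call_targets(
    genes: Iterable[GeneMeasurement],
    log2_threshold: float = LOG2_THRESHOLD_DEFAULT,
    sig_alpha: float = SIG_ALPHA_DEFAULT,
    delta_threshold: float = DELTA_THRESHOLD_DEFAULT,
) -> list[TargetCall]:
    """Two-fold (|log2| >= 1, inclusive) either-assay target calling.

    Significance is deliberately not part of the pass rule — the filter is
    pure fold change, inclusive at the threshold so a printed 1.00
    qualifies."""
    return [
        _call_one(g, log2_threshold, sig_alpha, delta_threshold) for g in genes
    ]


def classify_mode(
    call: TargetCall,
    gene: GeneMeasurement,
    sig_alpha: float = SIG_ALPHA_DEFAULT,
    delta_threshold: float = DELTA_THRESHOLD_DEFAULT,
) -> str:
    """Regulation-mode classification for a passing call.

    translational: the Ribo-seq change exceeds the RNA-seq change by at
    least ``delta_threshold`` in log2 units while the RNA-seq change is not
    significant; stability: concordant changes (small delta) with a
    significant RNA-seq change; anything else is mixed.
    """
    if not call.passes:
        raise ValueError(f"{call.gene}: mode is undefined for a failing call")
    delta = abs(gene.ribo_log2fc - gene.rna_log2fc)
    rna_significant = gene.rna_p < sig_alpha
    if delta >= delta_threshold and not rna_significant:
        return "translational"
    if delta < delta_threshold and rna_significant:
        return "stability"
    return "mixed"


def fold_linear(log2fc: float) -> float:
    """Linear fold change 2^|log2fc|, rounded to one decimal (half-up)."""
    if not math.isfinite(log2fc):
        raise ValueError("fold change must be finite")
    value = 2.0 ** abs(log2fc)
    return math.floor(value * 10.0 + 0.5) / 10.0


def summarize(calls: Iterable[TargetCall]) -> dict:
    """Tallies of passing calls by direction and mode."""
    calls = list(calls)
    repressed = sum(1 for c in calls if c.passes and c.direction == "repressed")
    activated = sum(1 for c in calls if c.passes and c.direction == "activated")
    by_mode: dict[str, int] = {}
    for c in calls:
        if c.passes:
            by_mode[c.mode] = by_mode.get(c.mode, 0) + 1
    return {
        "repressed": repressed,
        "activated": activated,
        "total": repressed + activated,
        "by_mode": dict(sorted(by_mode.items())),
    }


def load_measurements(path: str | Path | pd.DataFrame) -> list[GeneMeasurement]:
    """Read a gene table TSV (columns gene, rna_log2fc, rna_p, ribo_log2fc,
    ribo_p, optional rna_reads/ribo_reads) into measurements."""
    df = path if isinstance(path, pd.DataFrame) else pd.read_csv(path, sep="\t")
    have_reads = "rna_reads" in df.columns and "ribo_reads" in df.columns
    return [
        GeneMeasurement(
            gene=str(row.gene),
            rna_log2fc=float(row.rna_log2fc),
            rna_p=float(row.rna_p),
            ribo_log2fc=float(row.ribo_log2fc),
            ribo_p=float(row.ribo_p),
            rna_reads=int(row.rna_reads) if have_reads else None,
            ribo_reads=int(row.ribo_reads) if have_reads else None,
        )
        for row in df.itertuples()
    ]


def load_reference_table() -> pd.DataFrame:
    """The shipped RyhB differential table (transcribed printed values;
    read counts unknown — the printed table is already coverage-filtered)."""
    with resources.as_file(
        resources.files("srnatarget") / "data" / "ryhb_table1.tsv"
    ) as path:
        return pd.read_csv(path, sep="\t")


def calls_to_frame(calls: Iterable[TargetCall]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "gene": c.gene,
            "passes": c.passes,
            "direction": c.direction,
            "mode": c.mode,
            "qualifying_assay": c.qualifying_assay,
            "conflicting_signs": c.conflicting_signs,
        }
        for c in calls
    ])
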