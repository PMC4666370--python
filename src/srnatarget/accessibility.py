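"""Accessible-region seeding on the sRNA.

Single-stranded regions — in particular hairpin loops of the ensemble
centroid — nucleate the intermolecular interaction; a chosen loop is then
extended by flanking nucleotides into the hybridization search window.
Regions use 1-based inclusive coordinates throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .energy_model import SecondaryStructure

__all__ = [
    "AccessibleRegion",
    "find_hairpin_loops",
    "find_free_runs",
    "extend_region",
    "select_seed_regions",
    "DEFAULT_HAIRPIN_FLANKS",
    "DEFAULT_SYMMETRIC_FLANK",
]

# Flank sizes (upstream, downstream) that extend the largest centroid
# hairpin loop into the search window; symmetric fallback for other seeds.
DEFAULT_HAIRPIN_FLANKS = (9, 17)
DEFAULT_SYMMETRIC_FLANK = 15


@dataclass(frozen=True)
class AccessibleRegion:
    """A candidate single-stranded region, 1-based inclusive."""

    start: int
    end: int
    mean_ss_prob: float
    kind: str  # "hairpin_loop" or "free_run"
    source: str  # "centroid", "profile", or either + "+extended"

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid region {self.start}..{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def to_bed(self, seq_id: str) -> str:
        """0-based half-open BED line with the sequence id as chromosome."""
        return f"{seq_id}\t{self.start - 1}\t{self.end}\t{self.kind}"


def find_hairpin_loops(
    structure: SecondaryStructure,
    profile: Sequence[float] | None = None,
) -> list[AccessibleRegion]:
    """One region per hairpin loop (maximal unpaired run closed by a single
    pair), longest first. ``profile`` (per-position single-strandedness)
    fills in ``mean_ss_prob``; without it loop positions count as fully
    single-stranded in the source structure."""
    ordered = structure.sorted_pairs()
    regions = []
    for idx, (i, j) in enumerate(ordered):
        if any(i < k < j for k, _ in ordered if (k, _) != (i, j)):
            continue  # not innermost
        start1, end1 = i + 2, j  # loop occupies i+1 .. j-1 (0-based)
        if profile is not None:
            mean = float(np.mean(np.asarray(profile)[start1 - 1:end1]))
        else:
            mean = 1.0
        regions.append(
            AccessibleRegion(start1, end1, mean, kind="hairpin_loop", source="centroid")
        )
    regions.sort(key=lambda r: (-len(r), r.start))
    return regions


def find_free_runs(
    profile: Sequence[float],
    threshold: float = 0.5,
    min_len: int = 4,
) -> list[AccessibleRegion]:
    """Maximal runs of positions with single-strandedness >= threshold and
    length >= min_len, in sequence order."""
    prof = np.asarray(profile, dtype=float)
    regions = []
    start = None
    for pos, value in enumerate(prof):
        if value >= threshold:
            if start is None:
                start = pos
        else:
            if start is not None and pos - start >= min_len:
                regions.append(AccessibleRegion(
                    start + 1, pos, float(prof[start:pos].mean()),
                    kind="free_run", source="profile",
                ))
            start = None
    if start is not None and len(prof) - start >= min_len:
        regions.append(AccessibleRegion(
            start + 1, len(prof), float(prof[start:].mean()),
            kind="free_run", source="profile",
        ))
    return regions


def extend_region(
    region: AccessibleRegion,
    upstream_flank: int,
    downstream_flank: int,
    seq_len: int,
) -> AccessibleRegion:
    """Extend by the given flanks, clipped to [1, seq_len]."""
    if upstream_flank < 0 or downstream_flank < 0:
        raise ValueError("flanks must be non-negative")
    return replace(
        region,
        start=max(1, region.start - upstream_flank),
        end=min(seq_len, region.end + downstream_flank),
        source=region.source + "+extended",
    )


def select_seed_regions(
    centroid: SecondaryStructure,
    profile: Sequence[float],
    threshold: float = 0.5,
    min_len: int = 4,
) -> list[AccessibleRegion]:
    """Seed-source precedence: centroid hairpin loops of length >= min_len
    first; high-probability free runs of the profile as fallback."""
    loops = [r for r in find_hairpin_loops(centroid, profile) if len(r) >= min_len]
    if loops:
        return loops
    return find_free_runs(profile, threshold=threshold, min_len=min_len)


def regions_to_tsv(regions: Iterable[AccessibleRegion]) -> str:
    lines = ["start\tend\tlength\tmean_ss_prob\tkind\tsource"]
    for r in regions:
        lines.append(
            f"{r.start}\t{r.end}\t{len(r)}\t{r.mean_ss_prob:.4f}\t{r.kind}\t{r.source}"
        )
    return "\n".join(lines) + "\n"
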