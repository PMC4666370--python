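"""Intermolecular duplex prediction between an sRNA window and a target mRNA.

A duplex is a strictly monotone antiparallel pairing (sRNA index ascending,
mRNA index descending) scored with the duplex-only nearest-neighbor model:
stacks, bulge and interior loops (per-side span capped), and terminal AU/GU
penalties — no intramolecular pairs and no branching. The dynamic program
returns the minimum-free-energy hybrid plus non-redundant suboptimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy_model import (
    EnergyParameters,
    RnaSequence,
    default_parameters,
    duplex_energy,
    pair_index,
)

__all__ = ["HybridDuplex", "MutantPairingResult", "hybridize", "evaluate_mutant_pairing"]

_TIE_DECIMALS = 9


@dataclass(frozen=True)
class HybridDuplex:
    """An intermolecular duplex with its free energy.

    Intervals are 1-based inclusive; ``pairs`` hold 0-based (sRNA, mRNA)
    indices into the *full* sRNA and mRNA sequences.
    """

    srna_interval: tuple[int, int]
    mrna_interval: tuple[int, int]
    pairs: tuple[tuple[int, int], ...]
    dG_hybrid: float
    alignment_text: str = field(compare=False, default="")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def mrna_interval_relative(self, mrna: RnaSequence) -> tuple[int, int]:
        """The mRNA interval in start-codon-relative display coordinates."""
        return (mrna.to_relative(self.mrna_interval[0]),
                mrna.to_relative(self.mrna_interval[1]))

    def overlap_fraction(self, other: "HybridDuplex") -> float:
        """Fraction of this duplex's mRNA interval covered by ``other``."""
        a0, a1 = self.mrna_interval
        b0, b1 = other.mrna_interval
        overlap = max(0, min(a1, b1) - max(a0, b0) + 1)
        return overlap / (a1 - a0 + 1)


def _render_alignment(
    srna: str, mrna: str, pairs: tuple[tuple[int, int], ...]
) -> str:
    """Three-line human-readable duplex rendering (sRNA 5'->3' on top)."""
    top, mid, bot = [], [], []
    (i0, j0), (iL, jL) = pairs[0], pairs[-1]
    pos_s, pos_m = i0, j0
    for (i, j) in pairs:
        while pos_s < i:
            top.append(srna[pos_s].lower())
            mid.append(" ")
            bot.append("-")
            pos_s += 1
        while pos_m > j:
            top.append("-")
            mid.append(" ")
            bot.append(mrna[pos_m].lower())
            pos_m -= 1
        top.append(srna[i])
        mid.append("|")
        bot.append(mrna[j])
        pos_s, pos_m = i + 1, j - 1
    header = f"sRNA 5'-{''.join(top)}-3'  ({i0 + 1}..{iL + 1})"
    middle = f"        {''.join(mid)}"
    footer = f"mRNA 3'-{''.join(bot)}-5'  ({jL + 1}..{j0 + 1})"
    return "\n".join((header, middle, footer))


def _duplex_dp(
    window: str,
    mrna: str,
    params: EnergyParameters,
    max_loop: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Fill E[i, j] = best energy of a duplex whose 3'-most sRNA pair is
    (i, j), including duplex_init and the AU penalty of the *first* pair
    but not of (i, j) itself. Also returns the pair-type matrix."""
    nw, nm = len(window), len(mrna)
    pt = np.full((nw, nm), -1, dtype=np.int64)
    for i in range(nw):
        for j in range(nm):
            pt[i, j] = pair_index(window[i], mrna[j])
    au = np.array([params.au_penalty(*p) for p in
                   ("CG", "GC", "GU", "UG", "AU", "UA")])
    INF = np.inf
    E = np.full((nw, nm), INF)
    allowed = pt >= 0
    # Start a new duplex at (i, j).
    start = np.where(allowed, params.duplex_init + np.where(allowed, au[pt], 0.0), INF)
    stack_e = np.asarray(params.stack)
    loop_pen = np.full((max_loop + 1, max_loop + 1), INF)
    for a in range(max_loop + 1):
        for b in range(max_loop + 1):
            if a + b >= 1:
                loop_pen[a, b] = params.loop_energy(a, b)
    for i in range(nw):
        best = start[i].copy()
        for a in range(0, min(max_loop, i - 1) + 1):
            k = i - 1 - a
            if k < 0:
                break
            row = E[k]
            for b in range(0, max_loop + 1):
                # Predecessor (k, l) with l = j + 1 + b.
                if 1 + b >= nm:
                    break
                shifted = np.full(nm, INF)
                shifted[: nm - 1 - b] = row[1 + b:]
                if a == 0 and b == 0:
                    # Stack: energy depends on both pair types.
                    prev_pt = np.full(nm, -1, dtype=np.int64)
                    prev_pt[: nm - 1] = pt[k, 1:]
                    ok = (prev_pt >= 0) & (pt[i] >= 0) & np.isfinite(shifted)
                    cand = np.full(nm, INF)
                    cand[ok] = shifted[ok] + stack_e[prev_pt[ok], pt[i][ok]]
                else:
                    cand = shifted + loop_pen[a, b]
                best = np.minimum(best, cand)
        E[i] = np.where(allowed[i], best, INF)
    return E, pt


def _traceback(
    E: np.ndarray,
    pt: np.ndarray,
    window: str,
    mrna: str,
    params: EnergyParameters,
    max_loop: int,
    end: tuple[int, int],
) -> list[tuple[int, int]]:
    """Recover one optimal duplex ending at ``end`` (deterministic: the
    first predecessor in (loop-size ascending) order that achieves the
    score)."""
    au = np.array([params.au_penalty(*p) for p in
                   ("CG", "GC", "GU", "UG", "AU", "UA")])
    stack_e = np.asarray(params.stack)
    i, j = end
    pairs = [(i, j)]
    while True:
        target = E[i, j]
        if abs(target - (params.duplex_init + au[pt[i, j]])) < 1e-9:
            break
        found = False
        for a in range(0, max_loop + 1):
            k = i - 1 - a
            if k < 0:
                break
            for b in range(0, max_loop + 1):
                l = j + 1 + b
                if l >= E.shape[1] or not np.isfinite(E[k, l]):
                    continue
                if a == 0 and b == 0:
                    step = stack_e[pt[k, l], pt[i, j]]
                else:
                    step = params.loop_energy(a, b)
                if abs(E[k, l] + step - target) < 1e-9:
                    i, j = k, l
                    pairs.append((i, j))
                    found = True
                    break
            if found:
                break
        if not found:  # numerical safety net
            break
    pairs.reverse()
    return pairs


def hybridize(
    srna_window: str | RnaSequence,
    mrna: str | RnaSequence,
    params: EnergyParameters | None = None,
    max_loop: int = 15,
    n_suboptimal: int = 10,
    window_offset: int = 0,
    seed_region: tuple[int, int] | None = None,
    min_overlap_with_seed: int = 1,
    max_overlap_fraction: float = 0.5,
    min_contiguous_block: int | None = None,
) -> list[HybridDuplex]:
    """Predict hybrids between an sRNA search window and a target mRNA.

    Parameters
    ----------
    srna_window:
        Subsequence of the sRNA to search with; ``window_offset`` is its
        0-based offset within the full sRNA, so reported coordinates refer
        to the full molecule.
    seed_region:
        Optional 1-based inclusive interval (full-sRNA coordinates) of the
        original, unextended seed; retained hybrids must pair at least
        ``min_overlap_with_seed`` nucleotides inside it.
    max_overlap_fraction:
        Suboptimals whose mRNA interval overlaps an already-reported hybrid
        by at least this fraction are discarded (non-redundancy).
    min_contiguous_block:
        Optional post-filter requiring a run of at least this many
        consecutive stacked pairs (off by default).

    Returns the MFE hybrid plus up to ``n_suboptimal`` alternatives sorted
    by energy (ties: smaller mRNA start, then smaller sRNA start, then
    fewer pairs). Hybrids with dG_hybrid >= 0 are never reported; no
    favorable hybrid yields an empty list.
    """
    params = params or default_parameters()
    w = srna_window.seq if isinstance(srna_window, RnaSequence) else srna_window
    m = mrna.seq if isinstance(mrna, RnaSequence) else mrna
    if not w:
        raise ValueError("empty sRNA window")
    if not m:
        raise ValueError("empty mRNA sequence")
    E, pt = _duplex_dp(w, m, params, max_loop)
    au = np.array([params.au_penalty(*p) for p in
                   ("CG", "GC", "GU", "UG", "AU", "UA")])
    close = np.where(pt >= 0, au[np.maximum(pt, 0)], np.inf)
    score = E + close

    finite = np.argwhere(np.isfinite(score) & (score < 0.0))
    order = sorted(
        map(tuple, finite),
        key=lambda ij: (round(float(score[ij]), _TIE_DECIMALS), ij[1], ij[0]),
    )

    results: list[HybridDuplex] = []
    for i, j in order:
        if len(results) > n_suboptimal:
            break
        pairs_w = _traceback(E, pt, w, m, params, max_loop, (int(i), int(j)))
        pairs_full = tuple((int(pi) + window_offset, int(pj)) for pi, pj in pairs_w)
        if seed_region is not None:
            lo, hi = seed_region[0] - 1, seed_region[1] - 1
            inside = sum(1 for pi, _ in pairs_full if lo <= pi <= hi)
            if inside < min_overlap_with_seed:
                continue
        if min_contiguous_block is not None:
            if _longest_stack_run(pairs_full) < min_contiguous_block:
                continue
        dG = duplex_energy(
            srna_window if isinstance(srna_window, str) else w, m, pairs_w, params
        )
        srna_pos = [pi for pi, _ in pairs_full]
        mrna_pos = [pj for _, pj in pairs_full]
        duplex = HybridDuplex(
            srna_interval=(min(srna_pos) + 1, max(srna_pos) + 1),
            mrna_interval=(min(mrna_pos) + 1, max(mrna_pos) + 1),
            pairs=pairs_full,
            dG_hybrid=float(dG),
            alignment_text=_render_alignment(w, m, tuple(pairs_w)),
        )
        if any(duplex.overlap_fraction(kept) >= max_overlap_fraction
               for kept in results):
            continue
        results.append(duplex)
    results.sort(key=lambda h: (round(h.dG_hybrid, _TIE_DECIMALS),
                                h.mrna_interval[0], h.srna_interval[0], h.n_pairs))
    return results[: n_suboptimal + 1]


def _longest_stack_run(pairs: tuple[tuple[int, int], ...]) -> int:
    best = run = 1
    for (i, j), (k, l) in zip(pairs, pairs[1:]):
        run = run + 1 if (k == i + 1 and l == j - 1) else 1
        best = max(best, run)
    return best


@dataclass(frozen=True)
class MutantPairingResult:
    """2x2 grid of best hybrids for {wt, mut} sRNA x {wt, mut} mRNA."""

    grid: dict[tuple[str, str], HybridDuplex | None]
    energies: dict[tuple[str, str], float]
    compensatory: bool
    cutoff: float


def evaluate_mutant_pairing(
    srna_wt: RnaSequence,
    srna_mut: RnaSequence,
    mrna_wt: RnaSequence,
    mrna_mut: RnaSequence,
    site: tuple[int, int],
    params: EnergyParameters | None = None,
    cutoff: float = -7.0,
    max_loop: int = 15,
) -> MutantPairingResult:
    """Hybridize all four wt/mut combinations restricted to an mRNA site.

    ``site`` is 1-based inclusive on the mRNA. The interaction is called
    compensatory when both matched combinations (wt, wt) and (mut, mut)
    hybridize below ``cutoff`` (kcal/mol) while both cross combinations do
    not. Combinations with no favorable hybrid score 0.0.
    """
    if len(srna_wt) != len(srna_mut):
        raise ValueError("sRNA mutant must be an equal-length substitution")
    if len(mrna_wt) != len(mrna_mut):
        raise ValueError("mRNA mutant must be an equal-length substitution")
    params = params or default_parameters()
    lo, hi = site
    if not (1 <= lo <= hi <= len(mrna_wt)):
        raise ValueError(f"site {site} outside mRNA of length {len(mrna_wt)}")
    grid: dict[tuple[str, str], HybridDuplex | None] = {}
    energies: dict[tuple[str, str], float] = {}
    for s_label, srna in (("wt", srna_wt), ("mut", srna_mut)):
        for m_label, mrna in (("wt", mrna_wt), ("mut", mrna_mut)):
            segment = mrna.seq[lo - 1:hi]
            hits = hybridize(srna.seq, segment, params, max_loop=max_loop,
                             n_suboptimal=0)
            best = hits[0] if hits else None
            if best is not None:
                # Report coordinates on the full mRNA.
                pairs = tuple((pi, pj + lo - 1) for pi, pj in best.pairs)
                best = HybridDuplex(
                    srna_interval=best.srna_interval,
                    mrna_interval=(best.mrna_interval[0] + lo - 1,
                                   best.mrna_interval[1] + lo - 1),
                    pairs=pairs,
                    dG_hybrid=best.dG_hybrid,
                    alignment_text=best.alignment_text,
                )
            grid[(s_label, m_label)] = best
            energies[(s_label, m_label)] = best.dG_hybrid if best else 0.0
    compensatory = (
        energies[("wt", "wt")] < cutoff
        and energies[("mut", "mut")] < cutoff
        and energies[("wt", "mut")] >= cutoff
        and energies[("mut", "wt")] >= cutoff
    )
    return MutantPairingResult(grid=grid, energies=energies,
                               compensatory=compensatory, cutoff=cutoff)
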