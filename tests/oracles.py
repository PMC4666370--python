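"""Independent oracles used by the test suite.

Everything here deliberately re-derives results through a different route
than the package: term-by-term energy evaluation driven by a partner-array
scan, exhaustive enumeration of all valid structures for partition-function
and probability checks, and recursive enumeration of all monotone duplex
pairings for hybridization checks.
"""

from __future__ import annotations

import math

from srnatarget.energy_model import (
    EnergyParameters,
    RnaSequence,
    SecondaryStructure,
    duplex_energy,
    pair_index,
)


def naive_structure_energy(
    seq: RnaSequence, structure: SecondaryStructure, params: EnergyParameters
) -> float:
    """Term-enumeration re-implementation of the loop-sum energy."""
    s = seq.seq
    n = len(s)
    partner = structure.partner_map(n)

    def au(i: int, j: int) -> float:
        return params.au_penalty(s[i], s[j])

    def direct_children(lo: int, hi: int) -> list[tuple[int, int]]:
        kids = []
        k = lo
        while k <= hi:
            if partner[k] > k:
                kids.append((k, partner[k]))
                k = partner[k] + 1
            else:
                k += 1
        return kids

    total = 0.0
    for i, j in structure.pairs:
        kids = direct_children(i + 1, j - 1)
        if not kids:
            total += params.hairpin_energy(j - i - 1) + au(i, j)
        elif len(kids) == 1:
            (k, l) = kids[0]
            l1, l2 = k - i - 1, j - l - 1
            if l1 == 0 and l2 == 0:
                total += params.stack[pair_index(s[i], s[j])][pair_index(s[k], s[l])]
            else:
                total += params.loop_energy(l1, l2) + au(i, j) + au(k, l)
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in kids)
            total += (
                params.multiloop_closing
                + params.multiloop_branch * (len(kids) + 1)
                + params.multiloop_unpaired * unpaired
                + au(i, j)
                + sum(au(k, l) for k, l in kids)
            )
    total += sum(au(k, l) for k, l in direct_children(0, n - 1))
    return total


def enumerate_structures(s: str) -> list[frozenset]:
    """All valid non-crossing pair sets over sequence string ``s``."""

    def rec(positions: tuple[int, ...]):
        if not positions:
            yield frozenset()
            return
        first, rest = positions[0], positions[1:]
        yield from rec(rest)
        for j in rest:
            if j - first >= 4 and pair_index(s[first], s[j]) >= 0:
                inside = tuple(p for p in rest if first < p < j)
                outside = tuple(p for p in rest if p > j)
                for si in rec(inside):
                    for so in rec(outside):
                        yield frozenset({(first, j)}) | si | so

    return list(rec(tuple(range(len(s)))))


def enumeration_partition(
    seq: RnaSequence, params: EnergyParameters
) -> tuple[float, dict[frozenset, float]]:
    """(Z, per-structure Boltzmann probability) by exhaustive enumeration."""
    from srnatarget.energy_model import structure_energy

    RT = params.RT
    weights: dict[frozenset, float] = {}
    for pairs in enumerate_structures(seq.seq):
        E = structure_energy(seq, SecondaryStructure(pairs), params, validate=False)
        weights[pairs] = math.exp(-E / RT)
    Z = sum(weights.values())
    return Z, {k: w / Z for k, w in weights.items()}


def enumeration_pair_probabilities(seq: RnaSequence, params: EnergyParameters):
    import numpy as np

    _, probs = enumeration_partition(seq, params)
    P = np.zeros((len(seq), len(seq)))
    for pairs, pr in probs.items():
        for i, j in pairs:
            P[i, j] += pr
    return P


def bruteforce_duplex_mfe(
    w: str, m: str, params: EnergyParameters, max_loop: int = 15
) -> float | None:
    """Best (most negative) duplex energy over all monotone antiparallel
    pairings with per-side loop spans <= max_loop; None if no duplex scores
    below zero."""
    nw, nm = len(w), len(m)
    best: float | None = None

    def rec(i: int, j: int, pairs: list[tuple[int, int]]) -> None:
        nonlocal best
        if pairs:
            dG = duplex_energy(w, m, pairs, params)
            if dG < 0 and (best is None or dG < best - 1e-12):
                best = dG
        for ii in range(i, nw):
            for jj in range(j, -1, -1):
                if pair_index(w[ii], m[jj]) < 0:
                    continue
                if pairs:
                    pi, pj = pairs[-1]
                    if ii - pi - 1 > max_loop or pj - jj - 1 > max_loop:
                        continue
                rec(ii + 1, jj - 1, pairs + [(ii, jj)])

    rec(0, nm - 1, [])
    return best
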