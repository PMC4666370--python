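"""Boltzmann-ensemble machinery: partition function, exact base-pair
probabilities, seeded stochastic sampling, single-strandedness profiles,
centroids and structural clustering.

The inside/outside recursions use exactly the loop-based energy model of
:mod:`srnatarget.energy_model` (stacks, length-indexed loop penalties,
affine multiloops, terminal AU/GU at helix ends), so for short sequences the
partition function equals the exhaustive sum over all valid structures of
exp(-E/RT) — a property the test suite asserts by enumeration.

Sampling draws independent stochastic tracebacks; a given integer seed
reproduces the ensemble exactly (numpy PCG64, branching on cumulative
weights with candidates ordered toward smaller indices).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .energy_model import (
    EnergyParameters,
    RnaSequence,
    SecondaryStructure,
    ValidityError,
    default_parameters,
    pair_index,
    structure_energy,
)

__all__ = [
    "PartitionSummary",
    "StructureEnsemble",
    "InsideMatrices",
    "partition_function",
    "pair_probabilities",
    "sample_structures",
    "ss_profile",
    "centroid_structure",
    "Centroid",
    "cluster_ensemble",
]

MAX_SEQUENCE_LENGTH = 2000


class CapacityError(ValueError):
    """Sequence longer than the configured maximum."""


@dataclass(frozen=True)
class PartitionSummary:
    """Partition function with the unpaired chain as reference state."""

    Z: float
    ensemble_free_energy: float  # -RT ln Z, kcal/mol


@dataclass
class StructureEnsemble:
    """A seeded Boltzmann sample of secondary structures.

    ``pair_prob`` and ``ss_profile`` are the empirical profiles of the
    sample, so ``ss_profile[i] == 1 - pair_prob[i].sum()`` holds exactly.
    """

    seq: RnaSequence
    structures: list[SecondaryStructure]
    sample_size: int
    seed: int
    pair_prob: np.ndarray
    ss_profile: np.ndarray
    ensemble_energies: np.ndarray

    def __post_init__(self) -> None:
        if self.sample_size < 1:
            raise ValueError("ensemble must contain at least one structure")


class InsideMatrices:
    """Inside partition-function matrices for one sequence.

    ``ZB[i, j]`` sums over structures on [i, j] in which (i, j) is paired;
    ``ZM``/``ZM1`` are the multiloop-segment sums (at least one branch /
    exactly one branch starting at i); ``Zp``/``Zs`` are prefix and suffix
    exterior sums. All energies enter as Boltzmann factors at ``params.RT``.
    """

    def __init__(self, seq: RnaSequence, params: EnergyParameters):
        self.seq = seq
        self.params = params
        s = seq.seq
        n = self.n = len(s)
        RT = params.RT
        self.beta = 1.0 / RT

        pt = np.full((n, n), -1, dtype=np.int64)
        for i in range(n):
            for j in range(i + 4, n):
                pt[i, j] = pair_index(s[i], s[j])
        self.ptype = pt
        self.allowed = pt >= 0

        au_vals = np.array([params.au_penalty(*p) for p in
                            ("CG", "GC", "GU", "UG", "AU", "UA")])
        self.eAU = np.ones((n, n))
        self.eAU[self.allowed] = np.exp(-au_vals[pt[self.allowed]] * self.beta)

        self.estack = np.exp(-np.asarray(params.stack) * self.beta)
        span = params.max_loop_span
        # Boltzmann factor of the generic interior/bulge term by (l1, l2).
        self.eloop = np.zeros((span + 1, span + 1))
        for l1 in range(span + 1):
            for l2 in range(span + 1):
                if 1 <= l1 + l2 <= span:
                    self.eloop[l1, l2] = math.exp(-params.loop_energy(l1, l2) * self.beta)
        self.x = math.exp(-params.multiloop_unpaired * self.beta)
        self.eb = math.exp(-params.multiloop_branch * self.beta)
        self.ea_closing = math.exp(
            -(params.multiloop_closing + params.multiloop_branch) * self.beta
        )
        self.xpow = self.x ** np.arange(n + 1)

        self.ZB = np.zeros((n, n))
        self.ZBau = np.zeros((n, n))
        self.Wm = np.zeros((n, n))
        self.ZM = np.zeros((n, n))
        self.ZM1 = np.zeros((n, n))
        self._fill()

    def _fill(self) -> None:
        n, p = self.n, self.params
        beta, x = self.beta, self.x
        ZB, ZBau, Wm, ZM, ZM1 = self.ZB, self.ZBau, self.Wm, self.ZM, self.ZM1
        span = p.max_loop_span
        # One diagonal (fixed span d) at a time: ZB at span d only needs
        # ZM/ZM1 at spans <= d - 3, so filling ZB, then ZM1/ZM, per d keeps
        # every dependency behind us.
        for d in range(4, n):
            m = n - d  # number of cells on this diagonal
            idx = np.arange(m)
            allowed_d = self.allowed.diagonal(d)
            eau_d = self.eAU.diagonal(d)
            # Hairpin.
            val = np.full(m, math.exp(-p.hairpin_energy(d - 1) * beta)) * eau_d
            # Stack on the immediately enclosed pair.
            if d >= 6:
                inner_pt = self.ptype.diagonal(d - 2)[1:1 + m]
                outer_pt = self.ptype.diagonal(d)
                ok = (inner_pt >= 0) & (outer_pt >= 0)
                st = np.zeros(m)
                st[ok] = self.estack[outer_pt[ok], inner_pt[ok]] * \
                    ZB.diagonal(d - 2)[1:1 + m][ok]
                val += st
            # Bulge and interior loops (generic, capped at max_loop_span).
            interior = np.zeros(m)
            for l1 in range(0, min(span, d - 6) + 1):
                for l2 in range(0, min(span - l1, d - 6 - l1) + 1):
                    if l1 + l2 < 1:
                        continue
                    o = d - 2 - l1 - l2
                    diag = ZBau.diagonal(o)
                    interior += self.eloop[l1, l2] * diag[1 + l1:1 + l1 + m]
            val += interior * eau_d
            # Multiloop closure: >= 2 enclosed branches, last starts at k.
            if d >= 11:
                ml = np.zeros(m)
                for a in range(m):
                    i, j = a, a + d
                    ks = np.arange(i + 6, j - 4)
                    if ks.size:
                        ml[a] = float(ZM[i + 1, ks - 1] @ ZM1[ks, j - 1])
                val += self.ea_closing * eau_d * ml
            ZB_d = np.where(allowed_d, val, 0.0)
            ZB[idx, idx + d] = ZB_d
            ZBau[idx, idx + d] = ZB_d * eau_d
            Wm[idx, idx + d] = ZBau.diagonal(d) * self.eb
            # Multiloop segment matrices on the same diagonal.
            for i in range(m):
                j = i + d
                ZM1[i, j] = x * ZM1[i, j - 1] + Wm[i, j]
                ks = np.arange(i, j - 3)
                prefix = self.xpow[ks - i].copy()
                if ks.size > 1:
                    prefix[1:] += ZM[i, ks[1:] - 1]
                ZM[i, j] = float(prefix @ Wm[ks, j])
                if d > 4:
                    ZM[i, j] += x * ZM[i, j - 1]

        # Exterior prefix/suffix sums.
        Zp = np.ones(n + 1)
        for j in range(n):
            Zp[j + 1] = Zp[j]
            ks = np.arange(0, j - 3)
            if ks.size:
                Zp[j + 1] += float(Zp[ks] @ self.ZBau[ks, j])
        Zs = np.ones(n + 2)
        for i in range(n - 1, -1, -1):
            Zs[i] = Zs[i + 1]
            js = np.arange(i + 4, n)
            if js.size:
                Zs[i] += float(self.ZBau[i, js] @ Zs[js + 1])
        self.Zp, self.Zs = Zp, Zs
        self.Z = Zp[n]


def partition_function(
    seq: RnaSequence,
    params: EnergyParameters | None = None,
    max_len: int = MAX_SEQUENCE_LENGTH,
) -> PartitionSummary:
    """Partition function and ensemble free energy -RT ln Z (kcal/mol)."""
    params = params or default_parameters()
    if len(seq) > max_len:
        raise CapacityError(f"sequence of length {len(seq)} exceeds {max_len}")
    inside = InsideMatrices(seq, params)
    return PartitionSummary(Z=inside.Z, ensemble_free_energy=-params.RT * math.log(inside.Z))


def pair_probabilities(
    seq: RnaSequence,
    params: EnergyParameters | None = None,
) -> np.ndarray:
    """Exact base-pair probability matrix P[i, j] via the outside recursion.

    Quartic in sequence length (the multiloop-context sum ranges over all
    enclosing pairs); intended for short sequences — desk-scale profiles for
    long RNAs come from the empirical sample instead.
    """
    params = params or default_parameters()
    inside = InsideMatrices(seq, params)
    n = inside.n
    ZB, ZM, eAU = inside.ZB, inside.ZM, inside.eAU
    xpow = inside.xpow
    span = params.max_loop_span
    Bhat = np.zeros((n, n))
    pairs_by_span_desc = [
        (i, i + d) for d in range(n - 1, 3, -1) for i in range(n - d)
        if inside.allowed[i, i + d]
    ]

    def R(a: int, b: int) -> float:
        # Any content on [a, b]: all unpaired, or >= 1 multiloop branch.
        if b < a:
            return 1.0
        return xpow[b - a + 1] + ZM[a, b]

    for i, j in pairs_by_span_desc:
        total = inside.Zp[i] * inside.Zs[j + 1] * eAU[i, j]
        if i >= 1 and j + 1 < n and inside.allowed[i - 1, j + 1]:
            total += Bhat[i - 1, j + 1] * \
                inside.estack[inside.ptype[i - 1, j + 1], inside.ptype[i, j]]
        interior = 0.0
        for l1 in range(0, min(span, i) + 1):
            k = i - 1 - l1
            if k < 0:
                break
            for l2 in range(0, min(span - l1, n - 2 - j) + 1):
                if l1 + l2 < 1:
                    continue
                l = j + 1 + l2
                if inside.allowed[k, l]:
                    interior += (
                        inside.eloop[l1, l2] * Bhat[k, l] * eAU[k, l]
                    )
        total += interior * eAU[i, j]
        ml = 0.0
        for p_ in range(i):
            for q in range(j + 1, n):
                if not inside.allowed[p_, q] or Bhat[p_, q] == 0.0:
                    continue
                left_branch = ZM[p_ + 1, i - 1] if i - 1 >= p_ + 1 else 0.0
                inner = left_branch * R(j + 1, q - 1) + \
                    xpow[i - p_ - 1] * (ZM[j + 1, q - 1] if q - 1 >= j + 1 else 0.0)
                ml += Bhat[p_, q] * eAU[p_, q] * inside.ea_closing * inner
        total += ml * inside.eb * eAU[i, j]
        Bhat[i, j] = total

    P = ZB * Bhat / inside.Z
    return np.clip(P, 0.0, 1.0)


class _StochasticTraceback:
    """Samples structures from the inside matrices.

    Candidate distributions for each decomposition node are cached, so the
    cost of repeated sampling is dominated by cumulative-sum lookups.
    """

    def __init__(self, inside: InsideMatrices):
        self.inside = inside
        self._cache: dict[tuple, tuple[np.ndarray, list]] = {}

    def _candidates_B(self, i: int, j: int):
        ins = self.inside
        p, beta = ins.params, ins.beta
        acts: list[tuple] = []
        ws: list[float] = []
        d = j - i
        acts.append(("h",))
        ws.append(math.exp(-p.hairpin_energy(d - 1) * beta) * ins.eAU[i, j])
        if d >= 6 and ins.allowed[i + 1, j - 1]:
            acts.append(("p", i + 1, j - 1))
            ws.append(ins.estack[ins.ptype[i, j], ins.ptype[i + 1, j - 1]]
                      * ins.ZB[i + 1, j - 1])
        span = p.max_loop_span
        for l1 in range(0, min(span, d - 6) + 1):
            for l2 in range(0, min(span - l1, d - 6 - l1) + 1):
                if l1 + l2 < 1:
                    continue
                k, l = i + 1 + l1, j - 1 - l2
                if ins.allowed[k, l]:
                    w = ins.eloop[l1, l2] * ins.ZBau[k, l] * ins.eAU[i, j]
                    if w > 0.0:
                        acts.append(("p", k, l))
                        ws.append(w)
        for k in range(i + 6, j - 4):
            w = ins.ea_closing * ins.eAU[i, j] * ins.ZM[i + 1, k - 1] * ins.ZM1[k, j - 1]
            if w > 0.0:
                acts.append(("ml", k))
                ws.append(w)
        return acts, ws

    def _candidates_M(self, i: int, j: int):
        ins = self.inside
        acts: list[tuple] = []
        ws: list[float] = []
        if j - 4 >= i:
            w = ins.x * ins.ZM[i, j - 1] if j - 1 >= i + 4 else 0.0
            if w > 0.0:
                acts.append(("u",))
                ws.append(w)
        for k in range(i, j - 3):
            wmk = ins.Wm[k, j]
            if wmk == 0.0:
                continue
            acts.append(("be", k))
            ws.append(ins.xpow[k - i] * wmk)
            if k - 1 >= i + 4 and ins.ZM[i, k - 1] > 0.0:
                acts.append(("bm", k))
                ws.append(ins.ZM[i, k - 1] * wmk)
        return acts, ws

    def _candidates_M1(self, i: int, j: int):
        ins = self.inside
        acts, ws = [], []
        for l in range(i + 4, j + 1):
            w = ins.Wm[i, l] * ins.xpow[j - l]
            if w > 0.0:
                acts.append(("b", l))
                ws.append(w)
        return acts, ws

    def _candidates_E(self, j: int):
        ins = self.inside
        acts: list[tuple] = [("u",)]
        ws: list[float] = [ins.Zp[j]]
        for k in range(0, j - 3):
            w = ins.Zp[k] * ins.ZBau[k, j]
            if w > 0.0:
                acts.append(("p", k))
                ws.append(w)
        return acts, ws

    def _draw(self, key: tuple, rng: np.random.Generator) -> tuple:
        entry = self._cache.get(key)
        if entry is None:
            kind = key[0]
            if kind == "B":
                acts, ws = self._candidates_B(key[1], key[2])
            elif kind == "M":
                acts, ws = self._candidates_M(key[1], key[2])
            elif kind == "M1":
                acts, ws = self._candidates_M1(key[1], key[2])
            else:
                acts, ws = self._candidates_E(key[1])
            cum = np.cumsum(ws)
            entry = (cum, acts)
            self._cache[key] = entry
        cum, acts = entry
        u = rng.random() * cum[-1]
        return acts[int(np.searchsorted(cum, u, side="right").clip(0, len(acts) - 1))]

    def sample(self, rng: np.random.Generator) -> SecondaryStructure:
        pairs: list[tuple[int, int]] = []
        stack: list[tuple] = [("E", self.inside.n - 1)]
        while stack:
            node = stack.pop()
            kind = node[0]
            if kind == "E":
                j = node[1]
                if j < 0:
                    continue
                act = self._draw(node, rng)
                if act[0] == "u":
                    stack.append(("E", j - 1))
                else:
                    k = act[1]
                    pairs.append((k, j))
                    stack.append(("E", k - 1))
                    stack.append(("B", k, j))
            elif kind == "B":
                i, j = node[1], node[2]
                act = self._draw(node, rng)
                if act[0] == "p":
                    pairs.append((act[1], act[2]))
                    stack.append(("B", act[1], act[2]))
                elif act[0] == "ml":
                    k = act[1]
                    stack.append(("M", i + 1, k - 1))
                    stack.append(("M1", k, j - 1))
            elif kind == "M":
                i, j = node[1], node[2]
                act = self._draw(node, rng)
                if act[0] == "u":
                    stack.append(("M", i, j - 1))
                else:
                    k = act[1]
                    pairs.append((k, j))
                    stack.append(("B", k, j))
                    if act[0] == "bm":
                        stack.append(("M", i, k - 1))
            else:  # M1
                i, j = node[1], node[2]
                act = self._draw(node, rng)
                pairs.append((i, act[1]))
                stack.append(("B", i, act[1]))
        return SecondaryStructure(pairs)


def sample_structures(
    seq: RnaSequence,
    params: EnergyParameters | None = None,
    n: int = 1000,
    seed: int = 0,
    inside: InsideMatrices | None = None,
) -> StructureEnsemble:
    """Draw ``n`` independent stochastic tracebacks from the Boltzmann
    ensemble. Identical seeds give identical ensembles."""
    if n < 1:
        raise ValueError("sample size must be at least 1")
    params = params or default_parameters()
    if inside is None:
        inside = InsideMatrices(seq, params)
    tracer = _StochasticTraceback(inside)
    rng = np.random.Generator(np.random.PCG64(seed))
    length = len(seq)
    structures = []
    counts = np.zeros((length, length))
    energies = np.empty(n)
    for t in range(n):
        st = tracer.sample(rng)
        structures.append(st)
        for i, j in st.pairs:
            counts[i, j] += 1.0
        energies[t] = structure_energy(seq, st, params, validate=False)
    pair_prob = (counts + counts.T) / n
    return StructureEnsemble(
        seq=seq,
        structures=structures,
        sample_size=n,
        seed=seed,
        pair_prob=pair_prob,
        ss_profile=1.0 - pair_prob.sum(axis=1),
        ensemble_energies=energies,
    )


def ss_profile(source: StructureEnsemble | np.ndarray) -> np.ndarray:
    """Per-position single-strandedness probability.

    Empirical mode (a :class:`StructureEnsemble`): fraction of sampled
    structures in which the position is unpaired. Exact mode (a pair
    probability matrix): 1 - sum_j P(i, j).
    """
    if isinstance(source, StructureEnsemble):
        return source.ss_profile.copy()
    P = np.asarray(source)
    full = P + np.triu(P, 1).T if np.allclose(P, np.triu(P)) else P
    return np.clip(1.0 - full.sum(axis=1), 0.0, 1.0)


@dataclass(frozen=True)
class Centroid:
    structure: SecondaryStructure
    energy: float


def centroid_structure(
    ensemble: StructureEnsemble,
    threshold: float = 0.5,
    params: EnergyParameters | None = None,
) -> Centroid:
    """Structure formed by the pairs with empirical probability > threshold.

    Non-crossing is guaranteed for threshold >= 0.5 (two incompatible pairs
    cannot both occur in a strict majority of the sample); below that the
    result is validated and a crossing set raises :class:`ValidityError`.
    """
    n = len(ensemble.seq)
    iu = np.triu_indices(n, 1)
    keep = ensemble.pair_prob[iu] > threshold
    pairs = list(zip(iu[0][keep], iu[1][keep]))
    structure = SecondaryStructure(pairs)
    structure.validate(ensemble.seq)
    return Centroid(
        structure=structure,
        energy=structure_energy(ensemble.seq, structure, params, validate=False),
    )


def _pair_distance_matrix(structures: list[SecondaryStructure]) -> np.ndarray:
    all_pairs = sorted({p for st in structures for p in st.pairs})
    index = {p: k for k, p in enumerate(all_pairs)}
    M = np.zeros((len(structures), max(len(all_pairs), 1)), dtype=np.float32)
    for r, st in enumerate(structures):
        for p in st.pairs:
            M[r, index[p]] = 1.0
    row = M.sum(axis=1)
    # |A xor B| = |A| + |B| - 2 |A and B|
    D = row[:, None] + row[None, :] - 2.0 * (M @ M.T)
    np.fill_diagonal(D, 0.0)
    return np.maximum(D, 0.0).astype(float)


def cluster_ensemble(
    ensemble: StructureEnsemble,
    max_clusters: int = 5,
    params: EnergyParameters | None = None,
) -> list[tuple[list[int], Centroid]]:
    """Agglomerative clustering of the sample under base-pair distance.

    Distance is the symmetric difference of pair sets; average linkage;
    the cluster count in 2..max_clusters is chosen by largest mean
    silhouette, falling back to a single cluster when the sample is
    structurally homogeneous. Clusters are ordered by size, largest first;
    each comes with the majority-pair centroid of its members.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    structures = ensemble.structures
    if len(structures) < max(2, max_clusters):
        raise ValueError("ensemble smaller than the requested cluster count")
    D = _pair_distance_matrix(structures)
    if D.max() == 0.0:
        labels = np.zeros(len(structures), dtype=int)
    else:
        link = linkage(squareform(D, checks=False), method="average")
        best_labels, best_score = None, -np.inf
        for k in range(2, max_clusters + 1):
            labels_k = fcluster(link, t=k, criterion="maxclust")
            if len(np.unique(labels_k)) < 2:
                continue
            score = _mean_silhouette(D, labels_k)
            if score > best_score + 1e-12:
                best_labels, best_score = labels_k, score
        labels = best_labels if best_labels is not None else np.zeros(len(structures), int)

    clusters: list[tuple[list[int], Centroid]] = []
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        counts: dict[tuple[int, int], int] = {}
        for m in members:
            for p in structures[m].pairs:
                counts[p] = counts.get(p, 0) + 1
        majority = [p for p, c in counts.items() if c > len(members) / 2.0]
        st = SecondaryStructure(majority)
        clusters.append((
            members.tolist(),
            Centroid(st, structure_energy(ensemble.seq, st, params, validate=False)),
        ))
    clusters.sort(key=lambda item: (-len(item[0]), item[0]))
    return clusters


def _mean_silhouette(D: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    uniq = np.unique(labels)
    scores = np.zeros(n)
    for idx in range(n):
        own = labels[idx]
        same = np.flatnonzero((labels == own) & (np.arange(n) != idx))
        a = D[idx, same].mean() if same.size else 0.0
        b = min(
            (D[idx, labels == other].mean() for other in uniq if other != own),
            default=np.inf,
        )
        denom = max(a, b)
        scores[idx] = 0.0 if denom == 0 else (b - a) / denom
    return float(scores.mean())
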