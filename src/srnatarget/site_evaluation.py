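"""Structure-based energetic evaluation of candidate hybridization sites.

For a candidate duplex, sRNA binding is assumed to alter each molecule's
structure only locally: exactly the intramolecular pairs with an endpoint
among the duplex-paired nucleotides are broken, and nothing else moves.
The disruption energy of a molecule is the Boltzmann-sample average of
(original energy) - (locally altered energy); note that with this
before-minus-after convention breaking stabilizing pairs gives a
*non-positive* value, and the subtraction in the total restores it as a
penalty:

    dG_total = dG_initiation + dG_hybrid - (dG_T_disruption + dG_S_disruption)

A site is predicted functional when dG_total < 0 (strict).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .accessibility import (
    DEFAULT_HAIRPIN_FLANKS,
    DEFAULT_SYMMETRIC_FLANK,
    AccessibleRegion,
    extend_region,
    select_seed_regions,
)
from .energy_model import (
    EnergyParameters,
    RnaSequence,
    SecondaryStructure,
    default_parameters,
    structure_energy,
)
from .ensemble import (
    StructureEnsemble,
    centroid_structure,
    sample_structures,
)
from .hybridization import HybridDuplex, hybridize

__all__ = [
    "DG_INITIATION",
    "DisruptionResult",
    "HybridEvaluation",
    "PredictConfig",
    "locally_alter",
    "disruption_energy",
    "total_energy",
    "predict_sites",
    "child_seed",
]

#: Energy cost (kcal/mol) for initiating an interaction between two RNAs.
DG_INITIATION = 4.1


def child_seed(master: int, k: int) -> int:
    """Derive a stage seed from the master seed (stated integer hash)."""
    return (master * 1000003 + k) % (2**31 - 1)


@dataclass(frozen=True)
class DisruptionResult:
    """Ensemble-averaged local-disruption energetics (kcal/mol)."""

    dG_before: float
    dG_after: float
    dG_disruption: float  # dG_before - dG_after, exactly
    n_structures: int
    n_altered: int


@dataclass(frozen=True)
class HybridEvaluation:
    """A candidate site with its four-term energetic decomposition."""

    duplex: HybridDuplex
    target_disruption: DisruptionResult
    srna_disruption: DisruptionResult
    dG_initiation: float
    dG_total: float
    favorable: bool
    seed_region: AccessibleRegion | None = field(default=None, compare=False)

    def to_dict(self, mrna: RnaSequence | None = None) -> dict:
        rec = {
            "srna_interval": list(self.duplex.srna_interval),
            "mrna_interval": list(self.duplex.mrna_interval),
            "dG_hybrid": self.duplex.dG_hybrid,
            "dG_T_disruption": self.target_disruption.dG_disruption,
            "dG_S_disruption": self.srna_disruption.dG_disruption,
            "dG_initiation": self.dG_initiation,
            "dG_total": self.dG_total,
            "favorable": self.favorable,
            "n_pairs": self.duplex.n_pairs,
            "alignment": self.duplex.alignment_text,
        }
        if mrna is not None and mrna.start_codon_offset is not None:
            rec["mrna_interval_codon_relative"] = list(
                self.duplex.mrna_interval_relative(mrna)
            )
        return rec


def locally_alter(
    structure: SecondaryStructure, footprint: Iterable[int]
) -> SecondaryStructure:
    """Remove exactly the intramolecular pairs with >= 1 endpoint in the
    footprint (0-based positions paired in the duplex); all other pairs are
    untouched. Isolated leftover pairs are legitimate."""
    fp = set(footprint)
    return SecondaryStructure(
        p for p in structure.pairs if p[0] not in fp and p[1] not in fp
    )


def disruption_energy(
    ensemble: StructureEnsemble,
    footprint: Iterable[int],
    params: EnergyParameters | None = None,
) -> DisruptionResult:
    """Average energy of the sample before and after local alteration.

    Altered structures are re-scored from scratch with
    :func:`structure_energy` (no incremental updates)."""
    params = params or default_parameters()
    if not ensemble.structures:
        raise ValueError("empty ensemble")
    fp = frozenset(footprint)
    before = ensemble.ensemble_energies
    after = np.array(before, dtype=float)
    n_altered = 0
    cache: dict[frozenset, float] = {}
    for idx, st in enumerate(ensemble.structures):
        if any(p[0] in fp or p[1] in fp for p in st.pairs):
            n_altered += 1
            altered = locally_alter(st, fp)
            key = altered.pairs
            if key not in cache:
                cache[key] = structure_energy(
                    ensemble.seq, altered, params, validate=False
                )
            after[idx] = cache[key]
    dG_before = float(np.mean(before))
    dG_after = float(np.mean(after))
    return DisruptionResult(
        dG_before=dG_before,
        dG_after=dG_after,
        dG_disruption=dG_before - dG_after,
        n_structures=len(ensemble.structures),
        n_altered=n_altered,
    )


def total_energy(
    dG_hybrid: float,
    dG_T_disruption: float,
    dG_S_disruption: float,
    dG_initiation: float = DG_INITIATION,
) -> tuple[float, bool]:
    """Total energy change of hybridization and the favorability verdict."""
    dG_total = dG_initiation + dG_hybrid - (dG_T_disruption + dG_S_disruption)
    return dG_total, dG_total < 0.0


@dataclass
class PredictConfig:
    """Tunable knobs of the end-to-end site-prediction pipeline."""

    n_samples: int = 1000
    ss_threshold: float = 0.5
    min_loop_len: int = 4
    hairpin_flanks: tuple[int, int] = DEFAULT_HAIRPIN_FLANKS
    symmetric_flank: int = DEFAULT_SYMMETRIC_FLANK
    max_loop: int = 15
    n_suboptimal: int = 10
    min_overlap_with_seed: int = 1
    dG_initiation: float = DG_INITIATION
    centroid_threshold: float = 0.5
    max_mrna_len: int = 2000
    params: EnergyParameters | None = None


def predict_sites(
    srna: RnaSequence,
    mrna: RnaSequence,
    master_seed: int,
    config: PredictConfig | None = None,
) -> list[HybridEvaluation]:
    """Full pipeline: ensembles for both molecules, loop-seeded windows on
    the sRNA, hybridization against the mRNA, disruption energetics on both
    molecules, ranking by dG_total ascending.

    The two ensembles draw independent seeds derived from ``master_seed``,
    so the full output is reproducible from one integer.
    """
    config = config or PredictConfig()
    params = config.params or default_parameters()
    if len(mrna) > config.max_mrna_len:
        raise ValueError(
            f"mRNA of length {len(mrna)} exceeds configured maximum "
            f"{config.max_mrna_len}; fold an explicit subregion instead"
        )
    srna_ens = sample_structures(
        srna, params, n=config.n_samples, seed=child_seed(master_seed, 1)
    )
    mrna_ens = sample_structures(
        mrna, params, n=config.n_samples, seed=child_seed(master_seed, 2)
    )
    centroid = centroid_structure(srna_ens, config.centroid_threshold, params)
    seeds = select_seed_regions(
        centroid.structure,
        srna_ens.ss_profile,
        threshold=config.ss_threshold,
        min_len=config.min_loop_len,
    )
    evaluations: list[HybridEvaluation] = []
    seen: set[tuple] = set()
    for rank, seed_region in enumerate(seeds):
        if seed_region.kind == "hairpin_loop" and rank == 0:
            up, down = config.hairpin_flanks
        else:
            up = down = config.symmetric_flank
        window_region = extend_region(seed_region, up, down, len(srna))
        window = srna.seq[window_region.start - 1:window_region.end]
        duplexes = hybridize(
            window,
            mrna,
            params,
            max_loop=config.max_loop,
            n_suboptimal=config.n_suboptimal,
            window_offset=window_region.start - 1,
            seed_region=(seed_region.start, seed_region.end),
            min_overlap_with_seed=config.min_overlap_with_seed,
        )
        for duplex in duplexes:
            if duplex.pairs in seen:
                continue
            seen.add(duplex.pairs)
            mrna_fp = [pj for _, pj in duplex.pairs]
            srna_fp = [pi for pi, _ in duplex.pairs]
            t_dis = disruption_energy(mrna_ens, mrna_fp, params)
            s_dis = disruption_energy(srna_ens, srna_fp, params)
            dG_total, favorable = total_energy(
                duplex.dG_hybrid,
                t_dis.dG_disruption,
                s_dis.dG_disruption,
                config.dG_initiation,
            )
            evaluations.append(HybridEvaluation(
                duplex=duplex,
                target_disruption=t_dis,
                srna_disruption=s_dis,
                dG_initiation=config.dG_initiation,
                dG_total=dG_total,
                favorable=favorable,
                seed_region=seed_region,
            ))
    evaluations.sort(key=lambda ev: (
        round(ev.dG_total, 9),
        ev.duplex.mrna_interval[0],
        ev.duplex.srna_interval[0],
    ))
    return evaluations
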