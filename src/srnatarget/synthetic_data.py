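"""Seeded generators for end-to-end testing without downloads.

Two families:

* Sequence scenarios: an sRNA carrying a designed GC-clamped hairpin whose
  loop is the interaction seed, and an mRNA with the reverse complement of
  that loop planted at a recorded position. The loop is drawn from {G, U}
  so the planted site is {A, C}-only, and all context sequence is drawn
  from {A, C} — A and C cannot pair with each other, which makes the
  unstructured context genuinely unstructured and keeps spurious hybrids
  weak. The occluded variant additionally embeds the site in a stable
  hairpin by appending its reverse complement behind a short spacer.

* Table scenarios: two-condition x two-assay negative-binomial count
  tables with planted repressed (translational or stability-level) and
  activated genes. Fold changes and p-values come from a documented
  moment-based (delta-method Wald) two-sample count test inside the
  generator — a stand-in for an external differential pipeline that exists
  to exercise the caller, not to replicate it. Planted-truth columns are
  emitted alongside so tests never re-derive ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .energy_model import RnaSequence, reverse_complement

__all__ = [
    "SequenceScenario",
    "TableScenario",
    "make_sequence_scenario",
    "make_table_scenario",
]

STEM_5 = "CUCCCUCC"  # pairs GGAGGGAG; strong GC-clamped stem


@dataclass(frozen=True)
class SequenceScenario:
    """A designed sRNA/mRNA pair with a planted complementary site."""

    srna: RnaSequence
    mrna: RnaSequence
    site_start: int  # 1-based inclusive, on the mRNA
    site_end: int
    loop_start: int  # 1-based inclusive, on the sRNA
    loop_end: int
    site_context: str  # "unstructured" or "hairpin-occluded"
    seed: int


def _random_run(rng: np.random.Generator, length: int, a_frac: float = 1.0) -> str:
    """Unpairable context run over {A, C} (A and C never pair with each
    other). The default is a pure A-run, which also cannot pair with the
    {G, U} seed loop's G residues, keeping the context inert against the
    search window; lower ``a_frac`` admixes C to roughen the context."""
    if a_frac >= 1.0:
        return "A" * length
    return "".join(rng.choice(["A", "C"], size=length, p=[a_frac, 1 - a_frac]))


def make_sequence_scenario(
    loop_len: int = 9,
    site_context: str = "unstructured",
    seed: int = 0,
    stem: str = STEM_5,
    tail_len: int = 12,
    mrna_flank_5: int = 40,
    mrna_flank_3: int = 30,
    context_a_frac: float = 1.0,
) -> SequenceScenario:
    """Deterministic scenario for the given seed.

    The sRNA is tail5 + stem + loop + revcomp(stem) + tail3 with the loop
    drawn from {G, U}; the mRNA plants revcomp(loop) between {A, C} flanks
    (unstructured) or inside a designed hairpin (hairpin-occluded).
    """
    if loop_len < 4:
        raise ValueError("loop_len must be at least 4")
    if site_context not in ("unstructured", "hairpin-occluded"):
        raise ValueError(f"unknown site_context {site_context!r}")
    rng = np.random.Generator(np.random.PCG64(seed))
    # U-clamped {G, U} loop: the terminal U's cannot pair the G-rich stem
    # arm, so the designed helix cannot slip registers into the loop and
    # the planted duplex cannot extend into (and then have to break) the stem.
    middle = "".join(rng.choice(["G", "U"], size=loop_len - 2, p=[0.6, 0.4]))
    loop = "U" + middle + "U"
    tail5 = _random_run(rng, tail_len, context_a_frac)
    tail3 = _random_run(rng, tail_len, context_a_frac)
    srna_seq = tail5 + stem + loop + reverse_complement(stem) + tail3
    loop_start = len(tail5) + len(stem) + 1
    loop_end = loop_start + loop_len - 1
    srna = RnaSequence(id=f"synthetic_srna_seed{seed}", seq=srna_seq)

    site = reverse_complement(loop)  # {A, C} only
    flank5 = _random_run(rng, mrna_flank_5, context_a_frac)
    flank3 = _random_run(rng, mrna_flank_3, context_a_frac)
    if site_context == "unstructured":
        mrna_seq = flank5 + site + flank3
        site_start = len(flank5) + 1
    else:
        spacer = "ACAA"  # unpairable hairpin loop
        mrna_seq = flank5 + site + spacer + reverse_complement(site) + flank3
        site_start = len(flank5) + 1
    site_end = site_start + loop_len - 1
    mrna = RnaSequence(id=f"synthetic_mrna_seed{seed}_{site_context}", seq=mrna_seq)
    return SequenceScenario(
        srna=srna,
        mrna=mrna,
        site_start=site_start,
        site_end=site_end,
        loop_start=loop_start,
        loop_end=loop_end,
        site_context=site_context,
        seed=seed,
    )


@dataclass(frozen=True)
class TableScenario:
    """Design of a two-assay differential count table."""

    n_genes: int = 2000
    n_repressed_translational: int = 20
    n_repressed_stability: int = 30
    n_activated: int = 10
    effect_log2: float = 2.0
    nb_dispersion: float = 0.05
    baseline_mean: float = 500.0
    n_replicates: int = 2

    def __post_init__(self) -> None:
        planted = (self.n_repressed_translational + self.n_repressed_stability
                   + self.n_activated)
        if planted > self.n_genes:
            raise ValueError("planted classes exceed the number of genes")
        if self.nb_dispersion <= 0 or self.baseline_mean <= 0:
            raise ValueError("dispersion and baseline mean must be positive")


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, disp: float) -> np.ndarray:
    """Negative-binomial draws with Var = mu + disp * mu^2."""
    r = 1.0 / disp
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _wald_log_ratio(
    mean_minus: np.ndarray,
    mean_plus: np.ndarray,
    disp: float,
    n_rep: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Moment-based two-sample count comparison.

    log2 fold change of condition means (minus / plus, pseudocount 0.5) and
    a delta-method Wald p-value: Var[ln mean] ~ (1/mu + disp) / n_rep per
    condition under the negative-binomial model."""
    lfc = np.log2((mean_minus + 0.5) / (mean_plus + 0.5))
    var = ((1.0 / np.maximum(mean_minus, 0.5) + disp)
           + (1.0 / np.maximum(mean_plus, 0.5) + disp)) / n_rep
    z = np.log((mean_minus + 0.5) / (mean_plus + 0.5)) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return lfc, np.clip(p, 0.0, 1.0)


def make_table_scenario(scenario: TableScenario | None = None, seed: int = 0) -> pd.DataFrame:
    """Generate the gene table with planted-truth columns.

    Per gene and assay, ``n_replicates`` counts are drawn for each of the
    two conditions (sRNA-minus / sRNA-plus) around condition means.
    Translational targets shift only the Ribo-seq mean, stability targets
    shift both assays, activated targets shift the Ribo-seq mean the other
    way. Positive log2 fold change (minus over plus) marks repression.
    """
    sc = scenario or TableScenario()
    rng = np.random.Generator(np.random.PCG64(seed))
    n = sc.n_genes
    base = sc.baseline_mean * np.exp(rng.normal(0.0, 0.5, size=n))

    true_class = np.array(["null"] * n, dtype=object)
    idx = rng.permutation(n)
    a = sc.n_repressed_translational
    b = a + sc.n_repressed_stability
    c = b + sc.n_activated
    true_class[idx[:a]] = "repressed_translational"
    true_class[idx[a:b]] = "repressed_stability"
    true_class[idx[b:c]] = "activated"

    effect = 2.0 ** sc.effect_log2
    # Condition means per assay; repression = lower in the sRNA-plus state.
    rna_minus = base.copy()
    rna_plus = base.copy()
    ribo_minus = base.copy()
    ribo_plus = base.copy()
    stab = true_class == "repressed_stability"
    trans = true_class == "repressed_translational"
    act = true_class == "activated"
    rna_plus[stab] = base[stab] / effect
    ribo_plus[stab] = base[stab] / effect
    ribo_plus[trans] = base[trans] / effect
    ribo_plus[act] = base[act] * effect

    def assay(minus_mean, plus_mean):
        minus = np.stack([
            _nb_counts(rng, minus_mean, sc.nb_dispersion)
            for _ in range(sc.n_replicates)
        ])
        plus = np.stack([
            _nb_counts(rng, plus_mean, sc.nb_dispersion)
            for _ in range(sc.n_replicates)
        ])
        m_minus = minus.mean(axis=0)
        m_plus = plus.mean(axis=0)
        lfc, p = _wald_log_ratio(m_minus, m_plus, sc.nb_dispersion, sc.n_replicates)
        reads = minus.sum(axis=0) + plus.sum(axis=0)
        return lfc, p, reads.astype(int)

    rna_lfc, rna_p, rna_reads = assay(rna_minus, rna_plus)
    ribo_lfc, ribo_p, ribo_reads = assay(ribo_minus, ribo_plus)

    direction = np.where(
        true_class == "null", "none",
        np.where(true_class == "activated", "activated", "repressed"),
    )
    return pd.DataFrame({
        "gene": [f"g{k:05d}" for k in range(n)],
        "rna_log2fc": rna_lfc,
        "rna_p": rna_p,
        "ribo_log2fc": ribo_lfc,
        "ribo_p": ribo_p,
        "rna_reads": rna_reads,
        "ribo_reads": ribo_reads,
        "true_class": true_class,
        "true_direction": direction,
    })
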