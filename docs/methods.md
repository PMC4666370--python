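# Methods

This note documents the models inside `srnatarget`, the choices that were
genuinely open, and what the synthetic benchmarks do and do not show.

## Energy model

Structures are scored by a loop-decomposable nearest-neighbor model at
37 °C (310.15 K, R = 1.9872 cal/mol/K): helix stacks from a 6×6 table over
the pair types {CG, GC, GU, UG, AU, UA}; hairpin, bulge and interior loops
by length-indexed initiation tables; multiloops by an affine term
(closing 9.3, per-branch −0.9, per-unpaired-nucleotide 0.0 kcal/mol); and a
terminal penalty of 0.5 kcal/mol charged for every AU or GU pair side that
is not continued by a stack (helix ends, including isolated pairs, which
the local-alteration step can create and which are therefore priced without
special-casing). Loop tables extrapolate logarithmically beyond 30 nt with
coefficient 1.07856 kcal/mol. The numbers are the published Turner-2004
stacking and loop-initiation free energies, shipped as a plain-text table
(`data/nn_params_37C.txt`, format documented in the header) and loadable
from any file in the same format, so another parameterization can be
swapped in without code changes.

Deliberately omitted: dangling ends, terminal mismatches, coaxial stacking,
sequence-specific small loops (tetraloop bonuses, 1×1 tables), pseudoknots,
and enthalpy/entropy decomposition (no temperature scanning). The omissions
buy exact internal consistency: the intramolecular evaluator, the duplex
evaluator, the partition function and the stochastic sampler all implement
literally the same scoring, which is what makes the enumeration-based tests
meaningful. The cost is that absolute ΔG values differ from full-featured
folding engines by the omitted terms; conclusions here rest on energy
*differences* under one consistent model, and the backend contract (fold
energy, duplex energy, pair probabilities) is the seam where a
full-featured engine could be substituted.

The duplex-only model (used for hybrids) has stacks, bulges and interior
loops with both sides capped at `max_loop` (default 15 nt), terminal AU/GU
penalties at the two duplex ends, and no multiloops. Its `duplex_init`
constant defaults to 0.0 kcal/mol: the bimolecular initiation cost enters
the total-energy assembly once, as the explicit ΔG_initiation = 4.1
kcal/mol term, and a nonzero `duplex_init` would double-count it.

## Partition function, sampling, profiles

`ensemble.InsideMatrices` implements the O(n³)-style inside recursion over
ZB (subsequence closed by a pair), ZM/ZM1 (multiloop segments) and exterior
prefix/suffix sums, with interior loops capped at 30 nt per loop. The
reference state is the open chain (Z ≥ 1, ensemble free energy
−RT ln Z ≤ 0). Exact base-pair probabilities come from the matching
outside recursion; its multiloop-context sum ranges over all enclosing
pairs (quartic), so exact probabilities are intended for short sequences —
on anything desk-scale the empirical sample profile is used instead. On all
sequences short enough to enumerate, Z, the pair probabilities and the
sampled structure frequencies are tested against exhaustive enumeration.

Sampling draws independent stochastic tracebacks. The RNG contract is
integer-seeded numpy PCG64; every branch point draws one uniform variate
against the cumulative weights of its candidates, with candidates ordered
toward smaller indices (ties therefore resolve toward smaller j), and
per-node candidate distributions are cached so a 1000-structure sample
costs little more than its lookups. The default sample size is n = 1000,
the size shown in the literature to reproduce major structural
characteristics; identical seeds reproduce ensembles exactly.

The ensemble centroid keeps pairs with empirical probability strictly
above 0.5 (guaranteed non-crossing). Structural clustering uses the
base-pair symmetric-difference metric with average-linkage agglomeration;
the cluster count in 2..max_clusters is chosen by largest mean silhouette,
collapsing to one cluster for homogeneous samples. Both the overall
centroid and per-cluster centroids are exposed; the pipeline seeds from
the overall ensemble centroid by default, since only the seed loop feeds
downstream.

## Seeding and window extension

Seed regions are hairpin loops of the selected centroid (longest first),
falling back to maximal single-stranded runs of the profile (threshold 0.5,
minimum length 4) when the centroid has no loop of at least the minimum
length. The chosen loop is extended by flanks before hybridization:
(9, 17) nucleotides (upstream, downstream) for the largest centroid
hairpin loop — the extension that maps a loop at positions 37–51 of a
90-nt sRNA onto the 28–68 search window — and symmetric 15-nt flanks for
any other seed. Both are configurable. Multiple seeds each spawn a window;
candidate evaluations are ranked globally afterwards.

## Hybridization

The duplex dynamic program fills E[i, j] = best energy of a hybrid whose
3′-most sRNA pair is (i, j), over strictly monotone antiparallel pairings.
Suboptimals are harvested non-redundantly: candidate end cells are visited
in (energy, mRNA start, sRNA start) order, each is traced back
deterministically (smallest loop sizes first among ties), and a candidate
is kept only if its mRNA interval overlaps every already-kept hybrid by
less than 50% and it pairs at least one nucleotide inside the original
(unextended) seed region. Hybrids with ΔG_hybrid ≥ 0 are never reported.
An optional `min_contiguous_block` post-filter (off by default) can demand
a run of consecutive stacked pairs, reflecting the reported preference for
a ~7-bp contiguous block; it is background knowledge, not part of the core
method. The compensatory-mutation evaluator re-runs the restricted
hybridization for all four wild-type/mutant combinations and calls the
interaction compensatory when both matched combinations clear a
configurable favorability cutoff while both cross combinations do not.

## Disruption and the total energy

The local-alteration assumption: sRNA binding breaks exactly the
intramolecular pairs with at least one endpoint among the duplex-paired
nucleotides — nothing refolds, longer-range structure is untouched, and
bulged duplex nucleotides are not required to be free (only actually paired
positions define the footprint). For each molecule, ΔG_disruption is the
sample average of E(original) − E(locally altered) over its ensemble;
altered structures are re-scored from scratch, never incrementally. With
this before-minus-after sign convention, breaking stabilizing pairs gives a
*negative* disruption value; the subtraction in

    ΔG_total = ΔG_initiation + ΔG_hybrid − (ΔG_T-disruption + ΔG_S-disruption)

turns it back into a penalty. (Stated prominently because the double
negation is an easy place to go wrong; the identity is asserted to 1e−9 on
every emitted record.) ΔG_initiation defaults to 4.1 kcal/mol. Favorable
is the strict inequality ΔG_total < 0; a site at exactly zero is not
called. The sRNA disruption uses the full-sRNA ensemble with the sRNA-side
duplex-paired nucleotides as footprint (not just the extended window);
the mRNA is folded as the record provides it, with a configurable maximum
length and an explicit error beyond it rather than silent windowing.

Pipeline seeding: one master seed; the sRNA and mRNA ensembles use
`child_seed(master, 1)` and `child_seed(master, 2)` with
`child_seed(m, k) = (m·1000003 + k) mod (2³¹ − 1)`. Full pipeline output
is reproducible from the master seed alone.

## Target calling from Ribo-seq/RNA-seq tables

Fold changes follow the sRNA-minus/sRNA-plus orientation (positive log2 =
repressed). Genes with fewer than 200 reads in either assay are excluded
(inclusive at the floor); tables that arrive pre-filtered may omit read
counts. The pass rule is pure fold change: |log2 FC| ≥ 1 in either assay,
inclusive so a printed 1.00 qualifies; statistical significance is *not*
part of the rule, because the shipped reference table contains qualifying
rows that are non-significant in both assays and is reproducible only with
the fold-change-only filter. Direction comes from the sign of the
qualifying assay(s); conflicting signs resolve to the larger-magnitude
assay and are flagged. Mode classification for passing genes, with
Δ = |ribo log2FC − rna log2FC|: translational if Δ ≥ 0.5 and the RNA-seq
change is not significant (p ≥ 0.05); stability if Δ < 0.5 and the RNA-seq
change is significant; mixed otherwise. The 0.5/0.05 defaults are artifact
choices that reproduce the reference exemplars (fepB and yegD
translational, dhaK stability) and are configurable and echoed in output
metadata. Differential statistics themselves (alignment, assembly,
count testing) are upstream tools' business; this module consumes their
table.

## Synthetic data

Sequence scenarios build an sRNA as tail + GC-clamped stem (default
`CUCCCUCC` / complement) + loop + tail, with the loop drawn from {G, U}
and clamped by U at both ends, and an mRNA with the loop's reverse
complement planted between context runs. Context runs are pure A by
default: A pairs neither itself, nor C, nor the loop's G residues, so the
unstructured context is genuinely unstructured, the planted site is fully
accessible, and the designed helix can neither slip registers into the
loop nor let the planted duplex extend into the stem. The
hairpin-occluded variant appends the site's reverse complement behind a
4-nt spacer, verified by folding to leave the site mostly paired. What
this emulates is the loop-seeded interaction geometry and the
accessibility/occlusion contrast; what it does not emulate is the
compositional heterogeneity, partial structure and suboptimal-site
landscape of real 5′ UTRs — passing recovery tests shows the machinery is
correct and the ranking behaves as designed, not that real-genome accuracy
matches.

Table scenarios draw, per gene and assay, two replicate negative-binomial
counts per condition (Var = μ + φμ², default dispersion φ = 0.05, baseline
mean 500 reads with log-normal gene-to-gene spread) for 2000 genes by
default, with planted classes: repressed-translational (shift the Ribo-seq
condition mean only; default 20 genes), repressed-stability (shift both;
30), activated (shift Ribo-seq the other way; 10), at |log2| effect 2.0 —
roughly the repressed-heavy mix and effect scale of a strongly acting
sRNA. The generator's log2 fold changes and p-values come from a
moment-based delta-method Wald test on the condition means (documented
stand-in for an external differential pipeline; it exists to exercise the
classifier, not to replicate any particular tool). Planted-truth columns
ride along in the output so tests never re-derive ground truth.

## Problem sizes and numerics

Defaults used by the test suite and the acceptance script: scenario sRNAs
of 49 nt and mRNAs of 79–92 nt with 1000-structure ensembles; 100 scenario
seeds for recovery; enumeration cross-checks on sequences ≤ 20 nt; table
calibration on 2000-gene tables (20000 genes for the Monte-Carlo null
reference). Energies are float64 throughout; equal-energy alternatives are
broken deterministically (documented orderings above), and reported
energies are compared at 1e−9 where exactness is claimed. Degenerate
inputs: unpairable sequences yield Z = 1, empty ensembles are an error,
an empty hybrid list is a valid "no favorable site" result, and
length-changing mutations are rejected by the compensatory evaluator.

## Known limitations

No dangling-end or mismatch thermodynamics (absolute ΔG offsets vs
full-featured engines); no joint folding-and-binding partition function
(the duplex and the disruption terms are decoupled, per the
local-alteration assumption); no Hfq terms or sequence/conservation
features; exact pair probabilities are impractical beyond short sequences;
desk-scale inputs only (no genome-wide scanning engineering).
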