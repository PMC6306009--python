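# Methods

This note documents the models and conventions behind `cutinseq`: what is
computed, under which assumptions, with which defaults, and where the
limits are.

## Monomer and oligomer model

A cutin monomer is described by chain length *n*, double-bond count *d*,
hydroxyl positions, epoxy spans and carboxyl positions, with carbons
numbered 1-based from the carboxyl carbon (ω ≡ *n*).  The neutral formula
follows deterministically:

    acids:    C_n H_(2n − 2d − 2·n_epoxy − 2·(n_carboxyl − 1)) O_(2·n_carboxyl + n_OH + n_epoxy)
    alcohols: C_n H_(2n + 2 − 2d − 2·n_epoxy) O_(n_OH + n_epoxy)

Epoxides are +O −2H across adjacent carbons.  Double-bond *positions*,
epoxide stereochemistry and cis/trans geometry are not represented: they do
not change the exact mass, and single-stage collision-induced dissociation
cannot resolve them.

An oligomer is an ordered monomer sequence; index 1 carries the free
carboxyl, and monomer *i+1* esterifies a hydroxyl of monomer *i* (default:
the ω-hydroxyl).  Its formula is the monomer sum minus one water per ester
bond.  A mid-chain linkage site changes only the free-hydroxyl count, never
a fragment mass — which is precisely why MS alone cannot assign linkage
regiochemistry; results record sites, not evidence for them.

All arithmetic is performed on neutral formulas; ions are formed at the end
through an adduct specification ([M−H]⁻, [M+H]⁺, [M+Li]⁺, [M+2Li−H]⁺).
Summing deprotonated m/z values directly would double-count the lost
proton; the neutral convention reproduces printed oligomer ion values
exactly.  The atomic-mass table is frozen in source at ≥ 8 significant
digits; isotope envelopes and |z| > 1 are out of scope, and the electron
mass (~0.0005 Da) is below working precision and not corrected for.

Negative mode is the default throughout because detected cutin oligomers
carry at least one free carboxyl; adduct ions are ignored in negative mode
and spectra are assumed singly charged.

## Tolerances and printed-value comparison

Theoretical and observed m/z agree if within **10 ppm or 0.02 Da**
(whichever is looser): printed Q-TOF values drift up to ~0.02 Da from
theory.  Comparisons against printed two-decimal values use
round-half-away-from-zero, matching instrument-software display.
Chain-cleavage candidates (below) use a looser 0.03 Da window.

## Fragment prediction

Ester cleavage is modeled as **hydrolysis-form fragments**: each broken
bond yields the full acid on one side and the restored alcohol on the
other, and every contiguous terminal subsequence (plus all single
monomers) is emitted with 0..2 additional serial water losses, capped by
the fragment's free-hydroxyl count.  This one rule reproduces the observed
dimer/trimer daughters of cutin oligomers without explicit acid/ketene
channel modeling.

Internal fragments (two cleavages) are **opt-in**, not default.  Two
reasons: observed daughter ions of cutin di- to tetramers are fully
explained by terminal (single-cleavage) fragments, and internal fragments
create systematic mass coincidences — e.g. an internal epoxy–epoxy dimer
minus water is isobaric with a terminal epoxy–hydroxy dimer — that degrade
ordering discrimination without adding explanatory power.  Enabling them
(`include_internal=True`) is appropriate when analyzing longer oligomers
on instruments that do show secondary fragmentation.

Chain (C–C) cleavage ions, used to localize mid-chain oxygens, are
generated as **candidates, not assertions**: for each bond adjacent to (or
inside the span of) a mid-chain oxygen-bearing carbon, both cleavage-side
formulas are emitted with hydrogen-transfer offsets of −1/0/+1 H, optional
water loss, split-epoxide oxygen on either side (as hydroxyl or carbonyl),
and every feasible double-bond partition.  The reported epoxy-diagnostic
ions fall within 0.03 Da of this candidate set; no claim is made about
which candidate formula is the true assignment.

## Sequencing

1. **Decomposition.**  The precursor's neutral mass is decomposed into
   monomer multisets (each ester bond costs one water) by a depth-first
   search over mass-sorted monomers, pruned only by an additive bound, so
   the enumeration is complete within tolerance (verified against
   exhaustive enumeration).  Default length bounds come from the precursor
   m/z: an L-mer is expected within L × (164–331), the observed monomer
   window; the hard cap is length 6 (≤ 720 orderings per composition).
   Isobaric compositions are flagged, never merged.  Fatty alcohols are
   excluded unless requested — they cannot carry the free carboxyl that
   negative-mode detection requires.

2. **Scoring.**  Every distinct ordering of each composition (multiset
   permutations; orderings whose non-terminal monomers lack a hydroxyl are
   structurally impossible and skipped) is scored as the **number of
   predicted daughters matched** by at least one observed peak.  Intensity
   is recorded but unused: the underlying deduction argues from the
   presence of daughter ions, not their heights.  Noise peaks simply
   remain unmatched; no denoising is applied (centroided input assumed).

3. **Ranking and ambiguity.**  Candidates are ranked by score; equal
   scores share a competition rank and set the `ambiguous` flag with the
   tied orderings listed.  Presentation order within a tie is
   deterministic — fewest invoked water losses, then lexicographic
   symbolic form — but is *presentation only*, not evidence.  This matters
   because ester-only fragmentation is direction-blind: a sequence and its
   reversal predict identical fragment masses (a fragment's free-hydroxyl
   count is order-invariant), so the free-carboxyl terminus cannot be
   assigned from one MS/MS spectrum alone.  End-labeling chemistry (DmPA
   on free carboxyls, dansyl/benzyl on free hydroxyls) is the orthogonal
   experiment that breaks this symmetry.

4. **Trimer central-monomer evidence.**  When the top candidate is a
   trimer and both of its dimer daughters are matched, the monomer common
   to both is reported as central, with the two matched peaks cited —
   mirroring the shared-daughter argument used to place a dihydroxy acid
   mid-chain.

5. **Overlap assembly.**  Sequenced fragments sharing a terminal monomer
   run (suffix of one = prefix of another, k ≥ `min_overlap`) merge into
   supersequence candidates ranked by overlap length; longer overlaps give
   higher confidence that two fragments adjoin in the intact polymer.

## Labeling statistics

A monomer recovered *with* a hydroxyl/carboxyl tag had that group free in
the intact polymer; recovered *without*, the group was esterified.  Per
monomer, replicate abundances in each pool are averaged and summarized as
log2(free/esterified) with the delta-method standard error

    se_log2 = (1/ln 2) · sqrt((se_fr/fr)² + (se_es/es)²),

which is exact to first order and scale-invariant; at coefficients of
variation ≤ 10% it tracks a Monte-Carlo SD within a few percent (checked
at 10⁵ draws).  Tag mass shifts are reagent-minus-leaving-group: dansyl
+C12H11NO2S (233.0510 Da), benzyl ether +C7H6 (90.0470 Da), DmPA
+C10H11NO (161.0841 Da).  A benzyl shift is identical whichever hydroxyl
carries it; site localization needs fragment-level GC-MS evidence and is
recorded as annotation only.  Multi-site tagging is supported but
per-site-count species are reported separately (singly-tagged species
dominate in practice).  Internal-standard quantification is linear in peak
area against a spiked standard, default 10 µg heptadecanoic acid.

## Simulator

The simulator exists to give every other module a ground truth.

- **Polymer**: a tree of ester bonds grown monomer by monomer from
  hydroxyl-bearing acids.  Abundance weights follow the qualitative
  ranking of apple-cutin monomers — the six majors
  (9,10,18-trihydroxy-18:0/1/2/3, 10,16-dihydroxy-16:0, 18-hydroxy-18:2)
  carry ~80% of the draw weight (20/18/12/11/10/9), the remainder split
  evenly — because only the ranking, not the percentages, is established;
  exact weights are configuration.  16-hydroxy-16:0 and 18-hydroxy-18:2
  are up-weighted (default ×5) at the ω terminus, 16-hydroxy-16:0 and
  18-hydroxy-18:3 at the carboxyl terminus, reflecting the end-labeling
  findings.  Branching through secondary hydroxyls is available
  (`branching_prob`); branched subtrees are linearized along the longest
  carboxyl-to-ω path with a warning, since the sequencer only handles
  linear candidates.
- **Digestion**: each ester bond cleaves independently with probability
  `p_cleave` (hydrolysis form), so fragment count = cleaved edges + 1 and
  the monomer multiset is conserved.  The independent-cleavage assumption
  is explicit: no enzyme kinetics, site preference or time course is
  modeled.
- **Spectra**: predicted daughters perturbed by unbiased Gaussian ppm
  error (default σ = 5 ppm), unit true intensities, plus uniform noise
  peaks in the m/z 100–1700 scan window with intensity uniform in (0,
  median true intensity).  The precursor is set exactly.

All randomness flows from one explicit integer seed; identical seeds give
byte-identical digests, spectra and reports.

What passing simulator-based tests shows — and does not.  They validate
the deductive machinery: composition recovery, ordering discrimination
under mass error and noise, direction ambiguity handling.  They do not
validate intensity effects, co-eluting isomers, in-source fragmentation,
adduct clusters, or real instrument calibration drift; on real data the
practical accuracy bound is usually the isobar structure of the catalog,
not the ppm error.

## Numerical and formatting conventions

- Monoisotopic masses: H 1.00782503, C 12 (exact), N 14.00307401,
  O 15.99491462, S 31.97207100, Li 7.01600455, Na 22.98976928.
- m/z printed at 4 decimals in reports, 2 decimals in printed-value
  comparison columns; round-half-away-from-zero.
- Theoretical peak lists deduplicate by (m/z rounded to 4 decimals,
  ordered species) and sort by m/z; all result orderings are total, so
  reports are byte-reproducible.
- Degenerate inputs: empty spectra score 0; a precursor with no
  composition returns an empty result with a diagnostic, not an
  exception; a monomer without mid-chain oxygens has no chain-cleavage
  candidates; subtraction below zero atoms is a domain error naming the
  element.

## Problem sizes used in the bundled checks

Decomposition completeness is verified against exhaustive enumeration on
500 random precursors (catalog of 25 acids, lengths ≤ 4); round-trip
recovery uses 200 simulated distinct-monomer trimers at 5 ppm error and 5
noise peaks (observed recovery ≈ 94–97%, counting the true ordering at the
shared top rank); the delta-method comparison uses 10⁵ Gaussian draws.
These sizes make the checks statistically meaningful while keeping the
whole suite around half a minute on one core.

## Known limitations

- **Direction ambiguity** (see above): reversal ties are inherent to
  ester-only fragmentation and are reported, never silently broken.
- **Isobars**: 2-hydroxy vs ω-hydroxy acids, epoxy-18:*k* vs
  dihydroxy-18:*k+1*, and diacid vs dihydroxy-monoene pairs are
  mass-identical; candidates are flagged, and resolving them needs
  chain-cleavage diagnostics or chromatography.
- Cyclic or cross-linked (non-tree) topologies, intensity prediction,
  collision-energy modeling, spectral libraries and retention time are
  out of scope.
- Printed instrument values can drift beyond 0.02 Da at high mass; such
  values are excluded from exact comparisons rather than absorbed by
  loosening tolerances.
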