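# Methods

## Scope and model structure

`octadkit` models the sexual and vegetative genetics of chromosome
translocation heterozygotes in *Neurospora crassa* and *N. tetrasperma* at
the level of whole chromosome variants, not base pairs.  Each rearrangement
(`RearrangementSpec`) names a donor and recipient chromosome, one
translocated segment (two for an RT), the breakpoint junction classes of
its kind (IT: A, B, C; QT/RT: A, B) and default interstitial crossover
probabilities.  A haploid nucleus (`NucleusState`) holds, per
rearrangement, one donor-type and one recipient-type `ChromosomeVariant`;
the segmental genotype (T, N, Dp, Df; per-segment composites such as
Dp1/Df2 for an RT) follows deterministically from segment copy number —
2 → Dp, 0 → Df, 1 → T or N according to whether the variants are the
translocated forms.  Junction content follows the same bookkeeping: an IT
T nucleus carries {A, B, C}, Dp {B, C}, Df {A}, N none, so the junction
union of a [T + N] pair equals that of a [Dp + Df] pair — the ambiguity
the inference module exists to resolve.

Sequence-level work (RIP) lives in its own module; the core model never
manipulates nucleotides.

## Meiosis

The octet simulator is chromatid-resolved.  Each homolog contributes two
sister chromatids; with probability `c_donor` (`c_recipient`) exactly one
interstitial crossover swaps the breakpoint-distal content between one
chromatid of each donor (recipient) homolog.  One crossover per region per
meiosis suffices to generate the 6:2 and 2:6 ascus classes; multiple
crossovers are deliberately not modeled by default.  Meiosis I assigns
centromeres: when both homolog pairs of a rearrangement are T/N
heterozygous they form a quadrivalent that disjoins alternately with
probability `p_alt` (default 0.5 — both patterns equally likely; set 1.0
or 0.0 to force a pattern), otherwise each bivalent disjoins
independently at random.  Meiosis II separates sisters with random
donor/recipient chromatid assortment into the two pole nuclei, and the
postmeiotic mitosis duplicates each product into adjacent octet positions
(sister pairs (1,2), (3,4), (5,6), (7,8); positions 1–4 from pole 1).

The mating-type locus always shows first-division segregation — the
*N. tetrasperma mat* chromosome carries a recombination block and *mat* is
tightly centromere-linked — so every octet has exactly four *mat A* and
four *mat a* nuclei and each pole is mating-type-uniform.  Unlinked
markers segregate at MI independently per locus.

The simulator is validated against an independent brute-force oracle that
enumerates all chromatid assortments (crossover chromatid choices × MII
pairings) for every segregation × crossover configuration; the simulated
octet compositions must coincide exactly with the enumerated set.

## Ascospore packaging and scoring

*crassa* mode packages the octet in order into eight uninucleate spores.
*tetrasperma* mode pairs the j-th nucleus of the pole-1 lineage with the
j-th of pole-2 — nonsister by construction, hence one *mat A* + one
*mat a* per spore; a randomised cross-pole pairing option preserves that
guarantee.  Each dikaryotic spore is independently replaced with
probability `replacement_prob` by two homokaryotic spores (the
Eight-spore *E* mutant is modeled purely as an elevated replacement
probability, default 0.15, with incomplete penetrance; no measured rate
exists, so this value is an arbitrary documented choice).  With
probability `anomaly_prob` per ascus one spore receives a third nucleus
from an adjacent dikaryotic spore.  Nuclei are conserved: every ascus
holds exactly eight.

Spore viability defaults to the **union-coverage rule**: a spore is
viable iff its nuclei jointly cover every translocated segment, so a
binucleate [Dp + Df] spore is viable.  An **autonomous rule** (every
nucleus individually complete) is also provided: under it the
[Dp1/Df2 + Dp2/Df1] products of an RT-like *N. tetrasperma* cross are
inviable, matching the observed all-white asci of one such cross; whether
that phenotype reflects spore-autonomous inviability or a segregation
mutation is unresolved, so both rules are exposed and neither is asserted
as the biology.

Asci are scored black:white; eight-spored asci are classed
"8:0" … "0:8", smaller (binucleate-packaged) asci by spore count, matching
the conventional tally-table layout.

## Heterokaryon dynamics and conidiation

Nuclear ratios evolve deterministically by relative division fitness,
ρᵢ′ = ρᵢfᵢ / Σⱼρⱼfⱼ per mitotic generation.  Conidia draw k nuclei
(zero-truncated Poisson, rate 2.5 by default — the nuclei-per-conidium
distribution is not measured anywhere we know of, making this the main
free parameter controlling homokaryotic-conidium frequency; a fixed-k
option supports the closed-form check P(homokaryotic) = ρᵏ + (1−ρ)ᵏ)
multinomially from the fitness-weighted proportions.  A derivative is
self-fertile iff both mating types occur among its division-competent
(fitness > 0) nuclei; conidia whose nuclei do not jointly cover all
segments (bare Df) are inviable and never become derivatives.

The "nucleus-limited" [Dp + Df] phenotype — only self-sterile homokaryons
of the Dp mating type — is encoded solely as `division_fitness = 0` on
the Df component.  The two published candidate mechanisms (disrupted
co-evolved internuclear interaction vs deletion of a nucleus-limited
division gene) are observationally equivalent at this level, and the
module makes no mechanistic claim; likewise failure-to-divide vs
never-packaged is implemented as the single fitness knob.

A self-cross draws one division-competent nucleus of each mating type for
karyogamy.  A component is RIP-exposed iff some segment has copy number 2
in it (Dp nuclei only): RIP can occur in self-crosses of [Dp + Df], never
[T + N].  The fertility rule models MSUD: a cross is barren iff some
segment's **total copy number over the two zygote haplotypes is odd**
(an odd count leaves one copy unpairable; even counts pair, via the
quadrivalent where necessary) and `msud_strength` is at or above the
0.5 threshold.  This parity form — rather than "copy number differs
between haplotypes" — is required for a [Dp + Df] self-cross zygote
(2 + 0 copies) to be fertile, as it must be: its chromosome complement is
identical to a T × N zygote, and such self-crosses demonstrably produce
progeny.  Suppressor backgrounds (Sad, Esm) are scalar strength
reductions.

## Genotype inference

`infer_heterokaryon_genotype` is a flagged rule cascade, not a Bayesian
posterior — the published calls are reproducible by rules, and the flags
carry the residual uncertainty.  Junction patterns are interpreted
relative to the rearrangement's *assayable* junction set (for some
rearrangements not every junction has a working primer): full set → T,
full minus A → Dp, empty → N, {A} alone → a heterokaryotic [N + Df]
derivative (a bare-A homokaryon would be an inviable Df), which evidences
a Df nucleus and can produce triple-heterokaryon calls such as
[T a + N A + Df A].  A Df nucleus is also inferred whenever the
heterokaryon amplifies junction A but no T-pattern derivative does; it
receives the mating type its [N + Df] evidence carries, else the type
absent among derivatives.

Skewed segregation is quantified by `balanced_split_probability`, the
two-sided exact binomial tail of the observed mating-type split under
p = 0.5 (scipy's `binomtest`; defined as 1.0 with no data).  When all
self-sterile derivatives fall in a single class the call attaches a
"… not excluded" caveat if the count is below `n_min` (default 10) or the
split probability is at least `alpha` (default 0.05): a six-derivative
single-class result is thereby inconclusive while ten or more make the
call, matching the published treatment of the corresponding strains.  A
single derivative supports no partner call at all and yields
"[? a + T A]"-style output.  Without any derivative PCR the classifier
falls back to the mating-type split and marks the call "mat-only
evidence".

`summarize_observation_table` aggregates strain-level summary tables with
exact integer totals and consistency checks; the packaged
`data/table2.tsv` transcribes the published 47-strain table (counts,
genotype calls, footnote letters).  Per-derivative junction patterns for
the four reference strains are reconstructed in the test fixtures from
the published footnotes and genotype columns.

## RIP

`rip_mutate` applies one round of RIP to a two-copy duplication: each
copy takes a strand polarity (opposite by default), and every C (top
strand) or G (equivalently, C on the bottom strand) in the duplicated
window mutates independently with probability `rate`; flanks are
untouched.  Dinucleotide context preference is off by default and
available as weights, since no context data constrain it here.
`classify_substitutions` turns every differing aligned column into an
event (G>A, C>T, other-transition, transversion; A>G/T>C transitions are
non-RIP-direction and excluded from `rip_fraction`), splits events by BED
exon intervals (0-based half-open, ancestral coordinates), and derives
the polarity call.  Codon effects are reported one string per affected
codon, translated from the fully derived sequence ("H22Y", "Q122*",
"N97N"; residues 1-based on the CDS); because two events can hit one
codon, the report carries both the exonic event count and the
affected-codon count.  Input pairs are assumed co-linear and pre-aligned;
a convenience global aligner is included but exact counts are only
guaranteed on aligned input.

## Synthetic data and what it does not show

The fixture generator emulates the study's observables: toy genomes in
which junction PCR is substring detection of unique embedded motifs
(sufficient for presence/absence logic; no primer thermodynamics),
observation tables sampled from heterokaryons of known genotype, ascus
tallies, and RIP'd allele pairs, all byte-reproducible from a seed with a
ground-truth manifest.  Passing the closed-loop tests shows the inference
rules are consistent with the generative model under its assumptions —
independent multinomial nucleus sampling, no vegetative ratio drift
unless configured, complete junction PCR — not that real conidial
sampling is unbiased or real PCR is error-free.  Wet-lab ascus-type
percentages depend on unknown nuisance parameters (crossover rates,
background mutations) and are reproduced qualitatively (class
presence/absence), not numerically.

## Numerical and design choices

* All stochastic calls thread a single `numpy.random.Generator`; tallies
  record their seed, and fixture regeneration is byte-identical.
* Test problem sizes (2000 asci for frequency checks, 150 conidia per
  round-trip strain, 100–120 octets per enumeration configuration) keep
  Monte-Carlo error a few standard errors below the tested tolerances
  while the whole suite runs in seconds.
* Tolerances on stochastic checks are 3–4 binomial standard errors at the
  simulated sample size.
* The possibly-complex IBj5 rearrangement is shipped as a plain IT preset
  (its junction C primer is unavailable, so `assayable_junctions` =
  {A, B}); a linked-RT configuration can be user-defined but is not the
  default.  Rearrangement sizes and gene counts are metadata only.
* Degenerate inputs fail loudly: same-mating-type crosses, empty spores,
  all-zero fitness, derivative junction sets exceeding the heterokaryon's,
  unaligned sequence pairs and non-triplet CDSs all raise typed errors.

## Known limitations

No spindle geometry or ascus developmental timing; no het/tol
incompatibility, no hyphal spatial structure, no transcriptome-level
mating-type bias; at most one crossover per interstitial region; RIP has
no homology-search model and no genome-scale index scan; the classifier
handles one rearrangement at a time.
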