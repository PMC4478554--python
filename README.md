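# octadkit

Simulation and inference tools for the translocation genetics of
pseudohomothallic *Neurospora* — for fungal geneticists who work with
chromosome rearrangement strains, duplication/deficiency heterokaryons, or
RIP-mutagenised alleles, and for anyone who wants a tested forward model of
ordered-octad segregation.

## The biology in brief

A chromosome translocation moves a segment from a **donor** to a
**recipient** chromosome.  An insertional translocation (*IT*) is defined
by three breakpoint junctions (A at the donor deletion, B and C flanking
the insertion); quasiterminal (*QT*) and reciprocal (*RT*) translocations
by two (A, B).  In a *T* × *N* cross the meiosis-I quadrivalent disjoins
either by **alternate** segregation (both translocated centromeres to one
pole → 4 *T* + 4 *N* parental products) or by **adjacent-1** segregation
(→ 4 *Dp* + 4 *Df* products, the *Df* spores inviable).  Both patterns are
equally likely, so an *IT* × *N* cross shows 8B:0W ≈ 4B:4W asci
(black = viable, white = inviable); an *RT* × *N* cross shows
8B:0W ≈ 0B:8W, because adjacent-1 products of an RT all carry an
uncomplemented deficiency.  Interstitial crossovers between centromere and
breakpoint add 6:2 (and rarer) classes.

*N. crassa* packages the eight post-meiotic nuclei into eight uninucleate
ascospores.  *N. tetrasperma* packages four **binucleate** spores, each
with a nonsister *mat A* + *mat a* pair, so one ascospore founds a
self-fertile heterokaryotic mycelium (pseudohomothallism).  A spore that
receives complementary *Dp* and *Df* nuclei is viable: the resulting
[*Dp* + *Df*] heterokaryon carries the same chromosome complement as a
*T* × *N* zygote, and self-crosses of [*T* + *N*] and [*Dp* + *Df*]
strains interconvert the two genotypes.

Junction PCR cannot tell the two apart — the pooled junction set of
[*T* + *N*] equals that of [*Dp* + *Df*] — but their conidia can:
[*T* + *N*] strains yield viable homokaryotic conidial derivatives of both
mating types, [*Dp* + *Df*] strains only of the *Dp* nucleus' mating type.
`octadkit` implements this discrimination procedure as an explicit rule
cascade with an exact-binomial skewed-segregation statistic, plus the
supporting simulators: meiosis and ascus packaging, heterokaryon
nuclear-ratio dynamics and conidiation (including a division-incompetent
"nucleus-limited" *Df*), MSUD fertility rules, and RIP (repeat-induced
point mutation: G:C→A:T transitions on duplicated DNA, with opposite
strand polarity in the two duplicate copies).

## Worked example

```python
import numpy as np
from octadkit import (get_preset, nucleus, CrossParams, simulate_cross_tally,
                      infer_heterokaryon_genotype)

eb4 = get_preset("EB4")                      # IT(VR -> VII), junctions A,B,C
T, N = nucleus(eb4, "T", "A"), nucleus(eb4, "N", "a")
tally = simulate_cross_tally(T, N, [eb4], n_asci=2000,
                             params=CrossParams(rng_seed=1))
print(tally.to_string(index=False))
```

```
class  count  percent
  8:0    994     49.7
  6:2      0      0.0
  4:4   1006     50.3
  2:6      0      0.0
  0:8      0      0.0
```

The two segregation patterns are equally likely, so 8:0 and 4:4 asci occur
at statistically equal frequencies (994 vs 1006 of 2000 here) and the
expected black-spore fraction is 0.75; setting `c_donor > 0` populates the
6:2 class.  The same machinery drives genotype inference:

```python
from octadkit import ObservationRecord, DerivativeObs
obs = ObservationRecord("1E1", {"A", "B", "C"},
                        [DerivativeObs(False, "A", frozenset({"B", "C"}))] * 25)
call = infer_heterokaryon_genotype(obs, eb4)
print(call.label, call.flags)
```

```
[Df a + Dp A] []
```

Twenty-five self-sterile derivatives, all *mat A* with the B,C junction
pattern and none *mat a*, identify the strain as a [*Df a* + *Dp A*]
heterokaryon with no caveat; with only 6 single-class derivatives the call
would carry an explicit `"[T a + N A] not excluded"` flag.

The same operations are exposed on the command line:
`octadkit {simulate-cross, simulate-conidia, infer-genotype, rip-scan,
rip-sim, make-fixtures}`.

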