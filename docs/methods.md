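# Methods

## Model

We track a single autosomal biallelic locus in an infinite population with
discrete, non-overlapping generations. Each allele may carry a
parental-effect toxin–antidote element: the toxin is loaded by a parent that
carries the allele, and any zygote that inherits at least one copy of that
allele is rescued by the zygotically expressed antidote. Allele M₁'s toxin
kills unprotected zygotes with penetrance k₁ ∈ [0, 1], allele M₂'s with
k₂. Each element is delivered either maternally (*Medea*: the egg parent's
genotype decides whether the brood is poisoned) or paternally (*peel*: the
sperm parent's), or is inert (`none`, treated as k = 0). When both toxins hit
the same zygote class the survival factors multiply (independent action);
heterozygous zygotes always survive, since they carry both antidotes.

All dynamics are generated from a single enumeration: the 3 selfing × 9
outcross mating types, Mendelian segregation (genotypes encoded as M₁-allele
counts, never strings), and the survival tensor above. The closed-form
recursions are separate implementations tested against this enumeration to
1e-12 across random states and parameters, and every analytic equilibrium or
threshold is additionally confirmed dynamically (bisection on the recursion,
fixed-point iteration, or grid classification).

### Monoecy

Hermaphrodites self with fixed probability S and mate at random with
probability 1 − S; both selfed and outcross broods are the same size.
Under monoecy the egg and sperm parent of a selfed brood coincide and the
outcross sperm pool equals the egg pool, so maternal and paternal delivery
give identical recursions — a property asserted in the tests rather than
assumed in the code. Because only heterozygous parents expose toxins,
p = 0 and p = 1 are always equilibria and a heterozygote-free population
under complete selfing is frozen.

The internal equilibrium p̂ solves
(1−S)(1−r) p² + [S(1+r)/2 + (r−1)(1−S)] p − S/2 = 0 with r = k₁/k₂; the
root in (0, 1) is taken with the numerically stable quadratic form (the
naive formula loses ~7 digits near S = 1). Degenerate cases are handled as
analytic limits rather than float division: r = 1 → 0.5, S = 1 → 1/(1+r),
S = 0 with r ≠ 1 → no internal equilibrium. Note the S → 1 limit of the
threshold is 1/(1+r), not 1: a resident "holds its position" in the sense
that realistic migrant frequencies sit far below the threshold, which rises
monotonically in S toward that limit.

Equilibrium heterozygosity at held p is the stable root of the quadratic
fixed-point condition of the Y-recursion; it is cross-validated by damped
fixed-point iteration (damping 0.5, tolerance 1e-10, cap 10⁶ iterations —
convergence in practice takes tens of iterations). The per-generation
frequency change Δp is defined operationally as p′ − p from the recursion;
only its sign structure carries scientific weight.

### Androdioecy

The *Caenorhabditis* mating system: hermaphrodites (XX) self (probability S)
or mate with males (X0); selfed broods are all-hermaphrodite, outcross broods
half male / half hermaphrodite. The parameter b is the ratio of
hermaphrodite offspring in an outcross brood to a selfed brood; since each
outcross brood is half-and-half, b scales the male share equally. b = 1/2 is
the two-fold cost of males (fixed brood size), b = 1 means outcrossing
doubles the brood; plausible values span roughly 1/2–2. Males produced by X
nondisjunction in selfers are ignored.

The step extends the same enumeration with sex labels: hermaphrodite pool =
S·(selfed survivors) + (1−S)·b·(outcross survivors); male pool = the
outcross term only, with sperm-parent genotypes drawn from the male genotype
distribution. Maternal toxins key to the hermaphrodite in both brood types;
paternal toxins key to the male in outcrosses and to the hermaphrodite
itself in selfs. The male:hermaphrodite census ratio is updated each
generation from the relative surviving weights of the two pools (it is not
fixed by S once killing is asymmetric); the population allele frequency is
the census-weighted average (weights 1 and m_ratio). Initial states default
to the no-killing equilibrium ratio (1−S)b / (S + (1−S)b). In addition to
the S ∈ {0, 1} reductions to monoecy (checked per-generation to 1e-12), the
step was validated against an independently hand-derived closed form for the
Medea/Medea case at machine precision, and reproduces the structural facts
that male heterozygosity is irrelevant to Medea-only allele dynamics but
essential for *peel* configurations.

### Numerical invasion thresholds

Thresholds are estimated exactly the way the dynamics define them: start
pure-homozygote populations (identical in both sexes — the migration
scenario) at every frequency on a grid, iterate a fixed horizon, and classify
each start by whether the allele frequency ended above or below its starting
value. Defaults: frequency steps of 0.001 over (0, 1), selfing rates 0 to
0.99 in steps of 0.01, horizon 100 generations; all three are parameters.
The classification compares to the *starting frequency*, not to 0.5 —
deliberately, because the two rules differ transiently near the threshold.
The reported boundary is the lowest advancing frequency; a non-monotone
classification is logged and the first sign change returned. In monoecious
mode this scan brackets the analytic equilibrium within one frequency step
across the whole selfing grid, which is the primary validation of both
routes. The scans are vectorized across the frequency grid, so the full
default grid runs in seconds.

## Parameters that matter

| parameter | meaning | default | why |
|---|---|---|---|
| k₁, k₂ | killing penetrance per allele | — (required) | dimensionless probabilities; only r = k₁/k₂ matters for monoecious equilibria, absolute values matter under androdioecy |
| S | selfing rate | — (required) | fraction of broods selfed; wild *Caenorhabditis* populations are high-S |
| b | outcross brood ratio | 1.0 | *C. elegans* estimates put b near 1; 1/2 encodes the two-fold cost of males |
| horizon | generations before threshold classification | 100 | matches the grid estimator's definition; sensitivity exposed as a flag |
| fixation tolerance | \|p − {0,1}\| for terminal labels | 1e-9 | geometric approach to the boundary makes tighter values pointless in float64 |

## Interval-overlap module

BED-standard 0-based half-open coordinates; merge joins overlapping *and*
bookended intervals; a region "contains" a feature at ≥ 1 shared base;
strand is ignored. These conventions match the defaults of the standard
command-line tool for such analyses, and the test suite checks merge and
containment against both a per-base/quadratic brute-force oracle and
`bedtools` itself on seeded fixtures. The fixture generator partitions a
synthetic chromosome into slots, plants features inside a seeded random
subset of regions (exact planted count = round(fraction × n_regions)) and
drops decoys into region-free gaps, so the true containment fraction is
known by construction. It emulates only the *arithmetic* of the empirical
analysis — interval geometry and containment counting — not the biology:
real hyperdivergent regions vary in length, cluster along chromosomes, and
real gene sets overlap each other, so passing tests validate the pipeline,
not any empirical overlap percentage.

## Numerical choices

- Genotype frequencies are renormalized each generation; drift beyond 1e-9
  from the simplex raises instead of renormalizing (it would indicate a bug,
  not round-off).
- Mean fitness ≤ 0 raises a degenerate-population error rather than
  returning NaN; with valid simplex states this is unreachable (heterozygous
  zygotes always survive), so the guard only trips on misuse.
- A population placed exactly at p̂ is treated as at equilibrium; no
  perturbation is injected. The equilibrium is unstable, so float round-off
  eventually leaks — tests assert no systematic motion over ~100
  generations, not indefinite persistence.
- Trajectory export uses repr-precision floats ("%.17g"), so write → read is
  exact.

## Design choices that were genuinely open

- **One generative engine, closed forms as cross-checks.** The enumeration
  is the source of truth; Eq-style recursions are the fast path. This keeps
  the Medea/peel asymmetry under androdioecy from being hand-derived twice.
- **Census-weighted population frequency.** The sex-weighted average uses
  census weights (1, m_ratio) with m_ratio tracked from surviving brood
  weights. Fixation-speed orderings (free males hasten a single element's
  spread, b = 1/2 slows it relative to monoecy) are asserted at a p > 0.9
  crossing: the androdioecious trajectory leads through the entire spread
  phase, but the male pool — outcross-only, heterozygote-rich — converges
  last, so crossings measured in the extreme tail (p > 0.99) can invert by a
  generation at low S. That tail behavior is a feature of the sex structure,
  not noise.
- **Thresholds reported at grid resolution.** Published-style elimination
  thresholds are stated as the first failing point on the selfing grid
  (e.g. 0.67 for a 50× invader at p = 0.01, whose exact critical value is
  0.6644): the grid statement is the operationally testable claim.

## Limitations

Deterministic (no drift), single locus (no recombination between elements),
no fitness costs on carriers, no sex-specific penetrance, no reproductive
compensation or family-level soft selection, no spatial or metapopulation
structure, fixed selfing rate, autosomal elements only. Several of these
(drift near thresholds, group selection in patchy populations,
selfing-modifier evolution) are known to matter biologically; the package
deliberately implements the deterministic core that those extensions build
on.
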