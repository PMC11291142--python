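# parentaldrive

Deterministic population genetics of **parental-effect toxin–antidote gene
drives** — *Medea* (Maternal-Effect Dominant Embryonic Arrest) and *peel*
(paternal-effect) elements — in populations that mix self-fertilization with
outcrossing, including the androdioecious mating system of selfing
*Caenorhabditis* nematodes.

A *Medea* allele acts in a heterozygous mother: she deposits a toxin in every
egg, and zygotes that do not inherit the allele (and hence lack its zygotic
antidote) die with penetrance *k*. A *peel* element is the sperm-parent
counterpart. At some *Caenorhabditis* loci **both** alleles are independent
elements ("antagonistic" *Medeas*), so only the heterozygous offspring of a
heterozygote escape both toxins. Intuition says this should create
heterozygote advantage and balancing selection; the model shows the opposite:
under partial selfing these elements exhibit **positive frequency
dependence** — the common allele deterministically drives the rare one
extinct, and the internal equilibrium is an unstable invasion threshold.
The package is for population geneticists and gene-drive modelers who want
these recursions, equilibria, and thresholds as tested, scriptable code.

## The model

A biallelic locus with alleles M₁, M₂ and genotype frequencies
X = f(M₁M₁), Y = f(M₁M₂), Z = f(M₂M₂); p = X + Y/2. Hermaphrodites self
with fixed probability S, otherwise mate at random. Allele Mᵢ kills
unprotected zygotes with penetrance kᵢ. In (p, Y) coordinates the
monoecious recursion is

    p' = [p − (Y k₂/2)(S/2 + (1−S) p)] / w̄
    Y' = [S Y/2 + (1−S) 2pq] / w̄
    w̄  = 1 − (Y/2)[k₁(S/2 + (1−S) q) + k₂(S/2 + (1−S) p)]

Key analytic results implemented (and verified against a brute-force
mating-table oracle and dynamical iteration):

- **Internal equilibrium** p̂: depends only on S and the penetrance ratio
  r = k₁/k₂; unstable whenever 0 < S < 1 and r ≠ 1 (bistability). Equal
  penetrances give p̂ = 0.5; under obligate outcrossing the stronger element
  always sweeps (no threshold).
- **Equilibrium heterozygosity** Ŷ at held p, with an absolute heterozygote
  excess (negative fixation index) whenever S < k/2 at p = 0.5.
- **Critical selfing rate** S_C and **critical penetrance ratio** r_C for an
  invader at frequency p — e.g. a 50× more penetrant invader at p = 0.01 is
  eliminated once S exceeds ≈ 0.67.
- **Androdioecy** (hermaphrodites self or mate with males; males arise only
  from outcrossing, at brood ratio b): sex-structured recursions in which
  *Medea* and *peel* elements no longer behave identically — males carry
  excess heterozygosity, so *peel* elements drive harder, and a *peel* can
  displace an equally penetrant resident *Medea*.
- **Numerical invasion thresholds**: grid scans over starting frequency and
  selfing rate, classifying each start by whether the allele advanced after a
  fixed horizon.
- **Interval overlap utility**: BED read/write, merge, intersect, and
  fraction-of-regions-containing-a-feature, with a seeded synthetic fixture
  generator (mirrors the hyperdivergent-region × germline-expression
  analysis without external data).

## Worked example

Where is the invasion threshold when a *Medea* with penetrance k₁ = 0.9
faces a resident with k₂ = 0.5 in a population selfing at S = 0.6?

```sh
$ parentaldrive equilibria --S 0.6 --k1 0.9 --k2 0.5
{
  "S": 0.6,
  "r": 1.8,
  "p_hat": 0.28029366598359207,
  "neutral_fixation_index": 0.4285714285714286,
  "Y_hat": 0.2683661499494507
}
```

The invader must start above p̂ ≈ 0.28 to sweep; below that it is eliminated
despite being 1.8× as penetrant. Ŷ ≈ 0.27 is the (unstable) equilibrium
heterozygosity at that point; the neutral fixation index S/(2−S) ≈ 0.43 is
the inbreeding baseline the drive dynamics are compared against. Starting
below the threshold:

```sh
$ parentaldrive simulate --model monoecy --k1 0.9 --k2 0.5 --selfing 0.6 \
      --p0 0.2 --generations 200
generation  X      Y        Z      p        wbar
0           0.2    0.0      0.8    0.2
1           0.136  0.128    0.736  0.2      1.0
2           0.1099 0.17477  0.7153 0.19728  0.952128
...
200         3.4e-10  1.3e-09  0.99999999  1.0e-09  0.99999999
```

The first generation rebuilds heterozygotes at constant p (w̄ = 1 when
Y = 0); selection then drives the invader out (p → 0, "fixed_M2"). Other
subcommands: `threshold` (numerical invasion-threshold grids),
`ternary` (De Finetti coordinates and flow fields), `overlap` / `fixtures`
(interval analysis). Everything is deterministic: identical inputs give
byte-identical outputs.

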