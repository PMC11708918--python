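# Methods

## The model

`tadrive` studies a single biallelic locus whose alleles, `M1` and `M2`,
may each act as a toxin–antidote drive element. A *Medea*-type element in
a heterozygous egg parent deposits a toxin into every egg; progeny that do
not inherit the element (and hence its antidote) die with penetrance `k`.
A *peel*-type element is the sperm-delivered mirror image: killing is keyed
to the sperm parent's genotype. With both alleles active, `M1` kills
`M2M2` progeny of exposed matings with penetrance `k1` and `M2` kills
`M1M1` with penetrance `k2`. Heterozygous progeny carry both antidotes and
are never killed.

The population is infinite and generations are discrete; there is no
mutation, drift, migration, spatial structure, recombination with other
loci, or direct fitness cost to carriers. Each generation a hermaphrodite
selfs with fixed probability `S` and outcrosses at random with probability
`1 − S`.

### Monoecious recursion

With genotype frequencies `(X, Y, Z)` for `(M1M1, M1M2, M2M2)`, allele
frequency `p = X + Y/2` and `q = 1 − p`, one generation maps

    w̄  = 1 − (Y/2) [ k1 (S/2 + q(1−S)) + k2 (S/2 + p(1−S)) ]
    p′ = ( p − (Y/2) k2 (S/2 + p(1−S)) ) / w̄
    Y′ = ( S Y/2 + (1−S) 2pq ) / w̄

`w̄` is the mean fitness (the surviving fraction of the progeny pool).
Under monoecy the Medea/peel distinction is invisible: outcross frequencies
are symmetric in the parental roles, so the egg-parent and sperm-parent
exposure rules produce identical sums. An allele whose element type is
`none` is inert — its nominal penetrance is treated as zero, consistently
in both the compact recursion and the mating-table enumeration.

Two independent implementations of this map coexist deliberately: the
compact recursion above, and a brute-force enumeration of the 3 selfing
and 9 outcross mating classes with Mendelian segregation and per-class
killing. The suite requires componentwise agreement to 1e−12 on 1000
seeded random (state, parameter) pairs; the enumeration is the oracle.

### Equilibria and thresholds

Setting `p′ = p` gives the interior equilibrium condition
`p r (S/2 + q(1−S)) = q (S/2 + p(1−S))` with `r = k1/k2`: the interior
equilibrium depends only on `(S, r)`, not on heterozygosity or penetrance
magnitudes. It is always unstable — the dynamics are bistable under
partial selfing, and `p̂` is the invasion threshold (separatrix). The
closed-form root has removable singularities at `r = 1` (`p̂ = 1/2`) and
`S = 1` (`p̂ = 1/(1+r)`), both handled as explicit limits. Because printed
radicals are easy to mistranscribe, the implementation always verifies the
closed form against the implicit condition (residual < 1e−10) and falls
back to bisection of the implicit condition on (0, 1) otherwise; with no
sign change on (0, 1) there is no interior equilibrium (obligate
outcrossing with `r ≠ 1`).

Equilibrium heterozygosity solves the fixed point of the `Y` recursion at
`p̂`: `(K/2) Y² − (1 − S/2) Y + 2(1−S) p̂ q̂ = 0` with
`K = k1(S/2 + q̂(1−S)) + k2(S/2 + p̂(1−S))`. Both quadratic roots are
computed and filtered for feasibility (`Y ∈ [0,1]`, non-negative
homozygote frequencies); the feasible root is the smaller one. The
quadratic was rederived from the recursion rather than transcribed, and is
validated against fixed-point iteration in the tests.

The critical selfing rate and critical penetrance ratio,

    S_C = 2p(1−p)(1−r) / (2p²r − 2p² − pr + 3p − 1)
    r_C = [S + 2p(1−p)(1−S) − Sp] / [2p(1−p)(1−S) + Sp]

are algebraic rearrangements of the same condition (the suite checks
`r_C(p, S_C(p, r)) = r` and `p̂(S, r_C(p, S)) = p` to 1e−8). The `S_C`
denominator vanishes identically at `p = 1/2`; this is raised as a domain
error rather than clamped. Values outside [0, 1] are returned raw and
reported as "no threshold in range" by the CLI — a majority invader with
`r > 1` fixes at every selfing rate.

### Androdioecy

The *Caenorhabditis* mating system adds structure: hermaphrodites self
(producing only hermaphrodites) or mate with males (producing a 50:50
hermaphrodite/male brood); hermaphrodites cannot mate with each other, and
male production by X nondisjunction is ignored. The state is therefore
sex-specific, `(Xh, Yh, Zh; Xm, Ym, Zm)`, with separate normalizers `w_h`
and `w_m`. The parameter `b` — hermaphrodite offspring per outcross
relative to per selfing — weights only the outcross contribution to the
hermaphrodite pool (`b = 1/2` is the classical two-fold cost of males;
`b = 1` means mating doubles the brood). Male genotype frequencies are
normalized separately from outcross classes only and are b-independent.

The recursions are derived mechanically from one exposure rule per allele
(Medea → egg parent's heterozygosity; peel → sperm parent's, which under
selfing is the hermaphrodite itself and under outcross the male). This
single rule generates the pure-Medea, pure-peel, and mixed antagonism
cases without hand-written case analysis. The derivation is pinned down by
tested consequences rather than taken on trust:

* `S = 1` reduces exactly to monoecy with `S = 1` (male pool untouched);
* `S = 0` with equal sex frequencies reduces exactly to monoecy with
  `S = 0`;
* male heterozygosity `Ym` is irrelevant to allele-frequency dynamics when
  both elements are Medea-type;
* `Ym ≥ Yh` along trajectories (males are always outcross products);
* a single Medea spreads faster under androdioecy with `b = 1` than under
  monoecy at the same `S`, and slower with `b = 1/2`;
* a peel spreads faster than an equally penetrant Medea, and an invading
  peel can displace an equally penetrant resident Medea (threshold below
  1/2).

At `S = 1` the male pool receives no input; the male state is carried
forward unchanged and `w_m` is reported as NaN. This choice only affects
bookkeeping — male frequencies are dynamically irrelevant without
outcrossing.

The "population allele frequency" of a sex-structured state is a weighted
average of `ph` and `pm`. The weighting convention is selectable
(`hermaphrodite_only`, `equal`, or custom weights) and always recorded;
`equal` is the default and is the rule used by the fate classifier. With
symmetric starting conditions the qualitative orderings above hold under
any of the rules.

## Numerical procedures

**Fate classification.** The default comparator asks whether the allele
frequency after 100 generations is above or below its starting value
(ties within 1e−12 are "undecided"); an absorbing-boundary comparator
(stop when `p` leaves `(ε, 1−ε)`, `ε = 1e−6`) is available as a
robustness check, and the two agree away from the separatrix.

**Threshold scans.** For each selfing rate, trajectories start from
all-homozygote states (`X = p0, Y = 0`; both sexes identical under
androdioecy, matching introduction of migrants from a fixed population)
on a grid of `p0` from 0.001 to 0.999 in steps of 0.001, with selfing
rates 0 to 0.99 in steps of 0.01 by default; `S = 1` cells are reported
as degenerate (from `Y = 0`, every `p` is an equilibrium). The threshold
is the midpoint of the bracketing (largest-loss, smallest-fix) pair, with
the bracket retained; a non-monotone fate sequence flags the cell. An
optional bisection refinement reaches 1e−6 for monoecious cases. Grid
cells are independent; internally whole `p0` columns are advanced
simultaneously by numpy kernels that replicate the scalar maps exactly
(kernel-vs-scalar equivalence is itself a test), so batched and serial
evaluation give identical results. The test suite exercises coarser grids
(steps of 0.005–0.01, a handful of selfing rates) chosen as the package's
own working resolution; the full default grid is the documented one.

**Renormalization.** Each step renormalizes the genotype simplex to guard
against float drift; corrections above 1e−9 are logged. A step in which
killing removes every progeny class raises a distinct
degenerate-extinction error (CLI exit code 3) rather than returning NaN.

**Tolerances.** Dual-route (compact vs enumeration) agreement: 1e−12.
Implicit-equilibrium residual: 1e−10. Threshold inversions: 1e−8.
Scan-vs-analytic agreement: one `p0` grid step.

## Synthetic fixtures

The fixture generator draws genotype states uniformly on the simplex
(Dirichlet(1,1,1)), parameters uniformly on their ranges (`S, k ∈ [0,1]`,
`b ∈ [0.5, 2]`, the biologically plausible span), and element types
uniformly from {medea, peel, none}; everything is reproducible per seed.
These fixtures probe the full deterministic state space of the model —
they are not simulations of real populations, and passing tests certify
the correctness of the maps and formulas, not the model's adequacy for
any particular *Caenorhabditis* population (which would involve drift,
demography, costs, and multilocus structure, all outside scope).

## Known limitations

* Deterministic infinite-population dynamics only; no drift, so the
  "invasion threshold" is a separatrix, not a fixation probability.
* No fitness costs of carrying an element, no resistant or cross-reactive
  antidote alleles, no sex-specific penetrance, no sex-limited
  introductions, no multilocus systems.
* The androdioecious model tracks sex-specific genotype frequencies but
  not the population sex ratio; `b` is a pure bookkeeping weight on the
  hermaphrodite pool.
* Near `p = 0` or `1` under pure outcrossing, convergence is algebraic
  (selection vanishes quadratically at the boundary), so trajectory-based
  confirmations use generation counts suited to the parameter regime.
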