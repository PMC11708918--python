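# tadrive

Deterministic population-genetic dynamics of antagonistic **toxin–antidote
gene-drive elements** — maternal-effect *Medea* and paternal-effect *peel*
alleles — in populations that mix self-fertilization with outcrossing, as
in androdioecious *Caenorhabditis* nematodes.

A *Medea* element in a heterozygous mother poisons all of her eggs; only
offspring inheriting the element (and its linked antidote) reliably
survive. A *peel* element is the sperm-delivered analogue. When the two
alleles at a locus each carry such an element, each kills the opposite
homozygote class among progeny of heterozygous parents. Intuition suggests
balancing selection; instead, partial selfing makes the dynamics
*bistable*: the common allele deterministically drives the rare one
extinct, and an invader must start above an unstable threshold frequency
to sweep. `tadrive` computes these dynamics exactly and locates the
thresholds both in closed form and by numerical scanning. It is aimed at
population geneticists studying selfish genetic elements, mating-system
evolution, and engineered gene-drive feasibility in selfing species.

## The model

Genotypes `M1M1 : M1M2 : M2M2` at frequencies `(X, Y, Z)`, allele
frequency `p = X + Y/2`, selfing rate `S`, penetrances `k1` (of `M1`
against `M2M2` progeny) and `k2` (of `M2` against `M1M1`). One generation:

    w̄  = 1 − (Y/2) [ k1 (S/2 + q(1−S)) + k2 (S/2 + p(1−S)) ]
    p′ = ( p − (Y/2) k2 (S/2 + p(1−S)) ) / w̄
    Y′ = ( S Y/2 + (1−S) 2pq ) / w̄

The interior equilibrium `p̂` depends only on `S` and the penetrance ratio
`r = k1/k2`, and is always unstable. Closed forms are provided for `p̂`,
the equilibrium heterozygosity `Ŷ`, the critical selfing rate `S_C(p, r)`
above which an invader at frequency `p` is eliminated, and the critical
penetrance ratio `r_C(p, S)` it needs to sweep. A sex-structured extension
models the *Caenorhabditis* mating system (hermaphrodites self or mate
with males; males come only from outcrossing) with a cost-of-males
parameter `b`; there Medea and peel elements genuinely differ, because
males are always outcross products and hence more heterozygous. See
`docs/methods.md` for the full account.

## Worked example

Where is the invasion threshold when a strong Medea (`k1 = 0.9`) invades a
population carrying a weaker resident (`k2 = 0.5`) that selfs 60% of the
time?

```sh
tadrive equilibrium --s 0.6 --k1 0.9 --k2 0.5
```

```json
{
  "S": 0.6,
  "k1": 0.9,
  "k2": 0.5,
  "p_hat": 0.28029366598359273,
  "Y_hat": 0.26836614994945135,
  "K": 0.7351530134426252,
  "residual": 6.661338147750939e-16,
  "stability": "unstable"
}
```

The invader must exceed `p̂ ≈ 0.28` to sweep; below it, the resident
excludes it (`Y_hat` is the heterozygosity at that unstable point, `K` the
composite selection intensity, and the residual confirms `p̂` satisfies
the implicit equilibrium relation). An invader starting at `p = 0.2` is
therefore blocked at `S = 0.6` — but how much selfing is needed to block
it?

```sh
tadrive threshold --p 0.2 --r 1.8
```

```json
{
  "p": 0.2,
  "r": 1.8,
  "S_C": 0.3678160919540231,
  "in_range": true
}
```

Below `S_C ≈ 0.37` the invader fixes; above it, it is lost. Iterating the
recursions from `p = 0.2` confirms both fates: under obligate outcrossing
(`S = 0`) the frequency climbs 0.2 → 0.83 → 0.94 → 0.99 over 200
generations, while at `S = 0.6` it collapses 0.2 → 0.07 → 0.007 → 0
(`tadrive iterate --s 0.6 --k1 0.9 --k2 0.5 --p0 0.2 --generations 200`).

Other subcommands: `iterate --model androdioecious` (sex-structured
trajectories with `--element1/--element2` in `{medea, peel, none}` and
`--b`), `threshold-scan` (numerical separatrix grids), `vector-field`
(phase-portrait coordinates on the genotype simplex), and `fixtures`
(seeded random states). `examples/` holds scripts that regenerate the
standard figures' coordinate data through the public CLI.

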