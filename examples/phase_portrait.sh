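#!/bin/sh
# Ternary phase portrait data for S = 0.6, k1 = 0.9, k2 = 0.5: the
# one-step displacement field on the genotype simplex plus the unstable
# internal equilibrium marking the separatrix.
set -e
mkdir -p out
tadrive vector-field --s 0.6 --k1 0.9 --k2 0.5 --resolution 25 \
    --out out/vector_field.tsv
tadrive equilibrium --s 0.6 --k1 0.9 --k2 0.5 --out out/equilibrium.json
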