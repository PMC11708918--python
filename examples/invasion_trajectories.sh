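#!/bin/sh
# Allele-frequency trajectories of a strong Medea (k1 = 0.9) invading a
# resident (k2 = 0.5) at p0 = 0.2 across six selfing rates: the invader
# sweeps under high outcrossing and is eliminated under high selfing.
set -e
mkdir -p out
for S in 0.0 0.2 0.4 0.6 0.8 1.0; do
    tadrive iterate --s "$S" --k1 0.9 --k2 0.5 --p0 0.2 --y0 0 \
        --generations 200 --out "out/trajectory_S${S}.tsv"
done
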