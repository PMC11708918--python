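#!/bin/sh
# Invasion-threshold frequency as a function of selfing rate for a fully
# penetrant invader (k1 = 1) against residents of varying penetrance,
# monoecious model. The curves depend only on the penetrance ratio.
set -e
mkdir -p out
for k2 in 0.10 0.25 0.50 0.75 0.95; do
    tadrive threshold-scan --k1 1.0 --k2 "$k2" \
        --s-min 0.01 --s-max 0.99 --s-step 0.01 \
        --p-min 0.005 --p-max 0.995 --p-step 0.005 \
        --out "out/threshold_mono_k2_${k2}.tsv"
done
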