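#!/bin/sh
# Spread of a single fully penetrant element (p0 = 0.04, both sexes) under
# the Caenorhabditis mating system: Medea vs peel, free males (b = 1) vs
# a two-fold cost of males (b = 0.5), compared with monoecy at the same S.
set -e
mkdir -p out
S=0.5
tadrive iterate --s "$S" --k1 1.0 --k2 0.0 --p0 0.04 --generations 150 \
    --out out/spread_monoecy.tsv
for elem in medea peel; do
    for b in 1.0 0.5; do
        tadrive iterate --model androdioecious --element1 "$elem" \
            --element2 none --s "$S" --k1 1.0 --k2 0.0 --b "$b" \
            --p0 0.04 --generations 150 \
            --out "out/spread_${elem}_b${b}.tsv"
    done
done
# Invading peel vs resident Medea, both fully penetrant: the separatrix
# sits below one half.
tadrive threshold-scan --model androdioecious --element1 peel \
    --element2 medea --k1 1.0 --k2 1.0 --b 1.0 \
    --s-min 0.05 --s-max 0.95 --s-step 0.05 \
    --p-min 0.005 --p-max 0.995 --p-step 0.005 \
    --out out/threshold_peel_vs_medea.tsv
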