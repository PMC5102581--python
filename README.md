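# biocogs

Transparent, testable cost-of-goods modelling for uricase bioprocessing.

Uricase (urate oxidase) degrades uric acid to allantoin and is produced
recombinantly in *E. coli* as a gout therapeutic. Its classical
purification uses three sequential chromatography columns; an aqueous
two-phase system (ATPS) of PEG2000 and ammonium sulfate can replace them
with a single extraction, and a back-extraction stage can recycle part of
the phase-forming chemicals. `biocogs` implements the full economic
comparison of these three routes as an explicit, calibratable pipeline —
deterministic cost of goods per gram (CoG/g), one-at-a-time scenario
sensitivity with tornado ranking, Monte Carlo analysis under triangular
parameter uncertainty, and linear surrogate / overlap analysis — for
bioprocess engineers who want the arithmetic behind published
techno-economic comparisons to be inspectable and reproducible.

## Model

At a constant annual target output, with a 25 L fermentation at titer
*T* (g/L) and composite downstream yield *Y*:

    B     = target_output / (V · T · Y)                   batches per year
    annual= capital + other + labor + B · (materials + consumables per batch)
    CoG/g = annual / (B · V · T · Y)

Labor is a four-role wage set times a headcount equivalent (13% of base
CoG/g after calibration); UF/DF filter consumables follow a ceiling rule on
the processed volume. The engine is calibrated to the case-study base
values — $9,396.97/g (chromatography, Y = 43.2%) and $5,452.00/g (ATPS,
Y = 66%) — and the ATPS-with-recycle cost is then computed *emergently*
from the ATPS calibration plus the back-extraction mass balance (60% PEG /
20% salt reuse, 56% bottom-phase collection, 10× dilution). Uncertainty
uses T ~ Triangular(0.392, 0.484, 0.577) and ΔY ~ Triangular(−10, 0, +10)
percentage points; surrogates are OLS planes `cog = b0 + bT·T + bY·ΔY`.
See `docs/methods.md` for assumptions and design choices.

## Worked example

```python
from biocogs import load_config, cog_per_gram, breakdown_shares

bundle = load_config()          # packaged uricase case study, calibrated
for pid in ("chromatography", "atps", "atps_recycle"):
    r = cog_per_gram(bundle.flowsheets[pid], bundle.cost_configs[pid])
    print(f"{pid:15s} CoG/g = ${r.cog_per_gram:,.2f}  "
          f"({r.batches:.1f} batches/yr, labor share "
          f"{breakdown_shares(r)['labor']:.0%})")
```

prints

```
chromatography  CoG/g = $9,396.97  (19.1 batches/yr, labor share 13%)
atps            CoG/g = $5,452.00  (12.5 batches/yr, labor share 13%)
atps_recycle    CoG/g = $5,421.95  (12.5 batches/yr, labor share 13%)
```

ATPS cuts the cost of goods by ~42% against chromatography; recycling the
phase chemicals saves a further ~$30/g only, because the back-extraction
dilutes the product stream to 250 L and the extra UF/DF filters consume
almost the whole material credit.

The same analyses are available from the shell:

```
biocogs all --seed 1 --out results/     # cog, sensitivity, montecarlo,
                                        # surrogate fits and overlap
biocogs sensitivity --out results/      # tornado CSVs only
```

Every output directory gets a `manifest.json` with the command, config,
seed and package version; identical seeds give byte-identical outputs.

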