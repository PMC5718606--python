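# gutcross

Intestinal-environment chemistry and longitudinal microbiome statistics for
randomized crossover bed-rest studies, with a seeded synthetic-data generator
so the entire pipeline is testable end-to-end without any data download.

## Who this is for

Studies of inactivity and hypoxia in controlled confinement (three arms:
normoxic bed rest **NBR**, hypoxic bed rest **HBR**, hypoxic ambulation
**HAmb**; every participant crosses over through all arms; stool sampled at
days −5, −1, 3, 10, 18, 21) produce two kinds of data this package analyses
together:

* **intestinal chemistry** — DOM absorbance spectra, fecal conductivity
  (IEC), HPLC sterol/polyphenol fingerprints;
* **16S community tables** — genus/OTU counts with taxonomy and a phylogeny.

## What it computes

**Chemistry.** Napierian absorption coefficients `a = 2.303·A/l` (l = 2/3 cm)
and the five DOM indices: indole ratios a(217)/a(365) and a(287)/a(365),
SUVA254 = A(254)/TSOC, SViA420 = A(420)/TSOC, cDOM = a(350)/TSOC, and the
lignin-phenol model

    ln(TDLP9) = −2.282·ln a(350) − 8.209·ln a(275) + 11.365·ln a(295) + 2.909

plus linear IEC calibration against 1 M KCl standard series with drift
flagging, and fingerprint → chemical-diversity profiles.

**Microbiome statistics.** The 13-index α-diversity suite (ln-based Shannon,
bias-corrected Chao-1, Fisher's α via root solving, …); seeded rarefaction;
Bray-Curtis / Jaccard / ThetaYC / Morisita-Horn distances and both UniFrac
variants; PERMANOVA (pseudo-F), AMOVA (variance-component ratio), HOMOVA
(Bartlett-style dispersion), Mantel, all by permutation with BH-FDR; a
four-test differential battery (metastats-style t/Fisher, IndVal,
Kruskal-Wallis + effect gate, AWKS) whose conjunction flags "congruent"
responders; Corbata-style core-microbiome ubiquity curves, surfaces,
major/minor cores and the abundance-weighted KS statistic; the
Firmicutes:Bacteroidetes ratio and its rate of change; and step-down-screened
three-matrix variation partitioning by adjusted RDA R² on
Hellinger-transformed counts.

**Generator.** One seed produces the full study: 9×3×6 design,
Dirichlet-multinomial genus counts (~105,300 ± 39,200 reads/sample, scalable)
with a planted 2-fold *Bacteroides* enrichment in HBR's final week, a random
phylogeny, spectra in three dilutions, conductivity runs with +67 %/+32 %
week-1 IEC shifts in HBR/NBR, peak tables, and three metadata matrices
(109/12/110 variables) optionally coupled to the latent community gradient.
Ledgers name exactly what was planted.

## Worked example

```bash
gutcross run --seed 7 --scale 0.1 --outdir run
```

completes in well under a minute on one CPU and writes every stage's tables
plus `manifest.json`. The planted *Bacteroides* enrichment is recovered as the
only congruent taxon (`run/differential.tsv`):

```
taxon        contrast     metastats_q  indval   kw_effect  awks    congruent
Bacteroides  HBR_vs_NBR   0.006        69.97    0.367      0.294   True
Bacteroides  HBR_vs_HAmb  0.006        69.51    0.358      0.285   True
```

meaning: BH-adjusted metastats q = 0.006 (< 0.05), indicator value ≈ 70/100,
a 0.37 log₁₀ (≈ 2.3-fold) effect size passing the significance+effect gate,
and an abundance-weighted ubiquity shift of ≈ 0.29 between cohorts — all four
votes agree, in both contrasts. `run/iec.tsv` shows the calibrated
conductivity jumping at intervention onset (P01 HBR: 3.06, 3.01 mS/cm in
run-in → 5.04 at day 3, a ~67 % planted increase), and `run/partition.tsv`
decomposes community variance into pure/shared metadata fractions that sum to
1 with the unexplained remainder (≈ 0.90 at this noise level).

The same stages are importable as a library:

```python
from gutcross import synthetic, beta, differential

cfg = synthetic.GeneratorConfig(seed=7, scale=0.1)
design = synthetic.generate_design(cfg)
counts, ledger = synthetic.generate_counts(design, cfg)
dm = beta.pairwise_distance(counts, "thetayc")
res = beta.permanova(dm, design["arm"], n_perm=10_000, seed=7)
print(res.statistic, res.p_value)
```

## Layout

```
src/gutcross/
  synthetic.py     study-design emulator + ledgers
  chem.py          Napierian spectra, DOM indices, IEC calibration, fingerprints
  alpha.py         13-index alpha-diversity suite
  beta.py          rarefaction, distances, UniFrac, PERMANOVA/AMOVA/HOMOVA/Mantel, BH
  differential.py  metastats/IndVal/KW-effect battery, congruency, F:B ratio
  coremicro.py     ubiquity curves, core surfaces, AWKS
  varpart.py       step-down screening, three-way variation partitioning
  pipeline.py      staged orchestration, YAML config, manifest
  cli.py           `gutcross` command group
docs/methods.md    model and design notes
```
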