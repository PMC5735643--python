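# trophon

Trophic niche partitioning analysis for stomach-content surveys of fish.

`trophon` is aimed at fish feeding ecologists asking how two (or more)
sympatric, closely related carnivores share food and time — the classic
resource-partitioning question for piranhas (*Serrasalmus*) and similar
predators in Amazonian reservoirs. Given specimen records (species, sex,
morphometrics, capture date and 3-h net-check interval, stomach repletion
class) and stomach-content records (food category, volume), it computes:

* **Diet composition** per species × season over the six broad categories
  (fish, crustacean, microcrustacean, insect, plant, other):
  - frequency of occurrence `FOᵢ = 100·nᵢ/N` (nᵢ stomachs containing item
    *i*, N content-bearing stomachs),
  - volumetric frequency `VFᵢ` (a category's percent share of pooled item
    volume),
  - the Kawakami–Vazzoler index of feeding importance
    `IFᵢ = FOᵢ·VFᵢ / Σⱼ FOⱼ·VFⱼ`.
* **Niche breadth** — Levins standardized index
  `Bᵢ = (1/Σpⱼ² − 1)/(n − 1)` ∈ [0, 1], banded low (< 0.4), moderate
  (0.4–0.6) or high (> 0.6).
* **Niche overlap** — Pianka's symmetric index
  `Oⱼₖ = Σpᵢⱼpᵢₖ / √(Σpᵢⱼ²·Σpᵢₖ²)`, same banding.
* **Null models** — the RA3 randomization algorithm (each species' observed
  utilization values, zeros included, reshuffled among resource states,
  which conserves niche breadth), 5000 iterations by default, with the two
  one-tailed Monte-Carlo probabilities p(observed ≤ expected) and
  p(observed ≥ expected), ties counted in both tails. Observed overlap
  significantly *below* the simulated mean is the pattern consistent with
  interspecific competition.
* **Activity and frequency statistics** — capture profiles over the eight
  3-h net checks (18:00 … 15:00), chi-square heterogeneity among intervals
  and between the nocturnal (18:00–06:00, five checks) and diurnal (three
  checks) periods with optional Yates correction, sex-ratio chi-squares,
  G-tests of seasonal variation in diet occurrence, and size-structure
  comparisons (Kolmogorov–Smirnov and Bartlett pre-checks, then Student's
  t).
* **A synthetic survey generator** so every stage runs and is testable
  without field data: configurable abundances, sex ratios, seasonal diet
  vectors, repletion mixes and uniform vs nocturnal-bimodal activity
  rhythms.

## Worked example

Generate the built-in two-species preset (two piranha-like populations,
~341 vs ~61 specimens, both fish-dominated, one strictly nocturnal) and run
the full pipeline:

```bash
trophon simulate --out-dir sim
trophon diet      --specimens sim/specimens.csv --items sim/stomach_items.csv --out diet.csv
trophon niche     --specimens sim/specimens.csv --items sim/stomach_items.csv --by species --out niche.json
trophon nullmodel --specimens sim/specimens.csv --items sim/stomach_items.csv --seed 42 --out null.json
trophon activity  --specimens sim/specimens.csv --out activity.json
```

`diet.csv` starts:

```
species,season,interval,category,n,N,fo_pct,vf_pct,ifi
S. gibbus,flood,all,fish,72,77,93.506,79.608,0.974
S. gibbus,flood,all,crustacean,5,77,6.494,4.311,0.0037
```

i.e. of the 77 content-bearing *S. gibbus* flood-season stomachs, 72
contained fish (FO 93.5%), fish made up 79.6% of pooled content volume,
and the feeding-importance index concentrates 0.974 of dietary importance
on fish. `niche.json` reports both species as trophic specialists
(Bᵢ = 0.069 and 0.024, band "low") with near-complete diet overlap
(Oⱼₖ = 0.998, band "high"); the null model prints

```
observed 0.998 vs simulated 0.217 (p_le=0.964, p_ge=0.043)
```

— the observed overlap sits in the upper tail of the RA3 null
(p(obs ≥ exp) = 0.043), so the shared diet is not a randomization
artefact. The activity statistics separate the species in time rather than
diet: the common species shows no day/night bias (χ² = 0.058, p = 0.85)
while the rare one is strongly nocturnal (χ² = 25.4, p < 0.001) —
partitioning by foraging time, not by food.

Library use mirrors the CLI:

```python
from trophon import (generate, preset_paper_like, diet_tables,
                     UtilizationMatrix, null_overlap_test)

specimens, items = generate(preset_paper_like())
tables = diet_tables(items, specimens, by=("species",))
matrix = UtilizationMatrix.from_diet_tables(tables, measure="vf")
result = null_overlap_test(matrix, n_iterations=5000, seed=42)
```

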