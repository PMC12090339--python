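# fretlearn

Machine-learning-guided enzyme engineering on FRET-kinetics fitness data.

`fretlearn` implements the full *create–test–learn* loop used to improve a
protease by mutating two three-residue regions simultaneously:

1. **create** — design a random combinatorial library over the mutable
   positions (each position drawn uniformly from the 20 amino acids,
   duplicates redrawn), with per-position amino-acid coverage checking;
2. **test** — score each variant's activity from two-channel plate-reader
   time series: the FRET ratio (blank-subtracted 480 nm / blank-subtracted
   520 nm emission at 430 nm excitation) rises as substrate is cleaved; the
   trace is truncated before it first reaches 0.55, an ordinary
   least-squares line is fit to each replicate, and slopes are normalized by
   the wild-type mean slope so WT fitness is exactly 1;
3. **learn** — fit an ensemble of 5 feed-forward neural networks, each on a
   random 90 % subsample of the one-hot-encoded training data, treat the
   members as samples from a Bayesian posterior, and propose the next batch
   by Thompson sampling: for each batch slot, draw a member uniformly and
   take the argmax of its predicted fitness over the enumerated 20³ space,
   excluding everything already measured.

A synthetic-data module generates seeded ground-truth fitness landscapes
(fields + pairwise couplings, i.e. Potts-like, in "sparse"/"dense"/"additive"
flavours) and simulates noisy two-channel plates from them, so the whole
campaign runs, and is tested, entirely in silico.

## Worked example

```python
import numpy as np
from fretlearn import (REGION_B, enumerate_space, fit_ensemble,
                       make_landscape, random_library, score_plate,
                       simulate_plate, thompson_batch)
from fretlearn.surrogate import TrainingSet

# create: 48 random variants over positions 217/218/219 (WT = "LQE")
library = random_library(REGION_B, 48, seed=1)

# test: simulate a triplicate plate on a tolerant ("dense") landscape, score it
landscape = make_landscape(REGION_B, "dense", seed=3)
plate = simulate_plate(library, landscape, seed=5)
scores = score_plate(plate).set_index("variant_id")
print(round(scores.loc["WT", "fitness"], 3), round(scores.fitness.max(), 3))
# 1.0 1.048

# learn: ensemble on WT + 48 records, then a 32-variant Thompson batch
variants = [REGION_B.wildtype_variant()] + library
fitness = np.array([1.0] + [scores.loc[v.variant_id, "fitness"] for v in library])
ensemble = fit_ensemble(TrainingSet(REGION_B, variants, fitness), seed=7)
batch = thompson_batch(ensemble, enumerate_space(REGION_B), REGION_B,
                       {v.identities for v in variants}, batch_size=32, rng=7)
print(len(batch.variants), batch.to_table().identities.iloc[0])
# 32 LLW
```

The first two numbers are WT-normalized fitness: the wild type defines 1 by
construction, and the best random variant here is ~5 % faster than WT.  The
proposal table ranks the 32 suggested variants with the ensemble member and
predicted fitness behind each pick.

The same loop is available from the shell:

```bash
fretlearn design --region B -n 48 --seed 1 -o lib.tsv
fretlearn score plate.csv layout.csv -o scores.tsv
fretlearn propose scores.tsv --region B --variants lib.tsv --batch-size 32 -o next.tsv
fretlearn simulate campaign.yaml --run-dir runs/demo
fretlearn report runs/demo
```

Plate files are plain delimited text: one row per timepoint with a
`time_min` column and `<well>_480` / `<well>_520` columns, plus a layout
table (`well_id, variant_id, replicate, is_blank`).  A wide
"POLARstar-like" dialect with one block per emission channel (each block
headed by `channel,480` or `channel,520`, then `time_min,<well>,...`) is
read by `fretlearn.read_polarstar_plate`.

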