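# rrfsol

Recursive random-forest modelling of aqueous solubility (logS, log10 mol/L)
from molecular structure.

Aqueous solubility datasets compiled from the literature are noisy:
measurements arrive from many sources at unstated pH, temperature and solid
form, and replicate values for one compound can disagree by an order of
magnitude. `rrfsol` implements a QSPR workflow built around that problem,
for computational and medicinal chemists who need a solubility model that
copes with heterogeneous training data:

1. **Curation** — SMILES are standardized (largest organic fragment, charge
   neutralization, canonicalization) and deduplicated by InChIKey; replicate
   measurements per structure are aggregated to a mean and an inter-source
   standard deviation. Molecules with more than one measurement and
   0 < SD < 1 log unit form the **RELIABLE** test set (the optimization
   yardstick); everything else is **UNRELIABLE**.
2. **Shuffle-decoy variable selection** — every 0–2D descriptor X is offered
   to a regression random forest (RRF) together with a shuffled copy
   X__shuffled. The importance of a variable is its number of occurrences —
   the internal split nodes that use it, summed over all trees. X survives
   iff occurrences(X) > 110 (at the default 500-tree forest) and
   occurrences(X) ≥ occurrences(X__shuffled); survivors are pruned greedily
   so no retained pair has |Pearson r| > 0.51. The procedure recurses on the
   surviving set, with fresh decoys per round, to a fixed point.
3. **Prediction-variance (PV) cleaning** — the PV of a molecule is the
   (n−1)-variance of the individual tree predictions at its descriptor row.
   For a molecule inside the forest's training set, in-bag trees carry its
   reported logS while out-of-bag trees predict the descriptor-implied
   value, so a mislabelled molecule has a large PV. Starting from a 50/50
   split pass, molecules are recursively labelled CLEAN (PV ≤ threshold) or
   UNCLEAN until the labels reach a fixed point; the threshold is chosen by
   minimizing RMSE on the RELIABLE set.
4. **Consensus model** — a gradient-boosting classifier separates soluble
   from insoluble molecules at logS = −2; two class-specific regression
   forests plus one global forest are combined (default: classifier-routed
   forest averaged with the global forest) into the final prediction.
5. **Evaluation** — r²(validation) = 1 − SSres/SStot, r²(Pearson), RMSE,
   MAE, bias = mean(pred − obs), and the percent of molecules with
   |error| < 0.5 log units; plus repeated-run mean ± SD and a paired t-test
   for comparing two models.

A synthetic-data module generates descriptor tables with known sparse
linear signal, multi-source replicates, correlated duplicate columns and
injected gross outliers, so the whole pipeline is testable without any
external download.

## Worked example

```python
import numpy as np
from rrfsol.synthetic import standard_benchmarks, generate_descriptor_dataset
from rrfsol.selection import SelectionParams, select_variables

data = generate_descriptor_dataset(standard_benchmarks()["SELECTION"], seed=1)
selected, rounds = select_variables(data.X, data.y_true.to_numpy(),
                                    SelectionParams(seed=1))
print(sorted(selected)[:12])
print(sorted(data.informative_columns))
```

prints (500 molecules, 10 informative among 215 columns, plus 215 decoys
added internally per round):

```
['x000', 'x001', 'x002', 'x003', 'x004', 'x005', 'x006', 'x007', 'x008', 'x009', 'x081']
['x000', 'x001', 'x002', 'x003', 'x004', 'x005', 'x006', 'x007', 'x008', 'x009']
```

All ten planted informative columns are recovered (plus one lucky noise
column, `x081`); no shuffled decoy survives. The command-line interface
wires the same stages end to end:

```bash
rrfsol simulate CLEANING --out data --seed 1     # synthetic benchmark files
rrfsol curate records.csv --out curated          # real SMILES + logS input
rrfsol train curated/curated.csv --out run --seed 1
rrfsol predict run/model queries.smi --out preds.csv
rrfsol evaluate preds.csv truth.csv --out report
```

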