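# regenhubnet

Spatiotemporal single-cell weighted co-expression networks, hub-gene
frequency analysis, condition-specific gene sets, and spatial marker
co-localization — a reusable, tested pipeline for regeneration time-course
studies, of the kind performed on axolotl (*Ambystoma mexicanum*)
telencephalon sections sampled before injury and at 2–60 days post-injury
(DPI).

It is aimed at computational biologists who want the single-cell WGCNA
workflow (metacell aggregation, soft-threshold selection, topological
overlap, module eigengenes, kME hub ranking) as a plain, scriptable Python
library with planted-truth synthetic data for validation, rather than as an
interactive R session.

## The model

For each (cell-type, condition) context:

1. **Detection filter.** A gene is retained iff it is expressed (nonzero) in
   at least a fraction `f` of the context's cells (default 5%).
2. **Metacells.** Each cell is merged with its `k−1` nearest transcriptomic
   neighbours (PCA embedding, Euclidean; default `k = 25`) into a metacell;
   a greedy, seed-ordered pass accepts a candidate metacell iff its member
   overlap with every accepted metacell is ≤ `max_shared` (default 30).
   Metacell profiles are library-size normalized to the median total and
   log1p-transformed.
3. **Soft threshold.** Signed adjacency `a_ij = ((1 + cor(x_i, x_j))/2)^β`;
   β is the lowest candidate in 1…30 whose connectivity distribution
   satisfies an approximate scale-free law, measured by the signed fit index
   `R² = −sign(slope)·r²` of the log-log regression of binned degree
   frequencies (threshold 0.80). Contexts with no qualifying β are
   **excluded** — a recorded outcome, not an error.
4. **Topological overlap.** `TOM_ij = (Σ_u a_iu a_uj + a_ij) /
   (min(k_i, k_j) + 1 − a_ij)`; modules are detected on `1 − TOM` with
   average-linkage clustering, an adaptive branch cut, a kME
   completion/pruning stage, eigengene-correlation merging, and a minimum
   module size (default 30). Unassigned genes are labelled `grey`.
5. **Eigengenes and hubs.** The module eigengene (ME) is the first principal
   component of the module's standardized expression; `kME(g, M) =
   cor(x_g, ME_M)`; the top `n_hubs = 10` genes per module by own-module kME
   are its hub genes, rank 1 being the most central.

Across contexts, module memberships feed set algebra: genes present in any
post-injury module but in no control module are **regeneration-specific**;
identifiers are partitioned into species-specific (`AMEX60DD_`-prefixed) and
ortholog-annotated symbols. Hub tables are tallied into per-gene hub
frequencies across contexts. Finally, a marker gene's positive-cell fraction
is traced over the time course, and its spatial overlap with an annotated
cell population is quantified both on cell coordinates (radius rule) and on
rendered PNG maps (RGB thresholding → binary dilation → red/yellow
composite).

## Worked example

```python
import pandas as pd
from regenhubnet import (
    SynthConfig, generate_sections, CoexpressionNetwork, NetworkParams,
)

cfg = SynthConfig(
    timepoint_labels=("2dpi",), marker_fraction_course=(0.3,),
    n_celltypes=1, cells_per_type=200, n_genes=500,
    n_modules_shared=2, n_modules_regen_only=2, module_size=30, seed=1,
)
sections, truth = generate_sections(cfg)
frame = pd.DataFrame(sections[0].values, columns=list(sections[0].genes))
frame = frame.loc[:, frame.std(axis=0) > 0]

model = CoexpressionNetwork(frame, NetworkParams(min_module_size=25),
                            context=("typeA", "2dpi"))
res = model.fit()
print(res.summary())
```

```
Co-expression network results
=============================
context:        typeA / 2dpi
genes:          500
samples:        200
soft power:     13 (signed fit R^2 = 0.806)
mean k:         2.07
modules:        4  {'M4': 29, 'M1': 30, 'M3': 30, 'M2': 30}
grey genes:     381
var explained:  M1: 0.71, M2: 0.76, M3: 0.73, M4: 0.76
top hubs:       M1: SYNBS044,AMEX60DD_310125,SYNBN039; ...
```

The fixture plants four 30-gene modules; the fit selects β = 13 as the
lowest power with a qualifying scale-free fit, recovers all four as M1–M4
(one peripheral gene greyed), and each module's eigengene explains ~70–76%
of its standardized variance. `res.hub_genes(n_hubs=10)` returns the ranked
hub table; the rank-1 hubs are the planted genes with the highest factor
loadings.

The full pipeline — simulate, aggregate, fit every context, derive gene
sets, tally hubs, trace the marker course, render composites — runs from the
shell:

```sh
regen-hubnet run --out out/ --seed 1
```

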