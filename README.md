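# mksubloc — multi-label multi-kernel protein subcellular localization

`mksubloc` predicts the subcellular location(s) of a protein from its Gene
Ontology (GO) annotations and those of its BLAST homologs.  It is aimed at
computational biologists who need multi-label localization calls — many
human proteins reside in several of the K compartments at once — together
with honest performance estimates for *novel* proteins that carry no GO
annotation of their own.

## The model

Each protein is encoded as six binary indicator vectors over closed
per-aspect GO vocabularies: its own terms split by aspect
(t_F, t_C, t_P — molecular function, cellular component, biological
process) and the OR-union of its top-H homologs' terms (h_F, h_C, h_P).
Every view m yields a Gaussian kernel

    K_m(x, y) = exp(−γ ‖x_m − y_m‖²),

and the classifier operates on the convex combination K = Σ_m w_m K_m.
The weights w_m are estimated non-parametrically: each view alone is
cross-validated with one-vs-rest SVMs, its pooled multi-label confusion
matrix yields per-class sensitivity SE and Matthews correlation MCC, and
the view is scored by the class average of (SE + max(MCC, 0))/2,
normalized so Σ w_m = 1.  Views polluted by *divergent* homologs (homologs
with a different localization pattern — the source of negative transfer)
earn low weights automatically.

K one-vs-rest SVMs on the combined precomputed kernel produce decision
values that are Platt-calibrated (p = 1/(1+exp(A·f+B)), fitted on
cross-validated decision values) and normalized into a per-location
probability vector.  Locations with probability ≥ θ form the multi-label
prediction (default θ = 0.09).  Evaluation uses the *locative* convention
(a protein in m compartments counts m times), a K×K multi-label confusion
matrix filled by ranked top-N assignment, per-class SE/SP/MCC, overall
accuracy and Gorodkin's R_K, and — for multiplex proteins — the Label Hit
Rate (LHR), Perfect Label Match Rate (PLMR) and Non-target Label Hit Rate
(NT-LHR).

Three scenarios quantify annotation availability: **optimistic** (queries
keep their GO terms), **moderate** (novel queries: their homolog vectors
substitute for target vectors in the test kernels) and **pessimistic**
(target kernels dropped on both sides; 3-kernel homolog-only model).

See `docs/methods.md` for the full model description, parameter table and
limitations.

## Worked example

```python
from mksubloc import LocalizationModel, WorldConfig, generate_world

labels, annotations, homologs = generate_world(WorldConfig(seed=7, n_proteins=200))
model = LocalizationModel(labels, annotations, homologs,
                          scenario="optimistic", n_homologs=1, seed=7)
results = model.fit()
print(results.summary())
```

prints (abridged):

```
Multi-kernel subcellular localization model
============================================================
scenario: optimistic    proteins: 200    locative instances: 255
locations (K): 6    homologs pooled (H): 1
gamma: 0.125    C: 8.0    seed: 7

Kernel weights (inner 3-fold CV)
----------------------------------------
  t_F      0.1812
  t_C      0.1812
  t_P      0.1797
  h_C      0.1606
  h_P      0.1512
  h_F      0.1460
```

The target views carry most of the weight (queries are well annotated in
the optimistic scenario), and the noisier homolog group is dominated by
its cellular-component (C) kernel — C terms are the most
location-informative.  Prediction returns a probability vector per query
and a thresholded label set:

```python
probs = results.predict_proba(labels.accessions()[:1], annotations, homologs)
print(dict(zip(results.ova.classes, probs[0].round(3))))
# {'Cytoplasm': 0.064, 'Endoplasmic reticulum': 0.041, 'Extracell': 0.070,
#  'Mitochondrion': 0.065, 'Nucleus': 0.697, 'Plasma membrane': 0.063}
```

This query (whose true location is Nucleus) is called nuclear with
probability 0.70; at θ = 0.09 only Nucleus passes the threshold, so the
predicted label set is {Nucleus}.

A shell workflow is available via the console script:

```sh
mksubloc simulate --seed 7 --out world/
mksubloc train --gaf world/annotations.gaf --blast world/homologs.blast.tsv \
               --labels world/labels.tsv --out model/
mksubloc predict --model model/ --gaf world/annotations.gaf \
                 --blast world/homologs.blast.tsv --out predictions.tsv
mksubloc evaluate --pred predictions.tsv --truth world/labels.tsv --out-prefix eval
```

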