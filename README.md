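# gnnddi

Interpretable drug–drug interaction (DDI) prediction from chemical
structure alone.

Co-administered drugs can interact with dangerous consequences — the
classic example is a PDE5 inhibitor taken together with a nitrate-based
vasodilator.  Screening every candidate pair experimentally is infeasible,
and methods that propagate labels over the known interaction network
cannot say anything about a *new* drug that has no recorded interactions
yet.  `gnnddi` predicts interactions directly from each drug's molecular
graph, so it covers both settings, and it explains every prediction by
pointing at the substructures — in practice the functional groups — that
drive it.

## Model

Each drug is parsed from SMILES into its heavy-atom graph G(V, E); every
atom carries a 78-dimensional feature vector (element one-hot, degree,
valence, charge, radicals, hybridization, hydrogen count, aromaticity).
A K = 5 layer graph-attention encoder updates atom features as

    h_i^(k+1) = ReLU( Σ_{j∈N(i)} α_ij W^(k) h_j^(k) + W^(k) h_i^(k) )
    α_ij = softmax_j LeakyReLU( aᵀ [W h_i ‖ W h_j] )

with L = 2 attention heads of width F′ = 32 per layer (concatenated:
64-dim atom rows).  After every layer a soft self-attention readout scores
each atom with a one-channel graph convolution and pools the molecule:

    HG^(k) = Σ_i γ_i h_i^(k),   γ = softmax(scores)

Layer k sees a k-bond receptive field, so HG^(1)…HG^(5) summarize
substructures of growing size; their concatenation Z = ‖_k HG^(k)
(320-dim) is the drug embedding.  A pair (x, y) is represented by
[Z_x ‖ Z_y] (640-dim) and classified by a five-layer MLP
(640→128→64→32→2, ReLU hidden activations, softmax output) trained with
binary cross-entropy (Adam, lr 10⁻³).

Two evaluation protocols are built in: *edge partition* (warm start —
interaction edges split 75/5/20) and *drug partition* (cold start — 20% of
drugs held out entirely, test pairs join a known drug to a held-out one).
Metrics: accuracy, precision, recall, F1, AUC, AUPR over repeated seeded
splits with balanced negative sampling.

To explain a predicted interaction, every layer pair (s, t) is scored by
the inner product HG_x^(s)·HG_y^(t); the argmax names the receptive-field
depths that drive the prediction, and the readout weights γ at those
layers rank the atoms of each drug.

Because real interaction databases are large and license-encumbered, the
package ships a seeded generator of desk-scale libraries: scaffolds with
grafted functional groups (nitrate, carboxyl, phenol, amine, sulfonamide)
and rule-based labels ("nitrate interacts with sulfonamide", …) plus a
small label-noise rate, with full ground truth for scoring both learning
and attribution.

## Worked example

```
$ gnnddi simulate --profile quick --outdir .
wrote 60 drugs, 408 positive edges to .

$ gnnddi train --drugs drugs.tsv --edges edges.tsv --strategy edge \
      --seed 7 --epochs 50 --checkpoint model.json
final train loss 0.1506, best val loss 0.4268 -> model.json
```

`d0006` (`O=[N+]([O-])OCC1CCCCC1`) carries a nitrate ester, `d0002`
(`NS(=O)(=O)c1cccnc1`) a sulfonamide — a planted interacting pair —
while `d0009` (`Nc1cccnc1`) carries only an amine:

```
$ gnnddi predict --checkpoint model.json --drugs drugs.tsv \
      --pairs pairs.tsv --out preds.tsv
$ cat preds.tsv
drug_x  drug_y  probability
d0006   d0002   0.998797
d0006   d0009   0.034479
```

The model separates the rule-driven pair (p ≈ 0.999) from the inert one
(p ≈ 0.034).  Asking *why*:

```
$ gnnddi explain --checkpoint model.json --drugs drugs.tsv \
      --pair d0006 d0002 --out-prefix attr
best layer pair: d0006 k=5, d0002 k=5 (score 180.0712)
$ head -5 attr.tsv
drug_id layer  atom_index  element  weight
d0006   5      0           O        0.4690
d0006   5      1           N        0.0325
d0006   5      2           O        0.4807
d0006   5      3           O        0.0174
```

Roughly 98% of d0006's attribution weight sits on the four nitrate
atoms (O–N(=O)–O⁻ plus the ester oxygen); the cyclohexane scaffold is
weighted near zero.  The attention readout has localized the functional
group that the labeling rule actually used.

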