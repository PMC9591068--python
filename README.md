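# crossdti

Interpretable cross-attention networks for drug–target interaction
(DTI) prediction from raw sequences: the drug as a SMILES string, the
target as an amino-acid sequence, and a binary interacts/does-not
label. The package is aimed at computational chemists and ML
practitioners who want a fully inspectable, CPU-trainable
implementation of cross-attention DTI modeling — including the
statistical machinery for asking whether the attention weights mean
anything biologically — rather than a black-box benchmark script.

## The model

Both sequences are tokenized (characters, SELFIES words, or mined
frequent-consecutive-subsequence (FCS) tokens), label-encoded to fixed
caps (50 drug / 545 protein positions), and embedded (learned token +
position tables, hidden size 384, or one-hot). A multi-head
cross-attention layer (h = 4 heads, per-head width d = 96) computes,
for the protein side,

    Q_i = Y^P W_i^Q,   K_i = Y^D W_i^K,   V_i = Y^D W_i^V
    A_i = softmax(Q_i K_i^T / √d) V_i
    C^P = concat(Q_1…Q_h) + concat(A_1…A_h) W_0

and symmetrically C^D for the drug. A CNN decoder (two conv–ReLU–
pool–dropout blocks and a linear layer) turns the selected context
matrix into an interaction probability. Architectures: `CA_DP`,
`CA2_DP`, `CA3_DP`, `CA_DP_FCL`, `SA_DP`, `CA_D`, and the default
`CA_P` (cross-attention, depth 1, protein context, CNN).

For interpretability, the protein-query attention weights are
head-averaged, expanded to residue × atom resolution, and the top-30
cells ("attention sites") are compared against annotated binding
residues. A permutation null — random binding residues of the same
count per protein, 10,000 iterations — turns the observed mean
consistency number into a z-score.

The network and its training loop (Adam, binary cross-entropy,
best-validation-PRAUC model selection) run on a small reverse-mode
autodiff engine over NumPy included in the package; every operation is
finite-difference-tested. See `docs/methods.md` for assumptions,
defaults and limitations.

## Worked example

```python
import numpy as np
from crossdti import (DTIClassifier, SyntheticSpec, generate,
                      split_dataset, analyze_sites)

samples = generate(SyntheticSpec(n_pairs=2000, noise_rate=0.05, seed=1))
dataset = split_dataset(samples, seed=1)

def xy(split):
    ss = dataset.subset(split)
    return ([(s.drug_smiles, s.protein_seq) for s in ss],
            np.array([s.label for s in ss]))

X_train, y_train = xy("train")
X_valid, y_valid = xy("valid")
X_test, y_test = xy("test")

clf = DTIClassifier(architecture="CA_P", scheme="fcs",
                    max_len_protein=96, max_vocab_drug=200,
                    max_vocab_protein=400, max_epochs=10, random_state=1)
clf.fit(X_train, y_train, validation_data=(X_valid, y_valid))
print(clf.evaluate(X_test, y_test))

annotated = [s for s in dataset.subset("test")
             if s.binding_sites and s.label == 1][:160]
maps = clf.attention_maps([(s.drug_smiles, s.protein_seq)
                           for s in annotated])
result = analyze_sites([(m, s.binding_sites)
                        for m, s in zip(maps, annotated)],
                       k=30, iterations=10000, seed=1)
print(f"consistency {result.experimental_mean:.2f} "
      f"(null {result.null_mean:.2f} ± {result.null_sd:.3f}), "
      f"z = {result.z:.1f}")
```

Output (about 4 minutes on one CPU core):

```
MetricSet(SN=0.9444444444444444, SP=0.7342995169082126, PR=0.7727272727272727, F1=0.85, ROCAUC=0.9120431366808178, PRAUC=0.8815143321310435)
consistency 29.09 (null 2.11 ± 0.362), z = 74.6
```

The synthetic benchmark plants an interaction rule — label 1 iff a
drug SMILES motif and an 8-residue protein motif co-occur, with 5%
label noise — and annotates the protein motif residues as binding
sites. ROCAUC 0.91 means the model recovered the planted conjunction
from sequence pairs alone (label noise caps the achievable ROCAUC at
about 0.95). The consistency number says that, of each pair's top 30
attention sites, 29 on average sit on annotated binding residues,
against 2.1 expected under random placement — z = 74.6 — which is the
package's testable restatement of attention-weight interpretability.

The same workflow is available from the shell:

```bash
crossdti simulate --n-pairs 2000 --seed 1 --out dti.tsv --sites sites.tsv
crossdti train --data dti.tsv --out ckpt \
    --max-epochs 10 --max-len-protein 96 \
    --max-vocab-drug 200 --max-vocab-protein 400
crossdti evaluate --model ckpt --data dti.tsv
crossdti interpret --model ckpt --data dti.tsv --sites sites.tsv \
    --out report.json
```

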