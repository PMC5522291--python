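# m5cpred

Sequence-based prediction of RNA 5-methylcytosine (m⁵C) sites.

m⁵C is a post-transcriptional modification of cytosine that regulates RNA
metabolism in eukaryotes and prokaryotes; determining which C residues of a
transcript can be modified by experiment alone is slow and expensive.
`m5cpred` is for computational biologists who want a reproducible,
sequence-only classifier for candidate C sites — with the full pipeline
(window extraction, encoding, ensemble classification, evaluation) exposed
as a library of scikit-learn-compatible estimators plus a small CLI.

## Method

Each candidate cytosine is represented by its (2ξ+1)-nt window
**R**<sub>ξ</sub>(C) = N₋ξ … N₋₁ C N₊₁ … N₊ξ (default ξ=20, i.e. 41 nt;
windows running past a sequence end are completed by replicating the
terminal residue).  A window of length *L* is encoded through its *L*−1
overlapping dinucleotides: ten physical-chemical dinucleotide properties
(helical step geometry and nearest-neighbour thermodynamics, standardized
to mean 0 / SD 1 over the 16 dinucleotides) each give a numeric profile
P<sub>m</sub>(D₁ … D<sub>L−1</sub>), and the feature vector collects lagged
auto- and cross-covariances for lags g = 1…λ:

    AC(m, g)       = 1/(L−1−g) · Σᵢ (Pₘ(Dᵢ) − P̄ₘ)(Pₘ(Dᵢ₊g) − P̄ₘ)
    CC(μ₁, μ₂, g)  = 1/(L−1−g) · Σᵢ (P_μ₁(Dᵢ) − P̄_μ₁)(P_μ₂(Dᵢ₊g) − P̄_μ₂),  μ₁ ≠ μ₂

giving Ω = 10λ + 90λ = 100λ components (500 at the default λ=5) — a pseudo
dinucleotide composition carrying sequence-order information beyond plain
k-mer counts.  The classifier is a 100-tree random forest with a
22-dimensional random subspace per split; the score of a window is the
fraction of trees voting positive, thresholded at 0.5.  Performance is
reported as sensitivity, specificity, accuracy and the Matthews correlation
coefficient, parameterized by misclassification counts
(Sn = 1 − N₋⁺/N⁺, Sp = 1 − N₊⁻/N⁻, …), under jackknife (leave-one-out) or
stratified k-fold cross-validation, with ROC/AUC over the pooled
out-of-fold scores.

## Worked example

```python
from m5cpred import (SimConfig, simulate_benchmark, encode_dataset,
                     ForestConfig, kfold)

# a seeded synthetic benchmark with the real benchmark's structure:
# 475 positives, 1,425 negatives, 41-nt windows centered on C
dataset = simulate_benchmark(SimConfig(seed=1))
X, y, encoder = encode_dataset(dataset, lam=5)      # 1900 x 500 matrix
scores, report = kfold(X, y, k=10,
                       config=ForestConfig(n_trees=100, subspace_dim=22, seed=1))
print(report.to_dict())
```

prints (seed 1):

```
{'n_pos': 475, 'n_neg': 1425, 'fn': 117, 'fp': 16,
 'sn': 0.7537, 'sp': 0.9888, 'acc': 0.93, 'mcc': 0.8086, 'auc': 0.8981}
```

Read: of 475 true sites, 117 were missed (Sn 0.75); of 1,425 non-sites, 16
were called positive (Sp 0.99).  The asymmetry — high specificity, lower
sensitivity — is characteristic of an unweighted forest on 1:3 imbalanced
data.  MCC (0.81) summarizes both error types on a −1…1 scale.

The same workflow from the shell:

```sh
m5cpred simulate --seed 1 --out-prefix bench
m5cpred cv bench.tsv --mode kfold --k 10 --seed 1
m5cpred train bench.tsv --seed 1 --out model.joblib
m5cpred predict model.joblib transcripts.fasta > sites.tsv
```

`predict` scans every C in the input FASTA (DNA is converted T→U), extracts
its 41-nt window, encodes, and emits one `seq_id  position  score  label`
row per site.

## Layout

| module | contents |
|---|---|
| `m5cpred.windows` | window extraction, benchmark assembly, FASTA/TSV IO |
| `m5cpred.properties` | the 10×16 dinucleotide property table (swappable TSV) |
| `m5cpred.encoding` | k-mer composition, AC/CC, `PseDncEncoder` transformer |
| `m5cpred.forest` | `VoteForestClassifier`, training, model persistence |
| `m5cpred.evaluate` | confusion counts, Sn/Sp/Acc/MCC, jackknife/k-fold, ROC |
| `m5cpred.simulate` | seeded synthetic benchmark generator |
| `m5cpred.cli` | the `m5cpred` command |

See `docs/methods.md` for modelling assumptions, parameter defaults and
limitations.
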