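# kascade

Prediction and analysis of **lysine acetylation sites** in human proteins
with a **cascade of balanced SVM classifiers**.

Acetylation of lysine side chains is a reversible post-translational
modification central to chromatin regulation and metabolism. Predicting
which lysines are acetylated from sequence and structure is a heavily
imbalanced problem: curated data contain roughly ten non-acetylated lysines
per acetylated one, so a single SVM trained on everything collapses to the
majority class, while a single SVM on a balanced undersample throws away
most of the negative information. `kascade` implements the cascade
solution: train a balanced RBF-SVM layer, keep the decision-value threshold
T_i at the ceil(0.95·M)-th largest *positive* training score, discard every
negative scoring below it, retrain on the hardest surviving negatives, and
repeat until fewer than 5% of the original negative pool can be removed. A
sample is predicted positive only if it clears **every** layer:

    cascade = {(S_1, T_1), ..., (S_n, T_n)},   positive  <=>  Deci_i(x) >= T_i  for all i

Around the classifier the package provides:

* **Feature encoding** of 19-residue windows (632 named dimensions):
  physicochemical property profiles (PCP, 72), PSI-BLAST PSSM scores (380),
  auto-covariation at lags 1–2 (AC, 8), residue composition (RC, 20),
  DSSP secondary-structure one-hots (SS, 133) and accessible surface area
  (ASA, 19).
* **Two-step feature selection**: greedy mRMR (MID) ranking to the top 300,
  then incremental feature selection maximising validation MCC.
* **Evaluation**: Sn, Sp, Acc, MCC (MCC ≡ Pearson correlation of the binary
  label vectors).
* **Descriptive site analyses**: positional property profiles, information
  entropy, composition bias with two-proportion z-tests, secondary-structure
  frequencies F_i = N_i/N, and ASA histograms.
* A **synthetic data generator** that emits complete bundles (FASTA, site
  tables, ASCII PSSMs, structure annotations) with planted class contrasts,
  so the entire pipeline is testable offline.

See `docs/methods.md` for the full model description and design choices.

## Worked example

Simulate a dataset, train, and evaluate — all from the shell:

```bash
kascade simulate --out demo --seed 3 --split 0.6,0.2,0.2
kascade encode --bundle demo/train --out train.tsv
kascade encode --bundle demo/validation --out val.tsv
kascade encode --bundle demo/test --out test.tsv
kascade select --train train.tsv --val val.tsv --out-prefix sel
kascade train --features train.tsv --model cascade.joblib --selected sel.selected.txt
kascade predict --model cascade.joblib --features test.tsv --out pred.tsv
kascade evaluate --truth demo/test/sites.tsv --pred pred.tsv --out metrics.tsv
```

which prints (seed 3):

```
wrote bundle with 200 positive / 2000 negative sites to demo
encoded 1348 samples x 632 features -> train.tsv
selected 45 features (validation MCC 0.6004)
trained cascade with 3 layers -> cascade.joblib
wrote 441 predictions to pred.tsv
Sn 97.30%  Sp 76.24%  Acc 78.00%  MCC 0.4452
```

Reading: of the held-out test lysines (on proteins never seen in training),
97% of true acetylation sites are recovered (Sn) while 76% of
non-acetylated lysines are correctly rejected (Sp); MCC 0.45 summarises
both under the 10:1 imbalance. For contrast, a single SVM trained on the
full imbalanced pool (`kascade train --method single-all`) predicts almost
everything negative (Sn ≈ 0, Sp ≈ 100%) — the failure mode the cascade
exists to fix.

The same pipeline runs on real data by pointing `encode` at your own
FASTA + site TSV + PSI-BLAST ASCII PSSMs + DSSP/TSV structure annotations,
and `--config` at a YAML with a real AAindex1 file and accessions.

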