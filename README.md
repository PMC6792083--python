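# streamfdr

Online false discovery rate (FDR) control for hypothesis streams and growing
data repositories.

Public data repositories — mouse-knockout phenotyping databases, chemical–
genetic screening collections — accumulate hypothesis tests over time. Each
new batch of p-values must be judged as it arrives, without knowing future
p-values or the eventual number of tests, and a published decision must never
change afterwards. Fixed significance cutoffs (e.g. declaring hits at
P < 0.0001) do not adapt to the data and provide no error guarantee, while
recomputing an offline procedure like Benjamini–Hochberg on every release
silently rewrites past decisions. `streamfdr` implements the *online* FDR
procedures that solve this: for each test `i` an adjusted threshold
`alpha_i` is computed from past decisions only, `H_i` is rejected when
`p_i <= alpha_i`, and the FDR — the expected fraction of rejections that are
false — is controlled at the target level `alpha` across the whole growing
family.

Implemented procedures:

- **LOND** — thresholds `alpha_i = alpha * gamma_i * (D(i-1) + 1)` scale a
  spending sequence by the number of discoveries so far; a
  harmonic-corrected variant is valid under arbitrary dependence.
- **LORD 1, 2, 3 and LORD++** — generalized alpha-investing rules: testing
  spends alpha-wealth, each discovery earns some back, and thresholds depend
  on the wealth and the times since past discoveries
  (e.g. LORD 2: `alpha_i = gamma_i * w0 + b0 * sum_j gamma_{i - tau_j}`).
  LORD++ dominates LORD 2, which dominates LORD 1; a dependence-safe LORD
  variant is included.
- **Alpha-spending** — the Bonferroni-like rule `alpha_i = alpha * gamma_i`,
  valid under any dependence.
- **Offline benchmarks** — Benjamini–Hochberg, Benjamini–Yekutieli, and
  fixed-threshold testing, for comparison.

Plus a repository wrapper (date-batched ordering with reproducible
within-batch randomization; append-only re-analysis that provably never
perturbs earlier results) and a Monte-Carlo harness that verifies empirical
FDR control on synthetic p-value streams. See `docs/methods.md` for the full
model description and design rationale.

## Worked example

A small repository CSV (`id,date,pval`, dates ISO `YYYY-MM-DD`):

```csv
id,date,pval
geneA,2019-01-10,0.00002
geneB,2019-01-10,0.31
geneC,2019-01-10,0.0006
geneD,2019-02-04,0.0071
geneE,2019-02-04,0.64
geneF,2019-03-22,0.0013
```

Analyse it with LORD++ at a 5% FDR level:

```bash
$ streamfdr run --input repo.csv --procedure lord_pp --alpha 0.05 --seed 42 --out results.csv
6 tests, 2 discoveries -> results.csv
$ cat results.csv
id,date,pval,index,alphai,R
geneB,2019-01-10,0.31,1,0.00027407721133284761,0
geneA,2019-01-10,2.0000000000000002e-05,2,5.9603128729791168e-05,1
geneC,2019-01-10,0.00059999999999999995,3,0.002517460110370455,1
geneE,2019-02-04,0.64000000000000001,4,0.0033194185246319527,0
geneD,2019-02-04,0.0071000000000000004,5,0.0010887104925829333,0
geneF,2019-03-22,0.0012999999999999999,6,0.00091857942802449572,0
```

The three January tests were shuffled into a reproducible random order
(seeded by `(42, 2019-01-10)` — appending later batches can never reshuffle
them); `index` is the resulting stream position. `alphai` is each test's
adjusted threshold and `R` the decision. geneA's tiny p-value is the first
discovery; the threshold then jumps (0.0025 at position 3) because a recent
discovery earned alpha-wealth back — geneC becomes the second discovery.
geneD and geneF would both pass an unadjusted 0.01 cutoff but are *not*
discoveries at the thresholds that 5% FDR control allows. A JSON sidecar
(`results.meta.json`) records the procedure, alpha, w0, gamma kind and seed.

When the repository grows, extend the analysis without touching history
(new records must be dated after the last analysed batch):

```bash
streamfdr update --previous results.csv --input repo_v2.csv --out results_v2.csv
```

The first six rows of `results_v2.csv` are byte-identical to `results.csv`;
the wrapper recomputes from scratch and verifies this before writing.

The same analysis in Python:

```python
>>> from streamfdr import ProcedureConfig, read_records_csv, run_repository
>>> cfg = ProcedureConfig(alpha=0.05, variant="lord_pp")
>>> result = run_repository(read_records_csv("repo.csv"), cfg, seed=42)
>>> int(result.frame["R"].sum())
2
```

Other subcommands: `streamfdr sequence` (export a spending sequence),
`streamfdr compare` (discovery counts per procedure, including BH/BY and
fixed thresholds), `streamfdr simulate` (Monte-Carlo FDR/power estimates).

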