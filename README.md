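# netphase

Recover core community structure and detect phase-transition epochs in
sequences of weighted network snapshots.

Each snapshot `A(t)` is decomposed independently as

```
A(t) = L(t) + S(t) + E(t)
min ||L||_* + gamma ||S||_1 + alpha ||E||_F^2   s.t.  A = L + S + E
```

via an alternating splitting augmented Lagrangian solver (closed-form
dense-noise update, soft-thresholding for the sparse part, singular value
thresholding for the low-rank part, multiplier ascent). Phase transitions
are located by monitoring the *thresholded rank* (number of singular values
above a threshold `h`) of window-averaged low-rank components, with
recursive zoom-in to finer windows. Between transitions, community
structure is read off the segment-averaged low-rank matrix by spectral
clustering. Scalar diagnostics (modularity, relative polarization, per-node
variation) and three synthetic generators (factor model, SBM, weighted SBM)
plus a Kuramoto coupled-oscillator simulator are included for validation.

## Library overview

| module                 | contents |
|------------------------|----------|
| `netphase.types`       | `WeightedNetwork`, `TemporalNetwork`, `pad_to_union`, solver config/result types |
| `netphase.decompose`   | `asalm_decompose`, `decompose_sequence`, `svt`, `soft_threshold`, `default_beta` |
| `netphase.tuning`      | alpha grid over `(0.5, 10)/sqrt(N + sqrt(8N))`, rank/inconsistency scan, `select_alpha` |
| `netphase.phasescan`   | window partitioning, thresholded rank, `select_h`, multi-level `scan` |
| `netphase.community`   | spectral clustering of segment averages, label matching, misclassification & recovery scoring |
| `netphase.metrics`     | `modularity`, `relative_polarization`, `variation` |
| `netphase.netgen`      | factor/SBM/WSBM generators and the named scenario presets with planted truth |
| `netphase.kuramoto`    | degree-constrained support graphs, Euler integration, similarity networks |
| `netphase.io`          | Matrix Market directory and temporal edge-list TSV readers/writers |
| `netphase.pipeline`    | `RunConfig` / `run_pipeline` end-to-end driver |
| `netphase.experiments` | reproducible preset experiments used by the acceptance suite |

## CLI

```bash
# generate a preset scenario (TSV snapshots + truth.json)
netphase simulate --preset three-model-wsbm --seed 7 --out sim/

# end-to-end: decompose, tune alpha, scan, cluster, score
netphase run --input sim/snapshots.tsv --alpha auto --out results/

# individual stages
netphase decompose --input sim/snapshots.tsv --alpha 0.1 --out dec/
netphase tune-alpha --input sim/snapshots.tsv --step 0.015 --times 20 --out scan.json
netphase scan --input dec/ --levels auto --h auto --out report.json
netphase communities --l-dir dec/ --report report.json --out labels.csv
netphase metrics --input sim/snapshots.tsv --labels labels.csv --out metrics.csv
```

Input formats: a directory of per-snapshot Matrix Market files (lexicographic
time order) or a 4-column TSV `t<TAB>i<TAB>j<TAB>w` (1-based times,
undirected edges listed once). All time indices, epochs and segments are
reported as closed 1-based intervals.

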