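# matrixbank

Rule-based figural matrix item banking: generate uniquely solvable 3×3
matrix-reasoning items from six construction rules, assemble anchor-linked
multi-form banks, render them to SVG, simulate construction-based responses
under a two-parameter logistic (2PL) model, calibrate and equate the forms,
and produce a classical psychometric report.

## What it does

- **Item generation** (`matrixbank.elements`, `.rules`, `.items`, `.solver`):
  20 construction elements (5 shape families × 4 rotation orbits) and six
  row-wise construction rules — addition, subtraction, disjunctive union,
  intersection, rotation, completeness. A solver enumerates every rule
  hypothesis consistent with the visible cells and certifies that each
  generated item has a unique solution. Responses are scored by exact match
  of the selected element set.
- **Bank assembly** (`.bank`, `.render`): the default configuration builds
  220 validated items (20/50/80/50/20 with 1–5 rules, marginal rule-kind
  usage targets honoured exactly), splits them into 10 test sets of 22, and
  interleaves the same 6 anchor items (rule counts 1, 2, 3, 3, 4, 5) into
  every form — 28 scored tasks per form, plus 2 practice items. Items render
  deterministically to SVG (stem, full, and 20-element response panel).
- **Simulation** (`.simulate`): seeded 2PL response matrices for any
  multi-form design with missing-by-design structure, plus misfit injection
  (random responder / reversed item) for exercising the diagnostics.
- **Calibration** (`.irt`): 2PL marginal maximum likelihood via EM on a
  61-node quadrature grid with a Normal(0, 1) prior, EAP ability scoring,
  infit/outfit mean squares with Wilson–Hilferty standardisation, and a
  two-pass common-slope misfit screen (mean square outside [0.75, 1.33]
  with |z| ≥ 1.96 flags an item).
- **Equating** (`.equating`): mean-sigma (default) or mean-mean linking of
  separately calibrated forms through the common anchors;
  b\* = A·b + B, a\* = a / A.
- **Reporting** (`.report`): item difficulty and corrected item-total
  correlations per test set, Cronbach's alpha, one-way ANOVA with ω²,
  outlier-trimmed correlations (±3 SD), and OLS regression of item
  difficulty on the six rule indicators with an incremental F against the
  rule-count-only baseline.

## CLI

```sh
matrixbank generate --seed 42 --out bank.json         # 220-item default bank
matrixbank render --bank bank.json --item M001 --mode stem --out svg/
matrixbank simulate --bank bank.json --n 2560 --seed 7 --out responses.csv
matrixbank fit --responses responses.csv --out params.csv --drop-misfit
matrixbank equate --params F01.csv --params F02.csv \
    --anchors anchors.txt --method mean_sigma --out equated.csv
matrixbank report --responses responses.csv --params equated.csv \
    --bank bank.json --out report/
matrixbank demo --seed 7 --out demo/                  # full pipeline, ~20 s
```

`generate` accepts a YAML config mirroring `BankConfig` (rule-count
distribution, set composition, anchor composition, usage targets, seed).
Exit codes: 0 success, 2 usage/configuration, 3 data/parse, 4 numerical.

The demo chains generate → split/anchor → simulate (default n = 2560 over
10 forms) → per-form calibration → misfit exclusion → mean-sigma equating →
report, writing every artifact and a digest manifest to one directory;
identical seeds give byte-identical outputs.

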