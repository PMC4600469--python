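# phconn

Whole-brain connectivity-pattern analysis for pharmacological fMRI
(phMRI): tapered-window correlation graphs on parcellated BOLD time
series, density-normalised weighted degree centrality, Gaussian-process
classification between drug conditions with leave-one-subject-out
cross-validation and permutation inference, discriminative weight maps
(g-maps), and ordinal Gaussian-process regression across rank-ordered
conditions.

The package is aimed at researchers asking whether an acute drug
challenge (e.g. an NMDA-receptor antagonist) reorganises the *pattern* of
whole-brain functional connectivity — not just signal amplitude — in a
repeated-measures design where each participant is scanned under several
drug conditions. Because such datasets are rarely public, the package
ships a first-class synthetic cohort generator with planted, recoverable
connectivity effects, so every stage of the pipeline can be validated
against known ground truth.

## The method

For each subject × condition, a parcellated node-by-time matrix (default:
116 AAL regions, 150 volumes at TR = 2 s) is nuisance-regressed (mean CSF,
mean WM, six motion parameters, plus intercept) and band-pass filtered to
0.01–0.1 Hz. A Gaussian taper

    W(t) = exp(−t² / 2s²),   t ∈ {−T/2, …, T/2},  s = T/6

with T = 120 volumes slides in steps of s (centers s/2 + k·s,
boundary-clipped), producing eight windows per 150-volume condition. Within
each window the taper acts as observation weights in a weighted Pearson
correlation between all node pairs, giving one signed adjacency matrix
A per window. Each node's weighted degree centrality

    DC(i) = Σ_{j≠i} a_ij

is normalised by the network density (mean |a_ij| off the diagonal), and
the subject-wise mean-centred DC vectors from all windows of the two
contrasted conditions form the feature set (labels +1/−1).

Classification uses a Gaussian-process classifier with probit likelihood,
linear kernel k(x, x′) = θ·(x·x′) and Laplace-approximate inference; θ is
set by maximising the approximate marginal likelihood. Cross-validation
folds are whole participants (LOSO); a held-out subject's window
probabilities are averaged per condition and thresholded at 0.5.
Significance comes from within-subject label permutations with the
add-one estimator p = (1 + #{perm ≥ observed}) / (n_perm + 1), Bonferroni
corrected across contrasts. For significant contrasts the linear kernel's
dual form w = θ Xᵀα yields a per-node discriminative weight map exported
with MNI centroids. Ordinal GP regression (cumulative probit with ordered
thresholds) tests for an ordinal progression across ≥3 rank-ordered
conditions via LOSO confusion matrices.

## Worked example

```python
import numpy as np
from phconn import (CohortConfig, generate_cohort, assemble_features,
                    ContrastAnalysis)
from phconn.pipeline import _preprocess_runs, compute_dc_map

cfg = CohortConfig(conditions=("saline", "ketamine"), effect_size=2.0, seed=1)
cohort, truth = generate_cohort(cfg)                  # 16 subjects x 2 conditions
runs = _preprocess_runs(cohort.runs, cohort.nuisance, 0.01, 0.1)
dc_map = compute_dc_map(runs)                         # (subject, condition) -> 8 x 116 DC
fs = assemble_features(dc_map, "ketamine", "saline", truth.node_labels)

res = ContrastAnalysis(fs).fit()
res.permutation_test(n_perm=99, seed=1)
print(res.summary())
```

prints

```
LOSO GP classification: ketamine (+1) vs saline (-1)
  subjects            : 16
  test items          : 32
  accuracy            : 100.00 %
  permutation p       : 0.01 (99 permutations)
```

i.e. with a strongly planted covariance shift (cortical couplings
attenuated, subcortical/cerebellar couplings amplified; `effect_size=2`)
every one of the 32 subject × condition items is classified correctly and
no permuted labelling does as well, so p attains its minimum 1/(99+1).
`res.gmap(...)` then returns the per-node weight map, whose positive nodes
(higher centrality under ketamine) are the planted subcortical/cerebellar
gainers.

The same pipeline is scriptable from the shell:

```bash
phconn simulate --out cohort/ --seed 1 --effect-size 2.0
phconn classify --manifest cohort/manifest.json \
    --condition-a ketamine --condition-b saline --n-perm 99 --seed 1
phconn run-all --config study.yaml
```

## Layout

- `phconn.synthetic` — cohort generator with planted covariance effects
  and ground-truth centrality deltas
- `phconn.preprocess` — nuisance regression, band-pass, NIfTI parcellation
- `phconn.features` — taper, windows, weighted correlations, DC features
- `phconn.gp` — Laplace GP classification and ordinal GP (Model/Results)
- `phconn.inference` — LOSO, permutation tests, g-maps, univariate tests
- `phconn.pipeline` / `phconn.cli` — end-to-end orchestration and CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
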