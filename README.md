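# dynfc

Dynamic time-varying triple-network interaction analysis, as a tested,
reusable pipeline. Given per-subject four-component network time series
(salience, left/right frontoparietal, default mode), the package:

1. computes **exponentially tapered sliding-window correlations**
   (`dynamic_connectivity`),
2. identifies **group-specific latent brain states** by subsampled
   consensus k-means, with the number of states chosen by a majority vote
   of cluster-validity indices (`brain_states`),
3. computes **dwell-time** statistics and the **network interaction index
   (NII)** — the Fisher-z SN–FPN coupling (L/R averaged) minus the
   Fisher-z SN–DMN coupling — per window, per state, and per subject
   (mean / variability / static) (`nii_metrics`),
4. runs **group statistics**: paired and Welch t-tests with Cohen's d,
   Bonferroni correction, brain–behavior Pearson correlations, and an OLS
   model predicting treatment-induced attention change (`group_stats`),
5. performs **CART classification** of groups from (NII mean, NII SD)
   under leave-one-out cross-validation with a no-information-rate
   binomial test (`classification`).

Because the study's fMRI data are not deposited, a first-class
**synthetic cohort generator** (`synthetic_data`) produces network time
series from a hidden Markov chain with group-specific state counts,
self-transition probabilities (controlling dwell time), state covariances
engineered to hit target NII values, and behavioral scores linearly
coupled to connectivity metrics — so every stage can be validated against
known ground truth.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the recovery experiments (state-count,
dwell-time, NII-variability and regression recovery, plus exact oracle
checks); the remaining files are per-module unit and property tests.

## CLI

The `dynfc` entry point runs the pipeline from a single YAML config
(groups to simulate, window spec, clustering spec, classifier and
statistics settings):

```bash
dynfc run-all -c config.yaml          # simulate → windows → states →
                                      # metrics → compare → classify → predict
dynfc simulate -c config.yaml         # or any individual stage
```

All artifacts are plain text (TSV/CSV/JSON) under the configured output
directory, each carrying a provenance header (version, config hash,
seed). See `tests/test_cli.py::demo_config` for a complete config
example.

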