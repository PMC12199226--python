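# polysorb

Quantifying and modelling **protein adsorption on polymer microarrays**
from targeted-DIA LESA-MS/MS data.

High-throughput polymer screens print hundreds of candidate chemistries as
a microarray, incubate them in a protein-containing medium (here the four
proteins of Essential 8 stem-cell medium: insulin, transferrin, FGF2,
TGFβ1), digest the adsorbed protein on-surface, and read each spot out by
liquid extraction surface analysis (LESA) mass spectrometry. `polysorb`
implements the computational half of such a screen for analysts who want a
tested, scriptable pipeline:

- **In-silico tryptic digestion** with the Keil proline rule and
  disulfide-aware free-peptide determination (mature insulin releases
  exactly one free tryptic peptide, GFFYTPK — the classic digestion probe).
- **Targeted-DIA identification**: MS2 scans (1 m/z isolation windows)
  matched against a spectral library by union-vector cosine similarity,
  accepted at cos θ > 0.95 with ≥ 5 matched fragments at 0.02 Da.
- **MS1 label-free quantification**: per-ion extracted intensities at
  ±10 ppm, summed per protein and log10-transformed; missing intensities
  imputed at the 1000-count peak threshold; triplicate spots aggregated by
  geometric mean and filtered at replicate SNR > 1.5.
- **Fragment descriptors**: atom-signature substructure counts (e.g.
  `C(CCCO)`, `C(C(CFF)C(FFF)FF)`) computed from monomer structures, plus
  ingestion of external descriptor tables.
- **Sparse modelling**: per protein, LASSO feature selection (5-fold CV,
  1-SE rule) followed by sparse multiple linear regression fitted by
  expectation maximization (Laplace prior as a normal scale mixture),
  evaluated over 50 random 80/20 train/test splits with RMSE and R², and
  summarised as signed, ranked coefficients.
- **A ground-truthed simulator** generating full DIA acquisitions (cycles
  of 10 MS2 scans + 1 MS1 scan over m/z 400–900) whose signals encode a
  known sparse-linear adsorption truth, so every stage is testable without
  external downloads.

The modelling model is, per protein p with adsorption response
y = log₁₀(geometric-mean summed peptide intensity) and descriptor matrix X:

    y = β₀ + Σ_j β_j x_j + ε,   with β sparse.

β is estimated by LASSO selection followed by MAP-EM under a Laplace
prior: E-step u_j = λ/|β_j|, M-step (XᵀX + diag(u))β = Xᵀy, which is a
majorize–minimise scheme for ½‖y − Xβ‖² + λ‖β‖₁ whose objective is
monotone (asserted at every iteration). See `docs/methods.md` for the full
account.

## Worked example

Fit the adsorption model on a simulated 70-polymer screen with 5 true
descriptors among 120:

```python
import numpy as np
from polysorb import SimulationConfig, generate_polymer_library
from polysorb import ModelConfig, ProteinAdsorptionModel

cfg = SimulationConfig(n_polymers=70, seed=5)
X, truth = generate_polymer_library(cfg)
rng = np.random.default_rng(6)
y = truth.true_log_adsorption["insulin"].to_numpy() \
    + rng.normal(0, cfg.noise_sd_log10, 70)

model = ProteinAdsorptionModel(X, y, ModelConfig(n_boot=50, seed=7),
                               protein="insulin")
boot = model.fit_bootstrap()
print(boot.summary())
```

prints

```
Bootstrap evaluation — insulin
  n polymers   : 70
  splits       : 50 × 80%/20%
  test RMSE    : 0.217 ± 0.048
  test R^2     : 0.983 ± 0.008
  significant features (selected in >50% of splits): 7
    frag_015                 mean coef -1.2248  freq 1.00  negative
    frag_022                 mean coef -0.9229  freq 1.00  negative
    frag_084                 mean coef -0.6112  freq 1.00  negative
    cont_01                  mean coef +0.4898  freq 1.00  positive
    frag_038                 mean coef +0.4153  freq 1.00  positive
    ...
```

Read: across 50 held-out splits the model predicts log10 adsorption with
RMSE 0.217 (the generator's noise floor is 0.15 log units) and test
R² 0.983. The five planted descriptors (`frag_015`, `frag_022`,
`frag_084`, `cont_01`, `frag_038`, true coefficients −1.27, −0.96, −0.73,
+0.57, +0.54) head the ranking with the right signs and magnitudes;
negative coefficients mark chemistry that suppresses adsorption.
`boot.plot_predictions()` and `boot.plot_coefficients()` draw the
corresponding panels.

The full chain — simulate spots, identify MS2 scans, quantify, filter,
model — runs from the shell:

```sh
polysorb run --seed 17 --out results/
polysorb simulate --seed 17 --polymers 10 --out fixtures/
polysorb match --run fixtures/poly000_r0.runtable.csv \
               --library fixtures/library.csv --out matches.csv
polysorb validate --config pipeline.toml
```

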