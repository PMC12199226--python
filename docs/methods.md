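# Methods

`polysorb` implements the computational workflow of a polymer-microarray
protein-adsorption screen read out by LESA-MS/MS (liquid extraction surface
analysis tandem mass spectrometry): targeted-DIA identification against a
spectral library, MS1 label-free quantification with replicate filtering,
and sparse linear modelling of adsorption against polymer fragment
descriptors. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic-data generator does and does not
emulate.

## Digestion model

Proteins are chains of 1-letter residues with optional disulfide
annotations. Trypsin cleaves C-terminal to K or R except before proline
(the Keil rule, matching sequencing-grade trypsin). Identification search
space allows up to 2 missed cleavages; "formed" free peptides use the
complete digest (0 missed cleavages), because with missed cleavages insulin
would also release GFFYTPKT and the single-free-peptide property that makes
insulin a digestion-efficiency probe would not hold. A peptide containing
any disulfide-bonded cysteine remains tethered to its partner chain and is
excluded from the free set; cross-linked species are not modelled because
the pipeline quantifies linear peptides only. No fixed or variable
modifications are applied (the on-surface protocol digests without
reduction/alkylation). All masses are monoisotopic; residue masses come
from pyteomics and the water (18.010565 Da) and proton (1.007276 Da)
constants live in one `MassTable` used by every m/z equation. b/y fragment
m/z follow the usual prefix/suffix sums; the complementarity identity
b_i + y_{n−i} = M + 2·m_H is exact by construction and asserted in tests.

The bundled fixture proteins are the four proteins of Essential 8 medium.
Insulin carries the exact mature human A/B chains and disulfide topology
(A6–A11, A7–B7, A20–B19); FGF2 and TGFβ1 carry standard mature sequences.
The transferrin entry is a synthetic surrogate sequence with realistic
tryptic-site density — nothing downstream depends on the true sequence,
only on a valid peptide source, and the surrogate is documented as such in
`polysorb.e8`.

## Identification

Each targeted MS2 scan is compared only against library entries whose
precursor m/z falls inside the scan's isolation window, taken half-open
[precursor − w/2, precursor + w/2) so boundary behaviour is deterministic
(w = 1 m/z by default). Peaks are paired greedily by ascending |Δm/z| with
one-to-one use and a 0.02 Da admission tolerance. Greedy pairing can in
principle differ from the matching that maximises pair count, but on
peptide-like spectra (sparse peaks over hundreds of m/z at a 0.02 Da
tolerance) conflict chains essentially never arise; equivalence with an
exhaustive oracle is verified on 1,000 random instances per run of the
acceptance suite.

The score is the cosine over the union vector: paired peaks contribute to
the cross term, unmatched peaks of either side contribute only to their
own norm. This is the conservative reading of "cosine correlation" — a
matched-only cosine is trivially 1.0 whenever any single pair matches,
which would make a 0.95 threshold meaningless. Matched-only vectorisation
and sqrt/log intensity weighting exist as options; defaults are union and
raw intensities. Acceptance requires cosine strictly greater than 0.95 and
at least 5 matched fragments. The per-scan winner is the highest-cosine
accepted entry, ties broken by matched-fragment count then lexicographic
peptide id. No FDR machinery: the library is targeted and tiny, and decoy
modelling belongs to the (out-of-scope) search-engine stage that builds
libraries from discovery data.

## Quantification

For each target ion, MS1 intensities within ±10 ppm of the target m/z are
summed per survey scan and the median over scans with at least one
in-window peak is taken — median rather than mean for robustness to
single-scan electrospray instability in a direct-infusion measurement. A
protein's intensity in a run sums only ions with an accepted
identification in that same run (identify-then-quantify). Missing peptide
intensities are imputed at the peak-intensity threshold of 1000 counts
*before* summation and before the log10 transform: imputation is stated at
the peptide level, and positivity is required for the log. Replicates are
aggregated by geometric mean on the linear scale (appropriate for
multiplicative replicate noise), and the replicate SNR — arithmetic mean
over sample (n−1) standard deviation of the linear-scale intensities — must
exceed 1.5 strictly for a polymer × protein value to enter modelling.
Whether SNR should be computed on linear or log10 intensities, and with
population or sample sd, is not uniquely determined by convention; linear
scale and sample sd are the defaults and both choices are configurable.

## Fragment descriptors

Signature descriptors are atom-centred canonical substructure strings:
the root element followed by sorted neighbour subtrees, e.g. `C(CCCO)` for
the central carbon of a tert-butyl alcohol at height 1, and
`C(C(CFF)C(FFF)FF)` at height 2 for the fluorine-rich carbon of a
−CF2−CF3 unit (each neighbour expands with its own neighbours, excluding
the edge back to the root, again sorted). Bond order is not encoded;
aromatic atoms may be lowercased (off by default). Counts per molecule
over the union of observed signatures form the descriptor matrix.
Signatures are computed on monomer structures at heights {1, 2}. Dragon
descriptors are a proprietary commercial set and are only ever ingested as
CSV; `count_tertiary_amines` is a structural proxy for the nRNR2 count
(non-aromatic N single-bonded to three carbons, amide nitrogens excluded)
used in synthetic studies only.

## Sparse modelling

Per protein, log10 geometric-mean adsorption is regressed on descriptors
in two steps.

**LASSO selection.** L1-penalised regression on internally standardized
columns, penalty chosen by 5-fold cross-validation with the 1-SE rule
(largest penalty within one standard error of the CV optimum). The 1-SE
rule biases toward sparsity, which is the stated purpose of the selection
step; the plain CV-minimum is available via configuration.

**EM sparse regression.** MAP estimation under a Laplace prior written as
a normal scale mixture. With standardized design X and centred response y,
the E-step computes per-coefficient weights u_j = λ/|w_j|; the M-step
solves (XᵀX + diag(u)) w = Xᵀy. This is a majorize–minimise scheme for

  J(w) = ½‖y − Xw‖² + λ Σ_j |w_j|,

so J is non-increasing across iterations; the implementation *asserts*
this every iteration and raises on violation. Coefficients whose magnitude
falls below 1e-8 are set exactly to zero and leave the active set, giving
exactly sparse fits. λ = σ̂·sqrt(2·n·log p) (universal-threshold scaling)
with σ̂ estimated from a ridge pilot fit; on noise-free data σ̂ ≈ 0 and the
fit reduces to OLS on the selected columns. A singular M-step system is
retried with 1e-10 ridge jitter. Iteration stops at max|Δw| < 1e-6 or 500
iterations. Coefficients are reported on the standardized scale so their
magnitudes are comparable across descriptors.

**Evaluation.** "50 bootstraps with an 80/20 split" is implemented as 50
repeated random splits without replacement (Monte-Carlo cross-validation):
fixed 80/20 proportions are incompatible with classical with-replacement
bootstrap sizing, and repeated splitting is the reading that yields
held-out metrics. With-replacement resampling of the training side is not
offered; selection can optionally be run once on all data (`lasso_once`),
but the default re-runs LASSO inside every split and computes
standardization statistics on the training rows only, so no information
leaks into the test metrics. RMSE and R² are computed on the held-out 20%,
R² about the test-split mean; a zero-variance test split records R² as
undefined (NaN) and is excluded from summaries. Feature importance across
splits is the selection frequency and the mean coefficient counting
unselected fits as zero; "significant" means selected in strictly more
than half of the splits.

## Synthetic-data generator

The generator defines the study conditions: 208 polymer chemistries in
triplicate, four target proteins, 120 descriptors of which 5 drive each
protein's log10 adsorption, DIA cycles of 10 MS2 scans (1 m/z isolation)
plus one MS1 survey over m/z 400–900, 10 cycles per 2-minute spot
acquisition. Descriptor values are Poisson(λ=1) counts (emulating sparse
signature counts) plus 10 continuous standard-normal columns. True effects
have magnitudes uniform in [0.5, 1.5] with random signs on a log10 scale,
around an intercept of 5 (so typical adsorbed "amounts" are ~10⁵ counts,
comfortably above the 1000-count imputation floor). Per-replicate amounts
add N(0, 0.15) log10 measurement noise, unit-mean lognormal replicate
noise with CV 0.2, and 10% dropout. MS2 scans cycle round-robin through
the targets — insulin through GFFYTPK at charges 1 and 2, the other
proteins through their top-5 free tryptic peptides with doubly charged
precursors inside the MS1 range — with lognormal fragment noise (CV 0.1)
and 5 uniform noise peaks; MS1 peptide peaks carry ±3 ppm uniform m/z
jitter on top of 30 background peaks. Per-ion response factors sum to 1
within each protein, so with all noise disabled the extracted, summed,
log10-transformed intensities reproduce the true log adsorption to
floating-point precision — the pipeline's exactness check.

What the generator does *not* emulate: isotope envelopes (quantification
extracts one monoisotopic m/z per ion, so envelopes add no testable
behaviour), chimeric precursors and co-isolation, electrospray drift
within a run, detector saturation, digestion kinetics, and correlated
descriptor structure (real signature counts are strongly collinear).
Passing tests therefore certify the pipeline's algebra and statistics
under the assumed noise model, not robustness to every instrument
pathology of real arrays.

Droplet geometry: the sessile digestion droplet is modelled as a spherical
cap, V = (π a³/3)(1−cos θ)²(2+cos θ)/sin³ θ. For a 1.4 mm spot (contact
radius 0.7 mm) at a 5.2° contact angle this evaluates to ≈ 24.5 nL; a
published figure of 0.19 nL for this geometry is not reproducible from the
stated closed form (the inputs behind it are unknown), so the utility
implements the geometry and documents the discrepancy rather than matching
that number.

## Problem sizes and determinism

Every stochastic component draws from `numpy` generators seeded from a
single configuration seed (stage seeds derive from it), so identical
configurations are bit-identical, including the on-disk fixture sets. The
test and acceptance runs use the study-scale design (208 polymers ×
3 replicates × 4 proteins) for the closure and rank-correlation checks,
and the 70-polymer/120-descriptor scenario with 50 splits × 20 seeds for
recovery of the planted model. Smaller fixtures (6–40 polymers) back the
unit tests.

## Known limitations

- mzML support is read-only and covers the centroided subset the pipeline
  consumes; vendor raw files are out of scope entirely.
- The union-vector cosine and the greedy pairing are a specific, documented
  reading of "cosine correlation"; scores are not comparable to tools that
  use matched-only dot products with intensity weighting.
- SNR filtering with few replicates (triplicate) is a coarse
  reproducibility gate; with n = 3 the sample sd is itself noisy.
- The EM penalty's universal-threshold scaling assumes roughly independent
  standardized columns; under heavy collinearity the LASSO step, not the
  EM refit, is what controls which of a correlated group survives.
- TGFβ1 may legitimately yield an empty or sparse quantification row when
  its peptides go undetected; the pipeline treats it as a fourth target
  whose model is simply skipped if too few polymers survive filtering.
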