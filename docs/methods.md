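# Methods

## Problem and model

Apocrine sweat is collected from the axilla in amounts that cannot be
standardized: every sample carries an unknown volume, so every measured
peak area is the "true" signal multiplied by a sample-specific dilution
factor shared by all lipids of that sample. On top of that sit
instrument drift over the injection sequence and analytical noise. The
package models all of this multiplicatively — the standard error model for
LC-MS peak areas, and the model under which probabilistic quotient
normalization (PQN) is the right estimator. For study sample *s* and lipid
*j*:

    area[s, j] = k_c(j) · (1 − p13)^nC(j) · c[s, j] · d_s · g_j(t_s) · ε

with class response factor `k_c`, monoisotopic fraction `(1 − p13)^nC`
(`p13 = 0.0107`, natural ¹³C abundance; `nC` molecular carbons),
true concentration `c`, dilution `d_s`, smooth drift `g_j` at injection
order `t_s` and log-normal noise `ε`.

PQN estimates `d_s` as the median over lipids of `area[s, j] / ref_j`,
where `ref_j` is the median spectrum of the study samples (QCs are excluded
from the reference so the pooled matrix does not bias the dilution
estimate). `lnPQN` is PQN followed by the natural logarithm; PQN runs
first because the quotient is a ratio of linear-scale intensities.

## Transition library

The theoretical MRM panel enumerates, per lipid class, all total
carbon/double-bond combinations (sphingolipids additionally iterate the
long-chain bases d16:0, d16:1, d18:0, d18:1 and d20:1 with a variable
N-acyl chain). Elemental formulas are assembled from class backbones plus
ester/amide-linked chains; ether classes (PCO, PEO) are treated as a single
alkyl/alkenyl class without O-/P- disambiguation, matching the annotation
level the chromatography can support. All chemistry — backbones, adducts,
product-ion rules, enumeration ranges — lives in
`src/sweatlipidomics/data/class_rules.yaml` and can be edited without
touching code. The shipped ranges produce 3,665 transitions. m/z values
are reported to 4 decimals; protonation uses 1.007276 Da. Deduplication is
on species identity + adduct, where sphingolipid identity includes the
long-chain base (two species sharing total composition but differing in
base are chemically distinct transitions and are both kept).

Retention-pattern verification fits `rt = a + b·carbons + c·double_bonds`
per class and flags observations with externally studentized residuals
above 3 in magnitude. The external (deletion) form is deliberate:
internally studentized residuals are bounded by √(n − p) and can never
reach 3 in small classes, which would make the check vacuous.

## Synthetic study

The generator reproduces the study design: 10 individuals × 3 days × 2
sides (60 study samples) in randomized order, a pooled QC at every 5th
position of the sample stream (15 QCs), 3 process blanks, and a 6-level
matrix-matched calibration series at the end of the run. QC areas are the
mean of the study samples' pre-dilution signals (a pooled aliquot) times
drift and QC noise; blanks carry only contamination (two fatty acids as
solvent residues plus one ceramide, also added to every other injection so
blank subtraction has something real to remove); calibration injections
carry one labeled standard per class at known concentrations.

Default parameters (all log-sd on the natural-log scale) and why:

| parameter | default | rationale |
|---|---|---|
| lipids per class | 240 total (Cer 61, TG 37, SM 23, PC 20, DG 17, FA 17, …) | detected-panel proportions |
| class median conc | 2·10⁻⁵ (FA) … 8·10⁻¹⁰ mol/L (LPE) | FA-dominated composition, >4 orders dispersion |
| base_log_sd | 1.0 | lipid-to-lipid spread within a class |
| individual_log_sd | 0.35 | sets CVg above CVi under lnPQN and drives clustering |
| day_log_sd | 0.20 | day-to-day biology shared by both sides |
| sample_log_sd | 0.25 | residual per-sample biology; without it the two sides of a day differ only by analytical noise and any side shift becomes trivially significant |
| side_log2_shift | 0.10 (≈7 %) on Cer/DG up, PC/PCO/PE/PEO down | side trends below the 15 % band, sub-significant against sample noise |
| dilution_log_sd | 0.50 | the un-standardizable sweat volume |
| drift_amplitude | 0.20, smooth per-lipid curves | within-run drift a QC-LOESS correction should remove |
| analytical_log_sd / qc_log_sd | 0.08 / 0.07 | repeatability; QC CV ≈ 7–8 % |
| calibration | 6 levels, 5-fold serial, top = 100 × class median | covers the study concentration range |

These variance components were chosen by variance arithmetic so the
synthetic study reproduces the qualitative ln→lnPQN pattern of the real
one (intra-individual and group CV roughly halve, QC CV unchanged, ~9+/10
individuals cluster, left/right trends not significant). The generator
emulates the statistical structure of the data, not the raw signals: no
chromatographic peak shapes, no missingness mechanism beyond blank
deficits, no batch structure (the study is a single randomized batch), and
lipid-wise independence of drift and noise. Tests passing on these data
show the pipeline's estimators recover the generating parameters under the
model's assumptions; they cannot certify behavior under real-data
violations of those assumptions (correlated drift, detector saturation,
peak-integration errors).

## Preprocessing

Stages run in fixed order: blank subtraction → QC-LOESS → QC-CV filter.

**Blank subtraction.** The mean of the process-blank replicates is the
blank level. Cells whose area does not exceed the blank are deficit
candidates; an analyte with more than five deficit *study* samples is
discarded, otherwise candidate cells are set to half the minimum positive
post-subtraction value of that analyte (the post-subtraction minimum is
used; the pre-subtraction reading would re-inflate values by the blank
level). QC/calibration deficits are imputed but do not count toward the
discard rule. Note the half-minimum rule is applied exactly as stated even
in pathological tables where the imputed value can exceed the original
cell.

**QC-LOESS.** Per analyte, QC area is regressed on injection order with a
locally weighted linear smoother (span 0.75 of the QCs, no robustness
iterations, linear interpolation between QC orders, flat extrapolation
beyond them). The fitted curve divided by the QC median is the drift
factor, clipped to [0.1, 10]; every injection is divided by its factor.
Analytes with fewer than 4 usable QCs pass through unchanged and are
logged.

**QC-CV filter.** Analytes with QC CV (sd/mean × 100) above 30 % are
excluded; survivor order is preserved.

## Statistics

CVs are always computed on the linear scale; the `lnPQN` condition divides
intensities by their PQN quotients first (QCs by their own quotients
against the study-sample reference). CVi aggregates the per-individual CVs
by an arithmetic mean. Log-scale CVs are not used anywhere — a CV% of
log-intensities has no interpretation, and QC repeatability in percent
refers to linear intensities.

Calibration curves are straight lines. `fit_calibration` defaults to
ordinary least squares; the pipeline builds class curves with 1/x²-weighted
least squares because over a three-order calibration range with
multiplicative noise the unweighted intercept is set by the top levels and
can rival the low-level areas, biasing low-abundance back-calculations by
tens of percent. Back-calculated values outside the level range are masked
and counted. The isotopic type-I correction multiplies the back-calculated
value by `(1 − p13)^(nC_std − nC_analyte)`; the type-II (isotopologue
overlap) correction is deliberately absent because chromatographically
resolved species do not coelute with their M+2 neighbours. Quantitation
runs on LOESS-corrected, blank-subtracted areas — not PQN-normalized ones:
reported concentrations refer to the injected extract, dilution included.

Multivariate views run on the transformed matrix after Pareto scaling
(centring + division by √sd) — both the `ln` and `lnPQN` branches are
always computed. PCA uses a full SVD; hierarchical clustering uses Ward
linkage on Euclidean distances (no linkage is prescribed by the protocol;
Ward is the default for compact individual-level clusters) with purity =
fraction of individuals whose six samples share one cluster at the k = 10
cut. The Pearson significance threshold is
`r* = √(t²/(t² + n − 2))` with the two-tailed critical t at n − 2 df
(0.254 at n = 60, α = 0.05). The left/right comparison pairs samples on
(individual, day) — 30 pairs — runs a paired t-test on lnPQN-transformed
values (configurable to ln), reports the fold-change as log2 of the ratio
of linear-scale medians, and controls FDR with Benjamini–Hochberg at
q = 0.25. Exactly identical sides give t = 0, p = 1 rather than an
undefined test.

## Numerical choices and degenerate inputs

- Missing areas are NaN, never 0; medians and CVs skip them.
- PQN excludes analytes with non-positive reference from quotient
  estimation; re-normalizing against the *same* reference is an exact
  identity (quotients 1 to machine precision), while re-estimating the
  reference re-centres quotients only approximately.
- Pareto scaling passes constant columns through unscaled; `ln` rejects
  non-positive entries and names the offending cell.
- The BH implementation is statsmodels' step-up; tests compare it against
  a hand-written brute-force oracle exhaustively for p-vectors of length
  ≤ 4 on a 0.05 grid (BH is permutation-invariant, so sorted combinations
  cover all cases) and on large seeded samples for lengths 5–8.
- Monoisotopic masses come from the package's own atomic-mass table and
  are tested against pyteomics to ≤ 5·10⁻⁴ Da.

## Problem sizes

Tests and the acceptance script run the full 240-lipid, 84-injection
design (a complete pipeline pass takes about a second); the null
left/right comparison repeats 20 independent study simulations. Smaller
`lipid_scale` values are used only where the test exercises logic rather
than statistics.

## Known limitations

- One standard per class: within-class response-factor differences between
  acyl chains are not modeled, so concentrations are class-calibrated
  estimates, not absolute values.
- Collision energies, retention-time prediction and vendor method export
  are out of scope; the library emits m/z pairs and optional scheduling
  windows only.
- The generator's dilution distribution is an assumption (log-normal,
  sd 0.5); no measurement of real sweat-volume spread was available to
  calibrate it.
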