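# Methods

## Scope and model

`fieldqsar` implements ligand-based, field-style 3D-QSAR for congeneric
series — sets of analogues sharing a scaffold, pre-aligned in a common
Cartesian frame — together with the post-processing arithmetic applied to
per-complex binding-energy tables produced by upstream simulation work
(docking, MD, end-state and alchemical free-energy methods are *inputs*, not
part of this package).

### Molecular interaction fields

Aligned molecules are surrounded by a rectilinear lattice (default spacing
2.0 Å, margin 4.0 Å; the origin is anchored at floor(min − margin) per axis
so grids are bit-reproducible). Two field families are evaluated at every
lattice point q:

**Probe interaction energies (CoMFA-style).** An sp³-carbon-like probe of
van der Waals radius 1.52 Å carrying +1 e samples

* steric: `Σ_i ε_i* [(R_i*/r_iq)¹² − 2 (R_i*/r_iq)⁶]` with
  `R_i* = r_vdW,i + r_probe` and `ε_i* = sqrt(ε_i ε_probe)`,
* electrostatic: `Σ_i 332.0636 q_i q_probe / (ε(r) r_iq)` with a
  distance-dependent dielectric `ε(r) = r`,

both truncated to ±30 kcal/mol. A probe exactly on an atom centre counts as
inside the atom (steric = +cutoff). Where the untruncated steric energy
exceeds +cutoff the electrostatic value is meaningless; it is flagged
"sterically excluded" and replaced by the column mean over the non-excluded
training molecules (the stored mean is reused for prediction rows).

**Gaussian similarity indices (CoMSIA-style).**
`A_k(q) = −Σ_i w_probe,k w_ik exp(−α r_iq²)` with attenuation α = 0.3 Å⁻²,
probe weights +1, and no distance cutoff. Per-atom weights: steric
`w = r_vdW³`, electrostatic `w = partial charge`, hydrophobic `w` from an
atom-typed table, donor/acceptor `w ∈ {0, 1}` from rule-based typing (N–H/O–H
hydrogens are donors; N and O bearing a lone pair are acceptors — a
four-coordinate N is not).

Per-element parameters are frozen in `molio.py`: Bondi (1964) van der Waals
radii; GAFF/parm94-flavoured Lennard-Jones well depths; a coarse
Ghose/Crippen-flavoured hydrophobicity table (apolar carbons and their
hydrogens positive, polar heavy atoms and polar hydrogens negative, halogens
mildly positive). Hydrogens are retained; fields run over all atoms.

### Descriptor matrix and PLS

Field blocks are concatenated into a molecules × (grid point × field kind)
matrix. Columns with standard deviation below a per-kind floor are dropped
(2.0 kcal/mol for probe energies, 0.05 for similarity indices) — computed
once on the training set and frozen thereafter, including across
cross-validation folds.

Regression is PLS1 by NIPALS deflation on mean-centered X and y. Within a
field block no autoscaling is applied (the physical scale is informative);
when a model combines several kinds each block is divided by its overall
standard deviation so no kind dominates by units alone. Coefficients are
back-projected to the raw column scale, so latent-space and field-space
predictions coincide identically, and StDev*Coeff contributions are computed
on the physical scale.

Model selection is leave-one-out: `q²(a) = 1 − PRESS(a)/SS_tot` with the
model refit on each n−1 subset, `SEP(a) = sqrt(PRESS(a)/(n − a − 1))`, and
the optimal number of components (ONC) the argmax of q² capped at 6, ties
toward fewer components. If a leave-one-out fold exhausts the residual rank
early, the component count is capped at the minimum achieved across folds
rather than failing, so low-rank field subsets stay comparable in the
combination search. Bootstrap statistics (BS-r², BS-SD) come from refits on
row resamples with replacement (default 100); degenerate resamples are
redrawn and counted. The field-combination search evaluates every non-empty
subset of candidate kinds by LOO q², reusing precomputed field blocks, and
ranks by q², then fewer fields, then fewer components.

Training statistics use `r² = 1 − RSS/SS_tot`,
`SEE = sqrt(RSS/(n − a − 1))` and `F = [r²/a]/[(1 − r²)/(n − a − 1)]`.
(Published tables for this model class sometimes print F-values inconsistent
with this standard formula; the package does not attempt to reproduce such
values.)

### Validation metrics

The external-validation family follows the Golbraikh–Tropsha/Roy
conventions fixed in `validation.py`: through-origin slopes
`k = Σyŷ/Σŷ²`, `k′ = Σyŷ/Σy²`; through-origin determination coefficients
`r0² = 1 − Σ(y − kŷ)²/Σ(y − ȳ)²` (and the mirrored r′0²);
`r_m² = r²(1 − sqrt(max(r² − r0², 0)))` with the radicand clipped at zero so
adversarial inputs cannot go complex; `χ² = Σ(y − ŷ)²/|ŷ|` (the |ŷ|
denominator keeps it defined near zero — benign on the pIC50 5–9 scale);
`Q_F1² (= r_pred²)`, `Q_F2²`, `Q_F3²` and Lin's concordance correlation
coefficient over the test set. Train-block metrics are computed on fitted
(not cross-validated) training predictions. Thresholds (q² > 0.5, r² > 0.6,
r_pred² > 0.6, 0.85 ≤ k, k′ ≤ 1.15, |r0² − r′0²| < 0.3, (r² − r0²)/r² < 0.1,
r_m² family > 0.5, χ² < 1, RMSE < 0.5) are the published acceptance bands
for this model class.

### Applicability domain

Leverages are hat-values in latent-score space,
`h_i = 1/n + t_iᵀ(TᵀT)⁻¹t_i`, with test compounds projected through the
training rotation; the warning leverage is `h* = 3(p + 1)/n` with p the
number of latent components. Standardized residuals use the
degrees-of-freedom-corrected training residual scale
`s = sqrt(RSS/(n − p − 1))` (zero for a perfect fit, in which case all
standardized residuals are zero by convention). A compound is in-domain iff
`h ≤ h*` and |standardized residual| ≤ 3. Published Williams plots sometimes
quote h* values that do not follow from 3(p+1)/n for the stated n and ONC;
this package reports only the formula value.

### Contours

Per-column contributions are `stdev(column) × coefficient` on the raw field
scale, grouped by field kind. Favored regions are points at or above the
80th percentile of the strictly positive contributions; disfavored at or
below the 20th percentile of the strictly negative ones (linear-interpolation
percentiles; levels configurable). Exports: OpenDX scalar grids, PDB
pseudo-atoms (residues FAV/DIS), summary CSV.

### Binding-affinity post-processing

`ΔG_EXP = −RT ln10 · pIC50` with R = 1.98720425×10⁻³ kcal/(mol·K) and
T = 300 K by default (the customary thermostat target; configurable — some
published experimental energies imply ≈302 K). The linear-interaction-energy
combination is `ΔG_LIE = ½ΔE_cou + ½ΔE_vdW` over the bound→unbound change;
the MM-PB/GBSA assembly is `ΔE_vdW + ΔE_ELE + ΔE_GB + ΔE_SA − TΔS`, with the
equivalent (ΔE_MM + ΔG_sol − TΔS) grouping cross-checked by construction.
Correlations are Pearson over listwise-complete pairs after optional
exclusions, with a bootstrap standard error (default 1000 row resamples,
degenerate resamples redrawn and counted, explicit seed).

## Synthetic data: what it emulates, and what it does not

The generator produces a controlled stand-in for a ~35-compound
kinase-inhibitor analogue series: a planar pteridinone-like fused bicycle
(idealized 1.40 Å ring geometry, a lactam N–H and carbonyl O) with three
substitution sites, a small hand-built substituent library, a pIC50 span of
5.26–8.80, and Gaussian activity noise of 0.3 log units — the scale of
reproducibility typically claimed for kinase IC50 assays.

The activity is *by construction* a linear function of the steric and
hydrophobic Gaussian field values at six fixed probe positions (1.5 Å and
4.0 Å out along each attachment axis — one near probe saturated by the first
substituent atom, one far probe sensing extent, so the two probes per site
report different aspects of the group; at equal radial placement their
across-series correlation is ~0.99 and per-coefficient recovery would be
ill-posed for any estimator). Default planted coefficients are drawn
uniformly (magnitude 0.5–1.5, random sign) and then variance-balanced so the
steric and hydrophobic parts contribute equally — mirroring the near-even
field-contribution split of the models this emulates. The noiseless signal
is affinely mapped so it attains the target span exactly; noise is added
after mapping, so observed activities can slightly exceed the span while σ
stays in log-activity units.

The substituent library is deliberately structured for identifiability
rather than chemical realism: it contains hydrophobicity "twin" pairs
(tert-butyl-like vs a phosphorus blob of identical geometry; chloro vs a
single phosphorus) with matched charges, near-equal radii, and no
donor/acceptor flags, so that only the hydrophobic field separates them —
without such pairs the hydrophobic field is a near-linear combination of the
steric and acceptor fields under element-typed weight tables, and no method
could demonstrate that the hydrophobic field carries unique information.
Splits are activity-stratified: compounds are ranked, cut into tertiles, and
test picks drawn proportionally from each tertile without replacement
(default 26 train / 9 test).

What the generator does **not** emulate: conformational flexibility,
alignment uncertainty, tautomers/protonation states, realistic charge
distributions, activity cliffs unrelated to the planted fields, assay
heteroscedasticity. Passing the recovery tests therefore demonstrates the
*statistical machinery* (fields → PLS → validation → domain → contours)
works on data with the assumed structure, not that the method succeeds on
any real series.

The synthetic energy-table generator draws bivariate-normal pairs with a
specified population correlation, affinely mapped to per-column means/SDs
(defaults sized like real ΔG tables), and is used to calibrate the
correlation/bootstrap machinery.

## Numerical choices

* Coulomb constant 332.0636 kcal·Å/(mol·e²); all coordinates Å, charges e,
  energies kcal/mol; no unit auto-detection.
* NIPALS stops (or errors, in a direct fit) when the residual covariance
  norm falls below 1e-12 of the matrix scale; TᵀT condition numbers above
  1e12 are treated as singular in the leverage computation.
* Bootstrap and split randomness flow through explicit
  `numpy.random.default_rng` seeds; every CLI output carries its
  configuration hash and seeds in a manifest.
* Charge precedence on input: file-provided per-atom charges (SDF property
  lists, MOL2 charge column) over computed; the computed fallback is
  RDKit Gasteiger (PEOE), applied uniformly and documented in the model
  provenance.
* Metrics print at 3 decimals in text output; structured outputs keep full
  precision.

## Problem sizes

The test and acceptance runs use the generator's study conditions: 35
compounds, 26/9 splits, ~400–700 lattice points per field kind, 10 seeds for
recovery statistics, 100-resample bootstraps for model statistics and
1000-resample bootstraps for correlation standard errors. These sizes match
the scale of the emulated study; all runs complete in seconds on one CPU.

## Known limitations

* Pre-aligned input is a hard contract: the package never superposes or
  minimizes structures, and cannot detect a frame mismatch between model and
  prediction molecules.
* The MOL2 reader covers the MOLECULE/ATOM/BOND records used here, not the
  full SYBYL specification.
* Donor/acceptor typing is rule-based on elements and connectivity; it does
  not perceive aromaticity or tautomers.
* PLS1 only (one activity column); no SAMPLS acceleration, region focusing,
  or progressive scrambling.
* The hydrophobic atom-type table is coarse; real log P-derived atomic
  contributions vary far more by environment.
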