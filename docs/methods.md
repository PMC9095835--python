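# Methods

## Scope and rationale

`tcdeeg` implements the analysis chain used to characterize
thalamocortical-dysrhythmia (TCD) spectral signatures in resting-state EEG:
source-level band power, peak alpha frequency (PAF), power–power
cross-frequency coupling (CFC), and nonparametric group statistics.  The
original findings were established on a real clinical cohort; this package
does not ship that data.  Instead it pairs the full analysis chain with a
synthetic-cohort generator whose ground truth is known exactly, so every
estimator can be validated by parameter recovery and calibration rather
than by re-deriving cohort numbers.

## Forward model

The head is a homogeneous conducting sphere (default scalp radius 90 mm,
conductivity 0.33 S/m) with a cortical icosphere shell (default subdivision
level 3 → 642 vertices at 70 mm; sizes up to level 5 approach realistic
mesh densities).  One fixed dipole per vertex is oriented along the vertex
normal.  The surface potential of an interior current dipole is evaluated
in closed form: expanding the infinite-medium potential in Legendre
harmonics about the sphere centre and enforcing zero normal current at the
scalp multiplies each degree-n term by (2n+1)/n, and the resulting series
sums analytically (see `geometry.py`).  The implementation is checked in
the tests against an independently coded truncated Legendre-series oracle
(< 0.1 % relative error) and against exact invariants: average-referenced
columns, superposition, depth attenuation along a radial line, and
rotation equivariance.  Units: scalp potentials in µV, dipole moments in
pA·m.

An optional `radial_modulation` parameter wrinkles the shell so vertex
eccentricity varies; the default mesh is an exact sphere.  The modulated
mesh exists because depth-dependent behaviour (depth weighting of the
inverse, eccentricity quartiles) is degenerate on a constant-radius shell.

Electrodes are a Fibonacci lattice on the scalp sphere (deterministic for a
given channel count, default 32; 128 supported).

## Synthetic cohorts

Each subject's activity is generated per atlas node as a sum of seven
band-limited noise components (frequency-domain shaped Gaussian noise).
Design choices, fixed once:

- **1/f profile**: each component's amplitude is scaled by the inverse of
  its band-centre frequency before group gains, giving realistic
  relative-power profiles.
- **Dominant rhythm**: the alpha1 component is a Gaussian spectral bump
  (σ = 0.7 Hz) centred on the subject's drawn PAF rather than a fixed
  8–10 Hz band.  A group whose PAF is drawn near 7.8 Hz therefore spills
  oscillatory power into the theta band — the TCD mechanism itself, not a
  hand-set theta gain.
- **Source scale**: 1000 pA·m base per-vertex amplitude with 1 µV white
  sensor noise, producing scalp signals of a few µV RMS.
- **Coupling**: per 2-s epoch, log-normal amplitude modulation
  `A = exp(0.4·z − 0.08)` of theta/alpha1/alpha2/gamma1, with the latent
  normals drawn from a Gaussian copula.  Because Spearman's ρ is invariant
  under the monotone exp map, the latent correlation achieving a target
  rank correlation is exact: ρ_latent = 2 sin(πρ_s/6).  No numeric
  calibration is needed; the realized per-subject ρ (brute-force Spearman
  of the stored epoch amplitudes) is recorded as ground truth.
- **Focal gamma**: gamma-band gains act only on a designated focus-node
  set; elsewhere the gamma gain is 1.
- **Presets**: `control` (PAF 9.2 ± 0.9 Hz, alpha1 gain 3, θ→γ1 ρ = +0.2)
  and `affected` (PAF 7.8 ± 0.9 Hz, theta gain 1.25, alpha2 gain 0.7,
  gamma1 gain 1.8 / gamma2 1.4 on temporal/parietal/occipital nodes,
  θ→γ1 ρ = −0.4).  The PAF means mirror the reported male group estimates;
  the subject-level SD of 0.9 Hz is the reported standard error scaled to
  the subject level.

What the generator does **not** emulate: eye/muscle/cardiac artifacts,
non-dipolar sources, inter-node phase structure, nonstationary vigilance
drift, or individual anatomy.  Passing tests therefore demonstrate that
the chain recovers known spectral/coupling structure through a linear
forward model and realistic noise — not robustness to real-world artifact
mixtures, which the study handled with artifact-subspace reconstruction
and ICA (out of scope here; synthetic inputs are generated clean).

## Preprocessing

4th-order Butterworth filters applied forward–backward (zero phase): 2 Hz
high-pass and a 55–65 Hz band-stop, with harmonic stops (115–125 Hz, …)
added when the sampling rate resolves them.  Average reference.  2-s
non-overlapping epochs; epochs containing any sample above 100 µV
(configurable) are dropped and the earliest 40 survivors (80 s) are kept in
temporal order.  Every step appends its parameters to a provenance log;
replaying the log reproduces outputs bit-identically.

## Inverse

Depth-weighted L2 minimum norm with identity noise covariance:
`K = R Lᵀ (L R Lᵀ + λ²I)⁻¹`, `R = diag(‖lᵢ‖^(−2γ))` normalized to unit
mean, γ default 0.5 (configurable in [0, 1]), and
`λ² = mean diag(L R Lᵀ)/SNR²` with SNR default 3 — the regularization is
expressed relative to the gain matrix's own predicted signal power, so the
high-SNR limit of a square invertible system recovers the exact inverse.
The signed normal current is propagated; power is computed downstream.
Validation: γ = 0 reduces to Tikhonov minimum norm; point-spread peaks lie
in the true vertex's 1-ring for ≥ 90 % of sources on the default setup;
depth weighting does not worsen (and in practice improves) deep-source
localization on the wrinkled mesh; ‖K‖₂ is monotone in λ².

## Spectral analysis

Per-epoch spectra: linear detrend, Hann taper, squared FFT with taper
normalization, 0.5 Hz grid (2-s windows).  Source-level subject spectra:
Welch, 50 % overlap, on the concatenated clean epochs.  Both paths are
verified bin-for-bin against scipy's periodogram/welch.

Bands are half-open [low, high): 10.0 Hz belongs to alpha2; 55 Hz and the
55–65 Hz notch region, the 7.5–8 and 12.5–13 Hz gaps, and everything above
90 Hz belong to no band.  "Total power" for relative power is the sum over
the seven defined bands (a config switch to the full-grid integral is
available via a custom band table).  At 0.5 Hz resolution the bands
contain (3, 8, 4, 5, 34, 50, 50) bins.

Cortical smoothing is a geodesic (graph-shortest-path) Gaussian kernel,
FWHM 3 mm default, truncated at 4σ and made doubly stochastic by symmetric
Sinkhorn scaling, so constant maps are fixed points *and* total mass is
conserved.  On the desk-scale mesh (edge length ≈ 10 mm) the 3 mm kernel
is effectively the identity; it matters at realistic mesh densities.

PAF is the frequency of the largest strict local maximum of log power in
6–14 Hz, computed on the trial-averaged absolute spectrum; locations with
no interior peak carry a missing flag (NaN) rather than a value.

## Parcellation

Vertex values aggregate to nodes by unweighted arithmetic mean (icosphere
vertex areas are near-uniform).  Nodes group into 14 regions (7 lobes × 2
hemispheres) and 6 RSN classes; grouping keeps nodes as replicates and
provides group means separately.  The shipped 68-node Desikan–Killiany
classification (44 nodes in DMN/DAN/SAN/AUD/VIS, the rest Other) follows
published source-EEG RSN templates and is an editable CSV; the toy atlas
clusters mesh vertices by seeded k-means with round-robin region/RSN
labels so downstream paths run at desk scale.

## CFC

Whole-brain low-band relative power (mean over all nodes, including
"Other") against each node's gamma1 relative power, Spearman across
epochs (average ranks for ties), Fisher Z = atanh with |ρ| clipped at
1 − 1e−7.  Node-level relative power for CFC aggregates vertex absolute
band power to nodes per epoch and then normalizes; the opposite order is
configurable and satisfies the same share-sum invariant.  Gamma2 coupling
is off by default.

## Statistics

- Pooled-variance two-sample t maps; zero-variance locations get t = 0
  with a warning.
- Cluster permutation: clusters form at the 0.025 per-tail Student
  critical value, cluster statistic is the mass (sum of member t), the
  null is the max absolute mass under full label exchange (2000
  permutations at full scale; exact enumeration when the number of
  distinct relabellings is smaller), p = (1 + #{null ≥ obs})/(n + 1).
  Per-location permutation p values of |t| feed the FDR stage; cluster
  p values are reported separately (the study corrected "over signals and
  bands" after permutation; applying BH to location-level permutation p
  and keeping cluster p separate is the recorded reading).
- BH-FDR at q = 0.05 over the flattened signals × bands grid
  (statsmodels step-up behind the package surface; validated against the
  literal step-up definition).
- Scalp-level band report: Bonferroni 0.05/7.
- Partial Spearman: rank-transform all three series, partial Pearson on
  ranks, t approximation with n − 3 df; a constant covariate degrades to
  plain Spearman, and a variable that coincides with the covariate yields
  ρ = 0 with a warning.
- Mixed-effects group models are deliberately not reimplemented; the
  pipeline exports tidy long tables (subject × group × sex × band ×
  node/region/RSN log relative power) for external fitting and uses
  per-unit contrasts + FDR as its built-in inference path.

## Pipeline and problem sizes

`run_full` executes simulate → preprocess → invert → spectra → parcellate
→ CFC → stats from a single YAML-serializable config with one master seed;
reruns are bit-identical (timings are kept outside the report body), and
every exported table carries the config hash so artifacts from different
runs cannot be silently mixed.

Default desk-scale conditions: 642-vertex mesh, 32 electrodes, 24 nodes,
fs 500 Hz, 120 s per subject, 10 + 10 subjects, 500 permutations for the
in-run cluster tests.  Validation problem sizes: 50 subjects for PAF
recovery; 200 replicates × 40 epochs for coupling calibration (2000 for
the null rate); 200 null and 100 planted-effect replicates at 500
permutations on a 10 × 10 lattice for the cluster test.  Full-scale
parameters (15 k vertices, 128 channels, 1000 Hz, 2000 permutations) are
supported but not defaults.

## Known limitations

- The sphere forward model ignores skull/scalp conductivity layering; gain
  magnitudes are optimistic relative to a BEM head model.
- The toy atlas's region/RSN labels are structural placeholders; only the
  shipped DK table carries anatomically meaningful labels.
- PAF is grid-quantized at 0.5 Hz; no peak interpolation is attempted.
- Realized CFC at the pipeline output is attenuated relative to the latent
  copula target (sensor noise, relative-power compositional coupling);
  group *contrasts* of Fisher z are the validated quantity, matching how
  the statistic is used.
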