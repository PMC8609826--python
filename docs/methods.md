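# Methods

## Thermal-inactivation kinetics and activation thermodynamics

Inactivation at a fixed temperature is modelled as irreversible
first-order decay, ln(A/A₀) = −kt, with A the residual activity (percent
of the unheated control) and k in min⁻¹. k is the negative slope of an
ordinary least-squares fit of ln(A/A₀) on time. The fit uses a free
intercept by default — robust to small offsets in the t = 0 reference —
with a forced-zero-intercept option (slope = Σt·y/Σt², the textbook
through-origin estimator). Points with activity ≤ 0 have no logarithm and
are dropped with a warning and a count in the fit record; at least three
positive-activity points are required. A non-negative k is reported: a
positive fitted slope (activity apparently rising) is clipped to k = 0
and flagged.

Across temperatures, ln k regressed on 1/T (T in kelvin, T = °C + 273.15)
gives the Arrhenius activation energy Eₐ = −slope·R and frequency-factor
intercept c. At least two distinct temperatures are required. Derived
per-temperature quantities:

- half-life t₁/₂ = ln 2/k and decimal-reduction time D = ln 10/k, both in
  minutes, so D/t₁/₂ = ln 10/ln 2 ≈ 3.3219 identically;
- ΔH° = Eₐ − RT (kJ/mol);
- ΔG° = −RT·ln(k·h/(k_B·T)) (kJ/mol), the Eyring free-energy barrier;
- ΔS° = (ΔH° − ΔG°)/T, reported in kJ·mol⁻¹·K⁻¹.

Constants are fixed at R = 8.314 J·mol⁻¹·K⁻¹, h = 6.626×10⁻³⁴ J·s,
k_B = 1.38×10⁻²³ J·K⁻¹.

**Rate-constant unit in ΔG°.** The Eyring expression is dimensionally
consistent only with k in s⁻¹, yet published thermal-inactivation tables
in this literature are frequently computed with k in other time bases
(here, per-hour reproduces the reference parameter set this pipeline
targets: k in s⁻¹ gives ≈ 99 kJ/mol at 25 °C, per-minute ≈ 88.8, per-hour
≈ 78.7). The time base is therefore an explicit argument
(`rate_time_unit`, default `"hour"`), and the choice is echoed in the
table metadata so no reader mistakes it for a silent convention.

**ΔS° units.** The ΔS° values that accompany per-hour ΔG° are ≈ 0.24
kJ·mol⁻¹·K⁻¹ (≈ 241 J·mol⁻¹·K⁻¹). The column is labelled in kJ to match
the values actually produced; the J-scale figure is the same number ×1000.

**Two Eₐ values can legitimately differ.** Eₐ computed from rounded,
printed rate constants (≈ 153.1 kJ/mol on the reference set) differs by
~1.2% from the value computed from unrounded fits; the pipeline reports
what it computes and does not force either.

**D-value semantics.** D = ln 10/k is the time for activity to fall *to*
10% of initial (a 90% reduction); the formula is implemented as such.

## Assay fitting

**Michaelis–Menten.** v₀ = k_cat[E]₀[S]₀/([S]₀ + K_M) is fitted by
bounded nonlinear least squares (scipy `curve_fit`, trust-region
reflective) over (k_cat, K_M), both constrained positive. Initial guesses
are K_M⁰ = median positive substrate and V_max⁰ = max velocity; the
start point is perturbed geometrically on the rare non-convergence. The
response is internally rescaled to unit magnitude before optimization —
raw velocities of order 10⁻⁵ otherwise trip the optimizer's absolute
cost tolerance and stall the fit. At least four distinct substrate levels
are required; an all-zero velocity vector is rejected as degenerate.
Catalytic efficiency is k_cat/K_M with K_M converted to molar via the
monomer molecular weight of the released sugar (mg/ml = g/L, so
K_M(M) = K_M/MW; default MW 150 g/mol, xylose). With k_cat = 480 s⁻¹ and
K_M = 8.7 mg/ml this gives ≈ 8276 M⁻¹s⁻¹; the conversion is transparent
and no published figure is hard-coded, since mg/ml-based K_M values admit
no other consistent molar efficiency.

**DSF melt curves.** The standard Boltzmann sigmoid
F(T) = F_min + (F_max−F_min)/(1+exp((T_m−T)/slope)) is fitted by least
squares, T_m being the midpoint. The exponent is clipped at ±700 to avoid
overflow during line searches. An optional maximum-temperature cutoff
truncates the post-transition aggregation decline (common DSF practice);
default is no truncation. A fit with r² < 0.5 carries a quality flag
rather than raising. Ten points spanning the transition are the minimum.

**pH optimum.** Replicate wells at the same pH are averaged; the optimum
is the argmax of mean activity with ties broken toward lower pH and
flagged. The full ranking is returned for stability-versus-pH
comparisons.

## Marker-peptide profiling

Identity between two proteins is global-alignment identity: matching
columns over alignment length, under match +1 / mismatch 0 / gap open −10
/ extend −1 (Biopython `PairwiseAligner`; `X` never matches, including
against itself). Clustering is greedy and centroid-based (CD-HIT style):
sequences visited longest-first (ties by id), each joining the first
centroid at ≥ 85% identity or founding a new cluster. No k-mer prefilter
is used — unnecessary at the scales this package targets.

Markers are built per cluster from the centroid: all windows of
`min_marker_len` (default 8) residues absent as exact substrings from
every out-of-cluster sequence are kept, overlapping windows merge into
maximal unique regions, and the longest `max_markers_per_cluster` regions
become the markers. This is a deliberate simplification of
ShortBRED-style quasi/true-marker construction — explicit and exhaustively
checkable rather than equivalent to it. A cluster whose centroid has no
unique window is flagged marker-less.

Quantification is exact substring matching of markers against reads
(peptide reads by default; six-frame translation with stop-codon breaks
behind `translate=True`). A read increments at most one marker — markers
tried longest-first, ties by id — so assigned reads never exceed total
reads. Normalized abundance is an RPKM analogue on amino-acid length:
count/(marker_length_aa × total_reads/10⁶); cluster-level values sum over
the cluster's markers.

The annotation-hit filter keeps rows with e-value ≤ 1e-5, percent
identity ≥ 60 and alignment length ≥ 30 (all inclusive, order preserved,
idempotent). The alignment-length threshold is applied in the column's
native unit without conversion.

## Coulomb electrostatics

φ(r) = prefactor · Σᵢ qᵢ/(ε·dᵢ), vectorized over query points with
distances from `scipy.spatial.distance.cdist`. Default prefactor 1 leaves
φ in e·Å⁻¹·ε⁻¹; 332.06 yields kcal·mol⁻¹·e⁻¹ as molecular-graphics tools
conventionally report. A query within `min_distance` (default 10⁻⁶ Å) of
a charge raises a singularity error naming the atom. A
distance-dependent dielectric (ε ∝ d, i.e. 1/d² screening) is available;
the default is the constant-ε plain Coulomb sum, which is what the sign
and shape of a surface potential map (e.g. the negative groove at a
xylanase active site) depend on. Charges load from 5-column TSV
(atom_id, x, y, z, q) or whitespace-delimited PQR; PDB files without a
charge column are rejected with an explicit message.

## Synthetic data

Generators are seeded (`numpy.random.default_rng`); identical seed and
parameters give bit-identical output, and `noise_sd = 0` gives exact
noiseless curves. Noise is additive Gaussian on the observable (activity
percent, velocity, fluorescence), truncated at physical lower bounds,
with `replicate_count` independent wells (default 2, duplicate-well
practice) averaged into the returned observable. Defaults mirror the
study conditions: decay sampled at 0–70 min in 10-min steps at 25/40/50/
60 °C with the four reference rate constants; the kinetic assay on the
substrate grid 0, 0.88, 1.75, 3.5, 7.0, 15.0, 30.0 mg/ml at [E]₀ = 0.05
µM; DSF scanned 25–95 °C in 0.5 °C steps. No raw assay tables exist to
calibrate noise magnitudes against, so they are chosen, not inferred:
3% activity for decay and 5% of V_max for velocities are typical
plate-assay scatter.

Protein families descend from independent uniform-random ancestors with
i.i.d. per-site substitution (probability d to a uniformly random
different residue; no indels by default, so fixture identities need no
alignment). Expected pairwise identity between two family members is
(1−d)² + d²/19. Read sets embed each marker exactly its planted count in
rejection-sampled marker-free background reads, with a truth table of
placements; FASTA wraps at 60 columns and FASTQ carries constant Q40.

What the simulations do *not* emulate: substrate depletion and product
inhibition in velocity data, multi-phasic inactivation, DSF aggregation
tails, indels and alignment ambiguity in families, sequencing error, and
differential abundance between samples. Passing tests therefore certify
the estimators and the bookkeeping, not robustness to those real-data
features.

## Problem sizes and determinism

The test and acceptance runs use desk-scale problems chosen as the
smallest sizes at which each property is meaningful: 4 temperatures × 8
time points for the inactivation chain; 200 Monte-Carlo replicates for
bias checks (|mean bias| < 2·SE); 20 sequences (5 families × 4) and 500
reads for profiling; 50 random charges for the Coulomb oracle. Every
random draw flows from an explicit seed, and the pipeline's outputs are
byte-reproducible from `RunConfig` alone.

## Known limitations

Single-exponential inactivation only; no confidence machinery beyond OLS
standard errors; greedy clustering is order-dependent by design (the
documented longest-first rule makes it deterministic); marker uniqueness
is exact-substring, so a single substitution in a read defeats a match;
no Poisson–Boltzmann or solvent model in the electrostatics.
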