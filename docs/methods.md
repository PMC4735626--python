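# Methods

This note records the statistical conventions, the synthetic-data
design and the numerical choices behind `teleflux`, in the spirit of a
model-description appendix. Nothing here states an empirical result
that the test suite does not itself compute.

## Winter indices and phase composites

A "winter" is labelled by its January year: winter *y* averages the
monthly index over Dec(*y*−1), Jan(*y*), Feb(*y*). A winter enters the
record only when at least two of its three months are covered; its DJF
mean uses the unmasked months and is itself masked when fewer than two
are available. With a 1982–2012-style record this yields 31 winters.

Phases are defined by *strict* exceedance of the empirical terciles of
the base-period DJF means (linear interpolation of order statistics;
values exactly at a tercile are neutral). Classification is therefore
rank-based and invariant under monotone transforms of the index. A
winter joins one of the four non-neutral composites only when **both**
indices exceed a tercile; all other winters are neutral. This joint
rule is what makes the double-positive composite small in a
31-winter record (~31/9 ≈ 3–4 expected members). Base periods shorter
than 9 winters are rejected — terciles of fewer values are too
unstable to define phases.

## Rotated circulation modes

Monthly z500 anomalies over the North-Atlantic window (20–80° N,
90° W–50° E) are standardized per pixel and per calendar month over the
base period, weighted by √cos(lat), decomposed by SVD, and the leading
`n_retain` modes (default 10, the operational convention; 2 in the
synthetic recovery tests) are varimax-rotated. The raw varimax
criterion (no Kaiser normalization) is maximized with the classical
SVD-based alternating algorithm; for two modes the optimum is verified
in the tests against a 0.1° brute-force angle scan. Amplitude series
are re-standardized to unit variance; rotated amplitudes remain exactly
uncorrelated (orthogonal rotation of orthogonal scores). Mode signs
follow the meteorological convention that the positive phase carries
*negative* height anomalies at the northern centre of action; mode
naming (which rotated mode is "NAO") is by maximal absolute Tucker
congruence against reference patterns, never by variance rank, because
rotation does not preserve ordering.

Pixel-wise standardization divides the field by its local standard
deviation √(P₁² + P₂² + σ²); the spatial pattern recoverable by a
standardized analysis is therefore the injected dipole *scaled by that
factor*, and the generator's truth ledger records these "standardized
patterns" as the recovery reference alongside the raw dipoles.

## Anomalies, integrals, regions

Deseasonalization removes the per-pixel, per-calendar-month mean over
the base period (default: the full record). Annual anomalies are the
**sum** of the twelve monthly anomalies (flux month⁻¹ integrates to
flux yr⁻¹, PgC reporting); seasonal diagnostics are 5-month window
means, with December attributed to the following year's Dec–Apr
window. Because anomalies are defined against the record-period
climatology, any injected effect is recovered *relative to the record
mean of the injections* — an identity the parameter-recovery tests use
exactly, and a ~2 % -of-effect-size correction under the default
synthetic world.

Regions are the printed analysis boxes (Iberia −11…3.5° E / 34…44° N;
central Europe −5…25° E / 44…53° N minus a Great-Britain box; western
Russia 29…60° E / 46…62° N; Scandinavia 4.5…29° E / 56…71° N; the
continental window 30–75° N / −15–60° E). How the Great-Britain
exclusion was originally realized on coarse grids is not documented;
the box-exclusion is this package's choice. Masks carry fractional
cell coverage computed from cell bounds reconstructed as midpoints
between centers (registration is centers throughout). Cell areas use
R²·Δsin(lat)·Δlon — identical to the cos-lat approximation on uniform
grids, but exact on the sphere, which keeps conservative regridding
conservative to float precision. Flux variables regrid conservatively
(area-weighted density averaging; per-cell units are converted to
densities and back), intensive variables bilinearly.

## Composite statistics

The "one-sided" composite test is the F-test of the composite-mean
anomaly against zero, F = t² with p from F(1, n−1) — the test of
"is the average anomaly of this phase combination nonzero". The
"two-sided" test between two composites is the ordinary two-group
one-way ANOVA (equal-variance pooling, F equal to the squared pooled
two-sample t). Member-years are pooled across the datasets of a group
(inversions vs vegetation models are always tested separately);
treating each dataset as a factor is possible via the per-dataset
table but pooling is the default. No multiple-testing correction is
applied by default. Zero-variance degenerate inputs are flagged
explicitly rather than producing spurious p-values. Ensemble spread is
reported as the min–max envelope across members (not ±sd), honouring
per-dataset year masks for archives of unequal length.

## NBP field PCA

Annual anomaly fields on a common grid are scaled by √cos(lat),
flattened over the valid cells (cells masked in any year are excluded
throughout) and decomposed by SVD; explained-variance fractions come
from the squared singular values. PC1 is oriented to correlate
positively with the domain-integral series, so its positive phase
means a stronger continental sink. Centres of action are the extrema
of the leading pattern located on a centre-weighted 3×3 locally
averaged map — the kernel (2^−(di²+dj²)) suppresses single-pixel noise
without displacing an isolated extremum — and a pattern whose two
extrema share a sign is flagged non-dipolar. A region's "variance
share" of the continental signal is the squared Pearson correlation of
the two annual series, in percent; this is one of several defensible
readings of "variance explained" and is flagged as an interpretation.

## The synthetic world

The generator states a fixed world; its defaults were chosen once, for
realism at the scale of the European winter analysis, and are not
tuned to test outcomes:

* **Indices**: two independent AR(1) processes with unit marginal
  variance and lag-1 autocorrelation 0.3 (monthly teleconnection
  indices decorrelate within a few months), 31 years, one leading
  December so every winter has a full DJF.
* **z500**: NAO-like dipole (lobes at 64° N/38° N, 25° W, peak
  80 gpm) and EA-like dipole (52° N/28° N, displaced west-southwest,
  peak 60 gpm), Gaussian lobes of 8° width, Gram-Schmidt
  orthogonalized under area weights; white noise of 40 gpm per month
  and cell. Amplitudes, widths and noise are of the order of observed
  winter monthly z500 variability, with the northern lobes negative so
  that positive amplitudes give the conventional positive-phase sign.
* **Fluxes**: an 11-member pseudo-model ensemble plus 3
  pseudo-inversions on a 2° European grid, per-cell units
  PgC month⁻¹ cell⁻¹. A shared seasonal GPP cycle peaks in summer;
  composite effects β = (+0.10, −0.05, −0.05, +0.02) PgC yr⁻¹ for
  (NAO⁻EA⁻, NAO⁺EA⁻, NAO⁻EA⁺, NAO⁺EA⁺) are injected over May–Sep with
  raised-cosine monthly weights (smooth seasonal curves rather than
  steps), routed through GPP or RECO per composite following the
  qualitative mechanism (double-negative enhancement via GPP;
  anti-phase reduction via GPP drop or RECO rise). NBP ≡ GPP − RECO
  holds bitwise. Member noise of 0.1 PgC yr⁻¹ at the continental
  annual scale matches the order of model-ensemble spread; the
  spatial distribution of injected effects is normalized so the
  mask-weighted regional integral recovers the injected total exactly.
* **NDVI**: biweekly baseline cycle (0.35 ± 0.25) plus a gain times
  the GPP anomaly (two samples per month), clipped to [−1, 1].
* **Climate**: per-variable spatial templates with
  composite-conditional signs and amplitudes, active in Dec–Apr
  (circulation, snow, cloud, transports) or May–Sep (temperature, soil
  water), plus white noise; the soil-water stack draws per-year
  regional summer anomalies first, recorded in the truth ledger, so a
  configurable slope can couple them into summer GPP for the
  moisture-dependence diagnostic.

Truth phases are obtained by applying the package's own tercile rule
to the noise-free amplitude series, so classification disagreement is
attributable to index noise alone. Everything is reproducible bitwise
from (config, seed); independent random streams are spawned per
artifact so adding members never perturbs existing ones.

**What a green test establishes.** The generator produces additive,
Gaussian, stationary worlds with a single spatial effect footprint per
region. Real flux archives have trends, non-Gaussian extremes,
transport-model error structure, and observation networks that change
over time — none of which are emulated. Parameter-recovery results
therefore validate the *analysis machinery* (the estimator recovers
what was injected at the stated noise), not the geophysical
conclusions drawn from real archives.

### Stand-in index tables

The real observational monthly index tables cannot be redistributed
with the package; `standin_index_tables` writes a SYNTHETIC pair in
the same text dialect whose winter phase structure realizes, by
construction, the documented 1982–2012 record: four double-positive
winters, a double-negative composite containing 1985, 1996 and 1997,
anti-phase winters 1982–1984 and a six-year anti-phase run 1998–2003.
Per-index counts are engineered as 10/11/10 (negative/neutral/
positive), which pins the empirical terciles between the value bands
so the classification is unambiguous. Tests against these tables
verify the classification machinery end-to-end from raw text; they are
not observational evidence.

## Numerical choices and degenerate inputs

* Tolerances: conservative regridding is exact to float rounding
  (asserted at 1e−6 relative); varimax iteration stops at relative
  criterion change 1e−12 (cap 1000 iterations); composite aggregation
  identities hold to 1e−10 relative.
* Terciles with ties or zero spread raise (`lower < upper` is
  enforced) rather than silently classifying everything neutral.
* Standardization guards zero-variance pixels by substituting unit
  sd; ANOVA degenerate cases (zero variance, zero within-group
  variance) are flagged, with p forced to 0 or 1 as the limit demands.
* Longitude canon is [−180, 180); 0–360 inputs are rotated and
  re-sorted on read. Latitude is ascending everywhere.
* Incomplete years (missing months) are rejected by annual/seasonal
  integrals; per-dataset year masks let archives of different lengths
  coexist in composites and envelopes.

## Known limitations

* Regular lat/lon grids only; no curvilinear or reduced-Gaussian
  support, no shapefile country masks.
* Bilinear remapping does not treat the 180° longitude seam as
  periodic; domains crossing it must be rotated first.
* The NDVI annual integral weights the 24 biweekly samples equally;
  day-span weighting is not implemented (the original convention is
  undocumented).
* No gap-filling, no detrending (the analysis convention reports
  anomalies as-is), no EOF mode-separation significance testing, and
  no rotated EOFs for the flux fields (rotation applies to the
  circulation analysis only).
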