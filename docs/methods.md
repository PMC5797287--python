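# Methods

## Model and procedure

Each participant answers up to six location questions — live/sleep, inject,
spend most time, work/earn money, socialize, recruited — each with two
time-use follow-ups: days per week (0–7, "<1", not applicable, decline) and
hours per typical day (0–24, "<1", not applicable, decline). The pipeline
proceeds in four stages.

**1. Unique places.** Two reports of one participant denote the same
physical place when their coordinates match exactly or lie within 0.4
statute miles (643.7376 m with 1 mile = 1,609.344 m; the exact constant keeps
the threshold bit-stable). Distances are great-circle (haversine) on a sphere
of radius 6,371,000 m; at city scale the difference from an ellipsoidal
distance is orders of magnitude below the threshold's precision. The pairwise
rule is closed transitively (single linkage via union–find), because the
downstream multiplicity table requires a partition of the reports into
places; a no-chaining alternative ("seed" linkage: a report joins the first
earlier place whose seed lies within threshold) is available since the
original pairwise phrasing is ambiguous about chains. Each place's
representative coordinate is the member with the largest resolved weekly
hours, ties broken by the fixed survey order (live/sleep, inject, spend most
time, work/earn, socialize, recruited); the rationale is that the
highest-time member best locates where the participant actually is.

**2. Area assignment.** The representative coordinate is assigned by
ray-casting point-in-polygon test against the area polygons (first exterior
ring of each GeoJSON Polygon feature). Boundary points count as inside, and a
point on a shared boundary resolves deterministically to the lexicographically
smallest area id. Points outside every polygon are UNASSIGNED.

**3. Time weighting.** Weekly hours at a place are days × hours after token
resolution: "<1 day" and "<1 hour" resolve to 0.5 (the midpoint of the stated
open interval; configurable), and "not applicable"/"decline" are missing.
When co-located types report different hours, the place's tᵢ is the maximum
across members (the same physical place is visited once; the maximum keeps
the fullest estimate without double counting; a mean option exists). Time
fractions are wᵢ = tᵢ/Σtⱼ over places with non-missing tᵢ; zero-time places
get w = 0 and are retained for the overlap tables. The weighted exposure is
E = Σ wᵢ·X_c(i); the per-type exposure is X of the type's area. Participants
with any UNASSIGNED place are dropped from all exposure analyses by default
(mirroring out-of-area exclusion in such studies); a renormalize-over-assigned
policy is available. Weekly totals above 168 h are logged as warnings, not
errors: respondents genuinely report overlapping or inconsistent times, and
the fractions are scale-invariant anyway.

**4. Comparison.** Per indicator, the 6 + 1 measures are compared with a
classical one-way ANOVA (between/within mean squares, F(k−1, N−k)), followed
by two-sample pooled-variance t-tests for each distinct measure pair (Welch
optional), flagged against a Bonferroni-adjusted level. The adjusted level
follows the ordered-pair convention by default — 7 measures → 42 comparisons,
α_adj = 0.05/42 ≈ 0.0012 — reproducing the published convention even though
only 21 distinct pairs are tested; the unordered convention (α/21) is a
switch. Groups share participants but are compared as independent samples;
this matches the published analysis, is noted on every report, and generally
makes the tests conservative under the null (positively correlated group
means shrink between-group differences).

## Synthetic world

The generator states the emulated survey's conditions as defaults and is the
test bed for every stage.

**City.** A 7×8 grid trimmed to 55 rectangular areas (cell edge 1 km, origin
39.20° N, −76.70° E), ids `A000`–`A054`. Indicators: a "gradient" pattern is
strictly monotone along the east–west axis of cell centroids (defaults:
`violent_crime_rate` rising eastward 30→70 per 1,000, `median_income_k`
falling 75→30, emulating a disorder gradient with anticorrelated income), a
"hotspot" pattern is a Gaussian bump around a seeded random cell
(`vacant_housing_pct`), and "uniform" is iid noise. Rectangles rather than
realistic polygons make point-in-polygon ground truth exact; `read_areas`
accepts arbitrary user GeoJSON when realism is needed.

**Cohort.** Per participant: provided types are Bernoulli draws with
applicability defaults 540/547 (live/sleep), 534/547 (spend most time),
538/547 (recruited), 0.22 (inject), 0.30 (work), 0.78 (socialize). The first
provided type in a fixed priority order anchors the home place. Each other
provided type either re-uses an existing place (per-type co-location
probabilities 0.87/0.78/0.62/0.45/0.35 for spend-most-time / inject /
socialize / recruited / work, chosen to reproduce the observed overlap
ordering) — with member coordinates matching exactly or jittered uniformly
within 0.25× the threshold around the place's seed — or founds a new place at
least 2× the threshold from existing seeds (rejection sampling, 100 tries,
then a hard error naming the constraint). These margins guarantee the
clustering stage recovers the true partition exactly, which the tests assert.
New places land in areas drawn with probability ∝ exp(b·z), where z is the
standardized bias indicator (first city indicator by default) and b the
per-type bias in SD units (defaults: inject +1.5, recruited +0.75, work −1.5,
emulating injection/recruitment in higher-disorder and work in
lower-disorder neighborhoods). 13/547 of participants have one place
relocated far outside the city.

**Time answers** are generated on the discrete response grid (integer days
0–7, hours 0–24, occasional "<1" tokens, occasional missing answers on
non-primary members only) so the token-resolution path is exercised without
perturbing place-level truth. The home place gets 7 days × N(16, 3) hours
(median 112 h/week). The home time-share f is drawn from Beta(a, 1); the
shape a is solved in closed form so that the *realized cohort median* hits
the `home_time_share` target (default 0.89) given the fraction of
participants whose provided types all co-locate at home (share exactly 1):
P(share ≤ m) = (1−p₀)·mᵃ = 0.5 ⇒ a = log(0.5/(1−p₀))/log(m). Remaining time
h·(1−f)/f is split across distinct places by a symmetric Dirichlet and
rounded onto the response grid. The sidecar records true clusters, areas,
weekly hours, per-indicator weighted exposures, and home shares.

**What a green test does not establish.** The generator emulates marginal
applicability, co-location, time-concentration and spatial-bias structure; it
does not reproduce real street geography, the spatial autocorrelation of real
indicators, recall error, or deliberate location misreporting. Recovery and
detection results therefore validate the pipeline's arithmetic and its
statistical behavior under the stated world, not the substantive findings of
any particular survey.

## Numerical conventions and edge cases

- Median = mean of the central two values for even n; quartiles by linear
  interpolation (numpy defaults), pinned because summary tables are only
  reproducible under a fixed quantile rule.
- ANOVA/t degeneracies are explicit: essentially-constant data (total sum of
  squares below n·(10⁻¹² × value scale)²) give F = 0, p = 1 / t = 0, p = 1,
  so floating-point noise in a constant-indicator city never masquerades as
  significance; zero within-group variance with distinct means gives F = ∞,
  p = 0. Statistics are computed from the sums-of-squares formulas with
  p-values from `scipy.stats`; `scipy.stats.f_oneway`/`ttest_ind` serve as an
  independent cross-check in the test suite.
- Groups with n < 2 are dropped from comparisons with a warning; an indicator
  with fewer than two usable groups is skipped.
- Participants with no positive, non-missing time are flagged NO_TIME_DATA:
  they keep per-type exposures and overlap-table membership but produce no
  weighted exposure.
- Duplicate (participant, type) survey rows: the first is kept, later ones
  are rejected with a reason code; all row rejections satisfy
  accepted + rejected = read.
- I/O preserves "<1" as a token and resolves it only at the time-use stage,
  keeping the file layer lossless; coordinates are (lat, lon) internally,
  converted from GeoJSON's (lon, lat) at the boundary.

## Known limitations

- Planar ray-casting in degree space is exact for the synthetic grid and
  adequate for city-scale polygons, but not for polygons spanning many
  degrees or crossing the antimeridian.
- No road-network or walking-time distances: the walking-time gloss of the
  0.4-mile rule is not a second criterion.
- No repeated-measures or spatial-autocorrelation correction in the
  comparisons, by design fidelity to the emulated analysis.
- The null-cohort familywise error check uses 100 seeds of n = 300
  participants — large enough for t-validity, small enough to keep the suite
  fast; its binomial tolerance (rate ≤ 0.10 for a true rate ≤ 0.05) is the
  95% upper bound at 100 draws.
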