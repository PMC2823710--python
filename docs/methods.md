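# Methods

## The classification model

`samplex` treats per-residue perturbation mapping as a three-way
classification driven by two sources of information: the *contrast* of each
residue's value against the rest of the data, and the *spatial context* of
the residue in the 3D structure. The method assumes (i) values are
non-negative magnitudes on a common scale across residues, (ii) perturbed
residues form spatially coherent regions rather than a scattered set, and
(iii) the structure (of the free/ground state, or an NMR ensemble of it) is
a reasonable model of the geometry over which the perturbation spreads.

### Resampled standardization

A residue's value is never judged against a single global mean. Instead it
is standardized, `k = (value − μ)/σ`, within many small random sub-ensembles
of the data (population mean and SD of the subset, including the residue
itself). Sub-ensembles make the score robust to the overall shape of the
value distribution: a residue that stands out in most random contexts is
reliably extreme, one that stands out only against quiet subsets is not.

The map from `k` to a confidence increment is the clipped piecewise-linear

    Γ(k) = +1            if k ≥ k_high
           k / k_high    if 0 ≤ k < k_high
           −k / k_low    if k_low < k < 0
           −1            if k ≤ k_low
           0             if the subset SD is null (uninformative)

where `k_high`/`k_low` come from a calibration pass whose subsets always
contain the global maximum and minimum: `k_high` is the *lowest* `k` the
maximum attains and `k_low` the *highest* `k` of the minimum over all runs.
Clipping at the least-extreme scores of the true extremes stops a single
outlier from compressing everyone else's confidence toward zero, and makes
the residues carrying the global extremes reach ρ = ±1 exactly. The
confidence `ρ_i` is the average of `Γ` over `100·N` trials, hence lies in
[−1, 1] by construction and is invariant under positive affine scaling of
the data.

### Spatial kernel

Both inference and homogenization weight neighbor residues by a logistic
kernel on the distance between residue barycenters:

    φ(d) = 1 / (1 + α_ε · e^{λ(c)·d}),   α_ε = ε/(1−ε),   λ(c) = (2/c)·ln((1−ε)/ε)

which satisfies φ(0) = 1−ε, φ(c/2) = 1/2 and φ(c) = ε exactly. Barycenters
are unweighted means over heavy atoms (hydrogens are absent from most X-ray
files and would tie the geometry to the refinement protocol; an
`heavy_only=False` switch exists). For ensembles, distances are averaged
over models, letting conformational heterogeneity widen neighborhoods. The
neighbor test `d ≤ c` is closed so the nominal cutoff is attainable.

### Inference and exclusion

Missing residues receive the φ-weighted (inverse-distance) mean of
*measured* neighbors' confidences in a single pass — inferred values never
seed other inferences, which removes any order dependence among mutually
missing residues. Fewer than two measured neighbors leaves the
interpolation unsupported; the residue is excluded and ends as
`no-decision`.

### Homogenization

The smoothing iteration

    ρ_i(t+1) = ( ρ_i(0) + Σ_j φ(d_ij)·ρ_j(t) ) / ( 1 + Σ_j φ(d_ij) )

is a synchronous (Jacobi) fixed-point iteration anchored at each residue's
*starting* confidence with weight 1. Because the neighbor weights sum to
strictly less than the denominator, the update is a contraction: it
converges geometrically to the unique solution of `(I − W)ρ = b` (verified
against a direct linear solve in the tests), keeps every iterate bounded by
the starting maximum, and — crucially — anchoring to ρ(0) rather than to
ρ(t) preserves block structure instead of collapsing to a global consensus.
Convergence is declared when the RMSD between consecutive iterates (over
non-excluded residues) drops below `homog_tol`; a hard cap of 10⁵
iterations raises a diagnostic error.

### Decision and the flat-data guard

Boundaries ±`decision_threshold` belong to the ambiguous class; only strict
inequalities yield perturbed/unperturbed calls. Before any computation the
relative SD `σ_R = σ/μ` of the measured values (population convention,
measured residues only — missing values cannot contribute) is compared to
`sigma_r_guard`: below it the dataset is considered globally unperturbed and
every residue is labelled `no-decision`. All-zero data trigger the guard
with `σ_R` flagged as NaN. In non-interactive use `--force` (or
`force=True`) overrides the guard.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `subset_fraction` | 0.15 | fraction of measured data per sub-ensemble |
| `min_subset_size` | 3 | floor so calibration subsets can hold max + min + 1 random |
| `calib_multiplier` | 1000 | calibration runs per measured datum |
| `trial_multiplier` | 100 | per-residue trials per measured datum |
| `neighbor_cutoff` | 7.5 Å | barycenter-distance cutoff defining neighbors |
| `epsilon` | 10⁻³ | kernel floor: φ(0)=1−ε, φ(cutoff)=ε |
| `homog_tol` | 10⁻⁵ | RMSD convergence threshold of the smoothing |
| `decision_threshold` | 0.05 | half-width of the ambiguous dead zone |
| `sigma_r_guard` | 0.25 | relative-SD floor below which no mapping is made |
| `seed` | 0 | RNG seed; identical seeds give bit-identical results |

The two multipliers trade Monte-Carlo error against run time; at the
defaults the binomial sampling error of ρ is below ~0.01 for a
100-residue protein. Subset statistics use the population (not sample) SD —
subsets are small and μ is computed from the same subset; a different
convention would only rescale `k` uniformly and leave Γ nearly unchanged.

## The CSP combination

When two shift tables are supplied instead of a value table, per-residue
CSPs are computed as the weighted Euclidean norm of the backbone shift
differences, `sqrt(ΔHN² + (ΔN/SW_N)² + (ΔCα/SW_Cα)² + (ΔCO/SW_CO)²)`, over
whichever nuclei a residue has in both states. The spectral-width ratios
default to `SW_N = 6.5`, `SW_Cα = SW_CO = 10` — typical values, but they are
acquisition-dependent and results on real shift data are sensitive to them,
so they are explicit, user-overridable configuration rather than silent
constants. Residues with no common nucleus become missing (inferred in
Step 2), not zero.

## What the synthetic generator does and does not emulate

`samplex.synthetic` builds single-chain pseudo-structures with one atom per
residue — an ideal α-helix (1.5 Å rise, 100° turn, 2.3 Å radius; consecutive
barycenters then sit 3.83 Å apart, and residues i±1…i±4 fall inside the
7.5 Å cutoff) or a self-avoiding random coil (3.8 Å steps, 3.0 Å clash
floor). A planted patch (all residues within `patch_radius` of a center
residue) receives `effect_size` plus half-normal noise, the background
half-normal noise alone; half-normal keeps values non-negative without
truncation artifacts. A fraction of residues is then hidden as missing.
The default instance (120 residues, 12 Å patch ⇒ 15 contiguous residues,
effect 5× noise scale, 10% missing) is the study condition used by the
tests and the acceptance script; the `flat=True` variant (values ≈ 1 ± 5%)
exercises the σ_R guard.

This emulates the spatial coherence, non-negativity and missingness of real
perturbation data, but not its physics: no correlated noise, no low-CSP
interface residues flanked by high-CSP ones (every planted residue carries
at least `effect_size`), no multi-chain complexes (interface extraction is
tested on hand-built coordinate fixtures), and a sparser contact graph than
a globular protein (≈8 neighbors within 7.5 Å versus 10–15 in real folds,
so smoothing is weaker than on real structures). Passing the recovery tests
therefore demonstrates the machinery end to end, not performance on real
NMR data; conversely the clean 5:1 separation makes naive thresholding
nearly perfect on these fixtures, so they understate the method's relative
advantage on messy real data.

## Numerical choices

- Subset SDs below `10⁻¹² · max(1, |μ|)` are treated as null (Γ = 0):
  all-equal subsets give σ ≈ 10⁻¹⁶·|μ| from rounding alone.
- Calibration and attribution evaluate subsets through the same
  floating-point reduction (fixed members lead each row), so a residue whose
  subsets coincide with calibration subsets reproduces `k_high` bitwise and
  reaches ρ = 1 exactly, not merely approximately.
- Sampling without replacement is vectorized (arg-partition of uniform
  draws) and chunked to bound peak memory; a single `numpy` generator
  seeded from `SamplexParams.seed` is threaded through calibration then
  attribution, making runs bit-for-bit reproducible.
- Altloc resolution follows highest occupancy, ties to first listed;
  HETATM records (waters included) are dropped unless whitelisted; residues
  absent from some models of an ensemble are dropped from all with a
  warning.
- MCC with a degenerate denominator returns 0 with a warning.
- Threshold baselines use strict `>` at μ + nσ.

## Design choices where the design was open

- Data tables are matched to structures by strict (chain, residue number,
  insertion code) equality; a `strict` flag errors on table keys absent from
  the structure, otherwise they are warned about and ignored. Structure
  residues absent from the table are treated as missing and inferred.
- Attribution subsets contain only the residue itself plus random others;
  the global extremes are forced in during calibration only.
- Ambiguous residues count as negative predictions when scoring against a
  reference interface (they are "not called perturbed"); a `positive` and a
  `drop` policy are available.
- The threshold baselines are scored over the full residue set with
  unmeasured residues as negatives — they cannot select what they cannot
  see, which is precisely the weakness inference addresses.

## Known limitations

- Single-pass inference cannot reach missing residues whose neighbors are
  all missing too; such residues are excluded rather than chained.
- The method keeps isolated residues with genuinely extreme values: an
  isolated background outlier can retain a confidence just above the
  decision threshold after smoothing and appear as an isolated perturbed
  call far from any perturbed region. On real data such calls may reflect
  true indirect perturbations; on synthetic data they are false positives.
- CSPs conflate direct contact with induced conformational change; the
  classifier delimits *perturbed* regions, not binding interfaces per se.
- No mmCIF input; structures are PDB-format only.
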