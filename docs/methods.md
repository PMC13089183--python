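# Methods

This note documents the models implemented in `tpmtools`, the choices made
where the procedure was genuinely open, and what the synthetic-data tests
do and do not establish.

## Kinetic models

The single-substrate model is the Michaelis–Menten equation
`v0(S) = Vmax·S/(Km+S)` with `S` in μM and `v0` in nmol/min·mg. With these
units `Vmax/Km` is numerically in L/min·g, which is how catalytic
efficiencies are reported throughout.

**Fitting.** `fit_mm` minimises the unweighted residual sum of squares with
`scipy.optimize.least_squares` under bounds `Km > 0`, `Vmax ≥ 0`.
Initialisation is data-driven — `Vmax0` = largest observed rate, `Km0` = the
design concentration whose mean rate is closest to `Vmax0/2` — and two extra
starts at `Km0/10` and `Km0·10` guard against the flat-likelihood pathology
when the largest design concentration barely saturates the enzyme (a real
risk at the 0/20/200/2000 μM design when Km is in the mM range). The best of
the three starts by residual SS is reported, together with asymptotic
standard errors from the Jacobian at the optimum.

**Zero-concentration rows** are kept as blank anchors rather than dropped:
the model passes through the origin, so a blank with non-zero measured rate
correctly penalises the fit instead of silently disappearing.

**Degenerate data** (all rates zero) returns `Vmax = 0` with `Km` flagged
unidentifiable (`NaN`), not an exception: a flat-zero assay is a valid
observation, and any Km fits it equally well.

**Dual-substrate model.** When the dosed substrate is converted in situ to
a second species up to a breakpoint C1, the apparent rate is the sum of a
first branch following MM in S below C1 and frozen at MM(C1) above it, and
a second branch that is zero below C1 and follows MM in the excess S − C1
above it. The model is continuous at C1 by construction (the second branch
starts at MM(0) = 0) and non-decreasing in S. `fit_c1` holds the two branch
parameter pairs fixed — they are measured beforehand from single-substrate
reactions — and minimises over C1 alone on [0, max S]. Because the
objective has kinks wherever C1 crosses a design concentration, a
2001-point grid locates the basin and bounded scalar minimisation refines
within the bracketing cells (refinement tolerance 1e-6 μM; recovery on
noiseless synthetic data is well inside 0.1 μM). A joint five-parameter
refit is exposed (`refit_branches=True`) but off by default, to keep the
two-stage estimation structure the default analysis.

The published C1 estimate is not restated here; the breakpoint fitter is
validated by parameter recovery on synthetic data instead.

## Conformational energetics

The input is a conformations × fragments matrix of pair interaction
energies (kJ/mol). Per-conformation totals (row sums) measure the ligand's
interaction with the whole receptor/cofactor complex; per-fragment totals
(column sums, optionally within one cluster) rank residue contributions.
Conservation — the two double sums agree — is asserted in the tests to
1e-9 relative.

**Clustering.** Rows are clustered agglomeratively with Ward linkage on
Euclidean distances (`scipy.cluster.hierarchy`); "complete" and "average"
linkage are selectable. Raw PIEs are used as features — all columns share
units, so standardisation is unnecessary and would distort the energy
geometry; a caller can standardise beforehand if desired. The cluster count
can be given directly, via a dendrogram cut height, or left to an automatic
rule: the cut is placed at the largest *relative* gap between successive
merge heights. The relative (not absolute) gap makes the rule invariant to
rescaling all energies by a positive constant, which the tests verify.
Labels are renumbered by first appearance in input order, so the partition
is deterministic and permutation-equivariant. The same partition is
recovered by scikit-learn's `AgglomerativeClustering` on generic data,
which the tests use as an independent cross-check.

**Tukey–Kramer.** Cluster totals are compared all-pairs with the
studentized-range test in its Kramer form for unequal group sizes:
`q_ab = |mean_a − mean_b| / sqrt(s²_pooled/2 · (1/n_a + 1/n_b))`, with the
pooled within-group variance on N − k degrees of freedom and p-values from
`scipy.stats.studentized_range`. Each group needs n ≥ 2 (otherwise the
pooled variance would silently borrow all its information from elsewhere,
so the input is rejected with a message). If the pooled variance is exactly
zero, pairs with unequal means are rejected (q = ∞) and pairs with equal
means are not (q = 0) — comparisons degrade to exact mean equality.
The implementation is cross-checked against statsmodels'
`pairwise_tukeyhsd` in the tests; statsmodels is not used in the
implementation because the pairwise q table and the letter display both
need the q statistics directly.

**Letters and stable clusters.** The compact letter display uses the
insert-and-absorb procedure: start from one letter column containing all
clusters; for each rejected pair, split every column containing both;
absorb columns contained in another. This guarantees that two clusters
share a letter iff their comparison was not rejected. Letters are ordered
by ascending mean total PIE, so the strongest-binding group carries "a".
More negative PIE means stronger interaction; the "stable" clusters are all
those whose letter set equals that of the cluster with the most negative
mean — the statistically indistinguishable strongest-binding group, which
may contain several clusters.

**Binding energy.** `delta_g_bind` implements the bookkeeping identity
ΔG_bind = E_complex − (E_receptor + E_ligand) for component energies
computed by external electronic-structure codes; no energies are evaluated
in this package.

## Attack geometry

Four named atoms define the geometry: the SAM sulfur (S_SAM), the SAM
methyl carbon (C_SAM), the nucleophile (the anionic S of a persulfide, or
Se), and the nucleophile's substituent (the protonated sulfur S₂, or the
methyl carbon of methylselenide). Distances are Euclidean in Å; angles come
from the arccosine of normalised dot products, in degrees. θ is measured at
C_SAM between S_SAM and the nucleophile (near 180° = in-line attack); φ is
measured at the nucleophile between its substituent and C_SAM (100–180° =
the substituent is out of the attack path). For methylselenide the φ
definition carries over by direct analogy with the persulfide case, with
the methyl carbon as the substituent. The θ of the substituent is computed
and reported but never used for filtering.

All cutoffs are inclusive: frames with nucleophile–C_SAM distance ≤ 4.0 Å
and θ in [150°, 180°] are attack-competent; among those, φ in [100°, 180°]
counts as optimal, and the optimal fraction is reported as a percentage of
the extracted frames. An empty extraction yields an *undefined* fraction
(`None`), never 0%, since 0% is a meaningful steric verdict. The φ
histogram uses half-open 10° bins with the last bin closed at 180°.

Inputs are multi-frame XYZ (or a precomputed per-frame geometry table);
native MD-engine trajectory formats are deliberately not parsed —
conversion is one `mdtraj`/`MDAnalysis` call away for users who need it,
and keeping it out holds the package's required dependency set small.
Coordinates are assumed unwrapped and whole; a `units="nm"` flag rescales
nanometre inputs by 10.

## Synthetic-data generators

The generators define the study conditions for all tests.

* **Kinetics**: design concentrations default to the assay's 0/20/200/2000
  μM with 3 replicates. Rate noise is additive homoscedastic Gaussian; the
  assay's true error model is not published, and a luminescence readout at
  moderate signal is adequately summarised by a constant rate SD. The demo
  and the recovery studies use noise SD = 5% of Vmax. Heteroscedastic noise
  is out of scope.
* **PIE matrices**: each planted cluster is a per-fragment mean profile
  plus i.i.d. Gaussian within-cluster noise. The demo fixture mimics the
  scale of the persulfide analysis — 200 conformations, 9 clusters, 4 of
  them with equal totals (≈ −400 kJ/mol) but distinct fragment profiles, so
  they separate in feature space yet remain statistically indistinguishable
  in total energy, exercising the multi-cluster stable set.
* **Trajectories**: frames are constructed to realise exactly the sampled
  internal coordinates (d, θ, φ): C_SAM at the origin, S_SAM at 1.81 Å on
  an axis, the nucleophile at distance d and angle θ with random azimuth,
  the substituent at 2.05 Å from the nucleophile at angle φ with a random
  dihedral, then a uniformly random rigid rotation plus translation per
  frame. The random pose makes the rigid-motion-invariance tests
  non-trivial. Angle distributions (fixed, uniform, truncated normal) are
  truncated to [0°, 180°] by resampling, preserving the in-domain shape.
  The steric-contrast fixtures use φ ~ N(135°, 30°) versus N(75°, 30°) —
  matched widths, means on either side of the 100° boundary — which yields
  optimal fractions of roughly 87% versus 21% and reproduces the
  accessible-versus-hindered contrast qualitatively.

What passing these tests shows: the estimators and scores recover planted
truth under the stated noise models at assay-scale designs. What they do
not show: anything about force-field accuracy, conformational sampling
adequacy, fragment-based energy accuracy, or the real assay's error
structure — those live upstream of this package's inputs.

## Numerical choices and limitations

* Fit tolerances: `xtol = ftol = gtol = 1e-12` for the MM fits; C1 grid of
  2001 points with 1e-6 μM refinement.
* Angle computation clips cosines to [−1, 1]; angles at exactly 0° or 180°
  are returned exactly, but round-trip accuracy degrades (square-root-of-ε)
  in an infinitesimal neighbourhood of those endpoints, as for any
  arccosine-based angle.
* Clustering ties (equal merge heights) follow SciPy's deterministic
  ordering; partitions are reproducible for identical input bytes.
* Envelope JSON rounds floats to 12 significant digits with fixed key
  order, so two runs with the same config and seed produce byte-identical
  numeric payloads (timestamps excluded).
* Problem sizes in the tests — up to 10⁵ frames for distributional checks,
  1000 Monte-Carlo replicates for the family-wise error bound, 200-row PIE
  matrices — were chosen as the smallest sizes at which the statistical
  assertions have comfortable margins.
* The automatic cluster-count rule assumes the planted/true structure is
  separated by a dominant height gap; data with genuinely hierarchical or
  continuous structure should be cut explicitly via `n_clusters` or
  `cut_height`.
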