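# Methods

## Model and data structures

The unit of analysis is a gene class: a named set of gene identifiers
whose members carry a taxon-of-origin index on an ordered lineage
timeline of k taxa (1 = oldest).  Taxon s has a divergence time age_s
in Ma, strictly decreasing in s.  A gene's age is the divergence time
of its origin taxon — a lower bound, since the gene may have arisen
anywhere along the branch it is assigned to.  The default timeline has
16 taxa from Cellular Organisms to H. sapiens.  Four divergence times
are fixed literature values (Opisthokonta 1368 Ma, Bilateria 910 Ma,
Chordata 797 Ma, Homininae 6 Ma); the other twelve are editable
package defaults in the TimeTree style.  Because Deuterostomia sits
between two fixed neighbours it is constrained to (797, 910) Ma and
ships as 850 Ma, which is older than typical literature estimates for
that node; users who care should supply their own timeline CSV.  The
left anchor `root_age` (default 4200 Ma) is a display/median
convention, not a biological claim.

A class of n genes is summarized by per-taxon origination counts and
the cumulative origination curve C(s) = P(origin taxon ≤ s).  Since
taxon order is oldest-first, 1 − C(s−1) is the CDF-complement of age:
a class whose age is stochastically smaller (**younger**) has an
age-CDF that is everywhere larger and an origination curve that is
everywhere lower.  All comparisons operate on these curves.

## Median age

The class median is the Ma value where the piecewise-linear curve
through (root_age, 0), (age_1, C(1)), …, (age_k, C(k)) equals ½.  If
C hits ½ exactly at a breakpoint that taxon's age is returned (first
such breakpoint when the curve is flat at ½); otherwise the crossing
is interpolated linearly on the Ma axis between the bracketing
breakpoints.  Interpolation is needed because a step-function median
could only ever return one of the k taxon ages, while class medians
naturally fall between them.  The left anchor gives classes with ≥50%
mass in the oldest bucket a finite median.  Medians are validated
against an independent fine-grid inversion of the same polyline
(10⁶-point bracketing plus Brent refinement) to 1e-9.

Proportions are always relative to detected n (genes found in the age
table), not the listed class size; the coverage report records
listed/detected/missing per class, and genes missing from the age
table are excluded from all statistics.

## Pairwise tests

The KS distance is max_s |C_A(s) − C_B(s)|.  The two-sample KS test
reports both the asymptotic Kolmogorov p-value (at
√(n_A n_B/(n_A+n_B)) · D) and a pooled label-permutation p-value with
the add-one rule, default 9999 permutations.  With only k ≤ 16 support
points, ties are heavy and the asymptotic value is conservative; the
permutation value is exact-in-distribution under ties and is the
recommended headline number.  Chi-square homogeneity on the r × c
per-taxon count table drops all-zero columns (they would give zero
expected counts and carry no information), reports the column count
actually used, and takes df = (r−1)(c_used−1); three classes over 16
occupied taxa give df = 30.  Holm's step-down adjustment is used for
multiplicity (fewest assumptions among the standard corrections).

## Simultaneous band and the stochastic-order verdict

For a class pair, breakpoints are screened on the pooled curve: taxa
where the pooled cumulative count is 0 or the total are excluded (zero
asymptotic variance), and only the first breakpoint of any flat pooled
stretch is kept, because a taxon with no pooled mass duplicates the
previous coordinate exactly (same difference, same variance); the
screen is integer-exact.  At the m kept breakpoints with pooled
proportions p_1 < … < p_m, the centered difference of empirical curves
converges to a Brownian bridge with covariance
Σ_ij = p_min(i,j)(1 − p_max(i,j)).  Standard errors use the pooled
proportion, se_s = √(p_s(1−p_s)(1/n_A + 1/n_B)) — the null-consistent
choice, since the band is used to test equality/ordering.

The simultaneous critical value c_α is the Monte-Carlo (1 − α)
quantile of max_i |Z_i|/√Σ_ii with Z ~ N(0, Σ): the correlation matrix
is Cholesky-factorized (with an eigenvalue fallback that rejects
matrices below −1e-10 and clips tiny negatives), draws are generated
in blocks of 2·10⁵ rows to bound memory, and the default is 10⁶
replications.  The same draws give the two-sided p-value of
T = max_s |D_s|/se_s as a tail proportion.  Verdicts are signed and
band-supported: `A_younger` requires p ≤ α, at least one breakpoint
whose band excludes 0, and every such breakpoint with D_s < 0;
`crossing` flags band-excluding deviations of both signs;
`no_difference` otherwise.  Swapping the classes negates D, preserves
p and swaps the A/B verdicts.  A Scheffé-style calibration
(c = √χ²_{m,1−α}) is available behind a flag as a conservative
sensitivity check; the max-modulus band is the primary method because
the chi-square bound pays for all contrast directions while only m
coordinate deviations are examined.

Measured under simulated study conditions (fully occupied 16-taxon
profile, n = 500 per side, 1000 null simulations, 10⁵ MC replications
per test): type-I error ≈ 0.05–0.06 at α = 0.05; power ≥ 0.90 against
a two-taxon rootward shift (200 simulations); the α = 0.05 band covers
zero at all breakpoints in ≈ 95% of 500 null runs at n = 200 per side.
These problem sizes are the package's validation conditions and are
what the acceptance script re-runs.

## Clustering and bootstrap

Classes are clustered agglomeratively on the KS-distance matrix with
complete linkage (inter-cluster distance = maximum pairwise member
distance, so merge heights are nondecreasing).  Ties are broken by the
lexicographically smallest pair of cluster representatives, making the
tree deterministic; the implementation is cross-checked against
scipy's complete linkage on generic matrices.  Trees serialize to
ultrametric Newick (branch length = parent height − child height).

Bootstrap support resamples every class independently at its original
size — equivalently, a multinomial draw over the class's empirical
per-taxon proportions, which is how replicates are generated — and
rebuilds distance matrix and tree; a clade's support is the fraction of
replicate trees containing the same leaf set (topology-only
comparison; heights are ignored).  Classes sharing genes are still
resampled independently, which ignores the induced dependence between
their replicate curves; supports for clades joining heavily
overlapping classes should be read with that in mind.  Per-class
"first-merge" support (the clade formed when the leaf first merges) is
reported alongside node supports.  The same resampling yields
per-breakpoint bootstrap means, MSE against the original curve,
medians and quartiles, and the rates at which one class's replicate
curve lies entirely at-or-below the other's with strict inequality
somewhere (`A_lower` / `B_lower` / `no_strict_order`; curves tied
everywhere count as no strict order, and the three rates partition the
replicates).  Default 10⁴ replicates; validation suites use 500.

## Overlap analysis

Pairwise overlap of classes A, B over a universe of N genes is tested
against the independence expectation N·(|A|/N)·(|B|/N) via the 2×2
membership table: chi-square without continuity correction, and the
two-sided Fisher exact test by the point-probability rule (sum of
hypergeometric probabilities no larger than the observed table's, with
the standard 1 + 1e-7 relative gate; a zero margin gives p = 1 by
convention).  The universe defaults to all genes detected in the age
table and is overridable — expected counts are universe-sensitive.
Triple and quadruple intersections report counts and per-member
shares.  Derived subclasses (`A x B` intersection, `A - B`
difference) are added to the catalog by name and behave as ordinary
classes downstream.

## Synthetic generator

`simulate_study` realizes classes in order over a universe of
19,911 genes (the detected protein-coding count used as the reference
figure): each class draws taxon indices i.i.d. from its origination
profile π; a class declaring `overlap_with=(other, frac)` takes
round(frac·n) members without replacement from the earlier class —
shared genes keep the single age they were first drawn with (the first
class's profile) — and fills the rest with fresh universe genes;
remaining universe genes follow a base profile.  Generation is a pure
function of (specs, seed).

`paper_like_spec` provides ten classes at realistic detected sizes
(6789, 3697, 984, 231, 224, 121, 109, 78, 60, 53) in three stylized
profile families (old / intermediate / young step-up profiles, written
by hand, not digitized from any figure).  What the generator does
*not* emulate: identifier ambiguity across databases, non-multinomial
dependence between genes (e.g. gene families aging together),
class-membership errors, or any real database's actual curve shapes.
Passing tests therefore demonstrate that the statistical machinery is
correct and calibrated under the stated sampling model, not that any
biological conclusion about real gene classes is reproduced.

## Numerical choices and edge cases

- Empty classes are refused by every distribution builder; classes
  with zero detected genes are flagged in the coverage report.
- Ma-valued age tables map a value to the oldest taxon with
  divergence time ≤ value + 1e-6.
- Permutation and order-test comparisons use a 1e-12 slack when
  comparing replicate statistics to the observed one; bootstrap curve
  ordering uses the same slack for strictness.
- The MC p-value is a plain tail proportion (0 is reportable; the
  resolution is 1/n_mc).
- BLAST parsing enforces the 12-column tabular layout, treats the
  E-value threshold as a single scalar (default 1e-3; no universal
  cutoff exists), collects unmappable subjects into a reject list, and
  assigns empty profiles to the youngest bucket.
- All CLI outputs are flat CSV/TSV/Newick/JSON with no timestamps;
  every stage's randomness flows from one seed, so identical
  invocations are byte-identical.

## Known limitations

- The asymptotic band is slightly anti-conservative at moderate n
  (measured type-I ≈ 0.055 at n = 500); no finite-sample correction is
  applied.
- No one-sided band variant; the two-sided band is used for the
  signed verdict.
- Gene-id matching is exact-string; no symbol-alias resolution.
- The linear lineage cannot represent non-nested taxon sets; the
  clustering operates on classes, not on a species tree.
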