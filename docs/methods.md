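# Methods

## Scope and data model

The package implements the computational half of an HPLC
fingerprint + QAMS quality-evaluation workflow for a multi-herb formula.
All interchange is CSV; retention times are minutes and peak areas are
arbitrary detector units. The screening constant 0.4 ("area greater than
0.4") is interpreted in those same arbitrary units, and both screening
inequalities are strict: solvent shearing removes rt **<** 5 min (a peak
exactly at the cut survives), the area screen keeps area **>** 0.4 in
every batch. Duplicate retention times within one table (Δrt < 1e-6 min)
keep the larger area with a warning rather than failing, since real
integrators occasionally emit split rows.

## Peak detection

Apexes are local maxima above configurable height and prominence
thresholds (`scipy.signal.find_peaks`). Each peak is integrated by the
trapezoid rule between bounds at apex ± 4σ (σ estimated from the FWHM),
clipped at the signal minimum shared with a neighbouring apex, after
subtracting the linear chord joining the bounds. For an isolated Gaussian
this captures 99.99% of the analytic area; the unit test requires
agreement within 2% and apex placement within one grid step. Peaks whose
baseline-corrected area is non-positive are dropped. Deconvolution of
genuinely overlapping peaks is out of scope; the generator warns when it
plants peaks closer than 4σ.

## Cross-batch matching

The matching algorithm is deliberately simple and deterministic: clusters
are seeded from the reference batch's peaks (first batch by default); each
other batch contributes its nearest unassigned peak within the tolerance
window (0.5 min default — the window is configurable because no published
value exists). A single refinement pass then recomputes each cluster's
median retention time and re-assigns members against it. The refinement
matters at the tails: the seed's own jitter effectively doubles the
variance of the seed-to-member distance, whereas the median of ~10
jittered members is a much tighter center, so re-assignment against it
makes exact ground-truth recovery robust at jitter levels (0.1 min SD) a
fifth of the tolerance. A cluster is a common peak iff it has exactly one
member per batch and survives the area screen; columns are numbered 1..K
in elution order and the consensus rt is the member median. Ties in
localization queries (relative retention value or rt difference) break
toward the larger area, dominant peaks being the intended landmarks.

## Fingerprint similarity

The reference fingerprint is the per-peak median over batches; with an
even batch count the midpoint of the two central order statistics is used
(the source software's convention is undocumented; this is the numpy
convention and is what the 10-batch study most plausibly used). Batch
similarity is the included-angle cosine on common-peak area vectors — the
documented default of the similarity-evaluation software — with Pearson
correlation available as an alternative metric. RSDs use the sample
(n−1) denominator, the pharmacopoeial convention. Designation of the
reference peak for relative-area statistics is a caller input (an index),
not a guess.

## PCA and PLS-DA

PCA defaults to the correlation matrix, matching the SPSS factor-analysis
convention of the source tables: reported loadings are component loadings
`eigenvector · √λ` and therefore lie in [−1, 1], and the eigenvalue sum
equals the number of variables. Eigenvalues below 1e-10 of the trace
count as zero; eigenvector signs are fixed by making each component's
largest-magnitude loading positive. With 10 batches and 29 peaks the
standardized matrix has rank ≤ 9, so exactly 9 components carry 100.000%
cumulative contribution — an analytically forced result the acceptance
suite checks.

PLS-DA uses NIPALS with a centered dummy-coded response (one column per
class, deterministic class ordering by sorted label), X standardized
internally, weight vectors stored unit-norm, tolerance 1e-12 on the
weight change, 500 iterations maximum. The explained response sum of
squares per component is `SSₐ = (tₐᵀtₐ)(qₐᵀqₐ)`, giving
`VIPⱼ = √(p·Σ SSₐ wₐⱼ²/Σ SSₐ)` with the identity `Σ VIP² = p` (tested to
1e-9, and cross-checked against scikit-learn's PLS weights on balanced
two-class data, where response scaling is a harmless scalar). The study
never states which classes its 10 batches were assigned, so class labels
are a required input; the pipeline's default contrast (first half vs
second half of the batch sequence) is an arbitrary QC split and its VIP
ordering should be read qualitatively.

## Quantitation

Contents are mg per g of powder. The prep constants (0.5 g dissolved in
25 mL, 5 µL injected) imply that 1 µg on-column corresponds to 10 mg/g;
all published per-batch contents invert through their calibration lines
to amounts inside the published linear ranges, which is what fixes the
unit. The QAMS content equation `C_x = (A_x·C_is)/(f_x·A_is)` is the
standard single-marker form algebraically consistent with the correction
factor definition; under zero intercepts and shared calibration it is
*identical* to the external standard method (property-tested to 1e-10).
With nonzero intercepts QAMS acquires a bias of order
`intercept / area`; on the synthetic default panel this reaches ~6% for
neochlorogenic acid, whose intercept is ~6% of its peak area — a real
limitation of single-marker quantitation at low analyte levels, which the
published ±1% agreement implicitly avoided by working far from the
intercepts. Out-of-linear-range inversions warn rather than abort, since
a QC report must not die on one bad batch.

Reported values follow the tables' precision — contents to 3 decimals,
relative errors to 2, correction factors to 3 — rounding half away from
zero with a 1e-9 relative guard that absorbs binary-float accumulation
error just below rounding midpoints (the phillyrin replicate mean is
exactly 0.8375 in decimal but 0.83749999… in floats). Internal arithmetic
is always full precision. The replicate-level correction-factor RSDs
recompute from the printed 3-decimal replicates as 0.38% for phillyrin
where 0.41% was printed from unrounded areas; tests therefore assert a
±0.1 percentage-point band on RSDs and exactness only on the means.

## Synthetic data generator

The generator emulates the study's structure, not its chemistry. Defaults
(all recorded in the design manifest, not asserted as facts about the
study):

| parameter | default | rationale |
|---|---|---|
| batches | 10 | panel size of the study |
| common peaks | 29, rt 7–126 min | the screened fingerprint size |
| peak width σ | 0.1 min | plausible for a 130-min gradient; none published |
| area CV (between batches) | 8% | moderate batch variation; log-normal so areas stay positive |
| rt jitter SD | 0.1 min | one fifth of the matching tolerance |
| baseline noise SD | 0.01 | SNR ≫ 10 at the smallest common peak |
| spurious peaks | 15 (8 sub-threshold everywhere, 7 supra-threshold in ~60% of batches) | exercises both screening rules |
| solvent peaks | 3 before 5 min | exercises shearing |
| grid step | 0.01 min | ≥ 10 points per peak FWHM |

Common-peak mean areas start at 0.7, seven log-sigma above the 0.4
screen at 8% CV, so a planted common peak essentially never fails the
screen; sub-threshold means stop at 0.32, and partially present peaks are
*structurally* absent from at least one batch, so spurious peaks
essentially never pass. The seven analyte peaks carry the published
calibration-line responses: their 237 nm areas sit on the 237 nm lines at
typical contents, their 327 nm areas on the 327 nm lines (zero response
for phillyrin and arctiin, which do not absorb there) — which is why the
simulated correction factors land within ~1% of the published means.
The generator is a pure function of (design, seed).

What the generator does **not** emulate: peak tailing and asymmetry,
retention drift correlated along the gradient, column aging,
co-elution/deconvolution, heteroscedastic detector noise, and any real
chemical variation between herb lots. Passing tests therefore demonstrate
correctness of the algorithms under the stated statistical model, not
performance on real chromatograms with pathological peak shapes.

## Problem sizes in tests and acceptance runs

The stochastic checks use 50 seeded panels for exact common-peak recovery,
200 for the similarity gate, and 1000 light-weight replicate draws for
spike-recovery coverage — sizes at which the whole suite completes in
well under a minute while binomial noise on the asserted proportions is
negligible. The reported similarity bound is the 5th percentile of the
200 per-panel minima, i.e. the level the worst batch clears in 95% of
runs.

## Known limitations

* The study's intermediate screening counts (112 → 38 → 29) depend on its
  raw data; only the rules are implemented, and the 29 arises here because
  the generator plants 29 — the count validates the cascade, not the
  chemistry.
* Matching is greedy nearest-within-tolerance, not a global optimum;
  panels with retention drift larger than half the inter-peak spacing
  would need profile alignment (out of scope).
* Replicate-level correction-factor inputs behind the published means are
  not available; replicate regeneration is synthetic only.
* QAMS supports curve-based internal-standard contents (default) and
  single-point ones; which the study used is unstated.
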