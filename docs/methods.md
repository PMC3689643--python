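# Methods

This note records the scientific and numerical choices behind `precombi`,
in the package's own terms: what each quantity is, how it is computed, what
the simulator emulates, and where the design was genuinely open.

## Endpoints

**Tumor volume.** V = a²·b/2 with a the shorter and b the longer caliper
diameter (mm). Readers enforce a ≤ b by swapping (with a logged warning)
rather than rejecting, since caliper entry order is arbitrary while the
formula's roles are not. Units are fixed — mm, mm³, grams — with no
auto-detection.

**TGI.** 100 − (W_T/W_C)·100 on the same central statistic and day for both
groups. The central statistic defaults to the median (midpoint of the two
central order statistics for even n), matching the convention of reporting
median tumor burden; the mean is available for curve plotting. TGI can be
negative (treated larger than control) and is capped above at 100 by
construction since volumes are non-negative.

**ILS.** (MST_T/MST_C)·100 − 100 on Kaplan–Meier median survival times, so
that longer survival is positive. The formula is sometimes printed in the
literature with the opposite sign while the tabulated values are positive
for life extension; this package fixes the sign so positive = benefit.
Sacrifice of moribund animals counts as an event; animals alive at study
end are censored at that day. With no censoring the KM median reduces to the
sample median. An unreached median makes ILS undefined (error), not zero.

**TGD.** Time for the *group central* volume curve to reach a threshold
(default 1000 mm³). A crossing between measurement days is located by
linear interpolation of log-volume against day — exact for exponential
growth — and reported to one decimal; tables round to whole days.
Per-animal TGD can be obtained by running `tgd` on individual series. A
curve that never crosses yields a "not reached" sentinel rather than an
error. ΔTGD is the plain difference vs control, or vs the cytostatic-alone
group for combinations.

**BWC.** (ABW_n/ABW_1)·100 − 100 on the group mean body weight, with ABW_1
taken on the first treatment day (the earliest administration day in the
design unless overridden). The toxicity surrogate is the maximal decrease,
max(0, −min BWC), over days from baseline on.

**Proliferation inhibition.** 100 − (At−Am)/(Ac−Am)·100 from treated,
control and medium-blank absorbances; the same positive-=-benefit sign
convention as ILS. A plate with Ac ≤ Am is invalid. Replicates are averaged
with an SD.

**Rounding for reports.** Percentages in rendered tables are rounded half
away from zero to integers; raw values are always retained on the objects.

## Combination scoring

The fractional-product null assumes the two agents act independently on
the *unaffected* fraction: surviving fractions multiply, so
%H = 100 − (100−E₁)(100−E₂)/100. It is symmetric, has 0 as identity, and
for E₁,E₂ ∈ [0,100] satisfies max(E₁,E₂) ≤ %H ≤ 100. Effects above 100 are
rejected; negative effects (agent worse than control) are legal inputs.

Classification rule order: antagonism (E_obs < E_cytostatic) is checked
*before* the additive tolerance band — a combination that underperforms the
cytostatic alone is antagonistic even if it happens to sit numerically near
%H. The "comparable" band defaults to **3 percentage points**: in the
bundled reference dataset this is the only integer tolerance consistent
with an additive call at |E_obs − %H| = 3 alongside a synergism call at a
gap of 4. It is configurable everywhere.

%H is computed from unrounded single-agent effects when the pipeline
produced them; the replicate-tables mode, which works from printed
integers, necessarily uses the integers.

## Reference-dataset replication

The package bundles the printed single-agent/combination effect integers of
a published preclinical study (cytostatic 5-FU ± vitamin D analogs, mouse
colon cancer) across five experiments plus an SRB in-vitro panel and a TGD
table. Recomputing every %H and verdict reproduces 28 of 38 effect cells
and 4 of 5 TGD differences exactly after integer rounding. The remaining
10 cells and 1 TGD delta are internally inconsistent in the source report
itself — e.g. a printed %H of 44 where the printed inputs (48, 7) give 52
under any rounding (a sign slip in the modulator effect, −7, would give
44), several off-by-one cells consistent with %H having been computed from
unrounded effects before printing, and one verdict that contradicts the
stated rule order. These are catalogued in
`precombi.reference_tables.EXPECTED_INCONSISTENT` and regression-tested:
the set must not grow or shrink silently.

## Statistical tests

All four tests are implemented directly so the exact and asymptotic
branches share one statistic definition; scipy/lifelines and brute-force
enumeration serve as independent oracles in the test suite.

* **Kruskal–Wallis**: tie-corrected H, asymptotic χ²(k−1) p. Pairwise
  multiple comparisons use Dunn's z on mean ranks with Bonferroni
  adjustment, two-tailed — the conventional reading of a statistics suite's
  "ANOVA multiple comparison (2-tailed)" label; the adjustment choice is a
  documented convention, not a fact about any particular source.
* **Mann–Whitney U**: midrank ties; normal approximation with tie
  correction and continuity correction.
* **Peto–Peto Gehan–Wilcoxon**: weighted log-rank with weight equal to the
  left-continuous pooled Kaplan–Meier estimate just before each event time;
  hypergeometric variance with ties. Setting all weights to 1 recovers the
  standard log-rank statistic (cross-checked against lifelines).
* **Tukey HSD** (Tukey–Kramer for unequal n): studentized-range p-values.
  The q statistics are exposed separately (`tukey_q`) so large null
  simulations can compare against a single critical value instead of
  evaluating the studentized-range tail per replicate.

**Exact small-sample branch.** For total n ≤ 10 the rank and survival tests
switch automatically to full enumeration of label assignments (two-tailed:
probability of a statistic at least as extreme in absolute deviation).
Simulated type-I error at α = 0.05 for all four tests lies within
[0.03, 0.07] at the suite's simulation sizes (3×10 for KW, 12+12 for MWU,
10+10 uncensored exponential for the survival test, 3×8 normal for Tukey,
10 000 null replicates each) — computed by the acceptance tests, not
asserted from theory.

## Synthetic studies

The generator emulates a four-group subcutaneous mouse study. Latent growth
is exponential by default (Gompertz available): V₀ = 10 mm³ at
randomization, rate 0.19/day — a doubling time of ~3.6 days that carries
the control curve to 1 cm³ about day 24, typical of a brisk murine colon
tumor. Treatment enters as a volume fraction f at the evaluation day
(default day 21): the treated latent curve is the control curve times
f^(t/t_eval), i.e. a constant growth-rate reduction under continuous
dosing, exactly f at t_eval. Defaults f₁ = 0.5, f₂ = 0.8 give single-agent
TGIs of 50% and 20%, the range typical of a moderately active cytostatic
paired with a weak modulator.

The combination's fraction is f₁·f₂·γ: γ = 1 is the Bliss null (the
pipeline must and does return `additive` for any noiseless grid point),
γ < 1 super-additive, γ > 1 sub-additive; the γ-implied verdict under the
chosen tolerance is stored as ground truth. Measurement noise is
multiplicative lognormal on volume (default SD 0.08 ≈ 8% caliper error),
distributed onto two diameters with a fixed shape ratio b = 1.5·a so the
volume formula is exact in expectation on the log scale. Animals are
sacrificed on the first whole day the *latent* volume reaches 2000 mm³
(deliberately distinct from the 1000 mm³ TGD threshold), else censored at
the last measurement day; all randomness flows from one seed through
spawned substreams keyed by (group, animal index).

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: inter-animal heterogeneity in growth rate (within
a group, latent curves are identical; only measurement noise varies, so
within-group survival spread is absent), treatment-related toxicity and
body-weight loss, pharmacokinetics, resistance or regrowth after dosing
ends, and non-monotone or regressing tumors. Recovery results are
statements about the measurement-noise model, not about biological
variability.

Plate simulation inverts the inhibition formula: At is centered on
Am + (Ac−Am)(1 − I/100) with additive Gaussian noise, so the noiseless
round trip is exact.

## Problem sizes and degenerate inputs

The verification suite uses n = 3/group for noiseless grid recovery (exact
by construction), n = 8/group × 500 replicates for the noisy power check
(γ = 0.6 detected as synergism in ≥ 80% of replicates; observed ~100%),
and 10 000 replicates per type-I calibration — sizes chosen as the smallest
at which each property is meaningful. Degenerate inputs are errors, not
silent passes: empty groups, zero control volume, unreached medians,
invalid plates, n/group < 3 (medians degenerate), a > b after
normalization. All-identical observations give H = 0, p = 1.

## Known limitations

* TGD is computed on the group central curve by default; per-animal TGD
  averaging (the other convention in the field) is available by applying
  `tgd` per animal but is not the table default.
* The additive band is a plain ±tol on percentage points; no uncertainty
  propagation from group sizes into the verdict.
* Survival handling assumes right-censoring only; no competing risks.
* The CLI analyze path evaluates TGI only on days present in the
  measurement grid of every group involved.
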