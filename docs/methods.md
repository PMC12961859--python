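# Methods

## The measurement problem

Patient-reported outcome scales assume that an item means the same thing to
everyone, all the time.  Two well-documented violations are **differential
item functioning** (DIF) — two groups with the same level of the measured
construct respond differently to an item — and **recalibration response
shift** (RS) — a person's internal standard for the response categories
drifts between assessments.  Ignoring either biases estimated group
differences and changes over time in the construct.  This package detects
both at the item level in two-group, two-timepoint polytomous data, and
estimates group and time effects on the latent construct with the detected
non-invariances freed.

## Model

Responses follow the partial credit model (PCM).  Person *i* with latent
level θ answers category *x* ∈ {0, …, M<sub>j</sub>} of item *j*:

P(X = x | θ) = exp(xθ − Σ<sub>p≤x</sub> δ<sub>jp</sub>) / Σ<sub>l</sub> exp(lθ − Σ<sub>p≤l</sub> δ<sub>jp</sub>)

δ<sub>jp</sub> is the latent level at which categories p−1 and p are
equally probable.  The latent trait is normal: cross-sectionally
Θ<sub>g</sub> ~ N(μ<sub>g</sub>, σ²) with μ fixed at 0 in the reference
group and σ² shared across groups; longitudinally (Θ<sup>(T1)</sup>,
Θ<sup>(T2)</sup>) is bivariate normal per group with means free per
(group, time) except μ<sub>G0</sub><sup>(T1)</sup> = 0, variances free per
time but shared across groups, and a T1–T2 covariance shared across
groups.  Estimation is marginal maximum likelihood: the latent trait is
integrated out by fixed-order Gauss–Hermite quadrature (tensor-product grid
in the bivariate case) and the observed-data likelihood — missing responses
simply drop out of the within-person product — is maximized by L-BFGS with
the exact analytic score.

DIF on an item adds free offsets to its thresholds in the non-reference
group (at both time points); recalibration adds free shifts at T2, either
shared by both groups or group-specific.  "Uniform" variants restrict the
offsets/shifts to a single scalar — a horizontal translation of the item
characteristic curve; free per-threshold variants change its shape.
Because offsets enter additively, the quantities of interest (a -0.32 DIF
offset, a +0.56 time shift) are themselves model parameters with standard
errors from the observed information.

Identifiability is structural: if every item carries DIF, a common offset
is indistinguishable from the group mean, so μ<sub>G1</sub><sup>(T1)</sup>
is fixed at 0; if every item shifts over time within a group, that group's
time effect is fixed at 0 (the T2 mean is tied to the T1 mean).  These
constraints are derived from the item declarations, never from data, so
free-parameter counts — and hence likelihood-ratio degrees of freedom —
are deterministic.

## The detection procedure

Two sequential algorithms, each gated by an overall likelihood-ratio test
(fully non-invariant vs fully invariant model; the gate can be disabled):

1. **DIF at T1** (cross-sectional).  Starting from the invariant model,
   each unflagged item is tested by freeing its thresholds across groups
   (df = M<sub>j</sub>); the most significant item whose Bonferroni-adjusted
   p (multiplied by the number of candidates in that iteration) is below α
   is flagged, the model is refit with that item freed, and the scan
   repeats — so every iteration conditions on the effects already found.
   It stops when nothing is significant or when all but one item is
   flagged (freeing the last would merely re-express the group effect).
2. **RS between T1 and T2** (longitudinal, carrying the DIF structure
   forward unchanged — no second DIF scan at T2).  Identical iteration,
   freeing thresholds over time separately per group (df = 2M<sub>j</sub>).

Each flagged item is characterized by nested restrictions tested at the
same α, most restrictive form retained and adopted into the working model:
for RS, first scope (shared shift vs group-specific, including dropping a
group whose shift is indistinguishable from zero), then uniform vs free
form per scope (and per group when group-specific).  Flagging always uses
the fully free thresholds; the restrictions are follow-up tests, so a
uniform shift is reported as one offset "for all p" exactly when the data
do not contradict it.

Finally the adjusted longitudinal model (all retained non-invariances
freed) and the naive fully invariant model are both fit, and group effects
at each time point plus time effects per group are reported side by side
with delta-method standard errors and Wald p-values.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| α | 0.05 | level of every test (overall gates, Bonferroni-adjusted scans, characterizations) |
| quadrature order | 30 per dimension | Gauss–Hermite nodes; 30 is accurate to ≪1e-4 in log-likelihood over the \|θ\| ≤ 4 range relevant for these scales; simulation studies in this repository use 12–15 for speed, which leaves test decisions unchanged at these sample sizes |
| misfit band | [0.7, 1.3] | conventional rating-scale band for INFIT/OUTFIT |
| optimizer | L-BFGS-B, ftol 1e-11, gtol 5e-5 | deterministic quasi-Newton on the unconstrained scale (log variances, atanh correlation); analytic score |
| Hessian step | relative 1e-5 | central differences of the analytic score for standard errors |
| θ grid for curves | −4 … 4, step 0.05 | range displayed in practice for these scales |

Bonferroni denominators are the number of items tested in the current
iteration (shrinking as items are flagged): the per-iteration candidate set
is the natural testing family.  Ties in adjusted p are broken by item
order, making the whole procedure deterministic; identical input and
settings reproduce detection reports byte for byte.

## Item-fit screening

Before detection, items are screened at T1.  INFIT (information-weighted)
and OUTFIT (unweighted) mean-square statistics standardize each residual by
**leave-one-out posterior predictive moments**: for item j the person's
posterior over θ is formed from their other responses under the fitted
marginal model, and E, V are the predictive mean and variance of
X<sub>ij</sub> under that posterior.  With this construction
E[(x − E)²] = V holds exactly under the model, so both statistics center
at 1 for any scale length; plugging in a point estimate computed from all
items (the more traditional recipe) deflates them to ~0.75–0.85 on 4–7
item scales and would make the conventional band meaningless.  Items
leaving the band on either statistic are flagged; removal is an explicit
analyst decision, never automatic.  Screening also reports disordered
thresholds (δ<sub>p</sub> > δ<sub>p+1</sub>) and empty cells of the
category × group table per time point; adjacent categories can be
collapsed — identically in every (group, time) cell — with an automatic
suggestion that merges a sparse category toward the scale midpoint, and
explicit analyst-specified merges taking precedence.

## Synthetic data

The generator draws latent pairs from the group's bivariate normal and
responses from the PCM with that cell's effective thresholds (base + DIF
offset in the non-reference group + RS shift at T2); missingness is
completely at random.  Defaults mirror a two-cancer-cohort
HADS study design: groups of 336 and 110, six 4-category items, thresholds with
1.1-logit spacing and item locations spread over [−0.9, 1.35], unit
variances, T1–T2 correlation 0.6, 2% missingness.  The scenario library
plants effect magnitudes of the size such studies report: `anxiety_like` (uniform DIF −0.32
on one item; shared uniform shift +0.56 on another; group means −0.88 /
−0.79 / −0.96) and `depression_like` (shared uniform −0.41; a
group-specific shift non-uniform −1.59…−0.57 in the reference group — the
middle threshold set to −1.0 — and uniform −0.66 in the other;
the reference group's true time effect exactly 0, which is what makes the
recalibration bias visible).  What the generator does *not* emulate:
informative dropout, person covariates beyond the group, response styles,
or reprioritization/reconceptualization forms of response shift — passing
tests say nothing about those.

## Numerical choices and degenerate inputs

Category probabilities and per-person likelihoods are computed in log space
with max-subtraction, so extreme θ or thresholds cannot overflow.  The
correlation is estimated as atanh(ρ), keeping the longitudinal covariance
positive definite throughout optimization; degenerate inputs (non-PD
covariance, quadrature order < 5, non-finite θ or thresholds, unknown
cells) raise immediately.  An item with an entirely unobserved category is
refused at model construction with a pointer to category collapsing, since
its outer threshold would diverge.  A person missing every response at
both time points is excluded at ingestion (with a logged count); a person
missing one entire time point still contributes the other.  Fits that stop
without meeting the convergence test are returned flagged and warn, and
standard errors refuse to compute from them; a singular observed
information falls back to a pseudo-inverse with NaN standard errors for
the affected parameters.

## Monte-Carlo problem sizes

The test suite and `scripts/acceptance.py` run simulations at the study's
sample sizes with quadrature order 15 (12 for plain model fits in the bias
contrast).  Replicate counts are chosen to keep full runs practical on one
core: 200 replicates for null calibration in the test suite (100 in the
acceptance script), 25–30 for detection rates, 12–15 for scope
classification and the bias contrast.  With these counts a true rate of
0.05 is estimated to ±0.03 and the bias contrast's Monte-Carlo standard
error is ~0.02 on a bias of ~0.2.

## Known limitations

- Detection power at the planted effect magnitudes is modest: a uniform
  DIF offset of −0.32 with ~110 persons in the smaller group carries an
  overall-test noncentrality of ≈4 on 17 df (theoretical power ≈ 8%), and
  the group-scope contrast for the depression-like item has power ≈ 45%.
  The procedure controls false detection tightly; single planted effects
  of that size are simply not reliably detectable at these sample sizes,
  and the acceptance checks report those rates as measured.
- Exactly two groups and two time points; one binary covariate.
- Recalibration only; reprioritization/reconceptualization response shift
  is outside the model family.
- The latent trait is normal by assumption; no skew or mixture latent
  distributions.
- No person-level ML/WLE trait estimates are exposed; the screening
  statistics use posterior moments instead.
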