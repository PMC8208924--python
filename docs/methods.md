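# Methods

## Task model

One foraging run lasts 300 s in a square 600 × 600 px arena hiding nine
circular patches (radius 57 px) of 40 resources each. Patch centers are
drawn uniformly by rejection sampling under three constraints, all read
as Euclidean distances: patch boundaries at least 9 px apart (center
distance ≥ 2·57 + 9 = 123 px), patch boundaries at least 15 px from
every arena border (centers ≥ 72 px from each edge), and patch centers
at least 57 px from the arena midpoint. The distance phrasing of the
first two constraints is ambiguous between center-wise and boundary-wise
readings; the boundary-wise reading is used because radius-57 patches
with centers 9 px apart would effectively coincide. For the arena-center
constraint the looser center-to-center reading is used. Within each
patch's 600 × 600 px zoomed view, 40 resource positions are drawn
uniformly with pairwise spacing ≥ 30 px; the full canvas is allowed
(edge-avoidance is unstated in the task description). Rejection sampling
has a hard attempt cap (default 10,000) and raises on infeasible
configurations rather than falling back to constructive packing, because
the task draws positions from uniform distributions.

Aerial movement is capped at 60 px/s, patch-view movement at 90 px/s.
Patches become visible when any part lies within 15 px of the agent;
resources are found when they come within 30 px of the hand. The on-screen
counter starts at 60 px/s × 300 s = 18,000 and decreases 60 units/s,
floored at zero (the floor is a choice; the source is silent on negative
values, and with default parameters the counter hits exactly 0 at the end).

## Reward-rate signals and the LTD statistic

All analysis consumes a timestamped event log (position samples at 20 Hz
plus patch-enter/patch-exit/reward events). The sampling rate is a
package choice (none is stated for the original task); it is configurable.

* **CRR(t)** — rewards in the trailing window (t − W, t] divided by W.
  The window is causal: a real-time forager only has past rewards. W is
  the free parameter the window fit (below) selects.
* **ARR(t)** — cumulative rewards up to t divided by t, with ARR(0) := 0.
  Travel time is in the denominator (T = t + T_P); over one continuous
  session this equals the session-cumulative average.
* **OLT** — per visit, CRR peaks are strict local maxima of the sampled
  CRR within [t_enter, t_exit] (a plateau maximum reports its first
  sample). The visit's OLT is the first time at or after the **last**
  peak where CRR crosses ARR from above, located by linear interpolation
  between bracketing samples; exact ties count as crossings. The search
  runs past the visit's exit — the trailing-window CRR keeps decaying —
  up to the next patch entry (or the run's end). Positive LTD is only
  observable because of this extension.
* **LTD = OLT − ALT** per visit; the participant score is the mean over
  defined visits. Visits with no peak, no crossing before the next
  entry, or censoring (the run clock expired inside the patch) are
  excluded rather than imputed: a censored exit is not a leave decision,
  and the original handling of such visits is unreported.

The pairing of each visit's ALT with the first crossing after the
visit's *last* peak is a package decision (no pairing rule is stated in
the source description); it reads the final CRR rise before departure as
the decision-relevant one.

Conservation checks pin the signal definitions: each reward contributes
1/W to CRR for W seconds, so ∫CRR dt equals the reward count when every
reward is ≥ W before the end; ARR(t)·t equals the cumulative count
exactly.

## Window fit

The CRR window is chosen as the one whose cohort-average LTD is closest
to zero: iteration 1 scans 200 windows over 0–20 s in 100-ms steps,
iteration 2 scans 50 windows over ±0.25 s around the iteration-1 winner
in 10-ms steps. The published counts (200, not 201; 50, not 51) force a
half-open grid (start, stop] excluding the zero-length window, which is
undefined anyway. The aggregate is the mean over participants of
participant-mean LTD (mean-of-means; pooling across visits is the other
reading of an ambiguous phrase), ties break toward the smaller window,
and iteration 2 is generalized to ±0.25 s around any winner — the
published 8.75–9.25 s grid is the special case of a 9.0-s winner.

## Synthetic agents

Agents are test instruments with known ground truth, not models of human
cognition; their kinematics are unconstrained beyond the task's speed
caps, and no fidelity claim is made about movement statistics.

Policies: `fixed_residence` (leave a fixed time after entry),
`give_up_time` (leave a fixed time after the last reward; the clock
resets on every pickup), `random_walker` (uniform random residence), and
`mvt_offset` (below). Travel is either `nearest_known` (return to any
known, unexhausted patch, preferring never-visited ones) or `sweep`
(serpentine search; each patch entered at most once). Within a patch the
hand either random-walks or runs a lawnmower path whose progress
persists across visits to the same patch. Aerial travel defaults to the
60 px/s cap but can be slower (`travel_speed`): agents need not move at
the cap.

### The planted-offset instrument

`mvt_offset` agents leave `olt_offset_s` = δ seconds relative to their
own online OLT, so the analysis should recover LTD ≈ −δ. The agent runs
the same CRR/ARR machinery as the analysis (same window, default 9 s)
and mirrors the analysis pairing exactly: it tracks the last *sealed*
peak (a strict local maximum becomes a peak only once a lower sample
follows it) and the first crossing at or after it — observed once it
happens, otherwise projected forward under a no-further-reward
assumption, which becomes exact the moment the agent stops harvesting.

* δ > 0: once the crossing is observed the agent idles (harvesting more
  would create a later peak and re-pair the visit) and exits δ after it.
* δ = 0: exit at the crossing.
* δ < 0: exit δ before the *projected* crossing. This is non-causal for
  a real forager but well-defined for an instrument: the projection is
  valid because exiting stops the reward stream. A plan is only acted on
  while its crossing is still ahead; if the crossing has already passed,
  the agent keeps harvesting until a fresh peak resets the pairing. If
  the projected lead is smaller than |δ| the agent exits immediately,
  yielding a partial offset for that visit.

The early-leave head start requires the CRR to sit above the ARR for at
least |δ| seconds after a peak. After a visit, the windowed CRR decays to
the ARR in roughly W·(1 − ARR/r) seconds, where r is the recent harvest
rate, and ARR ≈ r × (fraction of time spent harvesting). A 3-s head
start under a 9-s window therefore needs the harvesting duty cycle below
about 2/3. The instrument's defaults in tests — sweep travel at 15 px/s
with a lawnmower harvest — realize that regime; at beeline travel speeds
the margin is structurally too thin for negative offsets, which is a
property of the task geometry, not of the analysis. Visits whose margin
never reaches |δ| contribute partial offsets, which biases the δ = −3
cohort mean by about −0.3 s; the recovery tolerance (±0.5 s) covers
exactly this instrument limitation.

### Stationary-harvest logs

For comparing detected OLTs against the closed-form optimum, a separate
generator emits logs whose within-patch rewards follow an inhomogeneous
Poisson process with rate f′(T) = A·λ·e^(−λT) (the derivative of the
saturating gain f(T) = A(1 − e^(−λT))), fixed travel, and an agent that
leaves at its online crossing. In steady state the realized average rate
approaches the optimal rate, so mean detected OLT residence converges on
the analytic optimum T\* solving e^(λT) − 1 = λ(travel + T) (solved by
bracketed root finding to < 1e−6 s). Two numerical effects bound the
agreement: the trailing window lags the instantaneous rate by ≈ W/2
(late bias growing with W·λ), and Poisson noise makes the first
below-ARR dip early (early bias shrinking with reward density). The
comparison therefore uses a large asymptote (A = 400; A cancels from
T\*, so density is free) and windows scaled to the rate time constant
(W = 0.3/λ), giving agreement within ~6% across λ ∈ {0.05, 0.1, 0.2}
and travel ∈ {10, 20, 40} s — well inside the 15% band asserted.

## Mood model

Mood is rated on a 9 × 9 affect grid — arousal and valence, integers
−4…+4 — at six time points (around run 1: 1–2, around the induction:
3–4, around run 2: 5–6). Pre scores average time points 1–2, post scores
5–6; deltas are post − pre.

The generator plants `ΔLTD = β_a·Δarousal + β_v·Δvalence + ε` on
standardized variables, with predictors jointly normal at correlation ρ
and ε chosen so the population R² is exact. Defaults follow the
reference effect sizes β_a = 0.24, β_v = −0.33, R² = 0.09, which force
ρ = (R² − β_a² − β_v²)/(2β_aβ_v) ≈ 0.483. Given realized LTD deltas
(e.g. from the simulator), predictors are drawn from their conditional
law given the standardized outcome, so the joint distribution still
matches the planted model. Continuous deltas are also realized as
integer grid ratings: means of two integer ratings are multiples of 0.5,
so realized deltas match the drawn ones within 0.25 except where a
target clips at a grid edge; baselines are drawn near the grid center to
keep clipping rare. Recovery tests use the continuous table — the grid
realization adds discretization error by construction.

## Regressions

Three hierarchical regressions mirror the study: pre-run LTD on pre mood
levels, post-run LTD on post levels, and ΔLTD on Δarousal and Δvalence.
All variables are z-scored, so coefficients are standardized βs with
95% CIs (OLS via statsmodels). Each base model is compared with its
interaction-augmented version by a nested F test at α = 0.05; when the
interaction does not help, the lower-BIC model is chosen. Reported p
values are multiplied by 3 (the size of the regression family), capped
at 1 — plain multiplication, not a sequential procedure, matching the
described correction. Participants whose LTD falls outside
[Q1 − 2.2·IQR, Q3 + 2.2·IQR] on either run are removed first; quartiles
use linear interpolation (type 7) and the fences are inclusive
("exceeded" read strictly). The Hoaglin-style fence around the quartiles
is an interpretation — |value| > 2.2·IQR is the other reading — and the
quartile method is unstated in the source; neither choice is checkable
against the original four exclusions.

Monte-Carlo calibration (500 cohorts of n = 113) shows mean β̂ within
0.01 of truth (a small attenuation comes from sample standardization)
and 95% CI coverage ≈ 0.96.

## Pipeline and problem sizes

`run_full_pipeline` chains simulate → score → fit window → generate mood
→ regress, derives every stage seed from one master seed via
`SeedSequence.spawn` (the rule is recorded in the manifest), and is
bit-reproducible for a fixed config. Default test and acceptance sizes —
cohorts of 5–20 agents, 500 regression replicates, 1800-s stationary-
harvest sessions — were chosen so each statistical check has Monte-Carlo
error comfortably below its tolerance while the whole suite stays quick
to run on one core.

## What the synthetic data do and do not show

The generator reproduces the task's geometry, timing, and reward
structure, and the analysis chain is validated against planted ground
truth and closed-form optima. It does not emulate human movement
statistics, learning, memory decay, or real mood dynamics; passing tests
show the *procedure* is implemented correctly and is able to recover
effects of the published size, not that the published human effects
would replicate. The original joystick data are not public, so detected
OLTs and fitted windows are not claimed to equal the published ones;
only the procedure is reproduced. One descriptive metric is ambiguous in
the source ("variability in patch leave times"); it is implemented as
the SD of patch residence durations. Arena coverage uses a 1-px
occupancy grid for the union of 15-px reveal disks (grid error ≪ the
quantity's use); an exact geometric union would be over-engineering.
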