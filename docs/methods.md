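# Methods

## The index

The package tracks the stability of a multivariate system by measuring, in
a sliding time window, how concentrated the system is among its observable
*states*. The system is described by `n` variables `y_1 .. y_n`; the
observation at time `t_j` is the vector `v_j = (y_1(t_j), ..., y_n(t_j))`.
Two observations are *indistinguishable* when, variable by variable,

    |y_i(t_j) - y_i(t_k)| <= Δy_i

for (enough of) the variables, where `Δy_i` is the measurement uncertainty
of variable `i` — the *size of state*. A state is therefore an
`n`-dimensional hyper-rectangle with half-sides `Δy_i` centred on a
founding observation.

Within one window of `w` consecutive points, binning is greedy and
time-ordered: the first point founds state 1 and captures every later point
inside its box; the earliest uncaptured point founds state 2; and so on
until all points are assigned. Two consequences are intentional and
load-bearing:

- **Membership is centre-based, not pairwise.** Two members of a state may
  differ by more than `Δy_i`, as long as each is within `Δy_i` of the
  founding point. (In the shipped worked example, points 3 and 5 of state 1
  differ by 0.65 in a variable whose uncertainty is 0.5.)
- **Capture is first-come and permanent.** A point already binned is never
  reassigned, even if a later state's box also covers it. The partition
  thus depends on time order; this is a property of the method, not a
  defect, and no order-normalised variant is offered.

With `m` states holding `c_1 .. c_m` points (discovery order), the state
probabilities are `p_i = c_i / w`, amplitudes `q_i = sqrt(p_i)`, and the
discrete Fisher information of the window is

    FI = 4 * [ (0 - q_1)^2 + Σ_{i=1}^{m-1} (q_i - q_{i+1})^2 + (q_m - 0)^2 ].

The amplitude form avoids dividing by small probabilities; the zero
boundary amplitudes make FI strictly positive. For count-based profiles
`0 < FI <= 8`, with `FI = 8` exactly when the window holds a single state,
and `FI = 8/m` for a profile uniform over `m` states. States enter the sum
in discovery order; any other ordering changes the value, so discovery
order is the canonical one throughout.

One FI value is computed per window and attributed to the window's **last**
time step (only past data enter each value); the window then advances by
`h` steps, and trailing windows that do not fill `w` are dropped, giving
`floor((T - w)/h) + 1` entries.

In the shipped eight-point walkthrough the exact interior terms of the sum
are 0.0126 and 0.0214; published presentations of this example sometimes
print them as 0.13 and 0.21, which is inconsistent with their own
expression, but the sum 0.534 and the total FI 2.136 agree with the exact
computation, so the exact computation is what the package (and its tests)
use.

## Parameters

| parameter | units | default | notes |
|---|---|---|---|
| `Δy_i` (size of state) | units of variable `i` | estimated | see below; explicit vectors accepted |
| `k` (Chebyshev multiplier) | — | 2 | coverage `1 - 1/k²` = 0.75 at the default |
| `w` (window width) | time steps | 8 | at least 8 recommended; small windows give noisy state counts |
| `h` (window increment) | time steps | 1 | must not exceed `w`; `h = w` allowed with a warning |
| tightening mode | — | `strict` | `strict` or `averaged` (below) |
| smoothing block `b` | entries | off (1) | non-overlapping block means |
| trend `slope_tolerance` | FI per step | 0.05 | heuristic; the interpretation rules are qualitative |
| trend `drop_threshold` | FI | 2.0 | single-step drop that signals a regime shift |
| trend `span` | entries | 8 | trailing least-squares assessment span |

**Size of state.** When uncertainty is not reported with the data, it is
estimated from an analyst-chosen *stable period* as `Δy_i = k * sd_i`, with
`sd_i` the **sample** (denominator `T−1`) standard deviation of variable
`i` over that period. Chebyshev's inequality makes the coverage claim
`P(|Y - mean| < k·sd) ≥ 1 - 1/k²` distribution-free, so `k = 2` guarantees
at least 75% whatever the noise looks like. The choice of sample rather
than population sd is deliberate (slightly larger, hence conservative,
boxes); with the recommended ≥ 8-point periods the difference is a few
percent. Automatic detection of a stable period is out of scope — it is a
domain judgement. A zero delta is legal (only exact ties bin together) but
warned about, since it usually flags a degenerate variable. Estimation is
homogeneous: scaling a variable by `c > 0` scales its delta by `c`, and
scaling data and deltas together leaves the FI series unchanged, as does
adding any constant to the data.

**Tightening level (TL).** Real variables fluctuate, so a point may be
declared inside a box when at least a fraction `tl` of the variables meet
their size-of-state criterion. The natural grid is multiples of `1/n`:
`n/n, (n-1)/n, ..., 1/n`, evaluated as an inclusive `count/n ≥ tl`
comparison. Loosening `tl` only merges states, so the state count is
non-increasing along the grid (property-tested). In `averaged` mode each
window is binned at every level of its own TL set — the contiguous grid
prefix from strict (1.0) down to the loosest level at which the window
still resolves more than one state (just `[1.0]` if even strict binning
gives one state) — and the mean FI over those levels is reported.

Two readings of "averaging the TLs" were possible: averaging the FI values
computed at each level (implemented), or collapsing the level fractions
into a single intermediate level. Averaging FI is the reading consistent
with treating each level as a complete binning rule; it is also continuous
in the data, which a collapsed level is not. Likewise the level set is
determined per window rather than globally, since the defining condition
("more than one state in a window") is a per-window event. Strict mode
sidesteps both choices and is the default.

**Smoothing.** Optional block averaging replaces each run of `b`
consecutive FI values by their mean (the mean represents every entry of its
block, so labels and entry count are preserved; a trailing partial block is
averaged over its own length). It acts as a high-frequency filter; the
default is off, and `b = 1` is the identity.

## Interpretation

The sustainable-regimes reading maps FI trends to system condition: a
nearly constant non-zero FI (`d<FI>/dt ≈ 0`) marks an orderly regime; a
steady decline is loss of order and an early warning; a steady rise is
stabilisation; a sharp drop signals a regime shift, with intensity related
to the drop's depth. `classify_trend` implements these rules with explicit
numeric thresholds (table above) labelled as heuristics — the underlying
rules are qualitative, and users comparing regimes should rely on the
regime summaries: mean FI (`μFI`) and sample-sd FI (`σFI`) over an
inclusive label range, a stable regime showing high `μFI` and low `σFI`
relative to others. Sample sd is used for `σFI` for the same conservatism
as in sizing.

## Synthetic data

`fisherinfo.synthetic` generates piecewise-stationary series: contiguous
regimes, each holding a fixed mean vector with independent Gaussian noise
per variable, all drawn from a mandatory seed (there is no unseeded API).
This is the minimal process the index is built to detect — windows inside a
regime see one or few states and high FI; windows straddling a mean step
see the state split, and a window with a fraction `f` of its points on one
side of the step has the closed-form `FI = 8 - 8*sqrt(f(1-f))`, which the
tests verify against the pipeline. Gaussian noise is a deliberate
light-tailed choice; since Chebyshev sizing is distribution-free, nothing
downstream assumes normality.

What the generator does *not* emulate: autocorrelation, trends within a
regime, heavy tails, seasonality, or cross-variable correlation. Passing
the synthetic tests therefore demonstrates the mechanics of binning,
windowing and recovery under idealised shifts, not performance on real
geophysical series, whose autocorrelation can make the effective
information per window smaller than the point count suggests.

The default benchmark scenario (`configs/two_regime_scenario.yaml`, and the
test suite's recovery check) uses 120 steps, a mean step of 10 units at
step 61, noise sd 0.1 = deltas/10, window 8 — i.e. regimes separated by
many times the size of state, the regime length comfortably above the
recommended minimum window, and a change point in the middle so straddling
windows exist on both sides.

## Numerical choices and degenerate inputs

- The size-of-state comparison is inclusive (`<=`), as is the TL fraction
  comparison (`count/n ≥ tl`, evaluated with a `1e-9` slack purely to
  absorb binary representation of fractions like `1/3`).
- Probabilities come from integer counts, so no renormalisation or
  small-denominator guard is needed; the profile validator enforces
  `Σp = 1` to `1e-12` and `p_i ≥ 1/w`.
- Missing data are resolved at ingestion by dropping the whole time step
  (binning needs all variables at a point) and logging the exclusion;
  imputation is out of scope. Time labels only need strict order —
  irregular spacing is accepted with a warning, since the method treats
  rows as sequential steps.
- An FI series is computed only when `T ≥ w`; empty windows, empty
  summary periods, overlapping or gapped regimes, and `h > w` are all
  rejected up front with named errors, and CLI config validation happens
  before any data are read so invalid runs leave no partial outputs.

## The global-temperature case study

The shipped configuration `configs/gistemp_case_study.yaml` reruns the
published analysis of global monthly temperature anomalies (one variable
per calendar month, yearly steps, `w = 40`, `h = 1`, anomalies in
0.01 °C): the reader excludes years with any missing month, and the
published per-month size-of-state vector (35.96 … 40.81, whose generating
stable period was not recorded) is supplied explicitly rather than
re-estimated. Reference regime summaries are `μFI = 5.09`, `σFI = 0.89`
for 1919–1978 and `μFI = 4.04`, `σFI = 1.32` for 1979–2015.

Exact reproduction is not possible offline or, strictly, at all: the
anomaly tables are revised retroactively, current releases print °C rather
than 0.01 °C (the attempt script rescales), and whether TL averaging or
smoothing was applied was not recorded. `scripts/gistemp_case_study.py`
documents the attempt end-to-end and treats agreement within roughly 15%
as consistent. The tests check the shipped artifacts and the reader-to-
pipeline path on synthetic monthly fixtures instead. A published "62.62%
change" summary statistic for this analysis has no stated definition that
matches its own inputs and is not implemented.

## Known limitations

- The partition, hence FI, depends on the time order of points within a
  window (greedy, centre-based binning); results are reproducible but not
  permutation-invariant.
- FI values are comparable only under a fixed configuration (deltas,
  window, tightening); the absolute level matters less than its stability
  within and between regimes.
- Trend classification thresholds are heuristics with no optimality claim.
- Windows shorter than 8 steps are allowed but warned against; state-count
  estimates from a handful of points are noisy.
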