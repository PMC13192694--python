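# Methods

This note documents the models, parameter choices and numerical
conventions behind `pulsetrace`, and what the synthetic benchmarks do
and do not demonstrate about real data.

## Input model and orientation inference

A trace matrix is `n_time × n_cells` fluorescence values on a uniform
time axis starting at 0; the axis is constructed from the user-supplied
experiment duration, never read from the file. Missing samples are an
explicit boolean mask (empty fields or `NA`/`NaN` tokens in CSV/TSV).

Files in the wild carry no orientation convention. A matrix read the
wrong way round alternates between distinct cells at successive "time"
points, which shows up as artificial discontinuity. We score each
orientation with a *jaggedness* metric: per putative trace, the mean
absolute second difference of its non-missing samples divided by the
trace's range (+ε, ε = 1e−12), averaged over traces. The metric is
invariant to adding a constant and to positive rescaling, so it
compares shape roughness, not signal magnitude. The orientation with the
strictly smaller score wins; ties go to columns-are-cells. Traces with
fewer than three usable samples contribute 0, and an orientation with
fewer than three putative time points is treated as infinitely jagged
(it cannot host traces at all). A user-stated orientation is never
overridden; a warning is issued when its jaggedness exceeds 1.5× the
alternative's. The 1.5 one-sided margin avoids spurious warnings on
near-square noisy matrices.

Caveat: the metric assumes traces are smoother along time than across
cells. If cells happen to be ordered so that their baselines form a
near-monotone ramp, the transposed matrix can look smooth too; the
inference is reliable for genuinely interleaved cell orderings (this is
what the fixture suite generates) and the user hint always wins.

## Quality control

Traces with a missing fraction **strictly greater** than the threshold
(default 0.10) are excluded — a trace at exactly 10% missing survives.
Remaining gaps are filled by linear interpolation between the nearest
observed neighbors; leading/trailing gaps take the nearest observed
value, since a line needs two flanks. Imputation is idempotent and never
touches observed entries. Normalization (optional) divides a trace by
its maximum or its initial value.

Pipeline order is fixed: orientation → missingness filter → imputation
→ normalization → smoothing → detection. Normalizing before smoothing
means the per-trace scale statistic is taken from the (imputed,
unsmoothed) data; smoothing then acts on complete, normalized traces.

## Adaptive smoothing

The default filter is a Gaussian window of one third of the expected
pulse period: `L = round(P · R / 3)` samples, forced odd, floored at 3,
capped at the trace length. The kernel uses σ = (L−1)/5, so the window
edge sits at ~2.5σ, a conventional truncation; the kernel is normalized
to unit sum. One third of the period is narrow enough to leave pulse
apexes in place while suppressing sample-to-sample noise.

Boundaries renormalize the truncated kernel rather than padding: no
data are invented and the local mean is preserved at the edges. The
operator is exactly linear and maps constants to constants everywhere;
it conserves total signal mass exactly wherever the kernel is fully
supported (i.e. for signal content at least one window from the trace
ends). Near the edges the row-stochastic renormalization redistributes
rather than conserves mass — an accepted property of not inventing
padding data.

Savitzky-Golay (local least-squares polynomial, default order 3) is
offered for better apex-height preservation, and a plain moving average
for maximal suppression. Smoothing reshapes frequency content, so
spectral analyses should always use raw traces.

## Derived peak-detection constraints

With `M` = mean over traces of the per-trace maximum, `R` = sampling
rate (samples/hour) and `P` = expected pulse period (hours):

| constraint | default | units |
|---|---|---|
| min height | `M/10` | trace units |
| min prominence | `M/20` | trace units |
| min width = min separation | `R·P/10` | samples |
| max width | `R·P·10` | samples |

Scaling the height/prominence floors to `M` makes the same rules work
across datasets on arbitrary fluorescence scales; scaling width and
spacing to the pulse period (≈ 5.5 h for p53 pulsing) rejects narrow
noise spikes and implausibly broad drifts alike. When several input
files are analyzed together, `M` is pooled over the whole loaded set so
all conditions share one constraint set (per-file derivation would make
conditions incomparable). Every value can be overridden; overrides are
flagged in the provenance record together with the default they
replaced. Minimum width and minimum separation share one default but
are separately overridable.

## Peak detection

Candidates are strict interior local maxima; a plateau (run of equal
values strictly above both flanks) yields one candidate at its midpoint
(lower index for even runs); trace endpoints are never candidates.

Prominence follows the standard topographic convention: walk outward
from the apex to the nearest strictly higher sample (or the trace end)
on each side; the base on each side is the minimum over the walked
interval (leftmost index on ties); prominence = apex − max(base
values). Width is measured at the level (apex − prominence/2) with
linear interpolation of the two crossings nearest the apex, searched no
further than the prominence bases; if a side never reaches the level
(flat signal) it falls back to its base, and the peak is flagged.

Filters apply in the order height → prominence → width → separation,
with prominence computed on the height-filtered candidates, so
threshold effects are independent of separation pruning. Separation
pruning is greedy: survivors sorted by height (desc), then prominence
(desc), then leftmost; a candidate is discarded iff its apex lies
strictly closer than the minimum separation (a real-valued sample
distance, since `R·P/10` is generally fractional) to an already kept
apex. All of this is implemented directly (no library peak finder); the
test suite cross-checks it against an exhaustive brute-force enumerator
on a thousand random traces, including integer-valued traces that
stress plateaus and ties.

## Features

Per peak: height (apex value of the smoothed, possibly normalized
trace), location (hours), width at half prominence (hours), prominence,
and integral — the trapezoidal area of the trace over the
half-prominence window with linearly interpolated fractional endpoints,
in trace units × hours, without baseline subtraction (reusing the width
extents avoids an arbitrary baseline model). Per trace: peak count,
frequency = peaks per observed hour (`n_peaks / D`, so frequency × D =
count exactly), mean inter-apex spacing, and the first peak's time and
height (a standard readout of signalling delay). Condition summaries
average peak features over all peaks of a condition and frequency over
its traces; dispersion is reported as the (population) standard
deviation. Undefined quantities (no peaks, fewer than two peaks) are
NaN markers, never errors.

## Downstream analyses

Agglomerative hierarchical clustering on pairwise trace distances
(euclidean, 1 − Pearson correlation, or 1 − cosine similarity; average,
complete, or — for euclidean — Ward linkage), cut at a user-chosen k.
Labels are canonicalized by first occurrence, making the partition
stable under trace permutation; the dendrogram leaf order is exported
for heatmap display. Per-condition averaged traces report the pointwise
mean and standard deviation.

## Provenance and replay

Each run writes a structured JSON record (inputs with dimensions and
orientation reports, full configuration, QC outcome including every
imputed sample, the smoothing-window derivation, each constraint
formula instantiated with its numbers, defaults and effective values
when overridden, output manifest, tool/library versions) and a
plain-language narrative generated deterministically from that
structure (numbers to six significant digits; only the timestamp line
varies between identical runs). The analysis path contains no
randomness, so `replay` — which reconstructs the configuration from the
JSON record and re-runs the pipeline — reproduces outputs byte for
byte; output CSVs use a fixed float format (`%.10g`) to make the
comparison meaningful.

## Synthetic pulse trains

Each simulated trace is `baseline + Σ pulses + noise`: Gaussian-shaped
pulses whose amplitude and FWHM are drawn per pulse, with centers
starting at a first-pulse delay and advancing by per-pulse period
draws; i.i.d. Gaussian noise; missing samples placed uniformly at
random. True apex times, amplitudes and FWHMs are recorded. For an
isolated Gaussian pulse on a flat baseline, the half-prominence width
of the trace equals the pulse FWHM, which makes width recovery directly
checkable.

The "natural" regime emulates unperturbed p53-like pulsing: baseline 1,
amplitude 1 ± 0.2, period 5.5 ± 0.5 h, FWHM 1.4 ± 0.15 h, first pulse
at 2 h, noise σ = 0.1 (amplitude SNR 10), 2% missing. The other five
regimes emulate pharmacological modulation by scaling one property:
high/low amplitude (×2 / ×0.5), high/low frequency (period 3.5 / 8 h),
long duration (FWHM 2.2 h, echoing the observation that lengthened
pulses run more than an hour wider than other conditions). These
numeric values are package defaults chosen to be realistic for
p53-class reporters, not measurements.

Detection is scored by greedy closest-first one-to-one matching of
detected to planted apexes within a tolerance (period/10 in the
benchmarks), reported as precision, recall and F1.

What the generator does *not* emulate: photobleaching and focus drift
(slow baseline trends), shot noise (signal-dependent variance),
asymmetric pulse shapes, segmentation/tracking errors (identity swaps,
block dropouts), and cell-cycle-linked amplitude trends. Passing the
synthetic benchmarks therefore demonstrates the correctness of the
algorithmic chain under the stated signal model, not performance on any
particular experimental dataset — on real data the derived constraints
remain the defaults and may need the documented overrides.

## Problem sizes and determinism

The bundled benchmarks use 100 traces × 48 h × 6 samples/h (≈ 900
planted pulses) for recovery and regime contrast, 1000 random traces of
length ≤ 50 for the oracle equivalence check, 200 fixtures for
orientation inference, and 10 end-to-end runs for replay fidelity —
sizes at which every property is measured with comfortable margins
while the whole suite runs in seconds. All stochastic tests and the
acceptance script derive their randomness from fixed or user-supplied
seeds; property-based tests run Hypothesis in derandomized mode.

## Known limitations

- Time axes must be uniform; experiments with irregular sampling need
  resampling upstream.
- The `.mat`-style binary container is not read; CSV/TSV is the
  interchange format.
- Peak integrals include the baseline contribution over the window; a
  baseline-subtracted variant would require a baseline model, which is
  deliberately out of scope.
- The jaggedness heuristic can be fooled by baseline-sorted cell
  orderings (see above); the user hint is authoritative.
- Frequency is defined as peaks per observed hour; for short recordings
  this underestimates the asymptotic pulse rate when the first pulse is
  delayed.
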