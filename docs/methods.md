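# Methods

This note documents the models, parameter choices, numerical decisions
and known limitations behind each stage of the pipeline. Defaults given
here are the package defaults; all are configurable.

## Behavior: velocity and bout segmentation

Two optical sensors at the treadmill ball's equator, an angle θ apart
(default 78°), each report a vertical surface displacement. The
perpendicular velocity components are `X = (L − R cos θ)/sin θ` and
`Y = R`, and linear speed `V = √(X² + Y²)` is interpolated onto a uniform
20 Hz grid. The denominator of the X formula is `sin θ`, the unique
reading under which X reduces to L when the sensors are orthogonal.

Bout segmentation is fuzzy-threshold based: membership
`F(V) = 1/(1 + e^{−a(V−c)})` with gain `a = 0.8` and threshold `c` the
session's 20th speed percentile floored at 5 cm/s; the membership trace
is smoothed with a centred 1.5-s moving average and thresholded at 10% of
its per-session maximum. Supra-threshold stretches of ≥ 2 s are run
bouts, sub-threshold stretches of ≥ 2 s rest bouts, everything else
unclassified. Numerical choices: percentiles use linear interpolation;
the 2-s rule converts to `ceil(2·fs)` samples; ties at the threshold
count as supra-threshold. A session whose smoothed membership never
reaches the sigmoid midpoint contains no sample above `c` and is labeled
all rest — without this guard a constant-zero session would be "run"
everywhere, since 10% of an all-baseline maximum is below baseline.

Two properties of this scheme are worth knowing. The smoothing widens
every genuine bout by roughly 0.6 s per side (the price of suppressing
jitter), so recovered bouts overlap planted ones with Jaccard ≈ 0.89 on
an ideal square wave, with recall ≈ 1. For the same reason a burst
shorter than 2 s but longer than ~0.5 s can smear past the 2-s rule; only
sub-half-second bursts are reliably rejected.

Sessions qualify for locomotion-conditioned analysis when they hold at
least 60 s of each state and at least 5 run bouts.

## Imaging: registration and trace extraction

The registration reference is the pixelwise mean of the first 2,047
frames. Enhancement removes a σ = 50 px Gaussian background estimate,
adds 100× the difference between σ = 2 and σ = 1 px blurs of the
background-free image to the σ = 2 blur, and z-scores the result (guards
against photobleaching trends). Displacement is the integer peak of the
circular FFT cross-correlation of enhanced reference and frame; the
corrective shift is its negation. Shifts are integer-pixel by design —
no subpixel interpolation — which makes registration exactly invertible
on integer-shifted scenes and keeps the procedure testable against known
shifts.

Traces are per-frame ROI-mean fluorescence minus the mean over a
background ring (radii 15–50 px around the centroid) that excludes all
other ROIs and a 25-px frame border (registration leaves bright strips
there). An empty ring after exclusions yields a flagged, unsubtracted
trace rather than an error. Traces are interpolated to 20 Hz, linearly
detrended, and min–max scaled to [0, 1]; a constant trace cannot be
normalized and is rejected. Manual artifact curation is out of scope; no
automated amplitude-outlier rejection is applied by default.

## Event detection

Candidates come from the trace's low-frequency power: the trace is
smoothed with a 1-s moving average (for power estimation only), windowed
(1 s window, 50 ms step, per-window mean removal), tapered with 3 DPSS
tapers of time–bandwidth 2, and the periodogram power is averaged below
2 Hz. Outliers of the power first-difference beyond 3 scaled MADs
(1.4826·MAD, the SD-consistent scaling) mark power rises; runs of at
least 3 consecutive outlier steps (150 ms, the minimum event rise time)
become candidates. Each candidate is localized on a lightly smoothed
(0.25 s) copy of the trace: the peak is the local maximum, the onset the
last pre-peak sample within 10% of event height above the minimum of the
preceding 0.75 s. Candidates with overlapping rising phases merge.

Acceptance is iterative. At iteration k a candidate is accepted when its
rise spans ≥ 3 samples and its amplitude exceeds
`7·(1 − 0.4)^k` times the local noise scale, measured in a lookback
window of `10·(1 + 0.75)^k` seconds before onset from which all
previously accepted events' samples (onset through the first return to
onset level) are excluded; candidates with fewer than 20 usable window
samples wait for the window to grow. Accepted events' samples are
removed, candidates falling inside removed spans are dropped, and the
process stops at the first iteration that accepts nothing.

Three numerical choices make this ladder robust on white-noise
baselines, where the candidate stage by construction selects the noise
extremes:

- the ladder's amplitude is measured on the smoothed trace against the
  *median* of the 0.75 s pre-onset baseline — smoothing suppresses
  single-sample noise peaks and the median does not chase noise dips, so
  noise candidates are not credited with selection-biased amplitude;
- the noise scale is a robust (MAD-based) SD of the raw trace in the
  lookback window, so a neighbouring not-yet-removed event cannot
  inflate the threshold and push true events into late iterations;
- the stop-at-empty-iteration rule then terminates the ladder two to
  three iterations in, well above the noise floor.

With these defaults the detector reaches ≥ 99% sensitivity with ~50 ms
mean onset error on synthetic traces whose amplitudes are ≥ 5 noise SDs,
and produces no detections on pure-noise traces. Reported event
amplitude remains `trace[t_peak] − trace[t_on]` on the raw trace. FWHM
is the time between interpolated 50%-height crossings on rise and decay;
it is withheld when the next event begins before the decay crossing or
when more than one local peak exceeds 75% of event height.

## Movement modulation

Binarized trains carry 1 over each event's rising phase (onset to peak,
inclusive) — the rising phase tracks spiking; including the slow decay
would overstate coincidence. The activity metric
`A = (Σ_run x/n_run − Σ_rest x/n_rest)·100` counts time in samples;
unclassified samples enter neither term. The null is built from 1,000
circular shifts of the binarized train with integer lags uniform on
[1, n−1]; percentiles use linear interpolation and the comparison is
strict (`A_obs > q97.5`), so an all-zero train is never modulated.

The null is computed without materializing shifted trains: shifting the
ones of a sparse train and summing a state mask at the shifted positions
is algebraically identical and ~100× faster.

Under the null the test is calibrated at its nominal 2.5% by
construction; with realistic (irregular) bout structure the simulated
false-positive rate sits at 2.0–2.5%. Under an exactly periodic rest/run
tiling the discreteness of event-sized steps in A interacts with the
periodic lag structure and the test becomes conservative (~1.5%) — a
property of the statistic, not a bug, and irrelevant for real bout
sequences, which are never periodic.

## Pairwise connectivity

Pairs with centroids closer than 20 px (26.2 μm at the 1.343 mm/1024 px
field of view) are excluded as potential optical crosstalk. For each
scope — rest, run, session — trains are restricted to the scope's bouts
and concatenated, and Pearson r of the two 0/1 vectors is classified
against 2,000 circular shifts of one train (the higher-id one, a fixed
convention that makes the test symmetric): correlated if r exceeds the
null's 95th percentile and is positive; negative r is excluded (events
are sparse; anticorrelation carries no signal at these rates); a pair
with an event-free train has undefined r and is reported ineligible.
For state scopes the shift is applied after concatenation, which
preserves state-specific event counts exactly — shifting before
concatenation would leak cross-state rate structure into the null.
Calibration on independent pairs sits at 5% within binomial error.

The rate control recomputes each pair's r under 100 circular shifts and
pairs it with the pair's mean event rate: in the sparse regime the
chance-level 95th percentile *falls* as rate rises (at 600-s sessions,
roughly 0.05 at 1 event/min to 0.04 at 4 events/min), so a rate increase
cannot masquerade as a correlation increase. At much shorter scopes the
null becomes atom-dominated and this monotonicity can invert — the
control is meaningful at session-scale lengths.

Session-relevant pairs (correlated over the full session) are decomposed
by member modulation into Mod–Mod / Mod–Non / Non–Non subgroups, with r
recomputed on state-restricted concatenations.

## Network centrality

Each state's correlated pairs form a simple undirected graph over all
recorded cells; isolated cells stay in the graph, enter N, and carry
c = 0 — otherwise the ×N normalization would not be comparable across
states. Edge weight is the pair's r clipped to ≤ 1 − 1e−9 (r = 1 would
give a zero-length edge and unbounded closeness); edge length is
`ln(1/w)` (natural log by default; base 10 available — the worked
example constrains only A and C, not the base). Shortest paths are
Dijkstra on the nonnegative lengths. Then
`c(i) = (A_i/(N−1))² / C_i`, the network value is mean(c)·N = Σc, and
the rest − run difference of network values measures state-dependent
desynchronization.

Note that closeness is *not* edge-monotone in general: deleting an edge
that disconnects a distant node removes a large term from C_i and can
raise c_i (the schematic's 1.25 → 1.11 illustrates the usual direction,
but the trade-off can go either way). Monotonicity does hold whenever
reachability is unchanged, and the tests check exactly that.

## Statistics

Proportion error bars are `1.96·√(P(1−P)/n)` (normal approximation, on
the percent scale). Group comparisons use Wilcoxon rank-sum, medians
against zero Wilcoxon signed-rank, proportions Fisher's exact test.
Factorial comparisons fit a Gaussian linear model
`Y ~ 1 + A + B + A:B` by maximum likelihood (OLS coincides); all
coefficient reporting is gated on a likelihood-ratio deviance test
against the intercept-only model, and per-level post-hoc sub-models
`Y ~ 1 + B` are fitted only when the interaction coefficient is
significant at 0.05. Factors are treatment-coded, so the B main-effect
coefficient is estimated within the reference level of A — at 1-SD
planted effects this reaches 80% power around 20 observations per cell.
No multiple-testing correction is applied anywhere, and the report
records that explicitly.

## The synthetic-data generator

The generator emulates the study conditions: 600-s sessions at 20 Hz;
~20 run bouts per session with exponential durations around 12.8 s and
plateau speeds near 10 cm/s; sparse calcium events at 1.71 events/min at
rest, rising to 2.79 events/min during running for the ~26% of cells
designated movement-modulated; an event kernel with 0.5-s linear rise
and 1-s exponential decay (sharper than the ~1.4-s rises of real GCaMP6f
averages, a deliberate choice that keeps detector-recovery tests sharp;
both constants are configurable); amplitudes ~N(0.5, 0.1) dF/F against
0.02 noise SD; and a 2.5-s refractory separation so events remain
resolvable. Event counts therefore follow a dead-time-thinned Poisson
law (~7% below the nominal rate), and the count tests use a brute-force
re-simulation of that law as the oracle.

Pair correlation is planted through latent Poisson source trains shared
by disjoint cell groups (group size configurable, default pairs): each
member copies each source event independently with probability
`shared_fraction`, so the Pearson r of a pair grows monotonically with
it. Sources can be restricted to rest samples, which plants the
desynchronization-during-running phenotype: the rest-state graph carries
the shared edges, the run graph only chance edges, and the rest − run
centrality difference is positive. The planted-cohort tests use groups
of four cells at `shared_fraction = 0.8` with rest-only sources
("WT-like") versus state-independent sources over more groups
("KO-like"), 6 sessions of 40 cells each — sizes chosen so one cohort
comparison runs in about two minutes on one CPU.

All randomness flows from one seed through fixed-offset substreams, so
identical configurations are bit-reproducible and adding a stage never
perturbs another stage's draws.

What the generator does not model: photon physics and shot noise
(Gaussian noise only), neuropil contamination beyond the ring fixture,
slow drift after detrending, bursting or refractory violations, spatial
correlation structure beyond planted groups, and inter-mouse
variability. Passing tests therefore demonstrate correctness of the
algorithms under the stated event model, not end-to-end performance on
raw recordings.

## Problem sizes used in the test suite

Calibration suites use 2,000 simulated null cells (1,000 shuffles each)
and 2,000 independent pairs (2,000 shuffles each) on 600-s sessions;
detector recovery uses 8 cells × 600 s at amplitude ≥ 5 noise SDs plus
80 minutes of pure noise; oracle equivalence uses 200 random graphs of
up to 8 nodes against a dense Floyd–Warshall implementation, exhaustive
MAD scans, and full hypergeometric enumeration for Fisher's test. These
sizes keep the whole suite under ~3 minutes on one CPU while leaving the
binomial acceptance bands narrow enough to be meaningful.

## Known limitations

- The detector's false-positive behavior is tuned for white-noise
  baselines; strongly autocorrelated noise (hemodynamics, z-drift) will
  shift both the MAD candidate stage and the SD ladder, and the printed
  thresholds would need re-validation.
- Bout edges inherit ±0.6 s uncertainty from the membership smoothing;
  event-to-bout assignment within that margin is correspondingly soft.
- The activity metric's permutation null assumes stationary event rates
  within states; slow within-session drift would inflate its tails.
- Closeness centrality on near-percolation graphs (mean degree ≈ 2) is
  sensitive to single chance edges; cohort-level conclusions should rest
  on multiple sessions, as the planted-effect tests do.
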