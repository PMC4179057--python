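# Methods

`nightwatch` couples four monitoring services to a synthetic night
generator. This note records the models behind each, the parameters
that matter, the numerical choices, and what the synthetic validation
does and does not establish.

## Active-rule substrate

The engine models an active database's ECA machinery as a synchronous,
single-threaded component: AFTER-INSERT triggers run inline during the
insert, in registration order, and `notify` delivers to subscribers
immediately, in subscription order. Asynchronous delivery was
deliberately traded away for determinism — identical insert sequences
produce identical firing and delivery sequences, which is what makes
the end-to-end equivalence tests (trigger-driven detector vs vectorized
detector) exact rather than statistical. A failing trigger action does
not undo the insert; remaining triggers still run and the first
exception is re-raised afterwards. FIFO tables assign a `sample_id`
cycling `1..capacity`, so a `WHEN sample_id == capacity` condition is a
per-window cadence gate; non-FIFO tables count monotonically. Only
AFTER-INSERT timing exists — no updates, deletes, transactions, or
permissions.

## Bed presence

*Signal model.* The load cell reports ADC counts at 80 Hz; weight is
`adc_out / r` with `r = −41943.0` counts/kg. Presence shows up jointly
in the 40-sample (half-second) window median `m_w` (body-weight shift)
and population standard deviation `σ_w` (movement disturbance). The
decision rule is the conjunction `(σ_w ≥ O_σw) AND (m_w ≥ O_mw)` with
inclusive bounds. Windows are consecutive non-overlapping 40-sample
blocks — the trigger fires once per FIFO wrap, and at that moment the
table holds exactly the current block.

*Calibration.* Thresholds are per-resident Otsu cuts over a calibration
period's window statistics (default: the first full night; the period
must contain both occupied and empty bed). Two robustness measures
were added after the plain procedure failed on realistic signals:

1. **Winsorization (q = 0.95).** Movement bursts give `σ_w` a long
   right tail; classic Otsu, which maximizes `σ_B²`, then prefers to
   split the tail from everything else, leaving both main clusters on
   one side. Clipping calibration values at the 95th percentile removes
   the tail's leverage. This assumes each genuine cluster holds well
   over 5% of the windows — true whenever the resident both sleeps and
   leaves the bed during calibration.
2. **Degeneracy gate.** A unimodal series (e.g. an all-empty night)
   still yields *some* Otsu cut, so calibration is rejected unless the
   two induced clusters are separated by at least 5 pooled median
   absolute deviations. The best split of a single Gaussian scores
   ≈ 3.4 on this statistic; genuine occupied/empty splits score 30–700.
   A variance-ratio gate (Otsu's η) was tried first and discarded:
   burst tails inflate the within-class variance and make it
   unreliable. The MAD-based gate is insensitive to tails by
   construction.

*Event emission.* The first window of a night sets the initial state
silently (there is no defensible event for "already in bed when the
sensors switch on"). A state change is emitted only after `confirm`
consecutive contrary windows; the default is 2. With half-second
windows a night contains 57,600 decisions, and the sample standard
deviation of 40 points fluctuates with ≈ 11% relative noise
(`1/√(2n)`), so a single-window excursion across any threshold placed
in the occupied/empty gap occurs by chance every few nights; one such
excursion under `confirm = 1` fabricates a spurious exit/entrance pair.
`confirm = 2` requires two consecutive ~4σ excursions (negligible
probability) and costs 0.5 s of latency. Nights are processed
independently; no state crosses the 6 a.m. boundary.

## Transition mining

A first-order model over the 8-symbol event alphabet. Counts are exact
integers; inter-event times use Welford accumulators, so `μ_t` and
`σ_t` (sample variance, `n−1`; undefined for `n = 1`) match a two-pass
recomputation to floating-point accuracy regardless of stream length.
Consecutive identical symbols within 30 s merge — real PIR sensors
retrigger continuously while a room is occupied, and the debounce
collapses a retrigger chain into one visit. An absorbed repeat
refreshes the remembered timestamp, so the transition time out of a
visit is measured from the visit's *last* firing, i.e. from when the
room actually fell quiet. Identical symbols farther apart than the gap
count as self-transitions. Rows of the probability matrix are defined
only where at least one outgoing transition was observed. The DOT
export keeps edges with confidence `P(e_j|e_i) ≥ 0.2` by default and
labels each with `p`, `μ_t`, `σ_t`; node and edge order is fixed by the
alphabet, so exports are byte-stable.

## Early-night classifier

*Features.* Each 20-minute window gives 15 features: the last four
event symbols (newest first, `N` when fewer events exist), the elapsed
times from the newest event to each of its three predecessors, and
eight per-type counts. "Lack of events" is represented by the `N` slot
value and zero counts, not by a ninth count — the only composition
that yields exactly 15. Missing elapsed times are coded with a
sentinel equal to the window width (1200 s); explicit missing-value
handling (fractional splits) is not implemented, so the sentinel keeps
those observations usable by ordinary numeric splits.

*Windows.* The grid starts at 10 p.m. and steps by the window width
(non-overlapping), giving 24 observations per 8-hour night — 336 for
14 nights — and no window straddles midnight, so the TPI label
(window starts before midnight) is unambiguous.

*Tree.* Classic C4.5: categorical attributes branch per observed
value, numeric attributes split binarily at midpoints between sorted
distinct values; candidates are filtered to those whose information
gain reaches the mean gain of all positive-gain candidates, and the
survivor with the highest gain ratio wins. Ties break by attribute
declaration order, then smaller threshold; class order is
lexicographic, making the tree invariant to observation order. Growth
stops on purity, `min_leaf = 5` (both numeric children, and the two
largest categorical branches, must reach it), `max_depth = 10`, or no
positive gain. No post-pruning. Prediction routes unseen categorical
values to the largest child. Cross-validation is stratified (per-class
shuffle with an explicit seed, round-robin dealing), k = 10.

## Simulator

*Resident model.* A semi-Markov chain over {Bed, Ba, K, H, L} with
truncated-normal dwell times (truncated below at zero; floored at 6 s).
Two parameter phases emulate the documented early-night pattern: before
midnight the resident is up and about (bed dwells 12 ± 5 min,
transitions out of bed go to kitchen/living room/hallway only, kitchen
and living-room dwells 12–22 min); after midnight sleep dominates
(bed dwells 100 ± 40 min) and 80% of exits go to the bathroom. The
night starts in bed at 10 p.m. and ends at 6 a.m.

*Sensor emission.*

- **Room PIR**: first firing a per-pair truncated-normal "event gap"
  after state entry — Bed→Ba defaults to 7 ± 7 min, matching the
  observed exit-to-bathroom transition time; other pairs 0.5 ± 0.25 min
  — then retriggers every uniform(10, 25) s while the room stays
  occupied. The first firing is capped at the interval end, so a room
  event never falls outside its room interval (affects < 2% of draws at
  default dwells). Because a truncated N(7, 7) does not have mean 7 and
  std 7, recovery tests compare empirical gap moments against the
  truncated distribution's theoretical moments (via `scipy.stats.truncnorm`).
- **Load cell**: empty bed = 0.4 kg tare + 0.02 kg noise floor;
  occupied = 20 kg (nominal fraction of body weight on the monitored
  leg) + 0.5 kg continuous micro-movement noise + Poisson movement
  bursts (2/min, 0.5–2 s, 2 kg amplitude) giving `σ_w` its heavy tail.
  ADC values are `round(weight × r)`.
- **Wearable inactivity (I)**: one event per bed interval exceeding the
  15-min timeout, re-armed by the next movement. Single-shot emission
  keeps the implied event-level chain derivable in closed form.
- **Film bed sensor**: ground-truth `Bout` events independently dropped
  with probability 0.6 (entrances pass through); optional spurious
  exits. Lives in a separate random substream, so changing its
  parameters never perturbs the ground truth or any other stream.
- **Door (D)**: only on an explicit patrol schedule; none by default.

*Planted-truth accounting.* For a homogeneous (single-phase) scenario
the event-level transition matrix is computed in closed form from the
state matrix, the bed-dwell distribution and the inactivity timeout
(`implied_event_matrix`), and serves as the planted truth for recovery
tests. The default two-phase scenario is a mixture with no single
planted matrix; there, recovery is instead measured as the disagreement
between matrices mined from detected vs ground-truth bed events.
Recovery runs use several thousand simulated nights (events only, no
load cell) so that even rarely-visited rows accumulate ≥ 1000
observations; this keeps the maximum estimation error near 0.02, well
inside sampling-noise expectations.

*What the simulator does not model.* Sleep stages, breathing or other
physiological structure in the load-cell signal; motionless-but-present
room occupancy (PIRs here retrigger for as long as the room is
occupied); multi-resident homes, pets, visitors; sensor dropouts other
than the bed sensor's; clock drift. Passing tests therefore demonstrate
that each service recovers the structure this generator plants at
realistic rates and noise levels — not that the services reach any
particular accuracy on real homes, where behavioral overlap between
early and late night is larger and PIR behavior is messier.

## Numerical choices

- Otsu: 256 uniform bins over `[min, max]`; the returned threshold is a
  bin boundary; ties (every cut through a run of empty bins scores
  identically) break toward the smaller threshold. Consequences: the
  result is affine-equivariant only up to one bin width, and mirroring
  the data mirrors the threshold only up to the width of the empty
  valley between clusters — both are checked as such.
- Window statistics use the population (n) standard deviation: the
  window is the complete object of interest, not a sample from it.
- Welford variance guards `n = 1` (reported as null / `None`).
- Metrics JSON is written with sorted keys from fully seeded
  computation, so identical config + seed reproduces byte-identical
  files.
- Event-level detector scoring matches detected to true events of the
  same symbol greedily in time order within a 10 s tolerance
  (detection latency is ≤ 1 s; the tolerance leaves room for
  confirmation delay without letting distinct excursions alias).

## Pipeline problem sizes

The bundled end-to-end run simulates 14 nights (≈ 32 M load-cell
samples), calibrates on the first, detects on all, mines transitions
from ambient + detected bed events, and cross-validates the classifier
on the resulting 336 observations. The standalone recovery experiment
uses 6000 event-only nights. These sizes were chosen so the full
validation completes in well under a minute of compute while leaving
every estimate comfortably inside its tolerance.

## Known limitations

- The calibration winsorization quantile (0.95) and the separation gate
  (5 MADs) are heuristics tuned to this emission model's cluster
  geometry; residents with very short total absence (< 5% of windows)
  would need a longer calibration period or a higher quantile.
- The C4.5 implementation omits fractional (missing-value) splits and
  pessimistic post-pruning.
- The transition model is first-order by design; longer behavioral
  motifs (e.g. bathroom visits that *follow* kitchen activity only on
  restless nights) are invisible to it.
- Anomaly scoring against the learned transition matrix is out of
  scope; the model only summarizes.
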