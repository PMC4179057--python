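"""Synthetic nighttime data generator with full ground truth.

Emulates a single resident monitored from 10 p.m. to 6 a.m. by a bedroom
load cell (80 Hz), PIR motion sensors in the bathroom/kitchen/hallway/
living room, a wearable inertial inactivity sensor, a door magnet and an
unreliable film-type bed sensor.  The resident follows a semi-Markov
model over the states {Bed, Ba, K, H, L}: a planted row-stochastic
transition matrix picks the next state and a truncated-normal dwell time
(truncation at zero) governs how long each state lasts.  Two parameter
phases capture early-night behavior: before midnight the resident is up
and about (short bed dwells, frequent kitchen / living-room visits);
after midnight bed dwells are long with occasional bathroom trips.

Sensor emission:

* the room PIR fires once per visit, an ``event gap`` after state entry;
  the gap is a per-pair truncated normal (default Bed->Ba: mean 7 min,
  std 7 min), capped so the event stays inside the room interval;
* the load cell yields an 80 Hz ADC stream: a large mean shift plus
  movement noise and seeded bursts while the bed is occupied, near-zero
  mean and tiny noise while empty;
* the wearable emits one inactivity event (I) per bed interval longer
  than the timeout;
* the film bed sensor reports the true bed events degraded by an
  independent per-exit miss probability (default 0.6) and optional
  spurious exits;
* door events (D) follow an explicit patrol schedule (default none).

Everything derives from ``(config.seed, night index)`` through
independent named substreams, so changing e.g. only the bed-sensor miss
rate never changes the ground-truth trajectory or the load-cell signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .events import ALPHABET, SYMBOL_INDEX, SensorEvent
from .signal_stats import VOLTAGE_WEIGHT_RATIO

STATES: tuple[str, ...] = ("Bed", "Ba", "K", "H", "L")
ROOM_STATES: tuple[str, ...] = ("Ba", "K", "H", "L")

# substream tags for per-night seeded generators
_SUB_TRAJ, _SUB_LOADCELL, _SUB_EMFIT = 11, 13, 17


class ConfigError(ValueError):
    pass


def _matrix(rows: dict[str, dict[str, float]]) -> np.ndarray:
    m = np.zeros((len(STATES), len(STATES)))
    for i, a in enumerate(STATES):
        for j, b in enumerate(STATES):
            m[i, j] = rows.get(a, {}).get(b, 0.0)
    return m


def default_base_matrix() -> np.ndarray:
    """Post-midnight regime: long sleep, exits almost always to the bathroom."""
    return _matrix({
        "Bed": {"Ba": 0.80, "K": 0.05, "H": 0.10, "L": 0.05},
        "Ba":  {"Bed": 0.85, "K": 0.05, "H": 0.10},
        "K":   {"Bed": 0.60, "Ba": 0.10, "H": 0.20, "L": 0.10},
        "H":   {"Bed": 0.60, "Ba": 0.30, "K": 0.05, "L": 0.05},
        "L":   {"Bed": 0.70, "Ba": 0.10, "K": 0.10, "H": 0.10},
    })


def default_early_matrix() -> np.ndarray:
    """Pre-midnight regime: up and about, kitchen / living room favored."""
    return _matrix({
        "Bed": {"K": 0.40, "L": 0.40, "H": 0.20},
        "Ba":  {"Bed": 0.50, "K": 0.20, "H": 0.20, "L": 0.10},
        "K":   {"Bed": 0.30, "H": 0.25, "L": 0.45},
        "H":   {"Bed": 0.20, "K": 0.40, "L": 0.40},
        "L":   {"Bed": 0.30, "K": 0.40, "H": 0.30},
    })


@dataclass(frozen=True)
class LoadcellConfig:
    """Emission model of the load cell under one bed leg."""

    sampling_hz: float = 80.0
    occupied_mean_kg: float = 20.0    # body-weight fraction on the monitored leg
    occupied_sigma_kg: float = 0.5    # continuous micro-movement noise in bed
    empty_mean_kg: float = 0.4        # mattress/frame tare on the cell
    empty_sigma_kg: float = 0.02      # electronic noise floor
    burst_rate_per_min: float = 2.0   # posture-change bursts while occupied
    burst_amp_kg: float = 2.0
    burst_duration_s: tuple[float, float] = (0.5, 2.0)
    adc_ratio: float = VOLTAGE_WEIGHT_RATIO


@dataclass(frozen=True)
class ScenarioConfig:
    n_nights: int = 14
    night_start_hour: int = 22        # sensors active 10 p.m. .. 6 a.m.
    night_hours: float = 8.0
    early_hours: float = 2.0          # TPI span: 10 p.m. .. midnight
    start_date: str = "2014-01-06"
    seed: int = 0

    transition_matrix: np.ndarray = field(default_factory=default_base_matrix)
    dwell_min: dict = field(default_factory=lambda: {
        "Bed": (100.0, 40.0), "Ba": (25.0, 5.0), "K": (8.0, 3.0),
        "H": (2.0, 1.0), "L": (15.0, 5.0),
    })
    # pre-midnight overrides; None disables the two-phase behavior
    early_transition_matrix: np.ndarray | None = field(
        default_factory=default_early_matrix)
    early_dwell_min: dict | None = field(default_factory=lambda: {
        "Bed": (12.0, 5.0), "Ba": (25.0, 5.0), "K": (12.0, 4.0),
        "H": (2.0, 1.0), "L": (22.0, 6.0),
    })

    # delay from state entry to the first room PIR firing, minutes
    event_gap_min: dict = field(default_factory=lambda: {("Bed", "Ba"): (7.0, 7.0)})
    default_gap_min: tuple[float, float] = (0.5, 0.25)
    # PIR retrigger interval while a room stays occupied, seconds
    # (uniform range; None emits a single firing per visit).  Kept below
    # the miner's 30 s debounce gap so retriggers merge into one visit.
    pir_retrigger_s: tuple[float, float] | None = (10.0, 25.0)

    loadcell: LoadcellConfig = field(default_factory=LoadcellConfig)
    emfit_miss_rate: float = 0.6
    emfit_spurious_per_night: float = 0.0
    inactivity_timeout_min: float = 15.0
    patrol_times: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name, m in (("transition_matrix", self.transition_matrix),
                        ("early_transition_matrix", self.early_transition_matrix)):
            if m is None:
                continue
            m = np.asarray(m, dtype=float)
            if m.shape != (len(STATES), len(STATES)):
                raise ConfigError(f"{name} must be {len(STATES)}x{len(STATES)}")
            if np.any(m < 0) or not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
                raise ConfigError(f"{name} rows must be nonnegative and sum to 1")
        if not 0.0 <= self.emfit_miss_rate <= 1.0:
            raise ConfigError("emfit_miss_rate must be in [0, 1]")

    @property
    def night_seconds(self) -> float:
        return self.night_hours * 3600.0


@dataclass
class NightRecord:
    """One simulated night: sensor streams plus ground truth."""

    night_id: str
    night_start: pd.Timestamp
    sampling_hz: float
    state_timeline: list            # (state, enter_s, exit_s) from night start
    ambient_events: list            # rooms + I + D
    true_bed_events: list           # ground-truth Bin/Bout
    emfit_events: list              # degraded bed events (source "emfit")
    adc: np.ndarray | None = None   # 80 Hz ADC stream, None when skipped
    adc_ratio: float = VOLTAGE_WEIGHT_RATIO

    @property
    def bed_intervals(self) -> list[tuple[float, float]]:
        return [(a, b) for s, a, b in self.state_timeline if s == "Bed"]

    @property
    def weights(self) -> np.ndarray:
        if self.adc is None:
            raise ValueError("night was simulated without the load-cell stream")
        return self.adc / self.adc_ratio

    @property
    def event_log(self) -> list[SensorEvent]:
        """Raw sensor log: ambient events plus the degraded bed sensor."""
        return sorted(self.ambient_events + self.emfit_events, key=lambda e: e.ts)

    def events_with_true_bed(self) -> list[SensorEvent]:
        """Ambient events merged with the ground-truth bed events."""
        return sorted(self.ambient_events + self.true_bed_events, key=lambda e: e.ts)


def truncated_normal_moments(
    mu: float, sigma: float, lower: float = 0.0
) -> tuple[float, float]:
    """(mean, std) of N(mu, sigma) truncated below at ``lower``.

    The truncation shifts both moments away from (mu, sigma); recovery
    tests must compare against these, the moments of the distribution
    actually sampled.
    """
    a = (lower - mu) / sigma
    mean, var = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sigma, moments="mv")
    return float(mean), float(np.sqrt(var))


def _trunc_normal(rng: np.random.Generator, mu: float, sigma: float,
                  lower: float = 0.0) -> float:
    if sigma <= 0:
        return max(mu, lower)
    a = (lower - mu) / sigma
    return float(stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, random_state=rng))


def _night_rng(cfg: ScenarioConfig, night_idx: int, sub: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, night_idx, sub])


def _sample_timeline(cfg: ScenarioConfig, rng: np.random.Generator) -> list:
    """Semi-Markov trajectory over the active span, seconds from start."""
    T = cfg.night_seconds
    early_end = cfg.early_hours * 3600.0
    timeline = []
    t = 0.0
    state = "Bed"                      # resident goes to bed at sensor-on
    while t < T:
        early = t < early_end and cfg.early_dwell_min is not None
        dwell_cfg = cfg.early_dwell_min if early else cfg.dwell_min
        mu, sigma = dwell_cfg[state]
        dwell = _trunc_normal(rng, mu * 60.0, sigma * 60.0, lower=6.0)
        exit_t = min(t + dwell, T)
        timeline.append((state, t, exit_t))
        if exit_t >= T:
            break
        use_early = (exit_t < early_end) and cfg.early_transition_matrix is not None
        m = cfg.early_transition_matrix if use_early else cfg.transition_matrix
        row = np.asarray(m, dtype=float)[STATES.index(state)]
        state = STATES[rng.choice(len(STATES), p=row)]
        t = exit_t
    return timeline


def _emit_events(cfg: ScenarioConfig, night_id: str, night_start: pd.Timestamp,
                 timeline: list, rng: np.random.Generator):
    """Ambient (rooms, I, D) and true bed events from a trajectory."""

    def ev(sym: str, t_s: float, source: str) -> SensorEvent:
        return SensorEvent(ts=night_start + pd.to_timedelta(t_s, unit="s"),
                           symbol=sym, night_id=night_id, source=source)

    T = cfg.night_seconds
    ambient: list[SensorEvent] = []
    bed: list[SensorEvent] = []
    timeout_s = cfg.inactivity_timeout_min * 60.0
    prev_state: str | None = None
    for state, enter, exit_ in timeline:
        if state == "Bed":
            if enter > 0.0:
                bed.append(ev("Bin", enter, "loadcell"))
            if exit_ < T:
                bed.append(ev("Bout", exit_, "loadcell"))
            if exit_ - enter > timeout_s:
                ambient.append(ev("I", enter + timeout_s, "wearable"))
        else:
            gap_mu, gap_sigma = cfg.event_gap_min.get(
                (prev_state, state), cfg.default_gap_min)
            gap = _trunc_normal(rng, gap_mu * 60.0, gap_sigma * 60.0, lower=0.0)
            dur = exit_ - enter
            t_fire = enter + (min(gap, dur - 1.0) if dur > 1.0 else dur / 2.0)
            ambient.append(ev(state, t_fire, "pir"))
            if cfg.pir_retrigger_s is not None:
                lo_rt, hi_rt = cfg.pir_retrigger_s
                t_rt = t_fire + rng.uniform(lo_rt, hi_rt)
                while t_rt < exit_ - 0.5:
                    ambient.append(ev(state, t_rt, "pir"))
                    t_rt += rng.uniform(lo_rt, hi_rt)
        prev_state = state
    for hhmm in cfg.patrol_times:
        hh, mm = (int(x) for x in hhmm.split(":"))
        t_s = ((hh - cfg.night_start_hour) % 24) * 3600.0 + mm * 60.0
        if 0 <= t_s < T:
            ambient.append(ev("D", t_s, "door"))
    ambient.sort(key=lambda e: e.ts)
    bed.sort(key=lambda e: e.ts)
    return ambient, bed


def degrade_emfit(
    true_bed_events: list[SensorEvent],
    miss_rate: float = 0.6,
    rng: np.random.Generator | int | None = None,
    spurious_per_night: float = 0.0,
    night_span: tuple[pd.Timestamp, pd.Timestamp] | None = None,
) -> list[SensorEvent]:
    """Model the film bed sensor: drop each true Bout independently with
    probability ``miss_rate``; optionally inject spurious exits
    (Poisson-many, uniform over ``night_span``)."""
    if not 0.0 <= miss_rate <= 1.0:
        raise ValueError("miss_rate must be in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = []
    for e in true_bed_events:
        if e.symbol == "Bout" and rng.random() < miss_rate:
            continue
        out.append(SensorEvent(ts=e.ts, symbol=e.symbol,
                               night_id=e.night_id, source="emfit"))
    if spurious_per_night > 0.0 and night_span is not None:
        n_spur = rng.poisson(spurious_per_night)
        lo, hi = night_span
        span_s = (hi - lo).total_seconds()
        for _ in range(n_spur):
            t = lo + pd.to_timedelta(rng.uniform(0.0, span_s), unit="s")
            nid = true_bed_events[0].night_id if true_bed_events else ""
            out.append(SensorEvent(ts=t, symbol="Bout", night_id=nid, source="emfit"))
    out.sort(key=lambda e: e.ts)
    return out


def gen_loadcell(
    bed_intervals: list[tuple[float, float]],
    cfg: LoadcellConfig,
    rng: np.random.Generator | int | None,
    duration_s: float,
) -> np.ndarray:
    """ADC stream for one night: ``round(weight_kg * adc_ratio)``.

    Occupied stretches carry the body-weight mean plus micro-movement
    noise and Poisson-seeded movement bursts; empty stretches only the
    tare and the electronic noise floor.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = int(round(duration_s * cfg.sampling_hz))
    occupied = np.zeros(n, dtype=bool)
    for a, b in bed_intervals:
        occupied[int(a * cfg.sampling_hz): int(b * cfg.sampling_hz)] = True

    weight = np.full(n, cfg.empty_mean_kg, dtype=float)
    if cfg.empty_sigma_kg > 0:
        weight += rng.normal(0.0, cfg.empty_sigma_kg, n)
    n_occ = int(occupied.sum())
    if n_occ:
        occ_noise = (rng.normal(0.0, cfg.occupied_sigma_kg, n_occ)
                     if cfg.occupied_sigma_kg > 0 else 0.0)
        weight[occupied] = cfg.occupied_mean_kg + occ_noise
        occ_minutes = n_occ / cfg.sampling_hz / 60.0
        n_bursts = rng.poisson(cfg.burst_rate_per_min * occ_minutes)
        if n_bursts and cfg.burst_amp_kg > 0:
            occ_idx = np.flatnonzero(occupied)
            starts = rng.choice(occ_idx, size=n_bursts)
            lo, hi = cfg.burst_duration_s
            durations = rng.uniform(lo, hi, n_bursts)
            extra = np.zeros(n)
            for s, d in zip(starts, durations):
                e = min(n, s + int(d * cfg.sampling_hz))
                extra[s:e] += rng.normal(0.0, cfg.burst_amp_kg, e - s)
            extra[~occupied] = 0.0        # bursts belong to the occupied bed
            weight += extra
    return np.rint(weight * cfg.adc_ratio).astype(np.int64)


def night_id_for(cfg: ScenarioConfig, night_idx: int) -> str:
    date = pd.Timestamp(cfg.start_date) + pd.Timedelta(days=night_idx)
    return date.strftime("%Y-%m-%d")


def night_start_for(cfg: ScenarioConfig, night_idx: int) -> pd.Timestamp:
    date = pd.Timestamp(cfg.start_date, tz="UTC") + pd.Timedelta(days=night_idx)
    return date + pd.Timedelta(hours=cfg.night_start_hour)


def simulate_night(
    cfg: ScenarioConfig, night_idx: int, include_loadcell: bool = True
) -> NightRecord:
    """One night, fully reproducible from ``(cfg.seed, night_idx)``."""
    night_id = night_id_for(cfg, night_idx)
    night_start = night_start_for(cfg, night_idx)
    rng_traj = _night_rng(cfg, night_idx, _SUB_TRAJ)
    timeline = _sample_timeline(cfg, rng_traj)
    ambient, true_bed = _emit_events(cfg, night_id, night_start, timeline, rng_traj)
    rng_emfit = _night_rng(cfg, night_idx, _SUB_EMFIT)
    night_end = night_start + pd.to_timedelta(cfg.night_seconds, unit="s")
    emfit = degrade_emfit(
        true_bed, cfg.emfit_miss_rate, rng_emfit,
        spurious_per_night=cfg.emfit_spurious_per_night,
        night_span=(night_start, night_end),
    )
    adc = None
    if include_loadcell:
        rng_lc = _night_rng(cfg, night_idx, _SUB_LOADCELL)
        bed_iv = [(a, b) for s, a, b in timeline if s == "Bed"]
        adc = gen_loadcell(bed_iv, cfg.loadcell, rng_lc, cfg.night_seconds)
    return NightRecord(
        night_id=night_id, night_start=night_start,
        sampling_hz=cfg.loadcell.sampling_hz, state_timeline=timeline,
        ambient_events=ambient, true_bed_events=true_bed, emfit_events=emfit,
        adc=adc, adc_ratio=cfg.loadcell.adc_ratio,
    )


def simulate(cfg: ScenarioConfig, include_loadcell: bool = True) -> list[NightRecord]:
    return [simulate_night(cfg, i, include_loadcell) for i in range(cfg.n_nights)]


def single_phase(cfg: ScenarioConfig) -> ScenarioConfig:
    """The same scenario with the early-night overrides disabled, so the
    whole night follows one homogeneous planted chain."""
    return replace(cfg, early_transition_matrix=None, early_dwell_min=None)


def implied_event_matrix(cfg: ScenarioConfig) -> np.ndarray:
    """Event-level transition matrix implied by a single-phase config.

    Maps the planted state matrix onto the 8-symbol event alphabet:
    a bed visit emits Bin, then I iff the dwell exceeds the inactivity
    timeout, then Bout; a room visit emits its PIR symbol once.  Rows
    with no outgoing mass (e.g. D with no patrols) are left at zero.
    Only defined for homogeneous scenarios (no early-night overrides).
    """
    if cfg.early_transition_matrix is not None or cfg.early_dwell_min is not None:
        raise ConfigError(
            "implied event matrix is only defined for single-phase scenarios; "
            "use single_phase(cfg)"
        )
    m = np.asarray(cfg.transition_matrix, dtype=float)
    if m[STATES.index("Bed"), STATES.index("Bed")] != 0.0:
        raise ConfigError("Bed self-transitions make the event mapping ambiguous")
    mu, sigma = cfg.dwell_min["Bed"]
    a = (0.0 - mu) / sigma
    q = float(stats.truncnorm.sf(cfg.inactivity_timeout_min, a, np.inf,
                                 loc=mu, scale=sigma))
    k = len(ALPHABET)
    p = np.zeros((k, k))
    bin_i, bout_i, i_i = SYMBOL_INDEX["Bin"], SYMBOL_INDEX["Bout"], SYMBOL_INDEX["I"]
    p[bin_i, i_i] = q
    p[bin_i, bout_i] = 1.0 - q
    p[i_i, bout_i] = 1.0
    bed_row = m[STATES.index("Bed")]
    for s in ROOM_STATES:
        p[bout_i, SYMBOL_INDEX[s]] = bed_row[STATES.index(s)]
    for r in ROOM_STATES:
        row = m[STATES.index(r)]
        p[SYMBOL_INDEX[r], bin_i] = row[STATES.index("Bed")]
        for s in ROOM_STATES:
            p[SYMBOL_INDEX[r], SYMBOL_INDEX[s]] = row[STATES.index(s)]
    return p
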