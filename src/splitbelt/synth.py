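"""Synthetic split-belt trials with known ground truth.

The generator emulates the statistical structure the analysis assumes —
burst-like phase-locked activity per gait cycle, speed-dependent
amplitude modulation, an anti-symmetric steady state during split-belt
walking, and transition transients that are linear mixtures of the
on(+) corrective pattern and its leg-transposed mirror — while keeping
every quantity the pipeline estimates exactly known:

* gait events are placed on the force-sample grid and the force profile
  crosses the 10 N threshold exactly at them, so the detector recovers
  them bit-exactly;
* per-stride muscle activity is specified as intended values of the 12
  phase bins; the emitted EMG is a +-1 square carrier (well above the
  highpass cutoff) amplitude-modulated by those values and then
  iteratively calibrated against the analysis front-end (dual-pass
  highpass, rectification, phase binning) so that binning the processed
  EMG returns the intended values to ~1e-9;
* transition transients hold their stride-1 value over a plateau that
  covers every early/whole epoch window and then decay to exactly zero
  before any late window, so epoch-level corrective responses equal the
  configured stride-1 deltas and the structure regression recovers the
  configured (b_adapt, b_no_adapt) exactly in the noiseless case.

Stride-to-stride noise is iid Gaussian per muscle-phase-stride in
normalized (% of baseline maximum) units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from . import gait_features as gf
from .signal_prep import GaitEvents, SampledSignal, highpass_sos
from .vectors import ActivityIndex, MUSCLES


class InvalidConfigError(ValueError):
    pass


# --------------------------------------------------------------------------
# Protocol schedule

ENVIRONMENTS = ("tied-slow", "tied-medium", "split(+)")


@dataclass(frozen=True)
class Condition:
    name: str
    stride_count: int
    environment: str
    blocks: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.environment not in ENVIRONMENTS:
            raise InvalidConfigError(f"unknown environment {self.environment!r}")
        if self.stride_count < 1:
            raise InvalidConfigError("stride_count must be positive")
        if self.blocks is not None and sum(self.blocks) != self.stride_count:
            raise InvalidConfigError("block lengths must sum to stride_count")

    @property
    def block_lengths(self) -> tuple[int, ...]:
        return self.blocks if self.blocks is not None else (self.stride_count,)


@dataclass(frozen=True)
class ProtocolSchedule:
    """Ordered walking conditions of one experimental session."""

    conditions: tuple[Condition, ...]

    def __post_init__(self) -> None:
        if not self.conditions:
            raise InvalidConfigError("schedule must contain at least one condition")

    def names(self) -> list[str]:
        return [c.name for c in self.conditions]

    def __getitem__(self, name: str) -> Condition:
        for c in self.conditions:
            if c.name == name:
                return c
        raise KeyError(name)

    @classmethod
    def default(cls) -> "ProtocolSchedule":
        """The six-condition study protocol (1760 strides).

        Split-belt blocks use a 2:1 belt-speed ratio obtained by scaling
        the medium speed by 4/3 (fast belt) and 2/3 (slow belt); long
        exposure and washout are divided into blocks with full treadmill
        stops between them.
        """
        return cls(conditions=(
            Condition("slow", 50, "tied-slow"),
            Condition("mid", 50, "tied-medium"),
            Condition("shortExposure", 10, "split(+)"),
            Condition("baseline", 150, "tied-medium"),
            Condition("longExposure", 900, "split(+)", blocks=(300, 300, 300)),
            Condition("washout", 600, "tied-medium", blocks=(300, 300)),
        ))

    @classmethod
    def compact(cls) -> "ProtocolSchedule":
        """A desk-scale schedule (262 strides) preserving the protocol's
        structure: every epoch the analysis needs (early 5, late 40,
        whole-of-short, 40-stride normalization window) exists.  Pair it
        with :meth:`SyntheticConfig.compact`, whose faster transient
        time-constant dies out before the shorter late windows.
        """
        return cls(conditions=(
            Condition("slow", 6, "tied-slow"),
            Condition("mid", 6, "tied-medium"),
            Condition("shortExposure", 10, "split(+)"),
            Condition("baseline", 60, "tied-medium"),
            Condition("longExposure", 60, "split(+)"),
            Condition("washout", 60, "tied-medium"),
        ))


def belt_speeds(environment: str, medium_speed: float) -> dict[str, float]:
    """Per-leg belt speed (m/s) implied by an environment label."""
    if environment == "tied-medium":
        v = {"slow": medium_speed, "fast": medium_speed}
    elif environment == "tied-slow":
        v = {"slow": 2 / 3 * medium_speed, "fast": 2 / 3 * medium_speed}
    else:  # split(+): fast belt at twice the slow belt
        v = {"slow": 2 / 3 * medium_speed, "fast": 4 / 3 * medium_speed}
    return v


# --------------------------------------------------------------------------
# Configuration

#: Burst templates per muscle: (amplitude, center, width) in gait-cycle
#: fraction, cycle starting at ipsilateral heel-strike.  Loosely follows
#: textbook activation timing (plantarflexors in late stance, TA around
#: swing/heel-strike, quads in early stance, hamstrings in late swing).
DEFAULT_BURSTS: dict[str, tuple[tuple[float, float, float], ...]] = {
    "TA":  ((1.0, 0.02, 0.05), (0.8, 0.90, 0.08)),
    "PER": ((0.9, 0.45, 0.10),),
    "MG":  ((1.0, 0.45, 0.08),),
    "LG":  ((1.0, 0.43, 0.08),),
    "SOL": ((1.0, 0.40, 0.10),),
    "BF":  ((0.9, 0.95, 0.06), (0.5, 0.05, 0.06)),
    "SMT": ((0.9, 0.93, 0.06), (0.4, 0.05, 0.06)),
    "SMB": ((0.8, 0.94, 0.06),),
    "RF":  ((0.8, 0.05, 0.07), (0.4, 0.65, 0.05)),
    "VL":  ((1.0, 0.04, 0.07),),
    "VM":  ((1.0, 0.05, 0.07),),
    "HIP": ((0.9, 0.68, 0.08),),
    "ADM": ((0.7, 0.70, 0.10),),
    "GLU": ((0.8, 0.05, 0.08),),
    "TFL": ((0.7, 0.66, 0.08),),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic-trial generator.

    The defaults reproduce the study conditions: 15 muscles per leg,
    2000/1000/100 Hz sampling, a 2:1 split obtained from the medium
    speed via 4/3 and 2/3 factors, early/whole epoch windows covered by
    a 10-stride transient plateau, and a 50-stride adaptation
    time-constant.  ``seed`` fully determines the output.
    """

    muscles: tuple[str, ...] = MUSCLES
    emg_rate: float = 2000.0
    force_rate: float = 1000.0
    marker_rate: float = 100.0
    medium_speed: float = 1.0          # m/s (cohort mean of Table-1-like speeds)
    stride_duration_mean: float = 1.1  # s
    stride_jitter: float = 0.05        # uniform +-fraction of the mean
    stance_fraction: float = 0.65      # ipsilateral toe-off at this cycle fraction
    ds_fraction: float = 0.15          # contralateral toe-off (end of first DS)
    burst_templates: dict[str, tuple[tuple[float, float, float], ...]] = field(
        default_factory=lambda: dict(DEFAULT_BURSTS)
    )
    tonic_level: float = 0.10          # tonic floor, fraction of burst max
    adaptation_tau: float = 50.0       # strides
    transient_plateau: int = 10        # strides held at the stride-1 value
    transient_len: int = 110           # stride at which the transient reaches 0
    b_adapt: float = 0.6
    b_no_adapt: float = 0.2
    b_adapt_short: float = 0.0         # off-transition after the short exposure
    b_no_adapt_short: float = 1.0      # (idealized environment-based response)
    delta_scale: float = 12.0          # sd of the on(+) delta per component, % units
    delta_leg_correlation: float = 0.2 # sets the on(-)/-on(+) collinearity cosine
    split_modulation: float = 0.25     # anti-symmetric steady-state burst gain
    speed_exponent: float = 1.0        # burst amplitude ~ (speed ratio)^q
    noise_sd: float = 10.0             # iid per muscle-phase-stride, % units
    sla_early_split: float = -0.25
    sla_late_split: float = -0.02
    sla_washout: float = 0.15
    carrier_hz: float = 250.0
    filter_cutoff_hz: float = 30.0     # front-end the EMG is calibrated against
    filter_order: int = 2
    calibration_iters: int = 5
    block_gap_s: float = 2.0
    force_plateau_n: float = 700.0
    seed: int = 0
    pattern_seed: int | None = None    # share burst/delta patterns across subjects

    def __post_init__(self) -> None:
        for name in ("emg_rate", "force_rate", "marker_rate"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")
        if self.stride_duration_mean <= 0:
            raise InvalidConfigError("stride_duration_mean must be positive")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be non-negative")
        if not 0 < self.ds_fraction < self.stance_fraction < 1:
            raise InvalidConfigError("need 0 < ds_fraction < stance_fraction < 1")
        if not 1 <= self.transient_plateau < self.transient_len:
            raise InvalidConfigError("need 1 <= transient_plateau < transient_len")

    @property
    def n_muscles_per_leg(self) -> int:
        return len(self.muscles)

    @classmethod
    def compact(cls, **overrides) -> "SyntheticConfig":
        """Defaults suited to :meth:`ProtocolSchedule.compact`: the
        transient dies out by stride 18, before the late windows of the
        60-stride conditions."""
        base = dict(adaptation_tau=2.0, transient_plateau=10, transient_len=18)
        base.update(overrides)
        return cls(**base)

    def decay(self, stride_index: np.ndarray) -> np.ndarray:
        """Transient decay g(k) for 1-based within-condition stride index.

        g = 1 on the plateau, then a shifted exponential reaching 0 at
        ``transient_len`` and staying there: monotone, continuous, and
        exactly zero in every late-epoch window of the study schedules.
        """
        k = np.asarray(stride_index, float)
        p, K, tau = self.transient_plateau, self.transient_len, self.adaptation_tau
        tail = np.exp(-(k - p) / tau)
        floor = np.exp(-(K - p) / tau)
        g = (tail - floor) / (1.0 - floor)
        return np.clip(np.where(k <= p, 1.0, g), 0.0, 1.0)


# --------------------------------------------------------------------------
# Ground-truth containers

@dataclass
class GroundTruth:
    """Everything the analysis is supposed to estimate."""

    events: GaitEvents
    stride_conditions: list[str]                 # per stride, schedule order
    stride_ordinal: np.ndarray                   # 1-based index within condition
    activity: np.ndarray                         # (n_strides, 360) noise-free, % units
    activity_noisy: np.ndarray                   # what the EMG encodes
    condition_steady: dict[str, np.ndarray]      # normalized steady-state vectors
    transition_deltas: dict[str, np.ndarray]     # stride-1 deltas, % units
    betas: dict[str, float]
    normalization: gf.NormalizationMap           # raw-unit map per channel
    sla: np.ndarray                              # per-stride step-length asymmetry
    step_lengths: np.ndarray                     # (n_strides, 2): fast, slow (m)

    def condition_strides(self, name: str) -> np.ndarray:
        idx = [i for i, c in enumerate(self.stride_conditions) if c == name]
        return np.asarray(idx, int)


@dataclass
class BlockSpan:
    condition: str
    start_s: float
    stop_s: float
    speeds: dict[str, float]


@dataclass
class SyntheticTrial:
    emg: SampledSignal
    forces: SampledSignal
    markers: SampledSignal
    schedule: ProtocolSchedule
    blocks: list[BlockSpan]
    ground_truth: GroundTruth
    config: SyntheticConfig


# --------------------------------------------------------------------------
# Pattern construction

def _phase_bin_centers(config: SyntheticConfig) -> np.ndarray:
    """Cycle-fraction midpoints of the 12 bins."""
    d = config.ds_fraction
    s = config.stance_fraction
    edges = np.concatenate([
        np.linspace(0.0, d, 3)[:-1],
        np.linspace(d, 0.5, 5)[:-1],
        np.linspace(0.5, s, 3)[:-1],
        np.linspace(s, 1.0, 5),
    ])
    return 0.5 * (edges[:-1] + edges[1:])


def _burst_profile(config: SyntheticConfig) -> np.ndarray:
    """Baseline burst pattern, (n_muscles, 12), tonic floor included."""
    centers = _phase_bin_centers(config)
    prof = np.zeros((len(config.muscles), centers.size))
    for mi, m in enumerate(config.muscles):
        for amp, c, w in config.burst_templates.get(m, ((1.0, 0.5, 0.1),)):
            dist = np.minimum(np.abs(centers - c), 1.0 - np.abs(centers - c))
            prof[mi] += amp * np.exp(-0.5 * (dist / w) ** 2)
    peak = prof.max(axis=1, keepdims=True)
    return config.tonic_level * peak + prof


def _smooth_circular(x: np.ndarray, sigma_bins: float = 1.5) -> np.ndarray:
    n = x.shape[-1]
    k = np.exp(-0.5 * ((np.arange(n) - n // 2) / sigma_bins) ** 2)
    k /= k.sum()
    return np.real(np.fft.ifft(np.fft.fft(x, axis=-1) * np.fft.fft(np.roll(k, -(n // 2)))))


@dataclass
class _Patterns:
    """Internal: normalized steady states and transition deltas."""

    index: ActivityIndex
    raw_base: np.ndarray                      # (m, 12) raw units, both legs
    shift: np.ndarray                         # (m,) raw min over bins
    scale: np.ndarray                         # (m,) raw range over bins
    steady: dict[str, np.ndarray]             # env name -> (360,) normalized
    d_on: np.ndarray                          # (360,) normalized stride-1 on(+)


def _normalize_profiles(raw_by_leg: dict[str, np.ndarray],
                        shift: np.ndarray, scale: np.ndarray,
                        index: ActivityIndex) -> np.ndarray:
    blocks = []
    for leg in index.legs:
        blocks.append((100.0 * (raw_by_leg[leg] - shift[:, None]) / scale[:, None]).ravel())
    return np.concatenate(blocks)


def _build_patterns(config: SyntheticConfig, rng: np.random.Generator) -> _Patterns:
    index = ActivityIndex(muscles=config.muscles)
    base = _burst_profile(config)                       # (m, 12)
    burst = base - base.min(axis=1, keepdims=True)      # burst part above the tonic floor
    floor = base.min(axis=1, keepdims=True)

    shift = base.min(axis=1)
    scale = base.max(axis=1) - base.min(axis=1)

    def leg_profile(speed_factor: float, split_sign: float) -> np.ndarray:
        f = speed_factor ** config.speed_exponent + split_sign * config.split_modulation
        return floor + f * burst

    steady: dict[str, np.ndarray] = {}
    for env in ENVIRONMENTS:
        v = belt_speeds(env, config.medium_speed)
        s = {
            "slow": leg_profile(v["slow"] / config.medium_speed,
                                +1.0 if env == "split(+)" else 0.0),
            "fast": leg_profile(v["fast"] / config.medium_speed,
                                -1.0 if env == "split(+)" else 0.0),
        }
        steady[env] = _normalize_profiles(s, shift, scale, index)

    # on(+) corrective pattern: smooth random per muscle, correlated across
    # legs so the inferred on(-) factor is far from collinear with -on(+).
    # Weighted by the local baseline activation level: corrective responses
    # modulate bursts, and rectified EMG cannot drop below zero, so deltas
    # at quiet phases must be small.
    m, nph = base.shape
    u = _smooth_circular(rng.standard_normal((m, nph)))
    w = _smooth_circular(rng.standard_normal((m, nph)))
    kappa = config.delta_leg_correlation
    slow_d = u
    fast_d = kappa * u + np.sqrt(max(0.0, 1 - kappa**2)) * w
    level = (base / base.max(axis=1, keepdims=True)).ravel()   # (m*nph,) in (0, 1]
    d = np.concatenate([slow_d.ravel() * level, fast_d.ravel() * level])
    sd = d.std()
    d_on = config.delta_scale * d / (sd if sd > 0 else 1.0)
    return _Patterns(index=index, raw_base=base, shift=shift, scale=scale,
                     steady=steady, d_on=d_on)


def transition_targets(config: SyntheticConfig, patterns: _Patterns) -> dict[str, np.ndarray]:
    """Stride-1 corrective-response deltas for the labelled transitions."""
    M = patterns.index.mirror
    d = patterns.d_on
    return {
        "on(+)": d,
        "off(+)-long": -config.b_no_adapt * d + config.b_adapt * M(d),
        "off(+)-short": -config.b_no_adapt_short * d + config.b_adapt_short * M(d),
        "on(-)-inferred": M(d),
    }


def _stride_truth(
    config: SyntheticConfig, schedule: ProtocolSchedule, patterns: _Patterns
) -> tuple[list[str], np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Noise-free per-stride normalized activity for the whole protocol."""
    targets = transition_targets(config, patterns)

    def accumulate(tg: dict[str, np.ndarray]):
        conds: list[str] = []
        ordinals: list[int] = []
        rows: list[np.ndarray] = []
        prev_end: np.ndarray | None = None  # activity at the previous condition's end
        prev_env: str | None = None
        prev_name: str | None = None
        for cond in schedule.conditions:
            steady = patterns.steady[cond.environment]
            if prev_end is None:
                transient = np.zeros_like(steady)
            else:
                # stride-1 corrective response relative to where the previous
                # condition actually ended (the short exposure never reaches
                # its steady state, so prev_end, not the split steady state,
                # anchors its off transition)
                if cond.environment == "split(+)" and prev_env != "split(+)":
                    d1 = tg["on(+)"]
                elif prev_env == "split(+)":
                    dur = "long" if prev_name == "longExposure" else "short"
                    d1 = tg[f"off(+)-{dur}"]
                else:
                    d1 = None   # tied-to-tied speed change: instant switch
                transient = (d1 + prev_end - steady) if d1 is not None \
                    else np.zeros_like(steady)
            k = np.arange(1, cond.stride_count + 1)
            g = config.decay(k)
            rows.append(steady[None, :] + g[:, None] * transient[None, :])
            conds.extend([cond.name] * cond.stride_count)
            ordinals.extend(k.tolist())
            prev_end = steady + float(config.decay(np.array([cond.stride_count]))[0]) * transient
            prev_env, prev_name = cond.environment, cond.name
        return conds, np.asarray(ordinals), np.vstack(rows)

    conds, ordinals, activity = accumulate(targets)

    # Rectified EMG cannot encode activity below zero raw amplitude.  The
    # activity is affine in the on(+) delta, so if any intended value
    # would fall below the raw floor the corrective component alone is
    # shrunk exactly by a common factor rather than clipped (which would
    # break the configured mixture relations).
    n_ph = activity.shape[1] // (2 * len(config.muscles))
    floor_m = -100.0 * patterns.shift / patterns.scale
    floor = np.tile(np.repeat(floor_m, n_ph), 2)
    zeros = {k: np.zeros_like(v) for k, v in targets.items()}
    base_rows = accumulate(zeros)[2]
    delta_part = activity - base_rows
    margin = 0.5
    with np.errstate(divide="ignore", invalid="ignore"):
        room = np.where(
            delta_part < 0,
            (base_rows - floor[None, :] - margin) / np.maximum(-delta_part, 1e-300),
            np.inf,
        )
    eta = float(min(1.0, np.min(room)))
    if eta < 1.0:
        activity = base_rows + eta * delta_part
        targets = {k: eta * v for k, v in targets.items()}
        patterns.d_on = targets["on(+)"]
    return conds, ordinals, activity, targets


def simulate_stride_vectors(
    config: SyntheticConfig, schedule: ProtocolSchedule | None = None
) -> dict:
    """Fast path: normalized per-stride activity without signal synthesis.

    Returns the noisy stride matrix (n_strides, 360) exactly as the full
    pipeline would recover it from continuous signals (the binning-
    equivalent construction), plus all ground truth.  Used for
    Monte-Carlo studies where rendering EMG would dominate runtime.
    """
    schedule = schedule or ProtocolSchedule.default()
    root = np.random.default_rng(config.seed)
    rng_pattern, _rng_timeline, rng_noise, _rng_gain = root.spawn(4)
    if config.pattern_seed is not None:
        rng_pattern = np.random.default_rng(config.pattern_seed)
    patterns = _build_patterns(config, rng_pattern)
    conds, ordinals, clean, targets = _stride_truth(config, schedule, patterns)
    noisy = clean + rng_noise.normal(0.0, config.noise_sd, clean.shape)
    return {
        "index": patterns.index,
        "stride_conditions": conds,
        "stride_ordinal": ordinals,
        "activity": clean,
        "activity_noisy": noisy,
        "condition_steady": {c.name: patterns.steady[c.environment]
                             for c in schedule.conditions},
        "transition_deltas": targets,
        "betas": {"b_adapt": config.b_adapt, "b_no_adapt": config.b_no_adapt,
                  "b_adapt_short": config.b_adapt_short,
                  "b_no_adapt_short": config.b_no_adapt_short},
    }


def stride_matrices_by_condition(sim: dict, noisy: bool = True) -> dict[str, np.ndarray]:
    """Split a :func:`simulate_stride_vectors` result per condition."""
    key = "activity_noisy" if noisy else "activity"
    conds = sim["stride_conditions"]
    out: dict[str, np.ndarray] = {}
    for name in dict.fromkeys(conds):
        rows = [i for i, c in enumerate(conds) if c == name]
        out[name] = sim[key][rows]
    return out


# --------------------------------------------------------------------------
# Event timeline

@dataclass
class _Timeline:
    events: GaitEvents
    blocks: list[BlockSpan]
    # per leg: heel-strike time -> (condition name, 1-based ordinal)
    stride_lookup: dict[str, dict[float, tuple[str, int]]]
    stride_durations: dict[float, float]       # keyed by slow heel-strike time
    t_end: float


def _build_timeline(
    config: SyntheticConfig, schedule: ProtocolSchedule, rng: np.random.Generator
) -> _Timeline:
    fr = config.force_rate

    def snap(t: float) -> float:
        return round(t * fr) / fr

    hs = {"slow": [], "fast": []}
    to = {"slow": [], "fast": []}
    lookup = {"slow": {}, "fast": {}}
    durations: dict[float, float] = {}
    blocks: list[BlockSpan] = []
    t = 0.5
    for cond in schedule.conditions:
        ordinal = 0
        speeds = belt_speeds(cond.environment, config.medium_speed)
        for nb in cond.block_lengths:
            block_start = t - 0.25
            # gait initiation: the fast foot is already in stance when the
            # belts start, so that leg's events alternate heel-strike first
            hs["fast"].append(snap(t - 0.3 * config.stride_duration_mean))
            for _ in range(nb):
                ordinal += 1
                T = config.stride_duration_mean * (
                    1.0 + config.stride_jitter * rng.uniform(-1, 1)
                )
                t0 = snap(t)
                hs["slow"].append(t0)
                to["fast"].append(snap(t + config.ds_fraction * T))
                t_fhs = snap(t + 0.5 * T)
                hs["fast"].append(t_fhs)
                to["slow"].append(snap(t + config.stance_fraction * T))
                lookup["slow"][t0] = (cond.name, ordinal)
                lookup["fast"][t_fhs] = (cond.name, ordinal)
                durations[t0] = T
                t += T
            # wind-down: closing heel-strikes so the block's last strides are
            # complete, then both feet off before the treadmill stops
            T = config.stride_duration_mean
            t0 = snap(t)
            hs["slow"].append(t0)
            to["fast"].append(snap(t + config.ds_fraction * T))
            hs["fast"].append(snap(t + 0.5 * T))
            to["slow"].append(snap(t + config.stance_fraction * T))
            to["fast"].append(snap(t + 0.8 * T))
            durations[t0] = T
            t += 0.8 * T
            blocks.append(BlockSpan(cond.name, block_start, t + 0.1, dict(speeds)))
            t += config.block_gap_s
    events = GaitEvents(
        heel_strikes={leg: np.asarray(v) for leg, v in hs.items()},
        toe_offs={leg: np.asarray(v) for leg, v in to.items()},
    )
    return _Timeline(events=events, blocks=blocks, stride_lookup=lookup,
                     stride_durations=durations, t_end=t + 0.5)


# --------------------------------------------------------------------------
# Signal rendering

def make_force_profile(
    events: GaitEvents, config: SyntheticConfig, t_end: float | None = None
) -> SampledSignal:
    """Vertical ground-reaction force consistent with the event rule.

    Fz exceeds 10 N from each heel-strike sample up to (not including)
    the toe-off sample and is zero elsewhere, with a smooth single-hump
    loading profile in between; empty events give an all-zero trace.
    """
    events.validate()
    legs = events.legs or ["slow", "fast"]
    last = 0.0
    for leg in legs:
        for arr in (events.heel_strikes.get(leg, []), events.toe_offs.get(leg, [])):
            if len(arr):
                last = max(last, float(np.max(arr)))
    t_end = t_end if t_end is not None else last + 0.5
    n = int(round(t_end * config.force_rate)) + 1
    out = np.zeros((n, len(legs)))
    for li, leg in enumerate(legs):
        hs = np.asarray(events.heel_strikes.get(leg, []), float)
        to = np.asarray(events.toe_offs.get(leg, []), float)
        for k, t0 in enumerate(hs):
            if k >= to.size:
                break
            i0 = int(round(t0 * config.force_rate))
            i1 = int(round(to[k] * config.force_rate))
            if i1 <= i0:
                continue
            s = np.arange(i1 - i0) / (i1 - i0)
            out[i0:i1, li] = 30.0 + (config.force_plateau_n - 30.0) * np.sin(np.pi * s) ** 0.7
    return SampledSignal(out, config.force_rate, [f"fz_{leg}_N" for leg in legs])


def _render_markers(
    config: SyntheticConfig, timeline: _Timeline,
    conds: list[str], ordinals: np.ndarray, schedule: ProtocolSchedule,
) -> tuple[SampledSignal, np.ndarray, np.ndarray]:
    """Piecewise-linear ankle trajectories + hip midpoint.

    Landing positions realize the per-stride target step-length
    asymmetry exactly; returns (markers, sla, step_lengths).
    """
    env_of = {c.name: c.environment for c in schedule.conditions}
    slow_hs = timeline.events.heel_strikes["slow"]
    n_t = int(round(timeline.t_end * config.marker_rate)) + 1
    ts = np.arange(n_t) / config.marker_rate

    # per counted stride: target SLA and belt speeds
    sla = np.zeros(len(conds))
    for i, (c, k) in enumerate(zip(conds, ordinals)):
        g = float(config.decay(np.array([k]))[0])
        if env_of[c] == "split(+)":
            sla[i] = config.sla_late_split + (config.sla_early_split - config.sla_late_split) * g
        elif c == "washout":
            sla[i] = config.sla_washout * g
        else:
            sla[i] = 0.0

    knots = {"slow": ([], []), "fast": ([], [])}  # (times, positions)
    step_lengths = np.zeros((len(conds), 2))
    c0 = 0.28  # nominal landing position ahead of treadmill center, m
    i_stride = 0
    lookup = timeline.stride_lookup["slow"]
    for t0 in slow_hs:
        info = lookup.get(float(t0))
        T = timeline.stride_durations.get(float(t0), config.stride_duration_mean)
        if info is None:
            v = belt_speeds("tied-medium", config.medium_speed)
            da, this_sla = 0.0, 0.0
        else:
            cname, k = info
            v = belt_speeds(env_of[cname], config.medium_speed)
            ssum = 0.5 * T * (v["slow"] + v["fast"])
            this_sla = sla[i_stride]
            da = 0.5 * (this_sla * ssum - 0.5 * T * (v["slow"] - v["fast"]))
            step_lengths[i_stride] = (da + 0.5 * T * v["slow"], -da + 0.5 * T * v["fast"])
            i_stride += 1
        a_s, a_f = c0 - da / 2, c0 + da / 2
        # slow ankle: lands at t0, moves back at belt speed until toe-off
        kt, kx = knots["slow"]
        kt += [t0, t0 + config.stance_fraction * T]
        kx += [a_s, a_s - v["slow"] * config.stance_fraction * T]
        kt2, kx2 = knots["fast"]
        kt2 += [t0 + 0.5 * T, t0 + 0.5 * T + config.stance_fraction * T]
        kx2 += [a_f, a_f - v["fast"] * config.stance_fraction * T]

    cols = {}
    for leg, side in (("slow", "left"), ("fast", "right")):
        kt, kx = knots[leg]
        order = np.argsort(kt, kind="stable")
        kt = np.asarray(kt)[order]
        kx = np.asarray(kx)[order]
        keep = np.concatenate([[True], np.diff(kt) > 0])
        cols[f"ankle_{side}_ap_m"] = np.interp(ts, kt[keep], kx[keep])
    body = 0.02 * np.sin(2 * np.pi * ts / config.stride_duration_mean)
    cols["hip_left_ap_m"] = body + 0.005
    cols["hip_right_ap_m"] = body - 0.005
    names = ["ankle_left_ap_m", "ankle_right_ap_m", "hip_left_ap_m", "hip_right_ap_m"]
    markers = SampledSignal(np.column_stack([cols[c] for c in names]),
                            config.marker_rate, names)
    return markers, sla, step_lengths


def _render_emg(
    config: SyntheticConfig, timeline: _Timeline, patterns: _Patterns,
    noisy: np.ndarray, conds: list[str], ordinals: np.ndarray,
    gains: np.ndarray,
) -> SampledSignal:
    """Carrier-modulated EMG calibrated against the analysis front-end."""
    fs = config.emg_rate
    n = int(round(timeline.t_end * fs)) + 1
    times = np.arange(n) / fs
    sos = highpass_sos(config.filter_cutoff_hz, config.filter_order, fs)
    index = patterns.index
    n_m = len(config.muscles)

    # where each counted stride sits in the noisy matrix
    row_of: dict[tuple[str, int], int] = {
        (c, int(k)): i for i, (c, k) in enumerate(zip(conds, ordinals))
    }
    emg = np.empty((n, 2 * n_m))
    n_ph = len(index.phases)
    ch_i = 0
    for li, leg in enumerate(index.legs):
        partitions = gf.segment_phases(timeline.events, leg)
        lookup = timeline.stride_lookup[leg]
        # flat arrays of bin sample ranges + stride rows for this leg
        starts, stops, rows = [], [], []
        for part in partitions:
            info = lookup.get(part.start)
            if info is None:
                continue
            for a, b in gf.bin_edges_to_sample_slices(part.edges, times):
                starts.append(a)
                stops.append(b)
            rows.append(row_of[info])
        A = np.asarray(starts, int)
        B = np.asarray(stops, int)
        rows = np.asarray(rows, int)
        widths = B - A
        for mi in range(n_m):
            comp0 = li * n_m * n_ph + mi * n_ph
            gain = gains[ch_i]
            vals = noisy[rows][:, comp0 : comp0 + n_ph].ravel()   # per rendered bin
            raw = np.maximum(
                gain * (patterns.shift[mi] + patterns.scale[mi] * vals / 100.0), 0.0
            )
            target = np.full(n, gain * patterns.shift[mi])
            step = np.zeros(n + 1)
            np.add.at(step, A, raw - target[A])
            np.add.at(step, B, -(raw - target[A]))
            target += np.cumsum(step[:-1])
            phase = 0.37 + 0.013 * ch_i
            carrier = np.sign(np.sin(2 * np.pi * config.carrier_hz * times + phase))
            env = target.copy()
            for _ in range(config.calibration_iters):
                cs = np.concatenate([[0.0], np.cumsum(np.abs(_sig.sosfiltfilt(sos, env * carrier)))])
                err = (cs[B] - cs[A]) / widths - raw
                step = np.zeros(n + 1)
                np.add.at(step, A, err)
                np.add.at(step, B, -err)
                env = np.maximum(env - np.cumsum(step[:-1]), 0.0)
            emg[:, ch_i] = env * carrier
            ch_i += 1
    side = {"slow": "left", "fast": "right"}
    names = [f"{side[leg]}_{m}" for leg in index.legs for m in config.muscles]
    return SampledSignal(emg, fs, names)


# --------------------------------------------------------------------------
# Top-level generation

def generate_trial(
    config: SyntheticConfig, schedule: ProtocolSchedule | None = None
) -> SyntheticTrial:
    """Generate a complete synthetic trial with known ground truth.

    The per-stride activity underlying the EMG equals each condition's
    steady-state pattern plus, after each environmental transition, a
    transient delta — the configured mixture
    ``-b_no_adapt*d_on(+) + b_adapt*mirror(d_on(+))`` for off
    transitions, the on(+) pattern itself for on transitions — held for
    ``transient_plateau`` strides and then decaying with the adaptation
    time-constant.  Additive iid Gaussian noise (``noise_sd``, % units)
    is applied per muscle-phase-stride.  The same (config, schedule)
    with the same seed reproduces the trial bit-exactly.
    """
    schedule = schedule or ProtocolSchedule.default()
    root = np.random.default_rng(config.seed)
    rng_pattern, rng_timeline, rng_noise, rng_gain = root.spawn(4)
    if config.pattern_seed is not None:
        rng_pattern = np.random.default_rng(config.pattern_seed)
    patterns = _build_patterns(config, rng_pattern)
    conds, ordinals, clean, targets = _stride_truth(config, schedule, patterns)
    noisy = clean + rng_noise.normal(0.0, config.noise_sd, clean.shape)

    timeline = _build_timeline(config, schedule, rng_timeline)
    forces = make_force_profile(timeline.events, config, timeline.t_end)
    forces.channels = ["fz_left_N", "fz_right_N"]   # slow leg on the left belt
    markers, sla, step_lengths = _render_markers(config, timeline, conds, ordinals, schedule)
    gains = np.exp(rng_gain.normal(0.0, 0.5, 2 * len(config.muscles)))
    emg = _render_emg(config, timeline, patterns, noisy, conds, ordinals, gains)

    side = {"slow": "left", "fast": "right"}
    nmap = gf.NormalizationMap(
        shift={f"{side[leg]}_{m}": float(gains[li * len(config.muscles) + mi]
                                         * patterns.shift[mi])
               for li, leg in enumerate(patterns.index.legs)
               for mi, m in enumerate(config.muscles)},
        scale={f"{side[leg]}_{m}": float(gains[li * len(config.muscles) + mi]
                                         * patterns.scale[mi])
               for li, leg in enumerate(patterns.index.legs)
               for mi, m in enumerate(config.muscles)},
    )
    gt = GroundTruth(
        events=timeline.events,
        stride_conditions=conds,
        stride_ordinal=ordinals,
        activity=clean,
        activity_noisy=noisy,
        condition_steady={c.name: patterns.steady[c.environment]
                          for c in schedule.conditions},
        transition_deltas=targets,
        betas={"b_adapt": config.b_adapt, "b_no_adapt": config.b_no_adapt,
               "b_adapt_short": config.b_adapt_short,
               "b_no_adapt_short": config.b_no_adapt_short},
        normalization=nmap,
        sla=sla,
        step_lengths=step_lengths,
    )
    return SyntheticTrial(emg=emg, forces=forces, markers=markers,
                          schedule=schedule, blocks=timeline.blocks,
                          ground_truth=gt, config=config)
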