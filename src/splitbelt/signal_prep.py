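"""Raw-signal conditioning and gait-event detection.

EMG is highpass filtered (dual-pass second-order Butterworth, 30 Hz
default, i.e. 80 dB/decade magnitude roll-off with zero net phase shift)
and rectified; no lowpass envelope is applied afterwards.  Gait events
are detected from the vertical ground-reaction force of each belt with a
10 N threshold: heel-strike when Fz rises above threshold, toe-off when
it falls below, both required to be sustained for a debounce window to
reject chatter around the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig


class SignalLengthError(ValueError):
    """Signal too short for the requested filter."""


class InvalidParameterError(ValueError):
    """Filter/detector parameter outside its valid range."""


class InvalidEventsError(ValueError):
    """Gait events violating ordering/overlap constraints."""


@dataclass
class SampledSignal:
    """Uniformly sampled multi-channel time series.

    ``values`` has shape (n_samples, n_channels); ``channels`` are the
    column labels.  All modalities share a common time base in seconds
    (``times = start_time + arange(n) / sample_rate``), so events found
    on the force clock can be applied to EMG and marker streams by time
    rather than by sample index.
    """

    values: np.ndarray
    sample_rate: float
    channels: list[str]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values))
        if self.values.shape[0] == 1 and len(self.channels) == 1:
            self.values = self.values.reshape(-1, 1)
        if self.sample_rate <= 0:
            raise InvalidParameterError("sample_rate must be positive")
        if self.values.shape[1] != len(self.channels):
            raise ValueError(
                f"{self.values.shape[1]} columns vs {len(self.channels)} channel labels"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sample_rate

    def channel(self, name: str) -> np.ndarray:
        return self.values[:, self.channels.index(name)]


@dataclass
class GaitEvents:
    """Heel-strike and toe-off times (seconds) per leg.

    Within each leg the two event types strictly alternate starting with
    a heel-strike; stance is the interval [heel_strike, next toe_off).
    """

    heel_strikes: dict[str, np.ndarray] = field(default_factory=dict)
    toe_offs: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def legs(self) -> list[str]:
        return list(self.heel_strikes)

    def validate(self, debounce_s: float = 0.0) -> None:
        for leg in self.legs:
            hs = np.asarray(self.heel_strikes[leg], float)
            to = np.asarray(self.toe_offs.get(leg, []), float)
            if np.any(np.diff(hs) <= debounce_s) or np.any(np.diff(to) <= debounce_s):
                raise InvalidEventsError(f"{leg}: same-type events too close")
            if len(to) > len(hs) or len(hs) - len(to) > 1:
                raise InvalidEventsError(f"{leg}: event count parity violated")
            merged = np.empty(len(hs) + len(to))
            merged[0::2] = hs
            merged[1::2] = to
            if np.any(np.diff(merged) <= 0):
                raise InvalidEventsError(f"{leg}: heel-strikes/toe-offs do not alternate")

    def to_dict(self) -> dict:
        return {
            leg: {
                "heel_strike": np.asarray(self.heel_strikes[leg]).tolist(),
                "toe_off": np.asarray(self.toe_offs[leg]).tolist(),
            }
            for leg in self.legs
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaitEvents":
        return cls(
            heel_strikes={leg: np.asarray(v["heel_strike"], float) for leg, v in d.items()},
            toe_offs={leg: np.asarray(v["toe_off"], float) for leg, v in d.items()},
        )


def highpass_sos(cutoff_hz: float, order: int, sample_rate: float) -> np.ndarray:
    if not 0 < cutoff_hz < sample_rate / 2:
        raise InvalidParameterError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={sample_rate / 2} Hz)"
        )
    return _sig.butter(order, cutoff_hz, btype="highpass", fs=sample_rate, output="sos")


def highpass_rectify(
    signal: SampledSignal, cutoff_hz: float = 30.0, order: int = 2
) -> SampledSignal:
    """Zero-lag highpass filter followed by full-wave rectification.

    The filter is applied forward and backward (``sosfiltfilt``), which
    squares the Butterworth magnitude response (an effective 2*order
    roll-off) and cancels the phase.  Edge transients are handled by
    ``sosfiltfilt``'s default odd-reflection padding.
    """
    sos = highpass_sos(cutoff_hz, order, signal.sample_rate)
    # sosfiltfilt needs a handful of samples per second-order section
    min_len = 3 * (2 * sos.shape[0] + 1)
    if signal.n_samples <= max(min_len, 3 * order):
        raise SignalLengthError(
            f"signal of {signal.n_samples} samples too short for order-{order} dual-pass filter"
        )
    filtered = _sig.sosfiltfilt(sos, signal.values, axis=0)
    return SampledSignal(
        values=np.abs(filtered),
        sample_rate=signal.sample_rate,
        channels=list(signal.channels),
        start_time=signal.start_time,
    )


def _debounce_bool(above: np.ndarray, min_samples: int) -> np.ndarray:
    """Suppress runs shorter than ``min_samples``.

    Short False runs (dips during stance) are filled first, then short
    True runs (spikes during swing) are removed, so an isolated blip in
    either direction never produces an event.
    """
    if min_samples <= 1:
        return above
    out = above.copy()
    for target in (False, True):
        n = out.size
        # run-length encode
        change = np.flatnonzero(np.diff(out.astype(np.int8))) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [n]])
        for s, e in zip(starts, ends):
            if out[s] == target and (e - s) < min_samples and s > 0 and e < n:
                out[s:e] = not target
    return out


def detect_gait_events(
    fz: SampledSignal,
    threshold_n: float = 10.0,
    debounce_s: float = 0.02,
    leg_names: dict[str, str] | None = None,
) -> GaitEvents:
    """Detect heel-strikes and toe-offs from per-belt vertical force.

    A heel-strike is the time of the first sample at which Fz exceeds
    ``threshold_n`` and stays above it for at least ``debounce_s``;
    a toe-off is the first sample back below threshold, with the same
    persistence requirement.  Each force channel is treated as one leg;
    ``leg_names`` optionally renames channels (e.g. ``{"fz_left_N":
    "slow"}``).  If a channel never crosses the threshold a warning is
    issued and that leg gets empty event arrays.
    """
    if threshold_n <= 0:
        raise InvalidParameterError("threshold_n must be positive")
    min_samples = max(1, int(round(debounce_s * fz.sample_rate)))
    events = GaitEvents()
    times = fz.times
    for ci, ch in enumerate(fz.channels):
        leg = (leg_names or {}).get(ch, ch)
        above = _debounce_bool(fz.values[:, ci] > threshold_n, min_samples)
        if not above.any():
            warnings.warn(f"force channel {ch!r} never crosses {threshold_n} N")
            events.heel_strikes[leg] = np.array([])
            events.toe_offs[leg] = np.array([])
            continue
        d = np.diff(above.astype(np.int8))
        rises = np.flatnonzero(d == 1) + 1
        falls = np.flatnonzero(d == -1) + 1
        # discard an initial stance already in progress so heel-strike comes first
        falls = falls[falls > (rises[0] if rises.size else np.inf)]
        # alternation: keep the first of any same-type pair
        hs, to = [], []
        ri = fi = 0
        expect_rise = True
        while ri < rises.size or fi < falls.size:
            if expect_rise:
                if ri >= rises.size:
                    break
                hs.append(rises[ri])
                ri += 1
                while fi < falls.size and falls[fi] <= hs[-1]:
                    fi += 1
            else:
                if fi >= falls.size:
                    break
                to.append(falls[fi])
                fi += 1
                while ri < rises.size and rises[ri] <= to[-1]:
                    ri += 1
            expect_rise = not expect_rise
        events.heel_strikes[leg] = times[np.asarray(hs, int)] if hs else np.array([])
        events.toe_offs[leg] = times[np.asarray(to, int)] if to else np.array([])
    return events
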