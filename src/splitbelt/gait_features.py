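"""Event-aligned EMG binning, baseline normalization, and stride kinematics.

Each leg's gait cycle runs from its own heel-strike to the next
ipsilateral heel-strike and is divided into four phases by the
contralateral events: double support (ipsi HS -> contra TO), single
stance (contra TO -> contra HS), second double support (contra HS ->
ipsi TO) and swing (ipsi TO -> next ipsi HS).  Double-support phases are
halved and single-stance/swing quartered, giving 12 contiguous bins per
cycle; rectified EMG is time-averaged within each bin.  Because each
leg's grid starts at its own heel-strike, the two legs' bins are not
synchronous.

Amplitude normalization is per (leg, muscle): the across-stride mean of
each bin over the last 40 strides of baseline defines a 12-bin profile
whose minimum maps to 0% and maximum to 100%; the same affine map is
applied to every condition, so values outside [0, 100] are possible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .signal_prep import GaitEvents, SampledSignal
from .vectors import ActivityIndex, PHASE_LABELS

logger = logging.getLogger(__name__)

#: Sub-bin counts of the four gait phases (DS1, SINGLE, DS2, SWING).
PHASE_DIVISIONS: tuple[int, int, int, int] = (2, 4, 2, 4)


class DegenerateNormalizationError(ValueError):
    """A muscle whose baseline profile has (near-)zero range."""


class EmptyBinError(ValueError):
    """A phase bin containing no samples."""


class InvalidGeometryError(ValueError):
    """Step geometry that admits no asymmetry value."""


@dataclass(frozen=True)
class PhasePartition:
    """The 12 time bins of one stride of one leg.

    ``edges`` has 13 ascending entries (seconds); bin ``i`` is the
    half-open interval [edges[i], edges[i+1]).  The bins tile the stride
    span exactly.
    """

    edges: np.ndarray
    labels: tuple[str, ...] = PHASE_LABELS

    @property
    def start(self) -> float:
        return float(self.edges[0])

    @property
    def end(self) -> float:
        return float(self.edges[-1])

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1


def _subdivide(a: float, b: float, k: int) -> np.ndarray:
    """Equal subdivision of [a, b] into k parts, endpoints exact."""
    return a + (b - a) * np.arange(k + 1) / k


def segment_phases(
    events: GaitEvents,
    leg: str,
    divisions: tuple[int, int, int, int] = PHASE_DIVISIONS,
) -> list[PhasePartition]:
    """One PhasePartition per complete stride of ``leg``.

    A stride is complete when the event quadruple (ipsi HS, contra TO,
    contra HS, ipsi TO) occurs in order before the next ipsilateral
    heel-strike; strides missing any event are skipped and logged.
    """
    legs = events.legs
    if leg not in legs:
        raise ValueError(f"unknown leg {leg!r}; have {legs}")
    contra = [l for l in legs if l != leg]
    if len(contra) != 1:
        raise ValueError("exactly two legs are required for phase segmentation")
    contra = contra[0]

    hs_i = np.asarray(events.heel_strikes[leg], float)
    to_i = np.asarray(events.toe_offs[leg], float)
    hs_c = np.asarray(events.heel_strikes[contra], float)
    to_c = np.asarray(events.toe_offs[contra], float)

    out: list[PhasePartition] = []
    if hs_i.size < 2:
        logger.warning("leg %s: fewer than one complete stride", leg)
        return out
    for k in range(hs_i.size - 1):
        t0, t1 = hs_i[k], hs_i[k + 1]

        def _first_in(arr: np.ndarray, lo: float, hi: float) -> float | None:
            sel = arr[(arr > lo) & (arr < hi)]
            return float(sel[0]) if sel.size else None

        cto = _first_in(to_c, t0, t1)
        chs = _first_in(hs_c, cto, t1) if cto is not None else None
        ito = _first_in(to_i, chs, t1) if chs is not None else None
        if cto is None or chs is None or ito is None:
            logger.info("leg %s stride %d [%.3f, %.3f): incomplete event quadruple, skipped",
                        leg, k, t0, t1)
            continue
        d1, d2, d3, d4 = divisions
        edges = np.concatenate([
            _subdivide(t0, cto, d1)[:-1],
            _subdivide(cto, chs, d2)[:-1],
            _subdivide(chs, ito, d3)[:-1],
            _subdivide(ito, t1, d4),
        ])
        labels = PHASE_LABELS if divisions == PHASE_DIVISIONS else tuple(
            f"P{i}" for i in range(sum(divisions))
        )
        out.append(PhasePartition(edges=edges, labels=labels))
    return out


def bin_edges_to_sample_slices(
    edges: np.ndarray, times: np.ndarray
) -> list[tuple[int, int]]:
    """Half-open sample index ranges for each bin of ``edges``.

    A sample belongs to bin i when edges[i] <= t < edges[i+1].  Shared by
    the analysis and by the synthetic generator so that sample-to-bin
    assignment is identical in both directions.
    """
    idx = np.searchsorted(times, edges, side="left")
    return [(int(idx[i]), int(idx[i + 1])) for i in range(len(edges) - 1)]


def bin_stride_activity(
    emg: SampledSignal, partitions: list[PhasePartition]
) -> np.ndarray:
    """Per-stride time-averages of each channel over each phase bin.

    Returns an array of shape (n_strides, n_channels, n_bins).  Raises
    :class:`EmptyBinError` naming the stride and phase if any bin spans
    no samples (cannot occur at 2000 Hz with the >= 75 ms bins typical
    of adult walking).
    """
    times = emg.times
    n_bins = partitions[0].n_bins if partitions else 0
    out = np.empty((len(partitions), emg.values.shape[1], n_bins))
    csum = np.concatenate([np.zeros((1, emg.values.shape[1])), np.cumsum(emg.values, axis=0)])
    for si, part in enumerate(partitions):
        for bi, (a, b) in enumerate(bin_edges_to_sample_slices(part.edges, times)):
            if b <= a:
                raise EmptyBinError(
                    f"stride {si}, phase {part.labels[bi]}: no samples in "
                    f"[{part.edges[bi]:.4f}, {part.edges[bi + 1]:.4f})"
                )
            out[si, :, bi] = (csum[b] - csum[a]) / (b - a)
    return out


@dataclass
class NormalizationMap:
    """Per-channel affine map ``x -> 100 * (x - shift) / scale``."""

    shift: dict[str, float]
    scale: dict[str, float]

    def to_dict(self) -> dict:
        return {"shift": self.shift, "scale": self.scale}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationMap":
        return cls(shift=dict(d["shift"]), scale=dict(d["scale"]))


def fit_baseline_normalization(
    baseline_bins: np.ndarray,
    channels: list[str],
    last_n: int = 40,
    eps: float = 1e-12,
) -> NormalizationMap:
    """Fit the 0-100% map from the last ``last_n`` baseline strides.

    ``baseline_bins`` (strides, channels, bins) must already have the
    condition's excluded strides removed (the final stride is excluded
    before counting back 40).  For each channel the across-stride mean
    of each bin is computed; shift is the minimum of those bin means and
    scale their range.  Channels with a flat profile raise
    :class:`DegenerateNormalizationError` listing the offenders.
    """
    if baseline_bins.shape[0] < last_n:
        raise ValueError(
            f"need >= {last_n} baseline strides after exclusions, have {baseline_bins.shape[0]}"
        )
    profile = baseline_bins[-last_n:].mean(axis=0)  # (channels, bins)
    lo = profile.min(axis=1)
    rng = profile.max(axis=1) - lo
    flat = [ch for ch, r in zip(channels, rng) if r < eps]
    if flat:
        raise DegenerateNormalizationError(
            f"zero baseline range for channel(s): {', '.join(flat)}"
        )
    return NormalizationMap(
        shift={ch: float(s) for ch, s in zip(channels, lo)},
        scale={ch: float(r) for ch, r in zip(channels, rng)},
    )


def apply_normalization(
    raw_bins: np.ndarray, nmap: NormalizationMap, channels: list[str]
) -> np.ndarray:
    """Apply the baseline-derived map to raw bin means of any condition."""
    missing = [ch for ch in channels if ch not in nmap.shift]
    if missing:
        raise KeyError(f"channels missing from normalization map: {missing}")
    shift = np.array([nmap.shift[ch] for ch in channels])[:, None]
    scale = np.array([nmap.scale[ch] for ch in channels])[:, None]
    return 100.0 * (raw_bins - shift) / scale


def build_activity_matrix(
    bins_by_leg: dict[str, np.ndarray],
    muscles_by_leg: dict[str, list[str]],
    index: ActivityIndex,
) -> np.ndarray:
    """Stack per-leg normalized bins into (strides, n_components) vectors.

    ``bins_by_leg[leg]`` is (strides, muscles, phases); legs are paired
    stride-by-stride in order, truncating to the shorter leg if counts
    differ.  Ordering follows ``index``: slow block then fast block,
    muscle-major, phase-minor.
    """
    n = min(bins_by_leg[leg].shape[0] for leg in index.legs)
    blocks = []
    for leg in index.legs:
        order = [muscles_by_leg[leg].index(m) for m in index.muscles]
        blocks.append(bins_by_leg[leg][:n][:, order, :].reshape(n, -1))
    return np.concatenate(blocks, axis=1)


def _interp_channel(markers: SampledSignal, name: str, t: np.ndarray) -> np.ndarray:
    return np.interp(t, markers.times, markers.channel(name))


def step_length_asymmetry(
    markers: SampledSignal,
    events: GaitEvents,
    ankle_channels: dict[str, str] | None = None,
) -> np.ndarray:
    """Per-stride step-length asymmetry (SL_fast - SL_slow)/(SL_fast + SL_slow).

    Step length is the fore-aft ankle-to-ankle distance at foot landing
    (landing ankle minus the other ankle, so lengths are positive for
    forward landings).  Each fast-leg heel-strike is paired with the
    next slow-leg heel-strike; zero means even steps, negative means the
    slow leg takes longer steps.  Marker positions are linearly
    interpolated at event times.
    """
    ch = ankle_channels or {"slow": "ankle_slow_ap_m", "fast": "ankle_fast_ap_m"}
    hs_f = np.asarray(events.heel_strikes["fast"], float)
    hs_s = np.asarray(events.heel_strikes["slow"], float)
    a_f = _interp_channel(markers, ch["fast"], hs_f)
    a_s_at_f = _interp_channel(markers, ch["slow"], hs_f)
    sl_fast_all = a_f - a_s_at_f
    a_s = _interp_channel(markers, ch["slow"], hs_s)
    a_f_at_s = _interp_channel(markers, ch["fast"], hs_s)
    sl_slow_all = a_s - a_f_at_s

    out = []
    for k, t_f in enumerate(hs_f):
        nxt = np.searchsorted(hs_s, t_f, side="right")
        if nxt >= hs_s.size:
            break
        sl_f, sl_s = sl_fast_all[k], sl_slow_all[nxt]
        denom = sl_f + sl_s
        if denom <= 0:
            raise InvalidGeometryError(
                f"non-positive step-length sum {denom:.4f} m at t={t_f:.3f}s"
            )
        out.append((sl_f - sl_s) / denom)
    return np.asarray(out)


def hip_displacement(
    markers: SampledSignal,
    events: GaitEvents,
    leg: str,
    hip_channels: tuple[str, str] = ("hip_left_ap_m", "hip_right_ap_m"),
    ankle_channel: str | None = None,
) -> np.ndarray:
    """Fore-aft body progression over each stance of ``leg``.

    Computed as the AP distance between the hip-marker midpoint and the
    ipsilateral ankle at contralateral heel-strike minus the same
    distance at ipsilateral heel-strike (forward positive).
    """
    contra = [l for l in events.legs if l != leg][0]
    hs_i = np.asarray(events.heel_strikes[leg], float)
    hs_c = np.asarray(events.heel_strikes[contra], float)
    ankle = ankle_channel or f"ankle_{leg}_ap_m"
    span = (markers.times[0], markers.times[-1])

    out = []
    for t0 in hs_i:
        nxt = hs_c[hs_c > t0]
        if not nxt.size:
            break
        t1 = float(nxt[0])
        if t0 < span[0] or t1 > span[1]:
            raise ValueError(f"marker record does not cover stance [{t0:.3f}, {t1:.3f}]s")
        ts = np.array([t0, t1])
        mid = 0.5 * (
            _interp_channel(markers, hip_channels[0], ts)
            + _interp_channel(markers, hip_channels[1], ts)
        )
        ank = _interp_channel(markers, ankle, ts)
        rel = mid - ank
        out.append(rel[1] - rel[0])
    return np.asarray(out)
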