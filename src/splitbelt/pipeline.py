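"""Per-subject and group orchestration of the full analysis.

``run_subject`` takes one subject's raw signals plus the realized
condition timeline and produces stride activity matrices, epoch vectors,
the three corrective-response deltas (on(+), off(+) after the short and
long exposures), the inferred on(-) factor, structure regressions,
cosine analyses, magnitudes, and stride kinematics.  ``run_group``
aggregates subject results into group-level vectors (median across
subjects by default), mass-univariate epoch contrasts with FDR control,
the short-vs-long paired comparisons of the regression coefficients,
and intersubject correlations with age and walking speed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from . import adaptation as ad
from . import gait_features as gf
from . import stats as st
from .signal_prep import GaitEvents, SampledSignal, detect_gait_events, highpass_rectify
from .synth import BlockSpan, SyntheticTrial
from .vectors import ActivityIndex, MUSCLES

logger = logging.getLogger(__name__)


class MissingConditionError(KeyError):
    """A requested transition needs a condition the schedule lacks."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis parameters; the defaults are the study's stated values."""

    filter_cutoff_hz: float = 30.0
    filter_order: int = 2
    event_threshold_n: float = 10.0
    debounce_s: float = 0.02
    early_n: int = 5
    late_n: int = 40
    norm_last_n: int = 40
    phase_divisions: tuple[int, int, int, int] = (2, 4, 2, 4)
    fdr_q: float = 0.05
    display_threshold_pct: float = 10.0
    group_aggregator: str = "median"     # or "mean"
    slow_side: str = "left"
    muscles: tuple[str, ...] = MUSCLES
    collinearity_limit: float = 0.99
    transitions: tuple[str, ...] = ("on(+)", "off(+)-long", "off(+)-short")
    seed: int = 0

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SubjectData:
    """One subject's raw recordings plus the realized condition timeline."""

    emg: SampledSignal
    forces: SampledSignal
    markers: SampledSignal | None
    blocks: list[BlockSpan]

    @classmethod
    def from_trial(cls, trial: SyntheticTrial) -> "SubjectData":
        return cls(emg=trial.emg, forces=trial.forces, markers=trial.markers,
                   blocks=list(trial.blocks))

    def condition_names(self) -> list[str]:
        names: list[str] = []
        for b in self.blocks:
            if b.condition not in names:
                names.append(b.condition)
        return names


@dataclass
class SubjectResult:
    subject_id: str
    index: ActivityIndex
    events: GaitEvents
    stride_matrices: dict[str, np.ndarray]      # condition -> (strides, 360)
    epochs: dict[str, np.ndarray]
    deltas: dict[str, ad.DeltaResponse]
    regressions: dict[str, ad.RegressionResult]
    cosines: dict[str, float]
    magnitudes: dict[str, float]
    normalization: dict[str, gf.NormalizationMap]
    kinematics: dict[str, object]
    manifest: dict

    def tidy_row(self) -> dict:
        row = {"subject": self.subject_id}
        for label, key in (("off(+)-long", "long"), ("off(+)-short", "short")):
            reg = self.regressions.get(label)
            if reg is not None:
                row[f"beta_adapt_{key}"] = reg.beta_adapt
                row[f"beta_no_adapt_{key}"] = reg.beta_no_adapt
                row[f"r2_{key}"] = reg.r2_uncentered
            row[f"cos_adapt_{key}"] = self.cosines.get(f"{label}|on(-)")
            row[f"cos_no_adapt_{key}"] = self.cosines.get(f"{label}|-on(+)")
        row.update({f"mag_{k}": v for k, v in self.magnitudes.items()})
        return row


_TRANSITION_NEEDS = {
    "on(+)": ("baseline", "longExposure"),
    "off(+)-long": ("longExposure", "washout"),
    "off(+)-short": ("shortExposure",),
}


def _strides_to_conditions(
    partitions: list[gf.PhasePartition], blocks: list[BlockSpan]
) -> dict[str, list[gf.PhasePartition]]:
    """Assign complete strides to conditions by full containment in a block.

    Strides spanning a treadmill stop (block gap) belong to no block and
    are dropped, with a log record for the stride accounting.
    """
    out: dict[str, list[gf.PhasePartition]] = {}
    dropped = 0
    for part in partitions:
        hit = None
        for b in blocks:
            if part.start >= b.start_s and part.end <= b.stop_s:
                hit = b.condition
                break
        if hit is None:
            dropped += 1
            continue
        out.setdefault(hit, []).append(part)
    if dropped:
        logger.info("dropped %d strides spanning block boundaries", dropped)
    return out


def run_subject(
    data: SubjectData, config: AnalysisConfig = AnalysisConfig(),
    subject_id: str = "S00",
) -> SubjectResult:
    """Run the full per-subject analysis.

    Raises :class:`MissingConditionError` if a requested transition
    needs a condition absent from the timeline, and propagates
    degenerate-normalization errors with channel names.
    """
    index = ActivityIndex(muscles=config.muscles)
    available = data.condition_names()
    for tr in config.transitions:
        for cond in _TRANSITION_NEEDS[tr]:
            if cond not in available:
                raise MissingConditionError(
                    f"transition {tr!r} requires condition {cond!r}, "
                    f"which the schedule lacks"
                )

    rect = highpass_rectify(data.emg, config.filter_cutoff_hz, config.filter_order)
    sides = {"slow": config.slow_side,
             "fast": "right" if config.slow_side == "left" else "left"}
    leg_names = {f"fz_{sides[leg]}_N": leg for leg in ("slow", "fast")}
    events = detect_gait_events(
        data.forces, config.event_threshold_n, config.debounce_s, leg_names
    )

    # per-leg binning and condition assignment
    norm_maps: dict[str, gf.NormalizationMap] = {}
    cond_bins: dict[str, dict[str, np.ndarray]] = {}
    for leg in ("slow", "fast"):
        channels = [f"{sides[leg]}_{m}" for m in config.muscles]
        sub = SampledSignal(
            np.column_stack([rect.channel(c) for c in channels]),
            rect.sample_rate, channels, rect.start_time,
        )
        partitions = gf.segment_phases(events, leg, config.phase_divisions)
        by_cond = _strides_to_conditions(partitions, data.blocks)
        if "baseline" not in by_cond:
            raise MissingConditionError("normalization requires a 'baseline' condition")
        flat = [p for cond in available for p in by_cond.get(cond, [])]
        bins = gf.bin_stride_activity(sub, flat)
        # split back per condition
        offsets = np.cumsum([0] + [len(by_cond.get(c, [])) for c in available])
        per_cond = {c: bins[offsets[i]:offsets[i + 1]]
                    for i, c in enumerate(available)}
        # final baseline stride is excluded first, then the last 40 used
        nmap = gf.fit_baseline_normalization(
            per_cond["baseline"][:-1], channels, config.norm_last_n
        )
        norm_maps[leg] = nmap
        cond_bins[leg] = {
            c: gf.apply_normalization(b, nmap, channels) for c, b in per_cond.items()
        }

    stride_matrices: dict[str, np.ndarray] = {}
    for c in available:
        n = min(cond_bins["slow"][c].shape[0], cond_bins["fast"][c].shape[0])
        if cond_bins["slow"][c].shape[0] != cond_bins["fast"][c].shape[0]:
            logger.warning("%s: unequal stride counts across legs, truncating to %d", c, n)
        stride_matrices[c] = np.concatenate(
            [cond_bins["slow"][c][:n].reshape(n, -1),
             cond_bins["fast"][c][:n].reshape(n, -1)], axis=1
        )

    core = analyze_stride_matrices(stride_matrices, available, config, subject_id, index)

    kinematics: dict[str, object] = {}
    if data.markers is not None:
        ankle = {"slow": f"ankle_{sides['slow']}_ap_m",
                 "fast": f"ankle_{sides['fast']}_ap_m"}
        # only steps inside condition blocks have defined geometry
        def _in_block(ts: np.ndarray) -> np.ndarray:
            keep = np.zeros(ts.size, dtype=bool)
            for b in data.blocks:
                keep |= (ts >= b.start_s) & (ts <= b.stop_s)
            return ts[keep]

        events_k = GaitEvents(
            heel_strikes={leg: _in_block(np.asarray(events.heel_strikes[leg], float))
                          for leg in events.legs},
            toe_offs={leg: np.asarray(events.toe_offs[leg], float)
                      for leg in events.legs},
        )
        sla = gf.step_length_asymmetry(data.markers, events_k, ankle)
        kinematics["sla"] = sla
        # per-condition SLA series, paired with the fast heel-strikes
        hs_f = np.asarray(events_k.heel_strikes["fast"], float)[: sla.size]
        per_cond: dict[str, np.ndarray] = {}
        for b in data.blocks:
            m = (hs_f >= b.start_s) & (hs_f <= b.stop_s)
            per_cond.setdefault(b.condition, np.array([]))
            per_cond[b.condition] = np.concatenate([per_cond[b.condition], sla[m]])
        kinematics["sla_by_condition"] = per_cond
        hip_chans = (f"hip_{config.slow_side}_ap_m",
                     "hip_right_ap_m" if config.slow_side == "left" else "hip_left_ap_m")
        for leg in ("slow", "fast"):
            try:
                kinematics[f"hip_displacement_{leg}"] = gf.hip_displacement(
                    data.markers, events_k, leg, hip_chans, ankle[leg])
            except ValueError:
                logger.info("hip displacement for %s leg not computable", leg)
        if "washout" in per_cond and per_cond["washout"].size >= 6:
            base = per_cond.get("baseline", np.array([0.0]))
            kinematics["sla_aftereffect"] = float(
                per_cond["washout"][1:6].mean() - base[-min(41, base.size):-1].mean()
            )

    core.events = events
    core.normalization = norm_maps
    core.kinematics = kinematics
    return core


def analyze_stride_matrices(
    stride_matrices: dict[str, np.ndarray],
    available: list[str] | None = None,
    config: AnalysisConfig = AnalysisConfig(),
    subject_id: str = "S00",
    index: ActivityIndex | None = None,
) -> SubjectResult:
    """Epochs, deltas and regressions from per-condition stride matrices.

    The vector-level back half of :func:`run_subject`, usable directly
    on already-binned (e.g. simulated) normalized stride activity.
    """
    available = available or list(stride_matrices)
    index = index or ActivityIndex(muscles=config.muscles)
    for tr in config.transitions:
        for cond in _TRANSITION_NEEDS[tr]:
            if cond not in available:
                raise MissingConditionError(
                    f"transition {tr!r} requires condition {cond!r}, "
                    f"which the schedule lacks"
                )

    def epoch(cond: str, mode: str) -> np.ndarray:
        n = {"early": config.early_n, "late": config.late_n, "whole": 1}[mode]
        return ad.epoch_vector(stride_matrices[cond], ad.EpochSpec(cond, mode, n))

    epochs: dict[str, np.ndarray] = {"lateBaseline": epoch("baseline", "late")}
    if "longExposure" in available:
        epochs["earlyLong"] = epoch("longExposure", "early")
        epochs["lateLong"] = epoch("longExposure", "late")
    if "washout" in available:
        epochs["earlyWashout"] = epoch("washout", "early")
    if "shortExposure" in available:
        epochs["wholeShort"] = epoch("shortExposure", "whole")
        nxt = available[available.index("shortExposure") + 1]
        epochs["earlyPostShort"] = epoch(nxt, "early")
    if "slow" in available:
        try:
            epochs["lateSlow"] = epoch("slow", "late")
        except ad.InsufficientStridesError:
            pass

    deltas: dict[str, ad.DeltaResponse] = {}
    if "on(+)" in config.transitions:
        deltas["on(+)"] = ad.delta_response(
            epochs["earlyLong"], epochs["lateBaseline"], "on(+)", index,
            {"after": "early longExposure", "before": "late baseline"},
        )
        deltas["on(-)-inferred"] = ad.mirror_transpose(deltas["on(+)"])
        deltas["on(-)-inferred"].label = "on(-)-inferred"
    if "off(+)-long" in config.transitions:
        deltas["off(+)-long"] = ad.delta_response(
            epochs["earlyWashout"], epochs["lateLong"], "off(+)-long", index,
            {"after": "early washout", "before": "late longExposure"},
        )
    if "off(+)-short" in config.transitions:
        deltas["off(+)-short"] = ad.delta_response(
            epochs["earlyPostShort"], epochs["wholeShort"], "off(+)-short", index,
            {"after": "early post-short", "before": "whole shortExposure"},
        )

    regressions: dict[str, ad.RegressionResult] = {}
    cosines: dict[str, float] = {}
    if "on(+)" in deltas:
        cosines["collinearity"] = ad.collinearity_check(deltas["on(+)"])
        for label in ("off(+)-long", "off(+)-short"):
            if label not in deltas:
                continue
            regressions[label] = ad.fit_structure(
                deltas[label], deltas["on(+)"], deltas["on(-)-inferred"],
                level="subject", collinearity_limit=config.collinearity_limit,
            )
            cosines[f"{label}|on(-)"] = ad.cosine(
                deltas[label].values, deltas["on(-)-inferred"].values)
            cosines[f"{label}|-on(+)"] = ad.cosine(
                deltas[label].values, -deltas["on(+)"].values)

    magnitudes: dict[str, float] = {}
    for label, d in deltas.items():
        magnitudes[label] = ad.vector_magnitude(d.values)
    if "earlyWashout" in epochs:
        magnitudes["aftereffect"] = ad.vector_magnitude(
            epochs["earlyWashout"] - epochs["lateBaseline"])
    if "lateLong" in epochs:
        magnitudes["steadySplit"] = ad.vector_magnitude(
            epochs["lateLong"] - epochs["lateBaseline"])

    manifest = {
        "subject": subject_id,
        "package_version": _pkg_version,
        "config": asdict(config),
        "config_digest": config.digest(),
        "strides_per_condition": {c: int(v.shape[0]) for c, v in stride_matrices.items()},
    }
    return SubjectResult(
        subject_id=subject_id, index=index, events=GaitEvents(),
        stride_matrices=stride_matrices, epochs=epochs, deltas=deltas,
        regressions=regressions, cosines=cosines, magnitudes=magnitudes,
        normalization={}, kinematics={}, manifest=manifest,
    )


# --------------------------------------------------------------------------
# Group level

@dataclass
class GroupResult:
    deltas: dict[str, ad.DeltaResponse]
    regressions: dict[str, ad.RegressionResult]
    cosines: dict[str, float]
    epoch_maps: dict[str, tuple[st.VariableTestResult, st.FdrResult]]
    paired: dict[str, st.PairedComparison]
    correlations: dict[str, tuple[float, float]]
    tidy: pd.DataFrame
    manifest: dict


def run_group(
    results: list[SubjectResult],
    config: AnalysisConfig = AnalysisConfig(),
    meta: dict[str, dict] | None = None,
) -> GroupResult:
    """Aggregate subject results into the group analysis.

    ``meta`` optionally maps subject id to {"age": years, "speed": m/s}
    for the intersubject correlations.  Requires >= 5 subjects with
    consistent component indexing.
    """
    if len(results) < 5:
        raise ValueError("group analysis needs at least 5 subject bundles")
    index = results[0].index
    if any(r.index.n_components != index.n_components for r in results):
        raise ValueError("inconsistent component indexing across subjects")
    agg = np.median if config.group_aggregator == "median" else np.mean

    # group-level delta vectors and structure regression
    deltas: dict[str, ad.DeltaResponse] = {}
    for label in ("on(+)", "off(+)-long", "off(+)-short"):
        mats = [r.deltas[label].values for r in results if label in r.deltas]
        if len(mats) == len(results):
            deltas[label] = ad.DeltaResponse(agg(np.vstack(mats), axis=0), label, index)
    regressions: dict[str, ad.RegressionResult] = {}
    cosines: dict[str, float] = {}
    if "on(+)" in deltas:
        d_on = deltas["on(+)"]
        d_minus = ad.mirror_transpose(d_on)
        deltas["on(-)-inferred"] = d_minus
        cosines["collinearity"] = ad.collinearity_check(d_on)
        for label in ("off(+)-long", "off(+)-short"):
            if label in deltas:
                regressions[label] = ad.fit_structure(
                    deltas[label], d_on, d_minus, level="group",
                    collinearity_limit=config.collinearity_limit,
                )
                cosines[f"{label}|on(-)"] = ad.cosine(deltas[label].values, d_minus.values)
                cosines[f"{label}|-on(+)"] = ad.cosine(deltas[label].values, -d_on.values)

    # mass-univariate epoch contrasts
    contrasts = {
        "on(+)": ("earlyLong", "lateBaseline"),
        "steadySplit": ("lateLong", "lateBaseline"),
        "aftereffects": ("earlyWashout", "lateBaseline"),
        "slowModulation": ("lateSlow", "lateBaseline"),
    }
    epoch_maps: dict[str, tuple[st.VariableTestResult, st.FdrResult]] = {}
    for name, (a, b) in contrasts.items():
        if all(a in r.epochs and b in r.epochs for r in results):
            A = np.vstack([r.epochs[a] for r in results])
            B = np.vstack([r.epochs[b] for r in results])
            test = st.wilcoxon_map(A, B)
            fdr = st.bky_fdr(test.p, config.fdr_q)
            st.display_mask(test, fdr, config.display_threshold_pct)
            epoch_maps[name] = (test, fdr)

    tidy = pd.DataFrame([r.tidy_row() for r in results])
    if meta:
        tidy["age"] = [meta.get(r.subject_id, {}).get("age") for r in results]
        tidy["speed"] = [meta.get(r.subject_id, {}).get("speed") for r in results]

    paired: dict[str, st.PairedComparison] = {}
    for quantity in ("beta_adapt", "beta_no_adapt", "cos_adapt", "cos_no_adapt"):
        lo, sh = f"{quantity}_long", f"{quantity}_short"
        if lo in tidy and sh in tidy and tidy[[lo, sh]].notna().all().all():
            paired[quantity] = st.paired_beta_comparison(tidy[lo].values, tidy[sh].values)

    correlations: dict[str, tuple[float, float]] = {}
    if meta:
        pairs = {
            "beta_adapt_long~age": ("beta_adapt_long", "age"),
            "beta_no_adapt_long~age": ("beta_no_adapt_long", "age"),
            "beta_adapt_long~speed": ("beta_adapt_long", "speed"),
            "mag_on(+)~age": ("mag_on(+)", "age"),
            "mag_off(+)-long~age": ("mag_off(+)-long", "age"),
            "mag_aftereffect~age": ("mag_aftereffect", "age"),
        }
        for name, (xc, yc) in pairs.items():
            if xc in tidy and yc in tidy and tidy[[xc, yc]].notna().all().all():
                try:
                    correlations[name] = st.spearman_assoc(
                        tidy[yc].values.astype(float), tidy[xc].values.astype(float))
                except (st.UndefinedCorrelationError, ValueError):
                    continue

    manifest = {
        "n_subjects": len(results),
        "aggregator": config.group_aggregator,
        "config_digest": config.digest(),
        "package_version": _pkg_version,
    }
    return GroupResult(deltas=deltas, regressions=regressions, cosines=cosines,
                       epoch_maps=epoch_maps, paired=paired,
                       correlations=correlations, tidy=tidy, manifest=manifest)
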