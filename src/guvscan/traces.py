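"""Scan-trace analysis: segmentation, per-section delta-|S21|, classification.

A scan trace is complex S21 sampled at a fixed odd-mode frequency while GUVs
flow over the split gap.  A flattened GUV produces a plateau of 0.6-0.9 s in
|S21|; a two-domain GUV produces two consecutive plateaus with the SM-rich
(liquid-ordered, raft-like) section first.  The per-section statistic is

    delta-|S21| = | mean(|S21|, baseline) - mean(|S21|, section) |

using magnitude means, and sections are classified SM-rich / POPC-rich by the
nearest published cohort mean in z-score units.

Change points on |S21| are found by binary segmentation on mean shifts with a
BIC-style penalty against the robust noise estimate; runs of consecutive
non-baseline levels are resolved into plateaus (long), transients (short) or
folded multi-level excursions (non-monotone level sequences, the signature of
a membrane folded over itself).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import AnalysisError, InputError

#: default minimum plateau duration, s (half the shortest printed scan time)
MIN_PLATEAU_S = 0.3
#: default detection threshold in units of the baseline |S21| noise sd
SENSITIVITY = 4.0


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ScanTrace:
    """Uniformly sampled complex S21 at a fixed measurement frequency."""

    time_s: np.ndarray
    s21: np.ndarray
    frequency_hz: float
    sample_rate_hz: float
    metadata: dict = dc_field(default_factory=dict)

    def validate(self) -> None:
        t = np.asarray(self.time_s, float)
        if t.size < 2:
            raise InputError("trace needs at least two samples")
        if len(self.s21) != t.size:
            raise InputError("time and s21 arrays must have equal length")
        dt = np.diff(t)
        if np.any(np.abs(dt - dt[0]) > 1e-9 * max(abs(dt[0]), 1e-30)):
            raise InputError("trace must be uniformly sampled")
        if not np.all(np.isfinite(self.s21)):
            raise InputError("trace contains non-finite values")


@dataclass
class Segment:
    start_s: float
    end_s: float
    kind: str  # baseline | plateau | transient | folded
    mean_s21: complex
    delta_magnitude: float = 0.0
    start_index: int = 0
    end_index: int = 0  # exclusive

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class SegmentationResult:
    segments: list
    baseline_mean: float  # mean |s21| over baseline segments
    baseline_sd: float  # sd of |s21| over baseline segments
    deltas: list = dc_field(default_factory=list)  # per non-baseline section
    classifications: list | None = None

    def sections(self, kinds=("plateau", "transient", "folded")):
        return [s for s in self.segments if s.kind in kinds]

    def plateaus(self):
        return self.sections(("plateau",))


@dataclass
class CohortStats:
    """Cohort summary on delta-|S21|: mean, spread and max/min error bars
    (err_plus = max - mean, err_minus = mean - min)."""

    n: int
    mean: float
    sd: float  # population sd (divide by n)
    sd_sample: float  # ddof = 1 (0 for n = 1)
    err_plus: float
    err_minus: float


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def detrend_phase(trace: ScanTrace, theta0_deg: float) -> np.ndarray:
    """Display phase phi = unwrap(angle(s21)) - theta0, in degrees."""
    trace.validate()
    return np.degrees(np.unwrap(np.angle(np.asarray(trace.s21)))) - float(theta0_deg)


def _robust_noise_sd(x: np.ndarray) -> float:
    d = np.diff(x)
    if d.size == 0:
        return 0.0
    return float(np.median(np.abs(d - np.median(d))) / 0.6744897501960817 / np.sqrt(2.0))


def _best_split(x, csum, csum2, lo, hi, min_size):
    """Best single mean-shift split of x[lo:hi]; returns (gain, index)."""
    n = hi - lo
    if n < 2 * min_size:
        return 0.0, -1
    total = csum[hi] - csum[lo]
    total2 = csum2[hi] - csum2[lo]
    sse_full = total2 - total * total / n
    ks = np.arange(lo + min_size, hi - min_size + 1)
    nl = ks - lo
    nr = hi - ks
    sl = csum[ks] - csum[lo]
    sr = total - sl
    sse_split = (csum2[ks] - csum2[lo] - sl * sl / nl) + (total2 - (csum2[ks] - csum2[lo]) - sr * sr / nr)
    i = int(np.argmin(sse_split))
    return float(sse_full - sse_split[i]), int(ks[i])


def _binary_segmentation(x: np.ndarray, penalty: float, min_size: int):
    csum = np.concatenate([[0.0], np.cumsum(x)])
    csum2 = np.concatenate([[0.0], np.cumsum(x * x)])
    breaks = []
    stack = [(0, x.size)]
    while stack:
        lo, hi = stack.pop()
        gain, k = _best_split(x, csum, csum2, lo, hi, min_size)
        if k >= 0 and gain > penalty:
            breaks.append(k)
            stack.append((lo, k))
            stack.append((k, hi))
    return sorted(breaks)


def segment(
    trace: ScanTrace,
    min_plateau_s: float = MIN_PLATEAU_S,
    sensitivity: float = SENSITIVITY,
    min_event_s: float = 0.02,
) -> SegmentationResult:
    """Decompose a scan trace into baseline / plateau / transient / folded parts.

    Change points of mean |s21| are found by binary segmentation with penalty
    ``6 sigma^2 ln n`` (sigma from the robust first-difference estimate);
    adjacent levels closer than ``sensitivity * sigma`` are merged.  Levels
    separated from the baseline by more than that threshold form events: an
    event run shorter than ``min_plateau_s`` is a transient, a run with a
    non-monotone multi-level profile is folded, and remaining long levels are
    plateaus.  A constant trace yields a single baseline segment.
    """
    trace.validate()
    mag = np.abs(np.asarray(trace.s21))
    n = mag.size
    if n < 3 * min_plateau_s * trace.sample_rate_hz:
        raise InputError("trace must be longer than three minimum plateau durations")

    sigma = _robust_noise_sd(mag)
    sigma_eff = max(sigma, 1e-12 * max(np.max(mag), 1.0))
    penalty = 6.0 * sigma_eff**2 * np.log(n)
    min_size = max(2, int(round(min_event_s * trace.sample_rate_hz)))
    breaks = _binary_segmentation(mag, penalty, min_size)
    edges = [0] + breaks + [n]

    # merge adjacent pieces whose mean levels are indistinguishable
    threshold = sensitivity * sigma_eff
    merged = [[edges[0], edges[1]]]
    for lo, hi in zip(edges[1:-1], edges[2:]):
        prev = merged[-1]
        if abs(mag[lo:hi].mean() - mag[prev[0]:prev[1]].mean()) <= threshold:
            prev[1] = hi
        else:
            merged.append([lo, hi])

    # the trace enters at baseline level
    base_level = mag[merged[0][0]:merged[0][1]].mean()
    is_event = [abs(mag[lo:hi].mean() - base_level) > threshold for lo, hi in merged]

    t = np.asarray(trace.time_s, float)
    dt = 1.0 / trace.sample_rate_hz

    def make(lo, hi, kind):
        return Segment(
            start_s=t[lo],
            end_s=t[hi - 1] + dt,
            kind=kind,
            mean_s21=complex(np.mean(np.asarray(trace.s21)[lo:hi])),
            start_index=lo,
            end_index=hi,
        )

    segments = []
    i = 0
    while i < len(merged):
        if not is_event[i]:
            segments.append(make(*merged[i], "baseline"))
            i += 1
            continue
        j = i
        while j < len(merged) and is_event[j]:
            j += 1
        run = merged[i:j]
        run_len = (run[-1][1] - run[0][0]) * dt
        levels = [abs(mag[lo:hi].mean() - base_level) for lo, hi in run]
        if run_len < min_plateau_s:
            segments.append(make(run[0][0], run[-1][1], "transient"))
        elif len(run) >= 2 and not (_monotone(levels)):
            for lo, hi in run:
                segments.append(make(lo, hi, "folded"))
        else:
            for (lo, hi), lev in zip(run, levels):
                kind = "plateau" if (hi - lo) * dt >= min_plateau_s else "transient"
                segments.append(make(lo, hi, kind))
        i = j

    base_segs = [s for s in segments if s.kind == "baseline"]
    base_mag = np.concatenate([mag[s.start_index:s.end_index] for s in base_segs])
    result = SegmentationResult(
        segments=segments,
        baseline_mean=float(base_mag.mean()),
        baseline_sd=float(base_mag.std()),
    )
    result.deltas = section_delta(trace, result)
    return result


def _monotone(levels) -> bool:
    d = np.diff(levels)
    return bool(np.all(d >= 0) or np.all(d <= 0))


def section_delta(trace: ScanTrace, result: SegmentationResult) -> list:
    """delta-|S21| per non-baseline section: |mean(|s21|, baseline) -
    mean(|s21|, section)|, stored on the segments and returned in time order."""
    base_segs = [s for s in result.segments if s.kind == "baseline"]
    if not base_segs:
        raise AnalysisError("no baseline segment; cannot form delta-|S21|")
    mag = np.abs(np.asarray(trace.s21))
    base = float(np.concatenate([mag[s.start_index:s.end_index] for s in base_segs]).mean())
    deltas = []
    for s in result.segments:
        if s.kind == "baseline":
            s.delta_magnitude = 0.0
            continue
        s.delta_magnitude = float(abs(base - mag[s.start_index:s.end_index].mean()))
        deltas.append(s.delta_magnitude)
    return deltas


def classify(delta: float, frequency_hz: float, reference=None) -> str:
    """'SM-rich' / 'POPC-rich' / 'ambiguous' by nearest published cohort mean
    in z-score units; within 0.5 z of a tie the call is ambiguous."""
    if reference is None:
        from .synth import presets

        reference = presets()
    try:
        sm = reference.delta_stats("SM", frequency_hz)
        popc = reference.delta_stats("POPC", frequency_hz)
    except KeyError as exc:
        raise InputError(f"no reference entries at {frequency_hz} Hz") from exc
    z_sm = abs(delta - sm[0]) / sm[1]
    z_popc = abs(delta - popc[0]) / popc[1]
    if abs(z_sm - z_popc) < 0.5:
        return "ambiguous"
    return "SM-rich" if z_sm < z_popc else "POPC-rich"


def classify_sections(trace: ScanTrace, result: SegmentationResult, reference=None) -> list:
    labels = [
        classify(s.delta_magnitude, trace.frequency_hz, reference)
        for s in result.segments
        if s.kind != "baseline"
    ]
    result.classifications = labels
    return labels


def cohort_stats(deltas) -> CohortStats:
    """Cohort mean, sd and max/min error bars of a list of delta-|S21|."""
    arr = np.asarray(list(deltas), float)
    if arr.size == 0:
        raise InputError("empty cohort")
    mu = float(arr.mean())
    return CohortStats(
        n=int(arr.size),
        mean=mu,
        sd=float(arr.std(ddof=0)),
        sd_sample=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        # the float mean can overshoot max/min by one ulp; the bars are >= 0
        err_plus=max(float(arr.max() - mu), 0.0),
        err_minus=max(float(mu - arr.min()), 0.0),
    )


def cohort_deltas(trace_list, skip_undetected: bool = True) -> list:
    """Per-trace dominant-plateau delta-|S21| over a cohort of traces.

    A GUV whose plateau stays below the detection threshold cannot be
    measured; with ``skip_undetected`` such traces are dropped (as in the
    experiment, where only detectable GUVs enter a cohort), otherwise an
    :class:`AnalysisError` propagates.
    """
    deltas = []
    for tr in trace_list:
        try:
            deltas.append(primary_delta(segment(tr)))
        except AnalysisError:
            if not skip_undetected:
                raise
    if not deltas:
        raise AnalysisError("no trace in the cohort shows a detectable plateau")
    return deltas


def primary_delta(result: SegmentationResult) -> float:
    """delta-|S21| of the dominant (longest) plateau of a single-GUV trace."""
    plateaus = result.plateaus()
    if not plateaus:
        raise AnalysisError("no plateau found in trace")
    return max(plateaus, key=lambda s: s.duration_s).delta_magnitude
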