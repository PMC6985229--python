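"""Spike detection and coupling-strength sweeps.

A spike is an action-potential peak: a local maximum of the membrane
potential at or above ``peak_threshold`` (default 0 mV -- rest sits near
-65 mV and healthy action potentials overshoot 0 mV, so 0 separates spikes
from subthreshold wiggles robustly).  Candidate peaks closer together than
``min_separation`` (default 2 ms) are greedily thinned, higher peak first,
so a slow shoulder riding on a spike is not double-counted.  The spike time
is the grid time of the maximum sample, with no sub-grid interpolation: at
the default 0.01 ms step the grid already matches the reporting precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pair_sim import PairConfig, simulate_pair

__all__ = [
    "SpikeEvent",
    "SpikeSummary",
    "SweepResult",
    "detect_spikes",
    "first_spike_time",
    "relative_error",
    "sweep_gsyn",
]


@dataclass(frozen=True)
class SpikeEvent:
    """One detected action-potential peak."""

    peak_time: float  # ms, grid time of the maximum sample
    peak_value: float  # mV, absolute peak potential
    amplitude_above_rest: float  # mV, peak minus resting potential


@dataclass(frozen=True)
class SpikeSummary:
    """Time-ordered spike events of one voltage trace."""

    events: tuple[SpikeEvent, ...]

    @property
    def count(self) -> int:
        return len(self.events)


def detect_spikes(
    t: np.ndarray,
    v: np.ndarray,
    peak_threshold: float = 0.0,
    min_separation: float = 2.0,
    v_rest: float = -65.0,
) -> SpikeSummary:
    """Detect action-potential peaks in the series ``v(t)``.

    Local maxima (``v[i-1] <= v[i] > v[i+1]``, interior samples only) with
    value >= ``peak_threshold`` are candidates; candidates are kept
    greedily in order of descending height (ties broken by earlier time),
    discarding any candidate within ``min_separation`` ms of an already
    kept peak.  Amplitudes are reported both as the absolute peak value
    and relative to ``v_rest``, since the natural baseline depends on the
    question being asked.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if len(t) != len(v) or len(t) == 0:
        raise ValueError("t and v must be equal-length, non-empty arrays")
    if min_separation < 0:
        raise ValueError(f"min_separation must be >= 0, got {min_separation}")

    interior = np.arange(1, len(v) - 1)
    mask = (v[interior] >= v[interior - 1]) & (v[interior] > v[interior + 1])
    mask &= v[interior] >= peak_threshold
    cand = interior[mask]

    kept_times: list[float] = []
    kept: list[SpikeEvent] = []
    for i in sorted(cand, key=lambda i: (-v[i], t[i])):
        ti = float(t[i])
        if all(abs(ti - tk) >= min_separation for tk in kept_times):
            kept_times.append(ti)
            kept.append(SpikeEvent(ti, float(v[i]), float(v[i] - v_rest)))
    kept.sort(key=lambda e: e.peak_time)
    return SpikeSummary(tuple(kept))


def first_spike_time(summary: SpikeSummary) -> float | None:
    """Time of the earliest spike, or ``None`` if the trace has none."""
    if not summary.events:
        return None
    return summary.events[0].peak_time


def relative_error(reference: float, value: float) -> float:
    """``|reference - value| / |reference| * 100`` (percent)."""
    if reference == 0 or not math.isfinite(reference):
        raise ValueError("relative_error needs a finite, non-zero reference")
    return abs(reference - value) / abs(reference) * 100.0


@dataclass
class SweepResult:
    """Posterior-neuron spike summaries across coupling strengths."""

    weights: tuple[float, ...]
    summaries: tuple[SpikeSummary, ...]

    def first_spike_times(self) -> list[float | None]:
        return [first_spike_time(s) for s in self.summaries]

    def spike_counts(self) -> list[int]:
        return [s.count for s in self.summaries]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for w, s in zip(self.weights, self.summaries):
            ev = s.events
            rows.append(
                {
                    "g_syn": w,
                    "n_spikes": s.count,
                    "first_spike_time_ms": ev[0].peak_time if len(ev) > 0 else None,
                    "first_peak_mV": ev[0].peak_value if len(ev) > 0 else None,
                    "second_spike_time_ms": ev[1].peak_time if len(ev) > 1 else None,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def sweep_gsyn(
    template: PairConfig,
    weights,
    peak_threshold: float = 0.0,
    min_separation: float = 2.0,
) -> SweepResult:
    """Re-run the pair simulation for each coupling strength in ``weights``.

    Everything but ``g_syn`` is held fixed.  Weights must be non-negative
    and strictly increasing.  The posterior neuron's voltage trace is spike-
    detected per weight; the first-spike-time curve and spike counts come
    from the returned summaries.
    """
    weights = tuple(float(w) for w in weights)
    if any(w < 0 for w in weights):
        raise ValueError("weights must be non-negative")
    if any(b <= a for a, b in zip(weights, weights[1:])):
        raise ValueError("weights must be strictly increasing")

    summaries = []
    for w in weights:
        traj = simulate_pair(template.with_weight(w))
        summaries.append(
            detect_spikes(
                traj.t,
                traj.post.V,
                peak_threshold=peak_threshold,
                min_separation=min_separation,
                v_rest=template.post_params.V_rest,
            )
        )
    return SweepResult(weights, tuple(summaries))
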