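"""Evoked-response magnitudes and spontaneous rates.

Mechanical response magnitude is the stimulus-evoked firing rate
normalized to the spontaneous rate and divided by the integral of the
applied force (g*s), so stronger pokes do not masquerade as stronger
neurons.  "Normalized" admits two readings: the default *subtract* mode
``(evoked - spontaneous) / integral`` stays finite for the sizeable
fraction of units with zero spontaneous firing; *ratio* mode divides by
the spontaneous rate with a floored denominator.  Thermal magnitude is a
rate ratio against the PSTH baseline mean.  Every output records the mode
used.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AnalysisConfig, SpikeTrain, ValidationError
from .psth import Psth, build_psth

logger = logging.getLogger("pbspike")


@dataclass
class ResponseMagnitude:
    unit_id: str
    site: str
    modality: str
    spontaneous_rate: float
    evoked_rate: float
    force_integral: float  # g*s; nan for thermal
    magnitude: float
    mode: str
    degenerate_baseline: bool = False


def spontaneous_rate(train: SpikeTrain, quiet_intervals) -> float:
    """Total spikes in the quiet intervals divided by total quiet time (Hz)."""
    total_time = 0.0
    total_spikes = 0
    for start, end in quiet_intervals:
        if end <= start:
            continue
        total_time += end - start
        total_spikes += int(
            np.count_nonzero(
                (train.spike_times >= start) & (train.spike_times < end)
            )
        )
    if total_time <= 0:
        raise ValidationError("quiet intervals contain no time")
    return total_spikes / total_time


def quiet_intervals(events, duration: float, pad_after: float = 10.0) -> list:
    """Complement of the stimulus windows and their post-offset scan pads."""
    busy = sorted((e.onset, e.offset + pad_after) for e in events)
    out = []
    cursor = 0.0
    for a, b in busy:
        if a > cursor:
            out.append((cursor, min(a, duration)))
        cursor = max(cursor, b)
    if cursor < duration:
        out.append((cursor, duration))
    return out


def force_integral(trace) -> float:
    """Trapezoidal integral (g*s) of a (time, force) trace."""
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[0] < 2:
        raise ValidationError("force trace needs at least 2 samples")
    return float(np.trapezoid(trace[:, 1], trace[:, 0]))


def evoked_rate(train: SpikeTrain, events) -> float:
    """Across-trial mean firing rate during the stimulus windows (Hz)."""
    rates = [
        np.count_nonzero(
            (train.spike_times >= e.onset) & (train.spike_times < e.offset)
        )
        / e.duration
        for e in events
    ]
    return float(np.mean(rates))


def mechanical_magnitude(
    evoked_rate_hz: float,
    spontaneous_rate_hz: float,
    force_integral_gs: float,
    mode: str = "subtract",
    ratio_floor_hz: float = 0.1,
) -> float:
    """Force-normalized mechanical response magnitude.

    ``subtract``: ``(evoked - spontaneous) / integral`` (Hz per g*s).
    ``ratio``: ``(evoked / max(spontaneous, floor)) / integral``; the
    floor (default 0.1 Hz, one spike per 10 s) guards silent baselines and
    is logged when it engages.
    """
    if force_integral_gs <= 0:
        raise ValidationError("force integral must be > 0")
    if mode == "subtract":
        return (evoked_rate_hz - spontaneous_rate_hz) / force_integral_gs
    if mode == "ratio":
        denom = max(spontaneous_rate_hz, ratio_floor_hz)
        if spontaneous_rate_hz < ratio_floor_hz:
            logger.info(
                "ratio-mode floor %.3g Hz engaged (spontaneous %.3g Hz)",
                ratio_floor_hz,
                spontaneous_rate_hz,
            )
        return (evoked_rate_hz / denom) / force_integral_gs
    raise ValidationError(f"unknown normalization mode {mode!r}")


def thermal_magnitude(psth: Psth, config: AnalysisConfig) -> tuple:
    """(magnitude, degenerate_flag) for a thermal-trial PSTH.

    Default is the rate ratio ``mean in-stimulus rate / baseline mean``
    (a non-responding unit scores ~1); subtract mode returns the rate
    difference in Hz.  A silent baseline engages the ratio floor and sets
    the degeneracy flag.
    """
    stim_rate = float(psth.mean_rate_per_bin[psth.stim_mask].mean())
    if config.normalization_mode == "subtract":
        return stim_rate - psth.baseline_mean, False
    degenerate = psth.baseline_mean < config.ratio_floor_hz
    denom = max(psth.baseline_mean, config.ratio_floor_hz)
    if degenerate:
        logger.info("thermal ratio floor engaged (baseline %.3g Hz)", psth.baseline_mean)
    return stim_rate / denom, degenerate


def response_table(session, config: AnalysisConfig) -> pd.DataFrame:
    """One row per unit x site x modality with all magnitude fields."""
    groups = {}
    for e in session.events:
        groups.setdefault((e.site, e.modality), []).append(e)
    rows = []
    for unit in session.units:
        quiet = quiet_intervals(
            session.events, unit.duration, pad_after=config.rebound_scan_window
        )
        spont = spontaneous_rate(unit, quiet)
        for (site, modality), evs in sorted(groups.items()):
            ev_rate = evoked_rate(unit, evs)
            if modality == "mechanical":
                integral = float(
                    np.mean([force_integral(e.force_trace) for e in evs])
                )
                mag = mechanical_magnitude(
                    ev_rate,
                    spont,
                    integral,
                    mode=config.normalization_mode,
                    ratio_floor_hz=config.ratio_floor_hz,
                )
                degenerate = False
            else:
                window = (
                    config.baseline_window,
                    evs[0].duration + config.rebound_scan_window,
                )
                psth = build_psth(unit, evs, window, config)
                # thermal default is the rate ratio: ~1 for weak responses
                cfg = dataclasses.replace(config, normalization_mode="ratio")
                mag, degenerate = thermal_magnitude(psth, cfg)
                integral = float("nan")
            rows.append(
                {
                    "unit_id": unit.unit_id,
                    "site": site,
                    "modality": modality,
                    "spontaneous_rate_hz": spont,
                    "evoked_rate_hz": ev_rate,
                    "force_integral_gs": integral,
                    "magnitude": mag,
                    "mode": (
                        config.normalization_mode
                        if modality == "mechanical"
                        else "ratio"
                    ),
                    "degenerate_baseline": degenerate,
                }
            )
    return pd.DataFrame(rows)
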