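"""Core domain types, analysis configuration, and session manifest I/O.

A recording *session* bundles sorted single-unit spike trains with the
stimulus events applied during the recording.  Spike times are seconds from
recording start; stimulus windows are half-open ``[onset, offset)`` so a
spike falling exactly on a boundary is counted once, in the bin to its
right.

Sessions are serialized as plain text: one spike-time file per unit, a
delimited event table, an optional force-trace file per mechanical event,
and a YAML manifest tying them together.  Proprietary acquisition formats
are out of scope; any system that can export timestamps can produce these
files.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("pbspike")

MODALITIES = ("mechanical", "thermal")
SITES = ("face_ipsi", "face_contra", "hindpaw_ipsi", "hindpaw_contra")
CONDITIONS = ("sham", "cci_ion")

#: Minimum spacing (s) between stimulus offset and the next onset.
MIN_INTER_STIMULUS_S = 8.0


class ValidationError(ValueError):
    """A domain invariant was violated."""


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike timestamps of one unit over one recording.

    Parameters
    ----------
    unit_id:
        Identifier of the sorted unit.
    spike_times:
        Non-decreasing spike times in seconds from recording start,
        all within ``[0, duration]``.
    duration:
        Total recorded duration in seconds (> 0).
    region_label:
        Free-text anatomical label (e.g. ``"lateral PB"``).
    """

    unit_id: str
    spike_times: np.ndarray
    duration: float
    region_label: str = ""

    def __post_init__(self):
        times = _as_float_array(self.spike_times)
        object.__setattr__(self, "spike_times", times)
        if not self.duration > 0:
            raise ValidationError(f"unit {self.unit_id}: duration must be > 0")
        if times.ndim != 1:
            raise ValidationError(f"unit {self.unit_id}: spike_times must be 1-D")
        if times.size:
            if np.any(np.diff(times) < 0):
                raise ValidationError(
                    f"unit {self.unit_id}: spike times are not sorted"
                )
            if times[0] < 0 or times[-1] > self.duration:
                raise ValidationError(
                    f"unit {self.unit_id}: spike times outside [0, duration]"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def mean_rate(self) -> float:
        return self.n_spikes / self.duration


@dataclass(frozen=True)
class StimulusEvent:
    """One stimulus application.

    ``force_trace`` is a ``(n, 2)`` array of ``(time_s, force_g)`` samples
    and is present exactly when ``modality == "mechanical"``; thermal events
    may carry laser duty-cycle parameters instead.
    """

    onset: float
    offset: float
    modality: str
    site: str
    force_trace: Optional[np.ndarray] = None
    laser_params: Optional[dict] = None

    def __post_init__(self):
        if not self.offset > self.onset:
            raise ValidationError(
                f"event at {self.onset}: offset must exceed onset"
            )
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        if self.site not in SITES:
            raise ValidationError(f"unknown site {self.site!r}")
        if self.modality == "mechanical":
            if self.force_trace is None:
                raise ValidationError(
                    "mechanical event requires a force_trace"
                )
            trace = _as_float_array(self.force_trace)
            if trace.ndim != 2 or trace.shape[1] != 2:
                raise ValidationError("force_trace must be (n, 2): time, grams")
            if np.any(trace[:, 1] < 0):
                raise ValidationError("force samples must be non-negative")
            object.__setattr__(self, "force_trace", trace)
        elif self.force_trace is not None:
            raise ValidationError("force_trace only valid for mechanical events")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class AnalysisConfig:
    """Fixed constants and knobs of the detection pipeline.

    The response criterion compares PSTH bin rates to a 99% confidence band
    of the baseline rate; after-discharges must last at least 500 ms past
    stimulus offset; suppression is tested against the 5 s pre-stimulus
    window.  Those three constants are the method's definition and default
    accordingly; ``ad_min_duration`` is snapped to a whole number of bins.
    """

    bin_width: float = 0.1
    baseline_window: float = 5.0
    ci_level: float = 0.99
    ad_min_duration: float = 0.5
    rebound_scan_window: float = 10.0
    suppression_alpha: float = 0.05
    normalization_mode: str = "subtract"  # or "ratio"
    baseline_band_mode: str = "normal"  # or "poisson_exact"
    ad_gap_bins: int = 0
    ratio_floor_hz: float = 0.1
    rng_seed: int = 0

    def __post_init__(self):
        if not self.bin_width > 0:
            raise ValidationError("bin_width must be > 0")
        if not 0 < self.ci_level < 1:
            raise ValidationError("ci_level must be in (0, 1)")
        if self.normalization_mode not in ("subtract", "ratio"):
            raise ValidationError("normalization_mode must be subtract|ratio")
        if self.baseline_band_mode not in ("normal", "poisson_exact"):
            raise ValidationError("baseline_band_mode must be normal|poisson_exact")
        if self.bin_width > self.ad_min_duration + 1e-12:
            raise ValidationError("bin_width must not exceed ad_min_duration")
        snapped = max(1, round(self.ad_min_duration / self.bin_width)) * self.bin_width
        if not math.isclose(snapped, self.ad_min_duration, rel_tol=0, abs_tol=1e-9):
            logger.warning(
                "ad_min_duration %.4g s snapped to %.4g s (multiple of bin_width)",
                self.ad_min_duration,
                snapped,
            )
        self.ad_min_duration = snapped

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class Session:
    """All units and stimulus events of one animal's recording."""

    animal_id: str
    condition: str
    units: list
    events: list
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        max_offset = max((e.offset for e in self.events), default=0.0)
        for u in self.units:
            if max_offset > u.duration + 1e-9:
                raise ValidationError(
                    f"event extends past duration of unit {u.unit_id}"
                )
        ordered = sorted(self.events, key=lambda e: e.onset)
        for a, b in zip(ordered, ordered[1:]):
            if b.onset - a.offset < MIN_INTER_STIMULUS_S - 1e-9:
                raise ValidationError(
                    f"events at {a.onset:.3f} and {b.onset:.3f} violate the "
                    f">= {MIN_INTER_STIMULUS_S:g} s inter-stimulus spacing"
                )


# ---------------------------------------------------------------------------
# Manifest I/O
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"  # full double precision round trip


def write_session(session: Session, out_dir) -> Path:
    """Write a session to ``out_dir`` and return the manifest path.

    Layout: ``manifest.yaml``, ``events.csv``, ``spikes/<unit>.txt`` (one
    timestamp per line), and ``forces/event_<k>.csv`` per mechanical event.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "spikes").mkdir(exist_ok=True)

    unit_entries = []
    for u in session.units:
        rel = f"spikes/{u.unit_id}.txt"
        with open(out / rel, "w") as fh:
            for t in u.spike_times:
                fh.write((_FLOAT_FMT % t) + "\n")
        unit_entries.append(
            {
                "unit_id": u.unit_id,
                "spike_file": rel,
                "duration": float(u.duration),
                "region_label": u.region_label,
            }
        )

    rows = []
    any_force = any(e.force_trace is not None for e in session.events)
    if any_force:
        (out / "forces").mkdir(exist_ok=True)
    for k, e in enumerate(session.events):
        force_file = ""
        if e.force_trace is not None:
            force_file = f"forces/event_{k}.csv"
            pd.DataFrame(e.force_trace, columns=["time", "force"]).to_csv(
                out / force_file, index=False, float_format=_FLOAT_FMT
            )
        lp = e.laser_params or {}
        rows.append(
            {
                "onset": e.onset,
                "offset": e.offset,
                "modality": e.modality,
                "site": e.site,
                "force_file": force_file,
                "duty_on": lp.get("duty_on", ""),
                "duty_off": lp.get("duty_off", ""),
                "power": lp.get("power", ""),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "onset", "offset", "modality", "site",
            "force_file", "duty_on", "duty_off", "power",
        ],
    ).to_csv(out / "events.csv", index=False, float_format=_FLOAT_FMT)

    manifest = {
        "animal_id": session.animal_id,
        "condition": session.condition,
        "units": unit_entries,
        "events_file": "events.csv",
        "metadata": session.metadata,
    }
    manifest_path = out / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path


def read_session(manifest_path) -> Session:
    """Read and fully validate a session written by :func:`write_session`."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    base = manifest_path.parent
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)

    units = []
    for entry in manifest.get("units", []):
        spike_path = base / entry["spike_file"]
        if not spike_path.exists():
            raise FileNotFoundError(f"spike file not found: {spike_path}")
        with open(spike_path) as fh:
            times = np.array([float(line) for line in fh if line.strip()])
        units.append(
            SpikeTrain(
                unit_id=str(entry["unit_id"]),
                spike_times=times,
                duration=float(entry["duration"]),
                region_label=entry.get("region_label", "") or "",
            )
        )
        logger.debug("read unit %s: %d spikes", entry["unit_id"], times.size)

    events = []
    events_file = manifest.get("events_file")
    if events_file:
        events_path = base / events_file
        if not events_path.exists():
            raise FileNotFoundError(f"event table not found: {events_path}")
        table = pd.read_csv(
            events_path, keep_default_na=False, float_precision="round_trip"
        )
        for _, row in table.iterrows():
            force = None
            if row.get("force_file", ""):
                fpath = base / row["force_file"]
                if not fpath.exists():
                    raise FileNotFoundError(f"force trace not found: {fpath}")
                force = pd.read_csv(fpath, float_precision="round_trip")[
                    ["time", "force"]
                ].to_numpy()
            laser = None
            if str(row.get("power", "")) != "":
                laser = {
                    "duty_on": float(row["duty_on"]),
                    "duty_off": float(row["duty_off"]),
                    "power": float(row["power"]),
                }
            events.append(
                StimulusEvent(
                    onset=float(row["onset"]),
                    offset=float(row["offset"]),
                    modality=str(row["modality"]),
                    site=str(row["site"]),
                    force_trace=force,
                    laser_params=laser,
                )
            )

    return Session(
        animal_id=str(manifest.get("animal_id", "")),
        condition=str(manifest.get("condition", "")),
        units=units,
        events=events,
        metadata=manifest.get("metadata", {}) or {},
    )


def sessions_equal(a: Session, b: Session) -> bool:
    """Field-by-field equality, used by round-trip tests."""
    if (a.animal_id, a.condition) != (b.animal_id, b.condition):
        return False
    if len(a.units) != len(b.units) or len(a.events) != len(b.events):
        return False
    for ua, ub in zip(a.units, b.units):
        if ua.unit_id != ub.unit_id or ua.duration != ub.duration:
            return False
        if ua.region_label != ub.region_label:
            return False
        if not np.array_equal(ua.spike_times, ub.spike_times):
            return False
    for ea, eb in zip(a.events, b.events):
        if (ea.onset, ea.offset, ea.modality, ea.site) != (
            eb.onset, eb.offset, eb.modality, eb.site,
        ):
            return False
        if (ea.force_trace is None) != (eb.force_trace is None):
            return False
        if ea.force_trace is not None and not np.array_equal(
            ea.force_trace, eb.force_trace
        ):
            return False
        if (ea.laser_params or {}) != (eb.laser_params or {}):
            return False
    return a.metadata == b.metadata
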