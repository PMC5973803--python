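"""Synthetic spike trains, stimulus protocols, force traces, and up-down
behavioral sequences.

The generator emulates extracellular recordings from nociceptive
parabrachial neurons under light anesthesia: low spontaneous rates
(0–5 Hz) with a sizeable "silent" fraction, 3 s cutaneous stimuli spaced
at least 8 s apart, stimulus-evoked rate elevations, after-discharges that
outlast the stimulus by up to a few seconds, and a minority of OFF-cells
whose firing is suppressed during the stimulus and may rebound after it.

Spikes are drawn from an inhomogeneous Poisson process with a
piecewise-constant rate, sampled exactly by exponential inter-arrival
times restarted at each rate breakpoint (valid by memorylessness).  Every
simulated unit carries its generating :class:`NeuronProfile` in the
session metadata so detection accuracy can be asserted against ground
truth.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from .core import (
    Session,
    SpikeTrain,
    StimulusEvent,
    ValidationError,
)

logger = logging.getLogger("pbspike")

RESPONSE_CLASSES = ("excited", "suppressed", "nonresponsive")


@dataclass(frozen=True)
class NeuronProfile:
    """Ground-truth firing model of one simulated unit.

    Rates are Hz.  ``ad_duration``/``ad_rate`` describe the after-discharge
    appended to each stimulus offset of an excited unit; ``rebound_*`` the
    post-offset burst of a suppressed unit.  ``ad_shape`` is ``rectangular``
    (constant ``ad_rate`` for ``ad_duration``, so the true duration is
    sharply defined) or ``exponential`` (decay from ``ad_rate`` back to
    baseline with time constant ``ad_duration / 3``).
    """

    baseline_rate: float
    response_class: str = "excited"
    evoked_gain: float = 0.0
    ad_duration: float = 0.0
    ad_rate: float = 0.0
    suppression_fraction: float = 0.0
    rebound_duration: float = 0.0
    rebound_rate: float = 0.0
    ad_shape: str = "rectangular"

    def __post_init__(self):
        if self.baseline_rate < 0:
            raise ValidationError("baseline_rate must be >= 0")
        if self.response_class not in RESPONSE_CLASSES:
            raise ValidationError(f"unknown response_class {self.response_class!r}")
        if self.response_class == "suppressed" and not (
            0 <= self.suppression_fraction < 1
        ):
            raise ValidationError("suppression_fraction must be in [0, 1)")
        if self.response_class == "nonresponsive" and self.ad_duration != 0:
            raise ValidationError("nonresponsive units cannot have an after-discharge")
        if min(self.evoked_gain + self.baseline_rate, self.ad_rate,
               self.rebound_rate, self.ad_duration, self.rebound_duration) < 0:
            raise ValidationError("negative rate or duration in profile")
        if self.ad_shape not in ("rectangular", "exponential"):
            raise ValidationError("ad_shape must be rectangular|exponential")


@dataclass
class StimulusProtocol:
    """Stimulation schedule applied to every simulated unit.

    Five repetitions per modality/site combination, 3 s stimuli, and an
    inter-stimulus interval long enough both to satisfy the >= 8 s rule
    and to let the 5 s baseline and post-offset scan windows of successive
    trials stay disjoint (extended further when after-discharges are long).
    """

    modalities: Sequence[str] = ("mechanical",)
    sites: Sequence[str] = ("face_ipsi",)
    n_repeats: int = 5
    stim_duration: float = 3.0
    isi: float = 16.0
    lead_in: float = 10.0
    force_peak: float = 15.0
    force_rise: float = 0.5
    force_sample_rate: float = 100.0
    force_noise_sd: float = 0.3
    laser_params: dict = field(
        default_factory=lambda: {"duty_on": 0.03, "duty_off": 0.03, "power": 2.0}
    )

    def __post_init__(self):
        if self.isi < 8.0:
            raise ValidationError("inter-stimulus interval must be >= 8 s")


def build_events(
    protocol: StimulusProtocol, seed: int, extra_isi: float = 0.0
) -> tuple[list, float]:
    """Lay out the protocol's events on a timeline.

    Returns ``(events, total_duration)``.  ``extra_isi`` lengthens every
    interval (used when a unit's after-discharge is long).  Mechanical
    events get a simulated aesthesiometer force trace.
    """
    rng = np.random.default_rng(seed)
    events = []
    t = protocol.lead_in
    isi = protocol.isi + extra_isi
    for modality in protocol.modalities:
        for rep in range(protocol.n_repeats):
            for site in protocol.sites:
                force = None
                laser = None
                if modality == "mechanical":
                    trace = simulate_force_trace(
                        peak=protocol.force_peak,
                        duration=protocol.stim_duration,
                        rise_time=protocol.force_rise,
                        sample_rate=protocol.force_sample_rate,
                        noise_sd=protocol.force_noise_sd,
                        seed=int(rng.integers(2**31)),
                    )
                    force = np.column_stack([trace[:, 0] + t, trace[:, 1]])
                else:
                    laser = dict(protocol.laser_params)
                events.append(
                    StimulusEvent(
                        onset=t,
                        offset=t + protocol.stim_duration,
                        modality=modality,
                        site=site,
                        force_trace=force,
                        laser_params=laser,
                    )
                )
                t += protocol.stim_duration + isi
    return events, t


# ---------------------------------------------------------------------------
# Point-process sampling
# ---------------------------------------------------------------------------

def _rate_segments(profile: NeuronProfile, events, duration: float):
    """Piecewise-constant rate breakpoints over [0, duration)."""
    segs = []  # (t0, t1, rate)
    cursor = 0.0
    for e in sorted(events, key=lambda e: e.onset):
        if e.onset > cursor:
            segs.append((cursor, e.onset, profile.baseline_rate))
        if profile.response_class == "excited":
            stim_rate = profile.baseline_rate + profile.evoked_gain
        elif profile.response_class == "suppressed":
            stim_rate = profile.baseline_rate * profile.suppression_fraction
        else:
            stim_rate = profile.baseline_rate
        segs.append((e.onset, e.offset, stim_rate))
        cursor = e.offset
        if profile.response_class == "excited" and profile.ad_duration > 0:
            ad_end = min(e.offset + profile.ad_duration, duration)
            if profile.ad_shape == "rectangular":
                segs.append((e.offset, ad_end, profile.ad_rate))
            else:
                # exponential decay discretized into thin exact slices
                tau = profile.ad_duration / 3.0
                n_slices = max(20, int(profile.ad_duration / 0.01))
                edges = np.linspace(e.offset, ad_end, n_slices + 1)
                mids = 0.5 * (edges[:-1] + edges[1:]) - e.offset
                rates = profile.baseline_rate + (
                    profile.ad_rate - profile.baseline_rate
                ) * np.exp(-mids / tau)
                segs.extend(zip(edges[:-1], edges[1:], rates))
            cursor = ad_end
        elif profile.response_class == "suppressed" and profile.rebound_duration > 0:
            rb_end = min(e.offset + profile.rebound_duration, duration)
            segs.append((e.offset, rb_end, profile.rebound_rate))
            cursor = rb_end
    if cursor < duration:
        segs.append((cursor, duration, profile.baseline_rate))
    return segs


def simulate_spike_train(
    profile: NeuronProfile,
    events,
    duration: float,
    seed: int,
    unit_id: str = "sim",
) -> SpikeTrain:
    """Draw one inhomogeneous-Poisson spike train.

    Exponential inter-arrival sampling within each piecewise-constant rate
    segment; identical ``seed`` and inputs give an identical train.
    """
    for e in events:
        if e.onset < 0 or e.offset > duration + 1e-9:
            raise ValidationError("event outside [0, duration]")
    rng = np.random.default_rng(seed)
    times = []
    for t0, t1, rate in _rate_segments(profile, events, duration):
        if rate < 0:
            raise ValidationError("profile produced a negative rate")
        if rate == 0 or t1 <= t0:
            continue
        t = t0
        while True:
            n = max(16, int(rate * (t1 - t) * 1.5) + 8)
            arr = t + np.cumsum(rng.exponential(1.0 / rate, size=n))
            inside = arr[arr < t1]
            times.append(inside)
            if inside.size < arr.size:
                break
            t = arr[-1]
    spikes = (
        np.sort(np.concatenate(times)) if times else np.empty(0, dtype=float)
    )
    return SpikeTrain(unit_id=unit_id, spike_times=spikes, duration=duration)


# ---------------------------------------------------------------------------
# Population generator
# ---------------------------------------------------------------------------

@dataclass
class PopulationSpec:
    """Sampling distribution of a simulated group of PB neurons.

    ``ad_incidence`` is the marginal probability that a tactile-responsive
    unit carries an after-discharge; ``off_cell_fraction`` the marginal
    probability of the suppressed (OFF-cell) class; ``silent_fraction`` the
    probability of zero spontaneous rate.  After-discharge units are always
    excited; the suppressed class is drawn from the non-AD remainder at
    ``off_cell_fraction / (1 - ad_incidence)`` so both marginals hold
    exactly.
    """

    n_neurons: int
    condition: str = "cci_ion"
    ad_incidence: float = 0.0
    ad_duration_dist: tuple = ("uniform", 0.5, 3.0)
    silent_fraction: float = 0.0
    off_cell_fraction: float = 0.0
    nonresponsive_fraction: float = 0.0
    baseline_median: float = 1.9
    baseline_sigma_log: float = 0.8
    baseline_max: float = 5.0
    evoked_gain: float = 60.0
    ad_rate: float = 60.0
    suppression_fraction: float = 0.1
    rebound_incidence: float = 0.5
    rebound_duration_dist: tuple = ("uniform", 1.0, 3.0)
    rebound_rate: float = 60.0

    def __post_init__(self):
        if self.n_neurons < 1:
            raise ValidationError("n_neurons must be >= 1")
        for name in (
            "ad_incidence", "silent_fraction", "off_cell_fraction",
            "nonresponsive_fraction", "rebound_incidence",
        ):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.ad_incidence < 1 and (
            self.off_cell_fraction / (1 - self.ad_incidence) > 1
        ):
            raise ValidationError(
                "off_cell_fraction incompatible with ad_incidence"
            )


#: Group-level presets mirroring the sham and nerve-injured study arms:
#: after-discharge incidence 13.6% vs 51.2%, silent fraction 11% vs 25%,
#: OFF-cell fraction 3/22 vs 11/43, spontaneous-rate medians 1.595 vs
#: 1.912 Hz.
PRESETS = {
    "sham_like": dict(
        condition="sham",
        ad_incidence=0.136,
        silent_fraction=0.11,
        off_cell_fraction=3 / 22,
        baseline_median=1.595,
    ),
    "cci_like": dict(
        condition="cci_ion",
        ad_incidence=0.512,
        silent_fraction=0.25,
        off_cell_fraction=11 / 43,
        baseline_median=1.912,
    ),
}


def preset_spec(name: str, n_neurons: int, **overrides) -> PopulationSpec:
    """A :class:`PopulationSpec` from a named condition preset."""
    if name not in PRESETS:
        raise ValidationError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return PopulationSpec(n_neurons=n_neurons, **kwargs)


def _draw(dist: tuple, rng) -> float:
    name, *params = dist
    if name == "uniform":
        return float(rng.uniform(params[0], params[1]))
    if name == "lognormal":  # params: (median, sigma_log)
        return float(params[0] * np.exp(rng.normal(0.0, params[1])))
    if name == "constant":
        return float(params[0])
    raise ValidationError(f"unknown distribution {name!r}")


def sample_profile(spec: PopulationSpec, rng) -> NeuronProfile:
    """Draw one ground-truth neuron profile from the population spec."""
    if rng.random() < spec.silent_fraction:
        baseline = 0.0
    else:
        baseline = min(
            spec.baseline_median * np.exp(rng.normal(0.0, spec.baseline_sigma_log)),
            spec.baseline_max,
        )
    if rng.random() < spec.nonresponsive_fraction:
        return NeuronProfile(baseline_rate=baseline, response_class="nonresponsive")
    has_ad = rng.random() < spec.ad_incidence
    if has_ad:
        return NeuronProfile(
            baseline_rate=baseline,
            response_class="excited",
            evoked_gain=spec.evoked_gain,
            ad_duration=_draw(spec.ad_duration_dist, rng),
            ad_rate=spec.ad_rate,
        )
    p_off = (
        spec.off_cell_fraction / (1 - spec.ad_incidence)
        if spec.ad_incidence < 1
        else 0.0
    )
    if rng.random() < p_off:
        rebound = rng.random() < spec.rebound_incidence
        return NeuronProfile(
            baseline_rate=max(baseline, 1.0),  # an OFF-cell must fire to suppress
            response_class="suppressed",
            suppression_fraction=spec.suppression_fraction,
            rebound_duration=_draw(spec.rebound_duration_dist, rng) if rebound else 0.0,
            rebound_rate=spec.rebound_rate if rebound else 0.0,
        )
    return NeuronProfile(
        baseline_rate=baseline,
        response_class="excited",
        evoked_gain=spec.evoked_gain,
    )


def simulate_population(
    spec: PopulationSpec,
    protocol: Optional[StimulusProtocol] = None,
    seed: int = 0,
    animal_id: str = "sim_animal",
) -> Session:
    """Simulate a session of ``spec.n_neurons`` i.i.d. units.

    Ground-truth profiles are retained in ``session.metadata["ground_truth"]``
    keyed by unit id.  The inter-stimulus interval is extended by the
    population's maximum after-discharge duration so every discharge is
    captured in full.
    """
    protocol = protocol or StimulusProtocol()
    rng = np.random.default_rng(seed)
    profiles = [sample_profile(spec, rng) for _ in range(spec.n_neurons)]
    max_ad = max(
        (max(p.ad_duration, p.rebound_duration) for p in profiles), default=0.0
    )
    extra = max(0.0, np.ceil(max_ad) - 0.0) if max_ad > 3.0 else 0.0
    events, duration = build_events(
        protocol, seed=int(rng.integers(2**31)), extra_isi=extra
    )
    units = []
    truth = {}
    for i, prof in enumerate(profiles):
        uid = f"u{i:03d}"
        units.append(
            simulate_spike_train(
                prof, events, duration, seed=int(rng.integers(2**31)), unit_id=uid
            )
        )
        truth[uid] = {
            k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
            for k, v in dataclasses.asdict(prof).items()
        }
    logger.info(
        "simulated %d units (%s), %d events, %.0f s",
        len(units), spec.condition, len(events), duration,
    )
    return Session(
        animal_id=animal_id,
        condition=spec.condition,
        units=units,
        events=events,
        metadata={"ground_truth": truth, "n_neurons": spec.n_neurons},
    )


# ---------------------------------------------------------------------------
# Aesthesiometer force traces
# ---------------------------------------------------------------------------

def simulate_force_trace(
    peak: float,
    duration: float,
    rise_time: float,
    sample_rate: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Trapezoidal ramp-hold-ramp force profile with clipped Gaussian noise.

    Returns a ``(n, 2)`` array of ``(time_s, force_g)``, non-negative
    everywhere.  With ``noise_sd = 0`` the integral is the closed-form
    trapezoid area ``peak * (duration - rise_time)``.
    """
    if peak < 0:
        raise ValidationError("peak force must be >= 0")
    if not rise_time < duration / 2:
        raise ValidationError("rise_time must be < duration / 2")
    t = np.arange(0.0, duration + 0.5 / sample_rate, 1.0 / sample_rate)
    up = np.minimum(t / rise_time, 1.0) if rise_time > 0 else np.ones_like(t)
    down = np.minimum((duration - t) / rise_time, 1.0) if rise_time > 0 else 1.0
    force = peak * np.clip(np.minimum(up, down), 0.0, 1.0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        force = force + rng.normal(0.0, noise_sd, size=force.shape)
    return np.column_stack([t, np.clip(force, 0.0, None)])


# ---------------------------------------------------------------------------
# Behavioral up-down sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PsychometricProfile:
    """Latent logistic psychometric function of a simulated animal.

    ``P(withdrawal | force) = logistic(slope * (log10 force - log10
    threshold_50))``; ``slope`` is per decade of force.
    """

    threshold_50: float
    slope: float = 10.0

    def __post_init__(self):
        if not self.threshold_50 > 0:
            raise ValidationError("threshold_50 must be > 0")
        if not self.slope > 0:
            raise ValidationError("slope must be > 0")

    def p_response(self, force_g: float) -> float:
        return float(
            expit(self.slope * (np.log10(force_g) - np.log10(self.threshold_50)))
        )


def simulate_updown_sequence(
    profile: PsychometricProfile,
    filament_ladder: Sequence[float],
    start_index: Optional[int] = None,
    seed: int = 0,
    n_after_reversal: int = 4,
    max_trials: int = 12,
    pin_run: int = 3,
) -> list:
    """Simulate one up-down (staircase) testing sequence.

    A withdrawal steps the next filament down, no response steps up.
    Testing continues for ``n_after_reversal`` stimuli after the first
    change in response, stops early after ``pin_run`` identical responses
    pinned at a ladder end, and is capped at ``max_trials``.  Returns a
    list of ``(force_g, responded)`` pairs.
    """
    ladder = np.asarray(filament_ladder, dtype=float)
    if ladder.size < 2 or np.any(np.diff(ladder) <= 0):
        raise ValidationError("filament ladder must be strictly increasing")
    if start_index is None:
        start_index = ladder.size // 2
    if not 0 <= start_index < ladder.size:
        raise ValidationError("start_index out of range")
    rng = np.random.default_rng(seed)
    idx = start_index
    seq: list = []
    reversal_seen = False
    count_after = 0
    pinned = 0
    while len(seq) < max_trials:
        force = ladder[idx]
        responded = bool(rng.random() < profile.p_response(force))
        seq.append((float(force), responded))
        if len(seq) >= 2 and seq[-1][1] != seq[-2][1]:
            reversal_seen = True
        if reversal_seen:
            count_after += 1
            if count_after > n_after_reversal:
                break
        at_edge = (responded and idx == 0) or (not responded and idx == ladder.size - 1)
        pinned = pinned + 1 if at_edge else 0
        if pinned >= pin_run:
            break
        idx = max(idx - 1, 0) if responded else min(idx + 1, ladder.size - 1)
    return seq
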