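"""Peristimulus time histograms and the baseline confidence band.

The PSTH aligns spike counts to stimulus onset in uniform half-open bins.
All detection criteria reference a 99% confidence band of the baseline
firing rate, estimated from the pooled per-bin counts of the pre-stimulus
baseline window (default 5 s) across trials.  Two band constructions are
available: a normal approximation ``mean ± z(0.995) * sd`` (default) and
an exact Poisson-quantile band; tests quantify their agreement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import AnalysisConfig, SpikeTrain, ValidationError

logger = logging.getLogger("pbspike")


@dataclass
class Psth:
    """Trial-aligned binned counts with baseline statistics.

    ``bin_edges`` are seconds relative to stimulus onset; ``counts`` is an
    ``(n_trials, n_bins)`` integer array; rates are Hz.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    n_trials: int
    bin_width: float
    stim_duration: float
    baseline_mean: float = 0.0
    baseline_sd: float = 0.0
    ci_lower: float = 0.0
    ci_upper: float = 0.0

    @property
    def mean_rate_per_bin(self) -> np.ndarray:
        """Across-trial mean firing rate in each bin (Hz)."""
        return self.counts.sum(axis=0) / (self.n_trials * self.bin_width)

    @property
    def baseline_mask(self) -> np.ndarray:
        """Bins lying wholly before stimulus onset."""
        return self.bin_edges[1:] <= 1e-12

    @property
    def stim_mask(self) -> np.ndarray:
        """Bins within the stimulus interval [0, stim_duration)."""
        starts = self.bin_edges[:-1]
        return (starts >= -1e-12) & (starts < self.stim_duration - 1e-12)

    def first_post_offset_bin(self) -> int:
        """Index of the first bin at or after stimulus offset."""
        starts = self.bin_edges[:-1]
        idx = np.nonzero(starts >= self.stim_duration - 1e-9)[0]
        if idx.size == 0:
            raise ValidationError("PSTH window does not extend past stimulus offset")
        return int(idx[0])

    def to_frame(self) -> pd.DataFrame:
        """Delimited-table form: bin bounds, per-trial counts, mean rate."""
        df = pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "mean_rate_hz": self.mean_rate_per_bin,
            }
        )
        for t in range(self.n_trials):
            df[f"trial_{t}"] = self.counts[t]
        return df


def build_psth(
    train: SpikeTrain,
    events,
    window: tuple,
    config: AnalysisConfig,
) -> Psth:
    """Bin one unit's spikes around each event of a trial set.

    ``window = (pre_s, post_s)`` extends the aligned window ``pre_s``
    before onset and ``post_s`` after onset.  Aligned windows must fit the
    recording and must not overlap one another.  The total PSTH count
    equals the number of spikes falling in the aligned windows (count
    conservation), with half-open bins assigning boundary spikes rightward.
    """
    pre_s, post_s = window
    if not events:
        raise ValidationError("no events supplied")
    durations = np.array([e.duration for e in events], dtype=float)
    if np.ptp(durations) > 1e-9:
        raise ValidationError("events in one PSTH must share a stimulus duration")
    stim_duration = float(durations[0])

    n_pre = int(round(pre_s / config.bin_width))
    n_post = int(round(post_s / config.bin_width))
    edges = (np.arange(n_pre + n_post + 1) - n_pre) * config.bin_width

    ordered = sorted(events, key=lambda e: e.onset)
    for a, b in zip(ordered, ordered[1:]):
        if b.onset - pre_s < a.onset + n_post * config.bin_width - 1e-9:
            raise ValidationError(
                f"aligned windows overlap for events at "
                f"{a.onset:.3f} s and {b.onset:.3f} s"
            )
    counts = np.empty((len(ordered), edges.size - 1), dtype=int)
    for t, e in enumerate(ordered):
        if e.onset - pre_s < -1e-9 or e.onset + n_post * config.bin_width > (
            train.duration + 1e-9
        ):
            raise ValidationError(
                f"aligned window of event at {e.onset:.3f} s exceeds recording"
            )
        rel = train.spike_times - e.onset
        # half-open bins [edge_i, edge_{i+1})
        idx = np.floor(rel / config.bin_width + 1e-12).astype(int) + n_pre
        valid = (idx >= 0) & (idx < counts.shape[1])
        counts[t] = np.bincount(idx[valid], minlength=counts.shape[1])

    psth = Psth(
        bin_edges=edges,
        counts=counts,
        n_trials=len(ordered),
        bin_width=config.bin_width,
        stim_duration=stim_duration,
    )
    mean, sd, lo, hi = baseline_band(psth, config)
    psth.baseline_mean, psth.baseline_sd = mean, sd
    psth.ci_lower, psth.ci_upper = lo, hi
    return psth


def baseline_band(psth: Psth, config: AnalysisConfig) -> tuple:
    """Baseline mean/sd and the confidence band in Hz.

    Pools the individual bin counts of all baseline bins across trials.
    ``normal`` mode: ``mean ± z((1 + ci_level)/2) * sd``, lower floored at
    0.  ``poisson_exact`` mode: Poisson quantiles of the mean bin count at
    the same tail levels.
    """
    pooled = psth.counts[:, psth.baseline_mask].ravel()
    if pooled.size == 0:
        raise ValidationError("baseline window contains no bins")
    if pooled.size < 10:
        logger.warning(
            "baseline window has only %d bin observations; band is unstable",
            pooled.size,
        )
    mean_count = float(pooled.mean())
    sd_count = float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0
    mean_hz = mean_count / psth.bin_width
    sd_hz = sd_count / psth.bin_width
    tail = (1.0 - config.ci_level) / 2.0
    if config.baseline_band_mode == "normal":
        z = stats.norm.ppf(1.0 - tail)
        upper = mean_hz + z * sd_hz
        lower = max(0.0, mean_hz - z * sd_hz)
    else:
        upper = float(stats.poisson.ppf(1.0 - tail, mean_count)) / psth.bin_width
        lower = float(stats.poisson.ppf(tail, mean_count)) / psth.bin_width
        lower = min(lower, mean_hz)  # ppf of 0-mass edge cases
    return mean_hz, sd_hz, lower, upper
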