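"""Response classification: excitation, after-discharges, suppression, rebound.

A unit is *responsive (excited)* when at least one in-stimulus PSTH bin's
across-trial mean rate exceeds the 99% baseline band.  An *after-discharge*
is a run of consecutive supra-band bins starting at the first post-offset
bin and lasting at least 500 ms (shorter runs are kept as diagnostics but
score 0).  *Suppression* is a two-tailed paired t-test of per-trial firing
rates in the 5 s pre-stimulus window against the stimulus window, requiring
the stimulus rate to be lower on average.  A *rebound* is any supra-band
run immediately after offset of a suppressed unit, scanned over a fixed
window (default 10 s).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import AnalysisConfig, SpikeTrain, ValidationError
from .psth import Psth, build_psth

logger = logging.getLogger("pbspike")


@dataclass
class DetectionResult:
    """Per-unit (per site x modality) response classification."""

    unit_id: str
    responsive: bool
    response_sign: str  # excited | suppressed | none
    ad_present: bool
    ad_duration: float
    suppression_p: float
    rebound_present: bool
    rebound_duration: float
    site: str = ""
    modality: str = ""
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.ad_present != (self.ad_duration >= 0.5 - 1e-9) and self.ad_duration:
            # invariant guarded properly in detect_after_discharge; keep cheap check
            logger.debug("ad flag/duration mismatch on %s", self.unit_id)


def _supra_run_length(psth: Psth, config: AnalysisConfig, max_bins: int) -> int:
    """Length (bins) of the supra-band run starting at the first post-offset bin."""
    start = psth.first_post_offset_bin()
    rates = psth.mean_rate_per_bin
    stop = min(rates.size, start + max_bins)
    run = 0
    gap = 0
    for i in range(start, stop):
        if rates[i] > psth.ci_upper:
            run = i - start + 1
            gap = 0
        else:
            gap += 1
            if run == 0 or gap > config.ad_gap_bins:
                break
    return run


def detect_response(psth: Psth, config: AnalysisConfig) -> tuple:
    """(responsive, sign) from the in-stimulus bins vs. the baseline band.

    Only the excited sign is decided here; the suppressed label comes from
    :func:`detect_suppression`, which tests rate decreases trial-by-trial.
    """
    excited = bool(np.any(psth.mean_rate_per_bin[psth.stim_mask] > psth.ci_upper))
    return (True, "excited") if excited else (False, "none")


def detect_after_discharge(psth: Psth, config: AnalysisConfig) -> tuple:
    """(ad_present, ad_duration_s) for one PSTH.

    The run must begin at the first post-offset bin (no leading gap) and,
    by default, contains no gap bins; it ends when activity returns below
    the band or the aligned window ends.  Runs shorter than
    ``ad_min_duration`` yield ``(False, 0.0)``.
    """
    post_span = psth.bin_edges[-1] - psth.stim_duration
    if post_span < config.rebound_scan_window - 1e-9:
        raise ValidationError(
            "PSTH window too short: extend at least rebound_scan_window "
            "past stimulus offset"
        )
    max_bins = psth.mean_rate_per_bin.size  # scan to end of window
    run = _supra_run_length(psth, config, max_bins)
    duration = run * psth.bin_width
    if duration >= config.ad_min_duration - 1e-9:
        return True, duration
    return False, 0.0


def detect_suppression(
    train: SpikeTrain, events, config: AnalysisConfig
) -> tuple:
    """(suppressed, p) from a paired t-test of pre vs. in-stimulus rates.

    Per trial the pre-rate is counted over ``baseline_window`` seconds
    before onset and the stimulus rate over ``[onset, offset)``.  The test
    is two-tailed; the suppressed label additionally requires the mean
    stimulus rate to be below the mean pre-rate.  A zero-variance set of
    paired differences with nonzero mean reports p = 0 with a
    degenerate-variance flag (returned p is exactly 0.0).
    """
    if len(events) < 3:
        raise ValidationError("paired t-test requires >= 3 trials")
    pre, stim = [], []
    for e in events:
        w = config.baseline_window
        pre.append(
            np.count_nonzero(
                (train.spike_times >= e.onset - w) & (train.spike_times < e.onset)
            )
            / w
        )
        stim.append(
            np.count_nonzero(
                (train.spike_times >= e.onset) & (train.spike_times < e.offset)
            )
            / e.duration
        )
    pre = np.array(pre)
    stim = np.array(stim)
    diff = pre - stim
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff.mean(), 0.0):
            return False, 1.0
        logger.warning("degenerate variance in paired differences; p set to 0")
        return bool(diff.mean() > 0), 0.0
    t, p = stats.ttest_rel(pre, stim)
    suppressed = bool(p < config.suppression_alpha and stim.mean() < pre.mean())
    return suppressed, float(p)


def detect_rebound(psth: Psth, config: AnalysisConfig) -> tuple:
    """(rebound_present, rebound_duration_s) for a suppressed unit.

    Same run rule as the after-discharge scan but limited to
    ``rebound_scan_window`` and with no minimum duration: any supra-band
    run starting at the first post-offset bin counts (events shorter than
    one bin are undetectable by construction).
    """
    max_bins = int(round(config.rebound_scan_window / config.bin_width))
    run = _supra_run_length(psth, config, max_bins)
    duration = run * psth.bin_width
    return duration > 0, duration


def classify_unit(
    train: SpikeTrain,
    events,
    config: AnalysisConfig,
    site: str = "",
    modality: str = "",
) -> DetectionResult:
    """Full per-unit classification on one set of like trials.

    Suppression takes precedence: a significantly suppressed unit is
    scanned for rebound and its after-discharge duration is 0 by
    definition; otherwise the excitation and after-discharge criteria
    apply.
    """
    window = (
        config.baseline_window,
        events[0].duration + config.rebound_scan_window,
    )
    psth = build_psth(train, events, window, config)
    suppressed, p_sup = detect_suppression(train, events, config)
    if suppressed:
        rb_present, rb_dur = detect_rebound(psth, config)
        return DetectionResult(
            unit_id=train.unit_id,
            responsive=True,
            response_sign="suppressed",
            ad_present=False,
            ad_duration=0.0,
            suppression_p=p_sup,
            rebound_present=rb_present,
            rebound_duration=rb_dur,
            site=site,
            modality=modality,
        )
    responsive, sign = detect_response(psth, config)
    ad_present, ad_dur = detect_after_discharge(psth, config)
    raw_run = _supra_run_length(psth, config, psth.mean_rate_per_bin.size)
    return DetectionResult(
        unit_id=train.unit_id,
        responsive=responsive,
        response_sign=sign,
        ad_present=ad_present,
        ad_duration=ad_dur,
        suppression_p=p_sup,
        rebound_present=False,
        rebound_duration=0.0,
        site=site,
        modality=modality,
        diagnostics={"raw_post_offset_run_s": raw_run * psth.bin_width},
    )


def detect_session(session, config: AnalysisConfig) -> pd.DataFrame:
    """Classify every unit for every (site, modality) trial group."""
    groups = {}
    for e in session.events:
        groups.setdefault((e.site, e.modality), []).append(e)
    rows = []
    for unit in session.units:
        for (site, modality), evs in sorted(groups.items()):
            res = classify_unit(unit, evs, config, site=site, modality=modality)
            rows.append(
                {
                    "unit_id": res.unit_id,
                    "site": site,
                    "modality": modality,
                    "responsive": res.responsive,
                    "response_sign": res.response_sign,
                    "ad_present": res.ad_present,
                    "ad_duration_s": res.ad_duration,
                    "suppression_p": res.suppression_p,
                    "rebound_present": res.rebound_present,
                    "rebound_duration_s": res.rebound_duration,
                }
            )
        logger.debug("classified unit %s", unit.unit_id)
    return pd.DataFrame(rows)
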