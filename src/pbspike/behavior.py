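"""Behavioral endpoints: up-down withdrawal thresholds, Hargreaves
latencies, and grimace-scale scores.

The 50% mechanical withdrawal threshold follows the up-down (staircase)
convention: filaments are applied in a ladder of calibrated forces,
stepping down after a withdrawal and up after none, and the threshold is
``10**(Xf + k*delta) / 10**4`` grams, where ``Xf`` is the final filament's
force on the conventional ``log10(10^4 * grams)`` scale, ``delta`` the
mean log-step of the ladder, and ``k`` a coefficient determined by the
response pattern.  ``k`` is obtained here by maximizing the likelihood of
the classical normal (probit) tolerance model with its scale fixed to one
log-step — the same model from which the traditional coefficient table
was computed; for the minimal two-trial series this gives k = -0.5 (O
then X) and +0.5 (X then O) exactly.  Sequences with no response change
are pinned to the ladder bounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .core import ValidationError

logger = logging.getLogger("pbspike")

#: Calibrated von Frey forces (g) for facial testing.
FACE_LADDER = (0.4, 0.6, 1.0, 1.4, 2.0, 4.0, 6.0, 8.0, 10.0, 15.0, 26.0)
#: Calibrated von Frey forces (g) for hind-paw testing.
HINDPAW_LADDER = (2.0, 4.0, 6.0, 8.0, 10.0, 15.0, 26.0, 60.0)


@dataclass
class UpDownRecord:
    """One up-down testing sequence.

    ``sequence`` is an ordered list of ``(filament_index, responded)``
    pairs into ``ladder`` (forces in grams, strictly increasing).
    Sequences outside 6–20 stimuli (10–12 are typical) trigger a warning,
    not an error.
    """

    ladder: Sequence[float]
    sequence: Sequence[tuple]
    side: str = "ipsi"
    site: str = "face"

    def __post_init__(self):
        ladder = np.asarray(self.ladder, dtype=float)
        if ladder.size < 2 or np.any(np.diff(ladder) <= 0):
            raise ValidationError("ladder must be strictly increasing")
        if np.any(ladder <= 0):
            raise ValidationError("ladder forces must be positive")
        self.ladder = ladder
        for idx, _ in self.sequence:
            if not 0 <= idx < ladder.size:
                raise ValidationError(f"filament index {idx} outside ladder")
        n = len(self.sequence)
        if n and not 6 <= n <= 20:
            logger.warning("up-down sequence length %d outside typical 6-20", n)

    @classmethod
    def from_forces(cls, ladder, force_response_pairs, **kw) -> "UpDownRecord":
        """Build from (force_g, responded) pairs, matching forces to the ladder."""
        ladder = np.asarray(ladder, dtype=float)
        seq = []
        for force, resp in force_response_pairs:
            idx = int(np.argmin(np.abs(ladder - force)))
            if not np.isclose(ladder[idx], force, rtol=1e-6):
                raise ValidationError(f"force {force} g not on the ladder")
            seq.append((idx, bool(resp)))
        return cls(ladder=ladder, sequence=seq, **kw)


def _log_step(ladder: np.ndarray) -> float:
    return float(np.mean(np.diff(np.log10(ladder))))


def dixon_k(
    levels_log: np.ndarray, responses: np.ndarray, delta: float
) -> float:
    """Staircase coefficient ``k = (mu_hat - x_final) / delta``.

    ``mu_hat`` maximizes the probit likelihood of the observed
    (level, response) pairs with the tolerance-curve scale fixed at
    ``delta`` (one log-step), the constraint under which the classical
    coefficient table was tabulated.
    """
    if responses.all() or (~responses).all():
        raise ValidationError("k undefined for a constant response pattern")

    def nll(mu):
        z = (levels_log - mu) / delta
        # log P(X) for responses, log P(O) otherwise
        return -(
            stats.norm.logcdf(z[responses]).sum()
            + stats.norm.logcdf(-z[~responses]).sum()
        )

    lo = levels_log.min() - 5 * delta
    hi = levels_log.max() + 5 * delta
    res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    return float((res.x - levels_log[-1]) / delta)


def updown_threshold(record: UpDownRecord) -> float:
    """50% withdrawal threshold (grams) from one up-down sequence.

    All-withdrawal sequences return the ladder minimum and
    all-non-response sequences the ladder maximum (pinned convention);
    otherwise the estimate is clipped to the ladder range.
    """
    if not record.sequence:
        raise ValidationError("empty up-down sequence")
    responses = np.array([bool(r) for _, r in record.sequence])
    forces = np.array([record.ladder[i] for i, _ in record.sequence])
    if responses.all():
        return float(record.ladder[0])
    if not responses.any():
        return float(record.ladder[-1])
    delta = _log_step(record.ladder)
    # conventional 10^4-gram scale: Xf = log10(force * 1e4)
    levels_log = np.log10(forces * 1e4)
    k = dixon_k(levels_log, responses, delta)
    xf = levels_log[-1]
    threshold = 10 ** (xf + k * delta) / 1e4
    return float(np.clip(threshold, record.ladder[0], record.ladder[-1]))


# ---------------------------------------------------------------------------
# Grimace scale
# ---------------------------------------------------------------------------

ACTION_UNITS = (
    "orbital_tightening",
    "nose_cheek_bulge",
    "whisker_tightening",
    "ear_position",
)


@dataclass
class GrimaceRecord:
    """Facial grimace scores: images x 4 action units, each 0, 1, or 2.

    ``image_scores`` is an ``(n_images, 4)`` array; NaN marks a missing
    (unscoreable) action unit, excluded from the mean.
    """

    image_scores: np.ndarray
    animal_id: str = ""
    condition: str = ""

    def __post_init__(self):
        scores = np.asarray(self.image_scores, dtype=float)
        if scores.ndim != 2 or scores.shape[1] != len(ACTION_UNITS):
            raise ValidationError(
                f"image_scores must have {len(ACTION_UNITS)} action-unit columns"
            )
        finite = scores[np.isfinite(scores)]
        if not np.all(np.isin(finite, (0.0, 1.0, 2.0))):
            raise ValidationError("grimace scores must be 0, 1, or 2")
        self.image_scores = scores


def grimace_mean(record: GrimaceRecord) -> float:
    """Mean grimace score across all non-missing image x action-unit cells."""
    finite = record.image_scores[np.isfinite(record.image_scores)]
    if finite.size == 0:
        raise ValidationError("no scored action units")
    return float(finite.mean())


# ---------------------------------------------------------------------------
# Hargreaves
# ---------------------------------------------------------------------------

@dataclass
class HargreavesRecord:
    """Hind-paw withdrawal latencies (s) from a radiant-heat source."""

    latencies: Sequence[float]
    side: str = "ipsi"

    def __post_init__(self):
        lats = np.asarray(self.latencies, dtype=float)
        if lats.size == 0:
            raise ValidationError("at least one latency required")
        if np.any(lats <= 0):
            raise ValidationError("latencies must be positive")
        if lats.size != 5:
            logger.warning("expected 5 Hargreaves trials, got %d", lats.size)
        self.latencies = lats


def hargreaves_latency(record: HargreavesRecord) -> float:
    """Mean withdrawal latency (s) across trials."""
    return float(np.mean(record.latencies))
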