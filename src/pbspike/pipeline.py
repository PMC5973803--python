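"""End-to-end orchestration: simulate/load -> detect -> metrics -> stats.

A run is driven by a single YAML config and a single seed.  The seed fans
out to per-stage child seeds through ``numpy.random.SeedSequence`` so
stages are individually reproducible without seed collisions.  All result
tables are delimited text; a run manifest records the config snapshot,
input hashes, seed, outputs, and tool version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import AnalysisConfig, Session, ValidationError, read_session, write_session
from .detection import detect_session
from .metrics import response_table
from .simulate import PopulationSpec, StimulusProtocol, preset_spec, simulate_population
from .stats import binomial_two_tailed, chi_square_2x2, mann_whitney_u, median_ci

logger = logging.getLogger("pbspike")


@dataclass
class RunManifest:
    config: dict
    seed: int
    input_hashes: dict
    outputs: list
    version: str
    started: str
    finished: str = ""


def child_seeds(seed: int, n: int) -> list:
    """Deterministic sub-2^31 child seeds derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint64)]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def compare_incidence(k_ref: int, n_ref: int, k_test: int, n_test: int) -> float:
    """Two-tailed binomial p of the test group's count against the
    reference group's observed proportion (floored at half a count when
    the reference observed zero)."""
    p0 = max(k_ref, 0.5) / n_ref
    p0 = min(p0, 1 - 0.5 / n_ref)
    return binomial_two_tailed(k_test, n_test, p0)


def group_report(detections: dict, magnitudes: dict) -> pd.DataFrame:
    """Between-condition comparisons mirroring the study's analyses.

    ``detections``/``magnitudes`` map condition label -> table.  Requires
    exactly two conditions; the first is treated as the reference (sham).
    """
    if len(detections) != 2:
        raise ValidationError("group report needs exactly two conditions")
    (ref_label, ref_det), (test_label, test_det) = detections.items()
    rows = []

    def add(name, comparison=None, **extra):
        row = {"comparison": name, "reference": ref_label, "test": test_label}
        if comparison is not None:
            row.update(
                statistic=comparison.statistic,
                p_value=comparison.p_value,
                effect_size=comparison.effect_size,
            )
            for label, s in zip((ref_label, test_label), comparison.group_summaries):
                row[f"{label}_n"] = s.n
                row[f"{label}_median"] = s.median
                row[f"{label}_ci"] = f"[{s.ci_low:.4g}, {s.ci_high:.4g}]"
        row.update(extra)
        rows.append(row)

    # after-discharge duration across all tactile-responsive units
    ref_ad = ref_det["ad_duration_s"].to_numpy()
    test_ad = test_det["ad_duration_s"].to_numpy()
    add("ad_duration_s", mann_whitney_u(ref_ad, test_ad))

    # after-discharge incidence: binomial test vs. the reference proportion
    k_ref, n_ref = int(ref_det["ad_present"].sum()), len(ref_det)
    k_test, n_test = int(test_det["ad_present"].sum()), len(test_det)
    add(
        "ad_incidence",
        statistic=float("nan"),
        p_value=compare_incidence(k_ref, n_ref, k_test, n_test),
        **{
            f"{ref_label}_n": n_ref,
            f"{test_label}_n": n_test,
            f"{ref_label}_median": k_ref / n_ref,
            f"{test_label}_median": k_test / n_test,
        },
    )

    # OFF-cell proportions: 2x2 chi-square
    off_ref = int((ref_det["response_sign"] == "suppressed").sum())
    off_test = int((test_det["response_sign"] == "suppressed").sum())
    table = [[off_ref, n_ref - off_ref], [off_test, n_test - off_test]]
    try:
        add("off_cell_proportions", chi_square_2x2(table))
    except ValidationError:
        logger.warning("OFF-cell chi-square skipped: degenerate margin")

    # response magnitudes and spontaneous rates
    for label_pair in [("magnitude", "magnitude"), ("spontaneous_rate_hz", "spontaneous_rate_hz")]:
        col = label_pair[1]
        a = magnitudes[ref_label][col].to_numpy()
        b = magnitudes[test_label][col].to_numpy()
        a = a[np.isfinite(a)]
        b = b[np.isfinite(b)]
        if a.size and b.size:
            add(col, mann_whitney_u(a, b))
    return pd.DataFrame(rows)


def run_pipeline(config, out_dir=None, seed=None) -> RunManifest:
    """Execute a full run from a config mapping or YAML path.

    Config keys: ``seed``; ``analysis`` (AnalysisConfig fields);
    ``populations`` — list of ``{preset|spec, n, label}`` to simulate —
    or ``sessions`` — list of manifest paths; ``out_dir``.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    config = dict(config or {})
    seed = int(config.get("seed", 0) if seed is None else seed)
    out = Path(out_dir or config.get("out_dir", "pbspike_run"))
    out.mkdir(parents=True, exist_ok=True)
    analysis = AnalysisConfig(**(config.get("analysis") or {}))
    manifest = RunManifest(
        config=config,
        seed=seed,
        input_hashes={},
        outputs=[],
        version=__version__,
        started=datetime.now(timezone.utc).isoformat(),
    )

    sessions = {}
    if config.get("sessions"):
        for path in config["sessions"]:
            sess = read_session(path)
            manifest.input_hashes[str(path)] = _sha256(Path(path))
            sessions[sess.condition] = sess
    else:
        pops = config.get("populations") or [
            {"preset": "sham_like", "n": 22, "label": "sham"},
            {"preset": "cci_like", "n": 43, "label": "cci_ion"},
        ]
        seeds = child_seeds(seed, len(pops))
        for pop, s in zip(pops, seeds):
            label = pop.get("label") or pop["preset"]
            spec = preset_spec(pop["preset"], int(pop["n"]))
            protocol = StimulusProtocol(**(pop.get("protocol") or {}))
            sess = simulate_population(spec, protocol, seed=s, animal_id=label)
            sessions[label] = sess
            mpath = write_session(sess, out / f"session_{label}")
            manifest.outputs.append(str(mpath))

    detections, magnitudes = {}, {}
    for label, sess in sessions.items():
        det = detect_session(sess, analysis)
        mag = response_table(sess, analysis)
        det_path = out / f"detection_{label}.csv"
        mag_path = out / f"magnitudes_{label}.csv"
        det.to_csv(det_path, index=False)
        mag.to_csv(mag_path, index=False)
        manifest.outputs += [str(det_path), str(mag_path)]
        detections[label] = det
        magnitudes[label] = mag
        logger.info("stage detect/metrics done for %s (%d rows)", label, len(det))

    if len(sessions) == 2:
        report = group_report(detections, magnitudes)
        report_path = out / "group_stats.csv"
        report.to_csv(report_path, index=False)
        manifest.outputs.append(str(report_path))

    manifest.finished = datetime.now(timezone.utc).isoformat()
    with open(out / "run_manifest.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(manifest), fh, sort_keys=False)
    return manifest
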