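"""Readers/writers and run provenance.

Cohort files are plain CSV with one row per woman: ``id, entry_time,
screen_times`` (semicolon-joined, years since entry), ``outcome``
(screen_detected | interval_cancer | clinical | censored),
``outcome_round, outcome_time, feature, period``.  Floats are written
with 12 significant digits, which round-trips the double values the
package produces.  Casting / architectural-distortion features parse but
are flagged excluded from analysis.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .likelihood import Cohort, DetectionMode, WomanRecord
from .natural_history import EXCLUDED_FEATURES, FeatureClass, ParamSet

__all__ = [
    "write_cohort", "read_cohort", "cohort_to_dataframe", "cohort_from_dataframe",
    "risk_curve_table", "RunManifest", "file_digest",
]

_COLUMNS = ["id", "entry_time", "screen_times", "outcome", "outcome_round",
            "outcome_time", "feature", "period"]


def _fmt(x: float) -> str:
    return format(float(x), ".12g")


def cohort_to_dataframe(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for r in cohort:
        rows.append({
            "id": r.id,
            "entry_time": _fmt(r.entry_time),
            "screen_times": ";".join(_fmt(t) for t in r.screen_times),
            "outcome": r.outcome.value,
            "outcome_round": "" if r.outcome_round is None else str(r.outcome_round),
            "outcome_time": _fmt(r.outcome_time),
            "feature": "" if r.feature is None else r.feature.value,
            "period": r.period,
        })
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    cohort_to_dataframe(cohort).to_csv(path, index=False)


def cohort_from_dataframe(df: pd.DataFrame) -> Cohort:
    """Build a validated cohort; collects row-level errors with their ids."""
    records, errors, excluded = [], [], 0
    for _, row in df.iterrows():
        rid = str(row["id"])
        try:
            feat = str(row.get("feature", "") or "")
            feature = FeatureClass(feat) if feat else None
            if feature in EXCLUDED_FEATURES:
                excluded += 1
                continue
            raw_rounds = row.get("outcome_round", "")
            rnd = None if raw_rounds in ("", None) or pd.isna(raw_rounds) else int(raw_rounds)
            st = str(row.get("screen_times", "") or "")
            screens = tuple(float(t) for t in st.split(";") if t != "")
            records.append(WomanRecord(
                id=rid,
                entry_time=float(row.get("entry_time", 0.0) or 0.0),
                screen_times=screens,
                outcome=DetectionMode(str(row["outcome"])),
                outcome_round=rnd,
                outcome_time=float(row["outcome_time"]),
                feature=feature,
                period=str(row.get("period", "") or ""),
            ))
        except (ValueError, KeyError) as exc:
            errors.append(f"row id={rid}: {exc}")
    if errors:
        raise ValueError(
            "invalid cohort rows:\n" + "\n".join(errors[:20])
            + ("" if len(errors) <= 20 else f"\n... {len(errors) - 20} more")
        )
    cohort = Cohort(records)
    cohort.n_excluded_feature_records = excluded
    return cohort


def read_cohort(path: str | Path) -> Cohort:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ("id", "outcome", "outcome_time") if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing columns: {missing}")
    return cohort_from_dataframe(df)


def risk_curve_table(params: ParamSet, t_grid) -> pd.DataFrame:
    """Per-feature cumulative risk of clinical surfacing, 1 - exp(-lambda2 t)."""
    from .natural_history import cumulative_risk_cp

    t = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t) <= 0) or np.any(t < 0):
        raise ValueError("t grid must be non-negative and increasing")
    out = pd.DataFrame({"t": t})
    for f, p in params.items():
        out[FeatureClass(f).value] = cumulative_risk_cp(p, t)
    return out


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


@dataclasses.dataclass
class RunManifest:
    """Provenance of one command invocation; one manifest per run."""

    command: str
    seed: int | None
    config: dict
    inputs: dict[str, str]      # path -> digest
    outputs: list[str]
    version: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.datetime.now(datetime.timezone.utc).isoformat()
        if not self.version:
            from . import __version__

            self.version = __version__

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
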