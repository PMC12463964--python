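"""Cohort CSV reading/writing, run configuration, and run manifests.

The cohort CSV schema is::

    subject_id,age_years,amh_ng_ml,oocytes_retrieved,por,cycle_day

Missing optional values are empty fields.  ``por`` is 0/1; when absent it
is derived from ``oocytes_retrieved`` (< 5 oocytes = poor response).  AMH
is always ng/mL at the file boundary; callers holding pmol/L values must
convert explicitly (x 0.14) — no silent unit handling.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd
import yaml

from .errors import SchemaError
from .records import COHORT_COLUMNS, CohortRecord, cohort_to_frame

MANDATORY_COLUMNS = ["subject_id", "age_years", "amh_ng_ml"]

#: ng/mL per pmol/L for AMH (assay-independent mass conversion).
PMOL_L_TO_NG_ML = 0.14


def read_cohort_csv(path) -> list[CohortRecord]:
    """Parse a cohort CSV into typed records.

    Row-level problems (unparseable numerics, out-of-domain values) are
    collected and reported together with their line numbers.  Extra columns
    are ignored with a warning; missing mandatory columns raise
    :class:`SchemaError`.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    extra = [c for c in frame.columns if c not in COHORT_COLUMNS]
    if extra:
        warnings.warn(f"{path}: ignoring unknown column(s) {extra}", stacklevel=2)

    records: list[CohortRecord] = []
    problems: list[str] = []
    for i, row in frame.iterrows():
        line = i + 2  # header is line 1
        try:
            records.append(
                CohortRecord(
                    subject_id=row["subject_id"],
                    age_years=_parse_float(row["age_years"], "age_years"),
                    amh_ng_ml=_parse_float(row["amh_ng_ml"], "amh_ng_ml"),
                    oocytes_retrieved=_parse_opt_int(row.get("oocytes_retrieved", "")),
                    por=_parse_opt_bool(row.get("por", "")),
                    cycle_day=_parse_opt_int(row.get("cycle_day", "")),
                )
            )
        except Exception as exc:  # collect every bad row, then fail once
            problems.append(f"line {line}: {exc}")
    if problems:
        raise SchemaError(f"{path}: {len(problems)} invalid row(s):\n" + "\n".join(problems))
    return records


def _parse_float(text: str, name: str) -> float:
    text = text.strip()
    if not text:
        raise ValueError(f"{name} is blank")
    return float(text)


def _parse_opt_int(text) -> int | None:
    text = str(text).strip()
    return int(float(text)) if text else None


def _parse_opt_bool(text) -> bool | None:
    text = str(text).strip().lower()
    if not text:
        return None
    if text in {"1", "true", "yes"}:
        return True
    if text in {"0", "false", "no"}:
        return False
    raise ValueError(f"por value {text!r} is not 0/1")


def write_cohort_csv(cohort, path) -> None:
    frame = cohort_to_frame(cohort)
    frame["por"] = frame["por"].map(lambda v: "" if pd.isna(v) else int(v))
    frame.to_csv(path, index=False)


DEFAULT_CONFIG: dict = {
    "model": {"name": "model2", "center": False},
    "evaluation": {"n_bins": 10, "n_boot": 2000, "seed": 20170101},
    "aging_curve": {"tau": 0.15, "min_n": 20},
    "milestones": {"p_score50": 0.5, "p_peri": 0.95},
    "synthetic": {"mode": "class_conditional", "n": 15241, "seed": 0},
    "output_dir": "ovaclock_out",
}


def load_run_config(path=None) -> dict:
    """Load a YAML run configuration, merged over the documented defaults."""
    config = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, values in user.items():
            if isinstance(values, dict) and isinstance(config.get(section), dict):
                config[section].update(values)
            else:
                config[section] = values
    tau = config["aging_curve"]["tau"]
    if not 0.0 < tau < 1.0:
        raise SchemaError(f"aging_curve.tau={tau} outside (0, 1)")
    return config


def write_manifest(out_dir, config: dict, seeds: dict) -> Path:
    """Record config, seeds and library versions for reproducibility."""
    import numpy
    import pandas
    import scipy

    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "ovaclock_version": __version__,
        "versions": {
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
        },
        "config": config,
        "seeds": seeds,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
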