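"""Cognitive test battery registry.

The default battery covers six cognitive domains commonly affected in
multiple sclerosis, each measured by one or more standard neuropsychological
tests:

* verbal memory — California Verbal Learning Test II (CVLT)
* information processing speed — Letter Digit Substitution Test (LDST)
* visuospatial memory — Location Learning Test (LLT)
* working memory — Digit Span Forward/Backward (DSF/DSB),
  Letter–Number Sequencing (LNS)
* verbal fluency — Word List Generation (WLG)
* attention — Stroop, Concept Shifting Test (CST), D2 test,
  Test of Everyday Attention (TEA)

Each entry records the direction of the score (for LLT, Stroop and CST a
higher raw score means a worse outcome), reference healthy-control moments,
patient-arm moments, and the mean practice effect per retest estimated from
untreated waiting-list controls.  These parameterize the synthetic cohort
generator and the direction registry used by the reliable-change pipeline.

A custom battery can be loaded from a YAML/JSON file with the same fields.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "TestDef",
    "DEFAULT_BATTERY",
    "DOMAINS",
    "domain_map",
    "direction_map",
    "battery_frame",
    "load_battery",
    "save_battery",
]

DOMAINS = (
    "verbal_memory",
    "information_processing_speed",
    "visuospatial_memory",
    "working_memory",
    "verbal_fluency",
    "attention",
)


@dataclass(frozen=True)
class TestDef:
    """Definition of one cognitive test in the battery.

    Parameters
    ----------
    test_id : short identifier, e.g. ``"LNS"``.
    domain : one of :data:`DOMAINS`.
    higher_is_better : direction flag; ``False`` for timed/error scores
        where a higher raw score means a worse outcome.
    hc_mean, hc_sd : healthy-control reference mean and SD of the raw score.
    patient_mean, patient_sd : patient-arm baseline mean and SD.
    practice_effect : mean raw-score change per retest in untreated
        controls (sign on the raw scale, not direction-aligned).
    """

    test_id: str
    domain: str
    higher_is_better: bool
    hc_mean: float
    hc_sd: float
    patient_mean: float
    patient_sd: float
    practice_effect: float

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r} for test {self.test_id!r}")
        if self.hc_sd <= 0 or self.patient_sd <= 0:
            raise ValueError(f"non-positive SD for test {self.test_id!r}")


# Reference moments: healthy controls at baseline; patient arms at baseline;
# practice effect = mean waiting-list change between the first two sessions.
DEFAULT_BATTERY: tuple[TestDef, ...] = (
    TestDef("CVLT", "verbal_memory", True, 67.24, 7.65, 56.33, 13.07, 1.84),
    TestDef("LDST", "information_processing_speed", True, 64.43, 11.64, 55.17, 15.08, 2.46),
    TestDef("LLT", "visuospatial_memory", False, 15.10, 10.77, 22.75, 26.93, -3.00),
    TestDef("DSF", "working_memory", True, 9.71, 1.98, 9.04, 1.78, -0.08),
    TestDef("DSB", "working_memory", True, 7.86, 1.28, 6.63, 1.71, 0.33),
    TestDef("LNS", "working_memory", True, 11.24, 1.87, 10.96, 2.65, -0.25),
    TestDef("WLG", "verbal_fluency", True, 17.45, 4.53, 15.46, 4.21, 1.11),
    TestDef("Stroop", "attention", False, 25.86, 7.55, 28.59, 13.90, -2.07),
    TestDef("CST", "attention", False, 8.80, 4.84, 11.69, 14.82, 0.03),
    TestDef("D2", "attention", True, 156.43, 43.44, 135.17, 59.25, 18.48),
    TestDef("TEA", "attention", True, -0.01, 0.60, -0.64, 1.23, 0.52),
)


def domain_map(battery: tuple[TestDef, ...] = DEFAULT_BATTERY) -> dict[str, str]:
    """Mapping test_id -> cognitive domain."""
    return {t.test_id: t.domain for t in battery}


def direction_map(battery: tuple[TestDef, ...] = DEFAULT_BATTERY) -> dict[str, bool]:
    """Mapping test_id -> higher_is_better flag."""
    return {t.test_id: t.higher_is_better for t in battery}


def battery_frame(battery: tuple[TestDef, ...] = DEFAULT_BATTERY) -> pd.DataFrame:
    """Battery as a DataFrame indexed by test_id."""
    return pd.DataFrame([asdict(t) for t in battery]).set_index("test_id")


def load_battery(path: str | Path) -> tuple[TestDef, ...]:
    """Load a battery registry from a YAML or JSON file.

    The file holds a list of mappings with the :class:`TestDef` fields.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    return tuple(TestDef(**entry) for entry in raw)


def save_battery(battery: tuple[TestDef, ...], path: str | Path) -> None:
    """Write a battery registry to YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    entries = [asdict(t) for t in battery]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(entries, indent=2), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(entries, sort_keys=False), encoding="utf-8")
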