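"""Practice-corrected reliable change and responder classification.

The reliable change index (RCI) asks whether an individual's test–retest
change exceeds what measurement noise and practice alone would produce.  The
practice-corrected, control-referenced form used here standardizes each
patient's direction-aligned change against the change distribution of
untreated waiting-list controls:

    RCI_i = (delta_i - mean(delta_ctrl)) / SD(delta_ctrl)

Subtracting the control mean removes the practice effect; dividing by the
control SD of change plays the role of the standard error of difference.
A change is a reliable improvement when RCI > +1.64 and a reliable decline
when RCI < -1.64 (strict inequalities; 1.64 is the 90% central-interval
normal quantile to two decimals).  A patient is a responder when at least
two of the six cognitive domains show reliable improvement on at least one
test.

An alternative denominator, the classical standard error of difference
``SD_baseline * sqrt(2 * (1 - r))`` for a supplied retest reliability ``r``,
is available via :func:`sediff_denominator` for users who prefer the
Jacobson–Truax convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .battery import DOMAINS, domain_map as default_domain_map

__all__ = [
    "RCI_THRESHOLD",
    "rci_threshold",
    "sediff_denominator",
    "align_direction",
    "change_scores",
    "control_change_stats",
    "compute_rci",
    "classify_responder",
    "responder_summary",
    "hc_zscores",
    "impairment_flag",
]

logger = logging.getLogger(__name__)

#: Reliable-change threshold for a 90% confidence band, as conventionally
#: printed to two decimals.
RCI_THRESHOLD = 1.64

_SCORE_COLS = ("subject_id", "arm", "timepoint", "test_id", "value")


class RciError(ValueError):
    """Invalid input to the reliable-change pipeline."""


def rci_threshold(confidence: float = 0.90) -> float:
    """Standard-normal quantile bounding the central ``confidence`` band.

    ``rci_threshold(0.90)`` is 1.6449, conventionally rounded to 1.64.
    """
    if not 0.0 < confidence < 1.0:
        raise RciError("confidence must lie in (0, 1)")
    return float(sps.norm.ppf(0.5 + confidence / 2.0))


def sediff_denominator(baseline_sd: float, reliability: float) -> float:
    """Classical standard error of difference ``SD * sqrt(2) * sqrt(1 - r)``."""
    if baseline_sd <= 0:
        raise RciError("baseline_sd must be positive")
    if not 0.0 <= reliability < 1.0:
        raise RciError("reliability must lie in [0, 1)")
    return float(baseline_sd * np.sqrt(2.0) * np.sqrt(1.0 - reliability))


def _require_columns(df: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise RciError(f"missing required columns: {missing}")


# ---------------------------------------------------------------------------
# Direction alignment
# ---------------------------------------------------------------------------

def align_direction(
    obs: pd.DataFrame,
    directions: dict[str, bool] | None = None,
) -> pd.DataFrame:
    """Return a copy of the score table with improvement-positive values.

    Tests whose raw scores are lower-is-better (timed or error scores) are
    negated so that a positive change always means improvement.  The
    direction comes from the ``higher_is_better`` column if present,
    otherwise from the ``directions`` registry (test_id -> bool).  The
    result carries ``attrs["direction_aligned"] = True``; aligning an
    already-aligned table is an error rather than a silent double negation.
    """
    _require_columns(obs, ("test_id", "value"))
    if obs.attrs.get("direction_aligned"):
        raise RciError("score table is already direction-aligned")
    out = obs.copy()
    if "higher_is_better" in out.columns:
        hib = out["higher_is_better"].astype(bool)
    else:
        if directions is None:
            raise RciError("no higher_is_better column and no direction registry given")
        unmapped = sorted(set(out["test_id"]) - set(directions))
        if unmapped:
            raise RciError(f"tests missing a direction flag: {unmapped}")
        hib = out["test_id"].map(directions).astype(bool)
    out["value"] = np.where(hib, out["value"], -out["value"])
    out["higher_is_better"] = True
    out.attrs["direction_aligned"] = True
    return out


def _check_aligned(obs: pd.DataFrame) -> None:
    if not obs.attrs.get("direction_aligned"):
        raise RciError("score table must be direction-aligned first (align_direction)")


# ---------------------------------------------------------------------------
# Change scores and control statistics
# ---------------------------------------------------------------------------

def change_scores(
    obs: pd.DataFrame,
    from_tp: str = "T0",
    to_tp: str = "T1",
) -> pd.DataFrame:
    """Per subject × test direction-aligned change ``to_tp - from_tp``.

    Subjects missing either timepoint for a test are dropped for that test.
    """
    _check_aligned(obs)
    _require_columns(obs, _SCORE_COLS)
    wide = (
        obs[obs["timepoint"].isin([from_tp, to_tp])]
        .pivot_table(index=["subject_id", "arm", "test_id"], columns="timepoint",
                     values="value", aggfunc="first")
        .reset_index()
    )
    if from_tp not in wide.columns or to_tp not in wide.columns:
        raise RciError(f"timepoints {from_tp!r}/{to_tp!r} not present in the table")
    wide = wide.dropna(subset=[from_tp, to_tp])
    wide["delta"] = wide[to_tp] - wide[from_tp]
    return wide[["subject_id", "arm", "test_id", "delta"]]


def control_change_stats(
    obs: pd.DataFrame,
    from_tp: str = "T0",
    to_tp: str = "T1",
    control_arm: str = "waitlist",
) -> pd.DataFrame:
    """Mean and sample SD of control change per test (practice correction).

    Uses only the untreated ``control_arm``; subjects missing either
    timepoint are excluded per test.  Requires at least two complete
    controls and strictly positive change SD for every test.

    Returns a DataFrame indexed by test_id with columns
    ``mean_change, sd_change, n_controls``.
    """
    deltas = change_scores(obs, from_tp, to_tp)
    ctrl = deltas[deltas["arm"] == control_arm]
    if ctrl.empty:
        raise RciError(f"no complete {control_arm!r} subjects between {from_tp} and {to_tp}")
    grouped = ctrl.groupby("test_id")["delta"]
    out = pd.DataFrame({
        "mean_change": grouped.mean(),
        "sd_change": grouped.std(ddof=1),
        "n_controls": grouped.size(),
    })
    thin = out.index[out["n_controls"] < 2].tolist()
    if thin:
        raise RciError(f"fewer than 2 complete controls for tests: {thin}")
    flat = out.index[~(out["sd_change"] > 0)].tolist()
    if flat:
        raise RciError(f"control change SD is not positive for tests: {flat}")
    return out


def compute_rci(
    deltas: pd.DataFrame,
    control_stats: pd.DataFrame,
    threshold: float = RCI_THRESHOLD,
) -> pd.DataFrame:
    """Practice-corrected RCI per subject × test with reliable-change flags.

    ``rci = (delta - mean_change) / sd_change`` using the control-arm change
    statistics for the same test; ``reliable_improvement`` iff
    ``rci > +threshold`` and ``reliable_decline`` iff ``rci < -threshold``
    (both strict, hence never both).
    """
    if threshold <= 0:
        raise RciError("threshold must be positive")
    _require_columns(deltas, ("subject_id", "test_id", "delta"))
    unmapped = sorted(set(deltas["test_id"]) - set(control_stats.index))
    if unmapped:
        raise RciError(f"no control change statistics for tests: {unmapped}")
    if not (control_stats["sd_change"] > 0).all():
        raise RciError("control change SD must be positive for every test")
    out = deltas.merge(
        control_stats[["mean_change", "sd_change"]],
        left_on="test_id", right_index=True, how="left",
    )
    out["rci"] = (out["delta"] - out["mean_change"]) / out["sd_change"]
    out["reliable_improvement"] = out["rci"] > threshold
    out["reliable_decline"] = out["rci"] < -threshold
    return out.drop(columns=["mean_change", "sd_change"])


# ---------------------------------------------------------------------------
# Responder classification
# ---------------------------------------------------------------------------

def classify_responder(
    records: pd.DataFrame,
    domains: dict[str, str] | None = None,
    min_domains_improved: int = 2,
    min_domains_determined: int = 5,
) -> pd.DataFrame:
    """Aggregate reliable-change records to domain flags and responder labels.

    A domain is *improved* when at least one of its tests shows reliable
    improvement, and *determined* when at least one of its tests has a valid
    record.  A subject is a ``responder`` with >= ``min_domains_improved``
    improved domains; a definitive ``non_responder`` label additionally
    requires >= ``min_domains_determined`` determined domains — otherwise
    the label is ``undetermined`` (too much missing data to rule response
    out), with the reason logged.

    Returns one row per subject: per-domain improvement flags,
    ``n_domains_improved``, ``n_domains_determined``, ``is_responder``
    (nullable boolean) and ``label``.
    """
    _require_columns(records, ("subject_id", "test_id", "reliable_improvement"))
    domains = default_domain_map() if domains is None else domains
    unmapped = sorted(set(records["test_id"]) - set(domains))
    if unmapped:
        raise RciError(f"tests not mapped to a domain: {unmapped}")
    rec = records.copy()
    rec["domain"] = rec["test_id"].map(domains)

    improved = (
        rec.pivot_table(index="subject_id", columns="domain",
                        values="reliable_improvement", aggfunc="any")
        .reindex(columns=list(DOMAINS))
    )
    determined = improved.notna()
    flags = improved.notna() & (improved == True)  # noqa: E712 — NaN-safe

    n_improved = flags.sum(axis=1)
    n_determined = determined.sum(axis=1)
    label = pd.Series("undetermined", index=flags.index, dtype=object)
    label[n_improved >= min_domains_improved] = "responder"
    label[(n_improved < min_domains_improved) & (n_determined >= min_domains_determined)] = (
        "non_responder"
    )
    for sid in label.index[label == "undetermined"]:
        logger.info(
            "subject %s undetermined: %d domains improved but only %d determined",
            sid, n_improved[sid], n_determined[sid],
        )

    out = flags.add_prefix("improved_")
    out["n_domains_improved"] = n_improved
    out["n_domains_determined"] = n_determined
    out["label"] = label
    out["is_responder"] = pd.array(
        [True if l == "responder" else False if l == "non_responder" else None
         for l in label], dtype="boolean",
    )
    return out.reset_index()


def responder_summary(labels: pd.DataFrame) -> dict:
    """Cohort-level responder summary.

    Returns the responder rate among determined subjects (percent), counts
    per label, and the distribution of ``n_domains_improved`` among
    responders (percent improving on exactly k domains).
    """
    determined = labels[labels["label"] != "undetermined"]
    n_det = len(determined)
    n_resp = int((determined["label"] == "responder").sum())
    resp = determined[determined["label"] == "responder"]
    dist = (
        (resp["n_domains_improved"].value_counts(normalize=True) * 100.0)
        .sort_index().to_dict()
        if n_resp else {}
    )
    return {
        "n_determined": n_det,
        "n_responders": n_resp,
        "n_non_responders": n_det - n_resp,
        "n_undetermined": int((labels["label"] == "undetermined").sum()),
        "responder_rate_pct": 100.0 * n_resp / n_det if n_det else float("nan"),
        "pct_responders_by_n_domains": dist,
    }


# ---------------------------------------------------------------------------
# HC-referenced z-scores and impairment
# ---------------------------------------------------------------------------

def hc_zscores(
    obs: pd.DataFrame,
    domains: dict[str, str] | None = None,
    hc_arm: str = "HC",
    timepoint: str = "T0",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Healthy-control-referenced z-scores at one timepoint.

    Per test: ``z = (aligned value - HC mean) / HC SD``; per domain: the mean
    of its tests' z-scores; *average cognition*: the mean of the six domain
    z-scores.  By construction the HC sample averages to zero on every test.

    Returns ``(test_z, domain_z, average_cognition)`` — subjects × tests,
    subjects × domains, and a per-subject Series.
    """
    _check_aligned(obs)
    _require_columns(obs, _SCORE_COLS)
    domains = default_domain_map() if domains is None else domains
    at_tp = obs[obs["timepoint"] == timepoint]
    hc = at_tp[at_tp["arm"] == hc_arm]
    if hc.empty:
        raise RciError(f"no {hc_arm!r} rows at {timepoint!r} for the HC reference")
    ref = hc.groupby("test_id")["value"].agg(["mean", "std"])
    flat = ref.index[~(ref["std"] > 0)].tolist()
    if flat:
        raise RciError(f"HC reference SD is not positive for tests: {flat}")

    wide = at_tp.pivot_table(index="subject_id", columns="test_id",
                             values="value", aggfunc="first")
    test_z = (wide - ref["mean"]) / ref["std"]
    cols = pd.Series([domains.get(t) for t in test_z.columns], index=test_z.columns)
    unmapped = sorted(cols.index[cols.isna()])
    if unmapped:
        raise RciError(f"tests not mapped to a domain: {unmapped}")
    domain_z = test_z.T.groupby(cols).mean().T.reindex(columns=list(DOMAINS))
    average_cognition = domain_z.mean(axis=1)
    average_cognition.name = "average_cognition"
    return test_z, domain_z, average_cognition


def impairment_flag(
    test_z: pd.DataFrame,
    cutoff: float = -2.0,
    min_tests: int = 2,
) -> pd.Series:
    """Cognitive impairment: z strictly below ``cutoff`` on >= ``min_tests`` tests."""
    below = (test_z < cutoff).sum(axis=1)
    flag = below >= min_tests
    flag.name = "impaired"
    return flag
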