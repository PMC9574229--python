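"""Network assignment and whole-brain-normalized between-network FC.

Atlas regions are assigned to canonical resting-state networks (default
mode, dorsal attention, ventral attention, frontoparietal) by maximal voxel
overlap with a network atlas; regions overlapping none of the four analysis
networks best fall into an ``other`` bucket.  Per subject, functional
connectivity is the Pearson correlation between regional timeseries; the
between-network value for a pair of networks is the mean correlation over
all region pairs with one region in each network, and it is normalized by
dividing with the subject's average brain connectivity (the mean over all
off-diagonal region pairs, all networks included).  Normalization removes
global scaling differences between subjects, so the profile is invariant to
multiplying every correlation by a positive constant.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

__all__ = [
    "ANALYSIS_NETWORKS",
    "NETWORK_PAIRS",
    "assign_networks",
    "timeseries_to_fc",
    "network_pair_fc",
    "profile_subjects",
    "group_fc_table",
]

logger = logging.getLogger(__name__)

ANALYSIS_NETWORKS = ("DMN", "DAN", "VAN", "FPN")
NETWORK_PAIRS = tuple(itertools.combinations(ANALYSIS_NETWORKS, 2))


class FcError(ValueError):
    """Invalid input to the functional-connectivity pipeline."""


def _pair_name(a: str, b: str) -> str:
    return f"{a}-{b}"


# ---------------------------------------------------------------------------
# Network assignment
# ---------------------------------------------------------------------------

def assign_networks(overlaps: pd.DataFrame) -> pd.Series:
    """Assign each region to the network with maximal voxel overlap.

    ``overlaps`` is a long table with columns ``region_id, network,
    voxel_count`` (counts >= 0).  Ties are broken deterministically toward
    the lowest network index in the order DMN, DAN, VAN, FPN, other, and
    logged.  A region whose overlaps are all zero is an error.

    Returns a Series region_id -> network label.
    """
    required = {"region_id", "network", "voxel_count"}
    missing = required - set(overlaps.columns)
    if missing:
        raise FcError(f"overlap table missing columns: {sorted(missing)}")
    if (overlaps["voxel_count"] < 0).any():
        raise FcError("voxel counts must be non-negative")
    order = {n: i for i, n in enumerate((*ANALYSIS_NETWORKS, "other"))}
    unknown = sorted(set(overlaps["network"]) - set(order))
    if unknown:
        raise FcError(f"unknown network labels in overlap table: {unknown}")

    assigned: dict = {}
    for region, grp in overlaps.groupby("region_id", sort=False):
        counts = grp.groupby("network")["voxel_count"].sum()
        if (counts <= 0).all():
            raise FcError(f"region {region!r} has no positive network overlap")
        best = counts.max()
        winners = sorted(counts.index[counts == best], key=order.__getitem__)
        if len(winners) > 1:
            logger.info("region %r overlap tie between %s; assigned %s",
                        region, winners, winners[0])
        assigned[region] = winners[0]
    return pd.Series(assigned, name="network").rename_axis("region_id")


# ---------------------------------------------------------------------------
# Connectivity
# ---------------------------------------------------------------------------

def timeseries_to_fc(timeseries: np.ndarray | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of regional timeseries.

    ``timeseries`` has rows = timepoints and columns = regions (a DataFrame
    keeps its column labels).  Requires >= 3 timepoints and no constant
    region series.
    """
    if isinstance(timeseries, pd.DataFrame):
        labels = list(timeseries.columns)
        arr = timeseries.to_numpy(dtype=float)
    else:
        arr = np.asarray(timeseries, dtype=float)
        labels = list(range(arr.shape[1])) if arr.ndim == 2 else []
    if arr.ndim != 2:
        raise FcError("timeseries must be 2-D (timepoints × regions)")
    if arr.shape[0] < 3:
        raise FcError("need at least 3 timepoints to estimate correlations")
    sd = arr.std(axis=0)
    constant = [labels[j] for j in np.flatnonzero(sd == 0)]
    if constant:
        raise FcError(f"constant timeseries for regions: {constant}")
    corr = np.corrcoef(arr, rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=labels, columns=labels)


def network_pair_fc(
    fc: pd.DataFrame | np.ndarray,
    assignment: pd.Series | np.ndarray,
    subject_id: str | None = None,
) -> pd.Series:
    """Raw and normalized mean FC for each between-network pair.

    The raw value for pair (A, B) averages the correlations over all region
    pairs with one region in A and one in B (between-network pairs only);
    the whole-brain mean averages every off-diagonal unordered region pair,
    including within-network pairs and regions assigned ``other``;
    normalized = raw / whole-brain mean.  A non-positive whole-brain mean
    makes the normalization undefined and is an error.

    Returns a Series with ``raw_A-B`` and ``norm_A-B`` entries for the six
    pairs plus ``whole_brain_mean`` (and ``subject_id`` if given).
    """
    mat = fc.to_numpy(dtype=float) if isinstance(fc, pd.DataFrame) else np.asarray(fc, dtype=float)
    nets = np.asarray(assignment.values if isinstance(assignment, pd.Series) else assignment)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise FcError("connectivity matrix must be square")
    if len(nets) != mat.shape[0]:
        raise FcError("assignment length does not match the connectivity matrix")
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise FcError("connectivity matrix must be symmetric")
    if not np.isfinite(mat).all():
        raise FcError("connectivity matrix contains non-finite values")

    empty = [n for n in ANALYSIS_NETWORKS if not (nets == n).any()]
    if empty:
        raise FcError(f"analysis networks with no region: {empty}")

    n = mat.shape[0]
    off = ~np.eye(n, dtype=bool)
    whole = mat[off].mean()
    if whole <= 0:
        raise FcError("whole-brain mean FC is not positive; normalization undefined")

    out: dict[str, float] = {}
    for a, b in NETWORK_PAIRS:
        block = mat[np.ix_(nets == a, nets == b)]
        raw = block.mean()
        out[f"raw_{_pair_name(a, b)}"] = raw
        out[f"norm_{_pair_name(a, b)}"] = raw / whole
    out["whole_brain_mean"] = whole
    result = pd.Series(out)
    if subject_id is not None:
        result["subject_id"] = subject_id
    return result


def profile_subjects(
    timeseries: dict[str, np.ndarray | pd.DataFrame],
    assignment: pd.Series | np.ndarray,
) -> pd.DataFrame:
    """Normalized FC profiles for a set of subjects.

    ``timeseries`` maps subject_id to a (timepoints × regions) array whose
    columns follow the same region order as ``assignment``.
    """
    rows = []
    for sid, ts in timeseries.items():
        fc = timeseries_to_fc(ts)
        rows.append(network_pair_fc(fc, assignment, subject_id=sid))
    profiles = pd.DataFrame(rows).set_index("subject_id")
    return profiles.astype(float)


def group_fc_table(profiles: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-group mean (SD) of normalized FC per network pair.

    ``groups`` maps subject_id to a group label.  Returns a tidy table with
    one row per group × pair: ``group, pair, mean, sd, n``.  SD is reported
    as 0 for single-subject groups.
    """
    joined = profiles.join(groups.rename("group"), how="inner")
    if joined.empty:
        raise FcError("no overlap between profiles and group labels")
    rows = []
    for group, grp in joined.groupby("group", sort=False):
        for a, b in NETWORK_PAIRS:
            col = f"norm_{_pair_name(a, b)}"
            vals = grp[col]
            sd = vals.std(ddof=1)
            rows.append({
                "group": group,
                "pair": _pair_name(a, b),
                "mean": vals.mean(),
                "sd": 0.0 if np.isnan(sd) else sd,
                "n": len(vals),
            })
    return pd.DataFrame(rows)
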