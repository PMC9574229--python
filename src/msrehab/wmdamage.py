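"""White-matter damage metrics from FA-skeleton voxel vectors.

Each subject's fractional anisotropy (FA) values on the white-matter
skeleton are z-scored voxelwise against a healthy-control reference
(per-voxel mean and SD).  Two whole-skeleton summaries follow:

* **severity** — the mean voxelwise z-score (0 in an intact brain, negative
  with diffuse FA loss);
* **extent** — the number of voxels with z strictly below −3.1, i.e. more
  extreme in the damage direction than a z of −3.1 (lower FA = damage).

Both summaries consume precomputed skeleton voxel vectors; tensor fitting,
registration and skeletonization are upstream concerns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["EXTENT_THRESHOLD", "voxel_zscores", "damage_summary"]

#: z threshold below which a skeleton voxel counts toward the damage extent.
EXTENT_THRESHOLD = -3.1


class WmError(ValueError):
    """Invalid input to the white-matter damage pipeline."""


def voxel_zscores(maps: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Voxelwise z-scores of subject FA maps against the HC reference.

    ``maps`` is subjects × voxels; ``reference`` has per-voxel ``mean`` and
    ``sd`` columns indexed by the same voxels (order-sensitive).
    """
    for col in ("mean", "sd"):
        if col not in reference.columns:
            raise WmError(f"reference is missing the {col!r} column")
    if maps.shape[1] != len(reference):
        raise WmError(
            f"voxel count mismatch: maps have {maps.shape[1]}, reference {len(reference)}"
        )
    if list(maps.columns) != list(reference.index):
        raise WmError("voxel labels of maps and reference do not match")
    sd = reference["sd"].to_numpy(dtype=float)
    if not (sd > 0).all():
        raise WmError("reference SD must be positive for every voxel")
    mean = reference["mean"].to_numpy(dtype=float)
    z = (maps.to_numpy(dtype=float) - mean) / sd
    if not np.isfinite(z).all():
        raise WmError("non-finite z-scores; check input FA values")
    return pd.DataFrame(z, index=maps.index, columns=maps.columns)


def damage_summary(
    z: pd.DataFrame | np.ndarray,
    threshold: float = EXTENT_THRESHOLD,
) -> pd.DataFrame:
    """Severity (mean z) and extent (# voxels with z < threshold) per subject.

    Accepts a subjects × voxels z-score frame (or a 1-D vector for a single
    subject).  The extent comparison is strict: a voxel at exactly the
    threshold does not count.
    """
    if isinstance(z, np.ndarray) and z.ndim == 1:
        z = pd.DataFrame(z[None, :], index=pd.Index(["subject"], name="subject_id"))
    elif isinstance(z, np.ndarray):
        z = pd.DataFrame(z)
    arr = z.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise WmError("z-scores must be finite")
    return pd.DataFrame({
        "severity": arr.mean(axis=1),
        "extent": (arr < threshold).sum(axis=1),
    }, index=z.index)
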