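"""Synthetic cohort generator for rehabilitation-response pipelines.

Emulates a three-arm trial design: healthy controls assessed once at
baseline, a waiting-list control arm and an intervention arm each assessed
at baseline (T0), post-intervention (T1) and follow-up (T2).  The generator
produces

* longitudinal cognitive test scores with test-level practice effects and a
  latent responder subgroup in the intervention arm,
* network-structured resting-state timeseries whose whole-brain-normalized
  between-network connectivity matches requested target ratios, and
* Gaussian FA-skeleton voxel maps with a group-level damage shift against a
  healthy-control voxelwise reference.

Score model
-----------
For subject *i* on test *t* the score at session *k* is

    y_itk = mu_t + u_it + k * practice_t + gain_it * [k >= 1] + e_itk

with ``u_it ~ N(0, rho * sd_t^2)`` a stable subject-by-test ability,
``e_itk ~ N(0, (1 - rho) * sd_t^2)`` session noise, so the marginal SD is
``sd_t`` and the test-retest correlation is ``rho`` (``retest_reliability``).
Change scores therefore have SD ``sd_t * sqrt(2 * (1 - rho))``.  Latent
responders receive ``responder_gain[t]`` (in units of the test's score SD,
in the improvement direction) from the first retest onward.  Scores are
independent across tests given the subject.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .battery import DEFAULT_BATTERY, TestDef

__all__ = [
    "CohortConfig",
    "FcGenConfig",
    "SkeletonGenConfig",
    "NetworkCovariance",
    "generate_scores",
    "generate_covariates",
    "immediate_effect_config",
    "construct_network_covariance",
    "generate_timeseries",
    "generate_skeleton_maps",
    "NETWORK_ORDER",
]

ARMS = ("HC", "waitlist", "intervention")
NETWORK_ORDER = ("DMN", "DAN", "VAN", "FPN")

#: Default between-network normalized-FC targets (healthy-control level).
DEFAULT_NORM_FC_TARGETS: dict[tuple[str, str], float] = {
    ("DMN", "DAN"): 0.81,
    ("DMN", "VAN"): 0.81,
    ("DMN", "FPN"): 1.05,
    ("DAN", "VAN"): 1.21,
    ("DAN", "FPN"): 1.11,
    ("VAN", "FPN"): 0.94,
}


class ConfigError(ValueError):
    """Invalid generator configuration."""


# ---------------------------------------------------------------------------
# Cognitive scores
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Configuration for the longitudinal cognitive-score generator.

    Arm sizes default to the trial design this package targets (21 healthy
    controls, 24 waiting-list, 58 intervention).  ``responder_gain`` maps
    test_id to the latent responders' mean gain in units of that test's
    score SD, applied from the first retest onward in the improvement
    direction.  The default gain profile concentrates improvement on working
    and verbal memory, the domains where trained patients most often show
    reliable gains.
    """

    n_hc: int = 21
    n_waitlist: int = 24
    n_intervention: int = 58
    responder_fraction: float = 22 / 58
    test_params: tuple[TestDef, ...] = DEFAULT_BATTERY
    responder_gain: dict[str, float] = field(
        default_factory=lambda: {"LNS": 2.0, "DSB": 2.0, "CVLT": 2.0}
    )
    retest_reliability: float = 0.75
    timepoints: tuple[str, ...] = ("T0", "T1", "T2")
    include_hc_followup: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_hc", "n_waitlist", "n_intervention"):
            if getattr(self, name) < 2:
                raise ConfigError(f"{name} must be >= 2")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ConfigError("responder_fraction must lie in [0, 1]")
        if not 0.0 <= self.retest_reliability < 1.0:
            raise ConfigError("retest_reliability must lie in [0, 1)")
        if len(self.timepoints) < 1:
            raise ConfigError("at least one timepoint required")
        for t in self.test_params:
            if t.hc_sd <= 0 or t.patient_sd <= 0:
                raise ConfigError(f"non-positive SD for test {t.test_id!r}")
        unknown = set(self.responder_gain) - {t.test_id for t in self.test_params}
        if unknown:
            raise ConfigError(f"responder_gain refers to unknown tests: {sorted(unknown)}")


def generate_scores(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a tidy longitudinal score table plus latent truth labels.

    Returns
    -------
    scores : DataFrame with columns ``subject_id, arm, timepoint, test_id,
        value, higher_is_better`` — one row per subject × test × applicable
        timepoint.  Healthy controls are assessed only at baseline unless
        ``include_hc_followup`` is set (such rows are flagged
        ``canonical=False``).
    truth : DataFrame with one row per subject: ``subject_id, arm,
        is_latent_responder``.
    """
    rng = np.random.default_rng(config.seed)
    rho = config.retest_reliability
    tps = list(config.timepoints)
    k = len(tps)

    arm_sizes = (("HC", config.n_hc), ("waitlist", config.n_waitlist),
                 ("intervention", config.n_intervention))
    n_resp = int(round(config.responder_fraction * config.n_intervention))
    subject_id = np.concatenate([
        np.array([f"{arm}_{j + 1:0{max(3, len(str(n)))}d}" for j in range(n)])
        for arm, n in arm_sizes
    ])
    arm = np.concatenate([np.full(n, a) for a, n in arm_sizes])
    is_resp = np.concatenate([
        np.zeros(config.n_hc + config.n_waitlist, dtype=bool),
        np.arange(config.n_intervention) < n_resp,
    ])
    n_sub = len(arm)
    is_hc = arm == "HC"

    frames: list[pd.DataFrame] = []
    for t in config.test_params:
        gain_sd = config.responder_gain.get(t.test_id, 0.0)
        sign = 1.0 if t.higher_is_better else -1.0
        mean = np.where(is_hc, t.hc_mean, t.patient_mean)
        sd = np.where(is_hc, t.hc_sd, t.patient_sd)
        u = rng.normal(0.0, 1.0, n_sub) * np.sqrt(rho) * sd
        e = rng.normal(0.0, 1.0, (n_sub, k)) * (np.sqrt(1.0 - rho) * sd)[:, None]
        retest = np.arange(k)
        vals = (mean + u)[:, None] + e + retest * t.practice_effect
        vals += np.outer(is_resp, retest >= 1) * sign * gain_sd * t.patient_sd
        keep = (~is_hc[:, None]) | (retest == 0) | config.include_hc_followup
        frames.append(pd.DataFrame({
            "subject_id": np.repeat(subject_id, k)[keep.ravel()],
            "arm": np.repeat(arm, k)[keep.ravel()],
            "timepoint": np.tile(tps, n_sub)[keep.ravel()],
            "test_id": t.test_id,
            "value": vals.ravel()[keep.ravel()],
            "higher_is_better": t.higher_is_better,
        }))

    scores = pd.concat(frames, ignore_index=True)
    canonical = ~((scores["arm"] == "HC") & (scores["timepoint"] != tps[0]))
    scores["canonical"] = canonical
    truth = pd.DataFrame({
        "subject_id": subject_id,
        "arm": arm,
        "is_latent_responder": is_resp,
    })
    return scores, truth


def generate_covariates(truth: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Demographic/clinical/volumetric covariates for generated subjects.

    Draws age, sex, education, EDSS (patients only), cortical grey-matter
    volume and white-matter damage severity from Gaussian/categorical models
    at cohort-typical levels.  Covariates are independent of latent responder
    status, matching a trial in which demographics and structural measures do
    not separate responders from non-responders.
    """
    rng = np.random.default_rng(seed)
    n = len(truth)
    is_hc = (truth["arm"] == "HC").to_numpy()
    df = pd.DataFrame({
        "subject_id": truth["subject_id"],
        "arm": truth["arm"],
        "age": np.where(is_hc, rng.normal(50.3, 10.2, n), rng.normal(48.5, 9.9, n)),
        "sex_female": rng.random(n) < np.where(is_hc, 0.714, 0.646),
        "education": rng.integers(3, 8, n),
        "edss": np.where(is_hc, np.nan, np.clip(rng.normal(4.0, 1.5, n), 0, 7.5)),
        "cortical_gmv": np.where(is_hc, rng.normal(800.1, 39.4, n), rng.normal(736.4, 69.4, n)),
    })
    return df


def immediate_effect_config(
    *,
    test: TestDef,
    baseline_mean: float,
    baseline_sd: float,
    followup_mean: float,
    practice_effect: float,
    n_intervention: int,
    responder_fraction: float = 22 / 58,
    seed: int = 0,
) -> CohortConfig:
    """Single-test cohort config calibrated to printed arm-level cell means.

    Solves the latent responder gain so that the intervention arm's expected
    post-intervention mean equals ``followup_mean`` given the baseline
    parameters and the untreated practice effect:

        followup_mean = baseline_mean + practice_effect
                        ± responder_fraction * gain * baseline_sd

    (sign per the test's improvement direction).
    """
    if responder_fraction <= 0:
        raise ConfigError("responder_fraction must be positive to calibrate a gain")
    sign = 1.0 if test.higher_is_better else -1.0
    gain = sign * (followup_mean - baseline_mean - practice_effect) / (
        responder_fraction * baseline_sd
    )
    calibrated = replace(
        test,
        patient_mean=baseline_mean,
        patient_sd=baseline_sd,
        practice_effect=practice_effect,
    )
    return CohortConfig(
        n_hc=2,
        n_waitlist=2,
        n_intervention=n_intervention,
        responder_fraction=responder_fraction,
        test_params=(calibrated,),
        responder_gain={test.test_id: gain},
        timepoints=("T0", "T1"),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Network-structured timeseries
# ---------------------------------------------------------------------------

def _canon_pair(pair) -> tuple[str, str]:
    if isinstance(pair, str):
        a, b = pair.split("-")
    else:
        a, b = pair
    order = {n: i for i, n in enumerate(NETWORK_ORDER)}
    if a not in order or b not in order or a == b:
        raise ConfigError(f"invalid network pair {pair!r}")
    return (a, b) if order[a] < order[b] else (b, a)


@dataclass
class FcGenConfig:
    """Configuration for the block-covariance timeseries generator.

    ``n_regions`` gives the number of atlas regions per resting-state
    network, with an ``"other"`` block for regions outside the four analysis
    networks.  ``target_norm_fc`` maps each unordered analysis-network pair
    to the desired normalized FC: the mean correlation of the between-network
    block divided by the mean off-diagonal correlation of the whole matrix.
    ``global_mean_corr`` is that whole-brain mean.
    """

    n_regions: dict[str, int] = field(default_factory=lambda: {
        "DMN": 12, "DAN": 8, "VAN": 8, "FPN": 10, "other": 22,
    })
    global_mean_corr: float = 0.2
    target_norm_fc: dict = field(default_factory=lambda: dict(DEFAULT_NORM_FC_TARGETS))
    n_timepoints: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        for net in (*NETWORK_ORDER, "other"):
            if self.n_regions.get(net, 0) < 1:
                raise ConfigError(f"need at least one region in block {net!r}")
        if not 0.0 < self.global_mean_corr < 1.0:
            raise ConfigError("global_mean_corr must lie in (0, 1)")
        self.target_norm_fc = {_canon_pair(p): float(v) for p, v in self.target_norm_fc.items()}
        missing = set(itertools.combinations(NETWORK_ORDER, 2)) - set(self.target_norm_fc)
        if missing:
            raise ConfigError(f"missing normalized-FC targets for pairs {sorted(missing)}")
        for p, v in self.target_norm_fc.items():
            if v <= 0:
                raise ConfigError(f"target for pair {p} must be positive")
        if self.n_timepoints < 3:
            raise ConfigError("n_timepoints must be >= 3")


@dataclass
class NetworkCovariance:
    """A constructed region×region correlation matrix with provenance.

    ``achieved`` re-reports the normalized FC ratios realized by the final
    matrix (identical to the request unless PSD projection was needed).
    """

    matrix: np.ndarray
    networks: np.ndarray  # region -> network label, block order
    requested: dict[tuple[str, str], float]
    achieved: dict[tuple[str, str], float]
    projected: bool


def _block_slices(n_regions: dict[str, int]) -> dict[str, slice]:
    out, start = {}, 0
    for net in (*NETWORK_ORDER, "other"):
        n = n_regions[net]
        out[net] = slice(start, start + n)
        start += n
    return out


def _achieved_ratios(mat: np.ndarray, n_regions: dict[str, int]) -> dict[tuple[str, str], float]:
    sl = _block_slices(n_regions)
    n = mat.shape[0]
    off = ~np.eye(n, dtype=bool)
    whole = mat[off].mean()
    return {
        (a, b): mat[sl[a], sl[b]].mean() / whole
        for a, b in itertools.combinations(NETWORK_ORDER, 2)
    }


def construct_network_covariance(config: FcGenConfig) -> NetworkCovariance:
    """Build a block-constant correlation matrix realizing normalized-FC targets.

    Between-network analysis blocks are set to ``target * g`` with ``g`` the
    requested whole-brain mean correlation; every remaining off-diagonal
    entry (within-network and anything involving the "other" block) takes
    the common value that makes the whole-brain off-diagonal mean exactly
    ``g``, so each achieved ratio equals its target.  If the result is not
    positive semi-definite it is projected onto the PSD cone (eigenvalue
    clipping, diagonal renormalized) and the achieved ratios are re-reported
    from the projected matrix.
    """
    g = config.global_mean_corr
    sl = _block_slices(config.n_regions)
    n = sum(config.n_regions[k] for k in (*NETWORK_ORDER, "other"))
    pairs_total = n * (n - 1) // 2

    block_vals: dict[tuple[str, str], float] = {}
    n_targeted = 0
    sum_targeted = 0.0
    for (a, b), t in config.target_norm_fc.items():
        v = t * g
        if abs(v) >= 1.0:
            raise ConfigError(
                f"unsatisfiable target for pair {a}-{b}: implied correlation {v:.3f}"
            )
        block_vals[(a, b)] = v
        n_ab = config.n_regions[a] * config.n_regions[b]
        n_targeted += n_ab
        sum_targeted += n_ab * v

    rest = pairs_total - n_targeted
    if rest <= 0:
        raise ConfigError("no untargeted region pairs left to balance the whole-brain mean")
    w = (g * pairs_total - sum_targeted) / rest
    if abs(w) >= 1.0:
        raise ConfigError(
            f"unsatisfiable configuration: balancing correlation {w:.3f} outside (-1, 1)"
        )

    mat = np.full((n, n), w)
    for (a, b), v in block_vals.items():
        mat[sl[a], sl[b]] = v
        mat[sl[b], sl[a]] = v
    np.fill_diagonal(mat, 1.0)

    projected = False
    eigval = np.linalg.eigvalsh(mat)
    if eigval[0] < -1e-10:
        evals, evecs = np.linalg.eigh(mat)
        mat = (evecs * np.clip(evals, 0.0, None)) @ evecs.T
        d = np.sqrt(np.diag(mat))
        mat = mat / np.outer(d, d)
        mat = (mat + mat.T) / 2.0
        projected = True

    networks = np.concatenate([
        np.full(config.n_regions[net], net) for net in (*NETWORK_ORDER, "other")
    ])
    return NetworkCovariance(
        matrix=mat,
        networks=networks,
        requested=dict(config.target_norm_fc),
        achieved=_achieved_ratios(mat, config.n_regions),
        projected=projected,
    )


def generate_timeseries(
    cov: np.ndarray | NetworkCovariance,
    n_timepoints: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw a zero-mean Gaussian timeseries (timepoints × regions).

    The sample covariance converges to ``cov`` as the series length grows.
    Rank-deficient (PSD but singular) covariances are supported via an
    eigenvalue factorization.
    """
    if isinstance(cov, NetworkCovariance):
        cov = cov.matrix
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be a square matrix")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] < -1e-8 * max(1.0, evals[-1]):
        raise ValueError("covariance is not positive semi-definite")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    factor = evecs * np.sqrt(np.clip(evals, 0.0, None))
    z = rng.standard_normal((n_timepoints, cov.shape[0]))
    return z @ factor.T


# ---------------------------------------------------------------------------
# FA-skeleton maps
# ---------------------------------------------------------------------------

@dataclass
class SkeletonGenConfig:
    """Configuration for Gaussian FA-skeleton map generation.

    ``hc_mean``/``hc_sd`` are the per-voxel reference parameters (scalars are
    broadcast).  ``group_shift`` is the mean FA decrement in HC-SD units; a
    healthy group uses shift 0.  ``subject_sd`` adds a subject-level global
    offset (in z units) reproducing the between-subject dispersion of mean
    skeleton z-scores seen in healthy cohorts (~0.23).
    """

    n_voxels: int = 2000
    hc_mean: float | np.ndarray = 0.45
    hc_sd: float | np.ndarray = 0.035
    group_shift: float = 0.0
    subject_sd: float = 0.23
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise ConfigError("n_voxels must be >= 1")
        if np.any(np.asarray(self.hc_sd) <= 0):
            raise ConfigError("hc_sd must be positive")
        if self.subject_sd < 0:
            raise ConfigError("subject_sd must be non-negative")


def generate_skeleton_maps(
    config: SkeletonGenConfig,
    n_subjects: int,
    seed: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate subject × voxel FA maps plus the HC voxelwise reference.

    Subject FA at voxel *v* is ``N(mean_v - (shift - delta_i) * sd_v, sd_v^2)``
    with ``delta_i ~ N(0, subject_sd^2)`` a per-subject global offset, so the
    expected mean voxelwise z-score equals ``-group_shift``.

    Returns ``(maps, reference)``: maps indexed by subject_id with one column
    per voxel; reference with per-voxel ``mean`` and ``sd``.
    """
    if n_subjects < 1:
        raise ConfigError("n_subjects must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        config.seed if seed is None else seed
    )
    mean = np.broadcast_to(np.asarray(config.hc_mean, dtype=float), (config.n_voxels,))
    sd = np.broadcast_to(np.asarray(config.hc_sd, dtype=float), (config.n_voxels,))
    delta = rng.normal(0.0, config.subject_sd, size=n_subjects)
    z = rng.standard_normal((n_subjects, config.n_voxels))
    fa = mean + sd * (z + delta[:, None] - config.group_shift)
    voxels = [f"v{j:05d}" for j in range(config.n_voxels)]
    maps = pd.DataFrame(fa, columns=voxels,
                        index=pd.Index([f"s{i + 1:03d}" for i in range(n_subjects)],
                                       name="subject_id"))
    reference = pd.DataFrame({"mean": mean, "sd": sd}, index=pd.Index(voxels, name="voxel"))
    return maps, reference
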