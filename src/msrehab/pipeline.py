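"""End-to-end reproducible run: generate → classify → profile → predict.

A single seeded configuration drives the whole analysis: synthesize (or
load) a cohort, classify responders via the practice-corrected reliable
change index, compute normalized between-network FC profiles and
white-matter damage summaries, produce the group tables, fit the blockwise
backward logistic prediction model, and write a machine-readable manifest
(config hash, seed, package versions) so a run can be reconstructed
byte-for-byte.

Synthetic runs draw each subject's resting-state timeseries from a block
covariance matched to that subject's group: healthy-control-level
connectivity for HC and latent responders, elevated DMN–attention coupling
for latent non-responders — the connectivity regime the pipeline is meant
to detect and exploit for prediction.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import battery, netfc, rci, stats, synth, wmdamage

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "DEFAULT_GROUP_FC_TARGETS"]

logger = logging.getLogger(__name__)

#: Baseline normalized-FC targets per generated group.  Healthy controls and
#: latent responders sit at healthy-control-level coupling; non-responders
#: show the elevated DMN–attention connectivity associated with
#: non-response; the waiting-list arm sits at the overall patient level.
DEFAULT_GROUP_FC_TARGETS: dict[str, dict[tuple[str, str], float]] = {
    "HC": dict(synth.DEFAULT_NORM_FC_TARGETS),
    "waitlist": {
        ("DMN", "DAN"): 0.89, ("DMN", "VAN"): 0.87, ("DMN", "FPN"): 1.14,
        ("DAN", "VAN"): 1.12, ("DAN", "FPN"): 1.19, ("VAN", "FPN"): 0.98,
    },
    "responder": {
        ("DMN", "DAN"): 0.84, ("DMN", "VAN"): 0.87, ("DMN", "FPN"): 1.18,
        ("DAN", "VAN"): 1.13, ("DAN", "FPN"): 1.13, ("VAN", "FPN"): 1.00,
    },
    "non_responder": {
        ("DMN", "DAN"): 0.92, ("DMN", "VAN"): 0.98, ("DMN", "FPN"): 1.18,
        ("DAN", "VAN"): 1.20, ("DAN", "FPN"): 1.25, ("VAN", "FPN"): 1.06,
    },
}

#: Mean FA-skeleton damage shift (HC-SD units) per generated group.
DEFAULT_GROUP_WM_SHIFT: dict[str, float] = {
    "HC": 0.0,
    "waitlist": 0.25,
    "responder": 0.17,
    "non_responder": 0.32,
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run.

    Either provide input paths (``scores_csv`` plus optional imaging inputs)
    or rely on the synthetic generator sections.  All decision thresholds
    are surfaced here rather than hard-coded downstream.
    """

    outdir: str = "msrehab_run"
    seed: int = 0
    threshold: float = rci.RCI_THRESHOLD
    min_domains_improved: int = 2
    from_timepoint: str = "T0"
    to_timepoint: str = "T1"
    # input-path mode
    scores_csv: str | None = None
    covariates_csv: str | None = None
    timeseries_dir: str | None = None
    overlaps_csv: str | None = None
    skeleton_maps_csv: str | None = None
    skeleton_ref_csv: str | None = None
    # synthetic mode
    cohort: synth.CohortConfig = field(default_factory=synth.CohortConfig)
    fc: synth.FcGenConfig = field(default_factory=synth.FcGenConfig)
    skeleton: synth.SkeletonGenConfig = field(default_factory=synth.SkeletonGenConfig)
    group_fc_targets: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_GROUP_FC_TARGETS.items()}
    )
    #: between-subject SD of each normalized-FC ratio around its group mean
    fc_between_subject_sd: float = 0.12
    group_wm_shift: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_WM_SHIFT))

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if not 1 <= self.min_domains_improved <= 6:
            raise ValueError("min_domains_improved must lie in 1..6")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a run configuration from YAML or JSON."""
        path = Path(path)
        raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
        for key, sub in (("cohort", synth.CohortConfig),
                         ("fc", synth.FcGenConfig),
                         ("skeleton", synth.SkeletonGenConfig)):
            if key in raw and isinstance(raw[key], dict):
                section = dict(raw[key])
                if key == "cohort" and "test_params" in section:
                    section["test_params"] = tuple(
                        battery.TestDef(**t) for t in section["test_params"]
                    )
                raw[key] = sub(**section)
        return cls(**raw)

    def config_hash(self) -> str:
        """SHA-256 over a canonical JSON rendering of the configuration.

        The output directory is excluded: it locates a run, it does not
        define one — two runs into different directories with the same
        scientific configuration hash identically.
        """
        def canon(o):
            if hasattr(o, "__dataclass_fields__"):
                o = asdict(o)
            if isinstance(o, dict):
                return sorted((str(k), canon(v)) for k, v in o.items())
            if isinstance(o, (list, tuple)):
                return [canon(v) for v in o]
            if isinstance(o, (str, int, float, bool)) or o is None:
                return o
            return str(o)
        payload = asdict(self)
        payload.pop("outdir", None)
        blob = json.dumps(canon(payload), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, time.perf_counter() - self.t0)
            return False
    return _Ctx()


def _subject_fc_group(row: pd.Series) -> str:
    if row["arm"] == "intervention":
        return "responder" if row["is_latent_responder"] else "non_responder"
    return str(row["arm"])


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and return the report as a dictionary.

    Writes responder labels, FC profiles, damage summaries, group tables,
    the prediction report and a run manifest under ``config.outdir``.  Any
    stage error aborts with the stage name.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    rng_fc = np.random.default_rng(seeds[1])
    rng_wm = np.random.default_rng(seeds[2])
    outputs: dict[str, str] = {}

    def save(df: pd.DataFrame, name: str, **kw) -> None:
        path = outdir / name
        df.to_csv(path, **kw)
        outputs[name] = str(path)

    # ---- scores ----------------------------------------------------------
    with _stage("scores"):
        if config.scores_csv is not None:
            scores = pd.read_csv(config.scores_csv)
            truth = None
        else:
            cohort = synth.CohortConfig(**{**asdict(config.cohort),
                                           "test_params": config.cohort.test_params,
                                           "seed": int(seeds[0].generate_state(1)[0] % 2**31)})
            scores, truth = synth.generate_scores(cohort)
            save(scores, "scores.csv", index=False)
            save(truth, "truth_labels.csv", index=False)
        if config.covariates_csv is not None:
            covariates = pd.read_csv(config.covariates_csv)
        elif truth is not None:
            covariates = synth.generate_covariates(
                truth, seed=int(seeds[3].generate_state(1)[0] % 2**31))
            save(covariates, "covariates.csv", index=False)
        else:
            covariates = None

    # ---- reliable change and responder labels ----------------------------
    with _stage("classify"):
        aligned = rci.align_direction(scores, battery.direction_map())
        ctrl = rci.control_change_stats(aligned, config.from_timepoint, config.to_timepoint)
        deltas = rci.change_scores(aligned, config.from_timepoint, config.to_timepoint)
        records = rci.compute_rci(deltas[deltas["arm"] == "intervention"],
                                  ctrl, threshold=config.threshold)
        labels = rci.classify_responder(
            records, battery.domain_map(),
            min_domains_improved=config.min_domains_improved)
        summary = rci.responder_summary(labels)
        save(records, "rci_records.csv", index=False)
        save(labels, "responder_labels.csv", index=False)

    # ---- HC-referenced cognition -----------------------------------------
    with _stage("cognition"):
        test_z, domain_z, avg_cog = rci.hc_zscores(aligned)
        impaired = rci.impairment_flag(test_z)
        cognition = domain_z.copy()
        cognition["average_cognition"] = avg_cog
        cognition["impaired"] = impaired
        save(cognition, "cognition_zscores.csv")

    # ---- functional connectivity -----------------------------------------
    with _stage("fc"):
        group_of: pd.Series
        if config.timeseries_dir is not None and config.overlaps_csv is not None:
            overlaps = pd.read_csv(config.overlaps_csv)
            assignment = netfc.assign_networks(overlaps)
            ts = {
                p.stem: pd.read_csv(p).to_numpy(dtype=float)
                for p in sorted(Path(config.timeseries_dir).glob("*.csv"))
            }
            profiles = netfc.profile_subjects(ts, assignment)
            group_of = pd.Series("all", index=profiles.index)
        elif truth is not None:
            fc_groups = truth.apply(_subject_fc_group, axis=1)
            group_of = pd.Series(fc_groups.values, index=truth["subject_id"])
            # per-subject targets jittered around the group means, mirroring
            # the between-subject spread of normalized FC in real cohorts
            ts, networks = {}, None
            for sid in truth["subject_id"]:
                mu = config.group_fc_targets[group_of[sid]]
                targets = {
                    pair: max(0.05, rng_fc.normal(v, config.fc_between_subject_sd))
                    for pair, v in mu.items()
                }
                cfg = synth.FcGenConfig(**{**asdict(config.fc),
                                           "target_norm_fc": targets})
                cov = synth.construct_network_covariance(cfg)
                networks = cov.networks
                ts[sid] = synth.generate_timeseries(cov, config.fc.n_timepoints, rng_fc)
            assignment = pd.Series(networks, index=pd.RangeIndex(len(networks)))
            profiles = netfc.profile_subjects(ts, assignment)
        else:
            profiles, group_of = None, None
        if profiles is not None:
            fc_table = netfc.group_fc_table(profiles, group_of)
            save(profiles, "fc_profiles.csv")
            save(fc_table, "fc_group_table.csv", index=False)

    # ---- white-matter damage ---------------------------------------------
    with _stage("wmdamage"):
        if config.skeleton_maps_csv is not None and config.skeleton_ref_csv is not None:
            maps = pd.read_csv(config.skeleton_maps_csv, index_col=0)
            reference = pd.read_csv(config.skeleton_ref_csv, index_col=0)
            damage = wmdamage.damage_summary(wmdamage.voxel_zscores(maps, reference))
            damage_groups = pd.Series("all", index=damage.index)
        elif truth is not None:
            frames = []
            for g, grp in truth.groupby(truth.apply(_subject_fc_group, axis=1)):
                cfg = synth.SkeletonGenConfig(**{**asdict(config.skeleton),
                                                 "group_shift": config.group_wm_shift[g]})
                maps, reference = synth.generate_skeleton_maps(cfg, len(grp), rng_wm)
                maps.index = pd.Index(grp["subject_id"], name="subject_id")
                frames.append(wmdamage.damage_summary(
                    wmdamage.voxel_zscores(maps, reference)))
            damage = pd.concat(frames)
            damage_groups = pd.Series(
                truth.apply(_subject_fc_group, axis=1).values, index=truth["subject_id"])
        else:
            damage, damage_groups = None, None
        if damage is not None:
            save(damage, "wm_damage.csv")
            dmg_table = (
                damage.join(damage_groups.rename("group"))
                .groupby("group")[["severity", "extent"]]
                .agg(["mean", "std", "count"])
            )
            save(dmg_table, "wm_damage_group_table.csv")

    # ---- baseline contrasts (responders vs non-responders) ---------------
    with _stage("contrasts"):
        contrasts = None
        if covariates is not None:
            lab = labels.set_index("subject_id")["label"]
            base = covariates.set_index("subject_id").join(lab, how="inner")
            base = base[base["label"].isin(["responder", "non_responder"])]
            if base["label"].nunique() == 2:
                variables = ["age", "education", "edss", "cortical_gmv", "sex_female"]
                contrasts = stats.baseline_contrasts(
                    base, "label", variables, categorical=("sex_female",))
                save(contrasts, "baseline_contrasts.csv", index=False)

    # ---- prediction ------------------------------------------------------
    with _stage("predict"):
        prediction = None
        if covariates is not None and profiles is not None and damage is not None:
            lab = labels.set_index("subject_id")["is_responder"]
            feats = (
                covariates.set_index("subject_id")
                .join(profiles[["norm_DMN-FPN", "norm_DMN-DAN", "norm_DMN-VAN"]])
                .join(damage[["severity"]])
                .join(lab)
            )
            feats = feats.dropna(subset=["is_responder"])
            feats["sex_female"] = feats["sex_female"].astype(float)
            blocks = {
                "demographics": ["age", "sex_female", "education", "edss"],
                "volumetrics": ["cortical_gmv"],
                "dti": ["severity"],
                "fc": ["norm_DMN-FPN", "norm_DMN-DAN", "norm_DMN-VAN"],
            }
            y = feats["is_responder"].astype(int).to_numpy()
            if 0 < y.sum() < len(y):
                prediction = stats.backward_logistic(feats, y, blocks)
                report = {
                    "retained": prediction.retained,
                    "coefficients": prediction.coefficients.to_dict(),
                    "pvalues": prediction.pvalues.to_dict(),
                    "eliminated": prediction.eliminated,
                    "nagelkerke_r2": prediction.nagelkerke,
                    "per_class_accuracy_pct": {str(k): v for k, v in
                                               prediction.accuracy.items()},
                    "separation": prediction.separation,
                }
                (outdir / "prediction.json").write_text(
                    json.dumps(report, indent=2), encoding="utf-8")
                outputs["prediction.json"] = str(outdir / "prediction.json")

    # ---- manifest --------------------------------------------------------
    with _stage("manifest"):
        import statsmodels

        manifest = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "threshold": config.threshold,
            "responder_summary": summary,
            "versions": {
                "python": sys.version.split()[0],
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "statsmodels": statsmodels.__version__,
            },
            "outputs": sorted(outputs),
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str), encoding="utf-8")

    return {
        "manifest": manifest,
        "responder_summary": summary,
        "labels": labels,
        "contrasts": contrasts,
        "prediction": prediction,
        "outputs": outputs,
    }
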