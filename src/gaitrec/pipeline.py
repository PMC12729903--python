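"""End-to-end orchestration: simulate -> impute -> augment -> assess ->
cluster/select-K -> validate.

Every stage writes delimited-text artifacts into the run directory and a
``manifest.json`` records per-stage seeds, output hashes and timings.  All
stage seeds derive deterministically from the global seed (CRC32 of
"<seed>:<stage>"), so two runs with the same config produce byte-identical
label files.  A completed stage (outputs present) is skipped on re-run.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .augmentation import TimeSeriesVAE, VAEConfig, augment_cohort
from .assessment import permutation_test
from .dtc import DTCConfig
from .imputation import BritsImputer, ImputerConfig
from .layout import CohortTensor
from .selection import select_k
from .statsval import ANALYSIS_WEEKS, anova_table, feature_table
from .synthetic import CohortSpec, default_archetypes, generate_cohort, normative_vector

STAGES = ("simulate", "impute", "augment", "assess", "select_k", "validate")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) & 0x7FFFFFFF


def smooth_moving_average(trajectory: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge-mirrored padding; window=1 is identity."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    trajectory = np.asarray(trajectory, float)
    if window == 1:
        return trajectory.copy()
    half = window // 2
    padded = np.pad(trajectory, half, mode="symmetric")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def smooth_cohort(cohort: CohortTensor, window: int) -> CohortTensor:
    """Moving-average smoothing applied per channel per patient-week."""
    out = cohort.copy()
    p = cohort.layout.points_per_cycle
    for c, _ in enumerate(cohort.layout.channels):
        sl = slice(c * p, (c + 1) * p)
        for i in range(cohort.n_patients):
            for j in range(cohort.n_weeks):
                if cohort.mask[i, j] == 1:
                    out.values[i, j, sl] = smooth_moving_average(
                        cohort.values[i, j, sl], window
                    )
    return out


@dataclass
class RunConfig:
    """Configuration for a full pipeline run; round-trips through YAML."""

    seed: int = 0
    n_patients: int = 31
    n_archetypes: int = 3
    noise_sd: float = 2.0
    use_missingness: bool = True
    smoothing_window: int = 5
    imputer: dict = field(default_factory=dict)
    vae: dict = field(default_factory=dict)
    dtc: dict = field(default_factory=dict)
    augmentation_ratio: int = 5
    n_permutations: int = 199
    k_min: int = 3
    k_max: int = 10
    n_trials: int = 2
    alpha: float = 0.15
    analysis_weeks: tuple[int, ...] = ANALYSIS_WEEKS

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["analysis_weeks"] = list(d["analysis_weeks"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["analysis_weeks"] = tuple(d.get("analysis_weeks", ANALYSIS_WEEKS))
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig, out_dir: str | Path, force: bool = False) -> dict:
    """Execute the full pipeline, returning the manifest dictionary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": []}
    manifest["config"]["analysis_weeks"] = list(config.analysis_weeks)

    def record(stage: str, seed: int, t0: float, outputs: list[Path]) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "seed": seed,
                "seconds": round(time.time() - t0, 3),
                "outputs": {p.name: _sha256(p) for p in outputs},
            }
        )

    # -- simulate ---------------------------------------------------------
    t0 = time.time()
    seed = stage_seed(config.seed, "simulate")
    spec = CohortSpec(
        n_patients=config.n_patients,
        archetypes=default_archetypes(config.n_archetypes),
        noise_sd=config.noise_sd,
        missingness_profile=_scaled_profile(config.n_patients)
        if config.use_missingness
        else None,
        seed=seed,
    )
    cohort = generate_cohort(spec)
    raw_dir = out / "cohort_raw"
    gio.write_cohort(cohort, raw_dir, seed=seed)
    record("simulate", seed, t0, sorted(raw_dir.iterdir()))

    # -- impute (smoothing + recurrent imputation) ------------------------
    t0 = time.time()
    seed = stage_seed(config.seed, "impute")
    smoothed = smooth_cohort(cohort, config.smoothing_window)
    imputer = BritsImputer(ImputerConfig(seed=seed, **config.imputer))
    imputer.fit(smoothed)
    completed = imputer.impute(smoothed)
    imp_dir = out / "cohort_imputed"
    gio.write_cohort(completed, imp_dir, seed=seed)
    prov = pd.DataFrame(
        {
            "patient_id": np.repeat(completed.patient_ids, completed.n_weeks),
            "week": np.tile(completed.weeks, completed.n_patients),
            "provenance": completed.week_provenance.reshape(-1),
        }
    )
    prov_path = imp_dir / "week_provenance.csv"
    prov.to_csv(prov_path, index=False)
    record("impute", seed, t0, sorted(imp_dir.iterdir()))

    # -- augment ----------------------------------------------------------
    t0 = time.time()
    seed = stage_seed(config.seed, "augment")
    vae = TimeSeriesVAE(VAEConfig(seed=seed, **config.vae))
    vae.fit(completed)
    combined = augment_cohort(completed, vae, ratio=config.augmentation_ratio, seed=seed)
    aug_dir = out / "cohort_augmented"
    gio.write_cohort(combined, aug_dir, seed=seed)
    record("augment", seed, t0, sorted(aug_dir.iterdir()))

    # -- assess -----------------------------------------------------------
    t0 = time.time()
    seed = stage_seed(config.seed, "assess")
    real = combined.values[: completed.n_patients].reshape(completed.n_patients, -1)
    synth = combined.values[completed.n_patients :].reshape(
        combined.n_patients - completed.n_patients, -1
    )
    res = permutation_test(real, synth, n_permutations=config.n_permutations, seed=seed)
    assess_path = out / "augmentation_assessment.csv"
    pd.DataFrame(
        [
            {
                "mmd2_obs": res.mmd2_obs,
                "bandwidth": res.bandwidth,
                "n_permutations": res.n_permutations,
                "p_value": res.p_value,
            }
        ]
    ).to_csv(assess_path, index=False)
    record("assess", seed, t0, [assess_path])

    # -- select_k / cluster ----------------------------------------------
    t0 = time.time()
    seed = stage_seed(config.seed, "select_k")
    base = DTCConfig(**{"K": 2, **config.dtc})
    sel = select_k(
        combined,
        k_range=range(config.k_min, config.k_max + 1),
        n_trials=config.n_trials,
        alpha=config.alpha,
        base_config=base,
        seed=seed,
    )
    sel_path = out / "selection_table.csv"
    sel.table.to_csv(sel_path, index=False)
    labels_path = out / "labels.csv"
    model = sel.best_model
    votes = model.majority_vote_patient_labels(list(combined.patient_ids))
    pd.DataFrame(
        {
            "sample_id": combined.patient_ids,
            "patient_id": [pid.split("_syn")[0] for pid in combined.patient_ids],
            "provenance": combined.provenance,
            "cluster": model.labels,
            "patient_cluster": [
                votes[pid.split("_syn")[0]] for pid in combined.patient_ids
            ],
        }
    ).to_csv(labels_path, index=False)
    record("select_k", seed, t0, [sel_path, labels_path])

    # -- validate ---------------------------------------------------------
    t0 = time.time()
    seed = stage_seed(config.seed, "validate")
    labels_df = pd.read_csv(labels_path)
    real_rows = labels_df[labels_df["provenance"] == "real"]
    label_map = dict(zip(real_rows["patient_id"], real_rows["patient_cluster"]))
    labels = np.array([label_map[pid] for pid in completed.patient_ids])
    reference = normative_vector(completed.layout)
    feats = feature_table(
        completed, labels, reference=reference, weeks=tuple(config.analysis_weeks)
    )
    feats_path = out / "features.csv"
    feats.to_csv(feats_path, index=False)
    outputs = [feats_path]
    anova_path = out / "anova.csv"
    try:
        anova = anova_table(feats)
        anova.to_csv(anova_path, index=False)
        outputs.append(anova_path)
    except ValueError as exc:  # e.g. a single occupied cluster among real patients
        anova_path.write_text(f"error,{exc}\n")
        outputs.append(anova_path)
    record("validate", seed, t0, outputs)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _scaled_profile(n_patients: int) -> dict[int, int]:
    """Rescale the study's missing-week profile to another cohort size."""
    base = {0: 7, 1: 6, 2: 5, 3: 9, 4: 4}
    total = sum(base.values())
    raw = {k: v * n_patients / total for k, v in base.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n_patients - sum(counts.values())
    for k in sorted(base, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


__all__ = [
    "RunConfig",
    "run_all",
    "smooth_moving_average",
    "smooth_cohort",
    "stage_seed",
    "STAGES",
]
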