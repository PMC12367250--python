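"""Orchestration: stratified dataset splitting and the end-to-end pipeline.

The split reproduces the cohort protocol: an 8:1:1 train/validation/test
partition stratified on a BMI-like covariate.  The covariate is binned into
quantile strata; within each stratum cases are shuffled (seeded) and
apportioned by the target fractions with largest-remainder rounding, then
the partition is rebalanced across strata so global split sizes match the
largest-remainder allocation of the whole cohort while each stratum stays
within one case of proportionality.

``run_pipeline`` chains simulate -> split -> train -> segment -> quantify ->
evaluate -> agree on synthetic cohorts, writing every artifact into a run
directory.  One master seed derives per-stage seeds by fixed offsets, so a
rerun with the same config is numerically identical.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import segmetrics
from .agreement import PairedMeasurements, agreement_summary, trend_test
from .imgio import DualVolume, write_dual_volume, write_mask, write_sidecar, znormalize
from .phantom import PhantomCase, PhantomParams, make_cohort
from .quantify import composition_profile, grade_bins, profile_from_truth
from .train import TrainConfig, train_model, validation_dsc
from .unet import SegmentationModel, build_unet, predict_volume, tiny_config

STAGE_SEED_OFFSETS = {"simulate": 1, "split": 2, "train": 3, "segment": 4,
                      "quantify": 5, "agree": 6}


@dataclass(frozen=True)
class SplitSpec:
    fractions: Tuple[float, float, float] = (0.8, 0.1, 0.1)
    stratify_on: str = "bmi"
    n_strata: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if (f <= 0).any():
            raise ValueError("fractions must be positive")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if self.n_strata < 1:
            raise ValueError("n_strata must be >= 1")


def _largest_remainder(n: int, fractions: Sequence[float]) -> np.ndarray:
    """Integer apportionment of n by fractions, largest remainder first."""
    quotas = np.asarray(fractions, dtype=float) * n
    counts = np.floor(quotas).astype(int)
    rem = quotas - counts
    for i in np.argsort(-rem, kind="stable")[: n - counts.sum()]:
        counts[i] += 1
    return counts


def stratified_split(
    covariates: pd.DataFrame,
    spec: SplitSpec,
) -> Tuple[List[str], List[str], List[str]]:
    """Split case ids into (train, val, test), stratified on a covariate.

    ``covariates`` needs columns ``case_id`` and ``spec.stratify_on``.
    Partitions are disjoint and exhaustive; within each quantile stratum the
    split proportions are within one case of the global fractions.
    """
    if spec.stratify_on not in covariates.columns:
        raise ValueError(f"covariate {spec.stratify_on!r} missing")
    if covariates[spec.stratify_on].isna().any():
        raise ValueError("covariate has missing values")
    n = len(covariates)
    ids = covariates["case_id"].to_numpy()
    x = covariates[spec.stratify_on].to_numpy(dtype=float)
    n_strata = min(spec.n_strata, n)
    # quantile binning on covariate rank (stable under ties)
    order = np.argsort(x, kind="stable")
    stratum = np.empty(n, dtype=int)
    stratum[order] = (np.arange(n) * n_strata) // n

    global_target = _largest_remainder(n, spec.fractions)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 53]))
    split_of = np.empty(n, dtype=int)
    for s in range(n_strata):
        members = np.flatnonzero(stratum == s)
        rng.shuffle(members)
        counts = _largest_remainder(len(members), spec.fractions)
        bounds = np.concatenate([[0], np.cumsum(counts)])
        for k in range(3):
            split_of[members[bounds[k]:bounds[k + 1]]] = k

    # rebalance so global counts hit the largest-remainder target exactly;
    # each move comes from the stratum where the source split is most
    # over-represented, keeping every stratum within one case of proportional
    fr = np.asarray(spec.fractions)
    for _ in range(n):
        counts = np.bincount(split_of, minlength=3)
        excess = counts - global_target
        if not excess.any():
            break
        src = int(np.argmax(excess))
        dst = int(np.argmin(excess))
        best_s, best_surplus = -1, -np.inf
        for s in range(n_strata):
            members = np.flatnonzero((stratum == s) & (split_of == src))
            if len(members) == 0:
                continue
            surplus = len(members) - (stratum == s).sum() * fr[src]
            if surplus > best_surplus:
                best_s, best_surplus = s, surplus
        movable = np.flatnonzero((stratum == best_s) & (split_of == src))
        split_of[movable[-1]] = dst

    out = tuple([ids[split_of == k].tolist() for k in range(3)])
    return out  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# pipeline


@dataclass(frozen=True)
class PipelineConfig:
    """One config block per stage; desk-scale defaults."""

    region: str = "thigh"
    n_cases: int = 25
    grid_shape: Tuple[int, int, int] = (8, 64, 64)
    spacing: Tuple[float, float, float] = (10.0, 1.0, 1.0)
    imat_fraction: float = 0.10
    noise_sd: float = 40.0
    split: SplitSpec = field(default_factory=SplitSpec)
    epochs: int = 8
    minibatches_per_epoch: int = 8
    batch_size: int = 2
    input_mode: str = "dual"
    deep_supervision: bool = False
    master_seed: int = 0
    write_volumes: bool = False

    def stage_seed(self, stage: str) -> int:
        return (self.master_seed * 131 + STAGE_SEED_OFFSETS[stage]) % (2**31 - 1)


def run_pipeline(config: PipelineConfig, out_dir: Path) -> Dict[str, object]:
    """Execute the full simulate->...->agree flow; returns a summary dict.

    Artifacts written: covariates.csv, split.json, training_log.csv,
    checkpoint npz, metrics.csv, profiles.json, agreement.json, run_log.json.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: Dict[str, object] = {"config": json.loads(json.dumps(asdict(config))),
                              "stages": {}}

    def stage(name):
        t0 = time.time()

        def done(**extra):
            log["stages"][name] = {"seconds": round(time.time() - t0, 3), **extra}
        return done

    # simulate
    fin = stage("simulate")
    base = PhantomParams(region=config.region, grid_shape=config.grid_shape,
                         spacing=config.spacing, imat_fraction=config.imat_fraction,
                         noise_sd=config.noise_sd)
    cases, cov = make_cohort(config.n_cases, base, seed=config.stage_seed("simulate"))
    cov.to_csv(out_dir / "covariates.csv", index=False)
    if config.write_volumes:
        vol_dir = out_dir / "volumes"
        vol_dir.mkdir(exist_ok=True)
        for case, cid in zip(cases, cov["case_id"]):
            write_dual_volume(case.volume, vol_dir / cid)
            write_mask(case.truth, vol_dir / f"{cid}_truth.nii.gz")
            write_sidecar(vol_dir / f"{cid}.json",
                          {"seed": case.params.seed,
                           "imat_fraction": case.params.imat_fraction})
    fin(n_cases=len(cases))

    # split
    fin = stage("split")
    spec = SplitSpec(fractions=config.split.fractions,
                     stratify_on=config.split.stratify_on,
                     n_strata=config.split.n_strata,
                     seed=config.stage_seed("split"))
    train_ids, val_ids, test_ids = stratified_split(cov, spec)
    (out_dir / "split.json").write_text(json.dumps(
        {"train": train_ids, "val": val_ids, "test": test_ids}, indent=2))
    by_id = dict(zip(cov["case_id"], cases))
    fin(sizes=[len(train_ids), len(val_ids), len(test_ids)])

    # train
    fin = stage("train")
    n_classes = len(cases[0].truth.schema.label_ids) + 1
    in_ch = 2 if config.input_mode == "dual" else 1
    model = build_unet(
        tiny_config(out_channels=n_classes, in_channels=in_ch,
                    deep_supervision=config.deep_supervision),
        seed=config.stage_seed("train"))
    tcfg = TrainConfig(epochs=config.epochs,
                       minibatches_per_epoch=config.minibatches_per_epoch,
                       batch_size=config.batch_size,
                       input_mode=config.input_mode,
                       deep_supervision=config.deep_supervision,
                       seed=config.stage_seed("train"))
    model, tlog = train_model(model, [by_id[i] for i in train_ids], tcfg,
                              val_cases=[by_id[i] for i in val_ids])
    tlog.to_csv(out_dir / "training_log.csv", index=False)
    model.save(out_dir / "checkpoint.npz")
    fin(final_loss=float(tlog["train_loss"].iloc[-1]))

    # segment + evaluate on the held-out test cases
    fin = stage("segment")
    preds = {}
    for cid in test_ids:
        case = by_id[cid]
        vol = znormalize(case.volume)
        if config.input_mode == "fat":
            vol = DualVolume(vol.fat, vol.fat, vol.spacing)
        elif config.input_mode == "water":
            vol = DualVolume(vol.water, vol.water, vol.spacing)
        preds[cid] = predict_volume(model, vol, case.truth.schema)
    per_case = [segmetrics.evaluate_case(preds[c], by_id[c].truth) for c in test_ids]
    table = segmetrics.aggregate_cases(per_case)
    table.to_csv(out_dir / "metrics.csv", index=False)
    mean_dsc = float(np.mean([m["dsc"] for cm in per_case for m in cm.values()]))
    fin(mean_dsc=mean_dsc)

    # quantify (on predicted masks, raw intensities)
    fin = stage("quantify")
    profiles = {}
    for cid in test_ids:
        prof = composition_profile(by_id[cid].volume, preds[cid],
                                   seed=config.stage_seed("quantify"))
        profiles[cid] = prof.as_dict()
    (out_dir / "profiles.json").write_text(json.dumps(profiles, indent=2))
    fin(n_profiles=len(profiles))

    # agree: model-derived vs ground-truth reference volumes
    fin = stage("agree")
    feats: Dict[str, Dict[str, float]] = {}
    muscle_name = cases[0].truth.schema.muscle_for_imat
    for cid in test_ids:
        ref = profile_from_truth(by_id[cid])
        feats.setdefault("muscle_volume", {})[cid] = ref.volumes_ml[muscle_name]
    agreement = {}
    a = np.array([profiles[c]["volumes_ml"][muscle_name] for c in test_ids])
    b = np.array([feats["muscle_volume"][c] for c in test_ids])
    if len(test_ids) >= 3:
        data = PairedMeasurements(test_ids, a, b, units="mL")
        agreement["muscle_volume"] = agreement_summary(data).as_dict()
    (out_dir / "agreement.json").write_text(json.dumps(agreement, indent=2))
    fin(n_features=len(agreement))

    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2))
    return {"mean_test_dsc": mean_dsc, "log": log,
            "split_sizes": (len(train_ids), len(val_ids), len(test_ids))}
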