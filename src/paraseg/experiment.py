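"""End-to-end experiment harness.

``run_experiment`` wires phantom generation, subject-level splitting,
optional offline augmentation, training, full-volume prediction, the
seven-metric accuracy report and the reliability/comparison statistics for
every requested model cell (2D/3D x with/without augmentation, optional
deeper variant), at a scale set entirely by the run configuration. Every
random draw derives from the config seed, so a results directory is
reproducible from its embedded config alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os

import numpy as np
import pandas as pd

from . import __version__
from .augment import augment_dataset
from .config import RunConfig, CellConfig, run_config_from_dict
from .metrics import compute_metrics
from .nn import UNetConfig
from .phantom import generate_cohort
from .preprocess import normalize_intensity
from .stats import bland_altman, icc_2_1, posthoc_best_vs_rest, rm_anova, assumption_checks
from .train import FoldSplit, TrainConfig, kfold_split, train_model
from .volume import read_manifest, read_pair


def config_hash(cfg: RunConfig) -> str:
    canon = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


def version_and_provenance(cfg: RunConfig, out_dir: str) -> dict:
    """Record package version, config hash and seed into the results dir."""
    record = {"package": "paraseg", "version": __version__,
              "config_hash": config_hash(cfg), "seed": int(cfg.seed),
              "config": cfg.to_dict()}
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "provenance.json"), "w") as fh:
        json.dump(record, fh, indent=2, default=str)
    return record


def _splits(cfg: RunConfig, subject_ids) -> list[FoldSplit]:
    if cfg.split.mode == "kfold":
        return kfold_split(subject_ids, cfg.split.k, cfg.seed)
    n_train = cfg.split.n_train
    if not 1 <= n_train < len(subject_ids):
        raise ValueError(f"holdout n_train={n_train} incompatible with {len(subject_ids)} subjects")
    rng = np.random.default_rng(cfg.seed)
    order = list(np.array(subject_ids, dtype=object)[rng.permutation(len(subject_ids))])
    return [FoldSplit(0, order[:n_train], order[n_train:])]


def _cell_metrics(cfg: RunConfig, cell: CellConfig, manifest_df: pd.DataFrame,
                  splits: list[FoldSplit], out_dir: str) -> pd.DataFrame:
    tcfg = TrainConfig(**{**dataclasses.asdict(cfg.train), "seed": cfg.seed})
    ucfg = UNetConfig(dims=cell.dims, channels=tuple(cfg.network.channels),
                      deeper=cell.deeper, out_channels=cfg.network.out_channels,
                      negative_slope=cfg.network.negative_slope, seed=cfg.seed)
    rows = []
    for split in splits:
        tag = f"{cell.name}_fold{split.fold_index}"
        train_df = manifest_df[manifest_df.subject_id.isin(split.train_ids)]
        if cell.augment:
            aug_cfg = dataclasses.replace(cfg.augment, seed=cfg.seed + split.fold_index)
            aug_manifest = augment_dataset(train_df, aug_cfg,
                                           os.path.join(out_dir, f"aug_{tag}"))
            train_df = read_manifest(aug_manifest)
        est = train_model(
            train_df, ucfg, tcfg,
            checkpoint_path=os.path.join(out_dir, f"model_{tag}.npz"),
            log_path=os.path.join(out_dir, f"loss_{tag}.csv"))
        for _, row in manifest_df[manifest_df.subject_id.isin(split.test_ids)].iterrows():
            img, gt = read_pair(row["image"], row["mask"])
            pred = est.predict([normalize_intensity(img)])[0]
            rep = compute_metrics(pred, gt, subject=row["subject_id"])
            rep["cell"] = cell.name
            rep["dims"] = f"{cell.dims}d"
            rep["augmentation"] = "aug" if cell.augment else "noaug"
            rep["deeper"] = cell.deeper
            rep["fold"] = split.fold_index
            rows.append(rep)
    return pd.concat(rows, ignore_index=True)


def _cell_stats(metrics: pd.DataFrame) -> dict:
    """ICC and Bland-Altman of volumes (pred vs ground truth), per cell."""
    out = {}
    for cell, grp in metrics.groupby("cell"):
        sm = grp["volume_sm_ml"].to_numpy()
        gt = grp["volume_gt_ml"].to_numpy()
        icc = icc_2_1(sm, gt)
        bias, lo, hi = bland_altman(sm, gt)
        out[cell] = {
            "volume_icc": icc.value, "icc_ci": [icc.ci_low, icc.ci_high],
            "bland_altman": {"bias_ml": bias, "loa_low_ml": lo, "loa_high_ml": hi},
            "mean_dice": float(grp["dice"].mean()),
            "mean_dice_per_muscle": {str(k): float(v) for k, v in
                                     grp.groupby("label_name")["dice"].mean().items()},
        }
    return out


def _comparison_stats(metrics: pd.DataFrame) -> dict:
    """Full-factorial repeated-measures ANOVA on Dice plus post-hoc tests."""
    df = metrics.rename(columns={"label_name": "muscle"})
    df["depth"] = np.where(df["deeper"], "deeper", "base")
    factors = [f for f in ("dims", "augmentation", "depth", "muscle") if df[f].nunique() > 1]
    out = {}
    if factors:
        anova = rm_anova(df, "dice", factors, subject="subject")
        out["anova"] = anova.to_dict(orient="records")
        resid = df["dice"] - df.groupby(factors, observed=True)["dice"].transform("mean")
        table = df.pivot_table(index="subject", columns="cell", values="dice")
        checks = assumption_checks(resid.to_numpy(),
                                   table.to_numpy() if table.shape[1] >= 2 else None)
        checks.pop("qq", None)
        out["assumptions"] = checks
    if df["cell"].nunique() > 1:
        per_subj = df.groupby(["subject", "cell"], as_index=False)["dice"].mean()
        out["posthoc"] = posthoc_best_vs_rest(per_subj, "dice", "cell").to_dict(orient="records")
    return out


def run_experiment(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns the machine-readable summary.

    Writes into ``cfg.out_dir``: the phantom cohort, per-cell checkpoints
    and loss logs, ``metrics.csv``, ``stats.json``, ``summary.json`` and a
    provenance record.
    """
    out_dir = cfg.out_dir
    os.makedirs(out_dir, exist_ok=True)
    version_and_provenance(cfg, out_dir)
    stage = "phantom"
    try:
        manifest = generate_cohort(cfg.cohort.n, cfg.phantom, cfg.seed,
                                   os.path.join(out_dir, "phantoms"))
        manifest_df = read_manifest(manifest)
        stage = "split"
        splits = _splits(cfg, list(manifest_df.subject_id))
        all_metrics = []
        for cell in cfg.cells:
            stage = f"train/{cell.name}"
            all_metrics.append(_cell_metrics(cfg, cell, manifest_df, splits, out_dir))
        metrics = pd.concat(all_metrics, ignore_index=True)
        metrics.to_csv(os.path.join(out_dir, "metrics.csv"), index=False)
        stage = "stats"
        stats = {"cells": _cell_stats(metrics)}
        if len(cfg.cells) > 1:
            stats["comparison"] = _comparison_stats(metrics)
        with open(os.path.join(out_dir, "stats.json"), "w") as fh:
            json.dump(stats, fh, indent=2, default=float)
    except Exception as err:
        raise RuntimeError(f"experiment failed at stage '{stage}': {err}") from err
    summary = {
        "seed": int(cfg.seed),
        "n_subjects": int(cfg.cohort.n),
        "cells": stats["cells"],
        "splits": [{"fold": s.fold_index, "n_train": len(s.train_ids),
                    "n_test": len(s.test_ids)} for s in splits],
    }
    if "comparison" in stats:
        summary["comparison"] = stats["comparison"]
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary


def scaled_accuracy_config(seed: int = 0, out_dir: str = "results/scaled") -> RunConfig:
    """Desk-scale single-cell accuracy/reliability experiment.

    24 phantoms at 64x64x12, a 16/8 holdout split, and a reduced 2D model
    (channels 8-16-32-64, 64x64x1 windows, batch 8, 2000 AdamW iterations
    of DiceCE, no augmentation) — the package's scaled-down counterpart of
    the full-cohort protocol, sized for a single CPU.
    """
    return run_config_from_dict({
        "seed": seed,
        "out_dir": out_dir,
        "phantom": {},
        "cohort": {"n": 24},
        "split": {"mode": "holdout", "n_train": 16},
        "network": {"channels": [8, 16, 32, 64]},
        "train": {"iterations": 2000, "window": [64, 64, 1],
                  "batch_size": 8, "num_samples": 4, "log_every": 100},
        "cells": [{"dims": 2, "augment": False}],
    })


def run_scaled_accuracy_experiment(seed: int = 0, out_dir: str = "results/scaled") -> dict:
    """Run :func:`scaled_accuracy_config` and return its summary."""
    return run_experiment(scaled_accuracy_config(seed, out_dir))
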