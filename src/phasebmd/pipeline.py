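"""End-to-end orchestration: generate -> train -> predict -> correct -> evaluate.

Each stage is a pure function of (config, on-disk inputs) and writes its
artifacts deterministically, so re-running a stage with the same seed and
inputs reproduces its outputs byte for byte.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bmd as bmd_mod
from .aggregate import aggregate_majority, aggregate_mean
from .anatomy import PHASES
from .classifier import load_checkpoint, make_folds, predict_slices, save_checkpoint, train
from .config import PipelineConfig, stage_seed
from .errors import ValidationError
from .io_ct import read_annotations, read_mask, read_volume, write_report
from .metrics import agreement_report, bland_altman_plot, classification_report, roc_plot
from .phantom import generate_cohort, load_manifest
from .preprocess import preprocess_scan


# ---------------------------------------------------------------------------
# stage: generate
# ---------------------------------------------------------------------------

def run_generate(cfg: PipelineConfig, out_dir: str | Path) -> pd.DataFrame:
    """Generate the synthetic cohort with the phantom child seed."""
    spec = replace(cfg.phantom, seed=stage_seed(cfg.seed, "phantom"))
    return generate_cohort(spec, out_dir)


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def split_patients(manifest: pd.DataFrame, cfg: PipelineConfig) -> dict[str, str]:
    """Deterministic patient-level train/test split ({patient_id: 'train'|'test'})."""
    patients = sorted(manifest["patient_id"].unique())
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 102]))
    order = rng.permutation(len(patients))
    n_test = max(1, int(round(cfg.split.test_fraction * len(patients))))
    if n_test >= len(patients):
        raise ValidationError("test fraction leaves no training patients")
    test = {patients[i] for i in order[:n_test]}
    return {p: ("test" if p in test else "train") for p in patients}


def _load_stack(cfg: PipelineConfig, data_dir: Path, row) -> "SliceStack":
    vol = read_volume(data_dir / row.scan_path, patient_id=row.patient_id,
                      scan_id=row.scan_id, phase_label=row.phase)
    annotations = read_annotations(data_dir / row.annotations_path)
    pp = cfg.preprocess
    return preprocess_scan(
        vol,
        annotations,
        target_mm=pp.target_mm,
        image_size=pp.image_size,
        selection_mode=pp.selection_mode,
        levels=pp.levels,
        k_random=pp.k_random,
        seed=np.random.default_rng(
            np.random.SeedSequence(
                [stage_seed(cfg.seed, "slices"), zlib.crc32(row.scan_id.encode()) % (2**31)]
            )
        ),
    )


# ---------------------------------------------------------------------------
# stage: train
# ---------------------------------------------------------------------------

def run_train(cfg: PipelineConfig, data_dir: str | Path, out_dir: str | Path) -> Path:
    """Train the slice classifier on the training split; returns checkpoint path.

    Training patients are folded patient-level (k = cfg.split.n_folds); the
    configured validation fold is held out for early stopping and the rest
    are trained on. Writes checkpoint.npz, training_log.csv and split.csv.
    """
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest, _ = load_manifest(data_dir)
    split = split_patients(manifest, cfg)
    train_patients = [p for p, s in split.items() if s == "train"]
    folds = make_folds(train_patients, k=cfg.split.n_folds, seed=stage_seed(cfg.seed, "split"))

    train_rows, val_rows = [], []
    for row in manifest.itertuples():
        if split[row.patient_id] != "train":
            continue
        (val_rows if folds[row.patient_id] == cfg.split.val_fold else train_rows).append(row)
    tcfg = replace(cfg.train, seed=stage_seed(cfg.seed, "train"),
                   image_size=cfg.preprocess.image_size)
    train_data = [(_load_stack(cfg, data_dir, r), r.phase) for r in train_rows]
    val_data = [(_load_stack(cfg, data_dir, r), r.phase) for r in val_rows]
    model, history = train(train_data, val_data, tcfg)

    ckpt = save_checkpoint(model, tcfg, out_dir / "checkpoint.npz", fold=cfg.split.val_fold)
    history.to_csv(out_dir / "training_log.csv", index=False)
    pd.DataFrame(
        [{"patient_id": p, "split": s, "fold": folds.get(p, -1)} for p, s in sorted(split.items())]
    ).to_csv(out_dir / "split.csv", index=False)
    (out_dir / "train_meta.json").write_text(
        json.dumps({"seed": cfg.seed, "n_train_scans": len(train_rows),
                    "n_val_scans": len(val_rows), "n_params": model.n_params}, indent=1)
    )
    return ckpt


# ---------------------------------------------------------------------------
# stage: predict
# ---------------------------------------------------------------------------

def run_predict(cfg: PipelineConfig, data_dir: str | Path, checkpoint: str | Path,
                out_path: str | Path) -> pd.DataFrame:
    """Predict the contrast phase of every scan in the manifest."""
    data_dir = Path(data_dir)
    manifest, _ = load_manifest(data_dir)
    model, _, _ = load_checkpoint(checkpoint)
    rows = []
    for row in manifest.itertuples():
        stack = _load_stack(cfg, data_dir, row)
        probs = predict_slices(model, stack)
        mean_pred = aggregate_mean(probs, scan_id=row.scan_id, levels=stack.levels)
        maj_pred = aggregate_majority(probs, scan_id=row.scan_id, levels=stack.levels)
        rows.append(
            {
                "patient_id": row.patient_id,
                "scan_id": row.scan_id,
                "true_phase": row.phase,
                "n_slices_used": mean_pred.n_slices_used,
                "p_NE": round(float(mean_pred.aggregated[0]), 6),
                "p_AR": round(float(mean_pred.aggregated[1]), 6),
                "p_PV": round(float(mean_pred.aggregated[2]), 6),
                "call_mean": mean_pred.phase_call,
                "call_majority": maj_pred.phase_call,
                "disagree_flag": int(mean_pred.phase_call != maj_pred.phase_call),
            }
        )
    write_report(rows, out_path, kind="phase_predictions")
    return pd.read_csv(out_path)


# ---------------------------------------------------------------------------
# stage: correct
# ---------------------------------------------------------------------------

def _scan_bmd(cfg: PipelineConfig, data_dir: Path, row) -> tuple[dict[str, float], dict]:
    calib = bmd_mod.CalibrationModel(slope=cfg.bmd.calib_slope,
                                     intercept=cfg.bmd.calib_intercept)
    vol = read_volume(data_dir / row.scan_path)
    mask = read_mask(data_dir / row.mask_path)
    annotations = read_annotations(data_dir / row.annotations_path)
    grades = {a.level: a.fracture_grade for a in annotations}
    per_vertebra = bmd_mod.extract_bmd(vol, mask, calib, levels=cfg.bmd.include_levels)
    return per_vertebra, grades


def run_correct(cfg: PipelineConfig, data_dir: str | Path, predictions_path: str | Path,
                out_bmd_path: str | Path, out_model_path: str | Path) -> pd.DataFrame:
    """Extract lumbar BMD, fit per-phase corrections on the training split
    using known phases, and correct every scan using its *predicted* phase."""
    data_dir = Path(data_dir)
    manifest, _ = load_manifest(data_dir)
    preds = pd.read_csv(predictions_path).set_index("scan_id")
    split = split_patients(manifest, cfg)
    call_col = "call_mean" if cfg.aggregation_mode == "mean" else "call_majority"

    lumbar: dict[str, tuple[float, list]] = {}
    per_scan: dict[str, dict[str, float]] = {}
    for row in manifest.itertuples():
        per_vertebra, grades = _scan_bmd(cfg, data_dir, row)
        mean_bmd, excl = bmd_mod.lumbar_mean(
            per_vertebra, grades, include_levels=cfg.bmd.include_levels,
            exclude_grade_above=cfg.bmd.exclude_grade_above,
        )
        lumbar[row.scan_id] = (mean_bmd, excl)
        per_scan[row.scan_id] = per_vertebra

    # correction models from the training split, paired via the NE scan
    models: dict[str, bmd_mod.CorrectionModel] = {}
    by_patient = manifest.groupby("patient_id")
    for phase in ("AR", "PV"):
        pairs = []
        for pid, grp in by_patient:
            if split[pid] != "train":
                continue
            ids = {r.phase: r.scan_id for r in grp.itertuples()}
            if phase in ids and "NE" in ids:
                pairs.append((lumbar[ids[phase]][0], lumbar[ids["NE"]][0]))
        fixed = 1.0 if cfg.bmd.constant_offset else None
        models[phase] = bmd_mod.fit_correction(pairs, phase, fixed_slope=fixed)

    out_model_path = Path(out_model_path)
    out_model_path.parent.mkdir(parents=True, exist_ok=True)
    out_model_path.write_text(yaml.safe_dump(
        {ph: asdict(m) for ph, m in models.items()}, sort_keys=True))

    rows = []
    for row in manifest.itertuples():
        mean_bmd, excl = lumbar[row.scan_id]
        call = str(preds.loc[row.scan_id, call_col])
        corrected = bmd_mod.apply_correction(mean_bmd, call, models)
        pv = per_scan[row.scan_id]
        rows.append(
            {
                "patient_id": row.patient_id,
                "scan_id": row.scan_id,
                "phase_called": call,
                "bmd_L1": round(pv.get("L1", np.nan), 4),
                "bmd_L2": round(pv.get("L2", np.nan), 4),
                "bmd_L3": round(pv.get("L3", np.nan), 4),
                "lumbar_mean_bmd": round(mean_bmd, 4),
                "corrected_bmd": round(corrected, 4),
                "exclusions": ";".join(f"{lv}:{why}" for lv, why in excl),
            }
        )
    write_report(rows, out_bmd_path, kind="bmd")
    return pd.read_csv(out_bmd_path)


# ---------------------------------------------------------------------------
# stage: evaluate
# ---------------------------------------------------------------------------

def run_evaluate(cfg: PipelineConfig, data_dir: str | Path, predictions_path: str | Path,
                 bmd_path: str | Path, out_path: str | Path,
                 plots_dir: str | Path | None = None) -> pd.DataFrame:
    """Test-split evaluation: phase-classification metrics and BMD agreement
    (corrected and uncorrected AR/PV vs the patient's NE scan)."""
    data_dir = Path(data_dir)
    manifest, _ = load_manifest(data_dir)
    split = split_patients(manifest, cfg)
    preds = pd.read_csv(predictions_path)
    bmd_df = pd.read_csv(bmd_path).set_index("scan_id")
    call_col = "call_mean" if cfg.aggregation_mode == "mean" else "call_majority"

    test_scans = manifest[manifest["patient_id"].map(split) == "test"]
    p = preds.set_index("scan_id").loc[test_scans["scan_id"]]
    rep = classification_report(
        p["true_phase"], p[call_col], y_prob=p[["p_NE", "p_AR", "p_PV"]].to_numpy()
    )
    rows = rep.as_rows()
    rows.append({"metric": "n_test_scans", "value": float(len(test_scans))})

    series: dict[tuple[str, str], tuple[list, list]] = {}
    for pid, grp in test_scans.groupby("patient_id"):
        ids = {r.phase: r.scan_id for r in grp.itertuples()}
        if "NE" not in ids:
            continue
        ne = bmd_df.loc[ids["NE"], "lumbar_mean_bmd"]
        for phase in ("AR", "PV"):
            if phase not in ids:
                continue
            for kind, col in (("uncorrected", "lumbar_mean_bmd"), ("corrected", "corrected_bmd")):
                ref, test = series.setdefault((phase, kind), ([], []))
                ref.append(float(ne))
                test.append(float(bmd_df.loc[ids[phase], col]))

    for (phase, kind), (ref, test) in sorted(series.items()):
        agree = agreement_report(ref, test)
        prefix = f"{phase}_{kind}"
        rows += [
            {"metric": f"{prefix}_rmse", "value": agree.rmse},
            {"metric": f"{prefix}_mean_difference", "value": agree.mean_difference},
            {"metric": f"{prefix}_loa_low", "value": agree.loa_low},
            {"metric": f"{prefix}_loa_high", "value": agree.loa_high},
            {"metric": f"{prefix}_p_value", "value": agree.p},
        ]
        if plots_dir is not None:
            Path(plots_dir).mkdir(parents=True, exist_ok=True)
            bland_altman_plot(ref, test, Path(plots_dir) / f"bland_altman_{prefix}.png",
                              title=f"{phase} vs NE ({kind})")
    if plots_dir is not None:
        roc_plot(p["true_phase"], p[["p_NE", "p_AR", "p_PV"]].to_numpy(),
                 Path(plots_dir) / "roc_test.png")

    out_rows = [{"metric": r["metric"], "value": round(float(r["value"]), 6)} for r in rows]
    write_report(out_rows, out_path, kind="metrics")
    return pd.read_csv(out_path)


def run_all(cfg: PipelineConfig, workdir: str | Path) -> dict[str, Path]:
    """Run the five stages in order under one working directory."""
    workdir = Path(workdir)
    data_dir = workdir / "data"
    run_generate(cfg, data_dir)
    ckpt = run_train(cfg, data_dir, workdir / "model")
    pred_path = workdir / "reports" / "phase_predictions.csv"
    run_predict(cfg, data_dir, ckpt, pred_path)
    bmd_path = workdir / "reports" / "bmd.csv"
    corr_path = workdir / "reports" / "correction_models.yaml"
    run_correct(cfg, data_dir, pred_path, bmd_path, corr_path)
    metrics_path = workdir / "reports" / "metrics.csv"
    run_evaluate(cfg, data_dir, pred_path, bmd_path, metrics_path)
    return {
        "data": data_dir,
        "checkpoint": ckpt,
        "predictions": pred_path,
        "bmd": bmd_path,
        "correction_models": corr_path,
        "metrics": metrics_path,
    }
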