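"""End-to-end orchestration: cohort simulation, volumetry, change
classification, radiomics extraction and the agreement / AUC report.

A cohort directory holds one subdirectory per patient with
``baseline.nii.gz``, ``followup.nii.gz``, ``mask_baseline.nii.gz`` and
``mask_followup.nii.gz``, plus an optional ``readers.csv`` at the root
(columns: patient_id, kidney_side, reader1, reader2).  ``run_pipeline``
writes per-stone, per-kidney and per-patient CSVs and a JSON report with
kappa and AUC blocks; all randomness flows from the single config seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sb_io
from .image import KidneyStudy
from .longitudinal import CHANGE_LABELS, patient_summary, reference_labels
from .phantom import (ChangeScenario, Ellipsoid, PhantomSpec, ReaderSimSpec,
                      StoneSpec, generate_followup, generate_phantom,
                      simulate_readers)
from .radiomics import extract_features
from .stats_eval import AgreementMatrix, cohen_kappa, reader_vs_reference_auc
from .volumetry import build_inventory

logger = logging.getLogger(__name__)

COHORT_FILES = ("baseline", "followup", "mask_baseline", "mask_followup")


# ---------------------------------------------------------------------------
# cohort simulation

def demo_scenarios(seed: int = 0, noise_sd: float = 15.0,
                   spacing=(0.7, 0.7, 5.0)) -> dict[str, ChangeScenario]:
    """A six-patient phantom cohort spanning all four patient categories.

    Change fractions are chosen far from the 15% band so that labels stay
    unambiguous even at the coarse 5 mm default slice spacing: stable uses
    f = 0 (identical re-rendering), increased f = +2.0, decreased f = -0.7,
    plus one complete resolution (f = -1) and one de-novo stone.
    """
    nx, ny, nz = 96, 96, 26
    kid = {
        "right": Ellipsoid(center=(20.0, 33.0, 62.0), semi_axes=(13.0, 13.0, 40.0)),
        "left": Ellipsoid(center=(46.0, 33.0, 62.0), semi_axes=(13.0, 13.0, 40.0)),
    }

    def spec(stones, s):
        return PhantomSpec(grid_shape=(nx, ny, nz), voxel_spacing=spacing,
                           kidneys=dict(kid), stones=stones,
                           noise_sd=noise_sd, seed=s)

    r_stone = lambda r=5.0: StoneSpec.sphere("right", (20.0, 33.0, 55.0), r)
    l_stone = lambda r=5.0: StoneSpec.sphere("left", (46.0, 33.0, 70.0), r)
    base = seed * 100
    return {
        "P01_stable": ChangeScenario(spec([r_stone(), l_stone()], base + 1), [0.0, 0.0]),
        "P02_increased": ChangeScenario(spec([r_stone(), l_stone()], base + 2), [2.0, 0.0]),
        "P03_decreased": ChangeScenario(spec([r_stone(), l_stone()], base + 3), [-0.7, 0.0]),
        "P04_mixed": ChangeScenario(spec([r_stone(), l_stone()], base + 4), [2.0, -0.7]),
        "P05_resolved": ChangeScenario(spec([r_stone()], base + 5), [-1.0]),
        "P06_denovo": ChangeScenario(spec([l_stone()], base + 6), [2.0]),
    }


def write_cohort(scenarios: dict[str, ChangeScenario], out_dir,
                 reader_confusions: tuple[np.ndarray, np.ndarray] | None = None,
                 seed: int = 0) -> Path:
    """Render scenarios to a cohort directory; optionally simulate two
    readers against the analytic ground-truth labels."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for pid, scenario in scenarios.items():
        pdir = out_dir / pid
        pdir.mkdir(exist_ok=True)
        img_b, mask_b, truth_b = generate_phantom(scenario.baseline)
        img_f, mask_f, truth_f = generate_followup(scenario)
        sb_io.write_volume(img_b, pdir / "baseline.nii.gz")
        sb_io.write_volume(img_f, pdir / "followup.nii.gz")
        sb_io.write_mask(mask_b, img_b.spacing, pdir / "mask_baseline.nii.gz")
        sb_io.write_mask(mask_f, img_f.spacing, pdir / "mask_followup.nii.gz")
        sb_io.write_ground_truth_csv(truth_b, pdir / "truth_baseline.csv")
        sb_io.write_ground_truth_csv(truth_f, pdir / "truth_followup.csv")
        for side, label in scenario.expected_labels().items():
            rows.append({"patient_id": pid, "kidney_side": side, "true_label": label})
    truth = pd.DataFrame(rows)
    truth.to_csv(out_dir / "truth_labels.csv", index=False)
    if reader_confusions is not None:
        labels = list(truth["true_label"])
        readers = {}
        for i, conf in enumerate(reader_confusions, start=1):
            spec = ReaderSimSpec(confusion=np.asarray(conf), seed=seed * 10 + i)
            readers[f"reader{i}"] = simulate_readers(labels, spec)
        out = truth[["patient_id", "kidney_side"]].copy()
        out["reader1"] = readers["reader1"]
        out["reader2"] = readers["reader2"]
        out.to_csv(out_dir / "readers.csv", index=False)
    return out_dir


def load_cohort(cohort_dir) -> tuple[list[KidneyStudy], pd.DataFrame | None]:
    cohort_dir = Path(cohort_dir)
    studies = []
    for pdir in sorted(p for p in cohort_dir.iterdir() if p.is_dir()):
        paths = {name: pdir / f"{name}.nii.gz" for name in COHORT_FILES}
        missing = [n for n, p in paths.items() if not p.exists()]
        if missing:
            raise FileNotFoundError(
                f"patient {pdir.name} is missing {missing} in {pdir}")
        studies.append(KidneyStudy(
            patient_id=pdir.name,
            baseline=sb_io.read_volume(paths["baseline"]),
            followup=sb_io.read_volume(paths["followup"]),
            mask_baseline=sb_io.read_mask(paths["mask_baseline"]),
            mask_followup=sb_io.read_mask(paths["mask_followup"]),
        ))
    if not studies:
        raise FileNotFoundError(f"no patient subdirectories under {cohort_dir}")
    readers_path = cohort_dir / "readers.csv"
    readers = pd.read_csv(readers_path) if readers_path.exists() else None
    return studies, readers


# ---------------------------------------------------------------------------
# pipeline stages

def _stone_tables(studies, cfg) -> tuple[pd.DataFrame, pd.DataFrame]:
    stone_rows, feat_rows = [], []
    for study in studies:
        for timepoint, image, mask in (("baseline", study.baseline, study.mask_baseline),
                                       ("followup", study.followup, study.mask_followup)):
            inv = build_inventory(image, mask, cfg.threshold_hu, cfg.connectivity,
                                  cfg.min_diameter_mm)
            df = sb_io.inventory_frame(inv, study.patient_id, timepoint)
            stone_rows.append(df)
            if cfg.extract_radiomics:
                for rec in inv.stones:
                    feats = extract_features(image, rec.voxels,
                                             bin_width=cfg.bin_width,
                                             wavelet_on=cfg.wavelet_on)
                    feat_rows.append({"patient_id": study.patient_id,
                                      "timepoint": timepoint,
                                      "kidney_side": rec.kidney_side,
                                      "stone_id": rec.stone_id, **feats})
    stone_rows = [df for df in stone_rows if not df.empty]
    stones = pd.concat(stone_rows, ignore_index=True) if stone_rows else pd.DataFrame()
    feats = pd.DataFrame(feat_rows)
    return stones, feats


def _agreement_report(readers: pd.DataFrame, reference: pd.DataFrame,
                      cfg) -> dict:
    merged = readers.merge(reference, on=["patient_id", "kidney_side"],
                           validate="one_to_one")
    out = {"n_kidneys": int(len(merged))}
    m = AgreementMatrix.from_labels(merged["reader1"], merged["reader2"])
    for scheme in ("unweighted", "linear"):
        res = cohen_kappa(m, scheme, n_boot=cfg.kappa_bootstrap, seed=cfg.seed)
        out[f"kappa_{scheme}"] = {"estimate": round(res.estimate, 4),
                                  "ci_lower": round(res.ci_lower, 4),
                                  "ci_upper": round(res.ci_upper, 4)}
    out["matrix_reader1_vs_reader2"] = m.counts.tolist()
    out["category_order"] = list(m.category_order)
    aucs = {}
    for reader in ("reader1", "reader2"):
        aucs[reader] = {}
        for target in CHANGE_LABELS:
            ref = list(merged["volumetric_label"])
            if len(set(lab == target for lab in ref)) < 2:
                aucs[reader][target] = None  # class absent in this cohort
                continue
            res = reader_vs_reference_auc(merged[reader], ref, target)
            aucs[reader][target] = {"auc_roc": round(res.auc_roc, 4),
                                    "auc_prc": round(res.auc_prc, 4),
                                    "n_pos": res.n_pos, "n_neg": res.n_neg}
    out["reader_vs_reference_auc"] = aucs
    return out


def run_pipeline(cfg: sb_io.PipelineConfig) -> dict:
    """Run the full comparison on a cohort directory.

    Writes ``stones.csv``, ``kidney_changes.csv``, ``patient_summary.csv``,
    optionally ``radiomics.csv``, and ``report.json`` under
    ``cfg.output_dir``; returns the report dict.  On any stage failure the
    partially-written outputs are removed and a stage-named error is raised.
    """
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "load"
    try:
        studies, readers = load_cohort(cfg.input_dir)
        logger.info("loaded %d paired studies from %s", len(studies), cfg.input_dir)

        stage = "volumetry"
        stones, feats = _stone_tables(studies, cfg)
        p = out_dir / "stones.csv"
        stones.to_csv(p, index=False)
        written.append(p)
        if cfg.extract_radiomics and not feats.empty:
            p = out_dir / "radiomics.csv"
            feats.to_csv(p, index=False)
            written.append(p)

        stage = "longitudinal"
        records = reference_labels(studies, cfg.threshold_hu, cfg.connectivity,
                                   cfg.min_diameter_mm, cfg.band)
        kidney_df = pd.DataFrame([{
            "patient_id": r.patient_id,
            "kidney_side": r.kidney_side,
            "v_baseline_ml": round(r.v_baseline_ml, sb_io.ML_DECIMALS),
            "v_followup_ml": round(r.v_followup_ml, sb_io.ML_DECIMALS),
            "relative_change": (round(r.relative_change, 4)
                                if np.isfinite(r.relative_change) else "new"),
            "volumetric_label": r.label,
        } for r in records])
        p = out_dir / "kidney_changes.csv"
        kidney_df.to_csv(p, index=False)
        written.append(p)

        patients = patient_summary(records)
        pat_df = pd.DataFrame(sorted(patients.items()),
                              columns=["patient_id", "patient_label"])
        p = out_dir / "patient_summary.csv"
        pat_df.to_csv(p, index=False)
        written.append(p)

        stage = "agreement"
        report = {
            "config": {"threshold_hu": cfg.threshold_hu, "band": cfg.band,
                       "min_diameter_mm": cfg.min_diameter_mm,
                       "connectivity": cfg.connectivity, "seed": cfg.seed},
            "n_patients": len(studies),
            "kidney_label_counts": kidney_df["volumetric_label"]
                .value_counts().to_dict(),
            "patient_label_counts": pat_df["patient_label"]
                .value_counts().to_dict(),
        }
        if readers is not None:
            report["agreement"] = _agreement_report(readers, kidney_df, cfg)

        p = out_dir / "report.json"
        with open(p, "w") as fh:
            json.dump(report, fh, indent=2)
        written.append(p)
        return report
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
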