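"""End-to-end orchestration: simulate -> preprocess -> quantify -> extract -> stats.

A run is fully described by a :class:`PipelineConfig`; the resolved config is
written beside the outputs together with a checksummed manifest, so any stage
can be re-run from the provenance alone. Per-subject failures are quarantined
with their reasons; the run aborts only if more than a configurable fraction
of subjects fail.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as aio
from .errors import ValidationError
from .models import PASLKineticParams, PCASLParams
from .physio import SubjectPhysiology
from .preprocess import background_stats, mean_difference, reliable_voxel_mask
from .quantify import fit_multiti, quantify_singleti
from .roi import ROISet, erode_mask, extract_features, high_signal_roi
from .stats import adjust_age_sex, bh_fdr, compare_groups, correlate, normality_gate
from .synthetic import (GM, SINUS, WM, AcquisitionSpec, CohortSpec,
                        CompartmentValues, HEMO_FEATURES, make_phantom,
                        simulate_cohort, simulate_series)

log = logging.getLogger("aslquant")

__all__ = ["PipelineConfig", "run_pipeline", "run_stats"]


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run."""
    seed: int = 0
    # imaging sub-cohort: image-level simulation is per-subject expensive, so
    # only the first (n_sca_imaging + n_control_imaging) rows get phantoms
    n_sca_imaging: int = 6
    n_control_imaging: int = 4
    matrix: tuple[int, int, int] = (32, 32, 8)
    noise_sd_single: float = 0.5     # signal units; pCASL GM dM ~ 7 at M0=1000
    noise_sd_multi: float = 1.5      # PASL GM peak dM ~ 15 at M0=1000
    corner_width: int = 5
    reliability_multiplier: float = 1.0
    erosion_width: int = 2
    sinus_percentile: float = 90.0
    shapiro_alpha: float = 0.05
    max_failed_fraction: float = 0.5
    cbf_max: float = 3000.0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    out_dir: str = "aslquant_out"

    def to_yaml(self, path: Path | str) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(_to_plain(dataclasses.asdict(self))))
        return path

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort_raw = raw.pop("cohort", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in
                     {f.name for f in dataclasses.fields(cls)} - {"cohort"}})
        if cfg_matrix := raw.get("matrix"):
            cfg.matrix = tuple(cfg_matrix)
        if cohort_raw:
            simple = {k: v for k, v in cohort_raw.items()
                      if k in {"n_sca", "n_control", "seed"}}
            cfg.cohort = CohortSpec(**simple)
            cfg.cohort.seed = cfg.seed
        else:
            cfg.cohort.seed = cfg.seed
        return cfg


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _subject_physio(row: pd.Series) -> SubjectPhysiology:
    return SubjectPhysiology(
        subject_id=row["subject_id"], group=row["group"], age=row["age"],
        sex=row["sex"], hemoglobin=row["hemoglobin"],
        hematocrit=row["hematocrit"], spo2=row["spo2"])


def process_subject(row: pd.Series, cfg: PipelineConfig,
                    out_dir: Optional[Path] = None) -> pd.Series:
    """Simulate, preprocess, quantify and extract features for one subject."""
    physio = _subject_physio(row)
    sub_seed = abs(hashable_seed(cfg.seed, row.name)) % (2 ** 31)

    truth_single = make_phantom(cfg.matrix, seed=sub_seed, values=CompartmentValues(
        cbf_gm=row["cbf_sti_gm"], cbf_wm=row["cbf_sti_wm"],
        cbf_sinus=row["cbf_sti_sinus"],
        bat_gm=row["bat_mti_gm"], bat_wm=row["bat_mti_wm"],
        bat_sinus=row["bat_mti_sinus"]))
    truth_multi = make_phantom(cfg.matrix, seed=sub_seed, values=CompartmentValues(
        cbf_gm=row["cbf_mti_gm"], cbf_wm=row["cbf_mti_wm"],
        cbf_sinus=row["cbf_mti_sinus"],
        bat_gm=row["bat_mti_gm"], bat_wm=row["bat_mti_wm"],
        bat_sinus=row["bat_mti_sinus"]))

    acq_s = AcquisitionSpec.single_ti(matrix=cfg.matrix,
                                      background_corner_width=cfg.corner_width)
    acq_m = AcquisitionSpec.multi_ti(matrix=cfg.matrix,
                                     background_corner_width=cfg.corner_width)
    series_s = simulate_series(truth_single, acq_s, physio,
                               noise_sd=cfg.noise_sd_single, seed=sub_seed)
    series_m = simulate_series(truth_multi, acq_m, physio,
                               noise_sd=cfg.noise_sd_multi, seed=sub_seed + 1)

    # preprocessing
    mean_s = mean_difference(series_s)
    bg = background_stats(series_m, width=cfg.corner_width)
    reliable = reliable_voxel_mask(series_m, bg,
                                   multiplier=cfg.reliability_multiplier)

    # quantification
    p_single = PCASLParams(t1_blood=physio.t1_blood)
    p_multi = PASLKineticParams(t1_blood=physio.t1_blood)
    seg = truth_single.segmentation
    head = seg > 0
    maps_s = quantify_singleti(mean_s, series_s.m0, p_single, mask=head)

    # ROIs: eroded anatomical masks; high-signal sinus from the singleTI map
    gm_roi = erode_mask(seg == GM, cfg.erosion_width)
    wm_roi = erode_mask(seg == WM, cfg.erosion_width)
    sinus_full = seg == SINUS
    sinus_high, _thr = high_signal_roi(maps_s.cbf, sinus_full,
                                       percentile=cfg.sinus_percentile,
                                       subject_id=physio.subject_id)

    # multiTI fit restricted to reliable voxels inside the analysis regions
    fit_mask = reliable & (gm_roi | wm_roi | sinus_full)
    maps_m = fit_multiti(series_m, series_m.m0, p_multi, fit_mask,
                         cbf_max=cfg.cbf_max, noise_floor=bg.threshold)
    log.info("%s: fit %d voxels, %d non-converged, %d below noise floor",
             physio.subject_id, int(fit_mask.sum()),
             int((fit_mask & ~maps_m.converged).sum()),
             maps_m.provenance["n_below_noise_floor"])

    rois = ROISet(gm=gm_roi, wm=wm_roi, sinus_full=sinus_full,
                  sinus_high=sinus_high)
    feats = extract_features(
        {"singleTI": {"cbf": maps_s.cbf},
         "multiTI": {"cbf": maps_m.cbf, "bat": maps_m.bat}},
        rois, subject_id=physio.subject_id)

    if out_dir is not None:
        sub = Path(out_dir) / physio.subject_id
        aff = truth_single.affine
        aio.save_nifti(series_s.data, aff, sub / "asl_singleTI.nii")
        aio.save_nifti(series_m.data, aff, sub / "asl_multiTI.nii")
        aio.save_nifti(series_s.m0, aff, sub / "m0.nii")
        aio.save_nifti(seg, aff, sub / "segmentation.nii")
        aio.save_nifti(maps_s.cbf, aff, sub / "cbf_singleTI.nii")
        aio.save_nifti(maps_m.cbf, aff, sub / "cbf_multiTI.nii")
        aio.save_nifti(maps_m.bat, aff, sub / "bat_multiTI.nii")
        aio.write_json({"singleTI": maps_s.provenance,
                        "multiTI": maps_m.provenance}, sub / "provenance.json")
    return feats


def hashable_seed(*parts: int) -> int:
    """Stable small seed from integer parts (avoids Python string hashing)."""
    out = 0
    for p in parts:
        out = (out * 1000003 + int(p)) % (2 ** 31 - 1)
    return out


def run_stats(cohort: pd.DataFrame, shapiro_alpha: float = 0.05) -> dict:
    """The statistical stage over a feature table.

    Returns group comparisons (FDR-adjusted within parameter-map families) and
    age/sex-adjusted CaO2 correlations within the SCA group (FDR-adjusted
    within map families).
    """
    family_of = {f: ("cbf_sti" if f.startswith("cbf_sti")
                     else "cbf_mti" if f.startswith("cbf_mti") else "bat_mti")
                 for f in HEMO_FEATURES}
    comparisons = []
    for feat in HEMO_FEATURES:
        res = compare_groups(cohort[feat], cohort["group"], comparison=feat,
                             family=family_of[feat], shapiro_alpha=shapiro_alpha)
        comparisons.append(res.__dict__ | {"group": "between"})
    comp_df = bh_fdr(pd.DataFrame(comparisons), by=["family"])

    sca = cohort[cohort["group"] == "SCA"]
    corrs = []
    for feat in HEMO_FEATURES:
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            gate = normality_gate(sca[feat], alpha=shapiro_alpha)
        adjusted = adjust_age_sex(sca[feat], sca["age"], sca["sex"],
                                  log_transform=(gate == "non_normal"))
        res = correlate(adjusted, sca["cao2"], method="pearson",
                        comparison=f"{feat}~cao2", family=family_of[feat])
        corrs.append(res.__dict__ | {"group": "SCA",
                                     "log_transformed": gate == "non_normal"})
    corr_df = bh_fdr(pd.DataFrame(corrs), by=["group", "family"])
    return {"group_comparisons": comp_df, "cao2_correlations": corr_df}


def run_pipeline(cfg: PipelineConfig, out_dir: Optional[Path | str] = None,
                 write_volumes: bool = False) -> dict:
    """Full run: cohort simulation, imaging sub-cohort, features, statistics."""
    out = Path(out_dir) if out_dir is not None else Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.cohort.seed = cfg.seed
    cohort = simulate_cohort(cfg.cohort)

    img_rows = pd.concat([
        cohort[cohort["group"] == "SCA"].head(cfg.n_sca_imaging),
        cohort[cohort["group"] == "control"].head(cfg.n_control_imaging)])
    features, failures = [], []
    for _, row in img_rows.iterrows():
        try:
            features.append(process_subject(
                row, cfg, out_dir=out / "subjects" if write_volumes else None))
        except Exception as exc:   # quarantine, keep going
            log.warning("subject %s quarantined: %s", row["subject_id"], exc)
            failures.append({"subject_id": row["subject_id"], "reason": str(exc)})
    if len(img_rows) and len(failures) / len(img_rows) > cfg.max_failed_fraction:
        raise ValidationError(
            f"{len(failures)}/{len(img_rows)} imaging subjects failed; aborting")

    feat_df = pd.DataFrame(features) if features else pd.DataFrame()
    if not feat_df.empty:
        feat_df = feat_df.merge(
            cohort.drop(columns=[c for c in HEMO_FEATURES if c in cohort], errors="ignore"),
            on="subject_id", how="left")

    stats_out = run_stats(cohort, shapiro_alpha=cfg.shapiro_alpha)

    outputs = [
        aio.write_table(cohort, out / "cohort.csv"),
        aio.write_table(feat_df, out / "imaging_features.csv"),
        aio.write_table(stats_out["group_comparisons"], out / "group_comparisons.csv"),
        aio.write_table(stats_out["cao2_correlations"], out / "cao2_correlations.csv"),
        cfg.to_yaml(out / "config_resolved.yaml"),
        aio.write_json({"failures": failures}, out / "quarantine.json"),
    ]
    aio.write_manifest(outputs, out / "manifest.json")
    return {"cohort": cohort, "imaging_features": feat_df,
            **stats_out, "failures": failures, "out_dir": out}
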