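"""Digital phantom and cohort simulator.

Two layers of synthesis:

* **Image level** — a three-compartment head phantom (gray-matter shell, white
  matter core, posterior midline sagittal-sinus tube) on a voxel grid whose
  four in-plane corners are guaranteed signal-free, so that background-noise
  statistics can be measured exactly as the pipeline expects. Difference-image
  series are generated directly from the forward models (singleTI pCASL with
  repeats; multiTI PASL sampled at each inflow time) plus i.i.d. Gaussian
  noise. Raw control/label pairs and background suppression are not modelled:
  downstream analysis consumes difference signal only.

* **Cohort level** — a per-subject table with demographics, hematology,
  treatments, SCI burden, intracranial volume, education, per-region
  hemodynamics and cognitive scores. Default effect directions and magnitudes
  emulate a pediatric/young-adult sickle-cell-anemia (SCA) cohort versus
  healthy controls: higher CBF and shorter gray/white-matter bolus arrival
  times in patients, longer and more variable venous (sagittal-sinus) arrival
  times, CBF negatively coupled to arterial oxygen content within patients,
  and cognition coupled to venous CBF and white-matter hemodynamics.

Median/IQR-summarised quantities (sinus CBF, arrival times, SCI burden) are
modelled lognormal with log-scale SD = ln(q3/q1)/(2*0.6745); mean/SD
quantities are Gaussian. Every draw is reproducible: each subject gets an
independent random stream derived from (cohort seed, subject index).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError
from .models import PCASLParams, PASLKineticParams, pcasl_forward, pasl_kinetic_signal
from .physio import Group, SubjectPhysiology, compute_cao2, estimate_t1_blood
from .preprocess import ASLSeries

__all__ = [
    "AcquisitionSpec",
    "PhantomTruth",
    "CompartmentValues",
    "CohortSpec",
    "make_ti_grid",
    "make_phantom",
    "simulate_series",
    "simulate_cohort",
    "HEMO_FEATURES",
]

# segmentation label codes
BACKGROUND, GM, WM, SINUS = 0, 1, 2, 3
LABEL_NAMES = {BACKGROUND: "background", GM: "gm", WM: "wm", SINUS: "sinus"}

#: per-subject hemodynamic feature columns: 3 ROIs x {singleTI CBF, multiTI CBF,
#: multiTI BAT}; the name prefix tags the parameter-map family used for FDR
#: stratification downstream.
HEMO_FEATURES = [
    "cbf_sti_gm", "cbf_sti_wm", "cbf_sti_sinus",
    "cbf_mti_gm", "cbf_mti_wm", "cbf_mti_sinus",
    "bat_mti_gm", "bat_mti_wm", "bat_mti_sinus",
]


def make_ti_grid(start_ms: float = 350.0, stop_ms: float = 2600.0,
                 step_ms: float = 250.0) -> np.ndarray:
    """Inclusive arithmetic inflow-time grid, returned in seconds."""
    if step_ms <= 0:
        raise ValidationError(f"step_ms must be positive, got {step_ms!r}")
    if start_ms > stop_ms:
        raise ValidationError("start_ms must not exceed stop_ms")
    n = int(np.floor((stop_ms - start_ms) / step_ms + 0.5 * 1e-9)) + 1
    # guard against float fuzz at the inclusive endpoint
    n = int(np.floor((stop_ms - start_ms + 1e-9) / step_ms)) + 1
    return (start_ms + step_ms * np.arange(n)) / 1000.0


@dataclass(frozen=True)
class AcquisitionSpec:
    """Sequence geometry and timing for one simulated acquisition."""
    kind: str                                  # "singleTI_pCASL" | "multiTI_PASL"
    matrix: tuple[int, int, int] = (32, 32, 8)
    voxel_size_mm: tuple[float, float, float] = (1.7, 1.7, 4.0)
    repeats: int = 10                          # singleTI only
    inflow_times: Optional[np.ndarray] = None  # multiTI only, seconds
    background_corner_width: int = 5

    def __post_init__(self):
        if self.kind not in ("singleTI_pCASL", "multiTI_PASL"):
            raise ValidationError(f"unknown acquisition kind {self.kind!r}")
        if self.repeats < 1:
            raise ValidationError("repeats must be >= 1")
        if self.kind == "multiTI_PASL":
            tis = self.inflow_times if self.inflow_times is not None else make_ti_grid()
            tis = np.asarray(tis, dtype=float)
            if np.any(np.diff(tis) <= 0):
                raise ValidationError("inflow_times must be strictly increasing")
            object.__setattr__(self, "inflow_times", tis)

    @property
    def n_volumes(self) -> int:
        if self.kind == "singleTI_pCASL":
            return self.repeats
        return len(self.inflow_times)

    @classmethod
    def single_ti(cls, **kw) -> "AcquisitionSpec":
        return cls(kind="singleTI_pCASL", **kw)

    @classmethod
    def multi_ti(cls, **kw) -> "AcquisitionSpec":
        return cls(kind="multiTI_PASL", **kw)


@dataclass(frozen=True)
class CompartmentValues:
    """Ground-truth CBF (mL/100g/min) and BAT (s) per tissue compartment."""
    cbf_gm: float = 54.0
    cbf_wm: float = 31.0
    cbf_sinus: float = 105.0
    bat_gm: float = 0.72
    bat_wm: float = 0.96
    bat_sinus: float = 1.17
    m0_head: float = 1000.0

    def cbf(self, label: int) -> float:
        return {GM: self.cbf_gm, WM: self.cbf_wm, SINUS: self.cbf_sinus}[label]

    def bat(self, label: int) -> float:
        return {GM: self.bat_gm, WM: self.bat_wm, SINUS: self.bat_sinus}[label]


@dataclass
class PhantomTruth:
    """Voxel-wise ground truth for one simulated subject."""
    segmentation: np.ndarray   # int labels {0 bg, 1 gm, 2 wm, 3 sinus}
    cbf_true: np.ndarray       # mL/100g/min, 0 in background
    bat_true: np.ndarray       # s
    m0: np.ndarray             # signal units, 0 in background
    affine: np.ndarray

    def mask(self, label: int) -> np.ndarray:
        return self.segmentation == label


# in-plane phantom geometry (voxels): WM disc, GM annulus, sinus tube
R_WM = 5.0
R_GM = 9.0
R_SINUS = 2.0
SINUS_POSTERIOR_OFFSET = 4.5   # tube centre this many voxels from the posterior edge


def make_phantom(matrix: tuple[int, int, int] = (32, 32, 8),
                 seed: int = 0,
                 values: CompartmentValues | None = None,
                 voxel_size_mm: tuple[float, float, float] = (1.7, 1.7, 4.0),
                 corner_width: int = 5) -> PhantomTruth:
    """Build the three-compartment phantom with ghost-free corners.

    Geometry is deterministic given the matrix (the seed is reserved for
    optional within-compartment variation and kept in the signature so callers
    can treat phantom construction uniformly with the stochastic stages).
    Compartments are extruded along z, so every slice shows the same in-plane
    layout and the four corner squares are background on every slice.
    """
    values = values or CompartmentValues()
    nx, ny, nz = matrix
    if min(nx, ny) < 24 or nz < 4:
        raise ValidationError(
            f"matrix {matrix} too small: need in-plane >= 24 and >= 4 slices")
    if min(nx, ny) < 3 * corner_width:
        raise ValidationError("in-plane matrix must be >= 3x the corner width")

    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    sy = (ny - 1) - SINUS_POSTERIOR_OFFSET
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    r2_centre = (x - cx) ** 2 + (y - cy) ** 2
    r2_sinus = (x - cx) ** 2 + (y - sy) ** 2

    plane = np.zeros((nx, ny), dtype=np.int16)
    plane[r2_centre <= R_GM ** 2] = GM
    plane[r2_centre <= R_WM ** 2] = WM
    plane[r2_sinus <= R_SINUS ** 2] = SINUS   # sinus wins on overlap

    # corner squares must stay background on every slice
    w = corner_width
    corners = np.zeros((nx, ny), dtype=bool)
    for xs in (slice(0, w), slice(nx - w, nx)):
        for ys in (slice(0, w), slice(ny - w, ny)):
            corners[xs, ys] = True
    if np.any(plane[corners] != BACKGROUND):
        raise ValidationError(
            f"matrix {matrix} too small: compartments reach the corner squares")

    seg = np.repeat(plane[:, :, None], nz, axis=2)
    cbf = np.zeros(matrix, dtype=float)
    bat = np.zeros(matrix, dtype=float)
    m0 = np.zeros(matrix, dtype=float)
    for label in (GM, WM, SINUS):
        sel = seg == label
        cbf[sel] = values.cbf(label)
        bat[sel] = values.bat(label)
        m0[sel] = values.m0_head

    affine = np.diag(list(voxel_size_mm) + [1.0])
    return PhantomTruth(segmentation=seg, cbf_true=cbf, bat_true=bat, m0=m0,
                        affine=affine)


def simulate_series(truth: PhantomTruth, acq: AcquisitionSpec,
                    physio: SubjectPhysiology, noise_sd: float,
                    seed: int = 0,
                    pcasl: PCASLParams | None = None,
                    pasl: PASLKineticParams | None = None) -> ASLSeries:
    """Forward-simulate a difference-image series for one subject.

    The subject's estimated T1-blood enters the forward model; background
    voxels carry pure noise (zero CBF and zero M0). Blood magnetisation is
    taken as M0_tissue / lam.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if truth.segmentation.shape != tuple(acq.matrix):
        raise ValidationError(
            f"phantom grid {truth.segmentation.shape} != acquisition matrix {acq.matrix}")
    rng = np.random.default_rng(seed)
    shape = truth.segmentation.shape

    if acq.kind == "singleTI_pCASL":
        p = pcasl or PCASLParams(t1_blood=physio.t1_blood)
        clean = pcasl_forward(truth.cbf_true, truth.m0, p)
        data = np.stack([clean + rng.normal(0.0, noise_sd, shape) if noise_sd > 0
                         else clean.copy()
                         for _ in range(acq.repeats)], axis=-1)
        return ASLSeries(data=data, m0=truth.m0.copy(), kind="singleTI",
                         affine=truth.affine.copy())

    p = pasl or PASLKineticParams(t1_blood=physio.t1_blood)
    m0_blood = truth.m0 / p.lam
    vols = []
    for ti in acq.inflow_times:
        clean = pasl_kinetic_signal(ti, truth.cbf_true, truth.bat_true, m0_blood, p)
        vols.append(clean + rng.normal(0.0, noise_sd, shape) if noise_sd > 0
                    else np.asarray(clean))
    data = np.stack(vols, axis=-1)
    return ASLSeries(data=data, m0=truth.m0.copy(), kind="multiTI",
                     inflow_times=np.asarray(acq.inflow_times, dtype=float),
                     affine=truth.affine.copy())


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

def _lognorm_params(median: float, q1: float, q3: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal from its median and quartiles."""
    return float(np.log(median)), float(np.log(q3 / q1) / (2.0 * 0.674490))


def _sd_from_iqr(q1: float, q3: float) -> float:
    return (q3 - q1) / 1.348980


@dataclass
class RegionEffects:
    """Group-wise generative parameters for one hemodynamic feature.

    Gaussian features carry (mean, sd); lognormal features carry log-scale
    (mu, sigma). ``cao2_r`` is the planted within-SCA correlation with
    arterial oxygen content (applied on the generative scale).
    """
    sca: tuple[float, float]
    control: tuple[float, float]
    lognormal: bool = False
    cao2_r: float = 0.0


def _default_regions() -> dict[str, RegionEffects]:
    # group summaries of a pediatric SCA vs control cohort: mean (SD) for
    # Gaussian features, median [IQR] -> lognormal for skewed ones
    return {
        "cbf_sti_gm": RegionEffects((54.06, 7.78), (42.52, 7.13), cao2_r=-0.45),
        "cbf_sti_wm": RegionEffects((31.25, 4.82), (22.91, 4.49), cao2_r=-0.45),
        "cbf_sti_sinus": RegionEffects(_lognorm_params(104.66, 80.06, 145.60),
                                       _lognorm_params(66.18, 57.03, 78.93),
                                       lognormal=True, cao2_r=-0.40),
        "cbf_mti_gm": RegionEffects((129.02, 22.26), (89.62, 11.83), cao2_r=-0.45),
        "cbf_mti_wm": RegionEffects((69.52, 11.99), (51.83, 7.46), cao2_r=-0.45),
        "cbf_mti_sinus": RegionEffects(_lognorm_params(253.77, 157.73, 467.67),
                                       _lognorm_params(145.83, 113.95, 202.52),
                                       lognormal=True, cao2_r=-0.40),
        "bat_mti_gm": RegionEffects((0.72, _sd_from_iqr(0.66, 0.75)),
                                    (0.82, _sd_from_iqr(0.77, 0.89)), cao2_r=0.40),
        "bat_mti_wm": RegionEffects((0.96, _sd_from_iqr(0.91, 1.05)),
                                    (1.15, _sd_from_iqr(1.08, 1.26)), cao2_r=0.40),
        "bat_mti_sinus": RegionEffects(_lognorm_params(1.17, 0.98, 1.45),
                                       _lognorm_params(1.01, 0.87, 1.10),
                                       lognormal=True, cao2_r=0.0),
    }


@dataclass
class CognitionEffect:
    """One cognitive outcome: group means/SDs plus planted predictor slopes.

    ``slopes`` maps feature name -> unstandardised coefficient; features
    prefixed ``log:`` enter through their natural logarithm. ``covariates``
    maps covariate column -> coefficient (applied in the SCA group only, where
    the planted structure lives). ``noise_sd`` is the residual SD, set so the
    marginal SD approximates the target group SD.
    """
    sca_mean: float
    sca_sd: float
    control_mean: float
    control_sd: float
    slopes: dict[str, float] = field(default_factory=dict)
    covariates: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 10.0


def _default_cognition() -> dict[str, CognitionEffect]:
    return {
        "iq": CognitionEffect(
            92.63, 13.44, 98.10, 12.00,
            slopes={"log:cbf_mti_sinus": -3.94},
            covariates={"age": -0.26, "male": -5.64, "transfusion": 9.09,
                        "hydroxycarbamide": 7.09, "sci_burden": -0.004,
                        "etiv": 0.004, "education_decile": 0.50},
            noise_sd=11.9),
        "wmi": CognitionEffect(91.73, 13.69, 99.24, 13.48, noise_sd=13.69),
        "psi": CognitionEffect(
            89.49, 12.96, 97.55, 13.17,
            slopes={"cbf_mti_wm": -0.29},
            covariates={"age": -0.64, "male": -9.77, "education_decile": 1.34},
            noise_sd=10.8),
        "tower_completion_time": CognitionEffect(
            559.44, 147.44, 561.17, 151.88,
            slopes={"log:cbf_mti_sinus": 70.44, "log:bat_mti_wm": 416.65},
            covariates={"etiv": 0.31},
            noise_sd=126.0),
        "tower_achievement": CognitionEffect(
            9.0, 1.48, 9.5, 2.22,
            slopes={"log:cbf_mti_sinus": -0.57},
            noise_sd=1.4),
    }


@dataclass
class CohortSpec:
    """Generative specification of the synthetic cohort."""
    n_sca: int = 90
    n_control: int = 40
    seed: int = 0
    # hematology: Hb g/dL mean/sd, Hct/Hb ratio, SpO2 mean/sd (fractions)
    hb_sca: tuple[float, float] = (8.84, 1.2)
    hb_control: tuple[float, float] = (13.1, 0.8)
    hct_over_hb_sca: float = 0.24 / 8.84
    hct_over_hb_control: float = 0.41 / 13.1
    spo2_sca: tuple[float, float] = (0.97, 0.015)
    spo2_control: tuple[float, float] = (0.99, 0.008)
    # demographics / treatments
    age_range: tuple[float, float] = (8.0, 30.0)
    age_mean_sd: tuple[float, float] = (17.0, 4.0)
    male_prevalence: dict[str, float] = field(
        default_factory=lambda: {"SCA": 0.49, "control": 0.38})
    hydroxycarbamide_prevalence: float = 0.36
    transfusion_prevalence: float = 0.074
    sci_prevalence: dict[str, float] = field(
        default_factory=lambda: {"SCA": 0.41, "control": 0.095})
    sci_burden_lognorm: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"SCA": _lognorm_params(59.0, 33.5, 149.5),
                                 "control": _lognorm_params(19.0, 15.0, 35.5)})
    etiv_mean_sd: tuple[float, float] = (1450.0, 120.0)
    regions: dict[str, RegionEffects] = field(default_factory=_default_regions)
    cognition: dict[str, CognitionEffect] = field(default_factory=_default_cognition)

    def __post_init__(self):
        for name, eff in self.regions.items():
            if eff.sca[1] < 0 or eff.control[1] < 0:
                raise ValidationError(f"negative SD for region {name}")
        for p in (self.hydroxycarbamide_prevalence, self.transfusion_prevalence,
                  *self.male_prevalence.values(), *self.sci_prevalence.values()):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"prevalence {p!r} outside [0, 1]")

    @classmethod
    def null(cls, **kw) -> "CohortSpec":
        """A cohort with no planted effects: pooled group parameters, zero
        hemodynamic-CaO2 and cognition couplings. Noise is retained (a
        zero-noise cohort has constant features and degenerate tests)."""
        spec = cls(**kw)
        for name, eff in spec.regions.items():
            pooled = ((eff.sca[0] + eff.control[0]) / 2.0,
                      (eff.sca[1] + eff.control[1]) / 2.0)
            spec.regions[name] = replace(eff, sca=pooled, control=pooled, cao2_r=0.0)
        for name, cog in spec.cognition.items():
            mean = (cog.sca_mean + cog.control_mean) / 2.0
            sd = (cog.sca_sd + cog.control_sd) / 2.0
            spec.cognition[name] = CognitionEffect(mean, sd, mean, sd,
                                                   noise_sd=cog.noise_sd)
        return spec


def _subject_rng(cohort_seed: int, index: int) -> np.random.Generator:
    # independent, reproducible stream per subject
    return np.random.default_rng(np.random.SeedSequence([int(cohort_seed), int(index)]))


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw the per-subject cohort table.

    Returns one row per subject with demographics, hematology (+ derived CaO2
    and T1-blood), treatments, SCI, eTIV, education, the nine hemodynamic
    features (which double as phantom ground truth for image-level simulation)
    and cognitive scores. Deterministic given ``spec.seed``.
    """
    rows = []
    groups = [Group.SCA.value] * spec.n_sca + [Group.CONTROL.value] * spec.n_control
    # pass 1: physiology and hemodynamics
    for i, grp in enumerate(groups):
        rng = _subject_rng(spec.seed, i)
        sca = grp == Group.SCA.value
        lo, hi = spec.age_range
        age = float(np.clip(rng.normal(*spec.age_mean_sd), lo, hi))
        male = bool(rng.random() < spec.male_prevalence[grp])
        hb_mu, hb_sd = spec.hb_sca if sca else spec.hb_control
        hb = float(np.clip(rng.normal(hb_mu, hb_sd), 4.0, 18.0))
        ratio = spec.hct_over_hb_sca if sca else spec.hct_over_hb_control
        hct = float(np.clip(hb * ratio * rng.normal(1.0, 0.02), 0.12, 0.55))
        sp_mu, sp_sd = spec.spo2_sca if sca else spec.spo2_control
        spo2 = float(np.clip(rng.normal(sp_mu, sp_sd), 0.80, 1.0))
        cao2 = compute_cao2(hb, spo2)
        t1b = estimate_t1_blood(hct, spo2)

        hydroxy = bool(sca and rng.random() < spec.hydroxycarbamide_prevalence)
        transf = bool(sca and rng.random() < spec.transfusion_prevalence)
        sci = bool(rng.random() < spec.sci_prevalence[grp])
        if sci:
            mu, sig = spec.sci_burden_lognorm[grp]
            sci_burden = float(np.round(np.exp(rng.normal(mu, sig))))
        else:
            sci_burden = 0.0
        etiv = float(rng.normal(*spec.etiv_mean_sd))
        edu = int(np.clip(np.round(rng.normal(5.0, 2.0)), 1, 10))

        row = {
            "subject_id": f"sub-{i:03d}", "group": grp, "age": age,
            "sex": "male" if male else "female", "male": int(male),
            "hemoglobin": hb, "hematocrit": hct, "spo2": spo2,
            "cao2": cao2, "t1_blood": t1b,
            "hydroxycarbamide": int(hydroxy), "transfusion": int(transf),
            "sci": int(sci), "sci_burden": sci_burden,
            "etiv": etiv, "education_decile": edu,
        }
        rows.append(row)
    df = pd.DataFrame(rows)

    # pass 2: hemodynamic features with CaO2 coupling inside the SCA group.
    # The coupling is expressed through the planted correlation r: slope =
    # r*sd_y/sd_x on the generative scale, residual SD shrunk so the marginal
    # SD stays at its configured value.
    for grp, sel in (("SCA", df["group"] == "SCA"),
                     ("control", df["group"] == "control")):
        cao2 = df.loc[sel, "cao2"].to_numpy()
        cao2_sd = cao2.std(ddof=1) if sel.sum() > 1 else 1.0
        cao2_c = cao2 - cao2.mean()
        for j, (name, eff) in enumerate(spec.regions.items()):
            loc, scale = eff.sca if grp == "SCA" else eff.control
            r = eff.cao2_r if grp == "SCA" else 0.0
            slope = r * scale / cao2_sd if cao2_sd > 0 else 0.0
            resid_sd = scale * np.sqrt(max(1.0 - r ** 2, 0.0))
            draws = np.empty(sel.sum())
            for k_sub, idx in enumerate(np.flatnonzero(sel.to_numpy())):
                rng = np.random.default_rng(
                    np.random.SeedSequence([int(spec.seed), int(idx), 1000 + j]))
                draws[k_sub] = loc + slope * cao2_c[k_sub] + rng.normal(0.0, resid_sd)
            if eff.lognormal:
                draws = np.exp(draws)
            else:
                draws = np.clip(draws, 1e-3, None)
            df.loc[sel, name] = draws

    # pass 3: cognition (stable per-outcome stream index, not hash(): string
    # hashing is randomised per process and would break determinism)
    for m, (name, cog) in enumerate(spec.cognition.items()):
        vals = np.empty(len(df))
        for idx in range(len(df)):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(spec.seed), int(idx), 2000 + m]))
            row = df.iloc[idx]
            if row["group"] == "SCA":
                systematic = 0.0
                for feat, b in cog.slopes.items():
                    if feat.startswith("log:"):
                        systematic += b * np.log(row[feat[4:]])
                    else:
                        systematic += b * row[feat]
                for cov, b in cog.covariates.items():
                    systematic += b * row[cov]
                # intercept centres the marginal mean at the configured value
                intercept = cog.sca_mean - _expected_systematic(spec, cog)
                vals[idx] = intercept + systematic + rng.normal(0.0, cog.noise_sd)
            else:
                vals[idx] = rng.normal(cog.control_mean, cog.control_sd)
        df[name] = vals
    return df


def _expected_systematic(spec: CohortSpec, cog: CognitionEffect) -> float:
    """Expected value of the planted systematic part over the SCA population."""
    exp = 0.0
    for feat, b in cog.slopes.items():
        if feat.startswith("log:"):
            eff = spec.regions[feat[4:]]
            exp += b * (eff.sca[0] if eff.lognormal else np.log(eff.sca[0]))
        else:
            eff = spec.regions[feat]
            exp += b * (np.exp(eff.sca[0]) if eff.lognormal else eff.sca[0])
    means = {
        "age": spec.age_mean_sd[0],
        "male": spec.male_prevalence["SCA"],
        "transfusion": spec.transfusion_prevalence,
        "hydroxycarbamide": spec.hydroxycarbamide_prevalence,
        "sci_burden": spec.sci_prevalence["SCA"]
        * np.exp(spec.sci_burden_lognorm["SCA"][0]
                 + spec.sci_burden_lognorm["SCA"][1] ** 2 / 2.0),
        "etiv": spec.etiv_mean_sd[0],
        "education_decile": 5.0,
    }
    for cov, b in cog.covariates.items():
        exp += b * means[cov]
    return exp
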