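"""End-to-end orchestration: phantom -> normalize -> register -> segment ->
measure -> biomarkers -> statistics.

A cohort run generates a synthetic two-group cohort table, renders one
phantom subject per row (the subject's true wall T2 signal drives the
phantom), executes the imaging pipeline in the study's order (T2w
normalization first, then registration of CT-like and T2w-like volumes onto
the UTE-like reference, tree extraction and wall measurement on the
registered CT, mask transfer onto the normalized registered T2w), and runs
the statistics battery on the assembled biomarker table.  Subjects are
processed in a seed-shuffled order recorded in the manifest, mirroring the
study's randomized, blinded measurement protocol.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import stats as bwstats
from .airway import (
    SelectionError,
    extract_centerline,
    pick_measurement_sites,
    reformat_cross_section,
    segment_lumen,
    select_paths,
)
from .cohort import CohortSpec, generate_cohort
from .phantom import PhantomSpec, generate_phantom
from .preprocess import DeformationField, RegistrationConfig, normalize_t2, register, warp_volume
from .volume import ImageVolume
from .wallquant import (
    WallMeasurementError,
    brwall_t2_mis,
    detect_wall,
    wall_mask_3d,
)


@dataclass
class MeasurementConfig:
    n_sites: int = 2
    section_size_mm: float = 14.0
    slab_thickness_mm: float = 2.5
    mask_margin_mm: float = 0.25  # partial-volume guard when sampling T2w
    sigma_sweep: tuple[float, ...] = (0.3, 0.5, 0.8)
    generation: int = 3


@dataclass
class RunConfig:
    """One configuration drives a full run; every parameter has a default."""

    seed: int = 0
    n_per_group: int = 15
    mode: str = "phantom"  # "phantom" | "table-only"
    output_dir: str | None = None
    phantom: dict = field(default_factory=dict)  # PhantomSpec overrides
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    #: RegistrationConfig overrides; the cohort default trades a little
    #: registration polish for throughput — the wall-mask margin absorbs
    #: the residual misalignment at the biomarker stage
    registration: dict = field(default_factory=lambda: {"iterations": (30, 20, 10)})
    measurement: MeasurementConfig = field(default_factory=MeasurementConfig)
    registration_enabled: bool = True

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        meas = MeasurementConfig(**raw.pop("measurement", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(measurement=meas, **raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.md5(payload.encode()).hexdigest()


@dataclass
class RunManifest:
    subject: str
    seed: int
    config_hash: str
    stages: dict = field(default_factory=dict)  # stage -> "ok" | error string
    checksums: dict = field(default_factory=dict)
    exclusions: list = field(default_factory=list)

    def record(self, stage: str, status: str = "ok") -> None:
        self.stages[stage] = status

    def checksum(self, name: str, arr: np.ndarray) -> None:
        self.checksums[name] = hashlib.md5(np.ascontiguousarray(arr).tobytes()).hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")


def _native_seed(ct: ImageVolume, truth, field: "DeformationField | None") -> np.ndarray:
    """Map the tracheal seed from the fixed frame into the native CT frame."""
    seed = np.asarray(truth.trachea_seed_mm, dtype=float)
    if field is None:
        return seed
    idx = np.clip(
        np.round(ct.world_to_index(seed)).astype(int), 0, np.asarray(ct.shape) - 1
    )
    return seed + field.displacement[tuple(idx)]


def _phantom_spec(config: RunConfig, wall_signal: float, seed: int) -> PhantomSpec:
    overrides = dict(config.phantom)
    overrides.setdefault("grid_shape", (96, 96, 96))
    return PhantomSpec(wall_t2_signal=wall_signal, seed=seed, **overrides)


def run_subject(
    config: RunConfig,
    subject_id: str,
    wall_signal: float = 60.0,
    seed: int | None = None,
    site_jitter_mm: float = 0.0,
    jitter_seed: int = 0,
    extra_readings: tuple = (),
):
    """Run one phantom subject through the full imaging pipeline.

    Returns (PatientBiomarkers, RunManifest).  ``site_jitter_mm`` perturbs
    the measurement-site positions along the centerline (used to emulate
    reader variability for reproducibility analyses).  ``extra_readings``
    is a tuple of (jitter_mm, jitter_seed) pairs: each yields an additional
    reading from the same registered volumes, appended to the primary
    biomarkers' ``replicates`` list.
    """
    seed = config.seed if seed is None else seed
    manifest = RunManifest(subject=subject_id, seed=seed, config_hash=config.config_hash())

    try:
        spec = _phantom_spec(config, wall_signal, seed)
        ct, ute, t2, truth = generate_phantom(spec)
    except Exception as err:
        manifest.record("phantom", f"error: {err}")
        raise StageError("phantom", str(err)) from err
    manifest.record("phantom")
    manifest.checksum("ute", ute.data)

    try:
        norm = normalize_t2(t2)
    except Exception as err:
        manifest.record("normalize", f"error: {err}")
        raise StageError("normalize", str(err)) from err
    manifest.record("normalize")

    reg_cfg = RegistrationConfig(**config.registration)
    ct_field: DeformationField | None = None
    if config.registration_enabled and spec.deformation_amplitude > 0:
        try:
            ct_res = register(ct, ute, reg_cfg)
            ct_reg, ct_field = ct_res.warped, ct_res.field
            t2_reg = register(norm.volume, ute, reg_cfg).warped
        except Exception as err:
            manifest.record("register", f"error: {err}")
            raise StageError("register", str(err)) from err
    else:
        ct_reg, t2_reg = ct, norm.volume
    manifest.record("register")
    manifest.checksum("ct_registered", ct_reg.data)

    meas_cfg = config.measurement
    try:
        # segment and skeletonize on the crisp native CT (reliable topology),
        # then carry the mask and the centerline into the UTE frame through
        # the recovered field
        native_seed = _native_seed(ct, truth, ct_field)
        lumen_native = segment_lumen(ct, native_seed)
        if ct_field is not None:
            lumen = (
                warp_volume(
                    ImageVolume(lumen_native.astype(np.float32), ct.affine),
                    ct_field,
                    ute,
                    order=0,
                ).data
                > 0.5
            )
        else:
            lumen = lumen_native
        tree = extract_centerline(lumen_native, ct.affine, native_seed)
        if ct_field is not None:
            from .preprocess import pullback_points

            for branch in tree.branches.values():
                branch.points_mm = pullback_points(branch.points_mm, ct_field)
        try:
            selection = select_paths(
                tree, truth.lobe_map, generation=meas_cfg.generation, ct=ct_reg, lumen_mask=lumen
            )
        except SelectionError as err:
            # a lobe whose path the skeleton could not resolve is excluded,
            # mirroring the study's per-bronchus exclusions; fail only when
            # no lobe resolves at all
            remaining = {k: v for k, v in truth.lobe_map.items() if k not in err.missing}
            if not remaining:
                raise
            selection = select_paths(
                tree, remaining, generation=meas_cfg.generation, ct=ct_reg, lumen_mask=lumen
            )
            for lobe in err.missing:
                selection.exclusions.append(
                    {"lobe": lobe, "reason": "no resolvable generation-3 branch"}
                )
    except (SelectionError, ValueError) as err:
        manifest.record("airway", f"error: {err}")
        raise StageError("airway", str(err)) from err
    manifest.record("airway")
    manifest.exclusions.extend(selection.exclusions)

    def measure_once(jmm: float, jseed: int, record: bool):
        jit_rng = np.random.default_rng(jseed)
        measurements = []
        for lobe, path in selection.paths.items():
            lumen_d = 2.0 * spec.lumen_radius_by_generation[
                min(meas_cfg.generation, spec.tree_depth)
            ]
            try:
                requests = pick_measurement_sites(
                    path,
                    n_sites=meas_cfg.n_sites,
                    lumen_diameter_mm=lumen_d,
                    section_size_mm=meas_cfg.section_size_mm,
                )
            except ValueError as err:
                if record:
                    manifest.exclusions.append({"lobe": lobe, "reason": str(err)})
                continue
            for req in requests:
                if jmm > 0:
                    s = req.arc_position_mm + jit_rng.uniform(-jmm, jmm)
                    pos, tan = path.point_at_arclength(float(np.clip(s, 0, path.arc_length)))
                    req.center_mm, req.normal = pos, tan
                try:
                    section = reformat_cross_section(ct_reg, req)
                    meas = detect_wall(section, sigma_sweep=meas_cfg.sigma_sweep)
                except (WallMeasurementError, ValueError) as err:
                    if record:
                        manifest.exclusions.append(
                            {"lobe": lobe, "site": req.site, "reason": f"measurement failure: {err}"}
                        )
                    continue
                measurements.append(meas)
        if not measurements:
            raise StageError("wallquant", "no successful wall measurements")
        masks = wall_mask_3d(
            measurements,
            ute,
            slab_thickness_mm=meas_cfg.slab_thickness_mm,
            lumen_mask=lumen,
            margin_mm=meas_cfg.mask_margin_mm,
        )
        return brwall_t2_mis(masks, t2_reg, measurements)

    try:
        biomarkers = measure_once(site_jitter_mm, jitter_seed, record=True)
    except StageError as err:
        manifest.record("wallquant", f"error: {err}")
        raise
    manifest.record("wallquant")
    biomarkers.exclusions = manifest.exclusions + biomarkers.exclusions
    biomarkers.replicates = [measure_once(jmm, jseed, record=False) for jmm, jseed in extra_readings]
    manifest.record("biomarker")
    return biomarkers, manifest


@dataclass
class CohortResult:
    table: pd.DataFrame
    report: dict
    manifests: list


def run_cohort(config: RunConfig) -> CohortResult:
    """Run a full two-group cohort and the statistics battery.

    In ``table-only`` mode the statistics are computed directly on a
    generated cohort table (no imaging).  In ``phantom`` mode each row also
    gets a rendered phantom subject whose measured BrWall_T2-MIS (plus a
    second, site-jittered reading for reproducibility) replaces the
    generator's true signal in the analysis.
    """
    rng = np.random.default_rng(config.seed)
    cohort_spec = CohortSpec(
        n_per_group=config.n_per_group, seed=int(rng.integers(2**31)), **config.cohort
    )
    table = generate_cohort(cohort_spec)
    manifests: list[RunManifest] = []

    if config.mode == "phantom":
        # randomized, blinded measurement order (recorded in the manifests)
        order = rng.permutation(len(table))
        measured = np.full(len(table), np.nan)
        measured_rep = np.full(len(table), np.nan)
        wa_meas = np.full(len(table), np.nan)
        subject_seeds = rng.integers(2**31, size=len(table))
        for row_idx in order:
            row = table.iloc[row_idx]
            bio, man = run_subject(
                config,
                row.subject,
                wall_signal=float(row.brwall_t2_mis),
                seed=int(subject_seeds[row_idx]),
                extra_readings=((0.8, int(subject_seeds[row_idx]) ^ 0x5EED),),
            )
            measured[row_idx] = bio.brwall_t2_mis
            measured_rep[row_idx] = bio.replicates[0].brwall_t2_mis
            wa_meas[row_idx] = bio.wa_percent
            manifests.append(man)
        table = table.rename(columns={"brwall_t2_mis": "brwall_true"})
        table["brwall_t2_mis"] = measured
        table["brwall_t2_mis_rep"] = measured_rep
        table["wa_percent"] = wa_meas

    report = build_stats_report(table)
    return CohortResult(table=table, report=report, manifests=manifests)


# ---------------------------------------------------------------------------
# report assembly


def _gated_columns(df: pd.DataFrame, col: str) -> np.ndarray:
    vals = df[col].to_numpy(dtype=float)
    try:
        gate = bwstats.shapiro_gate_transform(vals)
        return gate.values
    except ValueError:
        return vals


def build_stats_report(
    table: pd.DataFrame,
    biomarker: str = "brwall_t2_mis",
    group_col: str = "group",
    positive_group: str = "severe",
) -> dict:
    """Assemble the full statistics report for a cohort table.

    Sections mirror the study's analysis: per-variable group comparisons
    (normality-gated), a sex contingency test, biomarker ROC with the
    Youden operating point, stepwise logistic regression on the
    frequent-exacerbator outcome, biomarker correlations (whole cohort and
    per group), WA% quartile ANOVA when available, and ICC/Bland-Altman
    reproducibility when replicate readings are present.
    """
    df = table
    groups = df[group_col].unique()
    if len(groups) < 2:
        return {"warning": "single-group cohort: statistics skipped"}
    pos = df[df[group_col] == positive_group]
    neg = df[df[group_col] != positive_group]

    numeric = [
        c
        for c in df.columns
        if df[c].dtype.kind in "if"
        and c not in {"aer_ge2"}
        and not c.endswith("_rep")
        and df[c].notna().all()
    ]
    comparisons = {}
    for col in numeric:
        try:
            gc = bwstats.compare_groups_continuous(
                pos[col].to_numpy(float), neg[col].to_numpy(float)
            )
        except ValueError as err:
            comparisons[col] = {"error": str(err)}
            continue
        comparisons[col] = {
            "n": gc.n,
            "mean": gc.mean,
            "sd": gc.sd,
            "t": gc.statistic,
            "p": gc.p_value,
            "log_transformed": gc.transformed,
            "geometric": gc.geometric,
        }

    report: dict = {"group_comparisons": comparisons}

    if "sex" in df.columns:
        tab = [
            [int((pos.sex == "M").sum()), int((pos.sex == "F").sum())],
            [int((neg.sex == "M").sum()), int((neg.sex == "F").sum())],
        ]
        try:
            cat = bwstats.compare_groups_categorical(tab)
            report["sex"] = {"table": tab, "test": cat.test, "p": cat.p_value}
        except ValueError as err:
            report["sex"] = {"table": tab, "error": str(err)}

    labels = (df[group_col] == positive_group).astype(int).to_numpy()
    roc = bwstats.roc_youden(df[biomarker].to_numpy(float), labels)
    report["roc"] = {
        "auc": roc.auc,
        "auc_ci": roc.auc_ci,
        "auc_p": roc.auc_p,
        "cutoff": roc.cutoff,
        "sensitivity": roc.sensitivity,
        "sensitivity_ci": roc.sensitivity_ci,
        "specificity": roc.specificity,
        "specificity_ci": roc.specificity_ci,
        "youden_j": roc.youden_j,
    }

    corr_vars = [c for c in numeric if c not in {biomarker, "aer_next", "brwall_true"}]
    correlations: dict = {}
    for scope, sub in (("whole", df), ("severe", pos), ("non-severe", neg)):
        section = {}
        for col in corr_vars:
            try:
                x = _gated_columns(sub, biomarker)
                y = _gated_columns(sub, col)
                r, p = bwstats.pearson_corr(x, y)
                section[col] = {"r": r, "p": p}
            except ValueError as err:
                section[col] = {"error": str(err)}
        correlations[scope] = section
    report["correlations"] = correlations

    if "aer_ge2" in df.columns:
        candidates = {
            c: df[c].to_numpy(float)
            for c in ("fev1_pp", "fvc_pp", "fef2575_pp", "pef", biomarker)
            if c in df.columns
        }
        for c in ("feno", "eos"):
            if c in df.columns:
                candidates[c] = np.log(df[c].to_numpy(float))
        y = df["aer_ge2"].to_numpy(int)
        if len(np.unique(y)) == 2 and len(df) > len(candidates):
            step = bwstats.stepwise_logistic(y, candidates)
            report["stepwise_logistic"] = {
                "selected": step.selected,
                "odds_ratios": {k: list(v) for k, v in step.odds_ratios.items()},
                "p_values": step.p_values,
                "separation_flag": step.separation_flag,
            }

    if "wa_percent" in df.columns and df["wa_percent"].notna().all() and len(df) >= 8:
        try:
            qa = bwstats.quartile_anova(
                df["wa_percent"].to_numpy(float), df[biomarker].to_numpy(float)
            )
            report["quartile_anova_wa_groups"] = {
                "F": qa.f_statistic,
                "p": qa.p_value,
                "group_means": qa.group_means,
            }
            qa2 = bwstats.quartile_anova(
                df[biomarker].to_numpy(float), df["wa_percent"].to_numpy(float)
            )
            report["quartile_anova_biomarker_groups"] = {
                "F": qa2.f_statistic,
                "p": qa2.p_value,
                "group_means": qa2.group_means,
            }
        except ValueError as err:
            report["quartile_anova_wa_groups"] = {"error": str(err)}

    rep_col = f"{biomarker}_rep"
    if rep_col in df.columns and df[rep_col].notna().all():
        a = df[biomarker].to_numpy(float)
        b = df[rep_col].to_numpy(float)
        icc = bwstats.icc_absolute(np.column_stack([a, b]))
        ba = bwstats.bland_altman(a, b)
        report["reproducibility"] = {
            "icc": icc.icc,
            "icc_ci": icc.icc_ci,
            "icc_label": icc.icc_label,
            "mean_difference": ba.mean_difference,
            "mean_difference_ci": ba.mean_difference_ci,
            "loa": ba.loa,
        }
    return report
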