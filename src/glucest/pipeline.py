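"""Study-level driver: simulate -> correct -> quantify -> group statistics.

Stage order within a subject is fixed and logged:
normalise -> B0-correct -> GluCEST map -> B1 policy -> ROI statistics.
All randomness derives from the single study seed through per-subject
``SeedSequence`` spawn keys, so adding a subject never reshuffles the
noise of existing ones.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .b0 import apply_b0_correction, build_b0_map
from .b1 import DEFAULT_EXCLUDE_THRESHOLD, apply_b1_policy, compute_relative_b1
from .core import GluCestMap, RoiSummary, ZStack
from .io import save_image, save_mask, save_zstack
from .quant import glucest_map, mtr_asym_spectrum, normalize_zstack, roi_quantify
from .sim import AcquisitionSpec, SyntheticStudy, make_phantom, simulate_phantom
from .stats import GroupSummary, anova_oneway

logger = logging.getLogger(__name__)

STAGE_ORDER = ("normalize", "b0_correct", "glucest_map", "b1_policy", "roi")


@dataclass(frozen=True)
class GroupSpec:
    """One simulated animal group: label, size, glutamate pool amplitude."""

    label: str
    n_subjects: int
    glu_amplitude: float

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("group needs at least one subject")


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of a simulated GluCEST study.

    Serialises losslessly to/from JSON (``to_json`` / ``from_json``) so a
    run is reproducible from its written config alone.
    """

    groups: tuple[GroupSpec, ...] = (
        GroupSpec("CTRL", 7, 0.040),
        GroupSpec("SEP05", 7, 0.046),
        GroupSpec("SEP10", 7, 0.056),
    )
    matrix: tuple[int, int] = (16, 16)
    glu_amplitude_outside: float = 0.030
    b0_max: float = 0.1
    b1_range: tuple[float, float] = (0.9, 1.1)
    noise_sigma: float = 0.01
    b0_correction: bool = True
    b1_policy: str = "scale"
    b1_exclude_threshold: float = DEFAULT_EXCLUDE_THRESHOLD
    b0_method: str = "spline"
    seed: int = 0
    write_subject_maps: bool = True

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["groups"] = [dataclasses.asdict(g) for g in self.groups]
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["groups"] = tuple(GroupSpec(**g) for g in d["groups"])
        for key in ("matrix", "b1_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SubjectResult:
    group: str
    subject: str
    glu_map: GluCestMap
    roi: RoiSummary
    asym_offsets: np.ndarray
    asym_roi_mean: np.ndarray
    study: SyntheticStudy


@dataclass
class StudyReport:
    config: RunConfig
    subjects: list[SubjectResult]
    group_table: pd.DataFrame
    anova_table: pd.DataFrame
    tukey_table: pd.DataFrame
    asym_table: pd.DataFrame
    log_lines: list[str] = field(default_factory=list)


def subject_seed(study_seed: int, group_idx: int, subject_idx: int) -> int:
    """Deterministic per-subject seed; stable under adding later subjects."""
    ss = np.random.SeedSequence(entropy=study_seed, spawn_key=(group_idx, subject_idx))
    return int(ss.generate_state(1)[0] % (2**31))


def process_subject(
    study: SyntheticStudy,
    b0_correction: bool = True,
    b1_policy: str = "scale",
    b1_exclude_threshold: float = DEFAULT_EXCLUDE_THRESHOLD,
    b0_method: str = "spline",
) -> tuple[GluCestMap, ZStack]:
    """Run the per-subject quantification chain on a simulated subject.

    Returns the final GluCEST map and the normalised (optionally
    B0-corrected) stack the map was computed from.
    """
    norm = normalize_zstack(study.cest_stack)
    if b0_correction:
        b0 = build_b0_map(study.wassr_stack, method=b0_method)
        norm = apply_b0_correction(norm, b0)
    gmap = glucest_map(norm)
    gmap.provenance["b0_corrected"] = bool(b0_correction)
    if b1_policy != "none":
        b1 = compute_relative_b1(
            *study.angle_images, nominal_angle=study.acq.b1_angles[0]
        )
        gmap = apply_b1_policy(
            gmap, b1, policy=b1_policy, exclude_threshold=b1_exclude_threshold
        )
    else:
        gmap.provenance["b1_policy"] = "none"
    return gmap, norm


def run_study(config: RunConfig, out_dir: str | Path | None = None) -> StudyReport:
    """Execute a full simulated study and (optionally) write its report.

    Per subject: B0/B1/GluCEST maps and the ROI summary.  Per study: the
    group table, ANOVA and Tukey tables, the ROI-mean MTR-asymmetry
    spectra per group, and a plain-text run log recording the package
    version, seed, stage order and every policy decision.
    """
    acq = AcquisitionSpec(matrix=config.matrix)
    log: list[str] = [
        f"glucest {__version__}",
        f"seed {config.seed}",
        f"stage order: {' -> '.join(STAGE_ORDER)}",
        f"b0_correction {config.b0_correction} (method {config.b0_method})",
        f"b1_policy {config.b1_policy} (exclude threshold "
        f"{config.b1_exclude_threshold})",
    ]
    subjects: list[SubjectResult] = []
    stage = "simulate"
    try:
        for gi, group in enumerate(config.groups):
            for si in range(group.n_subjects):
                stage = f"simulate {group.label}#{si + 1}"
                phantom = make_phantom(
                    matrix=config.matrix,
                    glu_amplitude=group.glu_amplitude,
                    glu_amplitude_outside=config.glu_amplitude_outside,
                    b0_max=config.b0_max,
                    b1_range=config.b1_range,
                    noise_sigma=config.noise_sigma,
                    seed=subject_seed(config.seed, gi, si),
                )
                study = simulate_phantom(phantom, acq)
                stage = f"process {group.label}#{si + 1}"
                gmap, norm = process_subject(
                    study,
                    b0_correction=config.b0_correction,
                    b1_policy=config.b1_policy,
                    b1_exclude_threshold=config.b1_exclude_threshold,
                    b0_method=config.b0_method,
                )
                roi = roi_quantify(gmap, phantom.roi_mask, roi_label="hippocampus")
                offs, asym = mtr_asym_spectrum(norm.data, norm.offsets)
                sel = phantom.roi_mask & gmap.mask
                asym_mean = np.nanmean(asym[sel], axis=0)
                subjects.append(
                    SubjectResult(
                        group=group.label,
                        subject=f"{group.label}_{si + 1:02d}",
                        glu_map=gmap,
                        roi=roi,
                        asym_offsets=offs,
                        asym_roi_mean=asym_mean,
                        study=study,
                    )
                )
    except Exception as err:
        raise RuntimeError(f"study failed at stage '{stage}': {err}") from err

    stage = "stats"
    per_subject = pd.DataFrame(
        {
            "group": [s.group for s in subjects],
            "subject": [s.subject for s in subjects],
            "glucest_mean_pct": [s.roi.mean for s in subjects],
            "glucest_sd_pct": [s.roi.sd for s in subjects],
            "n_voxels": [s.roi.n_voxels for s in subjects],
        }
    )
    summaries = [
        GroupSummary(
            label=g.label,
            n=int(sub.shape[0]),
            mean=float(sub["glucest_mean_pct"].mean()),
            sd=float(sub["glucest_mean_pct"].std(ddof=1)),
        )
        for g in config.groups
        for sub in (per_subject[per_subject["group"] == g.label],)
    ]
    anova = anova_oneway(summaries)
    group_table = pd.DataFrame(
        {
            "group": [g.label for g in anova.groups],
            "n": [g.n for g in anova.groups],
            "mean_pct": [g.mean for g in anova.groups],
            "sd_pct": [g.sd for g in anova.groups],
        }
    )
    anova_table = pd.DataFrame(
        [
            {
                "f_stat": anova.f_stat,
                "df_between": anova.df_between,
                "df_within": anova.df_within,
                "p": anova.p,
            }
        ]
    )
    tukey_table = pd.DataFrame(
        [
            {
                "group_a": c.pair[0],
                "group_b": c.pair[1],
                "mean_diff": c.mean_diff,
                "q_stat": c.q_stat,
                "adjusted_p": c.adjusted_p,
            }
            for c in anova.pairwise
        ]
    )
    asym_rows = {}
    for g in config.groups:
        curves = [s.asym_roi_mean for s in subjects if s.group == g.label]
        asym_rows[g.label] = np.mean(curves, axis=0)
    asym_table = pd.DataFrame(asym_rows, index=subjects[0].asym_offsets)
    asym_table.index.name = "offset_ppm"

    report = StudyReport(
        config=config,
        subjects=subjects,
        group_table=group_table,
        anova_table=anova_table,
        tukey_table=tukey_table,
        asym_table=asym_table,
        log_lines=log,
    )
    if out_dir is not None:
        _write_report(report, per_subject, Path(out_dir))
    return report


def _write_report(report: StudyReport, per_subject: pd.DataFrame, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(report.config.to_json())
    per_subject.to_csv(out / "subjects.csv", index=False)
    report.group_table.to_csv(out / "groups.csv", index=False)
    report.anova_table.to_csv(out / "anova.csv", index=False)
    report.tukey_table.to_csv(out / "tukey.csv", index=False)
    report.asym_table.to_csv(out / "mtr_asym_spectra.csv")
    if report.config.write_subject_maps:
        maps_dir = out / "maps"
        maps_dir.mkdir(exist_ok=True)
        for s in report.subjects:
            save_image(s.glu_map.value, maps_dir / f"{s.subject}_glucest.nii.gz")
            save_mask(s.glu_map.mask, maps_dir / f"{s.subject}_mask.nii.gz")
    (out / "run.log").write_text("\n".join(report.log_lines) + "\n")


def write_simulation(study: SyntheticStudy, out: Path) -> None:
    """Write one simulated subject's raw data as NIfTI + sidecars."""
    out.mkdir(parents=True, exist_ok=True)
    acq, ph = study.acq, study.phantom
    save_zstack(
        study.cest_stack,
        out / "cest.nii.gz",
        sidecar={
            "sat_power_uT": acq.cest_sat_power,
            "sat_time_s": acq.cest_sat_time,
            "seed": ph.seed,
        },
    )
    save_zstack(
        study.wassr_stack,
        out / "wassr.nii.gz",
        sidecar={"sat_power_uT": acq.wassr_sat_power, "seed": ph.seed},
    )
    for angle, img in zip(acq.b1_angles, study.angle_images):
        save_image(img, out / f"angle{int(angle):02d}.nii.gz")
    save_mask(ph.roi_mask, out / "roi.nii.gz")
    save_image(study.truth_b0.shift, out / "truth_b0.nii.gz")
    save_image(study.truth_b1.relative, out / "truth_b1.nii.gz")
    save_image(study.truth_glucest.value, out / "truth_glucest.nii.gz")
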