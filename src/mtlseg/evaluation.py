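"""Metrics, full-pipeline orchestration, and cohort experiments.

`segment` runs the complete hybrid multi-template pipeline:
initial subset selection (n_a) -> boundary-weighted non-linear registration
per retained template -> subset restriction (n_b) -> global weighted
averaging -> multi-level local weighted averaging -> label synthesis,
and reports per-stage Dice when ground truth is available.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field

import numpy as np

from .fusion import (
    FusionConfig,
    FusionWeights,
    WarpedTemplate,
    finalize_segmentation,
    fuse_unweighted,
    optimize_global_weights,
    optimize_local_weights,
    restrict_subset,
    warp_template,
)
from .imaging import LabelVolume, STRUCTURES, Volume3D, crop_volume
from .library import TemplateLibrary, build_library
from .mesh import CorrespondedSurface, surface_to_label
from .registration import RegistrationConfig, register_hybrid
from .selection import SelectionConfig, SelectionResult, select_subset
from .synthetic import Cohort, TestSubject


# ---------------------------------------------------------------- metrics
def dice(m: LabelVolume, a: LabelVolume, structure: str) -> float:
    """Dice overlap 2|M∩A| / (|M|+|A|); both empty counts as 1.0."""
    if not m.same_geometry(a):
        raise ValueError("label geometries differ")
    mm = m.structure_mask(structure)
    aa = a.structure_mask(structure)
    denom = int(mm.sum()) + int(aa.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.sum(mm & aa)) / denom


def dice_report(m: LabelVolume, a: LabelVolume) -> dict:
    out = {s: dice(m, a, s) for s in STRUCTURES}
    out["mean"] = float(np.mean([out[s] for s in STRUCTURES]))
    return out


def cohens_d(control_volumes, patient_volumes) -> float:
    """(mean controls − mean patients) / pooled SD; positive = atrophy."""
    c = np.asarray(control_volumes, dtype=float)
    p = np.asarray(patient_volumes, dtype=float)
    if len(c) < 2 or len(p) < 2:
        raise ValueError("each group needs n >= 2")
    sc2, sp2 = c.var(ddof=1), p.var(ddof=1)
    pooled = np.sqrt(((len(c) - 1) * sc2 + (len(p) - 1) * sp2)
                     / (len(c) + len(p) - 2))
    if pooled < 1e-12:
        raise ValueError("zero pooled SD")
    return float((c.mean() - p.mean()) / pooled)


def atrophy_flag(volume: float, control_mean: float,
                 control_sd: float) -> tuple[float, bool]:
    """z-score of a volume against controls; flagged when z < -2 (strict)."""
    if control_sd <= 0:
        raise ValueError("control SD must be > 0")
    z = (volume - control_mean) / control_sd
    return float(z), bool(z < -2.0)


# ----------------------------------------------------------- configuration
@dataclass
class PipelineConfig:
    selection: SelectionConfig = dc_field(default_factory=SelectionConfig)
    registration: RegistrationConfig = dc_field(
        default_factory=RegistrationConfig)
    fusion: FusionConfig = dc_field(default_factory=FusionConfig)
    exclude_id: str | None = None

    @classmethod
    def desk_scale(cls, n_a: int = 6, n_b: int = 5,
                   exclude_id: str | None = None) -> "PipelineConfig":
        """Reduced-cost profile for desk-scale cohort studies.

        Uses a (10, 6) mm lattice schedule with short Nelder-Mead budgets
        and sub-sampled feature neighbourhoods; see the methods note for
        the rationale behind each value.
        """
        return cls(
            selection=SelectionConfig(
                n_a=n_a, n_b=n_b, max_samples_per_radius=100, fast_inside=True,
            ),
            registration=RegistrationConfig(
                lattice_spacings=(10.0, 6.0), sweeps_per_level=2, nm_maxiter=8,
                ri_n_points=48, ri_template_points=512, mask_subsample=4,
            ),
            fusion=FusionConfig(
                l0=2, l_max=3, nm_maxiter_global=30, nm_maxiter_local=10,
                max_samples_per_radius=100, fast_inside=True,
                local_skip_agreement_mm=1.0,
            ),
            exclude_id=exclude_id,
        )


@dataclass
class StageReport:
    """Per-stage Dice (against truth, when known) and similarity values."""

    stages: list = dc_field(default_factory=list)  # (name, dice dict | None)
    similarities: dict = dc_field(default_factory=dict)

    def add(self, name: str, dice_values: dict | None) -> None:
        self.stages.append((name, dice_values))

    def mean_dice(self, name: str) -> float:
        for n, d in self.stages:
            if n == name and d is not None:
                return d["mean"]
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {"stages": [(n, d) for n, d in self.stages],
                "similarities": self.similarities}


@dataclass
class SegmentationResult:
    label: LabelVolume
    surface: CorrespondedSurface
    stage_report: StageReport
    selection: list[SelectionResult]
    restricted: list[SelectionResult]
    weights: FusionWeights

    def structure_volumes(self) -> dict:
        return {s: self.label.structure_volume(s) for s in STRUCTURES}


# ------------------------------------------------------------------ pipeline
def _stage_dice(surface, truth):
    if truth is None:
        return None
    return dice_report(truth, surface_to_label(surface, truth))


def segment(
    test: Volume3D,
    library: TemplateLibrary,
    cfg: PipelineConfig | None = None,
    truth: LabelVolume | None = None,
) -> SegmentationResult:
    """Run the full hybrid multi-template segmentation of one test image."""
    cfg = cfg or PipelineConfig()
    n_candidates = sum(1 for t in library.templates if t.id != cfg.exclude_id)
    if cfg.selection.n_a > n_candidates:
        raise ValueError(
            f"n_a={cfg.selection.n_a} exceeds available templates "
            f"({n_candidates})"
        )
    report = StageReport()
    # all similarity/registration/fusion work runs on volumes cropped to the
    # registration-mask bounding box; world-mm geometry keeps results
    # consistent with the full grid
    full_test = test
    library = library.cropped()
    test = crop_volume(test, library._crop_slices)
    truth_c = (crop_volume(truth, library._crop_slices)
               if truth is not None else None)
    try:
        selected = select_subset(library, test, cfg.selection.n_a,
                                 cfg.selection, exclude_id=cfg.exclude_id)
        chosen = [library.get(r.id) for r in selected]
        report.add("initial_subset",
                   _stage_dice(fuse_unweighted([t.surface for t in chosen]),
                               truth))
        report.similarities["o_total_best"] = selected[0].o_total
    except Exception as exc:
        raise RuntimeError(f"stage initial_subset failed: {exc}") from exc

    try:
        warped: list[WarpedTemplate] = []
        for t in chosen:
            fld, _ = register_hybrid(t, test, library.registration_mask,
                                     cfg.registration)
            warped.append(warp_template(
                t, fld,
                max_samples_per_radius=cfg.selection.max_samples_per_radius,
                fast_inside=cfg.selection.fast_inside,
            ))
        report.add("registration",
                   _stage_dice(fuse_unweighted([w.surface for w in warped]),
                               truth))
        if truth_c is not None:
            report.similarities["warped_label_dice_mean"] = float(np.mean([
                dice_report(truth_c, w.label)["mean"] for w in warped
            ]))
    except Exception as exc:
        raise RuntimeError(f"stage registration failed: {exc}") from exc

    try:
        restricted = restrict_subset(warped, test, library.stats,
                                     cfg.selection, cfg.selection.n_b)
        keep = {r.id for r in restricted}
        subset = [w for w in warped if w.id in keep]
        report.add("restricted_subset",
                   _stage_dice(fuse_unweighted([w.surface for w in subset]),
                               truth))
    except Exception as exc:
        raise RuntimeError(f"stage restricted_subset failed: {exc}") from exc

    try:
        gweights, o_global, global_surface = optimize_global_weights(
            subset, test, cfg.fusion)
        report.add("global_weighting", _stage_dice(global_surface, truth))
        report.similarities["o_subset_global"] = o_global
    except Exception as exc:
        raise RuntimeError(f"stage global_weighting failed: {exc}") from exc

    try:
        final_surface, weights, o_local = optimize_local_weights(
            subset, test, gweights, cfg.fusion)
        report.add("local_weighting", _stage_dice(final_surface, truth))
        report.similarities["o_subset_local"] = o_local
    except Exception as exc:
        raise RuntimeError(f"stage local_weighting failed: {exc}") from exc

    try:
        label = finalize_segmentation(final_surface, full_test)
    except Exception as exc:
        raise RuntimeError(f"stage finalize failed: {exc}") from exc
    return SegmentationResult(label=label, surface=final_surface,
                              stage_report=report, selection=selected,
                              restricted=restricted, weights=weights)


def registration_only_dice(
    test: Volume3D,
    library: TemplateLibrary,
    cfg: PipelineConfig,
    truth: LabelVolume,
    w_surf_reg: float | None = None,
) -> float:
    """Mean warped-template-label Dice after the registration stage only.

    With ``w_surf_reg=0`` this is the pure intensity-driven ablation of the
    boundary-weighted registration.
    """
    library = library.cropped()
    test_c = crop_volume(test, library._crop_slices)
    truth_c = crop_volume(truth, library._crop_slices)
    reg_cfg = cfg.registration
    if w_surf_reg is not None:
        reg_cfg = dataclasses.replace(reg_cfg, w_surf_reg=w_surf_reg)
    selected = select_subset(library, test_c, cfg.selection.n_a,
                             cfg.selection, exclude_id=cfg.exclude_id)
    vals = []
    for r in selected:
        t = library.get(r.id)
        fld, _ = register_hybrid(t, test_c, library.registration_mask, reg_cfg)
        from .registration import apply_to_volume

        lab_w = apply_to_volume(fld, t.label, order=0)
        vals.append(dice_report(truth_c, lab_w)["mean"])
    return float(np.mean(vals))


# ------------------------------------------------------- cohort experiments
def segment_cohort(
    cohort: Cohort,
    cfg: PipelineConfig,
    subjects: list[TestSubject] | None = None,
) -> dict:
    """Segment test subjects; returns {subject id: SegmentationResult}."""
    subjects = subjects if subjects is not None else cohort.tests
    return {
        s.id: segment(s.volume, cohort.library, cfg, truth=s.truth_label)
        for s in subjects
    }


def library_size_experiment(
    cohort: Cohort,
    cfg: PipelineConfig,
    fractions=(1.0, 0.5, 1 / 3, 0.25, 0.2),
    repeats: int = 5,
    subjects: list[TestSubject] | None = None,
    seed: int = 0,
    full_results: dict | None = None,
) -> dict:
    """Mean Dice as the template library shrinks to a fraction of N.

    For each fraction < 1 random sub-libraries are drawn (seeded, keeping
    control/patient proportions constant); fraction 1 is the deterministic
    full-library baseline. `full_results` may supply precomputed
    full-library segmentations for the same subjects.
    """
    if repeats < 2:
        raise ValueError("repeats must be >= 2")
    subjects = subjects if subjects is not None else cohort.test_controls
    library = cohort.library
    controls = [t.id for t in library.templates if t.group == "control"]
    patients = [t.id for t in library.templates if t.group == "patient"]
    report: dict = {}
    for frac in fractions:
        n_keep = int(round(frac * library.size))
        if n_keep < 2:
            raise ValueError(f"fraction {frac} yields fewer than 2 templates")
        if frac >= 1.0 - 1e-12:
            if full_results is None:
                full_results = segment_cohort(cohort, cfg, subjects)
            per_struct = {
                s: float(np.mean([
                    dice(sub.truth_label, full_results[sub.id].label, s)
                    for sub in subjects
                ]))
                for s in STRUCTURES
            }
            per_struct["mean"] = float(np.mean(list(per_struct.values())))
            report[frac] = per_struct
            continue
        n_ctrl = int(round(frac * len(controls)))
        n_pat = n_keep - n_ctrl
        accum = {s: [] for s in STRUCTURES}
        for rep in range(repeats):
            rng = np.random.default_rng([seed, rep, int(round(frac * 1000))])
            ids = sorted(
                list(rng.choice(controls, size=min(n_ctrl, len(controls)),
                                replace=False))
                + list(rng.choice(patients, size=min(n_pat, len(patients)),
                                  replace=False))
            )
            sub_lib = build_library([library.get(i) for i in ids])
            sub_cfg = dataclasses.replace(cfg)
            if cfg.selection.n_a > len(ids):
                sub_cfg.selection = dataclasses.replace(
                    cfg.selection, n_a=len(ids),
                    n_b=min(cfg.selection.n_b, len(ids)))
            for sub in subjects:
                res = segment(sub.volume, sub_lib, sub_cfg,
                              truth=sub.truth_label)
                for s in STRUCTURES:
                    accum[s].append(dice(sub.truth_label, res.label, s))
        per_struct = {s: float(np.mean(accum[s])) for s in STRUCTURES}
        per_struct["mean"] = float(np.mean(list(per_struct.values())))
        report[frac] = per_struct
    return report


def atrophy_analysis(
    control_volumes: dict, patient_volumes: dict,
) -> dict:
    """Group effect sizes and per-patient atrophy flags from volume tables.

    Inputs map subject id -> {structure: volume mm^3}. Controls define the
    normative mean/SD; a patient structure is flagged atrophic at z < -2.
    """
    out: dict = {}
    for s in STRUCTURES:
        c = np.array([v[s] for v in control_volumes.values()])
        p = np.array([v[s] for v in patient_volumes.values()])
        d = cohens_d(c, p)
        mean, sd = float(c.mean()), float(c.std(ddof=1))
        z_flags = {
            pid: atrophy_flag(vols[s], mean, sd)
            for pid, vols in patient_volumes.items()
        }
        out[s] = {
            "cohens_d": d,
            "control_mean": mean,
            "control_sd": sd,
            "z_scores": {k: z for k, (z, _) in z_flags.items()},
            "flagged": {k: f for k, (_, f) in z_flags.items()},
            "flag_rate": float(np.mean([f for (_, f) in z_flags.values()])),
        }
    return out
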