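"""End-to-end pipeline: configuration, reference-plane setup, case analysis.

``run_measure`` executes the full single-scan pipeline
(binarize → fill holes → morphological closing → plane construction →
deviation assessment → conventional measurements → mirroring/overlap) and
writes CSV/JSON results.  ``run_cohort`` generates a synthetic cohort,
measures every subject at both timepoints, and writes the summary tables.

Every output embeds the effective configuration, sufficient to re-run the
analysis bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .asymmetry import (
    DeviationAssessment,
    OverlapResult,
    SegmentDistribution,
    assess_deviation,
    mirrored_similarity,
    nonoverlap_mask,
    segment_distribution,
)
from .cohort_stats import SubjectRecord, build_table, records_to_frame
from .geometry import (
    LandmarkSet,
    Plane,
    plane_from_points,
    plane_through_two_points_perpendicular_to,
    signed_distance,
)
from .measurements import measure_structure, sectioning_plane_for_side
from .phantom import DEFAULT_COHORT_SPEC, PhantomSpec, make_cohort, make_mandible_phantom
from .voxel_ops import (
    BONE_HU_BAND,
    SOFT_TISSUE_HU_BAND,
    HUBand,
    HUVolume,
    VoxelMask,
    binarize,
    crop_below_plane,
    fill_holes,
    morph_close,
    split_by_plane,
    surface_area_mm2,
    volume_mm3,
)

__all__ = [
    "RunConfig",
    "ReferencePlanes",
    "CaseResult",
    "build_reference_planes",
    "preprocess_mask",
    "analyze_case",
    "run_measure",
    "run_cohort",
]

log = logging.getLogger("mandisym")


@dataclass(frozen=True)
class RunConfig:
    """Effective configuration of one pipeline run.

    Defaults are the standard acquisition/processing parameters: bone band
    320–520 HU, soft-tissue band −480 to −360 HU, sphere closing radius 10
    voxels, face-count surface mode, 4 mm deviation threshold.
    """

    volume_path: Optional[str] = None
    landmark_path: Optional[str] = None
    out_dir: Optional[str] = None
    bone_band: tuple[float, float] = (BONE_HU_BAND.lower, BONE_HU_BAND.upper)
    soft_band: tuple[float, float] = (SOFT_TISSUE_HU_BAND.lower, SOFT_TISSUE_HU_BAND.upper)
    closing_radius_vox: int = 10
    surface_mode: str = "face_count"
    reference_planes: tuple[str, ...] = ("AMP", "MSP")
    deviation_threshold_mm: float = 4.0
    exclude_cut_surface: bool = True
    include_soft_tissue: bool = True
    mirror_method: str = "nearest"
    timepoint: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        HUBand(*self.bone_band)
        HUBand(*self.soft_band)
        if self.closing_radius_vox < 1:
            raise ValueError("closing_radius_vox must be >= 1")
        unknown = set(self.reference_planes) - {"AMP", "MSP"}
        if unknown:
            raise ValueError(f"unknown reference planes: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a JSON or YAML configuration document; keyword overrides win."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("bone_band", "soft_band", "reference_planes"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["package_version"] = __version__
        return d


@dataclass(frozen=True)
class ReferencePlanes:
    """Oriented FHP, MSP, and AMP for one subject.

    Orientation convention: FHP normal points superiorly (menton on the
    negative side), MSP normal toward the patient's left (left porion on
    the positive side), AMP normal aligned with the MSP normal.
    """

    fhp: Plane
    msp: Plane
    amp: Plane

    def by_name(self, name: str) -> Plane:
        return {"FHP": self.fhp, "MSP": self.msp, "AMP": self.amp}[name]


def build_reference_planes(landmarks: LandmarkSet) -> ReferencePlanes:
    """Construct the three cephalometric reference planes from landmarks.

    FHP through both porions and the left orbitale; MSP through nasion and
    sella, perpendicular to the FHP; AMP through menton, supramentale, and
    the genial tubercle.
    """
    landmarks.require(["Po_left", "Po_right", "Or_left", "N", "S",
                       "Me", "B_point", "G"])
    fhp = plane_from_points(landmarks["Po_left"], landmarks["Po_right"],
                            landmarks["Or_left"])
    # superior normal: menton lies below the FHP
    fhp = fhp.oriented_toward(landmarks["Me"]).flipped()
    msp = plane_through_two_points_perpendicular_to(landmarks["N"], landmarks["S"], fhp)
    msp = msp.oriented_toward(landmarks["Po_left"])
    amp = plane_from_points(landmarks["Me"], landmarks["B_point"], landmarks["G"])
    if float(amp.normal @ msp.normal) < 0:
        amp = amp.flipped()
    return ReferencePlanes(fhp=fhp, msp=msp, amp=amp)


def preprocess_mask(volume: HUVolume, band: HUBand, closing_radius_vox: int) -> VoxelMask:
    """Binarize → fill holes → morphological closing."""
    mask = binarize(volume, band)
    log.info("binarized %d voxels in band [%g, %g] HU", mask.count, band.lower, band.upper)
    mask = fill_holes(mask)
    log.info("after hole filling: %d voxels", mask.count)
    mask = morph_close(mask, closing_radius_vox)
    log.info("after closing (radius %d): %d voxels", closing_radius_vox, mask.count)
    return mask


@dataclass(frozen=True)
class CaseResult:
    """All computed outputs of one scan."""

    deviation: DeviationAssessment
    planes: ReferencePlanes
    overlap: dict[str, OverlapResult]  # keyed AMP / MSP / SOFT
    segments: dict[str, SegmentDistribution]  # keyed AMP / MSP
    measurements: pd.DataFrame  # one row per structure x plane x side
    timepoint: Optional[str] = None

    def to_subject_record(self, subject_id: str) -> SubjectRecord:
        measures: dict[tuple[str, str, str], float] = {}
        for row in self.measurements.itertuples(index=False):
            key_base = (row.reference_plane, row.side)
            for qty in ("hemi_surface_mm2", "hemi_volume_mm3", "ramal_length_mm",
                        "body_length_mm", "ramus_surface_mm2", "ramus_volume_mm3",
                        "body_surface_mm2", "body_volume_mm3"):
                v = getattr(row, qty, None)
                if v is not None and not (isinstance(v, float) and np.isnan(v)):
                    measures[(*key_base, f"{row.structure}_{qty}")] = float(v)
        return SubjectRecord(
            subject_id=subject_id,
            timepoint=self.timepoint or "T1",
            deviation_mm=self.deviation.deviation_mm,
            dev_side=self.deviation.dev_side,
            dice={k: v.dice for k, v in self.overlap.items()},
            nov_mm3={k: v.nonoverlap_mm3 for k, v in self.overlap.items()},
            total_voxels={k: v.count_a + v.count_b for k, v in self.overlap.items()},
            measures=measures,
        )


def analyze_case(
    volume: HUVolume,
    landmarks: LandmarkSet,
    config: RunConfig = RunConfig(),
) -> CaseResult:
    """Run the full measurement + mirroring analysis for one scan."""
    planes = build_reference_planes(landmarks)
    deviation = assess_deviation(landmarks, planes.msp, config.deviation_threshold_mm)
    log.info("menton deviation %.2f mm toward %s (included: %s)",
             deviation.deviation_mm, deviation.dev_side, deviation.included)
    # left/right labelling needs a concrete side even for midline subjects
    me_offset = signed_distance(landmarks["Me"], planes.msp)
    dev_side_effective = "left" if me_offset > 0 else "right"

    bone = preprocess_mask(volume, HUBand(*config.bone_band), config.closing_radius_vox)

    measurements = pd.DataFrame(
        [m.as_dict() for m in measure_structure(
            bone, landmarks, planes.amp, planes.msp, dev_side_effective,
            surface_mode=config.surface_mode,
            exclude_cut_surface=config.exclude_cut_surface,
            timepoint=config.timepoint,
        )]
    )
    measurements.insert(0, "structure", "mandible")

    overlap: dict[str, OverlapResult] = {}
    segments: dict[str, SegmentDistribution] = {}
    # NOV is segmented with the superimposed-side (right hemi) ramus/body plane
    section = sectioning_plane_for_side(landmarks, "right")
    for name in config.reference_planes:
        plane = planes.by_name(name)
        result, mirrored_left, right = mirrored_similarity(
            bone, plane, method=config.mirror_method, return_masks=True
        )
        overlap[name] = result
        segments[name] = segment_distribution(
            nonoverlap_mask(mirrored_left, right), section, ramus_side="positive"
        )
        log.info("%s: dice %.3f, NOV %.1f mm3", name, result.dice, result.nonoverlap_mm3)

    if config.include_soft_tissue:
        soft = preprocess_mask(volume, HUBand(*config.soft_band),
                               config.closing_radius_vox)
        soft = crop_below_plane(soft, planes.fhp)
        if soft.count:
            overlap["SOFT"] = mirrored_similarity(soft, planes.msp,
                                                  method=config.mirror_method)
            rows = []
            pos, neg = split_by_plane(soft, planes.msp)
            for sign, half in ((1, pos), (-1, neg)):
                anat = "left" if sign > 0 else "right"
                label = "dev" if anat == dev_side_effective else "ndev"
                cut = planes.msp if config.exclude_cut_surface else None
                rows.append({
                    "structure": "soft_tissue",
                    "side": label,
                    "reference_plane": "MSP",
                    "hemi_surface_mm2": surface_area_mm2(
                        half, mode=config.surface_mode, exclude=cut),
                    "hemi_volume_mm3": volume_mm3(half),
                    "timepoint": config.timepoint,
                })
            measurements = pd.concat(
                [measurements, pd.DataFrame(rows)], ignore_index=True
            )
        else:
            log.warning("soft-tissue mask empty below the FHP; skipping soft analysis")

    return CaseResult(
        deviation=deviation,
        planes=planes,
        overlap=overlap,
        segments=segments,
        measurements=measurements,
        timepoint=config.timepoint,
    )


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_measure(config: RunConfig) -> CaseResult:
    """Load inputs, analyze one scan, and write results to ``out_dir``.

    Writes ``measurements.csv`` (one row per structure × plane × side) and
    ``asymmetry.json`` (overlap results, NOV segment distributions, the
    deviation assessment, and the full effective configuration).
    """
    from .io import read_landmarks, read_volume

    if not config.volume_path or not config.landmark_path:
        raise ValueError("run_measure needs volume_path and landmark_path")
    volume = read_volume(config.volume_path)
    landmarks = read_landmarks(config.landmark_path)
    result = analyze_case(volume, landmarks, config)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.measurements.to_csv(out / "measurements.csv", index=False)
        payload = {
            "config": _jsonable(config.as_dict()),
            "deviation": result.deviation.as_dict(),
            "overlap": {k: v.as_dict() for k, v in result.overlap.items()},
            "nov_segments": {k: v.as_dict() for k, v in result.segments.items()},
        }
        (out / "asymmetry.json").write_text(json.dumps(_jsonable(payload), indent=1))
    return result


def run_cohort(
    n_subjects: int = 20,
    seed: int = 0,
    reduction: float = 0.5,
    base_spec: Optional[PhantomSpec] = None,
    config: RunConfig = RunConfig(),
    out_dir: Optional[str] = None,
) -> dict:
    """Generate a synthetic cohort, measure every subject at T1 and T2, and
    build the summary tables.

    Returns ``{"records": DataFrame, "tables": {name: DataFrame}}`` and, if
    ``out_dir`` is given, writes ``subjects.csv``, one CSV per table, and a
    ``summary.json`` with the effective configuration.
    """
    subjects = make_cohort(
        n_subjects=n_subjects, seed=seed, reduction=reduction,
        base_spec=base_spec or DEFAULT_COHORT_SPEC,
    )
    records = []
    for subject in subjects:
        for timepoint in ("T1", "T2"):
            volume, landmarks, _truth = subject.generate(timepoint)
            case_config = dataclasses.replace(config, timepoint=timepoint)
            result = analyze_case(volume, landmarks, case_config)
            records.append(result.to_subject_record(subject.subject_id))
            log.info("%s %s done", subject.subject_id, timepoint)
    frame = records_to_frame(records)
    tables = build_table(records)

    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out / "subjects.csv", index=False)
        for name, table in tables.items():
            table.to_csv(out / f"table_{name}.csv", index=False)
        summary = {
            "config": _jsonable(config.as_dict()),
            "cohort": {
                "n_subjects": n_subjects,
                "seed": seed,
                "reduction": reduction,
                "base_spec": _jsonable(dataclasses.asdict(base_spec or DEFAULT_COHORT_SPEC)),
            },
            "mean_dice": _jsonable({
                tp: frame[frame.timepoint == tp]
                .filter(like="dice_").mean().to_dict()
                for tp in ("T1", "T2")
            }),
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return {"records": frame, "tables": tables, "subject_records": records}
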