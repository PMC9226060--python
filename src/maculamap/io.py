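"""Cohort and result export/import.

A cohort on disk is three text files in one directory:

* ``thickness.csv`` — subject_id, scheme, layer, superpixel_id,
  thickness_um
* ``sensitivity.csv`` — subject_id, modality, location_id,
  sensitivity_db
* ``manifest.json`` — seed, simulator parameters and per-subject ground
  truth (diagnosis, FoBMO angle, severity tertile, damage patterns,
  measured mean GCL and MD)

Exports are deterministic: the same cohort writes byte-identical files.
Fixation offsets are not persisted; re-imported exams carry zeros.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import VFUnitMap, flip_vertical, make_10_2_pattern, make_grid
from .synth import (
    CohortParams,
    DamagePattern,
    LinkParams,
    SimulatedExam,
    SimulatedSubject,
    SubjectSpec,
    SyntheticCohort,
)

_FLOAT_FMT = "%.10g"


def _params_to_dict(params: CohortParams) -> dict:
    d = dataclasses.asdict(params)
    d["link"] = dataclasses.asdict(params.link)
    return d


def _params_from_dict(d: dict) -> CohortParams:
    d = dict(d)
    link = LinkParams(**{**d.pop("link")})
    for key in ("schemes", "modalities", "layers"):
        if key in d:
            d[key] = tuple(d[key])
    return CohortParams(link=link, **d)


def export_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write a cohort to ``outdir``; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    trows = []
    for s in cohort.subjects:
        for (scheme, layer), vals in sorted(s.thickness.items()):
            for sp, v in enumerate(vals, start=1):
                trows.append((s.spec.subject_id, scheme, layer, sp, v))
    thickness = pd.DataFrame(
        trows, columns=["subject_id", "scheme", "layer", "superpixel_id", "thickness_um"]
    )

    srows = []
    for s in cohort.subjects:
        for modality, exam in sorted(s.exams.items()):
            for lid, v in zip(exam.location_ids, exam.sensitivities):
                srows.append((s.spec.subject_id, modality, lid, v))
    sens = pd.DataFrame(
        srows, columns=["subject_id", "modality", "location_id", "sensitivity_db"]
    )

    manifest = dict(
        seed=cohort.seed,
        n_subjects=len(cohort),
        params=_params_to_dict(cohort.params),
        subjects=[
            dict(
                subject_id=s.spec.subject_id,
                diagnosis=s.spec.diagnosis,
                laterality=s.spec.laterality,
                fobmo_angle=s.spec.fobmo_angle,
                severity_tertile=s.spec.severity_tertile,
                mean_gcl=s.mean_gcl,
                md=s.md,
                damage=[dataclasses.asdict(p) for p in s.spec.damage],
            )
            for s in cohort.subjects
        ],
    )

    paths = {
        "thickness": outdir / "thickness.csv",
        "sensitivity": outdir / "sensitivity.csv",
        "manifest": outdir / "manifest.json",
    }
    thickness.to_csv(paths["thickness"], index=False, float_format=_FLOAT_FMT)
    sens.to_csv(paths["sensitivity"], index=False, float_format=_FLOAT_FMT)
    paths["manifest"].write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return paths


def import_cohort(indir: str | Path) -> SyntheticCohort:
    """Read a cohort previously written by :func:`export_cohort`."""
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    params = _params_from_dict(manifest["params"])
    thickness = pd.read_csv(indir / "thickness.csv")
    sens = pd.read_csv(indir / "sensitivity.csv")

    pattern = flip_vertical(make_10_2_pattern())
    grids = {s: make_grid(s) for s in params.schemes}

    subjects = []
    for rec in manifest["subjects"]:
        spec = SubjectSpec(
            subject_id=rec["subject_id"],
            diagnosis=rec["diagnosis"],
            laterality=rec["laterality"],
            fobmo_angle=rec["fobmo_angle"],
            damage=tuple(
                DamagePattern(
                    hemiretina=p["hemiretina"],
                    angular_extent=p["angular_extent"],
                    eccentricity_band=tuple(p["eccentricity_band"]),
                    depth=p["depth"],
                    edge_softness=p["edge_softness"],
                    center_angle=p["center_angle"],
                )
                for p in rec["damage"]
            ),
            severity_tertile=rec["severity_tertile"],
        )
        tsub = thickness[thickness.subject_id == rec["subject_id"]]
        thick = {}
        for (scheme, layer), grp in tsub.groupby(["scheme", "layer"]):
            thick[(scheme, layer)] = (
                grp.sort_values("superpixel_id")["thickness_um"].to_numpy()
            )
        ssub = sens[sens.subject_id == rec["subject_id"]]
        exams = {}
        for modality, grp in ssub.groupby("modality"):
            grp = grp.set_index("location_id").loc[list(pattern.ids)]
            exams[modality] = SimulatedExam(
                modality=modality,
                location_ids=pattern.ids,
                sensitivities=grp["sensitivity_db"].to_numpy(),
                fixation_offsets=np.zeros((len(pattern), 2)),
            )
        subjects.append(
            SimulatedSubject(
                spec=spec,
                thickness=thick,
                exams=exams,
                mean_gcl=rec["mean_gcl"],
                md=rec["md"],
            )
        )
    return SyntheticCohort(
        subjects=tuple(subjects),
        pattern=pattern,
        grids=grids,
        params=params,
        seed=manifest["seed"],
    )


def export_unit_map(unit_map: VFUnitMap, path: str | Path) -> Path:
    """Write a unit map as CSV (one row per unit-member location)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    unit_map.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path
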