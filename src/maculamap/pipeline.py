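"""Reproducible simulate -> analyze -> compare pipeline.

A run is fully described by a :class:`RunConfig`; rerunning the same
config writes identical files.  The single global seed is expanded into
per-stage substreams so a stage can be rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import (
    SuperpixelGrid,
    VFUnitMap,
    apply_onh_exclusion,
    assign_units,
    make_grid,
)
from .io import export_cohort, export_unit_map, import_cohort, _FLOAT_FMT
from .sfmap import CorrelationAtlas, VectorMap, correlation_atlas, hemimacula_split, summarize_vectors, vector_map
from .stats import compare_paired, distribution_summary, pair_units
from .synth import CohortParams, LinkParams, SyntheticCohort, simulate_cohort

log = logging.getLogger("maculamap")


@dataclass(frozen=True)
class RunConfig:
    """Serializable description of one full pipeline run."""

    seed: int = 0
    n_glaucoma: int = 38
    n_healthy: int = 10
    severity_mix: str | list = "balanced"
    thickness_noise_um: float = 2.5
    sensitivity_noise_db: float = 1.5
    jitter_sd_deg: float = 1.5
    displacement_on: bool = True
    max_loss_db: float = 30.0
    fobmo_mean_deg: float = -7.0
    fobmo_sd_deg: float = 2.5
    schemes: tuple[str, ...] = ("CMA", "LMA")
    modalities: tuple[str, ...] = ("standard", "tracked")
    layers: tuple[str, ...] = ("GCL", "IPL")
    onh_disc: tuple[float, float, float] | None = None  # (x, y, radius) deg
    outdir: str = "maculamap_run"
    figures: bool = True

    def cohort_params(self) -> CohortParams:
        return CohortParams(
            thickness_noise_um=self.thickness_noise_um,
            link=LinkParams(
                noise_db_sd=self.sensitivity_noise_db,
                jitter_sd_deg=self.jitter_sd_deg,
                displacement_on=self.displacement_on,
                max_loss_db=self.max_loss_db,
            ),
            fobmo_mean_deg=self.fobmo_mean_deg,
            fobmo_sd_deg=self.fobmo_sd_deg,
            schemes=tuple(self.schemes),
            modalities=tuple(self.modalities),
            layers=tuple(self.layers),
        )

    def stage_seed(self, stage: str) -> int:
        """A deterministic per-stage seed derived from the global seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("schemes", "modalities", "layers"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "onh_disc" in raw and raw["onh_disc"] is not None:
            raw["onh_disc"] = tuple(raw["onh_disc"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(
            yaml.safe_dump(
                json.loads(json.dumps(dataclasses.asdict(self), default=list)),
                sort_keys=True,
            )
        )
        return path


def build_unit_map(scheme: str, cohort: SyntheticCohort | None = None,
                   onh_disc=None) -> VFUnitMap:
    """Canonical unit map for a scheme (pattern flipped, unrotated grid)."""
    from .geometry import flip_vertical, make_10_2_pattern

    grid = make_grid(scheme)
    if onh_disc is not None:
        grid = apply_onh_exclusion(grid, (onh_disc[0], onh_disc[1]), onh_disc[2])
    pattern = cohort.pattern if cohort is not None else flip_vertical(make_10_2_pattern())
    return assign_units(pattern, grid, scheme)


def cmd_simulate(config: RunConfig) -> Path:
    """Simulate the cohort and write it under ``<outdir>/cohort``."""
    t0 = time.perf_counter()
    cohort = simulate_cohort(
        n_glaucoma=config.n_glaucoma,
        n_healthy=config.n_healthy,
        severity_mix=config.severity_mix,
        seed=config.stage_seed("simulate"),
        params=config.cohort_params(),
    )
    outdir = Path(config.outdir)
    paths = export_cohort(cohort, outdir / "cohort")
    config.to_yaml(outdir / "config.yaml")
    log.info(
        "simulate: version=%s digest=%s n=%d elapsed=%.2fs",
        __version__, config.digest(), len(cohort), time.perf_counter() - t0,
    )
    return outdir / "cohort"


def cmd_analyze(
    config: RunConfig,
    cohort: SyntheticCohort | None = None,
    scheme: str = "CMA",
    modality: str = "standard",
    layer: str = "GCL",
) -> tuple[CorrelationAtlas, VectorMap]:
    """Atlas + vector map for one (scheme, modality, layer) combination.

    Writes the atlas and vector CSVs (and figures when enabled) under
    ``<outdir>/analysis``.
    """
    t0 = time.perf_counter()
    outdir = Path(config.outdir)
    if cohort is None:
        cohort = import_cohort(outdir / "cohort")
    if scheme not in cohort.params.schemes or modality not in cohort.params.modalities:
        raise ValueError(
            f"cohort does not contain scheme={scheme!r} / modality={modality!r}"
        )
    unit_map = build_unit_map(scheme, cohort, onh_disc=config.onh_disc)
    atlas = correlation_atlas(cohort, unit_map, unit_map.grid, layer, modality)
    vmap = vector_map(atlas)

    tag = f"{scheme}_{modality}_{layer}"
    adir = outdir / "analysis"
    adir.mkdir(parents=True, exist_ok=True)
    atlas.to_frame().to_csv(adir / f"atlas_{tag}.csv", index=False, float_format=_FLOAT_FMT)
    vmap.frame.to_csv(adir / f"vectors_{tag}.csv", index=False, float_format=_FLOAT_FMT)
    export_unit_map(unit_map, adir / f"unitmap_{scheme}.csv")
    if config.figures:
        from .plots import heatmap_panel, vector_map_figure

        heatmap_panel(atlas, adir / f"heatmap_{tag}.png")
        vector_map_figure(vmap, adir / f"vectormap_{tag}.png")
    log.info("analyze %s: elapsed=%.2fs", tag, time.perf_counter() - t0)
    return atlas, vmap


#: The analysis combinations of a full run: the two clinical protocols
#: plus the two cross-over analyses (conventional aggregation on tracked
#: perimetry, localized aggregation on standard perimetry).
MAIN_COMBOS = (("CMA", "standard"), ("LMA", "tracked"))
CROSS_COMBOS = (("CMA", "tracked"), ("LMA", "standard"))


def cmd_compare(
    config: RunConfig, analyses: dict[tuple, tuple[CorrelationAtlas, VectorMap]]
) -> pd.DataFrame:
    """Scheme/modality comparisons with Fisher-z + signed-rank tests.

    ``analyses`` maps (scheme, modality, layer) to (atlas, vector map).
    Writes a comparison table (CSV + JSON) and box-plot figures.
    """
    if len(analyses) < 2:
        raise ValueError("need at least two analyses to compare")
    outdir = Path(config.outdir)
    cdir = outdir / "compare"
    cdir.mkdir(parents=True, exist_ok=True)

    rows = []
    boxes: dict[str, np.ndarray] = {}

    def vmap_of(scheme, modality, layer):
        key = (scheme, modality, layer)
        return analyses[key][1] if key in analyses else None

    for layer in config.layers:
        pairs = [
            ("CMA_standard_vs_LMA_tracked", ("CMA", "standard"), ("LMA", "tracked")),
            ("CMA_tracked_vs_LMA_standard", ("CMA", "tracked"), ("LMA", "standard")),
            ("LMA_tracked_vs_LMA_standard", ("LMA", "tracked"), ("LMA", "standard")),
            ("CMA_standard_vs_CMA_tracked", ("CMA", "standard"), ("CMA", "tracked")),
        ]
        for name, (s_a, m_a), (s_b, m_b) in pairs:
            va, vb = vmap_of(s_a, m_a, layer), vmap_of(s_b, m_b, layer)
            if va is None or vb is None:
                continue
            if s_a == s_b:
                if tuple(va.unit_map.unit_ids) != tuple(vb.unit_map.unit_ids):
                    raise ValueError(f"incompatible unit maps in {name}")
                ra = va.frame["r_max"].to_numpy()
                rb = vb.frame["r_max"].to_numpy()
                res = compare_paired(ra, rb, pairing_rule="same_units")
            else:
                za, zb = pair_units(va, vb)
                res = compare_paired(
                    za, zb, values_are_z=True, pairing_rule="lma_mean_within_cma_unit"
                )
            rows.append(dict(comparison=name, layer=layer, **res.to_dict()))
            boxes[f"{s_a}/{m_a}/{layer}"] = va.frame["r_max"].to_numpy()
            boxes[f"{s_b}/{m_b}/{layer}"] = vb.frame["r_max"].to_numpy()

        for (scheme, modality) in MAIN_COMBOS + CROSS_COMBOS:
            v = vmap_of(scheme, modality, layer)
            if v is None:
                continue
            split = hemimacula_split(v)
            for hemi, vals in split.items():
                summ = distribution_summary(vals)
                rows.append(
                    dict(
                        comparison=f"hemimacula_{scheme}_{modality}_{hemi}",
                        layer=layer,
                        median_a=summ["median"],
                        median_b=np.nan,
                        range_a=[summ["min"], summ["max"]],
                        range_b=[np.nan, np.nan],
                        p_value=np.nan,
                        n_pairs=len(vals),
                        pairing_rule="none",
                    )
                )

    table = pd.DataFrame(rows)
    table.to_csv(cdir / "comparisons.csv", index=False, float_format=_FLOAT_FMT)
    (cdir / "comparisons.json").write_text(
        json.dumps(rows, indent=1, default=float, sort_keys=True)
    )
    pd.DataFrame({k: pd.Series(v) for k, v in boxes.items()}).to_csv(
        cdir / "distributions.csv", index=False, float_format=_FLOAT_FMT
    )
    if config.figures and boxes:
        from .plots import boxplot_figure

        boxplot_figure(boxes, cdir / "distributions.png", "max-correlation distributions")
    return table


def cmd_report(config: RunConfig) -> dict:
    """Run the full pipeline and return a summary dictionary."""
    t0 = time.perf_counter()
    cohort_dir = cmd_simulate(config)
    cohort = import_cohort(cohort_dir)
    analyses = {}
    for scheme, modality in MAIN_COMBOS + CROSS_COMBOS:
        if scheme not in config.schemes or modality not in config.modalities:
            continue
        for layer in config.layers:
            analyses[(scheme, modality, layer)] = cmd_analyze(
                config, cohort, scheme, modality, layer
            )
    table = cmd_compare(config, analyses)
    summary = dict(
        config_digest=config.digest(),
        n_subjects=len(cohort),
        vectors={
            "_".join(k): summarize_vectors(v) for k, (a, v) in analyses.items()
        },
        comparisons=table.to_dict(orient="records"),
        elapsed_s=time.perf_counter() - t0,
    )
    (Path(config.outdir) / "summary.json").write_text(
        json.dumps(summary, indent=1, default=float, sort_keys=True)
    )
    return summary
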