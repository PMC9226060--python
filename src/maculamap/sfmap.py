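"""Correlation atlases, maximum-correlation vector maps and summaries.

For a mapping scheme (conventional 8x8/3-degree or localized 12x12/
2-degree) the atlas holds, for one retinal layer and one perimetric
modality, the Pearson correlation across subjects between mean linear
sensitivity in every VF unit and mean layer thickness in every OCT
superpixel.  The vector map links each unit to the superpixel of maximum
correlation; a "hit" is a vector of length zero, i.e. the maximum falls
in the unit's own mapped superpixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import SuperpixelGrid, VFUnitMap, distance_deg
from .synth import Layer, Modality, SimulatedExam, SyntheticCohort


class DegenerateCohortError(ValueError):
    """The cohort carries no usable between-subject variance."""


def db_to_linear(db):
    """Convert decibel sensitivity to the linear (1/Lambert) scale.

    Sensitivity in dB is 10 log10(1/L), so the linear value is
    10**(dB/10).
    """
    return np.power(10.0, np.asarray(db, float) / 10.0)


def unit_sensitivity(
    exam: SimulatedExam, unit_map: VFUnitMap, linearize_first: bool = True
) -> np.ndarray:
    """Per-unit mean sensitivity on the linear scale, unit order.

    Sensitivities are linearized before averaging by default; with
    ``linearize_first=False`` the dB values are averaged first and the
    mean converted.
    """
    sens = {lid: s for lid, s in zip(exam.location_ids, exam.sensitivities)}
    out = np.empty(len(unit_map))
    for i, u in enumerate(unit_map.units):
        try:
            vals = np.array([sens[l] for l in u.member_location_ids])
        except KeyError as e:
            raise KeyError(f"exam missing location {e} for unit {u.id}") from None
        if linearize_first:
            out[i] = float(np.mean(db_to_linear(vals)))
        else:
            out[i] = float(db_to_linear(np.mean(vals)))
    return out


def _pearson_matrix(U: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Pearson r between every row of U (units) and of T (superpixels).

    Rows with zero variance yield NaN (undefined correlation), mirroring
    the definitional formula rather than raising.
    """
    n = U.shape[1]
    Uc = U - U.mean(axis=1, keepdims=True)
    Tc = T - T.mean(axis=1, keepdims=True)
    su = np.sqrt((Uc**2).sum(axis=1))
    st = np.sqrt((Tc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Uc @ Tc.T) / np.outer(su, st)
    r[su == 0, :] = np.nan
    r[:, st == 0] = np.nan
    return np.clip(r, -1.0, 1.0, out=r, where=np.isfinite(r))


@dataclass(frozen=True)
class CorrelationAtlas:
    """Unit x superpixel Pearson-correlation matrix for one layer."""

    r: pd.DataFrame  # index: unit ids, columns: superpixel ids
    n_subjects: int
    scheme: str
    layer: Layer
    modality: Modality
    excluded: frozenset[int]
    unit_map: VFUnitMap

    @property
    def values(self) -> np.ndarray:
        return self.r.to_numpy()

    def to_frame(self) -> pd.DataFrame:
        """Long format: unit_id, superpixel_id, layer, r."""
        long = self.r.stack(future_stack=True).rename("r").reset_index()
        long.columns = ["unit_id", "superpixel_id", "r"]
        long.insert(2, "layer", self.layer)
        return long


def correlation_atlas(
    cohort: SyntheticCohort,
    unit_map: VFUnitMap,
    grid: SuperpixelGrid,
    layer: Layer,
    modality: Modality,
    linearize_first: bool = True,
) -> CorrelationAtlas:
    """Exhaustive Pearson atlas: every VF unit against every superpixel.

    All subjects (patients and healthy) are pooled.  Entries where either
    side has zero between-subject variance are NaN; superpixels in the
    grid's excluded set are masked out of downstream argmax operations
    but their correlations are still reported.
    """
    if len(cohort) < 3:
        raise DegenerateCohortError("correlation atlas needs at least 3 subjects")
    U = np.column_stack(
        [
            unit_sensitivity(s.exams[modality], unit_map, linearize_first)
            for s in cohort.subjects
        ]
    )
    T = cohort.thickness_matrix(unit_map.scheme, layer)
    if np.allclose(U, U[:, [0]]) and np.allclose(T, T[:, [0]]):
        raise DegenerateCohortError(
            "no between-subject variance in either sensitivities or thickness"
        )
    r = _pearson_matrix(U, T)
    frame = pd.DataFrame(
        r, index=list(unit_map.unit_ids), columns=list(grid.superpixel_ids)
    )
    return CorrelationAtlas(
        r=frame,
        n_subjects=len(cohort),
        scheme=unit_map.scheme,
        layer=layer,
        modality=modality,
        excluded=grid.excluded,
        unit_map=unit_map,
    )


@dataclass(frozen=True)
class VectorMap:
    """Per-unit maximum-correlation vectors for one atlas."""

    frame: pd.DataFrame  # unit_id, mapped_superpixel, target_superpixel,
    #                      r_max, length_deg, hit, crosses_midline
    scheme: str
    layer: Layer
    modality: Modality
    unit_map: VFUnitMap

    def __len__(self) -> int:
        return len(self.frame)


def vector_map(
    atlas: CorrelationAtlas,
    unit_map: VFUnitMap | None = None,
    grid: SuperpixelGrid | None = None,
    prefer_mapped_on_tie: bool = True,
) -> VectorMap:
    """Locate, per unit, the superpixel of maximum correlation.

    Masked (excluded) and undefined (NaN) superpixels never participate.
    Exact ties are broken toward the mapped superpixel when
    ``prefer_mapped_on_tie`` (the conservative convention), then by
    smallest center distance to the mapped superpixel, then by lowest id.
    Vector length is the Euclidean distance between superpixel centers in
    degrees; a hit is a zero-length vector.
    """
    unit_map = unit_map or atlas.unit_map
    grid = grid or unit_map.grid
    sp_ids = np.array(list(grid.superpixel_ids))
    usable = ~np.isin(sp_ids, list(atlas.excluded))
    rows = []
    for u in unit_map.units:
        rvals = atlas.r.loc[u.id].to_numpy().astype(float)
        ok = usable & np.isfinite(rvals)
        if not ok.any():
            raise DegenerateCohortError(
                f"all correlations undefined or masked for unit {u.id}"
            )
        rmax = rvals[ok].max()
        cand = sp_ids[ok & (rvals >= rmax - 1e-12)]
        if prefer_mapped_on_tie and u.mapped_superpixel in cand:
            target = u.mapped_superpixel
        else:
            target = min(
                cand, key=lambda s: (distance_deg(grid, s, u.mapped_superpixel), s)
            )
        length = distance_deg(grid, target, u.mapped_superpixel)
        my = grid.cell_center(u.mapped_superpixel)[1]
        ty = grid.cell_center(target)[1]
        rows.append(
            dict(
                unit_id=u.id,
                mapped_superpixel=u.mapped_superpixel,
                target_superpixel=int(target),
                r_max=float(rmax),
                length_deg=float(length),
                hit=bool(length == 0.0),
                crosses_midline=bool(my * ty < 0),
            )
        )
    return VectorMap(
        frame=pd.DataFrame(rows),
        scheme=atlas.scheme,
        layer=atlas.layer,
        modality=atlas.modality,
        unit_map=unit_map,
    )


def summarize_vectors(vmap: VectorMap) -> dict:
    """Hit counts and the median length of the nonzero vectors.

    ``median_nonzero_length`` is None when every vector is a hit.
    """
    f = vmap.frame
    nonzero = f.loc[~f["hit"], "length_deg"]
    return dict(
        n_units=len(f),
        hit_count=int(f["hit"].sum()),
        hit_rate=float(f["hit"].mean()),
        median_nonzero_length=(None if nonzero.empty else float(nonzero.median())),
        min_nonzero_length=(None if nonzero.empty else float(nonzero.min())),
        max_nonzero_length=(None if nonzero.empty else float(nonzero.max())),
        crossings=int(f["crosses_midline"].sum()),
    )


def hemimacula_split(vmap: VectorMap) -> dict[str, np.ndarray]:
    """Per-unit maximum correlations split by retinal hemifield.

    Units are grouped by the hemifield (superior retina: center y > 0) of
    their *mapped* superpixel center.  Group sizes sum to the number of
    units.
    """
    grid = vmap.unit_map.grid
    sup, inf = [], []
    for u, rmax in zip(vmap.unit_map.units, vmap.frame["r_max"]):
        y = grid.cell_center(u.mapped_superpixel)[1]
        (sup if y > 0 else inf).append(rmax)
    return {"superior": np.array(sup), "inferior": np.array(inf)}
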