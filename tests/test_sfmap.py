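"""Correlation atlases, vector maps and summaries."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from maculamap.geometry import apply_onh_exclusion, assign_units
from maculamap.sfmap import (
    CorrelationAtlas,
    DegenerateCohortError,
    correlation_atlas,
    db_to_linear,
    hemimacula_split,
    summarize_vectors,
    unit_sensitivity,
    vector_map,
)
from maculamap.synth import (
    CohortParams,
    SimulatedExam,
    SimulatedSubject,
    SubjectSpec,
    SyntheticCohort,
    simulate_cohort,
)


def identity_cohort(lma_units, retinal_pattern, n_subjects=6, seed=0):
    """Hand-built cohort whose sensitivities duplicate mapped thickness."""
    rng = np.random.default_rng(seed)
    grid = lma_units.grid
    mapped = {
        u.member_location_ids[0]: u.mapped_superpixel for u in lma_units.units
    }
    subjects = []
    for i in range(n_subjects):
        thick = rng.uniform(10.0, 50.0, size=grid.n_cells)
        sens = np.array(
            [10.0 * np.log10(thick[mapped[lid] - 1]) for lid in retinal_pattern.ids]
        )
        exam = SimulatedExam(
            "tracked", retinal_pattern.ids, sens, np.zeros((68, 2))
        )
        subjects.append(
            SimulatedSubject(
                spec=SubjectSpec(f"S{i}", "healthy"),
                thickness={("LMA", "GCL"): thick},
                exams={"tracked": exam},
                mean_gcl=float(thick.mean()),
                md=0.0,
            )
        )
    params = CohortParams(schemes=("LMA",), modalities=("tracked",), layers=("GCL",))
    return SyntheticCohort(tuple(subjects), retinal_pattern, {"LMA": grid}, params, seed)


class TestLinearization:
    def test_db_to_linear_closed_form(self):
        assert db_to_linear(0.0) == 1.0
        assert db_to_linear(10.0) == 10.0
        assert db_to_linear(30.0) == pytest.approx(1000.0)

    def test_unit_sensitivity_averages_linearized(self, cma_units, retinal_pattern):
        sens = np.full(68, 20.0)
        exam = SimulatedExam("tracked", retinal_pattern.ids, sens, np.zeros((68, 2)))
        vals = unit_sensitivity(exam, cma_units)
        assert np.allclose(vals, 100.0)

    def test_mixed_unit_mean(self, cma_units, retinal_pattern):
        # a two-member unit at {0 dB, 20 dB} averages to (1 + 100) / 2
        two = next(u for u in cma_units.units if len(u.member_location_ids) == 2)
        sens = np.full(68, 20.0)
        ids = list(retinal_pattern.ids)
        sens[ids.index(two.member_location_ids[0])] = 0.0
        exam = SimulatedExam("tracked", retinal_pattern.ids, sens, np.zeros((68, 2)))
        vals = unit_sensitivity(exam, cma_units)
        idx = list(cma_units.unit_ids).index(two.id)
        assert vals[idx] == pytest.approx(50.5)

    def test_singleton_unit_passthrough(self, lma_units, retinal_pattern):
        rng = np.random.default_rng(1)
        sens = rng.uniform(0, 33, 68)
        exam = SimulatedExam("tracked", retinal_pattern.ids, sens, np.zeros((68, 2)))
        vals = unit_sensitivity(exam, lma_units)
        for u, v in zip(lma_units.units, vals):
            i = list(retinal_pattern.ids).index(u.member_location_ids[0])
            assert v == pytest.approx(db_to_linear(sens[i]))


class TestAtlas:
    def test_matches_definitional_pearson(self, small_cohort, cma_units):
        atlas = correlation_atlas(
            small_cohort, cma_units, cma_units.grid, "GCL", "standard"
        )
        U = np.column_stack(
            [
                unit_sensitivity(s.exams["standard"], cma_units)
                for s in small_cohort.subjects
            ]
        )
        T = small_cohort.thickness_matrix("CMA", "GCL")
        rng = np.random.default_rng(0)
        for _ in range(60):
            i = rng.integers(0, U.shape[0])
            j = rng.integers(0, T.shape[0])
            want = pearsonr(U[i], T[j]).statistic
            got = atlas.r.iloc[i, j]
            assert got == pytest.approx(want, abs=1e-12)

    def test_identity_link_diagonal_is_one(self, lma_units, retinal_pattern):
        cohort = identity_cohort(lma_units, retinal_pattern)
        atlas = correlation_atlas(cohort, lma_units, lma_units.grid, "GCL", "tracked")
        for u in lma_units.units:
            assert atlas.r.loc[u.id, u.mapped_superpixel] == pytest.approx(1.0)
        vmap = vector_map(atlas)
        assert summarize_vectors(vmap)["hit_rate"] == 1.0

    def test_scale_invariance_of_thickness_units(self, small_cohort, cma_units):
        atlas = correlation_atlas(
            small_cohort, cma_units, cma_units.grid, "GCL", "standard"
        )
        rescaled_subjects = tuple(
            dataclasses.replace(
                s,
                thickness={k: v * 0.001 + 5.0 for k, v in s.thickness.items()},
            )
            for s in small_cohort.subjects
        )
        rescaled = dataclasses.replace(small_cohort, subjects=rescaled_subjects)
        atlas2 = correlation_atlas(
            rescaled, cma_units, cma_units.grid, "GCL", "standard"
        )
        assert np.allclose(atlas.values, atlas2.values)

    def test_subject_order_invariance(self, small_cohort, cma_units):
        atlas = correlation_atlas(
            small_cohort, cma_units, cma_units.grid, "GCL", "standard"
        )
        perm = np.random.default_rng(2).permutation(len(small_cohort))
        shuffled = dataclasses.replace(
            small_cohort,
            subjects=tuple(small_cohort.subjects[i] for i in perm),
        )
        atlas2 = correlation_atlas(
            shuffled, cma_units, cma_units.grid, "GCL", "standard"
        )
        assert np.allclose(atlas.values, atlas2.values)
        v1 = vector_map(atlas).frame
        v2 = vector_map(atlas2).frame
        pd.testing.assert_frame_equal(v1, v2)

    def test_too_few_subjects_rejected(self, small_cohort, cma_units):
        tiny = dataclasses.replace(small_cohort, subjects=small_cohort.subjects[:2])
        with pytest.raises(DegenerateCohortError):
            correlation_atlas(tiny, cma_units, cma_units.grid, "GCL", "standard")

    def test_degenerate_constant_cohort_flagged(self, quiet_params, cma_units):
        cohort = simulate_cohort(0, 5, seed=3, params=quiet_params)
        with pytest.raises(DegenerateCohortError):
            correlation_atlas(cohort, cma_units, cma_units.grid, "GCL", "tracked")


def toy_atlas(cma_units, fill=0.1):
    """Atlas with a controlled argmax for tie-break and geometry tests."""
    grid = cma_units.grid
    r = pd.DataFrame(
        fill,
        index=list(cma_units.unit_ids),
        columns=list(grid.superpixel_ids),
    )
    return r


class TestVectorMap:
    def _atlas(self, cma_units, r):
        return CorrelationAtlas(
            r=r, n_subjects=10, scheme="CMA", layer="GCL", modality="standard",
            excluded=cma_units.grid.excluded, unit_map=cma_units,
        )

    def test_argmax_at_mapped_superpixel_is_hit(self, cma_units):
        r = toy_atlas(cma_units)
        for u in cma_units.units:
            r.loc[u.id, u.mapped_superpixel] = 0.9
        vmap = vector_map(self._atlas(cma_units, r))
        assert vmap.frame["hit"].all()
        assert (vmap.frame["length_deg"] == 0).all()

    def test_offset_argmax_length_geometry(self, cma_units):
        # argmax 2 columns temporal and 1 row inferior: sqrt(6^2 + 3^2)
        r = toy_atlas(cma_units)
        u = next(
            u for u in cma_units.units
            if (u.mapped_superpixel - 1) % 8 >= 2
            and (u.mapped_superpixel - 1) // 8 <= 6
        )
        target = u.mapped_superpixel - 2 + 8
        r.loc[u.id, target] = 0.95
        vmap = vector_map(self._atlas(cma_units, r))
        row = vmap.frame.set_index("unit_id").loc[u.id]
        assert row.target_superpixel == target
        assert row.length_deg == pytest.approx(np.sqrt(45.0), abs=1e-9)
        assert row.length_deg == pytest.approx(6.7, abs=0.01)

    def test_exact_tie_prefers_mapped_superpixel(self, cma_units):
        r = toy_atlas(cma_units)
        u = cma_units.units[5]
        r.loc[u.id, u.mapped_superpixel] = 0.8
        r.loc[u.id, u.mapped_superpixel + 1] = 0.8
        vmap = vector_map(self._atlas(cma_units, r))
        row = vmap.frame.set_index("unit_id").loc[u.id]
        assert row.target_superpixel == u.mapped_superpixel
        assert row.hit

    def test_tie_away_from_mapped_breaks_by_distance_then_id(self, cma_units):
        r = toy_atlas(cma_units)
        u = next(u for u in cma_units.units if 18 <= u.mapped_superpixel <= 22)
        near, far = u.mapped_superpixel + 1, u.mapped_superpixel + 16
        r.loc[u.id, [near, far]] = 0.9
        vmap = vector_map(self._atlas(cma_units, r))
        assert vmap.frame.set_index("unit_id").loc[u.id].target_superpixel == near

    def test_excluded_superpixels_never_targeted(self, small_cohort, retinal_pattern):
        from maculamap.geometry import make_grid

        base = assign_units(retinal_pattern, make_grid("CMA"), "CMA")
        atlas = correlation_atlas(small_cohort, base, base.grid, "GCL", "standard")
        target0 = vector_map(atlas).frame["target_superpixel"].mode()[0]
        center = base.grid.cell_center(int(target0))
        masked_grid = apply_onh_exclusion(base.grid, center, 0.1)
        um2 = assign_units(retinal_pattern, masked_grid, "CMA")
        atlas2 = correlation_atlas(small_cohort, um2, masked_grid, "GCL", "standard")
        targets = vector_map(atlas2).frame["target_superpixel"]
        assert int(target0) not in set(targets)


class TestSummaries:
    def test_all_hits_summary(self, cma_units):
        r = toy_atlas(cma_units)
        for u in cma_units.units:
            r.loc[u.id, u.mapped_superpixel] = 0.9
        atlas = CorrelationAtlas(
            r=r, n_subjects=10, scheme="CMA", layer="GCL", modality="standard",
            excluded=frozenset(), unit_map=cma_units,
        )
        s = summarize_vectors(vector_map(atlas))
        assert s["hit_rate"] == 1.0
        assert s["median_nonzero_length"] is None

    def test_hit_rate_and_median_arithmetic(self):
        frame = pd.DataFrame(
            dict(
                unit_id=list("abcde"),
                mapped_superpixel=[1] * 5,
                target_superpixel=[1] * 5,
                r_max=[0.5] * 5,
                length_deg=[0.0, 0.0, 3.0, 6.0, 9.0],
                hit=[True, True, False, False, False],
                crosses_midline=[False] * 5,
            )
        )
        from maculamap.sfmap import VectorMap

        s = summarize_vectors(
            VectorMap(frame, "CMA", "GCL", "standard", unit_map=None)
        )
        assert s["hit_rate"] == pytest.approx(2 / 5)
        assert s["median_nonzero_length"] == 6.0

    def test_eight_hits_of_forty_is_twenty_percent(self, cma_units):
        r = toy_atlas(cma_units)
        for i, u in enumerate(cma_units.units):
            target = u.mapped_superpixel if i < 8 else (
                u.mapped_superpixel + (1 if u.mapped_superpixel % 8 else -1)
            )
            r.loc[u.id, target] = 0.9
        atlas = CorrelationAtlas(
            r=r, n_subjects=10, scheme="CMA", layer="GCL", modality="standard",
            excluded=frozenset(), unit_map=cma_units,
        )
        s = summarize_vectors(vector_map(atlas))
        assert s["hit_count"] == 8
        assert s["hit_rate"] == pytest.approx(0.20)

    def test_hemimacula_split_partitions_units(self, small_cohort, cma_units):
        atlas = correlation_atlas(
            small_cohort, cma_units, cma_units.grid, "GCL", "standard"
        )
        vmap = vector_map(atlas)
        split = hemimacula_split(vmap)
        assert len(split["superior"]) + len(split["inferior"]) == 40
        grid = cma_units.grid
        sup_ids = [
            u.mapped_superpixel
            for u in cma_units.units
            if grid.cell_center(u.mapped_superpixel)[1] > 0
        ]
        assert len(split["superior"]) == len(sup_ids)
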