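"""ICC forms against closed-form/oracle values, asymmetry formula
properties, and table validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twinscope.errors import (
    DegenerateDataError,
    InsufficientDataError,
    ValidationError,
)
from twinscope.morphometry import (
    ICC_FORMS,
    MorphometryTable,
    asymmetry_index,
    asymmetry_table,
    classify_direction,
    icc_from_matrix,
    pairwise_icc,
    read_morphometry,
)
from twinscope.regions import READING_SET, RegionSet

pg = pytest.importorskip("pingouin")

positive = st.floats(0.1, 100.0, allow_nan=False, allow_infinity=False)


def _wide_frame(subjects=("s1", "s2", "s3"), rois=("fusiform", "angular", "cuneus")):
    rng = np.random.default_rng(0)
    rows = []
    for s in subjects:
        for h in ("lh", "rh"):
            for r in rois:
                rows.append((s, h, r, rng.uniform(2, 3), rng.uniform(400, 800),
                             rng.uniform(1000, 3000)))
    return pd.DataFrame(
        rows, columns=["subject_id", "hemi", "roi", "thickness_mm", "area_mm2", "volume_mm3"]
    )


class TestReadValidation:
    def test_well_formed_table_shape(self, tmp_path):
        df = _wide_frame()
        df.to_csv(tmp_path / "m.tsv", sep="\t", index=False)
        t = read_morphometry(tmp_path / "m.tsv")
        # 3 subjects x 3 rois x 2 hemis rows per phenotype
        assert len(t.df) == 3 * 3 * 2 * 3

    def test_duplicate_row_rejected_with_key(self, tmp_path):
        df = _wide_frame()
        df = pd.concat([df, df.iloc[[0]]])
        df.to_csv(tmp_path / "m.tsv", sep="\t", index=False)
        with pytest.raises(ValidationError, match="fusiform"):
            read_morphometry(tmp_path / "m.tsv")

    def test_missing_hemisphere_rejected_naming_roi(self, tmp_path):
        df = _wide_frame()
        df = df[~((df.roi == "angular") & (df.hemi == "rh"))]
        df.to_csv(tmp_path / "m.tsv", sep="\t", index=False)
        with pytest.raises(ValidationError, match="angular"):
            read_morphometry(tmp_path / "m.tsv")


class TestICC:
    @pytest.mark.parametrize("form", ICC_FORMS)
    def test_self_agreement_is_exactly_one(self, form):
        v = np.array([2.1, 2.9, 3.4, 2.2, 2.8])
        icc, ci, p = icc_from_matrix(np.column_stack([v, v]), form)
        assert icc == 1.0

    def test_constant_shift_penalised_only_by_absolute_forms(self):
        """Hand oracle on a 4-item vector shifted by 0.5: with item variance
        sigma_r^2 = 5/3 and column variance c^2/2 = 0.125 the expected
        ICC(2,1) is sigma_r^2 / (sigma_r^2 + 0.125) = 40/43."""
        v = np.array([1.0, 2.0, 3.0, 4.0])
        Y = np.column_stack([v, v + 0.5])
        icc2, _, _ = icc_from_matrix(Y, "ICC(2,1)")
        icc3, _, _ = icc_from_matrix(Y, "ICC(3,1)")
        assert icc2 == pytest.approx(40 / 43, abs=1e-12)
        assert icc3 == 1.0
        assert icc2 < 1.0

    def test_independent_vectors_have_near_zero_icc(self):
        rng = np.random.default_rng(7)
        Y = rng.normal(size=(200, 2))
        icc, _, _ = icc_from_matrix(Y, "ICC(2,1)")
        assert abs(icc) < 0.15

    @pytest.mark.parametrize("form,pg_type", [
        ("ICC(1,1)", "ICC(1,1)"), ("ICC(2,1)", "ICC(A,1)"), ("ICC(3,1)", "ICC(C,1)"),
    ])
    def test_matches_pingouin_reference(self, form, pg_type):
        rng = np.random.default_rng(11)
        for _ in range(4):
            n = int(rng.integers(5, 40))
            Y = rng.normal(2.5, 0.4, size=(n, 2))
            rows = [(i, f"r{j}", Y[i, j]) for i in range(n) for j in range(2)]
            df = pd.DataFrame(rows, columns=["targets", "raters", "ratings"])
            ref = pg.intraclass_corr(
                df, targets="targets", raters="raters", ratings="ratings"
            ).set_index("Type").loc[pg_type]
            icc, ci, p = icc_from_matrix(Y, form)
            assert icc == pytest.approx(ref.ICC, abs=1e-9)
            assert p == pytest.approx(ref.pval, abs=1e-9)
            assert np.allclose(ci, ref.CI95, atol=5e-3)  # pingouin rounds CIs

    def test_too_few_items_raises(self):
        with pytest.raises(InsufficientDataError):
            icc_from_matrix(np.ones((2, 2)), "ICC(2,1)")

    def test_zero_item_variance_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            icc_from_matrix(np.full((5, 2), 2.5), "ICC(2,1)")

    def test_region_subsetting_consistency(self):
        table = MorphometryTable(
            _wide_frame().melt(
                id_vars=["subject_id", "hemi", "roi"],
                value_vars=["thickness_mm"], value_name="value",
            ).assign(phenotype="thickness").drop(columns="variable")
        )
        rs = RegionSet("two", ("fusiform", "angular"))
        direct = pairwise_icc(table, ("s1", "s2"), "thickness", rs)
        filtered = pairwise_icc(table.restrict(rs), ("s1", "s2"), "thickness", rs)
        assert direct.icc == filtered.icc
        assert direct.n_items == 4


class TestAsymmetry:
    def test_equal_hemispheres_give_zero(self):
        assert asymmetry_index(2.5, 2.5) == 0.0

    def test_direct_evaluation(self):
        assert asymmetry_index(3.0, 1.0) == pytest.approx(1.0)

    @given(a=positive, b=positive)
    @settings(max_examples=100, deadline=None)
    def test_antisymmetric_under_swap(self, a, b):
        assert asymmetry_index(a, b) == pytest.approx(-asymmetry_index(b, a), rel=1e-9)

    @given(a=positive, b=positive, c=st.floats(0.01, 100, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, a, b, c):
        assert asymmetry_index(c * a, c * b) == pytest.approx(
            asymmetry_index(a, b), rel=1e-9, abs=1e-12
        )

    @pytest.mark.parametrize("index,expected", [
        (-0.217, "rightward"),
        (0.084, "leftward"),
        (0.0, "symmetric"),
        (0.009, "symmetric"),
    ])
    def test_direction_classification(self, index, expected):
        assert classify_direction(index) == expected

    def test_table_indices_match_brute_force(self):
        df = _wide_frame()
        long = df.melt(
            id_vars=["subject_id", "hemi", "roi"],
            value_vars=["volume_mm3"], value_name="value",
        ).assign(phenotype="volume").drop(columns="variable")
        table = MorphometryTable(long)
        rs = RegionSet("all", ("fusiform", "angular", "cuneus"))
        for rec in asymmetry_table(table, rs, "volume"):
            L = table.value(rec.subject_id, "lh", rec.roi, "volume")
            R = table.value(rec.subject_id, "rh", rec.roi, "volume")
            assert rec.index == pytest.approx(2 * (L - R) / (L + R), abs=1e-12)

    def test_symmetric_input_gives_all_zero(self):
        rows = []
        for s in ("s1",):
            for r in ("fusiform", "angular", "cuneus"):
                for h in ("lh", "rh"):
                    rows.append((s, h, r, "thickness", 2.5))
        table = MorphometryTable(
            pd.DataFrame(rows, columns=["subject_id", "hemi", "roi", "phenotype", "value"])
        )
        recs = asymmetry_table(table, RegionSet("all", ("fusiform", "angular", "cuneus")), "thickness")
        assert all(r.index == 0.0 and r.direction == "symmetric" for r in recs)
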