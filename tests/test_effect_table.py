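"""Effect-table data model, serialization and the curated fixture."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mvmeta_mf import (
    TABLE2_STUDY_COUNTS,
    EffectEstimate,
    EffectTable,
    FactorDef,
    StudyRecord,
    TableFormatError,
    TableValidationError,
    builtin_table1,
    filter_factors_min_studies,
    load_effect_table,
    reporting_counts,
    write_effect_table,
)

# Every printed cell of the nine-study glottic carcinoma table, re-typed
# here independently of the package's own fixture module so that any
# transcription slip in either place fails loudly.
EXPECTED_CELLS = {
    ("elicin2019", "aci"): (0.51, 0.16),
    ("elicin2019", "t_substage"): (0.48, 0.21),
    ("elicin2019", "rt_technique"): (-0.17, 0.25),
    ("elicin2019", "total_rt_dose"): (0.45, 0.16),
    ("elicin2019", "gender"): (1.25, 0.59),
    ("elicin2019", "age"): (-0.04, 0.18),
    ("gultekin2012", "aci"): (0.73, 0.28),
    ("gultekin2012", "t_substage"): (0.64, 0.30),
    ("gultekin2012", "subglottic_extension"): (0.41, 0.35),
    ("gultekin2012", "rt_technique"): (0.30, 0.18),
    ("gultekin2012", "gender"): (-0.92, 1.27),
    ("gultekin2012", "smoking_status"): (0.97, 1.01),
    ("gultekin2012", "age"): (1.21, 0.30),
    ("gultekin2012", "tumor_grading"): (-0.08, 0.18),
    ("yamazaki2006", "aci"): (-0.20, 0.66),
    ("yamazaki2006", "t_substage"): (0.57, 0.73),
    ("yamazaki2006", "fraction_size"): (-1.17, 0.41),
    ("yamazaki2006", "gender"): (-0.62, 1.05),
    ("yamazaki2006", "hb_level"): (-0.21, 0.45),
    ("yamazaki2006", "smoking_status"): (0.25, 0.72),
    ("yamazaki2006", "age"): (-0.26, 0.44),
    ("almamgani2013", "aci"): (0.10, 0.20),
    ("almamgani2013", "total_rt_dose"): (-0.11, 0.11),
    ("almamgani2013", "fraction_size"): (0.47, 0.06),
    ("almamgani2013", "gender"): (0.18, 0.56),
    ("almamgani2013", "hb_level"): (0.99, 0.16),
    ("almamgani2013", "smoking_status"): (1.31, 0.10),
    ("almamgani2013", "age"): (0.00, 0.25),
    ("bignardi2004", "aci"): (-0.73, 0.47),
    ("bignardi2004", "vocal_cord_mobility"): (-0.07, 0.63),
    ("bignardi2004", "subglottic_extension"): (0.48, 0.75),
    ("bignardi2004", "rt_technique"): (0.34, 0.48),
    ("bignardi2004", "total_rt_dose"): (0.04, 0.08),
    ("bignardi2004", "ott"): (0.18, 0.20),
    ("bignardi2004", "field_size"): (0.17, 0.57),
    ("bignardi2004", "tumor_grading"): (0.00, 0.02),
    ("chung2018", "aci"): (0.51, 0.40),
    ("chung2018", "t_substage"): (0.72, 0.47),
    ("chung2018", "gender"): (-0.06, 0.74),
    ("chung2018", "age"): (0.37, 0.39),
    ("chung2018", "tumor_grading"): (-0.13, 0.45),
    ("matsumoto2016", "aci"): (-1.03, 0.83),
    ("matsumoto2016", "t_substage"): (1.00, 0.68),
    ("matsumoto2016", "fraction_size"): (1.26, 0.58),
    ("matsumoto2016", "ott"): (1.03, 0.69),
    ("matsumoto2016", "gender"): (-0.20, 1.14),
    ("matsumoto2016", "age"): (0.92, 0.63),
    ("raitiola2000", "aci"): (1.34, 0.47),
    ("raitiola2000", "t_substage"): (1.48, 0.46),
    ("raitiola2000", "vocal_cord_mobility"): (1.00, 0.64),
    ("deridder2023", "aci"): (-0.36, 0.72),
    ("deridder2023", "t_substage"): (2.08, 0.82),
    ("deridder2023", "field_size"): (0.02, 0.03),
    ("deridder2023", "gender"): (-0.01, 1.07),
    ("deridder2023", "smoking_status"): (2.22, 0.73),
    ("deridder2023", "age"): (-0.02, 0.04),
}


class TestFixture:
    def test_shape(self, table1):
        assert table1.n_studies == 9
        assert table1.n_factors == 14

    def test_every_cell_matches_the_printed_table(self, table1):
        observed = {
            (s.study_id, fid): (e.log_or, e.se)
            for s in table1.studies
            for fid, e in s.estimates.items()
        }
        assert observed == EXPECTED_CELLS
        assert len(observed) == 56

    def test_raitiola_reports_exactly_three_factors(self, table1):
        est = table1.study("raitiola2000").estimates
        assert set(est) == {"aci", "t_substage", "vocal_cord_mobility"}

    def test_gultekin_aci(self, table1):
        e = table1.study("gultekin2012").estimates["aci"]
        assert (e.log_or, e.se) == (0.73, 0.28)

    def test_all_ses_positive(self, table1):
        se = table1.se.to_numpy()
        assert np.nanmin(se) > 0

    def test_observed_zero_is_not_missing(self, table1):
        # Bignardi tumor grading 0.00 (0.02) is an observed estimate
        assert table1.mask.loc["bignardi2004", "tumor_grading"]
        assert table1.study("bignardi2004").estimates["tumor_grading"].log_or == 0.0


class TestReportingCounts:
    def test_counts_match_fixture_tallies(self, table1):
        from collections import Counter

        counts = reporting_counts(table1)
        expected = Counter(fid for _, fid in EXPECTED_CELLS)
        for fid in table1.factor_ids:
            assert counts[fid] == expected[fid]

    def test_documented_divergence_from_published_model_counts(self, table1):
        """The printed table exceeds the published fitted-model N by one
        study in exactly six columns (ACI 9 vs 8, T substage 7 vs 6, ...)."""
        counts = reporting_counts(table1)
        diverging = {f for f in table1.factor_ids if counts[f] != TABLE2_STUDY_COUNTS[f]}
        assert diverging == {
            "aci",
            "t_substage",
            "rt_technique",
            "gender",
            "smoking_status",
            "tumor_grading",
        }
        assert all(counts[f] == TABLE2_STUDY_COUNTS[f] + 1 for f in diverging)

    def test_single_study_table(self):
        t = EffectTable(
            studies=[
                StudyRecord("s1", "s1", {"a": EffectEstimate(0.0, 1.0)}),
            ],
            factors=[
                FactorDef("a", "A", "yes vs no"),
                FactorDef("b", "B", "yes vs no"),
            ],
        )
        counts = reporting_counts(t)
        assert counts["a"] == 1
        assert counts["b"] == 0


class TestValidation:
    def test_se_zero_rejected(self):
        with pytest.raises(TableValidationError):
            EffectEstimate(0.5, 0.0)

    def test_study_without_estimates_rejected(self):
        with pytest.raises(TableValidationError):
            StudyRecord("s1", "s1", {})

    def test_empty_contrast_rejected(self):
        with pytest.raises(TableValidationError):
            FactorDef("a", "A", "")

    def test_undeclared_factor_rejected(self):
        with pytest.raises(TableValidationError, match="undeclared"):
            EffectTable(
                studies=[StudyRecord("s1", "s1", {"zz": EffectEstimate(0.1, 0.2)})],
                factors=[FactorDef("a", "A", "yes vs no")],
            )


class TestIO:
    @pytest.mark.parametrize("layout", ["long", "wide"])
    def test_round_trip_preserves_every_cell_and_the_mask(self, table1, tmp_path, layout):
        path = tmp_path / f"t1.{layout}.csv"
        write_effect_table(table1, path, layout=layout)
        back = load_effect_table(path, layout=layout, factors=table1.factors)
        assert back.study_ids == table1.study_ids
        assert back.factor_ids == table1.factor_ids
        assert back.mask.equals(table1.mask)
        pd.testing.assert_frame_equal(back.log_or, table1.log_or)
        pd.testing.assert_frame_equal(back.se, table1.se)

    def test_minimal_long_file(self, tmp_path):
        path = tmp_path / "min.csv"
        path.write_text("study,factor,log_or,se\ns1,aci,0.0,1.0\n")
        t = load_effect_table(path, layout="long")
        assert (t.n_studies, t.n_factors) == (1, 1)
        assert t.mask.all().all()

    def test_nonpositive_se_names_the_cell(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("study,factor,log_or,se\ns1,aci,0.5,0.2\ns2,aci,0.1,0\n")
        with pytest.raises(TableValidationError, match="s2.*aci"):
            load_effect_table(path, layout="long")

    def test_duplicate_cell_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "study,factor,log_or,se\ns1,aci,0.5,0.2\ns1,aci,0.6,0.3\n"
        )
        with pytest.raises(TableFormatError, match="duplicate"):
            load_effect_table(path, layout="long")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_effect_table(tmp_path / "nope.csv")

    def test_malformed_wide_cell(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("study,aci\ns1,0.5/0.2\n")
        with pytest.raises(TableFormatError, match="not 'log_or \\(se\\)'"):
            load_effect_table(path, layout="wide")


class TestFilter:
    def test_published_inclusion_rule_keeps_14_factors(self, table1):
        assert filter_factors_min_studies(table1, 2).n_factors == 14

    def test_k1_is_identity(self, table1):
        t = filter_factors_min_studies(table1, 1)
        assert t.factor_ids == table1.factor_ids
        assert t.mask.equals(table1.mask)

    def test_k9_keeps_only_the_fully_reported_factor(self, table1):
        # independent tally: only ACI appears in all nine study rows
        per_column = {}
        for (_, fid) in EXPECTED_CELLS:
            per_column[fid] = per_column.get(fid, 0) + 1
        expect = sorted(f for f, c in per_column.items() if c >= 9)
        got = filter_factors_min_studies(table1, 9)
        assert got.factor_ids == expect == ["aci"]

    def test_idempotent(self, table1):
        once = filter_factors_min_studies(table1, 4)
        twice = filter_factors_min_studies(once, 4)
        assert twice.factor_ids == once.factor_ids
        assert twice.mask.equals(once.mask)

    def test_k_below_one_rejected(self, table1):
        with pytest.raises(ValueError):
            filter_factors_min_studies(table1, 0)

    def test_studies_left_empty_are_dropped(self, table1):
        # Raitiola reports only three sparse-ish factors; at k=8 it vanishes
        t = filter_factors_min_studies(table1, 8)
        assert "raitiola2000" in table1.study_ids
        assert t.factor_ids == ["aci"]
        assert set(t.study_ids) == set(table1.study_ids)  # all report ACI


class TestExclusions:
    def test_without_cells_drops_cell_and_empty_study(self, table1):
        t = table1.without_cells(
            [("raitiola2000", f) for f in ("aci", "t_substage", "vocal_cord_mobility")]
        )
        assert "raitiola2000" not in t.study_ids
        assert reporting_counts(t)["aci"] == 8

    def test_unknown_cell_rejected(self, table1):
        with pytest.raises(KeyError):
            table1.without_cells([("raitiola2000", "gender")])


@st.composite
def small_tables(draw):
    n_stud = draw(st.integers(1, 5))
    n_fac = draw(st.integers(1, 4))
    factors = [FactorDef(f"f{j}", f"f{j}", "yes vs no") for j in range(n_fac)]
    studies = []
    for i in range(n_stud):
        cells = draw(
            st.dictionaries(
                st.sampled_from([f.factor_id for f in factors]),
                st.tuples(
                    st.floats(-3, 3, allow_nan=False),
                    st.floats(0.01, 2.0, allow_nan=False),
                ),
                min_size=1,
            )
        )
        studies.append(
            StudyRecord(
                f"s{i}", f"s{i}", {k: EffectEstimate(*v) for k, v in cells.items()}
            )
        )
    return EffectTable(studies=studies, factors=factors)


@settings(max_examples=25, deadline=None)
@given(table=small_tables(), layout=st.sampled_from(["long", "wide"]))
def test_round_trip_property(table, layout, tmp_path_factory):
    path = tmp_path_factory.mktemp("rt") / "t.csv"
    write_effect_table(table, path, layout=layout)
    back = load_effect_table(path, layout=layout, factors=table.factors)
    assert back.mask.equals(table.mask)
    assert np.allclose(
        back.log_or.to_numpy(), table.log_or.to_numpy(), equal_nan=True
    )
    assert np.allclose(back.se.to_numpy(), table.se.to_numpy(), equal_nan=True)
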