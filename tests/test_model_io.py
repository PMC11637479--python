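"""Domain-type validation and delimited-text round-trips."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from capiscore import io
from capiscore.errors import TableFormatError, ValidationError
from capiscore.model import FeatureVector, ImageMeasurement, NvcExam
from capiscore.patterns import Verdict
from capiscore.pipeline import classify_exams
from capiscore.simulate import make_config, generate_cohort

HEADER = ",".join(io.IMAGE_COLUMNS)


def _row(exam="E1", img="I1", cal=1, caps=12, width=1.5, giant=0, abn=0, tort=0, haem=0):
    return f"{exam},{img},{cal},{caps},{width},{giant},{abn},{tort},{haem}"


class TestImageMeasurement:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_giant=5, n_capillaries=3),
            dict(n_abnormal=4, n_capillaries=3),
            dict(n_tortuous=9, n_capillaries=8),
            dict(width_mm=0.0),
            dict(width_mm=-1.0),
            dict(n_capillaries=-1),
            dict(n_haemorrhages=-2),
        ],
    )
    def test_invariant_violations_rejected(self, kwargs):
        base = dict(
            image_id="I1", n_capillaries=10, width_mm=1.5,
            n_giant=0, n_abnormal=0, n_tortuous=0, n_haemorrhages=0,
        )
        base.update(kwargs)
        with pytest.raises(ValidationError):
            ImageMeasurement(**base)

    @given(
        caps=st.integers(0, 400),
        width=st.floats(0.1, 5.0, allow_nan=False),
        haem=st.integers(0, 5),
        data=st.data(),
    )
    def test_valid_rows_accepted(self, caps, width, haem, data):
        giant = data.draw(st.integers(0, caps))
        abn = data.draw(st.integers(0, caps))
        tort = data.draw(st.integers(0, caps))
        img = ImageMeasurement("I1", caps, width, giant, abn, tort, haem)
        assert img.n_capillaries == caps

    def test_duplicate_image_id_rejected(self):
        img = ImageMeasurement("I1", 10, 1.5, 0, 0, 0, 0)
        with pytest.raises(ValidationError, match="duplicate image_id"):
            NvcExam("E1", True, (img, img))


class TestFeatureVector:
    def test_density_must_match_totals(self):
        with pytest.raises(ValidationError, match="inconsistent"):
            FeatureVector(5.0, 0, 0, 0, False, 100, 10.0)

    @pytest.mark.parametrize("field,value", [("pct_giant", 101.0), ("pct_abnormal", -0.1)])
    def test_percentage_bounds(self, field, value):
        kwargs = dict(
            density=10.0, pct_giant=0.0, pct_abnormal=0.0, pct_tortuous=0.0,
            haemorrhages_present=False, total_capillaries=100, total_width_mm=10.0,
        )
        kwargs[field] = value
        with pytest.raises(ValidationError):
            FeatureVector(**kwargs)

    def test_from_features_is_consistent(self):
        fv = FeatureVector.from_features(6.37, pct_giant=3.0)
        assert math.isclose(fv.density, fv.total_capillaries / fv.total_width_mm, rel_tol=1e-9)


class TestReadImageTable:
    def test_rows_grouped_by_exam_in_file_order(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "\n".join([HEADER, _row(img="I1"), _row(img="I2"), _row(exam="E0", img="I1")]) + "\n"
        )
        exams = io.read_image_table(path)
        assert [e.exam_id for e in exams] == ["E1", "E0"]
        assert exams[0].n_images == 2 and exams[1].n_images == 1

    def test_header_only_file_gives_empty_collection(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(HEADER + "\n")
        assert io.read_image_table(path) == []

    def test_count_exceeding_capillaries_names_row(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("\n".join([HEADER, _row(), _row(img="I2", giant=5, caps=3)]) + "\n")
        with pytest.raises(TableFormatError, match="row 2"):
            io.read_image_table(path)

    def test_malformed_number_names_row_and_field(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("\n".join([HEADER, _row(width="oops")]) + "\n")
        with pytest.raises(TableFormatError, match="width_mm"):
            io.read_image_table(path)

    def test_duplicate_image_id_within_exam_rejected(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("\n".join([HEADER, _row(), _row()]) + "\n")
        with pytest.raises(TableFormatError, match="duplicate image_id"):
            io.read_image_table(path)

    def test_inconsistent_calibration_flag_rejected(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("\n".join([HEADER, _row(cal=1), _row(img="I2", cal=0)]) + "\n")
        with pytest.raises(TableFormatError, match="calibrated"):
            io.read_image_table(path)


class TestRoundTrips:
    def test_image_table_read_write_identity(self, tmp_path):
        cohort = generate_cohort(make_config("separable", n_exams=20, seed=5))
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        io.write_image_table(cohort.exams, p1)
        exams = io.read_image_table(p1)
        assert tuple(exams) == cohort.exams
        io.write_image_table(exams, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_classification_table_round_trips_byte_identically(self, tmp_path):
        cohort = generate_cohort(make_config("overlapping", n_exams=100, seed=9))
        results, _ = classify_exams(cohort.exams)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        io.write_classification_table(results, p1)
        records = io.read_classification_table(p1)
        assert [r["exam_id"] for r in records] == [r.exam_id for r in results]
        assert [r["pattern"] for r in records] == [r.pattern for r in results]
        assert [r["trace"] for r in records] == [r.trace for r in results]
        # re-serialize from re-read values: bytes must not change
        io.write_classification_table(
            [
                type(results[0])(
                    exam_id=rec["exam_id"],
                    features=res.features,
                    pattern=rec["pattern"],
                    trace=rec["trace"],
                )
                for rec, res in zip(records, results)
            ],
            p2,
        )
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_results_give_header_only_file(self, tmp_path):
        path = tmp_path / "empty.csv"
        io.write_classification_table([], path)
        assert path.read_text() == ",".join(io.CLASSIFICATION_COLUMNS) + "\n"
        assert io.read_classification_table(path) == []

    def test_verdict_and_gold_tables_round_trip(self, tmp_path):
        verdicts = [
            ("E1", (Verdict.SSC_EARLY, Verdict.SSC_EARLY, Verdict.UNGRADABLE)),
            ("E2", (Verdict.NORMAL, Verdict.NON_SPECIFIC, Verdict.SSC_LATE)),
        ]
        vp = tmp_path / "v.csv"
        io.write_verdict_table(verdicts, vp)
        assert io.read_verdict_table(vp) == verdicts

    def test_unknown_verdict_rejected_with_row(self, tmp_path):
        vp = tmp_path / "v.csv"
        vp.write_text("exam_id,rater_1,rater_2,rater_3\nE1,normal,bogus,normal\n")
        with pytest.raises(TableFormatError, match="rater_2"):
            io.read_verdict_table(vp)
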