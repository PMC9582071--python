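"""Domain types, code canonicalization, and the CSV/JSON interchange formats."""

import json

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mrharmony import (
    CodeSetElement,
    DataError,
    ExamRecord,
    OverlapMatrix,
    ProtocolDefinition,
    ProtocolTree,
    SequenceAcquisition,
    canonicalize_code,
    read_exam_log,
    read_protocol_trees,
    write_exam_log,
    write_matrix_csv,
    write_protocol_trees,
)
import numpy as np


class TestCanonicalizeCode:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            (" m54.5 ", "M54.5"),
            ("M545", "M54.5"),
            ("g35", "G35"),
            ("s060x1a", "S06.0X1A"),
            ("M54.5", "M54.5"),
        ],
    )
    def test_normalizes(self, raw, expected):
        assert canonicalize_code(raw) == expected

    @pytest.mark.parametrize("bad", ["54X", "M", "", "  ", "5M4", "M5", "M54.55555"])
    def test_rejects_malformed(self, bad):
        with pytest.raises(DataError):
            canonicalize_code(bad)

    def test_error_names_offending_value(self):
        with pytest.raises(DataError, match="54X"):
            canonicalize_code("54X")

    @given(
        st.from_regex(r"[A-Za-z][0-9]{2}(\.?[A-Za-z0-9]{1,4})?", fullmatch=True)
    )
    def test_idempotent(self, raw):
        try:
            once = canonicalize_code(raw)
        except DataError:
            return
        assert canonicalize_code(once) == once


class TestDomainTypes:
    def test_code_set_element_sorted_dedup(self):
        elem = CodeSetElement.from_codes(["M54.5", "G35", "M54.5"])
        assert elem.codes == ("G35", "M54.5")
        assert elem == CodeSetElement.from_codes(["G35", "M54.5"])

    def test_code_set_element_rejects_empty_and_unsorted(self):
        with pytest.raises(DataError):
            CodeSetElement(())
        with pytest.raises(DataError):
            CodeSetElement(("M54.5", "G35"))

    def test_ti_without_inversion_recovery_rejected(self):
        with pytest.raises(DataError, match="inversion_recovery"):
            SequenceAcquisition(raw_name="x", tr_ms=9000, te_ms=100, ti_ms=2500)

    def test_diffusion_with_non_epi_technique_warns_not_rejects(self, caplog):
        seq = SequenceAcquisition(
            raw_name="dwi?", tr_ms=4000, te_ms=70, technique="SE", b_values=(0, 1000)
        )
        assert seq.b_values == (0, 1000)

    def test_duplicate_protocol_names_rejected(self):
        seq = SequenceAcquisition(raw_name="s", tr_ms=500, te_ms=10)
        proto = ProtocolDefinition("P", "spine", (seq,))
        with pytest.raises(DataError, match="duplicate"):
            ProtocolTree("sc1", "siteA", (proto, proto))


class TestExamLogIO:
    HEADER = "exam_id,scanner_id,site_id,body_region,protocol_name,admitting_codes"

    def write(self, tmp_path, rows):
        path = tmp_path / "log.csv"
        path.write_text("\n".join([self.HEADER] + rows) + "\n", encoding="utf-8")
        return path

    def test_basic_parse(self, tmp_path):
        path = self.write(tmp_path, ["e1,sc1,A,spine,CERVICAL/WITHOUT,M54.2"])
        (rec,) = read_exam_log(path)
        assert rec.admitting_codes == {"M54.2"}
        assert rec.body_region == "spine"

    def test_multi_code_cell_and_dedup(self, tmp_path):
        path = self.write(
            tmp_path,
            ["e1,sc1,A,spine,P,M54.2;M50.30", "e2,sc1,A,spine,P,M54.2;M54.2"],
        )
        recs = read_exam_log(path)
        assert recs[0].admitting_codes == {"M54.2", "M50.30"}
        assert recs[1].admitting_codes == {"M54.2"}

    def test_empty_codes_cell_kept_with_warning(self, tmp_path, caplog):
        path = self.write(tmp_path, ["e1,sc1,A,spine,P,"])
        with caplog.at_level("WARNING", logger="mrharmony"):
            (rec,) = read_exam_log(path)
        assert rec.admitting_codes == frozenset()
        assert any("without admitting" in m for m in caplog.messages)

    def test_duplicate_exam_id_rejected(self, tmp_path):
        path = self.write(tmp_path, ["e1,sc1,A,spine,P,M54.2", "e1,sc1,A,spine,P,G35"])
        with pytest.raises(DataError, match="duplicate exam_id"):
            read_exam_log(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "log.csv"
        path.write_text("exam_id,scanner_id\ne1,sc1\n", encoding="utf-8")
        with pytest.raises(DataError, match="missing required columns"):
            read_exam_log(path)

    def test_round_trip(self, tmp_path):
        records = [
            ExamRecord(
                exam_id=f"e{i}",
                scanner_id="sc1",
                site_id="A",
                body_region="spine",
                protocol_name="LUMBAR/WITHOUT",
                admitting_codes=frozenset({"M54.5", "G35"}),
                exam_date="2019-03-01",
            )
            for i in range(3)
        ]
        path = tmp_path / "rt.csv"
        write_exam_log(records, path)
        assert read_exam_log(path) == records


class TestProtocolTreeIO:
    def make_doc(self):
        return {
            "scanners": [
                {
                    "scanner_id": "sc1",
                    "site_id": "siteA",
                    "protocols": [
                        {
                            "protocol_name": "P1",
                            "body_region": "spine",
                            "sequences": [
                                {"raw_name": "t1_se_sag", "tr_ms": 500, "te_ms": 10},
                                {
                                    "raw_name": "stir_cor",
                                    "tr_ms": 4000,
                                    "te_ms": 40,
                                    "ti_ms": 180,
                                    "inversion_recovery": True,
                                    "technique": "TSE",
                                },
                                {"raw_name": "t2_tse_tra", "tr_ms": 4500, "te_ms": 110},
                            ],
                        },
                        {
                            "protocol_name": "P2",
                            "body_region": "spine",
                            "sequences": [
                                {"raw_name": "dwi", "tr_ms": 5000, "te_ms": 70,
                                 "technique": "EPI", "b_values": [0, 1000]},
                            ],
                        },
                    ],
                }
            ]
        }

    def test_parse_with_defaults(self, tmp_path):
        path = tmp_path / "trees.json"
        path.write_text(json.dumps(self.make_doc()), encoding="utf-8")
        (tree,) = read_protocol_trees(path)
        assert len(tree.protocols) == 2
        first = tree.protocols[0].sequences[0]
        assert first.technique == "UNKNOWN" and first.contrast_phase == "NONE"

    def test_invariant_violation_reports_json_path(self, tmp_path):
        doc = self.make_doc()
        doc["scanners"][0]["protocols"][0]["sequences"][1]["inversion_recovery"] = False
        path = tmp_path / "trees.json"
        path.write_text(json.dumps(doc), encoding="utf-8")
        with pytest.raises(DataError, match=r"\$\.scanners\[0\]\.protocols\[0\]\.sequences\[1\]"):
            read_protocol_trees(path)

    def test_missing_field_reports_json_path(self, tmp_path):
        doc = self.make_doc()
        del doc["scanners"][0]["protocols"][1]["sequences"][0]["tr_ms"]
        path = tmp_path / "trees.json"
        path.write_text(json.dumps(doc), encoding="utf-8")
        with pytest.raises(DataError, match=r"protocols\[1\]\.sequences\[0\]"):
            read_protocol_trees(path)

    def test_duplicate_protocol_name_rejected(self, tmp_path):
        doc = self.make_doc()
        doc["scanners"][0]["protocols"][1]["protocol_name"] = "P1"
        path = tmp_path / "trees.json"
        path.write_text(json.dumps(doc), encoding="utf-8")
        with pytest.raises(DataError, match="duplicate protocol names"):
            read_protocol_trees(path)

    def test_empty_tree_valid_with_warning(self, tmp_path, caplog):
        path = tmp_path / "trees.json"
        path.write_text(
            json.dumps({"scanners": [{"scanner_id": "s", "site_id": "a",
                                      "protocols": []}]}),
            encoding="utf-8",
        )
        with caplog.at_level("WARNING", logger="mrharmony"):
            (tree,) = read_protocol_trees(path)
        assert tree.protocols == ()

    def test_round_trip(self, tmp_path):
        path = tmp_path / "trees.json"
        path.write_text(json.dumps(self.make_doc()), encoding="utf-8")
        trees = read_protocol_trees(path)
        out = tmp_path / "rt.json"
        write_protocol_trees(trees, out)
        assert read_protocol_trees(out) == trees


class TestMatrixCSV:
    def test_shape_rounding_and_undefined_complement(self, tmp_path):
        matrix = OverlapMatrix(
            labels=("P1", "P2"),
            values=np.array([[1.0, 2 / 3], [2 / 3, 1.0]]),
            complement=(2 / 3, None),
            element_counts=(3, 4),
        )
        path = tmp_path / "m.csv"
        write_matrix_csv(matrix, path)
        lines = path.read_text(encoding="utf-8").strip().splitlines()
        assert lines[0] == "protocol,P1,P2,complement"
        assert lines[1] == "P1,1.00,0.67,0.67"
        assert lines[2] == "P2,0.67,1.00,"
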