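import json

import pytest
from hypothesis import given, settings, strategies as st

from ltrforest import io
from ltrforest.classify import PredictionRecord
from ltrforest.config import RunConfig
from ltrforest.errors import FormatError, ModelVersionError, VocabularyError
from ltrforest.forest import TrainingExample, induce_forest

from conftest import mk_hit


class TestReadFasta:
    def test_minimal_record(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">chr1\nACGT\n")
        seqs = io.read_fasta(p)
        assert len(seqs) == 1
        assert seqs[0].seq_id == "chr1"
        assert len(seqs[0]) == 4

    def test_empty_record_is_error_with_line_number(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">ok\n" + "A" * 10 + "\n>empty\n")
        with pytest.raises(FormatError, match=r":3:"):
            io.read_fasta(p)

    def test_wrapped_record_concatenates(self, tmp_path):
        # oracle: plain string concatenation of the wrapped lines
        lines = ["ACGTA" * 12, "TTGCA" * 12]
        expected = "".join(lines)
        p = tmp_path / "a.fa"
        p.write_text(">x\n" + "\n".join(lines) + "\n")
        (seq,) = io.read_fasta(p)
        assert seq.residues == expected
        assert len(seq) == 120

    def test_empty_file_is_error(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text("")
        with pytest.raises(FormatError, match="empty"):
            io.read_fasta(p)

    def test_data_before_header_is_error(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text("ACGT\n>x\nACGT\n")
        with pytest.raises(FormatError, match=r":1:"):
            io.read_fasta(p)

    def test_residues_uppercased(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">x\nacgtn\n")
        assert io.read_fasta(p)[0].residues == "ACGTN"

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.text(alphabet="ACGTN", min_size=1, max_size=200), min_size=1, max_size=5))
    def test_round_trip_preserves_sequences(self, tmp_path_factory, residues):
        tmp = tmp_path_factory.mktemp("fa")
        seqs = [io.GenomeSequence(f"s{i}", r) for i, r in enumerate(residues)]
        io.write_fasta(seqs, tmp / "x.fa")
        back = io.read_fasta(tmp / "x.fa")
        assert [(s.seq_id, s.residues) for s in back] == [
            (s.seq_id, s.residues) for s in seqs
        ]


class TestReadDomainHits:
    def test_direct_parse(self, tmp_path, hierarchy):
        p = tmp_path / "h.tsv"
        p.write_text("c1\tRT_LTR\t100\t600\t+\t1e-30\n")
        (h,) = io.read_domain_hits(p, hierarchy)
        assert (h.subject_id, h.start, h.end, h.strand, h.evalue, h.source_seq) == (
            "RT_LTR", 99, 600, "+", 1e-30, "c1",
        )

    def test_reversed_coordinates_normalized_to_minus(self, tmp_path, hierarchy):
        p = tmp_path / "h.tsv"
        p.write_text("c1\tRT_LTR\t600\t100\t+\t1e-30\n")
        (h,) = io.read_domain_hits(p, hierarchy)
        assert (h.start, h.end, h.strand) == (99, 600, "-")

    def test_unknown_subject_is_vocabulary_error(self, tmp_path, hierarchy):
        p = tmp_path / "h.tsv"
        p.write_text("c1\tFOO\t1\t10\t+\t1e-5\n")
        with pytest.raises(VocabularyError, match="FOO"):
            io.read_domain_hits(p, hierarchy)

    def test_non_numeric_evalue_is_format_error(self, tmp_path, hierarchy):
        p = tmp_path / "h.tsv"
        p.write_text("c1\tRT_LTR\t1\t10\t+\tnotanumber\n")
        with pytest.raises(FormatError, match="e-value"):
            io.read_domain_hits(p, hierarchy)

    def test_round_trip(self, tmp_path, hierarchy):
        hits = [mk_hit("RT_LTR", 99, 600), mk_hit("rve", 10, 50, "-", 1e-7, "c2")]
        io.write_domain_hits(hits, tmp_path / "h.tsv")
        assert io.read_domain_hits(tmp_path / "h.tsv", hierarchy) == hits


def _pred(cid, seq_id, start, end, probs, label, strand="+"):
    return PredictionRecord(cid, seq_id, start, end, strand, probs, label)


class TestPredictionsGff:
    def test_single_record(self, tmp_path):
        p = tmp_path / "p.gff3"
        io.write_predictions_gff(
            [_pred("c1", "chr1", 99, 500, {"Gypsy": 0.9}, "Gypsy")], p
        )
        lines = p.read_text().splitlines()
        assert lines[0] == "##gff-version 3"
        assert len(lines) == 2
        fields = lines[1].split("\t")
        assert fields[0] == "chr1"
        assert (fields[3], fields[4]) == ("100", "500")
        assert "Superfamily=Gypsy" in fields[8]
        assert "Probability=0.9000" in fields[8]

    def test_empty_list_is_header_only(self, tmp_path):
        p = tmp_path / "p.gff3"
        io.write_predictions_gff([], p)
        assert p.read_text() == "##gff-version 3\n"

    def test_sorted_by_start(self, tmp_path):
        p = tmp_path / "p.gff3"
        io.write_predictions_gff(
            [
                _pred("b", "chr1", 500, 900, {"Copia": 0.5}, "Copia"),
                _pred("a", "chr1", 100, 400, {"Copia": 0.5}, "Copia"),
            ],
            p,
        )
        starts = [int(l.split("\t")[3]) for l in p.read_text().splitlines()[1:]]
        assert starts == sorted(starts)

    def test_round_trip_intervals_and_attributes(self, tmp_path):
        preds = [
            _pred("c1", "chr1", 99, 500, {"Copia": 0.25, "Gypsy": 0.9}, "Gypsy"),
            _pred("c2", "chr2", 0, 150, {"Copia": 0.6, "Gypsy": 0.1}, "Copia", "-"),
        ]
        p = tmp_path / "p.gff3"
        io.write_predictions_gff(preds, p)
        back = io.read_predictions_gff(p)
        by_id = {r.candidate_id: r for r in back}
        for orig in preds:
            r = by_id[orig.candidate_id]
            assert (r.seq_id, r.start, r.end, r.strand) == (
                orig.seq_id, orig.start, orig.end, orig.strand,
            )
            assert r.combined_label == orig.combined_label
            for fam, prob in orig.probabilities.items():
                assert r.probabilities[fam] == pytest.approx(prob, abs=5e-5)


class TestAnnotationsGff:
    def test_round_trip(self, tmp_path):
        anns = [
            io.AnnotationRecord("chr1", 10, 500, "+", "Copia", "a1"),
            io.AnnotationRecord("chr1", 600, 900, "-", "Gypsy", "a2"),
        ]
        io.write_annotations_gff(anns, tmp_path / "a.gff3")
        assert io.read_annotations_gff(tmp_path / "a.gff3") == anns

    def test_unknown_label_rejected(self):
        with pytest.raises(FormatError):
            io.AnnotationRecord("chr1", 0, 10, "+", "LINE")


@pytest.fixture(scope="module")
def trained(hierarchy):
    """A small forest plus fixture candidates for round-trip checks."""
    import numpy as np

    rng = np.random.default_rng(3)
    subs = ["RT_LTR", "rve", "Retrotrans_gag", "RNase_HI_RT_Ty3", "retropepsin_like"]
    examples = []
    for i in range(40):
        label = i % 2 == 0
        hits = []
        pos = 0
        for s in subs[: 3 if label else 5]:
            start = pos + int(rng.integers(10, 50))
            end = start + int(rng.integers(100, 400))
            hits.append(mk_hit(s, start, end, evalue=10.0 ** -rng.integers(5, 40)))
            pos = end
        examples.append(TrainingExample(f"e{i}", tuple(hits), label))
    cfg = RunConfig(n_trees=100, rng_seed=11)
    forest = induce_forest(examples, cfg, hierarchy, seed=11, target="Gypsy")
    fixtures = [TrainingExample(f"f{i}", examples[i].hits, False) for i in range(10)]
    return forest, fixtures


class TestModelRoundTrip:
    def test_one_tree_round_trip(self, tmp_path, hierarchy, trained):
        forest, fixtures = trained
        import dataclasses

        small = dataclasses.replace(forest, trees=forest.trees[:1])
        io.save_model(small, tmp_path / "m.json")
        back = io.load_model(tmp_path / "m.json")
        for c in fixtures:
            assert back.predict_proba(c, hierarchy) == small.predict_proba(c, hierarchy)

    def test_full_forest_round_trip_bit_for_bit(self, tmp_path, hierarchy, trained):
        forest, fixtures = trained
        io.save_model(forest, tmp_path / "m.json")
        back = io.load_model(tmp_path / "m.json")
        assert len(back.trees) == 100
        for c in fixtures:
            assert back.predict_proba(c, hierarchy) == forest.predict_proba(c, hierarchy)

    def test_truncated_file_is_parse_error(self, tmp_path, trained):
        forest, _ = trained
        io.save_model(forest, tmp_path / "m.json")
        data = (tmp_path / "m.json").read_text()
        (tmp_path / "t.json").write_text(data[: len(data) // 2])
        with pytest.raises(FormatError):
            io.load_model(tmp_path / "t.json")

    def test_version_mismatch(self, tmp_path, trained):
        forest, _ = trained
        io.save_model(forest, tmp_path / "m.json")
        payload = json.loads((tmp_path / "m.json").read_text())
        payload["version"] = 99
        (tmp_path / "v.json").write_text(json.dumps(payload))
        with pytest.raises(ModelVersionError):
            io.load_model(tmp_path / "v.json")
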