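"""TSV dialect reading/writing, SSSOM export, lint, and summaries."""

import itertools

import pytest

from biomap import (
    EXACT_MATCH,
    LedgerParseError,
    MappingLedger,
    export_sssom,
    generate_ledger,
    lint_ledger,
    parse_sssom,
    read_ledger_dir,
    summarize_ledger,
    write_ledger_dir,
)
from biomap.ledger_io import LEDGER_FILENAMES
from conftest import ORCID, curated, predicted

FILES = [LEDGER_FILENAMES[c] for c in ("positive", "negative", "unsure", "predicted")]


def write_raw(directory, positive="", negative="", unsure="", predicted=""):
    """Write four raw files with the standard header plus the given body lines."""
    base = (
        "subject_prefix\tsubject_identifier\tsubject_name\tpredicate\t"
        "object_prefix\tobject_identifier\tobject_name\ttype\tsource"
    )
    bodies = {
        "positive.tsv": (base, positive),
        "negative.tsv": (base, negative),
        "unsure.tsv": (base, unsure),
        "predictions.tsv": (base + "\tconfidence", predicted),
    }
    for name, (header, body) in bodies.items():
        text = header + "\n" + (body + "\n" if body else "")
        (directory / name).write_text(text, encoding="utf-8")


CURATED_ROW = "chebi\t138488\talsterpaullone\tskos:exactMatch\tmesh\tC120793\talsterpaullone\tsemapv:ManualMappingCuration\torcid:" + ORCID
CURATED_ROW2 = "chebi\t27732\tcaffeine\tskos:exactMatch\tmesh\tD002110\tCaffeine\tsemapv:ManualMappingCuration\torcid:" + ORCID
PREDICTED_ROW = "dis\t7\tdengue\tskos:exactMatch\tenz\t9\tdengue fever\tsemapv:LexicalMatching\tbiomap-lexical\t0.9"


class TestReadLedger:
    def test_toy_positive_file(self, tmp_path):
        write_raw(tmp_path, positive=CURATED_ROW + "\n" + CURATED_ROW2)
        ledger = read_ledger_dir(tmp_path)
        assert len(ledger.positive) == 2
        assert ledger.sizes()["predicted"] == 0

    def test_provenance_parsed(self, tmp_path):
        write_raw(tmp_path, positive=CURATED_ROW, predicted=PREDICTED_ROW)
        ledger = read_ledger_dir(tmp_path)
        (pos,) = ledger.positive.values()
        assert pos.provenance.curator_orcid == ORCID
        (pred,) = ledger.predicted.values()
        assert pred.provenance.confidence == 0.9
        assert pred.provenance.method == "lexical"

    def test_tolerant_header_dialect(self, tmp_path):
        """source_*/target_*/relation headers resolve to the same columns."""
        header = (
            "source prefix\tsource identifier\tsource name\trelation\t"
            "target prefix\ttarget identifier\ttarget name\ttype\tsource"
        )
        write_raw(tmp_path)
        (tmp_path / "positive.tsv").write_text(
            header + "\n" + CURATED_ROW + "\n", encoding="utf-8"
        )
        ledger = read_ledger_dir(tmp_path)
        (key,) = ledger.positive.keys()
        assert key == ("chebi:138488", EXACT_MATCH, "mesh:C120793")

    def test_wrong_field_count_names_file_and_line(self, tmp_path):
        write_raw(tmp_path, positive=CURATED_ROW + "\nchebi\t1\tx")
        with pytest.raises(LedgerParseError, match=r"positive\.tsv:3"):
            read_ledger_dir(tmp_path)

    def test_confidence_outside_unit_interval_rejected(self, tmp_path):
        write_raw(tmp_path, predicted=PREDICTED_ROW.rsplit("\t", 1)[0] + "\t1.2")
        with pytest.raises(LedgerParseError, match="confidence"):
            read_ledger_dir(tmp_path)

    def test_duplicate_key_within_file_lists_both_lines(self, tmp_path):
        write_raw(tmp_path, positive=CURATED_ROW + "\n" + CURATED_ROW)
        with pytest.raises(LedgerParseError, match="line 2"):
            read_ledger_dir(tmp_path)

    def test_mirrored_duplicate_detected_via_canonicalization(self, tmp_path):
        row = "\t".join(
            ["mesh", "C120793", "alsterpaullone", "skos:exactMatch",
             "chebi", "138488", "alsterpaullone", "semapv:ManualMappingCuration", "orcid:" + ORCID]
        )
        write_raw(tmp_path, positive=CURATED_ROW + "\n" + row)
        with pytest.raises(LedgerParseError, match="duplicate"):
            read_ledger_dir(tmp_path)


class TestWriteLedger:
    def test_round_trip_preserves_key_sets(self, tmp_path):
        ledger = generate_ledger(30, 8, 3, 40, seed=5)
        write_ledger_dir(ledger, tmp_path)
        again = read_ledger_dir(tmp_path)
        for name in ("positive", "negative", "unsure", "predicted"):
            assert set(ledger.collection(name)) == set(again.collection(name))

    def test_write_read_write_is_byte_identical(self, tmp_path):
        ledger = generate_ledger(30, 8, 3, 40, seed=6)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_ledger_dir(ledger, d1)
        write_ledger_dir(read_ledger_dir(d1), d2)
        for name in FILES:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_insertion_order_does_not_affect_bytes(self, tmp_path):
        mappings = [curated(f"aa:{i}", f"bb:{i}") for i in range(6)]
        outs = []
        for i, order in enumerate(itertools.islice(itertools.permutations(mappings), 3)):
            ledger = MappingLedger()
            for m in order:
                ledger.add(m, "positive")
            out = tmp_path / str(i)
            write_ledger_dir(ledger, out)
            outs.append((out / "positive.tsv").read_bytes())
        assert outs[0] == outs[1] == outs[2]

    def test_empty_ledger_writes_header_only_files(self, tmp_path):
        write_ledger_dir(MappingLedger(), tmp_path)
        for name in FILES:
            lines = (tmp_path / name).read_text(encoding="utf-8").splitlines()
            assert len(lines) == 1
            assert lines[0].startswith("subject_prefix\t")


class TestSssom:
    CURIE_MAP = {p: f"https://example.org/{p}/" for p in
                 ("alpha", "bravo", "chem", "dis", "enz", "aa", "bb")}

    def test_row_count_and_distinct_justifications(self):
        ledger = MappingLedger()
        ledger.add(curated("aa:1", "bb:1"), "positive")
        ledger.add(predicted("aa:2", "bb:2"), "predicted")
        rows = parse_sssom(export_sssom(ledger, self.CURIE_MAP))
        assert len(rows) == 2
        justifications = {r["mapping_justification"] for r in rows}
        assert justifications == {"semapv:ManualMappingCuration", "semapv:LexicalMatching"}

    def test_curated_rows_carry_curator_orcid(self):
        ledger = MappingLedger()
        ledger.add(curated("aa:1", "bb:1"), "positive")
        (row,) = parse_sssom(export_sssom(ledger, self.CURIE_MAP))
        assert row["author_id"] == f"orcid:{ORCID}"

    def test_negative_rows_flagged_not_dropped(self):
        ledger = MappingLedger()
        ledger.add(curated("aa:1", "bb:1", verdict="negative"), "negative")
        ledger.add(curated("aa:2", "bb:2"), "positive")
        rows = parse_sssom(export_sssom(ledger, self.CURIE_MAP))
        modifiers = {r["subject_id"]: r["predicate_modifier"] for r in rows}
        assert modifiers == {"aa:1": "Not", "aa:2": ""}

    def test_full_ledger_reimports_to_identical_key_set(self):
        ledger = generate_ledger(25, 5, 2, 30, seed=7)
        rows = parse_sssom(export_sssom(ledger, self.CURIE_MAP))
        assert len(rows) == len(ledger)
        keys = {(r["subject_id"], r["predicate_id"], r["object_id"]) for r in rows}
        assert keys == ledger.all_keys()

    def test_missing_prefix_raises_naming_it(self):
        ledger = MappingLedger()
        ledger.add(curated("zz:1", "bb:1"), "positive")
        with pytest.raises(KeyError, match="zz"):
            export_sssom(ledger, self.CURIE_MAP)

    def test_header_block_carries_curie_map_and_license(self):
        ledger = MappingLedger()
        ledger.add(curated("aa:1", "bb:1"), "positive")
        doc = export_sssom(ledger, self.CURIE_MAP)
        header = [line for line in doc.splitlines() if line.startswith("#")]
        assert any("license" in line for line in header)
        assert any("aa: https://example.org/aa/" in line for line in header)


class TestLint:
    def test_compliant_ledger_is_clean(self, registry):
        ledger = generate_ledger(20, 5, 2, 20, seed=8)
        assert lint_ledger(ledger, registry) == []

    def test_identifier_failing_pattern(self, registry):
        ledger = MappingLedger()
        ledger.add(curated("chebi:138488", "mesh:c120793"), "positive")
        violations = lint_ledger(ledger, registry)
        assert [v.kind for v in violations] == ["pattern_mismatch"]
        assert "c120793" in violations[0].message

    def test_unknown_prefix_reported(self, registry):
        ledger = MappingLedger()
        ledger.add(curated("nope:1", "chebi:2"), "positive")
        assert [v.kind for v in lint_ledger(ledger, registry)] == ["unknown_prefix"]

    def test_cross_file_duplicate_reported_not_raised(self, tmp_path, registry):
        write_raw(tmp_path, positive=CURATED_ROW, negative=CURATED_ROW)
        ledger = read_ledger_dir(tmp_path)
        violations = [v for v in lint_ledger(ledger, registry) if v.kind == "cross_file_duplicate"]
        assert len(violations) == 1
        assert "positive" in violations[0].message and "negative" in violations[0].message


class TestSummarize:
    def test_worked_example(self):
        ledger = MappingLedger()
        ledger.add(curated("mesh:D1", "chebi:1"), "positive")
        ledger.add(curated("mesh:D2", "chebi:2"), "positive")
        ledger.add(curated("mesh:D3", "chebi:3", verdict="negative"), "negative")
        summary = summarize_ledger(ledger)
        assert summary.collections["positive"] == 2
        assert summary.collections["negative"] == 1
        assert summary.prefix_pairs[("chebi", "mesh")] == 3
        assert summary.curators[ORCID] == 3
        assert summary.predicates[EXACT_MATCH] == 3

    def test_empty_ledger_all_zero(self):
        summary = summarize_ledger(MappingLedger())
        assert summary.collections == {"positive": 0, "negative": 0, "unsure": 0, "predicted": 0}
        assert summary.prefix_pairs == {} and summary.curators == {}

    def test_prefix_pair_counts_partition_each_collection(self):
        ledger = generate_ledger(40, 10, 4, 60, seed=9)
        summary = summarize_ledger(ledger)
        for name, size in ledger.sizes().items():
            assert sum(summary.prefix_pairs_by_collection[name].values()) == size
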