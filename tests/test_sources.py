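"""Source-dialect parsing: filters, type deduction, direction expansion."""

import gzip

import pytest

from skelenet.model import Direction, InteractionType, SourceDB
from skelenet.sources import (
    BIOGRID_COLUMNS,
    PPAXE_COLUMNS,
    STRING_ACTIONS_COLUMNS,
    STRING_LINKS_COLUMNS,
    parse_biogrid,
    parse_ppaxe,
    parse_string,
)


def write_tsv(path, columns, rows):
    path.write_text("\n".join(["\t".join(columns)] + ["\t".join(r) for r in rows]) + "\n")
    return path


def biogrid_file(tmp_path, rows, name="biogrid.tsv"):
    return write_tsv(tmp_path / name, BIOGRID_COLUMNS, rows)


class TestBiogrid:
    def test_physical_experiment_yields_both_directions(self, tmp_path):
        """An undirected FRET row is a physical interaction, assumed bidirectional."""
        path = biogrid_file(tmp_path, [["G1", "G2", "9606", "9606", "-", "FRET", "unknown"]])
        edges, report = parse_biogrid(path)
        assert [(e.src, e.dst, e.itype) for e in edges] == [
            ("G1", "G2", InteractionType.PHYSICAL),
            ("G2", "G1", InteractionType.PHYSICAL),
        ]
        assert report.kept == 1
        assert all(ev.detail == "FRET" for e in edges for ev in e.evidences)

    def test_genetic_experiment_is_unidirectional(self, tmp_path):
        path = biogrid_file(
            tmp_path, [["G1", "G2", "9606", "9606", "-", "dosage lethality", "unknown"]]
        )
        edges, _ = parse_biogrid(path)
        assert [(e.src, e.dst, e.itype) for e in edges] == [
            ("G1", "G2", InteractionType.GENETIC)
        ]

    def test_cross_species_rows_dropped(self, tmp_path):
        path = biogrid_file(
            tmp_path, [["G1", "G2", "9606", "10090", "physical", "two hybrid", "unknown"]]
        )
        edges, report = parse_biogrid(path)
        assert edges == []
        assert report.dropped_taxid == 1

    def test_explicit_label_overrides_experiment(self, tmp_path):
        path = biogrid_file(
            tmp_path, [["G1", "G2", "9606", "9606", "genetic", "two hybrid", "unknown"]]
        )
        edges, _ = parse_biogrid(path)
        assert len(edges) == 1 and edges[0].itype is InteractionType.GENETIC

    def test_unmapped_experiment_system_stays_unknown(self, tmp_path):
        path = biogrid_file(
            tmp_path, [["G1", "G2", "9606", "9606", "-", "mystery assay", "unknown"]]
        )
        edges, _ = parse_biogrid(path)
        assert {e.itype for e in edges} == {InteractionType.UNKNOWN}
        assert len(edges) == 2  # untyped rows expand like physical ones

    def test_directed_physical_row_single_edge(self, tmp_path):
        path = biogrid_file(
            tmp_path, [["G1", "G2", "9606", "9606", "physical", "two hybrid", "b_to_a"]]
        )
        edges, _ = parse_biogrid(path)
        assert [(e.src, e.dst) for e in edges] == [("G2", "G1")]

    def test_malformed_row_skipped_and_counted(self, tmp_path):
        path = biogrid_file(
            tmp_path,
            [
                ["G1", "G2", "not-a-taxid", "9606", "-", "FRET", "unknown"],
                ["G1", "G2", "9606", "9606", "-", "FRET", "unknown", "extra-col"],
                ["G3", "G4", "9606", "9606", "-", "FRET", "unknown"],
            ],
        )
        edges, report = parse_biogrid(path)
        assert report.malformed == 2
        assert {(e.src, e.dst) for e in edges} == {("G3", "G4"), ("G4", "G3")}

    def test_unreadable_file_is_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nosuch"):
            parse_biogrid(tmp_path / "nosuch.tsv")

    def test_gzip_transparent(self, tmp_path):
        content = "\t".join(BIOGRID_COLUMNS) + "\nG1\tG2\t9606\t9606\t-\tFRET\tunknown\n"
        path = tmp_path / "biogrid.tsv.gz"
        with gzip.open(path, "wt") as handle:
            handle.write(content)
        edges, _ = parse_biogrid(path)
        assert len(edges) == 2


def string_files(tmp_path, link_rows, action_rows=None):
    links = write_tsv(tmp_path / "links.tsv", STRING_LINKS_COLUMNS, link_rows)
    actions = None
    if action_rows is not None:
        actions = write_tsv(tmp_path / "actions.tsv", STRING_ACTIONS_COLUMNS, action_rows)
    return links, actions


class TestString:
    def test_evidence_backed_pair_kept_bidirectional(self, tmp_path):
        links, _ = string_files(tmp_path, [["G1", "G2", "9606", "9606", "0", "0", "210", "0", "500"]])
        edges, _ = parse_string(links)
        assert {(e.src, e.dst) for e in edges} == {("G1", "G2"), ("G2", "G1")}
        assert {e.itype for e in edges} == {InteractionType.PHYSICAL}

    def test_prediction_only_pair_dropped(self, tmp_path):
        links, _ = string_files(tmp_path, [["G1", "G2", "9606", "9606", "0", "0", "0", "0", "900"]])
        edges, report = parse_string(links)
        assert edges == []
        assert report.dropped_score == 1

    def test_direction_tag_orients_single_edge(self, tmp_path):
        links, actions = string_files(
            tmp_path,
            [["G1", "G2", "9606", "9606", "0", "0", "150", "0", "0"]],
            [["G1", "G2", "a_to_b"]],
        )
        edges, _ = parse_string(links, actions)
        assert [(e.src, e.dst) for e in edges] == [("G1", "G2")]

    def test_orphan_action_ignored(self, tmp_path):
        links, actions = string_files(
            tmp_path,
            [["G1", "G2", "9606", "9606", "0", "0", "150", "0", "0"]],
            [["G9", "G8", "a_to_b"]],
        )
        edges, report = parse_string(links, actions)
        assert len(edges) == 2
        assert report.notes  # orphan logged

    def test_evidence_carries_qualifying_channels(self, tmp_path):
        links, _ = string_files(tmp_path, [["G1", "G2", "9606", "9606", "0", "0", "210", "400", "500"]])
        edges, _ = parse_string(links)
        details = {(ev.detail, ev.score) for ev in edges[0].evidences}
        assert details == {("experimental", 210.0), ("database", 400.0)}

    def test_configurable_channel_set(self, tmp_path):
        links, _ = string_files(tmp_path, [["G1", "G2", "9606", "9606", "0", "0", "0", "0", "900"]])
        edges, _ = parse_string(links, evidence_channels=frozenset({"textmining"}))
        assert len(edges) == 2

    def test_non_human_pairs_dropped(self, tmp_path):
        links, _ = string_files(tmp_path, [["G1", "G2", "10090", "10090", "0", "0", "210", "0", "0"]])
        edges, report = parse_string(links)
        assert edges == [] and report.dropped_taxid == 1


def ppaxe_file(tmp_path, rows):
    return write_tsv(tmp_path / "ppaxe.tsv", PPAXE_COLUMNS, rows)


class TestPpaxe:
    def test_passing_record_bidirectional_unknown_with_pmid(self, tmp_path):
        path = ppaxe_file(tmp_path, [["G1", "G2", "0.95", "123"]])
        edges, _ = parse_ppaxe(path, 0.5, {"G1", "G2"})
        assert {(e.src, e.dst, e.itype) for e in edges} == {
            ("G1", "G2", InteractionType.UNKNOWN),
            ("G2", "G1", InteractionType.UNKNOWN),
        }
        assert all(ev.reference == "123" and ev.source_db is SourceDB.PPAXE
                   for e in edges for ev in e.evidences)

    def test_non_nomenclature_symbol_dropped(self, tmp_path):
        path = ppaxe_file(tmp_path, [["G1", "XYZZY", "0.95", "123"]])
        edges, report = parse_ppaxe(path, 0.5, {"G1", "G2"})
        assert edges == [] and report.dropped_symbol == 1

    def test_below_threshold_dropped(self, tmp_path):
        path = ppaxe_file(tmp_path, [["G1", "G2", "0.30", "123"]])
        edges, report = parse_ppaxe(path, 0.5, {"G1", "G2"})
        assert edges == [] and report.dropped_score == 1

    def test_alias_spelling_resolves_before_symbol_filter(self, tmp_path):
        from skelenet.identifiers import AliasTable

        table = AliasTable(canonical={"TP53", "G2"}, alias_to_canonical={"p53": "TP53"})
        path = ppaxe_file(tmp_path, [["p53", "G2", "0.9", "7"]])
        edges, _ = parse_ppaxe(path, 0.5, table.canonical, alias_table=table)
        assert len(edges) == 2  # emitted with the original spelling, kept

    def test_missing_pmid_leaves_reference_empty(self, tmp_path):
        path = ppaxe_file(tmp_path, [["G1", "G2", "0.9", ""]])
        edges, _ = parse_ppaxe(path, 0.5, {"G1", "G2"})
        assert edges[0].evidences[0].reference is None

    def test_threshold_domain_checked(self, tmp_path):
        path = ppaxe_file(tmp_path, [["G1", "G2", "0.9", "1"]])
        with pytest.raises(ValueError):
            parse_ppaxe(path, 1.5, {"G1", "G2"})


def test_directed_undirected_edge_accounting(fixture_dataset):
    """Total emitted edges = 2 x undirected kept + 1 x directed kept."""
    out, manifest, table = fixture_dataset
    e1, _ = parse_biogrid(out / "biogrid.tsv")
    e2, _ = parse_string(out / "string_links.tsv", out / "string_actions.tsv")
    e3, _ = parse_ppaxe(out / "ppaxe.tsv", manifest["ppaxe_threshold"],
                        table.canonical, alias_table=table)
    total = len(e1) + len(e2) + len(e3)
    assert total == 2 * manifest["n_undirected_kept"] + manifest["n_directed_kept"]


def test_parsing_is_deterministic(fixture_dataset):
    out, _, _ = fixture_dataset
    first, _ = parse_biogrid(out / "biogrid.tsv")
    second, _ = parse_biogrid(out / "biogrid.tsv")
    assert [(e.src, e.dst, e.itype) for e in first] == [
        (e.src, e.dst, e.itype) for e in second
    ]
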