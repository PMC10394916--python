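import math

import pytest

from rlcomplex import (
    ComplexCollection,
    ValueTable,
    WeightedNetwork,
    load_value_table,
    preprocess_complexes,
    read_complexes,
    read_network,
    save_value_table,
)
from rlcomplex.network_io import (
    NetworkParseError,
    read_predictions,
    write_complexes,
    write_network,
    write_predictions,
)
from rlcomplex.prediction import CandidateComplex


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadNetwork:
    def test_basic_parse(self, tmp_path):
        net = read_network(write(tmp_path, "n.tsv", "A B 0.8\nB C 0.9\n"))
        assert net.n_nodes == 3
        assert net.n_edges == 2
        assert net.weight("A", "B") == 0.8
        assert net.neighbors("B") == {"A", "C"}

    def test_self_loop_dropped_but_node_kept(self, tmp_path, caplog):
        with caplog.at_level("WARNING"):
            net = read_network(write(tmp_path, "n.tsv", "A A 0.5\n"))
        assert net.n_nodes == 1
        assert net.n_edges == 0
        assert "self-loop" in caplog.text

    def test_duplicate_edges_keep_max(self, tmp_path):
        net = read_network(write(tmp_path, "n.tsv", "A B 0.3\nB A 0.7\n"))
        assert net.n_edges == 1
        assert net.weight("A", "B") == 0.7

    def test_comments_and_tabs(self, tmp_path):
        net = read_network(
            write(tmp_path, "n.tsv", "# header\nA\tB\t0.5\n\nC D 0.25\n")
        )
        assert net.n_edges == 2

    @pytest.mark.parametrize(
        "content", ["A B\n", "A B zero\n", "A B 0\n", "A B -0.5\n"]
    )
    def test_malformed_lines_raise_with_line_number(self, tmp_path, content):
        path = write(tmp_path, "bad.tsv", "A B 0.5\n" + content)
        with pytest.raises(NetworkParseError, match=":2"):
            read_network(path)

    def test_round_trip(self, tmp_path):
        net = read_network(write(tmp_path, "n.tsv", "A B 0.8\nB C 0.125\nA C 0.333\n"))
        out = tmp_path / "out.tsv"
        write_network(net, out)
        again = read_network(out)
        assert again.nodes == net.nodes
        assert sorted((min(u, v), max(u, v), w) for u, v, w in again.edges()) == \
            sorted((min(u, v), max(u, v), w) for u, v, w in net.edges())


class TestReadComplexes:
    def test_basic(self, tmp_path):
        col = read_complexes(write(tmp_path, "c.txt", "A B C\nD E F G\n"))
        assert len(col) == 2
        assert [len(m) for _, m in col] == [3, 4]
        assert col.names == ["Cx1", "Cx2"]

    def test_dedupe_members(self, tmp_path):
        col = read_complexes(write(tmp_path, "c.txt", "A A B\n"))
        assert col[0][1] == frozenset({"A", "B"})

    def test_seven_lines(self, tmp_path):
        text = "".join(f"P{i}a P{i}b P{i}c\n" for i in range(7))
        assert len(read_complexes(write(tmp_path, "c.txt", text))) == 7

    def test_blank_lines_skipped_with_warning(self, tmp_path, caplog):
        with caplog.at_level("WARNING"):
            col = read_complexes(write(tmp_path, "c.txt", "A B\n\nC D\n"))
        assert len(col) == 2
        assert "blank" in caplog.text

    def test_empty_file_errors(self, tmp_path):
        with pytest.raises(NetworkParseError):
            read_complexes(write(tmp_path, "c.txt", ""))

    def test_order_preserved(self, tmp_path):
        col = read_complexes(write(tmp_path, "c.txt", "X Y Z\nA B C\n"))
        assert col[0][1] == frozenset({"X", "Y", "Z"})


@pytest.fixture
def preprocess_net():
    return WeightedNetwork.from_edges(
        [
            ("A", "B", 0.5),
            ("B", "C", 0.5),
            ("1", "2", 0.5),
            ("2", "3", 0.5),
            ("3", "4", 0.5),
            ("4", "1", 0.5),
            ("X", "Y", 0.5),
        ]
    )


class TestPreprocessComplexes:
    def test_small_complex_dropped(self, preprocess_net):
        col = ComplexCollection.from_member_sets([{"A", "B"}, {"A", "B", "C"}])
        out = preprocess_complexes(col, preprocess_net)
        assert out.member_sets == [frozenset({"A", "B", "C"})]

    def test_disconnected_complex_dropped(self, preprocess_net):
        col = ComplexCollection.from_member_sets([{"A", "B", "X"}])
        assert len(preprocess_complexes(col, preprocess_net)) == 0

    def test_jaccard_merge(self, preprocess_net):
        col = ComplexCollection.from_member_sets(
            [{"1", "2", "3"}, {"1", "2", "3", "4"}]
        )
        out = preprocess_complexes(col, preprocess_net)
        assert out.member_sets == [frozenset({"1", "2", "3", "4"})]

    def test_members_absent_from_network_removed_first(self, preprocess_net):
        col = ComplexCollection.from_member_sets([{"A", "B", "C", "ZZZ"}])
        out = preprocess_complexes(col, preprocess_net)
        assert out.member_sets == [frozenset({"A", "B", "C"})]

    def test_idempotent(self, preprocess_net):
        col = ComplexCollection.from_member_sets(
            [{"1", "2", "3"}, {"1", "2", "3", "4"}, {"A", "B", "C"}]
        )
        once = preprocess_complexes(col, preprocess_net)
        twice = preprocess_complexes(once, preprocess_net)
        assert once.member_sets == twice.member_sets

    def test_no_over_threshold_pair_survives(self, preprocess_net):
        col = ComplexCollection.from_member_sets(
            [{"1", "2", "3"}, {"2", "3", "4"}, {"1", "2", "3", "4"}]
        )
        out = preprocess_complexes(col, preprocess_net)
        sets = out.member_sets
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                inter = len(sets[i] & sets[j])
                union = len(sets[i] | sets[j])
                assert inter / union <= 0.6

    def test_empty_network_errors(self):
        with pytest.raises(ValueError):
            preprocess_complexes(
                ComplexCollection.from_member_sets([{"A"}]), WeightedNetwork()
            )


class TestValueTablePersistence:
    def test_round_trip_bit_identical(self, tmp_path):
        table = ValueTable()
        table.values[3] = 0.1 + 0.2  # deliberately non-representable sum
        table.values[19] = 1.0 / 3.0
        path = tmp_path / "vt.json"
        save_value_table(table, path)
        loaded = load_value_table(path)
        assert loaded.equals(table)
        assert list(loaded.bin_edges) == list(table.bin_edges)

    def test_fresh_table_round_trips_all_zero(self, tmp_path):
        path = tmp_path / "vt.json"
        save_value_table(ValueTable(), path)
        loaded = load_value_table(path)
        assert all(v == 0.0 for v in loaded.values)

    def test_bin_count_mismatch_errors(self, tmp_path):
        path = tmp_path / "vt.json"
        save_value_table(ValueTable(n_bins=19), path)
        with pytest.raises(NetworkParseError, match="19"):
            load_value_table(path, expect_n_bins=20)

    def test_version_mismatch_errors(self, tmp_path):
        path = tmp_path / "vt.json"
        save_value_table(ValueTable(), path)
        data = path.read_text().replace('"format_version": 1', '"format_version": 99')
        path.write_text(data)
        with pytest.raises(NetworkParseError, match="version"):
            load_value_table(path)

    def test_missing_field_errors(self, tmp_path):
        path = tmp_path / "vt.json"
        save_value_table(ValueTable(), path)
        data = path.read_text().replace('"gamma": 0.5,', "")
        path.write_text(data)
        with pytest.raises(NetworkParseError, match="gamma"):
            load_value_table(path)


class TestPredictionsIO:
    def test_round_trip(self, tmp_path):
        cands = [
            CandidateComplex(frozenset({"A", "B", "C"}), 0.35, ("A", "B"), ("C",)),
            CandidateComplex(frozenset({"X", "Y"}), 1.0 / 7.0, ("X", "Y"), ()),
        ]
        path = tmp_path / "preds.txt"
        write_predictions(cands, path)
        loaded = read_predictions(path)
        assert loaded == [(c.members, c.score) for c in cands]

    def test_score_column_is_last(self, tmp_path):
        path = tmp_path / "preds.txt"
        write_predictions(
            [CandidateComplex(frozenset({"B", "A"}), 0.25, ("A", "B"), ())], path
        )
        assert path.read_text().split() == ["A", "B", "0.25"]
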