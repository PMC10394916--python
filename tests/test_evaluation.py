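import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rlcomplex import ComplexCollection, evaluate_all
from rlcomplex.evaluation import (
    cmmf,
    f_similarity,
    filter_to_known_nodes,
    fmmf,
    kclique_fscores,
    qi_fscore,
    spa_unspa,
)

from oracles import (
    brute_force_cmmf,
    brute_force_fmmf,
    brute_force_spa_unspa,
    fsim,
)


def collection(*sets):
    return ComplexCollection.from_member_sets([frozenset(s) for s in sets])


class TestFilterToKnownNodes:
    def test_reduced_below_min_size_dropped(self):
        known = collection({"A", "B", "C", "D", "E", "F"})
        assert filter_to_known_nodes([{"A", "B", "Z"}], known) == []

    def test_subset_of_universe_unchanged(self):
        known = collection({"A", "B", "C"})
        assert filter_to_known_nodes([{"A", "B", "C"}], known) == [
            frozenset({"A", "B", "C"})
        ]

    def test_partial_reduction_retained(self):
        known = collection({"A", "B", "C", "D"})
        assert filter_to_known_nodes([{"A", "B", "C", "Z"}], known) == [
            frozenset({"A", "B", "C"})
        ]


class TestFSimilarity:
    def test_identical(self):
        assert f_similarity({"A", "B"}, {"A", "B"}) == 1.0

    def test_hand_value(self):
        assert f_similarity({"A", "B", "C"}, {"A", "B", "C", "E"}) == pytest.approx(6 / 7)

    def test_disjoint(self):
        assert f_similarity({"A"}, {"B"}) == 0.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            f_similarity(set(), {"A"})


class TestFMMF:
    def test_perfect(self):
        col = collection({"A", "B", "C"})
        assert fmmf([{"A", "B", "C"}], col) == (1.0, 1.0, 1.0)

    def test_single_pair_hand_value(self):
        p, r, f = fmmf([{"A", "B", "C"}], collection({"A", "B", "C", "E"}))
        assert (p, r, f) == pytest.approx((6 / 7, 6 / 7, 6 / 7))

    def test_extra_unmatched_prediction(self):
        known = collection({"A", "B", "C", "E"})
        p, r, f = fmmf([{"A", "B", "C"}, {"X", "Y", "Z"}], known)
        assert p == pytest.approx(3 / 7)
        assert r == pytest.approx(6 / 7)
        assert f == pytest.approx(4 / 7)

    def test_empty_side_errors(self):
        with pytest.raises(ValueError):
            fmmf([], collection({"A", "B"}))

    @settings(max_examples=40, deadline=None)
    @given(data=st.data())
    def test_matches_brute_force_up_to_4x4(self, data):
        universe = [f"g{i}" for i in range(8)]
        def side(name):
            n = data.draw(st.integers(1, 4), label=name)
            return [
                set(data.draw(
                    st.sets(st.sampled_from(universe), min_size=1, max_size=5),
                    label=f"{name}{i}",
                ))
                for i in range(n)
            ]
        predicted = side("p")
        known = side("k")
        expected = brute_force_fmmf(predicted, known)
        got = fmmf(predicted, collection(*known))
        assert got == pytest.approx(expected, abs=1e-12)


class TestCMMF:
    def test_perfect(self):
        assert cmmf([{"A", "B"}], collection({"A", "B"})) == 1.0

    def test_hand_value(self):
        assert cmmf([{"A", "B", "C"}], collection({"A", "B", "C", "E"})) == pytest.approx(6 / 7)

    def test_unmatched_prediction_halves_precision_side(self):
        known = collection({"A", "B", "C"})
        predicted = [{"A", "B", "C"}, {"X", "Y", "Z"}]
        got = cmmf(predicted, known)
        assert got == pytest.approx(brute_force_cmmf(predicted, [{"A", "B", "C"}]))
        # precision side is 0.5, recall side 1.0 -> harmonic 2/3
        assert got == pytest.approx(2 / 3)


class TestSPA:
    def test_perfect_disjoint(self):
        known = collection({"A", "B"}, {"C", "D"})
        spa, unspa = spa_unspa([{"A", "B"}, {"C", "D"}], known)
        assert spa == 1.0
        assert unspa == 1.0

    def test_hand_value(self):
        spa, unspa = spa_unspa([{"A", "B"}], collection({"A", "B", "C"}))
        assert spa == pytest.approx(math.sqrt(2 / 3))
        assert unspa == pytest.approx(math.sqrt(2 / 3))

    def test_overlapping_prediction_matches_brute_force(self):
        known = [{"A", "B", "C"}, {"C", "D", "E"}]
        predicted = [{"A", "B", "C", "D", "E"}]
        got = spa_unspa(predicted, collection(*known))
        expected = brute_force_spa_unspa(predicted, known)
        assert got == pytest.approx(expected)
        assert got[0] < 1.0  # PPV penalizes the straddling prediction


class TestQiFscore:
    def test_perfect(self):
        assert qi_fscore([{"A", "B", "C"}], collection({"A", "B", "C"})) == 1.0

    def test_hand_ratios(self):
        got = qi_fscore([{"A", "B", "C"}], collection({"A", "B", "C", "E"}), tau=0.25)
        assert got == 1.0

    def test_no_match_above_tau(self):
        got = qi_fscore([{"A", "B", "C", "D"}], collection({"A", "X", "Y", "Z"}), tau=0.25)
        assert got == 0.0


class TestKClique:
    def test_perfect(self):
        col = collection({"A", "B", "C"}, {"D", "E", "F", "G"})
        assert kclique_fscores([{"A", "B", "C"}, {"D", "E", "F", "G"}], col) == (1.0, 1.0)

    def test_hand_counts(self):
        f_grand, f_weighted = kclique_fscores(
            [{"A", "B", "C"}], collection({"A", "B", "C", "E"}), k_max=3
        )
        f2 = 2 / 3  # harmonic(3/3, 3/6)
        f3 = 0.4    # harmonic(1/1, 1/4)
        assert f_grand == pytest.approx((f2 + f3) / 2)
        assert f_weighted == pytest.approx((6 * f2 + 4 * f3) / 10)

    def test_no_shared_pairs(self):
        got = kclique_fscores([{"A", "B", "C"}], collection({"X", "Y", "Z"}))
        assert got == (0.0, 0.0)

    def test_size_cap_warns_and_excludes(self, caplog):
        big = {f"n{i}" for i in range(25)}
        with caplog.at_level("WARNING"):
            kclique_fscores([big], collection({"n0", "n1", "n2"}), size_cap=20)
        assert "size cap" in caplog.text


class TestEvaluateAll:
    def test_perfect_prediction_all_ones(self):
        sets = [{"A", "B", "C"}, {"D", "E", "F", "G"}]
        report = evaluate_all(sets, collection(*sets))
        assert all(v == 1.0 for v in report.as_dict().values())

    def test_all_filtered_reports_zeros(self, caplog):
        known = collection({"A", "B", "C", "D", "E", "F"})
        with caplog.at_level("WARNING"):
            report = evaluate_all([{"X", "Y", "Z"}], known)
        assert all(v == 0.0 for v in report.as_dict().values())
        assert "zeros" in caplog.text

    def test_fixture_matches_brute_force(self):
        predicted = [{"A", "B", "C"}, {"C", "D", "E", "F"}, {"G", "H", "I"}]
        known = [{"A", "B", "C", "D"}, {"E", "F", "G", "H", "I"}]
        report = evaluate_all(predicted, collection(*known))
        bf_p, bf_r, bf_f = brute_force_fmmf(predicted, known)
        assert report.fmm_precision == pytest.approx(bf_p)
        assert report.fmm_recall == pytest.approx(bf_r)
        assert report.fmm_fscore == pytest.approx(bf_f)
        assert report.cmmf == pytest.approx(brute_force_cmmf(predicted, known))
        bf_spa, bf_unspa = brute_force_spa_unspa(predicted, known)
        assert report.spa == pytest.approx(bf_spa)
        assert report.unspa == pytest.approx(bf_unspa)

    def test_metrics_invariant_to_collection_order(self):
        predicted = [{"A", "B", "C"}, {"D", "E", "F"}]
        known = [{"A", "B", "C"}, {"D", "E", "X"}, {"A", "E", "F"}]
        r1 = evaluate_all(predicted, collection(*known))
        r2 = evaluate_all(predicted[::-1], collection(*known[::-1]))
        assert r1.as_dict() == pytest.approx(r2.as_dict())

    def test_every_metric_in_unit_interval(self, fig5_run):
        net, known, _, table, _ = fig5_run
        from rlcomplex import predict_all

        report = evaluate_all(
            [c.members for c in predict_all(net, table)], known
        )
        for name, value in report.as_dict().items():
            assert 0.0 <= value <= 1.0, name

    def test_harmonic_mean_lies_between_components(self):
        predicted = [{"A", "B", "C"}, {"X", "Y", "Z"}]
        known = [{"A", "B", "C", "D"}]
        report = evaluate_all(predicted, collection(*known))
        lo = min(report.fmm_precision, report.fmm_recall)
        hi = max(report.fmm_precision, report.fmm_recall)
        assert lo - 1e-12 <= report.fmm_fscore <= hi + 1e-12
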