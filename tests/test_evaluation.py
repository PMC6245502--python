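"""Ground-truth assignment thresholds and the demultiplexing metrics."""

import numpy as np
import pytest

from squigglebin import evaluation as ev
from squigglebin.classifier import ReadCall
from squigglebin.signal_io import PafRecord, QualityRecord


def _paf(rid, rlen, tid, alen):
    return PafRecord(rid, rlen, tid, alen)


class TestGroundTruth:
    def test_primary_above_threshold(self):
        # read 2000 bp: threshold min(100, 200) = 100; 150 passes
        t = ev.assign_ground_truth([_paf("r", 2000, "A", 150)])
        assert t[0].label == "A"

    def test_short_primary_is_unknown(self):
        # read 500 bp: threshold min(100, 50) = 50; 40 fails
        t = ev.assign_ground_truth([_paf("r", 500, "A", 40)])
        assert t[0].label == ev.UNKNOWN

    def test_secondary_reference_makes_chimera(self):
        # read 1000 bp: secondary threshold max(50, 50) = 50; 60 to B trips it
        t = ev.assign_ground_truth([_paf("r", 1000, "A", 800),
                                    _paf("r", 1000, "B", 60)])
        assert t[0].label == ev.CHIMERA

    def test_same_reference_secondary_is_not_chimera(self):
        t = ev.assign_ground_truth([_paf("r", 1000, "A", 800),
                                    _paf("r", 1000, "A", 300)])
        assert t[0].label == "A"

    def test_unaligned_read_defaults_to_unknown(self):
        t = ev.truth_from_paf_for_reads([_paf("a", 1000, "A", 500)], ["a", "b"])
        assert t[1].label == ev.UNKNOWN

    def test_pure_function(self):
        recs = [_paf("r", 1000, "A", 800), _paf("r", 1000, "B", 60)]
        assert ev.assign_ground_truth(recs)[0].label == \
            ev.assign_ground_truth(recs)[0].label


def _toy_calls_and_truths():
    """20 known-truth reads; 18 binned, 17 of them correctly."""
    calls, truths = [], []
    for i in range(20):
        rid = f"r{i}"
        truths.append(ev.GroundTruth(rid, "1"))
        if i < 17:
            calls.append(ReadCall(rid, 1, 1, 1))       # correct
        elif i == 17:
            calls.append(ReadCall(rid, 2, 2, 2))       # wrong bin
        else:
            calls.append(ReadCall(rid, None, None, None))  # unbinned
    return calls, truths


class TestScoreDemux:
    def test_hand_computed_precision_and_recall(self):
        calls, truths = _toy_calls_and_truths()
        rep = ev.score_demux(calls, truths)
        assert rep.precision == pytest.approx(17 / 18)
        assert rep.recall == pytest.approx(17 / 20)
        assert rep.binned_fraction == pytest.approx(18 / 20)

    def test_perfect_binning(self):
        truths = [ev.GroundTruth(f"r{i}", "3") for i in range(10)]
        calls = [ReadCall(f"r{i}", 3, 3, 3) for i in range(10)]
        rep = ev.score_demux(calls, truths)
        assert rep.precision == 1.0 and rep.recall == 1.0

    def test_nothing_binned_precision_undefined(self):
        truths = [ev.GroundTruth("r0", "1")]
        calls = [ReadCall("r0", None, None, None)]
        with pytest.warns(UserWarning):
            rep = ev.score_demux(calls, truths)
        assert rep.binned_fraction == 0.0
        assert np.isnan(rep.precision)

    def test_call_without_truth_raises(self):
        with pytest.raises(ValueError, match="r0"):
            ev.score_demux([ReadCall("r0", 1, 1, 1)], [])

    def test_confusion_matrix_totals(self):
        calls, truths = _toy_calls_and_truths()
        rep = ev.score_demux(calls, truths)
        assert int(rep.confusion.to_numpy().sum()) == 20
        assert int(rep.confusion.loc["1"].sum()) == 20

    def test_unknown_and_chimeric_tracked_separately(self):
        truths = [ev.GroundTruth("a", ev.UNKNOWN), ev.GroundTruth("b", ev.CHIMERA),
                  ev.GroundTruth("c", "1")]
        calls = [ReadCall("a", 5, 5, 5), ReadCall("b", None, None, None),
                 ReadCall("c", 1, 1, 1)]
        rep = ev.score_demux(calls, truths)
        assert rep.binned_unknown_fraction == 1.0
        assert rep.binned_chimeric_fraction == 0.0
        assert rep.n_known == 1
        assert rep.precision == 1.0  # the unknown read does not count

    def test_q_range_is_percentiles_of_binned(self):
        truths = [ev.GroundTruth(f"r{i}", "1") for i in range(40)]
        calls = [ReadCall(f"r{i}", 1, 1, 1 if i < 30 else None)
                 for i in range(40)]
        quals = [QualityRecord(f"r{i}", np.full(10, float(i % 15 + 5)))
                 for i in range(40)]
        rep = ev.score_demux(calls, truths, quals)
        binned_qs = [q.mean_q for q, c in zip(quals, calls)
                     if c.final_bin is not None]
        assert rep.q_range[0] == pytest.approx(np.percentile(binned_qs, 2.5))
        assert rep.q_range[1] == pytest.approx(np.percentile(binned_qs, 97.5))


class TestMetricsByQscore:
    def test_single_bin_reproduces_overall_scores(self):
        calls, truths = _toy_calls_and_truths()
        quals = [QualityRecord(c.read_id, np.full(5, 12.0)) for c in calls]
        table = ev.metrics_by_qscore(calls, truths, quals, bin_edges=[0, 100])
        rep = ev.score_demux(calls, truths)
        assert table.loc[0, "precision"] == pytest.approx(rep.precision)
        assert table.loc[0, "recall"] == pytest.approx(rep.recall)

    def test_empty_bin_emitted_with_zero_count(self):
        calls, truths = _toy_calls_and_truths()
        quals = [QualityRecord(c.read_id, np.full(5, 12.0)) for c in calls]
        table = ev.metrics_by_qscore(calls, truths, quals,
                                     bin_edges=[0, 5, 100])
        assert table.loc[0, "n_reads"] == 0
        assert bool(table.loc[0, "low_confidence"])


class TestConsensus:
    def test_identical_tables_unchanged(self):
        calls, _ = _toy_calls_and_truths()
        out = ev.consensus_bins([calls, list(calls)])
        assert [c.final_bin for c in out] == [c.final_bin for c in calls]

    def test_disagreement_gives_none(self):
        a = [ReadCall("r", 3, 3, 3)]
        b = [ReadCall("r", None, None, None)]
        assert ev.consensus_bins([a, b])[0].final_bin is None

    def test_consensus_is_intersection(self):
        rng = np.random.default_rng(0)
        ids = [f"r{i}" for i in range(50)]
        def table(seed):
            r = np.random.default_rng(seed)
            return [ReadCall(i, None, None,
                             int(r.integers(1, 4)) if r.random() > 0.3 else None)
                    for i in ids]
        t1, t2 = table(1), table(2)
        cons = ev.consensus_bins([t1, t2])
        binned = {c.read_id for c in cons if c.final_bin is not None}
        assert binned <= {c.read_id for c in t1 if c.final_bin is not None}
        assert binned <= {c.read_id for c in t2 if c.final_bin is not None}

    def test_consensus_improves_precision_at_recall_cost(self):
        """Where two demultiplexers disagree, one of them is wrong;
        consensus binning drops those reads, so its precision is at
        least the better single-table precision while recall falls."""
        truths = [ev.GroundTruth(f"r{i}", "1") for i in range(30)]
        # table A: 28 correct + 2 wrong bins; table B: 25 correct,
        # disagrees on A's wrong reads
        a = [ReadCall(f"r{i}", None, None, 1 if i < 28 else 2)
             for i in range(30)]
        b = [ReadCall(f"r{i}", None, None, 1 if i < 25 else None)
             for i in range(30)]
        cons = ev.consensus_bins([a, b])
        rep_a = ev.score_demux(a, truths)
        rep_b = ev.score_demux(b, truths)
        rep_c = ev.score_demux(cons, truths)
        assert rep_c.precision >= max(rep_a.precision, rep_b.precision)
        assert rep_c.recall <= min(rep_a.recall, rep_b.recall)

    def test_mismatched_read_sets_raise(self):
        with pytest.raises(ValueError):
            ev.consensus_bins([[ReadCall("a", 1, 1, 1)],
                               [ReadCall("b", 1, 1, 1)]])

    def test_fewer_than_two_tables_raise(self):
        with pytest.raises(ValueError):
            ev.consensus_bins([[ReadCall("a", 1, 1, 1)]])
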