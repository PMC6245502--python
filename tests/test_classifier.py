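"""Decision rules: windowing arithmetic, max/renormalise merging, the
probability-gap call, start/end combination and bin partitioning."""

import numpy as np
import pytest

from squigglebin import classifier as clf
from squigglebin import network
from squigglebin.signal_io import Squiggle


class TestWindowScheme:
    def test_default_span_is_6144(self):
        cfg = clf.WindowConfig()
        assert cfg.span == 6144
        assert (cfg.window_len, cfg.stride, cfg.n_windows) == (1024, 512, 11)

    def test_full_length_read_gives_11_windows(self):
        w = clf.extract_windows(np.random.default_rng(0).normal(size=6144))
        assert w.shape == (11, 1024)

    def test_2000_sample_read_gives_2_windows(self):
        w = clf.extract_windows(np.random.default_rng(0).normal(size=2000))
        assert w.shape[0] == 2  # offsets 0 and 512 fit; 1024 does not

    def test_1000_sample_read_gives_no_windows(self):
        w = clf.extract_windows(np.random.default_rng(0).normal(size=1000))
        assert w.shape[0] == 0

    def test_windows_are_independently_normalised(self):
        w = clf.extract_windows(np.random.default_rng(1).normal(size=4096))
        for row in w:
            assert abs(row.mean()) < 1e-9
            assert abs(row.var() - 1) < 1e-9

    def test_end_windows_come_from_reversed_tail(self):
        x = np.random.default_rng(2).normal(size=3000)
        w = clf.extract_windows(x, end="read_end")
        tail = x[::-1][:1024]
        np.testing.assert_allclose(w[0], (tail - tail.mean()) / tail.std())


class TestMergeProbs:
    def test_two_row_merge_hand_computed(self):
        # rows over [barcode1, barcode2, no-barcode]
        rows = np.array([[0.7, 0.2, 0.1],
                         [0.1, 0.8, 0.1]])
        merged = clf.merge_window_probs(rows, no_barcode_class=2)
        np.testing.assert_allclose(merged, [0.4375, 0.5, 0.0625])

    def test_single_row_unchanged(self):
        row = np.array([0.2, 0.5, 0.3])
        np.testing.assert_allclose(clf.merge_window_probs(row, 2), row)

    def test_output_sums_to_one(self):
        rng = np.random.default_rng(0)
        rows = rng.dirichlet(np.ones(13), size=7)
        assert clf.merge_window_probs(rows).sum() == pytest.approx(1.0)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(1)
        rows = rng.dirichlet(np.ones(13), size=5)
        a = clf.merge_window_probs(rows)
        b = clf.merge_window_probs(rows[::-1])
        np.testing.assert_allclose(a, b)

    def test_no_barcode_uses_minimum_across_windows(self):
        # a barcoded window among barcode-free windows: the no-barcode
        # evidence must not drown the barcode's
        rows = np.array([[0.01, 0.98, 0.01],   # window with barcode 2
                         [0.98, 0.01, 0.01],   # barcode-free window
                         [0.97, 0.01, 0.02]])  # barcode-free window
        merged = clf.merge_window_probs(rows, no_barcode_class=0)
        assert merged.argmax() == 1

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            clf.merge_window_probs(np.empty((0, 13)))


def _probs(**kw):
    """13-class vector with given barcode probabilities, rest on no-barcode."""
    p = np.zeros(13)
    for k, v in kw.items():
        p[int(k[2:])] = v
    p[0] = max(0.0, 1.0 - p.sum())
    return p


class TestCallBarcode:
    def test_clear_winner_called(self):
        p = _probs(bc3=0.90, bc5=0.05)
        assert clf.call_barcode(p) == 3  # gap 0.85

    def test_close_competitors_give_none(self):
        p = _probs(bc1=0.60, bc2=0.35)
        assert clf.call_barcode(p) is None  # gap 0.25

    def test_no_barcode_top_gives_none(self):
        p = np.zeros(13)
        p[0] = 0.95
        p[3] = 0.05
        assert clf.call_barcode(p) is None

    def test_gap_exactly_half_gives_none(self):
        p = _probs(bc1=0.75, bc2=0.25)
        p[0] = 0.0
        assert clf.call_barcode(p) is None  # gap 0.5 not > 0.5

    def test_exact_tie_gives_none(self):
        p = _probs(bc1=0.5, bc2=0.5)
        assert clf.call_barcode(p) is None


class TestCombineEnds:
    @pytest.mark.parametrize("start,end,mode,expect", [
        (3, 3, "default", (3, False)),
        (3, None, "default", (3, False)),
        (None, 3, "default", (3, False)),
        (3, 7, "default", (None, True)),     # chimera
        (None, None, "default", (None, False)),
        (3, 3, "stringent", (3, False)),
        (3, None, "stringent", (None, False)),
        (3, 7, "stringent", (None, True)),
        (3, 7, "start_only", (3, False)),
        (3, None, "start_only", (3, False)),
    ])
    def test_rule_table(self, start, end, mode, expect):
        assert clf.combine_ends(start, end, mode) == expect

    def test_invalid_mode_raises(self):
        with pytest.raises(ValueError):
            clf.combine_ends(1, 1, "nonsense")

    def test_stringent_bins_subset_of_default(self):
        """Whatever the per-end calls, stringent binning implies default
        binning of the same barcode."""
        options = [None] + list(range(1, 13))
        for s in options:
            for e in options:
                strict, _ = clf.combine_ends(s, e, "stringent")
                default, _ = clf.combine_ends(s, e, "default")
                if strict is not None:
                    assert default == strict


class TestDemultiplexPartition:
    def test_every_read_in_exactly_one_bin(self, tmp_path):
        """Bin counts sum to the input count, with an untrained model."""
        model = network.build_model(network.desk_scale_config(scale=0.1, seed=0))
        rng = np.random.default_rng(3)
        squiggles = [Squiggle(f"r{i}", rng.normal(450, 40, 3000))
                     for i in range(8)]
        calls = clf.demultiplex(squiggles, model, model, out_dir=tmp_path,
                                open_pore_threshold=None)
        assert len(calls) == 8
        assert len({c.read_id for c in calls}) == 8
        # chimera implies none bin
        for c in calls:
            if c.chimera_flag:
                assert c.final_bin is None
        assert (tmp_path / "calls.tsv").exists()
        back = clf.read_calls_table(tmp_path / "calls.tsv")
        assert [c.read_id for c in back] == [c.read_id for c in calls]
        assert [c.final_bin for c in back] == [c.final_bin for c in calls]

    def test_verbose_and_per_bin_signal_output(self, tmp_path):
        model = network.build_model(network.desk_scale_config(scale=0.1, seed=2))
        rng = np.random.default_rng(4)
        squiggles = [Squiggle(f"r{i}", rng.normal(450, 40, 3000))
                     for i in range(4)]
        clf.demultiplex(squiggles, model, model, out_dir=tmp_path,
                        open_pore_threshold=None, write_signals=True,
                        verbose=True)
        verbose = (tmp_path / "calls_verbose.tsv").read_text().splitlines()
        assert len(verbose) == 5  # header + 4 reads
        assert len(verbose[1].split("\t")) == 1 + 26  # id + 2x13 probs
        # every read's signal lands in exactly one bin directory
        binned_ids = []
        for d in tmp_path.iterdir():
            if d.is_dir() and (d / "signals.tsv").exists():
                for line in (d / "signals.tsv").read_text().splitlines():
                    binned_ids.append(line.split("\t")[0])
        assert sorted(binned_ids) == [f"r{i}" for i in range(4)]

    def test_missing_end_model_raises(self):
        model = network.build_model(network.desk_scale_config(scale=0.1))
        with pytest.raises(ValueError):
            clf.demultiplex([], model, None, mode="default")

    def test_short_read_assigned_none(self):
        model = network.build_model(network.desk_scale_config(scale=0.1, seed=1))
        sq = Squiggle("tiny", np.random.default_rng(0).normal(450, 40, 500))
        calls = clf.demultiplex([sq], model, model, open_pore_threshold=None)
        assert calls[0].final_bin is None
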