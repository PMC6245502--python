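"""Read classification: windowing, probability merging, calling, binning.

A read's barcode signal usually sits in the first ~1024 samples after
open-pore trimming, but long open-pore stretches can push it further in,
so classification examines several overlapping 1024-sample windows
(11 windows at stride 512 by default, spanning 6144 samples).  Window
probabilities are merged per class and a barcode is called only when the
top probability beats the runner-up by more than the gap threshold
(0.5) and the top class is not no-barcode.  Start and end calls combine
per library preparation: either end suffices by default, both ends must
agree in stringent mode, and conflicting ends flag a chimera.
"""

from __future__ import annotations

import logging
import os
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from squigglebin.signal_io import Squiggle, znormalize, trim_open_pore
from squigglebin.network import Model, predict_probs, NO_BARCODE_CLASS
from squigglebin import simulator as sim

log = logging.getLogger(__name__)

NONE_BIN = "none"


@dataclass
class WindowConfig:
    """The multi-window scheme: 1024-sample windows overlapping by 512."""

    window_len: int = 1024
    stride: int = 512
    n_windows: int = 11

    def __post_init__(self):
        if self.stride > self.window_len:
            raise ValueError("stride must not exceed window length")

    @property
    def span(self) -> int:
        """Total samples covered: window_len + (n_windows - 1) * stride."""
        return self.window_len + (self.n_windows - 1) * self.stride


@dataclass
class ReadCall:
    """Per-read demultiplexing outcome."""

    read_id: str
    start_call: int | None  # barcode id or None
    end_call: int | None
    final_bin: int | None
    chimera_flag: bool = False
    start_probs: np.ndarray | None = field(default=None, repr=False)
    end_probs: np.ndarray | None = field(default=None, repr=False)


def extract_windows(values: np.ndarray, end: str = "read_start",
                    config: WindowConfig | None = None) -> np.ndarray:
    """Cut the overlapping classification windows from a trimmed signal.

    Windows start at offsets 0, stride, 2*stride, ... from the read
    start; for ``end="read_end"`` the trailing signal is reversed first
    (the training orientation) and windows are cut the same way.  Only
    windows that fully fit yield output; a read shorter than one window
    yields none.  Each window is z-normalised independently, because
    windows can straddle signal regimes of very different amplitude.

    Returns an array of shape (n_emitted, window_len).
    """
    config = config or WindowConfig()
    values = np.asarray(values, dtype=np.float64)
    if end == "read_end":
        values = values[::-1]
    elif end != "read_start":
        raise ValueError(f"unknown end: {end!r}")
    L = values.size
    windows = []
    for i in range(config.n_windows):
        start = i * config.stride
        if start + config.window_len > L:
            break
        windows.append(znormalize(values[start:start + config.window_len]))
    if not windows:
        return np.empty((0, config.window_len))
    return np.stack(windows)


def merge_window_probs(rows: np.ndarray,
                       no_barcode_class: int = NO_BARCODE_CLASS) -> np.ndarray:
    """Merge per-window probability rows into one read-level row.

    Each barcode class keeps its maximum probability across windows —
    a barcode is present if any window shows it.  The no-barcode class
    keeps its minimum — a read is barcode-free only if every window is.
    (Taking the maximum there too would let the barcode-free windows
    that trail every real barcode mask the barcode's own evidence.)
    The merged values are renormalised to sum to 1.
    """
    rows = np.asarray(rows, dtype=np.float64)
    if rows.ndim == 1:
        rows = rows[None, :]
    if rows.shape[0] == 0:
        raise ValueError("no probability rows to merge")
    merged = rows.max(axis=0)
    merged[no_barcode_class] = rows[:, no_barcode_class].min()
    return merged / merged.sum()


def call_barcode(probs: np.ndarray, gap_threshold: float = 0.5,
                 no_barcode_class: int = NO_BARCODE_CLASS) -> int | None:
    """Call a barcode from merged probabilities.

    Returns the arg-max barcode only if its probability exceeds the
    second-highest by strictly more than ``gap_threshold`` and the
    arg-max class is not no-barcode; otherwise None.  An exact tie gives
    gap 0 and therefore None, deterministically.
    """
    probs = np.asarray(probs, dtype=np.float64)
    order = np.argsort(probs)
    best, second = order[-1], order[-2]
    if best == no_barcode_class:
        return None
    if probs[best] - probs[second] <= gap_threshold:
        return None
    return int(best)  # class index == barcode id (no-barcode is class 0)


def combine_ends(start_call: int | None, end_call: int | None,
                 mode: str = "default") -> tuple[int | None, bool]:
    """Combine per-end calls into (final_bin, chimera_flag).

    default: a match on either end bins the read; two different barcodes
    make it a chimera (binned none).  stringent: both ends must agree on
    the same barcode.  start_only: the end call is ignored.
    """
    if mode == "start_only":
        return start_call, False
    if mode == "default":
        if start_call is not None and end_call is not None:
            if start_call == end_call:
                return start_call, False
            return None, True  # conflicting ends: chimera
        return (start_call if start_call is not None else end_call), False
    if mode == "stringent":
        if start_call is not None and start_call == end_call:
            return start_call, False
        # conflicting non-None ends are still evidence of a chimera
        chimera = (start_call is not None and end_call is not None
                   and start_call != end_call)
        return None, chimera
    raise ValueError(f"unknown mode: {mode!r}")


def classify_read(squiggle: Squiggle, start_model: Model,
                  end_model: Model | None = None, mode: str = "default",
                  config: WindowConfig | None = None,
                  gap_threshold: float = 0.5,
                  open_pore_threshold: float | None = sim.DEFAULT_OPEN_PORE_THRESHOLD,
                  ) -> ReadCall:
    """Classify one read: trim, window, predict, merge, call, combine."""
    config = config or WindowConfig()
    try:
        trimmed = trim_open_pore(squiggle.values, open_pore_threshold, trim_end=True)
    except ValueError:
        return ReadCall(squiggle.read_id, None, None, None)

    def end_probs_and_call(model: Model, end: str):
        windows = extract_windows(trimmed, end=end, config=config)
        if windows.shape[0] == 0:
            return None, None
        merged = merge_window_probs(predict_probs(model, windows))
        return merged, call_barcode(merged, gap_threshold)

    start_probs, start_call = end_probs_and_call(start_model, "read_start")
    end_probs, end_call = (None, None)
    if mode != "start_only":
        if end_model is None:
            raise ValueError(f"mode {mode!r} requires an end model")
        end_probs, end_call = end_probs_and_call(end_model, "read_end")
    final, chimera = combine_ends(start_call, end_call, mode)
    return ReadCall(squiggle.read_id, start_call, end_call, final, chimera,
                    start_probs, end_probs)


def demultiplex(squiggles: list[Squiggle], start_model: Model,
                end_model: Model | None = None, mode: str = "default",
                config: WindowConfig | None = None,
                gap_threshold: float = 0.5,
                open_pore_threshold: float | None = sim.DEFAULT_OPEN_PORE_THRESHOLD,
                out_dir: str | Path | None = None,
                signal_paths: dict[str, Path] | None = None,
                write_signals: bool = False,
                verbose: bool = False,
                ) -> list[ReadCall]:
    """Demultiplex a read set into per-barcode bins.

    Every read lands in exactly one bin: its called barcode, or the
    ``none`` bin for unclassified and chimeric reads.  With ``out_dir``
    the binned read signals are written to per-bin directories (or, when
    ``signal_paths`` maps read ids to files, linked/copied there) plus a
    ``calls.tsv`` table with per-end calls and the chimera flag.

    Windows of many reads are batched through the network together,
    which is substantially faster than per-read prediction.
    """
    if mode != "start_only" and end_model is None:
        raise ValueError(f"mode {mode!r} requires an end model")
    config = config or WindowConfig()
    calls: list[ReadCall] = []

    # Collect windows for all reads, predict in large batches per end.
    per_read: list[dict] = []
    for sq in squiggles:
        try:
            trimmed = trim_open_pore(sq.values, open_pore_threshold, trim_end=True)
        except ValueError:
            trimmed = np.empty(0)
        entry = {"read_id": sq.read_id,
                 "start": extract_windows(trimmed, "read_start", config)}
        if mode != "start_only":
            entry["end"] = extract_windows(trimmed, "read_end", config)
        per_read.append(entry)

    def merged_for(key: str, model: Model) -> list[np.ndarray | None]:
        counts = [e[key].shape[0] for e in per_read]
        stacked = np.concatenate([e[key] for e in per_read if e[key].shape[0]]) \
            if sum(counts) else np.empty((0, config.window_len))
        probs = predict_probs(model, stacked) if stacked.shape[0] else None
        merged, pos = [], 0
        for c in counts:
            if c == 0:
                merged.append(None)
            else:
                merged.append(merge_window_probs(probs[pos:pos + c]))
                pos += c
        return merged

    start_merged = merged_for("start", start_model)
    end_merged = merged_for("end", end_model) if mode != "start_only" \
        else [None] * len(per_read)

    for entry, sp, ep in zip(per_read, start_merged, end_merged):
        start_call = call_barcode(sp, gap_threshold) if sp is not None else None
        end_call = call_barcode(ep, gap_threshold) if ep is not None else None
        final, chimera = combine_ends(start_call, end_call, mode)
        calls.append(ReadCall(entry["read_id"], start_call, end_call,
                              final, chimera, sp, ep))

    if out_dir is not None:
        write_bins(calls, Path(out_dir), signal_paths,
                   squiggles=squiggles if write_signals else None,
                   verbose=verbose)
    return calls


def _bin_dir(out_dir: Path, final_bin: int | None) -> Path:
    return out_dir / (f"barcode{final_bin:02d}" if final_bin is not None
                      else NONE_BIN)


def write_bins(calls: list[ReadCall], out_dir: Path,
               signal_paths: dict[str, Path] | None = None,
               squiggles: list[Squiggle] | None = None,
               verbose: bool = False) -> None:
    """Write per-bin directories, the calls table and, in verbose mode,
    the merged per-end class probabilities."""
    from squigglebin.signal_io import write_raw_signal

    out_dir.mkdir(parents=True, exist_ok=True)
    bins = sorted({c.final_bin for c in calls if c.final_bin is not None})
    for b in bins + [None]:
        _bin_dir(out_dir, b).mkdir(exist_ok=True)
    with open(out_dir / "calls.tsv", "w") as fh:
        fh.write("read_id\tstart_call\tend_call\tfinal\tchimera\n")
        for c in calls:
            fh.write(f"{c.read_id}\t{_fmt(c.start_call)}\t{_fmt(c.end_call)}\t"
                     f"{_fmt(c.final_bin)}\t{int(c.chimera_flag)}\n")
            if signal_paths and c.read_id in signal_paths:
                src = signal_paths[c.read_id]
                dest = _bin_dir(out_dir, c.final_bin) / src.name
                if not dest.exists():
                    try:
                        os.link(src, dest)
                    except OSError:
                        shutil.copy2(src, dest)
    if squiggles is not None:
        by_bin: dict = {}
        final_of = {c.read_id: c.final_bin for c in calls}
        for sq in squiggles:
            by_bin.setdefault(final_of.get(sq.read_id), []).append(sq)
        for b, sqs in by_bin.items():
            write_raw_signal(sqs, _bin_dir(out_dir, b) / "signals.tsv")
    if verbose:
        n = 13
        with open(out_dir / "calls_verbose.tsv", "w") as fh:
            cols = [f"start_p{i}" for i in range(n)] + [f"end_p{i}" for i in range(n)]
            fh.write("read_id\t" + "\t".join(cols) + "\n")
            for c in calls:
                row = []
                for probs in (c.start_probs, c.end_probs):
                    row += ["nan"] * n if probs is None else \
                        [f"{p:.6f}" for p in probs]
                fh.write(c.read_id + "\t" + "\t".join(row) + "\n")


def _fmt(v: int | None) -> str:
    return NONE_BIN if v is None else str(v)


def read_calls_table(path: str | Path) -> list[ReadCall]:
    """Read a calls.tsv back into ReadCall records (no probabilities)."""
    calls = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            read_id, s, e, f, chim = line.rstrip("\n").split("\t")
            parse = lambda v: None if v == NONE_BIN else int(v)
            calls.append(ReadCall(read_id, parse(s), parse(e), parse(f),
                                  bool(int(chim))))
    return calls
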