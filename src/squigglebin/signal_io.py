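"""Raw-signal, FASTQ and PAF I/O plus shared signal utilities.

Raw nanopore reads are stored either in fast5 (HDF5) containers — both the
single-read and multi-read dialects — or in a plain-text one-read-per-line
format (``read_id<TAB>comma-separated integers``) that serves as the
portable fixture medium.  Signal normalisation, open-pore trimming and
mean-q-score computation live here because every downstream module needs
them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np

log = logging.getLogger(__name__)

DEFAULT_SAMPLE_RATE = 4000.0  # Hz; MinION samples current at 4 kHz


@dataclass
class Squiggle:
    """A raw-current read: the signal a single DNA strand produced in the pore."""

    read_id: str
    values: np.ndarray
    sample_rate: float = DEFAULT_SAMPLE_RATE
    source: str = "text"  # one of {fast5, text, simulated}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class QualityRecord:
    """Per-base Phred qualities of a basecalled read, with the proper mean."""

    read_id: str
    per_base_quals: np.ndarray
    mean_q: float = field(init=False)

    def __post_init__(self) -> None:
        self.per_base_quals = np.asarray(self.per_base_quals, dtype=np.float64)
        if np.any(self.per_base_quals < 0):
            raise ValueError("Phred qualities must be non-negative")
        self.mean_q = mean_qscore(self.per_base_quals)


@dataclass
class PafRecord:
    """One alignment of a read to a target, reduced to what ground-truthing needs.

    ``alignment_len_on_read`` is the aligned span measured in read
    coordinates (query end minus query start).  ``rank`` is 1 for the
    longest alignment of the read, 2 for the next, and so on.
    """

    read_id: str
    read_len: int
    target_id: str
    alignment_len_on_read: int
    rank: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.alignment_len_on_read <= self.read_len):
            raise ValueError(
                f"{self.read_id}: alignment length {self.alignment_len_on_read} "
                f"outside [0, {self.read_len}]"
            )


# ---------------------------------------------------------------------------
# raw-signal I/O
# ---------------------------------------------------------------------------

def _read_text_signals(path: Path) -> list[Squiggle]:
    squiggles = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                read_id, values_str = line.split("\t", 1)
                values = np.array([float(v) for v in values_str.split(",")],
                                  dtype=np.float64)
                if values.size == 0:
                    raise ValueError("no signal values")
            except ValueError as exc:
                log.warning("%s line %d: skipping malformed record (%s)", path, line_no, exc)
                continue
            squiggles.append(Squiggle(read_id, values, source="text"))
    return squiggles


def _read_fast5_signals(path: Path) -> list[Squiggle]:
    squiggles = []
    with h5py.File(path, "r") as f:
        if "Raw" in f:  # single-read dialect: /Raw/Reads/Read_<n>/Signal
            for read_name, grp in f["Raw/Reads"].items():
                if "Signal" not in grp:
                    log.warning("%s: %s lacks a raw-signal dataset, skipped", path, read_name)
                    continue
                read_id = grp.attrs.get("read_id", read_name)
                if isinstance(read_id, bytes):
                    read_id = read_id.decode()
                squiggles.append(Squiggle(str(read_id), grp["Signal"][:], source="fast5"))
        else:  # multi-read dialect: /read_<id>/Raw/Signal
            for key in f:
                grp = f[key]
                if "Raw" not in grp or "Signal" not in grp["Raw"]:
                    log.warning("%s: %s lacks a raw-signal dataset, skipped", path, key)
                    continue
                read_id = key[5:] if key.startswith("read_") else key
                squiggles.append(Squiggle(read_id, grp["Raw/Signal"][:], source="fast5"))
    return squiggles


def read_raw_signal(path: str | Path, format: str = "text") -> list[Squiggle]:
    """Read raw-signal reads from a file or a directory of files.

    ``format`` is ``"text"`` or ``"fast5"``.  Reads are returned in a
    stable order (sorted file names; in-file order within each file).
    Unreadable containers raise; reads without a raw-signal dataset are
    skipped with a warning.
    """
    path = Path(path)
    if format not in ("text", "fast5"):
        raise ValueError(f"unknown raw-signal format: {format!r}")
    if path.is_dir():
        suffix = ".fast5" if format == "fast5" else ".tsv"
        files = sorted(p for p in path.iterdir() if p.suffix == suffix)
        if not files:
            log.warning("%s: no %s files found", path, suffix)
            return []
    elif path.exists():
        files = [path]
    else:
        raise FileNotFoundError(f"no such raw-signal path: {path}")

    reader = _read_fast5_signals if format == "fast5" else _read_text_signals
    squiggles: list[Squiggle] = []
    for f in files:
        try:
            squiggles.extend(reader(f))
        except OSError as exc:
            raise OSError(f"unreadable raw-signal container {f}: {exc}") from exc
    return squiggles


def write_raw_signal(squiggles: Iterable[Squiggle], path: str | Path,
                     format: str = "text") -> None:
    """Write squiggles to a text or fast5 (multi-read dialect) container.

    Signal values are stored as integers in the text format (raw device
    units are integral); the round trip is exact for integral input.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "text":
        with open(path, "w") as fh:
            for sq in squiggles:
                vals = ",".join(str(int(v)) if float(v).is_integer() else repr(float(v))
                                for v in sq.values)
                fh.write(f"{sq.read_id}\t{vals}\n")
    elif format == "fast5":
        with h5py.File(path, "w") as f:
            for sq in squiggles:
                grp = f.create_group(f"read_{sq.read_id}/Raw")
                grp.create_dataset("Signal", data=sq.values)
    else:
        raise ValueError(f"unknown raw-signal format: {format!r}")


# ---------------------------------------------------------------------------
# signal utilities
# ---------------------------------------------------------------------------

def znormalize(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Scale a signal to mean 0, variance 1 (population variance).

    A constant signal cannot be variance-scaled; it maps to all zeros
    (with a warning) so flat synthetic training signals pass through the
    same code path as real ones.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot z-normalise an empty signal")
    sd = values.std()
    if sd == 0:
        log.warning("constant signal z-normalised to zeros")
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def trim_open_pore(values: np.ndarray, threshold: float | None = None,
                   trim_end: bool = False, return_bounds: bool = False):
    """Remove leading (and optionally trailing) open-pore signal.

    Open-pore signal — the high current recorded while no DNA occupies
    the pore — precedes and follows the real read signal.  The maximal
    leading run of samples strictly above ``threshold`` is removed;
    with ``trim_end`` the maximal trailing run too.  Interior samples
    are never touched: the result is a contiguous slice of the input.

    When ``threshold`` is None a robust per-read fallback is used:
    median + 5 * MAD of the whole read.

    With ``return_bounds`` the result is ``(trimmed, start, end)`` where
    ``[start, end)`` is the retained slice of the input — callers use it
    to shift interval coordinates into trimmed space.

    Raises ``ValueError`` if every sample exceeds the threshold — the
    read contains no usable signal.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        return (values, 0, 0) if return_bounds else values
    if threshold is None:
        med = np.median(values)
        mad = np.median(np.abs(values - med))
        threshold = med + 5.0 * mad
    above = values > threshold
    if above.all():
        raise ValueError("every sample above the open-pore threshold: unusable read")
    start = int(np.argmin(above))  # first sample not above threshold
    end = values.size
    if trim_end:
        end = values.size - int(np.argmin(above[::-1]))
    if return_bounds:
        return values[start:end], start, end
    return values[start:end]


def mean_qscore(per_base_quals: Sequence[float] | np.ndarray) -> float:
    """Mean Phred score of a read, averaged in error-probability space.

    q = -10 * log10( mean_i 10^(-q_i / 10) ).  Arithmetic averaging of
    Phred values overstates read quality; this is the standard
    error-rate-faithful mean.
    """
    quals = np.asarray(per_base_quals, dtype=np.float64)
    if quals.size == 0:
        raise ValueError("cannot compute mean q-score of an empty read")
    return float(-10.0 * math.log10(np.mean(10.0 ** (-quals / 10.0))))


# ---------------------------------------------------------------------------
# FASTQ and PAF
# ---------------------------------------------------------------------------

def read_fastq_quals(path: str | Path) -> list[QualityRecord]:
    """Read per-base qualities from a FASTQ file (4-line records, Phred+33)."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = np.asarray(rec.letter_annotations["phred_quality"], dtype=np.float64)
        records.append(QualityRecord(rec.id, quals))
    return records


def read_paf(path: str | Path) -> list[PafRecord]:
    """Parse a PAF file into per-read, length-ranked alignment records.

    PAF lines have 12+ tab-separated fields; the ones used here are
    query name (1), query length (2) and the query start/end (3, 4)
    whose difference is the alignment length in read coordinates.
    Malformed lines are skipped with a warning carrying the line number.
    Within each read, records are ranked by descending alignment
    length (rank 1 = longest).
    """
    raw: dict[str, list[PafRecord]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                log.warning("%s line %d: %d fields (need >= 12), skipped",
                            path, line_no, len(fields))
                continue
            try:
                read_id = fields[0]
                read_len = int(fields[1])
                q_start, q_end = int(fields[2]), int(fields[3])
                target_id = fields[5]
                rec = PafRecord(read_id, read_len, target_id, q_end - q_start)
            except ValueError as exc:
                log.warning("%s line %d: %s, skipped", path, line_no, exc)
                continue
            if read_id not in raw:
                raw[read_id] = []
                order.append(read_id)
            raw[read_id].append(rec)

    out: list[PafRecord] = []
    for read_id in order:
        recs = sorted(raw[read_id], key=lambda r: -r.alignment_len_on_read)
        for rank, rec in enumerate(recs, start=1):
            rec.rank = rank
            out.append(rec)
    return out
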