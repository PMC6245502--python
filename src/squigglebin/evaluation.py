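"""Ground-truth assignment and demultiplexing metrics.

Ground truth comes either from alignments (PAF) — a read belongs to the
reference its longest alignment hits, provided that alignment spans at
least min(100 bp, 10% of the read); a sufficiently long alignment to a
*second* reference (at least max(50 bp, 5% of the read)) marks the read
a cross-bin chimera — or directly from the simulator's truth table.

Metrics follow the standard demultiplexing definitions: precision is
the proportion of binned reads correctly assigned, recall the
proportion of all known-truth reads correctly assigned, and the q-score
range is the 2.5th-97.5th percentile of binned reads' mean Phred score.
Reads of unknown or chimeric truth are excluded from precision/recall
but tracked as binned-unknown and binned-chimeric fractions.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from squigglebin.signal_io import PafRecord, QualityRecord
from squigglebin.classifier import ReadCall

log = logging.getLogger(__name__)

PRIMARY_MIN_BP = 100      # primary-alignment threshold: min(100, 10% of read)
PRIMARY_MIN_FRAC = 0.10
SECONDARY_MIN_BP = 50     # chimera threshold: max(50, 5% of read)
SECONDARY_MIN_FRAC = 0.05

UNKNOWN = "unknown"
CHIMERA = "chimera"


@dataclass
class GroundTruth:
    read_id: str
    label: str  # reference id, "unknown", or "chimera"


@dataclass
class DemuxReport:
    """Confusion matrix plus the headline demultiplexing metrics."""

    confusion: pd.DataFrame  # truth rows x predicted-bin columns
    binned_fraction: float
    precision: float  # NaN when nothing is binned
    recall: float
    q_range: tuple[float, float]
    binned_unknown_fraction: float
    binned_chimeric_fraction: float
    n_reads: int
    n_known: int

    def to_dict(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "n_known": self.n_known,
            "binned_fraction": self.binned_fraction,
            "precision": self.precision,
            "recall": self.recall,
            "q_range": list(self.q_range),
            "binned_unknown_fraction": self.binned_unknown_fraction,
            "binned_chimeric_fraction": self.binned_chimeric_fraction,
            "confusion": {str(k): {str(c): int(v) for c, v in row.items()}
                          for k, row in self.confusion.iterrows()},
        }


def assign_ground_truth(paf_records: list[PafRecord]) -> list[GroundTruth]:
    """Label reads from their reference alignments.

    The rank-1 (longest) alignment must span at least
    min(100 bp, 10% of read length) or the read is unknown.  Any
    alignment to a different reference spanning at least
    max(50 bp, 5% of read length) makes the read a chimera.  Alignment
    spans are measured in read coordinates.  Reads with no alignments
    at all do not appear in the input and must be defaulted to unknown
    by the caller (see truth_from_paf_for_reads).
    """
    by_read: dict[str, list[PafRecord]] = {}
    order = []
    for rec in paf_records:
        if rec.read_id not in by_read:
            by_read[rec.read_id] = []
            order.append(rec.read_id)
        by_read[rec.read_id].append(rec)

    truths = []
    for read_id in order:
        recs = sorted(by_read[read_id], key=lambda r: -r.alignment_len_on_read)
        primary = recs[0]
        primary_threshold = min(PRIMARY_MIN_BP, PRIMARY_MIN_FRAC * primary.read_len)
        if primary.alignment_len_on_read < primary_threshold:
            truths.append(GroundTruth(read_id, UNKNOWN))
            continue
        secondary_threshold = max(SECONDARY_MIN_BP, SECONDARY_MIN_FRAC * primary.read_len)
        is_chimera = any(
            r.target_id != primary.target_id
            and r.alignment_len_on_read >= secondary_threshold
            for r in recs[1:])
        truths.append(GroundTruth(read_id, CHIMERA if is_chimera else primary.target_id))
    return truths


def truth_from_paf_for_reads(paf_records: list[PafRecord],
                             read_ids: list[str]) -> list[GroundTruth]:
    """Ground truth for a full read set: unaligned reads become unknown."""
    truths = {t.read_id: t for t in assign_ground_truth(paf_records)}
    return [truths.get(rid, GroundTruth(rid, UNKNOWN)) for rid in read_ids]


def truth_from_simulation(sim_truths: list, barcode_to_ref: dict[int, str] | None = None
                          ) -> list[GroundTruth]:
    """Ground truth directly from the simulator's truth table.

    Labels are barcode ids as strings (the truth a demultiplexer should
    recover); chimeric reads are labelled chimera and barcode-less reads
    unknown — like real barcode-less reads, nothing in the evaluation
    can assign them a sample of origin.
    """
    out = []
    for t in sim_truths:
        if t.is_chimera:
            out.append(GroundTruth(t.read_id, CHIMERA))
        elif t.barcode_id is None:
            out.append(GroundTruth(t.read_id, UNKNOWN))
        else:
            out.append(GroundTruth(t.read_id, str(t.barcode_id)))
    return out


def _call_to_label(call: ReadCall) -> str:
    return "none" if call.final_bin is None else str(call.final_bin)


def score_demux(calls: list[ReadCall], truths: list[GroundTruth],
                quals: list[QualityRecord] | None = None) -> DemuxReport:
    """Score a demultiplexing run against ground truth.

    Precision and recall are computed over reads with known (non-unknown,
    non-chimeric) truth; the binned fraction is over all reads.  Raises
    if any call lacks a truth record.
    """
    truth_by_id = {t.read_id: t.label for t in truths}
    missing = [c.read_id for c in calls if c.read_id not in truth_by_id]
    if missing:
        raise ValueError(f"calls without truth records: {missing[:5]}"
                         f"{'...' if len(missing) > 5 else ''}")
    q_by_id = {q.read_id: q.mean_q for q in quals} if quals else {}

    rows = []
    for c in calls:
        rows.append((truth_by_id[c.read_id], _call_to_label(c)))
    df = pd.DataFrame(rows, columns=["truth", "predicted"])
    confusion = pd.crosstab(df["truth"], df["predicted"], dropna=False)

    n_reads = len(calls)
    binned = df["predicted"] != "none"
    known = ~df["truth"].isin([UNKNOWN, CHIMERA])
    correct = known & (df["truth"] == df["predicted"])

    n_known = int(known.sum())
    n_binned_known = int((binned & known).sum())
    n_correct = int(correct.sum())

    if n_binned_known == 0:
        warnings.warn("no known-truth reads were binned: precision undefined")
        precision = float("nan")
    else:
        precision = n_correct / n_binned_known
    recall = n_correct / n_known if n_known else float("nan")
    binned_fraction = float(binned.mean()) if n_reads else float("nan")

    def binned_frac_of(label: str) -> float:
        mask = df["truth"] == label
        return float((binned & mask).sum() / mask.sum()) if mask.any() else float("nan")

    if q_by_id:
        binned_qs = [q_by_id[c.read_id] for c, b in zip(calls, binned) if b
                     and c.read_id in q_by_id]
        q_range = (float(np.percentile(binned_qs, 2.5)),
                   float(np.percentile(binned_qs, 97.5))) if binned_qs \
            else (float("nan"), float("nan"))
    else:
        q_range = (float("nan"), float("nan"))

    return DemuxReport(
        confusion=confusion,
        binned_fraction=binned_fraction,
        precision=precision,
        recall=recall,
        q_range=q_range,
        binned_unknown_fraction=binned_frac_of(UNKNOWN),
        binned_chimeric_fraction=binned_frac_of(CHIMERA),
        n_reads=n_reads,
        n_known=n_known,
    )


def metrics_by_qscore(calls: list[ReadCall], truths: list[GroundTruth],
                      quals: list[QualityRecord],
                      bin_edges: np.ndarray | list[float] | None = None,
                      low_confidence_n: int = 20) -> pd.DataFrame:
    """Precision and recall per mean-q-score bin.

    Returns a DataFrame with one row per q bin (empty bins included,
    with zero count); bins holding fewer than ``low_confidence_n`` reads
    are flagged low-confidence.
    """
    q_by_id = {q.read_id: q.mean_q for q in quals}
    truth_by_id = {t.read_id: t.label for t in truths}
    if bin_edges is None:
        qs = np.array([q_by_id[c.read_id] for c in calls if c.read_id in q_by_id])
        bin_edges = np.linspace(qs.min(), np.nextafter(qs.max(), np.inf), 7)
    bin_edges = np.asarray(bin_edges, dtype=np.float64)

    rows = []
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        sub_calls = [c for c in calls
                     if c.read_id in q_by_id and lo <= q_by_id[c.read_id] < hi]
        n = len(sub_calls)
        if n == 0:
            rows.append({"q_lo": lo, "q_hi": hi, "n_reads": 0,
                         "precision": float("nan"), "recall": float("nan"),
                         "low_confidence": True})
            continue
        sub_truths = [GroundTruth(c.read_id, truth_by_id[c.read_id]) for c in sub_calls]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = score_demux(sub_calls, sub_truths)
        rows.append({"q_lo": lo, "q_hi": hi, "n_reads": n,
                     "precision": rep.precision, "recall": rep.recall,
                     "low_confidence": n < low_confidence_n})
    return pd.DataFrame(rows)


def consensus_bins(call_tables: list[list[ReadCall]]) -> list[ReadCall]:
    """Bin a read only where every demultiplexer agrees.

    All tables must cover the same read set.  A read keeps its barcode
    iff every table assigns the same non-none barcode; otherwise it goes
    to the none bin.  Consensus binning trades recall for precision.
    """
    if len(call_tables) < 2:
        raise ValueError("consensus needs at least 2 call tables")
    id_sets = [frozenset(c.read_id for c in t) for t in call_tables]
    if len(set(id_sets)) != 1:
        raise ValueError("call tables cover different read sets")
    by_id = [{c.read_id: c for c in t} for t in call_tables]
    out = []
    for c in call_tables[0]:
        bins = [m[c.read_id].final_bin for m in by_id]
        agreed = bins[0] if (bins[0] is not None and all(b == bins[0] for b in bins)) \
            else None
        out.append(ReadCall(c.read_id, c.start_call, c.end_call, agreed,
                            any(m[c.read_id].chimera_flag for m in by_id)))
    return out


def write_report(report: DemuxReport, path, by_q: pd.DataFrame | None = None) -> None:
    """Write a JSON report plus a TSV confusion matrix next to it."""
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    d = report.to_dict()
    if by_q is not None:
        d["by_qscore"] = by_q.to_dict(orient="records")
    path.write_text(json.dumps(d, indent=1))
    report.confusion.to_csv(path.with_suffix(".confusion.tsv"), sep="\t")
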