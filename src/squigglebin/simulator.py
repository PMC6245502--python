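"""Synthetic squiggle generation with known barcode ground truth.

The simulator emulates the essentials of a barcoded nanopore library: a
k-mer pore model maps sequence to expected current levels, each base
dwells in the pore for a geometrically distributed number of 4 kHz
samples (mean 4000/450 ~ 8.9 samples/base), Gaussian measurement noise
is added per sample, and each read is framed by open-pore signal,
sequencing adapters and 40 bp barcode constructs (24 bp core + 8 bp
flanks) on both ends.  A fraction of reads carry no barcode, and a small
fraction are cross-barcode chimeras joining inserts from two samples.

Everything is seeded and bitwise reproducible; the emitted truth table
records each read's barcode, insert source, chimera status and the exact
sample intervals of the barcode constructs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from squigglebin.signal_io import Squiggle, write_raw_signal

log = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

SAMPLE_RATE = 4000.0          # Hz
TRANSLOCATION_RATE = 450.0    # bases/second
DWELL_MEAN = SAMPLE_RATE / TRANSLOCATION_RATE  # ~8.9 samples per base

# Affine map from dimensionless pore levels to raw device units.
DEVICE_OFFSET = 460.0
DEVICE_SCALE = 40.0
OPEN_PORE_LEVEL = 5.0         # pore-level units; well above any k-mer level
OPEN_PORE_SD = 0.1
DEFAULT_OPEN_PORE_THRESHOLD = DEVICE_OFFSET + 2.5 * DEVICE_SCALE  # 560 device units

CORE_LEN = 24
FLANK_LEN = 8
CONSTRUCT_LEN = CORE_LEN + 2 * FLANK_LEN  # 40 bp

LEFT_FLANK = "ACGTAGCA"
RIGHT_FLANK = "TGCATCGT"
ADAPTER = "GGTTGTTTCTGTTGGTGCTGATATTGCTGG"  # fixed 30 bp synthetic adapter

_BARCODE_MASTER_SEED = 987_654_321  # barcode cores are global constants
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# pore model
# ---------------------------------------------------------------------------

@dataclass
class PoreModel:
    """Maps each k-mer occupying the pore to an expected current level.

    Levels are dimensionless (standard-normal spread); ``level_sd`` is
    the per-sample Gaussian measurement noise, expressed in the same
    units, so the default 0.25 is a quarter of the inter-k-mer spread.
    """

    k: int = 6
    means: np.ndarray = field(repr=False, default=None)
    level_sd: float = 0.25
    dwell_mean: float = DWELL_MEAN
    seed: int = 7

    @property
    def level_table(self) -> dict[str, tuple[float, float]]:
        """k-mer -> (mean level, sd), covering all 4**k k-mers."""
        table = {}
        for idx in range(4 ** self.k):
            kmer = "".join(BASES[(idx >> (2 * (self.k - 1 - j))) & 3]
                           for j in range(self.k))
            table[kmer] = (float(self.means[idx]), self.level_sd)
        return table


def build_pore_model(k: int = 6, seed: int = 7, level_sd: float = 0.25) -> PoreModel:
    """Deterministically draw a per-k-mer level table.

    Means are i.i.d. standard normal, so distinct k-mers differ by ~1
    level unit on average — well above the default noise sd of 0.25.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    means = rng.normal(0.0, 1.0, size=4 ** k)
    return PoreModel(k=k, means=means, level_sd=level_sd, seed=seed)


def _encode_kmers(seq: str, k: int) -> np.ndarray:
    """Indices of the len(seq)-k+1 successive k-mers of seq."""
    codes = np.array([_BASE_INDEX[b] for b in seq], dtype=np.int64)
    if codes.size < k:
        raise ValueError(f"sequence of length {codes.size} shorter than k={k}")
    idx = np.zeros(codes.size - k + 1, dtype=np.int64)
    for j in range(k):
        idx = idx * 4 + codes[j:codes.size - k + 1 + j]
    return idx


def sequence_to_expected_signal(seq: str, model: PoreModel,
                                dwell: int | None = None) -> np.ndarray:
    """Noise-free expected signal of a sequence: one level per k-mer
    window, each repeated ``dwell`` times (default: rounded model mean)."""
    if dwell is None:
        dwell = int(round(model.dwell_mean))
    levels = model.means[_encode_kmers(seq, model.k)]
    return np.repeat(levels, dwell)


def _simulate_with_boundaries(seq: str, model: PoreModel,
                              rng: np.random.Generator,
                              noise_multiplier: float = 1.0
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Noisy squiggle plus the starting sample of each k-mer.

    Returns (values, starts) where starts[i] is the first sample index
    of k-mer i and starts[-1] is the total length.
    """
    levels = model.means[_encode_kmers(seq, model.k)]
    # Shifted-geometric dwell, support {1, 2, ...}, mean = dwell_mean.
    dwells = rng.geometric(1.0 / model.dwell_mean, size=levels.size)
    starts = np.concatenate([[0], np.cumsum(dwells)])
    values = np.repeat(levels, dwells).astype(np.float64)
    values += rng.normal(0.0, model.level_sd * noise_multiplier, size=values.size)
    return values, starts


def simulate_squiggle(seq: str, model: PoreModel,
                      rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Simulate the raw signal of one sequence (pore-level units).

    Per-base dwell is geometric with mean 4000/450 (minimum 1 sample);
    Gaussian noise of sd ``model.level_sd`` is added per sample.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    values, _ = _simulate_with_boundaries(seq, model, rng)
    return values


# ---------------------------------------------------------------------------
# barcodes and references
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BarcodeSpec:
    """A 40 bp native-barcode construct: 8 bp flank + 24 bp core + 8 bp flank."""

    barcode_id: int
    core_seq: str
    left_flank: str = LEFT_FLANK
    right_flank: str = RIGHT_FLANK

    def __post_init__(self):
        if len(self.core_seq) != CORE_LEN:
            raise ValueError(f"core must be {CORE_LEN} bp")
        if len(self.left_flank) != FLANK_LEN or len(self.right_flank) != FLANK_LEN:
            raise ValueError(f"flanks must be {FLANK_LEN} bp")

    @property
    def construct(self) -> str:
        """The full 40 bp sequence as ligated at the read start."""
        return self.left_flank + self.core_seq + self.right_flank


def _random_seq(n: int, rng: np.random.Generator) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def make_barcodes(n: int = 12) -> dict[int, BarcodeSpec]:
    """The fixed barcode set: core sequences are global constants so the
    same barcodes appear in every simulated library."""
    barcodes = {}
    for bc in range(1, n + 1):
        rng = np.random.default_rng(_BARCODE_MASTER_SEED + bc)
        barcodes[bc] = BarcodeSpec(bc, _random_seq(CORE_LEN, rng))
    return barcodes


def make_references(n: int = 12, length: int = 800, seed: int = 11) -> dict[str, str]:
    """Random 'amplicon' reference sequences, one per sample."""
    rng = np.random.default_rng(seed)
    return {f"ref_{i:02d}": _random_seq(length, rng) for i in range(1, n + 1)}


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------

@dataclass
class SimTruth:
    """Ground truth for one simulated read."""

    read_id: str
    barcode_id: int | None
    insert_source: str
    is_chimera: bool = False
    start_barcode_interval: tuple[int, int] | None = None  # half-open samples
    end_barcode_interval: tuple[int, int] | None = None
    true_q: float = float("nan")


@dataclass
class SimConfig:
    """Study conditions for a simulated library."""

    n_reads: int = 2000
    n_barcodes: int = 12
    ref_length: int = 800  # long enough that one end's window span never
    # reaches the other end's barcode, as with real multi-kbp amplicons
    no_barcode_rate: float = 0.10
    chimera_rate: float = 0.003        # matches the ~0.3% seen in real libraries
    pad_range: tuple[int, int] = (50, 2000)  # open-pore samples per read end
    substitution_q_mean: float = 12.0  # mean true read q
    substitution_q_sd: float = 2.5
    q_range: tuple[float, float] = (5.0, 20.0)
    link_quality_to_noise: bool = True
    open_pore_threshold: float = DEFAULT_OPEN_PORE_THRESHOLD
    # "amplicon": barcode i always carries reference i (the evaluation
    # design, where internal sequence identifies the sample).  "random":
    # every read draws an arbitrary insert, so the barcode construct is
    # the only signal that identifies it — the right design for
    # harvesting training data, as a classifier trained on coupled reads
    # can cheat by reading the insert instead of the barcode.
    barcode_ref_coupling: str = "amplicon"


def _to_device_units(values: np.ndarray) -> np.ndarray:
    return DEVICE_OFFSET + DEVICE_SCALE * values


def _noise_multiplier(q: float, q_ref: float = 12.0) -> float:
    """Lower-quality reads get noisier signal (and vice versa)."""
    return float(10.0 ** ((q_ref - q) / 40.0))


def simulate_library(model: PoreModel | None = None,
                     config: SimConfig | None = None,
                     seed: int = 42,
                     refs: dict[str, str] | None = None,
                     barcodes: dict[int, BarcodeSpec] | None = None,
                     ) -> tuple[list[Squiggle], list[SimTruth], list]:
    """Simulate a barcoded library: squiggles, truth table, FASTQ records.

    Each read is open-pore pad + adapter + barcode construct + insert +
    reverse-complement barcode construct + adapter + open-pore pad.
    Chimeric reads join the first half of one sample's read to the
    second half of another's; barcode-less reads omit both constructs.

    Returns (squiggles, truths, fastq_records); fastq_records are
    Bio.SeqRecord objects carrying simulated basecalls with substitution
    errors at the rate implied by each read's simulated q-score.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    config = config or SimConfig()
    model = model or build_pore_model()
    rng = np.random.default_rng(seed)
    if not (0 <= config.no_barcode_rate <= 1 and 0 <= config.chimera_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    if config.no_barcode_rate + config.chimera_rate > 1:
        raise ValueError("no-barcode and chimera rates sum above 1")

    barcodes = barcodes or make_barcodes(config.n_barcodes)
    refs = refs or make_references(config.n_barcodes, config.ref_length)
    ref_ids = sorted(refs)
    bc_ids = sorted(barcodes)
    # amplicon design: barcode i sequences reference i
    bc_to_ref = {bc: ref_ids[i % len(ref_ids)] for i, bc in enumerate(bc_ids)}

    squiggles, truths, fastq_records = [], [], []
    for i in range(config.n_reads):
        read_id = f"sim_{i:05d}"
        u = rng.random()
        is_chimera = u < config.chimera_rate
        no_barcode = (not is_chimera) and u < config.chimera_rate + config.no_barcode_rate

        if no_barcode:
            bc = None
            insert_src = ref_ids[int(rng.integers(len(ref_ids)))]
            insert = refs[insert_src]
            seq_parts = [ADAPTER, insert, ADAPTER]
            construct_spans: list[tuple[int, int]] = []
        else:
            bc = int(rng.choice(bc_ids))
            if config.barcode_ref_coupling == "random":
                ref_a = ref_ids[int(rng.integers(len(ref_ids)))]
            else:
                ref_a = bc_to_ref[bc]
            start_construct = barcodes[bc].construct
            if is_chimera:
                other = int(rng.choice([b for b in bc_ids if b != bc]))
                if config.barcode_ref_coupling == "random":
                    ref_b = ref_ids[int(rng.integers(len(ref_ids)))]
                else:
                    ref_b = bc_to_ref[other]
                end_construct = revcomp(barcodes[other].construct)
                insert = refs[ref_a] + refs[ref_b]
                insert_src = f"{ref_a}+{ref_b}"
            else:
                end_construct = revcomp(barcodes[bc].construct)
                insert = refs[ref_a]
                insert_src = ref_a
            seq_parts = [ADAPTER, start_construct, insert, end_construct, ADAPTER]
            a = len(ADAPTER)
            construct_spans = [
                (a, a + CONSTRUCT_LEN),
                (a + CONSTRUCT_LEN + len(insert),
                 a + CONSTRUCT_LEN + len(insert) + CONSTRUCT_LEN),
            ]

        seq = "".join(seq_parts)
        true_q = float(np.clip(rng.normal(config.substitution_q_mean,
                                          config.substitution_q_sd), *config.q_range))
        mult = _noise_multiplier(true_q) if config.link_quality_to_noise else 1.0
        values, starts = _simulate_with_boundaries(seq, model, rng, noise_multiplier=mult)

        def span_to_samples(b0: int, b1: int) -> tuple[int, int]:
            # k-mers starting in [b0, b1-k+1) cover the construct bases
            k = model.k
            k0, k1 = b0, b1 - k + 1
            return int(starts[k0]), int(starts[k1])

        start_ivl = end_ivl = None
        if construct_spans:
            start_ivl = span_to_samples(*construct_spans[0])
            end_ivl = span_to_samples(*construct_spans[1])

        pad_lo, pad_hi = config.pad_range
        lead = int(rng.integers(pad_lo, pad_hi + 1))
        trail = int(rng.integers(pad_lo, pad_hi + 1))
        lead_pad = rng.normal(OPEN_PORE_LEVEL, OPEN_PORE_SD, size=lead)
        trail_pad = rng.normal(OPEN_PORE_LEVEL, OPEN_PORE_SD, size=trail)
        full = np.concatenate([lead_pad, values, trail_pad])
        raw = np.rint(_to_device_units(full))
        if start_ivl is not None:
            start_ivl = (start_ivl[0] + lead, start_ivl[1] + lead)
            end_ivl = (end_ivl[0] + lead, end_ivl[1] + lead)

        squiggles.append(Squiggle(read_id, raw, source="simulated"))
        truths.append(SimTruth(read_id, bc, insert_src, is_chimera,
                               start_ivl, end_ivl, true_q))

        # simulated basecall: substitutions at the error rate implied by q
        p_err = 10.0 ** (-true_q / 10.0)
        bases = np.array(list(seq))
        err_mask = rng.random(bases.size) < p_err
        if err_mask.any():
            shifts = rng.integers(1, 4, size=int(err_mask.sum()))
            codes = np.array([_BASE_INDEX[b] for b in bases[err_mask]])
            bases[err_mask] = [BASES[c] for c in (codes + shifts) % 4]
        quals = np.clip(np.rint(true_q + rng.normal(0, 1.0, size=bases.size)),
                        1, 50).astype(int)
        rec = SeqRecord(Seq("".join(bases)), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = list(quals)
        fastq_records.append(rec)

    return squiggles, truths, fastq_records


# ---------------------------------------------------------------------------
# no-barcode signal generators
# ---------------------------------------------------------------------------

def gen_flat(n: int, level: float = 0.0) -> np.ndarray:
    """Constant signal."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return np.full(n, level, dtype=np.float64)


def gen_gaussian(n: int, rng: np.random.Generator | int | None = None,
                 sd: float = 1.0) -> np.ndarray:
    """I.i.d. Gaussian noise."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return rng.normal(0.0, sd, size=n)


def gen_perlin(n: int, rng: np.random.Generator | int | None = None,
               scale: int = 64, octaves: int = 1) -> np.ndarray:
    """1-D Perlin (gradient) noise: smooth coherent noise, bounded in
    [-1, 1], exactly 0 at integer lattice points (before any octave
    mixing beyond the first).

    ``scale`` is the lattice spacing in samples; larger scale gives a
    smoother signal.  Gradient noise is visibly smoother than Gaussian
    noise — its lag-1 autocorrelation is near 1 rather than near 0 —
    which is what makes it a distinct no-barcode training class.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = np.zeros(n, dtype=np.float64)
    amp, sc = 1.0, scale
    for _ in range(octaves):
        n_lattice = n // sc + 2
        grads = rng.uniform(-1.0, 1.0, size=n_lattice)
        x = np.arange(n) / sc
        i0 = x.astype(int)
        t = x - i0
        fade = t * t * t * (t * (t * 6 - 15) + 10)  # 6t^5 - 15t^4 + 10t^3
        v0 = grads[i0] * t          # gradient ramp from the left lattice point
        v1 = grads[i0 + 1] * (t - 1.0)
        out += amp * ((1 - fade) * v0 + fade * v1)
        amp *= 0.5
        sc = max(1, sc // 2)
    return np.clip(out, -1.0, 1.0)


# ---------------------------------------------------------------------------
# on-disk library output
# ---------------------------------------------------------------------------

def write_library(out_dir: str | Path, squiggles: list[Squiggle],
                  truths: list[SimTruth], fastq_records: list,
                  config: SimConfig, signal_format: str = "text") -> None:
    """Write a simulated library: signals, FASTQ, truth TSV and run config."""
    from Bio import SeqIO

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sig_name = "signals.fast5" if signal_format == "fast5" else "signals.tsv"
    write_raw_signal(squiggles, out_dir / sig_name, format=signal_format)
    with open(out_dir / "reads.fastq", "w") as fh:
        SeqIO.write(fastq_records, fh, "fastq")
    with open(out_dir / "truth.tsv", "w") as fh:
        fh.write("read_id\tbarcode\tinsert\tchimera\tstart_ivl\tend_ivl\n")
        for t in truths:
            s_ivl = f"{t.start_barcode_interval[0]}-{t.start_barcode_interval[1]}" \
                if t.start_barcode_interval else "."
            e_ivl = f"{t.end_barcode_interval[0]}-{t.end_barcode_interval[1]}" \
                if t.end_barcode_interval else "."
            bc = t.barcode_id if t.barcode_id is not None else "none"
            fh.write(f"{t.read_id}\t{bc}\t{t.insert_source}\t"
                     f"{int(t.is_chimera)}\t{s_ivl}\t{e_ivl}\n")
    with open(out_dir / "run_config.json", "w") as fh:
        json.dump({"open_pore_threshold": config.open_pore_threshold,
                   "n_reads": config.n_reads,
                   "n_barcodes": config.n_barcodes,
                   "signal_format": signal_format}, fh, indent=1)


def read_truth_table(path: str | Path) -> list[SimTruth]:
    """Read a truth TSV back into SimTruth records."""
    truths = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            read_id, bc, insert, chim, s_ivl, e_ivl = line.rstrip("\n").split("\t")
            def parse_ivl(s):
                if s == ".":
                    return None
                a, b = s.split("-")
                return (int(a), int(b))
            truths.append(SimTruth(
                read_id,
                None if bc == "none" else int(bc),
                insert,
                bool(int(chim)),
                parse_ivl(s_ivl),
                parse_ivl(e_ivl),
            ))
    return truths
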