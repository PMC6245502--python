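"""Building labelled 1024-sample training sets.

Windows are cut from read signals so that each fully contains a located
barcode construct, with the construct's position jittered uniformly
within the window (so the classifier cannot memorise position).
Read-end windows are taken from the trailing signal and reversed, giving
both ends a common orientation so one architecture serves either end.

The 13th class — no barcode — mixes five signal subtypes: non-barcode
read signal, adapter-only signal, flat signal, Gaussian noise and Perlin
noise.  Their presence teaches the network to actively recognise
barcode-free signal rather than merely failing to match.

Augmentation distorts signals in the temporal dimension only: a quarter
of the positions are duplicated and a (disjoint) quarter deleted, giving
an equal-length signal elongated in some places and shortened in others.
Amplitude distortion is left to the network's Gaussian-noise layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from squigglebin.signal_io import Squiggle, znormalize, trim_open_pore
from squigglebin import simulator as sim

log = logging.getLogger(__name__)

WINDOW_LEN = 1024
NO_BARCODE = 0  # label 0; barcode b has label b

DEFAULT_NO_BARCODE_MIX = {
    "read": 0.50,      # non-barcode read signal (the hard negatives)
    "adapter": 0.14,   # adapter-only signal
    "flat": 0.06,
    "gaussian": 0.15,
    "perlin": 0.15,
}


@dataclass
class TrainingSample:
    """One 1024-value z-normalised window with its class label."""

    values: np.ndarray
    label: int  # 0 = no barcode, 1..n = barcode id
    end: str = "read_start"  # or "read_end"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.size != WINDOW_LEN:
            raise ValueError(f"training sample must have {WINDOW_LEN} values")


@dataclass
class TrainingSet:
    """A labelled window collection with provenance bookkeeping."""

    X: np.ndarray  # (n, 1024) float32
    y: np.ndarray  # (n,) int64
    end: str = "read_start"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float32)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y length mismatch")

    def __len__(self) -> int:
        return self.y.size

    @property
    def class_counts(self) -> dict[int, int]:
        labels, counts = np.unique(self.y, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


def extract_training_windows(values: np.ndarray,
                             barcode_interval: tuple[int, int],
                             label: int,
                             end: str = "read_start",
                             n_windows: int = 1,
                             rng: np.random.Generator | int | None = None,
                             ) -> list[TrainingSample]:
    """Cut jittered 1024-sample windows that fully contain the barcode.

    ``values`` is the open-pore-trimmed read signal; ``barcode_interval``
    is the construct's half-open sample range in those coordinates
    (from the simulator truth table or from locate_barcode).  For
    ``end="read_end"`` the signal and interval are reversed first, so
    emitted windows share the read-start orientation.

    Reads shorter than a window, or intervals longer than a window,
    yield no samples (with a warning).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    values = np.asarray(values, dtype=np.float64)
    L = values.size
    b0, b1 = barcode_interval
    if end == "read_end":
        values = values[::-1]
        b0, b1 = L - b1, L - b0
    elif end != "read_start":
        raise ValueError(f"unknown end: {end!r}")

    if L < WINDOW_LEN:
        log.warning("read of %d samples is shorter than one window, skipped", L)
        return []
    if b1 - b0 > WINDOW_LEN:
        log.warning("barcode interval of %d samples exceeds the window, skipped", b1 - b0)
        return []

    lo = max(0, b1 - WINDOW_LEN)        # window start must be <= b0 ...
    hi = min(b0, L - WINDOW_LEN)        # ... and window must fit in the read
    if hi < lo:
        log.warning("no window can contain interval [%d, %d) in a %d-sample read",
                    b0, b1, L)
        return []
    samples = []
    for _ in range(n_windows):
        start = int(rng.integers(lo, hi + 1))
        w = znormalize(values[start:start + WINDOW_LEN])
        samples.append(TrainingSample(w, label, end))
    return samples


def harvest_from_truth(squiggles: list[Squiggle], truths: list,
                       end: str = "read_start",
                       open_pore_threshold: float | None = sim.DEFAULT_OPEN_PORE_THRESHOLD,
                       n_windows: int = 1,
                       n_partial: int = 0,
                       partial_range: tuple[float, float] = (0.6, 0.95),
                       rng: np.random.Generator | int | None = None,
                       ) -> list[TrainingSample]:
    """Harvest barcode windows from a simulated library via its truth table.

    Besides ``n_windows`` fully-containing windows per read, ``n_partial``
    windows per read are cut so that only a fraction (``partial_range``)
    of the construct falls inside — the classifier's sliding windows
    routinely clip constructs at their edges, and a model that has never
    seen a clipped construct misreads them.

    Chimeric reads are excluded (their two ends disagree); barcode-less
    reads carry no interval and are skipped here — no-barcode samples
    come from make_no_barcode_samples instead.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    by_id = {t.read_id: t for t in truths}
    out: list[TrainingSample] = []
    for sq in squiggles:
        t = by_id.get(sq.read_id)
        if t is None or t.barcode_id is None or t.is_chimera:
            continue
        ivl = t.start_barcode_interval if end == "read_start" else t.end_barcode_interval
        if ivl is None:
            continue
        trimmed, offset, _ = trim_open_pore(sq.values, open_pore_threshold,
                                            trim_end=True, return_bounds=True)
        shifted = (ivl[0] - offset, ivl[1] - offset)
        if shifted[0] < 0 or shifted[1] > trimmed.size:
            continue  # trimming clipped the construct; unusable
        out.extend(extract_training_windows(trimmed, shifted, t.barcode_id,
                                            end=end, n_windows=n_windows, rng=rng))
        if n_partial:
            out.extend(_partial_windows(trimmed, shifted, t.barcode_id, end,
                                        n_partial, partial_range, rng))
    return out


def _partial_windows(values: np.ndarray, interval: tuple[int, int], label: int,
                     end: str, n: int, frac_range: tuple[float, float],
                     rng: np.random.Generator) -> list[TrainingSample]:
    """Windows containing only part of the construct, still barcode-labelled."""
    values = np.asarray(values, dtype=np.float64)
    L = values.size
    b0, b1 = interval
    if end == "read_end":
        values = values[::-1]
        b0, b1 = L - b1, L - b0
    span = b1 - b0
    if L < WINDOW_LEN or span >= WINDOW_LEN:
        return []
    out = []
    for _ in range(n):
        f = rng.uniform(*frac_range)
        if rng.random() < 0.5:  # clip the construct's left part
            start = int(round(b1 - f * span))
        else:                   # clip the right part
            start = int(round(b0 + f * span)) - WINDOW_LEN
        start = min(max(start, 0), L - WINDOW_LEN)
        w = znormalize(values[start:start + WINDOW_LEN])
        out.append(TrainingSample(w, label, end))
    return out


def harvest_by_dtw(squiggles: list[Squiggle], barcode_templates: dict,
                   end: str = "read_start",
                   open_pore_threshold: float | None = sim.DEFAULT_OPEN_PORE_THRESHOLD,
                   search_span: int = 3000,
                   n_windows: int = 1,
                   rng: np.random.Generator | int | None = None,
                   ) -> list[TrainingSample]:
    """Harvest barcode windows from unlabelled reads by DTW location.

    Only reads with a clear barcode match (normalised DTW cost below the
    locate threshold) contribute, mirroring training-set construction
    from real sequencing runs where no truth table exists.
    """
    from squigglebin.dtw_align import locate_barcode

    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out: list[TrainingSample] = []
    for sq in squiggles:
        trimmed = trim_open_pore(sq.values, open_pore_threshold, trim_end=True)
        region = trimmed[:search_span] if end == "read_start" else trimmed[-search_span:]
        if end == "read_end":
            region = region[::-1]
        hit = locate_barcode(region, barcode_templates)
        if hit is None:
            continue
        bc, (a, b) = hit
        # coordinates are within `region`, which is already oriented
        out.extend(extract_training_windows(region, (a, b), bc,
                                            end="read_start", n_windows=n_windows,
                                            rng=rng))
        for s in out[-n_windows:]:
            s.end = end
    return out


def harvest_no_barcode_windows(squiggles: list[Squiggle], truths: list,
                               end: str = "read_start",
                               open_pore_threshold: float | None = sim.DEFAULT_OPEN_PORE_THRESHOLD,
                               span: int = 6144,
                               n_windows: int = 2,
                               rng: np.random.Generator | int | None = None,
                               ) -> list[TrainingSample]:
    """Windows of real read signal that contain no part of a barcode.

    These are the non-barcode parts of actual reads — insert signal,
    adapter/insert seams — drawn from the same region the classifier
    will later window, which is what teaches the network to say
    no-barcode on the barcode-free windows of real reads rather than
    guessing a barcode from unfamiliar signal.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    by_id = {t.read_id: t for t in truths}
    out: list[TrainingSample] = []
    for sq in squiggles:
        t = by_id.get(sq.read_id)
        if t is None:
            continue
        trimmed, offset, _ = trim_open_pore(sq.values, open_pore_threshold,
                                            trim_end=True, return_bounds=True)
        values = trimmed if end == "read_start" else trimmed[::-1]
        L = values.size
        ivl = t.start_barcode_interval if end == "read_start" else t.end_barcode_interval
        if ivl is not None:
            a, b = ivl[0] - offset, ivl[1] - offset
            if end == "read_end":
                a, b = L - (ivl[1] - offset), L - (ivl[0] - offset)
            forbidden = (a, b)
        else:
            forbidden = None
        hi = min(span, L) - WINDOW_LEN
        if hi < 0:
            continue
        for _ in range(n_windows):
            for _attempt in range(20):
                start = int(rng.integers(0, hi + 1))
                if forbidden is None:
                    ok = True
                else:
                    a, b = forbidden
                    overlap = max(0, min(start + WINDOW_LEN, b) - max(start, a))
                    # a sliver of construct (<20%) is still no-barcode:
                    # the classifier's windows clip constructs the same way
                    ok = overlap <= 0.2 * (b - a)
                if ok:
                    w = znormalize(values[start:start + WINDOW_LEN])
                    out.append(TrainingSample(w, NO_BARCODE, end))
                    break
    return out


def mine_hard_negative_windows(squiggles: list[Squiggle], truths: list,
                               model, end: str = "read_start",
                               open_pore_threshold: float | None = sim.DEFAULT_OPEN_PORE_THRESHOLD,
                               spike_threshold: float = 0.12,
                               max_construct_overlap: float = 0.2,
                               ) -> list[TrainingSample]:
    """Barcode-free classification windows that a trained model misreads.

    Runs the model over the same sliding windows the classifier will
    use, on reads with known truth, and collects every window that
    contains (at most a sliver of) no construct yet receives barcode
    probability above ``spike_threshold``.  Because one confident wrong
    window can spoil a whole read's merged probability gap, a second
    training round on exactly these failures is far more effective than
    more randomly-sampled negatives.
    """
    from squigglebin.classifier import extract_windows, WindowConfig
    from squigglebin.network import predict_probs

    by_id = {t.read_id: t for t in truths}
    wc = WindowConfig()
    out: list[TrainingSample] = []
    for sq in squiggles:
        t = by_id.get(sq.read_id)
        if t is None:
            continue
        trimmed, offset, _ = trim_open_pore(sq.values, open_pore_threshold,
                                            trim_end=True, return_bounds=True)
        ivl = t.start_barcode_interval if end == "read_start" else t.end_barcode_interval
        windows = extract_windows(trimmed, end=end, config=wc)
        if windows.shape[0] == 0:
            continue
        probs = predict_probs(model, windows)
        L = trimmed.size
        for i, row in enumerate(probs):
            w0, w1 = i * wc.stride, i * wc.stride + wc.window_len
            if ivl is not None:
                a, b = ivl[0] - offset, ivl[1] - offset
                if end == "read_end":
                    a, b = L - (ivl[1] - offset), L - (ivl[0] - offset)
                overlap = max(0, min(w1, b) - max(w0, a)) / (b - a)
                if overlap > max_construct_overlap:
                    continue
            if np.delete(row, NO_BARCODE).max() > spike_threshold:
                out.append(TrainingSample(windows[i], NO_BARCODE, end))
    return out


def make_no_barcode_samples(n: int,
                            mix: dict[str, float] | None = None,
                            rng: np.random.Generator | int | None = None,
                            model: "sim.PoreModel | None" = None,
                            refs: dict[str, str] | None = None,
                            read_windows: list[TrainingSample] | None = None,
                            ) -> list[TrainingSample]:
    """Generate n windows of the no-barcode class from the subtype mix.

    The "read" subtype draws from ``read_windows`` (windows harvested
    from the non-barcode parts of real reads) when provided, falling
    back to freshly simulated barcode-free read signal otherwise.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    mix = dict(mix or DEFAULT_NO_BARCODE_MIX)
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError(f"no-barcode mix must sum to 1, got {sum(mix.values())}")
    unknown = set(mix) - {"read", "adapter", "flat", "gaussian", "perlin"}
    if unknown:
        raise ValueError(f"unknown no-barcode subtypes: {sorted(unknown)}")
    model = model or sim.build_pore_model()
    refs = refs or sim.make_references()
    ref_seqs = list(refs.values())

    subtypes = list(mix)
    probs = np.array([mix[s] for s in subtypes])
    draws = rng.choice(len(subtypes), size=n, p=probs)
    samples = []
    for d in draws:
        sub = subtypes[d]
        if sub == "flat":
            w = np.zeros(WINDOW_LEN)  # constant signal z-normalises to zeros
        elif sub == "gaussian":
            w = znormalize(sim.gen_gaussian(WINDOW_LEN, rng))
        elif sub == "perlin":
            w = znormalize(sim.gen_perlin(WINDOW_LEN, rng))
        elif sub == "read" and read_windows:
            w = read_windows[int(rng.integers(len(read_windows)))].values
        elif sub == "read":
            # a window of barcode-free read signal: random reference slice
            seq = ref_seqs[int(rng.integers(len(ref_seqs)))]
            need = int(np.ceil(WINDOW_LEN / model.dwell_mean)) + model.k + 20
            start = int(rng.integers(0, max(1, len(seq) - need)))
            sig = sim.simulate_squiggle(seq[start:start + need], model, rng)
            while sig.size < WINDOW_LEN:  # unlucky short dwells: extend
                sig = np.concatenate([sig, sim.simulate_squiggle(
                    seq[:need], model, rng)])
            w = znormalize(sig[:WINDOW_LEN])
        elif sub == "adapter":
            # adapter signal framed by open-pore level, as in an
            # adapter-only (no insert) read
            core = sim.simulate_squiggle(sim.ADAPTER, model, rng)
            pad = WINDOW_LEN - core.size
            lead = int(rng.integers(0, max(1, pad)))
            w = np.concatenate([
                rng.normal(sim.OPEN_PORE_LEVEL, sim.OPEN_PORE_SD, lead),
                core,
                rng.normal(sim.OPEN_PORE_LEVEL, sim.OPEN_PORE_SD, pad - lead)])
            w = znormalize(w[:WINDOW_LEN])
        samples.append(TrainingSample(w, NO_BARCODE))
        samples[-1].provenance = sub  # type: ignore[attr-defined]
    return samples


def augment_signal(values: np.ndarray,
                   rng: np.random.Generator | int | None = None,
                   fraction: float = 0.25) -> np.ndarray:
    """Temporal distortion: duplicate values at a quarter of the
    positions and delete values at a (disjoint) quarter.

    The output has exactly the input's length — elongated in some places
    and shortened in others — and contains no value absent from the
    input.  ``fraction=0`` is the identity.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    values = np.asarray(values)
    L = values.size
    d = int(L * fraction)
    if d == 0:
        return values.copy()
    if 2 * d > L:
        raise ValueError("distortion fraction too large: duplication and "
                         "deletion sets must be disjoint")
    pos = rng.permutation(L)
    repeats = np.ones(L, dtype=np.int64)
    repeats[pos[:d]] = 2      # duplicated positions
    repeats[pos[d:2 * d]] = 0  # deleted positions (disjoint)
    return np.repeat(values, repeats)


def assemble_training_set(extracted: list[TrainingSample],
                          no_barcode_fraction: float = 0.25,
                          augmentation_factor: int = 1,
                          rng: np.random.Generator | int | None = None,
                          mix: dict[str, float] | None = None,
                          model: "sim.PoreModel | None" = None,
                          refs: dict[str, str] | None = None,
                          read_windows: list[TrainingSample] | None = None,
                          ) -> TrainingSet:
    """Combine extracted barcode windows with generated no-barcode
    windows and optional augmentation into a shuffled TrainingSet.

    ``no_barcode_fraction`` is the no-barcode share of the final
    (pre-augmentation) set; ``augmentation_factor`` of 2 appends one
    time-distorted copy of every sample.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if not extracted:
        raise ValueError("no extracted samples to assemble")
    if not (0 <= no_barcode_fraction < 1):
        raise ValueError("no_barcode_fraction must lie in [0, 1)")
    if augmentation_factor < 1:
        raise ValueError("augmentation_factor must be >= 1")

    n_ext = len(extracted)
    n_nb = int(round(n_ext * no_barcode_fraction / (1.0 - no_barcode_fraction)))
    nb = make_no_barcode_samples(n_nb, mix=mix, rng=rng, model=model, refs=refs,
                                 read_windows=read_windows)

    all_samples = list(extracted) + nb
    X = np.stack([s.values for s in all_samples]).astype(np.float32)
    y = np.array([s.label for s in all_samples], dtype=np.int64)
    if augmentation_factor > 1:
        Xa = [X]
        for _ in range(augmentation_factor - 1):
            Xa.append(np.stack([augment_signal(x, rng) for x in X]).astype(np.float32))
        X = np.concatenate(Xa)
        y = np.tile(y, augmentation_factor)

    perm = rng.permutation(X.shape[0])
    end = extracted[0].end
    prov = {"extracted": n_ext, "no_barcode": n_nb,
            "augmentation_factor": augmentation_factor}
    return TrainingSet(X[perm], y[perm], end=end, provenance=prov)


def refine_by_cross_split(training_set: TrainingSet, trainer,
                          rng: np.random.Generator | int | None = None,
                          n_folds: int = 4) -> TrainingSet:
    """Purge ambiguous samples by a four-way split: classify each
    quarter with a model trained on the other three quarters, and
    discard samples whose predicted label disagrees with their training
    label.  The result is always a subset of the input.

    ``trainer`` is a callable ``trainer(X, y) -> predict`` where
    ``predict(X)`` returns integer labels (typically the network
    module's training routine at reduced settings).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = len(training_set)
    fold_of = rng.permutation(n) % n_folds
    keep = np.zeros(n, dtype=bool)
    for fold in range(n_folds):
        test = fold_of == fold
        Xtr, ytr = training_set.X[~test], training_set.y[~test]
        if np.unique(ytr).size < 2 or np.unique(training_set.y[test]).size < 1:
            raise ValueError(f"fold {fold}: training partition has fewer than 2 classes")
        predict = trainer(Xtr, ytr)
        pred = predict(training_set.X[test])
        keep[test] = pred == training_set.y[test]
    prov = dict(training_set.provenance)
    prov["refined_from"] = n
    log.info("cross-split refinement kept %d of %d samples", int(keep.sum()), n)
    return TrainingSet(training_set.X[keep], training_set.y[keep],
                       end=training_set.end, provenance=prov)


def network_trainer(epochs: int = 4, scale: float = 0.2, seed: int = 0,
                    samples_per_epoch: int | None = None):
    """The network module's training routine at reduced settings, in the
    shape refine_by_cross_split expects."""
    from squigglebin import network

    def trainer(X, y):
        cfg = network.desk_scale_config(scale=scale, n_groups=4,
                                        inception_after_group=2, seed=seed)
        model = network.build_model(cfg)
        tc = network.TrainConfig(epochs=epochs, samples_per_epoch=samples_per_epoch,
                                 augmentation_factor=1, seed=seed)
        network.train_model(model, (X, y), tc)

        def predict(Xq):
            return network.predict_probs(model, Xq).argmax(axis=1)
        return predict
    return trainer


# ---------------------------------------------------------------------------
# on-disk training sets: npz arrays + TSV label index
# ---------------------------------------------------------------------------

def save_training_set(ts: TrainingSet, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, X=ts.X, y=ts.y, end=np.array(ts.end))
    idx = path.with_suffix(".labels.tsv")
    with open(idx, "w") as fh:
        fh.write("index\tlabel\tend\n")
        for i, label in enumerate(ts.y):
            fh.write(f"{i}\t{label}\t{ts.end}\n")


def load_training_set(path: str | Path) -> TrainingSet:
    path = Path(path)
    if not path.exists() and path.with_suffix(".npz").exists():
        path = path.with_suffix(".npz")
    data = np.load(path)
    return TrainingSet(data["X"], data["y"], end=str(data["end"]))
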