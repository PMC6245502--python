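"""Semi-global dynamic time warping for locating signals inside reads.

The template (the expected signal of an adapter or barcode construct)
must be consumed end-to-end, while the read has free, unpenalised ends —
a subsequence search in signal space.  Local distance is |a - b| and the
step set is the symmetric three-step {diagonal, template-advance,
read-advance}, so the search is robust to the dwell-time warping that
makes the same sequence produce signals of different lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from squigglebin.signal_io import znormalize
from squigglebin.simulator import PoreModel, sequence_to_expected_signal


@dataclass
class DtwResult:
    """An alignment of a template into a read.

    ``read_start``/``read_end`` delimit the matched read interval
    (half-open, in samples); ``path`` is the ordered list of
    (template index, read index) pairs; ``cost`` is the path-summed
    local distance.
    """

    cost: float
    read_start: int
    read_end: int
    path: list[tuple[int, int]]

    @property
    def normalised_cost(self) -> float:
        """Cost per alignment step (path length), comparable across
        template lengths and robust to warping: a path that consumes
        many read samples is normalised by the steps it took."""
        return self.cost / len(self.path)


@njit(cache=False)
def _dtw_fill(template, read):  # pragma: no cover - exercised via semiglobal_dtw
    m, n = template.size, read.size
    D = np.empty((m, n), dtype=np.float64)
    for j in range(n):
        D[0, j] = abs(template[0] - read[j])  # free read prefix
    for i in range(1, m):
        D[i, 0] = abs(template[i] - read[0]) + D[i - 1, 0]
        for j in range(1, n):
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = abs(template[i] - read[j]) + best
    return D


def semiglobal_dtw(template: np.ndarray, read: np.ndarray) -> DtwResult:
    """Align a template end-to-end into a read with free read ends.

    Both inputs should be z-normalised (the function does not normalise,
    so callers can align in whatever units they have made comparable).
    Raises ``ValueError`` if the template is longer than the read.
    """
    template = np.ascontiguousarray(template, dtype=np.float64)
    read = np.ascontiguousarray(read, dtype=np.float64)
    if template.size == 0 or read.size == 0:
        raise ValueError("empty input to DTW")
    if template.size > read.size:
        raise ValueError(f"template ({template.size}) longer than read ({read.size})")

    D = _dtw_fill(template, read)
    m, n = template.size, read.size
    j_end = int(np.argmin(D[m - 1]))
    cost = float(D[m - 1, j_end])

    # traceback
    path = [(m - 1, j_end)]
    i, j = m - 1, j_end
    while i > 0:
        if j == 0:
            i -= 1
        else:
            local = abs(template[i] - read[j])
            if np.isclose(D[i, j], D[i - 1, j - 1] + local):
                i, j = i - 1, j - 1
            elif np.isclose(D[i, j], D[i - 1, j] + local):
                i -= 1
            else:
                j -= 1
        path.append((i, j))
    path.reverse()
    return DtwResult(cost=cost, read_start=path[0][1], read_end=j_end + 1, path=path)


def brute_force_semiglobal_cost(template: np.ndarray, read: np.ndarray) -> float:
    """Minimal semi-global cost by explicit enumeration of all monotone
    alignment paths.  Exponential: only for tiny instances; serves as an
    independent oracle for the DP implementation."""
    template = np.asarray(template, dtype=np.float64)
    read = np.asarray(read, dtype=np.float64)
    m, n = template.size, read.size
    best = [np.inf]

    def walk(i: int, j: int, cost: float) -> None:
        cost += abs(template[i] - read[j])
        if cost >= best[0]:
            return
        if i == m - 1:
            best[0] = min(best[0], cost)  # free read suffix
            return
        if i + 1 < m and j + 1 < n:
            walk(i + 1, j + 1, cost)
        if i + 1 < m:
            walk(i + 1, j, cost)
        if j + 1 < n:
            walk(i, j + 1, cost)

    for j0 in range(n):  # free read prefix
        walk(0, j0, 0.0)
    return float(best[0])


DEFAULT_COST_THRESHOLD = 0.23  # z-units per alignment step; see docs/methods.md

# Plausible construct-match span in samples.  The 40 bp construct covers
# ~35 k-mers at ~8.9 samples/base (mean ~311, typical range 250-600);
# noise "matches" betray themselves by warping the whole construct onto
# a far shorter read stretch.
CONSTRUCT_SPAN_RANGE = (120, 700)


@dataclass
class BarcodeTemplate:
    """Expected signal of adapter + 40 bp barcode construct, z-normalised.

    Aligning the adapter together with the construct anchors the match:
    reads without the construct (noise, or adapter-only reads) cannot
    borrow the adapter's good fit for the barcode region, which is what
    makes the normalised cost a usable accept/reject score.
    ``construct_start_sample`` is the template sample index where the
    construct region begins, used to report the construct's read interval.
    """

    barcode_id: int
    values: np.ndarray
    construct_start_sample: int


def build_barcode_templates(barcodes: dict, model: PoreModel,
                            dwell: int | None = None) -> dict[int, BarcodeTemplate]:
    """Expected adapter+construct signals for each barcode."""
    from squigglebin.simulator import ADAPTER

    if dwell is None:
        dwell = int(round(model.dwell_mean))
    templates = {}
    for bc, spec in barcodes.items():
        values = znormalize(sequence_to_expected_signal(ADAPTER + spec.construct, model,
                                                        dwell=dwell))
        construct_start = len(ADAPTER) * dwell  # first k-mer fully in the construct
        templates[bc] = BarcodeTemplate(bc, values, construct_start)
    return templates


def locate_barcode(read_signal: np.ndarray,
                   barcode_templates: dict[int, BarcodeTemplate],
                   cost_threshold: float = DEFAULT_COST_THRESHOLD,
                   span_range: tuple[int, int] = CONSTRUCT_SPAN_RANGE,
                   ) -> tuple[int, tuple[int, int]] | None:
    """Find the best-matching barcode construct in a read signal.

    The read signal (open-pore already trimmed) is z-normalised and each
    adapter+construct template is aligned by semi-global DTW.  The
    best-cost barcode is reported only if (a) its normalised cost is
    below ``cost_threshold`` and (b) the matched construct spans a
    dwell-plausible number of read samples (``span_range``) — a cheap
    match that squeezes the whole construct onto a few samples is noise,
    not a barcode.  Anything else is not a clear barcode signal and the
    read is unusable for training.  The returned half-open interval
    covers the construct region only (adapter excluded).
    """
    if not barcode_templates:
        raise ValueError("empty template set")
    read = znormalize(np.asarray(read_signal, dtype=np.float64))
    best, best_res = None, None
    for bc, template in barcode_templates.items():
        if template.values.size > read.size:
            continue
        res = semiglobal_dtw(template.values, read)
        if best_res is None or res.normalised_cost < best_res.normalised_cost:
            best, best_res = template, res
    if best_res is None or best_res.normalised_cost >= cost_threshold:
        return None
    construct_read_start = next(r for t, r in best_res.path
                                if t >= best.construct_start_sample)
    span = best_res.read_end - construct_read_start
    if not (span_range[0] <= span <= span_range[1]):
        return None
    return best.barcode_id, (construct_read_start, best_res.read_end)
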