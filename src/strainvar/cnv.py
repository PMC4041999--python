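"""Read-depth-ratio CNV detection between two strains.

Windows of dynamic size — each holding a fixed number of strain-A
unique read starts — equalize counting noise across coverage
fluctuations.  The library-size-normalized count ratio B/A flags
deletions (ratio < 0.3) and duplications (ratio > 1.6); consecutive
flagged windows merge into calls.  Two follow-up filters separate real
copy-number events from repeat-like regions: at least one strain's mean
coverage inside the call must sit near its genome mean (within ±0.5 x
mean), and deletions must show an uncovered-base fraction differing by
at least 10 percentage points between the strains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from strainvar.config import CnvParams


class CnvClass(str, Enum):
    DELETION_IN_A = "deletion_in_a"
    DELETION_IN_B = "deletion_in_b"
    DUPLICATION = "duplication"


@dataclass(frozen=True)
class CnvWindow:
    chrom: str
    start: int
    end: int
    count_a: int
    count_b: int
    ratio: float  # (count_b / count_a) x (total_a / total_b)


@dataclass
class CnvCall:
    chrom: str
    start: int
    end: int
    cnv_class: CnvClass
    mean_ratio: float
    n_windows: int
    uncovered_a: float = float("nan")  # fraction of bases with zero coverage
    uncovered_b: float = float("nan")
    mean_coverage_a: float = float("nan")
    mean_coverage_b: float = float("nan")
    passed_coverage_band: bool = True
    passed_uncovered_diff: bool = True


def _totals(track: dict[str, np.ndarray]) -> int:
    return int(sum(int(arr.sum()) for arr in track.values()))


def build_windows(
    counts_a: dict[str, np.ndarray],
    counts_b: dict[str, np.ndarray],
    params: CnvParams | None = None,
) -> list[CnvWindow]:
    """Cut each chromosome into consecutive windows of
    ``reads_per_window`` strain-A read starts and compute the
    normalized B/A count ratio per window.

    Window boundaries fall on whole positions, so a window can exceed
    the target by the multiplicity of its last position; the final
    window of a chromosome may be short.
    """
    params = params or CnvParams()
    total_a = _totals(counts_a)
    total_b = _totals(counts_b)
    if total_a == 0 or total_b == 0:
        return []
    norm = total_a / total_b
    windows: list[CnvWindow] = []
    for chrom in sorted(counts_a):
        a = np.asarray(counts_a[chrom], dtype=np.int64)
        b = np.asarray(counts_b.get(chrom, np.zeros_like(a)), dtype=np.int64)
        if len(b) != len(a):
            raise ValueError(f"track lengths differ on {chrom}")
        cum_a = np.cumsum(a)
        chrom_total = int(cum_a[-1]) if len(cum_a) else 0
        if chrom_total == 0:
            continue
        n_full = chrom_total // params.reads_per_window
        targets = np.arange(1, n_full + 1) * params.reads_per_window
        # boundary = first position where the cumulative count reaches the target
        bounds = np.searchsorted(cum_a, targets, side="left") + 1
        edges = [0, *bounds.tolist()]
        if edges[-1] < len(a):
            edges.append(len(a))
        cum_b = np.cumsum(b)

        def seg_sum(cum: np.ndarray, s: int, e: int) -> int:
            hi = int(cum[e - 1]) if e > 0 else 0
            lo = int(cum[s - 1]) if s > 0 else 0
            return hi - lo

        for s, e in zip(edges, edges[1:]):
            if e <= s:
                continue
            ca = seg_sum(cum_a, s, e)
            cb = seg_sum(cum_b, s, e)
            ratio = (cb / ca) * norm if ca > 0 else float("inf")
            windows.append(
                CnvWindow(chrom=chrom, start=s, end=e, count_a=ca, count_b=cb, ratio=ratio)
            )
    return windows


def classify_and_merge(
    windows: list[CnvWindow],
    params: CnvParams | None = None,
    genome_length: int | None = None,
    total_a: int | None = None,
) -> list[CnvCall]:
    """Merge consecutive same-side windows into calls.

    Ratio < ``del_ratio`` marks a deletion in strain B.  Ratio >
    ``dup_ratio`` is either a deletion in strain A or a duplication in
    B; the two are separated by strain A's read-start density in the
    window relative to its genome-wide mean (depleted A → deletion in
    A).  Runs shorter than ``min_event_windows`` are dropped.
    """
    params = params or CnvParams()
    if not windows:
        return []
    if total_a is None:
        total_a = sum(w.count_a for w in windows)
    if genome_length is None:
        genome_length = sum(w.end - w.start for w in windows)
    mean_density_a = total_a / max(genome_length, 1)
    # typical window span at genome-average strain-A coverage; a run of
    # flagged windows spanning at least min_event_windows of these is a
    # call even when it is a single (necessarily huge) window, as happens
    # for a deletion in strain A
    expected_span = params.reads_per_window / max(mean_density_a, 1e-12)

    def window_class(w: CnvWindow) -> CnvClass | None:
        if w.ratio < params.del_ratio:
            return CnvClass.DELETION_IN_B
        if w.ratio > params.dup_ratio:
            density_a = w.count_a / max(w.end - w.start, 1)
            if density_a < 0.5 * mean_density_a:
                return CnvClass.DELETION_IN_A
            return CnvClass.DUPLICATION
        return None

    calls: list[CnvCall] = []
    run: list[tuple[CnvWindow, CnvClass]] = []

    def flush() -> None:
        span = run[-1][0].end - run[0][0].start if run else 0
        if run and (
            len(run) >= params.min_event_windows
            or span >= params.min_event_windows * expected_span
        ):
            ws = [w for w, _c in run]
            calls.append(
                CnvCall(
                    chrom=ws[0].chrom,
                    start=ws[0].start,
                    end=ws[-1].end,
                    cnv_class=run[0][1],
                    mean_ratio=float(np.mean([w.ratio for w in ws])),
                    n_windows=len(ws),
                )
            )
        run.clear()

    prev_chrom = None
    for w in windows:
        cls = window_class(w)
        if (
            cls is None
            or w.chrom != prev_chrom
            or (run and cls is not run[0][1])
            or (run and w.start != run[-1][0].end)
        ):
            flush()
        if cls is not None:
            run.append((w, cls))
        prev_chrom = w.chrom
    flush()
    return calls


def _coverage_from_starts(starts: np.ndarray, read_length: int) -> np.ndarray:
    """Per-base coverage implied by read starts and a fixed read length."""
    cum = np.cumsum(np.asarray(starts, dtype=np.int64))
    cov = cum.copy()
    cov[read_length:] -= cum[:-read_length]
    return cov


def filter_calls(
    calls: list[CnvCall],
    counts_a: dict[str, np.ndarray],
    counts_b: dict[str, np.ndarray],
    params: CnvParams | None = None,
) -> list[CnvCall]:
    """Apply the coverage-band and uncovered-base filters.

    A call survives when at least one strain's mean coverage inside it
    lies within ±``coverage_band`` x (that strain's genome-wide mean) —
    regions where both strains sit far from their means behave like
    repeats.  Deletion calls additionally require the fractions of
    zero-coverage bases to differ by at least ``uncovered_diff``
    percentage points between the strains.  Per-base coverage is
    reconstructed from read starts with the fixed ``read_length``.
    """
    params = params or CnvParams()
    if not calls:
        return []
    coverage = {}
    genome_mean = {}
    for label, track in (("a", counts_a), ("b", counts_b)):
        cov = {c: _coverage_from_starts(arr, params.read_length) for c, arr in track.items()}
        coverage[label] = cov
        total = sum(int(v.sum()) for v in cov.values())
        size = sum(len(v) for v in cov.values())
        genome_mean[label] = total / max(size, 1)

    kept: list[CnvCall] = []
    for call in calls:
        cov_a = coverage["a"][call.chrom][call.start : call.end]
        cov_b = coverage["b"][call.chrom][call.start : call.end]
        call.mean_coverage_a = float(cov_a.mean())
        call.mean_coverage_b = float(cov_b.mean())
        in_band = False
        for label, mean_cov in (("a", call.mean_coverage_a), ("b", call.mean_coverage_b)):
            gm = genome_mean[label]
            if abs(mean_cov - gm) <= params.coverage_band * gm:
                in_band = True
        call.passed_coverage_band = in_band
        call.uncovered_a = float(np.count_nonzero(cov_a == 0) / max(len(cov_a), 1))
        call.uncovered_b = float(np.count_nonzero(cov_b == 0) / max(len(cov_b), 1))
        if call.cnv_class in (CnvClass.DELETION_IN_A, CnvClass.DELETION_IN_B):
            diff = abs(call.uncovered_a - call.uncovered_b) * 100.0
            call.passed_uncovered_diff = diff >= params.uncovered_diff
        else:
            call.passed_uncovered_diff = True
        if call.passed_coverage_band and call.passed_uncovered_diff:
            kept.append(call)
    return kept


def detect_cnvs(
    counts_a: dict[str, np.ndarray],
    counts_b: dict[str, np.ndarray],
    params: CnvParams | None = None,
) -> list[CnvCall]:
    """Full pipeline: windows → classify/merge → filters."""
    params = params or CnvParams()
    windows = build_windows(counts_a, counts_b, params)
    genome_length = sum(len(v) for v in counts_a.values())
    calls = classify_and_merge(
        windows, params, genome_length=genome_length, total_a=_totals(counts_a)
    )
    return filter_calls(calls, counts_a, counts_b, params)
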