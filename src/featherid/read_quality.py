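"""Per-read quality statistics (HQ%) and quality-based end trimming.

HQ% is the percentage of bases in a read at or above a Phred threshold
(default Q20, the conventional Sanger high-quality bar of ~1% error).  The
tiered classifier treats HQ% > 20 as the positive tier; reads without
qualities (FASTA input) are "not assessable" and can never reach the
positive tier on HQ grounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .formats_io import SampleRead

__all__ = ["QualityAssessment", "hq_percent", "trim_ends"]

DEFAULT_HQ_THRESHOLD_Q = 20


@dataclass(frozen=True)
class QualityAssessment:
    """``hq_percent`` is None when the read carries no quality scores."""

    hq_percent: Optional[float]
    n_bases: int
    threshold_q: int

    @property
    def assessable(self) -> bool:
        return self.hq_percent is not None


def hq_percent(read: SampleRead, threshold_q: int = DEFAULT_HQ_THRESHOLD_Q) -> QualityAssessment:
    """Exact percentage of bases with quality >= threshold_q."""
    if len(read.sequence) == 0:
        raise ValueError(f"read {read.read_id!r} is empty")
    if read.qualities is None:
        return QualityAssessment(None, len(read.sequence), threshold_q)
    n = len(read.qualities)
    n_hq = sum(1 for q in read.qualities if q >= threshold_q)
    return QualityAssessment(100.0 * n_hq / n, n, threshold_q)


def trim_ends(read: SampleRead, window: int = 10, mean_q_min: float = 20.0) -> SampleRead:
    """Trim low-quality ends using a sliding-window mean-quality rule.

    The leading cut is placed at the first window (size ``window``) whose
    mean quality reaches ``mean_q_min``; the trailing cut at the last such
    window.  A read with no acceptable window trims to empty.  Reads
    without qualities are returned unchanged.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if read.qualities is None:
        return read
    q = read.qualities
    n = len(q)
    if n < window:
        # too short to host a single window: keep only if overall mean passes
        if n > 0 and sum(q) / n >= mean_q_min:
            return read
        return read.slice(0, 0)
    # prefix sums for O(n) window means
    prefix = [0]
    for v in q:
        prefix.append(prefix[-1] + v)

    def wmean(i: int) -> float:
        return (prefix[i + window] - prefix[i]) / window

    start = next((i for i in range(n - window + 1) if wmean(i) >= mean_q_min), None)
    if start is None:
        return read.slice(0, 0)
    end_win = next(
        (i for i in range(n - window, -1, -1) if wmean(i) >= mean_q_min), None
    )
    assert end_win is not None  # start exists, so the reverse scan finds one
    end = end_win + window
    if end <= start:
        return read.slice(0, 0)
    return read.slice(start, end)
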