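"""Clustering of samples that may come from the same individual bird.

Two samples are candidate same-individual records when they were assigned
the same species, collected at the same facility within the same calendar
window (same ISO week, or same day as the stricter criterion), and their
sequences are identical — 100% matching over an aligned overlap of at
least ``min_overlap`` bases.  Identity over the overlap admits no
mismatches; the overlap floor guards against trivially short reads.
Clusters are transitive closures, since "same individual" is an
equivalence notion, and clustering is invariant to input order.

A sliding window ("sliding:7") is available where calendar weeks are too
coarse; the default is the deterministic ISO calendar week.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .similarity import ScoringScheme, local_align

__all__ = ["DedupRecord", "DedupCluster", "cluster_duplicates", "duplicate_fraction"]

logger = logging.getLogger("featherid")

# exact-overlap scoring: any mismatch or gap is prohibitive, so the optimal
# local alignment is the longest exact common substring and its score is
# that substring's length
_EXACT = ScoringScheme(match=1, mismatch=-(10 ** 6), gap_open=-(10 ** 6), gap_extend=-(10 ** 6))

DEFAULT_MIN_OVERLAP = 400


@dataclass(frozen=True)
class DedupRecord:
    sample_id: str
    site_id: str
    collection_date: _dt.date
    species: str
    sequence: str


@dataclass(frozen=True)
class DedupCluster:
    members: tuple[str, ...]
    site_id: str
    window: str
    representative_hash: str

    def __len__(self) -> int:
        return len(self.members)


def _identical_overlap(a: str, b: str, min_overlap: int) -> bool:
    if len(a) < min_overlap or len(b) < min_overlap:
        return False
    if a == b or a in b or b in a:
        return min(len(a), len(b)) >= min_overlap
    hit = local_align(a, b, _EXACT)
    return hit.score >= min_overlap


def _bucket_key(rec: DedupRecord, window: str):
    if window == "same_day":
        return (rec.site_id, rec.species, rec.collection_date)
    if window == "same_week":
        iso = rec.collection_date.isocalendar()
        return (rec.site_id, rec.species, (iso[0], iso[1]))
    return (rec.site_id, rec.species)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def cluster_duplicates(
    records: Iterable[DedupRecord],
    window: str = "same_week",
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> list[DedupCluster]:
    """Group potential same-individual samples (clusters of size >= 2).

    ``window`` is "same_day", "same_week" (ISO calendar weeks) or
    "sliding:<days>" for a pairwise date-difference criterion.  Records
    missing a date or site are excluded with a warning.
    """
    sliding_days: Optional[int] = None
    if window.startswith("sliding:"):
        sliding_days = int(window.split(":", 1)[1])
    elif window not in ("same_day", "same_week"):
        raise ValueError(f"unknown window {window!r}")

    recs = []
    for r in records:
        if not r.site_id or r.collection_date is None:
            logger.warning("dedup: sample %s missing site or date; excluded", r.sample_id)
            continue
        recs.append(r)
    recs.sort(key=lambda r: r.sample_id)  # input-order invariance

    buckets: dict[object, list[int]] = {}
    for i, r in enumerate(recs):
        buckets.setdefault(_bucket_key(r, window), []).append(i)

    uf = _UnionFind(len(recs))
    for members in buckets.values():
        for ai in range(len(members)):
            for bi in range(ai + 1, len(members)):
                a, b = recs[members[ai]], recs[members[bi]]
                if sliding_days is not None:
                    if abs((a.collection_date - b.collection_date).days) > sliding_days:
                        continue
                if _identical_overlap(a.sequence, b.sequence, min_overlap):
                    uf.union(members[ai], members[bi])

    groups: dict[int, list[int]] = {}
    for i in range(len(recs)):
        groups.setdefault(uf.find(i), []).append(i)

    clusters = []
    for idxs in groups.values():
        if len(idxs) < 2:
            continue
        ids = tuple(sorted(recs[i].sample_id for i in idxs))
        rep_seq = recs[min(idxs)].sequence
        clusters.append(
            DedupCluster(
                members=ids,
                site_id=recs[idxs[0]].site_id,
                window=window,
                representative_hash=hashlib.sha256(rep_seq.encode()).hexdigest()[:16],
            )
        )
    clusters.sort(key=lambda c: c.members)
    return clusters


def duplicate_fraction(clusters: Sequence[DedupCluster], n_total: int) -> float:
    """Percent of samples belonging to any multi-member cluster.

    This is the *maximum* fraction that could theoretically represent
    repeat finds of the same individual (flockmates can share a haplotype,
    so the true fraction is lower).
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    n_members = sum(len(c) for c in clusters)
    return 100.0 * n_members / n_total
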