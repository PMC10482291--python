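"""Local-alignment similarity search against a reference barcode database.

Every query is aligned to every reference with an exact affine-gap
Smith-Waterman (Gotoh) algorithm — no heuristic seeding.  At desk scale
(hundreds of references x ~600 bp reads) exhaustive alignment is fast
enough once jitted, and exactness makes the ranking reproducible.  An
optional k-mer prefilter (k=11, at least one shared k-mer) is available for
large databases.

Conventions, stated so they are testable:

* a gap of length k scores ``gap_open + (k-1) * gap_extend``;
* percent identity = 100 x matched columns / aligned columns, gap columns
  counting as non-matches (the usual BLAST-style convention);
* query coverage = 100 x aligned query bases / query length;
* traceback is deterministic: on ties diagonal > up (query base to gap)
  > left (subject base to gap), gap openings preferred over extensions,
  and the start cell is the first maximal cell in row-major order;
* IUPAC ambiguity codes are binary: a column is a match iff the two
  expansion sets intersect (no partial-match credit);
* both query orientations are searched and the better hit kept, since
  field reads have unknown strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from numba import njit

from .amplicon import reverse_complement
from .formats_io import BarcodeReference

__all__ = [
    "ScoringScheme",
    "AlignmentHit",
    "CandidateSet",
    "local_align",
    "search_database",
    "top_candidates",
]


@dataclass(frozen=True)
class ScoringScheme:
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5    # score of the first column of a gap
    gap_extend: int = -2  # each further gap column

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if not (self.gap_open <= self.gap_extend < 0):
            raise ValueError("need gap_open <= gap_extend < 0")


@dataclass(frozen=True)
class AlignmentHit:
    ref_id: str
    score: int
    identity_percent: float
    coverage_percent: float
    query_span: tuple[int, int]    # half-open, 0-based, in the searched orientation
    subject_span: tuple[int, int]
    orientation: str = "+"         # "+" query as given, "-" reverse complement


# IUPAC codes as 4-bit base masks; a match is a non-empty intersection.
_MASK = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "M": 3, "R": 5, "W": 9, "S": 6, "Y": 10, "K": 12,
    "V": 7, "H": 11, "D": 13, "B": 14, "N": 15,
}
_MASK_LUT = np.zeros(256, dtype=np.uint8)
for _c, _m in _MASK.items():
    _MASK_LUT[ord(_c)] = _m


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    masks = _MASK_LUT[arr]
    if (masks == 0).any():
        bad = sorted({seq[i] for i in np.nonzero(masks == 0)[0]})
        raise ValueError(f"sequence contains non-IUPAC characters {bad}")
    return masks


@njit(cache=False)
def _sw_kernel(q, s, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n = q.shape[0]
    m = s.shape[0]
    NEG = np.int64(-(10 ** 15))
    H = np.zeros((n + 1, m + 1), np.int64)
    E = np.full((n + 1, m + 1), NEG, np.int64)
    F = np.full((n + 1, m + 1), NEG, np.int64)
    ptr = np.zeros((n + 1, m + 1), np.uint8)    # 0 stop, 1 diag, 2 up, 3 left
    eopen = np.zeros((n + 1, m + 1), np.uint8)  # E came from H (gap opening)
    fopen = np.zeros((n + 1, m + 1), np.uint8)
    best = np.int64(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            eo = H[i, j - 1] + gap_open
            ee = E[i, j - 1] + gap_extend
            if eo >= ee:
                E[i, j] = eo
                eopen[i, j] = 1
            else:
                E[i, j] = ee
            fo = H[i - 1, j] + gap_open
            fe = F[i - 1, j] + gap_extend
            if fo >= fe:
                F[i, j] = fo
                fopen[i, j] = 1
            else:
                F[i, j] = fe
            if (q[i - 1] & s[j - 1]) != 0:
                sub = match
            else:
                sub = mismatch
            h = H[i - 1, j - 1] + sub
            p = 1
            if F[i, j] > h:
                h = F[i, j]
                p = 2
            if E[i, j] > h:
                h = E[i, j]
                p = 3
            if h <= 0:
                h = 0
                p = 0
            H[i, j] = h
            ptr[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback
    i = bi
    j = bj
    state = 0  # 0 in H, 2 in F (up gaps), 3 in E (left gaps)
    matches = 0
    aligned = 0
    while True:
        if state == 0:
            p = ptr[i, j]
            if p == 0:
                break
            if p == 1:
                aligned += 1
                if (q[i - 1] & s[j - 1]) != 0:
                    matches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:
            aligned += 1
            if fopen[i, j]:
                i -= 1
                state = 0
            else:
                i -= 1
        else:
            aligned += 1
            if eopen[i, j]:
                j -= 1
                state = 0
            else:
                j -= 1
    return best, matches, aligned, i, bi, j, bj


def local_align(
    query: str,
    subject: str,
    scoring: ScoringScheme = ScoringScheme(),
    ref_id: str = "",
    orientation: str = "+",
) -> AlignmentHit:
    """Optimal local alignment of query vs subject under affine-gap scoring."""
    if not query or not subject:
        raise ValueError("local_align requires nonempty sequences")
    score, matches, aligned, qs, qe, ss, se = _sw_kernel(
        _encode(query),
        _encode(subject),
        scoring.match,
        scoring.mismatch,
        scoring.gap_open,
        scoring.gap_extend,
    )
    identity = 100.0 * matches / aligned if aligned else 0.0
    coverage = 100.0 * (qe - qs) / len(query)
    return AlignmentHit(
        ref_id=ref_id,
        score=int(score),
        identity_percent=identity,
        coverage_percent=coverage,
        query_span=(qs, qe),
        subject_span=(ss, se),
        orientation=orientation,
    )


def _hit_rank_key(hit: AlignmentHit):
    return (-hit.identity_percent, -hit.coverage_percent, -hit.score, hit.ref_id)


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def search_database(
    query: str,
    references: Sequence[BarcodeReference],
    scoring: ScoringScheme = ScoringScheme(),
    min_report_identity: float = 90.0,
    try_reverse_complement: bool = True,
    prefilter: bool = False,
    prefilter_k: int = 11,
) -> list[AlignmentHit]:
    """Rank all references against a query read.

    Hits below ``min_report_identity`` (default 90, deliberately below the
    95% assignment floor so near-threshold cases stay visible) are dropped.
    Sorting is identity desc, coverage desc, score desc, ref_id asc, so
    byte-identical references land adjacent with equal metrics.
    """
    if not references:
        raise ValueError("reference database is empty")
    queries = [(query, "+")]
    if try_reverse_complement:
        queries.append((reverse_complement(query), "-"))
    if prefilter:
        qmers: set[str] = set()
        for q, _ in queries:
            qmers |= _kmers(q, prefilter_k)
        references = [
            r for r in references if qmers & _kmers(r.sequence, prefilter_k)
        ] or list(references)  # fall back to the full set rather than return nothing
    hits: list[AlignmentHit] = []
    for ref in references:
        best: Optional[AlignmentHit] = None
        for q, orient in queries:
            hit = local_align(q, ref.sequence, scoring, ref_id=ref.ref_id, orientation=orient)
            # orientation is chosen by alignment score: score weighs length
            # and identity together, so a spurious short perfect match on
            # the wrong strand cannot displace a full-length hit
            if best is None or hit.score > best.score:  # ties keep "+"
                best = hit
        assert best is not None
        if best.identity_percent >= min_report_identity:
            hits.append(best)
    hits.sort(key=_hit_rank_key)
    return hits


@dataclass(frozen=True)
class CandidateSet:
    """Outcome of tie resolution: one species, or a sister-taxon co-report."""

    species: tuple[str, ...]
    best: Optional[AlignmentHit]

    def __bool__(self) -> bool:
        return bool(self.species)


def top_candidates(
    hits: Sequence[AlignmentHit],
    species_of: Union[Mapping[str, str], Sequence[BarcodeReference]],
    identity_tie_epsilon: float = 0.5,
) -> CandidateSet:
    """Resolve ranked hits to candidate species.

    All hits within ``identity_tie_epsilon`` percentage points of the best
    identity compete; among them the highest coverage wins (coverage as the
    preferential tie parameter).  If two or more distinct species remain
    metric-identical (equal identity and coverage), all are co-reported —
    the sister-taxon case where barcodes cannot separate the pair.
    """
    if not hits:
        return CandidateSet((), None)
    if not isinstance(species_of, Mapping):
        species_of = {r.ref_id: r.species for r in species_of}
    best_identity = max(h.identity_percent for h in hits)
    pool = [h for h in hits if h.identity_percent >= best_identity - identity_tie_epsilon]
    pool.sort(key=lambda h: (-h.coverage_percent, -h.identity_percent, -h.score, h.ref_id))
    top = pool[0]
    tied = [
        h
        for h in pool
        if h.coverage_percent == top.coverage_percent
        and h.identity_percent == top.identity_percent
    ]
    species: list[str] = []
    for h in tied:
        sp = species_of[h.ref_id]
        if sp not in species:
            species.append(sp)
    if len(species) >= 2:
        return CandidateSet(tuple(sorted(species)), top)
    return CandidateSet((species_of[top.ref_id],), top)
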