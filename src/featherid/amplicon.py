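"""Degenerate-primer matching and in-silico PCR.

The four built-in primers are the degenerate avian CO1 oligos used in the
field protocol this toolkit automates:

* set 1: L7036 / H7548 spanning a 512 bp target region,
* set 2: L7525 / H8121 spanning an adjacent 596 bp fragment.

A primer binds a template window when at most ``max_mismatch`` positions are
IUPAC-incompatible *and* the 3 bases at the primer's 3' end are all
compatible (the 3'-anchor rule: polymerase extension needs a matched 3'
end).  Template ``N`` is incompatible with every primer code except ``N``,
which keeps masked bases from producing false priming sites.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .formats_io import PrimerSet

__all__ = [
    "IUPAC_EXPANSION",
    "DegeneratePrimer",
    "PrimerSite",
    "Amplicon",
    "PRIMERS",
    "PRIMER_PAIRS",
    "Strand",
    "reverse_complement",
    "iupac_compatible",
    "find_primer_sites",
    "in_silico_pcr",
    "compute_sar",
]

IUPAC_EXPANSION: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

ANCHOR_LEN = 3  # 3' bases that must match exactly


class Strand(str, enum.Enum):
    PLUS = "plus"
    MINUS = "minus"


class Orientation(str, enum.Enum):
    FORWARD = "forward"
    REVERSE = "reverse"


@dataclass(frozen=True)
class DegeneratePrimer:
    name: str
    iupac_sequence: str
    orientation: Orientation

    def __post_init__(self) -> None:
        if not self.iupac_sequence:
            raise ValueError(f"primer {self.name!r}: empty sequence")
        bad = set(self.iupac_sequence) - set(IUPAC_EXPANSION)
        if bad:
            raise ValueError(f"primer {self.name!r}: invalid IUPAC codes {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.iupac_sequence)


# Built-in degenerate CO1 primer constants (5'->3').
PRIMERS: dict[str, DegeneratePrimer] = {
    "L7036": DegeneratePrimer("L7036", "GGNACNGGNTGAACHGTNTAYCC", Orientation.FORWARD),
    "H7548": DegeneratePrimer("H7548", "GTDGCNGANGTRAARTADGCTCG", Orientation.REVERSE),
    "L7525": DegeneratePrimer("L7525", "GTNTGRGCHCAYCAYATRTTYAC", Orientation.FORWARD),
    "H8121": DegeneratePrimer("H8121", "GGGCAGCCRTGRATTCAYTC", Orientation.REVERSE),
}

PRIMER_PAIRS: dict[PrimerSet, tuple[DegeneratePrimer, DegeneratePrimer]] = {
    PrimerSet.SET1: (PRIMERS["L7036"], PRIMERS["H7548"]),
    PrimerSet.SET2: (PRIMERS["L7525"], PRIMERS["H8121"]),
}


@dataclass(frozen=True)
class PrimerSite:
    """One primer binding site; ``start`` is the plus-strand leftmost offset."""

    start: int
    strand: Strand
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    sequence: str
    primer_set: Optional[PrimerSet]
    template_span: tuple[int, int]  # half-open, 0-based

    def __len__(self) -> int:
        return len(self.sequence)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_compatible(template_base: str, primer_code: str) -> bool:
    """True iff the template base is within the primer code's expansion.

    Template N matches nothing unless the primer code is itself N.
    """
    if primer_code not in IUPAC_EXPANSION:
        raise ValueError(f"invalid IUPAC code {primer_code!r}")
    if template_base not in ("A", "C", "G", "T", "N"):
        raise ValueError(f"invalid template base {template_base!r}")
    if template_base == "N":
        return primer_code == "N"
    return template_base in IUPAC_EXPANSION[primer_code]


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _compat_table(primer: str) -> np.ndarray:
    """(primer_len, 5) boolean table: table[i, b] = base b compatible at i."""
    table = np.zeros((len(primer), 5), dtype=bool)
    for i, code in enumerate(primer):
        for base, j in _BASE_INDEX.items():
            table[i, j] = iupac_compatible(base, code)
    return table


def _scan_one_strand(template_codes: np.ndarray, primer: str, max_mismatch: int) -> list[tuple[int, int]]:
    """(offset, mismatches) for windows satisfying mismatch + 3'-anchor rules."""
    m = len(primer)
    n = template_codes.size
    if n < m:
        return []
    table = _compat_table(primer)
    windows = np.lib.stride_tricks.sliding_window_view(template_codes, m)
    compat = table[np.arange(m)[None, :], windows]  # (n-m+1, m)
    mism = (~compat).sum(axis=1)
    anchored = compat[:, m - ANCHOR_LEN :].all(axis=1)
    hits = np.nonzero((mism <= max_mismatch) & anchored)[0]
    return [(int(o), int(mism[o])) for o in hits]


def find_primer_sites(
    template: str, primer: DegeneratePrimer | str, max_mismatch: int = 2
) -> list[PrimerSite]:
    """Scan both strands of the template for primer binding sites.

    Reverse-strand sites are reported in plus-strand coordinates (leftmost
    offset of the binding window).  Sites are sorted by start position.
    """
    seq = primer.iupac_sequence if isinstance(primer, DegeneratePrimer) else primer
    bad = set(template) - set("ACGTN")
    if bad:
        raise ValueError(f"template contains non-ACGTN characters {sorted(bad)}")
    codes = np.fromiter((_BASE_INDEX[b] for b in template), dtype=np.int8, count=len(template))
    m = len(seq)
    sites = [
        PrimerSite(start, Strand.PLUS, mm)
        for start, mm in _scan_one_strand(codes, seq, max_mismatch)
    ]
    rc = reverse_complement(template)
    rc_codes = np.fromiter((_BASE_INDEX[b] for b in rc), dtype=np.int8, count=len(rc))
    for start, mm in _scan_one_strand(rc_codes, seq, max_mismatch):
        plus_start = len(template) - start - m
        sites.append(PrimerSite(plus_start, Strand.MINUS, mm))
    sites.sort(key=lambda s: (s.start, s.strand.value))
    return sites


def in_silico_pcr(
    template: str,
    primer_pair: tuple[DegeneratePrimer, DegeneratePrimer],
    max_mismatch: int = 2,
    max_product_len: int = 2000,
    primer_set: Optional[PrimerSet] = None,
) -> list[Amplicon]:
    """Extract every amplicon a forward/reverse primer pair would produce.

    A product forms for each (forward plus-strand site, reverse minus-strand
    site) pair with the forward site upstream of the reverse site's end and
    product length at most ``max_product_len``.  The returned sequence
    includes both primer-binding termini, matching how a sequenced PCR
    product is reported.  An empty list means amplification failure.
    """
    forward, reverse = primer_pair
    fwd_all = find_primer_sites(template, forward, max_mismatch)
    rev_all = find_primer_sites(template, reverse, max_mismatch)
    spans: set[tuple[int, int]] = set()
    # canonical configuration: forward on plus strand, reverse on minus
    for f in (s for s in fwd_all if s.strand == Strand.PLUS):
        for r in (s for s in rev_all if s.strand == Strand.MINUS):
            end = r.start + len(reverse)
            if f.start < end and (end - f.start) <= max_product_len:
                spans.add((f.start, end))
    # flipped configuration (the same duplex seen from the other strand):
    # reverse primer on plus, forward on minus — keeps PCR strand-symmetric
    for r in (s for s in rev_all if s.strand == Strand.PLUS):
        for f in (s for s in fwd_all if s.strand == Strand.MINUS):
            end = f.start + len(forward)
            if r.start < end and (end - r.start) <= max_product_len:
                spans.add((r.start, end))
    return [
        Amplicon(template[a:b], primer_set, (a, b)) for a, b in sorted(spans)
    ]


def compute_sar(n_detectable_products: int, n_samples_processed: int) -> float:
    """Successful amplification rate: detectable products / samples processed."""
    if n_samples_processed <= 0:
        raise ValueError("n_samples_processed must be positive")
    if not 0 <= n_detectable_products <= n_samples_processed:
        raise ValueError("n_detectable_products outside [0, n_samples_processed]")
    return n_detectable_products / n_samples_processed
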