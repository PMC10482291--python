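"""Independent brute-force oracles used only by the test suite.

These re-derive expected values from first principles (naive scans, full
dynamic programming in pure Python, textbook formulas) without touching
the package's implementation paths.
"""

from __future__ import annotations

from typing import Optional

IUPAC = {
    "A": set("A"), "C": set("C"), "G": set("G"), "T": set("T"),
    "R": set("AG"), "Y": set("CT"), "S": set("CG"), "W": set("AT"),
    "K": set("GT"), "M": set("AC"), "B": set("CGT"), "D": set("AGT"),
    "H": set("ACT"), "V": set("ACG"), "N": set("ACGT"),
}

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def compatible(template_base: str, code: str) -> bool:
    if template_base == "N":
        return code == "N"
    return template_base in IUPAC[code]


def primer_sites_bruteforce(template: str, primer: str, max_mismatch: int, anchor: int = 3):
    """(start, strand, mismatches) by position-by-position scan of both strands."""
    out = []
    m = len(primer)

    def scan(seq: str):
        for off in range(len(seq) - m + 1):
            mism = sum(
                0 if compatible(seq[off + k], primer[k]) else 1 for k in range(m)
            )
            anchored = all(compatible(seq[off + k], primer[k]) for k in range(m - anchor, m))
            if mism <= max_mismatch and anchored:
                yield off, mism

    for off, mism in scan(template):
        out.append((off, "plus", mism))
    rc = revcomp(template)
    for off, mism in scan(rc):
        out.append((len(template) - off - m, "minus", mism))
    return sorted(out)


def sw_affine_oracle(q: str, s: str, match=2, mismatch=-3, gap_open=-5, gap_extend=-2):
    """Full affine-gap local DP with the stated deterministic tie rules.

    Returns (score, matches, aligned_columns, (q_start, q_end), (s_start, s_end)).
    Tie rules: diagonal > up (query base to gap) > left; gap openings beat
    extensions; the start cell is the first maximum in row-major order.
    A match is a non-empty IUPAC expansion intersection.
    """
    n, m = len(q), len(s)
    NEG = -(10 ** 15)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    ptr = [[0] * (m + 1) for _ in range(n + 1)]
    eop = [[False] * (m + 1) for _ in range(n + 1)]
    fop = [[False] * (m + 1) for _ in range(n + 1)]

    def is_match(a: str, b: str) -> bool:
        return bool(IUPAC[a] & IUPAC[b])

    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            eo, ee = H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend
            if eo >= ee:
                E[i][j], eop[i][j] = eo, True
            else:
                E[i][j] = ee
            fo, fe = H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend
            if fo >= fe:
                F[i][j], fop[i][j] = fo, True
            else:
                F[i][j] = fe
            sub = match if is_match(q[i - 1], s[j - 1]) else mismatch
            h, p = H[i - 1][j - 1] + sub, 1
            if F[i][j] > h:
                h, p = F[i][j], 2
            if E[i][j] > h:
                h, p = E[i][j], 3
            if h <= 0:
                h, p = 0, 0
            H[i][j], ptr[i][j] = h, p
            if h > best:
                best, bi, bj = h, i, j

    i, j, state = bi, bj, 0
    matches = aligned = 0
    while True:
        if state == 0:
            p = ptr[i][j]
            if p == 0:
                break
            if p == 1:
                aligned += 1
                if is_match(q[i - 1], s[j - 1]):
                    matches += 1
                i, j = i - 1, j - 1
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:
            aligned += 1
            if fop[i][j]:
                i, state = i - 1, 0
            else:
                i -= 1
        else:
            aligned += 1
            if eop[i][j]:
                j, state = j - 1, 0
            else:
                j -= 1
    return best, matches, aligned, (i, bi), (j, bj)


def categorize_tier_table(identity: Optional[float], coverage: Optional[float],
                          hq: Optional[float], phenology: str) -> str:
    """Brute-force rule-table combination: per-criterion tiers, worst wins,
    positive requires every criterion in the positive tier."""
    if identity is None or coverage is None:
        return "no_identification"
    tiers = []
    # identity
    if identity > 97:
        tiers.append("pos")
    elif identity >= 95:
        tiers.append("quest")
    else:
        tiers.append("no")
    # coverage
    if coverage > 50:
        tiers.append("pos")
    elif coverage >= 30:
        tiers.append("quest")
    else:
        tiers.append("no")
    # hq (never fatal on its own)
    tiers.append("pos" if (hq is not None and hq > 20) else "quest")
    # phenology
    tiers.append(
        {"consistent": "pos", "unknown": "pos", "unlikely": "quest", "inconsistent": "no"}[phenology]
    )
    if "no" in tiers:
        return "no_identification"
    if all(t == "pos" for t in tiers):
        return "positive"
    return "questionable"


def pearson_chi2_oracle(table):
    """Textbook Pearson statistic from explicit loops."""
    r, c = len(table), len(table[0])
    row = [sum(table[i]) for i in range(r)]
    col = [sum(table[i][j] for i in range(r)) for j in range(c)]
    total = sum(row)
    stat = 0.0
    for i in range(r):
        for j in range(c):
            e = row[i] * col[j] / total
            stat += (table[i][j] - e) ** 2 / e
    return stat, (r - 1) * (c - 1)


def trim_span_oracle(quals, window, mean_q_min):
    """Exhaustive prefix/suffix scan for the trim span; None if empty."""
    n = len(quals)
    if n < window:
        return (0, n) if n and sum(quals) / n >= mean_q_min else None
    start = None
    for i in range(n - window + 1):
        if sum(quals[i : i + window]) / window >= mean_q_min:
            start = i
            break
    if start is None:
        return None
    end = None
    for j in range(n, window - 1, -1):
        if sum(quals[j - window : j]) / window >= mean_q_min:
            end = j
            break
    if end is None or end <= start:
        return None
    return (start, end)
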