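"""Ecological-group mapping and proportion comparisons.

Samples are binned into three broad avian groups — Terrestrial Birds
(non-passerines such as raptors, landfowl and hummingbirds), Songbirds
(passerines) and Waterbirds (ducks, geese, gulls, grebes) — by taxonomic
order, and group compositions are compared across identification methods
or solar technologies with a Pearson chi-squared test for proportions.

The order-to-group map ships as an editable default (and can be supplied
as a TSV), so users with an authoritative regional list can substitute
their own.  No continuity correction is applied by default (the intended
tables are large-count); a flag enables it for 2x2 tables.  The
chi-squared p-value is computed in-package from the regularized upper
incomplete gamma function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .classify import Category, IdentificationResult
from .formats_io import (
    BarcodeReference,
    EcoGroup,
    SampleMetadata,
    UNKNOWN_MORPHOLOGY,
)

__all__ = [
    "DEFAULT_GROUP_MAP",
    "Chi2Result",
    "GroupTally",
    "assign_group",
    "read_group_map_tsv",
    "chi2_sf",
    "chi2_proportions",
    "proportions_report",
]

DEFAULT_GROUP_MAP: dict[str, EcoGroup] = {
    "Passeriformes": EcoGroup.SONGBIRD,
    "Anseriformes": EcoGroup.WATERBIRD,
    "Charadriiformes": EcoGroup.WATERBIRD,
    "Podicipediformes": EcoGroup.WATERBIRD,
    "Pelecaniformes": EcoGroup.WATERBIRD,
    "Galliformes": EcoGroup.TERRESTRIAL,
    "Apodiformes": EcoGroup.TERRESTRIAL,
    "Accipitriformes": EcoGroup.TERRESTRIAL,
    "Falconiformes": EcoGroup.TERRESTRIAL,
    "Strigiformes": EcoGroup.TERRESTRIAL,
    "Columbiformes": EcoGroup.TERRESTRIAL,
    "Caprimulgiformes": EcoGroup.TERRESTRIAL,
    "Piciformes": EcoGroup.TERRESTRIAL,
    "Cuculiformes": EcoGroup.TERRESTRIAL,
}

GROUP_ORDER = (EcoGroup.TERRESTRIAL, EcoGroup.SONGBIRD, EcoGroup.WATERBIRD)


def assign_group(order_name: str, group_map: Optional[Mapping[str, EcoGroup]] = None) -> EcoGroup:
    """Map a taxonomic order to its broad group; unknown orders are an error
    (no silent bucket)."""
    gmap = DEFAULT_GROUP_MAP if group_map is None else group_map
    try:
        return gmap[order_name]
    except KeyError:
        raise ValueError(
            f"order {order_name!r} is not in the group map; add it to the map TSV"
        ) from None


def read_group_map_tsv(path: str | Path) -> dict[str, EcoGroup]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {rec["order_name"]: EcoGroup(rec["eco_group"]) for rec in df.to_dict("records")}


# ---------------------------------------------------------------------------
# Chi-squared machinery (own survival function via incomplete gamma)

_GAMMA_EPS = 1e-15
_GAMMA_ITMAX = 2000


def _gamma_series_p(a: float, x: float) -> float:
    """Regularized lower incomplete gamma P(a, x) by power series (x < a+1)."""
    ap = a
    term = 1.0 / a
    total = term
    for _ in range(_GAMMA_ITMAX):
        ap += 1.0
        term *= x / ap
        total += term
        if abs(term) < abs(total) * _GAMMA_EPS:
            break
    return total * math.exp(-x + a * math.log(x) - math.lgamma(a))


def _gamma_contfrac_q(a: float, x: float) -> float:
    """Regularized upper incomplete gamma Q(a, x) by continued fraction (x >= a+1)."""
    tiny = 1e-300
    b = x + 1.0 - a
    c = 1.0 / tiny
    d = 1.0 / b
    h = d
    for i in range(1, _GAMMA_ITMAX + 1):
        an = -i * (i - a)
        b += 2.0
        d = an * d + b
        if abs(d) < tiny:
            d = tiny
        c = b + an / c
        if abs(c) < tiny:
            c = tiny
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < _GAMMA_EPS:
            break
    return math.exp(-x + a * math.log(x) - math.lgamma(a)) * h


def _gammaincc(a: float, x: float) -> float:
    """Regularized upper incomplete gamma Q(a, x) = Gamma(a, x) / Gamma(a)."""
    if x < 0 or a <= 0:
        raise ValueError("need x >= 0 and a > 0")
    if x == 0:
        return 1.0
    if x < a + 1.0:
        return 1.0 - _gamma_series_p(a, x)
    return _gamma_contfrac_q(a, x)


def chi2_sf(statistic: float, df: int) -> float:
    """Survival function of the chi-squared distribution."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if statistic < 0:
        return 1.0
    return _gammaincc(df / 2.0, statistic / 2.0)


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p_value: float
    n: int


def chi2_proportions(table, continuity_correction: bool = False) -> Chi2Result:
    """Pearson chi-squared test of homogeneity on a contingency table.

    Expected counts come from the row/column marginals; a zero marginal is
    an error because the corresponding expected counts vanish.  The
    optional Yates continuity correction applies to 2x2 tables only.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero marginal: drop the empty row/column first")
    expected = np.outer(row, col) / total
    diff = np.abs(obs - expected)
    if continuity_correction and obs.shape == (2, 2):
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return Chi2Result(statistic=stat, df=df, p_value=chi2_sf(stat, df), n=int(total))


# ---------------------------------------------------------------------------
# Cross-tabulated proportion reports


@dataclass(frozen=True)
class GroupTally:
    counts: pd.DataFrame       # rows = facet levels, columns = eco groups
    percentages: pd.DataFrame  # per-row percentages, nearest integer
    chi2: Optional[Chi2Result]  # None when the table degenerates below 2x2


def _percent_rows(counts: pd.DataFrame) -> pd.DataFrame:
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    return pct.round(0).astype(int)


def proportions_report(
    results: Sequence[IdentificationResult],
    metadata: Sequence[SampleMetadata],
    references: Sequence[BarcodeReference],
    facet: str,
    group_map: Optional[Mapping[str, EcoGroup]] = None,
) -> GroupTally:
    """Cross-tabulate ecological groups by identification method or by
    solar technology, with an attached chi-squared test.

    facet="method": a sample counts in the *morphological* row when it has
    a field identification, and in the *genetic* row when it was
    morphologically unknown but genetically identified.  facet="technology"
    uses the combined identification (morphological if present, else the
    first genetic candidate) and rows are the facility technologies.
    Samples identified by neither method are excluded.
    """
    if facet not in ("method", "technology"):
        raise ValueError("facet must be 'method' or 'technology'")
    species_order = {r.species: r.order_name for r in references}
    results_by_id = {r.sample_id: r for r in results}

    def group_of(species: str) -> EcoGroup:
        if species not in species_order:
            raise ValueError(f"species {species!r} not in the reference database")
        return assign_group(species_order[species], group_map)

    cols = [g.value for g in GROUP_ORDER]
    counts: dict[str, dict[str, int]] = {}

    def bump(row: str, group: EcoGroup) -> None:
        counts.setdefault(row, {c: 0 for c in cols})[group.value] += 1

    for meta in metadata:
        res = results_by_id.get(meta.sample_id)
        morph_known = meta.morphological_id != UNKNOWN_MORPHOLOGY
        genetic_known = (
            res is not None
            and res.category != Category.NO_IDENTIFICATION
            and len(res.candidates) > 0
        )
        if not morph_known and not genetic_known:
            continue  # unidentified by either method
        if facet == "method":
            if morph_known:
                bump("morphological", group_of(meta.morphological_id))
            if not morph_known and genetic_known:
                assert res is not None
                bump("genetic", group_of(res.candidates[0]))
        else:
            species = (
                meta.morphological_id if morph_known else results_by_id[meta.sample_id].candidates[0]
            )
            bump(meta.technology.value, group_of(species))

    if not counts:
        raise ValueError("no identified samples to tabulate")
    for row, cells in counts.items():
        if sum(cells.values()) == 0:
            raise ValueError(f"facet level {row!r} has no identified samples")

    df = pd.DataFrame.from_dict(counts, orient="index")[cols]
    # groups absent from the data contribute nothing to the test; drop
    # their all-zero columns rather than fail on a zero marginal
    test_df = df.loc[:, df.sum(axis=0) > 0]
    chi2 = (
        chi2_proportions(test_df.to_numpy())
        if test_df.shape[0] >= 2 and test_df.shape[1] >= 2
        else None
    )
    return GroupTally(counts=df, percentages=_percent_rows(df), chi2=chi2)
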