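"""Pairwise p-distances, pair classification, locus summaries, barcoding gaps.

The distance throughout is the uncorrected p-distance (proportion of
differing sites) with pairwise deletion: a site enters a pair's comparison
iff both characters are unambiguous bases (A/C/G/T).  This mirrors the
standard "P-distance model, uniform rates among sites" setting of MEGA-style
barcoding analyses, where gaps and Ns are missing data per pair rather than
listwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .seq_io import Alignment, TaxonTable

PAIR_CLASSES = (
    "inter-species",
    "intra-species",
    "inter-variety",
    "intra-variety",
    "intra-population",
)

_BASES = (b"A", b"C", b"G", b"T")


class UndefinedDistanceError(ValueError):
    """A pair shares zero comparable sites."""


def _byte_row(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype="S1")


def p_distance(a: str, b: str) -> tuple[float, int]:
    """p-distance between two gapped sequences with pairwise deletion.

    Returns ``(p, L)`` where ``L`` counts columns with both characters in
    {A,C,G,T} and ``p`` = mismatches / L.  ``p`` is NaN when L == 0.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    ra, rb = _byte_row(a), _byte_row(b)
    va = np.isin(ra, _BASES)
    vb = np.isin(rb, _BASES)
    both = va & vb
    L = int(both.sum())
    if L == 0:
        return float("nan"), 0
    mism = int((ra[both] != rb[both]).sum())
    return mism / L, L


def _validity_and_onehot(aln: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """(n, L) float validity mask and (4, n, L) one-hot base indicators."""
    mat = aln.matrix
    onehot = np.stack([(mat == b).astype(np.float64) for b in _BASES])
    valid = onehot.sum(axis=0)
    return valid, onehot


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix with per-pair comparable-site counts."""

    ids: list[str]
    d: np.ndarray
    comparable_sites: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        assert self.d.shape == (n, n) and self.comparable_sites.shape == (n, n)

    def value(self, id1: str, id2: str) -> float:
        i, j = self.ids.index(id1), self.ids.index(id2)
        return float(self.d[i, j])

    def has_undefined(self) -> bool:
        iu = np.triu_indices(len(self.ids), k=1)
        return bool(np.isnan(self.d[iu]).any())

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                if np.isnan(self.d[i, j]):
                    out.append((self.ids[i], self.ids[j]))
        return out


def distance_matrix(aln: Alignment, *, allow_undefined: bool = False) -> DistanceMatrix:
    """All-pairs p-distance with pairwise deletion, via one-hot matmuls.

    Raises :class:`UndefinedDistanceError` listing the offending pairs if
    any pair has no comparable sites (unless ``allow_undefined``).
    """
    valid, onehot = _validity_and_onehot(aln)
    L = valid @ valid.T  # comparable sites per pair
    matches = np.zeros_like(L)
    for k in range(4):
        matches += onehot[k] @ onehot[k].T
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(L > 0, (L - matches) / np.maximum(L, 1), np.nan)
    np.fill_diagonal(d, 0.0)
    dm = DistanceMatrix(aln.ids, d, L.astype(np.int64))
    if not allow_undefined and dm.has_undefined():
        raise UndefinedDistanceError(
            f"pairs with no comparable sites: {dm.undefined_pairs()}"
        )
    return dm


def pair_class(id1: str, id2: str, table: TaxonTable, level: str) -> str:
    """Classify an unordered pair of distinct individuals at a taxonomic level.

    Species level: inter-species iff the species differ; pairs crossing
    varieties of one species are intra-species.  Variety level: defined only
    for pairs within a multi-variety species — inter-variety iff the
    varieties differ.  Population level: intra-population iff species,
    variety and population all agree.
    """
    if id1 == id2:
        raise ValueError("a pair must be two distinct individuals")
    sp1, sp2 = table.species_of(id1), table.species_of(id2)
    if level == "species":
        return "inter-species" if sp1 != sp2 else "intra-species"
    if level == "variety":
        multi = set(table.multi_variety_species())
        if sp1 != sp2 or sp1 not in multi:
            raise ValueError(
                "variety-level classification is defined only for pairs "
                "within a multi-variety species"
            )
        v1, v2 = table.variety_of(id1), table.variety_of(id2)
        return "inter-variety" if v1 != v2 else "intra-variety"
    if level == "population":
        if (sp1, table.variety_of(id1), table.population_of(id1)) == (
            sp2,
            table.variety_of(id2),
            table.population_of(id2),
        ):
            return "intra-population"
        raise ValueError("pair does not share a population")
    raise ValueError(f"unknown level {level!r}")


@dataclass
class DistanceSummary:
    """Per-pair-class (min, max, n_pairs) of pairwise distances at one locus."""

    locus: str
    per_class: dict[str, tuple[float, float, int]] = field(default_factory=dict)

    def range_of(self, cls: str) -> tuple[float, float]:
        if cls not in self.per_class:
            raise KeyError(f"class {cls!r} absent from summary of {self.locus!r}")
        lo, hi, _ = self.per_class[cls]
        return lo, hi


def locus_summary(
    aln: Alignment, table: TaxonTable, locus: str = "locus"
) -> DistanceSummary:
    """Min/max pairwise distance per pair class over all eligible pairs.

    Classes with no eligible pairs are simply absent from the result.
    """
    dm = distance_matrix(aln, allow_undefined=True)
    multi = set(table.multi_variety_species())
    acc: dict[str, list[float]] = {c: [] for c in PAIR_CLASSES}
    for id1, id2 in itertools.combinations(aln.ids, 2):
        p = dm.value(id1, id2)
        if np.isnan(p):
            continue
        acc[pair_class(id1, id2, table, "species")].append(p)
        sp1, sp2 = table.species_of(id1), table.species_of(id2)
        if sp1 == sp2 and sp1 in multi:
            acc[pair_class(id1, id2, table, "variety")].append(p)
        if sp1 == sp2 and table.rows[id1][1:] == table.rows[id2][1:]:
            acc["intra-population"].append(p)
    per_class = {
        c: (min(v), max(v), len(v)) for c, v in acc.items() if v
    }
    return DistanceSummary(locus, per_class)


@dataclass
class GapResult:
    """Barcoding-gap verdict at one grouping level."""

    level: str
    has_gap: bool
    gap_width: float  # min(between) - max(within), substitutions/site


_LEVEL_CLASSES = {
    "species": ("inter-species", "intra-species"),
    "variety": ("inter-variety", "intra-variety"),
}


def barcoding_gap(summary: DistanceSummary, level: str) -> GapResult:
    """Gap iff the between-class minimum strictly exceeds the within-class
    maximum ("no overlap" read strictly; touching ranges are no gap)."""
    try:
        between_cls, within_cls = _LEVEL_CLASSES[level]
    except KeyError:
        raise ValueError(f"unknown level {level!r}") from None
    for cls in (between_cls, within_cls):
        if cls not in summary.per_class:
            raise ValueError(
                f"summary of {summary.locus!r} lacks class {cls!r}"
            )
    between_min, _ = summary.range_of(between_cls)
    _, within_max = summary.range_of(within_cls)
    width = between_min - within_max
    return GapResult(level, width > 0, width)


def summary_table(summaries: list[DistanceSummary]) -> "pd.DataFrame":
    """Table mirroring the locus-by-locus barcoding-gap presentation."""
    import pandas as pd

    rows = []
    for s in summaries:
        row: dict[str, object] = {"locus": s.locus}
        for cls in PAIR_CLASSES:
            if cls in s.per_class:
                lo, hi, n = s.per_class[cls]
                row[cls] = f"{lo:.3f}-{hi:.3f}"
                row[f"{cls}_n"] = n
            else:
                row[cls] = "ND"
                row[f"{cls}_n"] = 0
        for level in ("species", "variety"):
            b, w = _LEVEL_CLASSES[level]
            if b in s.per_class and w in s.per_class:
                row[f"{level}_gap"] = barcoding_gap(s, level).has_gap
            else:
                row[f"{level}_gap"] = None
        rows.append(row)
    return pd.DataFrame(rows)
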