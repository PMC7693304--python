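"""Indel events from an alignment: extraction, lineage specificity, context.

An event is a maximal run of consecutive columns sharing one per-sequence
gap pattern with at least one (internal) gap — the "simple indel coding"
event model, which makes event counts well defined.  Leading and trailing
all-gap overhangs of any sequence are treated as missing data, not indels:
they reflect assembly length differences rather than mutation events.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .seq_io import Alignment, FeatureTable, TaxonTable, ungapped_to_column

SPECIFICITIES = ("species-specific", "variety-specific", "polymorphic", "uninformative")

# per-(sequence, column) state codes
_BASE, _GAP, _MISSING = 0, 1, 2

_CONTEXT_PRECEDENCE = {"CDS": 0, "intron": 1, "rRNA": 2, "ETS": 2, "ITS": 2, "other": 3}


@dataclass
class IndelEvent:
    start: int  # alignment columns, 0-based half-open
    end: int
    states: dict[str, int]  # id -> _BASE/_GAP/_MISSING
    specificity: str | None = None
    context: str | None = None
    lineage: str | None = None  # the species/variety the event separates

    @property
    def length(self) -> int:
        return self.end - self.start

    def gap_ids(self) -> list[str]:
        return [sid for sid, st in self.states.items() if st == _GAP]

    def base_ids(self) -> list[str]:
        return [sid for sid, st in self.states.items() if st == _BASE]


def _state_matrix(aln: Alignment) -> np.ndarray:
    """(n_seqs, n_cols) state codes with terminal overhangs marked missing."""
    gap = aln.matrix == b"-"
    states = np.where(gap, _GAP, _BASE).astype(np.int8)
    for i in range(aln.n_seqs):
        row = gap[i]
        nz = np.nonzero(~row)[0]
        if len(nz) == 0:
            states[i, :] = _MISSING
            continue
        states[i, : nz[0]] = np.where(row[: nz[0]], _MISSING, _BASE)
        states[i, nz[-1] + 1 :] = np.where(row[nz[-1] + 1 :], _MISSING, _BASE)
    return states


def indel_events(aln: Alignment) -> list[IndelEvent]:
    """Maximal runs of identical gap patterns containing >= 1 internal gap.

    Adjacent gap columns with different taxon patterns yield distinct
    events; columns whose only gaps are terminal overhangs yield none.
    """
    states = _state_matrix(aln)
    has_gap = (states == _GAP).any(axis=0)
    n_cols = aln.n_cols
    # column pattern change-points
    change = np.ones(n_cols, dtype=bool)
    change[1:] = (states[:, 1:] != states[:, :-1]).any(axis=0)
    starts = np.nonzero(change)[0]
    ends = np.append(starts[1:], n_cols)
    events = []
    for s, e in zip(starts, ends):
        if has_gap[s]:
            states_col = states[:, s]
            events.append(
                IndelEvent(int(s), int(e), dict(zip(aln.ids, states_col.tolist())))
            )
    return events


def classify_specificity(event: IndelEvent, table: TaxonTable) -> str:
    """Assign a lineage-specificity label to one event (also stored on it).

    species-specific: the members of exactly one species all share one
    state (gap or base) and every other sequence uniformly shows the other.
    variety-specific: the same at variety level within a multi-variety
    species.  Events matching both are species-specific.  Events touching a
    terminal-overhang (missing) region are uninformative; everything else
    is polymorphic.
    """
    if any(st == _MISSING for st in event.states.values()):
        event.specificity = "uninformative"
        return event.specificity
    gap_set = frozenset(event.gap_ids())
    base_set = frozenset(event.base_ids())
    if not gap_set or not base_set:
        event.specificity = "uninformative"
        return event.specificity

    species_groups = table.groups("species", ids=list(event.states))
    for sp, members in species_groups.items():
        mset = frozenset(members)
        if gap_set == mset or base_set == mset:
            event.specificity = "species-specific"
            event.lineage = sp
            return event.specificity

    multi = set(table.multi_variety_species())
    variety_groups = table.groups("variety", ids=list(event.states))
    for key, members in variety_groups.items():
        sp = key.split("|")[0]
        if sp not in multi or "|" not in key:
            continue
        mset = frozenset(members)
        if gap_set == mset or base_set == mset:
            event.specificity = "variety-specific"
            event.lineage = key
            return event.specificity

    event.specificity = "polymorphic"
    return event.specificity


def annotate_context(
    event: IndelEvent, features: FeatureTable, ref_id: str, aln: Alignment
) -> str:
    """Genomic context of an event's midpoint on the ungapped reference.

    The midpoint column is projected to reference coordinates (gap columns
    inherit the coordinate of the preceding reference base); the context is
    the class of the covering feature, 'intergenic' if none covers it, with
    ties broken CDS > intron > rRNA/ETS/ITS > other.
    """
    if ref_id not in aln.ids:
        raise KeyError(f"reference id {ref_id!r} not in alignment")
    cols = ungapped_to_column(aln, ref_id)
    mid_col = (event.start + event.end - 1) // 2
    # reference position of the last reference base at or before mid_col
    pos = int(np.searchsorted(cols, mid_col, side="right")) - 1
    pos = max(pos, 0)
    covering = [
        f for f in features.on(ref_id) if f.start <= pos < f.end
    ]
    if not covering:
        event.context = "intergenic"
        return event.context
    covering.sort(key=lambda f: _CONTEXT_PRECEDENCE.get(f.feature_class, 3))
    fclass = covering[0].feature_class
    event.context = fclass if fclass != "other" else "other"
    return event.context


_LENGTH_BINS = [(1, 10), (11, 100), (101, None)]


def indel_spectrum(events: Iterable[IndelEvent]) -> dict:
    """Length-by-specificity histogram plus headline shares.

    Returns a dict with a tidy ``table`` (DataFrame: length_bin,
    specificity, count), ``fraction_le_10bp`` and ``count_gt_100bp``
    (the latter restricted to no specificity — all classified events).
    """
    events = list(events)
    rows = []
    for ev in events:
        spec = ev.specificity or "unclassified"
        for lo, hi in _LENGTH_BINS:
            if ev.length >= lo and (hi is None or ev.length <= hi):
                label = f"{lo}-{hi}" if hi else f">{lo - 1}"
                rows.append({"length_bin": label, "specificity": spec})
                break
    if rows:
        table = (
            pd.DataFrame(rows)
            .groupby(["length_bin", "specificity"])
            .size()
            .rename("count")
            .reset_index()
        )
    else:
        table = pd.DataFrame(columns=["length_bin", "specificity", "count"])
    n = len(events)
    frac_le10 = sum(ev.length <= 10 for ev in events) / n if n else float("nan")
    return {
        "table": table,
        "n_events": n,
        "fraction_le_10bp": frac_le10,
        "count_gt_100bp": sum(ev.length > 100 for ev in events),
    }


def events_to_frame(events: Iterable[IndelEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        rows.append(
            {
                "start": ev.start,
                "end": ev.end,
                "length": ev.length,
                "specificity": ev.specificity,
                "lineage": ev.lineage,
                "context": ev.context,
                "gap_ids": ",".join(sorted(ev.gap_ids())),
            }
        )
    return pd.DataFrame(rows)
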