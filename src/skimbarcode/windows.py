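"""Non-overlapping sliding-window between-group substitution rates (Dxy).

Windows are laid on alignment columns.  Per window and grouping level the
rate is the mean over unordered group pairs of Dxy, where
Dxy(g1, g2) = (1 / (n1 n2)) * sum over cross pairs of the pairwise
p-distance restricted to the window (pairwise deletion of gaps/N).  Windows
whose average comparable-site count across cross pairs falls below a
minimum are flagged invalid and excluded from correlations and maxima.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .seq_io import Alignment, TaxonTable
from .distances import _validity_and_onehot


def window_partition(n_cols: int, w: int) -> list[tuple[int, int]]:
    """Consecutive [kw, (k+1)w) intervals over [0, n_cols).

    A final partial window is kept if it spans at least w/2 columns,
    otherwise it is merged into the previous window.
    """
    if n_cols < 1 or w < 1:
        raise ValueError("n_cols and w must be >= 1")
    bounds = list(range(0, n_cols, w))
    wins = [(s, min(s + w, n_cols)) for s in bounds]
    if len(wins) > 1 and (wins[-1][1] - wins[-1][0]) < w / 2:
        last = wins.pop()
        prev = wins.pop()
        wins.append((prev[0], last[1]))
    return wins


@dataclass
class Window:
    start: int
    end: int
    rates: dict[str, float] = field(default_factory=dict)  # level -> rate (NaN invalid)
    valid_sites: dict[str, float] = field(default_factory=dict)

    def rate(self, level: str) -> float:
        return self.rates[level]

    def is_valid(self, level: str) -> bool:
        return not math.isnan(self.rates[level])


@dataclass
class WindowProfile:
    """Windowed between-group substitution-rate profile of one molecule."""

    molecule: str
    w: int
    windows: list[Window]

    def levels(self) -> list[str]:
        return list(self.windows[0].rates) if self.windows else []

    def rates(self, level: str, *, valid_only: bool = True) -> np.ndarray:
        vals = np.array([win.rates[level] for win in self.windows])
        return vals[~np.isnan(vals)] if valid_only else vals

    def max_rate(self, level: str) -> float:
        vals = self.rates(level)
        if len(vals) == 0:
            raise ValueError(f"no valid window at level {level!r}")
        return float(vals.max())

    def to_frame(self) -> "pd.DataFrame":
        import pandas as pd

        rows = []
        for win in self.windows:
            for level in win.rates:
                rows.append(
                    {
                        "molecule": self.molecule,
                        "start": win.start,
                        "end": win.end,
                        "level": level,
                        "rate": win.rates[level],
                        "valid_sites": win.valid_sites[level],
                    }
                )
        return pd.DataFrame(rows)


def _group_indices(
    aln: Alignment, groups: dict[str, list[str]]
) -> dict[str, np.ndarray]:
    idx = {sid: i for i, sid in enumerate(aln.ids)}
    return {g: np.array([idx[s] for s in members]) for g, members in groups.items()}


def window_dxy(
    aln: Alignment,
    groups: dict[str, list[str]],
    w: int,
    *,
    level: str = "inter-group",
    molecule: str = "molecule",
    min_valid_sites: float | None = None,
) -> WindowProfile:
    """Windowed mean cross-group Dxy for one grouping.

    ``groups`` maps group label -> member sequence ids (>= 2 groups).
    ``min_valid_sites`` defaults to w/2 average comparable columns per
    cross pair; windows below it are flagged invalid (rate NaN).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for between-group rates")
    if min_valid_sites is None:
        min_valid_sites = w / 2
    gidx = _group_indices(aln, groups)
    valid, onehot = _validity_and_onehot(aln)
    wins = window_partition(aln.n_cols, w)
    out = []
    for start, end in wins:
        v = valid[:, start:end]
        L = v @ v.T
        matches = np.zeros_like(L)
        for k in range(4):
            o = onehot[k][:, start:end]
            matches += o @ o.T
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(L > 0, (L - matches) / np.maximum(L, 1), np.nan)
        dxy_vals = []
        site_means = []
        for g1, g2 in itertools.combinations(sorted(gidx), 2):
            block_p = p[np.ix_(gidx[g1], gidx[g2])]
            block_L = L[np.ix_(gidx[g1], gidx[g2])]
            site_means.append(float(block_L.mean()))
            dxy_vals.append(float(np.nanmean(block_p)) if not np.isnan(block_p).all() else float("nan"))
        mean_sites = float(np.mean(site_means))
        if mean_sites < min_valid_sites or any(math.isnan(x) for x in dxy_vals):
            rate = float("nan")
        else:
            rate = float(np.mean(dxy_vals))
        out.append(
            Window(start, end, {level: rate}, {level: mean_sites})
        )
    return WindowProfile(molecule, w, out)


def merge_profiles(a: WindowProfile, b: WindowProfile) -> WindowProfile:
    """Combine two single-level profiles of the same molecule and windows."""
    if [(w.start, w.end) for w in a.windows] != [(w.start, w.end) for w in b.windows]:
        raise ValueError("profiles have different window layouts")
    merged = []
    for wa, wb in zip(a.windows, b.windows):
        merged.append(
            Window(
                wa.start,
                wa.end,
                {**wa.rates, **wb.rates},
                {**wa.valid_sites, **wb.valid_sites},
            )
        )
    return WindowProfile(a.molecule, a.w, merged)


def rate_correlation(
    profile: WindowProfile, level_a: str, level_b: str
) -> float:
    """Pearson correlation of window rates between two levels.

    Uses windows valid at both levels; NaN when fewer than 3 such windows
    or when either level has zero variance.
    """
    xa = profile.rates(level_a, valid_only=False)
    xb = profile.rates(level_b, valid_only=False)
    both = ~np.isnan(xa) & ~np.isnan(xb)
    xa, xb = xa[both], xb[both]
    if len(xa) < 3 or np.ptp(xa) == 0 or np.ptp(xb) == 0:
        return float("nan")
    return float(stats.pearsonr(xa, xb).statistic)


def max_rate_ratio(
    profile_a: WindowProfile, profile_b: WindowProfile, level: str
) -> float:
    """max window rate of A over max window rate of B at one level.

    Returns +inf when B's maximum is zero (flagged infinite).
    """
    ma = profile_a.max_rate(level)
    mb = profile_b.max_rate(level)
    if mb == 0:
        return float("inf")
    return ma / mb


@dataclass
class Region:
    start: int  # column coordinates
    end: int
    peak_rate: float
    n_windows: int


@dataclass
class HypervariableCall:
    level: str
    threshold: float  # rate threshold actually applied
    regions: list[Region]  # sorted by peak rate descending


def call_hypervariable(
    profile: WindowProfile,
    level: str,
    threshold_quantile: float = 0.95,
    merge_gap: int = 1,
) -> HypervariableCall:
    """Call hypervariable regions as merged runs of high-rate windows.

    A window is selected when its rate is strictly greater than the given
    quantile of all valid window rates (strict, so a flat profile yields no
    calls); selected windows separated by at most ``merge_gap`` unselected
    windows coalesce into one region.  Regions are ranked by peak rate.
    """
    all_rates = profile.rates(level, valid_only=False)
    valid = ~np.isnan(all_rates)
    if not valid.any():
        raise ValueError(f"no valid window at level {level!r}")
    thr = float(np.quantile(all_rates[valid], threshold_quantile))
    selected = valid & (all_rates > thr)
    regions: list[Region] = []
    run: list[int] = []
    gap_budget = 0
    for i, sel in enumerate(selected):
        if sel:
            if run and gap_budget > 0:
                run.extend(range(run[-1] + 1, i))  # absorb the skipped windows
            run.append(i)
            gap_budget = merge_gap
        elif run:
            if gap_budget > 0:
                gap_budget -= 1
            else:
                regions.append(_close_region(profile, run, all_rates))
                run = []
    if run:
        regions.append(_close_region(profile, run, all_rates))
    regions.sort(key=lambda r: -r.peak_rate)
    return HypervariableCall(level, thr, regions)


def _close_region(
    profile: WindowProfile, run: list[int], rates: np.ndarray
) -> Region:
    wins = [profile.windows[i] for i in run]
    peak = float(np.nanmax(rates[run]))
    return Region(wins[0].start, wins[-1].end, peak, len(run))


def regions_to_bed(call: HypervariableCall, molecule: str) -> str:
    lines = []
    for i, r in enumerate(sorted(call.regions, key=lambda r: r.start), 1):
        lines.append(
            f"{molecule}\t{r.start}\t{r.end}\thv{i}_{call.level}\t"
            f"{r.peak_rate:.4f}\t."
        )
    return "\n".join(lines) + ("\n" if lines else "")
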