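import itertools
import math

import numpy as np
import pytest
from scipy import stats

from skimbarcode.distances import p_distance
from skimbarcode.seq_io import Alignment, SequenceRecord
from skimbarcode.synthetic_data import SimConfig, simulate
from skimbarcode.windows import (
    call_hypervariable,
    max_rate_ratio,
    merge_profiles,
    rate_correlation,
    window_dxy,
    window_partition,
)


class TestWindowPartition:
    @pytest.mark.parametrize(
        "n_cols,w,expected",
        [
            (400, 200, [(0, 200), (200, 400)]),
            (450, 200, [(0, 200), (200, 450)]),  # 50 < 100 merged back
            (150, 200, [(0, 150)]),
            (500, 200, [(0, 200), (200, 400), (400, 500)]),  # 100 >= 100 kept
            (1, 1, [(0, 1)]),
        ],
    )
    def test_examples(self, n_cols, w, expected):
        assert window_partition(n_cols, w) == expected

    def test_tiles_without_gap_or_overlap(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(1, 5000))
            w = int(rng.integers(1, 400))
            wins = window_partition(n, w)
            assert wins[0][0] == 0 and wins[-1][1] == n
            for (s1, e1), (s2, e2) in zip(wins, wins[1:]):
                assert e1 == s2 and s1 < e1


def brute_force_dxy(aln, g1_ids, g2_ids, start, end):
    """Exhaustive cross-pair mean of windowed p-distances."""
    vals = []
    for a, b in itertools.product(g1_ids, g2_ids):
        p, L = p_distance(aln.row(a)[start:end], aln.row(b)[start:end])
        vals.append(p)
    return float(np.nanmean(vals))


class TestWindowDxy:
    def test_single_difference_forced_by_formula(self):
        # both groups internally identical; one site of 50 differs
        base = "A" * 50
        alt = "A" * 25 + "C" + "A" * 24
        aln = Alignment(
            [
                SequenceRecord("g1a", base),
                SequenceRecord("g1b", base),
                SequenceRecord("g2a", alt),
                SequenceRecord("g2b", alt),
            ]
        )
        prof = window_dxy(aln, {"g1": ["g1a", "g1b"], "g2": ["g2a", "g2b"]}, 50)
        assert prof.windows[0].rates["inter-group"] == pytest.approx(0.02)

    def test_identical_groups_zero_everywhere(self):
        aln = Alignment([SequenceRecord(f"s{i}", "ACGT" * 30) for i in range(4)])
        prof = window_dxy(aln, {"g1": ["s0", "s1"], "g2": ["s2", "s3"]}, 40)
        assert all(w.rates["inter-group"] == 0 for w in prof.windows)

    def test_matches_exhaustive_cross_pairs(self, sim_small):
        aln, taxa = sim_small.alignment, sim_small.taxa
        groups = taxa.groups("species")
        prof = window_dxy(aln, groups, 50)
        g1, g2 = groups["sppA"], groups["sppB"]
        for win in prof.windows[:20]:
            if not win.is_valid("inter-group"):
                continue
            exp = brute_force_dxy(aln, g1, g2, win.start, win.end)
            assert win.rates["inter-group"] == pytest.approx(exp, abs=1e-12)

    def test_single_group_rejected(self, sim_small):
        with pytest.raises(ValueError):
            window_dxy(sim_small.alignment, {"g": sim_small.alignment.ids}, 50)

    def test_permutation_invariance(self, sim_small):
        aln, taxa = sim_small.alignment, sim_small.taxa
        groups = taxa.groups("species")
        p1 = window_dxy(aln, groups, 200)
        shuffled = Alignment(list(reversed(aln.records)))
        relabeled = {g: list(reversed(m)) for g, m in reversed(groups.items())}
        p2 = window_dxy(shuffled, relabeled, 200)
        r1 = p1.rates("inter-group", valid_only=False)
        r2 = p2.rates("inter-group", valid_only=False)
        np.testing.assert_allclose(r1, r2, equal_nan=True)

    def test_conservation_under_partition(self, sim_small):
        """Pooling windowed mismatch/site counts reproduces whole-molecule Dxy."""
        aln, taxa = sim_small.alignment, sim_small.taxa
        groups = taxa.groups("species")
        g1, g2 = groups["sppA"], groups["sppB"]
        w = 100
        # per-pair pooled counts across windows == whole-alignment counts
        for a, b in list(itertools.product(g1[:2], g2[:2])):
            tot_m = tot_L = 0
            for s, e in window_partition(aln.n_cols, w):
                p, L = p_distance(aln.row(a)[s:e], aln.row(b)[s:e])
                if L:
                    tot_m += round(p * L)
                    tot_L += L
            p_all, L_all = p_distance(aln.row(a), aln.row(b))
            assert tot_L == L_all
            assert tot_m / tot_L == pytest.approx(p_all)


class TestRateCorrelation:
    def _two_level_profile(self, sim_small):
        aln, taxa = sim_small.alignment, sim_small.taxa
        sp = window_dxy(aln, taxa.groups("species"), 200, level="inter-species")
        ids_b = [i for i in aln.ids if taxa.species_of(i) == "sppB"]
        vp = window_dxy(
            aln, taxa.groups("variety", ids=ids_b), 200, level="inter-variety"
        )
        return merge_profiles(sp, vp)

    def test_identical_levels_give_unity(self, sim_small):
        aln, taxa = sim_small.alignment, sim_small.taxa
        sp = window_dxy(aln, taxa.groups("species"), 200, level="a")
        sp2 = window_dxy(aln, taxa.groups("species"), 200, level="b")
        prof = merge_profiles(sp, sp2)
        assert rate_correlation(prof, "a", "b") == pytest.approx(1.0)

    def test_constant_level_undefined(self):
        aln = Alignment([SequenceRecord(f"s{i}", "ACGT" * 100) for i in range(4)])
        a = window_dxy(aln, {"g1": ["s0", "s1"], "g2": ["s2", "s3"]}, 100, level="a")
        b = window_dxy(aln, {"g1": ["s0", "s1"], "g2": ["s2", "s3"]}, 100, level="b")
        prof = merge_profiles(a, b)
        assert math.isnan(rate_correlation(prof, "a", "b"))

    def test_matches_textbook_pearson(self, sim_small):
        prof = self._two_level_profile(sim_small)
        r = rate_correlation(prof, "inter-species", "inter-variety")
        xa = prof.rates("inter-species", valid_only=False)
        xb = prof.rates("inter-variety", valid_only=False)
        ok = ~np.isnan(xa) & ~np.isnan(xb)
        x, y = xa[ok], xb[ok]
        exp = np.sum((x - x.mean()) * (y - y.mean())) / math.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(exp)


class TestMaxRateRatio:
    def test_printed_extremes_give_printed_ratio(self, sim_small):
        """Two profiles whose maxima match the published inter-variety window
        extremes (0.278 rDNA vs 0.036 plastome) must yield 7.72."""
        aln, taxa = sim_small.alignment, sim_small.taxa
        base = window_dxy(aln, taxa.groups("species"), 200, level="x")
        a = base
        b = window_dxy(aln, taxa.groups("species"), 200, level="x")
        for w in a.windows:
            w.rates["x"] = 0.0
        for w in b.windows:
            w.rates["x"] = 0.0
        a.windows[3].rates["x"] = 0.278
        b.windows[5].rates["x"] = 0.036
        assert max_rate_ratio(a, b, "x") == pytest.approx(7.72, abs=0.005)

    def test_identical_profiles_unity(self, sim_small):
        aln, taxa = sim_small.alignment, sim_small.taxa
        p = window_dxy(aln, taxa.groups("species"), 200, level="x")
        assert max_rate_ratio(p, p, "x") == 1.0

    def test_zero_denominator_flagged_infinite(self, sim_small):
        aln, taxa = sim_small.alignment, sim_small.taxa
        a = window_dxy(aln, taxa.groups("species"), 200, level="x")
        b = window_dxy(aln, taxa.groups("species"), 200, level="x")
        for w in b.windows:
            w.rates["x"] = 0.0
        assert math.isinf(max_rate_ratio(a, b, "x"))


class TestCallHypervariable:
    def _profile_with_rates(self, rates, sim_small):
        aln, taxa = sim_small.alignment, sim_small.taxa
        w = max(10, aln.n_cols // len(rates))
        prof = window_dxy(aln, taxa.groups("species"), w, level="x")
        assert len(prof.windows) == len(rates)
        for win, r in zip(prof.windows, rates):
            win.rates["x"] = r
        return prof

    def test_single_outlier_called(self, sim_small):
        rates = [0.01] * 19 + [0.1]
        prof = self._profile_with_rates(rates, sim_small)
        call = call_hypervariable(prof, "x", 0.95)
        assert len(call.regions) == 1
        assert call.regions[0].peak_rate == pytest.approx(0.1)

    def test_uniform_rates_call_nothing(self, sim_small):
        prof = self._profile_with_rates([0.02] * 20, sim_small)
        assert call_hypervariable(prof, "x", 0.95).regions == []

    def test_planted_hot_windows_recovered(self):
        mult = [1.0] * 30
        for i in (4, 15, 26):
            mult[i] = 25.0
        # indel-free so alignment columns coincide with ancestral coordinates
        cfg = SimConfig(seed=5, seq_length=6000, multipliers=mult, indel_plan=[])
        res = simulate(cfg)
        prof = window_dxy(
            res.alignment, res.taxa.groups("species"), 200, level="inter-species"
        )
        # 3 of 30 windows are hot, so the top decile is the matching cutoff
        call = call_hypervariable(prof, "inter-species", 0.9, merge_gap=0)
        assert len(call.regions) == 3
        hot_cols = {res.truth.windows[i][0] for i in (4, 15, 26)}
        called_starts = {r.start for r in call.regions}
        assert hot_cols == called_starts

    def test_all_invalid_rejected(self, sim_small):
        prof = self._profile_with_rates([float("nan")] * 20, sim_small)
        with pytest.raises(ValueError):
            call_hypervariable(prof, "x", 0.95)


class TestPlantedMultiplierRanks:
    def test_rank_correlation_exceeds_0_8(self):
        """Windowed rate estimates track planted per-window rate multipliers."""
        rng = np.random.default_rng(2)
        mult = list(rng.gamma(2.0, 0.5, size=25))
        cfg = SimConfig(
            seed=9,
            seq_length=5000,
            window_length=200,
            multipliers=mult,
            n_individuals=(10, 10, 10),
            d_s=0.02,
            indel_plan=[],
        )
        res = simulate(cfg)
        prof = window_dxy(
            res.alignment, res.taxa.groups("species"), 200, level="inter-species"
        )
        est = prof.rates("inter-species", valid_only=False)
        truth = np.array(res.truth.multipliers)
        ok = ~np.isnan(est)
        rho = stats.spearmanr(truth[ok], est[ok]).statistic
        assert rho > 0.8
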