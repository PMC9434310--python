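import numpy as np
import pytest

from pleiocov import (
    define_window,
    enumerate_windows,
    make_segments,
    seed_correlations,
    simulate_genotypes,
    SimConfig,
)
from pleiocov.segmentation import Segment

from conftest import make_panel


def brute_force_window(X, segment, seed, threshold=0.1):
    """Independent reference: full correlation vector via np.corrcoef, then a
    plain sequential scan with the one-gap allowance and two-failure stop."""
    included = {seed}
    for step in (-1, 1):
        pending = []
        j = seed + step
        while segment.start <= j < segment.stop:
            sa = X[:, seed].std()
            sb = X[:, j].std()
            r = 0.0 if sa == 0 or sb == 0 else np.corrcoef(X[:, seed], X[:, j])[0, 1]
            if abs(r) >= threshold:
                included.update(pending)
                included.add(j)
                pending = []
            else:
                pending.append(j)
                if len(pending) == 2:
                    break
            j += step
    lo, hi = min(included), max(included)
    return list(range(lo, hi + 1))


def _engineered_X(pattern, seed_pos, n=24, rng_seed=0):
    """Columns engineered against the seed: 'P' ~ seed (corr ~1), 'F' exactly
    orthogonal to the seed (corr ~0)."""
    rng = np.random.default_rng(rng_seed)
    s = rng.standard_normal(n)
    s -= s.mean()
    cols = []
    for i, ch in enumerate(pattern):
        if i == seed_pos:
            cols.append(s)
        elif ch == "P":
            c = s + 0.05 * rng.standard_normal(n)
            cols.append(c - c.mean())
        else:
            c = rng.standard_normal(n)
            c -= c.mean()
            c -= (c @ s) / (s @ s) * s  # exact zero correlation with the seed
            cols.append(c)
    return np.column_stack(cols)


def _whole_segment(p, chromosome=1):
    return Segment(chromosome=chromosome, core=(0, p), left_flank=(0, 0),
                   right_flank=(p, p))


class TestWorkedExamples:
    def test_two_left_one_right_then_failures(self):
        # pass for 2 SNPs left and 1 right; failures beyond in each direction
        X = _engineered_X("FFPPSPFF", seed_pos=4)
        seg = _whole_segment(8)
        w = define_window(X, seg, seed=4)
        assert list(w.member_indices) == [2, 3, 4, 5]

    def test_single_gap_rescue_includes_both(self):
        # corr(seed, j-1) < 0.1 but corr(seed, j-2) >= 0.1: both included
        X = _engineered_X("FFPFSFF", seed_pos=4)
        seg = _whole_segment(7)
        w = define_window(X, seg, seed=4)
        assert 3 in w.member_indices and 2 in w.member_indices
        assert list(w.member_indices) == [2, 3, 4]

    def test_isolated_seed_gives_singleton(self):
        X = _engineered_X("FFSFF", seed_pos=2)
        w = define_window(X, _whole_segment(5), seed=2)
        assert list(w.member_indices) == [2]

    def test_two_consecutive_failures_excluded(self):
        X = _engineered_X("PFFSP", seed_pos=3)
        w = define_window(X, _whole_segment(5), seed=3)
        # indices 1,2 fail consecutively: walk stops, 0 is never reached
        assert list(w.member_indices) == [3, 4]


class TestSeedCorrelations:
    def test_self_correlation_is_one(self, rng):
        X = rng.standard_normal((50, 3))
        assert seed_correlations(X, 1, 1) == pytest.approx(1.0)

    def test_independent_snps_nearly_uncorrelated(self):
        cfg = SimConfig(n_individuals=10000, n_snps=40, within_block_rho=0.0,
                        rng_seed=5)
        panel = simulate_genotypes(cfg)
        X = panel.dosages.astype(float)
        rs = [abs(seed_correlations(X, j, j + 1)) for j in range(0, 38, 2)]
        assert np.median(rs) < 0.02 and max(rs) < 0.05

    def test_matches_direct_covariance_ratio(self, rng):
        X = rng.integers(0, 3, size=(30, 2)).astype(float)
        X[:, 1] = X[:, 0]
        X[0, 1] = 2 - X[0, 1]  # flip one genotype pair
        a, b = X[:, 0] - X[:, 0].mean(), X[:, 1] - X[:, 1].mean()
        expect = (a @ b) / np.sqrt((a @ a) * (b @ b))
        assert seed_correlations(X, 0, 1) == pytest.approx(expect, abs=1e-12)

    def test_zero_variance_column_gives_zero(self, rng):
        X = rng.standard_normal((20, 2))
        X[:, 1] = 3.0
        assert seed_correlations(X, 0, 1) == 0.0


class TestDefineWindow:
    def test_seed_outside_core_raises(self, rng):
        X = rng.standard_normal((20, 10))
        seg = Segment(chromosome=1, core=(2, 8), left_flank=(0, 2),
                      right_flank=(8, 10))
        with pytest.raises(ValueError, match="core"):
            define_window(X, seg, seed=1)

    def test_walk_enters_flanks_but_not_beyond_segment(self):
        # all columns identical: window spans the whole segment, flanks included
        X = np.tile(np.linspace(-1, 1, 20)[:, None], (1, 10))
        seg = Segment(chromosome=1, core=(3, 7), left_flank=(1, 3),
                      right_flank=(7, 9))
        w = define_window(X, seg, seed=5)
        assert list(w.member_indices) == list(range(1, 9))

    def test_raising_threshold_never_enlarges(self, rng):
        cfg = SimConfig(n_individuals=400, n_snps=60, rng_seed=3)
        X = simulate_genotypes(cfg).dosages.astype(float)
        seg = _whole_segment(60)
        for seed in range(0, 60, 7):
            prev = None
            for thr in (0.05, 0.1, 0.3, 0.6):
                members = set(define_window(X, seg, seed, thr).member_indices.tolist())
                if prev is not None:
                    assert members <= prev
                prev = members


class TestEnumerate:
    def test_independent_snps_all_singletons(self):
        cfg = SimConfig(n_individuals=5000, n_snps=10, within_block_rho=0.0,
                        rng_seed=8)
        panel = simulate_genotypes(cfg)
        X = panel.dosages.astype(float)
        segs = make_segments(panel)
        wins, n_raw = enumerate_windows(X, segs, threshold=0.15)
        assert n_raw == 10
        assert all(w.n_snps == 1 for w in wins)
        assert len(wins) == 10

    def test_duplicate_member_sets_collapse(self):
        col = np.linspace(0, 2, 30)
        X = np.column_stack([col, col, col])
        panel = make_panel(np.zeros((30, 3), dtype=int))
        segs = make_segments(panel)
        wins, n_raw = enumerate_windows(X, segs)
        assert n_raw == 3 and len(wins) == 1
        assert wins[0].seed_index == 0  # first seed in map order kept

    def test_matches_brute_force_on_block_ld_panels(self):
        for rep in range(25):
            cfg = SimConfig(n_individuals=150, n_snps=40 + (rep % 3) * 20,
                            block_lengths=(3, 9),
                            within_block_rho=0.3 + 0.06 * (rep % 10),
                            rng_seed=100 + rep)
            panel = simulate_genotypes(cfg)
            X = panel.dosages.astype(float)
            X -= X.mean(0)
            segs = make_segments(panel, core_size=25, flank_size=8)
            for seg in segs:
                for seed in list(seg.core_indices)[::3]:
                    got = define_window(X, seg, seed).member_indices.tolist()
                    assert got == brute_force_window(X, seg, seed), (rep, seed)
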