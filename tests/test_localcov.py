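import numpy as np
import pytest

from pleiocov import (
    LDWindow,
    merge_significant_windows,
    summarize_window,
    window_cov_draws,
    write_results,
)
from pleiocov.localcov import WindowEstimate, read_windows_table
from pleiocov.segmentation import Segment

from conftest import make_panel


def _window(lo, hi, seed=None):
    seg = Segment(chromosome=1, core=(0, 10_000), left_flank=(0, 0),
                  right_flank=(10_000, 10_000))
    return LDWindow(seed_index=seed if seed is not None else lo,
                    member_indices=np.arange(lo, hi + 1), segment=seg)


def score_vector_route(X_w, beta_draws_w):
    """Independent oracle: per-draw sample moments of the genetic scores."""
    out = np.empty((beta_draws_w.shape[0], 3))
    for s in range(beta_draws_w.shape[0]):
        g1 = X_w @ beta_draws_w[s, :, 0]
        g2 = X_w @ beta_draws_w[s, :, 1]
        C = np.cov(g1, g2, ddof=1)
        out[s] = [C[0, 0], C[1, 1], C[0, 1]]
    return out


class TestWindowCovDraws:
    def test_single_snp_closed_form(self, rng):
        x = rng.integers(0, 3, size=(80, 1)).astype(float)
        B = rng.standard_normal((20, 1, 2))
        draws = window_cov_draws(x, B)
        v = np.var(x[:, 0], ddof=1)
        np.testing.assert_allclose(draws[:, 2], B[:, 0, 0] * B[:, 0, 1] * v,
                                   rtol=1e-12)
        np.testing.assert_allclose(draws[:, 0], B[:, 0, 0] ** 2 * v, rtol=1e-12)

    def test_identical_effect_columns_collapse(self, rng):
        X = rng.standard_normal((60, 4))
        B = rng.standard_normal((15, 4, 2))
        B[:, :, 1] = B[:, :, 0]
        draws = window_cov_draws(X, B)
        np.testing.assert_allclose(draws[:, 2], draws[:, 0], rtol=1e-12)
        np.testing.assert_allclose(draws[:, 0], draws[:, 1], rtol=1e-12)

    def test_two_route_equivalence(self, rng):
        X = rng.integers(0, 3, size=(120, 5)).astype(float)
        B = rng.standard_normal((20, 5, 2))
        a = window_cov_draws(X, B)
        b = score_vector_route(X - X.mean(0), B)
        np.testing.assert_allclose(a, b, rtol=1e-10)

    def test_cauchy_schwarz_per_draw(self, rng):
        X = rng.integers(0, 3, size=(100, 8)).astype(float)
        B = rng.standard_normal((200, 8, 2))
        d = window_cov_draws(X, B)
        assert np.all(np.abs(d[:, 2]) <= np.sqrt(d[:, 0] * d[:, 1]) + 1e-12)

    def test_scale_equivariance(self, rng):
        X = rng.standard_normal((50, 3))
        B = rng.standard_normal((10, 3, 2))
        base = window_cov_draws(X, B)
        both = B * 2.5
        np.testing.assert_allclose(window_cov_draws(X, both), base * 2.5 ** 2,
                                   rtol=1e-12)
        one = B.copy()
        one[:, :, 0] *= 2.5
        d = window_cov_draws(X, one)
        np.testing.assert_allclose(d[:, 0], base[:, 0] * 2.5 ** 2, rtol=1e-12)
        np.testing.assert_allclose(d[:, 1], base[:, 1], rtol=1e-12)
        np.testing.assert_allclose(d[:, 2], base[:, 2] * 2.5, rtol=1e-12)

    def test_dimension_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="SNPs"):
            window_cov_draws(rng.standard_normal((10, 3)),
                             rng.standard_normal((5, 4, 2)))


class TestSummarize:
    def test_degenerate_zero_draws_not_significant(self):
        w = _window(0, 1)
        draws = np.zeros((50, 3))
        e = summarize_window(w, draws)
        assert e.cr_low["Cov"] == e.cr_high["Cov"] == 0.0
        assert not e.significant  # CR [0, 0] does not EXCLUDE zero

    def test_quantiles_match_hand_interpolation(self):
        vals = np.arange(1.0, 101.0)
        draws = np.column_stack([vals, vals, vals])
        e = summarize_window(_window(0, 0), draws, level=0.95)
        # linear interpolation on sorted values: h = (n-1)q
        for q, got in [(0.025, e.cr_low["Cov"]), (0.975, e.cr_high["Cov"])]:
            h = (100 - 1) * q
            lo = int(np.floor(h))
            expect = vals[lo] + (h - lo) * (vals[lo + 1] - vals[lo])
            assert got == pytest.approx(expect, abs=1e-12)
        assert e.post_mean["Cov"] == pytest.approx(50.5)
        assert e.post_sd["Cov"] == pytest.approx(np.std(vals, ddof=1))

    def test_sign_definite_draws_are_significant(self, rng):
        draws = np.abs(rng.standard_normal((100, 3))) + 0.1
        e = summarize_window(_window(0, 2), draws)
        assert e.significant and e.cr_low["Cov"] > 0

    def test_nonfinite_draws_raise(self):
        draws = np.zeros((10, 3))
        draws[3, 2] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            summarize_window(_window(0, 0), draws)

    def test_too_few_draws_raise(self):
        with pytest.raises(ValueError, match="2 posterior draws"):
            summarize_window(_window(0, 0), np.zeros((1, 3)))


def _estimate(lo, hi, cov_mean):
    w = _window(lo, hi)
    q = {"V1": abs(cov_mean), "V2": abs(cov_mean), "Cov": cov_mean}
    z = {"V1": 0.0, "V2": 0.0, "Cov": 0.0}
    return WindowEstimate(window=w, post_mean=q, post_sd=z, cr_low=q, cr_high=q,
                          level=0.95, significant=True)


class TestMergeLoci:
    def test_disjoint_windows_stay_apart(self):
        loci = merge_significant_windows([_estimate(0, 3, 1.0), _estimate(5, 8, -1.0)])
        assert len(loci) == 2

    def test_transitive_chain_merges(self):
        a, b, c = _estimate(0, 3, 1.0), _estimate(3, 6, 2.0), _estimate(6, 9, -3.0)
        loci = merge_significant_windows([a, b, c])
        assert len(loci) == 1
        assert loci[0].representative is c  # largest |posterior mean Cov|
        assert loci[0].direction == -1

    def test_empty_input(self):
        assert merge_significant_windows([]) == []

    def test_matches_networkx_components(self, rng):
        import networkx as nx

        ests = []
        for _ in range(50):
            lo = int(rng.integers(0, 400))
            ests.append(_estimate(lo, lo + int(rng.integers(0, 12)),
                                  float(rng.standard_normal())))
        loci = merge_significant_windows(ests)
        G = nx.Graph()
        G.add_nodes_from(range(len(ests)))
        for i in range(len(ests)):
            si = set(ests[i].window.member_indices.tolist())
            for j in range(i + 1, len(ests)):
                if si & set(ests[j].window.member_indices.tolist()):
                    G.add_edge(i, j)
        expect = {frozenset(c) for c in nx.connected_components(G)}
        got = {
            frozenset(ests.index(e) for e in L.windows) for L in loci
        }
        assert got == expect


class TestReports:
    def test_round_trip_and_scaling(self, rng, tmp_path):
        panel = make_panel(rng.integers(0, 3, size=(30, 12)))
        X = panel.dosages.astype(float)
        ests = []
        for lo in (0, 4, 8):
            w = _window(lo, lo + 2)
            B = rng.standard_normal((40, 3, 2)) * 0.01
            ests.append(summarize_window(w, window_cov_draws(X[:, lo:lo + 3], B)))
        sig = [e for e in ests if e.significant]
        loci = merge_significant_windows(sig, panel=panel)
        paths = write_results(ests, loci, panel, tmp_path, scale=1e4)
        tab = read_windows_table(paths["windows"])
        assert len(tab) == 3
        for i, e in enumerate(ests):
            # printed values are scaled by 1e4 at 6 significant digits
            assert tab["Cov_mean"].iat[i] == pytest.approx(
                e.post_mean["Cov"] * 1e4, rel=1e-5
            )
        bed = (tmp_path / "windows.bed").read_text().strip().split("\n")
        assert len(bed) == 3 and bed[0].split("\t")[0] == "1"

    def test_printed_scale_example(self, tmp_path, rng):
        # a posterior mean of 6.42e-4 prints as 6.42 under the 1e4 scale
        panel = make_panel(rng.integers(0, 3, size=(20, 3)))
        w = _window(0, 0)
        q = {"V1": 6.42e-4, "V2": 6.42e-4, "Cov": 6.42e-4}
        e = WindowEstimate(window=w, post_mean=q, post_sd=q, cr_low=q, cr_high=q,
                           level=0.95, significant=True)
        write_results([e], [], panel, tmp_path)
        body = (tmp_path / "windows.tsv").read_text()
        assert "6.42" in body

    def test_empty_significant_set_header_only(self, tmp_path, rng):
        panel = make_panel(rng.integers(0, 3, size=(20, 3)))
        write_results([], [], panel, tmp_path)
        lines = (tmp_path / "loci.tsv").read_text().strip().split("\n")
        assert len(lines) == 2 and lines[0].startswith("#")
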