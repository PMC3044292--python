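"""Correlation estimators: hand examples, a brute-force quadrant oracle,
robustness/invariance properties, and the pair screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gmscreen.correlation import pearson, quadrant_correlation, screen_pairs
from gmscreen.synthdata import PanelConfig, generate_panel

NA = float("nan")


def brute_force_pqc(x, y, sine_transform=True):
    """Independent re-implementation of the sign formula, element by element."""
    pairs = [(a, b) for a, b in zip(x, y)
             if not (np.isnan(a) or np.isnan(b))]
    n = len(pairs)
    if n < 3:
        return float("nan"), n
    xs = sorted(a for a, _ in pairs)
    ys = sorted(b for _, b in pairs)

    def median(v):
        m = len(v) // 2
        return v[m] if len(v) % 2 else (v[m - 1] + v[m]) / 2.0

    mx, my = median(xs), median(ys)
    total = 0.0
    for a, b in pairs:
        u = 0 if a == mx else (1 if a > mx else -1)
        v = 0 if b == my else (1 if b > my else -1)
        total += u * v
    q = total / n
    return (float(np.sin(np.pi * q / 2.0)) if sine_transform else q), n


class TestPearson:
    @pytest.mark.parametrize("x, y, r, n", [
        ([1, 2, 3], [2, 4, 6], 1.0, 3),
        ([1, 2, 3, 4], [4, 3, 2, 1], -1.0, 4),
        ([1, 2, NA, 4], [2, 1, 5, NA], NA, 2),   # below minimum complete n
        ([1, 1, 1, 1], [1, 2, 3, 4], NA, 4),     # constant margin
    ])
    def test_examples(self, x, y, r, n):
        got_r, got_n = pearson(x, y)
        assert got_n == n
        if np.isnan(r):
            assert np.isnan(got_r)
        else:
            assert got_r == pytest.approx(r)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            pearson([1, 2, 3], [1, 2])


class TestQuadrant:
    def test_hand_example(self):
        # q = 4/5 (median elements contribute zero), r = sin(2*pi/5)
        r, n = quadrant_correlation([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert n == 5
        assert r == pytest.approx(np.sin(2 * np.pi / 5))
        r2, _ = quadrant_correlation([1, 2, 3, 4, 5], [10, 8, 6, 4, 2])
        assert r2 == pytest.approx(-r)

    def test_raw_statistic_without_sine(self):
        q, _ = quadrant_correlation([1, 2, 3, 4, 5], [2, 4, 6, 8, 10],
                                    sine_transform=False)
        assert q == pytest.approx(0.8)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(5, 26))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            x[rng.random(n) < 0.2] = np.nan
            y[rng.random(n) < 0.2] = np.nan
            want, wn = brute_force_pqc(x, y)
            got, gn = quadrant_correlation(x, y)
            assert gn == wn
            assert got == want or (np.isnan(got) and np.isnan(want))

    @given(st.lists(st.floats(-1e6, 1e6), min_size=5, max_size=30),
           st.integers(0, 2 ** 31 - 1))
    @settings(derandomize=True, max_examples=60)
    def test_symmetry_and_range(self, xs, seed):
        rng = np.random.default_rng(seed)
        ys = rng.normal(size=len(xs))
        r1, n1 = quadrant_correlation(xs, ys)
        r2, n2 = quadrant_correlation(ys, xs)
        assert n1 == n2
        if np.isnan(r1):
            assert np.isnan(r2)
        else:
            assert r1 == pytest.approx(r2)
            assert -1.0 <= r1 <= 1.0

    def test_invariant_under_monotone_transform(self):
        # odd n with unique values: signs depend only on ranks
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = 2 * int(rng.integers(3, 12)) + 1
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            base, _ = quadrant_correlation(x, y)
            trans, _ = quadrant_correlation(np.exp(2 * x), y ** 3)
            assert trans == pytest.approx(base)

    def test_normal_consistency(self):
        # sine-transformed PQC estimates rho on large bivariate normal samples
        for rho in (0.0, 0.7):
            for s in range(3):
                rng = np.random.default_rng(100 + s)
                z = rng.normal(size=(5000, 2))
                x = z[:, 0]
                y = rho * z[:, 0] + np.sqrt(1 - rho ** 2) * z[:, 1]
                r, _ = quadrant_correlation(x, y)
                assert abs(r - rho) < 0.05


class TestScreenPairs:
    def test_cardinality_and_order(self):
        rng = np.random.default_rng(0)
        genes = pd.DataFrame(rng.normal(size=(10, 20)),
                             index=[f"G{i:02d}" for i in range(10)])
        mets = pd.DataFrame(rng.normal(size=(5, 20)),
                            index=[f"C{i:02d}" for i in range(5)])
        rec = screen_pairs(genes, mets)
        assert len(rec) == 50
        keys = list(zip(rec["gene_id"], rec["metabolite_id"]))
        assert keys == sorted(keys)

    def test_noiseless_true_pair_is_perfect(self):
        cfg = PanelConfig(n_samples=20, class_sizes=(20,), class_names=("p",),
                          n_genes=5, n_metabolites_known=3, n_metabolites_unknown=0,
                          n_true_pairs=1, true_pair_slope_range=(2.0, 2.0),
                          metabolite_noise_sd=0.0, missing_rate=0.0,
                          informative_gene_fraction=0.0, heterogeneous_classes=(),
                          n_outlier_pairs=0, seed=5)
        panel, truth = generate_panel(cfg)
        rec = screen_pairs(panel.genes, panel.metabolites)
        g, m = truth.true_pairs.iloc[0][["gene_id", "metabolite_id"]]
        row = rec[(rec.gene_id == g) & (rec.metabolite_id == m)].iloc[0]
        assert row.pcc == pytest.approx(1.0)
        assert row.pqc == pytest.approx(1.0)

    def test_insufficient_n_marking(self):
        genes = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["G1"])
        mets = pd.DataFrame([[1.0, np.nan, 2.0, np.nan]], index=["C1"])
        rec = screen_pairs(genes, mets, min_complete=3)
        assert rec.iloc[0]["category"] == "insufficient_n"
        assert rec.iloc[0]["n_complete"] == 2

    def test_empty_matrix_raises(self):
        with pytest.raises(ValueError):
            screen_pairs(pd.DataFrame(), pd.DataFrame())

    def test_vectorized_path_matches_scalar_kernels(self):
        rng = np.random.default_rng(9)
        genes = pd.DataFrame(rng.normal(size=(8, 30)),
                             index=[f"G{i}" for i in range(8)])
        m = rng.normal(size=(4, 30))
        m[rng.random(m.shape) < 0.25] = np.nan
        mets = pd.DataFrame(m, index=[f"C{i}" for i in range(4)])
        rec = screen_pairs(genes, mets, min_complete=3)
        for row in rec.itertuples():
            x = genes.loc[row.gene_id].to_numpy()
            y = mets.loc[row.metabolite_id].to_numpy()
            want_p, want_n = pearson(x, y)
            want_q, _ = quadrant_correlation(x, y)
            assert row.n_complete == want_n
            assert row.pcc == pytest.approx(want_p, nan_ok=True)
            assert row.pqc == pytest.approx(want_q, nan_ok=True)

    def test_planted_pairs_rank_top_percentile_by_pqc(self):
        # 200 genes x 30 metabolites, 10 planted couplings with slope >= 1
        # over moderate noise: every planted pair lands in the top 1% by PQC
        cfg = PanelConfig(n_samples=57, class_sizes=(57,), class_names=("p",),
                          n_genes=200, n_metabolites_known=20,
                          n_metabolites_unknown=10, n_true_pairs=10,
                          true_pair_slope_range=(1.0, 2.0), gene_noise_sd=0.5,
                          metabolite_noise_sd=0.5, informative_gene_fraction=0.0,
                          heterogeneous_classes=(), n_outlier_pairs=0,
                          missing_rate=0.0, seed=7)
        panel, truth = generate_panel(cfg)
        rec = screen_pairs(panel.genes, panel.metabolites)
        top = rec.nlargest(int(len(rec) * 0.01), "pqc")
        planted = set(zip(truth.true_pairs.gene_id, truth.true_pairs.metabolite_id))
        found = set(zip(top.gene_id, top.metabolite_id))
        assert planted <= found

    def test_pair_list_restriction(self):
        rng = np.random.default_rng(1)
        genes = pd.DataFrame(rng.normal(size=(6, 15)),
                             index=[f"G{i}" for i in range(6)])
        mets = pd.DataFrame(rng.normal(size=(3, 15)),
                            index=[f"C{i}" for i in range(3)])
        wanted = [("G1", "C0"), ("G4", "C2")]
        rec = screen_pairs(genes, mets, pair_list=wanted)
        assert sorted(zip(rec.gene_id, rec.metabolite_id)) == sorted(wanted)
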