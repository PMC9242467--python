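"""GLS enrichment regression, influence diagnostics, overlap testing."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import sparse, stats

from celltrait.enrich import (CollinearDesignError, EnrichmentInput,
                              dfbetas_influence, drop_gene, enrich_scan,
                              gls_enrichment, hypergeom_overlap,
                              make_enrichment_input)


def make_input(Y, E, A=None, P=None, df=None):
    Y = np.asarray(Y, dtype=float)
    N = len(Y)
    E = pd.DataFrame(E, index=[f"g{i}" for i in range(N)])
    A = A if A is not None else E.mean(axis=1).to_numpy()
    P = P if P is not None else np.eye(N)
    df = df if df is not None else np.full(N, 2.0)
    return EnrichmentInput(Y, df, E, A, P, [f"g{i}" for i in range(N)])


def random_input(rng, N, T=3, banded=True):
    E = rng.normal(3.0, 1.0, (N, T))
    df = rng.integers(2, 30, N).astype(float)
    P = np.eye(N)
    if banded:
        for off in (1, 2):
            v = rng.uniform(0.0, 0.3, N - off)
            P[np.arange(N - off), np.arange(off, N)] = v
            P[np.arange(off, N), np.arange(N - off)] = v
        P += np.eye(N) * 0.2  # keep PD
        d = np.sqrt(np.diag(P))
        P = P / np.outer(d, d)
    Y = 1.0 + 0.2 * E[:, 0] + rng.standard_normal(N) * np.sqrt(2.0 / df)
    return make_input(Y, E, P=P, df=df)


class TestGls:
    def test_identity_whitening_equals_ols(self, rng):
        N, T = 60, 2
        inp = random_input(rng, N, T, banded=False)
        inp = make_input(inp.Y, inp.E.to_numpy(), df=np.full(N, 2.0))
        res = gls_enrichment(inp, 0)
        X = np.column_stack([np.ones(N), inp.E[0], inp.A])
        beta, *_ = np.linalg.lstsq(X, inp.Y, rcond=None)
        assert res.gamma_c == pytest.approx(beta[1], rel=1e-9)

    def test_perfect_fit_is_whitening_invariant(self):
        # Y exactly linear in E_c: gamma recovered for any W
        Y = np.array([1.0, 1.0, 2.0, 2.0] * 5)
        E = np.array([0.0, 0.0, 1.0, 1.0] * 5)[:, None]
        A = np.linspace(0, 1, 20) ** 2  # anything independent
        df = np.r_[np.full(19, 2.0), 8.0]  # W = diag(2/df), heteroskedastic
        inp = EnrichmentInput(Y, df, pd.DataFrame(E),
                              A, np.eye(20), [f"g{i}" for i in range(20)])
        res = gls_enrichment(inp, 0)
        assert res.gamma_c == pytest.approx(1.0, abs=1e-8)
        assert res.gamma_0 == pytest.approx(1.0, abs=1e-8)

    def test_one_sided_p_is_half_at_zero_slope(self, rng):
        N = 40
        E = rng.normal(size=(N, 1))
        Y = np.ones(N) + rng.standard_normal(N)
        inp = make_input(Y, np.column_stack([E]), A=rng.normal(size=N))
        res = gls_enrichment(inp, 0)
        assert stats.t.sf(0.0, res.df_resid) == 0.5
        if res.t > 0:
            assert res.p_one_sided < 0.5
        else:
            assert res.p_one_sided > 0.5

    def test_estimates_invariant_to_gene_permutation(self, rng):
        inp = random_input(rng, 50)
        res = gls_enrichment(inp, 0)
        perm = rng.permutation(50)
        P = inp.P[np.ix_(perm, perm)]
        inp2 = EnrichmentInput(inp.Y[perm], inp.df[perm],
                               inp.E.iloc[perm].reset_index(drop=True),
                               inp.A[perm], P,
                               [inp.gene_ids[i] for i in perm])
        res2 = gls_enrichment(inp2, 0)
        assert res.gamma_c == pytest.approx(res2.gamma_c, rel=1e-9)
        assert res.se_c == pytest.approx(res2.se_c, rel=1e-9)

    def test_collinear_design_names_column(self, rng):
        N = 30
        E = np.full((N, 1), 2.0)
        inp = make_input(np.ones(N), E, A=rng.normal(size=N))
        with pytest.raises(CollinearDesignError, match="E_c"):
            gls_enrichment(inp, 0)

    def test_parameter_recovery_and_null_uniformity(self):
        """gamma_c = 0.5 recovered without bias; one-sided p uniform
        under gamma_c = 0 (parametric model simulation)."""
        rng = np.random.default_rng(123)
        N, reps = 400, 150
        df = rng.integers(2, 30, N).astype(float)
        E = rng.normal(3.0, 1.0, (N, 2))
        A = E.mean(axis=1)
        # banded correlation P
        P = np.eye(N)
        v = rng.uniform(0.0, 0.4, N - 1)
        P[np.arange(N - 1), np.arange(1, N)] = v
        P[np.arange(1, N), np.arange(N - 1)] = v
        P = P + 0.3 * np.eye(N)
        d = np.sqrt(np.diag(P))
        P = P / np.outer(d, d)
        D = np.diag(np.sqrt(2.0 / df))
        W = D @ P @ D
        L = np.linalg.cholesky(W)
        gammas, null_ps = [], []
        for _ in range(reps):
            eps = L @ rng.standard_normal(N)
            Y1 = 1.0 + 0.5 * E[:, 0] + 0.2 * A + eps
            inp = EnrichmentInput(Y1, df, pd.DataFrame(E), A, P,
                                  [f"g{i}" for i in range(N)])
            gammas.append(gls_enrichment(inp, 0).gamma_c)
            Y0 = 1.0 + 0.2 * A + (L @ rng.standard_normal(N))
            inp0 = EnrichmentInput(Y0, df, pd.DataFrame(E), A, P,
                                   [f"g{i}" for i in range(N)])
            null_ps.append(gls_enrichment(inp0, 0).p_one_sided)
        mean, se = np.mean(gammas), np.std(gammas, ddof=1) / np.sqrt(reps)
        assert abs(mean - 0.5) < 3 * se
        assert stats.kstest(null_ps, "uniform").pvalue > 0.01


class TestEnrichScan:
    def test_single_cell_type_threshold(self, rng):
        inp = random_input(rng, 40, T=3)
        out = enrich_scan(inp, cell_types=[0])
        assert out["bonferroni_sig"].equals(out["p_one_sided"] < 0.05)

    def test_embedded_cell_type_found(self, rng):
        out_rank = []
        for rep in range(20):
            r = np.random.default_rng(500 + rep)
            inp = random_input(r, 300, T=8)
            table = enrich_scan(inp)
            out_rank.append(table.iloc[0]["cell_type"] == 0)
        assert np.mean(out_rank) >= 0.9


class TestInfluence:
    def test_downdate_matches_brute_force(self, rng):
        """Closed-form leave-one-out equals refitting without the gene."""
        for rep in range(10):
            r = np.random.default_rng(900 + rep)
            inp = random_input(r, 20)
            res = dfbetas_influence(inp, 0)
            full = gls_enrichment(inp, 0).gamma_c
            for gid in inp.gene_ids[:7]:
                sub = gls_enrichment(drop_gene(inp, gid), 0)
                brute_dfbeta = full - sub.gamma_c
                assert abs(res.dfbeta[gid] - brute_dfbeta) < 1e-8
                assert abs(res.dfbetas[gid] - brute_dfbeta / sub.se_c) < 1e-8

    def test_duplicate_gene_in_perfect_fit_has_zero_dfbeta(self):
        Y = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        E = np.array([0.0, 0.0, 1.0, 1.0, 2.0, 2.0])[:, None]
        A = np.array([0.3, 0.3, 0.1, 0.1, 0.5, 0.5])
        inp = make_input(Y, E, A=A)
        res = dfbetas_influence(inp, 0)
        assert np.all(np.abs(res.dfbeta.to_numpy()) < 1e-10)

    def test_cutoff_scales_as_two_over_sqrt_n(self, rng):
        inp = random_input(rng, 100)
        res = dfbetas_influence(inp, 0)
        assert res.cutoff == pytest.approx(0.2)

    def test_small_n_refused(self, rng):
        inp = random_input(rng, 12).__class__(
            **{k: getattr(random_input(rng, 12), k)
               for k in ("Y", "df", "E", "A", "P", "gene_ids")})
        small = drop_gene(inp, inp.gene_ids[0])
        while small.N > 4:
            small = drop_gene(small, small.gene_ids[0])
        with pytest.raises(ValueError, match="ill-posed"):
            dfbetas_influence(small, 0)


class TestHypergeomOverlap:
    def brute(self, q, m, n, k):
        """Exhaustive enumeration over labeled draws."""
        from math import comb
        total = comb(m + n, k)
        hits = sum(comb(m, x) * comb(n, k - x) for x in range(q + 1, min(m, k) + 1))
        return hits / total if total else 0.0

    def test_cannot_exceed_draws(self):
        assert hypergeom_overlap(4, 5, 5, 4) == 0.0
        assert hypergeom_overlap(0, 5, 5, 0) == 0.0

    def test_worked_example(self):
        assert hypergeom_overlap(2, 5, 5, 4) == pytest.approx(55.0 / 210.0,
                                                              rel=1e-12)

    def test_matches_enumeration_small_grid(self):
        for m in range(0, 7):
            for n in range(0, 7):
                for k in range(0, m + n + 1):
                    for q in range(0, min(m, k) + 1):
                        expected = self.brute(q, m, n, k)
                        got = hypergeom_overlap(q, m, n, k)
                        assert got == pytest.approx(expected, abs=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_overlap(6, 5, 5, 4)
        with pytest.raises(ValueError):
            hypergeom_overlap(0, 2, 2, 5)


def test_make_enrichment_input_aligns_and_drops(small_panel):
    from celltrait.expression import CellTypeExpression
    from celltrait.gene_corr import build_gene_corr
    from conftest import annotated_gene
    genes = [annotated_gene(small_panel, i) for i in range(6)]
    gc = build_gene_corr(genes, small_panel, d=4)
    gs = pd.DataFrame({"gene_id": gc.gene_ids,
                       "Q": np.arange(6, dtype=float) + 1.0,
                       "df": np.full(6, 4.0)})
    # expression missing one gene
    E = pd.DataFrame(np.ones((5, 2)) + np.arange(5)[:, None],
                     index=gc.gene_ids[:5], columns=["a", "b"])
    inp = make_enrichment_input(gs, CellTypeExpression(E), gc)
    assert inp.N == 5
    assert inp.gene_ids == gc.gene_ids[:5]
    np.testing.assert_allclose(inp.Y, (np.arange(5) + 1.0) / 4.0)
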