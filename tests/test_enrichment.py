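"""ORA hypergeometric exactness and preranked GSEA running-sum/permutations."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from synprot.enrichment import (
    gsea_enrichment_score,
    gsea_significance,
    ora_hypergeometric,
)
from synprot.io import GeneSet, GeneSetCollection


def make_sets(**named):
    return GeneSetCollection({k: GeneSet(k, "", tuple(v)) for k, v in named.items()})


def ranked_frame(genes, scores):
    return pd.DataFrame({"gene": genes, "score": scores})


def ref_running_sum(scores, hit_positions, w):
    """Scalar reference walk, independent of the package implementation."""
    N = len(scores)
    hits = set(hit_positions)
    nr = sum(abs(scores[i]) ** w for i in hits) or len(hits)
    run, out = 0.0, []
    for i in range(N):
        if i in hits:
            run += (abs(scores[i]) ** w) / nr if sum(abs(scores[j]) ** w for j in hits) else 1.0 / len(hits)
        else:
            run -= 1.0 / (N - len(hits))
        out.append(run)
    mx, mn = max(out), min(out)
    return (mx if mx >= -mn else mn), out


class TestOra:
    UNIVERSE = [f"G{i}" for i in range(20)]

    def test_zero_overlap_gives_p_1(self):
        sets = make_sets(S=self.UNIVERSE[:5])
        res = ora_hypergeometric(self.UNIVERSE[5:10], sets, self.UNIVERSE)
        row = res.table.iloc[0]
        assert row["overlap"] == 0 and row["nominal_p"] == 1.0

    def test_complete_overlap_is_one_over_choose(self):
        """Universe 20, set 5, query 5, overlap 5 -> p = 1/C(20,5)."""
        sets = make_sets(S=self.UNIVERSE[:5])
        res = ora_hypergeometric(self.UNIVERSE[:5], sets, self.UNIVERSE)
        assert res.table.iloc[0]["nominal_p"] == pytest.approx(1 / math.comb(20, 5),
                                                               rel=1e-12)
        assert res.table.iloc[0]["significant"]

    @pytest.mark.parametrize("n_universe,set_size,query_size", [(8, 3, 4), (12, 5, 6), (10, 4, 3)])
    def test_matches_exhaustive_enumeration(self, n_universe, set_size, query_size):
        """p equals the exact fraction of query draws with >= the observed
        overlap, enumerated over all C(N, n) draws."""
        universe = [f"G{i}" for i in range(n_universe)]
        gene_set = universe[:set_size]
        query = universe[1:1 + query_size]
        res = ora_hypergeometric(query, make_sets(S=gene_set), universe)
        k_obs = res.table.iloc[0]["overlap"]
        total = hits = 0
        for draw in itertools.combinations(universe, query_size):
            total += 1
            if len(set(draw) & set(gene_set)) >= k_obs:
                hits += 1
        assert res.table.iloc[0]["nominal_p"] == pytest.approx(hits / total, rel=1e-12)

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="absent from the universe"):
            ora_hypergeometric(["NOPE"], make_sets(S=self.UNIVERSE[:3]), self.UNIVERSE)

    def test_empty_inputs_rejected(self):
        sets = make_sets(S=self.UNIVERSE[:3])
        with pytest.raises(ValueError, match="universe"):
            ora_hypergeometric(["G1"], sets, [])
        with pytest.raises(ValueError, match="query"):
            ora_hypergeometric([], sets, self.UNIVERSE)

    def test_overlap_bounded_and_bh_monotone(self):
        rng = np.random.default_rng(0)
        sets = make_sets(**{f"S{i}": rng.choice(self.UNIVERSE, 6, replace=False)
                            for i in range(8)})
        query = list(rng.choice(self.UNIVERSE, 7, replace=False))
        res = ora_hypergeometric(query, sets, self.UNIVERSE)
        assert (res.table["overlap"] <= np.minimum(res.table["size_in_universe"],
                                                   res.table["query_size"])).all()
        assert (res.table["fdr_q"] >= res.table["nominal_p"] - 1e-12).all()


class TestEnrichmentScore:
    def test_set_of_all_genes_has_es_1(self):
        ranked = ranked_frame(list("ABC"), [3.0, 2.0, 1.0])
        es, _ = gsea_enrichment_score(ranked, {"A", "B", "C"})
        assert es == 1.0

    def test_single_top_gene_w0_has_es_1(self):
        ranked = ranked_frame(list("ABCDE"), [5.0, 4.0, 3.0, 2.0, 1.0])
        es, running = gsea_enrichment_score(ranked, {"A"}, weight_exponent=0.0)
        assert es == 1.0
        assert running[0] == 1.0

    @pytest.mark.parametrize("members,w", [(("B", "D"), 1.0), (("A", "E"), 0.0),
                                           (("C", "D"), 2.0)])
    def test_matches_scalar_reference_walk(self, members, w):
        """N = 5 fixtures: ES equals an independent hand-walked running sum."""
        genes = list("ABCDE")
        scores = [2.5, 1.5, 0.5, -1.0, -2.0]
        ranked = ranked_frame(genes, scores)
        es, running = gsea_enrichment_score(ranked, set(members), weight_exponent=w)
        ref_es, ref_run = ref_running_sum(scores, [genes.index(m) for m in members], w)
        assert es == pytest.approx(ref_es, abs=1e-12)
        np.testing.assert_allclose(running, ref_run, atol=1e-12)

    def test_es_bounded_on_random_rankings(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = rng.integers(5, 40)
            genes = [f"G{i}" for i in range(n)]
            scores = np.sort(rng.normal(size=n))[::-1]
            k = int(rng.integers(1, n))
            members = set(rng.choice(genes, k, replace=False))
            es, _ = gsea_enrichment_score(ranked_frame(genes, scores), members)
            assert -1.0 <= es <= 1.0

    def test_reversed_ranking_negates_es_for_w0(self):
        rng = np.random.default_rng(2)
        genes = [f"G{i}" for i in range(20)]
        scores = np.sort(rng.normal(size=20))[::-1]
        members = set(rng.choice(genes, 6, replace=False))
        es_fwd, _ = gsea_enrichment_score(ranked_frame(genes, scores), members, 0.0)
        es_rev, _ = gsea_enrichment_score(
            ranked_frame(genes[::-1], scores[::-1]), members, 0.0)
        assert es_rev == pytest.approx(-es_fwd, abs=1e-12)

    def test_no_overlap_errors(self):
        with pytest.raises(ValueError, match="no overlap"):
            gsea_enrichment_score(ranked_frame(list("AB"), [1.0, 0.5]), {"Z"})

    def test_agrees_with_gseapy_on_fixture(self):
        """Independent cross-check of the weighted running-sum statistic."""
        import gseapy

        rng = np.random.default_rng(3)
        genes = [f"G{i}" for i in range(60)]
        scores = np.sort(rng.normal(size=60))[::-1]
        members = sorted(rng.choice(genes, 12, replace=False))
        ranked = ranked_frame(genes, scores)
        es, _ = gsea_enrichment_score(ranked, set(members), weight_exponent=1.0)
        res = gseapy.prerank(rnk=ranked.set_index("gene")["score"],
                             gene_sets={"S": members}, permutation_num=4,
                             min_size=1, max_size=1000, weight=1.0, seed=0,
                             outdir=None, no_plot=True)
        assert es == pytest.approx(float(res.res2d["ES"].iloc[0]), abs=1e-6)


class TestSignificance:
    def test_planted_top_set_called_significant(self):
        """A set occupying the very top of a strong ranking passes FDR < 0.25
        and nominal p < 0.05 at 1000 permutations."""
        n = 100
        genes = [f"G{i}" for i in range(n)]
        scores = np.linspace(3.0, -3.0, n)
        sets = make_sets(TOP=genes[:10],
                         RANDOM=[genes[i] for i in range(3, n, 11)])
        res = gsea_significance(ranked_frame(genes, scores), sets, n_perm=1000, seed=5)
        top = res.table.set_index("name").loc["TOP"]
        assert top["significant"]
        assert top["nominal_p"] < 0.05 and top["fdr_q"] < 0.25
        assert top["es"] > 0 and top["nes"] > 1

    def test_exhaustive_permutation_p_matches_enumeration(self):
        """N = 6, set of 2: permutation p equals exact enumeration over all
        C(6,2) = 15 label placements."""
        genes = list("ABCDEF")
        scores = [2.0, 1.2, 0.7, -0.3, -0.9, -1.8]
        members = ("A", "C")
        ranked = ranked_frame(genes, scores)
        res = gsea_significance(ranked, make_sets(S=members), n_perm=1,
                                min_size=1, permutations="exhaustive")
        # independent enumeration with the scalar reference walk
        es_obs, _ = ref_running_sum(scores, [0, 2], 1.0)
        null = [ref_running_sum(scores, list(combo), 1.0)[0]
                for combo in itertools.combinations(range(6), 2)]
        same = [e for e in null if (e >= 0) == (es_obs >= 0)]
        p_ref = sum(abs(e) >= abs(es_obs) for e in same) / len(same)
        assert res.table.iloc[0]["nominal_p"] == pytest.approx(p_ref, rel=1e-12)

    def test_seeded_runs_bit_reproducible(self):
        rng = np.random.default_rng(7)
        genes = [f"G{i}" for i in range(50)]
        scores = np.sort(rng.normal(size=50))[::-1]
        sets = make_sets(A=genes[::7], B=genes[1::5])
        kw = dict(n_perm=200, seed=11, min_size=2)
        a = gsea_significance(ranked_frame(genes, scores), sets, **kw).table
        b = gsea_significance(ranked_frame(genes, scores), sets, **kw).table
        pd.testing.assert_frame_equal(a, b)

    def test_permutation_p_valid_under_null(self):
        """Random sets on random rankings: P(p <= alpha) stays near alpha."""
        rng = np.random.default_rng(13)
        genes = [f"G{i}" for i in range(60)]
        pvals = []
        for rep in range(60):
            scores = np.sort(rng.normal(size=60))[::-1]
            members = rng.choice(genes, 8, replace=False)
            res = gsea_significance(ranked_frame(genes, scores),
                                    make_sets(S=list(members)),
                                    n_perm=99, seed=int(rng.integers(2**31)),
                                    min_size=2)
            pvals.append(res.table.iloc[0]["nominal_p"])
        pvals = np.array(pvals)
        for alpha in (0.05, 0.1):
            # Monte-Carlo slack: 3 binomial SDs
            slack = 3 * np.sqrt(alpha * (1 - alpha) / len(pvals))
            assert np.mean(pvals <= alpha) <= alpha + slack

    def test_no_eligible_set_errors(self):
        ranked = ranked_frame(list("ABC"), [1.0, 0.5, 0.1])
        with pytest.raises(ValueError, match="no gene set eligible"):
            gsea_significance(ranked, make_sets(S=["Z", "Q"]), n_perm=10, seed=0)
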