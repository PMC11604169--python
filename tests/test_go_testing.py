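"""Bias computation, PWF fitting, and Wallenius category testing."""

import numpy as np
import pytest
from scipy import stats

from damid_kit.gatc_index import GatcRegion, InputError
from damid_kit.gene_annotation import GeneModel
from damid_kit.go_testing import (
    GoGeneRecord,
    compute_bias,
    fit_pwf,
)
from damid_kit.go_testing import test_categories as category_test


def _gene(gid, start, end, chrom="c"):
    return GeneModel(gid, gid, chrom, start, end, "+")


class TestBias:
    def test_counts_overlapping_regions_with_window(self):
        regions = [GatcRegion("c", s, s + 100) for s in range(0, 10_000, 100)]
        gene = _gene("g1", 4000, 4300)  # spans 3 regions; window 0
        assert compute_bias([gene], regions, window_bp=0)["g1"] == 3
        # 2 kb window adds 20 regions on each side
        assert compute_bias([gene], regions, window_bp=2000)["g1"] == 43

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(8)
        pos = np.sort(rng.choice(50_000, size=120, replace=False))
        regions = [GatcRegion("c", int(a), int(b)) for a, b in zip(pos, pos[1:])]
        genes = [_gene(f"g{i}", int(s), int(s) + 1500) for i, s in
                 enumerate(rng.choice(40_000, size=25, replace=False))]
        bias = compute_bias(genes, regions, window_bp=2000)
        for g in genes:
            lo, hi = g.start - 2000, g.end + 2000
            naive = sum(1 for r in regions if r.start < hi and r.end > lo)
            assert bias[g.gene_id] == naive

    def test_gene_on_empty_chromosome_has_zero_bias(self):
        regions = [GatcRegion("c", 0, 100)]
        assert compute_bias([_gene("g1", 0, 500, chrom="other")], regions)["g1"] == 0


class TestPwf:
    def test_constant_bias_gives_overall_fraction(self):
        recs = [GoGeneRecord(f"g{i}", i < 30, 7) for i in range(100)]
        pwf = fit_pwf(recs)
        np.testing.assert_allclose(pwf.weights, 0.3)

    def test_degenerate_significance_is_error(self):
        recs = [GoGeneRecord(f"g{i}", True, i) for i in range(10)]
        with pytest.raises(InputError):
            fit_pwf(recs)

    def test_weights_monotone_in_bias(self):
        rng = np.random.default_rng(1)
        bias = rng.integers(1, 60, 400)
        sig = rng.random(400) < np.clip(bias / 60, 0.05, 0.9)
        recs = [GoGeneRecord(f"g{i}", bool(sig[i]), int(bias[i])) for i in range(400)]
        pwf = fit_pwf(recs)
        order = np.argsort(bias, kind="stable")
        w = pwf.weights[order]
        assert (np.diff(w) >= -1e-12).all()

    def test_flat_when_significance_independent_of_bias(self):
        rng = np.random.default_rng(2)
        bias = rng.integers(1, 60, 2000)
        sig = rng.random(2000) < 0.3
        recs = [GoGeneRecord(f"g{i}", bool(sig[i]), int(bias[i])) for i in range(2000)]
        pwf = fit_pwf(recs)
        assert pwf.weights.std() < 0.05  # binomial noise only

    def test_invariant_to_gene_order(self):
        rng = np.random.default_rng(3)
        bias = rng.integers(1, 40, 300)
        sig = rng.random(300) < np.clip(bias / 50, 0.05, 0.9)
        recs = [GoGeneRecord(f"g{i}", bool(sig[i]), int(bias[i])) for i in range(300)]
        pwf1 = fit_pwf(recs)
        perm = rng.permutation(300)
        pwf2 = fit_pwf([recs[i] for i in perm])
        w2 = pwf2.as_series().reindex(pwf1.gene_ids).to_numpy()
        np.testing.assert_allclose(pwf1.weights, w2, atol=1e-12)


@pytest.fixture(scope="module")
def biased_records():
    rng = np.random.default_rng(5)
    bias = rng.poisson(20, 500) + 1
    sig = rng.random(500) < np.clip(bias / bias.max(), 0.02, 0.9) * 0.5
    recs = [GoGeneRecord(f"g{i}", bool(sig[i]), int(bias[i])) for i in range(500)]
    return recs, fit_pwf(recs)


class TestCategories:
    def test_constant_bias_reduces_to_hypergeometric(self):
        rng = np.random.default_rng(6)
        sig = rng.random(300) < 0.25
        if sig.all() or not sig.any():
            raise RuntimeError("fixture degenerate")
        recs = [GoGeneRecord(f"g{i}", bool(sig[i]), 4) for i in range(300)]
        pwf = fit_pwf(recs)
        cats = {"T1": {f"g{i}" for i in range(40)}, "T2": {f"g{i}" for i in range(50, 200)}}
        out = category_test(recs, pwf, cats).set_index("term_id")
        for term, members in cats.items():
            k = int(sum(sig[int(g[1:])] for g in members))
            exact = stats.hypergeom.sf(k - 1, 300, len(members), int(sig.sum()))
            assert abs(out.loc[term, "p_over"] - exact) < 1e-9

    def test_zero_hits_gives_p_one(self, biased_records):
        recs, pwf = biased_records
        nonsig = [r.gene_id for r in recs if not r.is_significant][:10]
        out = category_test(recs, pwf, {"T": set(nonsig)})
        assert out.loc[0, "p_over"] == pytest.approx(1.0)

    def test_wallenius_within_mc_confidence(self, biased_records):
        """Two-group Wallenius p within the MC oracle CI (+ approximation slack)."""
        recs, pwf = biased_records
        rng = np.random.default_rng(9)
        ids = [r.gene_id for r in recs]
        for t in range(5):
            members = set(rng.choice(ids, size=40, replace=False))
            p_w = category_test(recs, pwf, {"T": members}).loc[0, "p_over"]
            p_mc = category_test(
                recs, pwf, {"T": members}, mc_draws=20_000,
                rng=np.random.default_rng(100 + t),
            ).loc[0, "p_over"]
            se = np.sqrt(p_mc * (1 - p_mc) / 20_000)
            # slack covers the documented two-group mean-weight approximation
            assert abs(p_w - p_mc) <= 1.96 * se + max(0.01, 0.05 * p_mc)

    def test_unknown_category_genes_dropped(self, biased_records):
        recs, pwf = biased_records
        members = {recs[0].gene_id, "not_a_gene"}
        out = category_test(recs, pwf, {"T": members})
        assert out.loc[0, "n_in_cat"] == 1

    def test_bias_correction_controls_false_positives(self):
        """With bias-driven significance only, corrected FPR <= uncorrected."""
        from damid_kit import fixtures

        rng = np.random.default_rng(12)
        n_genes = 600
        bias_vals = rng.poisson(15, n_genes) + 1
        p_sig = np.clip(bias_vals / bias_vals.max(), 0.01, 1.0) * 0.9
        sig = rng.random(n_genes) < p_sig
        recs = [GoGeneRecord(f"g{i+1}", bool(sig[i]), int(bias_vals[i]))
                for i in range(n_genes)]
        pwf = fit_pwf(recs)
        gene_ids = [r.gene_id for r in recs]
        bias_map = {g: int(b) for g, b in zip(gene_ids, bias_vals)}
        cats = fixtures.make_categories(
            gene_ids, n_terms=60, mean_size=40, seed=3,
            bias=bias_map, bias_strength=4.0,
        )
        corrected = category_test(recs, pwf, cats)
        uncorrected = category_test(recs, pwf, cats, corrected=False)
        fpr_c = (corrected["p_over"] < 0.05).mean()
        fpr_u = (uncorrected["p_over"] < 0.05).mean()
        assert fpr_c <= fpr_u
        assert fpr_u > 0.05  # the uncorrected test is actually inflated here
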