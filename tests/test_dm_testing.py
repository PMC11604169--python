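"""Filtering, TMM normalization, and the quasi-likelihood NB test."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from damid_kit import fixtures
from damid_kit.counting import RegionCountMatrix, SampleInfo
from damid_kit.dm_testing import (
    DesignSpec,
    FilterConfig,
    RegionFits,
    bh_adjust,
    build_design,
    filter_regions,
    fit_ql_nb,
    tmm_factors,
)
from damid_kit.dm_testing import test_regions as assemble_results  # noqa: E402
from damid_kit.gatc_index import GatcRegion, InputError


def _matrix(counts, widths=None, groups=None, replicates=None):
    counts = np.asarray(counts)
    G, n = counts.shape
    widths = widths if widths is not None else [100] * G
    groups = groups or (["Dam"] * (n // 2) + ["Fusion"] * (n - n // 2))
    replicates = replicates or ([i + 1 for i in range(n // 2)] * 2)[:n]
    regions, pos = [], 0
    for w in widths:
        regions.append(GatcRegion("chr1", pos, pos + w))
        pos += w
    samples = [
        SampleInfo(f"s{j}", "", groups[j], replicates[j]) for j in range(n)
    ]
    return RegionCountMatrix(regions, samples, counts)


class TestFilter:
    def test_width_boundary_strict(self):
        m = _matrix(np.full((3, 4), 50), widths=[10_001, 10_000, 100])
        kept, removed = filter_regions(m, FilterConfig())
        assert removed.set_index("region_id")["reason"].to_dict() == {
            "chr1-0-10001": "width"
        }
        assert len(kept.regions) == 2

    def test_all_zero_region_removed_as_low_count(self):
        counts = np.full((4, 4), 50)
        counts[2] = 0
        m = _matrix(counts)
        kept, removed = filter_regions(m)
        assert list(removed["reason"]) == ["low_count"]
        assert len(kept.regions) == 3

    def test_everything_removed_is_an_error(self):
        m = _matrix(np.full((2, 4), 10), widths=[20_000, 30_000])
        with pytest.raises(InputError, match="nothing to test"):
            filter_regions(m)


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        col = np.arange(1, 21)
        f = tmm_factors(np.column_stack([col] * 4))
        np.testing.assert_allclose(f, 1.0, atol=1e-12)

    def test_doubled_column_absorbed_by_library_size(self):
        rng = np.random.default_rng(0)
        col = rng.poisson(50, 200) + 1
        f = tmm_factors(np.column_stack([col, 2 * col]))
        np.testing.assert_allclose(f, 1.0, atol=1e-12)

    def test_geometric_mean_is_one(self, small_matrix):
        matrix, _ = small_matrix
        f = tmm_factors(matrix)
        assert np.prod(f) ** (1 / len(f)) == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_region_order(self, small_matrix):
        matrix, _ = small_matrix
        rng = np.random.default_rng(1)
        perm = rng.permutation(matrix.counts.shape[0])
        np.testing.assert_allclose(
            tmm_factors(matrix.counts), tmm_factors(matrix.counts[perm]), atol=1e-12
        )

    def test_matches_edger_reference(self, tmp_path):
        """Cross-check factors against edgeR's calcNormFactors on a random matrix."""
        rng = np.random.default_rng(7)
        counts = rng.negative_binomial(5, 0.05, size=(300, 4))
        csv = tmp_path / "counts.csv"
        pd.DataFrame(counts).to_csv(csv, index=False)
        out = tmp_path / "factors.txt"
        script = textwrap.dedent(f"""
            suppressMessages(library(edgeR))
            x <- as.matrix(read.csv("{csv}"))
            f <- calcNormFactors(x, method="TMM")
            writeLines(format(f, digits=15), "{out}")
        """)
        proc = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
        if proc.returncode != 0:
            pytest.skip(f"edgeR unavailable: {proc.stderr[:200]}")
        ref = np.array([float(x) for x in out.read_text().split()])
        np.testing.assert_allclose(tmm_factors(counts), ref, rtol=1e-6)


class TestDesign:
    def test_replicate_confounded_with_group_is_rank_deficient(self):
        samples = [
            SampleInfo("d1", "", "Dam", 1), SampleInfo("d2", "", "Dam", 1),
            SampleInfo("f1", "", "Fusion", 2), SampleInfo("f2", "", "Fusion", 2),
        ]
        with pytest.raises(InputError, match="rank deficient"):
            build_design(samples, DesignSpec(replicate_factor=True))

    def test_group_plus_replicate_design_columns(self):
        samples = [
            SampleInfo("d1", "", "Dam", 1), SampleInfo("d2", "", "Dam", 2),
            SampleInfo("f1", "", "Fusion", 1), SampleInfo("f2", "", "Fusion", 2),
        ]
        X, names = build_design(samples, DesignSpec(replicate_factor=True))
        assert names == ["intercept", "groupFusion", "replicate2"]
        assert np.linalg.matrix_rank(X) == 3


@pytest.fixture(scope="module")
def null_fit():
    spec = fixtures.SimulationSpec(
        seed=11, n_chrom=1, chrom_length=300_000, motif_rate=3.5,
        n_dam=3, n_fusion=3, nb_dispersion=0.1,
        enriched_fraction=0.0, planted_logfc=0.0,
    )
    genome = fixtures.make_genome(spec)
    regions = fixtures.make_regions(genome)
    matrix, _ = fixtures.simulate_counts(regions, spec)
    kept, _ = filter_regions(matrix)
    factors = tmm_factors(kept)
    return kept, fit_ql_nb(kept, factors)


class TestQLFit:
    def test_null_type_one_error(self, null_fit):
        _, fits = null_fit
        p = fits.table["p_value"].to_numpy()
        frac = np.nanmean(p < 0.05)
        assert 0.035 <= frac <= 0.065

    def test_null_p_values_approximately_uniform(self, null_fit):
        from scipy import stats

        _, fits = null_fit
        p = fits.table["p_value"].dropna().to_numpy()
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01

    def test_dispersion_recovered(self, null_fit):
        _, fits = null_fit
        assert 0.07 <= fits.common_dispersion <= 0.14

    def test_swap_property(self, null_fit):
        """Relabeling Fusion<->Dam negates logFC and keeps p-values."""
        kept, fits = null_fit
        swapped_samples = [
            SampleInfo(s.sample_id, s.bam_path,
                       "Dam" if s.group == "Fusion" else "Fusion", s.replicate)
            for s in kept.samples
        ]
        swapped = RegionCountMatrix(kept.regions, swapped_samples, kept.counts)
        fits2 = fit_ql_nb(swapped, tmm_factors(swapped))
        ok = (fits.table["converged"] & fits2.table["converged"]).to_numpy()
        np.testing.assert_allclose(
            fits.table["logFC"].to_numpy()[ok], -fits2.table["logFC"].to_numpy()[ok],
            atol=1e-6,
        )
        np.testing.assert_allclose(
            fits.table["p_value"].to_numpy()[ok], fits2.table["p_value"].to_numpy()[ok],
            atol=1e-6,
        )

    def test_identical_counts_region_is_null(self):
        # equal library sizes: every column is a permutation of the same values
        rng = np.random.default_rng(2)
        base = rng.poisson(40, size=59)
        counts = np.column_stack([rng.permutation(base) for _ in range(6)])
        counts = np.vstack([np.full(6, 40), counts])
        m = _matrix(counts)
        fits = fit_ql_nb(m, np.ones(6))
        assert fits.table.loc[0, "logFC"] == pytest.approx(0.0, abs=1e-6)
        assert fits.table.loc[0, "p_value"] > 0.99

    def test_label_swap_within_replicates_finds_nothing(self):
        """Pairing one Dam and one Fusion per pseudo-group finds ~0 at FDR 0.01."""
        spec = fixtures.SimulationSpec(
            seed=13, n_chrom=1, chrom_length=250_000, motif_rate=3.5,
            n_dam=2, n_fusion=2, nb_dispersion=0.1,
            enriched_fraction=0.0, planted_logfc=0.0,
        )
        genome = fixtures.make_genome(spec)
        regions = fixtures.make_regions(genome)
        samples = fixtures.make_samples(spec)
        matrix, _ = fixtures.simulate_counts(regions, spec, samples)
        # relabel: Dam_1+Fusion_1 vs Dam_2+Fusion_2
        relabeled = [
            SampleInfo(s.sample_id, s.bam_path,
                       "Dam" if s.replicate == 1 else "Fusion", s.replicate)
            for s in samples
        ]
        m = RegionCountMatrix(matrix.regions, relabeled, matrix.counts)
        kept, removed = filter_regions(m)
        fits = fit_ql_nb(kept, tmm_factors(kept))
        res = assemble_results(fits)
        n_fdr_sig = int(((res["fdr"] < 0.01) & (res["logFC"] >= 1)).sum())
        assert n_fdr_sig == 0


class TestPowerRecovery:
    def test_planted_enrichment_recovered(self):
        spec = fixtures.SimulationSpec(
            seed=5, n_chrom=1, chrom_length=300_000, motif_rate=3.5,
            n_dam=3, n_fusion=3, nb_dispersion=0.1,
            enriched_fraction=0.05, planted_logfc=2.0,
        )
        genome = fixtures.make_genome(spec)
        regions = fixtures.make_regions(genome)
        matrix, enriched = fixtures.simulate_counts(regions, spec)
        truth = {r.region_id: e for r, e in zip(matrix.regions, enriched)}
        kept, removed = filter_regions(matrix)
        fits = fit_ql_nb(kept, tmm_factors(kept))
        res = assemble_results(fits, removed=removed)
        res = res[res["meth_status"] != "Not_included"]
        is_true = res["region_id"].map(truth).astype(bool)
        recall = ((res["fdr"] < 0.05) & is_true).sum() / is_true.sum()
        assert recall > 0.6
        assert abs(res.loc[is_true, "logFC"].median() - 2.0) <= 0.3


class TestResults:
    def test_bh_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
        )

    def test_bh_passes_nan_through(self):
        out = bh_adjust(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(out[1])
        assert not np.isnan(out[0])

    def test_logfc_gate(self):
        table = pd.DataFrame(
            {
                "region_id": ["chr1-0-100", "chr1-100-200"],
                "chrom": ["chr1", "chr1"], "start": [0, 100], "end": [100, 200],
                "width": [100, 100], "logFC": [0.8, 1.5], "aveLogCPM": [5.0, 5.0],
                "stat": [30.0, 30.0], "p_value": [0.005, 0.005],
                "converged": [True, True],
            }
        )
        fits = RegionFits(table=table)
        res = assemble_results(fits)
        assert list(res["meth_status"]) == ["No", "Upreg"]

    def test_removed_regions_marked_not_included(self):
        m = _matrix(np.vstack([np.full((40, 4), 30), np.zeros((1, 4), dtype=int)]))
        kept, removed = filter_regions(m)
        fits = fit_ql_nb(kept, tmm_factors(kept))
        res = assemble_results(fits, removed=removed)
        assert (res["meth_status"] == "Not_included").sum() == 1
        assert len(res) == 41
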