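import subprocess

import numpy as np
import pandas as pd
import pytest

from hybridreg.de import (CountMatrix, consensus_de, cpm, filter_low_expression,
                          median_of_ratios_factors, run_de_engine, tmm_factors)
from hybridreg.simulate import SimDesign, simulate_architecture, simulate_counts, truth_table


def _matrix(data, samples, groups):
    counts = pd.DataFrame(data, columns=samples,
                          index=[f"g{i}" for i in range(len(data))])
    design = pd.DataFrame({"sample": samples, "group": groups,
                           "replicate": range(1, len(samples) + 1)}
                          ).set_index("sample")
    return CountMatrix(counts, design)


class TestCpm:
    def test_definition(self):
        counts = pd.DataFrame({"s1": [10, 0, 1]}, index=["a", "b", "c"])
        out = cpm(counts, library_sizes=pd.Series({"s1": 10_000_000}))
        assert out.loc["a", "s1"] == pytest.approx(1.0)
        assert out.loc["b", "s1"] == 0.0
        out2 = cpm(counts, library_sizes=pd.Series({"s1": 1_000_000}))
        assert out2.loc["c", "s1"] == pytest.approx(1.0)

    def test_zero_library_size_rejected(self):
        counts = pd.DataFrame({"s1": [1]})
        with pytest.raises(ValueError):
            cpm(counts, library_sizes=pd.Series({"s1": 0}))


class TestFilterLowExpression:
    def test_gene_low_in_one_group_removed(self):
        cm = _matrix([[500, 500, 500, 500],   # expressed everywhere
                      [0, 0, 500, 500],       # absent in P1: removed
                      [900, 900, 900, 900]],
                     ["P1_1", "P1_2", "P2_1", "P2_2"],
                     ["P1", "P1", "P2", "P2"])
        out = filter_low_expression(cm, min_cpm=1.0)
        assert list(out.counts.index) == ["g0", "g2"]

    def test_lenient_mode_keeps_gene_expressed_somewhere(self):
        cm = _matrix([[0, 0, 500, 500],         # silent in P1 only
                      [0, 0, 0, 0],             # silent everywhere
                      [10_000, 10_000, 10_000, 10_000]],
                     ["P1_1", "P1_2", "P2_1", "P2_2"],
                     ["P1", "P1", "P2", "P2"])
        out = filter_low_expression(cm, mode="all_groups_low_excludes")
        assert list(out.counts.index) == ["g0", "g2"]

    def test_empty_matrix_passthrough(self):
        cm = _matrix(np.empty((0, 2), dtype=int), ["P1_1", "P2_1"], ["P1", "P2"])
        assert filter_low_expression(cm).counts.empty


def _tmm_oracle(counts, ref, sample):
    """Straight-line reimplementation of the published trimmed-mean formula."""
    ys = counts[sample].to_numpy(dtype=float)
    yr = counts[ref].to_numpy(dtype=float)
    ns, nr = ys.sum(), yr.sum()
    keep = (ys > 0) & (yr > 0)
    ys, yr = ys[keep], yr[keep]
    m = np.log2((ys / ns) / (yr / nr))
    a = 0.5 * np.log2((ys / ns) * (yr / nr))
    w = 1.0 / ((ns - ys) / (ns * ys) + (nr - yr) / (nr * yr))
    n = len(m)
    lo_m, hi_m = np.floor(n * 0.3) + 1, n - np.floor(n * 0.3)
    lo_a, hi_a = np.floor(n * 0.05) + 1, n - np.floor(n * 0.05)
    rm = pd.Series(m).rank().to_numpy()
    ra = pd.Series(a).rank().to_numpy()
    sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    return 2.0 ** (np.sum(w[sel] * m[sel]) / np.sum(w[sel]))


class TestTmm:
    def test_identical_samples_have_unit_factors(self):
        counts = pd.DataFrame({"s1": [10, 40, 90, 200, 500],
                               "s2": [10, 40, 90, 200, 500]})
        assert np.allclose(tmm_factors(counts), 1.0)

    def test_pure_depth_scaling_absorbed_by_library_size(self):
        rng = np.random.default_rng(1)
        base = rng.integers(20, 800, size=50)
        counts = pd.DataFrame({"s1": base, "s2": base * 2})
        assert np.allclose(tmm_factors(counts), 1.0, atol=1e-9)

    def test_matches_independent_trimmed_mean_oracle(self):
        rng = np.random.default_rng(7)
        counts = pd.DataFrame(rng.integers(5, 1000, size=(80, 3)),
                              columns=["s1", "s2", "s3"])
        counts.iloc[:8, 2] *= 10  # a handful of strongly DE genes
        factors = tmm_factors(counts, reference_sample="s1")
        raw = {s: _tmm_oracle(counts, "s1", s) for s in counts.columns}
        centred = {s: v / np.exp(np.mean(np.log(list(raw.values()))))
                   for s, v in raw.items()}
        for s in counts.columns:
            assert factors[s] == pytest.approx(centred[s], rel=1e-9)

    def test_matches_edger_calcnormfactors(self):
        # independent cross-check against the reference TMM implementation
        rng = np.random.default_rng(42)
        counts = pd.DataFrame(rng.integers(10, 2000, size=(200, 4)),
                              columns=["s1", "s2", "s3", "s4"],
                              index=[f"g{i}" for i in range(200)])
        counts.iloc[:20, 1] *= 8
        mine = tmm_factors(counts)
        script = (
            "suppressMessages(library(edgeR));"
            "x <- matrix(scan('stdin', quiet=TRUE), ncol=4, byrow=TRUE);"
            "cat(calcNormFactors(x, method='TMM'), sep='\\n')"
        )
        payload = "\n".join(" ".join(map(str, row))
                            for row in counts.to_numpy())
        proc = subprocess.run(["Rscript", "-e", script], input=payload,
                              capture_output=True, text=True, check=True)
        ref = np.array([float(v) for v in proc.stdout.split()])
        assert np.allclose(mine.to_numpy(), ref, rtol=1e-5)

    def test_invariant_to_gene_and_sample_order(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.integers(5, 500, size=(40, 3)),
                              columns=["s1", "s2", "s3"],
                              index=[f"g{i}" for i in range(40)])
        f1 = tmm_factors(counts, reference_sample="s2")
        shuffled = counts.sample(frac=1, random_state=0)[["s3", "s1", "s2"]]
        f2 = tmm_factors(shuffled, reference_sample="s2")
        for s in counts.columns:
            assert f1[s] == pytest.approx(f2[s])

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"s1": [5, 5], "s2": [0, 0]})
        with pytest.raises(ValueError):
            tmm_factors(counts)


class TestMedianOfRatios:
    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame({"s1": [10, 100, 50], "s2": [10, 100, 50]})
        assert np.allclose(median_of_ratios_factors(counts), 1.0)

    def test_scaled_sample_factor_ratio(self):
        counts = pd.DataFrame({"s1": [10, 100, 50], "s2": [10, 100, 50],
                               "s3": [30, 300, 150]})
        f = median_of_ratios_factors(counts)
        assert f["s3"] / f["s1"] == pytest.approx(3.0)

    def test_matches_hand_computed_medians(self):
        counts = pd.DataFrame({"s1": [4, 9, 25], "s2": [16, 36, 100]})
        # geometric means per gene: 8, 18, 50 -> ratios 0.5 / 2.0 each gene
        f = median_of_ratios_factors(counts)
        assert f["s1"] == pytest.approx(0.5)
        assert f["s2"] == pytest.approx(2.0)

    def test_requires_a_gene_nonzero_everywhere(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]})
        with pytest.raises(ValueError):
            median_of_ratios_factors(counts)


class TestEngines:
    @pytest.mark.parametrize("engine", ["nb_exact", "nb_wald"])
    def test_flat_gene_has_zero_lfc_and_null_pvalue(self, engine):
        rng = np.random.default_rng(11)
        per_gene = rng.integers(100, 400, size=20)
        data = np.tile(per_gene[:, None], (1, 6))  # every sample identical
        cm = _matrix(data, [f"P1_{i}" for i in range(3)] + [f"P2_{i}" for i in range(3)],
                     ["P1"] * 3 + ["P2"] * 3)
        res = run_de_engine(cm, ("P1", "P2"), engine)
        assert res.loc["g0", "lfc"] == pytest.approx(0.0, abs=1e-6)
        assert res.loc["g0", "pvalue"] > 0.99

    @pytest.mark.parametrize("engine", ["nb_exact", "nb_wald"])
    def test_strong_fold_change_detected(self, engine):
        rng = np.random.default_rng(12)
        data = rng.integers(100, 400, size=(20, 6))
        data[0, :3] = [100, 110, 105]
        data[0, 3:] = [820, 790, 805]  # ~8-fold up in P2
        cm = _matrix(data, [f"P1_{i}" for i in range(3)] + [f"P2_{i}" for i in range(3)],
                     ["P1"] * 3 + ["P2"] * 3)
        res = run_de_engine(cm, ("P1", "P2"), engine)
        assert res.loc["g0", "fdr"] < 0.01
        assert res.loc["g0", "lfc"] == pytest.approx(3.0, abs=0.5)

    def test_degenerate_contrast_rejected(self, small_count_matrix):
        with pytest.raises(ValueError):
            run_de_engine(small_count_matrix, ("P1", "P1"))
        with pytest.raises(ValueError):
            run_de_engine(small_count_matrix, ("P1", "Hyb"), "nb_exact")

    def test_unknown_engine_rejected(self, small_count_matrix):
        with pytest.raises(ValueError):
            run_de_engine(small_count_matrix, ("P1", "P2"), "deseq")

    def test_power_monotone_in_effect_size(self):
        powers = []
        for effect in (0.3, 0.7, 1.5):
            d = SimDesign(n_genes=300, n_replicates=4, library_size=500_000,
                          class_proportions={"conserved": 0.8, "cis_only": 0.2},
                          effect_size=effect, dispersion=0.05, seed=31)
            arch = simulate_architecture(d)
            cm = filter_low_expression(simulate_counts(arch, d))
            truth = truth_table(arch)
            res = run_de_engine(cm, ("P1", "P2"), "nb_exact")
            planted = truth.index[truth.true_class == "cis_only"]
            powers.append((res.loc[res.index.intersection(planted), "fdr"]
                           < 0.05).mean())
        assert powers[0] <= powers[1] <= powers[2]
        assert powers[0] < 0.5 < powers[2]


class TestConsensus:
    def _results(self, fdrs, lfcs, engine, contrast="P1:P2"):
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(len(fdrs))],
            "lfc": lfcs, "pvalue": fdrs, "fdr": fdrs,
            "engine": engine, "contrast": contrast})

    def test_intersection_and_threshold_logic(self):
        r1 = self._results([0.01, 0.01, 0.01, 0.4], [1.2, 0.7, 1.5, 2.0], "e1")
        r2 = self._results([0.01, 0.01, 0.01, 0.01], [1.1, 0.7, -1.4, 2.0], "e2")
        out = consensus_de(r1, r2, alpha=0.05, lfc_threshold=1.0)
        # g0 passes; g1 fails the lfc threshold; g2 has discordant signs;
        # g3 is not significant in engine 1
        assert list(out["gene_id"]) == ["g0"]
        out05 = consensus_de(r1, r2, alpha=0.05, lfc_threshold=0.5)
        assert set(out05["gene_id"]) == {"g0", "g1"}

    def test_idempotent_on_identical_engines(self):
        r = self._results([0.01, 0.2, 0.001], [1.5, 1.5, -2.0], "e1")
        out = consensus_de(r, r, alpha=0.05, lfc_threshold=1.0)
        expected = set(r.loc[(r.fdr < 0.05) & (r.lfc.abs() >= 1), "gene_id"])
        assert set(out["gene_id"]) == expected

    def test_contrast_mismatch_rejected(self):
        r1 = self._results([0.01], [1.5], "e1", contrast="P1:P2")
        r2 = self._results([0.01], [1.5], "e2", contrast="P1:HybSterile")
        with pytest.raises(ValueError):
            consensus_de(r1, r2)
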