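import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dimorphseq as ds
from dimorphseq.exceptions import DegenerateInputError, DimorphSeqError

from conftest import make_count_matrix


@pytest.fixture(scope="module")
def embryo_like(small_dataset):
    ann, cm, truth = small_dataset
    res = ds.DimorphismModel(cm, annotation=ann).fit()
    return ann, cm, truth, res, res.signature()


class TestProjectLogfc:
    def test_self_projection_signs_agree(self, embryo_like):
        _, cm, _, res, sig = embryo_like
        proj = ds.project_logfc(sig, cm)
        finite = sig.table["log2fc"].replace([np.inf, -np.inf], np.nan).dropna()
        shared = proj.table.index.intersection(finite.index)
        assert len(shared) > 0
        assert (
            np.sign(proj.table.loc[shared, "log2fc"]) == np.sign(finite.loc[shared])
        ).all()

    def test_null_target_class_medians_near_zero(self, embryo_like, small_config):
        ann, _, _, _, sig = embryo_like
        null_cfg = ds.SimulationConfig(
            n_autosomal=small_config.n_autosomal, n_x=small_config.n_x,
            n_y=small_config.n_y, dimorphic_fraction=0.0, x_dosage_log2=0.0,
            xist_log2fc=0.0, seed=99,
        )
        cm_null, _ = ds.simulate_counts(ann, null_cfg)
        proj = ds.project_logfc(sig, cm_null)
        med = proj.class_summary()["median"]
        for cls in ("X", "autosome"):
            if cls in med.index:
                assert abs(med[cls]) < 0.1

    def test_x_dosage_only_target_flags_x_conserved(self, embryo_like, small_config):
        ann, _, truth, _, sig = embryo_like
        cfg = ds.SimulationConfig(
            n_autosomal=small_config.n_autosomal, n_x=small_config.n_x,
            n_y=small_config.n_y, dimorphic_fraction=0.0, x_dosage_log2=1.0,
            seed=77,
        )
        cm_x, _ = ds.simulate_counts(ann, cfg)
        proj = ds.project_logfc(sig, cm_x)
        t = proj.table
        x_rows = t[t["cls"] == "X"]
        auto_rows = t[t["cls"] == "autosome"]
        assert x_rows["conserved"].mean() > 0.8
        # planted autosomal members are not dimorphic in this target
        if len(auto_rows):
            assert auto_rows["conserved"].mean() < 0.2

    def test_missing_genes_listed_not_dropped(self, embryo_like):
        _, cm, _, _, sig = embryo_like
        subset = ds.CountMatrix(cm.counts.iloc[:-40], cm.metadata)
        dropped = set(cm.counts.index[-40:]) & set(sig.gene_ids)
        assert dropped  # fixture sanity
        proj = ds.project_logfc(sig, subset)
        assert set(proj.missing) == dropped

    def test_no_shared_gene_errors(self, embryo_like):
        _, cm, _, _, sig = embryo_like
        renamed = cm.counts.copy()
        renamed.index = [f"other_{g}" for g in renamed.index]
        target = ds.CountMatrix(renamed, cm.metadata)
        with pytest.raises(DimorphSeqError):
            ds.project_logfc(sig, target)

    def test_depth_scaling_invariance(self, embryo_like):
        _, cm, _, _, sig = embryo_like
        proj = ds.project_logfc(sig, cm)
        scaled = cm.counts.copy()
        scaled.iloc[:, 0] = scaled.iloc[:, 0] * 3
        proj2 = ds.project_logfc(sig, ds.CountMatrix(scaled, cm.metadata))
        diff = (proj.table["log2fc"] - proj2.table["log2fc"]).abs()
        assert diff.max() < 0.05


class TestDirectionalConsistency:
    def test_identity_fully_consistent(self):
        lfc = pd.Series([1.0, -2.0, 0.5, -0.3], index=list("abcd"))
        r = ds.directional_consistency(lfc, lfc)
        assert r.fraction_consistent == 1.0
        assert r.n_compared == 4

    def test_hand_example_20_10(self):
        # (same, opposite) = (20, 10): chi2 = 25/15 + 25/15 = 10/3
        a = pd.Series(np.ones(30), index=[f"g{i}" for i in range(30)])
        b = pd.Series([1.0] * 20 + [-1.0] * 10, index=a.index)
        r = ds.directional_consistency(a, b)
        assert r.n_same_sign == 20 and r.n_opposite_sign == 10
        assert r.chi_square == pytest.approx(10 / 3)
        assert r.pvalue == pytest.approx(stats.chi2.sf(10 / 3, 1))
        assert 0.06 < r.pvalue < 0.08

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(3)
        idx = [f"g{i}" for i in range(50)]
        a = pd.Series(rng.normal(size=50), index=idx)
        b = pd.Series(rng.normal(size=50), index=idx)
        r1 = ds.directional_consistency(a, b)
        r2 = ds.directional_consistency(b, a)
        assert (r1.n_same_sign, r1.chi_square, r1.pvalue) == (
            r2.n_same_sign, r2.chi_square, r2.pvalue,
        )

    def test_matches_direct_formula_all_small_counts(self):
        # oracle: chi2 = (same - opp)^2 / n for every split with n <= 30
        for n in range(1, 31):
            for same in range(n + 1):
                a = pd.Series(np.ones(n), index=[f"g{i}" for i in range(n)])
                b = pd.Series([1.0] * same + [-1.0] * (n - same), index=a.index)
                r = ds.directional_consistency(a, b)
                assert r.chi_square == pytest.approx((same - (n - same)) ** 2 / n)

    def test_floor_excludes_weak_genes(self):
        a = pd.Series([1.0, 0.2, -1.0], index=list("abc"))
        b = pd.Series([1.0, -0.2, -1.0], index=list("abc"))
        r = ds.directional_consistency(a, b, floor=0.5)
        assert r.n_compared == 2 and r.fraction_consistent == 1.0
        assert r.floor == 0.5

    def test_no_shared_genes_errors(self):
        a = pd.Series([1.0], index=["a"])
        b = pd.Series([1.0], index=["b"])
        with pytest.raises(DegenerateInputError):
            ds.directional_consistency(a, b)

    def test_random_signs_calibrated(self):
        rng = np.random.default_rng(8)
        idx = [f"g{i}" for i in range(100)]
        a = pd.Series(np.abs(rng.normal(size=100)) + 0.1, index=idx)
        pvals = []
        for _ in range(1000):
            b = pd.Series(
                (np.abs(rng.normal(size=100)) + 0.1) * rng.choice([-1, 1], 100),
                index=idx,
            )
            pvals.append(ds.directional_consistency(a, b).pvalue)
        # the statistic is discrete (binomial lattice), so calibration is
        # checked as the type-I rate at nominal 0.05 rather than by KS
        rejection = np.mean(np.asarray(pvals) <= 0.05)
        assert 0.01 <= rejection <= 0.10


class TestCorrelateLogfc:
    def test_monotone_map_spearman_one(self):
        a = pd.Series([0.1, 1.0, -2.0, 3.0], index=list("abcd"))
        r, _ = ds.correlate_logfc(a, 2 * a)
        assert r == pytest.approx(1.0)
        r_neg, _ = ds.correlate_logfc(a, -a)
        assert r_neg == pytest.approx(-1.0)

    def test_noisy_replicates_high_correlation(self):
        rng = np.random.default_rng(4)
        idx = [f"g{i}" for i in range(69)]
        truth = pd.Series(rng.normal(0.0, 2.0, size=69), index=idx)
        a = truth + rng.normal(0, 0.3, 69)
        b = truth + rng.normal(0, 0.3, 69)
        r, p = ds.correlate_logfc(a, b)
        assert r > 0.9
        assert p < 1e-10

    def test_constant_vector_errors(self):
        a = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        b = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        with pytest.raises(DegenerateInputError):
            ds.correlate_logfc(a, b)

    def test_too_few_shared_errors(self):
        a = pd.Series([1.0, 2.0], index=list("ab"))
        with pytest.raises(DimorphSeqError):
            ds.correlate_logfc(a, a)


class TestXAutosomeRatio:
    def make_dataset(self, x_scale=1.0, seed=0, n=2000):
        rng = np.random.default_rng(seed)
        genes = [f"a{i}" for i in range(n)] + [f"x{i}" for i in range(n)]
        chroms = ["chr1"] * n + ["chrX"] * n
        ann = ds.GeneAnnotation(
            pd.DataFrame(
                {
                    "chrom": chroms,
                    "start": np.arange(2 * n) * 1000,
                    "end": np.arange(2 * n) * 1000 + 500,
                    "strand": "+",
                },
                index=pd.Index(genes, name="gene"),
            )
        )
        mu = np.concatenate([np.full(n, 50.0), np.full(n, 50.0 * x_scale)])
        counts = rng.poisson(mu[:, None], (2 * n, 4))
        cm = make_count_matrix(
            {g: counts[i] for i, g in enumerate(genes)},
            sex=["male", "male", "female", "female"],
        )
        return ann, cm

    def test_identical_distributions_ratio_one(self):
        ann, cm = self.make_dataset(1.0, seed=1)
        assert ds.x_autosome_ratio(cm, ann, "male") == pytest.approx(1.0, abs=0.05)

    def test_doubled_x_baseline_ratio_two(self):
        ann, cm = self.make_dataset(2.0, seed=2)
        assert ds.x_autosome_ratio(cm, ann, "female") == pytest.approx(2.0, abs=0.1)

    def test_female_dosage_doubles_female_ratio(self, small_config):
        cfg = ds.SimulationConfig(
            n_autosomal=1000, n_x=300, n_y=0, x_dosage_log2=1.0,
            dimorphic_fraction=0.0, xist_log2fc=0.0,
            baseline_log_mean_sd=0.5, seed=6,
        )
        ann = ds.simulate_annotation(cfg)
        cm, _ = ds.simulate_counts(ann, cfg)
        r_m = ds.x_autosome_ratio(cm, ann, "male")
        r_f = ds.x_autosome_ratio(cm, ann, "female")
        assert r_f / r_m == pytest.approx(2.0, abs=0.2)

    def test_empty_class_errors(self):
        ann, cm = self.make_dataset(1.0, seed=3, n=5)
        auto_only = ds.GeneAnnotation(ann.table[ann.table["cls"] == "autosome"])
        cm_auto = ds.CountMatrix(
            cm.counts.loc[auto_only.gene_ids], cm.metadata
        )
        with pytest.raises(DegenerateInputError):
            ds.x_autosome_ratio(cm_auto, auto_only, "male")
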