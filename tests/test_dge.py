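"""Moderated-t differential expression, with R limma as independent oracle."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sialonet import dge
from sialonet.errors import ValidationError
from sialonet.synthetic_data import SyntheticConfig, generate_expression


def _tiny_matrix(case_vals, control_vals):
    """One-or-more-gene matrix from per-gene (case tuple, control tuple)."""
    rows = [list(c) + list(n) for c, n in zip(case_vals, control_vals)]
    n_case = len(case_vals[0])
    n_control = len(control_vals[0])
    samples = [f"case_{i}" for i in range(n_case)] + [
        f"ctrl_{i}" for i in range(n_control)
    ]
    matrix = pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))],
                          columns=samples)
    annotation = pd.DataFrame(
        {
            "sample_id": samples,
            "batch": ["b1"] * len(samples),
            "group": ["case"] * n_case + ["control"] * n_control,
        }
    )
    return matrix, annotation


class TestFitGeneModels:
    def test_noiseless_logfc(self):
        matrix, annotation = _tiny_matrix([(2.0, 2.0)], [(1.0, 1.0)])
        fit = dge.fit_gene_models(matrix, annotation)
        assert fit.log_fc[0] == pytest.approx(1.0)
        assert fit.s2[0] == pytest.approx(0.0)

    def test_hand_computed_pooled_variance(self):
        matrix, annotation = _tiny_matrix([(3.0, 1.0)], [(2.0, 0.0)])
        fit = dge.fit_gene_models(matrix, annotation)
        assert fit.log_fc[0] == pytest.approx(1.0)
        assert fit.s2[0] == pytest.approx(2.0)  # (2 + 2) / (4 - 2)
        assert fit.df_residual[0] == 2

    def test_swapping_groups_negates_logfc(self, random_matrix,
                                           two_group_annotation):
        annotation = two_group_annotation(5, 4)
        matrix = random_matrix(40, annotation["sample_id"], seed=8)
        fit = dge.fit_gene_models(matrix, annotation)
        flipped = annotation.assign(
            group=annotation["group"].map({"case": "control", "control": "case"})
        )
        fit_flipped = dge.fit_gene_models(matrix, flipped)
        np.testing.assert_allclose(fit.log_fc, -fit_flipped.log_fc)

    def test_small_group_rejected(self):
        matrix, annotation = _tiny_matrix([(1.0,)], [(0.0, 0.0)])
        with pytest.raises(ValidationError):
            dge.fit_gene_models(matrix, annotation)


class TestEBayesPrior:
    def test_identical_variances_give_infinite_prior_df(self):
        s2 = np.full(100, 0.7)
        df = np.full(100, 50.0)
        params = dge.estimate_eb_params(s2, df)
        assert np.isinf(params.d0)
        assert params.s0_sq == pytest.approx(0.7, rel=0.05)

    def test_parameter_recovery_from_scaled_inv_chisq(self):
        """Moment recovery of (d0, s0^2) from its own sampling model."""
        rng = np.random.default_rng(99)
        d0_true, s0_true, df_g, n_genes = 4.0, 0.5, 8.0, 5000
        true_var = s0_true * d0_true / rng.chisquare(d0_true, n_genes)
        s2 = true_var * rng.chisquare(df_g, n_genes) / df_g
        params = dge.estimate_eb_params(s2, np.full(n_genes, df_g))
        assert params.d0 == pytest.approx(d0_true, rel=0.25)
        assert params.s0_sq == pytest.approx(s0_true, rel=0.15)

    def test_shrinkage_fixed_point_and_bounds(self):
        params = dge.EBayesParams(d0=4.0, s0_sq=1.0)
        s2 = np.array([1.0, 0.2, 5.0])
        df = np.array([6.0, 6.0, 6.0])
        post = params.posterior_var(s2, df)
        assert post[0] == pytest.approx(1.0)
        for raw, shrunk in zip(s2, post):
            assert abs(shrunk - 1.0) <= abs(raw - 1.0)
            assert min(raw, 1.0) - 1e-12 <= shrunk <= max(raw, 1.0) + 1e-12

    def test_degenerate_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            dge.estimate_eb_params(np.zeros(50), np.full(50, 4.0))


class TestModeratedT:
    def test_zero_prior_df_recovers_ordinary_t(self, random_matrix,
                                               two_group_annotation):
        annotation = two_group_annotation(6, 5)
        matrix = random_matrix(60, annotation["sample_id"], seed=4)
        fit = dge.fit_gene_models(matrix, annotation)
        t, df, p = dge.moderated_t(fit, dge.EBayesParams(d0=0.0, s0_sq=1.0))
        case = matrix.iloc[:, :6].to_numpy()
        ctrl = matrix.iloc[:, 6:].to_numpy()
        expected = np.array(
            [stats.ttest_ind(c, n).statistic for c, n in zip(case, ctrl)]
        )
        np.testing.assert_allclose(t, expected, atol=1e-10)

    def test_infinite_prior_df_makes_t_proportional_to_logfc(
        self, random_matrix, two_group_annotation
    ):
        annotation = two_group_annotation(5, 5)
        matrix = random_matrix(30, annotation["sample_id"], seed=6)
        fit = dge.fit_gene_models(matrix, annotation)
        t, _, _ = dge.moderated_t(fit, dge.EBayesParams(d0=np.inf, s0_sq=0.5))
        ratio = t / fit.log_fc
        np.testing.assert_allclose(ratio, ratio[0])

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(2024)
        samples = [f"s{i}" for i in range(10)]
        matrix = pd.DataFrame(
            rng.normal(size=(2000, 10)),
            index=[f"g{i}" for i in range(2000)], columns=samples,
        )
        annotation = pd.DataFrame(
            {"sample_id": samples, "batch": ["b1"] * 10,
             "group": ["case"] * 5 + ["control"] * 5}
        )
        table = dge.run_dge(matrix, annotation)
        frac = float((table["p"] < 0.05).mean())
        assert 0.04 <= frac <= 0.06

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not on PATH")
    def test_matches_reference_limma_implementation(self, tmp_path):
        """Independent oracle: limma lmFit + eBayes on the same contrast."""
        cfg = SyntheticConfig(
            n_genes=400, n_samples_per_group=(8, 6), n_batches=2,
            batch_shift_sd=0.0, n_de_genes=40, pathway_size=(8, 12),
            n_pathways=6, n_active_pathways_per_cluster=2, seed=11,
        )
        matrix, annotation, _ = generate_expression(cfg)
        matrix.to_csv(tmp_path / "mat.tsv", sep="\t")
        annotation.to_csv(tmp_path / "annot.tsv", sep="\t", index=False)
        table = dge.run_dge(matrix, annotation)
        script = """
        suppressMessages(library(limma))
        args <- commandArgs(trailingOnly=TRUE)
        m <- as.matrix(read.delim(args[1], row.names=1))
        a <- read.delim(args[2])
        design <- model.matrix(~0+group, data=a)
        colnames(design) <- c("case", "control")
        fit <- lmFit(m, design)
        fit <- contrasts.fit(fit, makeContrasts(case-control, levels=design))
        fit <- eBayes(fit)
        tab <- topTable(fit, number=Inf, sort.by="none")
        write.csv(data.frame(gene=rownames(tab), logFC=tab$logFC, t=tab$t,
                             p=tab$P.Value, adj_p=tab$adj.P.Val),
                  args[3], row.names=FALSE)
        """
        (tmp_path / "limma.R").write_text(script)
        subprocess.run(
            ["Rscript", str(tmp_path / "limma.R"), str(tmp_path / "mat.tsv"),
             str(tmp_path / "annot.tsv"), str(tmp_path / "out.csv")],
            check=True, capture_output=True,
        )
        reference = pd.read_csv(tmp_path / "out.csv")
        assert list(reference["gene"]) == list(table["gene"])
        for col in ("logFC", "t", "p", "adj_p"):
            np.testing.assert_allclose(
                table[col].to_numpy(), reference[col].to_numpy(), atol=1e-8
            )


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            dge.bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
        )

    def test_single_and_constant_inputs(self):
        np.testing.assert_allclose(dge.bh_adjust(np.array([0.2])), [0.2])
        np.testing.assert_allclose(
            dge.bh_adjust(np.full(5, 0.3)), np.full(5, 0.3)
        )

    def test_permutation_invariance_and_monotonicity(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=40)
        adj = dge.bh_adjust(p)
        perm = rng.permutation(40)
        adj_perm = dge.bh_adjust(p[perm])
        np.testing.assert_allclose(adj[perm], adj_perm)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            dge.bh_adjust(np.array([0.5, 1.2]))


class TestSelectDegs:
    def test_direction_and_alpha_filter(self):
        table = pd.DataFrame(
            {
                "gene": ["a", "b", "c"],
                "logFC": [1.0, -1.0, 2.0],
                "t": [5.0, -5.0, 1.0],
                "df": [10.0] * 3,
                "p": [0.001, 0.001, 0.5],
                "adj_p": [0.005, 0.005, 0.6],
                "direction": ["up", "down", "up"],
            }
        )
        assert dge.select_degs(table, alpha=0.01, direction="up") == ["a"]
        assert dge.select_degs(table, alpha=0.01, direction="down") == ["b"]
        assert dge.select_degs(table.iloc[:0], alpha=0.01) == []

    def test_planted_up_gene_recovery(self):
        cfg = SyntheticConfig(
            n_genes=2000, n_samples_per_group=(15, 15), n_batches=1,
            batch_shift_sd=0.0, n_de_genes=200, de_effect=2.0, noise_sd=0.5,
            cluster_shift=0.0, pathway_size=(8, 12), n_pathways=6,
            n_active_pathways_per_cluster=2, seed=17,
        )
        matrix, annotation, truth = generate_expression(cfg)
        table = dge.run_dge(matrix, annotation)
        selected = set(dge.select_degs(table, alpha=0.01, direction="up"))
        planted_up = {g for g, s in truth.de_genes.items() if s > 0}
        recall = len(selected & planted_up) / len(planted_up)
        fdr = len(selected - planted_up) / max(len(selected), 1)
        assert recall >= 0.9
        assert fdr <= 0.05
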