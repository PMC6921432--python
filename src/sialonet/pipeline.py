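"""End-to-end orchestration of the analysis pipeline.

Stage order mirrors the study workflow: normalize and batch-correct the
merged expression matrix, call differentially expressed genes, project
them onto the interactome (components, hubs, LCC), score pathways by ORA
and ssGSEA, stratify the case samples on their pathway profiles, train and
cross-validate the subgroup classifier, and finish with key driver
analysis on the directed network using the LCC genes as the target set.
Every intermediate artifact is written to the output directory along with
a manifest recording parameters, seeds and SHA-256 checksums, so a rerun
with the same configuration is byte-identical and verifiable.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from sialonet import io
from sialonet.errors import ConfigError, ValidationError
from sialonet.synthetic_data import SyntheticConfig, generate_all

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All inputs and stage parameters of one pipeline run.

    Either ``synthetic`` is set (the generator provides every input) or all
    five input paths must point to existing files.
    """

    outdir: str = "pipeline_out"
    seed: int = 0
    synthetic: SyntheticConfig | None = field(default_factory=SyntheticConfig)
    matrix_path: str | None = None
    annotation_path: str | None = None
    pathways_gmt: str | None = None
    cell_signatures_gmt: str | None = None
    interactome_path: str | None = None
    directed_network_path: str | None = None
    alpha_deg: float = 0.01
    hub_fraction: float = 0.10
    jaccard_threshold: float = 0.25
    k_min: int = 2
    k_max: int = 5
    gap_b: int = 50
    ssgsea_alpha: float = 0.25
    gsea_exponent: float = 1.0
    gsea_n_perm: int = 1000
    combat_mode: str = "location-scale"
    kda_h: int = 3
    kda_alpha: float = 0.01
    kda_direction: str = "downstream"
    linkage_method: str = "average"

    def validate(self) -> "PipelineConfig":
        if self.synthetic is None:
            required = {
                "matrix_path": self.matrix_path,
                "annotation_path": self.annotation_path,
                "pathways_gmt": self.pathways_gmt,
                "interactome_path": self.interactome_path,
                "directed_network_path": self.directed_network_path,
            }
            for name, path in required.items():
                if path is None:
                    raise ConfigError(f"config field {name!r} is required")
                if not Path(path).exists():
                    raise ConfigError(f"{name}: file not found: {path}")
        else:
            self.synthetic.validate()
        if not 0 < self.alpha_deg <= 1:
            raise ConfigError("alpha_deg must be in (0, 1]")
        if not 0 < self.hub_fraction <= 1:
            raise ConfigError("hub_fraction must be in (0, 1]")
        if not (2 <= self.k_min <= self.k_max):
            raise ConfigError("need 2 <= k_min <= k_max")
        if self.gap_b < 10:
            raise ConfigError("gap_b must be >= 10")
        if self.kda_h < 1:
            raise ConfigError("kda_h must be >= 1")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            payload = yaml.safe_load(handle) or {}
        synth = payload.pop("synthetic", "default")
        config = cls(**payload)
        if synth is None:
            config.synthetic = None
        elif synth == "default":
            pass
        else:
            config.synthetic = SyntheticConfig(
                **{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in synth.items()
                }
            )
        return config.validate()

    def to_dict(self) -> dict:
        payload = asdict(self)
        return payload


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2^31 from the global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class PipelineResult:
    """Key outputs of a completed run (files live under ``outdir``)."""

    outdir: Path
    deg_table: pd.DataFrame
    up_degs: list[str]
    lcc: set[str]
    hubs: set[str]
    score_matrix: pd.DataFrame
    cluster_labels: pd.Series
    chosen_k: int
    cv_accuracy: float
    key_drivers: pd.DataFrame
    manifest: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and write the result bundle."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": config.to_dict(), "stages": {}, "checksums": {}}
    current = "setup"
    try:
        # ------------------------------------------------------------ inputs
        current = "inputs"
        if config.synthetic is not None:
            data = generate_all(config.synthetic)
            matrix, annotation = data.matrix, data.annotation
            pathways = data.gene_sets
            interactome = data.interactome
            directed = data.directed_network
            io.write_matrix(matrix, outdir / "expression.tsv")
            io.write_annotation(annotation, outdir / "annotation.tsv")
            io.write_gmt(pathways, outdir / "pathways.gmt")
            io.write_edge_list(interactome, outdir / "interactome.tsv")
            io.write_edge_list(directed, outdir / "directed_network.tsv")
            io.write_json(data.manifest.to_dict(), outdir / "truth_manifest.json")
        else:
            matrix = io.read_matrix(config.matrix_path)
            annotation = io.read_annotation(config.annotation_path)
            pathways = io.read_gmt(config.pathways_gmt)
            interactome = io.read_edge_list(config.interactome_path)
            directed = io.read_edge_list(config.directed_network_path, directed=True)
        cell_signatures = (
            io.read_gmt(config.cell_signatures_gmt)
            if config.cell_signatures_gmt
            else None
        )
        annotation = io.align_annotation(annotation, matrix)
        manifest["stages"]["inputs"] = {
            "n_genes": int(matrix.shape[0]),
            "n_samples": int(matrix.shape[1]),
            "n_pathways": len(pathways),
        }

        # -------------------------------------------------------- preprocess
        current = "preprocess"
        from sialonet import preprocess

        normalized = preprocess.quantile_normalize(matrix)
        qc_before = preprocess.pca_qc(normalized, annotation)
        n_batches = annotation["batch"].nunique()
        if n_batches > 1:
            corrected, _ = preprocess.combat_adjust(
                normalized, annotation, mode=config.combat_mode
            )
        else:
            corrected = normalized
        qc_after = preprocess.pca_qc(corrected, annotation)
        io.write_matrix(corrected, outdir / "normalized.tsv")
        manifest["stages"]["preprocess"] = {
            "batch_r2_pc1_before": float(qc_before.batch_r2[0]),
            "batch_r2_pc1_after": float(qc_after.batch_r2[0]),
        }

        # --------------------------------------------------------------- dge
        current = "dge"
        from sialonet import dge

        deg_table = dge.run_dge(corrected, annotation)
        up_degs = dge.select_degs(deg_table, alpha=config.alpha_deg, direction="up")
        down_degs = dge.select_degs(deg_table, alpha=config.alpha_deg,
                                    direction="down")
        deg_table.to_csv(outdir / "deg_table.csv", index=False,
                         float_format="%.10g")
        io.write_gene_list(up_degs, outdir / "degs_up.txt")
        io.write_gene_list(down_degs, outdir / "degs_down.txt")
        manifest["stages"]["dge"] = {
            "n_up": len(up_degs),
            "n_down": len(down_degs),
            "eb_d0": float(deg_table.attrs["eb_d0"]),
        }
        logger.info("%d up / %d down DEGs at adjusted p < %g",
                    len(up_degs), len(down_degs), config.alpha_deg)

        # ------------------------------------------------------------ netcore
        current = "netcore"
        from sialonet import netcore

        projection = netcore.project_onto_interactome(up_degs, interactome)
        lcc: set[str] = set()
        hubs: set[str] = set()
        if projection.connected_genes:
            # topology is ranked over the interacting genes; isolated query
            # genes are reported as counts, not zero-centrality hub ties
            network = projection.subgraph.subgraph(
                projection.connected_genes
            ).copy()
            lcc = netcore.largest_connected_component(network)
            centrality = netcore.centralities(network)
            hubs = netcore.select_hubs(centrality, fraction=config.hub_fraction)
            centrality.to_csv(outdir / "centrality.csv", float_format="%.10g")
            io.write_gene_list(sorted(hubs), outdir / "hubs.txt")
            io.write_gene_list(sorted(lcc), outdir / "lcc_genes.txt")
        manifest["stages"]["netcore"] = {
            "n_connected": len(projection.connected_genes),
            "n_isolated": len(projection.isolated_genes),
            "n_edges": projection.n_edges,
            "lcc_size": len(lcc),
            "n_hubs": len(hubs),
        }

        # ------------------------------------------------------------- enrich
        current = "enrich"
        from sialonet import enrich

        universe = set(matrix.index)
        ora = enrich.ora_table(set(up_degs), pathways, universe)
        ora.to_csv(outdir / "ora_degs.csv", index=False, float_format="%.10g")

        ranked = deg_table.sort_values(["t", "gene"], ascending=[False, True])
        gsea = enrich.gsea_table(
            ranked["gene"].tolist(),
            ranked["t"].to_numpy(),
            pathways,
            exponent=config.gsea_exponent,
            n_perm=config.gsea_n_perm,
            seed=stage_seed(config.seed, "gsea"),
        )
        gsea.to_csv(outdir / "gsea.csv", index=False, float_format="%.10g")

        scores = enrich.ssgsea_matrix(corrected, pathways,
                                      alpha=config.ssgsea_alpha)
        io.write_matrix(scores, outdir / "ssgsea_scores.tsv")
        if cell_signatures is not None:
            cell_scores = enrich.ssgsea_matrix(
                corrected, cell_signatures, alpha=config.ssgsea_alpha
            )
            io.write_matrix(cell_scores, outdir / "cell_scores.tsv")
        emap = enrich.enrichment_map(pathways,
                                     threshold=config.jaccard_threshold)
        with open(outdir / "enrichment_map.tsv", "w") as handle:
            handle.write("set_a\tset_b\tjaccard\n")
            for a, b, d in sorted(emap.edges(data=True)):
                handle.write(f"{a}\t{b}\t{d['weight']:.6g}\n")
        manifest["stages"]["enrich"] = {
            "n_scored_pathways": int(scores.shape[0]),
            "n_map_edges": emap.number_of_edges(),
        }

        # ------------------------------------------------------------ cluster
        current = "cluster"
        from sialonet import cluster_subgroup as cs

        case_ids = annotation.loc[
            annotation["group"] == "case", "sample_id"
        ].tolist()
        case_scores = scores[case_ids]
        features = cs.zscore_features(case_scores.T)  # samples x pathways
        gap = cs.gap_statistic(
            features,
            k_range=range(config.k_min, config.k_max + 1),
            n_reference=config.gap_b,
            seed=stage_seed(config.seed, "gap"),
            method=config.linkage_method,
        )
        labels = cs.hier_cluster(features, gap.chosen_k,
                                 method=config.linkage_method)
        tests = None
        if gap.chosen_k == 2 and labels.value_counts().min() >= 2:
            tests = cs.between_cluster_tests(case_scores, labels)
        labels.rename("cluster").to_csv(outdir / "cluster_labels.csv")
        diag = pd.DataFrame(
            {
                "k": gap.k_values,
                "gap": gap.gap,
                "s_k": gap.s_k,
                "log_w": gap.log_w,
                "silhouette": [gap.mean_silhouette.get(k, np.nan)
                               for k in gap.k_values],
            }
        )
        diag.to_csv(outdir / "cluster_diagnostics.csv", index=False,
                    float_format="%.10g")
        if tests is not None:
            tests.to_csv(outdir / "between_cluster_tests.csv", index=False,
                         float_format="%.10g")
        manifest["stages"]["cluster"] = {"chosen_k": gap.chosen_k}

        # ----------------------------------------------------------- classify
        current = "classify"
        from sialonet import classify

        model = classify.train_nb(features, labels.astype(str))
        model.to_json(outdir / "nb_model.json")
        cv = classify.cv10(features, labels.astype(str),
                           seed=stage_seed(config.seed, "cv"))
        manifest["stages"]["classify"] = {
            "cv_mean_accuracy": cv.mean_accuracy,
            "fold_accuracy": cv.fold_accuracy,
        }

        # ---------------------------------------------------------------- kda
        current = "kda"
        from sialonet import kda as kda_mod

        targets = lcc if lcc else set(up_degs)
        drivers_df = pd.DataFrame()
        if targets & set(directed.nodes):
            candidates = kda_mod.key_driver_analysis(
                directed,
                targets,
                h_max=config.kda_h,
                alpha=config.kda_alpha,
                direction=config.kda_direction,
                return_all=True,
            )
            drivers_df = kda_mod.candidates_to_frame(candidates)
            drivers_df.to_csv(outdir / "kda_candidates.csv", index=False,
                              float_format="%.10g")
        manifest["stages"]["kda"] = {
            "n_candidates": int(len(drivers_df)),
            "n_key_drivers": int(drivers_df["is_key_driver"].sum())
            if len(drivers_df)
            else 0,
        }

        # ----------------------------------------------------------- manifest
        current = "manifest"
        for path in sorted(outdir.iterdir()):
            if path.name == "run_manifest.json" or path.is_dir():
                continue
            manifest["checksums"][path.name] = _sha256(path)
        io.write_json(manifest, outdir / "run_manifest.json")
    except (ConfigError, ValidationError):
        raise
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage={current}: {exc}\n")
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    return PipelineResult(
        outdir=outdir,
        deg_table=deg_table,
        up_degs=up_degs,
        lcc=lcc,
        hubs=hubs,
        score_matrix=scores,
        cluster_labels=labels,
        chosen_k=gap.chosen_k,
        cv_accuracy=cv.mean_accuracy,
        key_drivers=drivers_df,
        manifest=manifest,
    )
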