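"""Config-driven end-to-end runs and the clustering-order utility.

A run executes: generate or load inputs -> ratio matching (optional) ->
normalization -> three pairwise DE comparisons -> DEG filter -> Venn ->
median-split survival screen over DEGs -> eQTL scan (when genotypes are
present) -> directional-consistency calls -> candidate ranking -> optional
Bayesian network around the top candidate.  Every stage writes its TSV into
the output directory together with a manifest (config hash, seed, version)
so runs are auditable; the same config and seed give a byte-identical
bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import leaves_list, linkage

import raceqtl
from raceqtl import bayesnet, de, eqtl, integrate, io, survival
from raceqtl.errors import ConfigError
from raceqtl.sim import (
    PlantedDriver,
    PlantedShift,
    SimConfig,
    SurvivalGene,
    assemble_matched_cohort,
    simulate_dataset,
)

log = logging.getLogger("raceqtl")


@dataclass
class PipelineConfig:
    """Inputs (paths or a SimConfig) plus every analysis threshold."""

    sim: SimConfig | None = None
    counts_path: str | None = None
    clinical_path: str | None = None
    vcf_path: str | None = None
    eqtl_path: str | None = None
    freqs_path: str | None = None
    match_ratio: dict[str, int] | None = None
    target_library: int = de.DEFAULT_TARGET_LIBRARY
    lfc_threshold: float = de.DEFAULT_LFC_THRESHOLD
    alpha: float = de.DEFAULT_ALPHA
    eqtl_alpha: float = eqtl.DEFAULT_EQTL_ALPHA
    min_gap: float = integrate.DEFAULT_MIN_GAP
    survival_alpha: float = 0.05
    bn_thresholds: dict[str, float] = field(
        default_factory=lambda: dict(bayesnet.DEFAULT_THRESHOLDS)
    )
    run_bn: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sim is None and (self.counts_path is None or self.clinical_path is None):
            raise ConfigError("provide either a SimConfig or counts + clinical paths")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", None)
        sim = None
        if sim_raw is not None:
            sim_raw["planted_drivers"] = [
                PlantedDriver(**d) for d in sim_raw.get("planted_drivers", [])
            ]
            sim_raw["planted_de_only"] = [
                PlantedShift(**d) for d in sim_raw.get("planted_de_only", [])
            ]
            sim_raw["survival_genes"] = [
                SurvivalGene(**d) for d in sim_raw.get("survival_genes", [])
            ]
            for key in ("populations", "cancer_types"):
                if key in sim_raw:
                    sim_raw[key] = tuple(sim_raw[key])
            sim = SimConfig(**sim_raw)
        return cls(sim=sim, **raw)

    def digest(self) -> str:
        payload = {k: repr(v) for k, v in sorted(vars(self).items())}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _stage(name: str):
    log.info("stage %s", name)
    return time.perf_counter()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full analysis; returns the in-memory stage results.

    Stage TSVs and a manifest land in ``outdir``.  Any stage error aborts
    with a stage-labeled message; partial outputs are retained.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "load"
    try:
        t0 = _stage(stage)
        if config.sim is not None:
            ds = simulate_dataset(config.sim)
            counts, clinical = ds["counts"], ds["clinical"]
            genotypes, freqs = ds["genotypes"], ds["freqs"]
            driver_pairs = [(d.snp_id, d.gene_id) for d in config.sim.planted_drivers]
            io.write_counts(counts, out / "counts.tsv")
            io.write_clinical(clinical, out / "clinical.tsv")
            io.write_genotypes_vcf(genotypes, out / "genotypes.vcf")
            io.write_freq_table(freqs, out / "freqs.tsv")
            if len(ds["truth"]):
                io.write_truth_table(ds["truth"], out / "truth.tsv")
        else:
            counts = io.read_counts(config.counts_path)
            clinical = io.read_clinical(config.clinical_path)
            counts.sample_meta = clinical.set_index("sample_id")[["race", "cancer_type"]]
            genotypes = (
                io.read_genotypes_vcf(config.vcf_path) if config.vcf_path else None
            )
            freqs = io.read_freq_table(config.freqs_path) if config.freqs_path else None
            driver_pairs = None

        if config.match_ratio:
            stage = "match"
            _stage(stage)
            clinical = assemble_matched_cohort(clinical, config.match_ratio, seed=config.seed)
            keep = [s for s in counts.sample_ids if s in set(clinical["sample_id"])]
            counts.counts = counts.counts[keep]
            counts.sample_meta = counts.sample_meta.loc[keep]
        results["clinical"] = clinical

        stage = "normalize"
        _stage(stage)
        norm = de.normalize_log2(counts, target_library=config.target_library)
        results["norm"] = norm

        stage = "differential-expression"
        _stage(stage)
        race = counts.sample_meta["race"]
        de_tables = de.run_standard_comparisons(
            norm, race, lfc_threshold=config.lfc_threshold, alpha=config.alpha
        )
        deg_sets = {}
        for (g, r), table in de_tables.items():
            name = f"{g}_vs_{r}"
            table.to_csv(out / f"de_{name}.tsv", sep="\t", float_format="%.6g")
            deg_sets[name] = {gene for gene, _ in de.filter_degs(
                table, lfc_threshold=config.lfc_threshold, alpha=config.alpha
            )}
        results["de_tables"] = de_tables
        venn = de.intersect_comparisons(deg_sets)
        (out / "venn.json").write_text(json.dumps(venn, indent=2, sort_keys=True) + "\n")
        results["venn"] = venn
        all_degs = sorted(set().union(*deg_sets.values()))

        stage = "survival"
        has_surv = (
            {"time", "event"} <= set(clinical.columns)
            and len(clinical) > 0
            and int(clinical["event"].sum()) > 0
        )
        if has_surv and all_degs:
            _stage(stage)
            surv = survival.survival_screen(norm, clinical, genes=all_degs)
            surv.to_csv(out / "survival.tsv", sep="\t", float_format="%.6g")
        else:
            log.info("stage survival skipped: no survival data or no DEGs")
            surv = pd.DataFrame(
                columns=["logrank_statistic", "p", "padj", "direction_of_effect"]
            )
        results["survival"] = surv

        stage = "eqtl"
        calls = []
        if genotypes is not None and freqs is not None:
            _stage(stage)
            pairs = driver_pairs
            if pairs is None:
                # without a supplied pairing, scan every SNP against every DEG
                pairs = [(s, g) for s in genotypes.snp_ids for g in all_degs]
            if config.sim is not None:
                # include every simulated SNP against planted genes plus DEGs
                genes_to_scan = sorted(set(all_degs) | {g for _, g in pairs})
                pairs = [(s, g) for s in genotypes.snp_ids for g in genes_to_scan]
            records = eqtl.eqtl_scan(genotypes, norm, pairs)
            eqtl_frame = eqtl.eqtl_records_to_frame(records)
            eqtl_frame.to_csv(out / "eqtl.tsv", sep="\t", index=False, float_format="%.6g")
            results["eqtl"] = eqtl_frame

            stage = "consistency"
            _stage(stage)
            for rec in records:
                if rec.untestable or rec.padj is None or rec.padj > config.eqtl_alpha:
                    continue
                if rec.increasing_allele == "undetermined":
                    continue
                dv = integrate.build_direction_vector(rec.gene_id, de_tables)
                inc = eqtl.orient_effect_allele(rec, freqs)
                calls.append(
                    integrate.check_consistency(
                        dv, inc, min_gap=config.min_gap, snp_id=rec.snp_id
                    )
                )
            calls_frame = pd.DataFrame(
                [
                    {
                        "snp_id": c.snp_id,
                        "gene_id": c.gene_id,
                        "n_evaluated": c.n_evaluated,
                        "n_consistent": c.n_consistent,
                        "verdict": c.verdict,
                        **{f"status_{g}_vs_{r}": s for (g, r), s in sorted(c.status.items())},
                    }
                    for c in calls
                ]
            )
            calls_frame.to_csv(out / "consistency.tsv", sep="\t", index=False)
            results["consistency"] = calls_frame
            manhattan = integrate.manhattan_table(calls, genotypes, eqtl_frame)
            manhattan.to_csv(out / "manhattan.tsv", sep="\t", index=False, float_format="%.6g")
        else:
            log.info("stage eqtl skipped: genotypes or frequencies absent")

        stage = "ranking"
        _stage(stage)
        ranked = integrate.rank_candidates(
            calls, surv, de_tables, alpha=config.survival_alpha
        )
        ranked["candidates"].to_csv(
            out / "candidates.tsv", sep="\t", index=False, float_format="%.6g"
        )
        ranked["consistent_only"].to_csv(
            out / "consistent_only.tsv", sep="\t", index=False, float_format="%.6g"
        )
        results["candidates"] = ranked["candidates"]
        results["consistent_only"] = ranked["consistent_only"]

        if config.run_bn and len(ranked["candidates"]):
            stage = "bayesnet"
            _stage(stage)
            top_gene = ranked["candidates"].iloc[0]["gene_id"]
            layers = bayesnet.OmicsLayers(
                data=norm.T,
                layers=pd.Series("mrna", index=norm.index),
            )
            nodes = bayesnet.select_features(
                layers, top_gene, thresholds={"mrna": config.bn_thresholds["mrna"]}
            )
            if len(nodes) >= 2:
                model = bayesnet.hill_climb(layers.data, nodes, seed=config.seed)
                edges = model.edges_frame(layers.layers)
                edges.to_csv(out / "bn_edges.tsv", sep="\t", index=False)
                (out / "bn_score.json").write_text(
                    json.dumps({"score": model.score, "n_nodes": len(nodes)}) + "\n"
                )
                results["bn"] = model

        manifest = {
            "package": "raceqtl",
            "version": raceqtl.__version__,
            "seed": config.seed,
            "config_sha256": config.digest(),
            "thresholds": {
                "lfc_threshold": config.lfc_threshold,
                "alpha": config.alpha,
                "eqtl_alpha": config.eqtl_alpha,
                "min_gap": config.min_gap,
                "survival_alpha": config.survival_alpha,
                "target_library": config.target_library,
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        results["manifest"] = manifest
        return results
    except ConfigError as exc:
        raise ConfigError(f"[stage {stage}] {exc}") from exc


def ward_order(matrix: pd.DataFrame) -> dict:
    """Dendrogram leaf orders for heatmap export (Ward linkage, Euclidean).

    Uses the squared-Euclidean Ward update (Ward.D2); a constant matrix
    yields an arbitrary but deterministic order.
    """
    mat = matrix.to_numpy(dtype=float)
    if mat.shape[0] < 2:
        raise ConfigError("need at least 2 rows to cluster")
    row_order = leaves_list(linkage(mat, method="ward")).tolist()
    if mat.shape[1] >= 2:
        col_order = leaves_list(linkage(mat.T, method="ward")).tolist()
    else:
        col_order = list(range(mat.shape[1]))
    return {
        "rows": [matrix.index[i] for i in row_order],
        "cols": [matrix.columns[i] for i in col_order],
    }


def setup_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.handlers = [handler]
    log.setLevel(logging.INFO if verbose else logging.WARNING)
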