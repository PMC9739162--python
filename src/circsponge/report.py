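"""Tissue-level DE summaries and the end-to-end pipeline driver.

``summarize_de`` reproduces the arithmetic of a per-tissue DE summary
table: significant up/down/total counts per tissue at a given adjusted-p
threshold, the nonredundant union of significant feature IDs across
tissues, and each tissue's integer percentage of that union.

``run_pipeline`` chains every stage on a configured (or simulated) study:
caller consensus -> filtering/TMM/moderated-t DE for circRNAs and genes ->
covariate variance partition -> seed-site scanning and miRNA selection ->
target intersection and tripartite network -> hypergeometric enrichment ->
summary tables, writing all artifacts plus a run log into one directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as cio
from .consensus import consensus_from_records, detect_per_condition, detection_summary
from .diffexp import (
    DEResult,
    auto_min_samples,
    filter_by_expression,
    log_cpm,
    moderated_de,
    tmm_factors,
    variance_explained,
)
from .enrichment import hypergeom_enrich
from .sponge import (
    MiRNA,
    build_network,
    integrate_targets,
    select_mirnas,
    site_count_table,
)

logger = logging.getLogger("circsponge")

__all__ = ["DESummary", "summarize_de", "PipelineConfig", "run_pipeline"]


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass
class DESummary:
    """Significant-feature counts per tissue plus the nonredundant pool."""

    per_tissue: dict[str, dict[str, int]]  # tissue -> {up, down, total}
    n_nonredundant: int
    fraction_by_tissue: dict[str, int]  # integer percent of the union

    @property
    def n_up_total(self) -> int:
        return sum(v["up"] for v in self.per_tissue.values())

    @property
    def n_down_total(self) -> int:
        return sum(v["down"] for v in self.per_tissue.values())


def summarize_de(
    de_tables: Mapping[str, Sequence[DEResult]], alpha: float = 0.05
) -> DESummary:
    """Count significant features per tissue and pooled across tissues.

    up = adj_p < alpha and log2fc > 0; down = adj_p < alpha and log2fc < 0.
    A significant feature with log2fc exactly 0 counts as neither (with a
    warning).  "Nonredundant" is the union of significant feature IDs
    across tissues; percentages are of that union, rounded to the nearest
    integer (half away from zero).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    per_tissue: dict[str, dict[str, int]] = {}
    sig_ids_by_tissue: dict[str, set[str]] = {}
    for tissue, results in de_tables.items():
        up = down = 0
        ids: set[str] = set()
        for r in results:
            if r.adj_p >= alpha:
                continue
            if r.log2fc > 0:
                up += 1
            elif r.log2fc < 0:
                down += 1
            else:
                warnings.warn(
                    f"{tissue}/{r.feature_id}: significant with log2fc == 0; "
                    "counted as neither up nor down"
                )
                continue
            ids.add(r.feature_id)
        per_tissue[tissue] = {"up": up, "down": down, "total": up + down}
        sig_ids_by_tissue[tissue] = ids
    union: set[str] = set().union(*sig_ids_by_tissue.values()) if sig_ids_by_tissue else set()
    n_union = len(union)
    fractions = {
        t: _round_half_away(100.0 * len(ids & union) / n_union) if n_union else 0
        for t, ids in sig_ids_by_tissue.items()
    }
    return DESummary(
        per_tissue=per_tissue, n_nonredundant=n_union, fraction_by_tissue=fractions
    )


# ---------------------------------------------------------------------------
# pipeline configuration


_REQUIRED_INPUTS = [
    "caller_table_a",
    "caller_table_b",
    "circ_fasta",
    "mirna_fasta",
    "gene_counts",
    "metadata",
    "target_table",
    "gmt",
]


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "circsponge_run"
    simulate: bool = False
    simulate_params: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    # consensus
    min_reads_b: int = 2
    per_sample_consensus: bool = False
    # diffexp
    min_cpm: float = 10.0
    min_samples: int = 9
    use_auto_min_samples: bool = False
    alpha: float = 0.05
    covariates: list[str] = field(default_factory=list)
    auto_covariates: bool = False
    variance_threshold: float = 0.045
    # sponge
    min_circ: int = 10
    top_k: int = 12
    max_context_score: float | None = None
    scan_tissues: list[str] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def echo(self) -> dict:
        return dataclasses.asdict(self)

    def require_inputs(self) -> None:
        if self.simulate:
            return
        missing = [k for k in _REQUIRED_INPUTS if not self.inputs.get(k)]
        if missing:
            raise ValueError(f"config missing input path(s): {missing}")


# ---------------------------------------------------------------------------
# pipeline stages


def _write_de_table(results: Sequence[DEResult], path: Path) -> None:
    pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "log2fc": r.log2fc,
                "t_mod": r.t_mod,
                "df_total": r.df_total,
                "p": r.p,
                "adj_p": r.adj_p,
                "mean_log_cpm": r.mean_log_cpm,
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False)


def _de_per_tissue(
    counts, metadata: pd.DataFrame, cfg: PipelineConfig, outdir: Path, label: str
) -> dict[str, list[DEResult]]:
    """Filter, normalize and test one count matrix within each tissue."""
    results: dict[str, list[DEResult]] = {}
    var_rows = []
    for tissue in metadata["tissue"].unique():
        sub_meta = metadata[metadata["tissue"] == tissue]
        samples = [s for s in sub_meta["sample"] if s in counts.sample_ids]
        if len(samples) < 4:
            logger.warning("%s/%s: too few samples, skipped", label, tissue)
            continue
        sub_meta = sub_meta[sub_meta["sample"].isin(samples)]
        m = counts.subset_samples(samples)
        min_samples = (
            auto_min_samples(sub_meta) if cfg.use_auto_min_samples
            else min(cfg.min_samples, len(samples))
        )
        m = filter_by_expression(m, min_cpm=cfg.min_cpm, min_samples=min_samples)
        if not m.feature_ids:
            logger.warning("%s/%s: no features pass the expression filter", label, tissue)
            results[tissue] = []
            continue
        factors = tmm_factors(m)
        lcpm = log_cpm(m, factors)

        covs = sub_meta[["RIN", "PMI", "sex"]].reset_index(drop=True).copy()
        covs["group"] = (sub_meta["condition"] == "ALS").to_numpy(int)
        vp = variance_explained(lcpm, covs)
        for cov, med in vp.median_fraction.items():
            var_rows.append(
                {"matrix": label, "tissue": tissue, "covariate": cov,
                 "median_fraction": med}
            )
        de_covs = list(cfg.covariates)
        if cfg.auto_covariates:
            de_covs = [
                c for c in ("RIN", "PMI", "sex")
                if vp.median_fraction.get(c, 0.0) >= cfg.variance_threshold
            ]
            if de_covs:
                logger.info("%s/%s: covariates retained in the DE design: %s",
                            label, tissue, de_covs)
        groups = ["case" if c == "ALS" else "control" for c in sub_meta["condition"]]
        cov_df = sub_meta[de_covs].reset_index(drop=True) if de_covs else None
        res = moderated_de(lcpm, groups, covariates=cov_df)
        results[tissue] = res
        _write_de_table(res, outdir / f"de_{label}_{tissue}.tsv")
    if var_rows:
        pd.DataFrame(var_rows).to_csv(
            outdir / f"variance_partition_{label}.tsv", sep="\t", index=False
        )
    return results


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and return the artifact directory."""
    config.require_inputs()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # -- stage 0: inputs (simulated or supplied) --------------------------
    if config.simulate:
        from .synthetic import SimConfig, generate_study

        sim = SimConfig(seed=config.seed, **config.simulate_params)
        bundle = generate_study(sim, outdir / "simulated_study")
        inputs = {
            "caller_table_a": bundle.caller_table_a,
            "caller_table_b": bundle.caller_table_b,
            "circ_fasta": bundle.circ_fasta,
            "mirna_fasta": bundle.mirna_fasta,
            "gene_counts": bundle.gene_counts,
            "metadata": bundle.metadata,
            "target_table": bundle.target_table,
            "gmt": bundle.gmt,
        }
    else:
        inputs = dict(config.inputs)

    def _stage(name: str):
        logger.info("stage: %s", name)

    try:
        _stage("consensus")
        metadata = cio.read_metadata(inputs["metadata"])
        rec_a = cio.read_caller_table(inputs["caller_table_a"], cio.CIRI2_LIKE)
        rec_b = cio.read_caller_table(inputs["caller_table_b"], cio.CIRCEXPLORER2_LIKE)
        consensus, circ_counts = consensus_from_records(
            rec_a, rec_b, list(metadata["sample"]),
            min_reads_b=config.min_reads_b, per_sample=config.per_sample_consensus,
        )
        cio.write_counts(circ_counts, outdir / "consensus_circ_counts.tsv")
        det_rows = []
        for tissue in metadata["tissue"].unique():
            sub = metadata[metadata["tissue"] == tissue]
            per_cond = detect_per_condition(circ_counts, metadata, tissue)
            s = detection_summary(
                per_cond, tissue=tissue,
                n_case=int((sub["condition"] == "ALS").sum()),
                n_control=int((sub["condition"] == "control").sum()),
            )
            det_rows.append(dataclasses.asdict(s))
        pd.DataFrame(det_rows).to_csv(outdir / "detection_summary.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'consensus' failed: {exc}") from exc

    try:
        _stage("diffexp")
        de_circ = _de_per_tissue(circ_counts, metadata, config, outdir, "circ")
        gene_counts = cio.read_counts(inputs["gene_counts"])
        de_gene = _de_per_tissue(gene_counts, metadata, config, outdir, "gene")
    except Exception as exc:
        raise RuntimeError(f"stage 'diffexp' failed: {exc}") from exc

    try:
        _stage("sponge")
        circ_seqs = cio.read_fasta(inputs["circ_fasta"])
        mirna_seqs = cio.read_fasta(inputs["mirna_fasta"])
        panel = [MiRNA(i, s) for i, s in mirna_seqs.items()]
        targets = cio.read_targets(inputs["target_table"])

        scan_tissues = config.scan_tissues or [
            t for t in de_circ
            if any(r.adj_p < config.alpha for r in de_circ[t])
        ][:2]
        de_circ_ids = {
            t: [r.feature_id for r in de_circ.get(t, []) if r.adj_p < config.alpha]
            for t in scan_tissues
        }
        de_circ_up = {
            t: [r.feature_id for r in de_circ.get(t, [])
                if r.adj_p < config.alpha and r.log2fc > 0]
            for t in scan_tissues
        }
        tables = {
            t: site_count_table(circ_seqs, panel, circ_ids=ids)
            for t, ids in de_circ_ids.items() if ids
        }
        if not tables:
            raise ValueError("no DE circRNAs to scan in any tissue")
        for t, sct in tables.items():
            sct.table.to_csv(outdir / f"site_counts_{t}.tsv", sep="\t")
        selected = select_mirnas(
            tables, de_circ_up, min_circ=config.min_circ, top_k=config.top_k
        )
        selected.to_csv(outdir / "selected_mirnas.tsv", sep="\t")

        gene_de_pool = [r for t in scan_tissues for r in de_gene.get(t, [])]
        affected = integrate_targets(
            list(selected["mirna_id"]), targets, gene_de_pool,
            alpha=config.alpha, max_context_score=config.max_context_score,
        )
        affected.to_csv(outdir / "affected_genes.tsv", sep="\t", index=False)
        network = build_network(
            de_circ_up, list(selected["mirna_id"]), tables, affected, targets
        )
        cio.write_network(network, outdir / "sponge_network.edges.tsv", "edge_list")
        cio.write_network(network, outdir / "sponge_network.graphml", "graphml_like_xml")
    except Exception as exc:
        raise RuntimeError(f"stage 'sponge' failed: {exc}") from exc

    try:
        _stage("enrich")
        collection = cio.read_gmt(inputs["gmt"])
        universe: set[str] = set()
        for t in de_gene:
            universe |= {r.feature_id for r in de_gene[t]}
        enr = hypergeom_enrich(set(affected["gene_id"]), collection, universe)
        pd.DataFrame(
            [
                {"term_id": e.term_id, "name": e.name, "overlap": e.k,
                 "term_size": e.K, "query_size": e.n, "universe": e.N,
                 "p": e.p, "adj_p": e.adj_p}
                for e in enr
            ]
        ).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'enrich' failed: {exc}") from exc

    try:
        _stage("report")
        circ_summary = summarize_de(de_circ, alpha=config.alpha)
        gene_summary = summarize_de(de_gene, alpha=config.alpha)
        rows = []
        for label, summ in (("circ", circ_summary), ("gene", gene_summary)):
            for tissue, counts in summ.per_tissue.items():
                rows.append(
                    {"matrix": label, "tissue": tissue, **counts,
                     "nonredundant_union": summ.n_nonredundant,
                     "percent_of_union": summ.fraction_by_tissue[tissue]}
                )
        pd.DataFrame(rows).to_csv(outdir / "de_summary.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'report' failed: {exc}") from exc

    log = {
        "circsponge_version": __version__,
        "seed": config.seed,
        "parameters": config.echo(),
        "n_consensus_junctions": len(consensus),
        "n_selected_mirnas": int(len(selected)),
        "n_affected_genes": int(len(affected)),
        "network_edges": network.n_edges,
    }
    with open(outdir / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=1, sort_keys=True, default=str)
    return outdir
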