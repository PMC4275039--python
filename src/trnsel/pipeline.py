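"""End-to-end orchestration: simulate -> annotate -> estimate -> network -> compare.

A run is driven by a :class:`PipelineConfig` (YAML-loadable).  In
simulation mode the TRN, the per-gene true selection coefficients and the
MK count tables are generated with known ground truth; in file mode the
edge list and count tables (or genome + annotation + variants) are read
from disk.  Every artifact is plain TSV/JSON, every run writes a config
echo and a run log, and all randomness derives from one seed, so reruns
are bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import group_stats, network_analysis, selection_model, synthetic_data
from . import variant_annotation as va

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run.

    Defaults mirror the study constants: a 1000 bp upstream window, the top
    20% of each role class as hubs and selection-class thresholds at
    gamma = +/-1.
    """

    outdir: str = "trnsel_run"
    seed: int = 0
    simulate: bool = True
    sim: synthetic_data.SimulationConfig = field(
        default_factory=synthetic_data.SimulationConfig)
    coding_preset: str = "paper-coding"
    regulatory_preset: str = "paper-regulatory"
    window: int = 1000
    hub_fraction: float = 0.20
    gamma_thresholds: tuple[float, float] = (-1.0, 1.0)
    display_cap: float = 2.0
    n_boot: int = 200
    power_law_mode: str = "pooled"   # pooled | tf-only
    # file-mode inputs
    edges_path: str | None = None
    counts_coding_path: str | None = None
    counts_regulatory_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        cfg = cls(**raw)
        cfg.sim = synthetic_data.SimulationConfig(**sim_raw)
        if "seed" in raw:
            cfg.sim.seed = cfg.seed
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["version"] = __version__
        return d

    def validate(self) -> None:
        if self.power_law_mode not in ("pooled", "tf-only"):
            raise ConfigError(f"unknown power_law_mode {self.power_law_mode!r}")
        if not self.simulate:
            if self.edges_path is None:
                raise ConfigError("file mode requires edges_path")
            if (self.counts_coding_path is None
                    or self.counts_regulatory_path is None):
                raise ConfigError("file mode requires both count tables")
            for p in (self.edges_path, self.counts_coding_path,
                      self.counts_regulatory_path):
                if not Path(p).exists():
                    raise ConfigError(f"input does not exist: {p}")


def annotate_files(gff3_path, fasta_path, variants_path,
                   window: int = 1000) -> pd.DataFrame:
    """File-level annotation: GFF3 + FASTA + variant table -> MK counts."""
    genes = va.read_gff3(gff3_path)
    genomes = va.read_fasta(fasta_path)
    chrom_lengths = {c: len(s) for c, s in genomes.items()}
    if str(variants_path).endswith(".vcf"):
        variants = va.read_variants_vcf(variants_path)
    else:
        variants = va.read_variant_table(variants_path)
    regions = va.extract_upstream_regions(genes, chrom_lengths, window=window)
    return va.tabulate_mk_counts(genes, regions, variants, genomes)


def summarize_gamma_distribution(gamma: pd.DataFrame,
                                 thresholds: tuple[float, float] = (-1.0, 1.0),
                                 display_cap: float = 2.0,
                                 n_bins: int = 40) -> dict:
    """Selection-class fractions and a display histogram of gamma estimates.

    Genes above ``display_cap`` are left out of the histogram for
    readability but still counted in the class fractions.
    """
    if len(gamma) == 0:
        raise ValueError("empty gamma table")
    lo_t, hi_t = thresholds
    g = gamma["gamma_hat"].to_numpy()
    n = len(g)
    fractions = {
        "near_neutral": float(((g >= lo_t) & (g <= hi_t)).sum() / n),
        "negative": float((g < lo_t).sum() / n),
        "positive": float((g > hi_t).sum() / n),
    }
    shown = g[g <= display_cap]
    hist, edges = np.histogram(shown, bins=n_bins)
    return {
        "n_genes": n,
        "fractions": fractions,
        "mean_gamma": float(g.mean()),
        "histogram": {"counts": hist.tolist(), "edges": edges.tolist(),
                      "n_omitted": int(n - len(shown)),
                      "display_cap": display_cap},
    }


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2 ** 31))
            for child in ss.spawn(n)]


def _simulate_inputs(config: PipelineConfig, log: dict):
    """Synthetic TRN + per-context count tables with ground truth."""
    sim = dataclasses.replace(config.sim, seed=config.seed)
    seeds = _spawn_seeds(config.seed, 5)
    edges, truth = synthetic_data.simulate_trn(
        dataclasses.replace(sim, seed=seeds[0]))
    genes = truth.genes
    n = len(genes)
    g_cod, comp_cod = synthetic_data.draw_gamma_profile(
        n, config.coding_preset, seeds[1])
    g_reg, comp_reg = synthetic_data.draw_gamma_profile(
        n, config.regulatory_preset, seeds[2])
    shift = sim.hub_gamma_shift * genes["hub"].to_numpy()
    g_cod = g_cod + shift
    g_reg = g_reg + shift
    genes = genes.assign(gamma_coding=g_cod, gamma_regulatory=g_reg,
                         component_coding=comp_cod,
                         component_regulatory=comp_reg)
    truth.genes = genes
    ids = genes["gene_id"].to_numpy()
    counts_cod = synthetic_data.simulate_counts(
        g_cod, sim, "coding", seeds[3], gene_ids=ids)
    counts_reg = synthetic_data.simulate_counts(
        g_reg, sim, "regulatory", seeds[4], gene_ids=ids)
    truth.counts = {"coding": counts_cod, "regulatory": counts_reg}
    log["n_tf"] = int((genes["role"] == "TF").sum())
    log["n_target"] = int((genes["role"] == "target").sum())
    log["n_edges"] = int(len(edges))
    return edges, counts_cod, counts_reg, truth


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the artifacts.

    Any stage failure aborts with the stage name; partial outputs written
    before the failure stay on disk flagged in the run log.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"version": __version__, "seed": config.seed, "stages": []}
    (outdir / "config_echo.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=False))

    stage = "inputs"
    try:
        if config.simulate:
            edges, counts_cod, counts_reg, truth = _simulate_inputs(config, log)
            truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t",
                               index=False)
        else:
            edges = pd.read_csv(config.edges_path, sep="\t", comment="#")
            counts_cod = va.read_count_table(config.counts_coding_path)
            counts_reg = va.read_count_table(config.counts_regulatory_path)
            truth = None
        edges.to_csv(outdir / "edges.tsv", sep="\t", index=False)
        va.write_count_table(counts_cod, outdir / "counts_coding.tsv",
                             __version__)
        va.write_count_table(counts_reg, outdir / "counts_regulatory.tsv",
                             __version__)
        log["stages"].append(stage)

        stage = "fit"
        gammas = []
        fit_reports = {}
        for context, counts in (("coding", counts_cod),
                                ("regulatory", counts_reg)):
            fit = selection_model.fit_mk_glmm(counts, context=context)
            gamma = selection_model.estimate_gamma(fit)
            selection_model.write_gamma_table(
                gamma, outdir / f"gamma_{context}.tsv", __version__)
            fit_reports[context] = fit.to_report()
            gammas.append(gamma)
        gamma_all = pd.concat(gammas, ignore_index=True)
        (outdir / "fit_report.json").write_text(
            json.dumps(fit_reports, indent=1))
        log["genes_dropped_in_fit"] = {
            c: fit_reports[c]["n_dropped"] for c in fit_reports}
        log["stages"].append(stage)

        stage = "network"
        net = network_analysis.build_network(edges)
        metrics = network_analysis.node_metrics(net, config.hub_fraction)
        network_analysis.write_node_metrics(
            metrics, outdir / "node_metrics.tsv", __version__)
        if config.power_law_mode == "tf-only":
            k_pool = metrics.loc[metrics["role"].isin(["TF", "both"]),
                                 "k_out"].to_numpy()
        else:
            k_pool = metrics["k"].dropna().to_numpy()
        k_pool = k_pool[k_pool >= 1]
        pl_fit = network_analysis.fit_power_law_tail(k_pool)
        pl_fit.gof_p = network_analysis.bootstrap_gof(
            pl_fit, k_pool, n_boot=config.n_boot,
            seed=_spawn_seeds(config.seed + 7, 1)[0])
        (outdir / "power_law.json").write_text(
            json.dumps({"mode": config.power_law_mode, **pl_fit.to_dict()},
                       indent=1))
        log["stages"].append(stage)

        stage = "compare"
        comparisons = group_stats.compare_hub_vs_nonhub(gamma_all, metrics)
        comparison_errors = {}
        for context in ("coding", "regulatory"):
            try:
                comparisons.append(
                    group_stats.compare_betweenness_by_selection(
                        gamma_all, metrics, context))
            except ValueError as err:
                comparison_errors[f"betweenness_{context}"] = str(err)
                logger.warning("betweenness comparison (%s) skipped: %s",
                               context, err)
        group_stats.write_comparisons(
            comparisons, outdir / "comparisons.tsv", __version__)
        (outdir / "comparisons.json").write_text(json.dumps(
            {c.comparison_id: c.to_dict() for c in comparisons} |
            ({"errors": comparison_errors} if comparison_errors else {}),
            indent=1))
        log["stages"].append(stage)

        stage = "summary"
        summaries = {
            context: summarize_gamma_distribution(
                gamma_all[gamma_all["context"] == context],
                config.gamma_thresholds, config.display_cap)
            for context in ("coding", "regulatory")}
        (outdir / "gamma_summary.json").write_text(
            json.dumps(summaries, indent=1))
        log["stages"].append(stage)
    except Exception:
        log["failed_stage"] = stage
        (outdir / "run_log.json").write_text(json.dumps(log, indent=1))
        logger.error("pipeline aborted in stage %r", stage)
        raise

    log["status"] = "ok"
    (outdir / "run_log.json").write_text(json.dumps(log, indent=1))
    return {
        "edges": edges, "counts_coding": counts_cod,
        "counts_regulatory": counts_reg, "gamma": gamma_all,
        "metrics": metrics, "power_law": pl_fit,
        "comparisons": comparisons, "summaries": summaries,
        "truth": truth, "outdir": outdir,
    }
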