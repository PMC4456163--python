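"""End-to-end orchestration of the synthetic study analysis.

Stage order: simulate -> gblup + extreme selection -> filter + DE ->
FPKM + PCIT per group -> DH + RIF/PIF -> over-representation.  Each stage
writes its output files before the next starts, and the run ends with a
manifest recording the config, seed and output checksums.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, diffexpr, enrich, gblup, impact, io, pcit
from .enrich import GeneSetCollection
from .simdata import SimConfig, generate_study

log = logging.getLogger("imfnet")


@dataclasses.dataclass
class PipelineConfig:
    """Simulation conditions plus every stage threshold."""

    sim: SimConfig = dataclasses.field(default_factory=SimConfig)
    fdr: float = 0.10
    fdr_secondary: float = 0.20
    rmin: float = 0.90
    scale: str = "log"  # correlate on log2(FPKM+1) ("log") or raw fpkm
    dh_sign: str = "high_minus_low"
    dh_top: int = 10
    pif_top: int = 3000
    dispersion_sharing: str = "fit-only"
    gmt: str | None = None  # optional gene-set file for the enrichment stage

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim_keys = {f.name for f in dataclasses.fields(SimConfig)}
        sim_kwargs = {}
        for key in list(raw):
            if key in sim_keys:
                val = raw.pop(key)
                if isinstance(val, list):
                    val = tuple(val)
                sim_kwargs[key] = val
        pipe_keys = {f.name for f in dataclasses.fields(cls)} - {"sim"}
        unknown = set(raw) - pipe_keys
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(sim=SimConfig(**sim_kwargs), **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        sim = d.pop("sim")
        return {**sim, **d}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _truth_gene_sets(bundle) -> GeneSetCollection:
    """Planted modules plus size-matched random sets, for the ORA stage."""
    sets, desc = {}, {}
    for reg, members in bundle.truth.regulator_targets.items():
        name = f"module_{reg}"
        sets[name] = set(members)
        desc[name] = f"planted target module of {reg}"
    rng = np.random.default_rng(np.random.SeedSequence(bundle.config.seed).spawn(5)[4])
    genes = list(bundle.counts.index)
    for i in range(max(3, len(sets))):
        name = f"random_set_{i + 1}"
        size = max(5, bundle.config.module_size)
        sets[name] = set(rng.choice(genes, size=size, replace=False))
        desc[name] = "size-matched random gene set"
    return GeneSetCollection(sets=sets, descriptions=desc)


def run_pipeline(config: PipelineConfig, outdir, seed: int | None = None) -> dict:
    """Run every stage, writing declared outputs under ``outdir``.

    ``seed`` overrides ``config.sim.seed`` when given.  Returns the in-memory
    stage results keyed by name.  A stage failure raises :class:`StageError`
    naming the stage; outputs of earlier stages are preserved.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = dataclasses.replace(config, sim=dataclasses.replace(config.sim, seed=seed))
    manifest = io.RunManifest(version=__version__, seed=config.sim.seed, config=config.to_dict())
    manifest.start()
    results: dict = {}
    written: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        written.append(path)
        return path

    stage = "simulate"
    try:
        bundle = generate_study(config.sim)
        results["bundle"] = bundle
        emit("genotypes.tsv", lambda p: io.write_matrix_tsv(
            pd.DataFrame(bundle.genotypes.dosages,
                         index=pd.Index(bundle.genotypes.animal_ids, name="animal_id"),
                         columns=bundle.genotypes.snp_ids), p))
        emit("phenotypes.tsv", lambda p: bundle.trait.phenotypes.to_csv(p, sep="\t", lineterminator="\n"))
        emit("counts.tsv", lambda p: io.write_matrix_tsv(bundle.counts, p))
        emit("lengths.tsv", lambda p: io.write_matrix_tsv(bundle.gene_lengths.to_frame(), p))
        emit("library_sizes.tsv", lambda p: io.write_matrix_tsv(bundle.library_sizes.to_frame(), p))
        emit("truth.json", lambda p: io.write_json(bundle.truth.to_dict(), p))
        manifest.row_counts["genes_simulated"] = len(bundle.counts)
        log.info("simulate: %d animals, %d genes, %d samples",
                 config.sim.n_animals, len(bundle.counts), bundle.counts.shape[1])

        stage = "gblup"
        gebv = pd.DataFrame({"gebv": bundle.fit.gebv},
                            index=pd.Index(bundle.genotypes.animal_ids, name="animal_id"))
        emit("gebv.tsv", lambda p: gebv.to_csv(p, sep="\t", lineterminator="\n"))
        emit("varcomps.json", lambda p: io.write_json(
            {"sigma2_m": bundle.fit.varcomps.sigma2_m,
             "sigma2_e": bundle.fit.varcomps.sigma2_e,
             "heritability": bundle.fit.heritability}, p))
        emit("groups.tsv", lambda p: io.write_groups_tsv(bundle.groups, p))
        phen = bundle.trait.phenotypes["trait"]
        t, df_t, p_t = gblup.welch_t_test(
            phen.loc[bundle.extremes.high_ids], phen.loc[bundle.extremes.low_ids])
        emit("ttest.json", lambda p: io.write_json({"t": t, "df": df_t, "p": p_t}, p))
        log.info("gblup: h2=%.3f, extreme-group t=%.2f (p=%.3g)", bundle.fit.heritability, t, p_t)

        stage = "de"
        filtered = diffexpr.filter_counts(bundle.counts)
        emit("filtered_counts.tsv", lambda p: io.write_matrix_tsv(filtered, p))
        de_res = diffexpr.run_de(filtered, bundle.groups, fdr=config.fdr,
                                 sharing=config.dispersion_sharing)
        de_res["de_secondary"] = de_res["padj"] <= config.fdr_secondary
        results["de"] = de_res
        emit("de_results.tsv", lambda p: de_res.to_csv(p, sep="\t", lineterminator="\n"))
        manifest.row_counts["genes_analyzed"] = len(filtered)
        manifest.row_counts["de_genes"] = int(de_res["de"].sum())
        log.info("de: %d genes analyzed, %d DE at FDR %.2f",
                 len(filtered), int(de_res["de"].sum()), config.fdr)

        stage = "pcit"
        expr = pcit.fpkm(filtered, bundle.gene_lengths.reindex(filtered.index),
                         library_sizes=bundle.library_sizes)
        emit("fpkm.tsv", lambda p: io.write_matrix_tsv(expr.values, p))
        logexpr = pcit.log_transform(expr)
        corr_input = logexpr if config.scale == "log" else expr
        nets = {}
        for label in ("high", "low"):
            cols = bundle.groups.index[bundle.groups == label]
            nets[label] = pcit.group_network(
                corr_input.values[cols], r_min=config.rmin, group=label)
            emit(f"edges_{label}.tsv",
                 lambda p, lb=label: nets[lb].edges.to_csv(p, sep="\t", index=False, lineterminator="\n"))
            emit(f"degrees_{label}.tsv",
                 lambda p, lb=label: nets[lb].degrees.to_frame("degree").to_csv(p, sep="\t", lineterminator="\n"))
            manifest.row_counts[f"edges_{label}"] = nets[label].n_edges
        results["networks"] = nets
        log.info("pcit: %d high-group edges, %d low-group edges",
                 nets["high"].n_edges, nets["low"].n_edges)

        stage = "impact"
        dh = impact.differential_hubbing(nets["high"], nets["low"], sign=config.dh_sign)
        emit("dh.tsv", lambda p: dh.to_csv(p, sep="\t", lineterminator="\n"))
        pos, neg = impact.top_dh(dh, k=config.dh_top)
        emit("top_dh_positive.tsv", lambda p: pos.to_csv(p, sep="\t", lineterminator="\n"))
        emit("top_dh_negative.tsv", lambda p: neg.to_csv(p, sep="\t", lineterminator="\n"))
        cols_h = bundle.groups.index[bundle.groups == "high"]
        cols_l = bundle.groups.index[bundle.groups == "low"]
        expr_h, expr_l = logexpr.values[cols_h], logexpr.values[cols_l]
        candidates = impact.candidate_regulators(nets["high"], nets["low"])
        de_ids = list(de_res.index[de_res["de"]])
        results["dh"] = dh
        if candidates and de_ids:
            rif = impact.rif_scores(expr_h, expr_l, de_ids, candidates)
            results["rif"] = rif
            emit("rif.tsv", lambda p: rif.to_csv(p, sep="\t", lineterminator="\n"))
        else:
            log.warning("impact: no candidates or no DE genes; RIF skipped")
        pif = impact.pif_scores(expr_h, expr_l)
        top = impact.top_pif(pif["pif"], k=config.pif_top)
        emit("top_pif.tsv", lambda p: pif.loc[top].to_csv(p, sep="\t", lineterminator="\n"))
        manifest.row_counts["rif_candidates"] = len(candidates)

        stage = "enrich"
        collection = enrich.read_gmt(config.gmt) if config.gmt else _truth_gene_sets(bundle)
        universe = list(filtered.index)
        query = list(de_res.index[de_res["de_secondary"]])
        ora = enrich.ora(query, collection, universe)
        results["ora"] = ora
        emit("ora.tsv", lambda p: ora.to_csv(p, sep="\t", lineterminator="\n"))
        log.info("enrich: %d sets tested against %d query genes", len(ora), len(query))
    except Exception as exc:
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc

    for path in written:
        manifest.record_file(path)
    manifest.finish()
    manifest.write(outdir / "manifest.json")
    results["manifest"] = manifest
    return results
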