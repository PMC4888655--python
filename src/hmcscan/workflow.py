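"""Configuration-driven orchestration of the full 5hmC analysis.

A single YAML document drives simulate -> call -> quantify -> profile ->
compare -> cluster. Every stage communicates through files under the
output directory, and a manifest records parameters, the seed, and a
SHA-256 digest of every produced file, so a rerun with the same config
is verifiably identical for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .annotation import build_element_map, element_proportions, relative_density
from .cluster_dynamics import (GeneBodyMatrix, cluster_expression_summary,
                               cluster_genes, delta_analysis, select_high_cluster)
from .core import SiteTable
from .enhancer_tf import classify_enhancers, compare_tf_occupancy, split_by_5hmc
from .profiles import expression_tertiles, ks_two_sample, spearman_perm, tss_profile
from .rrhp_sites import call_sites, derive_cutoff, gene_body_levels
from .synthetic_data import SyntheticConfig, simulate

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("hmcscan")

_DEFAULT_PARAMS = {
    "cutoff_mode": "pooled",
    "tss_window": 5000,
    "tss_bin": 50,
    "flank_bp": 1000,
    "n_body_bins": 50,
    "flank_bin_bp": 50,
    "n_perm": 10000,
    "k_first": 5,
    "k_second": 6,
    "min_fpkm": 1.0,
    "lfc_threshold": 2.0,
}


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 0
    simulate: dict | None = None          # SyntheticConfig overrides, or None
    inputs: dict | None = None            # explicit file paths when not simulating
    reference_cell_type: str = "hESC"
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        merged = dict(_DEFAULT_PARAMS)
        merged.update(self.params)
        self.params = merged

    def validate(self) -> None:
        if self.simulate is None and self.inputs is None:
            raise ValueError("config needs either a 'simulate' block or an 'inputs' block")
        if self.inputs is not None:
            for key in ("genes", "sites", "expression"):
                if key not in self.inputs:
                    raise ValueError(f"inputs missing required field '{key}'")
            for key, val in self.inputs.items():
                paths = val.values() if isinstance(val, dict) else [val]
                for p in _flatten(paths):
                    if not Path(p).exists():
                        raise ValueError(f"inputs.{key}: file not found: {p}")


def _flatten(values):
    for v in values:
        if isinstance(v, (list, tuple)):
            yield from v
        elif isinstance(v, dict):
            yield from _flatten(v.values())
        else:
            yield v


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig(
        outdir=raw.get("outdir", "hmcscan_run"),
        seed=int(raw.get("seed", 0)),
        simulate=raw.get("simulate"),
        inputs=raw.get("inputs"),
        reference_cell_type=raw.get("reference_cell_type", "hESC"),
        params=raw.get("params", {}) or {},
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_simulated_inputs(bundle: dict, indir: Path) -> dict:
    """Serialise a simulated dataset as pipeline input files (truth kept apart)."""
    indir.mkdir(parents=True, exist_ok=True)
    genome = bundle["genome"]
    io.write_gtf(genome.genes, indir / "genes.gtf")
    io.write_chrom_sizes(genome.chrom_sizes, indir / "chrom.sizes")
    io.write_bed(genome.ccgg.assign(end=genome.ccgg["pos"] + 1)
                 .rename(columns={"pos": "start"}), indir / "ccgg.bed")
    sites: dict[str, list[str]] = {}
    for (ct, rep), table in bundle["rrhp"].items():
        p = indir / f"sites_{ct}_rep{rep}.tsv"
        io.write_site_table(table, p)
        sites.setdefault(ct, []).append(str(p))
    expression = {}
    for ct, expr in bundle["expression"].items():
        p = indir / f"expression_{ct}.tsv"
        io.write_expression(expr, p)
        expression[ct] = str(p)
    for name, peaks in bundle["peaks"].items():
        io.write_bed(peaks, indir / f"peaks_{name}.bed")
    tf_rows = []
    for chrom in bundle["tf_track"].chroms():
        starts, ends, values, _ = bundle["tf_track"]._data[chrom]
        tf_rows.append(pd.DataFrame({"chrom": chrom, "start": starts.astype(int),
                                     "end": ends.astype(int), "value": values}))
    if tf_rows:
        io.write_bedgraph(pd.concat(tf_rows, ignore_index=True), indir / "tf.bedgraph")
    truth = bundle["truth"]
    io.write_truth({
        "genes": truth.genes.to_dict(orient="list"),
        "enhancers": truth.enhancers.astype(
            {"hmc_positive": bool}).to_dict(orient="list"),
    }, indir / "truth.json")
    return {
        "genes": str(indir / "genes.gtf"),
        "chrom_sizes": str(indir / "chrom.sizes"),
        "sites": sites,
        "expression": expression,
        "peaks": {"H3K27ac": str(indir / "peaks_H3K27ac.bed"),
                  "H3K4me1": str(indir / "peaks_H3K4me1.bed")},
        "tf": str(indir / "tf.bedgraph"),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the manifest dict."""
    config.validate()
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)
    manifest: dict = {"seed": config.seed, "params": config.params,
                      "stages": {}, "timings_s": {}}
    produced: list[Path] = []

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                fn()
            except Exception as exc:
                raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
            manifest["timings_s"][name] = round(time.perf_counter() - t0, 3)
            log.info("stage %s: done", name)
        return deco

    inputs = config.inputs
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        scfg = SyntheticConfig(**sim_kwargs)
        bundle = simulate(scfg)
        inputs = _write_simulated_inputs(bundle, out / "inputs")
        manifest["simulate"] = {k: (list(v) if isinstance(v, tuple) else v)
                                for k, v in vars(scfg).items()}

    genes = io.read_gtf(inputs["genes"])
    tables: dict[str, list[SiteTable]] = {}
    for ct, paths in inputs["sites"].items():
        paths = paths if isinstance(paths, list) else [paths]
        tables[ct] = [io.read_site_table(p, cell_type=ct) for p in paths]

    results: dict = {}

    @stage("call")
    def _call():
        ref = config.reference_cell_type
        if ref not in tables:
            raise ValueError(f"reference cell type '{ref}' has no site tables")
        reps = tables[ref]
        if config.params["cutoff_mode"] == "pooled":
            cut = derive_cutoff(reps[0], reps[1:])
        else:
            cuts = [derive_cutoff(t) for t in reps]
            mean_cut = float(np.mean([c.cutoff for c in cuts]))
            cut = cuts[0].__class__(mean=float(np.mean([c.mean for c in cuts])),
                                    sem=float(np.mean([c.sem for c in cuts])),
                                    cutoff=mean_cut, n_sites=sum(c.n_sites for c in cuts),
                                    reference_cell_type=ref)
        results["cutoff"] = cut
        results["positive"] = {}
        for ct, reps_ct in tables.items():
            pooled = pd.concat([t.data for t in reps_ct]).groupby(
                ["chrom", "pos", "strand"], as_index=False)["count"].mean()
            merged = SiteTable(pooled, library_id=f"{ct}_mean", cell_type=ct)
            pos = call_sites(merged, cut.cutoff)
            results["positive"][ct] = pos
            results.setdefault("merged_tables", {})[ct] = merged
            p = out / f"positive_{ct}.bed"
            io.write_bed(pos.as_bed(), p, columns=("chrom", "start", "end", "name", "score", "strand"))
            produced.append(p)
        p = out / "cutoff.json"
        p.write_text(json.dumps(vars(cut), indent=1))
        produced.append(p)

    @stage("genebody")
    def _genebody():
        results["genebody"] = {}
        for ct, merged in results["merged_tables"].items():
            lev = gene_body_levels(genes, merged)
            results["genebody"][ct] = lev
            p = out / f"genebody_{ct}.tsv"
            lev.to_csv(p, sep="\t", index=False)
            produced.append(p)

    @stage("elements")
    def _elements():
        if "chrom_sizes" in inputs:
            sizes = io.read_chrom_sizes(inputs["chrom_sizes"])
        else:  # fall back to the observed extent of the site tables
            sizes = {}
            for t in results["merged_tables"].values():
                for chrom, sub in t.data.groupby("chrom"):
                    sizes[str(chrom)] = max(sizes.get(str(chrom), 0),
                                            int(sub["pos"].max()) + 10000)
        emap = build_element_map(genes, sizes)
        results["element_map"] = emap
        for ct, pos in results["positive"].items():
            if len(pos) == 0:
                continue
            prop = element_proportions(pos, emap)
            dens = relative_density(pos, emap)
            p = out / f"elements_{ct}.tsv"
            dens.assign(proportion=prop.to_numpy()).to_csv(p, sep="\t", index=False)
            produced.append(p)

    @stage("correlate")
    def _correlate():
        results["correlation"] = {}
        for ct, expr_path in inputs["expression"].items():
            if ct not in results["genebody"]:
                continue
            expr = io.read_expression(expr_path)
            lev = results["genebody"][ct].set_index("gene_id")["level"]
            joined = expr.set_index("gene_id").join(lev, how="inner").dropna()
            if len(joined) < 3:
                continue
            res = spearman_perm(joined["level"], np.log2(joined["fpkm"] + 1),
                                n_perm=config.params["n_perm"], seed=config.seed)
            tert = expression_tertiles(expr)
            prof = tss_profile(results["merged_tables"][ct], genes,
                               window=config.params["tss_window"],
                               bin_bp=config.params["tss_bin"])
            per_gene = prof.per_gene_enrichment(0, config.params["tss_window"])
            pg = pd.Series(per_gene, index=prof.gene_ids)
            groups = {lab: pg.reindex(tert.index[tert == lab]).dropna()
                      for lab in ("low", "intermediate", "high")}
            ks = (ks_two_sample(groups["high"], groups["low"])
                  if len(groups["high"]) and len(groups["low"]) else None)
            results["correlation"][ct] = {
                "rho": res.rho, "p": res.p,
                "tertile_means": {k: float(v.mean()) for k, v in groups.items() if len(v)},
                "ks_high_vs_low": vars(ks) if ks else None,
            }
        p = out / "correlation.json"
        p.write_text(json.dumps(results["correlation"], indent=1))
        produced.append(p)

    @stage("enhancers")
    def _enhancers():
        if "peaks" not in inputs or "tf" not in inputs:
            results["enhancers"] = None
            return
        k27 = io.read_bed(inputs["peaks"]["H3K27ac"])
        k4 = io.read_bed(inputs["peaks"]["H3K4me1"])
        tss = pd.DataFrame({"chrom": [g.chrom for g in genes],
                            "tss": [g.tss for g in genes]})
        classes = classify_enhancers(k27.sort_values(["chrom", "start"]),
                                     k4.sort_values(["chrom", "start"]), tss)
        ref_pos = results["positive"][config.reference_cell_type]
        split = split_by_5hmc(classes.active_dual, ref_pos)
        track = io.read_bedgraph(inputs["tf"])
        from .core import SignalTrack
        comp = compare_tf_occupancy(SignalTrack.from_dataframe(track), split,
                                    flank_bp=config.params["flank_bp"],
                                    n_body_bins=config.params["n_body_bins"],
                                    flank_bin_bp=config.params["flank_bin_bp"])
        results["enhancers"] = comp
        p = out / "enhancer_comparison.json"
        p.write_text(json.dumps({
            "n_positive": comp.n_positive, "n_negative": comp.n_negative,
            "ks": vars(comp.ks) if comp.ks else None,
            "significant": comp.significant, "status": comp.status,
        }, indent=1))
        produced.append(p)
        for name, df in (("positive", split.positive), ("negative", split.negative)):
            q = out / f"enhancers_5hmc_{name}.bed"
            io.write_bed(df, q)
            produced.append(q)

    @stage("cluster")
    def _cluster():
        mats = {ct: lev for ct, lev in results["genebody"].items()}
        matrix = GeneBodyMatrix.from_level_tables(mats)
        k1 = min(config.params["k_first"], len(matrix.values))
        first = cluster_genes(matrix, k=k1)
        high = select_high_cluster(matrix, first)
        sub = GeneBodyMatrix(matrix.values.loc[first.members(high)])
        k2 = min(config.params["k_second"], len(sub.values))
        second = cluster_genes(sub, k=k2)
        results["clusters"] = second
        expr_tables = {ct: io.read_expression(p) for ct, p in inputs["expression"].items()}
        summary = cluster_expression_summary(second, expr_tables,
                                             min_fpkm=config.params["min_fpkm"])
        p = out / "clusters.tsv"
        second.labels.rename_axis("gene_id").to_frame().to_csv(p, sep="\t")
        produced.append(p)
        q = out / "cluster_expression.tsv"
        summary.to_csv(q, sep="\t", index=False)
        produced.append(q)
        cts = list(results["genebody"])
        if len(cts) >= 2 and len(expr_tables) >= 2:
            prog, mat = cts[0], cts[1]
            try:
                delta, rho = delta_analysis(
                    expr_tables[prog], expr_tables[mat],
                    results["genebody"][prog], results["genebody"][mat],
                    lfc_threshold=config.params["lfc_threshold"],
                    n_perm=config.params["n_perm"], seed=config.seed)
                r = out / f"delta_{prog}_to_{mat}.tsv"
                delta.to_csv(r, sep="\t", index=False)
                produced.append(r)
                results["delta_rho"] = rho
            except ValueError as exc:
                log.warning("delta analysis skipped: %s", exc)

    for path in produced:
        manifest["stages"][str(path.relative_to(out))] = _sha256(path)
    mp = out / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.removeHandler(fh)
    fh.close()
    results["manifest"] = manifest
    return results
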