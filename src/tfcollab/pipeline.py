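"""End-to-end orchestration: expression prep -> CCG/SCCM -> Triple-Link ->
PC1 screen -> gene-set enrichment -> motif enrichment -> TGMI ranking.

Each stage reads and writes plain TSV/FASTA/JSON files under the output
directory, is keyed by a checksum manifest of its inputs (so re-runs with
unchanged inputs reuse cached outputs), and can be invoked on its own
through the CLI. ``run_pipeline`` strings them together from a single
config and emits a run manifest plus summary tables echoing the three
headline views: subnetwork membership, motif enrichment, and TF
interference ranking.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import ccg as ccg_mod
from . import enrichment as enr_mod
from . import motifs as motif_mod
from . import screen as screen_mod
from . import subnetworks as subnet_mod
from . import tgmi as tgmi_mod
from .expression import load_expression, filter_sparse_genes, log_transform, write_expression
from ._util import file_sha256, write_json

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    expression: str = ""
    groups: str = ""
    tf_list: str = ""
    annotations: str = ""           # GMT; optional
    promoters: str = ""             # FASTA; optional
    pwms: str = ""                  # MEME / CIS-BP; optional
    bp_genes: str = ""              # newline-separated gene ids; optional
    known_genes: str = ""           # optional curated list for summaries
    outdir: str = "tfcollab_out"
    max_zero_frac: float = 0.92
    k: int = 100
    corr_method: str = "pearson"
    min_shared: int = 25
    min_links: int = 3
    bins: int = 3
    n_perm: int = 1000
    alpha: float = 0.05
    motif_threshold: float = 0.85
    promoter_length: int = 2000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        stray = set(raw) - known
        if stray:
            raise ValueError(f"unknown config key {sorted(stray)[0]!r}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


class PipelineError(RuntimeError):
    pass


def _require(path: str, what: str) -> Path:
    if not path or not Path(path).exists():
        raise PipelineError(f"{what}: required input path missing: {path!r}")
    return Path(path)


def _read_gene_list(path) -> list:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def _stage_cached(outdir: Path, stage: str, inputs: dict, outputs: list) -> bool:
    """True when the stage's input checksums match its recorded manifest
    and every output file exists."""
    man = outdir / f"{stage}.manifest.json"
    if not man.exists():
        return False
    try:
        recorded = json.loads(man.read_text())
    except json.JSONDecodeError:
        return False
    return recorded == inputs and all((outdir / o).exists() for o in outputs)


def _record_stage(outdir: Path, stage: str, inputs: dict) -> None:
    write_json(outdir / f"{stage}.manifest.json", inputs)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns a dict of headline counts and paths.

    Any stage failure aborts with the stage name; partial outputs are
    retained next to a FAILED marker naming the stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"outdir": str(out)}
    stage = "preprocess"
    try:
        # ---- preprocess ------------------------------------------------
        expr_path = _require(config.expression, stage)
        groups_path = _require(config.groups, stage)
        tf_path = _require(config.tf_list, stage)
        params = {"max_zero_frac": config.max_zero_frac}
        inputs = {"expression": file_sha256(expr_path),
                  "groups": file_sha256(groups_path), **params}
        if not _stage_cached(out, stage, inputs, ["filtered.tsv", "filtered_groups.tsv"]):
            X = load_expression(expr_path, groups_path)
            n0 = X.n_genes
            X = filter_sparse_genes(X, config.max_zero_frac)
            write_expression(X, out / "filtered.tsv", out / "filtered_groups.tsv",
                             {"max_zero_frac": config.max_zero_frac,
                              "genes_in": n0, "genes_kept": X.n_genes})
            _record_stage(out, stage, inputs)
        X = load_expression(out / "filtered.tsv", out / "filtered_groups.tsv")
        Xlog = log_transform(X)
        tf_ids = [t for t in _read_gene_list(tf_path) if t in set(X.gene_ids)]
        report["genes_kept"] = X.n_genes
        report["n_tfs"] = len(tf_ids)
        logger.info("preprocess: %d genes kept, %d TFs usable", X.n_genes, len(tf_ids))

        # ---- sccm ------------------------------------------------------
        stage = "sccm"
        inputs = {"filtered": file_sha256(out / "filtered.tsv"),
                  "tfs": file_sha256(tf_path),
                  "k": config.k, "method": config.corr_method}
        if not _stage_cached(out, stage, inputs, ["rankings.tsv", "sccm.tsv"]):
            rankings = ccg_mod.rank_ccgs(Xlog, tf_ids, k=config.k,
                                         method=config.corr_method)
            S = ccg_mod.build_sccm(rankings, min_shared=config.min_shared)
            ccg_mod.rankings_to_tsv(rankings, out / "rankings.tsv")
            ccg_mod.sccm_to_tsv(S, out / "sccm.tsv")
            ccg_mod.edges_to_tsv(ccg_mod.threshold_edges(S), out / "edges.tsv")
            ccg_mod.sccm_to_graphml(S, out / "network.graphml")
            _record_stage(out, stage, inputs)
        rankings = ccg_mod.rankings_from_tsv(out / "rankings.tsv")
        S = ccg_mod.sccm_from_tsv(out / "sccm.tsv", k=config.k,
                                  min_shared=config.min_shared)
        edges = ccg_mod.threshold_edges(S)
        report["n_edges"] = len(edges)
        logger.info("sccm: %d TFs, %d edges at min_shared=%d",
                    len(S.tf_ids), len(edges), config.min_shared)

        # ---- decompose -------------------------------------------------
        stage = "decompose"
        inputs = {"sccm": file_sha256(out / "sccm.tsv"),
                  "min_shared": config.min_shared, "min_links": config.min_links}
        if not _stage_cached(out, stage, inputs, ["subnetworks.tsv", "merged_ccgs.tsv"]):
            subnets = subnet_mod.decompose(S, min_shared=config.min_shared,
                                           min_links=config.min_links)
            subnets = subnet_mod.assign_ccgs(subnets, rankings)
            subnet_mod.subnetworks_to_tsv(subnets, out / "subnetworks.tsv")
            subnet_mod.merged_ccgs_to_tsv(subnets, out / "merged_ccgs.tsv")
            for s in subnets:
                subnet_mod.subnetwork_to_graphml(s, out / f"subnetwork_{s.id}.graphml")
            _record_stage(out, stage, inputs)
        subnets = subnet_mod.subnetworks_from_tsv(out / "subnetworks.tsv", S)
        subnets = subnet_mod.assign_ccgs(subnets, rankings)
        known = _read_gene_list(config.known_genes) if config.known_genes else []
        subnet_mod.summary_table(subnets, known).to_csv(
            out / "subnetwork_summary.tsv", sep="\t", index=False)
        subnet_mod.classify_ccgs(subnets, set(tf_ids)).to_csv(
            out / "ccg_classes.tsv", sep="\t", index=False)
        report["n_subnetworks"] = len(subnets)
        logger.info("decompose: %d subnetworks", len(subnets))

        # ---- screen ----------------------------------------------------
        stage = "screen"
        screens = []
        for s in subnets:
            try:
                screens.append(screen_mod.subnetwork_pc1(Xlog, s))
            except ValueError as exc:
                logger.warning("screen: subnetwork %d skipped (%s)", s.id, exc)
        if screens:
            screen_mod.screen_report(screens, X.group_order).to_csv(
                out / "screen_report.tsv", sep="\t", index=False,
                float_format="%.6g")
            screen_mod.pc1_to_tsv(screens, X, out / "pc1_scores.tsv")
        report["n_screened"] = len(screens)

        # ---- gene-set enrichment --------------------------------------
        if config.annotations:
            stage = "enrich"
            ann = enr_mod.read_gmt(_require(config.annotations, stage))
            universe = set(X.gene_ids)
            enr_rows = []
            for s in subnets:
                query = set(s.merged_ccgs) & universe
                if not query:
                    continue
                results = enr_mod.enrich(query, ann, universe, alpha=config.alpha)
                enr_mod.results_to_tsv(results, out / f"enrichment_subnet{s.id}.tsv")
                enr_rows += [(s.id, r.term_id, r.adj_p, r.significant)
                             for r in results]
            report["n_enriched_terms"] = sum(1 for r in enr_rows if r[3])

        # ---- motif enrichment -----------------------------------------
        if config.pwms or config.promoters:
            stage = "motifs"
            promoters = motif_mod.read_promoters_fasta(_require(config.promoters, stage))
            pwms = motif_mod.load_pwms(_require(config.pwms, stage))
            background = motif_mod.estimate_background(promoters.values())
            all_genes = set(promoters)
            enrichments = []
            for s in subnets:
                fg = set(s.merged_ccgs) & all_genes
                if not fg:
                    continue
                for pwm in pwms:
                    hits = motif_mod.scan_promoters(promoters, pwm, background,
                                                    config.motif_threshold)
                    motif_mod.hits_to_tsv(hits, pwm.motif_id,
                                          out / f"hits_subnet{s.id}_{pwm.motif_id}.tsv",
                                          motif_length=pwm.length)
                    e = motif_mod.motif_enrichment_test(fg, all_genes, hits,
                                                        motif_id=pwm.motif_id)
                    e.motif_id = f"subnet{s.id}:{pwm.motif_id}"
                    enrichments.append(e)
            motif_mod.enrichment_to_tsv(enrichments, out / "motif_enrichment.tsv")
            report["n_motif_tests"] = len(enrichments)

        # ---- TGMI ------------------------------------------------------
        if config.bp_genes:
            stage = "tgmi"
            bp = [g for g in _read_gene_list(_require(config.bp_genes, stage))
                  if g in set(X.gene_ids)]
            rank_rows = []
            for s in subnets:
                members = [t for t in s.member_tfs if t not in set(bp)]
                if len(members) == 0 or len(bp) < 2:
                    continue
                records = tgmi_mod.score_triples(
                    Xlog, members, bp, n_perm=config.n_perm,
                    alpha=config.alpha, seed=config.seed, bins=config.bins)
                tgmi_mod.triples_to_tsv(records, out / f"triples_subnet{s.id}.tsv")
                ranking = tgmi_mod.rank_tfs(records)
                tgmi_mod.ranking_to_tsv(ranking, out / f"tgmi_ranking_subnet{s.id}.tsv")
                rank_rows += [(s.id, r.rank, r.tf_id, r.interference_frequency)
                              for r in ranking]
            pd.DataFrame(rank_rows, columns=["subnetwork", "rank", "tf",
                                             "interference_frequency"]).to_csv(
                out / "tgmi_ranking.tsv", sep="\t", index=False)
            report["n_interfering_tfs"] = sum(1 for r in rank_rows if r[3] >= 1)

        # ---- manifest --------------------------------------------------
        manifest = {
            "parameters": dataclasses.asdict(config),
            "inputs": {name: file_sha256(p) for name, p in
                       [("expression", config.expression), ("groups", config.groups),
                        ("tf_list", config.tf_list),
                        ("annotations", config.annotations),
                        ("promoters", config.promoters), ("pwms", config.pwms),
                        ("bp_genes", config.bp_genes)]
                       if p and Path(p).exists()},
            "report": {k: v for k, v in report.items() if k != "outdir"},
        }
        write_json(out / "manifest.json", manifest)
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    marker = out / "FAILED"
    if marker.exists():
        marker.unlink()
    return report


# -- demo fixture --------------------------------------------------------

def demo_fixture(outdir, seed: int = 1) -> dict:
    """Write a small, fully planted end-to-end fixture (<= 500 genes,
    78 samples): 2 collaborative modules, 4 regulator triples over 6 BP
    genes, promoters with a planted motif enriched in module-1 CCGs, a
    GMT with a planted enriched term, and the ground-truth JSON.

    Returns a dict of paths plus the truth structures.
    """
    import numpy as np

    from . import synth
    from .motifs import PWM, write_meme, write_promoters_fasta

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = None

    tf_ids, other_ids = synth.default_gene_ids(400, 30)
    mod1_tfs = tf_ids[:8]
    mod2_tfs = tf_ids[8:14]
    mod1_ccgs = other_ids[:60]
    mod2_ccgs = other_ids[60:110]
    bp = other_ids[110:116]                      # six BP genes
    # de-differentiation-peaked factor for module 1; a root/RAM-flavoured
    # factor for module 2, chosen orthogonal to f1 across the sample axis
    # so the two planted modules are statistically independent
    f1 = synth.group_factor_profile(synth.DEFAULT_GROUP_SIZES,
                                    [2, 2, 5, 5, 6, 3, 2, 2])
    f2 = synth.group_factor_profile(synth.DEFAULT_GROUP_SIZES,
                                    [2, 5, 3, 3, 3, 3, 2, 6])
    modules = [
        synth.PlantedModule(tf_ids=mod1_tfs, ccg_ids=mod1_ccgs,
                            factor_profile=f1, loading_sd=0.15),
        synth.PlantedModule(tf_ids=mod2_tfs, ccg_ids=mod2_ccgs,
                            factor_profile=f2, loading_sd=0.15),
    ]
    reg_a, reg_b = mod1_tfs[0], mod1_tfs[1]
    triples = [
        synth.PlantedTriple(reg_a, bp[0], bp[1], effect=0.9),
        synth.PlantedTriple(reg_a, bp[2], bp[3], effect=0.9),
        synth.PlantedTriple(reg_a, bp[0], bp[2], effect=0.9),
        synth.PlantedTriple(reg_b, bp[4], bp[5], effect=0.9),
    ]
    cfg = synth.SyntheticConfig(n_genes=400, n_tfs=30, modules=modules,
                                triples=triples, noise_sd=0.5,
                                zero_inflation=0.02, seed=seed)
    X, truth = synth.make_expression(cfg)
    write_expression(X, out / "expression.tsv", out / "groups.tsv",
                     {"synthetic": True, "seed": seed})

    # near-deterministic 8-mer planted preferentially in module-1 CCG promoters
    consensus = "TGACGTCA"
    mat = np.full((4, 8), 0.04)
    for j, b in enumerate(consensus):
        mat["ACGT".index(b), j] = 0.88
    pwm = PWM("SYNM1", mat / mat.sum(axis=0, keepdims=True))
    write_meme([pwm], out / "pwms.meme")
    promoters, motif_truth = synth.make_promoters(
        n_genes=cfg.n_genes, length=2000, motif=pwm,
        planted_fraction_fg=0.8, planted_fraction_bg=0.1,
        fg_ids=set(mod1_ccgs), seed=seed, gene_ids=tf_ids + other_ids)
    write_promoters_fasta(promoters, out / "promoters.fasta")
    truth.motif_placements = motif_truth.motif_placements

    ann = synth.make_annotations(terms=20, genes_per_term=40,
                                 enriched_term_overlap=30,
                                 query_set=set(mod1_ccgs),
                                 universe=set(tf_ids + other_ids), seed=seed)
    enr_mod.write_gmt(ann, out / "annotations.gmt")

    (out / "tf_list.txt").write_text("\n".join(tf_ids) + "\n")
    (out / "bp_genes.txt").write_text("\n".join(bp) + "\n")
    (out / "known_genes.txt").write_text("\n".join(mod1_tfs[:3]) + "\n")
    write_json(out / "truth.json", truth.to_jsonable())

    config = PipelineConfig(
        expression=str(out / "expression.tsv"), groups=str(out / "groups.tsv"),
        tf_list=str(out / "tf_list.txt"), annotations=str(out / "annotations.gmt"),
        promoters=str(out / "promoters.fasta"), pwms=str(out / "pwms.meme"),
        bp_genes=str(out / "bp_genes.txt"), known_genes=str(out / "known_genes.txt"),
        outdir=str(out / "results"), k=50, min_shared=25, seed=seed)
    config.to_yaml(out / "config.yaml")
    return {"dir": out, "config": config, "truth": truth,
            "modules": modules, "triples": triples, "bp_genes": bp,
            "planted_regulators": [reg_a, reg_b]}
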