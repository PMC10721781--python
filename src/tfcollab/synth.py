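"""Seeded synthetic data with known planted structure.

The generator emulates the shape of a curated plant de-/re-differentiation
RNA-seq compendium: 78 samples across 8 ordered tissue groups (leaves,
roots, whole explants, hypocotyls, calli, shoots, SAM, RAM with sizes
4, 4, 13, 11, 7, 11, 22, 6), genes on a non-negative FPKM-like scale, and
optional per-entry zero inflation mimicking dropout in lowly expressed
genes. Three kinds of structure can be planted, each with recorded ground
truth so every downstream stage is testable:

* collaborative TF modules — log-expression of every module gene is
  loading * factor + Gaussian noise for a shared per-sample latent factor,
  so module members share top-k co-expression lists;
* regulator triples — two BP genes respond linearly (on log scale) to a
  TF's expression, creating genuine TF->pair information flow for TGMI;
* promoter motif instances — PWM draws placed at recorded positions and
  strands in otherwise i.i.d. uniform-background promoters.

One root seed drives per-artifact derived streams, so regenerating one
artifact never perturbs another.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .expression import ExpressionMatrix
from .motifs import PWM, _BASES
from .enrichment import GeneSetAnnotation
from ._util import derive_rng

DEFAULT_GROUP_ORDER = ["leaves", "roots", "whole_explants", "hypocotyls",
                       "calli", "shoots", "SAM", "RAM"]
DEFAULT_GROUP_SIZES = [4, 4, 13, 11, 7, 11, 22, 6]   # sums to 78


@dataclass
class PlantedModule:
    """A collaborative TF module: TFs plus CCGs sharing one latent factor."""

    tf_ids: list
    ccg_ids: list
    factor_profile: np.ndarray      # per-sample latent activity (>= 0 advised)
    loading_sd: float = 0.0

    def __post_init__(self):
        self.factor_profile = np.asarray(self.factor_profile, dtype=float)
        if len(self.tf_ids) < 2:
            raise ValueError("a planted module needs at least 2 TFs")
        if set(self.tf_ids) & set(self.ccg_ids):
            raise ValueError("module tf_ids and ccg_ids must be disjoint")
        if self.loading_sd < 0:
            raise ValueError("loading_sd must be non-negative")


@dataclass
class PlantedTriple:
    """Ground truth for TGMI: two BP genes driven by one TF."""

    tf_id: str
    bp1_id: str
    bp2_id: str
    effect: float = 1.0

    def __post_init__(self):
        if len({self.tf_id, self.bp1_id, self.bp2_id}) != 3:
            raise ValueError("triple gene ids must be distinct")


@dataclass
class SyntheticConfig:
    n_genes: int = 400
    n_tfs: int = 30
    group_sizes: list = field(default_factory=lambda: list(DEFAULT_GROUP_SIZES))
    group_order: list = field(default_factory=lambda: list(DEFAULT_GROUP_ORDER))
    modules: list = field(default_factory=list)
    triples: list = field(default_factory=list)
    noise_sd: float = 0.5           # log2-scale Gaussian noise
    zero_inflation: float = 0.0     # per-entry dropout probability
    seed: int = 0

    def __post_init__(self):
        if len(self.group_sizes) != len(self.group_order):
            raise ValueError("group_sizes and group_order length mismatch")
        if sum(self.group_sizes) <= 0:
            raise ValueError("group_sizes must sum to a positive sample count")
        if not 0 <= self.zero_inflation <= 1:
            raise ValueError("zero_inflation must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        seen: set = set()
        for m in self.modules:
            overlap = seen & set(m.tf_ids)
            if overlap:
                raise ValueError(
                    f"module TF sets overlap at {sorted(overlap)[0]!r}")
            seen |= set(m.tf_ids)

    @property
    def n_samples(self) -> int:
        return sum(self.group_sizes)


@dataclass
class SyntheticTruth:
    """Ground truth accompanying generated artifacts."""

    module_members: dict = field(default_factory=dict)   # module idx -> {tfs, ccgs}
    triples: list = field(default_factory=list)          # (tf, bp1, bp2, effect)
    motif_placements: dict = field(default_factory=dict) # gene -> [(start, strand)]

    def to_jsonable(self) -> dict:
        return {
            "module_members": {str(k): {"tfs": sorted(v["tfs"]),
                                        "ccgs": sorted(v["ccgs"])}
                               for k, v in self.module_members.items()},
            "triples": [list(t) for t in self.triples],
            "motif_placements": {g: [[int(s), st] for s, st in pl]
                                 for g, pl in sorted(self.motif_placements.items())},
        }


def default_gene_ids(n_genes: int, n_tfs: int) -> tuple[list, list]:
    """TF ids TF001.. then background/target gene ids G0001.. ."""
    tfs = [f"TF{i + 1:03d}" for i in range(n_tfs)]
    others = [f"G{i + 1:04d}" for i in range(n_genes - n_tfs)]
    return tfs, others


def group_factor_profile(group_sizes, group_means, jitter: float = 0.0,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Latent factor with per-tissue-group mean shifts (plus optional
    within-group jitter) — gives PC1 screening a group-structured signal."""
    if len(group_sizes) != len(group_means):
        raise ValueError("group_sizes and group_means length mismatch")
    prof = np.concatenate([np.full(sz, mu, dtype=float)
                           for sz, mu in zip(group_sizes, group_means)])
    if jitter > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        prof = prof + rng.normal(0, jitter, prof.size)
    return prof


def make_expression(config: SyntheticConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate the FPKM-like matrix with planted modules and triples.

    Log-expression of module genes is loading * factor + N(0, noise_sd);
    BP genes of planted triples add effect * (TF log-profile, centered) to
    an independent baseline; background genes are independent noise around
    a per-gene mean. Values map to the positive scale as
    max(2^logexpr - 1, 0); zero inflation then zeroes entries i.i.d.
    """
    cfg = config
    n = cfg.n_samples
    tf_ids, other_ids = default_gene_ids(cfg.n_genes, cfg.n_tfs)
    gene_ids = tf_ids + other_ids
    gene_set = set(gene_ids)
    for m in cfg.modules:
        for g in list(m.tf_ids) + list(m.ccg_ids):
            if g not in gene_set:
                raise ValueError(f"module gene {g!r} not among generated gene ids")
    for t in cfg.triples:
        for g in (t.tf_id, t.bp1_id, t.bp2_id):
            if g not in gene_set:
                raise ValueError(f"triple gene {g!r} not among generated gene ids")

    pos = {g: i for i, g in enumerate(gene_ids)}
    rng_bg = derive_rng(cfg.seed, "expr", "background")
    rng_mod = derive_rng(cfg.seed, "expr", "modules")
    rng_tri = derive_rng(cfg.seed, "expr", "triples")
    rng_zero = derive_rng(cfg.seed, "expr", "zeros")

    # background baseline for every gene
    mu = rng_bg.uniform(1.0, 6.0, cfg.n_genes)
    L = mu[:, None] + rng_bg.normal(0.0, cfg.noise_sd, (cfg.n_genes, n))

    truth = SyntheticTruth()
    for mi, m in enumerate(cfg.modules):
        if m.factor_profile.size != n:
            raise ValueError(f"module {mi}: factor profile length != {n}")
        members = list(m.tf_ids) + list(m.ccg_ids)
        loadings = np.maximum(
            rng_mod.normal(1.0, m.loading_sd, len(members)), 0.05)
        noise = rng_mod.normal(0.0, cfg.noise_sd, (len(members), n))
        for (g, load, eps) in zip(members, loadings, noise):
            L[pos[g]] = load * m.factor_profile + eps
        truth.module_members[mi] = {"tfs": list(m.tf_ids), "ccgs": list(m.ccg_ids)}

    # BP genes respond to their driver TF (first triple naming them wins)
    driven: set = set()
    for t in cfg.triples:
        tf_log = L[pos[t.tf_id]]
        centered = tf_log - tf_log.mean()
        for bp in (t.bp1_id, t.bp2_id):
            if bp in driven:
                continue
            base = rng_tri.uniform(2.0, 5.0)
            L[pos[bp]] = base + t.effect * centered + rng_tri.normal(
                0.0, cfg.noise_sd, n)
            driven.add(bp)
        truth.triples.append((t.tf_id, t.bp1_id, t.bp2_id, t.effect))

    expr = np.maximum(np.exp2(L) - 1.0, 0.0)
    if cfg.zero_inflation > 0:
        mask = rng_zero.random(expr.shape) < cfg.zero_inflation
        expr = np.where(mask, 0.0, expr)

    sample_ids, group_of = [], {}
    for grp, sz in zip(cfg.group_order, cfg.group_sizes):
        for i in range(sz):
            sid = f"{grp}_{i + 1}"
            sample_ids.append(sid)
            group_of[sid] = grp

    import pandas as pd
    values = pd.DataFrame(expr, index=gene_ids, columns=sample_ids)
    X = ExpressionMatrix(values, group_of, list(cfg.group_order))
    return X, truth


def make_promoters(n_genes: int, length: int, motif: PWM,
                   planted_fraction_fg: float, planted_fraction_bg: float,
                   fg_ids, seed: int, gene_ids=None) -> tuple[dict, SyntheticTruth]:
    """Uniform-background promoters with PWM instances planted in a
    foreground gene subset (and, at a lower rate, in the background).

    Returns (gene_id -> sequence dict, truth with placement positions and
    strands). Default promoter length is 2000 bp.
    """
    if length < motif.length:
        raise ValueError(f"promoter length {length} < motif length {motif.length}")
    for frac in (planted_fraction_fg, planted_fraction_bg):
        if not 0 <= frac <= 1:
            raise ValueError("planted fractions must lie in [0, 1]")
    if gene_ids is None:
        gene_ids = [f"G{i + 1:04d}" for i in range(n_genes)]
    if len(gene_ids) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    fg = set(fg_ids)
    stray = fg - set(gene_ids)
    if stray:
        raise ValueError(f"foreground gene {sorted(stray)[0]!r} not among gene ids")

    rng = derive_rng(seed, "promoters")
    truth = SyntheticTruth()
    promoters: dict = {}
    base_arr = np.array(list(_BASES))
    for g in gene_ids:
        seq = rng.choice(base_arr, size=length)
        frac = planted_fraction_fg if g in fg else planted_fraction_bg
        if rng.random() < frac:
            start = int(rng.integers(0, length - motif.length + 1))
            inst_idx = np.array([rng.choice(4, p=motif.matrix[:, j])
                                 for j in range(motif.length)])
            inst = base_arr[inst_idx]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                comp = np.array([3, 2, 1, 0])
                inst = base_arr[comp[inst_idx][::-1]]
            seq[start: start + motif.length] = inst
            truth.motif_placements.setdefault(g, []).append((start, strand))
        promoters[g] = "".join(seq)
    return promoters, truth


def make_annotations(terms: int, genes_per_term: int, enriched_term_overlap: int,
                     query_set, universe, seed: int) -> GeneSetAnnotation:
    """GO-style annotation with one designed enriched term.

    The first term (TERM0001) is constructed to overlap ``query_set`` by
    exactly ``enriched_term_overlap`` genes; the remaining terms are drawn
    uniformly from the universe.
    """
    if terms < 1 or genes_per_term < 1:
        raise ValueError("terms and genes_per_term must be positive")
    query = sorted(set(query_set))
    universe = sorted(set(universe))
    if not set(query) <= set(universe):
        raise ValueError("query_set must be a subset of the universe")
    if enriched_term_overlap > min(genes_per_term, len(query)):
        raise ValueError(
            f"overlap {enriched_term_overlap} exceeds term size or query size")
    outside = sorted(set(universe) - set(query))
    if genes_per_term - enriched_term_overlap > len(outside):
        raise ValueError("universe too small for the requested term composition")

    rng = derive_rng(seed, "annotations")
    sets, names = {}, {}
    inside = list(rng.choice(query, size=enriched_term_overlap, replace=False))
    rest = list(rng.choice(outside, size=genes_per_term - enriched_term_overlap,
                           replace=False))
    sets["TERM0001"] = frozenset(inside + rest)
    names["TERM0001"] = "planted enriched term"
    for i in range(1, terms):
        term = f"TERM{i + 1:04d}"
        sets[term] = frozenset(rng.choice(universe, size=min(genes_per_term,
                                                             len(universe)),
                                          replace=False))
        names[term] = f"random term {i + 1}"
    return GeneSetAnnotation(sets=sets, names=names)
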