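"""PWM promoter scanning and TFBS enrichment.

Proximal promoters (2000 bp by default) are scanned on both strands with
position probability matrices. Each window is scored by its log-odds sum
sum_j log2(p(base_j, j) / bg(base_j)) and normalised to [0, 1] against the
PWM's analytic worst/best scores under the given background, so a hit at
the default threshold 0.85 means "within 15% of the best attainable
score" — the MotifLocator convention. Enrichment of motif presence in a
foreground gene set (e.g. a subnetwork's CCGs) against the genome-wide
promoter set uses the upper-tail hypergeometric test on genes-with-hit,
with raw occurrence totals reported alongside.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import hypergeom_tail

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PWM:
    """Position probability matrix, rows A, C, G, T."""

    motif_id: str
    matrix: np.ndarray            # 4 x L, columns sum to 1
    source_tf: str | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4 or self.matrix.shape[1] < 1:
            raise ValueError(f"motif {self.motif_id!r}: matrix must be 4 x L with L >= 1")
        if (self.matrix < 0).any():
            raise ValueError(f"motif {self.motif_id!r}: negative probabilities")
        sums = self.matrix.sum(axis=0)
        bad = np.where(np.abs(sums - 1.0) > 1e-6)[0]
        if bad.size:
            raise ValueError(
                f"motif {self.motif_id!r}: column {bad[0]} sums to {sums[bad[0]]:.6f}, not 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=0))

    def floored(self, pseudo: float = 1e-3) -> "PWM":
        """Floor zero cells at ``pseudo`` and renormalise each column."""
        m = np.maximum(self.matrix, pseudo)
        m = m / m.sum(axis=0, keepdims=True)
        return PWM(self.motif_id, m, self.source_tf)

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_id, self.matrix[::-1, ::-1].copy(), self.source_tf)


@dataclass
class MotifHit:
    gene_id: str
    start: int                    # 0-based offset on the forward promoter
    strand: str                   # '+' or '-'
    raw_score: float              # log-odds, bits
    norm_score: float             # (score - min) / (max - min), in [0, 1]


@dataclass
class MotifEnrichment:
    motif_id: str
    occurrences_in_ccgs: int      # total hits over foreground promoters
    genes_with_hit: int           # foreground genes with >= 1 hit
    pct_ccgs_with_motif: float
    p_value: float
    N: int = 0
    K: int = 0
    n: int = 0


# -- PWM readers ---------------------------------------------------------

def load_pwms(path) -> list[PWM]:
    """Read PWMs from MEME minimal format or CIS-BP text matrices.

    The dialect is sniffed from the header. Zero-probability cells are
    floored at 1e-3 and columns renormalised on load.
    """
    path = Path(path)
    head = path.read_text().lstrip()
    if head.startswith("MEME version"):
        pwms = _read_meme(path)
    elif head.startswith("Pos"):
        pwms = [_read_cisbp(path)]
    else:
        raise ValueError(f"unrecognised PWM file format: {path}")
    return [p.floored() for p in pwms]


def _read_meme(path) -> list[PWM]:
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        try:
            records = bio_motifs.parse(fh, "minimal")
            parsed = list(records)
        except Exception as exc:
            raise ValueError(f"malformed MEME file {path}: {exc}") from exc
    out = []
    for m in parsed:
        mat = np.array([[m.pwm[b][j] for j in range(m.length)] for b in _BASES])
        # Bio.motifs reconstitutes probabilities from rounded counts; renormalise
        mat = mat / mat.sum(axis=0, keepdims=True)
        out.append(PWM(motif_id=m.name or "motif", matrix=mat))
    if not out:
        raise ValueError(f"no motifs found in {path}")
    return out


def _read_cisbp(path) -> PWM:
    df = pd.read_csv(path, sep="\t")
    expected = ["Pos", "A", "C", "G", "T"]
    if list(df.columns[:5]) != expected:
        raise ValueError(
            f"CIS-BP matrix {path}: expected columns {expected}, got {list(df.columns[:5])}")
    mat = df[["A", "C", "G", "T"]].to_numpy(dtype=float).T
    return PWM(motif_id=Path(path).stem, matrix=mat)


def write_meme(pwms: list[PWM], path, background=None) -> None:
    bg = background or {b: 0.25 for b in _BASES}
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {bg[b]:.5f}" for b in _BASES) + "\n\n")
        for p in pwms:
            fh.write(f"MOTIF {p.motif_id}\n")
            fh.write(f"letter-probability matrix: alphabet= ACGT w= {p.length} "
                     f"nsites= 20 E= 0\n")
            for j in range(p.length):
                fh.write(" ".join(f"{p.matrix[i, j]:.6f}" for i in range(4)) + "\n")
            fh.write("\n")


# -- scanning ------------------------------------------------------------

def estimate_background(seqs) -> dict:
    """0-order base frequencies over a promoter collection (N ignored)."""
    counts = np.zeros(4)
    for s in seqs:
        su = s.upper()
        for i, b in enumerate(_BASES):
            counts[i] += su.count(b)
    if counts.sum() == 0:
        return {b: 0.25 for b in _BASES}
    freqs = counts / counts.sum()
    freqs = np.maximum(freqs, 1e-6)
    freqs = freqs / freqs.sum()
    return dict(zip(_BASES, freqs))


def _score_matrix(pwm: PWM, background: dict) -> np.ndarray:
    bg = np.array([background[b] for b in _BASES])[:, None]
    return np.log2(pwm.matrix / bg)


def scan_promoter(seq: str, pwm: PWM, background: dict | None = None,
                  threshold: float = 0.85, gene_id: str = "") -> list[MotifHit]:
    """Scan one promoter on both strands; return hits with normalised
    log-odds score >= threshold. Windows containing N are skipped; a
    promoter shorter than the motif yields an empty list.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    bg = background or {b: 0.25 for b in _BASES}
    L = pwm.length
    su = seq.upper()
    n = len(su)
    if n < L:
        return []
    if any(c not in "ACGTN" for c in su):
        bad = next(c for c in su if c not in "ACGTN")
        raise ValueError(f"invalid base {bad!r} in promoter sequence")

    S_fwd = _score_matrix(pwm, bg)
    S_rev = _score_matrix(pwm.reverse_complement(), bg)
    smin = S_fwd.min(axis=0).sum()
    smax = S_fwd.max(axis=0).sum()
    span = smax - smin
    # encode: A0 C1 G2 T3, N -> 4
    code = np.full(n, 4, dtype=np.int8)
    for i, b in enumerate(_BASES):
        code[np.frombuffer(su.encode(), dtype=np.uint8) == ord(b)] = i
    windows = np.lib.stride_tricks.sliding_window_view(code, L)
    valid = ~(windows == 4).any(axis=1)
    cols = np.arange(L)

    hits: list[MotifHit] = []
    for strand, S in (("+", S_fwd), ("-", S_rev)):
        Spad = np.vstack([S, np.zeros((1, L))])       # row 4 absorbs N (masked anyway)
        raw = Spad[windows, cols].sum(axis=1)
        if span > 0:
            norm = (raw - smin) / span
        else:
            norm = np.ones_like(raw)
        sel = valid & (norm >= threshold)
        for start in np.where(sel)[0]:
            hits.append(MotifHit(gene_id=gene_id, start=int(start), strand=strand,
                                 raw_score=float(raw[start]),
                                 norm_score=float(np.clip(norm[start], 0.0, 1.0))))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_promoters(promoters: dict, pwm: PWM, background: dict | None = None,
                   threshold: float = 0.85) -> dict:
    """Scan a gene_id -> sequence mapping; returns gene_id -> hit list
    (genes without hits map to empty lists)."""
    if background is None:
        background = estimate_background(promoters.values())
    return {g: scan_promoter(s, pwm, background, threshold, gene_id=g)
            for g, s in promoters.items()}


# -- enrichment ----------------------------------------------------------

def motif_enrichment_test(fg_genes, all_genes, hits: dict,
                          motif_id: str = "") -> MotifEnrichment:
    """Hypergeometric enrichment of motif presence in ``fg_genes`` against
    ``all_genes``: N = |all|, K = genes with >= 1 hit, n = |fg|,
    k = fg genes with >= 1 hit."""
    fg = set(fg_genes)
    allg = set(all_genes)
    if not fg:
        raise ValueError("empty foreground gene set")
    if not fg <= allg:
        stray = sorted(fg - allg)[0]
        raise ValueError(f"foreground gene {stray!r} not in the full gene set")
    with_hit = {g for g, h in hits.items() if h and g in allg}
    N, K, n = len(allg), len(with_hit), len(fg)
    k = len(fg & with_hit)
    occ = sum(len(hits.get(g, [])) for g in fg)
    return MotifEnrichment(
        motif_id=motif_id, occurrences_in_ccgs=occ, genes_with_hit=k,
        pct_ccgs_with_motif=k / n, p_value=hypergeom_tail(k, N, K, n),
        N=N, K=K, n=n)


# -- I/O -----------------------------------------------------------------

def read_promoters_fasta(path) -> dict:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_promoters_fasta(promoters: dict, path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    recs = [SeqRecord(Seq(s), id=g, description="") for g, s in promoters.items()]
    SeqIO.write(recs, str(path), "fasta")


def hits_to_tsv(hits: dict, motif_id: str, path, motif_length: int = 0) -> None:
    """BED-like table: gene-relative 0-based half-open coordinates."""
    rows = [{"gene": g, "start": h.start, "end": h.start + motif_length, "strand": h.strand,
             "motif": motif_id, "raw_score": h.raw_score, "norm_score": h.norm_score}
            for g, hl in sorted(hits.items()) for h in hl]
    df = pd.DataFrame(rows, columns=["gene", "start", "end", "strand",
                                     "motif", "raw_score", "norm_score"])
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def enrichment_to_tsv(enrichments: list[MotifEnrichment], path) -> None:
    rows = [{"motif": e.motif_id, "occurrences": e.occurrences_in_ccgs,
             "genes_with_hit": e.genes_with_hit,
             "pct_with_motif": e.pct_ccgs_with_motif, "p_value": e.p_value,
             "N": e.N, "K": e.K, "n": e.n} for e in enrichments]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def extract_promoters(genome: dict, features: list, length: int = 2000) -> dict:
    """Optional helper: pull strand-aware upstream promoters from genome
    sequences given (gene_id, chrom, tss_1based, strand) tuples. The
    promoter is the ``length`` bases upstream of the transcript start
    (clipped at the chromosome edge), returned 5'->3' on the gene strand.
    """
    out = {}
    for gene_id, chrom, tss, strand in features:
        seq = genome[chrom].upper()
        if strand == "+":
            start = max(0, tss - 1 - length)
            prom = seq[start: tss - 1]
        elif strand == "-":
            prom = seq[tss: tss + length].translate(_COMPLEMENT)[::-1]
        else:
            raise ValueError(f"gene {gene_id!r}: bad strand {strand!r}")
        out[gene_id] = prom
    return out
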