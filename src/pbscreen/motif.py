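"""Promoter extraction, motif scanning and motif-bearing-gene enrichment.

Motifs are either IUPAC consensus strings (matched exactly, both strands)
or JASPAR position frequency matrices converted to log-odds against the
promoter set's empirical mononucleotide background, thresholded to bound
the per-position false-positive rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneAnnotation, read_jaspar_pfm, revcomp

#: Canonical metal-responsive-element core consensus.  Bundled for test
#: fixtures only; real analyses should supply a JASPAR PFM.
MRE_CORE_CONSENSUS = "TGCRCNC"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_INDEX[ord(_b)] = _i


def iupac_revcomp(consensus: str) -> str:
    return consensus.translate(_IUPAC_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Promoter:
    gene_id: str
    seq: str  # strand-oriented, 5' -> 3'
    chrom: str
    start: int  # genomic, 0-based half-open
    end: int
    strand: str
    truncated: bool


@dataclass
class MotifModel:
    """IUPAC consensus or PFM-backed motif."""

    identifier: str
    consensus: str | None = None
    pfm: np.ndarray | None = None  # 4 x L, rows A,C,G,T
    fpr: float = 1e-4

    def __post_init__(self) -> None:
        if (self.consensus is None) == (self.pfm is None):
            raise ValueError("provide exactly one of consensus or pfm")
        if self.consensus is not None:
            bad = set(self.consensus.upper()) - set(IUPAC)
            if bad:
                raise ValueError(f"invalid IUPAC codes: {sorted(bad)}")
            self.consensus = self.consensus.upper()
        else:
            self.pfm = np.asarray(self.pfm, dtype=float)
            if self.pfm.shape[0] != 4 or self.pfm.shape[1] < 1:
                raise ValueError("pfm must be 4 x L")
            totals = self.pfm.sum(axis=0)
            if not np.allclose(totals, totals[0], rtol=0.05, atol=1.5):
                raise ValueError("pfm columns must sum to equal totals")

    @property
    def mode(self) -> str:
        return "consensus" if self.consensus is not None else "pwm"

    def __len__(self) -> int:
        return len(self.consensus) if self.consensus is not None else self.pfm.shape[1]

    @classmethod
    def from_consensus(cls, consensus: str, identifier: str = "consensus") -> "MotifModel":
        return cls(identifier=identifier, consensus=consensus)

    @classmethod
    def from_jaspar(cls, path: str | Path, fpr: float = 1e-4) -> "MotifModel":
        m = read_jaspar_pfm(path)
        pfm = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        name = getattr(m, "matrix_id", None) or m.name or Path(path).stem
        return cls(identifier=str(name), pfm=pfm, fpr=fpr)

    # -- log-odds machinery (PWM mode) ------------------------------------
    def log_odds(self, background: dict[str, float], pseudocount: float = 0.8) -> np.ndarray:
        """4 x L log2-odds matrix with background-proportional pseudocounts."""
        bg = np.array([background[b] for b in "ACGT"], dtype=float)
        bg = bg / bg.sum()
        counts = self.pfm + pseudocount * bg[:, None]
        probs = counts / counts.sum(axis=0, keepdims=True)
        return np.log2(probs / bg[:, None])

    def score_threshold(self, background: dict[str, float]) -> float:
        """Smallest score whose per-position tail probability under the
        background model is <= ``fpr`` (exact DP over the discretised score
        distribution)."""
        lo = self.log_odds(background)
        bg = np.array([background[b] for b in "ACGT"], dtype=float)
        bg = bg / bg.sum()
        precision = 1e-3
        q = np.round(lo / precision).astype(np.int64)
        offset = -q.min(axis=0).sum()
        width = (q.max(axis=0) - q.min(axis=0)).sum() + 1
        dist = np.zeros(width)
        dist[0] = 1.0
        shift = 0
        for j in range(q.shape[1]):
            col = np.zeros(q[:, j].max() - q[:, j].min() + 1)
            for b in range(4):
                col[q[b, j] - q[:, j].min()] += bg[b]
            dist = np.convolve(dist, col)[:width]
            shift += q[:, j].min()
        tail = np.cumsum(dist[::-1])[::-1]
        idx = np.searchsorted(-tail, -self.fpr, side="left")
        # score value at idx: (idx + shift) * precision
        return (idx + shift) * precision


def extract_promoters(
    genes: list[GeneAnnotation],
    genome: dict[str, str],
    window: tuple[int, int] = (1000, 100),
) -> list[Promoter]:
    """Strand-oriented promoter windows of (upstream, downstream) bp around
    each TSS, truncated (and flagged) at chromosome ends."""
    upstream, downstream = window
    promoters = []
    for g in genes:
        if g.chrom not in genome:
            raise ValueError(f"gene {g.gene_id}: chromosome {g.chrom} not in genome")
        chrom_len = len(genome[g.chrom])
        if not 0 <= g.tss < chrom_len:
            raise ValueError(f"gene {g.gene_id}: TSS {g.tss} outside {g.chrom}")
        if g.strand == "+":
            lo, hi = g.tss - upstream, g.tss + downstream
        else:
            lo, hi = g.tss - downstream + 1, g.tss + upstream + 1
        clo, chi = max(lo, 0), min(hi, chrom_len)
        seq = genome[g.chrom][clo:chi]
        if g.strand == "-":
            seq = revcomp(seq)
        promoters.append(
            Promoter(
                gene_id=g.gene_id,
                seq=seq,
                chrom=g.chrom,
                start=clo,
                end=chi,
                strand=g.strand,
                truncated=(clo != lo or chi != hi),
            )
        )
    return promoters


def _consensus_match_offsets(seq: str, consensus: str) -> list[int]:
    L = len(consensus)
    sets = [IUPAC[c] for c in consensus]
    return [
        o
        for o in range(len(seq) - L + 1)
        if all(seq[o + j] in sets[j] for j in range(L))
    ]


def _pwm_scores(seq: str, lo: np.ndarray) -> np.ndarray:
    """Score every offset; windows containing non-ACGT characters get -inf."""
    L = lo.shape[1]
    idx = _BASE_INDEX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(seq) - L + 1
    if n <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    valid = (windows >= 0).all(axis=1)
    scores = np.full(n, -np.inf)
    if valid.any():
        w = windows[valid]
        scores[valid] = lo[w, np.arange(L)[None, :]].sum(axis=1)
    return scores


def promoter_background(promoters: list[Promoter]) -> dict[str, float]:
    counts = {b: 1.0 for b in "ACGT"}  # +1 guards degenerate sets
    for p in promoters:
        for b in "ACGT":
            counts[b] += p.seq.count(b)
    total = sum(counts.values())
    return {b: counts[b] / total for b in "ACGT"}


def scan_motif(
    promoters: list[Promoter],
    motif: MotifModel,
    background: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Scan every promoter on both strands.

    Returns (hit table with columns gene_id, offset, strand, score;
    boolean per-gene "bears the motif" indicator).  A '-' strand hit at
    offset ``o`` means the reverse complement of ``seq[o:o+L]`` matches.
    """
    L = len(motif)
    for p in promoters:
        if L > len(p.seq):
            raise ValueError(f"motif longer than promoter window for {p.gene_id}")

    rows = []
    if motif.mode == "consensus":
        rc = iupac_revcomp(motif.consensus)
        for p in promoters:
            for o in _consensus_match_offsets(p.seq, motif.consensus):
                rows.append((p.gene_id, o, "+", float(L)))
            for o in _consensus_match_offsets(p.seq, rc):
                rows.append((p.gene_id, o, "-", float(L)))
    else:
        bg = background or promoter_background(promoters)
        lo = motif.log_odds(bg)
        lo_rc = lo[::-1, ::-1]  # reverse complement of the log-odds matrix
        threshold = motif.score_threshold(bg)
        for p in promoters:
            fwd = _pwm_scores(p.seq, lo)
            rev = _pwm_scores(p.seq, lo_rc)
            for o in np.nonzero(fwd >= threshold)[0]:
                rows.append((p.gene_id, int(o), "+", float(fwd[o])))
            for o in np.nonzero(rev >= threshold)[0]:
                rows.append((p.gene_id, int(o), "-", float(rev[o])))

    hits = pd.DataFrame(rows, columns=["gene_id", "offset", "strand", "score"])
    gene_ids = [p.gene_id for p in promoters]
    bears = pd.Series(False, index=pd.Index(gene_ids, name="gene_id"), name="bears_motif")
    if not hits.empty:
        bears[hits["gene_id"].unique()] = True
    return hits, bears


def mre_enrichment(
    hit_genes: set[str],
    regulated: set[str],
    universe: set[str],
) -> dict[str, float]:
    """One-sided Fisher exact test for over-representation of motif-bearing
    genes in the regulated set; also reports the regulated-set hit fraction."""
    if not regulated <= universe:
        raise ValueError("regulated set must be a subset of the universe")
    hit_genes = hit_genes & universe
    a = len(regulated & hit_genes)
    b = len(regulated) - a
    c = len(hit_genes) - a
    d = len(universe) - len(regulated) - c
    if len(regulated) == 0 or len(regulated) == len(universe):
        import warnings

        warnings.warn("degenerate 2x2 margins; p set to 1", stacklevel=2)
        p = 1.0
    else:
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    fraction = 100.0 * a / len(regulated) if regulated else float("nan")
    return {
        "n_regulated": len(regulated),
        "n_hit_bearing": len(hit_genes),
        "n_universe": len(universe),
        "overlap": a,
        "fraction_pct": fraction,
        "p": float(p),
    }
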