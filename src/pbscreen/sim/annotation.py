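"""Toy genomes: TTAA-scrubbed random sequence with TTAA sites planted at a
controlled density, plus a non-overlapping gene annotation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..io import GeneAnnotation, find_ttaa


@dataclass(frozen=True)
class SimScreenConfig:
    """Parameters for the synthetic integration screen.

    ``ttaa_rate`` is the expected number of TTAA sites per kb; the
    background sequence is scrubbed of accidental TTAA occurrences so the
    planted density is the realised density.  ``enrichment_multiplier``
    scales the integration propensity of TTAA sites falling within
    ``window_bp`` of a suppressor gene body.
    """

    n_chroms: int = 2
    chrom_length_bp: int = 1_000_000
    ttaa_rate: float = 1.0
    n_genes: int = 20
    n_experiments: int = 4
    events_per_experiment: int = 500
    suppressor_genes: frozenset[str] = field(default_factory=frozenset)
    enrichment_multiplier: float = 1.0
    clonal_read_dist: tuple[str, float] = ("poisson", 4.0)
    window_bp: int = 20_000
    gene_length_bp: int = 2_000
    gene_spacing_bp: int | None = None  # None -> 2 * window_bp
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chroms < 1 or self.chrom_length_bp < 100:
            raise ValueError("need >=1 chromosome of >=100 bp")
        if self.ttaa_rate < 0:
            raise ValueError("ttaa_rate must be >= 0")
        if self.enrichment_multiplier < 1:
            raise ValueError("enrichment_multiplier must be >= 1")
        if self.events_per_experiment < 1:
            raise ValueError("events_per_experiment must be >= 1")
        if self.n_experiments < 1:
            raise ValueError("n_experiments must be >= 1")

    @property
    def spacing(self) -> int:
        return 2 * self.window_bp if self.gene_spacing_bp is None else self.gene_spacing_bp


def _scrub_ttaa(seq: bytearray) -> None:
    """Destroy every TTAA occurrence in place (last A -> C).

    Changing position i+3 from A to C cannot complete a TTAA in any window
    overlapping it, so one left-to-right pass suffices.
    """
    i = seq.find(b"TTAA")
    while i != -1:
        seq[i + 3] = ord("C")
        i = seq.find(b"TTAA", i + 1)


def simulate_annotation(
    config: SimScreenConfig,
) -> tuple[dict[str, str], list[GeneAnnotation], dict[str, np.ndarray]]:
    """Generate (genome, genes, TTAA index) for ``config``.

    The TTAA index maps chromosome name to the sorted array of 0-based TTAA
    start positions, rebuilt by scanning the final sequence so it is exact
    by construction.
    """
    rng = np.random.default_rng([config.seed, 0xA])
    genome: dict[str, str] = {}
    ttaa_index: dict[str, np.ndarray] = {}
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)

    for c in range(config.n_chroms):
        name = f"chr{c + 1}"
        arr = rng.choice(bases, size=config.chrom_length_bp)
        seq = bytearray(arr.tobytes())
        _scrub_ttaa(seq)
        n_sites = rng.poisson(config.ttaa_rate * config.chrom_length_bp / 1000.0)
        if n_sites > 0:
            pos = np.sort(rng.choice(config.chrom_length_bp - 4, size=n_sites, replace=False))
            keep = np.concatenate([[True], np.diff(pos) >= 4])
            for p in pos[keep]:
                seq[p : p + 4] = b"TTAA"
        genome[name] = seq.decode("ascii")
        ttaa_index[name] = find_ttaa(genome[name])

    genes = _place_genes(config, rng)
    return genome, genes, ttaa_index


def _place_genes(config: SimScreenConfig, rng: np.random.Generator) -> list[GeneAnnotation]:
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    genes: list[GeneAnnotation] = []
    gid = 0
    for c, n in enumerate(per_chrom):
        if n == 0:
            continue
        slot = config.chrom_length_bp // n
        slack = slot - config.gene_length_bp - config.spacing
        if slack < 0:
            raise ValueError(
                f"chromosome of {config.chrom_length_bp} bp too short for {n} genes "
                f"of {config.gene_length_bp} bp with {config.spacing} bp spacing"
            )
        for i in range(n):
            jitter = rng.integers(0, slack + 1)
            start = int(i * slot + config.spacing // 2 + jitter)
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneAnnotation(
                    gene_id=f"gene{gid:04d}",
                    chrom=f"chr{c + 1}",
                    strand=strand,
                    start=start,
                    end=start + config.gene_length_bp,
                )
            )
            gid += 1
    return genes
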