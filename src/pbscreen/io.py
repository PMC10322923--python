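"""Readers and writers for the formats the pipeline exchanges.

FASTA and GTF follow their standard conventions (GTF is 1-based inclusive
on disk); all in-memory coordinates are 0-based half-open.  Tabular output
is tab-separated UTF-8 with ``#``-prefixed header comment lines carrying
provenance (tool version, parameters, input checksums).
"""

from __future__ import annotations

import hashlib
import io as _io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs

from . import __version__

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_TTAA_RE = re.compile("TTAA")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def find_ttaa(seq: str) -> np.ndarray:
    """All 0-based TTAA start positions (TTAA cannot overlap itself)."""
    return np.fromiter((m.start() for m in _TTAA_RE.finditer(seq)), dtype=np.int64)


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene: 0-based half-open body plus strand-aware TSS."""

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r} for {self.gene_id}")
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a genome as ``{chrom: uppercase sequence}``."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF (gene features only)
# ---------------------------------------------------------------------------

_GENE_ID_RE = re.compile(r'gene_id "([^"]+)"')


def read_gtf(path: str | Path) -> list[GeneAnnotation]:
    """Parse gene features from a GTF file (1-based inclusive on disk)."""
    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            if fields[2] != "gene":
                continue
            m = _GENE_ID_RE.search(fields[8])
            if m is None:
                raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
            genes.append(
                GeneAnnotation(
                    gene_id=m.group(1),
                    chrom=fields[0],
                    strand=fields[6],
                    start=int(fields[3]) - 1,
                    end=int(fields[4]),
                )
            )
    return genes


def write_gtf(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                "\t".join(
                    [g.chrom, "pbscreen", "gene", str(g.start + 1), str(g.end),
                     ".", g.strand, ".", attrs]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED6 integration records
# ---------------------------------------------------------------------------

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed_records(path: str | Path) -> pd.DataFrame:
    """Read integration records from BED6.

    The BED ``name`` carries ``experiment:sample``, ``score`` the read count
    and ``strand`` the integration orientation.  Returns a data frame with
    columns experiment_id, sample_id, chrom, pos, orientation, read_count.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=BED_COLUMNS,
                     dtype={"chrom": str, "name": str})
    out = []
    for i, row in enumerate(df.itertuples(index=False), 1):
        name = str(row.name)
        if ":" not in name:
            raise ValueError(f"record {i}: BED name {name!r} is not 'experiment:sample'")
        exp, sample = name.split(":", 1)
        out.append((exp, sample, row.chrom, int(row.start), row.strand, int(row.score)))
    return pd.DataFrame(
        out,
        columns=["experiment_id", "sample_id", "chrom", "pos", "orientation", "read_count"],
    )


def write_bed_records(records: pd.DataFrame, path: str | Path) -> None:
    bed = pd.DataFrame(
        {
            "chrom": records["chrom"],
            "start": records["pos"],
            "end": records["pos"] + 4,
            "name": records["experiment_id"].astype(str) + ":" + records["sample_id"].astype(str),
            "score": records["read_count"],
            "strand": records["orientation"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# JASPAR PFM
# ---------------------------------------------------------------------------

def read_jaspar_pfm(path: str | Path):
    """Load the first motif from a JASPAR-format PFM file."""
    with open(path) as fh:
        return bio_motifs.read(fh, "jaspar")


# ---------------------------------------------------------------------------
# TSV with provenance comments
# ---------------------------------------------------------------------------

def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_tsv(df: pd.DataFrame, path: str | Path,
              params: Mapping[str, object] | None = None,
              inputs: Mapping[str, str | Path] | None = None) -> None:
    """Write a TSV with '#' provenance header lines."""
    buf = _io.StringIO()
    buf.write(f"# pbscreen {__version__}\n")
    for key, val in (params or {}).items():
        buf.write(f"# param {key}={val}\n")
    for key, val in (inputs or {}).items():
        buf.write(f"# input {key}={val} sha256={sha256_of(val)}\n")
    df.to_csv(buf, sep="\t", index=False)
    Path(path).write_text(buf.getvalue())


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
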