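"""Promoter fixtures with planted motif occurrences and motif-free negatives."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from ..motif import (
    IUPAC,
    MotifModel,
    Promoter,
    _consensus_match_offsets,
    _pwm_scores,
    iupac_revcomp,
)


def _concrete_site(motif: MotifModel, rng: np.random.Generator) -> str:
    """A concrete DNA realisation of the motif (degenerate codes sampled)."""
    if motif.mode == "consensus":
        return "".join(IUPAC[c][rng.integers(len(IUPAC[c]))] for c in motif.consensus)
    return "".join("ACGT"[b] for b in np.argmax(motif.pfm, axis=0))


def _hit_checker(motif: MotifModel):
    if motif.mode == "consensus":
        rc = iupac_revcomp(motif.consensus)

        def check(seq: str) -> bool:
            return bool(
                _consensus_match_offsets(seq, motif.consensus)
                or _consensus_match_offsets(seq, rc)
            )

    else:
        bg = {b: 0.25 for b in "ACGT"}
        lo = motif.log_odds(bg)
        threshold = motif.score_threshold(bg)

        def check(seq: str) -> bool:
            return bool(
                (_pwm_scores(seq, lo) >= threshold).any()
                or (_pwm_scores(seq, lo[::-1, ::-1]) >= threshold).any()
            )

    return check


def plant_motifs(
    promoters: list[Promoter],
    motif: MotifModel,
    positive_genes: set[str],
    seed: int = 0,
) -> tuple[list[Promoter], pd.DataFrame]:
    """Insert >=1 exact motif occurrence into every positive gene's promoter
    and scrub all other promoters motif-free by rejection resampling.

    Returns the modified promoter set and a truth table with columns
    gene_id, is_positive, planted_offset (-1 for negatives).
    """
    ids = {p.gene_id for p in promoters}
    if not positive_genes <= ids:
        raise ValueError(f"positive genes missing from promoter set: {sorted(positive_genes - ids)}")
    L = len(motif)
    rng = np.random.default_rng([seed, 0xD])
    has_hit = _hit_checker(motif)

    out: list[Promoter] = []
    truth_rows = []
    for p in promoters:
        n = len(p.seq)
        if n < L:
            raise ValueError(f"promoter of {p.gene_id} shorter than the motif")
        seq = p.seq
        # motif-free background first, for positives and negatives alike
        for _ in range(1000):
            if not has_hit(seq):
                break
            seq = "".join(rng.choice(list("ACGT"), size=n))
        else:
            raise RuntimeError(f"could not scrub motif from promoter of {p.gene_id}")
        offset = -1
        if p.gene_id in positive_genes:
            site = _concrete_site(motif, rng)
            offset = int(rng.integers(0, n - L + 1))
            seq = seq[:offset] + site + seq[offset + L :]
            if not has_hit(seq):  # degenerate PWMs could miss their own consensus
                raise RuntimeError(f"planted site not detectable in {p.gene_id}")
        out.append(replace(p, seq=seq))
        truth_rows.append((p.gene_id, p.gene_id in positive_genes, offset))

    truth = pd.DataFrame(truth_rows, columns=["gene_id", "is_positive", "planted_offset"])
    return out, truth
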