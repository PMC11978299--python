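"""Flanking-sequence extraction and position frequency matrices.

Flanks are taken on the gene strand with the edited base centered, so the
matrix columns read 5'->3' along the transcript; information content per
column is 2 - H (bits) against a uniform background, the WebLogo convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genemodel import Transcriptome

__all__ = ["FlankMatrix", "extract_flanks", "build_pfm", "write_pfm", "write_flanks_fasta"]

_RNA = "ACGU"


@dataclass
class FlankMatrix:
    """Per-column base frequencies (A/C/G/U) and information content over 2k+1 columns."""

    frequencies: np.ndarray  # (width, 4)
    information: np.ndarray  # (width,) bits
    counts: np.ndarray  # (width, 4) integer counts, N excluded
    n_sequences: int

    @property
    def width(self) -> int:
        return self.frequencies.shape[0]

    def to_frame(self) -> pd.DataFrame:
        k = self.width // 2
        df = pd.DataFrame(self.frequencies, columns=list(_RNA))
        df.insert(0, "column", np.arange(-k, k + 1))
        df["IC"] = self.information
        return df


def extract_flanks(
    sites: pd.DataFrame, transcriptome: Transcriptome, k: int = 20
) -> pd.DataFrame:
    """Extract the +/-k nt transcript-strand flank around each called site.

    Sites need ref/pos/gene_strand columns.  The flank is read from the
    transcript sequence (reverse-complemented genome for minus-strand genes)
    so the center base is the edited base itself; sites within k of a
    transcript end are N-padded and flagged.  Sites outside any matching
    gene fall back to the reference strand indicated by ``gene_strand``.
    """
    rows = []
    for r in sites.itertuples(index=False):
        genes = [
            g
            for g in transcriptome.genes_at(r.ref, r.pos)
            if g.strand == r.gene_strand and g.in_exon(r.pos)
        ]
        if genes:
            gene = max(genes, key=lambda g: g.length)
            tseq = transcriptome.transcript_seq(gene)
            t = gene.to_transcript(r.pos)
        else:
            tseq = transcriptome.references[r.ref]
            t = r.pos
            if r.gene_strand == "-":
                from .genemodel import revcomp

                tseq = revcomp(tseq)
                t = len(tseq) - 1 - t
        lo, hi = t - k, t + k + 1
        padded = lo < 0 or hi > len(tseq)
        seq = (
            "N" * max(0, -lo)
            + tseq[max(0, lo) : min(len(tseq), hi)]
            + "N" * max(0, hi - len(tseq))
        )
        rows.append({"ref": r.ref, "pos": r.pos, "flank": seq, "padded": padded})
    return pd.DataFrame(rows, columns=["ref", "pos", "flank", "padded"])


def build_pfm(flanks: list[str] | pd.Series) -> FlankMatrix:
    """Position frequency matrix and per-column information content.

    N-padded cells are excluded from the column denominator; T is read as U.
    IC = 2 - Shannon entropy (bits) with a uniform background, 0 for empty
    columns.
    """
    seqs = list(flanks)
    if not seqs:
        raise ValueError("no flank sequences given")
    width = len(seqs[0])
    if any(len(s) != width for s in seqs):
        raise ValueError("flanks must share one length")
    idx = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate("ACGU"):
        idx[ord(b)] = i
    idx[ord("T")] = 3  # DNA input: T counts as U
    counts = np.zeros((width, 4), dtype=np.int64)
    for s in seqs:
        codes = idx[np.frombuffer(s.upper().encode(), dtype=np.uint8)]
        valid = codes >= 0
        np.add.at(counts, (np.flatnonzero(valid), codes[valid]), 1)
    totals = counts.sum(axis=1)
    freqs = np.zeros_like(counts, dtype=float)
    nonzero = totals > 0
    freqs[nonzero] = counts[nonzero] / totals[nonzero, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    ic = np.where(nonzero, 2.0 + plogp.sum(axis=1), 0.0)
    ic = np.clip(ic, 0.0, 2.0)
    return FlankMatrix(
        frequencies=freqs, information=ic, counts=counts, n_sequences=len(seqs)
    )


def write_pfm(pfm: FlankMatrix, path: str) -> None:
    pfm.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_flanks_fasta(flanks: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        for r in flanks.itertuples(index=False):
            fh.write(f">{r.ref}:{r.pos}\n{r.flank}\n")
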