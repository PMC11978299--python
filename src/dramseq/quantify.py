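"""Site-level quantification outside the transcriptome-wide caller.

Sanger-trace edit rates (secondary-peak proportion at the edited base),
bisulfite-amplicon methylation fractions with the >1000-read QC rule, and
Pearson correlation of per-gene mutation counts between replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AmpliconQuant",
    "sanger_edit_rate",
    "bisulfite_fraction",
    "replicate_correlation",
    "read_fastq_seqs",
]

_PARTNER = {"C": "T", "A": "G"}


@dataclass(frozen=True)
class AmpliconQuant:
    """Quantified conversion at one amplicon position.

    ``fraction`` is a percentage; in bisulfite mode it is the methylated
    (C-retained) fraction and ``qc_pass`` requires more than 1000 reads.
    """

    site_position: int
    n_reads: int
    retained: int
    converted: int
    fraction: float
    qc_pass: bool


def sanger_edit_rate(trace: pd.DataFrame, position: int, conversion: str = "C2U") -> float:
    """Edit rate (%) from an idealised Sanger trace at ``position``.

    The trace is a per-position base-proportion table (columns A/C/G/T).  The
    secondary-base proportion of the expected conversion pair (C->T for C2U,
    A->G for A2G) is returned as a percentage; a mismatch between the
    column's primary base and the conversion raises.
    """
    if conversion not in ("C2U", "A2G"):
        raise ValueError(f"conversion must be C2U or A2G, got {conversion!r}")
    primary = "C" if conversion == "C2U" else "A"
    partner = _PARTNER[primary]
    col = trace.iloc[position]
    if col[primary] + col[partner] <= 0:
        raise ValueError(f"position {position} has no {primary}/{partner} signal")
    others = col.drop([primary, partner])
    if len(others) and others.max() > col[primary] + col[partner]:
        raise ValueError(
            f"position {position} is dominated by a base outside the "
            f"{primary}->{partner} pair; wrong site for {conversion}"
        )
    return float(col[partner] * 100.0)


def _anchor_offset(read: str, amplicon: str) -> int | None:
    """Best gapless offset of a read on the amplicon, bisulfite-aware.

    A position is compatible when the bases match or the amplicon has C and
    the read T.  Returns the offset with the most compatible positions,
    requiring at least 90% compatibility (sequencing errors tolerated);
    None when the read cannot be placed.
    """
    n, m = len(amplicon), len(read)
    if m > n:
        return None
    best, best_score = None, -1
    for off in range(n - m + 1):
        ref = amplicon[off : off + m]
        score = sum(a == b or (a == "C" and b == "T") for a, b in zip(ref, read))
        if score > best_score:
            best, best_score = off, score
    if best is None or best_score < 0.9 * m:
        return None
    return best


def bisulfite_fraction(
    reads: list[str], amplicon: str, site_position: int
) -> AmpliconQuant:
    """Methylated fraction (%) at one cytosine of a bisulfite amplicon.

    Reads are anchored to the amplicon gaplessly; at the target site a C
    counts as retained (methylated) and a T as converted, any other base —
    a sequencing error — is excluded from the denominator.  QC passes when
    the deep-sequencing read count exceeds 1000.
    """
    if amplicon[site_position] != "C":
        raise ValueError("site_position is not a C on the amplicon")
    retained = converted = 0
    for read in reads:
        off = _anchor_offset(read, amplicon)
        if off is None or not off <= site_position < off + len(read):
            continue
        base = read[site_position - off]
        if base == "C":
            retained += 1
        elif base == "T":
            converted += 1
    total = retained + converted
    fraction = retained / total * 100.0 if total else 0.0
    return AmpliconQuant(
        site_position=site_position,
        n_reads=len(reads),
        retained=retained,
        converted=converted,
        fraction=fraction,
        qc_pass=len(reads) > 1000,
    )


def read_fastq_seqs(path: str) -> list[str]:
    from Bio import SeqIO

    return [str(rec.seq) for rec in SeqIO.parse(path, "fastq")]


def replicate_correlation(counts_a: dict | pd.Series, counts_b: dict | pd.Series) -> float:
    """Pearson correlation of per-gene mutation counts between two replicates.

    The union of genes defines the vectors; a gene absent from one replicate
    counts 0 there.  Raises when either vector is constant (r undefined).
    """
    a = pd.Series(counts_a, dtype=float)
    b = pd.Series(counts_b, dtype=float)
    genes = a.index.union(b.index)
    va = a.reindex(genes, fill_value=0.0).to_numpy()
    vb = b.reindex(genes, fill_value=0.0).to_numpy()
    if np.std(va) == 0 or np.std(vb) == 0:
        raise ValueError("Pearson r undefined: a replicate has zero variance")
    return float(np.corrcoef(va, vb)[0, 1])
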