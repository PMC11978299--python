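"""Per-position base counting and candidate edit extraction.

``build_pileup`` turns a coordinate-sorted SAM/BAM into a strand-agnostic
count table; ``extract_candidates`` then interprets the counts through the
gene model's strand to produce candidate C-to-U or A-to-G events (for a
minus-strand gene a transcript C-to-U is a reference G->A).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam

from .genemodel import Transcriptome

__all__ = ["build_pileup", "extract_candidates", "load_fasta", "write_pileup", "write_candidates"]

_BASES = "ACGTN"
PILEUP_COLUMNS = ["ref", "pos", "A", "C", "G", "T", "N", "depth"]
CANDIDATE_COLUMNS = [
    "ref",
    "pos",
    "gene_strand",
    "conversion",
    "ref_base",
    "coverage",
    "edited_reads",
    "edit_ratio",
    "ambiguous",
]

# (conversion, gene strand) -> (required reference base, edited read base)
_CONVERSION = {
    ("C2U", "+"): ("C", "T"),
    ("C2U", "-"): ("G", "A"),
    ("A2G", "+"): ("A", "G"),
    ("A2G", "-"): ("T", "C"),
}


def load_fasta(path: str) -> dict[str, str]:
    """Read a FASTA reference into a name -> sequence dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def build_pileup(
    alignments: str,
    reference: dict[str, str],
    min_base_quality: int = 20,
    min_mapping_quality: int = 20,
) -> pd.DataFrame:
    """Count read bases per reference position from a sorted SAM/BAM.

    Secondary, supplementary, duplicate-flagged and unmapped reads are
    excluded, as are reads below the mapping-quality floor; individual bases
    below the base-quality floor contribute to neither counts nor depth.
    Positions with zero depth are omitted.
    """
    base_of = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        base_of[ord(b)] = i
        base_of[ord(b.lower())] = i

    counts: dict[str, np.ndarray] = {}
    with pysam.AlignmentFile(alignments, check_sq=False) as fh:
        so = (fh.header.get("HD") or {}).get("SO")
        if so != "coordinate":
            raise ValueError(f"alignments must be coordinate-sorted (SO={so!r})")
        for sq in fh.header.get("SQ", []):
            name = sq["SN"]
            if name not in reference:
                raise ValueError(f"contig {name!r} in alignments but not in reference")
            if sq["LN"] != len(reference[name]):
                raise ValueError(f"contig {name!r} length mismatch with reference")
            counts[name] = np.zeros((sq["LN"], 5), dtype=np.int64)
        for read in fh:
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_duplicate
                or read.mapping_quality < min_mapping_quality
            ):
                continue
            arr = counts[read.reference_name]
            seq = read.query_sequence
            quals = read.query_qualities
            cig = read.cigartuples
            if len(cig) == 1 and cig[0][0] == 0:  # full-length match: fast path
                codes = base_of[np.frombuffer(seq.encode(), dtype=np.uint8)]
                pos = np.arange(read.reference_start, read.reference_start + len(seq))
                if quals is not None:
                    keep = np.asarray(quals) >= min_base_quality
                    codes, pos = codes[keep], pos[keep]
                np.add.at(arr, (pos, codes), 1)
            else:
                for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                    if quals is not None and quals[qpos] < min_base_quality:
                        continue
                    arr[rpos, base_of[ord(seq[qpos])]] += 1

    frames = []
    for name in counts:
        arr = counts[name]
        depth = arr.sum(axis=1)
        covered = np.flatnonzero(depth)
        if len(covered) == 0:
            continue
        df = pd.DataFrame(arr[covered], columns=list(_BASES))
        df.insert(0, "pos", covered)
        df.insert(0, "ref", name)
        df["depth"] = depth[covered]
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=PILEUP_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def extract_candidates(
    pileup: pd.DataFrame,
    transcriptome: Transcriptome,
    conversion: str,
) -> pd.DataFrame:
    """Extract candidate edits of one conversion class from a pileup.

    Gene strand decides which reference base and which read base constitute
    the conversion; positions outside any gene are evaluated on both strands,
    and positions under genes on both strands yield one candidate per strand
    flagged ambiguous.  Positions with zero edited reads are omitted.
    ``coverage`` is the full read depth (N bases included), so the edit ratio
    has a conservative denominator.
    """
    if conversion not in ("C2U", "A2G"):
        raise ValueError(f"conversion must be C2U or A2G, got {conversion!r}")
    rows = []
    refs = transcriptome.references
    for rec in pileup.itertuples(index=False):
        ref_base = refs[rec.ref][rec.pos]
        genes = transcriptome.genes_at(rec.ref, rec.pos)
        strands = sorted({g.strand for g in genes}) or ["+", "-"]
        ambiguous = len({g.strand for g in genes}) == 2
        for strand in strands:
            want_ref, edited_base = _CONVERSION[(conversion, strand)]
            if ref_base != want_ref:
                continue
            edited = getattr(rec, edited_base)
            if edited == 0:
                continue
            rows.append(
                (
                    rec.ref,
                    rec.pos,
                    strand,
                    conversion,
                    ref_base,
                    rec.depth,
                    edited,
                    edited / rec.depth,
                    ambiguous,
                )
            )
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)


def write_pileup(pileup: pd.DataFrame, path: str) -> None:
    pileup.to_csv(path, sep="\t", index=False)


def write_candidates(candidates: pd.DataFrame, path: str) -> None:
    candidates.to_csv(path, sep="\t", index=False)


def read_candidates(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
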