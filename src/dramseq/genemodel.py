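"""Transcript models and BED12 interchange.

A :class:`GeneModel` is a single transcript placed on a reference contig:
exon blocks in genomic coordinates plus 5'UTR/CDS/3'UTR extents measured
along the transcript (sense strand).  All genomic intervals are 0-based
half-open; transcript coordinates run 5'->3' on the gene strand.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

__all__ = [
    "GeneModel",
    "Transcriptome",
    "read_bed12",
    "write_bed12",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (keeps N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """One transcript on a reference contig.

    ``utr5_len``/``cds_len``/``utr3_len`` are measured on the transcript
    sense strand; for a minus-strand gene the 5'UTR therefore sits at the
    high-coordinate end of the genomic span.
    """

    transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str
    utr5_len: int
    cds_len: int
    utr3_len: int
    blocks: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        blocks = self.blocks or ((self.start, self.end),)
        object.__setattr__(self, "blocks", tuple(blocks))
        if sum(e - s for s, e in self.blocks) != self.length:
            raise ValueError(
                f"{self.transcript_id}: block lengths do not sum to "
                f"utr5+cds+utr3 = {self.length}"
            )

    @property
    def length(self) -> int:
        return self.utr5_len + self.cds_len + self.utr3_len

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.blocks)

    def to_transcript(self, gpos: int) -> int:
        """Map a genomic (exonic) position to a transcript offset."""
        offset = 0
        for s, e in self.blocks:
            if s <= gpos < e:
                t_plus = offset + (gpos - s)
                return t_plus if self.strand == "+" else self.length - 1 - t_plus
            offset += e - s
        raise ValueError(f"position {gpos} not exonic in {self.transcript_id}")

    def to_genomic(self, tpos: int) -> int:
        """Map a transcript offset back to a genomic position."""
        if not 0 <= tpos < self.length:
            raise ValueError(f"transcript position {tpos} out of range")
        t_plus = tpos if self.strand == "+" else self.length - 1 - tpos
        for s, e in self.blocks:
            if t_plus < e - s:
                return s + t_plus
            t_plus -= e - s
        raise AssertionError("unreachable")

    def region_of(self, tpos: int) -> str:
        """Region label (UTR5/CDS/UTR3) for a transcript offset."""
        if not 0 <= tpos < self.length:
            raise ValueError(f"transcript position {tpos} out of range")
        if tpos < self.utr5_len:
            return "UTR5"
        if tpos < self.utr5_len + self.cds_len:
            return "CDS"
        return "UTR3"

    def metagene_coordinate(self, tpos: int) -> float:
        """Scaled coordinate in [0,3): UTR5->[0,1), CDS->[1,2), UTR3->[2,3)."""
        region = self.region_of(tpos)
        if region == "UTR5":
            return tpos / self.utr5_len
        if region == "CDS":
            return 1.0 + (tpos - self.utr5_len) / self.cds_len
        return 2.0 + (tpos - self.utr5_len - self.cds_len) / self.utr3_len


class Transcriptome:
    """Reference contigs plus their gene models, with strand-aware access."""

    def __init__(self, references: dict[str, str], genes: list[GeneModel]):
        self.references = dict(references)
        self.genes = list(genes)
        for g in self.genes:
            if g.chrom not in self.references:
                raise ValueError(f"gene {g.transcript_id} on unknown contig {g.chrom}")
            if g.end > len(self.references[g.chrom]):
                raise ValueError(f"gene {g.transcript_id} extends past contig end")
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for lst in self._by_chrom.values():
            lst.sort(key=lambda g: (g.start, g.end))
        self._starts = {c: [g.start for g in lst] for c, lst in self._by_chrom.items()}

    def transcript_seq(self, gene: GeneModel) -> str:
        """Spliced transcript sequence on the gene's sense strand."""
        ref = self.references[gene.chrom]
        s = "".join(ref[b:e] for b, e in gene.blocks)
        return s if gene.strand == "+" else revcomp(s)

    def genes_at(self, chrom: str, pos: int) -> list[GeneModel]:
        """All gene models whose genomic span covers ``pos``."""
        lst = self._by_chrom.get(chrom, [])
        if not lst:
            return []
        # spans may overlap; scan genes starting at or before pos
        hi = bisect.bisect_right(self._starts[chrom], pos)
        return [g for g in lst[:hi] if g.contains(pos)]

    def gene_by_id(self, transcript_id: str) -> GeneModel:
        for g in self.genes:
            if g.transcript_id == transcript_id:
                return g
        raise KeyError(transcript_id)


def write_bed12(genes: list[GeneModel], path: str) -> None:
    """Write gene models as BED12 (thick interval = CDS)."""
    with open(path, "w") as fh:
        for g in genes:
            if g.strand == "+":
                cds_g0 = g.to_genomic(g.utr5_len) if g.cds_len else g.start
                cds_g1 = g.to_genomic(g.utr5_len + g.cds_len - 1) + 1 if g.cds_len else g.start
            else:
                cds_g0 = g.to_genomic(g.utr5_len + g.cds_len - 1) if g.cds_len else g.start
                cds_g1 = g.to_genomic(g.utr5_len) + 1 if g.cds_len else g.start
            sizes = ",".join(str(e - s) for s, e in g.blocks)
            starts = ",".join(str(s - g.start) for s, e in g.blocks)
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            g.chrom,
                            g.start,
                            g.end,
                            g.transcript_id,
                            0,
                            g.strand,
                            cds_g0,
                            cds_g1,
                            0,
                            len(g.blocks),
                            sizes,
                            starts,
                        ],
                    )
                )
                + "\n"
            )


def read_bed12(path: str) -> list[GeneModel]:
    """Parse a BED12 file into gene models.

    UTR/CDS extents are recovered from the thick (CDS) interval; introns are
    whatever the blocks leave uncovered inside the span.
    """
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5]
            thick0, thick1 = int(f[6]), int(f[7])
            nblocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offs = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != nblocks or len(offs) != nblocks:
                raise ValueError(f"malformed BED12 blocks for {name}")
            blocks = tuple((start + o, start + o + sz) for o, sz in zip(offs, sizes))
            exonic = sum(sz for sz in sizes)
            cds = sum(
                max(0, min(e, thick1) - max(s, thick0)) for s, e in blocks
            )
            left = sum(max(0, min(e, thick0) - s) for s, e in blocks)
            right = exonic - cds - left
            if strand == "+":
                utr5, utr3 = left, right
            else:
                utr5, utr3 = right, left
            genes.append(
                GeneModel(
                    transcript_id=name,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    utr5_len=utr5,
                    cds_len=cds,
                    utr3_len=utr3,
                    blocks=blocks,
                )
            )
    return genes
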