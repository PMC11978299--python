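"""Gene-structure context for called sites.

Region assignment (5'UTR/CDS/3'UTR/intron/intergenic), metagene profiles on
the scaled [0,3) coordinate, and signed distances from reference m5C sites
to the nearest called edit along the gene strand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genemodel import GeneModel, Transcriptome

__all__ = [
    "RegionCall",
    "assign_region",
    "assign_regions",
    "metagene_profile",
    "MetageneProfile",
    "distance_to_reference",
    "distance_histogram",
]

_PRECEDENCE = {"CDS": 0, "UTR5": 1, "UTR3": 2}


@dataclass(frozen=True)
class RegionCall:
    ref: str
    pos: int
    region: str  # UTR5 | CDS | UTR3 | intron | intergenic
    metagene_coordinate: float | None  # in [0,3) for exonic mRNA sites
    gene_id: str | None


def assign_region(ref: str, pos: int, transcriptome: Transcriptome) -> RegionCall:
    """Assign one genomic position to a region.

    When isoforms disagree the precedence is CDS > UTR5 > UTR3 > intron >
    intergenic, ties broken by the longest transcript; the metagene
    coordinate comes from the winning transcript.
    """
    genes = transcriptome.genes_at(ref, pos)
    best: tuple[int, int, str, GeneModel] | None = None
    intronic: GeneModel | None = None
    for g in genes:
        if not g.in_exon(pos):
            intronic = intronic or g
            continue
        region = g.region_of(g.to_transcript(pos))
        rank = (_PRECEDENCE[region], -g.length)
        if best is None or rank < (best[0], best[1]):
            best = (rank[0], rank[1], region, g)
    if best is not None:
        _, _, region, g = best
        coord = g.metagene_coordinate(g.to_transcript(pos))
        return RegionCall(ref, pos, region, coord, g.transcript_id)
    if intronic is not None:
        return RegionCall(ref, pos, "intron", None, intronic.transcript_id)
    return RegionCall(ref, pos, "intergenic", None, None)


def assign_regions(sites: pd.DataFrame, transcriptome: Transcriptome) -> pd.DataFrame:
    """Region calls for a table of sites (needs ref/pos columns)."""
    calls = [assign_region(r.ref, r.pos, transcriptome) for r in sites.itertuples(index=False)]
    return pd.DataFrame(
        {
            "ref": [c.ref for c in calls],
            "pos": [c.pos for c in calls],
            "region": [c.region for c in calls],
            "metagene_coordinate": [c.metagene_coordinate for c in calls],
            "gene_id": [c.gene_id for c in calls],
        }
    )


@dataclass
class MetageneProfile:
    table: pd.DataFrame  # columns: bin_left, bin_right, density
    n_sites: int  # exonic sites contributing mass

    @property
    def empty(self) -> bool:
        return self.n_sites == 0


def metagene_profile(region_calls: pd.DataFrame, n_bins: int = 90) -> MetageneProfile:
    """Bin exonic metagene coordinates over [0,3); densities sum to 1.

    ``n_bins`` spans the whole axis, so bins per segment is ``n_bins/3``
    (default 30 per segment).
    """
    coords = region_calls["metagene_coordinate"].dropna().to_numpy(dtype=float)
    edges = np.linspace(0.0, 3.0, n_bins + 1)
    counts, _ = np.histogram(coords, bins=edges)
    n = len(coords)
    density = counts / n if n else np.zeros(n_bins)
    table = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "density": density}
    )
    return MetageneProfile(table=table, n_sites=n)


def distance_to_reference(
    called_sites: pd.DataFrame,
    reference_m5c: pd.DataFrame,
    transcriptome: Transcriptome,
    window: int = 3000,
) -> pd.DataFrame:
    """Signed transcript-strand distance from each reference m5C site to its nearest edit.

    Each reference site (columns ref/pos, optionally strand) is set to 0 and
    the nearest called edit within +/-``window`` nt contributes one record;
    negative means upstream of the m5C site on the gene strand.  Equidistant
    up/downstream edits resolve to the downstream (positive) record.
    Distances are measured in transcript coordinates of the reference site's
    gene; reference sites outside genes use genomic plus-strand offsets.
    """
    by_ref: dict[str, np.ndarray] = {}
    for ref, grp in called_sites.groupby("ref"):
        by_ref[ref] = np.sort(grp["pos"].to_numpy(dtype=int))
    rows = []
    for r in reference_m5c.itertuples(index=False):
        pos_arr = by_ref.get(r.ref)
        if pos_arr is None or len(pos_arr) == 0:
            continue
        genes = [g for g in transcriptome.genes_at(r.ref, r.pos) if g.in_exon(r.pos)]
        gene = max(genes, key=lambda g: g.length) if genes else None
        lo = np.searchsorted(pos_arr, r.pos - window)
        hi = np.searchsorted(pos_arr, r.pos + window, side="right")
        best = None
        for edit_pos in pos_arr[lo:hi]:
            if gene is not None:
                try:
                    d = gene.to_transcript(int(edit_pos)) - gene.to_transcript(r.pos)
                except ValueError:  # edit outside the gene's exons
                    continue
            else:
                d = int(edit_pos) - r.pos
            if abs(d) > window:
                continue
            # nearest edit; ties (equal |d|) resolve downstream (d > 0)
            if best is None or abs(d) < abs(best[0]) or (
                abs(d) == abs(best[0]) and d > best[0]
            ):
                best = (d, int(edit_pos))
        if best is not None:
            rows.append(
                {
                    "ref": r.ref,
                    "reference_pos": r.pos,
                    "edit_pos": best[1],
                    "signed_distance": best[0],
                    "window": window,
                }
            )
    return pd.DataFrame(
        rows, columns=["ref", "reference_pos", "edit_pos", "signed_distance", "window"]
    )


def distance_histogram(records: pd.DataFrame, bin_width: int | None = None) -> pd.DataFrame:
    """Histogram of signed distances; 1 nt bins for the 80 nt window, 50 nt for 3000 nt."""
    if len(records) == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "count"])
    window = int(records["window"].iloc[0])
    if bin_width is None:
        bin_width = 1 if window <= 80 else 50
    edges = np.arange(-window, window + bin_width, bin_width)
    counts, _ = np.histogram(records["signed_distance"], bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
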