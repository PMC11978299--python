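"""Synthetic data generation for the editing-detection pipeline.

Emulates the experiment end to end: a toy transcriptome, planted m5C sites,
and condition-specific sequencing reads in which a reader-tethered deaminase
converts A->G (ABE) or C->U (CBE, read as T) within a +/-20 nt window of each
methylated cytosine.  Also produces bisulfite-converted amplicon reads and
Sanger-style base-proportion traces for the site-level quantifiers.

All randomness flows through ``numpy.random.default_rng`` seeded explicitly;
identical seeds give byte-identical output files.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pysam

from .genemodel import GeneModel, Transcriptome, revcomp, write_bed12

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticTruth",
    "ConditionSpec",
    "generate_transcriptome",
    "plant_m5c_sites",
    "simulate_reads",
    "simulate_bisulfite_amplicon",
    "simulate_sanger_trace",
    "write_fasta",
    "write_fastq",
    "write_truth",
    "read_truth",
]

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
# transcript-sense conversion: ABE edits A->G, CBE edits C->T(U)
_EDITOR_FROM = {"ABE": 0, "CBE": 1}
_EDITOR_TO = {"ABE": 2, "CBE": 3}


@dataclass(frozen=True)
class SyntheticTruth:
    """A planted m5C site and the editing behaviour it induces.

    ``edit_rate`` is the per-read probability that an editable base (A for
    ABE, C for CBE) inside the +/-``window_halfwidth`` nt window is
    deaminated.  ``m5c_fraction`` is only used in bisulfite-amplicon mode:
    the fraction of molecules methylated (C retained) at the site itself.
    """

    site_id: str
    transcript_id: str
    position: int  # 0-based offset on the transcript sense strand
    editor: str  # ABE | CBE
    edit_rate: float
    window_halfwidth: int = 20
    m5c_fraction: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.edit_rate <= 1.0:
            raise ValueError("edit_rate must lie in [0,1]")
        if not 0.0 <= self.m5c_fraction <= 1.0:
            raise ValueError("m5c_fraction must lie in [0,1]")
        if self.window_halfwidth < 0:
            raise ValueError("window_halfwidth must be >= 0")
        if self.position < 0:
            raise ValueError("position must be >= 0")
        if self.editor not in _EDITOR_FROM:
            raise ValueError(f"editor must be ABE or CBE, got {self.editor!r}")


@dataclass
class ConditionSpec:
    """Sequencing-condition parameters for one transfection arm.

    ``rate_multiplier`` scales every planted site's edit rate (1.0 for the
    reader-deaminase fusion, ~0 for the binding-mutant fusion, an attenuation
    factor for methyltransferase knockouts).  ``background_rate`` is the
    per-base off-target deamination probability; ``background_region_bias``
    multiplies it inside 3'UTRs, reproducing the diffuse 3'UTR-skewed pattern
    of deaminase-only samples.
    """

    condition: str
    replicate_count: int = 1
    coverage_mean: float = 100.0
    rate_multiplier: float = 1.0
    background_rate: float = 0.0
    background_region_bias: float = 3.0
    error_rate: float = 0.0
    seed: int = 0

    CONDITIONS = ("DRAM", "DRAM_MUT", "DEAMINASE_ONLY", "KNOCKOUT", "WILDTYPE_BS")

    def __post_init__(self):
        if self.condition not in self.CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be > 0")
        for name in ("background_rate", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1]")
        if self.rate_multiplier < 0:
            raise ValueError("rate_multiplier must be >= 0")


# ---------------------------------------------------------------------------
# reference generation


def generate_transcriptome(
    n_transcripts: int,
    length_range: tuple[int, int] = (600, 1200),
    utr_cds_fractions: tuple[float, float, float] = (0.2, 0.5, 0.3),
    seed: int = 0,
    pad: int = 50,
) -> Transcriptome:
    """Build a toy single-exon transcriptome, one transcript per contig.

    Each contig carries ``pad`` nt of intergenic flank on either side of the
    gene body; half the genes land on the minus strand so that transcript
    sense differs from reference sense.  CDS length is forced to a multiple
    of 3 and fractions must sum to 1.
    """
    f5, fc, f3 = utr_cds_fractions
    if abs(f5 + fc + f3 - 1.0) > 1e-9:
        raise ValueError("utr_cds_fractions must sum to 1")
    if length_range[0] < 150:
        raise ValueError("transcript lengths must be >= 150 nt")
    rng = np.random.default_rng(seed)
    refs: dict[str, str] = {}
    genes: list[GeneModel] = []
    for i in range(n_transcripts):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        u5 = max(1, int(round(f5 * L)))
        cds = max(3, int(round(fc * L)) // 3 * 3)
        u3 = L - u5 - cds
        if u3 < 1:
            u3 = 1
            cds = (L - u5 - u3) // 3 * 3
        L = u5 + cds + u3
        strand = "+" if i % 2 == 0 else "-"
        tseq = "".join(rng.choice(list(_BASES), size=L))
        body = tseq if strand == "+" else revcomp(tseq)
        left = "".join(rng.choice(list(_BASES), size=pad))
        right = "".join(rng.choice(list(_BASES), size=pad))
        name = f"tx{i:04d}"
        refs[name] = left + body + right
        genes.append(
            GeneModel(
                transcript_id=name,
                chrom=name,
                start=pad,
                end=pad + L,
                strand=strand,
                utr5_len=u5,
                cds_len=cds,
                utr3_len=u3,
            )
        )
    return Transcriptome(refs, genes)


def write_fasta(references: dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in references:
            fh.write(f">{name}\n")
            seq = references[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# planting sites


def plant_m5c_sites(
    transcriptome: Transcriptome,
    n_sites: int,
    region_weights: dict[str, float] | None = None,
    rate_range: tuple[float, float] = (0.1, 0.4),
    window_halfwidth: int = 20,
    editor: str = "CBE",
    seed: int = 0,
) -> list[SyntheticTruth]:
    """Plant ``n_sites`` m5C sites at cytosines of the transcript sense strand.

    Regions are drawn according to ``region_weights`` (default reflects the
    observed CDS/3'UTR predominance of mRNA m5C); within a region the site
    position is uniform over all unused sense-strand Cs across transcripts,
    so the empirical region distribution converges to the weights.
    """
    if region_weights is None:
        region_weights = {"CDS": 0.5, "UTR3": 0.35, "UTR5": 0.15}
    rng = np.random.default_rng(seed)
    pool: dict[str, list[tuple[str, int]]] = {r: [] for r in region_weights}
    for gene in transcriptome.genes:
        tseq = transcriptome.transcript_seq(gene)
        for t, base in enumerate(tseq):
            if base == "C":
                region = gene.region_of(t)
                if region in pool:
                    pool[region].append((gene.transcript_id, t))
    regions = sorted(region_weights)
    weights = np.array([region_weights[r] for r in regions], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("region weights must sum to a positive value")
    weights = weights / weights.sum()

    sites: list[SyntheticTruth] = []
    used: set[tuple[str, int]] = set()
    for i in range(n_sites):
        region = rng.choice(regions, p=weights)
        candidates = [c for c in pool[region] if c not in used]
        if not candidates:
            logger.warning("no unused C available in region %s; skipping site", region)
            continue
        tx, pos = candidates[int(rng.integers(len(candidates)))]
        used.add((tx, pos))
        rate = float(rng.uniform(rate_range[0], rate_range[1]))
        sites.append(
            SyntheticTruth(
                site_id=f"site{i:04d}",
                transcript_id=tx,
                position=pos,
                editor=editor,
                edit_rate=rate,
                window_halfwidth=window_halfwidth,
            )
        )
    return sites


def write_truth(sites: list[SyntheticTruth], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("site_id\ttranscript_id\tposition\teditor\tedit_rate\twindow_halfwidth\tm5c_fraction\n")
        for s in sites:
            fh.write(
                f"{s.site_id}\t{s.transcript_id}\t{s.position}\t{s.editor}\t"
                f"{s.edit_rate:.6g}\t{s.window_halfwidth}\t{s.m5c_fraction:.6g}\n"
            )


def read_truth(path: str) -> list[SyntheticTruth]:
    sites = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            rec = dict(zip(header, line.rstrip("\n").split("\t")))
            sites.append(
                SyntheticTruth(
                    site_id=rec["site_id"],
                    transcript_id=rec["transcript_id"],
                    position=int(rec["position"]),
                    editor=rec["editor"],
                    edit_rate=float(rec["edit_rate"]),
                    window_halfwidth=int(rec["window_halfwidth"]),
                    m5c_fraction=float(rec["m5c_fraction"]),
                )
            )
    return sites


# ---------------------------------------------------------------------------
# read simulation


def _edit_probabilities(
    gene: GeneModel,
    tcodes: np.ndarray,
    truth: list[SyntheticTruth],
    spec: ConditionSpec,
    editor: str,
) -> np.ndarray:
    """Per-position per-read edit probability on the transcript sense strand."""
    L = len(tcodes)
    editable = tcodes == _EDITOR_FROM[editor]
    p_keep = np.ones(L)  # probability of NOT being edited, multiplied per source
    for site in truth:
        if site.transcript_id != gene.transcript_id:
            continue
        lo = max(0, site.position - site.window_halfwidth)
        hi = min(L, site.position + site.window_halfwidth + 1)
        rate = min(1.0, site.edit_rate * spec.rate_multiplier)
        if rate > 0:
            p_keep[lo:hi] *= 1.0 - rate
    if spec.background_rate > 0:
        bg = np.full(L, spec.background_rate)
        u3_start = gene.utr5_len + gene.cds_len
        bg[u3_start:] = min(1.0, spec.background_rate * spec.background_region_bias)
        p_keep *= 1.0 - bg
    p = 1.0 - p_keep
    p[~editable] = 0.0
    return p


def simulate_reads(
    transcriptome: Transcriptome,
    truth: list[SyntheticTruth],
    spec: ConditionSpec,
    read_length: int = 100,
    out_dir: str = ".",
    editor: str | None = None,
    prefix: str | None = None,
) -> list[str]:
    """Simulate strand-specific transcript reads and write one sorted SAM per replicate.

    Reads are sense-strand transcript fragments placed uniformly; editable
    bases inside a planted site's window are deaminated per read with
    probability ``edit_rate * rate_multiplier``, background edits follow the
    condition's off-target rate (3'UTR-biased), and uniform sequencing errors
    are applied last.  Minus-strand genes are written reverse-complemented at
    the correct reference coordinates, so a transcript-level C->U appears as
    G->A on the reference.
    """
    if editor is None:
        editors = {s.editor for s in truth}
        if len(editors) != 1:
            raise ValueError("editor must be given when truth is empty or mixed")
        editor = editors.pop()
    if editor not in _EDITOR_FROM:
        raise ValueError(f"unknown editor {editor!r}")
    os.makedirs(out_dir, exist_ok=True)
    prefix = prefix or f"{spec.condition}_{editor}".lower()
    contigs = sorted(transcriptome.references)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(transcriptome.references[c])} for c in contigs],
    }
    ref_codes = {
        c: np.frombuffer(transcriptome.references[c].encode(), dtype=np.uint8)
        for c in contigs
    }
    base_of = np.zeros(256, dtype=np.int8)
    for b, i in _CODE.items():
        base_of[ord(b)] = i
    code_char = np.frombuffer(_BASES.encode(), dtype=np.uint8)

    paths = []
    for rep in range(spec.replicate_count):
        rng = np.random.default_rng(spec.seed + rep)
        path = os.path.join(out_dir, f"{prefix}_rep{rep + 1}.sam")
        reads: dict[str, list[tuple[int, str, bool, bytes]]] = {c: [] for c in contigs}
        for gene in sorted(transcriptome.genes, key=lambda g: g.transcript_id):
            L = gene.length
            if read_length > L:
                logger.warning(
                    "read_length %d exceeds transcript %s length %d; skipped",
                    read_length,
                    gene.transcript_id,
                    L,
                )
                continue
            tseq = transcriptome.transcript_seq(gene)
            tcodes = base_of[np.frombuffer(tseq.encode(), dtype=np.uint8)]
            p = _edit_probabilities(gene, tcodes, truth, spec, editor)
            nz = np.flatnonzero(p)
            pnz = p[nz]
            to_code = _EDITOR_TO[editor]
            n_reads = int(round(spec.coverage_mean * L / read_length))
            starts = rng.integers(0, L - read_length + 1, size=n_reads)
            for i in range(n_reads):
                s = int(starts[i])
                codes = tcodes[s : s + read_length].copy()
                lo = np.searchsorted(nz, s)
                hi = np.searchsorted(nz, s + read_length)
                if hi > lo:
                    idx = nz[lo:hi]
                    hits = rng.random(hi - lo) < pnz[lo:hi]
                    codes[idx[hits] - s] = to_code
                if spec.error_rate > 0:
                    k = rng.binomial(read_length, spec.error_rate)
                    if k:
                        epos = rng.choice(read_length, size=k, replace=False)
                        codes[epos] = (codes[epos] + rng.integers(1, 4, size=k)) % 4
                seq = code_char[codes].tobytes()
                if gene.strand == "+":
                    gpos = gene.start + s
                    reverse = False
                else:
                    gpos = gene.end - s - read_length
                    reverse = True
                    seq = revcomp(seq.decode()).encode()
                reads[gene.chrom].append(
                    (gpos, f"{gene.transcript_id}.r{rep + 1}.{i}", reverse, seq)
                )
        with pysam.AlignmentFile(path, "w", header=header) as out:
            for ci, contig in enumerate(contigs):
                ref = ref_codes[contig]
                for gpos, qname, reverse, seq in sorted(
                    reads[contig], key=lambda r: (r[0], r[1])
                ):
                    a = pysam.AlignedSegment(out.header)
                    a.query_name = qname
                    a.query_sequence = seq.decode()
                    a.flag = 16 if reverse else 0
                    a.reference_id = ci
                    a.reference_start = gpos
                    a.mapping_quality = 60
                    a.cigartuples = [(0, read_length)]
                    a.query_qualities = pysam.qualitystring_to_array("I" * read_length)
                    ref_slice = ref[gpos : gpos + read_length]
                    read_arr = np.frombuffer(seq, dtype=np.uint8)
                    mism = np.flatnonzero(ref_slice != read_arr)
                    md, last = [], 0
                    for m in mism:
                        md.append(str(m - last))
                        md.append(chr(ref_slice[m]))
                        last = m + 1
                    md.append(str(read_length - last))
                    a.set_tags([("NM", int(len(mism))), ("MD", "".join(md))])
                    out.write(a)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# amplicon and trace simulation


def simulate_bisulfite_amplicon(
    site: SyntheticTruth,
    amplicon_seq: str,
    n_reads: int,
    conversion_efficiency: float = 1.0,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Simulate bisulfite-converted amplicon reads as (name, sequence) pairs.

    At ``site.position`` a read retains C with probability ``m5c_fraction``
    (the molecule was methylated); otherwise, and at every other C, the base
    converts C->T with probability ``conversion_efficiency``.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if amplicon_seq[site.position] != "C":
        raise ValueError("target site is not a C on the amplicon")
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(amplicon_seq.encode(), dtype=np.uint8)
    c_pos = np.flatnonzero(arr == ord("C"))
    reads = []
    target_idx = np.searchsorted(c_pos, site.position)
    for i in range(n_reads):
        codes = arr.copy()
        convert = rng.random(len(c_pos)) < conversion_efficiency
        methylated = rng.random() < site.m5c_fraction
        if methylated:
            convert[target_idx] = False
        codes[c_pos[convert]] = ord("T")
        reads.append((f"{site.site_id}.bs.{i}", codes.tobytes().decode()))
    return reads


def write_fastq(reads: list[tuple[str, str]], path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def simulate_sanger_trace(edit_rate: float, flank: str, position: int):
    """Idealised Sanger trace: per-position base proportions, secondary peak at ``position``.

    Returns a DataFrame with columns A/C/G/T; at the edited position the
    primary base keeps proportion ``1 - edit_rate`` and its deamination
    partner (C->T or A->G) takes ``edit_rate``; every other column is pure.
    """
    import pandas as pd

    if not 0.0 <= edit_rate <= 1.0:
        raise ValueError("edit_rate must lie in [0,1]")
    if not 0 <= position < len(flank):
        raise ValueError("position outside flank")
    primary = flank[position]
    if primary not in "AC":
        raise ValueError("edited base must be A (ABE) or C (CBE)")
    partner = {"A": "G", "C": "T"}[primary]
    table = np.zeros((len(flank), 4))
    for i, b in enumerate(flank):
        table[i, _CODE[b]] = 1.0
    table[position, _CODE[primary]] = 1.0 - edit_rate
    table[position, _CODE[partner]] = edit_rate
    return pd.DataFrame(table, columns=list(_BASES))
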