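"""The comparative filter cascade for calling edited sites.

A candidate survives when it has enough coverage, an edit ratio inside the
allowed window, enough edited reads, and a ratio sufficiently above the
methyltransferase-knockout control; it must do so in a minimum number of
replicates, and must not appear in deaminase-only samples.  Default
thresholds: >=10 reads coverage, ratio 5-95%, >=1.5-fold over knockout,
>=2 edited reads.  The stricter high-confidence tier uses ratio 10-60%,
2-fold over knockout and >=4 edited reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FilterParams",
    "HIGH_CONFIDENCE",
    "filter_site",
    "knockout_ratio_map",
    "call_replicated_sites",
    "subtract_background",
    "high_confidence_tier",
    "merge_editor_genes",
    "write_sites_bed",
]

KEY = ["ref", "pos", "conversion"]


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the site-calling cascade (see module docstring)."""

    min_coverage: int = 10
    ratio_min: float = 0.05
    ratio_max: float = 0.95
    fold_vs_knockout: float = 1.5
    min_edited_reads: int = 2
    min_replicates: int = 2
    knockout_pseudocount: int = 1

    def __post_init__(self):
        if not 0.0 <= self.ratio_min < self.ratio_max <= 1.0:
            raise ValueError("need 0 <= ratio_min < ratio_max <= 1")
        if self.fold_vs_knockout < 1.0:
            raise ValueError("fold_vs_knockout must be >= 1")
        if self.min_edited_reads < 1:
            raise ValueError("min_edited_reads must be >= 1")


#: stricter parameter set for the high-confidence tier
HIGH_CONFIDENCE = FilterParams(
    ratio_min=0.10, ratio_max=0.60, fold_vs_knockout=2.0, min_edited_reads=4
)


def effective_knockout_ratio(
    ko_edited: float | None, ko_coverage: float | None, params: FilterParams
) -> float | None:
    """Knockout edit ratio used by the fold test.

    Covered but unedited positions get a pseudocount ratio; positions with no
    knockout coverage return None, which makes the fold test pass (absence of
    control coverage is not evidence of editing there).
    """
    if ko_coverage is None or not ko_coverage > 0:
        return None
    if ko_edited is None or ko_edited == 0:
        pc = params.knockout_pseudocount
        return pc / (ko_coverage + pc)
    return ko_edited / ko_coverage


def filter_site(candidate, knockout, params: FilterParams = FilterParams()):
    """Evaluate the threshold cascade on one candidate.

    ``candidate`` needs ``coverage``/``edit_ratio``/``edited_reads``
    attributes; ``knockout`` is a matched candidate, a precomputed knockout
    ratio, or None (no knockout coverage at this position).  Returns
    ``(passed, reason)`` where reason names the first failing predicate.
    """
    if knockout is None or isinstance(knockout, float) and math.isnan(knockout):
        ko_ratio = None
    elif isinstance(knockout, (int, float)):
        ko_ratio = float(knockout)
    else:
        ko_ratio = effective_knockout_ratio(
            knockout.edited_reads, knockout.coverage, params
        )
    if candidate.coverage < params.min_coverage:
        return False, "coverage"
    if candidate.edit_ratio < params.ratio_min:
        return False, "ratio_min"
    if candidate.edit_ratio > params.ratio_max:
        return False, "ratio_max"
    if candidate.edited_reads < params.min_edited_reads:
        return False, "edited_reads"
    if ko_ratio is not None and candidate.edit_ratio < params.fold_vs_knockout * ko_ratio:
        return False, "fold"
    return True, "pass"


def knockout_ratio_map(
    knockout_candidates: pd.DataFrame | None,
    knockout_pileup: pd.DataFrame | None,
    params: FilterParams,
) -> dict:
    """Map (ref, pos, conversion) -> effective knockout ratio.

    Built from the knockout candidate table plus, optionally, the knockout
    pileup (to know coverage at positions the knockout covers without any
    edited read).  Keys absent from the map have no knockout coverage.
    """
    ratios: dict = {}
    depth: dict = {}
    if knockout_pileup is not None and len(knockout_pileup):
        depth = {
            (r.ref, r.pos): r.depth for r in knockout_pileup.itertuples(index=False)
        }
    if knockout_candidates is not None and len(knockout_candidates):
        for r in knockout_candidates.itertuples(index=False):
            ratios[(r.ref, r.pos, r.conversion)] = r.edited_reads / r.coverage
    pc = params.knockout_pseudocount
    for (ref, pos), d in depth.items():
        for conv in ("C2U", "A2G"):
            ratios.setdefault((ref, pos, conv), pc / (d + pc))
    return ratios


def call_replicated_sites(
    replicates: list[pd.DataFrame],
    knockout_candidates: pd.DataFrame | None,
    params: FilterParams = FilterParams(),
    knockout_pileup: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Apply the cascade per replicate and keep sites passing in enough replicates.

    Reported coverage, edited reads and edit ratio are means over the passing
    replicates.  Per-replicate values are kept (``coverage_rep*`` etc.) so the
    high-confidence tier can re-evaluate the same evidence.
    """
    if len(replicates) < 1:
        raise ValueError("at least one replicate required")
    ko = knockout_ratio_map(knockout_candidates, knockout_pileup, params)
    n_rep = len(replicates)
    per_rep: dict = {}
    meta: dict = {}
    for i, rep in enumerate(replicates):
        for r in rep.itertuples(index=False):
            key = (r.ref, r.pos, r.conversion)
            per_rep.setdefault(key, {})[i] = (r.coverage, r.edited_reads, r.edit_ratio)
            meta.setdefault(key, (r.gene_strand, r.ref_base))
    rows = []
    for key in sorted(per_rep):
        ko_ratio = ko.get(key)
        reps = per_rep[key]
        passing = []
        for i, (cov, edited, ratio) in reps.items():
            cand = _Cand(cov, edited, ratio)
            ok, _ = filter_site(cand, ko_ratio, params)
            if ok:
                passing.append(i)
        if len(passing) < params.min_replicates:
            continue
        strand, ref_base = meta[key]
        row = {
            "ref": key[0],
            "pos": key[1],
            "conversion": key[2],
            "gene_strand": strand,
            "ref_base": ref_base,
            "n_pass": len(passing),
            "coverage": float(np.mean([reps[i][0] for i in passing])),
            "edited_reads": float(np.mean([reps[i][1] for i in passing])),
            "edit_ratio": float(np.mean([reps[i][2] for i in passing])),
            "ko_ratio": np.nan if ko_ratio is None else ko_ratio,
            "tier": "default",
        }
        for i in range(n_rep):
            cov, edited, ratio = reps.get(i, (np.nan, np.nan, np.nan))
            row[f"coverage_rep{i + 1}"] = cov
            row[f"edited_rep{i + 1}"] = edited
            row[f"ratio_rep{i + 1}"] = ratio
        rows.append(row)
    return pd.DataFrame(rows)


class _Cand:
    __slots__ = ("coverage", "edited_reads", "edit_ratio")

    def __init__(self, coverage, edited_reads, edit_ratio):
        self.coverage = coverage
        self.edited_reads = edited_reads
        self.edit_ratio = edit_ratio


def deaminase_appeared(
    replicates: list[pd.DataFrame], params: FilterParams = FilterParams()
) -> pd.DataFrame:
    """Positions where editing *appeared* in deaminase-only samples.

    A candidate appears when it passes the evidence predicates (coverage,
    ratio window, minimum edited reads) in at least one deaminase-only
    replicate; no knockout fold test applies.  The result feeds
    :func:`subtract_background`.
    """
    keys = set()
    rows = []
    for rep in replicates:
        for r in rep.itertuples(index=False):
            key = (r.ref, r.pos, r.conversion)
            if key in keys:
                continue
            ok, _ = filter_site(r, None, params)
            if ok:
                keys.add(key)
                rows.append({"ref": r.ref, "pos": r.pos, "conversion": r.conversion})
    return pd.DataFrame(rows, columns=["ref", "pos", "conversion"])


def subtract_background(
    sites: pd.DataFrame, deaminase_only_sites: pd.DataFrame | None
) -> pd.DataFrame:
    """Remove called sites that appear in deaminase-only samples (exact position match)."""
    if deaminase_only_sites is None or len(deaminase_only_sites) == 0 or len(sites) == 0:
        return sites.copy()
    bg = set(
        zip(
            deaminase_only_sites["ref"],
            deaminase_only_sites["pos"],
            deaminase_only_sites["conversion"],
        )
    )
    keep = [
        (r.ref, r.pos, r.conversion) not in bg for r in sites.itertuples(index=False)
    ]
    return sites.loc[keep].reset_index(drop=True)


def high_confidence_tier(
    sites: pd.DataFrame, hc_params: FilterParams = HIGH_CONFIDENCE
) -> pd.DataFrame:
    """Relabel the subset of default-tier sites that also satisfies the stricter thresholds.

    Re-evaluates the stored per-replicate evidence against ``hc_params``;
    a site is kept when enough replicates pass, and its reported values
    become means over those replicates.
    """
    if len(sites) == 0:
        return sites.copy()
    n_rep = sum(1 for c in sites.columns if c.startswith("ratio_rep"))
    rows = []
    for _, row in sites.iterrows():
        ko_ratio = None if pd.isna(row["ko_ratio"]) else float(row["ko_ratio"])
        passing = []
        for i in range(1, n_rep + 1):
            cov = row[f"coverage_rep{i}"]
            if pd.isna(cov):
                continue
            cand = _Cand(cov, row[f"edited_rep{i}"], row[f"ratio_rep{i}"])
            ok, _ = filter_site(cand, ko_ratio, hc_params)
            if ok:
                passing.append(i)
        if len(passing) < hc_params.min_replicates:
            continue
        new = row.copy()
        new["n_pass"] = len(passing)
        new["coverage"] = float(np.mean([row[f"coverage_rep{i}"] for i in passing]))
        new["edited_reads"] = float(np.mean([row[f"edited_rep{i}"] for i in passing]))
        new["edit_ratio"] = float(np.mean([row[f"ratio_rep{i}"] for i in passing]))
        new["tier"] = "high_confidence"
        rows.append(new)
    if not rows:
        return sites.iloc[0:0].copy()
    return pd.DataFrame(rows).reset_index(drop=True)


def assign_genes(sites: pd.DataFrame, transcriptome) -> pd.DataFrame:
    """Annotate each site with the ids of overlapping same-strand genes (comma-joined)."""
    out = sites.copy()
    gene_ids = []
    for r in sites.itertuples(index=False):
        genes = [
            g.transcript_id
            for g in transcriptome.genes_at(r.ref, r.pos)
            if g.strand == r.gene_strand
        ]
        gene_ids.append(",".join(genes))
    out["gene_id"] = gene_ids
    return out


def merge_editor_genes(
    abe_sites: pd.DataFrame, cbe_sites: pd.DataFrame, transcriptome
) -> pd.DataFrame:
    """Union of genes carrying ABE and/or CBE called sites, with per-editor site counts."""
    counts: dict[str, dict[str, int]] = {}
    for label, sites in (("ABE", abe_sites), ("CBE", cbe_sites)):
        if sites is None or len(sites) == 0:
            continue
        annotated = assign_genes(sites, transcriptome) if "gene_id" not in sites else sites
        for gid_field in annotated["gene_id"]:
            for gid in str(gid_field).split(","):
                if not gid or gid == "nan":
                    continue
                counts.setdefault(gid, {"ABE": 0, "CBE": 0})[label] += 1
    rows = []
    for gid in sorted(counts):
        a, c = counts[gid]["ABE"], counts[gid]["CBE"]
        editors = "+".join([e for e, n in (("ABE", a), ("CBE", c)) if n > 0])
        rows.append({"gene_id": gid, "abe_sites": a, "cbe_sites": c, "editors": editors})
    return pd.DataFrame(rows, columns=["gene_id", "abe_sites", "cbe_sites", "editors"])


def write_sites_bed(sites: pd.DataFrame, path: str) -> None:
    """Called sites as BED6; score = round(1000 * edit ratio)."""
    with open(path, "w") as fh:
        for r in sites.itertuples(index=False):
            name = f"{r.conversion}"
            score = int(round(1000 * r.edit_ratio))
            fh.write(
                f"{r.ref}\t{int(r.pos)}\t{int(r.pos) + 1}\t{name}\t{score}\t{r.gene_strand}\n"
            )
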