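import numpy as np
import pandas as pd
import pytest

from dramseq.genemodel import GeneModel, Transcriptome
from dramseq.simulate import generate_transcriptome, plant_m5c_sites


@pytest.fixture(scope="session")
def toy_transcriptome() -> Transcriptome:
    """Six short transcripts (alternating strands) with 50 nt intergenic pads."""
    return generate_transcriptome(6, (300, 600), (0.2, 0.5, 0.3), seed=11)


@pytest.fixture(scope="session")
def toy_truth(toy_transcriptome):
    return plant_m5c_sites(
        toy_transcriptome, 8, rate_range=(0.3, 0.3), editor="CBE", seed=12
    )


@pytest.fixture
def simple_gene() -> tuple[Transcriptome, GeneModel]:
    """One plus-strand gene with round region lengths: UTR5 100, CDS 300, UTR3 100."""
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=600))
    gene = GeneModel(
        transcript_id="g1",
        chrom="chr1",
        start=50,
        end=550,
        strand="+",
        utr5_len=100,
        cds_len=300,
        utr3_len=100,
    )
    return Transcriptome({"chr1": seq}, [gene]), gene


def make_candidates(rows) -> pd.DataFrame:
    """Candidate table from (ref, pos, coverage, edited) tuples, C2U on plus strand."""
    recs = [
        {
            "ref": ref,
            "pos": pos,
            "gene_strand": "+",
            "conversion": "C2U",
            "ref_base": "C",
            "coverage": cov,
            "edited_reads": edited,
            "edit_ratio": edited / cov,
            "ambiguous": False,
        }
        for ref, pos, cov, edited in rows
    ]
    return pd.DataFrame(recs)
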