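"""Default medulloblastoma biomarker table (synthetic convenience fixture).

Established diagnostic/prognostic genomic features of the consensus
medulloblastoma molecular groups, with approximate GRCh37/hg19 loci,
shipped as a starting point for :func:`scclone.clonality.annotate_biomarkers`.
Each marker is only meaningful within its subgroup context (``MB_WNT``,
``MB_SHH``, ``MB_Group3``, ``MB_Group4``); users analysing real data
should supply their own curated table.

Coordinates here are deliberately coarse (gene locus +/- margin, or whole
chromosomes/arms) — adequate for overlap flagging at 50 kb bin resolution,
not for annotation at gene resolution.
"""

from __future__ import annotations

import pandas as pd

_ROWS = [
    # marker, subgroup, chrom, start, end
    ("CTNNB1_mut", "MB_WNT", "chr3", 41_200_000, 41_300_000),
    ("chr6_loss", "MB_WNT", "chr6", 0, 171_115_067),
    ("PTCH1_mut", "MB_SHH", "chr9", 98_200_000, 98_300_000),
    ("TP53_mut", "MB_SHH", "chr17", 7_500_000, 7_620_000),
    ("MYCN_amp", "MB_SHH", "chr2", 16_000_000, 16_200_000),
    ("GLI2_amp", "MB_SHH", "chr2", 121_500_000, 121_800_000),
    ("chr9q_loss", "MB_SHH", "chr9", 49_000_000, 141_213_431),
    ("MYC_amp", "MB_Group3", "chr8", 128_700_000, 128_800_000),
    ("i17q", "MB_Group3", "chr17", 25_000_000, 81_195_210),
    ("chr7_gain", "MB_Group4", "chr7", 0, 159_138_663),
    ("chr8_loss", "MB_Group4", "chr8", 0, 146_364_022),
    ("chr11_loss", "MB_Group4", "chr11", 0, 135_006_516),
    ("i17q", "MB_Group4", "chr17", 25_000_000, 81_195_210),
]


def default_biomarker_table() -> pd.DataFrame:
    """The bundled marker table as a DataFrame (copy; safe to edit)."""
    return pd.DataFrame(
        _ROWS, columns=["marker", "subgroup", "chrom", "start", "end"]
    )
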