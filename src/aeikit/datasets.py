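"""Small published data tables bundled for worked examples and checks."""

from __future__ import annotations

import pandas as pd

# Published survey of 12 catalogued A-to-I editing sites in human brain,
# measured in two condition groups: 10 brain regions of one individual
# ("regions") and dorsolateral prefrontal cortex of 13 individuals
# ("dlpfc").  Columns per group: number of samples displaying editing,
# average read depth, mean % edited, and SEM of % edited across samples.
_BRAIN_EDITING_ROWS = [
    # gene, position, position_in_gene,
    #   n_regions, depth_regions, pct_regions, sem_regions,
    #   n_dlpfc,   depth_dlpfc,   pct_dlpfc,   sem_dlpfc
    ("CCDC75/EIF2AK2", "chr2:37327702", "intergenic", 8, 11.4, 59.8, 8.0, 8, 22.2, 32.0, 8.7),
    ("CTSB", "chr8:11702542", "3'UTR", 10, 16.8, 99.4, 0.6, 8, 11.0, 87.3, 4.0),
    ("FTX", "chrX:73499965", "exonic (ncRNA)", 9, 62.0, 31.8, 2.8, 10, 116.3, 27.1, 2.2),
    ("GRIA2", "chr4:158257875", "exonic (non-synonymous)", 10, 32.3, 88.9, 4.6, 13, 56.0, 97.5, 0.6),
    ("GRIA2", "chr4:158257879", "exonic (synonymous)", 8, 35.9, 21.0, 2.7, 8, 75.5, 16.4, 0.8),
    ("GRIK2", "chr6:102337689", "exonic (non-synonymous)", 10, 19.2, 44.5, 3.9, 13, 18.9, 37.2, 3.8),
    ("GRIK2", "chr6:102337702", "exonic (non-synonymous)", 9, 18.2, 62.0, 3.7, 13, 17.1, 63.9, 5.7),
    ("MTRNR2L1", "chr17:22021971", "intergenic", 10, 1595.7, 98.0, 0.1, 10, 1796.7, 96.9, 0.5),
    ("PAR-SN", "chr15:25227816", "exonic (ncRNA)", 9, 11.6, 67.8, 8.2, 13, 29.6, 79.4, 2.0),
    ("PAR-SN", "chr15:25227838", "exonic (ncRNA)", 7, 12.1, 43.5, 5.3, 11, 26.1, 35.4, 2.6),
    ("PAR-SN", "chr15:25227854", "exonic (ncRNA)", 5, 14.4, 25.4, 5.6, 8, 26.6, 22.1, 2.8),
    ("TRUB2", "chr9:131071533", "3'UTR", 5, 11.2, 54.6, 9.9, 11, 15.1, 59.8, 4.6),
]

_BRAIN_EDITING_COLUMNS = [
    "gene", "position", "position_in_gene",
    "n_regions", "depth_regions", "pct_edited_regions", "sem_regions",
    "n_dlpfc", "depth_dlpfc", "pct_edited_dlpfc", "sem_dlpfc",
]


def brain_editing_sites() -> pd.DataFrame:
    """Twelve retained brain A-to-I editing sites, as published.

    Mean edited fraction and its SEM are percentages across samples; depth
    is mean reads per sample.  The sites survive the survey's retention
    filters (support in >=5 of 10 regions, >=8 of 13 DLPFC individuals,
    average depth > 10 reads) and its reference-error exclusion.
    """
    return pd.DataFrame(_BRAIN_EDITING_ROWS, columns=_BRAIN_EDITING_COLUMNS)
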