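"""Published summary tables of the airborne-metagenome study.

The study's six air samples — indoor and outdoor air of a Manhattan high
rise (NY_INDOOR, NY_OUTDOOR), indoor and outdoor air of a San Diego
hospital (SD_IHOSP, SD_OHOSP), a San Diego house (SD_IHOUS) and a marine
pier (SD_SCRPP) — were sequenced, quality-filtered and assigned kingdom
taxonomy.  The printed per-sample read classification counts and the 16S
amplicon chimera counts are small published tables used as inputs to the
report arithmetic; the raw sequence data (BioProject PRJNA218551) are not
needed for that arithmetic.
"""

from __future__ import annotations

import pandas as pd

from .core import CATEGORIES

SAMPLES = ("NY_INDOOR", "NY_OUTDOOR", "SD_IHOSP", "SD_OHOSP", "SD_IHOUS",
           "SD_SCRPP")

_KINGDOM_COUNTS = {
    #            Archaea  Bacteria  Eukaryota   Mixed  Viruses  Other  Unclassified
    "NY_INDOOR":  (1048,   256691,   663225,    6012,    958,   1084,   504660),
    "NY_OUTDOOR": (269,     55681,   281601,    1915,    495,   1389,   620628),
    "SD_IHOSP":   (286,    347562,    68998,    5975,   1926,    491,   152468),
    "SD_OHOSP":   (606,    263396,   167883,    7010,    514,    167,   384538),
    "SD_IHOUS":   (90,     192326,    40334,    5936,   4186,    206,   148683),
    "SD_SCRPP":   (324,     44092,   375198,    2356,   2026,     67,   729639),
}

#: 16S amplicon sequences generated and flagged as chimeric, NYC samples.
SIXTEEN_S_COUNTS = {
    "NY_INDOOR": {"total": 410_373, "chimeric": 12_503},
    "NY_OUTDOOR": {"total": 230_506, "chimeric": 5_287},
}


def kingdom_count_table() -> pd.DataFrame:
    """The published per-sample kingdom classification counts, with totals.

    Rows are the six samples; columns are the seven categories plus Total.
    """
    cols = ("Archaea", "Bacteria", "Eukaryota", "Mixed", "Viruses", "Other",
            "Unclassified")
    table = pd.DataFrame.from_dict(_KINGDOM_COUNTS, orient="index",
                                   columns=cols)
    table = table.reindex(columns=list(CATEGORIES))
    table["Total"] = table.sum(axis=1)
    table.index.name = "sample"
    return table.loc[list(SAMPLES)]
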