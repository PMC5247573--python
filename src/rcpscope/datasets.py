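"""Small built-in input tables.

The KRAS tumour table below reproduces the pooled per-sample RCP counts and
the clinical next-generation-sequencing genotypes from a published
six-sample colon-carcinoma in situ genotyping study.  It is input data for
the scoring stage (and the worked examples), not a test fixture: the
ratios and Mutant/Wild-type labels are always recomputed from the counts.
"""

from __future__ import annotations

import pandas as pd

_KRAS_ROWS = [
    # sample, n_rois, n_mutant, n_wildtype, clinical label, clinical detail
    ("A",  14,  82, 345, "Mutant",    "G-12S 18%"),
    ("E",   9,   3, 546, "Wild type", "Wild type"),
    ("F",   7,  50, 262, "Mutant",    "G-12V 37%"),
    ("I",   8, 140, 255, "Mutant",    "G-12V (ratio NA)"),
    ("E1",  6,  51, 706, "Wild type", "Wild type"),
    ("J",   6,  64, 857, "Wild type", "Wild type"),
]


def kras_tumour_counts() -> pd.DataFrame:
    """Pooled mutant/wild-type RCP counts for six colon tumour sections.

    Columns: ``sample_id, n_rois, n_mutant, n_wildtype, clinical,
    clinical_detail``.  ``clinical`` is the Mutant/Wild-type genotype from
    clinical NGS of the same samples and serves as the concordance
    reference.
    """
    return pd.DataFrame(
        _KRAS_ROWS,
        columns=["sample_id", "n_rois", "n_mutant", "n_wildtype",
                 "clinical", "clinical_detail"],
    )


__all__ = ["kras_tumour_counts"]
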