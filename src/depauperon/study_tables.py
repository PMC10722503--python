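"""Published summary tables for the 248 angiosperm families classified by
strict consensus across five calibrated phylogenies.

These printed counts are inputs to the contingency analyses (the underlying
family-level databases are not redistributed here).  Cell values are
preserved exactly as published; some row totals in the mating-system table
are internally inconsistent in the source and are deliberately not
reconciled.
"""

import pandas as pd

__all__ = ["wgd_by_richness", "mating_by_richness", "STRICT_CONSENSUS_COUNTS"]

#: strict-consensus family counts per richness category
STRICT_CONSENSUS_COUNTS = {"poor": 75, "expected": 161, "high": 12}


def wgd_by_richness() -> pd.DataFrame:
    """Families by number of ancestral whole-genome duplications x richness category."""
    return pd.DataFrame(
        [[71, 119, 2], [3, 39, 5], [1, 3, 5]],
        index=pd.Index(["None", "One", ">Two"], name="wgd"),
        columns=pd.Index(["poor", "predicted", "high"], name="category"),
    )


def mating_by_richness() -> pd.DataFrame:
    """Families by mating/sexual-system label x richness category (cells as published)."""
    return pd.DataFrame(
        [[10, 2, 0], [8, 35, 0], [4, 57, 12], [3, 30, 0], [50, 37, 0]],
        index=pd.Index(["Dioecious", "SC", "SC-SI", "SI", "Unknown"], name="mating_system"),
        columns=pd.Index(["poor", "predicted", "high"], name="category"),
    )
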