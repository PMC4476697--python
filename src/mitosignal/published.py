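"""Published reference inputs carried with the package.

Per-gene group means/SEMs of relative mtDNA copy number for the two injury
models (diffuse rotational RNR at 6 h and 25 h; focal cortical-impact CCI at
25 h), the custom TaqMan assay oligo sequences, and the sham cerebral
respiration references. These ship as data files so the pooling arithmetic can
be reproduced offline; all pooled values are computed, never hard-coded.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .qpcr import pooled_mean_of_group_means

#: Sham (pre-injury baseline) cerebral respiration references, pmol O2 s^-1 mg^-1.
SHAM_HIPPOCAMPAL_OXPHOS = 82.6
SHAM_HIPPOCAMPAL_RCR = 5.91
SHAM_CORTICAL_OXPHOS = 76.0

GROUPS = ("RNR-6h", "RNR-25h", "CCI-25h")


def _read_csv(name: str) -> pd.DataFrame:
    with resources.files("mitosignal.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_group_means() -> pd.DataFrame:
    """Per-gene group means of RQ with SEM and per-group animal counts."""
    return _read_csv("published_group_means.csv")


def load_assays() -> pd.DataFrame:
    """Published TaqMan assay oligos (forward/reverse primer and probe per assay)."""
    return _read_csv("published_assays.csv")


def pooled_reference_values() -> dict[str, float]:
    """The three pooled RQ aggregates recomputed from the per-gene group means.

    * ``pre_injury``: all nine pre-injury per-gene means weighted by group size
      (4 + 4 + 5 animals across 3 genes, n = 39 values).
    * ``rnr_6h_post`` / ``cci_25h_post``: mean of the three post-injury per-gene
      means of the respective group (equal weights within a group).
    """
    gm = load_group_means()
    pre = gm[gm["timepoint"] == "pre"]
    out = {"pre_injury": pooled_mean_of_group_means(pre["mean"], pre["n_animals"])}
    for key, group in (("rnr_6h_post", "RNR-6h"), ("cci_25h_post", "CCI-25h")):
        sel = gm[(gm["group"] == group) & (gm["timepoint"] == "post")]
        out[key] = pooled_mean_of_group_means(sel["mean"], sel["n_animals"])
    return out
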