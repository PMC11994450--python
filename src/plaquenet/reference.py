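"""Published cell counts from a human carotid plaque scRNA-seq cohort.

Observed per-subcluster female/male cell counts for the smooth muscle cell
(SMC), macrophage (MP) and endothelial cell (EC) compartments of a deep
endarterectomy single-cell study (7 female and 8 male donors, 7,690 cells
total). Subclusters whose counts were not reported individually are pooled
into a ``rest`` row so every compartment's margins match the reported per-sex
compartment totals; one-vs-rest bias tests on the reported subclusters are
unaffected by the pooling.

These tables are inputs for recomputing the reported sex percentages with
:func:`plaquenet.composition.per_cluster_bias`; they are not simulation
output.
"""

from __future__ import annotations

import pandas as pd

# (female cells, male cells) per subcluster; "rest" pools unreported ones.
_SMC = {
    "SMC1": (20, 165),
    "SMC3": (244, 17),
    "SMC4": (182, 450),
    "SMC5": (55, 269),
    "SMC6": (0, 101),
    "SMC8": (72, 23),
    "SMC9": (31, 74),
    "rest": (747, 813),  # SMC2 + SMC7
}
_MP = {
    "MP1": (23, 211),
    "MP2": (488, 17),
    "MP3": (71, 16),
    "MP5": (528, 104),
    "MP7": (5, 267),
    "MP8": (137, 51),
    "rest": (418, 460),  # MP4 + MP6
}
_EC = {
    "EC1": (44, 249),
    "EC2": (144, 28),
    "EC4": (111, 7),
    "rest": (155, 154),  # EC3 + EC5
}

#: Reported per-sex totals: overall and per compartment.
COMPARTMENT_TOTALS: dict[str, tuple[int, int]] = {
    "all": (3841, 3849),
    "SMC": (1351, 1912),
    "MP": (1670, 1126),
    "EC": (454, 438),
}


def carotid_sex_counts(compartment: str) -> pd.DataFrame:
    """Subcluster x sex observed counts for one compartment (SMC, MP or EC)."""
    tables = {"SMC": _SMC, "MP": _MP, "EC": _EC}
    if compartment not in tables:
        raise KeyError(f"unknown compartment {compartment!r}; choose from {sorted(tables)}")
    df = pd.DataFrame(tables[compartment], index=["F", "M"]).T
    df.index.name = "subcluster"
    df.columns.name = "sex"
    return df
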