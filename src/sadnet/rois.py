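"""Network node (ROI) definitions.

Twenty bilateral regions span a dorsal, working-memory-related set
(dlPFC, iFG, mSFG, IPS, PCG) and a ventral, sadness-related set
(sACC, mFP, Amy, Hip, mOFG).  Each node is the center of a 5x5x5-voxel
cube in MNI space; the packaged table carries the peak coordinates,
the anatomical community each area belongs to, and whether it is a
cortical or subcortical structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

_ROI_RESOURCE = "roi_table.tsv"


@dataclass(frozen=True)
class RoiDefinition:
    """One network node: abbreviation, full name, hemisphere, MNI peak."""

    abbrev: str
    name: str
    hemisphere: str
    x: float
    y: float
    z: float
    community: str
    tissue: str

    @property
    def mni(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


def load_roi_table(path=None) -> pd.DataFrame:
    """Load the ROI definition table.

    Parameters
    ----------
    path : str or Path, optional
        External TSV with the same columns.  Defaults to the packaged
        20-ROI table.
    """
    if path is None:
        ref = resources.files("sadnet").joinpath("data", _ROI_RESOURCE)
        with resources.as_file(ref) as p:
            table = pd.read_csv(p, sep="\t")
    else:
        table = pd.read_csv(path, sep="\t")
    required = {"abbrev", "name", "hemisphere", "x", "y", "z", "community", "tissue"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"ROI table missing columns: {sorted(missing)}")
    if table["abbrev"].duplicated().any():
        dups = table.loc[table["abbrev"].duplicated(), "abbrev"].tolist()
        raise ValueError(f"duplicate ROI abbreviations: {dups}")
    return table


def rois_from_table(table: pd.DataFrame | None = None) -> list[RoiDefinition]:
    if table is None:
        table = load_roi_table()
    return [RoiDefinition(**row) for row in table.to_dict("records")]


def default_partition_labels(
    table: pd.DataFrame | None = None, by: str = "community"
) -> np.ndarray:
    """Integer community labels aligned with the table's ROI order.

    ``by="community"`` gives the dorsal/ventral split; ``by="tissue"``
    the cortical/subcortical split used as the anatomical sanity check
    in the resolution-parameter scan.
    """
    if table is None:
        table = load_roi_table()
    codes, _ = pd.factorize(table[by])
    return codes.astype(np.int64)
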