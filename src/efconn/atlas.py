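"""Cortical parcellation label tables.

Nodes of every graph in this package are atlas parcels (ROIs) of a
hemisphere/network/region parcellation in the Schaefer 17-network style:
labels look like ``LH_ContC_pCun_1`` — hemisphere prefix, network name,
region, and a within-region index.  ROI ids are 1-based and follow file
order (left hemisphere first).

The analysis focuses on executive function, so the visual and somatomotor
networks are excluded up front; in the 17-network nomenclature those are
exactly ``VisCent``, ``VisPeri``, ``SomMotA`` and ``SomMotB``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

#: The 17 network names of the Schaefer 17-network parcellation.
SCHAEFER17_NETWORKS: tuple[str, ...] = (
    "VisCent", "VisPeri", "SomMotA", "SomMotB",
    "DorsAttnA", "DorsAttnB", "SalVentAttnA", "SalVentAttnB",
    "LimbicA", "LimbicB", "ContA", "ContB", "ContC",
    "DefaultA", "DefaultB", "DefaultC", "TempPar",
)

#: Visual + somatomotor networks, removed before graph construction.
DEFAULT_EXCLUDED_NETWORKS: frozenset[str] = frozenset(
    {"VisCent", "VisPeri", "SomMotA", "SomMotB"}
)

HEMISPHERES = ("LH", "RH")


def parse_label(label: str) -> tuple[str, str, str, int]:
    """Split an atlas label into (hemisphere, network, region, index).

    >>> parse_label("LH_DorsAttnA_SPL_2")
    ('LH', 'DorsAttnA', 'SPL', 2)

    The region may itself contain underscores; the trailing integer, when
    present, is the within-region index (0 otherwise).
    """
    tokens = label.split("_")
    if len(tokens) < 3:
        raise ValueError(f"malformed atlas label {label!r}: expected at least "
                         "HEMI_Network_Region")
    hemi, network = tokens[0], tokens[1]
    if hemi not in HEMISPHERES:
        raise ValueError(f"malformed atlas label {label!r}: hemisphere prefix "
                         f"must be one of {HEMISPHERES}")
    if tokens[-1].isdigit() and len(tokens) >= 4:
        region = "_".join(tokens[2:-1])
        index = int(tokens[-1])
    else:
        region = "_".join(tokens[2:])
        index = 0
    return hemi, network, region, index


@dataclass
class AtlasTable:
    """Validated ROI table: one row per parcel, ids exactly 1..n_roi."""

    table: pd.DataFrame
    excluded_networks: frozenset[str] = field(default=DEFAULT_EXCLUDED_NETWORKS)

    def __post_init__(self) -> None:
        df = self.table
        required = {"roi_id", "label", "hemisphere", "network", "included"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"atlas table missing columns {sorted(missing)}")
        ids = df["roi_id"]
        dup = ids[ids.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate roi_id {int(dup.iloc[0])} in atlas")
        n = len(df)
        if sorted(ids) != list(range(1, n + 1)):
            raise ValueError("roi_ids must exactly cover 1..n_roi "
                             f"(got {n} rows, ids {ids.min()}..{ids.max()})")

    @property
    def n_roi(self) -> int:
        return len(self.table)

    def networks(self) -> set[str]:
        return set(self.table["network"])

    def label_of(self, roi_id: int) -> str:
        row = self.table.loc[self.table["roi_id"] == roi_id, "label"]
        return str(row.iloc[0])


def build_atlas_table(
    labels: "pd.Series | list[str]",
    roi_ids: "list[int] | None" = None,
    excluded_networks: "frozenset[str] | set[str]" = DEFAULT_EXCLUDED_NETWORKS,
) -> AtlasTable:
    """Assemble an AtlasTable from labels, parsing each into components."""
    labels = list(labels)
    if roi_ids is None:
        roi_ids = list(range(1, len(labels) + 1))
    rows = []
    for rid, lab in zip(roi_ids, labels):
        try:
            hemi, network, region, index = parse_label(lab)
        except ValueError as exc:
            raise ValueError(f"atlas row roi_id={rid}: {exc}") from exc
        rows.append((int(rid), lab, hemi, network,
                     network not in excluded_networks))
    df = pd.DataFrame(rows, columns=["roi_id", "label", "hemisphere",
                                     "network", "included"])
    return AtlasTable(df, frozenset(excluded_networks))


def load_atlas(path, excluded_networks=DEFAULT_EXCLUDED_NETWORKS) -> AtlasTable:
    """Read an atlas CSV with at least columns ``roi_id,label``.

    Extra columns are ignored.  Raises on duplicate ids, gaps in 1..n_roi,
    or labels that do not parse.
    """
    df = pd.read_csv(path)
    if not {"roi_id", "label"} <= set(df.columns):
        raise ValueError(f"atlas file {path} must have columns roi_id,label")
    try:
        roi_ids = [int(x) for x in df["roi_id"]]
    except (TypeError, ValueError) as exc:
        raise ValueError(f"atlas file {path}: roi_id not integer") from exc
    return build_atlas_table(df["label"], roi_ids, excluded_networks)


def write_atlas(atlas: AtlasTable, path) -> None:
    atlas.table[["roi_id", "label"]].to_csv(path, index=False)


def excluded_rois(atlas: AtlasTable, excluded_networks=None) -> set[int]:
    """ROI ids whose network is in the exclusion set (default: visual+motor)."""
    if excluded_networks is None:
        excluded_networks = atlas.excluded_networks
    unknown = set(excluded_networks) - atlas.networks()
    if unknown:
        logger.warning("exclusion networks not present in atlas: %s",
                       sorted(unknown))
    df = atlas.table
    return set(df.loc[df["network"].isin(excluded_networks), "roi_id"].astype(int))
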