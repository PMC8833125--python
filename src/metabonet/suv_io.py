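"""Reading, writing and normalizing regional SUV tables.

The pipeline's raw input is a table of standardized uptake values (SUV):
one row per subject, one column per atlas region, plus a group label.
Optionally, region means can be extracted from a 3-D uptake volume against
an integer label atlas volume (NIfTI-1), for data that arrive as images
already registered to the atlas space.

Region order follows the shipped 96-region rat atlas: regions 1-48 are the
right hemisphere, 49-96 the left; every matrix downstream uses this order.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "RegionAtlas",
    "SUVTable",
    "load_atlas",
    "read_suv_table",
    "write_suv_table",
    "extract_region_means",
    "region_means_from_nifti",
    "normalize_global",
    "normalize_table",
]


@dataclass(frozen=True)
class RegionAtlas:
    """Region metadata: integer ids 1..n, names, abbreviations, hemisphere."""

    table: pd.DataFrame  # columns: region_id, name, abbreviation, hemisphere

    def __post_init__(self):
        t = self.table
        required = {"region_id", "name", "abbreviation", "hemisphere"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"atlas missing columns: {sorted(missing)}")
        ids = t["region_id"].to_numpy()
        n = len(t)
        if not np.array_equal(np.sort(ids), np.arange(1, n + 1)):
            raise ValueError("atlas region ids must be unique and contiguous from 1")
        if t["abbreviation"].duplicated().any():
            dup = t.loc[t["abbreviation"].duplicated(), "abbreviation"].tolist()
            raise ValueError(f"duplicate atlas abbreviations: {dup}")

    @property
    def n_regions(self) -> int:
        return len(self.table)

    @property
    def abbreviations(self) -> list[str]:
        return self.table.sort_values("region_id")["abbreviation"].tolist()

    @property
    def region_ids(self) -> np.ndarray:
        return self.table.sort_values("region_id")["region_id"].to_numpy()


def load_atlas(path=None) -> RegionAtlas:
    """Load an atlas CSV (id,name,abbreviation,hemisphere).

    With no path, loads the shipped 96-region rat brain atlas
    (48 right / 48 left homotopic pairs).
    """
    if path is None:
        ref = importlib.resources.files("metabonet.data") / "rat_atlas_96.csv"
        with ref.open("r") as fh:
            t = pd.read_csv(fh)
    else:
        t = pd.read_csv(path)
    atlas = RegionAtlas(t)
    if path is None:
        # sanity contract for the shipped atlas
        counts = atlas.table["hemisphere"].value_counts()
        assert atlas.n_regions == 96 and counts["R"] == 48 and counts["L"] == 48
    return atlas


@dataclass
class SUVTable:
    """Subjects x regions uptake values with group labels.

    ``data`` is indexed by subject id with one column per region
    abbreviation, in atlas order. ``groups`` maps subject id -> group label.
    """

    data: pd.DataFrame
    groups: pd.Series
    normalized: bool = False
    atlas: RegionAtlas | None = field(default=None, repr=False)

    def __post_init__(self):
        if not self.data.index.equals(self.groups.index):
            raise ValueError("data and groups must share the subject index")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate subject ids: {dup}")
        vals = self.data.to_numpy()
        if not np.isfinite(vals).all():
            bad = np.argwhere(~np.isfinite(vals))
            cells = [(self.data.index[i], self.data.columns[j]) for i, j in bad[:10]]
            raise ValueError(f"non-finite SUV cells: {cells}")

    @property
    def group_labels(self) -> list[str]:
        return sorted(self.groups.unique().tolist())

    def group_values(self, group: str) -> np.ndarray:
        """(n_subjects, n_regions) float array for one group."""
        mask = (self.groups == group).to_numpy()
        if not mask.any():
            raise KeyError(f"no subjects in group {group!r}")
        return self.data.to_numpy()[mask]

    def group_sizes(self) -> dict[str, int]:
        return self.groups.value_counts().to_dict()


def read_suv_table(path, atlas: RegionAtlas) -> SUVTable:
    """Read a delimited SUV table, validating against the atlas.

    The file must have a header naming a subject column, a group column, and
    one column per atlas abbreviation (any column order; comma or tab
    delimited, sniffed). Column order is coerced to atlas region order.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") > header.count(",") else ","
    # round_trip parsing so write -> read -> write is bit-identical
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    cols = list(df.columns)
    if "subject" not in cols or "group" not in cols:
        raise ValueError(f"{path}: header must contain 'subject' and 'group' columns")
    missing = [a for a in atlas.abbreviations if a not in cols]
    if missing:
        raise ValueError(f"{path}: missing region columns: {missing}")
    groups = df["group"].astype(str)
    n_groups = groups.nunique()
    if n_groups > 2:
        raise ValueError(f"{path}: expected at most two group labels, got {sorted(groups.unique())}")
    values = df[atlas.abbreviations]
    for col in atlas.abbreviations:
        coerced = pd.to_numeric(values[col], errors="coerce")
        if coerced.isna().any():
            rows = df.loc[coerced.isna(), "subject"].tolist()
            raise ValueError(f"{path}: non-numeric SUV in column {col}, subjects {rows}")
    data = values.astype(float)
    data.index = df["subject"].astype(str)
    data.index.name = "subject"
    groups.index = data.index
    normalized = bool(np.allclose(data.mean(axis=1), 1.0, atol=1e-9))
    logger.info("read %d subjects x %d regions from %s; groups: %s",
                len(data), data.shape[1], path,
                groups.value_counts().to_dict())
    return SUVTable(data=data, groups=groups, normalized=normalized, atlas=atlas)


def write_suv_table(table: SUVTable, path, sep: str = ",") -> None:
    """Write a SUV table; read_suv_table(write_suv_table(t)) round-trips
    bit-identically at the stored decimal precision (full repr)."""
    out = table.data.copy()
    out.insert(0, "group", table.groups)
    out.insert(0, "subject", out.index)
    out.to_csv(path, sep=sep, index=False)


def extract_region_means(uptake_volume, label_volume, atlas: RegionAtlas) -> np.ndarray:
    """Per-region arithmetic mean of uptake over voxels carrying each label.

    Voxels labeled 0 (background) are ignored. Every atlas id must be
    present in the label volume.
    """
    uptake = np.asarray(uptake_volume, dtype=float)
    labels = np.asarray(label_volume)
    if uptake.shape != labels.shape:
        raise ValueError(f"shape mismatch: uptake {uptake.shape} vs labels {labels.shape}")
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError("label volume must be integer-typed")
    present = np.unique(labels)
    ids = atlas.region_ids
    absent = sorted(set(ids.tolist()) - set(present.tolist()))
    if absent:
        raise ValueError(f"atlas ids absent from label volume: {absent}")
    return np.asarray(ndimage.mean(uptake, labels=labels, index=ids), dtype=float)


def region_means_from_nifti(uptake_path, label_path, atlas: RegionAtlas) -> np.ndarray:
    """Load NIfTI-1 uptake and label volumes and extract region means."""
    import nibabel as nib

    up = nib.load(str(uptake_path))
    lab = nib.load(str(label_path))
    if up.shape != lab.shape:
        raise ValueError(f"volume shapes differ: {up.shape} vs {lab.shape}")
    labels = np.asanyarray(lab.dataobj)
    if not np.issubdtype(labels.dtype, np.integer):
        rounded = np.rint(labels)
        if not np.allclose(labels, rounded):
            raise ValueError("label volume is not integer-valued")
        labels = rounded.astype(np.int32)
    return extract_region_means(np.asanyarray(up.dataobj, dtype=float), labels, atlas)


def normalize_global(values: np.ndarray) -> np.ndarray:
    """Divide each regional value by the whole-brain mean (mean of all
    regions), so the normalized values average to 1.

    At the region level the union of atlas regions is the closest available
    proxy for the whole brain; image-driven runs may instead normalize by a
    voxelwise brain-mask mean before extraction.
    """
    values = np.asarray(values, dtype=float)
    m = values.mean()
    if not m > 0:
        raise ValueError(f"whole-brain mean must be positive, got {m}")
    return values / m


def normalize_table(table: SUVTable) -> SUVTable:
    """Apply global-mean normalization per subject. Idempotent."""
    means = table.data.mean(axis=1)
    if (means <= 0).any():
        bad = table.data.index[means <= 0].tolist()
        raise ValueError(f"non-positive whole-brain mean for subjects {bad}")
    return replace(table, data=table.data.div(means, axis=0), normalized=True)
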