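"""Region-level FDG-PET feature tables.

A feature table holds one row per subject: a unique subject identifier, a
diagnostic label (e.g. ``AD``, ``bvFTD``, ``PPA``, ``HC``), and the mean
normalized tracer uptake for each region of a brain parcellation. The default
parcellation is the 116-region Automatic Anatomical Labeling (AAL) atlas, one
mean-uptake feature per region. Uptake values are assumed to be intensity
normalized upstream (global mean scaling during image preprocessing); no
rescaling is applied here, though per-feature z-scoring is available as an
explicit option.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, TableParseError

__all__ = [
    "RegionAtlas",
    "FeatureTable",
    "aal116_atlas",
    "read_feature_table",
    "write_feature_table",
    "select_task",
    "combination_count",
    "zscore_features",
]


@dataclass(frozen=True)
class RegionAtlas:
    """An ordered, named brain parcellation; region names are the public identity
    of features (indices are internal only)."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) < 1:
            raise ValueError("atlas must contain at least one region")
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if list(self.names).count(n) > 1})
            raise ValueError(f"duplicate region names in atlas: {dupes}")

    @property
    def size(self) -> int:
        return len(self.names)

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"region {name!r} not in atlas") from None


def aal116_atlas() -> RegionAtlas:
    """The packaged AAL atlas with its 116 region names."""
    text = resources.files("gafs.data").joinpath("aal116.txt").read_text(encoding="utf-8")
    return RegionAtlas(tuple(line.strip() for line in text.splitlines() if line.strip()))


@dataclass
class FeatureTable:
    """Subjects x regions uptake matrix with diagnostic labels.

    Invariants: subject_ids unique, len(subject_ids) == len(labels) == values.shape[0],
    values.shape[1] == atlas.size, no missing values.
    """

    subject_ids: list[str]
    labels: list[str]
    values: np.ndarray
    atlas: RegionAtlas = field(default_factory=aal116_atlas)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        m, n = self.values.shape
        if not (len(self.subject_ids) == len(self.labels) == m):
            raise ValueError(
                f"inconsistent row counts: {len(self.subject_ids)} ids, "
                f"{len(self.labels)} labels, {m} value rows"
            )
        if n != self.atlas.size:
            raise ValueError(f"{n} value columns but atlas has {self.atlas.size} regions")
        if len(set(self.subject_ids)) != m:
            raise FormatError("duplicate subject_id values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain NaN or infinities")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def label_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for lab in self.labels:
            counts[lab] = counts.get(lab, 0) + 1
        return counts

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.atlas.names))
        df.insert(0, "label", self.labels)
        df.insert(0, "subject_id", self.subject_ids)
        return df


def read_feature_table(path: str | Path, delimiter: str = ",") -> FeatureTable:
    """Read a feature table from a delimited text file.

    Expected header: ``subject_id,label,<region_1>,...,<region_N>``; every
    uptake cell must be numeric and non-missing. Region column order from the
    header is preserved and becomes the table's atlas.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        header = next(csv.reader(fh, delimiter=delimiter), None)
    if header is None or len(header) < 3 or header[0] != "subject_id" or header[1] != "label":
        raise FormatError(
            f"{path}: header must start with 'subject_id,label' followed by region names"
        )
    region_names = header[2:]
    seen: set[str] = set()
    for name in region_names:
        if name in seen:
            raise FormatError(f"{path}: duplicate region column {name!r}")
        seen.add(name)

    df = pd.read_csv(
        path,
        sep=delimiter,
        header=0,
        dtype={"subject_id": str, "label": str},
        float_precision="round_trip",
    )
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise FormatError(f"{path}: duplicate subject_id {dupes}")

    raw = df[region_names]
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        row_idx, col_idx = np.argwhere(bad.to_numpy())[0]
        sid = df["subject_id"].iloc[row_idx]
        col = region_names[col_idx]
        cell = raw.iloc[row_idx, col_idx]
        raise TableParseError(
            f"{path}: non-numeric or missing uptake value {cell!r} "
            f"at subject {sid!r}, region {col!r}"
        )
    return FeatureTable(
        subject_ids=df["subject_id"].tolist(),
        labels=df["label"].tolist(),
        values=numeric.to_numpy(dtype=float),
        atlas=RegionAtlas(tuple(region_names)),
    )


def write_feature_table(table: FeatureTable, path: str | Path, delimiter: str = ",") -> None:
    """Write a table in the standard dialect; round-trips through
    :func:`read_feature_table` at full float precision."""
    # shortest decimal that round-trips each float exactly
    table.to_dataframe().to_csv(
        path, sep=delimiter, index=False, float_format=lambda x: repr(float(x))
    )


def select_task(table: FeatureTable, included_labels: Iterable[str]) -> FeatureTable:
    """Restrict a cohort to the diagnostic groups of one classification task.

    Row order and the atlas are preserved; labels are never renamed.
    """
    included = set(included_labels)
    present = set(table.labels)
    missing = included - present
    if missing:
        raise ValueError(f"labels not present in table: {sorted(missing)}")
    keep = [i for i, lab in enumerate(table.labels) if lab in included]
    return FeatureTable(
        subject_ids=[table.subject_ids[i] for i in keep],
        labels=[table.labels[i] for i in keep],
        values=table.values[keep],
        atlas=table.atlas,
    )


def combination_count(n: int) -> int:
    """Number of non-empty feature subsets of an n-feature pool.

    Sum over r = 1..n of C(n, r), which collapses to 2**n - 1; evaluated as an
    exact arbitrary-precision integer. This is the size of the search space an
    exhaustive wrapper would have to test, and the reason a stochastic search
    is used instead.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return sum(math.comb(n, r) for r in range(1, n + 1))


def zscore_features(table: FeatureTable) -> FeatureTable:
    """Optional per-feature standardization (mean 0, sd 1 across subjects).

    Off by default throughout the package; provided for cohorts whose uptake
    scaling differs from the global-mean normalization assumed upstream.
    """
    mu = table.values.mean(axis=0)
    sd = table.values.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return FeatureTable(
        subject_ids=list(table.subject_ids),
        labels=list(table.labels),
        values=(table.values - mu) / sd,
        atlas=table.atlas,
    )
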