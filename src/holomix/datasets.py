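"""Reading, validating, harmonizing and writing omics matrices and metadata.

An omics table is a samples x features numeric matrix with unique string ids
on both axes. Metadata maps every sample to a class label and, optionally,
every class to a hex color used in plots and network exports.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Upload size above which a warning is logged (deployment-style limit, not
#: an algorithmic one -- nothing is rejected).
SIZE_WARN_BYTES = 50 * 1024 * 1024

_HEX_COLOR = re.compile(r"^#?[0-9a-fA-F]{6}$")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class OmicsDataset:
    """One named samples x features block of continuous (or raw count) data.

    Parameters
    ----------
    name : str
        Block identifier, e.g. ``"16S"`` or ``"transcriptomics"``.
    values : pandas.DataFrame
        Numeric matrix, index = sample ids, columns = feature ids.
    is_microbiome : bool
        Marks raw amplicon (ASV/OTU) count blocks that must go through the
        compositional preprocessing before any model fit.
    provenance : list of dict
        Ordered records of every transform applied, ``{"operation": ...,
        "parameters": {...}}``.
    """

    name: str
    values: pd.DataFrame
    is_microbiome: bool = False
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = self.values.copy()
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)
        validate_dataset(self)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def with_values(self, values: pd.DataFrame, operation: str | None = None,
                    **parameters) -> "OmicsDataset":
        """Return a copy holding `values`, with `operation` appended to provenance."""
        prov = list(self.provenance)
        if operation is not None:
            prov.append({"operation": operation, "parameters": parameters})
        return OmicsDataset(name=self.name, values=values,
                            is_microbiome=self.is_microbiome, provenance=prov)

    def subset_features(self, feature_ids, operation: str | None = None,
                        **parameters) -> "OmicsDataset":
        keep = [f for f in self.feature_ids if f in set(feature_ids)]
        return self.with_values(self.values[keep], operation=operation, **parameters)

    def equals(self, other: "OmicsDataset", atol: float = 1e-12) -> bool:
        return (self.sample_ids == other.sample_ids
                and self.feature_ids == other.feature_ids
                and np.allclose(self.matrix(), other.matrix(), atol=atol, rtol=0.0))


@dataclass
class MetadataTable:
    """Sample -> class mapping with an optional class -> hex color scheme."""

    sample_to_class: dict
    class_to_color: dict | None = None

    def __post_init__(self) -> None:
        classes = set(self.sample_to_class.values())
        if not classes:
            raise ValidationError("metadata holds no samples")
        if self.class_to_color is not None:
            for cls, color in self.class_to_color.items():
                if not _HEX_COLOR.match(str(color)):
                    raise ValidationError(
                        f"class {cls!r} has malformed color {color!r} "
                        "(expected 6 hex digits)")

    def classes(self) -> list[str]:
        return sorted(set(self.sample_to_class.values()))

    def labels_for(self, sample_ids) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.sample_to_class]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing}")
        return np.array([self.sample_to_class[s] for s in sample_ids], dtype=object)


def validate_dataset(ds: OmicsDataset) -> None:
    dup_s = ds.values.index[ds.values.index.duplicated()].unique().tolist()
    if dup_s:
        raise ValidationError(f"duplicate sample ids: {dup_s}")
    dup_f = ds.values.columns[ds.values.columns.duplicated()].unique().tolist()
    if dup_f:
        raise ValidationError(f"duplicate feature ids: {dup_f}")
    try:
        mat = ds.values.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric value in dataset {ds.name!r}: {exc}") from exc
    bad = np.argwhere(~np.isfinite(mat))
    if bad.size:
        i, j = bad[0]
        raise ValidationError(
            f"dataset {ds.name!r} has a missing/non-finite value at sample "
            f"{ds.values.index[i]!r}, feature {ds.values.columns[j]!r} "
            f"({bad.shape[0]} such cells); impute upstream before loading")


def _sniff_sep(path: str, sep: str | None) -> str:
    if sep is not None:
        return sep
    p = str(path).lower()
    return "," if p.endswith(".csv") else "\t"


def read_omics_table(path, name: str, is_microbiome: bool = False,
                     transpose: bool = False, sep: str | None = None) -> OmicsDataset:
    """Read a CSV/TSV matrix into a validated :class:`OmicsDataset`.

    The first column holds sample ids (feature ids when ``transpose`` is set,
    for tables stored features x samples); the header row holds the other
    axis. Delimiter is sniffed from the extension (.csv -> comma, otherwise
    tab) unless ``sep`` is given.
    """
    import os
    try:
        size = os.path.getsize(path)
        if size > SIZE_WARN_BYTES:
            logger.warning("%s is %.1f Mb (> 50 Mb); large uploads are slow "
                           "but not rejected", path, size / 1e6)
    except OSError:
        pass
    df = pd.read_csv(path, sep=_sniff_sep(path, sep), index_col=0, dtype=str)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if transpose:
        df = df.T
    # locate non-numeric cells before the bulk cast so errors carry positions
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"non-numeric cell {df.iat[i, j]!r} at sample {df.index[i]!r}, "
            f"feature {df.columns[j]!r} in {path}")
    return OmicsDataset(name=name, values=numeric.astype(float),
                        is_microbiome=is_microbiome,
                        provenance=[{"operation": "read",
                                     "parameters": {"path": str(path),
                                                    "transpose": transpose}}])


def read_metadata(path, sep: str | None = None) -> MetadataTable:
    """Read a metadata CSV with columns ``sample,class[,color]``."""
    df = pd.read_csv(path, sep=_sniff_sep(path, sep), dtype=str)
    if df.shape[1] < 2:
        raise ValidationError("metadata needs at least sample and class columns")
    samples = df.iloc[:, 0].astype(str).str.strip()
    dup = samples[samples.duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"samples listed twice in metadata: {dup}")
    classes = df.iloc[:, 1].astype(str).str.strip()
    sample_to_class = dict(zip(samples, classes))
    class_to_color = None
    if df.shape[1] >= 3:
        colors = df.iloc[:, 2]
        class_to_color = {}
        for cls, color in zip(classes, colors):
            if pd.isna(color):
                continue
            class_to_color[cls] = str(color).strip()
        if not class_to_color:
            class_to_color = None
    return MetadataTable(sample_to_class=sample_to_class,
                         class_to_color=class_to_color)


def harmonize(datasets: list[OmicsDataset],
              metadata: MetadataTable) -> list[OmicsDataset]:
    """Restrict all blocks to their common samples, in a common sorted order.

    Samples are kept only if present in every block *and* in the metadata;
    rows are reordered ascending lexicographically so cross-validation fold
    assignment downstream is reproducible. Idempotent.
    """
    if not datasets:
        raise ValidationError("harmonize needs at least one dataset")
    common = set(metadata.sample_to_class)
    for ds in datasets:
        common &= set(ds.sample_ids)
    if not common:
        counts = {ds.name: ds.n_samples for ds in datasets}
        counts["metadata"] = len(metadata.sample_to_class)
        raise ValidationError(f"no samples shared by all inputs; sizes: {counts}")
    order = sorted(common)
    out = []
    for ds in datasets:
        if ds.sample_ids == order:
            out.append(ds)
        else:
            out.append(ds.with_values(ds.values.loc[order], operation="harmonize",
                                      n_samples=len(order)))
    return out


def write_table(ds: OmicsDataset, path, sep: str | None = None) -> None:
    """Write samples x features CSV that round-trips through :func:`read_omics_table`."""
    if ds.n_features == 0:
        raise ValidationError(f"dataset {ds.name!r} has no features to write")
    ds.values.to_csv(path, sep=_sniff_sep(path, sep), index_label="sample")
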