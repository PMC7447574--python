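"""Omics matrix I/O and preprocessing.

Handles the tabular formats used throughout the package (delimited text,
samples as rows by default) and the preprocessing pipeline applied before
dimensionality reduction: missingness filtering, median imputation,
gene-level CNV averaging, min-max scaling to [-1, 1] (the autoencoder uses
tanh activations on every layer, so reconstruction targets must lie in
tanh's range), and block concatenation with sample alignment.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, DegenerateInputError, FormatError

__all__ = [
    "OmicsMatrix",
    "MultiOmicsDataset",
    "FeatureScaler",
    "read_matrix",
    "write_matrix",
    "read_clinical",
    "write_clinical",
    "read_cnv_segments",
    "average_cnv_per_gene",
    "filter_missing",
    "impute_median",
    "scale_features",
    "assemble",
    "preprocess_blocks",
]


@dataclass
class OmicsMatrix:
    """One omics block: samples x features, NaN marks a missing value.

    ``data`` is indexed by sample ID with feature names as columns; both
    must be unique.
    """

    name: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate sample ID {dup!r} in block {self.name!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate feature name {dup!r} in block {self.name!r}")
        self.data = self.data.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def missing_fraction(self) -> float:
        return float(self.data.isna().to_numpy().mean()) if self.data.size else 0.0

    def equals(self, other: "OmicsMatrix", tol: float = 1e-9) -> bool:
        if self.sample_ids != other.sample_ids or self.feature_names != other.feature_names:
            return False
        a, b = self.values, other.values
        both_nan = np.isnan(a) & np.isnan(b)
        close = np.isclose(a, b, rtol=0.0, atol=tol)
        return bool(np.all(both_nan | close))


@dataclass
class MultiOmicsDataset:
    """Row-aligned omics blocks plus the per-sample clinical table.

    ``clinical`` is indexed by sample ID with columns ``time`` (follow-up,
    non-negative) and ``event`` (1 = death/event observed, 0 = censored),
    covering every sample exactly once.
    """

    blocks: list[OmicsMatrix]
    clinical: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.blocks:
            raise DegenerateInputError("dataset needs at least one omics block")
        ids = self.blocks[0].sample_ids
        for b in self.blocks:
            if b.sample_ids != ids:
                raise AlignmentError(
                    f"block {b.name!r} rows not aligned with block "
                    f"{self.blocks[0].name!r}; call assemble() first"
                )
        if list(self.clinical.index) != ids:
            raise AlignmentError("clinical table not aligned with omics blocks")
        if self.clinical.index.has_duplicates:
            raise FormatError("duplicate sample ID in clinical table")
        for col in ("time", "event"):
            if col not in self.clinical.columns:
                raise FormatError(f"clinical table missing column {col!r}")

    @property
    def sample_ids(self) -> list[str]:
        return self.blocks[0].sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def concat_feature_names(self) -> list[str]:
        return [f"{b.name}:{f}" for b in self.blocks for f in b.feature_names]

    @property
    def X(self) -> pd.DataFrame:
        """Concatenated feature matrix with block-prefixed column names."""
        frames = [
            b.data.set_axis([f"{b.name}:{f}" for f in b.feature_names], axis=1)
            for b in self.blocks
        ]
        return pd.concat(frames, axis=1)

    def block(self, name: str) -> OmicsMatrix:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(f"no omics block named {name!r}")


def _detect_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    with open(path, newline="") as fh:
        sample = fh.read(65536)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_matrix(
    path: str | Path,
    name: str | None = None,
    orientation: str = "samples",
    sep: str | None = None,
) -> OmicsMatrix:
    """Read a delimited matrix file into an :class:`OmicsMatrix`.

    Parameters
    ----------
    orientation
        ``"samples"`` (default): rows are samples, columns features.
        ``"features"``: rows are features (the TCGA convention); the matrix
        is transposed on load.
    sep
        Field delimiter; auto-detected when omitted.
    """
    path = Path(path)
    if orientation not in ("samples", "features"):
        raise FormatError(f"orientation must be 'samples' or 'features', got {orientation!r}")
    delim = _detect_sep(path, sep)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=delim))
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = rows[0]
    width = len(header)
    ids, records = [], []
    for lineno, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        if len(row) != width:
            raise FormatError(
                f"{path}: line {lineno} has {len(row)} fields, expected {width}"
            )
        ids.append(row[0])
        try:
            records.append([float(v) if v not in ("", "NA", "NaN", "nan") else np.nan for v in row[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    df = pd.DataFrame(records, index=ids, columns=header[1:], dtype=float)
    if orientation == "features":
        df = df.T
    return OmicsMatrix(name=name or path.stem, data=df)


def write_matrix(m: OmicsMatrix, path: str | Path, orientation: str = "samples", sep: str = ",") -> None:
    df = m.data if orientation == "samples" else m.data.T
    label = "sample_id" if orientation == "samples" else "feature"
    df.to_csv(path, sep=sep, index_label=label, float_format="%.12g")


def read_clinical(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a clinical table (columns: sample_id, time, event) indexed by sample."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path, sep))
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise FormatError(f"{path}: clinical table missing column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"{path}: duplicate sample ID {dup!r}")
    out = df.set_index("sample_id")[["time", "event"]]
    out["time"] = out["time"].astype(float)
    out["event"] = out["event"].astype(int)
    if (out["time"] < 0).any():
        raise FormatError(f"{path}: negative survival time")
    if not out["event"].isin([0, 1]).all():
        raise FormatError(f"{path}: event indicator must be 0/1")
    return out


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, index_label="sample_id")


def read_cnv_segments(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a CNV segment table with columns sample_id, gene_id, copy_number."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path, sep))
    for col in ("sample_id", "gene_id", "copy_number"):
        if col not in df.columns:
            raise FormatError(f"{path}: CNV table missing column {col!r}")
    if df.empty:
        raise DegenerateInputError(f"{path}: empty CNV segment table")
    return df


def average_cnv_per_gene(segments: pd.DataFrame, name: str = "cnv") -> OmicsMatrix:
    """Collapse per-variation copy numbers to one gene-level value per sample.

    Each (sample, gene) cell is the arithmetic mean of all copy-number records
    for that gene in that sample; pairs with no record are missing.
    """
    if segments.empty:
        raise DegenerateInputError("empty CNV segment table")
    wide = segments.pivot_table(
        index="sample_id", columns="gene_id", values="copy_number", aggfunc="mean"
    )
    wide.index.name = None
    wide.columns.name = None
    return OmicsMatrix(name=name, data=wide)


def filter_missing(m: OmicsMatrix, threshold: float = 0.2) -> OmicsMatrix:
    """Drop features, then samples, whose missing fraction exceeds ``threshold``.

    A feature (sample) is removed only when its missing fraction is strictly
    greater than the threshold; at exactly the threshold it is kept. The
    sample pass is computed on the surviving features. Row and column order
    are preserved.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    df = m.data
    feat_frac = df.isna().mean(axis=0)
    keep_feats = feat_frac[feat_frac <= threshold].index
    if len(keep_feats) == 0:
        raise DegenerateInputError(
            f"missingness filter removed every feature of block {m.name!r}"
        )
    df = df[keep_feats]
    samp_frac = df.isna().mean(axis=1)
    df = df.loc[samp_frac <= threshold]
    if df.shape[0] == 0:
        raise DegenerateInputError(
            f"missingness filter removed every sample of block {m.name!r}"
        )
    return OmicsMatrix(name=m.name, data=df.copy())


def impute_median(m: OmicsMatrix) -> OmicsMatrix:
    """Replace each missing cell with the median of its feature's observed values.

    Even observed counts take the midpoint of the two central values (the
    standard median). A fully missing feature is an error — it should have
    been removed by :func:`filter_missing`.
    """
    df = m.data
    all_missing = df.columns[df.isna().all(axis=0)]
    if len(all_missing):
        raise DegenerateInputError(
            f"block {m.name!r}: feature(s) with no observed values: "
            f"{list(all_missing)[:5]}"
        )
    return OmicsMatrix(name=m.name, data=df.fillna(df.median(axis=0)))


@dataclass
class FeatureScaler:
    """Per-feature min-max parameters mapping training data into [-1, 1].

    Constant features map to 0. The stored parameters are reused to scale
    new cohorts into the training cohort's range and to invert the mapping.
    """

    mins: pd.Series
    maxs: pd.Series

    @property
    def ranges(self) -> pd.Series:
        return self.maxs - self.mins

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        df = df[self.mins.index]
        rng = self.ranges.replace(0.0, np.nan)
        out = 2.0 * (df - self.mins) / rng - 1.0
        return out.fillna(0.0)

    def inverse(self, df: pd.DataFrame) -> pd.DataFrame:
        return (df + 1.0) / 2.0 * self.ranges + self.mins


def scale_features(m: OmicsMatrix) -> tuple[OmicsMatrix, FeatureScaler]:
    """Min-max scale each feature to [-1, 1]; constant features map to 0."""
    if m.data.isna().any().any():
        raise DegenerateInputError(
            f"block {m.name!r} has missing values; impute before scaling"
        )
    scaler = FeatureScaler(mins=m.data.min(axis=0), maxs=m.data.max(axis=0))
    return OmicsMatrix(name=m.name, data=scaler.transform(m.data)), scaler


def assemble(blocks: Sequence[OmicsMatrix], clinical: pd.DataFrame) -> MultiOmicsDataset:
    """Align omics blocks and clinical data on their common samples.

    Sample IDs are intersected across all blocks and the clinical table and
    ordered by sorted ID, so the result is independent of input row order.
    Feature columns keep their within-block order and are block-prefixed in
    the concatenated view.
    """
    common: set[str] = set(blocks[0].sample_ids)
    for b in blocks[1:]:
        common &= set(b.sample_ids)
    common &= set(clinical.index)
    if not common:
        counts = ", ".join(f"{b.name}={b.n_samples}" for b in blocks)
        raise AlignmentError(
            f"no common samples across blocks and clinical table ({counts}, "
            f"clinical={len(clinical)})"
        )
    order = sorted(common)
    aligned = [OmicsMatrix(name=b.name, data=b.data.loc[order].copy()) for b in blocks]
    return MultiOmicsDataset(blocks=aligned, clinical=clinical.loc[order].copy())


def preprocess_blocks(
    blocks: Iterable[OmicsMatrix],
    clinical: pd.DataFrame,
    missing_threshold: float = 0.2,
) -> tuple[MultiOmicsDataset, dict[str, FeatureScaler]]:
    """Per-block filter -> impute -> scale, then assemble.

    The missingness filter is applied per omics block before assembly, and
    the fitted scaling parameters are returned per block so external cohorts
    can be mapped into the same range.
    """
    scaled, scalers = [], {}
    for b in blocks:
        b = filter_missing(b, missing_threshold)
        b = impute_median(b)
        b, scaler = scale_features(b)
        scaled.append(b)
        scalers[b.name] = scaler
    return assemble(scaled, clinical), scalers
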