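"""Domain types and tabular I/O for parcel-level multispectral time series.

A *sample* is one agricultural parcel: a ``T_raw x B`` matrix of
mean-aggregated reflectances (one row per acquisition date, one column per
spectral band), a categorical region code and an integer crop-class label.
Datasets live on disk as a wide table (CSV or Parquet; one row per parcel,
one column per band x timestep cell) next to a JSON sidecar that declares
the dialect: band count, class count, class names and the reflectance
scale divisor.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesSample",
    "StandardizedSample",
    "DatasetSplit",
    "DatasetDialect",
    "read_dataset",
    "write_dataset",
    "standardize",
    "split_by_region",
    "stack_series",
]

#: canonical number of timesteps after standardization
DEFAULT_T = 45
#: canonical number of Sentinel-2 bands
DEFAULT_B = 13

SIDECAR_NAME = "metadata.json"
TABLE_STEM = "samples"


@dataclass
class TimeSeriesSample:
    """One parcel: raw (variable-length) reflectance time series with metadata.

    Attributes
    ----------
    parcel_id : str
        Opaque parcel identifier, unique within a dataset.
    region : str
        Categorical region code (e.g. one of four sub-region labels).
    label : int
        0-based crop-class index, ``0 <= label < n_classes``.
    series : ndarray of shape (T_raw, B)
        Non-negative, finite reflectances; band order is the file's
        column order and is never reordered.
    """

    parcel_id: str
    region: str
    label: int
    series: np.ndarray

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=np.float64)
        if self.series.ndim != 2 or self.series.shape[0] < 1:
            raise ValueError(
                f"sample {self.parcel_id!r}: series must be a non-empty "
                f"T x B matrix, got shape {self.series.shape}"
            )
        if not np.all(np.isfinite(self.series)):
            raise ValueError(
                f"sample {self.parcel_id!r}: series contains non-finite values"
            )
        if self.label < 0:
            raise ValueError(f"sample {self.parcel_id!r}: negative label {self.label}")

    @property
    def length(self) -> int:
        return self.series.shape[0]

    @property
    def n_bands(self) -> int:
        return self.series.shape[1]


@dataclass
class StandardizedSample:
    """A sample resampled/padded to a fixed temporal length ``T``.

    ``mask`` holds 1 at observed timesteps and 0 at zero-padded ones; it has
    exactly ``min(T_raw, T)`` ones.
    """

    parcel_id: str
    region: str
    label: int
    series: np.ndarray  # (T, B)
    mask: np.ndarray  # (T,) uint8

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        if self.series.ndim != 2 or self.mask.shape != (self.series.shape[0],):
            raise ValueError("series must be (T, B) with a length-T mask")


@dataclass
class DatasetSplit:
    """Region-based train/validation/test partition of standardized samples."""

    train: list[StandardizedSample]
    validation: list[StandardizedSample]
    test: list[StandardizedSample]
    class_count: int
    split_rule: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.parcel_id for part in (self.train, self.validation, self.test) for s in part]
        if len(ids) != len(set(ids)):
            raise ValueError("splits are not disjoint by parcel_id")
        train_classes = {s.label for s in self.train}
        missing = set(range(self.class_count)) - train_classes
        if missing:
            raise ValueError(
                f"classes {sorted(missing)} absent from the training split; "
                "class weights would be undefined"
            )


@dataclass
class DatasetDialect:
    """Declared file-format parameters; stored as the JSON sidecar.

    ``scale_divisor`` is applied on read (values are divided) and inverted on
    write; 10000 maps Sentinel-2 L1C digital numbers to reflectance, 1 leaves
    already-scaled data untouched. Scaling is always declared, never inferred.
    """

    n_classes: int = DEFAULT_B
    n_bands: int = DEFAULT_B
    layout: str = "wide"
    scale_divisor: float = 1.0
    class_names: list[str] | None = None
    region_names: list[str] | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "DatasetDialect":
        data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in known})


def _band_col(b: int, t: int) -> str:
    return f"b{b:02d}_t{t:03d}"


def _resolve_paths(path: str | Path) -> tuple[Path, Path]:
    """Return (table_path, sidecar_path) from a directory or a table file."""
    path = Path(path)
    if path.is_dir():
        for ext in (".csv", ".parquet"):
            cand = path / f"{TABLE_STEM}{ext}"
            if cand.exists():
                return cand, path / SIDECAR_NAME
        raise FileNotFoundError(f"no {TABLE_STEM}.csv/.parquet under {path}")
    return path, path.parent / SIDECAR_NAME


def read_dataset(
    path: str | Path, dialect: DatasetDialect | None = None
) -> list[TimeSeriesSample]:
    """Read a wide-layout tabular dataset into a list of samples.

    Parameters
    ----------
    path : directory containing ``samples.csv``/``samples.parquet`` plus
        ``metadata.json``, or the table file itself.
    dialect : optional explicit dialect; when omitted the JSON sidecar next
        to the table is loaded.

    Raises
    ------
    ValueError
        On a missing required column (named in the message), a non-numeric
        reflectance (row index in the message), or an out-of-range label.
    """
    table_path, sidecar_path = _resolve_paths(path)
    if dialect is None:
        if not sidecar_path.exists():
            raise FileNotFoundError(f"no dialect given and no sidecar at {sidecar_path}")
        dialect = DatasetDialect.from_json(sidecar_path.read_text())
    if dialect.layout != "wide":
        raise ValueError(f"unsupported layout {dialect.layout!r}")

    if table_path.suffix == ".parquet":
        df = pd.read_parquet(table_path)
    else:
        # round_trip parsing so write -> read is bit-exact
        df = pd.read_csv(table_path, float_precision="round_trip")

    for col in ("parcel_id", "region", "label", "length"):
        if col not in df.columns:
            raise ValueError(f"format error: required column {col!r} is missing")

    band_cols = [c for c in df.columns if c.startswith("b") and "_t" in c]
    if not band_cols:
        raise ValueError("format error: no band x timestep columns (b##_t###) found")
    t_max = 1 + max(int(c.split("_t")[1]) for c in band_cols)
    b_seen = 1 + max(int(c.split("_t")[0][1:]) for c in band_cols)
    if b_seen != dialect.n_bands:
        raise ValueError(
            f"format error: file has {b_seen} bands, dialect declares {dialect.n_bands}"
        )

    ordered = [[_band_col(b, t) for b in range(dialect.n_bands)] for t in range(t_max)]
    flat_cols = [c for row in ordered for c in row]
    missing = [c for c in flat_cols if c not in df.columns]
    if missing:
        raise ValueError(f"format error: required column {missing[0]!r} is missing")

    values = df[flat_cols].to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = df[flat_cols].apply(pd.to_numeric, errors="coerce")
        bad_rows = np.where(bad.isna().to_numpy() & df[flat_cols].notna().to_numpy())[0]
        row = int(bad_rows[0]) if len(bad_rows) else -1
        raise ValueError(f"parse error: non-numeric reflectance at row {row}")

    samples: list[TimeSeriesSample] = []
    for i in range(len(df)):
        length = int(df["length"].iloc[i])
        label = int(df["label"].iloc[i])
        if not 0 <= label < dialect.n_classes:
            raise ValueError(
                f"row {i}: label {label} outside [0, {dialect.n_classes})"
            )
        series = values[i].reshape(t_max, dialect.n_bands)[:length]
        if np.isnan(series).any():
            raise ValueError(f"parse error: missing reflectance inside row {i}")
        samples.append(
            TimeSeriesSample(
                parcel_id=str(df["parcel_id"].iloc[i]),
                region=str(df["region"].iloc[i]),
                label=label,
                series=series / dialect.scale_divisor,
            )
        )
    return samples


def write_dataset(
    samples: Sequence[TimeSeriesSample],
    path: str | Path,
    dialect: DatasetDialect,
    fmt: str = "csv",
) -> Path:
    """Write samples as a wide table plus JSON sidecar; returns the directory.

    Rows shorter than the longest sequence are right-filled with empty cells;
    the ``length`` column preserves the raw length. Values are multiplied by
    ``scale_divisor`` so the file stays in its declared on-disk units.
    """
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    B = dialect.n_bands
    for s in samples:
        if s.n_bands != B:
            raise ValueError(
                f"sample {s.parcel_id!r} has {s.n_bands} bands, dialect declares {B}"
            )
    t_max = max(s.length for s in samples)
    cols = [_band_col(b, t) for t in range(t_max) for b in range(B)]
    mat = np.full((len(samples), t_max * B), np.nan)
    for i, s in enumerate(samples):
        mat[i, : s.length * B] = (s.series * dialect.scale_divisor).ravel()
    df = pd.DataFrame(mat, columns=cols)
    df.insert(0, "length", [s.length for s in samples])
    df.insert(0, "label", [s.label for s in samples])
    df.insert(0, "region", [s.region for s in samples])
    df.insert(0, "parcel_id", [s.parcel_id for s in samples])

    if fmt == "csv":
        df.to_csv(out / f"{TABLE_STEM}.csv", index=False)
    elif fmt == "parquet":
        df.to_parquet(out / f"{TABLE_STEM}.parquet", index=False)
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    (out / SIDECAR_NAME).write_text(dialect.to_json())
    return out


def standardize(sample: TimeSeriesSample, T: int = DEFAULT_T) -> StandardizedSample:
    """Resample or pad a raw series to exactly ``T`` timesteps.

    For ``T_raw >= T`` the series is subsampled at evenly spaced indices
    ``round(linspace(0, T_raw-1, T))`` so the first and last observation are
    always kept; for ``T_raw < T`` it is right-padded with zero rows and the
    mask marks the padded steps. Deterministic, and the identity on series
    already of length ``T``.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    t_raw = sample.length
    if t_raw >= T:
        if T == 1:
            idx = np.array([0])
        else:
            # exact arithmetic (integer product before the division) so the
            # chosen indices equal round(i * (T_raw-1)/(T-1)) everywhere
            idx = np.rint(np.arange(T) * (t_raw - 1) / (T - 1)).astype(int)
        series = sample.series[idx]
        mask = np.ones(T, dtype=np.uint8)
    else:
        series = np.zeros((T, sample.n_bands))
        series[:t_raw] = sample.series
        mask = np.zeros(T, dtype=np.uint8)
        mask[:t_raw] = 1
    return StandardizedSample(
        parcel_id=sample.parcel_id,
        region=sample.region,
        label=sample.label,
        series=series,
        mask=mask,
    )


def split_by_region(
    samples: Sequence[TimeSeriesSample | StandardizedSample],
    rule: dict[str, str],
    class_count: int,
    T: int = DEFAULT_T,
) -> DatasetSplit:
    """Partition samples into train/validation/test by their region code.

    ``rule`` maps each region label to one of ``{"train", "val", "test"}``
    (``"validation"`` is accepted as an alias). Raw samples are standardized
    to length ``T`` on the way through.
    """
    alias = {"train": "train", "val": "val", "validation": "val", "test": "test"}
    norm_rule: dict[str, str] = {}
    for region, part in rule.items():
        if part not in alias:
            raise ValueError(f"split rule maps {region!r} to unknown part {part!r}")
        norm_rule[region] = alias[part]
    unknown = sorted({s.region for s in samples} - set(norm_rule))
    if unknown:
        raise ValueError(f"regions not covered by the split rule: {unknown}")

    parts: dict[str, list[StandardizedSample]] = {"train": [], "val": [], "test": []}
    for s in samples:
        std = s if isinstance(s, StandardizedSample) else standardize(s, T)
        parts[norm_rule[s.region]].append(std)
    return DatasetSplit(
        train=parts["train"],
        validation=parts["val"],
        test=parts["test"],
        class_count=class_count,
        split_rule=dict(rule),
    )


def stack_series(
    samples: Sequence[StandardizedSample], dtype=np.float64
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack standardized samples into ``(X, y, regions)`` arrays.

    X has shape (n, T, B); y is int64; regions is an object array of codes.
    """
    if not samples:
        raise ValueError("empty sample list")
    X = np.stack([s.series for s in samples]).astype(dtype)
    y = np.array([s.label for s in samples], dtype=np.int64)
    regions = np.array([s.region for s in samples], dtype=object)
    return X, y, regions
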