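"""Dataset manifests and feature-view matrices.

A *manifest* lists histopathology samples with a three-way raw category
(leukoplakia with dysplasia, leukoplakia without dysplasia, OSCC) that is
merged into a binary label: ``P`` (presence of dysplasia — the two dysplastic
categories plus OSCC) versus ``A`` (absence of dysplasia). A *feature view*
is an ``n x d`` numeric matrix of per-sample features tagged with a view name
and an ordered list of sample ids.

Both objects round-trip losslessly through plain delimited text so the
pipeline can run feature-first, without images.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Category",
    "Label",
    "Sample",
    "DatasetManifest",
    "ManifestSummary",
    "FeatureView",
    "InputError",
    "load_manifest",
    "write_manifest",
    "merge_labels",
    "summarize",
    "read_feature_view",
    "write_feature_view",
]


class InputError(ValueError):
    """Malformed or inconsistent input data."""


class Category(str, Enum):
    LEUKO_DYSPLASIA = "leukoplakia_with_dysplasia"
    LEUKO_NO_DYSPLASIA = "leukoplakia_without_dysplasia"
    OSCC = "oscc"


class Label(str, Enum):
    P = "P"  # presence of dysplasia
    A = "A"  # absence of dysplasia


# Case-insensitive category vocabulary. Keys are normalized (lower-case,
# separators collapsed to "_"); anything outside this table is an error
# rather than a silent drop, so a manifest stays auditable.
_CATEGORY_SYNONYMS = {
    "leukoplakia_with_dysplasia": Category.LEUKO_DYSPLASIA,
    "leuko_dysplasia": Category.LEUKO_DYSPLASIA,
    "leukoplakia_dysplasia": Category.LEUKO_DYSPLASIA,
    "with_dysplasia": Category.LEUKO_DYSPLASIA,
    "leukoplakia_without_dysplasia": Category.LEUKO_NO_DYSPLASIA,
    "leuko_no_dysplasia": Category.LEUKO_NO_DYSPLASIA,
    "leukoplakia_no_dysplasia": Category.LEUKO_NO_DYSPLASIA,
    "without_dysplasia": Category.LEUKO_NO_DYSPLASIA,
    "no_dysplasia": Category.LEUKO_NO_DYSPLASIA,
    "oscc": Category.OSCC,
}


def parse_category(raw: str) -> Category:
    """Map a raw category string onto the fixed vocabulary (case-insensitive)."""
    key = str(raw).strip().lower().replace("-", "_").replace(" ", "_")
    try:
        return _CATEGORY_SYNONYMS[key]
    except KeyError:
        raise InputError(
            f"unknown category {raw!r}; expected one of "
            f"{sorted(set(_CATEGORY_SYNONYMS))}"
        ) from None


@dataclass(frozen=True)
class Sample:
    sample_id: str
    category: Category
    image_path: Optional[str] = None
    label: Optional[Label] = None


@dataclass(frozen=True)
class DatasetManifest:
    """Ordered collection of samples; ids unique and non-empty."""

    samples: tuple[Sample, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for s in self.samples:
            if not s.sample_id:
                raise InputError("empty sample_id in manifest")
            if s.sample_id in seen:
                raise InputError(f"duplicate sample_id {s.sample_id!r}")
            seen.add(s.sample_id)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def labels(self) -> list[Optional[Label]]:
        return [s.label for s in self.samples]


@dataclass(frozen=True)
class ManifestSummary:
    """Class composition of a labeled manifest.

    Percentages are stored at full precision; integer rounding happens only
    through the ``*_rounded`` accessors at report time.
    """

    n_total: int
    n_P: int
    n_A: int

    @property
    def pct_P(self) -> float:
        return 100.0 * self.n_P / self.n_total if self.n_total else float("nan")

    @property
    def pct_A(self) -> float:
        return 100.0 * self.n_A / self.n_total if self.n_total else float("nan")

    @property
    def pct_P_rounded(self) -> int:
        return int(round(self.pct_P))

    @property
    def pct_A_rounded(self) -> int:
        return int(round(self.pct_A))

    @property
    def imbalance_ratio(self) -> Optional[float]:
        """n_P / n_A, or None when there are no absence samples."""
        if self.n_A == 0:
            return None
        return self.n_P / self.n_A

    @property
    def imbalance_ratio_rounded(self) -> Optional[int]:
        r = self.imbalance_ratio
        return None if r is None else int(round(r))


@dataclass(frozen=True)
class FeatureView:
    """An n-samples x d-features matrix aligned with ordered sample ids."""

    view_name: str
    sample_ids: tuple[str, ...]
    matrix: np.ndarray
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2:
            raise InputError(f"feature matrix must be 2-D, got shape {m.shape}")
        if m.shape[0] != len(self.sample_ids):
            raise InputError(
                f"row count {m.shape[0]} != number of sample ids "
                f"{len(self.sample_ids)}"
            )
        if m.shape[1] == 0:
            raise InputError("feature matrix must have at least one column")
        if not np.all(np.isfinite(m)):
            bad = int(np.argwhere(~np.isfinite(m))[0][0])
            raise InputError(f"non-finite feature value at row {bad}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise InputError("duplicate sample_ids in feature view")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


# ---------------------------------------------------------------------------
# manifest I/O


def load_manifest(path: str | Path) -> DatasetManifest:
    """Read a manifest CSV (``sample_id,image_path,category``; image_path
    optional). Labels are left unset; apply :func:`merge_labels` next.
    File row order is preserved."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"manifest file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"sample_id", "category"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"manifest missing required columns: {sorted(missing)}")
    samples = []
    for i, row in enumerate(df.itertuples(index=False)):
        sid = str(getattr(row, "sample_id")).strip()
        if not sid:
            raise InputError(f"empty sample_id at manifest row {i}")
        try:
            cat = parse_category(getattr(row, "category"))
        except InputError as e:
            raise InputError(f"row {i} (sample_id={sid!r}): {e}") from None
        img = getattr(row, "image_path", "") if "image_path" in df.columns else ""
        samples.append(Sample(sid, cat, image_path=img or None))
    return DatasetManifest(tuple(samples))


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "image_path", "category"])
        for s in manifest.samples:
            w.writerow([s.sample_id, s.image_path or "", s.category.value])


def merge_labels(manifest: DatasetManifest) -> DatasetManifest:
    """Merge the three raw categories into the binary dysplasia label.

    OSCC is folded into the presence class together with leukoplakia with
    dysplasia; only leukoplakia without dysplasia maps to absence.
    Idempotent and total over the category vocabulary.
    """
    merged = tuple(
        replace(
            s,
            label=Label.A if s.category is Category.LEUKO_NO_DYSPLASIA else Label.P,
        )
        for s in manifest.samples
    )
    return DatasetManifest(merged)


def summarize(manifest: DatasetManifest) -> ManifestSummary:
    """Count class composition of a labeled manifest."""
    labels = manifest.labels
    if any(l is None for l in labels):
        raise InputError("manifest has unset labels; call merge_labels first")
    n_p = sum(1 for l in labels if l is Label.P)
    n_a = len(labels) - n_p
    return ManifestSummary(n_total=len(labels), n_P=n_p, n_A=n_a)


# ---------------------------------------------------------------------------
# feature view I/O


def _detect_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_feature_view(path: str | Path, view_name: Optional[str] = None) -> FeatureView:
    """Read a delimited-text feature view.

    First column is ``sample_id``; remaining columns are numeric features.
    Tab or comma delimiter is auto-detected from the header line. A ragged
    row or non-numeric cell is an input error naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"feature view file not found: {path}")
    with open(path) as fh:
        header = fh.readline()
    delim = _detect_delimiter(header)
    try:
        df = pd.read_csv(path, sep=delim, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as e:
        raise InputError(f"malformed feature view {path}: {e}") from None
    if df.shape[1] < 2:
        raise InputError(f"feature view {path} has no feature columns")
    if df.columns[0] != "sample_id":
        raise InputError(
            f"feature view {path}: first column must be 'sample_id', "
            f"got {df.columns[0]!r}"
        )
    ids = tuple(df["sample_id"].astype(str))
    feat = df.iloc[:, 1:]
    numeric = feat.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy() & (feat.to_numpy() != "nan")
    if bad.any():
        r = int(np.argwhere(bad)[0][0])
        raise InputError(f"non-numeric cell in feature view {path} at data row {r}")
    # numpy's string->float conversion is correctly rounded (pandas' fast
    # parser can be off by one ulp, breaking bit-stable round-trips)
    matrix = feat.to_numpy().astype(np.float64)
    return FeatureView(
        view_name=view_name or path.stem, sample_ids=ids, matrix=matrix
    )


def write_feature_view(view: FeatureView, path: str | Path, delimiter: str = ",") -> None:
    """Write a feature view as delimited text at full float precision.

    Uses 17 significant digits so write-then-read reproduces the matrix
    bit-for-bit.
    """
    path = Path(path)
    header = ["sample_id"] + [f"f{j}" for j in range(view.n_features)]
    with open(path, "w", newline="") as fh:
        fh.write(delimiter.join(header) + "\n")
        for sid, row in zip(view.sample_ids, view.matrix):
            cells = [sid] + [format(v, ".17g") for v in row]
            fh.write(delimiter.join(cells) + "\n")
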