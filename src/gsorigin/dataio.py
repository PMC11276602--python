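"""Reading, writing and validation of expression matrices, sample metadata
and GMT gene-set collections.

All tabular formats are plain TSV (UTF-8).  An expression matrix has a header
row ``gene_id<TAB>sample1<TAB>sample2...`` and one row per gene symbol; an
enrichment matrix is identical except the first header field is ``gene_set``.
Sample metadata is a TSV with columns ``sample_id``, ``platform`` and
``origin_class`` (``origin_class`` may be empty for prediction-time input).
Gene sets use the MSigDB GMT dialect: one set per line,
``name<TAB>description<TAB>gene1<TAB>gene2...``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "OriginVocabulary",
    "read_expression",
    "read_metadata",
    "read_gmt",
    "write_gmt",
    "write_matrix",
    "read_enrichment",
]


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


def _check_sample_annotations(values: pd.DataFrame, platform: pd.Series, origin_class: pd.Series) -> None:
    if values.index.duplicated().any():
        dups = values.index[values.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate row labels: {dups[:5]}")
    if values.columns.duplicated().any():
        raise DataError("duplicate sample IDs")
    if values.shape[1] == 0:
        raise DataError("matrix has no samples")
    if values.shape[0] == 0:
        raise DataError("matrix has no rows")
    arr = values.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise DataError("non-numeric values in matrix")
    if not np.isfinite(arr).all():
        raise DataError("non-finite values in matrix")
    for name, series in (("platform", platform), ("origin_class", origin_class)):
        if not series.index.equals(values.columns):
            raise DataError(f"{name} annotation index does not match sample IDs")


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression with per-sample platform and origin labels.

    ``values`` is a genes x samples DataFrame of finite reals (units
    arbitrary: RSEM, normalized intensity, TPM).  ``origin_class`` entries may
    be ``None`` for unlabeled prediction input.
    """

    values: pd.DataFrame
    platform: pd.Series
    origin_class: pd.Series

    def __post_init__(self) -> None:
        self.values.index = self.values.index.astype(str).str.strip()
        _check_sample_annotations(self.values, self.platform, self.origin_class)

    @property
    def genes(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.values.columns.tolist()

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = list(samples)
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise DataError(f"unknown samples: {missing[:5]}")
        return ExpressionMatrix(
            values=self.values[samples].copy(),
            platform=self.platform[samples].copy(),
            origin_class=self.origin_class[samples].copy(),
        )


@dataclass
class GeneSetCollection:
    """Ordered, named gene sets with optional free-text descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise DataError(f"gene set {name!r} has no members")
            if len(set(members)) != len(members):
                self.sets[name] = list(dict.fromkeys(members))

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    @property
    def names(self) -> list[str]:
        return list(self.sets)


@dataclass(frozen=True)
class OriginVocabulary:
    """Fixed-order list of origin-class names; the axis for every probability
    vector and confusion matrix."""

    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.classes) == 0:
            raise DataError("empty vocabulary")
        if any(not c for c in self.classes):
            raise DataError("empty class name")
        if len(set(self.classes)) != len(self.classes):
            raise DataError("duplicate class names")

    def __len__(self) -> int:
        return len(self.classes)

    def index_of(self, cls: str) -> int:
        try:
            return self.classes.index(cls)
        except ValueError:
            raise DataError(f"class {cls!r} not in vocabulary") from None

    @classmethod
    def from_labels(cls, labels: Iterable[str]) -> "OriginVocabulary":
        seen = dict.fromkeys(str(l) for l in labels if l is not None and not pd.isna(l))
        return cls(tuple(sorted(seen)))


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "platform", "origin_class"}
    if not required.issubset(meta.columns):
        raise DataError(f"metadata must have columns {sorted(required)}, got {list(meta.columns)}")
    if meta["sample_id"].duplicated().any():
        raise DataError("duplicate sample_id in metadata")
    return meta.set_index("sample_id")


def read_expression(matrix_path: str | Path, metadata_path: str | Path) -> ExpressionMatrix:
    """Read a gene x sample TSV plus its metadata table.

    Samples present in the matrix but absent from metadata are an error
    ("unannotated sample").  Metadata rows for samples not in the matrix are
    ignored.  Duplicate gene rows are collapsed by keeping the row with the
    highest mean expression (the usual probe-to-symbol collapse rule).
    Joining is by sample ID, never by position.
    """
    values = _read_matrix_values(matrix_path, expect_first="gene_id")
    meta = read_metadata(metadata_path)
    missing = [s for s in values.columns if s not in meta.index]
    if missing:
        raise DataError(f"unannotated sample(s): {missing[:5]}")
    meta = meta.loc[values.columns]
    origin = meta["origin_class"]
    origin = origin.where(origin.notna() & (origin.str.strip() != ""), None)
    return ExpressionMatrix(values=values, platform=meta["platform"], origin_class=origin)


def _read_matrix_values(path: str | Path, expect_first: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise DataError(f"cannot parse matrix {path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise DataError(f"empty matrix in {path}")
    if df.index.name is None or df.index.name.strip() != expect_first:
        raise DataError(
            f"malformed header in {path}: first field must be {expect_first!r}, got {df.index.name!r}"
        )
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise DataError(f"non-numeric cell(s) in column(s) {non_numeric[:5]} of {path}")
    df.index = df.index.astype(str).str.strip()
    # collapse duplicate symbols: keep the row with the highest mean
    if df.index.duplicated().any():
        means = df.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        keep_first = df.iloc[order][~df.index[order].duplicated()]
        df = keep_first.loc[[g for g in dict.fromkeys(df.index)]]
    return df


def write_matrix(m, path: str | Path) -> None:
    """Write an ExpressionMatrix or EnrichmentMatrix as TSV.

    Round-trip contract: write then read yields identical labels and values
    to within 1e-12 (in practice bit-exact via repr-level float formatting).
    """
    if hasattr(m, "scores"):
        df, label = m.scores, "gene_set"
    elif hasattr(m, "values") and isinstance(m.values, pd.DataFrame):
        df, label = m.values, "gene_id"
    else:
        raise DataError("write_matrix expects an ExpressionMatrix or EnrichmentMatrix")
    if df.shape[1] == 0:
        raise DataError("refusing to write a matrix with no samples")
    out = df.copy()
    out.index.name = label
    out.to_csv(path, sep="\t", float_format="%.17g")


def write_metadata(m, path: str | Path) -> None:
    ann = getattr(m, "scores", None)
    cols = m.scores.columns if ann is not None else m.values.columns
    meta = pd.DataFrame(
        {
            "sample_id": cols,
            "platform": m.platform.loc[cols].to_numpy(),
            "origin_class": ["" if c is None or pd.isna(c) else c for c in m.origin_class.loc[cols]],
        }
    )
    meta.to_csv(path, sep="\t", index=False)


def read_enrichment(matrix_path: str | Path, metadata_path: str | Path):
    """Read an enrichment-score TSV (header field ``gene_set``) plus metadata."""
    from .enrichment import EnrichmentMatrix

    scores = _read_matrix_values(matrix_path, expect_first="gene_set")
    meta = read_metadata(metadata_path)
    missing = [s for s in scores.columns if s not in meta.index]
    if missing:
        raise DataError(f"unannotated sample(s): {missing[:5]}")
    meta = meta.loc[scores.columns]
    origin = meta["origin_class"]
    origin = origin.where(origin.notna() & (origin.str.strip() != ""), None)
    return EnrichmentMatrix(scores=scores, platform=meta["platform"], origin_class=origin, params={})


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file, preserving file order.

    Duplicate member symbols within a line are deduplicated keeping the first
    occurrence; a duplicate set name or a line with fewer than three fields is
    an error.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"{path}:{lineno}: gene set line has no members (need >= 3 fields)")
            name, desc, *members = fields
            name = name.strip()
            if name in sets:
                raise DataError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            members = [g.strip() for g in members if g.strip()]
            if not members:
                raise DataError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = list(dict.fromkeys(members))
            descriptions[name] = desc
    if not sets:
        raise DataError(f"no gene sets in {path}")
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(gs: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in gs:
            desc = gs.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")
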