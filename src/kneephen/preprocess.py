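"""Mixed-type clinical feature table -> standardized numeric matrix.

The biclustering stage consumes a fully numeric matrix on a common scale:

* nominal features become one indicator column per level (``name=level``),
* ordinal features become integer codes 1..k in their stated order,
* continuous (and, by default, ordinal-coded) columns are optionally
  normalized with a monotone shifted-log transform chosen to minimize
  |skewness|, then centered/scaled to mean 0, sd 1 (n-1 denominator),
* binary/indicator columns are left on their native {0,1} scale,
* rows with any missing cell are dropped (complete-case analysis).

Every transform parameter is logged so columns can be inverted exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FeatureMetadata",
    "TransformParams",
    "PreparedMatrix",
    "encode_features",
    "auto_transform_column",
    "standardize_matrix",
    "drop_incomplete_rows",
    "prepare",
]

#: columns with |skewness| at or below this are left untransformed
SKEW_THRESHOLD = 0.5
#: offsets for the shifted-log grid, as multiples of the data range
_SHIFT_GRID = (0.01, 0.02, 0.05, 0.1, 0.25, 0.5, 1.0, 2.0, 5.0)

CONTINUOUS = "continuous"
ORDINAL = "ordinal"
NOMINAL = "nominal"
BINARY = "binary"
INDICATOR = "indicator"
ORDINAL_CODE = "ordinal-code"
STD_CONTINUOUS = "standardized-continuous"


@dataclass(frozen=True)
class FeatureMetadata:
    """Declared kind (and level structure) of one raw column.

    ``levels`` is the ordered level list for ordinal features and the
    (unique) level list for nominal features; ignored for continuous.
    ``exclude`` carries a reason string when the column is to be dropped
    (e.g. "unrelated", "redundant", "sparse-collection").
    """

    name: str
    kind: str
    levels: Optional[tuple] = None
    exclude: Optional[str] = None

    def __post_init__(self):
        if self.kind not in (CONTINUOUS, ORDINAL, NOMINAL, BINARY):
            raise ValueError(f"unknown feature kind {self.kind!r} for {self.name!r}")
        if self.kind in (ORDINAL, NOMINAL):
            if not self.levels:
                raise ValueError(f"{self.kind} feature {self.name!r} needs levels")
            if len(set(self.levels)) != len(self.levels):
                raise ValueError(f"duplicate levels in {self.name!r}")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "kind": self.kind,
            "levels": list(self.levels) if self.levels else None,
            "exclude": self.exclude,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureMetadata":
        levels = d.get("levels")
        return cls(
            name=d["name"],
            kind=d["kind"],
            levels=tuple(levels) if levels else None,
            exclude=d.get("exclude"),
        )


@dataclass
class TransformParams:
    """Invertible record of what was done to one column.

    Normalizing transform: ``t(x) = s * log(s * (x - a) + c)`` with sign
    ``s`` in {+1, -1}; identity when ``family == 'identity'``.  Followed by
    standardization ``(t(x) - mean) / sd`` when ``mean``/``sd`` are set.
    """

    family: str = "identity"  # 'identity' | 'shifted-log'
    sign: float = 1.0
    shift: float = 0.0  # a
    offset: float = 1.0  # c
    mean: Optional[float] = None
    sd: Optional[float] = None
    degenerate: bool = False

    def apply_normalizer(self, x: np.ndarray) -> np.ndarray:
        if self.family == "identity":
            return np.asarray(x, dtype=float)
        return self.sign * np.log(self.sign * (np.asarray(x, dtype=float) - self.shift) + self.offset)

    def apply(self, x: np.ndarray) -> np.ndarray:
        y = self.apply_normalizer(x)
        if self.mean is not None:
            y = (y - self.mean) / self.sd
        return y

    def invert(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if self.mean is not None:
            y = y * self.sd + self.mean
        if self.family == "identity":
            return y
        return (np.exp(y / self.sign) - self.offset) / self.sign + self.shift

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "sign": self.sign,
            "shift": self.shift,
            "offset": self.offset,
            "mean": self.mean,
            "sd": self.sd,
            "degenerate": self.degenerate,
        }


@dataclass
class PreparedMatrix:
    """Standardized numeric matrix with identities and per-column provenance."""

    values: np.ndarray
    row_ids: list
    column_ids: list
    column_kinds: list  # per column: standardized-continuous | ordinal-code | indicator
    transform_log: dict = field(default_factory=dict)  # column id -> TransformParams

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.column_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def encode_features(
    raw: pd.DataFrame, metadata: Sequence[FeatureMetadata]
) -> tuple[pd.DataFrame, dict]:
    """Encode a raw mixed-type table into a numeric one.

    Nominal columns with k levels expand to k 0/1 indicator columns named
    ``name=level``; ordinal columns map to integer codes 1..k; excluded
    columns are dropped and reported with their reason.  Missing cells
    propagate as NaN (they are removed later by complete-case filtering).
    """
    meta_by_name = {m.name: m for m in metadata}
    missing_meta = [c for c in raw.columns if c not in meta_by_name]
    if missing_meta:
        raise ValueError(f"columns without metadata: {missing_meta}")

    out = {}
    kinds = {}
    excluded = {}
    for col in raw.columns:
        m = meta_by_name[col]
        if m.exclude:
            excluded[col] = m.exclude
            continue
        s = raw[col]
        if m.kind == CONTINUOUS:
            out[col] = pd.to_numeric(s, errors="raise").astype(float)
            kinds[col] = CONTINUOUS
        elif m.kind == BINARY:
            vals = pd.to_numeric(s, errors="raise").astype(float)
            bad = vals.dropna()[~vals.dropna().isin([0.0, 1.0])]
            if len(bad):
                raise ValueError(
                    f"binary column {col!r} has value {bad.iloc[0]!r} outside {{0, 1}}"
                )
            out[col] = vals
            kinds[col] = BINARY
        elif m.kind == ORDINAL:
            code = {lv: i + 1 for i, lv in enumerate(m.levels)}
            enc = s.map(lambda v: code.get(v, np.nan) if pd.notna(v) else np.nan)
            bad = s[pd.notna(s) & pd.isna(enc)]
            if len(bad):
                raise ValueError(
                    f"ordinal column {col!r} has value {bad.iloc[0]!r} outside declared levels"
                )
            out[col] = enc.astype(float)
            kinds[col] = ORDINAL
        else:  # nominal -> indicators
            known = set(m.levels)
            bad = s[pd.notna(s) & ~s.isin(known)]
            if len(bad):
                raise ValueError(
                    f"nominal column {col!r} has value {bad.iloc[0]!r} outside declared levels"
                )
            for lv in m.levels:
                name = f"{col}={lv}"
                ind = s.map(lambda v: np.nan if pd.isna(v) else float(v == lv))
                out[name] = ind
                kinds[name] = BINARY
    encoded = pd.DataFrame(out, index=raw.index)
    report = {"excluded": excluded, "column_kinds": kinds}
    return encoded, report


def auto_transform_column(values: np.ndarray) -> tuple[np.ndarray, TransformParams]:
    """Normalize a continuous vector with a monotone shifted-log transform.

    Searches ``t(x) = s*log(s*(x - a) + c)`` over a fixed offset grid,
    with the sign chosen by the direction of skew, and keeps the candidate
    that minimizes |sample skewness|; returns identity when nothing beats
    it or when |skewness| is already below the attempt threshold.
    Constant input is returned unchanged with a degenerate flag.
    """
    x = np.asarray(values, dtype=float)
    finite = x[np.isfinite(x)]
    if np.unique(finite).size < 2:
        return x.copy(), TransformParams(degenerate=True)
    if np.unique(finite).size < 3:
        return x.copy(), TransformParams()
    skew0 = float(stats.skew(finite))
    if abs(skew0) <= SKEW_THRESHOLD:
        return x.copy(), TransformParams()
    sign = 1.0 if skew0 > 0 else -1.0
    rng_width = float(finite.max() - finite.min())
    # anchor so the log argument is positive: s*(x - a) >= 0 at the extreme
    anchor = float(finite.min()) if sign > 0 else float(finite.max())
    best = (abs(skew0), TransformParams())
    for mult in _SHIFT_GRID:
        c = mult * rng_width
        if c <= 0:
            continue
        cand = TransformParams(family="shifted-log", sign=sign, shift=anchor, offset=c)
        y = cand.apply_normalizer(finite)
        if not np.all(np.isfinite(y)):
            continue
        sk = abs(float(stats.skew(y)))
        if sk < best[0] - 1e-12:
            best = (sk, cand)
    params = best[1]
    return params.apply_normalizer(x), params


def drop_incomplete_rows(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Complete-case filter: remove rows with any missing cell.

    Returns the kept table and a report mapping each removed row id to the
    columns that were missing.  Raises if nothing survives.
    """
    isna = table.isna()
    bad = isna.any(axis=1)
    removed = {
        idx: list(table.columns[isna.loc[idx].values])
        for idx in table.index[bad]
    }
    kept = table.loc[~bad]
    if kept.shape[0] == 0:
        raise ValueError("all rows have missing values; nothing left to analyze")
    return kept, {"removed": removed, "n_removed": int(bad.sum())}


def standardize_matrix(
    table: pd.DataFrame,
    column_kinds: dict,
    transform: bool = True,
    standardize_ordinal: bool = True,
) -> PreparedMatrix:
    """Center/scale numeric columns to mean 0, sd 1; leave 0/1 columns alone.

    ``column_kinds`` maps column name -> continuous | ordinal | binary (the
    post-encoding kinds from :func:`encode_features`).  Continuous columns
    optionally pass through :func:`auto_transform_column` first.  Ordinal
    codes are standardized like continuous features by default (they enter
    the same residue computation); a zero-variance continuous/ordinal
    column is an error — it must be excluded upstream.
    """
    if table.isna().any().any():
        raise ValueError("table has missing cells; run drop_incomplete_rows first")
    values = np.empty(table.shape, dtype=float)
    kinds_out = []
    log: dict[str, TransformParams] = {}
    for j, col in enumerate(table.columns):
        kind = column_kinds[col]
        x = table[col].to_numpy(dtype=float)
        if kind == BINARY:
            values[:, j] = x
            kinds_out.append(INDICATOR)
            log[col] = TransformParams()
            continue
        do_std = kind == CONTINUOUS or (kind == ORDINAL and standardize_ordinal)
        if kind == CONTINUOUS and transform:
            y, params = auto_transform_column(x)
        else:
            y, params = x.astype(float), TransformParams()
        if do_std:
            sd = float(np.std(y, ddof=1))
            if sd == 0.0 or params.degenerate:
                raise ValueError(
                    f"zero-variance column {col!r}: exclude it before standardizing"
                )
            params.mean = float(np.mean(y))
            params.sd = sd
            values[:, j] = (y - params.mean) / params.sd
            kinds_out.append(STD_CONTINUOUS if kind == CONTINUOUS else ORDINAL_CODE)
        else:
            values[:, j] = y
            kinds_out.append(ORDINAL_CODE)
        log[col] = params
    return PreparedMatrix(
        values=values,
        row_ids=list(table.index),
        column_ids=list(table.columns),
        column_kinds=kinds_out,
        transform_log=log,
    )


def prepare(
    raw: pd.DataFrame,
    metadata: Sequence[FeatureMetadata],
    transform: bool = True,
    standardize_ordinal: bool = True,
) -> tuple[PreparedMatrix, dict]:
    """Full preparation: encode -> complete-case filter -> standardize."""
    encoded, enc_report = encode_features(raw, metadata)
    complete, drop_report = drop_incomplete_rows(encoded)
    prepared = standardize_matrix(
        complete,
        enc_report["column_kinds"],
        transform=transform,
        standardize_ordinal=standardize_ordinal,
    )
    report = {"encoding": enc_report, "complete_case": drop_report}
    return prepared, report
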