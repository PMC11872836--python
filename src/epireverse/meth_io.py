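"""Readers, writers and validation for the on-disk data model.

All tables are UTF-8 with exactly one header line; the beta matrix and
annotation are tab-separated, the sample sheet and clock coefficients are
comma-separated. No quoting dialects are accepted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("young", "old_control", "old_treated")
REGION_CLASSES = ("promoter", "exon", "intron", "intergenic", "5'UTR", "3'UTR")

#: Tolerance for betas slightly outside [0,1] (rounding in upstream exports).
BETA_TOL = 1e-9

ANNOTATION_COLUMNS = (
    "cpg_id",
    "chrom",
    "start",
    "end",
    "nearest_gene",
    "tss_distance",
    "region_class",
    "island",
    "chromatin_state",
)


class MethIOError(ValueError):
    """Base class for parse/validation failures in this module."""


class ParseError(MethIOError):
    pass


class ValidationError(MethIOError):
    pass


@dataclass
class MethylationMatrix:
    """Beta values (methylated fraction, in [0,1]) as CpGs x samples."""

    cpg_ids: list[str]
    sample_ids: list[str]
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.cpg_ids = [str(c) for c in self.cpg_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (len(self.cpg_ids), len(self.sample_ids)):
            raise ValidationError(
                f"beta shape {self.beta.shape} does not match "
                f"{len(self.cpg_ids)} CpGs x {len(self.sample_ids)} samples"
            )
        if len(set(self.cpg_ids)) != len(self.cpg_ids):
            raise ValidationError("duplicate cpg_ids in methylation matrix")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample_ids in methylation matrix")
        if not np.all(np.isfinite(self.beta)):
            raise ValidationError("non-finite beta values")
        lo, hi = self.beta.min(initial=0.0), self.beta.max(initial=1.0)
        if lo < -BETA_TOL or hi > 1.0 + BETA_TOL:
            raise ValidationError(
                f"beta values outside [0,1]: min={lo!r}, max={hi!r}"
            )
        np.clip(self.beta, 0.0, 1.0, out=self.beta)

    @property
    def shape(self) -> tuple[int, int]:
        return self.beta.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.beta, index=pd.Index(self.cpg_ids, name="cpg_id"),
                            columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MethylationMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def subset_samples(self, sample_ids) -> "MethylationMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return MethylationMatrix(list(self.cpg_ids), list(sample_ids), self.beta[:, idx])


@dataclass
class SampleSheet:
    """Per-sample age, group assignment and species."""

    frame: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample_id", "age_years", "group", "species", "max_lifespan_years")

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        df = df.loc[:, list(self.REQUIRED)].copy()
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dups = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
            raise ValidationError(f"duplicate sample ids: {dups}")
        bad = sorted(set(df["group"]) - set(GROUPS))
        if bad:
            raise ValidationError(
                f"unknown group label(s) {bad}; allowed labels are {list(GROUPS)}"
            )
        df["age_years"] = df["age_years"].astype(float)
        df["max_lifespan_years"] = df["max_lifespan_years"].astype(float)
        if not np.all(np.isfinite(df["age_years"])) or (df["age_years"] <= 0).any():
            raise ValidationError("ages must be finite and strictly positive")
        if (df["max_lifespan_years"] <= df["age_years"]).any():
            raise ValidationError("species maximum lifespan must exceed observed age")
        self.frame = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def ids_for_group(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise ValidationError(f"unknown group {group!r}; allowed: {list(GROUPS)}")
        return list(self.frame.loc[self.frame["group"] == group, "sample_id"])

    def ages(self, sample_ids=None) -> np.ndarray:
        df = self.frame.set_index("sample_id")
        ids = self.sample_ids if sample_ids is None else list(sample_ids)
        return df.loc[ids, "age_years"].to_numpy(dtype=float)


@dataclass
class CpGAnnotation:
    """Per-CpG genomic context (BED-style 0-based half-open coordinates).

    ``tss_distance`` is signed; negative means upstream of the nearest TSS on
    the gene's strand.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"annotation missing columns: {missing}")
        df = df.loc[:, list(ANNOTATION_COLUMNS)].copy()
        df["cpg_id"] = df["cpg_id"].astype(str)
        if df["cpg_id"].duplicated().any():
            raise ValidationError("duplicate cpg_ids in annotation")
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        if (df["end"] <= df["start"]).any():
            raise ValidationError("interval end must exceed start (half-open)")
        bad = sorted(set(df["region_class"]) - set(REGION_CLASSES))
        if bad:
            raise ValidationError(
                f"unknown region class(es) {bad}; allowed: {list(REGION_CLASSES)}"
            )
        df["tss_distance"] = df["tss_distance"].astype(int)
        df["island"] = _parse_bool(df["island"])
        df["chromatin_state"] = df["chromatin_state"].astype(str)
        self.frame = df.reset_index(drop=True)

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.frame["cpg_id"])

    def indexed(self) -> pd.DataFrame:
        return self.frame.set_index("cpg_id")

    def subset(self, cpg_ids) -> "CpGAnnotation":
        ids = [str(c) for c in cpg_ids]
        missing = sorted(set(ids) - set(self.frame["cpg_id"]))
        if missing:
            raise ValidationError(
                f"{len(missing)} CpGs missing from annotation, e.g. {missing[:5]}"
            )
        df = self.frame.set_index("cpg_id").loc[ids].reset_index()
        return CpGAnnotation(df)


def _parse_bool(col: pd.Series) -> pd.Series:
    if col.dtype == bool:
        return col
    mapping = {"1": True, "0": False, "true": True, "false": False,
               "True": True, "False": False, 1: True, 0: False}
    out = col.map(mapping)
    if out.isna().any():
        bad = col[out.isna()].iloc[0]
        raise ValidationError(f"cannot parse island flag {bad!r} (use 0/1)")
    return out.astype(bool)


# ---------------------------------------------------------------------------
# readers


def read_beta_matrix(path, impute_mean: bool = False) -> MethylationMatrix:
    """Read a TSV beta matrix (first column ``cpg_id``, one column per sample).

    CpGs with any missing value are dropped (logged); ``impute_mean=True``
    fills missing cells with the per-CpG mean instead.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.columns[0] != "cpg_id":
        raise ParseError(f"{path}: first column must be 'cpg_id', got {raw.columns[0]!r}")
    cpg_ids = raw["cpg_id"].astype(str)
    data = raw.drop(columns="cpg_id")
    values = np.full(data.shape, np.nan)
    for j, col in enumerate(data.columns):
        raw = data[col]
        present = raw.notna() & (raw.str.strip() != "")
        try:
            # strtod via numpy: exact round-trip, unlike pandas' fast parser
            values[present, j] = raw[present].to_numpy(dtype=str).astype(np.float64)
        except ValueError:
            for i in np.flatnonzero(present):
                try:
                    float(raw.iloc[i])
                except ValueError:
                    raise ParseError(
                        f"{path}: non-numeric value {raw.iloc[i]!r} at CpG "
                        f"{cpg_ids.iloc[i]!r}, sample column {col!r}"
                    ) from None
            raise
    missing_rows = np.isnan(values).any(axis=1)
    if missing_rows.any():
        if impute_mean:
            row_means = np.nanmean(values, axis=1)
            all_missing = np.isnan(row_means)
            inds = np.where(np.isnan(values))
            values[inds] = np.take(row_means, inds[0])
            if all_missing.any():
                values = values[~all_missing]
                cpg_ids = cpg_ids[~all_missing]
                logger.info("dropped %d CpGs with all values missing", all_missing.sum())
            logger.info("imputed missing betas on %d CpGs by row mean",
                        int(missing_rows.sum()))
        else:
            values = values[~missing_rows]
            cpg_ids = cpg_ids[~missing_rows]
            logger.info("dropped %d CpGs with missing values", int(missing_rows.sum()))
    return MethylationMatrix(list(cpg_ids), list(data.columns), values)


def read_sample_sheet(path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path, sep=","))


def read_cpg_annotation(path) -> CpGAnnotation:
    return CpGAnnotation(pd.read_csv(path, sep="\t"))


def read_clock_coefficients(path):
    """Read a clock coefficient CSV with columns ``term,value``.

    Recognized terms: ``intercept``, ``transform``, ``max_lifespan_years``;
    every other term is taken as a CpG id with a numeric weight.
    """
    from .clock import ClockModel, TRANSFORMS

    df = pd.read_csv(path, sep=",", dtype=str)
    if list(df.columns) != ["term", "value"]:
        raise ParseError(f"{path}: expected header 'term,value', got {list(df.columns)}")
    if df["term"].duplicated().any():
        dups = sorted(df.loc[df["term"].duplicated(), "term"])
        raise ValidationError(f"duplicate terms in clock coefficients: {dups}")
    rows = dict(zip(df["term"], df["value"]))
    transform = rows.pop("transform", "identity")
    if transform not in TRANSFORMS:
        raise ValidationError(
            f"unknown transform {transform!r}; allowed: {sorted(TRANSFORMS)}"
        )
    if "intercept" not in rows:
        raise ValidationError("clock coefficients must declare an intercept row")
    intercept = float(rows.pop("intercept"))
    lifespan = rows.pop("max_lifespan_years", None)
    lifespan = float(lifespan) if lifespan is not None else None
    coefficients = {cpg: float(v) for cpg, v in rows.items()}
    return ClockModel(intercept=intercept, coefficients=coefficients,
                      transform=transform, max_lifespan_years=lifespan)


# ---------------------------------------------------------------------------
# writers


def write_beta_matrix(matrix: MethylationMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t")


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.frame.to_csv(path, sep=",", index=False)


def write_cpg_annotation(annotation: CpGAnnotation, path) -> None:
    df = annotation.frame.copy()
    df["island"] = df["island"].astype(int)
    df.to_csv(path, sep="\t", index=False)


def write_clock_coefficients(model, path) -> None:
    rows = [("intercept", repr(model.intercept)), ("transform", model.transform)]
    if model.max_lifespan_years is not None:
        rows.append(("max_lifespan_years", repr(model.max_lifespan_years)))
    rows.extend((cpg, repr(w)) for cpg, w in model.coefficients.items())
    pd.DataFrame(rows, columns=["term", "value"]).to_csv(path, sep=",", index=False)


def write_table(obj, path) -> None:
    """Write any of the package's data objects in its canonical format."""
    from .clock import ClockModel

    if isinstance(obj, MethylationMatrix):
        write_beta_matrix(obj, path)
    elif isinstance(obj, SampleSheet):
        write_sample_sheet(obj, path)
    elif isinstance(obj, CpGAnnotation):
        write_cpg_annotation(obj, path)
    elif isinstance(obj, ClockModel):
        write_clock_coefficients(obj, path)
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t", index=False)
    else:
        raise TypeError(f"no writer for {type(obj).__name__}")
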