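"""Case-control genotype datasets: container, validation, and plain-text I/O.

Genotypes are coded as minor-allele counts (0/1/2) and are always treated as
3-state categorical variables even when a state is unobserved in the sample;
the phenotype is binary (0 = control, 1 = case).

Two on-disk layouts are supported:

``tsv``
    One header row, one row per sample, tab-separated. The last column is
    named ``phenotype``; every other column is a SNP (an optional leading
    ``sample_id`` column carries sample identifiers).

``plink_raw``
    A PLINK ``.raw``-style additive table: the six meta columns
    FID/IID/PAT/MAT/SEX/PHENOTYPE followed by one dosage column per SNP.
    PHENOTYPE is coded 1 = control, 2 = case on disk and remapped to 0/1.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeDataset",
    "DatasetError",
    "ParseError",
    "SchemaError",
    "read_dataset",
    "write_dataset",
]

PLINK_META_COLUMNS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]

VALID_GENOTYPES = (0, 1, 2)


class DatasetError(ValueError):
    """Base class for dataset construction and parsing failures."""


class ParseError(DatasetError):
    """A cell could not be interpreted as a valid genotype/phenotype value."""


class SchemaError(DatasetError):
    """The file layout does not match the declared format."""


@dataclasses.dataclass
class GenotypeDataset:
    """An N x M case-control genotype matrix with a binary phenotype.

    Parameters
    ----------
    genotypes : array-like of int, shape (n_samples, n_snps)
        Minor-allele counts, each entry in {0, 1, 2}.
    phenotype : array-like of int, shape (n_samples,)
        0 for controls, 1 for cases. At least one of each must be present.
    snp_ids : sequence of str
        Unique identifier per SNP column.
    sample_ids : sequence of str, optional
        Unique identifier per sample row.
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    snp_ids: list[str]
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.ascontiguousarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.ascontiguousarray(self.phenotype, dtype=np.int8)
        self.snp_ids = [str(s) for s in self.snp_ids]
        if self.sample_ids is not None:
            self.sample_ids = [str(s) for s in self.sample_ids]
        self.validate()

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int(np.count_nonzero(self.phenotype == 1))

    @property
    def n_controls(self) -> int:
        return int(np.count_nonzero(self.phenotype == 0))

    def validate(self) -> None:
        """Raise :class:`DatasetError` unless every invariant holds."""
        g, y = self.genotypes, self.phenotype
        if g.ndim != 2:
            raise DatasetError("genotypes must be a 2-D matrix")
        n, m = g.shape
        if m < 1:
            raise DatasetError("at least one SNP column is required")
        if n < 2:
            raise DatasetError("at least two samples are required")
        if y.shape != (n,):
            raise DatasetError(
                f"phenotype length {y.shape} does not match {n} samples"
            )
        bad = ~np.isin(g, VALID_GENOTYPES)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DatasetError(
                f"genotype value {int(g[i, j])} at sample {i}, SNP {j} "
                "is not in {0, 1, 2}"
            )
        if not np.isin(y, (0, 1)).all():
            i = int(np.argwhere(~np.isin(y, (0, 1)))[0][0])
            raise DatasetError(f"phenotype value {int(y[i])} at sample {i} is not 0/1")
        if not (y == 1).any() or not (y == 0).any():
            raise DatasetError("dataset must contain at least one case and one control")
        if len(self.snp_ids) != m:
            raise DatasetError(f"{len(self.snp_ids)} snp_ids for {m} SNP columns")
        if len(set(self.snp_ids)) != m:
            raise DatasetError("snp_ids must be unique")
        if self.sample_ids is not None:
            if len(self.sample_ids) != n:
                raise DatasetError(
                    f"{len(self.sample_ids)} sample_ids for {n} samples"
                )
            if len(set(self.sample_ids)) != n:
                raise DatasetError("sample_ids must be unique")

    # -- equality --------------------------------------------------------
    def equals(self, other: "GenotypeDataset") -> bool:
        """Exact equality of matrix, phenotype and identifiers."""
        return (
            isinstance(other, GenotypeDataset)
            and np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.phenotype, other.phenotype)
            and self.snp_ids == other.snp_ids
            and self.sample_ids == other.sample_ids
        )

    __eq__ = equals  # type: ignore[assignment]

    def __hash__(self) -> int:  # dataclass with eq needs explicit opt-out
        return id(self)

    # -- conversion ------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        """Wide table with one column per SNP plus a ``phenotype`` column."""
        df = pd.DataFrame(self.genotypes, columns=self.snp_ids)
        df["phenotype"] = self.phenotype
        if self.sample_ids is not None:
            df.insert(0, "sample_id", self.sample_ids)
        return df

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, phenotype_col: str = "phenotype"
    ) -> "GenotypeDataset":
        if phenotype_col not in df.columns:
            raise SchemaError(f"missing required column {phenotype_col!r}")
        sample_ids = None
        work = df
        if "sample_id" in work.columns:
            sample_ids = work["sample_id"].astype(str).tolist()
            work = work.drop(columns=["sample_id"])
        snp_cols = [c for c in work.columns if c != phenotype_col]
        geno = _coerce_int_block(work[snp_cols], what="genotype")
        pheno = _coerce_int_block(work[[phenotype_col]], what="phenotype")[:, 0]
        return cls(geno, pheno, [str(c) for c in snp_cols], sample_ids)


def _coerce_int_block(block: pd.DataFrame, what: str) -> np.ndarray:
    """Convert a DataFrame block to integers, naming the offending cell on failure."""
    values = block.to_numpy()
    if values.dtype.kind in "iu":
        return values.astype(np.int64)
    out = np.empty(values.shape, dtype=np.int64)
    for j, col in enumerate(block.columns):
        numeric = pd.to_numeric(block[col], errors="coerce")
        arr = numeric.to_numpy(dtype=float)
        bad = np.isnan(arr) | (arr != np.floor(arr))
        if bad.any():
            i = int(np.argwhere(bad)[0][0])
            raise ParseError(
                f"malformed {what} value {block[col].iloc[i]!r} "
                f"at row {i}, column {col!r}"
            )
        out[:, j] = arr.astype(np.int64)
    return out


def _drop_missing_rows(df: pd.DataFrame, drop_missing: bool) -> pd.DataFrame:
    has_na = df.isna().any(axis=1)
    if not has_na.any():
        return df
    if drop_missing:
        return df.loc[~has_na].reset_index(drop=True)
    i = int(np.argwhere(has_na.to_numpy())[0][0])
    col = df.columns[int(np.argwhere(df.iloc[i].isna().to_numpy())[0][0])]
    raise ParseError(f"missing value at row {i}, column {col!r}")


def read_dataset(
    path: str | Path,
    format: str = "tsv",
    *,
    drop_missing: bool = False,
) -> GenotypeDataset:
    """Read a case-control genotype dataset from ``path``.

    Missing genotype cells raise :class:`ParseError` unless
    ``drop_missing=True``, in which case any sample containing a missing
    value is removed before validation.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if "phenotype" not in df.columns:
            raise SchemaError(f"{path}: TSV file lacks a 'phenotype' column")
        df = df.replace({"": None})
        df = _drop_missing_rows(df, drop_missing)
        return GenotypeDataset.from_dataframe(df)
    if format == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", dtype=str)
        missing_meta = [c for c in PLINK_META_COLUMNS if c not in df.columns]
        if missing_meta:
            raise SchemaError(
                f"{path}: PLINK .raw-style file lacks meta columns {missing_meta}"
            )
        df = _drop_missing_rows(df, drop_missing)
        snp_cols = [c for c in df.columns if c not in PLINK_META_COLUMNS]
        if not snp_cols:
            raise SchemaError(f"{path}: no SNP dosage columns after meta columns")
        geno = _coerce_int_block(df[snp_cols], what="genotype")
        pheno_raw = _coerce_int_block(df[["PHENOTYPE"]], what="phenotype")[:, 0]
        if not np.isin(pheno_raw, (1, 2)).all():
            i = int(np.argwhere(~np.isin(pheno_raw, (1, 2)))[0][0])
            raise ParseError(
                f"PHENOTYPE value {int(pheno_raw[i])} at row {i} is not 1/2"
            )
        return GenotypeDataset(
            geno, pheno_raw - 1, snp_cols, df["IID"].astype(str).tolist()
        )
    raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'plink_raw'")


def write_dataset(
    ds: GenotypeDataset, path: str | Path, format: str = "tsv"
) -> None:
    """Write ``ds`` so that :func:`read_dataset` recovers an equal dataset."""
    ds.validate()
    path = Path(path)
    if format == "tsv":
        ds.to_dataframe().to_csv(path, sep="\t", index=False)
        return
    if format == "plink_raw":
        ids = ds.sample_ids or [f"S{i + 1}" for i in range(ds.n_samples)]
        df = pd.DataFrame(
            {
                "FID": ids,
                "IID": ids,
                "PAT": 0,
                "MAT": 0,
                "SEX": 0,
                "PHENOTYPE": ds.phenotype.astype(int) + 1,
            }
        )
        for j, snp in enumerate(ds.snp_ids):
            df[snp] = ds.genotypes[:, j]
        df.to_csv(path, sep=" ", index=False)
        return
    raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'plink_raw'")
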