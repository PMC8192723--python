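"""Readers, writers, and joint validation for the study's external formats.

Formats handled
---------------
* ASV count table: TSV (samples in rows, first header ``sample_id``) and
  BIOM v2.1 (HDF5, read/written directly through h5py).
* Sample metadata: TSV with columns ``sample_id, treatment, replicate, week``.
* Rooted phylogeny: Newick with branch lengths (see :mod:`commvade.phylo`).
* Cumulative gas: long CSV with ``sample_id, week, cumulative_gas_ml``.

Counts are never rarefied anywhere downstream; relative abundances are
derived on the fly where an analysis needs them.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import sparse

from .errors import FormatError, ValidationError
from .phylo import PhyloTree, parse_newick, write_newick

__all__ = [
    "TREATMENTS",
    "INVASION_TREATMENTS",
    "TREATMENT_DOSE",
    "AsvCountTable",
    "SampleMetadata",
    "GasSeries",
    "read_asv_table",
    "write_asv_table",
    "read_metadata",
    "write_metadata",
    "read_gas",
    "write_gas",
    "read_newick",
    "write_newick_file",
    "validate_bundle",
]

#: Closed set of treatment labels: the two pure communities and the four
#: volumetric invasion doses (percent by volume).
TREATMENTS = ("LP", "HP", "D10", "D1", "D0.1", "D0.01")
INVASION_TREATMENTS = ("D10", "D1", "D0.1", "D0.01")
#: Volume fraction of invader community added at invasion.
TREATMENT_DOSE = {"D10": 0.1, "D1": 0.01, "D0.1": 0.001, "D0.01": 0.0001}


@dataclass
class AsvCountTable:
    """Integer read counts per (sample, ASV); the central object of the pipeline."""

    sample_ids: list[str]
    asv_ids: list[str]
    counts: np.ndarray  # shape (n_samples, n_asvs), non-negative integers

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape != (
            len(self.sample_ids),
            len(self.asv_ids),
        ):
            raise ValidationError("counts shape does not match sample/ASV ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise FormatError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValidationError("negative count encountered")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample_ids")
        if len(set(self.asv_ids)) != len(self.asv_ids):
            raise ValidationError("duplicate asv_ids")
        sums = self.counts.sum(axis=1)
        if (sums == 0).any():
            bad = [s for s, t in zip(self.sample_ids, sums) if t == 0]
            raise ValidationError(f"zero-sum sample(s): {', '.join(bad)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample(self, sample_id: str) -> np.ndarray:
        return self.counts[self.sample_ids.index(sample_id)]

    def relative_abundance(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        return self.counts / totals

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.asv_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AsvCountTable":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AsvCountTable)
            and self.sample_ids == other.sample_ids
            and self.asv_ids == other.asv_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class SampleMetadata:
    """Treatment, replicate, and week per sample."""

    frame: pd.DataFrame  # columns: sample_id, treatment, replicate, week

    REQUIRED = ("sample_id", "treatment", "replicate", "week")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"metadata missing column(s): {', '.join(missing)}")
        self.frame = self.frame.loc[:, list(self.REQUIRED)].copy()
        self.frame["sample_id"] = self.frame["sample_id"].astype(str)
        if self.frame["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in metadata")
        bad = set(self.frame["treatment"]) - set(TREATMENTS)
        if bad:
            raise ValidationError(f"unknown treatment label(s): {sorted(bad)}")
        self.frame["replicate"] = self.frame["replicate"].astype(int)
        self.frame["week"] = self.frame["week"].astype(int)
        if (self.frame["replicate"] <= 0).any():
            raise ValidationError("replicate must be a positive integer")
        if (self.frame["week"] < 0).any():
            raise ValidationError("week must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def treatment_of(self, sample_id: str) -> str:
        row = self.frame.loc[self.frame["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return row["treatment"].iloc[0]

    def samples_for(self, treatment: str, week: int | None = None) -> list[str]:
        sel = self.frame["treatment"] == treatment
        if week is not None:
            sel &= self.frame["week"] == week
        return list(self.frame.loc[sel, "sample_id"])


@dataclass
class GasSeries:
    """Weekly cumulative CO2-stripped biogas (mL) per sample."""

    frame: pd.DataFrame  # columns: sample_id, week, cumulative_gas_ml

    REQUIRED = ("sample_id", "week", "cumulative_gas_ml")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"gas series missing column(s): {', '.join(missing)}")
        self.frame = self.frame.loc[:, list(self.REQUIRED)].copy()
        self.frame["sample_id"] = self.frame["sample_id"].astype(str)
        self.frame["week"] = self.frame["week"].astype(int)
        self.frame["cumulative_gas_ml"] = self.frame["cumulative_gas_ml"].astype(float)
        if (self.frame["cumulative_gas_ml"] < 0).any():
            raise ValidationError("cumulative gas must be non-negative")
        for sid, grp in self.frame.sort_values("week").groupby("sample_id"):
            vals = grp["cumulative_gas_ml"].to_numpy()
            if (np.diff(vals) < 0).any():
                week = int(grp["week"].to_numpy()[np.argmax(np.diff(vals) < 0) + 1])
                raise ValidationError(
                    f"cumulative gas decreases for sample {sid} at week {week}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return sorted(set(self.frame["sample_id"]))


# ---------------------------------------------------------------------------
# ASV table I/O


def _table_from_tsv(path: Path) -> AsvCountTable:
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.columns.size == 0:
        raise FormatError("empty TSV")
    first = df.columns[0]
    if first == "asv_id":
        # transposed orientation: ASVs in rows
        df = df.set_index("asv_id").T
        df.index.name = "sample_id"
    elif first == "sample_id":
        df = df.set_index("sample_id")
    else:
        raise FormatError(
            f"first header cell must be 'sample_id' (or 'asv_id' for the "
            f"transposed layout), got {first!r}"
        )
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"non-numeric count in {path}: {exc}") from None
    if not np.all(np.equal(np.mod(values, 1), 0)):
        raise FormatError("non-integer count encountered")
    return AsvCountTable(
        list(df.index.astype(str)), list(df.columns.astype(str)), values.astype(np.int64)
    )


def _table_from_biom(path: Path) -> AsvCountTable:
    """Read a BIOM v2.1 HDF5 table (sample-by-observation convention)."""
    with h5py.File(path, "r") as f:
        sample_ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["sample/ids"][:]]
        asv_ids = [
            s.decode() if isinstance(s, bytes) else str(s) for s in f["observation/ids"][:]
        ]
        grp = f["sample/matrix"]
        mat = sparse.csr_matrix(
            (grp["data"][:], grp["indices"][:], grp["indptr"][:]),
            shape=(len(sample_ids), len(asv_ids)),
        )
    dense = np.asarray(mat.todense())
    if not np.all(np.equal(np.mod(dense, 1), 0)):
        raise FormatError("non-integer count in BIOM file")
    return AsvCountTable(sample_ids, asv_ids, dense.astype(np.int64))


def read_asv_table(path: str | Path, format: str | None = None) -> AsvCountTable:
    """Read an ASV count table from TSV or BIOM v2.1.

    ``format`` may be ``"tsv"`` or ``"biom"``; when omitted it is inferred
    from the file suffix (``.biom`` -> BIOM, anything else -> TSV).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "biom" if path.suffix == ".biom" else "tsv"
    if format == "tsv":
        return _table_from_tsv(path)
    if format == "biom":
        return _table_from_biom(path)
    raise ValueError(f"unknown table format {format!r}")


def write_asv_table(table: AsvCountTable, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "biom" if path.suffix == ".biom" else "tsv"
    if format == "tsv":
        df = table.to_dataframe()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")
        return
    if format != "biom":
        raise ValueError(f"unknown table format {format!r}")
    csr_sample = sparse.csr_matrix(table.counts)
    csr_obs = sparse.csr_matrix(table.counts.T)
    with h5py.File(path, "w") as f:
        f.attrs["id"] = "No Table ID"
        f.attrs["type"] = "OTU table"
        f.attrs["format-url"] = "http://biom-format.org"
        f.attrs["format-version"] = np.array([2, 1], dtype=np.int64)
        f.attrs["generated-by"] = "commvade"
        f.attrs["creation-date"] = datetime.datetime.now().isoformat()
        f.attrs["shape"] = np.array(
            [len(table.asv_ids), len(table.sample_ids)], dtype=np.int64
        )
        f.attrs["nnz"] = int(csr_sample.nnz)
        for name, ids, csr in (
            ("sample", table.sample_ids, csr_sample),
            ("observation", table.asv_ids, csr_obs),
        ):
            grp = f.create_group(name)
            grp.create_dataset("ids", data=np.array(ids, dtype="S"))
            mat = grp.create_group("matrix")
            mat.create_dataset("data", data=csr.data.astype(np.float64))
            mat.create_dataset("indices", data=csr.indices.astype(np.int64))
            mat.create_dataset("indptr", data=csr.indptr.astype(np.int64))
            grp.create_group("metadata")
            grp.create_group("group-metadata")


# ---------------------------------------------------------------------------
# Metadata / gas / tree I/O


def read_metadata(path: str | Path) -> SampleMetadata:
    return SampleMetadata(pd.read_csv(path, sep="\t"))


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.frame.to_csv(path, sep="\t", index=False)


def read_gas(path: str | Path) -> GasSeries:
    return GasSeries(pd.read_csv(path))


def write_gas(gas: GasSeries, path: str | Path) -> None:
    gas.frame.to_csv(path, index=False)


def read_newick(path: str | Path) -> PhyloTree:
    return parse_newick(Path(path).read_text())


def write_newick_file(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(write_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# Cross-file validation


def validate_bundle(
    table: AsvCountTable,
    metadata: SampleMetadata,
    tree: PhyloTree | None = None,
    gas: GasSeries | None = None,
) -> list[str]:
    """Cross-check the joint consistency of the loaded inputs.

    Returns a list of human-readable violations; an empty list means the
    bundle is consistent.
    """
    report: list[str] = []
    meta_ids = set(metadata.sample_ids)
    for sid in table.sample_ids:
        if sid not in meta_ids:
            report.append(f"table sample {sid!r} has no metadata row")
    if tree is not None:
        leaves = set(tree.leaf_names)
        present = np.asarray(table.counts).sum(axis=0) > 0
        for asv, seen in zip(table.asv_ids, present):
            if seen and asv not in leaves:
                report.append(f"ASV {asv!r} has reads but is not a leaf of the tree")
    if gas is not None:
        for sid in gas.sample_ids:
            if sid not in meta_ids:
                report.append(f"gas sample {sid!r} has no metadata row")
    return report
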