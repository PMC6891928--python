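"""Reading, writing and reshaping OTU tables, sample metadata and taxonomy.

The central container is :class:`OTUTable`, a thin frame around a pandas
DataFrame of taxa (rows) by samples (columns).  Tables are either in
``counts`` mode (non-negative reads) or ``relative`` mode (each sample column
sums to one).  Every downstream stage of the pipeline consumes these tables.

Two on-disk dialects are supported: the QIIME-classic tab-separated table
(first column = OTU id, header row = sample ids, optional leading
``#OTU ID`` header) and the BIOM 1.0 JSON table, both read and written
losslessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "OTUTable",
    "SampleMetadata",
    "TaxonomyMap",
    "OTUTableError",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "read_taxonomy",
    "to_relative",
    "filter_min_total",
    "split_by_group",
]

UNKNOWN_PHYLUM = "p__unclassified"


class OTUTableError(ValueError):
    """Raised on malformed input files or contract violations."""


@dataclass
class OTUTable:
    """Taxa-by-samples abundance table.

    Parameters
    ----------
    data:
        DataFrame with OTU ids as the index and sample ids as the columns,
        holding non-negative reals (read counts or relative abundances).
    mode:
        ``"counts"`` for reads, ``"relative"`` for per-sample proportions.
    """

    data: pd.DataFrame
    mode: str = "counts"

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "relative"):
            raise OTUTableError(f"unknown mode {self.mode!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise OTUTableError(f"duplicate otu_ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise OTUTableError(f"duplicate sample_ids: {dups}")
        values = self.data.to_numpy(dtype=float)
        if values.size and np.nanmin(values) < 0:
            raise OTUTableError("negative abundance values are not allowed")
        if not np.all(np.isfinite(values)):
            raise OTUTableError("non-finite abundance values are not allowed")
        if self.mode == "relative" and values.size:
            colsums = values.sum(axis=0)
            if not np.allclose(colsums, 1.0, atol=1e-9):
                bad = [c for c, s in zip(self.data.columns, colsums) if abs(s - 1.0) > 1e-9]
                raise OTUTableError(f"relative-mode columns must sum to 1; offending samples: {bad}")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        """Values as a float array, taxa x samples."""
        return self.data.to_numpy(dtype=float)

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def select_taxa(self, otu_ids: Iterable[str]) -> "OTUTable":
        """Row-subset preserving sample set (relative mode is dropped)."""
        ids = list(otu_ids)
        missing = [o for o in ids if o not in self.data.index]
        if missing:
            raise OTUTableError(f"unknown otu_ids: {missing}")
        # a row subset of a relative table no longer sums to 1, so the
        # result is always tagged as unnormalized
        return OTUTable(self.data.loc[ids].copy(), mode="counts")

    def select_samples(self, sample_ids: Iterable[str]) -> "OTUTable":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.data.columns]
        if missing:
            raise OTUTableError(f"unknown sample_ids: {missing}")
        return OTUTable(self.data[ids].copy(), mode=self.mode)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OTUTable):
            return NotImplemented
        return (
            self.mode == other.mode
            and self.otu_ids == other.otu_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class SampleMetadata:
    """Per-sample annotations: subject, group label (e.g. sex), body site."""

    records: pd.DataFrame  # index sample_id; columns subject_id, group, body_site

    REQUIRED = ("subject_id", "group", "body_site")

    def __post_init__(self) -> None:
        if self.records.index.duplicated().any():
            raise OTUTableError("duplicate sample_ids in metadata")
        for col in self.REQUIRED:
            if col not in self.records.columns:
                raise OTUTableError(f"metadata missing required column {col!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.records.index)

    def group_of(self, sample_id: str) -> str:
        try:
            return str(self.records.loc[sample_id, "group"])
        except KeyError:
            raise OTUTableError(f"sample {sample_id!r} absent from metadata") from None

    def samples_at_site(self, site: str) -> list[str]:
        return list(self.records.index[self.records["body_site"] == site])

    @property
    def sites(self) -> list[str]:
        return sorted(self.records["body_site"].unique())


@dataclass
class TaxonomyMap:
    """OTU id -> lineage string; ranks separated by ``;``.

    Phylum extraction is total: lineages without a recognisable phylum rank
    map to the sentinel ``p__unclassified``.
    """

    lineages: dict[str, str] = field(default_factory=dict)

    def phylum(self, otu_id: str) -> str:
        lineage = self.lineages.get(otu_id)
        if not lineage:
            return UNKNOWN_PHYLUM
        ranks = [r.strip() for r in lineage.split(";")]
        for rank in ranks:
            if rank.lower().startswith("p__"):
                name = rank[3:].strip()
                return f"p__{name}" if name else UNKNOWN_PHYLUM
        # fall back to positional convention kingdom;phylum;...
        if len(ranks) >= 2 and ranks[1]:
            return f"p__{ranks[1]}"
        return UNKNOWN_PHYLUM

    def taxa_in_phylum(self, otu_ids: Iterable[str], phylum: str) -> list[str]:
        want = phylum if phylum.startswith("p__") else f"p__{phylum}"
        return [o for o in otu_ids if self.phylum(o) == want]


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path: str) -> OTUTable:
    rows: list[list[str]] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise OTUTableError(f"{path}: empty file")
    start = 0
    # QIIME-classic tables may open with "# Constructed from biom file"
    while start < len(lines) and lines[start].startswith("#") and not lines[start].startswith("#OTU"):
        start += 1
    if start >= len(lines):
        raise OTUTableError(f"{path}: no header row found")
    header = lines[start].split("\t")
    sample_ids = header[1:]
    if not sample_ids:
        raise OTUTableError(f"{path}: header row (line {start + 1}) has no sample columns")
    otu_ids: list[str] = []
    for lineno, line in enumerate(lines[start + 1:], start=start + 2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise OTUTableError(
                f"{path}: line {lineno} has {len(fields)} fields, expected {len(header)}"
            )
        otu_ids.append(fields[0])
        row: list[float] = []
        for col, tok in enumerate(fields[1:], start=2):
            try:
                value = float(tok)
            except ValueError:
                raise OTUTableError(f"{path}: line {lineno}, field {col}: not a number: {tok!r}") from None
            if value < 0:
                raise OTUTableError(f"{path}: line {lineno}, field {col}: negative value {value}")
            row.append(value)
        rows.append(row)
    data = pd.DataFrame(rows, index=otu_ids, columns=sample_ids, dtype=float)
    return OTUTable(data, mode="counts")


def _read_biom(path: str) -> OTUTable:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise OTUTableError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from None
    for key in ("rows", "columns", "data", "matrix_type", "shape"):
        if key not in doc:
            raise OTUTableError(f"{path}: BIOM document missing field {key!r}")
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    n_rows, n_cols = doc["shape"]
    if len(otu_ids) != n_rows or len(sample_ids) != n_cols:
        raise OTUTableError(f"{path}: shape field disagrees with rows/columns")
    values = np.zeros((n_rows, n_cols), dtype=float)
    if doc["matrix_type"] == "dense":
        arr = np.asarray(doc["data"], dtype=float)
        if arr.shape != (n_rows, n_cols):
            raise OTUTableError(f"{path}: dense data block has shape {arr.shape}, expected {(n_rows, n_cols)}")
        values = arr
    elif doc["matrix_type"] == "sparse":
        for entry in doc["data"]:
            i, j, v = int(entry[0]), int(entry[1]), float(entry[2])
            if not (0 <= i < n_rows and 0 <= j < n_cols):
                raise OTUTableError(f"{path}: sparse entry {entry} out of bounds")
            values[i, j] = v
    else:
        raise OTUTableError(f"{path}: unknown matrix_type {doc['matrix_type']!r}")
    if values.size and values.min() < 0:
        raise OTUTableError(f"{path}: negative value in BIOM data")
    data = pd.DataFrame(values, index=otu_ids, columns=sample_ids)
    return OTUTable(data, mode="counts")


def read_otu_table(path: str, format: str = "tsv") -> OTUTable:
    """Read an OTU table in the named dialect (``tsv`` or ``biom``)."""
    if format == "tsv":
        return _read_tsv(path)
    if format == "biom":
        return _read_biom(path)
    raise OTUTableError(f"unknown format {format!r}; expected 'tsv' or 'biom'")


def write_otu_table(table: OTUTable, path: str, format: str = "tsv") -> None:
    """Write a table in the named dialect; round-trips exactly."""
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("#OTU ID\t" + "\t".join(table.sample_ids) + "\n")
            for otu, row in zip(table.otu_ids, table.counts):
                fh.write(otu + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
        return
    if format == "biom":
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "mgx",
            "date": "",
            "matrix_type": "sparse",
            "matrix_element_type": "float",
            "shape": [table.n_taxa, table.n_samples],
            "rows": [{"id": o, "metadata": None} for o in table.otu_ids],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": [
                [int(i), int(j), float(table.counts[i, j])]
                for i, j in zip(*np.nonzero(table.counts))
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
        return
    raise OTUTableError(f"unknown format {format!r}")


def read_metadata(path: str) -> SampleMetadata:
    """Read sample metadata TSV with columns sample_id, subject_id, sex, body_site."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "sample_id" not in cols:
        raise OTUTableError(f"{path}: metadata needs a sample_id column")
    group_col = cols.get("sex") or cols.get("group")
    if group_col is None:
        raise OTUTableError(f"{path}: metadata needs a sex (or group) column")
    out = pd.DataFrame(
        {
            "subject_id": df[cols.get("subject_id", cols["sample_id"])],
            "group": df[group_col],
            "body_site": df[cols.get("body_site", cols["sample_id"])],
        }
    )
    out.index = pd.Index(df[cols["sample_id"]], name="sample_id")
    return SampleMetadata(out)


def read_taxonomy(path: str) -> TaxonomyMap:
    """Read taxonomy TSV: otu_id <tab> lineage (``;``-separated ranks)."""
    lineages: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise OTUTableError(f"{path}: line {lineno}: expected otu_id<TAB>lineage")
            lineages[parts[0]] = parts[1]
    return TaxonomyMap(lineages)


# ---------------------------------------------------------------------------
# transforms


def to_relative(table: OTUTable) -> OTUTable:
    """Normalize each sample column to proportions summing to one."""
    if table.mode != "counts":
        raise OTUTableError("to_relative expects a counts-mode table")
    totals = table.counts.sum(axis=0)
    zero = [s for s, t in zip(table.sample_ids, totals) if t <= 0]
    if zero:
        raise OTUTableError(f"samples with zero total reads cannot be normalized: {zero}")
    data = table.data / totals
    return OTUTable(data, mode="relative")


def filter_min_total(table: OTUTable, min_reads: int = 80) -> OTUTable:
    """Drop OTUs whose total reads over all samples fall below ``min_reads``.

    The boundary is kept: a row summing to exactly ``min_reads`` survives.
    An empty result (0 taxa) is returned, not raised.
    """
    if table.mode != "counts":
        raise OTUTableError("filter_min_total is defined on read counts, not relative abundances")
    keep = table.counts.sum(axis=1) >= min_reads
    return OTUTable(table.data.loc[keep].copy(), mode="counts")


def split_by_group(
    table: OTUTable,
    metadata: SampleMetadata,
    site: str | None = None,
    group_field: str = "group",
) -> tuple[OTUTable, OTUTable]:
    """Partition a site's samples into the two group cohorts.

    Returns the two tables in sorted group-label order; taxa rows are
    identical (aligned) in both.
    """
    if site is not None:
        samples = [s for s in table.sample_ids if s in set(metadata.samples_at_site(site))]
    else:
        samples = table.sample_ids
    missing = [s for s in samples if s not in metadata.records.index]
    absent = [s for s in table.sample_ids if s not in metadata.records.index]
    if absent:
        raise OTUTableError(f"samples missing from metadata: {absent}")
    if missing:
        raise OTUTableError(f"samples missing from metadata: {missing}")
    if not samples:
        raise OTUTableError(f"no samples at site {site!r}")
    labels = sorted({metadata.group_of(s) for s in samples})
    if len(labels) != 2:
        raise OTUTableError(
            f"expected exactly two group labels at site {site!r}, found {labels}"
        )
    a_samples = [s for s in samples if metadata.group_of(s) == labels[0]]
    b_samples = [s for s in samples if metadata.group_of(s) == labels[1]]
    return table.select_samples(a_samples), table.select_samples(b_samples)
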