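"""Community count tables, readers/writers and pre-analysis filters.

The central object is :class:`CountTable`: a non-negative integer
taxa x samples matrix with aligned per-sample metadata (zone, depth
layer, date) and a provenance log recording every filter applied to it.

Filters implement the standard amplicon pre-processing rules for this
kind of survey: removal of dataset-wide singleton taxa, removal of
low-depth samples (strict ``< min_reads``), aggregation of ASV-level
counts to a taxonomic rank, and closure to relative abundances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

RANKS = ("phylum", "class", "order", "family", "genus")
UNASSIGNED = "unassigned"

#: QIIME-style 7-level lineage prefixes, domain..species.
_LINEAGE_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")


class CountTableError(ValueError):
    """Malformed or invariant-violating community table input."""


@dataclass
class CountTable:
    """Integer taxa x samples matrix with sample metadata and provenance.

    Parameters
    ----------
    counts
        DataFrame indexed by taxon id with one column per sample id;
        values are non-negative integers.
    sample_meta
        DataFrame indexed by sample id with columns ``zone``,
        ``depth_layer`` and ``date``. Every column of ``counts`` must
        have a metadata row. Extra metadata rows are tolerated (they
        describe samples filtered out upstream).
    provenance
        Free-text log of applied filters, oldest first.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise CountTableError(f"duplicate taxon ids: {dups}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise CountTableError(f"duplicate sample ids: {dups}")
        if c.size:
            arr = c.to_numpy()
            if not np.issubdtype(arr.dtype, np.integer):
                raise CountTableError("counts must be integers")
            if (arr < 0).any():
                raise CountTableError("counts must be non-negative")
        missing = set(c.columns) - set(self.sample_meta.index)
        if missing:
            raise CountTableError(
                f"samples without metadata: {sorted(missing)}"
            )

    # -- conveniences ---------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def taxon_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def log(self, message: str) -> None:
        self.provenance.append(message)


@dataclass
class TaxonomyMap:
    """Taxon id -> lineage at ranks phylum..genus.

    Unassigned ranks are stored as the explicit string ``"unassigned"``,
    never as an empty string or NaN.
    """

    lineages: pd.DataFrame  # index taxon_id, columns RANKS

    def __post_init__(self) -> None:
        missing_cols = set(RANKS) - set(self.lineages.columns)
        if missing_cols:
            raise CountTableError(f"taxonomy missing ranks: {sorted(missing_cols)}")
        self.lineages = self.lineages[list(RANKS)].copy()
        for rank in RANKS:
            col = self.lineages[rank]
            bad = col.isna() | (col.astype(str).str.strip() == "")
            self.lineages.loc[bad, rank] = UNASSIGNED
        self.lineages = self.lineages.astype(str)

    def rank_of(self, rank: str) -> pd.Series:
        if rank not in RANKS:
            raise CountTableError(f"unknown rank {rank!r}; choose from {RANKS}")
        return self.lineages[rank]


def parse_lineage(lineage: str) -> dict[str, str]:
    """Split a QIIME-style ``;``-separated lineage into rank values.

    Tolerates ``x__`` prefixes and missing trailing levels; the domain
    and species levels are parsed but dropped (only phylum..genus are
    kept, matching the ranks at which specialization is scored).
    """
    parts = [p.strip() for p in str(lineage).split(";")]
    values = []
    for part in parts:
        if len(part) >= 3 and part[1:3] == "__":
            part = part[3:]
        values.append(part.strip())
    # pad to 7 levels (domain..species)
    values += [""] * (7 - len(values))
    out = {}
    for rank, value in zip(RANKS, values[1:6]):
        out[rank] = value if value else UNASSIGNED
    return out


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read a taxonomy TSV with columns ``taxon_id`` and ``lineage``.

    A header row is required. Lineages are QIIME-style strings split on
    ``;`` with ``x__`` prefixes tolerated.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "taxon_id" not in cols or "lineage" not in cols:
        raise CountTableError(
            f"{path}: taxonomy TSV needs columns taxon_id and lineage"
        )
    records = {
        row[cols["taxon_id"]]: parse_lineage(row[cols["lineage"]])
        for _, row in df.iterrows()
    }
    lineages = pd.DataFrame.from_dict(records, orient="index")
    return TaxonomyMap(lineages)


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read metadata TSV with columns sample_id, zone, depth_layer, date."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "zone", "depth_layer", "date"}
    missing = required - set(meta.columns)
    if missing:
        raise CountTableError(f"{path}: metadata missing columns {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise CountTableError(f"{path}: duplicate sample ids {dups}")
    return meta.set_index("sample_id")


def _default_meta(sample_ids: Iterable[str]) -> pd.DataFrame:
    ids = list(sample_ids)
    return pd.DataFrame(
        {"zone": UNASSIGNED, "depth_layer": UNASSIGNED, "date": UNASSIGNED},
        index=pd.Index(ids, name="sample_id"),
    )


def read_count_table(
    path: str | Path,
    format: str = "tsv",
    sample_meta: pd.DataFrame | None = None,
    transposed: bool = False,
) -> CountTable:
    """Read a community count table from TSV or BIOM-JSON.

    TSV dialect is fixed: taxa as rows, samples as columns, header row
    of sample ids, first column taxon ids. Transposed input is handled
    only via the explicit ``transposed`` flag, never guessed.

    Raises
    ------
    CountTableError
        On missing files, non-integer cells (the offending line is
        named), or duplicate ids.
    """
    path = Path(path)
    if not path.exists():
        raise CountTableError(f"no such file: {path}")
    if format == "tsv":
        counts = _read_tsv_counts(path)
    elif format == "biom-json":
        counts = _read_biom_json(path)
    else:
        raise CountTableError(f"unknown format {format!r}; use 'tsv' or 'biom-json'")
    if transposed:
        counts = counts.T
    meta = sample_meta if sample_meta is not None else _default_meta(counts.columns)
    table = CountTable(counts, meta)
    table.log(f"read {counts.shape[0]} taxa x {counts.shape[1]} samples from {path} ({format})")
    return table


def _read_tsv_counts(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise CountTableError(f"{path}:1: empty header line")
        sample_ids = header.split("\t")[1:]
        taxon_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(sample_ids) + 1:
                raise CountTableError(
                    f"{path}:{lineno}: expected {len(sample_ids) + 1} fields, got {len(fields)}"
                )
            taxon_ids.append(fields[0])
            row = []
            for value in fields[1:]:
                try:
                    row.append(_parse_int_cell(value))
                except ValueError:
                    raise CountTableError(
                        f"{path}:{lineno}: non-integer count {value!r}"
                    ) from None
            rows.append(row)
    counts = pd.DataFrame(
        np.asarray(rows, dtype=np.int64).reshape(len(taxon_ids), len(sample_ids)),
        index=pd.Index(taxon_ids, name="taxon_id"),
        columns=sample_ids,
    )
    return counts


def _parse_int_cell(value: str) -> int:
    value = value.strip()
    n = int(value)  # rejects "2.5", "", "NA"
    if n < 0:
        raise ValueError(value)
    return n


def _read_biom_json(path: Path) -> pd.DataFrame:
    """Minimal dense/sparse BIOM-JSON (format 1.0) interpreter."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise CountTableError(f"{path}:{exc.lineno}: invalid JSON: {exc.msg}") from None
    try:
        taxon_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        shape = doc["shape"]
        data = doc["data"]
        matrix_type = doc.get("matrix_type", "dense")
    except (KeyError, TypeError) as exc:
        raise CountTableError(f"{path}: not a BIOM-JSON table ({exc})") from None
    if list(shape) != [len(taxon_ids), len(sample_ids)]:
        raise CountTableError(f"{path}: shape {shape} inconsistent with row/column lists")
    arr = np.zeros((len(taxon_ids), len(sample_ids)), dtype=np.int64)
    if matrix_type == "dense":
        for i, row in enumerate(data):
            for j, value in enumerate(row):
                arr[i, j] = _check_int(value, path)
    elif matrix_type == "sparse":
        for i, j, value in data:
            arr[int(i), int(j)] = _check_int(value, path)
    else:
        raise CountTableError(f"{path}: unsupported matrix_type {matrix_type!r}")
    return pd.DataFrame(arr, index=pd.Index(taxon_ids, name="taxon_id"), columns=sample_ids)


def _check_int(value: float, path: Path) -> int:
    if float(value) != int(value) or value < 0:
        raise CountTableError(f"{path}: non-integer count {value!r}")
    return int(value)


def write_count_table(table: CountTable, path: str | Path, format: str = "tsv") -> None:
    """Write counts to TSV or BIOM-JSON plus a JSON provenance sidecar."""
    path = Path(path)
    if format == "tsv":
        out = table.counts.copy()
        out.index.name = "taxon_id"
        out.to_csv(path, sep="\t")
    elif format == "biom-json":
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "habspec",
            "matrix_type": "dense",
            "matrix_element_type": "int",
            "shape": [table.n_taxa, table.n_samples],
            "rows": [{"id": t, "metadata": None} for t in table.taxon_ids],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": table.counts.to_numpy().tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
    else:
        raise CountTableError(f"unknown format {format!r}")
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    with open(sidecar, "w") as fh:
        json.dump({"provenance": table.provenance}, fh, indent=2)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def remove_singletons(table: CountTable) -> CountTable:
    """Drop taxa whose dataset-wide total count is exactly 1.

    "Occurred once" is read literally as a total of one individual, not
    as occupancy of a single sample: a taxon seen many times in one
    sample is clearly real and is kept. Idempotent.
    """
    totals = table.taxon_totals()
    removed = totals.index[totals <= 1].tolist()
    kept = table.counts.loc[totals >= 2]
    new = CountTable(kept, table.sample_meta.copy(), list(table.provenance))
    new.log(f"remove_singletons: removed {len(removed)} taxa {removed}")
    return new


def exclude_taxa(table: CountTable, exclusion_list: Iterable[str]) -> CountTable:
    """Drop a user-supplied list of taxa (e.g. externally flagged contaminants)."""
    excl = [t for t in exclusion_list if t in table.counts.index]
    kept = table.counts.drop(index=excl)
    new = CountTable(kept, table.sample_meta.copy(), list(table.provenance))
    new.log(f"exclude_taxa: removed {len(excl)} taxa {excl}")
    return new


def drop_low_depth_samples(table: CountTable, min_reads: int = 1000) -> CountTable:
    """Drop samples with total read count strictly below ``min_reads``.

    A sample with exactly ``min_reads`` reads is retained (the rule is
    strict "<"). Removing every sample yields an empty-sample table with
    a provenance warning, not an error.
    """
    if min_reads < 1:
        raise CountTableError("min_reads must be >= 1")
    totals = table.sample_totals()
    removed = totals.index[totals < min_reads].tolist()
    kept = table.counts.loc[:, totals >= min_reads]
    new = CountTable(kept, table.sample_meta.copy(), list(table.provenance))
    new.log(f"drop_low_depth_samples(min_reads={min_reads}): removed {len(removed)} samples {removed}")
    if kept.shape[1] == 0:
        new.log("warning: all samples removed by depth filter")
    return new


def aggregate_to_rank(
    table: CountTable,
    taxonomy: TaxonomyMap,
    rank: str,
    drop_unassigned: bool = False,
) -> CountTable:
    """Sum counts within each value of a taxonomic rank, per sample.

    With ``drop_unassigned`` unset the per-sample column sums are
    conserved exactly; set, rows whose rank value is ``"unassigned"``
    are excluded before summation.
    """
    missing = [t for t in table.taxon_ids if t not in taxonomy.lineages.index]
    if missing:
        raise CountTableError(f"taxa missing from taxonomy: {missing}")
    labels = taxonomy.rank_of(rank).reindex(table.counts.index)
    grouped = table.counts.groupby(labels, sort=True).sum()
    grouped.index.name = "taxon_id"
    n_unassigned = 0
    if drop_unassigned and UNASSIGNED in grouped.index:
        n_unassigned = int((labels == UNASSIGNED).sum())
        grouped = grouped.drop(index=UNASSIGNED)
    new = CountTable(grouped, table.sample_meta.copy(), list(table.provenance))
    new.log(
        f"aggregate_to_rank(rank={rank}, drop_unassigned={drop_unassigned}): "
        f"{table.n_taxa} taxa -> {new.n_taxa} groups"
        + (f"; dropped {n_unassigned} unassigned taxa" if drop_unassigned else "")
    )
    return new


def relative_abundance(table: CountTable) -> pd.DataFrame:
    """Close each sample column to sum 1.

    Raises on a zero-sum column, naming the sample.
    """
    totals = table.sample_totals()
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise CountTableError(f"zero-sum samples: {zero}")
    return table.counts / totals
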