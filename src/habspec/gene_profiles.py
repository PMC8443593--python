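"""Metagenomic marker-gene profiling arithmetic.

Read-level homology hits (BLAST/DIAMOND outfmt-6 style) are filtered
by query coverage and per-family identity thresholds, reduced to one
best hit per read, and normalized to RPKM (reads per kilobase of gene
per million reads). Dividing a gene's RPKM by the geometric mean RPKM
of 14 universal single-copy ribosomal marker genes gives its average
copy number per cell — i.e. the fraction of community members encoding
it. Process-level roll-ups, MAG completeness-normalized gene
occurrence, the pathway-presence rule, and MAG quality tiers complete
the genome-resolved side of the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

N_RIBOSOMAL_MARKERS = 14

#: outfmt-6 standard column order
BLAST6_COLUMNS = [
    "query_id",
    "target_gene_id",
    "percent_identity",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]

HIT_COLUMNS = [
    "query_id",
    "target_gene_id",
    "gene_family",
    "percent_identity",
    "query_coverage",
    "bitscore",
    "target_length_bp",
]


class GeneProfileError(ValueError):
    """Invalid configuration or hit-table input."""


@dataclass
class ThresholdConfig:
    """Identity/coverage thresholds for hit filtering.

    ``default_identity`` applies to every gene family without an
    override; families with stricter cutoffs (e.g. CoxL at 60, PsbA at
    70, PsaA at 80) go in ``identity_overrides``. Coverage is a strict
    ``>`` rule; identity is ``>=`` its threshold. ``min_read_length_bp``
    is applied upstream of hit generation by the caller and recorded
    here for provenance only.
    """

    default_identity: float = 50.0
    identity_overrides: dict[str, float] = field(default_factory=dict)
    coverage: float = 80.0
    min_read_length_bp: int = 140
    known_families: set[str] | None = None

    def __post_init__(self) -> None:
        for name, value in [("default_identity", self.default_identity), ("coverage", self.coverage)]:
            if not 0 < value <= 100:
                raise GeneProfileError(f"{name} must be in (0, 100], got {value}")
        for fam, value in self.identity_overrides.items():
            if not 0 < value <= 100:
                raise GeneProfileError(f"identity override for {fam} must be in (0, 100]")
        if self.known_families is not None:
            unknown = set(self.identity_overrides) - self.known_families
            if unknown:
                raise GeneProfileError(f"overrides for unknown gene families: {sorted(unknown)}")

    def identity_for(self, family: str) -> float:
        return self.identity_overrides.get(family, self.default_identity)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThresholdConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(
            default_identity=doc.get("default_identity", 50.0),
            identity_overrides=doc.get("identity_overrides", {}) or {},
            coverage=doc.get("coverage", 80.0),
            min_read_length_bp=doc.get("min_read_length_bp", 140),
        )


def read_hit_table(
    path: str | Path,
    gene_families: dict[str, str] | None = None,
    gene_lengths: dict[str, int] | None = None,
    read_length_bp: int = 150,
    column_names: list[str] | None = None,
) -> pd.DataFrame:
    """Read outfmt-6 style tabular hits into the internal hit schema.

    ``gene_families`` maps target ids to gene family names (default:
    the prefix of the target id before the last ``_``); query coverage
    is derived as alignment length x 3 / read length for protein
    alignments of nucleotide reads when not supplied as a column.
    """
    names = column_names or BLAST6_COLUMNS
    df = pd.read_csv(path, sep="\t", names=names, comment="#")
    if "query_coverage" not in df.columns:
        df["query_coverage"] = (df["length"] * 3 / read_length_bp * 100).clip(upper=100.0)
    if gene_families is None:
        df["gene_family"] = df["target_gene_id"].str.rsplit("_", n=1).str[0]
    else:
        df["gene_family"] = df["target_gene_id"].map(gene_families)
    if gene_lengths is not None:
        df["target_length_bp"] = df["target_gene_id"].map(gene_lengths)
    if "target_length_bp" not in df.columns:
        raise GeneProfileError("gene lengths required (gene_lengths map or target_length_bp column)")
    return df[HIT_COLUMNS]


def validate_hits(hits: pd.DataFrame) -> None:
    missing = set(HIT_COLUMNS) - set(hits.columns)
    if missing:
        raise GeneProfileError(f"hit table missing columns: {sorted(missing)}")
    if len(hits) == 0:
        return
    if (hits["target_length_bp"] <= 0).any():
        raise GeneProfileError("target lengths must be > 0")
    for col in ("percent_identity", "query_coverage"):
        if ((hits[col] < 0) | (hits[col] > 100)).any():
            raise GeneProfileError(f"{col} outside [0, 100]")


def filter_hits(hits: pd.DataFrame, cfg: ThresholdConfig) -> tuple[pd.DataFrame, dict[str, int]]:
    """Best-hit reduction then threshold filtering.

    Each query keeps its single best hit (max bitscore, ties broken by
    higher identity then first occurrence), which is then retained only
    if query coverage > ``cfg.coverage`` and identity >= the family's
    threshold. Returns the retained rows and per-reason removal counts;
    retained + removed always equals the input row count.
    """
    validate_hits(hits)
    removed = {"not_best_hit": 0, "low_coverage": 0, "low_identity": 0}
    if len(hits) == 0:
        return hits.copy(), removed
    ranked = hits.reset_index(drop=True)
    order = ranked.sort_values(
        ["query_id", "bitscore", "percent_identity"],
        ascending=[True, False, False],
        kind="stable",
    )
    best = order.drop_duplicates("query_id", keep="first")
    removed["not_best_hit"] = len(ranked) - len(best)
    cov_ok = best["query_coverage"] > cfg.coverage
    removed["low_coverage"] = int((~cov_ok).sum())
    best = best[cov_ok]
    thresholds = best["gene_family"].map(cfg.identity_for)
    id_ok = best["percent_identity"] >= thresholds
    removed["low_identity"] = int((~id_ok).sum())
    out = best[id_ok].sort_index().reset_index(drop=True)
    return out, removed


def rpkm(read_count: float, gene_length_bp: float, total_reads: int) -> float:
    """Reads per kilobase of gene per million total reads.

    count / (total_reads / 1e6) / (length / 1e3).
    """
    if gene_length_bp <= 0:
        raise GeneProfileError("gene length must be > 0")
    if total_reads <= 0:
        raise GeneProfileError("total read count must be > 0")
    return float(read_count) / (total_reads / 1e6) / (gene_length_bp / 1e3)


def copy_number(
    gene_rpkm: float,
    marker_rpkms: "np.ndarray | list[float]",
    pseudo_floor: bool = False,
) -> float:
    """Average per-cell copy number: gene RPKM / geomean(marker RPKMs).

    The markers are the universal single-copy ribosomal genes whose
    geometric-mean RPKM estimates total cell abundance; a result of 1.0
    therefore means one copy per cell, i.e. 100% of the community. A
    zero marker RPKM makes the geometric mean degenerate and raises by
    default; with ``pseudo_floor`` zeros are replaced by the smallest
    positive marker RPKM / 10 (logged use-at-own-risk behaviour).
    """
    markers = np.asarray(marker_rpkms, dtype=float)
    if (markers < 0).any():
        raise GeneProfileError("marker RPKMs must be non-negative")
    if (markers == 0).any():
        if not pseudo_floor:
            raise GeneProfileError(
                "zero RPKM ribosomal marker: geometric mean undefined "
                "(enable pseudo_floor to impute)"
            )
        positive = markers[markers > 0]
        if positive.size == 0:
            raise GeneProfileError("all marker RPKMs are zero")
        markers = np.where(markers == 0, positive.min() / 10, markers)
    return float(gene_rpkm / stats.gmean(markers))


def gene_profile(
    hits: pd.DataFrame,
    cfg: ThresholdConfig,
    total_reads: int,
    marker_families: list[str],
    pseudo_floor: bool = False,
) -> pd.DataFrame:
    """Filter hits and compute per-family read count, RPKM and copy number.

    ``marker_families`` names the single-copy ribosomal families whose
    geometric mean anchors the per-cell normalization; they must all be
    detected. Output is indexed by gene family with columns
    ``filtered_read_count``, ``rpkm``, ``copy_number_per_cell``,
    ``community_percent`` (= 100 x copy number) and ``is_marker``.
    """
    if len(marker_families) == 0:
        raise GeneProfileError("need at least one marker family")
    kept, _ = filter_hits(hits, cfg)
    grouped = kept.groupby("gene_family").agg(
        filtered_read_count=("query_id", "size"),
        mean_length=("target_length_bp", "mean"),
    )
    families = sorted(set(grouped.index) | set(marker_families))
    out = grouped.reindex(families).fillna({"filtered_read_count": 0})
    out["rpkm"] = [
        rpkm(row.filtered_read_count, row.mean_length, total_reads)
        if row.filtered_read_count > 0
        else 0.0
        for row in out.itertuples()
    ]
    marker_rpkms = out.loc[marker_families, "rpkm"].to_numpy()
    if (marker_rpkms == 0).any() and not pseudo_floor:
        zero = [f for f, r in zip(marker_families, marker_rpkms) if r == 0]
        raise GeneProfileError(f"markers with zero RPKM: {zero}")
    out["copy_number_per_cell"] = [
        copy_number(r, marker_rpkms, pseudo_floor=pseudo_floor) for r in out["rpkm"]
    ]
    out["community_percent"] = 100.0 * out["copy_number_per_cell"]
    out["is_marker"] = out.index.isin(marker_families)
    out.index.name = "gene_family"
    return out.drop(columns=["mean_length"])


def process_rollup(
    profile: pd.DataFrame,
    process_map: dict[str, list[str]],
    averaged_processes: tuple[str, ...] = ("oxygenic_photosynthesis",),
) -> pd.DataFrame:
    """Community percent per metabolic process.

    Member-gene community percentages are summed per process and capped
    at 100 (a cell encoding two member genes is still one cell). The
    named ``averaged_processes`` instead take the arithmetic mean of
    their members — used for oxygenic photosynthesis, where PsaA and
    PsbA are both required and their hit averages estimate the same set
    of cells.
    """
    rows = []
    for process, members in process_map.items():
        if not members:
            raise GeneProfileError(f"process {process!r} has no member genes")
        percents = [
            float(profile.loc[m, "community_percent"]) if m in profile.index else 0.0
            for m in members
        ]
        if process in averaged_processes:
            value = float(np.mean(percents))
            capped = False
        else:
            raw = float(np.sum(percents))
            value = min(raw, 100.0)
            capped = raw > 100.0
        rows.append((process, value, capped))
    return pd.DataFrame(rows, columns=["process", "community_percent", "capped"]).set_index("process")


# ---------------------------------------------------------------------------
# MAG-level summaries
# ---------------------------------------------------------------------------

def read_mag_summary(path: str | Path) -> pd.DataFrame:
    """MAG summary TSV: mag_id, order, completeness, contamination, genes_present.

    ``genes_present`` is a comma-separated gene family list.
    """
    df = pd.read_csv(path, sep="\t", dtype={"mag_id": str, "order": str})
    required = {"mag_id", "order", "completeness", "contamination", "genes_present"}
    missing = required - set(df.columns)
    if missing:
        raise GeneProfileError(f"{path}: MAG summary missing columns {sorted(missing)}")
    df["genes_present"] = df["genes_present"].fillna("").map(
        lambda s: frozenset(g for g in str(s).split(",") if g)
    )
    return df.set_index("mag_id")


def mag_quality_tier(completeness: float, contamination: float) -> str:
    """Quality tier: high (>90% complete, <5% contaminated), medium
    (>50%, <10%), or fail."""
    for value, name in ((completeness, "completeness"), (contamination, "contamination")):
        if not 0 <= value <= 100:
            raise GeneProfileError(f"{name} {value} outside [0, 100]")
    if completeness > 90 and contamination < 5:
        return "high"
    if completeness > 50 and contamination < 10:
        return "medium"
    return "fail"


def mag_occurrence(mags: pd.DataFrame, gene: str, group_by: str = "order") -> pd.DataFrame:
    """Percent of MAGs per order carrying a gene, completeness-normalized.

    Raw percent = 100 x carriers / MAGs in the order. Incomplete MAGs
    undercount gene carriage, so the normalized value divides the raw
    percent by the order's mean completeness fraction; values above 100
    are reported capped with ``capped=True`` and the uncapped value is
    kept alongside.
    """
    rows = []
    for group, sub in mags.groupby(group_by):
        n = len(sub)
        if n == 0:
            continue
        carriers = sum(1 for genes in sub["genes_present"] if gene in genes)
        raw = 100.0 * carriers / n
        mean_completeness = float(sub["completeness"].mean()) / 100.0
        if mean_completeness <= 0:
            raise GeneProfileError(f"order {group!r} has zero mean completeness")
        uncapped = raw / mean_completeness
        rows.append(
            (group, n, carriers, raw, uncapped, min(uncapped, 100.0), uncapped > 100.0)
        )
    return pd.DataFrame(
        rows,
        columns=[
            group_by,
            "n_mags",
            "n_with_gene",
            "raw_percent",
            "normalized_percent_uncapped",
            "normalized_percent",
            "capped",
        ],
    ).set_index(group_by)


def pathway_presence(genes_detected: set[str], pathway_def: set[str]) -> tuple[bool, float]:
    """Pathway present iff strictly more than 70% of its genes are detected.

    Returns (present, detected fraction). 7 of 10 genes (exactly 0.7)
    is absent; 8 of 10 is present.
    """
    if not pathway_def:
        raise GeneProfileError("pathway definition is empty")
    detected = len(set(genes_detected) & set(pathway_def))
    fraction = detected / len(pathway_def)
    return fraction > 0.7, fraction
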