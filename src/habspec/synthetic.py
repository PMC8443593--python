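"""Synthetic communities and metagenome hit tables with planted truth.

The community generator emulates a structured sediment survey: samples
on a zones x depth-layers x dates grid (default 2 x 3 x 8 = 48), taxa
split into habitat generalists — one expected density shared by every
(zone, depth) class, jittered per sample by modest log-normal temporal
noise — and specialists, whose expected density is positive only on a
proper subset of the classes and noisier where present. Reads are drawn
multinomially per sample at a variable depth, so downstream statistics
see realistic compositional sampling noise and every taxon's true role
is known.

The hit-table generator plants known genome content: each genome
carries the 14 single-copy ribosomal markers exactly once plus
arbitrary metabolic gene copy numbers; expected read counts are
proportional to abundance x copy number x gene length, realized as
Poisson, and each read becomes one tabular hit row with configurable
identity/coverage draws so threshold filtering is exercisable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from habspec.core_tables import CountTable, CountTableError
from habspec.gene_profiles import HIT_COLUMNS, N_RIBOSOMAL_MARKERS

#: single-copy ribosomal protein marker families used for per-cell
#: normalization (one per genome by construction)
DEFAULT_MARKERS = tuple(f"RibosomalS{i:02d}" for i in range(1, N_RIBOSOMAL_MARKERS + 1))


@dataclass
class CommunityDesign:
    """Parameters of the planted generalist/specialist community.

    Defaults mirror a 2-zone x 3-depth x 8-date survey (48 samples)
    with 40 generalists and 40 specialists, 5,000-50,000 reads per
    sample, log-normal temporal noise (sd 0.3 for generalists, 0.8 for
    specialists) and log-normal(0, 1) base abundances. Specialists
    occupy 1-2 of the 6 zone x depth classes.
    """

    zones: tuple[str, ...] = ("intertidal", "subtidal")
    depth_layers: tuple[str, ...] = ("shallow", "intermediate", "deep")
    dates: tuple[int, ...] = tuple(30 * i for i in range(8))  # ordinal days
    reads_per_sample: tuple[int, int] = (5000, 50000)
    n_generalists: int = 40
    n_specialists: int = 40
    generalist_noise_sd: float = 0.3
    specialist_noise_sd: float = 0.8
    specialist_n_classes: tuple[int, int] = (1, 2)
    base_abundance_mu: float = 0.0
    base_abundance_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_generalists + self.n_specialists < 1:
            raise CountTableError("design needs at least one taxon")
        if not (self.zones and self.depth_layers and self.dates):
            raise CountTableError("design needs >= 1 zone, depth layer and date")
        if self.reads_per_sample[0] < 1 or self.reads_per_sample[1] < self.reads_per_sample[0]:
            raise CountTableError("reads_per_sample must be a positive (low, high) range")
        n_classes = len(self.zones) * len(self.depth_layers)
        lo, hi = self.specialist_n_classes
        if self.n_specialists > 0 and not (1 <= lo <= hi < n_classes):
            raise CountTableError(
                "specialist class subsets must be non-empty proper subsets "
                f"(have {n_classes} classes, requested {lo}-{hi})"
            )
        if self.specialist_noise_sd <= self.generalist_noise_sd:
            raise CountTableError("specialists must be noisier than generalists")

    @property
    def n_classes(self) -> int:
        return len(self.zones) * len(self.depth_layers)

    @property
    def n_samples(self) -> int:
        return self.n_classes * len(self.dates)


@dataclass
class TruthTable:
    """Planted role and expected per-class density for every taxon."""

    roles: pd.Series  # taxon_id -> "generalist" | "specialist"
    expected_density: pd.DataFrame  # taxa x (zone|depth) classes, rows sum to anything
    specialist_classes: dict[str, frozenset[str]] = field(default_factory=dict)

    def taxa_with_role(self, role: str) -> list[str]:
        return self.roles.index[self.roles == role].tolist()


def simulate_community(design: CommunityDesign) -> tuple[CountTable, TruthTable]:
    """Draw a community count table from a planted design.

    One sample per (zone, depth, date) cell. Per sample, each taxon's
    expected density is its class density times a log-normal
    perturbation; reads are then multinomial with the sample's
    (uniformly drawn) depth over the normalized densities. Identical
    seed gives identical output.
    """
    rng = np.random.default_rng(design.seed)
    classes = [f"{z}|{d}" for z in design.zones for d in design.depth_layers]
    n_tax = design.n_generalists + design.n_specialists
    taxa = [f"gen{i:03d}" for i in range(design.n_generalists)] + [
        f"spec{i:03d}" for i in range(design.n_specialists)
    ]
    roles = pd.Series(
        ["generalist"] * design.n_generalists + ["specialist"] * design.n_specialists,
        index=taxa,
    )

    base = rng.lognormal(design.base_abundance_mu, design.base_abundance_sigma, size=n_tax)
    density = np.zeros((n_tax, len(classes)))
    density[: design.n_generalists, :] = base[: design.n_generalists, None]
    specialist_classes: dict[str, frozenset[str]] = {}
    lo, hi = design.specialist_n_classes
    for k in range(design.n_specialists):
        row = design.n_generalists + k
        n_occ = int(rng.integers(lo, hi + 1))
        occ = rng.choice(len(classes), size=n_occ, replace=False)
        density[row, occ] = base[row]
        specialist_classes[taxa[row]] = frozenset(classes[j] for j in occ)

    sample_ids, meta_rows, columns = [], [], []
    noise_sd = np.where(
        roles.to_numpy() == "generalist", design.generalist_noise_sd, design.specialist_noise_sd
    )
    for ci, (zone, depth) in enumerate(
        (z, d) for z in design.zones for d in design.depth_layers
    ):
        for date in design.dates:
            sid = f"{zone[:3]}_{depth[:3]}_d{date:03d}"
            sample_ids.append(sid)
            meta_rows.append((zone, depth, date))
            expected = density[:, ci] * rng.lognormal(0.0, noise_sd, size=n_tax)
            total = expected.sum()
            if total <= 0:
                raise CountTableError("degenerate design: a sample has zero expected density")
            depth_reads = int(rng.integers(design.reads_per_sample[0], design.reads_per_sample[1] + 1))
            columns.append(rng.multinomial(depth_reads, expected / total))
    counts = pd.DataFrame(
        np.column_stack(columns).astype(np.int64),
        index=pd.Index(taxa, name="taxon_id"),
        columns=sample_ids,
    )
    meta = pd.DataFrame(
        meta_rows, columns=["zone", "depth_layer", "date"], index=pd.Index(sample_ids, name="sample_id")
    )
    table = CountTable(counts, meta)
    table.log(
        f"simulate_community(seed={design.seed}): {n_tax} taxa x {len(sample_ids)} samples "
        f"({design.n_generalists} generalists, {design.n_specialists} specialists)"
    )
    truth = TruthTable(
        roles=roles,
        expected_density=pd.DataFrame(density, index=taxa, columns=classes),
        specialist_classes=specialist_classes,
    )
    return table, truth


@dataclass
class HitSimConfig:
    """Identity/coverage draw parameters per gene family (truncated normals)."""

    identity_mean: float = 75.0
    identity_sd: float = 8.0
    coverage_mean: float = 92.0
    coverage_sd: float = 5.0
    per_family: dict[str, dict[str, float]] = field(default_factory=dict)

    def params_for(self, family: str) -> tuple[float, float, float, float]:
        p = self.per_family.get(family, {})
        return (
            p.get("identity_mean", self.identity_mean),
            p.get("identity_sd", self.identity_sd),
            p.get("coverage_mean", self.coverage_mean),
            p.get("coverage_sd", self.coverage_sd),
        )


def simulate_metagenome_hits(
    genomes: dict[str, dict[str, int]],
    genome_abundances: dict[str, float],
    total_reads: int,
    gene_lengths: dict[str, int],
    seed: int = 0,
    markers: tuple[str, ...] = DEFAULT_MARKERS,
    hit_config: HitSimConfig | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a per-read hit table from known genome content.

    ``genomes`` maps genome id -> {gene family: copy number}; every
    genome must carry each of the 14 ribosomal ``markers`` exactly
    once. Expected reads for a gene are proportional to
    sum_g(abundance_g x copy_g x length) and realized counts are
    Poisson (total_reads sets the expected grand total). Returns the
    hit table (one row per read) and the realized true read count per
    gene family.
    """
    if not genomes:
        raise CountTableError("need at least one genome")
    for gid, content in genomes.items():
        for marker in markers:
            if content.get(marker, 0) != 1:
                raise CountTableError(
                    f"genome {gid!r}: marker {marker!r} must be present single-copy"
                )
    families = sorted({f for content in genomes.values() for f in content} | set(markers))
    for fam in families:
        if gene_lengths.get(fam, 0) <= 0:
            raise CountTableError(f"gene length for {fam!r} missing or non-positive")
    hit_config = hit_config or HitSimConfig()
    rng = np.random.default_rng(seed)

    weights = np.array(
        [
            sum(
                genome_abundances[gid] * content.get(fam, 0) * gene_lengths[fam]
                for gid, content in genomes.items()
            )
            for fam in families
        ],
        dtype=float,
    )
    if weights.sum() <= 0:
        raise CountTableError("no positive expected read mass")
    expected = total_reads * weights / weights.sum()
    realized = rng.poisson(expected)

    rows = []
    read_no = 0
    for fam, count in zip(families, realized):
        if count == 0:
            continue
        id_mu, id_sd, cov_mu, cov_sd = hit_config.params_for(fam)
        identities = np.clip(rng.normal(id_mu, id_sd, size=count), 0.0, 100.0)
        coverages = np.clip(rng.normal(cov_mu, cov_sd, size=count), 0.0, 100.0)
        bitscores = np.maximum(rng.normal(40 + 2 * identities, 10, size=count), 1.0)
        for j in range(count):
            rows.append(
                (
                    f"read{read_no:08d}",
                    f"{fam}_t1",
                    fam,
                    identities[j],
                    coverages[j],
                    bitscores[j],
                    gene_lengths[fam],
                )
            )
            read_no += 1
    hits = pd.DataFrame(rows, columns=HIT_COLUMNS)
    true_counts = pd.Series(realized, index=pd.Index(families, name="gene_family"), name="true_reads")
    return hits, true_counts


def write_truth_json(truth: TruthTable, path) -> None:
    """Dump the planted roles/classes to JSON for CLI consumers."""
    import json

    doc = {
        "roles": truth.roles.to_dict(),
        "specialist_classes": {k: sorted(v) for k, v in truth.specialist_classes.items()},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
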