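"""Rarefaction, repeated-rarefaction occupancy, and Shannon diversity.

Rarefaction subsamples each sample's reads *without replacement*
(multivariate hypergeometric) to a common depth; samples below the
depth are excluded rather than kept un-rarefied. Occupancy — the
number of samples in which a taxon is detected — is averaged over many
independent rarefactions so that rare taxa get fractional occupancy
reflecting their detection probability at the chosen depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from habspec.core_tables import CountTable, CountTableError


@dataclass
class OccupancyResult:
    """Per-taxon mean occupancy over repeated rarefactions.

    Attributes
    ----------
    per_taxon
        DataFrame indexed by taxon id with columns ``mean_occupancy``
        (real, in [0, n_samples_considered]), ``total_count`` (raw
        dataset-wide count) .
    n_samples_considered
        Number of samples retained at the rarefaction depth.
    depth, reps
        Rarefaction depth and number of repetitions used.
    """

    per_taxon: pd.DataFrame
    n_samples_considered: int
    depth: int
    reps: int


def rarefy(table: CountTable, depth: int, seed: int | np.random.SeedSequence) -> CountTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are excluded and
    logged; a sample with exactly ``depth`` reads is returned unchanged
    (the hypergeometric draw of all reads is the identity). Seeded and
    reproducible.
    """
    if depth < 1:
        raise CountTableError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep = totals.index[totals >= depth].tolist()
    dropped = totals.index[totals < depth].tolist()
    arr = table.counts[keep].to_numpy()
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        if col.sum() == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    counts = pd.DataFrame(out, index=table.counts.index, columns=keep)
    new = CountTable(counts, table.sample_meta.copy(), list(table.provenance))
    new.log(f"rarefy(depth={depth}): excluded {len(dropped)} samples {dropped}")
    if not keep:
        new.log("warning: no sample reaches rarefaction depth")
    return new


def mean_occupancy(
    table: CountTable,
    depth: int = 5000,
    reps: int = 200,
    seed: int | np.random.SeedSequence = 0,
) -> OccupancyResult:
    """Average occupancy over ``reps`` independent rarefactions.

    Occupancy per rarefaction is the number of retained samples in
    which the taxon has at least one post-rarefaction read. Per-rep
    random streams are spawned from the master seed with a counter
    scheme, so results are reproducible and rep-order independent.
    """
    if reps < 1:
        raise CountTableError("reps must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(reps)
    occ_sum = np.zeros(table.n_taxa)
    n_considered = None
    for child in children:
        r = rarefy(table, depth, child)
        if n_considered is None:
            n_considered = r.n_samples
        occ_sum += (r.counts.to_numpy() >= 1).sum(axis=1)
    per_taxon = pd.DataFrame(
        {
            "mean_occupancy": occ_sum / reps,
            "total_count": table.taxon_totals().to_numpy(),
        },
        index=table.counts.index,
    )
    return OccupancyResult(per_taxon, int(n_considered or 0), depth, reps)


def shannon(table: CountTable, rarefied: bool = False) -> pd.Series:
    """Shannon diversity H = -sum p_i ln p_i per sample (natural log).

    Zero counts contribute nothing. ``rarefied`` is a provenance flag
    only: callers rarefy first if they want depth-standardized H.
    """
    totals = table.sample_totals()
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise CountTableError(f"zero-sum samples: {zero}")
    h = table.counts.apply(lambda col: stats.entropy(col.to_numpy()), axis=0)
    h.name = "shannon"
    return h


def occupancy_abundance(table: CountTable, occ: OccupancyResult) -> pd.DataFrame:
    """Per-taxon (total sequence count, mean occupancy) pairs.

    The classic occupancy-abundance relationship: abundant taxa tend to
    occupy more samples. Output has one row per taxon of ``table``,
    suitable for log-abundance vs occupancy plotting.
    """
    out = pd.DataFrame(
        {
            "total_count": table.taxon_totals(),
            "mean_occupancy": occ.per_taxon["mean_occupancy"].reindex(table.counts.index).fillna(0.0),
        },
        index=table.counts.index,
    )
    return out
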