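"""Bias-corrected specialization index and generalist/specialist labels.

The specialization index (SI) of a taxon is the coefficient of
variation (sd/mean) of its densities across habitat classes, minus the
expected sampling bias ``sqrt(K / N)`` where K is the number of habitat
classes and N the taxon's total individual count. The bias term is the
expected CV of a taxon whose counts are Poisson with uniform intensity
across classes — so a perfectly even but undersampled taxon scores
near 0 rather than inheriting a spuriously high CV. Taxa are then
labelled relative habitat generalists (SI below a cutoff, by default
the community mean SI) or specialists (SI at or above it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from habspec.core_tables import CountTable, CountTableError, relative_abundance


@dataclass
class HabitatClassing:
    """Assignment of samples to habitat classes.

    ``per_sample`` mode treats every sample as its own class (K =
    number of samples), matching a CV "across samples". ``grouped``
    mode pools samples sharing metadata values (e.g. zone x depth) so
    dates act as replicates within a class.
    """

    assignment: pd.Series  # sample_id -> class_id
    mode: str = "per_sample"

    def __post_init__(self) -> None:
        if self.assignment.isna().any():
            raise CountTableError("every sample needs a habitat class")
        if self.K < 2:
            raise CountTableError("need at least 2 habitat classes")

    @property
    def K(self) -> int:
        return int(self.assignment.nunique())

    @classmethod
    def per_sample(cls, table: CountTable) -> "HabitatClassing":
        ids = pd.Index(table.sample_ids)
        return cls(pd.Series(ids, index=ids), mode="per_sample")

    @classmethod
    def grouped(cls, table: CountTable, keys: list[str]) -> "HabitatClassing":
        meta = table.sample_meta.loc[table.sample_ids, keys].astype(str)
        labels = meta.agg("|".join, axis=1)
        return cls(labels, mode=f"grouped({','.join(keys)})")


@dataclass
class SIResult:
    """Per-taxon raw CV, bias, corrected SI and label.

    ``per_taxon`` columns: raw_si, N, bias, si, label; label is
    "generalist", "specialist" or "NA" (taxon absent from the data).
    ``cutoff`` is filled by :func:`classify`.
    """

    per_taxon: pd.DataFrame
    K: int
    mode: str
    cutoff: float | None = None
    extra: dict = field(default_factory=dict)

    @property
    def community_mean(self) -> float:
        return float(self.per_taxon["si"].dropna().mean())


def raw_si(densities: np.ndarray | list[float]) -> float:
    """Coefficient of variation sd/mean with sample sd (n-1 denominator).

    Undefined (returns NaN) when the mean is 0, i.e. the taxon is
    absent from every class.
    """
    d = np.asarray(densities, dtype=float)
    if d.size < 2:
        raise CountTableError("raw_si needs at least 2 classes")
    m = d.mean()
    if m == 0:
        return float("nan")
    return float(d.std(ddof=1) / m)


def si_bias(K: int, N: int) -> float:
    """Expected CV bias sqrt(K/N) for Poisson counts over K classes."""
    if K < 2:
        raise CountTableError("K must be >= 2")
    if N < 1:
        raise CountTableError("N must be >= 1")
    return float(np.sqrt(K / N))


def specialization_index(
    table: CountTable,
    classing: HabitatClassing | None = None,
    use_relative: bool = True,
) -> SIResult:
    """Per-taxon corrected specialization index.

    For each taxon the density in a class is the mean relative
    abundance over the class's samples (the raw count proportions when
    ``use_relative``; raw counts otherwise, useful on rarefied tables
    where column sums are equal anyway). N is the taxon's total *raw*
    count — the true sampling effort behind the bias term. Taxa with
    zero total get label "NA" and are excluded from community means.
    """
    if classing is None:
        classing = HabitatClassing.per_sample(table)
    missing = set(table.sample_ids) - set(classing.assignment.index)
    if missing:
        raise CountTableError(f"samples without habitat class: {sorted(missing)}")
    data = relative_abundance(table) if use_relative else table.counts.astype(float)
    classes = classing.assignment.loc[table.sample_ids]
    # density per class = mean over samples within the class
    class_density = data.T.groupby(classes).mean().T  # taxa x classes
    K = classing.K
    N = table.taxon_totals()

    dens = class_density.to_numpy()
    means = dens.mean(axis=1)
    sds = dens.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(means > 0, sds / means, np.nan)
    bias = np.where(N.to_numpy() > 0, np.sqrt(K / np.maximum(N.to_numpy(), 1)), np.nan)
    si = raw - bias
    per_taxon = pd.DataFrame(
        {
            "raw_si": raw,
            "N": N.to_numpy(),
            "bias": bias,
            "si": si,
            "label": np.where(N.to_numpy() > 0, "unclassified", "NA"),
        },
        index=table.counts.index,
    )
    return SIResult(per_taxon, K=K, mode=classing.mode)


def classify(result: SIResult, cutoff: float | str = "community_mean") -> SIResult:
    """Label taxa as generalist (si < cutoff) or specialist (si >= cutoff).

    The default cutoff is the mean SI over all non-NA taxa — the
    "relative" in relative generalist/specialist. Ties at the cutoff
    are specialists (the rule defines generalists strictly *below* the
    cutoff). Idempotent: reclassifying with the same cutoff changes
    nothing.
    """
    valid = result.per_taxon["si"].dropna()
    if valid.empty:
        raise CountTableError("no taxon with a defined SI to classify")
    cut = float(valid.mean()) if cutoff == "community_mean" else float(cutoff)
    labels = pd.Series("NA", index=result.per_taxon.index, dtype=object)
    labels[valid.index[valid < cut]] = "generalist"
    labels[valid.index[valid >= cut]] = "specialist"
    per_taxon = result.per_taxon.copy()
    per_taxon["label"] = labels
    return SIResult(per_taxon, K=result.K, mode=result.mode, cutoff=cut, extra=dict(result.extra))
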