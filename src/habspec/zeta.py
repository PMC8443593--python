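"""Zeta diversity: decline over orders and temporal decay.

Zeta diversity of order *i* is the mean number of taxa shared by *i*
samples simultaneously, averaged over sample combinations; the Jaccard
normalization divides each combination's shared count by its union
richness, removing sample-richness effects and bounding values in
[0, 1]. The decline of zeta with order is summarised by competing
power-law and exponential fits selected by AIC; the temporal decay of
pairwise (order-2) zeta with time separation is fitted as a power law
with bootstrap confidence intervals.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from habspec.core_tables import CountTable, CountTableError

logger = logging.getLogger(__name__)

#: exact enumeration is used when C(n, i) is at most this many combinations
EXACT_CEILING = 100_000

_COMBO_CHUNK = 4096


@dataclass
class PresenceMatrix:
    """Boolean taxa x samples matrix with sample dates attached."""

    presence: pd.DataFrame
    dates: pd.Series | None = None  # sample_id -> ordinal day or datetime

    @property
    def n_samples(self) -> int:
        return self.presence.shape[1]


def presence_matrix(table: CountTable, date_key: str = "date") -> PresenceMatrix:
    """Presence/absence view of a count table (presence = count >= 1)."""
    pres = table.counts >= 1
    dates = None
    if date_key in table.sample_meta.columns:
        dates = table.sample_meta.loc[table.sample_ids, date_key]
    return PresenceMatrix(pres, dates)


def _combo_values(arr: np.ndarray, combos: np.ndarray, normalize: str) -> np.ndarray:
    """Shared-taxon value for each row of sample-index combinations.

    ``arr`` is bool taxa x samples. Vectorized over combination chunks:
    intersection = AND over the chosen columns, union = OR.
    """
    values = np.empty(len(combos))
    for start in range(0, len(combos), _COMBO_CHUNK):
        chunk = combos[start : start + _COMBO_CHUNK]  # (d, i)
        sub = arr[:, chunk]  # (taxa, d, i)
        inter = sub.all(axis=2).sum(axis=0).astype(float)
        if normalize == "jaccard":
            union = sub.any(axis=2).sum(axis=0).astype(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                v = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
        else:
            v = inter
        values[start : start + len(chunk)] = v
    return values


def zeta_order(
    p: PresenceMatrix,
    i: int,
    mode: str = "auto",
    n_draws: int = 1000,
    normalize: str = "none",
    seed: int | np.random.SeedSequence | None = 0,
) -> tuple[float, float, int]:
    """Zeta diversity of order ``i``: (estimate, sd, combinations used).

    Exact mode averages over every C(n, i) combination; Monte-Carlo
    draws ``n_draws`` combinations (each of i distinct samples)
    uniformly. ``mode="auto"`` uses exact enumeration up to
    ``EXACT_CEILING`` combinations and falls back to Monte-Carlo with a
    logged notice. The sd reported is the spread of per-combination
    values (exact) or of the Monte-Carlo draws.
    """
    n = p.n_samples
    if not 1 <= i <= n:
        raise CountTableError(f"zeta order {i} out of range for {n} samples")
    if normalize not in ("none", "jaccard"):
        raise CountTableError(f"unknown normalization {normalize!r}")
    arr = p.presence.to_numpy()
    total = math.comb(n, i)
    if mode == "auto":
        if total <= EXACT_CEILING:
            mode = "exact"
        else:
            logger.info("C(%d,%d)=%d exceeds exact ceiling; using Monte-Carlo", n, i, total)
            mode = "monte_carlo"
    if mode == "exact":
        if total > EXACT_CEILING:
            raise CountTableError(
                f"C({n},{i})={total} exceeds exact ceiling {EXACT_CEILING}"
            )
        combos = np.fromiter(
            itertools.chain.from_iterable(itertools.combinations(range(n), i)),
            dtype=np.intp,
        ).reshape(total, i)
        values = _combo_values(arr, combos, normalize)
    elif mode == "monte_carlo":
        if n_draws < 1:
            raise CountTableError("n_draws must be >= 1")
        rng = np.random.default_rng(seed)
        # i distinct samples per draw: first i entries of a random permutation
        combos = np.argsort(rng.random((n_draws, n)), axis=1)[:, :i].astype(np.intp)
        values = _combo_values(arr, combos, normalize)
    else:
        raise CountTableError(f"unknown mode {mode!r}")
    return float(values.mean()), float(values.std(ddof=1)) if len(values) > 1 else 0.0, len(values)


@dataclass
class ZetaCurve:
    """Zeta estimates per order with estimator bookkeeping."""

    per_order: pd.DataFrame  # index order, columns zeta, sd, n_combos_used, mode
    normalization: str

    @property
    def orders(self) -> np.ndarray:
        return self.per_order.index.to_numpy()


def zeta_decline(
    p: PresenceMatrix,
    max_order: int = 8,
    reps: int = 1000,
    normalize: str = "jaccard",
    seed: int | np.random.SeedSequence | None = 0,
    include_order_1: bool = True,
) -> ZetaCurve:
    """Zeta estimates for orders 1..max_order (1 = mean richness).

    ``reps`` is the number of Monte-Carlo combination draws used for
    any order whose exact enumeration would exceed the ceiling.
    """
    if max_order > p.n_samples:
        raise CountTableError(
            f"max_order {max_order} exceeds {p.n_samples} samples"
        )
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(max_order)
    rows = []
    start = 1 if include_order_1 else 2
    for order in range(start, max_order + 1):
        exact_ok = math.comb(p.n_samples, order) <= EXACT_CEILING
        z, sd, n_used = zeta_order(
            p,
            order,
            mode="exact" if exact_ok else "monte_carlo",
            n_draws=reps,
            normalize=normalize,
            seed=children[order - 1],
        )
        rows.append((order, z, sd, n_used, "exact" if exact_ok else "monte_carlo"))
    per_order = pd.DataFrame(
        rows, columns=["order", "zeta", "sd", "n_combos_used", "mode"]
    ).set_index("order")
    # set-intersection monotonicity must hold on every exact unnormalized run
    if normalize == "none":
        exact = per_order[per_order["mode"] == "exact"]["zeta"]
        diffs = np.diff(exact.to_numpy())
        assert (diffs <= 1e-9).all(), "exact unnormalized zeta must be non-increasing"
    return ZetaCurve(per_order, normalization=normalize)


@dataclass
class DeclineFit:
    """Power-law vs exponential fits to a zeta decline curve.

    Both families are fitted as ordinary least squares on ln(zeta):
    against ln(order) for the power law and against order for the
    exponential, so their AICs (Gaussian log-likelihood on the shared
    ln-zeta response scale, k = 3: intercept, slope, error variance)
    are directly comparable. ``selected`` is the family with lower AIC.
    """

    fits: dict  # family -> {intercept, slope, aic, r2, n}
    selected: str
    dropped_orders: list[int] = field(default_factory=list)


def _ols_fit(x: np.ndarray, y: np.ndarray) -> dict:
    model = sm.OLS(y, sm.add_constant(x)).fit()
    n = len(y)
    rss = float(model.ssr)
    # floor the MLE variance so a numerically perfect fit gets a large
    # finite likelihood instead of an infinity
    sigma2 = max(rss / n, np.finfo(float).tiny)
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1)
    tss = float(model.centered_tss)
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss <= 1e-300 else 0.0)
    return {
        "intercept": float(model.params[0]),
        "slope": float(model.params[1]),
        "aic": float(2 * 3 - 2 * loglik),
        "r2": r2,
        "n": n,
    }


def fit_decline(curve: ZetaCurve) -> DeclineFit:
    """Fit and select power-law vs exponential decline by AIC.

    Orders with zeta = 0 are dropped with a warning (their log is
    undefined; a pseudo-count would manufacture curvature). Requires at
    least 3 positive orders of 2 and above.
    """
    sub = curve.per_order.loc[curve.per_order.index >= 2]
    positive = sub[sub["zeta"] > 0]
    dropped = sub.index[sub["zeta"] <= 0].tolist()
    if dropped:
        logger.warning("dropping zero-zeta orders before log fits: %s", dropped)
    if len(positive) < 3:
        raise CountTableError(
            f"need >= 3 orders with zeta > 0 to fit decline, have {len(positive)}"
        )
    orders = positive.index.to_numpy(dtype=float)
    lnz = np.log(positive["zeta"].to_numpy())
    fits = {
        "power_law": _ols_fit(np.log(orders), lnz),
        "exponential": _ols_fit(orders, lnz),
    }
    selected = min(fits, key=lambda f: fits[f]["aic"])
    return DeclineFit(fits=fits, selected=selected, dropped_orders=dropped)


@dataclass
class DecayResult:
    """Pairwise zeta vs time separation with a power-law fit."""

    pairs: pd.DataFrame  # columns dt_days, zeta
    slope: float
    intercept: float
    r2: float
    slope_ci: tuple[float, float]
    n_boot: int


def _pair_dt_days(dates: pd.Series) -> np.ndarray:
    numeric = pd.to_numeric(dates, errors="coerce")
    if not numeric.isna().any():  # ordinal day numbers
        return numeric.to_numpy(dtype=float)
    vals = pd.to_datetime(dates, errors="raise")
    return (vals - vals.min()).dt.days.to_numpy(dtype=float)


def zeta_decay(
    p: PresenceMatrix,
    order: int = 2,
    normalize: str = "jaccard",
    n_boot: int = 1000,
    seed: int | np.random.SeedSequence | None = 0,
) -> DecayResult:
    """Temporal decay of pairwise shared richness, power-law fitted.

    Every sample pair contributes (delta-t in days, normalized shared
    value); the regression is OLS of ln(zeta) on ln(delta-t) over pairs
    with zeta > 0 and delta-t > 0, and pairs are bootstrapped
    ``n_boot`` times for a percentile 95% CI of the slope. Requires at
    least 3 distinct positive delta-t values.
    """
    if order != 2:
        raise CountTableError("temporal decay is defined on sample pairs (order 2)")
    if p.dates is None:
        raise CountTableError("presence matrix has no sample dates")
    days = _pair_dt_days(p.dates)
    if len(np.unique(days)) < 2:
        raise CountTableError("need >= 2 distinct dates for temporal decay")
    arr = p.presence.to_numpy()
    n = p.n_samples
    combos = np.array(list(itertools.combinations(range(n), 2)), dtype=np.intp)
    values = _combo_values(arr, combos, normalize)
    dt = np.abs(days[combos[:, 0]] - days[combos[:, 1]])
    pairs = pd.DataFrame({"dt_days": dt, "zeta": values})

    usable = (pairs["zeta"] > 0) & (pairs["dt_days"] > 0)
    fit_df = pairs[usable]
    if fit_df["dt_days"].nunique() < 3:
        raise CountTableError(
            "need >= 3 distinct positive time separations to fit decay"
        )
    x = np.log(fit_df["dt_days"].to_numpy())
    y = np.log(fit_df["zeta"].to_numpy())
    fit = _ols_fit(x, y)

    rng = np.random.default_rng(seed)
    slopes = []
    m = len(x)
    for _ in range(n_boot):
        idx = rng.integers(0, m, size=m)
        xb, yb = x[idx], y[idx]
        if np.ptp(xb) == 0:
            continue
        b = np.polyfit(xb, yb, 1)[0]
        slopes.append(b)
    lo, hi = np.percentile(slopes, [2.5, 97.5]) if slopes else (np.nan, np.nan)
    return DecayResult(
        pairs=pairs,
        slope=fit["slope"],
        intercept=fit["intercept"],
        r2=fit["r2"],
        slope_ci=(float(lo), float(hi)),
        n_boot=n_boot,
    )
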