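"""Stream-order diversity partitioning and river-network summaries.

Communities are defined by Strahler stream order (SO): small streams and
rivers at SO 1-5, large deep-channel rivers at SO 6-10.  Alpha diversity is
within-order richness, gamma the pooled richness over all orders, and
turnover between orders is measured two ways:

* Whittaker's multiplicative beta, ``beta_W = gamma / mean(alpha)``;
* absolute turnover between two communities,
  ``beta_A = (S1 - c) + (S2 - c)``, the number of unshared species, with
  ``c`` the shared count.

Alpha profiles can be min-max normalized (``N = (x - x_min)/(x_max -
x_min)``) and expressed as density per km of river channel, using a segment
table carrying per-order length, surface area and volume.  Occurrence
records are cleaned before analysis: malformed coordinates rejected,
duplicated (species, lat, lon) rows collapsed to avoid pseudoreplication,
and records outside a species' declared bounds dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

OCCURRENCE_COLUMNS = ["species", "lat", "lon", "basin", "stream_order"]
SEGMENT_COLUMNS = [
    "segment_id", "basin", "stream_order", "length_km", "area_km2", "volume_km3",
]


# -- occurrence QC -------------------------------------------------------


@dataclass
class QCReport:
    n_input: int
    n_malformed: int
    n_duplicate: int
    n_out_of_bounds: int
    n_retained: int

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def occurrence_qc(
    records: pd.DataFrame,
    bounds: Mapping[str, tuple[float, float, float, float]] | None = None,
    round_decimals: int = 4,
) -> tuple[pd.DataFrame, QCReport]:
    """Clean occurrence records; returns (cleaned records, QC report).

    Rules, applied in order: (1) rows with unparsable or out-of-domain
    coordinates (|lat| > 90, |lon| > 180) or stream order outside [1, 10]
    are rejected as malformed; (2) duplicates of (species, lat, lon) with
    coordinates rounded to ``round_decimals`` places (~11 m at 4) are
    collapsed to the first row; (3) rows outside their species' declared
    bounding box ``(lat_min, lat_max, lon_min, lon_max)`` are dropped
    (species without declared bounds are kept).  The operation is
    idempotent: re-running it on its own output changes nothing.
    """
    df = records.copy()
    missing = [c for c in OCCURRENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"occurrence table missing columns {missing}")
    n_input = len(df)

    lat = pd.to_numeric(df["lat"], errors="coerce")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    so = pd.to_numeric(df["stream_order"], errors="coerce")
    ok = (
        lat.notna() & lon.notna() & so.notna()
        & (lat.abs() <= 90) & (lon.abs() <= 180)
        & (so >= 1) & (so <= 10) & (so == so.round())
    )
    n_malformed = int((~ok).sum())
    df = df.loc[ok].copy()
    df["lat"] = lat[ok]
    df["lon"] = lon[ok]
    df["stream_order"] = so[ok].astype(int)

    key = pd.DataFrame(
        {
            "species": df["species"],
            "rlat": df["lat"].round(round_decimals),
            "rlon": df["lon"].round(round_decimals),
        }
    )
    dup = key.duplicated(keep="first")
    n_duplicate = int(dup.sum())
    df = df.loc[~dup]

    n_oob = 0
    if bounds:
        def in_bounds(row) -> bool:
            b = bounds.get(row["species"])
            if b is None:
                return True
            lat_min, lat_max, lon_min, lon_max = b
            return (lat_min <= row["lat"] <= lat_max
                    and lon_min <= row["lon"] <= lon_max)

        keep = df.apply(in_bounds, axis=1) if len(df) else pd.Series(dtype=bool)
        n_oob = int((~keep).sum()) if len(df) else 0
        df = df.loc[keep] if len(df) else df

    report = QCReport(
        n_input=n_input,
        n_malformed=n_malformed,
        n_duplicate=n_duplicate,
        n_out_of_bounds=n_oob,
        n_retained=len(df),
    )
    return df.reset_index(drop=True), report


# -- incidence and richness ---------------------------------------------


def incidence_by_stream_order(records: pd.DataFrame) -> pd.DataFrame:
    """Species x stream-order presence/absence matrix (0/1 ints).

    Rows are species, columns the stream orders observed (ascending);
    presence means the species was recorded at least once at that order.
    """
    if len(records) == 0:
        import warnings

        warnings.warn("empty occurrence table: returning empty incidence matrix")
        return pd.DataFrame()
    tab = pd.crosstab(records["species"], records["stream_order"].astype(int))
    return (tab > 0).astype(int)


def richness_by_order(incidence: pd.DataFrame) -> pd.Series:
    """Per-order pooled richness S_k (column sums of the incidence matrix)."""
    return incidence.sum(axis=0)


# -- the three diversity formulas ---------------------------------------


def minmax_normalize(x: Sequence[float]) -> np.ndarray:
    """Min-max normalization ``N = (x - x_min) / (x_max - x_min)``.

    Invariant under affine transforms of the input; degenerate (constant)
    input is an error rather than a silent zero vector.
    """
    arr = np.asarray(x, dtype=float)
    if arr.size < 2:
        raise ValidationError("minmax_normalize needs at least 2 values")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        raise ValidationError("degenerate input: all values identical")
    return (arr - lo) / (hi - lo)


def whittaker_beta(gamma: float, alphas: Sequence[float]) -> float:
    """Whittaker's multiplicative beta, ``gamma / mean(alphas)``."""
    alphas = np.asarray(alphas, dtype=float)
    mean_alpha = alphas.mean()
    if mean_alpha <= 0:
        raise ValidationError("mean alpha must be positive")
    if gamma < alphas.max():
        raise ValidationError(
            f"gamma ({gamma}) cannot be below the largest alpha ({alphas.max()})"
        )
    return float(gamma) / float(mean_alpha)


def absolute_turnover(S1: float, S2: float, c: float) -> float:
    """Absolute species turnover ``(S1 - c) + (S2 - c)``: the species found
    in exactly one of the two communities."""
    if c > min(S1, S2):
        raise ValidationError(
            f"shared count c={c} exceeds the smaller richness min({S1}, {S2})"
        )
    return (S1 - c) + (S2 - c)


def turnover_matrix(incidence: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise turnover between stream orders.

    Returns ``(beta_a, similarity)``: absolute turnover ``beta_A`` (diagonal
    0) and the proportion of shared species out of the pooled pair richness
    (diagonal 1).  A conventional single display matrix can show ``beta_A``
    below and similarity above the diagonal, as these two carry it both.
    """
    orders = list(incidence.columns)
    if len(orders) < 2:
        raise ValidationError("turnover requires at least 2 stream orders")
    X = incidence.to_numpy().astype(bool)
    k = len(orders)
    beta = np.zeros((k, k))
    sim = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = X[:, i], X[:, j]
            S1, S2 = int(a.sum()), int(b.sum())
            c = int((a & b).sum())
            pooled = int((a | b).sum())
            beta[i, j] = beta[j, i] = absolute_turnover(S1, S2, c)
            sim[i, j] = sim[j, i] = c / pooled if pooled else 0.0
    beta_df = pd.DataFrame(beta, index=orders, columns=orders)
    sim_df = pd.DataFrame(sim, index=orders, columns=orders)
    return beta_df, sim_df


# -- river network summaries --------------------------------------------


@dataclass
class RiverNetworkSummary:
    """Per-order and per-basin proportions of length, area and volume."""

    by_order: pd.DataFrame  # index stream_order; proportion columns
    by_basin: pd.DataFrame  # index (basin, stream_order)
    peak_order: dict[str, int]  # metric -> stream order maximizing it

    def share(self, metric: str, orders: Sequence[int]) -> float:
        """Summed proportion of ``metric`` over the given stream orders."""
        col = f"{metric}_prop"
        present = [o for o in orders if o in self.by_order.index]
        return float(self.by_order.loc[present, col].sum())


_METRICS = {"length": "length_km", "area": "area_km2", "volume": "volume_km3"}


def summarize_river_network(segments: pd.DataFrame) -> RiverNetworkSummary:
    """Aggregate a river-segment table into per-order / per-basin shares of
    total stream length, surface area and water volume."""
    missing = [c for c in SEGMENT_COLUMNS if c not in segments.columns]
    if missing:
        raise ValidationError(f"segment table missing columns {missing}")
    if len(segments) == 0:
        raise ValidationError("segment table is empty")
    for col in _METRICS.values():
        if (segments[col] < 0).any():
            raise ValidationError(f"negative values in {col}")
    so = segments["stream_order"].astype(int)
    if ((so < 1) | (so > 10)).any():
        raise ValidationError("stream_order must be in [1, 10]")

    by_order = segments.groupby(so)[list(_METRICS.values())].sum()
    totals = by_order.sum(axis=0)
    out = by_order.copy()
    for metric, col in _METRICS.items():
        out[f"{metric}_prop"] = by_order[col] / totals[col] if totals[col] > 0 else 0.0
    by_basin = segments.groupby(["basin", so])[list(_METRICS.values())].sum()
    peak = {m: int(out[f"{m}_prop"].idxmax()) for m in _METRICS}
    return RiverNetworkSummary(by_order=out, by_basin=by_basin, peak_order=peak)


def alpha_density(
    richness_by_order: pd.Series, length_by_order: pd.Series
) -> pd.Series:
    """Richness per km of channel, per stream order."""
    rich = richness_by_order.astype(float)
    length = length_by_order.reindex(rich.index).astype(float)
    bad = rich[(rich > 0) & ~(length > 0)]
    if len(bad):
        raise ValidationError(
            f"zero or missing river length at orders with richness: "
            f"{list(bad.index)}"
        )
    dens = rich / length
    return dens.fillna(0.0)


# -- regression ----------------------------------------------------------


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int


def ols_r2(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Simple least-squares regression of a diversity metric on stream order:
    R-squared and the two-sided t-test p-value of the slope (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValidationError("regression needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValidationError("x is constant; slope is undefined")
    if np.ptp(y) == 0:  # flat response: zero slope explains nothing
        return RegressionResult(slope=0.0, intercept=float(y[0]), r2=0.0,
                                p_value=1.0, n=int(x.size))
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


# -- profiles ------------------------------------------------------------


@dataclass
class DiversityProfile:
    """Everything Fig.-3-style diversity reporting needs, in tidy form."""

    per_order: pd.DataFrame  # pooled_richness, mean_alpha, normalized_alpha, ...
    gamma: int
    beta_w: float
    beta_a: pd.DataFrame
    similarity: pd.DataFrame


def diversity_profile(
    records: pd.DataFrame,
    segments: pd.DataFrame | None = None,
) -> DiversityProfile:
    """Full stream-order diversity partition of cleaned occurrence records.

    ``pooled_richness`` is the number of species observed at each order;
    ``mean_alpha`` the mean per-segment richness within the order when
    per-segment communities are resolvable (falls back to pooled richness
    for order-level data, the default interpretation); ``beta_w_order`` is
    gamma over that order's alpha.  When a segment table is supplied the
    profile adds per-km alpha density.
    """
    inc = incidence_by_stream_order(records)
    if inc.empty:
        raise ValidationError("no occurrence records to profile")
    S = richness_by_order(inc)
    gamma = int(inc.shape[0])
    per = pd.DataFrame({"pooled_richness": S})
    per["mean_alpha"] = S.astype(float)  # order-level communities (default)
    if len(S) >= 2 and S.max() > S.min():
        per["normalized_alpha"] = minmax_normalize(S.to_numpy())
    else:
        per["normalized_alpha"] = np.nan
    per["beta_w_order"] = gamma / per["mean_alpha"]
    if segments is not None:
        net = summarize_river_network(segments)
        lengths = net.by_order["length_km"]
        per["alpha_density"] = alpha_density(S, lengths)
    beta_w = whittaker_beta(gamma, per["mean_alpha"].to_numpy())
    beta_a, sim = turnover_matrix(inc) if inc.shape[1] >= 2 else (
        pd.DataFrame(), pd.DataFrame())
    per.index.name = "stream_order"
    return DiversityProfile(
        per_order=per, gamma=gamma, beta_w=beta_w, beta_a=beta_a, similarity=sim
    )
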