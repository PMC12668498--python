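"""Inter-/intra-operator variability statistics for repeated palpations.

The data unit is a *palpation panel*: long-format records of (operator,
repeat, bone, landmark code, x, y, z) in millimetres.  Offered analyses:

* displacements of each observation from its marker's mean position, per
  axis and as the Euclidean distance, with per-operator/per-repeat and
  pooled summaries;
* ICC(2,1) — two-way random effects, absolute agreement, single measurement —
  with the standard F-based 95% confidence interval;
* the D'Agostino skewness test;
* an unbalanced Friedman test (Skillings-Mack statistic, which reduces to
  the classical Friedman statistic on balanced complete data without ties);
* one-to-many two-sided Nemenyi post-hoc comparisons against a control
  group, with a caller-supplied critical z value.

Mid-ranks are used for ties throughout.  Where a (group, block) cell holds
replicate observations they are averaged before ranking.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateVarianceError,
    InsufficientBlocksError,
    SingletonGroupError,
    SmallSampleError,
    UnknownControlError,
)

_AXES = ("x", "y", "z")


class PalpationPanel:
    """Long-format repeated-palpation records.

    Wraps a DataFrame with columns (operator, repeat, bone, code, x, y, z);
    (operator, repeat, bone, code) must be unique.  ``euclidean`` (distance
    of the point from the frame origin) is derived.
    """

    COLUMNS = ("operator", "repeat", "bone", "code", "x", "y", "z")

    def __init__(self, df: pd.DataFrame) -> None:
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"panel missing columns {missing}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        key = ["operator", "repeat", "bone", "code"]
        if df.duplicated(subset=key).any():
            dup = df[df.duplicated(subset=key)].iloc[0]
            raise ValueError(
                f"duplicate record {tuple(dup[k] for k in key)} in panel"
            )
        df["euclidean"] = np.linalg.norm(df[list(_AXES)].to_numpy(float), axis=1)
        df["marker"] = df["bone"].astype(str) + ":" + df["code"].astype(str)
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records) -> "PalpationPanel":
        return cls(pd.DataFrame(records, columns=list(cls.COLUMNS)))

    @classmethod
    def from_csv(cls, path) -> "PalpationPanel":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.loc[:, list(self.COLUMNS)].to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.df)

    def ratings_matrix(self, coordinate: str, rater: str = "operator") -> pd.DataFrame:
        """Markers x raters matrix of a coordinate, averaging over repeats."""
        if coordinate not in (*_AXES, "euclidean"):
            raise ValueError(f"unknown coordinate {coordinate!r}")
        return self.df.pivot_table(
            index="marker", columns=rater, values=coordinate, aggfunc="mean"
        )


@dataclass
class DisplacementTable:
    """Per-record displacements from marker means, plus summary helpers."""

    records: pd.DataFrame  # panel columns + dx, dy, dz, d_euclidean

    def summary_by(self, column: str) -> pd.DataFrame:
        """Mean/SD/median/IQR of displacement magnitudes grouped by a column
        (e.g. ``operator`` or ``repeat``)."""
        rows = {}
        grouped = self.records.groupby(column)
        for name, g in grouped:
            row = {}
            for axis, col in (("ap", "dx"), ("is", "dy"), ("rl", "dz"),
                              ("euclidean", "d_euclidean")):
                mags = g[col].abs() if col != "d_euclidean" else g[col]
                row[f"{axis}_mean"] = mags.mean()
                row[f"{axis}_sd"] = mags.std(ddof=1)
                row[f"{axis}_median"] = mags.median()
                row[f"{axis}_iqr"] = mags.quantile(0.75) - mags.quantile(0.25)
            rows[name] = row
        return pd.DataFrame(rows).T

    def pooled_summary(self) -> pd.DataFrame:
        """Mean/SD/median/IQR over all records, per axis and Euclidean."""
        out = {}
        for axis, col in (("ap", "dx"), ("is", "dy"), ("rl", "dz"),
                          ("euclidean", "d_euclidean")):
            mags = self.records[col].abs() if col != "d_euclidean" else self.records[col]
            out[axis] = {
                "mean": mags.mean(),
                "sd": mags.std(ddof=1),
                "median": mags.median(),
                "iqr": mags.quantile(0.75) - mags.quantile(0.25),
            }
        return pd.DataFrame(out)


def displacements(panel: PalpationPanel, grouping: str = "per-marker") -> DisplacementTable:
    """Displacement of each observation from its marker's mean position.

    Per-axis displacements are signed (they sum to zero within each marker);
    the Euclidean displacement is the norm of the per-axis vector.
    ``grouping='pooled'`` returns the same records tagged for pooled
    summaries; the displacement definition is identical at both granularities.
    """
    if grouping not in ("per-marker", "pooled"):
        raise ValueError("grouping must be 'per-marker' or 'pooled'")
    df = panel.df.copy()
    counts = df.groupby("marker")["x"].transform("count")
    if (counts < 2).any():
        bad = df.loc[counts < 2, "marker"].iloc[0]
        raise SingletonGroupError(f"marker {bad} has fewer than 2 observations")
    for axis, dcol in zip(_AXES, ("dx", "dy", "dz")):
        df[dcol] = df[axis] - df.groupby("marker")[axis].transform("mean")
    df["d_euclidean"] = np.linalg.norm(df[["dx", "dy", "dz"]].to_numpy(float), axis=1)
    df["grouping"] = grouping
    return DisplacementTable(records=df)


@dataclass(frozen=True)
class ICCResult:
    """Intraclass correlation with its 95% confidence interval."""

    icc: float
    ci95: tuple[float, float]
    model: str = "ICC(2,1) two-way random, absolute agreement, single measurement"
    n_targets: int = 0
    k_raters: int = 0
    n_dropped: int = 0


def icc_2_1(ratings, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1) from the two-way ANOVA decomposition of a targets x raters
    matrix.  Rows containing missing values are dropped (and counted in
    ``n_dropped``); the confidence interval is the standard F-based one.

    Raises :class:`DegenerateVarianceError` when the total variance is zero
    (the coefficient would be 0/0), rather than silently returning 1.
    """
    x = np.asarray(pd.DataFrame(ratings), dtype=float)
    complete = ~np.isnan(x).any(axis=1)
    n_dropped = int((~complete).sum())
    x = x[complete]
    n, k = x.shape
    if n < 2 or k < 2:
        raise SmallSampleError("need at least 2 targets and 2 raters")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = float(((x - grand) ** 2).sum())
    if ss_total < 1e-12 * max(1.0, abs(grand)) ** 2:
        raise DegenerateVarianceError("zero total variance: ICC undefined")
    msr = k * float(((row_means - grand) ** 2).sum()) / (n - 1)
    msc = n * float(((col_means - grand) ** 2).sum()) / (k - 1)
    sse = float(((x - row_means[:, None] - col_means[None, :] + grand) ** 2).sum())
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom

    # F-based CI (two-way random, absolute agreement, single measurement)
    if mse <= 0:
        ci = (icc, icc)
    else:
        fj = msc / mse
        vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
        vd = (n - 1) * k**2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
        v = vn / vd
        f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
        upper = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
        ci = (float(lower), float(upper))
    return ICCResult(icc=float(icc), ci95=ci, n_targets=n, k_raters=k, n_dropped=n_dropped)


def skewness_dagostino(x) -> tuple[float, float, float]:
    """Sample skewness with the D'Agostino transformed z and two-sided p."""
    arr = np.asarray(x, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 8:
        raise SmallSampleError("D'Agostino skewness test needs n >= 8")
    if np.std(arr) == 0:
        raise DegenerateVarianceError("constant sample: skewness undefined")
    g1 = float(stats.skew(arr))
    z, p = stats.skewtest(arr)
    return g1, float(z), float(p)


def _block_ranks(df: pd.DataFrame, value: str, group: str, block: str):
    """Pivot to blocks x groups (replicates averaged) and drop empty blocks."""
    table = df.pivot_table(index=block, columns=group, values=value, aggfunc="mean")
    observed = table.notna().sum(axis=1)
    table = table.loc[observed >= 2]
    if table.empty or table.shape[1] < 2:
        raise InsufficientBlocksError(
            "need >= 2 groups and blocks observed in >= 2 groups"
        )
    return table


def friedman_unbalanced(
    data: pd.DataFrame,
    value: str = "value",
    group: str = "group",
    block: str = "block",
) -> tuple[float, int, float]:
    """Rank-based test of a group effect with block dependencies, tolerant of
    missing cells (Skillings-Mack statistic).

    Within each block the observed groups are mid-ranked; centred ranks are
    scaled by ``sqrt(12 / (c_j + 1))`` (``c_j`` observed groups in block j),
    summed per group, and the quadratic form with the pseudo-inverse of the
    incidence covariance is referred to a chi-squared distribution.  On
    balanced complete data without ties this equals the classical Friedman
    statistic.

    Returns (statistic, degrees of freedom, p value).
    """
    table = _block_ranks(data, value, group, block)
    groups = list(table.columns)
    k = len(groups)
    a = np.zeros(k)
    sigma = np.zeros((k, k))
    for _, row in table.iterrows():
        obs = row.dropna()
        c = len(obs)
        ranks = stats.rankdata(obs.to_numpy())
        scale = math.sqrt(12.0 / (c + 1))
        idx = [groups.index(g) for g in obs.index]
        for pos, i in enumerate(idx):
            a[i] += scale * (ranks[pos] - (c + 1) / 2.0)
        for i in idx:
            sigma[i, i] += c - 1
        for ii, i in enumerate(idx):
            for jj in idx[ii + 1:]:
                sigma[i, jj] -= 1
                sigma[jj, i] -= 1
    statistic = float(a @ np.linalg.pinv(sigma) @ a)
    df_chi = int(np.linalg.matrix_rank(sigma))
    p = float(stats.chi2.sf(statistic, df_chi))
    return statistic, df_chi, p


@dataclass(frozen=True)
class NemenyiComparison:
    """One control-versus-group comparison from the post-hoc test."""

    group: object
    z: float
    p: float
    significant: bool
    tier: str


def _tier(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    if p <= 0.1:
        return "."
    return ""


def nemenyi_one_to_many(
    data: pd.DataFrame,
    control,
    critical_z: float,
    value: str = "value",
    group: str = "group",
    block: str = "block",
    friedman_p: float | None = None,
) -> dict:
    """One-to-many two-sided Nemenyi comparisons of each group vs a control.

    For each non-control group, the mean within-block rank difference from
    the control is standardised over the blocks where both are observed:
    ``z = |sum_j (r_control,j - r_g,j)| / sqrt(sum_j c_j (c_j + 1) / 6)``,
    which reduces to the classical Nemenyi many-to-one z on balanced data.
    A comparison is significant when z >= ``critical_z``.  Tier codes follow
    the conventional brackets (*** <=0.001, ** <=0.01, * <=0.05, . <=0.1) on
    the two-sided normal p value.
    """
    if friedman_p is not None and friedman_p >= 0.05:
        warnings.warn(
            "omnibus Friedman test was not significant; post-hoc comparisons "
            "are exploratory",
            stacklevel=2,
        )
    table = _block_ranks(data, value, group, block)
    if control not in table.columns:
        raise UnknownControlError(f"control group {control!r} not in data")
    ranks = table.rank(axis=1, method="average")
    comparisons = []
    for g in table.columns:
        if g == control:
            continue
        both = ranks[[control, g]].dropna()
        if both.empty:
            continue
        blocks = both.index
        c = table.loc[blocks].notna().sum(axis=1).to_numpy(float)
        diff = float((both[control] - both[g]).sum())
        var = float((c * (c + 1) / 6.0).sum())
        z = abs(diff) / math.sqrt(var) if var > 0 else 0.0
        p = 2.0 * stats.norm.sf(z)
        comparisons.append(
            NemenyiComparison(group=g, z=z, p=p, significant=z >= critical_z, tier=_tier(p))
        )
    return {"control": control, "critical_z": critical_z, "comparisons": comparisons}
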