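"""Site-difference heteroscedasticity diagnostics.

Connectivity was acquired on two scanners (MGH, BU).  Beyond the binary site
covariate in the regression, a per-connection Levene's test screens for
between-site differences in variance that would call for harmonization.
The screen is descriptive: flags are reported at the raw level with no
multiplicity adjustment by default, and the verdict simply states whether
any connection was flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .behavioral import BehavioralRecord
from .connectivity import ConnectivityTable

__all__ = ["LeveneResult", "levene_test", "site_heteroscedasticity_screen"]


@dataclass(frozen=True)
class LeveneResult:
    statistic: float
    p_value: float
    df_between: int
    df_within: int
    center: str

    def __post_init__(self) -> None:
        if self.statistic < 0 or not 0.0 <= self.p_value <= 1.0:
            raise ValueError("invalid Levene result")


def levene_test(
    values: Sequence[float],
    groups: Sequence,
    center: Literal["mean", "median"] = "mean",
) -> LeveneResult:
    """Equality-of-variance test: one-way ANOVA on |x_ij - center(group i)|.

    ``center="mean"`` is the classic Levene form, ``"median"`` the
    Brown-Forsythe variant.  Zero within-group spread of the absolute
    deviations in every group with no between-group difference degenerates
    to statistic 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape or values.ndim != 1:
        raise ValueError("values and groups must be aligned 1-D sequences")
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in levels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least 2 observations")
    k, N = len(samples), values.size
    df1, df2 = k - 1, N - k

    centre = np.mean if center == "mean" else np.median
    devs = [np.abs(s - centre(s)) for s in samples]
    ssw = sum(float(np.sum((d - d.mean()) ** 2)) for d in devs)
    if ssw == 0.0:
        grand = np.concatenate(devs).mean()
        ssb = sum(len(d) * (d.mean() - grand) ** 2 for d in devs)
        if ssb == 0.0:
            return LeveneResult(0.0, 1.0, df1, df2, center)
        # deviations differ between groups but are constant within them:
        # the F ratio is unbounded, evidence of unequal spread is maximal
        return LeveneResult(float("inf"), 0.0, df1, df2, center)

    stat, p = stats.levene(*samples, center=center)
    return LeveneResult(float(stat), float(p), df1, df2, center)


def site_heteroscedasticity_screen(
    ct: ConnectivityTable,
    records: Sequence[BehavioralRecord],
    alpha: float = 0.05,
    center: Literal["mean", "median"] = "mean",
) -> pd.DataFrame:
    """Levene's test of MGH vs BU variance for every connection.

    Returns one row per connection (connection, F, df1, df2, p, flag);
    ``attrs["normalization_suggested"]`` is True iff any connection is
    flagged at the raw (unadjusted) alpha.
    """
    if len(ct.connection_labels) == 0:
        raise ValueError("empty connectivity table")
    site_by = {r.participant_id: r.site_code for r in records}
    missing = [s for s in ct.subject_ids if s not in site_by]
    if missing:
        raise ValueError(f"no site information for subjects: {missing}")
    sites = np.array([site_by[s] for s in ct.subject_ids])
    if len(set(sites.tolist())) < 2:
        raise ValueError("both scanner sites must be represented")

    rows = []
    for j, label in enumerate(ct.connection_labels):
        res = levene_test(ct.z_values[:, j], sites, center=center)
        rows.append({
            "connection": label,
            "F": res.statistic,
            "df1": res.df_between,
            "df2": res.df_within,
            "p": res.p_value,
            "flag": res.p_value < alpha,
        })
    out = pd.DataFrame(rows)
    out.attrs["normalization_suggested"] = bool(out["flag"].any())
    out.attrs["alpha"] = alpha
    return out
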