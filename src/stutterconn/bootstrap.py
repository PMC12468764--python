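"""Paired bootstrap of the cross-validated LASSO, with stability selection.

The inference procedure at the heart of the pipeline:

1. draw B paired bootstrap resamples of the subjects (predictor rows and
   outcome resampled jointly, with replacement);
2. on each resample, select the penalty by cross-validation and fit the
   LASSO at that optimum, recording the raw (original-scale) coefficients;
3. aggregate per-predictor means and SDs across the B draws, form
   Bonferroni-adjusted normal-approximation confidence intervals from the
   bootstrap standard errors, and flag predictors whose interval excludes 0;
4. rank predictors by how often their coefficient was nonzero (stability
   selection) and cut the ranking at the largest drop in selection
   frequency ("first drop" rule), yielding a small stable set.

The procedure does not formally control false discoveries; it trades that
for reproducibility of the selected set under resampling.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, replace, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import DesignMatrix
from .lasso import LassoConfig, cv_lasso

logger = logging.getLogger(__name__)

__all__ = [
    "BootstrapConfig",
    "BootstrapResult",
    "SelectionReport",
    "paired_bootstrap_indices",
    "run_bootstrap",
    "coefficient_ci",
    "stability_select",
    "first_drop_cutoff",
    "build_selection_report",
    "write_selection_report",
]

_SEED_MOD = 2**31


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap, confidence-interval and stable-set cutoff settings."""

    n_boot: int = 1000
    ci_level: float = 0.95
    #: comparisons for the Bonferroni adjustment; "auto" = predictors in the
    #: model including the site covariate
    bonferroni_m: int | Literal["auto"] = "auto"
    seed: int = 0
    cutoff_rule: Literal["largest_drop", "fixed_threshold"] = "largest_drop"
    threshold: float = 0.5
    ci_method: Literal["normal", "percentile"] = "normal"
    #: include zero draws in mean/SD (raw aggregation) or condition on selection
    condition_on_selection: bool = False

    def __post_init__(self) -> None:
        if self.n_boot < 2:
            raise ValueError("n_boot must be >= 2")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass(frozen=True)
class BootstrapResult:
    """Raw coefficient draws across bootstrap iterations plus aggregates."""

    labels: tuple[str, ...]
    coef_draws: np.ndarray  # B x p, original predictor scale
    lambdas: np.ndarray  # per-iteration optimal penalty (NaN for degenerate)
    degenerate: np.ndarray  # per-iteration flag: resample had constant outcome
    seed: int

    @property
    def n_boot(self) -> int:
        return self.coef_draws.shape[0]

    @property
    def mean_coef(self) -> np.ndarray:
        return self.coef_draws.mean(axis=0)

    @property
    def sd_coef(self) -> np.ndarray:
        return self.coef_draws.std(axis=0, ddof=1)

    @property
    def se_mean(self) -> np.ndarray:
        """Bootstrap SD scaled by sqrt(B) (Monte-Carlo SE of the mean)."""
        return self.sd_coef / np.sqrt(self.n_boot)

    @property
    def selection_count(self) -> np.ndarray:
        return np.count_nonzero(self.coef_draws, axis=0)

    @property
    def selection_freq(self) -> np.ndarray:
        return self.selection_count / self.n_boot

    @property
    def avg_lambda(self) -> float:
        """Mean optimal penalty over non-degenerate iterations."""
        ok = ~self.degenerate
        return float(np.mean(self.lambdas[ok])) if ok.any() else float("nan")


@dataclass(frozen=True)
class SelectionReport:
    """Confidence intervals, significance flags and the stable set."""

    labels: tuple[str, ...]
    mean_coef: np.ndarray
    sd_coef: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    significant: np.ndarray
    ranking: pd.DataFrame  # stability_select output, one row per predictor
    cutoff_index: int
    bonferroni_m: int
    avg_lambda: float

    @property
    def stable_set(self) -> tuple[str, ...]:
        return tuple(self.ranking["predictor"].iloc[: self.cutoff_index])

    def to_frame(self) -> pd.DataFrame:
        rank_of = {lbl: i + 1 for i, lbl in enumerate(self.ranking["predictor"])}
        stable = set(self.stable_set)
        counts = dict(zip(self.ranking["predictor"], self.ranking["selection_count"]))
        n_boot = int(self.ranking.attrs.get("n_boot", 0))
        rows = []
        for j, lbl in enumerate(self.labels):
            rows.append({
                "predictor": lbl,
                "mean_coef": self.mean_coef[j],
                "sd_coef": self.sd_coef[j],
                "se_mean": self.sd_coef[j] / np.sqrt(n_boot) if n_boot else np.nan,
                "ci_lower": self.ci_lower[j],
                "ci_upper": self.ci_upper[j],
                "significant": bool(self.significant[j]),
                "selection_count": int(counts[lbl]),
                "selection_freq": counts[lbl] / n_boot if n_boot else np.nan,
                "stability_rank": rank_of[lbl],
                "in_stable_set": lbl in stable,
            })
        return pd.DataFrame(rows)


def _iter_seed(seed: int, b: int) -> int:
    """Per-iteration sub-seed: seed XOR iteration index (kept below 2^31)."""
    return (seed ^ b) % _SEED_MOD


def paired_bootstrap_indices(n: int, B: int, seed: int) -> np.ndarray:
    """B uniform-with-replacement index vectors of length n (paired resampling).

    Row indices apply jointly to the predictor matrix and the outcome, so
    (x_i, y_i) pairs stay intact.  Iteration b draws from its own generator
    seeded with ``seed XOR b``, so any single iteration can be reproduced in
    isolation.
    """
    if n < 2:
        raise ValueError("need at least 2 subjects to resample")
    out = np.empty((B, n), dtype=np.intp)
    for b in range(B):
        rng = np.random.default_rng([_iter_seed(seed, b), 0x5EED])
        out[b] = rng.integers(0, n, size=n)
    return out


def run_bootstrap(
    design: DesignMatrix,
    lasso_cfg: LassoConfig = LassoConfig(),
    boot_cfg: BootstrapConfig = BootstrapConfig(),
) -> BootstrapResult:
    """Bootstrap the cross-validated LASSO for one outcome.

    Each iteration re-selects its own penalty by cross-validation on the
    resampled data (fold assignment reseeded per iteration) and records raw
    coefficients at that optimum.  Resamples with a constant outcome cannot
    be fit: their coefficients are recorded as all-zero and logged; more than
    50% such draws is an error.
    """
    X, y = design.X, design.y
    n, p = X.shape
    B = boot_cfg.n_boot
    idx = paired_bootstrap_indices(n, B, boot_cfg.seed)
    draws = np.zeros((B, p))
    lambdas = np.full(B, np.nan)
    degenerate = np.zeros(B, dtype=bool)
    for b in range(B):
        rows = idx[b]
        yb = y[rows]
        if np.all(yb == yb[0]):
            degenerate[b] = True
            logger.warning("bootstrap iteration %d degenerate (constant outcome)", b)
            continue
        cfg_b = replace(lasso_cfg, seed=_iter_seed(boot_cfg.seed, b))
        lam_opt, fit, _ = cv_lasso(X[rows], yb, cfg_b)
        draws[b] = fit.coefficients
        lambdas[b] = lam_opt
    n_deg = int(degenerate.sum())
    if n_deg > B / 2:
        raise RuntimeError(f"{n_deg}/{B} bootstrap draws degenerate; data unusable")
    if n_deg:
        logger.info("%d/%d degenerate bootstrap draws recorded as all-zero", n_deg, B)
    return BootstrapResult(
        labels=design.column_labels, coef_draws=draws,
        lambdas=lambdas, degenerate=degenerate, seed=boot_cfg.seed,
    )


def _conditional_mean_sd(draws: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean/SD over nonzero draws only (selection-conditioned variant)."""
    B, p = draws.shape
    mean = np.zeros(p)
    sd = np.zeros(p)
    for j in range(p):
        nz = draws[:, j][draws[:, j] != 0.0]
        if nz.size:
            mean[j] = nz.mean()
            sd[j] = nz.std(ddof=1) if nz.size > 1 else 0.0
    return mean, sd


def coefficient_ci(
    result: BootstrapResult, boot_cfg: BootstrapConfig = BootstrapConfig()
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bonferroni-adjusted confidence intervals from bootstrap standard errors.

    The per-comparison level is alpha' = (1 - ci_level)/m; the normal form is
    mean +/- z_{1-alpha'/2} * SD(draws).  A predictor is significant when its
    interval excludes zero; a degenerate all-zero predictor (mean 0, SD 0)
    yields the zero-width interval at 0, which contains 0.
    Returns (ci_lower, ci_upper, significant).
    """
    p = len(result.labels)
    m = p if boot_cfg.bonferroni_m == "auto" else int(boot_cfg.bonferroni_m)
    if m < 1:
        raise ValueError("bonferroni_m must be >= 1")
    alpha_adj = (1.0 - boot_cfg.ci_level) / m
    if boot_cfg.condition_on_selection:
        mean, sd = _conditional_mean_sd(result.coef_draws)
    else:
        mean, sd = result.mean_coef, result.sd_coef
    if not np.all(np.isfinite(sd)):
        raise ValueError("non-finite bootstrap SDs")
    if boot_cfg.ci_method == "normal":
        zq = stats.norm.ppf(1.0 - alpha_adj / 2.0)
        lo, hi = mean - zq * sd, mean + zq * sd
    elif boot_cfg.ci_method == "percentile":
        lo = np.quantile(result.coef_draws, alpha_adj / 2.0, axis=0)
        hi = np.quantile(result.coef_draws, 1.0 - alpha_adj / 2.0, axis=0)
    else:
        raise ValueError(f"unknown ci_method {boot_cfg.ci_method!r}")
    significant = (lo > 0.0) | (hi < 0.0)
    return lo, hi, significant


def stability_select(result: BootstrapResult) -> pd.DataFrame:
    """Predictors ranked by selection frequency across bootstrap draws.

    Ties break by |mean coefficient| descending, then label lexicographic.
    Returns a frame with columns predictor, selection_count, selection_freq,
    mean_coef; ``attrs["n_boot"]`` carries B.
    """
    counts = result.selection_count
    mean = result.mean_coef
    order = sorted(
        range(len(result.labels)),
        key=lambda j: (-counts[j], -abs(mean[j]), result.labels[j]),
    )
    df = pd.DataFrame({
        "predictor": [result.labels[j] for j in order],
        "selection_count": counts[order],
        "selection_freq": counts[order] / result.n_boot,
        "mean_coef": mean[order],
    })
    df.attrs["n_boot"] = result.n_boot
    return df


def first_drop_cutoff(sorted_counts: Sequence[int]) -> int:
    """Index of the last stable predictor under the largest-drop rule.

    Given selection counts sorted non-increasing, the cutoff is the i
    maximizing ``count_i - count_{i+1}`` (1-based; ties to the smallest i):
    the last variable before the sharpest decline in selection frequency.
    All-equal counts leave the cutoff undefined: returns 0 (empty stable
    set) with a warning.
    """
    c = np.asarray(sorted_counts, dtype=float)
    if c.ndim != 1 or c.size < 2:
        raise ValueError("need a 1-D sequence of at least 2 counts")
    if np.any(np.diff(c) > 0):
        raise ValueError("counts must be sorted non-increasing")
    drops = -np.diff(c)
    if np.all(drops == 0.0):
        warnings.warn("all selection counts equal; no drop exists, empty stable set")
        return 0
    return int(np.argmax(drops)) + 1


def build_selection_report(
    result: BootstrapResult, boot_cfg: BootstrapConfig = BootstrapConfig()
) -> SelectionReport:
    """Assemble CIs, significance flags, stability ranking and stable set."""
    lo, hi, significant = coefficient_ci(result, boot_cfg)
    ranking = stability_select(result)
    if boot_cfg.cutoff_rule == "largest_drop":
        cutoff = first_drop_cutoff(ranking["selection_count"].to_numpy())
    elif boot_cfg.cutoff_rule == "fixed_threshold":
        cutoff = int((ranking["selection_freq"] >= boot_cfg.threshold).sum())
    else:
        raise ValueError(f"unknown cutoff rule {boot_cfg.cutoff_rule!r}")
    m = len(result.labels) if boot_cfg.bonferroni_m == "auto" else int(boot_cfg.bonferroni_m)
    return SelectionReport(
        labels=result.labels,
        mean_coef=result.mean_coef,
        sd_coef=result.sd_coef,
        ci_lower=lo, ci_upper=hi, significant=significant,
        ranking=ranking, cutoff_index=cutoff,
        bonferroni_m=m, avg_lambda=result.avg_lambda,
    )


def write_selection_report(
    report: SelectionReport,
    result: BootstrapResult,
    boot_cfg: BootstrapConfig,
    csv_path: str | Path,
    json_path: str | Path | None = None,
) -> None:
    """Per-outcome results CSV plus a run-level JSON sidecar."""
    df = report.to_frame()
    float_cols = df.select_dtypes("float").columns
    df[float_cols] = df[float_cols].round(10)  # stable text representation
    df.to_csv(csv_path, index=False)
    if json_path is not None:
        cfg = asdict(boot_cfg)
        cfg_hash = hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest()
        meta = {
            "avg_lambda": report.avg_lambda,
            "n_boot": result.n_boot,
            "seed": result.seed,
            "n_degenerate": int(result.degenerate.sum()),
            "bonferroni_m": report.bonferroni_m,
            "cutoff_index": report.cutoff_index,
            "stable_set": list(report.stable_set),
            "config": cfg,
            "config_hash": cfg_hash,
        }
        Path(json_path).write_text(json.dumps(meta, indent=2, sort_keys=True))
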