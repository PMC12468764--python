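"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates the study design end to end with known ground truth:
a subject x connection matrix of correlated Fisher-z values (block-
exchangeable correlation on the typical resting-state scale, mean 0.4,
SD 0.3), a two-scanner cohort with a small additive site shift, and a
non-negative zero-inflated disfluency-percentage outcome driven by a sparse
linear model over three planted connections.  A matching behavioral table
(three speech samples per subject with integer counts) is back-computed so
the behavioral module reproduces the simulated outcome to count-rounding
precision.

Default planted effects sit at the scale of connection-level estimates one
observes in small-cohort speech studies (+0.2, -0.18, +0.17 percent per
z-unit); against a residual SD of 1 percent they give a deliberately weak
signal, so recovery at n = 20 is a genuine stress test rather than a
formality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
import numpy as np

from .behavioral import BehavioralRecord, DisfluencyRates, SpeechSample, aggregate_rates
from .connectivity import (
    ConnectivityTable,
    DesignMatrix,
    assemble_design,
    default_connection_list,
)

__all__ = ["SimulationConfig", "SyntheticDataset", "simulate_connectivity",
           "simulate_outcome", "simulate_behavioral_table", "simulate_dataset"]

#: default planted support, mirroring the kind of stable set the analysis is
#: meant to find: one feedback-map connection (L_vMC~R_vPMC), one cerebellar-
#: thalamic feedforward connection (R_aCb~L_VL, negative), one planning-loop
#: connection (L_pIFS~L_preSMA)
DEFAULT_SUPPORT = ((41, 0.2), (51, -0.18), (0, 0.17))

_Z_MEAN = 0.4
_Z_SD = 0.3
_TARGET_MEAN_PCT = 3.7  # block-rate scale
_TOTALS_RANGE = (200, 1100)  # syllables per sample, demographics-table range


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth generative settings; all draws are pure in (config, seed)."""

    n_subjects: int = 20
    n_connections: int = 58
    predictor_correlation: float = 0.3  # exchangeable rho within blocks
    block_size: int = 6
    true_support: tuple[tuple[int, float], ...] = DEFAULT_SUPPORT
    noise_sd: float = 1.0  # residual SD of the outcome, percent units
    site_fraction: float = 0.55  # fraction of subjects scanned at MGH
    site_shift: float = 0.1  # additive z-shift for MGH subjects
    zero_inflation: float = 0.15  # P(outcome set exactly to 0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.predictor_correlation < 1.0:
            raise ValueError("predictor_correlation must be in [0, 1)")
        if not 0.0 <= self.zero_inflation < 1.0:
            raise ValueError("zero_inflation must be in [0, 1)")
        if any(k >= self.n_connections or k < 0 for k, _ in self.true_support):
            raise ValueError("true_support index outside connection range")

    def truth_vector(self, n_columns: int) -> np.ndarray:
        """True coefficients over design columns (connections + site, coef 0)."""
        beta = np.zeros(n_columns)
        for k, eff in self.true_support:
            beta[k] = eff
        return beta


@dataclass(frozen=True)
class SyntheticDataset:
    """One simulated cohort with its generating truth."""

    design: DesignMatrix
    connectivity: ConnectivityTable
    behavioral: tuple[BehavioralRecord, ...]
    rates: tuple[DisfluencyRates, ...]
    truth: np.ndarray  # per design column
    support: tuple[int, ...]
    config: SimulationConfig


def _sites(cfg: SimulationConfig) -> np.ndarray:
    """Binary site codes (MGH=1), fixed count, seeded placement."""
    n1 = int(round(cfg.n_subjects * cfg.site_fraction))
    sites = np.zeros(cfg.n_subjects, dtype=int)
    sites[:n1] = 1
    rng = np.random.default_rng([cfg.seed % 2**31, 0])
    return sites[rng.permutation(cfg.n_subjects)]


def _subject_ids(cfg: SimulationConfig) -> list[str]:
    return [f"SIM{i + 1:03d}" for i in range(cfg.n_subjects)]


def simulate_connectivity(cfg: SimulationConfig) -> ConnectivityTable:
    """Correlated Fisher-z predictors with a scanner-site mean shift.

    Rows follow a multivariate normal with block-exchangeable correlation:
    within blocks of ``block_size`` consecutive connections the pairwise
    correlation is ``predictor_correlation``; across blocks, zero.  Marginal
    mean 0.4 and SD 0.3 put values on the typical resting-state Fisher-z
    scale; MGH rows get an extra ``site_shift``.
    """
    n, p, rho = cfg.n_subjects, cfg.n_connections, cfg.predictor_correlation
    rng = np.random.default_rng([cfg.seed % 2**31, 1])
    # exchangeable block: z = sqrt(rho)*shared + sqrt(1-rho)*idiosyncratic
    z = np.empty((n, p))
    start = 0
    while start < p:
        width = min(cfg.block_size, p - start)
        shared = rng.standard_normal((n, 1))
        noise = rng.standard_normal((n, width))
        z[:, start:start + width] = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise
        start += width
    z = _Z_MEAN + _Z_SD * z + cfg.site_shift * _sites(cfg)[:, None]
    if p == 58:
        labels = default_connection_list().labels
    else:
        labels = [f"conn_{i:03d}" for i in range(p)]
    return ConnectivityTable(
        subject_ids=tuple(_subject_ids(cfg)),
        connection_labels=tuple(labels),
        z_values=z,
    )


def simulate_outcome(ct: ConnectivityTable, cfg: SimulationConfig) -> np.ndarray:
    """Zero-inflated, non-negative disfluency percentage with sparse effects.

    y = max(0, mu + sum_k effect_k * z_k + eps), eps ~ N(0, noise_sd); then
    with probability ``zero_inflation`` an outcome is set exactly to 0.  The
    intercept mu is chosen so the pre-truncation mean sits near 3.7 percent
    (the block-rate scale).
    """
    z = ct.z_values
    n = z.shape[0]
    rng = np.random.default_rng([cfg.seed % 2**31, 2])
    effects = np.zeros(z.shape[1])
    for k, eff in cfg.true_support:
        effects[k] = eff
    mu = _TARGET_MEAN_PCT - _Z_MEAN * effects.sum()
    y = mu + z @ effects + rng.normal(0.0, cfg.noise_sd, size=n)
    y = np.maximum(y, 0.0)
    y[rng.random(n) < cfg.zero_inflation] = 0.0
    return np.minimum(y, 100.0)


def _counts_for_rate(rate_pct: float, totals: np.ndarray) -> np.ndarray:
    """Integer counts whose per-sample percentages average back to ~rate."""
    return np.rint(rate_pct / 100.0 * totals).astype(int)


def simulate_behavioral_table(
    cfg: SimulationConfig,
    block_rates: np.ndarray | None = None,
) -> tuple[BehavioralRecord, ...]:
    """Three-samples-per-subject behavioral records matching simulated rates.

    Block rates default to a fresh ``simulate_outcome`` draw on this config's
    connectivity; repetition and prolongation rates are null (no planted
    effects) at their typical cohort scales (~1.2% and ~0.5%).  Counts are
    back-computed from rates so that ``aggregate_rates`` reproduces the
    simulated outcome to integer-count rounding (within 50/min_total).
    """
    n = cfg.n_subjects
    if block_rates is None:
        block_rates = simulate_outcome(simulate_connectivity(cfg), cfg)
    block_rates = np.asarray(block_rates, dtype=float)
    if block_rates.shape != (n,):
        raise ValueError("block_rates length must equal n_subjects")
    rng = np.random.default_rng([cfg.seed % 2**31, 3])
    sites = _sites(cfg)
    ids = _subject_ids(cfg)
    # null companion rates on the cohort scales of the other two types
    rep_rates = np.maximum(rng.normal(1.2, 0.8, n), 0.0)
    pro_rates = np.maximum(rng.normal(0.5, 0.4, n), 0.0)
    rep_rates[rng.random(n) < cfg.zero_inflation] = 0.0
    pro_rates[rng.random(n) < cfg.zero_inflation] = 0.0

    records = []
    tasks = ("conversation", "phone", "reading")
    for i in range(n):
        totals = rng.integers(_TOTALS_RANGE[0], _TOTALS_RANGE[1] + 1, size=3)
        reps = _counts_for_rate(rep_rates[i], totals)
        pros = _counts_for_rate(pro_rates[i], totals)
        blocks = _counts_for_rate(block_rates[i], totals)
        # disfluency counts can never exceed the syllables produced
        blocks = np.minimum(blocks, totals - reps - pros)
        samples = tuple(
            SpeechSample(
                sample_id=f"{ids[i]}_{task}",
                task=task,
                total_syllables=int(totals[s]),
                repetitions=int(reps[s]),
                prolongations=int(pros[s]),
                blocks=int(blocks[s]),
            )
            for s, task in enumerate(tasks)
        )
        records.append(BehavioralRecord(
            participant_id=ids[i],
            age=float(rng.integers(18, 56)),
            gender="M" if rng.random() < 0.75 else "F",
            site="MGH" if sites[i] == 1 else "BU",
            ssi4=float(rng.integers(9, 43)),
            samples=samples,
        ))
    return tuple(records)


def simulate_dataset(cfg: SimulationConfig = SimulationConfig()) -> SyntheticDataset:
    """Full synthetic cohort: connectivity, outcome, behavioral table, design.

    The planted sparse effects drive the block rate; the design matrix is
    assembled exactly as for real data (connections in list order plus the
    binary site column), with the outcome taken from the behavioral records
    so count-rounding enters the pipeline as it would with coded speech data.
    """
    ct = simulate_connectivity(cfg)
    y = simulate_outcome(ct, cfg)
    records = simulate_behavioral_table(cfg, block_rates=y)
    rates = tuple(aggregate_rates(r) for r in records)
    design = assemble_design(ct, rates, records, outcome="block")
    truth = cfg.truth_vector(len(design.column_labels))
    return SyntheticDataset(
        design=design,
        connectivity=ct,
        behavioral=records,
        rates=rates,
        truth=truth,
        support=tuple(k for k, _ in cfg.true_support),
        config=cfg,
    )


def write_truth_json(ds: SyntheticDataset, path: str | Path) -> None:
    """Ground-truth sidecar for a simulated cohort."""
    payload = {
        "support_indices": list(ds.support),
        "support_labels": [ds.design.column_labels[k] for k in ds.support],
        "coefficients": {
            ds.design.column_labels[j]: ds.truth[j]
            for j in range(len(ds.truth)) if ds.truth[j] != 0.0
        },
        "seed": ds.config.seed,
        "n_subjects": ds.config.n_subjects,
        "n_connections": ds.config.n_connections,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
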