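"""End-to-end orchestration: data in, per-outcome selection reports out.

Wires the stages together: read behavioral and connectivity tables, build
the design matrix per outcome, run the bootstrapped cross-validated LASSO,
screen for site heteroscedasticity, and write reports, figures and a
reproducibility manifest.  Everything is deterministic given the inputs and
the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from . import __version__
from .behavioral import (
    aggregate_rates,
    read_behavioral_csv,
    summarize_cohort,
    write_cohort_summary,
)
from .bootstrap import (
    BootstrapConfig,
    build_selection_report,
    run_bootstrap,
    write_selection_report,
)
from .connectivity import (
    OUTCOMES,
    assemble_design,
    load_connection_list,
    read_connectivity_csv,
)
from .diagnostics import site_heteroscedasticity_screen
from .lasso import LassoConfig
from .report import coefficient_heatmap, connection_scatter, selection_scree

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """One analysis run: input paths, outcome choice, stage configs."""

    behavioral_csv: str
    connectivity_csv: str
    connection_list: str | None = None  # None = packaged default
    outcomes: tuple[str, ...] = OUTCOMES
    lasso: LassoConfig = field(default_factory=LassoConfig)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    out_dir: str = "results"
    make_plots: bool = True

    def __post_init__(self) -> None:
        bad = [o for o in self.outcomes if o not in OUTCOMES]
        if bad:
            raise ValueError(f"unknown outcomes {bad}; choose from {OUTCOMES}")


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; returns the artifact manifest (also written).

    Outputs under ``out_dir``: per-outcome ``report_<outcome>.csv`` and
    ``run_<outcome>.json``, ``cohort_summary.csv``, ``site_levene.csv``,
    figures, and ``manifest.json``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    for path in (cfg.behavioral_csv, cfg.connectivity_csv):
        if not Path(path).exists():
            raise FileNotFoundError(f"input file not found: {path}")
    records = read_behavioral_csv(cfg.behavioral_csv)
    ct = read_connectivity_csv(cfg.connectivity_csv)
    if cfg.connection_list is not None:
        conns = load_connection_list(cfg.connection_list)
        if list(ct.connection_labels) != conns.labels:
            raise ValueError("connectivity table columns do not match connection list")
    rates = [aggregate_rates(r) for r in records]

    artifacts: list[str] = []

    summary = summarize_cohort(records, rates)
    write_cohort_summary(summary, out / "cohort_summary.csv")
    artifacts.append("cohort_summary.csv")

    screen = site_heteroscedasticity_screen(ct, records)
    screen.round(6).to_csv(out / "site_levene.csv", index=False)
    artifacts.append("site_levene.csv")
    if screen.attrs["normalization_suggested"]:
        logger.warning("Levene screen flagged connections; consider site harmonization")

    reports = {}
    designs = {}
    for outcome in cfg.outcomes:
        design = assemble_design(ct, rates, records, outcome)
        result = run_bootstrap(design, cfg.lasso, cfg.bootstrap)
        report = build_selection_report(result, cfg.bootstrap)
        csv_path = out / f"report_{outcome}.csv"
        write_selection_report(report, result, cfg.bootstrap, csv_path,
                               out / f"run_{outcome}.json")
        artifacts += [csv_path.name, f"run_{outcome}.json"]
        reports[outcome] = report
        designs[outcome] = design
        logger.info(
            "%s: avg lambda %.4g, %d significant, stable set %s",
            outcome, report.avg_lambda, int(report.significant.sum()),
            list(report.stable_set),
        )

    if cfg.make_plots and reports:
        coefficient_heatmap(reports, out / "coefficient_heatmap.png")
        artifacts.append("coefficient_heatmap.png")
        for outcome, report in reports.items():
            selection_scree(report, out / f"scree_{outcome}.png", title=outcome)
            artifacts.append(f"scree_{outcome}.png")
            if report.stable_set:
                connection_scatter(designs[outcome], report.stable_set,
                                   out / f"scatter_{outcome}.png")
                artifacts.append(f"scatter_{outcome}.png")

    manifest = {
        "version": __version__,
        "config": asdict(cfg),
        "config_hash": _config_hash(cfg),
        "seed": cfg.bootstrap.seed,
        "artifacts": sorted(artifacts),
        "stable_sets": {o: list(r.stable_set) for o, r in reports.items()},
        "avg_lambda": {o: r.avg_lambda for o, r in reports.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest
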