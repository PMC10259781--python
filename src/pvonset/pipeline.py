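"""End-to-end orchestration of the report-profiling pipeline.

Stages: read the four tables -> join into cases -> restrict to the study
drug -> flag target-event status and history against the term query ->
build the cohort (exclusion ledger) -> adjusted reporting odds ratios; and,
for the target-event cases, the onset-day sample -> summaries -> Weibull
fit and failure-type classification. Each stage logs its flow counts so the
case-selection flowchart can be reconstructed from the log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from . import cohort as cohort_mod
from . import dispro, jader, smq, tto
from .config import PipelineConfig
from .errors import FitError
from .jader import Sex, TableKind

logger = logging.getLogger(__name__)


@dataclass
class ProfileResult:
    cohort_rows: list
    ledger: cohort_mod.ExclusionLedger
    fit: dispro.LogisticFit
    effects: list[dispro.EffectEstimate]
    coding: dispro.Coding
    y: np.ndarray


@dataclass
class TtoResult:
    sample: tto.OnsetSample
    summary: tto.OnsetSummary
    fit: tto.WeibullFit
    hist_edges: np.ndarray
    hist_counts: np.ndarray


def load_cases(cfg: PipelineConfig):
    """Read the four tables and join them; returns (cases, orphan report)."""
    entries = {}
    for kind in TableKind:
        entries[kind] = jader.read_table(
            cfg.table_path(kind.value),
            kind,
            mapping=cfg.column_mapping.get(kind.value),
            delimiter=cfg.delimiter,
            encoding=cfg.encoding,
        )
    cases, orphans = jader.build_cases(
        entries[TableKind.DEMO], entries[TableKind.DRUG],
        entries[TableKind.REAC], entries[TableKind.HIST],
    )
    logger.info("joined %d cases (%d orphan rows)", len(cases), len(orphans))
    return cases, orphans


def _flagged_drug_cases(cfg: PipelineConfig):
    cases, orphans = load_cases(cfg)
    terms = smq.load_term_list(cfg.term_list) if cfg.term_list else smq.bundled_demo_terms()
    drug_cases = jader.filter_drug_cases(cases, cfg.drug_name)
    logger.info("%d cases mention %s", len(drug_cases), cfg.drug_name)
    flags = {c.case_id: smq.flag_case(c, terms) for c in drug_cases}
    return drug_cases, flags, orphans


def run_profile(cfg: PipelineConfig, write: bool = True) -> ProfileResult:
    """Cohort construction plus the adjusted reporting-odds-ratio model."""
    drug_cases, flags, orphans = _flagged_drug_cases(cfg)
    rows, ledger = cohort_mod.build_cohort(drug_cases, flags, cfg.cohort_config())
    logger.info(
        "cohort: %d retained of %d (%s)", ledger.n_retained, ledger.n_input,
        {r.value: c for r, c in ledger.counts.items()},
    )
    y, X, coding = dispro.dummy_code(rows, sex_reference=Sex(cfg.sex_reference))
    fit = dispro.fit_logistic(y, X, column_names=list(coding.column_names))
    if not fit.converged:
        raise FitError("logistic model did not converge; see warnings")
    effects = dispro.effects_from_fit(fit, coding)
    result = ProfileResult(rows, ledger, fit, effects, coding, y)
    if write:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cohort_mod.cohort_to_frame(rows).to_csv(out / "cohort.csv", index=False)
        (out / "exclusion_ledger.json").write_text(
            json.dumps(ledger.to_dict(), indent=2), encoding="utf-8"
        )
        dispro.effects_to_frame(effects, y).to_csv(out / "effects.csv", index=False)
        (out / "effects.json").write_text(
            json.dumps(
                [e.__dict__ for e in effects] , indent=2, default=float
            ),
            encoding="utf-8",
        )
        if len(orphans):
            orphans.to_frame().to_csv(out / "orphans.csv", index=False)
    return result


def run_tto(cfg: PipelineConfig, write: bool = True) -> TtoResult:
    """Time-to-onset analysis of the target-event cases."""
    drug_cases, flags, _ = _flagged_drug_cases(cfg)
    sample = tto.onset_days(
        drug_cases, flags, drug_name=cfg.drug_name,
        window_days=cfg.window_days, convention=cfg.day_convention,
    )
    logger.info(
        "onset sample: n=%d (missing-date excl %d, beyond-window excl %d)",
        sample.n, sample.n_excluded_missing_dates, sample.n_excluded_beyond_window,
    )
    if sample.n == 0:
        raise FitError("empty onset sample after exclusions")
    summary = tto.summarize(sample)
    fit = tto.fit_weibull(sample)
    edges, counts = tto.histogram(sample, cfg.histogram_bin_days)
    result = TtoResult(sample, summary, fit, edges, counts)
    if write:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        payload = {
            "n": summary.n,
            "median_days": summary.median,
            "q1_days": summary.q1,
            "q3_days": summary.q3,
            "proportion_within_365d": tto.proportion_within(sample, 365),
            "n_excluded_missing_dates": sample.n_excluded_missing_dates,
            "n_excluded_beyond_window": sample.n_excluded_beyond_window,
            "window_days": sample.window_days,
            "weibull": fit.to_dict(),
            "seed": cfg.seed,
        }
        (out / "tto_summary.json").write_text(
            json.dumps(payload, indent=2), encoding="utf-8"
        )
        import pandas as pd

        pd.DataFrame(
            {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts}
        ).to_csv(out / "onset_histogram.csv", index=False)
    return result


def plot_onset_histogram(result: TtoResult, path: str | Path) -> None:
    """Optional onset histogram with the fitted Weibull density overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy import stats as sps

    edges, counts = result.hist_edges, result.hist_counts
    width = edges[1] - edges[0]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(edges[:-1], counts, width=width, align="edge",
           color="#4878a8", edgecolor="white")
    t = np.linspace(1, edges[-1], 400)
    dens = sps.weibull_min.pdf(t, result.fit.beta, scale=result.fit.alpha)
    ax.plot(t, dens * result.sample.n * width, color="#b0413e",
            label=f"Weibull fit (shape={result.fit.beta:.2f})")
    ax.set_xlabel("days from initiation to onset")
    ax.set_ylabel("reports")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
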