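"""Per-neuron consensus labelling and cohort-level comparison.

Each eligible neuron is classified twice -- by the autocorrelogram (primary)
and by the discharge density histogram (confirmation) -- and the two labels
are combined by a consensus policy:

* ``acg-primary`` (default): the ACG label is final; the DDH label and the
  agreement flag are recorded as confirmation.
* ``ddh-primary``: the DDH label is final.
* ``strict``: disagreements become 'unclassified'; no label is ever flipped.

Cohort summaries report, per group, mean +/- SEM firing rate, mean +/- SEM and
median CVisi, pattern proportions over classified neurons, and the three
between-group tests (Student's t on rate, Mann-Whitney U on CVisi, Pearson
chi-square on the pattern contingency table).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .acg import compute_autocorrelogram, extract_acg_features, classify_acg
from .config import PipelineConfig
from .core import NeuronMetrics, SpikeTrain, eligibility
from .ddh import compute_density_histogram, classify_ddh
from .stats import StatError, chi_square, mann_whitney_u, sem, students_t

__all__ = [
    "NeuronResult",
    "GroupSummary",
    "GroupComparison",
    "PATTERN_COLUMNS",
    "classify_neuron",
    "summarize_cohort",
    "contingency_table",
]

PATTERN_COLUMNS = ("regular", "irregular", "bursty")


@dataclass(frozen=True)
class NeuronResult:
    """Final classification record for one neuron."""

    neuron_id: str
    group: Optional[str]
    metrics: NeuronMetrics
    label_acg: str
    label_ddh: str
    label_final: str
    methods_agree: bool
    exclusion_reason: Optional[str] = None


@dataclass(frozen=True)
class GroupSummary:
    """Descriptive statistics of one group over its classified neurons."""

    group: str
    n_total: int
    n_classified: int
    rate_mean: float
    rate_sem: float
    cv_mean: float
    cv_sem: float
    cv_median: float
    pattern_counts: Dict[str, int]
    pattern_proportions: Dict[str, float]


@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison: descriptives plus the three test statistics."""

    groups: Tuple[GroupSummary, ...]
    t_statistic: Optional[float] = None
    t_df: Optional[int] = None
    t_pvalue: Optional[float] = None
    u_statistic: Optional[float] = None
    u_pvalue: Optional[float] = None
    chi2_statistic: Optional[float] = None
    chi2_df: Optional[int] = None
    chi2_pvalue: Optional[float] = None
    chi2_columns: Tuple[str, ...] = ()


def classify_neuron(
    train: SpikeTrain, config: Optional[PipelineConfig] = None
) -> NeuronResult:
    """Run eligibility gates and both classifiers on one spike train.

    Ineligible or degenerate trains never raise: they yield
    ``label_final='unclassified'`` with a machine-readable exclusion reason
    (``insufficient_spikes``, ``short_recording``, ``rate_out_of_range``).
    """
    cfg = config or PipelineConfig()
    metrics = eligibility(
        train,
        rate_range=cfg.rate_range,
        min_spikes=cfg.min_spikes,
        min_duration=cfg.min_duration,
    )
    reason = None
    if train.n_spikes < cfg.min_spikes:
        reason = "insufficient_spikes"
    elif train.duration < cfg.min_duration:
        reason = "short_recording"
    elif not metrics.is_putative_da:
        reason = "rate_out_of_range"
    if reason is not None:
        return NeuronResult(
            neuron_id=train.neuron_id,
            group=train.group,
            metrics=metrics,
            label_acg="unclassified",
            label_ddh="unclassified",
            label_final="unclassified",
            methods_agree=True,
            exclusion_reason=reason,
        )

    acg = compute_autocorrelogram(
        train,
        bin_width=cfg.acg.bin_width,
        max_lag=cfg.acg.max_lag,
        min_spikes=cfg.min_spikes,
    )
    label_acg = classify_acg(extract_acg_features(acg, cfg.acg), cfg.acg)
    hist = compute_density_histogram(
        train, m=cfg.ddh.m, noise_floor=cfg.ddh.noise_floor, min_spikes=cfg.min_spikes
    )
    label_ddh = classify_ddh(hist, cfg.ddh)

    agree = label_acg == label_ddh
    if cfg.consensus_policy == "acg-primary":
        final = label_acg
    elif cfg.consensus_policy == "ddh-primary":
        final = label_ddh
    else:  # strict
        final = label_acg if agree else "unclassified"
    return NeuronResult(
        neuron_id=train.neuron_id,
        group=train.group,
        metrics=metrics,
        label_acg=label_acg,
        label_ddh=label_ddh,
        label_final=final,
        methods_agree=agree,
    )


def results_frame(results: Sequence[NeuronResult]) -> pd.DataFrame:
    """Tabulate per-neuron results (one row per neuron)."""
    return pd.DataFrame.from_records(
        [
            {
                "neuron_id": r.neuron_id,
                "group": r.group,
                "n_spikes": r.metrics.n_spikes,
                "duration_s": r.metrics.duration,
                "firing_rate_hz": r.metrics.firing_rate,
                "cv_isi_pct": r.metrics.cv_isi,
                "label_acg": r.label_acg,
                "label_ddh": r.label_ddh,
                "label_final": r.label_final,
                "methods_agree": r.methods_agree,
                "exclusion_reason": r.exclusion_reason or "",
            }
            for r in results
        ]
    )


def contingency_table(
    results: Sequence[NeuronResult],
    columns: Sequence[str] = PATTERN_COLUMNS,
) -> pd.DataFrame:
    """Group x pattern counts over classified neurons (unclassified excluded)."""
    groups = sorted({r.group or "" for r in results})
    table = pd.DataFrame(0, index=groups, columns=list(columns))
    for r in results:
        if r.label_final in columns:
            table.loc[r.group or "", r.label_final] += 1
    return table


def summarize_cohort(results: Sequence[NeuronResult]) -> GroupComparison:
    """Summarize per-group descriptives and run the between-group tests.

    Requires at least 2 classified neurons per group.  The t, U and
    chi-square statistics are computed only for the two-group case;
    all-zero pattern columns are dropped from the chi-square table (the
    test is undefined on zero margins).
    """
    by_group: Dict[str, List[NeuronResult]] = {}
    for r in results:
        by_group.setdefault(r.group or "", []).append(r)

    summaries = []
    for group in sorted(by_group):
        rs = by_group[group]
        classified = [r for r in rs if r.label_final in PATTERN_COLUMNS]
        if len(classified) < 2:
            raise StatError(
                f"group {group!r} has fewer than 2 classified neurons"
            )
        rates = [r.metrics.firing_rate for r in classified]
        cvs = [r.metrics.cv_isi for r in classified]
        counts = {
            p: sum(r.label_final == p for r in classified) for p in PATTERN_COLUMNS
        }
        n_cls = len(classified)
        summaries.append(
            GroupSummary(
                group=group,
                n_total=len(rs),
                n_classified=n_cls,
                rate_mean=float(np.mean(rates)),
                rate_sem=sem(rates),
                cv_mean=float(np.mean(cvs)),
                cv_sem=sem(cvs),
                cv_median=float(np.median(cvs)),
                pattern_counts=counts,
                pattern_proportions={p: c / n_cls for p, c in counts.items()},
            )
        )

    comparison = GroupComparison(groups=tuple(summaries))
    if len(summaries) == 2:
        a = [
            r.metrics.firing_rate
            for r in by_group[summaries[0].group]
            if r.label_final in PATTERN_COLUMNS
        ]
        b = [
            r.metrics.firing_rate
            for r in by_group[summaries[1].group]
            if r.label_final in PATTERN_COLUMNS
        ]
        cv_a = [
            r.metrics.cv_isi
            for r in by_group[summaries[0].group]
            if r.label_final in PATTERN_COLUMNS
        ]
        cv_b = [
            r.metrics.cv_isi
            for r in by_group[summaries[1].group]
            if r.label_final in PATTERN_COLUMNS
        ]
        t, df, tp = students_t(a, b)
        u, up = mann_whitney_u(cv_a, cv_b)
        table = contingency_table(results)
        kept = [c for c in table.columns if table[c].sum() > 0]
        chi2, cdf, cp = chi_square(table[kept].to_numpy())
        comparison = GroupComparison(
            groups=tuple(summaries),
            t_statistic=t,
            t_df=df,
            t_pvalue=tp,
            u_statistic=u,
            u_pvalue=up,
            chi2_statistic=chi2,
            chi2_df=cdf,
            chi2_pvalue=cp,
            chi2_columns=tuple(kept),
        )
    return comparison
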