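"""End-to-end pipeline: manifest -> per-neuron labels -> cohort summary.

Deterministic given the inputs and configuration: re-running with the same
files and config produces byte-identical output tables.  Unreadable or
malformed neuron files are recorded in the exclusion log (one row per neuron,
machine-readable reason) and the pipeline continues; an empty group is fatal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Union

import pandas as pd

from .config import PipelineConfig
from .consensus import (
    GroupComparison,
    NeuronResult,
    classify_neuron,
    results_frame,
    summarize_cohort,
)
from .core import SpikeTrain
from .io import SpikeFileError, read_manifest, read_spike_file

__all__ = ["PipelineResult", "run_pipeline", "classify_trains", "write_outputs"]

log = logging.getLogger("spikepattern")


@dataclass
class PipelineResult:
    """Everything the pipeline produced for one cohort run."""

    results: List[NeuronResult]
    comparison: Optional[GroupComparison]
    table: pd.DataFrame
    exclusions: pd.DataFrame
    n_failed_files: int = 0


def classify_trains(
    trains: Sequence[SpikeTrain],
    config: Optional[PipelineConfig] = None,
    compare_groups: bool = True,
) -> PipelineResult:
    """Classify a list of in-memory trains and summarize by group."""
    cfg = config or PipelineConfig()
    results = [classify_neuron(t, cfg) for t in trains]
    return _assemble(results, cfg, n_failed=0, compare_groups=compare_groups)


def run_pipeline(
    manifest_path: Union[str, Path],
    config: Optional[PipelineConfig] = None,
    compare_groups: bool = True,
) -> PipelineResult:
    """Read a manifest, classify every resolvable neuron file, summarize.

    Per-row file errors are logged and recorded; the run continues with the
    remaining neurons.
    """
    cfg = config or PipelineConfig()
    manifest = read_manifest(manifest_path)
    base = Path(manifest_path).parent
    results: List[NeuronResult] = []
    failed_rows = []
    for row in manifest.itertuples(index=False):
        path = Path(row.path)
        if not path.is_absolute():
            path = base / path
        try:
            train = read_spike_file(
                path,
                neuron_id=row.neuron_id,
                group=row.group or None,
                duration=float(row.duration_s) if pd.notna(row.duration_s) else None,
            )
        except (OSError, SpikeFileError) as exc:
            log.error("skipping %s: %s", row.neuron_id, exc)
            failed_rows.append(
                {"neuron_id": row.neuron_id, "reason": "unreadable_file"}
            )
            continue
        results.append(classify_neuron(train, cfg))
    if not results:
        raise SpikeFileError(f"{manifest_path}: no readable neuron files")
    out = _assemble(
        results, cfg, n_failed=len(failed_rows), compare_groups=compare_groups
    )
    if failed_rows:
        out.exclusions = pd.concat(
            [out.exclusions, pd.DataFrame(failed_rows)], ignore_index=True
        )
    return out


def _assemble(
    results: List[NeuronResult],
    cfg: PipelineConfig,
    n_failed: int,
    compare_groups: bool,
) -> PipelineResult:
    table = results_frame(results)
    excl = pd.DataFrame(
        [
            {"neuron_id": r.neuron_id, "reason": r.exclusion_reason}
            for r in results
            if r.exclusion_reason
        ],
        columns=["neuron_id", "reason"],
    )
    comparison = None
    if compare_groups:
        groups = {r.group for r in results}
        if len(groups) >= 1 and groups != {None}:
            comparison = summarize_cohort(results)
    return PipelineResult(
        results=results,
        comparison=comparison,
        table=table,
        exclusions=excl,
        n_failed_files=n_failed,
    )


def write_outputs(
    result: PipelineResult, out_dir: Union[str, Path], cfg: Optional[PipelineConfig] = None
) -> None:
    """Write the per-neuron table, exclusion log and cohort summary report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.table.to_csv(out / "results.tsv", sep="\t", index=False, float_format="%.6f")
    result.exclusions.to_csv(out / "exclusions.tsv", sep="\t", index=False)
    if cfg is not None:
        cfg.write(out / "config.txt")
    if result.comparison is not None:
        (out / "summary.txt").write_text(format_summary(result.comparison))


def format_summary(cmp: GroupComparison) -> str:
    """Render a cohort comparison as a flat key = value report."""
    lines = []
    for g in cmp.groups:
        p = g.pattern_proportions
        lines += [
            f"group.{g.group}.n_total = {g.n_total}",
            f"group.{g.group}.n_classified = {g.n_classified}",
            f"group.{g.group}.rate_mean_hz = {g.rate_mean:.4f}",
            f"group.{g.group}.rate_sem_hz = {g.rate_sem:.4f}",
            f"group.{g.group}.cv_isi_mean_pct = {g.cv_mean:.4f}",
            f"group.{g.group}.cv_isi_sem_pct = {g.cv_sem:.4f}",
            f"group.{g.group}.cv_isi_median_pct = {g.cv_median:.4f}",
        ]
        for pat, prop in p.items():
            lines.append(f"group.{g.group}.prop_{pat} = {prop:.4f}")
    if cmp.t_statistic is not None:
        lines += [
            f"test.rate.t = {cmp.t_statistic:.4f}",
            f"test.rate.df = {cmp.t_df}",
            f"test.rate.p = {cmp.t_pvalue:.4g}",
            f"test.cv.U = {cmp.u_statistic:.1f}",
            f"test.cv.p = {cmp.u_pvalue:.4g}",
            f"test.pattern.chi2 = {cmp.chi2_statistic:.4f}",
            f"test.pattern.df = {cmp.chi2_df}",
            f"test.pattern.p = {cmp.chi2_pvalue:.4g}",
        ]
    return "\n".join(lines) + "\n"
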