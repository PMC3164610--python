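"""End-to-end library pipeline: filter -> quantify -> stratify -> summarize.

This is the programmatic surface the CLI wraps: it consumes in-memory spectra
and PSM lists (one pair per cross-linking condition) and produces collapsed
peptidoform quants, per-(class, condition) summaries, and the plot-ready
condition table, together with an accounting of every record that was
filtered or excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chem import LabelScheme
from .io import (
    FilterReport,
    GroupDefinition,
    PsmRecord,
    SpectrumMS1,
    filter_psms,
)
from .quant import PairQuant, QuantParams, QuantReport, pair_to_row, quantify_all
from .stats import GroupSummary, condition_table, summarize_conditions, summary_to_row


@dataclass
class PipelineResult:
    quants: dict[str, list[PairQuant]]
    summaries: list[GroupSummary]
    quant_rows: list[dict]
    summary_rows: list[dict]
    plot_rows: list[dict]
    filter_reports: dict[str, FilterReport]
    quant_reports: dict[str, QuantReport]
    condition_order: list[str] = field(default_factory=list)

    @property
    def n_quantified(self) -> int:
        return sum(len(v) for v in self.quants.values())


def run_pipeline(
    spectra_by_condition: dict[str, list[SpectrumMS1]],
    psms_by_condition: dict[str, list[PsmRecord]],
    groups: list[GroupDefinition],
    condition_order: list[str] | None = None,
    params: QuantParams | None = None,
    q_max: float = 0.01,
    scheme: LabelScheme | None = None,
) -> PipelineResult:
    """Run the full analysis across conditions.

    Raises ValueError when the condition labels of the spectra and PSM inputs
    disagree, or when no quantifiable peptide survives the filters.
    """
    params = params or QuantParams()
    scheme = scheme or LabelScheme()
    if set(spectra_by_condition) != set(psms_by_condition):
        raise ValueError(
            "condition labels differ between spectra "
            f"({sorted(spectra_by_condition)}) and PSMs ({sorted(psms_by_condition)})"
        )
    condition_order = condition_order or list(spectra_by_condition)

    quants: dict[str, list[PairQuant]] = {}
    filter_reports: dict[str, FilterReport] = {}
    quant_reports: dict[str, QuantReport] = {}
    quant_rows: list[dict] = []
    for condition in condition_order:
        kept, filter_reports[condition] = filter_psms(
            psms_by_condition[condition], q_max=q_max, scheme=scheme
        )
        pairs, quant_reports[condition] = quantify_all(
            spectra_by_condition[condition], kept, params
        )
        quants[condition] = pairs
        quant_rows.extend(pair_to_row(p, condition) for p in pairs)

    if not any(quants.values()):
        raise ValueError("no quantifiable peptides after filtering and extraction")

    summaries = summarize_conditions(quants, groups, condition_order)
    return PipelineResult(
        quants=quants,
        summaries=summaries,
        quant_rows=quant_rows,
        summary_rows=[summary_to_row(s) for s in summaries],
        plot_rows=condition_table(summaries, condition_order),
        filter_reports=filter_reports,
        quant_reports=quant_reports,
        condition_order=condition_order,
    )


def class_mean_percent_light(result: PipelineResult, class_label: str,
                             conditions: list[str] | None = None) -> tuple[float, int]:
    """Pooled mean percent light (and n) for one class across conditions."""
    values = [
        s.mean_percent_light
        for s in result.summaries
        if s.key.class_label == class_label
        and (conditions is None or s.key.condition in conditions)
    ]
    ns = [
        s.n_peptides
        for s in result.summaries
        if s.key.class_label == class_label
        and (conditions is None or s.key.condition in conditions)
    ]
    if not values:
        raise ValueError(f"no summaries for class {class_label!r}")
    total = sum(ns)
    pooled = sum(v * n for v, n in zip(values, ns)) / total
    return pooled, total
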