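"""Stratification of quantified peptidoforms and per-condition exchange summaries.

Classes are defined by a protein set plus required/forbidden PTM signatures in
protein coordinates (e.g. H3K9ac + H3K14ac required for the acetylated class,
forbidden for the bulk class). Per (class, condition) cell the summary reports
n, mean percent light, standard error, and two exchange readouts: the raw
fraction heavy (1 - mean) and that fraction normalized to the 0.5 level of a
fully equilibrated 1:1 mixture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .io import GroupDefinition
from .quant import PairQuant

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class GroupKey:
    class_label: str
    condition: str


@dataclass(frozen=True)
class GroupSummary:
    key: GroupKey
    n_peptides: int
    mean_percent_light: float
    sem: float | None  # None when n_peptides == 1
    exchange_fraction: float
    normalized_exchange: float

    def __post_init__(self) -> None:
        if self.n_peptides < 1:
            raise ValueError("n_peptides must be >= 1")
        if not 0.0 <= self.mean_percent_light <= 1.0:
            raise ValueError("mean_percent_light must be in [0, 1]")
        if self.sem is not None and self.sem < 0:
            raise ValueError("sem must be >= 0")


def exchange_metrics(mean_percent_light: float) -> tuple[float, float]:
    """(exchange_fraction, normalized_exchange) from a group's mean percent light.

    exchange_fraction is the fraction of signal that is heavy (1 - mean);
    normalized_exchange rescales it so that the 50% light level of complete
    equilibration with the 1:1 heavy culture maps to 1, clamped to [0, 1].
    """
    if not 0.0 <= mean_percent_light <= 1.0:
        raise ValueError("mean_percent_light must be in [0, 1]")
    exchange_fraction = 1.0 - mean_percent_light
    normalized = min(1.0, exchange_fraction / 0.5)
    return exchange_fraction, normalized


def _matches(pair: PairQuant, group: GroupDefinition) -> bool:
    if pair.protein_id not in group.protein_ids:
        return False
    start, end = pair.protein_start, pair.protein_start + len(pair.sequence) - 1
    present = set()
    for token in filter(None, pair.mod_string.split(";")):
        pos_str, name = token.split(":", 1)
        present.add((pair.protein_start + int(pos_str) - 1, name))
    required_in_span = {
        (pos, name) for pos, name in group.required_mods if start <= pos <= end
    }
    if group.required_mods and not required_in_span:
        # Span does not cover any signature position: cannot attest the class.
        return False
    if required_in_span - present:
        return False
    forbidden_in_span = {
        (pos, name) for pos, name in group.forbidden_mods if start <= pos <= end
    }
    if forbidden_in_span & present:
        return False
    return True


def classify(pair: PairQuant, group_defs: list[GroupDefinition]) -> str:
    """Class label for one peptidoform; 'unassigned' when no class matches.

    Raises if the definitions overlap on this peptidoform — strata must
    partition the data.
    """
    matches = [g.class_label for g in group_defs if _matches(pair, g)]
    if len(matches) > 1:
        raise ValueError(
            f"peptidoform {pair.protein_id}/{pair.sequence}/{pair.mod_string or '-'} "
            f"matches multiple classes: {', '.join(matches)}"
        )
    return matches[0] if matches else UNASSIGNED


def summarize(key: GroupKey, pairs: list[PairQuant]) -> GroupSummary:
    """Mean percent light +/- SEM over the unique peptidoforms of one group.

    SEM uses the sample standard deviation (n-1 denominator) and is absent
    at n = 1.
    """
    if not pairs:
        raise ValueError("summarize requires at least one peptidoform")
    values = [p.percent_light for p in pairs]
    n = len(values)
    mean = sum(values) / n
    if n == 1:
        sem = None
    else:
        var = sum((v - mean) ** 2 for v in values) / (n - 1)
        sem = math.sqrt(var / n)
    exchange_fraction, normalized = exchange_metrics(mean)
    return GroupSummary(key, n, mean, sem, exchange_fraction, normalized)


def summarize_conditions(
    quants_by_condition: dict[str, list[PairQuant]],
    group_defs: list[GroupDefinition],
    condition_order: list[str] | None = None,
) -> list[GroupSummary]:
    """Classify and summarize every (class, condition) cell with data."""
    if condition_order is None:
        condition_order = list(quants_by_condition)
    unknown = set(quants_by_condition) - set(condition_order)
    if unknown:
        raise ValueError(f"conditions not in declared order: {sorted(unknown)}")
    summaries = []
    for condition in condition_order:
        by_class: dict[str, list[PairQuant]] = {}
        for pair in quants_by_condition.get(condition, []):
            by_class.setdefault(classify(pair, group_defs), []).append(pair)
        for group in group_defs:
            label = group.class_label
            if by_class.get(label):
                summaries.append(
                    summarize(GroupKey(label, condition), by_class[label])
                )
        if by_class.get(UNASSIGNED):
            summaries.append(
                summarize(GroupKey(UNASSIGNED, condition), by_class[UNASSIGNED])
            )
    return summaries


def condition_table(
    summaries: list[GroupSummary], condition_order: list[str]
) -> list[dict]:
    """One row per (class, condition) in declared order, percentages x100.

    Cells with no data are emitted with n_peptides = 0 rather than dropped,
    so the table is a complete grid suitable for plotting percent light vs
    cross-linking condition with error bars.
    """
    known = {s.key.condition for s in summaries}
    unknown = known - set(condition_order)
    if unknown:
        raise ValueError(f"unknown condition label(s): {sorted(unknown)}")
    by_key = {(s.key.class_label, s.key.condition): s for s in summaries}
    class_order = []
    for s in summaries:
        if s.key.class_label not in class_order:
            class_order.append(s.key.class_label)
    rows = []
    for label in class_order:
        for condition in condition_order:
            s = by_key.get((label, condition))
            if s is None:
                rows.append(
                    {
                        "class_label": label,
                        "condition": condition,
                        "n_peptides": 0,
                        "mean_percent_light_pct": None,
                        "sem_pct": None,
                        "exchange_fraction_pct": None,
                        "normalized_exchange": None,
                    }
                )
            else:
                rows.append(
                    {
                        "class_label": label,
                        "condition": condition,
                        "n_peptides": s.n_peptides,
                        "mean_percent_light_pct": 100.0 * s.mean_percent_light,
                        "sem_pct": None if s.sem is None else 100.0 * s.sem,
                        "exchange_fraction_pct": 100.0 * s.exchange_fraction,
                        "normalized_exchange": s.normalized_exchange,
                    }
                )
    return rows


def summary_to_row(s: GroupSummary) -> dict:
    """Summary-table row (io.SUMMARY_COLUMNS) for one group."""
    return {
        "class_label": s.key.class_label,
        "condition": s.key.condition,
        "n_peptides": s.n_peptides,
        "mean_percent_light": s.mean_percent_light,
        "sem": s.sem,
        "exchange_fraction": s.exchange_fraction,
        "normalized_exchange": s.normalized_exchange,
    }
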