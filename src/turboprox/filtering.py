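"""Record-removal rules applied to proteinGroups tables before quantification.

Removed are: reverse (decoy-database) identifications, potential
contaminants, groups identified only by a modified peptide, groups with
fewer than ``min_group_values`` quantified LFQ values in one group, and
groups with fewer than ``min_razor`` razor+unique peptides.  Each removed
record is attributed to the first rule (in that fixed order) that rejects
it, so the report counts partition the input.
"""

from __future__ import annotations

from dataclasses import dataclass

from turboprox.design_io import ProteinGroupRecord, ProteinGroupTable

RULE_ORDER = ("reverse", "contaminant", "only-by-site", "min-group-values", "min-razor")

#: How "fewer than two quantitative values in one group" is resolved:
#: ``any_group`` keeps a record if either group has enough quantified values
#: (a proximity interactor absent from every control survives),
#: ``experimental_group`` requires them in the experimental group only,
#: ``both_groups`` requires them in both.
GROUP_VALUE_MODES = ("any_group", "experimental_group", "both_groups")


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    removed_reverse: int
    removed_contaminant: int
    removed_only_by_site: int
    removed_min_group_values: int
    removed_min_razor: int
    n_retained: int
    rule_order: tuple[str, ...] = RULE_ORDER

    @property
    def n_removed(self) -> int:
        return (
            self.removed_reverse
            + self.removed_contaminant
            + self.removed_only_by_site
            + self.removed_min_group_values
            + self.removed_min_razor
        )

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "removed_reverse": self.removed_reverse,
            "removed_contaminant": self.removed_contaminant,
            "removed_only_by_site": self.removed_only_by_site,
            "removed_min_group_values": self.removed_min_group_values,
            "removed_min_razor": self.removed_min_razor,
            "n_retained": self.n_retained,
        }


def _group_values_ok(
    record: ProteinGroupRecord,
    table: ProteinGroupTable,
    min_group_values: int,
    mode: str,
) -> bool:
    n_exp = sum(record.quantified(s) for s in table.design.experimental)
    n_ctl = sum(record.quantified(s) for s in table.design.control)
    if mode == "any_group":
        return max(n_exp, n_ctl) >= min_group_values
    if mode == "experimental_group":
        return n_exp >= min_group_values
    if mode == "both_groups":
        return min(n_exp, n_ctl) >= min_group_values
    raise ValueError(f"unknown group_value_mode {mode!r}")


def failing_rule(
    record: ProteinGroupRecord,
    table: ProteinGroupTable,
    min_razor: int = 2,
    min_group_values: int = 2,
    group_value_mode: str = "any_group",
) -> str | None:
    """Name of the first rule that rejects ``record``, or None if retained."""
    if record.is_reverse:
        return "reverse"
    if record.is_contaminant:
        return "contaminant"
    if record.only_identified_by_site:
        return "only-by-site"
    if not _group_values_ok(record, table, min_group_values, group_value_mode):
        return "min-group-values"
    if record.razor_unique_peptides < min_razor:
        return "min-razor"
    return None


def apply_filters(
    table: ProteinGroupTable,
    min_razor: int = 2,
    min_group_values: int = 2,
    group_value_mode: str = "any_group",
) -> tuple[ProteinGroupTable, FilterReport]:
    """Apply the removal rules; return the retained table and a removal report."""
    if group_value_mode not in GROUP_VALUE_MODES:
        raise ValueError(
            f"unknown group_value_mode {group_value_mode!r}; "
            f"expected one of {GROUP_VALUE_MODES}"
        )
    counts = {rule: 0 for rule in RULE_ORDER}
    kept = []
    for record in table.records:
        rule = failing_rule(record, table, min_razor, min_group_values, group_value_mode)
        if rule is None:
            kept.append(record)
        else:
            counts[rule] += 1
    report = FilterReport(
        n_input=len(table.records),
        removed_reverse=counts["reverse"],
        removed_contaminant=counts["contaminant"],
        removed_only_by_site=counts["only-by-site"],
        removed_min_group_values=counts["min-group-values"],
        removed_min_razor=counts["min-razor"],
        n_retained=len(kept),
    )
    return ProteinGroupTable(records=tuple(kept), design=table.design), report
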