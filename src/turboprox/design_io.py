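"""Readers for the sample design and MaxQuant-style proteinGroups tables.

A *sample design* maps sample labels to an experimental or control group
with a replicate index (the study design here is 3 experimental vs 3
control replicates).  A *proteinGroups table* is the tab-separated protein
quantification output of a MaxQuant search: one row per protein group with
identification-quality flags and one ``LFQ intensity <sample>`` column per
run, where an intensity of 0 means "not quantified".
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd

GROUP_EXPERIMENTAL = "experimental"
GROUP_CONTROL = "control"
VALID_GROUPS = (GROUP_EXPERIMENTAL, GROUP_CONTROL)

#: Default MaxQuant proteinGroups.txt column names.  Re-exported spreadsheets
#: (e.g. supplementary workbooks) may rename these; pass ``column_map``
#: overrides to :func:`read_protein_groups` in that case.
DEFAULT_COLUMN_MAP = {
    "protein_ids": "Majority protein IDs",
    "gene_names": "Gene names",
    "razor_unique_peptides": "Razor + unique peptides",
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
    "only_by_site": "Only identified by site",
}

LFQ_PREFIX = "LFQ intensity "


class DesignError(ValueError):
    """Raised when a sample design violates its invariants."""


class TableError(ValueError):
    """Raised when a proteinGroups table cannot be parsed or validated."""


@dataclass(frozen=True)
class SampleEntry:
    sample_id: str
    group: str
    replicate: int


@dataclass(frozen=True)
class SampleDesign:
    """Validated mapping of sample labels to groups and replicate indices."""

    entries: tuple[SampleEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dup = sorted({s for s in ids if ids.count(s) > 1})
            raise DesignError(f"duplicate sample_id(s): {', '.join(dup)}")
        for e in self.entries:
            if e.group not in VALID_GROUPS:
                raise DesignError(
                    f"unknown group label {e.group!r} for sample {e.sample_id!r} "
                    f"(expected one of {VALID_GROUPS})"
                )
            if e.replicate < 1:
                raise DesignError(
                    f"replicate index must be a positive integer "
                    f"(sample {e.sample_id!r} has {e.replicate})"
                )
        for group in VALID_GROUPS:
            members = [e for e in self.entries if e.group == group]
            if len(members) < 2:
                raise DesignError(
                    f"group {group!r} too small for t-test: has {len(members)} "
                    f"sample(s), need at least 2"
                )
            reps = [e.replicate for e in members]
            if len(set(reps)) != len(reps):
                raise DesignError(f"duplicate replicate indices within group {group!r}")

    def samples(self, group: str | None = None) -> list[str]:
        if group is None:
            return [e.sample_id for e in self.entries]
        return [e.sample_id for e in self.entries if e.group == group]

    @property
    def experimental(self) -> list[str]:
        return self.samples(GROUP_EXPERIMENTAL)

    @property
    def control(self) -> list[str]:
        return self.samples(GROUP_CONTROL)


@dataclass(frozen=True)
class ProteinGroupRecord:
    """One proteinGroups row: identity, QC flags and per-sample LFQ intensities."""

    group_id: str
    protein_ids: tuple[str, ...]
    gene_names: tuple[str, ...]
    razor_unique_peptides: int
    is_reverse: bool
    is_contaminant: bool
    only_identified_by_site: bool
    lfq: dict[str, float] = field(compare=True)

    def quantified(self, sample_id: str) -> bool:
        return self.lfq[sample_id] > 0


@dataclass(frozen=True)
class ProteinGroupTable:
    records: tuple[ProteinGroupRecord, ...]
    design: SampleDesign

    def __post_init__(self) -> None:
        gids = [r.group_id for r in self.records]
        if len(set(gids)) != len(gids):
            dup = sorted({g for g in gids if gids.count(g) > 1})
            raise TableError(f"duplicate group_id(s): {', '.join(dup)}")
        wanted = set(self.design.samples())
        for r in self.records:
            missing = wanted - set(r.lfq)
            if missing:
                raise TableError(
                    f"record {r.group_id!r} lacks LFQ values for sample(s) "
                    f"{sorted(missing)}"
                )
            for s, v in r.lfq.items():
                if not (v >= 0) or v != v or v in (float("inf"),):
                    raise TableError(
                        f"record {r.group_id!r} has invalid intensity {v!r} "
                        f"for sample {s!r}"
                    )
            if r.razor_unique_peptides < 0:
                raise TableError(
                    f"record {r.group_id!r} has negative razor+unique peptide count"
                )

    def __len__(self) -> int:
        return len(self.records)


def _sniff_sep(text: str) -> str:
    first = text.splitlines()[0] if text else ""
    return "\t" if "\t" in first else ","


def read_design(path) -> SampleDesign:
    """Read a sample design table (columns: sample_id, group[, replicate]).

    Accepts tab- or comma-separated files, UTF-8 with or without BOM.  When
    the replicate column is absent, replicates are numbered in file order
    within each group.
    """
    with open(path, encoding="utf-8-sig") as fh:
        text = fh.read()
    df = pd.read_csv(io.StringIO(text), sep=_sniff_sep(text), dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise DesignError(
            "design file needs 'sample_id' and 'group' columns, "
            f"found {list(df.columns)}"
        )
    counters: dict[str, int] = {}
    entries = []
    for i, row in df.iterrows():
        sample_id = str(row["sample_id"]).strip()
        group = str(row["group"]).strip().lower()
        if group not in VALID_GROUPS:
            raise DesignError(
                f"unknown group label {group!r} in design row {i + 1} "
                f"(sample {sample_id!r})"
            )
        if "replicate" in df.columns and not pd.isna(row["replicate"]):
            rep = int(row["replicate"])
        else:
            counters[group] = counters.get(group, 0) + 1
            rep = counters[group]
        entries.append(SampleEntry(sample_id=sample_id, group=group, replicate=rep))
    return SampleDesign(entries=tuple(entries))


def _flag(value) -> bool:
    # MaxQuant convention: "+" marks true, empty cell marks false.
    if pd.isna(value):
        return False
    return str(value).strip() == "+"


def _split_ids(value) -> tuple[str, ...]:
    if pd.isna(value) or str(value).strip() == "":
        return ()
    return tuple(p.strip() for p in str(value).split(";") if p.strip())


def read_protein_groups(
    path, design: SampleDesign, column_map: dict[str, str] | None = None
) -> ProteinGroupTable:
    """Parse a tab-separated proteinGroups table against a sample design.

    LFQ columns are resolved by exact match ``LFQ intensity <sample_id>``;
    empty numeric cells parse as 0 (not quantified).  ``column_map`` overrides
    the default MaxQuant header names for re-exported dialects.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str, encoding="utf-8-sig")

    missing_lfq = [
        s for s in design.samples() if LFQ_PREFIX + s not in df.columns
    ]
    if missing_lfq:
        raise TableError(
            "missing LFQ column(s): "
            + ", ".join(repr(LFQ_PREFIX + s) for s in missing_lfq)
        )
    if cmap["protein_ids"] not in df.columns:
        raise TableError(f"missing column {cmap['protein_ids']!r}")

    records = []
    for i, row in df.iterrows():
        protein_ids = _split_ids(row[cmap["protein_ids"]])
        if not protein_ids:
            raise TableError(f"row {i + 1}: empty protein ID list")
        gene_names = (
            _split_ids(row[cmap["gene_names"]])
            if cmap["gene_names"] in df.columns
            else ()
        )
        razor_raw = row.get(cmap["razor_unique_peptides"])
        try:
            razor = 0 if pd.isna(razor_raw) else int(float(razor_raw))
        except (TypeError, ValueError):
            raise TableError(
                f"row {i + 1}, column {cmap['razor_unique_peptides']!r}: "
                f"non-numeric peptide count {razor_raw!r}"
            ) from None
        lfq = {}
        for s in design.samples():
            cell = row[LFQ_PREFIX + s]
            if pd.isna(cell) or str(cell).strip() == "":
                lfq[s] = 0.0
                continue
            try:
                lfq[s] = float(cell)
            except ValueError:
                raise TableError(
                    f"row {i + 1}, column {LFQ_PREFIX + s!r}: "
                    f"non-numeric intensity {cell!r}"
                ) from None
        records.append(
            ProteinGroupRecord(
                group_id=protein_ids[0],
                protein_ids=protein_ids,
                gene_names=gene_names,
                razor_unique_peptides=razor,
                is_reverse=_flag(row.get(cmap["reverse"])),
                is_contaminant=_flag(row.get(cmap["contaminant"])),
                only_identified_by_site=_flag(row.get(cmap["only_by_site"])),
                lfq=lfq,
            )
        )
    return ProteinGroupTable(records=tuple(records), design=design)


def write_protein_groups(table: ProteinGroupTable, path) -> None:
    """Write a table back in the default MaxQuant dialect (round-trip safe)."""
    rows = []
    for r in table.records:
        row = {
            DEFAULT_COLUMN_MAP["protein_ids"]: ";".join(r.protein_ids),
            DEFAULT_COLUMN_MAP["gene_names"]: ";".join(r.gene_names),
            DEFAULT_COLUMN_MAP["razor_unique_peptides"]: r.razor_unique_peptides,
            DEFAULT_COLUMN_MAP["reverse"]: "+" if r.is_reverse else "",
            DEFAULT_COLUMN_MAP["contaminant"]: "+" if r.is_contaminant else "",
            DEFAULT_COLUMN_MAP["only_by_site"]: "+" if r.only_identified_by_site else "",
        }
        for s in table.design.samples():
            v = r.lfq[s]
            row[LFQ_PREFIX + s] = "" if v == 0 else repr(v)
        rows.append(row)
    cols = list(DEFAULT_COLUMN_MAP.values()) + [
        LFQ_PREFIX + s for s in table.design.samples()
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_design(design: SampleDesign, path) -> None:
    pd.DataFrame(
        [
            {"sample_id": e.sample_id, "group": e.group, "replicate": e.replicate}
            for e in design.entries
        ]
    ).to_csv(path, sep="\t", index=False)
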