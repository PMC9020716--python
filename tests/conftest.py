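import numpy as np
import pytest

from turboprox.design_io import (
    ProteinGroupRecord,
    ProteinGroupTable,
    SampleDesign,
    SampleEntry,
)
from turboprox.imputation import LogIntensityMatrix


@pytest.fixture
def design_3v3() -> SampleDesign:
    return SampleDesign(
        entries=tuple(
            [SampleEntry(f"exp{i}", "experimental", i) for i in (1, 2, 3)]
            + [SampleEntry(f"ctl{i}", "control", i) for i in (1, 2, 3)]
        )
    )


def make_record(
    gid: str,
    lfq: dict[str, float],
    razor: int = 5,
    reverse: bool = False,
    contaminant: bool = False,
    only_by_site: bool = False,
) -> ProteinGroupRecord:
    return ProteinGroupRecord(
        group_id=gid,
        protein_ids=(gid,),
        gene_names=(),
        razor_unique_peptides=razor,
        is_reverse=reverse,
        is_contaminant=contaminant,
        only_identified_by_site=only_by_site,
        lfq=lfq,
    )


def make_table(design: SampleDesign, records) -> ProteinGroupTable:
    return ProteinGroupTable(records=tuple(records), design=design)


def make_matrix(values, protein_ids=None, sample_ids=None) -> LogIntensityMatrix:
    """Matrix from a nested list; NaN cells count as missing."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return LogIntensityMatrix(
        protein_ids=protein_ids or [f"P{i}" for i in range(n)],
        sample_ids=sample_ids or [f"s{j}" for j in range(m)],
        values=values,
        observed_mask=~np.isnan(values),
    )
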