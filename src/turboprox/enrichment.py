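"""Per-protein differential enrichment: fold changes, t-tests, hit calling.

A proximity interactor is called significant when its log2 fold change
(mean experimental log2 intensity minus mean control log2 intensity)
exceeds 1 and its two-sided unpaired t-test p-value is below 0.05, both
strict.  No multiple-testing correction enters the call; a
Benjamini-Hochberg q-value column is emitted for information only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from turboprox.design_io import SampleDesign
from turboprox.imputation import LogIntensityMatrix


@dataclass(frozen=True)
class EnrichmentThresholds:
    """Hit-calling thresholds; both inequalities are strict."""

    min_log2_fc: float = 1.0
    max_p: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.max_p < 1):
            raise ValueError("max_p must lie in (0, 1)")


@dataclass(frozen=True)
class EnrichmentRecord:
    group_id: str
    log2_fc: float
    p_value: float
    neg_log10_p: float
    mean_log2_sample: float
    significant: bool
    q_value: float = float("nan")
    n_imputed_exp: int = 0
    n_imputed_ctrl: int = 0


@dataclass(frozen=True)
class EnrichmentTable:
    records: tuple[EnrichmentRecord, ...]
    thresholds: EnrichmentThresholds
    provenance: dict = field(default_factory=dict, compare=False)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group_id": r.group_id,
                    "log2_fc": r.log2_fc,
                    "p_value": r.p_value,
                    "neg_log10_p": r.neg_log10_p,
                    "mean_log2_sample": r.mean_log2_sample,
                    "significant": r.significant,
                    "q_value": r.q_value,
                    "n_imputed_exp": r.n_imputed_exp,
                    "n_imputed_ctrl": r.n_imputed_ctrl,
                }
                for r in self.records
            ]
        )


def _ttest(exp: np.ndarray, ctl: np.ndarray, welch: bool) -> float:
    # Degenerate case: zero variance in both groups.  Equal means carry no
    # evidence of difference (t = 0/0 -> p = 1); unequal means are infinitely
    # separated on the t scale (p = 0).
    if exp.std(ddof=1) == 0 and ctl.std(ddof=1) == 0:
        return 1.0 if exp.mean() == ctl.mean() else 0.0
    res = stats.ttest_ind(exp, ctl, equal_var=not welch)
    return float(res.pvalue)


def compute_enrichment(
    matrix: LogIntensityMatrix,
    design: SampleDesign,
    thresholds: EnrichmentThresholds | None = None,
    welch: bool = False,
    provenance: dict | None = None,
) -> EnrichmentTable:
    """Test every protein for enrichment in the experimental group.

    The matrix must be fully imputed.  ``welch`` switches from the classical
    pooled-variance Student test to Welch's unequal-variance form.
    """
    thresholds = thresholds or EnrichmentThresholds()
    if matrix.n_missing:
        raise ValueError(
            f"impute before testing: matrix has {matrix.n_missing} missing cell(s)"
        )
    col = {s: j for j, s in enumerate(matrix.sample_ids)}
    exp_idx = [col[s] for s in design.experimental]
    ctl_idx = [col[s] for s in design.control]
    if len(exp_idx) < 2 or len(ctl_idx) < 2:
        raise ValueError("need at least 2 samples per group")

    records = []
    pvals = []
    for i, gid in enumerate(matrix.protein_ids):
        exp = matrix.values[i, exp_idx]
        ctl = matrix.values[i, ctl_idx]
        log2_fc = float(exp.mean() - ctl.mean())
        p = _ttest(exp, ctl, welch)
        pvals.append(p)
        records.append(
            (
                gid,
                log2_fc,
                p,
                float(exp.mean()),
                int(matrix.imputed_mask[i, exp_idx].sum()),
                int(matrix.imputed_mask[i, ctl_idx].sum()),
            )
        )
    qvals = (
        multipletests(pvals, method="fdr_bh")[1] if pvals else np.array([])
    )
    out = tuple(
        EnrichmentRecord(
            group_id=gid,
            log2_fc=fc,
            p_value=p,
            neg_log10_p=float(-np.log10(p)) if p > 0 else float("inf"),
            mean_log2_sample=mean_exp,
            significant=(fc > thresholds.min_log2_fc) and (p < thresholds.max_p),
            q_value=float(q),
            n_imputed_exp=ni_e,
            n_imputed_ctrl=ni_c,
        )
        for (gid, fc, p, mean_exp, ni_e, ni_c), q in zip(records, qvals)
    )
    return EnrichmentTable(
        records=out, thresholds=thresholds, provenance=provenance or {}
    )


def significant_set(table: EnrichmentTable) -> list[str]:
    """Significant group_ids, strongest enrichment first.

    Sorted by descending log2 fold change, ties broken by ascending p-value
    then group_id.
    """
    hits = [r for r in table.records if r.significant]
    hits.sort(key=lambda r: (-r.log2_fc, r.p_value, r.group_id))
    return [r.group_id for r in hits]


def intersect_significant(a: list[str], b: list[str]) -> list[str]:
    """Intersection of two hit lists, preserving the order of ``a``."""
    b_set = set(b)
    return [gid for gid in a if gid in b_set]


def volcano_table(table: EnrichmentTable) -> pd.DataFrame:
    """Volcano projection: -log10 p against log2 fold change (sample/control)."""
    return pd.DataFrame(
        [
            {
                "label": r.group_id,
                "log2_fc": r.log2_fc,
                "neg_log10_p": r.neg_log10_p,
                "significant": r.significant,
            }
            for r in table.records
        ],
        columns=["label", "log2_fc", "neg_log10_p", "significant"],
    )


def ma_table(table: EnrichmentTable) -> pd.DataFrame:
    """MA projection: mean log2 sample intensity against log2 fold change."""
    return pd.DataFrame(
        [
            {
                "label": r.group_id,
                "mean_log2_sample": r.mean_log2_sample,
                "log2_fc": r.log2_fc,
                "significant": r.significant,
            }
            for r in table.records
        ],
        columns=["label", "mean_log2_sample", "log2_fc", "significant"],
    )
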