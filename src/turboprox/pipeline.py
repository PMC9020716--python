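"""Run orchestration: configuration, stage composition, logging, artifacts.

A single :class:`RunConfig` (typically loaded from YAML) drives a full
enrichment run — read, filter, log2, impute, test — and writes the
enrichment table, significant list, volcano/MA projections, filter report
and a run log into the output directory.  Every output table carries a
provenance header (config hash, seed, thresholds) so reruns are
byte-identical apart from log timestamps.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from turboprox.design_io import read_design, read_protein_groups
from turboprox.enrichment import (
    EnrichmentTable,
    EnrichmentThresholds,
    compute_enrichment,
    ma_table,
    significant_set,
    volcano_table,
)
from turboprox.filtering import apply_filters
from turboprox.frap import FrapTrace, extract_trace, fit_recovery, normalize_trace
from turboprox.imputation import (
    NDImputationParams,
    impute_lod,
    impute_nd,
    log_transform,
)

logger = logging.getLogger("turboprox")


class StageError(RuntimeError):
    """Wraps a failure with the name of the pipeline stage that raised it."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage
        self.cause = err


@dataclass
class RunConfig:
    protein_groups: str
    design: str
    output_dir: str
    min_razor: int = 2
    min_group_values: int = 2
    group_value_mode: str = "any_group"
    imputation: str = "lod"  # "lod" | "nd" | "both"
    nd_shift: float = 1.8
    nd_width: float = 0.3
    min_log2_fc: float = 1.0
    max_p: float = 0.05
    welch: bool = False
    seed: int = 0
    column_map: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def digest(self) -> str:
        # hash the analysis settings, not where the results are written
        payload = asdict(self)
        payload.pop("output_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _provenance_header(config: RunConfig, extra: dict | None = None) -> str:
    parts = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "min_log2_fc": config.min_log2_fc,
        "max_p": config.max_p,
    }
    if extra:
        parts.update(extra)
    return "# " + " ".join(f"{k}={v}" for k, v in parts.items()) + "\n"


def _write_tsv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def _methods(config: RunConfig) -> list[str]:
    if config.imputation == "both":
        return ["lod", "nd"]
    if config.imputation in ("lod", "nd"):
        return [config.imputation]
    raise ValueError(f"unknown imputation method {config.imputation!r}")


def run_enrichment(config: RunConfig) -> dict[str, EnrichmentTable]:
    """Execute read -> filter -> log2 -> impute -> enrich and write artifacts.

    Returns the enrichment table(s) keyed by imputation method.  Any stage
    failure raises :class:`StageError` naming the stage; no partial outputs
    are written in that case.
    """
    t0 = time.monotonic()
    methods = _methods(config)

    try:
        design = read_design(config.design)
        table = read_protein_groups(
            config.protein_groups, design, column_map=config.column_map or None
        )
    except Exception as err:
        raise StageError("read", err) from err
    logger.info("read %d protein groups, %d samples", len(table), len(design.entries))

    try:
        filtered, report = apply_filters(
            table,
            min_razor=config.min_razor,
            min_group_values=config.min_group_values,
            group_value_mode=config.group_value_mode,
        )
    except Exception as err:
        raise StageError("filter", err) from err
    logger.info("filter: retained %d/%d", report.n_retained, report.n_input)

    try:
        matrix = log_transform(filtered)
    except Exception as err:
        raise StageError("log2", err) from err

    thresholds = EnrichmentThresholds(
        min_log2_fc=config.min_log2_fc, max_p=config.max_p
    )
    results: dict[str, EnrichmentTable] = {}
    for method in methods:
        try:
            if method == "lod":
                imputed = impute_lod(matrix)
            else:
                imputed = impute_nd(
                    matrix,
                    NDImputationParams(
                        shift=config.nd_shift,
                        width=config.nd_width,
                        seed=config.seed,
                    ),
                )
        except Exception as err:
            raise StageError(f"impute-{method}", err) from err
        try:
            results[method] = compute_enrichment(
                imputed,
                design,
                thresholds,
                welch=config.welch,
                provenance={
                    "imputation": method,
                    "seed": config.seed,
                    "filter_report": report.as_dict(),
                },
            )
        except Exception as err:
            raise StageError(f"enrich-{method}", err) from err
        logger.info(
            "%s: %d significant of %d tested",
            method,
            len(significant_set(results[method])),
            len(results[method]),
        )

    # All stages succeeded; write artifacts.
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_tsv(
        pd.DataFrame([report.as_dict()]), out / "filter_report.tsv",
        _provenance_header(config),
    )
    for method, enr in results.items():
        hdr = _provenance_header(config, {"imputation": method})
        _write_tsv(enr.to_frame(), out / f"enrichment_{method}.tsv", hdr)
        _write_tsv(volcano_table(enr), out / f"volcano_{method}.tsv", hdr)
        _write_tsv(ma_table(enr), out / f"ma_{method}.tsv", hdr)
        (out / f"significant_{method}.txt").write_text(
            hdr + "\n".join(significant_set(enr)) + "\n"
        )
    if len(results) == 2:
        _write_tsv(
            compare_imputation(results["lod"], results["nd"]),
            out / "imputation_comparison.tsv",
            _provenance_header(config),
        )
    with open(out / "run.log", "a", encoding="utf-8") as fh:
        fh.write(
            f"run_enrichment config={config.digest()} seed={config.seed} "
            f"methods={','.join(methods)} elapsed_s={time.monotonic() - t0:.2f}\n"
        )
    return results


def compare_imputation(
    lod: EnrichmentTable, nd: EnrichmentTable
) -> pd.DataFrame:
    """Side-by-side fold changes and calls under the two imputation schemes.

    The ``inverted`` column flags proteins whose enrichment direction flips
    between LOD and ND imputation.
    """
    a = lod.to_frame().set_index("group_id")
    b = nd.to_frame().set_index("group_id")
    joined = a.join(b, lsuffix="_lod", rsuffix="_nd", how="inner")
    joined["inverted"] = np.sign(joined["log2_fc_lod"]) != np.sign(
        joined["log2_fc_nd"]
    )
    return joined.reset_index()[
        [
            "group_id",
            "log2_fc_lod",
            "p_value_lod",
            "significant_lod",
            "log2_fc_nd",
            "p_value_nd",
            "significant_nd",
            "inverted",
        ]
    ]


def read_trace_table(path, bleach_index: int | None = None) -> FrapTrace:
    """Load a delimited trace table with columns time_s, intensity.

    When ``bleach_index`` is not given it is inferred as the index after the
    largest single-step intensity drop.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    cols = {c.strip().lower(): c for c in df.columns}
    if "time_s" not in cols or "intensity" not in cols:
        raise ValueError(
            f"trace table needs 'time_s' and 'intensity' columns, found {list(df.columns)}"
        )
    if df.empty:
        raise ValueError("empty trace file")
    times = df[cols["time_s"]].to_numpy(dtype=float)
    raw = df[cols["intensity"]].to_numpy(dtype=float)
    if bleach_index is None:
        bleach_index = int(np.argmin(np.diff(raw))) + 1
    return FrapTrace(times=times, raw=raw, bleach_index=bleach_index)


def read_stack_trace(
    path,
    regions,
    bleach_index: int,
    frame_interval: float = 1.0,
    times=None,
) -> FrapTrace:
    """Measure a trace from a single-channel multi-frame TIFF stack.

    ``times`` defaults to ``frame_interval`` seconds per frame starting at 0.
    """
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    if times is None:
        times = np.arange(stack.shape[0]) * frame_interval
    return extract_trace(stack, regions, times, bleach_index)


def run_frap(
    traces: list[FrapTrace],
    output_dir,
    n_pre: int | None = None,
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Normalize and fit a set of recovery traces; write per-trace fits and
    an ensemble-mean summary row."""
    if not traces:
        raise ValueError("no traces to fit")
    labels = labels or [f"trace_{i + 1}" for i in range(len(traces))]
    rows = []
    for label, trace in zip(labels, traces):
        fit = fit_recovery(normalize_trace(trace, n_pre=n_pre))
        rows.append(
            {
                "trace": label,
                "A": fit.A,
                "k": fit.k,
                "B": fit.B,
                "t_half": fit.t_half,
                "r_squared": fit.r_squared,
            }
        )
    df = pd.DataFrame(rows)
    summary = {
        "trace": "ensemble_mean",
        **{c: df[c].mean() for c in ("A", "k", "B", "t_half", "r_squared")},
    }
    df = pd.concat([df, pd.DataFrame([summary])], ignore_index=True)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "frap_fits.tsv", sep="\t", index=False)
    logger.info(
        "frap: fitted %d trace(s), mean A=%.3f mean t_half=%.2fs",
        len(traces), summary["A"], summary["t_half"],
    )
    return df
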