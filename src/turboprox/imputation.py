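"""Log2 transformation and missing-value imputation for LFQ matrices.

LFQ intensities below the detection limit are reported as 0 by MaxQuant and
become missing cells after log2 transformation — a left-censored,
missing-not-at-random pattern.  Two fill-in schemes are provided:

``impute_lod``
    Deterministic lowest-of-detection: every missing cell takes the lowest
    measured log2 value of its own sample column (one MS run per column).

``impute_nd``
    Left-censored normal draws in log space: missing cells are sampled from
    ``Normal(m - shift*s, (width*s)^2)`` where ``m`` and ``s`` are the mean
    and standard deviation of all observed log2 values in the whole matrix.
    Defaults shift=1.8, width=0.3 (the common Perseus-style down-shifted
    distribution).

Both schemes leave observed cells untouched and record imputed cells in a
provenance mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from turboprox.design_io import ProteinGroupTable


class ImputationError(ValueError):
    pass


@dataclass
class LogIntensityMatrix:
    """Proteins x samples log2-intensity matrix with missingness provenance.

    ``values[i, j]`` is NaN exactly where the cell is neither observed nor
    imputed; ``observed_mask`` and ``imputed_mask`` are disjoint.
    """

    protein_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    observed_mask: np.ndarray
    imputed_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        if self.imputed_mask is None:
            self.imputed_mask = np.zeros_like(self.observed_mask)
        self.imputed_mask = np.asarray(self.imputed_mask, dtype=bool)
        shape = (len(self.protein_ids), len(self.sample_ids))
        if self.values.shape != shape or self.observed_mask.shape != shape:
            raise ImputationError(f"shape mismatch: expected {shape}")
        if np.any(self.observed_mask & self.imputed_mask):
            raise ImputationError("observed and imputed masks overlap")
        if not np.all(np.isfinite(self.values[self.observed_mask])):
            raise ImputationError("non-finite observed values")

    @property
    def missing_mask(self) -> np.ndarray:
        return ~(self.observed_mask | self.imputed_mask)

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def copy(self) -> "LogIntensityMatrix":
        return LogIntensityMatrix(
            protein_ids=list(self.protein_ids),
            sample_ids=list(self.sample_ids),
            values=self.values.copy(),
            observed_mask=self.observed_mask.copy(),
            imputed_mask=self.imputed_mask.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.protein_ids, columns=self.sample_ids
        )


@dataclass(frozen=True)
class NDImputationParams:
    shift: float = 1.8
    width: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ImputationError("ND width must be positive")


def log_transform(table: ProteinGroupTable) -> LogIntensityMatrix:
    """Convert linear LFQ intensities to log2; zeros become missing cells."""
    sample_ids = table.design.samples()
    protein_ids = [r.group_id for r in table.records]
    raw = np.array(
        [[r.lfq[s] for s in sample_ids] for r in table.records], dtype=float
    ).reshape(len(protein_ids), len(sample_ids))
    if np.any(raw < 0):
        raise ImputationError("negative intensity encountered")
    observed = raw > 0
    values = np.full(raw.shape, np.nan)
    values[observed] = np.log2(raw[observed])
    return LogIntensityMatrix(
        protein_ids=protein_ids,
        sample_ids=sample_ids,
        values=values,
        observed_mask=observed,
    )


def impute_lod(matrix: LogIntensityMatrix) -> LogIntensityMatrix:
    """Fill missing cells with the per-column minimum of observed values."""
    out = matrix.copy()
    missing = out.missing_mask
    if not missing.any():
        return out
    for j, sample in enumerate(out.sample_ids):
        col_missing = missing[:, j]
        if not col_missing.any():
            continue
        observed_vals = out.values[out.observed_mask[:, j], j]
        if observed_vals.size == 0:
            raise ImputationError(
                f"sample {sample!r} has no observed values; LOD undefined"
            )
        out.values[col_missing, j] = observed_vals.min()
        out.imputed_mask[col_missing, j] = True
    return out


def impute_nd(
    matrix: LogIntensityMatrix, params: NDImputationParams | None = None
) -> LogIntensityMatrix:
    """Fill missing cells with seeded draws from the down-shifted normal."""
    params = params or NDImputationParams()
    out = matrix.copy()
    observed_vals = out.values[out.observed_mask]
    if observed_vals.size < 2:
        raise ImputationError("need at least 2 observed values to model the dataset")
    m = float(observed_vals.mean())
    s = float(observed_vals.std(ddof=1))
    if s == 0:
        raise ImputationError("degenerate dataset: all observed values equal")
    missing = out.missing_mask
    if not missing.any():
        return out
    rng = np.random.default_rng(params.seed)
    draws = rng.normal(m - params.shift * s, params.width * s, size=int(missing.sum()))
    out.values[missing] = draws
    out.imputed_mask[missing] = True
    return out
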