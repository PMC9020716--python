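"""Synthetic proteomes and FRAP fixtures with ground-truth labels.

The proteome generator reproduces the statistical structure a proximity-
labeling pulldown analysis has to cope with:

* log-normal protein abundances (normal on the log2 scale);
* a small class of true bait-proximal *interactors* at low abundance,
  boosted only in experimental samples and therefore left-censored
  (missing) in most or all controls — missing-not-at-random structure;
* one *bait* simulated as a high-effect interactor present in every
  experimental replicate;
* very abundant *carboxylase-like* endogenously biotinylated background
  proteins (the PCCA-1/PYC-1/POD-2/MCCC-1 analogue) present in both groups;
* ordinary shared *background* proteins; and
* *decoy* records carrying reverse/contaminant/only-by-site flags or a
  single razor peptide, which quality filtering must remove entirely.

Censoring is a hard detection-limit threshold on the log2 scale (exactly
invertible for test oracles); a logistic-dropout option adds probabilistic
censoring near the limit for robustness testing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from turboprox.design_io import (
    GROUP_CONTROL,
    GROUP_EXPERIMENTAL,
    ProteinGroupRecord,
    ProteinGroupTable,
    SampleDesign,
    SampleEntry,
)
from turboprox.frap import FrapTrace, Rect, RegionPair, recovery_model

CLASSES = ("bait", "interactor", "carboxylase_like", "background", "decoy")


@dataclass(frozen=True)
class ProteomeSimConfig:
    """Parameters of the synthetic proteome.

    Abundance means are log2 LFQ units.  Defaults emulate a 3-vs-3 TurboID
    pulldown: interactors sit near the detection limit (so their control
    values censor), carboxylase-like proteins are far above it in both
    groups, and the interactor effect is a strong experimental-only boost.
    """

    n_interactors: int = 20
    n_carboxylase_like: int = 4
    n_background: int = 150
    n_decoys: int = 30
    replicates_per_group: int = 3
    mean_interactor: float = 21.0
    mean_carboxylase: float = 31.0
    mean_background: float = 26.0
    sd_abundance: float = 1.5
    interactor_effect: float = 4.0
    bait_effect: float = 6.0
    detection_limit_log2: float = 22.0
    noise_sd_log2: float = 0.4
    dropout: str = "hard"  # "hard" threshold or "logistic" near the limit
    dropout_scale: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_interactors, self.n_carboxylase_like, self.n_background,
               self.n_decoys) < 0:
            raise ValueError("class counts must be non-negative")
        if self.noise_sd_log2 <= 0:
            raise ValueError("noise_sd_log2 must be positive")
        if self.replicates_per_group < 2:
            raise ValueError("need at least 2 replicates per group")
        if self.dropout not in ("hard", "logistic"):
            raise ValueError("dropout must be 'hard' or 'logistic'")


def _default_design(replicates: int) -> SampleDesign:
    entries = [
        SampleEntry(f"exp{i + 1}", GROUP_EXPERIMENTAL, i + 1) for i in range(replicates)
    ] + [
        SampleEntry(f"ctl{i + 1}", GROUP_CONTROL, i + 1) for i in range(replicates)
    ]
    return SampleDesign(entries=tuple(entries))


def generate_proteome(
    config: ProteomeSimConfig,
) -> tuple[ProteinGroupTable, dict[str, str]]:
    """Simulate a proteinGroups table plus truth labels (group_id -> class).

    Returns linear-scale LFQ intensities with 0 marking censored
    (not-quantified) values; deterministic for a given config.
    """
    rng = np.random.default_rng(config.seed)
    design = _default_design(config.replicates_per_group)
    samples = design.samples()
    exp_cols = np.array([s in design.experimental for s in samples])

    plan: list[tuple[str, float, float]] = []  # (class, mean, experimental boost)
    plan.append(("bait", config.mean_interactor, config.bait_effect))
    plan += [
        ("interactor", config.mean_interactor, config.interactor_effect)
    ] * config.n_interactors
    plan += [("carboxylase_like", config.mean_carboxylase, 0.0)] * config.n_carboxylase_like
    plan += [("background", config.mean_background, 0.0)] * config.n_background
    plan += [("decoy", config.mean_background, 0.0)] * config.n_decoys

    counters = {c: itertools.count(1) for c in CLASSES}
    records = []
    labels: dict[str, str] = {}
    for cls, mean, boost in plan:
        base = rng.normal(mean, config.sd_abundance)
        log2_vals = base + rng.normal(0, config.noise_sd_log2, size=len(samples))
        log2_vals = log2_vals + boost * exp_cols
        if config.dropout == "hard":
            censored = log2_vals < config.detection_limit_log2
        else:
            p_drop = 1.0 / (
                1.0
                + np.exp(
                    (log2_vals - config.detection_limit_log2) / config.dropout_scale
                )
            )
            censored = rng.random(len(samples)) < p_drop
        intensities = np.where(censored, 0.0, np.exp2(log2_vals))

        idx = next(counters[cls])
        gid = f"{cls.upper()}_{idx:04d}"
        is_decoy = cls == "decoy"
        # Decoys rotate through the four removal modes so every rule is hit.
        decoy_mode = idx % 4 if is_decoy else -1
        records.append(
            ProteinGroupRecord(
                group_id=gid,
                protein_ids=(gid,),
                gene_names=(f"{cls[:3]}-{idx}",),
                razor_unique_peptides=1 if decoy_mode == 3 else int(rng.integers(2, 30)),
                is_reverse=decoy_mode == 0,
                is_contaminant=decoy_mode == 1,
                only_identified_by_site=decoy_mode == 2,
                lfq={s: float(v) for s, v in zip(samples, intensities)},
            )
        )
        labels[gid] = cls
    return ProteinGroupTable(records=tuple(records), design=design), labels


def generate_frap_trace(
    A: float,
    k: float,
    B: float,
    times: np.ndarray,
    bleach_index: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> FrapTrace:
    """Simulate a normalized recovery trace: pre-bleach at 1.0, post-bleach
    following ``A*(1-exp(-k*X))+B`` plus Gaussian noise."""
    if A <= 0 or k <= 0:
        raise ValueError("A and k must be positive")
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    raw = np.ones_like(times)
    x = times[bleach_index:] - times[bleach_index]
    post = recovery_model(x, A, k, B)
    if noise_sd > 0:
        post = post + rng.normal(0, noise_sd, size=post.shape)
    raw[bleach_index:] = post
    return FrapTrace(times=times, raw=raw, bleach_index=bleach_index)


def generate_frap_stack(
    trace: FrapTrace,
    frame_shape: tuple[int, int] = (64, 64),
    spot_center: tuple[float, float] | None = None,
    spot_sigma: float = 3.0,
    background_level: float = 50.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, RegionPair]:
    """Render a trace as a Gaussian spot on a flat background, one frame per
    time point, and return suitable concentric measurement regions."""
    h, w = frame_shape
    cy, cx = spot_center if spot_center is not None else (h / 2, w / 2)
    if not (0 <= cy < h and 0 <= cx < w):
        raise ValueError("spot center outside frame")
    half_inner = int(np.ceil(3 * spot_sigma))
    if 2 * half_inner + 8 > min(h, w):
        raise ValueError("spot larger than frame")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w]
    kernel = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * spot_sigma**2))
    kernel /= kernel.sum()  # unit integrated amplitude
    frames = np.empty((len(trace.raw), h, w))
    for t, amp in enumerate(trace.raw):
        frame = background_level + amp * kernel
        if noise_sd > 0:
            frame = frame + rng.normal(0, noise_sd, size=frame.shape)
        frames[t] = frame
    inner = Rect(
        int(cx) - half_inner, int(cy) - half_inner,
        int(cx) + half_inner + 1, int(cy) + half_inner + 1,
    )
    outer = Rect(
        max(inner.x0 - 4, 0), max(inner.y0 - 4, 0),
        min(inner.x1 + 4, w), min(inner.y1 + 4, h),
    )
    return frames, RegionPair(inner=inner, outer=outer)
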