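"""Tipping-point taxa screen.

Stage 1 keeps ASVs that are present in at least one replicate of *every*
high-dose invasion treatment while absent from *all* replicates of all
low-dose treatments; stage 2 refines stage 1 to ASVs detected in strictly
more than a prevalence fraction of the replicates within each high
treatment separately. These are the candidate taxa whose presence separates
invasions that stepped community function up from those that did not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .tables_io import AsvCountTable, SampleMetadata

__all__ = ["ScreenConfig", "tipping_point_asvs", "prevalence_refine", "screen"]


@dataclass
class ScreenConfig:
    high_treatments: tuple[str, ...] = ("D10", "D1")
    low_treatments: tuple[str, ...] = ("D0.1", "D0.01")
    prevalence_min: float = 0.5  # strict inequality: "> 50% of replicates"
    presence_threshold: int = 0  # presence means count > this
    require_all_high: bool = True  # conjunction over high treatments
    pooled_prevalence: bool = False  # prevalence within each high treatment

    def __post_init__(self):
        if not self.high_treatments or not self.low_treatments:
            raise ConfigurationError("high and low treatment sets must be non-empty")
        if set(self.high_treatments) & set(self.low_treatments):
            raise ConfigurationError("high and low treatment sets must be disjoint")
        if not 0 <= self.prevalence_min <= 1:
            raise ConfigurationError("prevalence_min must lie in [0, 1]")


def _presence_by_treatment(
    table: AsvCountTable, metadata: SampleMetadata, treatments: tuple[str, ...],
    threshold: int,
) -> dict[str, np.ndarray]:
    """treatment -> (replicates x ASVs) boolean presence matrix."""
    out = {}
    for t in treatments:
        sids = [s for s in metadata.samples_for(t) if s in table.sample_ids]
        if not sids:
            raise ConfigurationError(f"treatment {t!r} has no samples in the table")
        idx = [table.sample_ids.index(s) for s in sids]
        out[t] = table.counts[idx] > threshold
    return out


def tipping_point_asvs(
    table: AsvCountTable, metadata: SampleMetadata, config: ScreenConfig | None = None
) -> list[str]:
    """Stage-1 hits, in lexicographic order."""
    config = config or ScreenConfig()
    high = _presence_by_treatment(
        table, metadata, config.high_treatments, config.presence_threshold
    )
    low = _presence_by_treatment(
        table, metadata, config.low_treatments, config.presence_threshold
    )
    per_high = np.vstack([m.any(axis=0) for m in high.values()])
    in_high = per_high.all(axis=0) if config.require_all_high else per_high.any(axis=0)
    in_low = np.vstack([m.any(axis=0) for m in low.values()]).any(axis=0)
    hits = [a for a, h, l in zip(table.asv_ids, in_high, in_low) if h and not l]
    return sorted(hits)


def prevalence_refine(
    table: AsvCountTable,
    metadata: SampleMetadata,
    stage1_hits: list[str],
    config: ScreenConfig | None = None,
) -> list[str]:
    """Stage-2 hits: stage-1 ASVs detected in > ``prevalence_min`` of the
    replicates of each high treatment (or of the pooled high replicates when
    ``pooled_prevalence`` is set)."""
    config = config or ScreenConfig()
    unknown = set(stage1_hits) - set(table.asv_ids)
    if unknown:
        raise ConfigurationError(f"stage-1 hits not in table: {sorted(unknown)[:5]}")
    high = _presence_by_treatment(
        table, metadata, config.high_treatments, config.presence_threshold
    )
    col = {a: i for i, a in enumerate(table.asv_ids)}
    kept = []
    for asv in stage1_hits:
        j = col[asv]
        if config.pooled_prevalence:
            pooled = np.concatenate([m[:, j] for m in high.values()])
            ok = pooled.mean() > config.prevalence_min
        else:
            ok = all(m[:, j].mean() > config.prevalence_min for m in high.values())
        if ok:
            kept.append(asv)
    return sorted(kept)


def screen(
    table: AsvCountTable, metadata: SampleMetadata, config: ScreenConfig | None = None
) -> pd.DataFrame:
    """Run both stages; returns one row per stage-1 hit with its stage and
    per-high-treatment prevalence."""
    config = config or ScreenConfig()
    stage1 = tipping_point_asvs(table, metadata, config)
    stage2 = set(prevalence_refine(table, metadata, stage1, config))
    high = _presence_by_treatment(
        table, metadata, config.high_treatments, config.presence_threshold
    )
    col = {a: i for i, a in enumerate(table.asv_ids)}
    rows = []
    for asv in stage1:
        row = {"asv_id": asv, "stage": 2 if asv in stage2 else 1}
        for t, m in high.items():
            row[f"prevalence_{t}"] = float(m[:, col[asv]].mean())
        rows.append(row)
    return pd.DataFrame(rows, columns=["asv_id", "stage"] + [f"prevalence_{t}" for t in high])
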