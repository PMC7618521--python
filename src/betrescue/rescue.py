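"""Temporal rescue classification and binding-transcription correlation.

A gene is *rescued* when its nascent transcription drops significantly early
after BET inhibition (4 h) but returns toward baseline by 24 h — the signature
of compensatory co-activation.  *Redundant* genes decrease at both timepoints
with no rebound; *induced* genes end up significantly above baseline; the rest
are *unchanged*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RescueThresholds", "classify_rescue", "correlate_binding_transcription"]


@dataclass(frozen=True)
class RescueThresholds:
    """Operational thresholds behind "significantly decreased ... recovered".

    alpha      FDR level for significance calls at either timepoint.
    t_down     |log2 fold change| required for a decrease (or increase, for
               the induced class).
    t_recover  floor on lfc24 above which transcription counts as recovered.
    delta_min  minimum rebound lfc24 - lfc4; recovery is the OR of the floor
               and the rebound, since exemplar rescued genes both returned to
               baseline and overshot it.
    """

    alpha: float = 0.05
    t_down: float = float(np.log2(1.5))
    t_recover: float = float(np.log2(1.25))
    delta_min: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.t_down <= 0:
            raise ValueError("t_down must be positive")
        if self.delta_min < 0:
            raise ValueError("delta_min must be >= 0")


def classify_rescue(
    diff4: pd.DataFrame,
    diff24: pd.DataFrame,
    thresholds: RescueThresholds | None = None,
) -> pd.DataFrame:
    """Classify each gene as rescued / redundant / induced / unchanged.

    ``diff4`` and ``diff24`` are differential-test tables (columns ``lfc`` and
    ``fdr``) for 4 h vs baseline and 24 h vs baseline; genes are inner-joined.
    Untested genes (NaN fdr) are never significant.  Precedence:
    rescued > redundant > induced > unchanged.
    """
    th = thresholds or RescueThresholds()
    shared = diff4.index.intersection(diff24.index)
    if len(shared) == 0:
        raise ValueError("diff4 and diff24 share no genes")
    d4 = diff4.loc[shared]
    d24 = diff24.loc[shared]

    lfc4 = d4["lfc"].to_numpy(float)
    lfc24 = d24["lfc"].to_numpy(float)
    fdr4 = np.nan_to_num(d4["fdr"].to_numpy(float), nan=1.0)
    fdr24 = np.nan_to_num(d24["fdr"].to_numpy(float), nan=1.0)

    sig_down4 = (fdr4 <= th.alpha) & (lfc4 <= -th.t_down)
    recovered = (lfc24 >= -th.t_recover) | ((lfc24 - lfc4) >= th.delta_min)
    rescued = sig_down4 & recovered
    redundant = sig_down4 & (fdr24 <= th.alpha) & (lfc24 <= -th.t_down) & ~recovered
    induced = (fdr24 <= th.alpha) & (lfc24 >= th.t_down)

    label = np.full(len(shared), "unchanged", dtype=object)
    label[induced] = "induced"
    label[redundant] = "redundant"
    label[rescued] = "rescued"

    return pd.DataFrame(
        {
            "lfc4": lfc4,
            "fdr4": d4["fdr"].to_numpy(float),
            "lfc24": lfc24,
            "fdr24": d24["fdr"].to_numpy(float),
            "class": label,
        },
        index=shared.rename("gene_id"),
    )


def correlate_binding_transcription(
    binding_delta: pd.Series, expr_delta: pd.Series
) -> tuple[float, float, int]:
    """Spearman correlation of gene-matched binding vs transcription deltas.

    Both inputs are log2 fold changes indexed by gene; genes are matched on the
    index and pairs with missing values dropped.  Returns (rho, p, n_matched).
    """
    joined = pd.concat(
        {"binding": binding_delta, "expr": expr_delta}, axis=1, join="inner"
    ).dropna()
    n = len(joined)
    if n < 10:
        raise ValueError(f"only {n} matched genes (<10); correlation unreliable")
    rho, p = stats.spearmanr(joined["binding"], joined["expr"])
    return float(rho), float(p), n
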