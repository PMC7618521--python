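"""Region-level chromatin binding analysis.

Operations on genomic intervals carrying per-factor, per-condition signal:
nearest-TSS gene annotation, differential binding (log2 fold change of
depth-scaled signal), reciprocal compensation scoring between a lost and a
gained factor, top-fraction site selection, cross-model concordance via a
permutation test, and averaged metagene profiles.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RegionSignal",
    "annotate_regions_to_genes",
    "differential_binding",
    "compensation_score",
    "top_fraction_sites",
    "cross_model_concordance",
    "metagene_profile",
]


@dataclass
class RegionSignal:
    """Genomic intervals plus per (factor, condition, replicate) signal.

    ``regions``: DataFrame with region_id, chrom, start, end (0-based
    half-open) and optional linked_gene.  ``signal``: DataFrame indexed by
    region_id with MultiIndex columns (factor, condition, replicate), values
    nonnegative coverage.
    """

    regions: pd.DataFrame
    signal: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if (self.regions["start"] >= self.regions["end"]).any():
            raise ValueError("regions must satisfy start < end")
        if (self.signal.to_numpy() < 0).any():
            raise ValueError("signal must be nonnegative")

    def factors(self) -> list[str]:
        return sorted(self.signal.columns.get_level_values("factor").unique())


def annotate_regions_to_genes(
    regions: pd.DataFrame,
    tss_table: pd.DataFrame,
    max_distance_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Assign each region to the gene with the nearest TSS on its chromosome.

    Distance is measured from the region midpoint (integer floor of
    (start+end)/2) to the TSS, strand ignored.  Ties go to the
    lexicographically smaller gene_id.  Regions farther than
    ``max_distance_bp`` from every TSS, or on chromosomes absent from the TSS
    table, stay unassigned (the latter with a warning).

    Returns a DataFrame indexed by region_id with ``linked_gene`` (object,
    None when unassigned) and ``distance_to_tss`` (float, NaN when unassigned).
    """
    if tss_table.duplicated(subset=["gene_id", "tss_position"]).any():
        raise ValueError("tss_table has duplicate (gene, tss) rows")
    out_gene = np.full(len(regions), None, dtype=object)
    out_dist = np.full(len(regions), np.nan)

    mid = ((regions["start"] + regions["end"]) // 2).to_numpy()
    missing_chroms = set(regions["chrom"]) - set(tss_table["chrom"])
    if missing_chroms:
        warnings.warn(
            f"chromosome(s) {sorted(missing_chroms)} absent from TSS table; "
            "their regions stay unassigned",
            stacklevel=2,
        )
    for chrom, tss_sub in tss_table.groupby("chrom"):
        rows = np.flatnonzero((regions["chrom"] == chrom).to_numpy())
        if len(rows) == 0:
            continue
        # sort TSS by position, break exact-position ties by gene_id so that
        # the first minimal-distance hit is the lexicographically smaller gene
        tss_sub = tss_sub.sort_values(["tss_position", "gene_id"], kind="mergesort")
        pos = tss_sub["tss_position"].to_numpy()
        genes = tss_sub["gene_id"].to_numpy()
        m = mid[rows]
        right = np.searchsorted(pos, m)
        left = np.clip(right - 1, 0, len(pos) - 1)
        right = np.clip(right, 0, len(pos) - 1)
        d_left = np.abs(m - pos[left])
        d_right = np.abs(pos[right] - m)
        use_left = d_left < d_right
        tie = d_left == d_right
        # on a distance tie between two TSS, pick the smaller gene_id
        tie_left = tie & (genes[left] <= genes[right])
        pick = np.where(use_left | tie_left, left, right)
        dist = np.minimum(d_left, d_right)
        ok = dist <= max_distance_bp
        out_gene[rows[ok]] = genes[pick[ok]]
        out_dist[rows[ok]] = dist[ok]

    return pd.DataFrame(
        {"linked_gene": out_gene, "distance_to_tss": out_dist},
        index=pd.Index(regions["region_id"], name="region_id"),
    )


def _scaled_condition_mean(
    rs: RegionSignal, factor: str, condition: str, depth_scale: bool
) -> np.ndarray:
    try:
        block = rs.signal[factor][condition]
    except KeyError as exc:
        raise ValueError(f"condition {condition!r} missing for factor {factor!r}") from exc
    values = block.to_numpy(dtype=float)
    if depth_scale:
        totals = values.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError(f"all-zero sample in {factor}/{condition}")
        values = values / totals * 1e6
    return values.mean(axis=1)


def differential_binding(
    rs: RegionSignal,
    factor: str,
    cond_a: str,
    cond_b: str,
    pseudocount: float = 1.0,
    scale: str = "depth",
) -> pd.DataFrame:
    """Per-region log2 fold change of ``cond_b`` vs ``cond_a`` for one factor.

    Replicates are averaged after per-sample depth scaling (signal / total x
    1e6; pass ``scale="none"`` for raw signal — note depth scaling cancels any
    genome-wide uniform shift, so global losses are only visible unscaled).
    log2fc = log2((mean_b + pc) / (mean_a + pc)).
    """
    if scale not in ("depth", "none"):
        raise ValueError("scale must be 'depth' or 'none'")
    mean_a = _scaled_condition_mean(rs, factor, cond_a, scale == "depth")
    mean_b = _scaled_condition_mean(rs, factor, cond_b, scale == "depth")
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    out = pd.DataFrame(
        {"factor": factor, "log2fc": log2fc},
        index=pd.Index(rs.regions["region_id"], name="region_id"),
    )
    if "linked_gene" in rs.regions.columns:
        out["linked_gene"] = rs.regions["linked_gene"].to_numpy()
    return out


def compensation_score(
    delta_lost_factor: pd.DataFrame, delta_gained_factor: pd.DataFrame
) -> pd.Series:
    """Reciprocal-compensation score: log2fc(gained) - log2fc(lost) per region.

    Large positive values mark regions where the gained factor (e.g. p300)
    rises as the lost factor (e.g. BRD4) falls.  Antisymmetric under swapping
    the two factors.
    """
    if not delta_lost_factor.index.equals(delta_gained_factor.index):
        raise ValueError("lost and gained deltas must cover the same regions")
    score = delta_gained_factor["log2fc"] - delta_lost_factor["log2fc"]
    return score.rename("compensation_score")


def top_fraction_sites(deltas: pd.DataFrame, fraction: float = 0.05) -> pd.Index:
    """The ceil(fraction*n) regions with largest log2fc, restricted to gains.

    Ties break by region_id.  Any non-positive log2fc is truncated from the
    selection with a warning, so all returned sites strictly gained signal.
    """
    if len(deltas) == 0:
        raise ValueError("empty delta table")
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    k = int(np.ceil(fraction * len(deltas)))
    tmp = deltas[["log2fc"]].copy()
    tmp.index = tmp.index.rename("region_id")
    ranked = (
        tmp.reset_index()
        .sort_values(["log2fc", "region_id"], ascending=[False, True], kind="mergesort")
        .head(k)
    )
    keep = ranked["log2fc"] > 0
    if not keep.all():
        warnings.warn(
            f"{int((~keep).sum())} of top {k} sites had log2fc <= 0 and were dropped",
            stacklevel=2,
        )
        ranked = ranked[keep]
    return pd.Index(ranked["region_id"], name="region_id")


def cross_model_concordance(
    top_sites_a: pd.Index,
    deltas_b: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Are model A's top gained sites also shifted up in model B?

    Statistic: mean B log2fc over A's top sites minus the mean over all other
    B regions.  One-sided permutation p-value against random same-size region
    subsets, with add-one correction (1 + #{perm >= obs}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    values = deltas_b["log2fc"].to_numpy(dtype=float)
    in_top = deltas_b.index.isin(top_sites_a)
    k = int(in_top.sum())
    n = len(values)
    if k == 0 or k == n:
        raise ValueError("top sites and model-B regions share no usable split")

    total = values.sum()
    def shift(subset_sum: np.ndarray | float, size: int) -> np.ndarray | float:
        return subset_sum / size - (total - subset_sum) / (n - size)

    observed = float(shift(values[in_top].sum(), k))
    rng = np.random.default_rng(seed)
    keys = rng.random((n_perm, n))
    picks = np.argpartition(keys, k - 1, axis=1)[:, :k]
    perm = shift(values[picks].sum(axis=1), k)
    p = (1 + int(np.sum(perm >= observed))) / (1 + n_perm)
    return observed, float(p)


def metagene_profile(
    position_signal: dict[str, np.ndarray],
    regions: pd.DataFrame,
    flank_bp: int = 2000,
    n_bins: int = 50,
) -> tuple[np.ndarray, int]:
    """Average signal curve over windows centered on region midpoints.

    Each region's window [midpoint - flank, midpoint + flank) is resampled to
    ``n_bins`` values by mean pooling, then curves are averaged across regions.
    ``position_signal`` maps chromosome name to a per-base signal vector.
    Windows that exceed chromosome bounds are skipped; the skip count is
    returned alongside the curve.
    """
    if n_bins < 10:
        raise ValueError("n_bins must be >= 10")
    edges = np.linspace(0, 2 * flank_bp, n_bins + 1).astype(int)
    curves = []
    skipped = 0
    for _, reg in regions.iterrows():
        track = position_signal.get(reg["chrom"])
        mid = (int(reg["start"]) + int(reg["end"])) // 2
        lo, hi = mid - flank_bp, mid + flank_bp
        if track is None or lo < 0 or hi > len(track):
            skipped += 1
            continue
        window = np.asarray(track[lo:hi], dtype=float)
        curves.append(
            [window[edges[i]:edges[i + 1]].mean() for i in range(n_bins)]
        )
    if not curves:
        raise ValueError("every region window fell outside chromosome bounds")
    return np.mean(curves, axis=0), skipped
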