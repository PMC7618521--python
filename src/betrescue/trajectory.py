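"""Longitudinal resistance-module discovery and archetype assignment.

Expression is summarized per gene across four ordered resistance stages —
vehicle (DMSO), short-term treatment (BETi_72h), incipient resistance (IC50_r)
and full-blown resistance (IC90_r) — on a log-normalized scale.  Two routes are
offered: unsupervised hierarchical clustering of the most variable genes, and
direct assignment to named archetype templates.  They need not agree gene by
gene; the archetypes are interpretations of recurring cluster shapes.

Archetype templates over [DMSO, BETi_72h, IC50_r, IC90_r]:

* evolution     (0, 1, 2, 3)  — monotone rise into full resistance
* degression    (3, 2, 1, 0)  — monotone loss
* stress        (0, 1, 0, 0)  — transient early response only
* inflammation  (0, 0, 1, 0)  — expressed only in incipient resistance
* interferon    (0, 1, 1, -1) — early/incipient rise, collapse at IC90
* flat          — no template; the fallback when nothing correlates
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

__all__ = [
    "STAGES",
    "ARCHETYPES",
    "ARCHETYPE_TEMPLATES",
    "select_variable_genes",
    "hierarchical_cluster",
    "assign_archetypes",
    "stage_response_summary",
    "geneset_delta",
]

STAGES = ("DMSO", "BETi_72h", "IC50_r", "IC90_r")

ARCHETYPE_TEMPLATES: dict[str, np.ndarray] = {
    "evolution": np.array([0.0, 1.0, 2.0, 3.0]),
    "degression": np.array([3.0, 2.0, 1.0, 0.0]),
    "stress": np.array([0.0, 1.0, 0.0, 0.0]),
    "inflammation": np.array([0.0, 0.0, 1.0, 0.0]),
    "interferon": np.array([0.0, 1.0, 1.0, -1.0]),
    "flat": np.zeros(4),
}
ARCHETYPES = tuple(ARCHETYPE_TEMPLATES)


def select_variable_genes(matrix: pd.DataFrame, n: int, pseudocount: float = 1.0,
                          log_transform: bool = False) -> pd.Index:
    """The ``n`` genes with largest variance of stage means; ties by gene_id.

    Set ``log_transform=True`` when the matrix holds linear-scale values;
    variance is then taken on log2(x + pseudocount).
    """
    if n > len(matrix):
        raise ValueError(f"requested {n} genes from a {len(matrix)}-gene matrix")
    values = matrix.to_numpy(dtype=float)
    if log_transform:
        values = np.log2(values + pseudocount)
    var = pd.Series(values.var(axis=1, ddof=0), index=matrix.index)
    order = var.to_frame("var").reset_index(names="gene_id")
    order = order.sort_values(["var", "gene_id"], ascending=[False, True], kind="mergesort")
    return pd.Index(order["gene_id"].head(n), name="gene_id")


def _zscore_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sd = values.std(axis=1, ddof=0)
    constant = sd == 0
    safe = np.where(constant, 1.0, sd)
    z = (values - values.mean(axis=1, keepdims=True)) / safe[:, None]
    return z, constant


def hierarchical_cluster(profiles: pd.DataFrame, k: int) -> pd.Series:
    """Ward-linkage agglomerative clustering of per-gene z-scored stage profiles.

    Returns integer cluster ids (1..k) indexed by gene.  Constant-profile genes
    (zero variance) cannot be z-scored; each is assigned the cluster of its
    nearest non-constant neighbor (Euclidean on raw profiles) with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = profiles.to_numpy(dtype=float)
    z, constant = _zscore_rows(values)
    if constant.all():
        raise ValueError("all profiles are constant; nothing to cluster")
    active = ~constant
    merge = linkage(z[active], method="ward")
    ids = np.zeros(len(profiles), dtype=int)
    ids[active] = fcluster(merge, t=min(k, active.sum()), criterion="maxclust")
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant-profile gene(s) assigned to nearest neighbor",
            stacklevel=2,
        )
        act_idx = np.flatnonzero(active)
        for i in np.flatnonzero(constant):
            d = np.linalg.norm(values[act_idx] - values[i], axis=1)
            ids[i] = ids[act_idx[np.argmin(d)]]
    return pd.Series(ids, index=profiles.index, name="cluster_id")


def assign_archetypes(profiles: pd.DataFrame, r_floor: float = 0.5) -> pd.DataFrame:
    """Label each stage profile with its best-correlated archetype template.

    Pearson correlation of the z-scored profile against each z-scored template;
    the argmax wins if its r reaches ``r_floor``, otherwise (or on an exact tie,
    or for a constant profile) the gene is labeled flat.  Correlation is
    invariant to affine transforms of the profile, so scale and offset never
    matter.
    """
    if profiles.shape[1] != 4:
        raise ValueError("archetype templates are defined over exactly 4 stages")
    named = [a for a in ARCHETYPES if a != "flat"]
    tz = np.stack([ARCHETYPE_TEMPLATES[a] for a in named])
    tz = (tz - tz.mean(axis=1, keepdims=True)) / tz.std(axis=1, ddof=0, keepdims=True)

    z, constant = _zscore_rows(profiles.to_numpy(dtype=float))
    # Pearson r of z-scored rows is the mean elementwise product
    r = z @ tz.T / profiles.shape[1]
    best = np.argmax(r, axis=1)
    best_r = r[np.arange(len(r)), best]
    sorted_r = np.sort(r, axis=1)
    tie = (sorted_r[:, -1] - sorted_r[:, -2]) < 1e-12

    labels = np.array(named, dtype=object)[best]
    flat = constant | tie | (best_r < r_floor)
    labels[flat] = "flat"
    best_r = np.where(constant, 0.0, best_r)
    return pd.DataFrame(
        {"archetype": labels, "template_correlation": best_r},
        index=profiles.index,
    )


def stage_response_summary(
    profiles: pd.DataFrame,
    p300i_profiles: pd.DataFrame,
    archetypes: pd.Series | pd.DataFrame,
) -> pd.DataFrame:
    """Per archetype x stage: mean, SD and p300i-vs-control log2 ratio.

    ``profiles`` and ``p300i_profiles`` are paired log2-scale matrices over the
    same genes and stages; the log2 ratio per archetype/stage is the difference
    of the two arm means.
    """
    if isinstance(archetypes, pd.DataFrame):
        archetypes = archetypes["archetype"]
    if not profiles.index.equals(p300i_profiles.index) or not profiles.columns.equals(
        p300i_profiles.columns
    ):
        raise ValueError("control and p300i arms must be paired (same genes, same stages)")
    rows = []
    for arch, members in profiles.groupby(archetypes):
        paired = p300i_profiles.loc[members.index]
        for stage in profiles.columns:
            rows.append(
                {
                    "archetype": arch,
                    "stage": stage,
                    "mean": members[stage].mean(),
                    "sd": members[stage].std(ddof=1),
                    "p300i_mean": paired[stage].mean(),
                    "p300i_log2_ratio": paired[stage].mean() - members[stage].mean(),
                }
            )
    return pd.DataFrame(rows)


def geneset_delta(
    per_gene_lfc: pd.Series,
    genesets: dict[str, list[str]],
    min_genes: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean fold-change per gene set plus pairwise one-sided rank tests.

    For each ordered pair (A, B) a one-sided Mann-Whitney U tests whether set A
    is less down-regulated than set B (A's fold changes stochastically greater);
    p-values are BH-corrected across pairs.  Sets with fewer than ``min_genes``
    members present in the fold-change vector are excluded with a warning.
    """
    kept: dict[str, np.ndarray] = {}
    for name, genes in genesets.items():
        vals = per_gene_lfc.reindex(genes).dropna().to_numpy()
        if len(vals) < min_genes:
            warnings.warn(
                f"gene set {name!r} has {len(vals)} matched genes (<{min_genes}); excluded",
                stacklevel=2,
            )
            continue
        kept[name] = vals
    summary = pd.DataFrame(
        [
            {"set": name, "n": len(v), "mean_lfc": v.mean(), "sd_lfc": v.std(ddof=1)}
            for name, v in kept.items()
        ]
    )
    pairs = []
    for a, b in itertools.permutations(kept, 2):
        stat, p = stats.mannwhitneyu(kept[a], kept[b], alternative="greater")
        pairs.append(
            {
                "set_a": a,
                "set_b": b,
                "mean_diff": kept[a].mean() - kept[b].mean(),
                "u_stat": stat,
                "p_value": p,
            }
        )
    pairwise = pd.DataFrame(pairs)
    if len(pairwise):
        pairwise["fdr"] = multipletests(pairwise["p_value"], method="fdr_bh")[1]
    return summary, pairwise
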