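"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the study designs this package analyses:

* a three-timepoint (0/4/24 h) metabolic-labeling time course with three
  replicates per timepoint, negative-binomial counts, and planted gene classes
  (rescued / redundant / unchanged / induced);
* per-region chromatin factor binding with a global BRD4 loss under treatment
  and a p300 gain restricted to regions linked to rescued genes;
* Hill-curve dose-response matrices (4 dosages + vehicle per drug) with a
  controllable deviation from Bliss independence per scheduling mode;
* a four-stage resistance course whose per-gene stage means follow one of the
  named archetype templates (evolution, degression, stress, inflammation,
  interferon, flat).

Every generator is fully determined by its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .quantify import ConversionCounts, labeling_probabilities
from .trajectory import ARCHETYPES, ARCHETYPE_TEMPLATES, STAGES

__all__ = [
    "SimConfig",
    "BindingConfig",
    "SimConfigError",
    "GENE_CLASSES",
    "simulate_timecourse_counts",
    "simulate_binding",
    "simulate_dose_matrix",
    "simulate_resistance_course",
    "make_tss_table",
]

GENE_CLASSES = ("rescued", "redundant", "unchanged", "induced")


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Parameters of the nascent-transcription time-course generator.

    Defaults encode the study conditions: 5000 genes, 10% rescued with a
    log2 fold change of -2 at 4 h recovering to 0 by 24 h, NB dispersion 0.1,
    three replicates at each of 0/4/24 h.
    """

    n_genes: int = 5000
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "rescued": 0.10,
            "redundant": 0.20,
            "unchanged": 0.60,
            "induced": 0.10,
        }
    )
    lfc4_rescued: float = -2.0
    lfc24_rescued: float = 0.0
    lfc_redundant: float = -2.0
    lfc_induced: float = 1.5
    dispersion: float = 0.1
    n_reps: int = 3
    timepoints: tuple[float, ...] = (0.0, 4.0, 24.0)
    mean_expression_log_mu: float = 7.0
    mean_expression_log_sigma: float = 1.0
    baseline_new_fraction: float = 0.5
    conversion_rate: float = 0.03
    background_rate: float = 0.001
    n_t_sites: int = 20
    seed: int = 0
    deterministic_allocation: bool = False

    def validate(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise SimConfigError(f"class_proportions sum to {total}, expected 1")
        unknown = set(self.class_proportions) - set(GENE_CLASSES)
        if unknown:
            raise SimConfigError(f"unknown gene classes: {sorted(unknown)}")
        if self.dispersion < 0:
            raise SimConfigError("dispersion must be >= 0")
        if self.n_reps < 2:
            raise SimConfigError("n_reps must be >= 2")
        if not (0 <= self.background_rate < self.conversion_rate <= 1):
            raise SimConfigError("need 0 <= background_rate < conversion_rate <= 1")
        if len(self.timepoints) < 2 or self.timepoints[0] != 0:
            raise SimConfigError("timepoints must start at 0 (baseline)")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


def _allocate_classes(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    names = [c for c in GENE_CLASSES if cfg.class_proportions.get(c, 0) > 0]
    props = np.array([cfg.class_proportions[c] for c in names])
    if cfg.deterministic_allocation:
        counts = np.floor(props * cfg.n_genes).astype(int)
        counts[-1] += cfg.n_genes - counts.sum()  # remainder to the last class
        labels = np.repeat(names, counts)
    else:
        labels = np.array(names)[rng.choice(len(names), size=cfg.n_genes, p=props)]
    return np.asarray(labels, dtype=object)


def _true_lfc(cfg: SimConfig, classes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lfc4 = np.zeros(len(classes))
    lfc24 = np.zeros(len(classes))
    lfc4[classes == "rescued"] = cfg.lfc4_rescued
    lfc24[classes == "rescued"] = cfg.lfc24_rescued
    lfc4[classes == "redundant"] = cfg.lfc_redundant
    lfc24[classes == "redundant"] = cfg.lfc_redundant
    lfc24[classes == "induced"] = cfg.lfc_induced
    return lfc4, lfc24


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw; collapses to Poisson as dispersion -> 0."""
    if dispersion < 1e-9:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu / shape)
    return rng.poisson(lam)


def simulate_timecourse_counts(config: SimConfig) -> tuple[ConversionCounts, pd.DataFrame]:
    """Simulate the labeling time course; returns counts plus a truth table.

    Total counts per gene/sample are negative binomial around a log-normal
    baseline mean.  The new-read fraction at timepoint t is the baseline
    nascent fraction scaled by 2**true_lfc(t); each read is labeled with
    probability ``f*q_new + (1-f)*q_old`` where the q's come from a
    >=1-conversion-in-20-T-sites model.

    The truth table carries gene_id, true_class, true_lfc4, true_lfc24 and
    linked_region_ids (one promoter region per gene).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    classes = _allocate_classes(config, rng)
    lfc4, lfc24 = _true_lfc(config, classes)
    gene_ids = pd.Index([f"G{i:05d}" for i in range(config.n_genes)], name="gene_id")

    mu = rng.lognormal(config.mean_expression_log_mu, config.mean_expression_log_sigma, config.n_genes)
    q_new, q_old = labeling_probabilities(
        config.conversion_rate, config.background_rate, config.n_t_sites
    )

    lfc_by_time = {t: np.zeros(config.n_genes) for t in config.timepoints}
    for t in config.timepoints:
        if t == 4.0:
            lfc_by_time[t] = lfc4
        elif t == 24.0:
            lfc_by_time[t] = lfc24
        elif t != 0:
            # interpolate in time for non-canonical designs
            lfc_by_time[t] = lfc4 if t < 24 else lfc24

    totals, labels, meta = {}, {}, []
    for t in config.timepoints:
        frac = np.clip(config.baseline_new_fraction * 2.0 ** lfc_by_time[t], 0.0, 1.0)
        p_label = frac * q_new + (1.0 - frac) * q_old
        for r in range(1, config.n_reps + 1):
            sid = f"t{t:g}_r{r}"
            tot = _nb_draw(rng, mu, config.dispersion)
            lab = rng.binomial(tot, p_label)
            totals[sid] = tot
            labels[sid] = lab
            meta.append(
                {
                    "sample_id": sid,
                    "condition": "DMSO" if t == 0 else "BETi",
                    "timepoint_h": float(t),
                    "replicate": r,
                }
            )

    counts = ConversionCounts(
        total_counts=pd.DataFrame(totals, index=gene_ids),
        labeled_counts=pd.DataFrame(labels, index=gene_ids),
        samples=pd.DataFrame(meta),
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "true_class": classes,
            "true_lfc4": lfc4,
            "true_lfc24": lfc24,
            "linked_region_ids": [[f"reg_{g}"] for g in gene_ids],
        }
    ).set_index("gene_id", drop=False)
    return counts, truth


@dataclass
class BindingConfig:
    """Parameters of the per-region factor-binding generator.

    ``delta_log2_brd4`` applies at every region under treatment (global BRD4
    exclusion); ``delta_log2_p300_rescued`` applies only at regions linked to
    rescued genes.  Two replicates per condition mirror the ChIP design.
    """

    delta_log2_brd4: float = -1.5
    delta_log2_p300_rescued: float = 1.0
    n_reps: int = 2
    noise_log2_sd: float = 0.25
    baseline_log_mu: float = 4.0
    baseline_log_sigma: float = 0.8
    region_span_bp: int = 1000
    seed: int = 0


def make_tss_table(gene_ids, spacing_bp: int = 100_000, n_chroms: int = 5) -> pd.DataFrame:
    """Deterministic TSS annotation laid out round-robin over chromosomes."""
    rows = []
    per_chrom = {}
    for i, g in enumerate(gene_ids):
        chrom = f"chr{i % n_chroms + 1}"
        k = per_chrom.get(chrom, 0)
        per_chrom[chrom] = k + 1
        rows.append(
            {"gene_id": g, "chrom": chrom, "strand": "+", "tss_position": (k + 1) * spacing_bp}
        )
    return pd.DataFrame(rows)


def simulate_binding(config: BindingConfig, truth: pd.DataFrame):
    """Simulate per-region BRD4/p300 binding keyed to the time-course truth.

    Each gene contributes one promoter region (its linked_region_id).  Under
    treatment BRD4 drops by ``delta_log2_brd4`` everywhere; p300 rises by
    ``delta_log2_p300_rescued`` only at rescued-linked regions.  Replicate
    signal is log-normal around those means and nonnegative everywhere.

    Returns a :class:`~betrescue.chromatin.RegionSignal`.
    """
    from .chromatin import RegionSignal

    if truth is None or len(truth) == 0:
        raise ValueError("truth table is empty")
    rng = np.random.default_rng(config.seed)

    genes = list(truth["gene_id"])
    tss = make_tss_table(genes)
    half = config.region_span_bp // 2
    regions = pd.DataFrame(
        {
            "region_id": [rid[0] for rid in truth["linked_region_ids"]],
            "chrom": tss["chrom"].to_numpy(),
            "start": tss["tss_position"].to_numpy() - half,
            "end": tss["tss_position"].to_numpy() + half,
            "linked_gene": genes,
        }
    )
    n = len(regions)
    rescued = (truth["true_class"] == "rescued").to_numpy()

    delta = {
        "BRD4": np.full(n, config.delta_log2_brd4),
        "p300": np.where(rescued, config.delta_log2_p300_rescued, 0.0),
    }
    cols, data = [], []
    for factor in ("BRD4", "p300"):
        base = rng.lognormal(config.baseline_log_mu, config.baseline_log_sigma, n)
        for cond in ("DMSO", "BETi"):
            mult = 2.0 ** delta[factor] if cond == "BETi" else 1.0
            for r in range(1, config.n_reps + 1):
                noise = 2.0 ** rng.normal(0.0, config.noise_log2_sd, n)
                cols.append((factor, cond, r))
                data.append(base * mult * noise)
    signal = pd.DataFrame(
        np.column_stack(data),
        index=pd.Index(regions["region_id"], name="region_id"),
        columns=pd.MultiIndex.from_tuples(cols, names=["factor", "condition", "replicate"]),
    )
    return RegionSignal(regions=regions, signal=signal)


def simulate_dose_matrix(
    hill_params_a,
    hill_params_b,
    interaction_delta: float = 0.0,
    mode: str = "BETi_first",
    doses_a=None,
    doses_b=None,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Simulate a percent-inhibition dose matrix around Bliss independence.

    Monotherapy rows/columns follow the two Hill curves; every well with both
    doses positive follows the Bliss expectation ``yA + yB - yA*yB/100`` plus
    ``interaction_delta`` percentage points plus Gaussian noise, clipped to
    [0, 100].  ``mode`` is recorded as metadata only.  The default grid is
    4 dosages plus vehicle per drug (a 5x5 grid whose 24 non-vehicle wells
    comprise 20 drug-drug/monotherapy treatment combinations around DMSO).
    """
    from .synergy import DoseMatrix, hill_curve

    doses_a = np.asarray([0.0, 0.125, 0.25, 0.5, 1.0] if doses_a is None else doses_a, float)
    doses_b = np.asarray([0.0, 0.125, 0.25, 0.5, 1.0] if doses_b is None else doses_b, float)
    for d in (doses_a, doses_b):
        if (d < 0).any():
            raise ValueError("doses must be nonnegative")
        if 0.0 not in d:
            raise ValueError("dose grid must include a zero (vehicle) dose")
    rng = np.random.default_rng(seed)

    ya = hill_curve(doses_a, hill_params_a)
    yb = hill_curve(doses_b, hill_params_b)
    bliss = ya[:, None] + yb[None, :] - ya[:, None] * yb[None, :] / 100.0
    inhibition = bliss.copy()
    combo = (doses_a[:, None] > 0) & (doses_b[None, :] > 0)
    inhibition[combo] += interaction_delta
    if noise_sd > 0:
        inhibition = inhibition + rng.normal(0.0, noise_sd, inhibition.shape)
    inhibition = np.clip(inhibition, 0.0, 100.0)
    return DoseMatrix(doses_a=doses_a, doses_b=doses_b, inhibition=inhibition, mode=mode)


def simulate_resistance_course(
    archetype_props: dict[str, float],
    n_genes: int = 500,
    stage_labels: tuple[str, ...] = STAGES,
    noise_sd: float = 0.25,
    amplitude_range: tuple[float, float] = (1.0, 2.0),
    baseline_mean: float = 5.0,
    baseline_sd: float = 1.0,
    p300i_log2_effect: dict[str, np.ndarray] | None = None,
    seed: int = 0,
):
    """Simulate per-gene expression across the four resistance stages.

    Each gene draws an archetype by ``archetype_props``; its stage means are
    ``baseline + amplitude * template + N(0, noise_sd)``.  Optionally a paired
    p300i arm is produced by adding per-archetype, per-stage log2 effects.

    Returns ``(profiles, truth)`` — or ``(profiles, p300i_profiles, truth)``
    when ``p300i_log2_effect`` is given.
    """
    unknown = set(archetype_props) - set(ARCHETYPES)
    if unknown:
        raise ValueError(f"unknown archetypes: {sorted(unknown)}")
    total = sum(archetype_props.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"archetype proportions sum to {total}, expected 1")
    if len(stage_labels) != 4:
        raise ValueError("expected exactly 4 resistance stages")
    rng = np.random.default_rng(seed)

    names = [a for a in ARCHETYPES if archetype_props.get(a, 0) > 0]
    props = np.array([archetype_props[a] for a in names])
    labels = np.array(names, dtype=object)[rng.choice(len(names), size=n_genes, p=props)]

    templates = np.stack([ARCHETYPE_TEMPLATES[a] for a in labels])
    amp = rng.uniform(*amplitude_range, size=(n_genes, 1))
    base = rng.normal(baseline_mean, baseline_sd, size=(n_genes, 1))
    means = base + amp * templates
    noise = rng.normal(0.0, noise_sd, means.shape) if noise_sd > 0 else 0.0

    gene_ids = pd.Index([f"R{i:05d}" for i in range(n_genes)], name="gene_id")
    profiles = pd.DataFrame(means + noise, index=gene_ids, columns=list(stage_labels))
    truth = pd.DataFrame({"gene_id": gene_ids, "archetype": labels}).set_index(
        "gene_id", drop=False
    )
    if p300i_log2_effect is None:
        return profiles, truth

    effect = np.stack(
        [np.asarray(p300i_log2_effect.get(a, np.zeros(4)), float) for a in labels]
    )
    arm_noise = rng.normal(0.0, noise_sd, means.shape) if noise_sd > 0 else 0.0
    arm = pd.DataFrame(
        means + effect + arm_noise, index=gene_ids, columns=list(stage_labels)
    )
    return profiles, arm, truth
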