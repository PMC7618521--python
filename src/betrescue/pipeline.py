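"""Run orchestration: configuration, staged execution, manifest.

Stages run in dependency order (simulate -> quantify -> rescue -> chromatin ->
synergy -> trajectory -> report), each reading the previous stage's TSV/JSON
outputs from the run directory and writing its own with a '#'-commented header
(tool version, seed, config hash).  Every random draw flows from the single
config seed through a named per-stage substream, so adding or skipping a stage
never perturbs another stage's draws.  Output files carry no timestamps, so a
rerun with identical config and inputs is byte-identical; the manifest records
SHA-256 checksums to prove it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chromatin import (
    annotate_regions_to_genes,
    compensation_score,
    differential_binding,
    top_fraction_sites,
)
from .io import (
    read_counts,
    read_dose_matrix,
    read_regions,
    read_tss_table,
    write_counts,
    write_dose_matrix,
    write_regions,
    write_table,
)
from .quantify import differential_test, normalize_counts
from .rescue import RescueThresholds, classify_rescue
from .synergy import MODES, HillParams, compare_modes, zip_delta
from .synthio import (
    BindingConfig,
    SimConfig,
    simulate_binding,
    simulate_dose_matrix,
    simulate_resistance_course,
    simulate_timecourse_counts,
)
from .trajectory import assign_archetypes, hierarchical_cluster, select_variable_genes

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "STAGE_ORDER", "stage_seed"]

logger = logging.getLogger("betrescue")

STAGE_ORDER = (
    "simulate",
    "quantify",
    "rescue",
    "chromatin",
    "synergy",
    "trajectory",
    "report",
)


def stage_seed(seed: int, stage: str) -> int:
    """Named substream seed: stable under adding/removing other stages."""
    return int(
        np.random.SeedSequence([seed, zlib.crc32(stage.encode())]).generate_state(1)[0]
        % (2**31)
    )


@dataclass
class RunConfig:
    """Everything a pipeline run needs; loadable from YAML."""

    outdir: str = "betrescue_run"
    stages: list[str] = field(default_factory=lambda: list(STAGE_ORDER))
    seed: int = 0
    data_type: str = "slam"  # slam -> labeled counts tested; rna -> totals
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    binding: dict = field(default_factory=dict)  # BindingConfig overrides
    thresholds: dict = field(default_factory=dict)  # RescueThresholds overrides
    top_fraction: float = 0.05
    synergy_interaction: dict = field(
        default_factory=lambda: {"BETi_first": 20.0, "concomitant": 5.0, "p300i_first": -5.0}
    )
    synergy_noise_sd: float = 2.0
    trajectory_props: dict = field(
        default_factory=lambda: {
            "evolution": 0.2,
            "degression": 0.2,
            "stress": 0.2,
            "inflammation": 0.2,
            "interferon": 0.2,
        }
    )
    trajectory_n_genes: int = 500
    trajectory_noise_sd: float = 0.25
    trajectory_k: int = 5
    n_variable_genes: int = 100
    inputs: dict = field(default_factory=dict)  # optional external input paths

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        bad = [s for s in self.stages if s not in STAGE_ORDER]
        if bad:
            raise ValueError(f"unknown stage(s): {bad}")
        if self.data_type not in ("slam", "rna", "chip"):
            raise ValueError(f"unknown data_type {self.data_type!r}")
        for name, p in self.inputs.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"config input {name!r} does not exist: {p}")

    def hash(self) -> str:
        """Hash of the analysis-relevant configuration (where outputs land is excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir")
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Checksummed record of one run.

    ``checksums`` (SHA-256 per output file) are deterministic for a given
    config and seed; ``created_utc`` records when the run happened and is the
    only field expected to differ between identical reruns.
    """

    version: str
    config_hash: str
    seed: int
    checksums: dict[str, str]
    stages_run: list[str]
    created_utc: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _header(cfg: RunConfig) -> list[str]:
    return [f"betrescue {__version__}", f"seed {cfg.seed}", f"config {cfg.hash()}"]


def _require(outdir: Path, filename: str, producer: str) -> Path:
    p = outdir / filename
    if not p.exists():
        raise FileNotFoundError(
            f"missing {filename}; run the {producer!r} stage first (or supply it as an input)"
        )
    return p


def _stage_simulate(cfg: RunConfig, outdir: Path) -> list[Path]:
    sim = SimConfig(**{"seed": stage_seed(cfg.seed, "simulate"), **cfg.sim})
    counts, truth = simulate_timecourse_counts(sim)
    bind = BindingConfig(**{"seed": stage_seed(cfg.seed, "simulate_binding"), **cfg.binding})
    regions = simulate_binding(bind, truth)

    hdr = _header(cfg)
    written = []
    write_counts(counts, outdir / "counts.tsv", hdr)
    written.append(outdir / "counts.tsv")

    t = truth.copy()
    t["linked_region_ids"] = t["linked_region_ids"].map(",".join)
    write_table(t.drop(columns="gene_id"), outdir / "truth.tsv", hdr, index_label="gene_id")
    written.append(outdir / "truth.tsv")

    write_regions(regions.regions, outdir / "regions.bed")
    written.append(outdir / "regions.bed")
    flat = regions.signal.copy()
    flat.columns = [f"{f}|{c}|{r}" for f, c, r in flat.columns]
    write_table(flat, outdir / "region_signal.tsv", hdr, index_label="region_id")
    written.append(outdir / "region_signal.tsv")

    from .synthio import make_tss_table

    tss = make_tss_table(list(truth["gene_id"]))
    write_table(tss, outdir / "tss.tsv", hdr, index=False)
    written.append(outdir / "tss.tsv")

    for mode in MODES:
        dm = simulate_dose_matrix(
            HillParams(),
            HillParams(),
            interaction_delta=cfg.synergy_interaction.get(mode, 0.0),
            mode=mode,
            noise_sd=cfg.synergy_noise_sd,
            seed=stage_seed(cfg.seed, f"simulate_dose_{mode}"),
        )
        write_dose_matrix(dm, outdir / f"dose_{mode}.tsv", hdr)
        written.append(outdir / f"dose_{mode}.tsv")

    profiles, traj_truth = simulate_resistance_course(
        cfg.trajectory_props,
        n_genes=cfg.trajectory_n_genes,
        noise_sd=cfg.trajectory_noise_sd,
        seed=stage_seed(cfg.seed, "simulate_resistance"),
    )
    write_table(profiles, outdir / "resistance_profiles.tsv", hdr, index_label="gene_id")
    written.append(outdir / "resistance_profiles.tsv")
    write_table(
        traj_truth.drop(columns="gene_id"),
        outdir / "resistance_truth.tsv",
        hdr,
        index_label="gene_id",
    )
    written.append(outdir / "resistance_truth.tsv")
    logger.info("simulate: %d genes, %d regions", sim.n_genes, len(regions.regions))
    return written


def _stage_quantify(cfg: RunConfig, outdir: Path) -> list[Path]:
    from .io import _default_sample_sheet
    from .quantify import ConversionCounts

    counts_path = Path(cfg.inputs.get("counts", _require(outdir, "counts.tsv", "simulate")))
    counts = read_counts(counts_path)
    if isinstance(counts, ConversionCounts):
        matrix = counts.labeled_counts if cfg.data_type == "slam" else counts.total_counts
        samples = counts.samples
    else:
        if cfg.data_type == "slam":
            raise ValueError("data_type 'slam' needs labeled count columns")
        matrix, samples = counts, _default_sample_sheet(counts.columns)
    factors = normalize_counts(matrix)

    def at(t: float) -> list[str]:
        return list(samples.loc[samples["timepoint_h"] == t, "sample_id"])

    g0 = at(0.0)
    written = []
    for t, name in ((4.0, "diff4"), (24.0, "diff24")):
        res = differential_test(matrix, factors, g0, at(t))
        write_table(res, outdir / f"{name}.tsv", _header(cfg), index_label="gene_id")
        written.append(outdir / f"{name}.tsv")
        logger.info("quantify %s: %d genes tested", name, int(res["tested"].sum()))
    return written


def _stage_rescue(cfg: RunConfig, outdir: Path) -> list[Path]:
    diff4 = pd.read_csv(_require(outdir, "diff4.tsv", "quantify"), sep="\t", index_col=0, comment="#")
    diff24 = pd.read_csv(_require(outdir, "diff24.tsv", "quantify"), sep="\t", index_col=0, comment="#")
    cls = classify_rescue(diff4, diff24, RescueThresholds(**cfg.thresholds))
    write_table(cls, outdir / "classification.tsv", _header(cfg), index_label="gene_id")
    logger.info("rescue: %s", cls["class"].value_counts().to_dict())
    return [outdir / "classification.tsv"]


def _stage_chromatin(cfg: RunConfig, outdir: Path) -> list[Path]:
    from .chromatin import RegionSignal

    regions = read_regions(cfg.inputs.get("regions", _require(outdir, "regions.bed", "simulate")))
    flat = pd.read_csv(
        _require(outdir, "region_signal.tsv", "simulate"), sep="\t", index_col=0, comment="#"
    )
    cols = pd.MultiIndex.from_tuples(
        [(f, c, int(r)) for f, c, r in (name.split("|") for name in flat.columns)],
        names=["factor", "condition", "replicate"],
    )
    flat.columns = cols
    flat = flat.loc[regions["region_id"]]
    rs = RegionSignal(regions=regions, signal=flat)

    tss = read_tss_table(cfg.inputs.get("tss", _require(outdir, "tss.tsv", "simulate")))
    annotation = annotate_regions_to_genes(regions, tss)
    d_brd4 = differential_binding(rs, "BRD4", "DMSO", "BETi")
    d_p300 = differential_binding(rs, "p300", "DMSO", "BETi")
    comp = compensation_score(d_brd4, d_p300)
    top = top_fraction_sites(d_p300, cfg.top_fraction)

    out = annotation.copy()
    out["log2fc_BRD4"] = d_brd4["log2fc"]
    out["log2fc_p300"] = d_p300["log2fc"]
    out["compensation_score"] = comp
    out["in_top_p300"] = out.index.isin(top)
    write_table(out, outdir / "binding_deltas.tsv", _header(cfg), index_label="region_id")
    logger.info("chromatin: %d regions, %d top p300 sites", len(out), len(top))
    return [outdir / "binding_deltas.tsv"]


def _stage_synergy(cfg: RunConfig, outdir: Path) -> list[Path]:
    results = []
    for mode in MODES:
        path = Path(cfg.inputs.get(f"dose_{mode}", outdir / f"dose_{mode}.tsv"))
        if not path.exists():
            continue
        results.append(zip_delta(read_dose_matrix(path, mode=mode)))
    if not results:
        raise FileNotFoundError(
            "no dose matrices found; run the 'simulate' stage first or supply dose_* inputs"
        )
    table = compare_modes(results)
    write_table(table, outdir / "synergy_modes.tsv", _header(cfg), index=False)
    payload = {
        r.mode: {
            "mean_delta": r.mean_delta,
            "max_window_delta": r.max_window_delta,
            "call": r.call,
            "flags": r.flags,
            "delta_surface": r.delta_surface.to_numpy().tolist(),
        }
        for r in results
    }
    (outdir / "synergy.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    logger.info("synergy: %s", dict(zip(table["mode"], table["call"])))
    return [outdir / "synergy_modes.tsv", outdir / "synergy.json"]


def _stage_trajectory(cfg: RunConfig, outdir: Path) -> list[Path]:
    profiles = pd.read_csv(
        _require(outdir, "resistance_profiles.tsv", "simulate"),
        sep="\t",
        index_col=0,
        comment="#",
    )
    n = min(cfg.n_variable_genes, len(profiles))
    chosen = select_variable_genes(profiles, n)
    sub = profiles.loc[chosen]
    clusters = hierarchical_cluster(sub, cfg.trajectory_k)
    arch = assign_archetypes(profiles)
    out = arch.copy()
    out["cluster_id"] = clusters.reindex(arch.index).astype("Int64")
    write_table(out, outdir / "trajectory.tsv", _header(cfg), index_label="gene_id")
    logger.info("trajectory: %d genes, %d clustered", len(out), len(sub))
    return [outdir / "trajectory.tsv"]


def _stage_report(cfg: RunConfig, outdir: Path) -> list[Path]:
    report: dict = {"version": __version__, "seed": cfg.seed, "config_hash": cfg.hash()}
    cls_path = outdir / "classification.tsv"
    if cls_path.exists():
        cls = pd.read_csv(cls_path, sep="\t", index_col=0, comment="#")
        report["class_counts"] = cls["class"].value_counts().to_dict()
        truth_path = outdir / "truth.tsv"
        if truth_path.exists():
            truth = pd.read_csv(truth_path, sep="\t", index_col=0, comment="#")
            merged = cls.join(truth["true_class"], how="inner")
            tp = ((merged["class"] == "rescued") & (merged["true_class"] == "rescued")).sum()
            called = (merged["class"] == "rescued").sum()
            actual = (merged["true_class"] == "rescued").sum()
            report["rescued_sensitivity"] = float(tp / actual) if actual else None
            report["rescued_fdr"] = float((called - tp) / called) if called else None
    syn_path = outdir / "synergy_modes.tsv"
    if syn_path.exists():
        syn = pd.read_csv(syn_path, sep="\t", comment="#")
        report["synergy"] = syn.to_dict(orient="records")
    traj_path = outdir / "trajectory.tsv"
    if traj_path.exists():
        traj = pd.read_csv(traj_path, sep="\t", index_col=0, comment="#")
        report["archetype_counts"] = traj["archetype"].value_counts().to_dict()
        truth_path = outdir / "resistance_truth.tsv"
        if truth_path.exists():
            rt = pd.read_csv(truth_path, sep="\t", index_col=0, comment="#")
            agree = (traj["archetype"].reindex(rt.index) == rt["archetype"]).mean()
            report["archetype_accuracy"] = float(agree)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return [outdir / "report.json"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "quantify": _stage_quantify,
    "rescue": _stage_rescue,
    "chromatin": _stage_chromatin,
    "synergy": _stage_synergy,
    "trajectory": _stage_trajectory,
    "report": _stage_report,
}


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the configured stages in dependency order; returns the manifest.

    Fails fast on an invalid config (unknown stages/data type, missing input
    paths) before any stage runs.  The manifest (with per-file SHA-256
    checksums) is also written to ``<outdir>/manifest.json``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    written: list[Path] = []
    ran: list[str] = []
    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        logger.info("stage %s starting", stage)
        written.extend(_STAGE_FUNCS[stage](config, outdir))
        ran.append(stage)

    from datetime import datetime, timezone

    manifest = RunManifest(
        version=__version__,
        config_hash=config.hash(),
        seed=config.seed,
        checksums={p.name: _sha256(p) for p in sorted(set(written))},
        stages_run=ran,
        created_utc=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest
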