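"""Stage orchestration: simulate / silencing / chip runs with manifests.

Each run function takes a configuration mapping (typically parsed from
YAML), writes its outputs as plain-text tables into an output directory,
and records a JSON manifest with the configuration and seed so every
output row is traceable. The CLI in :mod:`xsilence.cli` is a thin wrapper
over these functions.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chip import (
    ChipConfig,
    ChipSample,
    blacklist_windows,
    summarize_profiles,
    window_enrichment,
)
from .classify import DependencyConfig, classify_genes, group_characteristics
from .expression import (
    FilterConfig,
    filter_informative_genes,
    normalize_expression,
    ratio_table,
    read_counts,
    sample_ratios,
    write_counts,
)
from .kinetics import KineticsConfig, fit_all
from .simulate import (
    LineSpec,
    SimulationDesign,
    gene_table,
    simulate_chip_windows,
    simulate_chrrna_counts,
    simulate_truth,
)

__all__ = ["load_config", "run_simulate", "run_silencing", "run_chip"]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def _build(cls, mapping: dict | None, **overrides):
    mapping = dict(mapping or {})
    mapping.update({k: v for k, v in overrides.items() if v is not None})
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    return cls(**mapping)


def _design_from_config(cfg: dict, seed: int | None) -> SimulationDesign:
    sim = dict(cfg.get("simulation", {}))
    lines = sim.pop("lines", None)
    if lines is not None:
        sim["lines"] = tuple(_build(LineSpec, spec) for spec in lines)
    for key in ("timepoints", "nodox_timepoints"):
        if key in sim and sim[key] is not None:
            sim[key] = tuple(sim[key])
    return _build(SimulationDesign, sim, seed=seed)


def _write_manifest(outdir: Path, stage: str, cfg: dict, seed) -> None:
    manifest = {
        "stage": stage,
        "xsilence_version": __version__,
        "seed": seed,
        "config": cfg,
    }
    (outdir / f"{stage}_manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str) + "\n"
    )


def run_simulate(cfg: dict, outdir, seed: int | None = None) -> dict:
    """Write a synthetic fixture bundle: counts, sample sheet, annotation,
    truth table, ChIP tracks and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = _design_from_config(cfg, seed)
    truth_cfg = dict(cfg.get("truth", {}))
    n_genes = int(truth_cfg.pop("n_genes", 300))
    truth = simulate_truth(n_genes, design, **truth_cfg)
    m, sheet = simulate_chrrna_counts(truth, design, xist_row=True)

    truth.to_csv(outdir / "truth.tsv", sep="\t")
    write_counts(m, outdir / "counts.tsv")
    sheet.to_csv(outdir / "sample_sheet.csv", index=False)
    gene_table(truth).to_csv(outdir / "annotation.tsv", sep="\t")

    chip_cfg = dict(cfg.get("chip_simulation", {}))
    n_windows = int(chip_cfg.pop("n_windows", 64))
    planted_xi = chip_cfg.pop("planted_xi", 3.0)
    planted_xa = chip_cfg.pop("planted_xa", 1.0)
    tracks, manifest = simulate_chip_windows(
        n_windows, planted_xi, planted_xa, seed=design.seed, **chip_cfg
    )
    for sid, frame in tracks.items():
        frame.to_csv(outdir / f"chip_{sid}.tsv", sep="\t", index=False)
    manifest.to_csv(outdir / "chip_manifest.csv", index=False)

    _write_manifest(outdir, "simulate", cfg, design.seed)
    return {"n_genes": n_genes, "n_samples": len(sheet), "n_windows": n_windows}


def run_silencing(cfg: dict, outdir, seed: int | None = None) -> dict:
    """Filter genes, compute allelic ratios, fit silencing kinetics and
    classify dependence; write tables and a statistics report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = cfg.get("paths", {})
    m, sheet = read_counts(paths["counts"], paths["sample_sheet"])
    fcfg = _build(FilterConfig, cfg.get("filter"))
    kcfg = _build(KineticsConfig, cfg.get("kinetics"), seed=seed)

    retained, reasons = filter_informative_genes(m, sheet, fcfg)
    reasons.to_frame().to_csv(outdir / "filter_report.tsv", sep="\t")
    kept = m.subset_genes(retained)

    ratios = sample_ratios(kept)
    ratios.to_csv(outdir / "ratios_per_sample.tsv", sep="\t")
    ratio_table(kept, sheet, average=True).to_csv(outdir / "ratios_averaged.tsv", sep="\t")

    wt_lines = sheet.loc[sheet["wt_flag"], "line"].unique()
    if len(wt_lines) == 0:
        raise ValueError("no wild-type line in sample sheet")
    fits = fit_all(kept, sheet, kcfg, line=wt_lines[0])
    fits.to_csv(outdir / "fits.tsv", sep="\t")

    # Optional dependence classification from a knockout/mutant line
    dcfg = _build(DependencyConfig, cfg.get("dependency"))
    ko_line = cfg.get("ko_line")
    stats_frames = []
    if ko_line is not None:
        meta = sheet.set_index("sample_id")
        mature = meta[(meta["condition"] == "dox") & (meta["day"] >= kcfg.mature_day_min)]
        wt_cols = mature.index[mature["line"] == wt_lines[0]]
        ko_cols = mature.index[mature["line"] == ko_line]
        if len(ko_cols) == 0:
            raise ValueError(f"no mature induced samples for ko_line {ko_line!r}")
        calls = classify_genes(
            wt_ratio=ratios[wt_cols].mean(axis=1),
            ko_ratio=ratios[ko_cols].mean(axis=1),
            cfg=dcfg,
        )
        calls.to_csv(outdir / "dependency_calls.tsv", sep="\t")
        summary, tests = group_characteristics(
            calls["smchd1_class"], fits["t_half"].rename("t_half")
        )
        stats_frames.append(tests)

    expr = normalize_expression(kept, mode="rpm").mean(axis=1).rename("mean_rpm")
    summary, tests = group_characteristics(fits["kinetic_class"], expr)
    stats_frames.append(tests)
    pd.concat(stats_frames, ignore_index=True).to_csv(
        outdir / "stats_report.tsv", sep="\t", index=False
    )

    _write_manifest(outdir, "silencing", cfg, kcfg.seed)
    return {"n_genes_retained": len(retained), "n_fits": len(fits)}


def run_chip(cfg: dict, outdir, seed: int | None = None) -> dict:
    """Calibrate, compute window enrichment, blacklist, and summarize."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = cfg.get("paths", {})
    ccfg = _build(ChipConfig, cfg.get("chip"))
    manifest = pd.read_csv(paths["chip_manifest"]).fillna({"input_id": ""})
    track_dir = Path(paths.get("track_dir", Path(paths["chip_manifest"]).parent))

    samples: dict[str, ChipSample] = {}
    for row in manifest.itertuples(index=False):
        if not np.isfinite(row.n_spike_reads):
            raise ValueError(f"sample {row.sample_id!r}: missing spike read count")
        signal = pd.read_csv(track_dir / f"chip_{row.sample_id}.tsv", sep="\t")
        samples[row.sample_id] = ChipSample(
            row.sample_id, row.role, signal,
            int(row.n_target_reads), int(row.n_spike_reads),
            antibody=getattr(row, "antibody", ""),
        )

    pairs = [
        (samples[r.sample_id], samples[r.input_id])
        for r in manifest.itertuples(index=False)
        if r.role == "IP"
    ]
    if not pairs:
        raise ValueError("no IP samples in manifest")

    enrichments = []
    for ip, inp in pairs:
        enr = window_enrichment(ip, inp, ccfg)
        enr.to_csv(outdir / f"enrichment_{ip.sample_id}.tsv", sep="\t", index=False)
        enrichments.append(enr)

    inputs = [inp for _, inp in pairs]
    input_total = np.mean([s.signal["total"].to_numpy(dtype=float) for s in inputs], axis=0)
    input_allelic = np.mean(
        [(s.signal["xi"] + s.signal["xa"]).to_numpy(dtype=float) for s in inputs], axis=0
    )
    mask = blacklist_windows(input_total, input_allelic, ccfg)

    first = pairs[0][0].signal
    bed = pd.DataFrame(
        {"chrom": first["chrom"], "start": first["start"], "end": first["end"],
         "mask": mask.to_numpy()}
    )
    bed[bed["mask"] != "ok"].to_csv(outdir / "blacklist.bed", sep="\t",
                                    index=False, header=False)

    mean_d, ratios, counts = summarize_profiles(enrichments, mask)
    prof = pd.DataFrame(
        {"chrom": first["chrom"], "start": first["start"], "end": first["end"],
         "mean_D": mean_d.to_numpy()}
    )
    prof.to_csv(outdir / "differential_mean.bedgraph", sep="\t", index=False, header=False)
    pd.Series(ratios, name="xi_over_xa").to_csv(outdir / "ratio_distribution.tsv",
                                                sep="\t", index=False)

    _write_manifest(outdir, "chip", cfg, seed)
    return counts
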