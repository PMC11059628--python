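"""End-to-end pipeline: calling -> QC -> statistics -> signatures -> heatmaps.

The pipeline consumes a YAML/TOML-style config (a mapping) with::

    reference: reference.fa          # FASTA of target loci
    targets: targets.tsv             # target table (see targets.load_targets)
    samples:                         # one entry per read file
      - {sample: ground_wt, replicate: R1, reads: reads/ground_wt_R1.fasta}
    footprints: footprints.tsv       # optional footprint spec file
    subregions:                      # optional per-target test windows
      T001: {CG: [3, 8]}
    heatmaps: {targets: [T001], metric: kendall_tau, max_reads: 1000}
    outdir: results/
    seed: 0
    min_reads: 10
    max_chh_run: 3

and writes tidy TSVs, a QC JSON, heatmap PNGs with row-order sidecars and a
run manifest recording versions, seeds and parameters.  All statistics run on
the full filtered call set; heatmap subsampling is display-only.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calls import (
    MoleculeCall,
    call_reads,
    conversion_rate,
    coverage_summary,
    read_fastx,
    write_call_matrix,
)
from .signatures import (
    conditional_mppm,
    load_footprint_specs,
    prevalence_by_replicate,
)
from .stats import (
    gc_reads_regression,
    level_correlations,
    mppm_table,
    pairwise_dmppm,
    site_levels,
    site_levels_and_anova,
    within_molecule_context_stats,
)
from .targets import CONTEXTS, TargetRegion, load_targets, write_site_catalog
from .viz import HeatmapSpec, render_heatmap

log = logging.getLogger(__name__)

ALL_STAGES = ("calls", "qc", "stats", "signatures", "heatmap")


def load_config(config: str | Path | Mapping) -> dict:
    if isinstance(config, Mapping):
        return dict(config)
    path = Path(config)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with open(path) as handle:
        return yaml.safe_load(handle)


def _call_stage(cfg: dict, targets: Sequence[TargetRegion]) -> tuple[list[MoleculeCall], dict]:
    calls: list[MoleculeCall] = []
    totals: dict[str, dict[str, int]] = {}
    for entry in cfg["samples"]:
        reads_path = Path(entry["reads"])
        if not reads_path.exists():
            raise FileNotFoundError(f"read file not found: {reads_path}")
        reads = read_fastx(reads_path)
        sample_calls, stats = call_reads(
            reads,
            targets,
            sample=entry["sample"],
            replicate=entry.get("replicate", ""),
            max_chh_run=int(cfg.get("max_chh_run", 3)),
        )
        calls.extend(sample_calls)
        bucket = totals.setdefault(entry["sample"], {"total": 0, "on_target": 0})
        bucket["total"] += stats["total"]
        bucket["on_target"] += stats["on_target"]
        log.info(
            "%s/%s: %d reads, %d on-target, %d kept",
            entry["sample"],
            entry.get("replicate", ""),
            stats["total"],
            stats["on_target"],
            len(sample_calls),
        )
    return calls, totals


def run_pipeline(
    config: str | Path | Mapping,
    outdir: str | Path | None = None,
    seed: int | None = None,
    stages: Sequence[str] = ALL_STAGES,
) -> dict:
    """Execute the pipeline and return the manifest dict.

    ``outdir`` and ``seed`` override the config's values.  Stage failures
    raise; partial outputs written so far are preserved on disk.
    """
    cfg = load_config(config)
    outdir = Path(outdir or cfg.get("outdir", "results"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(seed if seed is not None else cfg.get("seed", 0))
    min_reads = int(cfg.get("min_reads", 10))

    targets = load_targets(cfg["reference"], cfg["targets"])
    by_id = {t.target_id: t for t in targets}
    write_site_catalog(targets, outdir / "site_catalog.tsv")

    calls, totals = _call_stage(cfg, targets)
    calls_by_target: dict[str, list[MoleculeCall]] = {}
    for call in calls:
        calls_by_target.setdefault(call.target_id, []).append(call)

    if "calls" in stages:
        for target_id, target_calls in sorted(calls_by_target.items()):
            write_call_matrix(
                target_calls, by_id[target_id].sites(), outdir / f"calls_{target_id}.tsv"
            )

    manifest: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "min_reads": min_reads,
        "n_targets": len(targets),
        "n_samples": len({e["sample"] for e in cfg["samples"]}),
        "n_calls": len(calls),
        "stages": list(stages),
    }

    if "qc" in stages:
        qc = coverage_summary(calls, targets, min_reads=min_reads, totals=totals)
        qc.sample_stats.to_csv(outdir / "qc_samples.tsv", sep="\t", index=False)
        qc.detection.to_csv(outdir / "qc_detection.tsv", sep="\t", index=False)
        qc.pooled_target_counts.to_csv(
            outdir / "qc_target_counts.tsv", sep="\t", index=False
        )
        controls = [t.target_id for t in targets if t.is_control]
        rates = {}
        for sample in sorted({c.sample for c in calls}):
            control_calls = [
                c for c in calls if c.sample == sample and c.target_id in controls
            ]
            rates[sample] = conversion_rate(control_calls)
        payload = qc.to_dict()
        payload["conversion_rate"] = rates
        with open(outdir / "qc.json", "w") as out:
            json.dump(payload, out, indent=2, default=float)
        manifest["conversion_rate"] = rates

    if "stats" in stages:
        subregions = cfg.get("subregions") or {}
        mppm_frames, dmppm_frames, profile_frames, anova_rows = [], [], [], []
        context_rows = []
        for target_id, target_calls in sorted(calls_by_target.items()):
            target = by_id[target_id]
            sites = target.sites()
            table = mppm_table(target_calls, sites)
            if len(table):
                mppm_frames.append(table)
            for context in CONTEXTS:
                sub = table[table["context"] == context]
                groups = {
                    s: sub.loc[sub["sample"] == s, "mppm"].to_numpy()
                    for s in sorted(sub["sample"].unique())
                }
                if len(groups) >= 2:
                    dmppm_frames.append(
                        pairwise_dmppm(groups, target_id, context, adjust="bh")
                    )
                window = (subregions.get(target_id) or {}).get(context)
                profile, anova, tukey = site_levels_and_anova(
                    target_calls,
                    sites,
                    context,
                    subregion=tuple(window) if window else None,
                )
                profile.insert(0, "target_id", target_id)
                profile_frames.append(profile)
                row = {"target_id": target_id, "context": context, **anova}
                anova_rows.append(row)
                if tukey is not None:
                    tukey = tukey.assign(target_id=target_id, context=context)
                    anova_rows[-1]["tukey"] = tukey.to_dict(orient="records")
            triples, fractions, corr = within_molecule_context_stats(target_calls, sites)
            context_rows.append(
                {
                    "target_id": target_id,
                    "n_full_length": len(triples),
                    **fractions,
                    "corr_cg_chg": corr.loc["CG", "CHG"],
                    "corr_chg_chh": corr.loc["CHG", "CHH"],
                    "corr_cg_chh": corr.loc["CG", "CHH"],
                }
            )
        if mppm_frames:
            pd.concat(mppm_frames).to_csv(outdir / "mppm.tsv", sep="\t", index=False)
        if dmppm_frames:
            pd.concat(dmppm_frames).to_csv(outdir / "dmppm.tsv", sep="\t", index=False)
        if profile_frames:
            pd.concat(profile_frames).to_csv(
                outdir / "site_levels.tsv", sep="\t", index=False
            )
        with open(outdir / "region_anova.json", "w") as out:
            json.dump(anova_rows, out, indent=2, default=float)
        pd.DataFrame(context_rows).to_csv(
            outdir / "context_coupling.tsv", sep="\t", index=False
        )

        # replicate-vs-replicate correlation of per-site levels, contexts pooled
        corr_rows = []
        for target_id, target_calls in sorted(calls_by_target.items()):
            sites = by_id[target_id].sites()
            for sample in sorted({c.sample for c in target_calls}):
                reps = sorted(
                    {c.replicate for c in target_calls if c.sample == sample}
                )
                profiles = {}
                for rep in reps:
                    rep_calls = [
                        c
                        for c in target_calls
                        if c.sample == sample and c.replicate == rep
                    ]
                    profiles[rep] = np.concatenate(
                        [site_levels(rep_calls, sites, ctx) for ctx in CONTEXTS]
                    )
                for i, a in enumerate(reps):
                    for b in reps[i + 1 :]:
                        corr_rows.append(
                            {
                                "target_id": target_id,
                                "sample": sample,
                                "replicate_a": a,
                                "replicate_b": b,
                                "r": level_correlations(profiles[a], profiles[b]),
                            }
                        )
        if corr_rows:
            pd.DataFrame(corr_rows).to_csv(
                outdir / "replicate_correlations.tsv", sep="\t", index=False
            )

        # capture-bias QC: pooled filtered reads vs target GC (log-linear)
        pooled = {
            t.target_id: len(calls_by_target.get(t.target_id, ())) for t in targets
        }
        if sum(1 for t in targets if t.gc_content > 0) >= 3:
            regression = gc_reads_regression(
                [t.gc_content for t in targets],
                [pooled[t.target_id] for t in targets],
            )
            with open(outdir / "gc_regression.json", "w") as out:
                json.dump(regression, out, indent=2)
            manifest["gc_regression"] = regression

    if "signatures" in stages and cfg.get("footprints"):
        specs = load_footprint_specs(cfg["footprints"])
        prevalence_frames = []
        signature_tests = []
        for spec in specs:
            target = by_id.get(spec.target_id)
            if target is None:
                raise ValueError(f"footprint spec {spec.spec_id}: unknown target {spec.target_id}")
            sites = target.sites()
            spec.validate(sites)
            target_calls = calls_by_target.get(spec.target_id, [])
            frame, anova, tukey = prevalence_by_replicate(target_calls, sites, spec)
            prevalence_frames.append(frame)
            entry = {"spec_id": spec.spec_id, "anova": anova}
            if tukey is not None:
                entry["tukey"] = tukey.to_dict(orient="records")
            for context in CONTEXTS:
                if any(s.context == context for s in sites):
                    cond = conditional_mppm(target_calls, sites, spec, context)
                    entry[f"conditional_{context}"] = {
                        "H": cond["H"],
                        "p_value": cond["p_value"],
                        "n_matching": int(len(cond["matching"])),
                        "n_all": int(len(cond["all"])),
                    }
            signature_tests.append(entry)
        if prevalence_frames:
            pd.concat(prevalence_frames).to_csv(
                outdir / "footprint_prevalence.tsv", sep="\t", index=False
            )
        with open(outdir / "footprint_tests.json", "w") as out:
            json.dump(signature_tests, out, indent=2, default=float)

    if "heatmap" in stages:
        heat_cfg = cfg.get("heatmaps") or {}
        requested = heat_cfg.get("targets") or []
        for target_id in requested:
            target = by_id[target_id]
            target_calls = calls_by_target.get(target_id, [])
            for sample in sorted({c.sample for c in target_calls}):
                spec = HeatmapSpec(
                    target_id=target_id,
                    max_reads=int(heat_cfg.get("max_reads", 1000)),
                    subsample_seed=seed,
                    cluster_metric=heat_cfg.get("metric", "kendall_tau"),
                    cluster_context=heat_cfg.get("cluster_context", "CG"),
                )
                pooled = [c for c in target_calls if c.sample == sample]
                render_heatmap(
                    pooled, target, spec, outdir / f"heatmap_{target_id}_{sample}.png"
                )

    with open(outdir / "manifest.json", "w") as out:
        json.dump(manifest, out, indent=2, default=float)
    return manifest
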