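"""Default synthetic scenarios: a capture panel and epiallele mixtures.

The defaults emulate the structure of a real targeted methylation capture
experiment on plant roots: a panel of ~108 targets of 509-704 nt with GC
content between 19% and 52%, one internal-control region of 558 nt with
near-zero methylation (for conversion-rate QC), four conditions (ground /
flight crossed with wild type / epigenetic-regulator mutant) with four
biological replicates each, roughly 90% of reads on target, and >= 99%
C->T conversion of unmethylated cytosines.

Each condition's molecules are a two-class epiallele mixture: a *background*
class with stationary methylation CG/CHG/CHH = 0.70/0.35/0.10, run coupling
rho = 0.3 and a shared molecule-level propensity (sd 1.0) that couples the
three contexts within a molecule; and a *footprint* class identical except
that the first two CG sites are forced unmethylated (consecutive protection
flanking a cis element).  The default footprint-class weights of the four
conditions are 8.4%, 18.0%, 39.4% and 44.0% -- the prevalences this kind of
assay observes for such a footprint across ground/flight and wild-type/mutant
samples.  Per-target read yield follows a log-linear GC dependence, the
capture bias the GC-vs-reads regression is meant to detect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .simulate import (
    ConversionModel,
    EpialleleClass,
    EpialleleTruth,
    SimulatedRead,
    emit_reads,
    footprint_mask_first_context_sites,
    simulate_molecules,
    write_reads_fasta,
    write_truth_table,
)
from .targets import TargetRegion, write_targets_table

DEFAULT_CONDITIONS = ("ground_wt", "flight_wt", "ground_mut", "flight_mut")

#: Footprint-class mixture weight per condition (fraction of molecules whose
#: first two CG sites are protected from methylation).
DEFAULT_FOOTPRINT_WEIGHTS: Mapping[str, float] = {
    "ground_wt": 0.084,
    "flight_wt": 0.18,
    "ground_mut": 0.394,
    "flight_mut": 0.44,
}

DEFAULT_P_METH = {"CG": 0.70, "CHG": 0.35, "CHH": 0.10}
DEFAULT_RHO = {"CG": 0.3, "CHG": 0.3, "CHH": 0.3}
DEFAULT_PROPENSITY_SD = 1.0
DEFAULT_CONVERSION = ConversionModel(conv_eff=0.995, meth_retention=0.995, miss_rate=0.0)


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    bases = np.array(list("ACGT"))
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(bases, size=length, p=p))


def synthetic_panel(
    n_targets: int = 108,
    seed: int = 0,
    length_range: tuple[int, int] = (509, 704),
    gc_range: tuple[float, float] = (0.19, 0.52),
    control_length: int = 558,
) -> list[TargetRegion]:
    """Random capture panel with one internal-control target.

    Targets are named ``T001..``; the control (``control``, flagged) emulates
    a promoter region with no detectable methylation used to estimate the
    conversion rate.  Each target carries one annotated cis-element window in
    its middle third.
    """
    rng = np.random.default_rng(seed)
    targets: list[TargetRegion] = []
    for i in range(n_targets):
        is_control = i == n_targets - 1
        length = (
            control_length
            if is_control
            else int(rng.integers(length_range[0], length_range[1] + 1))
        )
        gc = float(rng.uniform(*gc_range))
        seq = _random_sequence(rng, length, gc)
        target_id = "control" if is_control else f"T{i + 1:03d}"
        lo = length // 3
        hi = lo + 20
        targets.append(
            TargetRegion(
                target_id=target_id,
                gene_id=f"GENE{i + 1:03d}",
                chrom=target_id,
                start=0,
                end=length,
                strand="+",
                sequence=seq,
                is_control=is_control,
                elements=[("element", lo, hi)],
            )
        )
    return targets


def condition_classes(
    target: TargetRegion,
    footprint_weight: float,
    p_meth: Mapping[str, float] = DEFAULT_P_METH,
    persistence: Mapping[str, float] = DEFAULT_RHO,
    propensity_sd: float = DEFAULT_PROPENSITY_SD,
    footprint_k: int = 2,
) -> list[EpialleleClass]:
    """Two-class epiallele mixture for one condition and target.

    The control target gets a single fully unmethylated class regardless of
    condition (it exists to measure conversion efficiency).
    """
    if target.is_control:
        return [
            EpialleleClass(
                class_id="unmethylated_control",
                weight=1.0,
                p_meth={"CG": 0.0, "CHG": 0.0, "CHH": 0.0},
            )
        ]
    mask = footprint_mask_first_context_sites(target, "CG", footprint_k)
    background = EpialleleClass(
        class_id="background",
        weight=1.0 - footprint_weight,
        p_meth=dict(p_meth),
        persistence=dict(persistence),
        propensity_sd=propensity_sd,
    )
    footprint = EpialleleClass(
        class_id="footprint",
        weight=footprint_weight,
        p_meth=dict(p_meth),
        persistence=dict(persistence),
        footprint_mask=mask,
        propensity_sd=propensity_sd,
    )
    return [background, footprint]


def _shuffled_read(rng: np.random.Generator, sequence: str) -> str:
    chars = np.frombuffer(sequence.encode(), dtype="S1").copy()
    rng.shuffle(chars)
    return chars.tobytes().decode()


def simulate_scenario(
    outdir: str | Path,
    seed: int = 0,
    n_targets: int = 8,
    reads_per_replicate: int = 40,
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
    footprint_weights: Mapping[str, float] = DEFAULT_FOOTPRINT_WEIGHTS,
    n_replicates: int = 4,
    model: ConversionModel = DEFAULT_CONVERSION,
    off_target_fraction: float = 0.1,
) -> Path:
    """Write a complete synthetic experiment bundle and its run config.

    ``reads_per_replicate`` is the mean per-target read count per replicate;
    actual counts are Poisson with a log-linear GC trend (low-GC targets yield
    fewer reads).  About ``off_target_fraction`` of each replicate's reads are
    shuffled decoys that no target should claim.  Returns the path of the
    written ``config.yaml`` (consumable by the pipeline / ``run`` command).
    """
    outdir = Path(outdir)
    (outdir / "reads").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    targets = synthetic_panel(n_targets=n_targets, seed=int(rng.integers(2**31)))
    with open(outdir / "reference.fa", "w") as out:
        for t in targets:
            out.write(f">{t.chrom}\n{t.sequence}\n")
    write_targets_table(targets, outdir / "targets.tsv")

    mean_gc = float(np.mean([t.gc_content for t in targets]))
    samples = []
    truths_all: list[EpialleleTruth] = []
    for condition in conditions:
        weight = float(footprint_weights.get(condition, 0.0))
        for rep in range(1, n_replicates + 1):
            replicate = f"R{rep}"
            reads: list[SimulatedRead] = []
            for target in targets:
                lam = reads_per_replicate * max(
                    0.1, 1.0 + 0.8 * math.log(target.gc_content / mean_gc)
                )
                n = int(rng.poisson(lam))
                classes = condition_classes(target, weight)
                truths = simulate_molecules(
                    target, classes, n, seed=int(rng.integers(2**31))
                )
                truths = [
                    replace(
                        t,
                        molecule_id=f"{condition}.{replicate}|{t.molecule_id}",
                    )
                    for t in truths
                ]
                truths_all.extend(truths)
                reads.extend(
                    emit_reads(truths, target, model, seed=int(rng.integers(2**31)))
                )
            n_off = int(round(off_target_fraction * len(reads) / (1 - off_target_fraction)))
            for k in range(n_off):
                template = targets[int(rng.integers(len(targets)))]
                reads.append(
                    SimulatedRead(
                        f"{condition}.{replicate}|offtarget{k:04d}",
                        _shuffled_read(rng, template.sequence),
                    )
                )
            path = outdir / "reads" / f"{condition}_{replicate}.fasta"
            write_reads_fasta(reads, path)
            samples.append(
                {"sample": condition, "replicate": replicate, "reads": str(path)}
            )

    write_truth_table(truths_all, outdir / "truth.tsv")

    heatmap_target = next(t.target_id for t in targets if not t.is_control)
    footprint_rows = [
        "spec_id\ttarget_id\tcontext\tkind\tstate\tindices\twindows\tmin_run",
        f"first2cg_unmeth\t{heatmap_target}\tCG\tset\t0\t0,1\t.\t1",
    ]
    (outdir / "footprints.tsv").write_text("\n".join(footprint_rows) + "\n")

    config = {
        "reference": str(outdir / "reference.fa"),
        "targets": str(outdir / "targets.tsv"),
        "samples": samples,
        "footprints": str(outdir / "footprints.tsv"),
        "outdir": str(outdir / "results"),
        "seed": int(seed),
        "min_reads": 10,
        "max_chh_run": 3,
        "heatmaps": {"targets": [heatmap_target], "metric": "kendall_tau"},
    }
    config_path = outdir / "config.yaml"
    with open(config_path, "w") as out:
        yaml.safe_dump(config, out, sort_keys=False)
    return config_path
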