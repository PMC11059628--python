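"""Synthetic epiallele populations and converted long reads with ground truth.

The generator emulates what a targeted single-molecule methylation assay of a
plant sample looks like statistically: each sequenced molecule comes from one
of a small number of epiallele subpopulations (classes), methylation runs along
a molecule are positively coupled (consecutively methylated stretches), the
three cytosine contexts co-vary within a molecule, and enzymatic conversion
turns unmethylated C into T with high (>= 99%) efficiency.

Model
-----
A molecule first draws its epiallele class by mixture weight, then a
molecule-level latent propensity ``z ~ Normal(0, propensity_sd)`` shared by all
three contexts (this induces within-molecule co-methylation across CG/CHG/CHH).
Within each context, site states follow a two-state Markov chain along site
order with stationary probability ``p_z = logistic(logit(p_meth) + z)`` and
first-order persistence ``rho``::

    P(1 -> 1) = p_z + rho * (1 - p_z)
    P(0 -> 1) = p_z * (1 - rho)

which leaves the stationary probability exactly ``p_z`` while ``rho`` tunes the
length of consecutive methylated (and unmethylated) runs.  Finally any sites in
the class's ``footprint_mask`` are forced unmethylated, emulating protected
footprints at cis-regulatory elements.

Conversion then rewrites each site's base independently: a methylated C is
retained as C with probability ``meth_retention``, an unmethylated C reads as T
with probability ``conv_eff``, and with probability ``miss_rate`` the base is
emitted as N (unreadable).  Non-site positions are copied verbatim; no
indel or substitution error is simulated outside site positions (HiFi
consensus error is negligible at this scale).

Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .targets import CONTEXTS, CytosineSite, TargetRegion

__all__ = [
    "EpialleleClass",
    "EpialleleTruth",
    "ConversionModel",
    "SimulatedRead",
    "simulate_molecules",
    "emit_reads",
    "footprint_mask_first_context_sites",
    "write_reads_fasta",
    "write_truth_table",
]


@dataclass
class EpialleleClass:
    """One epiallele subpopulation of molecules.

    Parameters
    ----------
    class_id : str
        Label carried into the ground-truth table.
    weight : float
        Mixture proportion in [0, 1]; weights over a scenario must sum to 1.
    p_meth : mapping context -> float
        Stationary methylation probability per context.
    persistence : mapping context -> float, or float
        Run-coupling parameter rho in [0, 1) per context (scalar applies to
        all contexts).  rho = 0 gives independent per-site Bernoulli states.
    footprint_mask : frozenset of int
        Site-list indices forced unmethylated after the chain is drawn.
    propensity_sd : float
        Standard deviation of the molecule-level latent propensity shared
        across contexts (on the logit scale); 0 disables coupling.
    """

    class_id: str
    weight: float
    p_meth: Mapping[str, float]
    persistence: Mapping[str, float] | float = 0.0
    footprint_mask: frozenset[int] = frozenset()
    propensity_sd: float = 0.0

    def rho(self, context: str) -> float:
        if isinstance(self.persistence, Mapping):
            return float(self.persistence.get(context, 0.0))
        return float(self.persistence)


@dataclass
class EpialleleTruth:
    """Ground truth for one simulated molecule (pre-conversion states)."""

    molecule_id: str
    target_id: str
    class_id: str
    states: np.ndarray  # uint8, one entry per site of the target


@dataclass
class ConversionModel:
    """Enzymatic conversion / readout noise model."""

    conv_eff: float = 0.995
    meth_retention: float = 0.995
    miss_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("conv_eff", "meth_retention", "miss_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str


def _stationary(p: np.ndarray, z: np.ndarray) -> np.ndarray:
    """logistic(logit(p) + z), with p = 0 and p = 1 held fixed."""
    out = np.empty_like(p, dtype=float)
    interior = (p > 0.0) & (p < 1.0)
    out[~interior] = p[~interior]
    pi = p[interior]
    out[interior] = 1.0 / (1.0 + np.exp(-(np.log(pi / (1.0 - pi)) + z[interior])))
    return out


def simulate_molecules(
    target: TargetRegion,
    classes: Sequence[EpialleleClass],
    n: int,
    seed: int,
) -> list[EpialleleTruth]:
    """Draw ``n`` molecules from the epiallele mixture for ``target``.

    Returns one :class:`EpialleleTruth` per molecule, in molecule order;
    ``states`` vectors are indexed by the target's site list.
    """
    if n < 0:
        raise ValueError(f"negative molecule count: {n}")
    weights = np.array([c.weight for c in classes], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"class weights must sum to 1, got {weights.sum()}")

    sites = target.sites()
    n_sites = len(sites)
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(classes), size=n, p=weights)
    states = np.zeros((n, n_sites), dtype=np.uint8)

    by_context = {
        ctx: np.array([s.index for s in sites if s.context == ctx], dtype=int)
        for ctx in CONTEXTS
    }

    for ci, cls in enumerate(classes):
        rows = np.flatnonzero(labels == ci)
        m = rows.size
        if m == 0:
            continue
        z = (
            rng.normal(0.0, cls.propensity_sd, size=m)
            if cls.propensity_sd > 0
            else np.zeros(m)
        )
        for ctx in CONTEXTS:
            idx = by_context[ctx]
            k = idx.size
            if k == 0:
                continue
            p = np.full(m, float(cls.p_meth.get(ctx, 0.0)))
            p_z = _stationary(p, z)
            rho = cls.rho(ctx)
            chain = np.empty((m, k), dtype=np.uint8)
            chain[:, 0] = rng.random(m) < p_z
            for j in range(1, k):
                prev = chain[:, j - 1].astype(bool)
                prob = np.where(prev, p_z + rho * (1.0 - p_z), p_z * (1.0 - rho))
                chain[:, j] = rng.random(m) < prob
            states[np.ix_(rows, idx)] = chain
        if cls.footprint_mask:
            mask = np.array(sorted(cls.footprint_mask), dtype=int)
            if mask.size and (mask.min() < 0 or mask.max() >= n_sites):
                raise ValueError(
                    f"{cls.class_id}: footprint_mask indices out of range "
                    f"for {n_sites} sites"
                )
            states[np.ix_(rows, mask)] = 0

    width = max(6, len(str(max(n - 1, 0))))
    return [
        EpialleleTruth(
            molecule_id=f"{target.target_id}|mol{i:0{width}d}",
            target_id=target.target_id,
            class_id=classes[labels[i]].class_id,
            states=states[i],
        )
        for i in range(n)
    ]


def emit_reads(
    truths: Sequence[EpialleleTruth],
    target: TargetRegion,
    model: ConversionModel,
    seed: int,
) -> list[SimulatedRead]:
    """Convert ground-truth molecules into read sequences.

    Each molecule becomes one read: the target sequence with every site's base
    rewritten according to the conversion model (methylated -> C with
    probability ``meth_retention`` else T; unmethylated -> T with probability
    ``conv_eff`` else C; missing -> N with probability ``miss_rate``).  The
    read id is the molecule id.
    """
    sites = target.sites()
    offsets = np.array([s.offset for s in sites], dtype=int)
    template = np.frombuffer(target.sequence.encode(), dtype="S1").copy()
    rng = np.random.default_rng(seed)
    reads: list[SimulatedRead] = []
    for truth in truths:
        if truth.states.shape[0] != len(sites):
            raise ValueError(
                f"{truth.molecule_id}: states length {truth.states.shape[0]} "
                f"!= site count {len(sites)}"
            )
        seq = template.copy()
        meth = truth.states.astype(bool)
        base = np.where(
            meth,
            np.where(rng.random(meth.size) < model.meth_retention, b"C", b"T"),
            np.where(rng.random(meth.size) < model.conv_eff, b"T", b"C"),
        )
        if model.miss_rate > 0:
            base = np.where(rng.random(meth.size) < model.miss_rate, b"N", base)
        seq[offsets] = base
        reads.append(SimulatedRead(truth.molecule_id, seq.tobytes().decode()))
    return reads


def footprint_mask_first_context_sites(
    target: TargetRegion, context: str = "CG", k: int = 2
) -> frozenset[int]:
    """Site-list indices of the first ``k`` sites of ``context`` in a target.

    Convenience for building footprint classes that protect e.g. the first two
    CG sites of a region from methylation.
    """
    indices = [s.index for s in target.sites() if s.context == context][:k]
    return frozenset(indices)


def write_reads_fasta(reads: Iterable[SimulatedRead], path: str | Path) -> None:
    with open(path, "w") as out:
        for read in reads:
            out.write(f">{read.read_id}\n{read.sequence}\n")


def write_truth_table(truths: Iterable[EpialleleTruth], path: str | Path) -> None:
    """Write ground truth as TSV: molecule_id, class_id, per-site states string."""
    with open(path, "w") as out:
        out.write("molecule_id\ttarget_id\tclass_id\tstates\n")
        for t in truths:
            states = "".join(str(int(s)) for s in t.states)
            out.write(f"{t.molecule_id}\t{t.target_id}\t{t.class_id}\t{states}\n")
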