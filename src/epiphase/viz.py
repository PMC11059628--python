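"""Single-molecule methylation heatmaps and read clustering.

Each heatmap row is one molecule; panels (CG / CHG / CHH) share rows so that
the i-th row of every panel is the same molecule.  The interval between two
adjacent context sites is colored by the flanking pair of calls:

* both methylated -> red,
* both unmethylated -> black,
* one of each -> gray (transition zone),
* either endpoint missing -> blank.

Site positions are drawn as vertical white lines at their true offsets, and
annotated cis-element windows as green bars under the panels.

Rows are ordered by agglomerative clustering of the binary calls of one
context (default CG) under either Kendall's tau distance (1 - tau; on binary
vectors tau-b coincides with the phi coefficient, computed in closed form) or
Euclidean distance.  Missing calls are imputed as 0 for the distance only.
When a sample has more than ``max_reads`` molecules, a seeded uniform
subsample is plotted; subsampling is display-only and never feeds statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist, squareform

from .calls import MISSING, MoleculeCall
from .targets import CONTEXTS, CytosineSite, TargetRegion

log = logging.getLogger(__name__)

_COLORS = {
    "red": (0.80, 0.10, 0.10),
    "black": (0.05, 0.05, 0.05),
    "gray": (0.55, 0.55, 0.55),
    "blank": (1.00, 1.00, 1.00),
}


@dataclass
class HeatmapSpec:
    """Rendering parameters for one target's single-molecule heatmap."""

    target_id: str
    contexts: tuple[str, ...] = CONTEXTS
    max_reads: int = 1000
    subsample_seed: int = 0
    cluster_metric: str = "kendall_tau"  # or "euclidean"
    cluster_context: str = "CG"
    linkage: str = "average"

    def __post_init__(self) -> None:
        if self.max_reads < 1:
            raise ValueError("max_reads must be >= 1")


def segment_classes(calls: np.ndarray) -> list[str]:
    """Interval color classes between adjacent context sites of one read.

    A pure function of the two flanking calls; fewer than 2 sites gives an
    empty track.
    """
    out = []
    for a, b in zip(calls[:-1], calls[1:]):
        if a == MISSING or b == MISSING:
            out.append("blank")
        elif a == 1 and b == 1:
            out.append("red")
        elif a == 0 and b == 0:
            out.append("black")
        else:
            out.append("gray")
    return out


def kendall_tau_distance_matrix(matrix: np.ndarray) -> np.ndarray:
    """Pairwise 1 - tau distances between binary row vectors.

    For paired binary vectors Kendall's tau-b equals the phi coefficient
    (the Pearson correlation of the 0/1 vectors), which is computed in closed
    form.  Constant vectors make tau undefined; the convention is distance 0
    for two identical constant vectors and distance 1 (tau treated as 0) when
    either vector of a non-identical pair is constant.
    """
    x = matrix.astype(float)
    n = x.shape[0]
    std = x.std(axis=1)
    constant = std == 0
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    safe_norms = np.where(norms == 0, 1.0, norms)
    unit = centered / safe_norms[:, None]
    tau = unit @ unit.T
    dist = 1.0 - tau
    # constant-vector conventions
    for i in range(n):
        if not constant[i]:
            continue
        for j in range(n):
            if i == j:
                continue
            if constant[j] and np.array_equal(x[i], x[j]):
                dist[i, j] = 0.0
            else:
                dist[i, j] = 1.0
    np.fill_diagonal(dist, 0.0)
    return np.clip((dist + dist.T) / 2.0, 0.0, None)


def cluster_reads(
    matrix: np.ndarray,
    metric: str = "kendall_tau",
    linkage_method: str = "average",
    read_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Deterministic leaf order of reads from agglomerative clustering.

    ``matrix`` holds one row per read of ternary calls for the clustering
    context; missing is imputed as 0 for the distance only.  Ties are broken
    by read id: rows are processed in read-id order, so equal-distance merges
    resolve identically for any input permutation.  A single read yields the
    identity order.
    """
    matrix = np.asarray(matrix)
    n = matrix.shape[0]
    if n == 0:
        return np.array([], dtype=int)
    if n == 1:
        return np.array([0], dtype=int)
    if read_ids is not None:
        if len(read_ids) != n:
            raise ValueError("read_ids length must match matrix rows")
        order0 = np.argsort(np.asarray(read_ids, dtype=object), kind="stable")
    else:
        order0 = np.arange(n)
    data = matrix[order0].astype(float)
    data[data == MISSING] = 0.0
    if metric == "kendall_tau":
        condensed = squareform(kendall_tau_distance_matrix(data), checks=False)
    elif metric == "euclidean":
        condensed = pdist(data, metric="euclidean")
    else:
        raise ValueError(f"unknown cluster metric {metric!r}")
    tree = linkage(condensed, method=linkage_method)
    leaves = leaves_list(tree)
    return order0[leaves]


def subsample_rows(n: int, max_reads: int, seed: int) -> np.ndarray:
    """Sorted indices of a seeded uniform subsample (all rows when n <= cap)."""
    if n <= max_reads:
        return np.arange(n)
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(n, size=max_reads, replace=False))


def render_heatmap(
    calls: Sequence[MoleculeCall],
    target: TargetRegion,
    spec: HeatmapSpec,
    out_path: str | Path,
) -> Path | None:
    """Render the per-molecule heatmap panels and write a row-order sidecar.

    ``calls`` are the replicate-pooled, filtered, full-length reads of one
    sample.  Rows are subsampled (seeded) above ``spec.max_reads``, clustered
    on ``spec.cluster_context``, and drawn across all panels in the same
    order.  Returns the sidecar TSV path (``<out>.rows.tsv``) listing plotted
    read ids in row order, or None when there are no reads (no-op with
    warning).
    """
    full = [c for c in calls if c.full_length]
    if not full:
        log.warning("render_heatmap %s: zero full-length reads, skipping", spec.target_id)
        return None
    sites = target.sites()
    keep = subsample_rows(len(full), spec.max_reads, spec.subsample_seed)
    plotted = [full[i] for i in keep]

    cluster_idx = [s.index for s in sites if s.context == spec.cluster_context]
    if len(cluster_idx) >= 1 and len(plotted) >= 2:
        cluster_matrix = np.array([c.calls[cluster_idx] for c in plotted])
        order = cluster_reads(
            cluster_matrix,
            metric=spec.cluster_metric,
            linkage_method=spec.linkage,
            read_ids=[c.read_id for c in plotted],
        )
    else:
        order = np.arange(len(plotted))
    plotted = [plotted[i] for i in order]

    n_rows = len(plotted)
    width = len(target)
    out_path = Path(out_path)
    fig, axes = plt.subplots(
        1,
        len(spec.contexts),
        figsize=(min(4 * len(spec.contexts), 16), 6),
        squeeze=False,
    )
    for panel, context in enumerate(spec.contexts):
        ax = axes[0][panel]
        offsets = [s.offset for s in sites if s.context == context]
        idx = [s.index for s in sites if s.context == context]
        image = np.ones((n_rows, width, 3))
        for row, call in enumerate(plotted):
            sub = call.calls[idx]
            classes = segment_classes(sub)
            for k, cls in enumerate(classes):
                lo, hi = offsets[k], offsets[k + 1]
                image[row, lo : hi + 1] = _COLORS[cls]
            for off in offsets:  # vertical white lines at true site offsets
                image[row, off] = _COLORS["blank"]
        ax.imshow(image, aspect="auto", interpolation="nearest")
        for label, lo, hi in target.elements:
            ax.axvspan(lo, hi, ymin=0.0, ymax=0.02, color=(0.1, 0.6, 0.1))
        ax.set_title(context, fontsize=10)
        ax.set_xlabel("position (nt)")
        ax.set_yticks([])
    axes[0][0].set_ylabel(f"{n_rows} molecules")
    fig.suptitle(spec.target_id)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)

    sidecar = Path(str(out_path) + ".rows.tsv")
    with open(sidecar, "w") as out:
        out.write("row\tread_id\n")
        for row, call in enumerate(plotted):
            out.write(f"{row}\t{call.read_id}\n")
    return sidecar
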