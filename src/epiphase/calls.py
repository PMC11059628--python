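"""Read-to-target assignment, per-molecule methylation calling, filters and QC.

Conversion chemistry leaves methylated C as C and turns unmethylated C into T,
so a converted read differs from its reference target mainly at unmethylated
cytosines.  Assignment and alignment must therefore be conversion-aware:

* assignment matches 30-nt terminal anchors with C and T collapsed to one
  letter on both read and anchor, so conversion state cannot break matching;
* alignment scores a read T against a reference C as a full match.

Per-site calls are ternary: 1 (C, methylated), 0 (T, converted unmethylated),
or missing (anything else: A/G/N/gap/uncovered).  A read is *full-length* when
it has an informative call at every site of its target -- the unit required for
per-molecule phasing statistics.

The molecule-level quality filter drops reads with more than three
consecutively methylated CHH sites (run of >= 4 over the CHH subsequence in
site order), the signature of a molecule that escaped enzymatic conversion;
missing calls break such runs, so a read is never dropped on unobserved
evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .targets import CONTEXTS, CytosineSite, TargetRegion

log = logging.getLogger(__name__)

#: Sentinel for a missing (uninformative) per-site call.
MISSING = -1

_COLLAPSE = str.maketrans("C", "T")


@dataclass
class MoleculeCall:
    """One read's ternary methylation-call vector over a target's sites."""

    read_id: str
    target_id: str
    calls: np.ndarray  # int8: 1 methylated, 0 unmethylated, -1 missing
    sample: str = ""
    replicate: str = ""

    @property
    def full_length(self) -> bool:
        return bool((self.calls != MISSING).all())

    def context_calls(self, sites: Sequence[CytosineSite], context: str) -> np.ndarray:
        """Calls restricted to the sites of ``context``, in site order."""
        idx = [s.index for s in sites if s.context == context]
        return self.calls[idx]


@dataclass
class ReadAlignment:
    """A read globally aligned to its assigned target.

    ``bases`` holds, for every target offset, the read base aligned there
    ('-' for a gap or an uncovered position).
    """

    read_id: str
    target_id: str
    bases: np.ndarray  # dtype S1, length == len(target)
    anchor_mismatches: int = 0


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _conversion_aware_aligner() -> Align.PairwiseAligner:
    alphabet = "ACGTN"
    matrix = substitution_matrices.Array(alphabet, dims=2)
    for x in alphabet:
        for y in alphabet:
            if "N" in (x, y):
                score = 0.0
            elif x == y or {x, y} == {"C", "T"}:
                score = 1.0  # read T on reference C: converted C, no penalty
            else:
                score = -1.0
            matrix[x, y] = score
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -1.0
    aligner.end_gap_score = 0.0  # tolerate truncated reads
    return aligner


class TargetAssigner:
    """Assign converted reads to targets by collapsed-alphabet terminal anchors.

    A read is compared to each target's first and last ``anchor_len`` bases
    with C->T collapsed on both sides; it is assignable to a target when
    either anchor matches with at most ``max_mismatch`` mismatches, and is
    assigned to the target with the fewest total anchor mismatches.  Reads
    failing both anchors for every target are off-target.
    """

    def __init__(
        self,
        targets: Sequence[TargetRegion],
        anchor_len: int = 30,
        max_mismatch: int = 5,
    ):
        if not targets:
            raise ValueError("zero targets")
        self.targets = {t.target_id: t for t in targets}
        self.anchor_len = anchor_len
        self.max_mismatch = max_mismatch
        self._anchors = {}
        for t in targets:
            collapsed = t.sequence.translate(_COLLAPSE)
            self._anchors[t.target_id] = (
                collapsed[:anchor_len],
                collapsed[-anchor_len:],
            )

    def assign(self, read_seq: str) -> tuple[str, int] | None:
        """Best target for a read, or None if off-target.

        Returns ``(target_id, total_anchor_mismatches)``.
        """
        collapsed = read_seq.upper().translate(_COLLAPSE)
        head = collapsed[: self.anchor_len]
        tail = collapsed[-self.anchor_len :]
        best: tuple[int, str] | None = None
        for target_id, (a5, a3) in self._anchors.items():
            m5 = _hamming(head, a5)
            m3 = _hamming(tail, a3)
            if min(m5, m3) > self.max_mismatch:
                continue
            total = m5 + m3
            if best is None or (total, target_id) < best:
                best = (total, target_id)
        if best is None:
            return None
        return best[1], best[0]


def align_read(
    read_id: str,
    read_seq: str,
    target: TargetRegion,
    aligner: Align.PairwiseAligner | None = None,
    fast_path_mismatch_frac: float = 0.1,
) -> ReadAlignment:
    """Globally align a read to its target, conversion-aware.

    When the read has the same length as the target and differs from it at no
    more than ``fast_path_mismatch_frac`` of positions under the collapsed
    alphabet, the identity alignment is used directly (the common case for
    full-length converted reads); otherwise a global alignment with T-vs-C
    scored as a match is computed.
    """
    read_seq = read_seq.upper()
    n = len(target)
    if len(read_seq) == n:
        collapsed_read = read_seq.translate(_COLLAPSE)
        collapsed_ref = target.sequence.translate(_COLLAPSE)
        mismatches = sum(
            1
            for x, y in zip(collapsed_read, collapsed_ref)
            if x != y and x != "N" and y != "N"
        )
        if mismatches <= fast_path_mismatch_frac * n:
            return ReadAlignment(
                read_id, target.target_id, np.frombuffer(read_seq.encode(), dtype="S1").copy()
            )
    if aligner is None:
        aligner = _conversion_aware_aligner()
    alignment = aligner.align(target.sequence, read_seq)[0]
    bases = np.full(n, b"-", dtype="S1")
    read_bytes = np.frombuffer(read_seq.encode(), dtype="S1")
    target_blocks, read_blocks = alignment.aligned
    for (t0, t1), (q0, q1) in zip(target_blocks, read_blocks):
        bases[t0:t1] = read_bytes[q0:q1]
    return ReadAlignment(read_id, target.target_id, bases)


def assign_and_align(
    reads: Iterable[tuple[str, str]],
    targets: Sequence[TargetRegion],
    anchor_len: int = 30,
    max_mismatch: int = 5,
) -> tuple[list[ReadAlignment], int]:
    """Assign each read to its best target and align it.

    ``reads`` yields ``(read_id, sequence)`` pairs.  Returns the alignments of
    on-target reads plus the number of off-target reads.
    """
    assigner = TargetAssigner(targets, anchor_len=anchor_len, max_mismatch=max_mismatch)
    aligner = _conversion_aware_aligner()
    alignments: list[ReadAlignment] = []
    n_off = 0
    for read_id, seq in reads:
        hit = assigner.assign(seq)
        if hit is None:
            n_off += 1
            continue
        target_id, mismatches = hit
        aln = align_read(read_id, seq, assigner.targets[target_id], aligner)
        aln.anchor_mismatches = mismatches
        alignments.append(aln)
    return alignments, n_off


def call_molecule(alignment: ReadAlignment, sites: Sequence[CytosineSite]) -> MoleculeCall:
    """Ternary per-site methylation calls for one aligned read."""
    calls = np.full(len(sites), MISSING, dtype=np.int8)
    for i, site in enumerate(sites):
        base = alignment.bases[site.offset]
        if base == b"C":
            calls[i] = 1
        elif base == b"T":
            calls[i] = 0
    return MoleculeCall(alignment.read_id, alignment.target_id, calls)


def max_methylated_run(calls: np.ndarray) -> int:
    """Longest run of consecutive methylated calls; missing breaks a run."""
    best = run = 0
    for value in calls:
        if value == 1:
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


def filter_chh_runs(
    call: MoleculeCall, sites: Sequence[CytosineSite], max_run: int = 3
) -> bool:
    """True if the read passes the consecutive-CHH-methylation filter.

    A read is dropped iff its CHH-context calls, taken in site order, contain
    a run of more than ``max_run`` consecutive methylated calls (adjacency is
    in the CHH subsequence, not genomic distance).  Missing calls interrupt a
    run.
    """
    chh = call.context_calls(sites, "CHH")
    return max_methylated_run(chh) <= max_run


def filter_gap_fraction(
    call: MoleculeCall, max_missing_frac: float = 0.2
) -> bool:
    """True if the read's missing-call fraction is acceptable (low-quality guard)."""
    if call.calls.size == 0:
        return False
    frac = float((call.calls == MISSING).mean())
    return frac <= max_missing_frac


def conversion_rate(control_calls: Iterable[MoleculeCall]) -> float:
    """Pooled C->T conversion-rate estimate over control-region calls.

    The denominator is every informative call (0 or 1) on the internal-control
    target across all reads and all three contexts; the numerator is the
    unmethylated (converted, T) calls.  Returns NaN when there are no
    informative calls.
    """
    n_total = 0
    n_converted = 0
    for call in control_calls:
        informative = call.calls != MISSING
        n_total += int(informative.sum())
        n_converted += int((call.calls == 0).sum())
    if n_total == 0:
        return float("nan")
    return n_converted / n_total


@dataclass
class QCSummary:
    """Assay-level QC: on-target fractions, coverage and target detection."""

    sample_stats: pd.DataFrame      # per sample: total/on-target reads + fraction
    replicate_target_counts: pd.DataFrame  # sample, replicate, target_id, n_reads
    pooled_target_counts: pd.DataFrame     # sample, target_id, n_reads (replicates pooled)
    detection: pd.DataFrame         # per sample: targets with >=1 / >=min_reads reads, coverage
    min_reads: int = 10

    def to_dict(self) -> dict:
        return {
            "min_reads": self.min_reads,
            "sample_stats": self.sample_stats.to_dict(orient="records"),
            "detection": self.detection.to_dict(orient="records"),
        }


def log2_coverage(read_counts: np.ndarray | Sequence[int]) -> np.ndarray:
    """Coverage display transform: log2(read number + 1)."""
    return np.log2(np.asarray(read_counts, dtype=float) + 1.0)


def coverage_summary(
    calls: Sequence[MoleculeCall],
    targets: Sequence[TargetRegion],
    min_reads: int = 10,
    totals: Mapping[str, Mapping[str, int]] | None = None,
) -> QCSummary:
    """Per-sample coverage and detection summary over filtered calls.

    ``totals`` optionally maps sample -> ``{"total": n, "on_target": n}`` from
    the assignment stage (on-target fractions are NaN without it).  Replicates
    are pooled per sample before the >= ``min_reads`` detection criterion; the
    per-replicate counts are also emitted.
    """
    target_ids = [t.target_id for t in targets]
    records = [
        {"sample": c.sample, "replicate": c.replicate, "target_id": c.target_id}
        for c in calls
    ]
    frame = pd.DataFrame(records, columns=["sample", "replicate", "target_id"])
    samples = sorted(frame["sample"].unique()) if len(frame) else []
    if totals:
        samples = sorted(set(samples) | set(totals))

    rep_counts = (
        frame.groupby(["sample", "replicate", "target_id"]).size().rename("n_reads").reset_index()
        if len(frame)
        else pd.DataFrame(columns=["sample", "replicate", "target_id", "n_reads"])
    )

    pooled_rows = []
    detection_rows = []
    sample_rows = []
    for sample in samples:
        sub = frame[frame["sample"] == sample]
        counts = sub.groupby("target_id").size()
        full = np.array([int(counts.get(tid, 0)) for tid in target_ids])
        for tid, n in zip(target_ids, full):
            pooled_rows.append({"sample": sample, "target_id": tid, "n_reads": int(n)})
        n_targets = len(target_ids)
        detection_rows.append(
            {
                "sample": sample,
                "n_targets": n_targets,
                "n_ge1": int((full >= 1).sum()),
                "n_ge_min": int((full >= min_reads).sum()),
                "pct_ge1": 100.0 * (full >= 1).mean() if n_targets else 0.0,
                "pct_ge_min": 100.0 * (full >= min_reads).mean() if n_targets else 0.0,
                "median_coverage": float(np.median(full)) if n_targets else 0.0,
                "mean_coverage": float(full.mean()) if n_targets else 0.0,
            }
        )
        total = on_target = None
        if totals and sample in totals:
            total = int(totals[sample]["total"])
            on_target = int(totals[sample]["on_target"])
        sample_rows.append(
            {
                "sample": sample,
                "n_filtered_reads": int(len(sub)),
                "total_reads": total,
                "on_target_reads": on_target,
                "on_target_fraction": (on_target / total) if total else float("nan"),
            }
        )

    return QCSummary(
        sample_stats=pd.DataFrame(
            sample_rows,
            columns=[
                "sample",
                "n_filtered_reads",
                "total_reads",
                "on_target_reads",
                "on_target_fraction",
            ],
        ),
        replicate_target_counts=rep_counts,
        pooled_target_counts=pd.DataFrame(
            pooled_rows, columns=["sample", "target_id", "n_reads"]
        ),
        detection=pd.DataFrame(detection_rows),
        min_reads=min_reads,
    )


def read_fastx(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA or FASTQ file into (read_id, sequence) pairs."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with open(path) as handle:
        first = handle.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), fmt)]


def alignments_from_sam(path: str | Path, targets: Sequence[TargetRegion]) -> list[ReadAlignment]:
    """Build read alignments from a pre-aligned SAM file.

    Reference names must equal target ids; the SAM's aligned pairs place read
    bases on target offsets directly, skipping anchor assignment.  Methylation
    tags in the SAM, if any, are ignored.
    """
    import pysam

    by_id = {t.target_id: t for t in targets}
    alignments = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.reference_name not in by_id:
                continue
            target = by_id[rec.reference_name]
            bases = np.full(len(target), b"-", dtype="S1")
            seq = rec.query_sequence or ""
            for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
                if 0 <= rpos < len(target):
                    bases[rpos] = seq[qpos].upper().encode()
            alignments.append(ReadAlignment(rec.query_name, target.target_id, bases))
    return alignments


def call_reads(
    reads: Iterable[tuple[str, str]],
    targets: Sequence[TargetRegion],
    sample: str = "",
    replicate: str = "",
    max_chh_run: int = 3,
    max_missing_frac: float = 0.2,
    anchor_len: int = 30,
    max_mismatch: int = 5,
) -> tuple[list[MoleculeCall], dict]:
    """Full per-sample calling stage: assign, align, call and filter.

    Returns the filtered calls plus a bookkeeping dict with ``total``,
    ``on_target`` and per-target pre/post-filter counts.
    """
    reads = list(reads)
    site_index = {t.target_id: t.sites() for t in targets}
    alignments, n_off = assign_and_align(
        reads, targets, anchor_len=anchor_len, max_mismatch=max_mismatch
    )
    kept: list[MoleculeCall] = []
    pre_counts: dict[str, int] = {}
    post_counts: dict[str, int] = {}
    n_gappy = n_chh_dropped = 0
    for aln in alignments:
        sites = site_index[aln.target_id]
        call = call_molecule(aln, sites)
        call.sample = sample
        call.replicate = replicate
        pre_counts[aln.target_id] = pre_counts.get(aln.target_id, 0) + 1
        if not filter_gap_fraction(call, max_missing_frac):
            n_gappy += 1
            continue
        if not filter_chh_runs(call, sites, max_run=max_chh_run):
            n_chh_dropped += 1
            continue
        post_counts[aln.target_id] = post_counts.get(aln.target_id, 0) + 1
        kept.append(call)
    if n_gappy:
        log.info("%s/%s: %d read(s) dropped for >20%% missing sites", sample, replicate, n_gappy)
    stats = {
        "total": len(reads),
        "on_target": len(alignments),
        "off_target": n_off,
        "chh_filtered": n_chh_dropped,
        "gap_filtered": n_gappy,
        "pre_filter_counts": pre_counts,
        "post_filter_counts": post_counts,
    }
    return kept, stats


def write_call_matrix(
    calls: Sequence[MoleculeCall], sites: Sequence[CytosineSite], path: str | Path
) -> None:
    """Write a per-read call matrix TSV: one row per read, one column per site.

    Values are 1 (methylated), 0 (unmethylated) or '.' (missing).
    """
    with open(path, "w") as out:
        header = ["read_id", "target_id", "sample", "replicate"] + [
            f"s{site.index}_{site.context}_{site.offset}" for site in sites
        ]
        out.write("\t".join(header) + "\n")
        for call in calls:
            values = ["." if v == MISSING else str(int(v)) for v in call.calls]
            out.write(
                "\t".join([call.read_id, call.target_id, call.sample, call.replicate] + values)
                + "\n"
            )


def read_call_matrix(path: str | Path) -> list[MoleculeCall]:
    """Read back a call matrix written by :func:`write_call_matrix`."""
    calls = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        n_meta = 4
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            values = np.array(
                [MISSING if v == "." else int(v) for v in fields[n_meta:]], dtype=np.int8
            )
            calls.append(
                MoleculeCall(
                    read_id=fields[0],
                    target_id=fields[1],
                    calls=values,
                    sample=fields[2],
                    replicate=fields[3],
                )
            )
    return calls
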