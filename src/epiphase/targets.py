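"""Target regions and cytosine-context extraction on the captured strand.

Targeted single-stranded capture sequences one strand of each locus (the coding
strand of the gene).  All downstream analysis therefore sees a single
captured-strand sequence per target; cytosines on the opposite strand are never
observed and are ignored entirely.

Plant genomes methylate cytosines in three sequence contexts -- CG, CHG and CHH
(H is A, C or T) -- classified from the two bases immediately downstream of the
C on the same strand.  ``extract_sites`` enumerates every cytosine of a target
whose context can be resolved inside the target sequence:

* CG needs only the +1 base (an immediate G settles the context);
* CHG/CHH need both the +1 and +2 bases;
* a context window containing N, or running off the 3' end, leaves the context
  unresolved and the site is dropped (with a logged warning for N).

Coordinates are 0-based half-open internally (BED convention); human-readable
catalogs additionally carry 1-based positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

#: Cytosine context classes, in canonical display order.
CONTEXTS = ("CG", "CHG", "CHH")

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class CytosineSite:
    """One cytosine on the captured strand of a target.

    Parameters
    ----------
    target_id : str
        Identifier of the target region the site belongs to.
    index : int
        Ordinal among the target's sites, 5'->3' on the captured strand,
        0-based.
    offset : int
        Position within the target sequence (0-based).
    context : {"CG", "CHG", "CHH"}
        Cytosine context classified from the two downstream bases.
    """

    target_id: str
    index: int
    offset: int
    context: str


@dataclass
class TargetRegion:
    """A captured locus: coordinates, captured-strand sequence and annotations.

    ``sequence`` is the captured (coding) strand; for ``strand == "-"`` it is
    the reverse complement of the reference slice.  ``elements`` holds
    cis-element annotations as ``(label, start, end)`` in target-local
    coordinates (0-based half-open).
    """

    target_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    is_control: bool = False
    elements: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.end - self.start != len(self.sequence):
            raise ValueError(
                f"{self.target_id}: end - start = {self.end - self.start} "
                f"but sequence length is {len(self.sequence)}"
            )
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(
                f"{self.target_id}: non-ACGTN characters in sequence: {sorted(bad)}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.target_id}: strand must be '+' or '-'")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc_content(self) -> float:
        """Exact G+C fraction of the captured-strand sequence."""
        seq = self.sequence
        return (seq.count("G") + seq.count("C")) / len(seq)

    def sites(self) -> list[CytosineSite]:
        """Cytosine sites of this target (cached after first call)."""
        cached = getattr(self, "_sites", None)
        if cached is None:
            cached = extract_sites(self)
            object.__setattr__(self, "_sites", cached)
        return cached


def classify_context(sequence: str, offset: int) -> str | None:
    """Classify the context of the cytosine at ``offset``, or None.

    Returns None when the base is not a C, or when the context cannot be
    resolved within the sequence: the +1 base is missing or N, or (for
    non-CG) the +2 base is missing or N.
    """
    n = len(sequence)
    if sequence[offset] != "C":
        return None
    if offset + 1 >= n:
        return None
    b1 = sequence[offset + 1]
    if b1 == "G":
        return "CG"
    if b1 == "N":
        return None
    if offset + 2 >= n:
        return None
    b2 = sequence[offset + 2]
    if b2 == "N":
        return None
    return "CHG" if b2 == "G" else "CHH"


def extract_sites(target: TargetRegion) -> list[CytosineSite]:
    """Enumerate resolvable cytosine sites of ``target`` in 5'->3' order."""
    seq = target.sequence
    if not seq:
        raise ValueError(f"{target.target_id}: empty sequence")
    sites: list[CytosineSite] = []
    n_unresolved = 0
    for offset, base in enumerate(seq):
        if base != "C":
            continue
        context = classify_context(seq, offset)
        if context is None:
            n_unresolved += 1
            continue
        sites.append(
            CytosineSite(
                target_id=target.target_id,
                index=len(sites),
                offset=offset,
                context=context,
            )
        )
    if n_unresolved:
        log.warning(
            "%s: %d cytosine(s) with unresolvable context (N or 3' edge) excluded",
            target.target_id,
            n_unresolved,
        )
    return sites


def context_indices(sites: Sequence[CytosineSite], context: str) -> list[int]:
    """Site-list indices of the sites with the given context, in site order."""
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    return [s.index for s in sites if s.context == context]


def genomic_position(target: TargetRegion, offset: int) -> int:
    """0-based reference coordinate of a target-local offset.

    For minus-strand targets the captured-strand sequence is the reverse
    complement of the reference slice, so local offset 0 maps to ``end - 1``.
    """
    if not 0 <= offset < len(target):
        raise ValueError(f"offset {offset} outside target {target.target_id}")
    if target.strand == "+":
        return target.start + offset
    return target.end - 1 - offset


def _parse_elements(text: str) -> list[tuple[str, int, int]]:
    """Parse ``label:start-end;label2:start-end`` (target-local coordinates)."""
    elements: list[tuple[str, int, int]] = []
    text = text.strip()
    if not text or text == ".":
        return elements
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        label, _, span = chunk.rpartition(":")
        lo, _, hi = span.partition("-")
        elements.append((label, int(lo), int(hi)))
    return elements


def load_targets(fasta: str | Path, table: str | Path) -> list[TargetRegion]:
    """Load target regions from a reference FASTA and a target table.

    The table is tab-separated with a header line; required columns are
    ``target_id, gene_id, chrom, start, end, strand`` and optional columns
    ``is_control`` (0/1) and ``elements`` (``label:start-end;...`` in
    target-local coordinates).  Sequences are extracted from the captured
    strand: rows with ``strand == "-"`` are reverse-complemented so that
    ``sequence`` always reads 5'->3' on the captured strand.
    """
    reference = {
        record.id: str(record.seq).upper() for record in SeqIO.parse(str(fasta), "fasta")
    }
    if not reference:
        raise ValueError(f"no sequences found in reference FASTA {fasta}")

    targets: list[TargetRegion] = []
    with open(table) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        for required in ("target_id", "gene_id", "chrom", "start", "end", "strand"):
            if required not in col:
                raise ValueError(f"target table missing column {required!r}")
        for row_number, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            chrom = fields[col["chrom"]]
            if chrom not in reference:
                raise ValueError(
                    f"target table row {row_number}: chrom {chrom!r} not in reference"
                )
            start = int(fields[col["start"]])
            end = int(fields[col["end"]])
            if start >= end:
                raise ValueError(
                    f"target table row {row_number}: start ({start}) >= end ({end})"
                )
            if start < 0 or end > len(reference[chrom]):
                raise ValueError(
                    f"target table row {row_number}: coordinates out of bounds "
                    f"for {chrom} (length {len(reference[chrom])})"
                )
            strand = fields[col["strand"]]
            seq = reference[chrom][start:end]
            if strand == "-":
                seq = str(Seq(seq).reverse_complement())
            is_control = False
            if "is_control" in col and len(fields) > col["is_control"]:
                is_control = fields[col["is_control"]].strip() in ("1", "true", "True")
            elements: list[tuple[str, int, int]] = []
            if "elements" in col and len(fields) > col["elements"]:
                elements = _parse_elements(fields[col["elements"]])
            targets.append(
                TargetRegion(
                    target_id=fields[col["target_id"]],
                    gene_id=fields[col["gene_id"]],
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    sequence=seq,
                    is_control=is_control,
                    elements=elements,
                )
            )
    return targets


def write_targets_table(targets: Iterable[TargetRegion], path: str | Path) -> None:
    """Write a target table readable by :func:`load_targets`."""
    with open(path, "w") as out:
        out.write("target_id\tgene_id\tchrom\tstart\tend\tstrand\tis_control\telements\n")
        for t in targets:
            elements = ";".join(f"{label}:{lo}-{hi}" for label, lo, hi in t.elements)
            out.write(
                f"{t.target_id}\t{t.gene_id}\t{t.chrom}\t{t.start}\t{t.end}\t"
                f"{t.strand}\t{int(t.is_control)}\t{elements or '.'}\n"
            )


def write_site_catalog(targets: Iterable[TargetRegion], path: str | Path) -> None:
    """Write the per-target cytosine site catalog as TSV.

    ``offset`` is 0-based within the target; ``position`` is the 1-based
    equivalent for human-readable reports.
    """
    with open(path, "w") as out:
        out.write("target_id\tindex\toffset\tposition\tcontext\n")
        for target in targets:
            for site in target.sites():
                out.write(
                    f"{site.target_id}\t{site.index}\t{site.offset}\t"
                    f"{site.offset + 1}\t{site.context}\n"
                )
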