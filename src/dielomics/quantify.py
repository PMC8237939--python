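"""Read-count assignment and RPKM quantification for mRNA and Ribo-seq.

Counting conventions for uniquely mapped, ungapped reads on a prokaryotic
genome:

* mRNA-seq: each read distributes a total count of 1 evenly over the genome
  positions it covers (1/length per position).
* Ribosome profiling: each read longer than 24 nt contributes a count of 1
  at a single position, 12 nt upstream (5'-ward) of its aligned 3' end —
  the position occupied by the ribosomal A-site. Reads of 24 nt or shorter
  are discarded.
* Gene abundance (RPKM): the summed per-position count on a gene's coding
  sequence, divided by the CDS length in kilobases and by the total counted
  reads on all coding sequences in millions.

Coordinates are 0-based half-open throughout (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AlignmentRecord",
    "GeneModel",
    "assign_mrna_coverage",
    "assign_asite",
    "count_and_rpkm",
    "read_alignments_bed",
    "read_gene_models",
]

MIN_RIBO_READ_LENGTH = 25  # only reads strictly longer than 24 nt are counted
A_SITE_OFFSET = 12  # nt upstream of the 3' end


@dataclass(frozen=True)
class AlignmentRecord:
    """One uniquely mapped, ungapped read alignment (0-based half-open)."""

    reference: str
    start: int
    end: int
    strand: str
    dataset: str = "mrna"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must be > start")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")

    @property
    def read_length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A coding sequence on the reference (0-based half-open)."""

    gene_id: str
    reference: str
    cds_start: int
    cds_end: int
    strand: str

    def __post_init__(self) -> None:
        if self.cds_end <= self.cds_start:
            raise ValueError("cds_end must be > cds_start")

    @property
    def length(self) -> int:
        return self.cds_end - self.cds_start


def _group_by_reference(alignments):
    by_ref: dict[str, list[AlignmentRecord]] = {}
    for aln in alignments:
        by_ref.setdefault(aln.reference, []).append(aln)
    return by_ref


def assign_mrna_coverage(
    alignments, reference_lengths: dict[str, int]
) -> dict[str, np.ndarray]:
    """Fractional per-position coverage: each read spreads weight 1/length.

    Returns one float array per reference. Reads extending past the
    reference end raise; the total assigned weight equals the number of
    reads exactly.
    """
    coverage = {
        ref: np.zeros(length, dtype=float) for ref, length in reference_lengths.items()
    }
    for ref, alns in _group_by_reference(alignments).items():
        if ref not in coverage:
            raise KeyError(f"alignment on unknown reference {ref!r}")
        cov = coverage[ref]
        for aln in alns:
            if aln.end > len(cov) or aln.start < 0:
                raise ValueError(
                    f"alignment {aln.start}-{aln.end} outside reference {ref!r}"
                )
            cov[aln.start : aln.end] += 1.0 / aln.read_length
    return coverage


def assign_asite(
    alignments, reference_lengths: dict[str, int]
) -> tuple[dict[str, np.ndarray], dict[str, int]]:
    """A-site counts for ribosome-profiling reads.

    Each read longer than 24 nt adds 1 at the position 12 nt upstream of its
    3' end: ``end - 1 - 12`` on the plus strand, ``start + 12`` on the minus
    strand (the 3' end of a minus-strand read is its leftmost coordinate).

    Returns (counts per reference, tally of excluded reads by reason:
    ``short`` for the length filter, ``out_of_bounds`` for offsets falling
    outside the reference).
    """
    counts = {
        ref: np.zeros(length, dtype=float) for ref, length in reference_lengths.items()
    }
    dropped = {"short": 0, "out_of_bounds": 0}
    for aln in alignments:
        if aln.read_length < MIN_RIBO_READ_LENGTH:
            dropped["short"] += 1
            continue
        if aln.reference not in counts:
            raise KeyError(f"alignment on unknown reference {aln.reference!r}")
        if aln.strand == "+":
            pos = aln.end - 1 - A_SITE_OFFSET
        else:
            pos = aln.start + A_SITE_OFFSET
        arr = counts[aln.reference]
        if pos < 0 or pos >= len(arr):
            dropped["out_of_bounds"] += 1
            continue
        arr[pos] += 1.0
    return counts, dropped


def count_and_rpkm(
    position_counts: dict[str, np.ndarray], genes
) -> pd.DataFrame:
    """CDS read counts and RPKM per gene.

    A position overlapping several coding sequences counts toward each of
    them. RPKM normalizes by CDS length (kb) and by the total counted reads
    over all CDSs (millions); a zero CDS total is an error.
    """
    rows = []
    for gene in genes:
        if gene.reference not in position_counts:
            raise KeyError(f"gene {gene.gene_id} on unknown reference")
        arr = position_counts[gene.reference]
        raw = float(arr[gene.cds_start : gene.cds_end].sum())
        rows.append((gene.gene_id, raw, gene.length))
    table = pd.DataFrame(rows, columns=["gene_id", "raw_count", "cds_length"])
    total = table["raw_count"].sum()
    if total <= 0:
        raise ValueError("no reads counted on any coding sequence")
    table["rpkm"] = (
        table["raw_count"] / (table["cds_length"] / 1e3) / (total / 1e6)
    )
    return table.set_index("gene_id")


# ---------------------------------------------------------------------------
# plain-text IO (BED6-like alignments, gene-model TSV)
# ---------------------------------------------------------------------------


def read_alignments_bed(path, dataset: str = "mrna") -> list[AlignmentRecord]:
    """Read alignments from a BED6-like TSV.

    Columns: chrom, start, end, name, score (read length, informational),
    strand. Coordinates are 0-based half-open as in BED.
    """
    table = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    return [
        AlignmentRecord(
            reference=row.chrom,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            dataset=dataset,
        )
        for row in table.itertuples()
    ]


def read_gene_models(path) -> list[GeneModel]:
    """Read gene models from a TSV: gene_id, chrom, start, end, strand."""
    table = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "chrom", "start", "end", "strand"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"gene model table missing columns: {sorted(missing)}")
    return [
        GeneModel(
            gene_id=str(row.gene_id),
            reference=row.chrom,
            cds_start=int(row.start),
            cds_end=int(row.end),
            strand=row.strand,
        )
        for row in table.itertuples()
    ]
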