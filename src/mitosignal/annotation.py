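"""Mitogenome annotation arithmetic.

Given a table of annotated features (gene name, 1-based inclusive start and
end, strand, feature kind), this module derives the bookkeeping quantities a
mitogenome description reports: per-gene lengths, intergenic nucleotides
(IGN) between adjacent features (negative values mean overlap), total genome
length, strand tallies, and the count/total of positive intergenic spacers.

Coordinates follow the GenBank convention.  Features wrapping around the
origin of a circular molecule are rejected rather than guessed: a feature
must satisfy ``end >= start``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import CoordinateError, DuplicateNameError

FEATURE_KINDS = {"PCG", "tRNA", "rRNA", "control_region"}


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated feature with 1-based inclusive coordinates."""

    name: str
    start: int
    end: int
    strand: str  # "+" (majority/J) or "-" (minority/N)
    kind: str = "PCG"
    start_codon: str | None = None
    stop_codon: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise CoordinateError(f"{self.name}: start must be >= 1")
        if self.end < self.start:
            raise CoordinateError(
                f"{self.name}: end {self.end} < start {self.start} (wrap-around unsupported)"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.name}: strand must be '+' or '-'")


def gene_length(a: GeneAnnotation) -> int:
    """Feature length in nucleotides: end - start + 1."""
    return a.end - a.start + 1


def intergenic_nucleotides(annotations: list[GeneAnnotation]) -> list[tuple[str, str, int]]:
    """IGN between each adjacent pair, in start order.

    ``IGN(prev, next) = next.start - prev.end - 1``; negative values are
    overlaps, zero means abutting features.
    """
    anns = sorted(annotations, key=lambda a: (a.start, a.end))
    return [
        (p.name, q.name, q.start - p.end - 1)
        for p, q in zip(anns, anns[1:])
    ]


@dataclass
class AnnotationSummary:
    genome_length: int
    gene_lengths: dict[str, int]
    ign: list[tuple[str, str, int]]
    n_positive_ign_locations: int
    total_positive_ign: int
    n_plus_strand: int  # genes only; control region excluded
    n_minus_strand: int
    circular: bool = False
    ign_terminal: int | None = None  # junction last-feature -> position 1
    annotations: list[GeneAnnotation] = field(default_factory=list)


def genome_summary(annotations: list[GeneAnnotation], circular: bool = False) -> AnnotationSummary:
    """Summarise a complete annotation table.

    Genome length is the maximum annotated end.  Strand counts cover genes
    only (the control region is not a gene).  If ``circular`` is set, the
    junction between the last feature and position 1 is reported as
    ``ign_terminal``; by default the table is treated as linear.
    """
    names = [a.name for a in annotations]
    if len(set(names)) != len(names):
        raise DuplicateNameError("duplicate feature names in annotation table")
    genome_length = max(a.end for a in annotations)
    ign = intergenic_nucleotides(annotations)
    positives = [v for *_, v in ign if v > 0]
    genes = [a for a in annotations if a.kind != "control_region"]
    summary = AnnotationSummary(
        genome_length=genome_length,
        gene_lengths={a.name: gene_length(a) for a in annotations},
        ign=ign,
        n_positive_ign_locations=len(positives),
        total_positive_ign=sum(positives),
        n_plus_strand=sum(1 for a in genes if a.strand == "+"),
        n_minus_strand=sum(1 for a in genes if a.strand == "-"),
        circular=circular,
        annotations=sorted(annotations, key=lambda a: (a.start, a.end)),
    )
    if circular:
        last = summary.annotations[-1]
        first = summary.annotations[0]
        summary.ign_terminal = genome_length - last.end + first.start - 1
    return summary


def read_annotation_tsv(path) -> list[GeneAnnotation]:
    """Read a TSV annotation table.

    Expected header columns: ``name start end strand kind start_codon
    stop_codon``; extra columns are ignored.  Empty codon cells mean None.
    """
    out: list[GeneAnnotation] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")

            def cell(col: str) -> str | None:
                v = f[idx[col]].strip() if col in idx and idx[col] < len(f) else ""
                return v or None

            out.append(
                GeneAnnotation(
                    name=cell("name"),
                    start=int(cell("start")),
                    end=int(cell("end")),
                    strand=cell("strand"),
                    kind=cell("kind") or "PCG",
                    start_codon=cell("start_codon"),
                    stop_codon=cell("stop_codon"),
                )
            )
    return out
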