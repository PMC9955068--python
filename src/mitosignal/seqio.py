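"""Alignment container and standard-format I/O.

The central object is :class:`Alignment`: a rectangular residue matrix over
either the nucleotide or the amino-acid alphabet, with an optional partition
map assigning columns to named genes.  All externally visible coordinates
(annotation positions, partition columns) are 1-based inclusive, following
the GenBank convention; the numpy matrix itself is indexed 0-based.

Gaps (``-``) and ambiguity codes (IUPAC nucleotide codes, ``X`` for amino
acids) are legal residues but are excluded from every count downstream --
composition, disparity, saturation -- so that a single exclusion rule is
inherited by the whole pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentShapeError,
    AlphabetError,
    DuplicateNameError,
    FrameError,
    PartitionError,
    TaxonSetError,
    TranslationWarning,
)

NT_CANONICAL = "ACGT"
NT_AMBIGUOUS = "RYSWKMBDHVN"
NT_ALPHABET = set(NT_CANONICAL + NT_AMBIGUOUS + "-?")
AA_CANONICAL = "ACDEFGHIKLMNPQRSTVWY"
AA_ALPHABET = set(AA_CANONICAL + "X*-?")

#: residues never counted in composition or pairwise statistics
NT_EXCLUDED = set(NT_AMBIGUOUS + "-?")
AA_EXCLUDED = set("X*-?")

DEFAULT_GENETIC_CODE = 5  # invertebrate mitochondrial


@dataclass
class PartitionSpec:
    """A named gene partition: which alignment columns it owns (1-based)."""

    gene: str
    columns: np.ndarray  # 1-based, ordered
    codon_position_of_column: np.ndarray | None = None  # entries in {1,2,3}

    def __len__(self) -> int:
        return len(self.columns)


@dataclass
class Alignment:
    """A multiple sequence alignment with optional gene partitions.

    Parameters
    ----------
    taxon_names:
        Unique sequence identifiers, one per row.
    matrix:
        2-D array of single characters, shape (n_taxa, n_sites).
    alphabet_kind:
        ``"nucleotide"`` or ``"amino_acid"``.
    partition_map:
        Mapping gene name -> ordered 1-based column indices.
    """

    taxon_names: list[str]
    matrix: np.ndarray
    alphabet_kind: str = "nucleotide"
    partition_map: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.ndim != 2:
            raise AlignmentShapeError("matrix must be 2-dimensional")
        if len(self.taxon_names) != self.matrix.shape[0]:
            raise AlignmentShapeError(
                f"{len(self.taxon_names)} names for {self.matrix.shape[0]} rows"
            )
        if len(set(self.taxon_names)) != len(self.taxon_names):
            raise DuplicateNameError("taxon names must be unique")
        alphabet = NT_ALPHABET if self.alphabet_kind == "nucleotide" else AA_ALPHABET
        bad = set(np.unique(self.matrix)) - alphabet
        if bad:
            raise AlphabetError(f"illegal residues for {self.alphabet_kind}: {sorted(bad)}")
        self.partition_map = {
            g: np.asarray(cols, dtype=int) for g, cols in self.partition_map.items()
        }
        seen: set[int] = set()
        for gene, cols in self.partition_map.items():
            if len(cols) and (cols.min() < 1 or cols.max() > self.n_sites):
                raise PartitionError(f"partition {gene!r} outside alignment")
            s = set(cols.tolist())
            if seen & s:
                raise PartitionError("partition column lists must be disjoint")
            seen |= s

    # -- basic queries -------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.matrix[self.taxon_names.index(taxon)]

    def sequence(self, taxon: str) -> str:
        return "".join(self.row(taxon))

    def columns0(self, gene: str) -> np.ndarray:
        """0-based column indices of a gene partition."""
        return self.partition_map[gene] - 1

    # -- derived alignments --------------------------------------------
    def take_columns(self, cols0: np.ndarray, partition_map: dict | None = None) -> "Alignment":
        """New alignment from 0-based column indices (partition map optional)."""
        cols0 = np.asarray(cols0, dtype=int)
        return Alignment(
            list(self.taxon_names),
            self.matrix[:, cols0],
            self.alphabet_kind,
            partition_map or {},
        )

    def subset_taxa(self, taxa: list[str]) -> "Alignment":
        idx = [self.taxon_names.index(t) for t in taxa]
        return Alignment(
            list(taxa), self.matrix[idx], self.alphabet_kind, dict(self.partition_map)
        )

    def gene(self, name: str) -> "Alignment":
        """Single-gene slice (partition map rebuilt for the slice)."""
        cols0 = self.columns0(name)
        pm = {name: np.arange(1, len(cols0) + 1)}
        return self.take_columns(cols0, pm)


def _detect_alphabet(residues: set[str]) -> str:
    if residues <= NT_ALPHABET:
        return "nucleotide"
    if residues <= AA_ALPHABET:
        return "amino_acid"
    raise AlphabetError(f"residues fit neither alphabet: {sorted(residues - AA_ALPHABET)}")


def read_fasta(path, alphabet_kind: str | None = None) -> Alignment:
    """Read a multi-FASTA alignment.

    Residues are upper-cased; the description after the first whitespace in
    a header is ignored for taxon identity.  Unequal record lengths raise
    :class:`AlignmentShapeError`.
    """
    names, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not names:
        raise AlignmentShapeError(f"no FASTA records in {path}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise AlignmentShapeError(f"unequal sequence lengths in {path}: {sorted(lengths)}")
    matrix = np.array([list(r) for r in rows], dtype="<U1")
    if alphabet_kind is None:
        alphabet_kind = _detect_alphabet(set(np.unique(matrix)))
    return Alignment(names, matrix, alphabet_kind)


def write_fasta(aln: Alignment, path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq("".join(row)), id=name, description="")
        for name, row in zip(aln.taxon_names, aln.matrix)
    ]
    SeqIO.write(records, str(path), "fasta")
    del width  # Biopython wraps at 60; wrapping is not part of the contract


def read_partitions(path) -> dict[str, np.ndarray]:
    """Read a TSV partition map: gene, start_col, end_col[, frame_offset].

    Columns are 1-based inclusive.  ``frame_offset`` (0/1/2, default 0) says
    how many columns of the first codon are missing at the gene's 5' end; it
    is recorded but ranges are returned as plain column lists.
    """
    out: dict[str, np.ndarray] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("gene\t"):
                continue
            parts = line.split("\t")
            gene, start, end = parts[0], int(parts[1]), int(parts[2])
            if gene in out:
                raise DuplicateNameError(f"duplicate gene {gene!r} in partition map")
            out[gene] = np.arange(start, end + 1)
    return out


def write_partitions(partition_map: dict[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tstart_col\tend_col\tframe_offset\n")
        for gene, cols in partition_map.items():
            fh.write(f"{gene}\t{cols.min()}\t{cols.max()}\t0\n")


def read_clusters(path) -> dict[str, int]:
    """Read a TSV cluster-assignment file: taxon, cluster_id in {1,2,3,4}."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("taxon\t"):
                continue
            taxon, cid = line.split("\t")[:2]
            out[taxon] = int(cid)
    return out


def extract_codon_positions(aln: Alignment, keep: set[int]) -> Alignment:
    """Keep only the requested codon positions of every coding partition.

    Every partition is assumed in frame (its column count must be divisible
    by 3, else :class:`FrameError`).  An alignment without partitions is
    treated as one single in-frame gene spanning all columns.  The partition
    map of the result is remapped to the surviving columns.
    """
    keep = set(keep)
    if not keep <= {1, 2, 3}:
        raise ValueError("codon positions must be among {1,2,3}")
    pm = aln.partition_map or {"all": np.arange(1, aln.n_sites + 1)}
    kept0: list[int] = []
    new_pm: dict[str, np.ndarray] = {}
    offset = 0
    for gene, cols in pm.items():
        if len(cols) % 3:
            raise FrameError(f"partition {gene!r} has {len(cols)} columns, not divisible by 3")
        pos = np.arange(len(cols)) % 3 + 1
        sel = np.isin(pos, list(keep))
        kept0.extend((cols[sel] - 1).tolist())
        n_kept = int(sel.sum())
        new_pm[gene] = np.arange(offset + 1, offset + n_kept + 1)
        offset += n_kept
    out = aln.take_columns(np.array(kept0, dtype=int), new_pm)
    return out


def translate(aln: Alignment, code: int = DEFAULT_GENETIC_CODE) -> Alignment:
    """Translate an in-frame nucleotide alignment to amino acids.

    Codons containing gaps or ambiguity codes become ``X``.  Internal stop
    codons translate to ``*`` and emit a :class:`TranslationWarning` rather
    than failing: truncated stop codons are routine in mitogenomes.
    """
    if aln.alphabet_kind != "nucleotide":
        raise AlphabetError("translate requires a nucleotide alignment")
    table = CodonTable.unambiguous_dna_by_id[code]
    pm = aln.partition_map or {"all": np.arange(1, aln.n_sites + 1)}
    out_rows = [[] for _ in aln.taxon_names]
    new_pm: dict[str, np.ndarray] = {}
    offset = 0
    n_internal_stops = 0
    for gene, cols in pm.items():
        if len(cols) % 3:
            raise FrameError(f"partition {gene!r} not divisible by 3")
        sub = aln.matrix[:, cols - 1]
        n_codons = len(cols) // 3
        for i in range(aln.n_taxa):
            seq = sub[i]
            for c in range(n_codons):
                codon = "".join(seq[3 * c : 3 * c + 3])
                if set(codon) & NT_EXCLUDED:
                    out_rows[i].append("X")
                elif codon in table.stop_codons:
                    out_rows[i].append("*")
                    if c < n_codons - 1:
                        n_internal_stops += 1
                else:
                    out_rows[i].append(table.forward_table[codon])
        new_pm[gene] = np.arange(offset + 1, offset + n_codons + 1)
        offset += n_codons
    if n_internal_stops:
        warnings.warn(
            f"{n_internal_stops} internal stop codon(s) translated to '*'",
            TranslationWarning,
            stacklevel=2,
        )
    matrix = np.array(out_rows, dtype="<U1")
    return Alignment(list(aln.taxon_names), matrix, "amino_acid", new_pm)


def concatenate(alns: list[Alignment]) -> Alignment:
    """Concatenate alignments over an identical taxon set.

    Columns are appended in the given order; the partition map of the result
    records each input gene's span.  Inputs without partitions contribute a
    single partition named ``gene<i>``.
    """
    if not alns:
        raise ValueError("nothing to concatenate")
    first = alns[0]
    taxa = set(first.taxon_names)
    for a in alns[1:]:
        if set(a.taxon_names) != taxa:
            raise TaxonSetError("taxon sets differ between alignments")
        if a.alphabet_kind != first.alphabet_kind:
            raise AlphabetError("alphabet kinds differ between alignments")
    order = list(first.taxon_names)
    blocks, new_pm = [], {}
    offset = 0
    for i, a in enumerate(alns):
        idx = [a.taxon_names.index(t) for t in order]
        blocks.append(a.matrix[idx])
        pm = a.partition_map or {f"gene{i + 1}": np.arange(1, a.n_sites + 1)}
        for gene, cols in pm.items():
            name = gene
            k = 2
            while name in new_pm:
                name = f"{gene}.{k}"
                k += 1
            new_pm[name] = cols + offset
        offset += a.n_sites
    return Alignment(order, np.hstack(blocks), first.alphabet_kind, new_pm)
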