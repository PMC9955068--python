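"""Base and amino-acid composition statistics.

AT content, AT/GC skew and the GARP fraction are the workhorse descriptors
of compositional heterogeneity in mitogenomes.  Skews are strand-asymmetry
measures::

    AT-skew = (A - T) / (A + T)        GC-skew = (G - C) / (G + C)

computed equivalently from counts or percentages.  GARP (Gly, Ala, Arg,
Pro) are the amino acids encoded by GC-rich codons, so their frequency in
mitochondrial proteins tracks genomic GC content.

Gaps and ambiguity codes are excluded from all counts (the package-wide
rule set in :mod:`mitosignal.seqio`).  Tables round percentages to 1 dp and
skews to 2 dp; internal computation keeps full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyCompositionError
from .seqio import AA_EXCLUDED, Alignment, NT_EXCLUDED

GARP = set("GARP")


@dataclass
class CompositionProfile:
    counts: dict[str, int]
    percentages: dict[str, float]
    at_content: float | None = None  # % (nucleotide only)
    at_skew: float | None = None
    gc_skew: float | None = None
    garp_fraction: float | None = None  # % (amino acid only)
    n_counted: int = 0
    extras: dict = field(default_factory=dict)


def at_skew(a: float, t: float) -> float:
    """(A - T)/(A + T); NaN when A + T == 0. Accepts counts or percentages."""
    if a + t == 0:
        return math.nan
    return (a - t) / (a + t)


def gc_skew(g: float, c: float) -> float:
    """(G - C)/(G + C); NaN when G + C == 0. Accepts counts or percentages."""
    if g + c == 0:
        return math.nan
    return (g - c) / (g + c)


def _counted(seq, excluded: set[str]) -> list[str]:
    return [ch for ch in seq if ch not in excluded]


def base_composition(seq) -> CompositionProfile:
    """Nucleotide composition of a sequence or alignment slice.

    ``seq`` may be a string, an iterable of characters, or a 2-D character
    array (the whole slice is pooled).  Gap/ambiguity-only input raises
    :class:`EmptyCompositionError`.
    """
    if isinstance(seq, np.ndarray):
        seq = seq.ravel()
    chars = _counted(seq, NT_EXCLUDED)
    n = len(chars)
    if n == 0:
        raise EmptyCompositionError("no unambiguous residues to count")
    counts = {b: 0 for b in "ACGT"}
    for ch in chars:
        counts[ch] += 1
    pct = {b: 100.0 * counts[b] / n for b in "ACGT"}
    return CompositionProfile(
        counts=counts,
        percentages=pct,
        at_content=pct["A"] + pct["T"],
        at_skew=at_skew(counts["A"], counts["T"]),
        gc_skew=gc_skew(counts["G"], counts["C"]),
        n_counted=n,
    )


def aa_composition(seq) -> CompositionProfile:
    """Amino-acid composition with GARP fraction; X/*/gaps excluded."""
    if isinstance(seq, np.ndarray):
        seq = seq.ravel()
    chars = _counted(seq, AA_EXCLUDED)
    n = len(chars)
    if n == 0:
        raise EmptyCompositionError("no unambiguous residues to count")
    counts: dict[str, int] = {}
    for ch in chars:
        counts[ch] = counts.get(ch, 0) + 1
    pct = {r: 100.0 * c / n for r, c in counts.items()}
    garp = 100.0 * sum(counts.get(r, 0) for r in GARP) / n
    return CompositionProfile(counts=counts, percentages=pct, garp_fraction=garp, n_counted=n)


def garp_fraction(seq) -> float:
    """Percentage of G+A+R+P residues among counted amino acids."""
    return aa_composition(seq).garp_fraction


def composition_profile(seq, alphabet_kind: str) -> CompositionProfile:
    if alphabet_kind == "nucleotide":
        return base_composition(seq)
    return aa_composition(seq)


def per_gene_table(aln: Alignment, ddof: int = 1) -> pd.DataFrame:
    """Per-gene composition summary across taxa.

    For each gene partition, the per-taxon AT% (nucleotide) or GARP%
    (amino acid) is computed and summarised as max/mean/min/sd across taxa.
    ``ddof`` selects sample (1, default) or population (0) sd.
    """
    if not aln.partition_map:
        raise KeyError("alignment has no gene partitions")
    stat = "AT%" if aln.alphabet_kind == "nucleotide" else "GARP%"
    rows = []
    for gene in aln.partition_map:
        cols0 = aln.columns0(gene)
        values = []
        for i in range(aln.n_taxa):
            prof = composition_profile(aln.matrix[i, cols0], aln.alphabet_kind)
            values.append(prof.at_content if stat == "AT%" else prof.garp_fraction)
        v = np.asarray(values, dtype=float)
        rows.append(
            {
                "gene": gene,
                "statistic": stat,
                "max": v.max(),
                "mean": v.mean(),
                "min": v.min(),
                "sd": v.std(ddof=ddof) if len(v) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def per_taxon_table(aln: Alignment) -> pd.DataFrame:
    """One composition row per taxon over the whole alignment."""
    rows = []
    for i, name in enumerate(aln.taxon_names):
        prof = composition_profile(aln.matrix[i], aln.alphabet_kind)
        row = {"taxon": name, "n_counted": prof.n_counted}
        if aln.alphabet_kind == "nucleotide":
            row.update(
                {
                    "T": round(prof.percentages["T"], 1),
                    "C": round(prof.percentages["C"], 1),
                    "A": round(prof.percentages["A"], 1),
                    "G": round(prof.percentages["G"], 1),
                    "A+T": round(prof.at_content, 1),
                    "AT_skew": round(prof.at_skew, 2),
                    "GC_skew": round(prof.gc_skew, 2),
                }
            )
        else:
            row["GARP%"] = round(prof.garp_fraction, 2)
        rows.append(row)
    return pd.DataFrame(rows)
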