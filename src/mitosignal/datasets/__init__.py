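"""Bundled reference tables for the *Lynceus grossipedia* mitogenome.

Small TSV transcriptions of the published annotation and composition
summaries of the first laevicaudatan mitogenome (GenBank OP746066) and of
the published pairwise disparity-test summary across branchiopod
mitogenomes.  They serve as ground-truth fixtures for the arithmetic the
package re-derives (gene lengths, intergenic nucleotides, skews, pairwise
proportions); ``*_published`` columns carry the values exactly as printed
in the source tables, including any typographical quirks.
"""

from importlib import resources

import pandas as pd

from ..annotation import GeneAnnotation


def _path(name: str):
    return resources.files(__package__) / name


def load_reference_annotation() -> tuple[list[GeneAnnotation], pd.DataFrame]:
    """Annotation of the L. grossipedia mitogenome.

    Returns the parsed :class:`GeneAnnotation` list and the raw table
    (including the published size and intergenic-nucleotide columns).
    """
    df = pd.read_csv(_path("lgrossipedia_annotation.tsv"), sep="\t", keep_default_na=False)
    anns = [
        GeneAnnotation(
            name=r["name"],
            start=int(r["start"]),
            end=int(r["end"]),
            strand=r["strand"],
            kind=r["kind"],
            start_codon=r["start_codon"] or None,
            stop_codon=r["stop_codon"] or None,
        )
        for _, r in df.iterrows()
    ]
    return anns, df


def load_reference_composition() -> pd.DataFrame:
    """Published per-region base composition and skews of L. grossipedia."""
    return pd.read_csv(_path("lgrossipedia_composition.tsv"), sep="\t")


def load_id_test_summary() -> pd.DataFrame:
    """Published per-gene disparity-test summary over 903 branchiopod pairs."""
    return pd.read_csv(_path("branchiopod_id_summary.tsv"), sep="\t")
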