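"""End-to-end orchestration of the signal-dissection workflow.

A :class:`RunConfig` names the inputs (a FASTA alignment with a partition
map, or the built-in synthetic scenario), a dataset recipe, the test
parameters and a master seed; :func:`run_report` executes composition
profiling, per-gene disparity testing, posterior-predictive compositional
checks, four-cluster likelihood mapping and fast-site stripping, and
writes machine-readable TSV/JSON reports plus a plain-text log.

Dataset recipes express the standard matrix constructions used in
mitogenomic work: a gene subset, then a codon-position filter, then
optional translation, then optional fast-site stripping -- always in that
order.  Named recipes for the common matrices (all genes at positions 1+2;
all-gene amino acids; a six-gene positions-1+2 matrix; a seven-protein
amino-acid matrix, with or without fast sites) are provided.

Every random stage consumes an independent sub-seed derived from the
master seed and recorded in the log, so reruns are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import composition, fclm, heterogeneity, phylo, synthetic
from .seqio import (
    Alignment,
    extract_codon_positions,
    read_clusters,
    read_fasta,
    read_partitions,
    translate,
    write_fasta,
)

SIX_GENE_SET = ["cox1", "cox2", "cox3", "cytb", "atp6", "nad3"]
SEVEN_PROTEIN_EXCLUDED = ["atp8", "nad2", "nad4", "nad4l", "nad5", "nad6"]


@dataclass
class Recipe:
    """A dataset construction: genes -> codon positions -> translation -> stripping."""

    genes: list[str] | None = None          # None = all partitioned genes
    exclude_genes: list[str] = field(default_factory=list)
    codon_positions: set[int] | None = None
    to_amino_acids: bool = False
    strip_fast: bool = False


DATASET_RECIPES: dict[str, Recipe] = {
    "PCG12": Recipe(codon_positions={1, 2}),
    "PAA": Recipe(to_amino_acids=True),
    "Pnuc6": Recipe(genes=SIX_GENE_SET, codon_positions={1, 2}),
    "Paa7": Recipe(exclude_genes=SEVEN_PROTEIN_EXCLUDED, to_amino_acids=True),
    "Paas7": Recipe(
        exclude_genes=SEVEN_PROTEIN_EXCLUDED, to_amino_acids=True, strip_fast=True
    ),
}


def build_dataset(
    aln: Alignment,
    recipe: Recipe,
    tree: phylo.Tree | None = None,
    model: phylo.SubstitutionModel | None = None,
) -> Alignment:
    """Apply a recipe to a partitioned alignment, in the fixed stage order."""
    if not aln.partition_map:
        raise ValueError("recipe application needs a partitioned alignment")
    genes = list(recipe.genes) if recipe.genes is not None else list(aln.partition_map)
    genes = [g for g in genes if g.lower() not in {e.lower() for e in recipe.exclude_genes}]
    if not genes:
        raise ValueError("recipe selects no genes")
    unknown = [g for g in genes if g not in aln.partition_map]
    if unknown:
        raise KeyError(f"recipe names unknown genes: {unknown}")
    cols0, pm, offset = [], {}, 0
    for g in genes:
        gc = aln.columns0(g)
        cols0.extend(gc.tolist())
        pm[g] = np.arange(offset + 1, offset + len(gc) + 1)
        offset += len(gc)
    out = aln.take_columns(np.array(cols0, dtype=int), pm)
    if recipe.codon_positions is not None:
        out = extract_codon_positions(out, recipe.codon_positions)
    if recipe.to_amino_acids:
        out = translate(out)
    if recipe.strip_fast:
        if tree is None:
            tree = phylo.nj_tree(out)
        if model is None:
            family = "gtr" if out.alphabet_kind == "nucleotide" else "poisson"
            model = phylo.fit_model(out, tree, family=family, max_sweeps=3).model
        assignment = phylo.assign_gamma_categories(out, tree, model)
        out, _ = phylo.strip_fast_sites(out, assignment)
    return out


def rank_genes_by_at_deviation(aln: Alignment, focal_taxon: str) -> pd.DataFrame:
    """Genes ranked by |gene AT% - whole-alignment AT%| for one taxon.

    The ranking behind the "drop the most compositionally deviant genes"
    reduction strategy; the caller chooses how many to drop.
    """
    row = aln.matrix[aln.taxon_names.index(focal_taxon)]
    overall = composition.base_composition(row).at_content
    recs = []
    for gene in aln.partition_map:
        prof = composition.base_composition(row[aln.columns0(gene)])
        recs.append(
            {"gene": gene, "at_percent": prof.at_content,
             "deviation": abs(prof.at_content - overall)}
        )
    return pd.DataFrame(recs).sort_values("deviation", ascending=False, ignore_index=True)


@dataclass
class RunConfig:
    """Inputs and parameters for one report run."""

    output_dir: str
    input_fasta: str | None = None
    partitions: str | None = None
    tree: str | None = None
    clusters: str | None = None
    scenario: str | None = None          # "branchiopod" to synthesise inputs
    recipe: str | None = None            # named recipe applied before analysis
    n_replicates: int = 1000             # disparity Monte-Carlo replicates
    alpha: float = 0.01
    n_sim: int = 100                     # posterior-predictive simulations
    fclm_cap: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_report(config: RunConfig) -> dict:
    """Execute the full dissection workflow and write the report bundle.

    Writes ``composition.tsv``, ``disparity.tsv``, ``ppa.tsv``,
    ``fclm.tsv`` (when clusters are available), ``siterates.tsv``,
    ``report.json`` and ``run.log`` into the output directory and returns
    the report dictionary.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    from . import __version__

    log(f"mitosignal {__version__}")
    log(f"master seed {config.seed}")
    seeds = np.random.SeedSequence(config.seed).spawn(6)
    sub = {name: s for name, s in zip(
        ["scenario", "disparity", "fit", "ppa", "fclm", "misc"], seeds)}
    for name, s in sub.items():
        log(f"sub-seed {name}: entropy={s.entropy} key={s.spawn_key}")

    # --- inputs --------------------------------------------------------
    if config.scenario:
        scen = synthetic.make_branchiopod_scenario(
            seed=int(np.random.default_rng(sub["scenario"]).integers(2**31))
        )
        aln, truth = synthetic.generate(scen)
        tree = phylo.Tree.from_newick(truth.true_newick)
        write_fasta(aln, out / "input.fasta")
        (out / "truth.json").write_text(truth.to_json())
        log(f"scenario {config.scenario}: {aln.n_taxa} taxa x {aln.n_sites} sites")
        cluster_map = {"A1": 1, "A2": 1, "N1": 2, "N2": 2, "L1": 3,
                       "S1": 4, "S2": 4, "C1": 4, "C2": 4}
    else:
        aln = read_fasta(config.input_fasta)
        if config.partitions:
            aln.partition_map = {
                g: c for g, c in read_partitions(config.partitions).items()
            }
        tree = phylo.Tree.from_newick(Path(config.tree).read_text()) if config.tree else None
        cluster_map = read_clusters(config.clusters) if config.clusters else None
        log(f"input {config.input_fasta}: {aln.n_taxa} taxa x {aln.n_sites} sites")

    if config.recipe:
        aln = build_dataset(aln, DATASET_RECIPES[config.recipe])
        log(f"recipe {config.recipe}: -> {aln.n_taxa} taxa x {aln.n_sites} sites")

    report: dict = {"seed": config.seed, "n_taxa": aln.n_taxa, "n_sites": aln.n_sites}

    # --- composition ---------------------------------------------------
    comp = composition.per_taxon_table(aln)
    per_gene = composition.per_gene_table(aln) if aln.partition_map else None
    _write_tsv(comp, out / "composition.tsv")
    if per_gene is not None:
        _write_tsv(per_gene, out / "composition_by_gene.tsv")
    log(f"composition: {len(comp)} taxa")

    # --- disparity -----------------------------------------------------
    rng_disp = np.random.default_rng(sub["disparity"])
    genes = list(aln.partition_map) if aln.partition_map else [None]
    disp_rows = []
    for gene in genes + (["__concatenated__"] if aln.partition_map else []):
        g = None if gene in (None, "__concatenated__") else gene
        summary, _ = heterogeneity.pairwise_heterogeneity_matrix(
            aln, g, config.n_replicates, config.alpha, rng_disp
        )
        disp_rows.append(
            {
                "gene": gene or "all",
                "n_pairs": summary.n_pairs_total,
                "n_significant": summary.n_pairs_significant,
                "proportion_significant": round(summary.proportion_significant, 1),
            }
        )
    disp = pd.DataFrame(disp_rows)
    _write_tsv(disp, out / "disparity.tsv")
    report["disparity"] = disp.to_dict(orient="records")
    log(f"disparity: {len(disp)} rows at alpha={config.alpha}")

    # --- model fit (shared by PPA / FcLM / stripping) -------------------
    if tree is None:
        tree = phylo.nj_tree(aln)
    family = "gtr" if aln.alphabet_kind == "nucleotide" else "poisson"
    fit = phylo.fit_model(aln, tree, family=family, n_categories=4, max_sweeps=3)
    log(f"model fit: {family}+G4 lnL={fit.log_likelihood:.3f} "
        f"alpha={fit.model.gamma_shape:.4g} converged={fit.converged}")

    # --- posterior predictive compositional test ------------------------
    rng_ppa = np.random.default_rng(sub["ppa"])
    ppa_rows = []
    for gene in genes + (["__concatenated__"] if aln.partition_map else []):
        sub_aln = aln if gene in (None, "__concatenated__") else aln.gene(gene)
        res = heterogeneity.compositional_ppa(
            sub_aln, fit.tree, fit.model, config.n_sim, rng_ppa
        )
        ppa_rows.append(
            {"gene": (gene or "all") if gene != "__concatenated__" else "concatenated",
             "z_score": round(res.z_score, 2),
             "p_score": round(res.p_score, 2),
             "ndt": res.ndt}
        )
    ppa = pd.DataFrame(ppa_rows)
    _write_tsv(ppa, out / "ppa.tsv")
    report["ppa"] = ppa.to_dict(orient="records")
    log(f"ppa: {len(ppa)} rows with {config.n_sim} simulations each")

    # --- four-cluster likelihood mapping --------------------------------
    if cluster_map:
        clusters = fclm.ClusterAssignment.from_mapping(
            {t: c for t, c in cluster_map.items() if t in aln.taxon_names}
        )
        summary, table = fclm.run_fclm(
            aln, clusters, fit.model, cap=config.fclm_cap,
            seed=np.random.default_rng(sub["fclm"]), preferred="12|34",
        )
        _write_tsv(table, out / "fclm.tsv")
        report["fclm"] = {
            "region_percentages": {k: round(v, 1) for k, v in
                                   summary.region_percentages.items()},
            "n_quartets": summary.n_quartets,
            "percent_preferred_corner": summary.percent_preferred_corner,
        }
        log(f"fclm: {summary.n_quartets} quartets")

    # --- site rates and stripping ---------------------------------------
    assignment = phylo.assign_gamma_categories(aln, fit.tree, fit.model)
    stripped, removed = phylo.strip_fast_sites(aln, assignment)
    rates_df = pd.DataFrame(
        {"site": np.arange(1, aln.n_sites + 1), "category": assignment.category + 1}
    )
    _write_tsv(rates_df, out / "siterates.tsv")
    report["site_rates"] = {
        "fraction_in_fastest_percent": round(assignment.fraction_in_fastest, 2),
        "removed_percent": round(removed, 2),
        "n_sites_after_stripping": stripped.n_sites,
    }
    log(f"stripping: removed {removed:.2f}% of sites "
        f"({aln.n_sites} -> {stripped.n_sites})")

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return report
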