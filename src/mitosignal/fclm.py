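"""Four-cluster likelihood mapping (FcLM).

Taxa are divided into four disjoint clusters; every quartet drawn with one
taxon per cluster is evaluated under the three possible quartet topologies

    T1: (c1,c2 | c3,c4)    T2: (c1,c3 | c2,c4)    T3: (c1,c4 | c2,c3)

by maximum likelihood (global model parameters, branch lengths re-optimised
per quartet).  The log-likelihoods become barycentric weights via a softmax
and each quartet is mapped into a 2-D simplex divided into seven regions:
three corners (fully resolved), three edges (partly resolved between two
topologies) and a centre (unresolved, star-like signal).  The aggregated
region percentages summarise how much resolved, conflicting and absent
signal an alignment carries for the split of interest.

Region rule (frozen here so percentages are bit-for-bit reproducible):
``corner_i`` iff ``w_i > 2/3``; ``center`` iff ``max(w) < 1/2`` and all
pairwise ``|w_i - w_j| < 1/3``; otherwise the edge between the two largest
weights.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import phylo
from .seqio import Alignment

REGIONS = ("corner1", "corner2", "corner3", "edge12", "edge13", "edge23", "center")

#: which clusters each topology index pairs with cluster 1
TOPOLOGY_LABELS = ("12|34", "13|24", "14|23")


@dataclass
class ClusterAssignment:
    """Four disjoint, non-empty taxon sets."""

    clusters: dict[int, list[str]]  # keys 1..4
    labels: dict[int, str] | None = None

    def __post_init__(self) -> None:
        if set(self.clusters) != {1, 2, 3, 4}:
            raise ValueError("exactly four clusters labelled 1..4 required")
        seen: set[str] = set()
        for cid, taxa in self.clusters.items():
            if not taxa:
                raise ValueError(f"cluster {cid} is empty")
            overlap = seen & set(taxa)
            if overlap:
                raise ValueError(f"taxa in more than one cluster: {sorted(overlap)}")
            seen |= set(taxa)

    @classmethod
    def from_mapping(cls, mapping: dict[str, int], labels: dict[int, str] | None = None):
        clusters: dict[int, list[str]] = {1: [], 2: [], 3: [], 4: []}
        for taxon, cid in mapping.items():
            clusters[cid].append(taxon)
        return cls(clusters, labels)


@dataclass
class QuartetResult:
    taxa: tuple[str, str, str, str]
    log_likelihoods: tuple[float, float, float]
    weights: tuple[float, float, float]
    region: str


@dataclass
class SimplexSummary:
    region_percentages: dict[str, float]
    n_quartets: int
    preferred_topology: str | None
    percent_preferred_corner: float | None
    percent_preferred_best: float | None


def enumerate_quartets(
    clusters: ClusterAssignment, cap: int | None = 1000, seed=None
) -> list[tuple[str, str, str, str]]:
    """All one-per-cluster quartets, or a seeded subsample of size ``cap``."""
    sets = [clusters.clusters[i] for i in (1, 2, 3, 4)]
    total = int(np.prod([len(s) for s in sets]))
    if cap is None or total <= cap:
        return list(itertools.product(*sets))
    rng = phylo._as_rng(seed)
    chosen = rng.choice(total, size=cap, replace=False)
    sizes = [len(s) for s in sets]
    out = []
    for flat in sorted(chosen.tolist()):
        idx = np.unravel_index(flat, sizes)
        out.append(tuple(sets[k][i] for k, i in enumerate(idx)))
    return out


def quartet_weights(l1: float, l2: float, l3: float) -> tuple[float, float, float]:
    """Softmax of three log-likelihoods with log-sum-exp stabilisation."""
    ls = np.array([l1, l2, l3], dtype=float)
    w = np.exp(ls - logsumexp(ls))
    w = w / w.sum()
    return tuple(w.tolist())


def classify_region(w1: float, w2: float, w3: float) -> str:
    """Map barycentric weights to one of the seven simplex regions."""
    w = np.array([w1, w2, w3])
    i_max = int(w.argmax())
    if w[i_max] > 2.0 / 3.0:
        return f"corner{i_max + 1}"
    diffs = [abs(w[0] - w[1]), abs(w[0] - w[2]), abs(w[1] - w[2])]
    if w.max() < 0.5 and all(d < 1.0 / 3.0 for d in diffs):
        return "center"
    top2 = sorted(np.argsort(w)[-2:] + 1)
    return f"edge{top2[0]}{top2[1]}"


def _quartet_trees(taxa: tuple[str, str, str, str], init: float = 0.1) -> list[phylo.Tree]:
    a, b, c, d = taxa
    arrangements = [(a, b, c, d), (a, c, b, d), (a, d, b, c)]
    trees = []
    for x1, x2, x3, x4 in arrangements:
        nwk = (
            f"(({x1}:{init},{x2}:{init}):{init},{x3}:{init},{x4}:{init});"
        )
        trees.append(phylo.Tree.from_newick(nwk))
    return trees


def evaluate_quartet(
    aln: Alignment,
    taxa: tuple[str, str, str, str],
    model: phylo.SubstitutionModel,
    branch_xatol: float = 1e-4,
) -> QuartetResult:
    """ML log-likelihoods, weights and region for one quartet."""
    sub = aln.subset_taxa(list(taxa))
    engine = phylo.LikelihoodEngine(sub, model)
    lnls = []
    for tree in _quartet_trees(taxa):
        lnl = phylo._optimize_branches(engine, tree, xatol=branch_xatol)
        lnl = phylo._optimize_branches(engine, tree, xatol=branch_xatol)
        lnls.append(lnl)
    w = quartet_weights(*lnls)
    return QuartetResult(taxa, tuple(lnls), w, classify_region(*w))


def run_fclm(
    aln: Alignment,
    clusters: ClusterAssignment,
    model: phylo.SubstitutionModel | None = None,
    cap: int | None = 1000,
    seed=None,
    preferred: str | None = None,
) -> tuple[SimplexSummary, pd.DataFrame]:
    """Full FcLM analysis: per-quartet table plus simplex summary.

    If ``model`` is None a GTR+G4 (nucleotide) or Poisson+G4 (amino acid)
    model is fitted once on the whole alignment with a neighbor-joining
    guide tree; branch lengths are then re-optimised per quartet under the
    shared model.  ``preferred`` names the topology of interest as one of
    ``"12|34"``, ``"13|24"``, ``"14|23"``.
    """
    rng = phylo._as_rng(seed)
    missing = {t for ts in clusters.clusters.values() for t in ts} - set(aln.taxon_names)
    if missing:
        raise ValueError(f"cluster taxa absent from alignment: {sorted(missing)}")
    if model is None:
        guide = phylo.nj_tree(aln)
        family = "gtr" if aln.alphabet_kind == "nucleotide" else "poisson"
        model = phylo.fit_model(
            aln, guide, family=family, n_categories=4, max_sweeps=3
        ).model
    quartets = enumerate_quartets(clusters, cap, rng)
    rows = []
    region_counts = {r: 0 for r in REGIONS}
    best_counts = np.zeros(3)
    for q in quartets:
        res = evaluate_quartet(aln, q, model)
        region_counts[res.region] += 1
        best_counts[int(np.argmax(res.weights))] += 1
        rows.append(
            {
                "taxon_1": q[0],
                "taxon_2": q[1],
                "taxon_3": q[2],
                "taxon_4": q[3],
                "lnL_12|34": res.log_likelihoods[0],
                "lnL_13|24": res.log_likelihoods[1],
                "lnL_14|23": res.log_likelihoods[2],
                "w1": res.weights[0],
                "w2": res.weights[1],
                "w3": res.weights[2],
                "region": res.region,
            }
        )
    n = len(quartets)
    pct = {r: 100.0 * c / n for r, c in region_counts.items()}
    pref_corner = pref_best = None
    if preferred is not None:
        if preferred not in TOPOLOGY_LABELS:
            raise ValueError(f"preferred must be one of {TOPOLOGY_LABELS}")
        k = TOPOLOGY_LABELS.index(preferred)
        pref_corner = pct[f"corner{k + 1}"]
        pref_best = 100.0 * best_counts[k] / n
    summary = SimplexSummary(pct, n, preferred, pref_corner, pref_best)
    return summary, pd.DataFrame(rows)


def plot_simplex(table: pd.DataFrame, path) -> None:
    """Scatter the quartet weights on the 2-D simplex (optional matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    w = table[["w1", "w2", "w3"]].to_numpy()
    # barycentric -> cartesian with corners (0,0), (1,0), (0.5, sqrt(3)/2)
    corners = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
    xy = w @ corners
    fig, ax = plt.subplots(figsize=(4, 4))
    tri = np.vstack([corners, corners[0]])
    ax.plot(tri[:, 0], tri[:, 1], color="black", lw=1)
    ax.scatter(xy[:, 0], xy[:, 1], s=8, alpha=0.6)
    for i, lab in enumerate(TOPOLOGY_LABELS):
        ax.annotate(lab, corners[i], fontsize=8, ha="center")
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
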