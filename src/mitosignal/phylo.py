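"""Minimal phylogenetic likelihood engine.

Felsenstein-pruning log-likelihoods under homogeneous reversible models
(JC69/HKY/GTR for nucleotides, Poisson for amino acids) with discrete-gamma
among-site rate variation, plus the operations the signal-dissection
pipeline needs on top of it:

* maximum-likelihood fitting of branch lengths, gamma shape and (optionally)
  exchangeabilities by coordinate ascent;
* sequence simulation along a tree, including per-branch stationary-frequency
  overrides (a simple form of nonstationary composition drift) and
  per-branch rate multipliers;
* empirical-Bayes assignment of sites to gamma rate categories and removal
  of the fastest category ("fast-site stripping");
* small-scale ML topology search (exhaustive for <= 8 taxa, NNI
  hill-climbing with restarts up to 12).

Trees are stored as simple rooted node structures; for reversible models the
likelihood does not depend on root placement, and topology search treats
trees as unrooted.  Newick reading/writing goes through dendropy.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
from scipy import optimize, special, stats

from .errors import TaxonSetError
from .seqio import AA_CANONICAL, Alignment, NT_CANONICAL

NT_STATES = NT_CANONICAL  # "ACGT"
AA_STATES = AA_CANONICAL  # 20 letters, alphabetical

_NT_AMBIG = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
    "-": "ACGT", "?": "ACGT",
}

MIN_BRANCH_LENGTH = 1e-8
MAX_BRANCH_LENGTH = 10.0


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

class Node:
    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.length = float(length)
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Tree:
    """A leaf-labelled tree with branch lengths (expected substitutions/site)."""

    def __init__(self, root: Node):
        self.root = root

    # -- construction ---------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dt = dendropy.Tree.get(data=newick, schema="newick")

        def convert(dnode) -> Node:
            name = dnode.taxon.label if dnode.taxon else dnode.label
            node = Node(name, dnode.edge.length or 0.0)
            for ch in dnode.child_nodes():
                node.add(convert(ch))
            return node

        return cls(convert(dt.seed_node))

    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.10g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = node.name or ""
            return f"({inner}){label}:{node.length:.10g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    def copy(self) -> "Tree":
        def dup(node: Node) -> Node:
            out = Node(node.name, node.length)
            for ch in node.children:
                out.add(dup(ch))
            return out

        return Tree(dup(self.root))

    # -- traversal ------------------------------------------------------
    def postorder(self) -> list[Node]:
        out: list[Node] = []

        def walk(node: Node) -> None:
            for ch in node.children:
                walk(ch)
            out.append(node)

        walk(self.root)
        return out

    def preorder(self) -> list[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def branches(self) -> list[Node]:
        """All nodes carrying a branch (everything but the root)."""
        return [n for n in self.postorder() if n.parent is not None]

    def find(self, name: str) -> Node:
        for n in self.postorder():
            if n.name == name:
                return n
        raise KeyError(name)

    def internal_edges(self) -> list[Node]:
        return [n for n in self.branches() if not n.is_leaf]

    def total_length(self) -> float:
        return sum(n.length for n in self.branches())


def same_topology(t1: Tree, t2: Tree) -> bool:
    """True when two trees have the same unrooted topology (RF distance 0)."""
    tns = dendropy.TaxonNamespace()
    d1 = dendropy.Tree.get(data=t1.to_newick(), schema="newick", taxon_namespace=tns)
    d2 = dendropy.Tree.get(data=t2.to_newick(), schema="newick", taxon_namespace=tns)
    d1.encode_bipartitions()
    d2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(d1, d2) == 0


# ---------------------------------------------------------------------------
# Substitution models
# ---------------------------------------------------------------------------

def discrete_gamma_rates(alpha: float, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean rates and weights of K equal-probability gamma categories.

    Uses the standard quadrature: category boundaries are gamma quantiles,
    the category rate is the conditional mean within the bin, so the
    weighted mean rate is exactly 1 for any shape ``alpha``.
    """
    if k == 1:
        return np.ones(1), np.ones(1)
    edges = stats.gamma.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    cum = special.gammainc(alpha + 1.0, alpha * edges)
    full = np.concatenate([[0.0], cum, [1.0]])
    rates = k * np.diff(full)
    weights = np.full(k, 1.0 / k)
    return rates, weights


@dataclass
class SubstitutionModel:
    """Reversible substitution model with optional discrete-gamma rates.

    ``exchangeabilities`` is a symmetric matrix with arbitrary scale and an
    ignored diagonal; the rate matrix is ``Q[i, j] = s[i, j] * pi[j]``,
    rescaled to one expected substitution per site at stationarity.
    """

    alphabet_kind: str
    exchangeabilities: np.ndarray
    freqs: np.ndarray
    gamma_shape: float | None = None
    n_categories: int = 1
    name: str = "custom"

    def __post_init__(self) -> None:
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.freqs = self.freqs / self.freqs.sum()
        self._cache: dict = {}

    # -- constructors ---------------------------------------------------
    @classmethod
    def jc69(cls, n_categories: int = 1, gamma_shape: float | None = None):
        ex = np.ones((4, 4))
        return cls("nucleotide", ex, np.full(4, 0.25), gamma_shape, n_categories, "jc69")

    @classmethod
    def hky(cls, kappa: float, freqs, n_categories: int = 1, gamma_shape: float | None = None):
        ex = np.ones((4, 4))
        ex[0, 2] = ex[2, 0] = kappa  # A<->G
        ex[1, 3] = ex[3, 1] = kappa  # C<->T
        return cls("nucleotide", ex, np.asarray(freqs, float), gamma_shape, n_categories, "hky")

    @classmethod
    def gtr(cls, rates, freqs, n_categories: int = 1, gamma_shape: float | None = None):
        """``rates``: six exchangeabilities in order AC, AG, AT, CG, CT, GT."""
        ex = np.zeros((4, 4))
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for (i, j), r in zip(pairs, rates):
            ex[i, j] = ex[j, i] = r
        return cls("nucleotide", ex, np.asarray(freqs, float), gamma_shape, n_categories, "gtr")

    @classmethod
    def poisson_aa(cls, freqs=None, n_categories: int = 1, gamma_shape: float | None = None):
        n = len(AA_STATES)
        f = np.full(n, 1.0 / n) if freqs is None else np.asarray(freqs, float)
        return cls("amino_acid", np.ones((n, n)), f, gamma_shape, n_categories, "poisson")

    # -- derived quantities ---------------------------------------------
    @property
    def states(self) -> str:
        return NT_STATES if self.alphabet_kind == "nucleotide" else AA_STATES

    @property
    def n_states(self) -> int:
        return len(self.states)

    def with_freqs(self, freqs) -> "SubstitutionModel":
        return replace(self, freqs=np.asarray(freqs, float))

    def rate_matrix(self) -> np.ndarray:
        Q = self.exchangeabilities * self.freqs[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(self.freqs * np.diag(Q)).sum()
        return Q / mu

    def _eig(self):
        if "eig" not in self._cache:
            Q = self.rate_matrix()
            rt = np.sqrt(self.freqs)
            B = (Q * rt[:, None]) / rt[None, :]
            B = (B + B.T) / 2.0
            lam, V = np.linalg.eigh(B)
            left = V / rt[:, None]
            right = V.T * rt[None, :]
            self._cache["eig"] = (lam, left, right)
        return self._cache["eig"]

    def transition_matrix(self, t: float) -> np.ndarray:
        lam, left, right = self._eig()
        P = (left * np.exp(lam * max(t, 0.0))[None, :]) @ right
        np.clip(P, 0.0, None, out=P)
        return P / P.sum(axis=1, keepdims=True)

    def transition_matrices(self, t: float, rates: np.ndarray) -> np.ndarray:
        """(K, S, S) stack of P(t * r_k), one einsum for all categories."""
        lam, left, right = self._eig()
        e = np.exp(np.outer(np.maximum(t, 0.0) * rates, lam))  # (K, S)
        P = np.einsum("ij,kj,jl->kil", left, e, right)
        np.clip(P, 0.0, None, out=P)
        return P / P.sum(axis=2, keepdims=True)

    def category_rates(self) -> tuple[np.ndarray, np.ndarray]:
        if self.n_categories == 1 or self.gamma_shape is None:
            return np.ones(1), np.ones(1)
        key = ("rates", self.gamma_shape, self.n_categories)
        if key not in self._cache:
            self._cache[key] = discrete_gamma_rates(self.gamma_shape, self.n_categories)
        return self._cache[key]


def empirical_freqs(aln: Alignment, pseudocount: float = 0.5) -> np.ndarray:
    """Stationary frequencies from pooled unambiguous residue counts."""
    states = NT_STATES if aln.alphabet_kind == "nucleotide" else AA_STATES
    counts = np.array(
        [np.count_nonzero(aln.matrix == s) for s in states], dtype=float
    )
    counts += pseudocount
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------

def _tip_row(ch: str, states: str) -> np.ndarray:
    n = len(states)
    if ch in states:
        row = np.zeros(n)
        row[states.index(ch)] = 1.0
        return row
    if states is NT_STATES or len(states) == 4:
        allowed = _NT_AMBIG.get(ch, states)
    else:
        allowed = states if ch in "X*-?" else states
    row = np.zeros(n)
    for a in allowed:
        if a in states:
            row[states.index(a)] = 1.0
    if row.sum() == 0:
        row[:] = 1.0
    return row


@dataclass
class _PatternData:
    tip_partials: dict[str, np.ndarray]  # taxon -> (P, S)
    weights: np.ndarray                  # (P,)
    site_to_pattern: np.ndarray          # (L,)

    @property
    def n_patterns(self) -> int:
        return len(self.weights)


def _compress(aln: Alignment, states: str) -> _PatternData:
    chars = sorted({c for c in np.unique(aln.matrix)})
    code = {c: i for i, c in enumerate(chars)}
    coded = np.vectorize(code.get)(aln.matrix)  # (N, L)
    patterns, site_to_pattern, counts = np.unique(
        coded.T, axis=0, return_inverse=True, return_counts=True
    )
    lut = np.array([_tip_row(c, states) for c in chars])  # (n_chars, S)
    tips = {
        name: lut[patterns[:, i]]
        for i, name in enumerate(aln.taxon_names)
    }
    return _PatternData(tips, counts.astype(float), site_to_pattern)


class LikelihoodEngine:
    """Caches pattern compression for repeated likelihood evaluations."""

    def __init__(self, aln: Alignment, model: SubstitutionModel):
        if aln.alphabet_kind != model.alphabet_kind:
            raise TaxonSetError(
                f"alignment is {aln.alphabet_kind} but model is {model.alphabet_kind}"
            )
        self.aln = aln
        self.model = model
        self.data = _compress(aln, model.states)

    def set_model(self, model: SubstitutionModel) -> None:
        self.model = model

    def _root_terms(self, tree: Tree):
        """Per-category, per-pattern log-likelihood at the root."""
        model = self.model
        rates, weights = model.category_rates()
        K, P, S = len(rates), self.data.n_patterns, model.n_states
        tips = self.data.tip_partials
        partial: dict[int, np.ndarray] = {}
        scale: dict[int, np.ndarray] = {}
        for node in tree.postorder():
            if node.is_leaf:
                if node.name not in tips:
                    raise TaxonSetError(f"tree leaf {node.name!r} not in alignment")
                continue
            prod = np.ones((K, P, S))
            logscale = np.zeros((K, P))
            for child in node.children:
                T = model.transition_matrices(child.length, rates)  # (K, S, S)
                if child.is_leaf:
                    L = tips[child.name][None, :, :]  # (1, P, S)
                else:
                    L = partial.pop(id(child))
                    logscale += scale.pop(id(child))
                prod *= np.matmul(L, np.transpose(T, (0, 2, 1)))
            m = prod.max(axis=2)
            m = np.where(m > 0, m, 1.0)
            prod /= m[:, :, None]
            logscale += np.log(m)
            partial[id(node)] = prod
            scale[id(node)] = logscale
        root = tree.root
        if root.is_leaf:
            raise ValueError("degenerate single-leaf tree")
        L = partial[id(root)]
        logscale = scale[id(root)]
        site_lik = L @ model.freqs  # (K, P)
        with np.errstate(divide="ignore"):
            logLk = np.log(site_lik) + logscale  # (K, P)
        return logLk, np.log(weights)

    def log_likelihood(self, tree: Tree) -> tuple[float, np.ndarray]:
        """Total and per-site log-likelihood."""
        logLk, logw = self._root_terms(tree)
        per_pattern = special.logsumexp(logLk + logw[:, None], axis=0)  # (P,)
        total = float(per_pattern @ self.data.weights)
        per_site = per_pattern[self.data.site_to_pattern]
        return total, per_site

    def category_posteriors(self, tree: Tree) -> np.ndarray:
        """(L, K) posterior probability of each gamma category per site."""
        logLk, logw = self._root_terms(tree)
        joint = logLk + logw[:, None]  # (K, P)
        post = np.exp(joint - special.logsumexp(joint, axis=0, keepdims=True))
        return post.T[self.data.site_to_pattern]


def log_likelihood(
    aln: Alignment, tree: Tree, model: SubstitutionModel
) -> tuple[float, np.ndarray]:
    """Felsenstein-pruning log-likelihood (total, per-site)."""
    return LikelihoodEngine(aln, model).log_likelihood(tree)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    model: SubstitutionModel
    tree: Tree
    log_likelihood: float
    converged: bool
    n_sweeps: int


def _optimize_branches(
    engine: LikelihoodEngine, tree: Tree, xatol: float = 1e-5, maxiter: int = 40
) -> float:
    best = engine.log_likelihood(tree)[0]
    for node in tree.branches():
        old = node.length

        def neg(x: float) -> float:
            node.length = x
            return -engine.log_likelihood(tree)[0]

        res = optimize.minimize_scalar(
            neg,
            bounds=(MIN_BRANCH_LENGTH, MAX_BRANCH_LENGTH),
            method="bounded",
            options={"xatol": xatol, "maxiter": maxiter},
        )
        if -res.fun >= best:
            node.length = float(res.x)
            best = -res.fun
        else:  # bounded search can stall on flat surfaces; keep previous value
            node.length = old
    return best


def fit_model(
    aln: Alignment,
    tree: Tree,
    family: str = "gtr",
    n_categories: int = 4,
    gamma_shape: float | None = 0.5,
    optimize_exchangeabilities: bool = False,
    optimize_alpha: bool = True,
    max_sweeps: int = 20,
    tol: float = 1e-6,
    branch_xatol: float = 1e-5,
) -> FitResult:
    """Fit a substitution model and branch lengths by coordinate ascent.

    Frequencies are fixed at their empirical estimates (with a small
    pseudocount); branch lengths use bounded 1-D optimisation; the gamma
    shape and, optionally, GTR exchangeabilities are optimised in turn.
    Iteration stops when a full sweep improves the log-likelihood by less
    than ``tol``; non-convergence within ``max_sweeps`` is flagged.
    """
    tree = tree.copy()
    freqs = empirical_freqs(aln)
    if family == "jc69":
        model = SubstitutionModel.jc69(n_categories, gamma_shape)
    elif family == "hky":
        model = SubstitutionModel.hky(2.0, freqs, n_categories, gamma_shape)
    elif family == "gtr":
        model = SubstitutionModel.gtr(np.ones(6), freqs, n_categories, gamma_shape)
    elif family == "poisson":
        model = SubstitutionModel.poisson_aa(freqs, n_categories, gamma_shape)
    else:
        raise ValueError(f"unknown model family {family!r}")
    if n_categories == 1:
        model = replace(model, gamma_shape=None)
        optimize_alpha = False

    engine = LikelihoodEngine(aln, model)
    prev = -np.inf
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        current = _optimize_branches(engine, tree, xatol=branch_xatol)

        if optimize_alpha:
            def neg_alpha(loga: float) -> float:
                engine.set_model(replace(engine.model, gamma_shape=float(np.exp(loga))))
                return -engine.log_likelihood(tree)[0]

            res = optimize.minimize_scalar(
                neg_alpha,
                bounds=(math.log(0.05), math.log(50.0)),
                method="bounded",
                options={"xatol": 1e-3, "maxiter": 30},
            )
            engine.set_model(replace(engine.model, gamma_shape=float(np.exp(res.x))))
            current = engine.log_likelihood(tree)[0]

        if optimize_exchangeabilities and family == "gtr":
            pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)]  # GT fixed at 1

            def neg_ex(logr: np.ndarray) -> float:
                ex = np.zeros((4, 4))
                for (i, j), r in zip(pairs, np.exp(logr)):
                    ex[i, j] = ex[j, i] = r
                ex[2, 3] = ex[3, 2] = 1.0
                engine.set_model(replace(engine.model, exchangeabilities=ex))
                return -engine.log_likelihood(tree)[0]

            cur_ex = engine.model.exchangeabilities
            x0 = np.log([max(cur_ex[i, j] / max(cur_ex[2, 3], 1e-8), 1e-6) for i, j in pairs])
            res = optimize.minimize(
                neg_ex, x0, method="L-BFGS-B", bounds=[(-7, 7)] * 5,
                options={"maxiter": 25},
            )
            neg_ex(res.x)
            current = engine.log_likelihood(tree)[0]

        if current - prev < tol:
            converged = True
            prev = current
            break
        prev = current

    return FitResult(engine.model, tree, prev, converged, sweeps)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate(
    tree: Tree,
    model: SubstitutionModel,
    n_sites: int,
    seed=None,
    branch_freq_overrides: dict[str, np.ndarray] | None = None,
    branch_rate_multipliers: dict[str, float] | None = None,
    return_info: bool = False,
):
    """Simulate an alignment along ``tree`` under ``model``.

    Sites are i.i.d.; each draws a gamma category, the root state comes from
    the stationary frequencies, and states evolve root-to-tips.  A branch
    listed in ``branch_freq_overrides`` (keyed by the name of the child node
    it leads to) evolves under a model with the override stationary
    frequencies but unchanged exchangeabilities -- composition drifts toward
    the override.  ``branch_rate_multipliers`` scale individual branch
    lengths (lineage-specific rate acceleration).
    """
    rng = _as_rng(seed)
    overrides = branch_freq_overrides or {}
    multipliers = branch_rate_multipliers or {}
    rates, weights = model.category_rates()
    K = len(rates)
    site_cat = rng.choice(K, size=n_sites, p=weights)
    states_idx = {id(tree.root): rng.choice(model.n_states, size=n_sites, p=model.freqs)}

    override_models = {
        name: model.with_freqs(f) for name, f in overrides.items()
    }
    for node in tree.preorder():
        if node.parent is None:
            continue
        parent_states = states_idx[id(node.parent)]
        m = override_models.get(node.name, model)
        t_eff = node.length * multipliers.get(node.name, 1.0)
        child_states = np.empty(n_sites, dtype=int)
        for k in range(K):
            mask = site_cat == k
            if not mask.any():
                continue
            P = m.transition_matrix(t_eff * rates[k])
            cum = P.cumsum(axis=1)
            u = rng.random(mask.sum())
            child_states[mask] = (u[:, None] > cum[parent_states[mask]]).sum(axis=1)
        states_idx[id(node)] = child_states

    leaves = tree.leaves()
    states = np.array(list(model.states))
    matrix = np.stack([states[states_idx[id(lf)]] for lf in leaves])
    aln = Alignment([lf.name for lf in leaves], matrix, model.alphabet_kind)
    if return_info:
        info = {
            "site_categories": site_cat,
            "site_rates": rates[site_cat],
            "category_rates": rates,
        }
        return aln, info
    return aln


# ---------------------------------------------------------------------------
# Gamma-category site assignment and fast-site stripping
# ---------------------------------------------------------------------------

@dataclass
class SiteRateAssignment:
    posterior: np.ndarray        # (L, K)
    category: np.ndarray         # (L,), argmax with ties to the slower category
    category_rates: np.ndarray   # (K,)
    fraction_in_fastest: float   # %


def assign_gamma_categories(
    aln: Alignment, tree: Tree, model: SubstitutionModel
) -> SiteRateAssignment:
    """Empirical-Bayes posterior over gamma rate categories per site.

    The posterior is proportional to category weight times the site
    likelihood at that category's rate.  Assignment is the posterior argmax;
    exact ties go to the slower category so downstream stripping errs on the
    side of keeping sites.
    """
    engine = LikelihoodEngine(aln, model)
    post = engine.category_posteriors(tree)
    category = post.argmax(axis=1)  # first max == slowest category on ties
    rates, _ = model.category_rates()
    frac = 100.0 * np.mean(category == len(rates) - 1)
    return SiteRateAssignment(post, category, rates, frac)


def strip_fast_sites(
    aln: Alignment, assignment: SiteRateAssignment
) -> tuple[Alignment, float]:
    """Remove sites assigned to the fastest gamma category.

    Returns the stripped alignment (partition map remapped) and the removed
    fraction in percent.  Raises if nothing would remain.
    """
    K = len(assignment.category_rates)
    keep0 = np.flatnonzero(assignment.category != K - 1)
    if keep0.size == 0:
        raise ValueError("stripping would remove every site")
    new_pm: dict[str, np.ndarray] = {}
    if aln.partition_map:
        rank = {c: i + 1 for i, c in enumerate(keep0.tolist())}
        for gene, cols in aln.partition_map.items():
            kept = [rank[c - 1] for c in cols.tolist() if (c - 1) in rank]
            new_pm[gene] = np.array(kept, dtype=int)
    out = aln.take_columns(keep0, new_pm)
    removed_fraction = 100.0 * (1.0 - keep0.size / aln.n_sites)
    return out, removed_fraction


# ---------------------------------------------------------------------------
# Distances, NJ, topology search
# ---------------------------------------------------------------------------

def jc_distance_matrix(aln: Alignment) -> np.ndarray:
    """Pairwise Jukes-Cantor distances (Poisson-corrected for amino acids)."""
    n = aln.n_taxa
    states = NT_STATES if aln.alphabet_kind == "nucleotide" else AA_STATES
    valid = np.isin(aln.matrix, list(states))
    b = len(states)
    cmax = (b - 1.0) / b
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        both = valid[i] & valid[j]
        nb = both.sum()
        p = np.mean(aln.matrix[i, both] != aln.matrix[j, both]) if nb else 0.0
        p = min(p, cmax - 1e-6)
        D[i, j] = D[j, i] = -cmax * math.log(1.0 - p / cmax)
    return D


def nj_tree(aln: Alignment) -> Tree:
    """Neighbor-joining starting tree from JC distances (via scikit-bio)."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    dm = DistanceMatrix(jc_distance_matrix(aln), ids=aln.taxon_names)
    t = nj(dm)
    tree = Tree.from_newick(str(t))
    _unroot(tree)
    for node in tree.branches():
        node.length = min(max(node.length, MIN_BRANCH_LENGTH), MAX_BRANCH_LENGTH)
    return tree


def _unroot(tree: Tree) -> None:
    """Collapse a bifurcating root into a trifurcation in place."""
    root = tree.root
    while len(root.children) == 2:
        a, b = root.children
        donor = a if not a.is_leaf else b
        if donor.is_leaf:
            return  # two-taxon tree
        keeper = b if donor is a else a
        keeper.length += donor.length
        root.children = [keeper] + donor.children
        for ch in donor.children:
            ch.parent = root


def _topology_key(tree: Tree) -> frozenset:
    """Canonical set of non-trivial bipartitions (as leaf-name frozensets)."""
    all_leaves = frozenset(tree.leaf_names())
    parts = set()

    def walk(node: Node) -> frozenset:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c in node.children))
        if node.parent is not None and 1 < len(below) < len(all_leaves) - 1:
            parts.add(min(below, all_leaves - below, key=sorted))
        return below

    walk(tree.root)
    return frozenset(parts)


def enumerate_topologies(taxa: list[str], init_length: float = 0.1) -> list[Tree]:
    """All unrooted leaf-labelled topologies (1*3*5*...*(2n-5) trees)."""
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")

    def base() -> Tree:
        root = Node()
        for t in taxa[:3]:
            root.add(Node(t, init_length))
        return Tree(root)

    trees = [base()]
    for taxon in taxa[3:]:
        grown: list[Tree] = []
        for tree in trees:
            for i, _ in enumerate(tree.branches()):
                t2 = tree.copy()
                edge = t2.branches()[i]
                parent = edge.parent
                mid = Node(None, edge.length / 2.0)
                edge.length /= 2.0
                parent.children[parent.children.index(edge)] = mid
                mid.parent = parent
                mid.add(edge)
                mid.add(Node(taxon, init_length))
                grown.append(t2)
        trees = grown
    return trees


@dataclass
class TreeSearchResult:
    tree: Tree
    log_likelihood: float
    method: str
    n_evaluated: int = 0


def _nni_neighbors(tree: Tree) -> list[Tree]:
    """Both NNI rearrangements of every internal edge."""
    out = []
    for i, edge in enumerate(tree.internal_edges()):
        if edge.parent is None or len(edge.children) < 2:
            continue
        for swap in (0, 1):
            t2 = tree.copy()
            e2 = t2.internal_edges()[i]
            parent = e2.parent
            sibs = [c for c in parent.children if c is not e2]
            if not sibs:
                continue
            sib = sibs[0]
            child = e2.children[swap]
            # swap `sib` (above the edge) with one child below it
            parent.children[parent.children.index(sib)] = child
            child.parent = parent
            e2.children[swap] = sib
            sib.parent = e2
            out.append(t2)
    return out


def ml_tree_small(
    aln: Alignment,
    model: SubstitutionModel,
    seed=None,
    max_exhaustive: int = 8,
    n_restarts: int = 2,
    branch_xatol: float = 1e-4,
    n_sweeps: int = 2,
) -> TreeSearchResult:
    """Best unrooted topology for a small alignment under a fixed model.

    Up to ``max_exhaustive`` taxa every topology is scored (branch lengths
    re-optimised per topology); for 9-12 taxa an NNI hill-climb from a
    neighbor-joining start (plus seeded random restarts) is used.
    """
    n = aln.n_taxa
    if n > 12:
        raise ValueError("ml_tree_small is limited to 12 taxa")
    engine = LikelihoodEngine(aln, model)

    def score(tree: Tree, coarse: bool = False) -> float:
        if coarse:
            return _optimize_branches(engine, tree, xatol=3e-3, maxiter=12)
        best = -np.inf
        for _ in range(n_sweeps):
            new = _optimize_branches(engine, tree, xatol=branch_xatol)
            if new - best < 1e-4:
                best = new
                break
            best = new
        return best

    if n <= max_exhaustive:
        # coarse screen of every topology, then refine the leaders
        candidates = enumerate_topologies(aln.taxon_names)
        coarse_scores = [score(t, coarse=True) for t in candidates]
        n_eval = len(candidates)
        order = np.argsort(coarse_scores)[::-1][: min(5, len(candidates))]
        best_tree, best_lnl = None, -np.inf
        for i in order:
            lnl = score(candidates[i])
            if lnl > best_lnl:
                best_tree, best_lnl = candidates[i], lnl
        best_lnl = _optimize_branches(engine, best_tree, xatol=1e-6)
        return TreeSearchResult(best_tree, best_lnl, "exhaustive", n_eval)

    rng = _as_rng(seed)
    starts = [nj_tree(aln)]
    for _ in range(n_restarts):
        order = list(aln.taxon_names)
        rng.shuffle(order)
        t = enumerate_topologies(order[:3])[0]
        for taxon in order[3:]:
            edges = t.branches()
            edge = edges[rng.integers(len(edges))]
            parent = edge.parent
            mid = Node(None, edge.length / 2)
            edge.length /= 2
            parent.children[parent.children.index(edge)] = mid
            mid.parent = parent
            mid.add(edge)
            mid.add(Node(taxon, 0.1))
        starts.append(t)

    best_tree, best_lnl, n_eval = None, -np.inf, 0
    for start in starts:
        tree = start
        lnl = score(tree)
        n_eval += 1
        improved = True
        while improved:
            improved = False
            for cand in _nni_neighbors(tree):
                cl = score(cand)
                n_eval += 1
                if cl > lnl + 1e-6:
                    tree, lnl = cand, cl
                    improved = True
                    break
        if lnl > best_lnl:
            best_tree, best_lnl = tree, lnl
    best_lnl = _optimize_branches(engine, best_tree, xatol=1e-6)
    return TreeSearchResult(best_tree, best_lnl, "nni", n_eval)
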