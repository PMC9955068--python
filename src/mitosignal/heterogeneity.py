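"""Tests for heterogeneity of the substitution process among lineages.

Two complementary diagnostics:

* the **disparity-index test** of substitution-pattern homogeneity between
  a pair of aligned sequences, with a Monte-Carlo null built by swapping
  the two observed residues at differing sites (exchangeable under the
  homogeneity hypothesis);
* a **posterior-predictive compositional test** (implemented as a
  parametric bootstrap around a fitted homogeneous model): the observed
  global statistic is the largest per-taxon compositional deviation, and
  replicate alignments simulated under the fitted model supply its null
  distribution, summarised as a Z score, a p score, and the number of taxa
  with significantly deviating composition (NDT).

Sites containing a gap or ambiguity code in either sequence of a pair are
excluded before counting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import phylo
from .errors import EmptyCompositionError
from .seqio import AA_CANONICAL, Alignment, NT_CANONICAL


# ---------------------------------------------------------------------------
# Disparity index
# ---------------------------------------------------------------------------

@dataclass
class DisparityResult:
    id_statistic: float
    p_value: float
    n_replicates: int
    n_sites_compared: int
    n_differences: int
    significant: bool
    alpha: float


def _states_for(alphabet_kind: str) -> str:
    return NT_CANONICAL if alphabet_kind == "nucleotide" else AA_CANONICAL


def _paired_arrays(x, y, alphabet_kind: str) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(list(x) if isinstance(x, str) else x, dtype="<U1")
    y = np.asarray(list(y) if isinstance(y, str) else y, dtype="<U1")
    if x.shape != y.shape:
        raise ValueError("sequences must be aligned to equal length")
    states = list(_states_for(alphabet_kind))
    ok = np.isin(x, states) & np.isin(y, states)
    if not ok.any():
        raise EmptyCompositionError("no comparable sites after exclusion")
    return x[ok], y[ok]


def _count_matrix(seq: np.ndarray, states: str) -> np.ndarray:
    return np.array([np.count_nonzero(seq == s) for s in states], dtype=float)


def disparity_index(x, y, alphabet_kind: str = "nucleotide", normalized: bool = False) -> float:
    """Raw disparity statistic ``D = 1/2 * sum_i (n_i(x) - n_i(y))^2``.

    ``normalized=True`` divides by the number of compared sites (the
    per-site scaling some implementations report); the Monte-Carlo test is
    invariant to this choice.
    """
    xs, ys = _paired_arrays(x, y, alphabet_kind)
    states = _states_for(alphabet_kind)
    d = _count_matrix(xs, states) - _count_matrix(ys, states)
    stat = 0.5 * float(np.sum(d * d))
    return stat / len(xs) if normalized else stat


def _swap_null_tail(d0: np.ndarray, deltas: np.ndarray, observed: float,
                    n_replicates: int, rng: np.random.Generator) -> int:
    """Count null replicates with statistic >= observed.

    ``d0`` is the count-difference vector with every differing site in its
    observed orientation; flipping site ``s`` adds ``deltas[s]`` (which is
    ``2*(e_b - e_a)``) to the vector.
    """
    nd = deltas.shape[0]
    count = 0
    block = max(1, min(n_replicates, int(4e7 / max(nd, 1) / deltas.shape[1])))
    done = 0
    while done < n_replicates:
        b = min(block, n_replicates - done)
        flips = rng.random((b, nd)) < 0.5
        d = d0[None, :] + flips @ deltas
        stats_rep = 0.5 * np.einsum("ij,ij->i", d, d)
        count += int(np.count_nonzero(stats_rep >= observed - 1e-12))
        done += b
    return count


def disparity_test(
    x,
    y,
    n_replicates: int = 1000,
    alpha: float = 0.01,
    seed=None,
    alphabet_kind: str = "nucleotide",
) -> DisparityResult:
    """Monte-Carlo test of substitution-pattern homogeneity for one pair.

    At each differing site the two observed residues are swapped between
    the sequences with probability 1/2, independently across sites; under
    pattern homogeneity the orientations are exchangeable, so the observed
    statistic is one draw from this null.  The p-value uses plus-one
    smoothing: ``p = (1 + #{replicates >= observed}) / (1 + n)``.
    """
    rng = phylo._as_rng(seed)
    xs, ys = _paired_arrays(x, y, alphabet_kind)
    states = _states_for(alphabet_kind)
    idx = {s: i for i, s in enumerate(states)}
    diff = xs != ys
    nd = int(diff.sum())
    d0 = _count_matrix(xs, states) - _count_matrix(ys, states)
    observed = 0.5 * float(d0 @ d0)
    if nd == 0:
        return DisparityResult(observed, 1.0, n_replicates, len(xs), 0, False, alpha)
    deltas = np.zeros((nd, len(states)))
    for row, (a, b) in enumerate(zip(xs[diff], ys[diff])):
        deltas[row, idx[a]] = -2.0
        deltas[row, idx[b]] = 2.0
    count = _swap_null_tail(d0, deltas, observed, n_replicates, rng)
    p = (1.0 + count) / (1.0 + n_replicates)
    return DisparityResult(observed, p, n_replicates, len(xs), nd, p < alpha, alpha)


def disparity_null_exact(x, y, alphabet_kind: str = "nucleotide") -> float:
    """Exact tail probability of the swap null by full enumeration.

    Feasible for up to ~16 differing sites; used as the oracle the
    Monte-Carlo test must converge to.
    """
    xs, ys = _paired_arrays(x, y, alphabet_kind)
    states = _states_for(alphabet_kind)
    idx = {s: i for i, s in enumerate(states)}
    diff = xs != ys
    nd = int(diff.sum())
    d0 = _count_matrix(xs, states) - _count_matrix(ys, states)
    observed = 0.5 * float(d0 @ d0)
    if nd == 0:
        return 1.0
    if nd > 16:
        raise ValueError("exact enumeration limited to 16 differing sites")
    deltas = np.zeros((nd, len(states)))
    for row, (a, b) in enumerate(zip(xs[diff], ys[diff])):
        deltas[row, idx[a]] = -2.0
        deltas[row, idx[b]] = 2.0
    count = 0
    for flips in itertools.product((0, 1), repeat=nd):
        d = d0 + np.asarray(flips, dtype=float) @ deltas
        if 0.5 * float(d @ d) >= observed - 1e-12:
            count += 1
    return count / 2**nd


# ---------------------------------------------------------------------------
# Pairwise summary (per-gene table machinery)
# ---------------------------------------------------------------------------

@dataclass
class PairwiseHeterogeneitySummary:
    gene: str
    n_pairs_total: int
    n_pairs_significant: int
    proportion_significant: float  # %
    alpha: float


def pairwise_heterogeneity_matrix(
    aln: Alignment,
    gene: str | None = None,
    n_replicates: int = 1000,
    alpha: float = 0.01,
    seed=None,
) -> tuple[PairwiseHeterogeneitySummary, pd.DataFrame]:
    """Disparity test over all C(n,2) taxon pairs of one gene (or all columns).

    Returns the per-gene summary row (count and percentage of significant
    pairs) and the full pairwise table.
    """
    rng = phylo._as_rng(seed)
    sub = aln.gene(gene) if gene else aln
    n = sub.n_taxa
    if n < 2:
        raise ValueError("need at least 2 taxa")
    rows = []
    n_sig = 0
    for i, j in itertools.combinations(range(n), 2):
        res = disparity_test(
            sub.matrix[i], sub.matrix[j], n_replicates, alpha, rng, sub.alphabet_kind
        )
        n_sig += int(res.significant)
        rows.append(
            {
                "taxon_1": sub.taxon_names[i],
                "taxon_2": sub.taxon_names[j],
                "id_statistic": res.id_statistic,
                "p_value": res.p_value,
                "n_differences": res.n_differences,
                "significant": res.significant,
            }
        )
    table = pd.DataFrame(rows)
    n_pairs = len(rows)
    summary = PairwiseHeterogeneitySummary(
        gene or "all", n_pairs, n_sig, 100.0 * n_sig / n_pairs, alpha
    )
    return summary, table


# ---------------------------------------------------------------------------
# Posterior-predictive compositional test
# ---------------------------------------------------------------------------

@dataclass
class PPAResult:
    z_score: float
    p_score: float
    ndt: int
    per_taxon_deviation: pd.DataFrame
    observed_statistic: float
    null_mean: float
    null_sd: float
    n_simulations: int


def _per_taxon_deviation(aln: Alignment, states: str) -> np.ndarray:
    """d_t = sum_i |f_i(taxon t) - f_i(pooled)| over unambiguous residues."""
    counts = np.stack(
        [
            np.array([np.count_nonzero(row == s) for s in states], dtype=float)
            for row in aln.matrix
        ]
    )
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    freqs = counts / totals
    pooled = counts.sum(axis=0) / counts.sum()
    return np.abs(freqs - pooled[None, :]).sum(axis=1)


def compositional_ppa(
    aln: Alignment,
    tree: phylo.Tree,
    model: phylo.SubstitutionModel,
    n_sim: int = 1000,
    seed=None,
    taxon_alpha: float = 0.05,
) -> PPAResult:
    """Posterior-predictive check of compositional homogeneity.

    The global statistic is the maximum per-taxon compositional deviation
    ``max_t d_t``.  ``n_sim`` replicate alignments of the same size are
    simulated on ``tree`` under the fitted homogeneous ``model`` (a
    parametric-bootstrap stand-in for draws from a posterior);
    ``Z = (obs - mean_sim)/sd_sim`` and ``p`` is the fraction of replicates
    at least as extreme.  NDT counts taxa whose observed ``d_t`` exceeds
    the ``1 - taxon_alpha`` quantile of their own simulated deviations.
    """
    rng = phylo._as_rng(seed)
    states = _states_for(aln.alphabet_kind)
    order = list(aln.taxon_names)
    obs_dev = _per_taxon_deviation(aln, states)
    observed = float(obs_dev.max())

    sim_dev = np.empty((n_sim, aln.n_taxa))
    for s in range(n_sim):
        sim = phylo.simulate(tree, model, aln.n_sites, seed=rng)
        idx = [sim.taxon_names.index(t) for t in order]
        sim_dev[s] = _per_taxon_deviation(sim, states)[idx]
    sim_global = sim_dev.max(axis=1)
    mean, sd = float(sim_global.mean()), float(sim_global.std(ddof=1))
    z = (observed - mean) / sd if sd > 0 else float("nan")
    p = float(np.mean(sim_global >= observed))
    cutoffs = np.quantile(sim_dev, 1.0 - taxon_alpha, axis=0)
    flagged = obs_dev > cutoffs
    per_taxon = pd.DataFrame(
        {
            "taxon": order,
            "deviation": obs_dev,
            "cutoff": cutoffs,
            "deviating": flagged,
        }
    )
    return PPAResult(
        z_score=z,
        p_score=p,
        ndt=int(flagged.sum()),
        per_taxon_deviation=per_taxon,
        observed_statistic=observed,
        null_mean=mean,
        null_sd=sd,
        n_simulations=n_sim,
    )
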