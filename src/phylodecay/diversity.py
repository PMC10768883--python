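"""Diversity-decay metrics for single-cell phylogenies.

Two raw tree-shape statistics -- Colless imbalance (pi) and the tip
count (n) -- both scale with how many cells were sampled.  The decay
metrics standardize them against their values on the *ancestral* tree,
obtained by cropping the phylogeny at the depth where the embryonic
burst of lineage diversification ended:

    alpha = log2(pi / pi_a)      beta = log2(n / n_a)

Both are 0 for an individual whose contemporary tree still equals the
embryonic tree (no post-embryonic branching, no lineage displacement)
and grow as subclonal expansions displace ancestral lineages.  Base-2
logarithms are used because lineage branching is a doubling process.

When the ancestral tree retains fewer than 4 lineages its imbalance is
not meaningfully defined, and ``pi_a`` is treated as 1 (log2 = 0) so
that ancestral imbalance is the smallest possible.
"""

from __future__ import annotations

import dataclasses
import math

from .tree import (
    AncestralTree,
    Phylogeny,
    TreeError,
    compute_ltt,
    crop_at,
    detect_inflection,
    prune_germline,
)

__all__ = [
    "DiversityResult",
    "colless",
    "alpha_metric",
    "beta_metric",
    "diversity_metrics",
    "shannon_index",
]


@dataclasses.dataclass(frozen=True)
class DiversityResult:
    """Raw and standardized diversity statistics for one phylogeny."""

    pi: int          # contemporary Colless imbalance
    pi_a: int        # ancestral imbalance (raw; see alpha for the floor)
    n: int           # sampled lineage (tip) count
    n_a: int         # ancestral lineages crossing the crop depth
    alpha: float     # log2(pi / pi_a), floored and clamped at 0
    beta: float      # log2(n / n_a), >= 0 since n_a <= n
    t_a: float       # crop depth used (SNA units)


def colless(phylo: Phylogeny) -> int:
    """Colless imbalance: sum over internal nodes of |left - right| clade size.

    Polytomies are resolved deterministically into a caterpillar of
    zero-length branches with children ordered by descendant tip count
    (largest first; ties broken by smallest tip label), which leaves
    depths and the LTT curve unchanged.
    """
    if phylo.n_tips < 2:
        raise TreeError("Colless imbalance requires at least 2 tips")
    size: dict = {}
    minlab: dict = {}
    score: dict = {}
    for node in phylo._tree.postorder_node_iter():
        if node.is_leaf():
            size[node] = 1
            minlab[node] = node.taxon.label
            score[node] = 0
            continue
        children = sorted(
            node.child_nodes(), key=lambda c: (-size[c], minlab[c])
        )
        sizes = [size[c] for c in children]
        total = sum(sizes)
        contrib = 0
        remaining = total
        # caterpillar resolution: node(c1, node(c2, ... node(c_{m-1}, c_m)))
        for s in sizes[:-1]:
            remaining -= s
            contrib += abs(s - remaining)
        size[node] = total
        minlab[node] = min(minlab[c] for c in children)
        score[node] = contrib + sum(score[c] for c in children)
    return int(score[phylo._tree.seed_node])


def _floored_pi_a(pi_a: int, n_a: int) -> int:
    return 1 if n_a < 4 else max(pi_a, 1)


@dataclasses.dataclass(frozen=True)
class AlphaResult:
    alpha: float
    pi: int
    pi_a: int
    n_a: int
    ancestral: AncestralTree


@dataclasses.dataclass(frozen=True)
class BetaResult:
    beta: float
    n: int
    n_a: int
    ancestral: AncestralTree


def alpha_metric(phylo: Phylogeny, t_a: float) -> AlphaResult:
    """Standardized imbalance decay at crop depth ``t_a``."""
    anc = crop_at(phylo, t_a)
    pi = colless(phylo)
    pi_a = colless(anc.tree) if anc.n_a >= 2 else 0
    alpha = max(
        0.0, math.log2(max(pi, 1)) - math.log2(_floored_pi_a(pi_a, anc.n_a))
    )
    return AlphaResult(alpha=alpha, pi=pi, pi_a=pi_a, n_a=anc.n_a, ancestral=anc)


def beta_metric(phylo: Phylogeny, t_a: float) -> BetaResult:
    """Standardized lineage-count decay at crop depth ``t_a``."""
    anc = crop_at(phylo, t_a)
    n = phylo.n_tips
    beta = math.log2(n) - math.log2(anc.n_a)
    return BetaResult(beta=beta, n=n, n_a=anc.n_a, ancestral=anc)


def diversity_metrics(
    phylo: Phylogeny,
    *,
    germline: str | None = None,
    crop_depth: float | None = None,
) -> DiversityResult:
    """Compute pi, n, alpha and beta for one phylogeny.

    Parameters
    ----------
    phylo:
        The contemporary cell phylogeny (SNA branch lengths).
    germline:
        Optional label of a germline outgroup tip, pruned before any
        statistic is computed.  The stem connecting the remaining tree
        to the germline root is kept, so subclone-only trees still crop
        to a single ancestral lineage.
    crop_depth:
        Fixed crop depth in SNA units; by default the end of the
        embryonic burst is detected from the LTT curve.
    """
    if germline is not None:
        phylo = prune_germline(phylo, germline)
    if phylo.n_tips < 2:
        raise TreeError("diversity metrics require at least 2 tips")
    ltt = compute_ltt(phylo)
    if crop_depth is None:
        t_a = detect_inflection(ltt)
    else:
        t_a = float(crop_depth)
        if not (0 < t_a <= ltt.max_depth):
            raise TreeError(
                f"crop depth must lie in (0, {ltt.max_depth:g}]"
            )
    a = alpha_metric(phylo, t_a)
    b = beta_metric(phylo, t_a)
    return DiversityResult(
        pi=a.pi, pi_a=a.pi_a, n=b.n, n_a=b.n_a,
        alpha=a.alpha, beta=b.beta, t_a=t_a,
    )


def shannon_index(phylo: Phylogeny, t_a: float) -> float:
    """Shannon diversity of tips across ancestral lineages (descriptive only).

    This statistic is *not* part of the phyloAge model; it is provided
    as an optional description of how evenly sampled cells distribute
    over the ancestral lineages crossing the crop depth.
    """
    anc = crop_at(phylo, t_a)
    counts: dict[str, int] = {}
    for lineage in anc.tip_to_lineage.values():
        counts[lineage] = counts.get(lineage, 0) + 1
    total = sum(counts.values())
    return -sum((c / total) * math.log(c / total) for c in counts.values())
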