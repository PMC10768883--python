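"""Rooted somatic-mutation phylogenies and tree-level operations.

Trees here describe the ancestry of single cells (HSC-derived colonies)
sampled from one individual.  Branch lengths are counts of somatic single
nucleotide alterations (SNAs) accumulated along a lineage, so a node's
depth -- its path length from the root -- is molecular time, not calendar
time.  No calendar-time calibration happens anywhere in this module.

The module provides:

* :class:`Phylogeny` -- a thin, validated wrapper around a dendropy tree;
* Newick reading/writing (:func:`read_newick`, :func:`write_newick`);
* lineages-through-time curves (:func:`compute_ltt`);
* detection of the depth at which the early (embryonic) burst of lineage
  diversification ends (:func:`detect_inflection`);
* level-cropping of a tree at a given depth (:func:`crop_at`), producing
  the ancestral tree whose tips are the lineages crossing that depth;
* random tip subsampling (:func:`subsample_tips`) and germline-outgroup
  pruning (:func:`prune_germline`).
"""

from __future__ import annotations

import dataclasses
import math

import dendropy
import numpy as np

__all__ = [
    "NewickParseError",
    "TreeError",
    "Phylogeny",
    "LTTCurve",
    "AncestralTree",
    "read_newick",
    "read_newick_file",
    "write_newick",
    "compute_ltt",
    "detect_inflection",
    "crop_at",
    "subsample_tips",
    "prune_germline",
    "patristic_distance",
]

_FMT = ".12g"  # branch-length format; round-trips to ~1e-12 relative


def _fmt(x: float) -> str:
    return format(float(x), _FMT)


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class TreeError(ValueError):
    """Raised for structurally invalid trees or invalid tree operations."""


class Phylogeny:
    """A rooted cell phylogeny with SNA-count branch lengths.

    Invariants enforced at construction: a single root, unique non-empty
    tip labels, and non-negative branch lengths on every non-root edge.
    Polytomies and zero-length branches are permitted.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        if tree.seed_node.edge.length is None:
            tree.seed_node.edge.length = 0.0
        self._validate()

    # -- validation ---------------------------------------------------
    def _validate(self) -> None:
        labels = []
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise TreeError("every tip must carry a label")
            labels.append(leaf.taxon.label)
        if len(set(labels)) != len(labels):
            seen, dups = set(), set()
            for lab in labels:
                (dups if lab in seen else seen).add(lab)
            raise TreeError(f"duplicate tip labels: {sorted(dups)}")
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            if node.edge.length is None:
                raise TreeError(
                    "branch without a length; re-read the tree with "
                    "default_branch_length=0 to permit this"
                )
            if node.edge.length < 0:
                raise TreeError(f"negative branch length {node.edge.length}")

    # -- basic properties ---------------------------------------------
    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    def node_depths(self) -> dict:
        """Map every node to its SNA depth from the root (root = 0)."""
        depths: dict = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                depths[node] = 0.0
            else:
                depths[node] = depths[node.parent_node] + node.edge.length
        return depths

    def tip_depths(self) -> dict[str, float]:
        depths = self.node_depths()
        return {
            lf.taxon.label: depths[lf] for lf in self._tree.leaf_node_iter()
        }

    @property
    def max_depth(self) -> float:
        return max(self.tip_depths().values())

    def copy(self) -> "Phylogeny":
        return Phylogeny(self._tree.clone(depth=1))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Phylogeny with {self.n_tips} tips, depth {self.max_depth:g}>"


# ---------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------

def read_newick(text: str, *, default_branch_length: float | None = None) -> Phylogeny:
    """Parse a single Newick tree from a string.

    Branch lengths are required on all non-root edges unless
    ``default_branch_length`` is given, in which case missing lengths are
    filled with that value (typically 0).
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several tokenizer subclasses
        raise NewickParseError(f"malformed Newick input: {exc}") from exc
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.edge.length is None:
            if default_branch_length is None:
                raise NewickParseError(
                    "branch without a length; pass default_branch_length=0 "
                    "to accept topology-only edges"
                )
            node.edge.length = float(default_branch_length)
    return Phylogeny(tree)


def read_newick_file(path, **kwargs) -> Phylogeny:
    """Read a single Newick tree from a file (one tree per file)."""
    try:
        with open(path) as fh:
            text = fh.read()
    except OSError as exc:
        raise NewickParseError(f"cannot read tree file {path}: {exc}") from exc
    return read_newick(text, **kwargs)


def write_newick(phylo: Phylogeny) -> str:
    """Serialize to Newick, preserving branch lengths to ~1e-12 relative."""
    root_edge = phylo._tree.seed_node.edge
    saved = root_edge.length
    try:
        root_edge.length = None  # the root has no parent branch
        s = phylo._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=_FMT,
        )
    finally:
        root_edge.length = saved
    return s.strip()


# ---------------------------------------------------------------------
# Lineages-through-time
# ---------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class LTTCurve:
    """Cumulative lineage count versus molecular depth.

    ``depths`` holds one entry per branching node (a multifurcation of
    ``c`` children appears once and raises the count by ``c - 1``);
    ``counts[i]`` is the number of lineages present just after the i-th
    branching event.  ``max_depth`` is the deepest root-to-tip depth and
    bounds any crop depth derived from the curve.
    """

    depths: np.ndarray
    counts: np.ndarray
    max_depth: float

    def __post_init__(self):
        d = np.asarray(self.depths, dtype=float)
        c = np.asarray(self.counts, dtype=int)
        if d.shape != c.shape or d.ndim != 1 or d.size == 0:
            raise TreeError("LTT curve needs matching 1-D depth/count arrays")
        if np.any(np.diff(d) < 0) or np.any(np.diff(c) < 0):
            raise TreeError("LTT depths and counts must be non-decreasing")
        object.__setattr__(self, "depths", d)
        object.__setattr__(self, "counts", c)

    @property
    def n_events(self) -> int:
        """Total unit branching events (= final lineage count - 1)."""
        return int(self.counts[-1]) - 1

    def unit_event_depths(self) -> np.ndarray:
        """Depths with one entry per unit event (multifurcations expanded)."""
        jumps = np.diff(np.concatenate(([1], self.counts)))
        return np.repeat(self.depths, jumps)


def compute_ltt(phylo: Phylogeny) -> LTTCurve:
    """Build the lineages-through-time curve of a phylogeny."""
    if phylo.n_tips < 2:
        raise TreeError("LTT curve requires at least 2 tips")
    depths = phylo.node_depths()
    events = []
    for node in phylo._tree.preorder_node_iter():
        nchild = len(node.child_nodes())
        if nchild >= 2:
            events.append((depths[node], nchild))
    events.sort(key=lambda e: e[0])
    d, c, running = [], [], 1
    for depth, nchild in events:
        running += nchild - 1
        d.append(depth)
        c.append(running)
    return LTTCurve(np.asarray(d), np.asarray(c), float(phylo.max_depth))


# ---------------------------------------------------------------------
# Inflection (end of the embryonic diversification burst)
# ---------------------------------------------------------------------

def _seg_loglik(b: float, L: float) -> float:
    # Poisson-process profile log-likelihood term B*log(B/L) (additive
    # constant -B dropped); conventions: no events -> 0, events in zero
    # lineage-time -> +inf (instantaneous burst).
    if b == 0:
        return 0.0
    if L <= 0:
        return math.inf
    return b * math.log(b / L)


def detect_inflection(ltt: LTTCurve, *, min_events: int = 4) -> float:
    """Depth at which the initial burst of lineage diversification ends.

    Branching is modelled as a pure-birth process.  For every candidate
    changepoint (an observed branching depth), the score is the
    log-likelihood ratio of "diversification ceased here" against "the
    branching rate observed so far continued", evaluated on the
    event-free interval that follows the candidate:

        score(c) = rate_before(c) * eventfree_lineage_time_after(c)

    where ``rate_before`` is the per-lineage branching rate over all
    events up to the candidate, and the event-free lineage time runs to
    the next branching event (or, for the last event, to the tips).
    The maximizing event marks the end of the embryonic burst: its
    following lull is the most surprising given the branching intensity
    that preceded it.  This stays put under tip subsampling and under
    renewed late branching from subclonal expansions, both of which only
    dilute rates elsewhere in the tree.

    The returned depth sits immediately after the selected event, so a
    crop there keeps the whole burst on the ancestral side.  Trees with
    fewer than ``min_events`` branching events fall back to the deepest
    branching depth.
    """
    e = ltt.unit_event_depths()
    E = len(e)
    D = float(ltt.max_depth)
    eps = 1e-9 * max(1.0, D)

    def _after(depth: float) -> float:
        return min(depth + eps, D)

    if E < min_events:
        return _after(float(e[-1]))

    # lineage-time prefix: L[m] = integral of lineage count from depth 0
    # to e[m] (k = i+1 lineages between unit events i and i+1; 1 lineage
    # before the first event).
    bounds = np.concatenate(([0.0], e))
    k = np.arange(1, E + 1, dtype=float)
    L = np.concatenate(([0.0], np.cumsum(k * np.diff(bounds))))  # L[0..E]
    L_total = L[E] + (E + 1) * max(0.0, D - e[-1])

    if L[E] <= 0:  # every branching at depth 0: instantaneous burst
        return _after(0.0)

    # Candidates are boundaries between distinct depths.  The rate
    # behind a candidate is smoothed with a small lineage-time
    # pseudo-count so that a burst represented by very few surviving
    # ancestral lineages (heavily displaced trees) still yields a
    # finite, comparable rate.
    tau = L_total / (E + 1) ** 2
    best_score, best_c = -math.inf, E
    for c in range(1, E + 1):
        if c < E and e[c] <= e[c - 1]:
            continue
        rate = c / (L[c] + tau)
        gap = (L_total - L[c]) if c == E else (L[c + 1] - L[c])
        score = rate * gap
        if score > best_score:
            best_score, best_c = score, c
    return _after(float(e[best_c - 1]))


# ---------------------------------------------------------------------
# Level-cropping
# ---------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class AncestralTree:
    """Result of cropping a phylogeny at depth ``depth``.

    ``tree`` has one tip per lineage crossing the crop depth; ``n_a`` is
    that tip count; ``tip_to_lineage`` maps every sampled tip label of
    the original tree to the label of its ancestral lineage.  Tips of the
    original tree shallower than the crop depth count as their own
    crossing lineage.
    """

    tree: Phylogeny
    n_a: int
    depth: float
    tip_to_lineage: dict[str, str]


def crop_at(phylo: Phylogeny, t: float) -> AncestralTree:
    """Crop a phylogeny at molecular depth ``t``.

    A branch (u, v) crosses the crop iff depth(u) < t <= depth(v); each
    crossing branch becomes one tip of the ancestral tree, truncated at
    depth ``t``.  The topology induced among crossing lineages is
    preserved.
    """
    if not (t > 0):
        raise TreeError("crop depth must be strictly positive")
    depths = phylo.node_depths()
    max_depth = phylo.max_depth
    if t > max_depth:
        raise TreeError(
            f"crop depth {t:g} exceeds deepest tip depth {max_depth:g}"
        )

    tip_map: dict[str, str] = {}
    leaf_frag: dict = {}  # original node -> newick fragment for new leaf
    anc_idx = 0
    for node in phylo._tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        d_u, d_v = depths[parent], depths[node]
        if d_u < t <= d_v:  # crossing branch -> ancestral tip
            if node.is_leaf():
                label = node.taxon.label
            else:
                label = f"anc{anc_idx}"
                anc_idx += 1
            leaf_frag[node] = f"{label}:{_fmt(t - d_u)}"
            for lf in node.leaf_iter():
                tip_map[lf.taxon.label] = label
        elif node.is_leaf() and d_v < t:  # shallow tip: its own lineage
            leaf_frag[node] = f"{node.taxon.label}:{_fmt(node.edge.length)}"
            tip_map[node.taxon.label] = node.taxon.label

    frags: dict = {}
    for node in phylo._tree.postorder_node_iter():
        if node in leaf_frag:
            frags[node] = leaf_frag[node]
            continue
        if depths[node] >= t:  # strictly below the crop; already absorbed
            continue
        if node.is_leaf():  # depth == t handled above; cannot reach here
            frags[node] = leaf_frag[node]
            continue
        parts = [frags[ch] for ch in node.child_nodes() if ch in frags]
        inner = "(" + ",".join(parts) + ")"
        if node.parent_node is None:
            frags[node] = inner
        else:
            frags[node] = f"{inner}:{_fmt(node.edge.length)}"
    root_frag = frags[phylo._tree.seed_node]
    cropped = read_newick(root_frag + ";")
    return AncestralTree(
        tree=cropped, n_a=cropped.n_tips, depth=float(t), tip_to_lineage=tip_map
    )


# ---------------------------------------------------------------------
# Pruning / subsampling
# ---------------------------------------------------------------------

def _prune_to_tips(phylo: Phylogeny, keep: set[str]) -> Phylogeny:
    """Retain only the given tips, merging unifurcations' branch lengths.

    If the pruned root has a single child, the stem to the remaining
    subtree is preserved (a unary root), so depth from the original root
    is kept -- this matters when the retained tips are all subclonal and
    connect to the germline reference through a long stem.
    """
    frags: dict = {}
    for node in phylo._tree.postorder_node_iter():
        if node.is_leaf():
            if node.taxon.label in keep:
                frags[node] = (node.taxon.label, float(node.edge.length or 0.0))
            continue
        kept = [frags[ch] for ch in node.child_nodes() if ch in frags]
        if not kept:
            continue
        length = float(node.edge.length or 0.0)
        if len(kept) == 1:
            sub, sub_len = kept[0]
            frags[node] = (sub, sub_len + length)
        else:
            inner = "(" + ",".join(f"{s}:{_fmt(l)}" for s, l in kept) + ")"
            frags[node] = (inner, length)
    root = phylo._tree.seed_node
    if root not in frags:
        raise TreeError("no tips retained")
    sub, sub_len = frags[root]
    if not sub.startswith("("):
        raise TreeError("pruning left fewer than 2 tips")
    if sub_len > 0:
        text = f"({sub}:{_fmt(sub_len)});"
    else:
        text = sub + ";"
    return read_newick(text)


def subsample_tips(phylo: Phylogeny, fraction: float, seed: int) -> Phylogeny:
    """Randomly retain ``max(2, round(fraction * n))`` tips.

    Rounding is half-away-from-zero; ``fraction=1.0`` returns an exact
    copy.  Sampling is uniform without replacement and reproducible for
    a given seed.  Pairwise path lengths among retained tips are
    unchanged; unifurcations created by pruning are suppressed with
    their branch lengths merged.
    """
    if not (0 < fraction <= 1):
        raise TreeError("fraction must be in (0, 1]")
    n = phylo.n_tips
    if n < 2:
        raise TreeError("subsampling requires at least 2 tips")
    if fraction == 1.0:
        return phylo.copy()
    k = max(2, int(math.floor(fraction * n + 0.5)))
    labels = sorted(phylo.tip_labels)
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=min(k, n), replace=False)
    keep = {labels[i] for i in idx}
    return _prune_to_tips(phylo, keep)


def prune_germline(phylo: Phylogeny, label: str) -> Phylogeny:
    """Remove a germline/outgroup tip before metric computation."""
    labels = set(phylo.tip_labels)
    if label not in labels:
        raise TreeError(f"germline tip {label!r} not found in tree")
    if len(labels) - 1 < 2:
        raise TreeError("pruning the germline would leave fewer than 2 tips")
    return _prune_to_tips(phylo, labels - {label})


def patristic_distance(phylo: Phylogeny, a: str, b: str) -> float:
    """Path length (in SNA units) between two tips."""
    depths = phylo.node_depths()
    nodes = {lf.taxon.label: lf for lf in phylo._tree.leaf_node_iter()}
    try:
        na, nb = nodes[a], nodes[b]
    except KeyError as exc:
        raise TreeError(f"unknown tip label {exc}") from exc
    anc_a = []
    node = na
    while node is not None:
        anc_a.append(node)
        node = node.parent_node
    anc_a_set = set(id(x) for x in anc_a)
    node = nb
    while id(node) not in anc_a_set:
        node = node.parent_node
    mrca = node
    return (depths[na] - depths[mrca]) + (depths[nb] - depths[mrca])
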