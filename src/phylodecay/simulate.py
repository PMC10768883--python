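"""Synthetic HSC phylogenies, genotype matrices and cohorts.

The generator reproduces the qualitative life history of the human HSC
pool as seen in single-cell phylogenies:

* an embryonic pure-birth burst that establishes ``n_founders`` lineages
  within the first ``t_emb`` somatic mutations;
* near-quiescent adult accumulation, with total root-to-tip mutation
  depth following the quadratic somatic clock
  ``M(age) = quad * age^2 + slope * age`` (Poisson-realized per branch);
* optional subclonal expansions (CHIP-like events): from a calendar
  onset age, one founder lineage spawns a within-clone birth process
  whose cells displace ancestral lineages *through sampling* -- clones
  contribute many cells, so a fixed-size sample of cells contains fewer
  distinct founders.

Branch lengths are mutation counts; calendar age enters only through
the clock map.  Every output is bit-reproducible for a fixed seed, and
truth labels record each sampled cell's founder lineage and expansion
membership.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .diversity import diversity_metrics
from .tree import Phylogeny, read_newick, _fmt

__all__ = [
    "Expansion",
    "SimConfig",
    "simulate_phylogeny",
    "simulate_sna_matrix",
    "simulate_marker_cohort",
    "simulate_cohort",
    "HEALTHY_ADULT_AGES",
]

# default healthy-adult sampling ages spanning the adult lifespan
HEALTHY_ADULT_AGES = (25.0, 29.0, 38.0, 48.0, 63.0, 75.0, 76.0, 81.0)


@dataclasses.dataclass(frozen=True)
class Expansion:
    """A subclonal (CHIP-like) expansion of one founder lineage."""

    onset_age: float               # calendar years
    growth_rate: float = 0.35      # clone divisions per year
    source: int | None = None      # founder index; None -> drawn at random
    mut_rate_multiplier: float = 1.0


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one synthetic individual."""

    age: float                        # calendar years at sampling
    n_founders: int = 100             # lineages established in the burst
    t_emb: float = 30.0               # embryonic burst span, SNA units
    quad: float = 0.06                # clock curvature, SNAs / yr^2
    slope: float = 12.43              # clock slope, SNAs / yr
    expansions: tuple[Expansion, ...] = ()
    sample_size: int = 50             # cells sampled into the phylogeny
    missing_rate: float = 0.0         # genotype missing-call rate
    max_clone_cells: int = 2000       # cap on cells per expansion clone
    neutral_split_rate: float = 0.003  # symmetric divisions / lineage / yr
    seed: int = 0

    def validate(self) -> None:
        if self.n_founders < 2:
            raise ValueError("n_founders must be >= 2")
        if self.t_emb <= 0:
            raise ValueError("t_emb must be positive")
        if self.sample_size < 2:
            raise ValueError("sample_size must be >= 2")
        if not (0 <= self.missing_rate <= 1):
            raise ValueError("missing_rate must be in [0, 1]")
        if self.age < 0 or self.quad < 0 or self.slope < 0:
            raise ValueError("age and clock coefficients must be >= 0")
        if self.neutral_split_rate < 0:
            raise ValueError("neutral_split_rate must be >= 0")
        for e in self.expansions:
            if e.onset_age >= self.age:
                raise ValueError(
                    f"expansion onset {e.onset_age} is not before the "
                    f"sampling age {self.age}"
                )
            if e.growth_rate < 0 or e.mut_rate_multiplier < 0:
                raise ValueError("expansion rates must be >= 0")

    def clock(self, t: float) -> float:
        """Expected total SNAs accumulated by calendar age t (years)."""
        return self.quad * t * t + self.slope * t

    def depth_at(self, t: float) -> float:
        """Expected mutation depth of a lineage at calendar age t."""
        return max(self.t_emb, self.clock(t))


class _SimNode:
    __slots__ = ("length", "children", "name", "founder", "expansion")

    def __init__(self, length=0.0, name=None, founder=None, expansion=None):
        self.length = float(length)
        self.children: list[_SimNode] = []
        self.name = name
        self.founder = founder
        self.expansion = expansion


def _newick(root: _SimNode) -> str:
    # iterative serialization (clone subtrees can be deep)
    parts: list[str] = []
    stack: list[tuple[str, object]] = [("node:root", root)]
    while stack:
        kind, obj = stack.pop()
        if kind == "text":
            parts.append(obj)  # type: ignore[arg-type]
            continue
        node: _SimNode = obj  # type: ignore[assignment]
        suffix = "" if kind == "node:root" else ":" + _fmt(node.length)
        if not node.children:
            parts.append((node.name or "") + suffix)
            continue
        parts.append("(")
        stack.append(("text", ")" + suffix))
        for idx in range(len(node.children) - 1, -1, -1):
            stack.append(("node", node.children[idx]))
            if idx > 0:
                stack.append(("text", ","))
    return "".join(parts) + ";"


def _yule_burst(n_founders: int, t_emb: float, rng) -> tuple[_SimNode, list[_SimNode]]:
    """Pure-birth burst to n_founders lineages, rescaled to span t_emb.

    Returns the root and the founder tips, each of which sits at depth
    exactly t_emb (pendant branches are extended to the end of the
    burst, so all founders are contemporaneous in mutation time).
    """
    root = _SimNode(length=0.0)
    if n_founders == 2:
        times = np.array([0.0])
    else:
        waits = rng.exponential(1.0 / np.arange(2, n_founders))
        times = np.concatenate(([0.0], np.cumsum(waits)))
        times = times * (t_emb / times[-1])
    active: list[tuple[_SimNode, float]] = [(root, 0.0)]
    for t in times:
        i = int(rng.integers(len(active)))
        node, birth = active.pop(i)
        node.length += t - birth
        left, right = _SimNode(), _SimNode()
        node.children = [left, right]
        active.append((left, t))
        active.append((right, t))
    founders = []
    for node, birth in active:
        node.length += t_emb - birth
        founders.append(node)
    return root, founders


def _grow_clone(cfg: SimConfig, exp_idx: int, exp: Expansion,
                founder_idx: int, attach: _SimNode, rng) -> list[_SimNode]:
    """Calendar-time Yule growth of one clone from onset to sampling age.

    Edge mutation lengths are Poisson with mean
    mut_rate_multiplier * (clock depth difference across the edge).
    """
    def seg_mutations(t0: float, t1: float) -> int:
        mean = exp.mut_rate_multiplier * max(
            0.0, cfg.depth_at(t1) - cfg.depth_at(t0)
        )
        return int(rng.poisson(mean))

    clone_root = _SimNode(
        length=rng.poisson(max(0.0, cfg.depth_at(exp.onset_age) - cfg.t_emb))
    )
    attach.children = [clone_root]
    active: list[tuple[_SimNode, float]] = [(clone_root, exp.onset_age)]
    t = exp.onset_age
    if exp.growth_rate > 0:
        while len(active) < cfg.max_clone_cells:
            t = t + rng.exponential(1.0 / (len(active) * exp.growth_rate))
            if t >= cfg.age:
                break
            i = int(rng.integers(len(active)))
            node, birth = active.pop(i)
            node.length += seg_mutations(birth, t)
            left, right = _SimNode(), _SimNode()
            node.children = [left, right]
            active.append((left, t))
            active.append((right, t))
    tips = []
    for node, birth in active:
        node.length += seg_mutations(birth, cfg.age)
        node.founder = founder_idx
        node.expansion = exp_idx
        tips.append(node)
    return tips


def _extend_founder(cfg: SimConfig, f_idx: int, node: _SimNode, rng) -> list[_SimNode]:
    """Adult extension of a non-expanded founder lineage.

    Rare symmetric self-renewal divisions (rate ``neutral_split_rate``
    per lineage-year, both daughters persisting) give young trees their
    occasional post-embryonic divergences without any growth advantage.
    """
    n_splits = int(rng.poisson(cfg.neutral_split_rate * cfg.age))
    if n_splits == 0:
        node.length += rng.poisson(max(0.0, cfg.clock(cfg.age) - cfg.t_emb))
        node.founder = f_idx
        node.expansion = -1
        return [node]
    times = np.sort(rng.uniform(0.0, cfg.age, size=n_splits))
    cells: list[_SimNode] = []
    cur, prev_t = node, 0.0
    for t in times:
        cur.length += rng.poisson(
            max(0.0, cfg.depth_at(t) - cfg.depth_at(prev_t))
        )
        branch = _SimNode(
            length=rng.poisson(max(0.0, cfg.depth_at(cfg.age) - cfg.depth_at(t))),
            founder=f_idx, expansion=-1,
        )
        cont = _SimNode()
        cur.children = [branch, cont]
        cells.append(branch)
        cur, prev_t = cont, t
    cur.length += rng.poisson(
        max(0.0, cfg.depth_at(cfg.age) - cfg.depth_at(prev_t))
    )
    cur.founder = f_idx
    cur.expansion = -1
    cells.append(cur)
    return cells


def simulate_phylogeny(config: SimConfig) -> tuple[Phylogeny, pd.DataFrame]:
    """Simulate one individual's sampled cell phylogeny.

    Returns the sampled tree (``config.sample_size`` tips) and a truth
    table with columns ``tip``, ``founder`` and ``expansion`` (-1 for
    ancestral, non-expanded cells).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    root, founders = _yule_burst(config.n_founders, config.t_emb, rng)

    # resolve expansion sources (one expansion per founder lineage)
    taken: set[int] = set()
    sources: list[int] = []
    for e in config.expansions:
        if e.source is not None:
            if e.source in taken or not 0 <= e.source < config.n_founders:
                raise ValueError(f"invalid or duplicate source {e.source}")
            src = e.source
        else:
            src = int(rng.integers(config.n_founders))
            while src in taken:
                src = int(rng.integers(config.n_founders))
        taken.add(src)
        sources.append(src)

    cells: list[_SimNode] = []
    by_source = {src: i for i, src in enumerate(sources)}
    for f_idx, node in enumerate(founders):
        if f_idx in by_source:
            e_idx = by_source[f_idx]
            cells.extend(
                _grow_clone(config, e_idx, config.expansions[e_idx],
                            f_idx, node, rng)
            )
        else:
            cells.extend(_extend_founder(config, f_idx, node, rng))

    if config.sample_size > len(cells):
        raise ValueError(
            f"sample_size {config.sample_size} exceeds the {len(cells)} "
            "cells generated; reduce the sample or enlarge the population"
        )
    for i, c in enumerate(cells):
        c.name = f"c{i}"
    picked = rng.choice(len(cells), size=config.sample_size, replace=False)
    picked_cells = [cells[i] for i in sorted(picked)]
    keep = {c.name for c in picked_cells}

    pruned = _prune_sim_tree(root, keep)
    phylo = read_newick(_newick(pruned))
    truth = pd.DataFrame(
        {
            "tip": [c.name for c in picked_cells],
            "founder": [c.founder for c in picked_cells],
            "expansion": [
                -1 if c.expansion is None else c.expansion
                for c in picked_cells
            ],
        }
    )
    return phylo, truth


def _prune_sim_tree(root: _SimNode, keep: set[str]) -> _SimNode:
    """Drop unsampled tips; merge unary chains (lengths summed)."""
    kept: dict[int, _SimNode] = {}
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if node.children and not done:
            stack.append((node, True))
            stack.extend((ch, False) for ch in node.children)
            continue
        if not node.children:
            if node.name in keep:
                kept[id(node)] = node
            continue
        sub = [kept[id(ch)] for ch in node.children if id(ch) in kept]
        if not sub:
            continue
        if len(sub) == 1:
            child = sub[0]
            child.length += node.length
            kept[id(node)] = child
        else:
            new = _SimNode(length=node.length)
            new.children = sub
            kept[id(node)] = new
    pruned = kept[id(root)]
    if not pruned.children:
        raise ValueError("pruning removed all internal structure")
    if pruned is not root:
        # sampled cells form a single clade: keep the stem to the root
        stem = _SimNode(length=0.0)
        stem.children = [pruned]
        pruned = stem
    return pruned


def simulate_sna_matrix(
    phylo: Phylogeny, missing_rate: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Generate a cells x sites genotype matrix from a phylogeny.

    Each branch receives a Poisson(branch length) batch of unique
    variant sites; a tip carries every variant on its root path.  Calls
    are then masked to missing independently at ``missing_rate``.
    """
    if missing_rate < 0 or missing_rate > 1:
        raise ValueError("missing_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    tree = phylo._tree
    site_ids: list[str] = []
    branch_sites: dict = {}
    for k, node in enumerate(tree.preorder_node_iter()):
        if node.parent_node is None:
            branch_sites[node] = []
            continue
        n_var = int(rng.poisson(node.edge.length))
        ids = [f"v{len(site_ids) + j}" for j in range(n_var)]
        site_ids.extend(ids)
        branch_sites[node] = ids
    rows = {}
    path_sites: dict = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        inherited = path_sites[parent] if parent is not None else []
        path_sites[node] = inherited + branch_sites[node]
        if node.is_leaf():
            rows[node.taxon.label] = set(path_sites[node])
    matrix = pd.DataFrame(
        0.0, index=list(rows), columns=site_ids if site_ids else ["v0"]
    )
    if not site_ids:  # degenerate zero-mutation tree: one all-absent site
        site_ids = ["v0"]
    for cell, present in rows.items():
        if present:
            matrix.loc[cell, list(present)] = 1.0
    if missing_rate > 0:
        mask = rng.random(matrix.shape) < missing_rate
        values = matrix.to_numpy()
        values[mask] = np.nan
        matrix = pd.DataFrame(values, index=matrix.index,
                              columns=matrix.columns)
    return matrix


def simulate_marker_cohort(
    ages,
    *,
    a_alpha: float = 0.002,
    b_alpha: float = 0.09,
    a_beta: float = 0.003,
    b_beta: float = 0.08,
    cv: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw (alpha, beta) for a cohort directly from exponential age models.

    Marker values are a * exp(b * age) with independent multiplicative
    lognormal noise of coefficient of variation ``cv``.  Useful for
    testing the phyloAge estimator against a known generative truth
    without tree simulation.
    """
    ages = np.asarray(ages, dtype=float)
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    mu = -0.5 * sigma * sigma  # unit-mean lognormal
    noise_a = rng.lognormal(mu, sigma, size=ages.size)
    noise_b = rng.lognormal(mu, sigma, size=ages.size)
    return pd.DataFrame(
        {
            "id": [f"ind{i}" for i in range(ages.size)],
            "age": ages,
            "alpha": a_alpha * np.exp(b_alpha * ages) * noise_a,
            "beta": a_beta * np.exp(b_beta * ages) * noise_b,
        }
    )


# -- cohort simulation from trees -------------------------------------

# CHIP-like expansions in the healthy scenario: clones arrive during a
# mid-life onset window and grow steadily thereafter, so clone sizes --
# and with them the decay metrics -- rise exponentially with age.
# Calibrated so beta stays near 0 before ~50, is a few tenths around
# 60-65 and reaches ~2 by the early 80s, the regime seen in elderly
# healthy donors.
_HEALTHY_CHIP_RATE = 0.05            # clone arrivals per onset-window year
_HEALTHY_ONSET_WINDOW = (15.0, 45.0)  # calendar years
_HEALTHY_GROWTH = (0.08, 0.12)       # divisions / yr, drawn uniformly
_MPN_ONSET_FRACTION = (0.3, 0.5)  # onset as a fraction of age at sampling
# The MPN driver clone grows to a target cell count by the sampling age
# (cells; ~10x the ancestral pool), so the clone keeps dividing up to
# the present and dominates any fixed-size sample of cells.
_MPN_CLONE_SIZE = (600.0, 1200.0)


def _scenario_expansions(scenario: str, age: float, rng) -> tuple[Expansion, ...]:
    if scenario not in ("healthy", "mpn"):
        raise ValueError(f"unknown scenario {scenario!r}")
    expansions: list[Expansion] = []
    if scenario == "mpn":
        onset = float(rng.uniform(*_MPN_ONSET_FRACTION)) * age
        target = float(rng.uniform(*_MPN_CLONE_SIZE))
        growth = math.log(target) / (age - onset)
        expansions.append(Expansion(onset_age=onset, growth_rate=growth))
    lo, hi = _HEALTHY_ONSET_WINDOW
    hi = min(hi, age - 1.0)
    if hi > lo:
        n_chip = int(rng.poisson(_HEALTHY_CHIP_RATE * (hi - lo)))
        for _ in range(n_chip):
            onset = float(rng.uniform(lo, hi))
            growth = float(rng.uniform(*_HEALTHY_GROWTH))
            expansions.append(Expansion(onset_age=onset, growth_rate=growth))
    return tuple(expansions)


def simulate_cohort(
    ages,
    scenarios,
    seed: int = 0,
    *,
    n_founders: int = 100,
    sample_size: int = 50,
) -> tuple[pd.DataFrame, dict[str, Phylogeny]]:
    """Simulate a cohort of individuals and their decay metrics.

    ``scenarios`` is either a single scenario name ("healthy" or "mpn")
    applied to everyone, or a sequence with one name per individual.
    Returns the cohort table (id, age, alpha, beta, scenario) ready for
    phyloAge fitting, plus each individual's sampled tree.
    """
    ages = [float(a) for a in ages]
    if len(ages) < 3:
        raise ValueError("cohort simulation needs at least 3 ages")
    if isinstance(scenarios, str):
        scenarios = [scenarios] * len(ages)
    scenarios = list(scenarios)
    if not scenarios:
        raise ValueError("scenario list must not be empty")
    if len(scenarios) != len(ages):
        raise ValueError("need one scenario per age")
    rng = np.random.default_rng(seed)
    rows = []
    trees: dict[str, Phylogeny] = {}
    for i, (age, scenario) in enumerate(zip(ages, scenarios)):
        ind = f"ind{i}"
        expansions = _scenario_expansions(scenario, age, rng)
        cfg = SimConfig(
            age=age, n_founders=n_founders, sample_size=sample_size,
            expansions=expansions, seed=int(rng.integers(2**31)),
        )
        phylo, _ = simulate_phylogeny(cfg)
        res = diversity_metrics(phylo)
        rows.append(
            {
                "id": ind, "age": age, "alpha": res.alpha, "beta": res.beta,
                "scenario": scenario,
            }
        )
        trees[ind] = phylo
    return pd.DataFrame(rows), trees
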