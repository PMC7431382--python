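"""Cross-species gene-module overlap enrichment.

Background construction from one-to-one mouse-human orthologs, one-tailed
hypergeometric over-representation tests, percent-overlap grids, permutation
verification of overlaps, and permutation tests of weighted-network
connectedness for gene lists.

All permutation p-values use the add-one estimator (b + 1) / (n_perm + 1),
which never reports zero: a list that beats all permutations attains the
floor 1 / (n_perm + 1) exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import WeightedGeneNetwork

__all__ = [
    "GeneSet",
    "OrthologMap",
    "Background",
    "OverlapResult",
    "PermutationResult",
    "build_background",
    "hypergeom_overlap",
    "overlap_matrix",
    "permutation_overlap_test",
    "connectedness",
    "connectedness_permutation",
    "read_gene_set",
    "read_gmt",
    "read_ortholog_map",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    """A named gene list with a species tag."""

    name: str
    members: frozenset[str]
    species: str = "mouse"

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def restrict(self, universe) -> "GeneSet":
        return GeneSet(self.name, self.members & frozenset(universe), self.species)


class OrthologMap:
    """Strictly one-to-one mouse <-> human identifier pairs.

    Pairs participating in many-to-many relationships are dropped at
    construction, as is standard for ortholog-restricted backgrounds.
    """

    def __init__(self, pairs: pd.DataFrame):
        df = pairs.iloc[:, :2].astype(str)
        df.columns = ["mouse", "human"]
        df = df.drop_duplicates()
        one_to_one = (~df["mouse"].duplicated(keep=False)) & (
            ~df["human"].duplicated(keep=False)
        )
        df = df[one_to_one]
        self.mouse_to_human = dict(zip(df["mouse"], df["human"]))
        self.human_to_mouse = dict(zip(df["human"], df["mouse"]))

    def __len__(self) -> int:
        return len(self.mouse_to_human)

    def to_mouse(self, genes) -> set[str]:
        return {self.human_to_mouse[g] for g in genes if g in self.human_to_mouse}

    def to_human(self, genes) -> set[str]:
        return {self.mouse_to_human[g] for g in genes if g in self.mouse_to_human}


@dataclass(frozen=True)
class Background:
    """The identifier universe from which overlaps are assessed."""

    universe: frozenset[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "universe", frozenset(self.universe))

    @property
    def size(self) -> int:
        return len(self.universe)


@dataclass
class OverlapResult:
    """One hypergeometric overlap test between two background-restricted sets."""

    set_a: str
    set_b: str
    n_a: int
    n_b: int
    overlap: int
    background: int
    pvalue: float
    percent_overlap: float  # 100 * m / n_a (module as denominator)


@dataclass
class PermutationResult:
    """Permutation-test summary with the add-one p-value estimator."""

    observed: float
    n_perm: int
    n_at_least: int  # permuted statistics >= observed
    p_raw: float
    p_bonferroni: float
    seed: int
    n_tests: int = 1


# ---------------------------------------------------------------------------
# background construction
# ---------------------------------------------------------------------------

def build_background(
    mouse_sets: list[GeneSet],
    human_sets: list[GeneSet],
    orthologs: OrthologMap,
    direction: str = "human_to_mouse",
) -> tuple[Background, list[GeneSet]]:
    """Ortholog-filtered background and background-restricted gene sets.

    Human lists are filtered for members with mouse orthologs and mapped into
    mouse identifier space (default direction; ``mouse_to_human`` flips it);
    mouse lists are filtered for members with orthologs on the other side.
    The background is the union of the filtered mouse-side universe and the
    filtered, mapped human-list genes.
    """
    if direction not in ("human_to_mouse", "mouse_to_human"):
        raise ValueError("direction must be human_to_mouse or mouse_to_human")
    to_target = orthologs.to_mouse if direction == "human_to_mouse" else orthologs.to_human
    if direction == "human_to_mouse":
        mouse_keep = set(orthologs.mouse_to_human)
    else:
        mouse_keep = set(orthologs.human_to_mouse)

    filtered: list[GeneSet] = []
    mouse_universe: set[str] = set()
    for s in mouse_sets:
        members = (
            s.members & mouse_keep
            if direction == "human_to_mouse"
            else to_target(s.members)
        )
        if not members:
            warnings.warn(f"gene set {s.name!r} has no orthologous members", stacklevel=2)
        mouse_universe |= members
        filtered.append(GeneSet(s.name, members, "mouse" if direction == "human_to_mouse" else "human"))

    mapped_universe: set[str] = set()
    for s in human_sets:
        members = (
            to_target(s.members)
            if direction == "human_to_mouse"
            else s.members & set(orthologs.human_to_mouse)
        )
        if not members:
            warnings.warn(f"gene set {s.name!r} has no orthologous members", stacklevel=2)
        mapped_universe |= members
        filtered.append(GeneSet(s.name, members, "mouse" if direction == "human_to_mouse" else "human"))

    universe = mouse_universe | mapped_universe
    note = (
        f"union of {len(mouse_universe)} ortholog-filtered measurement-side genes "
        f"and {len(mapped_universe)} mapped list genes"
    )
    return Background(universe, note), filtered


# ---------------------------------------------------------------------------
# hypergeometric overlap
# ---------------------------------------------------------------------------

def hypergeom_overlap(a: GeneSet, b: GeneSet, bg: Background) -> OverlapResult:
    """One-tailed over-representation p-value P(X >= m) for the overlap of two
    sets drawn from a finite background (one-tailed Fisher's exact test)."""
    for s in (a, b):
        stray = s.members - bg.universe
        if stray:
            raise ValueError(
                f"set {s.name!r} not contained in background: {sorted(stray)[:10]}"
            )
    m = len(a.members & b.members)
    n1, n2, N = len(a), len(b), bg.size
    # survival function at m-1 gives the inclusive upper tail P(X >= m)
    p = float(stats.hypergeom.sf(m - 1, N, n1, n2))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    percent = 100.0 * m / n1 if n1 else 0.0
    return OverlapResult(a.name, b.name, n1, n2, m, N, p, percent)


def overlap_matrix(
    modules: list[GeneSet],
    disease_lists: list[GeneSet],
    bg: Background,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full grid of overlap tests: one row per (module, list) pair."""
    rows = []
    for mod in modules:
        for lst in disease_lists:
            r = hypergeom_overlap(mod, lst, bg)
            rows.append(
                {
                    "module": r.set_a,
                    "list": r.set_b,
                    "n_module": r.n_a,
                    "n_list": r.n_b,
                    "overlap": r.overlap,
                    "background": r.background,
                    "pvalue": r.pvalue,
                    "percent_overlap": r.percent_overlap,
                    "significant": r.pvalue < alpha,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

def _random_subsets(rng: np.random.Generator, n_perm: int, n: int, size: int) -> np.ndarray:
    """n_perm uniform draws of ``size`` indices from range(n), no replacement.

    Vectorized via argpartition of a random matrix (each row an independent
    uniform subset)."""
    u = rng.random((n_perm, n))
    return np.argpartition(u, size - 1, axis=1)[:, :size]


def permutation_overlap_test(
    a: GeneSet,
    b: GeneSet,
    bg: Background,
    n_perm: int = 10_000,
    seed: int = 0,
    n_tests: int = 1,
) -> PermutationResult:
    """Permutation verification of an overlap: the observed |a & b| is
    compared with overlaps of ``a`` against uniform random background draws
    of size |b|."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(b) > bg.size:
        raise ValueError("list larger than background")
    rng = np.random.default_rng(seed)
    universe = sorted(bg.universe)
    index = {g: i for i, g in enumerate(universe)}
    mask = np.zeros(len(universe), dtype=bool)
    mask[[index[g] for g in a.members & bg.universe]] = True
    observed = len(a.members & b.members)
    draws = _random_subsets(rng, n_perm, len(universe), len(b))
    perm_stats = mask[draws].sum(axis=1)
    n_at_least = int((perm_stats >= observed).sum())
    p_raw = (n_at_least + 1) / (n_perm + 1)
    return PermutationResult(
        observed=float(observed),
        n_perm=n_perm,
        n_at_least=n_at_least,
        p_raw=p_raw,
        p_bonferroni=min(1.0, p_raw * n_tests),
        seed=seed,
        n_tests=n_tests,
    )


def connectedness(genes, net: WeightedGeneNetwork, statistic: str = "mean") -> float:
    """Overall connectedness of a gene list in a weighted network.

    The default statistic is the mean edge weight over all unordered pairs
    within the list; ``statistic="sum"`` uses the summed weight instead.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("connectedness requires a list of at least 2 genes")
    idx = net.index_of(genes)
    sub = net.weights[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    pair_weights = sub[iu]
    if statistic == "mean":
        return float(pair_weights.mean())
    if statistic == "sum":
        return float(pair_weights.sum())
    raise ValueError("statistic must be 'mean' or 'sum'")


def connectedness_permutation(
    genes,
    net: WeightedGeneNetwork,
    n_perm: int = 100_000,
    seed: int = 0,
    statistic: str = "mean",
    n_tests: int = 1,
) -> PermutationResult:
    """Connectedness of a list versus equal-size uniform random node draws."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    genes = list(genes)
    observed = connectedness(genes, net, statistic)
    rng = np.random.default_rng(seed)
    size = len(genes)
    n_nodes = len(net.nodes)
    draws = _random_subsets(rng, n_perm, n_nodes, size)
    iu, ju = np.triu_indices(size, k=1)
    pair_sum = net.weights[draws[:, iu], draws[:, ju]].sum(axis=1)
    perm_stats = pair_sum if statistic == "sum" else pair_sum / len(iu)
    n_at_least = int((perm_stats >= observed).sum())
    p_raw = (n_at_least + 1) / (n_perm + 1)
    return PermutationResult(
        observed=observed,
        n_perm=n_perm,
        n_at_least=n_at_least,
        p_raw=p_raw,
        p_bonferroni=min(1.0, p_raw * n_tests),
        seed=seed,
        n_tests=n_tests,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_gene_set(path, name: str | None = None, species: str = "mouse") -> GeneSet:
    """One identifier per line."""
    with open(path) as fh:
        members = {line.strip() for line in fh if line.strip()}
    return GeneSet(name or str(path), members, species)


def read_gmt(path, species: str = "mouse") -> list[GeneSet]:
    """GMT: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets.append(GeneSet(parts[0], {g for g in parts[2:] if g}, species))
    return sets


def read_ortholog_map(path) -> OrthologMap:
    """Two-column TSV: mouse id, human id."""
    return OrthologMap(pd.read_csv(path, sep="\t"))
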