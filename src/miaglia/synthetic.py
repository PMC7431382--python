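"""Synthetic inputs with the statistical structure the analysis pipeline assumes.

Generators for every input modality the pipeline consumes:

* negative-binomial RNA-seq counts for a 10-group x 3-replicate microglia
  design with planted expression modules and controlled cell-type-marker
  contamination,
* 3D dendrite/spine/microglia scenes on an anisotropic confocal voxel grid,
* BrdU/EdU fate-mapping cell tables with planted class proportions,
* complete weighted gene networks with a planted dense module.

Every generator takes an explicit integer seed and is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .transcriptome import CountsMatrix, MarkerPanel, DEFAULT_MARKER_PANEL

__all__ = [
    "DesignSpec",
    "PlantedModuleSpec",
    "ContaminationSpec",
    "SceneSpec",
    "SpineSpec",
    "SyntheticCounts",
    "WeightedGeneNetwork",
    "DEFAULT_VOXEL_SIZE",
    "default_design",
    "default_module_spec",
    "generate_counts",
    "generate_scene",
    "generate_fate_table",
    "generate_network",
]

AGES = ("E17", "P7", "P20", "P60")

#: confocal stack resolution in um per voxel (x, y, z)
DEFAULT_VOXEL_SIZE = (0.04, 0.04, 0.3)


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignSpec:
    """Sample layout: (age, prenatal, drug) groups x replicates."""

    groups: tuple[tuple[str, str, str], ...]
    replicates_per_group: int = 3

    def __post_init__(self) -> None:
        if self.replicates_per_group < 1:
            raise ValueError("replicates_per_group must be a positive integer")
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("duplicate groups in design")

    @property
    def n_samples(self) -> int:
        return len(self.groups) * self.replicates_per_group

    def group_labels(self) -> list[str]:
        return ["_".join(g) for g in self.groups]

    def sample_table(self) -> pd.DataFrame:
        """Enumerate samples with metadata, one row per replicate."""
        rows = []
        for age, prenatal, drug in self.groups:
            label = f"{age}_{prenatal}_{drug}"
            for r in range(1, self.replicates_per_group + 1):
                rows.append(
                    {
                        "sample": f"{label}_r{r}",
                        "age": age,
                        "prenatal": prenatal,
                        "drug": drug,
                        "group": label,
                        # balanced sexes, litter tracks replicate within group
                        "sex": "M" if r % 2 else "F",
                        "litter": f"{label}_L{r}",
                    }
                )
        return pd.DataFrame(rows).set_index("sample")


def default_design(replicates_per_group: int = 3) -> DesignSpec:
    """The study design: Saline/MIA at E17, P7, P20, P60 on control chow,
    plus the two P60 repopulation (MG-REP) groups; 3 replicates each,
    30 samples in total."""
    groups = [(age, prenatal, "CTRL") for age in AGES for prenatal in ("Saline", "MIA")]
    groups += [("P60", "Saline", "MG-REP"), ("P60", "MIA", "MG-REP")]
    return DesignSpec(tuple(groups), replicates_per_group)


# ---------------------------------------------------------------------------
# planted expression modules
# ---------------------------------------------------------------------------

#: the five module signatures: module name -> groups in which it is enriched
DEFAULT_MODULE_GROUPS: dict[str, tuple[str, ...]] = {
    "IM": ("E17_Saline_CTRL", "P7_Saline_CTRL"),
    "MIA-IM": ("E17_MIA_CTRL", "P7_MIA_CTRL"),
    "JM": ("P20_Saline_CTRL", "P20_MIA_CTRL"),
    "AM": ("P60_Saline_CTRL", "P60_MIA_CTRL", "P60_MIA_MG-REP"),
    "REP-AM": ("P60_Saline_MG-REP",),
}


@dataclass(frozen=True)
class PlantedModuleSpec:
    """Planted module structure for the counts generator.

    ``mean_shift`` is in log2 fold-change units: module genes are expressed
    ``2**mean_shift`` fold higher in their enriched groups than elsewhere.
    ``dispersion`` is the NB dispersion phi with variance mu + phi * mu**2.
    """

    n_genes_per_module: tuple[int, ...] = (300, 300, 300, 300, 300)
    module_names: tuple[str, ...] = tuple(DEFAULT_MODULE_GROUPS)
    enriched_groups_per_module: tuple[tuple[str, ...], ...] = tuple(
        DEFAULT_MODULE_GROUPS.values()
    )
    mean_shift: float = 4.0
    dispersion: float = 0.1
    n_background_genes: int = 100

    def __post_init__(self) -> None:
        if len(self.n_genes_per_module) != len(self.enriched_groups_per_module):
            raise ValueError("one gene count per module required")
        if len(self.module_names) != len(self.n_genes_per_module):
            raise ValueError("one name per module required")
        if any(n <= 0 for n in self.n_genes_per_module):
            raise ValueError("module sizes must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be strictly positive")
        if self.n_background_genes < 0:
            raise ValueError("background gene count must be non-negative")

    @property
    def n_modules(self) -> int:
        return len(self.n_genes_per_module)


def default_module_spec(**overrides) -> PlantedModuleSpec:
    return dataclasses.replace(PlantedModuleSpec(), **overrides)


@dataclass(frozen=True)
class ContaminationSpec:
    """Per-cell-type marker contamination fractions; remainder is microglia.

    Keys are the non-microglia cell types of the marker panel.  The planted
    fractions hold in expectation for the within-panel purity statistic.
    """

    fractions: dict[str, float] = field(
        default_factory=lambda: {
            "neurons": 0.005,
            "oligodendrocytes": 0.005,
            "astrocytes": 0.005,
            "endothelial": 0.005,
        }
    )
    panel: MarkerPanel = field(default_factory=lambda: DEFAULT_MARKER_PANEL)
    panel_budget_fraction: float = 0.02

    def __post_init__(self) -> None:
        for cell_type, f in self.fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"contamination fraction for {cell_type} outside [0, 1]")
            if cell_type not in self.panel.markers:
                raise ValueError(f"unknown cell type {cell_type!r} for panel")
            if cell_type == self.panel.reference_type:
                raise ValueError("contamination is specified for non-microglia types only")
        if sum(self.fractions.values()) > 1.0 + 1e-12:
            raise ValueError("contamination fractions must sum to <= 1")

    @property
    def microglia_fraction(self) -> float:
        return 1.0 - sum(self.fractions.values())


@dataclass
class SyntheticCounts:
    """A generated counts matrix plus the planted ground truth."""

    counts: CountsMatrix
    true_modules: dict[str, str]  # gene -> planted module name

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": list(self.true_modules), "module": list(self.true_modules.values())}
        ).set_index("gene")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draw in the mean/dispersion parameterization, var = mu + phi mu^2."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if dispersion <= 0:
        out[pos] = rng.poisson(mean[pos])
        return out
    size = 1.0 / dispersion
    p = size / (size + mean[pos])
    out[pos] = rng.negative_binomial(size, p)
    return out


def generate_counts(
    design: DesignSpec | None = None,
    modules: PlantedModuleSpec | None = None,
    contamination: ContaminationSpec | None = None,
    seed: int = 0,
    mean_library_size: float = 1e7,
    library_size_cv: float = 0.2,
) -> SyntheticCounts:
    """Simulate an integer gene x sample counts matrix.

    Background and module genes get log-normal relative abundances; module
    genes are shifted up by ``2**mean_shift`` in their enriched groups.
    Marker-panel genes receive a fixed share of the library
    (``panel_budget_fraction``) split across cell types according to the
    contamination fractions, so the planted purity holds in expectation.
    Library sizes are log-normal around ``mean_library_size`` with the given
    coefficient of variation.
    """
    design = design or default_design()
    modules = modules or PlantedModuleSpec()
    contamination = contamination or ContaminationSpec()
    rng = np.random.default_rng(seed)

    meta = design.sample_table()
    samples = meta.index.to_list()
    group_of_sample = meta["group"].to_numpy()

    # gene universe: planted module genes, background genes, panel markers
    genes: list[str] = []
    true_modules: dict[str, str] = {}
    for name, n in zip(modules.module_names, modules.n_genes_per_module):
        for i in range(n):
            g = f"{name}_{i + 1:04d}"
            genes.append(g)
            true_modules[g] = name
    background = [f"BG_{i + 1:04d}" for i in range(modules.n_background_genes)]
    genes.extend(background)
    panel_genes = [g for t in contamination.panel.markers.values() for g in t]
    collisions = set(genes) & set(panel_genes)
    if collisions:
        raise ValueError(f"gene name collision with marker panel: {sorted(collisions)}")
    genes.extend(panel_genes)

    n_genes = len(genes)
    n_samples = len(samples)

    # per-sample library sizes, log-normal with the requested CV
    sigma = np.sqrt(np.log1p(library_size_cv**2))
    lib = mean_library_size * rng.lognormal(-0.5 * sigma**2, sigma, size=n_samples)

    # relative abundances: log-normal weights, normalized within each sample
    base_weight = rng.lognormal(0.0, 1.0, size=n_genes)
    weight = np.tile(base_weight[:, None], (1, n_samples))

    # plant module structure: enriched groups get 2**shift the baseline
    fold = 2.0**modules.mean_shift
    gene_index = {g: i for i, g in enumerate(genes)}
    for name, enriched in zip(modules.module_names, modules.enriched_groups_per_module):
        in_group = np.isin(group_of_sample, list(enriched))
        rows = [gene_index[g] for g, m in true_modules.items() if m == name]
        weight[np.ix_(rows, np.flatnonzero(in_group))] *= fold

    # marker-panel budget split by contamination fractions
    budget = contamination.panel_budget_fraction
    type_fraction = dict(contamination.fractions)
    type_fraction[contamination.panel.reference_type] = contamination.microglia_fraction
    non_panel = np.ones(n_genes, dtype=bool)
    for cell_type, markers in contamination.panel.markers.items():
        rows = [gene_index[g] for g in markers]
        non_panel[rows] = False
        split = rng.dirichlet(np.full(len(markers), 5.0))
        for r, s in zip(rows, split):
            weight[r, :] = type_fraction[cell_type] * s  # relative to panel budget

    # normalize: non-panel genes share (1 - budget), panel genes share budget
    col_sum = weight[non_panel].sum(axis=0)
    mean_expr = np.empty_like(weight)
    mean_expr[non_panel] = weight[non_panel] / col_sum * (1.0 - budget) * lib
    mean_expr[~non_panel] = weight[~non_panel] * budget * lib

    counts = _nb_draw(rng, mean_expr, modules.dispersion)
    df = pd.DataFrame(counts, index=genes, columns=samples)
    return SyntheticCounts(CountsMatrix(df, meta), true_modules)


# ---------------------------------------------------------------------------
# 3D scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpineSpec:
    """Requested geometry for one synthetic spine."""

    position_um: float
    neck_um: float
    head_um: float
    offset_um: tuple[float, float, float] = (0.5, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.neck_um < 0 or self.head_um < 0:
            raise ValueError("spine geometry must be non-negative")
        if any(o < 0 for o in self.offset_um):
            raise ValueError("microglia offsets must be non-negative")


@dataclass(frozen=True)
class SceneSpec:
    """A dendrite with spines and microglia point clouds at controlled offsets."""

    dendrite_length_um: float = 100.0
    spines: tuple[SpineSpec, ...] = ()
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    cloud_points_per_spine: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dendrite_length_um <= 0:
            raise ValueError("dendrite length must be positive")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be strictly positive")
        for sp in self.spines:
            if not 0.0 <= sp.position_um <= self.dendrite_length_um:
                raise ValueError("spine position outside dendrite")


def generate_scene(spec: SceneSpec):
    """Emit spine records and a microglia point cloud on the voxel grid.

    The dendrite runs along x at y = z = 0.  Each spine head sits one head
    radius plus neck above the shaft in y; its microglia blob is placed so
    that the nearest blob point lies at the requested offset from the head
    center (up to voxel rounding: within one voxel diagonal), with the
    remaining blob points strictly farther away along the offset direction.
    Returns ``(spines, cloud)`` where ``spines`` is a list of
    :class:`miaglia.morphometry.SpineRecord` and ``cloud`` a
    :class:`miaglia.morphometry.ProcessPointCloud`.
    """
    from .morphometry import ProcessPointCloud, SpineRecord, classify_spine

    rng = np.random.default_rng(spec.seed)
    sx, sy, sz = spec.voxel_size_um
    voxel = np.array(spec.voxel_size_um)

    spines: list[SpineRecord] = []
    points: list[tuple[int, int, int]] = []
    for idx, sp in enumerate(spec.spines):
        head_center_um = np.array(
            [sp.position_um, sp.neck_um + sp.head_um / 2.0, 0.0]
        )
        head_vox = np.rint(head_center_um / voxel).astype(int)
        offset = np.array(sp.offset_um)
        nearest_um = head_vox * voxel + offset
        nearest_vox = np.rint(nearest_um / voxel).astype(int)
        if np.all(nearest_vox == head_vox):  # zero offset collapses onto the head
            nearest_vox = head_vox + np.array([0, 0, 0])
        points.append(tuple(nearest_vox))
        # pad the blob strictly beyond the nearest point along the offset ray
        direction = offset if np.linalg.norm(offset) > 0 else np.array([0.0, 1.0, 0.0])
        direction = direction / np.linalg.norm(direction)
        for _ in range(max(spec.cloud_points_per_spine - 1, 0)):
            extra_um = nearest_vox * voxel + direction * (
                0.5 + 2.0 * rng.random()
            )
            points.append(tuple(np.rint(extra_um / voxel).astype(int)))
        spines.append(
            SpineRecord(
                spine_id=f"sp{idx + 1:03d}",
                position_um=sp.position_um,
                neck_um=sp.neck_um,
                head_um=sp.head_um,
                head_voxel=tuple(head_vox),
                subtype=classify_spine(sp.neck_um, sp.head_um),
            )
        )
    cloud = ProcessPointCloud(
        np.array(points, dtype=int).reshape(-1, 3), spec.voxel_size_um
    )
    return spines, cloud


# ---------------------------------------------------------------------------
# fate-mapping tables
# ---------------------------------------------------------------------------

_CLASS_FLAGS = {  # (brdu, edu) per demographic class
    "BrdU+EdU-": (1, 0),
    "BrdU+EdU+": (1, 1),
    "BrdU-EdU+": (0, 1),
}


def generate_fate_table(
    n_cells: int,
    fractions: tuple[float, float, float],
    seed: int = 0,
    exact: bool = False,
    group: str = "Saline_MG-REP",
    n_sections: int = 4,
    n_animals: int = 2,
    n_unlabeled: int = 0,
) -> pd.DataFrame:
    """Simulate a labeled-cell table for fate-mapping demographics.

    ``fractions`` are the proportions of (BrdU+EdU-, BrdU+EdU+, BrdU-EdU+)
    among thymidine-analog-labeled IBA1+ cells and must sum to 1.  In
    ``exact`` mode the per-class counts are ``round(n * f)`` with a
    largest-remainder correction (deterministic fixtures); otherwise a
    multinomial draw.  ``n_unlabeled`` appends BrdU-EdU- IBA1+ cells, which
    enter labeling-efficiency denominators but not demographics.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be a length-3 point in the simplex")
    if n_cells < 0 or n_unlabeled < 0:
        raise ValueError("cell counts must be non-negative")
    rng = np.random.default_rng(seed)

    if exact:
        raw = np.array([n_cells * f for f in fractions])
        counts = np.floor(raw).astype(int)
        remainder = raw - counts
        for i in np.argsort(-remainder)[: n_cells - counts.sum()]:
            counts[i] += 1
    else:
        counts = rng.multinomial(n_cells, fractions)

    rows = []
    for cls, n in zip(_CLASS_FLAGS, counts):
        brdu, edu = _CLASS_FLAGS[cls]
        rows += [{"iba1": 1, "brdu": brdu, "edu": edu}] * int(n)
    rows += [{"iba1": 1, "brdu": 0, "edu": 0}] * n_unlabeled
    df = pd.DataFrame(rows)
    n_total = len(df)
    df.insert(0, "cell_id", [f"c{i + 1:05d}" for i in range(n_total)])
    section = rng.integers(1, n_sections + 1, size=n_total)
    animal = (section - 1) % n_animals + 1
    df.insert(1, "section_id", [f"s{s}" for s in section])
    df.insert(2, "animal_id", [f"a{a}" for a in animal])
    df.insert(3, "group", group)
    return df


# ---------------------------------------------------------------------------
# weighted gene networks
# ---------------------------------------------------------------------------

@dataclass
class WeightedGeneNetwork:
    """Complete weighted graph over gene identifiers (weights in [0, 1])."""

    nodes: list[str]
    weights: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("weight matrix shape does not match node count")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("self-loops are not allowed")
        self.weights = w
        self._index = {g: i for i, g in enumerate(self.nodes)}

    def index_of(self, genes) -> np.ndarray:
        missing = [g for g in genes if g not in self._index]
        if missing:
            raise KeyError(f"genes not in network: {missing}")
        return np.array([self._index[g] for g in genes])

    def to_edge_list(self) -> pd.DataFrame:
        iu, ju = np.triu_indices(len(self.nodes), k=1)
        return pd.DataFrame(
            {
                "gene_a": [self.nodes[i] for i in iu],
                "gene_b": [self.nodes[j] for j in ju],
                "weight": self.weights[iu, ju],
            }
        )

    @classmethod
    def from_edge_list(cls, edges: pd.DataFrame) -> "WeightedGeneNetwork":
        nodes = sorted(set(edges.iloc[:, 0]) | set(edges.iloc[:, 1]))
        index = {g: i for i, g in enumerate(nodes)}
        w = np.zeros((len(nodes), len(nodes)))
        for a, b, weight in edges.itertuples(index=False):
            w[index[a], index[b]] = w[index[b], index[a]] = float(weight)
        return cls(nodes, w)


def generate_network(
    n_genes: int,
    planted_module_size: int,
    in_weight: float = 0.8,
    out_weight: float = 0.2,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[WeightedGeneNetwork, list[str]]:
    """Complete weighted network with one planted dense module.

    Pairs inside the planted module get ``in_weight`` (plus optional Gaussian
    noise, clipped to [0, 1]); all other pairs get ``out_weight``.  Returns
    the network and the planted gene list.
    """
    if planted_module_size > n_genes:
        raise ValueError("planted module larger than the network")
    if not in_weight > out_weight >= 0:
        raise ValueError("require in_weight > out_weight >= 0")
    rng = np.random.default_rng(seed)
    nodes = [f"G{i + 1:04d}" for i in range(n_genes)]
    w = np.full((n_genes, n_genes), out_weight)
    w[:planted_module_size, :planted_module_size] = in_weight
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=(n_genes, n_genes))
        w = w + np.triu(noise, k=1) + np.triu(noise, k=1).T
    w = np.clip(w, 0.0, 1.0)
    np.fill_diagonal(w, 0.0)
    return WeightedGeneNetwork(nodes, w), nodes[:planted_module_size]
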