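"""Core model: differentiation trees, regulatory-network inputs, simulation
configuration, dataset grids and the ``M{p}{c}{s}`` label scheme.

The simulator is organised around a cell differentiation tree (the minimal
user input), a ground-truth gene regulatory network (GRN) given as a
regulator/target/effect edge table, and an optional ligand-receptor database
used for cell-cell interaction (CCI) simulation.  A :class:`SimConfig` holds
every user-facing knob; benchmark dataset grids are enumerated from it and
addressed by compact labels such as ``MD5c``.

Gene, cell and region identifiers are 1-based in all user-facing tables;
internally everything is 0-based NumPy indexing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "DifferentiationTree",
    "GrnSpec",
    "LigRecDatabase",
    "SimConfig",
    "DatasetLabel",
    "parse_tree",
    "builtin_tree",
    "load_grn",
    "load_lr_database",
    "resolve_dataset_label",
    "enumerate_grid",
    "module_stream",
]

# ---------------------------------------------------------------------------
# Random streams
# ---------------------------------------------------------------------------

#: Fixed child-stream keys per simulation stage.  Every module derives its own
#: generator from the single global seed through these keys, so enabling or
#: disabling one stage never perturbs another stage's draws.
STREAM_KEYS = {
    "cif": 0,
    "giv": 1,
    "atac": 2,
    "kinetics": 3,
    "expression": 4,
    "spatial": 5,
    "noise": 6,
    "grn_dynamics": 7,
    "fixtures": 8,
}


def module_stream(seed: int, name: str) -> np.random.Generator:
    """Independent random generator for one simulation stage."""
    key = STREAM_KEYS[name]
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# Differentiation tree
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DifferentiationTree:
    """Rooted tree with branch lengths; nodes are cell types.

    ``leaves`` preserve input order.  Branch lengths default to 1 where the
    Newick text omits them.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, float], ...]  # (parent, child, length)
    root: str
    leaves: tuple[str, ...]

    def __post_init__(self) -> None:
        children: dict[str, list[str]] = {n: [] for n in self.nodes}
        seen_child: set[str] = set()
        for parent, child, length in self.edges:
            if length < 0:
                raise ValueError(f"negative branch length on edge {parent}->{child}")
            if child in seen_child:
                raise ValueError(f"node {child} has two parents")
            seen_child.add(child)
            children[parent].append(child)
        if self.root in seen_child:
            raise ValueError("root has a parent")
        # connectivity
        stack, reached = [self.root], {self.root}
        while stack:
            for c in children[stack.pop()]:
                if c in reached:
                    raise ValueError("tree contains a cycle")
                reached.add(c)
                stack.append(c)
        if reached != set(self.nodes):
            raise ValueError("tree is not connected")
        if not self.leaves:
            raise ValueError("tree has no leaves")

    # -- derived structure -------------------------------------------------

    @property
    def parent_map(self) -> dict[str, tuple[str, float]]:
        return {c: (p, l) for p, c, l in self.edges}

    @property
    def children_map(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {n: [] for n in self.nodes}
        for p, c, _ in self.edges:
            out[p].append(c)
        return out

    def depth(self, node: str) -> float:
        """Path distance from the root."""
        parents = self.parent_map
        d = 0.0
        while node != self.root:
            node, length = parents[node][0], parents[node][1]
            d += length
        return d

    def root_path(self, node: str) -> list[str]:
        parents = self.parent_map
        path = [node]
        while node != self.root:
            node = parents[node][0]
            path.append(node)
        return path[::-1]

    def path_length(self, a: str, b: str) -> float:
        pa, pb = self.root_path(a), self.root_path(b)
        common = 0
        for x, y in zip(pa, pb):
            if x != y:
                break
            common += 1
        anc_depth = self.depth(pa[common - 1])
        return (self.depth(a) - anc_depth) + (self.depth(b) - anc_depth)

    def lineages(self) -> list[list[str]]:
        """Root-to-leaf node paths, one per leaf, in leaf order."""
        return [self.root_path(leaf) for leaf in self.leaves]

    def max_depth(self) -> float:
        return max(self.depth(leaf) for leaf in self.leaves)

    def to_newick(self) -> str:
        children = self.children_map
        lengths = {c: l for _, c, l in self.edges}

        def fmt(node: str) -> str:
            kids = children[node]
            if not kids:
                return node
            inner = ",".join(f"{fmt(c)}:{lengths[c]:g}" for c in kids)
            return f"({inner}){node}"

        return fmt(self.root) + ";"


def parse_tree(newick_text: str) -> DifferentiationTree:
    """Parse a Newick string into a :class:`DifferentiationTree`.

    Missing branch lengths default to 1; leaves are enumerated in input
    order.  Unlabeled internal nodes get generated names ``node_<k>``.
    """
    if not newick_text.strip():
        raise ValueError("empty Newick input")
    try:
        dtree = dendropy.Tree.get(
            data=newick_text, schema="newick", suppress_internal_node_taxa=False
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        pos = getattr(exc, "column_num", None)
        loc = f" near column {pos}" if pos is not None else ""
        raise ValueError(f"malformed Newick{loc}: {exc}") from exc

    names: dict[int, str] = {}
    counter = 0
    for nd in dtree.preorder_node_iter():
        label = None
        if nd.taxon is not None and nd.taxon.label:
            label = nd.taxon.label
        elif nd.label:
            label = nd.label
        if label is None:
            label = f"node_{counter}"
            counter += 1
        names[id(nd)] = label

    nodes: list[str] = []
    edges: list[tuple[str, str, float]] = []
    leaves: list[str] = []
    for nd in dtree.preorder_node_iter():
        name = names[id(nd)]
        if name in nodes:
            raise ValueError(f"duplicate node label {name!r}")
        nodes.append(name)
        if nd.parent_node is not None:
            length = nd.edge.length if nd.edge.length is not None else 1.0
            edges.append((names[id(nd.parent_node)], name, float(length)))
    for nd in dtree.leaf_node_iter():
        leaves.append(names[id(nd)])

    root = names[id(dtree.seed_node)]
    return DifferentiationTree(tuple(nodes), tuple(edges), root, tuple(leaves))


#: Built-in differentiation trees.  Leaf counts (1, 3, 5) follow the standard
#: example trees; the exact Phyla3/Phyla5 topologies are balanced stand-ins
#: with unit branch lengths.
_BUILTIN_TREES = {
    "Phyla1": "((A:1)M:1)root;",
    "Phyla3": "((A:1,B:1)M:1,C:1)root;",
    "Phyla5": "((A:1,B:1)M1:1,(C:1,D:1)M2:1,E:1)root;",
}


def builtin_tree(name: str) -> DifferentiationTree:
    """One of the bundled trees ``Phyla1``/``Phyla3``/``Phyla5``."""
    try:
        text = _BUILTIN_TREES[name]
    except KeyError:
        raise ValueError(
            f"unknown tree {name!r}; valid names: {sorted(_BUILTIN_TREES)}"
        ) from None
    return parse_tree(text)


# ---------------------------------------------------------------------------
# GRN and ligand-receptor inputs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrnSpec:
    """Ground-truth GRN: an edge table plus the derived effect matrix.

    ``mtg`` is the GRN effect matrix of shape ``n_tf x ngene``; entry (i, j)
    is the regulation strength of TF ``tf_ids[i]`` on gene ``j+1``.
    """

    edges: pd.DataFrame  # columns: regulator, target, effect (1-based ids)
    ngene: int
    tf_ids: tuple[int, ...]
    mtg: np.ndarray

    @property
    def n_tf(self) -> int:
        return len(self.tf_ids)

    def tf_index(self) -> dict[int, int]:
        return {g: i for i, g in enumerate(self.tf_ids)}

    def expand(self, ngene: int) -> "GrnSpec":
        """Pad the effect matrix with zero columns up to ``ngene`` genes
        (e.g. when extra ligand-only genes are simulated beyond the GRN)."""
        if ngene < self.ngene:
            raise ValueError(
                f"cannot shrink a {self.ngene}-gene GRN to {ngene} genes")
        if ngene == self.ngene:
            return self
        mtg = np.zeros((self.n_tf, ngene))
        mtg[:, : self.ngene] = self.mtg
        return GrnSpec(self.edges, ngene, self.tf_ids, mtg)


def load_grn(edge_table, ngene: int) -> GrnSpec:
    """Build a :class:`GrnSpec` from a 3-column (regulator, target, effect)
    table; accepts a DataFrame, a path, or an iterable of row triples."""
    df = _coerce_table(edge_table, ["regulator", "target", "effect"])
    for i, row in df.iterrows():
        reg, tgt, eff = int(row.regulator), int(row.target), float(row.effect)
        if reg == tgt:
            raise ValueError(f"row {i}: self-loop on gene {reg}")
        if eff <= 0:
            raise ValueError(f"row {i}: non-positive effect {eff}")
        for g in (reg, tgt):
            if not 1 <= g <= ngene:
                raise ValueError(f"row {i}: gene id {g} outside 1..{ngene}")
    df = df.astype({"regulator": int, "target": int, "effect": float})
    tf_ids = tuple(sorted(df.regulator.unique()))
    mtg = np.zeros((len(tf_ids), ngene))
    tf_pos = {g: i for i, g in enumerate(tf_ids)}
    for row in df.itertuples():
        mtg[tf_pos[row.regulator], row.target - 1] = row.effect
    return GrnSpec(df.reset_index(drop=True), ngene, tf_ids, mtg)


@dataclass(frozen=True)
class LigRecDatabase:
    """Ligand-receptor database: ``m`` rows of (ligand, receptor, effect)."""

    rows: pd.DataFrame  # columns: ligand, receptor, effect (1-based ids)

    @property
    def m(self) -> int:
        return len(self.rows)

    @property
    def ligands(self) -> tuple[int, ...]:
        return tuple(dict.fromkeys(int(x) for x in self.rows.ligand))


def load_lr_database(table, ngene: int | None = None) -> LigRecDatabase:
    df = _coerce_table(table, ["ligand", "receptor", "effect"])
    if len(df) < 1:
        raise ValueError("ligand-receptor database must have at least one row")
    for i, row in df.iterrows():
        if float(row.effect) <= 0:
            raise ValueError(f"row {i}: non-positive effect {row.effect}")
        if ngene is not None:
            for g in (int(row.ligand), int(row.receptor)):
                if not 1 <= g <= ngene:
                    raise ValueError(f"row {i}: gene id {g} outside 1..{ngene}")
    df = df.astype({"ligand": int, "receptor": int, "effect": float})
    return LigRecDatabase(df.reset_index(drop=True))


def _coerce_table(table, columns: list[str]) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        df = table.copy()
        df.columns = columns[: len(df.columns)]
    elif isinstance(table, (str,)) or hasattr(table, "read"):
        df = pd.read_csv(table, sep="\t")
        df.columns = columns[: len(df.columns)]
    else:
        df = pd.DataFrame(list(table), columns=columns)
    if df.shape[1] != len(columns):
        raise ValueError(f"expected {len(columns)} columns, got {df.shape[1]}")
    return df


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """All user-facing simulation parameters.

    The trajectory/cluster structure is set by ``tree`` and ``population``;
    ``sigma_cif`` is the sd of per-cell scatter around the tree position,
    ``rd`` the diff-to-nondiff CIF ratio, and ``sigma_i`` the intrinsic-noise
    weight.  ``ea`` couples chromatin accessibility into the kon kinetic
    parameter; ``bimod`` and ``scale_s`` shape the kinetic parameters.
    """

    ncell: int = 500
    ngene: int = 100
    ncif: int = 50
    rd: float = 0.8
    sigma_cif: float = 0.1
    sigma_i: float = 1.0
    population: str = "continuous"  # or "discrete"
    tree: DifferentiationTree = field(default_factory=lambda: builtin_tree("Phyla5"))
    grn: GrnSpec | None = None
    lr_db: LigRecDatabase | None = None
    ea: float = 0.5
    bimod: float = 0.0
    scale_s: float = 1.0
    velocity: bool = False
    spatial: bool = False
    seed: int = 1

    # GIV / RIV mixture parameters
    giv_p_zero: float = 0.7
    giv_mean: float = 0.0
    giv_sd: float = 1.0
    riv_p_zero: float = 0.7
    riv_mean: float = 0.0
    riv_sd: float = 1.0

    # ATAC modality
    region_dist: tuple[float, float, float] = (0.1, 0.5, 0.4)
    atac_p_zero: float = 0.7
    atac_density: float = 1.0

    # spatial / CCI
    pn: float = 0.8
    nnbs: int = 4
    #: fraction of a cell's previous-step expression retained per spatial
    #: step (relaxation toward the current kinetic steady state); nonzero
    #: persistence lets CCI effects from earlier developmental stages remain
    #: visible in the final snapshot
    step_persistence: float = 0.9
    grid_capacity_pct: float = 250.0
    tc: int = 10
    layout: str = "default"  # or "layers", "islands"
    lr_pairs_range: tuple[int, int] = (3, 6)
    cell_level_fraction: float = 0.8
    same_type_cci: bool = False
    single_cell_truth: bool = False

    # cell typing resolution for continuous populations (CCI truth / affinity)
    n_type_sections: int | None = None
    sections_per_edge: int = 2

    # cell-specific GRN mode
    grn_change_rate: float = 0.0

    def __post_init__(self) -> None:
        if min(self.ncell, self.ngene, self.ncif) < 1:
            raise ValueError("ncell, ngene and ncif must be >= 1")
        if not 0.0 <= self.rd <= 1.0:
            raise ValueError("rd must be in [0, 1]")
        if self.sigma_cif < 0:
            raise ValueError("sigma_cif must be >= 0")
        if not 0.0 <= self.sigma_i <= 1.0:
            raise ValueError("sigma_i must be in [0, 1]")
        if self.population not in ("continuous", "discrete"):
            raise ValueError("population must be 'continuous' or 'discrete'")
        if not 0.0 <= self.ea <= 1.0:
            raise ValueError("ea must be in [0, 1]")
        if self.bimod < 0:
            raise ValueError("bimod must be >= 0")
        if self.scale_s <= 0:
            raise ValueError("scale_s must be > 0")
        if self.grn is not None and self.grn.ngene != self.ngene:
            self.grn = self.grn.expand(self.ngene)

    @property
    def n_diff(self) -> int:
        """Width of the diff-CIF segment, ``round(rd * ncif)``."""
        return int(round(self.rd * self.ncif))

    @property
    def n_nd(self) -> int:
        return self.ncif - self.n_diff

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Dataset grids and labels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DatasetLabel:
    """Compact dataset address, e.g. ``MD5c``: grid letter, population letter
    (main grid only), configuration index and seed letter."""

    grid: str
    pop: str | None
    config: int
    seed_letter: str

    def __str__(self) -> str:
        pop = self.pop or ""
        return f"{self.grid}{pop}{self.config}{self.seed_letter}"


_MAIN_POPS = {"L": ("Phyla1", "continuous"), "T": ("Phyla3", "continuous"), "D": ("Phyla5", "discrete")}
_MAIN_BLOCKS = [(0.1, 500), (0.1, 800), (0.5, 500), (0.5, 800)]
_MAIN_GENES = [110, 200, 500]
_SEED_LETTERS = "abcdefgh"


@lru_cache(maxsize=None)
def _grn_100() -> GrnSpec:
    from . import fixtures

    return fixtures.build_grn_100()


def _main_config(pop: str, c: int, seed: int) -> SimConfig:
    tree_name, mode = _MAIN_POPS[pop]
    sigma, ncell = _MAIN_BLOCKS[(c - 1) // 3]
    ngene = _MAIN_GENES[(c - 1) % 3]
    from . import fixtures

    return SimConfig(
        ncell=ncell,
        ngene=ngene,
        sigma_cif=sigma,
        population=mode,
        tree=builtin_tree(tree_name),
        grn=_grn_100(),
        lr_db=fixtures.build_main_cci(),
        spatial=True,
        seed=seed,
    )


def _velocity_config(c: int, seed: int) -> SimConfig:
    cells = [500, 750, 1000][(c - 1) // 6]
    ngene = [100, 200, 500][((c - 1) // 2) % 3]
    with_grn = (c - 1) % 2 == 0
    from . import fixtures

    return SimConfig(
        ncell=cells,
        ngene=ngene,
        sigma_cif=0.1,
        population="continuous",
        tree=builtin_tree("Phyla5"),
        grn=_grn_100() if with_grn else None,
        lr_db=fixtures.build_main_cci() if with_grn else None,
        spatial=with_grn,
        velocity=True,
        seed=seed,
    )


def _g_config(c: int, seed: int) -> SimConfig:
    return SimConfig(
        ncell=1000,
        ngene=[110, 500][c - 1],
        ncif=50,
        rd=0.2,
        sigma_i=1.0,
        sigma_cif=0.1,
        population="continuous",
        tree=builtin_tree("Phyla1"),
        grn=_grn_100(),
        seed=seed,
    )


def _c_config(seed: int) -> SimConfig:
    from . import fixtures

    spec = fixtures.CciFixtureSpec()
    rng = module_stream(seed, "fixtures")
    return SimConfig(
        ncell=500,
        ngene=spec.total_genes,
        ncif=50,
        sigma_cif=0.1,
        population="continuous",
        tree=builtin_tree("Phyla1"),
        grn=fixtures.build_dataset_c_grn(rng, ngene=spec.total_genes),
        lr_db=fixtures.build_dataset_c_lr(spec),
        spatial=True,
        seed=seed,
    )


def _s_config(seed: int) -> SimConfig:
    from . import fixtures

    return SimConfig(
        ncell=400,
        ngene=120,
        ncif=50,
        sigma_cif=0.1,
        population="continuous",
        tree=builtin_tree("Phyla1"),
        grn=_grn_100(),
        lr_db=fixtures.build_main_cci(),
        spatial=True,
        single_cell_truth=True,
        seed=seed,
    )


_GRIDS = {
    "main": ("M", 12, 4, 1),
    "velocity": ("V", 18, 4, 5),
    "grn_aux": ("G", 2, 8, 1),
    "cci_aux": ("C", 1, 8, 1),
    "sc_cci_aux": ("S", 1, 8, 1),
}
_LETTER_TO_GRID = {v[0]: k for k, v in _GRIDS.items()}


def enumerate_grid(grid: str) -> list[tuple[DatasetLabel, SimConfig]]:
    """Complete, deterministically ordered enumeration of one dataset grid.

    Grids: ``main`` (144 datasets), ``velocity`` (72), ``grn_aux`` (16),
    ``cci_aux`` (8), ``sc_cci_aux`` (8).
    """
    if grid not in _GRIDS:
        raise ValueError(f"unknown grid {grid!r}; valid: {sorted(_GRIDS)}")
    letter, nconf, nseed, seed0 = _GRIDS[grid]
    out: list[tuple[DatasetLabel, SimConfig]] = []
    if grid == "main":
        for pop in "LTD":
            for c in range(1, nconf + 1):
                for si in range(nseed):
                    lab = DatasetLabel("M", pop, c, _SEED_LETTERS[si])
                    out.append((lab, _main_config(pop, c, seed0 + si)))
        return out
    builder = {
        "velocity": lambda c, s: _velocity_config(c, s),
        "grn_aux": lambda c, s: _g_config(c, s),
        "cci_aux": lambda c, s: _c_config(s),
        "sc_cci_aux": lambda c, s: _s_config(s),
    }[grid]
    for c in range(1, nconf + 1):
        for si in range(nseed):
            lab = DatasetLabel(letter, None, c, _SEED_LETTERS[si])
            out.append((lab, builder(c, seed0 + si)))
    return out


def parse_label(label: str) -> DatasetLabel:
    label = label.strip()
    if len(label) < 3:
        raise ValueError(f"label {label!r} too short")
    grid = label[0]
    if grid not in _LETTER_TO_GRID:
        raise ValueError(f"unknown grid letter {grid!r} in label {label!r}")
    rest = label[1:]
    pop = None
    if grid == "M":
        pop = rest[0]
        if pop not in _MAIN_POPS:
            raise ValueError(
                f"invalid population letter {pop!r} in label {label!r} (valid: L, T, D)"
            )
        rest = rest[1:]
    seed_letter = rest[-1]
    if seed_letter not in _SEED_LETTERS:
        raise ValueError(f"invalid seed letter {seed_letter!r} in label {label!r}")
    try:
        config = int(rest[:-1])
    except ValueError:
        raise ValueError(f"invalid configuration index in label {label!r}") from None
    return DatasetLabel(grid, pop, config, seed_letter)


def resolve_dataset_label(label: str) -> SimConfig:
    """Resolve a dataset label such as ``MD5c`` to its full configuration."""
    lab = parse_label(label)
    grid = _LETTER_TO_GRID[lab.grid]
    letter, nconf, nseed, seed0 = _GRIDS[grid]
    si = _SEED_LETTERS.index(lab.seed_letter)
    if not 1 <= lab.config <= nconf or si >= nseed:
        raise ValueError(f"label {label!r} is outside the {grid} grid")
    seed = seed0 + si
    if grid == "main":
        return _main_config(lab.pop, lab.config, seed)
    return {
        "velocity": _velocity_config,
        "grn_aux": _g_config,
        "cci_aux": lambda c, s: _c_config(s),
        "sc_cci_aux": lambda c, s: _s_config(s),
    }[grid](lab.config, seed)
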