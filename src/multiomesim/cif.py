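"""Cell Identity Factors (CIFs) and Gene Identity Vectors (GIVs).

Every kinetic parameter (kon, koff, s) is generated as a product
``CIF @ GIV`` of a per-cell factor matrix and a per-gene weight matrix.
Both matrices are split into four contiguous segments:

* **non-diff** — shared environmental heterogeneity, Gaussian(1, sigma_cif);
* **diff** — tree-position structure: a Brownian field along the
  differentiation tree evaluated at each cell's position, plus per-cell
  Gaussian scatter of sd ``sigma_cif``;
* **tf** — transcription-factor coupling: entries of cell ``t`` are the
  normalised TF expression of its predecessor cell (GRN effects enter the
  s parameter only);
* **lig** — ligand coupling from spatial neighbours (CCI; s only).

The diff segment's Brownian field has variance equal to the branch distance
travelled (unit variance per unit branch length), so tree positions set the
between-population separation while ``sigma_cif`` sets the within-population
scatter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DifferentiationTree, GrnSpec

__all__ = [
    "CellMeta",
    "CifSet",
    "GivSet",
    "BrownianTreeField",
    "assign_cells",
    "sample_nondiff_cif",
    "sample_diff_cif",
    "update_tf_cif",
    "sample_giv",
    "build_diff_giv",
    "evolve_grn",
    "assemble_cif",
    "assemble_giv",
]


# ---------------------------------------------------------------------------
# Cell metadata and placement along the tree
# ---------------------------------------------------------------------------


@dataclass
class CellMeta:
    """Per-cell ground truth: assigned type, pseudotime and lineage."""

    cell_type: np.ndarray  # dtype=object, tree node / leaf / section label
    pseudotime: np.ndarray  # path distance from the root
    lineage: np.ndarray  # lineage (root-to-leaf path) index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell": np.arange(1, len(self.pseudotime) + 1),
                "type": self.cell_type,
                "pseudotime": self.pseudotime,
                "lineage": self.lineage,
            }
        )


def _lineage_tables(tree: DifferentiationTree):
    """Per lineage: node path, cumulative distances from root."""
    out = []
    for path in tree.lineages():
        dists = [0.0]
        for parent, child in zip(path, path[1:]):
            length = dict(((p, c), l) for p, c, l in tree.edges)[(parent, child)]
            dists.append(dists[-1] + length)
        out.append((path, np.asarray(dists)))
    return out


def position_type(tree: DifferentiationTree, lineage: int, dist: float,
                  n_sections: int | None = None,
                  sections_per_edge: int | None = None) -> str:
    """Cell type at a tree position.

    Default: the next node endpoint on the lineage.  ``n_sections`` switches
    to equal-width pseudotime sections over the whole tree (``sec1``...);
    ``sections_per_edge`` subdivides every branch into that many consecutive
    states (``child.k``), giving the finer type resolution used by the
    stepwise spatial simulation.
    """
    path, dists = _lineage_tables(tree)[lineage]
    if n_sections is not None:
        total = tree.max_depth()
        sec = min(int(dist / total * n_sections), n_sections - 1)
        return f"sec{sec + 1}"
    idx = int(np.searchsorted(dists, dist, side="left"))
    idx = min(max(idx, 1), len(path) - 1)
    if sections_per_edge is None or sections_per_edge <= 1:
        return path[idx]
    length = dists[idx] - dists[idx - 1]
    frac = (dist - dists[idx - 1]) / length if length > 0 else 1.0
    k = min(int(frac * sections_per_edge) + 1, sections_per_edge)
    return f"{path[idx]}.{k}"


def assign_cells(
    tree: DifferentiationTree,
    ncell: int,
    mode: str,
    rng: np.random.Generator,
    n_sections: int | None = None,
) -> tuple[CellMeta, np.ndarray]:
    """Place cells on the tree.

    Continuous mode distributes cells over root-to-leaf lineages
    proportionally to lineage length with stratified-uniform positions;
    discrete mode assigns cells to leaves round-robin.  Returns the metadata
    and the per-cell position (distance from root along its lineage).
    """
    lineages = _lineage_tables(tree)
    nlin = len(lineages)
    types = np.empty(ncell, dtype=object)
    pseudo = np.zeros(ncell)
    lin = np.zeros(ncell, dtype=int)
    pos = np.zeros(ncell)
    if mode == "discrete":
        for i in range(ncell):
            j = i % nlin
            lin[i] = j
            path, dists = lineages[j]
            types[i] = path[-1]
            pseudo[i] = dists[-1]
            pos[i] = dists[-1]
        return CellMeta(types, pseudo, lin), pos

    lengths = np.array([d[-1] for _, d in lineages], dtype=float)
    if np.all(lengths == 0):
        lengths = np.ones(nlin)
    alloc = _largest_remainder(lengths / lengths.sum() * ncell)
    i = 0
    for j, (path, dists) in enumerate(lineages):
        nj = alloc[j]
        if nj == 0:
            continue
        # stratified-uniform positions along the lineage
        u = (np.arange(nj) + rng.uniform(0, 1, nj)) / nj
        d = u * dists[-1]
        for dj in np.sort(d):
            lin[i] = j
            pos[i] = dj
            pseudo[i] = dj
            types[i] = position_type(tree, j, dj, n_sections)
            i += 1
    return CellMeta(types, pseudo, lin), pos


def _largest_remainder(x: np.ndarray) -> np.ndarray:
    base = np.floor(x).astype(int)
    short = int(round(x.sum())) - base.sum()
    order = np.argsort(-(x - base))
    base[order[:short]] += 1
    return base


# ---------------------------------------------------------------------------
# diff-CIF: Brownian field along the tree
# ---------------------------------------------------------------------------


class BrownianTreeField:
    """One realisation of a Gaussian random walk along a differentiation tree.

    Every edge is discretised into sub-steps of at most ``step`` branch-length
    units; independent Gaussian increments with variance equal to the
    sub-step length are accumulated from the root.  Evaluating the field at
    the same (lineage, distance) position always returns the same value, a
    property required by the stepwise spatial simulation.
    """

    def __init__(self, tree: DifferentiationTree, ndim: int,
                 rng: np.random.Generator, step: float = 0.1) -> None:
        self.tree = tree
        self.ndim = ndim
        node_val: dict[str, np.ndarray] = {tree.root: np.zeros(ndim)}
        edge_grid: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        for parent, child, length in tree.edges:
            nsub = max(1, int(np.ceil(length / step))) if length > 0 else 1
            ds = np.full(nsub, length / nsub)
            incr = rng.normal(0.0, np.sqrt(np.maximum(ds, 1e-300))[:, None],
                              size=(nsub, ndim))
            vals = node_val[parent] + np.cumsum(incr, axis=0)
            grid = np.concatenate([[0.0], np.cumsum(ds)])
            edge_grid[(parent, child)] = (grid, np.vstack([node_val[parent], vals]))
            node_val[child] = vals[-1]
        self._node_val = node_val
        self._edge_grid = edge_grid
        self._lineages = _lineage_tables(tree)

    def at(self, lineage: int, dist: float) -> np.ndarray:
        """Field value at distance ``dist`` from the root along a lineage."""
        path, dists = self._lineages[lineage]
        if dist <= 0 or len(path) == 1:
            return self._node_val[self.tree.root].copy()
        dist = min(dist, dists[-1])
        seg = int(np.searchsorted(dists, dist, side="left"))
        seg = min(max(seg, 1), len(path) - 1)
        parent, child = path[seg - 1], path[seg]
        local = dist - dists[seg - 1]
        grid, vals = self._edge_grid[(parent, child)]
        j = int(np.searchsorted(grid, local, side="left"))
        j = min(max(j, 1), len(grid) - 1)
        span = grid[j] - grid[j - 1]
        w = (local - grid[j - 1]) / span if span > 0 else 0.0
        return vals[j - 1] + w * (vals[j] - vals[j - 1])

    def at_node(self, node: str) -> np.ndarray:
        return self._node_val[node].copy()


def sample_nondiff_cif(ncell: int, n_nd: int, sigma_cif: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Non-diff CIF segment: i.i.d. Gaussian(1, sigma_cif)."""
    if sigma_cif < 0:
        raise ValueError("sigma_cif must be >= 0")
    if n_nd < 0:
        raise ValueError("n_nd must be >= 0")
    return rng.normal(1.0, sigma_cif, size=(ncell, n_nd))


def sample_diff_cif(
    tree: DifferentiationTree,
    ncell: int,
    n_diff: int,
    sigma_cif: float,
    mode: str,
    rng: np.random.Generator,
    meta_pos: tuple[CellMeta, np.ndarray] | None = None,
    field: BrownianTreeField | None = None,
    scatter: np.ndarray | None = None,
) -> tuple[np.ndarray, CellMeta]:
    """diff-CIF segment plus the cell metadata that positioned it.

    Cell positions, the Brownian field and the per-cell scatter can all be
    supplied to share them across the three kinetic-parameter copies or
    across spatial time steps.
    """
    if mode == "continuous" and n_diff == 0:
        warnings.warn("n_diff=0 in continuous mode: the trajectory will not "
                      "be encoded in the CIF", stacklevel=2)
    if meta_pos is None:
        meta_pos = assign_cells(tree, ncell, mode, rng)
    meta, pos = meta_pos
    if field is None:
        field = BrownianTreeField(tree, n_diff, rng)
    if scatter is None:
        scatter = rng.normal(0.0, sigma_cif, size=(ncell, n_diff))
    mat = np.empty((ncell, n_diff))
    for i in range(ncell):
        if mode == "discrete":
            base = field.at_node(str(meta.cell_type[i]))
        else:
            base = field.at(int(meta.lineage[i]), float(pos[i]))
        mat[i] = base + scatter[i]
    return mat, meta


# ---------------------------------------------------------------------------
# tf-CIF (GRN coupling)
# ---------------------------------------------------------------------------


def update_tf_cif(prev_expression: np.ndarray, tf_ids) -> np.ndarray:
    """TF segment of a cell's CIF from its predecessor's expression.

    Entry i is ``x_i / (x_i + mean_TF(x))`` where the mean runs over the TF
    genes; an all-zero TF expression yields all zeros (zero expression exerts
    zero regulation).  Values always lie in [0, 1).
    """
    x = np.asarray(prev_expression, dtype=float)
    if np.any(x < 0):
        raise ValueError("expression must be nonnegative")
    idx = np.asarray(tf_ids, dtype=int) - 1
    xt = x[idx]
    mean = xt.mean() if len(xt) else 0.0
    denom = xt + mean
    out = np.zeros(len(xt))
    nz = denom > 0
    out[nz] = xt[nz] / denom[nz]
    return out


# ---------------------------------------------------------------------------
# GIVs
# ---------------------------------------------------------------------------


def sample_giv(n_rows: int, n_cols: int, p0: float, giv_mean: float,
               giv_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-inflated Gaussian GIV block: 0 w.p. ``p0``, else
    Gaussian(giv_mean, giv_sd)."""
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be in [0, 1]")
    vals = rng.normal(giv_mean, giv_sd, size=(n_rows, n_cols))
    mask = rng.uniform(size=(n_rows, n_cols)) < p0
    vals[mask] = 0.0
    return vals


def build_diff_giv(
    grn: GrnSpec,
    n_diff: int,
    rng: np.random.Generator,
    small: float = 0.2,
    p0: float = 0.7,
    giv_mean: float = 0.0,
    giv_sd: float = 1.0,
) -> np.ndarray:
    """diff segment of the s-parameter GIV, tying targets to their TFs.

    Each TF gene's column gets exactly two nonzero entries at a fixed small
    magnitude (``small``); each pure-target column is the TF-block product
    with its column of the GRN effect matrix; genes that are both TF and
    target get the average of the two constructions.  Unregulated genes fall
    back to the zero-inflated Gaussian block.
    """
    if n_diff < 2:
        raise ValueError("n_diff must be >= 2 to place two entries per TF")
    ngene, n_tf = grn.ngene, grn.n_tf
    tf_block = np.zeros((n_diff, n_tf))  # step (1)
    for j in range(n_tf):
        rows = rng.choice(n_diff, size=2, replace=False)
        tf_block[rows, j] = small
    target_block = tf_block @ grn.mtg  # step (2), n_diff x ngene

    out = sample_giv(n_diff, ngene, p0, giv_mean, giv_sd, rng)
    tf_pos = grn.tf_index()
    targets = set(int(t) for t in grn.edges.target)
    for g in range(1, ngene + 1):
        is_tf, is_target = g in tf_pos, g in targets
        if is_tf and is_target:
            out[:, g - 1] = 0.5 * (tf_block[:, tf_pos[g]] + target_block[:, g - 1])
        elif is_tf:
            out[:, g - 1] = tf_block[:, tf_pos[g]]
        elif is_target:
            out[:, g - 1] = target_block[:, g - 1]
    return out


# ---------------------------------------------------------------------------
# Cell-specific (evolving) GRN mode
# ---------------------------------------------------------------------------


def evolve_grn(
    grn: GrnSpec,
    ncell: int,
    change_rate: float,
    rng: np.random.Generator,
    allow_add: bool = True,
    allow_delete: bool = True,
) -> list[GrnSpec]:
    """Per-cell GRN series: edges appear/disappear gradually along pseudotime.

    Cell 1 uses the input GRN; in each subsequent cell every existing edge is
    deleted with probability ``change_rate`` and every absent
    regulator-target pair is created with probability ``change_rate`` scaled
    by the input edge density (keeping the expected density stable).
    """
    if change_rate < 0:
        raise ValueError("change_rate must be >= 0")
    ngene, tf_ids = grn.ngene, list(grn.tf_ids)
    possible = [
        (t, g) for t in tf_ids for g in range(1, ngene + 1) if g != t
    ]
    density = len(grn.edges) / max(len(possible), 1)
    current = {(int(r.regulator), int(r.target)): float(r.effect)
               for r in grn.edges.itertuples()}
    mean_eff = float(np.mean(list(current.values()))) if current else 1.0
    series = [grn]
    for _ in range(1, ncell):
        if change_rate > 0:
            if allow_delete and current:
                keep = {}
                for edge, eff in current.items():
                    if rng.uniform() >= change_rate:
                        keep[edge] = eff
                current = keep
            if allow_add:
                p_add = change_rate * density
                for edge in possible:
                    if edge not in current and rng.uniform() < p_add:
                        current[edge] = mean_eff
        rows = [(r, t, e) for (r, t), e in sorted(current.items())]
        df = pd.DataFrame(rows, columns=["regulator", "target", "effect"])
        mtg = np.zeros((len(tf_ids), ngene))
        tf_pos = {g: i for i, g in enumerate(tf_ids)}
        for r, t, e in rows:
            mtg[tf_pos[r], t - 1] = e
        # the TF list stays fixed so downstream tf-CIF widths never change
        series.append(GrnSpec(df, ngene, tuple(tf_ids), mtg))
    return series


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


@dataclass
class CifSet:
    """Per-kinetic-parameter CIF matrices with their segment layout."""

    kon: np.ndarray
    koff: np.ndarray
    s: np.ndarray
    widths: tuple[int, int, int, int]  # (n_nd, n_diff, n_tf, n_lig)

    def __post_init__(self) -> None:
        total = sum(self.widths)
        for name in ("kon", "koff", "s"):
            m = getattr(self, name)
            if m.shape[1] != total:
                raise ValueError(f"{name} CIF width {m.shape[1]} != {total}")

    @property
    def ncif_total(self) -> int:
        return sum(self.widths)


@dataclass
class GivSet:
    kon: np.ndarray
    koff: np.ndarray
    s: np.ndarray
    widths: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        total = sum(self.widths)
        for name in ("kon", "koff", "s"):
            m = getattr(self, name)
            if m.shape[0] != total:
                raise ValueError(f"{name} GIV height {m.shape[0]} != {total}")


def assemble_cif(nondiff, diff, tf, lig) -> np.ndarray:
    """Concatenate CIF segments (non-diff, diff, tf, lig) for one parameter."""
    segs = [np.atleast_2d(s) for s in (nondiff, diff, tf, lig)]
    ncells = {s.shape[0] for s in segs}
    if len(ncells) > 1:
        raise ValueError(f"segment cell counts disagree: {sorted(ncells)}")
    return np.hstack(segs)


def assemble_giv(nondiff, diff, tf, lig) -> np.ndarray:
    """Concatenate GIV segments for one parameter (rows = CIF dimensions)."""
    segs = [np.atleast_2d(s) for s in (nondiff, diff, tf, lig)]
    ngenes = {s.shape[1] for s in segs}
    if len(ngenes) > 1:
        raise ValueError(f"segment gene counts disagree: {sorted(ngenes)}")
    return np.vstack(segs)
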