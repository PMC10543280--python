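"""Stepwise spatial simulation with cell-cell interactions.

Cells live on a k x k grid; one cell is born per step (at the root of the
differentiation tree) and is placed with a same-type affinity ``pn``, or via
the ``layers``/``islands`` pre-layouts.  After all n cells are placed the
simulation continues for ``tc`` settling steps.  At every step each placed
cell advances along the differentiation tree and its expression is
re-simulated: its TF coupling is inherited from its own previous step and its
ligand coupling comes from the previous-step expression of its grid
neighbours (at most ``nnbs`` = 4, within the neighbourhood radius), masked by
the sampled CCI ground truth.  Only the final step is emitted, carrying the
accumulated CCI effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import LigRecDatabase, SimConfig, module_stream
from .cif import BrownianTreeField, CellMeta, position_type, update_tf_cif

__all__ = [
    "SpatialState",
    "CciTruth",
    "init_grid",
    "place_cell",
    "prelayout",
    "neighbors",
    "sample_cci_truth",
    "sample_cell_level_truth",
    "build_lig_cif",
    "lig_effect_giv",
    "run_spatial_simulation",
    "cci_correlation_check",
]


# ---------------------------------------------------------------------------
# Grid
# ---------------------------------------------------------------------------


@dataclass
class SpatialState:
    """Occupancy of the k x k grid plus neighbourhood parameters."""

    k: int
    nnbs: int = 4
    radius: float = 1.0
    positions: dict[int, tuple[int, int]] = field(default_factory=dict)
    occupancy: dict[tuple[int, int], int] = field(default_factory=dict)

    def free_positions(self) -> list[tuple[int, int]]:
        return [
            (r, c)
            for r in range(self.k)
            for c in range(self.k)
            if (r, c) not in self.occupancy
        ]

    def place(self, cell: int, pos: tuple[int, int]) -> None:
        if pos in self.occupancy:
            raise ValueError(f"position {pos} already occupied")
        if not (0 <= pos[0] < self.k and 0 <= pos[1] < self.k):
            raise ValueError(f"position {pos} outside the {self.k}x{self.k} grid")
        self.positions[cell] = pos
        self.occupancy[pos] = cell


def init_grid(ncell: int, capacity_pct: float = 250.0, nnbs: int = 4,
              radius: float = 1.0) -> SpatialState:
    """Empty grid with capacity ``capacity_pct`` percent of the cell count
    (default 250%), i.e. side ``k = ceil(sqrt(capacity_pct/100 * ncell))``."""
    if ncell < 1:
        raise ValueError("ncell must be >= 1")
    if capacity_pct < 100.0:
        raise ValueError("grid capacity below 100% cannot fit the cells")
    k = int(math.ceil(math.sqrt(capacity_pct / 100.0 * ncell)))
    return SpatialState(k=k, nnbs=nnbs, radius=radius)


_ADJ = [(-1, 0), (1, 0), (0, -1), (0, 1)]  # up, down, left, right


def place_cell(state: SpatialState, cell: int, cell_type,
               cell_types: dict[int, object], pn: float,
               rng: np.random.Generator) -> tuple[int, int]:
    """Place a newborn cell: with probability ``pn`` next to a same-type
    cell (uniform over free adjacent slots, falling back to uniform free when
    none exists), else at a uniform free position."""
    free = state.free_positions()
    if not free:
        raise ValueError("grid is full")
    pos = None
    if rng.uniform() < pn:
        candidates = sorted(
            {
                (r + dr, c + dc)
                for (r, c), occ in state.occupancy.items()
                if cell_types.get(occ) == cell_type
                for dr, dc in _ADJ
                if 0 <= r + dr < state.k and 0 <= c + dc < state.k
                and (r + dr, c + dc) not in state.occupancy
            }
        )
        if candidates:
            pos = candidates[rng.integers(len(candidates))]
    if pos is None:
        pos = free[rng.integers(len(free))]
    state.place(cell, pos)
    return pos


def neighbors(state: SpatialState, cell: int) -> list[int]:
    """Up to ``nnbs`` nearest occupied positions within the radius.

    Deterministic ordering: distance first, then up/down/left/right, then
    row/column offsets.  At radius 1 this is exact 4-adjacency (a diagonal
    cell is not a neighbour).
    """
    r0, c0 = state.positions[cell]
    found = []
    rmax = int(math.floor(state.radius))
    for (r, c), occ in state.occupancy.items():
        if occ == cell:
            continue
        dr, dc = r - r0, c - c0
        if abs(dr) > rmax or abs(dc) > rmax:
            continue
        dist = math.hypot(dr, dc)
        if dist <= state.radius + 1e-12:
            prio = _ADJ.index((np.sign(dr), np.sign(dc))) if (
                (np.sign(dr), np.sign(dc)) in _ADJ and dist == abs(dr) + abs(dc)
            ) else len(_ADJ)
            found.append((dist, prio, dr, dc, occ))
    found.sort(key=lambda t: t[:4])
    return [occ for *_, occ in found[: state.nnbs]]


def prelayout(layout: str, final_types: list, state: SpatialState,
              rng: np.random.Generator, pn: float = 0.8,
              island_types: list | None = None,
              randomize_frac: float = 0.05) -> None:
    """Pre-assign all cell positions for the ``layers`` or ``islands`` layout.

    ``layers``: cells sorted by type are grown one blob at a time so
    same-type cells form contiguous bands.  ``islands``: the designated types
    are grown as contiguous blobs first, the remaining cells placed with
    affinity ``pn``.  Finally a small fraction of cells have their locations
    shuffled.
    """
    if layout not in ("layers", "islands"):
        raise ValueError("layout must be 'layers' or 'islands'")
    ncell = len(final_types)
    if ncell > state.k * state.k:
        raise ValueError("cells exceed grid capacity")
    order: list[int]
    if layout == "layers":
        order = sorted(range(ncell), key=lambda i: str(final_types[i]))
        for i in order:
            _grow_adjacent(state, i, rng)
    else:
        if island_types is None:
            island_types = [sorted(set(map(str, final_types)))[0]]
        island_types = set(map(str, island_types))
        islanders = [i for i in range(ncell) if str(final_types[i]) in island_types]
        others = [i for i in range(ncell) if str(final_types[i]) not in island_types]
        for t in sorted(island_types):
            for i in [j for j in islanders if str(final_types[j]) == t]:
                _grow_adjacent(state, i, rng, restrict_type=t,
                               cell_types={j: str(final_types[j])
                                           for j in state.positions})
        types_so_far = {j: str(final_types[j]) for j in state.positions}
        for i in others:
            place_cell(state, i, str(final_types[i]), types_so_far, pn, rng)
            types_so_far[i] = str(final_types[i])
    if randomize_frac > 0:
        nshuf = int(round(randomize_frac * ncell))
        if nshuf >= 2:
            chosen = rng.choice(ncell, size=nshuf, replace=False)
            pos = [state.positions[i] for i in chosen]
            perm = rng.permutation(nshuf)
            for i, p in zip(chosen, (pos[j] for j in perm)):
                del state.occupancy[state.positions[i]]
            for i, j in zip(chosen, perm):
                state.positions[int(i)] = pos[j]
                state.occupancy[pos[j]] = int(i)


def _grow_adjacent(state: SpatialState, cell: int, rng: np.random.Generator,
                   restrict_type: str | None = None,
                   cell_types: dict | None = None) -> None:
    """Place a cell uniformly among free slots adjacent to the existing blob
    (adjacent to same-type cells when ``restrict_type`` is given)."""
    if not state.occupancy:
        mid = state.k // 2
        pos = (mid, mid) if restrict_type is None else (
            rng.integers(state.k), rng.integers(state.k))
        state.place(cell, tuple(int(x) for x in pos))
        return
    anchors = state.occupancy.items()
    if restrict_type is not None and cell_types:
        typed = [(p, o) for p, o in anchors if cell_types.get(o) == restrict_type]
        anchors = typed or list(state.occupancy.items())
    candidates = sorted(
        {
            (r + dr, c + dc)
            for (r, c), _ in anchors
            for dr, dc in _ADJ
            if 0 <= r + dr < state.k and 0 <= c + dc < state.k
            and (r + dr, c + dc) not in state.occupancy
        }
    )
    if not candidates:
        candidates = state.free_positions()
        if not candidates:
            raise ValueError("grid is full")
    state.place(cell, candidates[rng.integers(len(candidates))])


# ---------------------------------------------------------------------------
# CCI ground truth
# ---------------------------------------------------------------------------


@dataclass
class CciTruth:
    """CCI ground truth at cell-type level and (optionally) single-cell level.

    ``type_level`` maps an ordered type pair (sorted lexicographically) to
    the tuple of active ligand-receptor row indices (0-based into the LR
    database); ``cell_level`` holds (cell i, cell j, row) triples with i < j.
    """

    type_level: dict[tuple[str, str], tuple[int, ...]]
    cell_level: set[tuple[int, int, int]] = field(default_factory=set)
    fraction: float = 0.8

    def rows_for_types(self, a, b) -> tuple[int, ...]:
        key = tuple(sorted((str(a), str(b))))
        return self.type_level.get(key, ())

    def type_frame(self) -> pd.DataFrame:
        rows = [
            (a, b, r)
            for (a, b), rr in sorted(self.type_level.items())
            for r in rr
        ]
        return pd.DataFrame(rows, columns=["type_a", "type_b", "lr_row"])

    def cell_frame(self) -> pd.DataFrame:
        rows = sorted(self.cell_level)
        return pd.DataFrame(rows, columns=["cell_i", "cell_j", "lr_row"])


def sample_cci_truth(lr_db: LigRecDatabase, cell_types, rng: np.random.Generator,
                     pairs_range: tuple[int, int] = (3, 6),
                     include_same_type: bool = False) -> CciTruth:
    """Type-level truth: for each unordered type pair, a uniform
    without-replacement sample of LR rows of size drawn from
    ``pairs_range``."""
    lo, hi = pairs_range
    if not 1 <= lo <= hi:
        raise ValueError("invalid pairs range")
    if hi > lr_db.m:
        raise ValueError(f"pairs range {pairs_range} exceeds database size {lr_db.m}")
    types = sorted(set(map(str, cell_types)))
    truth: dict[tuple[str, str], tuple[int, ...]] = {}
    for i, a in enumerate(types):
        for b in types[i if include_same_type else i + 1:]:
            size = int(rng.integers(lo, hi + 1))
            rows = rng.choice(lr_db.m, size=size, replace=False)
            truth[(a, b)] = tuple(sorted(int(r) for r in rows))
    return CciTruth(truth)


def sample_cell_level_truth(type_truth: CciTruth, neighbor_pairs,
                            cell_types: dict[int, object], fraction: float,
                            rng: np.random.Generator) -> set[tuple[int, int, int]]:
    """Uniform sample of exactly ``round(fraction * total)`` of the
    (neighbouring cell pair, LR row) edges implied by the type-level truth."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    implied = []
    for i, j in neighbor_pairs:
        a, b = cell_types[i], cell_types[j]
        for r in type_truth.rows_for_types(a, b):
            implied.append((min(i, j), max(i, j), r))
    implied = sorted(set(implied))
    size = int(round(fraction * len(implied)))
    if size == 0:
        return set()
    chosen = rng.choice(len(implied), size=size, replace=False)
    return {implied[c] for c in chosen}


# ---------------------------------------------------------------------------
# Ligand CIF / GIV
# ---------------------------------------------------------------------------


def build_lig_cif(neighbor_slots, prev_expr: np.ndarray, cell: int,
                  active_rows, lr_db: LigRecDatabase, nnbs: int) -> np.ndarray:
    """lig-CIF segment of one cell (length m * nnbs).

    For neighbour slot j occupied by cell c, the entry of LR row k is the
    normalised ligand expression of c at the previous step,
    ``x_l / (x_l + mean over ligand genes of x)``, if row k is active in the
    CCI truth for the pair (c, cell); empty slots and inactive rows are 0.
    """
    m = lr_db.m
    ligs = np.asarray(lr_db.rows.ligand, dtype=int) - 1
    lig_set = np.asarray(sorted(set(ligs)), dtype=int)
    seg = np.zeros(m * nnbs)
    for j, c in enumerate(neighbor_slots[:nnbs]):
        if c is None:
            continue
        x = prev_expr[c]
        lig_mean = float(x[lig_set].mean()) if lig_set.size else 0.0
        rows = active_rows(c, cell)
        for k in rows:
            xl = float(x[ligs[k]])
            denom = xl + lig_mean
            if denom > 0:
                seg[j * m + k] = xl / denom
    return seg


def lig_effect_giv(lr_db: LigRecDatabase, ngene: int, nnbs: int) -> np.ndarray:
    """lig segment of the s-parameter GIV: the CCI effect matrix.

    Row ``j*m + k`` carries the effect of LR row k at the receptor gene's
    column, replicated for every neighbour slot j.
    """
    m = lr_db.m
    out = np.zeros((m * nnbs, ngene))
    for k, row in enumerate(lr_db.rows.itertuples()):
        rec = int(row.receptor) - 1
        for j in range(nnbs):
            out[j * m + k, rec] = float(row.effect)
    return out


# ---------------------------------------------------------------------------
# The stepwise simulation
# ---------------------------------------------------------------------------


def run_spatial_simulation(config: SimConfig):
    """Full spatial simulation; returns a :class:`multiomesim.SimResult`.

    Placement (n steps) is followed by ``tc`` settling steps.  Cell types
    used for placement affinity and for the CCI truth are the cells' final
    developmental types, which are known upfront because each cell's path
    along the tree is drawn at birth.
    """
    from .simulate import SimResult, build_givs, get_reference

    if config.lr_db is None:
        raise ValueError("spatial simulation requires a ligand-receptor database")
    cfg = config
    rng_sp = module_stream(cfg.seed, "spatial")
    rng_cif = module_stream(cfg.seed, "cif")
    rng_giv = module_stream(cfg.seed, "giv")
    rng_kin = module_stream(cfg.seed, "kinetics")
    rng_expr = module_stream(cfg.seed, "expression")
    rng_atac = module_stream(cfg.seed, "atac")

    tree, ncell, ngene = cfg.tree, cfg.ncell, cfg.ngene
    total_steps = ncell + cfg.tc
    n_sections = cfg.n_type_sections

    # --- developmental paths -------------------------------------------
    lineage, pos_by_step, type_by_step = _draw_paths(cfg, total_steps, rng_sp,
                                                     n_sections)
    final_types = [type_by_step[i][total_steps - 1] for i in range(ncell)]

    # --- CCI truth -------------------------------------------------------
    all_types = sorted(set(map(str, final_types)))
    lo, hi = cfg.lr_pairs_range
    pairs_range = (min(lo, cfg.lr_db.m), min(hi, cfg.lr_db.m))
    type_truth = sample_cci_truth(cfg.lr_db, all_types, rng_sp,
                                  pairs_range=pairs_range,
                                  include_same_type=cfg.same_type_cci)

    # --- placement -------------------------------------------------------
    state = init_grid(ncell, cfg.grid_capacity_pct, nnbs=cfg.nnbs)
    if cfg.layout in ("layers", "islands"):
        prelayout(cfg.layout, final_types, state, rng_sp, pn=cfg.pn)
    else:
        types_placed: dict[int, object] = {}
        for i in range(ncell):
            place_cell(state, i, str(final_types[i]), types_placed, cfg.pn, rng_sp)
            types_placed[i] = str(final_types[i])

    nb_lists = {i: neighbors(state, i) for i in range(ncell)}
    nb_pairs = sorted({(min(i, j), max(i, j)) for i, nl in nb_lists.items()
                       for j in nl})
    cell_truth = sample_cell_level_truth(
        type_truth, nb_pairs, dict(enumerate(map(str, final_types))),
        cfg.cell_level_fraction, rng_sp)
    truth = CciTruth(type_truth.type_level, cell_truth, cfg.cell_level_fraction)

    def active_rows_at(t):
        """Interaction mask at step t: rows active for the cells' *current*
        types (CCI follows the developmental state, so effects from earlier
        stages persist into the final snapshot); under single-cell truth the
        pre-determined cell-level sample additionally gates each pair."""

        def fn(c, cell):
            rows = type_truth.rows_for_types(type_by_step[c][t],
                                             type_by_step[cell][t])
            if cfg.single_cell_truth:
                a, b = min(c, cell), max(c, cell)
                rows = [r for r in rows if (a, b, r) in cell_truth]
            return rows

        return fn

    # --- static model pieces --------------------------------------------
    grn = cfg.grn
    n_tf = grn.n_tf if grn is not None else 0
    m_lig = cfg.lr_db.m
    n_lig_seg = m_lig * cfg.nnbs
    widths = (cfg.n_nd, cfg.n_diff, n_tf, n_lig_seg)
    givs = build_givs(cfg, rng_giv, n_lig_seg=n_lig_seg)
    ref = get_reference(cfg)

    field_kon = BrownianTreeField(tree, cfg.n_diff, rng_cif)
    field_koff = BrownianTreeField(tree, cfg.n_diff, rng_cif)
    field_s = BrownianTreeField(tree, cfg.n_diff, rng_cif)
    static = {}
    for name in ("kon", "koff", "s"):
        static[name] = {
            "nd": rng_cif.normal(1.0, cfg.sigma_cif, size=(ncell, cfg.n_nd)),
            "scatter": rng_cif.normal(0.0, cfg.sigma_cif, size=(ncell, cfg.n_diff)),
            # tf/lig CIF for kon and koff are static Gaussian draws
            "tf": rng_cif.normal(1.0, cfg.sigma_cif, size=(ncell, n_tf)),
            "lig": rng_cif.normal(1.0, cfg.sigma_cif, size=(ncell, n_lig_seg)),
        }
    fields = {"kon": field_kon, "koff": field_koff, "s": field_s}

    def diff_cif(name, step_idx):
        f = fields[name]
        out = np.empty((ncell, cfg.n_diff))
        for i in range(ncell):
            t = min(step_idx, total_steps - 1)
            if cfg.population == "discrete":
                out[i] = f.at_node(str(type_by_step[i][t]))
            else:
                out[i] = f.at(lineage[i], pos_by_step[i][t])
        return out + static[name]["scatter"]

    # --- stepping --------------------------------------------------------
    prev_expr = np.zeros((ncell, ngene))
    tf_root = rng_cif.normal(1.0, cfg.sigma_cif, size=(ncell, n_tf))
    expr = prev_expr
    born = np.zeros(ncell, dtype=bool)
    for t in range(total_steps):
        if t < ncell:
            born[t] = True
        alive = np.where(born)[0]
        dm_kon = diff_cif("kon", t)
        dm_koff = diff_cif("koff", t)
        dm_s = diff_cif("s", t)
        cif_kon = np.hstack([static["kon"]["nd"], dm_kon, static["kon"]["tf"],
                             static["kon"]["lig"]])
        cif_koff = np.hstack([static["koff"]["nd"], dm_koff,
                              static["koff"]["tf"], static["koff"]["lig"]])
        # dynamic s segments
        tf_seg = np.zeros((ncell, n_tf))
        lig_seg = np.zeros((ncell, n_lig_seg))
        for i in alive:
            if t == i or (grn is None):
                tf_seg[i] = tf_root[i]
            else:
                tf_seg[i] = update_tf_cif(prev_expr[i], grn.tf_ids) \
                    if n_tf else tf_root[i]
            if t > 0:
                slots = [c if born[c] else None for c in nb_lists[i]]
                slots += [None] * (cfg.nnbs - len(slots))
                lig_seg[i] = build_lig_cif(slots, prev_expr, i,
                                           active_rows_at(t), cfg.lr_db,
                                           cfg.nnbs)
        cif_s = np.hstack([static["s"]["nd"], dm_s, tf_seg, lig_seg])

        from .kinetics import assemble_koff, assemble_kon, assemble_s

        sub = alive
        M1 = cif_kon[sub] @ givs.kon
        M2 = cif_koff[sub] @ givs.koff
        M3 = cif_s[sub] @ givs.s
        kon = assemble_kon(M1, None, None, 0.0, ref.kon, rng_kin)
        kon /= 10.0 ** cfg.bimod
        koff = assemble_koff(M2, cfg.bimod, ref.koff, rng_kin)
        s = assemble_s(M3, cfg.scale_s, ref.s, rng_kin)
        # expression relaxes toward the current steady state instead of
        # re-equilibrating instantly, so effects from earlier developmental
        # stages persist into later steps
        expr = np.zeros((ncell, ngene))
        target = s * kon / (kon + koff)
        lam = cfg.step_persistence
        for row_i, i in enumerate(sub):
            if t == i:
                expr[i] = target[row_i]
            else:
                expr[i] = lam * prev_expr[i] + (1 - lam) * target[row_i]
        prev_expr = expr

    # --- final step: ATAC coupling and sampled counts --------------------
    from .atac import (default_atac_reference, derive_motif_matrix,
                       generate_region_to_gene, sample_riv, simulate_atac)
    from .kinetics import assemble_kon as _akon, assemble_koff as _akoff, \
        assemble_s as _as

    Z, nregion = generate_region_to_gene(ngene, cfg.region_dist, rng_atac)
    riv = sample_riv(sum(widths), nregion, cfg.riv_p_zero, cfg.riv_mean,
                     cfg.riv_sd, rng_atac)
    atac_ref = default_atac_reference(p_zero=cfg.atac_p_zero,
                                      density=cfg.atac_density,
                                      rng=rng_atac)
    accessibility = simulate_atac(cif_kon, riv, atac_ref, rng_atac)
    mtr = derive_motif_matrix(grn.mtg, Z) if grn is not None else \
        np.zeros((0, nregion))

    M1 = cif_kon @ givs.kon
    M2 = cif_koff @ givs.koff
    M3 = cif_s @ givs.s
    kon = _akon(M1, accessibility, Z, cfg.ea, ref.kon, rng_kin) / 10 ** cfg.bimod
    koff = _akoff(M2, cfg.bimod, ref.koff, rng_kin)
    s = _as(M3, cfg.scale_s, ref.s, rng_kin)

    # sampled counts are centred on the relaxed (history-carrying) expression:
    # s is rescaled so the Beta-Poisson mean equals the final-step expression
    from .expression import beta_poisson_counts
    target = s * kon / (kon + koff)
    ratio = np.where(target > 0, prev_expr / target, 1.0)
    s_eff = np.maximum(s * ratio, 1e-12)
    counts = beta_poisson_counts(kon, koff, s_eff, cfg.sigma_i, rng_expr)

    meta = CellMeta(
        cell_type=np.array([str(x) for x in final_types], dtype=object),
        pseudotime=np.array([pos_by_step[i][total_steps - 1] for i in range(ncell)]),
        lineage=np.asarray(lineage),
    )
    from .atac import AtacProfile
    from .kinetics import KineticParams

    return SimResult(
        config=cfg,
        counts=counts,
        meta=meta,
        kinetics=KineticParams(kon, koff, s),
        atac=AtacProfile(accessibility, Z, mtr, cfg.region_dist, cfg.ea),
        spatial_state=state,
        cci_truth=truth,
    )


def _draw_paths(cfg: SimConfig, total_steps: int, rng: np.random.Generator,
                n_sections):
    """Per-cell developmental path: lineage, position and type per step."""
    tree = cfg.tree
    lineages = tree.lineages()
    depth = tree.max_depth()
    step_adv = depth / cfg.ncell if cfg.ncell else depth
    lineage = np.zeros(cfg.ncell, dtype=int)
    pos_by_step = np.zeros((cfg.ncell, total_steps))
    type_by_step: list[list] = []
    children = tree.children_map
    for i in range(cfg.ncell):
        if cfg.population == "discrete":
            lineage[i] = i % len(lineages)
            leaf = lineages[lineage[i]][-1]
            type_by_step.append([leaf] * total_steps)
            pos_by_step[i, :] = tree.depth(leaf)
            continue
        # walk: at each junction choose a child uniformly
        node = tree.root
        path = [node]
        while children[node]:
            node = children[node][int(rng.integers(len(children[node])))]
            path.append(node)
        lineage[i] = next(
            j for j, lp in enumerate(lineages) if lp[: len(path)] == path
        )
        li_len = tree.depth(path[-1])
        types = []
        for t in range(total_steps):
            d = min(max(t - i, 0) * step_adv, li_len)
            pos_by_step[i, t] = d
            types.append(position_type(tree, int(lineage[i]), d, n_sections,
                                       cfg.sections_per_edge))
        type_by_step.append(types)
    return lineage, pos_by_step, type_by_step


# ---------------------------------------------------------------------------
# Correlation validation
# ---------------------------------------------------------------------------


def cci_correlation_check(result, lr_row: int, rng: np.random.Generator
                          ) -> tuple[float, float, float]:
    """Pearson correlations of ligand-receptor expression over (i) neighbour
    pairs with CCI, (ii) neighbour pairs without CCI, (iii) random
    non-adjacent pairs; same-type cell pairs are excluded throughout."""
    lr_db = result.config.lr_db
    if lr_row < 0 or lr_row >= lr_db.m:
        raise ValueError(f"lr_row {lr_row} not in database of size {lr_db.m}")
    lig = int(lr_db.rows.ligand[lr_row]) - 1
    rec = int(lr_db.rows.receptor[lr_row]) - 1
    x = result.counts
    state = result.spatial_state
    truth = result.cci_truth
    types = result.meta.cell_type
    ncell = x.shape[0]
    cci_pairs, noncci_pairs, far_pairs = [], [], []
    for i in range(ncell):
        nl = neighbors(state, i)
        far = [int(c) for c in rng.choice(ncell, size=min(4 + len(nl) + 1, ncell),
                                          replace=False)
               if c != i and c not in nl][:4]
        for j in nl:
            if types[i] == types[j]:
                continue
            key = (min(i, j), max(i, j))
            if result.config.single_cell_truth:
                has = (key[0], key[1], lr_row) in truth.cell_level
            else:
                has = lr_row in truth.rows_for_types(types[i], types[j])
            (cci_pairs if has else noncci_pairs).append((x[i, lig], x[j, rec]))
        for j in far:
            if types[i] == types[j]:
                continue
            far_pairs.append((x[i, lig], x[j, rec]))

    def corr(pairs):
        if len(pairs) < 3:
            return float("nan")
        a = np.asarray(pairs)
        if a[:, 0].std() == 0 or a[:, 1].std() == 0:
            return 0.0
        return float(stats.pearsonr(a[:, 0], a[:, 1])[0])

    return corr(cci_pairs), corr(noncci_pairs), corr(far_pairs)
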