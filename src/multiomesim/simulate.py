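"""End-to-end simulation: from a :class:`~multiomesim.core.SimConfig` to true
counts, accessibility, spliced/unspliced counts, velocity and all ground
truths.

Pipeline order: cell placement on the tree -> CIF/GIV construction -> the
scATAC-seq modality (accessibility affects expression, so it is generated
first) -> kinetic-parameter assembly -> true counts by the Beta-Poisson model
or the full kinetic model.  The sequential GRN coupling (a cell's TF segment
reflects its predecessor's expression) is resolved with two passes: pass 1
computes expression with Gaussian TF segments everywhere (the root-cell
rule), pass 2 recomputes each cell's TF segment from the pass-1 expression of
its pseudotime predecessor and re-assembles s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cif as _cif
from .atac import (AtacProfile, default_atac_reference, derive_motif_matrix,
                   generate_region_to_gene, sample_riv, simulate_atac)
from .cif import BrownianTreeField, CellMeta, CifSet, GivSet
from .core import SimConfig, module_stream
from .expression import (beta_poisson_counts, kinetic_init, rna_velocity,
                         sample_rates, simulate_kinetic)
from .kinetics import (KineticParams, ReferenceDistribution, assemble_koff,
                       assemble_kon, assemble_s, default_reference)

__all__ = ["SimResult", "simulate", "build_givs", "get_reference"]


@dataclass
class SimResult:
    """Everything a benchmark consumes: data matrices plus ground truth."""

    config: SimConfig
    counts: np.ndarray  # true counts (spliced counts in velocity mode)
    meta: CellMeta
    kinetics: KineticParams
    atac: AtacProfile | None = None
    unspliced: np.ndarray | None = None
    velocity: np.ndarray | None = None
    beta: np.ndarray | None = None
    d: np.ndarray | None = None
    spatial_state: object | None = None
    cci_truth: object | None = None
    grn_series: list | None = None  # cell-specific GRN mode
    extras: dict = field(default_factory=dict)

    def cell_meta_frame(self) -> pd.DataFrame:
        df = self.meta.to_frame()
        if self.spatial_state is not None:
            pos = self.spatial_state.positions
            df["row"] = [pos[i][0] for i in range(len(df))]
            df["col"] = [pos[i][1] for i in range(len(df))]
        return df


def get_reference(config: SimConfig) -> ReferenceDistribution:
    ref = config.__dict__.get("reference")
    return ref if ref is not None else default_reference()


def build_givs(config: SimConfig, rng: np.random.Generator,
               n_lig_seg: int = 0) -> GivSet:
    """GIV matrices for the three kinetic parameters.

    kon/koff: non-diff and diff blocks from the zero-inflated Gaussian, tf
    and lig blocks all zero (TFs and ligands affect s only).  s: non-diff
    block from the mixture, diff block tied to the GRN, tf block = the GRN
    effect matrix, lig block = the CCI effect matrix.
    """
    ngene = config.ngene
    n_nd, n_diff = config.n_nd, config.n_diff
    grn = config.grn
    n_tf = grn.n_tf if grn is not None else 0
    p0, gm, gs = config.giv_p_zero, config.giv_mean, config.giv_sd

    def block(rows):
        return _cif.sample_giv(rows, ngene, p0, gm, gs, rng)

    giv_kon = _cif.assemble_giv(block(n_nd), block(n_diff),
                                np.zeros((n_tf, ngene)),
                                np.zeros((n_lig_seg, ngene)))
    giv_koff = _cif.assemble_giv(block(n_nd), block(n_diff),
                                 np.zeros((n_tf, ngene)),
                                 np.zeros((n_lig_seg, ngene)))
    if grn is not None and n_diff >= 2:
        diff_s = _cif.build_diff_giv(grn, n_diff, rng, p0=p0, giv_mean=gm,
                                     giv_sd=gs)
        tf_s = grn.mtg
    else:
        diff_s = block(n_diff)
        tf_s = np.zeros((n_tf, ngene))
    if n_lig_seg and config.lr_db is not None:
        from .spatial import lig_effect_giv

        lig_s = lig_effect_giv(config.lr_db, ngene, config.nnbs)
    else:
        lig_s = np.zeros((n_lig_seg, ngene))
    giv_s = _cif.assemble_giv(block(n_nd), diff_s, tf_s, lig_s)
    widths = (n_nd, n_diff, n_tf, n_lig_seg)
    return GivSet(giv_kon, giv_koff, giv_s, widths)


def _predecessors(meta: CellMeta) -> np.ndarray:
    """Pseudotime predecessor within each lineage (-1 for lineage roots)."""
    n = len(meta.pseudotime)
    pred = np.full(n, -1, dtype=int)
    for lin in np.unique(meta.lineage):
        idx = np.where(meta.lineage == lin)[0]
        order = idx[np.argsort(meta.pseudotime[idx], kind="stable")]
        pred[order[1:]] = order[:-1]
    return pred


def simulate(config: SimConfig) -> SimResult:
    """Run the full simulation described by ``config``."""
    if config.spatial:
        from .spatial import run_spatial_simulation

        return run_spatial_simulation(config)

    cfg = config
    rng_cif = module_stream(cfg.seed, "cif")
    rng_giv = module_stream(cfg.seed, "giv")
    rng_atac = module_stream(cfg.seed, "atac")
    rng_kin = module_stream(cfg.seed, "kinetics")
    rng_expr = module_stream(cfg.seed, "expression")

    ncell, ngene = cfg.ncell, cfg.ngene
    grn = cfg.grn
    n_tf = grn.n_tf if grn is not None else 0
    n_sections = cfg.n_type_sections

    # --- cells and CIFs --------------------------------------------------
    meta, pos = _cif.assign_cells(cfg.tree, ncell, cfg.population, rng_cif,
                                  n_sections)
    cifs = {}
    for name in ("kon", "koff", "s"):
        nd = _cif.sample_nondiff_cif(ncell, cfg.n_nd, cfg.sigma_cif, rng_cif)
        fld = BrownianTreeField(cfg.tree, cfg.n_diff, rng_cif)
        diff, _ = _cif.sample_diff_cif(
            cfg.tree, ncell, cfg.n_diff, cfg.sigma_cif, cfg.population,
            rng_cif, meta_pos=(meta, pos), field=fld)
        tf = rng_cif.normal(1.0, cfg.sigma_cif, size=(ncell, n_tf))
        cifs[name] = {"nd": nd, "diff": diff, "tf": tf}

    widths = (cfg.n_nd, cfg.n_diff, n_tf, 0)
    givs = build_givs(cfg, rng_giv)
    ref = get_reference(cfg)

    def cif_mat(name, tf_override=None):
        c = cifs[name]
        tf = c["tf"] if tf_override is None else tf_override
        return _cif.assemble_cif(c["nd"], c["diff"], tf,
                                 np.zeros((ncell, 0)))

    cifset = CifSet(cif_mat("kon"), cif_mat("koff"), cif_mat("s"), widths)

    # --- ATAC modality (generated first; it feeds kon) -------------------
    Z, nregion = generate_region_to_gene(ngene, cfg.region_dist, rng_atac)
    riv = sample_riv(sum(widths), nregion, cfg.riv_p_zero, cfg.riv_mean,
                     cfg.riv_sd, rng_atac)
    atac_ref = default_atac_reference(p_zero=cfg.atac_p_zero,
                                      density=cfg.atac_density, rng=rng_atac)
    accessibility = simulate_atac(cifset.kon, riv, atac_ref, rng_atac)
    mtr = derive_motif_matrix(grn.mtg, Z) if grn is not None else \
        np.zeros((0, nregion))
    atac = AtacProfile(accessibility, Z, mtr, cfg.region_dist, cfg.ea)

    # --- kinetic parameters ----------------------------------------------
    M1 = cifset.kon @ givs.kon
    M2 = cifset.koff @ givs.koff
    kon = assemble_kon(M1, accessibility, Z, cfg.ea, ref.kon, rng_kin)
    kon /= 10.0 ** cfg.bimod
    koff = assemble_koff(M2, cfg.bimod, ref.koff, rng_kin)

    # s, pass 1: Gaussian tf segments everywhere (the root-cell rule)
    M3 = cifset.s @ givs.s
    s1 = assemble_s(M3, cfg.scale_s, ref.s, rng_kin)
    grn_series = None
    if grn is not None and n_tf:
        expr1 = s1 * kon / (kon + koff)
        pred = _predecessors(meta)
        if cfg.grn_change_rate > 0:
            order = np.argsort(meta.pseudotime, kind="stable")
            series = _cif.evolve_grn(grn, ncell, cfg.grn_change_rate,
                                     module_stream(cfg.seed, "grn_dynamics"))
            grn_series = [None] * ncell
            for rank, i in enumerate(order):
                grn_series[i] = series[rank]
        tf2 = np.empty((ncell, n_tf))
        for i in range(ncell):
            g_i = grn_series[i] if grn_series is not None else grn
            if pred[i] < 0 or g_i.n_tf == 0:
                tf2[i] = cifs["s"]["tf"][i]
            else:
                vec = _cif.update_tf_cif(expr1[pred[i]], grn.tf_ids)
                tf2[i] = vec
        if grn_series is not None:
            M3 = cif_mat("s", tf_override=np.zeros((ncell, n_tf)))[:, :cfg.ncif] \
                @ givs.s[:cfg.ncif]
            for i in range(ncell):
                M3[i] += tf2[i] @ grn_series[i].mtg if grn_series[i].n_tf \
                    else 0.0
        else:
            M3 = cif_mat("s", tf_override=tf2) @ givs.s
        s = assemble_s(M3, cfg.scale_s, ref.s, rng_kin)
    else:
        s = s1
    params = KineticParams(kon, koff, s)

    # --- counts ----------------------------------------------------------
    result = SimResult(config=cfg, counts=np.zeros((ncell, ngene)), meta=meta,
                       kinetics=params, atac=atac, grn_series=grn_series)
    if not cfg.velocity:
        result.counts = beta_poisson_counts(kon, koff, s, cfg.sigma_i, rng_expr)
        return result

    beta = sample_rates(ngene, rng_expr)
    d = sample_rates(ngene, rng_expr)
    pred = _predecessors(meta)
    order = np.argsort(meta.pseudotime, kind="stable")
    xs = np.zeros((ncell, ngene))
    xu = np.zeros((ncell, ngene))
    done = np.zeros(ncell, dtype=bool)
    for i in order:
        if pred[i] < 0 or not done[pred[i]]:
            xs0, xu0 = kinetic_init(kon[i], koff[i], s[i], beta, d)
        else:
            xs0, xu0 = xs[pred[i]], xu[pred[i]]
        xs[i], xu[i], _ = simulate_kinetic(xs0, xu0, kon[i], koff[i], s[i],
                                           beta, d, rng_expr)
        done[i] = True
    result.counts = np.round(xs)
    result.unspliced = np.round(xu)
    result.velocity = rna_velocity(xu, xs, beta, d)
    result.beta, result.d = beta, d
    return result
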