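"""Bundled benchmark inputs, constructed programmatically.

* a synthetic 100-gene GRN whose topology shape (about ten TFs, every gene
  regulated, TF-TF edges, the regulator-target pair 19 -> 20) mirrors the
  networks commonly used to benchmark GRN inference; it is generated from a
  fixed fixture seed and is a synthetic stand-in, not a published network;
* the main-dataset CCI pair list (ligands 99, 101-104 to receptors 91, 2, 6,
  10, 8 — four TFs and one non-TF);
* the layered "dataset C" GRN/CCI construction used to benchmark CCI
  inference methods that require a minimum receptor-to-TF chain depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GrnSpec, LigRecDatabase, load_grn, load_lr_database

__all__ = [
    "CciFixtureSpec",
    "build_grn_100",
    "build_main_cci",
    "build_dataset_c_grn",
    "build_dataset_c_lr",
    "build_dataset_c_cci",
]

_FIXTURE_SEED = 20230919
#: Default regulation strength for bundled ligand-receptor pairs, matching
#: the centre of the bundled GRN's effect range U(1, 5).
DEFAULT_LR_EFFECT = 3.0


def build_grn_100(ngene: int = 100) -> GrnSpec:
    """Synthetic 100-gene GRN stand-in (fixed fixture seed).

    Ten TFs (including genes 2, 6, 10, 19 and 91); every non-TF gene gets one
    or two TF regulators, gene 19 regulates gene 20, and a few TF -> TF edges
    are present.  Effects are drawn from U(1, 5).
    """
    rng = np.random.default_rng(np.random.SeedSequence(_FIXTURE_SEED, spawn_key=(0,)))
    tfs = [1, 2, 6, 10, 19, 30, 45, 60, 75, 91]
    edges: list[tuple[int, int, float]] = []

    def eff() -> float:
        return float(rng.uniform(1.0, 5.0))

    edges.append((19, 20, eff()))
    for g in range(1, ngene + 1):
        if g in tfs or g == 20:
            continue
        nreg = 1 + int(rng.uniform() < 0.3)
        regs = rng.choice(tfs, size=nreg, replace=False)
        for t in regs:
            edges.append((int(t), g, eff()))
    # a few TF -> TF edges
    for t_from, t_to in [(1, 2), (2, 6), (10, 19), (60, 91)]:
        edges.append((t_from, t_to, eff()))
    return load_grn(edges, ngene)


def build_main_cci(effect: float = DEFAULT_LR_EFFECT) -> LigRecDatabase:
    """Main-dataset ligand-receptor list: each cell's genes 99, 101-104 can
    signal to a neighbour's genes 91, 2, 6, 10 (TFs) and 8 (non-TF).

    Ligand genes 101-104 lie outside the 100-gene GRN; they only exist as
    ligands and carry no within-cell regulation.
    """
    pairs = [(99, 91), (101, 2), (102, 6), (103, 10), (104, 8)]
    return load_lr_database([(l, r, effect) for l, r in pairs])


@dataclass(frozen=True)
class CciFixtureSpec:
    """Layered GRN/CCI construction for benchmarking CCI inference.

    Genes 1-6 are TFs; 70 sampled edges fan out to first-layer targets 7-53,
    which chain consecutively into 54-100 and then 110-156.  Ligands are
    genes 101-106, receptors 2, 6, 10, 8, 20 and 30, and a linear trajectory
    is split into five equal sections acting as cell types.  Genes 101-109
    and 157-160 carry no GRN edges; they pad the total to 160.
    """

    tf_genes: tuple[int, ...] = tuple(range(1, 7))
    layer1: tuple[int, int] = (7, 53)
    layer2: tuple[int, int] = (54, 100)
    layer3: tuple[int, int] = (110, 156)
    ligand_genes: tuple[int, ...] = tuple(range(101, 107))
    receptor_genes: tuple[int, ...] = (2, 6, 10, 8, 20, 30)
    total_genes: int = 160
    n_sections: int = 5


def build_dataset_c_grn(rng: np.random.Generator, ngene: int = 160,
                        spec: CciFixtureSpec | None = None) -> GrnSpec:
    """Dataset-C GRN: 70 sampled TF edges + two consecutive chain layers.

    Exactly 70 distinct edges from genes 1-6 to genes 7-53, then 7->54 ...
    53->100 and 54->110 ... 100->156 (164 edges in total), guaranteeing at
    least three downstream genes below every receptor.
    """
    spec = spec or CciFixtureSpec()
    lo1, hi1 = spec.layer1
    lo2, hi2 = spec.layer2
    lo3, hi3 = spec.layer3
    possible = [(t, g) for t in spec.tf_genes for g in range(lo1, hi1 + 1)]
    idx = rng.choice(len(possible), size=70, replace=False)
    edges = [(possible[i][0], possible[i][1], float(rng.uniform(1.0, 5.0)))
             for i in sorted(idx)]
    for src, dst in zip(range(lo1, hi1 + 1), range(lo2, hi2 + 1)):
        edges.append((src, dst, float(rng.uniform(1.0, 5.0))))
    for src, dst in zip(range(lo2, hi2 + 1), range(lo3, hi3 + 1)):
        edges.append((src, dst, float(rng.uniform(1.0, 5.0))))
    return load_grn(edges, ngene)


def build_dataset_c_lr(spec: CciFixtureSpec | None = None,
                       effect: float = DEFAULT_LR_EFFECT) -> LigRecDatabase:
    """Dataset-C ligand-receptor database (ligands 101-106 to the six
    receptors)."""
    spec = spec or CciFixtureSpec()
    return load_lr_database(
        [(l, r, effect) for l, r in zip(spec.ligand_genes, spec.receptor_genes)]
    )


def build_dataset_c_cci(rng: np.random.Generator,
                        spec: CciFixtureSpec | None = None):
    """Type-level CCI ground truth for dataset C: for each of the C(5,2) = 10
    distinct section pairs, 3-6 of the six ligand-receptor rows."""
    from .spatial import sample_cci_truth

    spec = spec or CciFixtureSpec()
    types = [f"sec{i + 1}" for i in range(spec.n_sections)]
    return sample_cci_truth(build_dataset_c_lr(spec), types, rng,
                            pairs_range=(3, 6), include_same_type=False)
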