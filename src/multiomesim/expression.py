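"""True-count generation: Beta-Poisson sampling and the full two-state
kinetic model with spliced/unspliced counts and ground-truth RNA velocity.

In the two-state promoter model a gene switches between an *on* state
(activation rate kon) and an *off* state (deactivation rate koff); while on,
mRNA is synthesised at rate s and degrades at rate d (fixed at 1).  The
Beta-Poisson scheme samples the steady-state expression directly
(y ~ Beta(kon, koff), x ~ Poisson(y * s)); the full kinetic model steps the
promoter through a discretised cell cycle and yields spliced (xs) and
unspliced (xu) counts, from which the ground-truth velocity is
v = beta * xu - d * xs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cif import CellMeta

__all__ = [
    "ExpressionResult",
    "beta_poisson_counts",
    "kinetic_init",
    "simulate_kinetic",
    "rna_velocity",
    "sample_rates",
    "knn_smooth_velocity",
]


@dataclass
class ExpressionResult:
    """True counts (or spliced/unspliced), velocity and the rates behind it."""

    counts: np.ndarray  # ncell x ngene (spliced counts in velocity mode)
    meta: CellMeta
    unspliced: np.ndarray | None = None
    velocity: np.ndarray | None = None
    beta: np.ndarray | None = None  # per-gene splicing rate
    d: np.ndarray | None = None  # per-gene degradation rate
    extras: dict = field(default_factory=dict)


def beta_poisson_counts(kon, koff, s, sigma_i: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Expression by the Beta-Poisson scheme with intrinsic-noise weight.

    Per entry: y ~ Beta(kon, koff), x ~ Poisson(y * s); the returned value is
    ``sigma_i * x + (1 - sigma_i) * s * kon / (kon + koff)``, interpolating
    between the noisy draw and the theoretical mean.
    """
    kon, koff, s = (np.asarray(a, dtype=float) for a in (kon, koff, s))
    if np.any(kon <= 0) or np.any(koff <= 0) or np.any(s <= 0):
        raise ValueError("kinetic parameters must be strictly positive")
    if not 0.0 <= sigma_i <= 1.0:
        raise ValueError("sigma_i must be in [0, 1]")
    mean = s * kon / (kon + koff)
    if sigma_i == 0.0:
        return mean
    y = rng.beta(kon, koff)
    x = rng.poisson(y * s).astype(float)
    return sigma_i * x + (1.0 - sigma_i) * mean


def kinetic_init(kon, koff, s, beta, d) -> tuple[np.ndarray, np.ndarray]:
    """Initial spliced/unspliced counts of a root cell.

    ``xs = s * kon * beta / (kon + koff)`` and
    ``xu = s * kon * d / (kon + koff)``; the initial velocity
    ``beta * xu - d * xs`` is identically zero by construction.
    """
    kon, koff, s = (np.asarray(a, dtype=float) for a in (kon, koff, s))
    xs = s * kon * np.asarray(beta, dtype=float) / (kon + koff)
    xu = s * kon * np.asarray(d, dtype=float) / (kon + koff)
    return xs, xu


def simulate_kinetic(
    xs0,
    xu0,
    kon,
    koff,
    s,
    beta,
    d,
    rng: np.random.Generator,
    eta_l: float = 1.0,
    pon=None,
    poff=None,
    m_override: int | None = None,
    m_max: int = 1000,
    state0=None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Step the two-state promoter over one cell cycle (vectorised per gene).

    The cycle length is ``L = eta_l * (1/kon + 1/koff)`` divided into
    ``m = ceil(L / min(1/kon, 1/koff))`` steps of size ``L/m``; the per-step
    switching probabilities are ``pon = kon * (L/m)`` and
    ``poff = koff * (L/m)`` (both <= 1 since ``L/m <= min(1/kon, 1/koff)``).
    Counts are updated continuously:

    * spliced:   xs <- xs + (L/m) * (beta * xu - d * xs)
    * unspliced: xu <- xu + (L/m) * (s - beta * xu)  while on,
                 xu <- xu - (L/m) * beta * xu        while off,

    clipped at 0, and the step-m values are returned together with the final
    promoter state.  ``pon``/``poff``/``m_override`` allow pinning the
    promoter for diagnostics.
    """
    xs = np.array(xs0, dtype=float, copy=True, ndmin=1)
    xu = np.array(xu0, dtype=float, copy=True, ndmin=1)
    kon, koff, s = (np.broadcast_to(np.asarray(a, dtype=float), xs.shape).copy()
                    for a in (kon, koff, s))
    beta = np.broadcast_to(np.asarray(beta, dtype=float), xs.shape)
    d = np.broadcast_to(np.asarray(d, dtype=float), xs.shape)
    if eta_l <= 0:
        raise ValueError("eta_l must be > 0")

    L = eta_l * (1.0 / kon + 1.0 / koff)
    dt_nat = np.minimum(1.0 / kon, 1.0 / koff)
    m = np.minimum(np.ceil(L / dt_nat), m_max).astype(int)
    if m_override is not None:
        m = np.full_like(m, m_override)
    step = L / np.maximum(m, 1)
    p_on = np.clip(kon * step, 0.0, 1.0) if pon is None else np.broadcast_to(
        np.asarray(pon, dtype=float), xs.shape)
    p_off = np.clip(koff * step, 0.0, 1.0) if poff is None else np.broadcast_to(
        np.asarray(poff, dtype=float), xs.shape)

    if state0 is None:
        state = rng.uniform(size=xs.shape) < kon / (kon + koff)
    else:
        state = np.broadcast_to(np.asarray(state0, dtype=bool), xs.shape).copy()

    mmax = int(m.max()) if m.size else 0
    for t in range(mmax):
        active = t < m
        u = rng.uniform(size=xs.shape)
        turn_on = (~state) & (u < p_on)
        turn_off = state & (u < p_off)
        state = np.where(active, (state | turn_on) & ~turn_off, state)
        dxs = step * (beta * xu - d * xs)
        dxu = np.where(state, step * (s - beta * xu), -step * beta * xu)
        xs = np.where(active, np.clip(xs + dxs, 0.0, None), xs)
        xu = np.where(active, np.clip(xu + dxu, 0.0, None), xu)
    return xs, xu, state


def rna_velocity(xu, xs, beta, d) -> np.ndarray:
    """Ground-truth RNA velocity ``v = beta * xu - d * xs`` (elementwise)."""
    xu, xs = np.asarray(xu, dtype=float), np.asarray(xs, dtype=float)
    if xu.shape != xs.shape:
        raise ValueError("xu and xs shapes differ")
    return np.asarray(beta, dtype=float) * xu - np.asarray(d, dtype=float) * xs


def sample_rates(ngene: int, rng: np.random.Generator, mean: float = 1.0,
                 sd: float = 0.1, floor: float = 0.1) -> np.ndarray:
    """Per-gene splicing/degradation rates ~ Normal(mean, sd), truncated
    below at ``floor`` by resampling."""
    vals = rng.normal(mean, sd, ngene)
    while np.any(vals < floor):
        bad = vals < floor
        vals[bad] = rng.normal(mean, sd, int(bad.sum()))
    return vals


def knn_smooth_velocity(v: np.ndarray, cell_embedding: np.ndarray,
                        k: int | None = None) -> np.ndarray:
    """Gaussian-kernel kNN average of the velocity field, then per-cell
    normalisation by the cell's own velocity norm.

    ``k`` defaults to ``ncell / 50`` (at least 1).  The kernel bandwidth is
    the mean k-th-neighbour distance.  Zero-norm rows are left unnormalised.
    """
    from sklearn.neighbors import NearestNeighbors

    v = np.asarray(v, dtype=float)
    ncell = v.shape[0]
    if k is None:
        k = max(1, ncell // 50)
    k = min(k, ncell - 1) if ncell > 1 else 0
    if k == 0:
        out = v.copy()
    else:
        nn = NearestNeighbors(n_neighbors=k).fit(cell_embedding)
        dist, idx = nn.kneighbors(cell_embedding)
        bw = max(dist[:, -1].mean(), 1e-12)
        w = np.exp(-(dist ** 2) / (2 * bw ** 2))
        # include the cell itself with weight 1
        out = v.copy()
        for i in range(ncell):
            weights = np.concatenate([[1.0], w[i]])
            vecs = np.vstack([v[i], v[idx[i]]])
            out[i] = (weights[:, None] * vecs).sum(axis=0) / weights.sum()
    norms = np.linalg.norm(out, axis=1)
    nz = norms > 0
    out[nz] = out[nz] / norms[nz, None]
    return out
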