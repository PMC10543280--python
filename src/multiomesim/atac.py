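"""Chromatin-accessibility (scATAC-seq) modality.

Regions are abstract indices: every gene is controlled by 1-3 consecutive
chromatin regions drawn from a user probability vector ``r``.  Accessibility
is generated like expression — the kon-parameter CIF matrix times a Region
Identity Vector (RIV) matrix, rank-scaled to a reference accessibility
distribution, plus a small Gaussian intrinsic noise.  The region-to-gene map
``Mrg``/``Z`` and the binary TF-motif map ``Mtr`` couple chromatin to the GRN
through the support identity ``support(Mtr @ Mrg) >= support(Mtg)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import rank_scale

__all__ = [
    "RivMatrix",
    "AtacProfile",
    "sample_riv",
    "generate_region_to_gene",
    "derive_motif_matrix",
    "default_atac_reference",
    "simulate_atac",
]


@dataclass
class RivMatrix:
    """Region Identity Vector matrix (ncif_total x nregion) and its mixture
    parameters."""

    matrix: np.ndarray
    p_zero: float
    mean: float
    sd: float


@dataclass
class AtacProfile:
    """Accessibility matrix plus the maps coupling regions to genes and TFs."""

    accessibility: np.ndarray  # ncell x nregion, nonnegative
    region_to_gene: np.ndarray  # Z / Mrg, nregion x ngene, 0-1
    motif_matrix: np.ndarray  # Mtr, n_tf x nregion, 0-1
    region_dist: tuple[float, float, float]
    ea: float

    @property
    def nregion(self) -> int:
        return self.accessibility.shape[1]


def sample_riv(ncif_total: int, nregion: int, p_zero: float, riv_mean: float,
               riv_sd: float, rng: np.random.Generator) -> RivMatrix:
    """RIV mixture: each entry is 0 w.p. ``p_zero``, else Gaussian."""
    if not 0.0 <= p_zero <= 1.0:
        raise ValueError("p_zero must be in [0, 1]")
    vals = rng.normal(riv_mean, riv_sd, size=(ncif_total, nregion))
    vals[rng.uniform(size=(ncif_total, nregion)) < p_zero] = 0.0
    return RivMatrix(vals, p_zero, riv_mean, riv_sd)


def generate_region_to_gene(ngene: int, r, rng: np.random.Generator
                            ) -> tuple[np.ndarray, int]:
    """Assign each gene 1-3 consecutive fresh regions.

    ``r`` is a length-3 probability vector: ``r[k-1]`` is the probability a
    gene is controlled by ``k`` consecutive regions.  Returns the 0-1
    region-to-gene matrix Z (nregion x ngene) and the region count.
    """
    r = np.asarray(r, dtype=float)
    if r.shape != (3,) or np.any(r < 0) or abs(r.sum() - 1.0) > 1e-9:
        raise ValueError("r must be a length-3 probability vector summing to 1")
    counts = rng.choice([1, 2, 3], size=ngene, p=r)
    nregion = int(counts.sum())
    Z = np.zeros((nregion, ngene))
    start = 0
    for g, k in enumerate(counts):
        Z[start:start + k, g] = 1.0
        start += k
    return Z, nregion


def derive_motif_matrix(mtg: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Binary TF-motif matrix: Mtr[t, j] = 1 iff TF t regulates any gene
    associated with region j."""
    regulates = mtg > 0  # n_tf x ngene
    return ((regulates.astype(float) @ Z.T) > 0).astype(float)


def default_atac_reference(n: int = 10_000, p_zero: float = 0.7,
                           density: float = 1.0,
                           rng: np.random.Generator | None = None
                           ) -> np.ndarray:
    """Bundled accessibility reference: a zero-inflated exponential with
    zero-mass ``p_zero`` and rate set by ``density``.

    A parametric stand-in for an empirical accessibility-value sample; users
    can supply their own sample file instead.
    """
    if rng is None:
        rng = np.random.default_rng(715518)
    vals = rng.exponential(1.0 / density, size=n)
    vals[rng.uniform(size=n) < p_zero] = 0.0
    return vals


def simulate_atac(
    cif_kon: np.ndarray,
    riv: RivMatrix,
    reference: np.ndarray,
    rng: np.random.Generator,
    intrinsic_sd_frac: float = 0.05,
) -> np.ndarray:
    """Accessibility matrix: CIF @ RIV, rank-scaled to the reference, plus a
    small Gaussian intrinsic noise (sd = ``intrinsic_sd_frac`` of the
    reference's sd), clipped at zero."""
    reference = np.asarray(reference, dtype=float)
    if reference.size == 0:
        raise ValueError("empty ATAC reference sample")
    raw = cif_kon @ riv.matrix
    scaled = rank_scale(raw, reference, rng)
    noise_sd = intrinsic_sd_frac * reference.std()
    if noise_sd > 0:
        scaled = scaled + rng.normal(0.0, noise_sd, size=scaled.shape)
    return np.clip(scaled, 0.0, None)
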