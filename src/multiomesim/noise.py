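"""Technical noise and batch effects: true counts -> observed counts.

The observed scRNA-seq data is produced by simulating the main experimental
steps: per-cell mRNA capture (binomial thinning with efficiency alpha),
several rounds of amplification, allocation of a per-cell sequencing depth
over the amplified molecule pool, and UMI collapse (UMI protocol) or raw read
counting (non-UMI).  Batch effects multiply counts by exp of a gene- and
batch-specific shift factor drawn from Unif(mu_j - eb, mu_j + eb) with
mu_j ~ N(0, 1).  Observed scATAC-seq data keeps each entry with a fixed
observation probability and receives the same batch-shift treatment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NoiseConfig",
    "add_rna_technical_noise",
    "add_batch_effects",
    "add_atac_noise",
]


@dataclass
class NoiseConfig:
    """Technical-noise parameters (defaults mirror a deep non-UMI protocol:
    alpha ~ N(0.1, 0.02), depth ~ N(1e5, 3000), ATAC observation probability
    0.3)."""

    protocol: str = "nonUMI"  # or "UMI"
    alpha_mean: float = 0.1
    alpha_sd: float = 0.02
    depth_mean: float = 1e5
    depth_sd: float = 3000.0
    amp_rounds: int = 8
    amp_p: float = 0.7
    atac_obs_prob: float = 0.3
    nbatch: int = 1
    eb: float = 0.0
    #: optional per-gene multipliers on s for designated highly expressed
    #: (housekeeping-like) genes: {gene_id: multiplier}
    highly_expressed: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.protocol not in ("UMI", "nonUMI"):
            raise ValueError("protocol must be 'UMI' or 'nonUMI'")
        if self.nbatch < 1:
            raise ValueError("nbatch must be >= 1")
        if self.eb < 0:
            raise ValueError("eb must be >= 0")
        if not 0.0 <= self.atac_obs_prob <= 1.0:
            raise ValueError("atac_obs_prob must be in [0, 1]")


def add_rna_technical_noise(true_counts: np.ndarray, cfg: NoiseConfig,
                            rng: np.random.Generator) -> np.ndarray:
    """Observed counts from true counts.

    Per cell: every transcript is captured with probability alpha; the
    captured pool is amplified over ``amp_rounds`` rounds of per-molecule
    doubling with success ``amp_p``; a per-cell sequencing depth is allocated
    multinomially over the amplified pool.  Under UMI the reads of one gene
    are collapsed back onto its captured molecules (a molecule is observed
    when at least one of its amplicons is sequenced); under non-UMI the read
    counts are reported directly.  True zeros always stay zero.
    """
    x = np.floor(np.asarray(true_counts, dtype=float)).astype(np.int64)
    if np.any(x < 0):
        raise ValueError("true counts must be nonnegative")
    ncell = x.shape[0]
    alpha = np.clip(rng.normal(cfg.alpha_mean, cfg.alpha_sd, ncell), 1e-4, 1.0)
    captured = rng.binomial(x, alpha[:, None])
    amplified = captured.astype(np.int64)
    for _ in range(cfg.amp_rounds):
        amplified = amplified + rng.binomial(amplified, cfg.amp_p)
    depth = np.maximum(rng.normal(cfg.depth_mean, cfg.depth_sd, ncell), 1.0)
    observed = np.zeros_like(x)
    for c in range(ncell):
        total = int(amplified[c].sum())
        if total == 0:
            continue
        n_reads = int(round(depth[c]))
        reads = rng.multinomial(n_reads, amplified[c] / total)
        if cfg.protocol == "nonUMI":
            observed[c] = reads
        else:
            # per-gene molecule-pool approximation of UMI collapse
            cap = captured[c]
            nz = (cap > 0) & (reads > 0)
            frac = np.zeros_like(cap, dtype=float)
            frac[nz] = 1.0 - np.exp(-reads[nz] / cap[nz])
            observed[c] = rng.binomial(cap, frac)
    return observed


def add_batch_effects(observed_counts: np.ndarray, nbatch: int, eb: float,
                      rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Partition cells round-robin into batches and apply multiplicative
    gene- and batch-specific shifts ``exp(Unif(mu_j - eb, mu_j + eb))`` with
    ``mu_j ~ N(0, 1)``; counts are re-rounded."""
    if nbatch < 1:
        raise ValueError("nbatch must be >= 1")
    x = np.asarray(observed_counts, dtype=float)
    ncell, ngene = x.shape
    labels = np.arange(ncell) % nbatch
    mu = rng.normal(0.0, 1.0, ngene)
    shifts = rng.uniform(mu - eb, mu + eb, size=(nbatch, ngene))
    out = np.round(x * np.exp(shifts[labels]))
    return out, labels + 1


def add_atac_noise(atac_matrix: np.ndarray, observation_prob: float,
                   nbatch: int, eb: float, rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Observed scATAC-seq: each entry independently retained with
    ``observation_prob`` (else zeroed), then batch shifts as for RNA (without
    re-rounding; accessibility values are real-valued)."""
    if not 0.0 <= observation_prob <= 1.0:
        raise ValueError("observation_prob must be in [0, 1]")
    x = np.asarray(atac_matrix, dtype=float)
    kept = x * (rng.uniform(size=x.shape) < observation_prob)
    ncell, nregion = x.shape
    labels = np.arange(ncell) % nbatch
    if eb > 0 or nbatch > 1:
        mu = rng.normal(0.0, 1.0, nregion)
        shifts = rng.uniform(mu - eb, mu + eb, size=(nbatch, nregion))
        kept = kept * np.exp(shifts[labels])
    return kept, labels + 1
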