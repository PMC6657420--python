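"""Information-reduction engines: Gaussian noise and beta read down-sampling.

Two ways of degrading an expression matrix to probe model robustness:

* :func:`add_gaussian_noise` adds i.i.d. N(0, sigma^2) to every cell of a
  normalized matrix.
* :func:`downsample_counts` thins a raw count matrix towards a target total
  of ``f`` reads per sample by multiplying each gene's count by an
  independent Beta(alpha, beta) draw, with ``alpha = beta*(f/r)/(1 - f/r)``
  computed from that sample's own total ``r``.  Because
  ``E[Beta(alpha, beta)] = alpha/(alpha+beta) = f/r``, the expected
  down-sampled total equals ``f``; the small beta shape (0.1 by default)
  makes the factor distribution strongly bimodal, producing complete gene
  dropouts alongside mild reductions — the signature of shallow
  single-cell sequencing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import NORMALIZED, ConfigError, ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NoiseConfig:
    """Gaussian perturbation: zero-mean noise with standard deviation sigma."""

    sigma: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ConfigError(f"sigma must be >= 0, got {self.sigma}")


@dataclass(frozen=True)
class DownsampleConfig:
    """Beta-thinning towards a target of f reads per sample.

    ``beta_shape`` is the second shape parameter (beta); the first (alpha)
    is derived per sample from its total read count r as
    ``alpha = beta * (f/r) / (1 - f/r)``.
    """

    f: float
    beta_shape: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f < 1:
            raise ConfigError(f"target read count f must be >= 1, got {self.f}")
        if self.beta_shape <= 0:
            raise ConfigError(f"beta_shape must be > 0, got {self.beta_shape}")


def add_gaussian_noise(expr: ExpressionMatrix, config: NoiseConfig) -> ExpressionMatrix:
    """Return a copy of ``expr`` with N(0, sigma^2) added to every cell."""
    if expr.units != NORMALIZED:
        logger.warning(
            "add_gaussian_noise expects normalized input, got units=%r", expr.units
        )
    if config.sigma == 0:
        return expr.copy()
    rng = np.random.default_rng(config.seed)
    noisy = expr.values + rng.normal(0.0, config.sigma, size=expr.values.shape)
    return ExpressionMatrix(noisy, expr.units)


def downsample_counts(
    counts: ExpressionMatrix, config: DownsampleConfig
) -> ExpressionMatrix:
    """Beta-thin each sample of a raw count matrix towards ``config.f`` reads.

    Per sample with total r > f: draw one Beta(alpha, beta) factor per gene
    and set the new count to round-half-up(count * factor).  Zeros stay
    zero.  Samples whose total is already <= f are passed through unchanged
    with a warning (alpha is undefined there).
    """
    if counts.units != "counts":
        raise ConfigError(
            f"downsample_counts requires raw counts, got units={counts.units!r}"
        )
    rng = np.random.default_rng(config.seed)
    beta = config.beta_shape
    f = config.f
    arr = counts.values.to_numpy(dtype=np.float64, copy=True)
    totals = arr.sum(axis=0)
    for j, r in enumerate(totals):
        if f >= r:
            logger.warning(
                "sample %s: target f=%g >= total r=%g; passed through unchanged",
                counts.samples[j], f, r,
            )
            continue
        frac = f / r
        alpha = beta * frac / (1.0 - frac)
        d = rng.beta(alpha, beta, size=arr.shape[0])
        arr[:, j] = np.floor(arr[:, j] * d + 0.5)  # round half-up
    import pandas as pd

    out = pd.DataFrame(arr, index=counts.genes, columns=counts.samples)
    return ExpressionMatrix(out, "counts")


def sweep_seed(base_seed: int, level_index: int, rep: int) -> int:
    """Deterministic per-(level, rep) seed derived from the base seed."""
    ss = np.random.SeedSequence([int(base_seed), int(level_index), int(rep)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class PerturbedMatrix:
    """One perturbed matrix with the metadata needed to reproduce it."""

    matrix: ExpressionMatrix
    mode: str
    level: float
    rep: int
    seed: int


def perturbation_sweep(
    expr: ExpressionMatrix,
    levels: list[float],
    mode: str,
    reps: int = 100,
    base_seed: int = 0,
    beta_shape: float = 0.1,
):
    """Yield independently seeded perturbed matrices for each level x rep.

    ``mode`` is ``"noise"`` (levels are Gaussian sigmas) or ``"downsample"``
    (levels are target read counts f).  Matrices are yielded lazily to keep
    memory flat across large sweeps.
    """
    if not levels:
        raise ConfigError("levels must be non-empty")
    if mode not in ("noise", "downsample"):
        raise ConfigError(f"unknown perturbation mode {mode!r}")
    for li, level in enumerate(levels):
        for rep in range(reps):
            seed = sweep_seed(base_seed, li, rep)
            if mode == "noise":
                pert = add_gaussian_noise(expr, NoiseConfig(sigma=level, seed=seed))
            else:
                pert = downsample_counts(
                    expr, DownsampleConfig(f=level, beta_shape=beta_shape, seed=seed)
                )
            yield PerturbedMatrix(pert, mode, level, rep, seed)
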