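"""Continuous LRR/BAF signal synthesis from integer genotypes.

The LRR of locus *i* is a mixture over cell types of Gaussian copy-number
levels, plus a sample-wide baseline shift and an ARMA-autocorrelated bias:

    lrr_i = sum_j w_ij * r_{x_ij} + l + c_i,      r_x ~ N(mu_x, sigma_x)

The BAF is the weighted allele ratio plus genotype-dependent noise: full
Gaussian for heterozygous loci; for homozygous loci a mixture of a point
mass at the exact extreme (weight ``pi_extreme``) and a half-Gaussian
pointing into the unit interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.tsa.arima_process import arma_generate_sample

__all__ = [
    "LrrModel",
    "ArmaModel",
    "BafNoiseModel",
    "SignalTrack",
    "ConfigurationError",
    "arma_series",
    "draw_lrr_levels",
    "synthesize_lrr",
    "synthesize_baf",
    "expected_signals",
]


class ConfigurationError(ValueError):
    """A signal-model configuration is unusable."""


#: Default expected LRR per copy number (diploid anchored at zero).
DEFAULT_MU = {0: -2.00, 1: -0.55, 2: 0.00, 3: 0.30, 4: 0.54, 5: 0.70}
DEFAULT_SIGMA_X = 0.2
DEFAULT_SIGMA_BAF_HE = 0.03
DEFAULT_SIGMA_BAF_HO = 0.015
DEFAULT_PI_EXTREME = 0.30


def _rng(seed):
    return np.random.default_rng(seed)


@dataclass
class LrrModel:
    """Copy-number level model: per-CN Gaussian mean/sd plus baseline shift."""

    mu: dict = field(default_factory=lambda: dict(DEFAULT_MU))
    sigma: dict = field(default_factory=lambda: {k: DEFAULT_SIGMA_X for k in DEFAULT_MU})
    baseline_shift: float = 0.0

    def lookup(self, x: np.ndarray):
        """Vector (mu, sigma) for an integer copy-number array."""
        x = np.asarray(x)
        missing = sorted({int(v) for v in np.unique(x)} - set(self.mu))
        if missing:
            raise ConfigurationError(
                f"no expected LRR (mu) configured for copy number(s) {missing}")
        mu = np.vectorize(self.mu.__getitem__, otypes=[float])(x)
        sg = np.vectorize(lambda v: self.sigma.get(int(v), DEFAULT_SIGMA_X),
                          otypes=[float])(x)
        if np.any(sg < 0):
            raise ConfigurationError("sigma_x must be >= 0")
        return mu, sg

    def zero_noise(self) -> "LrrModel":
        return LrrModel(mu=dict(self.mu), sigma={k: 0.0 for k in self.mu},
                        baseline_shift=self.baseline_shift)


@dataclass
class ArmaModel:
    """Stationary ARMA process for the autocorrelated LRR bias."""

    ar_coeffs: tuple = ()
    ma_coeffs: tuple = ()
    innovation_sd: float = 0.0

    def __post_init__(self):
        self.ar_coeffs = tuple(float(a) for a in self.ar_coeffs)
        self.ma_coeffs = tuple(float(a) for a in self.ma_coeffs)
        if self.innovation_sd < 0:
            raise ConfigurationError("innovation_sd must be >= 0")

    @property
    def max_order(self) -> int:
        return max(len(self.ar_coeffs), len(self.ma_coeffs))

    def check_stationary(self):
        if not self.ar_coeffs:
            return
        # roots of 1 - a1 B - a2 B^2 - ... must lie outside the unit circle
        roots = np.polynomial.polynomial.polyroots(
            [1.0] + [-a for a in self.ar_coeffs])
        if np.any(np.abs(roots) <= 1.0):
            raise ConfigurationError(
                f"AR coefficients {self.ar_coeffs} are not stationary")

    def burnin(self) -> int:
        """Burn-in long enough to wash out the slowest AR mode."""
        n = max(10 * self.max_order, 50)
        if self.ar_coeffs:
            roots = np.polynomial.polynomial.polyroots(
                [1.0] + [-a for a in self.ar_coeffs])
            r = float(np.max(1.0 / np.abs(roots)))  # < 1 when stationary
            if 0 < r < 1:
                n = max(n, int(np.ceil(-8.0 / np.log(r))))
        return min(n, 20000)

    @classmethod
    def slow_waves(cls, phi: float = 0.995, marginal_sd: float = 0.05) -> "ArmaModel":
        """AR(1) tuned to a target marginal sd; default mimics slow genomic waves."""
        return cls(ar_coeffs=(phi,), ma_coeffs=(),
                   innovation_sd=marginal_sd * np.sqrt(1.0 - phi ** 2))


@dataclass
class BafNoiseModel:
    """Noise for the BAF signal (heterozygous vs homozygous loci)."""

    sigma_he: float = DEFAULT_SIGMA_BAF_HE
    sigma_ho: float = DEFAULT_SIGMA_BAF_HO
    pi_extreme: float = DEFAULT_PI_EXTREME

    def __post_init__(self):
        if self.sigma_he < 0 or self.sigma_ho < 0:
            raise ConfigurationError("BAF noise sds must be >= 0")
        if not (0 <= self.pi_extreme <= 1):
            raise ConfigurationError("pi_extreme must lie in [0, 1]")


@dataclass
class SignalTrack:
    """Per-SNP synthesized signals.  BAF is NaN where it is undefined."""

    lrr: np.ndarray
    baf: np.ndarray

    def __post_init__(self):
        self.lrr = np.asarray(self.lrr, dtype=float)
        self.baf = np.asarray(self.baf, dtype=float)
        if self.lrr.shape != self.baf.shape:
            raise ValueError("lrr and baf must have equal length")
        if np.any(~np.isfinite(self.lrr)):
            raise ValueError("lrr must be finite")
        ok = np.isnan(self.baf) | ((self.baf >= 0) & (self.baf <= 1))
        if not np.all(ok):
            raise ValueError("baf must lie in [0, 1] or be NaN")

    def __len__(self) -> int:
        return len(self.lrr)


def arma_series(model: ArmaModel, n: int, seed) -> np.ndarray:
    """One realization of the autocorrelated bias, length ``n``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    model.check_stationary()
    if model.innovation_sd == 0:
        return np.zeros(n)
    rng = _rng(seed)
    ar = np.r_[1.0, -np.asarray(model.ar_coeffs)]
    ma = np.r_[1.0, np.asarray(model.ma_coeffs)]
    return arma_generate_sample(
        ar, ma, nsample=n, scale=model.innovation_sd,
        distrvs=rng.standard_normal, burnin=model.burnin())


def draw_lrr_levels(x: np.ndarray, model: LrrModel, seed) -> np.ndarray:
    """Per-SNP, per-clone copy-number levels ``r ~ N(mu_x, sigma_x)``.

    Draws are independent across SNPs and clones; with all sigma zero the
    result equals ``mu_x`` exactly.
    """
    rng = _rng(seed)
    mu, sg = model.lookup(x)
    return rng.normal(mu, sg)


def synthesize_lrr(genotypes, weights: np.ndarray, model: LrrModel,
                   arma: ArmaModel, seed) -> np.ndarray:
    """LRR mixture of per-clone levels plus baseline shift and ARMA bias."""
    x = np.asarray(genotypes.x)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != x.shape:
        raise ValueError("weights must be SNPs x cell types, matching genotypes")
    if np.any(np.abs(weights.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("cell-type proportions must sum to one at every locus")
    rng = _rng(seed)
    r = draw_lrr_levels(x, model, rng)
    c = arma_series(arma, x.shape[0], rng)
    return (weights * r).sum(axis=1) + model.baseline_shift + c


def synthesize_baf(genotypes, weights: np.ndarray, noise: BafNoiseModel,
                   seed) -> np.ndarray:
    """BAF = weighted allele ratio plus the genotype-dependent noise mixture.

    Homozygous loci (noiseless value exactly 0 or 1) are forced to the exact
    extreme with probability ``pi_extreme`` and otherwise perturbed into the
    interval by a half-Gaussian of sd ``sigma_ho``; heterozygous loci get a
    full Gaussian of sd ``sigma_he``.  Output is clipped to [0, 1].  SNPs
    where every contributing clone has copy number zero get NaN.
    """
    x = np.asarray(genotypes.x)
    z = np.asarray(genotypes.z)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != x.shape:
        raise ValueError("weights must be SNPs x cell types, matching genotypes")
    rng = _rng(seed)
    n = x.shape[0]
    num = (weights * z).sum(axis=1)
    den = (weights * x).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        b = np.where(den > 0, num / den, np.nan)

    # fixed draw order keeps results reproducible across mask patterns
    u = rng.random(n)
    half = np.abs(rng.normal(0.0, noise.sigma_ho, size=n))
    gauss = rng.normal(0.0, noise.sigma_he, size=n)

    hom0 = b == 0.0
    hom1 = b == 1.0
    het = ~hom0 & ~hom1 & ~np.isnan(b)
    out = b.copy()
    forced = u < noise.pi_extreme
    out[hom0 & ~forced] = b[hom0 & ~forced] + half[hom0 & ~forced]
    out[hom0 & forced] = 0.0
    out[hom1 & ~forced] = b[hom1 & ~forced] - half[hom1 & ~forced]
    out[hom1 & forced] = 1.0
    out[het] = b[het] + gauss[het]
    return np.clip(out, 0.0, 1.0)


def expected_signals(genotypes, weights: np.ndarray, model: LrrModel):
    """Noiseless (lrr, baf): the synthesis equations with all noise zeroed.

    Matches ``synthesize_lrr``/``synthesize_baf`` bit-for-bit when every
    sigma and the ARMA innovation sd are zero and ``pi_extreme`` is one.
    """
    x = np.asarray(genotypes.x)
    z = np.asarray(genotypes.z)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != x.shape:
        raise ValueError("weights must be SNPs x cell types, matching genotypes")
    mu, _ = model.lookup(x)
    lrr = (weights * mu).sum(axis=1) + model.baseline_shift
    num = (weights * z).sum(axis=1)
    den = (weights * x).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        baf = np.where(den > 0, num / den, np.nan)
    return lrr, baf
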