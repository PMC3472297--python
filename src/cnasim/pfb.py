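"""Population B-allele frequency (PFB) sources.

Five ways to obtain the per-SNP PFB vector: a user file in the PennCNV
``.pfb`` dialect, a uniform distribution, any constant (0.5 maximizes
genotype information), a three-peak mixture at 0 / 0.5 / 1, or a packaged
empirical stand-in distribution (a beta mixture with point masses at the
extremes, shipped so the tool stays download-free).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import read_pfb

__all__ = ["PfbSource", "make_pfb"]

KINDS = ("file", "uniform", "constant", "three_peak", "packaged_empirical")

# packaged empirical stand-in: (weight, component); point masses then betas
_EMPIRICAL_MIX = (
    (0.15, ("point", 0.0)),
    (0.15, ("point", 1.0)),
    (0.50, ("beta", 0.8, 0.8)),
    (0.20, ("beta", 2.0, 2.0)),
)


@dataclass
class PfbSource:
    kind: str = "packaged_empirical"
    constant_value: float = 0.5
    peak_weights: tuple = (0.35, 0.30, 0.35)
    peak_sd: float = 0.02
    path: str | None = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown PFB source kind {self.kind!r}; "
                             f"valid kinds: {', '.join(KINDS)}")
        if not (0 <= self.constant_value <= 1):
            raise ValueError("constant_value must lie in [0, 1]")
        w = np.asarray(self.peak_weights, dtype=float)
        if len(w) != 3 or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("peak_weights must be three non-negative reals")
        self.peak_weights = tuple(w / w.sum())


def make_pfb(source: PfbSource, n: int, seed) -> np.ndarray:
    """Sample (or load) a PFB vector of length ``n``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if source.kind == "constant":
        return np.full(n, float(source.constant_value))
    if source.kind == "uniform":
        return rng.random(n)
    if source.kind == "three_peak":
        comp = rng.choice(3, size=n, p=source.peak_weights)
        mid = np.clip(rng.normal(0.5, source.peak_sd, size=n), 0.0, 1.0)
        out = np.where(comp == 0, 0.0, np.where(comp == 2, 1.0, mid))
        return out
    if source.kind == "packaged_empirical":
        weights = np.array([w for w, _ in _EMPIRICAL_MIX])
        comp = rng.choice(len(weights), size=n, p=weights)
        out = np.empty(n)
        for k, (_, spec) in enumerate(_EMPIRICAL_MIX):
            m = comp == k
            if spec[0] == "point":
                out[m] = spec[1]
            else:
                out[m] = rng.beta(spec[1], spec[2], size=int(m.sum()))
        return out
    # kind == "file"
    if source.path is None:
        raise ValueError("PFB source of kind 'file' needs a path")
    df = read_pfb(source.path)
    if len(df) < n:
        raise ValueError(
            f"PFB file {source.path} holds {len(df)} SNPs, need {n}")
    return df["PFB"].to_numpy(dtype=float)[:n]
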