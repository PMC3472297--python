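"""Whole-sample assembly: pattern presets, scaffold mode, replicate sets.

A sample is a tiling of the synthetic genome by altered regions.  Five
pattern presets reproduce characteristic tumour alteration profiles; each
is specified as a SNP-length share per region class, chosen so that the
length-weighted DNA index and the labelled composition hit the preset's
targets exactly before per-replicate jitter.  Region lengths are drawn from
{10, 20, 40, 80, 160} SNPs and every replicate carries between 205 and 280
truth fragments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .genotype import GenotypeMatrix, RegionSpec, SNPGrid, assign_region_genotypes
from .pfb import PfbSource, make_pfb
from .signals import (ArmaModel, BafNoiseModel, LrrModel, SignalTrack,
                      arma_series, expected_signals, synthesize_baf,
                      synthesize_lrr)

__all__ = [
    "RegionClass",
    "PatternPreset",
    "PRESETS",
    "SampleConfig",
    "TruthRegion",
    "SampleTruth",
    "ScaffoldRecord",
    "read_scaffold",
    "write_scaffold",
    "build_pattern",
    "build_pattern_detailed",
    "build_from_scaffold",
    "dna_index",
    "composition",
    "draw_baseline_shift",
    "generate_replicates",
    "BuildResult",
]

REGION_LENGTHS = (10, 20, 40, 80, 160)
DEFAULT_LENGTH_WEIGHTS = {10: 0.30, 20: 0.25, 40: 0.25, 80: 0.14, 160: 0.06}
FRAGMENT_BOUNDS = (205, 280)


@dataclass(frozen=True)
class RegionClass:
    """A reusable region template: per-clone CNs, haplotype events, fractions."""

    name: str
    cns: tuple
    haps: tuple
    fractions: tuple = (1.0,)
    germline: bool = False

    def to_region(self, snp_start: int, snp_end: int, label: str = "") -> RegionSpec:
        return RegionSpec(snp_start=snp_start, snp_end=snp_end, cns=self.cns,
                          haps=self.haps, subclone_fractions=self.fractions,
                          germline_loh=self.germline,
                          label=label or self.name)

    @property
    def cn_eff(self) -> float:
        return float(np.dot(self.fractions, self.cns))


# template library; single-copy deletions are somatic LOH by construction
CLASSES = {c.name: c for c in (
    RegionClass("cn1", (1,), ((1, 0),)),
    RegionClass("cn2het", (2,), ((1, 1),)),
    RegionClass("cn2loh", (2,), ((2, 0),)),
    RegionClass("cn2germ", (2,), ((1, 1),), germline=True),
    RegionClass("cn3", (3,), ((2, 1),)),
    RegionClass("cn3loh", (3,), ((3, 0),)),
    RegionClass("cn4bal", (4,), ((2, 2),)),
    RegionClass("cn4imb", (4,), ((3, 1),)),
    RegionClass("cn4loh", (4,), ((4, 0),)),
    RegionClass("cn5", (5,), ((3, 2),)),
    RegionClass("cn5imb", (5,), ((4, 1),)),
    RegionClass("cx2a", (2, 3), ((1, 1), (2, 1)), (0.5, 0.5)),
    RegionClass("cx2b", (1, 4), ((1, 0), (3, 1)), (0.3, 0.7)),
    RegionClass("cx3", (0, 3, 4), ((0, 0), (2, 1), (3, 1)), (0.25, 0.5, 0.25)),
)}


@dataclass(frozen=True)
class PatternPreset:
    """Named alteration pattern: SNP-length share per region class."""

    name: str
    shares: dict  # class name -> share of the genome, sums to 1
    target_dna_index: float
    label: str          # which composition metric the preset advertises
    target_label_pct: float

    def __post_init__(self):
        tot = sum(self.shares.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"preset {self.name}: shares sum to {tot}, not 1")
        for cname in self.shares:
            if cname not in CLASSES:
                raise ValueError(f"preset {self.name}: unknown class {cname}")


PRESETS = {p.name: p for p in (
    PatternPreset(
        "near_diploid",
        {"cn2het": 0.454, "cn1": 0.179, "cn2loh": 0.090, "cn2germ": 0.090,
         "cn3": 0.091, "cn4imb": 0.040, "cn5": 0.016, "cx3": 0.040},
        target_dna_index=1.03, label="cn2het", target_label_pct=45.4),
    PatternPreset(
        "near_triploid",
        {"cn1": 0.163, "cn2het": 0.124, "cn2loh": 0.050, "cn2germ": 0.050,
         "cn3": 0.313, "cn3loh": 0.090, "cn4imb": 0.130, "cn5": 0.040,
         "cx3": 0.040},
        target_dna_index=1.32, label="cn3", target_label_pct=40.3),
    PatternPreset(
        "near_tetraploid",
        {"cn1": 0.181, "cn2het": 0.016, "cn2loh": 0.040, "cn2germ": 0.040,
         "cn3": 0.140, "cn3loh": 0.030, "cn4bal": 0.200, "cn4imb": 0.143,
         "cn4loh": 0.040, "cn5": 0.120, "cx3": 0.050},
        target_dna_index=1.57, label="cn4", target_label_pct=38.3),
    PatternPreset(
        "loh_enriched",
        {"cn1": 0.100, "cn2het": 0.090, "cn2loh": 0.130, "cn2germ": 0.100,
         "cn3": 0.339, "cn3loh": 0.071, "cn4imb": 0.100, "cn5": 0.030,
         "cx3": 0.040},
        target_dna_index=1.31, label="loh", target_label_pct=40.1),
    PatternPreset(
        "complex",
        {"cn1": 0.0696, "cn2het": 0.0644, "cn2loh": 0.040, "cn2germ": 0.040,
         "cn3": 0.140, "cn4imb": 0.120, "cn5": 0.050, "cx3": 0.200,
         "cx2a": 0.140, "cx2b": 0.136},
        target_dna_index=1.39, label="complex", target_label_pct=47.6),
)}


@dataclass
class SampleConfig:
    """Everything about a sample except the alteration pattern itself."""

    lrr: LrrModel = field(default_factory=LrrModel)
    arma: ArmaModel = field(default_factory=ArmaModel.slow_waves)
    baf: BafNoiseModel = field(default_factory=BafNoiseModel)
    pfb: PfbSource = field(default_factory=PfbSource)
    shift_slope: float = 0.6       # l ~ N(-slope * (DI_eff - 1), shift_sd)
    shift_sd: float = 0.05
    total_snps: int = 8700
    snps_per_chrom: int = 2000
    spacing_bp: int = 5000
    cn_max: int = 5
    length_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_WEIGHTS))
    fragment_bounds: tuple = FRAGMENT_BOUNDS
    budget_jitter_sd: float = 0.04
    waves: ArmaModel | None = None      # optional long-distance component
    complexity: float = 0.0             # scaffold mode: P(region -> 2 subclones)
    max_layout_tries: int = 500

    def zero_noise(self) -> "SampleConfig":
        """Copy with every stochastic signal term silenced (shift included)."""
        return replace(
            self, lrr=self.lrr.zero_noise(),
            arma=ArmaModel(), waves=None, shift_sd=0.0,
            baf=BafNoiseModel(sigma_he=0.0, sigma_ho=0.0, pi_extreme=1.0))

    @classmethod
    def from_dict(cls, d: dict) -> "SampleConfig":
        kw = {}
        if "mu" in d or "sigma_x" in d or "baseline_shift" in d:
            mu = {int(k): float(v) for k, v in d.get("mu", LrrModel().mu).items()}
            sx = d.get("sigma_x", 0.2)
            sigma = ({int(k): float(v) for k, v in sx.items()}
                     if isinstance(sx, dict) else {k: float(sx) for k in mu})
            kw["lrr"] = LrrModel(mu=mu, sigma=sigma,
                                 baseline_shift=float(d.get("baseline_shift", 0.0)))
        if "arma" in d:
            a = d["arma"] or {}
            kw["arma"] = ArmaModel(ar_coeffs=tuple(a.get("ar", ())),
                                   ma_coeffs=tuple(a.get("ma", ())),
                                   innovation_sd=float(a.get("innovation_sd", 0.0)))
        if "waves" in d and d["waves"]:
            a = d["waves"]
            kw["waves"] = ArmaModel(ar_coeffs=tuple(a.get("ar", ())),
                                    ma_coeffs=tuple(a.get("ma", ())),
                                    innovation_sd=float(a.get("innovation_sd", 0.0)))
        baf_keys = {"sigma_baf_he", "sigma_baf_ho", "pi_extreme"}
        if baf_keys & set(d):
            kw["baf"] = BafNoiseModel(
                sigma_he=float(d.get("sigma_baf_he", 0.03)),
                sigma_ho=float(d.get("sigma_baf_ho", 0.015)),
                pi_extreme=float(d.get("pi_extreme", 0.30)))
        if "pfb" in d:
            p = d["pfb"] or {}
            kw["pfb"] = PfbSource(
                kind=p.get("kind", "packaged_empirical"),
                constant_value=float(p.get("constant_value", 0.5)),
                peak_weights=tuple(p.get("peak_weights", (0.35, 0.30, 0.35))),
                path=p.get("path"))
        if "shift_law" in d:
            s = d["shift_law"] or {}
            kw["shift_slope"] = float(s.get("slope", 0.6))
            kw["shift_sd"] = float(s.get("sd", 0.05))
        if "grid" in d:
            g = d["grid"] or {}
            kw["total_snps"] = int(g.get("total_snps", 8700))
            kw["snps_per_chrom"] = int(g.get("snps_per_chrom", 2000))
            kw["spacing_bp"] = int(g.get("spacing_bp", 5000))
        for key in ("cn_max", "complexity", "budget_jitter_sd"):
            if key in d:
                kw[key] = type(getattr(cls(), key))(d[key])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "SampleConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)


@dataclass(frozen=True)
class TruthRegion:
    """One truth fragment, in both SNP-index and bp coordinates."""

    chrom: str
    snp_start: int      # global SNP index, 0-based half-open
    snp_end: int
    start_bp: int       # 0-based half-open bp within the chromosome
    end_bp: int
    cns: tuple
    fractions: tuple
    loh_status: str
    name: str = ""
    n_snps: int = -1

    def __post_init__(self):
        if self.n_snps < 0:
            object.__setattr__(self, "n_snps", self.snp_end - self.snp_start)

    @property
    def cn_eff(self) -> float:
        return float(np.dot(self.fractions, self.cns))

    @property
    def is_complex(self) -> bool:
        return len(self.cns) > 1

    @property
    def is_diploid_het(self) -> bool:
        return self.cns == (2,) and self.loh_status == "none"


@dataclass
class SampleTruth:
    """All truth fragments of one sample plus its sample-wide draws."""

    regions: list
    dna_index: float
    shift: float
    contamination: float
    n_snps: int

    def __post_init__(self):
        if sum(r.n_snps for r in self.regions) != self.n_snps:
            raise ValueError("truth regions must tile the grid exactly")


@dataclass
class BuildResult:
    """Full output of a build, including internals used by tests/oracles."""

    grid: SNPGrid
    genotypes: GenotypeMatrix
    weights: np.ndarray
    truth: SampleTruth
    track: SignalTrack
    region_specs: list


def dna_index(truth: SampleTruth) -> float:
    """Half of the SNP-length-weighted mean tumour copy number.

    Subclone fractions weight copy numbers within regions; normal-cell
    contamination is excluded (the index describes the tumour genome).
    """
    if not truth.regions:
        raise ValueError("truth holds no regions")
    w = np.array([r.n_snps for r in truth.regions], dtype=float)
    cn = np.array([r.cn_eff for r in truth.regions], dtype=float)
    return float((w * cn).sum() / w.sum() / 2.0)


def composition(truth: SampleTruth) -> dict:
    """SNP-length-weighted composition fractions used by the presets."""
    total = float(sum(r.n_snps for r in truth.regions))
    out = {"cn2het": 0.0, "cn3": 0.0, "cn4": 0.0, "loh": 0.0, "complex": 0.0}
    for r in truth.regions:
        f = r.n_snps / total
        if r.is_complex:
            out["complex"] += f
        else:
            cn = r.cns[0]
            if cn == 2 and r.loh_status == "none":
                out["cn2het"] += f
            if cn == 3:
                out["cn3"] += f
            if cn == 4:
                out["cn4"] += f
        if r.loh_status in ("somatic", "germline"):
            out["loh"] += f
    return out


def draw_baseline_shift(dna_index_value: float, config: SampleConfig, seed,
                        contamination: float = 0.0) -> float:
    """Sample the LRR baseline shift from the DNA-index relationship.

    Contamination pulls the effective DNA index towards 1 before the draw:
    ``DI_eff = (1 - w1) * DI + w1``.
    """
    if dna_index_value <= 0:
        raise ValueError("dna_index must be > 0")
    rng = np.random.default_rng(seed)
    di_eff = (1.0 - contamination) * dna_index_value + contamination
    mean = -config.shift_slope * (di_eff - 1.0)
    return float(rng.normal(mean, config.shift_sd))


# ---------------------------------------------------------------------------
# layout machinery


def _partition_budget(budget: int, rng, weights: dict) -> list:
    """Split a SNP budget (multiple of 10) into menu lengths, summing exactly."""
    lengths = np.array(sorted(weights))
    probs = np.array([weights[l] for l in lengths], dtype=float)
    probs = probs / probs.sum()
    out = []
    rem = int(budget)
    while rem > 0:
        ok = lengths <= rem
        p = probs[ok]
        out.append(int(rng.choice(lengths[ok], p=p / p.sum())))
        rem -= out[-1]
    return out


def _class_budgets(preset: PatternPreset, total: int, rng,
                   jitter_sd: float) -> dict:
    names = list(preset.shares)
    shares = np.array([preset.shares[n] for n in names], dtype=float)
    if jitter_sd > 0:
        shares = shares * np.clip(rng.normal(1.0, jitter_sd, len(shares)),
                                  0.5, 1.5)
    shares = shares / shares.sum()
    budgets = np.maximum(10, np.round(shares * total / 10).astype(int) * 10)
    drift = total - int(budgets.sum())
    budgets[int(np.argmax(budgets))] += drift  # absorb rounding on the largest
    return dict(zip(names, (int(b) for b in budgets)))


def _layout_fragments(preset: PatternPreset, config: SampleConfig, rng):
    """One candidate layout: shuffled fragments split at chromosome ends.

    Returns a list of (RegionClass, global snp_start, snp_end).
    """
    budgets = _class_budgets(preset, config.total_snps, rng,
                             config.budget_jitter_sd)
    pieces = []
    for cname, budget in budgets.items():
        for length in _partition_budget(budget, rng, config.length_weights):
            pieces.append((cname, length))
    order = rng.permutation(len(pieces))
    fragments = []
    pos = 0
    spc = config.snps_per_chrom
    for k in order:
        cname, length = pieces[k]
        left = length
        while left > 0:
            room = spc - pos % spc
            seg = min(left, room)
            fragments.append((CLASSES[cname], pos, pos + seg))
            pos += seg
            left -= seg
    return fragments


def _assemble(fragments, contamination: float, config: SampleConfig,
              seeds) -> BuildResult:
    """Genotype, weight and synthesize a laid-out sample."""
    ss_pfb, ss_geno, ss_shift, ss_lrr, ss_waves, ss_baf = seeds
    total = fragments[-1][2]
    pfb = make_pfb(config.pfb, total, ss_pfb)
    grid = SNPGrid.synthetic(pfb, snps_per_chrom=config.snps_per_chrom,
                             spacing_bp=config.spacing_bp)

    rng_geno = np.random.default_rng(ss_geno)
    normal_z = rng_geno.binomial(2, pfb).astype(np.int64)
    j_max = max(len(c.cns) for c, _, _ in fragments)
    n = total
    x = np.full((n, 1 + j_max), 2, dtype=np.int64)
    z = np.zeros((n, 1 + j_max), dtype=np.int64)
    weights = np.zeros((n, 1 + j_max))
    weights[:, 0] = contamination

    specs, regions = [], []
    for i, (cls_, a, b) in enumerate(fragments):
        spec = cls_.to_region(a, b, label=f"{cls_.name}.{i:04d}")
        gm = assign_region_genotypes(spec, pfb[a:b], normal_z[a:b], rng_geno)
        jj = len(cls_.cns)
        x[a:b, :jj + 1] = gm.x
        z[a:b, :jj + 1] = gm.z
        weights[a:b, 1:jj + 1] = (np.asarray(cls_.fractions)
                                  * (1.0 - contamination))
        chrom_idx = a // config.snps_per_chrom
        off = chrom_idx * config.snps_per_chrom
        regions.append(TruthRegion(
            chrom=f"chr{chrom_idx + 1}",
            snp_start=a, snp_end=b,
            start_bp=(a - off) * config.spacing_bp,
            end_bp=(b - off) * config.spacing_bp,
            cns=cls_.cns, fractions=cls_.fractions,
            loh_status=spec.loh_status, name=spec.label))
        specs.append(spec)

    gm_all = GenotypeMatrix(x=x, z=z)
    truth = SampleTruth(regions=regions, dna_index=0.0, shift=0.0,
                        contamination=contamination, n_snps=n)
    truth.dna_index = dna_index(truth)
    truth.shift = draw_baseline_shift(truth.dna_index, config, ss_shift,
                                      contamination=contamination)

    model = replace(config.lrr, mu=dict(config.lrr.mu),
                    sigma=dict(config.lrr.sigma), baseline_shift=truth.shift)
    lrr = synthesize_lrr(gm_all, weights, model, config.arma, ss_lrr)
    if config.waves is not None:
        lrr = lrr + arma_series(config.waves, n, ss_waves)
    baf = synthesize_baf(gm_all, weights, config.baf, ss_baf)
    track = SignalTrack(lrr=lrr, baf=baf)
    return BuildResult(grid=grid, genotypes=gm_all, weights=weights,
                       truth=truth, track=track, region_specs=specs)


def build_pattern_detailed(preset, contamination: float, seed,
                           config: SampleConfig | None = None) -> BuildResult:
    """Like :func:`build_pattern` but returning genotypes and weights too."""
    if isinstance(preset, str):
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; valid presets: "
                             f"{', '.join(sorted(PRESETS))}")
        preset = PRESETS[preset]
    if not (0 <= contamination < 1):
        raise ValueError("contamination must lie in [0, 1)")
    config = config or SampleConfig()
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    ss_layout, *rest = ss.spawn(7)
    rng_layout = np.random.default_rng(ss_layout)
    lo, hi = config.fragment_bounds
    for _ in range(config.max_layout_tries):
        fragments = _layout_fragments(preset, config, rng_layout)
        if lo <= len(fragments) <= hi:
            break
    else:
        raise RuntimeError(
            f"could not lay out {lo}..{hi} fragments after "
            f"{config.max_layout_tries} tries; adjust total_snps or bounds")
    return _assemble(fragments, contamination, config, rest[:6])


def build_pattern(preset, contamination: float, seed,
                  config: SampleConfig | None = None):
    """Generate one preset sample.  Returns (SignalTrack, SampleTruth, SNPGrid)."""
    res = build_pattern_detailed(preset, contamination, seed, config)
    return res.track, res.truth, res.grid


# ---------------------------------------------------------------------------
# scaffold (hybrid) mode


@dataclass(frozen=True)
class ScaffoldRecord:
    length_snps: int
    cns: tuple
    haps: tuple
    germline_loh: bool = False
    fractions: tuple = None

    def __post_init__(self):
        if self.length_snps < 1:
            raise ValueError("scaffold record length must be >= 1")
        if self.fractions is None:
            object.__setattr__(
                self, "fractions",
                tuple([1.0 / len(self.cns)] * len(self.cns)))


def read_scaffold(path) -> list:
    """Parse a scaffold TSV: ``length_snps  cn  ratio  germline_loh [fractions]``.

    ``cn`` is a comma list of per-clone copy numbers; ``ratio`` a comma list
    of per-clone ``a:b`` haplotype copy counts (must sum to the clone CN).
    """
    records = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    for idx, line in enumerate(lines):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0].strip().lower() in ("length_snps", "length"):
            continue
        try:
            length = int(fields[0])
            cns = tuple(int(v) for v in fields[1].split(","))
            haps = tuple(tuple(int(u) for u in part.split(":"))
                         for part in fields[2].split(","))
            germ = bool(int(fields[3]))
            fracs = (tuple(float(v) for v in fields[4].split(","))
                     if len(fields) > 4 and fields[4].strip() else None)
            if len(haps) != len(cns):
                raise ValueError("ratio count != clone count")
            for cn, hap in zip(cns, haps):
                if hap[0] + hap[1] != cn:
                    raise ValueError(f"ratio {hap[0]}:{hap[1]} does not sum "
                                     f"to copy number {cn}")
            records.append(ScaffoldRecord(length_snps=length, cns=cns,
                                          haps=haps, germline_loh=germ,
                                          fractions=fracs))
        except (ValueError, IndexError) as exc:
            raise IOError(f"{path}: malformed scaffold record at line "
                          f"{idx + 1}: {exc}") from exc
    return records


def write_scaffold(records, path) -> None:
    with open(path, "w") as fh:
        fh.write("length_snps\tcn\tratio\tgermline_loh\tfractions\n")
        for r in records:
            fh.write("\t".join([
                str(r.length_snps),
                ",".join(str(c) for c in r.cns),
                ",".join(f"{a}:{b}" for a, b in r.haps),
                str(int(r.germline_loh)),
                ",".join(f"{f:g}" for f in r.fractions),
            ]) + "\n")


def build_from_scaffold(scaffold, contamination: float,
                        config: SampleConfig | None = None, seed=0):
    """Generate a hybrid sample whose regions follow the scaffold order."""
    config = config or SampleConfig()
    if isinstance(scaffold, (str, bytes)) or hasattr(scaffold, "__fspath__"):
        scaffold = read_scaffold(scaffold)
    if not scaffold:
        raise ValueError("scaffold holds no records")
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    ss_cx, *rest = ss.spawn(7)
    rng = np.random.default_rng(ss_cx)

    fragments = []
    pos = 0
    spc = config.snps_per_chrom
    for i, rec in enumerate(scaffold):
        cls_ = RegionClass(name=f"scaffold{i:04d}", cns=rec.cns,
                           haps=rec.haps, fractions=rec.fractions,
                           germline=rec.germline_loh)
        # overall intra-tumour complexity: occasionally split off a
        # diploid-het subclone from a single-clone altered region
        if (config.complexity > 0 and len(cls_.cns) == 1
                and not cls_.germline and cls_.cns != (2,)
                and rng.random() < config.complexity):
            cls_ = RegionClass(name=cls_.name + ".cx",
                               cns=cls_.cns + (2,),
                               haps=cls_.haps + ((1, 1),),
                               fractions=(0.7, 0.3))
        left = rec.length_snps
        while left > 0:
            room = spc - pos % spc
            seg = min(left, room)
            fragments.append((cls_, pos, pos + seg))
            pos += seg
            left -= seg
    res = _assemble(fragments, contamination, config, rest[:6])
    return res.track, res.truth, res.grid


def generate_replicates(preset, contamination: float, n_reps: int,
                        base_seed: int, config: SampleConfig | None = None):
    """Deterministic replicate set; per-replicate seeds spawn from base_seed."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    children = np.random.SeedSequence(base_seed).spawn(n_reps)
    return [build_pattern(preset, contamination, child, config)
            for child in children]
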