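"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the study system the pipeline is built for: ~15
remnant populations of a self-incompatible perennial herb in two climate
zones (~500 km apart) with mosaic soil variation, maternal (predominantly
half-sib) family structure in a common-garden trait experiment, ten
multi-allelic microsatellite loci, and a paired local/foreign transplant
design (12 population pairs × 15 family pairs × 2 origins × 4 blocks =
1440 pots).

Every generator is a pure function of its configuration (which carries the
seed): identical configurations give bit-identical tables.  Each returns a
truth record sufficient to score the downstream estimator — realized
variance components and implied true Q_ST, per-population allele
frequencies and the frequency-level θ expectation, planted adaptation
effects — without re-deriving ground truth.

Default parameter choices (documented in the methods note): trait variance
components give moderate quantitative differentiation; the Balding–Nichols
divergence F = 0.05 matches weak neutral structure with substantial gene
flow; population sizes span 10² – 10⁵ reproductive plants and pair
distances 0.7 – 600 km, the ranges of the emulated system.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    GenotypeTable,
    PairExperiment,
    SiteEnvironment,
    TraitTable,
    ValidationError,
)

__all__ = [
    "TraitSpec",
    "MarkerSpec",
    "EnvSpec",
    "PairSpec",
    "SimulationConfig",
    "gen_traits",
    "gen_genotypes",
    "gen_environment",
    "gen_pair_experiment",
    "expected_theta",
    "true_qst",
]


@dataclass(frozen=True)
class TraitSpec:
    """Generating variances for one trait: value = grand mean + pop + family + residual."""

    v_between: float = 0.2
    v_family: float = 0.25
    v_residual: float = 0.75
    h2: float = 0.4
    grand_mean: float = 10.0

    def __post_init__(self):
        if min(self.v_between, self.v_family, self.v_residual) < 0:
            raise ValidationError("variances must be >= 0")
        if not (0.0 <= self.h2 <= 1.0):
            raise ValidationError("h2 must be in [0, 1]")


@dataclass(frozen=True)
class MarkerSpec:
    n_loci: int = 10
    alleles_per_locus: int = 6
    bn_f: float = 0.05  # Balding-Nichols divergence

    def __post_init__(self):
        if not (0.0 < self.bn_f < 1.0):
            raise ValidationError("bn_f must be in (0, 1)")


@dataclass(frozen=True)
class EnvSpec:
    n_climate_vars: int = 27
    n_soil_vars: int = 16
    climate_zone_effect: float = 3.0  # zone shift in latent-sd units
    climate_collinear_noise: float = 0.15  # residual sd around the zone latent
    soil_collinear_blocks: int = 4  # planted blocks of near-duplicate soil vars
    soil_block_size: int = 3
    soil_collinear_noise: float = 0.02
    zone_separation_km: float = 500.0
    within_zone_spread_km: float = 80.0


@dataclass(frozen=True)
class PairSpec:
    n_pairs: int = 12
    families_per_pair: int = 15
    blocks: int = 4
    seeds_per_pot: int = 3  # sown per pot; thinned to one seedling
    germination_p: float = 0.85
    survival_p: float = 0.95
    biomass_log_mean: float = 0.0  # log-scale; exp -> ~1 g median
    biomass_log_sd: float = 0.3
    inflorescence_rate: float = 5.0
    seed_weight_mean: float = 1.0  # g (bulk of 12 seeds)
    seed_weight_sd: float = 0.1
    family_log_sd: float = 0.1  # maternal-family effect on log biomass
    # pair_id -> trait -> effect; biomass/inflorescences fractional local
    # advantage, survival a logit-scale shift for local origin
    adaptation_effects: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generators; defaults mirror the emulated design."""

    n_pops: int = 15
    fams_per_pop: int = 25  # within the 22-30 maternal-family range
    obs_per_fam: int = 4  # offspring measured per family
    trait_specs: dict = field(
        default_factory=lambda: {
            "leaves": TraitSpec(v_between=0.15, h2=0.35),
            "leaf_length": TraitSpec(v_between=0.25, h2=0.45),
            "stem_length": TraitSpec(v_between=0.30, h2=0.50),
            "stems": TraitSpec(v_between=0.10, h2=0.30),
            "prop_flowering": TraitSpec(v_between=0.20, h2=0.40),
            "inflorescences": TraitSpec(v_between=0.20, h2=0.35),
        }
    )
    markers: MarkerSpec = field(default_factory=MarkerSpec)
    env: EnvSpec = field(default_factory=EnvSpec)
    pairs: PairSpec = field(default_factory=PairSpec)
    seed: int = 0

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)

    def population_names(self) -> list[str]:
        return [f"P{i + 1:02d}" for i in range(self.n_pops)]


# distinct substreams so the generators are independent of call order
_STREAM = {"traits": 1, "genotypes": 2, "environment": 3, "pairs": 4}


def _rng(cfg: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, _STREAM[stream]])


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------


def true_qst(spec: TraitSpec, formula_variant: str = "heritability_scaled",
             model: str = "half_sib") -> float:
    """Q_ST implied by the generating variances under a formula variant."""
    if formula_variant == "heritability_scaled":
        v_gw = spec.h2 * (spec.v_family + spec.v_residual)
    elif formula_variant == "literal_4x":
        v_gw = (4.0 if model == "half_sib" else 2.0) * spec.v_family
    else:
        raise ValidationError(f"unknown formula variant {formula_variant!r}")
    denom = spec.v_between + 2.0 * v_gw
    return 0.0 if denom == 0 else spec.v_between / denom


def gen_traits(cfg: SimulationConfig) -> tuple[TraitTable, dict]:
    """Family-structured trait table plus truth record.

    value = grand mean + population effect N(0, V_B) + family effect
    N(0, V_fam) + residual N(0, V_res).  The truth record stores the
    generating components, realized population effects, the parameter-level
    true Q_ST under each formula variant, and the *realized* true pairwise
    Q_ST per population pair — the estimand of a pairwise estimate
    conditional on the drawn population effects: with realized between-pair
    variance s² = (e_a − e_b)²/2, realized Q_ST = s²/(s² + 2 V_GW).
    """
    rng = _rng(cfg, "traits")
    pops = cfg.population_names()
    f, o = cfg.fams_per_pop, cfg.obs_per_fam
    n_total = cfg.n_pops * f * o
    pop_col = np.repeat(pops, f * o)
    fam_col = np.tile(np.repeat([f"F{j + 1:02d}" for j in range(f)], o), cfg.n_pops)
    ids = [f"ind{i + 1:05d}" for i in range(n_total)]
    data = {"individual_id": ids, "population": pop_col, "family": fam_col}
    truth: dict = {"traits": {}, "config": cfg}
    for trait, spec in cfg.trait_specs.items():
        pop_eff = rng.normal(0.0, np.sqrt(spec.v_between), cfg.n_pops)
        fam_eff = rng.normal(0.0, np.sqrt(spec.v_family), (cfg.n_pops, f))
        res = rng.normal(0.0, np.sqrt(spec.v_residual), (cfg.n_pops, f, o))
        values = spec.grand_mean + pop_eff[:, None, None] + fam_eff[:, :, None] + res
        data[trait] = values.ravel()
        v_gw = {
            "heritability_scaled": spec.h2 * (spec.v_family + spec.v_residual),
            "literal_4x": 4.0 * spec.v_family,
        }
        realized = {variant: {} for variant in v_gw}
        for ia in range(cfg.n_pops):
            for ib in range(ia + 1, cfg.n_pops):
                s2 = (pop_eff[ia] - pop_eff[ib]) ** 2 / 2.0
                for variant, g in v_gw.items():
                    denom = s2 + 2.0 * g
                    realized[variant][(pops[ia], pops[ib])] = (
                        0.0 if denom == 0 else float(s2 / denom)
                    )
        truth["traits"][trait] = {
            "spec": spec,
            "pop_effects": dict(zip(pops, pop_eff)),
            "true_qst": {
                variant: true_qst(spec, variant)
                for variant in ("heritability_scaled", "literal_4x")
            },
            "realized_pairwise_qst": realized,
        }
    return TraitTable(pd.DataFrame(data)), truth


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def expected_theta(freqs_by_pop: list[np.ndarray] | np.ndarray) -> float:
    """Frequency-level θ expectation for known per-population allele frequencies.

    The large-sample limit of the Weir–Cockerham estimator under
    Hardy–Weinberg genotype proportions within populations: with r
    populations and per-allele frequency variance s² = Σ(p_i − p̄)²/(r−1),
    θ_∞ = Σ s² / Σ [ (r−1)/r · s² + p̄(1 − p̄) ], summed over alleles and
    loci.  Accepts one (L, A) array per population (or a (r, L, A) array).
    """
    freqs = np.asarray(freqs_by_pop, dtype=float)
    if freqs.ndim == 2:
        freqs = freqs[:, None, :]
    r = freqs.shape[0]
    if r < 2:
        raise ValidationError("need >= 2 populations")
    pbar = freqs.mean(axis=0)  # (L, A)
    s2 = ((freqs - pbar) ** 2).sum(axis=0) / (r - 1)
    num = s2.sum()
    den = (s2 * (r - 1) / r + pbar * (1.0 - pbar)).sum()
    return 0.0 if den == 0 else float(num / den)


def gen_genotypes(cfg: SimulationConfig) -> tuple[GenotypeTable, dict]:
    """Balding–Nichols genotypes plus truth record.

    Ancestral allele frequencies are Dirichlet(1,...,1); each population's
    frequencies are Dirichlet(p·(1−F)/F) around the ancestral vector;
    diploid genotypes are two independent multinomial draws (random union
    of gametes, i.e. Hardy–Weinberg within populations).  The truth record
    stores ancestral and per-population frequencies and the frequency-level
    θ expectation for every population pair.
    """
    rng = _rng(cfg, "genotypes")
    m = cfg.markers
    pops = cfg.population_names()
    n_per_pop = cfg.fams_per_pop  # one genotyped individual per maternal family
    scale = (1.0 - m.bn_f) / m.bn_f
    ancestral = rng.dirichlet(np.ones(m.alleles_per_locus), size=m.n_loci)  # (L, A)
    pop_freqs = np.empty((cfg.n_pops, m.n_loci, m.alleles_per_locus))
    for i in range(cfg.n_pops):
        for l in range(m.n_loci):
            pop_freqs[i, l] = rng.dirichlet(np.maximum(ancestral[l] * scale, 1e-6))
    individuals, populations, rows = [], [], []
    for i, pop in enumerate(pops):
        for k in range(n_per_pop):
            individuals.append(f"{pop}_i{k + 1:03d}")
            populations.append(pop)
            geno = np.empty((m.n_loci, 2), dtype=np.int64)
            for l in range(m.n_loci):
                geno[l] = rng.choice(m.alleles_per_locus, size=2, p=pop_freqs[i, l]) + 1
            rows.append(geno)
    table = GenotypeTable(
        individuals=individuals,
        populations=np.array(populations, dtype=object),
        loci=[f"locus{l + 1:02d}" for l in range(m.n_loci)],
        alleles=np.array(rows),
    )
    pairwise = {}
    for i in range(cfg.n_pops):
        for j in range(i + 1, cfg.n_pops):
            pairwise[(pops[i], pops[j])] = expected_theta(pop_freqs[[i, j]])
    truth = {
        "ancestral_freqs": ancestral,
        "pop_freqs": {pop: pop_freqs[i] for i, pop in enumerate(pops)},
        "expected_pairwise_theta": pairwise,
        "bn_f": m.bn_f,
    }
    return table, truth


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------


def gen_environment(cfg: SimulationConfig) -> list[SiteEnvironment]:
    """Per-site environments: two climate zones plus mosaic soil variation.

    Climate variables track a zone latent (all strongly inter-correlated,
    so the correlation filter has work to do); soil variables are iid per
    site (a mosaic, uncorrelated with geography) except for planted
    collinear blocks of near-duplicates.  Coordinates place the two zones
    ``zone_separation_km`` apart with within-zone scatter up to
    ``within_zone_spread_km``.
    """
    rng = _rng(cfg, "environment")
    e = cfg.env
    pops = cfg.population_names()
    n = cfg.n_pops
    zone = (np.arange(n) >= (n + 1) // 2).astype(float)  # 0 = north, 1 = south

    km_per_deg = 111.19
    base_lat = -35.3
    lat = (
        base_lat
        - zone * e.zone_separation_km / km_per_deg
        + rng.uniform(-0.5, 0.5, n) * e.within_zone_spread_km / km_per_deg
    )
    lon = 149.1 + rng.uniform(-0.5, 0.5, n) * e.within_zone_spread_km / (
        km_per_deg * np.cos(np.radians(base_lat))
    )
    elevation = 600.0 + rng.normal(0.0, 60.0, n)

    latent = zone * e.climate_zone_effect + rng.normal(0.0, 0.3, n)
    climate = {}
    for v in range(e.n_climate_vars):
        slope = rng.uniform(0.5, 1.5) * rng.choice([-1.0, 1.0])
        climate[f"clim{v + 1:02d}"] = slope * latent + rng.normal(
            0.0, e.climate_collinear_noise, n
        )

    soil = {}
    idx = 0
    for b in range(e.soil_collinear_blocks):
        base = rng.normal(0.0, 1.0, n)
        for j in range(e.soil_block_size):
            if idx >= e.n_soil_vars:
                break
            soil[f"soil{idx + 1:02d}"] = base + rng.normal(0.0, e.soil_collinear_noise, n)
            idx += 1
    while idx < e.n_soil_vars:
        soil[f"soil{idx + 1:02d}"] = rng.normal(0.0, 1.0, n)
        idx += 1

    sites = []
    for i, pop in enumerate(pops):
        variables = {"elevation_var": float(elevation[i])}
        variables.update({k: float(v[i]) for k, v in climate.items()})
        variables.update({k: float(v[i]) for k, v in soil.items()})
        sites.append(
            SiteEnvironment(
                site=pop,
                variables=variables,
                latitude=float(lat[i]),
                longitude=float(lon[i]),
                elevation=float(elevation[i]),
            )
        )
    return sites


# ---------------------------------------------------------------------------
# transplant pair experiment
# ---------------------------------------------------------------------------


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _inv_logit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def gen_pair_experiment(cfg: SimulationConfig) -> tuple[list[PairExperiment], dict]:
    """Paired local/foreign transplant design plus truth record.

    ``n_pairs`` population pairs × 2 origins × ``families_per_pair`` family
    pairs × ``blocks`` blocks, one pot each (default 12×2×15×4 = 1440
    pots).  Germination and survival are Bernoulli with logit-scale origin
    effects; biomass is log-normal with a maternal-family effect and a
    multiplicative local-origin effect; inflorescence counts are Poisson
    with a log-scale effect; family seed weight is normal.  Planted
    adaptation effects per pair/trait come from
    ``cfg.pairs.adaptation_effects`` and are echoed in the truth record.
    """
    rng = _rng(cfg, "pairs")
    p = cfg.pairs
    pops = cfg.population_names()
    if p.n_pairs > len(pops) * (len(pops) - 1):
        raise ValidationError("more pairs requested than ordered population pairs")

    # local/foreign assignments spanning the population list
    pair_defs = []
    for k in range(p.n_pairs):
        local = pops[k % len(pops)]
        foreign = pops[(k * 3 + 5) % len(pops)]
        if foreign == local:
            foreign = pops[(k * 3 + 6) % len(pops)]
        pair_defs.append((f"pair{k + 1:02d}", local, foreign))

    # distances log-uniform over 0.7-600 km, sizes log-uniform 1e2-1e5
    distances = np.exp(rng.uniform(np.log(0.7), np.log(600.0), p.n_pairs))
    local_N = np.round(10 ** rng.uniform(2.0, 5.0, p.n_pairs)).astype(int)
    foreign_N = np.round(10 ** rng.uniform(2.0, 5.0, p.n_pairs)).astype(int)

    experiments = []
    truth_effects = {}
    n_cols = 27  # row/column grid of the randomized layout
    for k, (pair_id, local, foreign) in enumerate(pair_defs):
        effects = dict(p.adaptation_effects.get(pair_id, {}))
        truth_effects[pair_id] = effects
        surv_shift = float(effects.get("survival", 0.0))
        biomass_adv = float(effects.get("biomass", 0.0))
        inflo_adv = float(effects.get("inflorescences", 0.0))

        seed_weight = {
            "local": rng.normal(p.seed_weight_mean, p.seed_weight_sd, p.families_per_pair),
            "foreign": rng.normal(p.seed_weight_mean, p.seed_weight_sd, p.families_per_pair),
        }
        fam_log_bio = {
            "local": rng.normal(0.0, p.family_log_sd, p.families_per_pair),
            "foreign": rng.normal(0.0, p.family_log_sd, p.families_per_pair),
        }
        rows = []
        for block in range(1, p.blocks + 1):
            # randomized positions within the block
            n_pots_block = 2 * p.families_per_pair
            pos = rng.permutation(n_pots_block)
            slot = 0
            for fam in range(1, p.families_per_pair + 1):
                for origin in ("local", "foreign"):
                    # several seeds sown per pot, thinned to one seedling:
                    # the pot germinates if any seed does
                    surv_logit = _logit(p.survival_p) + (surv_shift if origin == "local" else 0.0)
                    n_germ = int(rng.binomial(p.seeds_per_pot, p.germination_p))
                    germinated = n_germ > 0
                    survived = bool(
                        germinated and rng.random() < _inv_logit(np.array([surv_logit]))[0]
                    )
                    log_bio = (
                        p.biomass_log_mean
                        + fam_log_bio[origin][fam - 1]
                        + (np.log1p(biomass_adv) if origin == "local" else 0.0)
                        + rng.normal(0.0, p.biomass_log_sd)
                    )
                    biomass = float(np.exp(log_bio)) if survived else np.nan
                    rate = p.inflorescence_rate * (
                        (1.0 + inflo_adv) if origin == "local" else 1.0
                    )
                    inflor = int(rng.poisson(rate)) if survived else 0
                    rows.append(
                        {
                            "family_pair": fam,
                            "block": block,
                            "row": int(pos[slot] // n_cols) + 1,
                            "column": int(pos[slot] % n_cols) + 1,
                            "origin": origin,
                            "seed_weight": float(seed_weight[origin][fam - 1]),
                            "germinated": germinated,
                            "survived": survived,
                            "biomass": biomass,
                            "inflorescences": inflor,
                        }
                    )
                    slot += 1
        experiments.append(
            PairExperiment(
                pair_id=pair_id,
                local_pop=local,
                foreign_pop=foreign,
                distance_km=float(distances[k]),
                local_N=int(local_N[k]),
                foreign_N=int(foreign_N[k]),
                pots=pd.DataFrame(rows),
            )
        )
    truth = {"adaptation_effects": truth_effects,
             "pair_definitions": pair_defs,
             "n_pots_total": sum(e.n_pots for e in experiments)}
    return experiments, truth
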