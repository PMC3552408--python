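"""Domain containers shared by every stage of the pipeline.

The analysis moves between four kinds of object: family-structured trait
tables (quantitative genetics), diploid multi-allelic genotype tables
(neutral markers), per-site environment records, and labelled symmetric
distance matrices — the universal currency connecting the stages.  A fifth
container, :class:`PairExperiment`, holds one local/foreign transplant
comparison (pot-level fitness records plus design metadata).

All containers validate their invariants at construction time and raise
:class:`ValidationError` on violation, so downstream code can assume
well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "TraitTable",
    "GenotypeTable",
    "SiteEnvironment",
    "DistanceMatrix",
    "VarianceDecomposition",
    "validate_heritabilities",
    "PairExperiment",
    "DifferentialRecord",
    "ClusterLikelihoodTrace",
]

#: allowed distance-matrix kinds; fst may be negative (estimator property)
DISTANCE_KINDS = ("geographic", "environmental", "soil", "qst", "fst", "custom")

#: predictor names a complete DifferentialRecord must carry
PREDICTOR_NAMES = (
    "log_local_N",
    "log_foreign_N",
    "log_dist_km",
    "env_dist",
    "qst",
    "fst",
)


class ValidationError(ValueError):
    """An input violates a structural invariant of a domain type."""


# ---------------------------------------------------------------------------
# quantitative-trait data
# ---------------------------------------------------------------------------


@dataclass
class TraitTable:
    """Individual-level trait observations with population and maternal-family labels.

    ``data`` holds one row per individual with columns ``individual_id``,
    ``population``, ``family`` and one numeric column per trait; missing
    trait values are NaN and are dropped per-trait (not per-individual) by
    downstream estimators.
    """

    data: pd.DataFrame

    RESERVED = ("individual_id", "population", "family")

    def __post_init__(self) -> None:
        for col in self.RESERVED:
            if col not in self.data.columns:
                raise ValidationError(f"trait table missing required column {col!r}")
        if not self.traits:
            raise ValidationError("trait table has no trait columns")
        if self.data["individual_id"].duplicated().any():
            dup = self.data.loc[self.data["individual_id"].duplicated(), "individual_id"].iloc[0]
            raise ValidationError(f"duplicate individual_id {dup!r}")
        trait_block = self.data[self.traits]
        all_missing = trait_block.isna().all(axis=1)
        if all_missing.any():
            ind = self.data.loc[all_missing, "individual_id"].iloc[0]
            raise ValidationError(f"individual {ind!r} has no non-missing trait value")

    @property
    def traits(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.RESERVED]

    @property
    def populations(self) -> list[str]:
        return list(pd.unique(self.data["population"]))

    def subset(self, populations: list[str]) -> "TraitTable":
        """Rows belonging to the given populations, in the given order."""
        mask = self.data["population"].isin(populations)
        return TraitTable(self.data.loc[mask].copy())


@dataclass
class VarianceDecomposition:
    """Nested random-effects variance components for one trait.

    ``v_between`` is the among-population component, ``v_family`` the
    among-family-within-population component and ``v_residual`` the
    within-family residual.  ``v_within`` is the within-population variance
    under the configured definition (by default ``v_family + v_residual``).
    Components are truncated at zero.
    """

    trait: str
    v_between: float
    v_family: float
    v_residual: float
    v_within: float
    n_pops: int
    n_fams: int
    n_obs: int

    def __post_init__(self) -> None:
        for name in ("v_between", "v_family", "v_residual", "v_within"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0 after truncation")


def validate_heritabilities(h2: dict[str, float]) -> dict[str, float]:
    """Check a trait -> h² map: every value must lie in [0, 1]."""
    for trait, value in h2.items():
        if not (0.0 <= value <= 1.0):
            raise ValidationError(f"heritability for {trait!r} is {value}, outside [0, 1]")
    return dict(h2)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypeTable:
    """Diploid multi-allelic genotypes, individuals x loci.

    ``alleles`` has shape ``(n_individuals, n_loci, 2)`` with positive
    integer allele codes; 0 marks a missing allele.  A cell must be fully
    typed (both alleles > 0) or fully missing (both 0) — diploid data only.
    """

    individuals: list[str]
    populations: np.ndarray  # shape (n,), dtype object/str
    loci: list[str]
    alleles: np.ndarray  # shape (n, L, 2), int

    def __post_init__(self) -> None:
        self.populations = np.asarray(self.populations, dtype=object)
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        n = len(self.individuals)
        if self.populations.shape != (n,):
            raise ValidationError("populations must align with individuals")
        if self.alleles.shape != (n, len(self.loci), 2):
            raise ValidationError(
                f"allele array shape {self.alleles.shape} does not match "
                f"({n}, {len(self.loci)}, 2)"
            )
        if (self.alleles < 0).any():
            raise ValidationError("allele codes must be non-negative integers")
        half_missing = (self.alleles == 0).sum(axis=2) == 1
        if half_missing.any():
            i, j = np.argwhere(half_missing)[0]
            raise ValidationError(
                f"non-diploid cell: individual {self.individuals[i]!r}, "
                f"locus {self.loci[j]!r} has exactly one missing allele"
            )

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def population_labels(self) -> list[str]:
        """Unique population labels in first-appearance order."""
        return list(pd.unique(self.populations))

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L): True where the genotype is missing."""
        return (self.alleles == 0).all(axis=2)

    def population_indices(self, population: str) -> np.ndarray:
        idx = np.flatnonzero(self.populations == population)
        if idx.size == 0:
            raise ValidationError(f"population {population!r} not present")
        return idx


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------


@dataclass
class SiteEnvironment:
    """Numeric environment variables plus WGS84 coordinates for one site."""

    site: str
    variables: dict[str, float]
    latitude: float
    longitude: float
    elevation: float = 0.0

    def __post_init__(self) -> None:
        if not (-90.0 <= self.latitude <= 90.0):
            raise ValidationError(f"site {self.site!r}: latitude {self.latitude} outside [-90, 90]")
        if not (-180.0 <= self.longitude <= 180.0):
            raise ValidationError(
                f"site {self.site!r}: longitude {self.longitude} outside [-180, 180]"
            )
        for name, value in self.variables.items():
            if value is None or not np.isfinite(value):
                raise ValidationError(f"site {self.site!r}: variable {name!r} is missing")


def environment_frame(sites: list[SiteEnvironment]) -> pd.DataFrame:
    """Sites x variables DataFrame (site labels as index).

    Raises if the variable set differs between sites — the downstream
    filtering and ordination assume a rectangular table.
    """
    if not sites:
        raise ValidationError("no sites supplied")
    names = [s.site for s in sites]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate site names")
    varset = set(sites[0].variables)
    for s in sites[1:]:
        if set(s.variables) != varset:
            raise ValidationError(f"site {s.site!r} has a different variable set")
    return pd.DataFrame([s.variables for s in sites], index=names)


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Labelled symmetric matrix with zero diagonal.

    The shared currency between stages: geographic (km), environmental
    (Euclidean factor-score units), Q_ST and F_ST matrices are all carried
    in this type.  F_ST entries may be slightly negative (an estimator
    property); geographic entries must be non-negative.
    """

    labels: list[str]
    values: np.ndarray
    kind: str = "custom"

    SYMMETRY_TOL = 1e-9

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValidationError("duplicate labels in distance matrix")
        if self.values.shape != (n, n):
            raise ValidationError(f"matrix shape {self.values.shape} does not match {n} labels")
        if self.kind not in DISTANCE_KINDS:
            raise ValidationError(f"unknown distance-matrix kind {self.kind!r}")
        asym = np.abs(self.values - self.values.T).max() if n else 0.0
        if asym > self.SYMMETRY_TOL:
            raise ValidationError(f"matrix asymmetric (max |A - A.T| = {asym:g})")
        # symmetrise exactly so the stored matrix meets the 1e-12 invariant
        self.values = 0.5 * (self.values + self.values.T)
        diag = np.abs(np.diag(self.values)).max() if n else 0.0
        if diag > 0:
            raise ValidationError(f"nonzero diagonal (max |diag| = {diag:g})")
        if self.kind == "geographic" and (self.values < 0).any():
            raise ValidationError("geographic distances must be non-negative")
        if not np.isfinite(self.values).all():
            raise ValidationError("non-finite distance values")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ValidationError(f"label {label!r} not in matrix") from None

    def pair(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle (off-diagonal) entries, row-major order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        """Same matrix with rows/columns permuted to the given label order."""
        if set(labels) != set(self.labels):
            missing = sorted(set(labels) ^ set(self.labels))
            raise ValidationError(f"label sets differ: {missing}")
        idx = np.array([self.index(l) for l in labels])
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], kind=self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


# ---------------------------------------------------------------------------
# transplant experiment
# ---------------------------------------------------------------------------

POT_COLUMNS = (
    "family_pair",
    "block",
    "row",
    "column",
    "origin",
    "seed_weight",
    "germinated",
    "survived",
    "biomass",
    "inflorescences",
)


@dataclass
class PairExperiment:
    """One local/foreign population pair of the transplant experiment.

    ``pots`` holds one row per pot with the design position (family pair,
    block, row, column), the seed origin (``local`` or ``foreign``), family
    seed weight (g) and the fitness outcomes: germination, survival,
    dry biomass (g) and inflorescence count.  The design is balanced: each
    (family_pair, block, origin) combination appears exactly once.
    """

    pair_id: str
    local_pop: str
    foreign_pop: str
    distance_km: float
    local_N: int
    foreign_N: int
    pots: pd.DataFrame

    def __post_init__(self) -> None:
        if self.distance_km <= 0:
            raise ValidationError(f"pair {self.pair_id!r}: distance_km must be > 0")
        if self.local_N <= 0 or self.foreign_N <= 0:
            raise ValidationError(f"pair {self.pair_id!r}: population sizes must be > 0")
        for col in POT_COLUMNS:
            if col not in self.pots.columns:
                raise ValidationError(f"pair {self.pair_id!r}: pots missing column {col!r}")
        bad_origin = ~self.pots["origin"].isin(["local", "foreign"])
        if bad_origin.any():
            raise ValidationError(f"pair {self.pair_id!r}: origin must be 'local' or 'foreign'")
        cells = self.pots.groupby(["family_pair", "block", "origin"]).size()
        if (cells != 1).any():
            key = cells[cells != 1].index[0]
            raise ValidationError(
                f"pair {self.pair_id!r}: (family_pair, block, origin) {key} appears "
                f"{int(cells[cells != 1].iloc[0])} times (must be exactly once)"
            )
        per_block = self.pots.groupby("block")["origin"].value_counts().unstack(fill_value=0)
        if (per_block.get("local", 0) != per_block.get("foreign", 0)).any():
            raise ValidationError(f"pair {self.pair_id!r}: origins not balanced within block")
        if (self.pots["inflorescences"].dropna() < 0).any():
            raise ValidationError(f"pair {self.pair_id!r}: negative inflorescence count")

    @property
    def n_pots(self) -> int:
        return len(self.pots)


@dataclass
class DifferentialRecord:
    """Per-pair local-minus-foreign fitness differential with its predictors.

    ``delta_pct`` is 100·(local − foreign)/foreign for the named trait;
    positive values indicate local adaptation, negative foreign-genotype
    advantage.  ``absolute`` flags the fallback to an absolute difference
    when the foreign mean is zero.  ``predictors`` must carry all six
    candidate predictors for the regression stage.
    """

    pair_id: str
    trait: str
    delta_pct: float
    predictors: dict[str, float] = field(default_factory=dict)
    absolute: bool = False

    def require_complete(self) -> None:
        missing = [p for p in PREDICTOR_NAMES if p not in self.predictors]
        if missing:
            raise ValidationError(f"pair {self.pair_id!r}: missing predictors {missing}")
        if not np.isfinite(self.delta_pct):
            raise ValidationError(f"pair {self.pair_id!r}: non-finite differential")


# ---------------------------------------------------------------------------
# clustering likelihood traces
# ---------------------------------------------------------------------------


@dataclass
class ClusterLikelihoodTrace:
    """Log-likelihoods of Bayesian clustering runs, per K and replicate."""

    entries: pd.DataFrame  # columns K, replicate, lnL

    def __post_init__(self) -> None:
        for col in ("K", "replicate", "lnL"):
            if col not in self.entries.columns:
                raise ValidationError(f"trace missing column {col!r}")
        if (self.entries["K"] < 1).any():
            raise ValidationError("K values must be >= 1")
        ks = np.sort(self.entries["K"].unique())
        if len(ks) < 3 or not np.array_equal(ks, np.arange(ks[0], ks[0] + len(ks))):
            raise ValidationError("need >= 3 consecutive K values")
        reps = self.entries.groupby("K").size()
        if (reps < 2).any():
            k = int(reps[reps < 2].index[0])
            raise ValidationError(f"K={k} has fewer than 2 replicates")

    @property
    def k_values(self) -> np.ndarray:
        return np.sort(self.entries["K"].unique())
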