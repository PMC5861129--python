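"""Seeded generators emulating the statistical structure of the study data.

The study's raw tables (promoter assignments, proteomics, GC-MS titers,
HPLC sugars) are not publicly deposited, so this module generates datasets
with the same structure: ~18 strains whose protein abundance is driven by
promoter strength with multiplicative log-normal replicate noise, titers
produced by the ground-truth kinetic model, sugar attenuation linked to
total enzyme burden, OD600 growth curves, and the replicate-vs-hop-
preparation variation experiment.  Every generator is a pure function of
its arguments and seed, which makes exact parameter-recovery tests
possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import (
    GENES,
    MonoterpeneMeasurement,
    PromoterCatalog,
    ProteinProfile,
    StrainDataset,
    StrainDesign,
    SugarProfile,
    TargetBeer,
    default_catalog,
)
from .pathway_model import KineticParameterSet, predict_titers

__all__ = [
    "NoiseModel",
    "GroundTruth",
    "DEFAULT_WORT",
    "BASAL_EXPRESSION",
    "default_ground_truth",
    "simulate_expression",
    "initial_designs",
    "generate_dataset",
    "generate_targets",
    "generate_hop_variation",
    "generate_od_curve",
]

#: Basal expression fraction: even the weakest promoter leaks some protein.
BASAL_EXPRESSION = 0.05

#: Unfermented wort (malt extract) sugar profile, g/L — a typical all-malt
#: wort dominated by maltose with maltotriose and glucose.
DEFAULT_WORT = SugarProfile(
    strain_id="wort", maltotriose=15.0, maltose=65.0, glucose=10.0, ethanol=0.0
)

#: Ethanol yield on consumed fermentable sugar, g/g (practical brewing yield).
ETHANOL_YIELD = 0.46


@dataclass(frozen=True)
class NoiseModel:
    """Replicate-noise magnitudes: multiplicative log-normal for proteins and
    titers (sigma of the log ~ CV for small CVs), additive Gaussian for OD."""

    protein_cv: float = 0.2
    titer_cv: float = 0.15
    od_sd: float = 0.01

    def __post_init__(self) -> None:
        for name in ("protein_cv", "titer_cv", "od_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(protein_cv=0.0, titer_cv=0.0, od_sd=0.0)


@dataclass(frozen=True)
class GroundTruth:
    """Ground-truth generative model: kinetic parameters, catalog, and the
    maximum relative abundance each gene reaches at promoter strength 1."""

    params: KineticParameterSet = field(default_factory=KineticParameterSet)
    catalog: PromoterCatalog = field(default_factory=default_catalog)
    expression_gain: dict[str, float] = field(
        default_factory=lambda: {g: 1.0 for g in GENES}
    )

    def __post_init__(self) -> None:
        if set(self.expression_gain) != set(GENES):
            raise ValueError(f"expression_gain must cover {GENES}")
        if any(v <= 0 for v in self.expression_gain.values()):
            raise ValueError("expression gains must be > 0")


def default_ground_truth() -> GroundTruth:
    """Nominal kinetic parameters + default catalog + unit gains."""
    return GroundTruth()


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_expression(
    design: StrainDesign,
    truth: GroundTruth,
    noise: NoiseModel,
    seed,
) -> ProteinProfile:
    """Promoter-determined protein abundance with log-normal replicate noise.

    abundance_g = gain_g · (basal + strength(promoter_g)) · LogNormal(0, cv),
    with basal = 0.05, so promoter strength and median abundance are strictly
    monotone related.
    """
    design.validate_against(truth.catalog)
    rng = _rng(seed)
    abundance = {}
    for g in GENES:
        strength = truth.catalog.strength(design.promoter_of[g])
        mult = rng.lognormal(mean=0.0, sigma=noise.protein_cv)
        abundance[g] = truth.expression_gain[g] * (BASAL_EXPRESSION + strength) * mult
    return ProteinProfile(strain_id=design.strain_id, abundance=abundance)


def initial_designs(
    catalog: PromoterCatalog, n: int = 18, seed=0, prefix: str = "S"
) -> list[StrainDesign]:
    """A first-iteration design set: promoters drawn uniformly so the set
    spans a wide range of expression strengths."""
    rng = _rng(seed)
    names = catalog.names
    designs = []
    for i in range(n):
        promoter_of = {g: names[rng.integers(len(names))] for g in GENES}
        designs.append(StrainDesign(strain_id=f"{prefix}{i + 1:03d}", promoter_of=promoter_of))
    return designs


def _burden_residual_fraction(
    profile: ProteinProfile, truth: GroundTruth, burden_slope: float
) -> float:
    """Residual-sugar fraction from total enzyme burden (linear link).

    Burden is total relative abundance normalized to its maximum under the
    truth's gains; residual fraction = slope · burden, so the default slope
    0.2 caps residual sugar at ~20% for the most heavily loaded strain.
    """
    max_total = sum(truth.expression_gain[g] * (BASAL_EXPRESSION + 1.0) for g in GENES)
    burden = sum(profile.abundance[g] for g in GENES) / max_total
    return float(np.clip(burden_slope * burden, 0.0, 1.0))


def generate_dataset(
    designs: list[StrainDesign],
    truth: GroundTruth,
    noise: NoiseModel,
    replicates: int = 3,
    seed=0,
    wort: SugarProfile = DEFAULT_WORT,
    burden_slope: float = 0.2,
) -> StrainDataset:
    """Full synthetic dataset: protein profiles, replicate titers, sugars.

    Titers are the ground-truth kinetic model's predictions for the
    (noisy) expression profile, times per-replicate log-normal measurement
    noise.  End-of-fermentation sugars follow the burden→attenuation link:
    residual fraction rises with total enzyme load, emulating the reduced
    fermentation capacity of heavily burdened strains; ethanol is produced
    from the consumed sugar at a fixed practical yield.
    """
    if not designs:
        raise ValueError("generate_dataset: empty design list")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = _rng(seed)
    profiles: list[ProteinProfile] = []
    titers: list[MonoterpeneMeasurement] = []
    sugars: list[SugarProfile] = []
    for design in designs:
        profile = simulate_expression(design, truth, noise, rng)
        profiles.append(profile)
        pred = predict_titers(truth.params, profile)
        for rep in range(1, replicates + 1):
            m_l = rng.lognormal(mean=0.0, sigma=noise.titer_cv)
            m_g = rng.lognormal(mean=0.0, sigma=noise.titer_cv)
            titers.append(
                MonoterpeneMeasurement(
                    strain_id=design.strain_id,
                    replicate=rep,
                    linalool=pred.linalool * m_l,
                    geraniol=pred.geraniol * m_g,
                )
            )
        f = _burden_residual_fraction(profile, truth, burden_slope)
        consumed = wort.total_fermentable * (1.0 - f)
        sugars.append(
            SugarProfile(
                strain_id=design.strain_id,
                maltotriose=wort.maltotriose * f,
                maltose=wort.maltose * f,
                glucose=wort.glucose * f,
                ethanol=ETHANOL_YIELD * consumed,
            )
        )
    return StrainDataset(
        profiles=profiles, titers=titers, designs=list(designs), sugars=sugars, wort=wort
    )


def generate_targets(
    mode: str = "default",
    custom: list[TargetBeer] | None = None,
) -> list[TargetBeer]:
    """Three reference-beer targets, ascending in both monoterpenes.

    Defaults bracket the ~0.2 mg/L level typical of finished beer: a pale
    ale (0.05/0.05), a mid-range IPA (0.2/0.2) and an intensely hopped IPA
    (0.8/0.6 mg/L linalool/geraniol).  ``mode="custom"`` echoes the supplied
    targets unchanged.
    """
    if mode == "custom":
        if not custom:
            raise ValueError("custom mode requires targets")
        return list(custom)
    if mode != "default":
        raise ValueError(f"unknown target mode {mode!r}")
    return [
        TargetBeer(name="Pale Ale", linalool=0.05, geraniol=0.05),
        TargetBeer(name="Mid IPA", linalool=0.2, geraniol=0.2),
        TargetBeer(name="Intense IPA", linalool=0.8, geraniol=0.6),
    ]


def generate_hop_variation(
    n_preparations: int = 5,
    n_replicates: int = 3,
    between_cv: float = 1.0,
    within_cv: float = 0.05,
    seed=0,
    base_linalool: float = 0.5,
    base_geraniol: float = 0.3,
) -> tuple[list[MonoterpeneMeasurement], list[MonoterpeneMeasurement]]:
    """Replicate fermentations of one engineered strain vs hop preparations.

    Set A: ``n_replicates`` fermentations of a single engineered strain,
    scattered only by the within-strain CV.  Set B: one fermentation per hop
    preparation (different farms), scattered by the larger between-
    preparation CV.  Both are log-normal around the same base titers.
    """
    if between_cv < 0 or within_cv < 0:
        raise ValueError("CVs must be >= 0")
    rng = _rng(seed)
    set_a = [
        MonoterpeneMeasurement(
            strain_id="engineered",
            replicate=i + 1,
            linalool=base_linalool * rng.lognormal(0.0, within_cv),
            geraniol=base_geraniol * rng.lognormal(0.0, within_cv),
        )
        for i in range(n_replicates)
    ]
    set_b = [
        MonoterpeneMeasurement(
            strain_id=f"hop_prep_{i + 1}",
            replicate=1,
            linalool=base_linalool * rng.lognormal(0.0, between_cv),
            geraniol=base_geraniol * rng.lognormal(0.0, between_cv),
        )
        for i in range(n_preparations)
    ]
    return set_a, set_b


def generate_od_curve(
    mu: float,
    lag: float,
    carrying_capacity: float,
    times,
    noise: float = 0.0,
    seed=0,
    od0: float = 0.02,
) -> np.ndarray:
    """Logistic-with-lag OD600 curve plus additive Gaussian noise.

    OD stays at ``od0`` until ``lag`` hours, then follows logistic growth at
    maximum specific rate ``mu`` toward ``carrying_capacity``.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    t = np.asarray(times, dtype=float)
    rng = _rng(seed)
    shifted = np.maximum(t - lag, 0.0)
    if mu == 0:
        od = np.full_like(t, od0)
    else:
        K = carrying_capacity
        od = K * od0 / (od0 + (K - od0) * np.exp(-mu * shifted))
    od = od + rng.normal(0.0, noise, size=t.shape) if noise > 0 else od.copy()
    return np.maximum(od, 1e-6)
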