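"""The "Learn" stage: distance-to-target scoring, correlation analyses,
design-space sampling under the two empirical design principles, the
guided-vs-random search-efficiency experiment, and the replicate-vs-hop-
preparation variance comparison.

The two design principles distilled from the first strain iteration are:
(1) strong promoters driving tHMGR, FPPS* and the geraniol synthase push
overall monoterpene production up, and (2) a range of promoter strengths
on the linalool synthase varies the linalool/geraniol ratio.  The policy
experiment quantifies how much sampling designs under these principles
improves search efficiency over uniform random designs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    GENES,
    MonoterpeneMeasurement,
    PromoterCatalog,
    StrainDataset,
    StrainDesign,
    TargetBeer,
)
from .metrics import DEFAULT_TITER_FLOOR
from .pathway_model import ABUNDANCE_FLOOR, predict_titers_batch
from .synthetic_data import (
    GroundTruth,
    NoiseModel,
    _burden_residual_fraction,
    simulate_expression,
)

__all__ = [
    "DistanceScore",
    "DesignPolicy",
    "PolicyComparison",
    "VarianceTest",
    "distance_to_target",
    "correlation_report",
    "enumerate_design_space",
    "sample_designs",
    "evaluate_policies",
    "variance_comparison",
    "variance_comparison_titers",
]

MAX_ENUMERATION = 10**6


@dataclass(frozen=True)
class DistanceScore:
    """Manhattan-mean distance of a strain from a target beer.

    The three components — |Δlog10 linalool|, |Δlog10 geraniol| and the
    residual-sugar fraction — are averaged, so a perfect strain (both
    monoterpenes on target, fully attenuated wort) scores 0 and each
    ten-fold titer error adds 1/3.
    """

    strain_id: str
    target_name: str
    components: tuple[float, float, float]
    value: float


@dataclass(frozen=True)
class DesignPolicy:
    """How promoters are drawn for new designs.

    ``random`` draws each gene's promoter uniformly from the catalog;
    ``principled`` applies the two design principles: tHMGR, FPPS* and GES
    promoters uniform over {strength >= strong_threshold}, the LIS promoter
    uniform over the whole catalog.
    """

    kind: str = "principled"
    strong_threshold: float = 0.67

    def __post_init__(self) -> None:
        if self.kind not in ("random", "principled"):
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if not (0.0 < self.strong_threshold < 1.0):
            raise ValueError("strong_threshold must be in (0, 1)")


def distance_to_target(
    meas: MonoterpeneMeasurement,
    target: TargetBeer,
    sugar_fraction: float | None,
    floor: float = DEFAULT_TITER_FLOOR,
) -> DistanceScore:
    """Manhattan-mean distance of one measurement from a target beer.

    value = (|log10 L_s − log10 L_t| + |log10 G_s − log10 G_t| + f_sugar)/3,
    with titers floored before the log.  The sugar component is mandatory.
    """
    if sugar_fraction is None:
        raise ValueError("sugar_fraction is a mandatory distance component")
    if not (0.0 <= sugar_fraction <= 1.0):
        raise ValueError("sugar_fraction must be in [0, 1]")
    d_lin = abs(math.log10(max(meas.linalool, floor)) - math.log10(target.linalool))
    d_ger = abs(math.log10(max(meas.geraniol, floor)) - math.log10(target.geraniol))
    comps = (d_lin, d_ger, float(sugar_fraction))
    return DistanceScore(
        strain_id=meas.strain_id,
        target_name=target.name,
        components=comps,
        value=sum(comps) / 3.0,
    )


def correlation_report(
    dataset: StrainDataset,
    method: str = "pearson",
    titer_floor: float = DEFAULT_TITER_FLOOR,
    abundance_floor: float = ABUNDANCE_FLOOR,
) -> pd.DataFrame:
    """Correlations between protein abundances and production outcomes.

    Reports, on log10-transformed quantities, the pairs (tHMGR, total
    monoterpenes), (FPPS*, total), (LIS, linalool), (GES, geraniol) and
    (GES/LIS ratio, geraniol fraction); p-values come from the t statistic
    t = r·√((n−2)/(1−r²)).  A zero-variance member makes that pair's
    correlation undefined (NaN) rather than silently dropping it.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    ids, rows = dataset.abundance_matrix()
    if len(ids) < 4:
        raise ValueError("correlation_report needs at least 4 strains")
    A = np.array(rows)
    means = dataset.mean_titers()
    obs = np.array([means[s] for s in ids])
    lin, ger = obs[:, 0], obs[:, 1]
    total = lin + ger
    gfrac = (ger + titer_floor) / (total + 2 * titer_floor)

    gi = {g: i for i, g in enumerate(GENES)}
    log = lambda v: np.log10(np.asarray(v, dtype=float))
    pairs = {
        "tHMGR_vs_total": (log(A[:, gi["tHMGR"]] + abundance_floor), log(total + titer_floor)),
        "FPPS_star_vs_total": (
            log(A[:, gi["FPPS_star"]] + abundance_floor),
            log(total + titer_floor),
        ),
        "LIS_vs_linalool": (log(A[:, gi["LIS"]] + abundance_floor), log(lin + titer_floor)),
        "GES_vs_geraniol": (log(A[:, gi["GES"]] + abundance_floor), log(ger + titer_floor)),
        "GES_LIS_ratio_vs_geraniol_fraction": (
            log((A[:, gi["GES"]] + abundance_floor) / (A[:, gi["LIS"]] + abundance_floor)),
            log(gfrac),
        ),
    }
    records = []
    for name, (x, y) in pairs.items():
        # ptp, not std: std of a constant array can round to ~1e-20, not 0
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            r, p = float("nan"), float("nan")
        elif method == "pearson":
            r, p = stats.pearsonr(x, y)
        else:
            r, p = stats.spearmanr(x, y)
        records.append({"pair": name, "correlation": float(r), "p_value": float(p), "n": len(x)})
    return pd.DataFrame.from_records(records)


def enumerate_design_space(catalog: PromoterCatalog) -> list[StrainDesign]:
    """All promoter combinations over the four genes, lexicographic by rank."""
    n = len(catalog) ** len(GENES)
    if n > MAX_ENUMERATION:
        raise ValueError(
            f"design space has {n} combinations (> {MAX_ENUMERATION}); sample instead"
        )
    names = catalog.names
    designs = []
    for i, combo in enumerate(itertools.product(names, repeat=len(GENES))):
        designs.append(
            StrainDesign(strain_id=f"D{i:06d}", promoter_of=dict(zip(GENES, combo)))
        )
    return designs


def sample_designs(
    catalog: PromoterCatalog,
    policy: DesignPolicy,
    n: int,
    seed,
    prefix: str | None = None,
) -> list[StrainDesign]:
    """Draw ``n`` designs under a policy, reproducibly given the seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = catalog.names
    strong = [m for m in names if catalog.strength(m) >= policy.strong_threshold]
    if policy.kind == "principled" and not strong:
        raise ValueError(
            f"no promoter reaches strength >= {policy.strong_threshold}; "
            "principled policy is infeasible"
        )
    prefix = prefix or ("P" if policy.kind == "principled" else "R")
    designs = []
    for i in range(n):
        if policy.kind == "random":
            promoter_of = {g: names[rng.integers(len(names))] for g in GENES}
        else:
            promoter_of = {
                g: strong[rng.integers(len(strong))]
                for g in ("tHMGR", "FPPS_star", "GES")
            }
            promoter_of["LIS"] = names[rng.integers(len(names))]
        designs.append(StrainDesign(strain_id=f"{prefix}{i + 1:03d}", promoter_of=promoter_of))
    return designs


@dataclass
class PolicyComparison:
    """Distance distributions per policy/target plus directional p-values."""

    summary: pd.DataFrame  # columns: policy, target, mean, sd, n
    p_values: dict[str, float]  # target -> one-sided Welch p (principled < random)
    distances: pd.DataFrame  # per-design rows: policy, target, strain_id, distance


def evaluate_policies(
    truth: GroundTruth,
    catalog: PromoterCatalog,
    targets: list[TargetBeer],
    policies: tuple[DesignPolicy, DesignPolicy] = (
        DesignPolicy(kind="principled"),
        DesignPolicy(kind="random"),
    ),
    n_per_policy: int = 18,
    noise: NoiseModel | None = None,
    seed=0,
    include_sugar: bool = True,
    burden_slope: float = 0.2,
) -> PolicyComparison:
    """Guided-vs-random search-efficiency experiment in simulation.

    For each policy, ``n_per_policy`` designs are sampled, expression is
    simulated (with noise), titers are predicted from the ground-truth
    kinetic model, and the Manhattan-mean distance to every target is
    computed (sugar component via the burden→attenuation link, or 0 when
    disabled).  For each target a one-sided Welch t-test asks whether the
    principled policy lands closer to target than the random one.
    """
    if n_per_policy < 3:
        raise ValueError("n_per_policy must be >= 3")
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    labels = [p.kind for p in policies]
    if len(set(labels)) < len(labels):  # disambiguate identical policies
        labels = [f"{kind}_{i + 1}" for i, kind in enumerate(labels)]
    rows = []
    for label, policy in zip(labels, policies):
        designs = sample_designs(catalog, policy, n_per_policy, rng)
        for d in designs:
            profile = simulate_expression(d, truth, noise, rng)
            A = np.array([[profile.abundance[g] for g in GENES]])
            lin, ger = predict_titers_batch(truth.params, A)
            meas = MonoterpeneMeasurement(
                strain_id=d.strain_id, replicate=1, linalool=float(lin[0]), geraniol=float(ger[0])
            )
            f = (
                _burden_residual_fraction(profile, truth, burden_slope)
                if include_sugar
                else 0.0
            )
            for target in targets:
                score = distance_to_target(meas, target, f)
                rows.append(
                    {
                        "policy": label,
                        "target": target.name,
                        "strain_id": d.strain_id,
                        "distance": score.value,
                    }
                )
    distances = pd.DataFrame.from_records(rows)
    summary = distances.groupby(["policy", "target"], as_index=False)["distance"].agg(
        mean="mean", sd="std", n="count"
    )
    p_values = {}
    for target in targets:
        sub = distances[distances["target"] == target.name]
        a = sub[sub["policy"] == labels[0]]["distance"].to_numpy()
        b = sub[sub["policy"] == labels[1]]["distance"].to_numpy()
        t = stats.ttest_ind(a, b, equal_var=False, alternative="less")
        p_values[target.name] = float(t.pvalue)
    return PolicyComparison(summary=summary, p_values=p_values, distances=distances)


@dataclass(frozen=True)
class VarianceTest:
    """Primary deviations t-test plus a secondary F-ratio test."""

    t_statistic: float
    p_value: float
    f_statistic: float
    f_p_value: float
    sd_a: float
    sd_b: float


def variance_comparison(set_a, set_b) -> VarianceTest:
    """Test whether set B varies more than set A (one-sided).

    Primary: a one-sided Welch t-test on absolute deviations from each
    set's own mean (mean deviation greater in B).  Secondary: the F-ratio
    var(B)/var(A) with its one-sided p-value.  Degenerate inputs (both sets
    deviation-free) yield p = 1: no evidence of extra variation.
    """
    a = np.asarray(set_a, dtype=float)
    b = np.asarray(set_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("variance_comparison needs >= 3 values per set")
    dev_a = np.abs(a - a.mean())
    dev_b = np.abs(b - b.mean())
    if dev_a.std(ddof=1) == 0 and dev_b.std(ddof=1) == 0:
        t_stat = 0.0
        p = 0.0 if dev_b.mean() > dev_a.mean() else 1.0
    else:
        res = stats.ttest_ind(dev_b, dev_a, equal_var=False, alternative="greater")
        t_stat, p = float(res.statistic), float(res.pvalue)
    var_a, var_b = a.var(ddof=1), b.var(ddof=1)
    if var_a == 0:
        f_stat, f_p = float("inf") if var_b > 0 else float("nan"), 0.0 if var_b > 0 else 1.0
    else:
        f_stat = float(var_b / var_a)
        f_p = float(stats.f.sf(f_stat, b.size - 1, a.size - 1))
    return VarianceTest(
        t_statistic=t_stat,
        p_value=p,
        f_statistic=f_stat,
        f_p_value=f_p,
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
    )


def variance_comparison_titers(
    set_a: list[MonoterpeneMeasurement], set_b: list[MonoterpeneMeasurement]
) -> dict[str, VarianceTest]:
    """Per-species variance comparison for two titer record sets."""
    return {
        "linalool": variance_comparison(
            [m.linalool for m in set_a], [m.linalool for m in set_b]
        ),
        "geraniol": variance_comparison(
            [m.geraniol for m in set_a], [m.geraniol for m in set_b]
        ),
    }
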