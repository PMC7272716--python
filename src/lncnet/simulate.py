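"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure of the study design the
pipeline targets:

* a two-group (resistant vs sensitive) log2-intensity matrix at n = 3
  replicates per group, with planted fold changes and planted hub-lncRNA
  modules whose partner mRNAs track the hub profile at a controlled Pearson
  correlation;
* a follow-up cohort with group-dependent exponential hazards, independent
  censoring, binary clinical covariates, and injected records that the
  cohort-cleaning filters must remove (expression exactly 0, follow-up under
  30 days);
* gene-set collections with planted enriched terms;
* scored lncRNA-miRNA and miRNA-mRNA interaction tables with a configurable
  planted subset passing the ceRNA thresholds.

Everything is driven by a single integer seed per generator; a fixed seed
and config yield byte-identical output.

Hub modules are built analytically: a partner is an affine transform of the
hub profile plus Gaussian noise whose variance is chosen from the population
signal variance so that the population correlation equals the configured
target exactly (``sigma_e^2 = slope^2 sigma_h^2 (1/r^2 - 1)``).  With target
r = 1 the partner is an exact affine copy and the sample correlation is 1.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet, GeneSetCollection

__all__ = [
    "PlantedHub",
    "SimulationConfig",
    "GroundTruth",
    "generate_expression",
    "SurvivalSimConfig",
    "generate_survival",
    "generate_gene_sets",
    "generate_interactions",
]


def _signed_log2(fc: float) -> float:
    """Signed linear FC -> log2 effect (|fc| >= 1 by the signed convention)."""
    if abs(fc) < 1.0:
        raise ValueError(f"signed linear fold change must satisfy |fc| >= 1, got {fc}")
    return float(np.sign(fc) * np.log2(abs(fc)))


@dataclasses.dataclass(frozen=True)
class PlantedHub:
    """One hub-lncRNA module: the hub plus *size* correlated partner mRNAs."""

    size: int
    target_r: float = 0.999
    hub_fc: float = 8.0  # signed linear FC of the hub itself
    partner_fc: float = 8.0  # signed linear FC of each partner

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("hub module size must be >= 1")
        if not (0.0 < self.target_r <= 1.0):
            raise ValueError("target correlation must lie in (0, 1]")


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Two-group expression simulation parameters (defaults: 3-vs-3 design)."""

    n_genes: int = 200
    frac_lncrna: float = 0.3
    n_per_group: int = 3
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    planted_de: tuple[tuple[int, float], ...] = ()  # (count, signed linear FC)
    planted_hubs: tuple[PlantedHub, ...] = ()
    noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not (0.0 <= self.frac_lncrna <= 1.0):
            raise ValueError("frac_lncrna must lie in [0, 1]")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        for count, fc in self.planted_de:
            if count < 0:
                raise ValueError("planted DE set size must be >= 0")
            _signed_log2(fc)


@dataclasses.dataclass
class GroundTruth:
    """What was planted: true fold changes and hub module membership."""

    true_fc: dict[str, float]  # gene -> signed linear FC (planted genes only)
    hubs: list[str]
    hub_edges: list[tuple[str, str]]  # (hub lncRNA, partner mRNA)
    hub_target_r: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        """Sidecar table for test harnesses (one row per planted fact)."""
        rows = [
            {"kind": "de", "gene": g, "partner": "", "value": fc}
            for g, fc in sorted(self.true_fc.items())
        ]
        rows += [
            {"kind": "hub_edge", "gene": h, "partner": m,
             "value": self.hub_target_r[h]}
            for h, m in self.hub_edges
        ]
        return pd.DataFrame(rows, columns=["kind", "gene", "partner", "value"])


def generate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate a two-group log2 expression matrix with planted structure.

    Samples are ``case_1..case_n`` then ``control_1..control_n``; gene ids
    are ``LNC####`` / ``MRNA####``.  Planted DE genes are drawn at random
    from the non-hub pool (both biotypes); each planted hub consumes one
    lncRNA and *size* mRNAs and raises a sizing error when the mRNA pool is
    exhausted.
    """
    rng = np.random.default_rng(config.seed)
    n_lnc = int(round(config.n_genes * config.frac_lncrna))
    n_mrna = config.n_genes - n_lnc
    lnc_ids = [f"LNC{i:04d}" for i in range(n_lnc)]
    mrna_ids = [f"MRNA{i:04d}" for i in range(n_mrna)]
    genes = lnc_ids + mrna_ids
    n = config.n_per_group
    samples = [f"case_{i+1}" for i in range(n)] + [f"control_{i+1}" for i in range(n)]
    case_mask = np.array([1] * n + [0] * n, dtype=float)

    need_mrna = sum(h.size for h in config.planted_hubs)
    if need_mrna > n_mrna:
        raise ValueError(
            f"hub modules need {need_mrna} mRNAs but only {n_mrna} are available"
        )
    if len(config.planted_hubs) > n_lnc:
        raise ValueError("more planted hubs than available lncRNAs")

    baseline = config.baseline_mean + rng.normal(0.0, config.baseline_sd, len(genes))
    values = baseline[:, None] + rng.normal(
        0.0, config.noise_sd, (len(genes), 2 * n)
    )
    values = pd.DataFrame(values, index=genes, columns=samples)

    # reserve hub genes first, then scatter planted DE over the remainder
    free_lnc = list(lnc_ids)
    free_mrna = list(mrna_ids)
    truth = GroundTruth(true_fc={}, hubs=[], hub_edges=[], hub_target_r={})

    for hub_cfg in config.planted_hubs:
        hub = free_lnc.pop(0)
        partners = [free_mrna.pop(0) for _ in range(hub_cfg.size)]
        delta_h = _signed_log2(hub_cfg.hub_fc)
        hub_profile = (
            config.baseline_mean
            + delta_h * case_mask
            + rng.normal(0.0, config.noise_sd, 2 * n)
        )
        values.loc[hub] = hub_profile
        truth.hubs.append(hub)
        truth.true_fc[hub] = hub_cfg.hub_fc
        truth.hub_target_r[hub] = hub_cfg.target_r

        # population variance of the hub profile: balanced group shift + noise
        var_h = (delta_h / 2.0) ** 2 + config.noise_sd**2
        delta_p = _signed_log2(hub_cfg.partner_fc)
        slope = delta_p / delta_h if delta_h != 0 else 1.0
        sigma_e2 = slope**2 * var_h * (1.0 / hub_cfg.target_r**2 - 1.0)
        centered = hub_profile - (config.baseline_mean + delta_h * case_mask.mean())
        for m in partners:
            noise = (
                rng.normal(0.0, np.sqrt(sigma_e2), 2 * n) if sigma_e2 > 0 else 0.0
            )
            values.loc[m] = config.baseline_mean + slope * centered + noise
            truth.hub_edges.append((hub, m))
            truth.true_fc[m] = hub_cfg.partner_fc

    free = free_lnc + free_mrna
    total_de = sum(count for count, _ in config.planted_de)
    if total_de > len(free):
        raise ValueError("planted DE sets exceed the available gene pool")
    chosen = rng.choice(len(free), size=total_de, replace=False)
    cursor = 0
    for count, fc in config.planted_de:
        delta = _signed_log2(fc)
        for idx in chosen[cursor : cursor + count]:
            g = free[idx]
            values.loc[g] = values.loc[g] + delta * case_mask
            truth.true_fc[g] = fc
        cursor += count

    design = pd.Series(
        ["case"] * n + ["control"] * n, index=samples, name="group"
    )
    biotype = pd.Series(
        ["lncRNA"] * n_lnc + ["mRNA"] * n_mrna, index=genes, name="biotype"
    )
    matrix = ExpressionMatrix(values=values, design=design, biotype=biotype)
    return matrix, truth


# ---------------------------------------------------------------------------
# survival cohorts
# ---------------------------------------------------------------------------

COVARIATES = ("er", "pr", "her2", "chemoresistance")


@dataclasses.dataclass(frozen=True)
class SurvivalSimConfig:
    """Follow-up cohort simulation parameters.

    ``true_hr`` multiplies the baseline hazard in the high-expression half of
    the cohort.  ``subgroup_hr`` optionally overrides the hazard ratio inside
    one covariate-positive stratum (e.g. ``{"er": 3.0}`` plants an effect in
    ER-positive patients only; the complement keeps ``true_hr``).  Censoring
    is independent exponential, calibrated so each record is censored with
    probability ``censor_rate`` exactly.  ``frac_zero_expression`` and
    ``frac_short_followup`` overwrite disjoint record subsets post hoc so the
    cleaning filters have exact known counts to remove.
    """

    n_patients: int = 200
    true_hr: float = 2.0
    baseline_hazard: float = 1.0 / 1000.0  # events per day
    censor_rate: float = 0.2
    frac_zero_expression: float = 0.0
    frac_short_followup: float = 0.0
    covariate_probs: tuple[tuple[str, float], ...] = (
        ("er", 0.6),
        ("pr", 0.5),
        ("her2", 0.3),
        ("chemoresistance", 0.4),
    )
    subgroup_hr: tuple[tuple[str, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if self.true_hr <= 0:
            raise ValueError("true_hr must be > 0")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        for name, frac in (
            ("censor_rate", self.censor_rate),
            ("frac_zero_expression", self.frac_zero_expression),
            ("frac_short_followup", self.frac_short_followup),
        ):
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        for _, hr in self.subgroup_hr:
            if hr <= 0:
                raise ValueError("subgroup hazard ratios must be > 0")


def generate_survival(config: SurvivalSimConfig) -> pd.DataFrame:
    """Simulate a clinical cohort: time, event, expression, binary covariates.

    Event times are exponential with hazard ``baseline_hazard`` in the
    low-expression half and ``hr * baseline_hazard`` in the high half, where
    the halves are defined by the median of the simulated expression values
    (so a later median split recovers the generating groups).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    expression = rng.lognormal(mean=0.0, sigma=0.5, size=n)
    high = expression > np.median(expression)

    covs = {
        name: rng.binomial(1, p, size=n) for name, p in config.covariate_probs
    }
    hr = np.full(n, config.true_hr)
    for cov_name, sub_hr in config.subgroup_hr:
        if cov_name not in covs:
            raise ValueError(f"unknown covariate {cov_name!r} in subgroup_hr")
        hr[covs[cov_name] == 1] = sub_hr
    hazard = config.baseline_hazard * np.where(high, hr, 1.0)

    event_time = rng.exponential(1.0 / hazard)
    if config.censor_rate > 0:
        # P(C < T) = lc/(lc+lt) for independent exponentials; scaling the
        # censoring rate to each record's hazard fixes it at censor_rate
        c_rate = hazard * config.censor_rate / (1.0 - config.censor_rate)
        censor_time = rng.exponential(1.0 / c_rate)
    else:
        censor_time = np.full(n, np.inf)
    event = (event_time <= censor_time).astype(int)
    time = np.minimum(event_time, censor_time)

    cohort = pd.DataFrame(
        {
            "sample": [f"patient_{i+1:04d}" for i in range(n)],
            "time": time,
            "event": event,
            "expression": expression,
            **covs,
        }
    )

    n_zero = int(round(config.frac_zero_expression * n))
    n_short = int(round(config.frac_short_followup * n))
    if n_zero + n_short > n:
        raise ValueError("injected record fractions exceed the cohort size")
    idx = rng.choice(n, size=n_zero + n_short, replace=False)
    cohort.loc[cohort.index[idx[:n_zero]], "expression"] = 0.0
    cohort.loc[cohort.index[idx[n_zero:]], "time"] = rng.uniform(
        1.0, 29.0, size=n_short
    )
    return cohort


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------


def generate_gene_sets(
    universe: Sequence[str],
    n_terms: int,
    term_size_range: tuple[int, int] = (5, 30),
    planted_term_genes: Sequence[str] | None = None,
    category: str = "BP",
    seed: int = 0,
    prefix: str = "TERM",
) -> GeneSetCollection:
    """Random gene-set collection over *universe*, with an optional planted term.

    Random terms draw their members uniformly; when *planted_term_genes* is
    given an extra term consisting of exactly those genes is appended (id
    ``{prefix}_PLANTED``), so enrichment of that list is detectable by
    construction.  Planted genes must belong to the universe.
    """
    universe = list(universe)
    lo, hi = term_size_range
    if not (1 <= lo <= hi):
        raise ValueError("invalid term size range")
    if hi > len(universe):
        raise ValueError("term sizes exceed the universe size")
    rng = np.random.default_rng(seed)
    sets = []
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(universe), size=size, replace=False)
        sets.append(
            GeneSet(
                term_id=f"{prefix}_{i:04d}",
                name=f"random term {i}",
                category=category,
                genes=frozenset(universe[j] for j in members),
            )
        )
    if planted_term_genes is not None:
        missing = set(planted_term_genes) - set(universe)
        if missing:
            raise ValueError(
                f"planted gene {sorted(missing)[0]!r} not in universe"
            )
        sets.append(
            GeneSet(
                term_id=f"{prefix}_PLANTED",
                name="planted term",
                category=category,
                genes=frozenset(planted_term_genes),
            )
        )
    return GeneSetCollection(sets)


# ---------------------------------------------------------------------------
# interaction tables
# ---------------------------------------------------------------------------

# score ranges for rows planted to pass / fail the ceRNA thresholds
_PASS = {"correlation": (0.91, 0.99), "binding": (0.05, 0.15), "context": (-0.8, -0.25)}
_FAIL = {"correlation": (0.2, 0.88), "binding": (0.0, 0.035), "context": (-0.18, -0.01)}


def generate_interactions(
    lnc_ids: Sequence[str],
    mirna_ids: Sequence[str],
    mrna_ids: Sequence[str],
    planted_lnc_mirna: Sequence[tuple[str, str]] | None = None,
    planted_mirna_mrna: Sequence[tuple[str, str]] | None = None,
    pass_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scored interaction tables over the full id cross-products.

    Planted pairs receive scores drawn from the passing ranges; every other
    pair passes independently with probability *pass_fraction* and otherwise
    receives failing scores.  The three id namespaces must be disjoint.
    Returns ``(lnc_mirna, mirna_mrna)`` tables with the ceRNA column layout.
    """
    ids = list(lnc_ids) + list(mirna_ids) + list(mrna_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("lncRNA / miRNA / mRNA id namespaces must be disjoint")
    rng = np.random.default_rng(seed)
    planted1 = set(planted_lnc_mirna or ())
    planted2 = set(planted_mirna_mrna or ())

    def draw(kind: str, passing: bool) -> float:
        lo, hi = (_PASS if passing else _FAIL)[kind]
        return float(rng.uniform(lo, hi))

    rows1 = []
    for lnc in lnc_ids:
        for mir in mirna_ids:
            passing = (lnc, mir) in planted1 or rng.random() < pass_fraction
            rows1.append(
                {
                    "lncrna": lnc,
                    "mirna": mir,
                    "correlation_score": draw("correlation", passing),
                    "binding_score": draw("binding", passing),
                }
            )
    rows2 = []
    for mir in mirna_ids:
        for mrna in mrna_ids:
            passing = (mir, mrna) in planted2 or rng.random() < pass_fraction
            rows2.append(
                {
                    "mirna": mir,
                    "mrna": mrna,
                    "context_score": draw("context", passing),
                }
            )
    cols1 = ["lncrna", "mirna", "correlation_score", "binding_score"]
    cols2 = ["mirna", "mrna", "context_score"]
    return (
        pd.DataFrame(rows1, columns=cols1),
        pd.DataFrame(rows2, columns=cols2),
    )
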