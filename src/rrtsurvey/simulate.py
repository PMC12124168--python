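"""Synthetic household surveys with unrelated-question masking.

Generates a stratified household sample and, for every household x item
domain x season, a masked response: the randomizer routes the respondent to
the sensitive item with probability ``p_s``, otherwise to an unrelated one,
so the observed yes-rate in a cell is the mixture

    P(y = 1) = p_s * pi_s + (1 - p_s) * pi_ns.

Two tables are produced: a truth table retaining the latent question
assignment ``z`` and latent use, and an analysis table that drops both.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.special import expit

from ._seeds import derive_seed
from .design import (
    DEPENDENCY_SD,
    VISITS_RURAL_SD,
    VISITS_URBAN_SD,
    DesignError,
    RandomizerDesign,
    StudyDesign,
    TrueParams,
    split_item_domain,
    validate_design,
)

__all__ = [
    "HouseholdRecord",
    "MaskedResponse",
    "draw_randomizer",
    "simulate_households",
    "simulate_responses",
    "households_to_frame",
    "ANALYSIS_COLUMNS",
    "TRUTH_ONLY_COLUMNS",
]

SENSITIVE = "sensitive"
NONSENSITIVE = "nonsensitive"

ANALYSIS_COLUMNS = [
    "household_id",
    "municipality",
    "urbanization",
    "residence_status",
    "management",
    "n_minors",
    "n_working_adults",
    "visits_urban",
    "visits_rural",
    "season",
    "item_domain",
    "use",
    "quantity_category",
]
TRUTH_ONLY_COLUMNS = ["z", "latent_use"]

HOUSEHOLD_COLUMNS = [
    "household_id",
    "municipality",
    "urbanization",
    "residence_status",
    "management",
    "n_minors",
    "n_working_adults",
    "visits_urban",
    "visits_rural",
]


@dataclass(frozen=True)
class HouseholdRecord:
    """One surveyed household.

    Exactly one of ``visits_urban`` / ``visits_rural`` applies: urban
    households report visits to rural areas, rural and peri-urban households
    report visits to the urban center; the inapplicable one is ``None``,
    never silently zero.  Visit counts are for the season the access models
    use (the wet season).
    """

    household_id: str
    municipality: str
    urbanization: str
    residence_status: Literal["single_sited", "multisited"]
    management: Literal["single_adult", "dual_adult"]
    n_minors: int
    n_working_adults: int
    visits_urban: int | None
    visits_rural: int | None

    def __post_init__(self) -> None:
        if (self.visits_urban is None) == (self.visits_rural is None):
            raise DesignError(
                f"household {self.household_id}: exactly one of visits_urban / "
                "visits_rural must be applicable"
            )
        for name in ("n_minors", "n_working_adults", "visits_urban", "visits_rural"):
            v = getattr(self, name)
            if v is not None and (int(v) != v or v < 0):
                raise DesignError(
                    f"household {self.household_id}: {name} must be a "
                    f"non-negative integer, got {v!r}"
                )


@dataclass(frozen=True)
class MaskedResponse:
    """What the interviewer records for one household x item domain x season.

    ``z`` and ``latent_use`` exist only on truth rows; analysis-facing
    serialization drops them.
    """

    household_id: str
    item_domain: str
    season: str
    use: int
    quantity_category: int
    z: str | None = None
    latent_use: int | None = None

    def __post_init__(self) -> None:
        if (self.quantity_category == 0) != (self.use == 0):
            raise DesignError(
                f"response ({self.household_id}, {self.item_domain}, {self.season}): "
                "quantity_category must be 0 exactly when use is 0"
            )


def draw_randomizer(
    design: RandomizerDesign, rng: np.random.Generator
) -> Literal["sensitive", "nonsensitive"]:
    """One draw from the masking device: ``sensitive`` with probability
    exactly ``n_sensitive / n_total``."""
    # Draw an integer token so p_s is hit exactly, not via float rounding.
    token = rng.integers(design.n_total)
    return SENSITIVE if token < design.n_sensitive else NONSENSITIVE


def _draw_negbin(rng: np.random.Generator, mu: float, theta: float, size: int) -> np.ndarray:
    """NB2 draws with mean mu and variance mu + mu^2 / theta."""
    p = theta / (theta + mu)
    return rng.negative_binomial(theta, p, size=size)


def simulate_households(
    design: StudyDesign, params: TrueParams, seed: int
) -> list[HouseholdRecord]:
    """Generate one record per designed household.

    Covariates are drawn from stratum-specific distributions parameterized
    by ``params.glm_betas``; per-stratum counts match the design exactly.
    """
    if seed is None:
        raise ValueError("seed is required: all simulation is explicitly seeded")
    validate_design(design)
    g = params.glm_betas
    records: list[HouseholdRecord] = []
    counter = 0
    for stratum in design.strata:
        mun, urb = stratum.key
        n = stratum.n_households
        rng = np.random.default_rng(derive_seed(seed, "households", mun, urb))

        multisited = rng.random(n) < float(g["p_multisited"])
        mgmt = g["management"]
        eta = (
            mgmt["intercept"]
            + mgmt["manaus"] * (mun == "manaus")
            + mgmt["rural"] * (urb == "rural")
            + mgmt["peri_urban"] * (urb == "peri_urban")
        )
        dual = rng.random(n) < expit(eta)
        n_minors = rng.poisson(float(g["lambda_minors"]), size=n)
        n_working = 1 + rng.poisson(float(g["lambda_working"]), size=n)

        if urb == "urban":
            vr = g["visits_rural"]
            log_mu = (
                vr["intercept"]
                + vr["manaus"] * (mun == "manaus")
                + vr["multisited"] * multisited.astype(float)
            )
            visits = np.array(
                [_draw_negbin(rng, float(np.exp(m)), float(vr["theta"]), 1)[0] for m in log_mu]
            )
            visits_urban = [None] * n
            visits_rural = [int(v) for v in visits]
        else:
            vu = g["visits_urban"]
            log_mu = (
                vu["intercept"]
                + vu["manaus"] * (mun == "manaus")
                + vu["peri_urban"] * (urb == "peri_urban")
            )
            visits = _draw_negbin(rng, float(np.exp(log_mu)), float(vu["theta"]), n)
            visits_urban = [int(v) for v in visits]
            visits_rural = [None] * n

        for i in range(n):
            counter += 1
            records.append(
                HouseholdRecord(
                    household_id=f"HH{counter:05d}",
                    municipality=mun,
                    urbanization=urb,
                    residence_status="multisited" if multisited[i] else "single_sited",
                    management="dual_adult" if dual[i] else "single_adult",
                    n_minors=int(n_minors[i]),
                    n_working_adults=int(n_working[i]),
                    visits_urban=visits_urban[i],
                    visits_rural=visits_rural[i],
                )
            )
    return records


def households_to_frame(records: Iterable[HouseholdRecord]) -> pd.DataFrame:
    rows = [
        {
            "household_id": r.household_id,
            "municipality": r.municipality,
            "urbanization": r.urbanization,
            "residence_status": r.residence_status,
            "management": r.management,
            "n_minors": r.n_minors,
            "n_working_adults": r.n_working_adults,
            "visits_urban": r.visits_urban,
            "visits_rural": r.visits_rural,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=HOUSEHOLD_COLUMNS)
    for col in ("visits_urban", "visits_rural"):
        df[col] = df[col].astype("Int64")
    return df


def _quantity_linear_predictor(
    record: HouseholdRecord, season: str, betas: dict[str, float]
) -> float:
    visits = record.visits_urban if record.visits_urban is not None else record.visits_rural
    visits_sd = VISITS_URBAN_SD if record.visits_urban is not None else VISITS_RURAL_SD
    dependency = record.n_minors / record.n_working_adults if record.n_working_adults else 0.0
    return (
        betas.get("manaus", 0.0) * (record.municipality == "manaus")
        + betas.get("multisited", 0.0) * (record.residence_status == "multisited")
        + betas.get("rural", 0.0) * (record.urbanization == "rural")
        + betas.get("peri_urban", 0.0) * (record.urbanization == "peri_urban")
        + betas.get("dry", 0.0) * (season == "dry")
        + betas.get("visits_std", 0.0) * (visits / visits_sd)
        + betas.get("dependency_std", 0.0) * (dependency / DEPENDENCY_SD)
    )


def _ordinal_probs(eta: float, kappa: np.ndarray) -> np.ndarray:
    """Category probabilities 0..K under the proportional-odds model."""
    cum = expit(kappa - eta)
    return np.diff(np.concatenate(([0.0], cum, [1.0])))


def _draw_positive_category(probs: np.ndarray, rng: np.random.Generator) -> int:
    """Draw a category conditional on being non-zero."""
    p = probs.copy()
    p[0] = 0.0
    total = p.sum()
    if total <= 0:  # degenerate tail mass; put everything in the first bin
        return 1
    return int(rng.choice(len(p), p=p / total))


def simulate_responses(
    households: list[HouseholdRecord],
    params: TrueParams,
    design: StudyDesign,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate masked responses for every household x item domain x season.

    Returns ``(truth, analysis)`` frames; truth retains the latent
    assignment ``z`` and latent use, the analysis frame drops both.
    """
    if seed is None:
        raise ValueError("seed is required: all simulation is explicitly seeded")
    validate_design(design)
    known = {s.key for s in design.strata}
    rng = np.random.default_rng(derive_seed(seed, "responses"))

    rows: list[dict] = []
    for record in households:
        if (record.municipality, record.urbanization) not in known:
            raise DesignError(
                f"household {record.household_id} stratum "
                f"({record.municipality}, {record.urbanization}) absent from design"
            )
        for domain in design.item_domains:
            taxon, _ = split_item_domain(domain)
            kappa = params.cutpoints[taxon]
            ns_probs = params.pi_ns_quantity[domain]
            for season in design.seasons:
                cell = (record.municipality, record.urbanization, domain, season)
                if cell not in params.pi_s:
                    raise DesignError(f"pi_s missing for cell {cell}")
                z = draw_randomizer(design.randomizer, rng)
                # The household's sensitive-behavior status exists whether or
                # not the randomizer routed to it; the truth table keeps it.
                latent_use = int(rng.random() < params.pi_s[cell])
                if z == SENSITIVE:
                    use = latent_use
                    if use:
                        eta = _quantity_linear_predictor(record, season, params.quantity_betas)
                        cat = _draw_positive_category(_ordinal_probs(eta, kappa), rng)
                    else:
                        cat = 0
                else:
                    use = int(rng.random() < params.pi_ns[domain])
                    cat = _draw_positive_category(ns_probs, rng) if use else 0
                rows.append(
                    {
                        "household_id": record.household_id,
                        "municipality": record.municipality,
                        "urbanization": record.urbanization,
                        "residence_status": record.residence_status,
                        "management": record.management,
                        "n_minors": record.n_minors,
                        "n_working_adults": record.n_working_adults,
                        "visits_urban": record.visits_urban,
                        "visits_rural": record.visits_rural,
                        "season": season,
                        "item_domain": domain,
                        "use": use,
                        "quantity_category": cat,
                        "z": z,
                        "latent_use": latent_use,
                    }
                )

    truth = pd.DataFrame(rows, columns=ANALYSIS_COLUMNS + TRUTH_ONLY_COLUMNS)
    for col in ("visits_urban", "visits_rural"):
        truth[col] = truth[col].astype("Int64")
    analysis = truth[ANALYSIS_COLUMNS].copy()
    return truth, analysis
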