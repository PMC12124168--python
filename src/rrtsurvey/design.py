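"""Study design and true-parameter containers for masked household surveys.

The survey design is a stratified sample over municipality x urbanization
cells.  Responses about sensitive items are masked by an unrelated-question
randomizer: a physical device routes each respondent either to the sensitive
question (probability ``p_s``) or to an innocuous unrelated one, and the
interviewer never learns which.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

import numpy as np

__all__ = [
    "MANAUS",
    "CARAUARI",
    "MUNICIPALITIES",
    "URBANIZATIONS",
    "SEASONS",
    "TAXON_GROUPS",
    "USE_TYPES",
    "ITEM_DOMAINS",
    "DesignError",
    "RandomizerDesign",
    "Stratum",
    "StudyDesign",
    "TrueParams",
    "validate_design",
    "default_study_design",
    "default_true_params",
    "item_domain",
    "split_item_domain",
]

MANAUS = "manaus"
CARAUARI = "carauari"
MUNICIPALITIES = (MANAUS, CARAUARI)
URBANIZATIONS = ("rural", "peri_urban", "urban")
SEASONS = ("dry", "wet")
TAXON_GROUPS = ("mammals_birds", "chelonians")
USE_TYPES = ("consumption", "barter", "trade")

# Nominal 1-SD scales used to express continuous effects in original units.
VISITS_RURAL_SD = 6.56   # rural visits per season by urban households
VISITS_URBAN_SD = 21.76  # urban visits per season by rural/peri-urban households
DEPENDENCY_SD = 0.2


def item_domain(taxon_group: str, use_type: str) -> str:
    """Canonical item-domain label, e.g. ``mammals_birds:consumption``."""
    if taxon_group not in TAXON_GROUPS:
        raise DesignError(f"unknown taxon_group {taxon_group!r}")
    if use_type not in USE_TYPES:
        raise DesignError(f"unknown use_type {use_type!r}")
    return f"{taxon_group}:{use_type}"


def split_item_domain(domain: str) -> tuple[str, str]:
    taxon_group, _, use_type = domain.partition(":")
    if taxon_group not in TAXON_GROUPS or use_type not in USE_TYPES:
        raise DesignError(f"malformed item domain {domain!r}")
    return taxon_group, use_type


ITEM_DOMAINS = tuple(item_domain(t, u) for t in TAXON_GROUPS for u in USE_TYPES)


class DesignError(ValueError):
    """A study-design invariant was violated; the message names the field."""


@dataclass(frozen=True)
class RandomizerDesign:
    """The masking device: ``n_sensitive`` of ``n_total`` tokens route the
    respondent to the sensitive question, so ``p_s = n_sensitive / n_total``
    exactly (kept as a rational)."""

    n_total: int = 6
    n_sensitive: int = 4

    def __post_init__(self) -> None:
        if not (isinstance(self.n_total, (int, np.integer)) and self.n_total >= 1):
            raise DesignError(f"n_total must be an integer >= 1, got {self.n_total!r}")
        if not (
            isinstance(self.n_sensitive, (int, np.integer))
            and 0 <= self.n_sensitive <= self.n_total
        ):
            raise DesignError(
                f"n_sensitive must satisfy 0 <= n_sensitive <= n_total, "
                f"got n_sensitive={self.n_sensitive!r}, n_total={self.n_total!r}"
            )

    @property
    def p_s(self) -> Fraction:
        return Fraction(int(self.n_sensitive), int(self.n_total))


@dataclass(frozen=True)
class Stratum:
    municipality: str
    urbanization: str
    n_households: int

    def __post_init__(self) -> None:
        if self.municipality not in MUNICIPALITIES:
            raise DesignError(f"unknown municipality {self.municipality!r}")
        if self.urbanization not in URBANIZATIONS:
            raise DesignError(f"unknown urbanization {self.urbanization!r}")
        if not (isinstance(self.n_households, (int, np.integer)) and self.n_households > 0):
            raise DesignError(
                f"n_households must be a positive integer in stratum "
                f"({self.municipality}, {self.urbanization}), got {self.n_households!r}"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.municipality, self.urbanization)


@dataclass(frozen=True)
class StudyDesign:
    strata: tuple[Stratum, ...]
    seasons: tuple[str, ...] = SEASONS
    item_domains: tuple[str, ...] = ITEM_DOMAINS
    nonsensitive_items: tuple[str, ...] = ("legal_food", "merchandise")
    randomizer: RandomizerDesign = field(default_factory=RandomizerDesign)

    @property
    def n_households(self) -> int:
        return sum(s.n_households for s in self.strata)

    def stratum_keys(self) -> list[tuple[str, str]]:
        return [s.key for s in self.strata]


def validate_design(design: StudyDesign) -> StudyDesign:
    """Return ``design`` unchanged if every invariant holds, else raise
    :class:`DesignError` naming the offending field."""
    if not design.strata:
        raise DesignError("strata: at least one stratum is required")
    seen: set[tuple[str, str]] = set()
    for s in design.strata:
        if s.key in seen:
            raise DesignError(f"strata: duplicate stratum {s.key}")
        seen.add(s.key)
    if tuple(design.seasons) != SEASONS:
        raise DesignError(f"seasons: expected {SEASONS}, got {design.seasons!r}")
    for d in design.item_domains:
        split_item_domain(d)
    if not design.nonsensitive_items:
        raise DesignError("nonsensitive_items: at least one unrelated item is required")
    # RandomizerDesign validates itself on construction, but configs may
    # bypass the dataclass; re-check here.
    RandomizerDesign(design.randomizer.n_total, design.randomizer.n_sensitive)
    return design


def default_study_design() -> StudyDesign:
    """Default stratified design: six municipality x urbanization strata
    totalling 782 households."""
    strata = (
        Stratum(MANAUS, "rural", 120),
        Stratum(MANAUS, "peri_urban", 90),
        Stratum(MANAUS, "urban", 299),
        Stratum(CARAUARI, "rural", 73),
        Stratum(CARAUARI, "peri_urban", 41),
        Stratum(CARAUARI, "urban", 159),
    )
    return StudyDesign(strata=strata)


@dataclass
class TrueParams:
    """Generator truth: sensitive prevalences per cell, unrelated-item
    prevalences, and the quantity / covariate model coefficients.

    ``pi_s`` is keyed by ``(municipality, urbanization, item_domain, season)``.
    ``cutpoints`` hold K ordered thresholds per taxon group for the
    ordered-logistic quantity model over categories ``0..K``.
    """

    pi_s: dict[tuple[str, str, str, str], float]
    pi_ns: dict[str, float]
    cutpoints: dict[str, np.ndarray]
    quantity_betas: dict[str, float]
    glm_betas: dict[str, object]
    pi_ns_quantity: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, p in self.pi_s.items():
            if not 0.0 <= float(p) <= 1.0:
                raise DesignError(f"pi_s[{key}] = {p!r} outside [0, 1]")
        for key, p in self.pi_ns.items():
            if not 0.0 <= float(p) <= 1.0:
                raise DesignError(f"pi_ns[{key}] = {p!r} outside [0, 1]")
        for taxon, kappa in self.cutpoints.items():
            kappa = np.asarray(kappa, dtype=float)
            if kappa.ndim != 1 or kappa.size < 1:
                raise DesignError(f"cutpoints[{taxon}] must be a 1-D vector")
            if not np.all(np.diff(kappa) > 0):
                raise DesignError(f"cutpoints[{taxon}] must be strictly increasing")
            self.cutpoints[taxon] = kappa
        for domain, probs in self.pi_ns_quantity.items():
            probs = np.asarray(probs, dtype=float)
            if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
                raise DesignError(f"pi_ns_quantity[{domain}] is not a probability vector")
            self.pi_ns_quantity[domain] = probs

    def n_quantity_categories(self, taxon_group: str) -> int:
        """Number of non-zero ordered quantity bins K for a taxon group."""
        return int(self.cutpoints[taxon_group].size)


# Urban dry-season prevalence anchors per (taxon, use_type, municipality).
_URBAN_DRY_PI = {
    ("mammals_birds", "consumption", MANAUS): 0.22,
    ("mammals_birds", "consumption", CARAUARI): 0.57,
    ("mammals_birds", "barter", MANAUS): 0.17,
    ("mammals_birds", "barter", CARAUARI): 0.30,
    ("mammals_birds", "trade", MANAUS): 0.21,
    ("mammals_birds", "trade", CARAUARI): 0.07,
    ("chelonians", "consumption", MANAUS): 0.28,
    ("chelonians", "consumption", CARAUARI): 0.61,
    ("chelonians", "barter", MANAUS): 0.14,
    ("chelonians", "barter", CARAUARI): 0.20,
    ("chelonians", "trade", MANAUS): 0.16,
    ("chelonians", "trade", CARAUARI): 0.21,
}

# Non-urban dry-season cells with their own anchors.
_DRY_OVERRIDES = {
    (MANAUS, "peri_urban", "chelonians:barter"): 0.13,
    (CARAUARI, "peri_urban", "chelonians:barter"): 0.79,
    (MANAUS, "peri_urban", "chelonians:trade"): 0.44,
    (CARAUARI, "rural", "mammals_birds:trade"): 0.46,
}

_RURAL_MULT = 2.2
_PERI_MULT = 1.6
_WET_MULT = 0.75


def default_true_params(design: StudyDesign | None = None) -> TrueParams:
    """Default generator truth.

    Urban dry-season prevalences use the study's headline values; rural and
    peri-urban cells scale them up (use is higher away from the city) unless
    an explicit anchor exists; wet-season cells scale dry ones down.
    """
    if design is None:
        design = default_study_design()
    pi_s: dict[tuple[str, str, str, str], float] = {}
    for stratum in design.strata:
        mun, urb = stratum.key
        for domain in design.item_domains:
            taxon, use_type = split_item_domain(domain)
            base = _URBAN_DRY_PI[(taxon, use_type, mun)]
            if urb == "rural":
                dry = min(base * _RURAL_MULT, 0.92)
            elif urb == "peri_urban":
                dry = min(base * _PERI_MULT, 0.90)
            else:
                dry = base
            dry = _DRY_OVERRIDES.get((mun, urb, domain), dry)
            pi_s[(mun, urb, domain, "dry")] = round(dry, 4)
            pi_s[(mun, urb, domain, "wet")] = round(dry * _WET_MULT, 4)

    pi_ns = {domain: 0.5 for domain in design.item_domains}
    cutpoints = {taxon: np.array([-1.0, 0.2, 1.2, 2.2]) for taxon in TAXON_GROUPS}
    pi_ns_quantity = {
        domain: np.array([0.5, 0.2, 0.15, 0.1, 0.05]) for domain in design.item_domains
    }
    quantity_betas = {
        "manaus": -1.0,
        "multisited": 0.4,
        "rural": 1.0,
        "peri_urban": 0.6,
        "dry": 0.5,
        "visits_std": 0.3,
        "dependency_std": 0.3,
    }
    glm_betas = {
        "p_multisited": 0.19,
        "lambda_minors": 1.5,
        "lambda_working": 1.0,
        # dual-adult management: logistic on municipality and urbanization
        "management": {
            "intercept": 0.4,
            "manaus": float(np.log(0.41)),
            "rural": float(np.log(1.60)),
            "peri_urban": float(np.log(3.25)),
        },
        # urban visits by rural/peri-urban households: log-mean + dispersion
        "visits_urban": {
            "intercept": float(np.log(12.0)),
            "manaus": float(np.log(1.30)),
            "peri_urban": float(np.log(3.02)),
            "theta": 1.2,
        },
        # rural visits by urban households
        "visits_rural": {
            "intercept": float(np.log(6.0)),
            "manaus": float(np.log(0.24)),
            "multisited": float(np.log(4.78)),
            "theta": 0.9,
        },
    }
    return TrueParams(
        pi_s=pi_s,
        pi_ns=pi_ns,
        cutpoints=cutpoints,
        quantity_betas=quantity_betas,
        glm_betas=glm_betas,
        pi_ns_quantity=pi_ns_quantity,
    )
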