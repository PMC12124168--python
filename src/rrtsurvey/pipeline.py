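"""Config-driven generate -> estimate -> report pipeline.

Every stage derives its seeds from the single master seed, writes plain-text
artifacts into the workdir, and records them in a manifest of content
hashes; two runs from the same config produce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as survey_io
from ._seeds import derive_seed
from .design import (
    ITEM_DOMAINS,
    MUNICIPALITIES,
    SEASONS,
    TAXON_GROUPS,
    USE_TYPES,
    URBANIZATIONS,
    RandomizerDesign,
    Stratum,
    StudyDesign,
    TrueParams,
    default_study_design,
    default_true_params,
    item_domain,
    validate_design,
)
from .glms import dependency_measures, fit_logistic_structure, fit_negbin_visits
from .prevalence import (
    CELL_KEYS,
    CellPosterior,
    McmcConfig,
    MixtureModelSpec,
    fit_prevalence_gibbs,
)
from .quantity import QuantityModelSpec, fit_quantity_model, odds_ratio_summary, standardize_covariates
from .simulate import households_to_frame, simulate_households, simulate_responses

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "load_config",
    "run_pipeline",
    "render_prevalence_table",
    "survey_io_roundtrip",
]

logger = logging.getLogger(__name__)

SEASON_SPANS = {"dry": "dry season (June–December)", "wet": "wet season (January–May)"}


class PipelineError(RuntimeError):
    """Stage failure; message names the stage and the cell or model."""


@dataclass
class PipelineConfig:
    workdir: Path
    seed: int
    design: StudyDesign
    params: TrueParams
    mcmc: dict = field(default_factory=dict)
    input_csv: Path | None = None  # analysis CSV to estimate from, skips generate
    quantity_models: list[dict] = field(default_factory=list)
    glm_models: list[dict] = field(default_factory=list)
    report_options: dict = field(default_factory=dict)

    def mcmc_config(self, seed: int) -> McmcConfig:
        return McmcConfig(
            n_burnin=int(self.mcmc.get("n_burnin", 50_000)),
            n_samples=int(self.mcmc.get("n_samples", 25_000)),
            n_chains=int(self.mcmc.get("n_chains", 2)),
            thin=int(self.mcmc.get("thin", 1)),
            seed=seed,
        )


def _design_from_dict(raw: object) -> StudyDesign:
    if raw in (None, "default"):
        return default_study_design()
    assert isinstance(raw, dict)
    randomizer = RandomizerDesign(**raw.get("randomizer", {}))
    strata = tuple(
        Stratum(s["municipality"], s["urbanization"], int(s["n_households"]))
        for s in raw["strata"]
    )
    kwargs = {}
    if "item_domains" in raw:
        kwargs["item_domains"] = tuple(raw["item_domains"])
    if "nonsensitive_items" in raw:
        kwargs["nonsensitive_items"] = tuple(raw["nonsensitive_items"])
    return StudyDesign(strata=strata, randomizer=randomizer, **kwargs)


def _params_from_dict(raw: object, design: StudyDesign) -> TrueParams:
    params = default_true_params(design)
    if raw in (None, "default"):
        return params
    assert isinstance(raw, dict)
    for key, value in raw.get("pi_s", {}).items():
        parts = tuple(key.split("/"))
        if len(parts) != 4:
            raise PipelineError(f"config: pi_s key {key!r} must be mun/urb/domain/season")
        params.pi_s[parts] = float(value)
    for domain, value in raw.get("pi_ns", {}).items():
        params.pi_ns[domain] = float(value)
    for taxon, kappa in raw.get("cutpoints", {}).items():
        params.cutpoints[taxon] = np.asarray(kappa, dtype=float)
    params.quantity_betas.update(raw.get("quantity_betas", {}))
    return TrueParams(**vars(params))


def load_config(path: str | Path, *, seed: int | None = None, workdir: str | Path | None = None) -> PipelineConfig:
    """Load and validate a YAML pipeline config; ``seed`` / ``workdir``
    override the file values."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    if seed is None:
        if "seed" not in raw:
            raise PipelineError("config: master seed is mandatory")
        seed = int(raw["seed"])
    wd = Path(workdir) if workdir is not None else Path(raw.get("workdir", "rrtsurvey_out"))
    design = validate_design(_design_from_dict(raw.get("design")))
    params = _params_from_dict(raw.get("params"), design)
    input_csv = raw.get("input_csv")
    if input_csv is not None:
        input_csv = Path(input_csv)
        if not input_csv.exists():
            raise PipelineError(f"config: input_csv {input_csv} not resolvable")
    return PipelineConfig(
        workdir=wd,
        seed=seed,
        design=design,
        params=params,
        mcmc=raw.get("mcmc", {}),
        input_csv=input_csv,
        quantity_models=raw.get("quantity_models", []),
        glm_models=raw.get("glm_models", []),
        report_options=raw.get("report", {}),
    )


def survey_io_roundtrip(responses: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    """Write then re-read an analysis table; the result is semantically
    identical (missing fields stay missing, never zero)."""
    survey_io.write_responses(responses, path)
    return survey_io.read_responses(path)


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------


def _stage_generate(cfg: PipelineConfig) -> list[Path]:
    households = simulate_households(cfg.design, cfg.params, derive_seed(cfg.seed, "generate"))
    truth, analysis = simulate_responses(
        households, cfg.params, cfg.design, derive_seed(cfg.seed, "responses")
    )
    hh_path = cfg.workdir / "households.csv"
    survey_io.write_households(households_to_frame(households), hh_path)
    analysis_path = cfg.workdir / "responses.csv"
    truth_path = cfg.workdir / "responses.truth.csv"
    survey_io.write_responses(analysis, analysis_path)
    survey_io.write_responses(truth, truth_path, truth=True)
    return [hh_path, analysis_path, truth_path]


def _stage_prevalence(cfg: PipelineConfig, responses: pd.DataFrame) -> tuple[Path, dict]:
    spec = MixtureModelSpec(
        p_s=float(cfg.design.randomizer.p_s),
        pi_ns_mode="known",
        pi_ns_value=0.5,  # per-domain values override below
    )
    mcmc = cfg.mcmc_config(derive_seed(cfg.seed, "prevalence"))
    cells = fit_prevalence_gibbs(responses, spec, mcmc, pi_ns_by_domain=cfg.params.pi_ns)
    rows = []
    for cell, post in sorted(cells.items()):
        s = post.summary
        rows.append(
            dict(
                zip(CELL_KEYS, cell),
                mean=s.mean,
                median=s.median,
                cri_low=s.cri_low,
                cri_high=s.cri_high,
                rhat=s.rhat,
                ess=s.ess,
                n_households=post.n,
            )
        )
    out = cfg.workdir / "prevalence_summary.csv"
    pd.DataFrame(rows).to_csv(out, index=False, float_format="%.6g")
    return out, cells


_BINARY_TERMS = {
    "manaus": lambda df: (df["municipality"] == "manaus").astype(float),
    "rural": lambda df: (df["urbanization"] == "rural").astype(float),
    "peri_urban": lambda df: (df["urbanization"] == "peri_urban").astype(float),
    "multisited": lambda df: (df["residence_status"] == "multisited").astype(float),
    "dual_adult": lambda df: (df["management"] == "dual_adult").astype(float),
    "dry": lambda df: (df["season"] == "dry").astype(float),
}
_CONTINUOUS_TERMS = ("visits_urban", "visits_rural", "dependency_ratio")


def build_terms(df: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    """Build named model terms from a household or response frame.

    Reference levels are implicit: urban, Carauari, single-sited,
    single-adult, wet season.  Rows where a requested continuous term is
    not applicable are dropped by the caller via the returned NaNs.
    """
    out = pd.DataFrame(index=df.index)
    for term in terms:
        if term in _BINARY_TERMS:
            out[term] = _BINARY_TERMS[term](df)
        elif term == "dependency_ratio":
            ratios = [
                dependency_measures(int(m), int(w), int(w)).ratio if w > 0 else np.nan
                for m, w in zip(df["n_minors"], df["n_working_adults"])
            ]
            out[term] = [np.nan if r is None else r for r in ratios]
        elif term in ("visits_urban", "visits_rural"):
            out[term] = pd.to_numeric(df[term], errors="coerce").astype(float)
        else:
            raise PipelineError(f"unknown model term {term!r}")
    return out


def _stage_quantity(cfg: PipelineConfig, responses: pd.DataFrame) -> list[Path]:
    paths = []
    for model in cfg.quantity_models:
        domain = model["domain"]
        name = model.get("name", domain.replace(":", "_"))
        covariates = list(model.get("covariates", ["manaus", "rural", "peri_urban", "multisited", "dry"]))
        sub = responses[responses["item_domain"] == domain]
        if sub.empty:
            raise PipelineError(f"quantity model {name}: no responses for domain {domain}")
        X = build_terms(sub, covariates)
        keep = X.notna().all(axis=1)
        X, sub = X[keep], sub[keep]
        continuous = [t for t in covariates if t in _CONTINUOUS_TERMS]
        scales = None
        if continuous:
            X, scales = standardize_covariates(X, continuous)
        # The unrelated-item category distribution seen in the data mixes its
        # binary yes-rate with the positive-category split: category 0 with
        # probability 1 - pi_ns, else the renormalized positive bins.
        pi_ns = cfg.params.pi_ns[domain]
        cats = cfg.params.pi_ns_quantity[domain].copy()
        positive = cats[1:] / cats[1:].sum() if cats[1:].sum() > 0 else np.full(len(cats) - 1, 1.0 / (len(cats) - 1))
        ns_cats = np.concatenate(([1.0 - pi_ns], pi_ns * positive))
        spec = QuantityModelSpec(
            covariates=tuple(covariates),
            p_s=float(cfg.design.randomizer.p_s),
            pi_ns_cats=ns_cats,
        )
        mcmc = cfg.mcmc_config(derive_seed(cfg.seed, "quantity", name))
        try:
            post = fit_quantity_model(
                sub["quantity_category"].to_numpy(), X, spec, mcmc, label=name
            )
        except Exception as exc:
            raise PipelineError(f"stage estimate, quantity model {name}: {exc}") from exc
        table = odds_ratio_summary(post, scales)
        out = cfg.workdir / f"quantity_{name}.csv"
        table.to_csv(out, index=False, float_format="%.6g")
        paths.append(out)
    return paths


_DEFAULT_GLMS = [
    {
        "name": "visits_urban",
        "kind": "negbin",
        "outcome": "visits_urban",
        "terms": ["manaus", "peri_urban"],
    },
    {
        "name": "visits_rural",
        "kind": "negbin",
        "outcome": "visits_rural",
        "terms": ["manaus", "multisited"],
    },
    {
        "name": "dual_adult",
        "kind": "logistic",
        "outcome": "dual_adult",
        "terms": ["manaus", "rural", "peri_urban"],
    },
]


def _stage_glms(cfg: PipelineConfig, households: pd.DataFrame) -> list[Path]:
    paths = []
    defaulted = not cfg.glm_models
    models = cfg.glm_models if cfg.glm_models else _DEFAULT_GLMS
    for model in models:
        name = model["name"]
        try:
            X = build_terms(households, list(model["terms"]))
            if model["kind"] == "negbin":
                y = pd.to_numeric(households[model["outcome"]], errors="coerce")
            elif model["kind"] == "logistic":
                y = _BINARY_TERMS[model["outcome"]](households)
            else:
                raise PipelineError(f"unknown GLM kind {model['kind']!r}")
            keep = y.notna() & X.notna().all(axis=1)
            X, y = X[keep], y[keep]
            if defaulted:
                # default model list must survive designs missing some strata
                constant = [t for t in X.columns if X[t].nunique(dropna=True) <= 1]
                if constant:
                    logger.warning("GLM %s: dropping constant terms %s", name, constant)
                    X = X.drop(columns=constant)
            if model["kind"] == "negbin":
                result = fit_negbin_visits(y.astype(int).to_numpy(), X)
            else:
                result = fit_logistic_structure(y.to_numpy(), X)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage estimate, GLM {name}: {exc}") from exc
        table = result.terms.copy()
        table["n"] = result.n
        table["dispersion"] = result.dispersion if result.dispersion is not None else ""
        out = cfg.workdir / f"glm_{name}.csv"
        table.to_csv(out, index=False, float_format="%.6g")
        paths.append(out)
    return paths


def render_prevalence_table(
    summaries: pd.DataFrame, layout: dict | None = None
) -> tuple[pd.DataFrame, str]:
    """Percent-scale prevalence table over the full design layout.

    One row per municipality x urbanization x taxon group x use type x
    season; cells absent from ``summaries`` are rendered explicitly as
    missing.  Duplicate cell keys in ``summaries`` are an error.
    """
    layout = layout or {}
    munis = layout.get("municipalities", MUNICIPALITIES)
    urbs = layout.get("urbanizations", URBANIZATIONS)
    taxa = layout.get("taxon_groups", TAXON_GROUPS)
    uses = layout.get("use_types", USE_TYPES)
    seasons = layout.get("seasons", SEASONS)

    if summaries.duplicated(subset=CELL_KEYS).any():
        dup = summaries[summaries.duplicated(subset=CELL_KEYS)].iloc[0]
        raise PipelineError(f"duplicate cell key {tuple(dup[k] for k in CELL_KEYS)}")
    indexed = summaries.set_index(CELL_KEYS)

    rows = []
    lines = ["Prevalence of wild-meat use by stratum (percent of households)", ""]
    for season in seasons:
        lines.append(f"== {SEASON_SPANS.get(season, season)} ==")
        for mun in munis:
            for urb in urbs:
                for taxon in taxa:
                    for use in uses:
                        domain = item_domain(taxon, use)
                        key = (mun, urb, domain, season)
                        row = {
                            "municipality": mun,
                            "urbanization": urb,
                            "taxon_group": taxon,
                            "use_type": use,
                            "season": season,
                        }
                        if key in indexed.index:
                            s = indexed.loc[key]
                            row.update(
                                percent=100 * s["mean"],
                                ci_low_percent=100 * s["cri_low"],
                                ci_high_percent=100 * s["cri_high"],
                            )
                            text = (
                                f"{round(100 * s['mean']):.0f}% "
                                f"[95% CI {round(100 * s['cri_low']):.0f}–"
                                f"{round(100 * s['cri_high']):.0f}]"
                            )
                        else:
                            row.update(percent=np.nan, ci_low_percent=np.nan, ci_high_percent=np.nan)
                            text = "absent"
                        rows.append(row)
                        lines.append(f"{mun} {urb} {taxon} {use}: {text}")
        lines.append("")
    return pd.DataFrame(rows), "\n".join(lines)


def _stage_report(cfg: PipelineConfig) -> list[Path]:
    summary_path = cfg.workdir / "prevalence_summary.csv"
    if not summary_path.exists():
        raise PipelineError("stage report: prevalence_summary.csv missing (run estimate first)")
    summaries = pd.read_csv(summary_path)
    table, text = render_prevalence_table(summaries, cfg.report_options.get("layout"))
    table_path = cfg.workdir / "prevalence_table.csv"
    table.to_csv(table_path, index=False, float_format="%.6g")
    report_path = cfg.workdir / "report.txt"
    report_path.write_text(text, encoding="utf-8")
    return [table_path, report_path]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig, stages: tuple[str, ...] = ("generate", "estimate", "report")) -> dict[str, str]:
    """Run the requested stages and write ``manifest.json`` mapping each
    artifact to its SHA-256 content hash."""
    cfg.workdir.mkdir(parents=True, exist_ok=True)
    log_path = cfg.workdir / "run.log"
    handler = logging.FileHandler(log_path, mode="a", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("rrtsurvey")
    root.addHandler(handler)
    artifacts: list[Path] = []
    try:
        for stage in stages:
            t0 = time.monotonic()
            logger.info("stage %s: start (master seed %d)", stage, cfg.seed)
            try:
                if stage == "generate":
                    if cfg.input_csv is None:
                        artifacts += _stage_generate(cfg)
                elif stage == "estimate":
                    responses_path = cfg.input_csv or (cfg.workdir / "responses.csv")
                    if not responses_path.exists():
                        raise PipelineError("stage estimate: no responses.csv (run generate first)")
                    responses = survey_io.read_responses(responses_path)
                    out, _ = _stage_prevalence(cfg, responses)
                    artifacts.append(out)
                    artifacts += _stage_quantity(cfg, responses)
                    households_path = cfg.workdir / "households.csv"
                    if households_path.exists():
                        households = survey_io.read_households(households_path)
                        artifacts += _stage_glms(cfg, households)
                elif stage == "report":
                    artifacts += _stage_report(cfg)
                else:
                    raise PipelineError(f"unknown stage {stage!r}")
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {stage} failed: {exc}") from exc
            logger.info("stage %s: done in %.1fs", stage, time.monotonic() - t0)
    finally:
        root.removeHandler(handler)
        handler.close()
    manifest = {p.name: _sha256(p) for p in sorted(set(artifacts))}
    (cfg.workdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
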