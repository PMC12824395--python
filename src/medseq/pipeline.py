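"""End-to-end orchestration: registry → exposure → cohort → sequences →
SSA → typologies → trajectories → association, with persisted artifacts
and a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import fit_multinomial, fitted_probabilities, odds_ratios
from .cohort_builder import apply_eligibility, eligible_persons, exclusion_log
from .exposure_model import AtcClassMap, ExposureParams, build_use_periods, to_day
from .reporting import table_one
from .sequence_builder import build_sequences
from .ssa_core import (
    dissimilarity_matrix,
    mean_time_in_states,
    transition_rates,
    transversal_entropy,
    trate_costs,
    unique_index,
)
from .synthetic_registry import (
    GeneratorConfig,
    generate_cohort,
    read_registry,
    write_registry,
)
from .states import ANTIDEPRESSANT, ALPHABET
from .trajectory_stats import classify_trajectories
from .typology import name_typologies, select_typologies

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every stage's switches in one place.

    ``generator`` drives the synthetic registry; alternatively
    ``input_dir`` points at an existing registry directory. Defaults
    echo the documented design choices (grace 30 d, TRATE cval 2,
    indel 1, k scanned over 2–15).
    """

    out_dir: str = "medseq_out"
    input_dir: str | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    atc_rules: dict[str, str] | None = None
    grace_days: int = 30
    window: int = 3
    cval: float = 2.0
    indel: float = 1.0
    k_min: int = 2
    k_max: int = 15
    methods: tuple[str, ...] = ("pam", "ward_then_pam", "ward")
    do_associate: bool = True
    adjust_factors: tuple[str, ...] = (
        "population_group",
        "sex",
        "age_group",
        "education",
        "living_with_partner",
        "prior_depression",
    )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "generator" in d:
            d["generator"] = GeneratorConfig.from_dict(d["generator"])
        if "methods" in d:
            d["methods"] = tuple(d["methods"])
        if "adjust_factors" in d:
            d["adjust_factors"] = tuple(d["adjust_factors"])
        return cls(**d)


def _config_hash(config: PipelineConfig) -> str:
    def sanitize(o):
        if isinstance(o, dict):
            return {str(k): sanitize(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [sanitize(v) for v in o]
        return o

    blob = json.dumps(sanitize(asdict(config)), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _pre_dx_ad_flags(persons: pd.DataFrame, use_periods: pd.DataFrame) -> pd.Series:
    """Antidepressant use period spanning the diagnosis day, with no
    adequate-class period doing the same (pre-diagnosis AD monotherapy)."""
    dx = dict(zip(persons["person_id"], to_day(persons["diagnosis_date"])))
    ad_over, adequate_over = set(), set()
    for r in use_periods.itertuples(index=False):
        d = dx.get(r.person_id)
        if d is None or not (r.start_day <= d <= r.end_day):
            continue
        if r.drug_class == ANTIDEPRESSANT:
            ad_over.add(r.person_id)
        else:
            adequate_over.add(r.person_id)
    flags = {p: (p in ad_over and p not in adequate_over) for p in dx}
    return pd.Series(flags, name="pre_dx_ad_monotherapy")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and persist tidy CSV artifacts plus a manifest.

    Returns a dict of the in-memory results (tables, the selected
    cluster solution, regression effect tables). Deterministic for a
    fixed config: identical seeds give identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- ingest / simulate ------------------------------------------------
    if config.input_dir is not None:
        registry = read_registry(config.input_dir)
        log.info("stage ingest: read registry from %s", config.input_dir)
    else:
        registry = generate_cohort(config.generator)
        write_registry(registry, out / "registry")
        log.info("stage simulate: n=%d seed=%d", config.generator.n_persons,
                 config.generator.seed)

    # -- exposure ---------------------------------------------------------
    class_map = (
        AtcClassMap.from_dict(config.atc_rules) if config.atc_rules else AtcClassMap()
    )
    params = ExposureParams(grace_days=config.grace_days, window=config.window)
    use_periods = build_use_periods(registry.dispensings, class_map, params)
    use_periods.to_csv(out / "use_periods.csv", index=False)
    log.info("stage exposure: %d use periods (grace=%d, window=%d)",
             len(use_periods), params.grace_days, params.window)

    # -- cohort -----------------------------------------------------------
    report = apply_eligibility(registry.persons, registry.diagnoses, use_periods)
    persons = eligible_persons(registry.persons, report)
    excl = exclusion_log(report)
    log.info("stage cohort: %d/%d eligible", len(persons), len(report))

    # -- sequences --------------------------------------------------------
    sequences, seq_excl = build_sequences(persons, use_periods, registry.hospital_stays)
    excl = pd.concat([excl, seq_excl], ignore_index=True)
    excl.to_csv(out / "exclusions.csv", index=False)
    persons = persons[persons["person_id"].isin(set(sequences["person_id"]))]
    persons = persons.reset_index(drop=True)
    sequences.to_csv(out / "sequences.csv", index=False)
    log.info("stage sequences: %d sequences, %d excluded", len(sequences), len(seq_excl))

    # -- ssa --------------------------------------------------------------
    rates = transition_rates(sequences)
    pd.DataFrame(rates.probs, index=ALPHABET, columns=ALPHABET).to_csv(
        out / "transition_rates.csv"
    )
    costs = trate_costs(rates, cval=config.cval, indel=config.indel)
    log.info("stage ssa: TRATE costs cval=%.3g indel=%.3g (full 8-state alphabet)",
             config.cval, config.indel)
    dissim = dissimilarity_matrix(sequences, costs)
    pd.DataFrame(dissim.matrix).to_csv(out / "dissimilarity.csv", index=False)
    pd.DataFrame({"weight": dissim.weights}).to_csv(out / "weights.csv", index=False)
    groups = persons.set_index("person_id")["population_group"]
    ent = transversal_entropy(sequences)
    pd.DataFrame({"period": np.arange(1, len(ent) + 1), "entropy": ent}).to_csv(
        out / "transversal_entropy.csv", index=False
    )
    mts = mean_time_in_states(
        sequences, groups.reindex(sequences["person_id"]).to_numpy()
    )
    mts.to_csv(out / "time_in_states.csv", index=False)

    # -- cluster ----------------------------------------------------------
    best, asw_table = select_typologies(
        dissim, range(config.k_min, config.k_max + 1), config.methods
    )
    asw_table.to_csv(out / "asw_table.csv", index=False)
    names = name_typologies(best, dissim)
    uidx = unique_index(sequences, dissim)
    labels = pd.DataFrame(
        {
            "person_id": sequences["person_id"],
            "cluster": best.labels[uidx],
        }
    )
    labels["typology_name"] = labels["cluster"].map(names)
    labels.to_csv(out / "labels.csv", index=False)
    log.info("stage cluster: best method=%s k=%d asw=%.3f", best.method, best.k, best.asw)

    # -- trajectories -----------------------------------------------------
    flags = _pre_dx_ad_flags(persons, use_periods)
    trajectories = classify_trajectories(sequences, flags)
    trajectories.to_csv(out / "trajectories.csv", index=False)

    # -- associate --------------------------------------------------------
    effects = {}
    probs = {}
    if config.do_associate:
        # regression is over the named treatment typologies; clusters
        # without a typology interpretation (censoring-dominated) are
        # excluded from the outcome
        named = labels[labels["typology_name"] != "unclassified"]
        merged = named.merge(persons, on="person_id")
        refs = {"population_group": "swedish_born"}
        fit_uni = fit_multinomial(
            merged["typology_name"], merged[["population_group"]],
            reference_levels=refs,
        )
        effects["univariate"] = odds_ratios(fit_uni)
        probs["univariate"] = fitted_probabilities(fit_uni, merged, "population_group")
        factors = [f for f in config.adjust_factors if f in merged.columns]
        fit_adj = fit_multinomial(merged["typology_name"], merged[factors],
                                  reference_levels=refs)
        effects["adjusted"] = odds_ratios(fit_adj)
        probs["adjusted"] = fitted_probabilities(fit_adj, merged, "population_group")
        for kind in effects:
            effects[kind].to_csv(out / f"effects_{kind}.csv", index=False)
            probs[kind].to_csv(out / f"probs_{kind}.csv", index=False)
        log.info("stage associate: reference outcome %s", fit_uni.outcome_categories[0])

    # -- report -----------------------------------------------------------
    table = table_one(persons, trajectories, labels)
    table.to_csv(out / "table_one.csv", index=False)

    manifest = {
        "medseq_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.generator.seed,
        "n_input": len(registry.persons),
        "n_analyzed": len(sequences),
        "best_method": best.method,
        "best_k": int(best.k),
        "best_asw": float(best.asw),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {
        "registry": registry,
        "use_periods": use_periods,
        "eligibility": report,
        "persons": persons,
        "sequences": sequences,
        "exclusions": excl,
        "rates": rates,
        "costs": costs,
        "dissimilarity": dissim,
        "solution": best,
        "asw_table": asw_table,
        "typology_names": names,
        "labels": labels,
        "trajectories": trajectories,
        "effects": effects,
        "probabilities": probs,
        "table_one": table,
        "manifest": manifest,
    }
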