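"""Synthetic dispensing-register generator with known latent typologies.

Emulates the structure of a national-register cohort of incident
bipolar disorder: four population groups, covariate-dependent latent
medication-use typologies (seven archetype sequences over twelve
3-month periods), dispensing streams consistent with each latent
sequence, plus hospitalizations, deaths and register-level exclusion
triggers that exercise the downstream censoring and eligibility rules.

Every person's latent typology is drawn from a multinomial logit over
their covariates; the latent sequence is the typology's archetype with
optional per-period noise. Dispensings are written so that, at zero
noise and without hospitalizations, the exposure and sequence modules
reconstruct the latent sequence exactly: each "use" period receives one
dispensation per active medication class covering all 91 days.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .states import (
    AD_MONO,
    ANTIPSYCH,
    AUGMENT,
    LACK,
    LI_AUGMENT,
    LITHIUM,
    MOOD_STAB,
    N_PERIODS,
    PERIOD_DAYS,
    STATE_CLASSES,
    TREATMENT_STATES,
)

POPULATION_GROUPS = ("swedish_born", "second_gen", "non_refugee", "refugee")

#: Cohort composition of a Swedish incident-BD register population
#: (exact count fractions of 20361/1867/1462/888 out of 24578).
DEFAULT_GROUP_PROPORTIONS = (
    20361 / 24578,
    1867 / 24578,
    1462 / 24578,
    888 / 24578,
)

TYPOLOGY_ORDER = (
    "treatment_failure",
    "persistent_ad_monotherapy",
    "persistent_mood_stabilizers",
    "persistent_antipsychotics",
    "persistent_lithium",
    "persistent_augmentation",
    "persistent_li_augmentation",
)

#: Archetype sequences: treatment failure is a short mood-stabilizer
#: trial followed by lack of treatment; the others are persistent use of
#: their namesake state.
DEFAULT_ARCHETYPES: dict[str, tuple[str, ...]] = {
    "treatment_failure": (MOOD_STAB, MOOD_STAB) + (LACK,) * 10,
    "persistent_ad_monotherapy": (AD_MONO,) * 12,
    "persistent_mood_stabilizers": (MOOD_STAB,) * 12,
    "persistent_antipsychotics": (ANTIPSYCH,) * 12,
    "persistent_lithium": (LITHIUM,) * 12,
    "persistent_augmentation": (AUGMENT,) * 12,
    "persistent_li_augmentation": (LI_AUGMENT,) * 12,
}

#: Baseline typology shares (log-scale intercepts); roughly the overall
#: prevalence of the seven patterns in an incident-BD population.
DEFAULT_BASE_SHARES = (0.341, 0.187, 0.197, 0.089, 0.083, 0.050, 0.052)

#: Plausible covariate marginals. These are illustrative defaults, not a
#: reconstruction of any particular register population.
DEFAULT_COVARIATE_MARGINALS: dict[str, dict[str, float]] = {
    "sex": {"female": 0.56, "male": 0.44},
    "education": {"low": 0.25, "medium": 0.45, "high": 0.30},
    "living_with_partner": {"no": 0.55, "yes": 0.45},
    "prior_depression": {"no": 0.50, "yes": 0.50},
    "adhd": {"no": 0.90, "yes": 0.10},
    "substance_use": {"no": 0.85, "yes": 0.15},
    "neurotic_disorder": {"no": 0.80, "yes": 0.20},
    "obesity_diabetes": {"no": 0.90, "yes": 0.10},
    "prior_sickness_absence": {"no": 0.75, "yes": 0.25},
    "disability_pension": {"no": 0.90, "yes": 0.10},
}

#: Multinomial-logit shifts per covariate level, one entry per typology
#: in :data:`TYPOLOGY_ORDER` with the reference (treatment failure)
#: fixed at 0. Negative values on the non-failure typologies push a
#: level toward treatment failure. Magnitudes mimic the direction of
#: register findings (refugees and low education toward failure).
DEFAULT_LOGIT_COEFFICIENTS: dict[tuple[str, str], tuple[float, ...]] = {
    ("population_group", "second_gen"): (0, -0.45, -0.45, -0.45, -0.45, -0.45, -0.45),
    ("population_group", "non_refugee"): (0, -0.55, -0.55, -0.55, -0.55, -0.55, -0.55),
    ("population_group", "refugee"): (0, -0.9, -0.9, -0.9, -0.9, -0.9, -0.9),
    ("education", "low"): (0, -0.3, -0.3, -0.3, -0.3, -0.3, -0.3),
    ("education", "high"): (0, 0.25, 0.25, 0.25, 0.25, 0.25, 0.25),
    ("prior_depression", "yes"): (0, 0.2, 0.2, 0.0, 0.2, 0.0, 0.2),
}

#: One representative ATC code per medication class, used when writing
#: synthetic dispensings (citalopram, lamotrigine, lithium, olanzapine).
ATC_BY_CLASS = {
    "antidepressant": "N06AB04",
    "anticonvulsant_ms": "N03AX09",
    "lithium": "N05AN01",
    "antipsychotic": "N05AH03",
}

_EPOCH_START = pd.Timestamp("2006-07-01").toordinal()
_EPOCH_END = pd.Timestamp("2015-12-31").toordinal()


@dataclass(frozen=True)
class GeneratorConfig:
    n_persons: int = 2000
    group_proportions: tuple[float, ...] = DEFAULT_GROUP_PROPORTIONS
    typology_archetypes: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPES)
    )
    base_shares: tuple[float, ...] = DEFAULT_BASE_SHARES
    typology_logit_coefficients: dict[tuple[str, str], tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_LOGIT_COEFFICIENTS)
    )
    covariate_marginals: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_MARGINALS.items()}
    )
    state_noise_prob: float = 0.05
    hospitalization_rate: float = 0.05
    death_rate: float = 0.01
    #: rates of injected register histories triggering eligibility
    #: exclusions (prior bipolar code, washout-window medication,
    #: psychosis/dementia code)
    prior_bd_rate: float = 0.0
    washout_med_rate: float = 0.0
    psychosis_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        if len(self.group_proportions) != len(POPULATION_GROUPS):
            raise ValueError("group_proportions needs one entry per population group")
        total = sum(self.group_proportions)
        if abs(total - 1.0) > 5e-3:
            raise ValueError("group_proportions must sum to 1")
        if abs(total - 1.0) > 1e-9:
            # tolerate printed-table rounding slack; renormalize exactly
            object.__setattr__(
                self,
                "group_proportions",
                tuple(p / total for p in self.group_proportions),
            )
        if not 0.0 <= self.state_noise_prob <= 1.0:
            raise ValueError("state_noise_prob must be in [0, 1]")
        for name, arch in self.typology_archetypes.items():
            if len(arch) != N_PERIODS:
                raise ValueError(f"archetype {name!r} must have length {N_PERIODS}")
            bad = set(arch) - set(TREATMENT_STATES)
            if bad:
                raise ValueError(f"archetype {name!r} uses non-treatment states {bad}")

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "group_proportions" in d:
            d["group_proportions"] = tuple(d["group_proportions"])
        if "base_shares" in d:
            d["base_shares"] = tuple(d["base_shares"])
        if "typology_archetypes" in d:
            d["typology_archetypes"] = {
                k: tuple(v) for k, v in d["typology_archetypes"].items()
            }
        if "typology_logit_coefficients" in d:
            d["typology_logit_coefficients"] = {
                (f, lv): tuple(v)
                for (f, lv), v in (
                    ((e["factor"], e["level"]), e["coefficients"])
                    for e in d["typology_logit_coefficients"]
                )
            }
        return cls(**d)


@dataclass
class Registry:
    """The relational tables of a (synthetic) register extract."""

    persons: pd.DataFrame
    dispensings: pd.DataFrame
    hospital_stays: pd.DataFrame
    diagnoses: pd.DataFrame
    truth: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "persons": self.persons,
            "dispensings": self.dispensings,
            "hospital_stays": self.hospital_stays,
            "diagnoses": self.diagnoses,
            "truth": self.truth,
        }


def draw_typologies(
    persons: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw one latent typology per person from the covariate logit."""
    names = list(config.typology_archetypes)
    base = np.asarray(config.base_shares, dtype=float)
    if len(base) != len(names):
        raise ValueError("base_shares length must match number of archetypes")
    logits = np.tile(np.log(base), (len(persons), 1))
    for (factor, level), coefs in config.typology_logit_coefficients.items():
        if factor not in persons.columns:
            raise ValueError(f"logit coefficient refers to unknown factor {factor!r}")
        mask = (persons[factor].astype(str) == level).to_numpy()
        logits[mask] += np.asarray(coefs, dtype=float)
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(len(persons))
    idx = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return np.array(names, dtype=object)[idx]


def generate_cohort(config: GeneratorConfig) -> Registry:
    """Generate persons, dispensings, hospital stays, diagnoses and truth.

    All tables are reproducible bit-for-bit from ``config.seed``. The
    truth table records each person's latent typology and latent state
    sequence, against which pipeline output can be scored.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_persons
    ids = [f"P{i:06d}" for i in range(1, n + 1)]

    groups = rng.choice(
        POPULATION_GROUPS, size=n, p=np.asarray(config.group_proportions)
    )
    persons = pd.DataFrame({"person_id": ids, "population_group": groups})
    for cov, marg in config.covariate_marginals.items():
        levels = list(marg)
        probs = np.asarray([marg[lv] for lv in levels], dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"marginals for {cov!r} must sum to 1")
        persons[cov] = rng.choice(levels, size=n, p=probs)

    dx_day = rng.integers(_EPOCH_START, _EPOCH_END + 1, size=n)
    age = rng.integers(16, 66, size=n)
    birth_day = dx_day - (age * 365.25).astype(int) - rng.integers(0, 365, size=n)
    persons["age_group"] = np.where(age <= 35, "16_35", "36_65")
    persons["birth_date"] = [pd.Timestamp.fromordinal(int(d)) for d in birth_day]
    persons["diagnosis_date"] = [pd.Timestamp.fromordinal(int(d)) for d in dx_day]
    persons["residency_start"] = persons["diagnosis_date"] - pd.Timedelta(days=4 * 365 + 30)
    persons["residency_end"] = persons["diagnosis_date"] + pd.Timedelta(days=1200)

    death = rng.random(n) < config.death_rate
    death_offset = rng.integers(0, N_PERIODS * PERIOD_DAYS, size=n)
    persons["death_date"] = pd.NaT
    persons.loc[death, "death_date"] = persons.loc[death, "diagnosis_date"] + pd.to_timedelta(
        death_offset[death], unit="D"
    )

    typologies = draw_typologies(persons, config, rng)
    arche = config.typology_archetypes
    other_states = {
        s: [t for t in TREATMENT_STATES if t != s] for s in TREATMENT_STATES
    }
    latent = np.empty((n, N_PERIODS), dtype=object)
    for i in range(n):
        seq = list(arche[typologies[i]])
        if config.state_noise_prob > 0:
            flip = rng.random(N_PERIODS) < config.state_noise_prob
            for k in np.flatnonzero(flip):
                seq[k] = other_states[seq[k]][rng.integers(0, 6)]
        latent[i] = seq

    disp_rows: list[tuple] = []
    for i in range(n):
        d0 = int(dx_day[i])
        for k in range(N_PERIODS):
            for cls in sorted(STATE_CLASSES[latent[i, k]]):
                disp_rows.append(
                    (ids[i], ATC_BY_CLASS[cls], d0 + PERIOD_DAYS * k, PERIOD_DAYS)
                )

    diag_rows: list[tuple] = [
        (ids[i], "F31", int(dx_day[i]), "specialized") for i in range(n)
    ]

    stay_rows: list[tuple] = []
    hosp = rng.random(n) < config.hospitalization_rate
    admit_offset = rng.integers(0, N_PERIODS * PERIOD_DAYS - 1, size=n)
    stay_len = rng.integers(3, 61, size=n)
    for i in np.flatnonzero(hosp):
        a = int(dx_day[i]) + int(admit_offset[i])
        stay_rows.append((ids[i], a, a + int(stay_len[i]) - 1))

    # injected exclusion triggers
    prior_bd = rng.random(n) < config.prior_bd_rate
    for i in np.flatnonzero(prior_bd):
        diag_rows.append((ids[i], "F31", int(dx_day[i]) - 400, "specialized"))
    psych = rng.random(n) < config.psychosis_rate
    for i in np.flatnonzero(psych):
        diag_rows.append((ids[i], "F20", int(dx_day[i]) + 100, "specialized"))
    washout = rng.random(n) < config.washout_med_rate
    for i in np.flatnonzero(washout):
        disp_rows.append((ids[i], ATC_BY_CLASS["lithium"], int(dx_day[i]) - 300, 60))

    def _dates(days):
        return [pd.Timestamp.fromordinal(int(d)) for d in days]

    dispensings = pd.DataFrame(
        disp_rows, columns=["person_id", "atc_code", "dispense_day", "days_supply"]
    )
    dispensings = dispensings.sort_values(
        ["person_id", "dispense_day", "atc_code"], kind="mergesort"
    ).reset_index(drop=True)
    dispensings["dispense_date"] = _dates(dispensings.pop("dispense_day"))
    dispensings = dispensings[["person_id", "atc_code", "dispense_date", "days_supply"]]

    diagnoses = pd.DataFrame(
        diag_rows, columns=["person_id", "icd10_code", "day", "setting"]
    ).sort_values(["person_id", "day", "icd10_code"], kind="mergesort").reset_index(drop=True)
    diagnoses["date"] = _dates(diagnoses.pop("day"))
    diagnoses = diagnoses[["person_id", "icd10_code", "date", "setting"]]

    hospital_stays = pd.DataFrame(
        stay_rows, columns=["person_id", "admit_day", "discharge_day"]
    )
    hospital_stays["admit_date"] = _dates(hospital_stays.pop("admit_day"))
    hospital_stays["discharge_date"] = _dates(hospital_stays.pop("discharge_day"))
    hospital_stays = hospital_stays[["person_id", "admit_date", "discharge_date"]]

    truth = pd.DataFrame({"person_id": ids, "typology": typologies})
    for k in range(N_PERIODS):
        truth[f"s{k + 1}"] = latent[:, k]

    cols = (
        ["person_id", "birth_date", "sex", "population_group"]
        + [c for c in config.covariate_marginals if c != "sex"]
        + ["age_group", "diagnosis_date", "death_date", "residency_start", "residency_end"]
    )
    persons = persons[cols]
    return Registry(persons, dispensings, hospital_stays, diagnoses, truth)


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

_DATE_COLUMNS = {
    "persons": ["birth_date", "diagnosis_date", "death_date", "residency_start", "residency_end"],
    "dispensings": ["dispense_date"],
    "hospital_stays": ["admit_date", "discharge_date"],
    "diagnoses": ["date"],
    "truth": [],
}


def write_registry(registry: Registry, directory: str | Path) -> dict[str, Path]:
    """Write all tables as CSV (ISO-8601 dates, one header row)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in registry.tables().items():
        out = df.copy()
        for c in _DATE_COLUMNS[name]:
            out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d")
        path = directory / f"{name}.csv"
        out.to_csv(path, index=False)
        paths[name] = path
    return paths


def _parse_dates(df: pd.DataFrame, cols: list[str], fname: str) -> pd.DataFrame:
    for c in cols:
        if c not in df.columns:
            raise ValueError(f"{fname}: missing column {c!r}")
        try:
            df[c] = pd.to_datetime(df[c], format="%Y-%m-%d")
        except (ValueError, TypeError) as e:
            raise ValueError(f"{fname}: malformed date in column {c!r}: {e}") from None
    return df


def read_registry(directory: str | Path) -> Registry:
    """Read a registry directory, validating the table invariants.

    Raises ``ValueError`` naming the file, row and column for malformed
    dates and for invariant violations (discharge before admission,
    non-positive supply, death before diagnosis).
    """
    directory = Path(directory)
    frames = {}
    for name, date_cols in _DATE_COLUMNS.items():
        path = directory / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing registry file {path}")
        df = pd.read_csv(path, dtype={"person_id": str})
        frames[name] = _parse_dates(df, date_cols, path.name)

    hs = frames["hospital_stays"]
    bad = hs["discharge_date"] < hs["admit_date"]
    if bad.any():
        rows = (hs.index[bad] + 2).tolist()  # header + 1-based
        raise ValueError(
            f"hospital_stays.csv: discharge before admission at rows {rows}"
        )
    disp = frames["dispensings"]
    bad = disp["days_supply"] < 1
    if bad.any():
        rows = (disp.index[bad] + 2).tolist()
        raise ValueError(f"dispensings.csv: days_supply < 1 at rows {rows}")
    pers = frames["persons"]
    died = pers["death_date"].notna()
    bad = died & (pers["death_date"] < pers["diagnosis_date"])
    if bad.any():
        rows = (pers.index[bad] + 2).tolist()
        raise ValueError(f"persons.csv: death before diagnosis at rows {rows}")
    return Registry(**frames)
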