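"""Seeded synthetic trauma cohorts for exercising the analysis pipeline.

Generates admission records with the statistical structure the downstream
stages assume: a three-class outcome (cure / improved / poor prognosis)
with exact class counts, free-text primary and other diagnoses assembled
from the keyword library, six regional AIS scores, and a panel of
clinical/laboratory features whose per-class marginals follow configurable
median/IQR targets.  The default configuration emulates a 292-patient
severe-trauma registry with groups of 108 / 130 / 54 and under 5%
missingness.

Continuous features are drawn from log-normal distributions parameterized
so that the theoretical median and interquartile range hit the per-class
targets: for a log-normal with parameters (mu, sigma),

    median = exp(mu),  IQR = 2 * median * sinh(z75 * sigma)

with z75 = 0.6745, so mu = log(median) and
sigma = asinh(IQR / (2 * median)) / z75.

The outcome class is assigned first and every feature is sampled
conditionally on it; missing cells are inserted completely at random.
Diagnosis texts mix library keywords with neutral filler words, with
poor-prognosis records preferring high-weight modules (multiplicative
odds), so keyword match counts remain exactly recoverable downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from .injury_composite import REGIONS
from .text_scoring import KeywordLibrary, default_libraries

OUTCOMES = ["cure", "improved", "poor"]
_Z75 = 0.6744897501960817

# Filler vocabulary for realistic non-matching text; none of these words (or
# any juxtaposition separated by spaces) contains a library keyword.
FILLER_WORDS = [
    "patient", "admitted", "via", "ambulance", "after", "road", "incident",
    "found", "at", "scene", "alert", "on", "arrival", "observation",
    "continued", "ward", "review", "stable", "course", "noted", "during",
    "assessment", "history", "of", "presenting", "complaint", "documented",
]


@dataclass(frozen=True)
class FeatureSpec:
    """Marginal targets for one synthetic feature.

    ``kind='continuous'``: ``per_class`` maps outcome -> (median, p25, p75).
    ``kind='count'``: ``per_class`` maps outcome -> Poisson rate.
    ``kind='categorical'``: ``levels`` plus ``per_class`` outcome -> level
    probabilities (must sum to 1).
    """

    name: str
    kind: Literal["continuous", "count", "categorical"]
    per_class: dict
    levels: tuple[str, ...] = ()
    effect_direction: Literal["risk", "protective", "null"] = "null"

    def __post_init__(self) -> None:
        if self.kind == "categorical":
            for cls, probs in self.per_class.items():
                if abs(sum(probs) - 1.0) > 1e-9:
                    raise ValueError(
                        f"{self.name}: level probabilities for {cls} must sum to 1"
                    )
        if self.kind == "continuous":
            for cls, (m, p25, p75) in self.per_class.items():
                if not np.isfinite([m, p25, p75]).all() or m <= 0:
                    raise ValueError(f"{self.name}: invalid quartile targets for {cls}")


def default_feature_specs() -> list[FeatureSpec]:
    """The packaged default feature panel (a severe-trauma registry profile)."""
    text = resources.files("traumaprog.data").joinpath(
        "cohort_features.json"
    ).read_text(encoding="utf-8")
    raw = json.loads(text)
    specs: list[FeatureSpec] = []
    for e in raw["continuous"]:
        specs.append(
            FeatureSpec(
                name=e["name"],
                kind="continuous",
                per_class={c: tuple(e[c]) for c in OUTCOMES},
                effect_direction=e["direction"],
            )
        )
    for e in raw["count"]:
        specs.append(
            FeatureSpec(
                name=e["name"],
                kind="count",
                per_class=dict(e["rates"]),
                effect_direction=e["direction"],
            )
        )
    for e in raw["categorical"]:
        per_class = {
            c: tuple(np.asarray(e["counts"][c], dtype=float)
                     / np.sum(e["counts"][c]))
            for c in OUTCOMES
        }
        specs.append(
            FeatureSpec(
                name=e["name"],
                kind="categorical",
                per_class=per_class,
                levels=tuple(e["levels"]),
                effect_direction=e["direction"],
            )
        )
    return specs


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort; the seed determines the output."""

    n_cure: int = 108
    n_improved: int = 130
    n_poor: int = 54
    missing_rate: float = 0.03
    seed: int = 0
    feature_specs: list[FeatureSpec] = field(default_factory=default_feature_specs)
    high_weight_odds: float = 3.0  # propensity multiplier for poor-prognosis texts

    def __post_init__(self) -> None:
        if min(self.n_cure, self.n_improved, self.n_poor) < 0:
            raise ValueError("class counts must be non-negative")
        if self.n_cure + self.n_improved + self.n_poor < 30:
            raise ValueError("cohort must contain at least 30 patients")
        if not 0.0 <= self.missing_rate < 0.05:
            raise ValueError("missing_rate must lie in [0, 0.05)")

    @property
    def n_total(self) -> int:
        return self.n_cure + self.n_improved + self.n_poor

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "n_cure": self.n_cure,
            "n_improved": self.n_improved,
            "n_poor": self.n_poor,
            "missing_rate": self.missing_rate,
            "seed": self.seed,
            "high_weight_odds": self.high_weight_odds,
            "n_features": len(self.feature_specs),
        }


@dataclass
class PatientRecord:
    patient_id: str
    primary_dx_text: str
    other_dx_text: str
    ais: dict[str, int]
    features: dict[str, object]
    outcome: str

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        for region, v in self.ais.items():
            if not 0 <= int(v) <= 6:
                raise ValueError(f"AIS for {region} outside 0..6")


def lognormal_params(median: float, iqr: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal matching a (median, IQR) target."""
    if median <= 0:
        raise ValueError("median must be positive")
    mu = float(np.log(median))
    sigma = float(np.arcsinh(iqr / (2.0 * median)) / _Z75) if iqr > 0 else 0.0
    return mu, sigma


# Per-region mean severity on the 0-5 scale by outcome class, scaled to
# binomial(5, p) draws.  Head/neck and chest dominate, mirroring the injury
# pattern of a severe-trauma (largely TBI) cohort; severity rises with worse
# outcome so composite scores discriminate.
_AIS_SEVERITY = {
    "head_neck":      {"cure": 2.4, "improved": 2.9, "poor": 3.4},
    "face":           {"cure": 0.8, "improved": 0.9, "poor": 1.0},
    "chest":          {"cure": 1.4, "improved": 1.7, "poor": 2.1},
    "limbs_pelvis":   {"cure": 1.2, "improved": 1.4, "poor": 1.6},
    "abdomen_pelvis": {"cure": 0.9, "improved": 1.1, "poor": 1.4},
    "body_surface":   {"cure": 0.5, "improved": 0.6, "poor": 0.7},
}


def _sample_ais(rng: np.random.Generator, outcome: str) -> dict[str, int]:
    return {
        r: int(rng.binomial(5, _AIS_SEVERITY[r][outcome] / 5.0)) for r in REGIONS
    }


def _module_probs(
    library: KeywordLibrary, outcome: str, odds: float
) -> np.ndarray:
    """Module sampling propensities; poor prognosis up-weights heavy modules."""
    w = np.array([m.weight if m.weight is not None else 1.0 for m in library.modules])
    base = np.ones(len(w))
    if outcome == "poor":
        base[w >= 4] *= odds
    elif outcome == "improved":
        base[w >= 4] *= 1.0 + (odds - 1.0) / 2.0
    return base / base.sum()


def _sample_text(
    rng: np.random.Generator,
    library: KeywordLibrary,
    outcome: str,
    odds: float,
    n_min: int,
    n_max: int,
) -> str:
    probs = _module_probs(library, outcome, odds)
    n_mentions = int(rng.integers(n_min, n_max + 1))
    parts: list[str] = []
    for _ in range(n_mentions):
        j = int(rng.choice(len(probs), p=probs))
        kw = library.modules[j].keywords[
            int(rng.integers(len(library.modules[j].keywords)))
        ]
        parts.append(kw)
    fillers = rng.choice(FILLER_WORDS, size=int(rng.integers(2, 6)), replace=True)
    return "; ".join(parts) + ". " + " ".join(fillers)


def generate_cohort(
    spec: CohortSpec,
    libraries: dict[str, KeywordLibrary] | None = None,
) -> list[PatientRecord]:
    """Generate a synthetic cohort with exact class counts.

    Outcomes are laid down first (cure block, improved block, poor block,
    then shuffled), and every feature, AIS profile and diagnosis text is
    sampled conditionally on the outcome.
    """
    libraries = libraries or default_libraries()
    rng = np.random.default_rng(spec.seed)
    outcomes = (
        ["cure"] * spec.n_cure + ["improved"] * spec.n_improved
        + ["poor"] * spec.n_poor
    )
    outcomes = [outcomes[i] for i in rng.permutation(len(outcomes))]

    records: list[PatientRecord] = []
    for i, outcome in enumerate(outcomes):
        feats: dict[str, object] = {}
        for fs in spec.feature_specs:
            if fs.kind == "continuous":
                m, p25, p75 = fs.per_class[outcome]
                mu, sigma = lognormal_params(m, p75 - p25)
                feats[fs.name] = float(rng.lognormal(mu, sigma))
            elif fs.kind == "count":
                feats[fs.name] = int(rng.poisson(fs.per_class[outcome]))
            else:
                idx = int(rng.choice(len(fs.levels), p=fs.per_class[outcome]))
                feats[fs.name] = fs.levels[idx]
        records.append(
            PatientRecord(
                patient_id=f"P{i + 1:04d}",
                primary_dx_text=_sample_text(
                    rng, libraries["primary"], outcome, spec.high_weight_odds, 1, 3
                ),
                other_dx_text=_sample_text(
                    rng, libraries["other"], outcome, spec.high_weight_odds, 0, 4
                ),
                ais=_sample_ais(rng, outcome),
                features=feats,
                outcome=outcome,
            )
        )

    if spec.missing_rate > 0:
        names = [fs.name for fs in spec.feature_specs]
        for name in names:
            mask = rng.random(len(records)) < spec.missing_rate
            for rec, missing in zip(records, mask):
                if missing:
                    rec.features[name] = None
    return records


def cohort_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Flatten records to a table: id, texts, AIS columns, features, outcome."""
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "patient_id": rec.patient_id,
            "primary_dx_text": rec.primary_dx_text,
            "other_dx_text": rec.other_dx_text,
        }
        row.update({f"ais_{r}": rec.ais[r] for r in REGIONS})
        row.update(rec.features)
        row["outcome"] = rec.outcome
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(
    records: Sequence[PatientRecord], spec: CohortSpec, path: str | Path
) -> Path:
    """Write the cohort CSV (missing = empty cell) plus a JSON spec sidecar."""
    path = Path(path)
    cohort_to_frame(records).to_csv(path, index=False)
    sidecar = path.with_suffix(".spec.json")
    sidecar.write_text(json.dumps(spec.to_dict(), indent=2), encoding="utf-8")
    return path


def dichotomize_outcome(outcomes: Sequence[str]) -> np.ndarray:
    """Collapse the three classes to binary: cure/improved -> 0 (good
    prognosis, negative class), poor -> 1 (positive class)."""
    mapping = {"cure": 0, "improved": 0, "poor": 1}
    out = []
    for o in outcomes:
        label = o.outcome if isinstance(o, PatientRecord) else o
        if label not in mapping:
            raise ValueError(f"unknown outcome label {label!r}")
        out.append(mapping[label])
    return np.asarray(out, dtype=int)
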