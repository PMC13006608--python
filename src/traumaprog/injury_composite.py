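"""Composite severity scoring over the six AIS body regions.

Regions (in fixed column order): head/neck (incl. cervical spine), face
(incl. facial cranium), chest (incl. thoracic spine and diaphragm), limbs
and pelvis, abdomen and pelvis (incl. lumbar spine), body surface.

Three weighting schemes are implemented:

* **CRITIC** (CRiteria Importance Through Intercriteria Correlation):
  each region's weight combines its dispersion after min-max normalization
  (variability ``S_j``), its decorrelation from the other regions
  (conflict ``R_j = sum_k (1 - r_jk)``, Pearson ``r``), and their product
  (information amount ``C_j = S_j * R_j``), normalized to sum to one.
* **equal weight**: the plain mean of the six regional AIS values.
* **ISS**: sum of squares of the three highest regional AIS values, with
  the standard convention that any region scored 6 gives ISS = 75.

A comparison harness evaluates each scheme's composite against a binary
outcome by ROC AUC, Hosmer-Lemeshow calibration of a univariate logistic
recalibration, and decision-curve net benefit.  RTS and TRISS survival
scores are provided as classical baselines; their coefficient sets are
configuration data, not hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

REGIONS = [
    "head_neck",
    "face",
    "chest",
    "limbs_pelvis",
    "abdomen_pelvis",
    "body_surface",
]

__all__ = [
    "REGIONS",
    "CriticTable",
    "SchemeComparison",
    "critic_weights",
    "equal_weight_composite",
    "iss_score",
    "weighted_composite",
    "hosmer_lemeshow",
    "decision_curve",
    "compare_schemes",
    "rts_score",
    "triss_probability",
    "RTS_COEFFICIENTS",
    "TRISS_BLUNT_COEFFICIENTS",
]


def _validate_ais(ais: np.ndarray) -> np.ndarray:
    ais = np.asarray(ais, dtype=float)
    if ais.ndim != 2 or ais.shape[1] != len(REGIONS):
        raise ValueError(f"AIS matrix must have {len(REGIONS)} region columns")
    if np.any((ais < 0) | (ais > 6)):
        raise ValueError("AIS entries must lie in 0..6")
    return ais


@dataclass
class CriticTable:
    """Per-region CRITIC decomposition: S_j, R_j, C_j = S_j*R_j, w_j."""

    regions: list[str]
    variability: np.ndarray  # S_j: sample std of the min-max normalized column
    conflict: np.ndarray     # R_j = sum_k (1 - r_jk); self term contributes 0
    information: np.ndarray  # C_j = S_j * R_j
    weights: np.ndarray      # w_j = C_j / sum(C)
    constant_columns: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variability": self.variability,
                "conflict": self.conflict,
                "information": self.information,
                "weight": self.weights,
            },
            index=self.regions,
        )


def information_amount(variability: np.ndarray, conflict: np.ndarray) -> np.ndarray:
    """CRITIC information content C_j = S_j * R_j."""
    return np.asarray(variability, dtype=float) * np.asarray(conflict, dtype=float)


def critic_weights(ais: np.ndarray, regions: list[str] | None = None) -> CriticTable:
    """CRITIC objective weights for the regional AIS columns.

    Columns are min-max normalized (all AIS columns are severity-increasing,
    so no direction flip is needed); ``S_j`` is the sample (ddof=1) standard
    deviation of the normalized column.  A constant column carries no
    information: it gets S_j = 0 hence weight 0 and is flagged; correlations
    against it are taken as 0.
    """
    ais = np.asarray(ais, dtype=float)
    if ais.ndim != 2:
        raise ValueError("AIS matrix must be 2-D")
    n, J = ais.shape
    if n < 3:
        raise ValueError("need at least 3 patients for CRITIC weighting")
    regions = regions or (REGIONS if J == len(REGIONS) else [f"c{j}" for j in range(J)])

    rng_span = ais.max(axis=0) - ais.min(axis=0)
    constant = rng_span == 0
    span_safe = np.where(constant, 1.0, rng_span)
    norm = (ais - ais.min(axis=0)) / span_safe

    S = norm.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(norm, rowvar=False)
    r = np.atleast_2d(r)
    r[~np.isfinite(r)] = 0.0  # constant columns: treat as uncorrelated
    np.fill_diagonal(r, 1.0)  # self term contributes 1 - 1 = 0 to conflict
    R = (1.0 - r).sum(axis=1)
    C = information_amount(S, R)
    total = C.sum()
    w = C / total if total > 0 else np.zeros(J)
    return CriticTable(
        regions=list(regions),
        variability=S,
        conflict=R,
        information=C,
        weights=w,
        constant_columns=[regions[j] for j in range(J) if constant[j]],
    )


def equal_weight_composite(ais: np.ndarray) -> np.ndarray:
    """Mean of the six regional AIS values (weight 1/6 each)."""
    return _validate_ais(ais).mean(axis=1)


def iss_score(ais_row: np.ndarray) -> int:
    """Injury Severity Score for one patient (or each row of a matrix).

    Sum of squares of the three highest regional AIS values; any region
    scored 6 (unsurvivable) sets ISS to its maximum of 75.
    """
    row = np.asarray(ais_row, dtype=float)
    if row.ndim == 2:
        return np.array([iss_score(r) for r in row])
    if np.any((row < 0) | (row > 6)):
        raise ValueError("AIS entries must lie in 0..6")
    if np.any(row == 6):
        return 75
    top3 = np.sort(row)[-3:]
    return int(np.sum(top3**2))


def weighted_composite(ais: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise dot product of the AIS matrix with a non-negative weight vector."""
    ais = np.asarray(ais, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if ais.ndim != 2 or ais.shape[1] != weights.shape[0]:
        raise ValueError("weights length must match region columns")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    return ais @ weights


def hosmer_lemeshow(
    y: np.ndarray, prob: np.ndarray, n_bins: int = 10
) -> tuple[float, float]:
    """Hosmer-Lemeshow goodness-of-calibration test.

    Observations are grouped into ``n_bins`` risk-quantile bins; the
    statistic compares observed and expected event counts per bin and is
    referred to a chi-square with ``n_bins - 2`` degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    prob = np.asarray(prob, dtype=float)
    order = np.argsort(prob, kind="stable")
    bins = np.array_split(order, n_bins)
    stat = 0.0
    used = 0
    for idx in bins:
        if len(idx) == 0:
            continue
        o = y[idx].sum()
        e = prob[idx].sum()
        n_k = len(idx)
        denom = e * (1.0 - e / n_k)
        if denom > 1e-12:
            stat += (o - e) ** 2 / denom
        used += 1
    df = max(used - 2, 1)
    return float(stat), float(stats.chi2.sf(stat, df))


def decision_curve(
    y: np.ndarray,
    prob: np.ndarray,
    thresholds: np.ndarray | None = None,
) -> pd.DataFrame:
    """Decision-curve net benefit NB(pt) = TP/n - (FP/n) * pt/(1-pt).

    Includes the treat-all and treat-none reference policies.  Treat-none
    is identically 0; treat-all equals prevalence at pt = 0 and crosses 0
    at pt = prevalence.
    """
    y = np.asarray(y, dtype=float)
    prob = np.asarray(prob, dtype=float)
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    n = len(y)
    prevalence = y.mean()
    rows = []
    for pt in thresholds:
        odds = pt / (1.0 - pt)
        treat = prob >= pt
        tp = float(np.sum(treat & (y == 1)))
        fp = float(np.sum(treat & (y == 0)))
        nb = tp / n - fp / n * odds
        nb_all = prevalence - (1.0 - prevalence) * odds
        rows.append({"threshold": pt, "net_benefit": nb, "treat_all": nb_all,
                     "treat_none": 0.0})
    return pd.DataFrame(rows)


@dataclass
class SchemeComparison:
    schemes: dict[str, dict]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                name: {
                    "auc": d["auc"],
                    "hl_stat": d["hl_stat"],
                    "hl_p": d["hl_p"],
                }
                for name, d in self.schemes.items()
            }
        ).T


def compare_schemes(
    ais: np.ndarray,
    outcome: np.ndarray,
    critic: CriticTable | None = None,
) -> SchemeComparison:
    """Discrimination / calibration / decision-curve comparison of the
    CRITIC, equal-weight and ISS composites against a binary outcome.

    Each composite is recalibrated by a univariate logistic fit before the
    Hosmer-Lemeshow test and the decision curve (the raw composites are not
    probabilities).
    """
    ais = _validate_ais(ais)
    y = np.asarray(outcome, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    critic = critic or critic_weights(ais)
    composites = {
        "critic": weighted_composite(ais, critic.weights),
        "equal": equal_weight_composite(ais),
        "iss": iss_score(ais).astype(float),
    }
    weights_map = {
        "critic": critic.weights,
        "equal": np.full(len(REGIONS), 1.0 / len(REGIONS)),
        "iss": None,  # ISS is not a weighted sum
    }
    out: dict[str, dict] = {}
    for name, score in composites.items():
        lr = LogisticRegression(C=1e6, solver="lbfgs")
        lr.fit(score.reshape(-1, 1), y)
        prob = lr.predict_proba(score.reshape(-1, 1))[:, 1]
        stat, p = hosmer_lemeshow(y, prob)
        out[name] = {
            "weights": weights_map[name],
            "auc": float(roc_auc_score(y, score)),
            "hl_stat": stat,
            "hl_p": p,
            "dca": decision_curve(y, prob),
        }
    return SchemeComparison(out)


# Standard published coefficient sets for the classical trauma scores; kept
# as data so alternative revisions can be swapped in via configuration.
RTS_COEFFICIENTS = {"gcs": 0.9368, "sbp": 0.7326, "rr": 0.2908}
TRISS_BLUNT_COEFFICIENTS = {"b0": -0.4499, "rts": 0.8085, "iss": -0.0835,
                            "age": -1.7430}


def rts_score(
    gcs_code: int, sbp_code: int, rr_code: int,
    coefficients: dict[str, float] | None = None,
) -> float:
    """Revised Trauma Score from the coded (0-4) GCS / SBP / RR categories."""
    coef = coefficients or RTS_COEFFICIENTS
    codes = {"gcs": gcs_code, "sbp": sbp_code, "rr": rr_code}
    for k, v in codes.items():
        if not 0 <= v <= 4:
            raise ValueError(f"{k} code {v} outside 0..4")
    return float(sum(coef[k] * codes[k] for k in codes))


def triss_probability(
    rts: float, iss: float, age_index: int,
    coefficients: dict[str, float] | None = None,
) -> float:
    """TRISS survival probability (blunt-trauma coefficient set by default).

    ``age_index`` is 0 for age <= 54 and 1 otherwise.
    """
    c = coefficients or TRISS_BLUNT_COEFFICIENTS
    if age_index not in (0, 1):
        raise ValueError("age_index must be 0 or 1")
    b = c["b0"] + c["rts"] * rts + c["iss"] * iss + c["age"] * age_index
    return float(1.0 / (1.0 + np.exp(-b)))
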