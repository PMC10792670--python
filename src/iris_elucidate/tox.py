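"""Aggregation and zone classification of in silico toxicity predictions.

Outputs of external QSAR platforms are consumed as data: qualitative calls
are mapped to numeric scores in [0, 1], per-endpoint scores are combined by
an unweighted arithmetic mean, and the mean is classified into reliability
zones — below 0.33 a reliable negative, 0.33-0.5 an unreliable negative,
above 0.5 up to 0.66 an unreliable positive, and above 0.66 a reliable
positive. Dose endpoints (NOAEL, mg/kg bw per day) are averaged directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ToxPrediction",
    "ToxZonePolicy",
    "QUALITATIVE_SCORE_MAP",
    "aggregate_scores",
    "classify_zone",
    "average_noael",
    "qualitative_to_score",
    "build_report",
    "read_predictions_csv",
]

BINARY_ENDPOINTS = {"mutagenicity", "carcinogenicity", "endocrine"}
DOSE_ENDPOINTS = {"LD50", "NOAEL"}

#: documented default conversion of qualitative platform calls to scores
QUALITATIVE_SCORE_MAP: dict[str, float] = {
    "yes": 1.0,
    "active": 1.0,
    "positive": 1.0,
    "no": 0.0,
    "inactive": 0.0,
    "negative": 0.0,
}


@dataclass(frozen=True)
class ToxPrediction:
    """One model's prediction for one substance and endpoint."""

    substance_id: str
    endpoint: str
    model_name: str
    score: float  # [0,1] for binary endpoints; mg/kg for dose endpoints
    reliability: str = "none"  # low | moderate | good | none

    def __post_init__(self) -> None:
        if self.endpoint in BINARY_ENDPOINTS and not 0.0 <= self.score <= 1.0:
            raise ValueError(
                f"score {self.score} outside [0,1] for endpoint {self.endpoint}"
            )
        if self.endpoint in DOSE_ENDPOINTS and self.score <= 0:
            raise ValueError(f"dose value must be positive, got {self.score}")
        if self.reliability not in ("low", "moderate", "good", "none"):
            raise ValueError(f"unknown reliability {self.reliability!r}")


@dataclass(frozen=True)
class ToxZonePolicy:
    """Zone boundaries on the mean prediction score."""

    negative_reliable_max: float = 0.33  # mean < this -> reliable negative
    negative_max: float = 0.5  # mean <= this -> unreliable negative
    positive_reliable_min: float = 0.66  # mean > this -> reliable positive

    def __post_init__(self) -> None:
        if not (
            0.0
            < self.negative_reliable_max
            < self.negative_max
            < self.positive_reliable_min
            < 1.0
        ):
            raise ValueError("zone boundaries must be ordered within (0, 1)")


def qualitative_to_score(call: str) -> float:
    """Map a yes/no-style platform call to a numeric score."""
    key = call.strip().lower()
    if key not in QUALITATIVE_SCORE_MAP:
        raise ValueError(f"no score mapping for qualitative call {call!r}")
    return QUALITATIVE_SCORE_MAP[key]


def aggregate_scores(preds: list[ToxPrediction]) -> float:
    """Unweighted arithmetic mean of same-endpoint prediction scores."""
    if not preds:
        raise ValueError("cannot aggregate an empty prediction list")
    endpoints = {p.endpoint for p in preds}
    if len(endpoints) != 1:
        raise ValueError(f"mixed endpoints in aggregation: {sorted(endpoints)}")
    return sum(p.score for p in preds) / len(preds)


def classify_zone(mean: float, policy: ToxZonePolicy = ToxZonePolicy()) -> str:
    """Classify a mean score into exactly one reliability zone."""
    if not 0.0 <= mean <= 1.0:
        raise ValueError(f"mean score {mean} outside [0, 1]")
    if mean > policy.positive_reliable_min:
        return "positive_reliable"
    if mean > policy.negative_max:
        return "positive_unreliable"
    if mean >= policy.negative_reliable_max:
        return "negative_unreliable"
    return "negative_reliable"


def average_noael(a: float, b: float) -> float:
    """Arithmetic mean of two NOAEL predictions (mg/kg bw per day)."""
    if a <= 0 or b <= 0:
        raise ValueError("NOAEL values must be positive")
    return (a + b) / 2.0


def build_report(
    preds: list[ToxPrediction],
    iris_identified: set[str] | None = None,
    policy: ToxZonePolicy = ToxZonePolicy(),
) -> pd.DataFrame:
    """One row per (substance, endpoint): mean, zone, per-model scores.

    ``iris_identified`` flags substances whose structure was confirmed
    spectroscopically. Dose endpoints report the mean value with no zone.
    """
    iris_identified = iris_identified or set()
    rows = []
    groups: dict[tuple[str, str], list[ToxPrediction]] = {}
    for p in preds:
        groups.setdefault((p.substance_id, p.endpoint), []).append(p)
    for (sub, endpoint), group in sorted(groups.items()):
        mean = aggregate_scores(group)
        row = {
            "substance_id": sub,
            "endpoint": endpoint,
            "mean_score": mean,
            "zone": classify_zone(mean, policy) if endpoint in BINARY_ENDPOINTS else "",
            "n_models": len(group),
            "iris_identified": sub in iris_identified,
        }
        for p in group:
            row[f"score[{p.model_name}]"] = p.score
        rows.append(row)
    return pd.DataFrame(rows)


def read_predictions_csv(path) -> list[ToxPrediction]:
    """Read a predictions table (substance_id, endpoint, model, raw_call or
    score, reliability); qualitative calls are converted via the default map."""
    df = pd.read_csv(path)
    preds = []
    for _, r in df.iterrows():
        if "score" in df.columns and pd.notna(r.get("score")):
            score = float(r["score"])
        else:
            score = qualitative_to_score(str(r["raw_call"]))
        preds.append(
            ToxPrediction(
                substance_id=str(r["substance_id"]),
                endpoint=str(r["endpoint"]),
                model_name=str(r["model"]),
                score=score,
                reliability=str(r.get("reliability", "none")),
            )
        )
    return preds
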