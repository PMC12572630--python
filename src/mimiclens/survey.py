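"""Human-perception channel: Likert questionnaire design, simulated
respondents, validity screening and mean similarity scores.

The questionnaire pairs each mimic subspecies with model species and asks
for a perceived-similarity rating on a 1-10 scale.  Quality control follows
the published screening protocol: every control set holds three questions
with one designed answer (pairs of totally different butterflies), and a
response is discarded when its three control answers are not all equal, or
when it contradicts itself in two or more sets of highly similar questions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QuestionnaireDesign",
    "RespondentModel",
    "ValidationReport",
    "design_questionnaire",
    "simulate_responses",
    "validate_responses",
    "score_pairs",
]

SCALE_MIN, SCALE_MAX = 1, 10
CONTROL_SET_SIZE = 3          # three questions per control set, one answer
DEFAULT_CONTRADICTION_DELTA = 4


@dataclass
class QuestionnaireDesign:
    testing_questions: dict[str, tuple[str, str]]   # qid -> (mimic, model)
    control_sets: list[list[str]]                   # each: 3 qids
    control_answers: dict[str, int]                 # qid -> designed answer
    similar_sets: list[list[str]]                   # near-duplicate testing qids
    demographic_fields: tuple[str, ...] = (
        "gender", "age_band", "education", "familiarity")

    def __post_init__(self):
        for cs in self.control_sets:
            if len(cs) != CONTROL_SET_SIZE:
                raise ValueError("every control set must have exactly 3 questions")
        qids = list(self.testing_questions) + [q for cs in self.control_sets
                                               for q in cs]
        if len(set(qids)) != len(qids):
            raise ValueError("question ids are not unique")

    @property
    def all_question_ids(self) -> list[str]:
        return list(self.testing_questions) + [q for cs in self.control_sets
                                               for q in cs]


@dataclass
class RespondentModel:
    """Generative model of one survey cohort.

    ``latent_similarity`` maps mimic-model pairs to the cohort's shared
    perceived similarity in [1, 10]; honest respondents report it with
    Gaussian noise, careless respondents (a ``careless_rate`` fraction)
    answer control sets inconsistently and contradict similar sets.
    """

    latent_similarity: dict[tuple[str, str], float]
    noise_sd: float = 1.0
    careless_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.careless_rate <= 1.0):
            raise ValueError("careless_rate must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for pair, v in self.latent_similarity.items():
            if not (SCALE_MIN <= v <= SCALE_MAX):
                raise ValueError(f"latent similarity for {pair} outside [1,10]")


@dataclass
class ValidationReport:
    per_respondent: pd.DataFrame     # control_inconsistent, contradiction_count, valid
    collected: int = 0
    valid: int = 0
    contradiction_threshold: int = DEFAULT_CONTRADICTION_DELTA

    def summary(self) -> dict:
        return {"collected": int(self.collected), "valid": int(self.valid),
                "contradiction_threshold": int(self.contradiction_threshold)}


def design_questionnaire(pairs: list[tuple[str, str]], n_control_sets: int = 1,
                         n_similar_sets: int = 2,
                         seed: int = 0) -> QuestionnaireDesign:
    """Build a questionnaire over the given mimic-model pairs.

    Each control set contributes three questions sharing one designed answer
    (dissimilar reference butterflies -> low answers); similar sets duplicate
    a testing pair so self-consistency can be checked.
    """
    if not pairs:
        raise ValueError("pairs must be nonempty")
    if n_control_sets < 1:
        raise ValueError("at least one control set is required for validation")
    rng = np.random.default_rng(seed)
    testing = {f"T{i:03d}": tuple(p) for i, p in enumerate(pairs)}
    control_sets, control_answers = [], {}
    for c in range(n_control_sets):
        qids = [f"C{c}_{k}" for k in range(CONTROL_SET_SIZE)]
        ans = int(rng.integers(1, 4))     # totally different pairs -> low score
        control_sets.append(qids)
        control_answers.update({q: ans for q in qids})
    similar_sets = []
    base_qids = list(testing)
    n_similar_sets = min(n_similar_sets, len(base_qids))
    chosen = rng.choice(len(base_qids), size=n_similar_sets, replace=False)
    for s, bi in enumerate(sorted(chosen)):
        dup = f"S{s:02d}"
        testing[dup] = testing[base_qids[bi]]     # near-duplicate question
        similar_sets.append([base_qids[bi], dup])
    return QuestionnaireDesign(testing_questions=testing,
                               control_sets=control_sets,
                               control_answers=control_answers,
                               similar_sets=similar_sets)


def _clip_round(x: np.ndarray | float) -> np.ndarray:
    return np.clip(np.round(x), SCALE_MIN, SCALE_MAX).astype(int)


def simulate_responses(design: QuestionnaireDesign, model: RespondentModel,
                       n_respondents: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate a cohort; returns (responses, careless ground-truth labels).

    Honest respondents answer round(latent + noise) clipped to the scale and
    give all three control questions the designed answer; careless
    respondents answer controls inconsistently and contradict similar sets
    by construction, so the screening rules can be tested against ground
    truth.  One row per respondent: demographics + one column per question.
    """
    rng = np.random.default_rng(model.seed)
    careless = rng.random(n_respondents) < model.careless_rate
    rows = []
    genders = np.array(["female", "male", "undisclosed"])
    ages = np.array(["<20", "20-29", "30-39", "40-49", "50+"])
    edus = np.array(["secondary", "bachelor", "master", "doctorate"])
    fams = np.array(["none", "hobbyist", "expert"])
    for r in range(n_respondents):
        row: dict = {
            "respondent_id": f"R{r:04d}",
            "gender": str(rng.choice(genders)),
            "age_band": str(rng.choice(ages, p=[.1, .4, .25, .15, .1])),
            "education": str(rng.choice(edus, p=[.2, .5, .2, .1])),
            "familiarity": str(rng.choice(fams, p=[.7, .25, .05])),
        }
        for qid, pair in design.testing_questions.items():
            latent = model.latent_similarity.get(tuple(pair), 5.0)
            row[qid] = int(_clip_round(latent + rng.normal(0, model.noise_sd)))
        for cs in design.control_sets:
            ans = design.control_answers[cs[0]]
            for q in cs:
                row[q] = ans
        if careless[r]:
            # break every control set and contradict every similar set
            for cs in design.control_sets:
                ans = design.control_answers[cs[0]]
                row[cs[1]] = int(ans + 1 if ans < SCALE_MAX else ans - 1)
            for ss in design.similar_sets:
                row[ss[0]] = SCALE_MIN
                row[ss[1]] = SCALE_MAX
        rows.append(row)
    return pd.DataFrame(rows), careless


def validate_responses(responses: pd.DataFrame, design: QuestionnaireDesign,
                       contradiction_threshold: int = DEFAULT_CONTRADICTION_DELTA,
                       ) -> tuple[pd.DataFrame, ValidationReport]:
    """Apply the screening rules; returns (valid responses, report).

    A response is control-inconsistent when the three answers of any control
    set are not all equal; a similar set counts as contradicted when two of
    its answers differ by >= ``contradiction_threshold``.  Invalid iff
    control-inconsistent or >= 2 contradictions.
    """
    known = set(design.all_question_ids)
    answered = [c for c in responses.columns if c not in
                ("respondent_id",) + design.demographic_fields]
    unknown = set(answered) - known
    if unknown:
        raise ValueError(f"answers reference unknown question ids: {sorted(unknown)}")
    flags = []
    for _, row in responses.iterrows():
        incons = any(len({int(row[q]) for q in cs}) > 1
                     for cs in design.control_sets)
        contradictions = sum(
            max(int(row[a]) for a in ss) - min(int(row[a]) for a in ss)
            >= contradiction_threshold
            for ss in design.similar_sets)
        flags.append({"respondent_id": row["respondent_id"],
                      "control_inconsistent": bool(incons),
                      "contradiction_count": int(contradictions),
                      "valid": (not incons) and contradictions < 2})
    per = pd.DataFrame(flags).set_index("respondent_id")
    report = ValidationReport(per_respondent=per,
                              collected=len(responses),
                              valid=int(per["valid"].sum()),
                              contradiction_threshold=contradiction_threshold)
    keep = responses["respondent_id"].map(per["valid"]).to_numpy(bool)
    return responses.loc[keep].reset_index(drop=True), report


def score_pairs(valid_responses: pd.DataFrame,
                design: QuestionnaireDesign) -> pd.DataFrame:
    """Mean Likert score per mimic-model pair over valid respondents.

    Near-duplicate questions of the same pair pool into one row.  Columns:
    mimic_taxon, model_taxon, mean_score, n, sd.
    """
    if len(valid_responses) == 0:
        raise ValueError("no valid responses to score")
    melted = []
    for qid, (mimic, model) in design.testing_questions.items():
        vals = valid_responses[qid].astype(float)
        melted.append(pd.DataFrame({"mimic_taxon": mimic, "model_taxon": model,
                                    "score": vals}))
    long = pd.concat(melted, ignore_index=True)
    out = (long.groupby(["mimic_taxon", "model_taxon"], sort=True)["score"]
           .agg(mean_score="mean", n="count", sd="std")
           .reset_index())
    out["sd"] = out["sd"].fillna(0.0)
    return out
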