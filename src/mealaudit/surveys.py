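"""Scoring for the two usability instruments.

CSUQ (Computer Systems Usability Questionnaire): 19 items on a 7-point
Likert scale, *lower* scores more favorable.  Each participant's overall
score is the mean of their 19 items; the study-level score is the mean
(+/- SD) of those participant means.

USS (User Satisfaction Survey): 5 quantitative items on a 6-point scale,
*higher* more favorable; reported per question across participants.

No reverse-scored items are assumed; a ``reverse_items`` hook is
provided for instruments that need one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .records import SurveyResponses

logger = logging.getLogger(__name__)

CSUQ_N_ITEMS, CSUQ_SCALE = 19, (1, 7)
USS_N_ITEMS, USS_SCALE = 5, (1, 6)

#: Standard CSUQ subscale item groupings (1-based item numbers).
CSUQ_SUBSCALES = {
    "system usefulness": list(range(1, 9)),
    "information quality": list(range(9, 16)),
    "interface quality": list(range(16, 19)),
}

USS_QUESTIONS = [
    "How satisfied are you with the application for identifying the food provided?",
    "How satisfied are you with the application for estimating the amount of food provided?",
    "How easy was it to use the application to identify the food provided?",
    "How easy was it to use the application for estimating the amount of food provided?",
    "How much did the training help prepare you for using the app?",
]


@dataclass(frozen=True)
class SurveyScore:
    instrument: str
    item_label: str
    n: int
    mean: float
    sd: float


def _valid_vectors(
    responses: dict[str, list[int]],
    n_items: int,
    scale: tuple[int, int],
    instrument: str,
    reverse_items: Optional[Iterable[int]] = None,
) -> dict[str, np.ndarray]:
    lo, hi = scale
    reverse = set(reverse_items or ())
    out: dict[str, np.ndarray] = {}
    for pid, scores in responses.items():
        if len(scores) != n_items:
            raise ValueError(
                f"{instrument}: participant {pid}: expected {n_items} items, "
                f"got {len(scores)}"
            )
        if any(not (lo <= s <= hi) for s in scores):
            logger.warning(
                "%s: participant %s excluded (score outside %d..%d)",
                instrument, pid, lo, hi,
            )
            continue
        vec = np.array(scores, float)
        for i in reverse:
            vec[i - 1] = lo + hi - vec[i - 1]
        out[pid] = vec
    return out


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else math.nan
    return mean, sd


def score_csuq(
    responses: SurveyResponses,
    reverse_items: Optional[Iterable[int]] = None,
    include_subscales: bool = True,
) -> list[SurveyScore]:
    """Overall CSUQ score (first element) plus optional subscale scores."""
    vectors = _valid_vectors(
        responses.csuq, CSUQ_N_ITEMS, CSUQ_SCALE, "CSUQ", reverse_items
    )
    if not vectors:
        raise ValueError("CSUQ: no valid participant vectors")
    per_participant = np.array([v.mean() for v in vectors.values()])
    mean, sd = _mean_sd(per_participant)
    scores = [SurveyScore("CSUQ", "overall", len(vectors), mean, sd)]
    if include_subscales:
        for label, items in CSUQ_SUBSCALES.items():
            idx = [i - 1 for i in items]
            sub = np.array([v[idx].mean() for v in vectors.values()])
            m, s = _mean_sd(sub)
            scores.append(SurveyScore("CSUQ", label, len(vectors), m, s))
    return scores


def score_uss(responses: SurveyResponses) -> list[SurveyScore]:
    """Per-question USS mean +/- SD across participants."""
    vectors = _valid_vectors(responses.uss, USS_N_ITEMS, USS_SCALE, "USS")
    if not vectors:
        raise ValueError("USS: no valid participant vectors")
    matrix = np.stack(list(vectors.values()))
    scores = []
    for q in range(USS_N_ITEMS):
        m, s = _mean_sd(matrix[:, q])
        scores.append(SurveyScore("USS", USS_QUESTIONS[q], len(vectors), m, s))
    return scores
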