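"""The 0-10 Mediterranean-diet adherence score.

Following the Trichopoulou-style construction, each of ten components is
dichotomized at the sex-specific median of the control (reference)
population. Components considered beneficial in the Mediterranean pattern
— cereals, legumes, fruits and nuts, vegetables, fish and the MUFA/SFA
ratio — score one point at or above the median; detrimental components —
dairy, poultry, red meat and alcohol — score one point below it. The sum
ranges from 0 (minimal adherence) to 10 (maximal adherence) and is
analysed in three categories: low (0-3), medium (4-5), high (6-10).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .food_composition import SCORED_COMPONENTS

logger = logging.getLogger(__name__)

BENEFICIAL = ("cereals", "legumes", "fruits_nuts", "vegetables", "fish", "mufa_sfa_ratio")
DETRIMENTAL = ("dairy", "poultry", "red_meat", "alcohol")

SEXES = ("M", "F")
CATEGORIES = ("low", "medium", "high")


class ScoreError(ValueError):
    """Raised when the reference population or a score input is invalid."""


def control_medians(components: pd.DataFrame, subjects: pd.DataFrame) -> pd.DataFrame:
    """Sex-specific control medians for the ten scored components.

    ``components`` is the per-subject aggregate table (indexed by
    subject_id); ``subjects`` must carry ``status`` ('case'/'control') and
    ``sex`` ('M'/'F') indexed by subject_id. Controls whose MUFA/SFA ratio
    is undefined cannot be scored and are excluded before the medians are
    taken, so the reference population equals the scoreable controls.

    Returns a DataFrame indexed by component with one column per sex.
    Even-sized samples take the midpoint of the two central order
    statistics (the standard sample median).
    """
    subjects = subjects.loc[components.index]
    controls = components[(subjects["status"] == "control").to_numpy()]
    dropped = int((~controls["ratio_defined"]).sum())
    if dropped:
        logger.warning("excluding %d control(s) with undefined MUFA/SFA ratio", dropped)
        controls = controls[controls["ratio_defined"]]
    ctrl_sex = subjects.loc[controls.index, "sex"]
    table = pd.DataFrame(index=list(SCORED_COMPONENTS), columns=list(SEXES), dtype=float)
    for sex in SEXES:
        group = controls[(ctrl_sex == sex).to_numpy()]
        if group.empty:
            raise ScoreError(f"no controls of sex {sex!r}: reference medians undefined")
        table[sex] = group[list(SCORED_COMPONENTS)].median()
    return table


def categorize(total: int) -> str:
    """Map a 0-10 score to its adherence category: 0-3 low, 4-5 medium, 6-10 high."""
    if not (isinstance(total, (int, np.integer)) and 0 <= total <= 10):
        raise ScoreError(f"score total must be an integer in 0..10, got {total!r}")
    if total <= 3:
        return "low"
    if total <= 5:
        return "medium"
    return "high"


def score_subject(intake: pd.Series, medians: pd.DataFrame, sex: str) -> pd.Series:
    """Score one subject's component intakes against the medians for ``sex``.

    Ties (intake exactly at the median) always take the "at or above"
    branch: a beneficial component at the median scores 1, a detrimental
    one scores 0. Returns the ten 0/1 points plus ``total`` and
    ``category``. Subjects with an undefined ratio must be excluded by the
    caller; scoring them raises.
    """
    if "ratio_defined" in intake.index and not intake["ratio_defined"]:
        raise ScoreError(
            f"subject {intake.name!r}: MUFA/SFA ratio undefined, cannot be scored"
        )
    ref = medians[sex]
    points = {}
    for comp in BENEFICIAL:
        points[comp] = int(intake[comp] >= ref[comp])
    for comp in DETRIMENTAL:
        points[comp] = int(intake[comp] < ref[comp])
    ordered = {c: points[c] for c in SCORED_COMPONENTS}
    total = sum(ordered.values())
    return pd.Series({**ordered, "total": total, "category": categorize(total)})


def score_subjects(
    components: pd.DataFrame, subjects: pd.DataFrame, medians: pd.DataFrame
) -> pd.DataFrame:
    """Vectorized scoring of every scoreable subject.

    Subjects with an undefined MUFA/SFA ratio are dropped with a logged
    count; the result has one row per scored subject with the ten
    component points, ``total`` and ``category``.
    """
    keep = components["ratio_defined"].to_numpy()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("excluding %d subject(s) with undefined MUFA/SFA ratio", n_dropped)
    comp = components[keep]
    sex = subjects.loc[comp.index, "sex"]

    out = pd.DataFrame(index=comp.index)
    ref = medians[sex.to_numpy()].T.set_axis(comp.index)  # per-subject median row
    for c in BENEFICIAL:
        out[c] = (comp[c].to_numpy() >= ref[c].to_numpy()).astype(int)
    for c in DETRIMENTAL:
        out[c] = (comp[c].to_numpy() < ref[c].to_numpy()).astype(int)
    out = out[list(SCORED_COMPONENTS)]
    out["total"] = out.sum(axis=1)
    out["category"] = pd.Categorical(
        [categorize(int(t)) for t in out["total"]], categories=list(CATEGORIES)
    )
    return out
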