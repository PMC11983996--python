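"""End-to-end study orchestration.

One call runs the whole analysis — load (or generate) inputs, aggregate
FFQ items into score components, compute sex-specific control medians,
score every subject, compare cases and controls pair-wise, and fit crude
and adjusted conditional-logistic models for every subsite and sex
stratum — writing all tables plus a JSON run report with reproducibility
metadata (seed, config hash, exclusion tallies).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import food_composition as fc
from . import matched_analysis as ma
from . import md_score
from . import synthetic_data as sd

logger = logging.getLogger(__name__)

SUBSITE_ANALYSES = ("all", "colon", "rectum")
SEX_STRATA = ("all", "M", "F")

#: Categorical variables reported in the case/control comparison table.
COMPARISON_VARIABLES = (
    "residence", "education", "income", "smoking",
    "bmi_category", "activity", "family_history", "nsaid",
)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for context."""


def bmi_category(bmi: np.ndarray | pd.Series) -> np.ndarray:
    """WHO BMI bands: <18.5 underweight, <25 normal, <30 overweight, else obese."""
    bmi = np.asarray(bmi, dtype=float)
    out = np.empty(bmi.shape, dtype=object)
    out[bmi < 18.5] = "underweight"
    out[(bmi >= 18.5) & (bmi < 25.0)] = "normal"
    out[(bmi >= 25.0) & (bmi < 30.0)] = "overweight"
    out[bmi >= 30.0] = "obese"
    return out


def activity_category(met_minutes: np.ndarray | pd.Series) -> np.ndarray:
    """MET-minutes/week bands: <600 low, 600-3000 moderate, >=3000 high."""
    met = np.asarray(met_minutes, dtype=float)
    out = np.empty(met.shape, dtype=object)
    out[met < 600.0] = "low"
    out[(met >= 600.0) & (met < 3000.0)] = "moderate"
    out[met >= 3000.0] = "high"
    return out


def prepare_subjects(subjects: pd.DataFrame) -> pd.DataFrame:
    """Attach derived BMI and physical-activity categories."""
    out = subjects.copy()
    out["bmi_category"] = bmi_category(out["bmi"])
    out["activity"] = activity_category(out["met_minutes"])
    return out


@dataclass
class RunConfig:
    """Inputs and analysis settings for one study run.

    Exactly one of ``input_dir`` (directory with subjects.csv, intake.csv,
    fct.csv) or ``generator`` must be provided.
    """

    out_dir: str = "md_study_out"
    input_dir: str | None = None
    generator: sd.GeneratorConfig | None = None
    seed: int = 0
    subsites: tuple[str, ...] = SUBSITE_ANALYSES
    strata: tuple[str, ...] = SEX_STRATA
    adjusted_covariates: tuple[str, ...] = ma.ADJUSTED_COVARIATES
    crude_covariates: tuple[str, ...] = ma.CRUDE_COVARIATES

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.generator is None):
            raise PipelineError("provide exactly one of input_dir or generator settings")

    def digest(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # the hash identifies the analysis, not its location
        if self.generator is not None:
            payload["generator"] = yaml.safe_load(self.generator.to_yaml())
        text = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Counts, tables and diagnostics for one run; serialized to report.json."""

    config_hash: str
    seed: int
    n_loaded: int
    n_ratio_excluded: int
    n_scored: int
    n_pairs_dropped: int
    medians: pd.DataFrame
    scores: pd.DataFrame
    comparisons: pd.DataFrame
    distribution: pd.DataFrame
    or_table: pd.DataFrame
    skipped: list = field(default_factory=list)
    convergence: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "counts": {
                    "loaded": self.n_loaded,
                    "ratio_excluded": self.n_ratio_excluded,
                    "scored": self.n_scored,
                    "pairs_dropped": self.n_pairs_dropped,
                },
                "skipped_analyses": self.skipped,
                "convergence": self.convergence,
            },
            indent=2,
            sort_keys=True,
        )


def load_inputs(input_dir: str | Path):
    input_dir = Path(input_dir)
    items = fc.load_composition_table(input_dir / "fct.csv")
    intake = fc.load_intake_matrix(input_dir / "intake.csv", items)
    subjects = pd.read_csv(input_dir / "subjects.csv", dtype={"subject_id": str},
                           keep_default_na=False).set_index("subject_id")
    return subjects, intake, items


def score_distribution(scores: pd.DataFrame, subjects: pd.DataFrame) -> pd.DataFrame:
    """Case/control distribution by score category, overall and per sex.

    Percentages are within (stratum, category) across the two statuses,
    so each category row sums to 100.
    """
    joined = scores[["category"]].join(subjects[["status", "sex"]])
    rows = []
    for stratum in SEX_STRATA:
        sub = joined if stratum == "all" else joined[joined["sex"] == stratum]
        for category in md_score.CATEGORIES:
            in_cat = sub[sub["category"] == category]
            n_cases = int((in_cat["status"] == "case").sum())
            n_controls = int((in_cat["status"] == "control").sum())
            total = n_cases + n_controls
            rows.append(
                {
                    "stratum": stratum, "category": category,
                    "n_cases": n_cases, "n_controls": n_controls,
                    "pct_cases": 100.0 * n_cases / total if total else float("nan"),
                    "pct_controls": 100.0 * n_controls / total if total else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def comparison_table(subjects: pd.DataFrame) -> pd.DataFrame:
    """Table-1-style case/control comparison with McNemar tests.

    Each categorical level is compared level-vs-rest on the matched pairs
    using the discordant-pair chi-square.
    """
    pairs = _aligned_pairs(subjects)
    rows = []
    n_cases = int((subjects["status"] == "case").sum())
    n_controls = int((subjects["status"] == "control").sum())
    for var in COMPARISON_VARIABLES:
        values = subjects[var].astype(str)
        for level in sorted(values.unique()):
            case_vals = values.loc[pairs["case"]].to_numpy() == level
            ctrl_vals = values.loc[pairs["control"]].to_numpy() == level
            res = ma.mcnemar(case_vals, ctrl_vals)
            rows.append(
                {
                    "variable": var, "level": level,
                    "pct_cases": 100.0 * (values[subjects["status"] == "case"] == level).mean(),
                    "pct_controls": 100.0 * (values[subjects["status"] == "control"] == level).mean(),
                    "mcnemar_chi2": res.chi2, "mcnemar_p": res.p,
                    "defined": res.defined,
                }
            )
    table = pd.DataFrame(rows)
    table.attrs["n_cases"] = n_cases
    table.attrs["n_controls"] = n_controls
    return table


def _aligned_pairs(subjects: pd.DataFrame) -> pd.DataFrame:
    """Pair-aligned case and control subject ids (valid 1:1 pairs only)."""
    rows = []
    for pair_id, group in subjects.groupby("pair_id", sort=True):
        if len(group) != 2 or sorted(group["status"]) != ["case", "control"]:
            continue
        case_id = group.index[group["status"] == "case"][0]
        ctrl_id = group.index[group["status"] == "control"][0]
        rows.append({"pair_id": pair_id, "case": case_id, "control": ctrl_id})
    return pd.DataFrame(rows)


def run_study(config: RunConfig) -> RunReport:
    """Execute the full pipeline and write all report artifacts."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        if config.input_dir is not None:
            subjects, intake, items = load_inputs(config.input_dir)
        else:
            cohort = sd.generate_cohort(config.generator, seed=config.seed)
            subjects, intake = cohort.subjects, cohort.intake
            items = fc.items_from_frame(cohort.fct)
        subjects = prepare_subjects(subjects)
        n_loaded = len(subjects)

        stage = "aggregate"
        components = fc.aggregate_components(intake, items)
        n_excluded = int((~components["ratio_defined"]).sum())

        stage = "score"
        medians = md_score.control_medians(components, subjects)
        scores = md_score.score_subjects(components, subjects, medians)
        n_scored = len(scores)

        stage = "describe"
        distribution = score_distribution(scores, subjects)
        comparisons = comparison_table(subjects)

        stage = "fit"
        analysis = subjects.join(components[["energy_kcal_per_day"]])
        or_rows, skipped, convergence = [], [], {}
        n_dropped_overall = 0
        for subsite in config.subsites:
            for stratum in config.strata:
                label = f"{subsite}/{stratum}"
                try:
                    spec_adj = ma.ModelSpec(covariates=config.adjusted_covariates,
                                            subsite=subsite, sex=stratum)
                    sets, names, n_dropped = ma.build_sets(analysis, scores, spec_adj)
                    fit_adj = ma.fit_clogit(sets, names)
                    spec_crude = ma.ModelSpec(covariates=config.crude_covariates,
                                              subsite=subsite, sex=stratum)
                    sets_c, names_c, _ = ma.build_sets(analysis, scores, spec_crude)
                    fit_crude = ma.fit_clogit(sets_c, names_c)
                except ma.AnalysisError as exc:
                    logger.warning("analysis %s skipped: %s", label, exc)
                    skipped.append({"analysis": label, "reason": str(exc)})
                    continue
                if subsite == "all" and stratum == "all":
                    n_dropped_overall = n_dropped
                convergence[label] = {
                    "adjusted": fit_adj.converged, "crude": fit_crude.converged,
                    "flags": list(fit_adj.flags) + list(fit_crude.flags),
                    "n_sets": fit_adj.n_sets,
                }
                counts = _category_counts(sets, scores)
                or_rows.append({"subsite": subsite, "stratum": stratum,
                                "counts": counts, "crude": fit_crude, "adjusted": fit_adj})
        if not or_rows:
            raise ma.AnalysisError("every analysis cell was skipped")
        ors = ma.or_table(or_rows)
    except Exception as exc:
        # remove partial outputs so a failed run leaves no half-written report
        for leftover in out_dir.glob("*.tsv"):
            leftover.unlink()
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    report = RunReport(
        config_hash=config.digest(), seed=config.seed,
        n_loaded=n_loaded, n_ratio_excluded=n_excluded, n_scored=n_scored,
        n_pairs_dropped=n_dropped_overall,
        medians=medians, scores=scores, comparisons=comparisons,
        distribution=distribution, or_table=ors,
        skipped=skipped, convergence=convergence,
    )
    _write_report(report, out_dir)
    return report


def _category_counts(sets, scores) -> dict[str, tuple[int, int]]:
    counts = {c: [0, 0] for c in md_score.CATEGORIES}
    cat = scores["category"]
    for s in sets:
        case_id, ctrl_id = s.subject_ids
        counts[str(cat.loc[case_id])][0] += 1
        counts[str(cat.loc[ctrl_id])][1] += 1
    return {c: (v[0], v[1]) for c, v in counts.items()}


def _write_report(report: RunReport, out_dir: Path) -> None:
    header = f"# config_hash={report.config_hash} seed={report.seed}\n"

    def write_tsv(frame: pd.DataFrame, name: str, index: bool) -> None:
        path = out_dir / name
        with open(path, "w") as fh:
            fh.write(header)
            frame.to_csv(fh, sep="\t", index=index)

    write_tsv(report.medians, "medians.tsv", index=True)
    write_tsv(report.scores, "scores.tsv", index=True)
    write_tsv(report.comparisons, "table1_comparisons.tsv", index=False)
    write_tsv(report.distribution, "table3_distribution.tsv", index=False)
    write_tsv(report.or_table, "table4_or.tsv", index=False)
    (out_dir / "report.json").write_text(report.to_json() + "\n")
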