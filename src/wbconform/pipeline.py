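"""End-to-end woody-breast detection study on a cohort.

Runs the full analysis sequence: Spearman screen of the measurements
against the tactile score, stratified 70/30 training/validation split,
fitting and evaluation of the six candidate logistic models, selection of
the working model (lowest validation misclassification rate, highest
sensitivity as tie-break), refits within subgroups — strain, sex
(including the pooled "as-hatched" run), age (with the age-specific model
forms: M1+M9 at 6–7 wk, M1+M2+M3 at 8–10 wk), the 3.402 kg (7.5 lb) live
weight classes, and strain-by-weight cells — and the prediction profiler
that pushes group-mean measurements back through the selected fit.

Subgroups are split 70/30 within the subgroup (all with the study seed);
the pooled as-hatched run is exactly the global split.  A subgroup with
fewer than 5 positives, or a single response class, is recorded as skipped
rather than fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .logit import MODEL_SPECS, BinaryLogit, BinaryLogitResults, ModelSpec
from .metrics import EvalReport, evaluate_fit, spearman_screen, stratified_split
from .synthdata import CohortConfig, sample_cohort

__all__ = [
    "StudyConfig",
    "StudyReport",
    "SubgroupResult",
    "run_study",
    "profile_predictions",
    "WEIGHT_THRESHOLD_G",
]

#: live-weight class boundary: 3.402 kg = 7.5 lb
WEIGHT_THRESHOLD_G = 3402.0

_STAT_COLS = ("GenR2", "RMSE", "MAD", "MR", "TPR", "FPR", "AUC")


@dataclass(frozen=True)
class StudyConfig:
    """What to analyse and how.

    ``cohort`` is either a :class:`~wbconform.synthdata.CohortConfig` (the
    cohort is simulated) or a path to a cohort CSV.  ``seed`` drives the
    split (and the simulation, when the cohort is synthetic).
    """

    cohort: CohortConfig | str = field(default_factory=CohortConfig)
    seed: int = 0
    train_frac: float = 0.70
    specs: tuple[str, ...] = tuple(MODEL_SPECS)
    weight_threshold_g: float = WEIGHT_THRESHOLD_G
    min_positives: int = 5
    #: age-specific model forms for the by-age refits
    age_specs: dict[int, str] = field(
        default_factory=lambda: {6: "model5", 7: "model5", 8: "model1", 9: "model1", 10: "model1"}
    )

    def validate(self) -> None:
        if not self.weight_threshold_g > 0:
            raise ValueError("weight threshold must be positive")
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac must lie in (0, 1)")
        unknown = [s for s in self.specs if s not in MODEL_SPECS]
        if unknown:
            raise ValueError(f"unknown model spec(s) {unknown}")


@dataclass
class SubgroupResult:
    """One subgroup refit (or the reason it was skipped)."""

    family: str
    label: str
    n: int
    n_positive: int
    fit: BinaryLogitResults | None = None
    train_report: EvalReport | None = None
    val_report: EvalReport | None = None
    n_train: int = 0
    n_val: int = 0
    skipped_reason: str | None = None

    @property
    def skipped(self) -> bool:
        return self.skipped_reason is not None


@dataclass
class StudyReport:
    """Everything the study produces, ready for CSV export."""

    cohort: pd.DataFrame
    screen: pd.DataFrame
    train: pd.DataFrame
    validation: pd.DataFrame
    fits: dict[str, BinaryLogitResults]
    model_comparison: pd.DataFrame
    selected_model: str
    subgroups: dict[str, list[SubgroupResult]]
    profiler: pd.DataFrame
    seed: int

    def subgroup_table(self, family: str) -> pd.DataFrame:
        """Flat per-split statistics table for one subgroup family."""
        rows = []
        for res in self.subgroups[family]:
            if res.skipped:
                rows.append(
                    {"subgroup": res.label, "dataset": None, "n": res.n,
                     "skipped_reason": res.skipped_reason}
                )
                continue
            for dataset, rep, nn in (
                ("Training", res.train_report, res.n_train),
                ("Validation", res.val_report, res.n_val),
            ):
                d = {"subgroup": res.label, "dataset": dataset, "n": nn,
                     "skipped_reason": None}
                d.update({k: rep.to_dict()[k] for k in _STAT_COLS})
                rows.append(d)
        return pd.DataFrame(rows)

    def subgroup_params(self) -> pd.DataFrame:
        """Parameter estimates of every subgroup fit, long format."""
        rows = []
        for family, results in self.subgroups.items():
            for res in results:
                if res.skipped or res.fit is None:
                    continue
                fit = res.fit
                for name in fit.params.index:
                    rows.append(
                        {
                            "family": family,
                            "subgroup": res.label,
                            "model": fit.spec.name if fit.spec else "",
                            "parameter": name,
                            "estimate": fit.params[name],
                            "std_error": fit.bse[name],
                            "wald_chi2": fit.wald_chi2[name],
                            "p_value": fit.pvalues[name],
                            "odds_ratio": fit.odds_ratios[name]
                            if name != "const"
                            else np.nan,
                        }
                    )
        return pd.DataFrame(rows)


def _fit_and_eval(
    spec: ModelSpec, train: pd.DataFrame, val: pd.DataFrame
) -> tuple[BinaryLogitResults, EvalReport, EvalReport]:
    fit = BinaryLogit.from_dataframe(train, spec).fit()
    return fit, evaluate_fit(fit, train), evaluate_fit(fit, val)


def _comparison_rows(name: str, rep_tr: EvalReport, rep_va: EvalReport):
    for dataset, rep in (("Training", rep_tr), ("Validation", rep_va)):
        row = {"model": name, "dataset": dataset, "n": rep.n}
        row.update({k: rep.to_dict()[k] for k in _STAT_COLS})
        yield row


def _weight_class(df: pd.DataFrame, threshold: float) -> pd.Series:
    return pd.Series(
        np.where(df["live_weight_g"] < threshold, "<3.402", ">=3.402"),
        index=df.index,
    )


def _run_subgroup(
    family: str,
    label: str,
    subset: pd.DataFrame,
    spec: ModelSpec,
    cfg: StudyConfig,
) -> SubgroupResult:
    n_pos = int(subset["wb_binary"].sum())
    res = SubgroupResult(family=family, label=label, n=len(subset), n_positive=n_pos)
    if n_pos < cfg.min_positives:
        res.skipped_reason = f"insufficient positives ({n_pos} < {cfg.min_positives})"
        return res
    if subset["wb_binary"].nunique() < 2:
        res.skipped_reason = "single response class"
        return res
    train, val = stratified_split(subset, cfg.train_frac, seed=cfg.seed)
    if train["wb_binary"].nunique() < 2:
        res.skipped_reason = "single response class in training split"
        return res
    try:
        fit, rep_tr, rep_va = _fit_and_eval(spec, train, val)
    except ValueError as exc:
        res.skipped_reason = f"fit failed: {exc}"
        return res
    res.fit, res.train_report, res.val_report = fit, rep_tr, rep_va
    res.n_train, res.n_val = len(train), len(val)
    return res


def run_study(cfg: StudyConfig | None = None) -> StudyReport:
    """Run the full study; deterministic for a fixed config and seed."""
    from .io import read_cohort  # local import to avoid a cycle

    cfg = cfg if cfg is not None else StudyConfig()
    cfg.validate()
    if isinstance(cfg.cohort, str):
        cohort = read_cohort(cfg.cohort)
    else:
        from dataclasses import replace

        cohort = sample_cohort(replace(cfg.cohort, seed=cfg.seed))

    screen = spearman_screen(cohort)
    train, val = stratified_split(cohort, cfg.train_frac, seed=cfg.seed)

    fits: dict[str, BinaryLogitResults] = {}
    rows = []
    for name in cfg.specs:
        fit, rep_tr, rep_va = _fit_and_eval(MODEL_SPECS[name], train, val)
        fits[name] = fit
        rows.extend(_comparison_rows(name, rep_tr, rep_va))
    comparison = pd.DataFrame(rows)

    # selection: lowest validation MR, then highest validation TPR
    vrows = comparison[comparison["dataset"] == "Validation"].set_index("model")
    order = sorted(
        vrows.index, key=lambda m: (vrows.loc[m, "MR"], -vrows.loc[m, "TPR"])
    )
    selected = order[0]
    sel_spec = MODEL_SPECS[selected]

    subgroups: dict[str, list[SubgroupResult]] = {}
    subgroups["strain"] = [
        _run_subgroup("strain", strain, cohort[cohort["strain"] == strain], sel_spec, cfg)
        for strain in ("HBY", "SBY")
    ]
    subgroups["sex"] = [
        _run_subgroup("sex", sex, cohort[cohort["sex"] == sex], sel_spec, cfg)
        for sex in ("F", "M")
    ] + [_run_subgroup("sex", "As-hatched", cohort, sel_spec, cfg)]
    subgroups["age"] = [
        _run_subgroup(
            "age",
            f"{age} wk",
            cohort[cohort["age_wk"] == age],
            MODEL_SPECS[cfg.age_specs.get(age, selected)],
            cfg,
        )
        for age in sorted(cohort["age_wk"].unique())
    ]
    wclass = _weight_class(cohort, cfg.weight_threshold_g)
    subgroups["weight"] = [
        _run_subgroup("weight", label, cohort[wclass == label], sel_spec, cfg)
        for label in ("<3.402", ">=3.402")
    ]
    subgroups["strainxweight"] = [
        _run_subgroup(
            "strainxweight",
            f"{strain} {label}",
            cohort[(cohort["strain"] == strain) & (wclass == label)],
            sel_spec,
            cfg,
        )
        for strain in ("HBY", "SBY")
        for label in ("<3.402", ">=3.402")
    ]

    profiler = profile_predictions(
        fits[selected], cohort, weight_threshold_g=cfg.weight_threshold_g
    )
    return StudyReport(
        cohort=cohort,
        screen=screen,
        train=train,
        validation=val,
        fits=fits,
        model_comparison=comparison,
        selected_model=selected,
        subgroups=subgroups,
        profiler=profiler,
        seed=cfg.seed,
    )


def profile_predictions(
    fit: BinaryLogitResults,
    data: pd.DataFrame,
    weight_threshold_g: float = WEIGHT_THRESHOLD_G,
) -> pd.DataFrame:
    """Prediction profiler: group-mean predictors through the fitted model.

    For each (strain, weight class, actual status) group present in the
    data, reports the mean of each predictor of the fit, the predicted
    probabilities of both classes at those means, and the most-likely call
    (p >= 0.5).  Empty groups are simply absent.
    """
    preds = fit.predictor_names
    missing = [p for p in preds if p not in data.columns]
    if missing:
        raise ValueError(f"data lacks predictor column(s) {missing}")
    wclass = _weight_class(data, weight_threshold_g)
    status = np.where(data["wb_binary"].astype(int) == 1, "Yes", "No")
    rows = []
    grouped = data.groupby([data["strain"], wclass.rename("weight_class"), status])
    for (strain, wc, st), grp in sorted(grouped.groups.items()):
        sub = data.loc[grp]
        means = {p: float(sub[p].mean()) for p in preds}
        p_yes = float(fit.predict(pd.DataFrame([means]))[0])
        rows.append(
            {
                "strain": strain,
                "weight_class": wc,
                "actual_status": st,
                "n": len(sub),
                **means,
                "p_yes": p_yes,
                "p_no": 1.0 - p_yes,
                "most_likely": "Yes" if p_yes >= 0.5 else "No",
            }
        )
    return pd.DataFrame(rows)
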