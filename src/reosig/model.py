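"""Model/Results interface to the full discovery pipeline.

:class:`GenePairSignatureModel` is constructed from two training cohorts and
holds the screening/selection settings; :meth:`fit` runs the funnel
(age-differential gene screen → REO pair encoding → dual univariate Cox
screens → cross-cohort consistency → de-redundancy → forward-stepwise
C-index maximization) and returns a :class:`GenePairSignatureResults`
carrying the signature, per-pair hazard statistics, the funnel counts and
the selection trace.  Classification of new cohorts, survival evaluation and
Kaplan–Meier plotting hang off the results object.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    Cohort,
    PopulationFilter,
    RiskCall,
    RiskLabel,
    SURGERY_ONLY_ALL_AGES,
    SURGERY_ONLY_EOCRC,
    Signature,
    ValidationError,
)
from . import screening, selection, survival

__all__ = ["GenePairSignatureModel", "GenePairSignatureResults", "EmptyFunnelError",
           "evaluate_risk_groups"]


class EmptyFunnelError(RuntimeError):
    """A screening stage left nothing for the next stage to consume."""

    def __init__(self, stage: str, message: str | None = None) -> None:
        super().__init__(message or f"funnel stage {stage!r} produced no output")
        self.stage = stage


class GenePairSignatureModel:
    """REO gene-pair signature discovery on two training cohorts.

    Parameters
    ----------
    train_a, train_b
        Independent training cohorts containing both age strata and a
        surgery-only population with events.
    alpha_deg, alpha_cox
        Raw (uncorrected) significance thresholds of the differential-
        expression and Cox screens.
    screen_population
        Samples entering the Cox screen; default surgery-only, both strata.
    selection_population
        Samples scoring the forward-stepwise C-index; default surgery-only
        early-onset.
    ties
        Cox tie handling, ``"efron"`` (default) or ``"breslow"``.
    cindex_on
        Score samples during selection by the raw ``"votes"`` count
        (default) or the binary majority-vote ``"label"``; see
        :func:`reosig.selection.forward_stepwise`.
    """

    def __init__(
        self,
        train_a: Cohort,
        train_b: Cohort,
        *,
        alpha_deg: float = 0.05,
        alpha_cox: float = 0.05,
        screen_population: PopulationFilter = SURGERY_ONLY_ALL_AGES,
        selection_population: PopulationFilter = SURGERY_ONLY_EOCRC,
        ties: str = "efron",
        cindex_on: str = "votes",
    ) -> None:
        if train_a.name == train_b.name:
            raise ValidationError("training cohorts must have distinct names")
        self.train_a = train_a
        self.train_b = train_b
        self.alpha_deg = alpha_deg
        self.alpha_cox = alpha_cox
        self.screen_population = screen_population
        self.selection_population = selection_population
        self.ties = ties
        self.cindex_on = cindex_on

    def config(self) -> dict:
        return {
            "cohorts": [self.train_a.name, self.train_b.name],
            "alpha_deg": self.alpha_deg,
            "alpha_cox": self.alpha_cox,
            "screen_population": self.screen_population.describe(),
            "selection_population": self.selection_population.describe(),
            "ties": self.ties,
            "cindex_on": self.cindex_on,
        }

    def fit(self, raise_on_empty: bool = False) -> "GenePairSignatureResults":
        """Run the funnel.

        When a stage empties the funnel (e.g. no consistent pairs under a
        null dataset) the default is to return a results object with
        ``signature=None`` and ``status`` naming the stage; with
        ``raise_on_empty`` an :class:`EmptyFunnelError` is raised instead.
        """
        screen = screening.run_screen(
            self.train_a,
            self.train_b,
            alpha_deg=self.alpha_deg,
            alpha_cox=self.alpha_cox,
            population=self.screen_population,
            ties=self.ties,
        )
        empty_stage = None
        if len(screen.age_related) < 2:
            empty_stage = "age_related_genes"
        elif not screen.consistent:
            empty_stage = "consistent_pairs"
        elif not screen.candidates:
            empty_stage = "deredundant_pairs"
        if empty_stage is not None:
            if raise_on_empty:
                raise EmptyFunnelError(empty_stage)
            return GenePairSignatureResults(self, screen, None, None, f"empty:{empty_stage}")
        sig, trace = selection.forward_stepwise(
            screen.candidates,
            self.train_a,
            population=self.selection_population,
            score_on=self.cindex_on,
        )
        return GenePairSignatureResults(self, screen, sig, trace, "ok")


class GenePairSignatureResults:
    """Fitted signature plus diagnostics.

    ``signature`` is ``None`` when the funnel emptied before selection
    (``status`` then reads ``"empty:<stage>"``).
    """

    def __init__(self, model, screen, signature, trace, status) -> None:
        self.model = model
        self.screen = screen
        self.signature: Signature | None = signature
        self.trace = trace
        self.status: str = status

    @property
    def funnel(self) -> list[tuple[str, int]]:
        counts = list(self.screen.stage_counts)
        counts.append(("signature_pairs", self.signature.k if self.signature else 0))
        return counts

    def _require_signature(self) -> Signature:
        if self.signature is None:
            raise EmptyFunnelError(self.status.removeprefix("empty:"),
                                   "no signature was selected (empty funnel)")
        return self.signature

    def predict(self, cohort: Cohort) -> list[RiskCall]:
        """Per-sample votes and strict-majority risk label."""
        return selection.classify(cohort, self._require_signature())

    def predict_frame(self, cohort: Cohort) -> pd.DataFrame:
        calls = self.predict(cohort)
        return pd.DataFrame(
            {
                "sample_id": [c.sample_id for c in calls],
                "votes": [c.votes for c in calls],
                "k": [c.k for c in calls],
                "label": [c.label.value for c in calls],
            }
        )

    def evaluate(
        self,
        cohort: Cohort,
        population: PopulationFilter | None = None,
        covariates: Sequence[str] | None = None,
    ) -> dict:
        """Survival evaluation of the signature's risk groups on a cohort.

        See :func:`evaluate_risk_groups`; ``population`` (e.g. surgery-only
        EOCRC) restricts the evaluated samples first.
        """
        sub = population.apply(cohort) if population is not None else cohort
        calls = self.predict(sub)
        return evaluate_risk_groups(sub, calls, covariates=covariates)

    def summary(self) -> str:
        """Plain-text report: settings, funnel counts, selected pairs."""
        lines = ["REO gene-pair signature discovery", "=" * 34]
        for key, val in self.model.config().items():
            lines.append(f"{key:>22}: {val}")
        lines.append(f"{'status':>22}: {self.status}")
        lines.append("")
        lines.append("Funnel:")
        for stage, count in self.funnel:
            lines.append(f"  {stage:<28} {count}")
        if self.signature is not None:
            sig = self.signature
            lines.append("")
            lines.append(
                f"Signature: k={sig.k} pairs, rule high-risk iff {sig.threshold_rule()}, "
                f"training C-index {sig.training_cindex:.4f}"
            )
            rows = []
            for p in sig.pairs:
                row = {"gene_high": p.gene_high, "gene_low": p.gene_low}
                for cname, st in p.stats_per_cohort.items():
                    row[f"HR[{cname}]"] = round(st.hr, 3)
                    row[f"p[{cname}]"] = f"{st.p:.2e}"
                rows.append(row)
            lines.append(pd.DataFrame(rows).to_string(index=False))
        return "\n".join(lines)

    def plot_kaplan_meier(self, cohort: Cohort, population: PopulationFilter | None = None, ax=None):
        """Kaplan–Meier curves of the two risk groups on a cohort."""
        import matplotlib.pyplot as plt
        from lifelines import KaplanMeierFitter

        sub = population.apply(cohort) if population is not None else cohort
        calls = self.predict(sub)
        labels = np.array([c.label == RiskLabel.HIGH for c in calls])
        times, events = sub.times, sub.events
        if ax is None:
            _, ax = plt.subplots()
        for mask, name in ((labels, "high risk"), (~labels, "low risk")):
            if mask.any():
                KaplanMeierFitter().fit(times[mask], events[mask], label=f"{name} (n={mask.sum()})").plot_survival_function(ax=ax)
        ax.set_xlabel("time (months)")
        ax.set_ylabel("relapse-free survival")
        return ax


def _covariate_design(
    records, covariates: Sequence[str]
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Reference-coded design matrix for clinical covariates.

    Numeric-convertible covariates enter as-is; categoricals are expanded to
    indicator columns with the most frequent level as reference.  Returns
    (matrix, column names, complete-case mask).
    """
    frame = pd.DataFrame(
        {name: [r.covariates.get(name) for r in records] for name in covariates}
    )
    complete = frame.notna().all(axis=1).to_numpy()
    frame = frame[complete]
    cols: list[pd.Series] = []
    for name in covariates:
        col = frame[name]
        numeric = pd.to_numeric(col, errors="coerce")
        if numeric.notna().all():
            cols.append(numeric.rename(name))
            continue
        reference = col.value_counts().idxmax()
        for level in sorted(set(col) - {reference}):
            cols.append((col == level).astype(float).rename(f"{name}[{level} vs {reference}]"))
    if not cols:
        return np.empty((int(complete.sum()), 0)), [], complete
    design = pd.concat(cols, axis=1)
    return design.to_numpy(dtype=float), list(design.columns), complete


def evaluate_risk_groups(
    cohort: Cohort,
    calls: Sequence[RiskCall],
    covariates: Sequence[str] | None = None,
    ties: str = "efron",
) -> dict:
    """Survival and association statistics for HIGH vs LOW risk groups.

    Returns a JSON-serializable dict with group sizes, the log-rank test,
    the univariate Cox fit of the high-risk indicator (HR, 95% CI, Wald p),
    Harrell's C-index of the binary label, per-group Kaplan–Meier curves,
    and — when ``covariates`` are named — a multivariate Cox fit adjusting
    for them (complete cases, reference-coded categoricals) plus Fisher's
    exact association of the risk group with each categorical covariate.
    """
    if len(calls) != cohort.n_samples:
        raise ValidationError("one risk call per cohort sample required")
    by_id = {c.sample_id: c for c in calls}
    labels = np.array([by_id[s].label == RiskLabel.HIGH for s in cohort.sample_ids])
    times, events = cohort.times, cohort.events
    report: dict = {
        "n": int(cohort.n_samples),
        "n_high": int(labels.sum()),
        "n_low": int((~labels).sum()),
        "n_events": int(events.sum()),
    }
    report["km"] = {}
    for mask, name in ((labels, "high"), (~labels, "low")):
        if mask.any():
            curve = survival.km_estimate(times[mask], events[mask])
            report["km"][name] = {
                "event_times": curve.event_times.tolist(),
                "survival": curve.survival.tolist(),
                "at_risk": curve.at_risk.tolist(),
            }
    if labels.any() and (~labels).any() and events.sum() >= 1:
        lr = survival.logrank_test(times, events, labels)
        report["logrank"] = {"statistic": lr.statistic, "p": lr.p_value}
        fit = survival.cox_fit(labels.astype(float), times, events, ties=ties, names=("high_risk",))
        ci = fit.ci95[0]
        report["cox_univariate"] = {
            "hr": float(fit.hr[0]),
            "ci95": [float(ci[0]), float(ci[1])],
            "p": float(fit.p[0]),
            "log_hr": float(fit.coef[0]),
            "converged": fit.converged,
        }
        report["cindex"] = selection.cindex(labels.astype(float), times, events)
    else:
        report["logrank"] = None
        report["cox_univariate"] = None
        report["cindex"] = None
    if covariates:
        design, names, complete = _covariate_design(cohort.clinical, covariates)
        X = np.column_stack([labels[complete].astype(float), design])
        try:
            mfit = survival.cox_fit(
                X, times[complete], events[complete], ties=ties,
                names=("high_risk", *names),
            )
            report["cox_multivariate"] = {
                "n_complete": int(complete.sum()),
                "covariates": {
                    nm: {
                        "hr": float(h), "ci95": [float(lo), float(hi)], "p": float(p),
                    }
                    for nm, h, (lo, hi), p in zip(mfit.names, mfit.hr, mfit.ci95, mfit.p)
                },
                "converged": mfit.converged,
            }
        except ValidationError as exc:
            report["cox_multivariate"] = {"error": str(exc)}
        report["fisher"] = {}
        for name in covariates:
            vals = pd.Series([r.covariates.get(name) for r in cohort.clinical])
            if pd.to_numeric(vals, errors="coerce").notna().all():
                continue  # association tables only for categoricals
            ok = vals.notna().to_numpy()
            levels = sorted(set(vals[ok]))
            if len(levels) < 2 or len(levels) > 5:
                continue
            table = np.array(
                [
                    [(int(((vals == lv).to_numpy() & ok & m).sum())) for lv in levels]
                    for m in (labels, ~labels)
                ]
            )
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                continue
            res = survival.fisher_exact(table)
            report["fisher"][name] = {"levels": levels, "table": table.tolist(),
                                      "p": res.p_value, "method": res.method}
    return report
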