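"""Covariate selection by likelihood-ratio tests and ALDVMM class choice.

Baseline covariates are screened and selected with the same two-stage
procedure in every family: (1) a univariate screen keeps candidates
whose single-covariate likelihood-ratio test against the base model
(intercept + two time slopes + random effects) has p < 0.20; (2) a
forward selection then repeatedly adds the screened candidate with the
smallest LRT p-value against the current model while that p-value is
below 0.05.  Candidates only ever alter the fixed effects, so the LRT
is referred to a chi-square with df = number of added coefficients.

The number of ALDVMM latent classes (1 or 2 by default) is chosen by
the lowest BIC across converged fits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from dataclasses import replace
from scipy.stats import chi2

from .data import prepare_cohort
from .errors import ConvergenceError, NumericalError
from .models import FittedModel, ModelSpec, fit_model

__all__ = [
    "SelectionTrace",
    "univariate_screen",
    "forward_select",
    "select_aldvmm_classes",
]

SCREEN_ALPHA = 0.20
ENTRY_ALPHA = 0.05


@dataclass
class SelectionTrace:
    """Audit trail of the screen and forward steps."""

    screen: list[dict] = field(default_factory=list)  # candidate, lrt, df, p, kept
    forward_steps: list[dict] = field(default_factory=list)  # covariate, p_at_entry
    selected: list[str] = field(default_factory=list)
    screen_alpha: float = SCREEN_ALPHA
    entry_alpha: float = ENTRY_ALPHA

    @property
    def screened(self) -> list[str]:
        return [s["candidate"] for s in self.screen if s["kept"]]

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def log_lines(self) -> list[str]:
        lines = []
        for s in self.screen:
            verdict = "kept" if s["kept"] else ("failed" if s.get("error") else "dropped")
            lines.append(
                f"screen {s['candidate']}: LRT={s['lrt']:.3f} df={s['df']} "
                f"p={s['p']:.4g} -> {verdict}"
            )
        for s in self.forward_steps:
            lines.append(f"enter {s['covariate']}: p={s['p_at_entry']:.4g}")
        lines.append(f"final covariates: {self.selected}")
        return lines


def _lrt(ll_small: float, ll_big: float, df: int) -> tuple[float, float]:
    stat = max(2.0 * (ll_big - ll_small), 0.0)
    return stat, float(chi2.sf(stat, df))


def _fit_with(df: pd.DataFrame, base_spec: ModelSpec, covariates: Sequence[str], seed=None) -> FittedModel:
    spec = replace(base_spec, covariates=tuple(covariates))
    cohort = prepare_cohort(
        df, spec.covariates, u_min=spec.u_min, u_max=spec.u_max,
        check_range=spec.family != "lmm",
    )
    return fit_model(cohort, spec, seed=seed)


def _candidate_df(candidate) -> tuple[tuple[str, ...], int]:
    """A candidate is a column name or a tuple of columns (e.g. two BMI
    indicators entering together); df = number of added coefficients."""
    cols = (candidate,) if isinstance(candidate, str) else tuple(candidate)
    return cols, len(cols)


def univariate_screen(
    data: pd.DataFrame,
    base_spec: ModelSpec,
    candidates: Sequence,
    seed: int | None = None,
) -> SelectionTrace:
    """Stage 1: keep candidates whose univariate LRT has p < 0.20.

    ``base_spec`` should carry no baseline covariates (intercept + time
    slopes + random effects only).  Non-convergent candidate fits are
    flagged and excluded.
    """
    trace = SelectionTrace()
    base_fit = _fit_with(data, base_spec, base_spec.covariates, seed)
    for candidate in candidates:
        cols, df_add = _candidate_df(candidate)
        entry = {"candidate": "+".join(cols), "df": df_add}
        try:
            fit = _fit_with(data, base_spec, tuple(base_spec.covariates) + cols, seed)
            stat, p = _lrt(base_fit.loglik, fit.loglik, df_add)
            entry.update(lrt=stat, p=p, kept=bool(p < trace.screen_alpha), error=None)
        except (ConvergenceError, NumericalError) as exc:
            entry.update(lrt=float("nan"), p=float("nan"), kept=False, error=str(exc))
        trace.screen.append(entry)
    return trace


def forward_select(
    data: pd.DataFrame,
    base_spec: ModelSpec,
    screened: Sequence | None = None,
    trace: SelectionTrace | None = None,
    seed: int | None = None,
) -> SelectionTrace:
    """Stage 2: forward selection at p < 0.05 among screened candidates.

    Ties in p-value break deterministically by candidate order.  Returns
    the completed trace with the final covariate set.
    """
    if trace is None:
        trace = SelectionTrace()
    if screened is None:
        screened = trace.screened
    remaining = [(_candidate_df(c)) for c in screened]
    current: list[str] = list(base_spec.covariates)
    current_fit = _fit_with(data, base_spec, current, seed)
    while remaining:
        results = []
        for cols, df_add in remaining:
            try:
                fit = _fit_with(data, base_spec, tuple(current) + cols, seed)
                stat, p = _lrt(current_fit.loglik, fit.loglik, df_add)
            except (ConvergenceError, NumericalError):
                continue
            results.append((p, cols, df_add, fit))
        if not results:
            break
        best = min(results, key=lambda r: r[0])  # stable: first of ties wins
        p, cols, df_add, fit = best
        if p >= trace.entry_alpha:
            break
        current.extend(cols)
        current_fit = fit
        trace.forward_steps.append({"covariate": "+".join(cols), "p_at_entry": p})
        remaining = [r for r in remaining if r[0] != cols]
    trace.selected = [c for c in current if c not in base_spec.covariates]
    return trace


def select_aldvmm_classes(
    data: pd.DataFrame,
    spec_template: ModelSpec,
    k_values: Sequence[int] = (1, 2),
    seed: int | None = None,
) -> tuple[int | None, pd.DataFrame]:
    """Fit the mixture for each class count and keep the lowest BIC.

    Non-convergent class counts are reported in the table but excluded
    from the argmin; returns ``(chosen_k, table)``.
    """
    rows = []
    for k in k_values:
        spec = replace(spec_template, family="aldvmm", n_classes=int(k))
        try:
            fit = fit_model(data, spec, seed=seed)
            rows.append(
                {"k": int(k), "loglik": fit.loglik, "n_params": fit.n_params,
                 "bic": fit.bic, "converged": True, "error": None}
            )
        except ConvergenceError as exc:
            rows.append(
                {"k": int(k), "loglik": np.nan, "n_params": np.nan,
                 "bic": np.nan, "converged": False, "error": str(exc)}
            )
    table = pd.DataFrame(rows)
    ok = table[table["converged"]]
    chosen = int(ok.loc[ok["bic"].idxmin(), "k"]) if len(ok) else None
    return chosen, table
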