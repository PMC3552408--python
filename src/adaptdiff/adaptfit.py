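"""Local-adaptation inference from paired transplant experiments.

Three stages:

* ``differentials`` — per pair and fitness trait, the percentage difference
  between local and foreign means, 100·(local − foreign)/foreign; positive
  values indicate local adaptation.  Survival uses family-pooled
  proportions; biomass and inflorescence counts use means over survivors.
* ``origin_anova`` — fixed-effects two-way ANOVA (origin, population pair,
  origin × pair) on family means: biomass as the family mean, survival as
  the empirical logit of the family-pooled proportion, inflorescences as
  log(mean + 1).  Per-pair local-vs-foreign contrasts by LSD on the pooled
  residual, evaluated at a corrected alpha (default 0.034, accounting for
  testing three correlated fitness traits).
* ``stepwise_predict`` — forward AIC selection (AIC = n·ln(RSS/n) + 2k)
  over the six candidate predictors of the differential (log local and
  foreign population size, log distance, environmental distance, Q_ST,
  F_ST), capped at two terms because only twelve pairs are available; the
  final model is an OLS fit tested at the pair-sharing Bonferroni alpha
  (0.05/2 = 0.025).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .core import DifferentialRecord, PairExperiment, ValidationError, PREDICTOR_NAMES

__all__ = [
    "FITNESS_TRAITS",
    "CORRECTED_ALPHA",
    "REGRESSION_ALPHA",
    "OriginTestResult",
    "RegressionResult",
    "differentials",
    "origin_anova",
    "stepwise_predict",
]

FITNESS_TRAITS = ("survival", "biomass", "inflorescences")

#: alpha corrected for testing three correlated fitness traits
CORRECTED_ALPHA = 0.034
#: Bonferroni alpha for regressions on pairs sharing a home population (0.05/2)
REGRESSION_ALPHA = 0.025


@dataclass
class OriginTestResult:
    trait: str
    terms: dict[str, dict[str, float]]  # origin/pair/origin_x_pair -> {df, F, p}
    per_pair_contrasts: dict[str, dict]  # pair_id -> {delta_pct, significant, p}
    alpha: float


@dataclass
class RegressionResult:
    response_trait: str
    selected_predictors: list[str]
    coefficients: dict[str, float]
    stderrs: dict[str, float]
    r2: float
    p_model: float
    alpha_used: float
    aic_path: list[tuple[str, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# differentials
# ---------------------------------------------------------------------------


def _origin_mean(pots: pd.DataFrame, trait: str) -> float:
    if trait == "survival":
        germ = pots["germinated"].astype(bool)
        n = int(germ.sum())
        if n == 0:
            raise ValidationError("no germinated seeds for origin")
        return float(pots.loc[germ, "survived"].astype(bool).sum() / n)
    surv = pots["survived"].astype(bool)
    if not surv.any():
        raise ValidationError("no surviving plant for origin")
    return float(pots.loc[surv, trait].mean())


def differentials(
    pair: PairExperiment,
    trait: str,
    qst: float | None = None,
    fst: float | None = None,
    env_dist: float | None = None,
) -> DifferentialRecord:
    """Local-minus-foreign percentage differential for one pair and trait.

    ``delta_pct = 100 (mean_local − mean_foreign)/mean_foreign``; positive
    values mean local adaptation.  A zero foreign mean makes the ratio
    undefined: the absolute difference is reported instead with
    ``absolute=True``.  Predictors from the pair metadata (log10 population
    sizes and distance) are filled in; Q_ST, F_ST and environmental distance
    are attached when supplied.
    """
    if trait not in FITNESS_TRAITS:
        raise ValidationError(f"unknown fitness trait {trait!r}")
    by_origin = {}
    for origin in ("local", "foreign"):
        sub = pair.pots[pair.pots["origin"] == origin]
        try:
            by_origin[origin] = _origin_mean(sub, trait)
        except ValidationError as err:
            raise ValidationError(f"pair {pair.pair_id!r}, origin {origin!r}: {err}") from err
    m_local, m_foreign = by_origin["local"], by_origin["foreign"]
    if m_foreign == 0.0:
        delta, absolute = m_local - m_foreign, True
    else:
        delta, absolute = 100.0 * (m_local - m_foreign) / m_foreign, False
    predictors = {
        "log_local_N": math.log10(pair.local_N),
        "log_foreign_N": math.log10(pair.foreign_N),
        "log_dist_km": math.log10(pair.distance_km),
    }
    if env_dist is not None:
        predictors["env_dist"] = float(env_dist)
    if qst is not None:
        predictors["qst"] = float(qst)
    if fst is not None:
        predictors["fst"] = float(fst)
    return DifferentialRecord(
        pair_id=pair.pair_id, trait=trait, delta_pct=float(delta),
        predictors=predictors, absolute=absolute,
    )


# ---------------------------------------------------------------------------
# origin x pair ANOVA on family means
# ---------------------------------------------------------------------------


def _family_means(pairs: list[PairExperiment], trait: str) -> pd.DataFrame:
    """One row per (pair, origin, family_pair): transformed family-mean response.

    biomass -> mean over survivors; survival -> empirical logit
    log((s + 0.5)/(n − s + 0.5)) of the family-pooled counts;
    inflorescences -> log(mean + 1).  Family seed weight carried along for
    optional covariate adjustment.
    """
    rows = []
    for pe in pairs:
        for (fam, origin), sub in pe.pots.groupby(["family_pair", "origin"]):
            if trait == "survival":
                germ = sub["germinated"].astype(bool)
                n = int(germ.sum())
                s = int(sub.loc[germ, "survived"].astype(bool).sum())
                if n == 0:
                    raise ValidationError(
                        f"empty cell: pair {pe.pair_id!r}, origin {origin!r}, family {fam}"
                    )
                resp = math.log((s + 0.5) / (n - s + 0.5))
            else:
                surv = sub["survived"].astype(bool)
                if not surv.any():
                    raise ValidationError(
                        f"empty cell: pair {pe.pair_id!r}, origin {origin!r}, family {fam}"
                    )
                m = float(sub.loc[surv, trait].mean())
                resp = math.log(m + 1.0) if trait == "inflorescences" else m
            rows.append(
                {"pair": pe.pair_id, "origin": origin, "family_pair": fam,
                 "response": resp, "seed_weight": float(sub["seed_weight"].mean())}
            )
    return pd.DataFrame(rows)


def origin_anova(
    pairs: list[PairExperiment],
    trait: str,
    alpha: float = CORRECTED_ALPHA,
    seed_weight_covariate: bool = False,
) -> OriginTestResult:
    """Fixed-effects origin × pair ANOVA on family-mean responses.

    Per-pair local-vs-foreign contrasts use LSD with the pooled residual
    mean square, judged at the corrected ``alpha``.  When
    ``seed_weight_covariate`` is set, family means are residualized on
    family seed weight before the ANOVA (maternal-effect adjustment).
    """
    if trait not in FITNESS_TRAITS:
        raise ValidationError(f"unknown fitness trait {trait!r}")
    if len(pairs) < 1:
        raise ValidationError("no pair experiments supplied")
    fam = _family_means(pairs, trait)
    if seed_weight_covariate:
        X = sm.add_constant(fam["seed_weight"].to_numpy())
        fit = sm.OLS(fam["response"].to_numpy(), X).fit()
        fam = fam.assign(response=fit.resid)

    multi_pair = fam["pair"].nunique() > 1
    formula = (
        "response ~ C(origin) * C(pair)" if multi_pair else "response ~ C(origin)"
    )
    model = sm.OLS.from_formula(formula, data=fam).fit()
    table = sm.stats.anova_lm(model, typ=2)
    name_map = {"C(origin)": "origin", "C(pair)": "pair", "C(origin):C(pair)": "origin_x_pair"}
    terms = {}
    for raw, nice in name_map.items():
        if raw in table.index:
            row = table.loc[raw]
            terms[nice] = {"df": int(row["df"]), "F": float(row["F"]),
                           "p": float(row["PR(>F)"])}
    mse = float(table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"])
    df_resid = int(table.loc["Residual", "df"])

    contrasts: dict[str, dict] = {}
    for pe in pairs:
        sub = fam[fam["pair"] == pe.pair_id]
        m = sub.groupby("origin")["response"].agg(["mean", "count"])
        diff = float(m.loc["local", "mean"] - m.loc["foreign", "mean"])
        se = math.sqrt(mse * (1.0 / m.loc["local", "count"] + 1.0 / m.loc["foreign", "count"]))
        if se == 0.0:
            p = 0.0 if diff != 0 else 1.0
        else:
            t = diff / se
            p = 2.0 * sps.t.sf(abs(t), df_resid)
        delta = differentials(pe, trait).delta_pct
        contrasts[pe.pair_id] = {
            "delta_pct": delta,
            "significant": bool(p < alpha),
            "p": float(p),
        }
    return OriginTestResult(trait=trait, terms=terms, per_pair_contrasts=contrasts, alpha=alpha)


# ---------------------------------------------------------------------------
# stepwise regression of differentials on predictors
# ---------------------------------------------------------------------------


def _aic(rss: float, n: int, k: int) -> float:
    # Gaussian profile AIC; k counts all mean parameters including intercept
    rss = max(rss, 1e-300)
    return n * math.log(rss / n) + 2 * k


def stepwise_predict(
    records: list[DifferentialRecord],
    max_terms: int = 2,
    alpha: float = REGRESSION_ALPHA,
    predictors: tuple[str, ...] = PREDICTOR_NAMES,
    stop_on_aic: bool = True,
) -> RegressionResult:
    """Forward AIC selection of <= ``max_terms`` predictors of the differential.

    Starting from the intercept-only model, the predictor minimizing
    AIC = n·ln(RSS/n) + 2k is added while AIC decreases, stopping at
    ``max_terms``.  A candidate making the design matrix ill-conditioned
    (condition number > 1e8) is refused with a warning.  The selected model
    is refit by OLS; the overall F-test p-value is compared to ``alpha``.
    With ``stop_on_aic=False`` the best candidate is added every step up to
    ``max_terms`` regardless of AIC (``max_terms=len(predictors)`` then
    reduces to the full-model OLS fit).
    """
    if len(records) < 6:
        raise ValidationError(f"need >= 6 records for selection, got {len(records)}")
    for rec in records:
        missing = [p for p in predictors if p not in rec.predictors]
        if missing:
            raise ValidationError(f"pair {rec.pair_id!r}: missing predictors {missing}")
        if not np.isfinite(rec.delta_pct):
            raise ValidationError(f"pair {rec.pair_id!r}: non-finite differential")
    y = np.array([r.delta_pct for r in records], dtype=float)
    n = len(y)
    X_full = {p: np.array([r.predictors[p] for r in records], dtype=float) for p in predictors}

    selected: list[str] = []
    aic_path: list[tuple[str, float]] = []
    rss0 = float(((y - y.mean()) ** 2).sum())
    current_aic = _aic(rss0, n, 1)
    aic_path.append(("(intercept)", current_aic))

    def design(cols: list[str]) -> np.ndarray:
        return np.column_stack([np.ones(n)] + [X_full[c] for c in cols])

    while len(selected) < max_terms:
        best = None
        for cand in predictors:
            if cand in selected:
                continue
            X = design(selected + [cand])
            if np.linalg.cond(X) > 1e8:
                warnings.warn(
                    f"refusing predictor {cand!r}: design condition number > 1e8"
                )
                continue
            beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(((y - X @ beta) ** 2).sum())
            aic = _aic(rss, n, X.shape[1])
            if best is None or aic < best[1]:
                best = (cand, aic)
        if best is None or (stop_on_aic and best[1] >= current_aic):
            break
        selected.append(best[0])
        current_aic = best[1]
        aic_path.append(best)

    X = design(selected)
    fit = sm.OLS(y, X).fit()
    names = ["intercept"] + selected
    coefficients = dict(zip(names, map(float, fit.params)))
    stderrs = dict(zip(names, map(float, fit.bse)))
    if selected:
        r2 = float(fit.rsquared)
        p_model = float(fit.f_pvalue)
    else:
        r2, p_model = 0.0, 1.0
    return RegressionResult(
        response_trait=records[0].trait,
        selected_predictors=selected,
        coefficients=coefficients,
        stderrs=stderrs,
        r2=r2,
        p_model=p_model,
        alpha_used=alpha,
        aic_path=aic_path,
    )
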