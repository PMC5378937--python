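"""Likelihood-ratio testing of nested model variants.

Hypotheses about drug action are evaluated by constraining parameters
(point constraints such as nH = 1, removals of random effects or of the
residual-variance exponent, or freeing a block such as the pEC50-shift
parameters {nG, pA2, nS} of one drug), refitting, and referring the
objective-function difference to a chi-squared distribution.  Degrees of
freedom are bookkept automatically as the difference in free-parameter
counts between the two fits.

For variance-component nulls the true parameter lies on the boundary of
its space, where the naive chi-squared reference is conservative; the
50:50 chi-squared mixture p-value is reported alongside for df = 1
boundary tests.  Raw (uncorrected) p-values are the default across the
battery; a Bonferroni column is available behind a flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimation import FitResult, ModelSpec, fit_model
from .structural_model import ObservationRecord

logger = logging.getLogger(__name__)

__all__ = [
    "LrtResult",
    "likelihood_ratio_test",
    "run_test_battery",
    "table1_battery_rows",
    "propagate_se",
]

#: tolerance on a negative LRT statistic before it is treated as an
#: optimization failure rather than numerical noise
_NEG_STAT_TOL = 0.5


@dataclass
class LrtResult:
    """Outcome of one likelihood-ratio test of nested models."""

    description: str
    statistic: float
    df: int
    p_value: float
    p_value_mixture: float | None = None
    p_value_bonferroni: float | None = None
    interpretation: str = ""
    error: str | None = None

    def row(self) -> dict:
        return {
            "hypothesis": self.description,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "p_mixture": self.p_value_mixture,
            "interpretation": self.interpretation
            if self.error is None else f"FAILED: {self.error}",
        }


def _check_nested(full: ModelSpec, reduced: ModelSpec) -> None:
    if not set(reduced.free) <= set(full.free):
        raise ValueError(
            "models are not nested: the reduced model frees "
            f"{set(reduced.free) - set(full.free)} which the full model "
            "does not"
        )
    if not set(reduced.random_effects.targets) <= set(
        full.random_effects.targets
    ):
        raise ValueError(
            "models are not nested: reduced model carries extra etas"
        )


def likelihood_ratio_test(
    full: FitResult,
    reduced: FitResult,
    df: int | None = None,
    *,
    boundary: bool = False,
    description: str = "",
) -> LrtResult:
    """LRT of a reduced model against the full model it is nested in.

    statistic = OFV_reduced - OFV_full, floored at zero; p from the
    chi-squared upper tail with ``df`` degrees of freedom (default: the
    difference in free-parameter counts).  ``boundary=True`` adds the
    50:50 mixture p-value appropriate for a single variance constrained
    to its boundary.
    """
    _check_nested(full.model, reduced.model)
    if full.n_obs != reduced.n_obs:
        raise ValueError("full and reduced fits use different datasets")
    if df is None:
        df = full.n_params - reduced.n_params
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    stat = reduced.ofv - full.ofv
    if stat < -_NEG_STAT_TOL:
        logger.warning(
            "reduced model fits better than the full model by %.3f "
            "objective units: the full fit likely failed", -stat
        )
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df))
    p_mix = None
    if boundary and df == 1:
        p_mix = 0.5 * float(stats.chi2.sf(stat, 1)) if stat > 0 else 1.0
    return LrtResult(
        description=description, statistic=float(stat), df=int(df),
        p_value=p, p_value_mixture=p_mix,
    )


def propagate_se(se_components) -> float:
    """Gaussian error propagation for a sum or difference: sqrt(sum se^2)."""
    ses = np.asarray(list(se_components), dtype=float)
    if np.any(ses < 0):
        raise ValueError("standard errors must be >= 0")
    return float(np.sqrt((ses**2).sum()))


# ---------------------------------------------------------------------------
# the hypothesis-test battery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BatteryRow:
    name: str
    description: str
    build: "callable"
    direction: str            # "reduced" or "full"
    boundary: bool = False
    interpretation_reject: str = ""
    interpretation_keep: str = ""


def _pec50_block(spec: ModelSpec, drug: str) -> ModelSpec:
    out = spec.with_free(f"ng_{drug}", 1.0)
    out = out.with_free(f"pa2_{drug}", 3.0)
    out = out.with_free(f"ns_{drug}", 1.0)
    return out


def table1_battery_rows(base: ModelSpec) -> list[BatteryRow]:
    """The full hypothesis battery over the best-fit model structure.

    Rows are generated for whichever drugs and etas the base model
    actually carries, in the order of the published summary table:
    variance components and covariance, agonist slope and drift, per-drug
    slope and pEC50-shift hypotheses, and the residual-variance exponent.
    """
    targets = base.random_effects.targets
    rows: list[BatteryRow] = []

    if ("pec50_0" in targets and "max0" in targets
            and base.free_corr):
        i = base.random_effects.index_of("pec50_0")
        j = base.random_effects.index_of("max0")
        if (i, j) in base.free_corr or (j, i) in base.free_corr:
            rows.append(BatteryRow(
                "cov_pec50_max0", "H0: cov(eta_pec50, eta_max0) = 0",
                lambda s, i=i, j=j: s.without_corr(i, j), "reduced",
                boundary=False,
                interpretation_reject="Max and pEC50 correlate strongly",
            ))
    if "pec50_0" in targets:
        rows.append(BatteryRow(
            "omega_pec50", "H0: omega(pec50_0) = 0",
            lambda s: s.without_eta("pec50_0"), "reduced", boundary=True,
            interpretation_reject="pEC50 varies between oocytes",
        ))
    if "nh_a" in base.free:
        rows.append(BatteryRow(
            "nh_a_eq_3", "H0: nH(A) = 3",
            lambda s: s.with_fixed("nh_a", 3.0), "reduced",
            interpretation_keep="consistent with three cooperative "
                                "agonist sites",
        ))
    if "nt" in base.free:
        rows.append(BatteryRow(
            "nt_eq_0", "H0: nT = 0",
            lambda s: s.with_fixed("nt", 0.0), "reduced",
            interpretation_reject="response changes with time",
        ))
    if "nt" in targets:
        rows.append(BatteryRow(
            "omega_nt", "H0: omega(nT) = 0",
            lambda s: s.without_eta("nt"), "reduced", boundary=True,
            interpretation_reject="nT varies between oocytes",
        ))

    slope_null = {"citral": 1.0, "eucalyptol": 1.0, "linalool": 2.0}
    for drug in base.pop.drugs:
        if f"pic50_{drug}" in targets:
            rows.append(BatteryRow(
                f"omega_pic50_{drug}", f"H0: omega(pIC50 {drug}) = 0",
                lambda s, d=drug: s.without_eta(f"pic50_{d}"),
                "reduced", boundary=True,
                interpretation_reject=f"{drug} pIC50 varies between "
                                      "oocytes",
            ))
        if f"nh_{drug}" in base.free:
            null = slope_null.get(drug, 1.0)
            rows.append(BatteryRow(
                f"nh_{drug}_eq_{null:g}", f"H0: nH({drug}) = {null:g}",
                lambda s, d=drug, v=null: s.with_fixed(f"nh_{d}", v),
                "reduced",
            ))
        ng_free = f"ng_{drug}" in base.free
        ng_fixed_val = base.pop.drugs[drug].ng
        if not ng_free and ng_fixed_val == 0.0:
            rows.append(BatteryRow(
                f"{drug}_pec50_shift",
                f"H1: {{nG, pA2, nS}}({drug}) != 0",
                lambda s, d=drug: _pec50_block(s, d), "full",
                interpretation_reject=f"{drug} changes agonist pEC50",
                interpretation_keep=f"no evidence that {drug} changes "
                                    "agonist pEC50",
            ))
        elif ng_fixed_val != 0.0 or ng_free:
            def _drop_shift(s: ModelSpec, d=drug) -> ModelSpec:
                out = s.with_fixed(f"ng_{d}", 0.0)
                out = out.with_fixed(f"pa2_{d}")
                out = out.with_fixed(f"ns_{d}")
                if f"pa2_{d}" in out.random_effects.targets:
                    out = out.without_eta(f"pa2_{d}")
                return out
            rows.append(BatteryRow(
                f"ng_{drug}_eq_0", f"H0: nG({drug}) = 0",
                _drop_shift, "reduced",
                interpretation_reject=f"{drug} changes agonist pEC50",
            ))
            if f"pa2_{drug}" in targets:
                rows.append(BatteryRow(
                    f"omega_pa2_{drug}", f"H0: omega(pA2 {drug}) = 0",
                    lambda s, d=drug: s.without_eta(f"pa2_{d}"),
                    "reduced", boundary=True,
                    interpretation_reject=f"{drug} pA2 varies between "
                                          "oocytes",
                ))
            if f"ns_{drug}" in base.free:
                rows.append(BatteryRow(
                    f"ns_{drug}_eq_1", f"H0: nS({drug}) = 1",
                    lambda s, d=drug: s.with_fixed(f"ns_{d}", 1.0),
                    "reduced",
                    interpretation_reject="Schild slope differs from "
                                          "competitive antagonism",
                ))
    if "gamma" in base.free_ruv:
        rows.append(BatteryRow(
            "gamma_eq_0", "H0: gamma = 0",
            lambda s: s.with_fixed("gamma", 0.0), "reduced",
            interpretation_reject="residual variance grows with the "
                                  "current amplitude",
        ))
    return rows


def run_test_battery(
    dataset: list[ObservationRecord],
    base_model: ModelSpec,
    *,
    rows: list[str] | None = None,
    base_fit: FitResult | None = None,
    bonferroni: bool = False,
    fit_kwargs: dict | None = None,
) -> list[LrtResult]:
    """Run the hypothesis battery by refitting constrained variants.

    ``rows`` selects a named subset; a failed member fit flags its row
    and the battery continues.  ``base_fit`` allows reuse of an existing
    fit of ``base_model``.
    """
    fit_kwargs = fit_kwargs or {}
    all_rows = table1_battery_rows(base_model)
    if rows is not None:
        chosen = [r for r in all_rows if r.name in rows]
        missing = set(rows) - {r.name for r in chosen}
        if missing:
            raise KeyError(f"unknown battery rows: {sorted(missing)}")
    else:
        chosen = all_rows
    if base_fit is None:
        base_fit = fit_model(dataset, base_model, **fit_kwargs)

    results: list[LrtResult] = []
    for row in chosen:
        try:
            variant_spec = row.build(base_model)
            variant_fit = fit_model(dataset, variant_spec, **fit_kwargs)
            if row.direction == "reduced":
                full_fit, reduced_fit = base_fit, variant_fit
            else:
                full_fit, reduced_fit = variant_fit, base_fit
            res = likelihood_ratio_test(
                full_fit, reduced_fit, boundary=row.boundary,
                description=row.description,
            )
            res.interpretation = (
                row.interpretation_reject if res.p_value < 0.05
                else row.interpretation_keep
            )
            res.description = row.description
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("battery row %s failed: %s", row.name, exc)
            res = LrtResult(
                description=row.description, statistic=float("nan"),
                df=0, p_value=float("nan"), error=str(exc),
            )
        results.append(res)
    if bonferroni:
        m = len(results)
        for r in results:
            if r.error is None:
                r.p_value_bonferroni = min(1.0, r.p_value * m)
    return results
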