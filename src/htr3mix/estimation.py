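"""Maximum-likelihood estimation of the hierarchical peak-current model.

The marginal -2 log-likelihood (extended least squares, ELS) is
approximated per oocyte by the Laplace method: the inner penalized ELS
problem is minimized over each oocyte's random effects and the curvature
at the conditional mode supplies the Gaussian correction.  The outer
problem minimizes the summed contributions over all free fixed effects,
the OMEGA covariance (via log-SD / atanh-correlation or Cholesky
parameters, which keeps it positive definite), and the residual-variance
parameters.

Two objective conventions are reported: ``ofv`` drops the n*ln(2*pi)
data constant (the convention of population-modelling software), while
``ofv_full`` includes it; AIC and BIC are computed from ``ofv_full``.

A plain least-squares four-parameter-logistic fit for competition
binding curves (no random effects) is also provided.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from . import _core
from .population_model import (
    OmegaMatrix,
    RandomEffectsSpec,
    RuvParameters,
    individual_parameters,
    ruv_variance,
)
from .structural_model import (
    ObservationRecord,
    PopulationParameters,
    predict_peak,
)

logger = logging.getLogger(__name__)

LN2PI = math.log(2.0 * math.pi)

__all__ = [
    "ModelSpec",
    "FitResult",
    "inner_objective",
    "laplace_marginal",
    "fit_model",
    "standard_errors",
    "information_criteria",
    "fit_logistic_ls",
]


def _is_log_scale(name: str) -> bool:
    """Positivity-constrained parameters are optimized on the log scale."""
    if name in ("max0", "nh_a", "max_ratio_t6s", "alpha"):
        return True
    return name.startswith("nh_") or name.startswith("ns_")


@dataclass(frozen=True)
class ModelSpec:
    """Which parameters are estimated, and from which starting structure.

    ``pop`` is the fixed-effect template: free parameters take their
    start value from it, fixed parameters keep it.  ``omega`` and ``ruv``
    play the same dual start/fixed role for the random-effect covariance
    and the residual-variance model.  ``free_corr`` lists the OMEGA
    off-diagonal pairs estimated under the ``"pairs"`` structure
    (disjoint 2x2 correlation blocks); ``omega_structure="full"``
    estimates a full Cholesky factor instead.
    """

    pop: PopulationParameters
    free: tuple[str, ...]
    random_effects: RandomEffectsSpec
    omega: OmegaMatrix
    ruv: RuvParameters
    free_corr: tuple[tuple[int, int], ...] = ()
    free_ruv: tuple[str, ...] = ("alpha", "gamma")
    omega_structure: str = "pairs"
    #: eta indices whose SD is estimated; None means all of them
    free_omega_sd: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.omega.k != self.random_effects.k:
            raise ValueError("OMEGA dimension must match the eta count")
        for name in self.free:
            self.pop.get(name)  # raises KeyError for unknown names
        if len(set(self.free)) != len(self.free):
            raise ValueError("duplicate free parameter")
        for r in self.free_ruv:
            if r not in ("alpha", "gamma"):
                raise ValueError(f"unknown RUV parameter {r!r}")
        if self.omega_structure not in ("pairs", "full"):
            raise ValueError("omega_structure must be 'pairs' or 'full'")
        if self.omega_structure == "pairs":
            seen: set[int] = set()
            for i, j in self.free_corr:
                if i == j or i in seen or j in seen:
                    raise ValueError(
                        "free_corr pairs must be disjoint 2x2 blocks"
                    )
                seen.update((i, j))
        if not (self.free or self.free_ruv or self.random_effects.k):
            raise ValueError("model has no free parameters")

    # -- spec surgery (used by the hypothesis-test battery) --------------

    def with_fixed(self, name: str, value: float | None = None) -> "ModelSpec":
        """Fix a fixed effect or RUV parameter, optionally at a new value."""
        if name in ("alpha", "gamma"):
            ruv = replace(self.ruv)
            if value is not None:
                setattr(ruv, name, value)
            return replace(
                self, ruv=ruv,
                free_ruv=tuple(r for r in self.free_ruv if r != name),
            )
        pop = self.pop.copy()
        if value is not None:
            pop.set(name, value)
        return replace(
            self, pop=pop, free=tuple(f for f in self.free if f != name)
        )

    def with_free(self, name: str, start: float | None = None) -> "ModelSpec":
        """Free a fixed effect, optionally with a new start value."""
        if name in ("alpha", "gamma"):
            ruv = replace(self.ruv)
            if start is not None:
                setattr(ruv, name, start)
            free_ruv = self.free_ruv if name in self.free_ruv \
                else self.free_ruv + (name,)
            return replace(self, ruv=ruv, free_ruv=free_ruv)
        pop = self.pop.copy()
        if start is not None:
            pop.set(name, start)
        free = self.free if name in self.free else self.free + (name,)
        return replace(self, pop=pop, free=free)

    def without_eta(self, target: str) -> "ModelSpec":
        """Remove one random effect (and any correlation involving it)."""
        k = self.random_effects.k
        drop = self.random_effects.index_of(target)
        keep = [i for i in range(k) if i != drop]
        respec = RandomEffectsSpec(
            entries=tuple(
                e for i, e in enumerate(self.random_effects.entries)
                if i != drop
            )
        )
        remap = {old: new for new, old in enumerate(keep)}
        corr = tuple(
            (remap[i], remap[j]) for i, j in self.free_corr
            if i != drop and j != drop
        )
        osd = self.free_omega_sd
        if osd is not None:
            osd = tuple(remap[i] for i in osd if i != drop)
        omega = OmegaMatrix(self.omega.submatrix(np.array(keep)))
        return replace(
            self, random_effects=respec, omega=omega, free_corr=corr,
            free_omega_sd=osd,
        )

    def without_corr(self, i: int, j: int) -> "ModelSpec":
        """Fix one OMEGA covariance to zero."""
        m = self.omega.matrix.copy()
        m[i, j] = m[j, i] = 0.0
        return replace(
            self,
            omega=OmegaMatrix(m),
            free_corr=tuple(
                p for p in self.free_corr if set(p) != {i, j}
            ),
        )

    # -- parameter-vector packing ----------------------------------------

    def packing(self) -> list[tuple[str, object]]:
        """Ordered list of (kind, key) entries of the outer vector."""
        entries: list[tuple[str, object]] = [
            ("fe", name) for name in self.free
        ]
        targets = self.random_effects.targets
        if self.omega_structure == "pairs":
            osd = self.free_omega_sd if self.free_omega_sd is not None \
                else range(len(targets))
            entries += [("osd", i) for i in osd]
            entries += [("ocorr", p) for p in self.free_corr]
        else:
            k = len(targets)
            for i in range(k):
                for j in range(i + 1):
                    entries.append(("ochol", (i, j)))
        entries += [("ruv", r) for r in self.free_ruv]
        return entries

    @property
    def n_params(self) -> int:
        return len(self.packing())


def _omega_param_name(spec: ModelSpec, kind: str, key) -> str:
    targets = spec.random_effects.targets
    if kind == "osd":
        return f"omega_sd_{targets[key]}"
    if kind == "ocorr":
        i, j = key
        return f"omega_corr_{targets[i]}__{targets[j]}"
    i, j = key
    return f"omega_chol_{i}_{j}"


class _Packer:
    """Transform between the outer vector and natural-scale parameters."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.entries = spec.packing()
        self.n = len(self.entries)

    def names(self) -> list[str]:
        out = []
        for kind, key in self.entries:
            if kind == "fe":
                out.append(key)
            elif kind == "ruv":
                out.append(key)
            else:
                out.append(_omega_param_name(self.spec, kind, key))
        return out

    def encode(self) -> np.ndarray:
        spec = self.spec
        x = np.empty(self.n)
        if spec.omega_structure == "full" and spec.random_effects.k:
            L = np.linalg.cholesky(
                spec.omega.matrix
                + 1e-12 * np.eye(spec.random_effects.k)
            )
        for idx, (kind, key) in enumerate(self.entries):
            if kind == "fe":
                v = spec.pop.get(key)
                x[idx] = math.log(v) if _is_log_scale(key) else v
            elif kind == "osd":
                x[idx] = math.log(max(spec.omega.sd(key), 1e-6))
            elif kind == "ocorr":
                i, j = key
                r = spec.omega.matrix[i, j] / max(
                    spec.omega.sd(i) * spec.omega.sd(j), 1e-300
                )
                x[idx] = math.atanh(np.clip(r, -0.999, 0.999))
            elif kind == "ochol":
                i, j = key
                x[idx] = math.log(max(L[i, i], 1e-6)) if i == j else L[i, j]
            else:  # ruv
                v = getattr(spec.ruv, key)
                x[idx] = math.log(v) if key == "alpha" else v
        return x

    def bounds(self) -> list[tuple[float, float]]:
        out = []
        for kind, key in self.entries:
            if kind == "fe":
                out.append((-12.0, 12.0) if _is_log_scale(key)
                           else (-30.0, 30.0))
            elif kind == "osd":
                out.append((-7.0, 3.0))
            elif kind == "ocorr":
                out.append((-3.8, 3.8))
            elif kind == "ochol":
                i, j = key
                out.append((-7.0, 3.0) if i == j else (-20.0, 20.0))
            else:
                out.append((-7.0, 3.0) if key == "alpha" else (-5.0, 5.0))
        return out

    def decode_batch(self, X: np.ndarray):
        """Vectorized decode of a (B, n) matrix of outer vectors.

        Returns (table (B, n_slots), omega (B, k, k), alpha (B,),
        gamma (B,)) on the natural scale.
        """
        spec = self.spec
        X = np.atleast_2d(np.asarray(X, dtype=float))
        B = X.shape[0]
        tab = _core.ParamTable(tuple(spec.pop.drugs))
        table = np.tile(tab.from_population(spec.pop), (B, 1))
        k = spec.random_effects.k
        sds = np.array([
            [spec.omega.sd(i) for i in range(k)]
        ]).repeat(B, axis=0) if k else np.zeros((B, 0))
        omega = np.tile(spec.omega.matrix, (B, 1, 1)) if k \
            else np.zeros((B, 0, 0))
        alpha = np.full(B, spec.ruv.alpha)
        gamma = np.full(B, spec.ruv.gamma)
        chol_updates = []
        corr_updates = []
        for idx, (kind, key) in enumerate(self.entries):
            col = X[:, idx]
            if kind == "fe":
                table[:, tab.slot(key)] = np.exp(col) \
                    if _is_log_scale(key) else col
            elif kind == "osd":
                sds[:, key] = np.exp(col)
            elif kind == "ocorr":
                corr_updates.append((key, np.tanh(col)))
            elif kind == "ochol":
                chol_updates.append((key, col))
            elif key == "alpha":
                alpha = np.exp(col)
            else:
                gamma = col
        if k:
            if spec.omega_structure == "pairs":
                omega = np.zeros((B, k, k))
                omega[:, np.arange(k), np.arange(k)] = sds**2
                base_corr = {
                    (i, j): spec.omega.matrix[i, j]
                    / max(spec.omega.sd(i) * spec.omega.sd(j), 1e-300)
                    for i in range(k) for j in range(i)
                    if spec.omega.matrix[i, j] != 0.0
                }
                fixed_pairs = set(
                    tuple(sorted(p)) for p in spec.free_corr
                )
                for (i, j), r0 in base_corr.items():
                    if (j, i) not in fixed_pairs and \
                            (i, j) not in fixed_pairs:
                        omega[:, i, j] = omega[:, j, i] = \
                            r0 * sds[:, i] * sds[:, j]
                for (i, j), r in corr_updates:
                    omega[:, i, j] = omega[:, j, i] = \
                        r * sds[:, i] * sds[:, j]
            else:
                L = np.zeros((B, k, k))
                for (i, j), col in chol_updates:
                    L[:, i, j] = np.exp(col) if i == j else col
                omega = L @ np.transpose(L, (0, 2, 1))
        return table, omega, alpha, gamma

    def natural(self, x: np.ndarray) -> dict[str, float]:
        """One outer vector as a natural-scale estimates dict."""
        spec = self.spec
        table, omega, alpha, gamma = self.decode_batch(x[None])
        tab = _core.ParamTable(tuple(spec.pop.drugs))
        out: dict[str, float] = {}
        for kind, key in self.entries:
            if kind == "fe":
                out[key] = float(table[0, tab.slot(key)])
            elif kind == "ruv":
                out[key] = float(alpha[0] if key == "alpha" else gamma[0])
        k = spec.random_effects.k
        targets = spec.random_effects.targets
        for i in range(k):
            out[f"omega_sd_{targets[i]}"] = float(
                math.sqrt(omega[0, i, i])
            )
        pairs = spec.free_corr if spec.omega_structure == "pairs" else [
            (i, j) for i in range(k) for j in range(i)
        ]
        for i, j in pairs:
            denom = math.sqrt(omega[0, i, i] * omega[0, j, j])
            out[f"omega_corr_{targets[i]}__{targets[j]}"] = float(
                omega[0, i, j] / denom
            ) if denom > 0 else 0.0
        return out


@dataclass
class FitResult:
    """Estimates, uncertainty, objective values and diagnostics."""

    estimates: dict[str, float]
    se: dict[str, float] | None
    ofv: float
    ofv_full: float
    aic: float
    bic: float
    n_obs: int
    n_params: int
    etas: dict[str, np.ndarray]
    converged: bool
    n_iter: int
    grad_norm: float
    message: str
    model: ModelSpec
    x: np.ndarray = field(repr=False, default=None)
    n_inner_failures: int = 0

    def summary(self) -> str:
        lines = [
            f"{'parameter':<32}{'estimate':>12}{'SE':>12}",
            "-" * 56,
        ]
        for name, v in self.estimates.items():
            se = "" if not self.se or name not in self.se \
                else f"{self.se[name]:>12.4g}"
            lines.append(f"{name:<32}{v:>12.4g}{se:>12}")
        lines += [
            "-" * 56,
            f"OFV          {self.ofv:.4f}",
            f"OFV (full)   {self.ofv_full:.4f}",
            f"AIC          {self.aic:.4f}",
            f"BIC          {self.bic:.4f}",
            f"n_obs={self.n_obs}  n_params={self.n_params}  "
            f"converged={self.converged}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# reference (scalar) inner objective and single-oocyte Laplace marginal
# ---------------------------------------------------------------------------

def inner_objective(
    oocyte_data: list[ObservationRecord],
    pop: PopulationParameters,
    eta: np.ndarray,
    spec: RandomEffectsSpec,
    omega: OmegaMatrix,
    ruv: RuvParameters,
) -> float:
    """Penalized extended-least-squares objective for one oocyte.

    ``sum_obs [(y - PRED)^2 / V + ln V] + eta' Omega^-1 eta + ln det Omega``
    evaluated by the scalar structural-model path (the vectorized engine is
    validated against this reference in the test suite).
    """
    eta = np.asarray(eta, dtype=float)
    sign, logdet = np.linalg.slogdet(omega.matrix)
    if omega.k and sign <= 0:
        raise np.linalg.LinAlgError(
            "singular OMEGA: remove degenerate random effects"
        )
    ind = individual_parameters(pop, eta, spec)
    total = 0.0
    for rec in oocyte_data:
        pred = predict_peak(rec, ind)
        v = ruv_variance(pred, ruv)
        total += (rec.peak_current - pred) ** 2 / v + math.log(v)
    if omega.k:
        total += float(eta @ np.linalg.inv(omega.matrix) @ eta) + logdet
    return total


def laplace_marginal(
    oocyte_data: list[ObservationRecord],
    pop: PopulationParameters,
    spec: RandomEffectsSpec,
    omega: OmegaMatrix,
    ruv: RuvParameters,
    tol: float = 1e-8,
) -> tuple[float, np.ndarray]:
    """Laplace-approximated marginal contribution for one oocyte.

    Returns ``(contribution, eta_hat)`` where ``eta_hat`` is the
    conditional mode over the full eta vector (zeros in positions that
    cannot affect this oocyte's predictions; those components are
    marginalized exactly rather than approximated).
    """
    drug_names = tuple(pop.drugs)
    compiled = _core.compile_dataset(oocyte_data, spec, drug_names)
    if len(compiled.groups) != 1:
        raise ValueError("laplace_marginal expects a single oocyte")
    group = compiled.groups[0]
    tab = compiled.table.from_population(pop)[None]
    st = _core.assemble_instances(
        group, tab, omega.matrix[None],
        np.array([ruv.alpha]), np.array([ruv.gamma]),
    )
    sol = _core.solve_inner(st, tol=tol)
    if not bool(sol.converged[0]):
        raise RuntimeError(
            "inner optimization did not converge for this oocyte"
        )
    eta_full = np.zeros(spec.k)
    eta_full[group.active] = sol.eta[0]
    return float(sol.contribution[0]), eta_full


# ---------------------------------------------------------------------------
# outer objective and fitting
# ---------------------------------------------------------------------------

class _OuterObjective:
    def __init__(self, dataset, spec: ModelSpec, inner_tol: float = 1e-8):
        self.spec = spec
        self.packer = _Packer(spec)
        self.compiled = _core.compile_dataset(
            dataset, spec.random_effects, tuple(spec.pop.drugs)
        )
        self.inner_tol = inner_tol
        self.n_eval = 0
        self.last_inner_failures = 0

    def batch(self, X: np.ndarray) -> np.ndarray:
        """Objective at a batch of outer vectors; shape (B,)."""
        table, omega, alpha, gamma = self.packer.decode_batch(X)
        B = table.shape[0]
        total = np.zeros(B)
        failures = 0
        for group in self.compiled.groups:
            st = _core.assemble_instances(group, table, omega, alpha, gamma)
            sol = _core.solve_inner(st, tol=self.inner_tol)
            failures += int((~sol.converged).sum())
            total += sol.contribution.reshape(B, group.G).sum(axis=1)
        self.n_eval += B
        self.last_inner_failures = failures
        return np.where(np.isfinite(total), total, 1e12)

    def value(self, x: np.ndarray) -> float:
        return float(self.batch(x[None])[0])

    def value_and_grad(self, x: np.ndarray, eps: float = 1e-5):
        n = x.size
        h = eps * (1.0 + np.abs(x))
        X = np.repeat(x[None], 2 * n + 1, axis=0)
        for j in range(n):
            X[1 + 2 * j, j] += h[j]
            X[2 + 2 * j, j] -= h[j]
        f = self.batch(X)
        grad = (f[1::2] - f[2::2]) / (2.0 * h)
        return float(f[0]), grad

    def eb_etas(self, x: np.ndarray) -> tuple[dict[str, np.ndarray], int]:
        """Empirical-Bayes eta modes per oocyte at the optimum."""
        table, omega, alpha, gamma = self.packer.decode_batch(x[None])
        etas: dict[str, np.ndarray] = {}
        failures = 0
        for group in self.compiled.groups:
            st = _core.assemble_instances(group, table, omega, alpha, gamma)
            sol = _core.solve_inner(st, tol=self.inner_tol)
            failures += int((~sol.converged).sum())
            for g, oid in enumerate(group.oocyte_ids):
                full = np.zeros(self.spec.random_effects.k)
                full[group.active] = sol.eta[g]
                etas[oid] = full
        return etas, failures


def information_criteria(
    fit_or_ofv_full, n_obs: int, n_params: int
) -> tuple[float, float]:
    """AIC and BIC from the constant-inclusive objective value.

    ``AIC = OFV_full + 2 p`` and ``BIC = OFV_full + p ln n`` where
    ``OFV_full`` includes the ``n ln(2 pi)`` constant and p counts every
    free fixed effect, free OMEGA entry and free RUV parameter.
    """
    ofv_full = getattr(fit_or_ofv_full, "ofv_full", fit_or_ofv_full)
    aic = ofv_full + 2.0 * n_params
    bic = ofv_full + n_params * math.log(n_obs)
    return aic, bic


def fit_model(
    dataset: list[ObservationRecord],
    model: ModelSpec,
    start: dict[str, float] | None = None,
    *,
    compute_se: bool = False,
    outer_maxiter: int = 500,
    outer_ftol: float = 1e-11,
    outer_gtol: float = 1e-6,
    fd_eps: float = 1e-5,
    inner_tol: float = 1e-8,
    n_restarts: int = 3,
    polish: bool = True,
) -> FitResult:
    """Fit the hierarchical model by Laplace extended least squares.

    The outer problem runs L-BFGS-B on transformed parameters with
    central-finite-difference gradients (all difference points evaluated
    in one vectorized pass).  On failure the fit restarts from up to
    ``n_restarts`` deterministically perturbed start vectors.  ``start``
    may override any free parameter by name (including ``omega_sd_*``,
    ``omega_corr_*__*``, ``alpha`` and ``gamma``).
    """
    spec = _apply_start(model, start) if start else model
    obj = _OuterObjective(dataset, spec, inner_tol=inner_tol)
    packer = obj.packer
    x0 = packer.encode()
    if not np.all(np.isfinite(x0)):
        bad = [packer.names()[i] for i in
               np.flatnonzero(~np.isfinite(x0))]
        raise ValueError(f"non-finite start value for {bad}")
    f0 = obj.value(x0)
    if not np.isfinite(f0) or f0 >= 1e12:
        raise ValueError(
            "objective is non-finite at the start values; check the "
            "start for: " + ", ".join(packer.names())
        )

    bounds = packer.bounds()
    rng = np.random.default_rng(0)
    best = None
    x_try = x0
    for attempt in range(n_restarts + 1):
        res = optimize.minimize(
            lambda x: obj.value_and_grad(x, eps=fd_eps),
            x_try,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options=dict(
                maxiter=outer_maxiter, ftol=outer_ftol,
                gtol=outer_gtol, maxcor=30,
            ),
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success and np.isfinite(res.fun):
            break
        logger.info(
            "outer optimization attempt %d stopped early (%s); "
            "restarting from a perturbed start", attempt + 1,
            res.message,
        )
        x_try = x0 + 0.1 * rng.standard_normal(x0.size)
    res = best
    converged = bool(res.success and np.isfinite(res.fun))
    if polish and not converged and np.isfinite(res.fun):
        # the marginal objective has gradient kinks where an oocyte's
        # conditional modes swap; a derivative-free polish decides
        # whether the stop was a numerical artifact of such a kink
        pol = optimize.minimize(
            obj.value, res.x, method="Nelder-Mead",
            options=dict(maxfev=15 * res.x.size, xatol=1e-6,
                         fatol=1e-9),
        )
        if pol.fun <= res.fun:
            improvement = res.fun - pol.fun
            res = pol
            converged = bool(improvement < 0.05)
            logger.info(
                "derivative-free polish improved the objective by "
                "%.3g; converged=%s", improvement, converged,
            )

    estimates = packer.natural(res.x)
    etas, inner_failures = obj.eb_etas(res.x)
    n_obs = obj.compiled.n_obs_total
    p = packer.n
    ofv = float(res.fun)
    ofv_full = ofv + n_obs * LN2PI
    aic, bic = information_criteria(ofv_full, n_obs, p)
    jac = getattr(res, "jac", None)
    grad_norm = float(np.abs(jac).max()) if jac is not None \
        else float("nan")
    fit = FitResult(
        estimates=estimates, se=None,
        ofv=ofv, ofv_full=ofv_full, aic=aic, bic=bic,
        n_obs=n_obs, n_params=p, etas=etas,
        converged=converged, n_iter=int(res.nit),
        grad_norm=grad_norm,
        message=str(res.message), model=spec, x=res.x,
        n_inner_failures=inner_failures,
    )
    if compute_se:
        if converged:
            fit.se = standard_errors(fit, dataset, spec, _objective=obj)
        else:
            logger.warning("fit not converged: standard errors withheld")
    return fit


def _apply_start(model: ModelSpec, start: dict[str, float]) -> ModelSpec:
    pop = model.pop.copy()
    omega = model.omega.matrix.copy()
    ruv = replace(model.ruv)
    k = model.random_effects.k
    targets = model.random_effects.targets
    sds = np.sqrt(np.diag(omega))
    corr = omega / np.outer(np.maximum(sds, 1e-300),
                            np.maximum(sds, 1e-300))
    for name, value in start.items():
        if name in ("alpha", "gamma"):
            setattr(ruv, name, value)
        elif name.startswith("omega_sd_"):
            sds[targets.index(name[len("omega_sd_"):])] = value
        elif name.startswith("omega_corr_"):
            t1, t2 = name[len("omega_corr_"):].split("__")
            i, j = targets.index(t1), targets.index(t2)
            corr[i, j] = corr[j, i] = value
        else:
            pop.set(name, value)
    if k:
        np.fill_diagonal(corr, 1.0)
        omega = corr * np.outer(sds, sds)
    return replace(
        model, pop=pop, ruv=ruv,
        omega=OmegaMatrix(omega) if k else model.omega,
    )


def standard_errors(
    fit: FitResult,
    dataset: list[ObservationRecord],
    model: ModelSpec,
    *,
    h: float = 1e-3,
    _objective: "_OuterObjective | None" = None,
) -> dict[str, float] | None:
    """Delta-method SEs from the curvature of the marginal objective.

    The Hessian of half the objective (the -2 log-likelihood scale) is
    computed by central finite differences on the transformed parameters
    and inverted; non-positive-definite curvature withholds the SEs.
    """
    if fit.x is None or not fit.converged:
        logger.warning("standard errors withheld: no converged optimum")
        return None
    obj = _objective or _OuterObjective(dataset, fit.model)
    packer = obj.packer
    x = fit.x
    n = x.size
    hs = h * (1.0 + np.abs(x))
    points = [x]
    for i in range(n):
        for si in (1, -1):
            p = x.copy()
            p[i] += si * hs[i]
            points.append(p)
    for i in range(n):
        for j in range(i):
            for si, sj in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                p = x.copy()
                p[i] += si * hs[i]
                p[j] += sj * hs[j]
                points.append(p)
    X = np.array(points)
    f = np.empty(X.shape[0])
    chunk = max(1, int(2e6 / max(obj.compiled.n_obs_total, 1)))
    for lo in range(0, X.shape[0], chunk):
        f[lo:lo + chunk] = obj.batch(X[lo:lo + chunk])
    H = np.empty((n, n))
    f0 = f[0]
    for i in range(n):
        fp, fm = f[1 + 2 * i], f[2 + 2 * i]
        H[i, i] = (fp + fm - 2.0 * f0) / hs[i] ** 2
    pos = 1 + 2 * n
    for i in range(n):
        for j in range(i):
            fpp, fpm, fmp, fmm = f[pos:pos + 4]
            pos += 4
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (
                4.0 * hs[i] * hs[j]
            )
    H *= 0.5  # curvature of -log-likelihood = half the -2LL objective
    try:
        w = np.linalg.eigvalsh(H)
        if w.min() <= 0:
            raise np.linalg.LinAlgError
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        logger.warning(
            "curvature matrix not positive definite: SEs withheld"
        )
        return None
    se_x = np.sqrt(np.diag(cov))
    # delta method back to the natural scale
    out: dict[str, float] = {}
    names = packer.names()
    nat = packer.natural(x)
    for idx, (kind, key) in enumerate(packer.entries):
        name = names[idx]
        if kind == "fe":
            scale = abs(nat[key]) if _is_log_scale(key) else 1.0
        elif kind == "osd":
            scale = nat[name]
        elif kind == "ocorr":
            r = nat[name]
            scale = 1.0 - r * r
        elif kind == "ruv":
            scale = nat[key] if key == "alpha" else 1.0
        else:  # ochol: report on the transformed scale
            scale = 1.0
        out[name] = float(se_x[idx] * scale)
    return out


# ---------------------------------------------------------------------------
# plain logistic least squares (competition binding curves)
# ---------------------------------------------------------------------------

def fit_logistic_ls(
    x: np.ndarray,
    y: np.ndarray,
    *,
    decreasing: bool = True,
) -> tuple[float, float, float, float]:
    """Least-squares four-parameter logistic fit of a binding curve.

    Fits ``y = bottom + (top - bottom) / (1 + (x / XC50)^nh)`` (the
    decreasing, competition orientation by default) and returns
    ``(pxc50, nh, top, bottom)`` with ``pxc50 = -log10(XC50)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x[x > 0]).size < 4:
        raise ValueError("need at least 4 distinct positive concentrations")
    span = y.max() - y.min()
    if span <= 1e-12 * max(abs(y).max(), 1.0):
        raise ValueError("degenerate (flat) response data")

    sign = 1.0 if decreasing else -1.0
    pos = x > 0

    def model(theta):
        pxc50, lognh, top, bottom = theta
        nh = math.exp(lognh)
        z = nh * _core.LN10 * (np.log10(x[pos]) + pxc50)
        frac = 1.0 / (1.0 + np.exp(np.clip(sign * z, -60.0, 60.0)))
        pred = np.empty_like(y)
        pred[pos] = bottom + (top - bottom) * frac
        pred[~pos] = top if decreasing else bottom
        return pred

    theta0 = np.array([
        -np.log10(np.median(x[pos])), 0.0, y.max(), y.min()
    ])
    res = optimize.least_squares(
        lambda t: model(t) - y, theta0, method="lm", max_nfev=10000
    )
    pxc50, lognh, top, bottom = res.x
    return float(pxc50), float(math.exp(lognh)), float(top), float(bottom)
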