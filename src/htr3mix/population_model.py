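"""Population level of the hierarchical model.

Per-oocyte random effects (eta) perturb selected fixed effects either
additively or multiplicatively (``exp(eta)``), with a joint Gaussian
distribution whose covariance is the OMEGA matrix.  The residual
unexplained variance (RUV) around each prediction is a power function of
the prediction, ``RUV = alpha^2 * PRED^gamma``, spanning the constant
(gamma = 0), proportional-variance (gamma = 1) and constant-CV
(gamma = 2) error models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structural_model import IndividualParameters, PopulationParameters

__all__ = [
    "RandomEffectsSpec",
    "OmegaMatrix",
    "RuvParameters",
    "PAPER_RANDOM_EFFECTS",
    "individual_parameters",
    "ruv_variance",
    "omega_correlation",
]

#: floor applied to PRED inside the residual-variance model (microamps).
#: PRED = 0 (zero agonist) would give zero variance and an unbounded
#: likelihood; observations at [A] = 0 are not part of the fitted design.
RUV_PRED_FLOOR = 1e-4

ADDITIVE = "additive"
EXPONENTIAL = "exponential"


@dataclass(frozen=True)
class RandomEffectsSpec:
    """Ordered mapping eta_i -> (target fixed effect, transform).

    ``entries`` is a tuple of ``(parameter_name, transform)`` pairs where
    transform is ``"additive"`` (par + eta) or ``"exponential"``
    (par * exp(eta)).  Order defines the eta index used throughout.
    """

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        names = [t for t, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("random-effect targets must be unique")
        for _, transform in self.entries:
            if transform not in (ADDITIVE, EXPONENTIAL):
                raise ValueError(f"unknown transform {transform!r}")

    @property
    def k(self) -> int:
        return len(self.entries)

    @property
    def targets(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.entries)

    def index_of(self, target: str) -> int:
        return self.targets.index(target)


#: Random-effect configuration of the oocyte study: etas on agonist pEC50
#: (additive), Max0 (exponential), eucalyptol pA2 and pIC50, citral and
#: linalool pIC50, and the time-drift slope nT (all additive).
PAPER_RANDOM_EFFECTS = RandomEffectsSpec(
    entries=(
        ("pec50_0", ADDITIVE),          # eta1
        ("max0", EXPONENTIAL),          # eta2
        ("pa2_eucalyptol", ADDITIVE),   # eta3
        ("pic50_eucalyptol", ADDITIVE), # eta4
        ("pic50_citral", ADDITIVE),     # eta5
        ("pic50_linalool", ADDITIVE),   # eta6
        ("nt", ADDITIVE),               # eta7
    )
)


class OmegaMatrix:
    """Symmetric positive semi-definite covariance of the random effects."""

    def __init__(self, matrix: np.ndarray, *, tol: float = 1e-10):
        m = np.asarray(matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("OMEGA must be square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("OMEGA must be symmetric")
        if np.any(np.diag(m) < 0):
            raise ValueError("OMEGA diagonal must be >= 0")
        eigvals = np.linalg.eigvalsh(m) if m.size else np.zeros(0)
        if m.size and eigvals.min() < -tol:
            raise ValueError(
                f"OMEGA is not positive semi-definite "
                f"(min eigenvalue {eigvals.min():.3e})"
            )
        self.matrix = m

    @property
    def k(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_sd_corr(
        cls, sds: np.ndarray, corr: dict[tuple[int, int], float] | None = None
    ) -> "OmegaMatrix":
        """Build from per-eta SDs and selected pairwise correlations."""
        sds = np.asarray(sds, dtype=float)
        m = np.diag(sds**2)
        for (i, j), r in (corr or {}).items():
            m[i, j] = m[j, i] = r * sds[i] * sds[j]
        return cls(m)

    def submatrix(self, idx) -> np.ndarray:
        idx = np.asarray(idx, dtype=int)
        return self.matrix[np.ix_(idx, idx)]

    def sd(self, i: int) -> float:
        return float(np.sqrt(self.matrix[i, i]))

    def __repr__(self) -> str:  # pragma: no cover
        return f"OmegaMatrix(k={self.k})"


@dataclass
class RuvParameters:
    """Residual-variance model ``RUV = alpha^2 * PRED^gamma``."""

    alpha: float
    gamma: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")


def individual_parameters(
    pop: PopulationParameters,
    eta: np.ndarray,
    spec: RandomEffectsSpec,
) -> IndividualParameters:
    """Apply one oocyte's eta vector to the population fixed effects."""
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (spec.k,):
        raise ValueError(
            f"eta has length {eta.shape}, spec expects {spec.k}"
        )
    ind = pop.copy()
    for eta_i, (target, transform) in zip(eta, spec.entries):
        value = ind.get(target)
        if transform == ADDITIVE:
            ind.set(target, value + eta_i)
        else:
            ind.set(target, value * np.exp(eta_i))
    return ind


def ruv_variance(pred, ruv: RuvParameters):
    """Residual variance around a prediction, in microamps squared.

    The prediction enters through the smooth floor
    ``sqrt(pred^2 + RUV_PRED_FLOOR^2)`` so that predictions at (or
    numerically near) zero current keep a small positive variance
    (``alpha^2 * floor^gamma`` at pred = 0) while the variance model
    stays differentiable everywhere — a hard cutoff would put a crease
    in the marginal likelihood exactly where weakly responding oocytes
    sit.  Accepts scalars or arrays.
    """
    if ruv.alpha <= 0:
        raise ValueError("alpha must be > 0")
    p = np.asarray(pred, dtype=float)
    pf = np.sqrt(p * p + RUV_PRED_FLOOR**2)
    out = ruv.alpha**2 * pf**ruv.gamma
    return float(out) if out.ndim == 0 else out


def omega_correlation(omega: OmegaMatrix, i: int, j: int) -> float:
    """Correlation between eta_i and eta_j implied by OMEGA."""
    m = omega.matrix
    denom = m[i, i] * m[j, j]
    if denom <= 0:
        raise ZeroDivisionError(
            "correlation undefined: zero variance on the diagonal"
        )
    return float(m[i, j] / np.sqrt(denom))
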