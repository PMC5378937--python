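"""Deterministic structural model of 5-HT3 receptor peak currents.

The peak inward current evoked by an agonist concentration ``[A]`` in the
presence of an insurmountable inhibitor ``[D]`` is modelled as a chain of
four components:

1. a four-parameter logistic (Hill) agonist concentration-response curve,
2. a linear drift of the maximal response with experiment time,
3. a concentration-dependent depression of the maximal response by the
   inhibitor (insurmountable block, response -> 0 at [D] -> infinity),
4. a generalized Schild shift of the agonist pEC50, with a Schild
   exponent ``n_S`` and an inhibition coefficient ``n_G`` that allow the
   shift to deviate from (n_S = n_G = 1) or be absent from (n_G = 0) the
   classical competitive case.

All concentrations are molar internally; potencies are -log10 molar
(pEC50 / pIC50 / pA2).  Currents are stored as positive magnitudes of the
inward current, in microamps.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

__all__ = [
    "Variant",
    "DrugParams",
    "ObservationRecord",
    "PopulationParameters",
    "IndividualParameters",
    "logistic_response",
    "time_scaled_max",
    "inhibited_max",
    "shifted_pec50",
    "apply_variant_shift",
    "predict_peak",
    "pxc50_to_conc",
    "conc_to_pxc50",
]

LN10 = math.log(10.0)


class Variant(str, enum.Enum):
    """Receptor variant: wild type or the pore-lining T6'S substitution."""

    WT = "WT"
    T6S = "T6S"


@dataclass(frozen=True)
class ObservationRecord:
    """One peak-current measurement with its experimental covariates.

    Attributes
    ----------
    oocyte_id : str
        Opaque identifier of the oocyte the measurement came from.
    variant : Variant
        Receptor variant expressed in that oocyte.
    time_h : float
        Hours since the start of that oocyte's experiment.
    agonist_conc : float
        5-HT concentration in molar.
    drug_id : str
        ``"none"`` or the inhibitor name (``citral`` / ``eucalyptol`` /
        ``linalool`` by default; extensible).
    drug_conc : float
        Inhibitor concentration in molar; 0 iff ``drug_id == "none"``.
    peak_current : float or None
        Magnitude of the peak inward current in microamps; ``None`` for
        simulation-template records.
    """

    oocyte_id: str
    variant: Variant = Variant.WT
    time_h: float = 0.0
    agonist_conc: float = 0.0
    drug_id: str = "none"
    drug_conc: float = 0.0
    peak_current: float | None = None

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ValueError(f"time_h must be >= 0, got {self.time_h}")
        if self.agonist_conc < 0:
            raise ValueError("agonist_conc must be >= 0")
        if self.drug_conc < 0:
            raise ValueError("drug_conc must be >= 0")
        if (self.drug_id == "none") != (self.drug_conc == 0.0):
            raise ValueError(
                f"drug_conc must be 0 iff drug_id is 'none' "
                f"(got drug_id={self.drug_id!r}, drug_conc={self.drug_conc})"
            )
        if self.peak_current is not None and self.peak_current < 0:
            raise ValueError("peak_current must be a non-negative magnitude")


@dataclass
class DrugParams:
    """Per-inhibitor fixed effects.

    ``pic50``/``nh`` govern the depression of the maximal response;
    ``pa2``/``ns``/``ng`` govern the shift of the agonist pEC50;
    ``delta_pic50`` is the additive T6'S covariate shift on pIC50.
    """

    pic50: float
    nh: float = 1.0
    pa2: float = 0.0
    ns: float = 1.0
    ng: float = 0.0
    delta_pic50: float = 0.0

    def __post_init__(self) -> None:
        if self.nh <= 0:
            raise ValueError("inhibitor Hill coefficient nh must be > 0")
        if self.ng > 0 and self.ns <= 0:
            raise ValueError("Schild coefficient ns must be > 0 when active")
        if self.ng < 0:
            raise ValueError("inhibition coefficient ng must be >= 0")


@dataclass
class PopulationParameters:
    """All fixed effects of the structural model, plus variant shifts.

    ``min0`` is representable but fixed to zero by default (no basal
    current in the fitted experiments).
    """

    max0: float
    pec50_0: float
    nh_a: float
    nt: float = 0.0
    min0: float = 0.0
    drugs: dict[str, DrugParams] = field(default_factory=dict)
    delta_pec50: float = 0.0
    max_ratio_t6s: float = 1.0

    def __post_init__(self) -> None:
        if self.max0 <= 0:
            raise ValueError("max0 must be > 0")
        if self.nh_a <= 0:
            raise ValueError("agonist Hill coefficient nh_a must be > 0")
        if self.max_ratio_t6s <= 0:
            raise ValueError("max_ratio_t6s must be > 0")

    # -- flat name-based access ------------------------------------------
    # Used by the random-effects spec, the model spec and the optimizer to
    # address any fixed effect by a single string such as "pic50_citral".

    def get(self, name: str) -> float:
        obj, attr = self._resolve(name)
        return getattr(obj, attr)

    def set(self, name: str, value: float) -> None:
        obj, attr = self._resolve(name)
        setattr(obj, attr, value)

    def _resolve(self, name: str):
        simple = {"max0", "pec50_0", "nh_a", "nt", "min0",
                  "delta_pec50", "max_ratio_t6s"}
        if name in simple:
            return self, name
        for prefix in ("pic50", "nh", "pa2", "ns", "ng", "delta_pic50"):
            if name.startswith(prefix + "_"):
                drug = name[len(prefix) + 1:]
                if drug in self.drugs:
                    return self.drugs[drug], prefix
        raise KeyError(f"unknown parameter name {name!r}")

    def copy(self) -> "PopulationParameters":
        return replace(
            self, drugs={d: replace(p) for d, p in self.drugs.items()}
        )


# An oocyte's parameters after its random effects have been applied share
# the container with the population parameters; the alias keeps call sites
# explicit about which level they are working at.
IndividualParameters = PopulationParameters


def logistic_response(
    agonist_conc: float,
    min0: float,
    max_eff: float,
    pec50: float,
    nh_a: float,
) -> float:
    """Four-parameter logistic agonist response.

    ``PRED = min0 + (max_eff - min0) * [A]^nh / ([A]^nh + EC50^nh)`` with
    ``EC50 = 10**(-pec50)``: min0 at [A] = 0, half-way at [A] = EC50, and
    max_eff as [A] -> infinity.
    """
    if agonist_conc < 0:
        raise ValueError("agonist concentration must be >= 0")
    if nh_a <= 0:
        raise ValueError("Hill coefficient must be > 0")
    if agonist_conc == 0.0:
        return min0
    # work in log space to avoid overflow at extreme concentrations
    log_ratio = nh_a * LN10 * (math.log10(agonist_conc) + pec50)
    frac = 1.0 / (1.0 + math.exp(-log_ratio))
    return min0 + (max_eff - min0) * frac


def time_scaled_max(max0: float, nt: float, time_h: float) -> float:
    """Linear drift of the maximal response: ``MaxT = max0 * (1 + nt*T)``.

    ``nt`` is the proportional change per hour (-0.1 = 10% loss per hour).
    Floored at 0: a linear drift extrapolated far beyond the fitted design
    would otherwise predict negative maximal currents.
    """
    if time_h < 0:
        raise ValueError("time must be >= 0")
    return max(max0 * (1.0 + nt * time_h), 0.0)


def inhibited_max(
    max_t: float, drug_conc: float, pic50: float, nh_d: float
) -> float:
    """Insurmountable inhibition: ``MaxD = max_t / (1 + ([D]/IC50)^nh_d)``.

    Half the drug-free maximum at [D] = IC50 = 10**(-pic50); complete block
    as [D] -> infinity.
    """
    if drug_conc < 0:
        raise ValueError("drug concentration must be >= 0")
    if nh_d <= 0:
        raise ValueError("inhibitor Hill coefficient must be > 0")
    if drug_conc == 0.0:
        return max_t
    log_q = nh_d * LN10 * (math.log10(drug_conc) + pic50)
    return max_t / (1.0 + math.exp(log_q))


def shifted_pec50(
    pec50_0: float, drug_conc: float, pa2: float, ns: float, ng: float
) -> float:
    """Generalized Schild shift of the agonist pEC50.

    ``pEC50(D) = pec50_0 - ng * log10(1 + ([D] * 10^pa2)^ns)``.  At
    ns = ng = 1 this is the classical Schild relation (EC50 ratio
    1 + [D]/KB with KB = 10**(-pa2)); at ng = 0 the drug leaves agonist
    potency unchanged.
    """
    if drug_conc < 0:
        raise ValueError("drug concentration must be >= 0")
    if ng == 0.0 or drug_conc == 0.0:
        return pec50_0
    x = drug_conc * 10.0 ** pa2
    return pec50_0 - ng * math.log10(1.0 + x ** ns)


def apply_variant_shift(
    params: PopulationParameters, variant: Variant
) -> PopulationParameters:
    """Return the parameters that apply to one receptor variant.

    WT is the identity; T6'S adds ``delta_pec50`` to the agonist pEC50,
    ``delta_pic50`` to each inhibitor pIC50, and scales ``max0`` by
    ``max_ratio_t6s``.
    """
    variant = Variant(variant)
    if variant is Variant.WT:
        return params
    out = params.copy()
    out.pec50_0 = params.pec50_0 + params.delta_pec50
    out.max0 = params.max0 * params.max_ratio_t6s
    for drug in out.drugs.values():
        drug.pic50 = drug.pic50 + drug.delta_pic50
    return out


def predict_peak(
    record: ObservationRecord, ind: IndividualParameters
) -> float:
    """Predicted peak current for one observation (symbol PRED).

    Chains the four structural components; with min0 = 0 the prediction is
    0 at zero agonist.  ``ind`` should already be at the individual level
    (random effects applied); the variant covariate shift is applied here.
    """
    p = apply_variant_shift(ind, record.variant)
    max_t = time_scaled_max(p.max0, p.nt, record.time_h)
    if record.drug_id != "none":
        try:
            d = p.drugs[record.drug_id]
        except KeyError:
            raise KeyError(
                f"no parameters for drug {record.drug_id!r}"
            ) from None
        max_eff = inhibited_max(max_t, record.drug_conc, d.pic50, d.nh)
        pec50 = shifted_pec50(p.pec50_0, record.drug_conc, d.pa2, d.ns, d.ng)
    else:
        max_eff = max_t
        pec50 = p.pec50_0
    return logistic_response(
        record.agonist_conc, p.min0, max_eff, pec50, p.nh_a
    )


def pxc50_to_conc(pxc50: float) -> float:
    """-log10 molar potency to molar concentration: ``10**(-pxc50)``."""
    if not math.isfinite(pxc50):
        raise ValueError("pxc50 must be finite")
    return 10.0 ** (-pxc50)


def conc_to_pxc50(conc: float) -> float:
    """Molar concentration to -log10 molar potency (inverse of above)."""
    if conc <= 0:
        raise ValueError("concentration must be > 0")
    return -math.log10(conc)
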