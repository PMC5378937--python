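"""Synthetic datasets with the statistical structure the analysis assumes.

The generator emulates the two-electrode voltage-clamp design of the
motivating oocyte study: 55 wild-type oocytes contributing 532 peak
currents, split between control 5-HT concentration-response curves,
5-HT curves in the presence of a fixed inhibitor concentration, and
concentration-inhibition runs at a fixed (1.7 uM) 5-HT concentration,
optionally extended by an 11-oocyte T6'S block (113 observations).
Between-oocyte variability enters through Gaussian random effects with a
Max0-pEC50 covariance, and the residual noise follows the power variance
model, so fitted parameter recovery exercises exactly the assumptions of
the estimator.

Concentration grids (uM): 5-HT 0.3-300; citral 10, 30, 100, 200, 300,
500, 600, 1000; eucalyptol 100, 200, 500, 660, 2000; linalool 100, 200,
500.  Applications are spaced 0.07 h apart (a ~1-minute application
followed by a 3-minute wash).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .population_model import (
    PAPER_RANDOM_EFFECTS,
    OmegaMatrix,
    RandomEffectsSpec,
    RuvParameters,
    individual_parameters,
    ruv_variance,
)
from .structural_model import (
    DrugParams,
    ObservationRecord,
    PopulationParameters,
    Variant,
    predict_peak,
    pxc50_to_conc,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DesignSpec",
    "AGONIST_GRID_UM",
    "DRUG_GRIDS_UM",
    "reference_parameters",
    "reference_design",
    "paper_design",
    "simulate_dataset",
    "dual_design",
    "concentration_for_inhibition",
    "simulate_dual_records",
]

#: interval between successive drug applications, hours (1 min application
#: + 3 min wash)
APPLICATION_INTERVAL_H = 0.07

AGONIST_GRID_UM = (0.3, 0.56, 1.0, 1.7, 3.0, 5.6, 10.0, 30.0, 100.0, 300.0)
DRUG_GRIDS_UM = {
    "citral": (10.0, 30.0, 100.0, 200.0, 300.0, 500.0, 600.0, 1000.0),
    "eucalyptol": (100.0, 200.0, 500.0, 660.0, 2000.0),
    "linalool": (100.0, 200.0, 500.0),
}

_UM = 1e-6


@dataclass(frozen=True)
class DesignSpec:
    """A deterministic experiment skeleton: per-oocyte template records.

    ``protocols`` maps each oocyte to its ordered application sequence
    (records without measured currents).  The seed recorded here is the
    one handed to :func:`simulate_dataset` by the pipeline; the skeleton
    itself is deterministic.
    """

    protocols: tuple[tuple[ObservationRecord, ...], ...]
    seed: int = 0

    @property
    def n_oocytes(self) -> int:
        return len(self.protocols)

    @property
    def n_observations(self) -> int:
        return sum(len(p) for p in self.protocols)


def reference_parameters() -> tuple[
    PopulationParameters, RandomEffectsSpec, OmegaMatrix, RuvParameters
]:
    """Best-fit population estimates of the oocyte study, as generative truth.

    Fixed effects: Max0 4.94 uA, pEC50 5.65, nH(A) 2.94, nT -0.13 /h;
    citral pIC50 3.92 / nH 1.34 (no pEC50 effect), eucalyptol pIC50 3.59 /
    nH 1.04 with a pEC50 shift (pA2 3.09, nS 1.70, nG 1), linalool pIC50
    3.85 / nH 2.19.  Seven random effects with SDs (0.18, 0.95, 0.18,
    0.32, 0.16, 0.05, 0.19) and a 0.87 correlation between the pEC50 and
    Max0 etas; residual model alpha 0.30, gamma 1.30.  T6'S covariate
    shifts: pEC50 +0.35, pIC50s -0.36 / -0.45 / -0.34, Max ratio 0.98.
    """
    pop = PopulationParameters(
        max0=4.94, pec50_0=5.65, nh_a=2.94, nt=-0.13, min0=0.0,
        drugs={
            "citral": DrugParams(pic50=3.92, nh=1.34, ng=0.0,
                                 delta_pic50=-0.36),
            "eucalyptol": DrugParams(pic50=3.59, nh=1.04, pa2=3.09,
                                     ns=1.70, ng=1.0, delta_pic50=-0.45),
            "linalool": DrugParams(pic50=3.85, nh=2.19, ng=0.0,
                                   delta_pic50=-0.34),
        },
        delta_pec50=0.35,
        max_ratio_t6s=0.98,
    )
    respec = PAPER_RANDOM_EFFECTS
    omega = OmegaMatrix.from_sd_corr(
        np.array([0.18, 0.95, 0.18, 0.32, 0.16, 0.05, 0.19]),
        corr={(0, 1): 0.87},
    )
    ruv = RuvParameters(alpha=0.30, gamma=1.30)
    return pop, respec, omega, ruv


def reference_model_spec(include_t6s: bool = False):
    """The full estimation structure matching :func:`reference_parameters`.

    Free fixed effects: Max0, pEC50, nH(A), nT, the three pIC50/nH pairs,
    and the eucalyptol pA2/nS (its nG fixed at 1; citral and linalool nG
    fixed at 0); all seven eta SDs plus the pEC50-Max0 correlation; both
    residual-variance parameters.  22 free parameters in total.  With
    ``include_t6s`` the four variant-shift parameters are freed as well.
    """
    from .estimation import ModelSpec

    pop, respec, omega, ruv = reference_parameters()
    free = [
        "max0", "pec50_0", "nh_a", "nt",
        "pic50_citral", "nh_citral",
        "pic50_eucalyptol", "nh_eucalyptol",
        "pa2_eucalyptol", "ns_eucalyptol",
        "pic50_linalool", "nh_linalool",
    ]
    if include_t6s:
        free += [
            "delta_pec50", "max_ratio_t6s",
            "delta_pic50_citral", "delta_pic50_eucalyptol",
            "delta_pic50_linalool",
        ]
    return ModelSpec(
        pop=pop, free=tuple(free), random_effects=respec, omega=omega,
        ruv=ruv, free_corr=((0, 1),), free_ruv=("alpha", "gamma"),
    )


def default_start_values(
    dataset: list[ObservationRecord] | None = None,
) -> dict[str, float]:
    """Neutral starting values for fitting the reference model structure.

    Deliberately coarse (round numbers; Max0 from the largest observed
    current when data are supplied) so that fits demonstrate convergence
    from a generic start rather than from the generative truth.
    """
    max0 = 5.0
    if dataset:
        max0 = max(
            (r.peak_current for r in dataset
             if r.peak_current is not None),
            default=5.0,
        ) or 5.0
    start = {
        "max0": max0, "pec50_0": 5.5, "nh_a": 2.0, "nt": 0.0,
        "alpha": 0.3, "gamma": 1.0,
        "omega_sd_pec50_0": 0.3, "omega_sd_max0": 0.5,
        "omega_sd_pa2_eucalyptol": 0.2,
        "omega_sd_pic50_eucalyptol": 0.2,
        "omega_sd_pic50_citral": 0.2,
        "omega_sd_pic50_linalool": 0.1,
        "omega_sd_nt": 0.2,
        "omega_corr_pec50_0__max0": 0.0,
    }
    for drug in ("citral", "eucalyptol", "linalool"):
        start[f"pic50_{drug}"] = 3.5
        start[f"nh_{drug}"] = 1.0
    start["pa2_eucalyptol"] = 3.0
    start["ns_eucalyptol"] = 1.0
    return start


def _protocol(
    oid: str, variant: Variant, entries: list[tuple[float, str, float]]
) -> tuple[ObservationRecord, ...]:
    """Build one oocyte's protocol; entries are (agonist_uM, drug, drug_uM)."""
    return tuple(
        ObservationRecord(
            oocyte_id=oid, variant=variant,
            time_h=round(i * APPLICATION_INTERVAL_H, 6),
            agonist_conc=a_um * _UM, drug_id=drug,
            drug_conc=d_um * _UM,
        )
        for i, (a_um, drug, d_um) in enumerate(entries)
    )


def reference_design(seed: int = 0, include_t6s: bool = False) -> DesignSpec:
    """The 55-oocyte / 532-observation wild-type design (plus T6'S block).

    Allocation: 8 control oocytes with 9-point 5-HT curves (72
    observations); 28 oocytes with a 3-point drug-free curve followed by
    an 8-point 5-HT curve in the presence of one fixed inhibitor
    concentration (308 — the within-oocyte control applications are what
    separate an inhibitor-induced potency shift from that oocyte's own
    random effects); and 19 oocytes running concentration-inhibition
    series at 1.7 uM 5-HT bracketed by drug-free controls (152),
    totalling 532 exactly.  The optional T6'S block adds 11 oocytes /
    113 observations (control curves plus 2 uM 5-HT inhibition runs).
    """
    protocols: list[tuple[ObservationRecord, ...]] = []
    n = 0

    ctrl_curve = [(a, "none", 0.0) for a in AGONIST_GRID_UM if a != 1.7]
    assert len(ctrl_curve) == 9
    for i in range(8):
        protocols.append(_protocol(f"wt_ctrl_{i:02d}", Variant.WT,
                                   ctrl_curve))
    n += 8 * 9

    # control points, then the agonist curve under one inhibitor conc
    curve8 = [a for a in AGONIST_GRID_UM if a not in (0.56, 1.7)]
    assert len(curve8) == 8
    ctrl3 = [(a, "none", 0.0) for a in (1.0, 3.0, 30.0)]
    inhib_alloc = (
        [("citral", c) for c in DRUG_GRIDS_UM["citral"]]
        + [("citral", c) for c in (100.0, 300.0, 500.0)]
        + [("eucalyptol", c) for c in DRUG_GRIDS_UM["eucalyptol"]]
        + [("eucalyptol", c) for c in (500.0, 660.0, 2000.0, 2000.0)]
        + [("linalool", c) for c in DRUG_GRIDS_UM["linalool"]]
        + [("linalool", c) for c in (100.0, 200.0, 500.0, 200.0, 500.0)]
    )
    assert len(inhib_alloc) == 28
    for i, (drug, conc) in enumerate(inhib_alloc):
        entries = ctrl3 + [(a, drug, conc) for a in curve8]
        protocols.append(
            _protocol(f"wt_{drug[:3]}curve_{i:02d}", Variant.WT, entries)
        )
    n += 28 * 11

    # fixed-agonist (1.7 uM) concentration-inhibition runs
    run_alloc = (["citral"] * 8 + ["eucalyptol"] * 6 + ["linalool"] * 5)
    for i, drug in enumerate(run_alloc):
        grid = list(DRUG_GRIDS_UM[drug])
        body = [(1.7, drug, c) for c in grid]
        while len(body) < 6:              # repeat grid concentrations
            body.append((1.7, drug, grid[len(body) % len(grid)]))
        entries = ([(1.7, "none", 0.0)] + body[:6]
                   + [(1.7, "none", 0.0)])
        assert len(entries) == 8
        protocols.append(
            _protocol(f"wt_{drug[:3]}run_{i:02d}", Variant.WT, entries)
        )
    n += 19 * 8
    assert n == 532, n

    if include_t6s:
        for i in range(4):
            protocols.append(
                _protocol(f"t6s_ctrl_{i:02d}", Variant.T6S, ctrl_curve)
            )
        t6s_alloc = ["citral"] * 3 + ["eucalyptol"] * 2 + ["linalool"] * 2
        for i, drug in enumerate(t6s_alloc):
            grid = list(DRUG_GRIDS_UM[drug])
            body = [(2.0, drug, c) for c in grid]
            while len(body) < 8:
                body.append((2.0, drug, grid[len(body) % len(grid)]))
            entries = ([(2.0, "none", 0.0)] * 2 + body[:8]
                       + [(2.0, "none", 0.0)])
            protocols.append(
                _protocol(f"t6s_{drug[:3]}run_{i:02d}", Variant.T6S,
                          entries)
            )
        assert sum(len(p) for p in protocols) == 532 + 113

    return DesignSpec(protocols=tuple(protocols), seed=seed)


#: interface alias: the published study design
paper_design = reference_design


def simulate_dataset(
    design: DesignSpec,
    pop: PopulationParameters,
    spec: RandomEffectsSpec,
    omega: OmegaMatrix,
    ruv: RuvParameters,
    seed: int,
    return_etas: bool = False,
) -> list[ObservationRecord]:
    """Draw one dataset from the generative twin of the fitted model.

    Per oocyte: eta ~ MVN(0, OMEGA); per record: PRED from the structural
    model and an additive Gaussian residual with the power variance.
    Negative simulated currents are floored at zero (counted in the log).
    Byte-identical for identical seeds.  ``return_etas=True`` returns
    ``(records, etas)`` with one drawn eta vector per oocyte.
    """
    rng = np.random.default_rng(seed)
    out: list[ObservationRecord] = []
    etas: list[np.ndarray] = []
    n_floored = 0
    for protocol in design.protocols:
        eta = rng.multivariate_normal(
            np.zeros(omega.k), omega.matrix, method="svd"
        ) if omega.k else np.zeros(0)
        etas.append(eta)
        ind = individual_parameters(pop, eta, spec)
        for rec in protocol:
            pred = predict_peak(rec, ind)
            y = pred + rng.normal(0.0, math.sqrt(ruv_variance(pred, ruv)))
            if y < 0:
                n_floored += 1
                y = 0.0
            out.append(
                ObservationRecord(
                    oocyte_id=rec.oocyte_id, variant=rec.variant,
                    time_h=rec.time_h, agonist_conc=rec.agonist_conc,
                    drug_id=rec.drug_id, drug_conc=rec.drug_conc,
                    peak_current=float(y),
                )
            )
    if n_floored:
        logger.info("floored %d simulated currents at 0", n_floored)
    if return_etas:
        return out, etas
    return out


def concentration_for_inhibition(
    target: float, pic50: float, nh: float
) -> float:
    """Inhibitor concentration (molar) producing a target fractional block.

    Inverts the insurmountable-inhibition curve:
    ``[D] = IC50 * (target / (1 - target))^(1/nh)``.
    """
    if not 0.0 < target < 1.0:
        raise ValueError("target inhibition must be in (0, 1)")
    return pxc50_to_conc(pic50) * (target / (1.0 - target)) ** (1.0 / nh)


def dual_design(
    inhibition_target: float,
    seed: int = 0,
    pop: PopulationParameters | None = None,
    pairs: tuple[tuple[str, str], ...] | None = None,
    n_oocytes_per_pair: int = 6,
) -> DesignSpec:
    """Dual-application design at a supramaximal 100 uM 5-HT concentration.

    Each oocyte receives a drug-free control, each drug of its pair
    alone, and the pair together, at concentrations solved from the
    inhibition model to produce ``inhibition_target`` fractional block
    when applied alone.  Paired applications are encoded as the combined
    drug id ``"<a>+<b>"`` carrying drug A's concentration (the analysis
    layer treats combined records by their own measured inhibition).
    Raises if a solved concentration falls outside the declared grid
    range for that drug.
    """
    if pop is None:
        pop, _, _, _ = reference_parameters()
    if pairs is None:
        names = tuple(pop.drugs)
        pairs = tuple(
            (a, b) for i, a in enumerate(names) for b in names[i + 1:]
        )
    agonist = 100.0  # uM
    protocols = []
    for a, b in pairs:
        conc = {}
        for d in (a, b):
            dp = pop.drugs[d]
            c = concentration_for_inhibition(
                inhibition_target, dp.pic50, dp.nh
            )
            grid = DRUG_GRIDS_UM.get(d)
            if grid is not None and not (
                min(grid) * _UM <= c <= max(grid) * _UM
            ):
                raise ValueError(
                    f"target {inhibition_target} needs {c/_UM:.0f} uM "
                    f"{d}, outside its grid {grid}"
                )
            conc[d] = c
        for i in range(n_oocytes_per_pair):
            oid = f"dual_{a[:3]}_{b[:3]}_{i:02d}"
            entries = [
                (agonist, "none", 0.0),
                (agonist, a, conc[a] / _UM),
                (agonist, "none", 0.0),
                (agonist, b, conc[b] / _UM),
                (agonist, "none", 0.0),
                (agonist, f"{a}+{b}", conc[a] / _UM),
                (agonist, "none", 0.0),
            ]
            protocols.append(_protocol(oid, Variant.WT, entries))
    return DesignSpec(protocols=tuple(protocols), seed=seed)


def simulate_dual_records(
    n_oocytes: int,
    inhibition_a: float,
    inhibition_b: float,
    mode: str,
    noise_sd: float,
    seed: int,
    between_sd: float = 0.03,
):
    """Simulated dual-application records under one combination model.

    Per oocyte the single-drug inhibitions jitter around their targets
    (between-oocyte SD), the combined inhibition follows ``mode``
    ("allotopic" or "syntopic"), and the measured combined value adds
    Gaussian noise.  Returns a list of
    :class:`htr3mix.dual_application.DualRecord`.
    """
    from .dual_application import (
        DualRecord,
        allotopic_prediction,
        syntopic_prediction,
    )

    if mode not in ("allotopic", "syntopic"):
        raise ValueError("mode must be 'allotopic' or 'syntopic'")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_oocytes):
        ia = float(np.clip(
            inhibition_a + rng.normal(0, between_sd), 0.02, 0.97
        ))
        ib = float(np.clip(
            inhibition_b + rng.normal(0, between_sd), 0.02, 0.97
        ))
        true_ab = allotopic_prediction(ia, ib) if mode == "allotopic" \
            else syntopic_prediction(ia, ib)
        meas = float(np.clip(true_ab + rng.normal(0, noise_sd), 0.0, 1.0))
        out.append(
            DualRecord(
                oocyte_id=f"sim_{i:02d}", inhibition_a=ia,
                inhibition_b=ib, inhibition_ab_measured=meas,
                control_series=((0.0, 4.0), (0.5, 3.8)),
            )
        )
    return out
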