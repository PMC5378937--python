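"""Vectorized inner machinery for Laplace extended-least-squares fitting.

The marginal objective is a sum over oocytes of Laplace-approximated
contributions.  For each oocyte the inner problem minimizes

    g(eta) = sum_obs [ (y - PRED)^2 / V + ln V ]  +  eta' Omega_a^-1 eta
             + ln det Omega_a

over the oocyte's *active* eta subset, where V is the power residual
variance evaluated at PRED and Omega_a is the corresponding OMEGA
sub-block.  Etas that cannot influence an oocyte's predictions (random
effects on a drug the oocyte never received) are integrated out exactly
(their Gaussian factor integrates to one), which keeps the inner problem
low-dimensional.

Everything here is batched:  a single call can evaluate the inner problem
for every oocyte at every outer finite-difference point simultaneously.
Instances are laid out along a flat leading axis of size
``n_param_points * n_oocytes``; the inner Newton iteration, the
backtracking line search, and the final Hessian log-determinant are all
vectorized over that axis.  Analytic eta-gradients (chain rule through
the structural model) drive Newton steps whose Hessians are central
finite differences of that gradient.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .population_model import (
    ADDITIVE,
    EXPONENTIAL,
    RUV_PRED_FLOOR,
    RandomEffectsSpec,
)
from .structural_model import ObservationRecord, PopulationParameters, Variant

logger = logging.getLogger(__name__)

LN10 = math.log(10.0)
LN2PI = math.log(2.0 * math.pi)
_EXP_CLIP = 60.0  # exp(60) ~ 1e26: far enough into saturation for 1/(1+Q)

# eta target kinds understood by the vectorized model
K_PEC50 = 0      # additive on agonist pEC50
K_MAX0_EXP = 1   # multiplicative exp(eta) on Max0
K_MAX0_ADD = 2   # additive on Max0
K_NT = 3         # additive on the time-drift slope
K_PIC50 = 4      # additive on one drug's pIC50
K_PA2 = 5        # additive on one drug's pA2

# ---------------------------------------------------------------------------
# parameter table layout
# ---------------------------------------------------------------------------

_GLOBAL_SLOTS = (
    "max0", "pec50_0", "nh_a", "nt", "min0", "delta_pec50", "max_ratio_t6s",
)
_DRUG_SLOTS = ("pic50", "nh", "pa2", "ns", "ng", "delta_pic50")


class ParamTable:
    """Flat slot layout for every scalar fixed effect.

    Slot 0..6 are the global parameters; each drug then contributes six
    consecutive slots.  One extra trailing slot always holds 0.0 and is
    used as a dummy gather target for drug-free records.
    """

    def __init__(self, drug_names: tuple[str, ...]):
        self.drug_names = tuple(drug_names)
        self.slots: dict[str, int] = {
            name: i for i, name in enumerate(_GLOBAL_SLOTS)
        }
        base = len(_GLOBAL_SLOTS)
        for d, drug in enumerate(self.drug_names):
            for s, pref in enumerate(_DRUG_SLOTS):
                self.slots[f"{pref}_{drug}"] = base + 6 * d + s
        self.n_slots = base + 6 * len(self.drug_names)
        self.dummy = self.n_slots  # index of the appended zero column

    def slot(self, name: str) -> int:
        return self.slots[name]

    def from_population(self, pop: PopulationParameters) -> np.ndarray:
        """Flatten a parameter object into a slot vector."""
        t = np.zeros(self.n_slots)
        for name, i in self.slots.items():
            t[i] = pop.get(name)
        return t


def resolve_eta_kind(
    target: str, transform: str, drug_names: tuple[str, ...]
) -> tuple[int, int]:
    """Map a random-effect target to a vectorized kind and drug index."""
    if target == "pec50_0" and transform == ADDITIVE:
        return K_PEC50, -1
    if target == "max0":
        return (K_MAX0_EXP if transform == EXPONENTIAL else K_MAX0_ADD), -1
    if target == "nt" and transform == ADDITIVE:
        return K_NT, -1
    for prefix, kind in (("pic50_", K_PIC50), ("pa2_", K_PA2)):
        if target.startswith(prefix) and transform == ADDITIVE:
            drug = target[len(prefix):]
            if drug in drug_names:
                return kind, drug_names.index(drug)
            return kind, -2  # drug absent from the dataset: never active
    raise NotImplementedError(
        f"random effect on {target!r} ({transform}) is not supported by "
        "the fitting engine"
    )


# ---------------------------------------------------------------------------
# compiled dataset
# ---------------------------------------------------------------------------

@dataclass
class CompiledGroup:
    """Oocytes sharing one active-eta pattern, padded to a common length."""

    oocyte_ids: list[str]
    active: np.ndarray            # (ka,) indices into the full eta vector
    eta_kinds: list[tuple[int, int]]  # (kind, drug index or -1) per active eta
    n_obs: np.ndarray             # (G,)
    y: np.ndarray                 # (G, N)
    mask: np.ndarray              # (G, N) float 1/0
    T: np.ndarray                 # (G, N)
    A_l10: np.ndarray             # (G, N) log10 agonist conc (0 where A=0)
    Apos: np.ndarray              # (G, N) bool
    D_l10: np.ndarray             # (G, N)
    Dpos: np.ndarray              # (G, N) bool
    drug_idx: np.ndarray          # (G, N) int, -1 for none
    t6s: np.ndarray               # (G,) float 1/0
    dmask: np.ndarray             # (ka, G, N) float: record uses eta's drug
    # gather index arrays into the extended parameter table
    slot_pic50: np.ndarray = field(default=None)  # (G, N)
    slot_nh: np.ndarray = field(default=None)
    slot_pa2: np.ndarray = field(default=None)
    slot_ns: np.ndarray = field(default=None)
    slot_ng: np.ndarray = field(default=None)
    slot_dpic50: np.ndarray = field(default=None)

    @property
    def G(self) -> int:
        return len(self.oocyte_ids)

    @property
    def ka(self) -> int:
        return len(self.active)


@dataclass
class CompiledDataset:
    groups: list[CompiledGroup]
    table: ParamTable
    n_obs_total: int
    k: int
    oocyte_order: list[str]


def compile_dataset(
    dataset: list[ObservationRecord],
    respec: RandomEffectsSpec,
    drug_names: tuple[str, ...] | None = None,
) -> CompiledDataset:
    """Group the dataset by active-eta pattern and build padded arrays."""
    if not dataset:
        raise ValueError("dataset is empty")
    if drug_names is None:
        drug_names = tuple(
            sorted({r.drug_id for r in dataset if r.drug_id != "none"})
        )
    table = ParamTable(drug_names)

    by_oocyte: dict[str, list[ObservationRecord]] = {}
    for rec in dataset:
        by_oocyte.setdefault(rec.oocyte_id, []).append(rec)

    kinds = [
        resolve_eta_kind(t, tr, drug_names) for t, tr in respec.entries
    ]

    # active etas per oocyte
    pattern_groups: dict[tuple[int, ...], list[str]] = {}
    for oid, recs in by_oocyte.items():
        if len({r.variant for r in recs}) > 1:
            raise ValueError(f"oocyte {oid!r} mixes receptor variants")
        drugs_here = {
            drug_names.index(r.drug_id)
            for r in recs
            if r.drug_id != "none"
        }
        act = tuple(
            j
            for j, (kind, di) in enumerate(kinds)
            if di == -1 or di in drugs_here
        )
        pattern_groups.setdefault(act, []).append(oid)

    # covariance-block safety: exact marginalization of inactive etas needs
    # OMEGA to be block-separable between active and inactive sets; this is
    # checked later against the actual matrix in the assembler.

    groups = []
    n_total = 0
    for act, oids in pattern_groups.items():
        ooc_recs = [by_oocyte[o] for o in oids]
        n_obs = np.array([len(r) for r in ooc_recs])
        N = int(n_obs.max())
        G = len(oids)

        def padded(fn, fill=0.0):
            out = np.full((G, N), fill, dtype=float)
            for g, recs in enumerate(ooc_recs):
                out[g, : len(recs)] = [fn(r) for r in recs]
            return out

        y = padded(lambda r: r.peak_current if r.peak_current is not None
                   else np.nan)
        mask = np.zeros((G, N))
        for g, n in enumerate(n_obs):
            mask[g, :n] = 1.0
        A = padded(lambda r: r.agonist_conc)
        D = padded(lambda r: r.drug_conc)
        T = padded(lambda r: r.time_h)
        didx = np.full((G, N), -1, dtype=int)
        for g, recs in enumerate(ooc_recs):
            didx[g, : len(recs)] = [
                drug_names.index(r.drug_id) if r.drug_id != "none" else -1
                for r in recs
            ]
        t6s = np.array(
            [1.0 if recs[0].variant is Variant.T6S else 0.0
             for recs in ooc_recs]
        )
        Apos = A > 0
        Dpos = D > 0
        with np.errstate(divide="ignore"):
            A_l10 = np.where(Apos, np.log10(np.where(Apos, A, 1.0)), 0.0)
            D_l10 = np.where(Dpos, np.log10(np.where(Dpos, D, 1.0)), 0.0)

        eta_kinds = [kinds[j] for j in act]
        dmask = np.zeros((len(act), G, N))
        for jj, (kind, di) in enumerate(eta_kinds):
            if kind in (K_PIC50, K_PA2):
                dmask[jj] = (didx == di) & (mask > 0)
            else:
                dmask[jj] = mask

        present = didx >= 0
        di_safe = np.where(present, didx, 0)

        def slot_arr(pref):
            base = len(_GLOBAL_SLOTS)
            s = base + 6 * di_safe + _DRUG_SLOTS.index(pref)
            return np.where(present, s, table.dummy)

        groups.append(
            CompiledGroup(
                oocyte_ids=list(oids),
                active=np.array(act, dtype=int),
                eta_kinds=eta_kinds,
                n_obs=n_obs,
                y=y, mask=mask, T=T,
                A_l10=A_l10, Apos=Apos, D_l10=D_l10, Dpos=Dpos,
                drug_idx=didx, t6s=t6s, dmask=dmask,
                slot_pic50=slot_arr("pic50"),
                slot_nh=slot_arr("nh"),
                slot_pa2=slot_arr("pa2"),
                slot_ns=slot_arr("ns"),
                slot_ng=slot_arr("ng"),
                slot_dpic50=slot_arr("delta_pic50"),
            )
        )
        n_total += int(n_obs.sum())

    order = [oid for g in groups for oid in g.oocyte_ids]
    return CompiledDataset(
        groups=groups, table=table, n_obs_total=n_total,
        k=respec.k, oocyte_order=order,
    )


# ---------------------------------------------------------------------------
# instance state: one group x a batch of parameter points, flattened
# ---------------------------------------------------------------------------

@dataclass
class InstanceState:
    """Arrays for M = B*G independent inner problems over one group."""

    eta_kinds: list[tuple[int, int]]
    y: np.ndarray        # (M, N)
    mask: np.ndarray
    T: np.ndarray
    A_l10: np.ndarray
    Apos: np.ndarray
    D_l10: np.ndarray
    Dpos: np.ndarray
    dmask: np.ndarray    # (ka, M, N)
    pic50_r: np.ndarray  # (M, N) record-level baselines
    nh_r: np.ndarray
    pa2_r: np.ndarray
    ns_r: np.ndarray
    ng_r: np.ndarray
    pec50_b: np.ndarray  # (M,) oocyte-level
    max0_b: np.ndarray
    nt_b: np.ndarray
    nh_a: np.ndarray
    min0: np.ndarray
    alpha2: np.ndarray
    gamma: np.ndarray
    Oinv: np.ndarray     # (M, ka, ka)
    logdetO: np.ndarray  # (M,)

    @property
    def M(self) -> int:
        return self.y.shape[0]

    @property
    def ka(self) -> int:
        return len(self.eta_kinds)

    def take(self, idx: np.ndarray) -> "InstanceState":
        return InstanceState(
            eta_kinds=self.eta_kinds,
            y=self.y[idx], mask=self.mask[idx], T=self.T[idx],
            A_l10=self.A_l10[idx], Apos=self.Apos[idx],
            D_l10=self.D_l10[idx], Dpos=self.Dpos[idx],
            dmask=self.dmask[:, idx],
            pic50_r=self.pic50_r[idx], nh_r=self.nh_r[idx],
            pa2_r=self.pa2_r[idx], ns_r=self.ns_r[idx],
            ng_r=self.ng_r[idx],
            pec50_b=self.pec50_b[idx], max0_b=self.max0_b[idx],
            nt_b=self.nt_b[idx], nh_a=self.nh_a[idx], min0=self.min0[idx],
            alpha2=self.alpha2[idx], gamma=self.gamma[idx],
            Oinv=self.Oinv[idx] if self.Oinv is not None else None,
            logdetO=self.logdetO[idx] if self.logdetO is not None else None,
        )


def assemble_instances(
    group: CompiledGroup,
    table_values: np.ndarray,   # (B, n_slots)
    omega: np.ndarray | None,   # (B, k, k) full OMEGA per parameter point
    alpha: np.ndarray,          # (B,)
    gamma: np.ndarray,          # (B,)
) -> InstanceState:
    """Build the flat (M = B*G) instance arrays for one group."""
    B = table_values.shape[0]
    G, N = group.y.shape
    M = B * G
    ext = np.concatenate([table_values, np.zeros((B, 1))], axis=1)

    def gather(slot_idx):  # (B, G, N)
        return ext[:, slot_idx]

    t6s = group.t6s  # (G,)
    pic50_r = gather(group.slot_pic50) + t6s[None, :, None] * gather(
        group.slot_dpic50
    )
    nh_r = gather(group.slot_nh)
    pa2_r = gather(group.slot_pa2)
    ns_r = gather(group.slot_ns)
    ng_r = gather(group.slot_ng)

    def group_slot(name):
        return _GLOBAL_SLOTS.index(name)

    pec50_b = (
        table_values[:, [group_slot("pec50_0")]]
        + t6s[None, :] * table_values[:, [group_slot("delta_pec50")]]
    )  # (B, G)
    max0_b = table_values[:, [group_slot("max0")]] * (
        1.0
        + (table_values[:, [group_slot("max_ratio_t6s")]] - 1.0)
        * t6s[None, :]
    )
    nt_b = np.broadcast_to(table_values[:, [group_slot("nt")]], (B, G))
    nh_a = np.broadcast_to(table_values[:, [group_slot("nh_a")]], (B, G))
    min0 = np.broadcast_to(table_values[:, [group_slot("min0")]], (B, G))

    def flat2(a):  # (B, G, N) -> (M, N)
        return np.ascontiguousarray(a).reshape(M, N)

    def flat1(a):  # (B, G) -> (M,)
        return np.ascontiguousarray(a).reshape(M)

    def tile_rec(a):  # (G, N) -> (M, N)
        return np.broadcast_to(a[None], (B, G, N)).reshape(M, N)

    ka = group.ka
    if ka > 0 and omega is not None:
        act = group.active
        inact = np.setdiff1d(np.arange(omega.shape[1]), act)
        if inact.size and not np.allclose(
            omega[:, act][:, :, inact], 0.0, atol=1e-12
        ):
            raise ValueError(
                "OMEGA couples an eta to one that is inactive for some "
                "oocytes; exact marginalization requires a block-separable "
                "covariance"
            )
        Oa = omega[:, act][:, :, act]  # (B, ka, ka)
        sign, logdet = np.linalg.slogdet(Oa)
        if np.any(sign <= 0):
            raise np.linalg.LinAlgError(
                "singular OMEGA sub-block: remove degenerate random effects"
            )
        Oinv = np.linalg.inv(Oa)
        Oinv_m = np.repeat(Oinv, G, axis=0)
        logdet_m = np.repeat(logdet, G)
    else:
        Oinv_m = np.zeros((M, 0, 0))
        logdet_m = np.zeros(M)

    return InstanceState(
        eta_kinds=group.eta_kinds,
        y=tile_rec(group.y), mask=tile_rec(group.mask), T=tile_rec(group.T),
        A_l10=tile_rec(group.A_l10),
        Apos=np.broadcast_to(group.Apos[None], (B, G, N)).reshape(M, N),
        D_l10=tile_rec(group.D_l10),
        Dpos=np.broadcast_to(group.Dpos[None], (B, G, N)).reshape(M, N),
        dmask=np.broadcast_to(
            group.dmask[:, None], (max(ka, 1), B, G, N)
        ).reshape(max(ka, 1), M, N)[:ka] if ka else np.zeros((0, M, N)),
        pic50_r=flat2(pic50_r), nh_r=flat2(nh_r), pa2_r=flat2(pa2_r),
        ns_r=flat2(ns_r), ng_r=flat2(ng_r),
        pec50_b=flat1(pec50_b), max0_b=flat1(max0_b), nt_b=flat1(nt_b),
        nh_a=flat1(nh_a), min0=flat1(min0),
        alpha2=np.repeat(alpha**2, G), gamma=np.repeat(gamma, G),
        Oinv=Oinv_m, logdetO=logdet_m,
    )


# ---------------------------------------------------------------------------
# objective / gradient evaluation
# ---------------------------------------------------------------------------

def _evaluate(st: InstanceState, eta: np.ndarray, want_grad: bool,
              want_pred: bool = False):
    """Inner objective (and analytic eta-gradient) at a batch of etas.

    ``eta`` has shape (M, S, ka); returns (g, grad[, pred]) with shapes
    (M, S), (M, S, ka) and (M, S, N).
    """
    M, S, ka = eta.shape
    rec = lambda a: a[:, None, :]       # (M, N) -> (M, 1, N)
    ooc = lambda a: a[:, None, None]    # (M,)   -> (M, 1, 1)

    pec50 = ooc(st.pec50_b)
    pic50 = rec(st.pic50_r)
    pa2 = rec(st.pa2_r)
    max_mult = None
    max_add = 0.0
    nt_eff = ooc(st.nt_b)
    for j, (kind, _) in enumerate(st.eta_kinds):
        e = eta[:, :, j][:, :, None]    # (M, S, 1)
        if kind == K_PEC50:
            pec50 = pec50 + e
        elif kind == K_MAX0_EXP:
            m = np.exp(np.clip(e, -_EXP_CLIP, _EXP_CLIP))
            max_mult = m if max_mult is None else max_mult * m
        elif kind == K_MAX0_ADD:
            max_add = max_add + e
        elif kind == K_NT:
            nt_eff = nt_eff + e
        elif kind == K_PIC50:
            pic50 = pic50 + e * st.dmask[j][:, None, :]
        elif kind == K_PA2:
            pa2 = pa2 + e * st.dmask[j][:, None, :]

    max0_eff = ooc(st.max0_b) * (1.0 if max_mult is None else max_mult) \
        + max_add  # (M, S, 1) or (M, 1, 1)
    maxT_lin = max0_eff * (1.0 + nt_eff * rec(st.T))
    notclip = maxT_lin > 0
    maxT = np.where(notclip, maxT_lin, 0.0)

    nh_r = rec(st.nh_r)
    z_q = nh_r * LN10 * (rec(st.D_l10) + pic50)
    Q = np.where(rec(st.Dpos), np.exp(np.minimum(z_q, _EXP_CLIP)), 0.0)
    inv1Q = 1.0 / (1.0 + Q)
    maxD = maxT * inv1Q

    ns_r = rec(st.ns_r)
    ng_r = rec(st.ng_r)
    z_r = ns_r * LN10 * (rec(st.D_l10) + pa2)
    R = np.where(rec(st.Dpos), np.exp(np.minimum(z_r, _EXP_CLIP)), 0.0)
    shift = ng_r * np.log1p(R) / LN10
    pec_eff = pec50 - shift

    nh_a = ooc(st.nh_a)
    z_a = nh_a * LN10 * (rec(st.A_l10) + pec_eff)
    frac = np.where(rec(st.Apos), expit(z_a), 0.0)

    min0 = ooc(st.min0)
    pred = min0 + (maxD - min0) * frac

    pf = np.sqrt(pred * pred + RUV_PRED_FLOOR**2)
    a2 = ooc(st.alpha2)
    gam = ooc(st.gamma)
    V = a2 * pf**gam
    res = rec(st.y) - pred
    mask = rec(st.mask)
    g = ((res * res / V + np.log(V)) * mask).sum(axis=2)

    if ka:
        g = g + np.einsum("msi,mij,msj->ms", eta, st.Oinv, eta) \
            + st.logdetO[:, None]

    if not want_grad:
        return (g, None, pred) if want_pred else (g, None)

    dVdP = a2 * gam * pf ** (gam - 2.0) * pred
    invV = 1.0 / V
    dgdP = (-2.0 * res * invV + (invV - res * res * invV * invV) * dVdP) \
        * mask

    base_pec = (maxD - min0) * frac * (1.0 - frac) * nh_a * LN10
    grad = np.empty((M, S, ka))
    for j, (kind, _) in enumerate(st.eta_kinds):
        if kind == K_PEC50:
            dP = base_pec
        elif kind == K_PA2:
            dP = -base_pec * ng_r * ns_r * (R * (1.0 / (1.0 + R))) \
                * st.dmask[j][:, None, :]
        elif kind == K_MAX0_EXP:
            dP = frac * maxD
        elif kind == K_MAX0_ADD:
            dP = frac * (1.0 + nt_eff * rec(st.T)) * notclip * inv1Q
        elif kind == K_NT:
            dP = frac * max0_eff * rec(st.T) * notclip * inv1Q
        elif kind == K_PIC50:
            dP = -frac * maxD * (Q * inv1Q) * nh_r * LN10 \
                * st.dmask[j][:, None, :]
        grad[:, :, j] = (dgdP * dP).sum(axis=2)
    if ka:
        grad += 2.0 * np.einsum("mij,msj->msi", st.Oinv, eta)
    return (g, grad, pred) if want_pred else (g, grad)


def _fd_hessian(st: InstanceState, eta: np.ndarray) -> np.ndarray:
    """Hessian of g by central differences of the analytic gradient."""
    M, ka = eta.shape
    h = 1e-4 * (1.0 + np.abs(eta))             # (M, ka)
    stencil = np.repeat(eta[:, None, :], 2 * ka, axis=1)
    for j in range(ka):
        stencil[:, 2 * j, j] += h[:, j]
        stencil[:, 2 * j + 1, j] -= h[:, j]
    _, grads = _evaluate(st, stencil, want_grad=True)
    H = np.empty((M, ka, ka))
    for j in range(ka):
        H[:, :, j] = (grads[:, 2 * j, :] - grads[:, 2 * j + 1, :]) \
            / (2.0 * h[:, j, None])
    return 0.5 * (H + np.transpose(H, (0, 2, 1)))


def _pd_solve(H: np.ndarray, grad: np.ndarray, lam: np.ndarray):
    """Damped Newton step -(H_pd + lam I)^-1 grad.

    Negative eigenvalues are replaced by their magnitudes (a PSD repair
    that keeps the step a descent direction without exploding along
    near-null directions), and a per-instance Levenberg damping ``lam``
    shades the step towards steepest descent when line searches fail.
    """
    w, V = np.linalg.eigh(H)
    floor = np.maximum(np.abs(w).max(axis=1, keepdims=True), 1.0) * 1e-8
    w = np.maximum(np.abs(w), floor) + lam[:, None]
    gt = np.einsum("mij,mi->mj", V, grad)
    return -np.einsum("mij,mj->mi", V, gt / w)


def _logdet_pd(H: np.ndarray, floor: float = 1e-10):
    """log-determinant after PSD repair (absolute eigenvalues).

    A Hessian that is indefinite at the returned point signals an
    unconverged inner problem; using |eigenvalue| keeps the contribution
    finite and, importantly, never rewards the outer optimizer for
    producing indefinite curvature (a small-eigenvalue floor would).
    """
    w = np.linalg.eigvalsh(H)
    n_repaired = int(np.any(w < floor, axis=1).sum())
    return np.log(np.maximum(np.abs(w), floor)).sum(axis=1), n_repaired


@dataclass
class InnerSolution:
    g: np.ndarray             # (M,) inner objective at the mode
    eta: np.ndarray           # (M, ka) conditional modes
    contribution: np.ndarray  # (M,) Laplace contribution per instance
    converged: np.ndarray     # (M,) bool
    n_floored: int = 0


def _newton_minimize(
    st: InstanceState,
    eta_init: np.ndarray,
    tol: float,
    max_iter: int,
    max_step: float,
):
    """Damped-Newton minimization of every instance from one start."""
    M, ka = st.M, st.ka
    eta = eta_init.copy()
    g, grad = _evaluate(st, eta[:, None, :], want_grad=True)
    g = g[:, 0]
    grad = grad[:, 0, :]
    # instances whose line search can no longer improve the objective at
    # double precision; their gradient norm is judged relative to |g|
    stalled = np.zeros(M, dtype=bool)
    lam = np.zeros(M)  # per-instance Levenberg damping

    for _ in range(max_iter):
        gnorm = np.abs(grad).max(axis=1)
        # scale-aware tolerance: below it the objective can no longer be
        # distinguished at double precision for instances with large |g|
        act = np.flatnonzero((gnorm > tol * (1.0 + np.abs(g))) & ~stalled)
        if act.size == 0:
            break
        sub = st.take(act)
        H = _fd_hessian(sub, eta[act])
        step = _pd_solve(H, grad[act], lam[act])
        snorm = np.linalg.norm(step, axis=1)
        big = snorm > max_step
        if np.any(big):
            step[big] *= (max_step / snorm[big])[:, None]
        dd = np.einsum("mi,mi->m", step, grad[act])

        t = np.ones(act.size)
        accepted = np.zeros(act.size, dtype=bool)
        eta_new = eta[act].copy()
        for _ls in range(20):
            trial = np.flatnonzero(~accepted)
            if trial.size == 0:
                break
            e_try = eta[act][trial] + t[trial, None] * step[trial]
            g_try, _ = _evaluate(
                sub.take(trial), e_try[:, None, :], want_grad=False
            )
            g_try = g_try[:, 0]
            ok = np.isfinite(g_try) & (
                g_try <= g[act][trial] + 1e-4 * t[trial] * dd[trial]
            )
            eta_new[trial[ok]] = e_try[ok]
            accepted[trial[ok]] = True
            t[trial[~ok]] *= 0.5
        # a failed line search escalates damping (towards a short
        # steepest-descent step) rather than abandoning the instance;
        # only instances already near stationarity stop here
        failed = act[~accepted]
        near = np.abs(grad[failed]).max(axis=1) <= 1e-4 * (
            1.0 + np.abs(g[failed])
        )
        stalled[failed[near]] = True
        lam[failed] = np.maximum(lam[failed] * 10.0, 1.0)
        moved = np.flatnonzero(accepted)
        if moved.size == 0:
            if np.all(stalled[act]):
                break
            continue
        upd = act[moved]
        lam[upd] *= 0.2
        eta[upd] = eta_new[moved]
        g_u, grad_u = _evaluate(
            st.take(upd), eta[upd][:, None, :], want_grad=True
        )
        g_new = g_u[:, 0]
        # a step that no longer measurably lowers g has hit the double-
        # precision floor: stop iterating that instance
        stalled[upd[g[upd] - g_new <= 1e-13 * (1.0 + np.abs(g_new))]] = True
        g[upd] = g_new
        grad[upd] = grad_u[:, 0, :]

    converged = np.abs(grad).max(axis=1) <= max(tol, 1e-5) * (
        1.0 + np.abs(g)
    )
    return g, eta, converged


def solve_inner(
    st: InstanceState,
    tol: float = 1e-8,
    max_iter: int = 60,
    max_step: float = 10.0,
) -> InnerSolution:
    """Minimize the inner objective for every instance simultaneously.

    Damped Newton with Armijo backtracking, Levenberg damping escalation
    and a trust cap on the step norm, run from a fixed set of
    deterministic starts and keeping the lower mode per instance: eta = 0
    always, plus (when a multiplicative Max0 eta is present) a
    data-driven start that matches that eta to the observed/predicted
    current ratio.  Weakly expressing oocytes make the inner problem
    bimodal — a low-expression mode and a low-sensitivity mode — and a
    single cold start can hop between basins as the outer parameters
    move, which would make the marginal objective discontinuous.

    The Laplace contribution is

        g(eta_hat) + ln det( H(eta_hat)/2 )

    with H the Hessian of g at the mode: the (2*pi)^(k/2) factor of the
    Laplace integral cancels the eta-prior normalization exactly, so no
    2*pi constant remains (the contribution is exact for any
    linear-in-eta, constant-variance configuration).  The n*ln(2*pi)
    data constant is excluded throughout (the ``ofv`` convention).
    """
    M, ka = st.M, st.ka
    if ka == 0:
        g, _ = _evaluate(st, np.zeros((M, 1, 0)), want_grad=False)
        g = g[:, 0]
        return InnerSolution(
            g=g, eta=np.zeros((M, 0)), contribution=g.copy(),
            converged=np.ones(M, dtype=bool),
        )

    g, eta, converged = _newton_minimize(
        st, np.zeros((M, ka)), tol, max_iter, max_step
    )

    # second basin: oocytes whose overall response level differs a lot
    # from the eta = 0 prediction get a start with the multiplicative
    # Max0 eta matched to the observed/predicted current ratio
    exp_dims = [j for j, (kind, _) in enumerate(st.eta_kinds)
                if kind == K_MAX0_EXP]
    if exp_dims:
        _, _, pred0 = _evaluate(
            st, np.zeros((M, 1, ka)), want_grad=False, want_pred=True
        )
        num = (st.y * st.mask).sum(axis=1)
        den = np.maximum((pred0[:, 0, :] * st.mask).sum(axis=1), 1e-9)
        log_ratio = np.log(np.clip(num / den, 1e-3, 1e3))
        idx = np.flatnonzero(np.abs(log_ratio) > 0.3)
        if idx.size:
            alt = np.zeros((idx.size, ka))
            for j in exp_dims:
                alt[:, j] = log_ratio[idx]
            g2, eta2, conv2 = _newton_minimize(
                st.take(idx), alt, tol, max_iter, max_step
            )
            better = g2 < g[idx] - 1e-12
            upd = idx[better]
            g[upd] = g2[better]
            eta[upd] = eta2[better]
            converged[upd] = conv2[better]

    H = _fd_hessian(st, eta)
    logdet_half, n_floored = _logdet_pd(H / 2.0)
    if n_floored:
        logger.info(
            "PSD-repaired %d indefinite Laplace Hessians", n_floored
        )
    contribution = g + logdet_half
    return InnerSolution(
        g=g, eta=eta, contribution=contribution,
        converged=converged, n_floored=n_floored,
    )
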