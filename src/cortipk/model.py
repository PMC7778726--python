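"""Two-compartment disposition with first-order absorption depots.

Dexamethasone (DEX) and betamethasone (BET) are given as phosphate ester
prodrugs either intramuscularly (IM) or orally (PO); the one-to-one
betamethasone phosphate/acetate suspension (BET-PA) adds a very slow
acetate depot at the IM injection site.  Plasma kinetics of the free
alcohol are described by a linear two-compartment model whose inputs are
up to three first-order absorption depots:

    Vp dCp/dt = ka_IM*A_IM + ka_PO*A_PO + ka_IMa*A_IMa
                - (CL + CL_D)*Cp + CL_D*CT
    VT dCT/dt = CL_D*(Cp - CT)
    dA_x/dt   = -ka_x * A_x          for x in {IM, PO, IMa}

Without an intravenous reference the absolute bioavailability F_IM is
unidentifiable, so clearances and volumes are apparent (CL/F_IM, Vp/F_IM,
...) and the oral and acetate depots carry relative bioavailabilities
Fr = F_PO/F_IM and Fra = F_IMa/F_IM.

Units: doses in mg, volumes in L, clearances in L/h, times in h,
concentrations in ng/mL (= ug/L); the mg -> ug conversion happens inside
:func:`concentration`.

The closed-form (tri-exponential per dose) solution is the primary path;
numerical ODE integration is kept in the test-suite as an independent
oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "Depot",
    "StructuralParams",
    "DoseEvent",
    "Treatment",
    "TREATMENTS",
    "ConcentrationProfile",
    "Disposition",
    "disposition_constants",
    "concentration",
    "composite_ka",
]

#: relative tolerance below which an absorption rate constant is treated as
#: numerically equal to a disposition exponent (removable singularity)
DEGENERACY_RTOL = 1e-9


class Depot(str, Enum):
    """Absorption depot identity; decides which ka and which relative
    bioavailability apply to a dose."""

    IM_PHOSPHATE = "IM_PHOSPHATE"
    ORAL = "ORAL"
    IM_ACETATE = "IM_ACETATE"


class ModelError(ValueError):
    """Invalid structural parameters or dose events."""


@dataclass(frozen=True)
class StructuralParams:
    """Fixed-effect PK parameters of one drug (apparent, F_IM-referenced).

    DEX has no acetate formulation, so ``ka_ima``/``fra`` are ``None`` for
    it; BET carries all nine parameters.
    """

    cl_f: float   # apparent clearance CL/F_IM, L/h
    vp_f: float   # apparent central volume Vp/F_IM, L
    cld_f: float  # apparent distributional clearance CL_D/F_IM, L/h
    vt_f: float   # apparent peripheral volume VT/F_IM, L
    ka_im: float  # 1/h, IM phosphate depot
    ka_po: float  # 1/h, oral depot
    fr: float     # F_PO/F_IM
    ka_ima: float | None = None  # 1/h, IM acetate depot (BET only)
    fra: float | None = None     # F_IMa/F_IM (BET only)

    def __post_init__(self) -> None:
        for name in ("cl_f", "vp_f", "vt_f", "ka_im", "ka_po", "fr"):
            v = getattr(self, name)
            if not (v > 0.0) or not math.isfinite(v):
                raise ModelError(f"{name} must be strictly positive, got {v!r}")
        if not (self.cld_f >= 0.0) or not math.isfinite(self.cld_f):
            raise ModelError(f"cld_f must be non-negative, got {self.cld_f!r}")
        if (self.ka_ima is None) != (self.fra is None):
            raise ModelError("ka_ima and fra must be supplied together")
        if self.ka_ima is not None:
            if not (self.ka_ima > 0.0 and self.fra > 0.0):
                raise ModelError("ka_ima and fra must be strictly positive")

    @property
    def has_acetate(self) -> bool:
        return self.ka_ima is not None

    @property
    def vss_f(self) -> float:
        """Apparent steady-state volume Vss/F_IM = Vp/F_IM + VT/F_IM (L)."""
        return self.vp_f + self.vt_f

    def depot_ka(self, depot: Depot) -> float:
        if depot == Depot.IM_PHOSPHATE:
            return self.ka_im
        if depot == Depot.ORAL:
            return self.ka_po
        if self.ka_ima is None:
            raise ModelError("acetate depot requested for a drug without one")
        return self.ka_ima

    def depot_fraction(self, depot: Depot) -> float:
        """Fraction of a depot dose absorbed, relative to F_IM."""
        if depot == Depot.IM_PHOSPHATE:
            return 1.0
        if depot == Depot.ORAL:
            return self.fr
        if self.fra is None:
            raise ModelError("acetate depot requested for a drug without one")
        return self.fra

    def with_updates(self, **kwargs: float) -> "StructuralParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DoseEvent:
    """One administration into one depot.

    ``bioavail_scale`` overrides the relative-bioavailability fraction
    applied to ``amount``; left ``None`` it is taken from the parameters
    (1 for IM phosphate, Fr for oral, Fra for IM acetate).
    """

    time: float            # h since the subject's first dose
    amount: float          # mg free-alcohol equivalent
    depot: Depot
    bioavail_scale: float | None = None

    def __post_init__(self) -> None:
        if self.time < 0.0:
            raise ModelError(f"dose time must be >= 0, got {self.time!r}")
        if self.amount < 0.0:
            raise ModelError(f"dose amount must be >= 0, got {self.amount!r}")


@dataclass(frozen=True)
class Treatment:
    """One of the five single-dose treatments of the crossover trial."""

    code: str                    # A..E
    drug: str                    # "DEX" or "BET"
    route: str                   # "IM" or "PO"
    label: str
    doses: tuple[tuple[float, Depot], ...]  # (mg, depot) split rule

    def dose_events(self, time: float = 0.0) -> list[DoseEvent]:
        return [DoseEvent(time=time, amount=a, depot=d) for a, d in self.doses]

    @property
    def total_dose(self) -> float:
        return sum(a for a, _ in self.doses)


#: Treatment catalog: total dose is 6 mg in every arm; the phosphate/acetate
#: suspension (C) splits 3 mg + 3 mg between the fast and slow IM depots.
TREATMENTS: dict[str, Treatment] = {
    "A": Treatment("A", "DEX", "IM", "DEX-P IM solution",
                   ((6.0, Depot.IM_PHOSPHATE),)),
    "B": Treatment("B", "BET", "IM", "BET-P IM solution",
                   ((6.0, Depot.IM_PHOSPHATE),)),
    "C": Treatment("C", "BET", "IM", "BET-PA IM suspension",
                   ((3.0, Depot.IM_PHOSPHATE), (3.0, Depot.IM_ACETATE))),
    "D": Treatment("D", "DEX", "PO", "DEX-P tablets",
                   ((6.0, Depot.ORAL),)),
    "E": Treatment("E", "BET", "PO", "BET-P tablets",
                   ((6.0, Depot.ORAL),)),
}


class Disposition(NamedTuple):
    """Micro rate constants and disposition exponents (all 1/h)."""

    k10: float
    k12: float
    k21: float
    alpha: float
    beta: float


@dataclass
class ConcentrationProfile:
    """Central-compartment concentration over time for one dose history.

    ``params``/``doses`` record the generating model when the profile is
    model-based, which lets downstream code (AUC) use exact per-exponential
    integration instead of the trapezoid rule.
    """

    times: np.ndarray          # h, ascending
    cp: np.ndarray             # ng/mL
    ct: np.ndarray | None = None   # ng/mL, peripheral
    depots: dict[Depot, np.ndarray] | None = None  # mg remaining per depot
    params: StructuralParams | None = None
    doses: tuple[DoseEvent, ...] | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_h": self.times, "conc_ng_ml": self.cp})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def disposition_constants(params: StructuralParams) -> Disposition:
    """Micro constants k10, k12, k21 and exponents alpha > beta >= 0.

    alpha and beta are the roots of s^2 - (k10+k12+k21) s + k10*k21; the
    smaller root is computed from the product to avoid cancellation.  With
    cld_f = 0 the system decouples and (alpha, beta) = (k10, k21) = (k10, 0).
    """
    k10 = params.cl_f / params.vp_f
    k12 = params.cld_f / params.vp_f
    k21 = params.cld_f / params.vt_f
    a = k10 + k12 + k21
    disc = a * a - 4.0 * k10 * k21
    # disc >= (k10 - k21)^2 >= 0 analytically; guard rounding
    root = math.sqrt(max(disc, 0.0))
    alpha = 0.5 * (a + root)
    beta = (k10 * k21) / alpha if alpha > 0.0 else 0.0
    return Disposition(k10=k10, k12=k12, k21=k21, alpha=alpha, beta=beta)


def _close(x: float, y: float) -> bool:
    return abs(x - y) <= DEGENERACY_RTOL * max(abs(x), abs(y))


def _cp_terms(tau: np.ndarray, ka: float, k21: float,
              alpha: float, beta: float) -> np.ndarray:
    """Unit-dose central amount response (before ka*A0/Vp scaling):
    inverse Laplace transform of (s+k21)/((s+ka)(s+alpha)(s+beta)).

    Removable singularities at ka == alpha or ka == beta are evaluated with
    their analytic limit (L'Hopital) forms.
    """
    if _close(alpha, beta):
        # Near-coincident disposition exponents cannot arise from distinct
        # compartments unless k12 ~ 0 and k10 ~ k21; nudge beta (documented
        # perturbation, relative 1e-9) rather than stacking limit forms.
        beta = beta * (1.0 - 1e-7) if beta > 0.0 else -1e-12
    ea = np.exp(-alpha * tau)
    eb = np.exp(-beta * tau)
    if _close(ka, alpha):
        d = beta - alpha
        return ((beta - k21) / d ** 2) * ea \
            + ((k21 - alpha) / d) * tau * ea \
            + ((k21 - beta) / d ** 2) * eb
    if _close(ka, beta):
        d = alpha - beta
        return ((alpha - k21) / d ** 2) * eb \
            + ((k21 - beta) / d) * tau * eb \
            + ((k21 - alpha) / d ** 2) * ea
    ek = np.exp(-ka * tau)
    ca = (k21 - alpha) / ((ka - alpha) * (beta - alpha))
    cb = (k21 - beta) / ((ka - beta) * (alpha - beta))
    ck = (k21 - ka) / ((alpha - ka) * (beta - ka))
    return ca * ea + cb * eb + ck * ek


def _ct_terms(tau: np.ndarray, ka: float,
              alpha: float, beta: float) -> np.ndarray:
    """Inverse Laplace transform of 1/((s+ka)(s+alpha)(s+beta))."""
    if _close(alpha, beta):
        beta = beta * (1.0 - 1e-7) if beta > 0.0 else -1e-12
    ea = np.exp(-alpha * tau)
    eb = np.exp(-beta * tau)
    if _close(ka, alpha):
        d = beta - alpha
        return -ea / d ** 2 + tau * ea / d + eb / d ** 2
    if _close(ka, beta):
        d = alpha - beta
        return -eb / d ** 2 + tau * eb / d + ea / d ** 2
    ek = np.exp(-ka * tau)
    return ea / ((ka - alpha) * (beta - alpha)) \
        + eb / ((ka - beta) * (alpha - beta)) \
        + ek / ((alpha - ka) * (beta - ka))


def concentration(
    params: StructuralParams,
    doses: Sequence[DoseEvent],
    times: Sequence[float] | np.ndarray,
    *,
    include_tissue: bool = False,
    include_depots: bool = False,
) -> ConcentrationProfile:
    """Closed-form plasma concentration (ng/mL) by superposition over doses.

    Each dose contributes a tri-exponential response starting at its own
    time; linearity of the system makes the total profile the sum of the
    per-dose responses.  Doses are mg, converted to ug internally so that
    ug/L == ng/mL.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        raise ModelError("times must be one-dimensional")
    if t.size > 1 and np.any(np.diff(t) < 0.0):
        raise ModelError("times must be ascending")
    micro = disposition_constants(params)
    cp = np.zeros_like(t)
    ct = np.zeros_like(t) if include_tissue else None
    depots: dict[Depot, np.ndarray] | None = None
    if include_depots:
        depots = {}
    doses = sorted(doses, key=lambda d: d.time)
    for dose in doses:
        if dose.amount == 0.0:
            continue
        ka = params.depot_ka(dose.depot)
        frac = (dose.bioavail_scale if dose.bioavail_scale is not None
                else params.depot_fraction(dose.depot))
        a0_ug = dose.amount * 1000.0 * frac
        mask = t >= dose.time
        tau = t[mask] - dose.time
        live = tau > 0.0  # the response is exactly zero at tau = 0
        cp[mask] += live * (ka * a0_ug / params.vp_f) * _cp_terms(
            tau, ka, micro.k21, micro.alpha, micro.beta)
        if include_tissue:
            ct[mask] += live * (ka * micro.k12 * a0_ug / params.vt_f) \
                * _ct_terms(tau, ka, micro.alpha, micro.beta)
        if include_depots:
            amt = depots.setdefault(dose.depot, np.zeros_like(t))
            amt[mask] += dose.amount * frac * np.exp(-ka * tau)
    # superposition can leave -1e-18-scale dust at tau == 0
    np.clip(cp, 0.0, None, out=cp)
    if ct is not None:
        np.clip(ct, 0.0, None, out=ct)
    return ConcentrationProfile(
        times=t, cp=cp, ct=ct, depots=depots,
        params=params, doses=tuple(doses))


def cumulative_auc(
    params: StructuralParams,
    doses: Sequence[DoseEvent],
    times: Sequence[float] | np.ndarray,
) -> np.ndarray:
    """Exact cumulative integral of the closed-form Cp at ``times`` (ng*h/mL)."""
    t = np.asarray(times, dtype=float)
    micro = disposition_constants(params)
    out = np.zeros_like(t)
    for dose in doses:
        if dose.amount == 0.0:
            continue
        ka = params.depot_ka(dose.depot)
        frac = (dose.bioavail_scale if dose.bioavail_scale is not None
                else params.depot_fraction(dose.depot))
        a0_ug = dose.amount * 1000.0 * frac
        mask = t >= dose.time
        tau = t[mask] - dose.time
        scale = ka * a0_ug / params.vp_f
        alpha, beta = micro.alpha, micro.beta
        k21 = micro.k21
        if _close(ka, alpha) or _close(ka, beta) or _close(alpha, beta):
            ka = ka * (1.0 + 1e-7)  # documented nudge; AUC is ka-insensitive here
        terms = np.zeros_like(tau)
        for lam, c in (
            (alpha, (k21 - alpha) / ((ka - alpha) * (beta - alpha))),
            (beta, (k21 - beta) / ((ka - beta) * (alpha - beta))),
            (ka, (k21 - ka) / ((alpha - ka) * (beta - ka))),
        ):
            if lam > 0.0:
                terms += c * (1.0 - np.exp(-lam * tau)) / lam
            else:
                terms += c * tau
        out[mask] += scale * terms
    return np.clip(out, 0.0, None)


def auc_to_infinity(params: StructuralParams,
                    doses: Sequence[DoseEvent]) -> float:
    """AUC(0, inf) = total absorbed amount / (CL/F_IM), independent of ka."""
    total_ug = 0.0
    for dose in doses:
        frac = (dose.bioavail_scale if dose.bioavail_scale is not None
                else params.depot_fraction(dose.depot))
        total_ug += dose.amount * 1000.0 * frac
    return total_ug / params.cl_f


def composite_ka(weights: Sequence[float], kas: Sequence[float],
                 ) -> float:
    """Absorbed-fraction-weighted harmonic-mean absorption rate (1/h).

    For multiple parallel depots the mean absorption time is the weighted
    mean of the per-depot 1/ka, so the composite rate is
    sum(w) / sum(w/ka); its reciprocal is the MAT.  For BET-PA the weights
    are the F_IM-relative absorbed fractions (1 for the phosphate depot,
    Fra for the acetate depot).
    """
    w = np.asarray(weights, dtype=float)
    k = np.asarray(kas, dtype=float)
    if w.shape != k.shape:
        raise ModelError("weights and kas must have equal length")
    if np.any(w < 0.0):
        raise ModelError("weights must be non-negative")
    if np.any(k <= 0.0):
        raise ModelError("rate constants must be strictly positive")
    total = w.sum()
    if total <= 0.0:
        raise ModelError("at least one weight must be positive")
    return float(total / np.sum(w / k))
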