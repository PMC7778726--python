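"""Synthetic crossover-study generator.

Reproduces the structure of the single-dose, two-period trial: 48 healthy
women in 8 sequences x 6 subjects, treatments A-E (all 6 mg total),
17 samples per period at 0-96 h post-dose, a 10-day washout (period-2 dose
336 h after the first: 4 days of sampling + 10 days washout), LLOQ
0.1 ng/mL, and the BET-PA carryover that leaves quantifiable BET at the
period-2 pre-dose sample for the CE/EC sequences.

Every stochastic element flows from one integer seed: per subject the
body weight, one eta vector per drug, then the log-scale residuals in
row order.  Identical seeds give identical datasets, byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .likelihood import PopulationParams
from .model import TREATMENTS, DoseEvent, concentration

__all__ = ["StudyDesign", "build_design", "generate_study", "censor_lloq",
           "SAMPLING_TIMES", "SEQUENCES"]

#: per-period blood-sampling times, h post-dose
SAMPLING_TIMES = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 12.0, 18.0,
                  24.0, 30.0, 36.0, 48.0, 60.0, 72.0, 96.0)

#: crossover sequences (period-1 treatment, period-2 treatment)
SEQUENCES = ("AB", "BA", "CD", "DC", "ED", "DE", "CE", "EC")


@dataclass(frozen=True)
class StudyDesign:
    """Trial structure; defaults reproduce the study exactly."""

    sequences: tuple[str, ...] = SEQUENCES
    n_per_sequence: int = 6
    sampling_times: tuple[float, ...] = SAMPLING_TIMES
    period_offset: float = 336.0   # h between the two period doses
    lloq: float = 0.1              # ng/mL
    weight_range: tuple[float, float] = (47.0, 68.7)  # kg

    def __post_init__(self) -> None:
        for seq in self.sequences:
            if len(seq) != 2 or any(c not in TREATMENTS for c in seq):
                raise ValueError(f"unknown sequence {seq!r}")
        if self.n_per_sequence < 1:
            raise ValueError("n_per_sequence must be >= 1")
        if self.period_offset <= max(self.sampling_times):
            raise ValueError("periods must not overlap: offset too small")
        if not self.lloq > 0.0:
            raise ValueError("lloq must be positive")
        lo, hi = self.weight_range
        if not (0.0 < lo <= hi):
            raise ValueError("invalid weight range")

    @property
    def n_subjects(self) -> int:
        return len(self.sequences) * self.n_per_sequence

    def treatment_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for seq in self.sequences:
            for code in seq:
                counts[code] = counts.get(code, 0) + self.n_per_sequence
        return counts

    def drug_administrations(self, drug: str) -> int:
        return sum(n for code, n in self.treatment_counts().items()
                   if TREATMENTS[code].drug == drug)


def build_design(**overrides) -> StudyDesign:
    """The default study design, with keyword overrides for reduced-scale
    fixtures (e.g. ``n_per_sequence=1`` for an 8-subject mini-study)."""
    return StudyDesign(**overrides)


def _drug_doses(design: StudyDesign, sequence: str, drug: str) -> list[DoseEvent]:
    events: list[DoseEvent] = []
    for period, code in enumerate(sequence, start=1):
        trt = TREATMENTS[code]
        if trt.drug == drug:
            events.extend(trt.dose_events(time=design.period_offset * (period - 1)))
    return events


def generate_study(pop_dex: PopulationParams | None = None,
                   pop_bet: PopulationParams | None = None,
                   design: StudyDesign | None = None,
                   seed: int = 0,
                   cross_drug_corr: float = 0.0) -> pd.DataFrame:
    """Simulate a complete synthetic study as an event-level dataset.

    Per subject: weight uniform in the design's range (a label only -- no
    covariate enters the model), one eta vector per drug, and log-normal
    residual error per observation.  Concentrations below the LLOQ are
    flagged BLQ with the numeric value withheld; the latent value is kept
    in the hidden ``_dv_latent`` column for test oracles.

    ``cross_drug_corr`` optionally correlates the two drugs' clearance
    etas within a subject (a Gaussian coupling of the underlying CL
    normals); the default 0 reflects that no such correlation is imposed.
    """
    from .drugs import BET_POPULATION, DEX_POPULATION  # avoid import cycle

    pop_dex = pop_dex if pop_dex is not None else DEX_POPULATION
    pop_bet = pop_bet if pop_bet is not None else BET_POPULATION
    design = design if design is not None else build_design()
    if not -1.0 <= cross_drug_corr <= 1.0:
        raise ValueError("cross_drug_corr must be in [-1, 1]")
    rng = np.random.default_rng(seed)

    def chol_of(pop):
        d = len(pop.iiv_names)
        if d == 0:
            return np.zeros((0, 0))
        omega = np.asarray(pop.omega, float)
        try:
            # lower-triangular, so standard-normal component k feeds only
            # etas k..d-1 (the clearance coupling relies on this)
            return np.linalg.cholesky(omega)
        except np.linalg.LinAlgError:
            # semi-definite omegas are admitted in the generative direction
            ev, U = np.linalg.eigh(omega)
            return U @ np.diag(np.sqrt(np.clip(ev, 0.0, None)))

    chols = {"DEX": chol_of(pop_dex), "BET": chol_of(pop_bet)}
    pops = {"DEX": pop_dex, "BET": pop_bet}
    cl_idx = {drug: (pops[drug].iiv_names.index("cl_f")
                     if "cl_f" in pops[drug].iiv_names else None)
              for drug in ("DEX", "BET")}

    rows: list[dict] = []
    subject_id = 0
    for seq in design.sequences:
        for _ in range(design.n_per_sequence):
            subject_id += 1
            weight = rng.uniform(*design.weight_range)
            z = {d: rng.standard_normal(len(pops[d].iiv_names))
                 for d in ("DEX", "BET")}
            if (cross_drug_corr != 0.0 and cl_idx["DEX"] is not None
                    and cl_idx["BET"] is not None):
                rho = cross_drug_corr
                z["BET"][cl_idx["BET"]] = (
                    rho * z["DEX"][cl_idx["DEX"]]
                    + np.sqrt(1.0 - rho * rho) * z["BET"][cl_idx["BET"]])
            etas = {d: chols[d] @ z[d] for d in ("DEX", "BET")}
            params = {
                d: _apply_eta(pops[d], etas[d]) for d in ("DEX", "BET")}
            drug_dose_events = {d: _drug_doses(design, seq, d)
                                for d in ("DEX", "BET")}
            for period, code in enumerate(seq, start=1):
                trt = TREATMENTS[code]
                dose_time = design.period_offset * (period - 1)
                for amount, depot in trt.doses:
                    rows.append({
                        "ID": subject_id, "TIME": dose_time, "EVID": 1,
                        "AMT": amount, "CMT": depot.value, "DV": np.nan,
                        "MDV": 1, "BLQ": 0, "LLOQ": design.lloq,
                        "DRUG": trt.drug, "TRT": code, "SEQ": seq,
                        "PERIOD": period, "WT": weight,
                        "_dv_latent": np.nan,
                    })
                obs_times = dose_time + np.asarray(design.sampling_times)
                latent = concentration(params[trt.drug],
                                       drug_dose_events[trt.drug],
                                       obs_times).cp
                eps = rng.normal(0.0, np.sqrt(pops[trt.drug].sigma2),
                                 obs_times.size)
                latent = latent * np.exp(eps)
                for t, lv in zip(obs_times, latent):
                    rows.append({
                        "ID": subject_id, "TIME": t, "EVID": 0,
                        "AMT": np.nan, "CMT": np.nan, "DV": lv,
                        "MDV": 0, "BLQ": 0, "LLOQ": design.lloq,
                        "DRUG": trt.drug, "TRT": code, "SEQ": seq,
                        "PERIOD": period, "WT": weight,
                        "_dv_latent": lv,
                    })
    df = pd.DataFrame(rows)
    df = df.sort_values(["ID", "TIME", "EVID"],
                        ascending=[True, True, False], kind="stable")
    df = df.reset_index(drop=True)
    return censor_lloq(df, design.lloq)


def _apply_eta(pop: PopulationParams, eta: np.ndarray):
    from .likelihood import individual_params

    return individual_params(pop.theta, eta, pop.iiv_names)


def censor_lloq(dataset: pd.DataFrame, lloq: float | None = None) -> pd.DataFrame:
    """Flag observation rows with concentration < LLOQ as BLQ (idempotent).

    The pre-censoring value is preserved in the hidden ``_dv_latent``
    column (test oracles only; excluded from written datasets).  A latent
    value of exactly zero (pre-first-dose sample) is censored too.
    """
    df = dataset.copy()
    if lloq is None:
        lloq = float(df.loc[df["EVID"] == 0, "LLOQ"].iloc[0])
    if not lloq > 0.0:
        raise ValueError("lloq must be positive")
    obs = df["EVID"] == 0
    if "_dv_latent" not in df.columns:
        df["_dv_latent"] = np.where(obs, df["DV"], np.nan)
    latent = df["_dv_latent"]
    below = obs & (latent.fillna(-np.inf) < lloq)
    above = obs & ~below
    df.loc[below, "BLQ"] = 1
    df.loc[below, "DV"] = np.nan
    df.loc[below, "MDV"] = 1
    df.loc[above, "BLQ"] = 0
    df.loc[above, "DV"] = latent[above]
    df.loc[above, "MDV"] = 0
    df.loc[obs, "LLOQ"] = lloq
    return df
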