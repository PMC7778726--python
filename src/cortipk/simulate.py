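"""Population simulation, visual predictive checks, and dosing-regimen
simulation.

The VPC replicates an observed study's design many times under candidate
population parameters and overlays observed 5th/50th/95th percentiles on
the simulation-based confidence band of each percentile, per nominal
sampling time and treatment.  Values below the LLOQ (simulated and
observed alike) enter percentile computation as LLOQ/2 with the censored
fraction reported per bin; a percentile that itself falls in the censored
mass is reported as not numerically identified rather than a number.

Regimen simulation superposes multiple doses (exact, by linearity of the
model) for the standard antenatal corticosteroid regimens and summarizes
exposure (Cmax, Ctrough, AUC) over a simulated population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import LaplaceEngine, PRED_FLOOR
from .likelihood import PopulationParams, SubjectData
from .model import Depot, DoseEvent, concentration, cumulative_auc
from .study import StudyDesign, generate_study

__all__ = ["Regimen", "WHO_REGIMENS", "VpcResult", "RegimenResult",
           "simulate_population", "vpc", "regimen_metrics",
           "vpc_plot", "regimen_plot"]

_PCTS = (5.0, 50.0, 95.0)


# ---------------------------------------------------------------------------
# regimens


@dataclass(frozen=True)
class Regimen:
    """A repeated-dose schedule of one formulation."""

    drug: str           # DEX or BET
    formulation: str    # DEX-P, BET-P or BET-PA
    dose_mg: float      # per administration, free-alcohol equivalent
    interval_h: float
    n_doses: int
    route: str = "IM"

    def __post_init__(self) -> None:
        if not self.dose_mg > 0:
            raise ValueError("dose must be positive")
        if not self.interval_h > 0:
            raise ValueError("interval must be positive")
        if self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")

    def dose_events(self) -> list[DoseEvent]:
        events = []
        for i in range(self.n_doses):
            t = i * self.interval_h
            if self.formulation == "BET-PA":
                half = self.dose_mg / 2.0
                events.append(DoseEvent(t, half, Depot.IM_PHOSPHATE))
                events.append(DoseEvent(t, half, Depot.IM_ACETATE))
            elif self.route == "PO":
                events.append(DoseEvent(t, self.dose_mg, Depot.ORAL))
            else:
                events.append(DoseEvent(t, self.dose_mg, Depot.IM_PHOSPHATE))
        return events

    @property
    def last_dose_time(self) -> float:
        return (self.n_doses - 1) * self.interval_h


#: the three WHO-recommended antenatal corticosteroid regimens
WHO_REGIMENS = {
    "DEX-P": Regimen("DEX", "DEX-P", 6.0, 12.0, 4),    # 6 mg IM BID x4
    "BET-P": Regimen("BET", "BET-P", 12.0, 24.0, 2),   # 12 mg IM QD x2
    "BET-PA": Regimen("BET", "BET-PA", 12.0, 24.0, 2),  # 12 mg IM QD x2
}


# ---------------------------------------------------------------------------
# population simulation


def _omega_factor(pop: PopulationParams) -> np.ndarray:
    d = len(pop.iiv_names)
    if d == 0:
        return np.zeros((0, 0))
    omega = np.asarray(pop.omega, float)
    ev, U = np.linalg.eigh(omega)
    return U @ np.diag(np.sqrt(np.clip(ev, 0.0, None)))


def _drug_of(pop: PopulationParams) -> str:
    return "BET" if pop.theta.has_acetate else "DEX"


def simulate_population(pop: PopulationParams,
                        design,
                        n_subjects: int | None = None,
                        seed: int = 0,
                        *,
                        drug: str | None = None,
                        include_residual: bool = True) -> pd.DataFrame:
    """Simulate a study dataset under ``pop``.

    ``design`` is either a :class:`StudyDesign` (the crossover structure;
    rows for this drug are returned, scaled to about ``n_subjects`` when
    given) or a list of :class:`SubjectData` templates whose dose events
    and sampling times are replicated with fresh etas and residuals.
    Fully reproducible from ``seed``.
    """
    if drug is None:
        drug = _drug_of(pop)
    if isinstance(design, StudyDesign):
        if n_subjects is not None:
            per_seq = max(1, int(round(n_subjects / len(design.sequences))))
            design = replace(design, n_per_sequence=per_seq)
        sim_pop = pop if include_residual else replace_sigma(pop, 0.0)
        kw = {"pop_dex": sim_pop} if drug == "DEX" else {"pop_bet": sim_pop}
        df = generate_study(design=design, seed=seed, **kw)
        return df[df["DRUG"] == drug].reset_index(drop=True)
    templates = list(design)
    if n_subjects is None:
        n_subjects = len(templates)
    reps = [templates[i % len(templates)] for i in range(n_subjects)]
    conc, engine = _simulate_replicates(pop, reps, 1, seed,
                                        include_residual=include_residual)
    return _subjects_to_frame(reps, conc[0], engine, drug)


def replace_sigma(pop: PopulationParams, sigma2: float) -> PopulationParams:
    return PopulationParams(theta=pop.theta, iiv_names=pop.iiv_names,
                            omega=pop.omega, sigma2=sigma2)


def _simulate_replicates(pop, subjects, n_replicates, seed, *,
                         include_residual=True):
    """Concentrations (n_replicates, n_obs) over flattened subject obs."""
    engine = LaplaceEngine(subjects, pop.iiv_names)
    theta9 = pop.theta9()
    chol = _omega_factor(pop)
    d = len(pop.iiv_names)
    sigma = math.sqrt(pop.sigma2) if include_residual else 0.0
    rng = np.random.default_rng(seed)
    out = np.empty((n_replicates, engine.n_obs))
    for r in range(n_replicates):
        eta = rng.standard_normal((engine.n_s, d)) @ chol.T if d else \
            np.zeros((engine.n_s, 0))
        conc = np.exp(engine.predict_log_cp(theta9, eta))
        conc[conc <= 2.0 * PRED_FLOOR] = 0.0
        if sigma > 0.0:
            conc = conc * np.exp(rng.normal(0.0, sigma, engine.n_obs))
        out[r] = conc
    return out, engine


def _subjects_to_frame(subjects, conc, engine, drug):
    from .study import censor_lloq

    rows = []
    pos = 0
    for sid, sub in enumerate(subjects, start=1):
        for dt, da, dep in zip(sub.dose_times, sub.dose_amounts,
                               sub.dose_depots):
            rows.append({"ID": sid, "TIME": float(dt), "EVID": 1,
                         "AMT": float(da),
                         "CMT": getattr(dep, "value", dep), "DV": np.nan,
                         "MDV": 1, "BLQ": 0, "LLOQ": sub.lloq, "DRUG": drug,
                         "TRT": ".", "SEQ": sub.sequence or ".", "PERIOD": 1,
                         "WT": sub.weight if sub.weight else np.nan,
                         "_dv_latent": np.nan})
        for t in sub.obs_times:
            rows.append({"ID": sid, "TIME": float(t), "EVID": 0,
                         "AMT": np.nan, "CMT": np.nan, "DV": conc[pos],
                         "MDV": 0, "BLQ": 0, "LLOQ": sub.lloq, "DRUG": drug,
                         "TRT": ".", "SEQ": sub.sequence or ".", "PERIOD": 1,
                         "WT": sub.weight if sub.weight else np.nan,
                         "_dv_latent": conc[pos]})
            pos += 1
    df = pd.DataFrame(rows).sort_values(
        ["ID", "TIME", "EVID"], ascending=[True, True, False], kind="stable")
    return censor_lloq(df.reset_index(drop=True))


# ---------------------------------------------------------------------------
# visual predictive check


@dataclass
class VpcResult:
    """Observed percentiles and simulated confidence bands per bin.

    ``table`` columns: treatment, time (h post period dose), n, frac_blq,
    then for each of p5/p50/p95 the observed value and its simulated
    2.5-97.5% band.  Censored (below-LLOQ) percentiles are NaN with the
    censored fraction still reported.
    """

    table: pd.DataFrame
    lloq: float
    n_replicates: int
    drug: str

    def coverage_fraction(self) -> float:
        """Fraction of numerically identified observed-percentile points
        lying inside their simulated band."""
        inside = total = 0
        for p in ("p5", "p50", "p95"):
            o = self.table[f"obs_{p}"]
            lo = self.table[f"{p}_lo"]
            hi = self.table[f"{p}_hi"]
            ok = o.notna() & lo.notna() & hi.notna()
            total += int(ok.sum())
            inside += int(((o >= lo) & (o <= hi) & ok).sum())
        if total == 0:
            raise ValueError("no numerically identified percentile points")
        return inside / total


def _censored_percentiles(values: np.ndarray, lloq: float) -> np.ndarray:
    """Percentiles with the LLOQ/2 imputation; below-LLOQ results -> NaN."""
    imputed = np.where(values < lloq, lloq / 2.0, values)
    pct = np.percentile(imputed, _PCTS)
    return np.where(pct < lloq, np.nan, pct)


def vpc(observed: pd.DataFrame, pop: PopulationParams, *,
        drug: str | None = None, n_replicates: int = 500,
        seed: int = 12345, include_residual: bool = True) -> VpcResult:
    """Visual-predictive-check tables for one drug of an observed dataset.

    The observed design (every subject's doses and sampling times) is
    replicated ``n_replicates`` times under ``pop``; bins are the nominal
    sampling times within each treatment group, i.e. time since the
    period's dose.  Bands are the 2.5-97.5 percentile range of each
    simulated percentile.
    """
    from .dataset import subjects_from_dataset

    if drug is None:
        drug = _drug_of(pop)
    subjects, row_idx = subjects_from_dataset(observed, drug, with_index=True)
    if not subjects:
        raise ValueError(f"no {drug} observations in dataset")
    obs_rows = observed.loc[row_idx]
    lloq = float(obs_rows["LLOQ"].iloc[0])

    # time since the period's own dose, for binning at nominal times
    dose_times = observed[(observed["EVID"] == 1) & (observed["DRUG"] == drug)]
    key = dose_times.groupby(["ID", "PERIOD"])["TIME"].min()
    tau = np.array([
        row["TIME"] - key.loc[(row["ID"], row["PERIOD"])]
        for _, row in obs_rows.iterrows()
    ])
    trt = obs_rows["TRT"].to_numpy()
    obs_dv = np.where(obs_rows["BLQ"].to_numpy() > 0, 0.0,
                      obs_rows["DV"].to_numpy(float))

    sims, _ = _simulate_replicates(pop, subjects, n_replicates, seed,
                                   include_residual=include_residual)

    records = []
    bins = sorted(set(zip(trt, np.round(tau, 6))))
    for code, t in bins:
        sel = np.flatnonzero((trt == code) & (np.round(tau, 6) == t))
        vals = obs_dv[sel]
        obs_pct = _censored_percentiles(vals, lloq)
        sim_pct = np.empty((n_replicates, 3))
        for r in range(n_replicates):
            sim_pct[r] = _censored_percentiles(sims[r, sel], lloq)
        rec = {"treatment": code, "time": float(t), "n": int(sel.size),
               "frac_blq": float(np.mean(vals < lloq))}
        for j, p in enumerate(("p5", "p50", "p95")):
            rec[f"obs_{p}"] = obs_pct[j]
            col = sim_pct[:, j]
            ident = col[~np.isnan(col)]
            # a band is identified when enough replicates resolve it
            if ident.size >= 0.5 * n_replicates:
                rec[f"{p}_lo"], rec[f"{p}_hi"] = np.percentile(
                    ident, (2.5, 97.5))
            else:
                rec[f"{p}_lo"] = rec[f"{p}_hi"] = np.nan
        records.append(rec)
    table = pd.DataFrame(records).sort_values(["treatment", "time"])
    return VpcResult(table=table.reset_index(drop=True), lloq=lloq,
                     n_replicates=n_replicates, drug=drug)


# ---------------------------------------------------------------------------
# regimen simulation


@dataclass
class RegimenResult:
    regimen: Regimen
    metrics: pd.DataFrame    # per-subject cmax, tmax, ctrough, auc
    summary: pd.DataFrame    # median / p5 / p95 per metric
    profile: pd.DataFrame    # time, p5, p50, p95 concentration
    lloq: float


def regimen_metrics(pop: PopulationParams, regimen: Regimen,
                    n_subjects: int = 200, seed: int = 0, *,
                    include_residual: bool = False,
                    grid_step: float = 1.0,
                    horizon: float | None = None,
                    lloq: float = 0.1) -> RegimenResult:
    """Simulate a dosing regimen and summarize exposure.

    Per subject: Cmax and tmax over an hourly grid, Ctrough at the end of
    the final dosing interval, AUC to the simulation horizon and to
    infinity (exact).  Bands are IIV-only by default; residual error can
    be switched on.  ``horizon`` defaults to 336 h past the last dose.
    """
    from .likelihood import individual_params

    doses = regimen.dose_events()
    if horizon is None:
        horizon = regimen.last_dose_time + 336.0
    trough_time = regimen.last_dose_time + regimen.interval_h
    n = int(round(horizon / grid_step))
    times = np.linspace(0.0, n * grid_step, n + 1)
    chol = _omega_factor(pop)
    d = len(pop.iiv_names)
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(pop.sigma2) if include_residual else 0.0

    profiles = np.empty((n_subjects, times.size))
    rows = []
    for i in range(n_subjects):
        eta = chol @ rng.standard_normal(d) if d else np.zeros(0)
        params = individual_params(pop.theta, eta, pop.iiv_names)
        cp = concentration(params, doses, times).cp
        if sigma > 0.0:
            cp = cp * np.exp(rng.normal(0.0, sigma, cp.size))
        profiles[i] = cp
        j = int(np.argmax(cp))
        ctrough = float(concentration(params, doses, [trough_time]).cp[0])
        auc_h = float(cumulative_auc(params, doses, [horizon])[0])
        total_ug = sum(dv.amount * 1000.0 * params.depot_fraction(dv.depot)
                       for dv in doses)
        rows.append({"subject": i + 1, "cmax": float(cp[j]),
                     "tmax": float(times[j]), "ctrough": ctrough,
                     "auc_0_horizon": auc_h,
                     "auc_inf": total_ug / params.cl_f})
    metrics = pd.DataFrame(rows)
    summary = metrics.drop(columns="subject").quantile([0.05, 0.5, 0.95])
    summary.index = ["p5", "median", "p95"]
    p = np.percentile(profiles, _PCTS, axis=0)
    profile = pd.DataFrame({"time": times, "p5": p[0], "p50": p[1],
                            "p95": p[2]})
    return RegimenResult(regimen=regimen, metrics=metrics, summary=summary,
                         profile=profile, lloq=lloq)


# ---------------------------------------------------------------------------
# plots


def vpc_plot(result: VpcResult, path=None, *, log_scale: bool = True):
    """One panel per treatment: observed percentile lines over simulated
    bands, with the LLOQ reference line."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    groups = list(result.table.groupby("treatment"))
    fig, axes = plt.subplots(len(groups), 1,
                             figsize=(7, 3.2 * len(groups)), squeeze=False)
    for ax, (code, tab) in zip(axes[:, 0], groups):
        for p, color in (("p5", "tab:blue"), ("p50", "tab:red"),
                         ("p95", "tab:blue")):
            ax.fill_between(tab["time"], tab[f"{p}_lo"], tab[f"{p}_hi"],
                            alpha=0.25, color=color, linewidth=0)
            ax.plot(tab["time"], tab[f"obs_{p}"], "-o", ms=3, color=color,
                    label=f"observed {p}")
        ax.axhline(result.lloq, ls=":", color="k", lw=1, label="LLOQ")
        if log_scale:
            ax.set_yscale("log")
        ax.set_title(f"{result.drug} treatment {code}")
        ax.set_xlabel("time since dose (h)")
        ax.set_ylabel("concentration (ng/mL)")
    axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def regimen_plot(results: Sequence[RegimenResult], path=None, *,
                 log_scale: bool = True):
    """Median with 5th-95th percentile band per regimen, LLOQ marked."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 5))
    for res in results:
        label = res.regimen.formulation
        line, = ax.plot(res.profile["time"], res.profile["p50"], label=label)
        ax.fill_between(res.profile["time"], res.profile["p5"],
                        res.profile["p95"], alpha=0.2,
                        color=line.get_color(), linewidth=0)
    ax.axhline(results[0].lloq, ls=":", color="k", lw=1, label="LLOQ")
    if log_scale:
        ax.set_yscale("log")
        ax.set_ylim(bottom=results[0].lloq / 10.0)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("concentration (ng/mL)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
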