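"""Batch-adsorption analytics: removal, capacity, kinetics, isotherms,
imprinting/selectivity factors and reusability.

All primary fits are the field-standard linearizations, solved by ordinary
least squares, with the goodness-of-fit R^2 quoted on the linearized axes;
a nonlinear least-squares refit of the closed form is reported alongside as
a secondary check. Logarithms are base 10 throughout (the 2.303 factor in
the pseudo-first-order linearization is ln 10).

Kinetic models (Q in mg/cm^2, t in min):

    PFO   log10(Qe - Qt) = log10(Qe) - k1 t / 2.303
    PSO   t/Qt = 1/(k2 Qe^2) + t/Qe
    IPD   Qt = kid sqrt(t) + C          (fit window default 10-60 min)

Isotherms (Ce in mg/L):

    Langmuir     Ce/Qe = Ce/Qm + 1/(b Qm)
    Freundlich   log10 Qe = (1/n) log10 Ce + log10 Kf
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import synthetic

__all__ = [
    "BatchAdsorptionRecord",
    "BeerLambertCalibration",
    "KineticFitResult",
    "IsothermFitResult",
    "SelectivityResult",
    "removal_percent",
    "adsorption_capacity",
    "absorbance_to_concentration",
    "fit_kinetics",
    "fit_isotherm",
    "imprinting_factor",
    "selectivity_factor",
    "selectivity_analysis",
    "reusability_profile",
]


@dataclass(frozen=True)
class BatchAdsorptionRecord:
    """One batch observation: initial and equilibrium concentration (mg/L),
    solution volume (L) and plate area (cm^2)."""

    Co: float
    Ce: float
    V: float = 0.010
    A: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        for name, v in (("Co", self.Co), ("Ce", self.Ce), ("V", self.V), ("A", self.A)):
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.Ce > self.Co:
            warnings.warn(
                f"record {self.label!r}: Ce={self.Ce} exceeds Co={self.Co} "
                "(apparent negative uptake)",
                stacklevel=2,
            )


def removal_percent(rec: BatchAdsorptionRecord, convention: str = "standard") -> float:
    """Percentage of analyte removed from solution.

    ``standard`` (default) divides the depletion by the initial
    concentration, 100 (Co - Ce)/Co, which is bounded by 100 whenever
    Ce <= Co. ``as_printed`` divides by the equilibrium concentration
    instead, 100 (Co - Ce)/Ce; it is kept for fidelity with that written
    form but exceeds 100 for any removal above half.
    """
    if convention == "standard":
        if rec.Co == 0:
            raise ValueError("Co must be > 0 for the standard removal convention")
        return 100.0 * (rec.Co - rec.Ce) / rec.Co
    if convention == "as_printed":
        if rec.Ce == 0:
            raise ValueError("Ce must be > 0 for the as_printed removal convention")
        return 100.0 * (rec.Co - rec.Ce) / rec.Ce
    raise ValueError(f"unknown convention {convention!r}; use 'standard' or 'as_printed'")


def adsorption_capacity(rec: BatchAdsorptionRecord) -> float:
    """Adsorbed amount per plate area, Q = (Co - Ce) V / A, in mg/cm^2."""
    if rec.V <= 0 or rec.A <= 0:
        raise ValueError(f"V and A must be > 0, got V={rec.V}, A={rec.A}")
    return (rec.Co - rec.Ce) * rec.V / rec.A


@dataclass(frozen=True)
class BeerLambertCalibration:
    """Linear absorbance-vs-concentration calibration (427 nm for tartrazine)."""

    slope: float
    intercept: float = 0.0
    valid_range: tuple[float, float] = (0.0, np.inf)

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"calibration slope must be > 0, got {self.slope}")


def absorbance_to_concentration(
    absorbances: np.ndarray, cal: BeerLambertCalibration
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the calibration line: C = (A - intercept)/slope.

    Returns (concentrations, out_of_range_mask); out-of-range absorbances
    are flagged but still converted.
    """
    a = np.asarray(absorbances, dtype=float)
    conc = (a - cal.intercept) / cal.slope
    lo, hi = cal.valid_range
    flagged = (a < lo) | (a > hi)
    return conc, flagged


# ---------------------------------------------------------------------------
# kinetic fits


@dataclass
class KineticFitResult:
    model: str
    params: dict[str, float]
    r2: float
    q_exp: float | None = None
    window: tuple[float, float] | None = None
    n_points: int = 0
    nonlinear: dict[str, float] = field(default_factory=dict)
    r2_nonlinear: float | None = None

    @property
    def q_cal(self) -> float | None:
        return self.params.get("Q_cal")


def _linregress(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def _nonlinear_r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


def fit_kinetics(
    data: pd.DataFrame,
    model: str,
    window: tuple[float, float] | None = None,
    Qe_exp: float | None = None,
    nonlinear_refit: bool = True,
) -> KineticFitResult:
    """Fit one kinetic model to an uptake curve by its linearization.

    ``data`` needs columns ``t_min`` and ``Qt_mg_per_cm2``. For the PFO
    model the equilibrium capacity enters the linearization; by default the
    last (plateau) observation is used, and any point whose residual
    capacity Qe - Qt is non-positive is dropped with a warning. The IPD
    model is fitted on the 10-60 min window by default, the regime where
    uptake is diffusion-controlled.
    """
    if model not in {"PFO", "PSO", "IPD"}:
        raise ValueError(f"unknown kinetic model {model!r}")
    t_all = data["t_min"].to_numpy(dtype=float)
    q_all = data["Qt_mg_per_cm2"].to_numpy(dtype=float)

    if window is None and model == "IPD":
        window = (10.0, 60.0)
    if window is not None:
        mask = (t_all >= window[0]) & (t_all <= window[1])
    else:
        mask = np.ones_like(t_all, dtype=bool)
    t, q = t_all[mask], q_all[mask]
    if t.size < 3:
        raise ValueError(
            f"need at least 3 points in the fit window, got {t.size}"
        )

    if model == "PFO":
        qe = float(Qe_exp) if Qe_exp is not None else float(q_all[-1])
        resid = qe - q
        usable = resid > 0
        if not usable.all():
            warnings.warn(
                f"PFO: dropping {int((~usable).sum())} point(s) with "
                "Qe_exp - Qt <= 0 (log undefined)",
                stacklevel=2,
            )
        if usable.sum() < 3:
            raise ValueError(
                "PFO linearization needs >= 3 points with Qe_exp > Qt; "
                f"only {int(usable.sum())} usable"
            )
        slope, intercept, r2 = _linregress(t[usable], np.log10(resid[usable]))
        params = {"k1": -2.303 * slope, "Q_cal": 10.0**intercept}
        result = KineticFitResult(
            model="PFO", params=params, r2=r2, q_exp=qe,
            window=window, n_points=int(usable.sum()),
        )
        if nonlinear_refit:
            try:
                popt, _ = optimize.curve_fit(
                    synthetic.pfo_curve, t, q,
                    p0=[max(params["Q_cal"], 1e-6), max(params["k1"], 1e-6)],
                    maxfev=10000,
                )
                result.nonlinear = {"Qe": float(popt[0]), "k1": float(popt[1])}
                result.r2_nonlinear = _nonlinear_r2(q, synthetic.pfo_curve(t, *popt))
            except RuntimeError:
                pass
        return result

    if model == "PSO":
        if np.any(q <= 0):
            raise ValueError("PSO linearization requires Qt > 0 at every point")
        slope, intercept, r2 = _linregress(t, t / q)
        if intercept <= 0:
            warnings.warn("PSO: non-positive intercept; k2 is not physically valid",
                          stacklevel=2)
        qe = 1.0 / slope
        params = {"k2": slope**2 / intercept, "Q_cal": qe}
        result = KineticFitResult(
            model="PSO", params=params, r2=r2,
            q_exp=float(q_all[-1]), window=window, n_points=int(t.size),
        )
        if nonlinear_refit:
            try:
                popt, _ = optimize.curve_fit(
                    synthetic.pso_curve, t, q,
                    p0=[abs(qe), abs(params["k2"])], maxfev=10000,
                )
                result.nonlinear = {"Qe": float(popt[0]), "k2": float(popt[1])}
                result.r2_nonlinear = _nonlinear_r2(q, synthetic.pso_curve(t, *popt))
            except RuntimeError:
                pass
        return result

    # IPD
    slope, intercept, r2 = _linregress(np.sqrt(t), q)
    params = {"kid": slope, "C": intercept}
    result = KineticFitResult(
        model="IPD", params=params, r2=r2,
        q_exp=float(q_all[-1]), window=window, n_points=int(t.size),
    )
    if nonlinear_refit:
        result.nonlinear = dict(params)  # the model is linear in sqrt(t) already
        result.r2_nonlinear = _nonlinear_r2(q, synthetic.ipd_curve(t, slope, intercept))
    return result


# ---------------------------------------------------------------------------
# isotherm fits


@dataclass
class IsothermFitResult:
    model: str
    params: dict[str, float]
    r2: float
    favorable: bool | None = None  # Freundlich: 1/n in (0, 1)
    nonlinear: dict[str, float] = field(default_factory=dict)
    r2_nonlinear: float | None = None


def fit_isotherm(
    data: pd.DataFrame, model: str, nonlinear_refit: bool = True
) -> IsothermFitResult:
    """Fit the Langmuir or Freundlich isotherm by its linearization.

    ``data`` needs columns ``Ce_mg_per_L`` and ``Qe_mg_per_cm2``, all
    strictly positive (both linearizations divide by or take logs of the
    observations).
    """
    if model not in {"Langmuir", "Freundlich"}:
        raise ValueError(f"unknown isotherm model {model!r}")
    ce = data["Ce_mg_per_L"].to_numpy(dtype=float)
    qe = data["Qe_mg_per_cm2"].to_numpy(dtype=float)
    if ce.size < 3:
        raise ValueError(f"need at least 3 points, got {ce.size}")
    if np.any(ce <= 0) or np.any(qe <= 0):
        raise ValueError(f"{model} linearization requires strictly positive Ce and Qe")

    if model == "Langmuir":
        slope, intercept, r2 = _linregress(ce, ce / qe)
        if intercept == 0:
            raise ValueError("Langmuir linearization yielded zero intercept")
        params = {"Qm": 1.0 / slope, "b": slope / intercept}
        result = IsothermFitResult(model="Langmuir", params=params, r2=r2)
        if nonlinear_refit:
            try:
                popt, _ = optimize.curve_fit(
                    synthetic.langmuir_curve, ce, qe,
                    p0=[abs(params["Qm"]), abs(params["b"])], maxfev=10000,
                )
                result.nonlinear = {"Qm": float(popt[0]), "b": float(popt[1])}
                result.r2_nonlinear = _nonlinear_r2(qe, synthetic.langmuir_curve(ce, *popt))
            except RuntimeError:
                pass
        return result

    slope, intercept, r2 = _linregress(np.log10(ce), np.log10(qe))
    if slope == 0:
        raise ValueError("Freundlich linearization yielded zero slope")
    n = 1.0 / slope
    params = {"Kf": 10.0**intercept, "n": n}
    result = IsothermFitResult(
        model="Freundlich", params=params, r2=r2, favorable=0 < slope < 1
    )
    if nonlinear_refit:
        try:
            popt, _ = optimize.curve_fit(
                synthetic.freundlich_curve, ce, qe,
                p0=[params["Kf"], abs(n)], maxfev=10000,
            )
            result.nonlinear = {"Kf": float(popt[0]), "n": float(popt[1])}
            result.r2_nonlinear = _nonlinear_r2(qe, synthetic.freundlich_curve(ce, *popt))
        except RuntimeError:
            pass
    return result


# ---------------------------------------------------------------------------
# selectivity


def imprinting_factor(removal_mip: float, removal_nip: float) -> float:
    """Imprinting factor alpha = %removal(MIP) / %removal(NIP)."""
    if removal_nip <= 0:
        raise ValueError(f"NIP removal must be > 0, got {removal_nip}")
    return removal_mip / removal_nip


def selectivity_factor(alpha_template: float, alpha_interferent: float) -> float:
    """Selectivity factor beta = alpha(template) / alpha(interferent)."""
    if alpha_interferent <= 0:
        raise ValueError(f"interferent alpha must be > 0, got {alpha_interferent}")
    return alpha_template / alpha_interferent


@dataclass
class SelectivityResult:
    template: str
    removal_mip: dict[str, float]
    removal_nip: dict[str, float]
    alpha: dict[str, float]
    beta: dict[str, float]


def selectivity_analysis(
    records: pd.DataFrame | list[BatchAdsorptionRecord],
    template: str,
    convention: str = "standard",
) -> SelectivityResult:
    """Imprinting and selectivity factors from paired MIP/NIP batch records.

    Input rows need ``label`` (dye name), ``sorbent`` (MIP or NIP), ``Co``
    and ``Ce`` (plus V_L/A_cm2, unused here). Beta is computed relative to
    the named template dye; beta(template) = 1 exactly.
    """
    if isinstance(records, list):
        df = pd.DataFrame(
            {"label": r.label, "sorbent": "", "Co": r.Co, "Ce": r.Ce} for r in records
        )
    else:
        df = records
    removal_mip: dict[str, float] = {}
    removal_nip: dict[str, float] = {}
    for (dye, sorbent), grp in df.groupby(["label", "sorbent"]):
        rec = BatchAdsorptionRecord(
            Co=float(grp["Co"].mean()), Ce=float(grp["Ce"].mean()), label=str(dye)
        )
        target = removal_mip if sorbent == "MIP" else removal_nip
        target[str(dye)] = removal_percent(rec, convention)
    if set(removal_mip) != set(removal_nip):
        raise ValueError(
            "each dye needs both a MIP and a NIP record; got MIP for "
            f"{sorted(removal_mip)}, NIP for {sorted(removal_nip)}"
        )
    if template not in removal_mip:
        raise ValueError(f"template dye {template!r} not among {sorted(removal_mip)}")
    alpha = {
        dye: imprinting_factor(removal_mip[dye], removal_nip[dye]) for dye in removal_mip
    }
    beta = {
        dye: selectivity_factor(alpha[template], alpha[dye]) for dye in alpha
    }
    return SelectivityResult(
        template=template,
        removal_mip=removal_mip,
        removal_nip=removal_nip,
        alpha=alpha,
        beta=beta,
    )


# ---------------------------------------------------------------------------
# reusability


@dataclass
class ReusabilityProfile:
    removals: list[float]  # per cycle, in cycle order
    drop_cycle: int | None  # 1-based first cycle below threshold, or None
    threshold_fraction: float


def reusability_profile(
    records: list[BatchAdsorptionRecord],
    delta: float = 0.10,
    convention: str = "standard",
) -> ReusabilityProfile:
    """Per-cycle removal and the first cycle showing a material drop.

    The drop cycle is the first whose removal falls below (1 - delta) times
    the first cycle's removal; None when no cycle does.
    """
    if len(records) < 2:
        raise ValueError(f"need at least 2 cycles, got {len(records)}")
    removals = [removal_percent(r, convention) for r in records]
    threshold = (1.0 - delta) * removals[0]
    drop = next(
        (i + 1 for i, r in enumerate(removals) if r < threshold), None
    )
    return ReusabilityProfile(
        removals=removals, drop_cycle=drop, threshold_fraction=delta
    )
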