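"""Fluorescence-polarization binding models and fits.

Saturation binding of a fluorescent probe to a receptor follows

    Y = Bmax * X^h / (Kd^h + X^h) + Background

with Y in millipolarization units (mp), X the receptor concentration (uM),
and h an optional Hill coefficient (the free-ligand approximation: the
probe is held far below 10x Kd, so total receptor ~ free receptor). The fit
is run with h fixed at 1 and, on request, with h free, to check h ~ 1.

Competitive displacement is modelled by the exact two-ligand / one-site
equilibrium: mass balances for receptor R, probe L and competitor C with
dissociation constants Kd_probe and Ki are solved for free receptor, and
Y = Background + Bmax * (bound probe fraction). Ki is fitted by nonlinear
least squares; IC50 is located numerically on the fitted curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "BindingCurve", "SaturationFitResult", "HillComparison",
    "CompetitionFitResult", "saturation_model", "fit_saturation",
    "solve_competitive_equilibrium", "competition_signal", "fit_competition",
    "read_fp_csv", "write_fp_csv",
]


@dataclass
class BindingCurve:
    """Concentration-polarization data, possibly replicated.

    ``X`` is receptor concentration for saturation curves or competitor
    concentration for competition curves, in uM; ``Y`` in mp.
    """

    X: np.ndarray
    Y: np.ndarray
    replicate: np.ndarray | None = None
    role: str = "saturation"        # "saturation" | "competition"
    probe_conc_nM: float = 50.0
    receptor_conc_uM: float | None = None   # competition only

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.shape != self.Y.shape:
            raise ValueError("X and Y must have matching shapes")
        if np.any(self.X < 0) or not np.all(np.isfinite(self.Y)):
            raise ValueError("X must be >= 0 and Y finite")
        if len(np.unique(self.X)) < 4:
            raise ValueError("at least 4 distinct concentrations required")


def saturation_model(X, Kd: float, Bmax: float, Background: float, h: float = 1.0):
    """Single-site (optionally Hill) saturation binding, Y in mp."""
    if Kd <= 0:
        raise ValueError(f"Kd must be > 0, got {Kd}")
    X = np.asarray(X, dtype=float)
    Xh = np.power(X, h)
    return Bmax * Xh / (Kd**h + Xh) + Background


@dataclass
class HillComparison:
    """Hill-variant fit and its comparison against the h = 1 model."""

    h: float
    h_se: float
    kd: float
    rss_fixed: float
    rss_hill: float
    f_stat: float
    p_value: float


@dataclass
class SaturationFitResult:
    kd: float                       # uM
    bmax: float                     # mp
    background: float               # mp
    kd_se: float
    bmax_se: float
    background_se: float
    rss: float
    n: int
    converged: bool
    hill: HillComparison | None = None
    message: str = ""


def _initial_saturation_guess(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    bg0 = float(np.min(y))
    bmax0 = float(np.max(y) - np.min(y)) or 1.0
    half = bg0 + bmax0 / 2.0
    xs = np.unique(x)
    ymean = np.array([y[x == xi].mean() for xi in xs])
    kd0 = float(xs[np.argmin(np.abs(ymean - half))])
    if kd0 <= 0:
        kd0 = float(np.median(xs[xs > 0])) if np.any(xs > 0) else 1.0
    return kd0, bmax0, bg0


def fit_saturation(curve: BindingCurve, fit_hill: bool = False) -> SaturationFitResult:
    """Nonlinear least-squares fit of the saturation model on all replicate
    points. With ``fit_hill``, the Hill variant is fitted as well and
    compared to the h = 1 model by an extra-sum-of-squares F test; the
    primary parameters reported remain those of the h = 1 fit.

    Non-convergence is flagged on the result, not raised.
    """
    x, y = curve.X, curve.Y
    kd0, bmax0, bg0 = _initial_saturation_guess(x, y)
    n = len(x)

    def model3(x_, kd, bmax, bg):
        return bmax * x_ / (kd + x_) + bg

    try:
        popt, pcov = optimize.curve_fit(
            model3, x, y, p0=[kd0, bmax0, bg0],
            bounds=([1e-12, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
        se = np.sqrt(np.diag(pcov))
        rss = float(np.sum((y - model3(x, *popt)) ** 2))
        result = SaturationFitResult(
            kd=float(popt[0]), bmax=float(popt[1]), background=float(popt[2]),
            kd_se=float(se[0]), bmax_se=float(se[1]), background_se=float(se[2]),
            rss=rss, n=n, converged=True,
        )
    except RuntimeError as exc:
        return SaturationFitResult(
            kd=kd0, bmax=bmax0, background=bg0,
            kd_se=np.nan, bmax_se=np.nan, background_se=np.nan,
            rss=np.nan, n=n, converged=False, message=str(exc),
        )

    if fit_hill:
        if len(np.unique(x)) < 5:
            raise ValueError("Hill fit requires >= 5 distinct concentrations")

        def model4(x_, kd, bmax, bg, h):
            xh = np.power(x_, h)
            return bmax * xh / (kd**h + xh) + bg

        try:
            popt4, pcov4 = optimize.curve_fit(
                model4, x, y, p0=[result.kd, result.bmax, result.background, 1.0],
                bounds=([1e-12, 1e-12, -np.inf, 1e-6], [np.inf, np.inf, np.inf, 10.0]),
                maxfev=20000,
            )
            se4 = np.sqrt(np.diag(pcov4))
            rss4 = float(np.sum((y - model4(x, *popt4)) ** 2))
            dof4 = n - 4
            if rss4 > 0 and dof4 > 0:
                f_stat = (result.rss - rss4) / (rss4 / dof4)
                f_stat = max(f_stat, 0.0)
                p_value = float(stats.f.sf(f_stat, 1, dof4))
            else:
                f_stat, p_value = np.nan, np.nan
            result.hill = HillComparison(
                h=float(popt4[3]), h_se=float(se4[3]), kd=float(popt4[0]),
                rss_fixed=result.rss, rss_hill=rss4,
                f_stat=float(f_stat), p_value=p_value,
            )
        except RuntimeError as exc:
            result.message = f"Hill fit failed: {exc}"
    return result


# ---------------------------------------------------------------------------
# Competitive equilibrium
# ---------------------------------------------------------------------------

def solve_competitive_equilibrium(
    C_uM: float, Ki: float, Kd_probe: float, L_tot_nM: float, R_tot_uM: float
) -> dict[str, float]:
    """Exact two-ligand / one-site equilibrium at one competitor level.

    Solves the free-receptor mass balance
        R + L_tot*R/(Kd+R) + C_tot*R/(Ki+R) = R_tot
    by bracketed root finding (the left side is strictly increasing in R,
    so the root on [0, R_tot] is unique). Concentrations in uM internally;
    the probe total is given in nM. Returns free/bound species.
    """
    if Ki <= 0 or Kd_probe <= 0 or L_tot_nM <= 0 or R_tot_uM <= 0 or C_uM < 0:
        raise ValueError("all constants must be > 0 (competitor >= 0)")
    L_tot = L_tot_nM / 1000.0
    C_tot = float(C_uM)

    def g(R: float) -> float:
        return R + L_tot * R / (Kd_probe + R) + C_tot * R / (Ki + R) - R_tot_uM

    R_free = optimize.brentq(g, 0.0, R_tot_uM, xtol=1e-15, rtol=1e-14, maxiter=200)
    RL = L_tot * R_free / (Kd_probe + R_free)
    RC = C_tot * R_free / (Ki + R_free)
    return {
        "R_free": R_free,
        "L_free": L_tot - RL,
        "C_free": C_tot - RC,
        "RL": RL,
        "RC": RC,
        "bound_probe_fraction": RL / L_tot,
    }


def competition_signal(
    C_uM, Ki: float, Kd_probe: float, L_tot_nM: float = 50.0,
    R_tot_uM: float = 1.0, Bmax: float = 150.0, Background: float = 50.0,
):
    """Predicted polarization of the probe across competitor concentrations:
    Y = Background + Bmax * (bound probe fraction), strictly decreasing in
    the competitor concentration."""
    C = np.atleast_1d(np.asarray(C_uM, dtype=float))
    frac = np.array(
        [
            solve_competitive_equilibrium(c, Ki, Kd_probe, L_tot_nM, R_tot_uM)[
                "bound_probe_fraction"
            ]
            for c in C
        ]
    )
    y = Background + Bmax * frac
    return y if np.ndim(C_uM) else float(y[0])


@dataclass
class CompetitionFitResult:
    ki: float                       # uM
    ki_se: float
    ic50: float                     # uM
    bmax: float
    background: float
    rss: float
    n: int
    converged: bool
    identifiable: bool = True
    ki_lower_bound: float | None = None
    kd_probe: float = np.nan
    l_tot_nM: float = np.nan
    r_tot_uM: float = np.nan
    message: str = ""


def _ic50_from_fit(
    ki: float, kd_probe: float, l_tot_nM: float, r_tot_uM: float,
    bmax: float, background: float,
) -> float:
    """Competitor concentration at the midpoint of the fitted curve's
    zero-competitor-to-background span, located numerically."""
    y0 = competition_signal(0.0, ki, kd_probe, l_tot_nM, r_tot_uM, bmax, background)
    target = (y0 + background) / 2.0

    def f(log_c: float) -> float:
        return (
            competition_signal(10.0**log_c, ki, kd_probe, l_tot_nM, r_tot_uM,
                               bmax, background)
            - target
        )

    lo, hi = -9.0, 9.0
    while f(hi) > 0 and hi < 15:
        hi += 3
    return float(10.0 ** optimize.brentq(f, lo, hi, xtol=1e-12))


def fit_competition(
    curve: BindingCurve,
    Kd_probe: float,
    fix_bmax: float | None = None,
    fix_background: float | None = None,
) -> CompetitionFitResult:
    """Least-squares fit of Ki (plus Bmax and Background unless fixed) to a
    competitive-displacement curve; IC50 derived from the fitted curve.

    When the fitted Ki exceeds the top competitor concentration, the curve
    carries no lower plateau and Ki is not identifiable; the result is
    flagged and the top concentration reported as a Ki lower bound.
    """
    if curve.role != "competition":
        raise ValueError("curve role must be 'competition'")
    if curve.receptor_conc_uM is None:
        raise ValueError("competition curve requires receptor_conc_uM")
    x, y = curve.X, curve.Y
    l_tot, r_tot = curve.probe_conc_nM, curve.receptor_conc_uM

    bmax0 = fix_bmax if fix_bmax is not None else float(np.max(y) - np.min(y)) or 1.0
    bg0 = fix_background if fix_background is not None else float(np.min(y))
    pos = x[x > 0]
    half = (np.max(y) + np.min(y)) / 2.0
    ki0 = float(pos[np.argmin(np.abs(y[x > 0] - half))]) if len(pos) else 1.0

    def model(x_, log_ki, bmax, bg):
        return competition_signal(x_, 10.0**log_ki, Kd_probe, l_tot, r_tot, bmax, bg)

    free = ["log_ki"]
    p0 = [np.log10(ki0)]
    lower, upper = [-9.0], [9.0]
    if fix_bmax is None:
        free.append("bmax"); p0.append(bmax0); lower.append(1e-12); upper.append(np.inf)
    if fix_background is None:
        free.append("bg"); p0.append(bg0); lower.append(-np.inf); upper.append(np.inf)

    def wrapped(x_, *params):
        d = dict(zip(free, params))
        return model(
            x_, d["log_ki"],
            d.get("bmax", fix_bmax), d.get("bg", fix_background),
        )

    n = len(x)
    try:
        popt, pcov = optimize.curve_fit(
            wrapped, x, y, p0=p0, bounds=(lower, upper), maxfev=5000
        )
    except RuntimeError as exc:
        return CompetitionFitResult(
            ki=10.0**p0[0], ki_se=np.nan, ic50=np.nan, bmax=bmax0, background=bg0,
            rss=np.nan, n=n, converged=False, kd_probe=Kd_probe,
            l_tot_nM=l_tot, r_tot_uM=r_tot, message=str(exc),
        )
    d = dict(zip(free, popt))
    se = dict(zip(free, np.sqrt(np.diag(pcov))))
    ki = float(10.0 ** d["log_ki"])
    # delta method: SE(Ki) = ln(10) * Ki * SE(log10 Ki)
    ki_se = float(np.log(10) * ki * se["log_ki"])
    bmax = float(d.get("bmax", fix_bmax))
    bg = float(d.get("bg", fix_background))
    rss = float(np.sum((y - wrapped(x, *popt)) ** 2))
    top = float(np.max(x))
    # identifiability: Ki must sit below the top tested concentration and the
    # fitted displacement across the tested range must clear the noise floor
    # (a weak binder leaves an essentially flat curve, which the optimizer
    # can also explain with a degenerate fully-displaced model)
    n_par = len(popt)
    resid_sd = np.sqrt(rss / max(n - n_par, 1))
    span = float(wrapped(np.array([0.0]), *popt)[0] - wrapped(np.array([top]), *popt)[0])
    observed_span = float(np.mean(y[x == np.min(x)]) - np.mean(y[x == top]))
    identifiable = ki <= top and max(span, observed_span) > 3 * resid_sd
    ic50 = _ic50_from_fit(ki, Kd_probe, l_tot, r_tot, bmax, bg)
    return CompetitionFitResult(
        ki=ki, ki_se=ki_se, ic50=ic50, bmax=bmax, background=bg, rss=rss, n=n,
        converged=True, identifiable=identifiable,
        ki_lower_bound=None if identifiable else top,
        kd_probe=Kd_probe, l_tot_nM=l_tot, r_tot_uM=r_tot,
        message="" if identifiable else
        f"Ki exceeds the top competitor concentration ({top:g} uM); "
        f"report as Ki > {top:g} uM",
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fp_csv(
    path: str | Path,
    role: str = "saturation",
    probe_conc_nM: float = 50.0,
    receptor_conc_uM: float | None = None,
) -> BindingCurve:
    """Read a concentration-polarization CSV with columns
    ``conc_uM, mp[, replicate]``."""
    frame = pd.read_csv(path)
    rep = frame["replicate"].to_numpy() if "replicate" in frame else None
    return BindingCurve(
        X=frame["conc_uM"].to_numpy(), Y=frame["mp"].to_numpy(), replicate=rep,
        role=role, probe_conc_nM=probe_conc_nM, receptor_conc_uM=receptor_conc_uM,
    )


def write_fp_csv(curve: BindingCurve, path: str | Path) -> None:
    frame = pd.DataFrame({"conc_uM": curve.X, "mp": curve.Y})
    if curve.replicate is not None:
        frame["replicate"] = curve.replicate
    frame.to_csv(path, index=False)
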