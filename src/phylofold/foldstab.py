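"""Two-state equilibrium unfolding and folding/unfolding kinetics.

Equilibrium denaturation curves (far-UV CD ellipticity vs denaturant
molarity) are fit with the six-parameter Santoro-Bolen model: linear native
and unfolded baselines connected by a two-state transition with free energy
linear in denaturant,

    y(D) = [(yN + mN*D) + (yU + mU*D) * K] / (1 + K),
    K = exp((m*D - dG) / (R*T)),

where dG is the unfolding free energy in water (kcal/mol), m the denaturant
dependence (kcal/mol/M) and Cm = dG/m the transition midpoint.  R is in kcal
units so dG comes out in kcal/mol.

Kinetic traces (stopped-flow or conventional CD) are fit as sums of one or
two exponentials after excluding points inside the instrument dead time;
signal completed before the dead time (the burst phase) is quantified from
the fitted amplitude relative to the expected initial signal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "R_KCAL",
    "DenaturationCurve",
    "EquilibriumFit",
    "KineticTrace",
    "KineticFit",
    "santoro_bolen_signal",
    "fit_equilibrium",
    "fraction_unfolded",
    "delta_delta_g",
    "fit_kinetics",
    "burst_amplitude",
    "read_xy_tsv",
]

R_KCAL = 1.9872e-3  # gas constant, kcal / (mol K)


@dataclass
class DenaturationCurve:
    """Equilibrium unfolding data: denaturant (M) vs ellipticity."""

    denaturant: np.ndarray
    signal: np.ndarray
    temperature: float = 293.15  # K

    def __post_init__(self) -> None:
        self.denaturant = np.asarray(self.denaturant, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.denaturant.shape != self.signal.shape:
            raise ValueError("denaturant and signal lengths differ")
        if len(self.denaturant) < 8:
            raise ValueError("need at least 8 points")
        if np.any(self.denaturant < 0):
            raise ValueError("denaturant concentrations must be non-negative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        order = np.argsort(self.denaturant, kind="stable")
        self.denaturant = self.denaturant[order]
        self.signal = self.signal[order]


@dataclass
class EquilibriumFit:
    dG: float  # kcal/mol, unfolding free energy at 0 M denaturant
    m: float  # kcal/mol/M
    yN: float
    mN: float
    yU: float
    mU: float
    temperature: float
    stderr: dict = field(default_factory=dict)
    covariance: np.ndarray | None = None
    baselines_ok: bool = True

    @property
    def Cm(self) -> float:
        return self.dG / self.m

    @property
    def Cm_stderr(self) -> float | None:
        """First-order propagated error of Cm = dG/m."""
        if self.covariance is None:
            return None
        g = np.array([1.0 / self.m, -self.dG / self.m**2, 0, 0, 0, 0])
        var = float(g @ self.covariance @ g)
        return np.sqrt(var) if var >= 0 else None

    def to_dict(self) -> dict:
        return {
            "dG_kcal_mol": self.dG,
            "m_kcal_mol_M": self.m,
            "Cm_M": self.Cm,
            "yN": self.yN,
            "mN": self.mN,
            "yU": self.yU,
            "mU": self.mU,
            "temperature_K": self.temperature,
            "stderr": self.stderr,
            "Cm_stderr_M": self.Cm_stderr,
            "baselines_ok": self.baselines_ok,
        }


def santoro_bolen_signal(D, dG, m, yN, mN, yU, mU, T=293.15):
    """Two-state linear-extrapolation signal at denaturant concentration D."""
    D = np.asarray(D, dtype=float)
    K = np.exp((m * D - dG) / (R_KCAL * T))
    return ((yN + mN * D) + (yU + mU * D) * K) / (1.0 + K)


def _initial_guess(curve: DenaturationCurve) -> list[float]:
    D, y = curve.denaturant, curve.signal
    # baselines from the first/last three points
    nfit = np.polyfit(D[:3], y[:3], 1)
    ufit = np.polyfit(D[-3:], y[-3:], 1)
    mN0, yN0 = nfit[0], nfit[1]
    mU0, yU0 = ufit[0], ufit[1]
    # Cm from where the signal crosses halfway between the baselines
    half = ((yN0 + mN0 * D) + (yU0 + mU0 * D)) / 2
    cross = np.nonzero(np.diff(np.sign(y - half)))[0]
    Cm0 = float(D[cross[0]]) if len(cross) else float(np.median(D))
    Cm0 = max(Cm0, 1e-3)
    m0 = 2.0  # kcal/mol/M, typical for a small protein
    return [m0 * Cm0, m0, yN0, mN0, yU0, mU0]


def fit_equilibrium(curve: DenaturationCurve) -> EquilibriumFit:
    """Six-parameter Santoro-Bolen nonlinear least-squares fit.

    The fit is flagged ``baselines_ok=False`` when fewer than 2 points fall
    in each baseline region (folded fraction > 0.9 / < 0.1 at the optimum).
    """
    T = curve.temperature
    p0 = _initial_guess(curve)

    def f(D, dG, m, yN, mN, yU, mU):
        return santoro_bolen_signal(D, dG, m, yN, mN, yU, mU, T)

    try:
        popt, pcov = curve_fit(
            f, curve.denaturant, curve.signal, p0=p0, maxfev=20000
        )
    except RuntimeError as e:
        raise RuntimeError(f"equilibrium fit did not converge: {e}") from e
    dG, m, yN, mN, yU, mU = (float(v) for v in popt)
    if m <= 0:
        raise ValueError("no cooperative transition: fitted m <= 0")
    K = np.exp((m * curve.denaturant - dG) / (R_KCAL * T))
    f_folded = 1.0 / (1.0 + K)
    ok = int(np.sum(f_folded > 0.9)) >= 2 and int(np.sum(f_folded < 0.1)) >= 2
    if not ok:
        warnings.warn(
            "poorly determined baselines: transition not bracketed by data",
            stacklevel=2,
        )
    perr = np.sqrt(np.diag(pcov))
    names = ["dG", "m", "yN", "mN", "yU", "mU"]
    return EquilibriumFit(
        dG=dG, m=m, yN=yN, mN=mN, yU=yU, mU=mU,
        temperature=T,
        stderr=dict(zip(names, (float(e) for e in perr))),
        covariance=pcov,
        baselines_ok=ok,
    )


def fraction_unfolded(
    curve: DenaturationCurve, fit: EquilibriumFit, clamp: bool = False
) -> np.ndarray:
    """fU = (y - yN(D)) / (yU(D) - yN(D)) per data point.

    Values may fall slightly outside [0, 1] because of noise; pass
    ``clamp=True`` to clip them.
    """
    D, y = curve.denaturant, curve.signal
    base_n = fit.yN + fit.mN * D
    base_u = fit.yU + fit.mU * D
    denom = base_u - base_n
    if np.any(np.abs(denom) < 1e-12):
        raise ValueError("degenerate baselines: native and unfolded coincide")
    fu = (y - base_n) / denom
    return np.clip(fu, 0.0, 1.0) if clamp else fu


def delta_delta_g(
    fit_a: EquilibriumFit, fit_b: EquilibriumFit
) -> dict[str, float]:
    """Stability difference (a minus b) by two routes.

    ``ddG_direct`` subtracts the fitted free energies; ``ddG_midpoint``
    multiplies the Cm shift by the mean m value, which is more robust when
    the baselines are poorly determined.  Errors are first-order propagated.
    """
    dd_direct = fit_a.dG - fit_b.dG
    mean_m = 0.5 * (fit_a.m + fit_b.m)
    dd_mid = mean_m * (fit_a.Cm - fit_b.Cm)
    err_direct = np.sqrt(
        fit_a.stderr.get("dG", 0.0) ** 2 + fit_b.stderr.get("dG", 0.0) ** 2
    )
    ca = fit_a.Cm_stderr or 0.0
    cb = fit_b.Cm_stderr or 0.0
    err_mid = mean_m * np.sqrt(ca**2 + cb**2)
    return {
        "ddG_direct": dd_direct,
        "ddG_direct_stderr": float(err_direct),
        "ddG_midpoint": dd_mid,
        "ddG_midpoint_stderr": float(err_mid),
        "Cm_shift": fit_a.Cm - fit_b.Cm,
    }


@dataclass
class KineticTrace:
    """A kinetic CD trace; points inside the dead time are excluded from fits."""

    time: np.ndarray
    signal: np.ndarray
    dead_time: float = 0.0  # s
    wavelength: float | None = None  # nm

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape:
            raise ValueError("time and signal lengths differ")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    def fit_window(self) -> tuple[np.ndarray, np.ndarray]:
        mask = self.time > self.dead_time
        return self.time[mask], self.signal[mask]


@dataclass
class KineticFit:
    phases: list[dict]  # each: {"k": s^-1, "amplitude", "k_stderr"}
    offset: float
    residual_rms: float
    no_signal: bool = False

    def to_dict(self) -> dict:
        return {
            "phases": self.phases,
            "offset": self.offset,
            "residual_rms": self.residual_rms,
            "no_signal": self.no_signal,
        }

    @property
    def rate_constants(self) -> list[float]:
        return [p["k"] for p in self.phases]

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        y = np.full_like(t, self.offset)
        for p in self.phases:
            y = y + p["amplitude"] * np.exp(-p["k"] * t)
        return y


def fit_kinetics(trace: KineticTrace, n_phases: int = 1) -> KineticFit:
    """Least-squares fit of offset + sum of decaying exponentials.

    Rates are initialized from a log-linear regression of |y - y_end| and
    reported sorted by decreasing rate.  A flat trace (amplitude within the
    noise floor) is returned with ``no_signal=True`` rather than an error.
    """
    if n_phases not in (1, 2):
        raise ValueError("n_phases must be 1 or 2")
    t, y = trace.fit_window()
    if len(t) < 10:
        raise ValueError("need at least 10 points after dead-time exclusion")

    offset0 = float(np.mean(y[-max(3, len(y) // 10):]))
    amp0 = float(y[0] - offset0)
    span = float(np.ptp(y))
    if span < 1e-12 or abs(amp0) < 1e-6 * max(abs(offset0), 1.0):
        return KineticFit(
            phases=[{"k": 0.0, "amplitude": 0.0, "k_stderr": float("nan")}],
            offset=offset0,
            residual_rms=float(np.std(y)),
            no_signal=True,
        )

    # log-linear initial rate from the decaying part of |y - offset|
    resid = np.abs(y - offset0)
    good = resid > 0.05 * np.max(resid)
    k0 = 1.0 / max(t[good][-1] - t[0], 1e-9)
    slope = np.polyfit(t[good], np.log(resid[good]), 1)[0]
    if slope < 0:
        k0 = -slope

    if n_phases == 1:
        def f(tt, k, a, c):
            return c + a * np.exp(-k * tt)

        p0 = [k0, amp0, offset0]
        bounds = ([1e-12, -np.inf, -np.inf], [np.inf, np.inf, np.inf])
    else:
        def f(tt, k1, a1, k2, a2, c):
            return c + a1 * np.exp(-k1 * tt) + a2 * np.exp(-k2 * tt)

        p0 = [k0 * 5, amp0 / 2, k0 / 2, amp0 / 2, offset0]
        bounds = (
            [1e-12, -np.inf, 1e-12, -np.inf, -np.inf],
            [np.inf, np.inf, np.inf, np.inf, np.inf],
        )

    try:
        popt, pcov = curve_fit(f, t, y, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as e:
        raise RuntimeError(f"kinetic fit did not converge: {e}") from e
    perr = np.sqrt(np.diag(pcov))
    if n_phases == 1:
        phases = [{"k": float(popt[0]), "amplitude": float(popt[1]),
                   "k_stderr": float(perr[0])}]
        offset = float(popt[2])
    else:
        phases = [
            {"k": float(popt[0]), "amplitude": float(popt[1]),
             "k_stderr": float(perr[0])},
            {"k": float(popt[2]), "amplitude": float(popt[3]),
             "k_stderr": float(perr[2])},
        ]
        offset = float(popt[4])
    phases.sort(key=lambda p: -p["k"])
    for p in phases:
        if p["k"] <= 2e-12:
            warnings.warn("fitted rate at optimizer bound", stacklevel=2)
    fit = KineticFit(phases=phases, offset=offset, residual_rms=0.0)
    fit.residual_rms = float(np.sqrt(np.mean((fit.predict(t) - y) ** 2)))
    return fit


def burst_amplitude(fit: KineticFit, expected_initial: float) -> float:
    """Fraction of the total expected amplitude lost in the dead time.

    (expected_initial - fitted y(0)) / (expected_initial - fitted offset).
    """
    total = expected_initial - fit.offset
    if abs(total) < 1e-12:
        raise ValueError("zero total amplitude")
    y0 = float(fit.predict(np.array([0.0]))[0])
    return (expected_initial - y0) / total


def read_xy_tsv(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Two-column TSV with '#' comments; '# key: value' lines become metadata.

    Recognized metadata keys: temperature_K, dead_time_s, wavelength_nm.
    """
    xs, ys = [], []
    meta: dict[str, float] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, val = body.split(":", 1)
                    try:
                        meta[key.strip()] = float(val)
                    except ValueError:
                        pass
                continue
            parts = line.replace(",", "\t").split()
            if len(parts) < 2:
                raise ValueError(f"{path}: expected two columns, got {line!r}")
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
    return np.asarray(xs), np.asarray(ys), meta


def read_denaturation_tsv(path: str | Path) -> DenaturationCurve:
    x, y, meta = read_xy_tsv(path)
    return DenaturationCurve(x, y, temperature=meta.get("temperature_K", 293.15))


def read_trace_tsv(path: str | Path) -> KineticTrace:
    x, y, meta = read_xy_tsv(path)
    return KineticTrace(
        x, y,
        dead_time=meta.get("dead_time_s", 0.0),
        wavelength=meta.get("wavelength_nm"),
    )
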