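"""Surface plasmon resonance: 1:1 Langmuir simulation, referencing, fitting.

The 1:1 interaction model is

    dR/dt = ka * C * (Rmax - R) - kd * R,        KD = kd / ka,

whose closed form during a constant-concentration injection is

    R(t)  = Req * (1 - exp(-(ka*C + kd) * t)),   Req = Rmax * C / (C + KD)

and after injection end (washout) R decays as R(t_end) * exp(-kd * (t - t_end)).
Units: ka in 1/(M*s), kd in 1/s, KD in M, responses in resonance units (RU).

Kinetic fitting is a global least squares over all curves of a titration for
(ka, kd, Rmax), parameterised in log-space (positivity by construction) with
a multi-start grid (ka 1e3..1e7, kd 1e-5..1e-1, 5x5); the grid is screened
by initial residual and the best few starts are refined.  Steady-state
(equilibrium) affinity fitting of Req versus C is provided separately.
Mass-transport limitation, baseline drift and bulk refractive-index jumps
are not modelled.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares


class FitError(RuntimeError):
    """Raised on non-convergence; carries the best residual seen."""

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual


class SaturatedDataError(ValueError):
    """All equilibrium responses equal: KD is unidentifiable."""


@dataclass(frozen=True)
class KineticParams:
    """1:1 Langmuir rate constants and saturation response."""

    ka: float  # 1/(M s)
    kd: float  # 1/s
    rmax: float  # RU

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.kd <= 0 or self.rmax <= 0:
            raise ValueError("ka, kd and rmax must all be > 0")

    @property
    def KD(self) -> float:
        """Equilibrium dissociation constant kd/ka, in M."""
        return self.kd / self.ka

    def req(self, concentration: float) -> float:
        """Equilibrium response at an analyte concentration (Langmuir isotherm)."""
        return self.rmax * concentration / (concentration + self.KD)


@dataclass
class Sensorgram:
    """Time-resolved SPR response at one analyte concentration."""

    concentration: float  # M
    times: np.ndarray  # s, strictly increasing
    response: np.ndarray  # RU
    t_inject_end: float  # s; association/dissociation boundary

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.times.shape != self.response.shape:
            raise ValueError("times and response must have the same length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (0 < self.t_inject_end <= (self.times[-1] if self.times.size else 0)):
            raise ValueError("t_inject_end must lie within the time range")


@dataclass
class FitResult:
    """Global-fit parameters plus per-titration KD dispersion."""

    params: KineticParams
    residual_rms: float
    per_curve_req: dict[float, float]
    n_titrations: int
    KD_mean: float
    KD_sd: float | None  # defined for >= 2 titrations only


def model_response(
    ka: float, kd: float, rmax: float, concentration: float,
    times: np.ndarray, t_inject_end: float,
) -> np.ndarray:
    """Closed-form 1:1 Langmuir response over association + dissociation."""
    times = np.asarray(times, dtype=float)
    kobs = ka * concentration + kd
    req = rmax * ka * concentration / kobs
    assoc = req * (1.0 - np.exp(-kobs * np.minimum(times, t_inject_end)))
    r_end = req * (1.0 - math.exp(-kobs * t_inject_end))
    dissoc = r_end * np.exp(-kd * np.maximum(times - t_inject_end, 0.0))
    return np.where(times <= t_inject_end, assoc, dissoc)


def simulate_sensorgram(
    params: KineticParams,
    concentration: float,
    t_assoc: float = 120.0,
    t_dissoc: float = 80.0,
    dt: float = 0.1,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Sensorgram:
    """Simulate one injection/washout cycle with additive Gaussian noise.

    Defaults mirror a 120-s injection sampled at 0.1 s with an 80-s
    dissociation phase (300 s is typical for slow-dissociating analytes).
    """
    if min(concentration, t_assoc, t_dissoc, dt) <= 0:
        raise ValueError("concentration, t_assoc, t_dissoc and dt must be > 0")
    if dt >= t_assoc or dt >= t_dissoc:
        raise ValueError("dt must be smaller than each phase duration")
    times = np.arange(0.0, t_assoc + t_dissoc + dt / 2, dt)
    response = model_response(params.ka, params.kd, params.rmax, concentration, times, t_assoc)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        response = response + rng.normal(0.0, noise_sd, size=times.size)
    return Sensorgram(concentration, times, response, t_assoc)


def double_reference(sample: Sensorgram, reference: Sensorgram, blank: Sensorgram) -> Sensorgram:
    """Double referencing: subtract empty-flow-cell and buffer-blank traces."""
    for other in (reference, blank):
        if other.times.shape != sample.times.shape or not np.allclose(other.times, sample.times):
            raise ValueError("sensorgram time grids do not match")
    return Sensorgram(
        sample.concentration,
        sample.times.copy(),
        sample.response - reference.response - blank.response,
        sample.t_inject_end,
    )


_KA_GRID = np.logspace(3, 7, 5)
_KD_GRID = np.logspace(-5, -1, 5)


def _stacked_residuals(theta: np.ndarray, sensorgrams: Sequence[Sensorgram]) -> np.ndarray:
    ka, kd, rmax = np.exp(theta)
    parts = [
        g.response - model_response(ka, kd, rmax, g.concentration, g.times, g.t_inject_end)
        for g in sensorgrams
    ]
    return np.concatenate(parts)


def fit_langmuir_kinetic(
    sensorgrams: Sequence[Sensorgram],
    init: KineticParams | None = None,
    n_refine: int = 3,
) -> FitResult:
    """Global 1:1 kinetic fit of one titration (>= 2 distinct concentrations).

    Log-parameterised least squares; starting points come from ``init`` if
    given, otherwise from the 5x5 (ka, kd) grid with Rmax seeded at 1.2x the
    largest observed response.  All grid points are screened by their initial
    residual and the ``n_refine`` best are optimised to relative tolerance
    1e-10 with at most 10 000 evaluations each.
    """
    concs = {g.concentration for g in sensorgrams}
    if len(concs) < 2:
        raise ValueError("kinetic fitting needs >= 2 distinct analyte concentrations")
    rmax0 = 1.2 * max(float(np.max(g.response)) for g in sensorgrams)
    if rmax0 <= 0:
        rmax0 = 1.0
    if init is not None:
        starts = [np.log([init.ka, init.kd, init.rmax])]
    else:
        cands = [
            np.log([ka, kd, rmax0]) for ka, kd in itertools.product(_KA_GRID, _KD_GRID)
        ]
        sses = [float(np.sum(_stacked_residuals(t, sensorgrams) ** 2)) for t in cands]
        order = np.argsort(sses)
        starts = [cands[i] for i in order[:n_refine]]

    best = None
    best_cost = math.inf
    for theta0 in starts:
        sol = least_squares(
            _stacked_residuals,
            theta0,
            args=(sensorgrams,),
            method="lm",
            xtol=1e-10,
            ftol=1e-10,
            gtol=1e-10,
            max_nfev=10_000,
        )
        if sol.cost < best_cost:
            best, best_cost = sol, sol.cost
    n_points = sum(g.times.size for g in sensorgrams)
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitError(
            "kinetic fit did not converge from any start",
            best_residual=math.sqrt(2 * best_cost / n_points) if best is not None else None,
        )
    ka, kd, rmax = np.exp(best.x)
    params = KineticParams(ka=float(ka), kd=float(kd), rmax=float(rmax))
    rms = math.sqrt(2 * best.cost / n_points)
    per_req = {g.concentration: params.req(g.concentration) for g in sensorgrams}
    return FitResult(
        params=params,
        residual_rms=rms,
        per_curve_req=per_req,
        n_titrations=1,
        KD_mean=params.KD,
        KD_sd=None,
    )


def fit_titrations(
    titrations: Sequence[Sequence[Sensorgram]],
    init: KineticParams | None = None,
) -> FitResult:
    """Fit each titration independently; report mean and SD of KD across them.

    The returned parameters are the global fit over the pooled curves; the
    KD dispersion comes from the per-titration fits (the reported
    "average KD and standard deviation from two titrations" convention).
    """
    if not titrations:
        raise ValueError("no titrations given")
    fits = [fit_langmuir_kinetic(t, init=init) for t in titrations]
    kds = [f.params.KD for f in fits]
    pooled = fit_langmuir_kinetic([g for t in titrations for g in t], init=init)
    return FitResult(
        params=pooled.params,
        residual_rms=pooled.residual_rms,
        per_curve_req=pooled.per_curve_req,
        n_titrations=len(titrations),
        KD_mean=float(np.mean(kds)),
        KD_sd=float(np.std(kds, ddof=1)) if len(kds) >= 2 else None,
    )


def fit_equilibrium(req_by_concentration: Mapping[float, float]) -> tuple[float, float]:
    """Steady-state affinity fit Req = Rmax * C / (C + KD); returns (KD, Rmax).

    Requires >= 3 concentrations spanning more than a 4-fold range.  A flat
    response profile (saturated or empty) raises rather than fitting silently.
    """
    concs = np.array(sorted(req_by_concentration), dtype=float)
    reqs = np.array([req_by_concentration[c] for c in concs], dtype=float)
    if concs.size < 3:
        raise ValueError("equilibrium fitting needs >= 3 concentrations")
    if concs[0] <= 0:
        raise ValueError("concentrations must be > 0")
    if concs[-1] / concs[0] <= 4.0:
        raise ValueError("concentrations must span more than a 4-fold range")
    if np.allclose(reqs, reqs[0], rtol=1e-6, atol=1e-12):
        raise SaturatedDataError(
            "equilibrium responses are flat: surface saturated or empty, KD unidentifiable"
        )

    def isotherm(c, kd, rmax):
        return rmax * c / (c + kd)

    p0 = (float(np.median(concs)), float(reqs.max() * 1.2))
    try:
        popt, _ = curve_fit(
            isotherm, concs, reqs, p0=p0,
            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10_000,
        )
    except RuntimeError as exc:
        raise FitError(f"equilibrium fit did not converge: {exc}") from exc
    return float(popt[0]), float(popt[1])


# ---------------------------------------------------------------------------
# TSV plumbing: columns time_s, response_RU, concentration_M, phase


def write_sensorgrams_tsv(sensorgrams: Sequence[Sensorgram], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("time_s\tresponse_RU\tconcentration_M\tphase\n")
        for g in sensorgrams:
            for t, r in zip(g.times, g.response):
                phase = "association" if t <= g.t_inject_end else "dissociation"
                fh.write(f"{t:.6g}\t{r:.8g}\t{g.concentration:.8g}\t{phase}\n")
    return path


def read_sensorgrams_tsv(path: str | Path) -> list[Sensorgram]:
    frame = pd.read_csv(path, sep="\t")
    required = {"time_s", "response_RU", "concentration_M", "phase"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"sensorgram TSV missing columns: {sorted(missing)}")
    out: list[Sensorgram] = []
    for conc, sub in frame.groupby("concentration_M", sort=True):
        sub = sub.sort_values("time_s")
        assoc = sub[sub["phase"] == "association"]
        if len(assoc) == 0:
            raise ValueError(f"no association phase for concentration {conc}")
        t_end = float(assoc["time_s"].max())
        out.append(
            Sensorgram(
                float(conc),
                sub["time_s"].to_numpy(float),
                sub["response_RU"].to_numpy(float),
                t_end,
            )
        )
    return out
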