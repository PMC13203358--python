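"""1:1 Langmuir SPR kinetics: simulation, referencing, fitting, inhibition.

A sensorgram records resonance response R(t) (RU) while an analyte at
concentration C flows over the immobilised ligand.  Under the 1:1 model

    dR/dt = ka * C * (Rmax - R) - kd * R

the association phase follows the closed form
R(t) = Req (1 - exp(-(ka C + kd)(t - t0))) with Req = Rmax C / (C + KD),
and the dissociation phase decays as R(t_end) exp(-kd (t - t_end)),
KD = kd / ka.  Fitting is global: one (ka, kd, Rmax) shared across all
concentrations, least squares over both phases, multi-start initialisation
on a log grid.  Double referencing and peptide-only subtraction are plain
aligned-grid subtractions, and percent binding compares end-of-association
responses of analyte + inhibitor mixtures against the analyte-only
control (defined as 100%).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "Sensorgram", "KineticFit", "InhibitionResult",
    "sensorgram_model", "simulate_sensorgram", "double_reference",
    "subtract_peptide_only", "fit_1to1_global", "percent_binding",
]


@dataclass
class Sensorgram:
    """One time/response curve with its injection annotations.

    times in s, response in RU, analyte concentration in mol/L.  role is
    one of {active, reference, blank, peptide_only, mixture}.
    """

    times: np.ndarray
    response: np.ndarray
    analyte_concentration: float
    association_start: float
    association_end: float
    dissociation_end: float
    label: str = ""
    role: str = "active"
    peptide_concentration: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.times.shape != self.response.shape:
            raise ValueError("times and response must match")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (self.association_start < self.association_end
                <= self.dissociation_end):
            raise ValueError("need association_start < association_end "
                             "<= dissociation_end")

    def response_at(self, t: float) -> float:
        """Response at the sample closest to time t."""
        return float(self.response[np.argmin(np.abs(self.times - t))])

    def end_of_association_response(self) -> float:
        return self.response_at(self.association_end)


@dataclass(frozen=True)
class KineticFit:
    """Globally fitted 1:1 parameters; KD = kd/ka by construction."""

    ka: float        # 1/(M s)
    kd: float        # 1/s
    Rmax: float      # RU
    rss_per_curve: tuple[float, ...]
    converged: bool
    n_starts: int = 0

    def __post_init__(self) -> None:
        if min(self.ka, self.kd, self.Rmax) <= 0:
            raise ValueError("ka, kd and Rmax must be positive")

    @property
    def KD(self) -> float:
        return self.kd / self.ka

    @property
    def rss(self) -> float:
        return float(sum(self.rss_per_curve))


@dataclass(frozen=True)
class InhibitionResult:
    """Percent binding of one peptide concentration vs the control."""

    peptide_label: str
    peptide_concentration: float
    percent_binding: float
    replicate_values: tuple[float, ...]
    sd: float


def sensorgram_model(times: np.ndarray, ka: float, kd: float, Rmax: float,
                     C: float, association_start: float,
                     association_end: float) -> np.ndarray:
    """Closed-form two-phase 1:1 response on an arbitrary time grid."""
    times = np.asarray(times, dtype=float)
    r = np.zeros_like(times)
    if C > 0:
        kobs = ka * C + kd
        req = Rmax * C / (C + kd / ka)
        assoc = (times >= association_start) & (times <= association_end)
        r[assoc] = req * (1.0 - np.exp(-kobs * (times[assoc]
                                                - association_start)))
        r_end = req * (1.0 - np.exp(-kobs * (association_end
                                             - association_start)))
        dissoc = times > association_end
        r[dissoc] = r_end * np.exp(-kd * (times[dissoc] - association_end))
    return r


def simulate_sensorgram(ka: float, kd: float, Rmax: float, C: float,
                        association_start: float = 0.0,
                        association_end: float = 120.0,
                        dissociation_end: float = 300.0,
                        sampling_rate: float = 1.0,
                        noise_sigma: float = 0.0,
                        seed: int | None = None,
                        label: str = "", role: str = "active",
                        ) -> Sensorgram:
    """Simulate a noisy 1:1 sensorgram; deterministic given the seed.

    noise_sigma is the standard deviation (RU) of additive Gaussian noise.
    """
    if min(ka, kd, Rmax) <= 0 or C < 0:
        raise ValueError("ka, kd, Rmax must be positive and C >= 0")
    times = np.arange(association_start, dissociation_end + 0.5 / sampling_rate,
                      1.0 / sampling_rate)
    r = sensorgram_model(times, ka, kd, Rmax, C, association_start,
                         association_end)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        r = r + rng.normal(0.0, noise_sigma, size=times.shape)
    return Sensorgram(times, r, C, association_start, association_end,
                      dissociation_end, label=label, role=role)


def _check_grids(a: Sensorgram, b: Sensorgram, what: str) -> None:
    if a.times.shape != b.times.shape or not np.allclose(a.times, b.times):
        raise ValueError(f"{what}: sensorgram time grids are not aligned")


def double_reference(active: Sensorgram, reference: Sensorgram,
                     blank: Sensorgram) -> Sensorgram:
    """Subtract reference-surface and buffer-blank responses.

    corrected = active - reference - blank, on identical time grids.  The
    blank is assumed to be already reference-subtracted (as exported by
    the instrument software).
    """
    _check_grids(active, reference, "double_reference")
    _check_grids(active, blank, "double_reference")
    corrected = active.response - reference.response - blank.response
    return replace(active, response=corrected,
                   label=(active.label + "|double_referenced").lstrip("|"))


def subtract_peptide_only(mixture: Sensorgram,
                          peptide_only: Sensorgram) -> Sensorgram:
    """Remove the peptide's own response from a mixture sensorgram."""
    if mixture.role != "mixture" or peptide_only.role != "peptide_only":
        raise ValueError("expected roles 'mixture' and 'peptide_only'")
    mix_pep = mixture.label.split("+")[-1] if "+" in mixture.label else None
    if mix_pep and peptide_only.label and mix_pep != peptide_only.label:
        raise ValueError(
            f"peptide labels disagree: mixture {mixture.label!r} vs "
            f"peptide-only {peptide_only.label!r}")
    _check_grids(mixture, peptide_only, "subtract_peptide_only")
    return replace(mixture,
                   response=mixture.response - peptide_only.response,
                   label=(mixture.label + "|peptide_subtracted"))


def _residuals(log_params: np.ndarray, curves: list[Sensorgram]) -> np.ndarray:
    # clip keeps exploratory LM steps finite; the optimum is far inside
    ka, kd, rmax = np.exp(np.clip(log_params, -60.0, 60.0))
    res = []
    for c in curves:
        model = sensorgram_model(c.times, ka, kd, rmax,
                                 c.analyte_concentration,
                                 c.association_start, c.association_end)
        res.append(c.response - model)
    return np.concatenate(res)


def fit_1to1_global(curves: list[Sensorgram],
                    ka_range: tuple[float, float] = (1e3, 1e7),
                    kd_range: tuple[float, float] = (1e-5, 1e-1),
                    n_starts_per_axis: int = 3,
                    ) -> KineticFit:
    """Global 1:1 fit sharing ka, kd, Rmax across all curves.

    Parameters are optimised in log space (positivity built in) by
    Levenberg-Marquardt style least squares, with multi-start
    initialisation on a log-spaced (ka, kd) grid; the best start by
    residual sum of squares wins.  Raises on total non-convergence; warns
    when only a single concentration is supplied (ka and Rmax then trade
    off against each other).
    """
    if not curves:
        raise ValueError("no curves supplied")
    concs = {c.analyte_concentration for c in curves}
    if len(concs) < 2:
        import warnings
        warnings.warn("single analyte concentration: ka and Rmax are "
                      "weakly identifiable", stacklevel=2)
    rmax0 = max(float(np.max(np.abs(c.response))) for c in curves)
    rmax0 = max(rmax0, 1e-6)
    best = None
    n_starts = 0
    kas = np.geomspace(*ka_range, n_starts_per_axis)
    kds = np.geomspace(*kd_range, n_starts_per_axis)
    for ka0 in kas:
        for kd0 in kds:
            n_starts += 1
            x0 = np.log([ka0, kd0, rmax0])
            try:
                sol = least_squares(_residuals, x0, args=(curves,),
                                    method="lm", xtol=1e-14, ftol=1e-14,
                                    gtol=1e-14, max_nfev=4000)
            except Exception:
                continue
            rss = float(np.sum(sol.fun ** 2))
            if best is None or rss < best[0]:
                best = (rss, sol)
    if best is None:
        raise RuntimeError("1:1 global fit failed to converge from any start")
    _, sol = best
    ka, kd, rmax = np.exp(sol.x)
    rss_per_curve = []
    for c in curves:
        model = sensorgram_model(c.times, ka, kd, rmax,
                                 c.analyte_concentration,
                                 c.association_start, c.association_end)
        rss_per_curve.append(float(np.sum((c.response - model) ** 2)))
    return KineticFit(float(ka), float(kd), float(rmax),
                      tuple(rss_per_curve), bool(sol.success), n_starts)


def percent_binding(mixtures: list[Sensorgram], control: Sensorgram,
                    readout_time: float | None = None,
                    ) -> list[InhibitionResult]:
    """End-of-association responses as percent of the no-peptide control.

    percent = 100 * R_mixture(readout) / R_control(readout); the readout
    defaults to the control's end of association.  Duplicate injections
    (same label and peptide concentration) aggregate to mean +/- s.d.
    """
    t = control.association_end if readout_time is None else readout_time
    r_control = control.response_at(t)
    if r_control <= 0:
        raise ValueError("control response at readout is not positive; "
                         "percent binding undefined")
    groups: dict[tuple[str, float], list[float]] = {}
    for m in mixtures:
        pct = 100.0 * m.response_at(t) / r_control
        key = (m.label.split("|")[0], _peptide_conc(m))
        groups.setdefault(key, []).append(pct)
    out = []
    for (label, conc), vals in sorted(groups.items(), key=lambda kv: kv[0]):
        arr = np.asarray(vals)
        out.append(InhibitionResult(
            peptide_label=label, peptide_concentration=conc,
            percent_binding=float(arr.mean()),
            replicate_values=tuple(float(v) for v in arr),
            sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0))
    return out


def _peptide_conc(s: Sensorgram) -> float:
    return float(s.peptide_concentration
                 if s.peptide_concentration is not None else np.nan)
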