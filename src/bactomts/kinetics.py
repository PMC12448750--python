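"""1:1 Langmuir sensorgram fitting and MSD-based diffusion estimation.

``fit_langmuir`` performs a single global nonlinear least-squares fit of
(k_on, k_off, R_max) over every concentration and both phases of a
titration series, matching how an apparent K_D is reported from a
biosensor experiment; K_D = k_off / k_on by construction. Parameters are
fitted on a log scale so positivity is structural. Confidence intervals
come from residual-resampling bootstrap.

``msd_curve`` computes per-track time-averaged mean-squared displacements
over all overlapping frame pairs at each lag, then averages across tracks
(+- SD); ``fit_diffusion`` regresses MSD = 4 D tau + b over a configurable
lag range (2D motion; the intercept absorbs localization noise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .io import SensorgramSet, TrackSet
from .synthetic_timeseries import langmuir_signal


@dataclass
class KineticFit:
    k_on: float                 # 1/(M s)
    k_off: float                # 1/s
    r_max: float                # signal units
    rss: float
    n_points: int
    ci: dict[str, tuple[float, float]] | None = None
    identifiable: bool = True
    diagnostic: str = ""

    @property
    def k_d(self) -> float:
        return self.k_off / self.k_on

    def to_dict(self) -> dict:
        d = {"k_on": self.k_on, "k_off": self.k_off, "r_max": self.r_max,
             "K_D": self.k_d, "rss": self.rss, "n_points": self.n_points,
             "identifiable": self.identifiable,
             "diagnostic": self.diagnostic}
        if self.ci:
            d["ci"] = {k: list(v) for k, v in self.ci.items()}
        return d


def _model_signal(df, k_on: float, k_off: float, r_max: float,
                  t_assoc: float) -> np.ndarray:
    out = np.empty(len(df))
    for (conc, phase), idx in df.groupby(
            ["concentration_M", "phase"]).groups.items():
        t = df.loc[idx, "time_s"].to_numpy(dtype=float)
        out[df.index.get_indexer(idx)] = langmuir_signal(
            t, phase, float(conc), k_on, k_off, r_max, t_assoc)
    return out


def _residuals(logp: np.ndarray, df, t_assoc: float) -> np.ndarray:
    k_on, k_off, r_max = np.exp(logp)
    return _model_signal(df, k_on, k_off, r_max, t_assoc) \
        - df["signal"].to_numpy(dtype=float)


def _initial_guesses(sgrams: SensorgramSet) -> list[np.ndarray]:
    df = sgrams.data
    smax = float(df["signal"].abs().max()) or 1.0
    concs = sgrams.concentrations()
    t_span = float(df["time_s"].max()) or 1.0
    guesses = []
    for kd0 in (np.median(concs), concs.min(), concs.max()):
        for koff0 in (1.0 / t_span, 10.0 / t_span):
            guesses.append(np.log([koff0 / kd0, koff0, 1.5 * smax]))
    return guesses


def fit_langmuir(sensorgrams: SensorgramSet, n_bootstrap: int = 0,
                 bootstrap_seed: int = 0) -> KineticFit:
    """Global 1:1 Langmuir fit over all curves and both phases."""
    df = sensorgrams.data.reset_index(drop=True)
    concs = sensorgrams.concentrations()
    if len(concs) < 2:
        raise ValueError("need at least 2 analyte concentrations")
    if set(df["phase"]) != {"assoc", "dissoc"}:
        raise ValueError("need both association and dissociation phases")
    t_assoc = sensorgrams.t_assoc or float(
        df.loc[df["phase"] == "assoc", "time_s"].max())

    best = None
    for x0 in _initial_guesses(sensorgrams):
        try:
            sol = least_squares(_residuals, x0, args=(df, t_assoc),
                                xtol=1e-15, ftol=1e-15, gtol=1e-15,
                                max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("no Langmuir fit converged")
    k_on, k_off, r_max = np.exp(best.x)
    kd = k_off / k_on
    identifiable = bool(concs.min() < 10 * kd and concs.max() > kd / 10)
    diagnostic = "" if identifiable else (
        "all concentrations far from the fitted K_D; "
        "K_D is poorly constrained by this titration")
    fit = KineticFit(k_on=k_on, k_off=k_off, r_max=r_max,
                     rss=float(2 * best.cost), n_points=len(df),
                     identifiable=identifiable, diagnostic=diagnostic)
    if n_bootstrap > 0:
        fit.ci = _bootstrap_ci(df, t_assoc, best.x, n_bootstrap,
                               bootstrap_seed)
    return fit


def _bootstrap_ci(df, t_assoc: float, logp_hat: np.ndarray, n_boot: int,
                  seed: int) -> dict[str, tuple[float, float]]:
    """Residual-resampling bootstrap percentile CIs (95%)."""
    rng = np.random.default_rng(seed)
    fitted = _model_signal(df, *np.exp(logp_hat), t_assoc)
    resid = df["signal"].to_numpy(dtype=float) - fitted
    samples = []
    boot_df = df.copy()
    for _ in range(n_boot):
        boot_df["signal"] = fitted + rng.choice(resid, size=len(resid),
                                                replace=True)
        sol = least_squares(_residuals, logp_hat, args=(boot_df, t_assoc),
                            xtol=1e-12, ftol=1e-12, max_nfev=500)
        samples.append(np.exp(sol.x))
    arr = np.array(samples)
    kd = arr[:, 1] / arr[:, 0]
    lo, hi = 2.5, 97.5
    return {
        "k_on": tuple(np.percentile(arr[:, 0], [lo, hi])),
        "k_off": tuple(np.percentile(arr[:, 1], [lo, hi])),
        "r_max": tuple(np.percentile(arr[:, 2], [lo, hi])),
        "K_D": tuple(np.percentile(kd, [lo, hi])),
    }


def kobs_regression(sensorgrams: SensorgramSet) -> tuple[float, float]:
    """Diagnostic per-curve fallback: fit k_obs per association curve, then
    regress k_obs = k_on C + k_off. Returns (k_on, k_off)."""
    df = sensorgrams.data
    concs, kobs = [], []
    for conc, grp in df[df["phase"] == "assoc"].groupby("concentration_M"):
        t = grp["time_s"].to_numpy(dtype=float)
        y = grp["signal"].to_numpy(dtype=float)

        def res(p, t=t, y=y):
            r_eq, k = p
            return r_eq * (1 - np.exp(-k * t)) - y

        sol = least_squares(res, [max(y.max(), 1e-9), 1.0 / max(t.max(), 1e-9)])
        concs.append(float(conc))
        kobs.append(sol.x[1])
    slope, intercept = np.polyfit(concs, kobs, 1)
    return float(slope), float(intercept)


# ----------------------------------------------------------------- MSD/D

@dataclass
class MsdCurve:
    lags_s: np.ndarray          # includes lag 0
    mean: np.ndarray            # mean MSD across tracks, um^2
    sd: np.ndarray              # SD across tracks
    n_tracks: np.ndarray        # tracks contributing per lag
    dt: float


def msd_curve(tracks: TrackSet, max_lag: int = 20) -> MsdCurve:
    """Time-averaged MSD per track over all overlapping pairs at each lag,
    then mean +- SD across tracks; lag 0 is 0 by definition."""
    df = tracks.data
    per_track: list[np.ndarray] = []
    for _, grp in df.groupby("track_id"):
        grp = grp.sort_values("frame")
        xy = grp[["x_um", "y_um"]].to_numpy(dtype=float)
        n = len(xy)
        vals = np.full(max_lag, np.nan)
        for k in range(1, min(max_lag, n - 1) + 1):
            d = xy[k:] - xy[:-k]
            vals[k - 1] = np.mean((d * d).sum(axis=1))
        per_track.append(vals)
    arr = np.array(per_track)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(arr, axis=0)
        sd = np.nanstd(arr, axis=0, ddof=0)
    n_tracks = np.sum(~np.isnan(arr), axis=0)
    lags = np.arange(0, max_lag + 1) * tracks.dt
    return MsdCurve(lags_s=lags,
                    mean=np.concatenate([[0.0], mean]),
                    sd=np.concatenate([[0.0], sd]),
                    n_tracks=np.concatenate([[len(per_track)], n_tracks]),
                    dt=tracks.dt)


def fit_diffusion(msd: MsdCurve, fit_lags: tuple[int, int] = (2, 10),
                  ) -> tuple[float, float]:
    """OLS of MSD = 4 D tau + b over lag indices [lo, hi] (inclusive).
    Returns (D in um^2/s, intercept in um^2)."""
    lo, hi = fit_lags
    idx = np.arange(lo, hi + 1)
    tau = msd.lags_s[idx]
    y = msd.mean[idx]
    good = ~np.isnan(y)
    if good.sum() < 2:
        raise ValueError("not enough lags with data in the fit range")
    slope, intercept = np.polyfit(tau[good], y[good], 1)
    return float(slope / 4.0), float(intercept)
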