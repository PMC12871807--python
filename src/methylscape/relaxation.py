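"""Fitting η and δ from interleaved methyl 3Q/SQ relaxation series.

The triple-quantum ("forbidden") coherence builds up relative to the decaying
single-quantum ("allowed") coherence at a rate set by the intra-methyl
cross-correlated relaxation rate η, while δ collects dipolar contributions
from external protons. Two fit routes are provided:

* the classical ratio fit — non-linear least squares of I3Q/ISQ against the
  closed-form build-up ratio; cheap, but unstable on noisy, sparse data
  because the ratio divides by small late-delay SQ intensities;
* a simultaneous Bayesian fit of the separate 3Q and SQ time series with
  shared (η, δ, A0, relaxation envelope) parameters and per-coherence noise
  scales, sampled with an affine-invariant ensemble sampler.

Intensity model (T is the relaxation delay, s = sqrt(η² + δ²)):

    I3Q(T) = 3 η tanh(s T) · A0 · Σ_i f_i exp(−R_i T)
    ISQ(T) = 4 (s − δ tanh(s T)) · A0 · Σ_i f_i exp(−R_i T)

so that I3Q/ISQ = (3/4) η tanh(s T) / (s − δ tanh(s T)) with the common
amplitude and relaxation envelope cancelling exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import emcee
import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares

__all__ = [
    "DecayCurve",
    "RatioNLSResults",
    "RelaxationResults",
    "RelaxationModel",
    "intensity_3q",
    "intensity_sq",
    "intensity_ratio",
    "read_intensity_table",
    "write_intensity_table",
]


# ---------------------------------------------------------------------------
# Closed-form intensity models (single code path, shared by simulation, NLS
# and Bayesian likelihoods; the ratio is their exact quotient).
# ---------------------------------------------------------------------------

def _envelope(delays, amplitude, rates, fractions):
    delays = np.asarray(delays, dtype=float)
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    fractions = np.atleast_1d(np.asarray(fractions, dtype=float))
    return amplitude * np.sum(
        fractions[..., :, None] * np.exp(-rates[..., :, None] * delays), axis=-2
    )


def intensity_3q(eta, delta, delays, amplitude=1.0, rates=(0.0,), fractions=(1.0,)):
    """Noiseless 3Q build-up/decay intensity."""
    s = np.sqrt(np.asarray(eta) ** 2 + np.asarray(delta) ** 2)
    t = np.asarray(delays, dtype=float)
    return 3.0 * eta * np.tanh(s * t) * _envelope(t, amplitude, rates, fractions)


def intensity_sq(eta, delta, delays, amplitude=1.0, rates=(0.0,), fractions=(1.0,)):
    """Noiseless SQ decay intensity."""
    s = np.sqrt(np.asarray(eta) ** 2 + np.asarray(delta) ** 2)
    t = np.asarray(delays, dtype=float)
    return 4.0 * (s - delta * np.tanh(s * t)) * _envelope(t, amplitude, rates, fractions)


def intensity_ratio(eta, delta, delays):
    """Closed-form I3Q/ISQ ratio; amplitude and envelope cancel."""
    s = np.sqrt(eta**2 + delta**2)
    t = np.asarray(delays, dtype=float)
    th = np.tanh(s * t)
    return 0.75 * eta * th / (s - delta * th)


# ---------------------------------------------------------------------------
# Data container
# ---------------------------------------------------------------------------

@dataclass
class DecayCurve:
    """One peak's intensity-vs-delay series for one coherence type."""

    peak_id: str
    coherence: str  # "SQ" or "3Q"
    delays: np.ndarray  # seconds, strictly increasing
    intensities: np.ndarray
    noise_sd: float | None = None

    def __post_init__(self):
        self.delays = np.asarray(self.delays, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.coherence not in ("SQ", "3Q"):
            raise ValueError(f"coherence must be 'SQ' or '3Q', got {self.coherence!r}")
        if self.delays.size < 3:
            raise ValueError("a decay curve needs at least 3 delay points")
        if np.any(self.delays <= 0):
            raise ValueError("delays must be strictly positive (seconds)")
        if np.any(np.diff(self.delays) <= 0):
            raise ValueError("delays must be strictly increasing")
        if self.intensities.shape != self.delays.shape:
            raise ValueError("intensities and delays must have the same length")

    @property
    def n_points(self) -> int:
        return int(self.delays.size)


# ---------------------------------------------------------------------------
# Results objects
# ---------------------------------------------------------------------------

@dataclass
class RatioNLSResults:
    """Point estimates from the classical ratio NLS fit."""

    peak_id: str
    eta: float
    eta_sd: float
    delta: float
    delta_sd: float
    converged: bool
    residual_rms: float

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": [self.eta, self.delta],
                "std_err": [self.eta_sd, self.delta_sd],
            },
            index=["eta", "delta"],
        )


@dataclass
class RelaxationResults:
    """Posterior samples from the simultaneous Bayesian 3Q/SQ fit.

    ``samples`` holds one column per parameter; rates are reported ordered
    (r1 ≤ r2 in every draw) which removes exponential label switching.
    """

    peak_id: str
    n_exp: int
    samples: pd.DataFrame
    diagnostics: dict = field(default_factory=dict)
    model: "RelaxationModel | None" = None

    @property
    def eta(self) -> np.ndarray:
        return self.samples["eta"].to_numpy()

    @property
    def delta(self) -> np.ndarray:
        return self.samples["delta"].to_numpy()

    def summary(self) -> pd.DataFrame:
        q = self.samples.quantile([0.025, 0.5, 0.975])
        out = pd.DataFrame(
            {
                "mean": self.samples.mean(),
                "sd": self.samples.std(ddof=1),
                "hdi_2.5%": q.loc[0.025],
                "median": q.loc[0.5],
                "hdi_97.5%": q.loc[0.975],
            }
        )
        out.attrs["peak_id"] = self.peak_id
        out.attrs.update(self.diagnostics)
        return out

    def posterior_predictive(self, delays=None, n_draws: int = 500, seed: int = 0):
        """Simulate new data (intensities and their ratio) from the posterior.

        Returns a dict with arrays of shape (n_draws, n_delays) under keys
        ``"sq"``, ``"tq"`` and ``"ratio"``. Predictive spread in intensity
        space is delay-independent (homoscedastic noise); in ratio space it
        grows as the SQ mean decays, because the same absolute noise is
        divided by ever smaller SQ values.
        """
        if self.model is None:
            raise ValueError("results are detached from their model; pass delays data")
        if delays is None:
            delays = self.model.delays
        delays = np.asarray(delays, dtype=float)
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(self.samples), size=n_draws)
        draws = self.samples.iloc[idx]
        rates = draws[[f"r{i+1}" for i in range(self.n_exp)]].to_numpy()
        fracs = draws[[f"f{i+1}" for i in range(self.n_exp)]].to_numpy()
        eta = draws["eta"].to_numpy()[:, None]
        delta = draws["delta"].to_numpy()[:, None]
        a0 = draws["a0"].to_numpy()[:, None]
        s = np.sqrt(eta**2 + delta**2)
        th = np.tanh(s * delays[None, :])
        env = a0 * np.sum(
            fracs[:, :, None] * np.exp(-rates[:, :, None] * delays[None, None, :]),
            axis=1,
        )
        mean_tq = 3.0 * eta * th * env
        mean_sq = 4.0 * (s - delta * th) * env
        sig_sq = draws["sigma_sq"].to_numpy()[:, None]
        sig_3q = draws["sigma_3q"].to_numpy()[:, None]
        sq = mean_sq + rng.normal(0.0, 1.0, mean_sq.shape) * sig_sq
        tq = mean_tq + rng.normal(0.0, 1.0, mean_tq.shape) * sig_3q
        return {"delays": delays, "sq": sq, "tq": tq, "ratio": tq / sq}

    def plot_fit(self, n_curves: int = 100, seed: int = 0, ax=None):
        from .plotting import plot_relaxation_fit

        return plot_relaxation_fit(self, n_curves=n_curves, seed=seed, ax=ax)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class RelaxationModel:
    """Joint model for one peak's interleaved SQ and 3Q delay series.

    Parameters
    ----------
    sq, tq : DecayCurve
        Matched-grid SQ and 3Q curves for the same peak.
    normalize : {"sq_max", "none"}
        ``"sq_max"`` divides both curves by max |SQ| — a single positive
        scale, under which η is exactly invariant and A0 ≈ 1. A common
        scale (rather than per-curve maxima) keeps the shared amplitude of
        the simultaneous model meaningful.
    """

    def __init__(self, sq: DecayCurve, tq: DecayCurve, normalize: str = "sq_max"):
        if sq.coherence != "SQ" or tq.coherence != "3Q":
            raise ValueError("pass the SQ curve first and the 3Q curve second")
        if sq.peak_id != tq.peak_id:
            raise ValueError("SQ and 3Q curves must come from the same peak")
        if not np.allclose(sq.delays, tq.delays):
            raise ValueError("SQ and 3Q delay grids must match (interleaved acquisition)")
        self.peak_id = sq.peak_id
        self.delays = sq.delays.copy()
        if normalize == "sq_max":
            self.scale = float(np.max(np.abs(sq.intensities)))
            if self.scale == 0:
                raise ValueError("SQ curve is identically zero; cannot normalize")
        elif normalize == "none":
            self.scale = 1.0
        else:
            raise ValueError(f"unknown normalize mode {normalize!r}")
        self.sq = sq.intensities / self.scale
        self.tq = tq.intensities / self.scale

    # -- classical ratio fit ------------------------------------------------

    def fit_nls(self, p0=(20.0, 5.0)) -> RatioNLSResults:
        """Non-linear least squares of the 3Q/SQ ratio against the closed form.

        May legitimately fail to converge on noisy data; that is flagged,
        not raised — the failure mode is what motivates the simultaneous
        Bayesian fit.
        """
        if np.any(self.sq == 0):
            raise ValueError("SQ intensities must be nonzero to form the ratio")
        ratio = self.tq / self.sq
        converged = True
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(
                    lambda t, eta, delta: intensity_ratio(eta, delta, t),
                    self.delays,
                    ratio,
                    p0=p0,
                    bounds=([0.0, 0.0], [np.inf, np.inf]),
                    maxfev=10000,
                )
            perr = np.sqrt(np.diag(pcov))
            if not np.all(np.isfinite(perr)):
                converged = False
        except RuntimeError:
            popt = np.array(p0, dtype=float)
            perr = np.array([np.inf, np.inf])
            converged = False
        resid = ratio - intensity_ratio(popt[0], popt[1], self.delays)
        return RatioNLSResults(
            peak_id=self.peak_id,
            eta=float(popt[0]),
            eta_sd=float(perr[0]),
            delta=float(popt[1]),
            delta_sd=float(perr[1]),
            converged=converged,
            residual_rms=float(np.sqrt(np.mean(resid**2))),
        )

    # -- simultaneous Bayesian fit -----------------------------------------

    def _param_names(self, n_exp: int) -> list[str]:
        names = ["eta", "delta", "a0", "r1"]
        names += [f"dr{i}" for i in range(2, n_exp + 1)]
        if n_exp > 1:
            names += [f"f{i}" for i in range(1, n_exp)]
        names += ["log_sigma_sq", "log_sigma_3q"]
        return names

    def _map_start(self, n_exp: int):
        """Crude simultaneous least-squares fit used to seed the walkers."""

        def resid(p):
            eta, delta, a0 = p[0], p[1], p[2]
            rates, fracs = self._unpack_rates(p, n_exp)
            mtq = intensity_3q(eta, delta, self.delays, a0, rates, fracs)
            msq = intensity_sq(eta, delta, self.delays, a0, rates, fracs)
            return np.concatenate([msq - self.sq, mtq - self.tq])

        ndim = 3 + n_exp + max(0, n_exp - 1)
        p0 = np.zeros(ndim)
        p0[:4] = [20.0, 10.0, 0.3, 50.0]
        lo = np.zeros(ndim)
        hi = np.full(ndim, np.inf)
        hi[2] = 100.0
        if n_exp > 1:
            p0[4 : 3 + n_exp] = 50.0
            p0[3 + n_exp :] = 0.5
            hi[3 + n_exp :] = 1.0
        lo[2] = 1e-9
        sol = least_squares(resid, p0, bounds=(lo, hi))
        res_sd = max(float(np.std(sol.fun)), 1e-6)
        return sol.x, res_sd

    @staticmethod
    def _unpack_rates(p, n_exp):
        r1 = p[3]
        rates = [r1]
        for i in range(n_exp - 1):
            rates.append(rates[-1] + p[4 + i])
        if n_exp == 1:
            fracs = [1.0]
        else:
            fs = list(p[3 + n_exp : 3 + n_exp + n_exp - 1])
            fracs = fs + [1.0 - sum(fs)]
        return np.array(rates), np.array(fracs)

    def fit_bayes(
        self,
        n_exp: int = 2,
        seed: int = 0,
        priors: dict | None = None,
        n_walkers: int = 32,
        n_steps: int = 1200,
        n_burn: int = 400,
        allow_negative_eta: bool = False,
    ) -> RelaxationResults:
        """Sample the joint posterior of (η, δ, A0, {Ri, fi}, noise scales).

        Half-normal priors keep every scale parameter weakly informative;
        the rates are parameterized as (R1, R1+ΔR2, …) with ΔR ≥ 0 so draws
        are ordered by construction. Both coherence types get their own
        homoscedastic Gaussian noise scale.
        """
        if n_exp not in (1, 2):
            raise ValueError("n_exp must be 1 or 2")
        n_data = self.delays.size * 2
        if n_data < 2 * (n_exp + 2):
            raise ValueError(
                f"{n_data} data points are too few for n_exp={n_exp} "
                f"(need at least {2 * (n_exp + 2)})"
            )
        pri = {
            "eta_scale": 100.0,
            "delta_scale": 100.0,
            "a0_mean": 1.0,
            "a0_sd": 1.0,
            "rate_scale": 300.0,
            "noise_scale": 0.2,
        }
        if priors:
            pri.update(priors)

        delays = self.delays
        sq, tq = self.sq, self.tq
        names = self._param_names(n_exp)
        ndim = len(names)
        n_fr = n_exp - 1

        def log_prob(theta):
            theta = np.atleast_2d(theta)
            eta, delta, a0 = theta[:, 0], theta[:, 1], theta[:, 2]
            r1 = theta[:, 3]
            drs = theta[:, 4 : 4 + n_fr]
            fs = theta[:, 4 + n_fr : 4 + 2 * n_fr]
            lssq, ls3q = theta[:, -2], theta[:, -1]
            bad = (
                (delta < 0)
                | (a0 <= 0)
                | (r1 < 0)
                | np.any(drs < 0, axis=1)
                | np.any((fs < 0) | (fs > 1), axis=1)
                | (lssq < -14)
                | (lssq > 3)
                | (ls3q < -14)
                | (ls3q > 3)
            )
            if not allow_negative_eta:
                bad |= eta < 0
            s = np.sqrt(eta**2 + delta**2)
            th = np.tanh(s[:, None] * delays[None, :])
            if n_exp == 1:
                env = a0[:, None] * np.exp(-r1[:, None] * delays[None, :])
            else:
                r2 = r1 + drs[:, 0]
                f1 = fs[:, 0]
                env = a0[:, None] * (
                    f1[:, None] * np.exp(-r1[:, None] * delays[None, :])
                    + (1 - f1)[:, None] * np.exp(-r2[:, None] * delays[None, :])
                )
            m3 = 3.0 * eta[:, None] * th * env
            ms = 4.0 * (s[:, None] - delta[:, None] * th) * env
            ssq, s3q = np.exp(lssq), np.exp(ls3q)
            npt = delays.size
            ll = (
                -0.5 * np.sum((sq - ms) ** 2, axis=1) / ssq**2
                - npt * lssq
                - 0.5 * np.sum((tq - m3) ** 2, axis=1) / s3q**2
                - npt * ls3q
            )
            lp = (
                -0.5 * (eta / pri["eta_scale"]) ** 2
                - 0.5 * (delta / pri["delta_scale"]) ** 2
                - 0.5 * ((a0 - pri["a0_mean"]) / pri["a0_sd"]) ** 2
                - 0.5 * (r1 / pri["rate_scale"]) ** 2
                - 0.5 * np.sum((drs / pri["rate_scale"]) ** 2, axis=1)
                - 0.5 * (ssq / pri["noise_scale"]) ** 2
                + lssq
                - 0.5 * (s3q / pri["noise_scale"]) ** 2
                + ls3q
            )
            out = ll + lp
            out[bad] = -np.inf
            return out

        rng = np.random.default_rng(seed)
        map_x, res_sd = self._map_start(n_exp)
        p0 = np.empty(ndim)
        p0[: ndim - 2] = map_x
        p0[-2:] = np.log(res_sd)
        start = p0[None, :] + 1e-4 * rng.standard_normal((n_walkers, ndim)) * np.maximum(
            np.abs(p0), 0.1
        )
        if n_fr:
            start[:, 4 + n_fr : 4 + 2 * n_fr] = np.clip(
                start[:, 4 + n_fr : 4 + 2 * n_fr], 0.01, 0.99
            )
        start[:, 2] = np.maximum(start[:, 2], 1e-6)
        start[:, :2] = np.maximum(start[:, :2], 0.0)

        sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob, vectorize=True)
        sampler.random_state = np.random.RandomState(seed).get_state()
        with np.errstate(invalid="ignore"):  # -inf log-probs at rejected bounds
            sampler.run_mcmc(start, n_steps, progress=False)
        chain = sampler.get_chain(discard=n_burn, flat=True)

        cols = {"eta": chain[:, 0], "delta": chain[:, 1], "a0": chain[:, 2]}
        cols["r1"] = chain[:, 3]
        if n_exp == 2:
            cols["r2"] = chain[:, 3] + chain[:, 4]
            cols["f1"] = chain[:, 5]
            cols["f2"] = 1.0 - chain[:, 5]
        else:
            cols["f1"] = np.ones(chain.shape[0])
        cols["sigma_sq"] = np.exp(chain[:, -2])
        cols["sigma_3q"] = np.exp(chain[:, -1])
        samples = pd.DataFrame(cols)

        acc = float(np.mean(sampler.acceptance_fraction))
        diagnostics = {
            "acceptance_fraction": acc,
            "converged": bool(0.05 < acc < 0.95),
            "n_walkers": n_walkers,
            "n_steps": n_steps,
            "n_burn": n_burn,
            "seed": seed,
        }
        return RelaxationResults(
            peak_id=self.peak_id,
            n_exp=n_exp,
            samples=samples,
            diagnostics=diagnostics,
            model=self,
        )


# ---------------------------------------------------------------------------
# I/O: long-format intensity tables
# ---------------------------------------------------------------------------

_TABLE_COLS = ["peak_id", "coherence", "delay_s", "intensity"]


def write_intensity_table(curves: Sequence[DecayCurve], path) -> None:
    """Write decay curves as a long TSV with columns peak_id, coherence, delay_s, intensity."""
    rows = []
    for c in curves:
        for t, i in zip(c.delays, c.intensities):
            rows.append((c.peak_id, c.coherence, t, i))
    df = pd.DataFrame(rows, columns=_TABLE_COLS)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_intensity_table(path_or_buf) -> dict[str, tuple[DecayCurve, DecayCurve]]:
    """Read a TSV/CSV intensity table into {peak_id: (sq_curve, tq_curve)}."""
    df = pd.read_csv(path_or_buf, sep=None, engine="python")
    missing = set(_TABLE_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"intensity table missing columns: {sorted(missing)}")
    out = {}
    for peak, grp in df.groupby("peak_id", sort=True):
        curves = {}
        for coh, sub in grp.groupby("coherence"):
            sub = sub.sort_values("delay_s")
            curves[coh] = DecayCurve(
                peak_id=str(peak),
                coherence=str(coh),
                delays=sub["delay_s"].to_numpy(),
                intensities=sub["intensity"].to_numpy(),
            )
        if set(curves) != {"SQ", "3Q"}:
            raise ValueError(f"peak {peak!r} must have both SQ and 3Q series")
        out[str(peak)] = (curves["SQ"], curves["3Q"])
    return out
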