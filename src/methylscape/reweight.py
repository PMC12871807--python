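"""Maximum-entropy reweighting of ensemble frames against NMR order parameters.

Frame weights w (non-negative, summing to 1) are refined so that the
back-calculated O²axis values match their NMR targets, while staying close
to the prior ensemble. Because O² is quadratic in the weighted tensor
moments, the observable is non-linear in w and the usual Lagrange-dual
(linear-observable) maximum-entropy solution does not apply; instead the
penalized objective

    L(w) = χ²(w) + θ · S_REL(w)
    χ²(w) = Σ_i (O²_calc,i(w) − O²_NMR,i)² / σ_i²
    S_REL(w) = Σ_j w_j ln(w_j / w⁰_j)

is minimized directly over *unnormalized* weights u ≥ 0 (box-constrained
L-BFGS-B) with analytic gradients; the chain rule through the
normalization w = u/Σu projects naive ∂/∂w gradients onto the simplex
tangent. The regularization strength θ trades data fit against ensemble
diversity and is chosen at the elbow of the χ²-vs-θ L-curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .ensemble import TrajectoryEnsemble, frame_features, o2_from_moments

__all__ = [
    "ReweightTargets",
    "ReweightResults",
    "LCurve",
    "EnsembleReweighter",
    "weighted_o2",
    "neff",
    "select_theta_elbow",
]

_TINY = 1e-300


@dataclass
class ReweightTargets:
    """Per-residue experimental O² targets with uncertainties."""

    residue_ids: list
    o2_mean: np.ndarray
    o2_sd: np.ndarray

    def __post_init__(self):
        self.o2_mean = np.asarray(self.o2_mean, dtype=float)
        self.o2_sd = np.asarray(self.o2_sd, dtype=float)
        if not (len(self.residue_ids) == self.o2_mean.size == self.o2_sd.size):
            raise ValueError("targets fields must have equal length")
        if np.any(self.o2_sd <= 0):
            raise ValueError("target uncertainties must be strictly positive")

    @classmethod
    def from_tsv(cls, path) -> "ReweightTargets":
        df = pd.read_csv(path, sep="\t")
        return cls(
            residue_ids=df["residue_id"].astype(str).tolist(),
            o2_mean=df["o2_mean"].to_numpy(),
            o2_sd=df["o2_sd"].to_numpy(),
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"residue_id": self.residue_ids, "o2_mean": self.o2_mean, "o2_sd": self.o2_sd}
        ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def neff(weights, method: str = "exp_srel", prior_weights=None) -> float:
    """Effective fraction of frames retained by a weight vector.

    ``exp_srel`` (default): exp(−S_REL), the standard maximum-entropy
    effective sample fraction. ``kish``: (Σw)²/(N·Σw²). Both lie in (0, 1]
    and equal 1 iff the weights match the prior (uniform by default).
    """
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    n = w.size
    if method == "kish":
        return float(1.0 / (n * np.sum(w**2)))
    if method == "exp_srel":
        w0 = np.full(n, 1.0 / n) if prior_weights is None else np.asarray(prior_weights)
        pos = w > 0
        srel = float(np.sum(w[pos] * np.log(w[pos] / w0[pos])))
        return float(np.exp(-srel))
    raise ValueError(f"unknown neff method {method!r}")


def weighted_o2(ensemble: TrajectoryEnsemble, weights) -> pd.Series:
    """Back-calculated per-residue O² under (unnormalized) weights.

    Reduces exactly to the uniform-weight tensor expansion when the
    weights are uniform — same code path, weighted moments.
    """
    u = np.asarray(weights, dtype=float)
    if np.any(u < 0) or not np.all(np.isfinite(u)):
        raise ValueError("weights must be finite and non-negative")
    s = u.sum()
    if s == 0:
        raise ValueError("weights must not all be zero")
    w = u / s
    feats = frame_features(ensemble.vectors)  # (R, N, 6)
    m = np.einsum("j,rjc->rc", w, feats)
    return pd.Series(o2_from_moments(m), index=list(ensemble.residue_ids), name="o2")


@dataclass
class ReweightResults:
    """Optimized weights with fit diagnostics for one value of θ."""

    weights: np.ndarray
    theta: float
    chi2: float
    s_rel: float
    neff: float
    neff_kish: float
    converged: bool
    n_iterations: int
    grad_norm: float
    o2_prior: pd.Series
    o2_posterior: pd.Series
    targets: ReweightTargets
    message: str = ""

    def __post_init__(self):
        assert abs(self.weights.sum() - 1.0) < 1e-9

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "o2_target": pd.Series(
                    self.targets.o2_mean, index=self.targets.residue_ids
                ),
                "o2_sd": pd.Series(self.targets.o2_sd, index=self.targets.residue_ids),
                "o2_prior": self.o2_prior,
                "o2_reweighted": self.o2_posterior,
            }
        )
        df.attrs.update(
            theta=self.theta,
            chi2=self.chi2,
            s_rel=self.s_rel,
            neff=self.neff,
            converged=self.converged,
        )
        return df

    def weights_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(self.weights.size), "weight": self.weights})


@dataclass
class LCurve:
    """χ², S_REL and Neff along a log-spaced θ grid."""

    theta: np.ndarray
    chi2: np.ndarray
    s_rel: np.ndarray
    neff: np.ndarray
    results: list = field(default_factory=list)
    selected_theta: float | None = None
    selection_method: str = ""
    no_elbow: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"theta": self.theta, "chi2": self.chi2, "s_rel": self.s_rel, "neff": self.neff}
        )

    def plot(self, ax=None):
        from .plotting import plot_lcurve

        return plot_lcurve(self, ax=ax)


class EnsembleReweighter:
    """Fit frame weights of an ensemble to per-residue O² targets.

    Parameters
    ----------
    ensemble : TrajectoryEnsemble
    targets : ReweightTargets
        Every target residue must be present in the ensemble.
    prior_weights : array, optional
        Reference weights w⁰ (uniform 1/N by default).
    """

    def __init__(
        self,
        ensemble: TrajectoryEnsemble,
        targets: ReweightTargets,
        prior_weights=None,
    ):
        self.ensemble = ensemble
        self.targets = targets
        idx = {rid: i for i, rid in enumerate(ensemble.residue_ids)}
        missing = [r for r in targets.residue_ids if r not in idx]
        if missing:
            raise ValueError(f"target residues absent from ensemble: {missing}")
        rows = [idx[r] for r in targets.residue_ids]
        self._feats = frame_features(ensemble.vectors[rows])  # (n_targets, N, 6)
        self.n_frames = ensemble.n_frames
        if prior_weights is None:
            self.w0 = np.full(self.n_frames, 1.0 / self.n_frames)
        else:
            self.w0 = np.asarray(prior_weights, dtype=float)
            self.w0 = self.w0 / self.w0.sum()
        self._t = targets.o2_mean
        self._inv_var = 1.0 / targets.o2_sd**2

    # -- objective ----------------------------------------------------------

    def objective_and_gradient(self, u, theta: float):
        """L(u) and ∂L/∂u for unnormalized weights u ≥ 0.

        With w = u/Σu, ∂F/∂u_j = (g_j − Σ_k w_k g_k)/Σu for any F with
        simplex gradient g = ∂F/∂w: the tangent projection plus 1/Σu scale.
        """
        u = np.asarray(u, dtype=float)
        if not np.all(np.isfinite(u)):
            raise ValueError("non-finite weights")
        if theta < 0:
            raise ValueError("theta must be non-negative")
        total = u.sum()
        w = u / total
        m = np.einsum("j,rjc->rc", w, self._feats)
        o2 = o2_from_moments(m)
        resid = o2 - self._t
        chi2 = float(np.sum(resid**2 * self._inv_var))
        # w ln(w/w0) -> 0 as w -> 0; its one-sided derivative diverges there,
        # so frames at the zero bound get a bounded subgradient surrogate
        # (keeps the line search stable; such frames stay on the boundary)
        logterm = np.where(w > _TINY, np.log(np.maximum(w, _TINY) / self.w0), 0.0)
        srel = float(np.sum(np.where(w > 0, w * logterm, 0.0)))
        lval = chi2 + theta * srel
        # gradient wrt w
        do2_dw = 3.0 * np.einsum("rc,rjc->rj", m, self._feats)  # (n_targets, N)
        g_w = np.einsum("r,rj->j", 2.0 * resid * self._inv_var, do2_dw)
        g_w = g_w + theta * (logterm + 1.0)
        g_u = (g_w - np.dot(w, g_w)) / total
        return lval, g_u

    def chi2_srel(self, weights):
        """(χ², S_REL) of a normalized weight vector (diagnostics)."""
        l0, _ = self.objective_and_gradient(np.asarray(weights), 0.0)
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
        pos = w > 0
        srel = float(np.sum(w[pos] * np.log(w[pos] / self.w0[pos])))
        return l0, srel

    # -- single-θ solve -----------------------------------------------------

    def fit(
        self,
        theta: float,
        init=None,
        gtol: float = 1e-8,
        ftol: float = 1e-12,
        max_iter: int = 5000,
    ) -> ReweightResults:
        """Box-constrained L-BFGS-B minimization of L at one θ.

        Deterministic given the initial point and tolerances; optimizer
        failure is flagged in the results, and the best iterate returned.
        """
        u0 = np.ones(self.n_frames) if init is None else np.asarray(init, dtype=float)
        res = minimize(
            self.objective_and_gradient,
            u0,
            args=(theta,),
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, None)] * self.n_frames,
            options={"maxiter": max_iter, "ftol": ftol, "gtol": gtol, "maxfun": 10 * max_iter},
        )
        w = res.x / res.x.sum()
        chi2, srel = self.chi2_srel(w)
        o2_prior = weighted_o2(self.ensemble, self.w0)
        o2_post = weighted_o2(self.ensemble, w)
        return ReweightResults(
            weights=w,
            theta=float(theta),
            chi2=chi2,
            s_rel=srel,
            neff=neff(w, "exp_srel", self.w0),
            neff_kish=neff(w, "kish"),
            converged=bool(res.success),
            n_iterations=int(res.nit),
            grad_norm=float(np.max(np.abs(res.jac))),
            o2_prior=o2_prior,
            o2_posterior=o2_post,
            targets=self.targets,
            message=str(res.message),
        )

    # -- θ scan -------------------------------------------------------------

    def l_curve(self, thetas) -> LCurve:
        """Solve along a log-spaced θ grid, warm-starting descending in θ.

        High θ keeps weights near the prior, so scanning from large to
        small θ lets each solve start from the previous optimum (the
        continuation path of the regularized problem).
        """
        thetas = np.sort(np.asarray(thetas, dtype=float))
        if thetas.size < 1:
            raise ValueError("theta grid must not be empty")
        results: list[ReweightResults | None] = [None] * thetas.size
        init = None
        for k in range(thetas.size - 1, -1, -1):
            try:
                r = self.fit(thetas[k], init=init)
                results[k] = r
                init = r.weights * self.n_frames  # unnormalized warm start
            except Exception as exc:  # keep scanning on single-θ failure
                import warnings

                warnings.warn(f"reweighting failed at theta={thetas[k]:g}: {exc}")
        ok = [r for r in results if r is not None]
        if not ok:
            raise RuntimeError("every theta in the scan failed")
        return LCurve(
            theta=np.array([r.theta for r in ok]),
            chi2=np.array([r.chi2 for r in ok]),
            s_rel=np.array([r.s_rel for r in ok]),
            neff=np.array([r.neff for r in ok]),
            results=ok,
        )


def select_theta_elbow(
    lcurve: LCurve, method: str = "max_curvature", rel_tol: float = 0.10
) -> float:
    """Pick θ at the elbow of the (log θ, log χ²) trade-off curve.

    ``max_curvature`` maximizes the discrete curvature of log χ² against
    log θ; ``chi2_plateau`` returns the largest θ whose χ² is within
    ``rel_tol`` of the small-θ limit. A flat curve returns the largest θ
    and sets ``no_elbow``.
    """
    if lcurve.theta.size < 5:
        raise ValueError("elbow selection needs at least 5 grid points")
    x = np.log(lcurve.theta)
    chi2 = np.maximum(lcurve.chi2, 1e-300)
    span = chi2.max() - chi2.min()
    if span <= 1e-12 * max(chi2.max(), 1.0):
        lcurve.selected_theta = float(lcurve.theta[-1])
        lcurve.selection_method = method
        lcurve.no_elbow = True
        return lcurve.selected_theta
    if method == "chi2_plateau":
        ref = chi2[0]  # smallest θ: best attainable fit
        ok = np.nonzero(chi2 <= ref * (1.0 + rel_tol))[0]
        theta_sel = float(lcurve.theta[ok[-1]])
    elif method == "max_curvature":
        y = np.log(chi2)
        dy = np.gradient(y, x)
        d2y = np.gradient(dy, x)
        kappa = np.abs(d2y) / (1.0 + dy**2) ** 1.5
        theta_sel = float(lcurve.theta[int(np.argmax(kappa))])
    else:
        raise ValueError(f"unknown elbow method {method!r}")
    lcurve.selected_theta = theta_sel
    lcurve.selection_method = method
    lcurve.no_elbow = False
    return theta_sel
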