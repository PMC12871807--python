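"""Synthetic data with analytically known ground truth.

Two generators mirror the statistical structure the analysis assumes:

* noisy 3Q/SQ build-up/decay curves from known (η, δ), an amplitude and an
  N-exponential relaxation envelope, with independent homoscedastic
  Gaussian noise per coherence type;
* methyl χ-angle trajectories from a Markov rotamer-jump process among a
  small set of wells (e.g. the trans/gauche± wells of the methionine χ3)
  with Gaussian intra-well libration, mapped to unit bond vectors through
  the local spherical parameterization at a fixed polar bond angle.

Because the stationary law of the jump process is known, the order
parameter and the binned dihedral entropy of the generated ensembles have
closed forms (`analytic_o2_for_jump_model`, `analytic_bin_entropy`), which
serve as independent oracles for every downstream stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .ensemble import TrajectoryEnsemble, axis_vector_from_angles, o2_from_moments
from .relaxation import DecayCurve, intensity_3q, intensity_sq

__all__ = [
    "DecayCurveSpec",
    "RotamerJumpSpec",
    "simulate_decay_curves",
    "simulate_rotamer_trajectory",
    "assign_wells",
    "analytic_o2_for_jump_model",
    "analytic_bin_entropy",
    "simulate_weighted_ensemble",
]


@dataclass
class DecayCurveSpec:
    """Ground-truth parameters for one peak's 3Q/SQ decay pair.

    Rates are in s⁻¹, delays in seconds, noise scales in the intensity
    units of the generated curves.
    """

    eta: float = 30.0
    delta: float = 5.0
    amplitude: float = 1.0
    rates: tuple = (40.0, 120.0)
    fractions: tuple = (0.5, 0.5)
    delays: tuple = (0.4e-3, 1.6e-3, 3.0e-3, 4.0e-3, 6.0e-3, 8.0e-3, 10.0e-3)
    noise_sd_sq: float = 0.0
    noise_sd_3q: float = 0.0
    seed: int = 0
    peak_id: str = "synthetic"

    def __post_init__(self):
        delays = np.asarray(self.delays, dtype=float)
        if delays.size == 0 or np.any(delays <= 0):
            raise ValueError("delays must be strictly positive")
        if np.any(np.diff(delays) <= 0):
            raise ValueError("delays must be strictly increasing")
        rates = np.asarray(self.rates, dtype=float)
        fracs = np.asarray(self.fractions, dtype=float)
        if rates.size == 0:
            raise ValueError("at least one relaxation rate is required")
        if rates.size != fracs.size:
            raise ValueError("rates and fractions must have equal length")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if self.noise_sd_sq < 0 or self.noise_sd_3q < 0:
            raise ValueError("noise scales must be non-negative")


def simulate_decay_curves(spec: DecayCurveSpec) -> tuple[DecayCurve, DecayCurve]:
    """Simulate one interleaved (SQ, 3Q) decay pair.

    Noiseless means follow the closed-form intensity models exactly; the
    quotient of the two curves therefore reproduces the build-up ratio at
    every delay by construction.
    """
    rng = np.random.default_rng(spec.seed)
    delays = np.asarray(spec.delays, dtype=float)
    mean_tq = intensity_3q(
        spec.eta, spec.delta, delays, spec.amplitude, spec.rates, spec.fractions
    )
    mean_sq = intensity_sq(
        spec.eta, spec.delta, delays, spec.amplitude, spec.rates, spec.fractions
    )
    sq = mean_sq + rng.normal(0.0, 1.0, delays.shape) * spec.noise_sd_sq
    tq = mean_tq + rng.normal(0.0, 1.0, delays.shape) * spec.noise_sd_3q
    return (
        DecayCurve(spec.peak_id, "SQ", delays, sq, noise_sd=spec.noise_sd_sq),
        DecayCurve(spec.peak_id, "3Q", delays, tq, noise_sd=spec.noise_sd_3q),
    )


@dataclass
class RotamerJumpSpec:
    """A Markov rotamer-jump model for one χ dihedral.

    ``well_angles`` are the rotamer centers in degrees (e.g. 60/180/−60 for
    trans and gauche± of the methionine χ3), ``populations`` their
    stationary probabilities, ``libration_sd`` the Gaussian intra-well
    width, and ``theta_bond`` the fixed polar bond angle carrying the χ
    rotation onto the methyl axis.
    """

    well_angles: tuple = (60.0, 180.0, -60.0)
    populations: tuple = (1 / 3, 1 / 3, 1 / 3)
    exchange_prob: float = 0.5
    libration_sd: float = 10.0
    theta_bond: float = 109.47
    n_frames: int = 10000
    seed: int = 0
    kinetics: str = "metropolis"

    def __post_init__(self):
        pops = np.asarray(self.populations, dtype=float)
        wells = np.asarray(self.well_angles, dtype=float)
        if wells.size != pops.size:
            raise ValueError("well_angles and populations must have equal length")
        if np.any(pops < 0) or abs(pops.sum() - 1.0) > 1e-12:
            raise ValueError("populations must be non-negative and sum to 1")
        if not 0.0 <= self.exchange_prob <= 1.0:
            raise ValueError("exchange_prob must lie in [0, 1]")
        if self.libration_sd < 0:
            raise ValueError("libration_sd must be non-negative")
        if self.n_frames < 1:
            raise ValueError("n_frames must be at least 1")
        if self.kinetics not in ("metropolis", "iid"):
            raise ValueError("kinetics must be 'metropolis' or 'iid'")
        if wells.size > 1 and self.libration_sd > 0:
            sep = np.abs(wells[:, None] - wells[None, :])
            sep = np.minimum(sep, 360.0 - sep)
            np.fill_diagonal(sep, np.inf)
            if sep.min() < 3.0 * self.libration_sd:
                warnings.warn(
                    "rotamer wells closer than 3×libration_sd: histogram bins may mix",
                    stacklevel=2,
                )


def _wrap_angles(a):
    """Map angles (degrees) onto (−180, 180]."""
    out = np.mod(np.asarray(a, dtype=float) + 180.0, 360.0) - 180.0
    return np.where(out == -180.0, 180.0, out)


def _simulate_well_labels(spec: RotamerJumpSpec, rng) -> np.ndarray:
    """Metropolis jump chain among wells with the requested stationary law.

    Any scheme with the correct stationary distribution satisfies the
    contract (O² and entropy depend only on populations, not kinetics);
    Metropolis proposals to a uniformly random other well give geometric
    decorrelation controlled by ``exchange_prob``; ``kinetics="iid"`` draws
    every frame independently from the stationary law (the maximally mixing
    chain — appropriate for equilibrium-ensemble fixtures where no kinetic
    realism is wanted).
    """
    pops = np.asarray(spec.populations, dtype=float)
    k = pops.size
    if spec.kinetics == "iid":
        return rng.choice(k, size=spec.n_frames, p=pops)
    labels = np.empty(spec.n_frames, dtype=np.int64)
    state = int(rng.choice(k, p=pops))
    if k == 1 or spec.exchange_prob == 0.0:
        labels[:] = state
        return labels
    attempt = rng.random(spec.n_frames) < spec.exchange_prob
    # propose one of the other k-1 wells uniformly
    prop_off = rng.integers(1, k, size=spec.n_frames)
    accept_u = rng.random(spec.n_frames)
    for t in range(spec.n_frames):
        if attempt[t]:
            prop = (state + prop_off[t]) % k
            if pops[state] == 0.0 or accept_u[t] * pops[state] < pops[prop]:
                state = prop
        labels[t] = state
    return labels


def simulate_rotamer_trajectory(spec: RotamerJumpSpec):
    """Simulate (bond vectors, χ series) from the rotamer-jump model.

    Returns
    -------
    vectors : (n_frames, 3) unit methyl-axis vectors
    chi : (n_frames,) χ angles in degrees on (−180, 180]
    labels : (n_frames,) well indices (bookkeeping; nearest-center labels)
    """
    rng = np.random.default_rng(spec.seed)
    labels = _simulate_well_labels(spec, rng)
    wells = np.asarray(spec.well_angles, dtype=float)
    chi = wells[labels]
    if spec.libration_sd > 0:
        chi = chi + rng.normal(0.0, spec.libration_sd, chi.shape)
    chi = _wrap_angles(chi)
    vectors = axis_vector_from_angles(spec.theta_bond, chi)
    return vectors, chi, labels


def assign_wells(chi, well_angles) -> np.ndarray:
    """Label each angle by its nearest rotamer center (circular distance)."""
    chi = np.asarray(chi, dtype=float)
    wells = np.asarray(well_angles, dtype=float)
    d = np.abs(chi[..., None] - wells)
    d = np.minimum(d, 360.0 - d)
    return np.argmin(d, axis=-1)


def _circular_moments(spec: RotamerJumpSpec):
    """E[cos kχ], E[sin kχ] (k = 1, 2) of the stationary libration mixture.

    For χ = c + ε with ε ~ N(0, σ²), E[e^{ikχ}] = e^{ikc} e^{−k²σ²/2}
    exactly (integer harmonics are unaffected by wrapping), so the tensor
    moments of the mixture are available in closed form.
    """
    pops = np.asarray(spec.populations, dtype=float)
    wells = np.radians(np.asarray(spec.well_angles, dtype=float))
    sig = np.radians(spec.libration_sd)
    out = {}
    for k in (1, 2):
        damp = np.exp(-0.5 * (k * sig) ** 2)
        out[f"c{k}"] = float(np.sum(pops * np.cos(k * wells)) * damp)
        out[f"s{k}"] = float(np.sum(pops * np.sin(k * wells)) * damp)
    return out


def analytic_o2_for_jump_model(spec: RotamerJumpSpec, populations=None) -> float:
    """Exact O² of the stationary rotamer mixture (no trajectory sampling).

    Evaluates the second-moment tensor of μ̂ under the well mixture with
    Gaussian libration and applies the tensor expansion.
    """
    if populations is not None:
        spec = RotamerJumpSpec(
            well_angles=spec.well_angles,
            populations=tuple(populations),
            exchange_prob=spec.exchange_prob,
            libration_sd=spec.libration_sd,
            theta_bond=spec.theta_bond,
            n_frames=spec.n_frames,
            seed=spec.seed,
            kinetics=spec.kinetics,
        )
    m = _circular_moments(spec)
    thp = np.pi - np.radians(spec.theta_bond)
    s, c = np.sin(thp), np.cos(thp)
    mxx = s * s * (1.0 + m["c2"]) / 2.0
    myy = s * s * (1.0 - m["c2"]) / 2.0
    mzz = c * c
    mxy = s * s * m["s2"] / 2.0
    mxz = s * c * m["c1"]
    myz = s * c * m["s1"]
    packed = np.array([mxx, myy, mzz, np.sqrt(2) * mxy, np.sqrt(2) * mxz, np.sqrt(2) * myz])
    return float(o2_from_moments(packed))


def analytic_bin_entropy(spec: RotamerJumpSpec, bin_width: float = 10.0) -> float:
    """Exact Gibbs–Shannon entropy of the stationary χ mixture on fixed bins.

    Bin probabilities are wrapped-Gaussian mixture masses computed from the
    normal CDF (wrapping summed over ±3 periods), matching the histogram
    convention of the entropy stage: edges anchored at −180°, right-closed.
    """
    edges = np.arange(-180.0, 180.0 + bin_width / 2, bin_width)
    pops = np.asarray(spec.populations, dtype=float)
    wells = np.asarray(spec.well_angles, dtype=float)
    probs = np.zeros(edges.size - 1)
    if spec.libration_sd == 0:
        idx = np.clip(np.ceil((_wrap_angles(wells) + 180.0) / bin_width) - 1, 0, probs.size - 1)
        for p, i in zip(pops, idx.astype(int)):
            probs[i] += p
    else:
        for p, w in zip(pops, wells):
            for shift in (-360.0, 0.0, 360.0, -720.0, 720.0):
                cdf = norm.cdf(edges, loc=w + shift, scale=spec.libration_sd)
                probs += p * np.diff(cdf)
    probs = probs / probs.sum()
    nz = probs[probs > 0]
    return float(-np.sum(nz * np.log(nz)))


def simulate_weighted_ensemble(
    spec_prior: RotamerJumpSpec,
    populations_target,
    n_residues: int,
    seed: int = 0,
    residue_prefix: str = "M",
):
    """Reweighting recovery fixture: prior-sampled frames, known targets.

    Each residue gets an independent χ trajectory under the prior
    populations; the returned targets are the analytic O² of the *target*
    populations, so a reweighting run can be scored against ground truth.

    Returns (TrajectoryEnsemble, targets array, labels (n_res, n_frames)).
    """
    tgt = np.asarray(populations_target, dtype=float)
    prior = np.asarray(spec_prior.populations, dtype=float)
    if tgt.size != prior.size:
        raise ValueError("target populations must match the prior's wells")
    if np.any(tgt < 0) or abs(tgt.sum() - 1.0) > 1e-12:
        raise ValueError("target populations must be non-negative and sum to 1")
    if np.any((tgt > 0) & (prior == 0)):
        raise ValueError(
            "target places mass on wells the prior never visits: unreachable by reweighting"
        )
    if n_residues < 1:
        raise ValueError("n_residues must be at least 1")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_residues)]
    vecs, chis, labels = [], [], []
    for r in range(n_residues):
        spec_r = RotamerJumpSpec(
            well_angles=spec_prior.well_angles,
            populations=spec_prior.populations,
            exchange_prob=spec_prior.exchange_prob,
            libration_sd=spec_prior.libration_sd,
            theta_bond=spec_prior.theta_bond,
            n_frames=spec_prior.n_frames,
            seed=child_seeds[r],
            kinetics=spec_prior.kinetics,
        )
        v, c, lab = simulate_rotamer_trajectory(spec_r)
        vecs.append(v)
        chis.append(c)
        labels.append(lab)
    ens = TrajectoryEnsemble(
        residue_ids=[f"{residue_prefix}{100 + r}" for r in range(n_residues)],
        vectors=np.stack(vecs),
        chi=np.stack(chis),
        provenance="synthetic",
    )
    target_o2 = np.full(n_residues, analytic_o2_for_jump_model(spec_prior, populations=tgt))
    return ens, target_o2, np.stack(labels)
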