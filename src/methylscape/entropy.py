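"""Side-chain conformational entropy from weighted χ-angle histograms.

Each eligible side chain's χ dihedrals are binned on a fixed 10° grid over
(−180°, 180°]; the (possibly reweighted) bin probabilities P(k) are the
summed frame weights per bin, and the dimensionless per-residue entropy is
the Gibbs–Shannon form averaged over the residue's dihedrals:

    S_SC = (1/Nχ) Σ_χ [ −Σ_k P(k) ln P(k) ],     k_B ≡ 1.

Eligibility follows the number of χ angles: residues with 1 ≤ Nχ ≤ 3 are
included; alanine and glycine (no χ) and lysine/arginine (Nχ = 4,
intractable convergence) are excluded. The per-dihedral marginal treatment
is the default; a joint-histogram mode over the full χ space is available
but experimental (it needs far more sampling per residue).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NCHI",
    "DihedralHistogram",
    "EntropyProfile",
    "eligible_residues",
    "weighted_dihedral_histogram",
    "residue_entropy",
    "joint_residue_entropy",
    "entropy_buildup",
    "compute_entropy_profile",
    "delta_entropy",
    "GAS_CONSTANT_J_MOL_K",
]

GAS_CONSTANT_J_MOL_K = 8.31446261815324

# Number of side-chain χ dihedrals per standard residue.
NCHI = {
    "ALA": 0, "GLY": 0,
    "SER": 1, "CYS": 1, "THR": 1, "VAL": 1,
    "ASP": 2, "ASN": 2, "HIS": 2, "ILE": 2, "LEU": 2,
    "PHE": 2, "PRO": 2, "TRP": 2, "TYR": 2,
    "GLU": 3, "GLN": 3, "MET": 3,
    "LYS": 4, "ARG": 4,
}


def eligible_residues(residues):
    """Split residues into entropy-eligible and excluded, with reasons.

    Parameters
    ----------
    residues : iterable of (residue_id, three-letter name) pairs, or names.

    Returns
    -------
    included : list of (residue_id, name, n_chi)
    report : dict residue_id -> exclusion reason
    """
    included, report = [], {}
    for item in residues:
        rid, name = item if isinstance(item, tuple) else (item, item)
        code = str(name).upper()
        if code not in NCHI:
            report[rid] = f"unknown residue code {name!r}"
            warnings.warn(f"unknown residue code {name!r}; excluded", stacklevel=2)
            continue
        n = NCHI[code]
        if n == 0:
            report[rid] = "no chi angle"
        elif n > 3:
            report[rid] = f"{n} chi angles (> 3, intractable)"
        else:
            included.append((rid, code, n))
    return included, report


@dataclass
class DihedralHistogram:
    """Weighted probabilities of one χ angle on the fixed angular grid."""

    residue_id: str
    chi_index: int
    edges: np.ndarray
    probabilities: np.ndarray
    n_dropped: int = 0

    def __post_init__(self):
        p = self.probabilities
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("bin probabilities must be non-negative and sum to 1")


def _bin_index(angles, bin_width: float, offset: float):
    """Right-closed bins (lo, lo+w] anchored at −180° (+ optional offset)."""
    a = np.mod(np.asarray(angles, dtype=float) - offset + 180.0, 360.0)
    a = np.where(a == 0.0, 360.0, a)  # wrap −180 into the top bin
    idx = np.ceil(a / bin_width).astype(int) - 1
    return idx


def weighted_dihedral_histogram(
    angles,
    weights=None,
    bin_width: float = 10.0,
    residue_id: str = "",
    chi_index: int = 1,
    offset: float = 0.0,
) -> DihedralHistogram:
    """P(k) = Σ_{j ∈ bin k} w_j over right-closed 10° bins on (−180, 180].

    Non-finite angles are dropped (counted); the remaining weights are
    renormalized. ``offset`` shifts all bin edges (half-bin sensitivity
    analysis of rotamer-boundary effects).
    """
    angles = np.asarray(angles, dtype=float)
    n = angles.size
    if n == 0:
        raise ValueError("empty angle series")
    if 360.0 % bin_width:
        raise ValueError("bin width must divide 360°")
    w = np.full(n, 1.0 / n) if weights is None else np.asarray(weights, dtype=float)
    finite = np.isfinite(angles)
    n_dropped = int(n - finite.sum())
    angles, w = angles[finite], w[finite]
    if angles.size == 0:
        raise ValueError("no finite angles in series")
    w = w / w.sum()
    n_bins = int(round(360.0 / bin_width))
    idx = _bin_index(angles, bin_width, offset)
    probs = np.bincount(idx, weights=w, minlength=n_bins)
    edges = offset + np.arange(-180.0, 180.0 + bin_width / 2, bin_width)
    return DihedralHistogram(
        residue_id=residue_id,
        chi_index=chi_index,
        edges=edges,
        probabilities=probs,
        n_dropped=n_dropped,
    )


def _shannon(p):
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def residue_entropy(histograms, n_chi: int | None = None) -> float:
    """Dimensionless S_SC: per-dihedral Shannon entropies averaged over Nχ."""
    hists = list(histograms)
    if not hists:
        raise ValueError("need at least one histogram")
    n_chi = len(hists) if n_chi is None else n_chi
    return sum(_shannon(h.probabilities) for h in hists) / n_chi


def joint_residue_entropy(angle_matrix, weights=None, bin_width: float = 10.0) -> float:
    """Experimental: entropy of the joint χ distribution, divided by Nχ.

    Bins the full (χ1, …, χNχ) space; needs vastly more sampling than the
    marginal default and is provided for sensitivity analysis only.
    """
    a = np.asarray(angle_matrix, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    n, k = a.shape
    w = np.full(n, 1.0 / n) if weights is None else np.asarray(weights, dtype=float)
    finite = np.all(np.isfinite(a), axis=1)
    a, w = a[finite], w[finite]
    w = w / w.sum()
    n_bins = int(round(360.0 / bin_width))
    flat = np.zeros(a.shape[0], dtype=np.int64)
    for c in range(k):
        flat = flat * n_bins + _bin_index(a[:, c], bin_width, 0.0)
    probs = np.bincount(flat, weights=w)
    return _shannon(probs) / k


def entropy_buildup(angles, weights=None, checkpoints=None, bin_width: float = 10.0):
    """S_SC on growing frame prefixes (convergence build-up curve).

    ``angles`` may be (n_frames,) for one dihedral or (n_frames, n_chi).
    Prefix weights are renormalized at each checkpoint; the final
    checkpoint (full length) reproduces the full-series entropy exactly.
    """
    a = np.asarray(angles, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    n, k = a.shape
    if checkpoints is None:
        checkpoints = np.unique(np.geomspace(10, n, 20).astype(int))
    checkpoints = np.asarray(checkpoints, dtype=int)
    if np.any(np.diff(checkpoints) <= 0) or checkpoints[-1] > n:
        raise ValueError("checkpoints must be increasing and within the series")
    w = np.full(n, 1.0 / n) if weights is None else np.asarray(weights, dtype=float)
    rows = []
    for m in checkpoints:
        hs = [
            weighted_dihedral_histogram(a[:m, c], w[:m], bin_width, chi_index=c + 1)
            for c in range(k)
        ]
        rows.append((int(m), residue_entropy(hs)))
    return pd.DataFrame(rows, columns=["n_frames", "s_sc"])


@dataclass
class EntropyProfile:
    """Per-residue and total side-chain entropy for one ligand state."""

    state: str
    table: pd.DataFrame  # residue_id, residue_name, n_chi, s_sc, flag
    excluded: dict = field(default_factory=dict)
    neff: float = 1.0

    @property
    def total(self) -> float:
        return float(self.table["s_sc"].sum())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def compute_entropy_profile(
    ensemble,
    weights=None,
    state: str = "",
    bin_width: float = 10.0,
    mode: str = "marginal",
    min_effective_frames: int = 100,
) -> EntropyProfile:
    """Entropy profile of a TrajectoryEnsemble under optional reweighting.

    Nχ per residue is the number of χ series actually present (capped by
    the residue's chemical Nχ); residues whose effective frame count
    (Neff · n_frames) is below ``min_effective_frames`` are flagged
    low-confidence but still computed.
    """
    from .reweight import neff as _neff

    w = ensemble.weights if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    eff = _neff(w, "kish")
    pairs = list(zip(ensemble.residue_ids, ensemble.residue_names))
    included, report = eligible_residues(pairs)
    rows = []
    idx = {rid: i for i, rid in enumerate(ensemble.residue_ids)}
    for rid, name, n_chi_chem in included:
        r = idx[rid]
        chi_cols = [
            c for c in range(ensemble.n_chi) if np.any(np.isfinite(ensemble.chi[r, :, c]))
        ]
        chi_cols = chi_cols[: n_chi_chem]
        if not chi_cols:
            report[rid] = "no chi series in ensemble"
            continue
        if mode == "joint":
            s = joint_residue_entropy(ensemble.chi[r][:, chi_cols], w, bin_width)
        else:
            hists = [
                weighted_dihedral_histogram(
                    ensemble.chi[r, :, c], w, bin_width, residue_id=rid, chi_index=c + 1
                )
                for c in chi_cols
            ]
            s = residue_entropy(hists)
        flag = "" if eff * ensemble.n_frames >= min_effective_frames else "low_effective_frames"
        rows.append((rid, name, len(chi_cols), s, flag))
    table = pd.DataFrame(rows, columns=["residue_id", "residue_name", "n_chi", "s_sc", "flag"])
    return EntropyProfile(state=state, table=table, excluded=report, neff=eff)


def delta_entropy(profile_a: EntropyProfile, profile_b: EntropyProfile):
    """Per-residue ΔS = S_b − S_a on the shared residue set, plus totals.

    Positive ΔS means state b is more disordered. Mismatched residues are
    reported in the frame attrs; fully disjoint sets are an error.
    """
    a = profile_a.table.set_index("residue_id")["s_sc"]
    b = profile_b.table.set_index("residue_id")["s_sc"]
    common = a.index.intersection(b.index)
    if common.empty:
        raise ValueError("entropy profiles share no residues")
    out = pd.DataFrame(
        {
            "s_a": a.loc[common],
            "s_b": b.loc[common],
            "delta_s": b.loc[common] - a.loc[common],
        }
    )
    out.index.name = "residue_id"
    out.attrs["state_a"] = profile_a.state
    out.attrs["state_b"] = profile_b.state
    out.attrs["total_a"] = float(a.loc[common].sum())
    out.attrs["total_b"] = float(b.loc[common].sum())
    out.attrs["total_delta"] = float(out["delta_s"].sum())
    out.attrs["only_in_a"] = sorted(a.index.difference(b.index))
    out.attrs["only_in_b"] = sorted(b.index.difference(a.index))
    return out
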