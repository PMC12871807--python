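"""Methyl-axis order parameters from conformational ensembles.

The squared generalized order parameter O²axis of a methyl symmetry axis
(for methionine, the Sδ–Cε bond) measures its angular restriction in the
molecular frame: 1 for complete rigidity, 0 for isotropic disorder. Two
equivalent routes are implemented:

* the static expansion of the traceless second-rank tensor of the unit
  bond vector μ̂(t) over (optionally weighted) frames;
* the long-time plateau of the internal time correlation function
  C_int(τ) = ⟨P2(μ̂(t)·μ̂(t+τ))⟩ with P2(x) = (3x² − 1)/2.

The bond vector can be parameterized either directly in Cartesian
coordinates of the superposed molecular frame, or in a local spherical
system (polar angle = the Cγ–Sδ–Cε bond angle, azimuth = the χ3 dihedral)
which is insensitive to residual global motion by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "TrajectoryEnsemble",
    "TimeCorrelation",
    "axis_vector_from_angles",
    "compute_dihedral",
    "bond_angle",
    "superpose_frames",
    "extract_methyl_axes",
    "tensor_moments",
    "o2_from_moments",
    "o2_tensor",
    "internal_tcf",
    "average_tcf",
    "tcf_plateau",
]


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------

def axis_vector_from_angles(theta_bond_deg, chi_deg):
    """Unit bond vector from the local spherical parameterization.

    ``theta_bond_deg`` is the Cγ–Sδ–Cε bond angle θ; the axis polar angle is
    π − θ. ``chi_deg`` is the χ3 dihedral, used directly as azimuth φ:

        μ̂ = (sin(π−θ) cos φ, sin(π−θ) sin φ, cos(π−θ))
    """
    th = np.pi - np.radians(np.asarray(theta_bond_deg, dtype=float))
    ph = np.radians(np.asarray(chi_deg, dtype=float))
    th, ph = np.broadcast_arrays(th, ph)
    return np.stack(
        [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)], axis=-1
    )


def compute_dihedral(p1, p2, p3, p4):
    """Signed dihedral angle in degrees on (−180, 180], IUPAC cis = 0°.

    Accepts single points or (n, 3) coordinate series.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.any(np.linalg.norm(n1, axis=-1) < 1e-12) or np.any(
        np.linalg.norm(n2, axis=-1) < 1e-12
    ):
        raise ValueError("degenerate (collinear) geometry: dihedral undefined")
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b2n, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # IUPAC convention: angle of p4 relative to p1 looking down p2->p3,
    # cis (eclipsed) = 0. arctan2 form above yields exactly this, with the
    # branch (−180, 180]: map −180 to +180.
    return np.where(ang <= -180.0, ang + 360.0, ang)


def bond_angle(p1, p2, p3):
    """Angle at p2 between bonds p2–p1 and p2–p3, degrees."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    v1 = p1 - p2
    v2 = p3 - p2
    c = np.sum(v1 * v2, axis=-1) / (
        np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1)
    )
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))


def superpose_frames(coordinates, reference, selection=None):
    """Least-squares superposition of each frame onto a reference structure.

    Parameters
    ----------
    coordinates : (n_frames, n_atoms, 3) array
    reference : (n_atoms, 3) array
    selection : index array, optional
        Atoms used for the fit (e.g. backbone Cα); all atoms are moved.

    Returns
    -------
    aligned : (n_frames, n_atoms, 3) array
    rmsd : (n_frames,) array of post-fit RMSDs over the selection
    """
    coords = np.asarray(coordinates, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    sel = np.arange(ref.shape[0]) if selection is None else np.asarray(selection)
    if sel.size < 3:
        raise ValueError("superposition needs at least 3 fit atoms")
    ref_sel = ref[sel]
    ref_cen = ref_sel.mean(axis=0)
    centered = ref_sel - ref_cen
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) fit selection")
    aligned = np.empty_like(coords)
    rmsds = np.empty(coords.shape[0])
    for i, frame in enumerate(coords):
        mob = frame[sel]
        mob_cen = mob.mean(axis=0)
        rot, rssd = Rotation.align_vectors(centered, mob - mob_cen)
        aligned[i] = rot.apply(frame - mob_cen) + ref_cen
        rmsds[i] = rssd / np.sqrt(sel.size)
    return aligned, rmsds


# ---------------------------------------------------------------------------
# Ensemble container
# ---------------------------------------------------------------------------

_TSV_COLS = ["frame", "residue_id", "residue_name", "x", "y", "z", "chi1", "chi2", "chi3"]


@dataclass
class TrajectoryEnsemble:
    """Frames × residues of unit methyl-axis vectors and χ-angle series.

    Attributes
    ----------
    residue_ids : list of str, e.g. ``"M244"``.
    vectors : (n_residues, n_frames, 3) unit vectors in the molecular frame.
    chi : (n_residues, n_frames, n_chi) dihedrals in degrees; NaN columns
        mark angles a residue does not have.
    weights : (n_frames,) normalized frame weights (uniform prior default).
    residue_names : three-letter codes, used for entropy eligibility.
    """

    residue_ids: list
    vectors: np.ndarray
    chi: np.ndarray
    weights: np.ndarray | None = None
    residue_names: list | None = None
    theta_bond: np.ndarray | None = None  # optional (n_residues, n_frames) degrees
    provenance: str = "table"
    frame_stride: int = 1

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.chi = np.asarray(self.chi, dtype=float)
        if self.vectors.ndim != 3 or self.vectors.shape[2] != 3:
            raise ValueError("vectors must have shape (n_residues, n_frames, 3)")
        if self.chi.ndim == 2:
            self.chi = self.chi[:, :, None]
        if self.chi.shape[:2] != self.vectors.shape[:2]:
            raise ValueError("chi and vectors disagree on residues/frames")
        norms = np.linalg.norm(self.vectors, axis=2)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("bond vectors must be unit length")
        if self.weights is None:
            self.weights = np.full(self.n_frames, 1.0 / self.n_frames)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if np.any(self.weights < 0):
                raise ValueError("weights must be non-negative")
            s = self.weights.sum()
            if abs(s - 1.0) > 1e-9:
                self.weights = self.weights / s
        if self.residue_names is None:
            self.residue_names = ["MET"] * len(self.residue_ids)

    @property
    def n_frames(self) -> int:
        return self.vectors.shape[1]

    @property
    def n_residues(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_chi(self) -> int:
        return self.chi.shape[2]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r, rid in enumerate(self.residue_ids):
            df = pd.DataFrame(
                {
                    "frame": np.arange(self.n_frames),
                    "residue_id": rid,
                    "residue_name": self.residue_names[r],
                    "x": self.vectors[r, :, 0],
                    "y": self.vectors[r, :, 1],
                    "z": self.vectors[r, :, 2],
                }
            )
            for k in range(3):
                df[f"chi{k+1}"] = self.chi[r, :, k] if k < self.n_chi else np.nan
            rows.append(df)
        return pd.concat(rows, ignore_index=True)[_TSV_COLS]

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    def to_parquet(self, path) -> None:
        """Compact binary columnar form (same schema as the TSV)."""
        self.to_frame().to_parquet(path, index=False)

    @classmethod
    def _from_frame(cls, df: pd.DataFrame) -> "TrajectoryEnsemble":
        ids, names, vecs, chis = [], [], [], []
        for rid, grp in df.groupby("residue_id", sort=True):
            grp = grp.sort_values("frame")
            ids.append(str(rid))
            names.append(str(grp["residue_name"].iloc[0]))
            vecs.append(grp[["x", "y", "z"]].to_numpy())
            chis.append(grp[["chi1", "chi2", "chi3"]].to_numpy())
        chi = np.stack(chis)
        n_chi = 3
        while n_chi > 1 and np.all(np.isnan(chi[:, :, n_chi - 1])):
            n_chi -= 1
        return cls(
            residue_ids=ids,
            vectors=np.stack(vecs),
            chi=chi[:, :, :n_chi],
            residue_names=names,
        )

    @classmethod
    def from_tsv(cls, path) -> "TrajectoryEnsemble":
        return cls._from_frame(pd.read_csv(path, sep="\t"))

    @classmethod
    def from_parquet(cls, path) -> "TrajectoryEnsemble":
        return cls._from_frame(pd.read_parquet(path))


# ---------------------------------------------------------------------------
# Order parameter: tensor route
# ---------------------------------------------------------------------------

def tensor_moments(vectors, weights=None):
    """Weighted second moments (⟨x²⟩, ⟨y²⟩, ⟨z²⟩, √2⟨xy⟩, √2⟨xz⟩, √2⟨yz⟩).

    The √2 packing makes ‖m‖² equal the Frobenius norm of the full 3×3
    second-moment tensor, which is what the order parameter needs. This is
    the single code path used for uniform and reweighted ensembles alike.
    """
    v = np.asarray(vectors, dtype=float)
    n = v.shape[0]
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        s = w.sum()
        if s <= 0:
            raise ValueError("weights must have positive sum")
        if abs(s - 1.0) > 1e-9:
            import warnings

            warnings.warn("weights were not normalized; normalizing", stacklevel=2)
        w = w / s
    f = frame_features(v)
    return w @ f


def frame_features(vectors):
    """Per-frame feature rows (x², y², z², √2xy, √2xz, √2yz)."""
    v = np.asarray(vectors, dtype=float)
    s2 = np.sqrt(2.0)
    return np.stack(
        [
            v[..., 0] ** 2,
            v[..., 1] ** 2,
            v[..., 2] ** 2,
            s2 * v[..., 0] * v[..., 1],
            s2 * v[..., 0] * v[..., 2],
            s2 * v[..., 1] * v[..., 2],
        ],
        axis=-1,
    )


def o2_from_moments(m):
    """O² = (3/2)‖M‖²_F − 1/2 from packed second moments."""
    m = np.asarray(m, dtype=float)
    return 1.5 * np.sum(m * m, axis=-1) - 0.5


def o2_tensor(vectors, weights=None) -> float:
    """Order parameter by the static tensor expansion over frames."""
    v = np.asarray(vectors, dtype=float)
    if v.shape[0] < 2 and weights is None:
        raise ValueError("need at least 2 frames (a single vector is trivially rigid)")
    return float(o2_from_moments(tensor_moments(v, weights)))


# ---------------------------------------------------------------------------
# Order parameter: time-correlation route
# ---------------------------------------------------------------------------

@dataclass
class TimeCorrelation:
    """Internal TCF of a bond vector; C(0) = 1 by construction."""

    lags: np.ndarray
    values: np.ndarray
    parameterization: str = "vector"
    replicas: list = field(default_factory=list)

    def __post_init__(self):
        self.lags = np.asarray(self.lags)
        self.values = np.asarray(self.values, dtype=float)
        if abs(self.values[0] - 1.0) > 1e-9:
            raise ValueError("C(0) must equal 1")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"lag": self.lags, "c_int": self.values})
        for i, rep in enumerate(self.replicas):
            df[f"replica_{i}"] = rep
        return df

    def plot(self, ax=None):
        from .plotting import plot_tcf

        return plot_tcf(self, ax=ax)


def internal_tcf(vectors, max_lag: int, origin_stride: int = 1) -> TimeCorrelation:
    """C_int(τ) = ⟨P2(μ̂(t)·μ̂(t+τ))⟩ over time origins t.

    Origins are taken every ``origin_stride`` frames (dense by default).
    """
    v = np.asarray(vectors, dtype=float)
    n = v.shape[0]
    if max_lag >= n / 2:
        raise ValueError("max_lag must be below half the trajectory length")
    lags = np.arange(max_lag + 1)
    vals = np.empty(lags.size)
    for k, lag in enumerate(lags):
        dots = np.sum(v[: n - lag : origin_stride] * v[lag::1][: n - lag : origin_stride], axis=1)
        vals[k] = np.mean(1.5 * dots**2 - 0.5)
    return TimeCorrelation(lags=lags, values=vals)


def average_tcf(tcfs: Sequence[TimeCorrelation]) -> TimeCorrelation:
    """Average replica TCFs on a common lag grid."""
    lags = tcfs[0].lags
    for t in tcfs:
        if not np.array_equal(t.lags, lags):
            raise ValueError("replica TCFs must share the lag grid")
    curves = [t.values for t in tcfs]
    return TimeCorrelation(
        lags=lags,
        values=np.mean(curves, axis=0),
        parameterization=tcfs[0].parameterization,
        replicas=curves,
    )


def tcf_plateau(tcf: TimeCorrelation, mode: str = "last_point", window: float = 0.1) -> float:
    """Order parameter from the TCF long-time limit.

    ``last_point`` (default) takes C at the largest lag; ``tail_mean``
    averages the final ``window`` fraction of the curve.
    """
    if mode == "last_point":
        return float(tcf.values[-1])
    if mode == "tail_mean":
        k = max(1, int(round(window * tcf.values.size)))
        return float(np.mean(tcf.values[-k:]))
    raise ValueError(f"unknown plateau mode {mode!r}")


# ---------------------------------------------------------------------------
# Trajectory-file adapter (standard topology + trajectory formats)
# ---------------------------------------------------------------------------

_METHYL_ATOMS = {"MET": ("CB", "CG", "SD", "CE")}
_CHI_ATOMS = {
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"), ("CB", "CG", "SD", "CE")]
}


def extract_methyl_axes(
    topology,
    trajectory=None,
    residue_selection: str = "resname MET",
    superpose: bool = True,
    fit_selection: str = "name CA",
    atom_map: dict | None = None,
) -> TrajectoryEnsemble:
    """Build a TrajectoryEnsemble from standard trajectory files.

    Uses MDAnalysis to read any supported topology/trajectory pair (PDB,
    PDB+DCD/XTC, …). Frames are optionally superposed on the first frame's
    fit selection (backbone Cα by default) before the Cartesian axis
    vectors are taken; χ dihedrals are internal coordinates and are
    computed from the raw frames.
    """
    import MDAnalysis as mda

    atom_map = atom_map or _METHYL_ATOMS
    u = mda.Universe(topology) if trajectory is None else mda.Universe(topology, trajectory)
    residues = u.select_atoms(residue_selection).residues
    picked = []
    for res in residues:
        names = atom_map.get(res.resname)
        if names is None:
            continue
        atoms = {n: res.atoms.select_atoms(f"name {n}") for n in names}
        if any(len(a) != 1 for a in atoms.values()):
            import warnings

            warnings.warn(f"residue {res.resid} missing methyl atoms; skipped")
            continue
        picked.append(res)
    if not picked:
        raise ValueError("no usable methyl-bearing residues in selection")

    coords = []
    for _ in u.trajectory:
        coords.append(u.atoms.positions.copy())
    coords = np.asarray(coords, dtype=float)
    fit_idx = u.select_atoms(fit_selection).ix
    if superpose and fit_idx.size >= 3:
        aligned, _ = superpose_frames(coords, coords[0], fit_idx)
    else:
        aligned = coords

    ids, names3, vecs, chis, thetas = [], [], [], [], []
    for res in picked:
        names = atom_map[res.resname]
        idx = {n: res.atoms.select_atoms(f"name {n}").ix[0] for n in names}
        cb, cg, sd, ce = (idx[n] for n in names)
        v = aligned[:, sd] - aligned[:, ce]
        v = v / np.linalg.norm(v, axis=1, keepdims=True)
        theta = bond_angle(coords[:, cg], coords[:, sd], coords[:, ce])
        chi_defs = _CHI_ATOMS.get(res.resname, [])
        chi_cols = np.full((coords.shape[0], 3), np.nan)
        for k, quad in enumerate(chi_defs[:3]):
            try:
                qidx = [res.atoms.select_atoms(f"name {n}").ix[0] for n in quad]
            except IndexError:
                continue
            chi_cols[:, k] = compute_dihedral(*(coords[:, j] for j in qidx))
        one = res.resname[0] if res.resname != "MET" else "M"
        ids.append(f"{one}{res.resid}")
        names3.append(res.resname)
        vecs.append(v)
        chis.append(chi_cols)
        thetas.append(theta)
    return TrajectoryEnsemble(
        residue_ids=ids,
        vectors=np.stack(vecs),
        chi=np.stack(chis),
        residue_names=names3,
        theta_bond=np.stack(thetas),
        provenance="trajectory",
    )


def angle_parameterized_vectors(ens: TrajectoryEnsemble, chi_index: int = -1):
    """Rebuild axis vectors from (θ_bond, χ) — the global-motion-free form."""
    if ens.theta_bond is None:
        raise ValueError("ensemble carries no bond-angle series")
    return axis_vector_from_angles(ens.theta_bond, ens.chi[:, :, chi_index])
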