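"""End-to-end orchestration: simulate → fit → convert → reweight → entropy.

A single structured YAML config drives every stage; all seeds and physical
constants are echoed into a run manifest together with SHA-256 checksums
of every output file, so a rerun with the same config is byte-identical
for the deterministic stages and any single stage can be re-executed in
isolation from the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .constants import DEFAULT_CONSTANTS
from .entropy import compute_entropy_profile, delta_entropy
from .relaxation import RelaxationModel, read_intensity_table, write_intensity_table
from .reweight import EnsembleReweighter, ReweightTargets, select_theta_elbow
from .synthetic import (
    DecayCurveSpec,
    RotamerJumpSpec,
    analytic_o2_for_jump_model,
    simulate_decay_curves,
    simulate_weighted_ensemble,
)
from .tumbling import eta_from_o2, o2_from_eta, tau_c_from_rg

logger = logging.getLogger("methylscape")

__all__ = ["load_config", "validate_config", "run_all", "DEMO_CONFIG"]


DEMO_CONFIG = {
    "seed": 11,
    "output_dir": "runs/demo",
    "states": ["Apo", "agonist"],
    "jump": {
        "wells": [60.0, 180.0, -60.0],
        "prior_populations": [1 / 3, 1 / 3, 1 / 3],
        "state_populations": {
            "Apo": [0.45, 0.35, 0.20],
            "agonist": [0.70, 0.15, 0.15],
        },
        "libration_sd": 10.0,
        "theta_bond": 109.47,
        "exchange_prob": 0.5,
        "n_frames": 2000,
        "n_residues": 3,
    },
    "simulate": {"noise_frac": 0.02},
    "relaxation": {"n_exp": 2, "n_walkers": 24, "n_steps": 600, "n_burn": 250},
    "tumbling": {
        "rg": {"value": 37.85, "unit": "A", "sd": 0.4},
        "viscosity_cp": 1.099,
        "temperature_k": 298.15,
        "n_samples": 4000,
    },
    "reweight": {"theta_grid": [0.01, 0.1, 1.0, 10.0, 100.0], "select": "max_curvature"},
    "entropy": {"bin_width": 10.0},
}


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def validate_config(config: dict) -> dict:
    """Schema/unit/consistency checks. Returns {'errors': [...], 'warnings': [...]}."""
    errors, warnings_ = [], []
    if "seed" not in config:
        errors.append("missing top-level 'seed' (every run must pin its randomness)")
    if "output_dir" not in config:
        errors.append("missing 'output_dir'")
    states = config.get("states", [])
    if not states:
        errors.append("no ligand states configured")
    tum = config.get("tumbling", {})
    rg = tum.get("rg", {})
    unit = str(rg.get("unit", "A")).lower()
    if unit in ("nm",) and rg.get("value", 0) > 20:
        warnings_.append(
            f"Rg = {rg.get('value')} nm implies a ~{rg.get('value')} nm particle — "
            "implausibly large for a receptor–micelle complex; did you mean Å?"
        )
    if unit not in ("a", "angstrom", "nm"):
        errors.append(f"unknown Rg unit {rg.get('unit')!r}")
    t = tum.get("temperature_k")
    if t is not None and t < 200:
        warnings_.append(f"temperature_k = {t} looks like °C, not K")
    jump = config.get("jump", {})
    sp = jump.get("state_populations", {})
    missing = [s for s in states if s not in sp]
    if jump and missing:
        errors.append(f"states without simulated populations: {missing}")
    for s, pops in sp.items():
        if abs(sum(pops) - 1.0) > 1e-9:
            errors.append(f"state {s}: populations do not sum to 1")
    return {"errors": errors, "warnings": warnings_}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _rg_in_angstrom(rg_cfg: dict) -> tuple[float, float]:
    value, sd = float(rg_cfg["value"]), float(rg_cfg.get("sd", 0.0))
    if str(rg_cfg.get("unit", "A")).lower() == "nm":
        value, sd = value * 10.0, sd * 10.0
    return value, sd


def run_all(config: dict, base_dir=".") -> dict:
    """Execute the full pipeline per config; returns the manifest dict."""
    report = validate_config(config)
    for w in report["warnings"]:
        logger.warning(w)
    if report["errors"]:
        raise ValueError("invalid config: " + "; ".join(report["errors"]))

    out = Path(base_dir) / config["output_dir"]
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    states = config["states"]
    jump_cfg = config["jump"]
    outputs: list[Path] = []

    # -- tumbling: tau_c from configured Rg ---------------------------------
    tum_cfg = config["tumbling"]
    rg, rg_sd = _rg_in_angstrom(tum_cfg["rg"])
    tumbling = tau_c_from_rg(
        rg,
        rg_sd,
        float(tum_cfg["viscosity_cp"]),
        float(tum_cfg["temperature_k"]),
        n_samples=int(tum_cfg.get("n_samples", 4000)),
        seed=seed + 1,
    )
    logger.info("tau_c = %.2f ± %.2f ns", tumbling.tau_c_mean, tumbling.tau_c_sd)

    prior_spec = RotamerJumpSpec(
        well_angles=tuple(jump_cfg["wells"]),
        populations=tuple(jump_cfg["prior_populations"]),
        exchange_prob=float(jump_cfg.get("exchange_prob", 0.5)),
        libration_sd=float(jump_cfg.get("libration_sd", 10.0)),
        theta_bond=float(jump_cfg.get("theta_bond", 109.47)),
        n_frames=int(jump_cfg["n_frames"]),
        seed=seed + 2,
    )
    n_res = int(jump_cfg["n_residues"])
    ensemble, _, _ = simulate_weighted_ensemble(
        prior_spec, prior_spec.populations, n_res, seed=seed + 3
    )
    ens_path = out / "ensemble_prior.tsv"
    ensemble.to_tsv(ens_path)
    outputs.append(ens_path)

    noise_frac = float(config.get("simulate", {}).get("noise_frac", 0.02))
    rel_cfg = config.get("relaxation", {})
    profiles = {}
    o2_rows = []
    manifest_stages = {}

    for si, state in enumerate(states):
        pops = jump_cfg["state_populations"][state]
        o2_true = analytic_o2_for_jump_model(prior_spec, populations=pops)
        eta_true = float(eta_from_o2(o2_true, tumbling.tau_c_mean))
        # simulate decay curves, one peak per residue
        curves = []
        for r, rid in enumerate(ensemble.residue_ids):
            spec = DecayCurveSpec(
                eta=eta_true,
                delta=5.0,
                amplitude=1.0,
                noise_sd_sq=0.0,
                noise_sd_3q=0.0,
                seed=seed + 100 * si + r,
                peak_id=rid,
            )
            sq, tq = simulate_decay_curves(spec)
            scale = np.max(np.abs(sq.intensities))
            spec_noisy = DecayCurveSpec(
                eta=eta_true,
                delta=5.0,
                amplitude=1.0,
                noise_sd_sq=noise_frac * scale,
                noise_sd_3q=noise_frac * scale,
                seed=seed + 100 * si + r,
                peak_id=rid,
            )
            sq, tq = simulate_decay_curves(spec_noisy)
            curves += [sq, tq]
        tab_path = out / f"intensities_{state}.tsv"
        write_intensity_table(curves, tab_path)
        outputs.append(tab_path)

        # fit relaxation per peak
        fit_rows = []
        targets_mean, targets_sd = [], []
        for pi, (peak, (sq, tq)) in enumerate(read_intensity_table(tab_path).items()):
            model = RelaxationModel(sq, tq)
            res = model.fit_bayes(
                n_exp=int(rel_cfg.get("n_exp", 2)),
                seed=seed + 17 + 1000 * si + pi,
                n_walkers=int(rel_cfg.get("n_walkers", 24)),
                n_steps=int(rel_cfg.get("n_steps", 600)),
                n_burn=int(rel_cfg.get("n_burn", 250)),
            )
            est = o2_from_eta(
                res.eta, tumbling, seed=seed + 23, residue_id=peak, state=state
            )
            fit_rows.append(
                {
                    "peak_id": peak,
                    "state": state,
                    "eta_mean": float(res.eta.mean()),
                    "eta_sd": float(res.eta.std(ddof=1)),
                    "delta_mean": float(res.delta.mean()),
                    "delta_sd": float(res.delta.std(ddof=1)),
                    "eta_true": eta_true,
                }
            )
            o2_rows.append(est.to_row())
            targets_mean.append(est.mean)
            targets_sd.append(max(est.sd, 1e-3))
        fits_path = out / f"fits_{state}.tsv"
        pd.DataFrame(fit_rows).to_csv(fits_path, sep="\t", index=False, float_format="%.10g")
        outputs.append(fits_path)

        # reweight the shared prior ensemble to this state's NMR targets
        targets = ReweightTargets(
            residue_ids=list(ensemble.residue_ids),
            o2_mean=np.array(targets_mean),
            o2_sd=np.array(targets_sd),
        )
        rw = EnsembleReweighter(ensemble, targets)
        grid = np.asarray(config["reweight"]["theta_grid"], dtype=float)
        lcurve = rw.l_curve(grid)
        if grid.size >= 5:
            theta_sel = select_theta_elbow(
                lcurve, method=config["reweight"].get("select", "max_curvature")
            )
        else:
            theta_sel = float(grid[-1])
            lcurve.no_elbow = True
            lcurve.selection_method = "no elbow selection (grid too small)"
        sol = lcurve.results[int(np.argmin(np.abs(lcurve.theta - theta_sel)))]
        lc_path = out / f"lcurve_{state}.tsv"
        lcurve.to_frame().to_csv(lc_path, sep="\t", index=False, float_format="%.10g")
        w_path = out / f"weights_{state}.tsv"
        sol.weights_frame().to_csv(w_path, sep="\t", index=False, float_format="%.10g")
        outputs += [lc_path, w_path]

        # entropy under the reweighted ensemble
        profile = compute_entropy_profile(
            ensemble,
            weights=sol.weights,
            state=state,
            bin_width=float(config["entropy"].get("bin_width", 10.0)),
        )
        ent_path = out / f"entropy_{state}.tsv"
        profile.to_tsv(ent_path)
        outputs.append(ent_path)
        profiles[state] = profile
        manifest_stages[state] = {
            "eta_true": eta_true,
            "o2_true": o2_true,
            "theta_selected": theta_sel,
            "no_elbow": bool(lcurve.no_elbow),
            "neff": sol.neff,
            "chi2": sol.chi2,
            "entropy_total": profile.total,
        }

    # NMR O2 table across states
    o2_path = out / "o2_nmr.tsv"
    pd.DataFrame(o2_rows).to_csv(o2_path, sep="\t", index=False, float_format="%.10g")
    outputs.append(o2_path)

    # delta entropy between consecutive states
    for a, b in zip(states[:-1], states[1:]):
        ds = delta_entropy(profiles[a], profiles[b])
        ds_path = out / f"delta_entropy_{a}_vs_{b}.tsv"
        ds.reset_index().to_csv(ds_path, sep="\t", index=False, float_format="%.10g")
        outputs.append(ds_path)

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "constants": asdict(DEFAULT_CONSTANTS),
        "tau_c_ns": {"mean": tumbling.tau_c_mean, "sd": tumbling.tau_c_sd},
        "stages": manifest_stages,
        "checksums": {p.name: _sha256(p) for p in outputs},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
    return manifest
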