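"""Synthetic inputs with the statistical structure the analysis assumes.

Every generator is a pure function of its arguments and a seed: two-pose
probe/reporter coordinate ensembles feeding the PRE forward model, noisy
PRE intensity-ratio tables, endpoint dose-response curves from the kinetic
schemes, and exponential dissociation traces.  Defaults mirror the study
conditions (10-model ensembles with 0.5 Å jitter, 3% ratio noise, 3-minute
endpoints, 1 uM Arf with 0.5 mM accessible lipid at 5 mol% PI(4,5)P2).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import gap_kinetics as gk
from . import pre_forward as pf
from .structures import LabelSite, Structure, place_label, select_methyls

__all__ = [
    "make_two_pose_ensemble",
    "synth_pre_dataset",
    "synth_dose_response",
    "synth_dissociation_trace",
    "write_pdb",
]

UNDETECTABLE_THRESHOLD = 0.05  # exercises the bleached-beyond-detection branch


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

_REPORTER_RESIDUES = ("ILE", "LEU", "VAL")
_SIDECHAIN = {
    # offsets (Å) along the outward radial direction for each atom
    "ILE": [("N", 0.0), ("CA", 0.5), ("CB", 1.9), ("CG1", 3.2), ("CD1", 4.5)],
    "LEU": [("N", 0.0), ("CA", 0.5), ("CB", 1.9), ("CG", 3.2), ("CD1", 4.4), ("CD2", 4.6)],
    "VAL": [("N", 0.0), ("CA", 0.5), ("CB", 1.9), ("CG1", 3.1), ("CG2", 3.3)],
}


def _reporter_rows(n_residues: int) -> list[tuple]:
    """Rigid reporter body: methyl-bearing residues on a cylindrical lattice."""
    rows = []
    n_per_turn = 6
    for i in range(n_residues):
        resname = _REPORTER_RESIDUES[i % 3]
        angle = 2 * np.pi * (i % n_per_turn) / n_per_turn + 0.3 * (i // n_per_turn)
        z = 4.0 * (i // n_per_turn) - 8.0
        radial = np.array([np.cos(angle), np.sin(angle), 0.0])
        base = 8.0 * radial + np.array([0.0, 0.0, z])
        for k, (atom, offset) in enumerate(_SIDECHAIN[resname]):
            pos = base + offset * radial + np.array([0.0, 0.0, 0.15 * k])
            rows.append(("A", i + 1, resname, atom, pos))
    return rows


def _probe_rows(center: np.ndarray, resnum: int) -> list[tuple]:
    """Probe body: a CYS-bearing stub plus a small rigid cluster."""
    rows = [
        ("B", resnum, "CYS", "N", center + np.array([-1.3, 0.6, 0.0])),
        ("B", resnum, "CYS", "CA", center + np.array([-1.2, -0.7, 0.0])),
        ("B", resnum, "CYS", "CB", center),
        ("B", resnum, "CYS", "SG", center + np.array([1.4, 0.9, 0.4])),
        ("B", resnum + 1, "GLY", "N", center + np.array([-2.8, -1.2, 0.8])),
        ("B", resnum + 1, "GLY", "CA", center + np.array([-3.9, -0.4, 1.4])),
    ]
    return rows


def _assemble(rows: list[tuple], n_models: int, jitter: float,
              rng: np.random.Generator) -> Structure:
    records = []
    base = np.array([r[4] for r in rows])
    for m in range(n_models):
        noise = rng.normal(0.0, jitter, base.shape) if jitter > 0 else 0.0
        xyz = base + noise
        for (chain, resnum, resname, atom, _), p in zip(rows, xyz):
            records.append((m, chain, resnum, resname, atom, atom[0], *p))
    return Structure(pd.DataFrame(
        records, columns=["model", "chain", "resnum", "resname", "atom",
                          "element", "x", "y", "z"]))


def make_two_pose_ensemble(seed: int, n_models: int = 10, jitter: float = 0.5,
                           n_residues: int = 24,
                           ) -> tuple[Structure, Structure, LabelSite]:
    """Two ensembles of a labeled probe docked on opposite reporter faces.

    Returns (pose_a, pose_b, label_site): each pose is a multi-model
    Structure containing the same rigid reporter (>= 20 methyl-bearing
    residues, chain A) plus the probe body (chain B) on the +x or -x face.
    Models are jittered independently per pose with the given RMS (Å).
    """
    rng = np.random.default_rng(seed)
    reporter = _reporter_rows(n_residues)
    site_resnum = 1001
    pose_a = _assemble(reporter + _probe_rows(np.array([17.0, 0.0, 6.0]), site_resnum),
                       n_models, jitter, rng)
    pose_b = _assemble(reporter + _probe_rows(np.array([-17.0, 0.0, -6.0]), site_resnum),
                       n_models, jitter, rng)
    site = LabelSite(residue_number=site_resnum, attachment_atom="CB",
                     mutation_tag="K38C")
    return pose_a, pose_b, site


def write_pdb(structure: Structure, path) -> None:
    """Serialize a Structure as a multi-model PDB (fixed-format text)."""
    with open(path, "w") as fh:
        for mi, m in enumerate(structure.model_ids, 1):
            fh.write(f"MODEL     {mi:4d}\n")
            for i, row in enumerate(structure.model(m).itertuples(), 1):
                name = row.atom if len(row.atom) == 4 else f" {row.atom:<3s}"
                fh.write(
                    f"ATOM  {i:5d} {name:<4s} {row.resname:<3s} {row.chain}"
                    f"{row.resnum:4d}    {row.x:8.3f}{row.y:8.3f}{row.z:8.3f}"
                    f"  1.00  0.00          {row.element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# PRE dataset
# ---------------------------------------------------------------------------

def synth_pre_dataset(pose_a: Structure, pose_b: Structure, site: LabelSite,
                      rho_major: float, noise_sd: float,
                      params: pf.RelaxationParams = pf.RelaxationParams(),
                      seed: int = 0, r2: float = 100.0,
                      n_label_candidates: int = 200, scheme: str = "ILV",
                      ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Noisy intensity-ratio table from a two-state mixture of the poses.

    Per-methyl rates of both poses are mixed as rho*G_A + (1-rho)*G_B,
    converted to ratios, Gaussian noise (sd ``noise_sd``) is added on the
    ratio scale and the result clipped to [0, 1.2].  Ratios below 0.05 are
    flagged undetectable with probability 0.5 (rates/errors kept).

    Returns (observed, profile_a, profile_b); the profiles carry the exact
    forward-computed rates for fitting.
    """
    if not 0.0 <= rho_major <= 1.0:
        raise ValueError("rho_major must be in [0, 1]")
    rng = np.random.default_rng(seed)
    label_a = place_label(pose_a, site, n_label_candidates, seed=seed)
    label_b = place_label(pose_b, site, n_label_candidates, seed=seed)
    methyls_a = select_methyls(pose_a, scheme)
    methyls_b = select_methyls(pose_b, scheme)
    prof_a = pf.forward_profile(label_a, methyls_a, params, r2)
    prof_b = pf.forward_profile(label_b, methyls_b, params, r2)

    merged = prof_a.merge(prof_b, on=["residue", "methyl"], suffixes=("_a", "_b"))
    mixed = rho_major * merged["gamma2_a"] + (1 - rho_major) * merged["gamma2_b"]
    ratio = pf.intensity_ratio(mixed.to_numpy(), r2, params.t_evolution)
    if noise_sd > 0:
        ratio = ratio + rng.normal(0.0, noise_sd, len(ratio))
    ratio = np.clip(ratio, 0.0, 1.2)
    undetectable = (ratio < UNDETECTABLE_THRESHOLD) & (rng.random(len(ratio)) < 0.5)
    error = np.clip(ratio, 0.05, None) * np.sqrt(2) / 20.0  # S/N ~ 20 both states
    observed = pd.DataFrame({
        "residue": merged["residue"], "methyl": merged["methyl"],
        "ratio": ratio, "error": error, "detectable": ~undetectable,
    })
    return observed, prof_a, prof_b


# ---------------------------------------------------------------------------
# kinetics datasets
# ---------------------------------------------------------------------------

def synth_dose_response(conditions: list[gk.AssayCondition],
                        params: gk.RateParameters,
                        noise_sd: float = 0.05, seed: int = 0,
                        n_concentrations: int = 10,
                        bracket: tuple[float, float] = (1e-12, 1e-2),
                        ) -> list[tuple[gk.AssayCondition, pd.DataFrame]]:
    """Endpoint dose-response tables on log-spaced enzyme grids.

    Each condition gets ``n_concentrations`` log-spaced concentrations
    centered on its model C50 (falling back to the full bracket when the
    curve does not cross 0.5 there); fractions receive multiplicative
    Gaussian noise and are clipped to [0, 1].
    """
    if not 8 <= n_concentrations <= 12:
        raise ValueError("use 8-12 concentrations per condition")
    rng = np.random.default_rng(seed)
    out = []
    for condition in conditions:
        try:
            mid = gk.c50(condition, params, bracket=bracket)
            grid = np.logspace(np.log10(mid) - 2.0, np.log10(mid) + 2.0,
                               n_concentrations)
        except ValueError:
            grid = np.logspace(np.log10(bracket[0]), np.log10(bracket[1]),
                               n_concentrations)
        table = gk.dose_response_curve(condition, params, grid)
        frac = table["fraction"].to_numpy()
        if noise_sd > 0:
            frac = frac * (1 + rng.normal(0.0, noise_sd, len(frac)))
        table["fraction"] = np.clip(frac, 0.0, 1.0)
        table["sd"] = np.clip(noise_sd * np.clip(table["fraction"], 0.05, None),
                              1e-3, None)
        out.append((condition, table))
    return out


def synth_dissociation_trace(rate: float, amplitude: float = 1.0,
                             offset: float = 0.2, noise_sd: float = 0.0,
                             n_points: int = 200, t_max: float = 1800.0,
                             seed: int = 0) -> pd.DataFrame:
    """Exponential-decay fluorescence trace; ``rate`` in s^-1, time in s."""
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, t_max, n_points)
    y = offset + amplitude * np.exp(-rate * t)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd * amplitude, n_points)
    return pd.DataFrame({"time_s": t, "signal": y})
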