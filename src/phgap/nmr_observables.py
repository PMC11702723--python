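"""Chemical-shift perturbations, PRE intensity-ratio errors and docking
restraints.

CSP combines the proton and heteronucleus shift changes as
``sqrt(d_H^2 + A * d_X^2)`` with the nucleus-specific scale factor A.
Restraint generation follows the standard data-driven docking recipe:
ambiguous interaction restraints (AIRs) from CSP magnitude + solvent
exposure, and unambiguous 1.8-16 Å bounds for protons bleached below an
intensity-ratio threshold by the spin label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structures import LabelSite

__all__ = [
    "CSP_SCALE",
    "ACTIVE_CSP_THRESHOLD",
    "PASSIVE_WINDOWS",
    "PRE_RATIO_CUTOFF",
    "PRE_BOUNDS",
    "RestraintSet",
    "compute_csp",
    "csp_table",
    "pre_ratio_error",
    "classify_air",
    "pre_distance_restraints",
    "write_restraints_tsv",
    "restraints_to_tbl",
]

CSP_SCALE = {"N15": 0.17, "C13": 0.185}

# docking classification constants (ppm / Å)
ACTIVE_CSP_THRESHOLD = 0.1
EXPOSURE_THRESHOLD = 0.20
CONTACT_CUTOFF = 6.5
# passive windows (1-2 sigma) per partner: {partner: {group_kind: (lo, hi)}}
PASSIVE_WINDOWS = {
    "PH": {"methyl": (0.047, 0.095), "amide": (0.02, 0.04)},
    "Arf": {"methyl": (0.03, 0.06), "amide": (0.02, 0.04)},
}
PRE_RATIO_CUTOFF = 0.2
PRE_BOUNDS = (1.8, 16.0)


def compute_csp(delta_h: float, delta_x: float, nucleus: str) -> float:
    """Combined chemical-shift perturbation in ppm.

    ``sqrt(d_H^2 + A * d_X^2)`` with A = 0.17 for 15N and 0.185 for 13C.
    """
    if nucleus not in CSP_SCALE:
        raise KeyError(f"unknown nucleus {nucleus!r}; choose from {sorted(CSP_SCALE)}")
    dh = np.asarray(delta_h, float)
    dx = np.asarray(delta_x, float)
    if not (np.all(np.isfinite(dh)) and np.all(np.isfinite(dx))):
        raise ValueError("non-finite shift changes")
    return np.sqrt(dh**2 + CSP_SCALE[nucleus] * dx**2)


def pre_ratio_error(intensity: float, intensity0: float, sn: float, sn0: float):
    """Propagated error on the paramagnetic/diamagnetic intensity ratio.

    ``(I/I0) * sqrt(1/SN^2 + 1/SN0^2)`` with SN, SN0 the signal-to-noise of
    the paramagnetic and diamagnetic peaks.
    """
    intensity0 = np.asarray(intensity0, float)
    sn = np.asarray(sn, float)
    sn0 = np.asarray(sn0, float)
    if np.any(intensity0 <= 0) or np.any(sn <= 0) or np.any(sn0 <= 0):
        raise ValueError("I0, SN and SN0 must be positive")
    return (np.asarray(intensity, float) / intensity0) * np.sqrt(1 / sn**2 + 1 / sn0**2)


def _trimmed_sigma(csp: np.ndarray) -> float:
    """SD of CSPs after one round of 2-sigma trimming."""
    s = float(np.std(csp))
    if s == 0:
        return 0.0
    kept = csp[csp <= 2 * s]
    return float(np.std(kept)) if len(kept) >= 2 else s


def csp_table(free: pd.DataFrame, bound: pd.DataFrame) -> pd.DataFrame:
    """Per-residue/group CSPs between two peak-table states.

    Peak tables need columns residue, group, dH_ppm, dX_ppm, nucleus.
    Output columns: residue, group, csp, sigma_flag in {<1s, 1s-2s, >2s}.
    """
    merged = free.merge(bound, on=["residue", "group"], suffixes=("_free", "_bound"))
    csp = np.array([
        float(compute_csp(r.dH_ppm_bound - r.dH_ppm_free,
                          r.dX_ppm_bound - r.dX_ppm_free, r.nucleus_free))
        for r in merged.itertuples()
    ])
    sigma = _trimmed_sigma(csp)
    flags = np.where(csp > 2 * sigma, ">2s", np.where(csp >= sigma, "1s-2s", "<1s"))
    return pd.DataFrame({
        "residue": merged["residue"], "group": merged["group"],
        "csp": csp, "sigma_flag": flags,
    })


@dataclass
class RestraintSet:
    """Active/passive residue sets plus unambiguous distance bounds."""

    active: set[int] = field(default_factory=set)
    passive: set[int] = field(default_factory=set)
    unambiguous: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["label_site", "residue", "group", "lower", "upper"])
    )

    def __post_init__(self) -> None:
        if self.active & self.passive:
            raise ValueError("active and passive sets overlap")
        if len(self.unambiguous):
            lo = self.unambiguous["lower"].to_numpy(float)
            hi = self.unambiguous["upper"].to_numpy(float)
            if np.any(lo <= 0) or np.any(lo >= hi):
                raise ValueError("distance bounds must satisfy 0 < lower < upper")


def _group_kind(group: str) -> str:
    return "amide" if str(group).lower() in ("amide", "hn", "nh") else "methyl"


def classify_air(csp: pd.DataFrame, rel_sasa: pd.Series,
                 contacts: dict[int, set[int]], partner: str) -> RestraintSet:
    """Split residues into active/passive AIR sets for one binding partner.

    active  = exposed (rel SASA >= 0.20) and CSP > 0.1 ppm
    passive = exposed and (neighbor of an active residue within 6.5 Å or CSP
              inside the partner's 1-2 sigma window) and not active

    Residues absent from the SASA table are treated as buried.
    """
    if partner not in PASSIVE_WINDOWS:
        raise KeyError(f"unknown partner {partner!r}; choose from {sorted(PASSIVE_WINDOWS)}")
    windows = PASSIVE_WINDOWS[partner]

    best = csp.groupby("residue").apply(
        lambda g: g.loc[g["csp"].idxmax()], include_groups=False)
    exposed = {int(r) for r in best.index
               if float(rel_sasa.get(int(r), 0.0)) >= EXPOSURE_THRESHOLD}

    active = {int(r) for r in best.index
              if int(r) in exposed and float(best.loc[r, "csp"]) > ACTIVE_CSP_THRESHOLD}

    passive: set[int] = set()
    for r in best.index:
        r = int(r)
        if r in active or r not in exposed:
            continue
        near_active = bool(contacts.get(r, set()) & active)
        lo, hi = windows[_group_kind(best.loc[r, "group"])]
        in_window = lo <= float(best.loc[r, "csp"]) <= hi
        if near_active or in_window:
            passive.add(r)
    return RestraintSet(active=active, passive=passive)


def pre_distance_restraints(ratios: pd.DataFrame, site: LabelSite) -> RestraintSet:
    """Unambiguous label-to-proton bounds from PRE intensity ratios.

    Every proton with I/I0 < 0.2, or whose paramagnetic resonance is flagged
    undetectable, gets (1.8, 16.0) Å bounds to the label site.
    ``ratios`` columns: residue, group, ratio, detectable.
    """
    detectable = ratios.get("detectable", pd.Series(True, index=ratios.index))
    hit = (ratios["ratio"] < PRE_RATIO_CUTOFF) | (~detectable.astype(bool))
    rows = ratios.loc[hit, ["residue", "group"]].copy()
    rows.insert(0, "label_site", site.residue_number)
    rows["lower"], rows["upper"] = PRE_BOUNDS
    return RestraintSet(unambiguous=rows.reset_index(drop=True))


def write_restraints_tsv(rs: RestraintSet, path) -> None:
    """Canonical TSV serialization: AIR sets then distance rows."""
    with open(path, "w") as fh:
        fh.write("# active\t" + ",".join(map(str, sorted(rs.active))) + "\n")
        fh.write("# passive\t" + ",".join(map(str, sorted(rs.passive))) + "\n")
        rs.unambiguous.to_csv(fh, sep="\t", index=False)


def restraints_to_tbl(rs: RestraintSet, label_segid: str = "B",
                      target_segid: str = "A") -> str:
    """CNS-flavored ``assign`` lines for docking interoperability."""
    lines = []
    for r in rs.unambiguous.itertuples():
        center = 0.5 * (r.lower + r.upper)
        lines.append(
            f"assign (segid {label_segid} and resid {r.label_site} and name O1) "
            f"(segid {target_segid} and resid {r.residue} and name H*) "
            f"{center:.1f} {center - r.lower:.1f} {r.upper - center:.1f}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
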