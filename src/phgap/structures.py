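"""Coordinate ensembles, reporter-methyl selection, spin-label placement and
relative solvent accessibility.

Coordinates are Å throughout; residue numbering is taken verbatim from the
input file.  Multi-model PDB files (one MODEL block per ensemble frame) are
the only trajectory format consumed.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

__all__ = [
    "Structure",
    "MethylSelection",
    "LabelSite",
    "LabelEnsemble",
    "StructureError",
    "PlacementError",
    "load_structure",
    "select_methyls",
    "place_label",
    "relative_sasa",
    "residue_contacts",
    "write_label_ensemble",
    "METHYL_SCHEMES",
    "MAX_ASA",
]


class StructureError(ValueError):
    """Malformed or empty coordinate input."""


class PlacementError(RuntimeError):
    """Spin-label placement failed (no clash-free candidate)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Structure:
    """Atom table for a (possibly multi-model) structure.

    ``atoms`` columns: model, chain, resnum, resname, atom, element, x, y, z.
    """

    atoms: pd.DataFrame

    def __post_init__(self) -> None:
        coords = self.atoms[["x", "y", "z"]].to_numpy(float)
        if len(coords) == 0:
            raise StructureError("structure contains no atoms")
        if not np.all(np.isfinite(coords)):
            raise StructureError("non-finite coordinates")
        key = self.atoms[["model", "chain", "resnum", "atom"]]
        if key.duplicated().any():
            raise StructureError("duplicate (model, chain, residue, atom) records")

    @property
    def n_models(self) -> int:
        return self.atoms["model"].nunique()

    @property
    def model_ids(self) -> list[int]:
        return sorted(self.atoms["model"].unique())

    def model(self, model_id: int) -> pd.DataFrame:
        return self.atoms[self.atoms["model"] == model_id]

    def heavy_coords(self, model_id: int) -> np.ndarray:
        m = self.model(model_id)
        m = m[m["element"] != "H"]
        return m[["x", "y", "z"]].to_numpy(float)

    def atom_position(self, model_id: int, resnum: int, atom: str) -> np.ndarray:
        m = self.model(model_id)
        hit = m[(m["resnum"] == resnum) & (m["atom"] == atom)]
        if len(hit) != 1:
            raise KeyError(f"atom {atom} of residue {resnum} not unique/present in model {model_id}")
        return hit[["x", "y", "z"]].to_numpy(float)[0]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray | None = None) -> "Structure":
        """Return a rigidly transformed copy (used by equivariance checks)."""
        out = self.atoms.copy()
        xyz = out[["x", "y", "z"]].to_numpy(float) @ np.asarray(rotation, float).T
        if translation is not None:
            xyz = xyz + np.asarray(translation, float)
        out[["x", "y", "z"]] = xyz
        return Structure(out)


@dataclass
class MethylEntry:
    resnum: int
    resname: str
    methyl_id: str
    # (n_models, n_protons, 3); reconstructed centroids have n_protons == 1
    proton_positions: np.ndarray
    reconstructed: bool


@dataclass
class MethylSelection:
    entries: list[MethylEntry]
    model_ids: list[int]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class LabelSite:
    """Spin-label attachment site (engineered Cys carrying MTSL)."""

    residue_number: int
    attachment_atom: str = "CB"
    mutation_tag: str = ""


@dataclass
class LabelEnsemble:
    """Clash-free candidate positions of the nitroxide-oxygen proxy, per model."""

    site: LabelSite
    positions: list[np.ndarray]          # one (n_i, 3) array per model
    weights: list[np.ndarray] = field(default_factory=list)
    model_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.weights:
            self.weights = [np.full(len(p), 1.0 / len(p)) for p in self.positions]
        for w in self.weights:
            if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
                raise ValueError("candidate weights must be nonnegative and sum to 1 per model")
        if not self.model_ids:
            self.model_ids = list(range(len(self.positions)))

    @property
    def n_models(self) -> int:
        return len(self.positions)

    def mean_positions(self) -> np.ndarray:
        return np.array([w @ p for p, w in zip(self.positions, self.weights)])


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

_ELEMENT_FALLBACK = {"H": "H", "C": "C", "N": "N", "O": "O", "S": "S", "P": "P"}


def _element_of(atom_name: str, element_field: str) -> str:
    el = element_field.strip().capitalize()
    if el:
        return el
    name = atom_name.strip()
    # PDB v3 columns 13-16: digit-prefixed hydrogens like 1HB2
    stripped = name.lstrip("0123456789")
    return _ELEMENT_FALLBACK.get(stripped[:1], stripped[:1].upper())


def load_structure(path, format: str = "pdb") -> Structure:
    """Read a (multi-model) PDB file into a :class:`Structure`.

    One MODEL block per ensemble frame; files without MODEL records yield a
    single model 0.  Insertion codes are rejected, as are MODEL blocks whose
    atom lists differ.
    """
    if format != "pdb":
        raise StructureError(f"unsupported format {format!r}")
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bio = parser.get_structure("s", str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc

    rows = []
    for model in bio:
        for chain in model:
            for res in chain:
                het, resnum, icode = res.id
                if icode.strip():
                    raise StructureError(
                        f"insertion code {icode!r} at residue {resnum} not supported"
                    )
                for atom in res:
                    x, y, z = atom.coord
                    rows.append(
                        (model.id, chain.id, int(resnum), res.resname.strip(),
                         atom.get_name(), _element_of(atom.get_name(), atom.element or ""),
                         float(x), float(y), float(z))
                    )
    if not rows:
        raise StructureError(f"{path}: no atoms found")
    df = pd.DataFrame(rows, columns=["model", "chain", "resnum", "resname", "atom",
                                     "element", "x", "y", "z"])
    # identical atom lists across models
    sigs = {
        m: tuple(map(tuple, g[["chain", "resnum", "atom"]].to_numpy()))
        for m, g in df.groupby("model")
    }
    if len(set(sigs.values())) > 1:
        raise StructureError(f"{path}: MODEL blocks have differing atom lists")
    return Structure(df)


# ---------------------------------------------------------------------------
# methyl selection
# ---------------------------------------------------------------------------

# methyl carbon and the preceding carbon defining the rotation axis
_METHYL_GEOMETRY = {
    ("ILE", "Ile-d1"): ("CD1", "CG1"),
    ("LEU", "Leu-d1"): ("CD1", "CG"),
    ("LEU", "Leu-d2"): ("CD2", "CG"),
    ("VAL", "Val-g1"): ("CG1", "CB"),
    ("VAL", "Val-g2"): ("CG2", "CB"),
    ("ALA", "Ala-b"): ("CB", "CA"),
    ("THR", "Thr-g2"): ("CG2", "CB"),
}

METHYL_SCHEMES = {
    # Ile d1, Leu d1/d2, Val g1/g2
    "ILV": ["Ile-d1", "Leu-d1", "Leu-d2", "Val-g1", "Val-g2"],
    # proS-specific Leu/Val plus Ala-beta and Thr-gamma2
    "ILV-proS-AT": ["Ile-d1", "Leu-d1", "Val-g1", "Ala-b", "Thr-g2"],
}

# tetrahedral H-C-axis angle: the three-proton centroid sits on the methyl
# axis at 1.09*cos(180-109.5 deg) from the carbon
_CENTROID_OFFSET = 1.09 * np.cos(np.deg2rad(70.5))


def _proton_names(carbon: str) -> list[str]:
    stem = carbon[1:]  # CD1 -> D1
    return [f"H{stem}{i}" for i in (1, 2, 3)]


def select_methyls(structure: Structure, scheme: str) -> MethylSelection:
    """Pick the reporter methyls of a labeling scheme out of a structure.

    Proton positions come from standard PDB proton naming when present;
    otherwise the three-proton centroid is reconstructed from the methyl
    carbon and its axis-defining neighbor (entry flagged ``reconstructed``).
    """
    if scheme not in METHYL_SCHEMES:
        raise KeyError(f"unknown labeling scheme {scheme!r}; choose from {sorted(METHYL_SCHEMES)}")
    wanted = METHYL_SCHEMES[scheme]
    model_ids = structure.model_ids
    first = structure.model(model_ids[0])

    entries: list[MethylEntry] = []
    residues = first[["chain", "resnum", "resname"]].drop_duplicates()
    for _, (chain, resnum, resname) in residues.iterrows():
        for methyl_id in wanted:
            geo = _METHYL_GEOMETRY.get((resname, methyl_id))
            if geo is None:
                continue
            carbon, prev_carbon = geo
            res_atoms = set(first[(first["chain"] == chain) & (first["resnum"] == resnum)]["atom"])
            if carbon not in res_atoms:
                continue
            protons = [h for h in _proton_names(carbon) if h in res_atoms]
            per_model = []
            reconstructed = not protons
            for m in model_ids:
                if protons:
                    pos = np.array([structure.atom_position(m, resnum, h) for h in protons])
                else:
                    c = structure.atom_position(m, resnum, carbon)
                    if prev_carbon not in res_atoms:
                        raise StructureError(
                            f"residue {resnum} {resname}: cannot reconstruct {methyl_id} "
                            f"protons without {prev_carbon}"
                        )
                    p = structure.atom_position(m, resnum, prev_carbon)
                    axis = c - p
                    axis = axis / np.linalg.norm(axis)
                    pos = (c + _CENTROID_OFFSET * axis)[None, :]
                per_model.append(pos)
            entries.append(MethylEntry(int(resnum), resname, methyl_id,
                                       np.array(per_model), reconstructed))
    return MethylSelection(entries, model_ids)


# ---------------------------------------------------------------------------
# spin-label placement
# ---------------------------------------------------------------------------

TETHER_MIN = 6.0   # Å, brackets Cbeta -> nitroxide-O of extended MTSL rotamers
TETHER_MAX = 9.0
CLASH_RADIUS = 1.5  # Å against protein heavy atoms


def _local_frame(structure: Structure, model_id: int, site: LabelSite) -> tuple[np.ndarray, np.ndarray]:
    """Rotation-equivariant orthonormal frame anchored at the attachment atom.

    Built from attachment->CA as z and a third non-collinear heavy atom for x;
    falls back to an arbitrary fixed rule when the model has < 3 usable atoms.
    """
    cb = structure.atom_position(model_id, site.residue_number, site.attachment_atom)
    m = structure.model(model_id)
    heavy = m[m["element"] != "H"]
    try:
        ca = structure.atom_position(model_id, site.residue_number, "CA")
    except KeyError:
        others = heavy[~((heavy["resnum"] == site.residue_number) & (heavy["atom"] == site.attachment_atom))]
        if len(others) == 0:
            return cb, np.eye(3)
        ca = others[["x", "y", "z"]].to_numpy(float)[0]
    z = ca - cb
    nz = np.linalg.norm(z)
    if nz < 1e-9:
        return cb, np.eye(3)
    z = z / nz
    # third reference: first heavy atom (file order) non-collinear with the axis
    coords = heavy[["x", "y", "z"]].to_numpy(float)
    x = None
    for c in coords:
        v = c - cb
        v = v - (v @ z) * z
        if np.linalg.norm(v) > 1e-6:
            x = v / np.linalg.norm(v)
            break
    if x is None:  # collinear structure: any orthogonal completes the frame
        x = np.eye(3)[np.argmin(np.abs(z))]
        x = x - (x @ z) * z
        x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    return cb, np.column_stack([x, y, z])


def place_label(structure: Structure, site: LabelSite, n_candidates: int,
                seed: int) -> LabelEnsemble:
    """Rejection-sample nitroxide-center candidates on a 6-9 Å tether shell.

    Per model: ``n_candidates`` points are drawn uniformly (radius uniform in
    the tether range, direction uniform on the sphere, expressed in a local
    frame so that output co-rotates with the structure) and those within
    ``CLASH_RADIUS`` of any protein heavy atom are discarded.  Surviving
    candidates get uniform weights.  Deterministic for a fixed seed.
    """
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    rng = np.random.default_rng(seed)
    positions, model_ids = [], []
    for m in structure.model_ids:
        origin, frame = _local_frame(structure, m, site)
        r = rng.uniform(TETHER_MIN, TETHER_MAX, n_candidates)
        costh = rng.uniform(-1.0, 1.0, n_candidates)
        phi = rng.uniform(0.0, 2 * np.pi, n_candidates)
        sinth = np.sqrt(1 - costh**2)
        local = np.column_stack([r * sinth * np.cos(phi),
                                 r * sinth * np.sin(phi),
                                 r * costh])
        cand = origin + local @ frame.T
        heavy = structure.heavy_coords(m)
        d2 = ((cand[:, None, :] - heavy[None, :, :]) ** 2).sum(-1)
        keep = (d2.min(axis=1) >= CLASH_RADIUS**2)
        if not keep.any():
            raise PlacementError(
                f"no clash-free label candidate in model {m} for site {site.residue_number}"
            )
        positions.append(cand[keep])
        model_ids.append(m)
    return LabelEnsemble(site=site, positions=positions, model_ids=model_ids)


def write_label_ensemble(ensemble: LabelEnsemble, pdb_path=None, tsv_path=None) -> None:
    """Emit the candidate cloud as a multi-model pseudo-atom PDB and/or TSV."""
    if pdb_path is not None:
        with open(pdb_path, "w") as fh:
            for mi, (m, pos) in enumerate(zip(ensemble.model_ids, ensemble.positions), 1):
                fh.write(f"MODEL     {mi:4d}\n")
                for i, (x, y, z) in enumerate(pos, 1):
                    fh.write(
                        f"HETATM{i:5d}  O   MTS X{ensemble.site.residue_number:4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           O\n"
                    )
                fh.write("ENDMDL\n")
            fh.write("END\n")
    if tsv_path is not None:
        rows = []
        for m, pos, w in zip(ensemble.model_ids, ensemble.positions, ensemble.weights):
            for (x, y, z), wi in zip(pos, w):
                rows.append((m, x, y, z, wi))
        pd.DataFrame(rows, columns=["model", "x", "y", "z", "weight"]).to_csv(
            tsv_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# relative solvent accessibility
# ---------------------------------------------------------------------------

# Theoretical maximum ASA (Å^2) in an extended Gly-X-Gly context
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

# single-element van der Waals radii (Å), shared with the test oracle
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}


def _to_biotite(df: pd.DataFrame):
    import biotite.structure as struc

    arr = struc.AtomArray(len(df))
    arr.coord = df[["x", "y", "z"]].to_numpy(float)
    arr.chain_id = df["chain"].to_numpy(str)
    arr.res_id = df["resnum"].to_numpy(int)
    arr.res_name = df["resname"].to_numpy(str)
    arr.atom_name = df["atom"].to_numpy(str)
    arr.element = df["element"].to_numpy(str)
    arr.hetero = np.zeros(len(df), bool)
    return arr


def relative_sasa(structure: Structure, probe_radius: float = 1.4,
                  point_number: int = 500) -> pd.Series:
    """Per-residue relative solvent accessibility in [0, 1].

    Shrake-Rupley accessible surface (biotite) on heavy atoms, summed per
    residue and divided by the residue's extended Gly-X-Gly reference value.
    Residues without a reference value are flagged via warning and excluded.
    """
    import biotite.structure as struc

    if structure.n_models != 1:
        raise StructureError("relative_sasa expects a single-model structure")
    df = structure.atoms[structure.atoms["element"] != "H"]
    arr = _to_biotite(df)
    radii = np.array([VDW_RADII.get(e, 1.70) for e in arr.element])
    asa = struc.sasa(arr, probe_radius=probe_radius, vdw_radii=radii,
                     point_number=point_number)
    out = {}
    tab = pd.DataFrame({"resnum": arr.res_id, "resname": arr.res_name, "asa": asa})
    for (resnum, resname), g in tab.groupby(["resnum", "resname"]):
        ref = MAX_ASA.get(resname)
        if ref is None:
            warnings.warn(f"residue {resnum} {resname}: no reference ASA, excluded")
            continue
        out[int(resnum)] = float(np.clip(g["asa"].sum() / ref, 0.0, 1.0))
    return pd.Series(out, name="rel_sasa").sort_index()


def residue_contacts(structure: Structure, cutoff: float = 6.5,
                     model_id: int | None = None) -> dict[int, set[int]]:
    """Residue adjacency from heavy-atom distances within ``cutoff`` Å."""
    if model_id is None:
        model_id = structure.model_ids[0]
    m = structure.model(model_id)
    m = m[m["element"] != "H"]
    xyz = m[["x", "y", "z"]].to_numpy(float)
    res = m["resnum"].to_numpy(int)
    d2 = ((xyz[:, None, :] - xyz[None, :, :]) ** 2).sum(-1)
    close = d2 <= cutoff**2
    contacts: dict[int, set[int]] = {int(r): set() for r in np.unique(res)}
    ii, jj = np.nonzero(close)
    for a, b in zip(res[ii], res[jj]):
        if a != b:
            contacts[int(a)].add(int(b))
    return contacts
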