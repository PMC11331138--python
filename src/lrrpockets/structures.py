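"""Predicted complex structures: parsing, confidence filtering, contacts,
hydrogen bonds, pocket calls, cross-model consensus and superposition.

The module consumes predicted receptor-peptide(-coreceptor) models (PDB or
mmCIF) plus a JSON sidecar of per-model interface confidence (ipTM).
Models are filtered by the confidence scheme of their predictor (AFM:
confident iff ipTM > 0.84; AF3: confident iff ipTM > 0.8, gray zone
0.6 < ipTM <= 0.8 — both comparisons strict), contacts and hydrogen bonds
are extracted geometrically, per-peptide-position pockets are called, and
residues supported by at least a fraction of confident models form the
consensus pocket.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import gemmi
import numpy as np

DEFAULT_CONTACT_CUTOFF = 4.0     # A, min heavy-atom distance
DEFAULT_HBOND_CUTOFF = 3.5       # A, donor-acceptor distance
DEFAULT_HBOND_ANGLE = 120.0      # degrees, antecedent-donor-acceptor

#: heavy-atom antecedent used for the donor-angle check
_ANTECEDENT = {"N": "CA", "O": "C", "OG": "CB", "OG1": "CB", "OD1": "CB",
               "OD2": "CB", "ND1": "CB", "ND2": "CB", "NE2": "CB",
               "OE1": "CB", "OE2": "CB"}


@dataclass
class Residue:
    chain: str
    number: int                      # author numbering, 1-based
    name: str
    atoms: dict                      # atom name -> xyz (np.ndarray)
    elements: dict                   # atom name -> element symbol


@dataclass
class StructureModel:
    model_id: str
    roles: dict                      # chain id -> {receptor,peptide,coreceptor}
    residues: list                   # list[Residue]
    iptm: float | None = None

    def chain_residues(self, role: str):
        chains = [c for c, r in self.roles.items() if r == role]
        return [res for res in self.residues if res.chain in chains]


@dataclass(frozen=True)
class ContactRecord:
    receptor_residue: tuple          # (chain, number, name)
    peptide_position: int            # 1-based within the mature peptide
    distance: float                  # min heavy-atom distance, A
    hbond: bool = False
    donor: str | None = None
    acceptor: str | None = None

    def __post_init__(self):
        if self.distance <= 0:
            raise ValueError("contact distance must be positive")


@dataclass
class PocketCall:
    pockets: dict                    # peptide position -> {receptor resnum}
    support: dict = field(default_factory=dict)
    # (position, resnum) -> supporting model count
    n_models: int = 1
    nonpolar: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def read_sidecar(path_or_text) -> dict:
    """JSON sidecar mapping model filename -> ipTM."""
    try:
        return json.loads(path_or_text)
    except (json.JSONDecodeError, TypeError):
        with open(path_or_text) as fh:
            return json.load(fh)


def parse_structure(
    source, roles: dict, sidecar: dict | None = None,
    model_id: str | None = None, fmt: str | None = None,
) -> StructureModel:
    """Parse a PDB or mmCIF model and label its chains by role.

    ``source`` is a path or raw text; author residue numbering is
    preserved so receptor residue 246 reports as 246.  The ipTM is looked
    up in the sidecar under ``<model_id>.pdb`` / ``.cif`` / bare id; a
    missing score loads the model with ``iptm=None`` (flagged, filtered
    out later).
    """
    text = None
    if isinstance(source, str) and "\n" in source:
        text = source
    elif hasattr(source, "read"):
        text = source.read()
    if text is not None:
        if fmt is None:
            fmt = "cif" if text.lstrip().startswith("data_") else "pdb"
        if fmt == "pdb":
            st = gemmi.read_pdb_string(text)
        else:
            doc = gemmi.cif.read_string(text)
            st = gemmi.make_structure_from_block(doc.sole_block())
    else:
        st = gemmi.read_structure(str(source))
    st.setup_entities()
    if model_id is None:
        model_id = st.name or "model"
    chain_ids = {ch.name for ch in st[0]}
    unknown = set(roles) - chain_ids
    if unknown:
        raise KeyError(
            f"role chains {sorted(unknown)} not present in the structure "
            f"(chains: {sorted(chain_ids)})"
        )
    residues = []
    for ch in st[0]:
        if ch.name not in roles:
            continue
        for res in ch:
            atoms, elements = {}, {}
            for at in res:
                atoms[at.name] = np.array([at.pos.x, at.pos.y, at.pos.z])
                elements[at.name] = at.element.name
            residues.append(Residue(chain=ch.name, number=res.seqid.num,
                                    name=res.name, atoms=atoms,
                                    elements=elements))
    iptm = None
    if sidecar:
        for key in (f"{model_id}.pdb", f"{model_id}.cif", model_id):
            if key in sidecar:
                iptm = float(sidecar[key])
                break
    return StructureModel(model_id=model_id, roles=dict(roles),
                          residues=residues, iptm=iptm)


def filter_models(models, scheme: str = "afm"):
    """Partition models by interface confidence.

    ``afm``: confident iff ipTM > 0.84 (strict), everything else rejected.
    ``af3``: confident iff ipTM > 0.8; gray iff 0.6 < ipTM <= 0.8; else
    rejected.  Models without an ipTM are rejected.
    """
    confident, gray, rejected = [], [], []
    for m in models:
        if m.iptm is None:
            rejected.append(m)
        elif scheme == "afm":
            (confident if m.iptm > 0.84 else rejected).append(m)
        elif scheme == "af3":
            if m.iptm > 0.8:
                confident.append(m)
            elif 0.6 < m.iptm <= 0.8:
                gray.append(m)
            else:
                rejected.append(m)
        else:
            raise ValueError(f"unknown confidence scheme {scheme!r}")
    return confident, gray, rejected


# ---------------------------------------------------------------------------
# Contacts and hydrogen bonds
# ---------------------------------------------------------------------------

def find_contacts(
    model: StructureModel, cutoff: float = DEFAULT_CONTACT_CUTOFF
) -> list:
    """Min heavy-atom distance for every (receptor residue, peptide
    residue) pair; pairs at or below the cutoff are emitted, ordered by
    (receptor number, peptide position)."""
    rec = model.chain_residues("receptor")
    pep = model.chain_residues("peptide")
    if not rec or not pep:
        return []
    rec_xyz = np.array([xyz for r in rec for a, xyz in r.atoms.items()
                        if r.elements[a] != "H"])
    rec_idx = np.array([i for i, r in enumerate(rec)
                        for a in r.atoms if r.elements[a] != "H"])
    pep_xyz = np.array([xyz for p in pep for a, xyz in p.atoms.items()
                        if p.elements[a] != "H"])
    pep_idx = np.array([j for j, p in enumerate(pep)
                        for a in p.atoms if p.elements[a] != "H"])
    d = np.sqrt(
        ((rec_xyz[:, None, :] - pep_xyz[None, :, :]) ** 2).sum(-1)
    )
    # min distance per residue pair via grouped reduction
    n_rec, n_pep = len(rec), len(pep)
    mind = np.full((n_rec, n_pep), np.inf)
    np.minimum.at(mind, (rec_idx[:, None], pep_idx[None, :]), d)
    contacts = []
    for i, j in np.argwhere(mind <= cutoff):
        r, p = rec[i], pep[j]
        contacts.append(ContactRecord(
            receptor_residue=(r.chain, r.number, r.name),
            peptide_position=p.number,
            distance=float(mind[i, j]),
        ))
    contacts.sort(key=lambda c: (c.receptor_residue[1], c.peptide_position))
    return contacts


def _donor_angle_ok(res: Residue, donor: str, acceptor_xyz, angle_min):
    ante = _ANTECEDENT.get(donor)
    if ante is None or ante not in res.atoms:
        return True                      # no antecedent -> distance only
    d = res.atoms[donor]
    v1 = res.atoms[ante] - d
    v2 = acceptor_xyz - d
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return angle >= angle_min


def hydrogen_bonds(
    model: StructureModel,
    d_max: float = DEFAULT_HBOND_CUTOFF,
    angle_min: float = DEFAULT_HBOND_ANGLE,
    contacts: list | None = None,
) -> list:
    """Geometric hydrogen bonds between receptor and peptide.

    N/O atom pairs within ``d_max`` whose donor angle (antecedent-donor-
    acceptor, checked for whichever orientation has its antecedent atom
    present) reaches ``angle_min``.  Hydrogens and energies are ignored.
    Returns contacts upgraded with hbond flags; non-contact pairs are
    never hydrogen bonds.
    """
    if contacts is None:
        contacts = find_contacts(model)
    rec = {r.number: r for r in model.chain_residues("receptor")}
    pep = {p.number: p for p in model.chain_residues("peptide")}
    out = []
    for c in contacts:
        rres = rec[c.receptor_residue[1]]
        pres = pep[c.peptide_position]
        best = None
        for ra, rxyz in rres.atoms.items():
            if rres.elements[ra] not in ("N", "O"):
                continue
            for pa, pxyz in pres.atoms.items():
                if pres.elements[pa] not in ("N", "O"):
                    continue
                dist = float(np.linalg.norm(rxyz - pxyz))
                if dist > d_max:
                    continue
                ok = (
                    _donor_angle_ok(rres, ra, pxyz, angle_min)
                    or _donor_angle_ok(pres, pa, rxyz, angle_min)
                )
                if ok and (best is None or dist < best[0]):
                    best = (dist, ra, pa)
        if best is not None:
            out.append(ContactRecord(
                receptor_residue=c.receptor_residue,
                peptide_position=c.peptide_position,
                distance=c.distance, hbond=True,
                donor=best[1], acceptor=best[2],
            ))
        else:
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# Pocket calls and consensus
# ---------------------------------------------------------------------------

def call_pockets(contacts, positions_of_interest=(5, 7)) -> PocketCall:
    """Per requested peptide position, the receptor residues hydrogen-
    bonded to it; nonpolar-only contacts are reported separately."""
    pockets = {p: set() for p in positions_of_interest}
    nonpolar = {p: set() for p in positions_of_interest}
    for c in contacts:
        p = c.peptide_position
        if p not in pockets:
            continue
        if c.hbond:
            pockets[p].add(c.receptor_residue[1])
        else:
            nonpolar[p].add(c.receptor_residue[1])
    return PocketCall(pockets=pockets, nonpolar=nonpolar, n_models=1)


def consensus_pockets(
    models_contacts, positions_of_interest=(5, 7),
    min_support: float = 0.5,
) -> PocketCall:
    """Consensus pocket across models: a residue is kept at a position iff
    it appears in >= min_support * n_models of the per-model calls."""
    calls = [
        call_pockets(c, positions_of_interest) for c in models_contacts
    ]
    n = len(calls)
    support = {}
    for call in calls:
        for p, residues in call.pockets.items():
            for res in residues:
                support[(p, res)] = support.get((p, res), 0) + 1
    needed = min_support * n
    pockets = {p: set() for p in positions_of_interest}
    for (p, res), cnt in support.items():
        if cnt >= needed:
            pockets[p].add(res)
    return PocketCall(pockets=pockets, support=support, n_models=n)


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def superpose(coords_a: np.ndarray, coords_b: np.ndarray):
    """Least-squares rigid superposition (Kabsch) of paired coordinates.

    Returns (rotation 3x3, translation 3, rmsd) mapping b onto a, with a
    proper rotation (det = +1) enforced.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("need two equal (n, 3) coordinate arrays")
    ca, cb = a.mean(0), b.mean(0)
    h = (b - cb).T @ (a - ca)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = ca - rot @ cb
    moved = (rot @ b.T).T + trans
    rmsd = float(np.sqrt(((moved - a) ** 2).sum(-1).mean()))
    return rot, trans, rmsd


def superpose_models(model_a: StructureModel, model_b: StructureModel,
                     paired_residues=None, role: str = "receptor"):
    """Kabsch fit on paired CA atoms of two models.

    ``paired_residues`` is a list of (resnum_a, resnum_b); by default all
    residue numbers shared by the two chains of ``role`` are paired."""
    res_a = {r.number: r for r in model_a.chain_residues(role)}
    res_b = {r.number: r for r in model_b.chain_residues(role)}
    if paired_residues is None:
        shared = sorted(set(res_a) & set(res_b))
        paired_residues = [(n, n) for n in shared]
    ca_a, ca_b = [], []
    for na, nb in paired_residues:
        if "CA" in res_a[na].atoms and "CA" in res_b[nb].atoms:
            ca_a.append(res_a[na].atoms["CA"])
            ca_b.append(res_b[nb].atoms["CA"])
    return superpose(np.array(ca_a), np.array(ca_b))
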