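"""Seeded synthetic inputs for every stage of the pocket-inference pipeline.

The generators emulate, at desk scale, the four kinds of input the analysis
consumes:

* an aligned family of LRR receptor ectodomains evolved along a random
  coalescent tree, with a planted conserved surface patch against a
  diversified background;
* families of peptide-precursor proteins sharing a short fixed-position
  motif (SxS, minority SxT) inside an otherwise divergent 13-15 residue
  mature window;
* per-species gene tables containing a conserved anchor-flanked locus with
  inserted candidate genes plus shuffled decoys;
* toy receptor-solenoid + extended-peptide 3D complexes with known contact
  residues and assigned interface confidence (ipTM) scores.

Every generator is deterministic given ``SimConfig.seed`` and emits a
:class:`SimTruth` describing exactly what was planted, so downstream
operations can be tested by parameter recovery rather than against opaque
fixtures.
"""

from __future__ import annotations

import dataclasses
import io
import json
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

from ._aa import AA, BACKGROUND

# ---------------------------------------------------------------------------
# Canonical plant LRR unit
# ---------------------------------------------------------------------------

#: 24-residue plant LRR framework; upper-case letters are fixed anchor
#: residues, ``x`` positions are variable.
LRR_UNIT_PATTERN = "LxxLxLxxLxLxxNxLxGxIPxxx"
LRR_UNIT_LENGTH = len(LRR_UNIT_PATTERN)
#: (offset, residue) pairs of the fixed framework anchors.
LRR_ANCHORS = tuple(
    (i, c) for i, c in enumerate(LRR_UNIT_PATTERN) if c != "x"
)
#: Default solvent-exposed offsets (0-based within the unit): the variable
#: positions of the concave-face (beta-strand) segment of the unit.
EXPOSED_OFFSETS = (4, 6, 7, 9, 11, 12, 14, 16)

# Fixed N-/C-terminal cap segments flanking the repeat region.  They stand
# in for the conserved capping domains and never match the repeat pattern.
N_CAP = "MKTWSPQEAWNDPHRFCGQE"
C_CAP = "DTSHWNEFKQRCMAYDHPEW"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study conditions.

    Defaults reproduce the conditions the pipeline is designed around: a
    37-member receptor clade with 24 LRR units per ectodomain, a planted
    conserved patch on the concave face, 13-residue mature peptides carrying
    S at positions 5 and 7, and 12 confident + 3 low-confidence complex
    models sharing planted S5/S7 pockets.
    """

    seed: int = 0
    # receptor family
    n_species: int = 37
    tree_depth: float = 0.4          # root-to-tip, substitutions/site
    n_repeats: int = 24
    background_rate: float = 6.0     # relative site rate, exposed background
    internal_rate: float = 1.0       # relative site rate, buried x positions
    patch_rate: float = 0.02         # relative site rate inside the patch
    # planted conserved patch: the full exposed face of repeats 9-12,
    # the binding-canyon band that carries the planted pocket residues
    patch_cells: frozenset = frozenset(
        (r, c) for r in range(9, 13) for c in range(8)
    )
    exposed_offsets: tuple = EXPOSED_OFFSETS
    # peptide precursors
    n_clusters: int = 10
    peptide_species: int = 8
    motif: str = "S.S"
    motif_start: int = 5             # 1-based mature position of motif[0]
    mature_length: int = 13
    mature_divergence: float = 0.2
    flank_divergence: float = 0.35
    propeptide_length: int = 25
    tail_length: int = 10
    sxt_fraction: float = 0.2
    n_decoys: int = 20
    # gene tables / loci
    locus_window: int = 5            # genes each side of the anchors
    n_inserted: int = 2
    # toy complexes
    planted_contacts: frozenset = frozenset(
        {(246, 5), (268, 5), (292, 7), (294, 7), (316, 7)}
    )
    n_confident_models: int = 12
    n_decoy_models: int = 3

    def __post_init__(self):
        if self.patch_rate > self.background_rate:
            raise ValueError("patch_rate must not exceed background_rate")
        if not (13 <= self.mature_length <= 15):
            raise ValueError("mature_length must be within 13..15")
        ncols = len(self.exposed_offsets)
        for r, c in self.patch_cells:
            if not (0 <= r < self.n_repeats and 0 <= c < ncols):
                raise ValueError(
                    f"patch cell ({r}, {c}) outside the "
                    f"{self.n_repeats}x{ncols} grid"
                )
        if self.motif_start + len(self.motif) - 1 > self.mature_length:
            raise ValueError("motif does not fit inside the mature window")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SimTruth:
    """Ground truth planted by a generator, serialisable alongside outputs."""

    planted_patch: set = field(default_factory=set)
    planted_contacts: set = field(default_factory=set)
    planted_homologue_ids: list = field(default_factory=list)
    planted_locus_members: dict = field(default_factory=dict)
    generating_tree: str = ""
    cluster_members: dict = field(default_factory=dict)
    mature_offsets: dict = field(default_factory=dict)
    decoy_ids: list = field(default_factory=list)
    anchor_ids: dict = field(default_factory=dict)
    model_iptm: dict = field(default_factory=dict)
    confident_models: list = field(default_factory=list)

    def to_json(self) -> str:
        def _default(o):
            if isinstance(o, (set, frozenset)):
                return sorted(o)
            if isinstance(o, tuple):
                return list(o)
            raise TypeError(type(o))

        return json.dumps(dataclasses.asdict(self), default=_default,
                          sort_keys=True, indent=1)


# ---------------------------------------------------------------------------
# Shared helpers
# ---------------------------------------------------------------------------

def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed) % (2**31), stream])


def _random_seq(rng, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length, p=BACKGROUND))


def _mutate(seq: list, probs: np.ndarray, rng) -> list:
    """Per-site replacement: site i changes with probability probs[i]; the
    new residue is drawn from the background excluding the current one."""
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < probs)[0]
    for i in hits:
        cur = out[i]
        w = BACKGROUND.copy()
        w[AA.index(cur)] = 0.0
        w /= w.sum()
        out[i] = rng.choice(list(AA), p=w)
    return out


class _Node:
    __slots__ = ("name", "children", "height")

    def __init__(self, name=None, children=(), height=0.0):
        self.name = name
        self.children = list(children)   # (child, branch_length)
        self.height = height


def _coalescent_tree(rng, names, depth: float) -> _Node:
    """Kingman-style random binary tree over ``names``; root-to-tip height
    rescaled to ``depth`` substitutions/site."""
    lineages = [_Node(name=n, height=0.0) for n in names]
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(1.0) / (k * (k - 1) / 2.0)
        i, j = sorted(rng.choice(k, size=2, replace=False))
        b = lineages.pop(j)
        a = lineages.pop(i)
        parent = _Node(height=t)
        parent.children = [(a, t - a.height), (b, t - b.height)]
        lineages.append(parent)
    root = lineages[0]
    scale = depth / root.height if root.height > 0 else 1.0

    def _rescale(node):
        node.children = [(c, bl * scale) for c, bl in node.children]
        for c, _ in node.children:
            _rescale(c)

    _rescale(root)
    return root


def _newick(node: _Node) -> str:
    def fmt(n):
        if not n.children:
            return n.name
        inner = ",".join(f"{fmt(c)}:{bl:.6f}" for c, bl in n.children)
        return f"({inner})"

    return fmt(node) + ";"


def _evolve(root_seq: str, tree: _Node, probs_per_unit: np.ndarray, rng):
    """Evolve ``root_seq`` down the tree; probs_per_unit[i] is the
    substitution probability per unit branch length at site i."""
    leaves = {}

    def walk(node, seq):
        if not node.children:
            leaves[node.name] = "".join(seq)
            return
        for child, bl in node.children:
            p = 1.0 - np.exp(-probs_per_unit * bl)
            walk(child, _mutate(seq, p, rng))

    walk(tree, list(root_seq))
    return leaves


def write_fasta(records, width: int = 60) -> str:
    buf = io.StringIO()
    for name, seq in records:
        buf.write(f">{name}\n")
        for i in range(0, len(seq), width):
            buf.write(seq[i : i + width] + "\n")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Receptor family
# ---------------------------------------------------------------------------

def _species_names(n: int):
    return [f"sp{i:02d}" for i in range(1, n + 1)]


def curation_reference_receptor(cfg: SimConfig):
    """The canonical curation-reference ectodomain: N-cap, ``n_repeats``
    canonical 24-residue LRR units (variable positions drawn from the
    background), C-cap.  Deterministic in ``cfg.seed``."""
    rng = _rng(cfg, 10)
    units = []
    for _ in range(cfg.n_repeats):
        unit = [
            c if c != "x" else rng.choice(list(AA), p=BACKGROUND)
            for c in LRR_UNIT_PATTERN
        ]
        units.append("".join(unit))
    seq = N_CAP + "".join(units) + C_CAP
    return "reference_RK", seq


@dataclass
class ReceptorFamilySim:
    records: list                # [(id, aligned sequence)] — gap-free
    reference_id: str
    truth: SimTruth
    config: SimConfig

    def fasta(self) -> str:
        return write_fasta(self.records)


def _site_rates(cfg: SimConfig, seq_len: int) -> np.ndarray:
    """Per-site relative substitution rates over the full ectodomain.

    Caps and framework anchors are held fixed; buried variable positions
    evolve slowly (``internal_rate``), solvent-exposed positions fast
    (``background_rate``, diversifying-selection regime), and planted
    patch cells slowest of all (``patch_rate``)."""
    rates = np.zeros(seq_len)
    offset_col = {off: c for c, off in enumerate(cfg.exposed_offsets)}
    for rep in range(cfg.n_repeats):
        base = len(N_CAP) + rep * LRR_UNIT_LENGTH
        for off, ch in enumerate(LRR_UNIT_PATTERN):
            if ch != "x":
                continue
            col = offset_col.get(off)
            if col is None:
                rate = cfg.internal_rate
            elif (rep, col) in cfg.patch_cells:
                rate = cfg.patch_rate
            else:
                rate = cfg.background_rate
            rates[base + off] = rate
    return rates


def generate_receptor_family(cfg: SimConfig) -> ReceptorFamilySim:
    """Aligned receptor family evolved along a random coalescent tree.

    The alignment is gap-free by construction (per-site replacement only,
    no indels), so curation and grid building are exact."""
    rng = _rng(cfg, 11)
    _, root_seq = curation_reference_receptor(cfg)
    tree = _coalescent_tree(rng, _species_names(cfg.n_species), cfg.tree_depth)
    rates = _site_rates(cfg, len(root_seq))
    leaves = _evolve(root_seq, tree, rates, rng)
    records = [(f"{sp}_RK", leaves[sp]) for sp in _species_names(cfg.n_species)]
    truth = SimTruth(
        planted_patch=set(cfg.patch_cells),
        planted_homologue_ids=[r[0] for r in records],
        generating_tree=_newick(tree),
    )
    return ReceptorFamilySim(
        records=records, reference_id=records[0][0], truth=truth, config=cfg
    )


# ---------------------------------------------------------------------------
# Peptide precursors
# ---------------------------------------------------------------------------

@dataclass
class PrecursorSetSim:
    records: list                # [(id, sequence)] precursors then decoys
    truth: SimTruth
    config: SimConfig

    def fasta(self) -> str:
        return write_fasta(self.records)


def _motif_constraints(cfg: SimConfig, sxt: bool):
    """{0-based mature offset: fixed residue} for one cluster."""
    motif = cfg.motif
    if sxt and motif == "S.S":
        motif = "S.T"
    out = {}
    for i, ch in enumerate(motif):
        if ch not in (".", "x"):
            out[cfg.motif_start - 1 + i] = ch
    return out


def generate_precursor_set(cfg: SimConfig) -> PrecursorSetSim:
    """Precursor families: conserved mature window carrying the motif at
    fixed positions, flanked by a faster-diverging propeptide and tail,
    plus unrelated decoy proteins."""
    rng = _rng(cfg, 12)
    n_sxt = int(round(cfg.n_clusters * cfg.sxt_fraction))
    records, cluster_members, mature_offsets = [], {}, {}
    species = _species_names(cfg.peptide_species)
    for c in range(cfg.n_clusters):
        sxt = c >= cfg.n_clusters - n_sxt
        constraints = _motif_constraints(cfg, sxt)
        pro = _random_seq(rng, cfg.propeptide_length)
        mature = list(_random_seq(rng, cfg.mature_length))
        for off, ch in constraints.items():
            mature[off] = ch
        tail = _random_seq(rng, cfg.tail_length)
        consensus = list(pro) + mature + list(tail)
        probs = np.full(len(consensus), cfg.flank_divergence)
        m0 = cfg.propeptide_length
        probs[m0 : m0 + cfg.mature_length] = cfg.mature_divergence
        for off in constraints:
            probs[m0 + off] = 0.0
        members = []
        for sp in species:
            seq = "".join(_mutate(consensus, probs, rng))
            rid = f"{sp}_PSC{c:02d}"
            records.append((rid, seq))
            members.append(rid)
            mature_offsets[rid] = m0
        cluster_members[f"cluster{c:02d}"] = members
    decoys = []
    total_len = cfg.propeptide_length + cfg.mature_length + cfg.tail_length
    for d in range(cfg.n_decoys):
        rid = f"decoy{d:02d}"
        records.append((rid, _random_seq(rng, total_len)))
        decoys.append(rid)
    truth = SimTruth(
        planted_homologue_ids=[r for r, _ in records if not r.startswith("decoy")],
        cluster_members=cluster_members,
        mature_offsets=mature_offsets,
        decoy_ids=decoys,
    )
    return PrecursorSetSim(records=records, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# Gene tables / loci
# ---------------------------------------------------------------------------

GENE_TABLE_COLUMNS = ["gene_id", "contig", "start", "end", "strand", "species"]


@dataclass
class GeneTableSim:
    tables: dict                 # species -> DataFrame (GENE_TABLE_COLUMNS)
    proteins: dict               # gene_id -> protein sequence
    truth: SimTruth
    config: SimConfig

    def tsv(self, species: str) -> str:
        return self.tables[species].to_csv(sep="\t", index=False)


def generate_gene_tables(cfg: SimConfig) -> GeneTableSim:
    """Per-species gene tables with two anchor orthologues flanking
    ``n_inserted`` candidate genes, surrounded by decoy genes and a decoy
    contig.  Coordinates are 0-based half-open."""
    rng = _rng(cfg, 13)
    anchor_a_prot = _random_seq(rng, 180)
    anchor_b_prot = _random_seq(rng, 160)
    cand_consensus = [_random_seq(rng, 120) for _ in range(cfg.n_inserted)]
    tables, proteins = {}, {}
    locus_members, anchor_ids = {}, {}
    species = _species_names(cfg.peptide_species)
    for sp in species:
        rows = []
        pos = int(rng.integers(1000, 5000))

        def add_gene(gid, prot, contig="c1"):
            nonlocal pos
            length = int(rng.integers(300, 3000))
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((gid, contig, pos, pos + length, strand, sp))
            proteins[gid] = prot
            pos += length + int(rng.integers(200, 2000))

        for d in range(4):
            add_gene(f"{sp}_up{d}", _random_seq(rng, 100))
        aid_a = f"{sp}_anchorA"
        add_gene(aid_a, "".join(_mutate(list(anchor_a_prot),
                                        np.full(180, 0.05), rng)))
        cand_ids = []
        for i in range(cfg.n_inserted):
            cid = f"{sp}_cand{i}"
            add_gene(cid, "".join(_mutate(list(cand_consensus[i]),
                                          np.full(120, 0.1), rng)))
            cand_ids.append(cid)
        aid_b = f"{sp}_anchorB"
        add_gene(aid_b, "".join(_mutate(list(anchor_b_prot),
                                        np.full(160, 0.05), rng)))
        for d in range(4):
            add_gene(f"{sp}_down{d}", _random_seq(rng, 100))
        pos = int(rng.integers(1000, 3000))
        for d in range(3):
            add_gene(f"{sp}_far{d}", _random_seq(rng, 100), contig="c2")
        df = pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS)
        tables[sp] = df
        locus_members[sp] = cand_ids
        anchor_ids[sp] = [aid_a, aid_b]
    truth = SimTruth(planted_locus_members=locus_members,
                     anchor_ids=anchor_ids)
    return GeneTableSim(tables=tables, proteins=proteins, truth=truth,
                        config=cfg)


# ---------------------------------------------------------------------------
# Toy complexes
# ---------------------------------------------------------------------------

RECEPTOR_CHAIN = "A"
PEPTIDE_CHAIN = "B"
_REC_ATOM_OFFSETS = {
    "N": (-0.8, 0.4, 0.0), "CA": (0.0, 0.0, 0.0), "C": (0.8, 0.4, 0.0),
    "O": (0.9, -0.4, 0.0), "CB": (0.0, -0.8, 0.0), "OG": (0.0, 0.9, 0.0),
}
_PEP_ATOM_OFFSETS = {
    "N": (-0.5, 0.3, 0.0), "CA": (0.0, 0.0, 0.0), "C": (0.5, 0.3, 0.0),
    "O": (0.5, -0.35, 0.0), "CB": (-0.3, -0.5, 0.0), "OG": (0.0, 0.6, 0.0),
}
_SOLENOID_RADIUS = 16.0
_SOLENOID_RISE = 0.35
_PEPTIDE_SPACING = 4.6
_PLANT_DISTANCE = 2.9
_GUARD_MARGIN = 0.5
_DEFAULT_CONTACT_CUTOFF = 4.0


@dataclass
class ToyComplexSim:
    model_id: str
    pdb: str
    iptm: float
    truth: SimTruth
    structure: "gemmi.Structure"

    def mmcif(self) -> str:
        return self.structure.make_mmcif_document().as_string()


def _receptor_length(cfg: SimConfig) -> int:
    return len(N_CAP) + cfg.n_repeats * LRR_UNIT_LENGTH + len(C_CAP)


def generate_toy_complex(
    cfg: SimConfig,
    planted_contacts=None,
    iptm: float = 0.90,
    model_id: str = "model_000",
    coord_noise: float = 0.0,
    noise_stream: int = 0,
) -> ToyComplexSim:
    """One toy complex: receptor pseudo-atoms on a superhelical solenoid,
    peptide extended along the solenoid axis, and the side-chain polar atom
    of each planted receptor residue placed 2.9 A from the matching peptide
    polar atom.  All non-planted inter-chain residue pairs are verified to
    exceed the contact cutoff by the guard margin."""
    if planted_contacts is None:
        planted_contacts = cfg.planted_contacts
    planted = {(int(r), int(p)) for r, p in planted_contacts}
    n_rec = _receptor_length(cfg)
    n_pep = cfg.mature_length
    rec_of = {}
    for r, p in planted:
        if not (1 <= r <= n_rec) or not (1 <= p <= n_pep):
            raise ValueError(f"planted contact ({r}, {p}) outside the complex")
        if r in rec_of:
            raise ValueError(
                "geometric placement infeasible: receptor residue "
                f"{r} requested in more than one planted contact"
            )
        rec_of[r] = p

    rng = np.random.default_rng([int(cfg.seed) % (2**31), 14, noise_stream])
    z0 = (_SOLENOID_RISE * (n_rec - 1) - (n_pep - 1) * _PEPTIDE_SPACING) / 2.0

    pep_centers = {
        j: np.array([0.0, 0.0, z0 + (j - 1) * _PEPTIDE_SPACING])
        for j in range(1, n_pep + 1)
    }
    pep_atoms = {
        j: {a: pep_centers[j] + np.array(off)
            for a, off in _PEP_ATOM_OFFSETS.items()}
        for j in pep_centers
    }
    rec_atoms = {}
    for i in range(1, n_rec + 1):
        theta = 2.0 * np.pi * (i - 1) / LRR_UNIT_LENGTH
        center = np.array([
            _SOLENOID_RADIUS * np.cos(theta),
            _SOLENOID_RADIUS * np.sin(theta),
            _SOLENOID_RISE * (i - 1),
        ])
        atoms = {a: center + np.array(off)
                 for a, off in _REC_ATOM_OFFSETS.items()}
        if i in rec_of:
            j = rec_of[i]
            u = np.array([np.cos(theta), np.sin(theta), 0.0])
            atoms["OG"] = pep_atoms[j]["OG"] + _PLANT_DISTANCE * u
        rec_atoms[i] = atoms

    if coord_noise > 0:
        for atoms in list(rec_atoms.values()) + list(pep_atoms.values()):
            for a in atoms:
                atoms[a] = atoms[a] + rng.normal(0.0, coord_noise, size=3)

    _verify_toy_geometry(rec_atoms, pep_atoms, planted)

    st = gemmi.Structure()
    st.name = model_id
    model = gemmi.Model("1")
    for chain_name, atom_map in ((RECEPTOR_CHAIN, rec_atoms),
                                 (PEPTIDE_CHAIN, pep_atoms)):
        chain = gemmi.Chain(chain_name)
        for resnum in sorted(atom_map):
            res = gemmi.Residue()
            res.name = "SER"
            res.seqid = gemmi.SeqId(resnum, " ")
            for aname, xyz in atom_map[resnum].items():
                at = gemmi.Atom()
                at.name = aname
                at.element = gemmi.Element(aname[0])
                at.pos = gemmi.Position(*xyz)
                at.occ = 1.0
                at.b_iso = 0.0
                res.add_atom(at)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()

    truth = SimTruth(planted_contacts=set(planted),
                     model_iptm={f"{model_id}.pdb": iptm})
    return ToyComplexSim(model_id=model_id, pdb=st.make_pdb_string(),
                         iptm=iptm, truth=truth, structure=st)


def _verify_toy_geometry(rec_atoms, pep_atoms, planted):
    rec_ids = sorted(rec_atoms)
    rec_xyz = np.array([xyz for i in rec_ids for xyz in rec_atoms[i].values()])
    rec_res = np.array([i for i in rec_ids for _ in rec_atoms[i]])
    pep_ids = sorted(pep_atoms)
    pep_xyz = np.array([xyz for j in pep_ids for xyz in pep_atoms[j].values()])
    pep_res = np.array([j for j in pep_ids for _ in pep_atoms[j]])
    d = np.linalg.norm(rec_xyz[:, None, :] - pep_xyz[None, :, :], axis=-1)
    cutoff = _DEFAULT_CONTACT_CUTOFF
    for ri_idx, i in enumerate(rec_ids):
        mask_r = rec_res == i
        for j in pep_ids:
            dmin = d[np.ix_(mask_r, pep_res == j)].min()
            if (i, j) in planted:
                if dmin > 3.5:
                    raise ValueError(
                        f"planted contact ({i}, {j}) not within the "
                        "hydrogen-bond cutoff"
                    )
            elif dmin <= cutoff + _GUARD_MARGIN:
                raise ValueError(
                    "geometric placement infeasible: non-planted pair "
                    f"({i}, {j}) at {dmin:.2f} A"
                )


@dataclass
class ComplexEnsembleSim:
    models: list                 # [(model_id, pdb text, iptm)]
    sidecar: dict                # model filename -> iptm
    truth: SimTruth
    config: SimConfig

    def sidecar_json(self) -> str:
        return json.dumps(self.sidecar, sort_keys=True, indent=1)


def generate_complex_ensemble(cfg: SimConfig) -> ComplexEnsembleSim:
    """Toy model ensemble: ``n_confident_models`` jittered replicates that
    share the planted pockets with high ipTM, plus ``n_decoy_models`` with
    unrelated contacts and sub-threshold ipTM."""
    rng = _rng(cfg, 15)
    models, sidecar = [], {}
    confident = []
    for k in range(cfg.n_confident_models):
        iptm = float(np.round(rng.uniform(0.85, 0.95), 3))
        sim = generate_toy_complex(
            cfg, iptm=iptm, model_id=f"model_{k:03d}",
            coord_noise=0.05, noise_stream=k + 1,
        )
        models.append((sim.model_id, sim.pdb, iptm))
        sidecar[f"{sim.model_id}.pdb"] = iptm
        confident.append(sim.model_id)
    n_rec = _receptor_length(cfg)
    for k in range(cfg.n_decoy_models):
        iptm = float(np.round(rng.uniform(0.45, 0.70), 3))
        decoy_contacts = {
            (100 + 24 * k, 2),
            (min(400 + 24 * k, n_rec - 5), cfg.mature_length - 2),
        }
        sim = generate_toy_complex(
            cfg, planted_contacts=decoy_contacts, iptm=iptm,
            model_id=f"decoy_{k:03d}", coord_noise=0.05,
            noise_stream=100 + k,
        )
        models.append((sim.model_id, sim.pdb, iptm))
        sidecar[f"{sim.model_id}.pdb"] = iptm
    truth = SimTruth(
        planted_contacts=set(cfg.planted_contacts),
        model_iptm=dict(sidecar),
        confident_models=confident,
    )
    return ComplexEnsembleSim(models=models, sidecar=sidecar, truth=truth,
                              config=cfg)
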