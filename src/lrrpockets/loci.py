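"""Synteny-anchored locus mining.

Candidate homologues of a gene of interest are pulled out of per-species
gene tables by their position relative to conserved anchor genes, then
connected across species with local-alignment similarity links, and
finally collected by transitive closure from a set of seed genes.
Coordinates are 0-based half-open internally; the GFF3 reader converts
from 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align import evalue, local_score
from .simulate import GENE_TABLE_COLUMNS


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    species: str
    contig: str
    start: int
    end: int
    strand: str
    protein: str | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")


@dataclass
class GeneLocus:
    species: str
    anchor_ids: list
    members: list = field(default_factory=list)   # GeneRecord, sorted by start
    window_spec: int = 10

    def __post_init__(self):
        member_ids = {m.gene_id for m in self.members}
        missing = [a for a in self.anchor_ids if a not in member_ids]
        if missing:
            raise ValueError(f"anchors {missing} not among locus members")
        self.members = sorted(self.members, key=lambda m: (m.start, m.gene_id))

    @property
    def member_ids(self):
        return [m.gene_id for m in self.members]


@dataclass(frozen=True)
class LocusLink:
    gene_a: str
    gene_b: str
    score: float      # local-alignment bit-equivalent raw score
    evalue: float

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")

    def pair(self):
        return frozenset((self.gene_a, self.gene_b))


def read_gene_table(tsv_path_or_buffer) -> pd.DataFrame:
    """Read the native TSV gene-table dialect (0-based half-open)."""
    df = pd.read_csv(tsv_path_or_buffer, sep="\t")
    missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    return df[GENE_TABLE_COLUMNS]


def read_gff3(path, species: str) -> pd.DataFrame:
    """Minimal GFF3 gene reader: keeps ``gene`` features, converts 1-based
    inclusive coordinates to the internal 0-based half-open convention, and
    takes ``ID=`` as the gene id."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID", attrs.get("Name"))
            if gid is None:
                raise ValueError(f"gene feature without ID: {line!r}")
            rows.append(
                (gid, parts[0], int(parts[3]) - 1, int(parts[4]),
                 parts[6], species)
            )
    return pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS)


def table_to_records(df: pd.DataFrame, proteins: dict | None = None):
    proteins = proteins or {}
    return [
        GeneRecord(
            gene_id=row.gene_id, species=row.species, contig=row.contig,
            start=int(row.start), end=int(row.end), strand=row.strand,
            protein=proteins.get(row.gene_id),
        )
        for row in df.itertuples(index=False)
    ]


def extract_locus_window(
    table: pd.DataFrame,
    anchors,
    window_spec: int = 10,
    proteins: dict | None = None,
) -> GeneLocus:
    """Anchors plus every gene within ``window_spec`` genes of an anchor on
    the anchors' contig, ordered by ascending start regardless of strand.
    ``window_spec=0`` returns the anchors alone."""
    records = table_to_records(table, proteins)
    by_id = {r.gene_id: r for r in records}
    species = records[0].species if records else ""
    for a in anchors:
        if a not in by_id:
            raise KeyError(
                f"anchor {a!r} not found in the gene table of {species!r}"
            )
    contigs = {by_id[a].contig for a in anchors}
    if len(contigs) != 1:
        raise ValueError(f"anchors span multiple contigs: {sorted(contigs)}")
    contig = contigs.pop()
    ordered = sorted(
        (r for r in records if r.contig == contig),
        key=lambda r: (r.start, r.gene_id),
    )
    idx = {r.gene_id: i for i, r in enumerate(ordered)}
    keep = set()
    for a in anchors:
        i = idx[a]
        keep.update(range(max(0, i - window_spec),
                          min(len(ordered), i + window_spec + 1)))
    members = [ordered[i] for i in sorted(keep)]
    return GeneLocus(
        species=species, anchor_ids=list(anchors), members=members,
        window_spec=window_spec,
    )


def link_loci(
    locus_a: GeneLocus, locus_b: GeneLocus, evalue_max: float = 1e-6
) -> list:
    """All-vs-all local alignment between member proteins of two loci;
    links whose Karlin-Altschul E-value is strictly below ``evalue_max``."""
    links = []
    for ra in locus_a.members:
        if not ra.protein:
            continue
        for rb in locus_b.members:
            if not rb.protein:
                continue
            if ra.gene_id == rb.gene_id:
                continue
            s = local_score(ra.protein, rb.protein)
            e = evalue(s, len(ra.protein), len(rb.protein))
            if e < evalue_max:
                links.append(
                    LocusLink(gene_a=ra.gene_id, gene_b=rb.gene_id,
                              score=s, evalue=e)
                )
    return links


def link_all_loci(loci, evalue_max: float = 1e-6) -> list:
    links = []
    for i, la in enumerate(loci):
        for lb in loci[i + 1 :]:
            links.extend(link_loci(la, lb, evalue_max))
    return links


def candidate_genes(loci, links, seed_ids) -> dict:
    """Transitive closure over similarity links starting from the seeds,
    restricted to locus members.  Returns {gene_id: (species, locus index)}
    annotations; output is independent of locus ordering."""
    member_of = {}
    for i, locus in enumerate(loci):
        for m in locus.members:
            member_of.setdefault(m.gene_id, (m.species, i))
    adjacency = {}
    for link in links:
        if link.gene_a in member_of and link.gene_b in member_of:
            adjacency.setdefault(link.gene_a, set()).add(link.gene_b)
            adjacency.setdefault(link.gene_b, set()).add(link.gene_a)
    frontier = [s for s in seed_ids if s in member_of]
    seen = set(frontier)
    while frontier:
        g = frontier.pop()
        for nb in adjacency.get(g, ()):
            if nb not in seen:
                seen.add(nb)
                frontier.append(nb)
    return {g: member_of[g] for g in sorted(seen)}
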