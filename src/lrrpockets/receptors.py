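"""Receptor curation, similarity, distance trees and clade extraction.

Candidate LRR receptor kinases are curated by repeat architecture (the
homologue set must share one repeat count — 24 for the default plant
LRR ectodomain criterion — and show no gaps outside the repeat region),
then related by a distance matrix and a neighbor-joining tree from which
the seed-containing clade is extracted after outgroup rooting.

Neighbor joining is used as the distance-based stand-in for a
maximum-likelihood phylogeny: downstream stages consume the clade
membership, not branch support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .align import global_identity, global_similarity
from .simulate import LRR_ANCHORS, LRR_UNIT_LENGTH

logger = logging.getLogger(__name__)


@dataclass
class RepeatAnnotation:
    receptor_id: str
    repeats: list                    # [(start, end)] 0-based half-open

    def __post_init__(self):
        prev_end = -1
        for s, e in self.repeats:
            if s >= e or s < prev_end:
                raise ValueError("repeat segments must be ascending and "
                                 "non-overlapping")
            prev_end = e

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)


@dataclass
class DistanceMatrix:
    taxa: list
    matrix: np.ndarray               # 1 - fractional identity

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if m.min() < 0 or m.max() > 1:
            raise ValueError("distances must lie in [0, 1]")
        self.matrix = m


@dataclass
class PhyloTree:
    newick: str

    def dendropy_tree(self, rooting="force-unrooted") -> dendropy.Tree:
        return dendropy.Tree.get(data=self.newick, schema="newick",
                                 rooting=rooting,
                                 preserve_underscores=True)

    @property
    def leaf_names(self) -> set:
        t = self.dendropy_tree()
        return {lf.taxon.label for lf in t.leaf_node_iter()}


# ---------------------------------------------------------------------------
# Repeat detection and curation
# ---------------------------------------------------------------------------

def detect_lrr_repeats(
    sequence: str,
    receptor_id: str = "",
    anchors=LRR_ANCHORS,
    unit_length: int = LRR_UNIT_LENGTH,
    max_anchor_mismatches: int = 2,
) -> RepeatAnnotation:
    """Greedy left-to-right scan for the plant-LRR framework.

    A window of ``unit_length`` residues is a repeat when at most
    ``max_anchor_mismatches`` of its framework anchor positions deviate
    from the consensus.  Matched windows never overlap; zero repeats is a
    valid result.
    """
    repeats = []
    i = 0
    n = len(sequence)
    while i + unit_length <= n:
        window = sequence[i : i + unit_length]
        mism = sum(1 for off, res in anchors if window[off] != res)
        if mism <= max_anchor_mismatches:
            repeats.append((i, i + unit_length))
            i += unit_length
        else:
            i += 1
    return RepeatAnnotation(receptor_id=receptor_id, repeats=repeats)


def curation_filter(
    candidates: dict,
    expected_repeats: int = 24,
    alignment: dict | None = None,
    **detect_kwargs,
):
    """Keep candidates whose detected repeat count equals the curation
    criterion and whose alignment row (when given) has no gaps outside the
    repeat segments.  Returns (kept ids, annotations, rejected reasons);
    kept and rejected partition the input and every rejection carries a
    machine-readable reason."""
    kept, annotations, rejected = [], {}, {}
    for rid in sorted(candidates):
        ann = detect_lrr_repeats(candidates[rid], receptor_id=rid,
                                 **detect_kwargs)
        annotations[rid] = ann
        if ann.n_repeats != expected_repeats:
            rejected[rid] = (
                f"repeat_count:{ann.n_repeats}!={expected_repeats}"
            )
            continue
        if alignment is not None and rid in alignment:
            row = alignment[rid]

            def _in_one_segment(prev_pos, next_pos):
                # a gap column lies inside a repeat iff its flanking
                # residues belong to the same repeat segment
                return any(s <= prev_pos and next_pos < e
                           for s, e in ann.repeats)

            gap_outside = False
            next_pos = 0                 # sequence index of the next residue
            for ch in row:
                if ch != "-":
                    next_pos += 1
                elif not _in_one_segment(next_pos - 1, next_pos):
                    gap_outside = True
                    break
            if gap_outside:
                rejected[rid] = "gap_outside_repeats"
                continue
        kept.append(rid)
    return kept, annotations, rejected


# ---------------------------------------------------------------------------
# Distances and trees
# ---------------------------------------------------------------------------

def similarity_matrix(sequences: dict):
    """Pairwise global alignment over all sequences.

    Returns (DistanceMatrix, similarity report): distance is
    1 - fractional identity; the report lists percent similarity
    (positive-scoring matched columns / alignment length) per pair.
    """
    taxa = sorted(sequences)
    n = len(taxa)
    dist = np.zeros((n, n))
    report = {}
    for i in range(n):
        for j in range(i + 1, n):
            ident = global_identity(sequences[taxa[i]], sequences[taxa[j]])
            sim = global_similarity(sequences[taxa[i]], sequences[taxa[j]])
            dist[i, j] = dist[j, i] = 1.0 - ident
            report[(taxa[i], taxa[j])] = 100.0 * sim
    return DistanceMatrix(taxa=taxa, matrix=dist), report


def nj_tree(d: DistanceMatrix) -> PhyloTree:
    """Canonical Saitou-Nei neighbor joining.

    Ties in the Q-criterion are broken by the lexicographically smallest
    taxon pair, negative branch lengths are clamped to zero (logged), so
    the output is deterministic in the input matrix alone.
    """
    labels = list(d.taxa)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two taxa")
    if n == 2:
        bl = d.matrix[0, 1]
        return PhyloTree(f"({labels[0]}:{bl:.6f},{labels[1]}:0.000000);")
    dm = d.matrix.astype(float).copy()
    nodes = [f"{lab}" for lab in labels]          # newick fragments
    names = list(labels)                          # tie-break keys
    active = list(range(n))

    def clamp(x):
        if x < 0:
            logger.warning("negative NJ branch length %.4f clamped to 0", x)
            return 0.0
        return x

    while len(active) > 2:
        m = len(active)
        r = {i: sum(dm[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dm[i, j] - r[i] - r[j]
                key = (q, *sorted((names[i], names[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        vi = clamp(0.5 * dm[i, j] + (r[i] - r[j]) / (2 * (m - 2)))
        vj = clamp(dm[i, j] - vi)
        new = f"({nodes[i]}:{vi:.6f},{nodes[j]}:{vj:.6f})"
        new_name = min(names[i], names[j])
        # distances from the new node
        dnew = {}
        for k in active:
            if k in (i, j):
                continue
            dnew[k] = 0.5 * (dm[i, k] + dm[j, k] - dm[i, j])
        idx = len(nodes)
        nodes.append(new)
        names.append(new_name)
        dm = np.pad(dm, ((0, 1), (0, 1)))
        for k, val in dnew.items():
            dm[idx, k] = dm[k, idx] = val
        active = [k for k in active if k not in (i, j)] + [idx]

    i, j = active
    bl = clamp(dm[i, j])
    newick = f"({nodes[i]}:{bl:.6f},{nodes[j]}:0.000000);"
    return PhyloTree(newick)


def extract_clade(tree: PhyloTree, outgroup: str, seeds) -> set:
    """Root the tree at the outgroup and return the leaf set of the
    minimal rooted clade (MRCA subtree) containing all seeds."""
    t = tree.dendropy_tree(rooting="force-rooted")
    og = next(
        (lf for lf in t.leaf_node_iter() if lf.taxon.label == outgroup), None
    )
    if og is None:
        raise KeyError(f"outgroup {outgroup!r} not in the tree")
    # split the outgroup's edge so the root separates it from the ingroup
    half = (og.edge.length or 0.0) / 2.0
    t.reroot_at_edge(og.edge, length1=half, length2=half,
                     update_bipartitions=True)
    seeds = list(seeds)
    taxa = [t.taxon_namespace.get_taxon(s) for s in seeds]
    if any(tx is None for tx in taxa):
        missing = [s for s, tx in zip(seeds, taxa) if tx is None]
        raise KeyError(f"seed taxa not in the tree: {missing}")
    mrca = t.mrca(taxa=taxa)
    return {lf.taxon.label for lf in mrca.leaf_iter()}
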