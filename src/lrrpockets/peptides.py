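"""Peptide-precursor cataloguing.

Precursor candidates are clustered by single-linkage over local-alignment
identity, each cluster is aligned (center-star), a position-specific
log-odds profile (PSSM) is built from the alignment, and the profile is
used both to scan proteomes for further homologues and to select the
13-15 residue mature window of each precursor.  The PSSM is a deliberate
simplification of a profile HMM: the synthetic mature windows are
gap-free, so position-specific indel states add nothing here.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from ._aa import AA, AA_INDEX, BACKGROUND
from .align import evalue, local_identity, local_score, make_aligner

MAX_IC = math.log2(20.0)


@dataclass(frozen=True)
class PrecursorRecord:
    id: str
    species: str
    sequence: str
    source_locus: str | None = None

    def __post_init__(self):
        bad = set(self.sequence) - set(AA) - {"X"}
        if bad:
            raise ValueError(f"{self.id}: non amino-acid letters {sorted(bad)}")

    @property
    def has_unknown(self) -> bool:
        return "X" in self.sequence


@dataclass
class MaturePeptide:
    parent_id: str
    sequence: str
    offset: int                      # 0-based offset in the parent
    motif_positions: list            # 1-based positions matching the motif

    def __post_init__(self):
        for p in self.motif_positions:
            if not (1 <= p <= len(self.sequence)):
                raise ValueError("motif position outside the mature peptide")


@dataclass
class PeptideCluster:
    cluster_id: str
    member_ids: list
    alignment: list = field(default_factory=list)   # [(id, aligned seq)]
    consensus: str = ""


@dataclass
class ProfileModel:
    """Position log-odds matrix in bits, with provenance."""

    log_odds: np.ndarray             # (length, 20)
    frequencies: np.ndarray          # (length, 20), rows sum to 1
    background: np.ndarray
    alpha: float

    @property
    def length(self) -> int:
        return self.log_odds.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(AA[j] for j in np.argmax(self.log_odds, axis=1))

    def score(self, window: str) -> float:
        if len(window) != self.length:
            raise ValueError("window length does not match the profile")
        return float(sum(
            self.log_odds[i, AA_INDEX[c]]
            for i, c in enumerate(window) if c in AA_INDEX
        ))

    def to_json(self) -> str:
        return json.dumps(
            {
                "alphabet": AA,
                "alpha": self.alpha,
                "background": self.background.tolist(),
                "log_odds": np.round(self.log_odds, 6).tolist(),
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "ProfileModel":
        d = json.loads(text)
        bg = np.asarray(d["background"])
        lo = np.asarray(d["log_odds"])
        return cls(log_odds=lo, frequencies=np.power(2.0, lo) * bg,
                   background=bg, alpha=d["alpha"])


@dataclass
class MotifSummary:
    frequencies: np.ndarray          # (length, 20)
    information: np.ndarray          # bits per position
    fraction_sxs: float
    fraction_sxt: float


# ---------------------------------------------------------------------------
# Clustering and alignment
# ---------------------------------------------------------------------------

def cluster_precursors(
    records,
    identity_min: float = 0.45,
    min_alignment_length: int = 20,
    evalue_max: float = 1e-3,
) -> list:
    """Single-linkage components of the pairwise local-identity graph.

    A pair is an edge iff its optimal local alignment is both significant
    (Karlin-Altschul E-value < ``evalue_max``) and similar (identities /
    max(alignment length, ``min_alignment_length``) >= ``identity_min``).
    The significance gate removes the short, chance local hits that any
    two unrelated sequences share and that would otherwise chain
    single-linkage components together.  Clusters are numbered by their
    smallest member id.
    """
    records = list(records)
    n = len(records)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = records[i].sequence, records[j].sequence
            e = evalue(local_score(a, b), len(a), len(b))
            if e >= evalue_max:
                continue
            ident = local_identity(a, b, min_length=min_alignment_length)
            if ident >= identity_min:
                parent[find(i)] = find(j)

    groups = {}
    for i, rec in enumerate(records):
        groups.setdefault(find(i), []).append(rec.id)
    ordered = sorted(groups.values(), key=lambda ids: min(ids))
    return [
        PeptideCluster(cluster_id=f"cluster{k:03d}", member_ids=sorted(ids))
        for k, ids in enumerate(ordered)
    ]


def align_cluster(cluster: PeptideCluster, sequences: dict) -> PeptideCluster:
    """Center-star multiple alignment of a cluster.

    The center is the member maximising its summed global pairwise score
    to all others (ties by smallest id); every member is aligned to the
    center and gaps are merged column-wise ("once a gap, always a gap").
    """
    ids = cluster.member_ids
    if not ids:
        raise ValueError("cannot align an empty cluster")
    if len(ids) == 1:
        aln = [(ids[0], sequences[ids[0]])]
        return PeptideCluster(cluster.cluster_id, ids, aln,
                              consensus=sequences[ids[0]])
    aligner = make_aligner("global")
    totals = {
        a: sum(aligner.score(sequences[a], sequences[b])
               for b in ids if b != a)
        for a in ids
    }
    center = min(ids, key=lambda a: (-totals[a], a))

    center_seq = sequences[center]
    pair_alns = {}
    for other in ids:
        if other == center:
            continue
        aln = aligner.align(center_seq, sequences[other])[0]
        pair_alns[other] = (str(aln[0]), str(aln[1]))

    # merged gap pattern for the center: number of gap columns after each
    # center position (index 0 = before the first residue)
    n = len(center_seq)
    gaps_after = [0] * (n + 1)
    for ca, _ in pair_alns.values():
        pos, run = 0, 0
        local = [0] * (n + 1)
        for ch in ca:
            if ch == "-":
                run += 1
            else:
                local[pos] = max(local[pos], run)
                run = 0
                pos += 1
        local[n] = max(local[n], run)
        for i in range(n + 1):
            gaps_after[i] = max(gaps_after[i], local[i])

    rows = {}
    plain_center = "-" * gaps_after[0] + "".join(
        c + "-" * gaps_after[i + 1] for i, c in enumerate(center_seq)
    )
    rows[center] = plain_center
    for other, (ca, co) in pair_alns.items():
        # re-insert the merged gaps into this pairwise alignment
        projected = []
        gap_budget = list(gaps_after)
        cur = 0
        for ch_c, ch_o in zip(ca, co):
            if ch_c == "-":
                projected.append(ch_o)
                gap_budget[cur] -= 1
            else:
                projected.append("-" * gap_budget[cur])
                projected.append(ch_o)
                cur += 1
        projected.append("-" * gap_budget[cur])
        rows[other] = "".join(projected)

    width = len(plain_center)
    alignment = [(i, rows[i]) for i in ids]
    for _, row in alignment:
        assert len(row) == width, "center-star merge produced ragged rows"
    consensus = _alignment_consensus(alignment)
    return PeptideCluster(cluster.cluster_id, ids, alignment, consensus)


def _alignment_consensus(alignment) -> str:
    width = len(alignment[0][1])
    out = []
    for j in range(width):
        col = [row[j] for _, row in alignment if row[j] != "-"]
        if not col:
            out.append("-")
            continue
        vals, counts = np.unique(col, return_counts=True)
        out.append(sorted(zip(-counts, vals))[0][1])
    return "".join(out)


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def build_profile(
    alignment, alpha: float = 1.0, background: np.ndarray | None = None
) -> ProfileModel:
    """PSSM from an alignment: per-position frequencies
    (counts + alpha*background) / (n + alpha), log-odds in bits."""
    if background is None:
        background = BACKGROUND
    rows = [row for _, row in alignment] if not isinstance(
        alignment[0], str) else list(alignment)
    width = len(rows[0])
    freqs = np.zeros((width, 20))
    for j in range(width):
        col = [row[j] for row in rows if row[j] not in ("-", "X")]
        if not col:
            raise ValueError(f"alignment column {j} contains only gaps")
        counts = np.zeros(20)
        for c in col:
            counts[AA_INDEX[c]] += 1
        freqs[j] = (counts + alpha * background) / (len(col) + alpha)
    if alpha == 0 and np.any(freqs == 0):
        # indicator profile: unobserved residues get -inf log-odds replaced
        # by a large finite penalty to keep entries finite
        with np.errstate(divide="ignore"):
            lo = np.log2(freqs / background)
        lo[np.isneginf(lo)] = -30.0
    else:
        lo = np.log2(freqs / background)
    return ProfileModel(log_odds=lo, frequencies=freqs,
                        background=np.asarray(background), alpha=alpha)


def mature_window_profile(
    cluster: PeptideCluster,
    length: int = 13,
    alpha: float = 1.0,
    motif_columns: dict | None = None,
    motif_min_fraction: float = 0.9,
) -> tuple:
    """Locate the mature window of a cluster alignment and build its PSSM.

    Candidate windows are the ``length``-column stretches whose fixed
    motif positions are conserved: at each constrained position (default
    S at mature position 5 and S-or-T at position 7, mirroring the
    SxS/SxT anchor), at least ``motif_min_fraction`` of the non-gap
    residues must belong to the allowed set.  Among candidates, the
    window maximising summed per-column information content wins; if no
    window satisfies the motif (e.g. motif-free families), the
    information criterion alone decides.  Returns (profile, start column).
    """
    if motif_columns is None:
        motif_columns = {5: "S", 7: "ST"}
    rows = [row for _, row in cluster.alignment]
    width = len(rows[0])
    if width < length:
        raise ValueError("alignment shorter than the mature window")
    ic = np.empty(width)
    col_residues = []
    for j in range(width):
        col = [row[j] for row in rows if row[j] not in ("-", "X")]
        col_residues.append(col)
        if not col:
            ic[j] = -np.inf
            continue
        counts = np.zeros(20)
        for c in col:
            counts[AA_INDEX[c]] += 1
        p = counts / counts.sum()
        nz = p[p > 0]
        ic[j] = MAX_IC + float(np.sum(nz * np.log2(nz)))

    def motif_ok(s):
        for pos, allowed in motif_columns.items():
            col = col_residues[s + pos - 1]
            if not col:
                return False
            frac = sum(1 for c in col if c in allowed) / len(col)
            if frac < motif_min_fraction:
                return False
        return True

    starts = range(width - length + 1)
    sums = {s: ic[s : s + length].sum() for s in starts}
    candidates = [s for s in starts if motif_ok(s)] or list(starts)
    start = min(candidates, key=lambda s: (-sums[s], s))
    window_alignment = [(i, row[start : start + length])
                        for i, row in cluster.alignment]
    return build_profile(window_alignment, alpha=alpha), start


# ---------------------------------------------------------------------------
# Scanning and extraction
# ---------------------------------------------------------------------------

def scan_proteome(profile: ProfileModel, proteome, bitscore_min: float):
    """Sliding-window profile scores over every protein.

    ``proteome`` is an iterable of (id, sequence).  Hits with score >=
    ``bitscore_min`` are returned as (id, offset, score), sorted by score
    descending then (id, offset).
    """
    hits = []
    L = profile.length
    for pid, seq in proteome:
        for off in range(0, len(seq) - L + 1):
            s = profile.score(seq[off : off + L])
            if s >= bitscore_min:
                hits.append((pid, off, s))
    hits.sort(key=lambda h: (-h[2], h[0], h[1]))
    return hits


def extract_mature_peptide(
    record: PrecursorRecord,
    profile: ProfileModel,
    motif: str = "S.S",
    motif_start: int = 5,
) -> MaturePeptide:
    """The profile-optimal window of the precursor (window length = profile
    length, 13-15); ties broken by the smallest offset.  Motif positions
    are populated by matching the configured motif at its fixed mature
    positions."""
    L = profile.length
    if not (13 <= L <= 15):
        raise ValueError("profile length must be within the 13..15 bounds")
    if len(record.sequence) < L:
        raise ValueError(
            f"{record.id}: precursor shorter than the mature length {L}"
        )
    best_off, best_score = 0, -np.inf
    for off in range(0, len(record.sequence) - L + 1):
        s = profile.score(record.sequence[off : off + L])
        if s > best_score:
            best_off, best_score = off, s
    window = record.sequence[best_off : best_off + L]
    motif_positions = [
        motif_start + i
        for i, ch in enumerate(motif)
        if ch not in (".", "x") and window[motif_start - 1 + i] == ch
    ]
    return MaturePeptide(parent_id=record.id, sequence=window,
                         offset=best_off, motif_positions=motif_positions)


# ---------------------------------------------------------------------------
# Motif statistics
# ---------------------------------------------------------------------------

def motif_statistics(peptides, alpha: float = 0.0) -> MotifSummary:
    """Per-position frequencies/information content of equal-length mature
    peptides, plus the fractions carrying S at positions 5 and 7 (SxS) or
    S at 5 and T at 7 (SxT)."""
    seqs = [p.sequence if isinstance(p, MaturePeptide) else p
            for p in peptides]
    if not seqs:
        raise ValueError("no peptides given")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("peptides must share one mature length")
    freqs = np.zeros((length, 20))
    for j in range(length):
        counts = np.zeros(20)
        for s in seqs:
            if s[j] in AA_INDEX:
                counts[AA_INDEX[s[j]]] += 1
        freqs[j] = (counts + alpha * BACKGROUND) / (counts.sum() + alpha)
    info = np.empty(length)
    for j in range(length):
        nz = freqs[j][freqs[j] > 0]
        info[j] = MAX_IC + float(np.sum(nz * np.log2(nz)))
    info = np.clip(info, 0.0, MAX_IC)
    n = len(seqs)
    sxs = sum(1 for s in seqs if len(s) >= 7 and s[4] == "S" and s[6] == "S")
    sxt = sum(1 for s in seqs if len(s) >= 7 and s[4] == "S" and s[6] == "T")
    return MotifSummary(frequencies=freqs, information=info,
                        fraction_sxs=sxs / n, fraction_sxt=sxt / n)
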