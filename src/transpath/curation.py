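"""Dataset curation rules and contact-type statistics.

Implements the multi-state (MS) / single-state (SS) selection rules used to
build two-state protein datasets, the four-way classification of
conformational transitions, and residue-contact frequency statistics:

* an MS pair requires sequence identity > 90 %, best-fit Calpha RMSD > 0.5 nm
  (terminal loops excluded) and longest alignment gap < 21 residues;
* an SS cluster representative requires > 5 members whose largest pairwise
  RMSD is < 0.2 nm (the shortest sequence is kept);
* transitions are Category IV if > 5 mapped residues swap between helix and
  strand, Category III if > 5 residues melt from helix/strand to coil, and
  otherwise Category I (inter-domain rigid-body motion) or II (intra-domain
  rearrangement), separated by a rigid-block heuristic on the
  distance-difference matrix;
* contact-type frequencies F_pq over the 210 unordered residue-type pairs,
  the MS/SS frequency ratio R_pq = 2 F_MS / (F_MS + F_SS), and the
  changed-contact frequency counting pairs whose Calpha distance shifts by
  at least 0.5 nm between the two states.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from .constants import AA_ORDER
from .structio import CaStructure, StatePair, superpose_rmsd

__all__ = [
    "PairDecision",
    "TransitionCategory",
    "ContactTypeStats",
    "CONTACT_TYPES",
    "sequence_identity",
    "longest_gap",
    "trimmed_map",
    "evaluate_ms_pair",
    "evaluate_ss_cluster",
    "classify_transition",
    "contact_frequency",
    "ms_frequency_ratio",
    "changed_contact_frequency",
    "write_stats_table",
]

#: All 210 unordered residue-type pairs, canonically sorted one-letter codes.
CONTACT_TYPES = tuple(
    tuple(sorted(pq))
    for pq in itertools.combinations_with_replacement(AA_ORDER, 2)
)

# MS rule thresholds
MS_MIN_IDENTITY = 0.90
MS_MIN_RMSD_NM = 0.5
MS_MAX_GAP = 21
MIN_SEQ_LENGTH = 50

# SS cluster rule
SS_MIN_MEMBERS = 5          # strictly more than this
SS_MAX_RMSD_NM = 0.2

# contact distance window for frequency counting (3 A .. 10 A)
CONTACT_RANGE_NM = (0.3, 1.0)

# changed-contact threshold (5 A)
CHANGED_CONTACT_NM = 0.5

# category III / IV residue-count threshold (strictly more than)
CATEGORY_THRESHOLD = 5


@dataclass(frozen=True)
class PairDecision:
    """Outcome of the multi-state pair rules for one structure pair."""

    is_ms: bool
    seq_identity: float
    rmsd_nm: float
    longest_gap: int
    reasons: tuple = ()


@dataclass(frozen=True)
class TransitionCategory:
    """Four-way classification of a conformational transition."""

    category: str  # one of I, II, III, IV
    n_fold_to_loop: int
    n_helix_sheet_swap: int
    rationale: str = ""

    def __post_init__(self):
        if self.category not in {"I", "II", "III", "IV"}:
            raise ValueError("category must be one of I, II, III, IV")
        if self.category == "III" and not self.n_fold_to_loop > CATEGORY_THRESHOLD:
            raise ValueError("category III requires > 5 fold-to-loop residues")
        if self.category == "IV" and not self.n_helix_sheet_swap > CATEGORY_THRESHOLD:
            raise ValueError("category IV requires > 5 helix<->sheet residues")


@dataclass(frozen=True)
class ContactTypeStats:
    """Per-contact-type frequencies over a dataset (210 unordered types)."""

    F: dict
    n_proteins: int
    kind: str  # MS, SS or changed
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if set(self.F) != set(CONTACT_TYPES):
            raise ValueError("F must contain exactly the 210 contact types")
        if any(v < 0 for v in self.F.values()):
            raise ValueError("frequencies must be non-negative")


# ---------------------------------------------------------------------------
# sequence / alignment helpers
# ---------------------------------------------------------------------------

def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1.0
    al.mismatch_score = 0.0
    al.open_gap_score = -10.0
    al.extend_gap_score = -0.5
    return al


def sequence_identity(seq_a: str, seq_b: str) -> float:
    """Identity fraction over aligned columns of a global alignment.

    Identity-matrix scoring with affine gaps (open 10, extend 0.5); the
    fraction is matches / total alignment columns (gap columns included).
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    aln = _aligner().align(seq_a, seq_b)[0]
    a, b = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return matches / len(a)


def make_state_pair(state_a: CaStructure, state_b: CaStructure,
                    protein_id: str | None = None) -> StatePair:
    """Build a StatePair by globally aligning the two sequences.

    Aligned columns with identical residues become the residue map;
    mismatched columns are recorded as substitutions.
    """
    aln = _aligner().align(state_a.sequence, state_b.sequence)[0]
    rmap, subs = [], []
    ia = ib = 0
    for x, y in zip(str(aln[0]), str(aln[1])):
        if x != "-" and y != "-":
            rmap.append((ia, ib))
            if x != y:
                subs.append((ia, ib))
        if x != "-":
            ia += 1
        if y != "-":
            ib += 1
    return StatePair(
        protein_id=protein_id or state_a.id,
        state_a=state_a, state_b=state_b,
        residue_map=tuple(rmap), substitutions=tuple(subs),
    )


def longest_gap(pair: StatePair) -> int:
    """Longest run of unmapped residues between mapped positions."""
    if not pair.residue_map:
        raise ValueError("residue_map is empty")
    ia, ib = pair.mapped_a, pair.mapped_b
    gaps = [0]
    gaps.extend((np.diff(ia) - 1).tolist())
    gaps.extend((np.diff(ib) - 1).tolist())
    return int(max(gaps))


def trimmed_map(pair: StatePair) -> tuple[np.ndarray, np.ndarray]:
    """Mapped index arrays with terminal loops trimmed.

    When both states carry secondary structure, mapped pairs are dropped
    from either end while either state's code is 'C'; otherwise the map is
    used as-is (unmapped terminal residues are excluded by construction).
    At least 3 residues are always retained.
    """
    ia, ib = pair.mapped_a, pair.mapped_b
    ssa, ssb = pair.state_a.ss, pair.state_b.ss
    if ssa is not None and ssb is not None:
        lo, hi = 0, len(ia)
        while hi - lo > 3 and (ssa[ia[lo]] == "C" or ssb[ib[lo]] == "C"):
            lo += 1
        while hi - lo > 3 and (ssa[ia[hi - 1]] == "C" or ssb[ib[hi - 1]] == "C"):
            hi -= 1
        ia, ib = ia[lo:hi], ib[lo:hi]
    return ia, ib


# ---------------------------------------------------------------------------
# MS / SS rules
# ---------------------------------------------------------------------------

def evaluate_ms_pair(pair: StatePair) -> PairDecision:
    """Apply the three multi-state rules to a structure pair.

    is_ms is true iff identity > 0.90, trimmed best-fit RMSD > 0.5 nm and the
    longest alignment gap is < 21 residues.
    """
    if not pair.residue_map:
        raise ValueError("residue_map is empty")
    if min(len(pair.state_a), len(pair.state_b)) <= MIN_SEQ_LENGTH:
        raise ValueError(
            f"dataset rule requires sequence length > {MIN_SEQ_LENGTH}"
        )
    ident = sequence_identity(pair.state_a.sequence, pair.state_b.sequence)
    ia, ib = trimmed_map(pair)
    rmsd = superpose_rmsd(pair.state_a.coords[ia], pair.state_b.coords[ib])
    gap = longest_gap(pair)

    reasons = []
    ok_ident = ident > MS_MIN_IDENTITY
    ok_rmsd = rmsd > MS_MIN_RMSD_NM
    ok_gap = gap < MS_MAX_GAP
    reasons.append(f"identity {ident:.3f} {'>' if ok_ident else '<='} "
                   f"{MS_MIN_IDENTITY} -> {'pass' if ok_ident else 'fail'}")
    reasons.append(f"rmsd {rmsd:.3f} nm {'>' if ok_rmsd else '<='} "
                   f"{MS_MIN_RMSD_NM} -> {'pass' if ok_rmsd else 'fail'}")
    reasons.append(f"gap {gap} {'<' if ok_gap else '>='} {MS_MAX_GAP} "
                   f"-> {'pass' if ok_gap else 'fail (gap)'}")
    return PairDecision(
        is_ms=bool(ok_ident and ok_rmsd and ok_gap),
        seq_identity=float(ident),
        rmsd_nm=float(rmsd),
        longest_gap=gap,
        reasons=tuple(reasons),
    )


def evaluate_ss_cluster(structures) -> CaStructure | None:
    """Pick the single-state representative of a sequence cluster, if any.

    Returns the shortest-sequence member iff the cluster has more than five
    members and the largest pairwise best-fit RMSD is below 0.2 nm; otherwise
    None.  RMSD between members of unequal length is computed over the
    leading ``min(len)`` residues.
    """
    structures = list(structures)
    if not structures:
        raise ValueError("empty cluster")
    if len(structures) <= SS_MIN_MEMBERS:
        return None
    for sa, sb in itertools.combinations(structures, 2):
        n = min(len(sa), len(sb))
        if superpose_rmsd(sa.coords[:n], sb.coords[:n]) >= SS_MAX_RMSD_NM:
            return None
    return min(structures, key=lambda s: len(s))


# ---------------------------------------------------------------------------
# transition classification
# ---------------------------------------------------------------------------

def classify_transition(pair: StatePair,
                        rigid_threshold_nm: float = 0.2,
                        min_block_size: int = 30) -> TransitionCategory:
    """Classify a transition into Categories I-IV.

    Category IV (helix <-> strand swap) is checked first, then III
    (helix/strand -> coil melting); otherwise I and II are separated by a
    rigid-block heuristic: residues are greedily clustered into blocks whose
    internal distance changes stay below ``rigid_threshold_nm``, and the
    transition is Category I iff at least two blocks of ``min_block_size``
    residues move relative to each other.
    """
    ssa, ssb = pair.state_a.ss, pair.state_b.ss
    if ssa is None or ssb is None:
        raise ValueError(
            "classification requires secondary-structure strings on both "
            "states; supply ss when constructing the structures"
        )
    ia, ib = pair.mapped_a, pair.mapped_b
    a_codes = np.array([ssa[i] for i in ia])
    b_codes = np.array([ssb[i] for i in ib])

    swap = int(np.sum(((a_codes == "H") & (b_codes == "E"))
                      | ((a_codes == "E") & (b_codes == "H"))))
    to_loop = int(np.sum((np.isin(a_codes, ["H", "E"]) & (b_codes == "C"))
                         | ((a_codes == "C") & np.isin(b_codes, ["H", "E"]))))

    if swap > CATEGORY_THRESHOLD:
        return TransitionCategory(
            "IV", to_loop, swap,
            rationale=f"{swap} residues alternate between helix and strand",
        )
    if to_loop > CATEGORY_THRESHOLD:
        return TransitionCategory(
            "III", to_loop, swap,
            rationale=f"{to_loop} residues melt to or fold from loop",
        )

    blocks = _rigid_blocks(pair, rigid_threshold_nm)
    big = [b for b in blocks if len(b) >= min_block_size]
    if len(big) >= 2:
        return TransitionCategory(
            "I", to_loop, swap,
            rationale=f"{len(big)} rigid blocks of >= {min_block_size} "
                      "residues move relative to each other",
        )
    return TransitionCategory(
        "II", to_loop, swap,
        rationale="structural rearrangement confined within one rigid block",
    )


def _rigid_blocks(pair: StatePair, threshold_nm: float) -> list[list[int]]:
    """Greedy clustering of mapped residues into rigid blocks.

    Two residues belong to the same block only if the change in their mutual
    distance between the states is below the threshold for every member.
    """
    ca, cb = pair.mapped_coords()
    da = np.linalg.norm(ca[:, None] - ca[None, :], axis=-1)
    db = np.linalg.norm(cb[:, None] - cb[None, :], axis=-1)
    delta = np.abs(da - db)
    n = len(ca)
    blocks: list[list[int]] = []
    for i in range(n):
        for block in blocks:
            if np.all(delta[i, block] < threshold_nm):
                block.append(i)
                break
        else:
            blocks.append([i])
    return blocks


# ---------------------------------------------------------------------------
# contact-type statistics
# ---------------------------------------------------------------------------

def _zero_stats() -> dict:
    return {pq: 0.0 for pq in CONTACT_TYPES}


def _single_structure_frequencies(seq: str, coords: np.ndarray) -> dict:
    """F_pq contributions of one structure: N_pq / (N_p * N_q)."""
    lo, hi = CONTACT_RANGE_NM
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    iu, ju = np.triu_indices(len(seq), k=1)
    sel = (d[iu, ju] > lo) & (d[iu, ju] < hi)
    counts: dict = {}
    for i, j in zip(iu[sel], ju[sel]):
        key = tuple(sorted((seq[i], seq[j])))
        counts[key] = counts.get(key, 0) + 1
    n_type = {aa: seq.count(aa) for aa in set(seq)}
    out = _zero_stats()
    for (p, q), npq in counts.items():
        if (p, q) not in out:
            continue  # non-standard residue types are skipped
        denom = n_type.get(p, 0) * n_type.get(q, 0)
        if denom > 0:
            out[(p, q)] = npq / denom
    return out


def contact_frequency(dataset, kind: str = "MS") -> ContactTypeStats:
    """Per-type contact frequencies F_pq averaged over a dataset.

    Contacts are unordered residue pairs whose Calpha separation lies in
    (0.3 nm, 1.0 nm); each protein contributes N_pq / (N_p N_q) and the
    dataset average is taken.  For :class:`StatePair` entries both states
    are counted and their contributions averaged (pooled two-state counting).
    A protein lacking residue type p or q contributes 0 for that type.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty dataset")
    acc = _zero_stats()
    for entry in dataset:
        if isinstance(entry, StatePair):
            ia, ib = entry.mapped_a, entry.mapped_b
            seq = "".join(entry.state_a.sequence[i] for i in ia)
            fa = _single_structure_frequencies(seq, entry.state_a.coords[ia])
            fb = _single_structure_frequencies(seq, entry.state_b.coords[ib])
            contrib = {pq: 0.5 * (fa[pq] + fb[pq]) for pq in CONTACT_TYPES}
        else:
            contrib = _single_structure_frequencies(entry.sequence, entry.coords)
        for pq in CONTACT_TYPES:
            acc[pq] += contrib[pq]
    n = len(dataset)
    return ContactTypeStats(
        F={pq: v / n for pq, v in acc.items()},
        n_proteins=n,
        kind=kind,
        metadata={"contact_range_nm": CONTACT_RANGE_NM,
                  "two_state_counting": "both states pooled (averaged)"},
    )


def ms_frequency_ratio(f_ms: ContactTypeStats,
                       f_ss: ContactTypeStats) -> dict:
    """Frequency ratio R_pq = 2 F_MS / (F_MS + F_SS) in [0, 2].

    Types absent from both datasets are reported as NaN (missing), not 0.
    """
    out = {}
    for pq in CONTACT_TYPES:
        ms, ss = f_ms.F[pq], f_ss.F[pq]
        out[pq] = 2.0 * ms / (ms + ss) if (ms + ss) > 0 else float("nan")
    return out


def changed_contact_frequency(dataset) -> ContactTypeStats:
    """Frequency of contact types that form or break between the two states.

    A pair counts as *new* if its Calpha distance in state B is at least
    0.5 nm shorter than in state A and as *broken* if at least 0.5 nm longer;
    both are pooled.  Normalization mirrors the plain contact frequency
    (per-protein N'_pq / (N_p N_q), averaged over proteins).
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty dataset")
    acc = _zero_stats()
    for pair in dataset:
        ia, ib = pair.mapped_a, pair.mapped_b
        seq = "".join(pair.state_a.sequence[i] for i in ia)
        ca, cb = pair.state_a.coords[ia], pair.state_b.coords[ib]
        da = np.linalg.norm(ca[:, None] - ca[None, :], axis=-1)
        db = np.linalg.norm(cb[:, None] - cb[None, :], axis=-1)
        iu, ju = np.triu_indices(len(seq), k=1)
        dd = db[iu, ju] - da[iu, ju]
        sel = np.abs(dd) >= CHANGED_CONTACT_NM
        counts: dict = {}
        for i, j in zip(iu[sel], ju[sel]):
            key = tuple(sorted((seq[i], seq[j])))
            counts[key] = counts.get(key, 0) + 1
        n_type = {aa: seq.count(aa) for aa in set(seq)}
        for (p, q), npq in counts.items():
            if (p, q) not in acc:
                continue
            denom = n_type.get(p, 0) * n_type.get(q, 0)
            if denom > 0:
                acc[(p, q)] += npq / denom
    n = len(dataset)
    return ContactTypeStats(
        F={pq: v / n for pq, v in acc.items()},
        n_proteins=n,
        kind="changed",
        metadata={
            "changed_threshold_nm": CHANGED_CONTACT_NM,
            "normalization": "mirrors plain contact frequency "
                             "(N'_pq / (N_p N_q), averaged over proteins)",
        },
    )


def write_stats_table(path, f_ms=None, f_ss=None, ratio=None, f_changed=None):
    """Write the 210-row contact-type statistics table as TSV."""
    rows = []
    for pq in CONTACT_TYPES:
        rows.append({
            "type": "-".join(pq),
            "F_ms": f_ms.F[pq] if f_ms else float("nan"),
            "F_ss": f_ss.F[pq] if f_ss else float("nan"),
            "R": ratio[pq] if ratio else float("nan"),
            "F_changed": f_changed.F[pq] if f_changed else float("nan"),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
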