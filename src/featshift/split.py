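"""Homology-aware train/validation/test splitting at the sequence-cluster level.

Splitting whole clusters of similar sequences into the same partition keeps
near-homologs out of opposite splits, so held-out performance reflects
generalisation to unseen proteins rather than sequence memorisation.  Cluster
assignments are normally produced externally (MMseqs2 ``createtsv`` output is
read directly); a simplified greedy k-mer-identity clusterer is bundled so the
full pipeline runs with no external binary.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotations import ProteinRecord

__all__ = [
    "ClusterAssignment",
    "SplitAssignment",
    "read_cluster_tsv",
    "write_cluster_tsv",
    "greedy_cluster",
    "split_by_cluster",
    "write_split_tsv",
    "read_split_tsv",
]

SPLIT_NAMES = ("train", "validation", "test")


@dataclasses.dataclass(frozen=True)
class ClusterAssignment:
    """One sequence cluster: a representative id and its member set."""

    cluster_id: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"cluster {self.cluster_id!r} has no members")


@dataclasses.dataclass(frozen=True)
class SplitAssignment:
    """Protein id → split name mapping, with the seed and targets that made it."""

    assignment: Mapping[str, str]
    seed: int
    target_fractions: tuple[float, float, float]

    def ids_in(self, split: str) -> list[str]:
        return sorted(pid for pid, s in self.assignment.items() if s == split)

    def achieved_fractions(self) -> dict[str, float]:
        total = len(self.assignment)
        return {
            name: sum(1 for s in self.assignment.values() if s == name) / total
            for name in SPLIT_NAMES
        }


def read_cluster_tsv(path: str | Path) -> list[ClusterAssignment]:
    """Read a two-column ``representative_id<TAB>member_id`` cluster TSV.

    This is the dialect MMseqs2's ``createtsv`` emits: one row per member,
    with the representative appearing as its own member.  A member listed
    under two representatives violates the partition property and is an error.
    """
    members: dict[str, set[str]] = defaultdict(set)
    owner: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path} line {lineno}: expected 2 columns")
            rep, member = parts
            if member in owner and owner[member] != rep:
                raise ValueError(
                    f"{path} line {lineno}: member {member!r} appears under both "
                    f"{owner[member]!r} and {rep!r}"
                )
            owner[member] = rep
            members[rep].add(member)
    for rep in members:
        members[rep].add(rep)  # representative is itself a member
    return [
        ClusterAssignment(rep, frozenset(ms)) for rep, ms in sorted(members.items())
    ]


def write_cluster_tsv(clusters: Iterable[ClusterAssignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for cluster in sorted(clusters, key=lambda c: c.cluster_id):
            for member in sorted(cluster.members):
                fh.write(f"{cluster.cluster_id}\t{member}\n")


# ---------------------------------------------------------------------------
# Greedy fallback clusterer
# ---------------------------------------------------------------------------

def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    pos: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        pos[seq[i : i + k]].append(i)
    return pos


def _ungapped_identity(query: str, target: str, target_kmers: dict[str, list[int]],
                       k: int) -> tuple[float, float]:
    """Best ungapped identity/coverage between two sequences, k-mer seeded.

    Shared k-mers vote for diagonals (offset = query position − target
    position); the best-supported diagonal is scored by exact per-residue
    identity over the overlap.  Coverage is the overlap length relative to the
    shorter sequence.  Returns (identity, coverage); (0, 0) if no seed.
    """
    votes: dict[int, int] = defaultdict(int)
    for i in range(len(query) - k + 1):
        kmer = query[i : i + k]
        for j in target_kmers.get(kmer, ()):
            votes[i - j] += 1
    if not votes:
        return 0.0, 0.0
    # deterministic tie-break: most votes, then smallest |offset|, then offset
    offset = min(votes, key=lambda d: (-votes[d], abs(d), d))
    q_start = max(0, offset)
    t_start = max(0, -offset)
    overlap = min(len(query) - q_start, len(target) - t_start)
    if overlap <= 0:
        return 0.0, 0.0
    matches = sum(
        1 for a, b in zip(query[q_start : q_start + overlap],
                          target[t_start : t_start + overlap]) if a == b
    )
    # normalise identity by the shorter sequence, not the overlap: seeded
    # overlaps are short, and per-overlap identity would overestimate
    # similarity between unrelated sequences
    shorter = min(len(query), len(target))
    identity = matches / shorter
    coverage = overlap / shorter
    return identity, coverage


def greedy_cluster(
    proteins: Sequence[ProteinRecord],
    identity_threshold: float = 0.2,
    coverage_threshold: float = 0.2,
    k: int = 3,
) -> list[ClusterAssignment]:
    """Greedy incremental sequence clustering (simplified MMseqs2 stand-in).

    Proteins are visited by descending length (id as tie-break); each joins
    the first existing representative whose k-mer-seeded ungapped identity
    estimate reaches ``identity_threshold`` with alignment coverage at least
    ``coverage_threshold`` of the shorter sequence, otherwise it founds a new
    cluster.  Deterministic given the input set.
    """
    if not (0 < identity_threshold <= 1 and 0 < coverage_threshold <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    ordered = sorted(proteins, key=lambda p: (-p.length, p.id))
    reps: list[ProteinRecord] = []
    rep_kmers: list[dict[str, list[int]]] = []
    members: dict[str, set[str]] = {}
    for protein in ordered:
        placed = False
        for rep, kmers in zip(reps, rep_kmers):
            identity, coverage = _ungapped_identity(protein.sequence, rep.sequence,
                                                    kmers, k)
            if identity >= identity_threshold and coverage >= coverage_threshold:
                members[rep.id].add(protein.id)
                placed = True
                break
        if not placed:
            reps.append(protein)
            rep_kmers.append(_kmer_positions(protein.sequence, k))
            members[protein.id] = {protein.id}
    return [ClusterAssignment(rep, frozenset(ms)) for rep, ms in members.items()]


# ---------------------------------------------------------------------------
# Cluster-level splitting
# ---------------------------------------------------------------------------

def split_by_cluster(
    clusters: Sequence[ClusterAssignment],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> SplitAssignment:
    """Assign whole clusters to train/validation/test, balancing protein counts.

    Clusters are shuffled with ``seed``, ordered largest-first (cluster_id as
    the deterministic tie-break), then each is assigned to the split whose
    protein-count deficit relative to its target is currently largest; deficit
    ties go to the earlier split in (train, validation, test) order.  Fractions
    are measured in proteins, so the achieved fractions land within
    ±(largest cluster)/(total proteins) of the targets.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    if any(f < 0 for f in fractions):
        raise ValueError("fractions must be non-negative")
    all_ids = [pid for c in clusters for pid in c.members]
    if len(all_ids) != len(set(all_ids)):
        raise ValueError("clusters are not disjoint")
    total = len(all_ids)
    if total == 0:
        return SplitAssignment({}, seed, tuple(fractions))
    if len(clusters) == 1:
        warnings.warn("single cluster contains every protein; all go to train")
        return SplitAssignment(
            {pid: "train" for pid in clusters[0].members}, seed, tuple(fractions)
        )

    # Canonical order first so the shuffle depends only on (seed, cluster set),
    # then a stable size sort: equal-size clusters keep their shuffled order.
    order = sorted(clusters, key=lambda c: c.cluster_id)
    rng = np.random.default_rng(seed)
    rng.shuffle(order)
    order.sort(key=lambda c: -len(c.members))

    targets = [f * total for f in fractions]
    counts = [0, 0, 0]
    assignment: dict[str, str] = {}
    for cluster in order:
        deficits = [targets[i] - counts[i] for i in range(3)]
        best = max(range(3), key=lambda i: (deficits[i], -i))
        for pid in cluster.members:
            assignment[pid] = SPLIT_NAMES[best]
        counts[best] += len(cluster.members)
    return SplitAssignment(assignment, seed, tuple(fractions))


def write_split_tsv(split: SplitAssignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tsplit\n")
        for pid in sorted(split.assignment):
            fh.write(f"{pid}\t{split.assignment[pid]}\n")


def read_split_tsv(path: str | Path) -> dict[str, str]:
    assignment: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["protein_id", "split"]:
            raise ValueError(f"{path}: expected header protein_id/split")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            pid, split_name = line.split("\t")[:2]
            if split_name not in SPLIT_NAMES:
                raise ValueError(f"{path}: invalid split {split_name!r}")
            assignment[pid] = split_name
    return assignment
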