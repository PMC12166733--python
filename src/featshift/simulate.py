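"""Deterministic synthetic data with known ground truth.

Every input format the pipeline consumes can be generated here: protein
families (founder sequences plus mutated copies), per-residue feature
annotations defined by planted sequence motifs, cluster assignments (the
known family map), and labeled variant cohorts with a designed in-feature
pathogenic enrichment.

Motif-defined features make the per-residue label a deterministic function of
local sequence context, so classifier tasks built on these fixtures are
learnable at desk scale by construction.  That is a deliberate simplification:
real protein features are not local sequence grammars, and results on these
fixtures certify the machinery, not biological performance.

All randomness flows from one spec-level seed that fans out to per-component
seeds through fixed offsets, so regenerating one artifact never perturbs the
others.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotations import (AMINO_ACIDS, FeatureAnnotation, LabelTrack,
                          ProteinRecord, VariantRecord, write_fasta,
                          write_feature_table, write_variant_table)
from .split import ClusterAssignment, write_cluster_tsv

__all__ = ["FixtureSpec", "FixtureSet", "generate_proteins",
           "generate_variant_cohort", "generate_fixture_set"]

_SEED_OFFSETS = {"sequences": 1, "noise": 2, "variants": 3}


@dataclasses.dataclass(frozen=True)
class FixtureSpec:
    """Generator parameters; same spec + seed gives byte-identical fixtures."""

    seed: int = 0
    n_proteins: int = 60
    length_range: tuple[int, int] = (80, 160)
    n_families: int = 12
    substitution_rate: float = 0.05
    motif_rules: Mapping[str, tuple[str, ...]] = dataclasses.field(
        default_factory=lambda: {"motif": ("ACA",)})
    plants_per_protein: int = 2
    label_noise_rate: float = 0.0
    n_pathogenic: int = 150
    n_benign: int = 150
    n_vus: int = 50
    p_pathogenic_in: float = 0.8
    p_benign_in: float = 0.2
    p_vus_in: float = 0.5

    def __post_init__(self) -> None:
        for rate in (self.substitution_rate, self.label_noise_rate,
                     self.p_pathogenic_in, self.p_benign_in, self.p_vus_in):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("all rates must lie in [0, 1]")
        if self.length_range[0] > self.length_range[1] or self.length_range[0] < 1:
            raise ValueError("invalid length range")
        for feature, kmers in self.motif_rules.items():
            for kmer in kmers:
                if len(kmer) > self.length_range[0]:
                    raise ValueError(
                        f"motif {kmer!r} longer than the minimum protein length"
                    )

    @property
    def design_odds_ratio(self) -> float:
        """The in-feature enrichment the variant cohort is built to have."""
        p, b = self.p_pathogenic_in, self.p_benign_in
        return (p / (1 - p)) / (b / (1 - b))


@dataclasses.dataclass
class FixtureSet:
    """A full generated dataset plus its ground truth."""

    spec: FixtureSpec
    proteins: list[ProteinRecord]
    annotations: list[FeatureAnnotation]       # post-noise, as a reader sees them
    true_tracks: list[LabelTrack]              # pre-noise ground truth
    families: dict[str, list[str]]             # founder id -> member ids
    variants: list[VariantRecord]
    manifest: dict

    def clusters(self) -> list[ClusterAssignment]:
        return [ClusterAssignment(rep, frozenset(members))
                for rep, members in sorted(self.families.items())]

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Write FASTA / feature TSV / cluster TSV / variant TSV / manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": directory / "proteins.fasta",
            "features": directory / "features.tsv",
            "clusters": directory / "clusters.tsv",
            "variants": directory / "variants.tsv",
            "manifest": directory / "manifest.json",
        }
        write_fasta(self.proteins, paths["fasta"])
        write_feature_table(self.annotations, paths["features"])
        write_cluster_tsv(self.clusters(), paths["clusters"])
        write_variant_table(self.variants, paths["variants"])
        with open(paths["manifest"], "w") as fh:
            json.dump(self.manifest, fh, indent=2)
        return paths


def _scan_motifs(sequence: str, kmers: Sequence[str]) -> np.ndarray:
    """Binary track marking every residue covered by an exact k-mer match."""
    labels = np.zeros(len(sequence), dtype=np.int8)
    for kmer in kmers:
        start = sequence.find(kmer)
        while start != -1:
            labels[start: start + len(kmer)] = 1
            start = sequence.find(kmer, start + 1)
    return labels


def _labels_to_intervals(labels: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous 1-runs as 1-based inclusive (start, end) intervals."""
    intervals = []
    padded = np.concatenate(([0], labels, [0]))
    starts = np.nonzero(np.diff(padded) == 1)[0]
    ends = np.nonzero(np.diff(padded) == -1)[0]
    for s, e in zip(starts, ends):
        intervals.append((int(s) + 1, int(e)))
    return intervals


def generate_proteins(spec: FixtureSpec):
    """Generate protein families with motif-planted feature annotations.

    Returns ``(proteins, annotations, true_tracks, families)``.  Families are
    founders plus point-mutated copies; each feature's residue set on a given
    sequence is exactly the set of positions covered by an exact occurrence
    of one of its motif k-mers in *that* sequence (mutations can destroy or
    create occurrences).  Label noise, when enabled, flips per-residue labels
    in the emitted annotations; ``true_tracks`` always hold the pre-noise
    scan-based truth.
    """
    if spec.n_proteins == 0:
        return [], [], [], {}
    rng = np.random.default_rng([spec.seed, _SEED_OFFSETS["sequences"]])
    noise_rng = np.random.default_rng([spec.seed, _SEED_OFFSETS["noise"]])
    aa = np.array(list(AMINO_ACIDS))

    proteins: list[ProteinRecord] = []
    families: dict[str, list[str]] = {}
    sizes = np.full(spec.n_families, spec.n_proteins // spec.n_families)
    sizes[: spec.n_proteins % spec.n_families] += 1
    idx = 0
    for fam in range(spec.n_families):
        if sizes[fam] == 0:
            continue
        length = int(rng.integers(spec.length_range[0],
                                  spec.length_range[1] + 1))
        founder = rng.choice(aa, size=length)
        for feature, kmers in sorted(spec.motif_rules.items()):
            for _ in range(spec.plants_per_protein):
                kmer = kmers[int(rng.integers(len(kmers)))]
                pos = int(rng.integers(0, length - len(kmer) + 1))
                founder[pos: pos + len(kmer)] = list(kmer)
        founder_id = f"SYN{fam:03d}"
        member_ids = []
        for copy_i in range(int(sizes[fam])):
            seq = founder.copy()
            if copy_i > 0:
                flip = rng.random(length) < spec.substitution_rate
                for j in np.nonzero(flip)[0]:
                    choices = [x for x in AMINO_ACIDS if x != seq[j]]
                    seq[j] = choices[int(rng.integers(len(choices)))]
            pid = founder_id if copy_i == 0 else f"{founder_id}.{copy_i}"
            proteins.append(ProteinRecord(pid, "".join(seq)))
            member_ids.append(pid)
            idx += 1
        families[founder_id] = member_ids

    annotations: list[FeatureAnnotation] = []
    true_tracks: list[LabelTrack] = []
    for protein in proteins:
        for feature, kmers in sorted(spec.motif_rules.items()):
            labels = _scan_motifs(protein.sequence, kmers)
            true_tracks.append(LabelTrack(protein.id, feature, labels.copy(),
                                          np.ones_like(labels)))
            if spec.label_noise_rate > 0:
                flip = noise_rng.random(labels.size) < spec.label_noise_rate
                labels = np.where(flip, 1 - labels, labels).astype(np.int8)
            for start, end in _labels_to_intervals(labels):
                annotations.append(FeatureAnnotation(protein.id, feature,
                                                     start, end))
    return proteins, annotations, true_tracks, families


def generate_variant_cohort(proteins: Sequence[ProteinRecord],
                            true_tracks: Sequence[LabelTrack],
                            spec: FixtureSpec) -> list[VariantRecord]:
    """Labeled variants with a designed in-feature pathogenic enrichment.

    Pathogenic variants land inside feature residues with probability
    ``p_pathogenic_in``, benign with ``p_benign_in`` and VUS with
    ``p_vus_in``; within the chosen stratum positions are drawn uniformly
    (with replacement) over all residues of all proteins.  Alternate amino
    acids are drawn uniformly among the 19 non-reference letters, so an
    in-motif variant destroys its exact-match motif by construction.
    """
    rng = np.random.default_rng([spec.seed, _SEED_OFFSETS["variants"]])
    by_id = {p.id: p for p in proteins}
    in_feature: list[tuple[str, int]] = []
    out_feature: list[tuple[str, int]] = []
    feature_union: dict[str, np.ndarray] = {}
    for track in true_tracks:
        cur = feature_union.setdefault(track.protein_id,
                                       np.zeros(track.length, dtype=np.int8))
        feature_union[track.protein_id] = np.maximum(cur, track.labels)
    for pid, labels in sorted(feature_union.items()):
        seq = by_id[pid].sequence
        for i in range(labels.size):
            if seq[i] == "X":
                continue
            (in_feature if labels[i] else out_feature).append((pid, i + 1))

    plan = (["pathogenic"] * spec.n_pathogenic + ["benign"] * spec.n_benign
            + ["VUS"] * spec.n_vus)
    p_in = {"pathogenic": spec.p_pathogenic_in, "benign": spec.p_benign_in,
            "VUS": spec.p_vus_in}
    variants: list[VariantRecord] = []
    for label in plan:
        inside = rng.random() < p_in[label]
        pool = in_feature if inside else out_feature
        if not pool:
            raise ValueError(
                f"no {'in' if inside else 'out-of'}-feature residues available"
            )
        pid, position = pool[int(rng.integers(len(pool)))]
        ref = by_id[pid].sequence[position - 1]
        choices = [x for x in AMINO_ACIDS if x != ref]
        alt = choices[int(rng.integers(len(choices)))]
        variants.append(VariantRecord(pid, position, ref, alt, label))
    return variants


def generate_fixture_set(spec: FixtureSpec = FixtureSpec()) -> FixtureSet:
    """Generate the complete fixture bundle with its ground-truth manifest."""
    proteins, annotations, true_tracks, families = generate_proteins(spec)
    variants = (generate_variant_cohort(proteins, true_tracks, spec)
                if proteins else [])
    manifest = {
        "seed": spec.seed,
        "n_proteins": len(proteins),
        "lengths": {p.id: p.length for p in proteins},
        "families": families,
        "features": sorted(spec.motif_rules),
        "motif_rules": {k: list(v) for k, v in spec.motif_rules.items()},
        "design_odds_ratio": spec.design_odds_ratio,
        "true_feature_positions": {
            f"{t.protein_id}/{t.feature}":
                [int(i) + 1 for i in np.nonzero(t.labels)[0]]
            for t in true_tracks
        },
        "n_variants": {"pathogenic": spec.n_pathogenic,
                       "benign": spec.n_benign, "VUS": spec.n_vus},
    }
    return FixtureSet(spec, proteins, annotations, true_tracks, families,
                      variants, manifest)
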