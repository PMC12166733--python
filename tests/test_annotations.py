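"""Sequence, annotation and variant I/O plus label-track construction."""

import numpy as np
import pytest

from featshift import (FEATURE_GROUPS, FEATURE_VOCABULARY, AnnotationError,
                       FeatureAnnotation, ProteinRecord, VariantRecord,
                       apply_variant, build_label_track,
                       format_protein_variant, parse_protein_variant,
                       read_fasta, read_feature_table, write_fasta)
from featshift.annotations import AMINO_ACIDS


class TestFeatureVocabulary:
    def test_twenty_names_in_five_groups(self):
        assert len(FEATURE_VOCABULARY) == 20
        assert len(FEATURE_GROUPS) == 5

    def test_groups_partition_vocabulary(self):
        seen = [n for names in FEATURE_GROUPS.values() for n in names]
        assert len(seen) == len(set(seen)) == 20
        assert set(seen) == set(FEATURE_VOCABULARY)


class TestReadFasta:
    def test_single_entry(self, tmp_path):
        path = tmp_path / "one.fasta"
        path.write_text(">P1 some description\nMKV\n")
        (rec,) = read_fasta(path)
        assert rec.id == "P1" and rec.sequence == "MKV" and rec.length == 3

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        assert read_fasta(path) == []

    def test_duplicate_id_rejected(self, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(">P1\nMKV\n>P1\nMKW\n")
        with pytest.raises(AnnotationError, match="duplicate"):
            read_fasta(path)

    def test_fixture_roundtrip_lengths(self, fixture_set, tmp_path):
        path = tmp_path / "fx.fasta"
        write_fasta(fixture_set.proteins, path)
        records = read_fasta(path)
        assert len(records) == len(fixture_set.proteins)
        lengths = fixture_set.manifest["lengths"]
        for rec in records:
            assert rec.length == lengths[rec.id]


class TestFeatureTable:
    @pytest.fixture
    def proteins(self):
        return [ProteinRecord("P1", "MKV")]

    def _write(self, tmp_path, rows):
        path = tmp_path / "features.tsv"
        lines = ["protein_id\tfeature\tstart\tend"] + rows
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_whole_protein_interval(self, tmp_path, proteins):
        path = self._write(tmp_path, ["P1\tdomain\t1\t3"])
        (ann,) = read_feature_table(path, proteins)
        assert ann == FeatureAnnotation("P1", "domain", 1, 3)

    @pytest.mark.parametrize("row,match", [
        ("P1\tdomain\t0\t3", "invalid interval"),      # coordinates 1-based
        ("P1\tdomain\t3\t1", "invalid interval"),
        ("P1\tdomain\t1\t9", "exceeds length"),
        ("P1\tnot-a-feature\t1\t2", "unknown feature"),
        ("P9\tdomain\t1\t2", "unknown protein"),
    ])
    def test_invalid_rows_reported(self, tmp_path, proteins, row, match):
        path = self._write(tmp_path, [row])
        with pytest.raises(AnnotationError, match=match):
            read_feature_table(path, proteins)

    def test_fixture_annotations_match_generator_truth(self, fixture_set, tmp_path):
        from featshift.annotations import write_feature_table
        path = tmp_path / "fx_features.tsv"
        write_feature_table(fixture_set.annotations, path)
        anns = read_feature_table(path, fixture_set.proteins)
        truth = fixture_set.manifest["true_feature_positions"]
        by_protein = {}
        for ann in anns:
            by_protein.setdefault((ann.protein_id, ann.feature), set()).update(
                range(ann.start, ann.end + 1))
        for key, positions in truth.items():
            pid, feature = key.split("/")
            assert by_protein.get((pid, feature), set()) == set(positions)


class TestBuildLabelTrack:
    def test_union_of_overlapping_intervals(self):
        protein = ProteinRecord("P1", "MKVAW")
        anns = [FeatureAnnotation("P1", "domain", 2, 3),
                FeatureAnnotation("P1", "domain", 3, 4)]
        track = build_label_track(protein, anns, "domain")
        assert track.labels.tolist() == [0, 1, 1, 1, 0]
        assert track.mask.tolist() == [1, 1, 1, 1, 1]

    def test_no_intervals_annotated(self):
        track = build_label_track(ProteinRecord("P1", "MKV"), [], "domain")
        assert track.labels.tolist() == [0, 0, 0]
        assert track.mask.tolist() == [1, 1, 1]

    def test_disulfide_bond_labels_endpoints_only(self):
        """A disulfide annotation names a cysteine pair; residues between the
        two endpoints stay unlabelled."""
        protein = ProteinRecord("P1", "CKVAWHC")
        track = build_label_track(
            protein, [FeatureAnnotation("P1", "disulfide bond", 1, 7)],
            "disulfide bond")
        assert track.labels.tolist() == [1, 0, 0, 0, 0, 0, 1]

    def test_unannotated_protein_gets_zero_mask(self):
        track = build_label_track(ProteinRecord("P1", "MKV"), [], "domain",
                                  annotated=False)
        assert track.mask.tolist() == [0, 0, 0]

    def test_unknown_residue_masked_out(self):
        track = build_label_track(ProteinRecord("P1", "MXV"),
                                  [FeatureAnnotation("P1", "domain", 1, 3)],
                                  "domain")
        assert track.mask.tolist() == [1, 0, 1]
        assert track.labels.tolist() == [1, 0, 1]

    def test_foreign_annotation_rejected(self):
        protein = ProteinRecord("P1", "MKV")
        with pytest.raises(AnnotationError, match="does not belong"):
            build_label_track(protein,
                              [FeatureAnnotation("P2", "domain", 1, 2)],
                              "domain")

    def test_matches_bruteforce_membership_scan(self):
        """Interval union equals a per-residue brute-force membership check."""
        rng = np.random.default_rng(7)
        length = 200
        protein = ProteinRecord(
            "P1", "".join(rng.choice(list(AMINO_ACIDS), size=length)))
        for _ in range(50):
            n_intervals = int(rng.integers(0, 8))
            intervals = []
            for _ in range(n_intervals):
                start = int(rng.integers(1, length + 1))
                end = int(rng.integers(start, length + 1))
                intervals.append((start, end))
            anns = [FeatureAnnotation("P1", "domain", s, e)
                    for s, e in intervals]
            track = build_label_track(protein, anns, "domain")
            expected = [int(any(s <= pos <= e for s, e in intervals))
                        for pos in range(1, length + 1)]
            assert track.labels.tolist() == expected


class TestVariants:
    @pytest.fixture
    def protein(self):
        rng = np.random.default_rng(3)
        seq = list(rng.choice(list(AMINO_ACIDS), size=60))
        seq[34] = "H"  # His at position 35
        return ProteinRecord("P1", "".join(seq))

    def test_parse_three_letter_notation(self, protein):
        v = parse_protein_variant("P1:p.His35Asp", [protein])
        assert (v.protein_id, v.position, v.ref_aa, v.alt_aa) == ("P1", 35, "H", "D")

    def test_synonymous_rejected(self, protein):
        with pytest.raises(AnnotationError):
            parse_protein_variant("P1:p.His35His", [protein])

    def test_ref_mismatch_rejected(self, protein):
        with pytest.raises(AnnotationError, match="mismatch"):
            parse_protein_variant("P1:p.Ala35Asp", [protein])

    def test_position_out_of_range(self, protein):
        with pytest.raises(AnnotationError, match="outside"):
            parse_protein_variant("P1:p.His999Asp", [protein])

    def test_unknown_code(self, protein):
        with pytest.raises(AnnotationError, match="three-letter"):
            parse_protein_variant("P1:p.Xyz35Asp", [protein])

    def test_parse_serialize_roundtrip(self, protein):
        """Serialise→parse is the identity on 100 random valid variants."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            pos = int(rng.integers(1, protein.length + 1))
            ref = protein.sequence[pos - 1]
            alt = rng.choice([a for a in AMINO_ACIDS if a != ref])
            v = VariantRecord("P1", pos, ref, str(alt))
            assert parse_protein_variant(format_protein_variant(v),
                                         [protein]) == v

    def test_apply_variant_substitutes_one_residue(self):
        protein = ProteinRecord("P1", "MKV")
        v = parse_protein_variant("P1:p.Lys2Arg", [protein])
        assert apply_variant(protein, v).sequence == "MRV"

    def test_apply_variant_hamming_distance_one(self, protein):
        rng = np.random.default_rng(13)
        for _ in range(20):
            pos = int(rng.integers(1, protein.length + 1))
            ref = protein.sequence[pos - 1]
            alt = str(rng.choice([a for a in AMINO_ACIDS if a != ref]))
            mutated = apply_variant(protein, VariantRecord("P1", pos, ref, alt))
            diffs = sum(a != b for a, b in zip(protein.sequence,
                                               mutated.sequence))
            assert diffs == 1 and mutated.length == protein.length

    def test_apply_then_inverse_recovers_original(self, protein):
        v = VariantRecord("P1", 35, "H", "D")
        mutated = apply_variant(protein, v)
        inverse = VariantRecord("P1", 35, "D", "H")
        assert apply_variant(mutated, inverse).sequence == protein.sequence
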