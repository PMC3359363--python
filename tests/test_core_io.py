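"""Domain types, candidate enumeration, readers and synthetic generation."""

import math
import warnings

import numpy as np
import pytest

from inteinsite import (
    ExteinRecord,
    JUNCTION_FAR,
    SyntheticCaseParams,
    enumerate_candidate_sites,
    extract_cassette,
    generate_synthetic_case,
    load_xynb_table,
    read_pssm,
    read_ss_assignment,
    read_structure,
)
from inteinsite.conservation import conservation_rank, entropy_profile
from inteinsite.core_io import generate_extein_set, shuffle_native_labels
from inteinsite.errors import (
    CassetteRangeError,
    InteinSiteError,
    InteinSiteWarning,
    PSSMParseError,
    StrideParseError,
    StructureMappingError,
    SyntheticParameterError,
)

from conftest import make_pdb_text, make_pssm_text, make_stride_text, random_extein


# ---------------------------------------------------------------------------
# ExteinRecord and candidate enumeration
# ---------------------------------------------------------------------------

class TestExteinRecord:
    def test_rejects_non_standard_residue(self):
        with pytest.raises(InteinSiteError, match="non-standard"):
            ExteinRecord(id="b", sequence="MKVLZTAGW")

    def test_rejects_native_site_not_cst(self):
        with pytest.raises(InteinSiteError, match="not C/S/T"):
            ExteinRecord(id="b", sequence="MKVLSTAGW", native_sites=(2,))

    def test_rejects_native_site_out_of_range(self):
        with pytest.raises(InteinSiteError, match="outside"):
            ExteinRecord(id="b", sequence="MKVLSTAGW", native_sites=(99,))


class TestEnumerateCandidates:
    def test_interior_cst_sites_found(self):
        ext = ExteinRecord(id="t", sequence="MKVLSTAGW")
        sites = enumerate_candidate_sites(ext)
        assert [(s.position, s.plus_one_residue) for s in sites] == [
            (5, "S"),
            (6, "T"),
        ]

    def test_terminal_cst_excluded(self):
        # C at 1 has no -3..-1 context; no other C/S/T
        ext = ExteinRecord(id="t", sequence="CAAAAAA")
        assert enumerate_candidate_sites(ext) == []

    def test_short_sequence_warns_and_returns_empty(self):
        ext = ExteinRecord(id="t", sequence="MKCAI")
        with pytest.warns(InteinSiteWarning, match="shorter than 7"):
            assert enumerate_candidate_sites(ext) == []

    def test_native_flag_set_from_record(self):
        ext = ExteinRecord(id="t", sequence="MKVLSTAGW", native_sites=(6,))
        sites = {s.position: s.is_native for s in enumerate_candidate_sites(ext)}
        assert sites == {5: False, 6: True}

    def test_matches_brute_force_scan_on_random_sequences(self, rng):
        """Enumeration equals an independent linear scan on 1,000 sequences."""
        for k in range(1000):
            ext = random_extein(rng, int(rng.integers(7, 60)))
            got = [s.position for s in enumerate_candidate_sites(ext)]
            expected = [
                p
                for p in range(1, len(ext) + 1)
                if ext.sequence[p - 1] in "CST"
                and p - 3 >= 1
                and p + 3 <= len(ext)
            ]
            assert got == expected


class TestExtractCassette:
    def test_direct_slicing_example(self):
        ext = ExteinRecord(id="t", sequence="MKVLSTAGW")
        cas = extract_cassette(ext, 5)
        assert (cas.residues_minus, cas.plus_one, cas.residues_plus) == (
            "KVL",
            "S",
            "TAG",
        )
        assert cas.seven == "KVLSTAG"

    def test_window_past_terminus_raises(self):
        ext = ExteinRecord(id="t", sequence="MKVLSTA")
        with pytest.raises(CassetteRangeError):
            extract_cassette(ext, 6)

    def test_equals_naive_string_slice(self, rng):
        for _ in range(200):
            ext = random_extein(rng, 40)
            positions = [
                p
                for p in range(4, len(ext) - 2)
                if ext.sequence[p - 1] in "CST"
            ]
            for p in positions:
                cas = extract_cassette(ext, p)
                s = ext.sequence
                assert cas.seven == s[p - 4 : p - 1] + s[p - 1] + s[p : p + 3]

    def test_nonstandard_flank_recorded_as_x(self):
        ext = ExteinRecord(id="t", sequence="MKXLSTAGW")
        cas = extract_cassette(ext, 5)
        assert cas.residues_minus == "KXL"


# ---------------------------------------------------------------------------
# PSSM reader
# ---------------------------------------------------------------------------

class TestReadPSSM:
    def test_one_hot_percentage_row(self):
        text = make_pssm_text([("A", {"A": 100})])
        pssm = read_pssm(text)
        row = pssm.row(1)
        assert row[0] == 1.0 and row.sum() == 1.0

    def test_all_zero_row_becomes_uniform(self):
        text = make_pssm_text([("M", {})])
        row = read_pssm(text).row(1)
        assert np.allclose(row, 0.05)

    def test_renormalized_percentages(self):
        text = make_pssm_text([("A", {"A": 60, "C": 40}), ("G", {"G": 100})])
        pssm = read_pssm(text)
        row = pssm.row(1)
        assert abs(row[0] - 0.6) < 1e-12 and abs(row[1] - 0.4) < 1e-12
        assert np.all(np.abs(pssm.probabilities.sum(axis=1) - 1) < 1e-12)

    def test_malformed_row_names_line(self):
        good = make_pssm_text([("A", {"A": 100}), ("C", {"C": 100})])
        lines = good.splitlines()
        # truncate the second data row to fewer than 42 fields
        for i, ln in enumerate(lines):
            if ln.split()[:2] == ["2", "C"]:
                lines[i] = " ".join(ln.split()[:30])
        with pytest.raises(PSSMParseError, match=r"line \d+"):
            read_pssm("\n".join(lines))

    def test_missing_header_raises(self):
        with pytest.raises(PSSMParseError, match="header"):
            read_pssm("no matrix here\njust text\n")

    def test_mutated_inputs_raise_structured_errors(self, rng):
        """Truncations/corruptions parse or raise package errors, never crash."""
        base = make_pssm_text(
            [("A", {"A": 70, "G": 30}), ("C", {"C": 100}), ("G", {})]
        )
        lines = base.splitlines()
        for k in range(100):
            mutant = list(lines)
            op = rng.integers(3)
            idx = int(rng.integers(len(mutant)))
            if op == 0:
                mutant = mutant[:idx]  # truncate
            elif op == 1 and mutant[idx].split():
                toks = mutant[idx].split()
                del toks[int(rng.integers(len(toks)))]
                mutant[idx] = " ".join(toks)
            else:
                mutant[idx] = mutant[idx][: max(0, len(mutant[idx]) - 10)]
            try:
                read_pssm("\n".join(mutant))
            except InteinSiteError:
                pass


# ---------------------------------------------------------------------------
# Structure reader
# ---------------------------------------------------------------------------

class TestReadStructure:
    def test_glycine_cbeta_substituted_by_calpha(self):
        pdb = make_pdb_text([(1, "GLY", (1.0, 2.0, 3.0), None)])
        ctx = read_structure(pdb, chain="A")
        assert np.array_equal(ctx.cb_coords[1], ctx.ca_coords[1])

    def test_offset_renumbering(self):
        """Structure residue 1 with offset 28 maps to extein position 29."""
        pdb = make_pdb_text(
            [(i, "ALA", (float(i), 0.0, 0.0), (float(i), 1.5, 0.0)) for i in (1, 2, 3)]
        )
        ctx = read_structure(pdb, chain="A", offset=28)
        assert set(ctx.ca_coords) == {29, 30, 31}
        assert ctx.residue_index_map[1] == 29

    def test_coordinates_round_trip(self, rng):
        coords = np.round(rng.uniform(-50, 50, size=(5, 3)), 3)
        residues = [
            (i + 1, "ALA", tuple(coords[i]), tuple(coords[i] + 1.0))
            for i in range(5)
        ]
        ctx = read_structure(make_pdb_text(residues), chain="A")
        # PDB text carries 3 decimals, parsed to float32: exact at that width
        for i in range(5):
            assert np.array_equal(
                ctx.ca_coords[i + 1].astype(np.float32),
                coords[i].astype(np.float32),
            )

    def test_missing_cbeta_non_glycine_warns_and_uses_calpha(self):
        pdb = make_pdb_text([(1, "ALA", (0.0, 0.0, 0.0), None)])
        with pytest.warns(InteinSiteWarning, match="lacks C-beta"):
            ctx = read_structure(pdb, chain="A")
        assert np.array_equal(ctx.cb_coords[1], ctx.ca_coords[1])

    def test_unmapped_annotation_reported(self):
        pdb = make_pdb_text([(1, "ALA", (0.0, 0.0, 0.0), (0.0, 1.5, 0.0))])
        with pytest.warns(InteinSiteWarning, match="not present"):
            ctx = read_structure(
                pdb, chain="A", annotations={"active_site": [99]}
            )
        assert ctx.unmapped_annotations == {99}
        assert not ctx.active_site_positions

    def test_missing_chain_raises(self):
        pdb = make_pdb_text([(1, "ALA", (0.0, 0.0, 0.0), None)])
        with pytest.raises(StructureMappingError, match="chain"):
            read_structure(pdb, chain="B")


# ---------------------------------------------------------------------------
# Secondary-structure reader
# ---------------------------------------------------------------------------

class TestReadSSAssignment:
    def test_asg_records(self):
        text = make_stride_text([(i, c) for i, c in enumerate("HHHCC", 1)])
        assert read_ss_assignment(text) == {1: "H", 2: "H", 3: "H", 4: "C", 5: "C"}

    def test_two_column_table_agrees_with_asg(self):
        codes = [(i, c) for i, c in enumerate("HHECCTE", 1)]
        asg = read_ss_assignment(make_stride_text(codes))
        table = "\n".join(f"{i}\t{c}" for i, c in codes)
        assert read_ss_assignment(table) == asg

    def test_empty_input_raises(self):
        with pytest.raises(StrideParseError):
            read_ss_assignment("")

    def test_duplicate_position_raises(self):
        with pytest.raises(StrideParseError, match="duplicate"):
            read_ss_assignment("1\tH\n1\tC\n")

    def test_offset_applied(self):
        assert read_ss_assignment("1\tH\n2\tE\n", offset=28) == {29: "H", 30: "E"}


# ---------------------------------------------------------------------------
# Synthetic generation
# ---------------------------------------------------------------------------

SMALL = SyntheticCaseParams(length=80, n_decoy_sites=6, n_snapshots=10)


class TestSyntheticCase:
    def test_same_seed_identical_bundles(self):
        a = generate_synthetic_case(SMALL, seed=1)
        b = generate_synthetic_case(SMALL, seed=1)
        assert a.extein.sequence == b.extein.sequence
        assert np.array_equal(a.pssm.probabilities, b.pssm.probabilities)
        assert np.array_equal(
            a.snapshots.ca_trajectory, b.snapshots.ca_trajectory
        )
        assert all(
            np.array_equal(a.structure.ca_coords[p], b.structure.ca_coords[p])
            for p in a.structure.ca_coords
        )
        assert a.planted_site == b.planted_site

    def test_zero_length_rejected(self):
        with pytest.raises(SyntheticParameterError):
            SyntheticCaseParams(length=0)

    @pytest.mark.parametrize("seed", range(50))
    def test_planted_profile_holds_across_seeds(self, seed):
        """Planted site: top-decile conservation, near annotation, near junction."""
        case = generate_synthetic_case(SMALL, seed=seed)
        candidates = enumerate_candidate_sites(case.extein)
        prof = entropy_profile(case.pssm)
        rank = conservation_rank(prof, candidates, case.planted_site.position)
        assert rank >= 0.9
        p = case.planted_site.position
        ca = case.structure.ca_coords
        dmin = min(
            np.linalg.norm(ca[p] - ca[a])
            for a in case.structure.active_site_positions
        )
        assert dmin < 14.1
        from inteinsite import classify_site_ss

        ctx = classify_site_ss(case.structure.ss_codes, p)
        assert ctx.junction_distance <= 2

    def test_planted_motif_written(self):
        params = SyntheticCaseParams(
            length=80, n_decoy_sites=4, n_snapshots=4, planted_motif="AWGSPYD"
        )
        case = generate_synthetic_case(params, seed=3)
        cas = extract_cassette(case.extein, case.planted_site.position)
        assert cas.seven == "AWGSPYD"

    def test_candidate_set_is_exactly_planted_plus_decoys(self):
        case = generate_synthetic_case(SMALL, seed=5)
        candidates = enumerate_candidate_sites(case.extein)
        assert len(candidates) == SMALL.n_decoy_sites + 1
        assert sum(c.is_native for c in candidates) == 1


class TestExteinSet:
    def test_motif_written_on_native_cassettes(self):
        for ext in generate_extein_set(n_exteins=5, seed=2):
            cas = extract_cassette(ext, ext.native_sites[0])
            assert cas.residues_minus[2] == "G" and cas.residues_plus[0] == "P"

    def test_label_shuffle_moves_labels_off_motif(self):
        data = generate_extein_set(n_exteins=5, seed=2)
        shuffled = shuffle_native_labels(data, seed=0)
        for orig, shuf in zip(data, shuffled):
            assert shuf.native_sites[0] != orig.native_sites[0]
            assert shuf.sequence == orig.sequence


# ---------------------------------------------------------------------------
# Packaged XynB table
# ---------------------------------------------------------------------------

class TestXynbTable:
    def test_twenty_rows_eleven_splicing(self, xynb_rows):
        assert len(xynb_rows) == 20
        assert sum(1 for r in xynb_rows if r.splicing_label) == 11

    @pytest.mark.parametrize(
        "name, dist, svm, junc, cons, splice",
        [
            ("S158", 8.15, 0.34, 2.0, 0.91, True),
            ("T140", 21.71, -0.02, 2.0, 0.81, False),
            ("C64", 10.01, 0.41, JUNCTION_FAR, 0.55, True),
            ("S135", 17.22, -1.13, 1.0, 0.00, True),
        ],
    )
    def test_row_values(self, xynb_rows, name, dist, svm, junc, cons, splice):
        by_name = {
            f"{r.site.plus_one_residue}{r.site.position}": r for r in xynb_rows
        }
        r = by_name[name]
        assert r.distance_to_functional_site == dist
        assert r.svm_score == svm
        assert r.junction_distance == junc
        assert r.conservation_rank == cons
        assert r.splicing_label is splice

    def test_svm_score_loader_passthrough(self, xynb_rows):
        by_name = {
            f"{r.site.plus_one_residue}{r.site.position}": r for r in xynb_rows
        }
        assert by_name["S112"].svm_score == 0.11
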