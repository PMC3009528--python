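import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from conftest import standard_to_raw
from pm13 import fixtures
from pm13 import structure_io as sio
from pm13.errors import (ContractError, DetectionError, FormatError,
                         InputError, StandardizationError)

# ---------------------------------------------------------------------------
# parse_structure


def test_parse_roundtrip_counts(canonical_pdb):
    raw = sio.parse_structure(canonical_pdb)
    assert [c.id for c in raw.chains] == ["A", "B", "C"]
    assert [len(c) for c in raw.chains] == [74, 87, 13]
    # every non-GLY residue carries N, CA, C, O, CB
    for chain in raw.chains:
        for res in chain.residues:
            expected = 4 if res.name == "GLY" else 5
            assert len(res.atoms) == expected


def test_parse_keeps_highest_occupancy_altloc(tmp_path):
    pdb = tmp_path / "alt.pdb"
    pdb.write_text(
        "ATOM      1  N  AALA A   1       0.000   0.000   0.000  0.60  0.00           N\n"
        "ATOM      2  N  BALA A   1       5.000   0.000   0.000  0.40  0.00           N\n"
        "ATOM      3  CA  ALA A   1       1.500   0.000   0.000  1.00  0.00           C\n"
        "END\n")
    raw = sio.parse_structure(pdb)
    res = raw.chains[0].residues[0]
    ns = [a for a in res.atoms if a.name == "N"]
    assert len(ns) == 1
    assert ns[0].x == pytest.approx(0.0)  # altloc A, occupancy 0.60


def test_parse_drops_hydrogens_and_waters(tmp_path):
    pdb = tmp_path / "mix.pdb"
    pdb.write_text(
        "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
        "ATOM      2  H   ALA A   1       0.500   0.500   0.000  1.00  0.00           H\n"
        "HETATM    3  O   HOH A 101       9.000   9.000   9.000  1.00  0.00           O\n"
        "END\n")
    raw = sio.parse_structure(pdb)
    assert len(raw.chains) == 1
    assert [a.name for a in raw.chains[0].residues[0].atoms] == ["N"]


def test_water_only_file_is_an_input_error(tmp_path):
    pdb = tmp_path / "hoh.pdb"
    pdb.write_text(
        "HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\n"
        "END\n")
    with pytest.raises(InputError):
        sio.parse_structure(pdb)


def test_unparseable_file_is_a_format_error(tmp_path):
    pdb = tmp_path / "bad.pdb"
    pdb.write_text("ATOM      1  N   ALA A   1  garbage-coordinates\nEND\n")
    with pytest.raises((FormatError, InputError)):
        sio.parse_structure(pdb)


# ---------------------------------------------------------------------------
# identify_complexes


def test_identify_single_triple(canonical_pdb):
    raw = sio.parse_structure(canonical_pdb)
    specs = sio.identify_complexes(raw)
    assert len(specs) == 1
    s = specs[0]
    assert (s.alpha_chain, s.beta_chain, s.peptide_chain) == ("A", "B", "C")


def test_identify_two_copies(tmp_path):
    path = tmp_path / "two.pdb"
    fixtures.make_complex_pdb(fixtures.FixtureSpec(seed=5, n_copies=2), path)
    specs = sio.identify_complexes(sio.parse_structure(path))
    triples = {(s.alpha_chain, s.beta_chain, s.peptide_chain) for s in specs}
    assert triples == {("A", "B", "C"), ("D", "E", "F")}


def test_identify_single_chain_is_a_detection_error(tmp_path):
    pdb = tmp_path / "one.pdb"
    lines = []
    for i in range(40):
        lines.append(
            "ATOM  %5d  CA  ALA A%4d    %8.3f   0.000   0.000  1.00  0.00           C"
            % (i + 1, i + 1, 3.8 * i))
    pdb.write_text("\n".join(lines) + "\nEND\n")
    with pytest.raises(DetectionError):
        sio.identify_complexes(sio.parse_structure(pdb))


def test_explicit_spec_is_validated_and_returned(canonical_pdb):
    raw = sio.parse_structure(canonical_pdb)
    spec = sio.ComplexSpec("A", "B", "C")
    assert sio.identify_complexes(raw, spec) == [spec]
    with pytest.raises(InputError):
        sio.identify_complexes(raw, sio.ComplexSpec("A", "A", "C"))


# ---------------------------------------------------------------------------
# align_domain_sequence


def _exhaustive_best_score(q, r, match=1.0, mismatch=0.0, gap=-1.0):
    """Independent oracle: brute-force global alignment score by recursion."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def f(i, j):
        if i == len(q) and j == len(r):
            return 0.0
        best = -np.inf
        if i < len(q) and j < len(r):
            s = match if q[i] == r[j] else mismatch
            best = max(best, s + f(i + 1, j + 1))
        if i < len(q):
            best = max(best, gap + f(i + 1, j))
        if j < len(r):
            best = max(best, gap + f(i, j + 1))
        return best

    return f(0, 0)


def test_identical_sequences_give_identity_mapping():
    seq = fixtures.REF_ALPHA_SEQ
    aln = sio.align_domain_sequence(seq, seq, ref_start=5)
    assert aln.mapping == {i: i + 5 for i in range(len(seq))}
    assert aln.identity == 1.0
    assert not aln.low_identity


def test_internal_deletion_skips_exactly_that_position():
    ref = fixtures.REF_ALPHA_SEQ[:40]
    query = ref[:17] + ref[18:]  # delete reference position index 17
    aln = sio.align_domain_sequence(query, ref, ref_start=5)
    mapped = sorted(aln.mapping.values())
    assert mapped == [i + 5 for i in range(40) if i != 17]
    assert list(aln.mapping.keys()) == sorted(aln.mapping.keys())


def test_alignment_score_matches_exhaustive_oracle_on_short_strings():
    rng = np.random.default_rng(7)
    aa = "ACDEFGHIKL"
    for _ in range(25):
        q = "".join(rng.choice(list(aa), rng.integers(5, 13)))
        r = "".join(rng.choice(list(aa), rng.integers(5, 13)))
        # bypass the length-30 domain precondition via the core aligner
        from Bio import Align
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score, aligner.mismatch_score = 1.0, 0.0
        aligner.open_gap_score = aligner.extend_gap_score = -1.0
        assert aligner.score(q, r) == pytest.approx(_exhaustive_best_score(q, r))


def test_short_query_is_a_precondition_error():
    with pytest.raises(InputError):
        sio.align_domain_sequence("ACDEFGHIKL", fixtures.REF_ALPHA_SEQ)


def test_mapping_strictly_increasing_for_divergent_sequences():
    rng = np.random.default_rng(11)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    query = "".join(rng.choice(aa, 60))
    aln = sio.align_domain_sequence(query, fixtures.REF_BETA_SEQ, ref_start=5)
    vals = [aln.mapping[k] for k in sorted(aln.mapping)]
    assert all(b > a for a, b in zip(vals, vals[1:]))


# ---------------------------------------------------------------------------
# kabsch_superpose


def test_kabsch_identity():
    pts = np.random.default_rng(0).normal(size=(8, 3))
    rot, trans, rmsd = sio.kabsch_superpose(pts, pts)
    assert np.allclose(rot, np.eye(3), atol=1e-10)
    assert np.allclose(trans, 0.0, atol=1e-10)
    assert rmsd == pytest.approx(0.0, abs=1e-10)


def test_kabsch_recovers_known_transform():
    pts = np.random.default_rng(1).normal(size=(10, 3))
    true_rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    target = pts @ true_rot.T + np.array([1.0, 2.0, 3.0])
    rot, trans, rmsd = sio.kabsch_superpose(pts, target)
    assert np.allclose(rot, true_rot, atol=1e-8)
    assert np.allclose(trans, [1.0, 2.0, 3.0], atol=1e-8)
    assert rmsd < 1e-8
    assert np.linalg.det(rot) == pytest.approx(1.0)


def test_kabsch_matches_brute_force_minimum_on_noisy_points():
    rng = np.random.default_rng(2)
    mobile = rng.normal(size=(5, 3)) * 4
    target = mobile @ Rotation.from_euler("xyz", [20, -40, 65],
                                          degrees=True).as_matrix().T
    target += rng.normal(scale=0.3, size=(5, 3)) + np.array([2.0, -1.0, 0.5])
    _, _, rmsd = sio.kabsch_superpose(mobile, target)

    def objective(params):
        rot = Rotation.from_euler("xyz", params[:3]).as_matrix()
        moved = mobile @ rot.T + params[3:]
        return np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1)))

    # SVD-free oracle: coarse Euler-angle grid then local refinement
    best = np.inf
    for ex in np.linspace(-np.pi, np.pi, 7):
        for ey in np.linspace(-np.pi / 2, np.pi / 2, 5):
            for ez in np.linspace(-np.pi, np.pi, 7):
                start = np.array([ex, ey, ez, 0.0, 0.0, 0.0])
                res = minimize(objective, start, method="Nelder-Mead",
                               options={"xatol": 1e-8, "fatol": 1e-10,
                                        "maxiter": 4000})
                best = min(best, res.fun)
    assert rmsd == pytest.approx(best, abs=1e-4)


def test_kabsch_rejects_degenerate_input():
    with pytest.raises(InputError):
        sio.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
    with pytest.raises(InputError):
        sio.kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


# ---------------------------------------------------------------------------
# standardize_complex


def test_reference_complex_standardizes_to_itself(standard_complex):
    sc = standard_complex
    assert [r.seq for r in sc.alpha] == list(range(5, 79))
    assert [r.seq for r in sc.beta] == list(range(5, 92))
    assert [r.seq for r in sc.peptide] == list(range(308, 321))
    assert len(sc.alpha) == 74 and len(sc.beta) == 87 and len(sc.peptide) == 13
    assert np.allclose(sc.rotation, np.eye(3), atol=1e-4)
    assert np.allclose(sc.translation, 0.0, atol=1e-3)


def test_long_peptide_is_trimmed_to_13(tmp_path):
    path = tmp_path / "long.pdb"
    fixtures.make_complex_pdb(fixtures.FixtureSpec(seed=3, peptide_len=20), path)
    raw = sio.parse_structure(path)
    sc = sio.standardize_complex(raw, sio.identify_complexes(raw)[0])
    assert len(sc.peptide) == 13
    assert [r.seq for r in sc.peptide] == list(range(308, 321))


def test_displaced_peptide_is_a_standardization_error(tmp_path):
    path = tmp_path / "far.pdb"
    fixtures.make_complex_pdb(
        fixtures.FixtureSpec(seed=4, peptide_shift=(0.0, 0.0, 40.0)), path)
    raw = sio.parse_structure(path)
    with pytest.raises(StandardizationError):
        sio.standardize_complex(raw, sio.ComplexSpec("A", "B", "C"))


def test_standardization_is_idempotent(standard_complex):
    again = sio.standardize_complex(standard_to_raw(standard_complex),
                                    sio.ComplexSpec("A", "B", "C"))
    assert np.allclose(again.rotation, np.eye(3), atol=1e-6)
    assert np.allclose(again.translation, 0.0, atol=1e-6)
    for cid in "ABC":
        assert [r.seq for r in again.chain(cid)] == \
               [r.seq for r in standard_complex.chain(cid)]


def test_output_frame_is_invariant_to_input_pose(tmp_path):
    path = tmp_path / "jit.pdb"
    fixtures.make_complex_pdb(fixtures.FixtureSpec(seed=6, jitter=0.2), path)
    raw = sio.parse_structure(path)
    sc1 = sio.standardize_complex(raw, sio.ComplexSpec("A", "B", "C"))
    rot = Rotation.from_euler("xyz", [33, -71, 12], degrees=True).as_matrix()
    moved = sio.RawStructure(raw.entry_id, [
        sio.Chain(c.id, sio._transform_residues(c.residues, rot,
                                                np.array([8.0, -4.0, 13.0])))
        for c in raw.chains])
    sc2 = sio.standardize_complex(moved, sio.ComplexSpec("A", "B", "C"))
    for cid in "ABC":
        for r1, r2 in zip(sc1.chain(cid), sc2.chain(cid)):
            for a1, a2 in zip(r1.atoms, r2.atoms):
                assert np.allclose(a1.xyz, a2.xyz, atol=1e-6)


def test_peptide_assignment_is_injective_and_order_preserving(standard_complex):
    seqs = [r.seq for r in standard_complex.peptide]
    assert len(seqs) == len(set(seqs))
    assert seqs == sorted(seqs)


# ---------------------------------------------------------------------------
# write_standard_pdb


def test_write_roundtrip(standard_complex, tmp_path):
    path = sio.write_standard_pdb(standard_complex, tmp_path / "std.pdb")
    raw = sio.parse_structure(path)
    assert [c.id for c in raw.chains] == ["A", "B", "C"]
    for cid, residues in zip("ABC", (standard_complex.alpha,
                                     standard_complex.beta,
                                     standard_complex.peptide)):
        reread = raw.chain(cid).residues
        assert [r.seq for r in reread] == [r.seq for r in residues]
        for r1, r2 in zip(reread, residues):
            for a1, a2 in zip(r1.atoms, r2.atoms):
                assert np.allclose(a1.xyz, a2.xyz, atol=5e-4)


def test_written_residue_numbers_within_reference_ranges(standard_complex,
                                                         tmp_path):
    path = sio.write_standard_pdb(standard_complex, tmp_path / "std.pdb")
    raw = sio.parse_structure(path)
    for cid, (lo, hi) in (("A", (5, 78)), ("B", (5, 91)), ("C", (308, 320))):
        assert all(lo <= r.seq <= hi for r in raw.chain(cid).residues)


def test_refuse_to_write_empty_peptide(standard_complex, tmp_path):
    import dataclasses

    crippled = dataclasses.replace(standard_complex, peptide=[])
    with pytest.raises(ContractError):
        sio.write_standard_pdb(crippled, tmp_path / "bad.pdb")
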