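"""Chain parsing, SSE segmentation/filtering and axis geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ssealign as sa
from ssealign import synthetic as syn
from ssealign.errors import (
    AssignmentLengthError,
    ChainNotFoundError,
    DegenerateAxisError,
)
from ssealign.structure import (
    COIL,
    HELIX,
    STRAND,
    build_sse_vectors,
    labels_from_dssp_file,
    labels_from_user_string,
)


# ---------------------------------------------------------------------------
# parsing


class TestParseChain:
    def test_roundtrip_of_generated_helix_file(self, tmp_path):
        chain = syn.build_chain([syn.ElementSpec("H", 20, (0, 0, 0))])
        path = syn.write_pdb(chain, tmp_path / "helix.pdb")
        model = sa.parse_chain(path, "A")
        assert model.sequence_length == 20
        np.testing.assert_allclose(model.ca_coords, chain.coords, atol=1e-3)

    def test_missing_chain_raises(self, tmp_path):
        path = syn.write_pdb(syn.helix_bundle(), tmp_path / "b.pdb", chain_id="A")
        with pytest.raises(ChainNotFoundError, match="chain not found"):
            sa.parse_chain(path, "C")

    def test_mmcif_roundtrip(self, tmp_path):
        import gemmi

        chain = syn.build_chain([syn.ElementSpec("H", 12, (0, 0, 0))])
        pdb = syn.write_pdb(chain, tmp_path / "h.pdb")
        st_ = gemmi.read_structure(str(pdb))
        st_.setup_entities()
        cif = tmp_path / "h.cif"
        st_.make_mmcif_document().write_file(str(cif))
        model = sa.parse_chain(cif, "A")
        assert model.sequence_length == 12


# ---------------------------------------------------------------------------
# secondary-structure assignment


def _trace_chain(n: int) -> sa.ChainModel:
    """Generic n-residue chain (straight trace) for label-handling tests."""
    from ssealign.structure import Residue

    residues = [
        Residue(number=i + 1, icode="", ca=np.array([0.0, 0.0, 3.8 * i]))
        for i in range(n)
    ]
    return sa.ChainModel(chain_id="A", residues=residues)


class TestAssignment:
    def test_helix_subtypes_merge_to_one_class(self):
        labels = labels_from_user_string("GGGHHHHIII", _trace_chain(10))
        assert labels == HELIX * 10

    def test_strand_maps_directly(self):
        assert labels_from_user_string("EEEEEE", _trace_chain(6)) == STRAND * 6

    def test_other_classes_become_coil(self):
        assert labels_from_user_string("TS B.X", _trace_chain(6)) == COIL * 6

    def test_length_mismatch_raises(self):
        with pytest.raises(AssignmentLengthError, match="length mismatch"):
            labels_from_user_string("HHH", _trace_chain(8))

    def test_classic_dssp_file(self, tmp_path):
        path = tmp_path / "toy.dssp"
        path.write_text(_dssp_classic_text("A", "GGHHHIIEE"))
        labels = labels_from_dssp_file(path, _trace_chain(9))
        assert labels == HELIX * 7 + STRAND * 2


def _dssp_classic_text(chain_id: str, ss: str) -> str:
    header = (
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    "
        "N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA"
    )

    def line(i, code):
        buf = [" "] * 120
        for start, text in [
            (0, f"{i:5d}"), (5, f"{i:5d}"), (11, chain_id), (13, "A"), (16, code),
            (34, "   0"), (38, "      0"), (46, " 0.0"), (50, "     0"),
            (57, " 0.0"), (61, "     0"), (68, " 0.0"), (72, "     0"),
            (79, " 0.0"), (103, "   0.0"), (109, "   0.0"),
        ]:
            for k, ch in enumerate(text):
                buf[start + k] = ch
        return "".join(buf)

    rows = [line(i + 1, c) for i, c in enumerate(ss)]
    return "\n".join(["==== Secondary Structure Definition ====", header] + rows) + "\n"


# ---------------------------------------------------------------------------
# segmentation and filtering


class TestSegmentFilter:
    @pytest.mark.parametrize(
        ("labels", "expected"),
        [
            # helix of 6 kept, strand of 4 kept, trailing helix of 4 dropped
            ("HHHHHH" + "EEEE" + "HHHH", [("A", 6), ("B", 4)]),
            ("C" * 10, []),
            ("EEE", []),  # strand of exactly 3 fails the minimum
            ("HHHHH", [("A", 5)]),  # minimal surviving helix
            ("HHHH", []),  # helix of 4 dropped
        ],
    )
    def test_minimum_length_rules(self, labels, expected):
        chain = _trace_chain(len(labels))
        segs = sa.segment_and_filter(labels, chain)
        assert [(t, b - a + 1) for t, a, b in segs] == expected

    def test_numbering_is_sequential(self, mixed_fold):
        chain = mixed_fold.to_chain_model()
        sses = sa.chain_to_sses(chain, mixed_fold.labels)
        assert [s.index for s in sses] == list(range(1, len(sses) + 1))
        assert [s.sse_type for s in sses] == ["B", "A", "B", "A"]

    def test_filtering_monotone_in_minimum_lengths(self, monkeypatch):
        """Lowering the minimum lengths never removes a previously kept SSE."""
        from ssealign import structure as mod

        labels = "HHHHHHCCEEEECCHHHHHCCEEEE"
        chain = syn.build_chain(
            [syn.ElementSpec("H", len(labels), (0, 0, 0))]
        ).to_chain_model()
        strict = {(t, a, b) for t, a, b in sa.segment_and_filter(labels, chain)}
        monkeypatch.setattr(mod, "MIN_HELIX_LEN", 3)
        monkeypatch.setattr(mod, "MIN_STRAND_LEN", 2)
        relaxed = {(t, a, b) for t, a, b in mod.segment_and_filter(labels, chain)}
        assert strict <= relaxed


# ---------------------------------------------------------------------------
# axis fitting


class TestFitAxis:
    def test_collinear_points_exact(self):
        pts = np.array([[0.0, 0.0, 1.5 * i] for i in range(6)])
        start, end, mid = sa.fit_axis(pts)
        np.testing.assert_allclose(start, [0, 0, 0], atol=1e-9)
        np.testing.assert_allclose(end, [0, 0, 7.5], atol=1e-9)
        np.testing.assert_allclose(mid, [0, 0, 3.75], atol=1e-9)

    def test_ideal_helix_axis_within_two_degrees(self):
        direction = np.array([1.0, 2.0, 2.0]) / 3.0
        pts = syn.make_helix(12, (1, 2, 3), direction)
        start, end, _ = sa.fit_axis(pts)
        fitted = (end - start) / np.linalg.norm(end - start)
        angle = np.degrees(np.arccos(np.clip(fitted @ direction, -1, 1)))
        assert angle < 2.0

    def test_reversed_order_negates_direction_keeps_midpoint(self):
        pts = syn.make_helix(12, (0, 0, 0), (0, 0, 1))
        s1, e1, m1 = sa.fit_axis(pts)
        s2, e2, m2 = sa.fit_axis(pts[::-1])
        np.testing.assert_allclose(e1 - s1, -(e2 - s2), atol=1e-9)
        np.testing.assert_allclose(m1, m2, atol=1e-9)

    def test_coincident_points_degenerate(self):
        with pytest.raises(DegenerateAxisError):
            sa.fit_axis(np.ones((5, 3)))


# ---------------------------------------------------------------------------
# interaxial angle and midpoint distance


def _sse_from_axis(index, start, end):
    start = np.asarray(start, float)
    end = np.asarray(end, float)
    return sa.SSEVector(
        index=index, sse_type="A", start_residue="1", end_residue="2",
        axis_start=start, axis_end=end, midpoint=0.5 * (start + end), n_residues=10,
    )


class TestInteraxialAngle:
    def test_parallel_axes_zero(self):
        v1 = _sse_from_axis(1, (0, 0, 0), (0, 0, 10))
        v2 = _sse_from_axis(2, (7, 3, 0), (7, 3, 10))
        assert sa.interaxial_angle(v1, v2) == pytest.approx(0.0, abs=1e-9)

    def test_antiparallel_axes_half_turn(self):
        v1 = _sse_from_axis(1, (0, 0, 0), (0, 0, 10))
        v2 = _sse_from_axis(2, (5, 0, 10), (5, 0, 0))
        assert abs(sa.interaxial_angle(v1, v2)) == pytest.approx(180.0, abs=1e-9)

    def test_right_handed_perpendicular_is_plus_ninety(self):
        # axis 1 along +z at origin, connection along +x, axis 2 along -y:
        # the torsion (z, x, -y) is a +90 degree right-handed rotation
        v1 = _sse_from_axis(1, (0, 0, -5), (0, 0, 5))
        v2 = _sse_from_axis(2, (8, 5, 0), (8, -5, 0))
        assert sa.interaxial_angle(v1, v2) == pytest.approx(90.0, abs=1e-9)

    def test_angle_is_symmetric_and_in_range(self, rng):
        for _ in range(50):
            v1 = _sse_from_axis(1, rng.normal(size=3) * 10, rng.normal(size=3) * 10)
            v2 = _sse_from_axis(2, rng.normal(size=3) * 10, rng.normal(size=3) * 10)
            w12 = sa.interaxial_angle(v1, v2)
            w21 = sa.interaxial_angle(v2, v1)
            assert -180.0 < w12 <= 180.0
            assert w12 == pytest.approx(w21, abs=1e-9)

    def test_coincident_midpoints_fall_back_to_unsigned(self):
        v1 = _sse_from_axis(1, (0, 0, -5), (0, 0, 5))
        v2 = _sse_from_axis(2, (-5, 0, 0), (5, 0, 0))
        assert sa.interaxial_angle(v1, v2) == pytest.approx(90.0, abs=1e-9)


class TestMidpointDistance:
    def test_three_four_five(self):
        v1 = _sse_from_axis(1, (0, 0, -1), (0, 0, 1))
        v2 = _sse_from_axis(2, (3, 4, -1), (3, 4, 1))
        assert sa.midpoint_distance(v1, v2) == pytest.approx(5.0)
        assert sa.midpoint_distance(v2, v2) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry(self, seed):
        r = np.random.default_rng(seed)
        v1 = _sse_from_axis(1, r.normal(size=3), r.normal(size=3) + 3)
        v2 = _sse_from_axis(2, r.normal(size=3) * 5, r.normal(size=3) * 5 + 1)
        assert sa.midpoint_distance(v1, v2) == pytest.approx(
            sa.midpoint_distance(v2, v1), abs=1e-12
        )


class TestRigidMotionInvariance:
    def test_rotation_translation_preserves_angles_and_distances(self, rng, mixed_fold):
        from scipy.spatial.transform import Rotation

        chain = mixed_fold.to_chain_model()
        sses = sa.chain_to_sses(chain, mixed_fold.labels)
        R = Rotation.random(random_state=7).as_matrix()
        t = rng.normal(size=3) * 20
        moved = syn.SyntheticChain(
            coords=mixed_fold.coords @ R.T + t,
            labels=mixed_fold.labels,
            elements=mixed_fold.elements,
        )
        sses2 = sa.chain_to_sses(moved.to_chain_model(), moved.labels)
        for a, b in zip(sses, sses2):
            assert a.sse_type == b.sse_type
        for i in range(len(sses)):
            for j in range(i + 1, len(sses)):
                assert sa.interaxial_angle(sses[i], sses[j]) == pytest.approx(
                    sa.interaxial_angle(sses2[i], sses2[j]), abs=1e-6
                )
                assert sa.midpoint_distance(sses[i], sses[j]) == pytest.approx(
                    sa.midpoint_distance(sses2[i], sses2[j]), abs=1e-6
                )
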