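"""Face geometry: circumcenters, start positions, alignment, flips."""

import math

import numpy as np
import pytest

from fixmap.geometry import (
    AOI_LABELS,
    AoiRect,
    DegenerateGeometryError,
    FaceGeometry,
    InfeasibleDistanceError,
    Rect,
    alignment_translation,
    center_start,
    circumcenter,
    face_alignment,
    invert_geometry,
    lateral_start,
    mirror_flip,
    read_aoi_file,
    reference_frame,
    start_positions,
    vertical_start,
    write_aoi_file,
)

from helpers import random_face


def circumcenter_oracle(p1, p2, p3, lo=-30.0, hi=30.0):
    """Independent brute-force oracle: coarse-to-fine grid search for
    the point minimizing the variance of the three distances, refined
    to 0.001 deg resolution."""
    pts = np.array([p1, p2, p3], dtype=float)

    def variance_map(xs, ys):
        qx, qy = np.meshgrid(xs, ys)
        d = np.sqrt((qx[..., None] - pts[:, 0]) ** 2
                    + (qy[..., None] - pts[:, 1]) ** 2)
        return d.var(axis=-1)

    center = np.array([0.0, 0.0])
    for step, span in ((1.0, hi - lo), (0.05, 8.0), (0.005, 0.4),
                       (0.001, 0.04)):
        xs = np.arange(center[0] - span / 2, center[0] + span / 2 + step, step)
        ys = np.arange(center[1] - span / 2, center[1] + span / 2 + step, step)
        v = variance_map(xs, ys)
        j, i = np.unravel_index(v.argmin(), v.shape)
        center = np.array([xs[i], ys[j]])
    return center


class TestCircumcenter:
    def test_right_isosceles(self):
        assert circumcenter((0, 0), (4, 0), (0, 4)) == pytest.approx((2, 2))

    def test_collinear_raises_with_face_id(self):
        with pytest.raises(DegenerateGeometryError, match="faceX"):
            circumcenter((0, 0), (2, 0), (4, 0), face_id="faceX")

    @staticmethod
    def _min_angle_deg(pts):
        sides = np.array([np.linalg.norm(pts[1] - pts[2]),
                          np.linalg.norm(pts[0] - pts[2]),
                          np.linalg.norm(pts[0] - pts[1])])
        a, b, c = sides
        cosines = [(b * b + c * c - a * a) / (2 * b * c),
                   (a * a + c * c - b * b) / (2 * a * c),
                   (a * a + b * b - c * c) / (2 * a * b)]
        return np.degrees(np.arccos(np.clip(cosines, -1, 1))).min()

    def test_equidistance_and_oracle_on_random_triples(self, rng):
        n_checked = 0
        for _ in range(300):
            pts = rng.uniform(-5, 5, size=(3, 2))
            u, v = pts[1] - pts[0], pts[2] - pts[0]
            area = 0.5 * abs(u[0] * v[1] - u[1] * v[0])
            if area < 1e-6:
                continue
            c = np.array(circumcenter(*pts))
            d = np.linalg.norm(pts - c, axis=1)
            assert np.ptp(d) < 1e-9
            # the grid oracle can only resolve well-conditioned
            # triangles whose circumcenter its domain contains
            if self._min_angle_deg(pts) < 25 or np.abs(c).max() >= 25:
                continue
            n_checked += 1
            assert np.allclose(c, circumcenter_oracle(*pts), atol=2e-3)
        assert n_checked >= 100


class TestStartPositions:
    def test_lateral_reuses_circumcenter(self, canonical_face):
        left = lateral_start(canonical_face, "left")
        anchors = [canonical_face.center(lab)
                   for lab in ("left_eye", "left_nose", "left_mouth")]
        d = [math.dist(left, a) for a in anchors]
        assert max(d) - min(d) < 1e-9

    def test_mirror_symmetric_face_has_mirror_starts(self, canonical_face):
        # canonical layout is exactly mirror-symmetric about x=0
        left = lateral_start(canonical_face, "left")
        right = lateral_start(canonical_face, "right")
        assert left[0] == pytest.approx(-right[0], abs=1e-9)
        assert left[1] == pytest.approx(right[1], abs=1e-9)

    def test_vertical_closed_form(self, canonical_face):
        # anchors (-2, 0), (2, 0) at distance 3 -> (0, +-sqrt(5))
        face = canonical_face
        up = vertical_start(face, "upper", 3.0)
        eyes = np.array([face.center("left_eye"), face.center("right_eye")])
        assert np.linalg.norm(np.array(up) - eyes[0]) == pytest.approx(3.0)
        assert np.linalg.norm(np.array(up) - eyes[1]) == pytest.approx(3.0)
        # forehead side: above the eyes in image coordinates (smaller y)
        assert up[1] < eyes[:, 1].mean()

    def test_vertical_branch_selection_explicit(self):
        # symmetric toy: eye anchors at (-2, 0), (2, 0), mouth row below
        aois = {lab: AoiRect(*r, label=lab) for lab, r in {
            "left_eye": (-3, -1, -1, 1), "right_eye": (1, -1, 3, 1),
            "mid_eye": (-0.5, -1, 0.5, 1),
            "left_nose": (-1, 1.5, 0, 2.5), "right_nose": (0, 1.5, 1, 2.5),
            "left_mouth": (-2, 3, 0, 4), "right_mouth": (0, 3, 2, 4),
        }.items()}
        face = FaceGeometry("toy", aois, Rect(-6, -6, 6, 6))
        up = vertical_start(face, "upper", 3.0)
        assert up == pytest.approx((0.0, -math.sqrt(5.0)))

    def test_infeasible_distance(self, canonical_face):
        eyes = np.array([canonical_face.center("left_eye"),
                         canonical_face.center("right_eye")])
        half = 0.5 * np.linalg.norm(eyes[1] - eyes[0])
        with pytest.raises(InfeasibleDistanceError):
            vertical_start(canonical_face, "upper", 0.9 * half)

    def test_center_is_half_nose_midpoint(self, canonical_face):
        c = center_start(canonical_face)
        ln = canonical_face.center("left_nose")
        rn = canonical_face.center("right_nose")
        assert c == pytest.approx(((ln[0] + rn[0]) / 2, (ln[1] + rn[1]) / 2))

    def test_all_invariants_on_random_faces(self, rng):
        """left/right equidistant from their three anchors; upper/lower
        equidistant from their two anchors at the mean lateral distance;
        center at the half-nose midpoint — to 1e-9 deg."""
        for i in range(25):
            face = random_face(rng, f"f{i}")
            sp = start_positions(face)
            for side, sname in (("left", sp.left), ("right", sp.right)):
                anchors = [face.center(f"{side}_eye"),
                           face.center(f"{side}_nose"),
                           face.center(f"{side}_mouth")]
                d = [math.dist(sname, a) for a in anchors]
                assert max(d) - min(d) < 1e-9
            d_lat = 0.5 * (
                math.dist(sp.left, face.center("left_eye"))
                + math.dist(sp.right, face.center("right_eye")))
            for point, labs in ((sp.upper, ("left_eye", "right_eye")),
                                (sp.lower, ("left_mouth", "right_mouth"))):
                for lab in labs:
                    assert math.dist(point, face.center(lab)) == pytest.approx(
                        d_lat, abs=1e-9)

    def test_mirror_flip_swaps_lateral_starts(self, rng):
        face = random_face(rng, "m")
        sp = start_positions(face)
        flipped = mirror_flip(face, axis_x=0.0)
        sp_f = start_positions(flipped)
        assert sp_f.left == pytest.approx((-sp.right[0], sp.right[1]))
        assert sp_f.right == pytest.approx((-sp.left[0], sp.left[1]))


class TestAlignment:
    def test_identity_and_constant_offset(self, rng):
        centers = rng.uniform(-3, 3, (7, 2))
        t = alignment_translation(centers, centers)
        assert (t.dx, t.dy) == (0.0, 0.0)
        t = alignment_translation(centers, centers + [1.0, -2.0])
        assert (t.dx, t.dy) == pytest.approx((1.0, -2.0))

    def test_matches_grid_search_ssd_minimizer(self, rng):
        """Closed form equals the brute-force SSD minimizer over a
        translation grid, within grid resolution, on 100 fixtures."""
        step = 0.01
        for _ in range(100):
            fc = rng.uniform(-3, 3, (7, 2))
            ref = rng.uniform(-3, 3, (7, 2))
            t = alignment_translation(fc, ref)
            # grid centered on the mean offset, +-0.2 deg
            mean_off = (ref - fc).mean(axis=0)
            dxs = mean_off[0] + np.arange(-0.2, 0.2, step)
            dys = mean_off[1] + np.arange(-0.2, 0.2, step)
            ssd = ((fc[None, None, :, :]
                    + np.stack(np.meshgrid(dxs, dys), -1)[:, :, None, :]
                    - ref) ** 2).sum(axis=(2, 3))
            j, i = np.unravel_index(ssd.argmin(), ssd.shape)
            assert abs(t.dx - dxs[i]) <= step
            assert abs(t.dy - dys[j]) <= step

    def test_reference_frame_is_per_label_mean(self, rng):
        faces = [random_face(rng, f"f{i}") for i in range(5)]
        ref = reference_frame(faces)
        brute = np.mean([f.centers() for f in faces], axis=0)
        assert np.allclose(ref, brute)
        assert np.allclose(reference_frame(faces[:1]), faces[0].centers())

    def test_face_alignment_restores_reference(self, rng):
        faces = [random_face(rng, f"f{i}") for i in range(4)]
        ref = reference_frame(faces)
        for face in faces:
            t = face_alignment(face, ref)
            aligned = face.centers() + [t.dx, t.dy]
            # residuals after optimal translation have zero mean
            assert np.allclose((ref - aligned).mean(axis=0), 0, atol=1e-12)


class TestFlips:
    def test_double_inversion_identity(self, rng):
        face = random_face(rng, "f")
        twice = invert_geometry(invert_geometry(face, 1.3), 1.3)
        assert np.allclose(twice.centers(), face.centers())
        assert twice.orientation == face.orientation

    def test_inversion_preserves_pairwise_distances(self, rng):
        face = random_face(rng, "f")
        inv = invert_geometry(face, axis_y=0.7)
        assert inv.orientation == "inverted"
        d0 = np.linalg.norm(
            face.centers()[:, None] - face.centers()[None], axis=-1)
        d1 = np.linalg.norm(
            inv.centers()[:, None] - inv.centers()[None], axis=-1)
        assert np.allclose(d0, d1)

    def test_aoi_on_axis_is_fixed(self):
        r = AoiRect(0, -1, 2, 1, label="mid_eye")
        aois = {lab: AoiRect(*rect, label=lab)
                for lab, rect in {
                    "left_eye": (-4, -1, -3, 1), "right_eye": (3, -1, 4, 1),
                    "mid_eye": (0, -1, 2, 1),
                    "left_nose": (-1, 2, 0, 3), "right_nose": (0, 2, 1, 3),
                    "left_mouth": (-2, 4, 0, 5), "right_mouth": (0, 4, 2, 5),
                }.items()}
        face = FaceGeometry("f", aois, Rect(-6, -6, 6, 6))
        inv = invert_geometry(face, axis_y=0.0)
        assert inv.aois["mid_eye"].y_min == r.y_min
        assert inv.aois["mid_eye"].y_max == r.y_max


class TestIO:
    def test_aoi_file_round_trip(self, rng, tmp_path):
        faces = [random_face(rng, f"f{i}") for i in range(3)]
        path = tmp_path / "aois.tsv"
        write_aoi_file(faces, path)
        back = read_aoi_file(path)
        assert [f.face_id for f in back] == [f.face_id for f in faces]
        for a, b in zip(faces, back):
            assert np.allclose(a.centers(), b.centers())

    def test_geometry_validation(self, canonical_face):
        aois = dict(canonical_face.aois)
        del aois["mid_eye"]
        with pytest.raises(ValueError, match="mid_eye"):
            FaceGeometry("bad", aois, canonical_face.image_bounds)
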