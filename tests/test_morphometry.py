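"""Geometry-engine tests against analytic oracles and generator round-trips."""

import math

import numpy as np
import pytest
from shapely import affinity
from shapely.geometry import Point, Polygon

from capscore.errors import AnnotationError, InvalidInputError, MeasurementError
from capscore.morphometry import (
    CapillaryGeometry,
    ProcessAnnotation,
    TriMark,
    count_bm_layers,
    count_processes,
    extract_features,
    measure_bm_thickness,
    measure_endothelial_area,
)
from capscore.rubric import ProcessProminence
from capscore.synthetic import synthesize_geometry
from capscore.rubric import CapillaryFeatures, TriObservation


def circle(r, center=(0.0, 0.0), n=256):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Polygon(np.c_[center[0] + r * np.cos(t), center[1] + r * np.sin(t)])


def annulus(r_in, r_out, center=(0.0, 0.0), n=256):
    return Polygon(
        circle(r_out, center, n).exterior.coords, [circle(r_in, center, n).exterior.coords]
    )


def wedge(r_in, r_out, theta_c, half_width, center=(0.0, 0.0), n=24):
    a = np.linspace(theta_c - half_width, theta_c + half_width, n)
    outer = np.c_[center[0] + r_out * np.cos(a), center[1] + r_out * np.sin(a)]
    inner = np.c_[center[0] + r_in * np.cos(a[::-1]), center[1] + r_in * np.sin(a[::-1])]
    return Polygon(np.vstack([outer, inner]))


@pytest.fixture
def concentric():
    """Circular capillary: lumen r=1000, endothelium r=1500, one BM annulus
    1500-1750 nm (analytic thickness 250 nm)."""
    return CapillaryGeometry(
        lumen=circle(1000),
        endothelium_outer=circle(1500),
        bm_layers=[annulus(1500, 1750)],
    )


class TestBmThickness:
    def test_annulus_analytic(self, concentric):
        assert measure_bm_thickness(concentric) == pytest.approx(250.0, rel=0.01)

    @pytest.mark.parametrize("summary", ["median", "mean", "max"])
    def test_summaries_agree_on_uniform_annulus(self, concentric, summary):
        got = measure_bm_thickness(concentric, summary=summary)
        assert got == pytest.approx(250.0, rel=0.01)

    def test_multilayer_union_thickness(self):
        """Two contiguous 100 nm annuli measure 200 nm total."""
        geom = CapillaryGeometry(
            lumen=circle(1000),
            endothelium_outer=circle(1400),
            bm_layers=[annulus(1400, 1500), annulus(1500, 1600)],
        )
        assert measure_bm_thickness(geom) == pytest.approx(200.0, rel=0.01)

    def test_single_filled_lamina_polygon(self):
        """A single ring-shaped lamina of uniform width w returns w."""
        geom = CapillaryGeometry(lumen=circle(1000), bm_layers=[annulus(1200, 1450)])
        assert measure_bm_thickness(geom) == pytest.approx(250.0, rel=0.01)

    def test_zero_width_bm_fails(self):
        # lumen = endothelium and a zero-area BM ring: nothing to intersect
        degenerate = Polygon(circle(1500).exterior.coords, [circle(1500).exterior.coords])
        geom = CapillaryGeometry(
            lumen=circle(1000),
            endothelium_outer=circle(1000),
            bm_layers=[degenerate],
        )
        with pytest.raises(MeasurementError):
            measure_bm_thickness(geom)

    def test_no_layers_rejected(self):
        geom = CapillaryGeometry(lumen=circle(1000), endothelium_outer=circle(1500))
        with pytest.raises(InvalidInputError):
            measure_bm_thickness(geom)

    def test_too_few_rays_rejected(self, concentric):
        with pytest.raises(InvalidInputError):
            measure_bm_thickness(concentric, n_rays=4)

    def test_densification_invariance(self, concentric):
        dense = CapillaryGeometry(
            lumen=circle(1000, n=1024),
            endothelium_outer=circle(1500, n=1024),
            bm_layers=[annulus(1500, 1750, n=1024)],
        )
        a = measure_bm_thickness(concentric)
        b = measure_bm_thickness(dense)
        assert b == pytest.approx(a, rel=5e-3)


class TestLayerCount:
    @pytest.mark.parametrize("k", [1, 4])
    def test_nested_count(self, k):
        layers = [annulus(1500 + 100 * i, 1600 + 100 * i) for i in range(k)]
        geom = CapillaryGeometry(lumen=circle(1000), bm_layers=layers)
        assert count_bm_layers(geom) == k

    def test_non_nested_layers_rejected(self):
        geom = CapillaryGeometry(
            lumen=circle(1000),
            bm_layers=[annulus(1500, 1600), annulus(1550, 1650, center=(2000, 0))],
        )
        with pytest.raises(AnnotationError):
            count_bm_layers(geom)

    def test_generator_round_trip(self, rng):
        for k in range(1, 7):
            f = CapillaryFeatures(bm_thickness_nm=60.0 * k, bm_layer_count=k,
                                  activation_grade="none", process_count=0)
            geom = synthesize_geometry(f, seed=int(rng.integers(2**31)))
            assert count_bm_layers(geom) == k


class TestProcesses:
    def test_no_processes(self, concentric):
        assert count_processes(concentric) == (0, ProcessProminence.FOCAL_SMALL)

    def test_wedges_with_known_coverage(self):
        """8 wedges covering 80% of the perimeter -> (8, very_prominent);
        coverage oracle: total angular extent / 2*pi."""
        half = 0.80 * math.pi / 8
        procs = [
            ProcessAnnotation(wedge(1800, 2300, theta, half))
            for theta in np.linspace(0, 2 * math.pi, 8, endpoint=False)
        ]
        geom = CapillaryGeometry(
            lumen=circle(1000), bm_layers=[annulus(1500, 1750)], processes=procs
        )
        assert count_processes(geom) == (8, ProcessProminence.VERY_PROMINENT)

    def test_tiny_processes_are_focal(self):
        half = 0.10 * math.pi / 5
        procs = [
            ProcessAnnotation(wedge(1800, 2000, theta, half))
            for theta in np.linspace(0, 2 * math.pi, 5, endpoint=False)
        ]
        geom = CapillaryGeometry(
            lumen=circle(1000), bm_layers=[annulus(1500, 1750)], processes=procs
        )
        assert count_processes(geom) == (5, ProcessProminence.FOCAL_SMALL)

    def test_distant_processes_not_counted(self):
        procs = [ProcessAnnotation(circle(200, center=(8000, 0)))]
        geom = CapillaryGeometry(
            lumen=circle(1000), bm_layers=[annulus(1500, 1750)], processes=procs
        )
        assert count_processes(geom, annulus_width_nm=1000)[0] == 0


class TestEndothelialArea:
    def test_annulus_closed_form(self):
        """outer r=2000 nm, lumen r=1500 nm: area = pi*(4-2.25) um^2."""
        geom = CapillaryGeometry(lumen=circle(1500), endothelium_outer=circle(2000),
                                 bm_layers=[annulus(2000, 2100)])
        assert measure_endothelial_area(geom) == pytest.approx(math.pi * 1.75, rel=0.01)

    def test_zero_width(self):
        geom = CapillaryGeometry(lumen=circle(1500), endothelium_outer=circle(1500))
        assert measure_endothelial_area(geom) == pytest.approx(0.0, abs=1e-9)

    def test_swapped_contours_rejected(self):
        geom = CapillaryGeometry(lumen=circle(2000), endothelium_outer=circle(1500))
        with pytest.raises(AnnotationError):
            measure_endothelial_area(geom)

    def test_random_polygon_matches_shoelace(self, rng):
        for _ in range(10):
            t = np.sort(rng.uniform(0, 2 * np.pi, 64))
            r_l = rng.uniform(800, 1200)
            r_e = rng.uniform(1500, 2500)
            lum = Polygon(np.c_[r_l * np.cos(t), r_l * np.sin(t)])
            endo = Polygon(np.c_[r_e * np.cos(t), r_e * np.sin(t)])

            def shoelace(poly):
                x, y = np.asarray(poly.exterior.coords[:-1]).T
                return 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))

            geom = CapillaryGeometry(lumen=lum, endothelium_outer=endo)
            expect = (shoelace(endo) - shoelace(lum)) / 1e6
            assert measure_endothelial_area(geom) == pytest.approx(expect, rel=1e-9)


class TestRigidMotionInvariance:
    def _transform(self, geom, angle, dx, dy):
        def t(p):
            return affinity.translate(affinity.rotate(p, angle, origin=(0, 0)), dx, dy)

        return CapillaryGeometry(
            lumen=t(geom.lumen),
            endothelium_outer=t(geom.endothelium_outer) if geom.endothelium_outer else None,
            bm_layers=[t(p) for p in geom.bm_layers],
            processes=[ProcessAnnotation(t(p.polygon), p.size_tag) for p in geom.processes],
        )

    def test_measurements_invariant(self):
        f = CapillaryFeatures(bm_thickness_nm=220, bm_layer_count=3, activation_grade="mild",
                              process_count=6, process_prominence="prominent")
        geom = synthesize_geometry(f, seed=11)
        moved = self._transform(geom, 123.4, 5.4e5, -2.1e5)
        a = measure_bm_thickness(geom)
        b = measure_bm_thickness(moved)
        assert b == pytest.approx(a, rel=1e-6)
        assert measure_endothelial_area(moved) == pytest.approx(
            measure_endothelial_area(geom), rel=1e-6
        )
        assert count_bm_layers(moved) == count_bm_layers(geom)
        assert count_processes(moved)[0] == count_processes(geom)[0]


class TestExtractFeatures:
    def test_full_phantom_round_trip(self):
        f = CapillaryFeatures(
            bm_thickness_nm=260.0, bm_layer_count=4, activation_grade="marked",
            process_count=8, process_prominence="very_prominent",
            tri=(TriObservation("large", 1), TriObservation("small", 2)),
        )
        geom = synthesize_geometry(f, seed=5)
        got = extract_features(geom)
        assert got.bm_thickness_nm == pytest.approx(260.0, rel=0.02)
        assert got.bm_layer_count == 4
        assert got.process_count == 8
        assert got.process_prominence == ProcessProminence.VERY_PROMINENT
        tri_counts = {o.size_class.value: o.count for o in got.tri}
        assert tri_counts == {"large": 1, "small": 2}

    def test_empty_phantom(self):
        f = CapillaryFeatures(bm_thickness_nm=80.0, bm_layer_count=1,
                              activation_grade="none", process_count=0, tri=())
        got = extract_features(synthesize_geometry(f, seed=6))
        assert got.process_count == 0 and got.tri == ()

    def test_degraded_phantom_activation_missing(self):
        f = CapillaryFeatures(bm_thickness_nm=150.0, bm_layer_count=2,
                              process_count=0, degraded=True)
        geom = synthesize_geometry(f, seed=7)
        assert geom.endothelium_outer is None
        got = extract_features(geom)
        assert got.bm_thickness_nm == pytest.approx(150.0, rel=0.02)
        assert got.endothelial_area_um2 is None and got.degraded

    def test_pole_of_inaccessibility_fallback(self):
        """A horseshoe lumen whose centroid lies in its mouth still measures
        (rays start from the pole of inaccessibility instead)."""
        horseshoe = circle(1000).difference(circle(600)).difference(
            wedge(0, 1100, math.pi, 0.8)
        )
        assert not horseshoe.contains(horseshoe.centroid)
        geom = CapillaryGeometry(lumen=horseshoe, bm_layers=[annulus(1500, 1700)])
        # off-centre origin crosses the annulus obliquely: generous tolerance
        assert measure_bm_thickness(geom) == pytest.approx(200.0, rel=0.15)
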