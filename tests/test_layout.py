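"""Polar geometry: equal population spans, wedge tiling, pie exactness."""

from fractions import Fraction

import numpy as np
import pytest

from admixring import layout as lay
from admixring.errors import UnknownLabelError, ValidationError
from admixring.ordering import resolve_order
from helpers import make_dataset, random_dataset


def _dataset_with_sizes(sizes, k=3, rng=None):
    rng = rng or np.random.default_rng(7)
    rows, labels = [], []
    for i, n in enumerate(sizes):
        for _ in range(n):
            rows.append(rng.dirichlet(np.ones(k)))
            labels.append(f"P{i:03d}")
    return make_dataset(rows, labels)


class TestEqualSpans:
    def test_four_populations_get_quarter_circles(self):
        ds = _dataset_with_sizes([1, 2, 3, 4])
        l = lay.compute_layout(resolve_order(ds), ds.matrix)
        assert all(abs(s.width - 90.0) < 1e-9 for s in l.populations)
        assert len(l.separators) == 4

    def test_single_population_wedges(self):
        ds = _dataset_with_sizes([3])
        l = lay.compute_layout(resolve_order(ds), ds.matrix)
        assert len(l.wedges) == 3
        assert all(abs(w.width - 120.0) < 1e-9 for w in l.wedges)

    def test_cumulative_angles_match_exact_fractions(self):
        """Span boundaries agree with exact rational cumulative arithmetic."""
        sizes = list(range(1, 11))
        ds = _dataset_with_sizes(sizes)
        order = resolve_order(ds)
        l = lay.compute_layout(order, ds.matrix)
        assert all(abs(s.width - 36.0) < 1e-9 for s in l.populations)
        by_label = {s.label: m for s, m in zip(order.population_sequence, order.members_by_population)}
        # exact-fraction oracle for every wedge boundary
        span = Fraction(360, len(sizes))
        cursor = Fraction(90)
        wedge_iter = iter(l.wedges)
        for s in l.populations:
            n = len(by_label[s.label])
            step = span / n
            for j in range(n):
                w = next(wedge_iter)
                assert abs(w.start_angle - float(cursor - step * j)) < 1e-9
                assert abs(w.end_angle - float(cursor - step * (j + 1))) < 1e-9
            cursor -= span

    def test_equal_space_regardless_of_sizes(self, rng):
        for _ in range(50):
            sizes = rng.integers(1, 30, size=int(rng.integers(1, 12)))
            ds = _dataset_with_sizes(list(sizes), rng=rng)
            l = lay.compute_layout(resolve_order(ds), ds.matrix)
            widths = [s.width for s in l.populations]
            assert max(widths) - min(widths) < 1e-9
            assert abs(sum(w.width for w in l.wedges) - 360.0) < 1e-6

    def test_wedge_segments_reproduce_proportions(self, rng):
        ds = random_dataset(rng)
        l = lay.compute_layout(resolve_order(ds), ds.matrix)
        for w in l.wedges:
            np.testing.assert_allclose(
                w.segments, ds.matrix.values[w.row_index], atol=1e-9
            )
            assert abs(sum(w.segments) - 1.0) < 1e-9


class TestCenterPie:
    def test_slices_are_360_times_mean(self):
        ds = make_dataset([(0.2, 0.8), (0.4, 0.6)], ["A", "A"])
        slices = lay.compute_center_pie(ds, "A")
        assert [s.ancestry for s in slices] == [0, 1]
        assert abs(slices[0].width - 108.0) < 1e-9
        assert abs(slices[1].width - 252.0) < 1e-9

    def test_uniform_k4_gives_four_quarters(self):
        ds = make_dataset([(0.25, 0.25, 0.25, 0.25)], ["A"])
        slices = lay.compute_center_pie(ds, "A")
        assert all(abs(s.width - 90.0) < 1e-9 for s in slices)

    def test_pure_single_individual(self):
        ds = make_dataset([(1.0, 0.0, 0.0)], ["A"])
        slices = lay.compute_center_pie(ds, "A")
        assert abs(slices[0].width - 360.0) < 1e-9
        assert slices[1].width == 0.0 and slices[2].width == 0.0

    def test_slices_tile_the_circle(self, rng):
        ds = random_dataset(rng)
        label = ds.population_labels()[0]
        slices = lay.compute_center_pie(ds, label)
        assert abs(sum(s.width for s in slices) - 360.0) < 1e-9
        # contiguous: each slice starts where the previous ended
        for a, b in zip(slices, slices[1:]):
            assert abs(a.end_angle - b.start_angle) < 1e-12

    def test_unknown_target(self, small_dataset):
        with pytest.raises(UnknownLabelError):
            lay.compute_center_pie(small_dataset, "nope")


class TestLayoutAssembly:
    def test_pie_present_iff_target(self, small_dataset):
        order = resolve_order(small_dataset)
        assert lay.compute_layout(order, small_dataset.matrix).center_pie is None
        l = lay.compute_layout(order, small_dataset.matrix, target="B")
        assert l.center_pie is not None

    def test_target_not_in_order_is_an_error(self, small_dataset):
        order = resolve_order(small_dataset, exclude={"B"})
        with pytest.raises(UnknownLabelError, match="'B'"):
            lay.compute_layout(order, small_dataset.matrix, target="B")

    def test_target_removed_from_ring_when_flagged(self, small_dataset):
        order = resolve_order(small_dataset)
        cfg = lay.GeometryConfig(target_in_ring=False)
        l = lay.compute_layout(order, small_dataset.matrix, target="B", config=cfg)
        assert "B" not in [s.label for s in l.populations]
        assert l.center_pie is not None

    def test_separators_toggle(self, small_dataset):
        order = resolve_order(small_dataset)
        cfg = lay.GeometryConfig(separators=False)
        assert lay.compute_layout(order, small_dataset.matrix, None, cfg).separators == ()

    def test_pure_function_byte_stable(self, small_dataset):
        order = resolve_order(small_dataset)
        l1 = lay.compute_layout(order, small_dataset.matrix, target="A")
        l2 = lay.compute_layout(order, small_dataset.matrix, target="A")
        assert l1 == l2


class TestLabels:
    def test_anchor_at_midpoint(self):
        span = lay.PopulationSpan("x", 0.0, 90.0)
        placement = lay._label_for_span(span, lay.GeometryConfig())
        assert placement.anchor_angle == 45.0
        assert placement.flip is False

    def test_left_half_labels_flip(self):
        span = lay.PopulationSpan("x", 170.0, 190.0)
        placement = lay._label_for_span(span, lay.GeometryConfig())
        assert placement.anchor_angle == 180.0
        assert placement.flip is True
        assert placement.rotation == 0.0

    def test_anchors_equal_independent_midpoints(self, rng):
        ds = random_dataset(rng)
        order = resolve_order(ds)
        l = lay.compute_layout(order, ds.matrix)
        for span, label in zip(l.populations, l.labels):
            expected = ((span.start_angle + span.end_angle) / 2.0) % 360.0
            assert abs(label.anchor_angle - expected) < 1e-9
            assert label.label == span.label
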