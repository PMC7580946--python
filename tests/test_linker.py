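"""Budget linking and confidence-based extraction."""

import math

import numpy as np
import pytest

from xiclink.calibration import calibrate
from xiclink.linker import (
    CandidateWindow,
    Link,
    LinkGraph,
    candidate_window,
    extract,
    extract_xics,
    filter_points,
    link_from,
    run_linking,
    scaled_distance,
)
from xiclink.model import Point, run_from_points
from xiclink.synth import scenario


def _pt(pid, mz, rt, inten, scan=0):
    return Point(pid, mz, rt, inten, scan)


class TestScaledDistance:
    def test_one_resolution_unit_in_mz(self, injected_calib):
        calib = injected_calib(resolution_mz=0.02, sampling_rate_rt=0.5)
        a, b = _pt(0, 100.0, 10.0, 5.0), _pt(1, 100.02, 10.0, 4.0)
        assert scaled_distance(a, b, calib) == pytest.approx(1.0)

    def test_one_sampling_unit_in_rt(self, injected_calib):
        calib = injected_calib(resolution_mz=0.02, sampling_rate_rt=0.5)
        a, b = _pt(0, 100.0, 10.0, 5.0), _pt(1, 100.0, 10.5, 4.0)
        assert scaled_distance(a, b, calib) == pytest.approx(1.0)

    def test_diagonal_is_sqrt_two(self, injected_calib):
        calib = injected_calib(resolution_mz=0.02, sampling_rate_rt=0.5)
        a, b = _pt(0, 100.0, 10.0, 5.0), _pt(1, 100.02, 10.5, 4.0)
        assert scaled_distance(a, b, calib) == pytest.approx(math.sqrt(2))


class TestFilterPoints:
    def test_threshold_filter_and_order(self, make_run, injected_calib):
        run = make_run([(100.0, 1.0, 1.0), (101.0, 1.0, 5.0), (102.0, 1.0, 10.0)])
        calib = injected_calib(baseline=4.0)
        assert [p.intensity for p in filter_points(run, calib)] == [10.0, 5.0]

    def test_all_below_baseline_gives_empty(self, make_run, injected_calib):
        run = make_run([(100.0, 1.0, 1.0), (101.0, 1.0, 2.0)])
        assert filter_points(run, injected_calib(baseline=4.0)) == []

    def test_matches_independent_sort_and_filter(self, make_run, injected_calib):
        rng = np.random.default_rng(11)
        triples = [
            (float(100 + rng.uniform(0, 10)), float(1 + rng.integers(0, 50)), float(rng.exponential(20)))
            for _ in range(1000)
        ]
        run = make_run(triples)
        calib = injected_calib(baseline=20.0)
        got = filter_points(run, calib)
        # independently coded: list comprehension + different sort expression
        expected = sorted(
            (p for p in run.iter_points() if p.intensity >= 20.0),
            key=lambda p: (-p.intensity, p.rt, p.mz, p.point_id),
        )
        assert got == expected


class TestCandidateWindow:
    def test_empty_when_no_neighbors(self, make_run, injected_calib):
        run = make_run([(100.0, 10.0, 50.0), (105.0, 10.0, 20.0), (100.0, 11.0, 1.0)])
        calib = injected_calib(baseline=2.0, resolution_mz=0.01, sampling_rate_rt=0.5)
        center = max(run.iter_points(), key=lambda p: p.intensity)
        assert candidate_window(center, run, calib).members == ()

    def test_boundary_neighbor_included(self, make_run, injected_calib):
        calib = injected_calib(baseline=1.0, resolution_mz=0.01, sampling_rate_rt=0.5)
        # neighbor exactly at mz + 2*resolution and rt + 2*sampling
        run = make_run([(100.0, 10.0, 50.0), (100.02, 11.0, 20.0)])
        center = next(p for p in run.iter_points() if p.intensity == 50.0)
        members = candidate_window(center, run, calib).members
        assert [m.intensity for m in members] == [20.0]

    def test_lower_intensity_only(self, make_run, injected_calib):
        calib = injected_calib(baseline=1.0, resolution_mz=1.0, sampling_rate_rt=1.0)
        run = make_run([(100.0, 10.0, 50.0), (100.5, 10.0, 60.0), (100.6, 10.0, 40.0)])
        center = next(p for p in run.iter_points() if p.intensity == 50.0)
        members = candidate_window(center, run, calib).members
        assert [m.intensity for m in members] == [40.0]

    def test_matches_brute_force_scan_on_random_neighborhood(
        self, make_run, injected_calib
    ):
        rng = np.random.default_rng(5)
        calib = injected_calib(baseline=1.0, resolution_mz=0.05, sampling_rate_rt=0.7)
        triples = [
            (float(100 + rng.uniform(-0.3, 0.3)), float(round(10 + 0.7 * rng.integers(-4, 5), 4)), float(rng.uniform(1, 100)))
            for _ in range(200)
        ]
        run = make_run(triples)
        center = max(run.iter_points(), key=lambda p: (p.intensity, -p.point_id))
        got = candidate_window(center, run, calib).members
        # brute force over all points, coded independently
        half_mz, half_rt = 2 * 0.05, 2 * 0.7
        cand = []
        for w in run.iter_points():
            if w.point_id == center.point_id or w.intensity < calib.baseline:
                continue
            if abs(w.mz - center.mz) > half_mz or abs(w.rt - center.rt) > half_rt:
                continue
            if w.intensity > center.intensity or (
                w.intensity == center.intensity and w.point_id < center.point_id
            ):
                continue
            d = math.sqrt(
                ((w.mz - center.mz) / 0.05) ** 2 + ((w.rt - center.rt) / 0.7) ** 2
            )
            cand.append((-d, w.point_id, w))
        cand.sort(key=lambda t: t[:2])
        assert list(got) == [w for _, _, w in cand]


class TestLinkFrom:
    def _window(self, center, members, calib):
        ordered = sorted(
            members,
            key=lambda w: (-scaled_distance(center, w, calib), w.point_id),
        )
        return CandidateWindow(center, 1.0, 1.0, tuple(ordered))

    def test_zero_distance_member_costs_nothing(self, injected_calib):
        calib = injected_calib(baseline=1.0)
        center = _pt(0, 100.0, 10.0, 100.0)
        w = _pt(1, 100.0, 10.0, 40.0)
        (link,) = link_from(center, self._window(center, [w], calib), calib)
        assert link.cost == 0.0
        assert link.confidence == 1.0

    def test_hand_evaluated_single_step(self, injected_calib):
        # center 100, member 99 at scaled distance 1: cost 1, confidence 0.99
        calib = injected_calib(baseline=1.0, resolution_mz=0.01, sampling_rate_rt=1.0)
        center = _pt(0, 100.0, 10.0, 100.0)
        w = _pt(1, 100.01, 10.0, 99.0)
        (link,) = link_from(center, self._window(center, [w], calib), calib)
        assert link.cost == pytest.approx(1.0)
        assert link.confidence == pytest.approx(0.99)

    def test_stepwise_budget_recurrence(self, injected_calib):
        # center 100; w1(I=40, d=1) then w2(I=40, d=1):
        # link1 cost 60 confidence 0.40 budget 40; link2 cost 0 confidence 1.0
        calib = injected_calib(baseline=1.0, resolution_mz=0.01, sampling_rate_rt=1.0)
        center = _pt(0, 100.0, 10.0, 100.0)
        w1 = _pt(1, 100.01, 10.0, 40.0)
        w2 = _pt(2, 99.99, 10.0, 40.0)
        links = link_from(center, self._window(center, [w1, w2], calib), calib)
        assert [l.child.point_id for l in links] == [1, 2]
        assert links[0].cost == pytest.approx(60.0)
        assert links[0].confidence == pytest.approx(0.40)
        assert links[1].cost == pytest.approx(0.0, abs=1e-8)
        assert links[1].confidence == pytest.approx(1.0)

    def test_exhaustion_emits_clamped_link_then_stops(self, injected_calib):
        calib = injected_calib(baseline=1.0, resolution_mz=0.01, sampling_rate_rt=1.0)
        center = _pt(0, 100.0, 10.0, 100.0)
        far = _pt(1, 100.02, 12.0, 10.0)  # d = sqrt(8), cost ~ 254 > budget
        near = _pt(2, 100.0, 11.0, 90.0)
        links = link_from(center, self._window(center, [far, near], calib), calib)
        assert len(links) == 1
        assert links[0].child.point_id == 1
        assert links[0].cost == pytest.approx(100.0)  # clamped to budget
        assert links[0].confidence == 0.0

    def test_matches_independent_simulator(self, injected_calib):
        """The emitted links agree with a separately coded simulator of the
        same budget update on a randomized window."""
        rng = np.random.default_rng(23)
        calib = injected_calib(baseline=1.0, resolution_mz=0.05, sampling_rate_rt=0.7)
        center = _pt(0, 100.0, 10.0, 500.0)
        members = [
            _pt(
                i + 1,
                float(100.0 + rng.uniform(-0.1, 0.1)),
                float(10.0 + rng.uniform(-1.4, 1.4)),
                float(rng.uniform(1, 499)),
            )
            for i in range(30)
        ]
        window = self._window(center, members, calib)
        links = link_from(center, window, calib)

        budget = 500.0
        expected = []
        for w in window.members:
            if budget <= 0:
                break
            d = math.hypot((w.mz - 100.0) / 0.05, (w.rt - 10.0) / 0.7)
            cost = abs(budget - w.intensity) * d
            expected.append((w.point_id, min(cost, budget), max(min(1 - cost / budget, 1.0), 0.0)))
            budget = max(budget - cost, 0.0)
        assert [(l.child.point_id, l.cost, l.confidence) for l in links] == pytest.approx(expected)


class TestRunLinking:
    def test_empty_filtered_sequence_gives_empty_graph(self, make_run, injected_calib):
        run = make_run([(100.0, 1.0, 1.0)])
        graph = run_linking(run, injected_calib(baseline=5.0))
        assert len(graph) == 0

    def test_star_graph_from_single_seed(self, make_run, injected_calib):
        calib = injected_calib(baseline=10.0, resolution_mz=0.01, sampling_rate_rt=1.0)
        # seed at 100 (above threshold 20); 7 children between baseline and
        # threshold inside the window; nothing else above baseline
        # children sit close to the seed so the budget survives all 7 links
        triples = [(100.0, 10.0, 100.0)]
        for i in range(7):
            triples.append((100.0 + 0.0005 * (i + 1), 10.0, 12.0 + i))
        triples.append((105.0, 10.0, 5.0))  # below baseline
        triples.append((105.0, 11.0, 5.0))  # second scan
        run = make_run(triples)
        graph = run_linking(run, calib)
        seed = max(run.iter_points(), key=lambda p: p.intensity)
        assert len(graph) == 7
        assert all(l.parent.point_id == seed.point_id for l in graph.links)

    def test_deterministic_graph(self, make_run):
        run = scenario("crowded").run
        calib = calibrate(run)
        g1, g2 = run_linking(run, calib), run_linking(run, calib)
        key = lambda l: (l.parent.point_id, l.child.point_id)
        assert sorted(key(l) for l in g1.links) == sorted(key(l) for l in g2.links)
        assert [l.confidence for l in sorted(g1.links, key=key)] == [
            l.confidence for l in sorted(g2.links, key=key)
        ]


class TestLinkGraph:
    def test_rejects_self_links_and_duplicates(self):
        a, b = _pt(0, 100.0, 1.0, 10.0), _pt(1, 100.0, 2.0, 5.0)
        g = LinkGraph()
        with pytest.raises(ValueError):
            g.add(Link(a, a, 0.0, 1.0, 0.0))
        g.add(Link(a, b, 1.0, 0.5, 1.0))
        with pytest.raises(ValueError):
            g.add(Link(a, b, 2.0, 0.4, 1.0))


def _star_graph(n_children, root_intensity=100.0, child_intensity=30.0):
    root = _pt(0, 100.0, 10.0, root_intensity)
    graph = LinkGraph()
    children = [
        _pt(i + 1, 100.0, 10.0 + 0.1 * (i + 1), child_intensity - i)
        for i in range(n_children)
    ]
    for c in children:
        graph.add(Link(root, c, 1.0, 0.9, 0.5))
    return root, children, graph


class TestExtractXics:
    def test_star_becomes_single_xic_with_root_apex(self, injected_calib):
        root, children, graph = _star_graph(6)
        (xic,) = extract_xics(graph, injected_calib(baseline=10.0))
        assert xic.n_points == 7
        assert xic.root.point_id == 0
        assert xic.apex.point_id == 0

    @pytest.mark.parametrize(
        "mode,n_points,expect_kept",
        [
            ("centroid", 5, False),
            ("centroid", 6, True),
            ("profile", 15, False),
            ("profile", 16, True),
        ],
    )
    def test_size_filter_boundaries(self, injected_calib, mode, n_points, expect_kept):
        """Putative XICs must exceed 5 points (centroid) / 15 (profile)."""
        root, children, graph = _star_graph(n_points - 1)
        xics = extract_xics(graph, injected_calib(baseline=10.0, mode=mode))
        assert (len(xics) == 1) is expect_kept

    def test_child_follows_highest_confidence_link(self, injected_calib):
        rootA, childrenA, graph = _star_graph(6)
        rootB = _pt(50, 100.0, 12.0, 90.0)
        for i, c in enumerate(
            [_pt(60 + i, 100.0, 12.0 + 0.1 * i, 25.0 - i) for i in range(6)]
        ):
            graph.add(Link(rootB, c, 1.0, 0.9, 0.5))
        # contested child: 0.8 from A's root, 0.6 from B's root
        contested = _pt(99, 100.0, 11.0, 20.0)
        graph.add(Link(rootA, contested, 1.0, 0.8, 0.5))
        graph.add(Link(rootB, contested, 1.0, 0.6, 0.5))
        xics = extract_xics(graph, injected_calib(baseline=10.0))
        by_root = {x.root.point_id: x for x in xics}
        assert 99 in {p.point_id for p in by_root[0].points}
        assert 99 not in {p.point_id for p in by_root[50].points}

    def test_tree_rooted_below_seed_threshold_discarded(self, injected_calib):
        root, children, graph = _star_graph(6, root_intensity=19.0)
        assert extract_xics(graph, injected_calib(baseline=10.0)) == []

    def test_point_sets_disjoint(self, injected_calib):
        rootA, _, graph = _star_graph(6)
        rootB = _pt(50, 100.0, 12.0, 90.0)
        for i in range(6):
            c = _pt(60 + i, 100.0, 12.0 + 0.1 * i, 25.0 - i)
            graph.add(Link(rootB, c, 1.0, 0.9, 0.5))
            graph.add(Link(rootA, c, 1.0, 0.3, 0.5))
        xics = extract_xics(graph, injected_calib(baseline=10.0))
        all_ids = [pid for x in xics for pid in x.point_ids()]
        assert len(all_ids) == len(set(all_ids))


class TestExtractPipeline:
    def test_pure_noise_run_yields_no_xics(self, make_run):
        # constant intensities: baseline equals the constant, so no point
        # can reach twice the baseline and nothing may seed
        run = make_run(
            [(100.0 + 0.01 * i, 1.0 + 0.5 * s, 10.0) for s in range(10) for i in range(20)]
        )
        assert extract(run, mode_override="centroid") == []

    def test_deconvolves_bimodal_trace_into_two_xics(self):
        sim = scenario("bimodal")
        calib = calibrate(sim.run)
        xics = extract(sim.run)
        region = [
            x
            for x in xics
            if abs(x.apex.mz - 150.0) <= 2 * calib.resolution_mz
        ]
        assert len(region) == 2
        apex_rts = sorted(x.apex.rt for x in region)
        assert abs(apex_rts[0] - 60.0) < 2.0 and abs(apex_rts[1] - 78.0) < 2.0

    def test_sub_threshold_points_are_inert(self, make_run, injected_calib):
        """With an injected calibration, adding points below the baseline
        does not change the extracted XIC set."""
        calib = injected_calib(baseline=10.0, resolution_mz=0.01, sampling_rate_rt=1.0)
        triples = [(100.0, 10.0, 100.0)]
        triples += [(100.0 + 0.002 * (i - 3), 10.0 + (i % 3) - 1, 15.0 + i) for i in range(7)]
        run1 = make_run(triples)
        run2 = make_run(
            triples + [(100.0 + 0.001 * i, 10.0, 9.0 - 0.5 * i) for i in range(8)]
        )
        sig = lambda run: sorted(
            (
                tuple(sorted((p.mz, p.rt, p.intensity) for p in x.points)),
                (x.root.mz, x.root.rt, x.root.intensity),
            )
            for x in extract_xics(run_linking(run, calib), calib)
        )
        assert sig(run1) == sig(run2)

    def test_repeated_extraction_is_byte_identical(self, tmp_path):
        from xiclink.io import write_xic_table

        run = scenario("low_contrast").run
        paths = []
        for i in range(2):
            xics = extract(run)
            p = tmp_path / f"out{i}.csv"
            write_xic_table(xics, p, "points_csv")
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_structural_invariants_on_crowded_run(self):
        sim = scenario("crowded")
        calib = calibrate(sim.run)
        graph = run_linking(sim.run, calib)
        assert all(0.0 <= l.confidence <= 1.0 for l in graph.links)
        xics = extract_xics(graph, calib)
        seen = set()
        for x in xics:
            ids = x.point_ids()
            assert not (ids & seen)
            seen |= ids
            assert all(p.intensity >= calib.baseline for p in x.points)
            assert x.apex.point_id == x.root.point_id
            assert max(p.intensity for p in x.points) == x.root.intensity
        # window locality of every kept link
        kept = {}
        for child_id, incoming in graph.by_child.items():
            kept[child_id] = min(
                incoming,
                key=lambda l: (-l.confidence, -l.parent.intensity, l.distance, l.parent.point_id),
            )
        for link in kept.values():
            assert abs(link.parent.mz - link.child.mz) <= 2 * calib.resolution_mz + 1e-12
            assert abs(link.parent.rt - link.child.rt) <= 2 * calib.sampling_rate_rt + 1e-9
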