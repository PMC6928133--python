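"""Lesion-set construction: CPVI rings, linear lines, CFAE selection."""

import numpy as np
import pytest

from vablate import (
    PROTOCOL_NAMES,
    build_cfae_lesions,
    build_cpvi,
    build_linear_lesions,
    build_protocol_lesions,
)
from vablate.cfae import CfaeMap
from vablate.lesions import (
    _conduction_graph,
    _multi_source_distance,
    linear_lesion_paths,
    separates,
)
from vablate import rectangular_strip


@pytest.fixture(scope="module")
def cpvi(la_mesh):
    return build_cpvi(la_mesh)


def _fake_map(cl: np.ndarray) -> CfaeMap:
    cl = np.asarray(cl, dtype=float)
    counts = np.where(np.isfinite(cl), 5, 1)
    return CfaeMap(cl, counts, (0.0, 1000.0))


def _oracle_greedy(mesh, cl, threshold, cap_fraction):
    """Independent sort-and-accumulate implementation."""
    conductive = mesh.conductive_nodes
    total = mesh.node_area[conductive].sum()
    cand = [
        (cl[i], i)
        for i in conductive
        if np.isfinite(cl[i]) and cl[i] < threshold
    ]
    cand.sort()
    cap = cap_fraction * total
    eps = 1e-9 * max(cap, 1.0)
    chosen, cum = [], 0.0
    for _, i in cand:
        if cum + mesh.node_area[i] >= cap - eps:
            break
        chosen.append(i)
        cum += mesh.node_area[i]
    return np.asarray(sorted(chosen), dtype=np.int64)


class TestCpvi:
    def test_rings_are_closed_by_graph_separation(self, la_mesh, cpvi):
        lm = la_mesh.surface.landmark_sets
        g = _conduction_graph(la_mesh)
        for pair in (("LSPV", "LIPV"), ("RSPV", "RIPV")):
            pv = np.union1d(lm[pair[0]], lm[pair[1]])
            pv = pv[~la_mesh.nonconductive_mask[pv]]
            d = _multi_source_distance(g, pv)
            body = np.array([int(np.nanargmax(np.where(np.isfinite(d), d, -1)))])
            assert separates(la_mesh, cpvi.nodes, pv, body)

    def test_pv_side_nodes_survive(self, la_mesh, cpvi):
        # the veins are isolated, not ablated wholesale
        lm = la_mesh.surface.landmark_sets
        for name in ("LSPV", "RSPV", "LIPV", "RIPV"):
            pv = lm[name][~la_mesh.nonconductive_mask[lm[name]]]
            assert len(np.setdiff1d(pv, cpvi.nodes)) > 0

    def test_ring_nonempty_and_conductive(self, la_mesh, cpvi):
        assert len(cpvi.nodes) > 0
        assert not la_mesh.nonconductive_mask[cpvi.nodes].any()

    def test_area_bookkeeping(self, la_mesh, cpvi):
        assert cpvi.area_mm2 == pytest.approx(
            la_mesh.node_area[cpvi.nodes].sum(), rel=1e-12
        )


class TestLinearLesions:
    def test_paths_anchor_on_rings_and_annulus(self, la_mesh, cpvi):
        v = la_mesh.surface.vertices
        ann = la_mesh.surface.landmark_sets["mitral_annulus"]
        # LLI runs from the LIPV ring to the annulus boundary
        (path,) = linear_lesion_paths(la_mesh, "LLI", cpvi)
        assert path[0] in cpvi.nodes
        d_end = np.linalg.norm(v[ann] - v[path[-1]], axis=1).min()
        assert d_end < 6.0
        # AL starts at the anterior annulus and ends on the RSPV ring
        (path,) = linear_lesion_paths(la_mesh, "AL", cpvi)
        d_start = np.linalg.norm(v[ann] - v[path[0]], axis=1).min()
        assert d_start < 6.0
        assert path[-1] in cpvi.nodes

    def test_dilation_contract(self, la_mesh, cpvi):
        # every lesion node lies within width/2 of the centre path
        for which in ("RL", "AL", "LLI"):
            lesion = build_linear_lesions(la_mesh, which, cpvi)
            paths = linear_lesion_paths(la_mesh, which, cpvi)
            centre = np.concatenate([np.asarray(p) for p in paths])
            g = _conduction_graph(la_mesh)
            d = _multi_source_distance(g, centre)
            assert np.all(d[lesion.nodes] <= 0.5 * lesion.width_mm + 1e-9)
            assert len(lesion.nodes) > 0

    def test_pobi_closes_posterior_box(self, la_mesh, cpvi):
        pobi = build_linear_lesions(la_mesh, "POBI", cpvi)
        combined = np.union1d(cpvi.nodes, pobi.nodes)
        lm = la_mesh.surface.landmark_sets
        v = la_mesh.surface.vertices
        # posterior-wall point: centroid of the four PV directions
        post_centre = np.mean(
            [v[lm[n]].mean(axis=0) for n in ("LSPV", "LIPV", "RSPV", "RIPV")], axis=0
        )
        free = np.setdiff1d(la_mesh.conductive_nodes, combined)
        inside = np.array([free[np.argmin(np.linalg.norm(v[free] - post_centre, axis=1))]])
        anterior = lm["bachmann_site"]
        anterior = anterior[~la_mesh.nonconductive_mask[anterior]]
        assert separates(la_mesh, combined, inside, anterior)

    def test_unknown_lesion_rejected(self, la_mesh):
        with pytest.raises(ValueError):
            build_linear_lesions(la_mesh, "XYZ")


class TestCfaeSelection:
    def test_matches_oracle_on_random_maps(self, small_strip, rng):
        n = small_strip.n_nodes
        for _ in range(100):
            # quantized CLs force ties; some nodes undefined
            cl = rng.choice([80.0, 95.0, 110.0, 119.0, 130.0, np.inf], size=n)
            ours = build_cfae_lesions(small_strip, _fake_map(cl))
            ref = _oracle_greedy(small_strip, cl, 120.0, 0.05)
            assert np.array_equal(np.sort(ours.nodes), ref)

    def test_two_region_map_prefers_lower_cl(self, small_strip):
        n = small_strip.n_nodes
        cl = np.full(n, 130.0)
        cl[: n // 4] = 100.0
        lesion = build_cfae_lesions(small_strip, _fake_map(cl))
        assert len(lesion.nodes) > 0
        assert np.all(cl[lesion.nodes] == 100.0)

    def test_all_above_threshold_empty(self, small_strip):
        cl = np.full(small_strip.n_nodes, 125.0)
        lesion = build_cfae_lesions(small_strip, _fake_map(cl))
        assert len(lesion.nodes) == 0
        assert lesion.area_mm2 == 0.0

    def test_area_cap_strictly_respected(self, small_strip):
        cl = np.full(small_strip.n_nodes, 60.0)  # everything eligible
        lesion = build_cfae_lesions(small_strip, _fake_map(cl))
        total = small_strip.node_area[small_strip.conductive_nodes].sum()
        assert 0 < lesion.area_mm2 < 0.05 * total


class TestProtocols:
    def test_composability_superset(self, la_mesh):
        a = build_protocol_lesions(la_mesh, "CPVI+POBI")
        b = build_protocol_lesions(la_mesh, "CPVI+POBI+AL")
        assert np.all(np.isin(a.nodes, b.nodes))

    def test_all_protocols_constructible(self, la_mesh):
        cl = np.full(la_mesh.n_nodes, 100.0)
        cfae_map = CfaeMap(cl, np.full(la_mesh.n_nodes, 5), (0.0, 1000.0))
        for name in PROTOCOL_NAMES:
            lesion = build_protocol_lesions(la_mesh, name, cfae_map=cfae_map)
            assert len(lesion.nodes) > 0
            assert lesion.area_mm2 == pytest.approx(
                la_mesh.node_area[lesion.nodes].sum(), rel=1e-12
            )

    def test_cfae_protocol_requires_map(self, la_mesh):
        with pytest.raises(ValueError, match="map"):
            build_protocol_lesions(la_mesh, "CPVI+CFAE")

    def test_unknown_protocol_rejected(self, la_mesh):
        with pytest.raises(ValueError):
            build_protocol_lesions(la_mesh, "PVI")
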