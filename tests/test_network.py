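"""Connectivity: geometric fanout vs brute force, normalization, wiring."""

import numpy as np
import pytest

from spindlenet.network import (
    ConnectionRule,
    Network,
    NetworkSpec,
    Population,
    build_network,
    fanout_targets,
    normalize_weight,
)


def brute_force_targets(i, radius, ns, nt, exclude_self=False):
    """Independent geometric oracle: scan every target index."""
    out = []
    for j in range(nt):
        if abs(j / nt - i / ns) <= radius / ns + 1e-12:
            if exclude_self and j == i:
                continue
            out.append(j)
    return out


class TestFanout:
    def test_printed_example_101_targets(self):
        # thalamic source 100/200 with radius 10 onto 1000 cortical cells
        t = fanout_targets(100, 10.0, 200, 1000)
        assert len(t) == 101
        assert t[0] == 450 and t[-1] == 550

    def test_radius_zero_aligned_cell(self):
        assert list(fanout_targets(7, 0.0, 50, 50)) == [7]
        assert list(fanout_targets(7, 0.0, 50, 50, exclude_self=True)) == []

    def test_edge_truncation(self):
        interior = len(fanout_targets(25, 5.0, 50, 50))
        edge = len(fanout_targets(0, 5.0, 50, 50))
        assert edge < interior

    @pytest.mark.parametrize("ns,nt,radius", [
        (10, 50, 2.0), (50, 10, 2.0), (20, 20, 3.0), (7, 31, 1.5),
        (30, 6, 0.4),
    ])
    def test_matches_brute_force(self, ns, nt, radius):
        for i in range(ns):
            got = list(fanout_targets(i, radius, ns, nt))
            want = brute_force_targets(i, radius, ns, nt)
            assert got == want, f"source {i}"

    def test_bad_index_rejected(self):
        with pytest.raises(ValueError):
            fanout_targets(10, 1.0, 10, 10)


class TestNormalization:
    def test_single_input_gets_total(self):
        assert normalize_weight(0.6, 1) == 0.6

    def test_arithmetic(self):
        assert normalize_weight(0.15, 21) == pytest.approx(0.15 / 21)

    def test_no_inputs_rejected(self):
        with pytest.raises(ValueError):
            normalize_weight(0.6, 0)

    def test_doubling_radius_halves_weight(self):
        pops = [Population("PY_L34", 40)]
        w = {}
        for radius in (4.0, 8.0):
            net = Network(pops, [ConnectionRule("PY_L34", "PY_L34", "AMPA",
                                                radius, 0.6)])
            interior = net.post_idx == 20
            w[radius] = net.weight[interior].mean()
        ratio = w[4.0] / w[8.0]
        # 8 vs 16 inputs for an interior cell (within one count quantum)
        assert ratio == pytest.approx(2.0, rel=0.15)

    def test_total_conductance_conserved(self):
        # sum of normalized weights onto each interior target equals g_total
        # regardless of radius
        pops = [Population("PY_L34", 60), Population("IN_L34", 60)]
        for radius in (2.0, 5.0, 9.0):
            net = Network(pops, [ConnectionRule("PY_L34", "IN_L34", "AMPA",
                                                radius, 0.2)])
            sums = np.bincount(net.post_idx, weights=net.weight, minlength=60)
            interior = sums[15:45]
            np.testing.assert_allclose(interior, 0.2, rtol=1e-12)


@pytest.fixture(scope="module")
def small():
    return NetworkSpec().scaled(25.0)  # 40 PY / layer, 8 TC & RE / system


@pytest.fixture(scope="module")
def net(small):
    return build_network(small)


class TestBuildNetwork:

    def test_no_cross_system_thalamic_edges(self, net):
        names = [p.name for p in net.populations]
        core = {names.index("TC_core"), names.index("RE_core")}
        matrix = {names.index("TC_matrix"), names.index("RE_matrix")}
        pre_core = np.isin(net.pre_pop, list(core))
        post_matrix = np.isin(net.post_pop, list(matrix))
        assert not np.any(pre_core & post_matrix)
        pre_matrix = np.isin(net.pre_pop, list(matrix))
        post_core = np.isin(net.post_pop, list(core))
        assert not np.any(pre_matrix & post_core)

    def test_cross_system_rule_rejected(self, small):
        rules = [ConnectionRule("TC_core", "RE_matrix", "AMPA", 1.0, 0.06)]
        with pytest.raises(ValueError, match="cross-system"):
            Network(small.populations(), rules)

    def test_deterministic_rebuild(self, small):
        a = build_network(small)
        b = build_network(small)
        np.testing.assert_array_equal(a.pre_idx, b.pre_idx)
        np.testing.assert_array_equal(a.post_idx, b.post_idx)
        np.testing.assert_array_equal(a.weight, b.weight)

    def test_core_tc_inputs_match_oracle(self, small, net):
        # every PY_L34 cell's TC_core inputs equal the brute-force enumeration
        ri = next(i for i, r in enumerate(net.rules)
                  if r.source == "TC_core" and r.target == "PY_L34")
        rule = net.rules[ri]
        sel = net.edges_for_rule(ri)
        got = {(int(a), int(b))
               for a, b in zip(net.pre_idx[sel], net.post_idx[sel])}
        ns, nt = net.size("TC_core"), net.size("PY_L34")
        want = {(i, j) for i in range(ns)
                for j in brute_force_targets(i, rule.radius, ns, nt)}
        assert got == want

    def test_intrathalamic_reciprocity(self, net):
        # every TC cell has at least one RE input and one RE output
        for system in ("core", "matrix"):
            tc, re = f"TC_{system}", f"RE_{system}"
            names = [p.name for p in net.populations]
            tc_i, re_i = names.index(tc), names.index(re)
            inputs = set(net.post_idx[(net.pre_pop == re_i) & (net.post_pop == tc_i)])
            outputs = set(net.pre_idx[(net.pre_pop == tc_i) & (net.post_pop == re_i)])
            assert inputs == set(range(net.size(tc)))
            assert outputs == set(range(net.size(tc)))

    def test_weights_follow_conductance_table(self, net):
        # normalized per-target totals equal the rule total for every rule,
        # on targets receiving at least one input
        for ri, rule in enumerate(net.rules):
            sel = net.edges_for_rule(ri)
            sums = np.bincount(net.post_idx[sel], weights=net.weight[sel],
                               minlength=net.size(rule.target))
            nonzero = sums[sums > 0]
            np.testing.assert_allclose(nonzero, rule.g_total, rtol=1e-9,
                                       err_msg=str(rule))

    def test_gaba_reversals_by_target(self, net):
        df = net.to_dataframe()
        tc_gaba = df[(df.receptor == "GABA_A") & (df.target_pop.str.startswith("TC"))]
        re_gaba = df[(df.receptor == "GABA_A") & (df.target_pop.str.startswith("RE"))]
        py_gaba = df[(df.receptor == "GABA_A") & (df.target_pop.str.startswith("PY"))]
        assert (tc_gaba.e_syn == -85.0).all()
        assert (re_gaba.e_syn == -70.0).all()
        assert (py_gaba.e_syn == -70.0).all()
        assert (df[df.receptor == "GABA_B"].e_syn == -95.0).all()

    def test_depression_only_intracortical_excitatory(self, net):
        df = net.to_dataframe()
        dep = df[df.depressing]
        assert set(dep.receptor) <= {"AMPA", "NMDA"}
        assert dep.source_pop.str.startswith("PY").all()
        assert dep.target_pop.str.startswith("PY").all()

    def test_fanout_ratio_helper(self):
        spec = NetworkSpec().with_fanout_ratio(5.0)
        assert spec.radius_tc_matrix == 50.0
        assert spec.radius_ct_matrix == 10.0
        assert spec.fanout_ratio == 5.0

    def test_matrix_weights_weaker_than_core(self, net):
        # broader matrix fanout with the same totals means weaker synapses
        df = net.to_dataframe()
        w_core = df[(df.source_pop == "TC_core") & (df.target_pop == "PY_L34")
                    ].weight.mean()
        w_matrix = df[(df.source_pop == "TC_matrix") & (df.target_pop == "PY_L5")
                      ].weight.mean()
        assert w_matrix < w_core
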