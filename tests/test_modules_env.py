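"""Tests for module detection, Zi/Pi roles, eigenvalues, and Mantel tests."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from planknet.errors import SizeError, ValidationError
from planknet.modules_env import (
    ModulePartition,
    classify_role,
    detect_modules,
    mantel_connectivity_significance,
    module_env_correlation,
    module_eigenvalue,
    pair_preserved_modules,
    species_significance,
    zi_pi,
)
from planknet.netinfer import BipartiteNetwork
from planknet.tables_io import EnvironmentTable

from .conftest import make_net, random_bipartite_net


def _two_block_net(bridge=True):
    guilds, edges = {}, []
    for block in range(2):
        ps = [f"p{block}{i}" for i in range(4)]
        zs = [f"z{block}{i}" for i in range(4)]
        guilds.update(dict.fromkeys(ps, "phytoplankton"))
        guilds.update(dict.fromkeys(zs, "zooplankton"))
        edges += [(p, z, 0.9) for p in ps for z in zs]
    if bridge:
        edges.append(("p00", "z10", 0.31))
    return make_net(edges, guilds)


class TestDetectModules:
    def test_planted_blocks_recovered(self):
        net = _two_block_net()
        part = detect_modules(net, seed=0)
        blocks = {}
        for node, mid in part.assignment.items():
            blocks.setdefault(mid, set()).add(node[1])
        assert len(part.module_ids) == 2
        for members in blocks.values():
            assert len(members) == 1  # each module pure in block label

    def test_single_edge_one_module(self):
        net = make_net([("p", "z")],
                       {"p": "phytoplankton", "z": "zooplankton"})
        part = detect_modules(net)
        assert part.module_ids == [0]

    def test_deterministic(self):
        net = _two_block_net()
        assert detect_modules(net, seed=1).assignment == \
            detect_modules(net, seed=2).assignment

    def test_empty_network_rejected(self):
        with pytest.raises(ValidationError):
            detect_modules(BipartiteNetwork(nx.Graph()))

    def test_small_modules_flagged(self):
        net = make_net([("p", "z")],
                       {"p": "phytoplankton", "z": "zooplankton"})
        part = detect_modules(net)
        assert part.small_modules == [0]


class TestZiPi:
    def test_all_edges_inside_module_pi_zero(self):
        net = _two_block_net(bridge=False)
        part = detect_modules(net)
        for rec in zi_pi(net, part):
            assert rec.pi == 0.0

    def test_mean_degree_node_zi_zero(self):
        # complete block: all within-module degrees equal -> sd = 0 -> Zi = 0
        net = _two_block_net(bridge=False)
        part = detect_modules(net)
        assert all(rec.zi == 0.0 for rec in zi_pi(net, part))

    @pytest.mark.parametrize(
        "zi, pi, role", [
            (3.0, 0.5, "module hub"),
            (3.0, 0.7, "network hub"),
            (2.0, 0.7, "connector"),
            (2.0, 0.5, "peripheral"),
            (2.5, 0.62, "peripheral"),   # both thresholds are inclusive-left
            (2.5000001, 0.62, "module hub"),
            (2.5, 0.6200001, "connector"),
        ],
    )
    def test_role_thresholds(self, zi, pi, role):
        assert classify_role(zi, pi) == role

    def test_keystone_is_non_peripheral(self):
        net = _two_block_net()
        part = detect_modules(net)
        for rec in zi_pi(net, part):
            assert rec.is_keystone == (rec.role != "peripheral")

    def test_brute_force_equivalence(self):
        # independent recomputation from the raw edge list
        rng = np.random.default_rng(0)
        for trial in range(30):
            net = random_bipartite_net(rng, n_a=6, n_b=6, p_edge=0.4)
            nodes = sorted(net.graph.nodes)
            assignment = {n: int(rng.integers(0, 3)) for n in nodes}
            part = ModulePartition(assignment, 0.0)
            records = {r.node: r for r in zi_pi(net, part)}
            for node in nodes:
                own = assignment[node]
                members = [n for n in nodes if assignment[n] == own]
                k_own = {
                    m: sum(1 for nb in net.graph.neighbors(m)
                           if assignment[nb] == own)
                    for m in members
                }
                vals = np.array(list(k_own.values()), dtype=float)
                zi = (0.0 if vals.std() == 0
                      else (k_own[node] - vals.mean()) / vals.std())
                k_i = net.graph.degree(node)
                by_mod = {}
                for nb in net.graph.neighbors(node):
                    by_mod[assignment[nb]] = by_mod.get(assignment[nb], 0) + 1
                pi = 1.0 - sum((k / k_i) ** 2 for k in by_mod.values())
                assert records[node].zi == pytest.approx(zi, abs=1e-12)
                assert records[node].pi == pytest.approx(pi, abs=1e-12)
                assert 0.0 <= records[node].pi < 1.0

    def test_partition_must_cover(self):
        net = _two_block_net()
        with pytest.raises(ValidationError, match="cover"):
            zi_pi(net, ModulePartition({"p00": 0}, 0.0))


class TestModuleEigenvalue:
    def _abundance(self, data, samples=None):
        samples = samples or [f"s{i}" for i in range(len(next(iter(data.values()))))]
        return pd.DataFrame(data, index=samples)

    def test_single_species_equals_zscore(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(size=50)
        df = self._abundance({"a": x})
        eig = module_eigenvalue(["a"], df)
        z = (x - x.mean()) / x.std()
        np.testing.assert_allclose(eig.series.to_numpy(), z, atol=1e-10)
        assert eig.variance_explained == pytest.approx(1.0)

    def test_two_perfectly_correlated_members(self):
        rng = np.random.default_rng(2)
        x = rng.lognormal(size=50)
        df = self._abundance({"a": x, "b": 3.0 * x})
        eig = module_eigenvalue(["a", "b"], df)
        assert eig.variance_explained == pytest.approx(1.0)
        r = np.corrcoef(eig.series, x)[0, 1]
        assert abs(r) == pytest.approx(1.0)
        assert r > 0  # orientation: positive vs mean member profile

    def test_unit_variance(self):
        rng = np.random.default_rng(3)
        df = self._abundance({c: rng.lognormal(size=40) for c in "abcd"})
        eig = module_eigenvalue(list("abcd"), df)
        assert eig.series.to_numpy().std() == pytest.approx(1.0, rel=1e-6)

    def test_missing_member_listed(self):
        df = self._abundance({"a": np.ones(5)})
        with pytest.raises(ValidationError, match="ghost"):
            module_eigenvalue(["a", "ghost"], df)


class TestModuleEnvCorrelation:
    def _env(self, data, samples):
        return EnvironmentTable(pd.DataFrame(data, index=samples))

    def test_identity_series(self):
        rng = np.random.default_rng(4)
        samples = [f"s{i}" for i in range(60)]
        y = rng.normal(size=60)
        env = self._env({"temperature": y}, samples)
        from planknet.modules_env import ModuleEigen
        eig = ModuleEigen(0, pd.Series(y, index=samples), 1.0)
        out = module_env_correlation(eig, env)
        assert out["temperature"]["r"] == pytest.approx(1.0)
        assert out["temperature"]["stars"] == "***"

    def test_antisymmetry(self):
        rng = np.random.default_rng(5)
        samples = [f"s{i}" for i in range(60)]
        y = rng.normal(size=60)
        series = rng.normal(size=60)
        env = self._env({"pH": y}, samples)
        from planknet.modules_env import ModuleEigen
        r_pos = module_env_correlation(
            ModuleEigen(0, pd.Series(series, index=samples), 1.0), env
        )["pH"]["r"]
        r_neg = module_env_correlation(
            ModuleEigen(0, pd.Series(-series, index=samples), 1.0), env
        )["pH"]["r"]
        assert r_neg == pytest.approx(-r_pos)

    def test_constant_factor_flagged(self):
        samples = [f"s{i}" for i in range(10)]
        env = self._env({"pH": np.ones(10)}, samples)
        from planknet.modules_env import ModuleEigen
        rng = np.random.default_rng(6)
        out = module_env_correlation(
            ModuleEigen(0, pd.Series(rng.normal(size=10), index=samples), 1.0),
            env,
        )
        assert not out["pH"]["defined"]

    def test_independent_series_rarely_starred(self):
        rng = np.random.default_rng(7)
        samples = [f"s{i}" for i in range(200)]
        from planknet.modules_env import ModuleEigen
        starred = 0
        for _ in range(40):
            env = self._env({"DO": rng.normal(size=200)}, samples)
            eig = ModuleEigen(0, pd.Series(rng.normal(size=200),
                                           index=samples), 1.0)
            if module_env_correlation(eig, env)["DO"]["stars"]:
                starred += 1
        assert starred / 40 <= 0.15


class TestPairPreservedModules:
    def _partition(self, groups):
        assignment = {n: mid for mid, members in groups.items()
                      for n in members}
        return ModulePartition(assignment, 0.0)

    def test_identical_partitions_fully_paired(self):
        part = self._partition({0: ["a", "b"], 1: ["c", "d", "e"]})
        pairs = pair_preserved_modules(part, part)
        selected = [p for p in pairs if p.paired]
        assert {(p.module_small, p.module_big) for p in selected} == \
            {(0, 0), (1, 1)}
        assert all(p.overlap == 1.0 for p in selected)

    def test_disjoint_no_pairs(self):
        a = self._partition({0: ["a", "b"]})
        b = self._partition({0: ["x", "y"]})
        assert pair_preserved_modules(a, b) == []

    def test_boundary_overlap_half_pairs(self):
        a = self._partition({0: ["1", "2", "3", "4"]})
        b = self._partition({0: ["1", "2", "9", "10", "11", "12"]})
        pairs = pair_preserved_modules(a, b)
        assert len(pairs) == 1
        assert pairs[0].overlap == pytest.approx(0.5)
        assert pairs[0].paired

    def test_greedy_one_to_one(self):
        a = self._partition({0: ["x", "y"], 1: ["x2", "y2"]})
        b = self._partition({0: ["x", "y", "x2", "y2"]})
        pairs = pair_preserved_modules(a, b)
        selected = [p for p in pairs if p.paired]
        assert len(selected) == 1  # big module used at most once
        assert len(pairs) == 2     # both candidates reported

    def test_relabeling_invariance(self):
        a = self._partition({0: ["a", "b", "c"], 1: ["d", "e"]})
        b = self._partition({0: ["a", "b"], 1: ["d", "e", "f"]})
        b_relab = self._partition({5: ["a", "b"], 2: ["d", "e", "f"]})
        # dense ids are reassigned by ModulePartition consumers; compare via
        # member sets rather than raw ids
        pairs1 = {
            (frozenset(a.members(p.module_small)),
             frozenset(b.members(p.module_big)))
            for p in pair_preserved_modules(a, b) if p.paired
        }
        pairs2 = {
            (frozenset(a.members(p.module_small)),
             frozenset(b_relab.members(p.module_big)))
            for p in pair_preserved_modules(a, b_relab) if p.paired
        }
        assert pairs1 == pairs2

    def test_jaccard_option(self):
        a = self._partition({0: ["1", "2"]})
        b = self._partition({0: ["1", "2", "3", "4", "5"]})
        assert pair_preserved_modules(a, b)[0].overlap == 1.0
        # jaccard overlap 2/5 < 0.5 -> no candidate
        assert pair_preserved_modules(a, b, denominator="jaccard") == []


class TestMantel:
    def _setup(self, n_species=8, n_samples=60, seed=0, couple=False):
        rng = np.random.default_rng(seed)
        species = [f"z{i}" for i in range(n_species)]
        guilds = dict.fromkeys(species, "zooplankton")
        guilds["p0"] = "phytoplankton"
        edges = [("p0", s) for s in species]
        # extra phytoplankton partners give the zooplankton varying degrees
        for i, s in enumerate(species):
            for j in range(i % 4):
                ph = f"q{i}_{j}"
                guilds[ph] = "phytoplankton"
                edges.append((ph, s))
        net = make_net(edges, guilds)
        samples = [f"s{i}" for i in range(n_samples)]
        temp = rng.normal(size=n_samples)
        density = {}
        for i, s in enumerate(species):
            if couple:
                # significance (r^2 with temperature) increases with degree
                k = net.graph.degree(s)
                x = 10.0 + 0.5 * k * temp + rng.normal(scale=0.5,
                                                       size=n_samples)
                density[s] = np.clip(x, 0.0, None)
            else:
                density[s] = rng.lognormal(size=n_samples)
        abundance = pd.DataFrame(density, index=samples)
        env = EnvironmentTable(
            pd.DataFrame({"temperature": temp,
                          "NO3N": rng.normal(size=n_samples),
                          "NO2N": rng.normal(size=n_samples),
                          "NH4N": rng.normal(size=n_samples)},
                         index=samples)
        )
        return net, abundance, env

    def test_coupled_structure_detected(self):
        net, abundance, env = self._setup(seed=1, couple=True)
        res = mantel_connectivity_significance(
            net, abundance, env, "temperature", "zooplankton",
            n_permutations=199, seed=0,
        )
        assert res.statistic > 0.3
        assert res.p < 0.05

    def test_too_few_species(self):
        net, abundance, env = self._setup(n_species=4)
        with pytest.raises(SizeError):
            mantel_connectivity_significance(net, abundance, env,
                                             "temperature", "zooplankton")

    def test_unknown_group_rejected(self):
        net, abundance, env = self._setup()
        with pytest.raises(ValidationError, match="factor group"):
            species_significance(abundance, env, ["z0"], "chlorophyll")

    def test_determinism(self):
        net, abundance, env = self._setup(seed=2)
        r1 = mantel_connectivity_significance(net, abundance, env, "N",
                                              "zooplankton",
                                              n_permutations=99, seed=5)
        r2 = mantel_connectivity_significance(net, abundance, env, "N",
                                              "zooplankton",
                                              n_permutations=99, seed=5)
        assert (r1.statistic, r1.p) == (r2.statistic, r2.p)

    def test_null_pvalues_roughly_uniform(self):
        # KS check on the permutation grid under independence
        pvals = []
        for seed in range(60):
            net, abundance, env = self._setup(seed=100 + seed)
            res = mantel_connectivity_significance(
                net, abundance, env, "N", "zooplankton",
                n_permutations=99, seed=seed,
            )
            pvals.append(res.p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_joint_relabeling_invariance(self):
        net, abundance, env = self._setup(seed=3)
        res1 = mantel_connectivity_significance(
            net, abundance, env, "temperature", "zooplankton",
            n_permutations=99, seed=1,
        )
        # renaming species consistently everywhere leaves R unchanged
        mapping = {s: f"w{i}" for i, s in enumerate(sorted(
            net.nodes_in_guild("zooplankton")))}
        g2 = nx.relabel_nodes(net.graph, mapping)
        net2 = BipartiteNetwork(g2)
        ab2 = abundance.rename(columns=mapping)
        res2 = mantel_connectivity_significance(
            net2, ab2, env, "temperature", "zooplankton",
            n_permutations=99, seed=1,
        )
        assert res2.statistic == pytest.approx(res1.statistic)


class TestSpeciesSignificance:
    def test_squared_correlation_values(self):
        rng = np.random.default_rng(8)
        samples = [f"s{i}" for i in range(50)]
        temp = rng.normal(size=50)
        x = 2.0 * temp + rng.normal(scale=0.1, size=50)
        abundance = pd.DataFrame({"z0": x - x.min() + 0.1}, index=samples)
        env = EnvironmentTable(pd.DataFrame({"temperature": temp},
                                            index=samples))
        sig = species_significance(abundance, env, ["z0"], "temperature")
        expected = np.corrcoef(abundance["z0"], temp)[0, 1] ** 2
        assert sig.at["z0", "temperature"] == pytest.approx(expected)
        assert sig.at["z0", "temperature"] > 0.9
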