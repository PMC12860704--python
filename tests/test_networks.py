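import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipidstat.annotation import annotate_panel
from lipidstat.core import ContractError
from lipidstat.networks import (
    EdgeContingency,
    LipidNetwork,
    debiased_partial_correlations,
    dspc_network,
    edge_contingency_compare,
    export_network,
    ffa_correlation_profile,
    fisher_exact_test,
    fisher_z_pvalue,
    import_edge_csv,
    pearson_network,
)
from lipidstat.synth import generate_ggm

from conftest import make_matrix


def fisher_exact_enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by explicit hypergeometric enumeration."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(x):
        return (
            math.comb(row1, x) * math.comb(row2, col1 - x) / math.comb(n, col1)
        )

    support = range(max(0, col1 - row2), min(row1, col1) + 1)
    p_obs = prob(a)
    return sum(p for x in support if (p := prob(x)) <= p_obs * (1 + 1e-12))


class TestPearsonNetwork:
    def test_fisher_z_degenerate_and_null(self):
        assert fisher_z_pvalue(np.array(0.0), 12) == pytest.approx(1.0)
        # |r| = 1 is clamped, yielding a finite tiny p rather than an error
        assert 0 < fisher_z_pvalue(np.array(1.0), 12) < 1e-10

    def test_fisher_z_monotone(self):
        rs = np.linspace(0.0, 0.95, 20)
        ps = fisher_z_pvalue(rs, 12)
        assert (np.diff(ps) < 0).all()
        assert fisher_z_pvalue(np.array(0.5), 30) < fisher_z_pvalue(np.array(0.5), 10)

    def test_duplicate_feature_edge_r_one(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(12)
        vals = np.vstack([base, base, rng.standard_normal(12)])
        m = make_matrix(vals, stage="zscore", groups=["CTL"] * 12)
        net = pearson_network(m, "CTL")
        dup = net.edges.set_index(["u", "v"]).loc[
            (m.feature_names[0], m.feature_names[1])
        ]
        assert dup["estimate"] == pytest.approx(1.0)
        assert dup["significant"]

    def test_p_matches_permutation_oracle(self):
        """Independent features: Fisher-Z p agrees with a permutation test."""
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal(12), rng.standard_normal(12)
        r_obs = np.corrcoef(x, y)[0, 1]
        perm_r = np.array(
            [np.corrcoef(x, rng.permutation(y))[0, 1] for _ in range(4000)]
        )
        p_perm = (np.sum(np.abs(perm_r) >= abs(r_obs)) + 1) / 4001
        p_fisher = float(fisher_z_pvalue(np.array(r_obs), 12))
        assert p_fisher == pytest.approx(p_perm, abs=0.05)

    def test_small_n_rejected(self):
        m = make_matrix(np.random.default_rng(0).standard_normal((3, 3)),
                        groups=["CTL"] * 3, stage="zscore")
        with pytest.raises(ContractError, match="Fisher Z"):
            pearson_network(m, "CTL")


class TestFfaProfile:
    def test_identical_stratum_r_one(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(12)
        names = ["FFA(18:1)", "FFA(18:2)", "PC(34:2)", "PC(36:2)"]
        vals = np.vstack([base, base, base, base])  # all strata identical
        m = make_matrix(vals + rng.standard_normal((4, 12)) * 1e-9,
                        feature_names=names, stage="zscore", groups=["CTL"] * 12)
        prof = ffa_correlation_profile(m, annotate_panel(names), "CTL", "unsaturated")
        assert prof.loc["unsaturated PC", "r"] == pytest.approx(1.0, abs=1e-6)

    def test_group_restricted_block_detected(self, small_study, small_zscore,
                                             small_annotation):
        """The default study couples unsaturated FFA with TAG in CKD only."""
        prof_ckd = ffa_correlation_profile(
            small_zscore, small_annotation, "CKD", "unsaturated"
        )
        prof_ctl = ffa_correlation_profile(
            small_zscore, small_annotation, "CTL", "unsaturated"
        )
        tag_strata = [s for s in prof_ckd.index if s.endswith("TAG")]
        assert max(prof_ckd.loc[tag_strata, "r"]) > max(prof_ctl.loc[tag_strata, "r"])

    def test_orthogonal_class_usually_below_cutoff(self):
        rng = np.random.default_rng(2)
        hits = 0
        names = ["FFA(18:1)", "FFA(18:2)", "PC(34:2)", "PC(36:2)"]
        for rep in range(60):
            vals = rng.standard_normal((4, 12))
            m = make_matrix(vals, feature_names=names, stage="zscore",
                            groups=["CTL"] * 12)
            prof = ffa_correlation_profile(m, annotate_panel(names), "CTL",
                                           "unsaturated")
            hits += abs(prof["r"]).max() < 0.7
        assert hits >= 0.85 * 60  # two strata tested per rep

    def test_absent_stratum_rejected(self):
        names = ["PC(34:2)", "PC(36:2)"]
        m = make_matrix(np.random.default_rng(0).standard_normal((2, 8)),
                        feature_names=names, stage="zscore", groups=["CTL"] * 8)
        with pytest.raises(ContractError, match="FFA"):
            ffa_correlation_profile(m, annotate_panel(names), "CTL", "unsaturated")


class TestDspc:
    def test_chain_graph_partialization(self):
        """A-B-C chain: marginal A-C correlation present, partial absent."""
        p = 3
        prec = np.array([[1.0, -0.5, 0.0], [-0.5, 1.5, -0.5], [0.0, -0.5, 1.0]])
        m, true_edges = generate_ggm(1000, prec, seed=0)
        net = dspc_network(m, "CTL", alpha=0.1)
        e = net.edges.set_index(["u", "v"])
        ab = e.loc[("V1", "V2")]
        bc = e.loc[("V2", "V3")]
        ac = e.loc[("V1", "V3")]
        assert ab["significant"] and bc["significant"]
        assert abs(ac["estimate"]) < 0.1
        # closed-form check: partial corr of the chain is -prec_ij/sqrt(ii*jj)
        expected_ab = 0.5 / math.sqrt(1.0 * 1.5)
        assert ab["estimate"] == pytest.approx(expected_ab, abs=0.08)

    def test_converges_to_inverse_covariance_estimate(self):
        """n >> p: DSPC approaches the sample partial correlations."""
        rng = np.random.default_rng(8)
        p = 8
        a = rng.standard_normal((p, p)) * 0.3
        prec = a @ a.T + p * np.eye(p)
        d = np.sqrt(np.diag(prec))
        prec = prec / np.outer(d, d)
        m, _ = generate_ggm(2000, prec, seed=8)
        x = m.data.to_numpy().T
        pc, _ = debiased_partial_correlations(x, cv=5, seed=0)
        inv = np.linalg.inv(np.cov(x.T))
        dd = np.sqrt(np.diag(inv))
        pc_sample = -inv / np.outer(dd, dd)
        np.fill_diagonal(pc_sample, 1.0)
        off = ~np.eye(p, dtype=bool)
        assert np.max(np.abs(pc[off] - pc_sample[off])) < 0.05

    def test_null_edge_rate_near_alpha(self):
        """Independent features: flagged-edge fraction is close to alpha."""
        rates = []
        for seed in range(4):
            m, _ = generate_ggm(300, np.eye(10), seed=100 + seed)
            net = dspc_network(m, "CTL", alpha=0.1, cv=5)
            rates.append(net.edges["significant"].mean())
        assert 0.02 <= np.mean(rates) <= 0.2

    def test_small_n_rejected(self):
        m, _ = generate_ggm(5, np.eye(4), seed=0)
        with pytest.raises(ContractError, match="n >= 6"):
            dspc_network(m, "CTL")


class TestEdgeContingency:
    def _net(self, sig_flags, kind="dspc", group="CTL"):
        nodes = ["FFA(18:1)", "A", "B", "C", "D", "E"]
        pairs = [("FFA(18:1)", x) for x in nodes[1:]] + [("A", "B")]
        edges = pd.DataFrame(
            {
                "u": [p[0] for p in pairs],
                "v": [p[1] for p in pairs],
                "estimate": 0.5,
                "p": 0.05,
                "q": 0.1,
                "significant": list(sig_flags) + [False] * (len(pairs) - len(sig_flags)),
            }
        )
        return LipidNetwork(nodes=nodes, edges=edges, kind=kind,
                            group_label=group, n_samples=10)

    def test_balanced_table_p_one(self):
        orr, p = fisher_exact_test(EdgeContingency(1, 1, 1, 1))
        assert p == pytest.approx(1.0)

    def test_identical_networks(self):
        a = self._net([True, True, False, False, False])
        table, orr, p = edge_contingency_compare(a, a, ["FFA(18:1)"])
        assert p == pytest.approx(1.0)
        assert orr == pytest.approx(1.0)
        assert table.a == table.c == 2
        assert table.a + table.b + table.c + table.d == 2 * 5  # FFA-incident universe

    def test_matches_hypergeometric_enumeration(self):
        for a, b, c, d in [(5, 1, 1, 5), (3, 7, 6, 4), (0, 5, 5, 0), (2, 2, 2, 2)]:
            _, p = fisher_exact_test(EdgeContingency(a, b, c, d))
            assert p == pytest.approx(
                fisher_exact_enumeration_oracle(a, b, c, d), rel=1e-9
            )

    def test_enumeration_over_small_margins(self):
        """scipy agrees with the enumeration oracle on all tables with n <= 12."""
        for n in range(2, 13):
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        _, p = fisher_exact_test(np.array([[a, b], [c, d]]))
                        oracle = fisher_exact_enumeration_oracle(a, b, c, d)
                        assert p == pytest.approx(oracle, rel=1e-9, abs=1e-12)

    def test_empty_universe_rejected(self):
        a = self._net([True])
        with pytest.raises(ContractError, match="empty"):
            edge_contingency_compare(a, a, ["ZZZ"])


class TestExport:
    def test_edge_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.standard_normal((4, 10)), stage="zscore",
                        groups=["CTL"] * 10)
        net = pearson_network(m, "CTL")
        path = tmp_path / "net.csv"
        export_network(net, path, "edge-CSV")
        back = import_edge_csv(path)
        assert back.kind == net.kind and back.n_samples == net.n_samples
        pd.testing.assert_frame_equal(
            back.edges.reset_index(drop=True), net.edges.reset_index(drop=True)
        )

    def test_sif_line_count_and_empty_network(self, tmp_path):
        edges = pd.DataFrame(
            {"u": ["a", "a", "b"], "v": ["b", "c", "c"],
             "estimate": [0.9, -0.8, 0.5], "p": 0.01, "q": 0.02,
             "significant": True}
        )
        net = LipidNetwork(nodes=["a", "b", "c"], edges=edges, kind="pearson",
                           group_label="CTL", n_samples=8)
        sif = tmp_path / "net.sif"
        export_network(net, sif, "SIF")
        assert len(sif.read_text().strip().splitlines()) == 3

        empty = LipidNetwork(nodes=[], edges=edges.iloc[:0], kind="pearson",
                             group_label="CTL", n_samples=8)
        out = tmp_path / "empty.csv"
        export_network(empty, out, "edge-CSV")
        assert out.exists()

    def test_unknown_format_rejected(self, tmp_path):
        net = LipidNetwork(nodes=[], edges=pd.DataFrame(
            columns=["u", "v", "estimate", "p", "q", "significant"]),
            kind="pearson", group_label="CTL", n_samples=8)
        with pytest.raises(ContractError):
            export_network(net, tmp_path / "x", "XGMML")
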