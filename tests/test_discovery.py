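import warnings
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nesubtype as ns
from nesubtype.discovery import (
    DiscoveryError,
    ReversedPair,
    fisher_exact_pvalue,
    score_reversed_pairs,
)


def two_group_labels(n_pos, n_neg):
    labels = {f"P{i}": "pos" for i in range(n_pos)}
    labels.update({f"N{i}": "neg" for i in range(n_neg)})
    return ns.LabelTable(labels)


def gaussian_matrix(n_genes, n_pos, n_neg, seed, mean_pos=8.0, mean_neg=8.0, sd=1.0):
    rng = np.random.default_rng(seed)
    cols = [f"P{i}" for i in range(n_pos)] + [f"N{i}" for i in range(n_neg)]
    vals = np.concatenate(
        [
            rng.normal(mean_pos, sd, size=(n_genes, n_pos)),
            rng.normal(mean_neg, sd, size=(n_genes, n_neg)),
        ],
        axis=1,
    )
    genes = [f"g{i:03d}" for i in range(n_genes)]
    return ns.ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=cols))


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------


def test_find_de_genes_null_type_one_error_rate():
    """With both groups drawn from one distribution, ~5% of raw p-values
    should fall below 0.05 (within 2 binomial s.e. over 200 genes)."""
    m = gaussian_matrix(200, 20, 20, seed=42)
    de = ns.find_de_genes(m, two_group_labels(20, 20), "pos")
    frac = np.mean([g.p_value < 0.05 for g in de])
    se = np.sqrt(0.05 * 0.95 / 200)
    assert abs(frac - 0.05) <= 2 * se + 1e-12


def test_find_de_genes_null_gene_not_significant():
    rng = np.random.default_rng(0)
    m = gaussian_matrix(50, 20, 20, seed=1)
    de = {g.gene_id: g for g in ns.find_de_genes(m, two_group_labels(20, 20), "pos")}
    assert de["g000"].fdr > 0.05


def test_find_de_genes_planted_gene_detected():
    m = gaussian_matrix(100, 20, 20, seed=2, sd=0.5)
    data = m.data.copy()
    data.loc["g000", [c for c in data.columns if c.startswith("P")]] += 4.0  # 8 vs 4
    m2 = ns.ExpressionMatrix(data)
    de = {g.gene_id: g for g in ns.find_de_genes(m2, two_group_labels(20, 20), "pos")}
    assert de["g000"].fdr < 0.05
    assert de["g000"].log2_fold_change == pytest.approx(4.0, abs=0.5)


def test_find_de_genes_zero_variance_excluded():
    m = gaussian_matrix(30, 10, 10, seed=3)
    data = m.data.copy()
    data.loc["g000"] = 5.0  # constant everywhere: t undefined
    with pytest.warns(UserWarning, match="excluded"):
        de = ns.find_de_genes(ns.ExpressionMatrix(data), two_group_labels(10, 10), "pos")
    assert "g000" not in {g.gene_id for g in de}


def test_find_de_genes_small_group_rejected():
    m = gaussian_matrix(10, 1, 5, seed=4)
    with pytest.raises(DiscoveryError):
        ns.find_de_genes(m, two_group_labels(1, 5), "pos")


def _de(gene, lfc, fdr):
    return ns.DEGene(gene, t_statistic=1.0, p_value=fdr / 2, fdr=fdr, log2_fold_change=lfc)


def test_select_candidates_top_k_by_fold_change():
    genes = [
        _de("a", 3.0, 0.01),
        _de("b", -4.0, 0.01),
        _de("c", 1.0, 0.01),
        _de("d", 2.0, 0.01),
        _de("e", 0.5, 0.01),
    ]
    assert ns.select_candidates(genes, 3) == ["b", "a", "d"]


def test_select_candidates_tiebreak_fdr_then_gene_id():
    genes = [_de("z", 2.0, 0.04), _de("a", 2.0, 0.04), _de("m", 2.0, 0.01)]
    assert ns.select_candidates(genes, 2) == ["m", "a"]


def test_select_candidates_shortfall_warns():
    genes = [_de("a", 2.0, 0.01), _de("b", 1.0, 0.2)]
    with pytest.warns(UserWarning, match="only 1"):
        assert ns.select_candidates(genes, 10) == ["a"]


# ---------------------------------------------------------------------------
# reversed-pair mining
# ---------------------------------------------------------------------------


def _reversal_matrix(n=20, seed=0):
    """g000/g001 perfectly reversed between groups; g002/g003 null."""
    rng = np.random.default_rng(seed)
    cols = [f"P{i}" for i in range(n)] + [f"N{i}" for i in range(n)]
    base = rng.normal(8, 0.1, size=(4, 2 * n))
    base[0, :n] += 3; base[1, :n] -= 3
    base[0, n:] -= 3; base[1, n:] += 3
    return ns.ExpressionMatrix(
        pd.DataFrame(base, index=["g000", "g001", "g002", "g003"], columns=cols)
    )


def test_mine_perfect_reversal_matches_hypergeometric_tail():
    m = _reversal_matrix()
    labels = two_group_labels(20, 20)
    pairs = ns.mine_reversed_pairs(m, labels, ["g000", "g001"], "pos")
    assert len(pairs) == 1
    rp = pairs[0]
    assert (rp.pair.gene_a, rp.pair.gene_b) == ("g000", "g001")
    assert rp.freq_gt_pos == 1.0 and rp.freq_gt_neg == 0.0
    # independent textbook value: a 20/0 vs 0/20 split of 40 samples
    expected = 2 / comb(40, 20)
    assert rp.fisher_p == pytest.approx(expected, rel=1e-12)


def test_mine_identical_margins_discarded():
    rng = np.random.default_rng(1)
    cols = [f"P{i}" for i in range(20)] + [f"N{i}" for i in range(20)]
    vals = np.zeros((2, 40))
    # GT in exactly 10 of 20 samples of each group
    vals[0] = [1.0 if i % 2 == 0 else -1.0 for i in range(40)]
    m = ns.ExpressionMatrix(pd.DataFrame(vals, index=["a", "b"], columns=cols))
    assert ns.mine_reversed_pairs(m, two_group_labels(20, 20), ["a", "b"], "pos") == []
    assert fisher_exact_pvalue([[10, 10], [10, 10]]) == pytest.approx(1.0)


def test_mine_orients_pair_toward_positive_group():
    m = _reversal_matrix()
    labels = two_group_labels(20, 20)
    # pass genes in the "wrong" order: mining must flip the pair
    pairs = ns.mine_reversed_pairs(m, labels, ["g001", "g000"], "pos")
    rp = pairs[0]
    assert (rp.pair.gene_a, rp.pair.gene_b) == ("g000", "g001")
    assert rp.freq_gt_pos >= rp.freq_gt_neg


def test_mine_combinatorial_guard():
    m = gaussian_matrix(10, 3, 3, seed=5)
    cfg = ns.DiscoveryConfig(max_pairs=10)
    with pytest.raises(DiscoveryError, match="guard"):
        ns.mine_reversed_pairs(m, two_group_labels(3, 3), m.gene_ids, "pos", cfg)


# ---------------------------------------------------------------------------
# pair scoring: apparent accuracy and rank differences
# ---------------------------------------------------------------------------


def test_pair_accuracy_perfect_and_constant():
    m = _reversal_matrix()
    labels = two_group_labels(20, 20)
    good = ns.GenePair("g000", "g001")
    assert ns.pair_apparent_accuracy(good, m, labels, "pos") == pytest.approx(100.0)
    data = m.data.copy()
    data.loc["g000"] = 9.0
    data.loc["g001"] = 1.0  # GT everywhere: constant predictor
    m2 = ns.ExpressionMatrix(data)
    assert ns.pair_apparent_accuracy(good, m2, labels, "pos") == pytest.approx(50.0)


def _rank_diff_matrix(diffs_pos, diffs_neg, n_genes=10):
    """Matrix where |rank(a) − rank(b)| takes prescribed values per sample."""
    cols, data = [], []
    for i, d in enumerate(list(diffs_pos) + list(diffs_neg)):
        group = "P" if i < len(diffs_pos) else "N"
        col = np.arange(n_genes, dtype=float)  # ranks = position + 1
        # gene a sits at rank d+1, gene b at rank 1 -> |diff| = d
        col[0], col[1] = float(d), 0.0
        filler = [v for v in np.arange(n_genes, dtype=float) if v not in (float(d), 0.0)]
        col[2:] = filler[: n_genes - 2]
        cols.append(col)
        data.append(col)
    names = [f"{'P' if i < len(diffs_pos) else 'N'}{i}" for i in range(len(data))]
    genes = ["a", "b"] + [f"f{i}" for i in range(n_genes - 2)]
    return ns.ExpressionMatrix(pd.DataFrame(np.array(data).T, index=genes, columns=names))


def test_rank_difference_hand_computed_product():
    # group 1 diffs {2, 8}, group 2 diffs {4, 4}: geometric means 4 and 4
    m = _rank_diff_matrix([2, 8], [4, 4])
    labels = ns.LabelTable({"P0": "pos", "P1": "pos", "N2": "neg", "N3": "neg"})
    pair = ns.GenePair("a", "b")
    assert ns.pair_rank_difference(pair, m, labels, "pos") == pytest.approx(16.0)


def test_rank_difference_constant_case_is_square():
    m = _rank_diff_matrix([5, 5], [5, 5])
    labels = ns.LabelTable({"P0": "pos", "P1": "pos", "N2": "neg", "N3": "neg"})
    assert ns.pair_rank_difference(ns.GenePair("a", "b"), m, labels, "pos") == pytest.approx(25.0)


def test_rank_difference_tie_floored_at_half():
    # both genes equal in every sample: every diff floored to 0.5 -> 0.25
    vals = np.tile(np.arange(5.0), (4, 1)).T
    vals[1] = vals[0]  # b == a everywhere
    m = ns.ExpressionMatrix(
        pd.DataFrame(vals, index=["a", "b", "c", "d", "e"], columns=["P0", "P1", "N0", "N1"])
    )
    labels = ns.LabelTable({"P0": "pos", "P1": "pos", "N0": "neg", "N1": "neg"})
    score = ns.pair_rank_difference(ns.GenePair("a", "b"), m, labels, "pos")
    assert score == pytest.approx(0.25)


# ---------------------------------------------------------------------------
# de-redundant selection
# ---------------------------------------------------------------------------


def _rp(a, b, acc, rank=1.0):
    return ReversedPair(
        pair=ns.GenePair(a, b, positive_class="pos"),
        freq_gt_pos=1.0,
        freq_gt_neg=0.0,
        fisher_p=1e-9,
        fdr=1e-8,
        apparent_accuracy=acc,
        rank_diff_score=rank,
    )


def test_deredundant_greedy_hand_trace():
    pairs = [_rp("A", "B", 99), _rp("A", "C", 95), _rp("D", "E", 90)]
    sig, kept = ns.deredundant_select(pairs, "s", "pos", "neg")
    assert [(p.gene_a, p.gene_b) for p in sig.pairs] == [("A", "B"), ("D", "E")]


def test_deredundant_disjoint_pairs_all_kept():
    pairs = [_rp("A", "B", 50), _rp("C", "D", 99)]
    sig, _ = ns.deredundant_select(pairs, "s", "pos", "neg")
    assert len(sig) == 2


def test_deredundant_accuracy_tie_broken_by_rank_score():
    pairs = [_rp("A", "C", 99, rank=9.0), _rp("A", "B", 99, rank=16.0)]
    sig, _ = ns.deredundant_select(pairs, "s", "pos", "neg")
    assert [(p.gene_a, p.gene_b) for p in sig.pairs] == [("A", "B")]


def test_deredundant_invariant_to_input_order():
    pairs = [_rp("A", "B", 99), _rp("A", "C", 95), _rp("D", "E", 90), _rp("B", "F", 80)]
    sig1, _ = ns.deredundant_select(pairs, "s", "pos", "neg")
    sig2, _ = ns.deredundant_select(list(reversed(pairs)), "s", "pos", "neg")
    assert sig1.pairs == sig2.pairs


def test_deredundant_empty_input_rejected():
    with pytest.raises(DiscoveryError):
        ns.deredundant_select([], "s", "pos", "neg")


def test_deredundant_requires_scores():
    unscored = ReversedPair(
        pair=ns.GenePair("A", "B"), freq_gt_pos=1.0, freq_gt_neg=0.0,
        fisher_p=1e-9, fdr=1e-8,
    )
    with pytest.raises(ns.ValidationError):
        ns.deredundant_select([unscored], "s", "pos", "neg")


@settings(max_examples=30, deadline=None)
@given(st.data())
def test_deredundant_output_genes_pairwise_distinct(data):
    genes = [f"g{i}" for i in range(10)]
    n = data.draw(st.integers(1, 15))
    pairs = []
    for i in range(n):
        a, b = data.draw(
            st.tuples(st.sampled_from(genes), st.sampled_from(genes)).filter(
                lambda t: t[0] != t[1]
            )
        )
        acc = data.draw(st.floats(50, 100))
        rank = data.draw(st.floats(0.25, 30))
        pairs.append(_rp(a, b, acc, rank))
    sig, _ = ns.deredundant_select(pairs, "s", "pos", "neg")
    flat = [g for p in sig.pairs for g in p.genes]
    assert len(flat) == len(set(flat))


# ---------------------------------------------------------------------------
# end-to-end signature building and panel training
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def planted_two_group():
    cfg = ns.SimulationConfig(samples_per_group={"pos": 30, "neg": 30}, rng_seed=7)
    return ns.simulate(cfg)


def test_build_signature_recovers_planted_genes(planted_two_group):
    ds = planted_two_group
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = ns.build_signature(ds.matrix, ds.observed_labels, "pos")
    planted = ds.truth.all_planted_genes
    recovered = set(res.signature.genes) & planted
    assert len(recovered) / len(planted) >= 0.9
    assert res.training_stats.sensitivity == pytest.approx(100.0)
    assert res.training_stats.specificity == pytest.approx(100.0)


def test_build_signature_fails_on_permuted_labels(planted_two_group):
    """Label permutation destroys the signal: the pipeline must refuse to
    build a signature (no DE genes / no significant pairs) nearly always."""
    ds = planted_two_group
    ids = ds.matrix.sample_ids
    failures = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(ids))
        labels = ns.LabelTable({ids[i]: ds.observed_labels[ids[int(j)]] for i, j in enumerate(perm)})
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ns.build_signature(ds.matrix, labels, "pos")
        except DiscoveryError:
            failures += 1
    assert failures >= 19


def test_train_panel_filter_noop_on_clean_labels():
    cfg = ns.SimulationConfig(
        n_genes=150,
        samples_per_group={"SCLC": 8, "LCNEC": 8, "CARCI": 16, "ADC": 16, "SCC": 16},
        n_planted_pairs=8,
        rng_seed=5,
    )
    ds = ns.simulate(cfg)
    clus = ns.ClusteringConfig(n_resamples=100, n_top_genes=150, rng_seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        off = ns.train_panel(ds.matrix, ds.observed_labels, cluster_filter=False)
        on = ns.train_panel(
            ds.matrix, ds.observed_labels, cluster_filter=True, clustering_config=clus
        )
    assert all(len(r) == 0 for r in on.removed_samples)
    assert off.panel.steps == on.panel.steps


def test_train_panel_rejects_tiny_group():
    cfg = ns.SimulationConfig(
        n_genes=150,
        samples_per_group={"SCLC": 2, "LCNEC": 8, "CARCI": 10, "ADC": 10, "SCC": 10},
        n_planted_pairs=8,
        rng_seed=6,
    )
    ds = ns.simulate(cfg)
    with pytest.raises(DiscoveryError, match="SCLC"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ns.train_panel(ds.matrix, ds.observed_labels)


def test_train_panel_rejects_unknown_labels():
    cfg = ns.SimulationConfig(samples_per_group={"pos": 10, "neg": 10}, rng_seed=1)
    ds = ns.simulate(cfg)
    with pytest.raises(ns.ValidationError):
        ns.train_panel(ds.matrix, ds.observed_labels)
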