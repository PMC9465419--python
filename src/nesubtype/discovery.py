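"""Signature discovery: DE candidates, reversed-pair mining, scored selection.

Given a labelled two-group expression matrix, the pipeline is

1. pooled-variance two-sample *t* test per gene, Benjamini–Hochberg FDR,
   genes with FDR < 5% are differentially expressed (DE);
2. the top-``n`` DE genes by absolute log2 fold change become *candidates*;
3. every unordered candidate pair is tested for a *reversed* REO pattern:
   a two-sided Fisher exact test on the 2×2 table of GT/LE counts per group,
   again BH-corrected; surviving pairs are oriented so that GT
   (``E_a > E_b``) is the positive-class pattern;
4. each surviving pair is scored by its apparent accuracy
   (``S / N × 100``, concordance of the single-pair prediction with the
   reference labels) and, as tie-break, by a within-sample rank-difference
   score (product over the two groups of the geometric mean of
   ``|rank(gene_a) − rank(gene_b)|``);
5. a de-redundant greedy pass keeps, in score order, every pair neither of
   whose genes was already taken, so each gene ends up in at most one pair.

Three such binary signatures chained NE → CARCI → SCLC reproduce the
hierarchical subtyping panel; :func:`train_panel` drives the three steps,
optionally cleaning each step's training labels with the consensus-clustering
discordance filter first.

The whole pipeline is deterministic: there is no randomness anywhere, and all
orderings are total (ties broken by declared secondary keys, gene IDs last).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import consensus as _consensus
from .classify import AccuracyStats, evaluate_predictions, score_signature
from .model import (
    ExpressionMatrix,
    GenePair,
    LabelTable,
    NesubtypeError,
    Panel,
    PanelStep,
    Signature,
    ValidationError,
)

__all__ = [
    "DiscoveryError",
    "DEGene",
    "ReversedPair",
    "DiscoveryConfig",
    "NE_SUBTYPES",
    "NON_NE_SUBTYPES",
    "FIVE_SUBTYPES",
    "find_de_genes",
    "select_candidates",
    "mine_reversed_pairs",
    "fisher_exact_pvalue",
    "pair_apparent_accuracy",
    "pair_rank_difference",
    "score_reversed_pairs",
    "deredundant_select",
    "build_signature",
    "SignatureBuildResult",
    "train_panel",
    "TrainedPanel",
]

NE_SUBTYPES = ("SCLC", "LCNEC", "CARCI")
NON_NE_SUBTYPES = ("ADC", "SCC")
FIVE_SUBTYPES = NE_SUBTYPES + NON_NE_SUBTYPES

#: Rank differences of exactly zero (tied expression) are floored at this
#: value before entering the geometric mean, which is otherwise undefined.
RANK_DIFF_FLOOR = 0.5


class DiscoveryError(NesubtypeError):
    """Pipeline cannot proceed (empty groups, no significant pairs...)."""


@dataclass(frozen=True)
class DEGene:
    gene_id: str
    t_statistic: float
    p_value: float
    fdr: float
    log2_fold_change: float

    @property
    def fold_change(self) -> float:
        """Group-mean ratio on the linear scale."""
        return float(2.0 ** self.log2_fold_change)


@dataclass(frozen=True)
class ReversedPair:
    """A significantly reversed gene pair, oriented toward the positive class.

    ``freq_gt_pos`` / ``freq_gt_neg`` are the frequencies of the GT pattern
    among evaluable samples of the positive and negative group; after
    orientation ``freq_gt_pos >= freq_gt_neg``.
    """

    pair: GenePair
    freq_gt_pos: float
    freq_gt_neg: float
    fisher_p: float
    fdr: float
    apparent_accuracy: float | None = None
    rank_diff_score: float | None = None


@dataclass(frozen=True)
class DiscoveryConfig:
    """Tunable thresholds of the discovery pipeline.

    ``values_are_log`` declares the input scale for fold-change computation
    (difference of group means when log, ratio of means otherwise); it is
    never guessed from the data.
    """

    de_fdr_threshold: float = 0.05
    n_candidates: int = 1000
    pair_fdr_threshold: float = 0.05
    values_are_log: bool = True
    max_pairs: int = 10_000_000
    allow_large_pair_search: bool = False

    def __post_init__(self) -> None:
        for name in ("de_fdr_threshold", "pair_fdr_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValidationError(f"{name} must be in (0, 1], got {v}")
        if self.n_candidates < 2:
            raise ValidationError("n_candidates must be >= 2")


def _two_groups(
    matrix: ExpressionMatrix, labels: LabelTable, positive_label: str
) -> tuple[list[str], list[str], str]:
    """Split matrix samples into (positive, negative) sample-id lists."""
    labels.require_samples(matrix.sample_ids)
    observed = {labels[s] for s in matrix.sample_ids}
    if positive_label not in observed:
        raise DiscoveryError(f"no samples labelled {positive_label!r}")
    negatives = sorted(observed - {positive_label})
    if len(negatives) != 1:
        raise DiscoveryError(
            f"expected exactly two groups, got labels {sorted(observed)}"
        )
    pos = [s for s in matrix.sample_ids if labels[s] == positive_label]
    neg = [s for s in matrix.sample_ids if labels[s] != positive_label]
    return pos, neg, negatives[0]


def find_de_genes(
    matrix: ExpressionMatrix,
    labels: LabelTable,
    positive_label: str,
    config: DiscoveryConfig = DiscoveryConfig(),
) -> list[DEGene]:
    """Differential expression by pooled-variance two-sample *t* test.

    Returns one :class:`DEGene` per testable gene, FDR-significant genes
    first (sorted by \\|log2 FC\\| descending, then FDR, then gene id), then
    the rest in the same order.  Genes that cannot be tested — fewer than two
    detected values in a group, or zero variance in both groups — are
    excluded; their count is reported via a warning.
    """
    pos, neg, _ = _two_groups(matrix, labels, positive_label)
    if len(pos) < 2 or len(neg) < 2:
        raise DiscoveryError(
            f"each group needs >=2 samples (got {len(pos)} vs {len(neg)})"
        )
    a = matrix.data[pos].to_numpy()
    b = matrix.data[neg].to_numpy()
    n_a = np.sum(np.isfinite(a), axis=1)
    n_b = np.sum(np.isfinite(b), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_a = np.nanmean(np.where(np.isfinite(a), a, np.nan), axis=1)
        mean_b = np.nanmean(np.where(np.isfinite(b), b, np.nan), axis=1)
        var_a = np.nanvar(a, axis=1, ddof=1)
        var_b = np.nanvar(b, axis=1, ddof=1)
        t_res = stats.ttest_ind(a, b, axis=1, equal_var=True, nan_policy="omit")
    t_stat = np.asarray(t_res.statistic, dtype=float)
    p_val = np.asarray(t_res.pvalue, dtype=float)

    if config.values_are_log:
        lfc = mean_a - mean_b
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            lfc = np.where(
                (mean_a > 0) & (mean_b > 0), np.log2(mean_a / mean_b), np.nan
            )
    testable = (
        (n_a >= 2)
        & (n_b >= 2)
        & np.isfinite(t_stat)
        & np.isfinite(p_val)
        & ~((var_a == 0) & (var_b == 0))
        & np.isfinite(lfc)
    )
    n_dropped = int(np.sum(~testable))
    if n_dropped:
        warnings.warn(
            f"{n_dropped} gene(s) excluded from DE testing "
            "(insufficient data or undefined statistic)",
            stacklevel=2,
        )
    idx = np.flatnonzero(testable)
    if idx.size == 0:
        raise DiscoveryError("no testable genes")
    fdr = multipletests(p_val[idx], method="fdr_bh")[1]
    gene_ids = np.asarray(matrix.gene_ids, dtype=object)
    genes = [
        DEGene(
            gene_id=str(gene_ids[i]),
            t_statistic=float(t_stat[i]),
            p_value=float(p_val[i]),
            fdr=float(q),
            log2_fold_change=float(lfc[i]),
        )
        for i, q in zip(idx, fdr)
    ]
    thr = config.de_fdr_threshold
    genes.sort(
        key=lambda g: (
            g.fdr >= thr,  # significant block first
            -abs(g.log2_fold_change),
            g.fdr,
            g.gene_id,
        )
    )
    return genes


def select_candidates(
    de_genes: Sequence[DEGene],
    n: int,
    fdr_threshold: float = 0.05,
) -> list[str]:
    """The ``n`` FDR-significant genes with the largest absolute log2 FC.

    Ties at the cutoff are broken by smaller FDR, then by gene-id order.  If
    fewer than ``n`` genes are significant all of them are returned with a
    warning.
    """
    significant = [g for g in de_genes if g.fdr < fdr_threshold]
    significant.sort(key=lambda g: (-abs(g.log2_fold_change), g.fdr, g.gene_id))
    if len(significant) < n:
        warnings.warn(
            f"only {len(significant)} FDR-significant genes available "
            f"(requested {n})",
            stacklevel=2,
        )
    return [g.gene_id for g in significant[:n]]


def fisher_exact_pvalue(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value for a 2×2 contingency table."""
    return float(stats.fisher_exact(np.asarray(table), alternative="two-sided")[1])


def _pairwise_gt_counts(x: np.ndarray, block: int = 128):
    """For a genes × samples array, GT counts and evaluable counts per pair.

    Returns two g×g integer arrays: ``gt[i, j]`` = number of samples where
    ``x[i] > x[j]`` with both values detected, ``n_eval[i, j]`` = number of
    samples where both are detected.  NaN never wins a comparison.
    """
    g = x.shape[0]
    finite = np.isfinite(x)
    gt = np.empty((g, g), dtype=np.int64)
    n_eval = np.empty((g, g), dtype=np.int64)
    xz = np.where(finite, x, 0.0)
    for start in range(0, g, block):
        stop = min(start + block, g)
        cmp_ = (xz[start:stop, None, :] > xz[None, :, :]) & (
            finite[start:stop, None, :] & finite[None, :, :]
        )
        gt[start:stop] = cmp_.sum(axis=2)
        n_eval[start:stop] = (
            finite[start:stop, None, :] & finite[None, :, :]
        ).sum(axis=2)
    return gt, n_eval


def mine_reversed_pairs(
    matrix: ExpressionMatrix,
    labels: LabelTable,
    candidates: Sequence[str],
    positive_label: str,
    config: DiscoveryConfig = DiscoveryConfig(),
) -> list[ReversedPair]:
    """Fisher-exact screen of all unordered candidate pairs for reversed REOs.

    For each pair the 2×2 table crosses the REO pattern (GT vs LE, ties in
    LE) with the two groups, counting only samples where both genes are
    detected.  Two-sided p-values are BH-corrected across all tested pairs;
    pairs with FDR below ``config.pair_fdr_threshold`` are kept and oriented
    so the GT pattern is more frequent in the positive group.
    """
    candidates = list(dict.fromkeys(str(c) for c in candidates))
    if len(candidates) < 2:
        raise DiscoveryError("need at least 2 candidate genes")
    n_pairs = comb(len(candidates), 2)
    if n_pairs > config.max_pairs and not config.allow_large_pair_search:
        raise DiscoveryError(
            f"{n_pairs} candidate pairs exceed the guard of {config.max_pairs}; "
            "set allow_large_pair_search=True to proceed"
        )
    pos, neg, _ = _two_groups(matrix, labels, positive_label)
    sub = matrix.subset_genes(candidates)
    gt_p, ev_p = _pairwise_gt_counts(sub.data[pos].to_numpy())
    gt_n, ev_n = _pairwise_gt_counts(sub.data[neg].to_numpy())

    p_cache: dict[tuple[int, int, int, int], float] = {}
    raw: list[tuple[int, int, float]] = []
    for i, j in itertools.combinations(range(len(candidates)), 2):
        key = (gt_p[i, j], ev_p[i, j], gt_n[i, j], ev_n[i, j])
        p = p_cache.get(key)
        if p is None:
            table = [
                [key[0], key[1] - key[0]],
                [key[2], key[3] - key[2]],
            ]
            p = fisher_exact_pvalue(table)
            p_cache[key] = p
        raw.append((i, j, p))
    if not raw:
        raise DiscoveryError("no candidate pairs to test")
    fdr = multipletests([r[2] for r in raw], method="fdr_bh")[1]

    out: list[ReversedPair] = []
    for (i, j, p), q in zip(raw, fdr):
        if q >= config.pair_fdr_threshold:
            continue
        freq_p = gt_p[i, j] / ev_p[i, j] if ev_p[i, j] else np.nan
        freq_n = gt_n[i, j] / ev_n[i, j] if ev_n[i, j] else np.nan
        a, b = candidates[i], candidates[j]
        if np.isnan(freq_p) or np.isnan(freq_n):
            continue
        if freq_p < freq_n:
            # flip so GT is the positive-class pattern
            a, b = b, a
            freq_p = (ev_p[i, j] - gt_p[i, j]) / ev_p[i, j]
            freq_n = (ev_n[i, j] - gt_n[i, j]) / ev_n[i, j]
        out.append(
            ReversedPair(
                pair=GenePair(gene_a=a, gene_b=b, positive_class=positive_label),
                freq_gt_pos=float(freq_p),
                freq_gt_neg=float(freq_n),
                fisher_p=float(p),
                fdr=float(q),
            )
        )
    return out


def pair_apparent_accuracy(
    pair: GenePair,
    matrix: ExpressionMatrix,
    labels: LabelTable,
    positive_label: str,
) -> float:
    """Apparent accuracy ``S / N × 100`` of the single-pair predictor.

    A sample is predicted positive iff its REO pattern is GT; anything else
    (LE, tie, missing value) predicts negative.  ``S`` counts concordant
    samples over both groups, ``N`` is the total sample count.
    """
    labels.require_samples(matrix.sample_ids)
    va = matrix.data.loc[pair.gene_a]
    vb = matrix.data.loc[pair.gene_b]
    gt = (va > vb).to_numpy()
    truth = np.array([labels[s] == positive_label for s in matrix.sample_ids])
    return float(np.mean(gt == truth) * 100.0)


def _rank_diffs(
    pair: GenePair, ranks: pd.DataFrame, sample_ids: Sequence[str]
) -> np.ndarray:
    d = (
        ranks.loc[pair.gene_a, list(sample_ids)]
        - ranks.loc[pair.gene_b, list(sample_ids)]
    ).abs()
    d = d.dropna().to_numpy()
    return np.maximum(d, RANK_DIFF_FLOOR)


def within_sample_ranks(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Fractional (average-tie) ranks of each gene within each sample.

    The rank universe is the gene set of the supplied matrix; restrict the
    matrix to the candidate genes first to rank over the candidate universe.
    """
    return matrix.data.rank(axis=0, method="average", na_option="keep")


def pair_rank_difference(
    pair: GenePair,
    matrix: ExpressionMatrix,
    labels: LabelTable,
    positive_label: str,
    ranks: pd.DataFrame | None = None,
) -> float:
    """Rank-difference score: product over groups of the geometric mean of
    the within-sample absolute rank difference of the two genes.

    Ranks are fractional, taken within each sample over the genes of
    ``matrix``; zero differences (expression ties) are floored at 0.5 before
    the log, so the score is always >= 0.25.
    """
    if ranks is None:
        ranks = within_sample_ranks(matrix)
    pos, neg, _ = _two_groups(matrix, labels, positive_label)
    score = 1.0
    for group in (pos, neg):
        d = _rank_diffs(pair, ranks, group)
        if d.size == 0:
            raise DiscoveryError(
                f"pair ({pair.gene_a}, {pair.gene_b}): no evaluable samples in a group"
            )
        score *= float(np.exp(np.mean(np.log(d))))
    return score


def score_reversed_pairs(
    pairs: Sequence[ReversedPair],
    matrix: ExpressionMatrix,
    labels: LabelTable,
    positive_label: str,
    rank_universe: Sequence[str] | None = None,
) -> list[ReversedPair]:
    """Attach apparent accuracy and rank-difference scores to mined pairs.

    ``rank_universe`` (default: all genes of ``matrix``) fixes the gene set
    within which per-sample ranks are computed.
    """
    universe = matrix if rank_universe is None else matrix.subset_genes(rank_universe)
    ranks = within_sample_ranks(universe)
    out = []
    for rp in pairs:
        acc = pair_apparent_accuracy(rp.pair, matrix, labels, positive_label)
        rd = pair_rank_difference(
            rp.pair, universe, labels, positive_label, ranks=ranks
        )
        out.append(replace(rp, apparent_accuracy=acc, rank_diff_score=rd))
    return out


def deredundant_select(
    reversed_pairs: Sequence[ReversedPair],
    name: str,
    positive_label: str,
    negative_label: str,
) -> tuple[Signature, list[ReversedPair]]:
    """Greedy de-redundant selection: one pair per gene, best pairs first.

    Pairs are sorted by apparent accuracy (descending), then rank-difference
    score (descending), then gene ids; scanning in that order, a pair is
    accepted iff neither of its genes appears in an already accepted pair.
    The ordering is total, so the result does not depend on input order.

    Returns the resulting signature together with the accepted
    :class:`ReversedPair` records (same order as the signature's pairs).
    """
    if not reversed_pairs:
        raise DiscoveryError("cannot build a signature from zero reversed pairs")
    for rp in reversed_pairs:
        if rp.apparent_accuracy is None or rp.rank_diff_score is None:
            raise ValidationError(
                "reversed pairs must be scored before de-redundant selection"
            )
    ordered = sorted(
        reversed_pairs,
        key=lambda rp: (
            -rp.apparent_accuracy,
            -rp.rank_diff_score,
            rp.pair.gene_a,
            rp.pair.gene_b,
        ),
    )
    taken: set[str] = set()
    accepted: list[ReversedPair] = []
    for rp in ordered:
        if rp.pair.gene_a in taken or rp.pair.gene_b in taken:
            continue
        taken.update(rp.pair.genes)
        accepted.append(rp)
    signature = Signature(
        name=name,
        pairs=[rp.pair for rp in accepted],
        positive_label=positive_label,
        negative_label=negative_label,
    )
    return signature, accepted


def _pairs_report(accepted: Sequence[ReversedPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_a": [rp.pair.gene_a for rp in accepted],
            "gene_b": [rp.pair.gene_b for rp in accepted],
            "freq_gt_pos": [rp.freq_gt_pos for rp in accepted],
            "freq_gt_neg": [rp.freq_gt_neg for rp in accepted],
            "fisher_p": [rp.fisher_p for rp in accepted],
            "fdr": [rp.fdr for rp in accepted],
            "apparent_accuracy": [rp.apparent_accuracy for rp in accepted],
            "rank_diff_score": [rp.rank_diff_score for rp in accepted],
        }
    )


@dataclass(frozen=True)
class SignatureBuildResult:
    signature: Signature
    pairs_report: pd.DataFrame
    training_stats: AccuracyStats
    candidates: tuple[str, ...]
    n_de_significant: int
    n_reversed_pairs: int


def build_signature(
    matrix: ExpressionMatrix,
    labels: LabelTable,
    positive_label: str,
    config: DiscoveryConfig = DiscoveryConfig(),
    name: str | None = None,
) -> SignatureBuildResult:
    """Run the full two-group discovery pipeline and report training accuracy.

    DE genes → top-FC candidates → Fisher reversed-pair screen → accuracy and
    rank-difference scoring → greedy de-redundant selection.  Training
    apparent sensitivity/specificity of the final signature are computed with
    the same majority-vote classifier used at prediction time.
    """
    _, _, negative_label = _two_groups(matrix, labels, positive_label)
    de = find_de_genes(matrix, labels, positive_label, config)
    n_sig = sum(g.fdr < config.de_fdr_threshold for g in de)
    candidates = select_candidates(de, config.n_candidates, config.de_fdr_threshold)
    if len(candidates) < 2:
        raise DiscoveryError(
            f"only {len(candidates)} significant DE gene(s); cannot form pairs"
        )
    mined = mine_reversed_pairs(matrix, labels, candidates, positive_label, config)
    if not mined:
        raise DiscoveryError(
            f"no reversed pairs at FDR < {config.pair_fdr_threshold} "
            f"({comb(len(candidates), 2)} pairs tested over "
            f"{len(candidates)} candidates)"
        )
    scored = score_reversed_pairs(
        mined, matrix, labels, positive_label, rank_universe=candidates
    )
    sig_name = name or f"{positive_label}-signature"
    signature, accepted = deredundant_select(
        scored, sig_name, positive_label, negative_label
    )
    predictions = {
        s: score_signature(matrix.sample_values(s).to_dict(), signature).call
        for s in matrix.sample_ids
    }
    stats_ = evaluate_predictions(predictions, labels, positive_label)
    return SignatureBuildResult(
        signature=signature,
        pairs_report=_pairs_report(accepted),
        training_stats=stats_,
        candidates=tuple(candidates),
        n_de_significant=n_sig,
        n_reversed_pairs=len(mined),
    )


@dataclass(frozen=True)
class TrainedPanel:
    panel: Panel
    step_results: tuple[SignatureBuildResult, ...]
    removed_samples: tuple[tuple[str, ...], ...]  # per step, by consensus filter


def train_panel(
    matrix: ExpressionMatrix,
    labels: LabelTable,
    config: DiscoveryConfig = DiscoveryConfig(),
    cluster_filter: bool = False,
    clustering_config: "_consensus.ClusteringConfig | None" = None,
) -> TrainedPanel:
    """Train the three-step hierarchical panel from five-subtype labels.

    Step 1 contrasts NE (SCLC, LCNEC, CARCI) against non-NE (ADC, SCC) on all
    samples; step 2 contrasts CARCI against non-CARCI within the NE samples;
    step 3 contrasts SCLC against LCNEC.  With ``cluster_filter`` on, each
    step first removes samples whose consensus-clustering assignment at k = 2
    disagrees with their pathological side.
    """
    labels.require_samples(matrix.sample_ids)
    observed = {labels[s] for s in matrix.sample_ids}
    unknown = observed - set(FIVE_SUBTYPES)
    if unknown:
        raise ValidationError(f"unknown subtype labels: {sorted(unknown)}")

    step_specs = [
        # (name, sample filter, label → side, positive side, negative side)
        ("NE-signature", FIVE_SUBTYPES, {s: ("NE" if s in NE_SUBTYPES else "non-NE") for s in FIVE_SUBTYPES}, "NE", "non-NE"),
        ("CARCI-signature", NE_SUBTYPES, {s: ("CARCI" if s == "CARCI" else "non-CARCI") for s in NE_SUBTYPES}, "CARCI", "non-CARCI"),
        ("SCLC-signature", ("SCLC", "LCNEC"), {"SCLC": "SCLC", "LCNEC": "LCNEC"}, "SCLC", "LCNEC"),
    ]

    results: list[SignatureBuildResult] = []
    removed_all: list[tuple[str, ...]] = []
    for name, keep_subtypes, grouping, pos_side, neg_side in step_specs:
        sample_ids = [s for s in matrix.sample_ids if labels[s] in keep_subtypes]
        step_matrix = matrix.subset_samples(sample_ids)
        step_labels = labels.subset(sample_ids).relabel(grouping)
        for side in (pos_side, neg_side):
            n_side = sum(1 for s in sample_ids if step_labels[s] == side)
            if n_side < 4:
                raise DiscoveryError(
                    f"{name}: group {side!r} has only {n_side} samples (need >=4)"
                )
        removed: tuple[str, ...] = ()
        if cluster_filter:
            flagged = _consensus.filter_discordant(
                step_matrix,
                step_labels,
                {pos_side: pos_side, neg_side: neg_side},
                config=clustering_config,
            )
            removed = tuple(flagged)
            keep = [s for s in sample_ids if s not in set(flagged)]
            step_matrix = matrix.subset_samples(keep)
            step_labels = step_labels.subset(keep)
        removed_all.append(removed)
        results.append(
            build_signature(step_matrix, step_labels, pos_side, config, name=name)
        )

    ne_sig, carci_sig, sclc_sig = (r.signature for r in results)
    panel = Panel(
        name="trained-NEsubtype-panel",
        steps=[
            PanelStep(ne_sig, ("step", carci_sig.name), ("label", "non-NE")),
            PanelStep(carci_sig, ("label", "CARCI"), ("step", sclc_sig.name)),
            PanelStep(sclc_sig, ("label", "SCLC"), ("label", "LCNEC")),
        ],
    )
    return TrainedPanel(
        panel=panel,
        step_results=tuple(results),
        removed_samples=tuple(removed_all),
    )
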