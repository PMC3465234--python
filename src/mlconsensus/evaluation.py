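"""Leave-one-out cross-validation, slot ROC curves, and paired significance.

For each factor with at least three sites, each site in turn is held out as
the single known positive; the model is re-fitted on the remaining sites
and the positive plus every negative example (the sites of all other
factors of the species, minus any sequence identical to one of this
factor's own sites) are scored.  A negative counts as a false positive only
when it scores *strictly* higher than the positive — ties favour the
positive.

ROC curves are slot-based: the allowable false-positive-rate range
0..fpr_max (default 20%) is split into ``n_slots`` equal slots, a held-out
site is a true positive at slot k when its observed FPR is at most the
slot's allowable FPR, and the per-slot TPR is averaged first over a
factor's sites, then over factors.  The area measure is the plain sum of
per-slot TPRs, so it depends on ``n_slots`` (reported alongside).

Configurations are compared with the Wilcoxon matched-pair signed-ranks
test on per-experiment false-positive counts: zero differences dropped,
midranks for ties, exact two-sided p by enumeration for small n and the
tie-corrected normal approximation (Z) otherwise.  The *significance
plateau* over an ordered scope track is the run of scopes that starts
where performance rises significantly and then stops changing
significantly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .align import Alignment
from .model import MLConsensus
from .scoring import ScoringConfig
from .seqio import SiteSet, SpeciesDataset

MIN_SITES = 3  # admission rule for cross-validation


@dataclass
class LooExperiment:
    """One leave-one-out run: a held-out positive against the negatives."""

    tf_id: str
    site_id: str
    left_out_index: int
    config: ScoringConfig
    positive_score: float
    fp: int
    n_negatives: int

    @property
    def fpr(self) -> float:
        return self.fp / self.n_negatives if self.n_negatives else 0.0


def _negative_pool(dataset: SpeciesDataset, tf_id: str) -> list:
    """Negatives for one factor: all other factors' sites, excluding any
    sequence that is also a site of this factor."""
    own = set(dataset.site_sets[tf_id].sequences)
    pool = []
    for other in dataset:
        if other.tf_id == tf_id:
            continue
        for rec in other:
            if rec.sequence not in own:
                pool.append(rec)
    return pool


def _train_results(
    site_set: SiteSet,
    left_out_index: int,
    config_strategy: str,
    tie_rule: str,
    imported_alignment: Alignment | None,
):
    training = site_set.without(left_out_index)
    if len(training) < 2:
        raise ValueError(
            f"{site_set.tf_id!r}: fewer than 2 training sites after leave-out"
        )
    if config_strategy == "imported":
        if imported_alignment is None:
            raise ValueError(
                f"no imported alignment registered for TF {site_set.tf_id!r}"
            )
        left_id = site_set.sites[left_out_index].site_id
        try:
            row = imported_alignment.site_ids.index(left_id)
        except ValueError:
            raise ValueError(
                f"imported alignment for {site_set.tf_id!r} lacks site {left_id!r}"
            ) from None
        alignment = imported_alignment.without_row(row)
        model = MLConsensus(training, strategy="imported", alignment=alignment)
    else:
        model = MLConsensus(training, strategy="sorted", tie_rule=tie_rule)
    return model.fit()


def run_sweep(
    dataset: SpeciesDataset,
    configs: Sequence[ScoringConfig],
    *,
    tie_rule: str = "last_best",
    imported_alignments: Mapping[str, Alignment] | None = None,
    min_overlap: int = 1,
    min_sites: int = MIN_SITES,
) -> dict:
    """All leave-one-out experiments for several configurations at once.

    Training (alignment + consensus + IC tables) depends only on the
    alignment strategy, so each held-out model is fitted once per strategy
    and scored under every (IC, scope) variant in a single pass.  Returns
    ``{config: [LooExperiment, ...]}`` with experiments in deterministic
    (tf_id, site order) order, identically ordered across configs.
    """
    configs = list(configs)
    strategies = sorted({c.alignment_strategy for c in configs})
    by_strategy = {
        s: [c for c in configs if c.alignment_strategy == s] for s in strategies
    }
    results: dict = {c: [] for c in configs}
    admitted = dataset.admissible(min_sites)
    for site_set in admitted:
        negatives = _negative_pool(admitted, site_set.tf_id)
        neg_seqs = [rec.sequence for rec in negatives]
        for i, rec in enumerate(site_set.sites):
            for strategy in strategies:
                fitted = _train_results(
                    site_set,
                    i,
                    strategy,
                    tie_rule,
                    (imported_alignments or {}).get(site_set.tf_id),
                )
                scanner = fitted.scanner(min_overlap)
                variants = [(c.use_ic, c.ps_scope) for c in by_strategy[strategy]]
                pos = scanner.scores(rec.sequence, variants)
                if neg_seqs:
                    neg = np.vstack([scanner.scores(s, variants) for s in neg_seqs])
                    fp = (neg > pos[None, :]).sum(axis=0)
                else:
                    fp = np.zeros(len(variants), dtype=int)
                for c, p, f in zip(by_strategy[strategy], pos, fp):
                    results[c].append(
                        LooExperiment(
                            tf_id=site_set.tf_id,
                            site_id=rec.site_id,
                            left_out_index=i,
                            config=c,
                            positive_score=float(p),
                            fp=int(f),
                            n_negatives=len(neg_seqs),
                        )
                    )
    return results


def loo_experiment(
    tf: SiteSet,
    left_out_index: int,
    negatives: Iterable[SiteSet],
    config: ScoringConfig,
    *,
    tie_rule: str = "last_best",
    imported_alignment: Alignment | None = None,
    min_overlap: int = 1,
) -> LooExperiment:
    """A single leave-one-out experiment for one factor and one config."""
    if len(tf) < MIN_SITES:
        raise ValueError(f"{tf.tf_id!r}: need at least {MIN_SITES} sites")
    fitted = _train_results(
        tf, left_out_index, config.alignment_strategy, tie_rule, imported_alignment
    )
    own = set(tf.sequences)
    neg_seqs = [
        rec.sequence
        for ns in negatives
        if ns.tf_id != tf.tf_id
        for rec in ns
        if rec.sequence not in own
    ]
    scanner = fitted.scanner(min_overlap)
    pos = scanner.scan(tf.sites[left_out_index].sequence, config)
    fp = sum(scanner.scan(s, config) > pos for s in neg_seqs)
    return LooExperiment(
        tf_id=tf.tf_id,
        site_id=tf.sites[left_out_index].site_id,
        left_out_index=left_out_index,
        config=config,
        positive_score=pos,
        fp=int(fp),
        n_negatives=len(neg_seqs),
    )


def run_configuration(
    dataset: SpeciesDataset, config: ScoringConfig, **kwargs
) -> list:
    """All leave-one-out experiments of a species for one configuration."""
    return run_sweep(dataset, [config], **kwargs)[config]


# ---------------------------------------------------------------------------
# slot-based ROC
# ---------------------------------------------------------------------------


@dataclass
class RocCurve:
    """Per-slot TPR over the allowable FPR range, with sum-of-TPR area."""

    slot_fprs: np.ndarray
    tpr: np.ndarray
    fpr_max: float
    n_slots: int

    @property
    def auc(self) -> float:
        return float(self.tpr.sum())


def build_roc(
    experiments: Sequence[LooExperiment],
    fpr_max: float = 0.20,
    n_slots: int = 20,
) -> RocCurve:
    """Three-step slot ROC: per-experiment indicator, mean over a factor's
    sites, mean over factors."""
    if not experiments:
        raise ValueError("no experiments to build an ROC curve from")
    slot_fprs = fpr_max * np.arange(1, n_slots + 1) / n_slots
    by_tf: dict[str, list] = {}
    for exp in experiments:
        by_tf.setdefault(exp.tf_id, []).append(exp)
    per_tf = []
    for tf_id in sorted(by_tf):
        fprs = np.array([e.fpr for e in by_tf[tf_id]])
        per_tf.append((fprs[:, None] <= slot_fprs[None, :]).mean(axis=0))
    tpr = np.mean(per_tf, axis=0)
    return RocCurve(slot_fprs=slot_fprs, tpr=tpr, fpr_max=fpr_max, n_slots=n_slots)


def roc_curves_cross(a: RocCurve, b: RocCurve) -> bool:
    """True when the two curves cross (areas alone cannot rank them then)."""
    d = a.tpr - b.tpr
    return bool((d > 1e-12).any() and (d < -1e-12).any())


# ---------------------------------------------------------------------------
# Wilcoxon matched-pair signed-ranks test
# ---------------------------------------------------------------------------


@dataclass
class WilcoxonResult:
    """Signed-ranks comparison of two configurations on paired FP counts."""

    n_pairs: int  # pairs used, after zero-difference removal
    w_plus: float
    w_minus: float
    z: float
    p_value: float
    p_bound: str  # '<=0.01', '<=0.05' or 'ns'
    superior: str | None  # 'a', 'b' or None
    exact: bool


def _exact_two_sided_p(ranks: np.ndarray, w_small: float) -> float:
    """P(W <= w_small or W >= total - w_small) over all 2^n sign choices.

    The signed-rank distribution is symmetric about total/2 even with
    midranks, so twice the lower tail is the two-sided p.
    """
    # distribution of W+ via polynomial convolution over doubled ranks
    doubled = np.rint(2 * ranks).astype(int)
    dist = np.zeros(doubled.sum() + 1)
    dist[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: len(dist) - r]
        dist = dist + shifted
    dist /= dist.sum()
    lower = dist[: int(np.rint(2 * w_small)) + 1].sum()
    return float(min(1.0, 2.0 * lower))


def wilcoxon_compare(
    experiments_a: Sequence[LooExperiment],
    experiments_b: Sequence[LooExperiment],
    *,
    exact_max_n: int = 12,
) -> WilcoxonResult:
    """Wilcoxon matched-pair signed-ranks test on per-experiment FP counts.

    The experiment lists must be paired: same (tf_id, site_id) keys in the
    same order.  Lower FP counts are better, so ``superior='a'`` means the
    first configuration out-performed the second.
    """
    keys_a = [(e.tf_id, e.site_id) for e in experiments_a]
    keys_b = [(e.tf_id, e.site_id) for e in experiments_b]
    if keys_a != keys_b:
        raise ValueError("experiment lists are not paired (keys differ)")
    d = np.array([ea.fp - eb.fp for ea, eb in zip(experiments_a, experiments_b)], float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(0, 0.0, 0.0, 0.0, 1.0, "ns", None, True)
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    total = n * (n + 1) / 2
    mu = total / 2
    # tie correction on the normal approximation of the rank-sum variance
    _, counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24 - (counts**3 - counts).sum() / 48
    w_big = max(w_plus, w_minus)
    z = (w_big - mu) / np.sqrt(var) if var > 0 else 0.0
    exact = n <= exact_max_n
    if exact:
        p = _exact_two_sided_p(ranks, min(w_plus, w_minus))
    else:
        from scipy.stats import norm

        p = float(min(1.0, 2.0 * norm.sf(z)))
    if w_plus > w_minus:
        superior = "b"  # a accumulated more false positives
    elif w_minus > w_plus:
        superior = "a"
    else:
        superior = None
    bound = "<=0.01" if p <= 0.01 else "<=0.05" if p <= 0.05 else "ns"
    return WilcoxonResult(n, w_plus, w_minus, float(z), p, bound, superior, exact)


# ---------------------------------------------------------------------------
# significance plateau over a scope track
# ---------------------------------------------------------------------------


def _scope_sort_key(scope):
    if scope is None:
        return (0, 0)
    if scope == "full":
        return (2, 0)
    return (1, int(scope))


@dataclass
class PlateauReport:
    """Plateau of a scope track: where performance, after a significant
    rise, stops changing significantly."""

    scopes: list
    verdicts: list  # verdict entering scopes[i] from scopes[i-1]; verdicts[0] is None
    plateau: list = field(default_factory=list)
    aucs: dict = field(default_factory=dict)
    max_auc_scope: object = None
    peak_in_plateau: bool = False


def detect_plateau(
    per_scope_experiments: Mapping,
    *,
    alpha: float = 0.05,
    rule: str = "caption",
    fpr_max: float = 0.20,
    n_slots: int = 20,
) -> PlateauReport:
    """Locate the significance plateau over an ordered scope track.

    ``rule='caption'`` starts the plateau at the first scope that is
    significantly better than its predecessor *and* is followed by a
    non-significant change; ``rule='first_better'`` starts it at the first
    significantly-better scope regardless of what follows.  In both cases
    the plateau extends through consecutive non-significant changes.
    """
    if rule not in ("caption", "first_better"):
        raise ValueError("rule must be 'caption' or 'first_better'")
    scopes = sorted(per_scope_experiments, key=_scope_sort_key)
    if len(scopes) < 3:
        raise ValueError("plateau detection needs at least 3 scopes")
    exps = [per_scope_experiments[s] for s in scopes]
    verdicts: list = [None]
    for prev, cur in zip(exps, exps[1:]):
        res = wilcoxon_compare(prev, cur)
        if res.p_value <= alpha and res.superior == "b":
            verdicts.append("better")
        elif res.p_value <= alpha and res.superior == "a":
            verdicts.append("worse")
        else:
            verdicts.append("ns")
    aucs = {
        s: build_roc(e, fpr_max=fpr_max, n_slots=n_slots).auc
        for s, e in zip(scopes, exps)
    }
    max_scope = max(scopes, key=lambda s: (aucs[s], -scopes.index(s)))

    start = None
    for i in range(1, len(scopes)):
        if verdicts[i] != "better":
            continue
        if rule == "first_better" or (i + 1 < len(scopes) and verdicts[i + 1] == "ns"):
            start = i
            break
    plateau: list = []
    if start is not None:
        plateau = [scopes[start]]
        for i in range(start + 1, len(scopes)):
            if verdicts[i] == "ns":
                plateau.append(scopes[i])
            else:
                break
    return PlateauReport(
        scopes=scopes,
        verdicts=verdicts,
        plateau=plateau,
        aucs=aucs,
        max_auc_scope=max_scope,
        peak_in_plateau=max_scope in plateau,
    )
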