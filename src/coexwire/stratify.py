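"""Greedy block-based patient stratification.

The goal is to split a tumor cohort into subgroups whose members share a
coherent co-expression wiring: when distinct subgroups with different
wiring are mixed, their correlations superpose destructively, so the mixed
cohort shows few strong edges while each subgroup alone shows many.

The search proceeds per subgroup:

1. shuffle the cohort (seeded) and chunk it into blocks of 5 patients;
2. score every combination of 5 blocks (strong-edge count of the 25-sample
   union) exhaustively; the 5 blocks most frequent among the 100
   top-scoring combinations form the seed group;
3. *prune*: repeatedly delete the pair of patients whose removal gains the
   most strong edges, until no pair strictly gains — the "core group";
4. *extend*: repeatedly add the pair of remaining patients giving the best
   score, until the best addition strictly decreases the score (that pair
   is not added);
5. accept the resulting subgroup only if its score clears a null-calibrated
   bar (see :func:`stratify_cohort`), remove it, and repeat on the
   remainder; otherwise declare the remainder residual.

Scoring uses the fast complete-data strong-edge counter; every recorded
trace score is reproducible with :func:`score_group`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np

from .corrnet import (
    StrongEdgeCriteria,
    count_strong,
    pairwise_correlations,
    strong_count_complete,
)
from .data_io import ExpressionMatrix, GeneSet, subset_genes


@dataclass
class BlockPartition:
    """A seeded shuffle of a cohort chunked into fixed-size blocks."""

    blocks: list[list[str]]
    block_size: int
    seed: int

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def samples(self) -> list[str]:
        return [s for b in self.blocks for s in b]


@dataclass
class TraceRecord:
    """One step of the greedy search, with the score after the step."""

    stage: int
    action: str  # "seed" | "prune" | "extend" | "note"
    samples: tuple[str, ...]
    score: int


@dataclass
class SeedResult:
    samples: list[str]
    block_indices: tuple[int, ...]
    n_combinations: int
    top_combinations: list[tuple[tuple[int, ...], int]]  # (indices, score)


@dataclass
class StratifyConfig:
    block_size: int = 5
    choose: int = 5
    top_n: int = 100
    step: int = 2
    seed: int = 0
    acceptance_factor: float = 1.5
    n_null_runs: int = 2
    max_subgroups: int | None = None
    min_cohort: int = 10  # stop stratifying below this remainder size


@dataclass
class StratificationResult:
    subgroups: list[list[str]]
    residual: list[str]
    traces: list[TraceRecord]
    subgroup_scores: list[int]
    residual_score: int | None
    rejected_scores: list[tuple[int, int, int]] = field(default_factory=list)
    # (candidate score, parental score, null bar) for rejected stage candidates


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score_group(
    m: ExpressionMatrix,
    samples: list[str],
    genes: GeneSet,
    crit: StrongEdgeCriteria,
    method: str = "pearson",
    min_pair_n: int = 10,
) -> int:
    """Strong-edge count of a sample group over a gene set.

    The reference implementation behind every score in a stratification
    trace; the internal fast path is tested to be identical on complete
    data.
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 samples to score a group")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sub = subset_genes(m, genes)
        df = sub.values[list(samples)]
        if (df.std(axis=1, ddof=1).fillna(0.0) > 0).sum() < 2:
            raise ValueError(
                "correlations undefined: fewer than 2 genes vary over the group"
            )
        if method == "pearson" and not df.isna().any().any():
            return strong_count_complete(df.to_numpy(), crit)
        net = pairwise_correlations(sub, list(samples), method, min_pair_n)
    return count_strong(net, crit)


class _Scorer:
    """Cached fast scorer over a fixed gene panel (complete data only)."""

    def __init__(self, m: ExpressionMatrix, genes: GeneSet, crit: StrongEdgeCriteria):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sub = subset_genes(m, genes)
        self.columns = {s: j for j, s in enumerate(sub.sample_ids)}
        self.x = sub.values.to_numpy()
        self.complete = not np.isnan(self.x).any()
        self.m, self.genes, self.crit = m, genes, crit

    def __call__(self, samples: list[str]) -> int:
        if self.complete:
            idx = [self.columns[s] for s in samples]
            return strong_count_complete(self.x[:, idx], self.crit)
        return score_group(self.m, samples, self.genes, self.crit)


# ---------------------------------------------------------------------------
# Algorithm steps
# ---------------------------------------------------------------------------

def partition_blocks(
    cohort: list[str], block_size: int = 5, seed: int = 0
) -> BlockPartition:
    """Shuffle the cohort (seeded) and chunk into blocks of ``block_size``.

    All blocks have ``block_size`` members except possibly the last.
    """
    if block_size < 2:
        raise ValueError("block_size must be >= 2")
    cohort = list(cohort)
    if len(cohort) < 2 * block_size:
        raise ValueError("cohort too small to partition into blocks")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cohort))
    shuffled = [cohort[i] for i in order]
    blocks = [shuffled[i : i + block_size] for i in range(0, len(shuffled), block_size)]
    return BlockPartition(blocks, block_size, seed)


def seed_group(
    m: ExpressionMatrix,
    bp: BlockPartition,
    genes: GeneSet,
    crit: StrongEdgeCriteria,
    choose: int = 5,
    top_n: int = 100,
    scorer: "_Scorer | None" = None,
) -> SeedResult:
    """Exhaustively score all ``choose``-block combinations and seed from
    the blocks most frequent among the ``top_n`` best.

    Ranking ties break by lexicographic block-index tuple; frequency ties
    break by block index.
    """
    if bp.n_blocks < choose:
        raise ValueError(f"need at least {choose} blocks, have {bp.n_blocks}")
    total = comb(bp.n_blocks, choose)
    if top_n > total:
        warnings.warn(f"top_n clipped from {top_n} to the {total} combinations")
        top_n = total
    score = scorer or _Scorer(m, genes, crit)
    scored: list[tuple[int, tuple[int, ...]]] = []
    for idx in combinations(range(bp.n_blocks), choose):
        samples = [s for i in idx for s in bp.blocks[i]]
        scored.append((score(samples), idx))
    # descending score, ascending index tuple on ties
    scored.sort(key=lambda t: (-t[0], t[1]))
    top = scored[:top_n]
    freq = np.zeros(bp.n_blocks, dtype=int)
    for _, idx in top:
        for i in idx:
            freq[i] += 1
    chosen = tuple(sorted(np.lexsort((np.arange(bp.n_blocks), -freq))[:choose]))
    samples = [s for i in chosen for s in bp.blocks[i]]
    return SeedResult(
        samples, chosen, total, [(idx, sc) for sc, idx in top]
    )


def greedy_prune(
    m: ExpressionMatrix,
    group: list[str],
    genes: GeneSet,
    crit: StrongEdgeCriteria,
    step: int = 2,
    scorer: "_Scorer | None" = None,
    stage: int = 0,
) -> tuple[list[str], list[TraceRecord]]:
    """Iteratively delete the ``step`` patients whose removal maximally
    gains strong edges; stop when the best removal no longer strictly
    gains (that removal is not applied)."""
    score = scorer or _Scorer(m, genes, crit)
    current = sorted(group)
    trace: list[TraceRecord] = []
    if len(current) <= 2 * step:
        trace.append(TraceRecord(stage, "note", tuple(current), score(current)))
        return current, trace
    cur_score = score(current)
    while len(current) > 2 * step + 1:
        best_score, best_pair = -1, None
        for pair in combinations(current, step):
            remaining = [s for s in current if s not in pair]
            sc = score(remaining)
            if sc > best_score:
                best_score, best_pair = sc, pair
        if best_score <= cur_score:
            break
        current = [s for s in current if s not in best_pair]
        cur_score = best_score
        trace.append(TraceRecord(stage, "prune", best_pair, cur_score))
    return current, trace


def greedy_extend(
    m: ExpressionMatrix,
    core: list[str],
    candidates: list[str],
    genes: GeneSet,
    crit: StrongEdgeCriteria,
    step: int = 2,
    max_zero_gain: int | None = None,
    scorer: "_Scorer | None" = None,
    stage: int = 0,
) -> tuple[list[str], list[TraceRecord]]:
    """Iteratively add the ``step`` candidates giving the best score; stop
    at the first strictly score-decreasing best addition (that pair is
    excluded from the subgroup).

    Zero-gain additions are accepted (the stop condition is a *decrease*),
    optionally capped at ``max_zero_gain`` consecutive flat steps.
    """
    if set(core) & set(candidates):
        raise ValueError("candidates must be disjoint from the core")
    score = scorer or _Scorer(m, genes, crit)
    current = sorted(core)
    pool = sorted(candidates)
    trace: list[TraceRecord] = []
    if not pool:
        return current, trace
    cur_score = score(current)
    flat_streak = 0
    while len(pool) >= step:
        best_score, best_pair = -1, None
        for pair in combinations(pool, step):
            sc = score(current + list(pair))
            if sc > best_score:
                best_score, best_pair = sc, pair
        if best_score < cur_score:
            break
        if best_score == cur_score:
            flat_streak += 1
            if max_zero_gain is not None and flat_streak > max_zero_gain:
                break
        else:
            flat_streak = 0
        current = sorted(current + list(best_pair))
        pool = [s for s in pool if s not in best_pair]
        cur_score = best_score
        trace.append(TraceRecord(stage, "extend", best_pair, cur_score))
    return current, trace


# ---------------------------------------------------------------------------
# Full stratification
# ---------------------------------------------------------------------------

def _run_stage(
    m: ExpressionMatrix,
    cohort: list[str],
    genes: GeneSet,
    crit: StrongEdgeCriteria,
    config: StratifyConfig,
    seed: int,
    stage: int,
) -> tuple[list[str], int, list[TraceRecord]]:
    """One seed -> prune -> extend pass over a cohort; returns the candidate
    subgroup, its score, and the trace."""
    scorer = _Scorer(m, genes, crit)
    bp = partition_blocks(cohort, config.block_size, seed)
    seeded = seed_group(m, bp, genes, crit, config.choose, config.top_n, scorer)
    trace = [TraceRecord(stage, "seed", tuple(seeded.samples), scorer(seeded.samples))]
    core, t_prune = greedy_prune(
        m, seeded.samples, genes, crit, config.step, scorer, stage
    )
    remainder = [s for s in cohort if s not in set(core)]
    subgroup, t_extend = greedy_extend(
        m, core, remainder, genes, crit, config.step, None, scorer, stage
    )
    return subgroup, scorer(subgroup), trace + t_prune + t_extend


def _null_bar(
    m: ExpressionMatrix,
    cohort: list[str],
    genes: GeneSet,
    crit: StrongEdgeCriteria,
    config: StratifyConfig,
    seed: int,
    stage: int,
) -> int:
    """Best subgroup score the greedy search achieves on wiring-destroyed
    (gene-wise sample-permuted) copies of the cohort.

    Greedy maximization overfits: even on pure noise it assembles small
    groups with inflated strong-edge counts.  Running the identical search
    on permuted data measures that inflation, giving a calibrated
    acceptance bar for real candidates.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sub = subset_genes(m, genes)
    base = sub.values[list(cohort)]
    best = 0
    for j in range(config.n_null_runs):
        rng = np.random.default_rng((seed * 1009 + 7919 * (j + 1)) % (2**31))
        perm = base.to_numpy(copy=True)
        for g in range(perm.shape[0]):
            rng.shuffle(perm[g])
        null_vals = base.copy()
        null_vals.loc[:, :] = perm
        null_m = ExpressionMatrix(null_vals, scale_note="permutation null",
                                  log_base=m.log_base)
        _, sc, _ = _run_stage(null_m, list(cohort),
                              GeneSet(genes.name, list(null_vals.index)),
                              crit, config, seed + 1000 * (j + 1), stage)
        best = max(best, sc)
    return best


def stratify_cohort(
    m: ExpressionMatrix,
    cohort: list[str],
    genes: GeneSet,
    crit: StrongEdgeCriteria,
    config: StratifyConfig | None = None,
) -> StratificationResult:
    """Peel maximally-correlated subgroups off a cohort until the search
    stops finding real ones.

    A stage candidate is accepted only if its strong-edge score exceeds
    ``acceptance_factor`` times *both* the parental cohort's score and the
    null bar (the best score the same greedy search reaches on gene-wise
    permuted copies of the parental cohort, which calibrates greedy
    overfitting).  On rejection the stage's cohort becomes the residual.
    Fully deterministic given matrix, cohort order, and config.
    """
    config = config or StratifyConfig()
    remaining = list(cohort)
    subgroups: list[list[str]] = []
    scores: list[int] = []
    traces: list[TraceRecord] = []
    rejected: list[tuple[int, int, int]] = []
    residual_score: int | None = None
    stage = 0
    while True:
        stage += 1
        n_blocks = -(-len(remaining) // config.block_size)
        if (
            len(remaining) < max(config.min_cohort, 2 * config.block_size)
            or n_blocks < config.choose
        ):
            break
        if config.max_subgroups is not None and len(subgroups) >= config.max_subgroups:
            break
        parental = score_group(m, remaining, genes, crit)
        stage_seed = config.seed + stage - 1
        candidate, cand_score, trace = _run_stage(
            m, remaining, genes, crit, config, stage_seed, stage
        )
        bar = _null_bar(m, remaining, genes, crit, config, stage_seed, stage)
        threshold = config.acceptance_factor * max(parental, bar)
        if cand_score > threshold and len(candidate) < len(remaining):
            subgroups.append(candidate)
            scores.append(cand_score)
            traces.extend(trace)
            remaining = [s for s in remaining if s not in set(candidate)]
        else:
            rejected.append((cand_score, parental, bar))
            break
    if len(remaining) >= 3:
        residual_score = score_group(m, remaining, genes, crit)
    return StratificationResult(
        subgroups, remaining, traces, scores, residual_score, rejected
    )
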