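"""Pre-ranked gene set enrichment analysis (weighted Kolmogorov-Smirnov).

Genes are ranked by their correlation with an isoform proportion (descending
score).  For a gene set, a running sum walks the ranked list: each member
("hit") increments by its weighted score share ``|s_i|^p / sum_hits |s_j|^p``
and each non-member ("miss") decrements by ``1/(N - n_members)``.  The
enrichment score (ES) is the running-sum value of maximum absolute deviation
from zero; positive ES means the set concentrates among positively
correlated genes.

Because the input is a pre-ranked list, the permutation null resamples
member *labels* from the ranked universe (gene-label permutation): each null
draw places the same number of hits uniformly at random.  NES divides the ES
by the mean |null ES| of the same sign; the nominal p is the same-sign null
tail fraction; FDR uses the standard pooled positive/negative NES procedure
(a Benjamini-Hochberg alternative on nominal p is available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .correlation_screen import pearson_r

__all__ = [
    "GeneSet",
    "RankedList",
    "EnrichmentScore",
    "read_gmt",
    "rank_by_correlation",
    "enrichment_score",
    "run_preranked",
]

logger = logging.getLogger(__name__)

DEFAULT_WEIGHT = 1.0
DEFAULT_MIN_SIZE = 5
DEFAULT_MAX_SIZE = 500

#: |running sum| values within this tolerance of the maximum are treated as
#: tied; the earliest walk position wins.  Keeps the peak choice stable when
#: the positive and negative extremes are equal up to floating-point noise.
_TIE_TOL = 1e-9


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]
    description: str = ""


class RankedList:
    """Genes ordered by descending score; ties broken by gene id.

    Scores are typically correlation coefficients, so both signs occur.
    Gene ids must be unique.
    """

    def __init__(self, genes: Sequence[str], scores: Sequence[float]):
        if len(genes) != len(scores):
            raise ValueError("genes and scores differ in length")
        if len(set(genes)) != len(genes):
            raise ValueError("gene ids must be unique")
        order = sorted(range(len(genes)), key=lambda i: (-float(scores[i]), genes[i]))
        self.genes: tuple[str, ...] = tuple(genes[i] for i in order)
        self.scores: np.ndarray = np.asarray([float(scores[i]) for i in order])
        self._index = {g: i for i, g in enumerate(self.genes)}

    def __len__(self) -> int:
        return len(self.genes)

    def positions(self, members) -> np.ndarray:
        """Sorted ranked-list positions of the members present in the list."""
        return np.array(sorted(self._index[g] for g in members if g in self._index), dtype=int)


@dataclass(frozen=True)
class EnrichmentScore:
    es: float
    running_sum: np.ndarray
    peak_index: int


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, members per line)."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
            members = frozenset(g for g in fields[2:] if g)
            sets.append(GeneSet(name=fields[0], description=fields[1], members=members))
    return sets


def rank_by_correlation(
    expression: pd.DataFrame, phenotype: pd.Series, min_n: int = 10
) -> RankedList:
    """Rank genes by Pearson correlation with a phenotype vector.

    ``expression`` is genes x samples; samples are aligned by id.  Genes
    whose correlation is undefined (constant, too few complete pairs) are
    dropped.
    """
    common = expression.columns.intersection(phenotype.index)
    pheno = phenotype.loc[common].to_numpy(dtype=float)
    genes, scores = [], []
    for gene, row in expression[common].iterrows():
        val = pearson_r(pheno, row.to_numpy(dtype=float), min_n=min_n)
        if val.defined:
            genes.append(str(gene))
            scores.append(val.r)
    if not genes:
        raise ValueError("no gene has a defined correlation with the phenotype")
    return RankedList(genes, scores)


def _hit_weights(abs_scores_pow: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Normalized hit increments; falls back to equal weights when all
    member scores are zero under a positive weight exponent."""
    w = abs_scores_pow[positions]
    denom = w.sum()
    if denom == 0:
        logger.warning("all member scores are zero; falling back to unweighted increments")
        return np.full(len(positions), 1.0 / len(positions))
    return w / denom


def enrichment_score(
    ranked: RankedList, gene_set: GeneSet | Sequence[str], weight: float = DEFAULT_WEIGHT
) -> EnrichmentScore:
    """Weighted KS enrichment score with the full running sum.

    Ties in |running sum| resolve to the earliest position in the walk.
    """
    members = gene_set.members if isinstance(gene_set, GeneSet) else set(gene_set)
    positions = ranked.positions(members)
    n = len(ranked)
    nh = len(positions)
    if nh == 0:
        raise ValueError("gene set has no members in the ranked list")
    if nh >= n:
        raise ValueError("gene set covers the whole ranked list; ES undefined")

    abs_pow = np.abs(ranked.scores) ** weight
    increments = np.full(n, -1.0 / (n - nh))
    increments[positions] = _hit_weights(abs_pow, positions)
    running = np.cumsum(increments)
    abs_run = np.abs(running)
    peak = int(np.argmax(abs_run >= abs_run.max() - _TIE_TOL))
    return EnrichmentScore(es=float(running[peak]), running_sum=running, peak_index=peak)


def _es_batch(abs_scores_pow: np.ndarray, positions: np.ndarray, n: int) -> np.ndarray:
    """Enrichment scores for many hit-position sets at once.

    ``positions`` is (n_draws, n_hits), each row sorted ascending.  Only the
    running-sum values just before and just after each hit are candidate
    extremes, so the walk never needs to be materialized.
    """
    n_draws, nh = positions.shape
    miss_step = 1.0 / (n - nh)
    w = abs_scores_pow[positions]
    denom = w.sum(axis=1, keepdims=True)
    zero = denom[:, 0] == 0
    if zero.any():
        w[zero] = 1.0
        denom[zero] = float(nh)
    w = w / denom
    cumw = np.cumsum(w, axis=1)
    misses_before = positions - np.arange(nh)
    after = cumw - miss_step * misses_before
    before = after - w
    # interleave (before_0, after_0, before_1, ...) to preserve walk order
    cand = np.empty((n_draws, 2 * nh))
    cand[:, 0::2] = before
    cand[:, 1::2] = after
    abs_cand = np.abs(cand)
    idx = np.argmax(abs_cand >= abs_cand.max(axis=1, keepdims=True) - _TIE_TOL, axis=1)
    return cand[np.arange(n_draws), idx]


def _null_es(
    abs_scores_pow: np.ndarray, n: int, nh: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    positions = np.empty((n_perm, nh), dtype=int)
    for i in range(n_perm):
        positions[i] = rng.choice(n, size=nh, replace=False)
    positions.sort(axis=1)
    return _es_batch(abs_scores_pow, positions, n)


def run_preranked(
    ranked: RankedList,
    sets: Sequence[GeneSet],
    n_perm: int = 1000,
    seed: int | None = None,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
    weight: float = DEFAULT_WEIGHT,
    fdr_method: str = "nes_pooled",
) -> pd.DataFrame:
    """Run pre-ranked GSEA over gene sets with a seeded permutation null.

    Sets are filtered to those whose intersection with the ranked universe
    has size within [min_size, max_size].  Returns one row per retained set:
    name, n_genes, es, nes, nominal_p, fdr.
    """
    if fdr_method not in ("nes_pooled", "bh"):
        raise ValueError(f"unknown fdr_method {fdr_method!r}")
    rng = np.random.default_rng(seed)
    n = len(ranked)
    abs_pow = np.abs(ranked.scores) ** weight

    retained = []
    for gs in sets:
        positions = ranked.positions(gs.members)
        if min_size <= len(positions) <= max_size:
            retained.append((gs, positions))
    if not retained:
        raise ValueError("no gene set within the size bounds after intersection")

    rows = []
    null_nes_pos: list[np.ndarray] = []
    null_nes_neg: list[np.ndarray] = []
    for gs, positions in retained:
        es = _es_batch(abs_pow, positions[None, :], n)[0]
        null = _null_es(abs_pow, n, len(positions), n_perm, rng)

        pos_null = null[null > 0]
        neg_null = null[null < 0]
        mean_pos = np.abs(pos_null).mean() if len(pos_null) else np.nan
        mean_neg = np.abs(neg_null).mean() if len(neg_null) else np.nan

        same = pos_null if es >= 0 else neg_null
        if len(same) == 0:
            nominal_p = 1.0 / n_perm
            nes = np.nan
        else:
            nominal_p = float(np.mean(np.abs(same) >= abs(es)))
            norm = mean_pos if es >= 0 else mean_neg
            nes = float(es / norm)

        null_nes_pos.append(pos_null / mean_pos if len(pos_null) else np.array([]))
        null_nes_neg.append(neg_null / mean_neg if len(neg_null) else np.array([]))
        rows.append(
            {
                "set": gs.name,
                "n_genes": len(positions),
                "es": float(es),
                "nes": nes,
                "nominal_p": nominal_p,
            }
        )

    table = pd.DataFrame(rows)
    if fdr_method == "bh":
        from statsmodels.stats.multitest import multipletests

        table["fdr"] = multipletests(table["nominal_p"], method="fdr_bh")[1]
    else:
        table["fdr"] = _pooled_fdr(
            table["nes"].to_numpy(),
            np.concatenate(null_nes_pos) if null_nes_pos else np.array([]),
            np.concatenate(null_nes_neg) if null_nes_neg else np.array([]),
        )
    return table


def _pooled_fdr(
    nes: np.ndarray, pooled_pos: np.ndarray, pooled_neg: np.ndarray
) -> np.ndarray:
    """Standard GSEA FDR: for each observed NES, the pooled same-sign null
    tail fraction divided by the observed same-sign tail fraction, capped at 1."""
    fdr = np.full(len(nes), np.nan)
    obs_pos = nes[np.isfinite(nes) & (nes >= 0)]
    obs_neg = nes[np.isfinite(nes) & (nes < 0)]
    for i, v in enumerate(nes):
        if not np.isfinite(v):
            continue
        if v >= 0:
            null_frac = np.mean(pooled_pos >= v) if len(pooled_pos) else 0.0
            obs_frac = np.mean(obs_pos >= v)
        else:
            null_frac = np.mean(pooled_neg <= v) if len(pooled_neg) else 0.0
            obs_frac = np.mean(obs_neg <= v)
        fdr[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else np.nan
    return fdr
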