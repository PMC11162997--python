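"""Correlation screen of gene expression against isoform proportions.

For each candidate gene (typically a curated list of RNA-splicing factors)
the Pearson correlation is computed against every configured isoform
proportion in every configured measurement layer (e.g. cohort mRNA, cohort
protein).  A gene is flagged in a cohort when its maximum absolute
correlation over all (layer x isoform) pairs strictly exceeds the threshold
(default 0.4); factors are then ranked by the number of cohorts in which
they were flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_THRESHOLD",
    "PearsonValue",
    "ScreenResult",
    "pearson_r",
    "screen_genes",
    "screen_to_frame",
    "rank_factors",
]

DEFAULT_THRESHOLD = 0.4
DEFAULT_MIN_N = 10


@dataclass(frozen=True)
class PearsonValue:
    """A Pearson correlation or the reason it is undefined."""

    r: float
    n_used: int
    reason: str | None = None  # None, "insufficient_n", "zero_variance"

    @property
    def defined(self) -> bool:
        return self.reason is None


@dataclass
class ScreenResult:
    """Screen outcome for one gene in one cohort."""

    gene: str
    r_by_pair: dict[tuple[str, str], PearsonValue] = field(default_factory=dict)
    max_abs_r: float = np.nan
    flag: int = 0

    @property
    def n_used(self) -> dict[tuple[str, str], int]:
        return {k: v.n_used for k, v in self.r_by_pair.items()}


def pearson_r(x, y, min_n: int = DEFAULT_MIN_N) -> PearsonValue:
    """Sample Pearson correlation on pairwise-complete observations.

    Undefined (with a reason code) when fewer than ``min_n`` complete pairs
    remain or either vector is constant over them.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = len(x)
    if n < min_n:
        return PearsonValue(np.nan, n, "insufficient_n")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return PearsonValue(np.nan, n, "zero_variance")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    return PearsonValue(max(-1.0, min(1.0, r)), n)


def screen_genes(
    proportions: Mapping[str, pd.Series],
    layers: Mapping[str, pd.DataFrame],
    gene_list: Sequence[str],
    threshold: float = DEFAULT_THRESHOLD,
    min_n: int = DEFAULT_MIN_N,
    log2_expression: bool = False,
) -> list[ScreenResult]:
    """Correlate each gene with each isoform proportion in each layer.

    ``proportions`` maps isoform label -> Series indexed by sample id;
    ``layers`` maps layer name -> genes x samples expression DataFrame.
    Samples are aligned by id per (layer, isoform) pair.  A gene absent from
    a layer simply has no value for that layer.  The flag is 1 iff the
    maximum |r| over all defined pairs strictly exceeds ``threshold``.
    """
    results = []
    for gene in gene_list:
        res = ScreenResult(gene=gene)
        best = np.nan
        for layer_name, expr in layers.items():
            if gene not in expr.index:
                continue
            g = expr.loc[gene].astype(float)
            if log2_expression:
                g = np.log2(g + 1.0)
            for label, prop in proportions.items():
                common = g.index.intersection(prop.index)
                val = pearson_r(prop.loc[common], g.loc[common], min_n=min_n)
                res.r_by_pair[(layer_name, label)] = val
                if val.defined:
                    best = val.r if np.isnan(best) or abs(val.r) > abs(best) else best
        res.max_abs_r = abs(best) if np.isfinite(best) else np.nan
        res.flag = int(np.isfinite(best) and abs(best) > threshold)
        results.append(res)
    return results


def screen_to_frame(results: Sequence[ScreenResult]) -> pd.DataFrame:
    """Flatten screen results into a table (one row per gene)."""
    rows = []
    for res in results:
        row: dict = {"gene": res.gene, "max_abs_r": res.max_abs_r, "flag": res.flag}
        for (layer, label), val in res.r_by_pair.items():
            row[f"r[{layer}|{label}]"] = val.r
            row[f"n[{layer}|{label}]"] = val.n_used
        rows.append(row)
    return pd.DataFrame(rows)


def rank_factors(
    results_per_cohort: Mapping[str, Sequence[ScreenResult]], k: int = 5
) -> pd.DataFrame:
    """Rank genes by the number of cohorts in which they were flagged.

    Ties are broken lexicographically by gene name.  When no gene is flagged
    anywhere the top-k is still returned (all counts zero) with
    ``no_signal=True``.
    """
    if not results_per_cohort:
        raise ValueError("at least one screened cohort is required")
    counts: dict[str, int] = {}
    for results in results_per_cohort.values():
        for res in results:
            counts[res.gene] = counts.get(res.gene, 0) + int(res.flag)
    table = pd.DataFrame(
        {"gene": list(counts), "n_cohorts_flagged": list(counts.values())}
    )
    table = table.sort_values(
        ["n_cohorts_flagged", "gene"], ascending=[False, True], kind="mergesort"
    ).head(k)
    table["no_signal"] = bool((table["n_cohorts_flagged"] == 0).all())
    return table.reset_index(drop=True)
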