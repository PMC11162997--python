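"""Synthetic cohorts with known ground truth.

Emulates the statistical structure of junction-count cohorts so every
pipeline stage is testable without consortium downloads:

* per-sample isoform counts follow a Dirichlet-multinomial: a group-specific
  Dirichlet draw gives the sample's true isoform proportions, sequencing
  depth is negative-binomial, and reads are multinomial over the isoform
  classes plus a small "noise" class landing on a spurious acceptor (which
  exercises the unclassified path deterministically);
* expression matrices contain genes constructed to have a specified Pearson
  correlation with one isoform's proportion, plus independent background
  genes;
* EMT-style time courses move one isoform's proportion along a monotone
  logistic trajectory with truncated Gaussian noise, rescaling the other
  isoforms to stay on the simplex.

A single global seed spawns one independent stream per sample, so any sample
subset is reproducible on its own.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exon_model import GeneModel, build_classifier
from .junction_quant import JunctionRecord

__all__ = [
    "DEFAULT_LABEL_ORDER",
    "SimGroup",
    "SimConfig",
    "SimTruth",
    "SimulatedCohort",
    "toy_gene_model",
    "simulate_cohort",
    "simulate_correlated_expression",
    "simulate_timecourse",
]

#: Default isoform label order, by decreasing cohort-wide abundance in
#: healthy tissue (ex4:22bp most common at ~61%).
DEFAULT_LABEL_ORDER = ("ex4:22bp", "ex4:22bp/3bp", "ex4:ex6", "ex4:22bp/18bp")

#: Healthy-tissue mean isoform shares used as the default composition.
DEFAULT_MEAN_PROPORTIONS = (0.61, 0.15, 0.14, 0.10)

MAX_NOISE_FRACTION = 0.05


def toy_gene_model() -> GeneModel:
    """A small + strand gene model with the RPS24 microexon architecture
    (3, 18 and 22 bp microexons between the anchor and terminal exons)."""
    return GeneModel.from_dict(
        {
            "gene_id": "toygene",
            "chrom": "chr10",
            "strand": "+",
            "anchor": "ex4",
            "terminal": "ex6",
            "exons": [
                {"name": "ex4", "start": 901, "end": 1000, "kind": "constitutive"},
                {"name": "me3", "start": 2001, "end": 2003, "kind": "microexon"},
                {"name": "me18", "start": 3001, "end": 3018, "kind": "microexon"},
                {"name": "me22", "start": 4001, "end": 4022, "kind": "microexon"},
                {"name": "ex6", "start": 5001, "end": 5200, "kind": "constitutive"},
            ],
        }
    )


@dataclass(frozen=True)
class SimGroup:
    """One cohort group: name, size, and the Dirichlet parameters of its
    isoform composition (ordered as ``SimConfig.labels``)."""

    name: str
    n_samples: int
    alpha: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if any(a <= 0 for a in self.alpha):
            raise ValueError("Dirichlet alphas must be positive")


@dataclass
class SimConfig:
    seed: int
    groups: list[SimGroup]
    model: GeneModel = field(default_factory=toy_gene_model)
    labels: tuple[str, ...] = DEFAULT_LABEL_ORDER
    depth_mean: float = 2000.0
    depth_dispersion: float = 10.0  # NB size parameter; larger = less dispersed
    noise_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.noise_fraction <= MAX_NOISE_FRACTION):
            raise ValueError(f"noise_fraction must be in [0, {MAX_NOISE_FRACTION}]")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth_mean and depth_dispersion must be positive")


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort."""

    labels: tuple[str, ...]
    true_proportions: pd.DataFrame  # samples x labels, Dirichlet draws
    realized_counts: pd.DataFrame  # samples x (labels + "unclassified")
    group_means: pd.DataFrame  # groups x labels (Dirichlet means)


@dataclass
class SimulatedCohort:
    records: dict[str, list[JunctionRecord]]
    metadata: pd.DataFrame  # indexed by sample_id; columns: group, tissue
    truth: SimTruth
    config: SimConfig

    def write(self, out_dir: str | Path) -> None:
        """Emit one SJ.out.tab per sample, a metadata TSV and a truth JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sample, recs in self.records.items():
            with open(out / f"{sample}.SJ.out.tab", "w") as fh:
                for r in recs:
                    fh.write(
                        f"{r.chrom}\t{r.intron_start}\t{r.intron_end}\t{r.strand_code}\t"
                        f"{r.motif_code}\t{r.annotated}\t{r.unique_reads}\t"
                        f"{r.multimap_reads}\t{r.max_overhang}\n"
                    )
        self.metadata.to_csv(out / "metadata.tsv", sep="\t")
        truth = {
            "labels": list(self.truth.labels),
            "true_proportions": self.truth.true_proportions.round(10).to_dict(orient="index"),
            "realized_counts": self.truth.realized_counts.to_dict(orient="index"),
            "group_means": self.truth.group_means.round(10).to_dict(orient="index"),
        }
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)


def _acceptor_coords(model: GeneModel) -> tuple[int, dict[str, int], int]:
    """Donor coordinate, label -> acceptor coordinate, and a spurious
    acceptor coordinate inside the first intron (for noise reads)."""
    clf = build_classifier(model)
    label_to_acceptor = {label: coord for coord, label in clf.acceptor_map.items()}
    if model.strand == "+":
        spurious = min(label_to_acceptor.values()) - 7
        assert spurious > clf.donor_coord
    else:
        spurious = max(label_to_acceptor.values()) + 7
        assert spurious < clf.donor_coord
    return clf.donor_coord, label_to_acceptor, spurious


def _make_records(
    model: GeneModel,
    counts: dict[str, int],
    donor: int,
    label_to_acceptor: dict[str, int],
    spurious_acceptor: int,
) -> list[JunctionRecord]:
    strand_code = 1 if model.strand == "+" else 2
    records = []
    coords = dict(label_to_acceptor)
    coords["unclassified"] = spurious_acceptor
    for label in sorted(coords, key=lambda lab: coords[lab]):
        n = counts.get(label, 0)
        if n == 0:
            continue
        a, b = donor, coords[label]
        records.append(
            JunctionRecord(
                chrom=model.chrom,
                intron_start=min(a, b),
                intron_end=max(a, b),
                strand_code=strand_code,
                motif_code=1,
                annotated=1,
                unique_reads=int(n),
                multimap_reads=0,
                max_overhang=50,
            )
        )
    return records


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Draw a Dirichlet-multinomial junction-count cohort.

    Per sample: true proportions ~ Dirichlet(group alpha); depth ~ negative
    binomial(depth_mean, depth_dispersion) floored at 1; the number of noise
    reads ~ Binomial(depth, noise_fraction) lands on the spurious acceptor
    and the rest are multinomial over the isoform classes.
    """
    labels = config.labels
    donor, label_to_acceptor, spurious = _acceptor_coords(config.model)
    missing = [lab for lab in labels if lab not in label_to_acceptor]
    if missing:
        raise ValueError(f"labels absent from the gene model's classifier: {missing}")

    n_total = sum(g.n_samples for g in config.groups)
    streams = np.random.SeedSequence(config.seed).spawn(n_total)

    sample_ids, group_col = [], []
    true_rows, count_rows = [], []
    records: dict[str, list[JunctionRecord]] = {}
    size = config.depth_dispersion
    nb_p = size / (size + config.depth_mean)

    i = 0
    for group in config.groups:
        for _ in range(group.n_samples):
            rng = np.random.default_rng(streams[i])
            sample_id = f"{group.name}_{i:04d}"
            p = rng.dirichlet(group.alpha)
            depth = max(1, int(rng.negative_binomial(size, nb_p)))
            n_noise = int(rng.binomial(depth, config.noise_fraction)) if config.noise_fraction else 0
            class_counts = rng.multinomial(depth - n_noise, p)
            counts = {lab: int(c) for lab, c in zip(labels, class_counts)}
            counts["unclassified"] = n_noise

            sample_ids.append(sample_id)
            group_col.append(group.name)
            true_rows.append(dict(zip(labels, p)))
            count_rows.append(counts)
            records[sample_id] = _make_records(
                config.model, counts, donor, label_to_acceptor, spurious
            )
            i += 1

    index = pd.Index(sample_ids, name="sample_id")
    metadata = pd.DataFrame({"group": group_col, "tissue": group_col}, index=index)
    truth = SimTruth(
        labels=labels,
        true_proportions=pd.DataFrame(true_rows, index=index),
        realized_counts=pd.DataFrame(count_rows, index=index),
        group_means=pd.DataFrame(
            {
                g.name: {lab: a / sum(g.alpha) for lab, a in zip(labels, g.alpha)}
                for g in config.groups
            }
        ).T,
    )
    return SimulatedCohort(records=records, metadata=metadata, truth=truth, config=config)


def simulate_correlated_expression(
    proportions: pd.DataFrame,
    targets: Sequence[tuple[str, str, float]],
    n_background: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Build a genes x samples expression matrix with planted correlations.

    ``targets`` is a list of (gene, isoform label, true r): each target gene
    is ``r * z + sqrt(1 - r^2) * eps`` where z is the standardized isoform
    proportion across samples and eps is unit normal, so its population
    Pearson correlation with the proportion is exactly r.  Background genes
    are independent unit-normal noise named ``BG0001``...
    """
    rng = np.random.default_rng(seed)
    n = len(proportions)
    rows, names = [], []
    for gene, label, true_r in targets:
        if not (-1.0 < true_r < 1.0):
            raise ValueError(f"|true_r| must be < 1, got {true_r}")
        p = proportions[label].to_numpy(dtype=float)
        sd = p.std()
        if sd == 0:
            raise ValueError(f"proportions of {label!r} are constant; cannot standardize")
        z = (p - p.mean()) / sd
        eps = rng.standard_normal(n)
        rows.append(true_r * z + np.sqrt(1.0 - true_r**2) * eps)
        names.append(gene)
    for j in range(n_background):
        rows.append(rng.standard_normal(n))
        names.append(f"BG{j + 1:04d}")
    return pd.DataFrame(rows, index=pd.Index(names, name="gene"), columns=proportions.index)


def _logistic_path(
    time_points: np.ndarray, start_p: float, end_p: float, steepness: float = 3.0
) -> np.ndarray:
    """Monotone logistic interpolation hitting start_p and end_p exactly.

    ``steepness`` is the half-range of the underlying logistic argument; the
    default of 3 keeps the trajectory sigmoidal while every sampled time
    point still shows appreciable progression (very large values degenerate
    toward a step function whose flat ends are indistinguishable under
    measurement noise).
    """
    t = np.asarray(time_points, dtype=float)
    if t.max() == t.min():
        raise ValueError("time points must span a nonzero interval")
    x = 2.0 * steepness * (t - t.min()) / (t.max() - t.min()) - steepness
    lo = 1.0 / (1.0 + np.exp(steepness))
    hi = 1.0 / (1.0 + np.exp(-steepness))
    u = (1.0 / (1.0 + np.exp(-x)) - lo) / (hi - lo)
    return start_p + (end_p - start_p) * u


def simulate_timecourse(
    time_points: Sequence[float],
    start_p: float,
    end_p: float,
    noise_sd: float = 0.0,
    replicates: int = 1,
    seed: int | None = None,
    label: str = "ex4:22bp",
    labels: tuple[str, ...] = DEFAULT_LABEL_ORDER,
    base_proportions: tuple[float, ...] = DEFAULT_MEAN_PROPORTIONS,
    steepness: float = 3.0,
) -> pd.DataFrame:
    """EMT-style time course: one isoform's proportion moves along a logistic
    trajectory from start_p to end_p with truncated Gaussian noise.

    Returns a cohort-style table (one row per replicate per time point) with
    one column per isoform label plus a ``time`` column.  The tracked
    isoform's noise is truncated to (0, 1); the remaining isoforms keep
    their relative base composition scaled to ``1 - p(t)``.
    """
    if not (0.0 < start_p < 1.0 and 0.0 < end_p < 1.0):
        raise ValueError("start_p and end_p must lie in (0, 1)")
    if label not in labels:
        raise ValueError(f"{label!r} not among labels {labels}")
    rng = np.random.default_rng(seed)
    tp = np.asarray(list(time_points), dtype=float)
    if len(np.unique(tp)) < len(tp):
        raise ValueError("time points must be distinct")
    path = _logistic_path(tp, start_p, end_p, steepness=steepness)

    others = [lab for lab in labels if lab != label]
    base = np.asarray([base_proportions[labels.index(lab)] for lab in others], dtype=float)
    base = base / base.sum()

    eps = 1e-9
    rows, times = [], []
    for t, mu in zip(tp, path):
        for _ in range(replicates):
            if noise_sd > 0:
                a, b = (eps - mu) / noise_sd, (1.0 - eps - mu) / noise_sd
                p_t = float(stats.truncnorm.rvs(a, b, loc=mu, scale=noise_sd, random_state=rng))
            else:
                p_t = float(mu)
            row = {label: p_t}
            for lab, share in zip(others, base):
                row[lab] = share * (1.0 - p_t)
            rows.append(row)
            times.append(t)
    table = pd.DataFrame(rows)
    table["time"] = times
    table.index = pd.Index([f"T{i:03d}" for i in range(len(table))], name="sample_id")
    return table
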