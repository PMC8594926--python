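"""Descriptive analytics over annotated count tables.

Covers the standard small-RNA library characterisations: per-biotype size
distributions, first-nucleotide bias (the canonical 5'-U bias of piRNA),
between-method log2 fold differences per unique sequence, sample correlation
with hierarchical clustering, and saturation (sequence-richness vs depth)
analysis fitted with an asymptotic regression
``richness(d) = Asym + (R0 - Asym) * exp(-exp(lrc) * d)`` — the classic
self-starting asymptotic form.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.optimize import curve_fit
from scipy.spatial.distance import squareform

from .annotate import AnnotationRecord


def _biotype_series(cpm_values: pd.DataFrame, records: Mapping[str, AnnotationRecord]) -> pd.Series:
    def label(seq: str) -> str:
        rec = records.get(seq)
        if rec is None or rec.status != "annotated":
            return "unannotated"
        return rec.biotype

    return pd.Series({seq: label(seq) for seq in cpm_values.index}).reindex(cpm_values.index)


def size_distribution(
    cpm_values: pd.DataFrame,
    records: Mapping[str, AnnotationRecord],
    min_len: int = 5,
    max_len: int = 70,
) -> pd.DataFrame:
    """Mean-over-samples cpm per (biotype, fragment length).

    Rows: MultiIndex (biotype, length) over lengths ``min_len..max_len``;
    values: the across-sample mean of the summed cpm of sequences with that
    biotype and length. Summing every cell recovers the table's mean total
    cpm (conservation).
    """
    biotype = _biotype_series(cpm_values, records)
    length = pd.Series([len(s) for s in cpm_values.index], index=cpm_values.index)
    mean_cpm = cpm_values.mean(axis=1)
    grouped = mean_cpm.groupby([biotype, length]).sum()
    grouped.index.names = ["biotype", "length"]
    biotypes = sorted(biotype.unique())
    full_index = pd.MultiIndex.from_product(
        [biotypes, range(min_len, max_len + 1)], names=["biotype", "length"]
    )
    return grouped.reindex(full_index, fill_value=0.0).to_frame("mean_cpm")


def first_nt_bias(
    cpm_values: pd.DataFrame,
    records: Mapping[str, AnnotationRecord],
    position: int = 1,
) -> pd.DataFrame:
    """cpm-weighted base composition at ``position`` (1-based) per biotype.

    Reported in the RNA alphabet (T shown as U); A/C/G/U fractions sum to 1
    per biotype, with the N mass reported separately in an ``N`` column.
    """
    biotype = _biotype_series(cpm_values, records)
    base = pd.Series(
        [s[position - 1] if len(s) >= position else "N" for s in cpm_values.index],
        index=cpm_values.index,
    ).replace("T", "U")
    mean_cpm = cpm_values.mean(axis=1)
    table = mean_cpm.groupby([biotype, base]).sum().unstack(fill_value=0.0)
    table = table.reindex(columns=["A", "C", "G", "U", "N"], fill_value=0.0)
    acgu = table[["A", "C", "G", "U"]]
    fractions = acgu.div(acgu.sum(axis=1), axis=0)
    fractions["N"] = table["N"] / table.sum(axis=1)
    return fractions


@dataclass
class FoldChangeResult:
    table: pd.DataFrame  # sequence-indexed: mean_cpm_A, mean_cpm_B, log2fc, direction
    pct_up: float
    pct_down: float
    pct_unchanged: float


def log2_fold(
    cpm_values: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    pseudocount: float = 1.0,
    threshold: float = 0.0,
) -> FoldChangeResult:
    """Per-sequence log2 fold difference between two sample groups.

    ``log2fc = log2((mean_A + pc) / (mean_B + pc))``; direction is the sign
    (sequences with |log2fc| <= ``threshold`` count as unchanged; the default
    threshold 0 makes the call sign-only). Swapping the groups negates every
    log2fc.
    """
    if not list(group_a) or not list(group_b):
        raise ValueError("both groups must be non-empty")
    mean_a = cpm_values[list(group_a)].mean(axis=1)
    mean_b = cpm_values[list(group_b)].mean(axis=1)
    log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    direction = pd.Series("unchanged", index=cpm_values.index)
    direction[log2fc > threshold] = "up"
    direction[log2fc < -threshold] = "down"
    table = pd.DataFrame(
        {"mean_cpm_A": mean_a, "mean_cpm_B": mean_b, "log2fc": log2fc, "direction": direction}
    )
    n = len(table)
    counts = direction.value_counts()
    pct = lambda k: 100.0 * counts.get(k, 0) / n if n else float("nan")
    return FoldChangeResult(table, pct("up"), pct("down"), pct("unchanged"))


def correlation_cluster(
    cpm_values: pd.DataFrame,
    method: str = "pearson",
    linkage_method: str = "average",
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise sample correlation on log2(cpm+1) with hierarchical clustering.

    Returns the correlation matrix and the dendrogram leaf order (sample ids)
    from average-linkage clustering on the ``1 - r`` distance.
    """
    if cpm_values.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    log_vals = np.log2(cpm_values + 1.0)
    constant = log_vals.columns[log_vals.std(axis=0) == 0]
    if len(constant):
        raise ValueError(f"constant sample column(s), correlation undefined: {list(constant)}")
    corr = log_vals.corr(method=method)
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    order = leaves_list(linkage(condensed, method=linkage_method))
    return corr, [corr.columns[i] for i in order]


@dataclass
class SaturationFit:
    """Sequence richness vs sequencing depth with an asymptotic fit."""

    depths: list[int]
    richness: list[float]  # mean over replicate subsamples
    Asym: Optional[float] = None
    R0: Optional[float] = None
    lrc: Optional[float] = None
    fitted: Optional[list[float]] = None
    converged: bool = False
    seed: Optional[int] = None

    def predict(self, depth: np.ndarray | float) -> np.ndarray | float:
        if not self.converged:
            raise ValueError("fit did not converge")
        return _asymp(np.asarray(depth, dtype=float), self.Asym, self.R0, self.lrc)


def _asymp(d, Asym, R0, lrc):
    return Asym + (R0 - Asym) * np.exp(-np.exp(lrc) * d)


def _initial_values(depths: np.ndarray, rich: np.ndarray) -> tuple[float, float, float]:
    """Self-starting initial values: Asym just above the max observed
    richness, R0 at the shallowest depth, lrc from a log-linear probe."""
    asym0 = float(rich.max()) * 1.05 or 1.0
    r00 = float(rich[np.argmin(depths)])
    resid = np.clip(asym0 - rich, 1e-9, None)
    slope = np.polyfit(depths, np.log(resid), 1)[0]
    lrc0 = float(np.log(max(-slope, 1e-12)))
    return asym0, r00, lrc0


def saturation_curve(
    sequences: Sequence[str],
    fractions: Sequence[float] = (0.05, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0),
    threshold: int = 1,
    n_reps: int = 3,
    seed: int = 0,
) -> SaturationFit:
    """Richness (distinct sequences with count >= ``threshold``) at subsampled
    depths, fitted with the asymptotic regression model.

    Subsampling is without replacement from the read list; each fraction is
    drawn ``n_reps`` times and the mean richness reported. On fit
    non-convergence the raw points are returned with ``converged=False``.
    """
    sequences = list(sequences)
    if not sequences:
        raise ValueError("empty read list")
    if not all(0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    arr = np.asarray(sequences, dtype=object)
    n = len(arr)
    depths: list[int] = []
    richness: list[float] = []
    for f in sorted(fractions):
        depth = max(1, round(f * n))
        reps = []
        for _ in range(n_reps):
            if depth == n:
                sub = arr
            else:
                sub = arr[rng.choice(n, size=depth, replace=False)]
            counts = Counter(sub)
            reps.append(sum(1 for v in counts.values() if v >= threshold))
        depths.append(depth)
        richness.append(float(np.mean(reps)))
    fit = SaturationFit(depths=depths, richness=richness, seed=seed)
    d_arr = np.asarray(depths, dtype=float)
    r_arr = np.asarray(richness, dtype=float)
    if np.ptp(r_arr) == 0:  # already saturated at every depth: flat asymptote
        fit.Asym = fit.R0 = float(r_arr[0])
        fit.lrc = 0.0
        fit.fitted = [float(r_arr[0])] * len(depths)
        fit.converged = True
        return fit
    try:
        p0 = _initial_values(d_arr, r_arr)
        popt, _ = curve_fit(_asymp, d_arr, r_arr, p0=p0, maxfev=10000)
        fit.Asym, fit.R0, fit.lrc = map(float, popt)
        fit.fitted = [float(v) for v in _asymp(d_arr, *popt)]
        fit.converged = True
    except (RuntimeError, TypeError, ValueError):
        fit.converged = False
    return fit
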