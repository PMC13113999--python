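"""Taxon-biomarker Spearman correlation networks and the F/B ratio.

Correlations between genus-level relative abundances and biomarker
relative expression are measured by Spearman's rank correlation
(Pearson correlation of midranks, so ties get average ranks).
Significance is two-sided; for small sample sizes (n <= 8) the exact
permutation null over all n! rank orderings is enumerated, otherwise
the usual t approximation t = rho * sqrt((n-2)/(1-rho^2)) on n-2 df is
used.  Edges are kept at p <= alpha (boundary inclusive), optionally
after Benjamini-Hochberg adjustment.

The Firmicutes/Bacteroidota (F/B) abundance ratio, a coarse
gut-ecology indicator, is computed per sample from a phylum-rank
table; "Bacteroidetes" is accepted as a synonym for Bacteroidota.
"""

from __future__ import annotations

import itertools
import math
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    JoinError,
    MissingPhylumError,
    NormalizationError,
    TableParseError,
    UndefinedCorrelationError,
    ValidationError,
)

PValueMethod = Literal["exact_permutation", "t_approx", "auto"]
Adjust = Literal["none", "bh"]

EXACT_N_MAX = 8

# Phylum-name synonyms, lower-cased (older vs current nomenclature).
_PHYLUM_SYNONYMS = {"bacteroidetes": "bacteroidota"}


@dataclass(frozen=True)
class AbundanceTable:
    """Taxon x sample abundance matrix with a rank tag per taxon."""

    data: pd.DataFrame  # rows: taxa, columns: samples
    ranks: pd.Series  # taxon -> "phylum" | "genus"

    def __post_init__(self) -> None:
        if (self.data.to_numpy() < 0).any():
            raise ValidationError("abundances must be nonnegative")
        if not self.data.index.equals(self.ranks.index):
            raise ValidationError("rank tags must cover exactly the table's taxa")

    @classmethod
    def from_frame(cls, data: pd.DataFrame, rank: str = "genus") -> "AbundanceTable":
        return cls(data=data, ranks=pd.Series(rank, index=data.index))


@dataclass(frozen=True)
class BiomarkerTable:
    """Marker x sample relative-expression matrix (positive values)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or (vals <= 0).any():
            raise ValidationError("biomarker expression must be positive and finite")


@dataclass(frozen=True)
class CorrelationEdge:
    """One significant taxon-marker association."""

    taxon: str
    marker: str
    rho: float
    p_value: float

    @property
    def sign(self) -> Literal["positive", "negative"]:
        return "positive" if self.rho >= 0 else "negative"


def relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Normalize each sample column to sum to 1 (idempotent)."""
    sums = table.data.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise NormalizationError(f"all-zero sample(s): {list(zero.index)}")
    return AbundanceTable(data=table.data.div(sums, axis=1), ranks=table.ranks)


def _find_phylum(table: AbundanceTable, name: str) -> str:
    target = name.lower()
    for taxon in table.data.index:
        canon = _PHYLUM_SYNONYMS.get(str(taxon).lower(), str(taxon).lower())
        if canon == target:
            return taxon
    raise MissingPhylumError(f"phylum {name!r} not found in the table")


def fb_ratio(table: AbundanceTable) -> pd.Series:
    """Per-sample Firmicutes/Bacteroidota ratio from a phylum-rank table.

    Samples where Bacteroidota is zero get NaN (undefined ratio) rather
    than raising.  Scale-invariant: normalization does not change it.
    """
    if not (table.ranks.str.lower() == "phylum").all():
        raise ValidationError("F/B ratio requires a phylum-rank table")
    f = table.data.loc[_find_phylum(table, "firmicutes")].astype(float)
    b = table.data.loc[_find_phylum(table, "bacteroidota")].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = f / b
    return ratio.where(b != 0, other=np.nan).rename("fb_ratio")


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman's rho: Pearson correlation of midranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValidationError("need at least 3 paired samples")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("inputs must be finite")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise UndefinedCorrelationError("constant vector: correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(abs(rho) - 1.0) < 1e-12:  # perfectly monotone up to rounding
        rho = math.copysign(1.0, rho)
    return max(-1.0, min(1.0, rho))


def _exact_permutation_p(rho_obs: float, n: int) -> float:
    """Two-sided exact p over all n! orderings of untied ranks."""
    base = np.arange(1, n + 1, dtype=float)
    base_c = base - base.mean()
    denom = float(np.sum(base_c**2))
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        rho_perm = float(np.dot(base_c, base_c[list(perm)])) / denom
        if abs(rho_perm) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman_pvalue(rho: float, n: int, method: PValueMethod = "auto") -> float:
    """Two-sided p-value for an observed Spearman rho at sample size n.

    ``exact_permutation`` enumerates the n! permutation null (untied
    ranks; n <= 8).  ``t_approx`` uses the Student-t approximation.
    ``auto`` picks exact for n <= 8.
    """
    if n < 3:
        raise ValidationError("need n >= 3")
    if not -1.0 <= rho <= 1.0:
        raise ValidationError("rho must be in [-1, 1]")
    if method == "auto":
        method = "exact_permutation" if n <= EXACT_N_MAX else "t_approx"
    if method == "exact_permutation":
        if n > EXACT_N_MAX:
            raise ValidationError(f"exact enumeration limited to n <= {EXACT_N_MAX}")
        return _exact_permutation_p(rho, n)
    if method == "t_approx":
        if abs(rho) >= 1.0:
            return sys.float_info.min  # |rho| = 1 limit: p underflows to ~0
        t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
        return 2.0 * stats.t.sf(abs(t), n - 2)
    raise ValidationError(f"unknown p-value method {method!r}")


def spearman_test(x: np.ndarray, y: np.ndarray, method: PValueMethod = "auto") -> tuple[float, float]:
    """Convenience: (rho, two-sided p) for one pair of vectors."""
    rho = spearman_rho(x, y)
    return rho, spearman_pvalue(rho, len(np.asarray(x)), method)


def build_network(
    abundance: AbundanceTable,
    biomarkers: BiomarkerTable,
    alpha: float = 0.05,
    adjust: Adjust = "none",
    p_method: PValueMethod = "auto",
) -> list[CorrelationEdge]:
    """All-pairs taxon x marker Spearman network thresholded at p <= alpha.

    Tables are joined on their shared samples (>= 3 required).  Pairs
    with a constant vector (correlation undefined) are skipped.  Edge
    order is deterministic: taxon then marker, lexicographic.
    """
    shared = sorted(set(abundance.data.columns) & set(biomarkers.data.columns))
    if len(shared) < 3:
        raise JoinError(
            f"only {len(shared)} shared sample(s) between abundance and biomarker tables"
        )
    n = len(shared)
    a = abundance.data[shared]
    b = biomarkers.data[shared]
    records: list[tuple[str, str, float, float]] = []
    for taxon in sorted(map(str, a.index)):
        for marker in sorted(map(str, b.index)):
            try:
                rho = spearman_rho(a.loc[taxon].to_numpy(), b.loc[marker].to_numpy())
            except UndefinedCorrelationError:
                continue
            p = spearman_pvalue(rho, n, p_method)
            records.append((taxon, marker, rho, p))
    if not records:
        return []
    pvals = np.array([r[3] for r in records])
    if adjust == "bh":
        pvals = multipletests(pvals, method="fdr_bh")[1]
    elif adjust != "none":
        raise ValidationError(f"unknown adjustment {adjust!r}")
    return [
        CorrelationEdge(taxon=t, marker=m, rho=rho, p_value=float(p_adj))
        for (t, m, rho, _), p_adj in zip(records, pvals)
        if p_adj <= alpha
    ]


def edges_to_frame(edges: list[CorrelationEdge]) -> pd.DataFrame:
    """Edge list as a tidy DataFrame (taxon, marker, rho, p, sign)."""
    return pd.DataFrame(
        [(e.taxon, e.marker, e.rho, e.p_value, e.sign) for e in edges],
        columns=["taxon", "marker", "rho", "p", "sign"],
    )


def edges_to_graphml(edges: list[CorrelationEdge], path: str | Path) -> None:
    """Export the bipartite network to GraphML (taxon and marker nodes)."""
    import networkx as nx

    g = nx.Graph()
    for e in edges:
        g.add_node(e.taxon, kind="taxon")
        g.add_node(e.marker, kind="marker")
        g.add_edge(e.taxon, e.marker, rho=e.rho, p=e.p_value, sign=e.sign)
    nx.write_graphml(g, str(path))


def read_abundance_tsv(path: str | Path) -> AbundanceTable:
    """Read an abundance TSV: columns `taxon`, `rank`, then samples."""
    df = pd.read_csv(path, sep="\t")
    for col in ("taxon", "rank"):
        if col not in df.columns:
            raise TableParseError(f"{path}: missing column {col!r}")
    ranks = pd.Series(df["rank"].to_numpy(), index=df["taxon"])
    data = df.drop(columns=["taxon", "rank"]).set_axis(df["taxon"], axis=0)
    return AbundanceTable(data=data.astype(float), ranks=ranks)


def read_biomarker_tsv(path: str | Path) -> BiomarkerTable:
    """Read a biomarker TSV: first column `marker`, remaining columns samples."""
    df = pd.read_csv(path, sep="\t")
    if "marker" not in df.columns:
        raise TableParseError(f"{path}: missing column 'marker'")
    data = df.drop(columns=["marker"]).set_axis(df["marker"], axis=0)
    return BiomarkerTable(data=data.astype(float))
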