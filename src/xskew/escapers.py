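"""Covariation profiling: escaper calls, direction tests, distribution shifts.

Because every X-inactivated gene in an individual reads out the same
realised inactivation fraction, X-inactivated genes covary strongly
across individuals, while escapers and autosomal genes — whose allelic
ratio is set by cis regulation alone — do not.  This module turns that
contrast into an explicit classifier:

* a gene-by-gene Pearson correlation matrix over per-individual mean
  fractions (technical replicates averaged, both crosses pooled);
* agglomerative (AGNES-style) hierarchical clustering under the absolute
  Pearson correlation distance d = 1 - |r|, average linkage — the
  absolute value matters because an Xist-like gene expressed from the
  *inactive* X is perfectly anti-correlated with the inactivated set and
  must cluster with it;
* per-gene consensus scores (median |r| against a seed set of known
  inactivated genes) thresholded with autosomal controls as the
  calibration null.

Also here: the exact binomial sign test for a chromosome-wide direction
of parent-of-origin bias, per-gene reciprocal-cross differences, and
pairwise Kolmogorov-Smirnov tests for chromosome-level shifts of those
differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance
import scipy.stats

from .data_model import ExpressionTable, maternal_is_reference
from .errors import DesignError

_ZERO_VAR = 1e-12


# ---------------------------------------------------------------------------
# correlation profile


@dataclass
class CorrelationProfile:
    """Gene-by-gene correlation structure over individuals.

    ``corr`` is the Pearson matrix over per-individual mean fractions;
    ``consensus`` maps each gene to its median |r| against the seed set
    of known-inactivated genes (self-correlations excluded).
    """

    corr: pd.DataFrame
    consensus: pd.Series
    individuals: list[str]
    excluded: list[str] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return list(self.corr.index)


def correlation_profile(
    table: ExpressionTable,
    genes: Sequence[str] | None = None,
    *,
    min_individuals: int = 3,
) -> CorrelationProfile:
    """Pearson correlation of per-individual mean fractions between genes.

    Females from both reciprocal crosses are pooled and duplicates are
    averaged per (gene, individual) before correlating.  Genes with
    (numerically) zero variance across individuals are excluded with a
    warning.
    """
    fem = table.females()
    if genes is not None:
        fem = fem[fem["gene_id"].isin(set(genes))]
    wide = (
        fem.groupby(["individual_id", "gene_id"])["ref_fraction"]
        .mean()
        .unstack("gene_id")
        .sort_index(axis=1)
    )
    if len(wide) < min_individuals:
        raise DesignError(
            f"correlation profile needs >= {min_individuals} individuals; got {len(wide)}"
        )
    sds = wide.std(ddof=1)
    constant = sorted(sds.index[sds.fillna(0.0) <= _ZERO_VAR])
    if constant:
        warnings.warn(
            f"excluding constant gene(s) from correlation profile: {constant}",
            stacklevel=2,
        )
        wide = wide.drop(columns=constant)
    if wide.shape[1] < 2:
        raise DesignError("fewer than 2 variable genes; no correlation structure")
    corr = wide.corr(method="pearson")

    seed = [
        g
        for g in table.genes_of_class(["inactivated"])
        if g in corr.index
    ]
    consensus = _consensus_scores(corr, seed)
    return CorrelationProfile(
        corr=corr,
        consensus=consensus,
        individuals=list(wide.index),
        excluded=constant,
    )


def _consensus_scores(corr: pd.DataFrame, seed: Sequence[str]) -> pd.Series:
    """Median |r| of each gene against the seed set, excluding itself."""
    scores = {}
    for g in corr.index:
        others = [s for s in seed if s != g]
        if not others:
            scores[g] = np.nan
            continue
        scores[g] = float(np.median(np.abs(corr.loc[g, others])))
    return pd.Series(scores, name="consensus_score")


# ---------------------------------------------------------------------------
# clustering


@dataclass
class ClusterTree:
    """Agglomerative merge tree under d = 1 - |r|.

    ``linkage`` is a scipy linkage matrix over ``labels`` (which are
    sorted lexicographically before clustering so ties break
    deterministically).
    """

    linkage: np.ndarray
    labels: list[str]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> list[str]:
        order = scipy.cluster.hierarchy.leaves_list(self.linkage)
        return [self.labels[i] for i in order]

    def cophenetic(self) -> pd.DataFrame:
        d = scipy.cluster.hierarchy.cophenet(self.linkage)
        return pd.DataFrame(
            scipy.spatial.distance.squareform(d), index=self.labels, columns=self.labels
        )

    def to_newick(self) -> str:
        """Serialize as a Newick string with branch lengths from merge heights."""
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}

        def node(i: int) -> str:
            if i < n:
                return self.labels[i]
            a, b, h, _ = self.linkage[i - n]
            a, b = int(a), int(b)
            return (
                f"({node(a)}:{h - heights[a]:.6g},{node(b)}:{h - heights[b]:.6g})"
            )

        for k, (_, _, h, _) in enumerate(self.linkage):
            heights[n + k] = h
        return node(2 * n - 2) + ";"


def cluster_genes(profile: CorrelationProfile, *, method: str = "average") -> ClusterTree:
    """Agglomerative clustering of genes on absolute-correlation distance.

    Average linkage by default (the classical agglomerative-nesting
    choice); any scipy linkage method may be requested.
    """
    labels = sorted(profile.genes)
    if len(labels) < 2:
        raise DesignError("clustering needs at least 2 genes")
    corr = profile.corr.loc[labels, labels]
    dist = 1.0 - corr.abs().to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # exact symmetry for squareform
    condensed = scipy.spatial.distance.squareform(dist, checks=False)
    Z = scipy.cluster.hierarchy.linkage(condensed, method=method)
    return ClusterTree(linkage=Z, labels=labels)


# ---------------------------------------------------------------------------
# escaper calling


@dataclass
class EscaperReport:
    """Per-gene XCI-status calls with the calibration used to make them."""

    calls: pd.DataFrame  # gene_id, consensus_score, call, known_class
    escaper_ceiling: float
    inactivated_floor: float
    tree: ClusterTree | None = None
    warnings: list[str] = field(default_factory=list)


def call_escapers(
    table: ExpressionTable,
    *,
    inactivated_floor: float = 0.5,
    calibration_margin: float = 0.05,
    fallback_ceiling: float = 0.25,
    attach_tree: bool = True,
) -> EscaperReport:
    """Classify each X-linked gene as inactivated / partial / escaper.

    The consensus score (median |r| with the known-inactivated seed set)
    is high for genes sharing the inactivation sampling factor and near
    zero for genes whose variation is measurement noise only.  Autosomal
    controls calibrate the null: the escaper ceiling is their maximum
    score plus ``calibration_margin``.  A gene scoring at or below the
    ceiling is called ``escaper``; at or above ``inactivated_floor``,
    ``inactivated``; in between, ``partial``.  Without autosomal controls
    a fixed fallback ceiling is used, with a warning.
    """
    profile = correlation_profile(table)
    classes = table.gene_classes()
    seed = [g for g in profile.genes if classes.get(g) == "inactivated"]
    if len(seed) < 3:
        raise DesignError(f"need >= 3 known inactivated seed genes; got {len(seed)}")

    report_warnings: list[str] = []
    autosomal = [g for g in profile.genes if classes.get(g) == "autosomal"]
    if len(autosomal) >= 2:
        ceiling = float(profile.consensus[autosomal].max()) + calibration_margin
    else:
        report_warnings.append(
            "no (or a single) autosomal control present; using fixed fallback thresholds"
        )
        warnings.warn(report_warnings[-1], stacklevel=2)
        ceiling = fallback_ceiling
    if ceiling >= inactivated_floor:
        report_warnings.append(
            f"autosomal calibration ceiling {ceiling:.3f} reaches the inactivated floor "
            f"{inactivated_floor}; controls correlate with the inactivated set"
        )
        ceiling = inactivated_floor - 1e-9

    x_genes = [g for g in profile.genes if classes.get(g) != "autosomal"]
    rows = []
    for g in sorted(x_genes):
        score = profile.consensus[g]
        if score <= ceiling:
            call = "escaper"
        elif score >= inactivated_floor:
            call = "inactivated"
        else:
            call = "partial"
        rows.append(
            {
                "gene_id": g,
                "consensus_score": score,
                "call": call,
                "known_class": classes.get(g, "unknown"),
            }
        )
    calls = pd.DataFrame(rows)
    tree = cluster_genes(profile) if attach_tree else None
    return EscaperReport(
        calls=calls,
        escaper_ceiling=ceiling,
        inactivated_floor=inactivated_floor,
        tree=tree,
        warnings=report_warnings,
    )


# ---------------------------------------------------------------------------
# direction and shift statistics


def sign_test_direction(differences: Sequence[float]) -> dict:
    """Exact two-sided binomial sign test on per-gene bias directions.

    ``differences`` are per-gene reciprocal-cross differences oriented so
    positive means maternal-biased.  Zero differences are dropped with a
    warning (standard tie treatment).  Returns the two-sided
    p = 2 P(X >= max(k, n-k)) under Binomial(n, 1/2), capped at 1.
    """
    d = np.asarray(list(differences), dtype=float)
    zeros = d == 0
    if zeros.any():
        warnings.warn(f"dropping {int(zeros.sum())} zero difference(s)", stacklevel=2)
        d = d[~zeros]
    n = len(d)
    if n == 0:
        raise DesignError("sign test needs at least one non-zero difference")
    k = int((d > 0).sum())
    m = max(k, n - k)
    p = min(1.0, 2.0 * float(scipy.stats.binom.sf(m - 1, n, 0.5)))
    return {"n": n, "n_positive": k, "p": p}


@dataclass
class ReciprocalBias:
    """Per-gene reciprocal-cross bias summary.

    ``frame`` has one row per gene with the mean reference fraction in
    each cross (p1 for the cross where the reference strain is the
    mother, p2 for the reciprocal), the difference d = p1 - p2, its SE
    over individuals, and a Welch t summary.  Positive d means
    maternal-biased.
    """

    frame: pd.DataFrame
    cross_maternal_ref: str
    cross_paternal_ref: str


def reciprocal_difference(
    table: ExpressionTable, genes: Sequence[str] | None = None
) -> ReciprocalBias:
    """Per-gene difference of mean reference fractions between crosses."""
    fem = table.females()
    if genes is not None:
        fem = fem[fem["gene_id"].isin(set(genes))]
    crosses = sorted(fem["cross_id"].unique())
    if len(crosses) != 2:
        raise DesignError(f"reciprocal difference needs exactly 2 crosses; got {crosses}")
    pair = fem["strain_pair_id"].iloc[0]
    c1 = next(c for c in crosses if maternal_is_reference(c, pair))
    c2 = next(c for c in crosses if c != c1)

    per_ind = fem.groupby(["gene_id", "cross_id", "individual_id"])["ref_fraction"].mean()
    rows = []
    dropped = []
    for gene, sub in per_ind.groupby("gene_id"):
        sub = sub.droplevel("gene_id")
        if not {c1, c2} <= set(sub.index.get_level_values("cross_id")):
            dropped.append(gene)
            continue
        a = sub.loc[c1].to_numpy()
        b = sub.loc[c2].to_numpy()
        se = float(np.sqrt(np.var(a, ddof=1) / len(a) + np.var(b, ddof=1) / len(b)))
        t, p = scipy.stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "gene_id": gene,
                "p1": float(a.mean()),
                "p2": float(b.mean()),
                "difference": float(a.mean() - b.mean()),
                "se": se,
                "t": float(t),
                "p": float(p),
                "n1": len(a),
                "n2": len(b),
            }
        )
    if dropped:
        warnings.warn(
            f"gene(s) present in only one cross excluded: {sorted(dropped)}", stacklevel=2
        )
    return ReciprocalBias(
        frame=pd.DataFrame(rows), cross_maternal_ref=c1, cross_paternal_ref=c2
    )


def ks_shift_test(
    bias: ReciprocalBias,
    annotations: pd.DataFrame,
    *,
    min_genes: int = 2,
    method: str = "auto",
    pool_autosomes: bool = False,
) -> pd.DataFrame:
    """Pairwise two-sample KS tests of per-gene bias between chromosomes.

    Compares the distributions of reciprocal differences d_g between every
    pair of chromosomes with at least ``min_genes`` genes; chromosome
    groups below that are skipped with a warning.  ``method`` is passed to
    :func:`scipy.stats.ks_2samp` ("exact" recommended for small groups).
    With ``pool_autosomes`` all non-X chromosomes form one group, useful
    when only a handful of autosomal controls are available.
    """
    chrom = annotations.set_index("gene_id")["chromosome"]
    frame = bias.frame.copy()
    frame["chromosome"] = frame["gene_id"].map(chrom)
    if pool_autosomes:
        frame.loc[frame["chromosome"] != "X", "chromosome"] = "autosome"
    groups = {
        c: g["difference"].to_numpy() for c, g in frame.groupby("chromosome")
    }
    small = sorted(c for c, v in groups.items() if len(v) < min_genes)
    if small:
        warnings.warn(f"skipping chromosome group(s) with < {min_genes} genes: {small}",
                      stacklevel=2)
        groups = {c: v for c, v in groups.items() if len(v) >= min_genes}
    if len(groups) < 2:
        raise DesignError("KS shift test needs >= 2 chromosome groups")
    rows = []
    names = sorted(groups)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            res = scipy.stats.ks_2samp(groups[a], groups[b], method=method)
            rows.append(
                {
                    "chrom_a": a,
                    "chrom_b": b,
                    "D": float(res.statistic),
                    "p": float(res.pvalue),
                    "n_a": len(groups[a]),
                    "n_b": len(groups[b]),
                }
            )
    return pd.DataFrame(rows)
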