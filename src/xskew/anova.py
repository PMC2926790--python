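"""Three-factor nested ANOVA for reciprocal-cross allelic fractions.

The model is

    y_ijk = mu + alpha_i + beta_j + gamma_k(j) + eps

with *gene* (alpha, fixed, the per-gene cis-regulatory effect), *mother*
(beta, fixed, the parent-of-origin effect distinguishing the two
reciprocal crosses) and *individual* (gamma, random, the cell-sampling
effect, nested within mother).  Technical replicates enter as
residual-level observations.

Sums of squares are computed by explicit least-squares projection on an
effect-coded design matrix (sum-to-zero contrasts; individuals are
effect-coded *within* their cross so the mother contrast stays estimable),
which keeps the fit correct on unbalanced data.  Both sequential (Type I)
and Type III decompositions are available; they coincide on balanced
designs.

F tests use the error strata appropriate to the mixed model: the mother
effect is tested against the individual-within-mother mean square, while
gene and individual effects are tested against the residual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .data_model import ExpressionTable, maternal_is_reference
from .errors import DesignError, FormatError

#: Error stratum used as the F-test denominator for each source.
F_DENOMINATORS = {
    "gene": "residual",
    "mother": "individual(mother)",
    "strain_pair": "individual(mother)",
    "individual(mother)": "residual",
}

DEFAULT_GENE_CLASSES = ("inactivated",)


@dataclass
class AnovaModelSpec:
    """Options controlling a nested-ANOVA fit.

    ``response`` selects the modelled fraction: ``"ref_fraction"`` (the
    reference-strain allele share, the conventional choice) or
    ``"maternal_fraction"`` (the derived maternal view).  ``gene_classes``
    picks which annotated XCI classes enter the response set; escapers,
    partial escapers, Xist-like and autosomal genes are excluded by
    default because they do not share the inactivation sampling factor.
    """

    response: str = "ref_fraction"
    ss_type: str = "sequential"  # or "type_iii"
    gene_classes: Sequence[str] = DEFAULT_GENE_CLASSES

    def __post_init__(self) -> None:
        if self.response not in ("ref_fraction", "maternal_fraction"):
            raise FormatError(f"unknown response {self.response!r}")
        if self.ss_type not in ("sequential", "type_iii"):
            raise FormatError(f"ss_type must be 'sequential' or 'type_iii'")


@dataclass
class AnovaResult:
    """Fitted nested ANOVA.

    ``table`` has one row per source (gene, mother, individual(mother),
    residual, plus strain_pair for pooled fits) with columns
    ``sum_sq, df, mean_sq, F, p, error_stratum``.  ``data`` retains the
    observation-level frame used for the fit (columns ``gene, mother,
    individual, y``) so downstream summaries (LS means, variance
    components) stay consistent with the fit.
    """

    table: pd.DataFrame
    data: pd.DataFrame
    spec: AnovaModelSpec
    meta: dict = field(default_factory=dict)

    @property
    def balanced(self) -> bool:
        return bool(self.meta.get("balanced", False))

    def __repr__(self) -> str:
        return f"AnovaResult(n={self.meta.get('n_obs')}, sources={list(self.table.index)})"


# ---------------------------------------------------------------------------
# design-matrix building blocks


def _effect_code(labels: np.ndarray, levels: Sequence[str]) -> np.ndarray:
    """Sum-to-zero coding: one column per non-last level."""
    levels = list(levels)
    codes = pd.Categorical(labels, categories=levels).codes
    n, L = len(labels), len(levels)
    X = np.zeros((n, L - 1))
    for j in range(L - 1):
        X[codes == j, j] = 1.0
    X[codes == L - 1, :] = -1.0
    return X

def _nested_effect_code(
    inner: np.ndarray, outer: np.ndarray, outer_levels: Sequence[str]
) -> np.ndarray:
    """Effect-code ``inner`` separately within each level of ``outer``.

    The resulting columns are orthogonal to the outer factor's indicator
    space, so outer contrasts remain estimable alongside them.
    """
    blocks = []
    n = len(inner)
    for lev in outer_levels:
        mask = outer == lev
        inner_levels = sorted(pd.unique(inner[mask]))
        if len(inner_levels) < 2:
            raise DesignError(
                f"cross {lev!r} has a single individual; the mother effect is untestable"
            )
        codes = pd.Categorical(inner[mask], categories=inner_levels).codes
        B = np.zeros((n, len(inner_levels) - 1))
        rows = np.flatnonzero(mask)
        for j in range(len(inner_levels) - 1):
            B[rows[codes == j], j] = 1.0
        B[rows[codes == len(inner_levels) - 1], :] = -1.0
        blocks.append(B)
    return np.hstack(blocks)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _compose_table(
    ss: Mapping[str, float], df: Mapping[str, int], order: Sequence[str]
) -> pd.DataFrame:
    """Assemble MS, F and p from sums of squares with the nested wiring."""
    rows = {}
    for src in order:
        d = df[src]
        ms = ss[src] / d if d > 0 else np.nan
        rows[src] = {"sum_sq": ss[src], "df": d, "mean_sq": ms}
    table = pd.DataFrame.from_dict(rows, orient="index")
    f_table = f_tests_from_mean_squares(
        table["mean_sq"].to_dict(), table["df"].to_dict()
    )
    table["F"] = f_table["F"]
    table["p"] = f_table["p"]
    table["error_stratum"] = [F_DENOMINATORS.get(s, "") for s in table.index]
    return table


def f_tests_from_mean_squares(
    mean_squares: Mapping[str, float], df: Mapping[str, int]
) -> pd.DataFrame:
    """F ratios and p-values from mean squares, using the nested strata.

    Each tested source is divided by the mean square of its error stratum
    (mother by individual(mother); gene and individual(mother) by the
    residual) and referred to an F distribution with the matching degrees
    of freedom.  Exposed separately so the ratio -> F wiring can be
    exercised on externally supplied mean squares.
    """
    rows = {}
    for src, ms in mean_squares.items():
        denom_name = F_DENOMINATORS.get(src)
        if denom_name is None or denom_name not in mean_squares:
            rows[src] = {"F": np.nan, "p": np.nan}
            continue
        denom = mean_squares[denom_name]
        F = ms / denom if denom > 0 else np.nan
        p = (
            float(scipy.stats.f.sf(F, df[src], df[denom_name]))
            if np.isfinite(F)
            else np.nan
        )
        rows[src] = {"F": F, "p": p}
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# fitting


def _prepare_frame(
    table: ExpressionTable, spec: AnovaModelSpec, genes: Sequence[str] | None
) -> pd.DataFrame:
    if genes is None:
        genes = table.genes_of_class(spec.gene_classes)
    if len(genes) < 2:
        raise DesignError(
            f"nested ANOVA needs >= 2 response genes; got {len(genes)} "
            f"of class(es) {tuple(spec.gene_classes)}"
        )
    data = table.data
    mask = (data["sex"] == "female") & data["gene_id"].isin(set(genes))
    sub = data[mask].copy()
    if sub["cross_id"].nunique() < 2:
        raise DesignError("nested ANOVA needs both reciprocal crosses")
    if spec.response == "maternal_fraction":
        ref_mat = sub.apply(
            lambda r: maternal_is_reference(r["cross_id"], r["strain_pair_id"]), axis=1
        )
        y = sub["ref_fraction"].where(ref_mat, 1.0 - sub["ref_fraction"])
    else:
        y = sub["ref_fraction"]
    # strict nesting: individual labels are qualified by their cross
    return pd.DataFrame(
        {
            "gene": sub["gene_id"].to_numpy(),
            "mother": sub["cross_id"].to_numpy(),
            "individual": (sub["cross_id"] + ":" + sub["individual_id"]).to_numpy(),
            "y": y.to_numpy(float),
        }
    )


def _fit_frame(
    frame: pd.DataFrame,
    ss_type: str,
    factor_order: Sequence[str],
    nested_outer: str = "mother",
) -> tuple[pd.DataFrame, dict]:
    """Least-squares ANOVA of y on effect-coded factors.

    ``factor_order`` lists the non-residual sources in fitting order; the
    factor named ``individual(mother)`` is coded nested within
    ``nested_outer``.
    """
    y = frame["y"].to_numpy()
    n = len(y)
    blocks: dict[str, np.ndarray] = {}
    dfs: dict[str, int] = {}
    for src in factor_order:
        if src == "individual(mother)":
            X = _nested_effect_code(
                frame["individual"].to_numpy(),
                frame[nested_outer].to_numpy(),
                sorted(frame[nested_outer].unique()),
            )
        else:
            col = {"gene": "gene", "mother": "mother", "strain_pair": "strain_pair"}[src]
            levels = sorted(frame[col].unique())
            if len(levels) < 2:
                raise DesignError(f"factor {src!r} has a single level")
            X = _effect_code(frame[col].to_numpy(), levels)
        blocks[src] = X
        dfs[src] = X.shape[1]

    intercept = np.ones((n, 1))
    X_full = np.hstack([intercept] + [blocks[s] for s in factor_order])
    rss_full = _rss(X_full, y)
    tss = float(((y - y.mean()) ** 2).sum())

    ss: dict[str, float] = {}
    if ss_type == "sequential":
        prev = tss
        X_cum = intercept
        for src in factor_order:
            X_cum = np.hstack([X_cum, blocks[src]])
            cur = _rss(X_cum, y)
            ss[src] = prev - cur
            prev = cur
    else:  # type III: drop each block from the full model
        for src in factor_order:
            X_wo = np.hstack(
                [intercept] + [blocks[s] for s in factor_order if s != src]
            )
            ss[src] = _rss(X_wo, y) - rss_full

    ss["residual"] = rss_full
    dfs["residual"] = n - 1 - sum(dfs[s] for s in factor_order)
    if dfs["residual"] <= 0:
        raise DesignError("no residual degrees of freedom (need replicate measurements)")

    order = list(factor_order) + ["residual"]
    table = _compose_table(ss, dfs, order)

    counts = frame.groupby(["gene", "individual"]).size()
    meta = {
        "n_obs": n,
        "total_ss": tss,
        "balanced": bool(counts.nunique() == 1)
        and frame.groupby("mother")["individual"].nunique().nunique() == 1,
        "n_genes": int(frame["gene"].nunique()),
        "n_individuals": int(frame["individual"].nunique()),
        "n_crosses": int(frame["mother"].nunique()),
        "obs_per_individual": n / frame["individual"].nunique(),
        "obs_per_gene": n / frame["gene"].nunique(),
        "obs_per_cross": n / frame["mother"].nunique(),
    }
    return table, meta


def fit_nested_anova(
    table: ExpressionTable,
    spec: AnovaModelSpec | None = None,
    genes: Sequence[str] | None = None,
) -> AnovaResult:
    """Fit the nested three-factor model to the X-inactivated gene set.

    Only female individuals enter the fit.  ``genes`` overrides the
    class-based response-gene selection.
    """
    spec = spec or AnovaModelSpec()
    frame = _prepare_frame(table, spec, genes)
    tab, meta = _fit_frame(frame, spec.ss_type, ["gene", "mother", "individual(mother)"])
    meta["individuals_per_cross"] = (
        frame.groupby("mother")["individual"].nunique().to_dict()
    )
    return AnovaResult(table=tab, data=frame, spec=spec, meta=meta)


def rank_transform_anova(
    table: ExpressionTable,
    spec: AnovaModelSpec | None = None,
    genes: Sequence[str] | None = None,
) -> AnovaResult:
    """Nonparametric variant: global midrank transform, then the same fit."""
    spec = spec or AnovaModelSpec()
    frame = _prepare_frame(table, spec, genes)
    frame["y"] = scipy.stats.rankdata(frame["y"].to_numpy())
    tab, meta = _fit_frame(frame, spec.ss_type, ["gene", "mother", "individual(mother)"])
    meta["response_transform"] = "midrank"
    return AnovaResult(table=tab, data=frame, spec=spec, meta=meta)


def pooled_fit(
    tables: Sequence[ExpressionTable],
    spec: AnovaModelSpec | None = None,
) -> AnovaResult:
    """Joint fit across strain pairs with a strain_pair fixed factor.

    The mother factor is recoded as the *orientation* of each cross
    (reference strain maternal vs paternal), which is comparable across
    strain pairs.  Genes are restricted to the intersection of the pairs'
    rosters (with a warning if that drops any).  Type III sums of squares
    are the default because pooled designs are typically unbalanced.
    """
    if len(tables) < 2:
        raise DesignError("pooled fit needs at least two strain-pair datasets")
    spec = spec or AnovaModelSpec(ss_type="type_iii")

    frames = []
    gene_sets = []
    for t in tables:
        genes = t.genes_of_class(spec.gene_classes)
        gene_sets.append(set(genes))
    common = sorted(set.intersection(*gene_sets))
    if len(common) < 2:
        raise DesignError("fewer than 2 response genes shared across strain pairs")
    if any(s - set(common) for s in gene_sets):
        warnings.warn(
            f"pooled fit restricted to the {len(common)} genes shared by all strain pairs",
            stacklevel=2,
        )
    for t in tables:
        frame = _prepare_frame(t, spec, common)
        sub = t.data[
            (t.data["sex"] == "female") & t.data["gene_id"].isin(set(common))
        ]
        pair = sub["strain_pair_id"].to_numpy()
        orient = np.where(
            [maternal_is_reference(c, p) for c, p in zip(sub["cross_id"], pair)],
            "reference_maternal",
            "reference_paternal",
        )
        frame["strain_pair"] = pair
        frame["mother"] = orient
        frame["individual"] = pair + ":" + frame["individual"]
        # nest individuals within (pair, orientation) cells
        frame["cell"] = frame["strain_pair"] + "|" + frame["mother"]
        frames.append(frame)
    frame = pd.concat(frames, ignore_index=True)

    tab, meta = _fit_frame(
        frame,
        spec.ss_type,
        ["gene", "strain_pair", "mother", "individual(mother)"],
        nested_outer="cell",
    )
    meta["strain_pairs"] = sorted(frame["strain_pair"].unique())
    return AnovaResult(table=tab, data=frame, spec=spec, meta=meta)


# ---------------------------------------------------------------------------
# summaries


def ls_means(result: AnovaResult) -> pd.DataFrame:
    """Per-cross least-squares means of the response with standard errors.

    The LS mean of a cross averages the gene-by-cross cell means with
    equal gene weights (individuals weighted equally within cells), the
    standard convention for fixed-effect marginal means on unbalanced
    data.  Standard errors come from the individual(mother) stratum —
    the correct yardstick for between-cross comparisons under the mixed
    model: SE_j = sqrt(MS_ind / (n_j * c_j)) with n_j individuals in
    cross j and c_j observations per individual.
    """
    frame = result.data
    ms_ind = result.table.loc["individual(mother)", "mean_sq"]
    cell = (
        frame.groupby(["gene", "mother", "individual"])["y"]
        .mean()
        .groupby(["gene", "mother"])
        .mean()
    )
    means = cell.groupby("mother").mean()
    out = []
    for cross, mean in means.items():
        sub = frame[frame["mother"] == cross]
        n_j = sub["individual"].nunique()
        c_j = len(sub) / n_j
        out.append(
            {
                "mother": cross,
                "ls_mean": mean,
                "se": float(np.sqrt(ms_ind / (n_j * c_j))),
                "n_individuals": n_j,
            }
        )
    return pd.DataFrame(out).set_index("mother")


def variance_components(result: AnovaResult) -> pd.DataFrame:
    """Effect-size decomposition of the fitted ANOVA.

    Two labelled methods:

    * ``ems`` — expected-mean-square solutions.  The random individual
      component is (MS_ind - MS_res) / c with c the average observations
      per individual; fixed factors get the analogous average squared
      effect size, e.g. (MS_gene - MS_res) / n_gene-level-obs and
      (MS_mother - MS_ind) / n_cross-obs.  Negative solutions clamp to 0
      with a warning.
    * ``ss`` — naive share of the total sum of squares.

    Proportions are each method's components normalised to 1.  A fit with
    zero total variation is flagged degenerate (proportions NaN).
    """
    tab = result.table
    meta = result.meta
    ms = tab["mean_sq"]
    c = meta["obs_per_individual"]

    comps: dict[str, float] = {"residual": float(ms["residual"])}
    clamped = []

    def _solve(name: str, numerator: float, divisor: float) -> None:
        val = numerator / divisor
        if val < 0:
            clamped.append(name)
            val = 0.0
        comps[name] = float(val)

    _solve("individual(mother)", ms["individual(mother)"] - ms["residual"], c)
    _solve("gene", ms["gene"] - ms["residual"], meta["obs_per_gene"])
    _solve("mother", ms["mother"] - ms["individual(mother)"], meta["obs_per_cross"])
    if "strain_pair" in tab.index:
        n_pairs = result.data["strain_pair"].nunique()
        _solve(
            "strain_pair",
            ms["strain_pair"] - ms["individual(mother)"],
            meta["n_obs"] / n_pairs,
        )
    if clamped:
        warnings.warn(
            f"negative EMS variance-component estimate(s) clamped to 0: {clamped}",
            stacklevel=2,
        )

    order = [s for s in tab.index if s != "residual"] + ["residual"]
    out = pd.DataFrame(index=order)
    out["component_ems"] = [comps.get(s, np.nan) for s in order]
    total_ems = np.nansum(out["component_ems"])
    total_ss = tab["sum_sq"].sum()
    # all-identical observations leave only float noise in the strata
    degenerate = bool(total_ss <= 1e-12 or total_ems <= 1e-15)
    out["prop_ems"] = out["component_ems"] / total_ems if not degenerate else np.nan
    out["prop_ss"] = tab["sum_sq"] / total_ss if not degenerate else np.nan
    out.attrs["degenerate"] = degenerate
    out.attrs["clamped"] = clamped
    return out
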