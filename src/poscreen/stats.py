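"""Downstream statistics: imputation, t-tests with permutation FDR, ΔΔCt, overlaps.

The proteomics branch reproduces the Perseus-style workflow applied to the
screen's follow-up data: log2 intensities, missing values replaced by draws
from a down-shifted Normal (width 0.3, downshift 1.8, in units of each
column's observed standard deviation), a two-sample Student's t-test with
permutation-based FDR (250 randomizations, FDR 0.05), and volcano filtering
(fold change <0.5 or >2, p < 0.05, strict).  The qPCR branch implements
ΔΔCt relative quantification with one or two reference genes, plus the
isoform-subtraction trick used when one primer pair spans two transcript
isoforms.  Overlap summaries round percentages half away from zero.
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .omics import CtTable, OmicsMatrix

# ---- imputation ---------------------------------------------------------


def impute_missing(
    m: OmicsMatrix, width: float = 0.3, downshift: float = 1.8, seed: int = 0
) -> OmicsMatrix:
    """Replace missing values column-wise from a down-shifted Normal.

    Per column with observed mean μ and (sample) standard deviation σ, each
    missing cell is drawn from Normal(μ − downshift·σ, (width·σ)²); observed
    cells are untouched.  Deterministic given the seed.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    rng = np.random.default_rng(seed)
    values = m.values.copy()
    for col in values.columns:
        x = values[col]
        observed = x.dropna()
        n_missing = int(x.isna().sum())
        if n_missing == 0:
            continue
        if len(observed) < 2:
            raise ValueError(f"column {col!r} has fewer than 2 observed values")
        mu = observed.mean()
        sigma = observed.std(ddof=1)
        draws = rng.normal(mu - downshift * sigma, width * sigma, size=n_missing)
        values.loc[x.isna(), col] = draws
    return OmicsMatrix(values=values, groups=m.groups, truth=m.truth)


# ---- two-sample tests ---------------------------------------------------


@dataclasses.dataclass
class StatResult:
    """Per-feature two-group test results.

    ``table`` columns: mean_group1, mean_group2, log2_fc (group1 − group2 of
    log2 intensities), t, p, bh_q, constant_flag, significant.
    """

    table: pd.DataFrame
    group_labels: tuple[str, str]
    variant: str


def _group_arrays(m: OmicsMatrix) -> tuple[np.ndarray, np.ndarray, tuple[str, str]]:
    g1, g2 = m.group_labels
    a = m.values.loc[:, m.groups[m.values.columns] == g1].to_numpy()
    b = m.values.loc[:, m.groups[m.values.columns] == g2].to_numpy()
    return a, b, (g1, g2)


def two_sample_test(
    m: OmicsMatrix, variant: str = "welch", alpha: float = 0.05
) -> StatResult:
    """Unpaired two-sided t-test per feature with Benjamini–Hochberg q-values.

    ``variant``: "welch" (Satterthwaite df) or "student" (pooled variance).
    Features constant in both groups get t = 0, p = 1 and a flag.
    """
    if variant not in ("welch", "student"):
        raise ValueError(f"unknown test variant {variant!r}")
    a, b, labels = _group_arrays(m)
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("matrix contains missing values; impute first")
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples")

    res = sps.ttest_ind(a, b, axis=1, equal_var=(variant == "student"))
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    constant = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    t = np.where(np.isnan(t), 0.0, t)
    p = np.where(np.isnan(p), 1.0, p)

    q = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "mean_group1": a.mean(axis=1),
            "mean_group2": b.mean(axis=1),
            "log2_fc": a.mean(axis=1) - b.mean(axis=1),
            "t": t,
            "p": p,
            "bh_q": q,
            "constant_flag": constant,
            "significant": q <= alpha,
        },
        index=m.values.index,
    )
    return StatResult(table=table, group_labels=labels, variant=variant)


# ---- permutation FDR ----------------------------------------------------


def _tstats(x: np.ndarray, mask1: np.ndarray, s0: float) -> np.ndarray:
    """Student t per row for one group labelling; zero-variance rows give t=0."""
    n1, n2 = int(mask1.sum()), int((~mask1).sum())
    a, b = x[:, mask1], x[:, ~mask1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    sp = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    se = sp * np.sqrt(1.0 / n1 + 1.0 / n2) + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / se
    return np.where(np.isfinite(t), t, 0.0)


def permutation_fdr(
    m: OmicsMatrix,
    n_randomizations: int = 250,
    fdr: float = 0.05,
    seed: int = 0,
    s0: float = 0.0,
    method: str = "auto",
) -> pd.DataFrame:
    """Permutation-based FDR for the per-feature Student t statistic.

    The null |t| distribution is built by permuting group labels (pooled
    over features).  Per feature, q = (mean null count of |t| >= observed)
    / (observed count of |t| >= observed), clipped to [0, 1] and made
    monotone in |t|; a feature is significant iff q <= ``fdr``.  Label
    splits are enumerated exhaustively when there are at most
    ``n_randomizations`` of them, otherwise sampled with replacement;
    ``method`` forces one path ("exhaustive" / "sample" / "auto").
    Deterministic given the seed.
    """
    if method not in ("auto", "exhaustive", "sample"):
        raise ValueError(f"unknown method {method!r}")
    x = m.values.to_numpy()
    if np.isnan(x).any():
        raise ValueError("matrix contains missing values; impute first")
    g1, _ = m.group_labels
    mask1 = (m.groups[m.values.columns] == g1).to_numpy()
    n, n1 = mask1.size, int(mask1.sum())
    n_distinct = math.comb(n, n1)
    if n_distinct <= 1:
        raise ValueError("only a single label permutation possible")

    obs = np.abs(_tstats(x, mask1, s0))

    if method == "exhaustive" or (method == "auto" and n_distinct <= n_randomizations):
        masks = []
        for combo in itertools.combinations(range(n), n1):
            mk = np.zeros(n, dtype=bool)
            mk[list(combo)] = True
            masks.append(mk)
    else:
        rng = np.random.default_rng(seed)
        masks = []
        for _ in range(n_randomizations):
            perm = rng.permutation(n)
            mk = np.zeros(n, dtype=bool)
            mk[perm[:n1]] = True
            masks.append(mk)

    null_abs = np.concatenate([np.abs(_tstats(x, mk, s0)) for mk in masks])
    null_sorted = np.sort(null_abs)
    obs_sorted = np.sort(obs)
    n_perms = len(masks)

    # mean over permutations of the null exceedance count at each observed |t|
    null_ge = len(null_sorted) - np.searchsorted(null_sorted, obs, side="left")
    mean_null = null_ge / n_perms
    obs_ge = len(obs_sorted) - np.searchsorted(obs_sorted, obs, side="left")
    q = np.clip(mean_null / obs_ge, 0.0, 1.0)

    # q-value: min estimated FDR over all cutoffs lenient enough to include the
    # feature, i.e. running min along ascending |t|; monotone in |t| by construction
    order = np.argsort(obs)  # least significant first
    q_sorted = np.minimum.accumulate(q[order])
    q_mono = np.empty_like(q)
    q_mono[order] = q_sorted

    return pd.DataFrame(
        {"abs_t": obs, "perm_q": q_mono, "significant": q_mono <= fdr},
        index=m.values.index,
    )


# ---- volcano filtering --------------------------------------------------


def volcano_filter(
    stats: StatResult | pd.DataFrame,
    fc_low: float = 0.5,
    fc_high: float = 2.0,
    alpha: float = 0.05,
) -> pd.Index:
    """Features with (linear fold change < fc_low OR > fc_high) AND p < alpha.

    All inequalities strict; fold change is 2**log2_fc.
    """
    table = stats.table if isinstance(stats, StatResult) else stats
    fc = 2.0 ** table["log2_fc"]
    selected = ((fc < fc_low) | (fc > fc_high)) & (table["p"] < alpha)
    return table.index[selected]


# ---- ΔΔCt qPCR quantification -------------------------------------------


def ddct_fold_change(
    ct: CtTable,
    references: tuple[str, ...] | None = None,
    calibrator: str | None = None,
) -> pd.DataFrame:
    """Relative expression by the ΔΔCt method.

    ΔCt(sample, target) = Ct(target) − reference Ct, where the reference Ct
    is the single reference gene's Ct or the arithmetic mean of the two
    reference Cts (equivalent to the geometric mean of their expression).
    ΔΔCt = ΔCt − mean ΔCt over the calibrator condition's samples; fold =
    2^(−ΔΔCt); per-sample folds are averaged arithmetically within each
    condition.  Returns a (condition, gene) → fold_change table.
    """
    references = tuple(references) if references is not None else ct.reference_genes
    calibrator = calibrator if calibrator is not None else ct.calibrator
    wide = ct.data.pivot_table(
        index=["sample_id", "condition"], columns="gene", values="ct"
    )
    for ref in references:
        if ref not in wide.columns or wide[ref].isna().any():
            raise ValueError(f"missing Ct for reference gene {ref!r}")
    conditions = wide.index.get_level_values("condition")
    if calibrator not in set(conditions):
        raise ValueError(f"calibrator condition {calibrator!r} absent")

    ref_ct = wide[list(references)].mean(axis=1)
    targets = [g for g in wide.columns if g not in references]
    dct = wide[targets].sub(ref_ct, axis=0)
    calib_mean = dct[conditions == calibrator].mean(axis=0)
    ddct = dct.sub(calib_mean, axis=1)
    fold = 2.0 ** (-ddct)
    out = fold.groupby(level="condition").mean()
    out = out.rename_axis(index="condition", columns="gene")
    return out


@dataclasses.dataclass(frozen=True)
class IsoformExpression:
    """Result of subtracting one isoform's expression from a combined measurement."""

    value: float
    floored: bool


def isoform_subtract(expr_combined: float, expr_single: float) -> IsoformExpression:
    """Expression of the isoform not covered by the single-isoform primer.

    The combined primer pair measures two isoforms together; subtracting the
    single isoform's expression leaves the other.  Negative differences
    (possible with noisy estimates) are floored at 0 and flagged.
    """
    if expr_combined < 0 or expr_single < 0:
        raise ValueError("expression values must be non-negative")
    diff = expr_combined - expr_single
    if diff < 0:
        return IsoformExpression(value=0.0, floored=True)
    return IsoformExpression(value=float(diff), floored=False)


# ---- overlap summaries --------------------------------------------------


@dataclasses.dataclass(frozen=True)
class OverlapSummary:
    overlap: int
    total: int
    percentage: int

    def __post_init__(self) -> None:
        if not 0 <= self.overlap <= self.total:
            raise ValueError("need 0 <= overlap <= total")


def overlap_summary(overlap: int, total: int) -> OverlapSummary:
    """Percentage of events shared between two result sets.

    percentage = round(100·overlap/total), half away from zero.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= overlap <= total:
        raise ValueError("need 0 <= overlap <= total")
    pct = int(math.floor(100.0 * overlap / total + 0.5))
    return OverlapSummary(overlap=overlap, total=total, percentage=pct)
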