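"""Screen analysis: normalization, fold changes, calibrated enrichment, hit filtering.

The analysis follows the positive-selection screen's published scheme:

1. every sample's guide counts are normalized to the sample total and to the
   complexity sample (the library-abundance snapshot taken one day after
   transduction), with a pseudocount so every value is positive and finite;
2. normalized counts are averaged over technical replicates within each
   experiment (cell line x biological replicate);
3. per-guide fold changes are poly(I:C)-treated over PBS-treated means;
4. the enrichment threshold is *calibrated by count*: the top ``target_count``
   guides by fold change (default 2,000, deterministic tie-break by guide id)
   form the enriched set, and the threshold is the smallest fold change in it;
5. gene-level candidates are called from the per-experiment enriched sets by
   one of three published filter phrasings (see :func:`call_candidates`).

Because a large genotype-independent fraction of cells survives stimulation,
the enriched sets carry a heavy random background; the expected number of
candidates under a label-free null is estimable by Monte Carlo
(:func:`expected_null_candidates`).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .library import GuideLibrary
from .screen import ScreenCountSet

FILTER_VARIANTS = ("methods", "fig1c", "results_text")


@dataclasses.dataclass(frozen=True)
class FilterParams:
    """Gene-level candidate filter parameters.

    ``variant`` selects among the three published phrasings of the filter;
    ``min_occurrences_combined`` doubles as "five of six guides in one
    experiment" for the distinct-guide variants.
    """

    target_count: int = 2000
    min_occurrences_combined: int = 5
    min_datasets: int = 3
    variant: str = "methods"

    def __post_init__(self) -> None:
        for field in ("target_count", "min_occurrences_combined", "min_datasets"):
            if getattr(self, field) <= 0:
                raise ValueError(f"{field} must be a positive integer")
        if self.variant not in FILTER_VARIANTS:
            raise ValueError(f"unknown filter variant {self.variant!r}")


@dataclasses.dataclass
class NormalizedTable:
    """Normalized read counts (guides x samples) plus the metadata needed downstream."""

    values: pd.DataFrame
    meta: pd.DataFrame
    pseudocount: float
    complexity_ref: dict[str, str]  # sample_id -> complexity sample_id used


@dataclasses.dataclass
class HitResult:
    """Calibrated enrichment plus the final candidate lists."""

    thresholds: dict[str, float]
    enriched: dict[str, pd.Index]
    candidate_genes: list[str]
    candidate_mirnas: list[str]
    params: FilterParams
    occurrences: pd.DataFrame | None = None
    control_report: dict | None = None


def _resolve_complexity(meta: pd.DataFrame) -> dict[str, str]:
    """Map each sample to its complexity reference sample.

    Preference order: complexity sample of the same cell line and biological
    replicate, else the cell line's single complexity sample.
    """
    comp = meta[meta["condition"] == "complexity"]
    if comp.empty:
        raise ValueError("no complexity sample in metadata")
    refs: dict[str, str] = {}
    for row in meta.itertuples():
        sub = comp[comp["cell_line"] == row.cell_line]
        if sub.empty:
            raise ValueError(f"no complexity sample for cell line {row.cell_line!r}")
        same_rep = sub[sub["bio_rep"] == row.bio_rep]
        chosen = same_rep if not same_rep.empty else sub
        refs[row.sample_id] = chosen["sample_id"].iloc[0]
    return refs


def normalize_counts(
    countset: ScreenCountSet,
    complexity_sample_id: str | None = None,
    pseudocount: float = 0.5,
) -> NormalizedTable:
    """Normalize counts to sample totals and to the complexity sample.

    normalized(g, s) = proportion(g, s) / proportion(g, complexity), with a
    pseudocount added to every raw count before proportions so values stay
    positive and finite.  If ``complexity_sample_id`` is given it is used for
    every sample; otherwise each sample is referenced to its own cell line's
    (and where available its own biological replicate's) complexity sample.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    counts = countset.counts
    totals = counts.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero)}")

    if complexity_sample_id is not None:
        if complexity_sample_id not in counts.columns:
            raise ValueError(f"complexity sample {complexity_sample_id!r} not found")
        refs = {s: complexity_sample_id for s in counts.columns}
    else:
        refs = _resolve_complexity(countset.meta)

    padded = counts + pseudocount
    props = padded / padded.sum(axis=0)
    ref_props = pd.DataFrame({s: props[refs[s]] for s in counts.columns})
    values = props / ref_props
    return NormalizedTable(
        values=values, meta=countset.meta, pseudocount=pseudocount, complexity_ref=refs
    )


def average_replicates(norm: NormalizedTable) -> pd.DataFrame:
    """Mean normalized counts over technical replicates.

    Returns guides x (experiment, condition) with experiments enumerated as
    cell line x biological replicate (e.g. ``CL1_b2``).
    """
    meta = norm.meta[norm.meta["condition"].isin(["PBS", "polyIC"])]
    if meta.empty:
        raise ValueError("no PBS/polyIC samples to average")
    cols = {}
    for (cell_line, bio_rep, condition), grp in meta.groupby(
        ["cell_line", "bio_rep", "condition"]
    ):
        exp = f"{cell_line}_b{bio_rep}"
        cols[(exp, condition)] = norm.values[grp["sample_id"]].mean(axis=1)
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["experiment", "condition"])
    return out.sort_index(axis=1)


def fold_changes(means: pd.DataFrame) -> pd.DataFrame:
    """Per-guide poly(I:C)/PBS fold change, one column per experiment."""
    experiments = means.columns.get_level_values("experiment").unique()
    out = {}
    for exp in experiments:
        sub = means[exp]
        for needed in ("polyIC", "PBS"):
            if needed not in sub.columns:
                raise ValueError(f"experiment {exp!r} lacks condition {needed!r}")
        out[exp] = sub["polyIC"] / sub["PBS"]
    return pd.DataFrame(out)


def calibrate_threshold(
    fc: pd.Series, target_count: int
) -> tuple[float, pd.Index]:
    """Top-``target_count`` guides by fold change, ties broken by ascending guide id.

    Returns ``(threshold, enriched_guide_ids)`` where the threshold is the
    minimum fold change inside the enriched set; the set size is exactly
    ``target_count``.
    """
    if target_count <= 0 or target_count > len(fc):
        raise ValueError(f"target_count must be in [1, {len(fc)}], got {target_count}")
    df = fc.rename("fc").rename_axis("guide_id").reset_index()
    df = df.sort_values(["fc", "guide_id"], ascending=[False, True], kind="mergesort")
    top = df.head(target_count)
    return float(top["fc"].min()), pd.Index(top["guide_id"])


def enrich_all(fcs: pd.DataFrame, target_count: int) -> tuple[dict[str, float], dict[str, pd.Index]]:
    """Calibrate every experiment's threshold; returns thresholds and enriched sets."""
    thresholds: dict[str, float] = {}
    enriched: dict[str, pd.Index] = {}
    for exp in fcs.columns:
        thr, ids = calibrate_threshold(fcs[exp], target_count)
        thresholds[exp] = thr
        enriched[exp] = ids
    return thresholds, enriched


def _occurrence_table(
    enriched: dict[str, pd.Index], library: GuideLibrary
) -> pd.DataFrame:
    """targets x experiments table of enriched-guide occurrences.

    Within one experiment a guide is enriched or not, so the entry equals
    the number of that target's distinct guides in the experiment's enriched
    set.  Non-targeting controls are excluded.
    """
    lib = library.records
    target_of = dict(zip(lib["guide_id"], lib["target_id"]))
    targeting = lib[lib["target_class"] != "non_targeting"]
    targets = pd.Index(targeting["target_id"].unique(), name="target_id")
    table = pd.DataFrame(0, index=targets, columns=list(enriched), dtype=int)
    for exp, ids in enriched.items():
        hit_targets = pd.Series([target_of[g] for g in ids])
        vc = hit_targets.value_counts()
        vc = vc[vc.index.isin(targets)]
        table.loc[vc.index, exp] = vc.astype(int)
    return table


def call_candidates(
    enriched: dict[str, pd.Index],
    library: GuideLibrary,
    params: FilterParams = FilterParams(),
    thresholds: dict[str, float] | None = None,
) -> HitResult:
    """Apply the gene-level candidate filter to per-experiment enriched sets.

    Variants (selected by ``params.variant``):

    * ``methods`` (default): total guide-occurrences summed over all
      experiments >= ``min_occurrences_combined`` AND >=1 enriched guide in
      >= ``min_datasets`` experiments.  Occurrence-counting (a guide enriched
      in k experiments contributes k) is required for any 4-guide miRNA to
      reach five occurrences at all.
    * ``fig1c``: >=1 enriched guide in >= ``min_datasets`` experiments AND
      >= ``min_occurrences_combined`` distinct guides enriched within at
      least one single experiment.
    * ``results_text``: >= ``min_occurrences_combined`` distinct guides
      enriched in at least one experiment AND >=1 guide in >=2 experiments.
    """
    if params.variant not in FILTER_VARIANTS:
        raise ValueError(f"unknown filter variant {params.variant!r}")
    if params.min_datasets > len(enriched):
        raise ValueError("min_datasets exceeds the number of experiments")
    occ = _occurrence_table(enriched, library)
    combined = occ.sum(axis=1)
    n_datasets_hit = (occ > 0).sum(axis=1)
    best_single = occ.max(axis=1)

    if params.variant == "methods":
        passed = (combined >= params.min_occurrences_combined) & (
            n_datasets_hit >= params.min_datasets
        )
    elif params.variant == "fig1c":
        passed = (n_datasets_hit >= params.min_datasets) & (
            best_single >= params.min_occurrences_combined
        )
    else:  # results_text: "two out of three replicates" reading
        passed = (best_single >= params.min_occurrences_combined) & (n_datasets_hit >= 2)

    class_of = (
        library.records.drop_duplicates("target_id").set_index("target_id")["target_class"]
    )
    candidates = occ.index[passed]
    genes = sorted(t for t in candidates if class_of[t] == "gene")
    mirnas = sorted(t for t in candidates if class_of[t] == "mirna")
    return HitResult(
        thresholds=thresholds or {},
        enriched=enriched,
        candidate_genes=genes,
        candidate_mirnas=mirnas,
        params=params,
        occurrences=occ,
    )


def check_positive_controls(
    enriched: dict[str, pd.Index],
    library: GuideLibrary,
    controls: set[str] | tuple[str, ...],
    cell_line_of: dict[str, str] | None = None,
) -> dict:
    """Report whether each positive control has >=1 enriched guide.

    Per experiment: control represented in that experiment's enriched set.
    Overall pass: every control represented in every cell line (union over
    that cell line's experiments).  An empty control set passes vacuously
    (with a warning flag in the report).
    """
    controls = set(controls)
    known = set(library.targets())
    unknown = controls - known
    if unknown:
        raise ValueError(f"unknown control target(s): {sorted(unknown)}")
    if cell_line_of is None:
        cell_line_of = {exp: exp.rsplit("_b", 1)[0] for exp in enriched}
    target_of = dict(zip(library.records["guide_id"], library.records["target_id"]))

    per_experiment: dict[str, dict[str, bool]] = {}
    cell_line_hits: dict[str, set[str]] = {}
    for exp, ids in enriched.items():
        hit_targets = {target_of[g] for g in ids}
        per_experiment[exp] = {c: c in hit_targets for c in sorted(controls)}
        cl = cell_line_of[exp]
        cell_line_hits.setdefault(cl, set()).update(hit_targets & controls)

    per_cell_line = {
        cl: {c: c in hits for c in sorted(controls)} for cl, hits in cell_line_hits.items()
    }
    overall = all(all(d.values()) for d in per_cell_line.values()) if controls else True
    return {
        "per_experiment": per_experiment,
        "per_cell_line": per_cell_line,
        "overall_pass": overall,
        "vacuous": not controls,
    }


def evaluate_hits(hit: HitResult, truth: set[str] | frozenset[str]) -> dict:
    """Precision/recall/false-positive count of the candidate genes vs simulation truth."""
    if not truth:
        raise ValueError("truth set must be non-empty")
    called = set(hit.candidate_genes) | set(hit.candidate_mirnas)
    tp = len(called & set(truth))
    fp = len(called - set(truth))
    precision = tp / len(called) if called else None
    recall = tp / len(truth)
    return {
        "precision": precision,
        "recall": recall,
        "false_positives": fp,
        "n_called": len(called),
        "n_truth": len(truth),
    }


def expected_null_candidates(
    library: GuideLibrary,
    params: FilterParams,
    n_experiments: int,
    n_permutations: int = 200,
    seed: int = 0,
) -> dict:
    """Monte-Carlo expected candidate count under a label-free null.

    Each permutation draws ``params.target_count`` enriched guides uniformly
    without replacement per experiment and applies the candidate filter;
    reports the mean candidate count and its Monte-Carlo standard error.
    """
    rng = np.random.default_rng(seed)
    guide_ids = library.guide_ids
    n = len(guide_ids)
    if params.target_count > n:
        raise ValueError("target_count exceeds library size")
    counts = []
    for _ in range(n_permutations):
        enriched = {
            f"perm_e{j + 1}": pd.Index(
                guide_ids[rng.choice(n, size=params.target_count, replace=False)]
            )
            for j in range(n_experiments)
        }
        res = call_candidates(enriched, library, params)
        counts.append(len(res.candidate_genes) + len(res.candidate_mirnas))
    counts_arr = np.asarray(counts, dtype=float)
    return {
        "mean": float(counts_arr.mean()),
        "mc_se": float(counts_arr.std(ddof=1) / np.sqrt(len(counts_arr)))
        if len(counts_arr) > 1
        else float("nan"),
        "n_permutations": n_permutations,
    }
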