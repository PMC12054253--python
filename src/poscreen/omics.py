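"""Synthetic proteomics matrices and qPCR Ct tables with known ground truth.

These generators produce the inputs consumed by the downstream statistics:
log2-intensity matrices with intensity-dependent (missing-not-at-random)
missingness, as is characteristic of data-independent-acquisition
proteomics, and Ct tables consistent with the ΔΔCt relative-quantification
model (one PCR cycle = a two-fold expression change).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd


@dataclasses.dataclass
class OmicsMatrix:
    """features x samples log2 intensities with explicit missingness.

    ``values`` uses NaN for missing cells.  ``groups`` maps sample_id to one
    of two group labels.  ``truth`` (optional) is the per-feature true log2
    fold change (group1 - group2).
    """

    values: pd.DataFrame
    groups: pd.Series
    truth: pd.Series | None = None

    def __post_init__(self) -> None:
        obs = self.values.to_numpy()
        if not np.isfinite(obs[~np.isnan(obs)]).all():
            raise ValueError("non-missing values must be finite")
        labels = self.groups.unique()
        if len(labels) != 2:
            raise ValueError(f"exactly two groups required, got {list(labels)}")
        for lab in labels:
            if (self.groups == lab).sum() < 2:
                raise ValueError(f"group {lab!r} has fewer than 2 samples")
        if set(self.groups.index) != set(self.values.columns):
            raise ValueError("group labels must cover exactly the sample columns")

    @property
    def group_labels(self) -> tuple[str, str]:
        # first label by column order = "group1" in fold-change orientation
        seen: list[str] = []
        for s in self.values.columns:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return tuple(seen)  # type: ignore[return-value]


@dataclasses.dataclass
class CtTable:
    """Long-format qPCR Ct measurements.

    ``data`` columns: sample_id, condition, gene, ct.  ``reference_genes``
    are the normalizer(s) (e.g. GAPDH, or GAPDH and HMBS); ``calibrator`` is
    the condition everything is expressed relative to.
    """

    data: pd.DataFrame
    reference_genes: tuple[str, ...]
    calibrator: str
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        required = {"sample_id", "condition", "gene", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing columns: {sorted(missing)}")
        ct = self.data["ct"]
        if not np.isfinite(ct).all() or (ct <= 0).any():
            raise ValueError("Ct values must be finite and positive")
        if not self.reference_genes:
            raise ValueError("at least one reference gene required")
        genes_by_sample = self.data.groupby("sample_id")["gene"].apply(set)
        for ref in self.reference_genes:
            lacking = genes_by_sample.index[~genes_by_sample.map(lambda s: ref in s)]
            if len(lacking):
                raise ValueError(f"sample {lacking[0]!r} lacks reference gene {ref!r}")
        if self.calibrator not in set(self.data["condition"]):
            raise ValueError(f"calibrator condition {self.calibrator!r} absent from table")


@dataclasses.dataclass(frozen=True)
class EffectSpec:
    """Which features carry a true effect and how large it is (log2 scale)."""

    n_affected: int = 0
    log2_fc: float = 0.0

    def __post_init__(self) -> None:
        if self.n_affected < 0:
            raise ValueError("n_affected must be non-negative")


@dataclasses.dataclass(frozen=True)
class MissingSpec:
    """Intensity-dependent missingness.

    A cell with log2 intensity x is missing with probability
    ``max_rate / (1 + exp((x - t) / scale))`` where t is the
    ``threshold_quantile`` of all simulated intensities — low-abundance
    values are preferentially missing (MNAR), as in real proteomes.
    """

    max_rate: float = 0.0
    threshold_quantile: float = 0.15
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_rate <= 1.0:
            raise ValueError("max_rate must lie in [0, 1]")
        if not 0.0 < self.threshold_quantile < 1.0:
            raise ValueError("threshold_quantile must lie in (0, 1)")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


def generate_proteomics(
    n_features: int,
    n_per_group: int,
    effect_spec: EffectSpec = EffectSpec(),
    missing_spec: MissingSpec = MissingSpec(),
    seed: int = 0,
    baseline_mean: float = 25.0,
    baseline_sd: float = 2.0,
    noise_sd: float = 0.4,
) -> OmicsMatrix:
    """Simulate a two-group log2-intensity proteomics matrix.

    Per-feature baselines are Normal(baseline_mean, baseline_sd); replicate
    noise is Normal(0, noise_sd).  The first ``effect_spec.n_affected``
    features get the true log2 fold change (added to group "treated");
    missingness follows ``missing_spec``.  Truth is recorded per feature.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if effect_spec.n_affected > n_features:
        raise ValueError("more affected features than features")
    rng = np.random.default_rng(seed)
    features = [f"P{i + 1:05d}" for i in range(n_features)]
    samples = [f"treated_{i + 1}" for i in range(n_per_group)] + [
        f"control_{i + 1}" for i in range(n_per_group)
    ]
    groups = pd.Series(
        ["treated"] * n_per_group + ["control"] * n_per_group, index=samples, name="group"
    )

    baseline = rng.normal(baseline_mean, baseline_sd, size=n_features)
    truth = np.zeros(n_features)
    truth[: effect_spec.n_affected] = effect_spec.log2_fc
    mean_mat = baseline[:, None] + np.where(
        (groups == "treated").to_numpy()[None, :], truth[:, None], 0.0
    )
    values = mean_mat + rng.normal(0.0, noise_sd, size=mean_mat.shape)

    if missing_spec.max_rate > 0:
        t = np.quantile(values, missing_spec.threshold_quantile)
        p_missing = missing_spec.max_rate / (1.0 + np.exp((values - t) / missing_spec.scale))
        values = np.where(rng.random(values.shape) < p_missing, np.nan, values)

    df = pd.DataFrame(values, index=features, columns=samples)
    return OmicsMatrix(values=df, groups=groups, truth=pd.Series(truth, index=features))


@dataclasses.dataclass(frozen=True)
class QpcrDesign:
    """Design of a synthetic qPCR experiment.

    ``true_fold_changes``: {condition: {target_gene: fold vs calibrator}}.
    Conditions not listed (including the calibrator) have fold 1.
    """

    target_genes: tuple[str, ...]
    reference_genes: tuple[str, ...]
    conditions: tuple[str, ...]
    calibrator: str
    true_fold_changes: dict
    n_replicates: int = 3
    noise_sd: float = 0.0
    base_ct_target: float = 25.0
    base_ct_reference: float = 18.0

    def __post_init__(self) -> None:
        if not self.reference_genes:
            raise ValueError("design must name at least one reference gene")
        if self.calibrator not in self.conditions:
            raise ValueError("calibrator must be one of the conditions")
        overlap = set(self.reference_genes) & set(self.target_genes)
        if overlap:
            raise ValueError(f"genes cannot be both target and reference: {sorted(overlap)}")


def generate_qpcr(design: QpcrDesign, seed: int = 0) -> CtTable:
    """Simulate a Ct table consistent with the ΔΔCt model.

    A target with true fold change f in a condition has its Ct lowered by
    log2(f) cycles relative to the calibrator; reference genes keep a
    constant Ct.  Gaussian cycle noise with sd ``design.noise_sd`` is added
    to every measurement.  Truth (the designed fold changes) is recorded.
    """
    rng = np.random.default_rng(seed)
    rows = []
    truth_rows = []
    for condition in design.conditions:
        fcs = design.true_fold_changes.get(condition, {})
        for rep in range(1, design.n_replicates + 1):
            sample_id = f"{condition}_rep{rep}"
            for ref in design.reference_genes:
                ct = design.base_ct_reference + rng.normal(0.0, design.noise_sd)
                rows.append((sample_id, condition, ref, ct))
            for gene in design.target_genes:
                f = float(fcs.get(gene, 1.0))
                if f <= 0:
                    raise ValueError(f"true fold change must be positive, got {f}")
                ct = design.base_ct_target - np.log2(f) + rng.normal(0.0, design.noise_sd)
                rows.append((sample_id, condition, gene, ct))
        for gene in design.target_genes:
            truth_rows.append((condition, gene, float(fcs.get(gene, 1.0))))

    data = pd.DataFrame(rows, columns=["sample_id", "condition", "gene", "ct"])
    truth = pd.DataFrame(truth_rows, columns=["condition", "gene", "true_fold_change"])
    return CtTable(
        data=data,
        reference_genes=tuple(design.reference_genes),
        calibrator=design.calibrator,
        truth=truth,
    )
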