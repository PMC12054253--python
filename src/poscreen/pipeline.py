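"""One-command end-to-end run: simulate → quantify → call hits → evaluate → stats.

The pipeline is driven by a validated YAML/JSON config (unknown keys are
rejected), logs every stage and every derived sub-seed to stderr and to a
JSONL run log, writes all intermediate tables under the output directory,
and emits a machine-readable RunReport with file digests and the headline
metrics (library composition, enriched-set sizes, non-targeting survival
fraction, candidate precision/recall, proteomics FDR results).  Re-running
with the same config reproduces every output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import hits as hits_mod
from . import library as lib_mod
from . import omics as omics_mod
from . import quantify as quant_mod
from . import screen as screen_mod
from . import stats as stats_mod

logger = logging.getLogger("poscreen")

#: fixed order in which per-stage sub-seeds are spawned from the master seed
SEED_CHILDREN = ("library", "truth_pick", "screen", "fastq", "proteomics", "impute", "permfdr", "qpcr")


def _child_seed(master: int, name: str) -> int:
    idx = SEED_CHILDREN.index(name)
    child = np.random.SeedSequence(master).spawn(len(SEED_CHILDREN))[idx]
    return int(child.generate_state(1)[0] % (2**31))


class LibrarySection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    profile: str = "gecko_v2_default"


class ScreenSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_cells: int = Field(default=2_000_000, gt=0)
    read_depth: int = Field(default=10_000_000, gt=0)
    moi: float = Field(default=0.3, gt=0)
    non_responder_fraction: float = Field(default=0.25, ge=0.0, le=1.0)
    kill_prob: float = Field(default=1.0, ge=0.0, le=1.0)
    ko_efficacy_alpha: float = Field(default=8.0, gt=0)
    ko_efficacy_beta: float = Field(default=2.0, gt=0)
    ko_efficacy_fixed: float | None = Field(default=None, ge=0.0, le=1.0)
    n_cell_lines: int = Field(default=2, gt=0)
    n_bio_reps: int = Field(default=2, gt=0)
    n_tech_reps: int = Field(default=2, gt=0)
    n_truth_genes: int = Field(default=10, ge=3)
    truth_genes: list[str] | None = None


class FilterSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    target_count: int = Field(default=2000, gt=0)
    min_occurrences_combined: int = Field(default=5, gt=0)
    min_datasets: int = Field(default=3, gt=0)
    variant: str = "methods"
    pseudocount: float = Field(default=0.5, gt=0)


class ProteomicsSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_features: int = Field(default=1000, gt=1)
    n_per_group: int = Field(default=4, ge=2)
    n_affected: int = Field(default=50, ge=0)
    log2_fc: float = 2.0
    missing_max_rate: float = Field(default=0.3, ge=0.0, le=1.0)


class StatsSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    impute_width: float = Field(default=0.3, gt=0)
    impute_downshift: float = 1.8
    n_randomizations: int = Field(default=250, gt=1)
    fdr: float = Field(default=0.05, gt=0, lt=1)
    volcano_fc_low: float = Field(default=0.5, gt=0)
    volcano_fc_high: float = Field(default=2.0, gt=0)
    volcano_alpha: float = Field(default=0.05, gt=0, lt=1)
    proteomics: ProteomicsSection = ProteomicsSection()


class PipelineConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    output_dir: str = "poscreen_run"
    emit_fastq: bool = False
    library: LibrarySection = LibrarySection()
    screen: ScreenSection = ScreenSection()
    filter: FilterSection = FilterSection()
    stats: StatsSection = StatsSection()

    @model_validator(mode="after")
    def _cross_checks(self) -> "PipelineConfig":
        n_experiments = self.screen.n_cell_lines * self.screen.n_bio_reps
        if self.filter.min_datasets > n_experiments:
            raise ValueError(
                f"filter.min_datasets={self.filter.min_datasets} exceeds the "
                f"{n_experiments} experiments (cell lines x bio reps)"
            )
        if self.library.profile not in lib_mod.PROFILES:
            raise ValueError(f"unknown library profile {self.library.profile!r}")
        return self


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} did not parse to a mapping")
    return PipelineConfig.model_validate(raw)


def validate_config(path: str | Path) -> list[str]:
    """Return a list of violations (empty list = config is valid)."""
    try:
        load_config(path)
    except ValidationError as exc:
        return [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        ]
    except (ValueError, OSError, yaml.YAMLError) as exc:
        return [str(exc)]
    return []


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.fh = open(path, "w")

    def event(self, stage: str, **payload) -> None:
        rec = {"stage": stage, **payload}
        self.fh.write(json.dumps(rec) + "\n")
        self.fh.flush()
        logger.info("%s: %s", stage, payload)

    def close(self) -> None:
        self.fh.close()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and return (and write) the RunReport."""
    if not logging.getLogger().handlers:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    runlog = _RunLog(out / "run_log.jsonl")
    report: dict = {"config": config.model_dump(), "stages": {}, "files": {}}
    seeds = {name: _child_seed(config.seed, name) for name in SEED_CHILDREN}
    runlog.event("seeds", **seeds)

    try:
        # ---- simulate ----------------------------------------------------
        library = lib_mod.generate_library(config.library.profile, seed=seeds["library"])
        lib_path = out / "library.tsv"
        library.to_tsv(lib_path)
        report["stages"]["library"] = {
            "n_records": len(library),
            "n_gene_targets": len(library.targets("gene")),
            "n_mirna_targets": len(library.targets("mirna")),
            "n_nontargeting": int(
                (library.records["target_class"] == "non_targeting").sum()
            ),
            "n_distinct_spacers": library.n_distinct_spacers,
        }
        runlog.event("library", **report["stages"]["library"])

        sc = config.screen
        if sc.truth_genes is not None:
            truth_genes = set(sc.truth_genes)
        else:
            gene_targets = library.targets("gene")
            rng = np.random.default_rng(seeds["truth_pick"])
            picked = rng.choice(len(gene_targets), size=sc.n_truth_genes, replace=False)
            truth_genes = set(gene_targets[sorted(picked)])
        screen_config = screen_mod.ScreenConfig(
            n_cells=sc.n_cells,
            truth_genes=frozenset(truth_genes),
            read_depth=sc.read_depth,
            moi=sc.moi,
            non_responder_fraction=sc.non_responder_fraction,
            kill_prob=sc.kill_prob,
            ko_efficacy_params=(sc.ko_efficacy_alpha, sc.ko_efficacy_beta),
            ko_efficacy_fixed=sc.ko_efficacy_fixed,
            n_cell_lines=sc.n_cell_lines,
            n_bio_reps=sc.n_bio_reps,
            n_tech_reps=sc.n_tech_reps,
            seed=seeds["screen"],
        )
        countset, truth = screen_mod.simulate_screen(library, screen_config)
        quant_mod.write_counts(countset, out / "counts.tsv", out / "samples.tsv")
        screen_mod.write_truth(truth, out / "truth.json")
        nt_fracs = {
            exp: d["nt_survival_fraction"] for exp, d in truth["populations"].items()
        }
        report["stages"]["screen"] = {
            "n_samples": len(countset.meta),
            "truth_genes": sorted(truth_genes),
            "positive_controls": truth["positive_controls"],
            "nt_survival_fraction": nt_fracs,
        }
        runlog.event("screen", n_samples=len(countset.meta), nt_survival=nt_fracs)

        # ---- quantify (FASTQ round trip on one sample, optional) ----------
        if config.emit_fastq:
            sample_id = countset.meta["sample_id"].iloc[0]
            fq_path = out / f"{sample_id}.fastq.gz"
            screen_mod.emit_fastq(
                countset.sample_counts(sample_id), library, fq_path, seed=seeds["fastq"]
            )
            counted = quant_mod.count_spacers(fq_path, library, offset=0)
            recovered = quant_mod.guide_count_series(counted, library)
            # shared spacers make per-guide counts over-complete; compare per spacer
            by_spacer = (
                countset.sample_counts(sample_id)
                .groupby(library.records.set_index("guide_id")["spacer"])
                .sum()
            )
            round_trip_ok = bool(
                all(
                    counted.spacer_counts.get(sp, 0) == c
                    for sp, c in by_spacer.items()
                )
                and counted.unassigned == 0
            )
            report["stages"]["quantify"] = {
                "sample": sample_id,
                "reads": counted.total_reads,
                "round_trip_ok": round_trip_ok,
                "recovered_total": int(recovered.sum()),
            }
            runlog.event("quantify", **report["stages"]["quantify"])

        # ---- call hits ----------------------------------------------------
        fp = config.filter
        norm = hits_mod.normalize_counts(countset, pseudocount=fp.pseudocount)
        means = hits_mod.average_replicates(norm)
        fcs = hits_mod.fold_changes(means)
        params = hits_mod.FilterParams(
            target_count=min(fp.target_count, len(library)),
            min_occurrences_combined=fp.min_occurrences_combined,
            min_datasets=fp.min_datasets,
            variant=fp.variant,
        )
        thresholds, enriched = hits_mod.enrich_all(fcs, params.target_count)
        controls = truth["positive_controls"]
        control_report = hits_mod.check_positive_controls(enriched, library, set(controls))
        result = hits_mod.call_candidates(enriched, library, params, thresholds)
        result.control_report = control_report
        for exp, ids in enriched.items():
            pd.Series(ids).to_csv(out / f"enriched_{exp}.tsv", sep="\t", index=False, header=["guide_id"])
        pd.DataFrame(
            {"target_id": result.candidate_genes + result.candidate_mirnas}
        ).to_csv(out / "candidates.tsv", sep="\t", index=False)
        metrics = hits_mod.evaluate_hits(result, set(truth_genes))
        hits_json = {
            "thresholds": thresholds,
            "enriched_set_sizes": {e: len(ids) for e, ids in enriched.items()},
            "candidate_genes": result.candidate_genes,
            "candidate_mirnas": result.candidate_mirnas,
            "positive_controls": control_report,
            "evaluation": metrics,
            "variant": params.variant,
        }
        with open(out / "hits.json", "w") as fh:
            json.dump(hits_json, fh, indent=1)
        report["stages"]["hits"] = {
            "enriched_set_sizes": hits_json["enriched_set_sizes"],
            "thresholds": thresholds,
            "n_candidate_genes": len(result.candidate_genes),
            "n_candidate_mirnas": len(result.candidate_mirnas),
            "controls_pass": control_report["overall_pass"],
            "evaluation": metrics,
        }
        runlog.event("hits", **report["stages"]["hits"])

        # ---- downstream stats ---------------------------------------------
        st = config.stats
        pr = st.proteomics
        matrix = omics_mod.generate_proteomics(
            n_features=pr.n_features,
            n_per_group=pr.n_per_group,
            effect_spec=omics_mod.EffectSpec(n_affected=pr.n_affected, log2_fc=pr.log2_fc),
            missing_spec=omics_mod.MissingSpec(max_rate=pr.missing_max_rate),
            seed=seeds["proteomics"],
        )
        imputed = stats_mod.impute_missing(
            matrix, width=st.impute_width, downshift=st.impute_downshift, seed=seeds["impute"]
        )
        test = stats_mod.two_sample_test(imputed, variant="student")
        perm = stats_mod.permutation_fdr(
            imputed, n_randomizations=st.n_randomizations, fdr=st.fdr, seed=seeds["permfdr"]
        )
        volcano = stats_mod.volcano_filter(
            test, fc_low=st.volcano_fc_low, fc_high=st.volcano_fc_high, alpha=st.volcano_alpha
        )
        truth_set = set(matrix.truth.index[matrix.truth != 0])
        perm_hits = set(perm.index[perm["significant"]])
        recovered = len(perm_hits & truth_set) / len(truth_set) if truth_set else None
        test.table.to_csv(out / "proteomics_stats.tsv", sep="\t")
        perm.to_csv(out / "proteomics_perm_fdr.tsv", sep="\t")
        report["stages"]["stats"] = {
            "n_significant_perm": int(perm["significant"].sum()),
            "n_volcano": int(len(volcano)),
            "affected_recovered_fraction": recovered,
        }

        design = omics_mod.QpcrDesign(
            target_genes=("IFIT1",),
            reference_genes=("GAPDH",),
            conditions=("mock", "stimulated"),
            calibrator="mock",
            true_fold_changes={"stimulated": {"IFIT1": 8.0}},
            noise_sd=0.1,
        )
        ct = omics_mod.generate_qpcr(design, seed=seeds["qpcr"])
        folds = stats_mod.ddct_fold_change(ct)
        report["stages"]["qpcr"] = {
            "fold_change": {c: dict(row) for c, row in folds.iterrows()},
            "true_fold_change": {"stimulated": {"IFIT1": 8.0}},
        }
        runlog.event("stats", **report["stages"]["stats"])
    except Exception as exc:
        runlog.event("error", message=str(exc))
        runlog.close()
        raise

    for p in sorted(out.iterdir()):
        if p.is_file() and p.name not in ("run_report.json", "run_log.jsonl", "MANIFEST"):
            report["files"][p.name] = _digest(p)
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    with open(out / "MANIFEST", "w") as fh:
        for name, dig in sorted(report["files"].items()):
            fh.write(f"{dig}  {name}\n")
    runlog.event("done", n_files=len(report["files"]))
    runlog.close()
    return report
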