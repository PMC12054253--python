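"""Positive-selection ("death reporter") screen simulator.

The generative model mirrors how such a screen works: cells stably carrying a
suicide-gene reporter driven by an interferon-stimulated promoter are
transduced with a pooled knockout library at low MOI, so each cell carries a
single guide.  With a per-guide probability (the knockout efficacy, drawn
from a Beta law) the cell is a true knockout for the guide's target.  On
stimulation of the pathway (poly(I:C)), a cell survives if

* its target is a pathway gene whose knockout rescues it (a "truth" gene and
  the cell is a knockout), or
* it is a non-responder — a genotype-independent fraction ``q`` of cells that
  survive stimulation regardless of guide (the dominant source of
  false-positive enrichment in the real screen, observed at ~25%), or
* stimulation simply fails to kill it (``kill_prob`` < 1).

Mock-treated (PBS) samples remove no cells; the complexity sample is drawn
from the population before stimulation.  Every sequenced sample is a
multinomial draw of ``read_depth`` reads over the guide proportions of the
relevant cell population.  Technical replicates are independent multinomial
re-draws from one population; biological replicates (and cell lines) are
independent end-to-end simulations.  All randomness flows from a single
master seed through ``numpy.random.SeedSequence`` spawning, in a fixed
documented order (efficacy draw, then one stream per cell-line x bio-rep
population, then one per sequenced sample).
"""

from __future__ import annotations

import dataclasses
import gzip
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .library import GuideLibrary

CONDITIONS = ("complexity", "PBS", "polyIC")

#: constant vector context flanking the spacer in a sequencing read
#: (upstream U6/vector tail, downstream tracrRNA scaffold head)
VECTOR_PREFIX = "TTGTGGAAAGGACGAAACACCG"
VECTOR_SUFFIX = "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAAC"


@dataclasses.dataclass
class ScreenConfig:
    """Parameters of one simulated screen.

    ``non_responder_fraction`` may be a single value or a per-cell-line
    mapping; ``ko_efficacy_params`` are the (alpha, beta) of the Beta law for
    per-guide knockout probability.  ``truth_genes`` are the targets whose
    knockout confers survival and must contain the three positive-control
    labels (the screen calibration checks them, like TLR3/TRIF/UNC93B1 in a
    TLR3 screen).
    """

    n_cells: int
    truth_genes: frozenset[str] | set[str]
    read_depth: int = 10_000_000
    moi: float = 0.3
    non_responder_fraction: float | dict[str, float] = 0.25
    kill_prob: float = 1.0
    ko_efficacy_params: tuple[float, float] = (8.0, 2.0)
    ko_efficacy_fixed: float | None = None
    positive_controls: tuple[str, ...] | None = None
    n_cell_lines: int = 2
    n_bio_reps: int = 2
    n_tech_reps: int = 2
    seed: int = 0

    def q_for(self, cell_line: str) -> float:
        q = self.non_responder_fraction
        if isinstance(q, dict):
            return q[cell_line]
        return q

    def validate(self, library: GuideLibrary) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if self.read_depth <= 0:
            raise ValueError("read_depth must be positive")
        if self.moi <= 0:
            raise ValueError("moi must be positive")
        qs = (
            list(self.non_responder_fraction.values())
            if isinstance(self.non_responder_fraction, dict)
            else [self.non_responder_fraction]
        )
        for q in qs + [self.kill_prob]:
            if not 0.0 <= q <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        a, b = self.ko_efficacy_params
        if a <= 0 or b <= 0:
            raise ValueError("ko_efficacy_params must be positive Beta parameters")
        if self.ko_efficacy_fixed is not None and not 0.0 <= self.ko_efficacy_fixed <= 1.0:
            raise ValueError("ko_efficacy_fixed must lie in [0, 1]")
        for field in ("n_cell_lines", "n_bio_reps", "n_tech_reps"):
            if getattr(self, field) <= 0:
                raise ValueError(f"{field} must be positive")
        targets = set(library.targets())
        unknown = set(self.truth_genes) - targets
        if unknown:
            raise ValueError(f"truth_genes not in library: {sorted(unknown)[:5]}")
        if not self.truth_genes and self.kill_prob == 1.0 and min(qs, default=0) == 0.0:
            raise ValueError(
                "no cell can survive stimulation: empty truth set with q=0 and kill_prob=1"
            )
        controls = self.resolved_controls()
        if controls and not set(controls) <= set(self.truth_genes):
            raise ValueError("positive_controls must be a subset of truth_genes")

    def resolved_controls(self) -> tuple[str, ...]:
        """The three designated positive-control targets (defaults to the
        first three truth genes in sorted order)."""
        if self.positive_controls is not None:
            return tuple(self.positive_controls)
        return tuple(sorted(self.truth_genes)[:3])


class ScreenCountSet:
    """Integer read-count tables for every sequenced sample of a screen.

    ``counts``: guides x samples DataFrame (index guide_id); ``meta``: one
    row per sample with cell_line, bio_rep, tech_rep and condition.
    """

    def __init__(self, counts: pd.DataFrame, meta: pd.DataFrame, library: GuideLibrary):
        self.counts = counts
        self.meta = meta.reset_index(drop=True)
        self.library = library
        self._validate()

    def _validate(self) -> None:
        if self.meta["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in metadata")
        missing = set(self.counts.columns) - set(self.meta["sample_id"])
        if missing:
            raise ValueError(f"count columns without metadata: {sorted(missing)}")
        unknown = self.counts.index.difference(self.library.guide_ids)
        if len(unknown):
            raise ValueError(f"count rows not in library: {list(unknown[:5])}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        bad = ~self.meta["condition"].isin(CONDITIONS)
        if bad.any():
            raise ValueError(f"unknown condition {self.meta.loc[bad, 'condition'].iloc[0]!r}")

    def sample_counts(self, sample_id: str) -> pd.Series:
        return self.counts[sample_id]


def _population(
    library: GuideLibrary,
    config: ScreenConfig,
    efficacy: np.ndarray,
    cell_line: str,
    rng: np.random.Generator,
) -> dict:
    """Simulate one transduced cell population and its fate on stimulation."""
    n_guides = len(library)
    guides = rng.integers(0, n_guides, size=config.n_cells)

    target_ids = library.records["target_id"].to_numpy()
    truth_mask_per_guide = np.isin(target_ids, list(config.truth_genes))
    nt_mask_per_guide = (library.records["target_class"] == "non_targeting").to_numpy()

    ko = rng.random(config.n_cells) < efficacy[guides]
    rescued = ko & truth_mask_per_guide[guides]
    q = config.q_for(cell_line)
    non_responder = rng.random(config.n_cells) < q
    killed = ~rescued & ~non_responder & (rng.random(config.n_cells) < config.kill_prob)
    surviving = ~killed

    initial_counts = np.bincount(guides, minlength=n_guides)
    surviving_counts = np.bincount(guides[surviving], minlength=n_guides)

    nt_cells = nt_mask_per_guide[guides]
    truth_cells = truth_mask_per_guide[guides]
    return {
        "initial": initial_counts,
        "surviving": surviving_counts,
        "n_nt_initial": int(nt_cells.sum()),
        "n_nt_surviving": int((nt_cells & surviving).sum()),
        "n_truth_initial": int(truth_cells.sum()),
        "n_truth_surviving": int((truth_cells & surviving).sum()),
        "n_surviving": int(surviving.sum()),
    }


def _sequence(counts: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    total = counts.sum()
    if total == 0:
        raise ValueError("no surviving cells to sequence")
    return rng.multinomial(depth, counts / total)


def simulate_screen(
    library: GuideLibrary, config: ScreenConfig
) -> tuple[ScreenCountSet, dict]:
    """Simulate a full screen: count tables for every sample plus ground truth.

    Returns ``(countset, truth)`` where ``truth`` records the truth genes,
    positive controls, per-guide knockout efficacy, the non-responder
    fraction(s), the seed, and per-population survival diagnostics
    (including the realized survival fraction of non-targeting-guide cells,
    the simulated analogue of the screen's genotype-independent surviving
    background).
    """
    config.validate(library)
    n_guides = len(library)
    pops = [
        (f"CL{cl + 1}", br + 1)
        for cl in range(config.n_cell_lines)
        for br in range(config.n_bio_reps)
    ]
    n_seq_per_pop = 1 + 2 * config.n_tech_reps  # complexity + PBS/polyIC tech reps
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(1 + len(pops) * (1 + n_seq_per_pop))
    it = iter(children)

    a, b = config.ko_efficacy_params
    eff_rng = np.random.default_rng(next(it))
    if config.ko_efficacy_fixed is not None:
        efficacy = np.full(n_guides, config.ko_efficacy_fixed)
    else:
        efficacy = eff_rng.beta(a, b, size=n_guides)

    sample_rows = []
    count_cols: dict[str, np.ndarray] = {}
    diagnostics = {}
    for cell_line, bio_rep in pops:
        pop = _population(library, config, efficacy, cell_line, np.random.default_rng(next(it)))
        exp = f"{cell_line}_b{bio_rep}"
        diagnostics[exp] = {
            "n_cells": config.n_cells,
            "n_surviving": pop["n_surviving"],
            "n_nt_initial": pop["n_nt_initial"],
            "n_nt_surviving": pop["n_nt_surviving"],
            "nt_survival_fraction": (
                pop["n_nt_surviving"] / pop["n_nt_initial"] if pop["n_nt_initial"] else None
            ),
            "n_truth_initial": pop["n_truth_initial"],
            "n_truth_surviving": pop["n_truth_surviving"],
            "truth_survival_fraction": (
                pop["n_truth_surviving"] / pop["n_truth_initial"]
                if pop["n_truth_initial"]
                else None
            ),
        }

        sid = f"{exp}_complexity"
        count_cols[sid] = _sequence(pop["initial"], config.read_depth, np.random.default_rng(next(it)))
        sample_rows.append((sid, cell_line, bio_rep, 1, "complexity"))
        for tech in range(1, config.n_tech_reps + 1):
            sid = f"{exp}_PBS_t{tech}"
            count_cols[sid] = _sequence(
                pop["initial"], config.read_depth, np.random.default_rng(next(it))
            )
            sample_rows.append((sid, cell_line, bio_rep, tech, "PBS"))
        for tech in range(1, config.n_tech_reps + 1):
            sid = f"{exp}_polyIC_t{tech}"
            count_cols[sid] = _sequence(
                pop["surviving"], config.read_depth, np.random.default_rng(next(it))
            )
            sample_rows.append((sid, cell_line, bio_rep, tech, "polyIC"))

    counts = pd.DataFrame(count_cols, index=library.guide_ids)
    counts.index.name = "guide_id"
    meta = pd.DataFrame(
        sample_rows, columns=["sample_id", "cell_line", "bio_rep", "tech_rep", "condition"]
    )
    truth = {
        "truth_genes": sorted(config.truth_genes),
        "positive_controls": list(config.resolved_controls()),
        "ko_efficacy": dict(zip(library.guide_ids, efficacy.tolist())),
        "non_responder_fraction": config.non_responder_fraction,
        "kill_prob": config.kill_prob,
        "seed": config.seed,
        "populations": diagnostics,
    }
    return ScreenCountSet(counts, meta, library), truth


def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)


def emit_fastq(
    counts: pd.Series,
    library: GuideLibrary,
    path: str | Path,
    read_length: int = 50,
    offset: int = 0,
    seed: int = 0,
) -> Path:
    """Write one sample's counts as a gzipped single-end FASTQ file.

    One read per counted occurrence; each read carries the guide's 20-nt
    spacer at position ``offset``, padded left and right with constant vector
    context out to ``read_length``.  Read order is shuffled deterministically
    by ``seed`` and the gzip stream is written with a zeroed mtime, so the
    output is byte-identical across runs.
    """
    if read_length < offset + 20:
        raise ValueError("read_length must accommodate offset + 20 nt spacer")
    if offset > len(VECTOR_PREFIX):
        raise ValueError(f"offset may be at most {len(VECTOR_PREFIX)}")
    spacer_by_guide = dict(zip(library.records["guide_id"], library.records["spacer"]))
    missing = [g for g, c in counts.items() if c > 0 and g not in spacer_by_guide]
    if missing:
        raise ValueError(f"counts for guides without a spacer: {missing[:5]}")

    prefix = VECTOR_PREFIX[len(VECTOR_PREFIX) - offset :] if offset else ""
    reads: list[str] = []
    for guide_id, c in counts.items():
        if c <= 0:
            continue
        seq = prefix + spacer_by_guide[guide_id]
        while len(seq) < read_length:
            seq += VECTOR_SUFFIX
        seq = seq[:read_length]
        reads.extend([seq] * int(c))

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(reads))
    qual = "I" * read_length
    path = Path(path)
    # write via fileobj so neither mtime nor filename lands in the gzip header
    with open(path, "wb") as fh, gzip.GzipFile(filename="", fileobj=fh, mode="wb", mtime=0) as raw:
        out = []
        for i, idx in enumerate(order):
            out.append(f"@read{i + 1}\n{reads[idx]}\n+\n{qual}\n")
        raw.write("".join(out).encode())
    return path
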