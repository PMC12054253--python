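"""sgRNA library model and generator.

A pooled knockout library is a collection of guide records, each carrying a
20-nt spacer sequence that targets a gene, a miRNA, or nothing (non-targeting
control).  The default profile mirrors the composition of the GeCKOv2.0
human genome-wide library: 19,050 genes with six guides each, 1,864 miRNAs
with four guides each, and 1,000 non-targeting guides — 122,756 guide
records carrying 122,411 distinct spacers.  The shortfall of 345 spacers is
reproduced deliberately: real genome-wide libraries contain a small number
of spacers annotated to two different targets, and the counting and
aggregation code must handle that ambiguity, so the generator designates 345
spacers as shared by exactly two records with different targets.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

#: reserved target label carried by every non-targeting control guide
NON_TARGETING_LABEL = "non_targeting_control"

TARGET_CLASSES = ("gene", "mirna", "non_targeting")

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclasses.dataclass(frozen=True)
class GuideRecord:
    """One sgRNA: identifier, 20-nt spacer, and its annotated target."""

    guide_id: str
    spacer: str
    target_id: str
    target_class: str

    def __post_init__(self) -> None:
        if len(self.spacer) != 20 or set(self.spacer) - set("ACGT"):
            raise ValueError(f"spacer must be a 20-mer over ACGT: {self.spacer!r}")
        if self.target_class not in TARGET_CLASSES:
            raise ValueError(f"unknown target_class {self.target_class!r}")
        if self.target_class == "non_targeting" and self.target_id != NON_TARGETING_LABEL:
            raise ValueError("non-targeting guides must carry the reserved control label")


@dataclasses.dataclass(frozen=True)
class LibraryProfile:
    """Composition of a library: how many targets of each class, guides per target."""

    name: str
    n_genes: int
    guides_per_gene: int = 6
    n_mirnas: int = 0
    guides_per_mirna: int = 4
    n_nontargeting: int = 0
    n_shared_spacers: int = 0

    def __post_init__(self) -> None:
        for field in ("n_genes", "guides_per_gene"):
            if getattr(self, field) <= 0:
                raise ValueError(f"{field} must be positive, got {getattr(self, field)}")
        for field in ("n_mirnas", "guides_per_mirna", "n_nontargeting", "n_shared_spacers"):
            if getattr(self, field) < 0:
                raise ValueError(f"{field} must be non-negative, got {getattr(self, field)}")
        if self.n_shared_spacers * 2 > self.n_records:
            raise ValueError("n_shared_spacers exceeds what the record count allows")

    @property
    def n_records(self) -> int:
        return (
            self.n_genes * self.guides_per_gene
            + self.n_mirnas * self.guides_per_mirna
            + self.n_nontargeting
        )

    @property
    def n_distinct_spacers(self) -> int:
        return self.n_records - self.n_shared_spacers


#: named profiles selectable by string
PROFILES: dict[str, LibraryProfile] = {
    "gecko_v2_default": LibraryProfile(
        name="gecko_v2_default",
        n_genes=19_050,
        guides_per_gene=6,
        n_mirnas=1_864,
        guides_per_mirna=4,
        n_nontargeting=1_000,
        n_shared_spacers=345,
    ),
    # scaled-down profile for fast simulation and testing
    "mini": LibraryProfile(
        name="mini",
        n_genes=500,
        guides_per_gene=6,
        n_mirnas=50,
        guides_per_mirna=4,
        n_nontargeting=200,
        n_shared_spacers=5,
    ),
}


class GuideLibrary:
    """An ordered sgRNA library backed by a DataFrame.

    Columns: ``guide_id`` (unique), ``spacer`` (20-mer), ``target_id``,
    ``target_class`` in {gene, mirna, non_targeting}.
    """

    def __init__(self, records: pd.DataFrame, profile_name: str = "custom"):
        self.records = records.reset_index(drop=True)
        self.profile_name = profile_name
        self._validate()

    def _validate(self) -> None:
        df = self.records
        required = ["guide_id", "spacer", "target_id", "target_class"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"library table missing columns: {missing}")
        if df["guide_id"].duplicated().any():
            dup = df.loc[df["guide_id"].duplicated(), "guide_id"].iloc[0]
            raise ValueError(f"duplicate guide_id {dup!r}")
        lengths = df["spacer"].str.len()
        if (lengths != 20).any():
            bad = df.loc[lengths != 20, "guide_id"].iloc[0]
            raise ValueError(f"guide {bad!r} spacer is not 20 nt")
        bad_class = ~df["target_class"].isin(TARGET_CLASSES)
        if bad_class.any():
            raise ValueError(
                f"unknown target_class {df.loc[bad_class, 'target_class'].iloc[0]!r}"
            )
        nt = df["target_class"] == "non_targeting"
        if (df.loc[nt, "target_id"] != NON_TARGETING_LABEL).any():
            raise ValueError("non-targeting guides must use the reserved control label")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def guide_ids(self) -> pd.Index:
        return pd.Index(self.records["guide_id"])

    @property
    def n_distinct_spacers(self) -> int:
        return self.records["spacer"].nunique()

    def targets(self, target_class: str | None = None) -> pd.Index:
        """Distinct target ids, optionally restricted to one class (controls excluded)."""
        df = self.records[self.records["target_class"] != "non_targeting"]
        if target_class is not None:
            df = df[df["target_class"] == target_class]
        return pd.Index(df["target_id"].unique())

    def shared_spacers(self) -> pd.Index:
        """Spacer sequences carried by more than one record (ambiguous on sequencing)."""
        counts = self.records["spacer"].value_counts()
        return pd.Index(counts.index[counts > 1])

    # ---- persistence -----------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, profile_name: str = "custom") -> "GuideLibrary":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(df, profile_name=profile_name)

    def to_fasta(self, path: str | Path) -> None:
        """Write spacers as FASTA, record id = guide_id."""
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(row.spacer), id=row.guide_id, description="")
            for row in self.records.itertuples()
        ]
        seqio_write(records, str(path), "fasta")


def _random_unique_spacers(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` distinct random 20-mers over ACGT."""
    if n > 4**20:  # pragma: no cover - absurd request
        raise ValueError("cannot draw that many distinct 20-mers")
    out: list[np.ndarray] = []
    seen = 0
    need = n
    while need > 0:
        draw = _BASES[rng.integers(0, 4, size=(int(need * 1.05) + 8, 20))]
        flat = draw.view(dtype="S20").ravel()
        out.append(flat)
        pool = pd.unique(np.concatenate(out))
        seen = len(pool)
        need = n - seen
        out = [pool]
    return out[0][:n]


def generate_library(
    profile: str | LibraryProfile = "gecko_v2_default", seed: int = 0
) -> GuideLibrary:
    """Generate a synthetic guide library with the requested composition.

    Deterministic for a fixed seed.  ``profile`` is a named profile
    (``"gecko_v2_default"``, ``"mini"``) or a :class:`LibraryProfile`.  When
    the profile requests shared spacers, that many spacers are assigned to
    exactly two records each, always annotating two *different* targets, so
    the distinct-spacer count equals ``n_records - n_shared_spacers``.
    """
    if isinstance(profile, str):
        try:
            profile = PROFILES[profile]
        except KeyError:
            raise ValueError(
                f"unknown profile {profile!r}; known: {sorted(PROFILES)}"
            ) from None
    rng = np.random.default_rng(seed)

    guide_ids: list[str] = []
    target_ids: list[str] = []
    classes: list[str] = []
    for g in range(profile.n_genes):
        tid = f"GENE{g + 1:05d}"
        for k in range(profile.guides_per_gene):
            guide_ids.append(f"{tid}_sg{k + 1}")
            target_ids.append(tid)
            classes.append("gene")
    for m in range(profile.n_mirnas):
        tid = f"MIR{m + 1:04d}"
        for k in range(profile.guides_per_mirna):
            guide_ids.append(f"{tid}_sg{k + 1}")
            target_ids.append(tid)
            classes.append("mirna")
    for k in range(profile.n_nontargeting):
        guide_ids.append(f"NT_sg{k + 1:04d}")
        target_ids.append(NON_TARGETING_LABEL)
        classes.append("non_targeting")

    n = profile.n_records
    spacers = _random_unique_spacers(n, rng).astype("U20")
    targets_arr = np.asarray(target_ids)

    if profile.n_shared_spacers:
        # pick donor/acceptor record pairs with different targets; the acceptor
        # record inherits the donor's spacer, creating a cross-target duplicate
        picked = rng.choice(n, size=2 * profile.n_shared_spacers, replace=False)
        donors, acceptors = picked[: profile.n_shared_spacers], picked[profile.n_shared_spacers :]
        clash = targets_arr[donors] == targets_arr[acceptors]
        guard = 0
        while clash.any():
            # reroll acceptors that landed on the donor's own target
            pool = np.setdiff1d(np.arange(n), picked)
            repl = rng.choice(pool, size=int(clash.sum()), replace=False)
            acceptors = acceptors.copy()
            acceptors[clash] = repl
            picked = np.concatenate([donors, acceptors])
            clash = targets_arr[donors] == targets_arr[acceptors]
            guard += 1
            if guard > 100:  # pragma: no cover
                raise RuntimeError("could not place shared spacers across targets")
        spacers[acceptors] = spacers[donors]

    df = pd.DataFrame(
        {
            "guide_id": guide_ids,
            "spacer": spacers,
            "target_id": target_ids,
            "target_class": classes,
        }
    )
    return GuideLibrary(df, profile_name=profile.name)
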