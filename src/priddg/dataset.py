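"""Mutation dataset curation for protein–RNA binding ΔΔG regression.

A dataset is a list of validated missense-mutation records plus a registry of
the protein chain sequences they refer to.  The module covers loading from
CSV/FASTA, duplicate and conflict resolution, thermodynamic-reversibility
augmentation (every wild-type→mutant record gains a mutant→wild-type partner
with negated ΔΔG), mutation-level random splitting, and the summary counts
used to characterise benchmark sets.

ΔΔG = ΔG_mutant − ΔG_wild-type, in kcal/mol; positive values mean the
mutation weakens binding.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "MutationRecord",
    "MutationDataset",
    "DatasetStats",
    "SplitSpec",
    "MutationValidationError",
    "load_dataset",
    "parse_mutation_token",
    "deduplicate_and_resolve",
    "reverse_augment",
    "random_split",
    "compute_stats",
]

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_TOKEN_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


class MutationValidationError(ValueError):
    """A mutation row failed validation; the message identifies the row."""


@dataclass(frozen=True)
class MutationRecord:
    """One missense mutation on a protein–RNA complex with its ΔΔG label.

    ``context_id`` names the sequence-registry entry the record is read
    against: the wild-type chain for forward records, the forward partner's
    mutant chain for reverse records.
    """

    complex_id: str
    chain: str
    wt_residue: str
    position: int  # 1-based within the chain sequence
    mut_residue: str
    ddg: float  # kcal/mol
    direction: str = "forward"  # "forward" | "reverse"
    source: str = ""
    context_id: str = ""

    def __post_init__(self):
        if self.wt_residue == self.mut_residue:
            raise MutationValidationError(
                f"{self.complex_id}_{self.chain} {self.token}: identity substitution"
            )
        for res in (self.wt_residue, self.mut_residue):
            if res not in AMINO_ACIDS:
                raise MutationValidationError(
                    f"{self.complex_id}_{self.chain} {self.token}: unknown residue {res!r}"
                )
        if self.position < 1:
            raise MutationValidationError(
                f"{self.complex_id}_{self.chain} {self.token}: position must be >= 1"
            )
        if self.direction not in ("forward", "reverse"):
            raise MutationValidationError(f"bad direction {self.direction!r}")
        if not self.context_id:
            object.__setattr__(self, "context_id", f"{self.complex_id}_{self.chain}")

    @property
    def token(self) -> str:
        return f"{self.wt_residue}{self.position}{self.mut_residue}"

    @property
    def key(self) -> tuple:
        return (self.complex_id, self.chain, self.wt_residue, self.position, self.mut_residue)

    @property
    def pair_key(self) -> tuple:
        """Identifies a forward/reverse pair (direction-independent)."""
        a, b = sorted((self.wt_residue, self.mut_residue))
        return (self.complex_id, self.chain, self.position, a, b)


@dataclass
class MutationDataset:
    records: list[MutationRecord] = field(default_factory=list)
    sequences: dict[str, str] = field(default_factory=dict)  # context_id -> sequence

    def __len__(self) -> int:
        return len(self.records)

    def sequence_for(self, rec: MutationRecord) -> str:
        try:
            return self.sequences[rec.context_id]
        except KeyError:
            raise MutationValidationError(
                f"no sequence registered for context {rec.context_id!r}"
            ) from None

    def validate(self) -> None:
        """Check every record against its registered context sequence."""
        for rec in self.records:
            seq = self.sequence_for(rec)
            if rec.position > len(seq):
                raise MutationValidationError(
                    f"{rec.complex_id}_{rec.chain} {rec.token}: position beyond "
                    f"sequence length {len(seq)}"
                )
            found = seq[rec.position - 1]
            if found != rec.wt_residue:
                raise MutationValidationError(
                    f"{rec.complex_id}_{rec.chain} {rec.token}: sequence has "
                    f"{found} at position {rec.position}, expected {rec.wt_residue}"
                )

    def subset(self, indices) -> "MutationDataset":
        recs = [self.records[i] for i in indices]
        ctx = {r.context_id for r in recs}
        return MutationDataset(recs, {k: v for k, v in self.sequences.items() if k in ctx})


@dataclass(frozen=True)
class DatasetStats:
    n_complexes: int
    n_mutations: int
    n_ddg_neg: int
    n_ddg_nonneg: int
    n_ddg_lt1: int
    n_ddg_ge1: int

    def to_dict(self) -> dict:
        return {
            "complex_count": self.n_complexes,
            "mutation_count": self.n_mutations,
            "ddg_lt_0": self.n_ddg_neg,
            "ddg_ge_0": self.n_ddg_nonneg,
            "ddg_lt_1": self.n_ddg_lt1,
            "ddg_ge_1": self.n_ddg_ge1,
        }


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    seed: int = 0
    pair_grouping: bool = True

    def __post_init__(self):
        if not 0.0 < self.train_fraction <= 1.0:
            raise ValueError(f"train_fraction must be in (0, 1], got {self.train_fraction}")


def parse_mutation_token(token: str) -> tuple[str, int, str]:
    m = _TOKEN_RE.match(token.strip())
    if m is None:
        raise MutationValidationError(f"malformed mutation token {token!r}")
    wt, pos, mut = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    return wt, pos, mut


def read_fasta_registry(path: str | Path) -> dict[str, str]:
    """FASTA → {record id: sequence}; ids are expected as ``complexid_chain``."""
    registry = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        registry[rec.id] = str(rec.seq).upper()
    return registry


def load_dataset(mutation_table: str | Path,
                 sequence_source: str | Path | dict[str, str]) -> MutationDataset:
    """Load and validate a forward mutation table against chain sequences.

    The table is CSV with header ``complex_id,chain,mutation,ddg[,source]``
    (``mutation`` is a ``<WT><pos><MUT>`` token, e.g. ``Q53E``) or with the
    token split into ``wt_residue,position,mut_residue`` columns.  Rows
    failing validation raise with a per-row diagnostic.
    """
    registry = (dict(sequence_source) if isinstance(sequence_source, dict)
                else read_fasta_registry(sequence_source))
    df = pd.read_csv(mutation_table, dtype={"complex_id": str, "chain": str})
    required = {"complex_id", "chain", "ddg"}
    missing = required - set(df.columns)
    if missing:
        raise MutationValidationError(f"mutation table missing columns: {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        if "mutation" in df.columns:
            wt, pos, mut = parse_mutation_token(str(row["mutation"]))
        else:
            wt = str(row["wt_residue"]).upper()
            pos = int(row["position"])
            mut = str(row["mut_residue"]).upper()
        try:
            rec = MutationRecord(
                complex_id=str(row["complex_id"]),
                chain=str(row["chain"]),
                wt_residue=wt,
                position=pos,
                mut_residue=mut,
                ddg=float(row["ddg"]),
                source=str(row.get("source", "")) if "source" in df.columns else "",
            )
        except MutationValidationError as exc:
            raise MutationValidationError(f"row {i}: {exc}") from None
        records.append(rec)
    ds = MutationDataset(records, registry)
    ds.validate()
    return ds


def deduplicate_and_resolve(records: list[MutationRecord],
                            tolerance: float = 1e-6) -> list[MutationRecord]:
    """Collapse duplicate mutations; drop mutations with conflicting ΔΔG.

    Records sharing (complex, chain, wt, position, mut) whose ΔΔG values all
    agree within ``tolerance`` kcal/mol collapse to the first occurrence.
    If any pair disagrees beyond tolerance, every copy of that mutation is
    removed and the conflict logged — a conservative policy that never
    silently picks one of several inconsistent measurements.
    """
    for rec in records:
        if rec.direction != "forward":
            raise MutationValidationError("deduplication expects forward records only")
    groups: dict[tuple, list[MutationRecord]] = {}
    order: list[tuple] = []
    for rec in records:
        if rec.key not in groups:
            groups[rec.key] = []
            order.append(rec.key)
        groups[rec.key].append(rec)
    kept = []
    for key in order:
        group = groups[key]
        ddgs = [r.ddg for r in group]
        if max(ddgs) - min(ddgs) <= tolerance:
            kept.append(group[0])
        else:
            logger.warning(
                "conflicting ddG for %s_%s %s: %s (all copies dropped)",
                key[0], key[1], f"{key[2]}{key[3]}{key[4]}", ddgs,
            )
    return kept


def reverse_augment(dataset: MutationDataset) -> MutationDataset:
    """Thermodynamic-reversibility augmentation.

    Every forward record wt→mut (ΔΔG) gains a reverse record mut→wt (−ΔΔG)
    whose context sequence is the forward record's *mutant* chain, so the
    reverse record's wild-type residue matches its own context.  Output size
    is exactly twice the input size.
    """
    from .windowing import apply_mutation

    for rec in dataset.records:
        if rec.direction != "forward":
            raise MutationValidationError(
                "input already contains reverse records; double augmentation is forbidden"
            )
    out = MutationDataset(list(dataset.records), dict(dataset.sequences))
    for rec in dataset.records:
        seq = dataset.sequence_for(rec)
        mutant_seq = apply_mutation(seq, rec.position, rec.wt_residue, rec.mut_residue)
        ctx_id = f"{rec.context_id}|{rec.token}"
        out.sequences[ctx_id] = mutant_seq
        out.records.append(
            MutationRecord(
                complex_id=rec.complex_id,
                chain=rec.chain,
                wt_residue=rec.mut_residue,
                position=rec.position,
                mut_residue=rec.wt_residue,
                ddg=-rec.ddg,
                direction="reverse",
                source=rec.source,
                context_id=ctx_id,
            )
        )
    return out


def random_split(dataset: MutationDataset,
                 spec: SplitSpec) -> tuple[MutationDataset, MutationDataset]:
    """Random mutation-level partition into train and test.

    ``|train| = floor(train_fraction · n)``, remainder to test.  With
    ``pair_grouping`` on, forward/reverse partners are assigned as a unit
    (grouping by pair, with the floor rule applied to groups) so a reverse
    record never leaks its partner's label across the partition boundary.
    """
    n = len(dataset)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    rng = np.random.default_rng(spec.seed)
    if spec.pair_grouping:
        keys: list[tuple] = []
        members: dict[tuple, list[int]] = {}
        for i, rec in enumerate(dataset.records):
            k = rec.pair_key
            if k not in members:
                members[k] = []
                keys.append(k)
            members[k].append(i)
        perm = rng.permutation(len(keys))
        n_train_groups = int(np.floor(spec.train_fraction * len(keys)))
        train_idx: list[int] = []
        test_idx: list[int] = []
        for rank, gi in enumerate(perm):
            (train_idx if rank < n_train_groups else test_idx).extend(members[keys[gi]])
    else:
        perm = rng.permutation(n)
        n_train = int(np.floor(spec.train_fraction * n))
        train_idx = sorted(perm[:n_train].tolist())
        test_idx = sorted(perm[n_train:].tolist())
    return dataset.subset(sorted(train_idx)), dataset.subset(sorted(test_idx))


def compute_stats(dataset: MutationDataset) -> DatasetStats:
    """Benchmark summary counts; ΔΔG = 0 falls in the ≥0 and <1 bins."""
    ddg = np.array([r.ddg for r in dataset.records], dtype=float)
    n = len(ddg)
    return DatasetStats(
        n_complexes=len({r.complex_id for r in dataset.records}),
        n_mutations=n,
        n_ddg_neg=int((ddg < 0).sum()) if n else 0,
        n_ddg_nonneg=int((ddg >= 0).sum()) if n else 0,
        n_ddg_lt1=int((ddg < 1).sum()) if n else 0,
        n_ddg_ge1=int((ddg >= 1).sum()) if n else 0,
    )
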