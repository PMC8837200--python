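"""Pedigrees, additive relationship matrices, and breeding-design simulation.

The additive (numerator) relationship matrix A carries the expected
proportional allele sharing implied by a pedigree; it defines the covariance
structure of the additive genetic random effect in an animal model
(``cov(a) = A * Va`` for one trait, ``A (x) G`` for several).  Construction
uses the tabular method; a Monte-Carlo gene-dropping estimator is provided as
an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

UNKNOWN = ""
#: strings accepted as "parent unknown" in pedigree files
_UNKNOWN_TOKENS = {"", "0", "NA", "NaN", "nan", "None", "<NA>"}


class PedigreeError(ValueError):
    """Structural or validation problem with a pedigree."""


@dataclass(frozen=True)
class PedigreeRecord:
    """One individual: its label, parents (may be unknown), sex and generation."""

    id: str
    sire: str = UNKNOWN
    dam: str = UNKNOWN
    sex: str = "NA"  # {"M", "F", "NA"}
    generation: int = 0

    def __post_init__(self):
        if not str(self.id).strip():
            raise PedigreeError("individual label must be non-empty")


def _clean_parent(label) -> str:
    s = "" if label is None else str(label).strip()
    return UNKNOWN if s in _UNKNOWN_TOKENS else s


@dataclass
class Pedigree:
    """Topologically ordered pedigree (every parent precedes its offspring)."""

    records: list[PedigreeRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def index(self) -> dict[str, int]:
        return {r.id: i for i, r in enumerate(self.records)}

    def founders(self) -> list[str]:
        return [r.id for r in self.records if r.sire == UNKNOWN and r.dam == UNKNOWN]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "sire": [r.sire or "NA" for r in self.records],
                "dam": [r.dam or "NA" for r in self.records],
                "sex": [r.sex for r in self.records],
                "generation": [r.generation for r in self.records],
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_pedigree_csv(path) -> Pedigree:
    """Read a pedigree from CSV with columns id, sire, dam[, sex, generation].

    ``NA``, ``0`` and empty fields all parse as "parent unknown".
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = {c.lower(): c for c in df.columns}
    for need in ("id", "sire", "dam"):
        if need not in cols:
            raise PedigreeError(f"pedigree CSV lacks required column {need!r}")
    records = []
    for _, row in df.iterrows():
        records.append(
            PedigreeRecord(
                id=str(row[cols["id"]]).strip(),
                sire=_clean_parent(row[cols["sire"]]),
                dam=_clean_parent(row[cols["dam"]]),
                sex=str(row[cols["sex"]]).strip() if "sex" in cols else "NA",
                generation=int(row[cols["generation"]]) if "generation" in cols else 0,
            )
        )
    return validate_and_sort(records)


def validate_and_sort(records: Sequence[PedigreeRecord]) -> Pedigree:
    """Validate records and return a parents-before-offspring ordered pedigree.

    Ties are broken by input order so that repeated runs are reproducible.
    Raises :class:`PedigreeError` on duplicate ids, references to missing
    parents, self-parenting, or ancestry cycles (named in the message).
    """
    ids = [r.id for r in records]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise PedigreeError(f"duplicate individual id {i!r}")
        seen.add(i)
    known = set(ids)
    for r in records:
        for parent in (r.sire, r.dam):
            if parent != UNKNOWN and parent not in known:
                raise PedigreeError(f"parent {parent!r} of {r.id!r} has no record")
        if r.id in (r.sire, r.dam):
            raise PedigreeError(f"cycle detected involving {r.id!r} (own parent)")

    # Kahn's algorithm, preserving input order among ready nodes.
    by_id = {r.id: r for r in records}
    children: dict[str, list[str]] = {i: [] for i in ids}
    indeg = {i: 0 for i in ids}
    for r in records:
        for parent in (r.sire, r.dam):
            if parent != UNKNOWN:
                children[parent].append(r.id)
                indeg[r.id] += 1
    order: list[str] = []
    ready = [i for i in ids if indeg[i] == 0]
    pos = {i: k for k, i in enumerate(ids)}
    while ready:
        ready.sort(key=pos.__getitem__)
        nxt = ready.pop(0)
        order.append(nxt)
        for ch in children[nxt]:
            indeg[ch] -= 1
            if indeg[ch] == 0:
                ready.append(ch)
    if len(order) != len(ids):
        cyclic = sorted(i for i in ids if indeg[i] > 0)
        raise PedigreeError(f"cycle detected involving id(s) {cyclic}")
    return Pedigree([by_id[i] for i in order])


@dataclass
class RelationshipMatrix:
    """Labelled additive relationship matrix."""

    individuals: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.individuals)
        if self.values.shape != (n, n):
            raise PedigreeError("relationship matrix shape does not match labels")

    def loc(self, a: str, b: str) -> float:
        idx = {lab: i for i, lab in enumerate(self.individuals)}
        return float(self.values[idx[a], idx[b]])

    def submatrix(self, labels: Iterable[str]) -> "RelationshipMatrix":
        idx = {lab: i for i, lab in enumerate(self.individuals)}
        sel = [idx[l] for l in labels]
        return RelationshipMatrix(list(labels), self.values[np.ix_(sel, sel)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.individuals, columns=self.individuals)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def read_relationship_csv(path) -> RelationshipMatrix:
    df = pd.read_csv(path, index_col=0)
    return RelationshipMatrix([str(c) for c in df.columns], df.to_numpy(dtype=float))


def additive_relationship_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Tabular-method additive relationship matrix A.

    ``A_ii = 1 + 0.5 * A(sire_i, dam_i)`` (inbreeding from parental kinship;
    zero if either parent is unknown) and for j earlier in the order
    ``A_ij = 0.5 * (A(j, sire_i) + A(j, dam_i))``.  Unknown parents are
    treated as unrelated, non-inbred founders.
    """
    n = len(ped)
    idx = ped.index()
    A = np.zeros((n, n))
    sires = np.full(n, -1)
    dams = np.full(n, -1)
    for i, r in enumerate(ped.records):
        if r.sire != UNKNOWN:
            sires[i] = idx[r.sire]
        if r.dam != UNKNOWN:
            dams[i] = idx[r.dam]
        if sires[i] >= i or dams[i] >= i:
            raise PedigreeError("pedigree is not sorted parents-first")
    for i in range(n):
        s, d = sires[i], dams[i]
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
        if i == 0:
            continue
        j = np.arange(i)
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[j, s]
        if d >= 0:
            row += 0.5 * A[j, d]
        A[:i, i] = A[i, :i] = row
    return RelationshipMatrix(ped.ids, A)


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """F_i = A_ii - 1 for each individual in pedigree order."""
    return additive_relationship_matrix(ped).values.diagonal() - 1.0


def gene_drop_relationship(ped: Pedigree, n_reps: int = 10_000, seed: int = 0) -> RelationshipMatrix:
    """Monte-Carlo estimate of A by dropping founder alleles through the pedigree.

    Every allele copy of every founder (including the unknown parents of
    non-founders) gets a unique label; each replicate transmits one allele per
    parent per offspring.  ``A_ij`` is estimated as twice the probability that
    a random allele from i is identical by descent to a random allele from j.
    Converges to the tabular matrix as ``n_reps`` grows; intended as a
    brute-force oracle for tests.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(ped)
    idx = ped.index()
    sires = np.array([idx.get(r.sire, -1) for r in ped.records])
    dams = np.array([idx.get(r.dam, -1) for r in ped.records])

    # Founder (and unknown-parent) slots get a unique allele label per slot;
    # labels are shared across replicates, which is harmless because IBD is
    # only ever compared within a replicate.
    alleles = np.zeros((n_reps, n, 2), dtype=np.int64)
    counter = 0
    for i in range(n):
        for slot, parent in enumerate((sires[i], dams[i])):
            if parent < 0:
                alleles[:, i, slot] = counter
                counter += 1
    pick = rng.integers(0, 2, size=(n_reps, n, 2))
    for i in range(n):
        for slot, parent in enumerate((sires[i], dams[i])):
            if parent >= 0:
                choice = pick[:, i, slot]
                alleles[:, i, slot] = alleles[np.arange(n_reps), parent, choice]

    A = np.zeros((n, n))
    for i in range(n):
        ai = alleles[:, i, :]
        for j in range(i, n):
            aj = alleles[:, j, :]
            # mean over the 4 allele pairings of IBD indicator
            share = (
                (ai[:, 0] == aj[:, 0]).mean() + (ai[:, 0] == aj[:, 1]).mean()
                + (ai[:, 1] == aj[:, 0]).mean() + (ai[:, 1] == aj[:, 1]).mean()
            ) / 4.0
            if i == j:
                # self-pairs: a_0==a_0 and a_1==a_1 always; kinship = (2 + 2F)/4
                A[i, i] = 2.0 * share
            else:
                A[i, j] = A[j, i] = 2.0 * share
    return RelationshipMatrix(ped.ids, A)


def simulate_pedigree(
    n_generations: int = 3,
    n_sires: int = 10,
    dams_per_sire: int = 3,
    offspring_per_dam: int = 6,
    unknown_paternity: float = 0.0,
    seed: int = 0,
) -> Pedigree:
    """Simulate a breeding design of maternal full-sib families nested in
    paternal half-sib groups, as produced by pairing each sire with several
    dams over successive rounds of breeding work (up to five generations of
    depth in the emulated study).

    Generation 0 holds unrelated founders (``n_sires`` males and
    ``n_sires * dams_per_sire`` females).  Each later generation mates every
    sire with ``dams_per_sire`` dams, each dam producing
    ``offspring_per_dam`` offspring with sexes assigned ~1:1.  Parents of
    generation g+1 are sampled from generation g avoiding full-sib matings
    where possible.  A fraction ``unknown_paternity`` of offspring have their
    sire recorded as unknown (broods conceived before the designated pairing).
    """
    if n_sires < 1 or dams_per_sire < 1 or offspring_per_dam < 1:
        raise PedigreeError("infeasible design: need >= 1 sire, dam and offspring per dam")
    if not 0.0 <= unknown_paternity <= 1.0:
        raise PedigreeError("unknown_paternity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    records: list[PedigreeRecord] = []
    males = [f"G0S{k}" for k in range(n_sires)]
    females = [f"G0D{k}" for k in range(n_sires * dams_per_sire)]
    for m in males:
        records.append(PedigreeRecord(m, sex="M", generation=0))
    for f in females:
        records.append(PedigreeRecord(f, sex="F", generation=0))
    family_of = {i: i for i in males + females}  # full-sib family label

    counter = 0
    for g in range(1, n_generations + 1):
        new_m: list[str] = []
        new_f: list[str] = []
        # assign dams to sires, avoiding same full-sib family where possible
        dams = list(females)
        rng.shuffle(dams)
        offspring_records = []
        for s_i, sire in enumerate(males[:n_sires]):
            chosen: list[str] = []
            for d in list(dams):
                if len(chosen) == dams_per_sire:
                    break
                if family_of[d] != family_of[sire] or len(dams) <= dams_per_sire:
                    chosen.append(d)
                    dams.remove(d)
            while len(chosen) < dams_per_sire and dams:
                chosen.append(dams.pop())
            for dam in chosen:
                fam = f"g{g}s{s_i}d{dam}"
                for _ in range(offspring_per_dam):
                    cid = f"G{g}I{counter}"
                    counter += 1
                    sex = "M" if rng.random() < 0.5 else "F"
                    rec_sire = UNKNOWN if rng.random() < unknown_paternity else sire
                    offspring_records.append(PedigreeRecord(cid, rec_sire, dam, sex, g))
                    family_of[cid] = fam
                    (new_m if sex == "M" else new_f).append(cid)
        records.extend(offspring_records)
        if g == n_generations:
            break
        # next round's breeders; fall back to current if a sex is missing
        rng.shuffle(new_m)
        rng.shuffle(new_f)
        males = new_m if len(new_m) >= n_sires else new_m + males
        females = new_f if len(new_f) >= n_sires * dams_per_sire else new_f + females
    return validate_and_sort(records)
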