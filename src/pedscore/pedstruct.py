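"""Pedigree structures and relationship matrices.

A pedigree is a directed acyclic parent graph over individuals grouped into
families.  From it we build the dense relationship matrices that
parameterize the trait covariance model:

* ``2Φ`` — twice the kinship matrix, the additive (polygenic) kernel.  φ_ij
  is the probability that one allele drawn at random from i and one from j
  are identical by descent (IBD).
* ``Δ7`` — the condensed identity coefficient for both-pairs IBD sharing,
  which drives dominance covariance.
* ``H`` — household sharing indicator.

Kinship is computed by the classic recursion over a topological ordering
(parents before children): founders are mutually unrelated with
φ_ii = 1/2, and for a non-founder i with parents f and m,

    φ_ii = 1/2 (1 + φ_fm),      φ_ij = 1/2 (φ_fj + φ_mj)   (j before i).

Δ7 uses the non-inbred closed form from parental kinships: for i with
parents (a, b) and j with parents (c, d),

    Δ7_ij = φ_ac φ_bd + φ_ad φ_bc,

with Δ7 = 0 whenever either member of the pair is a founder and the
diagonal set to 1 (a non-inbred individual shares both of its genes with
itself).  If an inbred individual is present (its parents have φ > 0) the
same formula is applied after emitting a warning; exact condensed identity
coefficients for inbred pedigrees are out of scope.

Matrices are dense; pedigrees of up to a few thousand individuals are the
intended scale.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pedscore._errors import ConfigurationError, CycleError, ValidationError

__all__ = [
    "Individual",
    "Pedigree",
    "RelationshipMatrix",
    "read_pedigree",
    "kinship_matrix",
    "delta7_matrix",
    "household_matrix",
]

SEX_CODES = {
    "1": "male", "m": "male", "male": "male",
    "2": "female", "f": "female", "female": "female",
}


@dataclass(frozen=True)
class Individual:
    family: str
    person: str
    father: str | None
    mother: str | None
    sex: str = "unknown"  # {male, female, unknown}; validated, not used in kernels
    household: str | None = None

    @property
    def is_founder(self) -> bool:
        return self.father is None


@dataclass
class Pedigree:
    """A validated pedigree with a stored topological ordering.

    ``individuals`` keeps the input order; ``order`` is a permutation of
    indices such that every parent precedes each of its children.
    """

    individuals: list[Individual]
    order: list[int] = field(default_factory=list)

    def __post_init__(self):
        self._validate()
        if not self.order:
            self.order = self._topological_order()

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_records(cls, records) -> "Pedigree":
        """Build from an iterable of (family, person, father, mother[, sex[, household]])."""
        inds = []
        for rec in records:
            rec = tuple(rec) + (None,) * (6 - len(rec))
            fam, per, fa, mo, sex, hh = rec[:6]
            inds.append(Individual(
                str(fam), str(per),
                None if fa in (None, "", "0") else str(fa),
                None if mo in (None, "", "0") else str(mo),
                sex if sex in ("male", "female") else SEX_CODES.get(str(sex).lower(), "unknown"),
                None if hh in (None, "") else str(hh),
            ))
        return cls(inds)

    # -- validation -----------------------------------------------------------

    def _validate(self):
        seen: set[tuple[str, str]] = set()
        by_family: dict[str, set[str]] = {}
        for ind in self.individuals:
            key = (ind.family, ind.person)
            if key in seen:
                raise ValidationError(
                    f"duplicated person id {ind.person!r} in family {ind.family!r}")
            seen.add(key)
            by_family.setdefault(ind.family, set()).add(ind.person)
        for ind in self.individuals:
            if (ind.father is None) != (ind.mother is None):
                raise ValidationError(
                    f"individual {ind.person!r} in family {ind.family!r} has exactly one "
                    "known parent; parents must be both known or both missing")
            for role, pid in (("father", ind.father), ("mother", ind.mother)):
                if pid is not None and pid not in by_family[ind.family]:
                    raise ValidationError(
                        f"{role} {pid!r} of {ind.person!r} not found in family {ind.family!r}")

    def _topological_order(self) -> list[int]:
        # Kahn's algorithm per family, stable in input order; a leftover node
        # means a cycle in the parent graph.
        index = {(ind.family, ind.person): i for i, ind in enumerate(self.individuals)}
        children: dict[int, list[int]] = {i: [] for i in range(len(self.individuals))}
        indeg = [0] * len(self.individuals)
        for i, ind in enumerate(self.individuals):
            for pid in (ind.father, ind.mother):
                if pid is not None:
                    p = index[(ind.family, pid)]
                    children[p].append(i)
                    indeg[i] += 1
        queue = deque(i for i in range(len(self.individuals)) if indeg[i] == 0)
        order: list[int] = []
        while queue:
            i = queue.popleft()
            order.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) < len(self.individuals):
            leftover = next(i for i in range(len(self.individuals)) if indeg[i] > 0)
            raise CycleError(self.individuals[leftover].person)
        return order

    # -- views ----------------------------------------------------------------

    @property
    def ids(self) -> list[str]:
        return [ind.person for ind in self.individuals]

    @property
    def n(self) -> int:
        return len(self.individuals)

    @property
    def founders(self) -> list[Individual]:
        return [ind for ind in self.individuals if ind.is_founder]

    def parent_indices(self) -> np.ndarray:
        """(n, 2) array of father/mother positional indices, -1 for founders."""
        index = {(ind.family, ind.person): i for i, ind in enumerate(self.individuals)}
        out = np.full((self.n, 2), -1, dtype=np.int64)
        for i, ind in enumerate(self.individuals):
            if not ind.is_founder:
                out[i, 0] = index[(ind.family, ind.father)]
                out[i, 1] = index[(ind.family, ind.mother)]
        return out

    def add_singletons(self, ids) -> "Pedigree":
        """Return a new pedigree with extra unrelated founders, one per id.

        Each singleton becomes the sole member (and founder) of its own
        family named after itself; this is how unrelated sample individuals
        are merged with pedigree data.
        """
        extra = [Individual(str(i), str(i), None, None) for i in ids]
        return Pedigree(self.individuals + extra)


@dataclass
class RelationshipMatrix:
    """Symmetric n×n relationship kernel over a fixed individual ordering."""

    kind: str  # {kinship, delta7, household, identity}
    values: np.ndarray
    ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("relationship matrix shape does not match ids")

    def subset(self, positions) -> "RelationshipMatrix":
        positions = np.asarray(positions, dtype=np.int64)
        return RelationshipMatrix(
            self.kind, self.values[np.ix_(positions, positions)],
            [self.ids[i] for i in positions])

    def to_text(self, path) -> None:
        """Write ids header plus the dense lower triangle, tab-delimited."""
        with open(path, "w") as fh:
            fh.write("#kind\t%s\n" % self.kind)
            fh.write("\t".join(self.ids) + "\n")
            for i in range(len(self.ids)):
                fh.write("\t".join(repr(float(v)) for v in self.values[i, : i + 1]) + "\n")

    @classmethod
    def from_text(cls, path) -> "RelationshipMatrix":
        with open(path) as fh:
            kind = fh.readline().strip().split("\t")[1]
            ids = fh.readline().rstrip("\n").split("\t")
            n = len(ids)
            vals = np.zeros((n, n))
            for i in range(n):
                row = [float(v) for v in fh.readline().split("\t")]
                vals[i, : i + 1] = row
                vals[: i + 1, i] = row
        return cls(kind, vals, ids)


def read_pedigree(path, dialect: str = "csv") -> Pedigree:
    """Read a pedigree file.

    Parameters
    ----------
    path : str or Path
    dialect : {"plink_fam", "csv"}
        ``plink_fam``: whitespace-delimited ``FID IID PAT MAT SEX PHENO``
        with ``0`` meaning a missing parent.  ``csv``: header with named
        columns ``family, person, father, mother`` and optionally ``sex``
        and ``household``; empty string means missing.
    """
    if dialect == "plink_fam":
        df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str,
                         names=["family", "person", "father", "mother", "sex", "pheno"])
        records = df[["family", "person", "father", "mother", "sex"]].itertuples(index=False)
    elif dialect == "csv":
        df = pd.read_csv(path, dtype=str).fillna("")
        required = {"family", "person", "father", "mother"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"pedigree CSV missing columns: {sorted(missing)}")
        cols = ["family", "person", "father", "mother"]
        for opt in ("sex", "household"):
            if opt in df.columns:
                cols.append(opt)
        records = df[cols].itertuples(index=False)
    else:
        raise ConfigurationError(f"unknown pedigree dialect {dialect!r}")
    return Pedigree.from_records(records)


def kinship_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Recursive kinship matrix Φ over the pedigree's individuals.

    Founders of the same or different families are mutually unrelated;
    cross-family entries are exactly 0 (Φ is block-diagonal by family once
    rows are grouped).  Complexity O(n²) time and memory.
    """
    n = ped.n
    parents = ped.parent_indices()
    phi = np.zeros((n, n))
    # Sweep in topological order: when i is processed, every j handled so far
    # is not a descendant of i, so the parental recursion for φ_ij is valid.
    done: list[int] = []
    for i in ped.order:
        f, m = parents[i]
        if f < 0:
            phi[i, i] = 0.5
        else:
            phi[i, i] = 0.5 * (1.0 + phi[f, m])
        if done and f >= 0:
            js = np.array(done)
            vals = 0.5 * (phi[f, js] + phi[m, js])
            phi[i, js] = vals
            phi[js, i] = vals
        done.append(i)
    return RelationshipMatrix("kinship", phi, ped.ids)


def _check_inbreeding(ped: Pedigree, phi: np.ndarray) -> bool:
    parents = ped.parent_indices()
    nonfounder = parents[:, 0] >= 0
    if not nonfounder.any():
        return False
    f = parents[nonfounder, 0]
    m = parents[nonfounder, 1]
    return bool((phi[f, m] > 0).any())


def delta7_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Condensed identity coefficient matrix Δ7 (both-alleles-IBD sharing).

    Uses the non-inbred closed form from parental kinships.  Warns and
    applies the same formula if inbred individuals are present.
    """
    phi = kinship_matrix(ped).values
    if _check_inbreeding(ped, phi):
        warnings.warn(
            "pedigree contains inbred individuals; Δ7 uses the non-inbred "
            "closed form, which is approximate in this case", stacklevel=2)
    parents = ped.parent_indices()
    n = ped.n
    d7 = np.zeros((n, n))
    nonf = np.where(parents[:, 0] >= 0)[0]
    if len(nonf):
        a = parents[nonf, 0]
        b = parents[nonf, 1]
        # Δ7_ij = φ_ac φ_bd + φ_ad φ_bc for non-founder pairs
        pac = phi[np.ix_(a, a)]
        pbd = phi[np.ix_(b, b)]
        pad = phi[np.ix_(a, b)]
        pbc = phi[np.ix_(b, a)]
        block = pac * pbd + pad * pbc
        d7[np.ix_(nonf, nonf)] = block
    np.fill_diagonal(d7, 1.0)
    return RelationshipMatrix("delta7", d7, ped.ids)


def household_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Household sharing indicator H: h_ij = 1 iff same household, diag 1."""
    labels = [ind.household for ind in ped.individuals]
    if any(h is None for h in labels):
        bad = next(ind.person for ind in ped.individuals if ind.household is None)
        raise ConfigurationError(
            f"household component requested but individual {bad!r} has no household label")
    arr = np.asarray(labels, dtype=object)
    h = (arr[:, None] == arr[None, :]).astype(float)
    np.fill_diagonal(h, 1.0)
    return RelationshipMatrix("household", h, ped.ids)


def identity_matrix(ped: Pedigree) -> RelationshipMatrix:
    return RelationshipMatrix("identity", np.eye(ped.n), ped.ids)
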