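"""Pedigree representation, kinship and consanguinity analysis.

A pedigree is a directed family graph: each individual points at (up to)
two parents.  Marriage loops — the hallmark of consanguineous families —
are explicitly allowed; only ancestry cycles (an individual being its own
ancestor) are rejected.  Kinship coefficients are computed exactly, as
rationals, with the classical recursion over parents:

    phi(a, b) = 1/2 * [phi(father_a, b) + phi(mother_a, b)]

with founder base cases phi(f, g) = 0 for distinct founders and
phi(x, x) = 1/2 * (1 + F_x), where the inbreeding coefficient F_x equals
the kinship of x's parents.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Iterator, Mapping

import networkx as nx

__all__ = [
    "Individual",
    "Pedigree",
    "Branch",
    "KinshipResult",
    "PedigreeError",
    "parse_ped",
    "parse_ped_cohort",
    "write_ped",
]

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"
AFFECTED = "affected"
UNAFFECTED = "unaffected"

_SEX_CODES = {"1": MALE, "2": FEMALE, "0": UNKNOWN}
_SEX_TO_CODE = {MALE: "1", FEMALE: "2", UNKNOWN: "0"}
_PHENO_CODES = {"2": AFFECTED, "1": UNAFFECTED, "0": UNKNOWN, "-9": UNKNOWN}
_PHENO_TO_CODE = {AFFECTED: "2", UNAFFECTED: "1", UNKNOWN: "0"}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees or malformed PED input."""


@dataclass
class Individual:
    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = UNKNOWN
    affection: str = UNKNOWN

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Branch:
    """A maximal nuclear family: one parent couple plus their sibship."""

    father_id: str | None
    mother_id: str | None
    offspring: tuple[str, ...]

    @property
    def members(self) -> tuple[str, ...]:
        parents = tuple(p for p in (self.father_id, self.mother_id) if p is not None)
        return parents + self.offspring


@dataclass(frozen=True)
class KinshipResult:
    pair: tuple[str, str]
    phi: Fraction
    inbreeding_f: tuple[Fraction, Fraction]


class Pedigree:
    """A validated single-family pedigree.

    Parameters
    ----------
    family_id:
        Family label (PED column 1).
    members:
        Individuals; parent references must resolve within the pedigree
        or be ``None`` (founder).
    """

    def __init__(self, family_id: str, members: Iterable[Individual]):
        self.family_id = family_id
        self.members: dict[str, Individual] = {}
        for ind in members:
            if ind.id in self.members:
                raise PedigreeError(f"duplicate individual id {ind.id!r} in family {family_id!r}")
            self.members[ind.id] = ind
        self._validate()
        self._phi_cache: dict[frozenset[str], Fraction] = {}
        self.generation_index = self._generation_index()

    # -- construction / validation -------------------------------------

    def _validate(self) -> None:
        for ind in self.members.values():
            for role, pid in (("father", ind.father_id), ("mother", ind.mother_id)):
                if pid is None:
                    continue
                parent = self.members.get(pid)
                if parent is None:
                    raise PedigreeError(
                        f"{role} {pid!r} of {ind.id!r} not present in family {self.family_id!r}"
                    )
                want = MALE if role == "father" else FEMALE
                if parent.sex not in (want, UNKNOWN):
                    raise PedigreeError(
                        f"{pid!r} is {role} of {ind.id!r} but has sex {parent.sex!r}"
                    )
        g = self.parent_graph()
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise PedigreeError(f"ancestry cycle detected: {cyc}")

    def parent_graph(self) -> nx.DiGraph:
        """Directed graph with an edge parent -> child."""
        g = nx.DiGraph()
        g.add_nodes_from(self.members)
        for ind in self.members.values():
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    g.add_edge(pid, ind.id)
        return g

    def _generation_index(self) -> dict[str, int]:
        # longest path from any founder; founders sit at 0
        order = list(nx.topological_sort(self.parent_graph()))
        gen = {i: 0 for i in order}
        for node in order:
            ind = self.members[node]
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    gen[node] = max(gen[node], gen[pid] + 1)
        return gen

    # -- basic accessors ------------------------------------------------

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self.members

    def __iter__(self) -> Iterator[Individual]:
        return iter(self.members.values())

    def __len__(self) -> int:
        return len(self.members)

    def founders(self) -> list[str]:
        return [i.id for i in self if i.is_founder]

    def affected(self) -> list[str]:
        return [i.id for i in self if i.affection == AFFECTED]

    def unaffected(self) -> list[str]:
        return [i.id for i in self if i.affection == UNAFFECTED]

    def parents_of(self, ind_id: str) -> tuple[str | None, str | None]:
        ind = self.members[ind_id]
        return ind.father_id, ind.mother_id

    def children_of(self, ind_id: str) -> list[str]:
        return [i.id for i in self if ind_id in (i.father_id, i.mother_id)]

    # -- kinship ---------------------------------------------------------

    def kinship(self, a: str, b: str) -> Fraction:
        """Exact kinship coefficient phi(a, b)."""
        for x in (a, b):
            if x not in self.members:
                raise PedigreeError(f"unknown individual {x!r}")
        return self._phi(a, b)

    def _phi(self, a: str, b: str) -> Fraction:
        key = frozenset((a, b))
        cached = self._phi_cache.get(key)
        if cached is not None:
            return cached
        if a == b:
            ind = self.members[a]
            if ind.is_founder:
                val = Fraction(1, 2)
            else:
                f = self._parental_phi(ind)
                val = Fraction(1, 2) * (1 + f)
        else:
            # recurse on the individual further from the founders; with
            # longest-path generation numbering that one can never be an
            # ancestor of the other
            if self.generation_index[a] < self.generation_index[b]:
                a, b = b, a
            ind = self.members[a]
            if ind.is_founder:
                val = Fraction(0)
            else:
                val = Fraction(0)
                for pid in (ind.father_id, ind.mother_id):
                    if pid is not None:
                        val += Fraction(1, 2) * self._phi(pid, b)
        self._phi_cache[key] = val
        return val

    def _parental_phi(self, ind: Individual) -> Fraction:
        # a missing parent is treated as an unrelated founder
        if ind.father_id is None or ind.mother_id is None:
            return Fraction(0)
        return self._phi(ind.father_id, ind.mother_id)

    def inbreeding(self, ind_id: str) -> Fraction:
        """Inbreeding coefficient F = kinship of the parents."""
        if ind_id not in self.members:
            raise PedigreeError(f"unknown individual {ind_id!r}")
        return self._parental_phi(self.members[ind_id])

    def kinship_result(self, a: str, b: str) -> KinshipResult:
        return KinshipResult(
            pair=(a, b),
            phi=self.kinship(a, b),
            inbreeding_f=(self.inbreeding(a), self.inbreeding(b)),
        )

    # -- consanguinity and branches --------------------------------------

    def unions(self) -> list[tuple[str | None, str | None]]:
        """All distinct parent couples, in stable (sorted offspring) order."""
        seen: dict[tuple[str | None, str | None], None] = {}
        for ind_id in sorted(self.members):
            ind = self.members[ind_id]
            if not ind.is_founder:
                seen.setdefault((ind.father_id, ind.mother_id), None)
        return list(seen)

    def consanguineous_unions(self) -> list[tuple[str, str, Fraction]]:
        """Mating pairs with phi > 0; third element is the offspring F."""
        out = []
        for father, mother in self.unions():
            if father is None or mother is None:
                continue
            phi = self.kinship(father, mother)
            if phi > 0:
                out.append((father, mother, phi))
        return out

    def is_consanguineous(self) -> bool:
        return bool(self.consanguineous_unions())

    def branches(self) -> list[Branch]:
        """Partition of non-founders into nuclear-family sibships."""
        groups: dict[tuple[str | None, str | None], list[str]] = {}
        for ind_id in sorted(self.members):
            ind = self.members[ind_id]
            if not ind.is_founder:
                groups.setdefault((ind.father_id, ind.mother_id), []).append(ind_id)
        return [
            Branch(father_id=f, mother_id=m, offspring=tuple(kids))
            for (f, m), kids in groups.items()
        ]

    def branch_subpedigree(self, branch: Branch) -> "Pedigree":
        """The branch as a standalone pedigree (parents become founders)."""
        members = []
        for pid in (branch.father_id, branch.mother_id):
            if pid is not None:
                src = self.members[pid]
                members.append(
                    Individual(pid, None, None, src.sex, src.affection)
                )
        for kid in branch.offspring:
            src = self.members[kid]
            members.append(
                Individual(
                    kid,
                    branch.father_id,
                    branch.mother_id,
                    src.sex,
                    src.affection,
                )
            )
        return Pedigree(self.family_id, members)


# -- PED I/O -------------------------------------------------------------


def _iter_ped_rows(stream) -> Iterator[tuple[str, Individual]]:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    for lineno, line in enumerate(stream, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) < 6:
            raise PedigreeError(f"PED line {lineno}: expected 6 columns, got {len(cols)}")
        fam, iid, fid, mid, sex, pheno = cols[:6]
        if sex not in _SEX_CODES:
            raise PedigreeError(f"PED line {lineno}: bad sex code {sex!r}")
        if pheno not in _PHENO_CODES:
            raise PedigreeError(f"PED line {lineno}: bad phenotype code {pheno!r}")
        yield fam, Individual(
            id=iid,
            father_id=None if fid == "0" else fid,
            mother_id=None if mid == "0" else mid,
            sex=_SEX_CODES[sex],
            affection=_PHENO_CODES[pheno],
        )


def parse_ped_cohort(stream) -> dict[str, Pedigree]:
    """Parse a (possibly multi-family) PED file into one Pedigree per family."""
    fams: dict[str, list[Individual]] = {}
    for fam, ind in _iter_ped_rows(stream):
        fams.setdefault(fam, []).append(ind)
    return {fam: Pedigree(fam, members) for fam, members in fams.items()}


def parse_ped(stream) -> Pedigree:
    """Parse a PED file holding exactly one family."""
    cohort = parse_ped_cohort(stream)
    if len(cohort) != 1:
        raise PedigreeError(f"expected one family, found {sorted(cohort)}")
    return next(iter(cohort.values()))


def write_ped(peds: Pedigree | Iterable[Pedigree]) -> str:
    if isinstance(peds, Pedigree):
        peds = [peds]
    lines = []
    for ped in peds:
        for ind_id in sorted(ped.members, key=lambda i: (ped.generation_index[i], i)):
            ind = ped.members[ind_id]
            lines.append(
                "\t".join(
                    [
                        ped.family_id,
                        ind.id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        _SEX_TO_CODE[ind.sex],
                        _PHENO_TO_CODE[ind.affection],
                    ]
                )
            )
    return "\n".join(lines) + "\n"
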